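"""Final-stage statistics and end-to-end study orchestration.

Pearson correlations between per-subject measures (P200, learning rate,
choice consistency, FRN; one value per prime condition) and the five PANSS
symptom factors, corrected with the Holm-Bonferroni sequential procedure.
The Holm family defaults to the 15 tests (3 conditions x 5 factors) sharing
a measurement type, mirroring how the correlation table groups its rows; the
family layout is explicit and configurable.

:func:`run_study` chains the whole pipeline on a synthetic cohort:
simulate -> behavioral metrics -> hierarchical fits -> ERP extraction ->
correlation table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior, erp as erp_mod
from .cohort import CONDITIONS, FACTORS, CohortConfig, SyntheticStudy, generate_cohort
from .errors import DataError, DomainError, UndefinedCorrelationError
from .hbayes import (
    McmcConfig,
    SubjectDataset,
    fast_mcmc_config,
    fit_hierarchical,
    paper_mcmc_config,
    posterior_summary,
)

logger = logging.getLogger(__name__)

MEASUREMENT_TYPES = ("P200", "learning_rate", "choice_consistency", "FRN")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-sided p from the t transform
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise DataError(f"need at least 3 points, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined: zero variance input")
    result = sps.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Holm's step-down sequential correction.

    Adjusted p for the k-th smallest raw p is
    ``max_{j<=k} min(1, (m - j + 1) * p_(j))``; hypotheses are rejected
    sequentially while the adjusted p stays <= alpha.  Results are returned
    in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) | np.any(p > 1)):
        raise DomainError("p values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[idx]))
        adjusted_sorted[k] = running
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist(), (adjusted <= alpha).tolist()


@dataclass(frozen=True)
class CorrelationEntry:
    measure: str
    factor: str
    n: int
    r: float
    p: float
    p_holm: float
    significant_raw: bool
    significant_holm: bool
    family: str
    available: bool = True


def correlation_table(
    measures: pd.DataFrame,
    symptoms: pd.DataFrame,
    family_spec: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Measure x factor Pearson correlations with per-family Holm correction.

    ``measures`` is subjects x measure columns (e.g. ``"FRN:angry"``),
    ``symptoms`` subjects x factor columns; they are aligned on their index.
    ``family_spec`` maps a family label to its (measure, factor) cells; the
    default groups each measure column's tests against all factors into one
    family.  Subjects with missing values are dropped pairwise, counts are
    reported per cell, and all-missing cells are flagged unavailable rather
    than dropped.
    """
    subjects = measures.index.intersection(symptoms.index)
    measures = measures.loc[subjects]
    symptoms = symptoms.loc[subjects]
    if family_spec is None:
        family_spec = {
            col: [(col, factor) for factor in symptoms.columns] for col in measures.columns
        }

    rows: list[CorrelationEntry] = []
    for family, cells in family_spec.items():
        computed = []
        for measure, factor in cells:
            x = measures[measure]
            y = symptoms[factor]
            keep = x.notna() & y.notna()
            n = int(keep.sum())
            if n < 3:
                computed.append((measure, factor, n, math.nan, math.nan, False))
                continue
            r, p = pearson_r(x[keep].to_numpy(), y[keep].to_numpy())
            computed.append((measure, factor, n, r, p, True))
        valid = [c for c in computed if c[5]]
        p_adj, rejected = (
            holm_bonferroni([c[4] for c in valid], alpha) if valid else ([], [])
        )
        adj_iter = iter(zip(p_adj, rejected))
        for measure, factor, n, r, p, ok in computed:
            if ok:
                ph, rej = next(adj_iter)
                rows.append(
                    CorrelationEntry(measure, factor, n, r, p, ph,
                                     significant_raw=p <= alpha, significant_holm=rej,
                                     family=family)
                )
            else:
                rows.append(
                    CorrelationEntry(measure, factor, n, math.nan, math.nan, math.nan,
                                     False, False, family, available=False)
                )
    return pd.DataFrame([e.__dict__ for e in rows])


# --------------------------------------------------------------------------
# per-subject measures feeding the correlation table and summary tables


def behavioral_summary(study: SyntheticStudy) -> pd.DataFrame:
    """One row per subject x condition: score, strategy rates, PANAS diffs."""
    rows = []
    for (sid, condition), records in study.trials.items():
        events = behavior.classify_strategy_events(records)
        summary = behavior.strategy_rates(events)
        diffs = study.panas_difference(sid, condition)
        truth = study.params[(sid, condition)]
        rows.append(
            {
                "subject_id": sid,
                "group": study.group_of(sid),
                "condition": condition,
                "total_score": behavior.total_score(records),
                "win_stay": summary.win_stay.value,
                "lose_shift": summary.lose_shift.value,
                "win_stay_rich": summary.win_stay_rich.value,
                "win_stay_poor": summary.win_stay_poor.value,
                "lose_shift_rich": summary.lose_shift_rich.value,
                "lose_shift_poor": summary.lose_shift_poor.value,
                "panas_positive_diff": diffs.positive_diff,
                "panas_negative_diff": diffs.negative_diff,
                "true_alpha": truth.alpha,
                "true_beta": truth.beta,
            }
        )
    return pd.DataFrame(rows)


def erp_summary(
    study: SyntheticStudy,
    subjects: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pipeline-extracted N170/P200/FRN amplitudes per subject x condition."""
    rows = []
    for sid in subjects if subjects is not None else study.subject_ids:
        for condition in conditions if conditions is not None else study.config.conditions:
            amplitudes = erp_mod.extract_component_amplitudes(study.eeg(sid, condition))
            rows.append(
                {"subject_id": sid, "group": study.group_of(sid), "condition": condition,
                 **amplitudes}
            )
    return pd.DataFrame(rows)


def fit_by_group_condition(
    study: SyntheticStudy,
    config: McmcConfig | None = None,
) -> pd.DataFrame:
    """Independent hierarchical fits per group x condition.

    Returns per-subject posterior means of alpha and beta plus the group
    hyperparameter posterior means.
    """
    rows = []
    base = config or fast_mcmc_config()
    for gi, group in enumerate(("SZ", "CTRL")):
        members = study.roster.loc[study.roster["group"] == group, "subject_id"]
        for ci, condition in enumerate(study.config.conditions):
            dataset = SubjectDataset.from_records(
                [r for sid in members for r in study.trials[(sid, condition)]]
            )
            fit_config = McmcConfig(
                n_chains=base.n_chains, n_iterations=base.n_iterations,
                burn_in=base.burn_in, thin=base.thin,
                seed=base.seed + 101 * gi + 11 * ci,
            )
            samples = fit_hierarchical(dataset, config=fit_config)
            summary = posterior_summary(samples)
            for sid in dataset.subject_ids:
                rows.append(
                    {
                        "subject_id": sid, "group": group, "condition": condition,
                        "alpha_mean": summary.loc[f"alpha[{sid}]", "mean"],
                        "beta_mean": summary.loc[f"beta[{sid}]", "mean"],
                        "mu_alpha": summary.loc["mu_alpha", "mean"],
                        "mu_beta": summary.loc["mu_beta", "mean"],
                    }
                )
    return pd.DataFrame(rows)


def _pivot_measures(
    erp_table: pd.DataFrame | None,
    fit_table: pd.DataFrame | None,
    sz_ids: Sequence[str],
) -> pd.DataFrame:
    """Wide subjects x 'measure:condition' table for the correlation stage."""
    columns: dict[str, pd.Series] = {}
    if erp_table is not None:
        sz = erp_table[erp_table["subject_id"].isin(sz_ids)]
        for condition, sub in sz.groupby("condition"):
            sub = sub.set_index("subject_id")
            columns[f"P200:{condition}"] = sub["p200"]
            columns[f"FRN:{condition}"] = sub["frn"]
    if fit_table is not None:
        sz = fit_table[fit_table["subject_id"].isin(sz_ids)]
        for condition, sub in sz.groupby("condition"):
            sub = sub.set_index("subject_id")
            columns[f"learning_rate:{condition}"] = sub["alpha_mean"]
            columns[f"choice_consistency:{condition}"] = sub["beta_mean"]
    return pd.DataFrame(columns)


def default_family_spec(
    conditions: Sequence[str] = CONDITIONS,
    factors: Sequence[str] = FACTORS,
) -> dict[str, list[tuple[str, str]]]:
    """One Holm family per measurement type: its 3 conditions x 5 factors."""
    return {
        mtype: [(f"{mtype}:{c}", f) for c in conditions for f in factors]
        for mtype in MEASUREMENT_TYPES
    }


@dataclass
class StudyReport:
    """Output bundle of :func:`run_study`."""

    behavioral: pd.DataFrame
    group_summary: pd.DataFrame
    erp: pd.DataFrame | None
    fits: pd.DataFrame | None
    correlations: pd.DataFrame | None
    manifest: dict

    def checksum(self) -> str:
        """Deterministic digest over all result tables."""
        digest = hashlib.sha256()
        for table in (self.behavioral, self.group_summary, self.erp, self.fits,
                      self.correlations):
            if table is not None:
                digest.update(table.round(10).to_csv(index=True).encode())
        return digest.hexdigest()

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.behavioral.to_csv(out / "behavioral.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        if self.erp is not None:
            self.erp.to_csv(out / "erp.csv", index=False)
        if self.fits is not None:
            self.fits.to_csv(out / "fits.csv", index=False)
        if self.correlations is not None:
            self.correlations.to_csv(out / "correlations.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def run_study(
    config: CohortConfig,
    mode: str = "fast",
    include_erp: bool = True,
    include_fit: bool = True,
    include_correlations: bool = True,
    mcmc_config: McmcConfig | None = None,
) -> StudyReport:
    """Execute the full pipeline: simulate -> metrics -> fit -> ERP -> correlate.

    ``mode`` selects the MCMC protocol: ``"paper"`` (3 x 16,000 / 6,000 /
    thin 5) or ``"fast"`` (3 x 4,000 / 1,000 / thin 2); an explicit
    ``mcmc_config`` overrides the mode.
    """
    if mode not in ("fast", "paper"):
        raise DataError(f"mode must be 'fast' or 'paper', got {mode!r}")
    timings = {}

    start = time.perf_counter()
    study = generate_cohort(config)
    timings["simulate_s"] = round(time.perf_counter() - start, 3)
    logger.info("cohort simulated in %.1fs", timings["simulate_s"])

    start = time.perf_counter()
    behavioral = behavioral_summary(study)
    timings["behavior_s"] = round(time.perf_counter() - start, 3)

    erp_table = fits = correlations = None
    if include_erp:
        start = time.perf_counter()
        erp_table = erp_summary(study)
        timings["erp_s"] = round(time.perf_counter() - start, 3)
        logger.info("ERP extraction in %.1fs", timings["erp_s"])
    if include_fit:
        start = time.perf_counter()
        mcmc = mcmc_config or (
            paper_mcmc_config(config.seed) if mode == "paper" else fast_mcmc_config(config.seed)
        )
        fits = fit_by_group_condition(study, mcmc)
        timings["fit_s"] = round(time.perf_counter() - start, 3)
        logger.info("hierarchical fits in %.1fs", timings["fit_s"])

    group_keys = ["group", "condition"]
    summary_parts = [behavioral.groupby(group_keys).mean(numeric_only=True)]
    if erp_table is not None:
        summary_parts.append(
            erp_table.groupby(group_keys)[["n170", "p200", "frn"]].mean()
        )
    if fits is not None:
        summary_parts.append(
            fits.groupby(group_keys)[["alpha_mean", "beta_mean", "mu_alpha", "mu_beta"]].mean()
        )
    group_summary = pd.concat(summary_parts, axis=1).reset_index()

    if include_correlations:
        sz_ids = [s for s in study.subject_ids if study.group_of(s) == "SZ"]
        measures = _pivot_measures(erp_table, fits, sz_ids)
        if not measures.empty:
            families = {
                fam: [cell for cell in cells if cell[0] in measures.columns]
                for fam, cells in default_family_spec(study.config.conditions).items()
            }
            families = {fam: cells for fam, cells in families.items() if cells}
            correlations = correlation_table(measures, study.symptoms, families)

    manifest = {
        "seed": config.seed,
        "mode": mode,
        "n_sz": config.n_sz,
        "n_ctrl": config.n_ctrl,
        "conditions": list(config.conditions),
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "timings": timings,
    }
    return StudyReport(
        behavioral=behavioral, group_summary=group_summary, erp=erp_table,
        fits=fits, correlations=correlations, manifest=manifest,
    )
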