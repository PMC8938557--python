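# Methods

## Task model

Each experimental session is a two-armed bandit: two card decks whose
reward probabilities sum to a configurable total (default 0.60) and stand
in a configurable rich:poor ratio.  A session comprises 480 trials divided
into six blocks of 70–90 trials.  Block lengths are drawn exactly
uniformly over all compositions of 480 into six parts within [70, 90]
(sequential sampling weighted by composition counts; plain
accept/reject over iid uniform lengths targets the same distribution but
degenerates near the edges of the feasible set, e.g. when only one
composition exists).  Each block's ratio is drawn uniformly from the ratio
set and the rich side is randomized independently; nothing prevents
consecutive blocks from sharing a rich side, since the protocol does not
constrain it.

Feedback is an independent Bernoulli draw per trial on the chosen deck;
the unchosen deck's outcome is never materialized.  "Scheduled" rewards in
the ancestor paradigm can imply baiting (outcome persistence), but
independence is the simplest reading consistent with the learning rule's
outcome variable; a `baited` config flag is reserved and off.

The default ratio set {6:1, 1:6, 3:1, 1:3} includes the two documented
extreme ratios plus two intermediate ones; the exact intermediate ratios
used in practice vary by protocol, so the set is configurable.

Training runs in cycles of 20 trials followed by a probe (identify the
rich deck) and repeats until the probe is answered correctly.

## Choice model

Deck expectations start at q0 = 0.5 (midpoint of the binary outcome
range; configurable) and only the chosen deck updates:

    Q(t) = Q(t-1) + alpha * (R(t) - Q(t-1)),        alpha in [0, 1]
    P_A(t) = sigma(beta * (Q_A - Q_B)),             beta in [0, 10]

computed as a numerically safe logistic of the value difference.
Expectations are not reset at block boundaries: players are not told where
blocks begin, so continuity is the behaviorally faithful choice.

## Hierarchical estimation

Subject parameters are modelled as draws from group normals truncated to
their supports — alpha_i ~ N(mu_a, sigma_a) on [0, 1], beta_i ~
N(mu_b, sigma_b) on [0, 10] — with uniform hyperpriors mu_a, sigma_a ~
U(0, 1), mu_b ~ U(0, 10), sigma_b ~ U(0, 5).  Truncation (rather than a
logit/log transform) keeps the sampled values directly on the scales the
likelihood needs while matching the hyperprior supports.  Each group x
condition dataset is fit independently; the point estimate is the
posterior mean (medians are also reported).

The sampler is Metropolis-within-Gibbs:

* per iteration, random-walk proposals for all subjects' alphas (then
  betas) are accepted independently per subject, since the likelihood
  factorizes over subjects; the trial likelihood is evaluated by a
  numba-compiled kernel (bit-equivalent numpy fallback, equivalence
  tested);
* the four hyperparameters get scalar random-walk updates whose full
  conditionals involve only the truncated-normal group densities;
* proposal scales adapt in batches of 50 during burn-in only (target
  acceptance roughly 0.2–0.5), so the post-burn-in chain is a fixed
  Markov kernel.

Iteration accounting is literal: retained draws per chain are iterations
`burn_in, burn_in + thin, ...`, so the default protocol (3 × 16,000,
burn-in 6,000, thin 5) retains exactly 2,000 per chain and 6,000 total.
A fast protocol (3 × 4,000, burn-in 1,000, thin 2; 4,500 draws) is the
default for tests and `run_study`.  Split R-hat (rank-normalized, via
arviz) is computed after every multi-chain fit; exceeding 1.1 raises a
warning with the offending values attached rather than failing silently —
with the small per-cell datasets of a fast-mode study run this warning is
expected and signals honest uncertainty, not an error.

Parameter recovery at 20 subjects × 480 trials (truth mu_a = 0.30,
sigma_a = 0.10, mu_b = 4.0, sigma_b = 1.0) lands the hyper-means within
±0.10 / ±1.0 and correlates per-subject posterior-mean alphas with truth
at r > 0.6; prior-only runs reproduce the uniform hyperprior means.

## ERP pipeline

All windows are half-open [start, end) at sample resolution with 0 ms the
first poststimulus sample; the baseline window is [−100, 0) ms for both
epoch types.  The band-pass is a 4th-order Butterworth applied
forward-backward (zero phase); only the band itself is protocol-pinned,
the design is a package choice.  Artifact rejection is strict
(|x| > 50 µV rejects; exactly ±50.0 is retained) and is evaluated on the
analysis channels (P7, P8, Fz, FCz, Cz, Pz) because the rejection channel
set is not specified by the protocol.  Component aggregation over a
channel set is an unweighted mean.  Feedback expectancy classes:
poor+reward = unexpected win, rich+omission = unexpected loss, the
complements expected.  The FRN is quantified on the unexpected-loss minus
unexpected-win difference wave.  Averaged-mastoid re-referencing and
blink *correction* are omitted — synthetic records are generated
reference-free, and blinks (optionally injected) are handled by the
rejection stage.

## Synthetic cohort

The generator emulates the study design: 38 SZ and 26 CTRL subjects, three
sessions each (neutral / angry / happy primes), 480 trials per session.

Generator defaults, chosen once to realize the qualitative group and
condition patterns of such studies:

* Group (α, β): CTRL neutral (0.25, 6.0), CTRL emotional (0.35, 4.5);
  SZ neutral/angry (0.45, 2.0), SZ happy (0.55, 1.5); subject SDs 0.10–0.12
  (α) and 0.8–1.0 (β).  SZ thus has a higher learning rate and lower
  choice consistency overall; CTRL shifts in both emotional conditions,
  SZ only in the happy condition.
* ERP templates (µV, defined as window means): N170 −5.01 (CTRL) vs
  −3.51 (SZ) in all conditions with P8 carrying 1.1× and P7 0.9× (right
  lateralization); P200 rises for CTRL in both emotional conditions
  (4.0 → 6.0) but for SZ only in happy (4.0 → 5.5, angry 4.2); FRN
  effect CTRL (−3.0 neutral, −4.3 emotional), SZ (−2.8, −2.0, −2.6) —
  comparable groups in neutral, attenuated SZ FRN in emotional conditions,
  overall means near −3.9 (CTRL) and −2.4 (SZ).
* PANSS five-factor scores use published patient-sample moments as
  defaults (positive 8.39 ± 3.53, negative 12.68 ± 4.03, cognitive
  6.68 ± 2.52, excitement 5.45 ± 2.37, depressive 4.95 ± 1.89), clipped at
  the theoretical minimum of one point per item.
* Planted measure × symptom correlations (SZ, angry condition) default to
  the cells a study of this design reports as significant: FRN × positive
  −0.436, FRN × cognitive −0.447, β × positive −0.334, P200 × negative
  −0.362, P200 × cognitive −0.344.

Correlations are realized through a Gaussian copula: a 9-dimensional
standard normal (4 measure latents, 5 factor latents) with identity
diagonal blocks and the planted cross-block (checked positive
semi-definite at configuration time).  Measure latents map to α/β through
the truncated-normal inverse CDF and to per-subject ERP template offsets
linearly; only the observed correlation magnitudes are specified by the
emulated design, not a generative mechanism, so the copula is the minimal
construction that hits them.

EEG is generated as epoch-aligned 2 s trial segments (prime at 200 ms,
feedback at 1000 ms within the segment) rather than a full session
timeline; epoching is exercised identically and records stay small.
Components are Gaussian bumps (N170 peak 180 ms, SD 20 ms; P200 peak
200 ms, SD 20 ms; FRN center 450 ms, SD 80 ms) scaled so the configured
amplitude equals the component's mean over its analysis window on the
sample grid — injection-recovery is therefore exact at zero noise, and the
FRN bump is added only on unexpected-loss trials so the difference wave
isolates it.  Channel noise is white Gaussian (default SD 10 µV), with
optional 1/f shaping and optional high-amplitude frontal blink transients.
Records are synthesized in single precision and regenerated lazily and
deterministically per (seed, subject, condition); a full cohort's raw EEG
is never held in memory at once.

What the generator does **not** emulate: volume-conducted topographies
from dipole sources, ocular/muscle artifact morphology beyond simple
transients, autocorrelated drift, medication effects, dropout, or
session-order effects.  Passing tests therefore demonstrate that the
pipeline is correct and well-calibrated on data whose ground truth is
known — not that real recordings meet the generator's assumptions.

## Statistics

Pearson r with two-sided p from the t transform (n − 2 df).
Holm–Bonferroni: adjusted p for the k-th smallest raw p is
max_{j≤k} min(1, (m − j + 1) p_(j)); rejection requires adjusted p ≤ α.
The implementation is by hand (the procedure is part of the package's
contract, with hand-computed examples frozen in tests) and is
cross-checked against statsmodels' `multipletests(method="holm")` on
random inputs.  The Holm family defaults to the 15 tests (3 conditions ×
5 factors) per measurement type, mirroring how such correlation tables
group rows; the family layout is explicit and configurable because the
emulated protocol does not state it.  Missing data are deleted pairwise
with per-cell counts reported.

## Numerical and scale choices

* Softmax and likelihood computations route through `log1p`/`logaddexp`
  forms; no overflow for any β in support.
* Undefined strategy rates (empty denominators) propagate as NaN and are
  excluded from group means — averaging in zeros would bias rates downward.
* Problem sizes: the test suite runs reduced protocols (fast MCMC,
  10-seed direction checks at full cohort size, 40-cohort correlation
  averages on 60-trial sessions) chosen to keep the whole suite under
  about ten minutes on one CPU while leaving every check's sampling error
  well inside its tolerance.
* Known limitations: the sampler is random-walk MH, so very small or very
  large β regions mix more slowly than a gradient-based sampler would;
  fast-mode fits on few-subject cells can trip the R-hat warning; the
  P200 display channel in some protocols (FCz) differs from its
  quantification set (Fz/Cz/Pz) — the quantification set is implemented
  and the synthesizer injects P200 on FCz as well, so either convention
  can be read out.
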