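# Methods

## Data model and preprocessing

The interchange object is a samples × metabolites peak-area matrix with
sample metadata (class label, fraction, platform, cell line, media-control
flag, treatment) and metabolite metadata (display name, pathway,
internal-standard flag). Each (platform, fraction) pair is a *stratum* and
is modelled independently throughout; nothing is ever merged across
platforms, because peak tables from different instruments do not share a
reliable metabolite namespace.

Preprocessing order is fixed and enforced by the pipeline driver:

1. **Internal-standard normalization.** Every intensity is divided by the
   sample's internal-standard intensity (the spiked reference compound,
   e.g. norvaline for amino-acid panels), cancelling per-sample injection
   and loading variation; the IS column is consumed. Applied only when an
   IS metabolite is flagged — GC panels without a designated IS pass
   through unchanged.
2. **Media subtraction** (supernatant strata only). The arithmetic mean of
   the media-only control wells is subtracted per metabolite on the
   intensity scale, and the control wells are dropped. Results may be
   negative: a cell line consuming a medium component sits below the
   blank. Negatives are kept signed by default because the downstream rank
   test uses that ordering; `clip_at_zero` exists for ratio-based uses.
3. **Centring and scaling.** Optional log transform, column centring, then
   division by the column SD (unit variance, the default for metabolomics
   OPLS-DA), by √SD (Pareto) or by 1. The learned parameters transform
   held-out samples identically and invert to 1e-10 relative error.
   Zero-variance columns are left unscaled with a warning and become
   all-zero.

Scaling ddof is 1 (sample SD). The main pipeline default is raw-intensity
unit-variance scaling with no log transform; the log option matters for
property tests (below) because the generator is log-normal.

## OPLS-DA

Classes are encoded as K−1 non-redundant 0/1 dummy columns (reference class
= lexicographically first), centred. With the scaled matrix X:

*Orthogonal extraction*, repeated `A_ortho` times: compute the predictive
weight(s) `w` of the current X by the NIPALS inner relation (for a single
response, `w = Xᵀy/‖Xᵀy‖`); form `t = Xw`, `p = Xᵀt/(tᵀt)`; project the
loading against every predictive weight,
`w_o = p − Σ_k (w_kᵀp)/(w_kᵀw_k) · w_k`, normalize; `t_o = Xw_o`,
`p_o = Xᵀt_o/(t_oᵀt_o)`; deflate `X ← X − t_o p_oᵀ`. For multi-class
models the predictive weight set of a temporary NIPALS PLS2 fit supplies
the `w_k`.

*Predictive fit* on the filtered X: `A_pred ≤ K−1` NIPALS PLS components
with X- and Y-deflation. `w*` is the unit-norm predictive weight vector(s)
on the filtered X — the variable-contribution values used for selection.

Structural guarantees (tested to 1e-8 or better): predictive and orthogonal
scores and weights are mutually orthogonal; `X = TPᵀ + T_oP_oᵀ + E` exactly;
and for two classes the fitted responses of OPLS(1, k) coincide with a
(k+1)-component PLS1 — the orthogonal split redistributes variance between
components without changing the fit.

Prediction strips orthogonal components sequentially, then computes
predictive scores with predictive deflation; class calls are
nearest-class-mean in fitted-response space, ties toward the reference
class.

NIPALS numerics: PLS inner loops stop at 1e-12 relative score change or 500
iterations. PCA (used for the overview/outlier model, with Hotelling-T²
and its 95% F-based limit) iterates to a 1e-14 floor under the same
iteration cap: the power-iteration error after stopping scales like
(score change)/(spectral gap), and the tighter floor keeps NIPALS within
1e-8 of an eigendecomposition whenever adjacent singular values are
separated by ≥ 5%. Under near-ties the per-component comparison is
ill-posed for any power method; only the spanned subspace is stable.

## Cross-validation and CV-ANOVA

Folds are stratified and deterministic: within each class (visited in
first-occurrence order, so renaming classes cannot change the partition)
samples are shuffled by the seeded RNG and dealt round-robin to folds
through a global counter; `n_folds = N` therefore degenerates exactly to
leave-one-out. Scaling is re-learned inside every training fold — the
held-out wells contribute nothing to centres or variances.

Out-of-fold predictive scores (`tcv`) and responses give
`PRESS = Σ(y − ŷ_cv)²` and `Q² = 1 − PRESS/SS_tot`. CV-ANOVA compares the
cross-validated residual to the total response variation:
`F = (max(SS_tot − PRESS, 0)/df₁)/(PRESS/df₂)` with `df₁ = A` (total fitted
components, predictive + orthogonal) and `df₂ = N − 1 − A`, upper-tail F
probability. The degrees-of-freedom bookkeeping varies across software
implementing this test; this convention is fixed here and used everywhere.
`PRESS = 0` maps to `F = ∞, p = 0`; `df₂ ≤ 0` is an error (model larger
than the data support).

The orthogonal-component count is chosen greedily (`auto`): add components
while Q² improves by more than 0.01, up to `max_ortho` (default 3), backing
off when the data run out of extractable orthogonal rank. The chosen count
is logged in the run summary.

## Variable selection

One pass: fit the full model, rank metabolites by |w*| (maximum across
predictive components when there are several), discard |w*| < τ (default
0.05), refit and re-cross-validate on the survivors. Orthogonal weights
never gate selection. Fewer than two survivors is an error rather than a
silent degenerate model. The selection is deliberately not iterated to
convergence — iterated selection on cross-validated criteria overfits the
selection itself.

## Univariate table and over-representation

Per metabolite, a two-sided Mann–Whitney U from midranks, reported as
min(U₁, U₂): exact null enumeration when n₁+n₂ ≤ 20 with no ties, otherwise
the normal approximation with midrank tie correction and 0.5 continuity
correction (completely symmetric input yields p = 1 by construction).
Direction (up/down/flat) follows the sign of the median difference —
consistent with the rank test — while the fold change uses class means on
the unscaled, media-subtracted intensities (undefined and flagged when the
negative-class mean is ≤ 0). Raw p-values are the primary column; the
Benjamini–Hochberg `q_bh` column is an explicitly labelled extension, since
the tabular convention this reproduces reports raw values. Replicate wells
are treated as independent observations and cell lines are pooled within
class, as the two-class design implies.

Over-representation is a one-sided hypergeometric test `P(X ≥ k)` of the
selected set against each pathway, with the universe restricted to
metabolites observed in the stratum (a database-wide universe would inflate
significance, since detection is platform-limited), BH across tested
pathways. Depletion is out of scope.

## Synthetic data generator

Log-scale model per fraction:
`log x_ij = μ_j + c_i δ_j + γ g_i b_j + e_ij`, with `c_i = ±½` by class,
`g_i ~ N(0,1)` independent of class (drawn per well, or per cell line with
`orthogonal_level="line"`, emulating line-to-line metabolic individuality —
the dominant class-unrelated structure in replicated line panels), `b` a
fixed unit-norm loading, and `e_ij` Gaussian with SD σ and equicorrelation
ρ inside declared pathway blocks. Intensities are `exp(log x)·s_i` with a
log-normal per-sample load `s_i` (CV 0.1); supernatant wells receive an
additive media background `m_j(1+ε)` on the intensity scale (subtraction
happens on intensities, hence the background is additive there), and
media-only control wells plus an internal-standard channel
`IS₀·s_i·(1+η)` complete the tables.

Defaults mirror the emulated design: 3 cell lines per class × 6 replicate
wells, 6 media controls, a 400-metabolite panel with a 10-metabolite
planted block (δ = 1.5, within the 1–2 σ range that makes recovery
testable; the block carries arginine-pathway display names and the urea-
cycle pathway label so enrichment is exercisable end to end), γ = 1,
σ = 1. The treatment scenario generates 3 populations × (untreated,
treated) × 12 replicate wells with per-population baseline profiles
(SD 0.5) and a treatment shift (default δ_t = 2 on 10 metabolites) applied
only to the responder's treated wells.

All draws flow from one seed through fixed named substreams (structure,
per-fraction noise, media for cells, media for controls, internal standard,
treatment), so changing e.g. the number of media controls cannot perturb
cell-sample values, and identical configurations are bitwise reproducible.

What the generator does *not* emulate: chromatographic drift, co-elution,
missing peaks, batch structure, heavy-tailed instrument noise, or any
relationship between metabolite identity and abundance. Passing tests
therefore show that the pipeline behaves correctly under its own
statistical assumptions — not that those assumptions hold for any
particular instrument's data.

## Statistical behaviour measured on the generator

With the null configuration (no class effect, no orthogonal factor, 12
wells per class, one predictive component, 7 folds, an 80-metabolite panel
matching a typical 1D GC panel), the CV-ANOVA false-positive rate at 0.05
sits near 0.04 over 500 seeds — the wide acceptance band [0.01, 0.12]
acknowledges that the F reference distribution is approximate for
cross-validated residuals. Median p is monotone non-increasing in the
planted effect over δ ∈ {0, 0.5, 1, 2}. |w*| selection on a 400-metabolite
panel recovers all ten δ = 2 planted biomarkers in ≥ 90% of runs, and the
treatment scenario attributes the dominant treated-vs-untreated score
shift to the designated responder in ≥ 90% of runs.

Two property tests run on log intensities rather than raw: strong-effect Q²
and the greedy orthogonal-component rule. On the exp scale the log-normal
tails dominate unit-variance scaling and both quantities become erratic;
on the generator's own (log) scale they are stable. This is a statement
about the generator's tails, not about the algorithms.

## Problem sizes

Default test and acceptance problem sizes — panels of 50–400 metabolites,
12–36 wells per model, 50–500 Monte-Carlo repetitions — were chosen to
match the emulated study's scale (tens of wells, tens to hundreds of
peaks); the full suite and the acceptance script each run in well under a
minute on one CPU.

## Known limitations

- CV-ANOVA's F reference is approximate; its p-values are calibrated but
  not exact, and the df convention differs between software families.
- The exact Mann–Whitney path requires tie-free data; heavily tied small
  samples fall back to the corrected normal approximation.
- |w*| thresholding at a fixed τ interacts with panel size (‖w*‖ = 1, so
  the typical weight scales like 1/√M); τ = 0.05 is the conventional
  value, not an optimized one.
- Multi-class orthogonalization projects against the weight set of a
  temporary PLS2 fit; other OPLS generalizations (e.g. full O2PLS) are out
  of scope, as are VIP scores and permutation-based model p-values.
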