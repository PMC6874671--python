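# Methods

This note documents the models, algorithms and numerical choices behind
`carasr`, and what the synthetic-data generators do and do not emulate.

## The reconstruction problem

Given a gapped amino-acid alignment of extant enzymes and a rooted
phylogeny with branch lengths (expected substitutions per site), the
pipeline infers the sequence at one internal node — here, the common
ancestor of a clade of carboxylic acid reductases (CARs) — and then
characterizes the resulting enzymes quantitatively. Reconstruction is
*marginal*: at each alignment column the posterior distribution over the 20
amino acids at the target node is computed by integrating over the states
of every other internal node, and the most-probable (MAP) residue is taken
per column. Residue reconstruction and gap (presence/absence)
reconstruction are deliberately separated, mirroring how the standard
tools treat them.

## Substitution model and likelihood

Substitution follows a reversible 20-state CTMC built from a symmetric
exchangeability matrix S and equilibrium frequencies π: Q_ij = S_ij·π_j
(i ≠ j), with rows summing to zero and the mean rate normalized to one so
branch lengths stay in substitutions per site. WAG, LG, JTT and Dayhoff
exchangeabilities ship as plain-text data files (PAML layout) with a
checksum test; a uniform Poisson model is generated in code. Transition
matrices P(t) = exp(Qt) are computed once per edge via the symmetric
eigendecomposition of diag(√π)·Q·diag(1/√π); a test pins this route to
scipy's scaling-and-squaring `expm` at 1e-10.

Across-site rate variation uses the discrete-gamma treatment: K
equal-probability categories of a mean-one gamma with shape α, each
represented by its class mean (computed from regularized incomplete gamma
functions and cross-checked against adaptive quadrature). An optional
invariant fraction p_inv enters as a zero-rate class; the gamma rates are
then inflated by 1/(1−p_inv) so the mixture mean stays one. With this
convention the invariant class's likelihood contribution reduces to the
familiar "equilibrium frequency of the shared residue" term, because a
zero-rate pruning pass collapses to identity transitions.

Site likelihoods come from Felsenstein pruning over `(n_sites, 20)`
conditional arrays with per-site rescaling (log-scalers carried alongside)
to avoid underflow on large trees. Gaps and `X` at leaves are missing data
(all-ones conditionals). The engine accepts either a scalar category rate
(one 20×20 matrix per edge) or a per-site rate vector (an
`(n_sites, 20, 20)` tensor per edge) — the latter is what the
Ancescon-style reconstruction needs. Exhaustive-enumeration oracles verify
the pruning likelihood and the marginals to 1e-10 on quartets, including a
root polytomy.

Rate parameters (α, p_inv, and a single global branch-length scale) are
fitted by bounded L-BFGS-B in log coordinates, with bounds α ∈ [0.02, 100],
p_inv ∈ [0, 0.99], scale ∈ [1e-3, 1e3]. Branch-length optimization is a
global scale only: input trees arrive with posterior-mean lengths, and
per-edge optimization is out of scope. If the optimizer fails to improve on
its starting point the starting point is returned (the fit is contractually
monotone). An alignment with no variable column leaves α unidentifiable;
the fit returns the upper bound with an explicit warning instead of
raising. Model ranking uses AIC = −2 lnL + 2k, k counting only the
parameters actually fitted, ties broken toward fewer parameters; AIC was
chosen over AICc/BIC as the conventional default for this model-ranking
step.

## Marginal posteriors and the three algorithm styles

The marginal at node v combines the inside (subtree below v) and outside
(rest of the tree) conditional likelihoods per rate category, with the
category shared across the whole tree at a site — the standard +Γ model
assumption. The inside–outside identity (summing the unnormalized marginal
over states reproduces the site likelihood at every node) is tested
directly.

Three styles emulate the configurations of the common marginal ASR tools:

* **P** — discrete gamma with K = 8 and fitted α, model frequencies,
  p_inv available behind a flag but off by default (the reference
  configuration pairs 8 gamma categories with an estimated shape, and
  whether an invariant class was simultaneously active is not stated).
* **F** — as P, plus a fitted global branch scale, plus binary ML
  presence/absence reconstruction of gaps (below).
* **A** — a single rate class with per-site ML rate factors and
  alignment-derived frequencies (+1 pseudocount per residue). Per-site
  rates are found by an 81-point log-spaced grid search over [1e-3, 100]
  with local quadratic refinement — a bounded search whose accuracy is
  pinned against a 400-point grid in the tests. Columns with at most one
  non-gap character carry no rate signal and are pinned at the lower bound
  with a warning.

MAP extraction breaks exact posterior ties alphabetically (deterministic,
logged). Styles F and A install their own ML gap calls; style P leaves an
all-present placeholder because its gap pattern arrives by cross-mapping —
exactly how the PAML-derived ancestors acquire gaps from FastML/Ancescon
output in the study design this pipeline reproduces.

## Indel reconstruction and cross-mapping

Gaps are recoded as binary presence characters. Under the default *block*
granularity, maximal runs of adjacent columns sharing one presence pattern
across all rows collapse into a single character, so a multi-column gap
event counts once rather than per column. Presence evolves under a
reversible two-state CTMC: a gain/loss rate ratio g implies stationary
presence frequency g/(1+g) (default g = 1, symmetric, since no indel-model
parameters are given in the source configuration), branch lengths are the
amino-acid lengths times a scale (default 1), and the mean rate is
normalized to one. The closed-form two-state transition matrix feeds the
same pruning recursion; posteriors match exhaustive enumeration to 1e-12,
including a property-based sweep over random ≤6-leaf trees. The presence
call is posterior > 0.5; an exact 0.5 tie (which arises under perfect
symmetry) is called *absent* — conservative toward shorter ancestors — and
logged.

Cross-mapping transposes a donor ancestor's presence track onto a
recipient's residues by shared alignment column, valid because both
reconstructions live in the same curated alignment; no re-alignment is
needed or performed. Columns where the donor is present but the recipient's
own method called a gap take the recipient's MAP residue (always defined
per column) and are logged.

## Curation

Two steps precede reconstruction. (1) Insertion columns supported by at
most `max_support` rows (default 1) are removed — a parameterized form of
manually stripping insertions carried by one or very few leaves. (2) A
re-implemented Gblocks-style filter classifies each column by the count m
of its most frequent residue (gaps and `X` occupy but never match):
non-conserved if m < ceil(min_id·n), highly conserved if
m ≥ ceil(high_id·n), conserved otherwise; runs of more than
`max_nonconserved_run` contiguous non-conserved columns are rejected,
blocks are trimmed to highly-conserved flanks, and short blocks dropped.
Defaults mirror the published defaults of the original filter: identity
threshold floor(n/2)+1 sequences, high threshold 0.85, run limit 8, minimum
block length 10, no gap columns. The filter is idempotent and
provenance-preserving (every output column maps to exactly one unaltered
input column); both properties are tested. The analysis drivers run it with
`allow_gaps=True` so that gap columns survive for the downstream indel
reconstruction.

## Variant sampling and comparison statistics

The posterior-sampling variant replaces the MAP residue with the
second-most-probable residue wherever the runner-up's posterior exceeds a
threshold (default 0.30). Substitution count is non-increasing in the
threshold (tested).

Pairwise percent identity defaults to the alignment-viewer convention:
columns where both sequences are gaps leave the denominator, a residue
aligned to a gap is a mismatch. A literal policy (`count-gap-mismatch`,
all columns in the denominator, both-gap counting as identical) is also
exposed because the published identity figures do not state their gap
handling. The identity barcode reports, per column, the fraction of
unordered sequence pairs carrying the identical character (gaps literal);
conservation is the percentage of columns identical across all sequences
and is provably ≤ every pairwise identity. Shared derived variation between
two variants of a reference counts columns where both differ from the
reference *and* agree with each other; directional (per-variant) and
symmetric (union) denominators are all reported, and the looser
"both differ somehow" set is recorded for transparency, because the
published 16%/22% figures do not state which definition was used.

## Assay models

The readout throughout is NADPH depletion at 340 nm. Absorbance traces are
blank-subtracted, converted to µM NADPH through an OLS standard curve, and
the initial rate is the slope of the most linear prefix window: among all
prefixes of ≥ 4 points with R² ≥ 0.98, the one maximizing R² (longer on
ties) — short near-perfect windows win on curved progress traces, long
ones on noisy linear traces. If no prefix qualifies, the first quarter of
points is used and the result flagged low-confidence. Rates are µM·min⁻¹,
positive for consumption.

Kinetics: v = Vmax·S/(KM+S), or v = Vmax·S/(KM + S·(1+S/Ki)) with
substrate inhibition; nonlinear least squares from documented starting
values (Vmax₀ = max rate, KM₀ = interpolated half-max concentration,
Ki₀ = max S); kcat = Vmax/[E]; standard errors from the fit covariance
(reported and labeled as fit SEs). Substrate-inhibition trimming fits the
inhibition model first and removes concentrations where the inhibition term
depresses the rate by more than 3% (floor of five distinct concentrations);
fallbacks are the empirical rate peak and an iterative residual rule (top
residual negative and > 2× residual SD). The pre-fit criterion was chosen
because residual-based rules are blinded by their own lack-of-fit: on
noiseless inhibited data the systematic misfit inflates the residual SD so
the residual rule never triggers, while the pre-fit recovers KM to within
10% in the weak-inhibition regime (Ki ≫ KM) that motivates trimming in the
first place. Substrate units (µM or mM) are preserved per dataset and carry
into kcat/KM.

pH dependence follows the diprotic bell v = V100/(h/K1 + 1 + K2/h),
h = 10^(−pH); at h = K1 with well-separated pKs the model sits at 50% of
V100, an identity the tests assert. Fitting is in pK coordinates with
starting values from interpolated half-max crossings. A flank whose extreme
point still sits at ≥ 90% of the maximum shows no decline and leaves its pK
unidentifiable: that pK is reported at the pH bound with a warning. A flank
that declines without crossing 50% is still fitted (mild model-based
extrapolation). The fit is invariant to uniform rescaling of activities.

Stability: A50 (and solvent C50) by linear interpolation of the first
downward crossing of 50% at or after the activity peak, with an explicit
"> max condition" marker when the level is never reached (never a number);
half-life by fitting A(t) = 100·e^(−kt) (t½ = ln 2/k) or by the same
interpolation; DSF Tm as the temperature of the interior maximum of the
smoothed (5-point moving average) first derivative dF/dT, refined by a
three-point quadratic. A derivative peak must stand at least 5% of the
derivative range above the median, which rejects flat or linear melt
curves.

Activity significance uses Welch's unequal-variance t-test (the source
states only "t-test"; unequal variance is the safer default for
enzyme-vs-control rates) with the screen's star bands:
**** P ≤ 1e-6, *** ≤ 1e-5, ** ≤ 1e-4, * ≤ 1e-3, ns above. Two identical
zero-variance groups return p = 1 rather than raising.

## Synthetic data: what it emulates, and what it does not

`simulate_msa` evolves sequences root-down under the same CTMC + discrete
gamma (+ invariant) machinery, one rate category per site shared across the
tree, with indels as Poisson events per edge (expected count
indel_rate × branch length × current length, split evenly between
deletions and insertions) of geometric length. Deletions mask contiguous
present columns for the whole subtree; insertions add fresh columns
(states drawn from π) gapped everywhere outside the subtree. The true
gapped sequence at every node, the per-site category draws and the event
list are recorded. Indel bookkeeping is deliberately simple — no
overlapping-event history beyond column masking — because the
reconstruction model it exercises is itself binary presence/absence.
Default study conditions: 12 taxa on a birth–death tree rescaled to mean
root-to-tip depth 0.3 substitutions/site (leaf pairwise identity ~65–80%,
the divergence regime of a conserved enzyme family), 500 sites, α = 1 with
K = 8, indel rate 0.05 with mean length 3. Under these conditions every
final gap-aware ancestor (A, F, and the cross-mapped PA/PF) recovers ≥ 90%
identity to the recorded truth, and binned MAP confidence tracks empirical
accuracy within ±10 points.

`simulate_plate_assay` produces NADPH-depletion traces: NADPH falls
linearly at the Michaelis–Menten (or substrate-inhibition) initial rate
until exhausted, then stays flat; absorbance is the standard-curve image
(slope 0.005 A·µM⁻¹, a plausible pathlength-corrected NADPH response;
the source provides no coefficient, so the generator carries its own curve)
plus homoscedastic Gaussian noise; blanks carry a slow background drift.
Condition profiles are closed-form curves — falling logistic
(temperature/solvent), exponential decay (time), the diprotic bell (pH),
rising two-state sigmoid (melt) — plus Gaussian noise, with the generating
parameters recorded.

What the generators do *not* emulate: real CAR sequence content or domain
structure; alignment error (leaves are emitted in true columns);
heteroscedastic or correlated plate noise (a heteroscedastic option exists
but is off by default); ATP regeneration, product inhibition, or buffer
chemistry. Passing recovery tests therefore demonstrate correctness of the
inference machinery under the stated generative assumptions, not field
accuracy on real data.

## Numerical conventions and degenerate inputs

Column coordinates are 0-based half-open everywhere. All simulators are
pure functions of (parameters, seed). Mixture weights/rates always satisfy
Σw = 1 and Σw·r = 1 to 1e-10. Degenerate inputs favour flagged results
over exceptions where a defined answer exists (unidentifiable α, flat pH
profiles, never-crossed A50) and raise early, named errors where none does
(ragged alignments, all-gap rows, non-decaying half-life profiles, flat
melt curves).

## Problem sizes

The shipped test suite and drivers use quartets for enumeration oracles,
8–12 taxa and 500–2000 sites for fitting/recovery/calibration runs, and
12-point dilution series with 3 replicates for assay loops; the full suite
runs in well under a minute on one CPU.
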