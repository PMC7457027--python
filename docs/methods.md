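# Methods

## The regulatory–metabolic circuit

The model couples a four-variable gene-regulatory layer — pAMPK (`A`,
nM), HIF-1 (`H`, nM), mitochondrial ROS (`Rmt`, mM), NOX-derived ROS
(`Rnox`, mM) — to three metabolic pathway rates: glucose oxidation
(`G1`), glycolysis (`G2`) and fatty-acid oxidation (`F`), all in mM/min.
Each regulator obeys

    dx/dt = g_x · F_g(state) − k_x · F_k(state) · x

with `F_g`, `F_k` products of shifted-Hill multipliers
`λ + (1−λ)/(1+(x/x₀)ⁿ)` over the incoming production/degradation edges
(empty product = 1; `λ>1` activation, `λ<1` inhibition). Enzyme kinetics
relax much faster than gene expression, so the metabolic layer is
treated as equilibrated at each `(A, H)`: pathway rates are algebraic,
each the product of a basal rate and shifted-Hill factors of `A` and
`H`. ATP outputs are yield constants times rates (defaults 29 ATP per
glucose oxidized, 2 per glucose fermented, 106 per palmitate —
configurable).

**Topology** (an explicit, config-overridable edge list in
`src/metabostate/data/baseline.yaml`):

* mutual inhibition `A ⊣ H` and `H ⊣ A` (production arms);
* `Rmt → A` production; `Rmt` production driven by the oxidative flux
  `OX = G1 + F`, closing the positive loop A → (G1+F) → Rmt → A;
* `H → Rnox` production; `Rnox ⊣ degradation of H`, closing the positive
  loop that stabilizes HIF-1;
* rates: `G1` and `F` activated by `A`, `G1` repressed by `H`; `G2`
  activated by `H`, repressed by `A`.

The two positive loops make each axis (A and H) bistable on its own;
the moderate mutual inhibition couples them, so four combinations —
(A high, H low) = OXPHOS "O", (A low, H high) = glycolytic "W", both
high = hybrid "W/O", both low = inactive "L/L" — can all be stable.
ROS variables are fast (`k` of 60–300 h⁻¹) and effectively slave to
`(A, H)`, which makes the quadstability robust.

**Units.** Internal time unit is hours. ROS production rates are
customarily quoted in mM/min (the scenario values 45 and 30 mM/min);
the config loader accepts `g_mm_per_min` and converts (×60) on read.
HIF-1 degradation is quoted in h⁻¹ (0.25/0.45) and passes through
unchanged.

**Baseline calibration.** The shipped baseline is this package's own
calibration of the circuit (no published parameter set is redistributed
here). It was tuned — threshold placement relative to the low/high branches of each
positive loop, and mutual-inhibition strength — until (i) the baseline
itself is quadstable, (ii) random ±25% ensembles preserve all four
phenotypes with the pure states W and O dominating, and (iii) the 2×2
scenario grid orders the L/L fraction as low-mtROS/low-HIF-1 > mixed >
high/high. It was then frozen; all shipped statistics refer to this
file. Edit the YAML to explore other regimes.

## Steady-state finding and stability

Multi-start damped Newton search, run as one vectorized batch:

* starts: `n_starts = 100` points log-uniform over `10⁻³–10²` times the
  basal scale `g/k` of each variable;
* residual: dimensionless, `rhs/(k_x · g_x/k_x) = rhs/g_x`, converged
  below `tol = 1e−9` (relative — an absolute 1e−9 on mM/h quantities of
  magnitude ~10³ would sit below float64 resolution);
* damping: full Newton step first, backtracking line search
  (α ∈ {0.5, 0.25, 0.1, 0.03}) only for rows the full step did not
  improve; a 1e−12 ridge guards fold-point singularity;
* deduplication at relative tolerance `dedup_rtol = 1e−3` in scaled
  coordinates; an LSODA forward-integration fallback runs only if no
  start converges;
* stability: largest real eigenvalue of the central-difference Jacobian,
  threshold −1e−8 h⁻¹ so marginal roots are never called stable.

Saddle capture from random starts is inherently probabilistic; the
*stable* state set is what downstream statistics use, and it is invariant
to doubling `n_starts` (tested).

## Ensembles, clustering, labels

Each ensemble draws every scalar parameter uniformly from
`((1−f)·P₀, (1+f)·P₀)` with `f = 0.25`; Hill coefficients are resampled
in the same window and rounded to integers (min 1). Scenarios pin
`g_Rmt` (45 or 30 mM/min) and `k_H` (0.25 or 0.45 h⁻¹). 500 sets per
scenario, 3 repeats with fresh sub-seeds, all randomness flowing from
one seeded `numpy` generator.

Stable records are assembled in the feature order
`(F, Rmt, G1, A, Rnox, H, G2)`, log10-transformed, then z-scored with
the mean/sd of the *reference* scenario (high mtROS, high HIF-1) only;
projection uses only the reference's first two PCA loadings. The log
transform is the natural scale for multiplicative parameter sampling
(steady states spread over decades); the labelling below depends only on
signs relative to the cohort mean, not on the transform.

Clustering is Ward/Euclidean agglomerative, tree cut at k = 4 (the
method is named "HCA" in the source analysis without linkage details;
Ward is the standard choice for compact clusters). Cluster centroids in
z-space are labelled by sign pattern: W/O if A>0 and H>0; O if A>0, H<0,
(G1 or F)>0 and G2<0; W if A<0, H>0, G2>0; L/L if A, H, G1, G2 all <0.
Ambiguities (a centroid matching no rule, or two clusters claiming one
label) fall back to a one-to-one nearest-prototype assignment with a
logged warning.

## Transcriptome scoring

Inputs are genes × samples matrices of library-size-normalized,
log-scale values (a `log2p1` flag converts raw counts). z-scores use the
sample (n−1) standard deviation — cohorts here are small. Listed genes
missing from the matrix, or constant across samples, are dropped with a
warning rather than imputed; `n` in the pathway score reflects genes
actually used.

The activity signature restricts to a regulator's downstream targets
(mRNA of AMPK/HIF-1 themselves does not report their activity),
standardizes each gene, and takes PC1 over samples. A principal
component's sign is arbitrary, so the signature is oriented to correlate
positively with the mean standardized target expression ("higher = more
active"). Longitudinal cohorts are scored pooled (one PCA over all
samples of all subjects), and each subject's direction of change is
`last − first` along its time axis. Gene lists ship as an editable GMT
file; the default lists are reconstructions assembled from standard
pathway annotation at the documented sizes (10 TCA, 8 glycolysis, 14 FAO
enzymes; AMPK targets downstream of PGC-1α/CREB/FOXO; canonical HIF-1
targets), with the enzyme sets disjoint from the target sets so the two
read-outs stay independent. List membership is configuration, not code.

## Flux stress tests

Phase summary = mean of the last three measurements per well per phase
(the post-injection plateau; manufacturer convention), normalized per
cell, averaged over wells. Mito arm: non-mito = rotenone/antimycin-A
phase; basal = baseline − non-mito; ATP-linked = baseline − oligomycin;
maximal = FCCP − non-mito; spare = maximal − basal. Glyco arm:
non-glycolytic = no-glucose baseline; glycolysis = glucose −
non-glycolytic; capacity = oligomycin − non-glycolytic; reserve =
capacity − glycolysis. The reserve and spare identities therefore hold
exactly, and noisy traces can produce negative derived values — these
are returned flagged, not silently clipped.

The 2-D aggregation z-scores each parameter across conditions and
averages the four glycolytic (x) and four mitochondrial (y) parameters'
z-scores; non-mito respiration is background, not an OXPHOS read-out,
and is excluded. JATP conversion: `jatp_ox = atp_linked × 2 × P/O` and
`jatp_glyc = glycolysis × (mpH→pmol H⁺) × ATP-per-lactate`, constants in
`data/jatp.yaml` (defaults P/O = 2.45, 10 pmol H⁺ per mpH,
1 ATP/lactate — the buffering conversion is assay-medium dependent and
should be calibrated per platform).

## Idling population model

Linear dynamics of three subpopulations H/I/L on the chain H↔I↔L:
`dn_s/dt = (d_s·g(o_s, y_s) − m_s)·n_s + Σ transitions`, with growth
coupling `g(o, y) = (o+y)/2` by default (the simplest monotone map from
metabolic capacities to growth; override via the `growth_coupling`
field). Trajectories are computed with the matrix exponential (exact for
a linear system); the DIP rate is the least-squares slope of `ln N(t)`;
"idling" means |DIP| < 0.005 h⁻¹ over the final quarter of the horizon.

The three presets are illustrative calibrations, not data fits: a common
chassis (division 0.04 h⁻¹ everywhere; L capacities (0.5, 0.5) so the
low/low state divides at half rate, with death matched at 0.02 h⁻¹;
forward transitions 0.03 and 0.02 h⁻¹, reverse 2e−4 h⁻¹) in which only
the death rate of the starting H state differs (0.08 / 0.04 / 0.02 h⁻¹),
producing negative / ~zero / positive early DIP and a common late DIP
within 5e−5 of zero. Drug effect enters as this parameter switch at
t = 0; transitions beyond the chain, stochastic birth–death and
resistance evolution are out of scope.

## Synthetic data

Expression: gene value = baseline + β·latent + Gaussian noise on the log
scale; AMPK targets and TCA/FAO enzymes read the AMPK axis, HIF-1
targets and glycolytic enzymes the HIF-1 axis; background genes are pure
noise. Defaults (n = 30 subjects, β = 2, noise sd = 1, i.e. per-gene
SNR 2) are the regime in which PC1 recovery is expected to work on small
cohorts. The patient-course generator plants a chosen number of subjects
with strictly decreasing latent activity on both axes (default 6 of 7;
the others decline only in HIF-1). Flux fixtures are phase-wise constant
traces built by inverting the extraction arithmetic, so zero-noise round
trips are exact. What these generators do **not** emulate: count noise
(negative-binomial), batch effects, gene–gene correlation beyond the
single latent factor, and instrument drift — so passing recovery tests
demonstrates the estimators' correctness, not their robustness on real
cohorts.

## Problem sizes and numerics

Shipped analyses use 500 parameter sets per scenario and 3 repeats
(the headline statistic), 100 Newton starts per set, 20 seeds × n = 30
for recovery statistics, and 1000 h population horizons; the examples
use reduced sizes where the point is illustration. Determinism: every
entry point takes a `numpy.random.Generator` (or integer seed) and child
streams are spawned per stage/scenario/repeat, so equal seeds give
byte-identical outputs.

## Known limitations

* The baseline circuit is a calibrated reconstruction; quantitative
  steady-state values are not comparable to any specific cell line —
  only the qualitative four-state structure and scenario trends are.
* Cluster labelling assumes the four phenotypes are all present; heavily
  perturbed configs can legitimately produce fewer, triggering the
  nearest-prototype fallback.
* MAPK/ERK signalling and glutamine metabolism are outside the circuit;
  the population model is deterministic and linear.
* The JATP buffering constant default is a placeholder magnitude;
  cross-platform comparisons require per-assay calibration.
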