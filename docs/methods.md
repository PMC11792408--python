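# Methods

## Data model

A study dataset is three tables. The **cell table** is a QuPath-style
export: `cell_id, slide_id, region_id, x_um, y_um` plus one 0/1 column
per marker. Coordinates are micrometres in image convention (origin
top-left, y downward); every downstream quantity depends only on
Euclidean distances, so the orientation convention is unobservable and
documented purely for interoperability. Marker positivity is consumed as
boolean calls: intensity thresholding belongs to the upstream imaging
software, and "relative intensity" gradations are deliberately collapsed
to binary positivity. The **region table** carries the classifier/
pathologist compartment assignment (`TC-Tumour, TC-Stroma, TC-TLS,
IM-TLS, IM-non-TLS, N-TLS, N-non-TLS`), a measured area in mm², and an
optional WKT polygon. Region membership of a cell is taken from its
label column, never recomputed from polygons; polygons serve validation
(containment, area agreement within 1 %, TLS caliper diameter > 200 µm)
and the optional edge correction below. The TLS diameter check uses the
maximum pairwise distance of convex-hull vertices — exact for the convex
aggregates TLS effectively are. The **clinical table** holds per-patient
times (months) and event flags for four endpoints: irOS and irPFS
clocked from the initiation of immunotherapy, OS and PFS from diagnosis.

The marker panel is configurable rather than fixed: the default
vocabulary is the seventeen-marker gastric TME panel (CD8, PD-1, TIM-3,
LAG-3, CD4, FoxP3, CTLA-4, PD-L1, CD68, CD163, CD86, STING, CD20, CD21,
CD3, FAP, CD66b), but a `PanelDefinition` accepts any marker list, since
panel compositions vary between studies and even between descriptions of
one study.

## Phenotype gating

A phenotype is a conjunction over markers (required-positive set,
required-negative set). Gating is a pure function of the marker vector;
a cell may satisfy several gates. `expand_subtype_space` enumerates the
2^k sign assignments of k conditional markers around a fixed
lineage-positive anchor (e.g. CD8⁺ × {LAG-3, PD-1, TIM-3}), refusing
k > 6 as a combinatorial guard. The shipped registry contains the gates
commonly profiled in TLS studies (exhaustion-receptor combinations,
CD4/Treg and checkpoint combinations, macrophage combinations, lymphoid
and stromal markers); the full feature space a model consumes is
config-defined, not hard-coded, because no canonical enumeration of such
a space exists.

## Densities

Density of phenotype *P* in a compartment is `ΣC_P / Area` in cells/mm².
When a patient contributes several region instances of one compartment
(possibly across slides), the default pooling is the **ratio of sums**
(total member count over total area), which weights regions by area and
equals the density of the merged region; the unweighted mean of
per-region densities is available by configuration since either pooling
is defensible when a study does not state one. A compartment absent for
a patient yields a *missing* value, never zero — absence of a TLS is not
the same observation as an empty TLS.

## The effective score

For a centre phenotype and a surround phenotype inside one compartment,
cells are paired when their nucleus-to-nucleus distance is at most r
(default 20 µm, a conventional interaction radius for gastrointestinal
tumour cell maps). The boundary is inclusive (≤ r), a convention that
must be fixed arbitrarily and is therefore documented and tested.
Pairing uses a KD-tree and is verified exactly against an O(n²)
brute-force reference. A cell id never pairs with itself even when it
satisfies both phenotypes; pairing never crosses slides; region
instances of one compartment are pooled within a patient by summing
counts before dividing.

The published verbal definitions of the score support two numerators
(distinct surrounding cells with ≥1 paired centre, vs all
centre–surround pairs) and two denominators (all centre cells, vs only
centres with ≥1 pair). Rather than guessing the intended combination,
all four are first-class modes; the default is
`unique_surround / all_centres`. The modes obey provable inequalities
(`unique_surround ≤ all_pairs` numerators; `paired_centres ≤
all_centres` denominators) and the default score is non-decreasing in r,
all property-tested.

Under complete spatial randomness with surround intensity λ (cells/µm²)
the `all_pairs/all_centres` score has expectation λπr² in the interior
of a window. The raw statistic is negatively edge-biased — centres
within r of the region boundary see truncated discs, a deficit of order
8r³λ/(3L) for window scale L, which no feasible window outgrows relative
to Monte-Carlo error. `compute_effective_score` therefore accepts a
minus-sampling guard (`guard_um`): centre cells closer than `guard_um`
to the region boundary are dropped from both counts while surround cells
are kept everywhere, making the CSR expectation exact. The default is
`guard_um = 0` — the uncorrected statistic as used on real slides — and
the closed-form validation uses `guard_um = r`.

## The DSS risk model

`DSS = Σ β_j x_j` with no intercept over five TC-TLS features: densities
of CD8⁺LAG-3⁺, CD4⁺FoxP3⁺CTLA-4⁺ and CD4⁺CTLA-4⁺PD-L1⁺, and effective
scores of CD8⁺LAG-3⁻PD-1⁻TIM-3⁻ (surround CD8⁺LAG-3⁻PD-1⁻TIM-3⁺) and
CD8⁺LAG-3⁻PD-1⁺TIM-3⁻ (surround CD8⁺LAG-3⁻PD-1⁺TIM-3⁺), with published
coefficients (−0.0027, −0.0003, −0.0004, −0.1978, −0.1214). The model
ships as a versioned YAML; scoring propagates missingness (a patient
without a TC-TLS compartment has no DSS).

Refitting uses an L1-penalised Cox model (scikit-survival Coxnet) on
internally standardised features, with coefficients reported on the
original scale. The penalty is chosen by ten-fold cross-validated
partial-likelihood deviance computed on the held-out fold (Breslow
likelihood, written in-package because the library scores by concordance
only); the deviance-minimising penalty is the default and the sparser
1-SE rule is a configuration option. Patients with any missing feature
are excluded, not imputed — the model is defined on patients whose
TC-TLS exists. Fold assignment is seeded, so fits are deterministic.

Dichotomisation uses the maximally selected log-rank statistic: candidate
cutoffs are midpoints of consecutive sorted unique scores, each group
must retain ≥ 10 % of patients (configurable), ties break toward the
smaller cutoff, labels are "high" (> cutoff) / "low" (≤ cutoff). This is
the standard construction behind "optimal cutoff" survival splits; the
resulting p-value is exploratory, not corrected for the maximisation.
The anchoring endpoint defaults to OS. Note the Cox HR reported after a
maximally selected split is often quasi-separated; the estimator flags
monotone or non-convergent partial likelihoods and reports a
ridge-stabilised bound.

## Cohort statistics

Kaplan–Meier, log-rank and univariate Cox regressions are backed by
lifelines; the median is the first time S(t) ≤ 0.5 and is reported as
"not reached" when the curve never crosses it. Cox ties use Efron's
method (checked against an independent statsmodels PHReg fit). With no
events the log-rank p is defined as 1 with a warning. Two-group
comparisons use the Wilcoxon rank-sum test (exact for small tie-free
samples); three or more groups use Kruskal–Wallis plus Dunn's post hoc —
tie-corrected pairwise z tests on pooled mid-ranks, family-wise adjusted
by multiplying each p by the number of comparisons — implemented
in-package since no installed library provides it, and validated against
a hand-computed example and a family-wise-error simulation. Baseline
tables use the Pearson chi-square without continuity correction, which
is the convention that reproduces the printed cohort p-values, including
the per-variable treatment of "Unknown" rows (kept for tumour
differentiation, dropped for Lauren type); Fisher's exact alternative is
out of scope. The time-dependent AUC is the IPCW cumulative/dynamic
(Uno) estimator from scikit-survival; the incident/dynamic variant would
also satisfy the null (0.5), directional and perfect-separation
properties tested, and the cumulative/dynamic form was chosen because a
maintained reference implementation exists.

## Synthetic data

The tissue generator emulates the geometry the analysis assumes rather
than the biology of any particular tumour: a circular tumour whose
boundary defines the tumour core, a ±1 mm invasion-margin band, and
normal tissue beyond; non-overlapping TLS discs with diameters sampled
above the 200 µm recognition floor (default 250–450 µm, the size range
of small lymphoid aggregates); a stripe lattice standing in for
intratumoural stroma. Cells are homogeneous Poisson per (population,
region) with intensities in the tens-to-hundreds of cells/mm² typical of
immune infiltrates, times compartment enrichments (5–10× lymphocyte
enrichment inside TLS, stromal fibroblasts, extra-TLS exhausted T cells
and M1-like macrophages at the margin). Attraction between populations
is Neyman–Scott-like — each centre cell receives Poisson(μ) surround
daughters uniform within 20 µm — chosen because it shifts the
`all_pairs` effective score by approximately μ, giving the statistic
under test a controllable expected value; μ = 0 recovers CSR and the
λπr² closed form. Marker vectors are deterministic per population: the
generator makes no attempt at realistic marker co-expression covariance,
staining noise, segmentation error or irregular tumour boundaries, so
passing tests certify the estimators, not robustness to imaging
artefacts.

The cohort generator draws features from an equicorrelated log-normal
model (densities around 150 cells/mm², effective scores around 0.8,
copula correlation 0.2) or measures them from simulated slides. Survival
is exponential with hazard `h₀·exp(Σ β_j z_j)` over standardised true
features (default h₀ = 0.03/month — median ≈ 23 months at the baseline —
and five protective features at β = −0.5, hazard ratio ≈ 0.61 per SD, a
strong but realistic prognostic effect). Progression is a first event
with twice the death hazard sharing the same linear predictor, so
PFS ≤ OS by construction; immunotherapy-clock endpoints subtract a
1–6 month diagnosis-to-treatment delay; censoring is independent
exponential at 0.0075/month, giving ≈ 30 % censoring under the default
effects. Exponential hazards were chosen over Weibull for closed-form
checkability.

## Validation scales and numerical choices

The shipped checks run at desk scale on one CPU: 50 slides for the CSR
closed form (3×3 mm windows, λ = 10⁻³ cells/µm², agreement within 3
Monte-Carlo SE), 50 random 300-cell configurations for exact brute-force
equivalence in all four score modes, 20 seeded cohorts of n = 300 × 143
features for LASSO recovery (≥4/5 true features in ≥90 % of seeds), 200
replicates for 95 % CI coverage of a true HR 0.4, and 1 000 replicates
for null calibration of the log-rank (rejection in [0.03, 0.07],
Kolmogorov distance of null p-values < 0.05) and Dunn (family-wise error
≤ 0.05 + 3 SE) procedures. Degenerate inputs are contracts, not crashes:
zero-area compartments raise, zero centre cells yield a missing score
with a reason, all-identical scores make the cutoff infeasible, and
no-event outcomes are unfittable.

## Limitations

The published survival headlines of the original cohort (irOS 30.3
months, HR 0.37, P = 0.049; OS 26.20 vs 16.02 months, P = 0.0033) were
estimated from patient-level follow-up that is not publicly deposited;
they ship as flagged reference metadata and are not recomputable here.
The shipped phenotype registry is a reconstruction of commonly reported
gates, not a canonical enumeration of any study's full subtype space.
The generator's idealised geometry (convex tumour, circular TLS) means
the caliper-diameter validator and edge correction are untested against
strongly concave real-world annotations.
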