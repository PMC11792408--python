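# tlsscape

Spatial quantification of the immune microenvironment around **tertiary
lymphoid structures (TLS)** in gastric cancer, from multiplexed
immunohistochemistry cell maps.

Whole-slide multiplex IHC pipelines (QuPath and kin) export one row per
segmented cell: planar coordinates in micrometres, per-marker positivity
calls, and a tissue-region label. `tlsscape` turns those exports — for
regions classed as tumour core (TC-Tumour / TC-Stroma / TC-TLS), invasion
margin (IM-TLS / IM-non-TLS, the ±1 mm band around the tumour boundary)
and adjacent normal tissue (N-TLS / N-non-TLS), with TLS required to
exceed 200 µm in diameter — into patient-level quantities:

* **Phenotype gating.** A phenotype is a conjunction of required-positive
  and required-negative markers, e.g. `CD8+LAG-3-PD-1+TIM-3-` for a
  non-exhausted PD-1⁺ cytotoxic T cell. A registry of common gates ships
  with the package and is user-extensible.
* **Regional densities.** For phenotype *P* in a compartment,
  `density = ΣC_P / Area` (cells/mm²), pooling a patient's region
  instances by summed counts over summed areas (ratio of sums;
  mean-of-ratios available).
* **Effective score.** A radius-based proximity statistic: cells of a
  *surrounding* phenotype are paired to cells of a *centre* phenotype when
  their nucleus-to-nucleus distance is ≤ r (default 20 µm, boundary
  inclusive), and

  `effective score = (# paired surrounding cells) / (# centre cells)`.

  Both numerator conventions (distinct surround cells vs all pairs) and
  both denominator conventions (all centres vs paired centres) are
  first-class. Under complete spatial randomness with surround intensity
  λ, the all-pairs/all-centres score tends to λπr².
* **DSS risk model.** The Density-and-Spatial Score is a linear risk
  score over five TC-TLS features (three densities, two effective
  scores),

  `DSS = −0.0027·d(CD8⁺LAG-3⁺) − 0.0003·d(CD4⁺FoxP3⁺CTLA-4⁺)
         − 0.0004·d(CD4⁺CTLA-4⁺PD-L1⁺) − 0.1978·es(CD8⁺LAG-3⁻PD-1⁻TIM-3⁻)
         − 0.1214·es(CD8⁺LAG-3⁻PD-1⁺TIM-3⁻)`,

  with all coefficients negative: low DSS means denser, more closely
  apposed TLS infiltrates and longer survival. The package ships the
  published model and can refit the screen (L1-penalised Cox with
  ten-fold cross-validated partial-likelihood deviance) on any
  patient × feature matrix, then dichotomise patients at a maximally
  selected log-rank cutoff.
* **Cohort statistics.** Kaplan–Meier with "not reached" medians,
  Mantel–Cox log-rank, univariate Cox hazard ratios (Efron ties),
  IPCW time-dependent AUC, Wilcoxon / Kruskal–Wallis with Dunn's post
  hoc, and Pearson chi-square baseline tables, for the four endpoints
  irOS / irPFS / OS / PFS.
* **Synthetic data.** A tissue generator (tumour disc, invasion-margin
  band, non-overlapping TLS discs > 200 µm, compartment-specific Poisson
  intensities, Neyman–Scott attraction between phenotypes) and a cohort
  generator (correlated log-normal features, proportional-hazards
  survival with coupled PFS ≤ OS) make every stage testable without
  patient data.

## Worked example

```python
from tlsscape.simulate import TissueSimConfig, simulate_slide
from tlsscape.phenotyping import load_registry, assign_phenotypes
from tlsscape.density import compute_density
from tlsscape.proximity import EffectiveScoreSpec, compute_effective_score

ds = simulate_slide(TissueSimConfig(seed=7), slide_id="S1", patient_id="P1")
ds.memberships = assign_phenotypes(ds.cells, load_registry())

d_tls = compute_density(ds, "CD8+PD-1+", "TC-TLS", "P1")
d_str = compute_density(ds, "CD8+PD-1+", "TC-Stroma", "P1")
es = compute_effective_score(
    ds, EffectiveScoreSpec("CD4+FoxP3+", "CD4+FoxP3-", "TC-TLS", 20.0), "P1")
```

prints (via the obvious f-strings):

```
CD8+PD-1+ density in TC-TLS:    220.2 cells/mm^2  (59 cells / 0.268 mm^2)
CD8+PD-1+ density in TC-Stroma:  66.2 cells/mm^2
effective score (CD4+FoxP3+ <- CD4+FoxP3-, TC-TLS, r=20um): 0.444
```

— the PD-1⁺ cytotoxic infiltrate is ~3× denser inside the tumour-core TLS
than in the stroma, and on average 0.44 regulatory-T-cell centres carry a
conventional CD4 cell within 20 µm. Scoring a simulated 120-patient
cohort with the published model and splitting at the optimal cutoff:

```python
from tlsscape.simulate import CohortSimConfig, simulate_cohort
from tlsscape.dss import published_dss_model, score_dss, find_optimal_cutoff

X, clinical = simulate_cohort(CohortSimConfig(seed=1, n_patients=120))
dss = score_dss(X, published_dss_model())
```

```
DSS cutoff -0.507: 19 high / 101 low
median OS: high-DSS 2.48 vs low-DSS 25.37 months
log-rank P = 7.9e-20, HR (high vs low) = 7.64 [4.17, 13.99]
```

High-DSS patients (sparse, loosely organised TLS infiltrates) die much
earlier — the direction the model's negative coefficients encode. The
same flows are available from the shell: `tlsscape run -c config.yaml`,
`tlsscape simulate slide|cohort`, `tlsscape dss score|fit`,
`tlsscape stats baseline|survival`.

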