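# The published five-term Density-and-Spatial-Score (DSS) model:
# DSS = sum(coefficient × feature), all features measured in the TC-TLS
# compartment; three density terms (cells/mm²) and two effective-score
# terms (radius 20 µm). All coefficients negative: low DSS corresponds to
# larger densities / effective scores and longer survival.
version: 1
terms:
  - feature: "density::CD8+LAG-3+::TC-TLS"
    coefficient: -0.0027
  - feature: "density::CD4+FoxP3+CTLA-4+::TC-TLS"
    coefficient: -0.0003
  - feature: "density::CD4+CTLA-4+PD-L1+::TC-TLS"
    coefficient: -0.0004
  - feature: "effscore::CD8+LAG-3-PD-1-TIM-3-::CD8+LAG-3-PD-1-TIM-3+::TC-TLS"
    coefficient: -0.1978
  - feature: "effscore::CD8+LAG-3-PD-1+TIM-3-::CD8+LAG-3-PD-1+TIM-3+::TC-TLS"
    coefficient: -0.1214
cutoff: null
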