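# Default effective-score specifications: centre phenotype, surrounding
# phenotype, compartment, radius (µm). These are the centre/surround
# pairings profiled in TC-TLS, including the two that enter the DSS model.
- {centre: "CD8+LAG-3-PD-1-TIM-3-", surround: "CD8+LAG-3-PD-1-TIM-3+", compartment: "TC-TLS", radius_um: 20}
- {centre: "CD8+LAG-3-PD-1+TIM-3-", surround: "CD8+LAG-3-PD-1+TIM-3+", compartment: "TC-TLS", radius_um: 20}
- {centre: "CD8+LAG-3-PD-1-TIM-3-", surround: "CD8+LAG-3-PD-1+TIM-3-", compartment: "TC-TLS", radius_um: 20}
- {centre: "CD8+PD-1-TIM-3+",       surround: "CD8+PD-1-TIM-3-",       compartment: "TC-TLS", radius_um: 20}
- {centre: "CD4+FoxP3+",            surround: "CD4+FoxP3-",            compartment: "TC-TLS", radius_um: 20}
- {centre: "CD3+",                  surround: "CD20+",                 compartment: "TC-TLS", radius_um: 20}
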