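# Default phenotype registry: marker-combination gates commonly profiled in
# gastric tumour microenvironment panels (T-cell exhaustion-receptor
# combinations on CD8 cells, CD4/Treg and checkpoint combinations,
# macrophage CD68/CD163/CD86/STING combinations, CD20/CD21/CD3 lymphoid
# markers, FAP fibroblasts, CD66b neutrophils). User-extensible; the
# modelled feature space is produced by configuration, not fixed here.
- {name: "CD8+",                     positive: [CD8]}
- {name: "CD4+",                     positive: [CD4]}
- {name: "CD3+",                     positive: [CD3]}
- {name: "CD20+",                    positive: [CD20]}
- {name: "CD21+",                    positive: [CD21]}
- {name: "CD8+PD-1+",                positive: [CD8, PD-1]}
- {name: "CD8+PD-1-",                positive: [CD8], negative: [PD-1]}
- {name: "CD8+TIM-3-",               positive: [CD8], negative: [TIM-3]}
- {name: "CD8+LAG-3+",               positive: [CD8, LAG-3]}
- {name: "CD8+PD-1+TIM-3-",          positive: [CD8, PD-1], negative: [TIM-3]}
- {name: "CD8+PD-1-TIM-3+",          positive: [CD8, TIM-3], negative: [PD-1]}
- {name: "CD8+PD-1-TIM-3-",          positive: [CD8], negative: [PD-1, TIM-3]}
- {name: "CD8+LAG-3-TIM-3-",         positive: [CD8], negative: [LAG-3, TIM-3]}
- {name: "CD8+LAG-3-PD-1+TIM-3-",    positive: [CD8, PD-1], negative: [LAG-3, TIM-3]}
- {name: "CD8+LAG-3-PD-1+TIM-3+",    positive: [CD8, PD-1, TIM-3], negative: [LAG-3]}
- {name: "CD8+LAG-3-PD-1-TIM-3-",    positive: [CD8], negative: [LAG-3, PD-1, TIM-3]}
- {name: "CD8+LAG-3-PD-1-TIM-3+",    positive: [CD8, TIM-3], negative: [LAG-3, PD-1]}
- {name: "CD8+LAG-3+PD-1+TIM-3+",    positive: [CD8, LAG-3, PD-1, TIM-3]}
- {name: "CD4+FoxP3+",               positive: [CD4, FoxP3]}
- {name: "CD4+FoxP3-",               positive: [CD4], negative: [FoxP3]}
- {name: "CD4+CTLA-4+",              positive: [CD4, CTLA-4]}
- {name: "CD4+CTLA-4-",              positive: [CD4], negative: [CTLA-4]}
- {name: "CD4+PD-L1+",               positive: [CD4, PD-L1]}
- {name: "CD4+FoxP3+CTLA-4+",        positive: [CD4, FoxP3, CTLA-4]}
- {name: "CD4+FoxP3-CTLA-4+",        positive: [CD4, CTLA-4], negative: [FoxP3]}
- {name: "CD4+FoxP3-CTLA-4-",        positive: [CD4], negative: [FoxP3, CTLA-4]}
- {name: "CD4+CTLA-4+PD-L1+",        positive: [CD4, CTLA-4, PD-L1]}
- {name: "CD4+CTLA-4-FoxP3-PD-L1-",  positive: [CD4], negative: [CTLA-4, FoxP3, PD-L1]}
- {name: "CD68+CD86+",               positive: [CD68, CD86]}
- {name: "CD68+CD163+",              positive: [CD68, CD163]}
- {name: "CD68+CD86+STING+",         positive: [CD68, CD86, STING]}
- {name: "CD163+CD86+STING+",        positive: [CD163, CD86, STING]}
- {name: "FAP+",                     positive: [FAP]}
- {name: "CD66b+",                   positive: [CD66b]}
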