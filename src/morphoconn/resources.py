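"""Fixed domain constants: gene lists, cell classes, clinical-score calibration.

The AD-risk list is the 28-symbol high-risk compilation distributed with the
Allen Human Brain Atlas documentation.  The seven cell classes follow the
standard single-cell compilation used in imaging-transcriptomics work
(microglia, endothelial cells, oligodendrocyte precursors, oligodendrocytes,
astrocytes, inhibitory neurons, excitatory neurons).
"""

from __future__ import annotations

AD_RISK_GENES: tuple[str, ...] = (
    "A2M", "ACE", "ACHE", "APBA1", "APBB2", "APLP1", "APLP2", "APOC1",
    "APP", "BACE2", "BCHE", "BLMH", "CASP3", "CHRNA3", "CTSB", "DBN1",
    "ESR1", "GSK3B", "IL1B", "KCNIP3", "KLK6", "LRP1", "LRRC15", "MAPT",
    "PLAU", "PSEN1", "PSEN2", "SORL1",
)

CELL_CLASSES: tuple[str, ...] = (
    "microglia",
    "endothelial",
    "opc",
    "oligodendrocyte",
    "astrocyte",
    "inhibitory_neuron",
    "excitatory_neuron",
)

#: Clinical measures carried in the covariate table, with the linear
#: calibration used by the synthetic cohort: score = base + slope * burden
#: + Normal(0, sd) noise, where burden is the subject's latent disease load
#: (0 for controls, rising through MCI to AD).  base/sd mirror a typical
#: elderly NC population; slope is set so a unit burden reproduces the
#: NC-to-AD span seen in large memory-clinic cohorts.
CLINICAL_CALIBRATION: dict[str, tuple[float, float, float]] = {
    "MMSE": (29.1, -5.9, 1.10),
    "ADAS-cog11": (7.0, 12.7, 3.00),
    "ADAS-cog13": (10.4, 19.7, 4.40),
    "AVLT-Im": (45.3, -22.3, 10.00),
    "Memory": (1.01, -1.87, 0.55),
    "Executive": (0.90, -1.82, 0.82),
}

CLINICAL_MEASURES: tuple[str, ...] = tuple(CLINICAL_CALIBRATION)

GROUPS: tuple[str, ...] = ("NC", "MCI", "AD")
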