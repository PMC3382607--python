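"""The PBMC marker panel, shipped subset definitions, and study scenarios.

The subset definitions transcribe the surface phenotypes of the 18 lymphoid
and myeloid PBMC populations resolved by the polychromatic panel (naive and
memory B cells, four CD4 and four CD8 T-cell differentiation stages, two NK
subsets split on CD56/CD16, two monocyte and two myeloid-DC subsets split on
CD16, plasmacytoid DCs and basophils). ``study_scenario`` builds the default
22-donor synthetic cohort whose per-subset CD52 densities carry the
reference antigen-density values for a healthy-donor cohort; where only a
qualitative ordering is known the values are plausible interpolations
consistent with that ordering (documented in the methods note).
"""

from __future__ import annotations

import importlib.resources as resources

import yaml

from .config import BimodalSpec, CDCModelParams, SimulationConfig, SubsetSpec
from .gating import SubsetDefinition

__all__ = [
    "MARKER_CHANNELS",
    "THREE_LEVEL_CHANNELS",
    "REFERENCE_ABC",
    "load_subset_definitions",
    "study_scenario",
    "cdc_scenario",
]

MARKER_CHANNELS = [
    "CD3", "CD19", "CD27", "CD45RA", "CD4", "CD8", "CD56", "CD16",
    "CD14", "CD11c", "CD123", "HLADR", "BDCA2",
]
#: channels gated with both a positivity and a hi/lo cutoff
THREE_LEVEL_CHANNELS = frozenset({"CD16", "CD56"})

VIABILITY_CHANNELS = ["AnnexinV", "7AAD"]
SCATTER_CHANNELS = ["FSC", "SSC"]
CIP_CHANNELS = ["CD46", "CD55", "CD59"]

#: grand-mean CD52 antigen density (ABC units) +- between-donor SD for the six
#: subsets with reported healthy-donor cohort averages; these anchor the synthetic cohort.
REFERENCE_ABC = {
    "Memory-B": (634_692.0, 68_919.0),
    "CD16lo-NK": (135_418.0, 43_632.0),
    "CD8-Effector": (205_559.0, 51_904.0),
    "CD16pos-Mono": (481_083.0, 137_931.0),
    "CD16pos-mDC": (434_011.0, 129_432.0),
    "Basophils": (72_308.0, 30_230.0),
}


def load_subset_definitions() -> list[SubsetDefinition]:
    """Load the shipped subset-definition file (users may ship their own)."""
    text = resources.files("cytoabc.data").joinpath("pbmc_subsets.yaml").read_text()
    raw = yaml.safe_load(text)
    return [
        SubsetDefinition(name=s["name"], predicates=dict(s["predicates"]),
                         lineage=s.get("lineage", ""))
        for s in raw["subsets"]
    ]


# name, lineage, frequency, abc_mean, abc_sd  (means without a reported value
# are interpolations consistent with the observed expression hierarchy)
_SUBSET_TABLE = [
    ("Naive-B",      "lymphoid", 0.060, 430_000.0,  70_000.0),
    ("Memory-B",     "lymphoid", 0.040, *REFERENCE_ABC["Memory-B"]),
    ("CD4-Naive",    "lymphoid", 0.150, 380_000.0,  70_000.0),
    ("CD4-CM",       "lymphoid", 0.100, 400_000.0,  70_000.0),
    ("CD4-EM",       "lymphoid", 0.060, 390_000.0,  70_000.0),
    ("CD4-Effector", "lymphoid", 0.020, 290_000.0,  60_000.0),
    ("CD8-Naive",    "lymphoid", 0.080, 340_000.0,  65_000.0),
    ("CD8-CM",       "lymphoid", 0.040, 310_000.0,  62_000.0),
    ("CD8-EM",       "lymphoid", 0.040, 280_000.0,  60_000.0),
    ("CD8-Effector", "lymphoid", 0.040, *REFERENCE_ABC["CD8-Effector"]),
    ("CD16lo-NK",    "lymphoid", 0.020, *REFERENCE_ABC["CD16lo-NK"]),
    ("CD16hi-NK",    "lymphoid", 0.080, 150_000.0,  45_000.0),
    ("CD16pos-Mono", "myeloid",  0.030, *REFERENCE_ABC["CD16pos-Mono"]),
    ("CD16neg-Mono", "myeloid",  0.100, 260_000.0,  60_000.0),
    ("CD16pos-mDC",  "myeloid",  0.005, *REFERENCE_ABC["CD16pos-mDC"]),
    ("CD16neg-mDC",  "myeloid",  0.015, 230_000.0,  55_000.0),
    ("pDC",          "myeloid",  0.005, 130_000.0,  30_000.0),
    ("Basophils",    "myeloid",  0.010, *REFERENCE_ABC["Basophils"]),
]

# complement-inhibitory-protein median MFI per subset (CD46, CD55, CD59):
# myeloid >> lymphoid, basophils highest, monocyte CD59 close to lymphocytes.
_CIP_LYMPHOID = {"CD46": 300.0, "CD55": 300.0, "CD59": 300.0}
_CIP_TABLE = {
    "Basophils":    {"CD46": 900.0, "CD55": 900.0, "CD59": 900.0},
    "CD16pos-Mono": {"CD46": 750.0, "CD55": 750.0, "CD59": 330.0},
    "CD16neg-Mono": {"CD46": 750.0, "CD55": 750.0, "CD59": 400.0},
    "CD16pos-mDC":  {"CD46": 450.0, "CD55": 600.0, "CD59": 400.0},
    "CD16neg-mDC":  {"CD46": 450.0, "CD55": 600.0, "CD59": 400.0},
    "pDC":          {"CD46": 350.0, "CD55": 350.0, "CD59": 350.0},
}

#: CIP-mediated protection from complement lysis (fraction of lysis removed)
DEFAULT_PROTECTION = {
    "CD16pos-Mono": 0.85,
    "CD16neg-Mono": 0.85,
    "CD16pos-mDC": 0.85,
    "CD16neg-mDC": 0.85,
    "Basophils": 0.5,
}

#: bimodal CD52 populations: bright fraction, bright and dim component means
DEFAULT_BIMODAL = {
    "Naive-B": BimodalSpec(frac_hi=0.60, abc_hi=430_000.0, abc_lo=86_000.0),
    "pDC": BimodalSpec(frac_hi=0.75, abc_hi=130_000.0, abc_lo=32_500.0),
}


def _subset_specs() -> list[SubsetSpec]:
    defs = {d.name: d for d in load_subset_definitions()}
    specs = []
    for name, lineage, freq, mean, sd in _SUBSET_TABLE:
        specs.append(SubsetSpec(
            name=name,
            lineage=lineage,
            frequency=freq,
            profile=dict(defs[name].predicates),
            abc_mean=mean,
            abc_sd=sd,
            cip=dict(_CIP_TABLE.get(name, _CIP_LYMPHOID)),
        ))
    return specs


def study_scenario(n_donors: int = 22, events_per_subset: int = 5000,
                   seed: int = 1) -> SimulationConfig:
    """The quantitation cohort: equal event depth per subset, 22 donors."""
    return SimulationConfig(
        subsets=_subset_specs(),
        n_donors=n_donors,
        events_per_subset=events_per_subset,
        composition="fixed",
        bimodal=dict(DEFAULT_BIMODAL),
        cdc=CDCModelParams(cip_protection=dict(DEFAULT_PROTECTION)),
        seed=seed,
    ).validate()


def cdc_scenario(n_donors: int = 4, total_events: int = 40_000,
                 seed: int = 1) -> SimulationConfig:
    """The cytolysis assay: frequency-driven wells, antigen density fixed at
    the cohort means (the assay models the average donor, not cohort spread)."""
    cfg = study_scenario(n_donors=n_donors, seed=seed)
    cfg.composition = "multinomial"
    cfg.total_events = total_events
    cfg.donor_sd_scale = 0.0
    return cfg.validate()
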