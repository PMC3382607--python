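"""Reference-study runners: the full quantitation and cytolysis experiments.

These convenience entry points execute the pipeline the way the reference
experimental design does — a 22-donor bead-calibrated quantitation cohort
and a 4-donor duplicate-well CDC comparison — and return the in-memory
results. They are what the acceptance script and the higher-level tests
drive; each stage remains individually accessible through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import CalibrationCurve, fit_calibration
from .cdc import CDCResult, depletion_table
from .config import SimulationConfig
from .events import EventTable
from .gating import assign_subsets, resolve_thresholds
from .panels import (MARKER_CHANNELS, THREE_LEVEL_CHANNELS, cdc_scenario,
                     load_subset_definitions, study_scenario)
from .quantify import HierarchyResult, QuantResult, aggregate_quant, quantify_abc, rank_hierarchy
from .simulate import generate_bead_set, generate_donor_events, simulate_cdc, spike_counting_beads

__all__ = ["QuantStudy", "run_quantitation_study", "run_cdc_study"]

_CDC_REPLICATES = 2
_CDC_BEADS = 2500


@dataclass
class QuantStudy:
    config: SimulationConfig
    curve: CalibrationCurve
    quant: QuantResult
    lymphoid: HierarchyResult
    myeloid: HierarchyResult


def run_quantitation_study(seed: int = 1, n_donors: int = 22,
                           events_per_subset: int = 5000,
                           config: SimulationConfig | None = None) -> QuantStudy:
    """Simulate the quantitation cohort and recover per-subset ABC.

    Calibration is fitted on a fresh simulated bead set; each donor is
    gated with density-valley thresholds resolved on that donor's own
    events, then quantified through the shared standard curve.
    """
    cfg = config if config is not None else study_scenario(
        n_donors=n_donors, events_per_subset=events_per_subset, seed=seed
    )
    curve = fit_calibration(generate_bead_set(cfg))
    definitions = load_subset_definitions()
    frames = []
    for d in range(cfg.n_donors):
        events = generate_donor_events(cfg, d)
        thresholds = resolve_thresholds(events, MARKER_CHANNELS + ["FSC"],
                                        three_level=THREE_LEVEL_CHANNELS)
        labels = assign_subsets(events, definitions, thresholds)
        frames.append(quantify_abc(events, labels, curve))
    quant = aggregate_quant(frames)
    scopes = {
        lineage: rank_hierarchy(
            quant, [d.name for d in definitions if d.lineage == lineage]
        )
        for lineage in ("lymphoid", "myeloid")
    }
    return QuantStudy(cfg, curve, quant, scopes["lymphoid"], scopes["myeloid"])


def run_cdc_study(seed: int = 1, n_donors: int = 4, total_events: int = 40_000,
                  alpha: float = 0.05,
                  config: SimulationConfig | None = None) -> CDCResult:
    """Simulate the duplicate-well CDC comparison and build the depletion
    table, pooling wells across donors (the assay fixes antigen density at
    the cohort means, so donor wells are genuine replicates)."""
    cfg = config if config is not None else cdc_scenario(
        n_donors=n_donors, total_events=total_events, seed=seed
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 29])
    )
    controls: list[EventTable] = []
    treateds: list[EventTable] = []
    for d in range(cfg.n_donors):
        base = generate_donor_events(cfg, d)
        for _ in range(_CDC_REPLICATES):
            for arm, bucket in (("control", controls), ("antibody", treateds)):
                well = simulate_cdc(base, cfg.cdc, arm, rng=rng)
                bucket.append(spike_counting_beads(well, _CDC_BEADS, cfg, rng=rng))
    return depletion_table(controls, treateds, load_subset_definitions(),
                           alpha=alpha, seed=seed)
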