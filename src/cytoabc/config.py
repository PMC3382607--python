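"""Simulation and run configuration types.

These dataclasses carry the full generative parameterization of a synthetic
quantitative-cytometry experiment: subset composition, per-subset CD52
antigen density (ABC units) with between-donor and within-donor variation,
the MFI transfer function, calibration-bead levels, the
complement-dependent-cytolysis (CDC) outcome model and counting-bead
spike-ins. Validation happens in :meth:`SimulationConfig.validate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import yaml

from .errors import ConfigurationError

__all__ = [
    "SubsetSpec",
    "BimodalSpec",
    "CDCModelParams",
    "SimulationConfig",
    "RunConfig",
]

#: simulated component medians for marker channels, linear intensity units
MARKER_LEVELS = {"-": 10.0, "lo": 200.0, "+": 1600.0, "hi": 3200.0}


@dataclass
class SubsetSpec:
    """One phenotypic subset: frequency, marker profile and CD52 truth.

    ``profile`` maps marker channel -> one of ``+ - hi lo``; channels not
    mentioned are simulated negative. ``abc_mean``/``abc_sd`` parameterize the
    between-donor normal for the subset's true antigen density; for subsets
    with a bimodal CD52 distribution they refer to the bright component and a
    :class:`BimodalSpec` supplies the rest.
    """

    name: str
    lineage: str  # "lymphoid" | "myeloid"
    frequency: float
    profile: dict
    abc_mean: float
    abc_sd: float
    cip: dict = field(default_factory=dict)  # CIP channel -> median MFI


@dataclass
class BimodalSpec:
    frac_hi: float
    abc_hi: float
    abc_lo: float


@dataclass
class CDCModelParams:
    """Phenomenological antigen-density-dependent lysis model.

    Per-event death probability under antibody treatment::

        p = bg + (max_lysis - bg) * logistic(slope * (ln ABC - ln threshold)) * (1 - prot)

    where ``prot`` is the subset's complement-inhibitory-protein protection,
    replaced by ``prot * (1 - blocking_efficiency)`` when CIP blocking
    antibodies are present. Under the control arm every event dies with
    probability ``background_death``. A fraction ``lysed_loss`` of necrotic
    cells disintegrates and leaves the event stream entirely, which is what
    produces the apparent enrichment of surviving subsets.
    """

    threshold_abc: float = 2.7e5
    slope: float = 9.0
    max_lysis: float = 0.95
    background_death: float = 0.16
    cip_protection: dict = field(default_factory=dict)
    blocking_efficiency: float = 0.9
    necrotic_fraction: float = 0.5
    lysed_loss: float = 0.35

    def validate(self) -> None:
        if self.threshold_abc <= 0:
            raise ConfigurationError("threshold_abc must be > 0")
        if self.slope < 0:
            raise ConfigurationError("slope must be >= 0")
        for name in ("max_lysis", "background_death", "blocking_efficiency",
                     "necrotic_fraction", "lysed_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for subset, frac in self.cip_protection.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"cip_protection[{subset!r}] must lie in [0, 1], got {frac}"
                )


@dataclass
class SimulationConfig:
    subsets: list
    n_donors: int = 22
    events_per_subset: int = 5000
    composition: str = "fixed"  # "fixed" | "multinomial"
    bimodal: dict = field(default_factory=dict)  # subset name -> BimodalSpec
    bead_abc_levels: tuple = (80_000.0, 160_000.0, 320_000.0, 640_000.0)
    bead_blank: bool = False
    bead_blank_mfi: float = 5.0
    bead_cv: float = 0.02
    bead_events_per_level: int = 2000
    total_events: int | None = None  # multinomial composition only
    within_donor_cv: float = 0.25
    fluorescence_cv: float = 0.05
    cip_donor_cv: float = 0.15
    cip_event_cv: float = 0.30
    marker_sigma10: float = 0.15  # log10 SD of marker-channel components
    donor_correlation: float = 0.9
    donor_sd_scale: float = 1.0  # 0 freezes donors at the subset means
    cohort_match: bool = True
    transfer_gain: float = 0.01
    transfer_exponent: float = 1.0
    cdc: CDCModelParams = field(default_factory=CDCModelParams)
    counting_bead_assigned: int = 25_000
    seed: int = 1

    def validate(self) -> "SimulationConfig":
        names = [s.name for s in self.subsets]
        if len(set(names)) != len(names):
            raise ConfigurationError("subset names must be unique")
        if self.n_donors <= 0:
            raise ConfigurationError("n_donors must be positive")
        if self.events_per_subset < 0:
            raise ConfigurationError("events_per_subset must be >= 0")
        if self.composition not in ("fixed", "multinomial"):
            raise ConfigurationError("composition must be 'fixed' or 'multinomial'")
        if self.total_events is not None and self.total_events < 0:
            raise ConfigurationError("total_events must be >= 0")
        total = sum(s.frequency for s in self.subsets)
        if total > 1.0 + 1e-9:
            raise ConfigurationError(f"subset frequencies sum to {total:.3f} > 1")
        for s in self.subsets:
            if s.frequency < 0:
                raise ConfigurationError(f"{s.name}: frequency must be >= 0")
            if s.abc_mean <= 0:
                raise ConfigurationError(f"{s.name}: abc_mean must be > 0")
            if s.abc_sd < 0:
                raise ConfigurationError(f"{s.name}: abc_sd must be >= 0")
            for ch, level in s.profile.items():
                if level not in MARKER_LEVELS:
                    raise ConfigurationError(
                        f"{s.name}: profile level {level!r} for {ch} not in +/-/hi/lo"
                    )
        for name, bm in self.bimodal.items():
            if name not in names:
                raise ConfigurationError(f"bimodal spec for unknown subset {name!r}")
            if not 0.0 <= bm.frac_hi <= 1.0:
                raise ConfigurationError(f"{name}: frac_hi must lie in [0, 1]")
            if bm.abc_lo <= 0 or bm.abc_hi <= bm.abc_lo:
                raise ConfigurationError(f"{name}: need 0 < abc_lo < abc_hi")
        levels = tuple(self.bead_abc_levels)
        if len(levels) < 2:
            raise ConfigurationError("calibration needs at least 2 bead ABC levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError("bead ABC levels must be strictly increasing")
        if any(v <= 0 for v in levels):
            raise ConfigurationError("bead ABC levels must be positive")
        for name in ("bead_cv", "within_donor_cv", "fluorescence_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.donor_correlation <= 1.0:
            raise ConfigurationError("donor_correlation must lie in [0, 1]")
        if self.transfer_gain <= 0 or self.transfer_exponent <= 0:
            raise ConfigurationError("transfer gain and exponent must be > 0")
        if self.counting_bead_assigned <= 0:
            raise ConfigurationError("counting_bead_assigned must be positive")
        self.cdc.validate()
        return self

    def subset(self, name: str) -> SubsetSpec:
        for s in self.subsets:
            if s.name == name:
                return s
        raise ConfigurationError(f"unknown subset name {name!r}")


@dataclass
class RunConfig:
    """End-to-end pipeline run: simulate (or ingest) -> reports."""

    mode: str = "simulate"  # "simulate" | "ingest"
    simulation: SimulationConfig | None = None
    input_paths: list = field(default_factory=list)
    alpha: float = 0.05
    seed: int = 1
    output_dir: str = "cytoabc_out"

    def validate(self) -> "RunConfig":
        if self.mode not in ("simulate", "ingest"):
            raise ConfigurationError("mode must be 'simulate' or 'ingest'")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode == "simulate":
            if self.simulation is None:
                raise ConfigurationError("simulate mode requires a simulation config")
            self.simulation.validate()
        else:
            missing = [p for p in self.input_paths if not __import__("os").path.exists(p)]
            if missing:
                raise ConfigurationError(f"ingest inputs do not exist: {missing}")
        return self


# ---------------------------------------------------------------------------
# YAML round trip (single structured text config file)
# ---------------------------------------------------------------------------

def run_config_to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=False)


def run_config_from_yaml(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    sim = raw.get("simulation")
    if sim is not None:
        sim = sim.copy()
        sim["subsets"] = [SubsetSpec(**s) for s in sim.get("subsets", [])]
        sim["bimodal"] = {k: BimodalSpec(**v) for k, v in (sim.get("bimodal") or {}).items()}
        if "bead_abc_levels" in sim:
            sim["bead_abc_levels"] = tuple(sim["bead_abc_levels"])
        if "cdc" in sim and sim["cdc"] is not None:
            sim["cdc"] = CDCModelParams(**sim["cdc"])
        raw = {**raw, "simulation": SimulationConfig(**sim)}
    return RunConfig(**raw).validate()
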