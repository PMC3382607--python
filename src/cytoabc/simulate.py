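"""Synthetic event-level cytometry data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without instrument data:

* each subset's true CD52 antigen density is drawn per donor from a normal
  with the configured between-donor mean/SD (optionally standardized so the
  synthetic cohort's sample mean/SD match the configured values exactly, and
  correlated across subsets through a shared donor factor — the expression
  hierarchy is consistent within donors);
* per-event antigen density is log-normal around the donor value with the
  within-donor CV, parameterized so the *median* equals the donor value;
* fluorescence = a power-law transfer of antigen density (MFI =
  gain * ABC^exponent, linear by default) times multiplicative log-normal
  measurement noise — the standard model for cytometry intensities;
* phenotyping markers are drawn from well-separated log-normal components
  (negative / positive, plus a dim "lo" component on hi/lo channels);
* calibration beads are one labelled population per assigned ABC level;
* complement-dependent cytolysis assigns per-event death by an
  antigen-density logistic, damped by complement-inhibitory-protein
  protection, and marks dead cells with Annexin-V/7-AAD signatures.

All randomness flows from ``SimulationConfig.seed``; per-donor streams are
derived deterministically from the donor index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MARKER_LEVELS, CDCModelParams, SimulationConfig
from .errors import ConfigurationError, ContractError
from .events import EventTable

__all__ = [
    "transfer",
    "donor_abc_table",
    "generate_donor_events",
    "generate_bead_set",
    "simulate_cdc",
    "spike_counting_beads",
]

# channels that only depend on the marker profile (not on antigen density)
_SCATTER = {"cell": (1000.0, 500.0), "debris": (30.0, 50.0), "bead": (800.0, 300.0)}
_BEAD_BRIGHT = 5e4
_VIABILITY_LO, _VIABILITY_HI = 20.0, 2000.0

# channels with three simulated components; a "+" profile renders at the hi
# component there so every channel has at most three well-separated modes
_THREE_LEVEL = {"CD16", "CD56"}


def transfer(abc, config: SimulationConfig):
    """Fluorescence transfer function: MFI = gain * ABC ** exponent."""
    return config.transfer_gain * np.asarray(abc, dtype=float) ** config.transfer_exponent


def _ln_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _lognoise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    return np.exp(_ln_sigma(cv) * rng.standard_normal(n))


def _donor_rng(config: SimulationConfig, stream: int, donor_index: int = 0
               ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream, donor_index])
    )


# ---------------------------------------------------------------------------
# donor-level truth
# ---------------------------------------------------------------------------

def donor_abc_table(config: SimulationConfig) -> pd.DataFrame:
    """True per-donor, per-subset CD52 density (donors x subsets, ABC units).

    A shared donor factor (weight ``donor_correlation``) makes subsets
    co-vary within donors; with ``cohort_match`` the columns are affinely
    standardized so the cohort sample mean/SD equal the configured values.
    Values are floored at 2% of the subset mean (no negative densities).
    """
    config.validate()
    rng = _donor_rng(config, stream=1)
    n_d, n_s = config.n_donors, len(config.subsets)
    rho = config.donor_correlation
    z_shared = rng.standard_normal(n_d)
    z_own = rng.standard_normal((n_d, n_s))
    w = np.sqrt(rho) * z_shared[:, None] + np.sqrt(1.0 - rho) * z_own
    if config.cohort_match and n_d >= 2:
        w = (w - w.mean(axis=0)) / np.where(w.std(axis=0, ddof=1) > 0,
                                            w.std(axis=0, ddof=1), 1.0)
    means = np.array([s.abc_mean for s in config.subsets])
    sds = np.array([s.abc_sd for s in config.subsets]) * config.donor_sd_scale
    values = means[None, :] + sds[None, :] * w
    values = np.maximum(values, 0.02 * means[None, :])
    return pd.DataFrame(values, columns=[s.name for s in config.subsets],
                        index=pd.RangeIndex(n_d, name="donor"))


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

def _panel_channels(config: SimulationConfig) -> list[str]:
    markers: list[str] = []
    cips: list[str] = []
    for s in config.subsets:
        markers += [c for c in s.profile if c not in markers]
        cips += [c for c in s.cip if c not in cips]
    return ["FSC", "SSC"] + markers + ["CD52"] + cips


def _marker_intensity(rng, level_key: str, channel: str, sigma10: float, n: int):
    if level_key == "+" and channel in _THREE_LEVEL:
        level_key = "hi"
    level = MARKER_LEVELS[level_key]
    if sigma10 == 0.0:
        return np.full(n, level)
    return level * 10.0 ** (sigma10 * rng.standard_normal(n))


def _subset_counts(config: SimulationConfig, rng) -> dict[str, int]:
    debris_frac = max(0.0, 1.0 - sum(s.frequency for s in config.subsets))
    if config.composition == "fixed":
        counts = {s.name: config.events_per_subset for s in config.subsets}
        total = config.events_per_subset * len(config.subsets)
        counts["debris"] = (
            int(round(total * debris_frac / (1.0 - debris_frac)))
            if debris_frac < 1.0 else 0
        )
        return counts
    total = (config.total_events if config.total_events is not None
             else config.events_per_subset * len(config.subsets))
    probs = [s.frequency for s in config.subsets] + [debris_frac]
    draw = rng.multinomial(total, np.asarray(probs) / sum(probs))
    counts = {s.name: int(c) for s, c in zip(config.subsets, draw[:-1])}
    counts["debris"] = int(draw[-1])
    return counts


def generate_donor_events(config: SimulationConfig, donor_index: int) -> EventTable:
    """Simulate one donor's stained PBMC sample.

    Every event carries a hidden truth label (subset name or ``debris``) and,
    for cell events, its generative antigen density in ABC units.
    """
    config.validate()
    if not 0 <= donor_index < config.n_donors:
        raise ConfigurationError(
            f"donor_index {donor_index} outside 0..{config.n_donors - 1}"
        )
    rng = _donor_rng(config, stream=2, donor_index=donor_index)
    donor_truth = donor_abc_table(config).iloc[donor_index]
    channels = _panel_channels(config)
    counts = _subset_counts(config, rng)

    blocks: list[pd.DataFrame] = []
    labels: list[np.ndarray] = []
    truth: list[np.ndarray] = []
    sigma_w = _ln_sigma(config.within_donor_cv)

    for spec in config.subsets:
        n = counts[spec.name]
        cols = {}
        cols["FSC"] = _marker_intensity(rng, "+", "FSC", 0.05, n) / MARKER_LEVELS["+"] \
            * _SCATTER["cell"][0]
        cols["SSC"] = _SCATTER["cell"][1] * 10.0 ** (0.05 * rng.standard_normal(n))
        for ch in channels:
            if ch in ("FSC", "SSC", "CD52") or ch in spec.cip:
                continue
            cols[ch] = _marker_intensity(
                rng, spec.profile.get(ch, "-"), ch, config.marker_sigma10, n
            )
        # per-event antigen density (median = donor truth)
        donor_abc = float(donor_truth[spec.name])
        if spec.name in config.bimodal:
            bm = config.bimodal[spec.name]
            mult = donor_abc / spec.abc_mean
            comp_hi = rng.random(n) < bm.frac_hi
            base = np.where(comp_hi, bm.abc_hi * mult, bm.abc_lo * mult)
        else:
            base = np.full(n, donor_abc)
        abc_event = base * (np.exp(sigma_w * rng.standard_normal(n))
                            if config.within_donor_cv else 1.0)
        cols["CD52"] = transfer(abc_event, config) * _lognoise(
            rng, config.fluorescence_cv, n
        )
        for ch, med in spec.cip.items():
            donor_mult = float(_lognoise(rng, config.cip_donor_cv, 1)[0])
            cols[ch] = med * donor_mult * _lognoise(rng, config.cip_event_cv, n)
        blocks.append(pd.DataFrame(cols))
        labels.append(np.full(n, spec.name, dtype=object))
        truth.append(abc_event)

    n_debris = counts["debris"]
    if n_debris:
        cols = {ch: _marker_intensity(rng, "-", ch, config.marker_sigma10, n_debris)
                for ch in channels if ch not in ("FSC", "SSC", "CD52")}
        cols["FSC"] = _SCATTER["debris"][0] * 10.0 ** (0.1 * rng.standard_normal(n_debris))
        cols["SSC"] = _SCATTER["debris"][1] * 10.0 ** (0.1 * rng.standard_normal(n_debris))
        cols["CD52"] = transfer(2000.0, config) * _lognoise(
            rng, max(config.fluorescence_cv, 0.3), n_debris
        )
        blocks.append(pd.DataFrame(cols))
        labels.append(np.full(n_debris, "debris", dtype=object))
        truth.append(np.full(n_debris, np.nan))

    if not blocks or sum(len(b) for b in blocks) == 0:
        table = EventTable.empty(channels)
        table.labels = pd.Series([], dtype=object)
        table.truth_abc = pd.Series([], dtype=float)
    else:
        data = pd.concat(blocks, ignore_index=True)[channels]
        table = EventTable(
            data,
            labels=pd.Series(np.concatenate(labels)),
            truth_abc=pd.Series(np.concatenate(truth)),
        )
    table.metadata.update(donor_id=int(donor_index), seed=int(config.seed))
    return table


def generate_bead_set(config: SimulationConfig) -> EventTable:
    """Calibration-bead acquisition: one labelled population per ABC level."""
    config.validate()
    rng = _donor_rng(config, stream=3)
    levels = list(config.bead_abc_levels)
    n = config.bead_events_per_level
    frames, labels = [], []
    for i, abc in enumerate(levels):
        mfi = transfer(abc, config) * _lognoise(rng, config.bead_cv, n)
        frames.append(pd.DataFrame({"CD52": mfi}))
        labels.append(np.full(n, f"bead_{i}", dtype=object))
    if config.bead_blank:
        mfi = config.bead_blank_mfi * _lognoise(rng, max(config.bead_cv, 0.2), n)
        frames.append(pd.DataFrame({"CD52": mfi}))
        labels.append(np.full(n, "blank", dtype=object))
    table = EventTable(pd.concat(frames, ignore_index=True),
                       labels=pd.Series(np.concatenate(labels)))
    table.metadata.update(
        bead_abc_levels=[float(v) for v in levels], seed=int(config.seed)
    )
    table.truth_abc = pd.Series(
        np.concatenate([np.full(n, float(abc)) for abc in levels]
                       + ([np.full(n, 0.0)] if config.bead_blank else []))
    )
    return table


# ---------------------------------------------------------------------------
# complement-dependent cytolysis
# ---------------------------------------------------------------------------

def death_probability(abc: np.ndarray, params: CDCModelParams,
                      protection: np.ndarray | float = 0.0,
                      blocking: bool = False) -> np.ndarray:
    """Antibody-arm per-event death probability (closed form of the model)."""
    abc = np.asarray(abc, dtype=float)
    prot = np.asarray(protection, dtype=float)
    if blocking:
        prot = prot * (1.0 - params.blocking_efficiency)
    with np.errstate(divide="ignore"):
        logit = params.slope * (np.log(abc) - np.log(params.threshold_abc))
    lysis = 1.0 / (1.0 + np.exp(-logit))
    lysis = np.where(np.isnan(abc), 0.0, lysis)
    bg = params.background_death
    return bg + (params.max_lysis - bg) * lysis * (1.0 - prot)


def simulate_cdc(events: EventTable, params: CDCModelParams,
                 treatment: str = "antibody", blocking: bool = False,
                 rng: np.random.Generator | int | None = None) -> EventTable:
    """Expose a stained sample to antibody + complement (or control IgG).

    Adds Annexin-V and 7-AAD channels; dead events split into necrotic
    (both dyes high) and apoptotic (Annexin-V high only) signatures. A
    fraction ``params.lysed_loss`` of necrotic cells disintegrates and is
    removed from the event stream — the survivors are thereby enriched.
    """
    params.validate()
    if treatment not in ("antibody", "control"):
        raise ConfigurationError("treatment must be 'antibody' or 'control'")
    if events.truth_abc is None:
        raise ContractError("simulate_cdc needs per-event truth ABC "
                            "(synthetic tables carry it; see EventTable.truth_abc)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n = events.n_events
    labels = (events.labels.to_numpy() if events.labels is not None
              else np.full(n, "unlabelled", dtype=object))
    if treatment == "antibody":
        prot = np.array([params.cip_protection.get(l, 0.0) for l in labels])
        p = death_probability(events.truth_abc.to_numpy(), params, prot, blocking)
    else:
        p = np.full(n, params.background_death)

    dead = rng.random(n) < p
    necrotic = dead & (rng.random(n) < params.necrotic_fraction)
    lysed = necrotic & (rng.random(n) < params.lysed_loss)

    sigma10 = 0.15
    annexin = np.where(dead, _VIABILITY_HI, _VIABILITY_LO) \
        * 10.0 ** (sigma10 * rng.standard_normal(n))
    aad = np.where(necrotic, _VIABILITY_HI, _VIABILITY_LO) \
        * 10.0 ** (sigma10 * rng.standard_normal(n))

    data = events.data.copy()
    data["AnnexinV"] = annexin
    data["7AAD"] = aad
    out = EventTable(data, dict(events.metadata),
                     labels=None if events.labels is None else events.labels.copy(),
                     truth_abc=events.truth_abc.copy())
    out.metadata.update(treatment=treatment, cip_blocking=bool(blocking))
    keep = ~lysed
    return out.select(keep)


def spike_counting_beads(events: EventTable, n_bead_events: int,
                         config: SimulationConfig,
                         rng: np.random.Generator | int | None = None) -> EventTable:
    """Append counting-bead events with the lot's assigned count in metadata.

    Beads are bright in every stain channel (in particular both CD3 and CD19,
    a combination no cell shows) with intermediate scatter, so they are
    separable by gating alone.
    """
    if n_bead_events < 0:
        raise ConfigurationError("n_bead_events must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = EventTable(events.data.copy(), dict(events.metadata),
                     labels=None if events.labels is None else events.labels.copy(),
                     truth_abc=None if events.truth_abc is None else events.truth_abc.copy())
    out.metadata["counting_bead_assigned"] = int(config.counting_bead_assigned)
    if n_bead_events == 0:
        return out
    n = n_bead_events
    cols = {}
    for ch in out.channels:
        if ch == "FSC":
            cols[ch] = _SCATTER["bead"][0] * 10.0 ** (0.03 * rng.standard_normal(n))
        elif ch == "SSC":
            cols[ch] = _SCATTER["bead"][1] * 10.0 ** (0.03 * rng.standard_normal(n))
        elif ch in ("AnnexinV", "7AAD"):
            cols[ch] = _VIABILITY_LO * 10.0 ** (0.1 * rng.standard_normal(n))
        else:
            cols[ch] = _BEAD_BRIGHT * 10.0 ** (0.05 * rng.standard_normal(n))
    beads = EventTable(pd.DataFrame(cols)[out.channels],
                       labels=pd.Series(np.full(n, "bead", dtype=object)),
                       truth_abc=pd.Series(np.full(n, np.nan)))
    return out.concat(beads)
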