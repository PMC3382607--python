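"""Boolean phenotypic gating of cytometry events.

Manual workflows place gates by eye; this module replaces manual gate
placement with reproducible density-valley thresholds so assignments are
deterministic and testable against simulator truth. For each channel the
positivity cutoff sits at the kernel-density valley between the two largest
modes of log-intensity; channels gated hi/lo (CD16, CD56) get a secondary
cutoff from the next valley. Events exactly at a cutoff classify
negative/lo (lower-closed intervals).

Subset definitions are boolean marker predicates (one per phenotype row);
they are checked for pairwise logical disjointness at load time and again on
the actual events at assignment time — ambiguity is an error, never silently
resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import density_peaks, kmeans1d, log_density
from .errors import ConfigurationError, ContractError
from .events import EventTable

__all__ = [
    "SubsetDefinition",
    "ChannelThreshold",
    "ThresholdSet",
    "resolve_thresholds",
    "check_disjoint",
    "assign_subsets",
    "split_bimodal",
    "BimodalSplit",
]

_VALID_PREDICATES = ("+", "-", "hi", "lo")


@dataclass
class SubsetDefinition:
    name: str
    predicates: dict
    lineage: str = ""
    parent_gate: str | None = None

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ConfigurationError(f"{self.name}: predicates must be non-empty")
        bad = {c: p for c, p in self.predicates.items() if p not in _VALID_PREDICATES}
        if bad:
            raise ConfigurationError(f"{self.name}: invalid predicates {bad}")


@dataclass
class ChannelThreshold:
    positivity: float
    hi: float | None = None
    method: str = "density-valley"
    unimodal: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.positivity) or self.positivity <= 0:
            raise ConfigurationError("positivity cutoff must be finite and positive")
        if self.hi is not None and self.hi <= self.positivity:
            raise ConfigurationError("hi cutoff must exceed the positivity cutoff")


@dataclass
class ThresholdSet:
    channels: dict = field(default_factory=dict)  # channel -> ChannelThreshold

    def __getitem__(self, channel: str) -> ChannelThreshold:
        if channel not in self.channels:
            raise ContractError(f"no threshold resolved for channel {channel!r}")
        return self.channels[channel]

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels


# ---------------------------------------------------------------------------
# threshold resolution
# ---------------------------------------------------------------------------

def _valley(grid: np.ndarray, dens: np.ndarray, i: int, j: int) -> int:
    """Deepest point between two modes; the centre of a flat minimum run.

    Well-separated components leave a plateau of near-zero density between
    them — every plateau point is a minimum, and the centre is the stable,
    symmetric choice.
    """
    seg = dens[i:j + 1]
    lo = seg.min()
    tol = lo + 1e-9 * max(dens[i], dens[j])
    flat = np.flatnonzero(seg <= tol)
    return i + int(flat[(len(flat) - 1) // 2])


def resolve_thresholds(events: EventTable, panel: list[str],
                       three_level: frozenset | set = frozenset(),
                       unimodal_quantile: float = 0.99,
                       min_events: int = 1000) -> ThresholdSet:
    """Place per-channel cutoffs at density valleys of log-intensity.

    ``three_level`` names channels that need both a positivity and a hi/lo
    cutoff. Unimodal channels are flagged and cut at ``unimodal_quantile`` of
    the single mode, with a warning. If the expected number of modes is not
    resolvable from the density, the fallback is midpoints between 1-D
    cluster centers (method tag ``"kmeans-midpoint"``).
    """
    if events.n_events < min_events:
        raise ContractError(
            f"threshold resolution needs >= {min_events} events, got {events.n_events}"
        )
    out = ThresholdSet()
    for channel in panel:
        x = events.intensities(channel)
        n_levels = 3 if channel in three_level else 2
        grid, dens = log_density(x)
        peaks = density_peaks(grid, dens)
        if len(peaks) >= n_levels:
            # keep the n_levels tallest modes, in position order
            top = np.sort(peaks[np.argsort(dens[peaks])[::-1][:n_levels]])
            cuts = [
                10.0 ** grid[_valley(grid, dens, a, b)]
                for a, b in zip(top[:-1], top[1:])
            ]
            out.channels[channel] = ChannelThreshold(
                positivity=cuts[0],
                hi=cuts[1] if n_levels == 3 else None,
            )
        elif len(peaks) <= 1:
            cut = float(np.quantile(x, unimodal_quantile))
            warnings.warn(
                f"channel {channel}: unimodal intensity distribution; cutoff "
                f"placed at the {unimodal_quantile:.2f} quantile", stacklevel=2,
            )
            out.channels[channel] = ChannelThreshold(
                positivity=max(cut, np.finfo(float).tiny),
                hi=None if n_levels == 2 else max(cut * 4, cut + 1.0),
                method="quantile", unimodal=True,
            )
        else:
            lx = np.log10(np.clip(x, 1e-6, None))
            centers = kmeans1d(lx, n_levels)
            mids = 10.0 ** (0.5 * (centers[:-1] + centers[1:]))
            out.channels[channel] = ChannelThreshold(
                positivity=float(mids[0]),
                hi=float(mids[1]) if n_levels == 3 else None,
                method="kmeans-midpoint",
            )
    return out


def resolve_sample_thresholds(events: EventTable, panel: list[str],
                              three_level: frozenset | set = frozenset(),
                              bead_channels: tuple[str, str] = ("CD3", "CD19"),
                              ) -> ThresholdSet:
    """Two-pass threshold resolution for samples that may contain counting
    beads.

    Beads fluoresce brightly in every stain channel and would add a spurious
    mode to each density; a first pass on the two bead-identifying channels
    removes them, then cutoffs are placed on the cell events alone. The
    returned thresholds still classify beads correctly downstream (bead
    intensities sit far above any cell-derived cutoff).
    """
    cells = events
    if all(c in events.data.columns for c in bead_channels):
        pre = resolve_thresholds(events, list(bead_channels))
        a, b = bead_channels
        bead = ((events.intensities(a) > pre[a].positivity)
                & (events.intensities(b) > pre[b].positivity))
        if bead.any():
            cells = events.select(~bead)
    return resolve_thresholds(cells, panel, three_level=three_level)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _incompatible(p: str, q: str) -> bool:
    if p == q:
        return False
    pair = {p, q}
    # "+" overlaps both the lo and the hi interval, so it only conflicts with "-"
    return "-" in pair or pair == {"lo", "hi"}


def check_disjoint(definitions: list[SubsetDefinition]) -> None:
    """Raise unless every pair of definitions conflicts on some channel."""
    for i, a in enumerate(definitions):
        for b in definitions[i + 1:]:
            shared = set(a.predicates) & set(b.predicates)
            if not any(_incompatible(a.predicates[c], b.predicates[c]) for c in shared):
                raise ConfigurationError(
                    f"subset definitions {a.name!r} and {b.name!r} are not "
                    "logically disjoint under the panel"
                )


def _predicate_mask(x: np.ndarray, pred: str, thr: ChannelThreshold,
                    channel: str) -> np.ndarray:
    if pred == "+":
        return x > thr.positivity
    if pred == "-":
        return x <= thr.positivity
    if thr.hi is None:
        raise ConfigurationError(
            f"channel {channel}: predicate {pred!r} needs a hi/lo cutoff"
        )
    if pred == "hi":
        return x > thr.hi
    return (x > thr.positivity) & (x <= thr.hi)  # "lo"


def assign_subsets(events: EventTable, definitions: list[SubsetDefinition],
                   thresholds: ThresholdSet,
                   scatter_channel: str | None = "FSC",
                   bead_channels: tuple[str, str] | None = ("CD3", "CD19"),
                   ) -> pd.Series:
    """Assign each event to a unique subset (or bead / debris / unassigned).

    Counting beads are recognised first (bright in two mutually exclusive
    lineage channels — no cell is CD3+CD19+), then low-scatter debris is
    removed, then the boolean definitions are applied. Overlapping
    definitions raise, naming the colliding pair.
    """
    check_disjoint(definitions)
    n = events.n_events
    labels = pd.Series(["unassigned"] * n, index=events.data.index, dtype=object)
    free = np.ones(n, dtype=bool)

    if bead_channels and all(c in events.data.columns and c in thresholds
                             for c in bead_channels):
        a, b = bead_channels
        bead = ((events.intensities(a) > thresholds[a].positivity)
                & (events.intensities(b) > thresholds[b].positivity))
        labels[bead] = "bead"
        free &= ~bead
    if scatter_channel and scatter_channel in events.data.columns \
            and scatter_channel in thresholds:
        debris = events.intensities(scatter_channel) <= thresholds[scatter_channel].positivity
        debris &= free
        labels[debris] = "debris"
        free &= ~debris

    owner = np.full(n, -1)
    for k, d in enumerate(definitions):
        mask = free.copy()
        for channel, pred in d.predicates.items():
            if channel not in events.data.columns:
                raise ConfigurationError(
                    f"{d.name}: channel {channel!r} referenced but absent from panel"
                )
            mask &= _predicate_mask(events.intensities(channel), pred,
                                    thresholds[channel], channel)
            if not mask.any():
                break
        clash = mask & (owner >= 0)
        if clash.any():
            other = definitions[int(owner[clash][0])].name
            raise ConfigurationError(
                f"subset definitions {d.name!r} and {other!r} both match "
                f"{int(clash.sum())} event(s)"
            )
        owner[mask] = k
        labels[mask] = d.name
    return labels


# ---------------------------------------------------------------------------
# bimodal marker splitting
# ---------------------------------------------------------------------------

@dataclass
class BimodalSplit:
    labels: pd.Series  # "hi" / "lo", or "single" when not bimodal
    bimodal: bool
    cutoff: float | None
    score: float


def split_bimodal(events: EventTable, labels: pd.Series, subset: str,
                  channel: str = "CD52", min_events: int = 200,
                  score_threshold: float = 0.3) -> BimodalSplit:
    """Split one subset's events into marker-bright/-dim components.

    The split sits at the density valley between the two largest log-intensity
    modes. The bimodality score is the valley depth, ``1 - valley_density /
    min(mode heights)`` — 0 for a flat saddle, -> 1 for fully separated modes;
    the subset is called bimodal when the score exceeds ``score_threshold``.
    """
    mask = np.asarray(labels) == subset
    x = events.intensities(channel)[mask]
    if len(x) < min_events:
        warnings.warn(
            f"{subset}: only {len(x)} events (< {min_events}); bimodal split skipped",
            stacklevel=2,
        )
        return BimodalSplit(pd.Series([], dtype=object), False, None, 0.0)
    grid, dens = log_density(x)
    peaks = density_peaks(grid, dens, min_rel_height=0.02)
    single = pd.Series(["single"] * len(x))
    if len(peaks) < 2:
        return BimodalSplit(single, False, None, 0.0)
    top = np.sort(peaks[np.argsort(dens[peaks])[::-1][:2]])
    v = _valley(grid, dens, top[0], top[1])
    score = 1.0 - dens[v] / min(dens[top[0]], dens[top[1]])
    if score < score_threshold:
        return BimodalSplit(single, False, None, float(score))
    cutoff = 10.0 ** grid[v]
    out = pd.Series(np.where(x > cutoff, "hi", "lo"))
    return BimodalSplit(out, True, float(cutoff), float(score))
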