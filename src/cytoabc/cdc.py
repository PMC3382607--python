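"""Complement-dependent cytolysis outcome analysis.

Viability is a quadrant classification on Annexin-V x 7-AAD: necrotic =
7-AAD positive (regardless of Annexin-V — membrane-compromised cells count
as dead either way), apoptotic = Annexin-V positive and 7-AAD negative,
live = double negative. Total lysis is the apoptotic plus necrotic
percentage of gated cells.

Absolute cell concentrations come from counting-bead ratios::

    cells / 100 ul = cell events x assigned bead count / bead events

Treated-vs-control depletion is assessed per subset on live-cell absolute
counts after seeded down-sampling of every well to equal gated-cell depth
(the software-concatenation normalization of the assay), with Welch's
unequal-variance t on replicate wells at a configurable alpha. Holm-adjusted
p-values are reported alongside but the primary flags are unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CDCModelParams
from .errors import ContractError
from .events import EventTable
from .gating import (SubsetDefinition, ThresholdSet, assign_subsets,
                     resolve_sample_thresholds, resolve_thresholds)
from .simulate import simulate_cdc

__all__ = [
    "classify_viability",
    "viability_percentages",
    "percent_lysis",
    "absolute_count",
    "depletion_table",
    "CDCResult",
    "purified_population_cdc",
]

_GATE_EXCLUDE = {"bead", "debris"}


def classify_viability(events: EventTable, thresholds: ThresholdSet) -> pd.Series:
    """Per-event live / apoptotic / necrotic quadrant call."""
    for ch in ("AnnexinV", "7AAD"):
        if ch not in events.data.columns:
            raise ContractError(f"viability channel {ch!r} missing from events")
        if ch not in thresholds:
            raise ContractError(f"no threshold resolved for viability channel {ch!r}")
    annexin = events.intensities("AnnexinV") > thresholds["AnnexinV"].positivity
    aad = events.intensities("7AAD") > thresholds["7AAD"].positivity
    out = np.where(aad, "necrotic", np.where(annexin, "apoptotic", "live"))
    return pd.Series(out, index=events.data.index)


def viability_percentages(viability: pd.Series) -> dict:
    """%live / %apoptotic / %necrotic of gated cells; sums to 100 exactly."""
    n = len(viability)
    if n == 0:
        raise ContractError("no gated cells: viability percentages undefined")
    counts = viability.value_counts()
    # percentages are quantized to multiples of 2^-20 of a point (~1e-6, far
    # below reportable precision); dyadic values this size add without
    # rounding in float64, so %live + %apoptotic + %necrotic == 100 and
    # %lysis == %apoptotic + %necrotic hold exactly, not just approximately
    q = 2.0 ** 20
    pct = {f"pct_{k}": round(100.0 * counts.get(k, 0) / n * q) / q
           for k in ("apoptotic", "necrotic")}
    pct["pct_lysis"] = pct["pct_apoptotic"] + pct["pct_necrotic"]
    pct["pct_live"] = 100.0 - pct["pct_lysis"]
    return pct


def percent_lysis(viability: pd.Series) -> float:
    """Total lysis: 100 x (apoptotic + necrotic) / gated cells."""
    return viability_percentages(viability)["pct_lysis"]


def absolute_count(n_cell_events: int, n_bead_events: int,
                   assigned_bead_count: int) -> float:
    """Counting-bead absolute concentration (cells per 100 ul of sample)."""
    if min(n_cell_events, n_bead_events, assigned_bead_count) < 0:
        raise ContractError("counts must be non-negative")
    if n_bead_events == 0:
        raise ContractError(
            "no counting-bead events gated: absolute counts are undefined. "
            "Check the bead gate or re-acquire with beads added."
        )
    return n_cell_events * assigned_bead_count / n_bead_events


# ---------------------------------------------------------------------------
# treated-vs-control depletion
# ---------------------------------------------------------------------------

@dataclass
class CDCResult:
    viability: pd.DataFrame  # one row per well: arm, replicate, percentages
    counts: pd.DataFrame     # per subset: mean counts, Welch t, p, flag
    alpha: float
    n_downsampled: int


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    adj = np.empty_like(pvals)
    running = 0.0
    m = len(pvals)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _panel_for(definitions: list[SubsetDefinition], events: EventTable) -> list[str]:
    chans: list[str] = []
    for d in definitions:
        chans += [c for c in d.predicates if c not in chans]
    for extra in ("FSC", "AnnexinV", "7AAD"):
        if extra in events.data.columns and extra not in chans:
            chans.append(extra)
    return chans


def _well_stats(table: EventTable, definitions, thresholds, rng) -> dict:
    labels = assign_subsets(table, definitions, thresholds)
    lab = np.asarray(labels)
    n_beads = int((lab == "bead").sum())
    gated = ~np.isin(lab, list(_GATE_EXCLUDE))
    return {"table": table, "labels": lab, "gated": gated, "n_beads": n_beads,
            "rng": rng}


def depletion_table(controls, treateds, definitions: list[SubsetDefinition],
                    thresholds: ThresholdSet | None = None,
                    alpha: float = 0.05, seed: int = 0) -> CDCResult:
    """Per-subset absolute live counts, control vs antibody arm.

    ``controls``/``treateds`` are replicate wells (single tables accepted).
    Every well is down-sampled (without replacement, seeded) to the smallest
    gated-cell depth so arms are compared at equal event numbers; counting
    beads are exempt from down-sampling. With a single well per arm, counts
    are reported and the tests are skipped with a warning.
    """
    controls = [controls] if isinstance(controls, EventTable) else list(controls)
    treateds = [treateds] if isinstance(treateds, EventTable) else list(treateds)
    if not controls or not treateds:
        raise ContractError("need at least one well per arm")
    wells = [("control", i, t) for i, t in enumerate(controls)] \
        + [("antibody", i, t) for i, t in enumerate(treateds)]
    for _, _, t in wells:
        if "counting_bead_assigned" not in t.metadata:
            raise ContractError("wells must carry counting-bead metadata "
                                "(spike_counting_beads records it)")
    if thresholds is None:
        pooled = wells[0][2]
        for _, _, t in wells[1:]:
            pooled = pooled.concat(t)
        thresholds = resolve_sample_thresholds(
            pooled, _panel_for(definitions, pooled),
            three_level={"CD16", "CD56"},
        )

    # down-sampling streams are paired by replicate index across arms, so
    # identical paired wells down-sample identically (zero spurious depletion)
    stats_by_well = [
        _well_stats(t, definitions, thresholds,
                    np.random.default_rng(
                        np.random.SeedSequence([seed & 0x7FFFFFFF, 17, rep])))
        for arm, rep, t in wells
    ]
    n_min = min(int(s["gated"].sum()) for s in stats_by_well)
    if n_min == 0:
        raise ContractError("a well has no gated cells")

    via_rows = []
    counts_acc: dict[str, dict[str, list]] = {
        d.name: {"control": [], "antibody": []} for d in definitions
    }
    for (arm, rep, table), s in zip(wells, stats_by_well):
        gated_idx = np.flatnonzero(s["gated"])
        keep = s["rng"].choice(gated_idx, size=n_min, replace=False)
        keep.sort()
        sub = table.select(keep)
        sub_labels = pd.Series(s["labels"][keep])
        viability = classify_viability(sub, thresholds)
        pct = viability_percentages(viability)
        via_rows.append({"arm": arm, "replicate": rep, "n_gated": n_min, **pct})
        live = np.asarray(viability) == "live"
        assigned = int(table.metadata["counting_bead_assigned"])
        for d in definitions:
            n_live = int(((np.asarray(sub_labels) == d.name) & live).sum())
            counts_acc[d.name][arm].append(
                absolute_count(n_live, s["n_beads"], assigned)
            )

    can_test = len(controls) >= 2 and len(treateds) >= 2
    if not can_test:
        warnings.warn("fewer than 2 replicate wells per arm: counts reported, "
                      "tests skipped", stacklevel=2)
    rows = []
    for name, acc in counts_acc.items():
        c = np.asarray(acc["control"], dtype=float)
        t = np.asarray(acc["antibody"], dtype=float)
        row = {
            "subset": name,
            "control_mean": c.mean(),
            "treated_mean": t.mean(),
            "difference": t.mean() - c.mean(),
        }
        if can_test:
            with warnings.catch_warnings():
                # identical replicate counts trip scipy's precision-loss
                # warning; the resulting t=0 / p=1 is exactly what we want
                warnings.filterwarnings("ignore", "Precision loss",
                                        RuntimeWarning)
                res = stats.ttest_ind(t, c, equal_var=False)
            row["t"] = float(res.statistic)
            row["p"] = float(res.pvalue)
        else:
            row["t"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    counts = pd.DataFrame(rows)
    if can_test:
        counts["p_holm"] = _holm(counts["p"].to_numpy())
        sig = counts["p"] < alpha
        counts["flag"] = np.select(
            [sig & (counts.difference < 0), sig & (counts.difference > 0)],
            ["depleted", "enriched"], default="ns",
        )
    else:
        counts["p_holm"] = np.nan
        counts["flag"] = "untested"
    return CDCResult(
        viability=pd.DataFrame(via_rows),
        counts=counts,
        alpha=alpha,
        n_downsampled=n_min,
    )


# ---------------------------------------------------------------------------
# purified-population assays
# ---------------------------------------------------------------------------

def purified_population_cdc(events: EventTable, params: CDCModelParams,
                            blocking: bool = False,
                            rng: np.random.Generator | int | None = None) -> float:
    """Background-subtracted lysis of a sorted (single-subset) population.

    Runs matched antibody and control-IgG arms on the same input cells and
    returns treated-minus-control total lysis in percentage points. With
    CIP-blocking antibodies present the antibody arm's protection is reduced
    by the blocking efficiency. The input should be one sorted population;
    a sort gate may span phenotypic siblings (e.g. CD16+ and CD16-
    monocytes), whose per-event labels keep their own CIP protection.
    """
    if events.n_events == 0:
        raise ContractError("purified assay needs a non-empty population")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r_t, r_c, r_thr = rng.spawn(3)
    treated = simulate_cdc(events, params, "antibody", blocking=blocking, rng=r_t)
    control = simulate_cdc(events, params, "control", rng=r_c)
    pooled = treated.concat(control)
    thresholds = resolve_thresholds(pooled, ["AnnexinV", "7AAD"])
    lysis_t = percent_lysis(classify_viability(treated, thresholds))
    lysis_c = percent_lysis(classify_viability(control, thresholds))
    return lysis_t - lysis_c
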