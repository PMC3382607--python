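"""Per-subset antigen quantitation and expression-hierarchy summaries.

The workflow converts each subset's *median* fluorescence intensity through
the bead standard curve (convert-the-median — for a monotone curve this
coincides with the median of per-event conversions) and aggregates ABC
values across donors with an unweighted arithmetic mean and SD.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve, mfi_to_abc
from .errors import ContractError
from .events import EventTable

__all__ = ["QuantResult", "quantify_abc", "aggregate_quant", "rank_hierarchy",
           "HierarchyResult"]

_NON_SUBSET = {"bead", "debris", "unassigned", "unlabelled"}


@dataclass
class QuantResult:
    per_donor: pd.DataFrame  # donor, subset, n_events, median_mfi, abc, flags
    summary: pd.DataFrame    # subset, mean_abc, sd_abc, n_donors

    def donor_values(self, subset: str) -> np.ndarray:
        rows = self.per_donor[(self.per_donor.subset == subset)
                              & self.per_donor.reliable]
        return rows.abc.to_numpy()


def quantify_abc(events: EventTable, labels: pd.Series, curve: CalibrationCurve,
                 channel: str = "CD52", min_events: int = 50) -> pd.DataFrame:
    """One donor's per-subset median MFI and ABC conversion.

    Entries with fewer than ``min_events`` events are kept but marked
    unreliable; conversions outside the bead anchor range carry an
    extrapolation flag.
    """
    if len(labels) != events.n_events:
        raise ContractError("labels must cover every event")
    x = events.intensities(channel)
    lab = np.asarray(labels)
    rows = []
    for subset in sorted(set(lab) - _NON_SUBSET):
        vals = x[lab == subset]
        med = float(np.median(vals)) if len(vals) else np.nan
        if len(vals) and med > 0:
            abc, flag = mfi_to_abc(curve, med, with_flag=True)
        else:
            abc, flag = np.nan, False
        rows.append({
            "donor": events.metadata.get("donor_id", 0),
            "subset": subset,
            "n_events": int(len(vals)),
            "median_mfi": med,
            "abc": abc,
            "extrapolated": bool(flag),
            "reliable": len(vals) >= min_events,
        })
    return pd.DataFrame(rows)


def aggregate_quant(per_donor_frames: list[pd.DataFrame]) -> QuantResult:
    """Pool donors: arithmetic mean and SD of ABC per subset (equal donor
    weights); unreliable donor entries are excluded from aggregates."""
    per_donor = pd.concat(per_donor_frames, ignore_index=True)
    usable = per_donor[per_donor.reliable & per_donor.abc.notna()]
    dropped = per_donor[~(per_donor.reliable & per_donor.abc.notna())]
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} donor x subset entries excluded from aggregates "
            f"(too few events or undefined median)", stacklevel=2,
        )
    summary = (usable.groupby("subset")["abc"]
               .agg(mean_abc="mean", sd_abc="std", n_donors="count")
               .reset_index())
    return QuantResult(per_donor=per_donor, summary=summary)


@dataclass
class HierarchyResult:
    per_donor_order: dict      # donor -> tuple of subset names, descending ABC
    modal_order: tuple
    n_donors_modal: int
    pair_concordance: pd.DataFrame  # higher, lower, fraction of donors agreeing


def rank_hierarchy(result: QuantResult, scope_subsets: list[str]) -> HierarchyResult:
    """Per-donor descending-ABC ordering over a scope (lymphoid or myeloid).

    Ties break alphabetically for determinism. The summary reports the modal
    ordering, how many donors share it and, for every subset pair, the
    fraction of donors ranking the pair the modal way round.
    """
    pd_frame = result.per_donor[result.per_donor.subset.isin(scope_subsets)
                                & result.per_donor.reliable]
    missing = set(scope_subsets) - set(pd_frame.subset)
    if missing:
        warnings.warn(f"subsets absent from all donors: {sorted(missing)}; "
                      "ordering computed over the rest", stacklevel=2)
    orders = {}
    for donor, grp in pd_frame.groupby("donor"):
        grp = grp.sort_values(["abc", "subset"], ascending=[False, True],
                              kind="mergesort")
        orders[donor] = tuple(grp.subset)
    if not orders:
        raise ContractError("no reliable entries in the requested scope")
    modal, n_modal = Counter(orders.values()).most_common(1)[0]
    rows = []
    present = sorted(set(pd_frame.subset))
    for a, b in combinations(present, 2):
        agree = 0
        total = 0
        for order in orders.values():
            if a in order and b in order:
                total += 1
                agree += order.index(a) < order.index(b)
        frac = agree / total if total else np.nan
        hi, lo, f = (a, b, frac) if frac >= 0.5 else (b, a, 1 - frac)
        rows.append({"higher": hi, "lower": lo, "concordance": f, "n_donors": total})
    return HierarchyResult(
        per_donor_order=orders,
        modal_order=modal,
        n_donors_modal=n_modal,
        pair_concordance=pd.DataFrame(rows),
    )
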