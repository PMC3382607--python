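"""Bead calibration: the MFI <-> ABC standard curve.

Calibrated beads carry lot-assigned antibody binding capacities (ABC units,
molecules of antibody bound per particle). Stained with the same conjugate
and acquired under the same instrument settings as the cells, their median
fluorescence intensities (MFI) anchor a standard curve; a least-squares line
in log10–log10 space (the convention of quantitative-cytometry bead vendors)
then converts any subset median MFI into an absolute antigen density.

Values outside the bead anchor range are computed by extending the line but
flagged as extrapolated — dim populations (basophils, ~7e4 ABC) can fall
below the lowest anchor depending on the bead lot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._util import kmeans1d
from .errors import CalibrationError, ContractError
from .events import EventTable

__all__ = ["CalibrationCurve", "fit_calibration", "mfi_to_abc", "abc_to_mfi"]


@dataclass
class CalibrationCurve:
    bead_points: list  # [(abc, median MFI), ...] in increasing ABC order
    slope: float       # d log10(ABC) / d log10(MFI)
    intercept: float   # log10(ABC) at log10(MFI) = 0
    valid_mfi_range: tuple
    fit_quality: float  # R^2 in log10-log10 space
    background_mfi: float | None = None
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        if len(self.bead_points) < 2:
            raise CalibrationError("a calibration curve needs >= 2 bead points")
        abcs = [p[0] for p in self.bead_points]
        if any(b <= a for a, b in zip(abcs, abcs[1:])):
            raise CalibrationError("bead ABC values must be strictly increasing")
        if self.slope <= 0:
            raise CalibrationError(
                "fitted mapping must be strictly increasing (slope > 0)"
            )

    @property
    def response_exponent(self) -> float:
        """Exponent of the fluorescence response MFI ~ ABC^e (= 1/slope)."""
        return 1.0 / self.slope

    def is_extrapolated(self, mfi) -> np.ndarray:
        mfi = np.asarray(mfi, dtype=float)
        lo, hi = self.valid_mfi_range
        return (mfi < lo) | (mfi > hi)

    # structured text report
    def to_json(self) -> str:
        return json.dumps({
            "bead_points": [[float(a), float(m)] for a, m in self.bead_points],
            "slope": self.slope, "intercept": self.intercept,
            "valid_mfi_range": [float(v) for v in self.valid_mfi_range],
            "fit_quality": self.fit_quality,
            "background_mfi": self.background_mfi,
            "background_subtracted": self.background_subtracted,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        raw = json.loads(text)
        raw["bead_points"] = [tuple(p) for p in raw["bead_points"]]
        raw["valid_mfi_range"] = tuple(raw["valid_mfi_range"])
        return cls(**raw)


def _population_medians(beads: EventTable, channel: str,
                        n_levels: int | None) -> tuple[np.ndarray, float | None]:
    """Per-population median MFI, ascending, plus blank-bead background."""
    x = beads.intensities(channel)
    background = None
    if beads.labels is not None:
        groups = {}
        for lab in beads.labels.unique():
            vals = x[np.asarray(beads.labels) == lab]
            if lab == "blank":
                background = float(np.median(vals))
            else:
                groups[lab] = vals
        small = {k: len(v) for k, v in groups.items() if len(v) < 10}
        if small:
            raise CalibrationError(f"bead populations with < 10 events: {small}")
        medians = np.array(sorted(float(np.median(v)) for v in groups.values()))
    else:
        if n_levels is None:
            raise CalibrationError(
                "unlabeled bead data needs n_levels for 1-D population partition"
            )
        lx = np.log10(np.clip(x, 1e-9, None))
        centers = kmeans1d(lx, n_levels)
        bounds = 0.5 * (centers[:-1] + centers[1:])
        assign = np.searchsorted(bounds, lx)
        medians = []
        for j in range(n_levels):
            vals = x[assign == j]
            if len(vals) < 10:
                raise CalibrationError(
                    f"bead population {j} has {len(vals)} events (< 10)"
                )
            medians.append(float(np.median(vals)))
        medians = np.array(sorted(medians))
    return medians, background


def fit_calibration(beads: EventTable, channel: str = "CD52",
                    abc_levels: list | None = None,
                    n_levels: int | None = None,
                    subtract_background: bool = False) -> CalibrationCurve:
    """Fit the log10–log10 standard line through per-population bead medians.

    ``abc_levels`` are the lot-assigned ABC values (taken from the table
    metadata if omitted), matched to populations in increasing-MFI order.
    With truth labels present, non-monotone medians versus assigned ABC
    signal corrupted beads and raise. The blank population, if present, only
    estimates background MFI (subtracted when requested, off by default).
    """
    if abc_levels is None:
        abc_levels = beads.metadata.get("bead_abc_levels")
    if abc_levels is None:
        raise CalibrationError("no assigned bead ABC levels (argument or metadata)")
    abc_levels = np.asarray(abc_levels, dtype=float)
    if len(abc_levels) < 2:
        raise CalibrationError("calibration impossible with < 2 bead levels")
    if np.any(np.diff(abc_levels) <= 0):
        raise CalibrationError("assigned bead ABC levels must be strictly increasing")

    if beads.labels is not None:
        # medians in assigned-level order, to detect non-monotone corruption
        x = beads.intensities(channel)
        med_by_level = []
        for i in range(len(abc_levels)):
            vals = x[np.asarray(beads.labels) == f"bead_{i}"]
            if len(vals) < 10:
                raise CalibrationError(f"bead population bead_{i} has < 10 events")
            med_by_level.append(float(np.median(vals)))
        if np.any(np.diff(med_by_level) <= 0):
            raise CalibrationError(
                "bead medians are not strictly increasing with assigned ABC "
                "(corrupted bead set)"
            )
        medians = np.asarray(med_by_level)
        background = None
        if "blank" in set(beads.labels):
            background = float(np.median(x[np.asarray(beads.labels) == "blank"]))
    else:
        medians, background = _population_medians(beads, channel,
                                                  n_levels or len(abc_levels))
        if len(medians) != len(abc_levels):
            raise CalibrationError(
                f"{len(medians)} bead populations found for "
                f"{len(abc_levels)} assigned levels"
            )

    if subtract_background and background is not None:
        adj = medians - background
        if np.any(adj <= 0):
            raise CalibrationError("background subtraction produced non-positive MFI")
        medians = adj

    lx = np.log10(medians)
    ly = np.log10(abc_levels)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = intercept + slope * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        bead_points=[(float(a), float(m)) for a, m in zip(abc_levels, medians)],
        slope=float(slope),
        intercept=float(intercept),
        valid_mfi_range=(float(medians.min()), float(medians.max())),
        fit_quality=r2,
        background_mfi=background,
        background_subtracted=bool(subtract_background and background is not None),
    )


def mfi_to_abc(curve: CalibrationCurve, mfi, with_flag: bool = False):
    """Convert MFI to ABC units: 10 ** (intercept + slope * log10 MFI).

    With ``with_flag`` also returns whether the value lies outside the bead
    anchor range (extrapolated).
    """
    arr = np.asarray(mfi, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ContractError("mfi must be positive and finite")
    abc = 10.0 ** (curve.intercept + curve.slope * np.log10(arr))
    abc = abc if np.ndim(mfi) else float(abc)
    if with_flag:
        flag = curve.is_extrapolated(arr)
        return abc, (flag if np.ndim(mfi) else bool(flag))
    return abc


def abc_to_mfi(curve: CalibrationCurve, abc):
    """Exact inverse of :func:`mfi_to_abc` over the valid range."""
    arr = np.asarray(abc, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ContractError("abc must be positive and finite")
    mfi = 10.0 ** ((np.log10(arr) - curve.intercept) / curve.slope)
    return mfi if np.ndim(abc) else float(mfi)
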