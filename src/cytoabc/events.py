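"""Event-level cytometry data container.

An :class:`EventTable` is the universal currency of the pipeline: a matrix of
per-event channel intensities (events x channels, linear scale, >= 0), a
key -> value metadata map (donor id, treatment arm, counting-bead assigned
count, ...), and two optional per-event sidecars that are never stored in the
primary channel data:

* ``labels`` — a categorical per-event assignment (simulator truth or gate
  output),
* ``truth_abc`` — the generative per-event CD52 antigen density in ABC units,
  carried by synthetic data so that downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = ["EventTable"]


@dataclass
class EventTable:
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    labels: pd.Series | None = None
    truth_abc: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ContractError(f"duplicate channel names: {dup}")
        if len(self.data) and not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ContractError("event intensities must be finite")
        for name in ("labels", "truth_abc"):
            side = getattr(self, name)
            if side is not None:
                side = pd.Series(np.asarray(side), name=name)
                if len(side) != len(self.data):
                    raise ContractError(
                        f"{name} length {len(side)} != event count {len(self.data)}"
                    )
                side.index = self.data.index
                setattr(self, name, side)

    # -- basic accessors -------------------------------------------------
    @property
    def channels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_events(self) -> int:
        return len(self.data)

    def intensities(self, channel: str) -> np.ndarray:
        if channel not in self.data.columns:
            raise ContractError(f"channel {channel!r} not present (have {self.channels})")
        return self.data[channel].to_numpy(dtype=float)

    # -- construction helpers --------------------------------------------
    @classmethod
    def empty(cls, channels: Sequence[str], metadata: Mapping | None = None) -> "EventTable":
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in channels})
        return cls(df, dict(metadata or {}))

    def select(self, mask: np.ndarray) -> "EventTable":
        """Row subset; sidecars follow. ``mask`` may be boolean or positional."""
        mask = np.asarray(mask)
        sub = self.data.iloc[mask] if mask.dtype.kind in "iu" else self.data.loc[mask]
        out = EventTable(
            sub.reset_index(drop=True),
            dict(self.metadata),
            None if self.labels is None else self.labels[sub.index].reset_index(drop=True),
            None if self.truth_abc is None else self.truth_abc[sub.index].reset_index(drop=True),
        )
        return out

    def concat(self, other: "EventTable") -> "EventTable":
        if self.channels != other.channels:
            raise ContractError("cannot concatenate tables with different channel sets")

        def _cat(a, b, fill):
            if a is None and b is None:
                return None
            a = a if a is not None else pd.Series([fill] * self.n_events)
            b = b if b is not None else pd.Series([fill] * other.n_events)
            return pd.concat([a, b], ignore_index=True)

        return EventTable(
            pd.concat([self.data, other.data], ignore_index=True),
            {**other.metadata, **self.metadata},
            _cat(self.labels, other.labels, "unlabelled"),
            _cat(self.truth_abc, other.truth_abc, np.nan),
        )

    def __eq__(self, other: object) -> bool:  # value equality, used by tests
        if not isinstance(other, EventTable):
            return NotImplemented
        return (
            self.channels == other.channels
            and self.data.shape == other.data.shape
            and np.array_equal(self.data.to_numpy(float), other.data.to_numpy(float))
            and self.metadata == other.metadata
        )
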