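"""Reading and writing event-level cytometry data.

Two on-disk representations are supported:

* **FCS** — the list-mode flow cytometry standard. Files are written as
  FCS3.1, list mode, floating-point data (``$DATATYPE D`` by default so
  round trips are bit-exact); FCS2.0/3.0/3.1 files with ``$DATATYPE``
  ``F``/``D``/``I`` are read. Only channel names and declared metadata are
  preserved — compensation and other acquisition keywords are out of scope.
* **tabular** — delimited text with a header row of channel names, one event
  per line. Metadata travels in a ``<path>.meta.json`` sidecar.

Per-event labels (simulator truth or gate assignments) and the synthetic
per-event ABC truth are never written into the primary channel data; they go
to a ``<path>.labels.tsv`` sidecar keyed by 0-based event index.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, ParseError
from .events import EventTable

__all__ = ["read_events", "write_events"]

_DELIM = b"\x0c"  # TEXT-segment delimiter; a control char never present in values
_META_KEY = "CYTOABCMETA"


# ---------------------------------------------------------------------------
# FCS writing
# ---------------------------------------------------------------------------

def _fcs_bytes(table: EventTable, datatype: str = "D") -> bytes:
    if datatype not in ("F", "D"):
        raise ContractError("writer supports $DATATYPE F or D")
    arr = table.data.to_numpy(dtype=np.float64 if datatype == "D" else np.float32)
    n_events, n_par = arr.shape if arr.ndim == 2 else (0, len(table.channels))
    width = 64 if datatype == "D" else 32

    pairs = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": datatype,
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(table.channels, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = str(width)
        pairs[f"$P{i}E"] = "0,0"
        peak = float(np.max(arr[:, i - 1])) if n_events else 1.0
        pairs[f"$P{i}R"] = str(int(max(peak, 1.0)) + 1)
    if table.metadata:
        pairs[_META_KEY] = json.dumps(table.metadata, sort_keys=True)

    # $BEGINDATA/$ENDDATA depend on TEXT length; fixed-width values break the cycle
    pairs["$BEGINDATA"] = "0" * 12
    pairs["$ENDDATA"] = "0" * 12
    d = _DELIM

    def render() -> bytes:
        out = d
        for k, v in pairs.items():
            out += k.encode("ascii") + d + str(v).encode("utf-8") + d
        return out

    header_len = 58
    text = render()
    data_start = header_len + len(text)
    data_end = data_start + n_events * n_par * (width // 8) - 1 if n_events else 0
    pairs["$BEGINDATA"] = str(data_start).zfill(12)
    pairs["$ENDDATA"] = str(max(data_end, 0)).zfill(12)
    text = render()

    def _off(x: int) -> bytes:
        s = str(x) if x <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _off(header_len) + _off(header_len + len(text) - 1)
    header += _off(data_start if n_events else 0) + _off(data_end if n_events else 0)
    header += _off(0) + _off(0)
    assert len(header) == 58
    payload = arr.astype("<f8" if datatype == "D" else "<f4").tobytes(order="C")
    return header + text + payload


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------

def _read_fcs(path: Path) -> EventTable:
    raw = path.read_bytes()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise ParseError(f"{path}: HEADER segment is not FCS (magic bytes missing)")
    version = raw[:10].decode("ascii", "replace").strip()

    def _int_at(lo: int, hi: int, what: str) -> int:
        field = raw[lo:hi].decode("ascii", "replace").strip()
        try:
            return int(field) if field else 0
        except ValueError as exc:
            raise ParseError(f"{path}: HEADER offset field {what!r} is not numeric") from exc

    text_start = _int_at(10, 18, "text start")
    text_end = _int_at(18, 26, "text end")
    if text_start <= 0 or text_end <= text_start:
        raise ParseError(f"{path}: TEXT segment offsets invalid in HEADER")
    delim = raw[text_start:text_start + 1]
    if not delim:
        raise ParseError(f"{path}: TEXT segment truncated")
    tokens = raw[text_start + 1:text_end + 1].split(delim)
    if tokens and tokens[-1] == b"":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise ParseError(f"{path}: TEXT segment has an odd keyword/value count")
    kw = {
        tokens[i].decode("utf-8", "replace").strip().upper():
        tokens[i + 1].decode("utf-8", "replace")
        for i in range(0, len(tokens), 2)
    }

    def _require(key: str) -> str:
        if key not in kw:
            raise ParseError(f"{path}: TEXT segment missing required keyword {key}")
        return kw[key]

    n_par = int(_require("$PAR"))
    n_tot = int(_require("$TOT"))
    datatype = _require("$DATATYPE").strip().upper()
    byteord = _require("$BYTEORD").strip()
    endian = "<" if byteord.startswith("1") else ">"
    channels = []
    widths = []
    for i in range(1, n_par + 1):
        channels.append(kw.get(f"$P{i}N", f"P{i}").strip())
        widths.append(int(kw.get(f"$P{i}B", "32")))

    data_start = int(kw.get("$BEGINDATA", "0") or 0) or _int_at(26, 34, "data start")
    data_end = int(kw.get("$ENDDATA", "0") or 0) or _int_at(34, 42, "data end")

    if n_tot == 0:
        table = EventTable.empty(channels)
    else:
        if datatype in ("F", "D"):
            width = widths[0]
            if any(w != width for w in widths):
                raise ParseError(f"{path}: DATA segment has mixed $PnB for type {datatype}")
            code = {("F", 32): "f4", ("D", 64): "f8"}.get((datatype, width))
            if code is None:
                raise ParseError(f"{path}: DATA segment $PnB {width} invalid for $DATATYPE {datatype}")
            nbytes = n_tot * n_par * (width // 8)
            blob = raw[data_start:data_start + nbytes]
            if len(blob) < nbytes:
                raise ParseError(f"{path}: DATA segment shorter than $TOT x $PAR declares")
            arr = np.frombuffer(blob, dtype=endian + code).reshape(n_tot, n_par)
        elif datatype == "I":
            arr = _read_int_data(raw, data_start, n_tot, widths, endian, path)
        else:
            raise ParseError(f"{path}: DATA segment type {datatype!r} unsupported (F/D/I)")
        table = EventTable(pd.DataFrame(np.asarray(arr, dtype=float), columns=channels))
    if _META_KEY in kw:
        try:
            table.metadata = json.loads(kw[_META_KEY])
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: TEXT metadata keyword is not valid JSON") from exc
    table.metadata.setdefault("fcs_version", version)
    return table


def _read_int_data(raw, start, n_tot, widths, endian, path):
    if any(w not in (8, 16, 32) for w in widths):
        raise ParseError(f"{path}: DATA segment integer widths must be 8/16/32 bits")
    out = np.empty((n_tot, len(widths)))
    offset = start
    row_bytes = sum(w // 8 for w in widths)
    blob = raw[start:start + n_tot * row_bytes]
    if len(blob) < n_tot * row_bytes:
        raise ParseError(f"{path}: DATA segment shorter than $TOT x $PAR declares")
    col = 0
    for j, w in enumerate(widths):
        fmt = {8: "u1", 16: "u2", 32: "u4"}[w]
        stride = np.frombuffer(blob, dtype=np.uint8).reshape(n_tot, row_bytes)
        field = stride[:, col:col + w // 8].copy().tobytes()
        out[:, j] = np.frombuffer(field, dtype=endian + fmt)
        col += w // 8
    return out


# ---------------------------------------------------------------------------
# sidecars and the tabular fallback
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return Path(str(path) + ".labels.tsv"), Path(str(path) + ".meta.json")


def _write_sidecars(table: EventTable, path: Path, with_meta: bool) -> None:
    labels_path, meta_path = _sidecar_paths(path)
    if table.labels is not None or table.truth_abc is not None:
        side = pd.DataFrame({"event_index": np.arange(table.n_events)})
        if table.labels is not None:
            side["label"] = table.labels.to_numpy()
        if table.truth_abc is not None:
            side["truth_abc"] = table.truth_abc.to_numpy()
        side.to_csv(labels_path, sep="\t", index=False)
    if with_meta and table.metadata:
        meta_path.write_text(json.dumps(table.metadata, sort_keys=True, indent=1))


def _read_sidecars(table: EventTable, path: Path, with_meta: bool) -> None:
    labels_path, meta_path = _sidecar_paths(path)
    if labels_path.exists():
        side = pd.read_csv(labels_path, sep="\t")
        if len(side) != table.n_events:
            raise ParseError(f"{labels_path}: sidecar row count differs from event count")
        if "label" in side:
            table.labels = pd.Series(side["label"].astype(str).to_numpy())
        if "truth_abc" in side:
            table.truth_abc = pd.Series(side["truth_abc"].to_numpy(dtype=float))
    if with_meta and meta_path.exists():
        table.metadata = {**json.loads(meta_path.read_text()), **table.metadata}


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_events(table: EventTable, path: str | os.PathLike, format: str | None = None) -> None:
    """Write ``table`` to ``path`` as FCS or delimited text (inferred from suffix)."""
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "tabular")
    try:
        if fmt == "fcs":
            path.write_bytes(_fcs_bytes(table))
            _write_sidecars(table, path, with_meta=False)
        elif fmt == "tabular":
            # %.17g is lossless for float64, so the round trip is bit-exact
            table.data.to_csv(path, index=False, float_format="%.17g")
            _write_sidecars(table, path, with_meta=True)
        else:
            raise ContractError(f"unknown format {fmt!r} (use 'fcs' or 'tabular')")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_events(path: str | os.PathLike, format: str | None = None) -> EventTable:
    """Read an :class:`EventTable`; an empty event set is a valid empty table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "tabular")
    if fmt == "fcs":
        table = _read_fcs(path)
        _read_sidecars(table, path, with_meta=False)
    elif fmt == "tabular":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: tabular body failed to parse: {exc}") from exc
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: tabular file has no header row") from exc
        table = EventTable(df.astype(float))
        _read_sidecars(table, path, with_meta=True)
    else:
        raise ContractError(f"unknown format {fmt!r} (use 'fcs' or 'tabular')")
    return table
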