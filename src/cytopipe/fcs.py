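"""Minimal FCS 3.1 reader/writer for float list-mode data.

Writes single-precision little-endian list-mode files with one parameter per
channel ($DATATYPE/F, $MODE/L, $BYTEORD/1,2,3,4) and reads them (and any
FCS 3.x file using that layout) back.  $PnN carries the metal/channel name
and $PnS the marker short name.  Round-trips preserve values to float32
precision and channel order; the acquisition-time channel is stored like any
other parameter.

This is intentionally a small subset of the standard: integer data types,
analysis segments and multi-dataset files are not supported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import Panel, TIME_CHANNEL
from .synthetic import EventMatrix

# ASCII record separator: legal as an FCS TEXT delimiter and cannot occur in
# marker names (unlike '/', which appears in e.g. pErk1/2)
_DELIM = b"\x1e"


class FCSParseError(ValueError):
    """Malformed FCS file; message names the offending offset or keyword."""


def write_fcs(events: EventMatrix, path) -> None:
    """Write an event matrix as an FCS 3.1 float list-mode file."""
    panel = events.panel
    cols = [c for c in events.data.columns]
    data = np.ascontiguousarray(events.data[cols].to_numpy(dtype="<f4"))
    n_events, n_par = data.shape

    def pns(name: str) -> str:
        return name

    def pnn(name: str) -> str:
        if name == TIME_CHANNEL:
            return "Time"
        try:
            return panel.metal(name)
        except KeyError:
            return name

    keywords: list[tuple[str, str]] = [
        ("$FCSVersion", "3.1"),
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
        ("$NEXTDATA", "0"),
    ]
    for i, c in enumerate(cols, start=1):
        keywords += [
            (f"$P{i}N", pnn(c)),
            (f"$P{i}S", pns(c)),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1.0, float(np.nanmax(data[:, i - 1]))
                                    if n_events else 1.0)) + 1)),
        ]

    # two-pass build: TEXT length depends on the data offsets it encodes
    header_len = 58
    data_len = data.nbytes

    def build_text(begin_data: int, end_data: int) -> bytes:
        kws = keywords + [("$BEGINDATA", str(begin_data)),
                          ("$ENDDATA", str(end_data)),
                          ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0")]
        out = _DELIM
        for k, v in kws:
            v = v if v else " "
            out += k.encode() + _DELIM + v.encode() + _DELIM
        return out

    text = build_text(0, 0)
    for _ in range(3):
        begin_data = header_len + len(text)
        end_data = begin_data + max(data_len - 1, 0) if data_len else 0
        new_text = build_text(begin_data, end_data)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    begin_text = header_len
    end_text = begin_text + len(text) - 1

    header = b"FCS3.1    "
    header += f"{begin_text:>8d}".encode() + f"{end_text:>8d}".encode()
    if data_len and end_data <= 99_999_999:
        header += f"{begin_data:>8d}".encode() + f"{end_data:>8d}".encode()
    else:
        header += f"{0:>8d}".encode() + f"{0:>8d}".encode()
    header += f"{0:>8d}".encode() + f"{0:>8d}".encode()   # analysis
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FCSParseError(f"empty TEXT segment at offset {offset}")
    delim = raw[:1]
    parts = raw[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FCSParseError(
            f"TEXT segment at offset {offset} has an odd number of tokens")
    kw = {}
    for i in range(0, len(parts), 2):
        kw[parts[i].decode("utf-8", "replace").strip()] = \
            parts[i + 1].decode("utf-8", "replace")
    return kw


def read_fcs(path, panel: Panel | None = None) -> EventMatrix:
    """Read an FCS 3.x float list-mode file written by :func:`write_fcs`.

    Column names are taken from $PnS (marker short name) when present,
    falling back to $PnN.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FCSParseError("file shorter than the 58-byte FCS header")
    version = blob[:6]
    if not version.startswith(b"FCS3"):
        raise FCSParseError(f"unsupported FCS version {version!r} at offset 0")

    def _off(a: int, b: int, what: str) -> tuple[int, int]:
        try:
            return int(blob[a:b][:8]), int(blob[a:b][8:16])
        except ValueError as e:
            raise FCSParseError(
                f"non-numeric {what} offsets at header bytes {a}-{b}") from e

    begin_text, end_text = _off(10, 26, "TEXT")
    begin_data_h, end_data_h = _off(26, 42, "DATA")
    kw = _parse_text(blob[begin_text:end_text + 1], begin_text)

    for required in ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD", "$MODE"):
        if required not in kw:
            raise FCSParseError(f"missing required keyword {required}")
    if kw["$DATATYPE"] != "F":
        raise FCSParseError(f"unsupported $DATATYPE {kw['$DATATYPE']!r}")
    if kw["$MODE"] != "L":
        raise FCSParseError(f"unsupported $MODE {kw['$MODE']!r}")
    endian = "<" if kw["$BYTEORD"].startswith("1") else ">"
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])

    begin_data = int(kw.get("$BEGINDATA", begin_data_h) or begin_data_h)
    end_data = int(kw.get("$ENDDATA", end_data_h) or end_data_h)
    need = n_par * n_tot * 4
    if n_tot:
        avail = min(end_data - begin_data + 1, len(blob) - begin_data)
        if avail < need:
            raise FCSParseError(
                f"DATA segment [{begin_data}, {end_data}] holds {avail} bytes, "
                f"expected {need} for $TOT={n_tot}, $PAR={n_par}")
        payload = blob[begin_data:begin_data + need]
    else:
        payload = b""

    arr = np.frombuffer(payload, dtype=f"{endian}f4").reshape(n_tot, n_par) \
        if n_tot else np.zeros((0, n_par), dtype="f4")

    names = []
    for i in range(1, n_par + 1):
        short = kw.get(f"$P{i}S", "").strip()
        names.append(short or kw.get(f"$P{i}N", f"P{i}"))
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=names)
    return EventMatrix(df, panel or _panel_from_keywords(kw, names))


def _panel_from_keywords(kw: dict[str, str], names: list[str]) -> Panel:
    from .panel import Channel
    chans = []
    for i, name in enumerate(names, start=1):
        metal = kw.get(f"$P{i}N", name)
        role = "time" if name == TIME_CHANNEL else "phenotype"
        chans.append(Channel(name, metal, role))
    return Panel(chans)


def write_csv(events: EventMatrix, path) -> None:
    """Plain-text fallback: events as CSV (gzip if the path ends in .gz)."""
    events.data.to_csv(path, index=False)


def read_csv(path, panel: Panel) -> EventMatrix:
    return EventMatrix(pd.read_csv(path), panel)
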