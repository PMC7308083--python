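"""Minimal FCS 3.1 reader/writer (single dataset, 32-bit float, list mode).

Covers the subset of the standard the rest of the package needs: one TEXT
segment with ``/``-delimited keywords, little-endian float32 event data,
channel short names in ``$PnN``. Not a general-purpose FCS library; files
written here are readable by standard cytometry software that accepts
float list-mode data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_fcs", "read_fcs"]

_DELIM = "/"


def write_fcs(path, data: pd.DataFrame) -> None:
    """Write an events x channels DataFrame as FCS 3.1 float32."""
    path = Path(path)
    values = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    n_events, n_par = values.shape
    keywords = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
    }
    for i, name in enumerate(data.columns, start=1):
        if _DELIM in str(name):
            raise ValueError(f"channel name {name!r} contains the delimiter")
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        rng = float(np.max(values[:, i - 1])) if n_events else 1.0
        keywords[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)

    # iterate: the TEXT segment contains the data offsets, whose width can
    # change the TEXT length; two passes always converge here
    header_len = 58  # "FCS3.1    " + 6 x 8-char offsets
    begin_data, end_data = 0, 0
    for _ in range(3):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _DELIM + _DELIM.join(
            f"{k}{_DELIM}{v}" for k, v in sorted(kw.items())
        ) + _DELIM
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + values.nbytes - 1 if values.nbytes else 0
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = (
        f"FCS3.1    {text_start:>8d}{text_end:>8d}"
        f"{begin_data:>8d}{end_data:>8d}{0:>8d}{0:>8d}"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("utf-8"))
        fh.write(values.tobytes())


def read_fcs(path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file written in float list mode."""
    raw = Path(path).read_bytes()
    magic = raw[:6].decode("ascii", errors="replace")
    if not magic.startswith("FCS3"):
        raise ValueError(f"not an FCS 3.x file: magic {magic!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("utf-8")
    delim = text[0]
    parts = text[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    kw = {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    begin = int(kw["$BEGINDATA"]) or int(raw[26:34])
    end = int(kw["$ENDDATA"]) or int(raw[34:42])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype = kw.get("$DATATYPE", "F").upper()
    if dtype != "F":
        raise NotImplementedError(f"only $DATATYPE F supported, got {dtype}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    buf = raw[begin : end + 1]
    expect = n_par * n_tot * 4
    if len(buf) < expect:
        raise ValueError("truncated DATA segment")
    values = np.frombuffer(buf[:expect], dtype=f"{endian}f4").reshape(n_tot, n_par)
    return pd.DataFrame(values.astype(float), columns=names)
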