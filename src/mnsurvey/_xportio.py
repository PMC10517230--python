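"""Minimal SAS XPORT (transport, version 5) writer.

pandas reads XPORT files (``pandas.read_sas``) but cannot write them, so the
synthetic-fixture generator needs its own writer to exercise the SAS ingestion
path.  Only the subset required for rectangular survey data is implemented:

* numeric variables stored as 8-byte IBM System/360 hexadecimal floats
  (exactly representable round-trip for any IEEE double in range);
* character variables as fixed-width blank-padded ASCII;
* variable names of at most 8 characters (the v5 limit).

The byte layout follows the published transport-format specification:
80-byte card images, library/member/namestr/obs header records, 140-byte
NAMESTR entries, observation records padded with blanks to a card boundary.
"""

from __future__ import annotations

import math
import struct
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = ["write_xport"]

_EPOCH = datetime(1970, 1, 1)


def _ibm_double(x: float) -> bytes:
    """Encode an IEEE double as an 8-byte IBM hex float (big-endian).

    NaN encodes as the SAS standard missing value (``.`` in the first byte).
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return b"." + b"\x00" * 7
    x = float(x)
    # values below the smallest normal IBM hex float (16**-65) flush to zero
    if x == 0.0 or abs(x) < 16.0**-65:
        return b"\x00" * 8
    sign = 0x80 if x < 0 else 0x00
    m, e = math.frexp(abs(x))  # abs(x) = m * 2**e, 0.5 <= m < 1
    ibm_exp = -(-e // 4)  # ceil(e / 4); base-16 exponent
    shift = 3 + (e - 4 * ibm_exp)  # in 0..3
    frac = int(m * (1 << 53)) << shift  # exact: 56-bit fraction f = m * 2**(e-4E)
    biased = ibm_exp + 64
    if biased > 127:
        raise OverflowError(f"value {x!r} outside IBM hex float range")
    return bytes([sign | biased]) + frac.to_bytes(7, "big")


def _card(text: str) -> bytes:
    b = text.encode("ascii")
    if len(b) > 80:
        raise ValueError("card image longer than 80 bytes")
    return b.ljust(80)


def _header_card(kind: str, payload: str = "0" * 30) -> bytes:
    return _card(f"HEADER RECORD*******{kind:<8}HEADER RECORD!!!!!!!{payload}  ")


def _namestr(
    name: str, is_char: bool, length: int, varnum: int, pos: int
) -> bytes:
    ntype = 2 if is_char else 1
    fmt_name = b"" if is_char else b"BEST"
    rec = struct.pack(
        ">hhhh8s40s8shhh2s8shhi",
        ntype,
        0,
        length,
        varnum,
        name.upper().encode("ascii").ljust(8),
        name.encode("ascii")[:40].ljust(40),
        fmt_name.ljust(8),
        0,
        0,
        0,
        b"  ",
        fmt_name.ljust(8),
        0,
        0,
        pos,
    )
    return rec + b"\x00" * (140 - len(rec))


def write_xport(df: pd.DataFrame, path, dataset_name: str = "DATA") -> None:
    """Write ``df`` to ``path`` in SAS transport (XPORT v5) format."""
    if df.shape[0] == 0:
        raise ValueError("refusing to write an empty table")
    names = [str(c) for c in df.columns]
    for c in names:
        if len(c) > 8 or not c.isascii():
            raise ValueError(f"XPORT v5 variable name must be ASCII and <= 8 chars: {c!r}")
    if len({c.upper() for c in names}) != len(names):
        raise ValueError("XPORT variable names must be case-insensitively unique")

    ts = _EPOCH.strftime("%d%b%y:%H:%M:%S").upper()
    sas_line = f"{'SAS':<8}{'SAS':<8}{'SASLIB':<8}{'6.06':<8}{'bsd4.2':<8}" + " " * 24 + ts
    member_payload = "0" * 16 + "0160" + "0" * 6 + "0140"

    cols: list[tuple[str, bool, int, np.ndarray | list]] = []
    for c in names:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append((c, False, 8, np.asarray(s, dtype=float)))
        else:
            vals = ["" if pd.isna(v) else str(v) for v in s]
            width = max(1, max((len(v) for v in vals), default=1))
            cols.append((c, True, width, vals))

    out = bytearray()
    out += _header_card("LIBRARY")
    out += _card(sas_line)
    out += _card(ts)
    out += _header_card("MEMBER", member_payload)
    out += _header_card("DSCRPTR")
    out += _card(
        f"{'SAS':<8}{dataset_name.upper():<8}{'SASDATA':<8}{'6.06':<8}{'bsd4.2':<8}"
        + " " * 24
        + ts
    )
    out += _card(ts + " " * 16 + " " * 40 + " " * 8)
    out += _header_card("NAMESTR", f"{'0' * 6}{len(cols):04d}{'0' * 20}")

    pos = 0
    namestrs = bytearray()
    for i, (c, is_char, width, _) in enumerate(cols, start=1):
        namestrs += _namestr(c, is_char, width, i, pos)
        pos += width
    pad = (-len(namestrs)) % 80
    namestrs += b" " * pad
    out += namestrs

    out += _header_card("OBS")
    data = bytearray()
    nrows = df.shape[0]
    for i in range(nrows):
        for _, is_char, width, vals in cols:
            if is_char:
                data += vals[i].encode("ascii")[:width].ljust(width)
            else:
                data += _ibm_double(vals[i])
    data += b" " * ((-len(data)) % 80)
    out += data

    with open(path, "wb") as fh:
        fh.write(bytes(out))
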