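"""Minimal SPSS system-file (.sav) writer and reader.

No installed library in this stack reads or writes SPSS system files, so this
module implements the uncompressed subset of the documented format needed for
rectangular survey data: the 176-byte file header, type-2 variable records
(numeric, and strings up to 8 bytes), the type-999 dictionary terminator, and
raw 8-byte data elements (doubles little-endian; the SPSS system-missing
value maps to NaN).

The reader is deliberately more general than the writer — it skips variable
labels, missing-value specifications, document records and type-7 extension
records — but it does not support compressed files.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

__all__ = ["write_sav", "read_sav"]

_SYSMIS = -1.7976931348623157e308  # lowest double; SPSS system-missing
_FMT_F = 5  # SPSS print-format code for F (numeric)
_FMT_A = 1  # SPSS print-format code for A (string)


def _fmt(code: int, width: int, dec: int) -> int:
    return dec | (width << 8) | (code << 16)


def write_sav(df: pd.DataFrame, path, file_label: str = "mnsurvey") -> None:
    """Write ``df`` as an uncompressed SPSS system file.

    Column names must be ASCII, at most 8 characters (stored upper-case, the
    classic SPSS short-name limit) and case-insensitively unique.  String
    columns are limited to 8 bytes.
    """
    if df.shape[0] == 0:
        raise ValueError("refusing to write an empty table")
    names = [str(c) for c in df.columns]
    for c in names:
        if len(c) > 8 or not c.isascii():
            raise ValueError(f".sav variable name must be ASCII and <= 8 chars: {c!r}")
    if len({c.upper() for c in names}) != len(names):
        raise ValueError(".sav variable names must be case-insensitively unique")

    cols: list[tuple[str, int, object]] = []  # (name, string width or 0, values)
    for c in names:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append((c, 0, np.asarray(s, dtype=float)))
        else:
            vals = ["" if pd.isna(v) else str(v) for v in s]
            width = max(1, max((len(v.encode("ascii")) for v in vals), default=1))
            if width > 8:
                raise ValueError(f".sav string column {c!r} wider than 8 bytes")
            cols.append((c, width, vals))

    case_size = len(cols)  # every column occupies one 8-byte element
    out = bytearray()
    out += struct.pack(
        "<4s60siiiiid9s8s64s3s",
        b"$FL2",
        b"@(#) SPSS DATA FILE mnsurvey".ljust(60),
        2,  # layout code
        case_size,
        0,  # uncompressed
        0,  # no weight variable
        df.shape[0],
        100.0,  # compression bias (unused)
        b"01 Jan 70",
        b"00:00:00",
        file_label.encode("ascii")[:64].ljust(64),
        b"\x00" * 3,
    )
    for name, width, _ in cols:
        if width == 0:
            vtype, fmt = 0, _fmt(_FMT_F, 8, 2)
        else:
            vtype, fmt = width, _fmt(_FMT_A, width, 0)
        out += struct.pack(
            "<iiiiii8s",
            2,  # variable record
            vtype,
            0,  # no variable label
            0,  # no missing-value spec
            fmt,
            fmt,
            name.upper().encode("ascii").ljust(8),
        )
    out += struct.pack("<ii", 999, 0)  # dictionary terminator

    for i in range(df.shape[0]):
        for _, width, vals in cols:
            if width == 0:
                x = vals[i]
                out += struct.pack("<d", _SYSMIS if np.isnan(x) else float(x))
            else:
                out += vals[i].encode("ascii").ljust(8)

    with open(path, "wb") as fh:
        fh.write(bytes(out))


def read_sav(path) -> pd.DataFrame:
    """Read an uncompressed SPSS system file written by :func:`write_sav`
    (or any other producer of the uncompressed subset)."""
    with open(path, "rb") as fh:
        buf = fh.read()

    if len(buf) < struct.calcsize("<4s60siiiiid9s8s64s3s") or buf[:4] != b"$FL2":
        raise ValueError("not an SPSS system file (missing $FL2 magic)")
    head = struct.unpack_from("<4s60siiiiid9s8s64s3s", buf, 0)
    if head[0] != b"$FL2":
        raise ValueError("not an SPSS system file (missing $FL2 magic)")
    case_size, compression, ncases = head[3], head[4], head[6]
    if compression != 0:
        raise ValueError("compressed .sav files are not supported")
    off = struct.calcsize("<4s60siiiiid9s8s64s3s")

    names: list[str] = []
    widths: list[int] = []  # 0 numeric, >0 string byte width
    while True:
        (rec,) = struct.unpack_from("<i", buf, off)
        off += 4
        if rec == 999:
            off += 4  # filler
            break
        if rec == 2:
            vtype, has_label, n_missing, _pf, _wf, raw = struct.unpack_from(
                "<iiiii8s", buf, off
            )
            off += 28
            if has_label:
                (lab_len,) = struct.unpack_from("<i", buf, off)
                off += 4 + lab_len + ((-lab_len) % 4)
            off += 8 * abs(n_missing)
            if vtype >= 0:
                names.append(raw.decode("ascii").strip())
                widths.append(vtype)
            # vtype == -1: continuation of a long string; occupies a data slot
            elif widths:
                widths[-1] += 0  # width already covers it; slot tracked below
        elif rec == 6:  # document record
            (n_lines,) = struct.unpack_from("<i", buf, off)
            off += 4 + 80 * n_lines
        elif rec == 7:  # extension record: subtype, size, count
            _sub, size, count = struct.unpack_from("<iii", buf, off)
            off += 12 + size * count
        else:
            raise ValueError(f"unsupported .sav record type {rec}")

    # slots per variable: numeric/short string = 1, long string = ceil(w/8)
    slots = [1 if w == 0 else -(-w // 8) for w in widths]
    if sum(slots) != case_size:
        raise ValueError(".sav dictionary is inconsistent with the case size")

    columns: dict[str, list] = {n: [] for n in names}
    for i in range(ncases):
        base = off + i * 8 * case_size
        k = 0
        for name, w, ns in zip(names, widths, slots):
            chunk = buf[base + 8 * k : base + 8 * (k + ns)]
            k += ns
            if w == 0:
                (x,) = struct.unpack("<d", chunk)
                columns[name].append(np.nan if x == _SYSMIS else x)
            else:
                columns[name].append(chunk[:w].decode("ascii").rstrip())
    return pd.DataFrame(columns)
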