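"""Converter for wide-format count workbooks into the long CountTable TSV.

Deposited screen counts ship as an Excel workbook with one sheet per
experimental and technical condition.  Sheet names end in ``Upstream`` /
``Downstream`` (the barcode position) optionally followed by a technical
replicate number, e.g. ``hybrid_YPD_A_Upstream1`` or ``cerevisiae_EtOH8_B_Downstream``.
The leading label is split on underscores into pool, condition and biological
replicate (a missing replicate defaults to 'A').  Within a sheet, the first
column holds strain ids and each remaining column one time point, its header
giving the generations at sampling.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .simulate import COUNT_COLUMNS

_SHEET_RE = re.compile(r"^(?P<label>.*?)[ _\-]*(?P<pos>Upstream|Downstream)(?P<tech>\d*)$")


def parse_sheet_name(name: str) -> dict:
    """Split a sheet name into pool/condition/bio_rep/barcode_position/tech_rep.

    Raises ValueError for names not following the Upstream/Downstream
    convention.
    """
    m = _SHEET_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse sheet name {name!r}: no Upstream/Downstream suffix")
    pos = "B1" if m.group("pos") == "Upstream" else "B2"
    tech = int(m.group("tech")) if m.group("tech") else 1
    parts = [p for p in m.group("label").split("_") if p]
    if len(parts) >= 3:
        pool, condition, bio_rep = parts[0], "_".join(parts[1:-1]), parts[-1]
    elif len(parts) == 2:
        pool, condition, bio_rep = parts[0], parts[1], "A"
    elif len(parts) == 1:
        pool, condition, bio_rep = "pool", parts[0], "A"
    else:
        pool, condition, bio_rep = "pool", "unknown", "A"
    return {
        "pool": pool,
        "condition": condition,
        "bio_rep": bio_rep,
        "barcode_position": pos,
        "tech_rep": tech,
    }


def convert_workbook(path: str | Path) -> pd.DataFrame:
    """Read a wide-format count workbook into a long CountTable DataFrame."""
    sheets = pd.read_excel(path, sheet_name=None)
    frames = []
    for name, df in sheets.items():
        meta = parse_sheet_name(name)  # raises listing the offending sheet
        if df.shape[1] < 2:
            raise ValueError(f"sheet {name!r} has no time-point columns")
        strain_col = df.columns[0]
        long = df.melt(id_vars=[strain_col], var_name="generations", value_name="count")
        long = long.rename(columns={strain_col: "strain_id"})
        try:
            long["generations"] = long["generations"].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"sheet {name!r}: time-point headers must be numeric generations ({exc})"
            ) from exc
        gen_order = {g: i for i, g in enumerate(sorted(long["generations"].unique()))}
        long["timepoint_index"] = long["generations"].map(gen_order)
        long["count"] = pd.to_numeric(long["count"], errors="coerce").fillna(0).astype(int)
        for key, value in meta.items():
            long[key] = value
        long["background"] = meta["pool"]
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[COUNT_COLUMNS]
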