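"""Immune cell-type composition profiling from marker-gene fold changes.

Each cell type is represented by a small set of marker genes; its score at a
(contrast, time) is the arithmetic mean log2FC of the significant markers.
Cell types whose significant markers disagree in sign are excluded
(status ``opposing_markers``) rather than averaged to a misleading value,
and cell types with no significant marker are reported as
``no_significant_markers``.  This is marker averaging, not deconvolution:
it tracks shifts in marker expression, which in bulk data conflate cell
abundance and per-cell expression.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATUS_SCORED = "scored"
STATUS_NO_SIG = "no_significant_markers"
STATUS_OPPOSING = "opposing_markers"


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT marker panel: cell type -> set of marker gene ids.

    GMT lines are tab-separated: name, description, then members.
    """
    path = Path(path)
    panel: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 fields "
                    f"(name, description, members...)")
            name = parts[0].strip()
            members = {m.strip() for m in parts[2:] if m.strip()}
            if not members:
                raise ValueError(
                    f"{path.name}:{lineno}: set {name!r} has no members")
            panel[name] = members
    _warn_overlaps(panel)
    return panel


def write_gmt(panel: dict[str, set[str]], path: str | Path,
              description: str = "marker set") -> None:
    with Path(path).open("w") as fh:
        for name in sorted(panel):
            members = "\t".join(sorted(panel[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def _warn_overlaps(panel: dict[str, set[str]]) -> None:
    seen: dict[str, str] = {}
    for name, members in panel.items():
        for m in members:
            if m in seen:
                logger.warning(
                    "marker %s shared by cell types %s and %s",
                    m, seen[m], name,
                )
            else:
                seen[m] = name


def cell_scores(panel: dict[str, set[str]], deg_table: pd.DataFrame,
                contrast: str, tau: float = 0.05) -> pd.DataFrame:
    """Aggregated marker log2FC per (time, cell type) for one contrast.

    Returns a DataFrame (contrast, time_h, cell_type, score, status,
    n_markers_used); score is NaN unless status is ``scored``.
    Marker matching to DEG gene symbols is case-insensitive.
    """
    sub = deg_table[deg_table["contrast"] == contrast]
    if sub.empty:
        raise ValueError(f"no rows for contrast {contrast!r}")
    sub = sub.assign(_key=sub["gene"].astype(str).str.strip().str.upper())
    panel_keys = {
        ct: {m.strip().upper() for m in markers}
        for ct, markers in panel.items()
    }
    measured = set(sub["_key"])
    records = []
    for time_h, rows in sub.groupby("time_h"):
        rows = rows.set_index("_key")
        for cell_type in sorted(panel_keys):
            markers = panel_keys[cell_type]
            if not markers & measured:
                logger.warning(
                    "cell type %s: no marker measured in %s",
                    cell_type, contrast,
                )
            present = [m for m in markers if m in rows.index]
            sig = rows.loc[present]
            sig = sig[sig["padj"] < tau]
            if sig.empty:
                status, score = STATUS_NO_SIG, np.nan
            else:
                signs = np.sign(sig["log2fc"].to_numpy())
                if signs.max() > 0 and signs.min() < 0:
                    status, score = STATUS_OPPOSING, np.nan
                else:
                    status = STATUS_SCORED
                    score = float(sig["log2fc"].mean())
            records.append({
                "contrast": contrast,
                "time_h": int(time_h),
                "cell_type": cell_type,
                "score": score,
                "status": status,
                "n_markers_used": 0 if status != STATUS_SCORED else len(sig),
            })
    return pd.DataFrame(records)
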