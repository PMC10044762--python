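"""Phenotype activity scores from DEG overlays, with permutation p-values.

The activity of phenotype p at one (contrast, time) is the
influence-weighted sum of significant genes' fold changes,

    A_p = sum over significant genes g of I(g, p) * log2FC_g,

a signed, directional statistic: positive A_p predicts net upregulation of
the process.  Scores are normalized per (contrast, time) to [-1, +1] by the
largest |A| across phenotypes, so normalized values support within-phenotype
comparison across time, not comparison between different processes.

Significance comes from a permutation null that shuffles the
(log2FC, padj) tuples across all measured mapped genes, preserving the
map-coverage structure of the data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .influence import InfluenceMatrix
from .mim import MolecularInteractionMap
from .overlay import OverlaySet

logger = logging.getLogger(__name__)


def _activity(fc: np.ndarray, sig: np.ndarray, I: np.ndarray) -> np.ndarray:
    return (fc * sig) @ I


def phenotype_scores(mim: MolecularInteractionMap, infl: InfluenceMatrix,
                     overlay_set: OverlaySet,
                     tau: float = 0.05) -> pd.DataFrame:
    """Raw and normalized phenotype activities for one (contrast, time).

    Returns a DataFrame (contrast, time_h, phenotype, score, score_norm).
    Phenotypes with an empty upstream universe score exactly 0 and are
    flagged in the ``empty_universe`` column.
    """
    phenos = list(infl.I.columns)
    measured = overlay_set.measured
    genes = [g for g in measured.index if g in infl.I.index]
    I = infl.I.loc[genes, phenos].to_numpy() if genes else np.zeros(
        (0, len(phenos)))
    fc = measured.loc[genes, "log2fc"].to_numpy() if genes else np.zeros(0)
    sig = (measured.loc[genes, "padj"].to_numpy() < tau) if genes else (
        np.zeros(0, dtype=bool))
    raw = _activity(fc, sig, I)
    peak = np.max(np.abs(raw)) if raw.size else 0.0
    norm = raw / peak if peak > 0 else np.zeros_like(raw)
    empty = (infl.I.loc[:, phenos] != 0).sum(axis=0).to_numpy() == 0
    if empty.any():
        logger.warning(
            "%d phenotype(s) have an empty upstream universe", empty.sum())
    return pd.DataFrame({
        "contrast": overlay_set.contrast,
        "time_h": overlay_set.time_h,
        "phenotype": phenos,
        "score": raw,
        "score_norm": norm,
        "empty_universe": empty,
    })


def phenotype_permutation_test(mim: MolecularInteractionMap,
                               infl: InfluenceMatrix,
                               overlay_set: OverlaySet,
                               n_perm: int = 1000,
                               seed: int | None = None,
                               tau: float = 0.05) -> pd.Series:
    """Permutation p-value per phenotype for |A_p| under gene-label shuffling.

    The null shuffles the (log2FC, padj) tuples across all measured mapped
    genes; p = (1 + #{|A_p^perm| >= |A_p|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    phenos = list(infl.I.columns)
    measured = overlay_set.measured
    genes = [g for g in measured.index if g in infl.I.index]
    if not genes:
        logger.warning("empty overlay: permutation p-values set to 1")
        return pd.Series(1.0, index=phenos, name="p_perm")
    I = infl.I.loc[genes, phenos].to_numpy()
    fc = measured.loc[genes, "log2fc"].to_numpy()
    sig = measured.loc[genes, "padj"].to_numpy() < tau
    observed = np.abs(_activity(fc, sig, I))
    weights = fc * sig  # tuples shuffle jointly, so permute the product
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(phenos), dtype=int)
    perm_block = np.empty((n_perm, len(genes)))
    for i in range(n_perm):
        perm_block[i] = rng.permutation(weights)
    null = np.abs(perm_block @ I)
    exceed = (null >= observed[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(pvals, index=phenos, name="p_perm")


def phase_wheel_export(activities: pd.DataFrame,
                       phase_annotation: dict[str, str | None]) -> pd.DataFrame:
    """Long-format table (phase, phenotype, time_h, score_norm[, p_perm])
    ordered for radial ("wheel") plotting by inflammation phase.

    Phenotypes without a phase label are grouped under ``unassigned``;
    missing (phenotype, time) combinations are simply absent, never
    NaN-filled.
    """
    rows = activities.copy()
    rows["phase"] = rows["phenotype"].map(
        lambda p: phase_annotation.get(p) or "unassigned")
    cols = ["phase", "phenotype", "time_h", "score_norm"]
    if "p_perm" in rows.columns:
        cols.append("p_perm")
    return (rows[cols]
            .sort_values(["phase", "phenotype", "time_h"])
            .reset_index(drop=True))
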