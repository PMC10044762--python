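"""Count normalization, PCA outlier screening, and a simple DE stand-in.

The differential-expression routine here is an explicitly simple stand-in
(log-scale Welch t-test with Benjamini-Hochberg correction), not a
negative-binomial GLM: the pipeline's contribution is downstream of DE, and
externally computed DEG tables (e.g. from DESeq2) are accepted as
first-class input via :func:`read_deg_table`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["contrast", "time_h", "gene", "log2fc", "padj", "base_mean"]


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (genes x samples input).

    For sample j, the factor is the median over genes g -- restricted to
    genes with strictly positive counts in every sample -- of
    count[g, j] / geometric-mean over samples of count[g, .].
    """
    _validate_counts(counts)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "consider a pseudo-count fallback"
        )
    logc = np.log(positive.to_numpy(dtype=float))
    log_geo_means = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geo_means, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame,
                     factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided per-sample by their size factors."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# PCA outlier screening


def pca_outliers(counts: pd.DataFrame, metadata: pd.DataFrame,
                 n_components: int = 2,
                 threshold_mads: float = 3.0) -> pd.DataFrame:
    """Flag outlying samples per (group, time) stratum on a PC1-2 distance.

    Within each stratum, log2(normalized + 1) profiles are gene-centered and
    projected onto the top two principal components; a sample is flagged when
    its Euclidean distance from the stratum centroid exceeds
    median + threshold_mads * MAD of the stratum's distances.  Strata with
    fewer than 4 samples are skipped with a warning.

    Returns a DataFrame (sample, group, time_h, distance, flagged).
    """
    norm = normalize_counts(counts)
    logn = np.log2(norm + 1.0)
    records = []
    for (group, time_h), sub in metadata.groupby(["group", "time_h"]):
        samples = [s for s in sub["sample"] if s in logn.columns]
        if len(samples) < 4:
            logger.warning(
                "stratum (%s, %s h): %d sample(s) < 4, skipped",
                group, time_h, len(samples),
            )
            continue
        x = logn[samples].to_numpy(dtype=float).T  # samples x genes
        x = x - x.mean(axis=0, keepdims=True)      # gene-centered
        k = min(n_components, len(samples) - 1)
        scores = PCA(n_components=k, svd_solver="full").fit_transform(x)
        centroid = scores.mean(axis=0)
        dist = np.linalg.norm(scores - centroid, axis=1)
        med = np.median(dist)
        mad = stats.median_abs_deviation(dist, scale=1.0)
        cut = med + threshold_mads * mad
        for s, d in zip(samples, dist):
            records.append({
                "sample": s, "group": group, "time_h": time_h,
                "distance": float(d), "flagged": bool(d > cut),
            })
    return pd.DataFrame(
        records, columns=["sample", "group", "time_h", "distance", "flagged"])


# ---------------------------------------------------------------------------
# Differential expression stand-in


def simple_de(counts: pd.DataFrame, metadata: pd.DataFrame, contrast: str,
              time_h: int) -> pd.DataFrame:
    """Per-gene DE at one time point: Welch t-test on log2(normalized + 0.5).

    log2FC is the treatment-minus-control difference of group means on the
    log scale; p-values are BH-adjusted across genes within the
    (contrast, time) stratum; base_mean is the mean normalized count over
    both groups' samples.  Degenerate genes (identical values in both
    groups) get p = 1 by convention.
    """
    meta = metadata[(metadata["contrast"] == contrast)
                    & (metadata["time_h"] == time_h)]
    t_samples = meta.loc[meta["group"] == "treatment", "sample"].tolist()
    c_samples = meta.loc[meta["group"] == "control", "sample"].tolist()
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError(
            f"contrast {contrast!r} at {time_h} h needs >= 2 samples per "
            f"group (got {len(t_samples)} vs {len(c_samples)})"
        )
    norm = normalize_counts(counts[t_samples + c_samples])
    logs = np.log2(norm + 0.5)
    xt = logs[t_samples].to_numpy(dtype=float)
    xc = logs[c_samples].to_numpy(dtype=float)
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    degenerate = (xt.std(axis=1) == 0) & (xc.std(axis=1) == 0)
    pvals[degenerate] = 1.0
    log2fc = np.where(degenerate & (np.abs(log2fc) < 1e-12), 0.0, log2fc)
    padj = multipletests(pvals, method="fdr_bh")[1]
    base_mean = norm.to_numpy(dtype=float).mean(axis=1)
    return pd.DataFrame({
        "contrast": contrast,
        "time_h": time_h,
        "gene": counts.index,
        "log2fc": log2fc,
        "padj": padj,
        "base_mean": base_mean,
    })


def de_all_times(counts: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: str) -> pd.DataFrame:
    """Concatenated simple_de over every time point present for a contrast."""
    times = sorted(
        metadata.loc[metadata["contrast"] == contrast, "time_h"].unique())
    if not times:
        raise ValueError(f"no samples for contrast {contrast!r}")
    return pd.concat(
        [simple_de(counts, metadata, contrast, t) for t in times],
        ignore_index=True,
    )


def drop_samples(counts: pd.DataFrame, metadata: pd.DataFrame,
                 samples: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flagged samples from counts and metadata together."""
    keep = [s for s in counts.columns if s not in set(samples)]
    return counts[keep], metadata[metadata["sample"].isin(keep)].copy()


# ---------------------------------------------------------------------------
# I/O


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    _validate_counts(counts)
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "contrast", "group", "time_h", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Long-format DEG table: contrast, time_h, gene, log2fc, padj, base_mean."""
    deg = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(deg.columns)
    if missing:
        raise ValueError(f"DEG table missing column(s): {sorted(missing)}")
    return deg


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    deg[DEG_COLUMNS].to_csv(path, sep="\t", index=False)
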