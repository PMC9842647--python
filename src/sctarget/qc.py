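"""Cell quality filtering, depth normalization and rank-sum marker statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["QCThresholds", "qc_filter", "normalize_log", "rank_sum_markers"]


@dataclass
class QCThresholds:
    """Cell-level QC gates: detected-gene range and mitochondrial fraction cap."""

    min_genes: int = 200
    max_genes: int = 5000
    max_mito_frac: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.min_genes < self.max_genes:
            raise ValueError("require 0 < min_genes < max_genes")
        if not 0.0 < self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in (0, 1]")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds = QCThresholds(),
    mito_gene_set: set[str] | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells on raw counts.

    A cell is kept iff min_genes <= detected genes <= max_genes (detected =
    count > 0) and its mitochondrial count fraction is <= max_mito_frac.
    Returns the filtered AnnData and a report listing removed cells with the
    first violated criterion (min_genes | max_genes | mito_frac).
    """
    mito_gene_set = mito_gene_set or set()
    unknown = mito_gene_set - set(adata.var_names)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    mito_cols = adata.var_names.isin(mito_gene_set)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito_cols].sum(axis=1) / np.maximum(total, 1), 1.0)

    reason = np.full(adata.n_obs, "", dtype=object)
    reason[mito_frac > thresholds.max_mito_frac] = "mito_frac"
    reason[detected > thresholds.max_genes] = "max_genes"
    reason[detected < thresholds.min_genes] = "min_genes"
    keep = reason == ""
    if not keep.any():
        counts = pd.Series(reason).value_counts().to_dict()
        raise ValueError(f"all cells removed by QC: {counts}")
    report = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "detected_genes": detected,
            "mito_frac": mito_frac,
            "removed": ~keep,
            "reason": reason,
        }
    )
    return adata[keep].copy(), report


def normalize_log(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to a common total then apply log2(x + 1).

    Zeros stay zero; a zero-total cell is rejected (run qc_filter first).
    """
    X = _dense(adata.X)
    if (X < 0).any():
        raise ValueError("negative entries in count matrix")
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; run qc_filter first")
    out = adata.copy()
    out.X = np.log2(X * (scale / totals)[:, None] + 1.0)
    out.uns["normalized"] = {"scale": scale, "log_base": 2}
    return out


def rank_sum_markers(adata: ad.AnnData, labels: str | pd.Series) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum, each group vs the rest.

    Normal approximation with tie and continuity corrections; BH adjustment
    within each group's gene list; log_fc = log2((mean_in + eps) /
    (mean_out + eps)).  Constant genes get p = 1 and log_fc = 0.
    """
    lab = adata.obs[labels] if isinstance(labels, str) else labels
    lab = pd.Series(np.asarray(lab), index=adata.obs_names)
    groups = lab.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 labels")
    if (lab.value_counts() < 2).any():
        raise ValueError("every group needs >= 2 cells")
    X = _dense(adata.X)
    n_cells, n_genes = X.shape
    eps = 1e-9

    # Ranks over all cells are shared by every group-vs-rest comparison.
    ranks = stats.rankdata(X, axis=0)
    # tie correction term per gene: sum(t^3 - t) over tied groups
    tie_term = np.zeros(n_genes)
    for g in range(n_genes):
        _, counts = np.unique(X[:, g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)

    frames = []
    N = n_cells
    for grp in groups:
        mask = (lab == grp).to_numpy()
        n1 = int(mask.sum())
        n2 = N - n1
        W = ranks[mask].sum(axis=0)
        mu = n1 * (N + 1) / 2.0
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.maximum(np.abs(W - mu) - 0.5, 0.0) / np.sqrt(var)
        p = np.where(var > 0, 2.0 * stats.norm.sf(z), 1.0)
        stat = np.where(var > 0, W, 0.0)
        mean_in = X[mask].mean(axis=0)
        mean_out = X[~mask].mean(axis=0)
        log_fc = np.where(var > 0, np.log2((mean_in + eps) / (mean_out + eps)), 0.0)
        padj = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": adata.var_names,
                    "group": grp,
                    "rank_sum_statistic": stat,
                    "p_value": p,
                    "adjusted_p": padj,
                    "log_fc": log_fc,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "adjusted_p", "p_value"], kind="mergesort").reset_index(
        drop=True
    )


def deg_list(markers: pd.DataFrame, group, padj_max: float = 0.01, min_log_fc: float = 1.0) -> list[str]:
    """Genes significantly up in ``group``: adjusted_p < padj_max and log_fc > min_log_fc."""
    m = markers[markers["group"] == group]
    hit = m[(m["adjusted_p"] < padj_max) & (m["log_fc"] > min_log_fc)]
    return list(hit["gene_id"])
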