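"""Expression-inferred copy-number profiles and the malignancy classifier.

A cell's relative copy-number profile is obtained from log-normalized
expression by (1) centering each gene on the reference-cell mean,
(2) clipping to +/- ``clip``, (3) a symmetric moving average over ``window``
genes within each chromosome (genes ordered by start coordinate, window
truncated at chromosome ends), (4) re-centering each cell on its median, and
(5) subtracting the mean reference profile.

Cells are called malignant when BOTH their CNV signal (mean squared profile
value) exceeds ``signal_threshold`` and their Pearson correlation with a
tumor consensus profile exceeds ``corr_threshold`` (strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "CNVProfiles",
    "infer_cnv_profiles",
    "cnv_signal",
    "cnv_correlation",
    "consensus_profile",
    "classify_malignant",
    "call_malignancy",
    "epithelial_score",
]

EPITHELIAL_MARKERS = (
    "EPCAM",
    "KRT8",
    "KRT18",
    "KRT19",
    "SFN",
)


@dataclass
class CNVProfiles:
    """Smoothed relative log2-dosage profiles, cells x genomically ordered genes."""

    values: pd.DataFrame  # index: cell_id, columns: ordered gene_id
    gene_chrom: pd.Series  # chrom per ordered gene

    @property
    def chrom_boundaries(self) -> list[int]:
        ch = self.gene_chrom.to_numpy()
        return [0, *list(np.flatnonzero(ch[1:] != ch[:-1]) + 1), len(ch)]


def _moving_average_by_chrom(mat: np.ndarray, chrom: np.ndarray, window: int) -> np.ndarray:
    """Symmetric moving average over genes within each chromosome block."""
    out = np.empty_like(mat)
    half = window // 2
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        block = mat[:, idx]
        m = block.shape[1]
        if m < max(window // 4, 1):
            warnings.warn(f"chromosome {c}: only {m} genes for window {window}")
        csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
        lo = np.maximum(np.arange(m) - half, 0)
        hi = np.minimum(np.arange(m) + half + 1, m)
        out[:, idx] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv_profiles(
    adata: ad.AnnData,
    annotation: pd.DataFrame,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
) -> CNVProfiles:
    """Infer smoothed relative CNV profiles from log-normalized expression.

    ``annotation`` needs gene_id/chrom/start columns; genes without annotation
    are dropped (warning when coverage falls below 80%).  Reference cells get
    profiles too; against themselves they average to ~0.
    """
    ref = pd.Index(reference_cells)
    missing = ref.difference(adata.obs_names)
    if len(missing) or len(ref) == 0:
        raise ValueError("reference_cells must be non-empty and present in the matrix")
    ann = annotation.set_index("gene_id")
    present = adata.var_names.intersection(ann.index)
    frac = len(present) / adata.n_vars if adata.n_vars else 0.0
    if frac < 0.8:
        warnings.warn(f"annotation covers only {frac:.0%} of genes; others dropped")
    ann = ann.loc[present].sort_values(["chrom", "start"], kind="mergesort")
    order = ann.index

    X = adata[:, order].X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, dtype=float)
    ref_mask = adata.obs_names.isin(ref)

    centered = X - X[ref_mask].mean(axis=0)
    clipped = np.clip(centered, -clip, clip)
    smoothed = _moving_average_by_chrom(clipped, ann["chrom"].to_numpy(), window)
    recentered = smoothed - np.median(smoothed, axis=1, keepdims=True)
    final = recentered - recentered[ref_mask].mean(axis=0)

    values = pd.DataFrame(final, index=adata.obs_names, columns=order)
    return CNVProfiles(values=values, gene_chrom=ann["chrom"])


def cnv_signal(profile: np.ndarray | pd.Series, statistic: str = "mean_square") -> float:
    """CNV signal of one profile: mean of squared values (or max - min)."""
    v = np.asarray(profile, dtype=float)
    if v.size == 0:
        raise ValueError("empty profile")
    if statistic == "mean_square":
        return float(np.mean(v**2))
    if statistic == "range":
        return float(v.max() - v.min())
    raise ValueError(f"unknown statistic {statistic!r}")


def cnv_correlation(profile, consensus) -> float:
    """Pearson r between a profile and the consensus; 0 if either is constant."""
    a = np.asarray(profile, dtype=float)
    b = np.asarray(consensus, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profile and consensus must share the gene set")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def consensus_profile(
    profiles: CNVProfiles, signals: pd.Series, top_frac: float = 0.05
) -> pd.Series:
    """Mean profile of the top ``top_frac`` cells by CNV signal."""
    n_top = max(1, int(np.ceil(top_frac * len(signals))))
    top = signals.sort_values(ascending=False).index[:n_top]
    return profiles.values.loc[top].mean(axis=0)


def classify_malignant(
    signal: float,
    correlation: float,
    signal_threshold: float = 0.05,
    corr_threshold: float = 0.5,
) -> str:
    """Malignant iff signal > signal_threshold AND correlation > corr_threshold."""
    if not (np.isfinite(signal) and np.isfinite(correlation)):
        raise ValueError("signal and correlation must be finite")
    ok = signal > signal_threshold and correlation > corr_threshold
    return "malignant" if ok else "non-malignant"


def call_malignancy(
    profiles: CNVProfiles,
    samples: pd.Series | None = None,
    signal_threshold: float = 0.05,
    corr_threshold: float = 0.5,
    consensus_top_frac: float = 0.05,
    signal_statistic: str = "mean_square",
) -> pd.DataFrame:
    """Score and classify every cell.

    The consensus profile used for the correlation is the mean profile of the
    top ``consensus_top_frac`` cells by CNV signal, computed within each
    sample when ``samples`` is given (one consensus per sample of origin).
    Returns a table (cell_id, cnv_signal, cnv_correlation, label).
    """
    vals = profiles.values
    signals = pd.Series(
        np.mean(vals.to_numpy() ** 2, axis=1)
        if signal_statistic == "mean_square"
        else np.ptp(vals.to_numpy(), axis=1),
        index=vals.index,
    )
    corr = pd.Series(index=vals.index, dtype=float)
    if samples is None:
        samples = pd.Series("all", index=vals.index)
    samples = samples.loc[vals.index]
    for _, cells in samples.groupby(samples):
        idx = cells.index
        cons = consensus_profile(
            CNVProfiles(vals.loc[idx], profiles.gene_chrom), signals.loc[idx], consensus_top_frac
        ).to_numpy()
        sub = vals.loc[idx].to_numpy()
        if np.ptp(cons) == 0:
            corr.loc[idx] = 0.0
            continue
        c = cons - cons.mean()
        s = sub - sub.mean(axis=1, keepdims=True)
        denom = np.sqrt((s**2).sum(axis=1) * (c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, s @ c / denom, 0.0)
        corr.loc[idx] = r
    label = np.where(
        (signals > signal_threshold) & (corr > corr_threshold), "malignant", "non-malignant"
    )
    return pd.DataFrame(
        {
            "cell_id": vals.index,
            "cnv_signal": signals.to_numpy(),
            "cnv_correlation": corr.to_numpy(),
            "label": label,
        }
    ).set_index("cell_id")


def epithelial_score(adata: ad.AnnData, marker_set=EPITHELIAL_MARKERS) -> pd.Series:
    """Per-cell mean log-normalized expression over the present markers.

    Serves any gene-set score (epithelial panel, meta-signatures, exhaustion
    panels); absent markers are dropped with a warning, an empty overlap is an
    error.
    """
    markers = pd.Index(pd.unique(pd.Series(list(marker_set))))
    present = markers.intersection(adata.var_names)
    if len(present) == 0:
        raise ValueError("no marker gene present in the matrix")
    if len(present) < len(markers):
        warnings.warn(f"{len(markers) - len(present)} marker(s) absent; dropped")
    X = adata[:, present].X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, dtype=float)
    return pd.Series(X.mean(axis=1), index=adata.obs_names, name="score")
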