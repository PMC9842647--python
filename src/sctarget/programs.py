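"""Per-cluster NMF expression programs and their cross-cluster consensus.

Each malignant cluster is factorized independently (non-negative matrix
factorization on log-normalized expression, best of ``n_restarts`` by
reconstruction error).  Factor loading vectors from all clusters are then
hierarchically clustered in gene space with distance 1 - Pearson r and the
tree is cut at a fixed correlation threshold; each consensus cluster is a
meta-program whose top genes by mean loading form its meta-signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF

__all__ = [
    "ProgramSet",
    "MetaProgram",
    "relative_expression",
    "nmf_programs",
    "consensus_metaprograms",
    "score_cells_by_signature",
    "annotate_program",
]


@dataclass
class ProgramSet:
    """NMF factors for one malignant cluster (loadings L2-normalized per factor)."""

    cluster_id: str
    factors: pd.DataFrame  # genes x k, non-negative
    cell_usages: pd.DataFrame  # cells x k, non-negative
    reconstruction_error: float
    top_genes: list[list[str]] = field(default_factory=list)


@dataclass
class MetaProgram:
    """A consensus cluster of programs recurring across malignant clusters."""

    members: list[tuple[str, int]]
    mean_loading: pd.Series
    meta_signature: list[str]
    annotation: str = "unassigned"
    annotation_p: float = 1.0


def relative_expression(adata_or_matrix):
    """Variance-scaled relative expression: (x - gene mean) / gene std,
    negatives clipped to zero.

    NMF on raw log-normalized values mostly recovers the shared baseline
    (highly expressed genes dominate every factor, so all factors correlate
    across clusters).  Centering each gene on its within-cluster mean removes
    the baseline; dividing by the gene's standard deviation flattens the
    residual-noise floor so it cannot masquerade as a recurrent program; the
    zero clip keeps the matrix non-negative for NMF.
    """

    def _transform(X: np.ndarray) -> np.ndarray:
        C = X - X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return np.clip(C / sd, 0.0, None)

    if hasattr(adata_or_matrix, "X"):
        out = adata_or_matrix.copy()
        X = out.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, dtype=float)
        out.X = _transform(X)
        return out
    return _transform(np.asarray(adata_or_matrix, dtype=float))


def nmf_programs(
    adata_or_matrix,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    cluster_id: str = "cluster",
    top_n: int = 50,
    max_iter: int = 500,
) -> ProgramSet:
    """Factorize one cluster's non-negative expression into ``k`` programs.

    Multiplicative-update NMF minimizing Frobenius error; the best of
    ``n_restarts`` random initializations is kept.  Factors are L2-normalized
    with the scale absorbed into the cell usages, so results are comparable
    across clusters.  Deterministic given ``seed``.
    """
    if hasattr(adata_or_matrix, "X"):
        X = adata_or_matrix.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, dtype=float)
        genes = list(adata_or_matrix.var_names)
        cells = list(adata_or_matrix.obs_names)
    else:
        X = np.asarray(adata_or_matrix, dtype=float)
        genes = [f"g{i}" for i in range(X.shape[1])]
        cells = [f"c{i}" for i in range(X.shape[0])]
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be < min(matrix shape)={min(X.shape)}")
    if X.shape[0] < 10 * k:
        raise ValueError(f"need >= 10*k cells (have {X.shape[0]}, k={k})")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=1e-6,
            random_state=seed + 10_007 * r,
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (float(model.reconstruction_err_), W, model.components_)
    err, W, H = best

    norms = np.linalg.norm(H, axis=1)
    norms[norms == 0] = 1.0
    factors = pd.DataFrame((H / norms[:, None]).T, index=genes, columns=range(k))
    usages = pd.DataFrame(W * norms[None, :], index=cells, columns=range(k))
    top = [
        list(factors[j].sort_values(ascending=False, kind="mergesort").index[:top_n])
        for j in range(k)
    ]
    return ProgramSet(
        cluster_id=cluster_id,
        factors=factors,
        cell_usages=usages,
        reconstruction_error=err,
        top_genes=top,
    )


def consensus_metaprograms(
    program_sets: list[ProgramSet],
    r_threshold: float = 0.2,
    linkage_method: str = "average",
    signature_size: int = 20,
) -> list[MetaProgram]:
    """Cluster program loading vectors across clusters into meta-programs.

    Loading vectors are aligned on the union gene universe (absent genes as
    0), clustered hierarchically with distance 1 - Pearson r and cut at
    distance 1 - ``r_threshold``.  Per consensus cluster, genes are ranked by
    mean loading (ties broken lexicographically) and the top
    ``signature_size`` form the meta-signature.  Output is sorted by cluster
    size then member identity, so it is invariant to input order.
    """
    members_all: list[tuple[str, int]] = []
    vectors: list[pd.Series] = []
    for ps in sorted(program_sets, key=lambda p: p.cluster_id):
        for j in sorted(ps.factors.columns):
            members_all.append((ps.cluster_id, int(j)))
            vectors.append(ps.factors[j])
    if len(vectors) == 0:
        raise ValueError("no programs supplied")
    universe = sorted(set().union(*[set(v.index) for v in vectors]))
    L = np.zeros((len(vectors), len(universe)))
    uidx = {g: i for i, g in enumerate(universe)}
    for i, v in enumerate(vectors):
        L[i, [uidx[g] for g in v.index]] = v.to_numpy()

    if len(vectors) == 1:
        assignments = np.array([1])
    else:
        corr = np.corrcoef(L)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum((dist + dist.T) / 2.0, 0.0)
        from scipy.spatial.distance import squareform

        Z = linkage(squareform(dist, checks=False), method=linkage_method)
        assignments = fcluster(Z, t=1.0 - r_threshold, criterion="distance")

    metas: list[MetaProgram] = []
    for cid in np.unique(assignments):
        rows = np.flatnonzero(assignments == cid)
        members = sorted(members_all[i] for i in rows)
        mean_loading = pd.Series(L[rows].mean(axis=0), index=universe)
        order = sorted(universe, key=lambda g: (-mean_loading[g], g))
        sig = [g for g in order if mean_loading[g] > 0][:signature_size]
        metas.append(MetaProgram(members=members, mean_loading=mean_loading, meta_signature=sig))
    metas.sort(key=lambda m: (-len(m.members), m.members))
    return metas


def score_cells_by_signature(adata, meta_signature) -> pd.Series:
    """Per-cell mean expression over the signature genes (order-invariant)."""
    from .cnv import epithelial_score

    return epithelial_score(adata, marker_set=meta_signature)


def annotate_program(
    meta_signature,
    reference_sets: dict[str, set[str]],
    universe,
    alpha: float = 0.01,
) -> tuple[str, float]:
    """Label a meta-signature by hypergeometric over-representation.

    The label is the reference set with the smallest over-representation
    p-value, assigned only when its Bonferroni-adjusted p (over the reference
    sets) is below ``alpha``; otherwise "unassigned".  Returns
    (label, adjusted p of the best set).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not reference_sets:
        raise ValueError("no reference sets")
    sig = set(meta_signature) & universe
    N, n = len(universe), len(sig)
    best_label, best_p = "unassigned", 1.0
    for label in sorted(reference_sets):
        ref = reference_sets[label] & universe
        K = len(ref)
        k = len(sig & ref)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        if p < best_p:
            best_label, best_p = label, p
    p_adj = min(1.0, best_p * len(reference_sets))
    if p_adj < alpha:
        return best_label, p_adj
    return "unassigned", p_adj
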