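"""Hi-C matrix balancing, A/B compartments, insulation-score TAD calling and
cross-condition structural comparison.

All analysis is cis-only and runs per chromosome on dense symmetric matrices.
Balancing is iterative correction (ICE): low-coverage bins are masked, then
rows/columns are scaled until the retained marginals are uniform.
Compartments come from the leading eigenvector of the Pearson correlation
matrix of the observed/expected map at 500-kb resolution, with the sign
oriented so the gene-denser compartment is A.  TADs come from insulation-score
valleys at 40-kb resolution, filtered by a 200-kb minimum size and excluded
(telomere/centromere) regions, and matched across conditions by 70% reciprocal
overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMap",
    "ice_normalize",
    "observed_expected",
    "compartment_track",
    "compartment_switch",
    "insulation_track",
    "call_tads",
    "conserved_tads",
    "gene_structure_report",
]


@dataclass
class ContactMap:
    """A binned symmetric contact matrix with its bin table.

    ``bias`` is the ICE balancing vector (NaN on masked bins); ``balanced``
    flags whether ``matrix`` already holds balanced counts.
    """

    bins: pd.DataFrame  # columns chrom, start, end
    matrix: np.ndarray
    resolution: int
    bias: np.ndarray | None = None
    balanced: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.bins):
            raise ValueError("matrix must be square and match the bin table")
        if not np.allclose(m, m.T, rtol=1e-8, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if np.nanmin(m) < 0:
            raise ValueError("matrix must be non-negative")
        self.matrix = m

    def chrom_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        ch = self.bins["chrom"].to_numpy()
        start = 0
        for i in range(1, len(ch) + 1):
            if i == len(ch) or ch[i] != ch[start]:
                out[ch[start]] = slice(start, i)
                start = i
        return out


def ice_normalize(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 200,
    low_coverage_frac: float = 0.02,
) -> ContactMap:
    """Iterative-correction balancing of a contact map.

    Bins with zero marginal plus the lowest ``low_coverage_frac`` of nonzero
    marginals are masked (NaN bias).  Row/column scaling repeats until the
    coefficient of variation of the retained marginals drops below ``tol``;
    non-convergence is flagged, not raised.
    """
    M = cmap.matrix.copy()
    n = M.shape[0]
    marg = M.sum(axis=1)
    mask = marg > 0
    if mask.any() and low_coverage_frac > 0:
        # quantile over all bins: zero (already-masked) bins occupy the bottom,
        # which keeps re-balancing an already-balanced map a no-op
        cut = np.quantile(marg, low_coverage_frac)
        mask &= marg >= cut
    W = M[np.ix_(mask, mask)]
    bias_r = np.ones(int(mask.sum()))
    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=1)
        mean_s = s.mean()
        if mean_s == 0:
            break
        cv = s.std() / mean_s
        if cv < tol:
            converged = True
            break
        d = s / mean_s
        d[d == 0] = 1.0
        W = W / np.outer(d, d)
        bias_r *= d
    if not converged:
        warnings.warn("ICE did not converge within max_iter")
    # rescale so balanced totals match raw totals on retained bins
    bias = np.full(n, np.nan)
    bias[mask] = bias_r
    balanced = np.full_like(M, np.nan)
    balanced[np.ix_(mask, mask)] = W
    return ContactMap(
        bins=cmap.bins,
        matrix=np.nan_to_num(balanced, nan=0.0),
        resolution=cmap.resolution,
        bias=bias,
        balanced=True,
        converged=converged,
    )


def observed_expected(cmap: ContactMap) -> ContactMap:
    """Divide each entry by the mean of its diagonal (per chromosome).

    Entries on diagonals whose mean is zero, and masked bins, become 0 with a
    NaN-free matrix; retained diagonals of the output average to 1.
    """
    if not cmap.balanced:
        raise ValueError("observed_expected expects a balanced map")
    out = np.zeros_like(cmap.matrix)
    if cmap.bias is not None:
        mask = np.isfinite(cmap.bias)
    else:
        mask = np.ones(cmap.matrix.shape[0], dtype=bool)
    for _, sl in cmap.chrom_slices().items():
        sub = cmap.matrix[sl, sl]
        m = mask[sl]
        k = sub.shape[0]
        for d in range(k):
            i = np.arange(k - d)
            j = i + d
            keep = m[i] & m[j]
            if not keep.any():
                continue
            exp = sub[i[keep], j[keep]].mean()
            if exp == 0:
                continue
            vals = sub[i[keep], j[keep]] / exp
            out[sl, sl][i[keep], j[keep]] = vals
            out[sl, sl][j[keep], i[keep]] = vals
    return ContactMap(
        bins=cmap.bins,
        matrix=out,
        resolution=cmap.resolution,
        bias=cmap.bias,
        balanced=True,
        converged=cmap.converged,
    )


def compartment_track(oe: ContactMap, gene_density: np.ndarray) -> pd.DataFrame:
    """A/B compartment track from the leading eigenvector of the O/E
    correlation matrix, oriented so A bins are gene-denser.

    Returns the bin table plus ``eigenvector`` and ``compartment`` (A/B, NaN
    on masked bins).  Equal gene density between signs falls back to "larger
    block is A" with a warning.
    """
    gd = np.asarray(gene_density, dtype=float)
    if gd.shape[0] != len(oe.bins):
        raise ValueError("gene_density length must match bin table")
    ev = np.full(len(oe.bins), np.nan)
    for chrom, sl in oe.chrom_slices().items():
        sub = oe.matrix[sl, sl]
        retained = sub.any(axis=1)
        if retained.sum() < 10:
            warnings.warn(f"{chrom}: fewer than 10 retained bins; skipped")
            continue
        R = sub[np.ix_(retained, retained)]
        sd = R.std(axis=0)
        if np.all(sd == 0):
            warnings.warn(f"{chrom}: degenerate correlation matrix; all-NA track")
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(R.T)
        C = np.nan_to_num(C, nan=0.0)
        w, V = np.linalg.eigh(C)
        lead = V[:, np.argmax(np.abs(w))]
        vec = np.full(sub.shape[0], np.nan)
        vec[retained] = lead
        # orient: gene-denser sign is positive (A)
        pos, neg = vec > 0, vec < 0
        dens_pos = gd[sl][pos].mean() if pos.any() else -np.inf
        dens_neg = gd[sl][neg].mean() if neg.any() else -np.inf
        if np.isclose(dens_pos, dens_neg):
            warnings.warn(f"{chrom}: equal gene density; larger block assigned A")
            if neg.sum() > pos.sum():
                vec = -vec
        elif dens_neg > dens_pos:
            vec = -vec
        ev[sl] = vec
    track = oe.bins.copy()
    track["eigenvector"] = ev
    track["compartment"] = np.where(np.isnan(ev), None, np.where(ev > 0, "A", "B"))
    return track


def _locus_bins(bins: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    hit = (bins["chrom"] == chrom) & (bins["start"] < end) & (bins["end"] > start)
    return np.flatnonzero(hit.to_numpy())


def _majority_status(track: pd.DataFrame, idx: np.ndarray) -> str:
    labels = track["compartment"].iloc[idx]
    n_a = int((labels == "A").sum())
    n_b = int((labels == "B").sum())
    if n_a == n_b:
        return "ambiguous"
    return "A" if n_a > n_b else "B"


def compartment_switch(
    track_cond1: pd.DataFrame, track_cond2: pd.DataFrame, locus: tuple[str, int, int]
) -> str:
    """Compartment switch label at a locus, e.g. "B->A"; ties are "ambiguous".

    Per condition the status is the majority sign over the bins overlapping
    the locus; the two tracks must share a bin table.
    """
    if not track_cond1[["chrom", "start", "end"]].equals(track_cond2[["chrom", "start", "end"]]):
        raise ValueError("tracks must share a bin table")
    idx = _locus_bins(track_cond1, *locus)
    if idx.size == 0:
        raise ValueError(f"locus {locus} overlaps no bin")
    s1 = _majority_status(track_cond1, idx)
    s2 = _majority_status(track_cond2, idx)
    if "ambiguous" in (s1, s2):
        return "ambiguous"
    return f"{s1}->{s2}"


def insulation_track(cmap: ContactMap, window: int = 480_000) -> pd.DataFrame:
    """Insulation score per bin: log2 of the mean contact in the square
    window crossing the bin over the chromosome mean of that quantity.

    NaN within ``window`` of chromosome ends.  Invariant under global scaling
    of the matrix.
    """
    if window % cmap.resolution:
        raise ValueError("window must be a multiple of the resolution")
    w = window // cmap.resolution
    score = np.full(len(cmap.bins), np.nan)
    for chrom, sl in cmap.chrom_slices().items():
        sub = cmap.matrix[sl, sl]
        k = sub.shape[0]
        if k < 3 * w:
            warnings.warn(f"{chrom}: shorter than 3x window; skipped")
            continue
        means = np.full(k, np.nan)
        for i in range(w, k - w):
            sq = sub[i - w : i, i + 1 : i + 1 + w]
            means[i] = sq.mean()
        valid = np.isfinite(means) & (means > 0)
        if not valid.any():
            warnings.warn(f"{chrom}: all-NA insulation; skipped")
            continue
        chrom_mean = means[valid].mean()
        is_ = np.full(k, np.nan)
        is_[valid] = np.log2(means[valid] / chrom_mean)
        score[sl] = is_
    track = cmap.bins.copy()
    track["insulation"] = score
    return track


def call_tads(
    track: pd.DataFrame,
    resolution: int,
    delta_window: int = 100_000,
    strength_min: float = 0.1,
    min_size: int = 200_000,
    excluded: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Call TADs from insulation-score valleys.

    The delta vector at bin i is mean(IS over ``delta_window`` left of i)
    minus mean(IS right of i); a boundary sits at the IS minimum around each
    downward zero crossing whose peak-to-trough depth is >= ``strength_min``.
    TADs are the intervals between consecutive boundaries; those shorter than
    ``min_size`` or overlapping an excluded region are flagged filtered with
    the reason (min_size | excluded_region) but kept in the output.
    """
    excluded = excluded or []
    dw = max(1, delta_window // resolution)
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        is_ = grp["insulation"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        k = len(is_)
        delta = np.full(k, np.nan)
        for i in range(k):
            left = is_[max(0, i - dw) : i]
            right = is_[i + 1 : i + 1 + dw]
            left, right = left[np.isfinite(left)], right[np.isfinite(right)]
            if left.size and right.size:
                delta[i] = left.mean() - right.mean()
        boundaries: list[int] = []
        i = 0
        finite = np.isfinite(delta)
        while i < k - 1:
            if finite[i] and finite[i + 1] and delta[i] > 0 and delta[i + 1] <= 0:
                # depth: preceding positive peak minus following negative trough
                j = i
                while j > 0 and finite[j - 1] and delta[j - 1] > 0:
                    j -= 1
                peak = np.nanmax(delta[j : i + 1])
                j2 = i + 1
                while j2 < k - 1 and finite[j2 + 1] and delta[j2 + 1] <= 0:
                    j2 += 1
                trough = np.nanmin(delta[i + 1 : j2 + 1])
                if peak - trough >= strength_min:
                    lo, hi = max(0, i - dw), min(k, i + 2 + dw)
                    seg = np.where(np.isfinite(is_[lo:hi]), is_[lo:hi], np.inf)
                    boundaries.append(lo + int(np.argmin(seg)))
                i = j2
            i += 1
        boundaries = sorted(set(boundaries))
        edges = [0, *boundaries, k]
        low_conf = len(boundaries) == 0
        for lo_b, hi_b in zip(edges[:-1], edges[1:]):
            if hi_b <= lo_b:
                continue
            start, end = int(starts[lo_b]), int(ends[hi_b - 1])
            reason = ""
            if end - start < min_size:
                reason = "min_size"
            else:
                for (xc, xs, xe) in excluded:
                    if xc == chrom and xs < end and xe > start:
                        reason = "excluded_region"
                        break
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "boundary_strength": np.nan,
                    "retained": reason == "",
                    "reason": reason,
                    "low_confidence": low_conf,
                }
            )
    return pd.DataFrame(rows)


def tad_boundaries(tads: pd.DataFrame) -> pd.DataFrame:
    """Internal boundaries (chrom, pos) of the retained TADs of a TAD table."""
    rows = []
    for chrom, grp in tads[tads["retained"]].groupby("chrom", sort=False):
        g = grp.sort_values("start")
        for pos in g["start"].iloc[1:]:
            rows.append((chrom, int(pos)))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def conserved_tads(
    tads_a: pd.DataFrame,
    tads_b: pd.DataFrame,
    min_overlap: float = 0.70,
    reciprocal: bool = True,
) -> pd.DataFrame:
    """Match retained TADs across conditions by fractional overlap.

    A pair is conserved iff overlap/len(a) >= ``min_overlap`` and, when
    ``reciprocal``, overlap/len(b) >= ``min_overlap`` too.  Each TAD is
    matched to at most one partner (greatest overlap, ties to the leftmost).
    Returns one row per retained TAD of ``tads_a`` with its match and flag.
    """
    a = tads_a[tads_a["retained"]].reset_index(drop=True)
    b = tads_b[tads_b["retained"]].reset_index(drop=True)
    rows = []
    used_b: set[int] = set()
    for ia, ra in a.iterrows():
        best: tuple[float, int] | None = None
        for ib, rb in b.iterrows():
            if rb["chrom"] != ra["chrom"] or ib in used_b:
                continue
            ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if ov <= 0:
                continue
            if best is None or ov > best[0] or (ov == best[0] and rb["start"] < b.loc[best[1], "start"]):
                best = (float(ov), ib)
        conserved = False
        match = None
        if best is not None:
            ov, ib = best
            rb = b.loc[ib]
            f_a = ov / (ra["end"] - ra["start"])
            f_b = ov / (rb["end"] - rb["start"])
            conserved = f_a >= min_overlap and (not reciprocal or f_b >= min_overlap)
            if conserved:
                used_b.add(ib)
                match = (rb["chrom"], int(rb["start"]), int(rb["end"]))
        rows.append(
            {
                "chrom": ra["chrom"],
                "start": int(ra["start"]),
                "end": int(ra["end"]),
                "conserved": conserved,
                "match_start": match[1] if match else np.nan,
                "match_end": match[2] if match else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "conserved", "match_start", "match_end"]
    )


def gene_structure_report(
    annotation: pd.DataFrame,
    comp_track_1: pd.DataFrame,
    comp_track_2: pd.DataFrame,
    tads_1: pd.DataFrame,
    tads_2: pd.DataFrame,
    ins_track_1: pd.DataFrame,
    ins_track_2: pd.DataFrame,
    boundary_tolerance_bins: int = 2,
) -> pd.DataFrame:
    """Per-gene structural comparison between two conditions.

    Columns: compartment status in each condition, switch label, a
    boundary-change flag (a retained TAD boundary within
    ``boundary_tolerance_bins`` of the gene in exactly one condition) and the
    insulation difference (condition 2 minus 1) at the gene's bin.  Genes that
    map to no bin get an NA row.
    """
    if not comp_track_1[["chrom", "start", "end"]].equals(comp_track_2[["chrom", "start", "end"]]):
        raise ValueError("compartment tracks must share a bin table")
    comp_res = int((comp_track_1["end"] - comp_track_1["start"]).iloc[0])
    ins_res = int((ins_track_1["end"] - ins_track_1["start"]).iloc[0])
    b1 = tad_boundaries(tads_1)
    b2 = tad_boundaries(tads_2)
    tol = boundary_tolerance_bins * ins_res
    rows = []
    for _, g in annotation.iterrows():
        gene, chrom = g["gene_id"], g["chrom"]
        mid = (int(g["start"]) + int(g["end"])) // 2
        cidx = _locus_bins(comp_track_1, chrom, int(g["start"]), int(g["end"]))
        if cidx.size == 0:
            rows.append({"gene_id": gene, "status_1": None, "status_2": None,
                         "switch": None, "boundary_change": None, "is_diff": np.nan})
            continue
        s1 = _majority_status(comp_track_1, cidx)
        s2 = _majority_status(comp_track_2, cidx)
        switch = "ambiguous" if "ambiguous" in (s1, s2) else f"{s1}->{s2}"
        near1 = bool(((b1["chrom"] == chrom) & ((b1["pos"] - mid).abs() <= tol)).any())
        near2 = bool(((b2["chrom"] == chrom) & ((b2["pos"] - mid).abs() <= tol)).any())
        iidx = _locus_bins(ins_track_1, chrom, mid, mid + 1)
        if iidx.size:
            d = float(
                ins_track_2["insulation"].iloc[iidx[0]] - ins_track_1["insulation"].iloc[iidx[0]]
            )
        else:
            d = np.nan
        rows.append(
            {
                "gene_id": gene,
                "status_1": s1,
                "status_2": s2,
                "switch": switch,
                "boundary_change": near1 != near2,
                "is_diff": d,
            }
        )
    return pd.DataFrame(rows)
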