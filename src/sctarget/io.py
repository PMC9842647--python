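"""Readers and writers for the plain-text formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) everywhere inside the
package.  All readers validate and reject malformed input rather than
silently coercing; every writer produces files its paired reader parses back
to an equal object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "PipelineConfig",
    "read_counts",
    "write_counts",
    "read_contacts",
    "write_contacts",
    "read_bed_like",
    "write_bed_like",
]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    Validated on construction; ``from_yaml`` rejects unknown keys so a typo in
    a config file cannot silently fall back to a default.
    """

    qc_min_genes: int = 200
    qc_max_genes: int = 5000
    qc_max_mito_frac: float = 0.30
    norm_scale: float = 10_000.0
    cnv_window: int = 101
    cnv_clip: float = 3.0
    cnv_signal_threshold: float = 0.05
    cnv_corr_threshold: float = 0.5
    cnv_consensus_top_frac: float = 0.05
    nmf_k: int = 4
    nmf_restarts: int = 10
    consensus_r_threshold: float = 0.2
    signature_size: int = 20
    hic_compartment_resolution: int = 500_000
    hic_tad_resolution: int = 40_000
    insulation_window: int = 480_000
    tad_delta_window: int = 100_000
    tad_strength_min: float = 0.1
    tad_min_size: int = 200_000
    tad_overlap_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.qc_min_genes < self.qc_max_genes:
            raise ValueError("require 0 < qc_min_genes < qc_max_genes")
        if not 0.0 < self.qc_max_mito_frac <= 1.0:
            raise ValueError("qc_max_mito_frac must be in (0, 1]")
        if self.insulation_window % self.hic_tad_resolution:
            raise ValueError("insulation_window must be a multiple of the TAD resolution")
        if not 0.0 < self.tad_overlap_fraction <= 1.0:
            raise ValueError("tad_overlap_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_counts(
    mtx_path: str | Path, barcodes_path: str | Path, features_path: str | Path
) -> ad.AnnData:
    """Read a 10x-style MTX triplet (genes x cells on disk) into cells x genes.

    The matrix header must agree with the barcode and feature list lengths;
    non-integer values are accepted with a warning (normalized input).
    """
    mtx_path, barcodes_path, features_path = map(Path, (mtx_path, barcodes_path, features_path))
    for p in (mtx_path, barcodes_path, features_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    m = scipy.io.mmread(str(mtx_path)).tocsr()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    features = pd.read_csv(features_path, sep="\t", header=None)
    if m.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: {mtx_path.name} is {m.shape}, expected "
            f"({len(features)} features from {features_path.name}, "
            f"{len(barcodes)} barcodes from {barcodes_path.name})"
        )
    if m.nnz and np.any(m.data != np.round(m.data)):
        warnings.warn("non-integer values in count matrix; keeping as-is")
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene_id"))
    for i, name in zip(range(1, features.shape[1]), ("chrom", "start", "end", "strand")):
        var[name] = features[i].to_numpy()
    for name in ("start", "end"):
        if name in var:
            var[name] = var[name].astype(int)
    obs = pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="cell_id"))
    for i, name in zip(range(1, barcodes.shape[1]), ("sample", "cell_type")):
        obs[name] = barcodes[i].to_numpy()
    return ad.AnnData(X=np.asarray(m.T.todense(), dtype=np.float64), obs=obs, var=var)


def write_counts(adata: ad.AnnData, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx, barcodes.tsv and features.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
    }
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(paths["mtx"]), X.T.tocoo())
    obs_cols = [c for c in ("sample", "cell_type") if c in adata.obs]
    adata.obs[obs_cols].reset_index().to_csv(
        paths["barcodes"], sep="\t", header=False, index=False
    )
    var_cols = [c for c in ("chrom", "start", "end", "strand") if c in adata.var]
    adata.var[var_cols].reset_index().to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    return paths


def read_contacts(bins_path: str | Path, triplet_path: str | Path):
    """Read a bin table + (i, j, count) triplet file into a ContactMap.

    The stored triplet is the upper triangle; the matrix is mirrored to be
    symmetric and zero where unreported.  Duplicate (i, j) entries are summed
    with a warning.
    """
    from .hic import ContactMap

    bins = pd.read_csv(bins_path, sep="\t")
    if not {"chrom", "start", "end"} <= set(bins.columns):
        raise ValueError(f"{bins_path}: bin table needs chrom/start/end columns")
    trip = pd.read_csv(triplet_path, sep="\t")
    n = len(bins)
    mat = np.zeros((n, n))
    if len(trip):
        i = trip["i"].to_numpy(dtype=int)
        j = trip["j"].to_numpy(dtype=int)
        if i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n:
            raise ValueError(f"{triplet_path}: bin index outside bin table of size {n}")
        if trip.duplicated(subset=["i", "j"]).any():
            warnings.warn(f"{triplet_path}: duplicate (i, j) entries summed")
        np.add.at(mat, (i, j), trip["count"].to_numpy(dtype=float))
        upper = np.triu(mat, k=1)
        mat = np.diag(np.diag(mat)) + upper + upper.T
    res = int((bins["end"] - bins["start"]).iloc[0]) if n else 0
    return ContactMap(bins=bins, matrix=mat, resolution=res)


def write_contacts(cmap, bins_path: str | Path, triplet_path: str | Path) -> None:
    """Write the bin table and the upper-triangle nonzero triplet of a ContactMap."""
    cmap.bins.to_csv(bins_path, sep="\t", index=False)
    iu, ju = np.triu_indices(cmap.matrix.shape[0])
    vals = cmap.matrix[iu, ju]
    keep = vals != 0
    pd.DataFrame({"i": iu[keep], "j": ju[keep], "count": vals[keep]}).to_csv(
        triplet_path, sep="\t", index=False
    )


def read_bed_like(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a sorted DataFrame of 0-based half-open intervals.

    Columns: chrom, start, end and, when present, name and strand.  Lines with
    start >= end are rejected with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            strand = parts[5] if len(parts) > 5 else (parts[4] if len(parts) > 4 and parts[4] in "+-" else ".")
            rows.append((chrom, start, end, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed_like(df: pd.DataFrame, path: str | Path, name_col: str = "name") -> None:
    """Write chrom/start/end(/name/score/strand) rows as BED."""
    out = df.copy()
    if name_col != "name" and name_col in out:
        out = out.rename(columns={name_col: "name"})
    cols = ["chrom", "start", "end"]
    if "name" in out:
        cols.append("name")
        if "strand" in out:
            out["score"] = 0
            cols += ["score", "strand"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def annotation_from_var(var: pd.DataFrame) -> pd.DataFrame:
    """Gene annotation table (gene_id, chrom, start, end, strand) from AnnData.var."""
    ann = var.reset_index()
    ann = ann.rename(columns={ann.columns[0]: "gene_id"})
    missing = {"chrom", "start", "end"} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if "strand" not in ann:
        ann["strand"] = "."
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    if (ann["start"] >= ann["end"]).any():
        raise ValueError("annotation contains start >= end")
    return ann[["gene_id", "chrom", "start", "end", "strand"]]
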