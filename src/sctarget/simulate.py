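"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (CNV malignancy calling, NMF
meta-programs, survival filtering, Hi-C compartments/TADs) is exercised on
data produced here, so each generator returns both the dataset and a
:class:`SimTruth` record describing exactly what was planted.

Count model: per-gene baseline means are log-normal; per-cell library-size
factors scale them; copy-number segments act multiplicatively (2**log2_dosage)
on malignant-cell means before noise; program genes are jointly up-shifted in
their active cells.  Noise is negative binomial (gamma-Poisson) followed by
Bernoulli dropout.  Hi-C contact means follow a distance power law with
within-TAD enrichment and a rank-1 sign-outer-product compartment modulation;
noise is multiplicative log-normal, symmetrized.  Survival times are
exponential with a group hazard ratio and independent exponential censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "ScSimConfig",
    "HicSimConfig",
    "SurvSimConfig",
    "SimTruth",
    "simulate_scrna",
    "simulate_hic",
    "simulate_survival",
    "simulate_ihc_fractions",
]

MALIGNANT = "malignant"


@dataclass
class ScSimConfig:
    """Configuration for the single-cell count simulator.

    ``cnv_segments`` are (chrom, start_gene_idx, end_gene_idx, log2_dosage)
    with 0-based half-open *global* gene indices that must fall inside the
    named chromosome's gene block.  ``programs`` are
    (gene_set_size, n_active_cells, log2_effect); program gene sets are
    disjoint and active cells are drawn from the malignant population.
    """

    n_samples: int = 4
    cell_counts: dict[str, int] = field(
        default_factory=lambda: {MALIGNANT: 150, "epithelial": 50, "immune": 100}
    )
    n_genes: int = 2000
    n_chroms: int = 10
    cnv_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    programs: list[tuple[int, int, float]] = field(default_factory=list)
    celltype_markers: dict[str, tuple[list[int], float]] = field(default_factory=dict)
    library_size_mean: float = 5000.0
    dropout_rate: float = 0.2
    nb_dispersion: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValueError("counts must be positive")
        if any(v <= 0 for v in self.cell_counts.values()):
            raise ValueError("cell counts must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        blocks = self.chrom_blocks()
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, lo, hi, _ in self.cnv_segments:
            if chrom not in blocks:
                raise ValueError(f"unknown chromosome {chrom!r}")
            blo, bhi = blocks[chrom]
            if not (blo <= lo < hi <= bhi):
                raise ValueError(
                    f"segment [{lo},{hi}) outside {chrom} gene block [{blo},{bhi})"
                )
            for plo, phi in seen.get(chrom, []):
                if lo < phi and plo < hi:
                    raise ValueError(f"overlapping CNV segments on {chrom}")
            seen.setdefault(chrom, []).append((lo, hi))

    def chrom_blocks(self) -> dict[str, tuple[int, int]]:
        """Contiguous gene-index block per chromosome (roughly equal sizes)."""
        edges = np.linspace(0, self.n_genes, self.n_chroms + 1).astype(int)
        return {
            f"chr{i + 1}": (int(edges[i]), int(edges[i + 1]))
            for i in range(self.n_chroms)
        }


@dataclass
class HicSimConfig:
    """Configuration for the block-structured contact-matrix simulator.

    ``compartment_blocks`` maps condition name to alternating-sign run
    lengths (first run is +); ``tad_boundaries`` maps condition to strictly
    increasing internal boundary bin indices.
    """

    n_bins: int = 100
    bin_size: int = 40_000
    compartment_blocks: dict[str, list[int]] = field(default_factory=dict)
    tad_boundaries: dict[str, list[int]] = field(default_factory=dict)
    contact_decay_exponent: float = 1.0
    compartment_strength: float = 0.3
    tad_enrichment: float = 2.0
    depth: float = 100.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        for cond, blocks in self.compartment_blocks.items():
            if any(b <= 0 for b in blocks):
                raise ValueError(f"non-positive run length in {cond}")
            if sum(blocks) != self.n_bins:
                raise ValueError(f"compartment runs of {cond} must sum to n_bins")
        for cond, bounds in self.tad_boundaries.items():
            arr = list(bounds)
            if arr != sorted(set(arr)):
                raise ValueError(f"tad_boundaries of {cond} must be strictly increasing")
            if arr and (arr[0] <= 0 or arr[-1] >= self.n_bins):
                raise ValueError(f"tad_boundaries of {cond} must lie inside (0, n_bins)")

    @property
    def conditions(self) -> list[str]:
        names = set(self.compartment_blocks) | set(self.tad_boundaries)
        return sorted(names) if names else ["cond1"]


@dataclass
class SurvSimConfig:
    """Two-group exponential survival with independent exponential censoring."""

    n_per_group: int = 100
    hazard_ratio: float = 2.0
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.hazard_ratio <= 0 or self.baseline_rate <= 0 or self.censor_rate < 0:
            raise ValueError("rates must be positive (censor_rate >= 0)")


@dataclass
class SimTruth:
    """Planted ground truth accompanying each simulated dataset."""

    malignant_cell_ids: list[str] = field(default_factory=list)
    cnv_segment_map: list[tuple[str, int, int, float]] = field(default_factory=list)
    program_gene_sets: list[list[str]] = field(default_factory=list)
    program_cell_sets: list[list[str]] = field(default_factory=list)
    compartment_sign_track: dict[str, np.ndarray] = field(default_factory=dict)
    tad_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    group_labels: list[str] = field(default_factory=list)


def _sign_track(blocks: list[int]) -> np.ndarray:
    signs = np.empty(sum(blocks), dtype=int)
    pos, sign = 0, 1
    for run in blocks:
        signs[pos : pos + run] = sign
        pos += run
        sign = -sign
    return signs


def simulate_scrna(config: ScSimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Simulate a multi-sample cell x gene count matrix with planted truth.

    Returns an AnnData whose ``obs`` carries ``sample``, ``cell_type`` and the
    boolean ``is_malignant``, and whose ``var`` carries the gene annotation
    (chrom, start, end, strand; 0-based half-open, genes laid out in index
    order along each chromosome block).
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    blocks = config.chrom_blocks()
    chrom = np.empty(config.n_genes, dtype=object)
    start = np.empty(config.n_genes, dtype=int)
    for name, (lo, hi) in blocks.items():
        chrom[lo:hi] = name
        start[lo:hi] = (np.arange(hi - lo)) * 10_000
    var = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + 1_000, "strand": "+"},
        index=genes,
    )

    # baseline gene means, shared by all cells
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)

    obs_rows = []
    for s in range(config.n_samples):
        for ctype, n in config.cell_counts.items():
            for k in range(n):
                obs_rows.append((f"S{s}_{ctype}_{k}", f"S{s}", ctype))
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "sample", "cell_type"]).set_index(
        "cell_id"
    )
    obs["is_malignant"] = obs["cell_type"] == MALIGNANT
    n_cells = len(obs)

    # per-cell multiplicative effects on top of the baseline
    log2_fc = np.zeros((n_cells, config.n_genes))
    malig = obs["is_malignant"].to_numpy()
    for chrom_name, lo, hi, dosage in config.cnv_segments:
        log2_fc[malig, lo:hi] += dosage

    # planted co-expression programs: disjoint gene sets, malignant active cells
    free = np.ones(config.n_genes, dtype=bool)
    for _, lo, hi, _ in config.cnv_segments:
        free[lo:hi] = False  # keep programs off CNV segments
    free_idx = np.flatnonzero(free)
    malig_idx = np.flatnonzero(malig)
    truth = SimTruth(
        malignant_cell_ids=list(obs.index[malig]),
        cnv_segment_map=list(config.cnv_segments),
    )
    used = 0
    for size, n_active, effect in config.programs:
        gset = free_idx[used : used + size]
        if len(gset) < size:
            raise ValueError("not enough genes free of CNV segments for programs")
        used += size
        active = rng.choice(malig_idx, size=min(n_active, len(malig_idx)), replace=False)
        log2_fc[np.ix_(active, gset)] += effect
        truth.program_gene_sets.append(list(genes[gset]))
        truth.program_cell_sets.append(list(obs.index[active]))

    for ctype, (gidx, effect) in config.celltype_markers.items():
        mask = (obs["cell_type"] == ctype).to_numpy()
        log2_fc[np.ix_(mask, np.asarray(gidx, dtype=int))] += effect

    lib = rng.gamma(shape=10.0, scale=config.library_size_mean / 10.0, size=n_cells)
    mean = base[None, :] * (2.0 ** log2_fc)
    mean *= (lib / mean.sum(axis=1))[:, None]

    # gamma-Poisson (negative binomial), then dropout
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=shape, scale=1.0, size=mean.shape) / shape * mean
    counts = rng.poisson(lam).astype(np.int64)
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts *= keep

    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)
    return adata, truth


def simulate_hic(config: HicSimConfig) -> tuple[dict[str, "np.ndarray"], SimTruth]:
    """Simulate one symmetric contact matrix per condition on a shared bin table.

    Returns ``(maps, truth)`` where ``maps`` maps condition name to a
    :class:`sctarget.hic.ContactMap`.  With ``noise_sd == 0`` and no planted
    structure the matrix is an exact power law of genomic distance.
    """
    from .hic import ContactMap  # local import to avoid a cycle

    n = config.n_bins
    if config.tad_boundaries and n < 24:
        warnings.warn("n_bins is small for downstream insulation windows")
    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * config.bin_size,
            "end": (np.arange(n) + 1) * config.bin_size,
        }
    )
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    decay = (dist + 1.0) ** (-config.contact_decay_exponent)

    maps: dict[str, ContactMap] = {}
    truth = SimTruth()
    for ci, cond in enumerate(config.conditions):
        rng = np.random.default_rng(config.seed + 7919 * ci)
        expected = config.depth * decay.copy()
        blocks = config.compartment_blocks.get(cond)
        if blocks:
            signs = _sign_track(blocks)
            expected *= 1.0 + config.compartment_strength * np.outer(signs, signs)
            truth.compartment_sign_track[cond] = signs
        bounds = config.tad_boundaries.get(cond)
        if bounds is not None:
            edges = [0, *bounds, n]
            tads = list(zip(edges[:-1], edges[1:]))
            truth.tad_intervals[cond] = tads
            for lo, hi in tads:
                expected[lo:hi, lo:hi] *= config.tad_enrichment
        if config.noise_sd > 0:
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=expected.shape))
            noise = np.sqrt(noise * noise.T)  # symmetrize multiplicatively
            expected = expected * noise
        maps[cond] = ContactMap(bins=bins.copy(), matrix=expected, resolution=config.bin_size)
    return maps, truth


def simulate_survival(config: SurvSimConfig) -> pd.DataFrame:
    """Simulate a two-group survival table (subject_id, group, time, event)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    rates = np.concatenate(
        [
            np.full(n, config.baseline_rate),
            np.full(n, config.baseline_rate * config.hazard_ratio),
        ]
    )
    event_t = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        censor_t = rng.exponential(1.0 / config.censor_rate, size=2 * n)
    else:
        censor_t = np.full(2 * n, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in range(2 * n)],
            "group": ["low"] * n + ["high"] * n,
            "time": time,
            "event": event,
        }
    )


def simulate_ihc_fractions(n: int, seed: int = 0, concentration: float = 2.0) -> pd.DataFrame:
    """Draw ``n`` four-class IHC percentage vectors (rows sum to 100)."""
    rng = np.random.default_rng(seed)
    frac = rng.dirichlet(np.full(4, concentration), size=n) * 100.0
    return pd.DataFrame(
        frac, columns=["negative", "low_positive", "positive", "high_positive"]
    )
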