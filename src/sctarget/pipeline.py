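"""End-to-end demonstration pipeline on synthetic data with planted truth.

``run_demo`` wires every stage together: simulate a multi-sample single-cell
cohort with planted chromosome-arm CNVs and co-expression programs, call
malignant cells from inferred CNV profiles, discover meta-programs by NMF
consensus, intersect malignant-vs-rest DEGs with the metastasis program's
signature, filter candidates on a synthetic survival cohort with one planted
hazardous gene, and compare two simulated Hi-C conditions at a locus carrying
a planted compartment flip and a new TAD boundary.  Returns a summary dict of
the quantities a run prints.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, hic, programs, qc, targets
from .simulate import (
    HicSimConfig,
    ScSimConfig,
    SurvSimConfig,
    simulate_hic,
    simulate_scrna,
)


def default_sc_config(seed: int) -> ScSimConfig:
    """Study-condition single-cell simulation: 4 samples, arm-level CNVs on
    ~30% of the genome at |log2 dosage| >= 0.5, four planted programs of which
    two mark metastasis-like states."""
    return ScSimConfig(
        n_samples=4,
        cell_counts={"malignant": 200, "epithelial": 40, "immune": 60},
        n_genes=2000,
        n_chroms=10,
        cnv_segments=[
            ("chr1", 0, 200, 1.0),
            ("chr3", 400, 600, -1.0),
            ("chr5", 800, 1000, 0.5),
        ],
        programs=[(30, 300, 2.0), (30, 280, 2.0), (30, 260, 2.0), (30, 240, 2.0)],
        library_size_mean=5000.0,
        dropout_rate=0.2,
        seed=seed,
    )


def default_hic_config(seed: int) -> HicSimConfig:
    """Two Hi-C conditions: a compartment flip over bins 40-49 and an extra
    TAD boundary at bin 45 in the second (tumor-like) condition."""
    return HicSimConfig(
        n_bins=100,
        bin_size=40_000,
        compartment_blocks={
            "normal": [20, 30, 10, 20, 20],
            "tumor": [20, 20, 20, 20, 20],
        },
        tad_boundaries={"normal": [20, 40, 60, 80], "tumor": [20, 40, 45, 60, 80]},
        contact_decay_exponent=1.0,
        compartment_strength=0.4,
        tad_enrichment=2.0,
        noise_sd=0.1,
        seed=seed,
    )


def run_demo(seed: int = 0, outdir: str | Path | None = None) -> dict:
    rng = np.random.default_rng(seed)
    summary: dict = {"seed": seed}

    # --- single cell: simulate, QC, normalize, malignancy -------------------
    sc_cfg = default_sc_config(seed)
    adata, truth = simulate_scrna(sc_cfg)
    adata, report = qc.qc_filter(adata, qc.QCThresholds(min_genes=50))
    lognorm = qc.normalize_log(adata)
    annotation = lognorm.var.reset_index().rename(columns={"index": "gene_id"})
    annotation.columns = ["gene_id", *annotation.columns[1:]]
    reference = lognorm.obs_names[~lognorm.obs["is_malignant"]]
    profiles = cnv.infer_cnv_profiles(lognorm, annotation, reference)
    calls = cnv.call_malignancy(profiles, samples=lognorm.obs["sample"])
    truth_lab = lognorm.obs["is_malignant"].map({True: "malignant", False: "non-malignant"})
    tp = ((calls["label"] == "malignant") & (truth_lab == "malignant")).sum()
    tn = ((calls["label"] == "non-malignant") & (truth_lab == "non-malignant")).sum()
    sens = tp / (truth_lab == "malignant").sum()
    spec = tn / (truth_lab == "non-malignant").sum()
    summary["n_cells"] = int(lognorm.n_obs)
    summary["n_called_malignant"] = int((calls["label"] == "malignant").sum())
    summary["malignancy_balanced_accuracy"] = float((sens + spec) / 2)

    # --- programs: NMF per malignant cluster, consensus ---------------------
    malignant = lognorm[calls["label"] == "malignant"]
    program_sets = []
    for s, idx in malignant.obs.groupby("sample", observed=True).groups.items():
        sub = programs.relative_expression(malignant[idx])
        k = 8  # planted 4 programs + headroom for noise factors
        if sub.n_obs >= 10 * k:
            program_sets.append(
                programs.nmf_programs(
                    sub, k=k, n_restarts=4, seed=seed, cluster_id=str(s), max_iter=800
                )
            )
    metas = programs.consensus_metaprograms(program_sets, r_threshold=0.2)
    multi = [m for m in metas if len(m.members) >= 2]
    summary["n_meta_programs_multi_member"] = len(multi)
    summary["n_planted_programs"] = len(truth.program_gene_sets)

    # annotate against the planted gene sets (metastasis programs last two)
    labels = ["epithelial-1", "epithelial-2", "metastasis-I", "metastasis-II"]
    refsets = {lab: set(gs) for lab, gs in zip(labels, truth.program_gene_sets)}
    universe = list(lognorm.var_names)
    for m in metas:
        m.annotation, m.annotation_p = programs.annotate_program(
            m.meta_signature, refsets, universe
        )
    met_programs = [m for m in metas if m.annotation.startswith("metastasis")]
    summary["metastasis_program_found"] = bool(met_programs)

    # --- target funnel: DEG ∩ program, survival filter ----------------------
    markers = qc.rank_sum_markers(lognorm, calls["label"].reindex(lognorm.obs_names))
    deg = qc.deg_list(markers, "malignant", padj_max=0.01, min_log_fc=0.5)
    program_top = sorted({g for m in met_programs for g in m.meta_signature})
    if not program_top or not deg:
        candidates = []
    else:
        candidates = targets.intersect_candidates(deg, program_top)
    summary["n_candidates"] = len(candidates)

    passing: list[str] = []
    if candidates:
        planted = candidates[0]
        n_subj = 200
        expr = pd.DataFrame(
            rng.normal(size=(n_subj, len(candidates))), columns=candidates
        )
        high = expr[planted].to_numpy() > np.median(expr[planted])
        rate = 0.05 * np.where(high, 2.0, 1.0)  # planted HR = 2 for the first candidate
        event_t = rng.exponential(1.0 / rate)
        censor_t = rng.exponential(1.0 / 0.02, size=n_subj)
        surv = pd.DataFrame(
            {"time": np.minimum(event_t, censor_t), "event": (event_t <= censor_t).astype(int)}
        )
        lfc = pd.Series(0.0, index=candidates)
        lfc[planted] = 1.5  # up in tumor
        ranked = targets.rank_targets(candidates, expr, surv, lfc)
        passing = list(ranked.loc[ranked["pass"], "gene_id"])
        summary["planted_target"] = planted
    summary["passing_targets"] = passing

    # --- Hi-C: compartments, switch at locus, TADs --------------------------
    hic_cfg = default_hic_config(seed)
    maps, hic_truth = simulate_hic(hic_cfg)
    gene_density = rng.poisson(5, size=hic_cfg.n_bins).astype(float)
    # planted A bins are gene-denser in each condition, so the orientation
    # rule can recover the planted signs
    for signs in hic_truth.compartment_sign_track.values():
        gene_density[signs > 0] += 5.0
    tracks, tad_sets, ins_tracks = {}, {}, {}
    for cond, cmap in maps.items():
        balanced = hic.ice_normalize(cmap)
        oe = hic.observed_expected(balanced)
        tracks[cond] = hic.compartment_track(oe, gene_density)
        ins = hic.insulation_track(balanced, window=480_000)
        ins_tracks[cond] = ins
        tad_sets[cond] = hic.call_tads(ins, resolution=hic_cfg.bin_size)
    locus = ("chr1", 45 * hic_cfg.bin_size, 46 * hic_cfg.bin_size)
    summary["locus_compartment_switch"] = hic.compartment_switch(
        tracks["normal"], tracks["tumor"], locus
    )
    cons = hic.conserved_tads(tad_sets["normal"], tad_sets["tumor"])
    summary["n_tads_normal"] = int(tad_sets["normal"]["retained"].sum())
    summary["n_tads_tumor"] = int(tad_sets["tumor"]["retained"].sum())
    summary["n_conserved_tads"] = int(cons["conserved"].sum())

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out / "malignancy_calls.tsv", sep="\t")
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        for cond in maps:
            tracks[cond].to_csv(out / f"compartments_{cond}.tsv", sep="\t", index=False)
            tad_sets[cond].to_csv(out / f"tads_{cond}.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
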