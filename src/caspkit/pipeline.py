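"""End-to-end orchestration of the multi-omics profiling pipeline.

Stages communicate through flat files in a run directory, so any stage can
be re-run from cached upstream outputs and reproduces its downstream tables
bit-identically: generate (or ingest) -> quantify -> confidence ->
cleavage_map -> kinetic_cluster -> transcriptome -> enrichment ->
integrate_classify -> report.  All randomness derives from the root seed in
the config; a manifest records the config hash and output checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleavage, classify, cluster, confidence, enrichment, quantify, synthetic, transcriptome
from .config import RunConfig, dump_config
from .design import DEFAULT_DESIGN, GPP_ARCHETYPES, RNA_ARCHETYPES
from .io import read_fasta, read_gmt, read_tsv, write_fasta, write_gmt, write_json, write_tsv

STAGES = [
    "generate",
    "quantify",
    "confidence",
    "cleavage_map",
    "kinetic_cluster",
    "transcriptome",
    "enrichment",
    "integrate_classify",
    "report",
]

# fixed per-stage seed offsets (never derived from unstable hashes)
_SEED_OFFSETS = {name: 101 + 13 * i for i, name in enumerate(STAGES)}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seed(cfg: RunConfig, stage: str) -> int:
    return (cfg.seed * 100003 + _SEED_OFFSETS[stage]) % (2**31)


def _need(outdir: Path, stage: str, *names: str) -> list[Path]:
    paths = [outdir / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise StageError(stage, f"missing upstream outputs: {', '.join(missing)}")
    return paths


# ---------------------------------------------------------------------------
# Stage: generate / ingest
# ---------------------------------------------------------------------------

def stage_generate(cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    design = DEFAULT_DESIGN
    s = cfg.synthetic
    if cfg.mode == "user-data":
        _ingest_user_data(cfg, outdir)
        return
    seed = stage_seed(cfg, "generate")
    db = synthetic.gen_protein_db(s.n_proteins, s.length_range, seed=seed)
    write_fasta(db, outdir / "db.fasta")
    psms, truth = synthetic.gen_cleavage_psms(
        db, design, n_psms=s.n_psms, n_peptides=s.n_peptides,
        noise_sd=s.noise_sd, decoy_fraction=s.decoy_fraction,
        false_target_fraction=s.false_target_fraction,
        base_intensity=s.base_intensity, seed=seed + 1,
    )
    write_tsv(psms, outdir / "psms.tsv")
    write_tsv(truth["psms"], outdir / "truth_psms.tsv")
    write_tsv(truth["peptides"], outdir / "truth_peptides.tsv")

    # GPP layer: planted protein kinetic profiles for every db accession
    accs = sorted(db)[: min(s.n_gpp_proteins, len(db))]
    gpp, gpp_truth = synthetic.gen_trajectories(
        len(accs), GPP_ARCHETYPES, noise_sd=s.gpp_noise_sd, seed=seed + 2
    )
    gpp.index = accs
    gpp_truth.index = accs
    write_tsv(gpp.reset_index(names="accession"), outdir / "gpp_trajectories.tsv")
    write_tsv(gpp_truth.reset_index(name="archetype").rename(columns={"index": "accession"}),
              outdir / "truth_gpp.tsv")

    # gene universe: db accessions plus unlinked genes
    genes = sorted(db) + [f"GENE{i:05d}" for i in range(max(0, s.n_genes - len(db)))]
    sets, tf_map, dual = synthetic.gen_tf_collection(
        genes, n_sets=s.n_tf_sets, set_size=s.tf_set_size, n_dual=s.n_dual_tfs,
        seed=seed + 3,
    )
    write_gmt(sets, outdir / "gene_sets.gmt")
    write_tsv(pd.DataFrame(sorted(tf_map.items()), columns=["tf", "set"]),
              outdir / "tf_map.tsv")

    # transcript kinetics coupled to the protein layer: genes whose protein
    # profile is planted get an RNA archetype with a matching trend most of
    # the time, mirroring the predominantly co-regulated substrate pool
    rna_coupling = {
        "up_early": ("up_fast", "up_mid"),
        "up_late": ("up_mid", "up_late"),
        "transient": ("transient_early", "transient_mid"),
        "mid_wave": ("flat_wave", "transient_mid"),
        "down_early": ("down_fast", "down_mid"),
        "down_late": ("down_mid", "down_late"),
    }
    rng = np.random.default_rng(seed + 6)
    rna_names = sorted(RNA_ARCHETYPES)
    arch_override = {}
    for acc in accs:
        if rng.random() < 0.8:
            prefs = rna_coupling[gpp_truth.loc[acc]]
            arch_override[acc] = prefs[int(rng.integers(len(prefs)))]
        else:
            arch_override[acc] = rna_names[int(rng.integers(len(rna_names)))]

    # inhibitor-contrast counts (TM/TMZ x 0/8/24/72 h x replicates)
    counts, lengths, samples, ct_truth = synthetic.gen_counts(
        genes, design, planted_sets=sets, dual_tf_sets=dual, tf_map=tf_map,
        target_up_fc=s.target_up_fc, dispersion=s.dispersion, seed=seed + 4,
        time_archetypes=RNA_ARCHETYPES, time_amplitude=s.rna_time_amplitude,
        archetype_override=arch_override,
    )
    write_tsv(counts.reset_index(names="gene"), outdir / "counts.tsv")
    write_tsv(lengths.reset_index(name="length").rename(columns={"index": "gene"}),
              outdir / "gene_lengths.tsv")
    write_tsv(samples, outdir / "samples.tsv")

    # kinetic (stress-only) counts over the full 6-point time course
    kcounts, klengths, ksamples, _ = synthetic.gen_counts(
        genes, design, time_points=design.time_points_h, treatments=("TM",),
        dispersion=s.dispersion, seed=seed + 5,
        time_archetypes=RNA_ARCHETYPES, time_amplitude=s.rna_time_amplitude,
        archetype_override=arch_override,
    )
    write_tsv(kcounts.reset_index(names="gene"), outdir / "counts_kinetic.tsv")
    write_tsv(ksamples, outdir / "samples_kinetic.tsv")

    truth_run = {
        "dual_tfs": sorted(tf for tf, st in tf_map.items() if st in dual),
        "dual_tf_sets": dual,
        "target_genes": ct_truth["target_genes"],
        "tf_own_fc": ct_truth["tf_own_fc"],
    }
    write_json(truth_run, outdir / "truth_run.json")


def _ingest_user_data(cfg: RunConfig, outdir: Path) -> None:
    import shutil

    cfg.validate_inputs()
    u = cfg.user_data
    mapping = {
        "psms.tsv": u.psm_table,
        "db.fasta": u.fasta,
        "counts.tsv": u.counts,
        "gene_lengths.tsv": u.gene_lengths,
        "samples.tsv": u.sample_table,
    }
    if u.gene_sets_gmt:
        mapping["gene_sets.gmt"] = u.gene_sets_gmt
    if u.tf_map:
        mapping["tf_map.tsv"] = u.tf_map
    for dst, src in mapping.items():
        shutil.copyfile(src, outdir / dst)


# ---------------------------------------------------------------------------
# Stage: quantify (intensity filter)
# ---------------------------------------------------------------------------

def stage_quantify(cfg: RunConfig, outdir: Path) -> None:
    (psm_path,) = _need(outdir, "quantify", "psms.tsv")
    psms = read_tsv(psm_path)
    if cfg.quantify.normalize_channels:
        psms = quantify.normalize_channels(psms)
    kept = quantify.filter_min_intensity(psms, cfg.quantify.min_intensity)
    write_tsv(kept, outdir / "psms_filtered.tsv")


# ---------------------------------------------------------------------------
# Stage: confidence (LDA + FDR)
# ---------------------------------------------------------------------------

def stage_confidence(cfg: RunConfig, outdir: Path) -> None:
    (path,) = _need(outdir, "confidence", "psms_filtered.tsv")
    psms = read_tsv(path)
    scored = confidence.fit_discriminant(psms, cfg.fdr.features)
    res, survivors = confidence.threshold_at_fdr(scored, cfg.fdr.psm_level)
    pres, prot_surv = confidence.protein_level_fdr(survivors if len(survivors) else scored,
                                                  cfg.fdr.protein_level)
    write_tsv(scored, outdir / "psms_scored.tsv")
    write_tsv(survivors, outdir / "psms_surviving.tsv")
    write_tsv(prot_surv, outdir / "proteins_surviving.tsv")
    write_json(
        {
            "psm": res.__dict__,
            "protein": pres.__dict__,
            "peptide_level_fdr": confidence.peptide_level_fdr_estimate(
                scored, threshold=res.threshold
            ),
        },
        outdir / "fdr_summary.json",
    )


# ---------------------------------------------------------------------------
# Stage: cleavage map
# ---------------------------------------------------------------------------

def stage_cleavage(cfg: RunConfig, outdir: Path) -> None:
    _need(outdir, "cleavage_map", "psms_surviving.tsv", "db.fasta")
    surv = read_tsv(outdir / "psms_surviving.tsv")
    db = read_fasta(outdir / "db.fasta")
    peptides = surv[["peptide", "proteins"]].drop_duplicates().copy()
    truth_path = outdir / "truth_peptides.tsv"
    if truth_path.exists():
        proteases = read_tsv(truth_path).set_index("peptide")["protease"]
        peptides["protease"] = [
            proteases.get(p, "trypsin") for p in peptides["peptide"]
        ]
    else:
        peptides["protease"] = "trypsin"
    sites = cleavage.map_sites(peptides, db)
    if not sites:
        raise StageError("cleavage_map", "no digest-valid sites mapped")
    write_tsv(cleavage.sites_table(sites), outdir / "sites.tsv")
    mat = cleavage.motif_matrix(sites)
    write_tsv(mat.reset_index(names="residue"), outdir / "motif_matrix.tsv")
    refs = {}
    for ref_path in sorted(outdir.glob("known_sites_*.tsv")):
        refs[ref_path.stem.replace("known_sites_", "")] = read_tsv(ref_path)
    if cfg.mode == "synthetic" and not refs:
        refs = synthetic.gen_known_sites(
            cleavage.sites_table(sites), seed=stage_seed(cfg, "cleavage_map")
        )
        for name, df in refs.items():
            write_tsv(df, outdir / f"known_sites_{name}.tsv")
    if refs:
        write_tsv(cleavage.overlap_known(sites, refs), outdir / "site_overlap.tsv")


# ---------------------------------------------------------------------------
# Stage: kinetic clustering + overlay
# ---------------------------------------------------------------------------

def _cluster_layer(X: pd.DataFrame, c: int, cfg: RunConfig, layer: str, seed: int):
    Xs = cluster.standardize(X)
    cl = cfg.clustering
    fc = cluster.fuzzy_cmeans(Xs, c=c, m=cl.m, seed=seed, tol=cl.tol,
                              max_iter=cl.max_iter, n_starts=cl.n_starts)
    report = cluster.cluster_report(Xs.index, layer, fc)
    return Xs, fc, report


def stage_kinetic_cluster(cfg: RunConfig, outdir: Path) -> None:
    _need(outdir, "kinetic_cluster", "psms_surviving.tsv", "gpp_trajectories.tsv",
          "counts_kinetic.tsv", "samples_kinetic.tsv", "gene_lengths.tsv")
    design = DEFAULT_DESIGN
    seed = stage_seed(cfg, "kinetic_cluster")
    cl = cfg.clustering

    surv = read_tsv(outdir / "psms_surviving.tsv")
    peptide_quant = quantify.rollup_peptides(surv, design)
    write_tsv(peptide_quant, outdir / "peptides_quant.tsv")
    protein_quant = quantify.rollup_proteins(
        peptide_quant, design, unique_only=cfg.quantify.unique_peptides_only
    )
    write_tsv(protein_quant, outdir / "proteins_quant.tsv")
    rel_cols = [f"rel_{c}" for c in design.channels]
    csp_matrix = peptide_quant.set_index("peptide")[rel_cols]
    csp_matrix = csp_matrix[~csp_matrix.index.duplicated()]
    csp_s, csp_fc, csp_rep = _cluster_layer(csp_matrix, cl.csp_c, cfg, "CSP", seed)

    gpp = read_tsv(outdir / "gpp_trajectories.tsv").set_index("accession")
    gpp_s, gpp_fc, gpp_rep = _cluster_layer(gpp, cl.gpp_c, cfg, "GPP", seed + 1)
    gpp_trends = cluster.cluster_trends(gpp_fc)
    down_clusters = [int(i) + 1 for i in np.flatnonzero(gpp_trends < 0)]

    kcounts = read_tsv(outdir / "counts_kinetic.tsv").set_index("gene")
    ksamples = read_tsv(outdir / "samples_kinetic.tsv")
    lengths = read_tsv(outdir / "gene_lengths.tsv").set_index("gene")["length"]
    expr = transcriptome.rpkm(kcounts, lengths)
    by_time = np.log2(expr + 0.5).T.groupby(ksamples.set_index("sample")["time_h"]).mean().T
    by_time = by_time[sorted(by_time.columns)]
    rna_s, rna_fc, rna_rep = _cluster_layer(by_time, cl.rna_c, cfg, "RNA", seed + 2)
    write_tsv(rna_s.reset_index(names="gene"), outdir / "rna_trajectories.tsv")

    write_tsv(pd.concat([csp_rep, gpp_rep, rna_rep], ignore_index=True),
              outdir / "cluster_report.tsv")
    write_json({"gpp_down_clusters": down_clusters,
                "objectives": {"CSP": csp_fc.objective, "GPP": gpp_fc.objective,
                               "RNA": rna_fc.objective}},
               outdir / "cluster_meta.json")

    # id map: peptide -> protein accession -> gene (gene ids share the
    # accession namespace in synthetic mode)
    truth_path = outdir / "truth_peptides.tsv"
    if truth_path.exists():
        tp = read_tsv(truth_path)
        id_map = tp[["peptide", "accession"]].drop_duplicates()
    else:
        id_map = surv[["peptide", "proteins"]].drop_duplicates().rename(
            columns={"proteins": "accession"})
        id_map["accession"] = id_map["accession"].str.split(";").str[0]
    id_map = id_map[id_map["peptide"].isin(csp_s.index)].copy()
    id_map["gene"] = id_map["accession"]
    write_tsv(id_map, outdir / "id_map.tsv")

    csp_labels = csp_rep.set_index("feature")["cluster"]
    gpp_labels = gpp_rep.set_index("feature")["cluster"]
    rna_s.columns = list(csp_s.columns)
    gpp_s.columns = list(csp_s.columns)
    ov = cluster.overlay(
        csp_s, gpp_s, rna_s, csp_labels, gpp_labels, id_map,
        restrict_gpp_clusters=down_clusters if cl.restrict_overlay_to_down else None,
    )
    write_tsv(ov, outdir / "overlay.tsv")
    ov_all = cluster.overlay(csp_s, gpp_s, rna_s, csp_labels, gpp_labels, id_map,
                             restrict_gpp_clusters=None)
    write_tsv(ov_all, outdir / "overlay_unrestricted.tsv")


# ---------------------------------------------------------------------------
# Stage: transcriptome (DE + sample clustering)
# ---------------------------------------------------------------------------

def de_design(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cell-means design: one column per treatment x time condition."""
    groups = samples["treatment"].astype(str) + "_t" + samples["time_h"].astype(int).astype(str)
    levels = sorted(groups.unique())
    X = np.zeros((len(samples), len(levels)))
    for i, g in enumerate(groups):
        X[i, levels.index(g)] = 1.0
    return X, levels


def stage_transcriptome(cfg: RunConfig, outdir: Path) -> None:
    _need(outdir, "transcriptome", "counts.tsv", "samples.tsv", "gene_lengths.tsv")
    counts = read_tsv(outdir / "counts.tsv").set_index("gene")
    samples = read_tsv(outdir / "samples.tsv")
    lengths = read_tsv(outdir / "gene_lengths.tsv").set_index("gene")["length"]
    write_tsv(transcriptome.rpkm(counts, lengths).reset_index(names="gene"),
              outdir / "rpkm.tsv")
    X, levels = de_design(samples)
    t = int(cfg.de.contrast_time_h)
    arms = sorted(samples["treatment"].unique())
    if len(arms) < 2:
        raise StageError("transcriptome", "need two treatment arms for the contrast")
    con = np.zeros(len(levels))
    try:
        con[levels.index(f"{arms[1]}_t{t}")] = 1.0
        con[levels.index(f"{arms[0]}_t{t}")] = -1.0
    except ValueError as exc:
        raise StageError("transcriptome", f"contrast time {t} h not in design") from exc
    we = transcriptome.precision_weights(counts, X)
    de = transcriptome.moderated_fit(we, X, con)
    write_tsv(de.reset_index(), outdir / "de_results.tsv")
    sig = transcriptome.significant_genes(de, cfg.de.p_cut, cfg.de.fc_cut)
    write_tsv(sig.reset_index(), outdir / "de_significant.tsv")
    _, _, newick = transcriptome.sample_cluster(counts, cfg.sample_cluster.top_n,
                                                cfg.sample_cluster.vst)
    (outdir / "sample_tree.newick").write_text(newick + "\n")
    write_json({"contrast": f"{arms[1]}_t{t} - {arms[0]}_t{t}",
                "n_up": sig.attrs["n_up"], "n_down": sig.attrs["n_down"],
                "d0": de.attrs["d0"], "df_resid": de.attrs["df_resid"]},
               outdir / "de_meta.json")


# ---------------------------------------------------------------------------
# Stage: enrichment
# ---------------------------------------------------------------------------

def stage_enrichment(cfg: RunConfig, outdir: Path) -> None:
    _need(outdir, "enrichment", "de_results.tsv", "gene_sets.gmt", "tf_map.tsv", "de_meta.json")
    de = read_tsv(outdir / "de_results.tsv").set_index("gene")
    sets = read_gmt(outdir / "gene_sets.gmt")
    tf_map = dict(read_tsv(outdir / "tf_map.tsv")[["tf", "set"]].itertuples(index=False))
    meta = json.loads((outdir / "de_meta.json").read_text())
    df = meta["d0"] + meta["df_resid"] if np.isfinite(meta["d0"]) else np.inf
    cam = enrichment.camera_test(de["t"], sets, rho=cfg.enrichment.rho,
                                 df=df, min_size=cfg.enrichment.min_size)
    write_tsv(cam, outdir / "camera_results.tsv")
    calls = enrichment.tf_dual_calls(cam, de, tf_map, cfg.enrichment.fc_flat,
                                     cfg.enrichment.p_cut)
    write_tsv(calls, outdir / "tf_dual_calls.tsv")


# ---------------------------------------------------------------------------
# Stage: integrate + classify
# ---------------------------------------------------------------------------

def stage_integrate_classify(cfg: RunConfig, outdir: Path) -> None:
    _need(outdir, "integrate_classify", "overlay_unrestricted.tsv")
    ov = read_tsv(outdir / "overlay_unrestricted.tsv")
    triads = classify.triads_from_overlay(ov)
    calls = classify.classify_table(triads, cfg.classify.trend_cut, cfg.classify.r_cut)
    write_tsv(calls, outdir / "regulatory_calls.tsv")
    complete = ov[ov["complete"]]
    if len(complete):
        prot = complete.pivot_table(index="gene", columns="time", values="protein")
        trans = complete.pivot_table(index="gene", columns="time", values="transcript")
        reg = classify.substrate_regression(prot, trans)
        write_json(reg, outdir / "substrate_regression.json")


# ---------------------------------------------------------------------------
# Stage: report + manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    from importlib.metadata import version

    metrics: dict = {}
    truth_path = outdir / "truth_peptides.tsv"
    sites_path = outdir / "sites.tsv"
    if truth_path.exists() and sites_path.exists():
        truth = read_tsv(truth_path)
        sites = read_tsv(sites_path)
        planted = set(zip(truth["accession"], truth["p1_position"]))
        mapped = set(zip(sites["accession"], sites["p1_position"]))
        metrics["sites_planted"] = len(planted)
        metrics["sites_mapped"] = len(mapped)
        metrics["sites_recovered_fraction"] = (
            len(planted & mapped) / len(planted) if planted else np.nan
        )
    rep_path = outdir / "cluster_report.tsv"
    if rep_path.exists() and truth_path.exists():
        from sklearn.metrics import adjusted_rand_score

        rep = read_tsv(rep_path)
        truth = read_tsv(truth_path).drop_duplicates("peptide").set_index("peptide")
        csp = rep[rep["layer"] == "CSP"].set_index("feature")
        common = csp.index.intersection(truth.index)
        if len(common):
            metrics["csp_cluster_ari"] = float(adjusted_rand_score(
                truth.loc[common, "archetype"], csp.loc[common, "cluster"]))
        gtruth_path = outdir / "truth_gpp.tsv"
        if gtruth_path.exists():
            gt = read_tsv(gtruth_path).set_index("accession")
            gpp = rep[rep["layer"] == "GPP"].set_index("feature")
            common = gpp.index.intersection(gt.index)
            metrics["gpp_cluster_ari"] = float(adjusted_rand_score(
                gt.loc[common, "archetype"], gpp.loc[common, "cluster"]))
    run_truth_path = outdir / "truth_run.json"
    calls_path = outdir / "tf_dual_calls.tsv"
    if run_truth_path.exists() and calls_path.exists():
        run_truth = json.loads(run_truth_path.read_text())
        calls = read_tsv(calls_path)
        called = set(calls.loc[calls["called"], "tf"])
        dual = set(run_truth["dual_tfs"])
        metrics["tf_true_calls"] = len(called & dual)
        metrics["tf_false_calls"] = len(called - dual)
        metrics["tf_planted"] = len(dual)
        de_sig_path = outdir / "de_significant.tsv"
        if de_sig_path.exists():
            sig = read_tsv(de_sig_path)
            up = set(sig.loc[sig["direction"] == "up", "gene"])
            targets = set(run_truth["target_genes"])
            metrics["de_target_sensitivity"] = (
                len(up & targets) / len(targets) if targets else np.nan
            )
    reg_path = outdir / "substrate_regression.json"
    if reg_path.exists():
        metrics["protein_transcript_r"] = json.loads(reg_path.read_text())["r"]
    calls_path = outdir / "regulatory_calls.tsv"
    if calls_path.exists():
        calls = read_tsv(calls_path)
        metrics["mode_counts"] = calls["mode"].value_counts().to_dict()
    write_json(metrics, outdir / "report.json")

    lines = ["# Run report", ""]
    for k, v in metrics.items():
        lines.append(f"- {k}: {v}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")

    cfg_dict = cfg.model_dump(mode="json")
    cfg_dict.pop("outdir", None)  # scientific parameters only
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "caspkit_version": version("caspkit"),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".tsv", ".fasta", ".gmt", ".json", ".newick", ".md")
            and p.name != "manifest.json"
        },
    }
    write_json(manifest, outdir / "manifest.json")


_STAGE_FUNCS = {
    "generate": stage_generate,
    "quantify": stage_quantify,
    "confidence": stage_confidence,
    "cleavage_map": stage_cleavage,
    "kinetic_cluster": stage_kinetic_cluster,
    "transcriptome": stage_transcriptome,
    "enrichment": stage_enrichment,
    "integrate_classify": stage_integrate_classify,
    "report": stage_report,
}


def run_stage(cfg: RunConfig, stage: str, outdir: str | Path | None = None) -> Path:
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        _STAGE_FUNCS[stage](cfg, outdir)
    except StageError:
        raise
    except Exception as exc:  # tag the stage; keep partial outputs
        raise StageError(stage, str(exc)) from exc
    return outdir


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> Path:
    """Run every stage in order; returns the run directory."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, outdir / "config.yaml")
    for stage in STAGES:
        run_stage(cfg, stage, outdir)
    return outdir
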