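"""End-to-end orchestration: simulate -> process -> qc -> dmc -> annotate.

A run is described by one YAML/dict config; all randomness flows from its
single seed, so identical configs reproduce identical numeric outputs.
Every stage writes under one output directory (fastq/, calls/, qc/,
stats/, tracks/) and the run closes with a manifest listing each output
file with its SHA-256 digest, the seed and the config.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import bsproc, longstats, qc, simdata
from .panel import AmpliconPanel, load_panel, write_panel_table

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": "study1",
    "simulate": {
        "enabled": True,
        "panel": {"n_amplicons": 3, "length": 240, "gap": 30},
        "n_dmc": 4,
        "delta_max_range": [-17.0, -1.0],
        "coverage_mean": 200.0,
        "read_length": 150,
        "conversion_rate": 0.995,
        "seq_error": 0.002,
        "subject_sd": 3.0,
        "residual_sd": 1.5,
        "n_subjects": None,  # default of the cohort template
        "genotype_interaction": 1.0,  # applied to simulated DMC sites
    },
    "qc": {
        "min_conversion": 95.0,
        "min_site_coverage": 50,
        "artifact_low_coverage_frac": 0.1,
        "amplicon_min_reads": 50.0,
        "amplicon_max_chh_level": 5.0,
    },
    "stats": {
        "fdr": 0.05,
        "delta": 1.0,
        "alpha": 0.05,
        "n_sim": 100,
        "run_power": False,
        "run_genotype": True,
    },
    "annotate": {"window": 50},
    "paths": {},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in (over or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_stage(cfg: dict, outdir: str, seed: int):
    sim = cfg["simulate"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51D3]))
    panel, contig = simdata.make_toy_panel(seed=seed, **sim["panel"])
    chrom = panel.amplicons[0].chrom

    ref_path = os.path.join(outdir, "reference.fa")
    simdata.write_reference(contig, chrom, ref_path)
    panel_path = os.path.join(outdir, "panel.tsv")
    write_panel_table(panel, panel_path)

    sites = panel.site_table()
    cpg_ids = sites.loc[sites["context"] == "CpG", "cpg_id"].tolist()
    times = {"study1": (0.0, 1.0, 3.0, 6.0, 23.0), "study2": (0.0, 3.0, 18.0)}[
        cfg["cohort"]
    ]
    baseline, profile, dmc_ids = simdata.default_site_effects(
        cpg_ids,
        times,
        n_dmc=min(sim["n_dmc"], len(cpg_ids)),
        rng=rng,
        delta_max_range=tuple(sim["delta_max_range"]),
    )
    maker = simdata.study1_config if cfg["cohort"] == "study1" else simdata.study2_config
    overrides = {
        k: sim[k]
        for k in (
            "coverage_mean",
            "read_length",
            "conversion_rate",
            "seq_error",
            "subject_sd",
            "residual_sd",
        )
    }
    if sim.get("n_subjects"):
        overrides["n_subjects"] = int(sim["n_subjects"])
    gi = float(sim.get("genotype_interaction", 1.0))
    sim_cfg = maker(
        baseline,
        profile,
        seed=seed,
        genotype_interaction={s: gi for s in dmc_ids},
        **overrides,
    )
    truth = simdata.simulate_cohort(sim_cfg)
    truth.write_tsv(os.path.join(outdir, "truth.tsv"))
    truth.sample_sheet.to_csv(
        os.path.join(outdir, "sample_sheet.tsv"), sep="\t", index=False
    )
    pd.Series(dmc_ids, name="cpg_id").to_csv(
        os.path.join(outdir, "true_dmcs.tsv"), sep="\t", index=False
    )
    fastq = simdata.simulate_reads(truth, panel, sim_cfg, os.path.join(outdir, "fastq"))

    # synthetic regulatory features: GR motifs on responsive CpGs, CTCF
    # motifs on a few null CpGs, one TSS
    features = []
    for i, s in enumerate(dmc_ids):
        pos = int(sites.loc[sites["cpg_id"] == s, "pos"].iloc[0])
        features.append(
            ann.FeatureInterval(chrom, pos - 7, pos + 7, "GR_motif", 0, "+", "GR_motif")
        )
    null_ids = [s for s in cpg_ids if s not in dmc_ids][:3]
    for s in null_ids:
        pos = int(sites.loc[sites["cpg_id"] == s, "pos"].iloc[0])
        features.append(
            ann.FeatureInterval(
                chrom, pos - 9, pos + 9, "CTCF_motif", 0, "+", "CTCF_motif"
            )
        )
    a0 = panel.amplicons[0]
    features.append(
        ann.FeatureInterval(chrom, a0.start, a0.start + 1, "TSS", 0, "+", "TSS")
    )
    feat_path = os.path.join(outdir, "features.bed")
    ann.write_bed(features, feat_path)
    return panel, truth.sample_sheet, fastq, feat_path


def run_pipeline(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Execute the configured stages; returns the output manifest dict."""
    cfg = _merge(DEFAULT_CONFIG, cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []

    def _track(*paths):
        outputs.extend(str(p) for p in paths)

    if cfg["simulate"]["enabled"]:
        panel, sheet, fastq, feat_path = _simulate_stage(cfg, outdir, seed)
        _track(
            os.path.join(outdir, "reference.fa"),
            os.path.join(outdir, "panel.tsv"),
            os.path.join(outdir, "sample_sheet.tsv"),
            os.path.join(outdir, "truth.tsv"),
            os.path.join(outdir, "true_dmcs.tsv"),
            feat_path,
            *[p for pair in fastq.values() for p in pair],
        )
    else:
        paths = cfg["paths"]
        for key in ("panel", "reference", "sample_sheet", "fastq_dir"):
            if key not in paths or not os.path.exists(str(paths[key])):
                raise FileNotFoundError(f"required input path {key!r} missing")
        panel = load_panel(paths["panel"], paths["reference"])
        sheet = pd.read_csv(paths["sample_sheet"], sep="\t")
        fastq = {
            row.sample_id: (
                os.path.join(paths["fastq_dir"], f"{row.sample_id}_R1.fastq.gz"),
                os.path.join(paths["fastq_dir"], f"{row.sample_id}_R2.fastq.gz"),
            )
            for row in sheet.itertuples(index=False)
        }
        feat_path = paths.get("features")

    # process
    calls_dir = os.path.join(outdir, "calls")
    os.makedirs(calls_dir, exist_ok=True)
    index = bsproc.PanelIndex(panel)
    per_sample, logs = {}, {}
    for sample_id, (fq1, fq2) in fastq.items():
        counts, log = bsproc.process_fastq_pair(fq1, fq2, index)
        per_sample[sample_id] = counts
        logs[sample_id] = log
    matrix = bsproc.build_matrix(per_sample)
    matrix_path = os.path.join(calls_dir, "matrix.tsv")
    matrix.write_tsv(matrix_path)
    log_path = os.path.join(calls_dir, "assignment_log.tsv")
    pd.DataFrame(logs).T.rename_axis("sample_id").to_csv(log_path, sep="\t")
    _track(matrix_path, log_path)

    # qc
    qc_dir = os.path.join(outdir, "qc")
    os.makedirs(qc_dir, exist_ok=True)
    thresholds = qc.QCThresholds(**cfg["qc"])
    filtered, report = qc.apply_qc(matrix, thresholds)
    filtered_path = os.path.join(qc_dir, "filtered.tsv")
    filtered.write_tsv(filtered_path)
    report.write_tsv(os.path.join(qc_dir, "removed_cells.tsv"))
    pd.Series(report.conversion, name="conversion_pct").rename_axis("sample_id").to_csv(
        os.path.join(qc_dir, "conversion.tsv"), sep="\t"
    )
    with open(os.path.join(qc_dir, "summary.txt"), "w") as fh:
        fh.write(report.summary() + "\n")
    _track(
        filtered_path,
        os.path.join(qc_dir, "removed_cells.tsv"),
        os.path.join(qc_dir, "conversion.tsv"),
        os.path.join(qc_dir, "summary.txt"),
    )

    # dmc statistics
    stats_dir = os.path.join(outdir, "stats")
    os.makedirs(stats_dir, exist_ok=True)
    st = cfg["stats"]
    dmc = longstats.dmc_analysis(
        filtered, sheet, fdr_threshold=st["fdr"], delta_threshold=st["delta"]
    )
    dmc_path = os.path.join(stats_dir, "dmc.tsv")
    dmc.to_csv(dmc_path, sep="\t", index=False, float_format="%.6g")
    _track(dmc_path)

    if st.get("run_genotype", True) and len(dmc):
        geno_rows = []
        for cpg_id, series in longstats.series_from_matrix(filtered, sheet):
            if not dmc.loc[dmc["cpg_id"] == cpg_id, "is_dmc"].any():
                continue
            s = series.copy()
            s["genotype_group"] = np.where(s["genotype"] == "CC", "CC", "T-carrier")
            try:
                g = longstats.fit_genotype_model(s)
            except ValueError:
                continue
            for t in g.interaction_p:
                geno_rows.append(
                    (cpg_id, t, g.additive_p[t], g.interaction_p[t], g.interaction_coef[t])
                )
        geno = pd.DataFrame(
            geno_rows,
            columns=["cpg_id", "time_h", "additive_p", "interaction_p", "interaction_coef"],
        )
        geno_path = os.path.join(stats_dir, "genotype.tsv")
        geno.to_csv(geno_path, sep="\t", index=False, float_format="%.6g")
        _track(geno_path)

    if st.get("run_power", False) and len(dmc):
        power_rows = []
        dmc_sites = dmc.loc[dmc["is_dmc"], "cpg_id"].tolist()[:3]
        for cpg_id, series in longstats.series_from_matrix(filtered, sheet):
            if cpg_id not in dmc_sites:
                continue
            fit = longstats.fit_time_model(series)
            pw = longstats.power_sim(
                fit, n_sim=st["n_sim"], alpha=st["alpha"], seed=seed
            )
            power_rows.append(
                (cpg_id, pw.power, pw.ci_low, pw.ci_high, pw.n_sim, pw.alpha)
            )
        power_path = os.path.join(stats_dir, "power.tsv")
        pd.DataFrame(
            power_rows,
            columns=["cpg_id", "power", "ci_low", "ci_high", "n_sim", "alpha"],
        ).to_csv(power_path, sep="\t", index=False, float_format="%.6g")
        _track(power_path)

    # annotation
    if feat_path:
        tracks_dir = os.path.join(outdir, "tracks")
        os.makedirs(tracks_dir, exist_ok=True)
        sites = panel.site_table()
        cpg_sites = sites[sites["context"] == "CpG"][["cpg_id", "chrom", "pos"]]
        features = ann.read_bed(feat_path)
        annotations = ann.annotate_sites(
            cpg_sites, features, window=cfg["annotate"]["window"]
        )
        ann_path = os.path.join(tracks_dir, "annotation.tsv")
        annotations.to_csv(ann_path, sep="\t", index=False)
        summ = ann.summarize_localization(dmc, annotations)
        summ_path = os.path.join(tracks_dir, "localization.tsv")
        summ.to_csv(summ_path, sep="\t", index=False)
        bg_path = os.path.join(tracks_dir, "max_delta.bedGraph")
        ann.write_bedgraph(
            cpg_sites,
            dmc.set_index("cpg_id")["max_abs_delta"],
            bg_path,
        )
        _track(ann_path, summ_path, bg_path)

    manifest = {
        "seed": seed,
        "config": cfg,
        "outputs": {
            os.path.relpath(p, outdir): _sha256(p) for p in outputs if os.path.exists(p)
        },
        "qc": {
            "removed_samples": report.removed_samples,
            "removed_amplicons": report.removed_amplicons,
            "thresholds": asdict(thresholds),
        },
        "n_dmcs": int(dmc["is_dmc"].sum()) if len(dmc) else 0,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
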