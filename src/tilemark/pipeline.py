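"""End-to-end pipeline: normalize -> call regions -> annotate -> profile -> cluster."""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotation, clustering, io, normalization, profiles, regions
from .types import HMMConfig

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "signal_table": None,
    "gff3": None,
    "het_bed": None,
    "expression": None,
    "outdir": "tilemark_out",
    "marks": ["me2", "me3"],
    "h3_mark": "H3",
    "h3_adjust": True,
    "probe_spacing_bp": 35,
    "hmm": {},
    "min_5prime": 350,
    "min_3prime": 150,
    "coverage_window_bp": 20_000,
    "k_transposon": 4,
    "k_protein_coding": 5,
    "n_restarts": 10,
    "seed": 0,
}


def _require_paths(config: dict) -> None:
    for key in ("signal_table", "gff3"):
        path = config.get(key)
        if path is None:
            raise ValueError(f"pipeline config is missing required input path: {key!r}")
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline input {key!r} does not exist: {path}")
    for key in ("het_bed", "expression"):
        path = config.get(key)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"pipeline input {key!r} does not exist: {path}")


def run_pipeline(config: dict) -> dict:
    """Run all stages and return (and write) a machine-readable report."""
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["hmm"] = {**DEFAULT_CONFIG["hmm"], **(config.get("hmm") or {})}
    _require_paths(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    hmm_config = HMMConfig(**cfg["hmm"])
    spacing = int(cfg["probe_spacing_bp"])
    logger.info(
        "parameters: max_gap=%d min_run=%d cutoff=%.2f spacing_filters=(%d,%d) coverage_window=%d",
        hmm_config.max_gap_bp, hmm_config.min_run_bp, hmm_config.posterior_cutoff,
        cfg["min_5prime"], cfg["min_3prime"], cfg["coverage_window_bp"],
    )

    report: dict = {"config": {k: v for k, v in cfg.items() if k != "hmm"},
                    "hmm": vars(hmm_config)}

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    stage = _stage("normalize")
    try:
        tracks = io.read_signal_table(cfg["signal_table"])
        genes = io.read_gff3(cfg["gff3"])
        ratio_tracks = {}
        normed = {}
        all_marks = sorted({m for m, _ in tracks})
        for mark in all_marks:
            ip, inp, ratio = normalization.normalize_channel_pair(
                tracks[(mark, "ip")], tracks[(mark, "input")]
            )
            normed[mark] = (ip, inp)
            ratio_tracks[mark] = ratio
        h3_mark = cfg["h3_mark"]
        if cfg["h3_adjust"] and h3_mark in ratio_tracks:
            for mark in all_marks:
                if mark != h3_mark:
                    ratio_tracks[mark] = normalization.h3_adjust(
                        ratio_tracks[mark], ratio_tracks[h3_mark]
                    )
        for mark, track in ratio_tracks.items():
            io.write_bedgraph(track, outdir / f"{mark}.bedgraph", span=spacing)

        stage = _stage("callpeaks")
        chrom = next(iter(tracks.values())).chrom
        layout = next(iter(tracks.values())).positions
        chrom_lengths = {chrom: int(layout[-1]) + spacing}
        called = {}
        for mark in cfg["marks"]:
            if (mark, "ip") not in tracks:
                continue
            t_track = regions.probe_t_statistics(
                *normed[mark], shrinkage=hmm_config.variance_shrinkage_weight
            )
            posterior = regions.fit_two_state_hmm(t_track, hmm_config)
            regs = regions.call_regions(
                posterior, t_track.positions, hmm_config, chrom=chrom, probe_spacing=spacing
            )
            called[mark] = regs
            io.write_regions_bed(regs, outdir / f"{mark}_peaks.bed")
            cov = regions.coverage_track(regs, chrom_lengths, cfg["coverage_window_bp"])
            io.write_coverage_bedgraph(cov, cfg["coverage_window_bp"], outdir / f"{mark}_coverage.bedgraph")
        report["region_summary"] = {
            mark: regions.region_size_summary(regs) for mark, regs in called.items()
        }

        stage = _stage("annotate")
        flags = {mark: annotation.link_regions_to_genes(regs, genes) for mark, regs in called.items()}
        report["gene_type_tables"] = {}
        for mark, f in flags.items():
            table = annotation.gene_type_table(f, genes)
            table.to_csv(outdir / f"{mark}_gene_types.tsv", sep="\t")
            report["gene_type_tables"][mark] = json.loads(table.to_json(orient="index"))
        if len(flags) >= 2:
            a, b = (flags[m] for m in cfg["marks"][:2])
            report["set_overlap"] = annotation.set_overlap_test(a, b)
        if cfg.get("het_bed"):
            het = io.read_bed(cfg["het_bed"])
            strata = annotation.stratified_enrichment(flags[cfg["marks"][0]], genes, het)
            report["stratified"] = {
                name: json.loads(tab.to_json(orient="index")) if not tab.empty else {}
                for name, tab in strata.items()
            }

        stage = _stage("profile")
        spaced = profiles.select_spaced_genes(genes, cfg["min_5prime"], cfg["min_3prime"])
        report["n_spaced_genes"] = len(spaced)
        mats = {}
        for mark in cfg["marks"]:
            if mark not in ratio_tracks:
                continue
            mat = profiles.profile_matrix(ratio_tracks[mark], spaced)
            mats[mark] = mat
            mat.to_csv(outdir / f"{mark}_profiles.tsv", sep="\t")

        stage = _stage("cluster")
        report["clusters"] = {}
        if mats:
            spaced_by_id = {g.gene_id: g for g in spaced}
            for label, k in (("transposon", cfg["k_transposon"]), ("protein_coding", cfg["k_protein_coding"])):
                ids = [gid for gid in next(iter(mats.values())).index
                       if spaced_by_id[gid].gene_type == label]
                if len(ids) < k:
                    continue
                subset = [m.loc[ids] for m in mats.values()]
                result = clustering.concat_and_cluster(
                    subset, k=k, seed=cfg["seed"], n_restarts=cfg["n_restarts"]
                )
                result.as_series().to_csv(outdir / f"clusters_{label}.tsv", sep="\t")
                sizes = np.bincount(result.assignments, minlength=k + 1)[1:]
                report["clusters"][label] = {
                    "k": k,
                    "sizes": sizes.tolist(),
                    "within_cluster_ss": result.within_cluster_ss,
                }

        if cfg.get("expression"):
            import pandas as pd

            expr = pd.read_csv(cfg["expression"], sep="\t", index_col=0)
            expr = expr.loc[expr.index.intersection([g.gene_id for g in spaced])]
            if len(expr) >= 10:
                first_mark = cfg["marks"][0]
                if first_mark in mats:
                    common = mats[first_mark].index.intersection(expr.index)
                    if len(common) >= 10:
                        level = expr.loc[common].mean(axis=1)
                        dec = profiles.decile_profiles(
                            mats[first_mark].loc[common], level.to_dict()
                        )
                        dec.to_csv(outdir / "decile_profiles.tsv", sep="\t")
                        report["decile_profiles"] = json.loads(dec.to_json(orient="index"))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    logger.info("report written to %s", report_path)
    return report
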