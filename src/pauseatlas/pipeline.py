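"""End-to-end workflows over on-disk inputs: the per-species pausing
atlas with its cross-species join, and the depletion/heat-shock
perturbation analysis. Configuration is a single YAML file whose
parameter defaults are the analysis defaults throughout the package
(pause window 150/150, body offsets 300, pause-site search 100 bp,
E-value 1e-6, fold-change pseudocount 0.1, 3 kb body exclusion,
padj 0.05).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import comparative_stats, orthology, pause_motif, pausing_metrics, perturbation, tss_refine
from .io_formats import (
    THREE_PRIME,
    FIVE_PRIME,
    ValidationError,
    read_fasta_sequences,
    read_gene_annotations,
    read_signal_track,
    write_gene_annotations,
    write_signal_track,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_ATLAS_KEYS = {"seed", "outdir", "species", "pwm", "params", "proteomes"}
_PERTURB_KEYS = {"seed", "outdir", "annotation", "control", "samples", "spike_in",
                 "bins", "k", "hs_table", "params"}


@dataclass
class PipelineConfig:
    raw: dict[str, Any]
    base_dir: Path

    @classmethod
    def load(cls, path: str | Path, allowed_keys: set[str]) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - allowed_keys
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(raw=raw, base_dir=path.parent)

    def path(self, value: str) -> Path:
        """Resolve a configured path: absolute, else relative to the
        config file's directory, else relative to the working
        directory."""
        p = Path(value)
        if p.is_absolute():
            candidates = [p]
        else:
            candidates = [self.base_dir / p, p]
        for cand in candidates:
            if cand.exists():
                return cand
        raise ValidationError(f"configured path does not exist: {candidates[0]}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.entries: dict[str, dict[str, str]] = {}

    def record(self, name: str, path: Path) -> None:
        self.entries[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self) -> Path:
        out = self.outdir / "manifest.json"
        out.write_text(json.dumps(self.entries, indent=1, sort_keys=True))
        return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.monotonic()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.monotonic() - t0)
            return result
        return wrapped
    return deco


# -- species atlas ------------------------------------------------------


def run_species_atlas(config_path: str | Path) -> dict[str, dict[str, str]]:
    """Per species: TSS refinement, RPM normalisation, pausing records
    and summary, pause sites, top-positioned quartile, PWM (built or
    loaded), motif enrichment. Cross-species: presence matrix, subunit
    groups, Mann-Whitney table, enrichment-vs-mean-PI regression.
    Returns the output manifest."""
    cfg = PipelineConfig.load(config_path, _ATLAS_KEYS)
    species_cfg = cfg.raw.get("species") or {}
    if len(species_cfg) < 3:
        raise ValidationError("the cross-species regression needs >= 3 species")
    outdir = Path(cfg.raw.get("outdir", "atlas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    params = cfg.raw.get("params") or {}

    shared_pwm = None
    if cfg.raw.get("pwm"):
        shared_pwm = pause_motif.read_pwm(cfg.path(cfg.raw["pwm"]))

    summaries = []
    per_gene_pis: dict[str, list[float]] = {}
    enrichments = {}
    for sp in sorted(species_cfg):
        entry = species_cfg[sp]
        result = _run_one_species(cfg, sp, entry, params, shared_pwm, outdir, manifest)
        summaries.append(result["summary"])
        per_gene_pis[sp] = result["pis"]
        enrichments[sp] = result["enrichment"]

    # cross-species join
    fit = None
    x = [enrichments[s.species_id].enrichment for s in summaries]
    y = [s.mean_log10_pi for s in summaries]
    fit = _cross_species_regression(x, y)
    fit_path = outdir / "regression.json"
    fit_path.write_text(json.dumps({
        "slope": fit.slope, "intercept": fit.intercept, "r_squared": fit.r_squared,
        "p_value": fit.p_value, "n": fit.n,
    }, indent=1))
    manifest.record("regression", fit_path)

    summary_path = outdir / "species_summary.tsv"
    pd.DataFrame({
        "species": [s.species_id for s in summaries],
        "n_genes_ok": [s.n_genes_ok for s in summaries],
        "mean_log10_pi": [s.mean_log10_pi for s in summaries],
        "geometric_mean_pi": [s.geometric_mean_pi for s in summaries],
        "motif_enrichment": x,
    }).to_csv(summary_path, sep="\t", index=False)
    manifest.record("species_summary", summary_path)

    if cfg.raw.get("proteomes"):
        _run_orthology_stage(cfg, summaries, per_gene_pis, outdir, manifest)

    manifest.write()
    manifest.record("manifest", outdir / "manifest.json")
    return manifest.entries


@_stage("cross_species_regression")
def _cross_species_regression(x, y):
    return comparative_stats.fit_linear_regression(x, y)


@_stage("species")
def _run_one_species(cfg, sp, entry, params, shared_pwm, outdir, manifest):
    spdir = outdir / sp
    spdir.mkdir(exist_ok=True)
    genes = read_gene_annotations(cfg.path(entry["annotation"]))
    genome = read_fasta_sequences(cfg.path(entry["genome"]))[0]
    five = read_signal_track(
        cfg.path(entry["five_prime"]["plus"]), cfg.path(entry["five_prime"]["minus"]),
        FIVE_PRIME,
    )
    three = read_signal_track(
        cfg.path(entry["three_prime"]["plus"]), cfg.path(entry["three_prime"]["minus"]),
        THREE_PRIME,
    )

    refine_params = tss_refine.TssRefineParams(**(params.get("tss_refine") or {}))
    genes, reports = tss_refine.refine_tss(genes, five, refine_params)
    bed = spdir / "genes.refined.bed"
    write_gene_annotations(genes, bed)
    manifest.record(f"{sp}/refined_annotation", bed)
    rep_path = spdir / "tss_refinement.tsv"
    tss_refine.write_refinement_report(reports, rep_path)
    manifest.record(f"{sp}/tss_report", rep_path)

    three_rpm = pausing_metrics.rpm_normalize(three)
    pausing_params = pausing_metrics.PausingParams(**(params.get("pausing") or {}))
    records = pausing_metrics.compute_pausing_indexes(genes, three_rpm, pausing_params)
    rec_path = spdir / "pausing_records.tsv"
    pausing_metrics.write_pausing_records(records, rec_path)
    manifest.record(f"{sp}/pausing_records", rec_path)
    summary = pausing_metrics.summarize_species(records, species_id=sp)

    motif_params = params.get("motif") or {}
    sites = [
        s for s in (
            pause_motif.call_pause_site(g, three_rpm, motif_params.get("search_width", 100))
            for g in genes
        ) if s is not None
    ]
    sites_path = spdir / "pause_sites.tsv"
    pause_motif.write_pause_sites(sites, sites_path)
    manifest.record(f"{sp}/pause_sites", sites_path)

    top = pause_motif.select_top_positioned_quartile(sites)
    if shared_pwm is not None:
        pwm = shared_pwm
    else:
        seqs, _ = pause_motif.extract_centered_sequences(genome, top, width=20)
        pwm = pause_motif.build_pwm(seqs)
        pwm_path = spdir / "pause_pwm.txt"
        pause_motif.write_pwm(pwm, pwm_path)
        manifest.record(f"{sp}/pwm", pwm_path)
    enrichment = pause_motif.motif_enrichment_score(pwm, genome, sites, species_id=sp)
    return {
        "summary": summary,
        "pis": [r.pausing_index for r in records if r.status == "ok"],
        "enrichment": enrichment,
    }


@_stage("orthology")
def _run_orthology_stage(cfg, summaries, per_gene_pis, outdir, manifest):
    pcfg = cfg.raw["proteomes"]
    query = read_fasta_sequences(cfg.path(pcfg["query"]), alphabet="protein")
    proteomes = {
        sp: read_fasta_sequences(cfg.path(p), alphabet="protein")
        for sp, p in pcfg["species"].items()
    }
    mode = pcfg.get("mode", "lenient")
    matrix = orthology.build_presence_matrix(
        [r.name for r in query], query, proteomes, mode=mode
    )
    mat_path = outdir / "presence_matrix.tsv"
    matrix.to_tsv(mat_path)
    manifest.record("presence_matrix", mat_path)
    matrix.evidence_json(outdir / "presence_evidence.json")
    manifest.record("presence_evidence", outdir / "presence_evidence.json")

    subunits = pcfg.get("subunits") or list(matrix.matrix.index)
    in_matrix = [s for s in summaries if s.species_id in matrix.matrix.columns]
    if in_matrix:
        groups = comparative_stats.group_by_subunit_count(
            in_matrix, matrix, subunits, per_gene_pis
        )
        comps = comparative_stats.adjacent_group_comparisons(groups)
        comp_path = outdir / "subunit_group_tests.tsv"
        pd.DataFrame(comps).to_csv(comp_path, sep="\t", index=False)
        manifest.record("subunit_group_tests", comp_path)


# -- perturbation workflow ---------------------------------------------


def run_perturbation_analysis(config_path: str | Path) -> dict[str, dict[str, str]]:
    """Spike scaling, log2 fold-change tracks, binned response matrix,
    k-means clustering, and (when a differential table is configured)
    heat-shock classification and the induction-defect report."""
    cfg = PipelineConfig.load(config_path, _PERTURB_KEYS)
    for key in ("annotation", "control", "samples", "spike_in"):
        if key not in cfg.raw:
            raise ValidationError(f"perturbation config missing {key!r}")
    samples = cfg.raw["samples"]
    spike = cfg.raw["spike_in"]
    missing = ({"control"} | set(samples)) - set(spike)
    if missing:
        raise ValidationError(f"missing spike-in counts for samples: {sorted(missing)}")

    outdir = Path(cfg.raw.get("outdir", "perturb_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    genes = read_gene_annotations(cfg.path(cfg.raw["annotation"]))

    scaling = perturbation.spike_in_scaling_factors(spike)
    control = scaling.scale_track(
        "control",
        read_signal_track(cfg.path(cfg.raw["control"]["plus"]),
                          cfg.path(cfg.raw["control"]["minus"]), THREE_PRIME),
    )
    bins = cfg.raw.get("bins") or {}
    upstream = bins.get("upstream", 1000)
    downstream = bins.get("downstream", 50000)
    bin_size = bins.get("bin_size", 1000)

    matrices = []
    for name in sorted(samples):
        treated = scaling.scale_track(
            name,
            read_signal_track(cfg.path(samples[name]["plus"]),
                              cfg.path(samples[name]["minus"]), THREE_PRIME),
        )
        fc = perturbation.log2fc_track(treated, control)
        fc_plus = outdir / f"log2fc_{name}.plus.bedGraph"
        fc_minus = outdir / f"log2fc_{name}.minus.bedGraph"
        write_signal_track(fc, fc_plus, fc_minus)
        manifest.record(f"log2fc_{name}_plus", fc_plus)
        manifest.record(f"log2fc_{name}_minus", fc_minus)
        anchors = [(g, g.tss) for g in genes]
        matrices.append(
            perturbation.binned_region_matrix(
                fc, anchors, upstream=upstream, downstream=downstream, bin_size=bin_size
            )
        )

    features = np.hstack([m.imputed() for m in matrices])
    combined = perturbation.ResponseMatrix(
        gene_ids=matrices[0].gene_ids,
        values=features,
        missing=np.zeros_like(features, dtype=bool),
        bin_size=bin_size,
        upstream=upstream,
        downstream=downstream,
    )
    labels = perturbation.kmeans_cluster(
        combined, k=int(cfg.raw.get("k", 3)), seed=int(cfg.raw.get("seed", 0))
    )
    cluster_path = outdir / "clusters.tsv"
    pd.DataFrame({"gene_id": combined.gene_ids, "cluster": labels + 1}).to_csv(
        cluster_path, sep="\t", index=False
    )
    manifest.record("clusters", cluster_path)
    matrix_path = outdir / "response_matrix.tsv"
    pd.DataFrame(features, index=combined.gene_ids).to_csv(matrix_path, sep="\t")
    manifest.record("response_matrix", matrix_path)

    if cfg.raw.get("hs_table"):
        table = pd.read_csv(cfg.path(cfg.raw["hs_table"]), sep="\t")
        classes = perturbation.classify_hs_response(table.to_dict("records"))
        fc_a = dict(zip(table["gene_id"], table["fc_condition_a"]))
        fc_b = dict(zip(table["gene_id"], table["fc_condition_b"]))
        report = perturbation.hs_induction_defect(classes, fc_a, fc_b)
        rep_path = outdir / "induction_defect.json"
        rep_path.write_text(json.dumps(report, indent=1))
        manifest.record("induction_defect", rep_path)

    manifest.write()
    manifest.record("manifest", outdir / "manifest.json")
    return manifest.entries


def validate_config(config_path: str | Path, kind: str) -> None:
    allowed = _ATLAS_KEYS if kind == "atlas" else _PERTURB_KEYS
    cfg = PipelineConfig.load(config_path, allowed)
    # touch every configured path so missing inputs fail before compute
    def walk(node):
        if isinstance(node, dict):
            for v in node.values():
                walk(v)
        elif isinstance(node, str) and ("/" in node or node.endswith(
                (".bed", ".fa", ".bedGraph", ".tsv", ".txt"))):
            cfg.path(node)
    for key in ("species", "control", "samples", "annotation", "pwm", "proteomes", "hs_table"):
        if key in cfg.raw and cfg.raw[key]:
            walk(cfg.raw[key] if isinstance(cfg.raw[key], dict) else {"p": cfg.raw[key]})
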