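"""End-to-end pipeline: simulate/load -> QC -> cluster -> markers -> ASE ->
heterosis -> enrichment, with a YAML config and a JSON run manifest.

Each stage writes TSVs into its own subdirectory of the output directory
and can be re-run individually (later stages reload earlier outputs from
disk).  Reruns with the same config and seed reproduce identical result
tables.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import cluster as cluster_mod
from importlib import import_module

enrich_mod = import_module("endoase.enrich")  # package attr is shadowed by the function
from . import heterosis as het_mod
from . import io as io_mod
from . import qc as qc_mod
from .containers import AlleleCountMatrix
from .simulate import SAMPLES, SimConfig, simulate_trio, write_simulated_dataset

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline",
           "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "cluster", "markers", "ase", "heterosis", "enrich"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every problem found."""


@dataclass
class PipelineConfig:
    """All stage parameters, mirroring the module defaults."""

    mode: str = "synthetic"                      # synthetic | real
    out_dir: str = "endoase_run"
    seed: int = 0
    simulation: SimConfig = field(default_factory=SimConfig)
    inputs: Dict[str, Dict[str, str]] = field(default_factory=dict)
    # qc
    min_genes_per_cell: int = 3000
    min_cells_per_gene: int = 5
    # feature selection / embedding / clustering
    n_hvg: int = 2000
    n_pcs: int = 15
    k_neighbors: int = 20
    resolution: float = 0.4
    # markers
    logfc_threshold: float = 0.58
    min_pct: float = 0.10
    specific_log2fc: float = 0.25
    specific_max_pct2: float = 0.10
    # ase
    expected_fraction: float = 2.0 / 3.0
    min_reads: int = 20
    min_nuclei: int = 5
    ase_alpha: float = 0.05
    # heterosis
    fc_threshold: float = 1.5
    k: float = 3.0
    deg_alpha: float = 0.05
    # enrichment
    fdr: float = 0.05
    gmt: Optional[str] = None

    def validate(self) -> None:
        errs = []
        if self.mode not in ("synthetic", "real"):
            errs.append(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if self.mode == "real":
            for s in SAMPLES:
                spec = self.inputs.get(s)
                if not spec:
                    errs.append(f"real mode requires inputs.{s}")
                    continue
                for key in ("matrix", "genes", "barcodes"):
                    if key not in spec:
                        errs.append(f"inputs.{s} missing {key!r}")
            hyb = self.inputs.get("hybrid", {})
            for key in ("maternal", "paternal"):
                if hyb and key not in hyb:
                    errs.append(f"inputs.hybrid missing allele layer {key!r}")
        if not 0.0 < self.expected_fraction < 1.0:
            errs.append(f"expected_fraction={self.expected_fraction} outside (0, 1)")
        for name in ("resolution", "fc_threshold", "k"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        for name in ("min_pct", "ase_alpha", "deg_alpha", "fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} outside [0, 1]")
        if errs:
            raise ConfigError("; ".join(errs))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}


def validate_config(path: Optional[str] = None,
                    overrides: Optional[dict] = None) -> PipelineConfig:
    """Load and normalise a YAML pipeline config.

    Unknown keys are rejected with a closest-match suggestion; all problems
    are reported together, not first-failure.  An empty file yields the
    all-defaults synthetic config.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        raw = {**raw, **overrides}

    errs: List[str] = []
    cfg = PipelineConfig()
    sim_raw = raw.pop("simulation", {}) or {}
    if not isinstance(sim_raw, dict):
        errs.append("simulation must be a mapping")
        sim_raw = {}
    for key, value in raw.items():
        if key not in _TOP_KEYS:
            hint = difflib.get_close_matches(key, _TOP_KEYS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errs.append(f"unknown key {key!r}{suffix}")
            continue
        try:
            setattr(cfg, key, type(getattr(cfg, key))(value)
                    if value is not None and not isinstance(getattr(cfg, key), (dict, SimConfig))
                    else value)
        except (TypeError, ValueError):
            errs.append(f"key {key!r}: cannot coerce {value!r}")
    sim_kwargs = {}
    for key, value in sim_raw.items():
        if key not in _SIM_KEYS:
            hint = difflib.get_close_matches(key, _SIM_KEYS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errs.append(f"unknown simulation key {key!r}{suffix}")
        else:
            sim_kwargs[key] = value
    if not errs:
        try:
            cfg.simulation = SimConfig(**sim_kwargs)
            cfg.simulation.seed = cfg.seed if "seed" not in sim_kwargs else cfg.simulation.seed
            cfg.validate()
            cfg.simulation.validate()
        except (ConfigError, ValueError) as e:
            errs.append(str(e))
    if errs:
        raise ConfigError("; ".join(errs))
    return cfg


# --------------------------------------------------------------------------
# stage helpers

def _sample_dir(out_dir: str, stage: str, sample: str = "") -> str:
    d = os.path.join(out_dir, stage, sample) if sample else os.path.join(out_dir, stage)
    os.makedirs(d, exist_ok=True)
    return d


def _load_sample(path: str) -> AlleleCountMatrix:
    acm = io_mod.read_count_matrix(
        os.path.join(path, "matrix.mtx"),
        os.path.join(path, "genes.txt"),
        os.path.join(path, "barcodes.txt"),
    )
    if os.path.exists(os.path.join(path, "maternal.mtx")):
        acm = io_mod.attach_allele_layers(
            acm, os.path.join(path, "maternal.mtx"),
            os.path.join(path, "paternal.mtx"),
        )
    return acm


def _load_filtered(cfg: PipelineConfig) -> Dict[str, AlleleCountMatrix]:
    return {
        s: qc_mod.normalize_log_cpm(_load_sample(os.path.join(cfg.out_dir, "qc", s)))
        for s in SAMPLES
    }


def _load_labels(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(os.path.join(cfg.out_dir, "cluster", "labels.tsv"), sep="\t")


def _labels_for(matrices: Dict[str, AlleleCountMatrix],
                labels_df: pd.DataFrame) -> Dict[str, np.ndarray]:
    lookup = dict(zip(labels_df["barcode"], labels_df["cluster"]))
    return {
        s: np.array([lookup[b] for b in m.barcodes])
        for s, m in matrices.items()
    }


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig) -> None:
    trio = simulate_trio(cfg.simulation)
    write_simulated_dataset(trio, os.path.join(cfg.out_dir, "simulate"))


def _stage_qc(cfg: PipelineConfig) -> None:
    for s in SAMPLES:
        if cfg.mode == "synthetic":
            raw = _load_sample(os.path.join(cfg.out_dir, "simulate", s))
        else:
            spec = cfg.inputs[s]
            raw = io_mod.read_count_matrix(spec["matrix"], spec["genes"],
                                           spec["barcodes"])
            if s == "hybrid":
                raw = io_mod.attach_allele_layers(raw, spec["maternal"],
                                                  spec["paternal"])
        filtered = qc_mod.filter_cells_genes(
            raw, cfg.min_genes_per_cell, cfg.min_cells_per_gene
        )
        out = _sample_dir(cfg.out_dir, "qc", s)
        io_mod.write_count_matrix(filtered, out)
        meta = pd.DataFrame({
            "barcode": filtered.barcodes,
            "sample": s,
            "n_genes_detected": filtered.genes_detected_per_nucleus(),
            "total_counts": filtered.total_counts_per_nucleus(),
        })
        io_mod.write_table(meta, os.path.join(out, "metadata.tsv"),
                           sort_by=["barcode"])


def _common_genes(matrices: Dict[str, AlleleCountMatrix]) -> List[str]:
    shared = set(matrices[SAMPLES[0]].gene_ids)
    for s in SAMPLES[1:]:
        shared &= set(matrices[s].gene_ids)
    return sorted(shared)


def _concatenate(matrices: Dict[str, AlleleCountMatrix]):
    """Stack the per-sample filtered matrices on their shared gene set."""
    import scipy.sparse as sp

    genes = _common_genes(matrices)
    parts, barcodes, samples = [], [], []
    for s in SAMPLES:
        m = matrices[s]
        sub = m.subset(genes=m.gene_index(genes))
        parts.append(sub.counts)
        barcodes.extend(sub.barcodes)
        samples.extend([s] * sub.n_nuclei)
    acm = AlleleCountMatrix(
        counts=sp.vstack(parts).tocsr(),
        gene_ids=np.array(genes, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
    )
    return qc_mod.normalize_log_cpm(acm), np.array(samples, dtype=object)


def _stage_cluster(cfg: PipelineConfig) -> None:
    matrices = _load_filtered(cfg)
    combined, samples = _concatenate(matrices)
    hvg = qc_mod.select_hvg(combined, n_top=min(cfg.n_hvg, combined.n_genes))
    emb = qc_mod.run_pca(combined, hvg, n_pcs=cfg.n_pcs)
    res = cluster_mod.cluster_snn(emb, k_neighbors=cfg.k_neighbors,
                                  resolution=cfg.resolution, seed=cfg.seed)
    out = _sample_dir(cfg.out_dir, "cluster")
    labels = pd.DataFrame({"barcode": combined.barcodes, "sample": samples,
                           "cluster": res.labels})
    io_mod.write_table(labels, os.path.join(out, "labels.tsv"),
                       sort_by=["barcode"])
    with open(os.path.join(out, "hvg.txt"), "w") as fh:
        fh.write("\n".join(hvg) + "\n")


def _stage_markers(cfg: PipelineConfig) -> None:
    matrices = _load_filtered(cfg)
    combined, _ = _concatenate(matrices)
    labels_df = _load_labels(cfg)
    lookup = dict(zip(labels_df["barcode"], labels_df["cluster"]))
    labels = np.array([lookup[b] for b in combined.barcodes])
    markers = cluster_mod.find_markers(
        combined, labels, logfc_threshold=cfg.logfc_threshold,
        min_pct=cfg.min_pct, specific_log2fc=cfg.specific_log2fc,
        specific_max_pct2=cfg.specific_max_pct2,
    )
    io_mod.write_table(markers,
                       os.path.join(_sample_dir(cfg.out_dir, "markers"),
                                    "markers.tsv"),
                       sort_by=["cluster", "q_value", "gene"])


def _stage_ase(cfg: PipelineConfig) -> None:
    hyb = _load_filtered(cfg)["hybrid"]
    agg = ase_mod.aggregate_allelic_counts(hyb)
    res = ase_mod.assess_ase(agg, expected_fraction=cfg.expected_fraction,
                             min_reads=cfg.min_reads, min_nuclei=cfg.min_nuclei,
                             alpha=cfg.ase_alpha)
    res = ase_mod.classify_bias_strength(res)
    out = _sample_dir(cfg.out_dir, "ase")
    io_mod.write_table(res, os.path.join(out, "ase_results.tsv"),
                       sort_by=["q_value", "gene"])
    labels_df = _load_labels(cfg)
    lookup = dict(zip(labels_df["barcode"], labels_df["cluster"]))
    labels = np.array([lookup[b] for b in hyb.barcodes])
    asegs = sorted(res.loc[res["call"].isin(["MEG", "PEG"]), "gene"])
    if asegs and np.unique(labels).size >= 2:
        scores = ase_mod.cluster_enrichment_scores(hyb, labels, asegs)
        io_mod.write_table(scores, os.path.join(out, "enrichment_scores.tsv"),
                           sort_by=["gene", "cluster"])
        frac = ase_mod.per_cluster_maternal_fraction(
            hyb, labels, asegs, min_reads=cfg.min_reads
        )
        frac.insert(0, "cluster", frac.index)
        io_mod.write_table(frac, os.path.join(out, "per_cluster_fraction.tsv"))


def _stage_heterosis(cfg: PipelineConfig) -> None:
    matrices = _load_filtered(cfg)
    genes = _common_genes(matrices)
    matrices = {s: m.subset(genes=m.gene_index(genes))
                for s, m in matrices.items()}
    labels = _labels_for(matrices, _load_labels(cfg))
    deg, patterns, summary = het_mod.trio_heterosis_analysis(
        matrices, labels=labels, fc_threshold=cfg.fc_threshold,
        alpha=cfg.deg_alpha, k=cfg.k,
    )
    out = _sample_dir(cfg.out_dir, "heterosis")
    io_mod.write_table(deg, os.path.join(out, "deg.tsv"),
                       sort_by=["comparison", "cluster", "q_value", "gene"])
    io_mod.write_table(patterns, os.path.join(out, "patterns.tsv"),
                       sort_by=["cluster", "gene"])
    if len(summary):
        io_mod.write_table(summary, os.path.join(out, "pattern_fractions.tsv"),
                           sort_by=["cluster"])


def _stage_enrich(cfg: PipelineConfig) -> None:
    gmt = cfg.gmt
    if gmt is None and cfg.mode == "synthetic":
        gmt = os.path.join(cfg.out_dir, "simulate", "gene_sets.gmt")
    if gmt is None or not os.path.exists(gmt):
        logger.warning("no GMT annotation available; enrichment skipped")
        return
    deg = pd.read_csv(os.path.join(cfg.out_dir, "heterosis", "deg.tsv"), sep="\t")
    query = sorted(set(deg.loc[deg["significant"], "gene"]))
    collection = enrich_mod.read_gene_sets(gmt)
    query = [g for g in query if g in collection.universe]
    out = _sample_dir(cfg.out_dir, "enrich")
    if not query:
        logger.warning("no significant DEG overlaps the annotation universe")
        io_mod.write_table(pd.DataFrame(columns=["term_id"]),
                           os.path.join(out, "enrichment.tsv"))
        return
    res = enrich_mod.enrich(query, collection, fdr_threshold=cfg.fdr)
    io_mod.write_table(res, os.path.join(out, "enrichment.tsv"))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "markers": _stage_markers,
    "ase": _stage_ase,
    "heterosis": _stage_heterosis,
    "enrich": _stage_enrich,
}


def run_pipeline(cfg: PipelineConfig,
                 stages: Optional[List[str]] = None) -> dict:
    """Execute the requested stages in order and write the run manifest.

    ``stages=None`` runs everything (skipping ``simulate`` in real mode).
    A stage failure aborts the run, leaves earlier outputs in place and
    drops a FAILED marker naming the stage and cause.
    """
    cfg.validate()
    if stages is None:
        stages = [s for s in STAGES if not (s == "simulate" and cfg.mode == "real")]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = {
        "package": "endoase",
        "version": _package_version(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    if cfg.mode == "real":
        manifest["input_hashes"] = {
            s: {k: _file_hash(v) for k, v in spec.items()}
            for s, spec in cfg.inputs.items()
        }
    failed_marker = os.path.join(cfg.out_dir, "FAILED")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)
    for stage in stages:
        t0 = time.time()
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as e:
            with open(failed_marker, "w") as fh:
                fh.write(f"stage {stage} failed: {e}\n")
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest["stages"][stage] = {"wall_time_s": round(time.time() - t0, 3)}
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("endoase")
    except Exception:
        return "unknown"
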