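"""Ground-truth simulator for a parents + hybrid single-nucleus trio.

Emulates the statistical structure the downstream analyses assume:

* three samples — maternal parent, paternal parent, F1 hybrid — sharing one
  set of nucleus clusters (negative-binomial counts over cluster-specific
  expression programs);
* allele-informative read subsampling in the hybrid (only a fraction ``rho``
  of reads overlaps parental SNPs and is assignable);
* a 2:1 maternal:paternal dosage baseline for unbiased genes in triploid
  endosperm, with planted maternally / paternally biased genes (MEGs/PEGs)
  of known allelic fraction;
* planted parent/hybrid fold-change genes covering the five hybrid
  expression-pattern classes (BLP/BMP/MPV/OMP/OHP) and the three heterosis
  modes (additive/dominant/overdominant).

Counts are negative binomial with variance mu + dispersion * mu**2
(gamma–Poisson mixture), the standard overdispersion model for droplet UMI
data.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import AlleleCountMatrix, metadata_table

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TrioData",
    "simulate_trio",
    "simulate_null_allelic",
    "fixture_qc_matrix",
    "ground_truth_gene_sets",
    "write_simulated_dataset",
    "PATTERN_TARGETS",
    "MODE_TARGETS",
]

SAMPLES = ("maternal_parent", "paternal_parent", "hybrid")

# Hybrid expression level of planted pattern genes, as a multiple of the
# lower parent's level, for fold factor k = 3 and parent fold 4 (lower
# parent at 1x, higher at 4x).  Targets sit at the geometric midpoint of
# each class region, except OHP which is open above (placed at 2 * 3*HP):
#   BLP (0, LP/3), BMP [LP/3, LP), MPV [LP, HP], OMP (HP, 3HP), OHP [3HP, inf)
PATTERN_TARGETS = {
    "BLP": 1.0 / 6.0,
    "BMP": (1.0 / 3.0) ** 0.5,  # sqrt(1/3 * 1) ~ 0.577
    "MPV": 2.0,                  # sqrt(1 * 4)
    "OMP": (4.0 * 12.0) ** 0.5,  # sqrt(HP * 3HP) ~ 6.93
    "OHP": 24.0,                 # 2 * 3HP
}

# Hybrid level of planted heterosis-mode genes (same parent folds):
# additive at the arithmetic mid-parent, dominant at the higher parent,
# overdominant well above the higher parent.
MODE_TARGETS = {"additive": 2.5, "dominant": 4.0, "overdominant": 24.0}

PATTERN_CLASSES = tuple(PATTERN_TARGETS)
MODE_CLASSES = tuple(MODE_TARGETS)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_trio`.

    The defaults describe a desk-scale trio: 1,000 nuclei per sample over
    10,000 genes in 5 clusters, overdispersed UMI counts, 20% of reads
    allele-assignable, 200 planted MEGs (maternal fraction 0.95) and 200
    PEGs (0.20) against the 2/3 endosperm dosage baseline, and 100 planted
    genes per expression-pattern class and per heterosis mode.
    """

    n_nuclei_per_sample: int = 1000
    n_genes: int = 10000
    n_clusters: int = 5
    frac_program_genes: float = 0.10
    program_log2fc: float = 2.0
    library_size_lognormal: Tuple[float, float] = (9.2, 0.35)
    nb_dispersion: float = 0.3
    snp_coverage_rho: float = 0.2
    n_meg: int = 200
    n_peg: int = 200
    meg_maternal_fraction: float = 0.95
    peg_maternal_fraction: float = 0.20
    baseline_maternal_fraction: float = 2.0 / 3.0
    n_pattern_genes_per_class: int = 100
    n_mode_genes_per_class: int = 100
    parent_fold: float = 4.0
    pattern_k: float = 3.0
    baseline_gamma_shape: float = 0.45
    special_abundance_band: Tuple[float, float] = (0.50, 0.90)
    program_abundance_floor: float = 0.30
    parent_allele_layers: bool = False
    seed: int = 0

    def validate(self) -> None:
        errs = []
        for name in ("n_nuclei_per_sample", "n_genes", "n_clusters"):
            if getattr(self, name) < 1:
                errs.append(f"{name} must be positive")
        for name in ("frac_program_genes", "snp_coverage_rho",
                     "meg_maternal_fraction", "peg_maternal_fraction",
                     "baseline_maternal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion < 0:
            errs.append("nb_dispersion must be >= 0")
        n_special = (self.n_meg + self.n_peg
                     + len(PATTERN_CLASSES) * self.n_pattern_genes_per_class
                     + len(MODE_CLASSES) * self.n_mode_genes_per_class)
        n_program = int(round(self.frac_program_genes * self.n_genes))
        lo, hi = self.special_abundance_band
        band = int((hi - lo) * self.n_genes)
        if n_special + n_program > self.n_genes:
            errs.append(
                f"{n_special} biased/pattern genes + {n_program} program genes "
                f"exceed n_genes={self.n_genes}"
            )
        if n_special > band:
            errs.append(
                f"{n_special} biased/pattern genes exceed the "
                f"{band}-gene abundance band they are drawn from"
            )
        if errs:
            raise ConfigError("; ".join(errs))


@dataclass
class GroundTruth:
    """Planted truth used as the oracle for recovery testing."""

    cluster_of_nucleus: Dict[str, int]
    ase_class_of_gene: Dict[str, str]            # MEG / PEG / unbiased
    planted_maternal_fraction: Dict[str, float]
    pattern_class_of_gene: Dict[str, str]        # BLP..OHP / none
    heterosis_mode_of_gene: Dict[str, str]       # additive/dominant/overdominant/none
    program_cluster_of_gene: Dict[str, int] = field(default_factory=dict)
    high_parent_of_gene: Dict[str, str] = field(default_factory=dict)

    def gene_table(self) -> pd.DataFrame:
        genes = sorted(self.ase_class_of_gene)
        return pd.DataFrame(
            {
                "gene": genes,
                "ase_class": [self.ase_class_of_gene[g] for g in genes],
                "maternal_fraction": [self.planted_maternal_fraction[g] for g in genes],
                "pattern_class": [self.pattern_class_of_gene[g] for g in genes],
                "heterosis_mode": [self.heterosis_mode_of_gene[g] for g in genes],
                "program_cluster": [self.program_cluster_of_gene.get(g, -1) for g in genes],
            }
        )

    def nucleus_table(self) -> pd.DataFrame:
        bcs = sorted(self.cluster_of_nucleus)
        return pd.DataFrame(
            {"barcode": bcs,
             "cluster": [self.cluster_of_nucleus[b] for b in bcs]}
        )


@dataclass
class TrioData:
    matrices: Dict[str, AlleleCountMatrix]
    metadata: Dict[str, pd.DataFrame]
    truth: GroundTruth
    config: SimConfig
    noiseless_means: Optional[pd.DataFrame] = None


def _gene_roles(cfg: SimConfig, rng: np.random.Generator):
    """Draw baseline abundances and assign planted roles to genes.

    Biased and pattern genes are drawn from a mid-to-high abundance band
    (default 50th–90th percentile): imprinting and hybrid fold-change calls
    are only observable for adequately expressed genes, and strongly induced
    genes are rarely the extreme top of the abundance distribution.
    Pattern/mode genes are further scaled so no class dominates library
    composition (documented constants; pattern classes are scale-invariant).
    """
    abundance = rng.gamma(cfg.baseline_gamma_shape, 1.0, size=cfg.n_genes)
    abundance = np.maximum(abundance, 1e-8)
    order = np.argsort(abundance)
    lo, hi = cfg.special_abundance_band
    band = order[int(lo * cfg.n_genes):int(hi * cfg.n_genes)]
    band = rng.permutation(band)

    roles: Dict[str, np.ndarray] = {}
    pos = 0

    def take(n: int) -> np.ndarray:
        nonlocal pos
        sel = band[pos:pos + n]
        pos += n
        return np.sort(sel)

    roles["meg"] = take(cfg.n_meg)
    roles["peg"] = take(cfg.n_peg)
    for cls in PATTERN_CLASSES:
        roles[f"pattern:{cls}"] = take(cfg.n_pattern_genes_per_class)
    for cls in MODE_CLASSES:
        roles[f"mode:{cls}"] = take(cfg.n_mode_genes_per_class)

    # cluster programs come from the remaining measurably expressed genes:
    # marker programs of real nucleus types are expressed genes, so the
    # planted ones sit above the program_abundance_floor quantile
    n_program = int(round(cfg.frac_program_genes * cfg.n_genes))
    used = np.concatenate([v for v in roles.values()]) if roles else np.array([], int)
    floor = order[int(cfg.program_abundance_floor * cfg.n_genes):]
    free = np.setdiff1d(floor, used)
    if free.size < n_program:
        raise ConfigError(
            f"{n_program} program genes exceed the {free.size} genes available "
            "above the program abundance floor"
        )
    program = rng.choice(free, size=n_program, replace=False)
    per_cluster = np.array_split(np.sort(program), cfg.n_clusters)
    roles["program"] = {c: idx for c, idx in enumerate(per_cluster)}
    return abundance, roles


def _sample_weights(cfg: SimConfig, abundance: np.ndarray, roles) -> Dict[str, np.ndarray]:
    """Per-sample gene weight vectors before cluster-program factors.

    Which parent is the higher-expressing one is randomised per planted
    gene elsewhere; here ``high_parent`` marks genes where the *paternal*
    parent carries the fold-up.
    """
    w = {s: abundance.copy() for s in SAMPLES}
    targets = {f"pattern:{c}": t for c, t in PATTERN_TARGETS.items()}
    targets.update({f"mode:{c}": t for c, t in MODE_TARGETS.items()})
    for key, t in targets.items():
        idx = roles[key]
        # per-class abundance rescale keeps any one class from dominating
        # the library; harmless because pattern classes are scale-invariant
        kappa = 6.0 / (1.0 + cfg.parent_fold + t)
        for s in SAMPLES:
            w[s][idx] = abundance[idx] * kappa
        w["hybrid"][idx] *= t
        w["paternal_parent"][idx] *= cfg.parent_fold  # flipped later per gene
    return w


def simulate_trio(config: SimConfig = SimConfig()) -> TrioData:
    """Simulate the parents + hybrid trio with full ground truth.

    Per nucleus, a library size L ~ LogNormal is drawn; gene g in cluster c
    of sample s has mean mu = L * pi_g(c, s) with pi a normalised expression
    program, and count ~ NB(mu, dispersion).  Hybrid allele layers arise by
    binomial thinning: s_g ~ Binom(count, rho) allele-informative reads,
    maternal ~ Binom(s_g, f_g) with f_g the planted maternal fraction.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    abundance, roles = _gene_roles(cfg, rng)
    weights = _sample_weights(cfg, abundance, roles)

    # randomise which parent is the high one for each planted fold gene
    gene_names = np.array([f"gene_{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    high_parent: Dict[str, str] = {}
    for key in list(roles):
        if not (key.startswith("pattern:") or key.startswith("mode:")):
            continue
        for gi in roles[key]:
            if rng.random() < 0.5:  # flip: maternal parent is the high one
                a = weights["maternal_parent"][gi]
                weights["maternal_parent"][gi] = weights["paternal_parent"][gi]
                weights["paternal_parent"][gi] = a
                high_parent[gene_names[gi]] = "maternal_parent"
            else:
                high_parent[gene_names[gi]] = "paternal_parent"

    # planted maternal fractions (hybrid allele layers)
    f_gene = np.full(cfg.n_genes, cfg.baseline_maternal_fraction)
    f_gene[roles["meg"]] = cfg.meg_maternal_fraction
    f_gene[roles["peg"]] = cfg.peg_maternal_fraction

    program_factor = 2.0 ** cfg.program_log2fc

    matrices: Dict[str, AlleleCountMatrix] = {}
    metadata: Dict[str, pd.DataFrame] = {}
    cluster_of_nucleus: Dict[str, int] = {}
    noiseless_rows = []

    mean_log, sd_log = cfg.library_size_lognormal
    prefix = {"maternal_parent": "MAT", "paternal_parent": "PAT", "hybrid": "HYB"}

    for s in SAMPLES:
        n = cfg.n_nuclei_per_sample
        barcodes = np.array([f"{prefix[s]}_{i:05d}" for i in range(n)], dtype=object)
        clusters = rng.integers(0, cfg.n_clusters, size=n)
        libsizes = rng.lognormal(mean_log, sd_log, size=n)

        counts = np.zeros((n, cfg.n_genes), dtype=np.int64)
        for c in range(cfg.n_clusters):
            w = weights[s].copy()
            w[roles["program"][c]] *= program_factor
            pi = w / w.sum()
            members = np.flatnonzero(clusters == c)
            if members.size == 0:
                continue
            mu = libsizes[members, None] * pi[None, :]
            if cfg.nb_dispersion > 0:
                shape = 1.0 / cfg.nb_dispersion
                lam = rng.gamma(shape, cfg.nb_dispersion * mu)
            else:
                lam = mu
            counts[members] = rng.poisson(lam)
            noiseless_rows.append(
                pd.DataFrame({"sample": s, "cluster": c,
                              "gene": gene_names, "mean_cpm": pi * 1e6})
            )

        maternal = paternal = None
        if s == "hybrid":
            informative = rng.binomial(counts, cfg.snp_coverage_rho)
            m = rng.binomial(informative, f_gene[None, :])
            p = informative - m
            maternal = sp.csr_matrix(m)
            paternal = sp.csr_matrix(p)
        elif cfg.parent_allele_layers:
            informative = rng.binomial(counts, cfg.snp_coverage_rho)
            if s == "maternal_parent":
                maternal = sp.csr_matrix(informative)
                paternal = sp.csr_matrix(counts.shape, dtype=np.int64)
            else:
                maternal = sp.csr_matrix(counts.shape, dtype=np.int64)
                paternal = sp.csr_matrix(informative)

        acm = AlleleCountMatrix(
            counts=sp.csr_matrix(counts), gene_ids=gene_names.copy(),
            barcodes=barcodes, maternal=maternal, paternal=paternal,
        )
        matrices[s] = acm
        cl_map = dict(zip(barcodes, map(int, clusters)))
        cluster_of_nucleus.update(cl_map)
        metadata[s] = metadata_table(acm, s, clusters=cl_map)

    ase_class = {g: "unbiased" for g in gene_names}
    for gi in roles["meg"]:
        ase_class[gene_names[gi]] = "MEG"
    for gi in roles["peg"]:
        ase_class[gene_names[gi]] = "PEG"
    pattern_class = {g: "none" for g in gene_names}
    mode = {g: "none" for g in gene_names}
    for cls in PATTERN_CLASSES:
        for gi in roles[f"pattern:{cls}"]:
            pattern_class[gene_names[gi]] = cls
    for cls in MODE_CLASSES:
        for gi in roles[f"mode:{cls}"]:
            mode[gene_names[gi]] = cls
    program_cluster = {}
    for c, idx in roles["program"].items():
        for gi in idx:
            program_cluster[gene_names[gi]] = c

    truth = GroundTruth(
        cluster_of_nucleus=cluster_of_nucleus,
        ase_class_of_gene=ase_class,
        planted_maternal_fraction=dict(zip(gene_names, f_gene)),
        pattern_class_of_gene=pattern_class,
        heterosis_mode_of_gene=mode,
        program_cluster_of_gene=program_cluster,
        high_parent_of_gene=high_parent,
    )
    noiseless = pd.concat(noiseless_rows, ignore_index=True)
    return TrioData(matrices=matrices, metadata=metadata, truth=truth,
                    config=cfg, noiseless_means=noiseless)


def simulate_null_allelic(n_genes: int, reads_per_gene: int, f0: float,
                          seed: int = 0) -> pd.DataFrame:
    """Null allelic-count table: maternal ~ Binom(reads_per_gene, f0) i.i.d.

    Calibration harness for the dosage test: every gene truly sits at the
    expected maternal fraction ``f0``.
    """
    if reads_per_gene < 1:
        raise ValueError("reads_per_gene must be >= 1")
    if not 0.0 < f0 <= 1.0:  # f0 = 1 allowed as the all-maternal degenerate case
        raise ValueError("f0 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = rng.binomial(reads_per_gene, f0, size=n_genes)
    return pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n_genes)],
            "m_reads": m,
            "p_reads": reads_per_gene - m,
            "n_informative_nuclei": reads_per_gene,  # one read per nucleus
        }
    )


def fixture_qc_matrix() -> AlleleCountMatrix:
    """Deterministic hand-built matrix exercising the QC filters exactly.

    12 nuclei x 3,408 genes of 0/1 counts.  Two nuclei detect 2,999 and 100
    genes (below the 3,000-gene cell filter); the ten survivors detect
    3,006–3,404 genes.  The first eight genes are tracked: among the ten
    surviving nuclei they are detected in (10, 6, 5, 4, 1, 0, 10, 10)
    nuclei, so the 5-cell gene filter removes exactly genes 3, 4 and 5; all
    filler genes are detected in at least 5 survivors.  Filtering at the
    default thresholds therefore removes exactly 2 nuclei and 3 genes.
    """
    n_tracked = 8
    # filler quota per nucleus: filler gene j is detected iff j < quota
    quotas = [3400, 3400, 3400, 3400, 3400, 3100, 3100, 3100, 3000, 3000,
              2999, 100]
    # tracked-gene detection per surviving nucleus (s0..s9)
    tracked_rows = {
        0: [0, 6, 7], 1: [0, 6, 7], 2: [0, 6, 7], 3: [0, 6, 7],
        4: [0, 1, 6, 7], 5: [0, 1, 2, 6, 7],
        6: [0, 1, 2, 3, 6, 7], 7: [0, 1, 2, 3, 6, 7], 8: [0, 1, 2, 3, 6, 7],
        9: [0, 1, 2, 3, 4, 6, 7],
        10: [], 11: [],
    }
    n_filler = max(quotas)
    n_genes = n_tracked + n_filler
    rows, cols = [], []
    for i, q in enumerate(quotas):
        for g in tracked_rows[i]:
            rows.append(i)
            cols.append(g)
        rows.extend([i] * q)
        cols.extend(range(n_tracked, n_tracked + q))
    data = np.ones(len(rows), dtype=np.int64)
    counts = sp.csr_matrix((data, (rows, cols)), shape=(len(quotas), n_genes))
    genes = np.array([f"g{j:04d}" for j in range(n_genes)], dtype=object)
    barcodes = np.array([f"nuc_{i:02d}" for i in range(len(quotas))], dtype=object)
    return AlleleCountMatrix(counts=counts, gene_ids=genes, barcodes=barcodes)


def ground_truth_gene_sets(truth: GroundTruth, n_random: int = 20,
                           genes_per_random: int = 50,
                           seed: int = 0) -> dict:
    """Build a GMT-style term -> (description, members) mapping from the
    planted gene roles, plus random terms, for enrichment testing."""
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(truth.ase_class_of_gene), dtype=object)
    sets = {}
    for c in sorted(set(truth.program_cluster_of_gene.values())):
        members = sorted(g for g, cc in truth.program_cluster_of_gene.items() if cc == c)
        sets[f"PROGRAM_CLUSTER_{c}"] = (f"cluster {c} expression program", members)
    for cls in PATTERN_CLASSES:
        members = sorted(g for g, p in truth.pattern_class_of_gene.items() if p == cls)
        if members:
            sets[f"PATTERN_{cls}"] = (f"planted {cls} fold-change genes", members)
    for cls in ("MEG", "PEG"):
        members = sorted(g for g, a in truth.ase_class_of_gene.items() if a == cls)
        if members:
            sets[f"ASE_{cls}"] = (f"planted {cls}s", members)
    for i in range(n_random):
        members = sorted(rng.choice(genes, size=genes_per_random, replace=False))
        sets[f"RANDOM_{i:02d}"] = ("random background term", list(members))
    return sets


def write_simulated_dataset(trio: TrioData, out_dir: str) -> None:
    """Write the trio in the on-disk layout the readers consume, plus
    ground-truth TSVs and a gene-set GMT file."""
    from .io import write_count_matrix, write_table
    from .enrich import write_gene_sets

    os.makedirs(out_dir, exist_ok=True)
    for s, acm in trio.matrices.items():
        sample_dir = os.path.join(out_dir, s)
        write_count_matrix(acm, sample_dir)
        write_table(trio.metadata[s], os.path.join(sample_dir, "metadata.tsv"),
                    sort_by=["barcode"])
    write_table(trio.truth.gene_table(),
                os.path.join(out_dir, "truth_genes.tsv"), sort_by=["gene"])
    write_table(trio.truth.nucleus_table(),
                os.path.join(out_dir, "truth_nuclei.tsv"), sort_by=["barcode"])
    sets = ground_truth_gene_sets(trio.truth, seed=trio.config.seed)
    write_gene_sets(sets, os.path.join(out_dir, "gene_sets.gmt"))
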