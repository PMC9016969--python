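"""Synthetic multi-cohort generator with planted expression-methylation structure.

The generator emulates the statistical structure the screen assumes in bulk
tumour cohorts:

* per-sample TF expression on a log-normal scale, optionally confounded by a
  tumour-purity component with a signed loading;
* "planted" emTFs whose expression drives methylation at CpGs placed within
  the proximity window of their own binding sites, through a logistic link
  ``beta = logistic(a_j - slope * z + eps)`` that keeps betas in (0, 1)
  (demethylating direction: higher expression, lower methylation);
* constitutively hypomethylated "protected" CpGs near the sites of designated
  protector TFs, drawn i.i.d. from a Beta law;
* null CpGs placed both near and far from binding sites, with a mixture of
  variable and near-constant beta baselines so the IQR filter has work to do;
* target genes whose (log) expression decreases in the methylation of their
  linked emCpG, plus pure-noise decoy genes;
* ATAC-like accessibility counts over peaks at emCpGs, anti-coupled to beta.

Every TF occupies its own block of 2 kb site slots on one synthetic
chromosome, which keeps different TFs' proximity windows disjoint and makes
ground-truth recovery well defined.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CohortBundle,
    CpGManifest,
    GeneAnnotation,
    GenomicInterval,
    RegulatoryMap,
    SampleMatrix,
    TFBSCollection,
    write_bed,
)

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedGenome",
    "SimulatedCohort",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_cohort",
    "simulate_study",
    "write_fixture",
    "standard_config",
    "null_config",
    "small_config",
    "scaled_min_sig",
]

SLOT_LEN = 2000  # one binding locus per slot; windows never cross slots
# CpG universe of a 450K-style screen restricted to TFBS-proximal probes; the
# min_sig=5000 default was calibrated at this scale and is rescaled
# proportionally for synthetic universes.
REFERENCE_UNIVERSE = 376_997


def scaled_min_sig(n_cpgs: int, real_scale_min_sig: int = 5000) -> int:
    """Rescale the >= 5000-significant-CpGs gate to a smaller CpG universe."""
    return max(20, round(real_scale_min_sig * n_cpgs / REFERENCE_UNIVERSE))


@dataclass(frozen=True)
class PlantedEffect:
    tf: str
    slope: float  # effect on the logit scale per SD of log-expression; >= 0
    direction: str = "demethylating"  # or "methylating"

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("effect slope must be >= 0")
        if self.direction not in ("demethylating", "methylating"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class SimulationConfig:
    n_cohorts: int = 2
    n_samples: int = 150
    n_tfs: int = 40
    n_cpgs: int = 30_000
    sites_per_tf: int = 100
    window: int = 200
    planted_emtfs: list[PlantedEffect] = field(default_factory=list)
    n_emcpgs_per_tf: int = 750
    homotypic_cluster_factor: int = 3
    homotypic_fraction: float = 0.3
    protector_tfs: list[str] = field(default_factory=list)
    n_protected_cpgs: int = 1000
    protected_cpg_beta_params: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.5
    purity_loadings: dict[str, float] = field(default_factory=dict)
    n_linked_per_tf: int = 60
    n_noise_genes: int = 150
    gene_effect: float = 0.8
    gene_noise_sd: float = 1.0
    atac_slope: float = 1.0
    atac_noise_sd: float = 0.3
    n_atac_samples: int = 60
    n_atac_peaks: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cohorts", "n_samples", "n_tfs", "n_cpgs", "sites_per_tf",
            "homotypic_cluster_factor", "n_emcpgs_per_tf",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.homotypic_cluster_factor < 1:
            raise ValueError("homotypic_cluster_factor must be >= 1")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples per cohort")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @property
    def planted_names(self) -> list[str]:
        return [p.tf for p in self.planted_emtfs]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_emtfs"] = [dataclasses.asdict(p) for p in self.planted_emtfs]
        d["protected_cpg_beta_params"] = list(self.protected_cpg_beta_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["planted_emtfs"] = [PlantedEffect(**p) for p in d.get("planted_emtfs", [])]
        d["protected_cpg_beta_params"] = tuple(d.get("protected_cpg_beta_params", (2.0, 8.0)))
        return cls(**d)


def standard_config(seed: int = 0, effect_slope: float = 0.3) -> SimulationConfig:
    """The standard recovery conditions: 2 cohorts x 150 samples, 40 TFs,
    30,000 CpGs, 5 planted demethylating emTFs.

    ``effect_slope=0.3`` with ``noise_sd=0.5`` targets a median planted
    |Spearman rho| of about 0.5 at n=150 (for bivariate-normal latents,
    rho_S = (6/pi) asin(r/2) with r = slope / sqrt(slope^2 + noise_sd^2)).
    """
    planted = [PlantedEffect(f"TF{i + 1:02d}", effect_slope) for i in range(5)]
    return SimulationConfig(
        planted_emtfs=planted,
        protector_tfs=["TF38", "TF39", "TF40"],
        purity_loadings={"TF01": 0.8, "TF02": 0.8, "TF03": -0.8, "TF04": -0.8},
        seed=seed,
    )


def null_config(seed: int = 0) -> SimulationConfig:
    """The standard conditions with every effect slope set to zero."""
    cfg = standard_config(seed=seed)
    cfg.planted_emtfs = [dataclasses.replace(p, slope=0.0) for p in cfg.planted_emtfs]
    cfg.gene_effect = 0.0
    cfg.atac_slope = 0.0
    return cfg


def small_config(seed: int = 0, effect_slope: float = 0.45) -> SimulationConfig:
    """A fast, reduced-scale variant for unit tests and CLI round trips."""
    return SimulationConfig(
        n_cohorts=2,
        n_samples=60,
        n_tfs=8,
        n_cpgs=1500,
        sites_per_tf=20,
        planted_emtfs=[PlantedEffect("TF01", effect_slope), PlantedEffect("TF02", effect_slope)],
        n_emcpgs_per_tf=80,
        protector_tfs=["TF07", "TF08"],
        n_protected_cpgs=120,
        purity_loadings={"TF01": 0.8, "TF03": -0.8},
        n_linked_per_tf=25,
        n_noise_genes=40,
        n_atac_samples=30,
        n_atac_peaks=60,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Planted structure for recovery testing."""

    planted_emtfs: list[str]
    emcpgs: dict[str, list[str]]  # tf -> probe ids
    emcpg_sign: dict[str, int]  # probe -> -1 (demethylating) / +1 (methylating)
    protected_cpgs: list[str]
    protector_tfs: list[str]
    true_links: list[tuple[str, str]]  # (probe, gene)
    target_genes: list[str]
    purity: dict[str, pd.Series]  # cohort -> per-sample purity
    purity_loadings: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple[str, str, str]] = []
        for tf, probes in sorted(self.emcpgs.items()):
            for p in probes:
                rows.append(("emcpg", p, tf))
        for p in self.protected_cpgs:
            rows.append(("protected", p, ";".join(self.protector_tfs)))
        for probe, gene in self.true_links:
            rows.append(("link", probe, gene))
        return pd.DataFrame(rows, columns=["kind", "item", "partner"])


# ---------------------------------------------------------------------------
# Genome


@dataclass
class SimulatedGenome:
    manifest: CpGManifest
    tfbs: TFBSCollection
    annotation: GeneAnnotation
    regmap: RegulatoryMap
    chrom: str
    chrom_length: int
    cpg_roles: pd.DataFrame  # probe_id index: role, tf
    truth_links: list[tuple[str, str]]
    target_genes: list[str]
    noise_genes: list[str]


def _place_near_site(rng: np.random.Generator, site: GenomicInterval, window: int) -> int:
    """Uniform position with gap-distance <= window from the site."""
    return int(rng.integers(site.start - window, site.end + window))


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Lay out TFBSs, CpGs, genes and regulatory elements on one synthetic chromosome."""
    rng = np.random.default_rng([config.seed, 101])
    chrom = "chrS"
    planted = set(config.planted_names)
    unknown = planted - set(config.tf_names)
    if unknown:
        raise ValueError(f"planted TFs not in TF panel: {sorted(unknown)}")
    n_gene_slots = len(config.planted_emtfs) * config.n_linked_per_tf + config.n_noise_genes
    n_slots = config.n_tfs * config.sites_per_tf + n_gene_slots
    chrom_length = (n_slots + 1) * SLOT_LEN
    if config.n_cpgs > 3 * n_slots * SLOT_LEN // SLOT_LEN * 4:
        # the used position space must comfortably exceed the CpG count
        raise ValueError("chromosome too short for the requested CpG density")

    slot_order = rng.permutation(n_slots)
    site_slots = slot_order[: config.n_tfs * config.sites_per_tf]
    gene_slots = slot_order[config.n_tfs * config.sites_per_tf :]

    # --- binding sites -----------------------------------------------------
    sites: dict[str, list[GenomicInterval]] = {tf: [] for tf in config.tf_names}
    for i, tf in enumerate(config.tf_names):
        for k in range(config.sites_per_tf):
            slot = int(site_slots[i * config.sites_per_tf + k])
            base = slot * SLOT_LEN
            start = base + 900 + int(rng.integers(0, 200))
            length = int(rng.integers(10, 21))
            sites[tf].append(GenomicInterval(chrom, start, start + length, name=tf))
            if tf in planted and rng.random() < config.homotypic_fraction:
                prev_end = start + length
                for _ in range(config.homotypic_cluster_factor - 1):
                    gap = int(rng.integers(5, 31))
                    length2 = int(rng.integers(10, 21))
                    sites[tf].append(
                        GenomicInterval(chrom, prev_end + gap, prev_end + gap + length2, name=tf)
                    )
                    prev_end = prev_end + gap + length2
    tfbs = TFBSCollection(sites)

    # --- CpGs --------------------------------------------------------------
    used: set[int] = set()

    def unique_pos(draw) -> int:
        while True:
            pos = draw()
            if pos not in used and pos >= 0:
                used.add(pos)
                return pos

    probes: list[tuple[str, int, str, str]] = []  # (probe, pos, role, tf)
    counter = 0

    def add_probe(pos: int, role: str, tf: str) -> str:
        nonlocal counter
        counter += 1
        pid = f"cg{counter:06d}"
        probes.append((pid, pos, role, tf))
        return pid

    truth_emcpgs: dict[str, list[str]] = {}
    for eff in config.planted_emtfs:
        own = sites[eff.tf]
        ids = []
        for _ in range(config.n_emcpgs_per_tf):
            site = own[int(rng.integers(len(own)))]
            pos = unique_pos(lambda: _place_near_site(rng, site, config.window))
            ids.append(add_probe(pos, "emcpg", eff.tf))
        truth_emcpgs[eff.tf] = ids

    protected_ids: list[str] = []
    if config.protector_tfs:
        for _ in range(config.n_protected_cpgs):
            ptf = config.protector_tfs[int(rng.integers(len(config.protector_tfs)))]
            site = sites[ptf][int(rng.integers(len(sites[ptf])))]
            pos = unique_pos(lambda: _place_near_site(rng, site, config.window))
            protected_ids.append(add_probe(pos, "protected", ptf))

    n_planted_cpgs = len(config.planted_emtfs) * config.n_emcpgs_per_tf
    n_null = config.n_cpgs - n_planted_cpgs - len(protected_ids)
    if n_null < 0:
        raise ValueError("n_cpgs smaller than planted + protected CpG count")
    n_near = n_null // 2
    all_tfs = config.tf_names
    for j in range(n_null):
        if j < n_near:
            tf = all_tfs[int(rng.integers(len(all_tfs)))]
            site = sites[tf][int(rng.integers(len(sites[tf])))]
            pos = unique_pos(lambda: _place_near_site(rng, site, config.window))
            add_probe(pos, "null_near", tf)
        else:
            slot = int(rng.integers(n_slots))
            pos = unique_pos(lambda: slot * SLOT_LEN + int(rng.integers(0, 400)))
            add_probe(pos, "null_far", "")

    roles = pd.DataFrame(
        [(p, r, t) for p, _, r, t in probes], columns=["probe_id", "role", "tf"]
    ).set_index("probe_id")
    manifest = CpGManifest(
        pd.DataFrame(
            {"chrom": chrom, "pos": [pos for _, pos, _, _ in probes]},
            index=pd.Index([p for p, _, _, _ in probes], name="probe_id"),
        )
    )

    # --- genes and regulatory elements -------------------------------------
    n_targets = len(config.planted_emtfs) * config.n_linked_per_tf
    gene_rows = []
    exons: dict[str, list[GenomicInterval]] = {}
    for g in range(n_gene_slots):
        slot = int(gene_slots[g])
        base = slot * SLOT_LEN
        start, end = base + 500, base + 1500
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"GENE{g + 1:04d}"
        gene_rows.append((gid, chrom, start, end, strand))
        exons[gid] = [
            GenomicInterval(chrom, start, start + 200, name=gid),
            GenomicInterval(chrom, end - 200, end, name=gid),
        ]
    gene_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    annotation = GeneAnnotation(gene_df, exons)
    target_genes = gene_df.index[:n_targets].tolist()
    noise_genes = gene_df.index[n_targets:].tolist()

    truth_links: list[tuple[str, str]] = []
    reg_records: list[tuple[GenomicInterval, str]] = []
    gi = 0
    for eff in config.planted_emtfs:
        ids = truth_emcpgs[eff.tf]
        chosen = rng.choice(len(ids), size=min(config.n_linked_per_tf, len(ids)), replace=False)
        for idx in sorted(int(c) for c in chosen):
            probe = ids[idx]
            gene = target_genes[gi]
            gi += 1
            pos = int(manifest.df.loc[probe, "pos"])
            reg_records.append(
                (GenomicInterval(chrom, max(0, pos - 50), pos + 51), gene)
            )
            truth_links.append((probe, gene))
    regmap = RegulatoryMap(reg_records)

    return SimulatedGenome(
        manifest=manifest,
        tfbs=tfbs,
        annotation=annotation,
        regmap=regmap,
        chrom=chrom,
        chrom_length=chrom_length,
        cpg_roles=roles,
        truth_links=truth_links,
        target_genes=target_genes,
        noise_genes=noise_genes,
    )


def genome_sequence(genome: SimulatedGenome, seed: int, gc_background: float = 0.4) -> str:
    """Random nucleotide sequence for the synthetic chromosome (for %GC tests)."""
    rng = np.random.default_rng([seed, 909])
    p = np.array([(1 - gc_background) / 2, gc_background / 2, gc_background / 2, (1 - gc_background) / 2])
    bases = rng.choice(np.array(list("ACGT")), size=genome.chrom_length, p=p)
    return "".join(bases)


# ---------------------------------------------------------------------------
# Cohort


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulatedCohort:
    bundle: CohortBundle
    purity: pd.Series  # per-sample tumour purity
    atac_peaks: list[GenomicInterval]
    atac_counts: SampleMatrix  # peak x ATAC-sample normalised counts


def simulate_cohort(
    config: SimulationConfig, genome: SimulatedGenome, cohort_index: int = 0
) -> SimulatedCohort:
    """Draw one cohort's expression, methylation, purity and ATAC matrices."""
    if config.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng([config.seed, 211, cohort_index])
    name = f"COH{cohort_index + 1}"
    samples = [f"{name}-{i + 1:03d}" for i in range(config.n_samples)]
    n = config.n_samples

    purity = pd.Series(rng.uniform(0.2, 0.95, size=n), index=samples, name="purity")
    purity_z = (purity.to_numpy() - purity.mean()) / purity.std(ddof=0)

    # TF log-expression: standard-normal latent plus optional purity loading
    tf_log = rng.normal(0.0, 1.0, size=(config.n_tfs, n))
    for i, tf in enumerate(config.tf_names):
        loading = config.purity_loadings.get(tf, 0.0)
        if loading:
            tf_log[i] += loading * purity_z
    tf_z = (tf_log - tf_log.mean(axis=1, keepdims=True)) / tf_log.std(axis=1, keepdims=True)

    roles = genome.cpg_roles
    probe_ids = roles.index.to_numpy()
    beta = np.empty((len(probe_ids), n))
    tf_index = {tf: i for i, tf in enumerate(config.tf_names)}
    planted_by_tf = {p.tf: p for p in config.planted_emtfs}

    role_arr = roles["role"].to_numpy()
    tf_arr = roles["tf"].to_numpy()

    # planted emCpGs: logistic link to the owning TF's standardised expression
    for kind in ("emcpg",):
        idx = np.flatnonzero(role_arr == kind)
        for j in idx:
            eff = planted_by_tf[tf_arr[j]]
            z = tf_z[tf_index[eff.tf]]
            a_j = rng.uniform(-1.0, 1.0)
            sign = -1.0 if eff.direction == "demethylating" else 1.0
            eps = rng.normal(0.0, config.noise_sd, size=n)
            beta[j] = _logistic(a_j + sign * eff.slope * z + eps)

    # protected CpGs: i.i.d. Beta(a, b) — low mean, IQR just above the filter
    a_b, b_b = config.protected_cpg_beta_params
    idx = np.flatnonzero(role_arr == "protected")
    if len(idx):
        beta[idx] = rng.beta(a_b, b_b, size=(len(idx), n))

    # null CpGs: mixture of variable (kept by IQR filter) and flat (dropped)
    idx = np.flatnonzero(np.isin(role_arr, ["null_near", "null_far"]))
    if len(idx):
        variable = rng.random(len(idx)) < 0.5
        nv = int(variable.sum())
        beta[idx[variable]] = rng.beta(2.0, 2.0, size=(nv, n))
        flat_centre = rng.uniform(0.05, 0.95, size=(len(idx) - nv, 1))
        flat = flat_centre + rng.normal(0.0, 0.02, size=(len(idx) - nv, n))
        beta[idx[~variable]] = np.clip(flat, 0.0, 1.0)

    methylation = SampleMatrix(
        pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        kind="methylation",
    )

    # target-gene log-expression: anti-coupled to the linked emCpG's beta
    gene_log: dict[str, np.ndarray] = {}
    probe_row = {p: i for i, p in enumerate(probe_ids)}
    for probe, gene in genome.truth_links:
        b = beta[probe_row[probe]]
        bz = (b - b.mean()) / b.std()
        gene_log[gene] = (
            1.0 - config.gene_effect * bz + rng.normal(0.0, config.gene_noise_sd, size=n)
        )
    for gene in genome.noise_genes:
        gene_log[gene] = rng.normal(1.0, 1.0, size=n)

    expr_rows = list(config.tf_names) + list(gene_log)
    expr_vals = np.vstack([np.exp(tf_log)] + [np.exp(gene_log[g])[None, :] for g in gene_log])
    expression = SampleMatrix(
        pd.DataFrame(expr_vals, index=pd.Index(expr_rows, name="id"), columns=samples),
        kind="expression",
    )
    bundle = CohortBundle(name=name, expression=expression, methylation=methylation)

    # ATAC: one peak over each of n_atac_peaks emCpGs; counts anti-coupled to beta
    em_idx = np.flatnonzero(role_arr == "emcpg")
    n_peaks = min(config.n_atac_peaks, len(em_idx))
    atac_samples = samples[: min(config.n_atac_samples, n)]
    peaks: list[GenomicInterval] = []
    counts = np.empty((n_peaks, len(atac_samples)))
    if n_peaks:
        peak_rows = rng.choice(em_idx, size=n_peaks, replace=False)
        pos_lookup = genome.manifest.df["pos"]
        for k, j in enumerate(sorted(int(r) for r in peak_rows)):
            pos = int(pos_lookup.iloc[j])
            peaks.append(
                GenomicInterval(genome.chrom, max(0, pos - 150), pos + 151, name=f"peak{k + 1:05d}")
            )
            b = beta[j, : len(atac_samples)]
            bz = (b - b.mean()) / b.std()
            counts[k] = np.exp(
                1.0 - config.atac_slope * bz
                + rng.normal(0.0, config.atac_noise_sd, size=len(atac_samples))
            )
    atac_counts = SampleMatrix(
        pd.DataFrame(
            counts,
            index=pd.Index([p.name for p in peaks], name="peak_id"),
            columns=atac_samples,
        ),
        kind="expression",
    )
    return SimulatedCohort(bundle=bundle, purity=purity, atac_peaks=peaks, atac_counts=atac_counts)


# ---------------------------------------------------------------------------
# Study


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: SimulatedGenome
    cohorts: list[SimulatedCohort]
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    genome = simulate_genome(config)
    cohorts = [simulate_cohort(config, genome, i) for i in range(config.n_cohorts)]
    roles = genome.cpg_roles
    emcpgs = {
        tf: roles.index[(roles["role"] == "emcpg") & (roles["tf"] == tf)].tolist()
        for tf in config.planted_names
    }
    sign = {
        p: (-1 if eff.direction == "demethylating" else 1)
        for eff in config.planted_emtfs
        for p in emcpgs[eff.tf]
    }
    truth = GroundTruth(
        planted_emtfs=[p.tf for p in config.planted_emtfs if p.slope > 0],
        emcpgs=emcpgs,
        emcpg_sign=sign,
        protected_cpgs=roles.index[roles["role"] == "protected"].tolist(),
        protector_tfs=list(config.protector_tfs),
        true_links=list(genome.truth_links),
        target_genes=list(genome.target_genes),
        purity={c.bundle.name: c.purity for c in cohorts},
        purity_loadings=dict(config.purity_loadings),
    )
    return SimulatedStudy(config=config, genome=genome, cohorts=cohorts, truth=truth)


# ---------------------------------------------------------------------------
# Fixture writer


def write_fixture(study: SimulatedStudy, outdir: str | Path, force: bool = False) -> dict[str, str]:
    """Write the study as the pipeline's on-disk input formats.

    Returns a {relative path: sha256} manifest of everything written.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    genome = study.genome
    genome.manifest.to_tsv(outdir / "manifest.tsv", one_based=True)
    write_bed(sorted(genome.tfbs.all_intervals()), outdir / "tfbs.bed")
    genome.annotation.to_tsv(outdir / "genes.tsv")
    exon_ivs = [iv for g in genome.annotation.gene_ids for iv in genome.annotation.exons.get(g, [])]
    write_bed(sorted(exon_ivs), outdir / "exons.bed")
    genome.regmap.to_bed(outdir / "regmap.bed")
    study.truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(study.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    for cohort in study.cohorts:
        name = cohort.bundle.name
        cohort.bundle.expression.to_tsv(outdir / f"{name}_expression.tsv")
        cohort.bundle.methylation.to_tsv(outdir / f"{name}_methylation.tsv")
        cohort.purity.to_frame().to_csv(outdir / f"{name}_purity.tsv", sep="\t", index_label="sample")
        write_bed(cohort.atac_peaks, outdir / f"{name}_atac_peaks.bed")
        cohort.atac_counts.to_tsv(outdir / f"{name}_atac_counts.tsv")

    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file():
            checksums[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return checksums
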