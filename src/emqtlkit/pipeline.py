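"""End-to-end orchestration: configuration, staged execution, run manifest.

Stages (filter/proximity/screen -> call -> signatures -> link -> context ->
report) communicate exclusively through TSV files under a single run
directory, so running ``run_pipeline`` is byte-identical to running the
stages one at a time. Every output carries the config hash and seed in a
header comment, and ``run_manifest.json`` records a checksum per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine, signatures as sigmod
from .context import atac_methylation_correlation, purity_classification
from .core_io import (
    CohortBundle,
    CpGManifest,
    GeneAnnotation,
    RegulatoryMap,
    SampleMatrix,
    align_cohort,
    read_bed,
    read_manifest,
    read_matrix,
    read_tfbs_bed,
)
from .linking import anticorrelation_filter, link_cpgs, over_representation, read_gmt
from .synthetic import SimulationConfig, simulate_study, write_fixture

logger = logging.getLogger(__name__)

__all__ = ["Thresholds", "PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class Thresholds:
    """Analysis thresholds with their real-data-scale defaults."""

    alpha: float = 0.01  # Bonferroni level of the Spearman screen
    window: int = 200  # CpG-to-TFBS proximity window, bp
    iqr: float = 0.1  # beta IQR filter (strictly greater)
    min_sig: int = 5000  # minimum significant CpGs per TF-cohort pair
    percentile: float = 95.0  # pooled proximal-fraction percentile gate
    min_cohorts: int = 2  # recurrence requirement for emTF calls
    flank: int = 200  # region half-width around CpGs, bp
    link_alpha: float = 0.01  # Bonferroni level of the anti-correlation filter
    ora_alpha: float = 0.05  # BH level of over-representation reporting
    purity_p: float = 0.05  # purity-classification p threshold
    atac_min_samples: int = 20  # matched-sample gate for ATAC coupling
    family: str = "grid"  # Bonferroni family: grid | per_tf
    max_missing: float = 0.2  # per-CpG missing-beta tolerance


@dataclass
class CohortPaths:
    name: str
    expression: str
    methylation: str
    purity: str | None = None
    atac_peaks: str | None = None
    atac_counts: str | None = None


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    synthetic: SimulationConfig | None = None
    manifest: str | None = None
    tfbs: str | None = None
    genes: str | None = None
    exons: str | None = None
    regmap: str | None = None
    gene_sets: str | None = None
    cohorts: list[CohortPaths] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "manifest": self.manifest,
            "tfbs": self.tfbs,
            "genes": self.genes,
            "exons": self.exons,
            "regmap": self.regmap,
            "gene_sets": self.gene_sets,
            "cohorts": [dataclasses.asdict(c) for c in self.cohorts],
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SimulationConfig.from_dict(d["synthetic"])
        d["cohorts"] = [CohortPaths(**c) for c in d.get("cohorts", [])]
        d["thresholds"] = Thresholds(**d.get("thresholds", {}))
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # the hash identifies the analysis, not its location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def for_synthetic(cls, simconfig: SimulationConfig, outdir: str) -> "PipelineConfig":
        """A pipeline config for a synthetic study, with the min_sig and
        percentile gates rescaled to the simulated design."""
        from .experiments import scaled_percentile
        from .synthetic import scaled_min_sig

        thr = Thresholds(
            min_sig=scaled_min_sig(simconfig.n_cpgs),
            percentile=scaled_percentile(simconfig),
        )
        return cls(outdir=outdir, seed=simconfig.seed, synthetic=simconfig, thresholds=thr)


# ---------------------------------------------------------------------------
# I/O helpers


def _header(cfg: PipelineConfig) -> str:
    return f"# emqtlkit config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", float_format="%.6g", index=index)


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


class StageError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _fixture_dir(cfg: PipelineConfig) -> Path:
    return Path(cfg.outdir) / "fixture"


def _input_paths(cfg: PipelineConfig) -> dict:
    """Resolve input file paths: explicit paths, or the synthetic fixture."""
    if cfg.synthetic is not None:
        fx = _fixture_dir(cfg)
        cohorts = [
            CohortPaths(
                name=f"COH{i + 1}",
                expression=str(fx / f"COH{i + 1}_expression.tsv"),
                methylation=str(fx / f"COH{i + 1}_methylation.tsv"),
                purity=str(fx / f"COH{i + 1}_purity.tsv"),
                atac_peaks=str(fx / f"COH{i + 1}_atac_peaks.bed"),
                atac_counts=str(fx / f"COH{i + 1}_atac_counts.tsv"),
            )
            for i in range(cfg.synthetic.n_cohorts)
        ]
        return {
            "manifest": fx / "manifest.tsv",
            "tfbs": fx / "tfbs.bed",
            "genes": fx / "genes.tsv",
            "exons": fx / "exons.bed",
            "regmap": fx / "regmap.bed",
            "cohorts": cohorts,
        }
    return {
        "manifest": Path(cfg.manifest) if cfg.manifest else None,
        "tfbs": Path(cfg.tfbs) if cfg.tfbs else None,
        "genes": Path(cfg.genes) if cfg.genes else None,
        "exons": Path(cfg.exons) if cfg.exons else None,
        "regmap": Path(cfg.regmap) if cfg.regmap else None,
        "cohorts": cfg.cohorts,
    }


def _require(path: Path | None, what: str, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise StageError(f"stage {stage!r}: missing {what}: {path}")
    return Path(path)


def _load_cohort(paths: CohortPaths, stage: str) -> CohortBundle:
    expr = read_matrix(_require(Path(paths.expression), "expression matrix", stage), kind="expression")
    meth = read_matrix(_require(Path(paths.methylation), "methylation matrix", stage), kind="methylation")
    return align_cohort(paths.name, expr, meth)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig, force: bool = False) -> None:
    if cfg.synthetic is None:
        logger.info("no synthetic block in config; simulate stage skipped")
        return
    study = simulate_study(cfg.synthetic)
    write_fixture(study, _fixture_dir(cfg), force=force)


def stage_screen(cfg: PipelineConfig) -> None:
    ins = _input_paths(cfg)
    manifest = read_manifest(_require(ins["manifest"], "CpG manifest", "screen"))
    tfbs = read_tfbs_bed(_require(ins["tfbs"], "TFBS BED", "screen"))
    thr = cfg.thresholds
    outdir = Path(cfg.outdir) / "screen"
    for paths in ins["cohorts"]:
        bundle = _load_cohort(paths, "screen")
        tf_list = [tf for tf in tfbs.tf_names if tf in bundle.expression.data.index]
        screen = engine.screen_cohort(
            bundle, manifest, tfbs,
            tf_list=tf_list,
            window=thr.window, iqr_threshold=thr.iqr, alpha=thr.alpha,
            family=thr.family, max_missing=thr.max_missing,
        )
        _write_tsv(screen.stats.reset_index(), outdir / f"{paths.name}.tf_stats.tsv", cfg)
        _write_tsv(screen.table.to_frame(significant_only=True),
                   outdir / f"{paths.name}.emqtl.tsv", cfg)
        universe = pd.DataFrame({"probe_id": screen.table.cpgs})
        _write_tsv(universe, outdir / f"{paths.name}.universe.tsv", cfg)


def _read_screen_outputs(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, list[str]]]:
    outdir = Path(cfg.outdir) / "screen"
    stats_frames, emqtl, universes = [], {}, {}
    for path in sorted(outdir.glob("*.tf_stats.tsv")):
        cohort = path.name.split(".")[0]
        df = _read_tsv(path)
        df["cohort"] = cohort
        stats_frames.append(df)
        emqtl[cohort] = _read_tsv(outdir / f"{cohort}.emqtl.tsv")
        universes[cohort] = _read_tsv(outdir / f"{cohort}.universe.tsv")["probe_id"].tolist()
    if not stats_frames:
        raise StageError("stage 'call': no screen outputs found; run the screen stage first")
    pairs = pd.concat(stats_frames, ignore_index=True).set_index(["cohort", "tf"]).sort_index()
    return pairs, emqtl, universes


def stage_call(cfg: PipelineConfig) -> None:
    thr = cfg.thresholds
    pairs, emqtl, universes = _read_screen_outputs(cfg)
    ins = _input_paths(cfg)
    manifest = read_manifest(_require(ins["manifest"], "CpG manifest", "call"))
    tfbs = read_tfbs_bed(_require(ins["tfbs"], "TFBS BED", "call"))

    pooled = pairs["fraction"].dropna().to_numpy()
    cutoff = float(np.percentile(pooled, thr.percentile)) if len(pooled) else float("nan")
    n_tested = int(pairs["mwu_p"].notna().sum())
    pairs["mwu_p_bonf"] = np.minimum(pairs["mwu_p"] * max(n_tested, 1), 1.0)
    pairs["passed_min_sig"] = pairs["n_significant_total"] >= thr.min_sig
    pairs["passed_percentile"] = pairs["fraction"] >= cutoff
    pairs["passed_mwu"] = pairs["mwu_p_bonf"] < thr.alpha
    pairs["is_candidate"] = (
        pairs["passed_min_sig"] & pairs["passed_percentile"] & pairs["passed_mwu"]
    )
    cand = pairs[pairs["is_candidate"]].reset_index()
    counts = cand.groupby("tf")["cohort"].nunique()
    emtfs = sorted(counts[counts >= thr.min_cohorts].index)
    if len(emqtl) < thr.min_cohorts:
        logger.warning("fewer cohorts than min_cohorts=%d; empty emTF call", thr.min_cohorts)

    outdir = Path(cfg.outdir) / "call"
    _write_tsv(pairs.reset_index(), outdir / "pair_stats.tsv", cfg)
    _write_tsv(pd.DataFrame({"tf": emtfs}), outdir / "emtfs.tsv", cfg)

    sign_rows = []
    for tf in emtfs:
        for cohort, table in sorted(emqtl.items()):
            sub = table[table["tf"] == tf]
            if len(sub):
                probe_manifest = manifest.subset(sub["probe_id"].tolist())
                prox = engine.map_cpgs_to_tfbs(probe_manifest, tfbs, window=thr.window)[tf]
                sub = sub[prox]
            em = sub[["probe_id", "rho"]].copy().sort_values("probe_id")
            em["sign"] = np.where(em["rho"] < 0, -1, 1)
            _write_tsv(em, outdir / "emcpgs" / f"{tf}.{cohort}.tsv", cfg)
            n_prox = int(pairs.loc[(cohort, tf), "n_proximal"])
            if len(em):
                _, _, pneg, ppos = engine.partition_sign(em["rho"].to_numpy(), n_prox)
            else:
                pneg = ppos = 0.0
            sign_rows.append((tf, cohort, len(em), n_prox, 100 * pneg, 100 * ppos))
    sign_summary = pd.DataFrame(
        sign_rows, columns=["tf", "cohort", "n_emcpgs", "n_proximal", "pct_negative", "pct_positive"]
    )
    _write_tsv(sign_summary, outdir / "sign_summary.tsv", cfg)
    meta = {"fraction_cutoff": cutoff, "n_pairs_tested": n_tested}
    with open(outdir / "call_meta.json", "w") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def _read_call_outputs(cfg: PipelineConfig, stage: str) -> tuple[list[str], dict[tuple[str, str], pd.DataFrame]]:
    outdir = Path(cfg.outdir) / "call"
    path = _require(outdir / "emtfs.tsv", "emTF list (run the call stage first)", stage)
    df = _read_tsv(path)
    emtfs = df["tf"].tolist() if len(df) else []
    emcpgs = {}
    for p in sorted((outdir / "emcpgs").glob("*.tsv")) if (outdir / "emcpgs").exists() else []:
        tf, cohort = p.stem.split(".")
        emcpgs[(tf, cohort)] = _read_tsv(p)
    return emtfs, emcpgs


def stage_signatures(cfg: PipelineConfig) -> None:
    thr = cfg.thresholds
    emtfs, emcpgs = _read_call_outputs(cfg, "signatures")
    if not emtfs:
        logger.info("no emTFs called; signatures stage writes nothing")
        return
    ins = _input_paths(cfg)
    manifest = read_manifest(_require(ins["manifest"], "CpG manifest", "signatures"))
    tfbs = read_tfbs_bed(_require(ins["tfbs"], "TFBS BED", "signatures"))
    _, _, universes = _read_screen_outputs(cfg)
    outdir = Path(cfg.outdir) / "signatures"
    for (tf, cohort), em in sorted(emcpgs.items()):
        if not len(em):
            continue
        em_ids = em["probe_id"].tolist()
        noncorr = sorted(set(universes[cohort]) - set(em_ids))
        fg = sigmod.window_regions(em_ids, manifest, flank=thr.flank, name="emcpg")
        ot = sigmod.window_regions(noncorr, manifest, flank=thr.flank, name="noncorr")
        _write_tsv(sigmod.differential_tfbs_enrichment(fg, ot, tfbs),
                   outdir / f"{tf}.{cohort}.emcpg_enrichment.tsv", cfg)
        _write_tsv(sigmod.differential_tfbs_enrichment(ot, fg, tfbs),
                   outdir / f"{tf}.{cohort}.noncorr_enrichment.tsv", cfg)


def stage_link(cfg: PipelineConfig) -> None:
    thr = cfg.thresholds
    emtfs, emcpgs = _read_call_outputs(cfg, "link")
    if not emtfs:
        logger.info("no emTFs called; link stage writes nothing")
        return
    ins = _input_paths(cfg)
    manifest = read_manifest(_require(ins["manifest"], "CpG manifest", "link"))
    annotation = GeneAnnotation.from_tsv(
        _require(ins["genes"], "gene annotation", "link"),
        exon_bed=ins["exons"] if ins["exons"] and Path(ins["exons"]).exists() else None,
    )
    regmap = RegulatoryMap.from_bed(ins["regmap"]) if ins["regmap"] and Path(ins["regmap"]).exists() else None
    bundles = {p.name: _load_cohort(p, "link") for p in ins["cohorts"]}
    gene_sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else None
    outdir = Path(cfg.outdir) / "link"
    for (tf, cohort), em in sorted(emcpgs.items()):
        if not len(em):
            continue
        links = link_cpgs(em["probe_id"].tolist(), manifest, regmap, annotation)
        links = anticorrelation_filter(links, bundles[cohort], alpha=thr.link_alpha)
        _write_tsv(links, outdir / f"{tf}.{cohort}.links.tsv", cfg)
        if gene_sets:
            genes = sorted(set(links.loc[links["retained"], "gene_id"]))
            universe = bundles[cohort].expression.row_ids
            ora = over_representation(genes, gene_sets, universe, alpha=thr.ora_alpha)
            _write_tsv(ora, outdir / f"{tf}.{cohort}.ora.tsv", cfg)


def stage_context(cfg: PipelineConfig) -> None:
    thr = cfg.thresholds
    emtfs, emcpgs = _read_call_outputs(cfg, "context")
    ins = _input_paths(cfg)
    manifest = read_manifest(_require(ins["manifest"], "CpG manifest", "context"))
    outdir = Path(cfg.outdir) / "context"
    purity_frames = []
    atac_frames = []
    for paths in ins["cohorts"]:
        bundle = _load_cohort(paths, "context")
        if paths.purity and Path(paths.purity).exists() and emtfs:
            purity = pd.read_csv(paths.purity, sep="\t", index_col=0)["purity"]
            calls = purity_classification(
                bundle.expression, purity,
                [tf for tf in emtfs if tf in bundle.expression.data.index],
                p_threshold=thr.purity_p,
            ).reset_index()
            calls.insert(0, "cohort", paths.name)
            purity_frames.append(calls)
        if paths.atac_peaks and Path(paths.atac_peaks).exists():
            peaks = read_bed(paths.atac_peaks)
            counts = read_matrix(Path(paths.atac_counts), kind=None)
            em_here = sorted(
                {p for (tf, cohort), df in emcpgs.items() if cohort == paths.name for p in df["probe_id"]}
            )
            if em_here:
                table, median_rho = atac_methylation_correlation(
                    em_here, manifest, peaks, counts, bundle.methylation,
                    flank=thr.flank, min_samples=thr.atac_min_samples,
                )
                table.insert(0, "cohort", paths.name)
                atac_frames.append((table, median_rho))
    if purity_frames:
        _write_tsv(pd.concat(purity_frames, ignore_index=True), outdir / "purity_calls.tsv", cfg)
    if atac_frames:
        _write_tsv(pd.concat([t for t, _ in atac_frames], ignore_index=True),
                   outdir / "atac_correlations.tsv", cfg)


def stage_report(cfg: PipelineConfig) -> None:
    pairs, emqtl, universes = _read_screen_outputs(cfg)
    outdir = Path(cfg.outdir) / "report"
    fractions = pairs.reset_index().pivot(index="tf", columns="cohort", values="fraction")
    _write_tsv(fractions.reset_index(), outdir / "fractions.tsv", cfg)
    call_dir = Path(cfg.outdir) / "call"
    if (call_dir / "sign_summary.tsv").exists():
        sign = _read_tsv(call_dir / "sign_summary.tsv")
    else:
        sign = pd.DataFrame(columns=["tf", "cohort", "n_emcpgs", "n_proximal", "pct_negative", "pct_positive"])
    _write_tsv(sign, outdir / "sign_proportions.tsv", cfg)

    ins = _input_paths(cfg)
    genes_path = ins["genes"]
    if genes_path and Path(genes_path).exists():
        manifest = read_manifest(_require(ins["manifest"], "CpG manifest", "report"))
        annotation = GeneAnnotation.from_tsv(
            genes_path,
            exon_bed=ins["exons"] if ins["exons"] and Path(ins["exons"]).exists() else None,
        )
        frames = []
        for cohort, probes in sorted(universes.items()):
            _, dist = sigmod.annotate_genomic_context(probes, manifest, annotation)
            dist = dist.reset_index(names="category")
            dist.insert(0, "set", f"universe:{cohort}")
            frames.append(dist)
        _, emcpg_sets = _read_call_outputs(cfg, "report")
        for (tf, cohort), em in sorted(emcpg_sets.items()):
            if not len(em):
                continue
            _, dist = sigmod.annotate_genomic_context(em["probe_id"].tolist(), manifest, annotation)
            dist = dist.reset_index(names="category")
            dist.insert(0, "set", f"emcpg:{tf}:{cohort}")
            frames.append(dist)
        if frames:
            _write_tsv(pd.concat(frames, ignore_index=True), outdir / "genomic_context.tsv", cfg)


STAGES = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "call": stage_call,
    "signatures": stage_signatures,
    "link": stage_link,
    "context": stage_context,
    "report": stage_report,
}


def _write_manifest(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            files[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "files": files}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Execute every stage in order and write the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config_used.yaml")
    for name, fn in STAGES.items():
        logger.info("stage %s", name)
        try:
            if name == "simulate":
                fn(cfg, force=force)
            else:
                fn(cfg)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    _write_manifest(cfg)
    return outdir
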