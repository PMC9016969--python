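"""CpG-to-target-gene linking and over-representation analysis.

Each emCpG is assigned to candidate target genes either through a
regulatory-element map (CpG inside an element -> element's target genes) or,
as a fallback, to the gene with the nearest TSS. Links are then refined by
requiring a Bonferroni-significant negative Spearman correlation between CpG
methylation and target-gene expression in the cohort.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CohortBundle, CpGManifest, GeneAnnotation, RegulatoryMap
from .stats import bh_adjust, hypergeom_tail, spearman_pair

logger = logging.getLogger(__name__)

__all__ = ["link_cpgs", "anticorrelation_filter", "over_representation", "read_gmt"]


def link_cpgs(
    probes: Sequence[str],
    manifest: CpGManifest,
    regmap: RegulatoryMap | None,
    annotation: GeneAnnotation,
) -> pd.DataFrame:
    """Link CpGs to genes via regulatory elements, else nearest TSS.

    A CpG inside >= 1 element yields one link per target gene
    (source ``regulatory_map``); otherwise one link to the gene minimising
    ``|pos - tss|`` (source ``nearest_tss``; ties broken to the
    lexicographically smallest gene_id, all candidates logged).
    """
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    pos = manifest.positions(probes)
    genes = annotation.df
    rows: list[tuple[str, str, str]] = []
    for probe, row in pos.iterrows():
        chrom, q = row["chrom"], int(row["pos"])
        targets = regmap.genes_at(chrom, q) if regmap is not None else []
        if targets:
            for gene in targets:
                rows.append((probe, gene, "regulatory_map"))
            continue
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            sub = genes
        dist = (sub["tss"] - q).abs()
        best = dist.min()
        candidates = sorted(sub.index[dist == best])
        if len(candidates) > 1:
            logger.info("probe %s equidistant to TSSs of %s; keeping %s", probe, candidates, candidates[0])
        rows.append((probe, candidates[0], "nearest_tss"))
    links = pd.DataFrame(rows, columns=["probe_id", "gene_id", "source"])
    n = len(links)
    for src, cnt in links["source"].value_counts().items():
        logger.info("links via %s: %d/%d (%.1f%%)", src, cnt, n, 100 * cnt / n)
    return links


def anticorrelation_filter(
    links: pd.DataFrame,
    cohort: CohortBundle,
    alpha: float = 0.01,
    method: str = "spearman",
) -> pd.DataFrame:
    """Retain links with a significantly negative methylation-expression
    correlation.

    Retained iff rho < 0 and ``p_raw * n_links_tested < alpha`` (Bonferroni
    over the links tested in this call). Links whose gene is absent from the
    expression matrix are dropped with a log entry; links with < 3 complete
    sample pairs stay with undefined rho and are not retained.
    """
    expr = cohort.expression.data
    meth = cohort.methylation.data
    present = links["gene_id"].isin(expr.index) & links["probe_id"].isin(meth.index)
    dropped = links[~present]
    if len(dropped):
        logger.info("dropped %d links with genes/probes absent from the cohort", len(dropped))
    out = links[present].copy().reset_index(drop=True)
    rhos = np.empty(len(out))
    ps = np.empty(len(out))
    for i, rec in out.iterrows():
        x = meth.loc[rec["probe_id"]].to_numpy(dtype=float)
        y = expr.loc[rec["gene_id"]].to_numpy(dtype=float)
        if method == "spearman":
            rhos[i], ps[i] = spearman_pair(x, y)
        elif method == "pearson":
            from scipy.stats import pearsonr

            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
                rhos[i], ps[i] = np.nan, np.nan
            else:
                r = pearsonr(x[mask], y[mask])
                rhos[i], ps[i] = r.statistic, r.pvalue
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    out["rho"] = rhos
    out["p_raw"] = ps
    m = max(len(out), 1)
    with np.errstate(invalid="ignore"):
        out["retained"] = (out["rho"] < 0) & (out["p_raw"] * m < alpha)
    out["retained"] = out["retained"].fillna(False)
    return out


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def over_representation(
    genes: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    universe: Sequence[str],
    alpha: float = 0.05,
    top_k: int = 10,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set,
    BH-adjusted across sets; report sets with adjusted p < alpha, at most
    ``top_k`` ranked by adjusted p."""
    universe_set = set(universe)
    query = set(genes) & universe_set
    if not set(genes) <= universe_set:
        logger.info("%d query genes outside the universe ignored", len(set(genes) - universe_set))
    if not query:
        return pd.DataFrame(columns=["gene_set", "overlap", "set_size", "p", "p_adjusted"])
    rows = []
    for name, members in gene_sets.items():
        members = members & universe_set
        k = len(query & members)
        p = hypergeom_tail(k, population=len(universe_set), successes=len(members), draws=len(query))
        rows.append((name, k, len(members), p))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    df = df[df["p_adjusted"] < alpha].sort_values(["p_adjusted", "p"], kind="mergesort")
    return df.head(top_k).reset_index(drop=True)
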