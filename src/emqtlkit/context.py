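"""Tumour-cell vs microenvironment context of emTFs, and ATAC-methylation coupling.

A TF whose expression correlates positively with tumour purity most likely
acts within cancer cells; a negative correlation points to the tumour
microenvironment (immune/stromal infiltrate). Accessibility at emCpGs is
expected to anti-correlate with their methylation.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core_io import CpGManifest, GenomicInterval, IntervalIndex, SampleMatrix
from .stats import spearman_pair

logger = logging.getLogger(__name__)

__all__ = ["purity_classification", "atac_methylation_correlation"]


def purity_classification(
    expression: SampleMatrix,
    purity: pd.Series,
    tfs: Sequence[str],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classify TFs by the Pearson correlation of expression with tumour purity.

    class = ``cancer_cell`` (r > 0, p < threshold), ``microenvironment``
    (r < 0, p < threshold), else ``ambiguous``.
    """
    shared = [s for s in expression.sample_ids if s in purity.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples with both expression and purity")
    pur = purity.loc[shared].to_numpy(dtype=float)
    rows = []
    for tf in tfs:
        x = expression.data.loc[tf, shared].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(pur))
        if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(pur[mask]) == 0:
            rows.append((tf, np.nan, np.nan, "ambiguous"))
            continue
        res = pearsonr(x[mask], pur[mask])
        r, p = float(res.statistic), float(res.pvalue)
        if p < p_threshold and r > 0:
            cls = "cancer_cell"
        elif p < p_threshold and r < 0:
            cls = "microenvironment"
        else:
            cls = "ambiguous"
        rows.append((tf, r, p, cls))
    return pd.DataFrame(rows, columns=["tf", "pearson_r", "p", "class"]).set_index("tf")


def atac_methylation_correlation(
    emcpg_probes: Sequence[str],
    manifest: CpGManifest,
    peaks: Sequence[GenomicInterval],
    atac_counts: SampleMatrix,
    methylation: SampleMatrix,
    flank: int = 200,
    min_samples: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Spearman correlation between methylation and ATAC counts at peaks
    overlapping each emCpG's ±flank window.

    Every (CpG, overlapping peak) pair yields one rho. Returns the pair table
    and the median rho; cohorts with fewer than ``min_samples`` matched
    samples are skipped (empty result, logged).
    """
    shared = [s for s in atac_counts.sample_ids if s in methylation.sample_ids]
    empty = pd.DataFrame(columns=["probe_id", "peak_id", "rho", "p"])
    if len(shared) < min_samples:
        logger.info(
            "only %d matched ATAC/methylation samples (< %d); cohort skipped",
            len(shared), min_samples,
        )
        return empty, float("nan")

    named = [(p.name or f"peak{i}", p) for i, p in enumerate(peaks)]
    pos = manifest.positions(emcpg_probes)
    rows = []
    # peaks are few: per-chromosome linear candidate scan via sorted starts
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for pid, peak in named:
        by_chrom.setdefault(peak.chrom, []).append((pid, peak))
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t[1].start)
    for probe, rec in pos.iterrows():
        chrom, q = rec["chrom"], int(rec["pos"])
        for pid, peak in by_chrom.get(chrom, []):
            if peak.start < q + flank + 1 and peak.end > q - flank:
                if pid not in atac_counts.data.index:
                    continue
                rho, p = spearman_pair(
                    methylation.data.loc[probe, shared].to_numpy(dtype=float),
                    atac_counts.data.loc[pid, shared].to_numpy(dtype=float),
                )
                rows.append((probe, pid, rho, p))
    table = pd.DataFrame(rows, columns=["probe_id", "peak_id", "rho", "p"])
    if table.empty:
        logger.info("no ATAC peaks overlap the emCpG windows")
        return table, float("nan")
    return table, float(np.nanmedian(table["rho"]))
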