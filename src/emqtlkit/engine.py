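"""The emQTL screen and emTF selection cascade.

Per cohort: IQR-filter the beta matrix, restrict to CpGs within the proximity
window of any TF binding site, Spearman-correlate every TF against every
considered CpG, flag Bonferroni-significant pairs, and compute per-TF summary
statistics (significant-CpG count, proximal fraction, Mann-Whitney proximity
enrichment). Across cohorts: gate TF-cohort pairs on (1) a minimum number of
significant CpGs, (2) a pooled percentile cutoff on the proximal fraction and
(3) a Bonferroni-corrected MWU p-value, then call emTFs as TFs passing in at
least ``min_cohorts`` cohorts. emCpGs of an emTF in a cohort are its
significant TFBS-proximal CpGs, partitioned by correlation sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CohortBundle, CpGManifest, SampleMatrix, TFBSCollection
from .stats import mann_whitney_greater, spearman_matrix, spearman_pair

logger = logging.getLogger(__name__)

__all__ = [
    "EmqtlTable",
    "CohortScreen",
    "EmtfCallSet",
    "drop_high_missing",
    "iqr_filter",
    "map_cpgs_to_tfbs",
    "spearman_screen",
    "bonferroni_flag",
    "proximal_fraction",
    "mwu_proximity_enrichment",
    "screen_cohort",
    "select_candidates",
    "call_emtfs",
    "partition_sign",
]


# ---------------------------------------------------------------------------
# Filters and proximity


def drop_high_missing(methylation: SampleMatrix, max_missing: float = 0.2) -> SampleMatrix:
    """Drop CpGs missing in more than ``max_missing`` of samples."""
    vals = methylation.values
    frac = np.isnan(vals).mean(axis=1)
    keep = frac <= max_missing
    if not keep.all():
        logger.info("dropped %d CpGs with > %.0f%% missing betas", (~keep).sum(), 100 * max_missing)
    return SampleMatrix(methylation.data.loc[keep], kind=methylation.kind)


def iqr_filter(methylation: SampleMatrix, threshold: float = 0.1) -> SampleMatrix:
    """Retain CpGs whose beta interquartile range is strictly above ``threshold``.

    Quartiles use linear-interpolation (type-7) quantiles, NaN-aware.
    """
    vals = methylation.values
    q1, q3 = np.nanpercentile(vals, [25, 75], axis=1)
    keep = (q3 - q1) > threshold
    if keep.sum() == 0:
        logger.warning("IQR filter removed every CpG (threshold=%g)", threshold)
    return SampleMatrix(methylation.data.loc[keep], kind=methylation.kind)


def map_cpgs_to_tfbs(
    manifest: CpGManifest, tfbs: TFBSCollection, window: int = 200
) -> dict[str, np.ndarray]:
    """Proximity map: TF -> boolean mask over manifest probes.

    A CpG maps to a TF iff its gap distance to the nearest binding site is at
    most ``window`` bp (0 inside a site).
    """
    df = manifest.df
    out: dict[str, np.ndarray] = {}
    for tf in tfbs.tf_names:
        if tfbs.n_sites(tf) == 0:
            logger.info("TF %s has no binding sites; empty proximity set", tf)
            out[tf] = np.zeros(len(df), dtype=bool)
            continue
        index = tfbs.index(tf)
        mask = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            loc = df.index.get_indexer(sub.index)
            mask[loc] = index.overlaps_points(chrom, sub["pos"].to_numpy(), window=window)
        out[tf] = mask
    return out


# ---------------------------------------------------------------------------
# Screen table


@dataclass
class EmqtlTable:
    """Per (TF, CpG) Spearman rho, two-sided p and Bonferroni significance."""

    cohort: str
    tfs: list[str]
    cpgs: list[str]
    rho: np.ndarray  # (n_tfs, n_cpgs)
    p_raw: np.ndarray
    n_samples: int
    significant: np.ndarray | None = None
    alpha: float | None = None
    family_size: int | None = None

    def tf_row(self, tf: str) -> int:
        return self.tfs.index(tf)

    def to_frame(self, significant_only: bool = True) -> pd.DataFrame:
        if self.significant is None:
            raise ValueError("call bonferroni_flag first")
        ti, ci = np.nonzero(self.significant if significant_only else np.ones_like(self.rho, bool))
        return pd.DataFrame(
            {
                "tf": np.asarray(self.tfs, object)[ti],
                "probe_id": np.asarray(self.cpgs, object)[ci],
                "rho": self.rho[ti, ci],
                "p_raw": self.p_raw[ti, ci],
                "significant": self.significant[ti, ci],
            }
        )


def spearman_screen(
    cohort: CohortBundle, tf_list: list[str], cpg_list: list[str]
) -> EmqtlTable:
    """Spearman-correlate every TF's expression with every CpG's methylation.

    CpG rows with missing betas fall back to pairwise-complete correlations;
    complete rows go through the vectorised rank-Pearson path.
    """
    missing = [tf for tf in tf_list if tf not in cohort.expression.data.index]
    if missing:
        raise KeyError(f"TFs missing from expression matrix: {missing}")
    expr = cohort.expression.data.loc[tf_list].to_numpy(dtype=float)
    meth = cohort.methylation.data.loc[cpg_list].to_numpy(dtype=float)
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 paired samples")

    has_nan = np.isnan(meth).any(axis=1)
    rho = np.full((len(tf_list), len(cpg_list)), np.nan)
    p = np.full_like(rho, np.nan)
    if (~has_nan).any():
        r, pv = spearman_matrix(expr, meth[~has_nan])
        rho[:, ~has_nan] = r
        p[:, ~has_nan] = pv
    for j in np.flatnonzero(has_nan):
        for i in range(len(tf_list)):
            rho[i, j], p[i, j] = spearman_pair(expr[i], meth[j])
    return EmqtlTable(
        cohort=cohort.name, tfs=list(tf_list), cpgs=list(cpg_list), rho=rho, p_raw=p, n_samples=n
    )


def bonferroni_flag(
    table: EmqtlTable, alpha: float = 0.01, family_size: int | None = None
) -> EmqtlTable:
    """Flag pairs with ``p_raw < alpha / family_size``.

    ``family_size`` defaults to the full per-cohort TF x CpG grid. Undefined
    (NaN) correlations are never significant.
    """
    if family_size is None:
        family_size = len(table.tfs) * len(table.cpgs)
    if family_size <= 0:
        raise ValueError("family_size must be positive")
    with np.errstate(invalid="ignore"):
        sig = table.p_raw < (alpha / family_size)
    sig &= ~np.isnan(table.rho)
    table.significant = sig
    table.alpha = alpha
    table.family_size = family_size
    return table


# ---------------------------------------------------------------------------
# Per-TF statistics


def proximal_fraction(table: EmqtlTable, proximity: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-TF: proximal CpG counts and the fraction of them that are significant."""
    if table.significant is None:
        raise ValueError("call bonferroni_flag first")
    rows = []
    for tf in table.tfs:
        mask = proximity[tf]
        n_prox = int(mask.sum())
        i = table.tf_row(tf)
        n_sig_total = int(table.significant[i].sum())
        if n_prox == 0:
            logger.info("TF %s has no proximal CpGs in cohort %s; excluded", tf, table.cohort)
            rows.append((tf, 0, 0, np.nan, n_sig_total))
            continue
        n_prox_sig = int(table.significant[i, mask].sum())
        rows.append((tf, n_prox, n_prox_sig, n_prox_sig / n_prox, n_sig_total))
    return pd.DataFrame(
        rows,
        columns=["tf", "n_proximal", "n_proximal_significant", "fraction", "n_significant_total"],
    ).set_index("tf")


def mwu_proximity_enrichment(
    table: EmqtlTable, proximity: dict[str, np.ndarray], tf: str
) -> float:
    """One-sided MWU p that |rho| of the TF's proximal CpGs exceeds the rest
    of the considered universe."""
    i = table.tf_row(tf)
    mask = proximity[tf]
    absr = np.abs(table.rho[i])
    defined = ~np.isnan(absr)
    x = absr[mask & defined]
    y = absr[~mask & defined]
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    _, p = mann_whitney_greater(x, y)
    return p


@dataclass
class CohortScreen:
    """One cohort's screen: considered universe, emQTL table, proximity map
    and per-TF statistics."""

    cohort: str
    table: EmqtlTable
    proximity: dict[str, np.ndarray]  # over table.cpgs order
    stats: pd.DataFrame  # index tf: counts, fraction, n_significant_total, mwu_p
    n_considered: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_considered = len(self.table.cpgs)


def screen_cohort(
    bundle: CohortBundle,
    manifest: CpGManifest,
    tfbs: TFBSCollection,
    tf_list: list[str] | None = None,
    window: int = 200,
    iqr_threshold: float = 0.1,
    alpha: float = 0.01,
    family: str = "grid",
    max_missing: float = 0.2,
) -> CohortScreen:
    """Run the full per-cohort screen.

    The considered universe is the set of manifest CpGs present in the beta
    matrix, within ``window`` bp of at least one TF's binding sites, surviving
    the missingness and IQR filters.
    """
    if tf_list is None:
        tf_list = [tf for tf in tfbs.tf_names if tf in bundle.expression.data.index]
    meth = bundle.methylation
    present = [p for p in manifest.probe_ids if p in meth.data.index]
    meth = meth.subset_rows(present)
    meth = drop_high_missing(meth, max_missing)
    meth = iqr_filter(meth, iqr_threshold)

    sub_manifest = manifest.subset(meth.row_ids)
    proximity = map_cpgs_to_tfbs(sub_manifest, tfbs, window=window)
    any_prox = np.zeros(len(meth.row_ids), dtype=bool)
    for tf in tf_list:
        any_prox |= proximity[tf]
    considered = [p for p, keep in zip(meth.row_ids, any_prox) if keep]
    keep_idx = np.flatnonzero(any_prox)
    proximity = {tf: proximity[tf][keep_idx] for tf in tf_list}

    screen_bundle = CohortBundle(
        name=bundle.name,
        expression=bundle.expression,
        methylation=meth.subset_rows(considered),
    )
    table = spearman_screen(screen_bundle, tf_list, considered)
    if family == "grid":
        family_size = len(tf_list) * len(considered)
    elif family == "per_tf":
        family_size = len(considered)
    else:
        raise ValueError(f"unknown Bonferroni family {family!r}")
    table = bonferroni_flag(table, alpha=alpha, family_size=family_size)

    stats = proximal_fraction(table, proximity)
    stats["mwu_p"] = [mwu_proximity_enrichment(table, proximity, tf) for tf in stats.index]
    return CohortScreen(cohort=bundle.name, table=table, proximity=proximity, stats=stats)


# ---------------------------------------------------------------------------
# Candidate selection across cohorts


def select_candidates(
    screens: list[CohortScreen],
    percentile: float = 95.0,
    min_sig: int = 5000,
    mwu_alpha: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Gate every TF-cohort pair and return the pair table plus the pooled
    fraction cutoff.

    Gates, in order: (1) total significant CpGs >= ``min_sig``; (2) proximal
    fraction >= the ``percentile``-th type-7 quantile of the pooled fraction
    distribution over all TF-cohort pairs; (3) MWU p, Bonferroni-corrected
    across all tested pairs, < ``mwu_alpha``.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    frames = []
    for screen in screens:
        df = screen.stats.copy()
        df["cohort"] = screen.cohort
        frames.append(df.reset_index())
    pairs = pd.concat(frames, ignore_index=True).set_index(["cohort", "tf"]).sort_index()

    pooled = pairs["fraction"].dropna().to_numpy()
    cutoff = float(np.percentile(pooled, percentile)) if len(pooled) else float("nan")

    n_tested = int(pairs["mwu_p"].notna().sum())
    pairs["mwu_p_bonf"] = np.minimum(pairs["mwu_p"] * max(n_tested, 1), 1.0)
    pairs["passed_min_sig"] = pairs["n_significant_total"] >= min_sig
    pairs["passed_percentile"] = pairs["fraction"] >= cutoff
    pairs["passed_mwu"] = pairs["mwu_p_bonf"] < mwu_alpha
    pairs["is_candidate"] = (
        pairs["passed_min_sig"] & pairs["passed_percentile"] & pairs["passed_mwu"]
    )
    return pairs, cutoff


# ---------------------------------------------------------------------------
# emTF calling and sign partition


@dataclass
class EmtfCallSet:
    """Final emTF calls: pair-level gate table, emTF list, and per
    (emTF, cohort) emCpG sets with sign proportions."""

    pair_stats: pd.DataFrame  # index (cohort, tf)
    fraction_cutoff: float
    min_cohorts: int
    emtfs: list[str]
    emcpgs: dict[tuple[str, str], pd.DataFrame]  # (tf, cohort) -> probe/rho/sign
    sign_summary: pd.DataFrame  # per (tf, cohort): pct negative/positive of proximal

    def emcpg_ids(self, tf: str, cohort: str) -> list[str]:
        return self.emcpgs[(tf, cohort)]["probe_id"].tolist()


def partition_sign(emcpg_rho: np.ndarray, n_proximal: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Split emCpG correlations by sign; proportions are relative to all
    proximal CpGs of the TF (significant or not)."""
    if np.any(emcpg_rho == 0):
        # a zero correlation cannot clear any Bonferroni threshold
        raise AssertionError("rho == 0 among significant emCpGs")
    neg = emcpg_rho < 0
    n = max(n_proximal, 1)
    return neg, ~neg, float(neg.sum()) / n, float((~neg).sum()) / n


def call_emtfs(
    screens: list[CohortScreen],
    percentile: float = 95.0,
    min_sig: int = 5000,
    mwu_alpha: float = 0.01,
    min_cohorts: int = 2,
) -> EmtfCallSet:
    """Select candidates per cohort and call emTFs recurrent in >= min_cohorts."""
    pairs, cutoff = select_candidates(screens, percentile=percentile, min_sig=min_sig, mwu_alpha=mwu_alpha)
    if len(screens) < min_cohorts:
        logger.warning(
            "only %d cohort(s) screened but min_cohorts=%d; emTF set will be empty",
            len(screens), min_cohorts,
        )
    cand = pairs[pairs["is_candidate"]]
    counts = cand.reset_index().groupby("tf")["cohort"].nunique()
    emtfs = sorted(counts[counts >= min_cohorts].index)

    emcpgs: dict[tuple[str, str], pd.DataFrame] = {}
    sign_rows = []
    by_cohort = {s.cohort: s for s in screens}
    for tf in emtfs:
        for cohort, screen in by_cohort.items():
            i = screen.table.tf_row(tf)
            mask = screen.table.significant[i] & screen.proximity[tf]
            probes = np.asarray(screen.table.cpgs, object)[mask]
            rho = screen.table.rho[i, mask]
            order = np.argsort(probes)
            df = pd.DataFrame(
                {
                    "probe_id": probes[order],
                    "rho": rho[order],
                    "sign": np.where(rho[order] < 0, -1, 1),
                }
            )
            emcpgs[(tf, cohort)] = df
            n_prox = int(screen.proximity[tf].sum())
            if len(df):
                _, _, pneg, ppos = partition_sign(df["rho"].to_numpy(), n_prox)
            else:
                pneg = ppos = 0.0
            sign_rows.append((tf, cohort, len(df), n_prox, 100 * pneg, 100 * ppos))
    sign_summary = pd.DataFrame(
        sign_rows,
        columns=["tf", "cohort", "n_emcpgs", "n_proximal", "pct_negative", "pct_positive"],
    ).set_index(["tf", "cohort"])

    return EmtfCallSet(
        pair_stats=pairs,
        fraction_cutoff=cutoff,
        min_cohorts=min_cohorts,
        emtfs=emtfs,
        emcpgs=emcpgs,
        sign_summary=sign_summary,
    )
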