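"""Statistical comparison utilities for site efficacy and model benchmarks.

Includes the partial correlation used by the window grid searches, the
cumulative-distribution comparison of site-type efficacy, the
sliding-sensitivity-threshold benchmark of ranked target predictions, the
naive baselines, and the ceiling on explainable variance set by noise and
secondary effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .site_finder import SiteType

__all__ = [
    "partial_correlation",
    "site_efficacy_cdfs",
    "BenchmarkCurve",
    "sliding_threshold_curve",
    "baseline_curves",
    "threshold_significance",
    "explainable_variance_ceiling",
]


def partial_correlation(
    x: np.ndarray, y: np.ndarray, site_type_labels: list
) -> float:
    """Pearson correlation of *x* and *y* controlling for site type.

    Both variables are residualised on one-hot site-type indicators by
    least squares; with a single site type this reduces to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = pd.Categorical(site_type_labels)
    design = np.column_stack([
        np.ones(len(x)),
        pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float),
    ]) if len(labels.categories) > 1 else np.ones((len(x), 1))

    def residual(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = residual(x), residual(y)
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        return np.nan
    return float(np.sum(rx * ry) / denom)


def site_efficacy_cdfs(
    fold_changes_by_category: dict[str, np.ndarray],
    no_site: np.ndarray,
) -> pd.DataFrame:
    """Compare each site category's fold-change distribution with no-site.

    Returns per category the one-sided Kolmogorov-Smirnov statistic and P
    value against the no-site distribution, and the minimal fraction of
    sites conferring destabilisation — the maximal vertical displacement
    of the category's empirical CDF above the no-site CDF.
    """
    no_site = np.sort(np.asarray(no_site, dtype=float))
    records = []
    for category, values in fold_changes_by_category.items():
        values = np.sort(np.asarray(values, dtype=float))
        # one-sided K-S: site-containing CDF lies above (shifted negative)
        ks = stats.ks_2samp(values, no_site, alternative="greater")
        grid = np.concatenate([values, no_site])
        cdf_cat = np.searchsorted(values, grid, side="right") / len(values)
        cdf_ref = np.searchsorted(no_site, grid, side="right") / len(no_site)
        displacement = float(np.max(cdf_cat - cdf_ref))
        records.append(
            {
                "category": category,
                "n": len(values),
                "ks_statistic": float(ks.statistic),
                "p_value": float(ks.pvalue),
                "min_fraction_destabilized": max(displacement, 0.0),
            }
        )
    return pd.DataFrame.from_records(records).set_index("category")


@dataclass
class BenchmarkCurve:
    """Mean repression of top-ranked predictions over a sliding threshold."""

    algorithm: str
    thresholds: np.ndarray
    mean_of_means: np.ndarray
    n_mirnas_contributing: np.ndarray
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None


def sliding_threshold_curve(
    ranked_predictions: dict[str, list[str]],
    fold_changes: pd.DataFrame,
    max_threshold: int | None = None,
    n_resample: int = 1000,
    algorithm: str = "model",
    seed: int | np.random.Generator = 0,
) -> BenchmarkCurve:
    """Mean of per-miRNA mean fold changes of top-*t* predictions vs *t*.

    *ranked_predictions* maps each miRNA (a column of *fold_changes*) to
    its gene ids, best first, already filtered to quantified genes.  At
    threshold *t* the per-miRNA mean fold change of its top *t*
    predictions is computed, skipping miRNAs with fewer than *t*
    predictions, and the mean of the available means is the curve value.
    The background band is the 95% interval of the same statistic over
    random gene draws without replacement.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    per_mirna = {
        m: [g for g in genes if g in fold_changes.index]
        for m, genes in ranked_predictions.items()
        if m in fold_changes.columns
    }
    longest = max((len(g) for g in per_mirna.values()), default=0)
    if longest == 0:
        return BenchmarkCurve(
            algorithm, np.zeros(0, int), np.zeros(0), np.zeros(0, int)
        )
    t_max = min(max_threshold or longest, longest)
    thresholds = np.arange(1, t_max + 1)

    means = np.full(len(thresholds), np.nan)
    n_contrib = np.zeros(len(thresholds), dtype=int)
    for i, t in enumerate(thresholds):
        vals = [
            fold_changes.loc[genes[:t], m].mean()
            for m, genes in per_mirna.items()
            if len(genes) >= t
        ]
        if vals:
            means[i] = float(np.mean(vals))
            n_contrib[i] = len(vals)

    band_low = np.full(len(thresholds), np.nan)
    band_high = np.full(len(thresholds), np.nan)
    universe = {m: fold_changes[m].to_numpy() for m in per_mirna}
    for i, t in enumerate(thresholds):
        active = [m for m, genes in per_mirna.items() if len(genes) >= t]
        if not active:
            continue
        stat = np.empty(n_resample)
        for r in range(n_resample):
            draws = [
                universe[m][rng.choice(len(universe[m]), size=t, replace=False)].mean()
                for m in active
            ]
            stat[r] = np.mean(draws)
        band_low[i], band_high[i] = np.percentile(stat, [2.5, 97.5])
    return BenchmarkCurve(
        algorithm, thresholds, means, n_contrib, band_low, band_high
    )


def baseline_curves(
    fold_changes: pd.DataFrame,
    site_genes: dict[str, set[str]],
    conserved_genes: dict[str, set[str]] | None = None,
) -> dict[str, float]:
    """Horizontal baselines: mean-of-means over site-containing mRNAs.

    ``any_site`` averages, per miRNA, the fold changes of all quantified
    mRNAs with at least one cognate canonical 7-8-nt 3' UTR site, then
    averages across miRNAs; ``conserved_site`` restricts to genes whose
    sites pass the per-type branch-length cutoffs (1.0 / 1.6 / 1.6 for
    8mer / 7mer-m8 / 7mer-A1).  NaN when no gene qualifies.
    """
    def mean_of_means(gene_sets: dict[str, set[str]]) -> float:
        vals = []
        for m, genes in gene_sets.items():
            if m not in fold_changes.columns:
                continue
            idx = [g for g in genes if g in fold_changes.index]
            if idx:
                vals.append(fold_changes.loc[idx, m].mean())
        return float(np.mean(vals)) if vals else float("nan")

    out = {"any_site": mean_of_means(site_genes)}
    if conserved_genes is not None:
        out["conserved_site"] = mean_of_means(conserved_genes)
    return out


#: Branch-length cutoffs at which a site counts as conserved (the cutoff
#: giving a ~2:1 signal:background ratio for each type).
CONSERVED_BLS_CUTOFFS = {
    SiteType.EIGHTMER: 1.0,
    SiteType.SEVENMER_M8: 1.6,
    SiteType.SEVENMER_A1: 1.6,
}


def threshold_significance(
    fold_changes_a: dict[int, np.ndarray],
    fold_changes_b: dict[int, np.ndarray],
) -> pd.Series:
    """One-sided Wilcoxon rank-sum P per threshold (a more repressed).

    Exact for small groups, normal approximation with continuity
    correction otherwise; thresholds with fewer than two points per side
    give NaN.
    """
    out = {}
    for t in sorted(set(fold_changes_a) & set(fold_changes_b)):
        a = np.asarray(fold_changes_a[t], dtype=float)
        b = np.asarray(fold_changes_b[t], dtype=float)
        if len(a) < 2 or len(b) < 2:
            out[t] = np.nan
            continue
        method = "exact" if max(len(a), len(b)) < 50 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="less", method=method)
        out[t] = float(res.pvalue)
    return pd.Series(out, name="p_value")


def explainable_variance_ceiling(
    fold_changes: pd.DataFrame,
    predicted_targets: dict[str, list[str]],
) -> float:
    """Upper bound on the fold-change variance any direct-targeting model
    can explain.

    The fold-change variance of miRNA A's predicted targets measured in
    *non-cognate* transfections reflects only noise and secondary effects;
    its ratio to the variance in the cognate transfection bounds the
    unexplainable share.  The ceiling is one minus that ratio, clamped to
    [0, 1].
    """
    cognate, non_cognate = [], []
    for m, genes in predicted_targets.items():
        idx = [g for g in genes if g in fold_changes.index]
        if not idx or m not in fold_changes.columns:
            continue
        cognate.append(float(fold_changes.loc[idx, m].var()))
        others = [c for c in fold_changes.columns if c != m]
        non_cognate.extend(
            float(fold_changes.loc[idx, c].var()) for c in others
        )
    if not cognate or not non_cognate:
        raise ValueError("no usable predicted-target sets")
    ratio = float(np.mean(non_cognate) / np.mean(cognate))
    return float(np.clip(1.0 - ratio, 0.0, 1.0))
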