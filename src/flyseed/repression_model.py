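"""Fold-change normalisation and the capped linear context model.

The pipeline from raw transfection fold changes to ranked predictions:

1. **Shared-variation removal** — partial least-squares regression (PLSR)
   learns, on genes without a cognate site, the variation each experiment
   shares with the others (batch effects, de-repression of endogenous
   miRNA targets) and subtracts it from every gene.
2. **Covariate residualisation** — a multiple linear regression of fold
   changes on seven gene-level covariates (region lengths, region AU
   contents, log expression), fitted on no-site genes only, is subtracted
   from all genes.
3. **Quartile rescaling** — each experiment's fold-change distribution is
   affinely mapped so that its quartiles match the pooled quartiles,
   removing between-experiment differences in global repression strength.
4. **Feature scaling** — each feature is affinely mapped so its training
   5th-95th percentile range covers [0, 1], making coefficients
   comparable; the spec is persisted and re-applied verbatim at scoring
   time.
5. **Feature selection** — bidirectional stepwise regression by AIC over
   bootstrap samples; features chosen in >= 90% of bootstraps form the
   robust set.
6. **Context model** — one least-squares fit per 7-8-nt site type over
   the robust features; predicted scores are capped at -0.03 / -0.02 /
   -0.01 for 8mer / 7mer-m8 / 7mer-A1 sites (piecewise linear), weighted
   by the fraction of 3' UTR isoforms containing the site, and summed per
   (gene, miRNA family) into the cumulative weighted context score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .isoform_profiles import UtrProfile, site_weight
from .site_finder import STRONG_TYPES, WEAK_TYPES, SiteMatch, SiteType

__all__ = [
    "DEFAULT_CAPS",
    "NormalizationQuartiles",
    "ScalingSpec",
    "ContextModelParams",
    "PredictionRecord",
    "remove_shared_variation",
    "covariate_residualize",
    "quartile_rescale",
    "scale_features",
    "stepwise_aic",
    "bootstrap_stepwise_selection",
    "fit_context_model",
    "context_score",
    "cumulative_weighted_context_score",
    "context_score_percentile",
    "six_mer_training_rows",
    "fit_six_mer_model",
    "cross_validated_scores",
]

#: Published per-site-type score caps (piecewise-linear bounds).
DEFAULT_CAPS = {
    SiteType.EIGHTMER: -0.03,
    SiteType.SEVENMER_M8: -0.02,
    SiteType.SEVENMER_A1: -0.01,
}

#: The seven gene-level covariates used in the residualisation step.
COVARIATE_FEATURES = [
    "len_5UTR", "len_ORF", "len_3UTR",
    "AU_5UTR", "AU_ORF", "AU_3UTR", "log_expression",
]


def remove_shared_variation(
    fold_changes: pd.DataFrame,
    no_site_mask: pd.DataFrame,
    n_components: int = 2,
) -> pd.DataFrame:
    """Remove variation common to multiple transfection experiments.

    For each experiment, a PLSR model predicting its fold changes from all
    other experiments is fitted on genes lacking a cognate site for that
    experiment's miRNA (where no direct targeting signal exists), and its
    prediction is subtracted from every gene.
    """
    if fold_changes.shape[1] < 2:
        raise ValueError("need >= 2 experiments to estimate shared variation")
    if n_components >= fold_changes.shape[1]:
        raise ValueError("n_components must be < number of experiments")
    out = fold_changes.copy()
    for col in fold_changes.columns:
        others = fold_changes.drop(columns=[col])
        mask = no_site_mask[col].to_numpy(dtype=bool)
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(others.loc[mask].to_numpy(), fold_changes.loc[mask, col].to_numpy())
        predicted = pls.predict(others.to_numpy()).ravel()
        out[col] = fold_changes[col].to_numpy() - predicted
    return out


def covariate_residualize(
    fold_changes: pd.DataFrame,
    gene_features: pd.DataFrame,
    no_site_mask: pd.DataFrame,
) -> pd.DataFrame:
    """Residualise fold changes on gene-level covariates.

    Per experiment, ordinary least squares with intercept is fitted on the
    no-site genes only; the fitted model predicts all genes and the
    residuals are the final normalised fold changes.
    """
    X = np.column_stack([
        np.ones(len(gene_features)),
        gene_features.to_numpy(dtype=float),
    ])
    out = fold_changes.copy()
    for col in fold_changes.columns:
        mask = no_site_mask[col].to_numpy(dtype=bool)
        y = fold_changes[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        out[col] = y - X @ beta
    return out


@dataclass(frozen=True)
class NormalizationQuartiles:
    """Dataset and pooled fold-change quartiles for quartile rescaling."""

    lq_dataset: float
    uq_dataset: float
    lq_pooled: float
    uq_pooled: float

    def __post_init__(self) -> None:
        if self.uq_dataset <= self.lq_dataset or self.uq_pooled <= self.lq_pooled:
            raise ValueError("upper quartiles must exceed lower quartiles")


def quartile_rescale(
    dataset_values: np.ndarray,
    pooled_values: np.ndarray | None = None,
    quartiles: NormalizationQuartiles | None = None,
) -> np.ndarray:
    """Affinely map a dataset's quartiles onto the pooled quartiles.

    ``x_hat = (x - LQ_D) / (UQ_D - LQ_D) * (UQ_P - LQ_P) + LQ_P`` — an
    order-preserving transform that equalises global repression strength
    across experiments without being driven by outliers.
    """
    x = np.asarray(dataset_values, dtype=float)
    if quartiles is not None:
        q = quartiles
    else:
        if pooled_values is None:
            raise ValueError("provide pooled_values or explicit quartiles")
        pooled = np.asarray(pooled_values, dtype=float)
        q = NormalizationQuartiles(
            *np.percentile(x, [25, 75]), *np.percentile(pooled, [25, 75])
        )
    return (
        (x - q.lq_dataset) / (q.uq_dataset - q.lq_dataset)
        * (q.uq_pooled - q.lq_pooled)
        + q.lq_pooled
    )


@dataclass
class ScalingSpec:
    """Per-feature affine transforms fitted on training data.

    Each feature's training 5th percentile maps to 0 and 95th to 1, so
    that regression coefficients are directly comparable in magnitude.
    """

    params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, (lo, hi) in self.params.items():
            if name in out.columns:
                out[name] = (out[name] - lo) / (hi - lo)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({k: list(v) for k, v in self.params.items()}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ScalingSpec":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(params={k: tuple(v) for k, v in json.loads(text).items()})


def scale_features(
    table: pd.DataFrame, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> ScalingSpec:
    """Fit a :class:`ScalingSpec` on a training feature table."""
    params = {}
    for name in table.columns:
        lo, hi = np.percentile(table[name].to_numpy(dtype=float), [lo_pct, hi_pct])
        if hi <= lo:
            raise ValueError(f"feature {name!r} is constant on the training data")
        params[name] = (float(lo), float(hi))
    return ScalingSpec(params=params)


# ---------------------------------------------------------------------------
# Stepwise selection and model fitting


def _ols_aic(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    k = X.shape[1] + 1  # coefficients + error variance
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def stepwise_aic(
    features: pd.DataFrame, y: np.ndarray, max_steps: int = 100
) -> list[str]:
    """Bidirectional stepwise regression from the intercept-only model.

    At each step the single add-or-drop move that most lowers the AIC is
    taken; the search stops when no move improves it.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = {name: features[name].to_numpy(dtype=float) for name in features.columns}
    selected: list[str] = []

    def design(names: list[str]) -> np.ndarray:
        if not names:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n)] + [cols[c] for c in names])

    current = _ols_aic(design(selected), y)
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for name in features.columns:
            if name not in selected:
                moves.append((_ols_aic(design(selected + [name]), y), "add", name))
        for name in selected:
            trial = [c for c in selected if c != name]
            moves.append((_ols_aic(design(trial), y), "drop", name))
        if not moves:
            break
        best_aic, action, name = min(moves, key=lambda m: (m[0], m[2]))
        if best_aic >= current - 1e-10:
            break
        current = best_aic
        if action == "add":
            selected.append(name)
        else:
            selected.remove(name)
    return selected


def bootstrap_stepwise_selection(
    table: pd.DataFrame,
    feature_names: list[str],
    response: str = "fold_change",
    experiment: str | None = "experiment",
    n_boot: int = 1000,
    train_frac: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Per-feature selection frequency over bootstrapped stepwise fits.

    Each bootstrap draws *train_frac* of the single-site mRNAs from each
    experiment without replacement and runs bidirectional stepwise-AIC
    selection; the frequency of each feature is the fraction of bootstraps
    in which it was chosen.  Features at frequency >= 0.90 form the robust
    set.
    """
    if len(table) < 10 * len(feature_names):
        import warnings

        warnings.warn(
            f"only {len(table)} rows for {len(feature_names)} features; "
            "selection frequencies may be unstable",
            stacklevel=2,
        )
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    groups = (
        [idx.to_numpy() for _, idx in table.groupby(experiment).groups.items()]
        if experiment is not None and experiment in table.columns
        else [table.index.to_numpy()]
    )
    hits = pd.Series(0.0, index=feature_names)
    for _ in range(n_boot):
        take: list[np.ndarray] = []
        for idx in groups:
            k = max(1, int(round(train_frac * len(idx))))
            take.append(rng.choice(idx, size=k, replace=False))
        sample = table.loc[np.concatenate(take)]
        chosen = stepwise_aic(
            sample[feature_names], sample[response].to_numpy()
        )
        hits[chosen] += 1.0
    return hits / n_boot


@dataclass
class ContextModelParams:
    """Per-site-type linear models with score caps.

    ``models[site_type] = (intercept, {feature: coefficient})``; scores
    are capped from above at ``caps[site_type]`` where a cap is defined,
    making the score a piecewise-linear function of the features.
    """

    models: dict[SiteType, tuple[float, dict[str, float]]]
    caps: dict[SiteType, float] = field(default_factory=lambda: dict(DEFAULT_CAPS))
    scaling: ScalingSpec | None = None

    def __post_init__(self) -> None:
        strong = [SiteType.EIGHTMER, SiteType.SEVENMER_M8, SiteType.SEVENMER_A1]
        present = [t for t in strong if t in self.caps]
        values = [self.caps[t] for t in present]
        if values != sorted(values):
            raise ValueError(
                "caps must increase from 8mer to 7mer-A1 (stronger sites "
                "get more negative caps)"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "models": {
                t.value: {"intercept": b0, "coefficients": coefs}
                for t, (b0, coefs) in self.models.items()
            },
            "caps": {t.value: c for t, c in self.caps.items()},
            "scaling": (
                {k: list(v) for k, v in self.scaling.params.items()}
                if self.scaling else None
            ),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ContextModelParams":
        p = Path(str(text_or_path))
        payload = json.loads(p.read_text() if p.exists() else str(text_or_path))
        return cls(
            models={
                SiteType(t): (m["intercept"], dict(m["coefficients"]))
                for t, m in payload["models"].items()
            },
            caps={SiteType(t): c for t, c in payload["caps"].items()},
            scaling=(
                ScalingSpec({k: tuple(v) for k, v in payload["scaling"].items()})
                if payload.get("scaling") else None
            ),
        )


def fit_context_model(
    table: pd.DataFrame,
    robust_features: list[str],
    response: str = "fold_change",
    site_type_col: str = "site_type",
    caps: dict[SiteType, float] | None = None,
    scaling: ScalingSpec | None = None,
) -> ContextModelParams:
    """Fit one least-squares model per 7-8-nt site type.

    *table* holds single-site training mRNAs with already-scaled feature
    columns.  The per-type intercepts absorb the site-type effect; the
    published caps are attached for scoring.
    """
    models: dict[SiteType, tuple[float, dict[str, float]]] = {}
    for site_type, rows in table.groupby(site_type_col):
        st = SiteType(site_type)
        X = np.column_stack(
            [np.ones(len(rows))]
            + [rows[f].to_numpy(dtype=float) for f in robust_features]
        )
        y = rows[response].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        models[st] = (
            float(beta[0]),
            {f: float(b) for f, b in zip(robust_features, beta[1:])},
        )
    return ContextModelParams(
        models=models,
        caps=dict(DEFAULT_CAPS) if caps is None else caps,
        scaling=scaling,
    )


def context_score(
    params: ContextModelParams,
    features: dict[str, float],
    site_type: SiteType,
) -> float:
    """Capped linear score of one site: ``min(raw prediction, cap)``."""
    if site_type not in params.models:
        raise KeyError(f"no model fitted for site type {site_type.value}")
    intercept, coefs = params.models[site_type]
    raw = intercept + sum(b * features[f] for f, b in coefs.items())
    cap = params.caps.get(site_type)
    return float(raw if cap is None else min(raw, cap))


@dataclass
class PredictionRecord:
    """Ranked prediction for one (gene, miRNA family) pair."""

    gene_id: str
    family_key: str
    sites: list[SiteMatch]
    scores: list[float]
    weights: list[float]
    cumulative_weighted_score: float
    aggregate_pct: float = 0.0
    percentile: float | None = None


def cumulative_weighted_context_score(
    gene_id: str,
    family_key: str,
    scored_sites: list[tuple[SiteMatch, float]],
    profile: UtrProfile | None = None,
    site_pcts: list[float] | None = None,
) -> PredictionRecord | None:
    """Weight per-site scores by isoform inclusion and sum them.

    Each site's score is multiplied by the fraction of 3' UTR molecules
    containing it (weight 1 without a profile).  Genes with no 7-8-nt
    3' UTR site yield no prediction.
    """
    strong = [
        (s, sc) for s, sc in scored_sites if s.site_type in STRONG_TYPES
    ]
    if not strong:
        return None
    weights = [
        site_weight(profile, s) if profile is not None else 1.0
        for s, _ in strong
    ]
    from .conservation import aggregate_pct as _aggregate

    return PredictionRecord(
        gene_id=gene_id,
        family_key=family_key,
        sites=[s for s, _ in strong],
        scores=[sc for _, sc in strong],
        weights=weights,
        cumulative_weighted_score=float(
            sum(w * sc for w, (_, sc) in zip(weights, strong))
        ),
        aggregate_pct=_aggregate(site_pcts) if site_pcts else 0.0,
    )


def context_score_percentile(score: float, all_scores: np.ndarray) -> float:
    """Percentile rank of a score among a family's genome-wide scores.

    More negative (more repressive) scores rank higher; the most negative
    score scores 100.
    """
    all_scores = np.asarray(all_scores, dtype=float)
    if all_scores.size == 0:
        raise ValueError("no scores to rank against")
    return float(100.0 * np.mean(all_scores >= score))


def six_mer_training_rows(
    table: pd.DataFrame, site_type_col: str = "site_type"
) -> pd.DataFrame:
    """Rows usable by the 6mer context model.

    The 6mer variant considers only mRNAs whose 3' UTR lacks any 7-8-nt
    canonical site but carries at least one 6mer, offset-6mer or 6mer-A1
    site; their marginal effects are modelled additively.
    """
    weak_values = {t.value for t in WEAK_TYPES}
    strong_values = {t.value for t in STRONG_TYPES}
    strong_genes = set(
        table.loc[table[site_type_col].isin(strong_values), "gene_id"]
    )
    keep = table[site_type_col].isin(weak_values) & ~table["gene_id"].isin(
        strong_genes
    )
    return table.loc[keep]


def fit_six_mer_model(
    table: pd.DataFrame,
    robust_features: list[str],
    response: str = "fold_change",
) -> ContextModelParams:
    """Fit the 6mer context-model variant (weak site types, no caps)."""
    rows = six_mer_training_rows(table)
    models: dict[SiteType, tuple[float, dict[str, float]]] = {}
    for site_type, sub in rows.groupby("site_type"):
        st = SiteType(site_type)
        X = np.column_stack(
            [np.ones(len(sub))]
            + [sub[f].to_numpy(dtype=float) for f in robust_features]
        )
        beta, *_ = np.linalg.lstsq(X, sub[response].to_numpy(dtype=float), rcond=None)
        models[st] = (
            float(beta[0]),
            {f: float(b) for f, b in zip(robust_features, beta[1:])},
        )
    return ContextModelParams(models=models, caps={})


def cross_validated_scores(
    table: pd.DataFrame,
    robust_features: list[str],
    response: str = "fold_change",
    experiment: str = "experiment",
) -> dict[str, pd.DataFrame]:
    """Leave-one-experiment-out predictions.

    For each transfection dataset a context model is fitted on the other
    datasets and applied to the held-out one, so no prediction is made by
    a model trained on its own miRNA.
    """
    out = {}
    for held_out in table[experiment].unique():
        train = table[table[experiment] != held_out]
        test = table[table[experiment] == held_out].copy()
        params = fit_context_model(train, robust_features, response)
        test["predicted"] = [
            context_score(
                params,
                {f: row[f] for f in robust_features},
                SiteType(row["site_type"]),
            )
            for _, row in test.iterrows()
        ]
        out[held_out] = test
    return out
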