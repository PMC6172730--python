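"""Normalisation, feature selection, and the capped context model."""

import numpy as np
import pandas as pd
import pytest

from flyseed.isoform_profiles import build_profile
from flyseed.repression_model import (
    DEFAULT_CAPS,
    ContextModelParams,
    NormalizationQuartiles,
    ScalingSpec,
    bootstrap_stepwise_selection,
    context_score,
    context_score_percentile,
    covariate_residualize,
    cross_validated_scores,
    cumulative_weighted_context_score,
    fit_context_model,
    quartile_rescale,
    remove_shared_variation,
    scale_features,
    six_mer_training_rows,
    stepwise_aic,
)
from flyseed.site_finder import Region, SiteMatch, SiteType


def _site(start=10, site_type=SiteType.EIGHTMER):
    length = {SiteType.EIGHTMER: 8, SiteType.SEVENMER_M8: 7,
              SiteType.SEVENMER_A1: 7, SiteType.SIXMER: 6}[site_type]
    return SiteMatch("g", Region.UTR3, start, start + length, site_type,
                     "GGAAUGU")


class TestSharedVariationRemoval:
    def _world(self, rng, n=400, k=4, noise=0.1, batch_scale=1.0):
        batch = rng.normal(size=n)
        loadings = rng.normal(1.0, 0.2, size=k)
        fc = batch_scale * np.outer(batch, loadings) + rng.normal(
            0, noise, size=(n, k)
        )
        cols = [f"m{i}" for i in range(k)]
        mask = pd.DataFrame(True, index=range(n), columns=cols)
        return pd.DataFrame(fc, columns=cols), mask, batch

    def test_planted_batch_component_removed(self):
        rng = np.random.default_rng(0)
        fc, mask, batch = self._world(rng)
        out = remove_shared_variation(fc, mask, n_components=1)
        for col in out.columns:
            assert abs(np.corrcoef(out[col], batch)[0, 1]) < 0.05

    def test_noise_only_matrix_roughly_unchanged(self):
        rng = np.random.default_rng(1)
        fc, mask, _ = self._world(rng, batch_scale=0.0, noise=1.0)
        out = remove_shared_variation(fc, mask, n_components=1)
        assert float((out - fc).abs().mean().mean()) < 1.0  # below noise SD

    def test_single_component_zero_noise_exact(self):
        rng = np.random.default_rng(2)
        fc, mask, batch = self._world(rng, noise=0.0)
        out = remove_shared_variation(fc, mask, n_components=1)
        assert np.allclose(out.to_numpy(), 0.0, atol=1e-8)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(3)
        fc, mask, _ = self._world(rng, k=3)
        with pytest.raises(ValueError):
            remove_shared_variation(fc, mask, n_components=3)


class TestCovariateResidualization:
    def test_no_site_residual_mean_is_zero(self):
        rng = np.random.default_rng(0)
        n = 300
        feats = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        fc = pd.DataFrame({"m": rng.normal(size=n)})
        mask = pd.DataFrame({"m": rng.random(n) < 0.5})
        out = covariate_residualize(fc, feats, mask)
        assert abs(out.loc[mask["m"], "m"].mean()) < 1e-9

    def test_planted_length_dependence_removed(self):
        rng = np.random.default_rng(1)
        n = 1000
        length = rng.normal(size=n)
        feats = pd.DataFrame({"len_3UTR": length})
        fc = pd.DataFrame({"m": 0.5 * length + rng.normal(0, 0.1, n)})
        mask = pd.DataFrame({"m": np.ones(n, dtype=bool)})
        out = covariate_residualize(fc, feats, mask)
        assert abs(np.corrcoef(out["m"], length)[0, 1]) < 0.05

    def test_orthogonal_features_leave_data_unchanged(self):
        rng = np.random.default_rng(2)
        n = 2000
        feats = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.normal(size=n)
        fc = pd.DataFrame({"m": y})
        mask = pd.DataFrame({"m": np.ones(n, dtype=bool)})
        out = covariate_residualize(fc, feats, mask)
        assert np.corrcoef(out["m"], y)[0, 1] > 0.99


class TestQuartileRescale:
    def test_formula_identities(self):
        q = NormalizationQuartiles(-1.0, 1.0, -2.0, 2.0)
        out = quartile_rescale(np.array([-1.0, 1.0, 0.5]), quartiles=q)
        assert out[0] == pytest.approx(-2.0)  # LQ_D -> LQ_P
        assert out[1] == pytest.approx(2.0)   # UQ_D -> UQ_P
        assert out[2] == pytest.approx(1.0)   # hand-evaluated formula

    def test_output_quartiles_equal_pooled_quartiles(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ds = rng.normal(rng.normal(), rng.uniform(0.5, 2.0), size=500)
            pooled = rng.normal(0, 1, size=2000)
            out = quartile_rescale(ds, pooled)
            assert np.percentile(out, 25) == pytest.approx(
                np.percentile(pooled, 25), abs=1e-12
            )
            assert np.percentile(out, 75) == pytest.approx(
                np.percentile(pooled, 75), abs=1e-12
            )

    def test_transform_is_order_preserving(self):
        rng = np.random.default_rng(4)
        ds = rng.normal(size=100)
        out = quartile_rescale(ds, rng.normal(size=100))
        assert np.all(np.argsort(out) == np.argsort(ds))


class TestScalingSpec:
    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale_features(pd.DataFrame({"x": np.ones(50)}))

    def test_ninety_percent_of_training_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({"x": rng.normal(size=1000),
                              "y": rng.exponential(size=1000)})
        spec = scale_features(table)
        scaled = spec.apply(table)
        for col in table.columns:
            inside = ((scaled[col] >= 0) & (scaled[col] <= 1)).mean()
            assert inside == pytest.approx(0.90, abs=0.01)

    def test_json_round_trip(self):
        spec = ScalingSpec({"x": (0.0, 2.0), "y": (-1.5, 3.5)})
        assert ScalingSpec.from_json(spec.to_json()).params == spec.params


class TestStepwiseSelection:
    def _table(self, rng, n=600, beta=(1.0, -0.8, 0.6)):
        X = pd.DataFrame(
            rng.normal(size=(n, 6)),
            columns=["p1", "p2", "p3", "n1", "n2", "n3"],
        )
        y = (X[["p1", "p2", "p3"]].to_numpy() @ np.array(beta)
             + rng.normal(0, 0.3, n))
        X["fold_change"] = y
        return X

    def test_planted_features_selected_deterministically(self):
        rng = np.random.default_rng(6)
        table = self._table(rng)
        chosen = stepwise_aic(table[["p1", "p2", "p3", "n1", "n2", "n3"]],
                              table["fold_change"].to_numpy())
        assert {"p1", "p2", "p3"} <= set(chosen)

    def test_single_bootstrap_with_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(7)
        table = self._table(rng)
        feats = ["p1", "p2", "p3", "n1", "n2", "n3"]
        a = bootstrap_stepwise_selection(table, feats, n_boot=1, seed=3,
                                         experiment=None)
        b = bootstrap_stepwise_selection(table, feats, n_boot=1, seed=3,
                                         experiment=None)
        assert a.equals(b)

    def test_selection_frequencies_separate_signal_from_noise(self):
        # a single dataset can carry a chance correlation with a noise
        # feature that persists across its bootstraps, so the null check
        # averages selection frequencies over replicate datasets
        rng = np.random.default_rng(8)
        feats = ["p1", "p2", "p3", "n1", "n2", "n3"]
        freqs = []
        for _ in range(5):
            table = self._table(rng, n=800)
            freqs.append(
                bootstrap_stepwise_selection(table, feats, n_boot=20, seed=1,
                                             experiment=None)
            )
        mean_freq = pd.concat(freqs, axis=1).mean(axis=1)
        assert all(mean_freq[f] >= 0.90 for f in ("p1", "p2", "p3"))
        assert all(mean_freq[f] < 0.90 for f in ("n1", "n2", "n3"))


class TestContextModel:
    def _training_table(self, rng, n=900, noise=0.0):
        types = rng.choice(
            [t.value for t in DEFAULT_CAPS], size=n
        )
        X = pd.DataFrame(rng.uniform(0, 1, size=(n, 2)), columns=["f1", "f2"])
        intercepts = {"8mer": -0.4, "7mer-m8": -0.25, "7mer-A1": -0.12}
        y = (np.array([intercepts[t] for t in types])
             + 0.3 * X.f1 - 0.2 * X.f2 + rng.normal(0, noise, n))
        X["site_type"] = types
        X["fold_change"] = y
        return X

    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(9)
        table = self._training_table(rng)
        params = fit_context_model(table, ["f1", "f2"])
        b0, coefs = params.models[SiteType.EIGHTMER]
        assert b0 == pytest.approx(-0.4, abs=1e-9)
        assert coefs["f1"] == pytest.approx(0.3, abs=1e-9)
        assert coefs["f2"] == pytest.approx(-0.2, abs=1e-9)

    def test_intercepts_follow_site_type_hierarchy(self):
        rng = np.random.default_rng(10)
        table = self._training_table(rng, noise=0.05)
        params = fit_context_model(table, ["f1", "f2"])
        b8 = params.models[SiteType.EIGHTMER][0]
        b7m8 = params.models[SiteType.SEVENMER_M8][0]
        b7a1 = params.models[SiteType.SEVENMER_A1][0]
        assert b8 < b7m8 < b7a1

    def test_invalid_cap_ordering_rejected(self):
        with pytest.raises(ValueError, match="caps"):
            ContextModelParams(
                models={}, caps={SiteType.EIGHTMER: -0.01,
                                 SiteType.SEVENMER_M8: -0.02,
                                 SiteType.SEVENMER_A1: -0.03},
            )

    def test_json_round_trip(self):
        params = ContextModelParams(
            models={SiteType.EIGHTMER: (-0.4, {"f1": 0.3})},
            scaling=ScalingSpec({"f1": (0.0, 1.0)}),
        )
        back = ContextModelParams.from_json(params.to_json())
        assert back.models == params.models
        assert back.caps == params.caps
        assert back.scaling.params == params.scaling.params


class TestScoring:
    PARAMS = ContextModelParams(
        models={t: (0.0, {"f": 1.0}) for t in DEFAULT_CAPS}
    )

    @pytest.mark.parametrize(
        "site_type, raw, expected",
        [
            (SiteType.EIGHTMER, 0.10, -0.03),   # capped
            (SiteType.EIGHTMER, -0.50, -0.50),  # below cap: untouched
            (SiteType.SEVENMER_A1, 0.00, -0.01),
            (SiteType.SEVENMER_M8, 0.05, -0.02),
        ],
    )
    def test_score_capping(self, site_type, raw, expected):
        assert context_score(self.PARAMS, {"f": raw}, site_type) == expected

    def test_cumulative_weighted_score(self):
        profile = build_profile([(100, 50.0), (200, 50.0)])
        sites = [
            (_site(10, SiteType.EIGHTMER), -0.2),    # weight 1.0
            (_site(150, SiteType.SEVENMER_M8), -0.1),  # weight 0.5
        ]
        rec = cumulative_weighted_context_score("g", "GGAAUGU", sites, profile)
        assert rec.cumulative_weighted_score == pytest.approx(-0.25)

    def test_zero_weight_site_contributes_nothing(self):
        profile = build_profile([(100, 100.0)])
        sites = [
            (_site(10, SiteType.EIGHTMER), -0.2),
            (_site(150, SiteType.SEVENMER_M8), -0.9),  # beyond the only end
        ]
        rec = cumulative_weighted_context_score("g", "GGAAUGU", sites, profile)
        assert rec.cumulative_weighted_score == pytest.approx(-0.2)

    def test_gene_without_strong_site_yields_no_record(self):
        sites = [(_site(10, SiteType.SIXMER), -0.05)]
        assert cumulative_weighted_context_score("g", "GGAAUGU", sites) is None

    def test_cumulative_score_permutation_invariant(self):
        sites = [
            (_site(10, SiteType.EIGHTMER), -0.2),
            (_site(50, SiteType.SEVENMER_A1), -0.05),
        ]
        a = cumulative_weighted_context_score("g", "k", sites)
        b = cumulative_weighted_context_score("g", "k", sites[::-1])
        assert a.cumulative_weighted_score == b.cumulative_weighted_score

    def test_percentile_conventions(self):
        scores = np.array([-0.5, -0.3, -0.1, -0.05])
        assert context_score_percentile(-0.5, scores) == 100.0
        assert context_score_percentile(-0.05, scores) == pytest.approx(25.0)
        assert context_score_percentile(-0.9, np.array([-0.9])) == 100.0


class TestVariants:
    def test_six_mer_rows_exclude_strong_site_genes(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a", "a", "b", "c"],
                "site_type": ["7mer-m8", "6mer", "6mer", "offset-6mer"],
                "fold_change": [0.0, 0.0, -0.1, -0.05],
            }
        )
        rows = six_mer_training_rows(table)
        assert set(rows.gene_id) == {"b", "c"}

    def test_cross_validation_excludes_held_out_experiment(self):
        rng = np.random.default_rng(11)
        n = 300
        table = pd.DataFrame({
            "f1": rng.uniform(0, 1, n),
            "site_type": rng.choice(["8mer", "7mer-m8", "7mer-A1"], n),
            "fold_change": rng.normal(-0.2, 0.1, n),
            "experiment": rng.choice(["e1", "e2", "e3"], n),
            "gene_id": [f"g{i}" for i in range(n)],
        })
        folds = cross_validated_scores(table, ["f1"])
        assert set(folds) == {"e1", "e2", "e3"}
        for held_out, test in folds.items():
            assert (test["experiment"] == held_out).all()

    def test_identical_folds_give_identical_coefficients(self):
        rng = np.random.default_rng(12)
        base = pd.DataFrame({
            "f1": rng.uniform(0, 1, 90),
            "site_type": ["8mer"] * 90,
            "fold_change": rng.normal(-0.3, 0.1, 90),
        })
        stacked = pd.concat(
            [base.assign(experiment=e) for e in ("e1", "e2", "e3")],
            ignore_index=True,
        )
        folds = cross_validated_scores(stacked, ["f1"])
        preds = [f["predicted"].to_numpy() for f in folds.values()]
        assert np.allclose(preds[0], preds[1]) and np.allclose(preds[1], preds[2])
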