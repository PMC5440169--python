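import numpy as np
import pandas as pd
import pytest

from ncddetect.annotate import POSITION_COVARIATES
from ncddetect.io import CandidateElement, MutationRecord
from ncddetect.nullmodel import (
    COUNT_COLUMNS,
    CountTable,
    Encoding,
    FitError,
    ModelConfig,
    build_count_table,
    fit_multinomial_exact,
    fit_null_model,
    full_factorial_size,
    impute_replication_timing,
    predict_probabilities,
)
from ncddetect.simulate import simulate_count_table


def _position_table(n=10, chrom="chr1", rep_bin=2, usable=True):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n),
            "usable": usable,
            "rep_bin": rep_bin,
            "central": "A",
            "flanks": "AA",
            "segment": "other",
            "expr_bin": 1,
            "rate_bin": 1,
        }
    )


def _intercept_count_table(exposure=1000, n_ts=10, n_tv1=5, n_tv2=5):
    return CountTable(
        pd.DataFrame(
            {
                "sample": ["S1"],
                "rep_bin": [1],
                "central": ["A"],
                "flanks": ["AA"],
                "segment": ["other"],
                "expr_bin": [1],
                "rate_bin": [1],
                "n_positions": [exposure],
                "n_ts": [n_ts],
                "n_tv_at_gt": [n_tv1],
                "n_tv_ac_gc": [n_tv2],
            }
        )
    )


class TestCombinatorics:
    def test_full_factorial_cohort_scale(self):
        assert full_factorial_size(505) == 12_120_000

    def test_full_factorial_is_product(self):
        assert full_factorial_size(1) == 5 * 2 * 16 * 6 * 5 * 5


class TestBuildCountTable:
    def test_conservation_of_exposure_and_mutations(self):
        pt = _position_table(10)
        muts = [
            MutationRecord("S1", "chr1", 3, "A", "G"),
            MutationRecord("S1", "chr1", 7, "A", "T"),
        ]
        ct = build_count_table(pt, ["S1"], muts)
        assert ct.total_exposure == 10
        assert ct.total_mutations == 2
        assert ct.df["n_ts"].sum() == 1 and ct.df["n_tv_at_gt"].sum() == 1

    def test_exposure_scales_with_samples(self):
        ct = build_count_table(_position_table(10), ["S1", "S2", "S3"], [])
        assert ct.total_exposure == 30

    def test_excluded_element_dropped(self):
        pt = _position_table(10)
        muts = [MutationRecord("S1", "chr1", 3, "A", "G")]
        excl = [CandidateElement("x", "x", "protein_coding", [("chr1", 0, 5)])]
        ct = build_count_table(pt, ["S1"], muts, exclude_elements=excl)
        assert ct.total_exposure == 5
        assert ct.total_mutations == 0

    def test_mutation_outside_table_rejected(self):
        with pytest.raises(ValueError, match="chr1:100"):
            build_count_table(_position_table(10), ["S1"], [MutationRecord("S1", "chr1", 99, "A", "G")])

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="S9"):
            build_count_table(_position_table(10), ["S1"], [MutationRecord("S9", "chr1", 3, "A", "G")])

    def test_unusable_positions_do_not_count(self):
        pt = _position_table(10)
        pt.loc[:4, "usable"] = False
        ct = build_count_table(pt, ["S1"], [])
        assert ct.total_exposure == 5


class TestImputation:
    def _table_with_missing(self):
        df = pd.concat([_position_table(60, rep_bin=2), _position_table(40, rep_bin=0)])
        df.loc[df["rep_bin"] == 0, "pos"] += 1000
        return build_count_table(df, ["S1"], [])

    def test_no_missing_identical_copies(self):
        ct = build_count_table(_position_table(10), ["S1"], [])
        tables = impute_replication_timing(ct, k=3, seed=0)
        assert len(tables) == 3
        for t in tables:
            pd.testing.assert_frame_equal(t.df, ct.df)

    def test_degenerate_marginal(self):
        ct = self._table_with_missing()
        for t in impute_replication_timing(ct, k=3, seed=1):
            assert (t.df["rep_bin"] == 2).all()
            assert t.total_exposure == 100

    def test_seed_determinism(self):
        ct = self._table_with_missing()
        a = impute_replication_timing(ct, k=3, seed=42)
        b = impute_replication_timing(ct, k=3, seed=42)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.df, tb.df)

    def test_all_missing_rejected(self):
        ct = build_count_table(_position_table(10, rep_bin=0), ["S1"], [])
        with pytest.raises(ValueError, match="no observed"):
            impute_replication_timing(ct, k=3, seed=0)

    def test_marginal_distribution_used(self):
        df = pd.concat(
            [
                _position_table(300, rep_bin=1),
                _position_table(700, rep_bin=5),
                _position_table(1000, rep_bin=0),
            ]
        ).reset_index(drop=True)
        df["pos"] = np.arange(len(df))
        ct = build_count_table(df, ["S1"], [])
        # the missing rows form one aggregated row; over many imputations the
        # drawn bin follows the 30/70 marginal
        draws = [
            t.df.loc[t.df["n_positions"] >= 1000, "rep_bin"].iloc[0] if len(t.df) == 2 else None
            for t in impute_replication_timing(ct, k=200, seed=7)
        ]
        counts = pd.Series([d for d in draws if d is not None]).value_counts(normalize=True)
        assert 0.2 < counts.get(5, 0) < 1.0


class TestFit:
    def test_intercept_only_mle(self):
        ct = _intercept_count_table()
        model = fit_null_model(ct, config=ModelConfig(covariates=()))
        probs = predict_probabilities(model, ct.df)
        assert probs[0, 1] == pytest.approx(10 / 1000, rel=0.03)
        assert probs[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_replication_must_be_imputed(self):
        ct = build_count_table(_position_table(10, rep_bin=0), ["S1"], [])
        ct.df.loc[:, COUNT_COLUMNS[0]] = 1
        with pytest.raises(FitError, match="impute"):
            fit_null_model(ct, config=ModelConfig(covariates=("rep_bin",)))

    def test_score_equation_per_binomial_fit(self):
        config = ModelConfig(covariates=("sample", "central", "rep_bin"))
        samples = ["S1", "S2", "S3"]
        enc = Encoding.for_config(config, samples)
        p = len(enc.column_names)
        rng = np.random.default_rng(3)
        true = np.full((3, p), 0.0)
        true[:, 0] = -7.0
        true[:, 1:] = rng.normal(0, 0.3, (3, p - 1))
        ct, _ = simulate_count_table(true, config, samples, 500, 2000, seed=8)
        model = fit_null_model(ct, config=config)
        X = model.encoding.build(ct.df)
        trials = ct.df["n_positions"].to_numpy()
        from scipy.special import expit

        for j, col in enumerate(COUNT_COLUMNS):
            mu = expit(X @ model.coef_sets[0][j])
            assert (trials * mu).sum() == pytest.approx(ct.df[col].sum(), rel=1e-6)

    def test_identical_covariates_identical_probs(self):
        ct = _intercept_count_table()
        model = fit_null_model(ct, config=ModelConfig(covariates=()))
        df = pd.concat([ct.df, ct.df]).reset_index(drop=True)
        probs = model.predict(df)
        assert (probs[0] == probs[1]).all()

    def test_unseen_level_rejected(self):
        config = ModelConfig(covariates=("sample",))
        ct, _ = simulate_count_table(
            np.column_stack([[-6.0, -6.0, -6.0], [0.1, 0.1, 0.1]]), config, ["S1", "S2"], 50, 5000, seed=2
        )
        model = fit_null_model(ct, config=config)
        bad = ct.df.copy()
        bad.loc[0, "sample"] = "S99"
        with pytest.raises(ValueError, match="unseen level"):
            model.predict(bad)

    def test_monotone_in_positive_coefficient(self):
        config = ModelConfig(covariates=("rep_bin",))
        enc = Encoding.for_config(config, ["S1"])
        p = len(enc.column_names)
        true = np.zeros((3, p))
        true[:, 0] = -6.0
        true[:, 1:] = np.linspace(0.2, 0.8, p - 1)  # increasing rep effect
        ct, _ = simulate_count_table(true, config, ["S1"], 400, 10_000, seed=5)
        model = fit_null_model(ct, config=config)
        rows = ct.df.drop_duplicates("rep_bin").sort_values("rep_bin")
        probs = model.predict(rows)
        mut = probs[:, 1:].sum(axis=1)
        assert (np.diff(mut) > 0).all()

    def test_separation_is_reported(self):
        ct = _intercept_count_table(n_ts=0, n_tv1=0, n_tv2=0)
        with pytest.raises(FitError):
            fit_null_model(ct, config=ModelConfig(covariates=()))

    def test_save_load_round_trip(self, tmp_path):
        config = ModelConfig(covariates=("sample", "central"))
        true = np.tile([-6.5, 0.2, 0.3], (3, 1))
        ct, _ = simulate_count_table(true, config, ["S1", "S2"], 100, 5000, seed=4)
        model = fit_null_model(ct, config=config, seed=11)
        path = tmp_path / "model.json"
        model.save(path)
        from ncddetect.nullmodel import NullModel

        again = NullModel.load(path)
        np.testing.assert_allclose(again.predict(ct.df), model.predict(ct.df))
        assert again.seed == 11
        assert again.config == config

    def test_model_ladder_presets_fit(self):
        rng = np.random.default_rng(9)
        for preset in ("basic", "1a", "1b", "1c", "final"):
            config = ModelConfig.preset(preset)
            enc = Encoding.for_config(config, ["S1", "S2"])
            p = len(enc.column_names)
            true = np.zeros((3, p))
            true[:, 0] = -6.0
            true[:, 1:] = rng.normal(0, 0.1, (3, p - 1))
            ct, _ = simulate_count_table(true, config, ["S1", "S2"], 3000, 3000, seed=10)
            model = fit_null_model(ct, config=config)
            assert model.predict(ct.df.head(5)).shape == (5, 4)

    def test_signature_interaction_columns(self):
        config = ModelConfig(covariates=("sample", "central", "flanks"), signature_interaction=True)
        enc = Encoding.for_config(config, ["S1", "S2"])
        names = enc.column_names
        assert "sample[S2]:flanks[AC]" in names
        assert "sample[S2]:central[G]" in names


class TestRecovery:
    CONFIG = ModelConfig(covariates=("sample", "rep_bin", "central"))
    SAMPLES = ["S1", "S2", "S3", "S4"]

    def _true(self, rng, null_column=None):
        enc = Encoding.for_config(self.CONFIG, self.SAMPLES)
        p = len(enc.column_names)
        true = np.zeros((3, p))
        true[:, 0] = [-7.0, -7.7, -7.7]
        true[:, 1:] = rng.normal(0, 0.3, (3, p - 1))
        if null_column is not None:
            true[:, null_column] = 0.0
        return true

    def test_coefficients_within_3se_at_1e6_exposures(self):
        rng = np.random.default_rng(17)
        true = self._true(rng)
        ct, _ = simulate_count_table(true, self.CONFIG, self.SAMPLES, 2000, 500, seed=17)
        assert ct.total_exposure == 1_000_000
        model = fit_null_model(ct, config=self.CONFIG)
        z = (model.coef_sets[0] - true) / model.se_sets[0]
        assert np.abs(z).max() < 3.0

    def test_null_effect_ci_covers_zero(self):
        # a covariate with true effect 0: its 95% CI (first outcome) covers
        # 0 in >= 90% of 50 replicates
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            true = self._true(rng, null_column=4)
            ct, _ = simulate_count_table(true, self.CONFIG, self.SAMPLES, 400, 2500, seed=200 + rep)
            model = fit_null_model(ct, config=self.CONFIG)
            lo = model.coef_sets[0][0, 4] - 1.96 * model.se_sets[0][0, 4]
            hi = model.coef_sets[0][0, 4] + 1.96 * model.se_sets[0][0, 4]
            hits += bool(lo <= 0 <= hi)
        assert hits >= 45

    def test_binomial_decomposition_matches_exact_multinomial(self):
        rng = np.random.default_rng(23)
        true = self._true(rng)
        ct, _ = simulate_count_table(true, self.CONFIG, self.SAMPLES, 2000, 2000, seed=23)
        model = fit_null_model(ct, config=self.CONFIG)
        exact = fit_multinomial_exact(ct, config=self.CONFIG)
        pb = model.predict(ct.df)[:, 1:]
        pe = exact.predict(ct.df)[:, 1:]
        assert np.max(np.abs(pb - pe) / pe) < 0.02

    def test_imputed_fit_averages_probabilities(self):
        config = ModelConfig(covariates=("central",))
        true = np.tile([-6.0, 0.3], (3, 1))
        ct, _ = simulate_count_table(true, config, ["S1"], 200, 5000, seed=31)
        missing = ct.df.copy()
        missing.loc[:49, "rep_bin"] = 0
        tables = impute_replication_timing(CountTable(missing), k=3, seed=5)
        model = fit_null_model(tables, config=config)
        assert len(model.coef_sets) == 3
        probs = model.predict(ct.df.head(3))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
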