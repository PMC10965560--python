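"""Lobe PCA, mean absolute correlation, Gini importance and EII ranking."""

import numpy as np
import pandas as pd
import pytest

from emorec import (
    EffectSpec,
    GeneratorConfig,
    WindowSpec,
    best_band,
    build_feature_table,
    correlation_table,
    eii_ranking,
    generate_recordings,
    gi_table,
    lobe_pca_first_component,
    mean_abs_corr,
)
from emorec.montage import CHANNELS_32, LOBE_MAP, OPTIMAL_CHANNELS_8
from emorec.select import EIIChannelSelector, _pearson


class TestLobeMap:
    def test_lobes_partition_the_montage(self):
        seen = [ch for members in LOBE_MAP.values() for ch in members]
        assert len(seen) == 32
        assert set(seen) == set(CHANNELS_32)

    def test_lobe_sizes(self):
        sizes = {lobe: len(m) for lobe, m in LOBE_MAP.items()}
        assert sizes == {
            "Frontal": 9, "Temporal": 2, "Parietal": 7,
            "Occipital": 3, "Central": 7, "Central-Parietal": 4,
        }

    def test_temporal_lobe_members(self):
        assert set(LOBE_MAP["Temporal"]) == {"T7", "T8"}


class TestLobePCA:
    def test_rank_one_two_identical_channels(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        proj = lobe_pca_first_component(np.column_stack([x, x]))
        np.testing.assert_allclose(np.abs(proj.loading), 1 / np.sqrt(2), atol=1e-12)
        assert proj.explained_ratio == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n, m = rng.integers(5, 11), rng.integers(1, 11)
            X = rng.standard_normal((n, m))
            proj = lobe_pca_first_component(X)
            Xc = X - X.mean(axis=0)
            _, vecs = np.linalg.eigh(Xc.T @ Xc)
            top = vecs[:, -1]
            if np.dot(top, proj.loading) < 0:
                top = -top
            assert np.abs(proj.loading - top).max() < 1e-8

    def test_loading_is_unit_norm_with_fixed_sign(self):
        rng = np.random.default_rng(2)
        proj = lobe_pca_first_component(rng.standard_normal((50, 4)))
        assert np.linalg.norm(proj.loading) == pytest.approx(1.0)
        assert proj.loading[np.argmax(np.abs(proj.loading))] > 0

    def test_projection_maximizes_variance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 5)) * np.array([3.0, 1, 1, 1, 1])
        proj = lobe_pca_first_component(X)
        for _ in range(20):
            v = rng.standard_normal(5)
            v /= np.linalg.norm(v)
            Xc = X - X.mean(axis=0)
            assert np.var(Xc @ v) <= np.var(proj.scores) + 1e-9

    def test_zero_variance_fallback(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            proj = lobe_pca_first_component(np.ones((10, 3)))
        assert np.linalg.norm(proj.loading) == 1.0
        assert not proj.scores.any()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            lobe_pca_first_component(np.ones((1, 3)))


class TestMeanAbsCorr:
    def test_perfect_correlation(self):
        y = [np.arange(10.0), np.arange(5.0)]
        assert mean_abs_corr(y, y) == pytest.approx(1.0)

    def test_sign_invariance(self):
        y = [np.arange(10.0)]
        z = [-np.arange(10.0)]
        assert mean_abs_corr(z, y) == pytest.approx(1.0)

    def test_constant_subject_excluded(self, caplog):
        z = [np.ones(10), np.arange(10.0)]
        y = [np.arange(10.0), np.arange(10.0)]
        with caplog.at_level("WARNING"):
            r = mean_abs_corr(z, y)
        assert r == pytest.approx(1.0)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            mean_abs_corr([np.ones(5)], [np.ones(5)])

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        from scipy.stats import pearsonr

        for _ in range(25):
            x, y = rng.standard_normal((2, 40))
            assert _pearson(x, y) == pytest.approx(pearsonr(x, y)[0], abs=1e-12)


@pytest.fixture(scope="module")
def temporal_gamma_table():
    """3 subjects with gamma-band couplings planted on T7/T8 only."""
    eff = EffectSpec(
        couplings=(
            ("T7", "gamma", "arousal", 2.0),
            ("T8", "gamma", "arousal", 2.0),
            ("T7", "gamma", "valence", 1.0),
        ),
        noise_sd=0.3,
    )
    cfg = GeneratorConfig(n_subjects=3, trials_per_subject=12, trial_duration_s=8.0)
    rs = generate_recordings(cfg, eff, seed=31)
    return build_feature_table(rs, WindowSpec(2.0, 0.5))


class TestCorrelationTable:
    def test_grid_is_30_cells(self, temporal_gamma_table):
        table = correlation_table(temporal_gamma_table)
        assert len(table) == 30  # 6 lobes x 5 bands
        assert {"arousal", "valence", "dominance", "sum"} <= set(table.columns)
        vals = table[["arousal", "valence", "dominance"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        np.testing.assert_allclose(
            table["sum"], table[["arousal", "valence", "dominance"]].sum(axis=1)
        )

    def test_planted_temporal_gamma_wins(self, temporal_gamma_table):
        table = correlation_table(temporal_gamma_table)
        top = table.loc[table["sum"].idxmax()]
        assert (top["lobe"], top["band"]) == ("Temporal", "gamma")
        assert best_band(table) == "gamma"

    def test_missing_lobe_member_rejected(self, temporal_gamma_table):
        broken = temporal_gamma_table.drop(columns=["T8_gamma"])
        with pytest.raises(ValueError, match="T8_gamma"):
            correlation_table(broken)

    def test_subject_block_order_invariance(self, temporal_gamma_table):
        subjects = list(temporal_gamma_table["subject"].unique())
        shuffled = pd.concat(
            [temporal_gamma_table[temporal_gamma_table["subject"] == s]
             for s in reversed(subjects)],
            ignore_index=True,
        )
        a = correlation_table(temporal_gamma_table)
        b = correlation_table(shuffled)
        np.testing.assert_allclose(
            a[["arousal", "valence", "dominance"]].to_numpy(),
            b[["arousal", "valence", "dominance"]].to_numpy(),
            atol=1e-12,
        )


class TestBestBand:
    @staticmethod
    def _table(weights):
        rows = []
        for lobe in LOBE_MAP:
            for band, w in weights.items():
                rows.append(
                    {"lobe": lobe, "band": band, "arousal": w, "valence": w,
                     "dominance": w, "sum": 3 * w}
                )
        return pd.DataFrame(rows)

    def test_all_equal_breaks_to_gamma(self):
        table = self._table({b: 0.2 for b in ("delta", "theta", "alpha", "beta", "gamma")})
        assert best_band(table) == "gamma"

    def test_planted_theta_wins(self):
        weights = {"delta": 0.1, "theta": 0.6, "alpha": 0.1, "beta": 0.1, "gamma": 0.1}
        assert best_band(self._table(weights)) == "theta"

    def test_incomplete_table_rejected(self):
        table = self._table({"delta": 0.1, "theta": 0.2})
        with pytest.raises(ValueError, match="cover"):
            best_band(table)


def _informative_features(seed=5, n=300, driver=10):
    """Two subjects, 32 'gamma' channels of noise, one linearly driving y."""
    rng = np.random.default_rng(seed)
    frames = []
    for s in ("s01", "s02"):
        X = rng.standard_normal((n, 32))
        y = 2.0 * X[:, driver] + 0.05 * rng.standard_normal(n)
        data = {f"{ch}_gamma": X[:, j] for j, ch in enumerate(CHANNELS_32)}
        data["subject"] = s
        for comp in ("arousal", "valence", "dominance"):
            data[comp] = y
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


class TestGiTable:
    def test_normalization_and_single_informative_channel(self):
        feats = _informative_features()
        gi = gi_table(feats, "gamma", n_iterations=3, seed=0, n_estimators=30)
        sums = gi[["arousal", "valence", "dominance"]].sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        driver = CHANNELS_32[10]
        for comp in ("arousal", "valence", "dominance"):
            assert gi[comp].idxmax() == driver
            assert gi.loc[driver, comp] > 0.5

    def test_default_iteration_count_is_ten(self):
        import inspect

        assert inspect.signature(gi_table).parameters["n_iterations"].default == 10

    def test_too_few_windows_rejected(self):
        feats = _informative_features(n=5)
        with pytest.raises(ValueError, match=">= 10"):
            gi_table(feats, "gamma", n_iterations=1, n_estimators=5)

    def test_missing_column_rejected(self):
        feats = _informative_features().drop(columns=["T7_gamma"])
        with pytest.raises(ValueError, match="T7_gamma"):
            gi_table(feats, "gamma")


class TestEIIRanking:
    def test_identical_columns_give_that_column(self):
        col = pd.Series(np.arange(1, 33, dtype=float) / np.arange(1, 33).sum(),
                        index=list(CHANNELS_32))
        gi = pd.DataFrame({"arousal": col, "valence": col, "dominance": col})
        ranking = eii_ranking(gi, k=8)
        np.testing.assert_allclose(ranking.eii, col)
        assert ranking.eii.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tie_break_is_alphabetical(self):
        gi = pd.DataFrame(
            {c: [1 / 32] * 32 for c in ("arousal", "valence", "dominance")},
            index=list(CHANNELS_32),
        )
        ranking = eii_ranking(gi, k=4)
        assert ranking.selected == sorted(CHANNELS_32)[:4]

    def test_k_too_large_rejected(self):
        gi = pd.DataFrame(
            {c: [1 / 32] * 32 for c in ("arousal", "valence", "dominance")},
            index=list(CHANNELS_32),
        )
        with pytest.raises(ValueError, match="k=40"):
            eii_ranking(gi, k=40)

    def test_reference_channel_set_constant(self):
        assert OPTIMAL_CHANNELS_8 == (
            "Fp1", "F7", "FC5", "FC6", "T7", "T8", "P7", "O2"
        )


class TestSelectorEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        sel = EIIChannelSelector(k=4, n_iterations=2, n_estimators=10)
        params = sel.get_params()
        assert params["k"] == 4
        cloned = clone(sel)
        assert cloned.get_params() == params

    def test_fit_and_transform(self, temporal_gamma_table):
        sel = EIIChannelSelector(
            k=4, n_iterations=2, n_estimators=15, random_state=0
        ).fit(temporal_gamma_table)
        assert sel.best_band_ == "gamma"
        assert len(sel.channels_) == 4
        assert {"T7", "T8"} <= set(sel.channels_)
        out = sel.transform(temporal_gamma_table)
        kept_channels = {c.split("_", 1)[0] for c in out.columns if "_" in c}
        assert not (set(CHANNELS_32) - set(sel.channels_)) & kept_channels
        assert "subject" in out.columns and "arousal" in out.columns
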