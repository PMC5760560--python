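"""Preprocessing tests: correlations vs direct oracles, greedy reduction,
scaling contracts, baseline subtraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musemo import preprocess as pp
from musemo import synthetic_data as sd


def _pearson_oracle(x, y):
    """Independent covariance/sigma implementation of Pearson r."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(np.sum(x * y) / np.sqrt(np.sum(x ** 2) * np.sum(y ** 2)))


class TestCorrelationMatrix:
    def test_identity_and_exact_linearity(self):
        t = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6], "c": [3.0, 2, 1]})
        rep = pp.correlation_matrix(t)
        assert rep.r.loc["a", "a"] == pytest.approx(1.0)
        assert rep.r.loc["a", "b"] == pytest.approx(1.0)
        assert rep.r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(rep.r.to_numpy(), rep.r.to_numpy().T)

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.standard_normal((10, 5)), columns=list("abcde"))
        rep = pp.correlation_matrix(t)
        for i in "abcde":
            for j in "abcde":
                assert rep.r.loc[i, j] == pytest.approx(
                    _pearson_oracle(t[i], t[j]), abs=1e-12)

    def test_zero_variance_flagged_not_violating(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        rep = pp.correlation_matrix(t)
        assert rep.zero_variance == ["b"]
        assert rep.violations(0.8)["b"] == []

    def test_missing_values_rejected(self):
        t = pd.DataFrame({"a": [1.0, np.nan, 3], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="missing"):
            pp.correlation_matrix(t)


def _report_from_matrix(names, high_pairs, base=0.1, rolloff_bg=0.35):
    """Build a CorrelationReport directly from a constructed r matrix."""
    r = pd.DataFrame(base, index=names, columns=names)
    for f in names:
        r.loc[f, f] = 1.0
    spectral = {"centroid", "spread", "rolloff", "brightness"}
    for f in names:
        if f not in spectral and "rolloff" in names:
            r.loc["rolloff", f] = r.loc[f, "rolloff"] = rolloff_bg
    for (a, b), v in high_pairs.items():
        r.loc[a, b] = r.loc[b, a] = v
    return pp.CorrelationReport(r=r)


@pytest.fixture
def study_pattern_report():
    """Correlation pattern of the original audio features: centroid above
    threshold with spread, rolloff and brightness; spread-rolloff above; all
    other pairs below."""
    high = {("centroid", "spread"): 0.85, ("centroid", "rolloff"): 0.84,
            ("centroid", "brightness"): 0.82, ("spread", "rolloff"): 0.83}
    return _report_from_matrix(list(sd.AUDIO_FEATURES), high)


class TestReduceFeatures:
    def test_study_pattern_removes_centroid_then_rolloff(self, study_pattern_report):
        kept, trace = pp.reduce_features(study_pattern_report, 0.8)
        assert [t["feature"] for t in trace] == ["centroid", "rolloff"]
        assert "spread" in kept and "brightness" in kept
        assert len(kept) == 10

    def test_physio_all_below_threshold_nothing_removed(self):
        rng = np.random.default_rng(1)
        frame = sd.excerpts_to_frame(sd.generate_excerpts(sd.GeneratorConfig(seed=6)))
        rep = pp.correlation_matrix(frame[list(sd.PHYSIO_FEATURES)])
        assert (np.abs(rep.r.to_numpy()[~np.eye(5, dtype=bool)]) < 0.8).all()
        kept, trace = pp.reduce_features(rep, 0.8)
        assert kept == list(sd.PHYSIO_FEATURES) and trace == []

    @pytest.mark.parametrize("seed", range(20))
    def test_no_surviving_pair_violates(self, seed):
        """Brute-force post-check on random correlation structures."""
        rng = np.random.default_rng(seed)
        n, p = 12, 6
        base = rng.standard_normal((n, 3))
        loadings = rng.uniform(-1, 1, size=(3, p))
        t = pd.DataFrame(base @ loadings + 0.3 * rng.standard_normal((n, p)),
                         columns=[f"f{i}" for i in range(p)])
        rep = pp.correlation_matrix(t)
        kept, _ = pp.reduce_features(rep, 0.8)
        sub = rep.r.loc[kept, kept].to_numpy()
        assert (np.abs(sub[~np.eye(len(kept), dtype=bool)]) <= 0.8).all()

    def test_idempotent(self, study_pattern_report):
        kept, _ = pp.reduce_features(study_pattern_report, 0.8)
        rep2 = pp.CorrelationReport(r=study_pattern_report.r.loc[kept, kept])
        kept2, trace2 = pp.reduce_features(rep2, 0.8)
        assert kept2 == kept and trace2 == []

    def test_trace_stable_under_row_permutation(self):
        frame = sd.excerpts_to_frame(sd.generate_excerpts(sd.GeneratorConfig(seed=8)))
        table = frame[list(sd.AUDIO_FEATURES)]
        perm = np.random.default_rng(0).permutation(len(table))
        _, trace_a = pp.reduce_features(pp.correlation_matrix(table), 0.8)
        _, trace_b = pp.reduce_features(
            pp.correlation_matrix(table.iloc[perm].reset_index(drop=True)), 0.8)
        assert [t["feature"] for t in trace_a] == [t["feature"] for t in trace_b]


class TestScaling:
    def test_minmax_maps_endpoints(self):
        t = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        params = pp.fit_minmax(t)
        np.testing.assert_allclose(pp.apply_minmax(params, t)["x"], [0, 0.5, 1])

    def test_constant_column_maps_to_half_with_warning(self):
        t = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        params = pp.fit_minmax(t)
        with pytest.warns(UserWarning, match="constant"):
            out = pp.apply_minmax(params, t)
        assert (out["x"] == 0.5).all()

    def test_new_data_may_exceed_unit_interval(self):
        params = pp.fit_minmax(pd.DataFrame({"x": [0.0, 1.0]}))
        out = pp.apply_minmax(params, pd.DataFrame({"x": [-1.0, 2.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, 2.0])

    def test_rating_rescale_endpoints(self):
        np.testing.assert_allclose(pp.rescale_rating([-1, 0, 1]), [0, 0.5, 1])
        assert pp.rescale_rating(0.5) == pytest.approx(0.75)

    @given(st.floats(min_value=-1, max_value=1, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_rating_round_trip_identity(self, v):
        assert pp.unscale_rating(pp.rescale_rating(v)) == pytest.approx(v, abs=1e-12)


class TestBaselineSubtract:
    def test_values(self):
        assert pp.baseline_subtract(5.2, 3.1) == pytest.approx(2.1)
        assert pp.baseline_subtract(3.0, 3.0) == 0.0

    def test_columnwise_equals_elementwise(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(20)
        b = rng.standard_normal(20)
        out = pp.baseline_subtract(e, b)
        for i in range(20):
            assert out[i] == pytest.approx(e[i] - b[i], abs=1e-15)

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="missing"):
            pp.baseline_subtract(1.0, np.nan)


class TestFeatureRatingCorrelations:
    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(rng.standard_normal((60, 3)), columns=["a", "b", "c"])
        ratings = pd.DataFrame(rng.uniform(-1, 1, (60, 2)), columns=["valence", "arousal"])
        out = pp.feature_rating_correlations(feats, ratings)
        assert (out["df"] == 58).all()
        assert len(out) == 6

    def test_perfect_linearity(self):
        feats = pd.DataFrame({"a": np.arange(10.0)})
        ratings = pd.DataFrame({"valence": np.arange(10.0) * 2 + 1})
        out = pp.feature_rating_correlations(feats, ratings)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-10

    def test_p_agrees_with_permutation_oracle(self):
        """Two-sided t-based p-value vs a 10^4-draw permutation oracle."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        y = 0.7 * x + rng.standard_normal(10)
        out = pp.feature_rating_correlations(
            pd.DataFrame({"x": x}), pd.DataFrame({"valence": y}))
        r_obs, p_t = out["r"].iloc[0], out["p"].iloc[0]
        n_perm = 10_000
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_perm = (pc @ xc) / np.sqrt((xc ** 2).sum() * (pc ** 2).sum(axis=1))
        p_perm = (np.abs(r_perm) >= abs(r_obs) - 1e-12).mean()
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01
        assert p_t == pytest.approx(p_perm, abs=mc_err)
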