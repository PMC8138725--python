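"""Shrunken-centroid estimator: brute-force oracle agreement, shrinkage
monotonicity, the probability rule, CV fold construction and shrinkage
selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import oracle_fit, oracle_probabilities
from conftest import profiles_from_arrays
from tgx_hdaci import (
    NSC,
    NSCResults,
    ShrinkagePath,
    SimConfig,
    class_probabilities,
    classify_nsc,
    fit_nsc,
    select_shrinkage,
    simulate_profiles,
    soft_threshold,
)
from tgx_hdaci.simulate import make_oracle_instance


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "d,delta,expected",
        [
            (2.0, 3.449, 0.0),
            (-5.0, 3.449, -1.551),
            (0.0, 1.0, 0.0),
            (1.5, 1.5, 0.0),
        ],
    )
    def test_values(self, d, delta, expected):
        assert soft_threshold(d, delta) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-100, 100), st.floats(0, 50))
    @settings(max_examples=200, derandomize=True)
    def test_shrinks_toward_zero_preserving_sign(self, d, delta):
        out = soft_threshold(d, delta)
        assert abs(out) <= abs(d)
        assert out == 0.0 or np.sign(out) == np.sign(d)
        assert abs(out) == pytest.approx(max(abs(d) - delta, 0.0), abs=1e-12)

    def test_delta_zero_is_identity(self):
        d = np.array([-3.0, 0.0, 7.25])
        np.testing.assert_array_equal(soft_threshold(d, 0.0), d)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestFitAgainstOracle:
    @pytest.mark.parametrize("seed", [7, 19, 23])
    @pytest.mark.parametrize("delta", [0.0, 0.4, 1.3])
    def test_all_internal_quantities(self, seed, delta):
        X, y, genes = make_oracle_instance(n_genes=5, n_samples=6, seed=seed)
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=delta)
        ref = oracle_fit(X.tolist(), list(y), delta)
        np.testing.assert_allclose(res.overall_centroid, ref["overall"], atol=1e-12)
        np.testing.assert_allclose(res.pooled_sd, ref["s"], atol=1e-12)
        assert res.s0 == pytest.approx(ref["s0"], abs=1e-12)
        for k, cls_ in enumerate(res.classes):
            np.testing.assert_allclose(
                res.class_centroids[:, k], ref["centroids"][cls_], atol=1e-12
            )
            np.testing.assert_allclose(
                res.shrunken_dstat[:, k], ref["dprime"][cls_], atol=1e-12
            )
            np.testing.assert_allclose(
                res.shrunken_centroids[:, k], ref["shrunken"][cls_], atol=1e-12
            )
        assert [genes[i] for i in ref["surviving"]] == list(res.surviving_genes)

    def test_probabilities_match_oracle(self, tiny_instance):
        X, y, genes = tiny_instance
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=0.3)
        ref = oracle_fit(X.tolist(), list(y), 0.3)
        rng = np.random.default_rng(99)
        for _ in range(20):
            x = rng.normal(0.0, 2.0, size=len(genes))
            got = res.predict_proba(x)[0]
            want = oracle_probabilities(ref, x.tolist())
            for k, cls_ in enumerate(res.classes):
                assert got[k] == pytest.approx(want[cls_], abs=1e-12)


class TestFitContracts:
    def test_identical_profiles_degenerate(self):
        genes = ("G1", "G2")
        X = np.array([[1.0, 2.0]] * 4)
        y = ["HDACi", "HDACi", "non-HDACi", "non-HDACi"]
        with pytest.raises(ValueError, match="degenerate"):
            fit_nsc(profiles_from_arrays(X, y, genes))

    def test_class_with_one_member_rejected(self):
        X = np.random.default_rng(1).normal(size=(3, 2))
        y = ["HDACi", "non-HDACi", "non-HDACi"]
        with pytest.raises(ValueError, match="HDACi"):
            fit_nsc(profiles_from_arrays(X, y, ("G1", "G2")))

    def test_empirical_priors(self, tiny_instance):
        X, y, genes = tiny_instance
        X, y = np.vstack([X, X[-1] + 0.1]), list(y) + ["non-HDACi"]
        res = NSC.from_profiles(
            profiles_from_arrays(X, y, genes), priors="empirical"
        ).fit(0.0)
        np.testing.assert_allclose(res.priors, [3 / 7, 4 / 7])

    def test_zero_delta_nearest_centroid_equivalence(self, tiny_instance):
        """At delta=0 with uniform priors the call is nearest class centroid
        in (s_i + s0)-standardized Euclidean distance."""
        X, y, genes = tiny_instance
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=0.0)
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.normal(0.0, 2.0, size=len(genes))
            dist = [
                (((x - res.class_centroids[:, k]) / res.denom) ** 2).sum()
                for k in range(2)
            ]
            assert res.predict_proba(x)[0].argmax() == int(np.argmin(dist))

    def test_fully_shrunken_model_errors(self, tiny_instance):
        X, y, genes = tiny_instance
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=1e6)
        assert res.n_surviving == 0
        with pytest.raises(ValueError, match="fully shrunken"):
            res.predict_proba(np.zeros(len(genes)))


class TestProbabilityRule:
    def test_probabilities_sum_to_one(self, tiny_instance):
        X, y, genes = tiny_instance
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=0.2)
        rng = np.random.default_rng(77)
        P = res.predict_proba(rng.normal(0, 50, size=(200, len(genes))))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_equidistant_profile_is_fifty_fifty(self):
        genes = ("G1",)
        X = np.array([[1.0], [1.2], [-1.0], [-1.2]])
        y = ["HDACi", "HDACi", "non-HDACi", "non-HDACi"]
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=0.0)
        p = class_probabilities(res, np.array([0.0]))
        assert p["HDACi"] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "p_hdaci,expected", [(0.95, "HDACi"), (0.90, "non-HDACi"), (0.55, "non-HDACi")]
    )
    def test_strict_cutoff(self, p_hdaci, expected, panel_model):
        proba = np.array([[p_hdaci, 1.0 - p_hdaci]])
        assert panel_model._calls_from_proba(proba, 0.90)[0] == expected

    def test_classify_nsc_returns_probability(self, panel_model, asset):
        call, p = classify_nsc(panel_model, asset.centroid_hdaci)
        assert call == "HDACi"
        assert p > 0.999


class TestShrinkagePathCV:
    def _reference(self, seed=1):
        cfg = SimConfig.table2(seed=seed)
        profiles, _ = simulate_profiles(cfg, prefix="ref")
        return profiles

    def test_fold_structure_20_compounds_10_folds(self):
        profiles = self._reference()
        model = NSC.from_profiles(profiles)
        assignment = model._fold_assignment(folds=10, seed=3)
        folds = {}
        for comp, f in assignment.items():
            folds.setdefault(f, []).append(comp)
        assert len(folds) == 10
        labels = {p.compound: p.class_label for p in profiles}
        for members in folds.values():
            assert len(members) == 2
            assert sorted(labels[m] for m in members) == ["HDACi", "non-HDACi"]

    def test_path_monotone_and_delta0_survivors(self):
        profiles = self._reference()
        model = NSC.from_profiles(profiles)
        path = model.path(folds=5, seed=11)
        assert np.all(np.diff(path.genes_surviving) <= 0)
        res0 = model.fit(0.0)
        expected = int((np.abs(res0.dstat) > 0).any(axis=1).sum())
        assert path.genes_surviving[0] == expected

    def test_well_separated_data_perfect_cv_below_collapse(self):
        profiles = self._reference(seed=4)
        path = NSC.from_profiles(profiles).path(folds=10, seed=4)
        # at low shrinkage CV classification is perfect...
        low = path.thresholds <= 0.25 * path.thresholds[-1]
        assert low.sum() >= 5
        assert np.all(path.cv_accuracy[low] == 1.0)
        # ...and accuracy collapses as the panel shrinks away
        assert path.cv_accuracy[-1] < 1.0

    def test_too_many_folds_rejected(self):
        profiles = self._reference()
        with pytest.raises(ValueError, match="impossible"):
            NSC.from_profiles(profiles).path(folds=21, seed=0)

    def test_monotone_survivors_random_grid(self, tiny_instance):
        X, y, genes = tiny_instance
        model = NSC.from_profiles(profiles_from_arrays(X, y, genes))
        res = model.fit(0.0)
        rng = np.random.default_rng(13)
        grid = np.sort(rng.uniform(0, np.abs(res.dstat).max() * 1.2, size=40))
        counts = [
            int((np.abs(soft_threshold(res.dstat, d)) > 0).any(axis=1).sum())
            for d in grid
        ]
        assert np.all(np.diff(counts) <= 0)


class TestSelectShrinkage:
    def _path(self, deltas, genes, acc):
        return ShrinkagePath(
            thresholds=np.asarray(deltas, float),
            genes_surviving=np.asarray(genes),
            cv_accuracy=np.asarray(acc, float),
            fold_assignment={},
            folds=10,
            cutoff=0.9,
        )

    def test_only_one_in_range(self):
        path = self._path([1, 2, 3], [500, 120, 81], [1.0, 1.0, 1.0])
        assert select_shrinkage(path) == 3.0

    def test_tie_goes_to_larger_delta(self):
        path = self._path([1, 2, 3], [90, 60, 20], [1.0, 1.0, 1.0])
        assert select_shrinkage(path) == 2.0

    def test_fallback_nearest_range_with_warning(self):
        path = self._path([1, 2], [300, 110], [1.0, 1.0])
        with pytest.warns(UserWarning, match="110 genes"):
            assert select_shrinkage(path) == 2.0

    def test_no_accurate_delta_is_hard_error(self):
        path = self._path([1, 2], [80, 60], [0.6, 0.7])
        with pytest.raises(ValueError, match="0.700"):
            select_shrinkage(path)


class TestModelPersistence:
    def test_roundtrip_preserves_predictions(self, tiny_instance, tmp_path):
        X, y, genes = tiny_instance
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=0.3)
        res.save(tmp_path / "model.json")
        back = NSCResults.load(tmp_path / "model.json")
        x = np.linspace(-1, 1, res.n_surviving)
        np.testing.assert_allclose(
            back.predict_proba(x)[0],
            res.predict_proba(
                np.array([
                    x[list(res.surviving_genes).index(g)] if g in res.surviving_genes else 0.0
                    for g in res.genes
                ])
            )[0],
            atol=1e-12,
        )

    def test_summary_mentions_panel_size(self, tiny_instance):
        X, y, genes = tiny_instance
        res = fit_nsc(profiles_from_arrays(X, y, genes), delta=0.1)
        text = res.summary()
        assert f"genes surviving: {res.n_surviving}" in text
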