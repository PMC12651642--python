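import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thalrisk as tr
from thalrisk.errors import ConfigError
from thalrisk.explain import mann_whitney_p


def brute_force_mwu_p(x, y):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    total = 0
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = sum(np.sum(g > rest) + 0.5 * np.sum(g == rest) for g in grp)
        us.append(u)
        total += 1
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.fixture(scope="module")
def trained_model():
    """Boosted model on data with one dominant feature, plus its matrix."""
    rng = np.random.default_rng(0)
    n = 400
    frame = pd.DataFrame(
        {
            "dominant": rng.normal(size=n),
            "weak": rng.normal(size=n),
            "constant": np.zeros(n),
        }
    )
    labels = (frame["dominant"] + 0.1 * rng.normal(size=n) > 0).astype(int)
    matrix = tr.EncodedMatrix(
        values=frame, encoding={c: {"kind": "numeric"} for c in frame}
    )
    model = tr.ModelSpec("extreme_gradient_boosting", seed=0).build()
    model.fit(matrix.to_numpy(), labels.to_numpy())
    return model, matrix


class TestGlobalAttributions:
    def test_additivity(self, trained_model):
        model, matrix = trained_model
        expl = tr.global_attributions(model, matrix)
        import xgboost as xgb

        margins = model.get_booster().predict(
            xgb.DMatrix(matrix.to_numpy()), output_margin=True
        )
        reconstructed = expl.values.sum(axis=1).to_numpy() + expl.base_value
        np.testing.assert_allclose(reconstructed, margins, atol=1e-3)

    def test_constant_feature_attributes_nothing(self, trained_model):
        model, matrix = trained_model
        expl = tr.global_attributions(model, matrix)
        assert expl.values["constant"].abs().max() < 1e-8

    def test_dominant_feature_dominates(self, trained_model):
        model, matrix = trained_model
        expl = tr.global_attributions(model, matrix)
        assert expl.mean_abs().index[0] == "dominant"

    def test_lightgbm_backend(self, trained_model):
        _, matrix = trained_model
        labels = (matrix.values["dominant"] > 0).astype(int).to_numpy()
        model = tr.ModelSpec("ordered_boosting", params={"n_estimators": 50}).build()
        model.fit(matrix.to_numpy(), labels)
        expl = tr.global_attributions(model, matrix)
        assert expl.mean_abs().index[0] == "dominant"

    def test_unsupported_backend_rejected(self, trained_model):
        _, matrix = trained_model
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression().fit(matrix.to_numpy(), matrix.values["dominant"] > 0)
        with pytest.raises(ConfigError):
            tr.global_attributions(clf, matrix)


class TestLocalExplanation:
    def test_deterministic_under_seed(self, trained_model):
        model, matrix = trained_model
        inst = matrix.to_numpy()[0]
        a = tr.local_explanation(model, inst, matrix.to_numpy(), n_perturb=200, seed=4)
        b = tr.local_explanation(model, inst, matrix.to_numpy(), n_perturb=200, seed=4)
        pd.testing.assert_series_equal(a.weights, b.weights)

    def test_dominant_feature_has_largest_weight(self, trained_model):
        model, matrix = trained_model
        inst = matrix.to_numpy()[np.argmax(matrix.values["dominant"].to_numpy())]
        expl = tr.local_explanation(model, inst, matrix.to_numpy(), n_perturb=500, seed=0)
        assert expl.weights.abs().idxmax() == "x0"  # column 0 = dominant

    def test_top_k_limits_features(self, trained_model):
        model, matrix = trained_model
        inst = matrix.to_numpy()[0]
        expl = tr.local_explanation(
            model, inst, matrix.to_numpy(), n_perturb=100, seed=0, top_k=2
        )
        assert len(expl.weights) <= 2

    def test_too_few_perturbations_rejected(self, trained_model):
        model, matrix = trained_model
        with pytest.raises(ConfigError):
            tr.local_explanation(model, matrix.to_numpy()[0], matrix.to_numpy(), n_perturb=5)


def _expl(frame):
    return tr.ExplanationSet(values=frame, base_value=0.0)


class TestKruskal:
    def test_identical_distributions_not_significant(self):
        block = np.tile(np.arange(10.0), 3)
        expl = _expl(pd.DataFrame({"f": block}))
        report = tr.kruskal_by_class(expl, np.repeat(["a", "b", "c"], 10))
        assert report.kruskal["H"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert report.kruskal["p"].iloc[0] > 0.9

    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])
        expl = _expl(pd.DataFrame({"f": vals}))
        report = tr.kruskal_by_class(expl, np.repeat(["lo", "hi"], 200))
        assert report.kruskal["p"].iloc[0] < 0.05

    def test_permuted_labels_destroy_significance(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 150), rng.normal(2, 1, 150)])
        expl = _expl(pd.DataFrame({"f": vals}))
        ps = []
        for i in range(30):
            perm = np.random.default_rng(i).permutation(np.repeat(["lo", "hi"], 150))
            ps.append(tr.kruskal_by_class(expl, perm).kruskal["p"].iloc[0])
        assert np.mean(np.array(ps) < 0.05) < 0.3

    def test_degenerate_classes_rejected(self):
        expl = _expl(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
        with pytest.raises(ConfigError):
            tr.kruskal_by_class(expl, np.array(["a", "a", "b"]))


class TestPairwiseMwu:
    def test_matches_exact_enumeration_small_groups(self):
        """The package's exact-path p equals brute-force enumeration, n <= 8."""
        rng = np.random.default_rng(3)
        for nx, ny in [(4, 4), (5, 7), (8, 8), (3, 6)]:
            x = rng.normal(size=nx)
            y = rng.normal(loc=0.8, size=ny)
            p_pkg, tied = mann_whitney_p(x, y)
            assert not tied
            assert p_pkg == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_feature_against_itself(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        expl = _expl(pd.DataFrame({"a": col, "b": col + 10}))
        report = tr.pairwise_mwu(expl)
        assert report.mwu_matrix.loc["a", "a"] == 1.0
        assert report.mwu_matrix.loc["b", "b"] == 1.0

    def test_offset_features_significant(self):
        rng = np.random.default_rng(0)
        expl = _expl(
            pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100) + 5})
        )
        report = tr.pairwise_mwu(expl)
        assert report.mwu_matrix.loc["a", "b"] < 0.05

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        expl = _expl(pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd")))
        M = tr.pairwise_mwu(expl).mwu_matrix
        np.testing.assert_array_equal(M.to_numpy(), M.to_numpy().T)
        np.testing.assert_array_equal(np.diag(M.to_numpy()), 1.0)
        assert ((M.to_numpy() >= 0) & (M.to_numpy() <= 1)).all()

    def test_constant_pair_flagged(self):
        expl = _expl(pd.DataFrame({"a": np.ones(10), "b": np.ones(10)}))
        report = tr.pairwise_mwu(expl)
        assert report.mwu_matrix.loc["a", "b"] == 1.0
        assert ("a", "b") in report.tie_flags

    def test_benjamini_hochberg_recorded_and_monotone(self):
        rng = np.random.default_rng(5)
        expl = _expl(
            pd.DataFrame(
                {"a": rng.normal(size=60), "b": rng.normal(2, 1, 60), "c": rng.normal(size=60)}
            )
        )
        raw = tr.pairwise_mwu(expl)
        adj = tr.pairwise_mwu(expl, correction="benjamini_hochberg")
        assert adj.correction == "benjamini_hochberg"
        assert (adj.mwu_matrix.to_numpy() >= raw.mwu_matrix.to_numpy() - 1e-15).all()

    def test_kw_mwu_agree_for_two_balanced_classes(self):
        """KW and MWU give the same alpha=0.05 call almost always (2 groups)."""
        agree = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(i)
            x = rng.normal(size=25)
            y = rng.normal(loc=0.6, size=25)
            p_mwu, _ = mann_whitney_p(x, y)
            _, p_kw = stats.kruskal(x, y)
            agree += (p_mwu < 0.05) == (p_kw < 0.05)
        assert agree / reps > 0.95


class TestHeatmapExport:
    def test_image_and_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        expl = _expl(pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz")))
        report = tr.pairwise_mwu(expl)
        img, csv = tr.heatmap_export(report, tmp_path / "heat.png")
        assert (tmp_path / "heat.png").exists()
        back = pd.read_csv(csv, index_col=0)
        np.testing.assert_allclose(back.to_numpy(), report.mwu_matrix.to_numpy())

    def test_color_mapping_monotone_in_p(self):
        import matplotlib

        gray = matplotlib.colormaps["gray"]
        ps = np.linspace(0, 1, 11)
        lum = [sum(gray(p)[:3]) for p in ps]
        assert all(a <= b for a, b in zip(lum, lum[1:]))
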