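"""OPLS-DA model structure, VIP normalization, and the marker screen."""

import numpy as np
import pytest
from scipy import stats

from herbdiff.chemometrics import (
    OPLSDA,
    autoscale,
    opls_da_fit,
    select_markers,
    ttest_screen,
    vip_scores,
)
from herbdiff.errors import ValidationError
from herbdiff.fingerprint import match_common_peaks
from herbdiff.simulate import GeneratorConfig, generate_sample_set


def _toy(seed=0, n=40, p=10, effect=3.0, informative=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.array(["CM"] * (n // 2) + ["CI"] * (n // 2))
    X[:, informative] += (y == "CI") * effect
    return X, y


class TestAutoscale:
    def test_idempotent_on_standardized_input(self, rng):
        X = rng.standard_normal((50, 4))
        Xs, *_ = autoscale(X)
        Xss, *_ = autoscale(Xs)
        np.testing.assert_allclose(Xss, Xs, atol=1e-10)

    def test_constant_column_flagged_and_zeroed(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        Xs, _, _, const = autoscale(X)
        assert const.tolist() == [False, True]
        np.testing.assert_allclose(Xs[:, 1], 0.0)

    def test_inverse_transform_round_trip(self, rng):
        X = rng.uniform(-5, 5, size=(30, 6))
        Xs, mean, scale, _ = autoscale(X)
        np.testing.assert_allclose(Xs * scale + mean, X, atol=1e-10)


class TestOplsDa:
    def test_informative_variable_has_largest_weight(self):
        X, y = _toy()
        m = opls_da_fit(X, y)
        assert int(np.argmax(np.abs(m.weights_))) == 3

    def test_scores_orthogonal_to_orthogonal_scores(self):
        X, y = _toy()
        m = opls_da_fit(X, y, n_ortho=2)
        for t_o in m.ortho_scores_:
            assert abs(m.scores_ @ t_o) < 1e-8

    def test_explained_fractions_in_unit_interval(self, fp_matrix):
        m = OPLSDA(random_state=0).fit(fp_matrix.areas, np.array(fp_matrix.class_labels))
        assert 0.0 <= m.r2x_ <= 1.0
        assert 0.0 <= m.r2y_ <= 1.0
        assert m.q2_ <= m.r2y_

    def test_permuted_labels_give_low_q2(self):
        X, y = _toy()
        q2s = []
        for s in range(5):
            yp = np.random.default_rng(100 + s).permutation(y)
            q2s.append(OPLSDA(random_state=s).fit(X, yp).q2_)
        assert max(q2s) < 0.2

    def test_synthetic_defaults_separate_classes(self, fp_matrix):
        y = np.array(fp_matrix.class_labels)
        m = OPLSDA(random_state=0).fit(fp_matrix.areas, y)
        assert m.q2_ > 0.5
        t = m.scores_
        assert t[y == "CM"].max() < t[y == "CI"].min() or t[y == "CI"].max() < t[y == "CM"].min()

    def test_predict_recovers_training_labels_on_separated_data(self):
        X, y = _toy(effect=5.0)
        m = opls_da_fit(X, y)
        assert (m.predict(X) == y).all()

    def test_single_class_rejected(self):
        X, _ = _toy()
        with pytest.raises(ValidationError, match="two classes"):
            opls_da_fit(X, np.array(["CM"] * len(X)))

    def test_excessive_n_ortho_rejected(self):
        X, y = _toy(n=10, p=4)
        with pytest.raises(ValidationError, match="n_ortho"):
            opls_da_fit(X, y, n_ortho=4)

    def test_deterministic_given_data_and_seed(self, fp_matrix):
        y = np.array(fp_matrix.class_labels)
        a = OPLSDA(random_state=3).fit(fp_matrix.areas, y)
        b = OPLSDA(random_state=3).fit(fp_matrix.areas, y)
        assert a.q2_ == b.q2_ and (a.weights_ == b.weights_).all()


class TestVip:
    def test_mean_squared_vip_is_one(self, fp_matrix):
        m = OPLSDA(random_state=0).fit(fp_matrix.areas, np.array(fp_matrix.class_labels))
        assert np.mean(vip_scores(m) ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_equally_informative_symmetric_design_gives_unit_vips(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(40)
        y = np.array(["CM"] * 20 + ["CI"] * 20)
        v += (y == "CI") * 2
        X = np.column_stack([v, v])  # two identical informative variables
        m = OPLSDA(n_ortho=0).fit(X, y)
        np.testing.assert_allclose(m.vip_, 1.0, atol=1e-8)

    def test_informative_variable_above_one_noise_below(self):
        X, y = _toy()
        m = opls_da_fit(X, y)
        vip = vip_scores(m)
        assert vip[3] > 1.0
        assert np.median(np.delete(vip, 3)) < 1.0


class TestTtestScreen:
    def test_identical_groups_give_p_one(self):
        X = np.tile(np.arange(6.0).reshape(-1, 1), (2, 1))
        y = np.array(["CM"] * 6 + ["CI"] * 6)
        assert ttest_screen(X, y)[0] == pytest.approx(1.0)

    def test_strong_shift_gives_tiny_p(self, rng):
        X = np.concatenate([rng.normal(0, 1, (20, 1)), rng.normal(5, 1, (20, 1))])
        y = np.array(["CM"] * 20 + ["CI"] * 20)
        assert ttest_screen(X, y)[0] < 1e-6

    def test_null_p_values_uniform(self, rng):
        # 1000 pure-noise variables in one two-group design
        X = rng.standard_normal((40, 1000))
        y = np.array(["CM"] * 20 + ["CI"] * 20)
        p = ttest_screen(X, y)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_matches_scipy_pooled_variant(self, rng):
        X = rng.standard_normal((30, 5))
        y = np.array(["CM"] * 14 + ["CI"] * 16)
        expected = stats.ttest_ind(X[y == "CM"], X[y == "CI"], axis=0, equal_var=True).pvalue
        np.testing.assert_allclose(ttest_screen(X, y), expected)


class TestSelectMarkers:
    def test_thresholds_are_strict(self):
        panel = select_markers([1.0, 2.0], [0.01, 0.05], peak_ids=[1, 2])
        assert panel.selected.tolist() == [False, False]

    def test_clear_marker_selected(self):
        panel = select_markers([2.0], [0.01], peak_ids=[7])
        assert panel.selected_ids == [7]

    @pytest.mark.parametrize("seed", range(8))
    def test_structural_markers_found_and_noise_rejected(self, seed):
        """With equal sample masses (so shared-range peaks carry no class
        signal), the structurally class-distinct peaks are selected and the
        shared-range peaks are not."""
        cfg = GeneratorConfig(seed=seed, sample_mass_g={"CM": 0.25, "CI": 0.25, "unknown": 0.25})
        tables = generate_sample_set(cfg=cfg)
        m = match_common_peaks(tables)
        y = np.array(m.class_labels)
        model = OPLSDA(random_state=seed).fit(m.areas, y)
        p = ttest_screen(m.areas, y)
        panel = select_markers(model.vip_, p, peak_ids=m.peak_ids)
        selected = set(panel.selected_ids)
        assert {11, 12, 14, 15, 16, 18} <= selected
        assert not selected & {1, 3, 4, 5, 8, 17}
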