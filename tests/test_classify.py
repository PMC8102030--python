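"""The printed discriminant and the fitted logistic marker model."""

import numpy as np
import pandas as pd
import pytest

from herbdiff.classify import (
    DEFAULT_MARKERS,
    LogisticMarkerClassifier,
    LogisticModel,
    classify_samples,
    eval_discriminant,
    fit_logistic,
    printed_discriminant,
)
from herbdiff.errors import ValidationError
from herbdiff.simulate import GeneratorConfig
from herbdiff.ssdmc import build_rrf_table, quantify_tables


class TestPrintedDiscriminant:
    def test_zero_contents_return_intercept_and_ci(self):
        model = printed_discriminant()
        y, label = eval_discriminant(model, {pid: 0.0 for pid in model.marker_ids})
        assert y == pytest.approx(14.52)
        assert label == "CI"

    def test_duplicate_terms_summed_verbatim(self):
        model = printed_discriminant("sum")
        assert model.coefficients[6] == pytest.approx(51.52 - 445.74)
        assert 15 not in model.coefficients

    def test_alternative_reading_moves_second_term_to_peak_15(self):
        model = printed_discriminant("peak15")
        assert model.coefficients[6] == pytest.approx(51.52)
        assert model.coefficients[15] == pytest.approx(-445.74)

    def test_boundary_assigned_to_ci(self):
        model = LogisticModel(14.52, {13: -53.16})
        y, label = eval_discriminant(model, {13: 14.52 / 53.16})
        assert y == pytest.approx(0.0, abs=1e-12)
        assert label == "CI"

    def test_affine_in_intercept(self):
        contents = {pid: 0.1 for pid in (6, 10, 11, 13, 16)}
        base = printed_discriminant()
        shifted = LogisticModel(base.intercept + 5.0, base.coefficients)
        assert eval_discriminant(shifted, contents)[0] - eval_discriminant(base, contents)[0] == pytest.approx(5.0)

    def test_missing_marker_named_in_error(self):
        model = printed_discriminant()
        with pytest.raises(ValidationError, match="peak 13"):
            eval_discriminant(model, {6: 0.1})

    def test_superposition(self, rng):
        model = printed_discriminant()
        ids = model.marker_ids
        a = {pid: float(v) for pid, v in zip(ids, rng.uniform(0, 1, len(ids)))}
        b = {pid: float(v) for pid, v in zip(ids, rng.uniform(0, 1, len(ids)))}
        ya = eval_discriminant(model, a)[0]
        yb = eval_discriminant(model, b)[0]
        yab = eval_discriminant(model, {pid: a[pid] + b[pid] for pid in ids})[0]
        assert yab == pytest.approx(ya + yb - model.intercept)

    def test_global_sign_flip_flips_labels(self, rng):
        model = printed_discriminant()
        flipped = LogisticModel(-model.intercept, {k: -v for k, v in model.coefficients.items()})
        contents = {pid: float(v) for pid, v in zip(model.marker_ids, rng.uniform(0, 1, 5))}
        y, label = eval_discriminant(model, contents)
        yf, labelf = eval_discriminant(flipped, contents)
        assert yf == pytest.approx(-y)
        if y != 0:
            assert {label, labelf} == {"CM", "CI"}


class TestFitting:
    def test_separated_1d_data_fit_perfectly(self):
        X = np.concatenate([np.linspace(0, 1, 10), np.linspace(3, 4, 10)]).reshape(-1, 1)
        y = np.array(["CM"] * 10 + ["CI"] * 10)
        clf = LogisticMarkerClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_cm_scores_negative(self):
        X = np.concatenate([np.linspace(0, 1, 10), np.linspace(3, 4, 10)]).reshape(-1, 1)
        y = np.array(["CM"] * 10 + ["CI"] * 10)
        clf = LogisticMarkerClassifier().fit(X, y)
        assert (clf.decision_function(X[:10]) < 0).all()

    def test_label_permutation_gives_chance_accuracy(self, rng):
        X = rng.standard_normal((80, 4))
        X[:40] += 2.0
        y = np.array(["CM"] * 40 + ["CI"] * 40)
        yp = rng.permutation(y)
        clf = LogisticMarkerClassifier().fit(X[:60], yp[:60])
        acc = (clf.predict(X[60:]) == yp[60:]).mean()
        assert 0.2 <= acc <= 0.8  # binomial CI around 50% at n=20

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((6, 2)), np.array(["CM"] * 6))

    def test_model_round_trips_through_eval(self, rng):
        X = np.vstack([rng.uniform(0, 1, (10, 3)), rng.uniform(2, 3, (10, 3))])
        y = np.array(["CM"] * 10 + ["CI"] * 10)
        clf = LogisticMarkerClassifier(marker_ids=(6, 11, 13)).fit(X, y)
        for i in range(0, 20, 5):
            score, label = eval_discriminant(clf.model_, dict(zip((6, 11, 13), X[i])))
            assert score == pytest.approx(clf.decision_function(X[[i]])[0], rel=1e-9)
            assert label == clf.predict(X[[i]])[0]


class TestClassifySamples:
    def test_empty_input_gives_empty_table(self):
        out = classify_samples(printed_discriminant(),
                               pd.DataFrame(columns=["sample_id", "peak_id", "content"]))
        assert out.empty

    def test_noiseless_cm_profiles_all_labeled_cm(self, noiseless_world):
        """End to end: generate -> quantify -> classify with a model fitted
        on the same noiseless world labels every CM sample CM."""
        registry, cfg, tables, _ = noiseless_world
        rrf_table = build_rrf_table(cfg, compounds=registry)
        quant = quantify_tables(tables, rrf_table, cfg, compounds=registry)
        labels = {t.sample_id: t.class_label for t in tables}
        quant["true_label"] = quant["sample_id"].map(labels)
        wide = quant.pivot_table(index="sample_id", columns="peak_id", values="content", sort=False)
        wide = wide.reindex(columns=list(DEFAULT_MARKERS))
        y = np.array([labels[s] for s in wide.index])
        model = fit_logistic(wide.to_numpy(), y, marker_ids=DEFAULT_MARKERS)
        out = classify_samples(model, quant)
        out = out.set_index("sample_id")
        for t in tables:
            if t.class_label == "CM":
                assert out.loc[t.sample_id, "label"] == "CM"
        assert 0.0 <= out.attrs["accuracy_pct"] <= 100.0
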