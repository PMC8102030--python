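"""Binary logistic discrimination of the two species from marker contents.

The decision statistic is affine in the marker contents (% w/w):

    Y = b0 + sum_x b_x * C_x,     Y < 0 -> CM,  Y >= 0 -> CI

Two models are provided: the published discriminant with its printed
intercept and coefficients (:func:`printed_discriminant`), and a
scikit-learn-style penalized logistic regression
(:class:`LogisticMarkerClassifier`) fitted to (synthetic) marker-content
data.  The published equation contains the term "C6" twice with different
signs; by default duplicate keys are summed, exactly as printed, and the
alternative reading (the second occurrence meaning peak 15) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .errors import ValidationError

__all__ = [
    "LogisticModel",
    "printed_discriminant",
    "eval_discriminant",
    "LogisticMarkerClassifier",
    "fit_logistic",
    "classify_samples",
]

#: Marker peaks used when fitting our own discriminant: the six distinct
#: quantified markers.
DEFAULT_MARKERS = (6, 10, 11, 13, 15, 16)


@dataclass(frozen=True)
class LogisticModel:
    """Intercept plus per-marker-peak coefficients (per % w/w content)."""

    intercept: float
    coefficients: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for pid in self.coefficients:
            if not 1 <= int(pid) <= 18:
                raise ValidationError(f"coefficient key {pid} is not a peak id in 1..18")

    @property
    def marker_ids(self) -> list[int]:
        return sorted(self.coefficients)


#: Terms of the published equation, in printed order: (peak, coefficient).
#: The peak-6 key appears twice, as printed.
_PRINTED_TERMS = ((13, -53.16), (6, 51.52), (11, -313.09), (6, -445.74), (16, 109.94), (10, 26.33))
_PRINTED_INTERCEPT = 14.52


def printed_discriminant(duplicate_handling: str = "sum") -> LogisticModel:
    """The published six-term discriminant.

    ``duplicate_handling="sum"`` (default) keeps the equation verbatim and
    sums the two peak-6 coefficients; ``"peak15"`` reads the second C6 term
    as peak 15 (the reading suggested by the six-distinct-marker list).
    """
    coeffs: dict[int, float] = {}
    for i, (pid, coef) in enumerate(_PRINTED_TERMS):
        if duplicate_handling == "peak15" and i == 3:
            pid = 15
        elif duplicate_handling != "sum" and duplicate_handling != "peak15":
            raise ValidationError(f"unknown duplicate_handling {duplicate_handling!r}")
        coeffs[pid] = coeffs.get(pid, 0.0) + coef
    return LogisticModel(_PRINTED_INTERCEPT, coeffs)


def eval_discriminant(model: LogisticModel, contents: Mapping[int, float]) -> tuple[float, str]:
    """Evaluate Y = intercept + sum(coef * content) and apply the sign rule.

    Every marker in the model must be present in ``contents`` (a missing
    marker is an error naming it).  Negative Y labels the sample CM; the
    boundary Y = 0 goes to CI (zero is not negative).
    """
    y = model.intercept
    for pid, coef in model.coefficients.items():
        if pid not in contents:
            raise ValidationError(f"missing content for marker peak {pid}")
        y += coef * float(contents[pid])
    return y, ("CM" if y < 0 else "CI")


class LogisticMarkerClassifier(BaseEstimator, ClassifierMixin):
    """Penalized maximum-likelihood logistic regression on raw contents.

    Contents are standardized internally and an L2 penalty of strength
    ``penalty_lambda`` (default 1e-4) is applied on the standardized scale
    — perfectly separated classes otherwise push the unpenalized MLE to
    infinity.  Reported coefficients are back-transformed to the raw
    %-w/w scale, with the sign convention arranged so CM scores negative.

    Attributes
    ----------
    classes_ : ``array(["CM", "CI"])`` (CI is the positive class).
    intercept_, coef_ : raw-scale discriminant parameters.
    model_ : the equivalent :class:`LogisticModel`.
    """

    def __init__(self, penalty_lambda: float = 1e-4, marker_ids: tuple | None = None,
                 max_iter: int = 1000):
        self.penalty_lambda = penalty_lambda
        self.marker_ids = marker_ids
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D samples x markers matrix")
        labels = set(np.unique(y))
        if len(labels) < 2:
            raise ValidationError("need two classes to fit the discriminant")
        if not labels <= {"CM", "CI"}:
            raise ValidationError(f"labels must be CM/CI, got {sorted(labels)}")
        counts = {lab: int((y == lab).sum()) for lab in ("CM", "CI")}
        if min(counts.values()) < 3:
            raise ValidationError(f"each class needs >= 3 samples, got {counts}")
        self.classes_ = np.array(["CM", "CI"])
        y01 = (y == "CI").astype(int)

        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd <= 1e-12, 1.0, sd)
        Xs = (X - mean) / sd
        if self.penalty_lambda <= 0:
            raise ValidationError("penalty_lambda must be positive")
        lr = LogisticRegression(C=1.0 / self.penalty_lambda, max_iter=self.max_iter)
        lr.fit(Xs, y01)

        w = lr.coef_.ravel() / sd
        b = float(lr.intercept_[0] - (lr.coef_.ravel() * mean / sd).sum())
        self.coef_ = w
        self.intercept_ = b
        ids = self.marker_ids if self.marker_ids is not None else tuple(range(1, X.shape[1] + 1))
        if len(ids) != X.shape[1]:
            raise ValidationError("marker_ids length does not match number of columns")
        self.model_ = LogisticModel(b, {int(pid): float(c) for pid, c in zip(ids, w)})
        return self

    def decision_function(self, X):
        if not hasattr(self, "coef_"):
            raise ValidationError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])


def fit_logistic(contents_matrix, labels, marker_ids: tuple | None = None,
                 penalty_lambda: float = 1e-4) -> LogisticModel:
    """Functional wrapper: fit the penalized model, return its LogisticModel."""
    clf = LogisticMarkerClassifier(penalty_lambda=penalty_lambda, marker_ids=marker_ids)
    clf.fit(contents_matrix, labels)
    return clf.model_


def classify_samples(model: LogisticModel, quant: pd.DataFrame) -> pd.DataFrame:
    """Score and label each sample from a long quantification table.

    ``quant`` needs columns sample_id, peak_id and content (as produced by
    the quantification stage); a true_label column, when present, is
    carried through and an ``accuracy_pct`` attribute is attached to the
    result (``result.attrs["accuracy_pct"]``).
    """
    required = {"sample_id", "peak_id", "content"}
    if not required <= set(quant.columns):
        raise ValidationError(f"quant table needs columns {sorted(required)}")
    if quant.empty:
        return pd.DataFrame(columns=["sample_id", "score", "label"])
    wide = quant.pivot_table(index="sample_id", columns="peak_id", values="content", sort=False)
    rows = []
    for sample_id, contents in wide.iterrows():
        score, label = eval_discriminant(model, contents.dropna().to_dict())
        rows.append((sample_id, score, label))
    out = pd.DataFrame(rows, columns=["sample_id", "score", "label"])
    if "true_label" in quant.columns:
        truth = quant.drop_duplicates("sample_id").set_index("sample_id")["true_label"]
        out["true_label"] = out["sample_id"].map(truth)
        known = out["true_label"].isin(["CM", "CI"])
        if known.any():
            acc = 100.0 * float((out.loc[known, "label"] == out.loc[known, "true_label"]).mean())
            out.attrs["accuracy_pct"] = acc
    return out
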