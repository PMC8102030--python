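"""Common-peak matching, mean-reference chromatogram and similarity scores.

Herbal-fingerprint quality control compares each sample's common-peak area
vector against a mean reference chromatogram using the angle cosine and/or
Pearson correlation coefficient of the original data.  This module matches
sample peaks onto the 18-slot common-peak template by retention time,
stacks them into a samples x peaks matrix (unmatched peaks are 0), and
scores similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import PEAK_COMPOUNDS
from .errors import ValidationError
from .io import PeakTable

__all__ = [
    "FingerprintMatrix",
    "match_common_peaks",
    "reference_chromatogram",
    "similarity",
    "similarity_table",
]


@dataclass
class FingerprintMatrix:
    """Samples x common-peaks area matrix with sample metadata."""

    sample_ids: list[str]
    class_labels: list[str]
    peak_ids: list[int]
    areas: np.ndarray          # shape (n_samples, n_peaks)

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.peak_ids)):
            raise ValidationError("area matrix shape does not match sample/peak id lists")

    def rpa(self, reference_peak: int = 2) -> np.ndarray:
        """Relative peak areas: each area divided by the reference peak's
        area within the same sample (chlorogenic acid, peak 2, by default)."""
        if reference_peak not in self.peak_ids:
            raise ValidationError(f"reference peak {reference_peak} not in matrix")
        j = self.peak_ids.index(reference_peak)
        ref = self.areas[:, j]
        if np.any(ref <= 0):
            bad = self.sample_ids[int(np.argmax(ref <= 0))]
            raise ValidationError(f"sample {bad!r}: reference peak {reference_peak} has zero area")
        return self.areas / ref[:, None]


def match_common_peaks(
    tables: list[PeakTable],
    rt_tolerance: float = 0.1,
    template: dict[int, float] | None = None,
) -> FingerprintMatrix:
    """Match sample peaks to the common-peak template by retention time.

    A sample peak matches template slot ``k`` when ``|rt - rt_k| <=
    rt_tolerance``; a peak within tolerance of several slots goes to the
    nearest one.  Two distinct peaks landing in the same slot is an
    ambiguity error naming the sample.  Unmatched slots get area 0.
    """
    if not tables:
        raise ValidationError("no peak tables to match")
    if rt_tolerance <= 0:
        raise ValidationError("rt_tolerance must be positive")
    if template is None:
        template = {pid: spec.nominal_rt for pid, spec in PEAK_COMPOUNDS.items()}
    peak_ids = sorted(template)
    slot_rts = np.array([template[pid] for pid in peak_ids])

    areas = np.zeros((len(tables), len(peak_ids)))
    for i, table in enumerate(tables):
        claimed: dict[int, float] = {}
        for p in table.peaks:
            deltas = np.abs(slot_rts - p.rt)
            j = int(np.argmin(deltas))
            if deltas[j] > rt_tolerance:
                continue  # no common-peak slot for this peak
            if j in claimed:
                raise ValidationError(
                    f"sample {table.sample_id!r}: two peaks match common peak "
                    f"{peak_ids[j]} within {rt_tolerance} min"
                )
            claimed[j] = p.area
            areas[i, j] = p.area
    return FingerprintMatrix(
        [t.sample_id for t in tables], [t.class_label for t in tables], peak_ids, areas
    )


def reference_chromatogram(matrix: FingerprintMatrix) -> np.ndarray:
    """Mean chromatogram: arithmetic column mean of the area matrix."""
    if matrix.areas.shape[0] < 1:
        raise ValidationError("need at least one sample")
    return matrix.areas.mean(axis=0)


def similarity(x, ref, method: str = "cosine") -> float:
    """Similarity of two common-peak area vectors.

    ``cosine`` is x.ref/(|x||ref|); ``correlation`` is the Pearson
    coefficient.  Both lie in [-1, 1] and equal 1 for identical vectors.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("similarity needs two equal-length vectors of length >= 2")
    if method == "cosine":
        nx, nr = np.linalg.norm(x), np.linalg.norm(ref)
        if nx == 0 or nr == 0:
            raise ValidationError("cosine similarity undefined for an all-zero vector")
        return float(np.clip(x @ ref / (nx * nr), -1.0, 1.0))
    if method == "correlation":
        if np.ptp(x) == 0 or np.ptp(ref) == 0:
            raise ValidationError("correlation undefined for a constant vector")
        return float(np.clip(np.corrcoef(x, ref)[0, 1], -1.0, 1.0))
    raise ValidationError(f"unknown similarity method {method!r}")


def similarity_table(
    matrix: FingerprintMatrix,
    method: str = "cosine",
    use_rpa: bool = False,
    reference_peak: int = 2,
) -> pd.DataFrame:
    """Score every sample against the pooled mean chromatogram.

    Returns a DataFrame with sample_id, class_label and similarity.
    """
    data = matrix.rpa(reference_peak) if use_rpa else matrix.areas
    ref = data.mean(axis=0)
    scores = [similarity(row, ref, method=method) for row in data]
    return pd.DataFrame(
        {"sample_id": matrix.sample_ids, "class_label": matrix.class_labels, "similarity": scores}
    )
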