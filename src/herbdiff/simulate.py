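"""Synthetic chromatographic data with the structure the analysis assumes.

The generator emulates the study design: two-class 18-common-peak HPLC
fingerprints (53 *C. morifolium* = CM and 33 *C. indicum* = CI batches),
seven-level two-fold serial-dilution calibration series on two instruments,
spike-recovery samples at 75/100/125% of the native amount, and blank
injections for signal-to-noise work.

Per sample and peak, a true content (% w/w) is drawn uniformly from the
class range, converted to a solution concentration through the fixed sample
preparation (0.25 g CM / 0.5 g CI powder extracted into 25 ml), and to a
detector area through the compound's calibration slope (response through
the origin); measured areas get multiplicative Gaussian noise with a fixed
CV and retention times get Gaussian jitter.  CI fingerprints lack peaks 11,
12, 14, 15 and 16 and are enriched in peak 18 (linarin); class content
ranges reproduce the published class totals (see docs/methods.md for which
per-peak splits are assumptions).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compounds import PEAK_COMPOUNDS, CompoundSpec
from .errors import ValidationError
from .io import CalibrationSeries, Peak, PeakTable

__all__ = [
    "GeneratorConfig",
    "ClassProfile",
    "default_profiles",
    "generate_calibration_series",
    "generate_sample_set",
    "spike_sample",
    "generate_blank_areas",
    "content_to_conc",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_cm: int = 53                       # CM batches
    n_ci: int = 33                       # CI batches
    area_cv: float = 0.01                # relative SD of multiplicative area noise
    rt_jitter_sd: float = 0.02           # min
    baseline_sd: float = 20.0            # detector units; blank-injection noise
    n_levels: int = 7                    # calibration levels (2-fold dilution)
    extraction_volume_ml: float = 25.0
    sample_mass_g: dict = field(default_factory=lambda: {"CM": 0.25, "CI": 0.5, "unknown": 0.25})
    instrument_ids: tuple = ("Shimadzu-20A", "Agilent-1260")
    #: per-instrument multiplicative detector-response factor
    instrument_response: dict = field(default_factory=lambda: {"Shimadzu-20A": 1.0, "Agilent-1260": 1.01})
    #: peaks whose content is drawn log-uniformly instead of uniformly
    log_uniform_peaks: tuple = ()

    def __post_init__(self):
        if self.n_cm < 0 or self.n_ci < 0:
            raise ValidationError("sample counts must be non-negative")
        if self.area_cv < 0 or self.rt_jitter_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("noise parameters must be non-negative")
        if self.n_levels < 2:
            raise ValidationError("need at least 2 calibration levels")


@dataclass
class ClassProfile:
    """Per-peak content range (% w/w) for one class; absent peaks omitted."""

    label: str
    ranges: dict[int, tuple[float, float]]

    def __post_init__(self):
        for pid, (low, high) in self.ranges.items():
            if not 1 <= pid <= 18:
                raise ValidationError(f"profile {self.label}: peak_id {pid} outside 1..18")
            if low < 0 or high < low:
                raise ValidationError(f"profile {self.label}, peak {pid}: need 0 <= low <= high")

    @property
    def present(self) -> set[int]:
        return set(self.ranges)


# Ranges shared by both classes for the minor, non-discriminating peaks.
_COMMON = {1: (0.02, 0.20), 3: (0.02, 0.20), 4: (0.01, 0.15),
           5: (0.02, 0.15), 8: (0.01, 0.10), 17: (0.01, 0.10)}


def default_profiles() -> dict[str, ClassProfile]:
    """Default class content profiles.

    Per-peak ranges are chosen so that their low/high sums reproduce the
    published class totals: four caffeoylquinic acids (peaks 2, 9, 10, 13)
    0.684-3.445% (CM) vs 0.166-2.112% (CI); six flavone glycosides (peaks
    6, 7, 11, 15, 16, 18) 0.315-4.161% (CM) vs 0.144-2.078% (CI); linarin
    (peak 18) mean 0.636% in CI, about six-fold its CM mean.  CI lacks
    peaks 11, 12, 14, 15 and 16 entirely.
    """
    cm = {
        **_COMMON,
        12: (0.01, 0.10), 14: (0.01, 0.10),
        # caffeoylquinic acids: totals 0.684-3.445
        2: (0.30, 1.50), 9: (0.084, 0.345), 10: (0.20, 1.00), 13: (0.10, 0.60),
        # flavone glycosides: totals 0.315-4.161, linarin mean 0.106
        6: (0.10, 1.50), 7: (0.05, 0.80), 11: (0.06, 0.90),
        15: (0.03, 0.40), 16: (0.015, 0.409), 18: (0.06, 0.152),
    }
    ci = {
        **_COMMON,
        # caffeoylquinic acids: totals 0.166-2.112
        2: (0.07, 0.90), 9: (0.016, 0.212), 10: (0.05, 0.60), 13: (0.03, 0.40),
        # flavone glycosides: totals 0.144-2.078, linarin mean 0.636
        6: (0.03, 0.60), 7: (0.014, 0.306), 18: (0.10, 1.172),
    }
    return {"CM": ClassProfile("CM", cm), "CI": ClassProfile("CI", ci)}


def content_to_conc(content_pct: float, sample_mass_g: float, volume_ml: float = 25.0) -> float:
    """Convert % w/w content in the powder to ug/ml in the extract."""
    return content_pct / 100.0 * sample_mass_g * 1e6 / volume_ml


def generate_calibration_series(
    spec: CompoundSpec,
    cfg: GeneratorConfig,
    n_levels: int | None = None,
    instrument_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> CalibrationSeries:
    """Simulate a two-fold serial-dilution calibration series.

    Concentrations run down from the stock; areas follow the compound's
    calibration line (times the instrument response factor) with
    multiplicative Gaussian noise of CV ``cfg.area_cv``.
    """
    n_levels = cfg.n_levels if n_levels is None else n_levels
    if n_levels < 2:
        raise ValidationError("need at least 2 calibration levels")
    if spec.stock_conc is None:
        raise ValidationError(f"{spec.name}: no stock concentration; cannot build a dilution series")
    instrument_id = instrument_id or cfg.instrument_ids[0]
    response = cfg.instrument_response.get(instrument_id, 1.0)
    if rng is None:
        rng = np.random.default_rng([cfg.seed, spec.peak_id, abs(hash(instrument_id)) % 2**31])
    concs = spec.stock_conc * 1000.0 / 2.0 ** np.arange(n_levels)   # ug/ml
    areas = (spec.calib_slope * concs + spec.calib_intercept) * response
    if cfg.area_cv > 0:
        areas = areas * (1.0 + cfg.area_cv * rng.standard_normal(n_levels))
    levels = [(float(c), float(a)) for c, a in zip(concs, areas)]
    return CalibrationSeries(spec.name, instrument_id, levels)


def generate_sample_set(
    profiles: dict[str, ClassProfile] | None = None,
    cfg: GeneratorConfig | None = None,
    compounds: dict[int, CompoundSpec] | None = None,
    return_truth: bool = False,
):
    """Draw a two-class synthetic sample set.

    Returns a list of :class:`PeakTable` (CM samples first), and, when
    ``return_truth`` is set, also a DataFrame of the generating per-peak
    contents (% w/w) and solution concentrations (ug/ml).
    """
    profiles = profiles if profiles is not None else default_profiles()
    cfg = cfg if cfg is not None else GeneratorConfig()
    compounds = compounds if compounds is not None else PEAK_COMPOUNDS
    rng = np.random.default_rng([cfg.seed, 0x5A11])

    tables: list[PeakTable] = []
    truth_rows = []
    plan = [("CM", i) for i in range(cfg.n_cm)] + [("CI", i) for i in range(cfg.n_ci)]
    for label, i in plan:
        profile = profiles[label]
        mass = cfg.sample_mass_g[label]
        sample_id = f"{label}{i + 1:02d}"
        peaks = []
        for pid in sorted(compounds):
            spec = compounds[pid]
            if pid in profile.ranges:
                low, high = profile.ranges[pid]
                if pid in cfg.log_uniform_peaks and low > 0:
                    content = float(np.exp(rng.uniform(np.log(low), np.log(high))))
                else:
                    content = float(rng.uniform(low, high))
                conc = content_to_conc(content, mass, cfg.extraction_volume_ml)
                area = spec.calib_slope * conc
                if cfg.area_cv > 0:
                    area *= 1.0 + cfg.area_cv * rng.standard_normal()
                area = max(area, 0.0)
            else:
                content, conc, area = 0.0, 0.0, 0.0
            rt = spec.nominal_rt
            if cfg.rt_jitter_sd > 0:
                rt += rng.normal(0.0, cfg.rt_jitter_sd)
            peaks.append(Peak(pid, float(rt), float(area)))
            truth_rows.append((sample_id, label, pid, content, conc))
        tables.append(PeakTable(sample_id, label, peaks))

    if return_truth:
        truth = pd.DataFrame(
            truth_rows, columns=["sample_id", "class_label", "peak_id", "content_pct", "conc_ug_ml"]
        )
        return tables, truth
    return tables


def spike_sample(
    table: PeakTable,
    compound: CompoundSpec,
    level: float,
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PeakTable, float]:
    """Add a known amount of ``compound`` at ``level`` x the native amount.

    The spiked area is native + level * native response; the re-measured
    total carries fresh multiplicative noise when ``cfg.area_cv > 0``.
    Returns the spiked table and the added amount in ug/ml (the recovery
    bookkeeping quantity).
    """
    if level <= 0:
        raise ValidationError("spike level must be positive")
    if not table.has_peak(compound.peak_id) or table.peak(compound.peak_id).area <= 0:
        raise ValidationError(
            f"sample {table.sample_id!r}: peak {compound.peak_id} ({compound.name}) absent; cannot spike"
        )
    native = table.peak(compound.peak_id)
    added_area = level * native.area
    total = native.area + added_area
    if cfg is not None and cfg.area_cv > 0:
        if rng is None:
            rng = np.random.default_rng([cfg.seed, 0x59C3, compound.peak_id])
        total *= 1.0 + cfg.area_cv * rng.standard_normal()
    added_ug_ml = added_area / compound.calib_slope
    peaks = [
        p if p.peak_id != compound.peak_id else Peak(p.peak_id, p.rt, float(max(total, 0.0)))
        for p in table.peaks
    ]
    spiked = PeakTable(f"{table.sample_id}+{int(round(level * 100))}%", table.class_label, peaks)
    return spiked, float(added_ug_ml)


def generate_blank_areas(cfg: GeneratorConfig, n: int = 20, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulated blank-injection baseline areas (zero-mean Gaussian)."""
    if n < 2:
        raise ValidationError("need at least 2 blank injections")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 0xB1A])
    return rng.normal(0.0, cfg.baseline_sd, size=n)
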