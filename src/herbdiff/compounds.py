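"""Reference-compound metadata for the 18 common fingerprint peaks.

The fingerprint of *C. morifolium* / *C. indicum* flower extracts is built
from 18 common HPLC peaks (327 nm, 65-min gradient).  Fourteen are
identified caffeoylquinic acids and flavone glycosides; four are recurring
but unidentified.  Each peak carries a :class:`CompoundSpec` with its
molecular formula, nominal molecular weight Mr (g/mol), nominal retention
time on the reference gradient, the detector calibration line
``area = slope * conc + intercept`` (conc in ug/ml) where a standard was
available, and the stock concentration of the standard solution (mg/ml).

Calibration slopes/intercepts and stock concentrations for the seven
calibrated compounds are the published method values; compounds quantified
through relative response factors carry slopes consistent with their RRF
relative to the internal reference of their compound class.  Unidentified
peaks get a generic response so that synthetic chromatograms are complete.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import yaml

from .errors import ValidationError
from .masspec import parse_formula

__all__ = [
    "CompoundSpec",
    "PEAK_COMPOUNDS",
    "COMPOUND_CLASSES",
    "REFERENCE_PEAK_BY_CLASS",
    "compound_by_name",
    "zero_intercept_registry",
    "load_compounds",
    "save_compounds",
]

COMPOUND_CLASSES = ("caffeoylquinic_acid", "flavone_glycoside", "other")

#: Internal reference peak for each quantified compound class: chlorogenic
#: acid (peak 2) for the caffeoylquinic acids, luteolin-7-O-glucoside
#: (peak 6) for the flavone glycosides.
REFERENCE_PEAK_BY_CLASS = {"caffeoylquinic_acid": 2, "flavone_glycoside": 6}

#: Generic detector response (area per ug/ml) for peaks with no standard.
GENERIC_SLOPE = 2.5e4


@dataclass(frozen=True)
class CompoundSpec:
    """Identity, chromatographic and calibration metadata for one peak."""

    name: str
    peak_id: int
    compound_class: str
    nominal_rt: float            # min
    mr: float                    # nominal molecular weight, g/mol
    formula: str | None = None   # molecular formula, e.g. "C16H18O9"
    calib_slope: float = GENERIC_SLOPE   # detector area per (ug/ml)
    calib_intercept: float = 0.0         # detector area
    stock_conc: float | None = None      # mg/ml of the standard stock

    def __post_init__(self):
        if self.mr <= 0:
            raise ValidationError(f"{self.name}: Mr must be positive")
        if self.nominal_rt <= 0:
            raise ValidationError(f"{self.name}: retention time must be positive")
        if self.calib_slope <= 0:
            raise ValidationError(f"{self.name}: calibration slope must be positive")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(f"{self.name}: unknown compound class {self.compound_class!r}")
        if not 1 <= self.peak_id <= 18:
            raise ValidationError(f"{self.name}: peak_id must be in 1..18")
        if self.formula is not None:
            parse_formula(self.formula)  # raises on invalid formulas


def _c(name, peak_id, cls, rt, mr, formula=None, slope=GENERIC_SLOPE, intercept=0.0, stock=None):
    return CompoundSpec(name, peak_id, cls, rt, mr, formula, slope, intercept, stock)


# Peaks 8, 12, 14 and 17 recur in the fingerprint but are unidentified; they
# carry a nominal Mr and a generic response.  Slopes of the three flavones
# quantified by MW-extrapolated RRFs are slope(reference)/RRF so that the
# synthetic truth is self-consistent with the published RRF values.
PEAK_COMPOUNDS: dict[int, CompoundSpec] = {
    1: _c("neochlorogenic acid", 1, "caffeoylquinic_acid", 7.03, 354.3, "C16H18O9"),
    2: _c("chlorogenic acid", 2, "caffeoylquinic_acid", 9.89, 354.3, "C16H18O9",
          slope=2.564e4, intercept=5.208e3, stock=0.1782),
    3: _c("cryptochlorogenic acid", 3, "caffeoylquinic_acid", 10.24, 354.3, "C16H18O9"),
    4: _c("caffeic acid", 4, "other", 12.14, 180.2, "C9H8O4"),
    5: _c("luteolin-7-O-rutinoside", 5, "flavone_glycoside", 18.86, 594.5, "C27H30O15"),
    6: _c("luteolin-7-O-glucoside", 6, "flavone_glycoside", 20.45, 448.3, "C21H20O11",
          slope=2.628e4, intercept=7.102e3, stock=0.1110),
    7: _c("luteolin-7-O-glucuronide", 7, "flavone_glycoside", 21.13, 462.3, "C21H18O12",
          slope=2.628e4 / 1.03),
    8: _c("unknown-8", 8, "other", 22.60, 300.0),
    9: _c("isochlorogenic acid B", 9, "caffeoylquinic_acid", 23.96, 516.4, "C25H24O12",
          slope=2.006e4, intercept=0.745e3, stock=0.1234),
    10: _c("isochlorogenic acid A", 10, "caffeoylquinic_acid", 26.28, 516.4, "C25H24O12",
           slope=2.756e4, intercept=1.954e3, stock=0.1882),
    11: _c("apigenin-7-O-glucoside", 11, "flavone_glycoside", 29.01, 432.8, "C21H20O10",
           slope=2.918e4, intercept=3.478e3, stock=0.1338),
    12: _c("unknown-12", 12, "other", 30.70, 300.0),
    13: _c("isochlorogenic acid C", 13, "caffeoylquinic_acid", 32.22, 516.4, "C25H24O12",
           slope=3.129e4, intercept=0.973e3, stock=0.1122),
    14: _c("unknown-14", 14, "other", 35.20, 300.0),
    15: _c("diosmetin-7-O-glucoside", 15, "flavone_glycoside", 38.12, 462.3, "C22H22O11",
           slope=2.628e4 / 1.03),
    # slope chained through the MW-extrapolation rule from the measured
    # apigenin-7-O-glucoside RRF (slope ratio 2.628/2.918 = 0.9006,
    # extrapolated by 518.1/432.8 and reported at 2 decimals -> 1.08), so
    # extrapolated quantification is exact on noiseless synthetic data
    16: _c("apigenin-7-O-6''-malonylglucoside", 16, "flavone_glycoside", 45.96, 518.1, "C24H22O13",
           slope=2.628e4 / 1.08),
    17: _c("unknown-17", 17, "other", 49.00, 300.0),
    18: _c("linarin", 18, "flavone_glycoside", 52.45, 592.6, "C28H32O14",
           slope=1.918e4, intercept=7.238e3, stock=0.2458),
}


def compound_by_name(name: str, registry: dict[int, CompoundSpec] | None = None) -> CompoundSpec:
    registry = registry if registry is not None else PEAK_COMPOUNDS
    for spec in registry.values():
        if spec.name == name:
            return spec
    raise KeyError(name)


def zero_intercept_registry(registry: dict[int, CompoundSpec] | None = None) -> dict[int, CompoundSpec]:
    """Copy of a registry with all calibration intercepts forced to zero.

    Single-standard quantification assumes a proportional detector response;
    this variant makes SSDMC and external-standard quantification exactly
    equivalent on noiseless data.
    """
    registry = registry if registry is not None else PEAK_COMPOUNDS
    return {pid: replace(spec, calib_intercept=0.0) for pid, spec in registry.items()}


def save_compounds(registry: dict[int, CompoundSpec], path) -> None:
    """Write a compound registry as a YAML config keyed by compound name."""
    data = {
        spec.name: {
            "peak_id": spec.peak_id,
            "compound_class": spec.compound_class,
            "nominal_rt": spec.nominal_rt,
            "mr": spec.mr,
            "formula": spec.formula,
            "calib_slope": spec.calib_slope,
            "calib_intercept": spec.calib_intercept,
            "stock_conc": spec.stock_conc,
        }
        for spec in registry.values()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_compounds(path) -> dict[int, CompoundSpec]:
    """Read a compound registry written by :func:`save_compounds`."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    registry: dict[int, CompoundSpec] = {}
    for name, fields in data.items():
        spec = CompoundSpec(
            name=name,
            peak_id=int(fields["peak_id"]),
            compound_class=fields["compound_class"],
            nominal_rt=float(fields["nominal_rt"]),
            mr=float(fields["mr"]),
            formula=fields.get("formula"),
            calib_slope=float(fields.get("calib_slope", GENERIC_SLOPE)),
            calib_intercept=float(fields.get("calib_intercept", 0.0)),
            stock_conc=None if fields.get("stock_conc") is None else float(fields["stock_conc"]),
        )
        if spec.peak_id in registry:
            raise ValidationError(f"duplicate peak_id {spec.peak_id} in {path}")
        registry[spec.peak_id] = spec
    return dict(sorted(registry.items()))
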