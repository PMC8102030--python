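"""End-to-end workflow: simulate -> fingerprint -> screen -> quantify -> classify.

Each stage reads its inputs from and writes its outputs to a run
directory as CSV, so stages can be toggled off and resumed from previous
outputs.  A config echo written at the start makes every run reproducible;
all randomness derives from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import chemometrics, classify, fingerprint, ssdmc
from .compounds import PEAK_COMPOUNDS
from .errors import ValidationError
from .io import read_peak_table, write_calibration, write_peak_table
from .simulate import GeneratorConfig, default_profiles, generate_calibration_series, generate_sample_set

logger = logging.getLogger("herbdiff")

ALL_STAGES = ("simulate", "fingerprint", "screen", "rrf", "quantify", "classify")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; fully serializable."""

    outdir: str = "herbdiff-run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    rt_tolerance: float = 0.1          # min, common-peak matching window
    similarity_method: str = "cosine"
    use_rpa: bool = True               # screen on relative peak areas
    n_ortho: int = 1
    vip_threshold: float = 1.0
    alpha: float = 0.05
    marker_peaks: tuple = classify.DEFAULT_MARKERS
    holdout_fraction: float = 0.5
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s) {sorted(unknown)}")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        # one seed to rule the run: the generator inherits it
        self.generator.seed = self.seed

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        data["stages"] = tuple(data.get("stages", ALL_STAGES))
        if "marker_peaks" in data:
            data["marker_peaks"] = tuple(data["marker_peaks"])
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the staged workflow and return the machine-readable summary.

    Stage outputs (all CSV) land in ``cfg.outdir``; stages not listed in
    ``cfg.stages`` are skipped and their outputs read from earlier runs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_echo.yaml")
    summary: dict = {"seed": cfg.seed}
    gen = cfg.generator

    # -- simulate ----------------------------------------------------------
    tables_path = out / "peak_tables.csv"
    if "simulate" in cfg.stages:
        tables, truth = generate_sample_set(default_profiles(), gen, return_truth=True)
        write_peak_table(tables, tables_path)
        truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
        calib = [
            generate_calibration_series(PEAK_COMPOUNDS[pid], gen, instrument_id=inst)
            for pid in (2, 6, 9, 10, 11, 13, 18)
            for inst in gen.instrument_ids
        ]
        write_calibration(calib, out / "calibration.csv")
        logger.info("simulate: %d samples, %d calibration series", len(tables), len(calib))
    else:
        tables = read_peak_table(tables_path)
    summary["n_samples"] = len(tables)
    labels = np.array([t.class_label for t in tables])

    # -- fingerprint -------------------------------------------------------
    matrix = fingerprint.match_common_peaks(tables, rt_tolerance=cfg.rt_tolerance)
    summary["n_common_peaks"] = len(matrix.peak_ids)
    if "fingerprint" in cfg.stages:
        sim = fingerprint.similarity_table(matrix, method=cfg.similarity_method)
        sim.to_csv(out / "similarity.csv", index=False, float_format="%.6g")
        by_class = sim.groupby("class_label")["similarity"].mean().to_dict()
        summary["mean_similarity"] = {k: round(v, 4) for k, v in by_class.items()}
        logger.info("fingerprint: similarity written for %d samples", len(sim))

    # -- screen ------------------------------------------------------------
    if "screen" in cfg.stages:
        X = matrix.rpa() if cfg.use_rpa else matrix.areas
        model = chemometrics.OPLSDA(n_ortho=cfg.n_ortho, random_state=cfg.seed).fit(X, labels)
        p = chemometrics.ttest_screen(X, labels)
        panel = chemometrics.select_markers(
            model.vip_, p, peak_ids=matrix.peak_ids,
            vip_threshold=cfg.vip_threshold, alpha=cfg.alpha,
        )
        pd.DataFrame({
            "peak_id": panel.peak_ids, "vip": panel.vip, "p": panel.p, "selected": panel.selected,
        }).to_csv(out / "markers.csv", index=False, float_format="%.6g")
        summary["opls"] = {"r2x": round(model.r2x_, 4), "r2y": round(model.r2y_, 4),
                           "q2": round(model.q2_, 4)}
        summary["selected_markers"] = panel.selected_ids
        logger.info("screen: %d/%d peaks selected, q2=%.3f",
                    len(panel.selected_ids), len(panel.peak_ids), model.q2_)

    # -- rrf ---------------------------------------------------------------
    rrf_table = ssdmc.build_rrf_table(gen)
    if "rrf" in cfg.stages:
        pd.DataFrame([
            {"peak_id": pid, "analyte": e.analyte, "reference": e.reference,
             "rrf": round(e.rrf, 2), "rrt": round(e.rrt, 2), "n_levels": e.n_levels,
             "instrument_id": e.instrument_id}
            for pid, e in sorted(rrf_table.items())
        ]).to_csv(out / "rrf.csv", index=False)
        logger.info("rrf: %d entries", len(rrf_table))

    # -- quantify ----------------------------------------------------------
    quant_path = out / "quant.csv"
    if "quantify" in cfg.stages:
        quant = ssdmc.quantify_tables(tables, rrf_table, gen)
        label_map = {t.sample_id: t.class_label for t in tables}
        quant["true_label"] = quant["sample_id"].map(label_map)
        quant.to_csv(quant_path, index=False, float_format="%.8g")
        logger.info("quantify: %d results", len(quant))
    else:
        quant = pd.read_csv(quant_path)
    summary["n_quant_results"] = len(quant)

    # -- classify ----------------------------------------------------------
    if "classify" in cfg.stages:
        wide = quant.pivot_table(index="sample_id", columns="peak_id", values="content", sort=False)
        wide = wide.reindex(columns=list(cfg.marker_peaks))
        y = quant.drop_duplicates("sample_id").set_index("sample_id")["true_label"].loc[wide.index]
        X = wide.to_numpy()
        idx = np.arange(len(wide))
        train, test = train_test_split(
            idx, test_size=cfg.holdout_fraction, stratify=y, random_state=cfg.seed
        )
        clf = classify.LogisticMarkerClassifier(marker_ids=tuple(cfg.marker_peaks))
        clf.fit(X[train], y.to_numpy()[train])
        holdout_acc = 100.0 * float((clf.predict(X[test]) == y.to_numpy()[test]).mean())
        resub_acc = 100.0 * float((clf.predict(X[train]) == y.to_numpy()[train]).mean())
        scores = clf.decision_function(X)
        result = pd.DataFrame({
            "sample_id": wide.index, "score": scores,
            "label": clf.classes_[(scores >= 0).astype(int)],
            "true_label": y.to_numpy(),
            "split": np.where(np.isin(idx, train), "train", "holdout"),
        })
        result.to_csv(out / "classification.csv", index=False, float_format="%.6g")
        summary["holdout_accuracy_pct"] = holdout_acc
        summary["resubstitution_accuracy_pct"] = resub_acc
        summary["fitted_model"] = {
            "intercept": round(clf.intercept_, 4),
            "coefficients": {int(k): round(v, 4) for k, v in clf.model_.coefficients.items()},
        }
        logger.info("classify: holdout accuracy %.1f%%", holdout_acc)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        for key, value in summary.items():
            fh.write(f"{key}: {value}\n")
    return summary
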