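"""End-to-end orchestration: phantom cohort -> enhancement -> segmentation
-> texture features -> selection -> classifier report.

A single top-level seed deterministically derives per-stage seeds, so one
number reproduces every artifact bit-for-bit. Stage parameters are echoed
into a JSON run-config for provenance, and skipped/failed cases are logged
with their ids.
"""

from __future__ import annotations

import ast
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify_eval, phantom, preprocess, segment, texture
from .mias_io import MammogramRecord, records_to_csv

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "stage_seeds", "extract_feature_table", "run_all"]


@dataclass
class RunConfig:
    seed: int = 0
    # phantom cohort
    n_normal: int = 20
    n_benign: int = 10
    n_malign: int = 10
    size: int = 256
    contrast_low: int = 60
    contrast_high: int = 100
    noise_gaussian_sd: float = 2.0
    noise_salt_pepper_p: float = 0.0
    # enhancement
    combos: tuple[str, ...] = tuple(preprocess.COMBOS)
    median_kernel: int = 3
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    usm_radius: float = 2.0
    usm_amount: float = 1.0
    morph_radius: int = 5
    # segmentation / ROI
    k: int = 3
    patch_size: int = 64
    # texture
    ng: int = 8
    d: int = 1
    # selection / evaluation
    selection_mode: str = "corr"  # corr | preset | none
    selection_threshold: float = 0.90
    train_fraction: float = 0.70
    tasks: tuple[str, ...] = ("normal_abnormal", "benign_malign")
    classifiers: tuple[str, ...] = classify_eval.CLASSIFIERS
    out_dir: str = "mammotex_run"

    def filter_params(self) -> preprocess.FilterParams:
        return preprocess.FilterParams(
            median_kernel=self.median_kernel,
            clahe_clip=self.clahe_clip,
            clahe_tiles=(self.clahe_tiles, self.clahe_tiles),
            usm_radius=self.usm_radius,
            usm_amount=self.usm_amount,
            morph_radius=self.morph_radius,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` text file; lists given comma-separated."""
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if "," in value:
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            else:
                try:
                    kwargs[key] = ast.literal_eval(value)
                except (ValueError, SyntaxError):
                    kwargs[key] = value
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Collect invariant violations; an empty list means the config is ok."""
    v = []
    if min(config.n_normal, config.n_benign, config.n_malign) < 0:
        v.append("cohort counts must be non-negative")
    if config.size < 32:
        v.append("image size must be >= 32")
    if not 0 < config.selection_threshold <= 1:
        v.append("correlation threshold must be in (0,1]")
    if not 0 < config.train_fraction < 1:
        v.append("train_fraction must be in (0,1)")
    if config.ng < 2:
        v.append("ng must be >= 2")
    if config.d < 1:
        v.append("d must be >= 1")
    if config.k < 2:
        v.append("k must be >= 2")
    if config.patch_size < 8:
        v.append("patch_size must be >= 8")
    if not 0 <= config.noise_salt_pepper_p <= 1:
        v.append("noise_salt_pepper_p must be in [0,1]")
    for combo in config.combos:
        if combo.upper().replace("&", "_") not in preprocess.COMBOS:
            v.append(f"unknown combo {combo!r}")
    for name in config.classifiers:
        if name not in classify_eval.CLASSIFIERS:
            v.append(f"unknown classifier {name!r}")
    for task in config.tasks:
        if task not in ("normal_abnormal", "benign_malign"):
            v.append(f"unknown task {task!r}")
    v.extend(config.filter_params().violations())
    return v


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive per-stage seeds from the top-level seed (kept below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def extract_feature_table(
    cohort: list[tuple[MammogramRecord, dict]],
    combo: str,
    fp: preprocess.FilterParams,
    k: int = 3,
    patch_size: int = 64,
    ng: int = 8,
    d: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Run enhancement -> segmentation -> texture for one combination.

    Returns one row per case (id, tissue_class, severity, then the 33
    features). Cases failing any stage are skipped with a log entry.
    """
    rows = []
    for record, _masks in cohort:
        try:
            stripped, breast_mask = preprocess.remove_label(record.image, fp)
            enhanced = preprocess.apply_combo(stripped, combo, fp)
            enhanced = np.where(breast_mask, enhanced, 0).astype(np.uint8)
            model = segment.kmeans_segment(enhanced, k=k, seed=seed)
            cleaned, pect = segment.remove_pectoral(model, enhanced, record.laterality)
            roi = segment.extract_roi(
                record, cleaned, model, patch_size, breast_mask=breast_mask & ~pect
            )
            feats = texture.roi_features(roi, d=d, levels=ng)
        except (segment.MissingGeometryError, texture.DegenerateROIError, ValueError) as exc:
            log.warning("%s [%s]: skipped (%s)", record.id, combo, exc)
            continue
        rows.append(
            {"id": record.id, "tissue_class": record.tissue_class,
             "severity": record.severity or "", **feats}
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> Path:
    """Execute the full study and write the artifact directory.

    Artifacts: cohort PGMs + metadata, per-combo features CSV, selection
    JSON, per-task report CSV in the benchmark table shape
    (classifier x combination x metrics), AUC plot data and figure, and a
    line-per-event log.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mammotex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        seeds = stage_seeds(config.seed)
        (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=list))

        log.info("generating cohort: %d normal / %d benign / %d malign, size %d",
                 config.n_normal, config.n_benign, config.n_malign, config.size)
        cohort = phantom.generate_cohort(
            config.n_normal, config.n_benign, config.n_malign,
            seed=seeds[0], size=config.size,
            contrast_range=(config.contrast_low, config.contrast_high),
            noise_gaussian_sd=config.noise_gaussian_sd,
            noise_salt_pepper_p=config.noise_salt_pepper_p,
        )
        phantom.save_cohort(cohort, out / "cohort", write_masks=False)
        records_to_csv([r for r, _ in cohort], out / "cohort" / "records.csv")

        fp = config.filter_params()
        tables: dict[str, pd.DataFrame] = {}
        for combo in config.combos:
            key = combo.upper().replace("&", "_")
            log.info("extracting features under %s", key)
            tab = extract_feature_table(
                cohort, key, fp, k=config.k, patch_size=config.patch_size,
                ng=config.ng, d=config.d, seed=seeds[1],
            )
            tab.to_csv(out / f"features_{key}.csv", index=False)
            tables[key] = tab

        for task in config.tasks:
            report, plot_data = classify_eval.run_experiment(
                tables, task=task, classifiers=config.classifiers,
                seed=seeds[2], selection_mode=config.selection_mode,
                selection_threshold=config.selection_threshold,
                train_fraction=config.train_fraction,
            )
            report.to_csv(out / f"report_{task}.csv", index=False)
            plot_data.to_csv(out / f"auc_{task}.csv")
            classify_eval.plot_auc_comparison(plot_data, out / f"auc_{task}.png")
            log.info("task %s: %d report rows", task, len(report))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
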