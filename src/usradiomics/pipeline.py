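"""End-to-end orchestration: simulate -> extract -> select -> train the
three ensemble models under nested CV -> pick the best by internal ROC-AUC
-> external test -> univariate statistics -> report files.

One global seed fans out deterministically to named substreams (cohort
generation, CV folds, ADASYN/ensemble fitting), so re-running with the same
config reproduces every table byte-for-byte; stage outputs are
content-hashed into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CohortConfig, external_config, generate_cohort, write_cohort
from .prep import PrepConfig, read_image, read_mask, read_labels
from .filters import FILTER_KINDS, FilterSpec
from .features import TextureConfig, extract_table, feature_schema
from .selection import SelectionConfig, run_selection
from .modeling import AdasynConfig, EnsembleSpec, ENSEMBLE_KINDS
from .evaluation import (
    NestedCVResult,
    export_reports,
    external_test,
    make_cv_plan,
    run_nested_cv,
    reorient_external,
    select_best_model,
    univariate_feature_stats,
)

logger = logging.getLogger("usradiomics")

# named substreams of the global seed
_STREAMS = ("cohort_train", "cohort_external", "cv", "models")


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STREAMS))
    return {
        name: int(child.generate_state(1, np.uint32)[0] % (2**31 - 1))
        for name, child in zip(_STREAMS, children)
    }


@dataclass
class RunConfig:
    """Flat, documented configuration for a full study run."""

    seed: int = 0
    out_dir: str = "run"
    train_cohort: CohortConfig = field(default_factory=CohortConfig)
    external_cohort_overrides: dict = field(default_factory=dict)
    prep: PrepConfig = field(default_factory=PrepConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    adasyn: AdasynConfig = field(default_factory=AdasynConfig)
    models: tuple[str, ...] = ENSEMBLE_KINDS
    filters: tuple[str, ...] = FILTER_KINDS  # the extraction filter bank
    log_sigma_mm: float = 1.0
    positive_class: str = "malignant"
    write_images: bool = False  # cohort PNG/CSV export is optional

    def filter_bank(self) -> list[FilterSpec]:
        return [FilterSpec(kind=k, log_sigma_mm=self.log_sigma_mm)
                for k in self.filters]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        kw = dict(raw)
        if "train_cohort" in kw:
            kw["train_cohort"] = CohortConfig(**kw["train_cohort"])
        for key, klass in (
            ("prep", PrepConfig), ("texture", TextureConfig),
            ("selection", SelectionConfig), ("adasyn", AdasynConfig),
        ):
            if key in kw:
                kw[key] = klass(**kw[key])
        for key in ("models", "filters"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def cohort_tables(
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate both cohorts and extract their feature tables."""
    seeds = derive_seeds(cfg.seed)
    train_cc = CohortConfig(**{**asdict(cfg.train_cohort),
                               "seed": seeds["cohort_train"]})
    ext_over = dict(cfg.external_cohort_overrides)
    for key in ("image_height", "image_width", "pixel_spacing_mm", "speckle_shape",
                "roi_axes_range", "malignant_focus_rate", "focus_radius_range",
                "focus_intensity_factor", "malignant_speckle_contrast", "bit_depth"):
        ext_over.setdefault(key, getattr(cfg.train_cohort, key))
    ext_cc = external_config(seed=seeds["cohort_external"], **ext_over)
    train_cases = generate_cohort(train_cc)
    ext_cases = generate_cohort(ext_cc)
    filters = cfg.filter_bank()
    t0 = time.time()
    train_tab = extract_table(train_cases, cfg.prep, filters, cfg.texture)
    ext_tab = extract_table(ext_cases, cfg.prep, filters, cfg.texture)
    logger.info("feature extraction: %.1fs for %d cases",
                time.time() - t0, len(train_cases) + len(ext_cases))
    if cfg.write_images:
        out = Path(cfg.out_dir)
        write_cohort(train_cases, out / "cohort_train", train_cc)
        write_cohort(ext_cases, out / "cohort_external", ext_cc)
    return train_tab, ext_tab


def load_cohort_tables(
    images_dir: str | Path, cfg: RunConfig
) -> pd.DataFrame:
    """Extract features for a user-provided cohort directory
    (images/, masks/, labels.csv) instead of simulating one."""
    from .synth import SyntheticCase

    root = Path(images_dir)
    labels = read_labels(root / "labels.csv")
    cases = []
    for _, row in labels.iterrows():
        img_path = next(p for p in (root / "images").glob(f"{row.case_id}.*")
                        if p.suffix.lower() in {".png", ".tif", ".tiff"})
        cases.append(SyntheticCase(
            case_id=row.case_id, label=row.label,
            split=row.get("split", "train_internal"),
            image=read_image(img_path),
            mask=read_mask(root / "masks" / f"{row.case_id}.png"),
        ))
    return extract_table(cases, cfg.prep, cfg.filter_bank(), cfg.texture)


def run_all(
    cfg: RunConfig,
    train_table: pd.DataFrame | None = None,
    external_table: pd.DataFrame | None = None,
) -> dict:
    """Run the full study; returns a dict with all in-memory results and
    writes report files under ``cfg.out_dir``.

    Pre-extracted feature tables may be supplied to skip simulation
    (``--skip-simulate`` flow); downstream behaviour is identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg.seed)
    if train_table is None or external_table is None:
        sim_train, sim_ext = cohort_tables(cfg)
        train_table = train_table if train_table is not None else sim_train
        external_table = external_table if external_table is not None else sim_ext

    y_train = train_table["label"].to_numpy()
    selected, sel_report = run_selection(train_table, y_train, cfg.selection)
    sel_report.write(out / "selection_report.csv", out / "selection_report.json")
    sel_cols = [c for c in selected.columns if c not in ("case_id", "label")]
    ext_selected = external_table[[c for c in external_table.columns
                                   if c in ("case_id", "label")] + sel_cols]

    plan = make_cv_plan(y_train, seed=seeds["cv"])
    model_rng = np.random.default_rng(seeds["models"])
    cv_results: dict[str, NestedCVResult] = {}
    for kind in cfg.models:
        spec = EnsembleSpec(kind=kind)
        cv_results[kind] = run_nested_cv(
            selected, y_train, spec, plan, cfg.adasyn,
            positive_class=cfg.positive_class,
            seed=int(model_rng.integers(2**31 - 1)),
        )
        logger.info("model %s internal mean ROC-AUC %.1f", kind,
                    cv_results[kind].internal_mean.values.get("roc_auc", np.nan))
    best = select_best_model(cv_results)
    y_ext = ext_selected["label"].to_numpy()
    ext_metrics = external_test(
        cv_results[best].all_ensembles(), ext_selected, y_ext, cfg.positive_class,
    )
    # the same external predictions in the opposite orientation (sensitivity
    # toward the other class), so both confusion-matrix readings are on file
    other = "benign" if cfg.positive_class == "malignant" else "malignant"
    ext_metrics_flipped = reorient_external(
        cv_results[best].all_ensembles(), ext_selected, y_ext,
        positive_class=other, negative_class=cfg.positive_class,
    )
    stats = univariate_feature_stats(selected, y_train, sel_cols,
                                     positive_class=cfg.positive_class)
    manifest = {
        "config": {
            "seed": cfg.seed, "models": list(cfg.models),
            "filters": list(cfg.filters), "log_sigma_mm": cfg.log_sigma_mm,
            "positive_class": cfg.positive_class,
            "train_cohort": asdict(cfg.train_cohort),
            "prep": asdict(cfg.prep), "texture": {
                "glcm_distance": cfg.texture.glcm_distance,
                "ngldm_alpha": cfg.texture.ngldm_alpha,
            },
            "selection": asdict(cfg.selection),
            "adasyn": {"beta": cfg.adasyn.beta, "k_neighbors": cfg.adasyn.k_neighbors},
            "ensemble_defaults": asdict(EnsembleSpec()),
        },
        "derived_seeds": seeds,
        "n_selected_features": len(sel_cols),
        "best_model": best,
        "hashes": {
            "train_features": _hash_frame(train_table),
            "external_features": _hash_frame(external_table),
            "selected_features": _hash_frame(selected),
        },
    }
    export_reports(
        out, cv_results=cv_results, external=[ext_metrics, ext_metrics_flipped],
        best_model=best, univariate=stats, table=selected, labels=y_train,
        manifest=manifest,
    )
    (out / "features_train.csv").write_text(train_table.to_csv(index=False))
    (out / "features_external.csv").write_text(external_table.to_csv(index=False))
    (out / "feature_schema.json").write_text(
        json.dumps(feature_schema(train_table), indent=2)
    )
    return {
        "train_table": train_table, "external_table": external_table,
        "selected": selected, "selection_report": sel_report, "plan": plan,
        "cv_results": cv_results, "best_model": best,
        "external_metrics": ext_metrics, "univariate": stats,
        "manifest": manifest, "out_dir": out,
    }
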