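"""Two-step univariate feature screen: variance filter then a mutual
information (MI) screen against the binary class label.

Step 1 drops features whose unbiased sample variance (raw scale) falls below
``variance_threshold`` — a near-constancy screen. Step 2 discretizes each
surviving feature into equal-frequency bins, computes the plug-in MI with
the class label in nats, and keeps features with MI at or above
``mi_threshold`` (default 0.19): the surviving features are the ones most
informative about the label. The opposite, literal reading (dropping
high-MI features) is available via ``drop_high_mi`` for completeness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SelectionConfig:
    variance_threshold: float = 0.1
    mi_threshold: float = 0.19
    mi_bins: int = 10  # equal-frequency
    drop_high_mi: bool = False

    def __post_init__(self) -> None:
        if self.variance_threshold < 0 or self.mi_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


@dataclass
class SelectionReport:
    """Per-feature variance, MI estimate, kept/dropped flag and drop reason."""

    rows: list[dict] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return [r["feature"] for r in self.rows if r["kept"]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(Path(csv_path), index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.rows, indent=2))


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("case_id", "label")]


def feature_variances(table: pd.DataFrame) -> pd.Series:
    """Unbiased (ddof=1) sample variance per feature column."""
    cols = _feature_columns(table)
    return table[cols].var(ddof=1)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into (up to) n_bins equal-frequency bins; duplicate
    quantile edges collapse, so fewer effective bins are possible."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in MI (nats) between an equal-frequency-binned feature and a
    discrete label."""
    xb = _equal_frequency_bins(np.asarray(x, float), n_bins)
    _, xi = np.unique(xb, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def variance_filter(table: pd.DataFrame, cfg: SelectionConfig | None = None) -> SelectionReport:
    cfg = cfg or SelectionConfig()
    if len(table) < 2:
        raise ValueError("variance filter requires >= 2 cases")
    variances = feature_variances(table)
    report = SelectionReport()
    for feat, v in variances.items():
        kept = bool(v >= cfg.variance_threshold)
        report.rows.append({
            "feature": feat,
            "variance": float(v),
            "mi": None,
            "kept": kept,
            "drop_reason": None if kept else "low_variance",
        })
    return report


def mutual_information_filter(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    cfg: SelectionConfig | None = None,
    features: list[str] | None = None,
) -> SelectionReport:
    cfg = cfg or SelectionConfig()
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        warnings.warn("single-class labels: MI screen is a no-op")
        return SelectionReport()
    n_bins = cfg.mi_bins
    if len(table) < n_bins:
        n_bins = max(2, len(table) // 2)
        warnings.warn(f"fewer cases than MI bins; reduced to {n_bins}")
    feats = features if features is not None else _feature_columns(table)
    report = SelectionReport()
    for feat in feats:
        mi = mutual_information(table[feat].to_numpy(), y, n_bins)
        informative = mi >= cfg.mi_threshold
        kept = (not informative) if cfg.drop_high_mi else informative
        reason = None if kept else ("high_mi" if cfg.drop_high_mi else "low_mi")
        report.rows.append({
            "feature": feat, "variance": None, "mi": float(mi),
            "kept": kept, "drop_reason": reason,
        })
    return report


def run_selection(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    cfg: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Variance screen then MI screen; surviving column order preserved.

    Deterministic given the table; raises if no feature survives.
    """
    cfg = cfg or SelectionConfig()
    var_rep = variance_filter(table, cfg)
    var_kept = set(var_rep.kept)
    ordered = [c for c in _feature_columns(table) if c in var_kept]
    mi_rep = mutual_information_filter(table, labels, cfg, features=ordered)
    mi_map = {r["feature"]: r for r in mi_rep.rows}
    report = SelectionReport()
    for row in var_rep.rows:
        feat = row["feature"]
        if not row["kept"]:
            report.rows.append(row)
            continue
        mi_row = mi_map.get(feat)
        if mi_row is None:  # degenerate single-class labels
            report.rows.append(row)
            continue
        report.rows.append({
            "feature": feat, "variance": row["variance"], "mi": mi_row["mi"],
            "kept": mi_row["kept"], "drop_reason": mi_row["drop_reason"],
        })
    survivors = [c for c in ordered if mi_map.get(c, {"kept": True})["kept"]]
    if not survivors:
        raise ValueError(
            "no features survived selection; lower variance_threshold or mi_threshold"
        )
    keep_cols = [c for c in table.columns if c in ("case_id", "label")] + survivors
    return table[keep_cols].copy(), report
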