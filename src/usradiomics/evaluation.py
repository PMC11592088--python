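"""Nested 4-fold cross-validation, the six performance metrics with 95% CIs,
one-sided Wilcoxon signed-rank tests versus chance, model selection by
internal-test ROC-AUC, external testing, and univariate Mann-Whitney
statistics with Bonferroni-Holm adjustment.

CV structure: 4 stratified folds; 4 rotations, each with two folds for
training, one for validation and one for internal testing, so every fold is
the internal-test fold exactly once. ADASYN rebalancing and all ensemble
preprocessing are fitted inside each rotation on the training folds only.

Two internal-testing summaries are reported, mirroring how ensemble studies
print their tables: the *mean* over the 64 member x rotation metric values
(with normal-approximation CIs and a one-sided Wilcoxon signed-rank test of
those 64 values against the chance level), and the *majority vote* metrics
of the pooled per-case predictions (each case predicted by the one rotation
whose test fold contains it).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .modeling import (
    AdasynConfig,
    EnsembleSpec,
    PredictionSet,
    TrainedEnsemble,
    adasyn_oversample,
    fit_ensemble,
    predict,
)

METRICS = ("roc_auc", "accuracy", "sensitivity", "specificity", "ppv", "npv")

#: chance levels (percent) for the one-sided Wilcoxon tests; PPV/NPV nulls
#: are the benign/malignant prevalences of the study design (72% / 28%).
DEFAULT_NULL_LEVELS = {
    "roc_auc": 50.0, "accuracy": 50.0, "sensitivity": 50.0,
    "specificity": 50.0, "ppv": 72.0, "npv": 28.0,
}


@dataclass
class CVPlan:
    """4 stratified folds + 4 rotations (train 2 / validation 1 / test 1)."""

    folds: list[np.ndarray]
    rotations: list[dict]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(labels, seed: int = 0, n_folds: int = 4) -> CVPlan:
    """Stratified fold assignment; rotation r tests fold r, validates fold
    (r+1) mod 4 and trains on the remaining two. Deterministic given seed."""
    y = np.asarray(labels)
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError("too few cases for the fold plan")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("class too small to stratify")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(n), y)]
    rotations = []
    for r in range(n_folds):
        val = (r + 1) % n_folds
        train = [f for f in range(n_folds) if f not in (r, val)]
        rotations.append({"train": train, "validation": val, "test": r})
    return CVPlan(folds=folds, rotations=rotations, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (0.0, 100.0)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (100 * max(0.0, centre - half), 100 * min(1.0, centre + half))


def _auc_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley-McNeil standard error for the AUC."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    se = np.sqrt(
        (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2))
        / (n_pos * n_neg)
    )
    return (100 * max(0.0, a - 1.96 * se), 100 * min(1.0, a + 1.96 * se))


@dataclass
class MetricSet:
    """The six metrics (percent) with 95% CIs and optional p-values."""

    stage: str
    values: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def as_rows(self, model: str = "") -> list[dict]:
        rows = []
        for m in METRICS:
            if m not in self.values:
                continue
            lo, hi = self.ci.get(m, (np.nan, np.nan))
            rows.append({
                "model": model, "stage": self.stage, "metric": m,
                "value": self.values[m], "ci_low": lo, "ci_high": hi,
                "p_value": self.p_values.get(m, np.nan), "n": self.n,
            })
        return rows


def compute_metrics(
    y_true,
    y_pred,
    y_score=None,
    positive_class: str = "malignant",
    stage: str = "",
    ci: bool = True,
) -> MetricSet:
    """Confusion-matrix metrics plus rank-based ROC-AUC (ties averaged),
    on the percent scale. Proportion CIs are Wilson score intervals; the
    AUC CI uses the Hanley-McNeil normal approximation."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = positive_class
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    n = len(y_true)
    n_pos, n_neg = tp + fn, tn + fp
    values: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}

    def prop(name: str, k: int, d: int) -> None:
        if d == 0:
            return
        values[name] = 100.0 * k / d
        if ci:
            cis[name] = _wilson_ci(k, d)

    prop("accuracy", tp + tn, n)
    prop("sensitivity", tp, n_pos)
    prop("specificity", tn, n_neg)
    prop("ppv", tp, tp + fp)
    prop("npv", tn, tn + fn)
    if y_score is not None and n_pos > 0 and n_neg > 0:
        auc = roc_auc_score((y_true == pos).astype(int), np.asarray(y_score))
        values["roc_auc"] = 100.0 * auc
        if ci:
            cis["roc_auc"] = _auc_ci(auc, n_pos, n_neg)
    elif y_score is not None:
        warnings.warn("single-class truth: ROC-AUC undefined")
    return MetricSet(stage=stage, values=values, ci=cis, n=n)


def wilcoxon_vs_chance(
    metric_samples, null_level: float, alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p-value of metric samples against a
    chance level. Exact for small tie-free samples, normal approximation
    with tie correction otherwise; all-zero differences give p = 1."""
    d = np.asarray(metric_samples, dtype=float) - null_level
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    if len(d) < 5:
        warnings.warn("fewer than 5 non-zero differences; p-value unstable")
    method = "exact" if (len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass
class RotationResult:
    rotation: int
    ensemble: TrainedEnsemble
    metrics: dict[str, MetricSet]  # training / validation / internal_test
    member_metrics: pd.DataFrame  # one row per member, internal-test fold
    test_index: np.ndarray
    test_predictions: PredictionSet
    roc_points: pd.DataFrame


@dataclass
class NestedCVResult:
    model_kind: str
    rotations: list[RotationResult]
    internal_mean: MetricSet
    internal_majority: MetricSet
    stage_means: dict[str, MetricSet]

    def all_ensembles(self) -> list[TrainedEnsemble]:
        return [r.ensemble for r in self.rotations]


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in table.columns if c not in ("case_id", "label")]
    return table[cols].to_numpy(dtype=float), cols


def run_nested_cv(
    table: pd.DataFrame,
    labels,
    spec: EnsembleSpec,
    plan: CVPlan,
    adasyn_cfg: AdasynConfig | None = None,
    positive_class: str = "malignant",
    seed: int = 0,
    null_levels: dict[str, float] | None = None,
) -> NestedCVResult:
    """Per rotation: ADASYN on the two training folds only, fit the
    ensemble, evaluate on training / validation / internal-test folds.

    ``internal_mean`` averages the 64 member x rotation internal-test metric
    values and carries Wilcoxon p-values against chance; ``internal_majority``
    scores the pooled per-case majority-vote predictions.
    """
    y = np.asarray(labels)
    X, cols = _feature_matrix(table)
    if any(len(f) > len(y) for f in plan.folds):
        raise ValueError("plan/table mismatch")
    adasyn_cfg = adasyn_cfg or AdasynConfig()
    null_levels = null_levels or DEFAULT_NULL_LEVELS
    rng = np.random.default_rng(seed)
    rotations: list[RotationResult] = []
    pooled_idx: list[np.ndarray] = []
    pooled_pred: list[PredictionSet] = []
    for rot in plan.rotations:
        train_idx = np.concatenate([plan.folds[f] for f in rot["train"]])
        val_idx = plan.folds[rot["validation"]]
        test_idx = plan.folds[rot["test"]]
        a_cfg = AdasynConfig(
            beta=adasyn_cfg.beta, k_neighbors=adasyn_cfg.k_neighbors,
            seed=int(rng.integers(2**31 - 1)),
        )
        Xb, yb = adasyn_oversample(X[train_idx], y[train_idx], a_cfg)
        ens = fit_ensemble(
            Xb, yb, spec, seed=int(rng.integers(2**31 - 1)),
            feature_names=cols, positive_class=positive_class,
        )
        stage_sets: dict[str, MetricSet] = {}
        preds = {}
        for stage, idx in (("training", train_idx), ("validation", val_idx),
                           ("internal_test", test_idx)):
            p = predict(ens, X[idx], columns=cols)
            preds[stage] = p
            stage_sets[stage] = compute_metrics(
                y[idx], p.labels, p.score, positive_class, stage=stage
            )
        member_rows = []
        Zt = ens._transform(X[test_idx])
        from .modeling import _member_scores

        for mi, member in enumerate(ens.members):
            mp = member.predict(Zt)
            ms = _member_scores(ens, member, Zt)
            mset = compute_metrics(y[test_idx], mp, ms, positive_class, ci=False)
            member_rows.append({"rotation": rot["test"], "member": mi, **mset.values})
        fpr, tpr, _ = roc_curve(
            (y[test_idx] == positive_class).astype(int), preds["internal_test"].score
        )
        rotations.append(RotationResult(
            rotation=rot["test"], ensemble=ens, metrics=stage_sets,
            member_metrics=pd.DataFrame(member_rows), test_index=test_idx,
            test_predictions=preds["internal_test"],
            roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        ))
        pooled_idx.append(test_idx)
        pooled_pred.append(preds["internal_test"])

    member_df = pd.concat([r.member_metrics for r in rotations], ignore_index=True)
    mean_values, mean_ci, mean_p = {}, {}, {}
    for m in METRICS:
        if m not in member_df.columns:
            continue
        vals = member_df[m].dropna().to_numpy()
        if len(vals) == 0:
            continue
        mean_values[m] = float(vals.mean())
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        mean_ci[m] = (mean_values[m] - 1.96 * se, mean_values[m] + 1.96 * se)
        mean_p[m] = wilcoxon_vs_chance(vals, null_levels[m])
    internal_mean = MetricSet("internal_mean", mean_values, mean_ci, mean_p,
                              n=len(member_df))

    all_idx = np.concatenate(pooled_idx)
    all_pred = np.concatenate([p.labels for p in pooled_pred])
    all_score = np.concatenate([p.score for p in pooled_pred])
    internal_majority = compute_metrics(
        y[all_idx], all_pred, all_score, positive_class, stage="internal_majority"
    )

    stage_means: dict[str, MetricSet] = {}
    for stage in ("training", "validation"):
        vals = {}
        for m in METRICS:
            per_rot = [r.metrics[stage].values[m] for r in rotations
                       if m in r.metrics[stage].values]
            if per_rot:
                vals[m] = float(np.mean(per_rot))
        stage_means[stage] = MetricSet(stage, vals, n=len(y))
    return NestedCVResult(
        model_kind=spec.kind, rotations=rotations,
        internal_mean=internal_mean, internal_majority=internal_majority,
        stage_means=stage_means,
    )


def select_best_model(results: dict[str, NestedCVResult]) -> str:
    """Argmax of internal-test mean ROC-AUC; ties break by majority-vote
    ROC-AUC, then by model order."""
    if not results:
        raise ValueError("no models to select from")
    kinds = list(results)
    key = lambda k: (
        results[k].internal_mean.values.get("roc_auc", -1.0),
        results[k].internal_majority.values.get("roc_auc", -1.0),
        -kinds.index(k),
    )
    return max(kinds, key=key)


def external_predictions(
    ensembles: list[TrainedEnsemble],
    external_table: pd.DataFrame,
    positive_class: str = "malignant",
    negative_class: str = "benign",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled majority vote of all rotation ensembles (4 x 16 = 64 members):
    (hard labels, pooled vote fraction, mean score). The tie rule follows the
    ensembles' positive class regardless of reporting orientation."""
    preds = [predict(e, external_table) for e in ensembles]
    frac = np.mean([p.vote_fraction for p in preds], axis=0)
    score = np.mean([p.score for p in preds], axis=0)
    hard = np.where(frac >= 0.5, positive_class, negative_class)
    return hard, frac, score


def external_test(
    ensembles: list[TrainedEnsemble],
    external_table: pd.DataFrame,
    labels,
    positive_class: str = "malignant",
) -> MetricSet:
    """Pooled majority vote of all rotation ensembles on every external
    case, scored with ``positive_class`` as the positive label."""
    y = np.asarray(labels)
    neg = [c for c in np.unique(y) if c != positive_class]
    neg = neg[0] if neg else "benign"
    hard, _, score = external_predictions(ensembles, external_table,
                                          positive_class, neg)
    return compute_metrics(y, hard, score, positive_class, stage="external")


def reorient_external(
    ensembles: list[TrainedEnsemble],
    external_table: pd.DataFrame,
    labels,
    positive_class: str,
    negative_class: str,
) -> MetricSet:
    """The same pooled external predictions scored with the opposite class
    as positive (sensitivity/specificity and PPV/NPV swap roles)."""
    y = np.asarray(labels)
    hard, _, score = external_predictions(ensembles, external_table,
                                          negative_class, positive_class)
    m = compute_metrics(y, hard, 1.0 - score, positive_class,
                        stage=f"external_{positive_class}_positive")
    return m


# ---------------------------------------------------------------------------
# univariate feature statistics
# ---------------------------------------------------------------------------

def median_ci(x: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    """Distribution-free 95% CI for the median from binomial order
    statistics."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 3:
        return (x[0], x[-1])
    alpha = 1 - conf
    lo = int(stats.binom.ppf(alpha / 2, n, 0.5))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, 0.5))
    lo = max(lo, 0)
    hi = min(hi, n - 1)
    return (float(x[lo]), float(x[hi]))


@dataclass
class UnivariateStat:
    feature: str
    median_benign: float
    median_benign_ci: tuple[float, float]
    median_malignant: float
    median_malignant_ci: tuple[float, float]
    u_statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    stars: str = ""


def univariate_feature_stats(
    table: pd.DataFrame,
    labels,
    features: list[str] | None = None,
    positive_class: str = "malignant",
) -> list[UnivariateStat]:
    """Per-feature class medians with order-statistic 95% CIs, two-sided
    Mann-Whitney U test (exact for small tie-free samples), Holm step-down
    adjustment across the feature set, and significance stars at 0.05 (*)
    and 0.005 (**). Results are sorted by adjusted p."""
    y = np.asarray(labels)
    feats = features if features is not None else [
        c for c in table.columns if c not in ("case_id", "label")
    ]
    if len(feats) == 0:
        warnings.warn("empty feature set: no univariate statistics")
        return []
    out: list[UnivariateStat] = []
    for f in feats:
        x = table[f].to_numpy(dtype=float)
        a = x[y != positive_class]  # benign
        b = x[y == positive_class]  # malignant
        if np.all(x == x[0]):
            u, p = float(len(a) * len(b)) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        out.append(UnivariateStat(
            feature=f,
            median_benign=float(np.median(a)), median_benign_ci=median_ci(a),
            median_malignant=float(np.median(b)), median_malignant_ci=median_ci(b),
            u_statistic=u, p_raw=p,
        ))
    adj = multipletests([s.p_raw for s in out], method="holm")[1]
    for s, pa in zip(out, adj):
        s.p_adjusted = float(pa)
        s.stars = "**" if pa < 0.005 else ("*" if pa < 0.05 else "")
    out.sort(key=lambda s: (s.p_adjusted, s.p_raw, s.feature))
    return out


def univariate_frame(statrows: list[UnivariateStat]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": s.feature,
        "median_benign": s.median_benign,
        "median_benign_ci_low": s.median_benign_ci[0],
        "median_benign_ci_high": s.median_benign_ci[1],
        "median_malignant": s.median_malignant,
        "median_malignant_ci_low": s.median_malignant_ci[0],
        "median_malignant_ci_high": s.median_malignant_ci[1],
        "u_statistic": s.u_statistic,
        "p_raw": s.p_raw,
        "p_adjusted": s.p_adjusted,
        "stars": s.stars,
    } for s in statrows])


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

def export_reports(
    out_dir: str | Path,
    cv_results: dict[str, NestedCVResult] | None = None,
    external: MetricSet | None = None,
    best_model: str | None = None,
    univariate: list[UnivariateStat] | None = None,
    table: pd.DataFrame | None = None,
    labels=None,
    manifest: dict | None = None,
) -> Path:
    """Write the run's report files: metric tables (CSV + JSON), univariate
    statistics, per-feature per-class value dumps (violin/box-plot data) and
    per-rotation ROC curve coordinates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    if cv_results:
        for kind, res in cv_results.items():
            for stage, mset in res.stage_means.items():
                rows.extend(mset.as_rows(model=kind))
            rows.extend(res.internal_mean.as_rows(model=kind))
            rows.extend(res.internal_majority.as_rows(model=kind))
            roc = []
            for r in res.rotations:
                df = r.roc_points.copy()
                df.insert(0, "rotation", r.rotation)
                roc.append(df)
            pd.concat(roc, ignore_index=True).to_csv(
                out / f"roc_{kind}.csv", index=False
            )
    if external is not None:
        ext_list = external if isinstance(external, (list, tuple)) else [external]
        for e in ext_list:
            rows.extend(e.as_rows(model=best_model or ""))
    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(out / "metrics.csv", index=False)
    metrics_df.to_json(out / "metrics.json", orient="records", indent=2)
    if univariate is not None:
        univariate_frame(univariate).to_csv(out / "univariate_stats.csv", index=False)
        if not univariate:
            warnings.warn("empty selected-feature set: univariate stats file is empty")
    if table is not None and labels is not None and univariate:
        feats = [s.feature for s in univariate]
        dump = table[["case_id"] + feats].copy()
        dump.insert(1, "label", np.asarray(labels))
        dump.to_csv(out / "feature_values_by_class.csv", index=False)
    if best_model is not None:
        (out / "best_model.json").write_text(json.dumps({"best_model": best_model}))
    if manifest is not None:
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
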