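"""Cross-validation, forward SAAP selection, independent test, metrics.

Evaluation follows the residue-level protocol: candidate sites of one
center residue type (C or H) are stratified into k folds; each fold is
predicted by a network trained on the other k-1 folds and predictions
are pooled into a single confusion matrix.  By default SAAP mining and
ranking are re-run inside each training split only, so the test fold
never influences feature definitions; mining once on the full dataset
before CV (which leaks fold information but mirrors common practice)
is available as an explicit mode.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), accuracy (TP+TN)/total and Matthews correlation
(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Zero
denominators yield an explicit "undefined" flag, never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import rbfn, saap
from .encoders import PssmProfile, encode_dataset
from .io import ProteinRecord, ResidueSite, windows_for_sites


class LeakageError(ValueError):
    """Raised when train and test share protein accessions."""


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int).ravel()
        yp = np.asarray(y_pred, dtype=int).ravel()
        if yt.size != yp.size:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


@dataclass
class MetricsReport:
    """Proportions in [0, 1] (NaN where undefined) plus MCC in [-1, 1]."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    undefined: frozenset[str] = frozenset()


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision, accuracy and MCC from counts."""
    undefined: set[str] = set()
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", undefined)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", undefined)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", undefined)
    acc = _ratio(c.tp + c.tn, c.total, "accuracy", undefined)
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        undefined.add("mcc")
        mcc = float("nan")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)
    return MetricsReport(sens, spec, prec, acc, mcc, frozenset(undefined))


REPORT_COLUMNS = (
    "TP",
    "FP",
    "TN",
    "FN",
    "Sensitivity",
    "Precision",
    "Specificity",
    "Accuracy",
    "MCC",
)


def format_report_row(c: ConfusionCounts, m: MetricsReport | None = None) -> dict:
    """One evaluation row with display rounding: 1 dp percentages, 2 dp MCC."""
    m = m or compute_metrics(c)

    def pct(v: float) -> str:
        return "undefined" if math.isnan(v) else f"{round(100 * v, 1)}%"

    return {
        "TP": c.tp,
        "FP": c.fp,
        "TN": c.tn,
        "FN": c.fn,
        "Sensitivity": pct(m.sensitivity),
        "Precision": pct(m.precision),
        "Specificity": pct(m.specificity),
        "Accuracy": pct(m.accuracy),
        "MCC": "undefined" if math.isnan(m.mcc) else f"{round(m.mcc, 2):.2f}",
    }


def write_report(rows: list[dict], path: str | Path, labels: list[str] | None = None) -> None:
    """Evaluation report TSV in the standard column order."""
    labels = labels or [str(i) for i in range(len(rows))]
    with open(path, "w") as fh:
        fh.write("Model\t" + "\t".join(REPORT_COLUMNS) + "\n")
        for name, row in zip(labels, rows):
            fh.write(name + "\t" + "\t".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    k: int
    seed: int
    assignment: np.ndarray  # fold index per site

    def fold_mask(self, f: int) -> np.ndarray:
        return self.assignment == f


def make_cv_plan(sites: list[ResidueSite], k: int = 10, seed: int = 0) -> CvPlan:
    """Seeded, stratified, reproducible fold assignment at residue level.

    Fold sizes differ by at most 1 within each class.  Requires at
    least k members per class.
    """
    y = np.array([1 if s.is_binding else 0 for s in sites])
    for cls in (0, 1):
        count = int(np.sum(y == cls))
        if count < k:
            raise ValueError(
                f"class {cls} has only {count} sites; use k <= {count}"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(sites), dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(sites)), y)):
        assignment[test_idx] = f
    return CvPlan(k=k, seed=seed, assignment=assignment)


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------


@dataclass
class SaapConfig:
    """How SAAP indicator features enter a CV run.

    mode "per_fold": mine and rank inside each training split, keep the
    top ``n_features`` significant pairs (all significant if None).
    mode "fixed": use the supplied pre-ranked ``features`` list verbatim
    in every fold (mined once on the full dataset; leaks fold
    information, provided for protocol reproduction).
    """

    mode: str = "per_fold"
    alpha: float = 0.05
    n_features: int | None = None
    features: list[saap.SaapFeature] = field(default_factory=list)
    pvalue_mode: str = "tail"

    def __post_init__(self) -> None:
        if self.mode not in ("per_fold", "fixed"):
            raise ValueError(f"unknown SAAP mode {self.mode!r}")


@dataclass
class CvResult:
    counts: ConfusionCounts
    predictions: np.ndarray
    labels: np.ndarray
    per_fold: list[ConfusionCounts]
    plan: CvPlan


def run_cv(
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    plan: CvPlan,
    encoding: str = "PSSM",
    profiles: dict[str, PssmProfile] | None = None,
    saap_config: SaapConfig | None = None,
    sigma: float = rbfn.DEFAULT_BANDWIDTH,
    ridge: float = rbfn.DEFAULT_RIDGE,
    w: int = 6,
) -> CvResult:
    """k-fold cross-validated evaluation pooled into one confusion matrix."""
    X_base, y = encode_dataset(sites, records, encoding, profiles, w=w)
    windows = windows_for_sites(sites, records, w)
    preds = np.empty(len(sites), dtype=int)
    per_fold = []
    for f in range(plan.k):
        test = plan.fold_mask(f)
        train = ~test
        feats: list[saap.SaapFeature] = []
        if saap_config is not None:
            if saap_config.mode == "fixed":
                feats = list(saap_config.features)
            else:
                train_windows = [win for win, t in zip(windows, train) if t]
                ranked = saap.mine_saaps(
                    train_windows, saap_config.alpha, saap_config.pvalue_mode
                )
                feats = ranked.features[: saap_config.n_features]
        if feats:
            B = saap.indicator_matrix(windows, feats)
            X = np.hstack([X_base, B])
        else:
            X = X_base
        model = rbfn.train(X[train], y[train], sigma=sigma, ridge=ridge)
        fold_pred = rbfn.predict(model, X[test])
        preds[test] = fold_pred
        per_fold.append(ConfusionCounts.from_labels(y[test], fold_pred))
    counts = ConfusionCounts.from_labels(y, preds)
    return CvResult(counts=counts, predictions=preds, labels=y, per_fold=per_fold, plan=plan)


# ---------------------------------------------------------------------------
# forward feature selection over a ranked catalog
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    k_star: int
    features: list[saap.SaapFeature]
    base_accuracy: float
    audit: list[tuple[int, float]]  # (prefix length, pooled CV accuracy)


def _cv_accuracy_from_kernel(
    Phi: np.ndarray, y: np.ndarray, plan: CvPlan, ridge: float
) -> float:
    """Pooled CV accuracy given a precomputed full kernel matrix."""
    T = rbfn.one_hot_targets(y)
    correct = 0
    for f in range(plan.k):
        test = plan.fold_mask(f)
        train = ~test
        Ptt = Phi[np.ix_(train, train)]
        W = rbfn.solve_weights(Ptt, T[train], ridge)
        G = Phi[np.ix_(test, train)] @ W
        pred = (G[:, 0] > G[:, 1]).astype(int)
        correct += int(np.sum(pred == y[test]))
    return correct / y.size


def forward_select_saaps(
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    catalog: saap.SaapCatalog,
    plan: CvPlan,
    encoding: str = "PSSM",
    profiles: dict[str, PssmProfile] | None = None,
    sigma: float = rbfn.DEFAULT_BANDWIDTH,
    ridge: float = rbfn.DEFAULT_RIDGE,
    w: int = 6,
    max_features: int | None = None,
) -> SelectionResult:
    """Greedy prefix scan of a ranked catalog by cross-validated accuracy.

    Ranked pairs are added one at a time; after each addition the pooled
    CV accuracy is recorded.  The selected prefix length k* maximizes
    accuracy, with ties resolved to the smallest k (k* = 0 keeps base
    features only).  ``max_features`` caps the scanned prefix length.

    Adding one binary indicator changes squared distances by at most 1
    per pair of windows, so the kernel matrix is updated incrementally
    rather than recomputed from the features.
    """
    X, y = encode_dataset(sites, records, encoding, profiles, w=w)
    windows = windows_for_sites(sites, records, w)
    scan = catalog.features[:max_features] if max_features else catalog.features
    B = saap.indicator_matrix(windows, scan)
    from scipy.spatial.distance import cdist

    D2 = cdist(X, X, "sqeuclidean")
    two_s2 = 2.0 * sigma**2
    base_acc = _cv_accuracy_from_kernel(np.exp(-D2 / two_s2), y, plan, ridge)
    best_k, best_acc = 0, base_acc
    audit: list[tuple[int, float]] = []
    for k in range(1, len(scan) + 1):
        b = B[:, k - 1]
        D2 += (b[:, None] - b[None, :]) ** 2
        acc = _cv_accuracy_from_kernel(np.exp(-D2 / two_s2), y, plan, ridge)
        audit.append((k, acc))
        if acc > best_acc:
            best_k, best_acc = k, acc
    return SelectionResult(
        k_star=best_k,
        features=scan[:best_k],
        base_accuracy=base_acc,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# final training and independent test
# ---------------------------------------------------------------------------


def train_model(
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    encoding: str = "PSSM",
    profiles: dict[str, PssmProfile] | None = None,
    saap_features: list[saap.SaapFeature] | None = None,
    sigma: float = rbfn.DEFAULT_BANDWIDTH,
    ridge: float = rbfn.DEFAULT_RIDGE,
    w: int = 6,
) -> rbfn.RbfnModel:
    """Train a final network on all given sites.

    The returned model's ``feature_spec`` records the encoding, flank
    width, SAAP list and training accessions, so prediction inputs can
    be checked for compatibility and leakage.
    """
    feats = list(saap_features or [])
    X, y = encode_dataset(sites, records, encoding, profiles, feats, w=w)
    spec = {
        "encoding": encoding,
        "w": w,
        "center_residue": sites[0].residue if sites else None,
        "saap_features": [[f.offset1, f.aa1, f.offset2, f.aa2] for f in feats],
        "train_proteins": sorted({s.protein_id for s in sites}),
    }
    return rbfn.train(X, y, sigma=sigma, ridge=ridge, feature_spec=spec)


def saap_features_from_spec(spec: dict) -> list[saap.SaapFeature]:
    return [
        saap.SaapFeature(offset1=o1, aa1=a1, offset2=o2, aa2=a2)
        for o1, a1, o2, a2 in spec.get("saap_features", [])
    ]


def predict_sites(
    model: rbfn.RbfnModel,
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    profiles: dict[str, PssmProfile] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and predicted labels for sites, per the model's spec."""
    spec = model.feature_spec
    X, _ = encode_dataset(
        sites,
        records,
        spec.get("encoding", "PSSM"),
        profiles,
        saap_features_from_spec(spec),
        w=spec.get("w", 6),
    )
    G = rbfn.decision_values(model, X)
    return G, (G[:, 0] > G[:, 1]).astype(int)


def run_independent_test(
    model: rbfn.RbfnModel,
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    profiles: dict[str, PssmProfile] | None = None,
) -> tuple[ConfusionCounts, MetricsReport]:
    """Evaluate a trained model on held-out proteins.

    Any accession shared between the model's training set and the test
    sites raises :class:`LeakageError` naming the offenders.
    """
    if not sites:
        raise ValueError("empty independent test set")
    train_ids = set(model.feature_spec.get("train_proteins", []))
    overlap = sorted(train_ids & {s.protein_id for s in sites})
    if overlap:
        raise LeakageError(
            f"test proteins overlap the training set: {', '.join(overlap)}"
        )
    _, preds = predict_sites(model, sites, records, profiles)
    y = np.array([1 if s.is_binding else 0 for s in sites])
    counts = ConfusionCounts.from_labels(y, preds)
    return counts, compute_metrics(counts)
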