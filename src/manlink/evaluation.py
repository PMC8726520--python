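"""Five-fold cross-validation and the binary classification metric suite.

Metrics: SEN = TP/(TP+FN), SPE = TN/(FP+TN), PRE = TP/(TP+FP),
ACC = (TP+TN)/total, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

plus the ROC curve and its trapezoid area (equal to the normalized
Mann-Whitney U statistic).  A metric with a zero denominator is reported
as NA (None), never coerced to 0.

Cross-validation is stratified by label.  In the default leakage-safe
mode the positive drug-disease edges of the held-out fold are removed
from the network before the embedding of that fold is trained, so no test
signal can reach the features; ``leakage_safe=False`` embeds the full
graph once, which is cheaper but optimistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .attributes import AttributeStore
from .classifier import (
    ClassifierSpec,
    PairSample,
    VARIANTS,
    fuse_features,
    score_pairs,
    train_classifier,
)
from .line_embedding import EmbeddingResult, LineConfig, train_line
from .man_graph import AssociationEdge, MANGraph

logger = logging.getLogger(__name__)

METRIC_NAMES = ("SEN", "SPE", "PRE", "ACC", "MCC", "AUC")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def make_folds(pairs: list[PairSample], k: int = 5, seed: int = 0) -> list[PairSample]:
    """Assign stratified fold indices 0..k-1 in place (and return pairs).

    Folds are disjoint, exhaustive, sized within 1 of each other and
    stratified by label; requires at least k pairs per class.
    """
    labels = np.array([p.label for p in pairs])
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} pairs")
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(pairs)), labels)):
        for i in test_idx:
            pairs[i].fold = fold
    return pairs


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den else None


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """SEN/SPE/PRE/ACC/MCC from a confusion matrix; NA where undefined."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "SEN": _safe_div(tp, tp + fn),
        "SPE": _safe_div(tn, fp + tn),
        "PRE": _safe_div(tp, tp + fp),
        "ACC": _safe_div(tp + tn, counts.total),
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den else None,
    }


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    pred = np.asarray(scores) >= threshold
    lab = np.asarray(labels).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & lab)),
        fp=int(np.sum(pred & ~lab)),
        tn=int(np.sum(~pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, AUC) by threshold sweep and trapezoid integration."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVMetrics:
    variant: str
    per_fold: list[dict[str, float | None]]
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def mean(self, name: str) -> float:
        vals = [m[name] for m in self.per_fold if m[name] is not None]
        return float(np.mean(vals))

    def sd(self, name: str) -> float:
        vals = [m[name] for m in self.per_fold if m[name] is not None]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {n: {"mean": self.mean(n), "sd": self.sd(n)} for n in METRIC_NAMES}


def _dda_edges(pairs: list[PairSample]) -> list[AssociationEdge]:
    return [
        AssociationEdge(p.drug, p.disease, "drug-disease")
        for p in pairs
        if p.label == 1
    ]


def _fold_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(k)]


def fold_embeddings(
    g: MANGraph,
    pairs: list[PairSample],
    line_cfg: LineConfig,
    k: int,
    seed: int,
    leakage_safe: bool = True,
) -> list[EmbeddingResult]:
    """One embedding per fold.

    Leakage-safe mode drops the held-out fold's positive drug-disease
    edges from the graph before training and asserts none survived.
    Without it, a single full-graph embedding is shared by all folds.
    """
    seeds = _fold_seeds(seed, k)
    if not leakage_safe:
        cfg = LineConfig(**{**line_cfg.__dict__, "seed": seeds[0]})
        emb = train_line(g, cfg)
        return [emb] * k
    out = []
    for fold in range(k):
        held = [p for p in pairs if p.fold == fold and p.label == 1]
        g_fold = g.without_edges(_dda_edges(held))
        for p in held:
            assert not (
                p.drug in g_fold
                and p.disease in g_fold
                and g_fold.has_edge(p.drug, p.disease, "drug-disease")
            ), "held-out positive edge leaked into embedding graph"
        cfg = LineConfig(**{**line_cfg.__dict__, "seed": seeds[fold]})
        out.append(train_line(g_fold, cfg))
    return out


def _eval_fold(
    fold: int,
    pairs: list[PairSample],
    attributes: AttributeStore,
    emb: EmbeddingResult,
    spec: ClassifierSpec,
    variant: str,
    seed: int,
) -> tuple[dict[str, float | None], tuple[np.ndarray, np.ndarray]]:
    train = [p for p in pairs if p.fold != fold]
    test = [p for p in pairs if p.fold == fold]
    if variant != "attributes_only" and emb is not None:
        # a node whose every edge was held out has no embedding in this
        # fold's graph (cold start); its pairs cannot be featurized
        def embeddable(p: PairSample) -> bool:
            return p.drug in emb.index and p.disease in emb.index

        n_before = len(train) + len(test)
        train = [p for p in train if embeddable(p)]
        test = [p for p in test if embeddable(p)]
        dropped = n_before - len(train) - len(test)
        if dropped:
            logger.warning(
                "fold %d: %d pairs dropped (endpoint unembeddable)", fold, dropped
            )
    x_tr = fuse_features(train, attributes, emb, variant)
    x_te = fuse_features(test, attributes, emb, variant)
    y_tr = np.array([p.label for p in train])
    y_te = np.array([p.label for p in test])
    model = train_classifier(x_tr, y_tr, spec, seed=seed)
    scores = score_pairs(model, x_te)
    metrics = compute_metrics(confusion_from_scores(scores, y_te))
    fpr, tpr, auc = roc_auc(scores, y_te)
    metrics["AUC"] = auc
    return metrics, (fpr, tpr)


def run_cv(
    g: MANGraph,
    pairs: list[PairSample],
    attributes: AttributeStore,
    line_cfg: LineConfig | None = None,
    spec: ClassifierSpec | None = None,
    variant: str = "full",
    k: int = 5,
    seed: int = 0,
    leakage_safe: bool = True,
) -> CVMetrics:
    """Stratified k-fold CV of one feature variant."""
    return compare_variants(
        g, pairs, attributes, line_cfg, spec, [variant], k, seed, leakage_safe
    )[variant]


def compare_variants(
    g: MANGraph,
    pairs: list[PairSample],
    attributes: AttributeStore,
    line_cfg: LineConfig | None = None,
    spec: ClassifierSpec | None = None,
    variants: list[str] = list(VARIANTS),
    k: int = 5,
    seed: int = 0,
    leakage_safe: bool = True,
) -> dict[str, CVMetrics]:
    """CV of several feature variants on identical pairs, folds, seeds and
    per-fold embeddings, so ablations differ only in feature columns."""
    line_cfg = line_cfg or LineConfig()
    spec = spec or ClassifierSpec()
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    usable = [
        p for p in pairs
        if attributes.usable(p.drug) and attributes.usable(p.disease)
    ]
    if len(usable) < len(pairs):
        logger.warning(
            "%d pairs dropped (flagged attributes)", len(pairs) - len(usable)
        )
    make_folds(usable, k=k, seed=seed)
    need_emb = any(v != "attributes_only" for v in variants)
    embs = (
        fold_embeddings(g, usable, line_cfg, k, seed, leakage_safe)
        if need_emb
        else [None] * k  # type: ignore[list-item]
    )
    results: dict[str, CVMetrics] = {}
    for variant in variants:
        per_fold, rocs = [], []
        for fold in range(k):
            metrics, roc = _eval_fold(
                fold, usable, attributes, embs[fold], spec, variant, seed=seed + fold
            )
            per_fold.append(metrics)
            rocs.append(roc)
            logger.info("variant=%s fold=%d AUC=%.4f", variant, fold, metrics["AUC"])
        results[variant] = CVMetrics(variant=variant, per_fold=per_fold, roc_points=rocs)
    return results
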