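"""Drug-disease pair assembly, feature fusion and classification.

A labeled pair couples one drug and one disease; the positive class is a
known association and negatives are unobserved pairs sampled uniformly at
a 1:1 ratio.  Each pair's feature row fuses attribute and behaviour
(embedding) vectors of both endpoints:

    [drug attr (64) | drug emb (64) | disease attr (64) | disease emb (64)]

The ``attributes_only`` and ``embeddings_only`` variants keep the matching
128 columns of the same rows, so ablations differ only in feature columns.
The default classifier is a random forest with n_estimators=100 and
max_depth=110 (grid-searched values); AdaBoost, logistic regression and
Gaussian naive Bayes are drop-in alternatives with library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attributes import AttributeStore
from .line_embedding import EmbeddingResult
from .man_graph import MANGraph, NodeRef

VARIANTS = ("full", "attributes_only", "embeddings_only")


@dataclass
class PairSample:
    drug: NodeRef
    disease: NodeRef
    label: int
    fold: int = -1

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug.id, self.disease.id)


@dataclass
class ClassifierSpec:
    kind: str = "random_forest"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "adaboost", "logistic", "naive_bayes"):
            raise ValueError(f"unknown classifier kind: {self.kind!r}")


def sample_negatives(
    positives: list[PairSample], g: MANGraph, seed: int
) -> list[PairSample]:
    """Uniformly sample unobserved (drug, disease) pairs, one per positive.

    Candidates are all drug x disease pairs over the graph's nodes minus
    every known positive; sampling is without replacement and seeded.
    """
    if not positives:
        raise ValueError("need at least one positive pair")
    drugs = g.nodes_of_kind("drug")
    diseases = g.nodes_of_kind("disease")
    if len(drugs) < 2 or len(diseases) < 2:
        raise ValueError("need at least 2 drugs and 2 diseases")
    taken = {p.key for p in positives}
    candidates = [
        (d, e) for d in drugs for e in diseases if (d.id, e.id) not in taken
    ]
    if len(candidates) < len(positives):
        raise ValueError(
            f"only {len(candidates)} unobserved pairs available for "
            f"{len(positives)} negatives"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(candidates), size=len(positives), replace=False)
    return [PairSample(*candidates[i], label=0) for i in sorted(picks)]


def fuse_features(
    pairs: list[PairSample],
    attributes: AttributeStore,
    embeddings: EmbeddingResult | None,
    variant: str = "full",
) -> np.ndarray:
    """Feature matrix, one row per pair in order.

    full: width 256; attributes_only / embeddings_only: width 128.
    Raises naming the node if a required vector is missing.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    rows = []
    for p in pairs:
        parts = []
        for node in (p.drug, p.disease):
            if variant in ("full", "attributes_only"):
                if node not in attributes.vectors:
                    raise KeyError(f"no attribute vector for {node.kind} {node.id!r}")
                parts.append(attributes.get(node))
            if variant in ("full", "embeddings_only"):
                if embeddings is None or node not in embeddings.index:
                    raise KeyError(f"no embedding for {node.kind} {node.id!r}")
                parts.append(embeddings.vector(node))
        rows.append(np.concatenate(parts))
    out = np.asarray(rows, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature values")
    return out


def make_classifier(spec: ClassifierSpec, seed: int):
    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB

    if spec.kind == "random_forest":
        params = {"n_estimators": 100, "max_depth": 110, **spec.params}
        return RandomForestClassifier(random_state=seed, **params)
    if spec.kind == "adaboost":
        return AdaBoostClassifier(random_state=seed, **spec.params)
    if spec.kind == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed, **spec.params)
    return GaussianNB(**spec.params)


def train_classifier(
    features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec, seed: int = 0
):
    """Fit the requested classifier; scores are P(class 1) in [0, 1]."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in training labels")
    model = make_classifier(spec, seed)
    model.fit(features, labels)
    return model


def score_pairs(model, features: np.ndarray) -> np.ndarray:
    return model.predict_proba(features)[:, 1]


def predict_ranking(
    model, candidate_pairs: list[PairSample], features: np.ndarray
) -> list[tuple[PairSample, float]]:
    """Candidates sorted by descending score; ties broken by drug id then
    disease id for reproducibility."""
    scores = score_pairs(model, features)
    order = sorted(
        range(len(candidate_pairs)),
        key=lambda i: (-scores[i], candidate_pairs[i].drug.id, candidate_pairs[i].disease.id),
    )
    return [(candidate_pairs[i], float(scores[i])) for i in order]
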