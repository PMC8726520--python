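"""End-to-end orchestration: load inputs, featurize, embed, cross-validate.

One master seed fully determines every stochastic stage (attribute
autoencoders, negative sampling, fold assignment, embedding training,
classifier); stage seeds are derived from it, so a rerun of the same
configuration reproduces the report bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import man_graph as mg
from .attributes import (
    AttributeStore,
    SAEConfig,
    build_attribute_store,
    load_drug_table,
    load_fasta,
    load_mesh_table,
)
from .classifier import ClassifierSpec, PairSample, sample_negatives, predict_ranking, fuse_features, train_classifier
from .evaluation import METRIC_NAMES, CVMetrics, compare_variants, make_folds
from .line_embedding import LineConfig, dump_embedding, train_line
from .man_graph import MANGraph, NodeRef

logger = logging.getLogger(__name__)

STANDARD_FILES = {
    "edges": {k: f"{k}.tsv" for k in mg.EDGE_KINDS},
    "protein_fasta": "proteins.fasta",
    "rna_fasta": "ncrna.fasta",
    "drugs": "drugs.tsv",
    "mesh": "mesh.tsv",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    data_dir: Path
    out_dir: Path
    epsilon: float = 0.5
    sae: SAEConfig = None  # type: ignore[assignment]
    line: LineConfig = None  # type: ignore[assignment]
    classifier: ClassifierSpec = None  # type: ignore[assignment]
    variant: str = "full"
    k_folds: int = 5
    leakage_safe: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        self.sae = self.sae or SAEConfig()
        self.line = self.line or LineConfig()
        self.classifier = self.classifier or ClassifierSpec()

    @classmethod
    def from_mapping(cls, cfg: dict) -> "RunConfig":
        """Build from a flat key-value mapping (the config-file format)."""
        def get(key, default):
            return cfg.get(key, default)

        line = LineConfig(
            dim_total=int(get("embedding.dim", 64)),
            negatives_k=int(get("embedding.negatives", 5)),
            initial_lr=float(get("embedding.lr", 0.025)),
            total_samples=(
                int(cfg["embedding.total_samples"])
                if cfg.get("embedding.total_samples") is not None
                else None
            ),
        )
        sae = SAEConfig(
            hidden=tuple(
                int(w) for w in str(get("sae.hidden", "256")).split(",") if w
            ),
            epochs=int(get("sae.epochs", 50)),
            lr=float(get("sae.lr", 0.01)),
            batch_size=int(get("sae.batch_size", 16)),
        )
        return cls(
            data_dir=Path(cfg["data_dir"]),
            out_dir=Path(get("out", "manlink_out")),
            epsilon=float(get("epsilon", 0.5)),
            sae=sae,
            line=line,
            classifier=ClassifierSpec(kind=get("classifier.kind", "random_forest")),
            variant=get("variant", "full"),
            k_folds=int(get("cv.k", 5)),
            leakage_safe=bool(get("cv.leakage_safe", True)),
            seed=int(get("seed", 0)),
        )

    def to_mapping(self) -> dict:
        return {
            "data_dir": str(self.data_dir),
            "out": str(self.out_dir),
            "epsilon": self.epsilon,
            "sae.hidden": ",".join(str(w) for w in self.sae.hidden),
            "sae.epochs": self.sae.epochs,
            "sae.lr": self.sae.lr,
            "sae.batch_size": self.sae.batch_size,
            "embedding.dim": self.line.dim_total,
            "embedding.negatives": self.line.negatives_k,
            "embedding.lr": self.line.initial_lr,
            "embedding.total_samples": self.line.total_samples,
            "classifier.kind": self.classifier.kind,
            "variant": self.variant,
            "cv.k": self.k_folds,
            "cv.leakage_safe": self.leakage_safe,
            "seed": self.seed,
        }


def stage_seeds(master: int, n: int = 4) -> list[int]:
    """Independent per-stage seeds derived from the master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(master).generate_state(n)]


def load_dataset(
    data_dir: str | Path,
) -> tuple[MANGraph, dict]:
    """Load a dataset directory laid out with the standard file names."""
    data_dir = Path(data_dir)
    edge_lists = []
    for kind, fname in STANDARD_FILES["edges"].items():
        path = data_dir / fname
        if path.exists():
            edge_lists.append((mg.load_edge_list(path, kind), kind))
    if not edge_lists:
        raise mg.GraphError(f"no edge-list files found in {data_dir}")
    g = mg.build_graph(edge_lists)
    raw = {
        "protein_seqs": {},
        "rna_seqs": {},
        "smiles": {},
        "mesh": None,
    }
    p = data_dir / STANDARD_FILES["protein_fasta"]
    if p.exists():
        raw["protein_seqs"] = load_fasta(p)
    p = data_dir / STANDARD_FILES["rna_fasta"]
    if p.exists():
        raw["rna_seqs"] = load_fasta(p)
    p = data_dir / STANDARD_FILES["drugs"]
    if p.exists():
        raw["smiles"] = load_drug_table(p)
    p = data_dir / STANDARD_FILES["mesh"]
    if p.exists():
        raw["mesh"] = load_mesh_table(p)
    return g, raw


def build_pairs(g: MANGraph, seed: int) -> list[PairSample]:
    """Known drug-disease edges as positives plus 1:1 sampled negatives."""
    positives = [
        PairSample(*( (e.u, e.v) if e.u.kind == "drug" else (e.v, e.u) ), label=1)
        for e in g.edges
        if e.edge_kind == "drug-disease"
    ]
    negatives = sample_negatives(positives, g, seed=seed)
    return positives + negatives


def featurize(g: MANGraph, raw: dict, cfg: RunConfig, seed: int) -> AttributeStore:
    return build_attribute_store(
        g.nodes,
        mesh=raw.get("mesh"),
        protein_seqs=raw.get("protein_seqs"),
        rna_seqs=raw.get("rna_seqs"),
        smiles=raw.get("smiles"),
        epsilon=cfg.epsilon,
        sae_config=cfg.sae,
        seed=seed,
    )


def run_pipeline(cfg: RunConfig, variants: list[str] | None = None) -> dict:
    """build -> featurize -> embed -> CV -> report.

    Returns the report dict and writes report.json / report.tsv, per-fold
    ROC points, a full-graph embedding dump and the exact configuration
    into ``cfg.out_dir``.
    """
    t0 = time.time()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    (cfg.out_dir / "config.json").write_text(json.dumps(cfg.to_mapping(), indent=1))
    seeds = stage_seeds(cfg.seed)
    stage = "load"
    try:
        g, raw = load_dataset(cfg.data_dir)
        stage = "featurize"
        attributes = featurize(g, raw, cfg, seeds[0])
        stage = "pairs"
        pairs = build_pairs(g, seeds[1])
        stage = "cross_validation"
        results = compare_variants(
            g,
            pairs,
            attributes,
            line_cfg=cfg.line,
            spec=cfg.classifier,
            variants=variants or [cfg.variant],
            k=cfg.k_folds,
            seed=seeds[2],
            leakage_safe=cfg.leakage_safe,
        )
        stage = "report"
        report = {
            "config": cfg.to_mapping(),
            "n_nodes": len(g),
            "n_edges": g.n_edges,
            "n_pairs": len(pairs),
            "variants": {v: _variant_report(m) for v, m in results.items()},
            "runtime_s": round(time.time() - t0, 2),
        }
        _write_report(report, results, cfg.out_dir)
        stage = "embedding_dump"
        emb = train_line(g, LineConfig(**{**cfg.line.__dict__, "seed": seeds[3]}))
        dump_embedding(emb, cfg.out_dir / "embeddings.tsv")
    except Exception as exc:
        (cfg.out_dir / "MANIFEST").write_text(
            f"status: failed\nstage: {stage}\nerror: {exc}\n"
        )
        raise
    (cfg.out_dir / "MANIFEST").write_text("status: ok\nstage: complete\n")
    return report


def _variant_report(m: CVMetrics) -> dict:
    return {
        "per_fold": [
            {k: (None if v is None else round(v, 6)) for k, v in row.items()}
            for row in m.per_fold
        ],
        "summary": {
            k: {"mean": round(s["mean"], 6), "sd": round(s["sd"], 6)}
            for k, s in m.summary().items()
        },
    }


def _write_report(report: dict, results: dict[str, CVMetrics], out_dir: Path) -> None:
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    with (out_dir / "report.tsv").open("w") as fh:
        fh.write("variant\tfold\t" + "\t".join(METRIC_NAMES) + "\n")
        for v, m in results.items():
            for i, row in enumerate(m.per_fold):
                vals = "\t".join(
                    "NA" if row[n] is None else f"{row[n]:.4f}" for n in METRIC_NAMES
                )
                fh.write(f"{v}\t{i}\t{vals}\n")
            means = "\t".join(f"{m.mean(n):.4f}" for n in METRIC_NAMES)
            fh.write(f"{v}\tmean\t{means}\n")
    for v, m in results.items():
        for i, (fpr, tpr) in enumerate(m.roc_points):
            with (out_dir / f"roc_{v}_fold{i}.csv").open("w") as fh:
                fh.write("fpr,tpr\n")
                for x, y in zip(fpr, tpr):
                    fh.write(f"{x:.6f},{y:.6f}\n")


# ---------------------------------------------------------------------------
# Case-study style ranking
# ---------------------------------------------------------------------------

def rank_drugs(
    g: MANGraph,
    attributes: AttributeStore,
    disease: NodeRef,
    cfg: RunConfig,
    top_n: int = 20,
) -> list[tuple[str, float]]:
    """Rank every drug against one disease.

    All known drug edges of the query disease are first deleted from the
    network, the graph is re-embedded, the classifier is trained on the
    remaining associations, and every drug is scored against the query —
    so the ranking cannot read off the very edges it is asked to recover.
    """
    if disease not in g:
        import difflib

        near = difflib.get_close_matches(
            disease.id, [n.id for n in g.nodes_of_kind("disease")], n=5
        )
        raise KeyError(f"unknown disease {disease.id!r}; nearest ids: {near}")
    seeds = stage_seeds(cfg.seed)
    drop = [
        e for e in g.edges
        if e.edge_kind == "drug-disease" and disease in (e.u, e.v)
    ]
    g2 = g.without_edges(drop)
    for e in drop:
        assert not g2.has_edge(e.u, e.v, e.edge_kind)
    if disease not in g2:
        raise ValueError(
            f"disease {disease.id!r} would be isolated without its drug edges"
        )
    emb = train_line(g2, LineConfig(**{**cfg.line.__dict__, "seed": seeds[3]}))
    pairs = build_pairs(g2, seeds[1])
    pairs = [
        p for p in pairs
        if attributes.usable(p.drug) and attributes.usable(p.disease)
        and p.drug in emb.index and p.disease in emb.index
    ]
    x = fuse_features(pairs, attributes, emb, cfg.variant)
    y = np.array([p.label for p in pairs])
    model = train_classifier(x, y, cfg.classifier, seed=seeds[2])
    candidates = [
        PairSample(d, disease, label=0)
        for d in g2.nodes_of_kind("drug")
        if attributes.usable(d) and d in emb.index
    ]
    xc = fuse_features(candidates, attributes, emb, cfg.variant)
    ranked = predict_ranking(model, candidates, xc)
    return [(p.drug.id, s) for p, s in ranked[:top_n]]
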