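"""Self-consistent synthetic inputs: a planted-community molecular
association network plus matching sequences, SMILES and MeSH-style tables.

The generator plants a block structure: every node of every kind belongs
to one of ``n_communities`` communities, and each of the nine association
kinds draws a fixed number of edges, each of which is a random
within-community pair with probability ``signal`` and a uniformly random
pair otherwise.  ``signal = 0`` therefore yields a structureless null
network, while ``signal = 0.8`` makes community co-membership the
dominant explanation of drug-disease associations — a tunable ground
truth for recovery experiments.  Node attributes carry the same signal:
sequences of a community share a residue-group profile, drugs of a
community favour a common scaffold pool, and diseases of a community sit
under nearby branches of the generated MeSH tree.

A fraction of the true drug-disease associations is held out of the
network and returned as ground truth for ranking experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .man_graph import (
    EDGE_KINDS,
    AssociationEdge,
    MANGraph,
    NodeRef,
    build_graph,
)

logger = logging.getLogger(__name__)

#: Target edge counts per association kind at the default ~310-node scale;
#: relative sizes loosely follow real multi-source association sets, with
#: drug-disease, protein-disease and miRNA-disease the densest layers.
DEFAULT_EDGE_COUNTS: dict[str, int] = {
    "drug-disease": 280,
    "drug-protein": 180,
    "protein-protein": 300,
    "protein-disease": 380,
    "lncrna-protein": 60,
    "lncrna-disease": 80,
    "mirna-protein": 120,
    "mirna-disease": 250,
    "mirna-lncrna": 130,
}

# all scaffolds end on a carbon atom so a linear tail can be appended;
# linkers are divalent fragments, terminals close the chain
_SCAFFOLDS = [
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCNCC1",
    "c1ccoc1", "c1ccsc1", "C1CCOC1", "c1nc2ccccc2nc1", "C1CCNC1",
]
_LINKERS = ["C", "CC", "CO", "CN", "CCC", "COC", "C(C)C", "CNC"]
_TERMINALS = ["C", "O", "N", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "CO", "C(F)(F)F"]


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic network."""

    n_drugs: int = 40
    n_diseases: int = 60
    n_proteins: int = 120
    n_mirnas: int = 60
    n_lncrnas: int = 30
    n_communities: int = 10
    edge_counts: dict[str, int] | None = None
    signal: float = 0.8
    holdout_frac: float = 0.1
    seq_len_range: tuple[int, int] = (150, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if self.edge_counts is None:
            self.edge_counts = self._scaled_default_counts()
        for kind, count in self.edge_counts.items():
            if kind not in EDGE_KINDS:
                raise ValueError(f"unknown edge kind {kind!r}")
            if count < 0:
                raise ValueError(f"negative edge count for {kind!r}")

    def _scaled_default_counts(self) -> dict[str, int]:
        """Default edge counts, rescaled to preserve the per-kind edge
        density when node counts deviate from the reference scale."""
        ref = {"drug": 40, "disease": 60, "protein": 120, "mirna": 60, "lncrna": 30}
        cur = {
            "drug": self.n_drugs, "disease": self.n_diseases,
            "protein": self.n_proteins, "mirna": self.n_mirnas,
            "lncrna": self.n_lncrnas,
        }
        out = {}
        for kind, base in DEFAULT_EDGE_COUNTS.items():
            ku, kv = EDGE_KINDS[kind]
            scale = (cur[ku] * cur[kv]) / (ref[ku] * ref[kv])
            out[kind] = max(1, int(round(base * scale)))
        return out

    def kind_nodes(self) -> dict[str, list[NodeRef]]:
        def mk(prefix: str, kind: str, n: int) -> list[NodeRef]:
            return [NodeRef(f"{prefix}{i:04d}", kind) for i in range(n)]

        return {
            "drug": mk("DR", "drug", self.n_drugs),
            "disease": mk("d", "disease", self.n_diseases),
            "protein": mk("PR", "protein", self.n_proteins),
            "mirna": mk("MI", "mirna", self.n_mirnas),
            "lncrna": mk("LN", "lncrna", self.n_lncrnas),
        }


@dataclass
class GroundTruth:
    communities: dict[NodeRef, int]
    held_out: list[tuple[NodeRef, NodeRef]]  # true DDAs kept out of the graph
    positives: list[tuple[NodeRef, NodeRef]]  # DDAs present in the graph


def _assign_communities(nodes: dict[str, list[NodeRef]], k: int) -> dict[NodeRef, int]:
    comm: dict[NodeRef, int] = {}
    for members in nodes.values():
        for i, n in enumerate(members):
            comm[n] = i % k
    return comm


def _draw_edges(
    kind: str,
    us: list[NodeRef],
    vs: list[NodeRef],
    count: int,
    comm: dict[NodeRef, int],
    signal: float,
    rng: np.random.Generator,
) -> list[AssociationEdge]:
    """Draw ``count`` distinct pairs: a ``signal`` share from the
    within-community pair pool, the rest uniformly over all pairs.

    Both draws are without replacement, so the planted within-community
    fraction is exact (up to pool exhaustion) and ``signal = 0`` reduces
    to a uniform random bipartite (or unipartite) graph.
    """
    unipartite = us is vs or (us[0].kind == vs[0].kind if us and vs else False)
    if unipartite:
        all_pairs = [(us[i], us[j]) for i in range(len(us)) for j in range(i + 1, len(us))]
    else:
        all_pairs = [(u, v) for u in us for v in vs]
    within = [p for p in all_pairs if comm[p[0]] == comm[p[1]]]
    count = min(count, len(all_pairs))
    n_within = min(int(round(signal * count)), len(within))
    chosen: dict[tuple, tuple[NodeRef, NodeRef]] = {}
    for i in rng.choice(len(within), size=n_within, replace=False):
        p = within[i]
        chosen[(p[0], p[1])] = p
    rest = [p for p in all_pairs if (p[0], p[1]) not in chosen]
    n_rest = count - len(chosen)
    for i in rng.choice(len(rest), size=n_rest, replace=False):
        chosen.setdefault((rest[i][0], rest[i][1]), rest[i])
    return [AssociationEdge(u, v, kind) for u, v in chosen.values()]


def generate_man(spec: SyntheticSpec) -> tuple[MANGraph, GroundTruth]:
    """Planted-community MAN plus ground truth.

    A ``holdout_frac`` share of the drug-disease edges is reserved as
    held-out true positives (absent from the graph).  Drugs and diseases
    that would end up isolated get one rescue edge (drug-protein or
    protein-disease) within their community so every drug/disease is
    embeddable.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = spec.kind_nodes()
    comm = _assign_communities(nodes, spec.n_communities)

    per_kind: dict[str, list[AssociationEdge]] = {}
    for kind, count in spec.edge_counts.items():
        ku, kv = EDGE_KINDS[kind]
        if count == 0:
            continue
        if not nodes[ku] or not nodes[kv]:
            raise ValueError(f"edge kind {kind!r} requested but no {ku}/{kv} nodes")
        per_kind[kind] = _draw_edges(
            kind, nodes[ku], nodes[kv], count, comm, spec.signal, rng
        )

    ddas = per_kind.get("drug-disease", [])
    n_hold = int(round(spec.holdout_frac * len(ddas)))
    hold_idx = set(rng.choice(len(ddas), size=n_hold, replace=False).tolist())
    held_out = [ddas[i] for i in sorted(hold_idx)]
    kept = [e for i, e in enumerate(ddas) if i not in hold_idx]
    per_kind["drug-disease"] = kept

    # rescue isolated drugs/diseases with one within-community edge
    touched = {n for edges in per_kind.values() for e in edges for n in (e.u, e.v)}
    proteins = nodes["protein"]
    for kind_name, members, ekind in (
        ("drug", nodes["drug"], "drug-protein"),
        ("disease", nodes["disease"], "protein-disease"),
    ):
        for n in members:
            if n in touched:
                continue
            pool = [p for p in proteins if comm[p] == comm[n]] or proteins
            partner = pool[rng.integers(len(pool))]
            e = (
                AssociationEdge(n, partner, ekind)
                if kind_name == "drug"
                else AssociationEdge(partner, n, ekind)
            )
            per_kind.setdefault(ekind, []).append(e)
            touched.add(n)

    g = build_graph([(edges, kind) for kind, edges in per_kind.items()])
    def _ordered(e: AssociationEdge) -> tuple[NodeRef, NodeRef]:
        return (e.u, e.v) if e.u.kind == "drug" else (e.v, e.u)

    truth = GroundTruth(
        communities=comm,
        held_out=[_ordered(e) for e in held_out],
        positives=[_ordered(e) for e in kept],
    )
    return g, truth


# ---------------------------------------------------------------------------
# Attribute inputs
# ---------------------------------------------------------------------------

_PROT_LETTERS = ("AVLIMFWP", "GSTCNQY", "RKH", "DE")
_RNA_LETTERS = ("A", "C", "G", "U")


def generate_sequences(
    nodes: list[NodeRef],
    kind: str,
    communities: dict[NodeRef, int],
    length_range: tuple[int, int],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Community-biased random sequences.

    Nodes of a community share a Dirichlet-drawn frequency profile over
    the four residue groups, so grouped 3-mer vectors separate
    communities; within a group the letter is uniform.
    """
    if kind not in ("protein", "rna"):
        raise ValueError("kind must be 'protein' or 'rna'")
    letters = _PROT_LETTERS if kind == "protein" else _RNA_LETTERS
    n_comm = max(communities.values(), default=0) + 1
    profiles = rng.dirichlet([0.8] * 4, size=n_comm)
    out: dict[str, str] = {}
    lo, hi = length_range
    for node in nodes:
        p = profiles[communities[node]]
        length = int(rng.integers(lo, hi + 1))
        groups = rng.choice(4, size=length, p=p)
        seq = "".join(
            letters[gidx][rng.integers(len(letters[gidx]))] for gidx in groups
        )
        out[node.id] = seq
    return out


def generate_drug_table(
    drugs: list[NodeRef],
    communities: dict[NodeRef, int],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Valid SMILES with community-correlated scaffold/substituent choices:
    a drug takes its community's preferred scaffold and terminal group
    with probability 0.8, with a random linker chain in between."""
    from rdkit import Chem

    out: dict[str, str] = {}
    for d in drugs:
        c = communities[d]
        scaffold = (
            _SCAFFOLDS[c % len(_SCAFFOLDS)]
            if rng.random() < 0.8
            else _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        )
        n_link = int(rng.integers(1, 3))
        linker_pool = [_LINKERS[(c + j) % len(_LINKERS)] for j in range(3)]
        chain = "".join(
            linker_pool[rng.integers(len(linker_pool))] for _ in range(n_link)
        )
        terminal = (
            _TERMINALS[c % len(_TERMINALS)]
            if rng.random() < 0.8
            else _TERMINALS[rng.integers(len(_TERMINALS))]
        )
        smi = scaffold + chain + terminal
        assert Chem.MolFromSmiles(smi) is not None, f"invalid generated SMILES {smi}"
        out[d.id] = smi
    return out


def generate_mesh_table(
    diseases: list[NodeRef],
    communities: dict[NodeRef, int],
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """MeSH-style rows (descriptor_id, name, tree_number).

    Each community owns a top-level branch ``Cxx`` with two mid-level
    descriptors; a disease receives one or two tree numbers under its
    community's mids, so semantic similarity correlates with community
    co-membership (different communities share no ancestors).
    """
    rows: list[tuple[str, str, str]] = []
    n_comm = max(communities.values(), default=0) + 1
    mids: dict[int, list[str]] = {}
    for c in range(n_comm):
        top = f"C{c + 1:02d}"
        rows.append((f"dt{c:02d}", f"branch {c} root", top))
        mids[c] = []
        for j in range(2):
            tn = f"{top}.{100 + j}"
            rows.append((f"dm{c:02d}{j}", f"branch {c} mid {j}", tn))
            mids[c].append(tn)
    used: set[str] = set()
    for i, d in enumerate(diseases):
        c = communities[d]
        n_tn = 1 + int(rng.random() < 0.3)
        chosen = rng.choice(2, size=n_tn, replace=False)
        for j in chosen:
            while True:
                leaf = f"{mids[c][j]}.{int(rng.integers(100, 1000))}"
                if leaf not in used:
                    used.add(leaf)
                    break
            rows.append((d.id, f"synthetic disease {i}", leaf))
    return rows


# ---------------------------------------------------------------------------
# Dataset directory
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticSpec, outdir: str | Path) -> Path:
    """Emit a loadable dataset directory: 9 edge-list TSVs, protein and
    ncRNA FASTA, drug SMILES TSV, MeSH TSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, truth = generate_man(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E05]))
    nodes = spec.kind_nodes()

    by_kind: dict[str, list[AssociationEdge]] = {k: [] for k in EDGE_KINDS}
    for e in g.edges:
        by_kind[e.edge_kind].append(e)
    for kind, edges in by_kind.items():
        with (outdir / f"{kind}.tsv").open("w") as fh:
            fh.write("#source_id\ttarget_id\n")
            ku, _ = EDGE_KINDS[kind]
            for e in sorted(edges, key=lambda e: e.key):
                u, v = (e.u, e.v) if e.u.kind == ku else (e.v, e.u)
                fh.write(f"{u.id}\t{v.id}\n")

    prot = generate_sequences(
        nodes["protein"], "protein", truth.communities, spec.seq_len_range, rng
    )
    rna = generate_sequences(
        nodes["mirna"] + nodes["lncrna"], "rna", truth.communities,
        spec.seq_len_range, rng,
    )
    for fname, seqs in (("proteins.fasta", prot), ("ncrna.fasta", rna)):
        with (outdir / fname).open("w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")

    smiles = generate_drug_table(nodes["drug"], truth.communities, rng)
    with (outdir / "drugs.tsv").open("w") as fh:
        fh.write("#drug_id\tsmiles\n")
        for did, smi in smiles.items():
            fh.write(f"{did}\t{smi}\n")

    mesh_rows = generate_mesh_table(nodes["disease"], truth.communities, rng)
    with (outdir / "mesh.tsv").open("w") as fh:
        fh.write("#descriptor_id\tname\ttree_number\n")
        for desc, name, tn in mesh_rows:
            fh.write(f"{desc}\t{name}\t{tn}\n")

    with (outdir / "ground_truth.json").open("w") as fh:
        json.dump(
            {
                "communities": {f"{n.kind}:{n.id}": c for n, c in truth.communities.items()},
                "held_out": [[d.id, e.id] for d, e in truth.held_out],
                "positives": [[d.id, e.id] for d, e in truth.positives],
                "spec": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in spec.__dict__.items()
                },
            },
            fh,
            indent=1,
        )
    logger.info("synthetic dataset written to %s", outdir)
    return outdir
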