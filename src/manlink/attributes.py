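"""Per-node attribute vectors (width 64) for all five molecule kinds.

Diseases
    A directed acyclic graph of MeSH ancestors is built from tree numbers.
    Each ancestor d contributes C_e(d) = max over children d' in the DAG of
    eps * C_e(d'), with C_e(e) = 1, so a member's contribution decays with
    its shortest ancestor distance.  The semantic value DV(e) is the sum of
    contributions, and two diseases are compared by

        SV1(i, j) = sum_{d in N_i ^ N_j} (C_i(d) + C_j(d)) / (DV(i) + DV(j)).

    The row of the full pairwise SV1 matrix is the disease's raw attribute;
    it is brought to width 64 by a stacked autoencoder (or zero-padding
    when there are at most 64 diseases, which is lossless).

Proteins and ncRNAs
    Overlapping 3-mers over a reduced 4-letter alphabet: amino acids are
    pooled into four physicochemical groups, ribonucleotides are their own
    groups.  The 4^3 = 64 window counts are normalized to frequencies.

Drugs
    Morgan (circular, radius 2) 1024-bit fingerprints from SMILES,
    compressed to 64 dimensions by the stacked autoencoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autoencoder import SAEModel, encode, train_sae
from .man_graph import NodeRef, normalize_id

logger = logging.getLogger(__name__)

ATTR_DIM = 64

#: Physicochemical amino-acid groups (group index 0..3).
PROTEIN_GROUPS: dict[str, int] = {}
for _i, _letters in enumerate(("AVLIMFWP", "GSTCNQY", "RKH", "DE")):
    for _c in _letters:
        PROTEIN_GROUPS[_c] = _i

RNA_GROUPS = {"A": 0, "C": 1, "G": 2, "U": 3}


class AttributeUnavailable(ValueError):
    """Raised when a node's raw data cannot yield an attribute vector."""


@dataclass
class SAEConfig:
    """Stacked-autoencoder settings used for drug and disease compression."""

    hidden: tuple[int, ...] = (256,)
    epochs: int = 50
    lr: float = 0.01
    batch_size: int = 16


# ---------------------------------------------------------------------------
# Disease semantic similarity
# ---------------------------------------------------------------------------

@dataclass
class MeshTable:
    """Flattened MeSH: descriptor -> tree numbers, plus the reverse map."""

    tree_numbers: dict[str, list[str]]
    names: dict[str, str] = field(default_factory=dict)
    by_tree_number: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.by_tree_number = {}
        for desc, tns in self.tree_numbers.items():
            for tn in tns:
                self.by_tree_number[tn] = desc

    def __contains__(self, descriptor: str) -> bool:
        return descriptor in self.tree_numbers


def load_mesh_table(path: str | Path) -> MeshTable:
    """Read TSV ``descriptor_id<TAB>name<TAB>tree_number`` (one row per
    tree number).  Descriptor ids are case-folded to match disease node
    normalization."""
    tns: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            desc = normalize_id(parts[0], "disease")
            tns.setdefault(desc, []).append(parts[2].strip())
            names[desc] = parts[1].strip()
    return MeshTable(tree_numbers=tns, names=names)


@dataclass
class DiseaseDAG:
    """Ancestor DAG of one disease: members, parent->children links, and
    the shortest hop count from the disease up to each member."""

    disease: NodeRef
    members: set[str]
    children: dict[str, set[str]]
    depth: dict[str, int]


def build_disease_dag(disease: NodeRef, mesh: MeshTable) -> DiseaseDAG:
    """Union, over the disease's tree numbers, of every prefix's descriptor.

    A prefix whose descriptor is absent from the table is skipped (its
    child links jump to the nearest present ancestor).
    """
    key = normalize_id(disease.id, "disease")
    if key not in mesh:
        raise AttributeUnavailable(f"disease {disease.id!r} has no MeSH entry")
    members: set[str] = {key}
    children: dict[str, set[str]] = {}
    for tn in mesh.tree_numbers[key]:
        segs = tn.split(".")
        chain: list[str] = [key]  # the full tree number is the disease itself
        for i in range(len(segs) - 1, 0, -1):
            prefix = ".".join(segs[:i])
            desc = mesh.by_tree_number.get(prefix)
            if desc is None:
                logger.warning(
                    "tree number prefix %s has no descriptor; skipped", prefix
                )
                continue
            chain.append(desc)
        # chain runs from the disease itself up to the root
        for lower, upper in zip(chain, chain[1:]):
            members.add(upper)
            if upper != lower:
                children.setdefault(upper, set()).add(lower)
    # shortest hop count from the disease, walking child -> parent
    parents: dict[str, set[str]] = {}
    for p, cs in children.items():
        for c in cs:
            parents.setdefault(c, set()).add(p)
    depth = {key: 0}
    frontier = [key]
    while frontier:
        nxt = []
        for d in frontier:
            for p in parents.get(d, ()):
                if p not in depth:
                    depth[p] = depth[d] + 1
                    nxt.append(p)
        frontier = nxt
    members = set(depth)  # members unreachable from e cannot contribute
    children = {
        p: {c for c in cs if c in members} for p, cs in children.items() if p in members
    }
    return DiseaseDAG(disease=disease, members=members, children=children, depth=depth)


@dataclass
class SemanticContribution:
    """Contributions C_e(d) of every DAG member and their sum DV(e)."""

    disease: NodeRef
    epsilon: float
    contributions: dict[str, float]

    @property
    def dv(self) -> float:
        return sum(self.contributions.values())


def semantic_contribution(dag: DiseaseDAG, epsilon: float = 0.5) -> SemanticContribution:
    """Recursive max rule: C_e(e)=1, C_e(d)=max_{d' child of d} eps*C_e(d')."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0,1), got {epsilon}")
    root = normalize_id(dag.disease.id, "disease")
    memo: dict[str, float] = {}

    def rec(d: str, on_path: frozenset[str]) -> float:
        if d == root:
            return 1.0
        if d in memo:
            return memo[d]
        best = 0.0
        for c in dag.children.get(d, ()):
            if c in on_path:  # guard against malformed cyclic input
                continue
            best = max(best, epsilon * rec(c, on_path | {d}))
        memo[d] = best
        return best

    contrib = {d: rec(d, frozenset()) for d in sorted(dag.members)}
    return SemanticContribution(disease=dag.disease, epsilon=epsilon, contributions=contrib)


def semantic_similarity(ci: SemanticContribution, cj: SemanticContribution) -> float:
    """SV1 similarity from shared DAG members; symmetric, in [0, 1]."""
    if ci.epsilon != cj.epsilon:
        raise ValueError("contributions built with different epsilon")
    shared = ci.contributions.keys() & cj.contributions.keys()
    num = sum(ci.contributions[d] + cj.contributions[d] for d in shared)
    return num / (ci.dv + cj.dv)


def disease_attribute_matrix(
    diseases: list[NodeRef],
    mesh: MeshTable,
    epsilon: float = 0.5,
    sae_config: SAEConfig | None = None,
    seed: int = 0,
) -> tuple[dict[NodeRef, np.ndarray], list[NodeRef], np.ndarray]:
    """Pairwise SV1 matrix over all diseases with a DAG, each row brought
    to width 64.

    Returns (attribute map, flagged diseases without a DAG, raw similarity
    matrix in the order of the non-flagged diseases).  When the number of
    diseases is at most 64 the rows are zero-padded (lossless); above 64
    they are compressed by the stacked autoencoder.
    """
    sae_config = sae_config or SAEConfig()
    contribs: dict[NodeRef, SemanticContribution] = {}
    flagged: list[NodeRef] = []
    for d in diseases:
        try:
            contribs[d] = semantic_contribution(build_disease_dag(d, mesh), epsilon)
        except AttributeUnavailable:
            flagged.append(d)
            logger.warning("disease %r: no DAG; attribute flagged missing", d.id)
    ok = [d for d in diseases if d in contribs]
    if len(ok) < 2:
        raise AttributeUnavailable("fewer than 2 diseases have a MeSH DAG")
    n = len(ok)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = semantic_similarity(contribs[ok[i]], contribs[ok[j]])
    if n <= ATTR_DIM:
        rows = np.zeros((n, ATTR_DIM))
        rows[:, :n] = sim
    else:
        widths = [n] + [w for w in sae_config.hidden if ATTR_DIM < w < n] + [ATTR_DIM]
        model = train_sae(
            sim, widths, epochs=sae_config.epochs, lr=sae_config.lr,
            batch_size=sae_config.batch_size, seed=seed,
        )
        rows = encode(model, sim)
    return {d: rows[i] for i, d in enumerate(ok)}, flagged, sim


# ---------------------------------------------------------------------------
# Sequence 3-mer features
# ---------------------------------------------------------------------------

def kmer_vector(sequence: str, alphabet_kind: str) -> np.ndarray:
    """Grouped 3-mer frequency vector, length 64, entries >= 0, sum 1.

    Residues outside the alphabet are removed before windowing (DNA-style
    'T' is first mapped to 'U' for RNA).  A cleaned sequence shorter than
    3 cannot yield a window and raises :class:`AttributeUnavailable`.
    """
    if alphabet_kind == "protein":
        groups = PROTEIN_GROUPS
        seq = sequence.upper()
    elif alphabet_kind == "rna":
        groups = RNA_GROUPS
        seq = sequence.upper().replace("T", "U")
    else:
        raise ValueError(f"alphabet_kind must be 'protein' or 'rna', got {alphabet_kind!r}")
    codes = [groups[c] for c in seq if c in groups]
    dropped = len(seq) - len(codes)
    if dropped:
        logger.info("kmer_vector: dropped %d out-of-alphabet residues", dropped)
    if len(codes) < 3:
        raise AttributeUnavailable(
            f"sequence too short after cleaning ({len(codes)} residues)"
        )
    arr = np.asarray(codes)
    cells = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
    vec = np.bincount(cells, minlength=ATTR_DIM).astype(np.float64)
    return vec / vec.sum()


# ---------------------------------------------------------------------------
# Drug fingerprints
# ---------------------------------------------------------------------------

def drug_fingerprint(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Morgan circular fingerprint bit vector from a SMILES string."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AttributeUnavailable(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.float64)


def load_drug_table(path: str | Path) -> dict[str, str]:
    """TSV ``drug_id<TAB>smiles``."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            drug_id, smiles = line.rstrip("\n").split("\t")[:2]
            out[drug_id.strip()] = smiles.strip()
    return out


def load_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records keyed by record id (must match node ids)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Attribute store
# ---------------------------------------------------------------------------

@dataclass
class AttributeStore:
    """Width-64 attribute per node; flagged nodes hold a zero vector and
    are excluded from classifier training pairs."""

    vectors: dict[NodeRef, np.ndarray] = field(default_factory=dict)
    flagged: dict[NodeRef, str] = field(default_factory=dict)

    def get(self, node: NodeRef) -> np.ndarray:
        return self.vectors[node]

    def usable(self, node: NodeRef) -> bool:
        return node in self.vectors and node not in self.flagged

    def add(self, node: NodeRef, vec: np.ndarray) -> None:
        v = np.asarray(vec, dtype=np.float64)
        if v.shape != (ATTR_DIM,):
            raise ValueError(f"attribute for {node.id!r} has shape {v.shape}")
        self.vectors[node] = v

    def flag(self, node: NodeRef, reason: str) -> None:
        self.vectors[node] = np.zeros(ATTR_DIM)
        self.flagged[node] = reason
        logger.warning("node %s/%s flagged: %s", node.kind, node.id, reason)


def build_attribute_store(
    nodes: list[NodeRef],
    *,
    mesh: MeshTable | None = None,
    protein_seqs: dict[str, str] | None = None,
    rna_seqs: dict[str, str] | None = None,
    smiles: dict[str, str] | None = None,
    epsilon: float = 0.5,
    sae_config: SAEConfig | None = None,
    seed: int = 0,
) -> AttributeStore:
    """Compute attributes for every node of every kind present in *nodes*."""
    sae_config = sae_config or SAEConfig()
    store = AttributeStore()
    protein_seqs = protein_seqs or {}
    rna_seqs = rna_seqs or {}
    smiles = smiles or {}

    diseases = [n for n in nodes if n.kind == "disease"]
    if diseases:
        if mesh is None:
            raise ValueError("disease nodes present but no MeSH table given")
        attrs, flagged, _ = disease_attribute_matrix(
            diseases, mesh, epsilon=epsilon, sae_config=sae_config, seed=seed
        )
        for d, vec in attrs.items():
            store.add(d, vec)
        for d in flagged:
            store.flag(d, "no MeSH DAG")

    for n in nodes:
        if n.kind == "protein":
            self_seqs, kind = protein_seqs, "protein"
        elif n.kind in ("mirna", "lncrna"):
            self_seqs, kind = rna_seqs, "rna"
        else:
            continue
        seq = self_seqs.get(n.id)
        if seq is None:
            store.flag(n, "no sequence")
            continue
        try:
            store.add(n, kmer_vector(seq, kind))
        except AttributeUnavailable as exc:
            store.flag(n, str(exc))

    drugs = [n for n in nodes if n.kind == "drug"]
    if drugs:
        fps: dict[NodeRef, np.ndarray] = {}
        for d in drugs:
            smi = smiles.get(d.id)
            if smi is None:
                store.flag(d, "no SMILES")
                continue
            try:
                fps[d] = drug_fingerprint(smi)
            except AttributeUnavailable as exc:
                store.flag(d, str(exc))
        if len(fps) >= 2:
            mat = np.vstack(list(fps.values()))
            widths = [mat.shape[1]] + list(sae_config.hidden) + [ATTR_DIM]
            model = train_sae(
                mat, widths, epochs=sae_config.epochs, lr=sae_config.lr,
                batch_size=sae_config.batch_size, seed=seed + 1,
            )
            codes = encode(model, mat)
            for d, code in zip(fps, codes):
                store.add(d, code)
        else:
            for d in fps:
                store.flag(d, "too few drugs to train the autoencoder")
    return store
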