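import numpy as np
import pytest

from manlink.attributes import (
    AttributeUnavailable,
    DiseaseDAG,
    SAEConfig,
    build_attribute_store,
    build_disease_dag,
    disease_attribute_matrix,
    drug_fingerprint,
    kmer_vector,
    semantic_contribution,
    semantic_similarity,
)
from manlink.autoencoder import SAEError, encode, train_sae
from manlink.man_graph import NodeRef

from conftest import disease, mesh_from_rows


# ---------------------------------------------------------------------------
# DAG construction
# ---------------------------------------------------------------------------

def test_root_descriptor_dag_is_singleton():
    mesh = mesh_from_rows([("d1", "root disease", "C01")])
    dag = build_disease_dag(disease(1), mesh)
    assert dag.members == {"d1"}
    assert dag.depth == {"d1": 0}


def test_chain_dag_members_and_depth():
    mesh = mesh_from_rows(
        [("a", "A", "C01"), ("b", "B", "C01.100"), ("c", "C", "C01.100.200")]
    )
    dag = build_disease_dag(NodeRef("c", "disease"), mesh)
    assert dag.members == {"a", "b", "c"}
    assert dag.depth == {"c": 0, "b": 1, "a": 2}
    assert dag.children == {"a": {"b"}, "b": {"c"}}


def test_two_tree_numbers_shared_ancestor_appears_once():
    mesh = mesh_from_rows(
        [
            ("root", "shared root", "C05"),
            ("m1", "mid 1", "C05.1"),
            ("m2", "mid 2", "C05.2"),
            ("e", "query", "C05.1.9"),
            ("e", "query", "C05.2.9"),
        ]
    )
    dag = build_disease_dag(NodeRef("e", "disease"), mesh)
    assert dag.members == {"root", "m1", "m2", "e"}
    assert dag.depth["root"] == 2


def test_missing_disease_flags_no_dag():
    mesh = mesh_from_rows([("other", "x", "C01")])
    with pytest.raises(AttributeUnavailable):
        build_disease_dag(disease(1), mesh)


# ---------------------------------------------------------------------------
# Semantic contributions (recursive max rule vs brute force)
# ---------------------------------------------------------------------------

def brute_force_contribution(dag: DiseaseDAG, epsilon: float) -> dict[str, float]:
    """Independent oracle: enumerate every descending path from each member
    to the disease; the contribution is the max of epsilon^path_length."""
    root = dag.disease.id

    def paths(d, seen):
        if d == root:
            yield 0
            return
        for c in dag.children.get(d, ()):
            if c in seen:
                continue
            for length in paths(c, seen | {c}):
                yield length + 1

    out = {}
    for d in dag.members:
        lengths = list(paths(d, {d}))
        out[d] = max((epsilon**k for k in lengths), default=0.0)
    out[root] = 1.0
    return out


def random_dag(rng: np.random.Generator, n_max: int = 20) -> DiseaseDAG:
    """Random ancestor DAG: every member above the disease links down to at
    least one previously created member, guaranteeing a path to it."""
    n = int(rng.integers(1, n_max + 1))
    names = [f"m{i}" for i in range(n)]
    children: dict[str, set[str]] = {}
    for i in range(1, n):
        k = int(rng.integers(1, min(i, 3) + 1))
        kids = rng.choice(i, size=k, replace=False)
        children[names[i]] = {names[j] for j in kids}
    node = NodeRef(names[0], "disease")
    # depth map is irrelevant to the contribution recursion; fill via oracle
    return DiseaseDAG(disease=node, members=set(names), children=children, depth={})


def test_contribution_base_cases():
    mesh = mesh_from_rows([("e", "solo", "C09")])
    dag = build_disease_dag(NodeRef("e", "disease"), mesh)
    for eps in (0.1, 0.5, 0.9):
        assert semantic_contribution(dag, eps).dv == 1.0


def test_contribution_chain_hand_value():
    mesh = mesh_from_rows([("p", "parent", "C01"), ("e", "child", "C01.5")])
    dag = build_disease_dag(NodeRef("e", "disease"), mesh)
    c = semantic_contribution(dag, 0.5)
    assert c.contributions == {"e": 1.0, "p": 0.5}
    assert c.dv == 1.5


def test_contribution_diamond_takes_max_over_paths():
    # p reachable from e at depth 1 (direct) and depth 2 (via m)
    mesh = mesh_from_rows(
        [
            ("p", "apex", "C01"),
            ("m", "mid", "C01.2"),
            ("e", "query", "C01.9"),
            ("e", "query", "C01.2.9"),
        ]
    )
    dag = build_disease_dag(NodeRef("e", "disease"), mesh)
    c = semantic_contribution(dag, 0.5)
    assert c.contributions["p"] == pytest.approx(max(0.5, 0.25))


def test_epsilon_out_of_range_rejected():
    mesh = mesh_from_rows([("e", "solo", "C01")])
    dag = build_disease_dag(NodeRef("e", "disease"), mesh)
    for eps in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            semantic_contribution(dag, eps)


def test_recursion_equals_brute_force_on_random_dags():
    rng = np.random.default_rng(42)
    for _ in range(200):
        dag = random_dag(rng)
        eps = float(rng.uniform(0.05, 0.95))
        got = semantic_contribution(dag, eps).contributions
        want = brute_force_contribution(dag, eps)
        assert got.keys() == want.keys()
        for d in want:
            assert got[d] == pytest.approx(want[d], abs=1e-12)


# ---------------------------------------------------------------------------
# Semantic similarity
# ---------------------------------------------------------------------------

def _contrib(rows, did, eps=0.5):
    mesh = mesh_from_rows(rows)
    return semantic_contribution(build_disease_dag(NodeRef(did, "disease"), mesh), eps)


def test_identical_diseases_similarity_one():
    rows = [("p", "parent", "C01"), ("e", "child", "C01.5")]
    c = _contrib(rows, "e")
    assert semantic_similarity(c, c) == pytest.approx(1.0)


def test_disjoint_dags_similarity_zero():
    c1 = _contrib([("e1", "x", "C01")], "e1")
    c2 = _contrib([("e2", "y", "C02")], "e2")
    assert semantic_similarity(c1, c2) == 0.0


def test_shared_parent_hand_value():
    rows = [
        ("p", "parent", "C01"),
        ("e1", "left", "C01.1"),
        ("e2", "right", "C01.2"),
    ]
    c1 = _contrib(rows, "e1")
    c2 = _contrib(rows, "e2")
    sv = semantic_similarity(c1, c2)
    assert sv == pytest.approx((0.5 + 0.5) / (1.5 + 1.5))
    assert semantic_similarity(c2, c1) == pytest.approx(sv)


def test_adding_shared_ancestor_never_decreases_similarity():
    shallow = [
        ("p", "parent", "C01"),
        ("e1", "left", "C01.1"),
        ("e2", "right", "C01.2"),
    ]
    deeper = [
        ("g", "grandparent", "C01"),
        ("p", "parent", "C01.3"),
        ("e1", "left", "C01.3.1"),
        ("e2", "right", "C01.3.2"),
    ]
    before = semantic_similarity(_contrib(shallow, "e1"), _contrib(shallow, "e2"))
    after = semantic_similarity(_contrib(deeper, "e1"), _contrib(deeper, "e2"))
    assert after >= before


def test_mismatched_epsilon_rejected():
    rows = [("e1", "x", "C01"), ("e2", "y", "C01.2")]
    with pytest.raises(ValueError):
        semantic_similarity(_contrib(rows, "e1", 0.5), _contrib(rows, "e2", 0.4))


# ---------------------------------------------------------------------------
# Disease attribute matrix
# ---------------------------------------------------------------------------

def test_identical_diseases_give_all_ones_matrix():
    # the same disease listed twice is maximally similar to itself
    rows = [("x", "x", "C01.1"), ("r", "root", "C01")]
    mesh = mesh_from_rows(rows)
    attrs, flagged, sim = disease_attribute_matrix(
        [NodeRef("x", "disease"), NodeRef("x", "disease")], mesh
    )
    assert not flagged
    np.testing.assert_allclose(sim, np.ones((2, 2)))


def test_similarity_matrix_symmetric_and_padded(default_synthetic):
    d = default_synthetic
    diseases = d["graph"].nodes_of_kind("disease")
    attrs, flagged, sim = disease_attribute_matrix(diseases, d["mesh"])
    assert not flagged
    np.testing.assert_allclose(sim, sim.T)
    np.testing.assert_allclose(np.diag(sim), 1.0)
    assert all(v.shape == (64,) for v in attrs.values())


def test_many_diseases_compressed_to_64(default_synthetic):
    # above 64 diseases the autoencoder path engages
    rows = []
    for i in range(100):
        branch = i % 5
        rows.append((f"dd{i}", f"dis {i}", f"C{branch + 1:02d}.{100 + i}"))
        if i < 5:
            rows.append((f"root{i}", "root", f"C{i + 1:02d}"))
    mesh = mesh_from_rows(rows)
    nodes = [NodeRef(f"dd{i}", "disease") for i in range(100)]
    attrs, _, sim = disease_attribute_matrix(
        nodes, mesh, sae_config=SAEConfig(epochs=5)
    )
    assert sim.shape == (100, 100)
    assert all(v.shape == (64,) for v in attrs.values())


# ---------------------------------------------------------------------------
# k-mer vectors
# ---------------------------------------------------------------------------

def test_protein_single_window():
    v = kmer_vector("AAA", "protein")
    assert v.shape == (64,)
    assert v[0] == 1.0 and v.sum() == 1.0


def test_rna_two_windows():
    v = kmer_vector("ACGU", "rna")
    acg = 0 * 16 + 1 * 4 + 2
    cgu = 1 * 16 + 2 * 4 + 3
    assert v[acg] == 0.5 and v[cgu] == 0.5 and v.sum() == 1.0


def test_random_rna_normalized():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGU"), size=1000))
    v = kmer_vector(seq, "rna")
    assert v.shape == (64,)
    assert np.all(v >= 0)
    assert v.sum() == pytest.approx(1.0, abs=1e-9)


def test_dna_thymine_mapped_to_uracil():
    np.testing.assert_allclose(kmer_vector("ACGT", "rna"), kmer_vector("ACGU", "rna"))


def test_out_of_alphabet_residues_dropped():
    np.testing.assert_allclose(
        kmer_vector("AXC*GU", "rna"), kmer_vector("ACGU", "rna")
    )


def test_too_short_sequence_flagged():
    with pytest.raises(AttributeUnavailable):
        kmer_vector("AC", "rna")
    with pytest.raises(AttributeUnavailable):
        kmer_vector("AXXXC", "rna")  # only 2 valid residues


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGUTNX-", min_size=3, max_size=200))
def test_kmer_vector_is_a_distribution_or_flags(seq):
    try:
        v = kmer_vector(seq, "rna")
    except AttributeUnavailable:
        cleaned = [c for c in seq.upper().replace("T", "U") if c in "ACGU"]
        assert len(cleaned) < 3
        return
    assert v.shape == (64,) and np.all(v >= 0)
    assert v.sum() == pytest.approx(1.0, abs=1e-9)


def test_grouped_protein_alphabet():
    # V and A share a group; D and E share a group
    np.testing.assert_allclose(
        kmer_vector("AVA", "protein"), kmer_vector("VAV", "protein")
    )
    np.testing.assert_allclose(
        kmer_vector("DED", "protein"), kmer_vector("EDE", "protein")
    )


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def test_fingerprint_deterministic():
    np.testing.assert_array_equal(
        drug_fingerprint("CCO"), drug_fingerprint("CCO")
    )


def test_fingerprint_distinguishes_molecules():
    assert not np.array_equal(drug_fingerprint("C"), drug_fingerprint("CCO"))


def test_fingerprint_canonicalization_invariant():
    # two SMILES spellings of ethanol
    np.testing.assert_array_equal(
        drug_fingerprint("OCC"), drug_fingerprint("CCO")
    )


def test_unparseable_smiles_flagged():
    with pytest.raises(AttributeUnavailable):
        drug_fingerprint("not_a_molecule((")


# ---------------------------------------------------------------------------
# Stacked autoencoder
# ---------------------------------------------------------------------------

def test_identity_passthrough_when_already_at_code_width():
    x = np.random.default_rng(0).random((5, 64))
    model = train_sae(x, [64])
    np.testing.assert_array_equal(encode(model, x), x)


def test_training_reproducible_under_fixed_seed():
    rng = np.random.default_rng(1)
    x = (rng.random((50, 256)) < 0.1).astype(float)
    m1 = train_sae(x, [256, 64], epochs=3, seed=9)
    m2 = train_sae(x, [256, 64], epochs=3, seed=9)
    np.testing.assert_array_equal(encode(m1, x), encode(m2, x))


def test_compressible_input_loss_halves():
    rng = np.random.default_rng(2)
    base = rng.random(128)
    x = np.outer(rng.random(60), base)  # rank-1, highly compressible
    model = train_sae(x, [128, 64], epochs=150, lr=0.1, seed=0)
    trace = model.loss_trace[0]
    assert trace[-1] <= 0.5 * trace[0]


def test_encode_shapes_and_determinism():
    rng = np.random.default_rng(3)
    x = rng.random((10, 128))
    model = train_sae(x, [128, 64], epochs=2, seed=0)
    out = encode(model, x)
    assert out.shape == (10, 64)
    assert encode(model, np.zeros((0, 128))).shape == (0, 64)
    doubled = encode(model, np.vstack([x, x]))
    np.testing.assert_array_equal(doubled[:10], doubled[10:])


def test_width_mismatch_and_bad_widths_rejected():
    x = np.random.default_rng(0).random((4, 100))
    with pytest.raises(SAEError):
        train_sae(x, [100, 120, 64])  # not decreasing
    model = train_sae(x, [100, 64], epochs=1)
    with pytest.raises(SAEError):
        encode(model, np.zeros((2, 99)))


# ---------------------------------------------------------------------------
# Attribute store
# ---------------------------------------------------------------------------

def test_store_flags_missing_inputs(default_synthetic):
    d = default_synthetic
    g = d["graph"]
    smiles = dict(d["smiles"])
    drugs = g.nodes_of_kind("drug")
    bad = drugs[0]
    smiles[bad.id] = "((("
    store = build_attribute_store(
        g.nodes,
        mesh=d["mesh"],
        protein_seqs=d["protein_seqs"],
        rna_seqs=d["rna_seqs"],
        smiles=smiles,
        seed=5,
    )
    assert not store.usable(bad)
    np.testing.assert_array_equal(store.get(bad), np.zeros(64))
    good = [n for n in g.nodes if store.usable(n)]
    assert len(good) == len(g.nodes) - 1
    assert all(store.get(n).shape == (64,) for n in g.nodes)
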