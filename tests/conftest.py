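import numpy as np
import pytest

from manlink.attributes import MeshTable, build_attribute_store
from manlink.man_graph import AssociationEdge, MANGraph, NodeRef
from manlink.synthetic import (
    SyntheticSpec,
    generate_drug_table,
    generate_man,
    generate_mesh_table,
    generate_sequences,
)


def protein(i: int) -> NodeRef:
    return NodeRef(f"P{i}", "protein")


def drug(i: int) -> NodeRef:
    return NodeRef(f"DR{i}", "drug")


def disease(i: int) -> NodeRef:
    return NodeRef(f"d{i}", "disease")


def protein_clique(ids, offset=0) -> list[AssociationEdge]:
    nodes = [protein(i + offset) for i in ids]
    return [
        AssociationEdge(nodes[i], nodes[j], "protein-protein")
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
    ]


def mesh_from_rows(rows) -> MeshTable:
    tns, names = {}, {}
    for desc, name, tn in rows:
        tns.setdefault(desc, []).append(tn)
        names[desc] = name
    return MeshTable(tree_numbers=tns, names=names)


@pytest.fixture(scope="session")
def triangle_graph() -> MANGraph:
    return MANGraph(protein_clique([0, 1, 2]))


@pytest.fixture(scope="session")
def default_synthetic():
    """Default-scale planted-signal network with all attribute inputs."""
    spec = SyntheticSpec(seed=1)
    g, truth = generate_man(spec)
    rng = np.random.default_rng(1001)
    nodes = spec.kind_nodes()
    prot = generate_sequences(
        nodes["protein"], "protein", truth.communities, spec.seq_len_range, rng
    )
    rna = generate_sequences(
        nodes["mirna"] + nodes["lncrna"], "rna", truth.communities,
        spec.seq_len_range, rng,
    )
    smiles = generate_drug_table(nodes["drug"], truth.communities, rng)
    mesh = mesh_from_rows(generate_mesh_table(nodes["disease"], truth.communities, rng))
    return {
        "spec": spec,
        "graph": g,
        "truth": truth,
        "protein_seqs": prot,
        "rna_seqs": rna,
        "smiles": smiles,
        "mesh": mesh,
    }


@pytest.fixture(scope="session")
def default_attributes(default_synthetic):
    d = default_synthetic
    return build_attribute_store(
        d["graph"].nodes,
        mesh=d["mesh"],
        protein_seqs=d["protein_seqs"],
        rna_seqs=d["rna_seqs"],
        smiles=d["smiles"],
        seed=5,
    )
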