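import networkx as nx
import numpy as np
import pytest

from funcshift.structgraph import Atom, Residue, RootedEnvironment, Structure


def build_env(labels: dict, edges, root) -> RootedEnvironment:
    """Rooted labeled environment from a {vertex: label} map and edge list."""
    g = nx.Graph()
    for v, lab in labels.items():
        g.add_node(v, label=lab, aa=lab.upper())
    g.add_edges_from(edges)
    return RootedEnvironment(graph=g, root=root, level=99)


def build_structure(
    chains: dict,
    structure_id: str = "toy",
    resolution: float = 1.5,
    het_atoms=(),
) -> Structure:
    """Structure from {chain: [(index, aa, [(element, name, xyz), ...])]}."""
    out = {}
    for chain_id, residues in chains.items():
        out[chain_id] = [
            Residue(
                chain=chain_id,
                index=str(index),
                aa=aa,
                atoms=tuple(Atom(element=e, name=n, xyz=tuple(x)) for e, n, x in atoms),
            )
            for index, aa, atoms in residues
        ]
    return Structure(
        id=structure_id,
        chains=out,
        het_atoms=list(het_atoms),
        resolution=resolution,
        experiment="X-RAY DIFFRACTION",
    )


def linear_chain_structure(
    seq: str, structure_id: str = "toy", resolution: float = 1.5, spacing: float = 3.8
) -> Structure:
    """A straight chain of CA-only residues with the given sequence."""
    residues = [
        (i + 1, aa, [("C", "CA", (i * spacing, 0.0, 0.0))])
        for i, aa in enumerate(seq)
    ]
    return build_structure(
        {"A": residues}, structure_id=structure_id, resolution=resolution
    )


@pytest.fixture
def env_factory():
    return build_env


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
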