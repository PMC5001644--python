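"""Protein structures, residue contact graphs and variant mapping.

The module turns a PDB-format structure into a vertex-labeled residue
contact graph: every standard amino acid residue becomes a vertex and two
residues are joined when they are spatially close (by default, any pair of
atoms within 4.5 Å; a 6 Å Cα–Cα rule is available as an alternative).
Functional-site labels for metal binding are derived from geometry (a
residue coordinates a metal ion when one of its N, O or S atoms lies
within 3 Å of the ion).  Sequence variants are mapped onto structure
residues through exact matching of a 51-residue window against the
atom-record-derived sequences of quality-filtered structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .registry import METAL_ELEMENTS

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA20 = tuple(sorted(AA3_TO_1.values()))
AA40 = tuple(sorted(AA3_TO_1.values()) + sorted(a.lower() for a in AA3_TO_1.values()))


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class ContactRuleError(ValueError):
    """Raised when residues lack the atoms required by a contact rule."""


class Atom(NamedTuple):
    element: str
    name: str
    xyz: tuple


@dataclass(frozen=True)
class Residue:
    """A standard amino acid residue with author numbering.

    ``index`` is the author residue number with any insertion code
    concatenated (e.g. ``"83"`` or ``"100A"``).
    """

    chain: str
    index: str
    aa: str
    atoms: tuple

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class HetAtom:
    element: str
    name: str
    resname: str
    chain: str
    index: str
    xyz: tuple


@dataclass
class Structure:
    id: str
    chains: dict  # chain id -> list[Residue]
    het_atoms: list = field(default_factory=list)
    resolution: Optional[float] = None
    experiment: str = ""

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    def residue(self, chain: str, index: str) -> Residue:
        for r in self.chains[chain]:
            if r.index == index:
                return r
        raise KeyError(f"no residue {chain}:{index} in structure {self.id}")

    def sequence(self, chain: str) -> tuple:
        """Return (one-letter sequence, residue index list) for a chain."""
        residues = self.chains[chain]
        return "".join(r.aa for r in residues), [r.index for r in residues]


@dataclass
class ContactGraph:
    """Vertex-labeled residue contact graph.

    Vertices are ``(chain, index)`` tuples with node attributes ``aa``
    (the amino acid) and ``label`` (a symbol from the alphabet: the amino
    acid itself for |Σ| = 20, or a case-split conservation class for
    |Σ| = 40).
    """

    graph: nx.Graph
    alphabet: tuple

    def label(self, node) -> str:
        return self.graph.nodes[node]["label"]


@dataclass
class RootedEnvironment:
    """A residue microenvironment: the contact graph restricted to a BFS
    ball of radius ``level`` around ``root``."""

    graph: nx.Graph
    root: object
    level: int

    def labels(self) -> dict:
        return {v: d["label"] for v, d in self.graph.nodes(data=True)}


@dataclass(frozen=True)
class VariantRecord:
    protein: str
    position: int  # 1-based
    wt_aa: str
    mt_aa: str
    mapped: Optional[tuple] = None  # (structure id, chain, residue index)
    reason: str = ""

    def __post_init__(self):
        if self.wt_aa == self.mt_aa:
            raise ValueError("wild-type and mutant amino acids must differ")


@dataclass(frozen=True)
class SiteLabel:
    chain: str
    index: str
    function: str
    evidence: str = "geometry"


def _residue_index(seqid) -> str:
    icode = seqid.icode.strip() if seqid.icode else ""
    return f"{seqid.num}{icode}"


def parse_structure(text: str, structure_id: str = "struct") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc identifier).  Non-standard polymer residues are
    dropped with a logged warning.  HETATM records are retained as
    heteroatoms so that metal ions and ligands stay available for
    geometric site labeling.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ParseError(f"truncated coordinate record at line {lineno}")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"malformed {what} coordinate at line {lineno}: "
                        f"{line[lo:hi]!r}"
                    ) from None
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise ParseError(f"malformed PDB record: {exc}") from exc
    if len(st) == 0:
        raise ParseError("no model found in structure text")
    if st.name:
        structure_id = st.name.lower() if structure_id == "struct" else structure_id

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    try:
        experiment = st.info["_exptl.method"]
    except (AttributeError, KeyError):
        experiment = ""

    chains: dict = {}
    het_atoms: list = []
    n_atom_records = 0
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.name not in AA3_TO_1:
                if res.name in ("HOH", "WAT", "DOD"):
                    continue
                if res.het_flag != "H" and res.name not in AA3_TO_1:
                    logger.warning(
                        "dropping non-standard residue %s %s:%s",
                        res.name, chain.name, _residue_index(res.seqid),
                    )
                    continue
                for atom in res:
                    het_atoms.append(HetAtom(
                        element=atom.element.name.upper() or atom.name[:1],
                        name=atom.name,
                        resname=res.name,
                        chain=chain.name,
                        index=_residue_index(res.seqid),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    ))
                continue
            n_atom_records += 1
            # resolve altlocs: per atom name keep the highest-occupancy copy
            best: dict = {}
            for atom in res:
                key = atom.name
                alt = atom.altloc if atom.altloc not in ("\x00",) else ""
                cand = (atom.occ, "" if not alt else alt, atom)
                if key not in best:
                    best[key] = cand
                else:
                    prev_occ, prev_alt, _ = best[key]
                    if atom.occ > prev_occ or (
                        atom.occ == prev_occ and (alt or "~") < (prev_alt or "~")
                    ):
                        best[key] = cand
            atoms = tuple(
                Atom(
                    element=a.element.name.upper() or a.name[:1],
                    name=a.name,
                    xyz=(a.pos.x, a.pos.y, a.pos.z),
                )
                for _, _, a in best.values()
            )
            for a in atoms:
                if not all(math.isfinite(c) for c in a.xyz):
                    raise ParseError(
                        f"non-finite coordinates for atom {a.name} in "
                        f"{chain.name}:{_residue_index(res.seqid)}"
                    )
            chains.setdefault(chain.name, []).append(Residue(
                chain=chain.name,
                index=_residue_index(res.seqid),
                aa=AA3_TO_1[res.name],
                atoms=atoms,
            ))
    if n_atom_records == 0:
        raise ParseError("structure text contains no standard ATOM records")
    return Structure(
        id=structure_id, chains=chains, het_atoms=het_atoms,
        resolution=resolution, experiment=experiment,
    )


def build_contact_graph(
    s: Structure, rule: str = "any_atom", threshold: float = 4.5
) -> ContactGraph:
    """Build the residue contact graph of a structure.

    Under ``any_atom`` two residues are linked when their closest pair of
    atoms is within ``threshold`` Å; under ``c_alpha`` when their Cα atoms
    are (with the conventional 6 Å default in mind).
    """
    if rule not in ("any_atom", "c_alpha"):
        raise ValueError(f"unknown contact rule {rule!r}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    g = nx.Graph()
    residues = list(s.residues())
    for r in residues:
        g.add_node((r.chain, r.index), aa=r.aa, label=r.aa)

    if rule == "c_alpha":
        missing = [f"{r.chain}:{r.index}" for r in residues if r.atom("CA") is None]
        if missing:
            raise ContactRuleError(
                "residues lacking a CA atom under the c_alpha rule: "
                + ", ".join(missing)
            )
        coords = np.array([r.atom("CA").xyz for r in residues])
        owners = list(range(len(residues)))
    else:
        coords_list, owners = [], []
        for i, r in enumerate(residues):
            for a in r.atoms:
                coords_list.append(a.xyz)
                owners.append(i)
        coords = np.array(coords_list)

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(threshold):
        ri, rj = owners[i], owners[j]
        if ri != rj:
            u = (residues[ri].chain, residues[ri].index)
            v = (residues[rj].chain, residues[rj].index)
            g.add_edge(u, v)
    return ContactGraph(graph=g, alphabet=AA20)


def extract_environment(cg: ContactGraph, root, level: int) -> RootedEnvironment:
    """Induced subgraph on all vertices within ``level`` hops of ``root``."""
    g = cg if isinstance(cg, nx.Graph) else cg.graph
    if root not in g:
        raise KeyError(f"root {root!r} is not a vertex of the contact graph")
    if level < 0:
        raise ValueError("level must be nonnegative")
    ball = nx.single_source_shortest_path_length(g, root, cutoff=level)
    sub = g.subgraph(ball.keys()).copy()
    return RootedEnvironment(graph=sub, root=root, level=level)


def label_metal_sites(
    s: Structure,
    metal_codes: Optional[set] = None,
    threshold: float = 3.0,
) -> list:
    """Label residues coordinating a metal ion.

    A residue is labeled for metal M when at least one of its heavy N, O
    or S atoms lies within ``threshold`` Å (3 Å by default) of an M ion
    present among the structure's heteroatoms.
    """
    codes = set(metal_codes) if metal_codes is not None else set(METAL_ELEMENTS)
    labels: list = []
    seen: set = set()
    metals = [h for h in s.het_atoms if h.element.upper() in codes]
    if not metals:
        return []
    for r in s.residues():
        for a in r.atoms:
            if a.element.upper() not in ("N", "O", "S"):
                continue
            for ion in metals:
                d = math.dist(a.xyz, ion.xyz)
                if d <= threshold:
                    func = METAL_ELEMENTS.get(ion.element.upper(), ion.element)
                    key = (r.chain, r.index, func)
                    if key not in seen:
                        seen.add(key)
                        labels.append(SiteLabel(
                            chain=r.chain, index=r.index,
                            function=func, evidence="geometry",
                        ))
    return labels


def conservation_pivot(scores: Iterable[float]) -> float:
    """Median conservation over the whole data collection (the split pivot)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no conservation scores supplied")
    return float(np.median(arr))


def split_alphabet_by_conservation(
    cg: ContactGraph, scores: dict, pivot: float
) -> ContactGraph:
    """Split the 20-letter alphabet into 40 conservation classes.

    A vertex whose conservation score is >= ``pivot`` keeps the uppercase
    amino acid symbol (conserved class); below the pivot it is assigned the
    lowercase symbol.  Ties at the pivot go to the conserved class.  The
    underlying amino acid stays recoverable through the ``aa`` attribute.
    """
    g = cg.graph
    missing = [v for v in g.nodes if v not in scores]
    if missing:
        raise KeyError(
            "missing conservation scores for residues: "
            + ", ".join(str(v) for v in missing)
        )
    out = g.copy()
    for v, data in out.nodes(data=True):
        aa = data["aa"]
        data["label"] = aa.upper() if scores[v] >= pivot else aa.lower()
    return ContactGraph(graph=out, alphabet=AA40)


# ---------------------------------------------------------------------------
# Variant mapping


@dataclass(frozen=True)
class ChainSequence:
    structure_id: str
    chain: str
    seq: str
    indices: tuple
    resolution: float


class SequenceIndex:
    """Atom-record-derived sequences of structures passing quality filters
    (X-ray, more than 50 residues, resolution below 2.5 Å)."""

    def __init__(self, entries: Sequence[ChainSequence]):
        self.entries = list(entries)

    @classmethod
    def from_structures(
        cls,
        structures: Iterable[Structure],
        min_length: int = 51,
        max_resolution: float = 2.5,
        require_xray: bool = True,
    ) -> "SequenceIndex":
        entries = []
        for s in structures:
            if s.resolution is None or s.resolution >= max_resolution:
                continue
            if require_xray and s.experiment and "X-RAY" not in s.experiment.upper():
                continue
            for chain_id in s.chains:
                seq, indices = s.sequence(chain_id)
                if len(seq) < min_length:
                    continue
                entries.append(ChainSequence(
                    structure_id=s.id, chain=chain_id, seq=seq,
                    indices=tuple(indices), resolution=s.resolution,
                ))
        return cls(entries)


def map_variant_to_structure(
    v: VariantRecord,
    seq_db: SequenceIndex,
    protein_seqs: dict,
    window: int = 51,
) -> VariantRecord:
    """Map a sequence variant onto a structure residue.

    A ``window``-residue sequence centred on the variant position (clamped
    at the termini) is matched by exact substring search against every
    indexed chain.  Only 100%-identity matches qualify; among multiple
    hits the best (lowest) resolution wins, with lexicographic structure
    id as the deterministic tie-break.  Unmapped variants are returned
    flagged with a reason, never dropped silently.
    """
    if v.protein not in protein_seqs:
        return replace(v, mapped=None, reason="unknown protein sequence")
    seq = protein_seqs[v.protein]
    p = v.position - 1
    if p < 0 or p >= len(seq):
        return replace(v, mapped=None, reason="position outside protein sequence")
    if seq[p] != v.wt_aa:
        return replace(
            v, mapped=None,
            reason=f"wild-type mismatch: sequence has {seq[p]} at position {v.position}",
        )
    half = window // 2
    start = max(0, p - half)
    end = min(len(seq), p + half + 1)
    frag = seq[start:end]
    offset = p - start

    hits = []
    for entry in seq_db.entries:
        pos = entry.seq.find(frag)
        while pos != -1:
            hits.append((entry, pos))
            pos = entry.seq.find(frag, pos + 1)
    if not hits:
        return replace(v, mapped=None, reason="no exact 100%-identity match")
    entry, pos = min(
        hits, key=lambda h: (h[0].resolution, h[0].structure_id, h[0].chain, h[1])
    )
    res_index = entry.indices[pos + offset]
    if entry.seq[pos + offset] != v.wt_aa:  # defensive; exact match implies equality
        return replace(v, mapped=None, reason="wild-type mismatch at matched residue")
    return replace(
        v, mapped=(entry.structure_id, entry.chain, res_index), reason=""
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def node_key(node) -> str:
    return f"{node[0]}:{node[1]}"


def parse_node_key(key: str) -> tuple:
    chain, index = key.split(":", 1)
    return chain, index


def write_contact_graph(cg: ContactGraph, edges_path, vertices_path) -> None:
    edges = pd.DataFrame(
        [(node_key(u), node_key(v)) for u, v in sorted(cg.graph.edges())],
        columns=["u", "v"],
    )
    edges.to_csv(edges_path, sep="\t", index=False)
    verts = pd.DataFrame(
        [
            (node_key(v), d["aa"], d["label"])
            for v, d in sorted(cg.graph.nodes(data=True))
        ],
        columns=["vertex", "aa", "label"],
    )
    verts.to_csv(vertices_path, sep="\t", index=False)


def read_contact_graph(edges_path, vertices_path) -> ContactGraph:
    verts = pd.read_csv(vertices_path, sep="\t", dtype=str)
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    g = nx.Graph()
    for _, row in verts.iterrows():
        g.add_node(parse_node_key(row["vertex"]), aa=row["aa"], label=row["label"])
    for _, row in edges.iterrows():
        g.add_edge(parse_node_key(row["u"]), parse_node_key(row["v"]))
    labels = set(verts["label"])
    alphabet = AA40 if any(l.islower() for l in labels) else AA20
    return ContactGraph(graph=g, alphabet=alphabet)


def write_site_labels(labels: Sequence[SiteLabel], path) -> None:
    pd.DataFrame(
        [(l.chain, l.index, l.function, l.evidence) for l in labels],
        columns=["chain", "index", "function", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def read_site_labels(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SiteLabel(row["chain"], row["index"], row["function"], row["evidence"])
        for _, row in df.iterrows()
    ]


def write_variants(variants: Sequence[VariantRecord], path) -> None:
    pd.DataFrame(
        [(v.protein, v.position, v.wt_aa, v.mt_aa) for v in variants],
        columns=["protein", "position", "wt", "mt"],
    ).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantRecord(str(r["protein"]), int(r["position"]), str(r["wt"]), str(r["mt"]))
        for _, r in df.iterrows()
    ]
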