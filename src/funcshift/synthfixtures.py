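"""Synthetic inputs for tests, demos and the end-to-end pipeline.

Every generator is a pure function of its parameters and a mandatory seed,
and writes the same formats the real pipeline reads.  The structure
generator produces a coarse self-avoiding backbone walk with pseudo side
chains; geometry is deliberately unphysical except for the inter-atomic
distances every downstream rule consumes.  Planted metal sites place an
ion with k coordinating N/O/S atoms at 2.0-2.9 Å while keeping every
other heavy N/O/S atom beyond 3.5 Å, so geometric labeling recovers the
planted residues exactly.  Score mixtures use Beta components bounded to
[0, 1] like calibrated posteriors (background Beta(1, 9), positive
Beta(9, 1) by default).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy.stats import beta as beta_dist

from .graphlets import Graphlet, count_graphlets
from .structgraph import AA20, RootedEnvironment


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # structure | pu_scores | motif_graphs | null_scores | cohort
    parameters: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "parameters": self.parameters, "seed": self.seed},
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Toy structures

_BACKBONE_OFFSETS = {
    "N": (-1.2, 0.5, 0.0),
    "C": (1.2, 0.5, 0.0),
    "O": (1.2, 1.5, 0.0),
    "CB": (0.0, -1.4, 0.6),
}
# coordinating side-chain atom per coordinating amino acid
_COORD_ATOM = {"C": ("SG", "S"), "H": ("NE2", "N"), "D": ("OD1", "O"), "E": ("OE1", "O")}
_AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_STEP = 3.8  # Å between consecutive CA positions
_DIRS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass
class MetalSiteSpec:
    metal: str = "ZN"
    k: int = 4


@dataclass
class SynthStructure:
    text: str
    sequence: str
    coordinating: tuple  # residue indices (1-based author numbers) as str
    metal_xyz: Optional[tuple]
    spec: FixtureSpec


def _self_avoiding_walk(n: int, rng) -> Optional[list]:
    pos = [(0, 0, 0)]
    occupied = {pos[0]}
    for _ in range(n - 1):
        dirs = [d for d in rng.permutation(len(_DIRS))]
        placed = False
        for di in dirs:
            d = _DIRS[di]
            nxt = tuple(p + q for p, q in zip(pos[-1], d))
            if nxt not in occupied:
                pos.append(nxt)
                occupied.add(nxt)
                placed = True
                break
        if not placed:
            return None
    return [tuple(_STEP * c for c in p) for p in pos]


def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, element, het=False):
    record = "HETATM" if het else "ATOM  "
    return (
        f"{record}{serial:5d}  {name:<3s}{resname:>4s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def synth_structure(
    n_residues: int,
    motif: Optional[MetalSiteSpec] = None,
    seed: int = 0,
    resolution: float = 1.5,
    max_tries: int = 200,
) -> SynthStructure:
    """Generate PDB text for a toy structure, optionally with a planted
    metal site.

    The backbone is a self-avoiding lattice walk (3.8 Å steps).  With a
    motif, a metal ion is placed so that exactly ``k`` residues have a
    side-chain N/O/S atom at 2.0-2.9 Å from it while all other N/O/S
    atoms stay beyond 3.5 Å.  Byte-identical output per seed.
    """
    if n_residues < 3:
        raise FixtureError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        kind="structure",
        parameters={
            "n_residues": n_residues,
            "motif": None if motif is None else {"metal": motif.metal, "k": motif.k},
            "resolution": resolution,
        },
        seed=seed,
    )

    for _attempt in range(max_tries):
        ca = _self_avoiding_walk(n_residues, rng)
        if ca is None:
            continue
        ca = np.array(ca)
        seq = [AA20[i] for i in rng.integers(0, len(AA20), size=n_residues)]
        zn_xyz = None
        coordinators: list = []
        if motif is not None:
            placed = False
            for _ in range(100):
                anchor = int(rng.integers(0, n_residues))
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                zn = ca[anchor] + 6.5 * direction
                d = np.linalg.norm(ca - zn, axis=1)
                if d.min() < 5.6:
                    continue
                near = np.argsort(d)
                if d[near[motif.k - 1]] > 8.5:
                    continue
                coordinators = sorted(int(i) for i in near[: motif.k])
                zn_xyz = tuple(zn)
                placed = True
                break
            if not placed:
                continue
            coord_aas = rng.choice(sorted(_COORD_ATOM), size=len(coordinators))
            for idx, aa in zip(coordinators, coord_aas):
                seq[idx] = str(aa)

        # assemble atoms
        atoms = []  # (name, element, xyz, residue index)
        ok = True
        for i in range(n_residues):
            base = ca[i]
            atoms.append(("CA", "C", tuple(base), i))
            for name, off in _BACKBONE_OFFSETS.items():
                if name == "CB" and seq[i] == "G":
                    continue
                atoms.append((
                    name, "C" if name in ("C", "CB") else name[0],
                    tuple(base + np.array(off)), i,
                ))
            if zn_xyz is not None and i in coordinators:
                aname, elem = _COORD_ATOM[seq[i]]
                to_zn = np.array(zn_xyz) - base
                dist = np.linalg.norm(to_zn)
                target = float(rng.uniform(2.0, 2.9))
                sc = np.array(zn_xyz) - to_zn / dist * target
                atoms.append((aname, elem, tuple(sc), i))
        if zn_xyz is not None:
            for name, elem, xyz, i in atoms:
                if elem not in ("N", "O", "S"):
                    continue
                d = math.dist(xyz, zn_xyz)
                if i in coordinators and name in (
                    _COORD_ATOM[seq[i]][0],
                ):
                    if not (2.0 - 1e-9 <= d <= 2.9 + 1e-9):
                        ok = False
                        break
                elif d <= 3.5:
                    ok = False
                    break
        if not ok:
            continue

        lines = [
            "HEADER    SYNTHETIC TOY PROTEIN                   01-JAN-00   XXXX",
            "EXPDTA    X-RAY DIFFRACTION",
            f"REMARK   2 RESOLUTION.    {resolution:4.2f} ANGSTROMS.",
        ]
        serial = 1
        for name, elem, xyz, i in atoms:
            lines.append(_pdb_atom_line(
                serial, name, _AA1_TO_3[seq[i]], "A", i + 1, xyz, elem
            ))
            serial += 1
        if zn_xyz is not None:
            lines.append(_pdb_atom_line(
                serial, motif.metal, motif.metal, "A", n_residues + 1,
                zn_xyz, motif.metal, het=True,
            ))
        lines.append("END")
        return SynthStructure(
            text="\n".join(lines) + "\n",
            sequence="".join(seq),
            coordinating=tuple(str(i + 1) for i in coordinators),
            metal_xyz=zn_xyz,
            spec=spec,
        )
    raise FixtureError("could not realise the requested geometry; try another seed")


# ---------------------------------------------------------------------------
# PU score mixtures


@dataclass
class PUScores:
    """Raw component draws plus calibrated labeledness posteriors.

    ``labeled``/``unlabeled``/``background`` are draws from the positive
    component, the alpha-mixture, and the background component.
    ``p_labeled``/``p_unlabeled`` are the corresponding exact posteriors
    P(l=+1|score) of the labeled-vs-unlabeled problem, computed from the
    known component densities with label fraction m/(m+n); these are the
    calibrated scores that prior estimators consume.
    """

    labeled: np.ndarray
    unlabeled: np.ndarray
    background: np.ndarray
    p_labeled: np.ndarray
    p_unlabeled: np.ndarray
    unlabeled_is_positive: np.ndarray
    alpha: float
    spec: FixtureSpec
    degenerate: bool = False


def synth_pu_scores(
    alpha: float,
    m: int,
    n: int,
    pos_params: tuple = (9.0, 1.0),
    bg_params: tuple = (1.0, 9.0),
    seed: int = 0,
) -> PUScores:
    """Two-component Beta score mixture with a known class prior."""
    if not (0.0 <= alpha <= 1.0):
        raise FixtureError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    degenerate = tuple(pos_params) == tuple(bg_params)
    if degenerate:
        warnings.warn(
            "positive and background components coincide; the class prior "
            "is unidentifiable", UserWarning,
        )
    labeled = rng.beta(*pos_params, size=m)
    is_pos = rng.random(n) < alpha
    unlabeled = np.where(
        is_pos, rng.beta(*pos_params, size=n), rng.beta(*bg_params, size=n)
    )
    background = rng.beta(*bg_params, size=n)

    q = m / (m + n)

    def p_l(x):
        f_pos = beta_dist.pdf(x, *pos_params)
        f_mix = alpha * f_pos + (1 - alpha) * beta_dist.pdf(x, *bg_params)
        num = q * f_pos
        den = num + (1 - q) * f_mix
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, 0.5)
        return np.clip(out, 0.0, 1.0)

    return PUScores(
        labeled=labeled,
        unlabeled=unlabeled,
        background=background,
        p_labeled=p_l(labeled),
        p_unlabeled=p_l(unlabeled),
        unlabeled_is_positive=is_pos,
        alpha=alpha,
        spec=FixtureSpec(
            kind="pu_scores",
            parameters={
                "alpha": alpha, "m": m, "n": n,
                "pos": list(pos_params), "bg": list(bg_params),
            },
            seed=seed,
        ),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Planted-motif graph datasets


def _random_connected_graph(n: int, rng, labels, extra_edge_p: float = 0.25):
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, label=labels[i], aa=labels[i].upper())
    for i in range(1, n):
        g.add_edge(i, int(rng.integers(0, i)))
    for i in range(n):
        for j in range(i + 1, n):
            if not g.has_edge(i, j) and rng.random() < extra_edge_p:
                g.add_edge(i, j)
    return g


def _contains_motif(env: RootedEnvironment, motif: Graphlet) -> bool:
    profile = count_graphlets(env, motif.n)
    return profile.phi.get(motif, 0) > 0


def synth_motif_graphs(
    n_pos: int,
    n_neg: int,
    motif: Graphlet,
    noise: float = 0.1,
    n_extra: tuple = (3, 8),
    alphabet: tuple = AA20,
    seed: int = 0,
) -> tuple:
    """Rooted labeled environments with/without a planted motif at the root.

    Positives contain the motif as an induced subgraph at the root (noise
    adds edges only outside the motif block so the induced motif
    survives); negatives are size-matched random rooted graphs verified
    not to contain the motif.  Returns ``(envs, y)``.
    """
    if motif.n > 5:
        raise FixtureError("motif must have at most 5 vertices")
    rng = np.random.default_rng(seed)
    envs, y = [], []
    for _ in range(n_pos):
        extra = int(rng.integers(n_extra[0], n_extra[1] + 1))
        n_total = motif.n + extra
        g = nx.Graph()
        for i in range(motif.n):
            g.add_node(i, label=motif.labels[i], aa=motif.labels[i].upper())
        for i, j in motif.edges:
            g.add_edge(i, j)
        for i in range(motif.n, n_total):
            lab = alphabet[int(rng.integers(0, len(alphabet)))]
            g.add_node(i, label=lab, aa=lab.upper())
            g.add_edge(i, int(rng.integers(0, i)))
        for i in range(n_total):
            for j in range(max(i + 1, motif.n), n_total):
                if not g.has_edge(i, j) and rng.random() < noise:
                    g.add_edge(i, j)
        env = RootedEnvironment(graph=g, root=0, level=3)
        envs.append(env)
        y.append(1)
    for _ in range(n_neg):
        extra = int(rng.integers(n_extra[0], n_extra[1] + 1))
        n_total = motif.n + extra
        for _try in range(50):
            labels = [motif.labels[0]] + [
                alphabet[int(rng.integers(0, len(alphabet)))]
                for _ in range(n_total - 1)
            ]
            g = _random_connected_graph(n_total, rng, labels, extra_edge_p=noise)
            env = RootedEnvironment(graph=g, root=0, level=3)
            if not _contains_motif(env, motif):
                break
        else:
            raise FixtureError("could not generate a motif-free negative")
        envs.append(env)
        y.append(0)
    return envs, np.asarray(y)


# ---------------------------------------------------------------------------
# Enrichment cohorts


@dataclass
class CohortScores:
    disease: np.ndarray
    neutral: np.ndarray
    spec: FixtureSpec


def synth_cohorts(
    n_disease: int,
    n_neutral: int,
    exceedance_effect: float,
    base_params: tuple = (1.0, 19.0),
    tail_params: tuple = (20.0, 1.0),
    seed: int = 0,
) -> CohortScores:
    """Score cohorts for enrichment testing.

    Neutral scores come from the base Beta distribution; disease scores
    mix in the high-tail component with probability ``exceedance_effect``,
    which therefore approximates the extra exceedance mass above any
    high null quantile.
    """
    if n_disease < 100 or n_neutral < 100:
        raise FixtureError("cohort sizes must be at least 100")
    if not (0.0 <= exceedance_effect <= 1.0):
        raise FixtureError("exceedance effect must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    neutral = rng.beta(*base_params, size=n_neutral)
    from_tail = rng.random(n_disease) < exceedance_effect
    disease = np.where(
        from_tail,
        rng.beta(*tail_params, size=n_disease),
        rng.beta(*base_params, size=n_disease),
    )
    return CohortScores(
        disease=disease,
        neutral=neutral,
        spec=FixtureSpec(
            kind="cohort",
            parameters={
                "n_disease": n_disease, "n_neutral": n_neutral,
                "effect": exceedance_effect,
                "base": list(base_params), "tail": list(tail_params),
            },
            seed=seed,
        ),
    )


def synth_null_scores(n: int, params: tuple = (1.0, 9.0), seed: int = 0) -> np.ndarray:
    """A plain null score sample (tie-free with probability one)."""
    rng = np.random.default_rng(seed)
    return rng.beta(*params, size=n)
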