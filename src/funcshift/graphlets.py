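"""Labeled rooted graphlets and edit-distance graphlet kernels.

A graphlet is a small, simple, connected, rooted, vertex-labeled graph.
For a rooted residue microenvironment we count, for every graphlet size
n = 1..N (N <= 5), each connected induced root-containing subgraph under a
canonical id (raw counts phi).  Counts are then smoothed over an edit
neighborhood: psi(g_i) sums the raw counts of every graphlet reachable
from g_i within m edit operations (unit weights).  The kernel between two
vertices is the inner product of their smoothed count vectors, summed over
graphlet sizes, optionally normalized to unit self-similarity.

Edit operations are vertex-label substitutions and edge insertions or
deletions; vertex insertion/deletion acts atomically on leaves (a leaf and
its single incident edge count as one operation) so that every
intermediate is itself a valid graphlet.  Three operation modes are
available: ``label_sub`` (label substitutions only), ``edge_indel`` (edge
insertions/deletions only) and ``full`` (all operations, including the
cross-size leaf operations).  With m = 0 the kernel reduces to the
standard labeled graphlet kernel.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

MAX_GRAPHLET_SIZE = 5
MODES = ("full", "label_sub", "edge_indel")


class GraphletError(ValueError):
    pass


@dataclass(frozen=True)
class Graphlet:
    """A canonical vertex-labeled rooted graphlet.

    Vertices are integers ``0..n-1`` with the root fixed at position 0;
    ``labels[i]`` is the label of vertex ``i`` and ``edges`` holds sorted
    vertex pairs.  Instances produced by :func:`canonical_form` are in
    canonical form: two rooted labeled graphs are isomorphic (root- and
    label-preserving) iff their canonical forms are equal.
    """

    n: int
    labels: tuple
    edges: frozenset

    @property
    def id(self) -> str:
        edge_str = ";".join(f"{i}-{j}" for i, j in sorted(self.edges))
        return f"{self.n}|{','.join(self.labels)}|{edge_str}"

    @classmethod
    def from_id(cls, gid: str) -> "Graphlet":
        n_str, labels_str, edge_str = gid.split("|")
        labels = tuple(labels_str.split(","))
        edges = frozenset(
            tuple(int(x) for x in e.split("-")) for e in edge_str.split(";") if e
        )
        return cls(n=int(n_str), labels=labels, edges=edges)

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)


def _is_connected(n: int, edges: Iterable[tuple]) -> bool:
    if n <= 1:
        return True
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


def canonical_form(labels: Sequence[str], edges: Iterable[tuple]) -> Graphlet:
    """Canonicalize a rooted labeled graph given with root at index 0.

    Exhaustive minimisation over the (n-1)! root-fixing permutations;
    feasible because graphlets have at most five vertices.
    """
    n = len(labels)
    if n < 1 or n > MAX_GRAPHLET_SIZE:
        raise GraphletError(f"graphlet size {n} outside 1..{MAX_GRAPHLET_SIZE}")
    edges = {(min(i, j), max(i, j)) for i, j in edges}
    for i, j in edges:
        if i == j:
            raise GraphletError("self-loops are not allowed")
        if not (0 <= i < n and 0 <= j < n):
            raise GraphletError("edge endpoint outside vertex range")
    if not _is_connected(n, edges):
        raise GraphletError("graphlet must be connected")

    best = None
    for perm in itertools.permutations(range(1, n)):
        mapping = {0: 0}
        for new_pos, old in enumerate(perm, start=1):
            mapping[old] = new_pos
        new_labels = [None] * n
        for old, new in mapping.items():
            new_labels[new] = labels[old]
        new_edges = tuple(sorted(
            (min(mapping[i], mapping[j]), max(mapping[i], mapping[j]))
            for i, j in edges
        ))
        cand = (tuple(new_labels), new_edges)
        if best is None or cand < best:
            best = cand
    return Graphlet(n=n, labels=best[0], edges=frozenset(best[1]))


def canonicalize(graph: nx.Graph, root, label_attr: str = "label") -> Graphlet:
    """Canonical id of an arbitrary rooted labeled graph of <= 5 vertices."""
    if root not in graph:
        raise GraphletError("root is not a vertex of the graph")
    nodes = [root] + [v for v in graph.nodes if v != root]
    if len(nodes) > MAX_GRAPHLET_SIZE:
        raise GraphletError(
            f"graph has {len(nodes)} vertices; graphlets are limited to "
            f"{MAX_GRAPHLET_SIZE}"
        )
    index = {v: i for i, v in enumerate(nodes)}
    labels = [graph.nodes[v][label_attr] for v in nodes]
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    return canonical_form(labels, edges)


# ---------------------------------------------------------------------------
# Counting


def _connected_root_subsets(adj: dict, root, max_size: int):
    """Yield every connected vertex subset containing ``root`` with size
    <= ``max_size``, each exactly once (extension/forbidden enumeration)."""

    def rec(S: frozenset, ext: list, forb: set):
        yield S
        if len(S) == max_size:
            return
        ext = list(ext)
        forb = set(forb)
        while ext:
            v = ext.pop()
            new_candidates = [
                u for u in adj[v]
                if u not in S and u not in forb and u not in ext and u != v
            ]
            yield from rec(S | {v}, ext + new_candidates, forb)
            forb.add(v)

    initial_ext = list(adj[root])
    yield from rec(frozenset([root]), initial_ext, set())


@dataclass(frozen=True)
class KernelSpec:
    """Parameters identifying a graphlet-kernel representation."""

    N: int
    m: int
    mode: str
    alphabet: tuple

    def __post_init__(self):
        if not (1 <= self.N <= MAX_GRAPHLET_SIZE):
            raise GraphletError(f"N must be in 1..{MAX_GRAPHLET_SIZE}")
        if self.m not in (0, 1):
            raise GraphletError("edit budget m must be 0 or 1")
        if self.mode not in MODES:
            raise GraphletError(f"mode must be one of {MODES}")


@dataclass
class GraphletProfile:
    """Sparse raw (phi) and edit-smoothed (psi) graphlet count vectors."""

    phi: dict
    N: int
    spec: Optional[KernelSpec] = None
    psi: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps({g.id: c for g, c in sorted(
            self.phi.items(), key=lambda kv: kv[0].id)})

    @classmethod
    def from_json(cls, text: str, N: int) -> "GraphletProfile":
        phi = {Graphlet.from_id(k): v for k, v in json.loads(text).items()}
        return cls(phi=phi, N=N)


def count_graphlets(env, N: int) -> GraphletProfile:
    """Exact raw graphlet counts phi of a rooted environment.

    Every connected induced subgraph of size n <= N that contains the root
    is counted once under its canonical id.
    """
    if not (1 <= N <= MAX_GRAPHLET_SIZE):
        raise GraphletError(f"N must be in 1..{MAX_GRAPHLET_SIZE}")
    g = env.graph
    root = env.root
    adj = {v: sorted(g.neighbors(v), key=str) for v in g.nodes}
    labels = {v: g.nodes[v]["label"] for v in g.nodes}
    phi: dict = {}
    for subset in _connected_root_subsets(adj, root, N):
        nodes = [root] + sorted((v for v in subset if v != root), key=str)
        index = {v: i for i, v in enumerate(nodes)}
        sub_labels = [labels[v] for v in nodes]
        sub_edges = [
            (index[u], index[v])
            for u, v in itertools.combinations(nodes, 2)
            if g.has_edge(u, v)
        ]
        glet = canonical_form(sub_labels, sub_edges)
        phi[glet] = phi.get(glet, 0) + 1
    return GraphletProfile(phi=phi, N=N)


# ---------------------------------------------------------------------------
# Edit neighborhoods


def _single_edits(center: Graphlet, mode: str, alphabet: tuple, max_n: int):
    n, labels, edges = center.n, center.labels, center.edges
    results = set()

    if mode in ("full", "label_sub"):
        for v in range(n):
            for sym in alphabet:
                if sym != labels[v]:
                    new_labels = list(labels)
                    new_labels[v] = sym
                    results.add(canonical_form(new_labels, edges))

    if mode in ("full", "edge_indel"):
        for i, j in itertools.combinations(range(n), 2):
            if (i, j) not in edges:
                results.add(canonical_form(labels, set(edges) | {(i, j)}))
        for e in edges:
            remaining = set(edges) - {e}
            if _is_connected(n, remaining):
                results.add(canonical_form(labels, remaining))

    if mode == "full":
        if n < max_n:
            for attach in range(n):
                for sym in alphabet:
                    results.add(canonical_form(
                        list(labels) + [sym], set(edges) | {(attach, n)}
                    ))
        for v in range(1, n):
            if center.degree(v) == 1:
                keep = [u for u in range(n) if u != v]
                remap = {u: i for i, u in enumerate(keep)}
                new_labels = [labels[u] for u in keep]
                new_edges = {
                    (min(remap[i], remap[j]), max(remap[i], remap[j]))
                    for i, j in edges if v not in (i, j)
                }
                results.add(canonical_form(new_labels, new_edges))
    return results


@lru_cache(maxsize=None)
def edit_neighborhood(
    center: Graphlet, m: int, mode: str, alphabet: tuple, max_n: int
) -> frozenset:
    """All valid graphlets within ``m`` edit operations of ``center``.

    The neighborhood always contains the center (distance 0).  Results are
    precomputed and cached per (center, m, mode, alphabet, max size); they
    depend only on the kernel spec, never on the data.
    """
    if m not in (0, 1):
        raise GraphletError("edit budget m must be 0 or 1")
    if mode not in MODES:
        raise GraphletError(f"mode must be one of {MODES}")
    members = {center}
    if m >= 1:
        members |= _single_edits(center, mode, alphabet, max_n)
    return frozenset(members)


def smooth(profile: GraphletProfile, spec: KernelSpec) -> GraphletProfile:
    """Fill the edit-smoothed counts psi of a raw profile.

    psi(g_i) = sum over g_j in the edit neighborhood of g_i of phi(g_j).
    Because every single edit operation is invertible within the size
    budget, the sum is computed by scattering each observed raw count over
    its own neighborhood.  With m = 0, psi equals phi exactly.
    """
    if spec.N != profile.N:
        raise GraphletError("profile N does not match kernel spec N")
    if spec.m == 0:
        psi = {g: float(c) for g, c in profile.phi.items()}
    else:
        psi = {}
        for g, c in profile.phi.items():
            for nb in edit_neighborhood(g, spec.m, spec.mode, spec.alphabet, spec.N):
                psi[nb] = psi.get(nb, 0.0) + c
    return GraphletProfile(phi=dict(profile.phi), N=profile.N, spec=spec, psi=psi)


def compute_profile(env, spec: KernelSpec) -> GraphletProfile:
    """Count and smooth in one step, validating the environment labels."""
    labels = set(env.labels().values()) if hasattr(env, "labels") else set()
    unknown = labels - set(spec.alphabet)
    if unknown:
        raise GraphletError(
            f"environment labels {sorted(unknown)} outside kernel alphabet"
        )
    return smooth(count_graphlets(env, spec.N), spec)


# ---------------------------------------------------------------------------
# Kernels


def _dot(a: dict, b: dict) -> float:
    if len(a) > len(b):
        a, b = b, a
    return float(sum(c * b[g] for g, c in a.items() if g in b))


def kernel(u: GraphletProfile, v: GraphletProfile, normalized: bool = True) -> float:
    """Edit-distance graphlet kernel between two smoothed profiles.

    The inner product of the smoothed vectors, implicitly summed over all
    graphlet sizes n = 1..N; the normalized variant divides by
    sqrt(k(u,u) k(v,v)), with 0/0 defined as 0.
    """
    if u.spec is None or v.spec is None or u.psi is None or v.psi is None:
        raise GraphletError("profiles must be smoothed before kernel evaluation")
    if u.spec != v.spec:
        raise GraphletError("kernel spec mismatch between profiles")
    k = _dot(u.psi, v.psi)
    if not normalized:
        return k
    kuu = _dot(u.psi, u.psi)
    kvv = _dot(v.psi, v.psi)
    denom = np.sqrt(kuu * kvv)
    return float(k / denom) if denom > 0 else 0.0


@dataclass
class KernelMatrix:
    entries: np.ndarray
    ids: list
    spec: KernelSpec
    normalized: bool = True

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=self.ids, columns=self.ids)


def _sparse_matrix(profiles: Sequence[GraphletProfile], vocab: dict):
    from scipy.sparse import csr_matrix

    rows, cols, vals = [], [], []
    for i, p in enumerate(profiles):
        for g, c in p.psi.items():
            rows.append(i)
            cols.append(vocab.setdefault(g, len(vocab)))
            vals.append(c)
    return rows, cols, vals


def _profile_stack(row_profiles, col_profiles=None):
    """Stack psi vectors into sparse matrices over a shared vocabulary."""
    from scipy.sparse import csr_matrix

    vocab: dict = {}
    r1 = _sparse_matrix(row_profiles, vocab)
    r2 = _sparse_matrix(col_profiles, vocab) if col_profiles is not None else None
    width = len(vocab)
    A = csr_matrix((r1[2], (r1[0], r1[1])), shape=(len(row_profiles), width))
    B = (
        csr_matrix((r2[2], (r2[0], r2[1])), shape=(len(col_profiles), width))
        if r2 is not None else None
    )
    return A, B


def kernel_matrix(
    profiles: Sequence[GraphletProfile],
    ids: Optional[Sequence] = None,
    normalized: bool = True,
) -> KernelMatrix:
    if not profiles:
        raise GraphletError("no profiles supplied")
    spec = profiles[0].spec
    for p in profiles:
        if p.spec != spec:
            raise GraphletError("kernel spec mismatch between profiles")
        if p.psi is None:
            raise GraphletError("profiles must be smoothed before kernel evaluation")
    n = len(profiles)
    A, _ = _profile_stack(profiles)
    K = np.asarray((A @ A.T).todense(), dtype=float)
    if normalized:
        diag = np.sqrt(np.diag(K))
        with np.errstate(invalid="ignore", divide="ignore"):
            K = K / np.outer(diag, diag)
        K[~np.isfinite(K)] = 0.0
        np.fill_diagonal(K, np.where(diag > 0, 1.0, 0.0))
    return KernelMatrix(
        entries=K,
        ids=list(ids) if ids is not None else list(range(n)),
        spec=spec,
        normalized=normalized,
    )


def cross_kernel(
    rows: Sequence[GraphletProfile],
    cols: Sequence[GraphletProfile],
    normalized: bool = True,
) -> np.ndarray:
    """Kernel block between two profile collections (rows x cols)."""
    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    spec = rows[0].spec
    for p in list(rows) + list(cols):
        if p.spec != spec:
            raise GraphletError("kernel spec mismatch between profiles")
        if p.psi is None:
            raise GraphletError("profiles must be smoothed before kernel evaluation")
    A, B = _profile_stack(list(rows), list(cols))
    K = np.asarray((A @ B.T).todense(), dtype=float)
    if normalized:
        da = np.sqrt(np.asarray(A.multiply(A).sum(axis=1)).ravel())
        db = np.sqrt(np.asarray(B.multiply(B).sum(axis=1)).ravel())
        with np.errstate(invalid="ignore", divide="ignore"):
            K = K / np.outer(da, db)
        K[~np.isfinite(K)] = 0.0
    return K
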