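"""Registry of residue function types.

Thirty site types organised into seven categories: protein stability plus
six functional groups (metal binding, PTMs, catalytic activity,
macromolecular binding, ligand binding, allosteric regulation).  PTM types
carry a residue restriction: only modifiable amino acids can carry or
acquire the modification (Asn for N-linked glycosylation; Ser/Thr/Tyr for
phosphorylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FunctionType:
    """A residue function that can be predicted, lost or gained.

    Parameters
    ----------
    id : str
        Short unique identifier (e.g. ``"Zn"``, ``"Cat"``, ``"Phos"``).
    category : str
        One of ``stability``, ``metal``, ``PTM``, ``catalytic``,
        ``macromolecular``, ``ligand``, ``allosteric``.
    restriction : frozenset of str
        Amino acids (one-letter) that can carry the function; empty set
        means no restriction.
    """

    id: str
    category: str
    restriction: frozenset = field(default_factory=frozenset)

    def allows(self, aa: str) -> bool:
        return not self.restriction or aa.upper() in self.restriction


CATEGORIES = (
    "stability",
    "metal",
    "PTM",
    "catalytic",
    "macromolecular",
    "ligand",
    "allosteric",
)

_METALS = ("Ca", "Cd", "Co", "Cu", "Fe", "K", "Mg", "Mn", "Na", "Ni", "Zn")
_LIGANDS = ("ADP", "ATP", "FAD", "FMN", "GDP", "GTP", "HEM", "NAD", "PLP", "UDP")

REGISTRY: dict[str, FunctionType] = {}


def _register(ft: FunctionType) -> None:
    if ft.id in REGISTRY:
        raise ValueError(f"duplicate function id {ft.id!r}")
    REGISTRY[ft.id] = ft


_register(FunctionType("S", "stability"))
for _m in _METALS:
    _register(FunctionType(_m, "metal"))
_register(FunctionType("Nglyco", "PTM", frozenset("N")))
_register(FunctionType("Phos", "PTM", frozenset("STY")))
_register(FunctionType("Cat", "catalytic"))
for _f in ("DNA", "RNA", "PPI", "Hotspot"):
    _register(FunctionType(_f, "macromolecular"))
for _l in _LIGANDS:
    _register(FunctionType(_l, "ligand"))
_register(FunctionType("Allo", "allosteric"))


def functional_types() -> list[FunctionType]:
    """The 29 non-stability function types."""
    return [ft for ft in REGISTRY.values() if ft.category != "stability"]


def by_category(category: str) -> list[FunctionType]:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return [ft for ft in REGISTRY.values() if ft.category == category]


# Element symbol of the metal ion -> function id
METAL_ELEMENTS = {
    "CA": "Ca",
    "CD": "Cd",
    "CO": "Co",
    "CU": "Cu",
    "FE": "Fe",
    "K": "K",
    "MG": "Mg",
    "MN": "Mn",
    "NA": "Na",
    "NI": "Ni",
    "ZN": "Zn",
}
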