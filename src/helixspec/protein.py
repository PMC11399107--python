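"""Featured heavy-atom protein graph.

Vertex features are pure lookups on (residue_name, atom_name, element):
a 6-way element one-hot (C, N, O, S, P, other), hydrogen-bond donor/acceptor
flags from a fixed per-residue atom-name table, an aromatic-ring flag for
His/Phe/Tyr/Trp ring atoms, a backbone flag, a 5-way residue-class one-hot
(positive, negative, polar, hydrophobic, other) and a formal charge sign.
Edges connect heavy atoms within ``r_graph`` Å; vertices over ``max_degree``
keep their nearest neighbors and the edge set is re-symmetrized by union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from helixspec.structure import AMINO_ACIDS, Atom

ELEMENTS = ("C", "N", "O", "S", "P")  # + other
RESIDUE_CLASSES = ("positive", "negative", "polar", "hydrophobic", "other")

_RESIDUE_CLASS = {
    **{r: "positive" for r in ("ARG", "LYS", "HIS")},
    **{r: "negative" for r in ("ASP", "GLU")},
    **{r: "polar" for r in ("SER", "THR", "ASN", "GLN", "CYS", "TYR")},
    **{r: "hydrophobic" for r in (
        "ALA", "GLY", "ILE", "LEU", "MET", "PHE", "PRO", "TRP", "VAL")},
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Sidechain H-bond donor heavy atoms per residue.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
# Sidechain H-bond acceptor heavy atoms per residue. Cys SG can accept an
# H-bond through its thiol sulfur (a specificity-conferring contact in some
# major-groove interfaces), so it appears in both tables.
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "CYS": {"SG"},
}
_AROMATIC_RING_ATOMS = {
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}
# Formal charge signs of ionizable sidechain atoms at physiological pH.
_CHARGE_SIGN = {
    ("ARG", "NH1"): 1, ("ARG", "NH2"): 1, ("ARG", "NE"): 1, ("ARG", "CZ"): 1,
    ("LYS", "NZ"): 1,
    ("HIS", "ND1"): 1, ("HIS", "NE2"): 1,
    ("ASP", "OD1"): -1, ("ASP", "OD2"): -1,
    ("GLU", "OE1"): -1, ("GLU", "OE2"): -1,
}

N_ATOM_FEATURES = 6 + 4 + 5 + 1  # element + flags + residue class + charge


@dataclass(frozen=True)
class AtomFeatures:
    element_onehot: np.ndarray  # (6,) C,N,O,S,P,other
    donor_flag: bool
    acceptor_flag: bool
    aromatic_flag: bool
    backbone_flag: bool
    residue_class_onehot: np.ndarray  # (5,)
    charge_sign: int

    @property
    def residue_class(self) -> str:
        return RESIDUE_CLASSES[int(np.argmax(self.residue_class_onehot))]

    def as_vector(self) -> np.ndarray:
        return np.concatenate([
            self.element_onehot,
            [float(self.donor_flag), float(self.acceptor_flag),
             float(self.aromatic_flag), float(self.backbone_flag)],
            self.residue_class_onehot,
            [float(self.charge_sign)],
        ])


def featurize_atom(atom: Atom) -> AtomFeatures:
    elem = np.zeros(6)
    elem[ELEMENTS.index(atom.element) if atom.element in ELEMENTS else 5] = 1.0

    res, name = atom.residue_name, atom.atom_name
    standard = res in AMINO_ACIDS
    backbone = standard and name in BACKBONE_ATOMS

    if backbone:
        donor = name == "N"
        acceptor = name in ("O", "OXT")
    elif standard:
        donor = name in _SIDECHAIN_DONORS.get(res, ())
        acceptor = name in _SIDECHAIN_ACCEPTORS.get(res, ())
    else:
        # nonstandard residue: element defaults
        donor = atom.element == "N"
        acceptor = atom.element in ("O", "S")

    rclass = _RESIDUE_CLASS.get(res, "other") if standard else "other"
    rc = np.zeros(5)
    rc[RESIDUE_CLASSES.index(rclass)] = 1.0

    return AtomFeatures(
        element_onehot=elem,
        donor_flag=bool(donor),
        acceptor_flag=bool(acceptor),
        aromatic_flag=name in _AROMATIC_RING_ATOMS.get(res, set()),
        backbone_flag=bool(backbone),
        residue_class_onehot=rc,
        charge_sign=_CHARGE_SIGN.get((res, name), 0),
    )


def featurize_atoms(atoms: Sequence[Atom]) -> list[AtomFeatures]:
    """Per-atom feature lookup; position-independent by construction."""
    return [featurize_atom(a) for a in atoms]


@dataclass
class ProteinGraph:
    """Heavy-atom vertices with features and undirected distance edges."""

    atoms: list[Atom]
    features: list[AtomFeatures]
    edges: np.ndarray  # (E, 2) int, i < j, unique
    edge_lengths: np.ndarray  # (E,)

    @property
    def n_vertices(self) -> int:
        return len(self.atoms)

    def feature_matrix(self) -> np.ndarray:
        return np.array([f.as_vector() for f in self.features]).reshape(
            len(self.atoms), N_ATOM_FEATURES
        )

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(-1, 3)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}


def build_graph(
    atoms: Sequence[Atom], r_graph: float = 4.0, max_degree: int = 16
) -> ProteinGraph:
    """Distance graph over protein heavy atoms.

    Edges join atoms at most ``r_graph`` Å apart.  A vertex whose raw degree
    exceeds ``max_degree`` keeps only its nearest ``max_degree`` neighbors;
    the pruned edge set is then re-symmetrized by union, so the effective
    degree cap is approximate but the graph stays symmetric.
    """
    if not atoms:
        raise ValueError("need at least one atom")
    atoms = list(atoms)
    pos = np.array([a.position for a in atoms]).reshape(-1, 3)
    tree = cKDTree(pos)
    raw = tree.query_pairs(r_graph, output_type="ndarray")  # i < j

    if raw.size:
        lengths = np.linalg.norm(pos[raw[:, 0]] - pos[raw[:, 1]], axis=1)
        neighbors: dict[int, list[tuple[float, int, int]]] = {}
        for (i, j), d in zip(raw, lengths):
            neighbors.setdefault(int(i), []).append((float(d), int(j), 1))
            neighbors.setdefault(int(j), []).append((float(d), int(i), 1))
        kept: set[tuple[int, int]] = set()
        for v, nbrs in neighbors.items():
            nbrs.sort()
            for d, u, _ in nbrs[:max_degree]:
                kept.add((min(v, u), max(v, u)))
        edges = np.array(sorted(kept), int).reshape(-1, 2)
        edge_lengths = np.linalg.norm(
            pos[edges[:, 0]] - pos[edges[:, 1]], axis=1
        )
    else:
        edges = np.zeros((0, 2), int)
        edge_lengths = np.zeros(0)

    return ProteinGraph(
        atoms=atoms,
        features=featurize_atoms(atoms),
        edges=edges,
        edge_lengths=edge_lengths,
    )
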