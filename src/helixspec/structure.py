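"""Structure reading and the in-memory protein–DNA complex.

Parsing keeps protein and DNA *heavy* atoms only (hydrogens, deuteriums,
waters, ions and non-polymer ligands are dropped; for alternate locations the
highest-occupancy conformer is kept, ties resolved toward altloc "A"; only the
first model of multi-model files is read).  DNA is accepted only as standard
deoxyribonucleotides (DA, DC, DG, DT) — chemically modified bases and RNA are
rejected.  Watson–Crick pairing is detected geometrically and the complex
exposes one ordered duplex with 0-based pair indices running 5′→3′ along the
Watson strand (the longer strand; tie → lexicographically smaller chain id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from helixspec.errors import AmbiguityError, FormatError, InputError

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
DNA_RESIDUES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PURINES = {"A", "G"}

SUGAR_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

# pairing-geometry gates (Å); see detect_base_pairs
C1P_DISTANCE_RANGE = (9.0, 11.5)
GLYCOSIDIC_N_MAX_DISTANCE = 4.0
# a complex must have at least one protein atom this close to the DNA
INTERFACE_CUTOFF = 15.0


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its residue context."""

    atom_id: str
    element: str
    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    is_protein: bool
    is_heavy: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InputError(f"atom {self.atom_id}: bad position {self.position!r}")
        object.__setattr__(self, "position", pos)


@dataclass
class Nucleotide:
    """One standard deoxyribonucleotide with its key reference atoms."""

    chain_id: str
    residue_index: int
    base: str
    atoms: list[Atom]
    c1p: Atom
    glycosidic_nitrogen: Atom
    phosphate: Optional[Atom] = None

    @property
    def sugar_centroid(self) -> np.ndarray:
        ring = [a for a in self.atoms if a.atom_name in SUGAR_RING_ATOMS]
        if not ring:
            raise InputError(
                f"nucleotide {self.chain_id}/{self.residue_index} has no sugar ring atoms"
            )
        return np.mean([a.position for a in ring], axis=0)


@dataclass
class BasePair:
    """A Watson–Crick pair; ``pair_index`` runs 5′→3′ on the Watson strand."""

    watson: Nucleotide
    crick: Nucleotide
    pair_index: int


@dataclass
class ComplexStructure:
    """Parsed heavy atoms of the protein plus one ordered DNA duplex."""

    protein_atoms: list[Atom]
    duplex: list[BasePair]
    source_id: str = ""
    dna_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.duplex) < 4:
            raise InputError(
                f"duplex too short: {len(self.duplex)} pairs (need >= 4)"
            )
        if not self.protein_atoms:
            raise InputError("no protein atoms found")
        self.dna_sequence = "".join(bp.watson.base for bp in self.duplex)
        if _min_interface_distance(self) > INTERFACE_CUTOFF:
            raise InputError(
                f"no protein atom within {INTERFACE_CUTOFF} Å of the DNA duplex"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.duplex)

    @property
    def dna_atoms(self) -> list[Atom]:
        out: list[Atom] = []
        for bp in self.duplex:
            out.extend(bp.watson.atoms)
            out.extend(bp.crick.atoms)
        return out

    def protein_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.protein_atoms]).reshape(-1, 3)

    def dna_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.dna_atoms]).reshape(-1, 3)


def _min_interface_distance(complex_: ComplexStructure) -> float:
    d = cdist(complex_.protein_positions(), complex_.dna_positions())
    return float(d.min())


def contact_count(complex_: ComplexStructure, cutoff: float = 5.0) -> int:
    """Number of (protein heavy atom, DNA heavy atom) pairs within ``cutoff`` Å."""
    d = cdist(complex_.protein_positions(), complex_.dna_positions())
    return int((d <= cutoff).sum())


# ---------------------------------------------------------------------------
# Base-pair detection
# ---------------------------------------------------------------------------

def detect_base_pairs(
    nucleotides: Sequence[Nucleotide],
    *,
    c1p_range: tuple[float, float] = C1P_DISTANCE_RANGE,
    max_n_distance: float = GLYCOSIDIC_N_MAX_DISTANCE,
) -> list[BasePair]:
    """Assemble Watson–Crick pairs from a pool of nucleotides.

    A candidate pair must have complementary bases (A·T or G·C), come from
    different strands, a C1′–C1′ distance inside ``c1p_range`` and a
    glycosidic-nitrogen distance at most ``max_n_distance``.  Candidates are
    accepted greedily by increasing glycosidic-N distance so each nucleotide
    joins at most one pair.  Pairs are returned ordered 5′→3′ along the
    Watson strand; unpaired overhangs are dropped.
    """
    if len(nucleotides) < 8:
        raise InputError(f"need >= 8 nucleotides, got {len(nucleotides)}")
    if len({nt.chain_id for nt in nucleotides}) < 2:
        raise InputError("need nucleotides on >= 2 strands")

    candidates = []
    for i, a in enumerate(nucleotides):
        for j in range(i + 1, len(nucleotides)):
            b = nucleotides[j]
            if a.chain_id == b.chain_id:
                continue
            if COMPLEMENT[a.base] != b.base:
                continue
            dc1 = float(np.linalg.norm(a.c1p.position - b.c1p.position))
            if not (c1p_range[0] <= dc1 <= c1p_range[1]):
                continue
            dn = float(np.linalg.norm(
                a.glycosidic_nitrogen.position - b.glycosidic_nitrogen.position
            ))
            if dn > max_n_distance:
                continue
            candidates.append((dn, i, j))

    candidates.sort()
    used: set[int] = set()
    raw_pairs: list[tuple[Nucleotide, Nucleotide]] = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        raw_pairs.append((nucleotides[i], nucleotides[j]))

    if len(raw_pairs) < 4:
        raise InputError(f"fewer than 4 base pairs found ({len(raw_pairs)})")

    chains = sorted({nt.chain_id for p in raw_pairs for nt in p})
    if len(chains) != 2:
        raise AmbiguityError(
            "more than one DNA duplex candidate; paired chains: "
            + ", ".join(chains)
        )

    # Watson strand: more paired nucleotides, tie → smaller chain id.
    counts = {c: 0 for c in chains}
    for a, b in raw_pairs:
        counts[a.chain_id] += 1
        counts[b.chain_id] += 1
    watson_chain = min(chains, key=lambda c: (-counts[c], c))

    oriented = []
    for a, b in raw_pairs:
        w, c = (a, b) if a.chain_id == watson_chain else (b, a)
        oriented.append((w, c))
    oriented.sort(key=lambda wc: wc[0].residue_index)
    return [
        BasePair(watson=w, crick=c, pair_index=k)
        for k, (w, c) in enumerate(oriented)
    ]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy altloc per atom name; ties prefer altloc 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in residue:
        by_name.setdefault(at.name, []).append(at)
    chosen = []
    for group in by_name.values():
        group.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        chosen.append(group[0])
    return chosen


def _is_modified_nucleotide(residue: gemmi.Residue) -> bool:
    """A residue with a sugar C1′ whose name is not a standard DNA code."""
    has_c1p = any(at.name == "C1'" for at in residue)
    return has_c1p and residue.name not in DNA_RESIDUES


def parse_structure(
    path: Union[str, Path],
    format: str = "auto",
    *,
    max_n_distance: float = GLYCOSIDIC_N_MAX_DISTANCE,
) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Raises :class:`FormatError` for unparseable files, :class:`InputError`
    when no DNA duplex or no protein is present or a modified nucleotide is
    encountered, and :class:`AmbiguityError` when more than one disconnected
    duplex is found.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise FormatError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")

    model = st[0]  # first model only
    protein_atoms: list[Atom] = []
    nucleotides: list[Nucleotide] = []

    for chain in model:
        for residue in chain:
            rname = residue.name.strip()
            if rname in WATER_RESIDUES:
                continue
            if _is_modified_nucleotide(residue):
                raise InputError(
                    f"unsupported nucleotide chemistry: residue {rname} "
                    f"{chain.name}/{residue.seqid.num} (only standard "
                    "unmodified DA/DC/DG/DT deoxyribonucleotides are accepted)"
                )
            is_protein = rname in AMINO_ACIDS
            is_dna = rname in DNA_RESIDUES
            if not (is_protein or is_dna):
                continue  # ions, ligands, unknown polymers
            res_index = residue.seqid.num
            icode = (residue.seqid.icode or "").strip()
            res_token = f"{res_index}{icode}"
            atoms: list[Atom] = []
            for gat in _pick_altlocs(residue):
                elem = gat.element.name
                if elem in ("H", "D"):
                    continue
                atoms.append(Atom(
                    atom_id=f"{chain.name}/{res_token}/{gat.name}",
                    element=elem,
                    atom_name=gat.name,
                    residue_name=rname,
                    residue_index=res_index,
                    chain_id=chain.name,
                    position=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                    is_protein=is_protein,
                ))
            if not atoms:
                continue
            if is_protein:
                protein_atoms.extend(atoms)
            else:
                nucleotides.append(_make_nucleotide(atoms, rname, chain.name, res_index))

    if not nucleotides:
        raise InputError("no DNA duplex found")
    if not protein_atoms:
        raise InputError("no protein chains found")

    duplex = detect_base_pairs(nucleotides, max_n_distance=max_n_distance)
    return ComplexStructure(
        protein_atoms=protein_atoms, duplex=duplex, source_id=path.stem
    )


def _make_nucleotide(
    atoms: list[Atom], rname: str, chain_id: str, res_index: int
) -> Nucleotide:
    base = DNA_RESIDUES[rname]
    glyco_name = "N9" if base in PURINES else "N1"
    by_name = {a.atom_name: a for a in atoms}
    c1p = by_name.get("C1'")
    glyco = by_name.get(glyco_name)
    if c1p is None or glyco is None:
        raise InputError(
            f"nucleotide {chain_id}/{res_index} ({rname}) missing "
            f"C1' or {glyco_name}"
        )
    return Nucleotide(
        chain_id=chain_id,
        residue_index=res_index,
        base=base,
        atoms=atoms,
        c1p=c1p,
        glycosidic_nitrogen=glyco,
        phosphate=by_name.get("P"),
    )


# ---------------------------------------------------------------------------
# Writing (synthetic fixtures and round-trip tests)
# ---------------------------------------------------------------------------

def write_pdb(
    complex_: ComplexStructure,
    path: Union[str, Path],
    bfactors: Optional[dict[str, float]] = None,
) -> None:
    """Write the complex as a PDB file (protein chains then DNA chains).

    ``bfactors`` optionally maps atom_id → value stamped into the B-factor
    column (e.g. relative-importance scores for sphere visualization).
    """
    st = gemmi.Structure()
    st.name = complex_.source_id or "helixspec"
    model = gemmi.Model("1")

    def add(atom: Atom, chains: dict[str, gemmi.Chain]) -> None:
        ch = chains.setdefault(atom.chain_id, gemmi.Chain(atom.chain_id))
        res = None
        if len(ch) and ch[-1].seqid.num == atom.residue_index \
                and ch[-1].name == atom.residue_name:
            res = ch[-1]
        if res is None:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_index, " ")
            ch.add_residue(res)
            res = ch[-1]
        gat = gemmi.Atom()
        gat.name = atom.atom_name
        gat.element = gemmi.Element(atom.element)
        gat.pos = gemmi.Position(*atom.position)
        gat.occ = 1.0
        if bfactors is not None:
            gat.b_iso = float(bfactors.get(atom.atom_id, 0.0))
        res.add_atom(gat)

    chains: dict[str, gemmi.Chain] = {}
    for atom in complex_.protein_atoms:
        add(atom, chains)
    seen: set[tuple[str, int]] = set()
    for bp in complex_.duplex:
        for nt in (bp.watson, bp.crick):
            key = (nt.chain_id, nt.residue_index)
            if key in seen:
                continue
            seen.add(key)
            for atom in nt.atoms:
                add(atom, chains)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
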