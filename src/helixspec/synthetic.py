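"""Desk-scale synthetic protein–DNA complexes with known ground-truth PWMs.

The generator emits an idealized B-form duplex built on a straight helix
axis: every nucleotide contributes a phosphate, the five sugar-ring atoms
and its glycosidic nitrogen, placed at fixed offsets in an ideal base-pair
frame that twists by ``twist`` degrees and climbs by ``rise`` Å per step
(plus small seeded Gaussian coordinate noise).  The two strands are
antiparallel; their phosphates sit ``minor_groove_phase`` degrees apart
across the minor groove, which sets the minor-groove width.

"Protein" context comes from three-atom pseudo-residues (probes) docked
2.8–3.2 Å outside chosen sym-helix points along their outward normals.
Probes are named after real residues so the standard featurization applies
unmodified: a donor probe is an arginine guanidinium fragment (NH1/NH2/CZ —
the bidentate major-groove H-bond donor geometry that canonically selects
guanine), an acceptor probe an aspartate carboxylate (OD1/OD2/CG) and a
hydrophobic probe an alanine fragment (CB/CA/C).  Each planted probe imposes
a known base-preference column on the ground-truth PWM at its pair; all
unplanted pairs stay uniform, so a well-calibrated model should predict
near-uniform flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from helixspec.errors import InputError
from helixspec.pwm import PWM, read_pwm, write_pwm
from helixspec.structure import (
    Atom,
    BasePair,
    ComplexStructure,
    Nucleotide,
    detect_base_pairs,
    write_pdb,
)
from helixspec.symhelix import GROUP_SLOTS, build_sym_helix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_DNA_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

# Fixed atom offsets in the ideal base-pair frame (Å), Watson strand; the
# Crick strand is the 180° rotation about the frame x axis: (x, -y, -z).
# +x faces the major groove; glycosidic nitrogens straddle the helix axis.
_GLYCO_N_OFFSET = np.array([0.0, 1.6, 0.0])
_SUGAR_OFFSETS = {
    "C1'": np.array([-2.0, 5.2, 0.0]),
    "C2'": np.array([-2.9, 6.1, 0.6]),
    "C3'": np.array([-2.4, 7.4, 0.2]),
    "C4'": np.array([-1.1, 7.2, -0.3]),
    "O4'": np.array([-0.8, 5.8, -0.4]),
}

_PROBE_ATOMS = {
    # class -> (residue_name, [(atom_name, element), ...]); first atom is
    # placed closest to the target point.
    "donor": ("ARG", [("NH1", "N"), ("NH2", "N"), ("CZ", "C")]),
    "acceptor": ("ASP", [("OD1", "O"), ("OD2", "O"), ("CG", "C")]),
    "hydrophobic": ("ALA", [("CB", "C"), ("CA", "C"), ("C", "C")]),
}

# Base-preference columns (A, C, G, T) imposed by a probe at its pair.
_G_COLUMN = np.array([1, 1, 12, 1]) / 15.0
_A_COLUMN = np.array([12, 1, 1, 1]) / 15.0
_T_COLUMN = np.array([1, 1, 1, 12]) / 15.0
_AT_COLUMN = np.array([0.35, 0.15, 0.15, 0.35])
_UNIFORM = np.full(4, 0.25)

DEFAULT_PREFERRED_COLUMNS: dict[tuple[str, str], np.ndarray] = {
    ("donor", "major"): _G_COLUMN,
    ("acceptor", "major"): _A_COLUMN,
    ("hydrophobic", "major"): _T_COLUMN,
    ("donor", "minor"): _AT_COLUMN,
    ("acceptor", "minor"): _AT_COLUMN,
    ("hydrophobic", "minor"): _AT_COLUMN,
}
for _cls in _PROBE_ATOMS:
    DEFAULT_PREFERRED_COLUMNS[(_cls, "phosphate")] = _UNIFORM
    DEFAULT_PREFERRED_COLUMNS[(_cls, "sugar")] = _UNIFORM

# sampling mixture for generate_corpus: (probe_class, target_group) -> weight
DEFAULT_RULE_MIXTURE: dict[tuple[str, str], float] = {
    ("donor", "major"): 0.30,
    ("acceptor", "major"): 0.25,
    ("hydrophobic", "major"): 0.25,
    ("donor", "minor"): 0.10,
    ("donor", "phosphate"): 0.05,
    ("hydrophobic", "sugar"): 0.05,
}


@dataclass(frozen=True)
class HelixParams:
    """Idealized B-DNA helical parameters."""

    twist: float = 36.0              # deg per step
    rise: float = 3.4                # Å per step
    backbone_radius: float = 9.4     # Å, phosphate radius
    minor_groove_phase: float = 154.0  # deg between strand phosphates
    coordinate_noise_sd: float = 0.05  # Å

    def __post_init__(self) -> None:
        if not (20.0 < self.twist < 45.0):
            raise InputError(f"twist out of range (20, 45): {self.twist}")
        if not (2.5 < self.rise < 4.5):
            raise InputError(f"rise out of range (2.5, 4.5): {self.rise}")


@dataclass(frozen=True)
class ProbeRule:
    """Probe chemistry, target point group and imposed base preference."""

    probe_class: str                      # donor | acceptor | hydrophobic
    target_group: str                     # major | minor | phosphate | sugar
    preferred_column: np.ndarray = None   # type: ignore[assignment]
    narrow_groove: bool = False

    def __post_init__(self) -> None:
        if self.probe_class not in _PROBE_ATOMS:
            raise InputError(f"unknown probe class {self.probe_class!r}")
        if self.target_group not in GROUP_SLOTS:
            raise InputError(f"unknown target group {self.target_group!r}")
        col = self.preferred_column
        if col is None:
            col = DEFAULT_PREFERRED_COLUMNS[(self.probe_class, self.target_group)]
        col = np.asarray(col, float)
        if col.shape != (4,) or not math.isclose(col.sum(), 1.0, abs_tol=1e-6):
            raise InputError("preferred_column must be a 4-vector summing to 1")
        object.__setattr__(self, "preferred_column", col)
        if self.target_group in ("phosphate", "sugar") and not self.narrow_groove:
            object.__setattr__(self, "narrow_groove", True)

    @property
    def signature(self) -> str:
        return f"{self.probe_class}@{self.target_group}"


@dataclass
class SyntheticDataPoint:
    complex: ComplexStructure
    truth_pwm: PWM
    planted: list[tuple[int, ProbeRule, tuple[str, ...]]]
    group_label: str = ""


def _frame_rotation(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_bdna(
    sequence: str,
    params: HelixParams = HelixParams(),
    seed: int = 0,
) -> list[Nucleotide]:
    """Generate both strands of an idealized duplex for ``sequence``.

    Returns the nucleotides of the Watson strand (chain A, residues numbered
    5′→3′) and the complementary antiparallel Crick strand (chain B).  The
    emitted atoms parse through the structure module and pair fully.
    """
    sequence = sequence.upper()
    if not (6 <= len(sequence) <= 60):
        raise InputError(f"sequence length must be in [6, 60], got {len(sequence)}")
    if any(b not in "ACGT" for b in sequence):
        raise InputError(f"sequence must be over ACGT: {sequence!r}")
    rng = np.random.default_rng(seed)
    n = len(sequence)

    phos_angle = 180.0 - params.minor_groove_phase / 2.0
    phos_w = params.backbone_radius * np.array([
        math.cos(math.radians(phos_angle)),
        math.sin(math.radians(phos_angle)), 0.0,
    ])

    def build_strand(chain_id: str, watson: bool) -> list[Nucleotide]:
        nts = []
        for i in range(n):
            base = sequence[i] if watson else _COMPLEMENT[sequence[i]]
            res_index = (i + 1) if watson else (n - i)
            rot = _frame_rotation(i * params.twist)
            shift = np.array([0.0, 0.0, i * params.rise])
            mirror = 1.0 if watson else -1.0

            def lab(offset: np.ndarray) -> np.ndarray:
                local = offset * np.array([1.0, mirror, mirror])
                noise = rng.normal(0.0, params.coordinate_noise_sd, 3)
                return rot @ local + shift + noise

            glyco_name = "N9" if base in "AG" else "N1"
            rname = _DNA_NAME[base]
            atoms = []

            def add(name: str, element: str, offset: np.ndarray) -> Atom:
                atom = Atom(
                    atom_id=f"{chain_id}/{res_index}/{name}",
                    element=element, atom_name=name,
                    residue_name=rname, residue_index=res_index,
                    chain_id=chain_id, position=lab(offset),
                    is_protein=False,
                )
                atoms.append(atom)
                return atom

            p_atom = add("P", "P", phos_w)
            for sname, offset in _SUGAR_OFFSETS.items():
                add(sname, "C" if sname.startswith("C") else "O", offset)
            glyco = add(glyco_name, "N", _GLYCO_N_OFFSET)
            c1p = next(a for a in atoms if a.atom_name == "C1'")
            nts.append(Nucleotide(
                chain_id=chain_id, residue_index=res_index, base=base,
                atoms=atoms, c1p=c1p, glycosidic_nitrogen=glyco,
                phosphate=p_atom,
            ))
        return nts

    return build_strand("A", watson=True) + build_strand("B", watson=False)


def _narrow_groove(duplex: Sequence[BasePair], pair_index: int,
                   inward: float = 1.2) -> None:
    """Pull the phosphates of pairs i−1…i+1 toward the helix axis.

    Locally narrows the grooves around a backbone-targeted probe; leaves the
    truth PWM untouched.  Operates in place on the nucleotide atoms.
    """
    for j in range(max(0, pair_index - 1), min(len(duplex), pair_index + 2)):
        for nt in (duplex[j].watson, duplex[j].crick):
            p = nt.phosphate
            if p is None:
                continue
            radial = p.position - np.array([0.0, 0.0, p.position[2]])
            norm = np.linalg.norm(radial)
            if norm < 1e-6:
                continue
            new_pos = p.position - inward * radial / norm
            new_p = Atom(
                atom_id=p.atom_id, element=p.element, atom_name=p.atom_name,
                residue_name=p.residue_name, residue_index=p.residue_index,
                chain_id=p.chain_id, position=new_pos, is_protein=False,
            )
            nt.atoms[nt.atoms.index(p)] = new_p
            nt.phosphate = new_p


_PROBE_TARGET_SLOT = {"major": 2, "minor": 1, "phosphate": 0, "sugar": 0}


def plant_probes(
    duplex: Union[Sequence[Nucleotide], Sequence[BasePair]],
    rules: Sequence[tuple[int, ProbeRule]],
    seed: int = 0,
    source_id: str = "synthetic",
) -> SyntheticDataPoint:
    """Dock probe pseudo-residues at sym-helix points and emit the truth PWM.

    Each rule places a 3-atom probe 2.8–3.2 Å (seeded jitter) outside the
    targeted point along its outward normal; the ground-truth PWM is uniform
    except at planted pairs, which take the rule's preferred column.  Probes
    closer than 2 Å to each other are retried, then rejected.
    """
    if duplex and isinstance(duplex[0], Nucleotide):
        pairs = detect_base_pairs(list(duplex))
    else:
        pairs = list(duplex)
    n = len(pairs)
    indices = [i for i, _ in rules]
    if len(set(indices)) != len(indices):
        raise InputError("rule pair indices must be distinct")
    if any(not (0 <= i < n) for i in indices):
        raise InputError(f"rule pair index out of range [0, {n})")

    for i, rule in rules:
        if rule.narrow_groove and rule.target_group in ("phosphate", "sugar"):
            _narrow_groove(pairs, i)
    helix = build_sym_helix(pairs)

    rng = np.random.default_rng(seed)
    probs = np.full((n, 4), 0.25)
    planted: list[tuple[int, ProbeRule, tuple[str, ...]]] = []
    probe_atoms: list[Atom] = []

    for ordinal, (i, rule) in enumerate(rules, start=1):
        slot = _PROBE_TARGET_SLOT[rule.target_group]
        point = next(
            p for p in helix.points
            if p.pair_index == i and p.group == rule.target_group
            and p.slot == slot
        )
        if not point.present:
            raise InputError(
                f"target point pair {i} group {rule.target_group} is absent"
            )
        rname, atom_spec = _PROBE_ATOMS[rule.probe_class]
        lateral = point.axis_dir

        placed: Optional[list[Atom]] = None
        for _attempt in range(10):
            d = rng.uniform(2.8, 3.2)
            jitter = rng.normal(0.0, 0.05, 3)
            base_pos = point.position + d * point.outward_normal + jitter
            offsets = [
                np.zeros(3),
                1.2 * point.outward_normal + 0.8 * lateral,
                1.2 * point.outward_normal - 0.8 * lateral,
            ]
            candidate = [
                Atom(
                    atom_id=f"P/{ordinal}/{name}",
                    element=element, atom_name=name, residue_name=rname,
                    residue_index=ordinal, chain_id="P",
                    position=base_pos + off, is_protein=True,
                )
                for (name, element), off in zip(atom_spec, offsets)
            ]
            clash = any(
                np.linalg.norm(a.position - b.position) < 2.0
                for a in candidate for b in probe_atoms
            )
            if not clash:
                placed = candidate
                break
        if placed is None:
            raise InputError(
                f"could not place probe at pair {i} without a < 2 Å clash"
            )
        probe_atoms.extend(placed)
        probs[i] = rule.preferred_column
        planted.append((i, rule, tuple(a.atom_id for a in placed)))

    if not probe_atoms:
        # No rules: dock one inert spectator probe well outside the bipartite
        # cutoff (no edges, no specificity signal) so the complex is still a
        # valid protein–DNA structure; the truth PWM stays fully uniform.
        point = next(
            p for p in helix.points
            if p.pair_index == n // 2 and p.group == "phosphate" and p.present
        )
        rname, atom_spec = _PROBE_ATOMS["hydrophobic"]
        base_pos = point.position + 8.0 * point.outward_normal
        for (name, element), off in zip(
            atom_spec,
            [np.zeros(3), np.array([0.0, 0.0, 1.2]), np.array([0.0, 0.0, -1.2])],
        ):
            probe_atoms.append(Atom(
                atom_id=f"P/1/{name}", element=element, atom_name=name,
                residue_name=rname, residue_index=1, chain_id="P",
                position=base_pos + off, is_protein=True,
            ))

    complex_ = ComplexStructure(
        protein_atoms=probe_atoms, duplex=pairs, source_id=source_id
    )
    label = "+".join(sorted(r.signature for _, r in rules))
    return SyntheticDataPoint(
        complex=complex_,
        truth_pwm=PWM(probs, name=source_id),
        planted=planted,
        group_label=label,
    )


def generate_corpus(
    n: int,
    length_range: tuple[int, int] = (10, 16),
    rules_per_complex_range: tuple[int, int] = (1, 3),
    seed: int = 0,
    params: HelixParams = HelixParams(),
    rule_mixture: Optional[dict[tuple[str, str], float]] = None,
    flank: int = 2,
) -> list[SyntheticDataPoint]:
    """Seeded, reproducible corpus of probe complexes.

    Planted pairs are kept ``flank`` pairs away from the duplex ends so every
    complex has unbound flanking DNA.  ``group_label`` is the sorted rule
    signature, making cross-validation folds cluster-aware.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    mixture = dict(DEFAULT_RULE_MIXTURE if rule_mixture is None else rule_mixture)
    kinds = sorted(mixture)
    weights = np.array([mixture[k] for k in kinds], float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    corpus = []
    for idx in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        sequence = "".join(rng.choice(list("ACGT"), size=length))
        n_rules = int(rng.integers(
            rules_per_complex_range[0], rules_per_complex_range[1] + 1
        ))
        allowed = list(range(flank, length - flank))
        n_rules = min(n_rules, len(allowed))
        pair_indices = sorted(
            rng.choice(allowed, size=n_rules, replace=False).tolist()
        )
        chosen = [
            kinds[k] for k in rng.choice(len(kinds), size=n_rules, p=weights)
        ]
        rules = [
            (i, ProbeRule(probe_class=cls, target_group=grp))
            for i, (cls, grp) in zip(pair_indices, chosen)
        ]
        bdna_seed = int(rng.integers(2**31))
        probe_seed = int(rng.integers(2**31))
        nucleotides = make_bdna(sequence, params=params, seed=bdna_seed)
        corpus.append(plant_probes(
            nucleotides, rules, seed=probe_seed, source_id=f"synth{idx:04d}"
        ))
    return corpus


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

def write_corpus(corpus: Sequence[SyntheticDataPoint],
                 out_dir: Union[str, Path]) -> Path:
    """Write PDB complexes, truth PWMs and a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["structure\tpwm\tgroup_label\tplanted"]
    for dp in corpus:
        sid = dp.complex.source_id
        pdb = out_dir / f"{sid}.pdb"
        pwm_path = out_dir / f"{sid}.pwm"
        write_pdb(dp.complex, pdb)
        write_pwm(dp.truth_pwm, pwm_path)
        planted_tok = ";".join(
            f"{i}:{rule.signature}" for i, rule, _ in dp.planted
        )
        lines.append(f"{pdb.name}\t{pwm_path.name}\t{dp.group_label}\t{planted_tok}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def load_corpus(manifest: Union[str, Path]) -> list[SyntheticDataPoint]:
    """Reload a corpus written by :func:`write_corpus`.

    Planted probe atom ids are not recoverable from disk; the planted list
    carries pair index and rule signature only.
    """
    from helixspec.structure import parse_structure

    manifest = Path(manifest)
    base = manifest.parent
    corpus = []
    rows = manifest.read_text().strip().splitlines()[1:]
    for row in rows:
        pdb_name, pwm_name, label, planted_tok = row.split("\t")
        complex_ = parse_structure(base / pdb_name)
        truth = read_pwm(base / pwm_name)
        planted = []
        if planted_tok:
            for tok in planted_tok.split(";"):
                i, sig = tok.split(":")
                cls, grp = sig.split("@")
                planted.append((
                    int(i), ProbeRule(probe_class=cls, target_group=grp), ()
                ))
        corpus.append(SyntheticDataPoint(
            complex=complex_, truth_pwm=truth, planted=planted,
            group_label=label,
        ))
    return corpus
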