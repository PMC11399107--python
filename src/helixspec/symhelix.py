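"""The symmetrized helix: a sequence-agnostic stand-in for the DNA.

Each Watson–Crick pair gets an orthonormal right-handed *base-pair frame*
(origin at the midpoint of the two glycosidic nitrogens, y along the
Crick-C1′→Watson-C1′ axis, z along the local helix direction, x toward the
major groove).  The DNA is then replaced by 11 grouped, oriented points per
pair:

* 7 base-edge points placed at canonical template offsets in the frame —
  4 in the major groove, 3 in the minor groove.  Their positions depend only
  on the frame, never on the base identity, which is how sequence information
  is removed while double-helix shape is preserved.
* 4 backbone points taken from the actual coordinates — the two strand
  phosphates (P atoms) and the two sugar-ring centroids.

Every point carries an outward normal (away from the frame origin) and the
local helix-axis direction, the geometric cues the bipartite convolutions
consume.  Per-pair shape features (minor groove width, twist, rise, roll) are
derived from the frames and cross-strand phosphate distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from helixspec.errors import GeometryError, InputError
from helixspec.pwm import _BASE_INDEX
from helixspec.structure import BasePair

GROUP_ORDER = ("major", "minor", "phosphate", "sugar")
GROUP_SLOTS = {"major": 4, "minor": 3, "phosphate": 2, "sugar": 2}
POINTS_PER_PAIR = 11

# Canonical base-edge template offsets in frame coordinates (Å); +x faces the
# major groove.  Config-overridable: pass a template dict to build_sym_helix.
DEFAULT_BASE_EDGE_TEMPLATE: dict[str, tuple[tuple[float, float, float], ...]] = {
    "major": ((2.2, -2.4, 0.0), (2.9, -0.8, 0.0), (2.9, 0.8, 0.0), (2.2, 2.4, 0.0)),
    "minor": ((-2.6, -1.6, 0.0), (-3.0, 0.0, 0.0), (-2.6, 1.6, 0.0)),
}

# minor-groove width: cross-strand P–P distance minus two phosphate radii
PHOSPHATE_RADIUS_CORRECTION = 5.8
_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class Frame:
    """Orthonormal right-handed base-pair frame."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("frame axes not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis,
                           atol=_ORTHO_TOL):
            raise GeometryError("frame not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3×3 matrix with columns x, y, z (frame → lab)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    def to_lab(self, local: np.ndarray) -> np.ndarray:
        return self.origin + self.rotation @ np.asarray(local, float)


@dataclass
class SymHelixPoint:
    pair_index: int
    group: str
    slot: int
    position: np.ndarray
    outward_normal: np.ndarray
    axis_dir: np.ndarray
    seq_feature: Optional[np.ndarray] = None
    present: bool = True


@dataclass
class SymHelix:
    """Ordered sym-helix points plus per-pair frames and shape features.

    Points are ordered pair-major: by pair index, then group in the fixed
    order major→minor→phosphate→sugar, then slot.
    """

    points: list[SymHelixPoint]
    frames: list[Frame]
    n_pairs: int
    shape: Optional[np.ndarray] = None  # (n_pairs, 4): mgw, twist, rise, roll

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [k for k, p in enumerate(self.points) if p.group == group], int
        )

    def present_mask(self) -> np.ndarray:
        return np.array([p.present for p in self.points], bool)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymHelix):
            return NotImplemented
        if self.n_pairs != other.n_pairs or len(self.points) != len(other.points):
            return False
        for a, b in zip(self.points, other.points):
            if (a.pair_index, a.group, a.slot, a.present) != (
                    b.pair_index, b.group, b.slot, b.present):
                return False
            if not (np.allclose(a.position, b.position, atol=1e-9)
                    and np.allclose(a.outward_normal, b.outward_normal, atol=1e-9)
                    and np.allclose(a.axis_dir, b.axis_dir, atol=1e-9)):
                return False
            if (a.seq_feature is None) != (b.seq_feature is None):
                return False
            if a.seq_feature is not None and not np.array_equal(
                    a.seq_feature, b.seq_feature):
                return False
        return True


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise GeometryError(f"degenerate geometry: zero-length {context}")
    return v / n


def compute_frame(
    pair: BasePair,
    prev_origin: Optional[np.ndarray] = None,
    next_origin: Optional[np.ndarray] = None,
) -> Frame:
    """Base-pair frame from C1′/glycosidic-N anchors and neighbor origins.

    The local helix direction needs at least one neighboring pair origin;
    an isolated pair raises :class:`GeometryError`.
    """
    origin = 0.5 * (pair.watson.glycosidic_nitrogen.position
                    + pair.crick.glycosidic_nitrogen.position)
    y = _unit(pair.watson.c1p.position - pair.crick.c1p.position, "C1'-C1' axis")

    if prev_origin is None and next_origin is None:
        raise GeometryError(
            f"pair {pair.pair_index}: no neighboring pair to define the helix axis"
        )
    lo = prev_origin if prev_origin is not None else origin
    hi = next_origin if next_origin is not None else origin
    z_raw = np.asarray(hi, float) - np.asarray(lo, float)
    z_raw = z_raw - np.dot(z_raw, y) * y
    z = _unit(z_raw, "helix axis (collinear anchors)")
    x = np.cross(y, z)

    # x must point toward the major groove: same sense as the vector from the
    # C1'-C1' midpoint to the glycosidic-N midpoint. Flip z (and hence x) if
    # needed; right-handedness is preserved.
    c1_mid = 0.5 * (pair.watson.c1p.position + pair.crick.c1p.position)
    toward_major = origin - c1_mid
    if np.dot(x, toward_major) < 0:
        x, z = -x, -z
    return Frame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def compute_frames(duplex: Sequence[BasePair]) -> list[Frame]:
    """Frames for a whole duplex; terminal pairs use their single neighbor."""
    origins = [
        0.5 * (bp.watson.glycosidic_nitrogen.position
               + bp.crick.glycosidic_nitrogen.position)
        for bp in duplex
    ]
    n = len(duplex)
    frames = []
    for i, bp in enumerate(duplex):
        frames.append(compute_frame(
            bp,
            prev_origin=origins[i - 1] if i > 0 else None,
            next_origin=origins[i + 1] if i < n - 1 else None,
        ))
    return frames


def build_sym_helix(
    duplex: Sequence[BasePair],
    template: Optional[dict] = None,
) -> SymHelix:
    """Replace a duplex by its sym-helix points.

    Base-edge points are template offsets expressed in each pair's frame;
    phosphate points are the actual P positions of the two strands (marked
    absent when the P atom is missing, e.g. at a 5′ terminus); sugar points
    are the per-strand sugar-ring centroids.
    """
    template = dict(DEFAULT_BASE_EDGE_TEMPLATE if template is None else template)
    if len(template["major"]) != 4 or len(template["minor"]) != 3:
        raise InputError("base-edge template must have 4 major and 3 minor slots")
    frames = compute_frames(duplex)
    points: list[SymHelixPoint] = []

    def norm_from(origin: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return _unit(pos - origin, "outward normal")

    for bp, frame in zip(duplex, frames):
        for group in ("major", "minor"):
            for slot, offset in enumerate(template[group]):
                pos = frame.to_lab(offset)
                points.append(SymHelixPoint(
                    pair_index=bp.pair_index, group=group, slot=slot,
                    position=pos,
                    outward_normal=norm_from(frame.origin, pos),
                    axis_dir=frame.z_axis.copy(),
                ))
        for slot, nt in enumerate((bp.watson, bp.crick)):
            if nt.phosphate is not None:
                pos = nt.phosphate.position.copy()
                present = True
                normal = norm_from(frame.origin, pos)
            else:
                pos = frame.origin.copy()
                present = False
                normal = np.zeros(3)
            points.append(SymHelixPoint(
                pair_index=bp.pair_index, group="phosphate", slot=slot,
                position=pos, outward_normal=normal,
                axis_dir=frame.z_axis.copy(), present=present,
            ))
        for slot, nt in enumerate((bp.watson, bp.crick)):
            pos = nt.sugar_centroid
            points.append(SymHelixPoint(
                pair_index=bp.pair_index, group="sugar", slot=slot,
                position=pos,
                outward_normal=norm_from(frame.origin, pos),
                axis_dir=frame.z_axis.copy(),
            ))
    helix = SymHelix(points=points, frames=frames, n_pairs=len(duplex))
    helix.shape = compute_shape_features(helix)
    return helix


def attach_sequence(helix: SymHelix, sequence: str) -> SymHelix:
    """Reintroduce sequence identity: every point of pair i carries the
    one-hot of ``sequence[i]``.  Returns a new helix; all else unchanged."""
    if len(sequence) != helix.n_pairs:
        raise InputError(
            f"sequence length {len(sequence)} != n_pairs {helix.n_pairs}"
        )
    onehots = []
    for b in sequence:
        if b not in _BASE_INDEX:
            raise InputError(f"invalid base {b!r}")
        v = np.zeros(4)
        v[_BASE_INDEX[b]] = 1.0
        onehots.append(v)
    new_points = [
        replace(p, seq_feature=onehots[p.pair_index].copy())
        for p in helix.points
    ]
    return SymHelix(points=new_points, frames=helix.frames,
                    n_pairs=helix.n_pairs, shape=helix.shape)


def detach_sequence(helix: SymHelix) -> SymHelix:
    """Drop any attached sequence identity (inverse of attach_sequence)."""
    new_points = [replace(p, seq_feature=None) for p in helix.points]
    return SymHelix(points=new_points, frames=helix.frames,
                    n_pairs=helix.n_pairs, shape=helix.shape)


def _signed_angle_deg(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    return math.degrees(math.atan2(
        float(np.dot(np.cross(a, b), axis)), float(np.dot(a, b))
    ))


def compute_shape_features(helix: SymHelix) -> np.ndarray:
    """Per-pair shape vector (minor_groove_width Å, twist °, rise Å, roll °).

    Step parameters come from the relative transform between consecutive
    frames and are assigned to the earlier pair (the last pair copies its
    neighbor).  Minor groove width at pair i is the minimum cross-strand
    distance between the Watson phosphate of pair i and the Crick phosphates
    of pairs i−4…i−2, minus 5.8 Å of phosphate radii, floored at 0; pairs
    lacking the needed phosphates get the helix-mean width imputed.
    """
    n = helix.n_pairs
    if n < 4:
        raise InputError(f"need >= 4 pairs for shape features, got {n}")
    frames = helix.frames
    twist = np.zeros(n)
    rise = np.zeros(n)
    roll = np.zeros(n)
    for i in range(n - 1):
        f0, f1 = frames[i], frames[i + 1]
        twist[i] = _signed_angle_deg(f0.x_axis, f1.x_axis, f0.z_axis)
        rise[i] = float(np.dot(f1.origin - f0.origin, f0.z_axis))
        roll[i] = _signed_angle_deg(f0.z_axis, f1.z_axis, f0.y_axis)
    twist[n - 1], rise[n - 1], roll[n - 1] = twist[n - 2], rise[n - 2], roll[n - 2]

    # phosphate positions per (pair, strand-slot)
    phos: dict[tuple[int, int], np.ndarray] = {}
    for p in helix.points:
        if p.group == "phosphate" and p.present:
            phos[(p.pair_index, p.slot)] = p.position

    mgw = np.full(n, np.nan)
    for i in range(n):
        pw = phos.get((i, 0))
        if pw is None:
            continue
        dists = [
            float(np.linalg.norm(pw - phos[(j, 1)]))
            for j in range(max(0, i - 4), i - 1)
            if (j, 1) in phos
        ]
        if dists:
            mgw[i] = max(0.0, min(dists) - PHOSPHATE_RADIUS_CORRECTION)
    if np.all(np.isnan(mgw)):
        mgw[:] = 0.0
    else:
        mgw = np.where(np.isnan(mgw), np.nanmean(mgw), mgw)
    return np.column_stack([mgw, twist, rise, roll])


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def sym_helix_table(helix: SymHelix) -> str:
    """Tabular text export: one point per row."""
    lines = ["pair_index\tgroup\tslot\tx\ty\tz\tnx\tny\tnz\tpresent"]
    for p in helix.points:
        lines.append("\t".join([
            str(p.pair_index), p.group, str(p.slot),
            *(f"{v:.4f}" for v in p.position),
            *(f"{v:.4f}" for v in p.outward_normal),
            "1" if p.present else "0",
        ]))
    return "\n".join(lines) + "\n"


_GROUP_PSEUDO = {"major": "MAJ", "minor": "MIN", "phosphate": "PHO", "sugar": "SUG"}


def write_sym_helix_pdb(helix: SymHelix, path: Union[str, Path]) -> None:
    """PDB-like pseudo-atom file for visualization (one HETATM per point)."""
    lines = []
    serial = 1
    for p in helix.points:
        if not p.present:
            continue
        x, y, z = p.position
        lines.append(
            f"HETATM{serial:5d}  C   {_GROUP_PSEUDO[p.group]} H"
            f"{p.pair_index + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{float(p.slot):6.2f}           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
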