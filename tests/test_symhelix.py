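"""Base-pair frames, sym-helix construction and shape features."""

import numpy as np
import pytest

import helixspec as hx
from helixspec.errors import GeometryError, InputError
from helixspec.symhelix import (
    GROUP_SLOTS,
    attach_sequence,
    build_sym_helix,
    compute_frame,
    compute_frames,
    compute_shape_features,
    detach_sequence,
    sym_helix_table,
)
from test_structure import swap_chain_ids


def random_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    # QR of a random matrix gives a uniform-ish rotation; fix determinant
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return q, t


def transform_nucleotides(nucleotides, q, t):
    out = []
    for nt in nucleotides:
        atoms = [
            hx.Atom(
                atom_id=a.atom_id, element=a.element, atom_name=a.atom_name,
                residue_name=a.residue_name, residue_index=a.residue_index,
                chain_id=a.chain_id, position=q @ a.position + t,
                is_protein=a.is_protein,
            )
            for a in nt.atoms
        ]
        by_name = {a.atom_name: a for a in atoms}
        out.append(hx.Nucleotide(
            chain_id=nt.chain_id, residue_index=nt.residue_index,
            base=nt.base, atoms=atoms, c1p=by_name["C1'"],
            glycosidic_nitrogen=by_name[nt.glycosidic_nitrogen.atom_name],
            phosphate=by_name.get("P"),
        ))
    return out


class TestFrames:
    def test_frames_are_orthonormal_right_handed(self, pairs12):
        for f in compute_frames(pairs12):
            axes = np.stack([f.x_axis, f.y_axis, f.z_axis])
            np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(
                np.cross(f.x_axis, f.y_axis), f.z_axis, atol=1e-9
            )

    def test_ideal_bdna_step_geometry(self, pairs12):
        """Consecutive frames: ~36° twist about z and ~3.4 Å rise."""
        frames = compute_frames(pairs12)
        twists, rises = [], []
        for f0, f1 in zip(frames[:-1], frames[1:]):
            cos_twist = float(np.dot(f0.x_axis, f1.x_axis))
            twists.append(np.degrees(np.arccos(np.clip(cos_twist, -1, 1))))
            rises.append(float(np.dot(f1.origin - f0.origin, f0.z_axis)))
        # per-step values jitter with the generator's coordinate noise;
        # the mean recovers the generator parameters tightly
        assert np.mean(twists) == pytest.approx(36.0, abs=0.5)
        assert np.mean(rises) == pytest.approx(3.4, abs=0.05)
        assert np.all(np.abs(np.array(twists) - 36.0) < 2.0)
        assert np.all(np.abs(np.array(rises) - 3.4) < 0.2)

    def test_mirror_image_keeps_right_handedness(self, bdna12):
        mirrored = transform_nucleotides(bdna12, np.diag([1.0, 1.0, -1.0]),
                                         np.zeros(3))
        # mirroring is not rigid; frames must still come out right-handed
        pairs = hx.detect_base_pairs(mirrored)
        for f in compute_frames(pairs):
            np.testing.assert_allclose(
                np.cross(f.x_axis, f.y_axis), f.z_axis, atol=1e-9
            )

    def test_isolated_pair_is_geometry_error(self, pairs12):
        with pytest.raises(GeometryError):
            compute_frame(pairs12[5])


class TestBuildSymHelix:
    def test_counts_per_pair(self, helix12):
        for i in range(helix12.n_pairs):
            pts = [p for p in helix12.points if p.pair_index == i]
            by_group = {g: [p for p in pts if p.group == g]
                        for g in GROUP_SLOTS}
            assert len(by_group["major"]) == 4
            assert len(by_group["minor"]) == 3
            assert len(by_group["phosphate"]) == 2
            assert len(by_group["sugar"]) == 2
            base_edge = by_group["major"] + by_group["minor"]
            assert len(base_edge) == 7
            assert len(pts) == 11

    def test_total_count(self, helix12):
        assert len(helix12.points) == 11 * helix12.n_pairs
        assert all(p.present for p in helix12.points)

    def test_missing_phosphate_marked_absent(self):
        # fresh duplex: this test strips an atom in place
        nts = hx.make_bdna("ACGTACGTACGT", seed=1)
        victim = nts[0]
        victim.atoms = [a for a in victim.atoms if a.atom_name != "P"]
        victim.phosphate = None
        helix = build_sym_helix(hx.detect_base_pairs(nts))
        absent = [p for p in helix.points if not p.present]
        assert len(absent) == 1
        assert absent[0].group == "phosphate"

    def test_sequence_invariance(self):
        """Identical coordinates, relabeled bases → identical point positions."""
        nts_a = hx.make_bdna("ACGTACGTACGT", seed=9,
                             params=hx.HelixParams(coordinate_noise_sd=0.0))
        nts_b = hx.make_bdna("GCATGCATGCAT", seed=9,
                             params=hx.HelixParams(coordinate_noise_sd=0.0))
        ha = build_sym_helix(hx.detect_base_pairs(nts_a))
        hb = build_sym_helix(hx.detect_base_pairs(nts_b))
        np.testing.assert_allclose(ha.positions(), hb.positions(), atol=1e-12)

    def test_rigid_motion_equivariance(self, bdna12, helix12):
        q, t = random_rigid_transform(4)
        moved = transform_nucleotides(bdna12, q, t)
        helix_t = build_sym_helix(hx.detect_base_pairs(moved))
        np.testing.assert_allclose(
            helix_t.positions(), helix12.positions() @ q.T + t, atol=1e-6
        )
        for p0, p1 in zip(helix12.points, helix_t.points):
            np.testing.assert_allclose(p1.outward_normal,
                                       q @ p0.outward_normal, atol=1e-6)
            np.testing.assert_allclose(p1.axis_dir, q @ p0.axis_dir, atol=1e-6)

    def test_strand_swap_point_multiset(self, bdna12, helix12):
        """Swapped chain records: same points, reversed pair order,
        Watson/Crick backbone slots exchanged."""
        swapped = build_sym_helix(hx.detect_base_pairs(swap_chain_ids(bdna12)))
        n = helix12.n_pairs
        for p in swapped.points:
            mirror_pair = n - 1 - p.pair_index
            slot = p.slot
            if p.group in ("phosphate", "sugar"):
                slot = 1 - p.slot
            group = p.group
            if group in ("major", "minor"):
                # base-edge template is y-symmetric; slots mirror within group
                slot = GROUP_SLOTS[group] - 1 - p.slot
            match = [
                q for q in helix12.points
                if q.pair_index == mirror_pair and q.group == group
                and q.slot == slot
            ]
            assert len(match) == 1
            np.testing.assert_allclose(p.position, match[0].position, atol=1e-9)


class TestAttachSequence:
    def test_one_hot_attachment(self, pairs12):
        helix = build_sym_helix(pairs12[:4])
        seq = "ACGT"
        attached = attach_sequence(helix, seq)
        for p in attached.points:
            expected = np.zeros(4)
            expected["ACGT".index(seq[p.pair_index])] = 1.0
            np.testing.assert_array_equal(p.seq_feature, expected)

    def test_detach_is_inverse(self, helix12):
        attached = attach_sequence(helix12, "ACGTACGTACGT")
        assert detach_sequence(attached) == helix12

    def test_length_mismatch_rejected(self, helix12):
        with pytest.raises(InputError):
            attach_sequence(helix12, "ACGT")


class TestShapeFeatures:
    def test_parameter_recovery(self, helix12):
        shape = helix12.shape
        assert shape[:, 1].mean() == pytest.approx(36.0, abs=0.5)
        assert shape[:, 2].mean() == pytest.approx(3.4, abs=0.05)

    def test_distinguishes_twist_34_from_36(self):
        params34 = hx.HelixParams(twist=34.0)
        nts = hx.make_bdna("ACGTACGTACGT", params=params34, seed=5)
        helix = hx.build_sym_helix(hx.detect_base_pairs(nts))
        assert helix.shape[:, 1].mean() == pytest.approx(34.0, abs=0.5)

    def test_rigid_invariance(self, bdna12, helix12):
        q, t = random_rigid_transform(11)
        moved = transform_nucleotides(bdna12, q, t)
        helix_t = hx.build_sym_helix(hx.detect_base_pairs(moved))
        np.testing.assert_allclose(
            compute_shape_features(helix_t), helix12.shape, atol=1e-6
        )

    def test_narrower_phase_narrows_minor_groove(self):
        wide = hx.make_bdna("ACGTACGTACGT", seed=3,
                            params=hx.HelixParams(minor_groove_phase=170.0))
        narrow = hx.make_bdna("ACGTACGTACGT", seed=3,
                              params=hx.HelixParams(minor_groove_phase=130.0))
        mgw = [
            hx.build_sym_helix(hx.detect_base_pairs(n)).shape[:, 0].mean()
            for n in (wide, narrow)
        ]
        assert mgw[1] < mgw[0]


def test_table_export_row_count(helix12):
    table = sym_helix_table(helix12)
    assert len(table.strip().splitlines()) == 1 + len(helix12.points)
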