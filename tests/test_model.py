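"""End-to-end properties of the specificity network."""

import dataclasses

import numpy as np
import pytest

import helixspec as hx
from helixspec.errors import ConfigError
from helixspec.model import (
    EdgeMask,
    ModelConfig,
    SpecNet,
    predict_pwm,
    prepare_inputs,
)
from helixspec.nn import Tensor
from test_symhelix import random_rigid_transform, transform_nucleotides


def transform_complex(complex_, q, t):
    atoms = [
        hx.Atom(
            atom_id=a.atom_id, element=a.element, atom_name=a.atom_name,
            residue_name=a.residue_name, residue_index=a.residue_index,
            chain_id=a.chain_id, position=q @ a.position + t,
            is_protein=True,
        )
        for a in complex_.protein_atoms
    ]
    nts = {}
    for bp in complex_.duplex:
        for nt in (bp.watson, bp.crick):
            nts[(nt.chain_id, nt.residue_index)] = nt
    moved = transform_nucleotides(list(nts.values()), q, t)
    pairs = hx.detect_base_pairs(moved)
    return hx.ComplexStructure(protein_atoms=atoms, duplex=pairs,
                               source_id=complex_.source_id)


@pytest.fixture(scope="module")
def model_and_inputs(probe_datapoint):
    config = ModelConfig(seed=5)
    model = SpecNet(config)
    # random weights everywhere except the (intentionally zero) head
    rng = np.random.default_rng(8)
    model.head.weight.data = rng.normal(scale=0.3, size=model.head.weight.shape)
    model.head.bias.data = rng.normal(scale=0.1, size=model.head.bias.shape)
    inputs = prepare_inputs(probe_datapoint.complex, config)
    return model, inputs


class TestPredictionContract:
    def test_pwm_shape_and_simplex(self, model_and_inputs, probe_datapoint):
        model, inputs = model_and_inputs
        result = model.predict(inputs)
        assert result.pwm.probs.shape == (probe_datapoint.complex.n_pairs, 4)
        np.testing.assert_allclose(result.pwm.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(result.pwm.probs > 0) and np.all(result.pwm.probs < 1)

    def test_zero_head_gives_exact_uniform(self, probe_datapoint):
        model = SpecNet(ModelConfig(seed=1))  # head is zero-initialized
        result = model.predict(probe_datapoint.complex)
        np.testing.assert_array_equal(result.pwm.probs, 0.25)

    def test_determinism_across_instances(self, probe_datapoint):
        config = ModelConfig(seed=9)
        p1 = SpecNet(config).predict(probe_datapoint.complex).pwm.probs
        p2 = SpecNet(config).predict(probe_datapoint.complex).pwm.probs
        np.testing.assert_array_equal(p1, p2)

    def test_rigid_motion_invariance(self, model_and_inputs, probe_datapoint):
        model, inputs = model_and_inputs
        ref = model.predict(inputs).pwm.probs
        for seed in (21, 22):
            q, t = random_rigid_transform(seed)
            moved = transform_complex(probe_datapoint.complex, q, t)
            got = model.predict(moved).pwm.probs
            np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_sequence_relabel_invariance(self, model_and_inputs):
        """With SeqInfo off the prediction ignores base identity."""
        model, _ = model_and_inputs
        params = hx.HelixParams(coordinate_noise_sd=0.0)
        rules = [(5, hx.ProbeRule("donor", "major"))]
        a = hx.plant_probes(hx.make_bdna("ACGTACGTACGT", params, seed=3),
                            rules, seed=4)
        b = hx.plant_probes(hx.make_bdna("GCATGCATGCAT", params, seed=3),
                            rules, seed=4)
        pa = model.predict(a.complex).pwm.probs
        pb = model.predict(b.complex).pwm.probs
        np.testing.assert_array_equal(pa, pb)

    def test_seqinfo_mode_sees_sequence(self):
        config = ModelConfig(mode="full_seqinfo", seed=2)
        model = SpecNet(config)
        rng = np.random.default_rng(0)
        model.head.weight.data = rng.normal(scale=0.3,
                                            size=model.head.weight.shape)
        params = hx.HelixParams(coordinate_noise_sd=0.0)
        rules = [(5, hx.ProbeRule("donor", "major"))]
        a = hx.plant_probes(hx.make_bdna("ACGTACGTACGT", params, seed=3),
                            rules, seed=4)
        b = hx.plant_probes(hx.make_bdna("GCATGCATGCAT", params, seed=3),
                            rules, seed=4)
        pa = model.predict(a.complex).pwm.probs
        pb = model.predict(b.complex).pwm.probs
        assert not np.allclose(pa, pb)


class TestMasking:
    def test_mask_of_far_atom_is_bitwise_noop(self, model_and_inputs):
        model, inputs = model_and_inputs
        ref = model.predict(inputs).pwm.probs
        # an id not on any bipartite edge changes nothing, bit for bit
        edge_atoms = {
            inputs.atom_ids[i]
            for arr in inputs.bip_atom.values() for i in arr
        }
        non_edge = sorted(set(inputs.atom_ids) - edge_atoms)
        mask = EdgeMask.of(non_edge or {"Z/999/XX"})
        got = model.predict(inputs, mask).pwm.probs
        np.testing.assert_array_equal(got, ref)

    def test_masking_all_atoms_zeroes_bipartite_messages(self, model_and_inputs):
        model, inputs = model_and_inputs
        mask = EdgeMask.of(set(inputs.atom_ids))
        result = model.predict(inputs, mask)
        for group, emb in result.per_point_embeddings.items():
            np.testing.assert_array_equal(emb, 0.0)

    def test_masking_contact_atom_changes_prediction(self, model_and_inputs):
        model, inputs = model_and_inputs
        ref = model.predict(inputs).pwm.probs
        edge_atoms = sorted({
            inputs.atom_ids[i]
            for arr in inputs.bip_atom.values() for i in arr
        })
        got = model.predict(inputs, EdgeMask.of({edge_atoms[0]})).pwm.probs
        assert not np.array_equal(got, ref)


class TestModes:
    def test_groove_mode_ignores_backbone_and_shape(self, probe_datapoint):
        config = ModelConfig(mode="groove", seed=6)
        model = SpecNet(config)
        rng = np.random.default_rng(1)
        model.head.weight.data = rng.normal(scale=0.3,
                                            size=model.head.weight.shape)
        inputs = prepare_inputs(probe_datapoint.complex, config)
        ref = model.predict(inputs).pwm.probs
        # wipe backbone edges and shape features: groove output unchanged
        stripped = dataclasses.replace(
            inputs,
            bip_atom={**inputs.bip_atom,
                      "phosphate": np.zeros(0, int), "sugar": np.zeros(0, int)},
            bip_point={**inputs.bip_point,
                       "phosphate": np.zeros(0, int), "sugar": np.zeros(0, int)},
            bip_geo={**inputs.bip_geo,
                     "phosphate": inputs.bip_geo["phosphate"][:0],
                     "sugar": inputs.bip_geo["sugar"][:0]},
            shape_z=np.full_like(inputs.shape_z, 7.7),
        )
        np.testing.assert_array_equal(model.predict(stripped).pwm.probs, ref)

    def test_shape_mode_ignores_groove(self, probe_datapoint):
        config = ModelConfig(mode="shape", seed=6)
        model = SpecNet(config)
        rng = np.random.default_rng(1)
        model.head.weight.data = rng.normal(scale=0.3,
                                            size=model.head.weight.shape)
        inputs = prepare_inputs(probe_datapoint.complex, config)
        ref = model.predict(inputs).pwm.probs
        stripped = dataclasses.replace(
            inputs,
            bip_atom={**inputs.bip_atom,
                      "major": np.zeros(0, int), "minor": np.zeros(0, int)},
            bip_point={**inputs.bip_point,
                       "major": np.zeros(0, int), "minor": np.zeros(0, int)},
            bip_geo={**inputs.bip_geo,
                     "major": inputs.bip_geo["major"][:0],
                     "minor": inputs.bip_geo["minor"][:0]},
        )
        np.testing.assert_array_equal(model.predict(stripped).pwm.probs, ref)

    def test_active_embeddings_match_mode(self, probe_datapoint):
        for mode, groups in [
            ("groove", {"major", "minor"}),
            ("shape", {"phosphate", "sugar"}),
            ("full", {"major", "minor", "phosphate", "sugar"}),
        ]:
            model = SpecNet(ModelConfig(mode=mode, seed=0))
            result = model.predict(probe_datapoint.complex)
            assert set(result.per_point_embeddings) == groups


class TestProteinMessagePassing:
    def test_isolated_vertex_is_input_projection(self):
        """With no edges the embedding is the learnable map of the features."""
        from helixspec.protein import build_graph
        from test_protein import atom

        config = ModelConfig(seed=3)
        model = SpecNet(config)
        atoms = [atom("ALA", "CB", "C", (0, 0, 0)),
                 atom("ALA", "CB", "C", (30, 0, 0), idx=2)]
        graph = build_graph(atoms, r_graph=4.0)
        feats = graph.feature_matrix()
        h = model.protein_embeddings(prepare_fake_inputs(model, feats))
        expected = model.lin_in(Tensor(feats)).data
        np.testing.assert_array_equal(h.data, expected)

    def test_duplicated_subgraph_gets_identical_embeddings(self, probe_datapoint):
        config = ModelConfig(seed=4)
        model = SpecNet(config)
        inputs = prepare_inputs(probe_datapoint.complex, config)
        h = model.protein_embeddings(inputs).data
        # the two probes are geometrically congruent fragments with distinct
        # chemistry; per-atom embeddings must be equal across exact copies
        n = inputs.features.shape[0]
        doubled = dataclasses.replace(
            inputs,
            features=np.vstack([inputs.features, inputs.features]),
            edge_src=np.concatenate([inputs.edge_src, inputs.edge_src + n]),
            edge_dst=np.concatenate([inputs.edge_dst, inputs.edge_dst + n]),
            edge_rbf=np.vstack([inputs.edge_rbf, inputs.edge_rbf]),
        )
        h2 = model.protein_embeddings(doubled).data
        np.testing.assert_allclose(h2[:n], h, atol=1e-12)
        np.testing.assert_allclose(h2[n:], h, atol=1e-12)


def prepare_fake_inputs(model, feats):
    """Minimal ModelInputs stand-in for protein-embedding unit tests."""
    import types

    return types.SimpleNamespace(
        features=feats,
        edge_src=np.zeros(0, int),
        edge_dst=np.zeros(0, int),
        edge_rbf=np.zeros((0, model.config.n_rbf)),
    )


class TestCheckpoint:
    def test_round_trip(self, tmp_path, probe_datapoint):
        model = SpecNet(ModelConfig(seed=7))
        rng = np.random.default_rng(2)
        for _, p in model.parameters():
            p.data = rng.normal(scale=0.2, size=p.shape)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SpecNet.load(path)
        a = model.predict(probe_datapoint.complex).pwm.probs
        b = loaded.predict(probe_datapoint.complex).pwm.probs
        np.testing.assert_array_equal(a, b)

    def test_version_mismatch_refused(self, tmp_path):
        import json

        model = SpecNet(ModelConfig(seed=0))
        path = tmp_path / "model.npz"
        model.save(path)
        data = dict(np.load(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["format"] = "helixspec-ckpt-0"
        data["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(tmp_path / "old.npz", **data)
        with pytest.raises(ConfigError):
            SpecNet.load(tmp_path / "old.npz")


def test_predict_pwm_wrapper(probe_datapoint):
    model = SpecNet(ModelConfig(seed=0))
    result = predict_pwm(model, probe_datapoint.complex)
    assert result.pwm.probs.shape == (12, 4)
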