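"""The specificity network.

Pipeline: spatial message passing on the protein heavy-atom graph →
four grouped bipartite geometric convolutions from protein atoms onto the
sym-helix points (one parameter set per point group: major groove, minor
groove, phosphate, sugar) → flattening of point features to a per-base-pair
1D sequence (concatenated with z-scored DNA shape features and, optionally,
sequence one-hots) → same-length 1D convolutions → a 4-way linear head with
per-position softmax, yielding an N×4 PWM over the whole duplex including
flanks.

All geometric quantities entering the network (edge lengths, angle cosines
between edge directions and point normals / local helix axes) are rigid-
motion invariant scalars, so the prediction is invariant under rigid
transforms of the input complex by construction.  Readout modes:

* ``full`` — all four point groups plus shape features;
* ``groove`` — major/minor convolutions only, no backbone, no shape;
* ``shape`` — phosphate/sugar convolutions plus shape features, no groove;
* ``full_seqinfo`` — ``full`` with the structure's DNA sequence reattached
  as a point feature.

Bipartite edge masks remove edges of selected protein atoms only; the
protein graph itself is never altered.  This is the hook the interpretation
module uses for atom-importance scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from helixspec.errors import ConfigError
from helixspec.nn.autodiff import Tensor, concat, constant, segment_max, \
    segment_mean, softmax_rows, take_rows
from helixspec.nn.layers import MLP, Conv1d, Linear, Module, rbf_expand
from helixspec.protein import N_ATOM_FEATURES, ProteinGraph, build_graph
from helixspec.pwm import PWM
from helixspec.structure import ComplexStructure
from helixspec.symhelix import GROUP_ORDER, GROUP_SLOTS, SymHelix, build_sym_helix

CHECKPOINT_FORMAT = "helixspec-ckpt-1"

MODES = ("full", "groove", "shape", "full_seqinfo")
_ACTIVE_GROUPS = {
    "full": ("major", "minor", "phosphate", "sugar"),
    "full_seqinfo": ("major", "minor", "phosphate", "sugar"),
    "groove": ("major", "minor"),
    "shape": ("phosphate", "sugar"),
}
_SHAPE_MODES = ("full", "shape", "full_seqinfo")


@dataclass(frozen=True)
class ModelConfig:
    mode: str = "full"
    embed_dim: int = 32
    n_protein_layers: int = 3
    r_bipartite: float = 5.0
    n_rbf: int = 16
    conv1d_kernel: int = 5
    n_conv1d_layers: int = 2
    conv1d_channels: int = 48
    r_graph: float = 4.0
    max_degree: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; one of {MODES}")
        if self.r_bipartite <= 0:
            raise ConfigError("r_bipartite must be positive")
        if self.conv1d_kernel % 2 != 1:
            raise ConfigError("conv1d_kernel must be odd")

    @property
    def pair_feature_width(self) -> int:
        # 11 points × (mean ⊕ max) embeddings + 4 shape + 4 sequence slots;
        # inactive blocks are zero-filled so the width is mode-independent.
        return 11 * 2 * self.embed_dim + 4 + 4


@dataclass(frozen=True)
class EdgeMask:
    """Protein atoms whose bipartite edges are deactivated."""

    excluded_atoms: frozenset = frozenset()

    @staticmethod
    def of(atom_ids) -> "EdgeMask":
        return EdgeMask(frozenset(atom_ids))


EMPTY_MASK = EdgeMask()


@dataclass
class PredictionResult:
    pwm: PWM
    per_point_embeddings: dict[str, np.ndarray]


@dataclass
class ModelInputs:
    """Static per-complex arrays the forward pass consumes (mask-independent)."""

    atom_ids: list[str]
    atom_index: dict[str, int]
    features: np.ndarray            # (A, F_atom)
    edge_src: np.ndarray            # directed protein edges
    edge_dst: np.ndarray
    edge_rbf: np.ndarray            # (2E, n_rbf)
    bip_atom: dict[str, np.ndarray]      # per group: edge atom index
    bip_point: dict[str, np.ndarray]     # per group: edge point index (group-local)
    bip_geo: dict[str, np.ndarray]       # per group: (K, n_rbf + 2)
    n_points: dict[str, int]
    n_pairs: int
    shape_z: np.ndarray             # (n_pairs, 4), z-scored per helix
    seq_onehot: np.ndarray          # (n_pairs, 4)
    helix: SymHelix
    graph: ProteinGraph


def prepare_inputs(
    complex_: ComplexStructure,
    config: ModelConfig,
    template: Optional[dict] = None,
) -> ModelInputs:
    """Build the protein graph, sym-helix and bipartite edge arrays once."""
    graph = build_graph(
        complex_.protein_atoms, r_graph=config.r_graph,
        max_degree=config.max_degree,
    )
    helix = build_sym_helix(complex_.duplex, template=template)

    atom_ids = [a.atom_id for a in graph.atoms]
    atom_index = {aid: k for k, aid in enumerate(atom_ids)}
    pos = graph.positions()

    if graph.edges.size:
        src = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
        dst = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
        lengths = np.concatenate([graph.edge_lengths, graph.edge_lengths])
        edge_rbf = rbf_expand(lengths, config.n_rbf, config.r_graph)
    else:
        src = dst = np.zeros(0, int)
        edge_rbf = np.zeros((0, config.n_rbf))

    tree = cKDTree(pos)
    bip_atom: dict[str, np.ndarray] = {}
    bip_point: dict[str, np.ndarray] = {}
    bip_geo: dict[str, np.ndarray] = {}
    n_points: dict[str, int] = {}
    for group in GROUP_ORDER:
        idxs = helix.group_indices(group)
        n_points[group] = len(idxs)
        atoms_k, points_k, geo_k = [], [], []
        for local, pt_idx in enumerate(idxs):
            p = helix.points[pt_idx]
            if not p.present:
                continue
            for a in sorted(tree.query_ball_point(p.position, config.r_bipartite)):
                delta = pos[a] - p.position
                d = float(np.linalg.norm(delta))
                u = delta / d if d > 1e-9 else np.zeros(3)
                atoms_k.append(a)
                points_k.append(local)
                geo_k.append(np.concatenate([
                    rbf_expand([d], config.n_rbf, config.r_bipartite)[0],
                    [float(u @ p.outward_normal), float(u @ p.axis_dir)],
                ]))
        bip_atom[group] = np.array(atoms_k, int)
        bip_point[group] = np.array(points_k, int)
        bip_geo[group] = (
            np.array(geo_k) if geo_k else np.zeros((0, config.n_rbf + 2))
        )

    shape = helix.shape
    mu = shape.mean(axis=0)
    sd = shape.std(axis=0)
    shape_z = (shape - mu) / np.where(sd > 1e-9, sd, 1.0)

    seq_onehot = PWM.from_sequence(complex_.dna_sequence).probs

    return ModelInputs(
        atom_ids=atom_ids, atom_index=atom_index,
        features=graph.feature_matrix(),
        edge_src=src, edge_dst=dst, edge_rbf=edge_rbf,
        bip_atom=bip_atom, bip_point=bip_point, bip_geo=bip_geo,
        n_points=n_points, n_pairs=helix.n_pairs,
        shape_z=shape_z, seq_onehot=seq_onehot,
        helix=helix, graph=graph,
    )


class SpecNet(Module):
    """Trainable structure→PWM model."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.lin_in = Linear(N_ATOM_FEATURES, d, rng)
        self.prot_layers = [
            MLP([d + config.n_rbf, d, d], rng)
            for _ in range(config.n_protein_layers)
        ]
        # one bipartite convolution per point group, each with its own weights
        self.bip_layers = [
            MLP([d + config.n_rbf + 2, d, d], rng) for _ in GROUP_ORDER
        ]
        channels = [config.pair_feature_width] + \
            [config.conv1d_channels] * config.n_conv1d_layers
        self.convs = [
            Conv1d(a, b, config.conv1d_kernel, rng)
            for a, b in zip(channels[:-1], channels[1:])
        ]
        # zero-initialized head: an untrained model predicts uniform columns
        self.head = Linear(channels[-1], 4, rng, zero_init=True)

    # -- forward ----------------------------------------------------------
    def protein_embeddings(self, inputs: ModelInputs) -> Tensor:
        """Spatial graph convolutions: residual mean-aggregated messages."""
        h = self.lin_in(constant(inputs.features))
        n = inputs.features.shape[0]
        rbf = constant(inputs.edge_rbf)
        for layer in self.prot_layers:
            if inputs.edge_src.size:
                msg = layer(concat([take_rows(h, inputs.edge_src), rbf], axis=1))
                h = h + segment_mean(msg, inputs.edge_dst, n)
            # no edges: the embedding stays the learnable map of the features
        return h

    def bipartite_readout(
        self, h: Tensor, inputs: ModelInputs, group: str,
        mask: EdgeMask = EMPTY_MASK,
    ) -> Tensor:
        """Mean⊕max aggregation of geometric messages onto one point group."""
        gi = GROUP_ORDER.index(group)
        n_pts = inputs.n_points[group]
        atoms = inputs.bip_atom[group]
        points = inputs.bip_point[group]
        geo = inputs.bip_geo[group]
        if mask.excluded_atoms:
            excluded = {
                inputs.atom_index[a] for a in mask.excluded_atoms
                if a in inputs.atom_index
            }
            if excluded:
                keep = ~np.isin(atoms, sorted(excluded))
                atoms, points, geo = atoms[keep], points[keep], geo[keep]
        if atoms.size == 0:
            zero = constant(np.zeros((n_pts, 2 * self.config.embed_dim)))
            return zero
        msg = self.bip_layers[gi](
            concat([take_rows(h, atoms), constant(geo)], axis=1)
        )
        return concat([
            segment_mean(msg, points, n_pts),
            segment_max(msg, points, n_pts),
        ], axis=1)

    def forward_probs(
        self, inputs: ModelInputs, mask: EdgeMask = EMPTY_MASK,
        return_embeddings: bool = False,
    ):
        cfg = self.config
        h = self.protein_embeddings(inputs)
        active = _ACTIVE_GROUPS[cfg.mode]
        blocks = []
        embeddings: dict[str, np.ndarray] = {}
        for group in GROUP_ORDER:
            slots = GROUP_SLOTS[group]
            if group in active:
                v = self.bipartite_readout(h, inputs, group, mask)
                embeddings[group] = v.data.copy()
                blocks.append(v.reshape(inputs.n_pairs, slots * 2 * cfg.embed_dim))
            else:
                blocks.append(constant(
                    np.zeros((inputs.n_pairs, slots * 2 * cfg.embed_dim))
                ))
        shape_block = (
            constant(inputs.shape_z) if cfg.mode in _SHAPE_MODES
            else constant(np.zeros_like(inputs.shape_z))
        )
        seq_block = (
            constant(inputs.seq_onehot) if cfg.mode == "full_seqinfo"
            else constant(np.zeros_like(inputs.seq_onehot))
        )
        x = concat(blocks + [shape_block, seq_block], axis=1)
        for conv in self.convs:
            x = conv(x).relu()
        probs = softmax_rows(self.head(x))
        if return_embeddings:
            return probs, embeddings
        return probs

    def predict(
        self,
        complex_or_inputs: Union[ComplexStructure, ModelInputs],
        mask: EdgeMask = EMPTY_MASK,
    ) -> PredictionResult:
        inputs = (
            complex_or_inputs
            if isinstance(complex_or_inputs, ModelInputs)
            else prepare_inputs(complex_or_inputs, self.config)
        )
        probs, embeddings = self.forward_probs(
            inputs, mask, return_embeddings=True
        )
        return PredictionResult(
            pwm=PWM(probs.data.copy()),
            per_point_embeddings=embeddings,
        )

    # -- persistence -------------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        meta = {"format": CHECKPOINT_FORMAT, "config": asdict(self.config)}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SpecNet":
        with np.load(path) as data:
            if "__meta__" not in data:
                raise ConfigError(f"not a model checkpoint: {path}")
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ConfigError(
                    f"checkpoint format {meta.get('format')!r} does not match "
                    f"{CHECKPOINT_FORMAT!r}"
                )
            model = cls(ModelConfig(**meta["config"]))
            model.load_state_dict(
                {k: v for k, v in data.items() if k != "__meta__"}
            )
        return model


def predict_pwm(
    model: SpecNet,
    complex_: Union[ComplexStructure, ModelInputs],
    mask: EdgeMask = EMPTY_MASK,
) -> PredictionResult:
    """Run the full pipeline on one complex and return the predicted PWM."""
    return model.predict(complex_, mask)
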