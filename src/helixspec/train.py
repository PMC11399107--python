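"""Training: loss, cluster-aware folds, gradient loop, ensembling, reports.

The loss is the L1 distance between predicted and target base probabilities,
averaged over the duplex columns the target PWM covers after its ungapped
alignment onto the structure's DNA sequence (uncovered flank columns carry
no loss).  This matches the MAE metric family used for evaluation; a
cross-entropy alternative is available by flag.  Alignment is computed once
when a datapoint is built and frozen during training.

Cross-validation folds are cluster-aware: all datapoints sharing a
``group_label`` land in the same fold.  The ensemble prediction is the
column-wise arithmetic mean of the member PWMs (a mean of simplex points
stays on the simplex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from helixspec.errors import HelixspecError, InputError
from helixspec.model import (
    EMPTY_MASK,
    EdgeMask,
    ModelConfig,
    ModelInputs,
    PredictionResult,
    SpecNet,
    prepare_inputs,
)
from helixspec.nn.autodiff import Tensor, constant, take_rows
from helixspec.nn.optim import Adam
from helixspec.pwm import PWM, AlignmentResult, align_pwm_to_sequence, mae, rmse
from helixspec.structure import ComplexStructure


@dataclass
class DataPoint:
    """One training example: a complex, its target PWM and their alignment."""

    complex: ComplexStructure
    target_pwm: PWM
    alignment: AlignmentResult
    group_label: str = ""
    inputs: Optional[ModelInputs] = None

    def covered_columns(self) -> np.ndarray:
        """Duplex column indices covered by the aligned target PWM."""
        return np.array(list(self.alignment.covered_positions(
            self.complex.n_pairs, len(self.target_pwm)
        )), int)

    def aligned_target(self) -> np.ndarray:
        """Target probability rows for each covered duplex column."""
        mat = self.target_pwm.probs
        if self.alignment.strand == "reverse":
            mat = self.target_pwm.reverse_complement().probs
        cols = self.covered_columns()
        return mat[cols - self.alignment.offset]


def build_datapoint(
    complex_: ComplexStructure,
    target_pwm: PWM,
    group_label: str = "",
    min_overlap: int = 4,
    alignment: Optional[AlignmentResult] = None,
) -> DataPoint:
    """Freeze the target→structure correspondence for loss computation.

    Without an explicit ``alignment`` the target PWM is placed by ungapped
    local alignment against the structure's DNA sequence — appropriate for
    experimentally derived PWMs whose register on the bound DNA is unknown.
    Pass an alignment (e.g. :func:`identity_alignment`) when the target is
    already in structure coordinates, as for synthetic ground truths: a
    near-uniform PWM carries almost no positional signal for the aligner,
    so re-aligning it against the sequence would scramble the register.
    """
    if alignment is None:
        alignment = align_pwm_to_sequence(
            target_pwm, complex_.dna_sequence, min_overlap=min_overlap
        )
    return DataPoint(
        complex=complex_, target_pwm=target_pwm,
        alignment=alignment, group_label=group_label,
    )


def identity_alignment(
    complex_: ComplexStructure, target_pwm: PWM
) -> AlignmentResult:
    """Positional correspondence: target row i ↔ duplex pair i."""
    from helixspec.pwm import _BASE_INDEX

    n = min(len(target_pwm), complex_.n_pairs)
    score = float(np.mean([
        target_pwm.probs[i, _BASE_INDEX[complex_.dna_sequence[i]]]
        for i in range(n)
    ]))
    return AlignmentResult(offset=0, strand="forward", score=score, overlap=n)


def datapoints_from_corpus(corpus) -> list[DataPoint]:
    """Datapoints for synthetic corpus entries (identity alignment)."""
    return [
        build_datapoint(
            sdp.complex, sdp.truth_pwm, group_label=sdp.group_label,
            alignment=identity_alignment(sdp.complex, sdp.truth_pwm),
        )
        for sdp in corpus
    ]


def make_folds(
    dataset: Sequence[DataPoint], k: int = 5, seed: int = 0
) -> list[list[DataPoint]]:
    """k disjoint folds; points sharing a group_label stay together.

    Groups are shuffled with the seed and dealt round-robin, so fold sizes
    are balanced to within one group.
    """
    groups: dict[str, list[DataPoint]] = {}
    for dp in dataset:
        groups.setdefault(dp.group_label, []).append(dp)
    labels = sorted(groups)
    if k > len(labels):
        raise InputError(
            f"k={k} exceeds number of distinct groups ({len(labels)})"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    folds: list[list[DataPoint]] = [[] for _ in range(k)]
    for pos, label in enumerate(labels):
        folds[pos % k].extend(groups[label])
    return folds


def column_loss(pred: PWM, dp: DataPoint) -> float:
    """Mean over target-covered duplex columns of Σ_b |pred − target|."""
    if len(pred) != dp.complex.n_pairs:
        raise InputError(
            f"prediction length {len(pred)} != duplex length {dp.complex.n_pairs}"
        )
    cols = dp.covered_columns()
    diff = np.abs(pred.probs[cols] - dp.aligned_target())
    return float(diff.sum(axis=1).mean())


def _loss_tensor(probs: Tensor, dp: DataPoint, kind: str) -> Tensor:
    cols = dp.covered_columns()
    target = constant(dp.aligned_target())
    pred = take_rows(probs, cols)
    if kind == "l1":
        return (pred - target).abs().sum(axis=1).mean()
    if kind == "ce":
        return -(target * (pred + 1e-12).log()).sum(axis=1).mean()
    raise InputError(f"unknown loss kind {kind!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf


def _ensure_inputs(dataset: Sequence[DataPoint], config: ModelConfig) -> None:
    for dp in dataset:
        if dp.inputs is None:
            dp.inputs = prepare_inputs(dp.complex, config)


def train(
    config: ModelConfig,
    train_set: Sequence[DataPoint],
    val_set: Sequence[DataPoint],
    seed: int = 0,
    epochs: int = 60,
    lr: float = 5e-3,
    batch_size: int = 16,
    patience: int = 8,
    loss: str = "l1",
) -> tuple[SpecNet, TrainHistory]:
    """Gradient training of a single model with early stopping.

    Deterministic for a fixed seed: the seed drives weight initialization
    and batch shuffling, and every numerical operation is deterministic.
    """
    if not train_set:
        raise InputError("empty train set")
    if not val_set:
        raise InputError("empty validation set")
    model = SpecNet(dc_replace(config, seed=seed))
    _ensure_inputs(train_set, config)
    _ensure_inputs(val_set, config)
    rng = np.random.default_rng(seed + 1)
    optimizer = Adam(model.param_list(), lr=lr)
    history = TrainHistory()
    best_state = model.state_dict()

    order = np.arange(len(train_set))
    for epoch in range(epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            batch = [train_set[i] for i in order[start:start + batch_size]]
            optimizer.zero_grad()
            total = None
            for dp in batch:
                l = _loss_tensor(model.forward_probs(dp.inputs), dp, loss)
                total = l if total is None else total + l
            total = total * (1.0 / len(batch))
            if not np.isfinite(total.data):
                raise HelixspecError(
                    f"training diverged at epoch {epoch}: loss={total.data!r}"
                )
            total.backward()
            optimizer.step()
            epoch_losses.append(total.item())

        val = float(np.mean([
            column_loss(PWM(model.forward_probs(dp.inputs).data), dp)
            for dp in val_set
        ]))
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val)
        if val < history.best_val_loss - 1e-6:
            history.best_val_loss = val
            history.best_epoch = epoch
            best_state = model.state_dict()
        elif epoch - history.best_epoch >= patience:
            break

    model.load_state_dict(best_state)
    return model, history


@dataclass
class Ensemble:
    """Ordered collection of trained models sharing mode and conventions."""

    members: list[SpecNet]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError("ensemble needs at least one member")
        modes = {m.config.mode for m in self.members}
        if len(modes) != 1:
            raise InputError(f"ensemble members disagree on mode: {modes}")

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config

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
        results = [m.predict(inputs, mask) for m in self.members]
        mean = np.mean([r.pwm.probs for r in results], axis=0)
        return PredictionResult(
            pwm=PWM(mean), per_point_embeddings=results[0].per_point_embeddings
        )


def ensemble_predict(
    ensemble: Ensemble,
    complex_: Union[ComplexStructure, ModelInputs],
) -> PWM:
    """Column-wise arithmetic mean of the member predictions."""
    return ensemble.predict(complex_).pwm


def train_cross_validation(
    config: ModelConfig,
    dataset: Sequence[DataPoint],
    k: int = 5,
    seed: int = 0,
    **train_kwargs,
) -> tuple[Ensemble, list[TrainHistory]]:
    """Train k models, each holding out one cluster-aware fold."""
    folds = make_folds(dataset, k=k, seed=seed)
    members, histories = [], []
    for i in range(k):
        val = folds[i]
        trn = [dp for j, fold in enumerate(folds) if j != i for dp in fold]
        model, hist = train(config, trn, val, seed=seed + 1000 * (i + 1),
                            **train_kwargs)
        members.append(model)
        histories.append(hist)
    return Ensemble(members), histories


def evaluation_report(
    predictor: Union[SpecNet, Ensemble],
    dataset: Sequence[DataPoint],
) -> pd.DataFrame:
    """Per-datapoint table: id, covered-column loss, mae, rmse, alignment."""
    if isinstance(predictor, SpecNet):
        _ensure_inputs(dataset, predictor.config)
    else:
        _ensure_inputs(dataset, predictor.config)
    rows = []
    for dp in dataset:
        pred = predictor.predict(dp.inputs).pwm
        cols = dp.covered_columns()
        covered_pred = PWM(
            pred.probs[cols] / pred.probs[cols].sum(axis=1, keepdims=True)
        )
        covered_target = PWM(dp.aligned_target())
        rows.append({
            "id": dp.complex.source_id,
            "column_loss": column_loss(pred, dp),
            "mae": mae(covered_target, covered_pred),
            "rmse": rmse(covered_target, covered_pred),
            "alignment_score": dp.alignment.score,
            "alignment_offset": dp.alignment.offset,
            "alignment_strand": dp.alignment.strand,
        })
    return pd.DataFrame(rows)
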