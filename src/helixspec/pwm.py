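"""Position weight matrices: container, metrics, file I/O, sequence alignment.

A PWM is an N×4 row-stochastic matrix over the bases A, C, G, T: row ``i``
gives the probability of each base occurring at position ``i`` of the binding
site.  The performance metrics follow the convention used throughout the
package: the per-position error is summed over the four bases (not averaged),
and only the position axis is normalized::

    MAE(Y, Yp)  = (1/N) Σ_i Σ_b |Y_ib − Yp_ib|
    RMSE(Y, Yp) = sqrt( (1/N) Σ_i Σ_b (Y_ib − Yp_ib)² )

so a uniform column against a one-hot column contributes 1.5 to MAE.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from helixspec.errors import InputError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# complement permutation of the A,C,G,T columns
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])

ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PWM:
    """N×4 row-stochastic matrix over bases A, C, G, T."""

    probs: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise InputError(f"PWM must be N×4, got shape {probs.shape}")
        if not np.all(np.isfinite(probs)):
            raise InputError("PWM entries must be finite")
        if np.any(probs < -ROW_SUM_TOL):
            raise InputError("PWM entries must be nonnegative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
            raise InputError("every PWM row must sum to 1")
        object.__setattr__(self, "probs", np.clip(probs, 0.0, None))

    def __len__(self) -> int:
        return self.probs.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return self.probs.shape == other.probs.shape and np.allclose(
            self.probs, other.probs, atol=1e-9
        )

    def reverse_complement(self) -> "PWM":
        """Rows reversed, columns swapped A↔T and C↔G."""
        return PWM(self.probs[::-1, _COMPLEMENT_PERM].copy(), name=self.name)

    def argmax_sequence(self) -> str:
        """Most probable base at each position (ties → first of A,C,G,T)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @staticmethod
    def uniform(n: int, name: str = "") -> "PWM":
        return PWM(np.full((n, 4), 0.25), name=name)

    @staticmethod
    def from_sequence(seq: str, name: str = "") -> "PWM":
        """One-hot PWM of a DNA sequence."""
        _check_sequence(seq)
        probs = np.zeros((len(seq), 4))
        for i, b in enumerate(seq):
            probs[i, _BASE_INDEX[b]] = 1.0
        return PWM(probs, name=name)


@dataclass(frozen=True)
class AlignmentResult:
    """Best ungapped placement of a PWM along a reference DNA sequence.

    ``offset`` is the 0-based position on the *forward* reference sequence at
    which PWM row 0 (after reverse-complementing when ``strand == "reverse"``)
    lands; negative offsets mean the PWM hangs off the 5′ end.  ``score`` is
    the mean probability the PWM assigns to the aligned reference bases.
    """

    offset: int
    strand: str  # "forward" | "reverse"
    score: float
    overlap: int

    def covered_positions(self, seq_len: int, pwm_len: int) -> range:
        """Reference positions covered by the aligned PWM."""
        return range(max(0, self.offset), min(seq_len, self.offset + pwm_len))


def _check_lengths(y: PWM, ypred: PWM) -> None:
    if len(y) != len(ypred):
        raise InputError(f"PWM length mismatch: {len(y)} vs {len(ypred)}")


def mae(y: PWM, ypred: PWM) -> float:
    """Mean absolute error: positions averaged, bases summed."""
    _check_lengths(y, ypred)
    return float(np.abs(y.probs - ypred.probs).sum() / len(y))


def rmse(y: PWM, ypred: PWM) -> float:
    """Root mean squared error: positions averaged, bases summed."""
    _check_lengths(y, ypred)
    return float(math.sqrt(((y.probs - ypred.probs) ** 2).sum() / len(y)))


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits: 2 + Σ_b p log2 p, 0·log 0 = 0."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=1)


def _check_sequence(seq: str) -> None:
    if not seq or re.search(r"[^ACGT]", seq):
        raise InputError(f"sequence must be nonempty over ACGT, got {seq!r}")


def reverse_complement_seq(seq: str) -> str:
    _check_sequence(seq)
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def align_pwm_to_sequence(
    pwm: PWM, seq: str, min_overlap: int = 4
) -> AlignmentResult:
    """Ungapped local alignment of a PWM against a DNA sequence.

    Every offset with at least ``min_overlap`` overlapping positions is scored
    on the forward strand and, with the PWM reverse-complemented, on the
    reverse strand.  The score of a placement is the mean of
    ``pwm[i, base at aligned position]`` over the overlap.  Ties are broken by
    larger overlap, then forward strand, then smallest offset.
    """
    _check_sequence(seq)
    n, m = len(pwm), len(seq)
    if m < min_overlap:
        raise InputError(f"sequence shorter than min_overlap={min_overlap}")
    if n < min_overlap:
        raise InputError(f"PWM shorter than min_overlap={min_overlap}")
    seq_idx = np.array([_BASE_INDEX[b] for b in seq])

    best: AlignmentResult | None = None
    for strand, mat in (("forward", pwm.probs),
                        ("reverse", pwm.reverse_complement().probs)):
        for offset in range(-(n - min_overlap), m - min_overlap + 1):
            lo, hi = max(0, offset), min(m, offset + n)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            rows = np.arange(lo, hi) - offset
            score = float(mat[rows, seq_idx[lo:hi]].mean())
            cand = AlignmentResult(offset=offset, strand=strand,
                                   score=score, overlap=overlap)
            if best is None or _alignment_key(cand) > _alignment_key(best):
                best = cand
    assert best is not None
    return best


def _alignment_key(a: AlignmentResult) -> tuple:
    return (round(a.score, 12), a.overlap, a.strand == "forward", -a.offset)


# ---------------------------------------------------------------------------
# File I/O: plain N×4 probability tables and JASPAR-style 4-row count blocks.
# ---------------------------------------------------------------------------

def read_pwm(path: Union[str, Path], pseudocount: float = 0.5) -> PWM:
    """Read a PWM from a plain table or JASPAR-style file (auto-detected).

    Plain dialect: whitespace-separated N×4 probability rows, ``#`` comments.
    JASPAR dialect: an optional ``>name`` header then four rows like
    ``A  [ 3 10  2 ... ]``; counts are converted to probabilities after adding
    ``pseudocount`` to every cell.
    """
    path = Path(path)
    text = path.read_text()
    stripped = [ln.strip() for ln in text.splitlines()]
    body = [ln for ln in stripped if ln and not ln.startswith("#")]
    if not body:
        raise InputError(f"empty PWM file: {path}")
    if any(ln.startswith(">") or re.match(r"^[ACGT](\s|\[)", ln) for ln in body):
        return _read_jaspar(body, name=path.stem, pseudocount=pseudocount)
    rows = []
    for ln in body:
        vals = ln.split()
        if len(vals) != 4:
            raise InputError(f"expected 4 columns per row, got: {ln!r}")
        rows.append([float(v) for v in vals])
    return PWM(np.array(rows), name=path.stem)


def _read_jaspar(lines: list[str], name: str, pseudocount: float) -> PWM:
    counts: dict[str, list[float]] = {}
    for ln in lines:
        if ln.startswith(">"):
            name = ln[1:].split()[0] if len(ln) > 1 else name
            continue
        m = re.match(r"^([ACGT])\s*\[?\s*([-\d.\seE+]*?)\s*\]?\s*$", ln)
        if not m:
            raise InputError(f"unrecognized JASPAR row: {ln!r}")
        counts[m.group(1)] = [float(v) for v in m.group(2).split()]
    if set(counts) != set(BASES):
        raise InputError(f"JASPAR block missing bases: have {sorted(counts)}")
    lengths = {len(v) for v in counts.values()}
    if len(lengths) != 1:
        raise InputError("JASPAR rows have unequal lengths")
    mat = np.array([counts[b] for b in BASES], dtype=float).T  # N×4
    if np.any(mat < 0):
        raise InputError("negative counts in JASPAR block")
    mat = mat + pseudocount
    return PWM(mat / mat.sum(axis=1, keepdims=True), name=name)


def write_pwm(pwm: PWM, path: Union[str, Path], dialect: str = "plain") -> None:
    """Write a PWM as a plain probability table or a JASPAR-style block."""
    path = Path(path)
    if dialect == "plain":
        lines = [f"# PWM {pwm.name}".rstrip(), "# columns: A C G T"]
        for row in pwm.probs:
            lines.append(" ".join(f"{v:.6f}" for v in row))
    elif dialect == "jaspar":
        # JASPAR blocks hold counts; emit a nominal total of 1000 per column
        lines = [f">{pwm.name or 'pwm'}"]
        for j, b in enumerate(BASES):
            vals = " ".join(f"{1000 * v:.1f}" for v in pwm.probs[:, j])
            lines.append(f"{b} [ {vals} ]")
    else:
        raise InputError(f"unknown PWM dialect: {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def logo_table(pwm: PWM):
    """Logo-ready long-form table: (position, base, probability, bits)."""
    import pandas as pd

    ic = information_content(pwm)
    rows = []
    for i in range(len(pwm)):
        for j, b in enumerate(BASES):
            rows.append({
                "position": i, "base": b,
                "probability": pwm.probs[i, j],
                "bits": pwm.probs[i, j] * ic[i],
            })
    return pd.DataFrame(rows)
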