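"""Position weight matrices and genome-wide scoring.

The specificity of the cognate TF is expressed as a position weight
matrix: a 4 x W real matrix of additive score contributions, one row per
base (A, C, G, T), one column per motif position.  The score of a binding
window is the sum over columns of the weight of the observed base; higher
scores mean stronger binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_BASE_INDEX["N"] = 4  # ambiguous base: contributes zero score


@dataclass(frozen=True)
class PWM:
    """4 x W additive scoring matrix, row order A, C, G, T."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4:
            raise ValueError(f"PWM weights must be 4 x W, got shape {w.shape}")
        if w.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(w)):
            raise ValueError("PWM weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in np.argmax(self.weights, axis=0))

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer-encode a DNA string (A=0, C=1, G=2, T=3, N=4)."""
    return np.fromiter((_BASE_INDEX[b] for b in sequence), dtype=np.int8, count=len(sequence))


def pwm_score(pwm: PWM, genome: Genome, position: int) -> float:
    """Score one left-aligned binding window.

    ``position`` may index a wrap-around window on a circular genome.
    """
    L, W = genome.length, pwm.width
    n_pos = genome.n_positions(W)
    if not 0 <= position < n_pos:
        raise ValueError(f"position {position} out of range [0, {n_pos})")
    total = 0.0
    for j in range(W):
        base = genome.sequence[(position + j) % L]
        bi = _BASE_INDEX[base]
        if bi < 4:
            total += pwm.weights[bi, j]
    return total


def scan_scores(pwm: PWM, genome: Genome) -> np.ndarray:
    """Score every admissible window (vectorised).

    Returns length L - W + 1 scores for a linear genome and length L
    (wrap-around windows included) for a circular one.
    """
    W = pwm.width
    seq = genome.sequence
    if genome.topology == "circular":
        seq = seq + seq[: W - 1]
    codes = encode_sequence(seq)
    # append a zero row so N (code 4) contributes nothing
    wext = np.vstack([pwm.weights, np.zeros(W)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)
    return wext[windows, np.arange(W)].sum(axis=1)


def read_pwm(path) -> PWM:
    """Read a PWM from a whitespace-delimited text matrix.

    Format: one header line naming the row order (must be ``A C G T``),
    then four rows of W numbers each.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty PWM file {path}")
    header = lines[0].lstrip("#").split()
    if [h.upper() for h in header] != list(BASE_ORDER):
        raise ValueError(f"PWM header must name rows 'A C G T', got {lines[0]!r}")
    rows = [np.array([float(x) for x in ln.split()]) for ln in lines[1:5]]
    if len(rows) != 4 or len({len(r) for r in rows}) != 1:
        raise ValueError("PWM body must be 4 rows of equal width")
    return PWM(np.vstack(rows))


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(BASE_ORDER) + "\n")
        for row in pwm.weights:
            fh.write(" ".join(f"{x:.6g}" for x in row) + "\n")
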