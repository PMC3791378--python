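"""Binding-energy landscape: per-position mean residence times.

A bound molecule waits at each position for an exponentially distributed
time whose mean is set by the local binding score:

    mean_residence[i] = tau0 * exp(beta * score[i])

so a stronger (higher) score gives a longer residence.  ``tau0`` is the
residence at a zero-score position (seconds) and ``beta`` converts score
units into the exponent (a score already expressed in units of kT uses
beta = 1).  Sequence-nonspecific species use a flat landscape: score 0
everywhere, mean residence tau0 at every position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome
from .pwm import PWM, scan_scores


@dataclass(frozen=True)
class EnergyLandscape:
    """Per-position binding scores and mean residence times (seconds)."""

    scores: np.ndarray
    mean_residence: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        m = np.asarray(self.mean_residence, dtype=float)
        if s.shape != m.shape or s.ndim != 1:
            raise ValueError("scores and mean_residence must be 1-D and equally long")
        if not np.all(m > 0):
            raise ValueError("mean residence times must be strictly positive")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "mean_residence", m)

    @property
    def n_positions(self) -> int:
        return len(self.scores)

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.scores == self.scores[0]))


def build_landscape(pwm: PWM, genome: Genome, tau0: float, beta: float = 1.0) -> EnergyLandscape:
    """PWM-derived landscape over all admissible windows of the genome."""
    if tau0 <= 0:
        raise ValueError(f"tau0 must be positive, got {tau0}")
    scores = scan_scores(pwm, genome)
    return EnergyLandscape(scores=scores, mean_residence=tau0 * np.exp(beta * scores))


def flat_landscape(genome: Genome, footprint: int, tau0: float) -> EnergyLandscape:
    """Sequence-nonspecific landscape: mean residence tau0 everywhere."""
    if tau0 <= 0:
        raise ValueError(f"tau0 must be positive, got {tau0}")
    n = genome.n_positions(footprint)
    return EnergyLandscape(scores=np.zeros(n), mean_residence=np.full(n, tau0))
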