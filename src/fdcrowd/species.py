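"""Molecule species: kinetic and geometric parameters.

Two kinds of DNA-binding molecules are represented:

* the cognate TF (lac repressor in the reference system): 21 bp footprint,
  PWM-derived landscape, searches for the target site;
* non-cognate DNA-binding proteins: 46 bp footprint, flat landscape,
  acting as mobile obstacles (full slide/hop/unbind kinetics) or immobile
  roadblocks (placed at random at t = 0 and never moved).

When a bound molecule's residence time expires it slides one bp left or
right, hops a short distance, or unbinds, with fixed probabilities
``(p_slide_left, p_slide_right, p_hop, p_unbind)``.  A free molecule
re-binds at a uniformly random position after an exponential waiting time
with rate ``k_assoc`` (per free molecule); an attempt onto an occluded
window fails and the waiting time is redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .landscape import EnergyLandscape

#: footprint of the lac repressor (bp), equal to the O1 operator width
COGNATE_FOOTPRINT = 21
#: footprint of a generic non-cognate DNA-binding protein (bp)
NONCOGNATE_FOOTPRINT = 46

#: default per-base residence scale (s) and move probabilities; see docs/methods.md
DEFAULT_NC_TAU0 = 5e-4
DEFAULT_NC_MOVE_PROBS = (0.445, 0.445, 0.01, 0.1)
DEFAULT_COGNATE_TAU0 = 1e-5
DEFAULT_COGNATE_MOVE_PROBS = (0.494, 0.494, 0.01, 0.002)
DEFAULT_HOP_RANGE = 100


@dataclass
class TFSpecies:
    """One molecule type participating in the simulation."""

    name: str
    copy_number: int
    footprint: int
    k_assoc: float
    move_probs: tuple = DEFAULT_NC_MOVE_PROBS
    hop_range: int = DEFAULT_HOP_RANGE
    mobile: bool = True
    cognate: bool = False
    tau0: float = DEFAULT_NC_TAU0
    landscape: Optional[EnergyLandscape] = None
    #: optional test hook: start the first molecules bound at these positions
    initial_positions: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.mobile:
            p = tuple(float(x) for x in self.move_probs)
            if len(p) != 4 or any(x < 0 for x in p):
                raise ValueError("move_probs must be 4 non-negative numbers")
            if abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"move_probs must sum to 1, got {sum(p)}")
            self.move_probs = p
            if self.k_assoc <= 0:
                raise ValueError("mobile species need a positive k_assoc")
            if self.hop_range < 1:
                raise ValueError("hop_range must be >= 1")

    @property
    def p_unbind(self) -> float:
        return self.move_probs[3]


def calibrate_association_rate(
    tau0: float, p_unbind: float, bound_fraction: float = 0.9
) -> float:
    """Association rate that yields a given stationary bound fraction.

    On an uncrowded flat landscape a bound episode lasts a geometric number
    of residence periods (mean ``1/p_unbind``), each of mean ``tau0``, so
    the mean episode is ``tau0 / p_unbind``; the free period is
    ``1 / k_assoc``.  Solving ``f = T_b / (T_b + 1/k)`` for k gives

        k_assoc = f / (1 - f) * p_unbind / tau0.

    With the defaults this reproduces the reference nonspecific
    association rate of 1800 s^-1 for a 90% bound fraction.
    """
    if not 0 < bound_fraction < 1:
        raise ValueError("bound_fraction must be in (0, 1)")
    if tau0 <= 0 or not 0 < p_unbind <= 1:
        raise ValueError("need tau0 > 0 and 0 < p_unbind <= 1")
    return bound_fraction / (1.0 - bound_fraction) * p_unbind / tau0


def cognate_species(
    copy_number: int,
    k_assoc: float,
    landscape: EnergyLandscape,
    *,
    name: str = "lacI",
    tau0: float = DEFAULT_COGNATE_TAU0,
    move_probs: tuple = DEFAULT_COGNATE_MOVE_PROBS,
    hop_range: int = DEFAULT_HOP_RANGE,
    initial_positions: Optional[Sequence[int]] = None,
) -> TFSpecies:
    """Cognate (target-seeking) species with a PWM-derived landscape."""
    return TFSpecies(
        name=name,
        copy_number=copy_number,
        footprint=COGNATE_FOOTPRINT,
        k_assoc=k_assoc,
        move_probs=move_probs,
        hop_range=hop_range,
        mobile=True,
        cognate=True,
        tau0=tau0,
        landscape=landscape,
        initial_positions=initial_positions,
    )


def noncognate_species(
    copy_number: int,
    k_assoc: float,
    *,
    mobile: bool = True,
    name: Optional[str] = None,
    footprint: int = NONCOGNATE_FOOTPRINT,
    tau0: float = DEFAULT_NC_TAU0,
    move_probs: tuple = DEFAULT_NC_MOVE_PROBS,
    hop_range: int = DEFAULT_HOP_RANGE,
) -> TFSpecies:
    """Non-cognate obstacle species (flat landscape)."""
    return TFSpecies(
        name=name or ("nc_mobile" if mobile else "nc_immobile"),
        copy_number=copy_number,
        footprint=footprint,
        k_assoc=k_assoc if mobile else max(k_assoc, 1.0),
        move_probs=move_probs,
        hop_range=hop_range,
        mobile=mobile,
        cognate=False,
        tau0=tau0,
    )
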