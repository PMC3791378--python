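"""Synthetic inputs: random genomes, a stand-in operator PWM, experiment grids.

Everything the pipeline needs is generated reproducibly from parameters
and a seed — no downloads.  The default target is the 21 bp consensus of
the strongest lac operator, embedded at a known coordinate in an i.i.d.
random background of chosen GC content.  The stand-in PWM is synthetic:
it rewards the consensus base at every column so the embedded operator
is, by construction, the unique top-scoring window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np
import yaml

from .genome import Genome
from .pwm import PWM, BASE_ORDER
from .reduction import (
    DEFAULT_SUBSYSTEM_LENGTH,
    ExperimentPreset,
    ReductionSpec,
    copy_number_scale,
    load_table1_presets,
)

#: 21 bp lac O1 operator consensus used as the default embedded target.
#: Synthetic stand-in constant for the reference operator sequence.
LACI_O1_SITE = "AATTGTGAGCGGATAACAATT"

#: default cell-cycle duration (s), approximately one E. coli cell cycle
CELL_CYCLE_S = 3000.0


def generate_genome(
    length: int,
    gc: float = 0.5,
    site_sequence: str = LACI_O1_SITE,
    site_position: Optional[int] = None,
    seed: int = 0,
    topology: str = "circular",
) -> Genome:
    """Random genome of the given GC content with the target site spliced in.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) =
    (1-gc)/2; ``site_sequence`` replaces the bases at ``site_position``
    (default: the centre of the segment).
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    w = len(site_sequence)
    if site_position is None:
        site_position = (length - w) // 2
    if not 0 <= site_position <= length - w:
        raise ValueError(
            f"site of width {w} at {site_position} overhangs genome of length {length}"
        )
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs)
    bases = np.array(list(BASE_ORDER))
    seq = bases[codes]
    seq[site_position : site_position + w] = list(site_sequence.upper())
    return Genome(
        sequence="".join(seq),
        target_start=site_position,
        target_width=w,
        topology=topology,
        name=f"synthetic_L{length}_seed{seed}",
    )


def generate_pwm(
    width: int = 21,
    specificity: float = 0.8,
    seed: int = 0,
    site_sequence: str = LACI_O1_SITE,
) -> PWM:
    """Stand-in PWM whose unique top-scoring window is the operator.

    The consensus base of each column scores ``+specificity``; the other
    three bases score a small seeded negative jitter (scaled by the same
    specificity, so ``specificity=0`` gives an exactly flat matrix).
    With the residence-time convention ``tau ~ exp(score)`` the default
    specificity 0.8 per matched base puts the operator's residence a
    factor ``exp(0.8 * 21)`` above the zero-score baseline.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    site = site_sequence.upper()[:width]
    if len(site) != width:
        raise ValueError("site_sequence shorter than requested width")
    rng = np.random.default_rng(seed)
    jitter = -np.abs(rng.normal(0.0, 0.1, size=(4, width))) * specificity
    weights = jitter
    for j, base in enumerate(site):
        weights[BASE_ORDER.index(base), j] = specificity
    return PWM(weights)


@dataclass(frozen=True)
class ExperimentCondition:
    """Fully resolved parameters of one simulated condition."""

    name: str
    obstacle_mode: str
    l_sub: int
    n_nc: int
    k_assoc_nc: float
    n_cognate: int
    k_assoc_cognate: float
    crowding: float  # nominal covered-DNA fraction of the condition
    duration: float = CELL_CYCLE_S

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentCondition":
        return cls(**d)


def _rescale_cognate(n: int, scale: float) -> int:
    """Cognate abundances: the two larger values scale with segment size."""
    if n < 100:
        return n
    scaled = copy_number_scale(n, DEFAULT_SUBSYSTEM_LENGTH, max(int(DEFAULT_SUBSYSTEM_LENGTH * scale), 1))
    return scaled


def make_experiment_grid(
    scale: float = 1.0,
    obstacle_mode: str = "mobile",
    duration: float = CELL_CYCLE_S,
) -> List[ExperimentCondition]:
    """Published presets rescaled to a segment of ``scale`` x 100 kbp.

    ``scale=1`` reproduces the published subsystem parameters exactly;
    smaller scales rescale the non-cognate copy numbers by the
    copy-number model and the two larger cognate abundances likewise.
    A preset whose rescaled copy number would vanish is clamped to one
    molecule with a warning.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    l_sub = int(round(DEFAULT_SUBSYSTEM_LENGTH * scale))
    spec = ReductionSpec(l_sub=l_sub)
    conditions: List[ExperimentCondition] = []
    for preset in load_table1_presets(obstacle_mode, spec=spec):
        n_nc = preset.n_nc_sub
        if preset.n_nc_full > 0 and n_nc == 0:  # unreachable with ceiling scaling
            warnings.warn(
                f"{preset.name}: rescaled non-cognate copy number is 0; clamping to 1"
            )
            n_nc = 1
        n_cog = _rescale_cognate(preset.n_cognate, scale)
        if preset.n_cognate > 0 and n_cog == 0:
            warnings.warn(
                f"{preset.name}: rescaled cognate copy number is 0; clamping to 1"
            )
            n_cog = 1
        conditions.append(
            ExperimentCondition(
                name=preset.name,
                obstacle_mode=preset.obstacle_mode,
                l_sub=l_sub,
                n_nc=n_nc,
                k_assoc_nc=preset.k_assoc_nc,
                n_cognate=n_cog,
                k_assoc_cognate=preset.k_assoc_cognate,
                crowding=preset.covered_dna_pct / 100.0,
                duration=duration,
            )
        )
    return conditions


def grid_to_yaml(conditions: List[ExperimentCondition]) -> str:
    return yaml.safe_dump([c.to_dict() for c in conditions], sort_keys=False)


def grid_from_yaml(text: str) -> List[ExperimentCondition]:
    return [ExperimentCondition.from_dict(d) for d in yaml.safe_load(text)]
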