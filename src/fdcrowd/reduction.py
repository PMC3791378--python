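"""System-size reduction: scale genome-wide abundances to a subsegment.

Simulating the full 4.6 Mbp E. coli genome is not desk-scale, so the
search process is simulated on a smaller segment (typically 100 kbp)
containing the target site.  Highly abundant species are rescaled with
the copy-number model: the subsystem carries the same molecule density
as the full genome,

    N_sub = ceil(N_full * L_sub / L_full).

Ceiling rounding is the only mode consistent with every published
subsystem count for the reference genome length below; see
docs/methods.md.  Low-abundance species keep their copy number and
instead carry a rescaled association rate; that rate model is not
re-derived here — the published subsystem rates are shipped as presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional

import yaml

#: E. coli K-12 genome length (bp) consistent with all published subsystem counts
ECOLI_GENOME_LENGTH = 4_639_675

#: default subsystem length (bp)
DEFAULT_SUBSYSTEM_LENGTH = 100_000

#: cognate (lacI) association rate in the full system, s^-1
FULL_SYSTEM_COGNATE_K_ASSOC = 2400.0


def copy_number_scale(n_full: int, l_full: int = ECOLI_GENOME_LENGTH,
                      l_sub: int = DEFAULT_SUBSYSTEM_LENGTH) -> int:
    """Copy-number model: subsystem abundance at equal molecule density."""
    if n_full < 0:
        raise ValueError("n_full must be >= 0")
    if l_full <= 0 or l_sub <= 0:
        raise ValueError("lengths must be positive")
    if l_sub > l_full:
        raise ValueError(f"subsystem length {l_sub} exceeds full length {l_full}")
    return -((-n_full * l_sub) // l_full)  # ceiling with integer arithmetic


@dataclass(frozen=True)
class ReductionSpec:
    """Parameters of a full-system -> subsystem reduction."""

    l_full: int = ECOLI_GENOME_LENGTH
    l_sub: int = DEFAULT_SUBSYSTEM_LENGTH

    def __post_init__(self) -> None:
        if not 0 < self.l_sub <= self.l_full:
            raise ValueError("need 0 < l_sub <= l_full")

    def scale(self, n_full: int) -> int:
        return copy_number_scale(n_full, self.l_full, self.l_sub)


@dataclass(frozen=True)
class ExperimentPreset:
    """One crowding condition of the published subsystem parameter table."""

    name: str
    obstacle_mode: str  # "mobile" | "immobile"
    n_nc_full: int
    n_nc_sub: int
    k_assoc_nc: float
    covered_dna_pct: float  # nominal steady-state coverage, percent
    n_cognate: int
    k_assoc_cognate: float
    l_sub: int = DEFAULT_SUBSYSTEM_LENGTH

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPreset":
        return cls(**d)


# published subsystem parameters: non-cognate abundance rows
# (N_nc_full, k_assoc_nc [s^-1], covered DNA [%]) and the cognate
# association rates per lacI abundance {1, 10, 100, 1000}
_MOBILE_ROWS = [
    (0, 1800.0, 0.0, (4.19, 4.04, 4.11, 4.19)),
    (10_000, 2000.0, 9.0, (4.58, 4.63, 4.67, 4.74)),
    (30_000, 2571.0, 26.0, (6.11, 6.10, 6.19, 6.32)),
    (50_000, 3600.0, 42.0, (8.63, 8.76, 8.73, 8.88)),
    (70_000, 6000.0, 55.0, (13.15, 13.05, 13.06, 13.26)),
]

COGNATE_ABUNDANCES = (1, 10, 100, 1000)

#: immobile-obstacle case: subsystem cognate association rate, identical
#: for all cognate abundances (binding is fast relative to the obstacles'
#: infinite residence, so the exact rate is immaterial)
IMMOBILE_COGNATE_K_ASSOC = 7.37
#: immobile-obstacle abundance published explicitly (40% covered DNA)
IMMOBILE_EXTRA_ABUNDANCE = 40_000
#: nominal covered-DNA percentages for immobile obstacles, where all
#: copies are permanently bound: N_sub * 46 / L_sub
_IMMOBILE_ABUNDANCES = (0, 10_000, 30_000, 40_000, 50_000, 70_000)


def load_table1_presets(
    obstacle_mode: str = "mobile",
    spec: Optional[ReductionSpec] = None,
) -> List[ExperimentPreset]:
    """Published subsystem presets, one per (crowding, cognate abundance).

    ``mobile`` yields the 5 x 4 mobile-obstacle grid; ``immobile`` the
    immobile-roadblock grid (including the 40,000-copy condition) with the
    published common cognate rate.
    """
    spec = spec or ReductionSpec()
    presets: List[ExperimentPreset] = []
    if obstacle_mode == "mobile":
        for n_full, k_nc, cov, k_cogs in _MOBILE_ROWS:
            n_sub = spec.scale(n_full)
            for n_cog, k_cog in zip(COGNATE_ABUNDANCES, k_cogs):
                presets.append(
                    ExperimentPreset(
                        name=f"mobile_nc{n_full}_lacI{n_cog}",
                        obstacle_mode="mobile",
                        n_nc_full=n_full,
                        n_nc_sub=n_sub,
                        k_assoc_nc=k_nc,
                        covered_dna_pct=cov,
                        n_cognate=n_cog,
                        k_assoc_cognate=k_cog,
                        l_sub=spec.l_sub,
                    )
                )
    elif obstacle_mode == "immobile":
        for n_full in _IMMOBILE_ABUNDANCES:
            n_sub = spec.scale(n_full)
            cov = round(100.0 * n_sub * 46 / spec.l_sub, 1)
            for n_cog in COGNATE_ABUNDANCES:
                presets.append(
                    ExperimentPreset(
                        name=f"immobile_nc{n_full}_lacI{n_cog}",
                        obstacle_mode="immobile",
                        n_nc_full=n_full,
                        n_nc_sub=n_sub,
                        k_assoc_nc=0.0,
                        covered_dna_pct=cov,
                        n_cognate=n_cog,
                        k_assoc_cognate=IMMOBILE_COGNATE_K_ASSOC,
                        l_sub=spec.l_sub,
                    )
                )
    else:
        raise ValueError(f"obstacle_mode must be mobile or immobile, got {obstacle_mode!r}")
    return presets


def presets_to_yaml(presets: List[ExperimentPreset]) -> str:
    return yaml.safe_dump([p.to_dict() for p in presets], sort_keys=False)


def presets_from_yaml(text: str) -> List[ExperimentPreset]:
    return [ExperimentPreset.from_dict(d) for d in yaml.safe_load(text)]
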