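"""Event-driven stochastic simulation of facilitated diffusion on crowded DNA.

Every molecule is represented explicitly.  A free molecule carries an
exponential clock (rate ``k_assoc``) for its next binding attempt at a
uniformly random position; the attempt succeeds only if the footprint
window is completely vacant (steric hindrance: no two bound molecules may
cover the same base pair).  A bound molecule waits an exponential
residence time whose mean comes from its energy landscape, then slides
one bp, hops within ``hop_range`` bp, or unbinds, with the species' move
probabilities.  A blocked slide leaves the molecule in place; a hop into
an occluded window unbinds it (a micro-dissociation).  Immobile obstacle
species are placed at random non-overlapping positions at t = 0 and never
move.

The simulation is exact next-event scheduling: each mobile molecule owns
exactly one pending event and events are processed in time order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Dict, List, Optional, Sequence, Tuple

from .genome import Genome
from .species import TFSpecies

__all__ = [
    "Simulator",
    "Trajectory",
    "run_simulation",
    "exclusion_window",
]


def exclusion_window(cognate_footprint: int = 21, obstacle_footprint: int = 46) -> int:
    """Width of the region around the target in which a bound obstacle
    sterically excludes the cognate TF from its site.

    An obstacle whose left edge falls anywhere within
    ``cognate_footprint + obstacle_footprint - 1`` bp around the site
    overlaps every placement of the cognate on the site (66 bp for the
    21 bp lacI footprint and 46 bp non-cognate footprint).
    """
    return cognate_footprint + obstacle_footprint - 1


@dataclass
class Trajectory:
    """Per-replicate observables of one simulation run."""

    duration: float
    seed: int
    first_passage: Optional[float]
    censored: bool
    target_intervals: List[Tuple[float, float]]
    occupancy_fraction: float
    mean_coverage: float
    bound_fraction: Dict[str, float]
    n_bind_events: Dict[str, int]
    n_events: int

    def summary(self) -> dict:
        return {
            "duration": self.duration,
            "seed": self.seed,
            "first_passage": self.first_passage,
            "censored": self.censored,
            "occupancy_fraction": self.occupancy_fraction,
            "mean_coverage": self.mean_coverage,
        }

    def intervals_csv(self) -> str:
        lines = ["t_on,t_off"]
        lines += [f"{a:.9g},{b:.9g}" for a, b in self.target_intervals]
        return "\n".join(lines) + "\n"


class SimulationError(RuntimeError):
    pass


class Simulator:
    """Event-driven simulator for one replicate.

    Parameters
    ----------
    genome, species
        The DNA segment and the molecule species acting on it.
    seed
        Seed of the single RNG driving the replicate.
    stop_at_first_passage
        Halt as soon as a cognate molecule binds the target site.
    coverage_burn_in
        Simulated seconds excluded from the time-averaged coverage
        (equilibration of the adsorbed phase).
    """

    def __init__(
        self,
        genome: Genome,
        species: Sequence[TFSpecies],
        seed: int,
        *,
        stop_at_first_passage: bool = False,
        coverage_burn_in: float = 0.0,
        max_placement_tries: int = 10_000,
    ) -> None:
        self.genome = genome
        self.species = list(species)
        self.seed = seed
        self.rng = random.Random(seed)
        self.stop_at_first_passage = stop_at_first_passage
        self.burn_in = float(coverage_burn_in)

        L = genome.length
        self.L = L
        self.circular = genome.topology == "circular"
        self.occ = bytearray(L)
        self.target_start = genome.target_start

        # per-species caches (indexed by species id)
        self._w: List[int] = []
        self._npos: List[int] = []
        self._k: List[float] = []
        self._tau: List[object] = []  # float (flat) or list of floats
        self._cum1: List[float] = []  # p_slide_left
        self._cum2: List[float] = []  # + p_slide_right
        self._cum3: List[float] = []  # + p_hop
        self._hopr: List[int] = []
        self._ones: List[bytes] = []
        self._zeros: List[bytes] = []
        self._cognate: List[bool] = []

        self.sp: List[int] = []  # molecule -> species id
        self.pos: List[int] = []  # molecule -> left edge, -1 if free
        self._mobile_of: List[bool] = []

        for si, s in enumerate(self.species):
            w = s.footprint
            npos = genome.n_positions(w)
            if s.landscape is not None:
                mr = s.landscape.mean_residence
                if len(mr) != npos:
                    raise ValueError(
                        f"landscape of {s.name} has {len(mr)} positions, expected {npos}"
                    )
                tau = float(mr[0]) if s.landscape.is_flat else mr.tolist()
            else:
                tau = float(s.tau0)
            self._w.append(w)
            self._npos.append(npos)
            self._k.append(float(s.k_assoc))
            self._tau.append(tau)
            if s.mobile:
                p = s.move_probs
                self._cum1.append(p[0])
                self._cum2.append(p[0] + p[1])
                self._cum3.append(p[0] + p[1] + p[2])
            else:
                self._cum1.append(0.0)
                self._cum2.append(0.0)
                self._cum3.append(0.0)
            self._hopr.append(s.hop_range)
            self._ones.append(b"\x01" * w)
            self._zeros.append(b"\x00" * w)
            self._cognate.append(s.cognate)

        # time accounting
        self.time = 0.0
        self._last_t = 0.0
        self.covered_bp = 0
        self._cov_integral = 0.0
        self._bound_integral = [0.0] * len(self.species)
        self.n_bound = [0] * len(self.species)
        self.n_bind_events = [0] * len(self.species)
        self.n_reject_events = [0] * len(self.species)
        self.n_events = 0

        # target bookkeeping
        self.first_passage: Optional[float] = None
        self._target_on_since: Optional[float] = None
        self._target_time = 0.0
        self.target_intervals: List[Tuple[float, float]] = []

        self.heap: List[Tuple[float, int]] = []
        self._init_state(max_placement_tries)

    # ------------------------------------------------------------------ init

    def _init_state(self, max_tries: int) -> None:
        rng = self.rng
        for si, s in enumerate(self.species):
            if not s.mobile:
                self._place_immobile(si, s, max_tries)
        for si, s in enumerate(self.species):
            if not s.mobile:
                continue
            preplaced = list(s.initial_positions or [])
            if len(preplaced) > s.copy_number:
                raise ValueError(f"{s.name}: more initial positions than copies")
            for i in range(s.copy_number):
                m = len(self.sp)
                self.sp.append(si)
                self._mobile_of.append(True)
                if i < len(preplaced):
                    p = preplaced[i]
                    if not self._window_free(p, self._w[si]):
                        raise ValueError(f"{s.name}: initial position {p} is occluded")
                    self._occupy(si, m, p, 0.0)
                    heappush(self.heap, (self._draw_residence(si, p), m))
                else:
                    self.pos.append(-1)
                    heappush(self.heap, (rng.expovariate(self._k[si]), m))

    def _place_immobile(self, si: int, s: TFSpecies, max_tries: int) -> None:
        w, npos = self._w[si], self._npos[si]
        for _ in range(s.copy_number):
            m = len(self.sp)
            self.sp.append(si)
            self._mobile_of.append(False)
            placed = False
            for _try in range(max_tries):
                c = self.rng.randrange(npos)
                if self._window_free(c, w):
                    self._occupy(si, m, c, 0.0)
                    placed = True
                    break
            if not placed:
                raise SimulationError(
                    f"could not place immobile molecule of {s.name} after "
                    f"{max_tries} tries; achievable coverage "
                    f"{self.covered_bp / self.L:.3f} of requested "
                    f"{s.copy_number * w / self.L:.3f}"
                )

    # ----------------------------------------------------------- primitives

    def _window_free(self, a: int, w: int) -> bool:
        b = a + w
        occ = self.occ
        if b <= self.L:
            return occ.find(1, a, b) == -1
        return occ.find(1, a, self.L) == -1 and occ.find(1, 0, b - self.L) == -1

    def _fill(self, a: int, w: int, block: bytes) -> None:
        b = a + w
        if b <= self.L:
            self.occ[a:b] = block
        else:
            head = self.L - a
            self.occ[a : self.L] = block[:head]
            self.occ[0 : b - self.L] = block[head:]

    def _occupy(self, si: int, m: int, p: int, t: float) -> None:
        self._fill(p, self._w[si], self._ones[si])
        if m == len(self.pos):
            self.pos.append(p)
        else:
            self.pos[m] = p
        self.covered_bp += self._w[si]
        self.n_bound[si] += 1
        if self._cognate[si] and p == self.target_start:
            self._target_arrive(t)

    def _vacate(self, si: int, m: int, t: float) -> None:
        p = self.pos[m]
        self._fill(p, self._w[si], self._zeros[si])
        self.pos[m] = -1
        self.covered_bp -= self._w[si]
        self.n_bound[si] -= 1
        if self._cognate[si] and p == self.target_start:
            self._target_leave(t)

    def _target_arrive(self, t: float) -> None:
        if self.first_passage is None:
            self.first_passage = t
        self._target_on_since = t

    def _target_leave(self, t: float) -> None:
        if self._target_on_since is not None:
            self.target_intervals.append((self._target_on_since, t))
            self._target_time += t - self._target_on_since
            self._target_on_since = None

    def _draw_residence(self, si: int, p: int) -> float:
        tau = self._tau[si]
        mean = tau if isinstance(tau, float) else tau[p]
        return self.rng.expovariate(1.0) * mean

    # --------------------------------------------------------------- events

    def _attempt_bind(self, m: int, t: float) -> bool:
        """Binding attempt of a free molecule; returns True on success."""
        si = self.sp[m]
        if self.pos[m] >= 0:
            raise SimulationError("attempt_bind called on a bound molecule")
        c = self.rng.randrange(self._npos[si])
        if self._window_free(c, self._w[si]):
            self._occupy(si, m, c, t)
            self.n_bind_events[si] += 1
            heappush(self.heap, (t + self._draw_residence(si, c), m))
            return True
        self.n_reject_events[si] += 1
        heappush(self.heap, (t + self.rng.expovariate(self._k[si]), m))
        return False

    def _step_bound(self, m: int, t: float) -> None:
        """Residence expired: slide, hop or unbind."""
        si = self.sp[m]
        if not self._mobile_of[m]:
            raise SimulationError("step called on an immobile molecule")
        p = self.pos[m]
        if p < 0:
            raise SimulationError("step called on a free molecule")
        rng = self.rng
        u = rng.random()
        L, w = self.L, self._w[si]
        cognate, ts = self._cognate[si], self.target_start

        if u < self._cum2[si]:
            # slide one bp; blocked (steric or linear end) => stay in place
            if u < self._cum1[si]:  # left
                if self.circular:
                    newp = p - 1 if p > 0 else L - 1
                    edge = newp
                else:
                    newp = p - 1
                    edge = newp
                    if newp < 0:
                        newp = -2  # blocked at end
                if newp >= 0 and self.occ[edge] == 0:
                    self.occ[(p + w - 1) % L] = 0
                    self.occ[edge] = 1
                    self.pos[m] = newp
                    if cognate:
                        if p == ts:
                            self._target_leave(t)
                        elif newp == ts:
                            self._target_arrive(t)
                    p = newp
            else:  # right
                if self.circular:
                    newp = p + 1 if p + 1 < L else 0
                    edge = (p + w) % L
                else:
                    newp = p + 1
                    edge = p + w
                    if newp >= self._npos[si]:
                        newp = -2
                if newp >= 0 and self.occ[edge] == 0:
                    self.occ[p] = 0
                    self.occ[edge] = 1
                    self.pos[m] = newp
                    if cognate:
                        if p == ts:
                            self._target_leave(t)
                        elif newp == ts:
                            self._target_arrive(t)
                    p = newp
            heappush(self.heap, (t + self._draw_residence(si, self.pos[m]), m))
        elif u < self._cum3[si]:
            # hop: uniform displacement in +-hop_range excluding 0,
            # re-checked for steric clash after vacating the old window;
            # clash (or off the end of a linear genome) => unbind
            d = rng.randrange(1, self._hopr[si] + 1)
            if rng.random() < 0.5:
                d = -d
            newp = p + d
            if self.circular:
                newp %= L
            self._vacate(si, m, t)
            if 0 <= newp < self._npos[si] and self._window_free(newp, w):
                self._occupy(si, m, newp, t)
                heappush(self.heap, (t + self._draw_residence(si, newp), m))
            else:
                heappush(self.heap, (t + rng.expovariate(self._k[si]), m))
        else:
            self._vacate(si, m, t)
            heappush(self.heap, (t + rng.expovariate(self._k[si]), m))

    # ----------------------------------------------------------------- run

    def _accumulate(self, t: float) -> None:
        dt = t - self._last_t
        if dt < 0:
            raise SimulationError("event time regression detected")
        if dt == 0.0:
            return
        self._cov_dt(self._last_t, t)
        for si in range(len(self.species)):
            self._bound_integral[si] += self.n_bound[si] * dt
        self._last_t = t

    def _cov_dt(self, a: float, b: float) -> None:
        lo = max(a, self.burn_in)
        if b > lo:
            self._cov_integral += self.covered_bp * (b - lo)

    def advance_to(self, t_end: float) -> None:
        """Process all events up to simulated time ``t_end``."""
        heap = self.heap
        stop = self.stop_at_first_passage
        while heap and heap[0][0] <= t_end:
            if stop and self.first_passage is not None:
                break
            te, m = heappop(heap)
            self._accumulate(te)
            self.n_events += 1
            if self.pos[m] < 0:
                self._attempt_bind(m, te)
            else:
                self._step_bound(m, te)
        end = self.time = (
            self.first_passage
            if (stop and self.first_passage is not None)
            else t_end
        )
        self._accumulate(end)

    def run(self, duration: float) -> Trajectory:
        """Simulate up to ``duration`` seconds and summarise the replicate."""
        if duration < 0:
            raise ValueError("duration must be >= 0")
        if duration > 0:
            self.advance_to(duration)
        end = self.time
        if self._target_on_since is not None:
            self.target_intervals.append((self._target_on_since, end))
            self._target_time += end - self._target_on_since
            self._target_on_since = end  # keep state consistent if run again
        span = max(end - self.burn_in, 0.0)
        names = [s.name for s in self.species]
        bound_fraction = {
            n: (
                self._bound_integral[si] / (end * self.species[si].copy_number)
                if end > 0 and self.species[si].copy_number > 0
                else 0.0
            )
            for si, n in enumerate(names)
        }
        return Trajectory(
            duration=duration,
            seed=self.seed,
            first_passage=self.first_passage,
            censored=self.first_passage is None,
            target_intervals=list(self.target_intervals),
            occupancy_fraction=(self._target_time / duration if duration > 0 else 0.0),
            mean_coverage=(self._cov_integral / (self.L * span) if span > 0 else 0.0),
            bound_fraction=bound_fraction,
            n_bind_events={n: self.n_bind_events[si] for si, n in enumerate(names)},
            n_events=self.n_events,
        )

    # ----------------------------------------------------------- inspection

    def coverage_fraction(self) -> float:
        """Instantaneous fraction of base pairs under any bound footprint."""
        return self.covered_bp / self.L

    def vacant_position_count(self, footprint: int) -> int:
        """Number of left-aligned positions whose window is fully vacant."""
        npos = self.genome.n_positions(footprint)
        return sum(1 for a in range(npos) if self._window_free(a, footprint))

    def audit(self) -> None:
        """Full steric/consistency audit (debug aid; raises on violation)."""
        fresh = bytearray(self.L)
        covered = 0
        for m, p in enumerate(self.pos):
            if p < 0:
                continue
            si = self.sp[m]
            w = self._w[si]
            covered += w
            for j in range(w):
                cell = (p + j) % self.L
                if fresh[cell]:
                    raise SimulationError(f"steric overlap at bp {cell}")
                fresh[cell] = 1
        if fresh != self.occ:
            raise SimulationError("occupancy index inconsistent with positions")
        if covered != self.covered_bp:
            raise SimulationError("covered bp counter inconsistent")
        for si, s in enumerate(self.species):
            n = sum(1 for m, p in enumerate(self.pos) if p >= 0 and self.sp[m] == si)
            expect = self.n_bound[si]
            if n != expect:
                raise SimulationError(f"bound count mismatch for {s.name}")
            total = sum(1 for m in range(len(self.sp)) if self.sp[m] == si)
            if total != s.copy_number:
                raise SimulationError(f"molecule count not conserved for {s.name}")


def run_simulation(
    genome: Genome,
    species: Sequence[TFSpecies],
    duration: float,
    seed: int,
    *,
    stop_at_first_passage: bool = False,
    coverage_burn_in: float = 0.0,
) -> Trajectory:
    """Convenience wrapper: build a :class:`Simulator` and run one replicate."""
    sim = Simulator(
        genome,
        species,
        seed,
        stop_at_first_passage=stop_at_first_passage,
        coverage_burn_in=coverage_burn_in,
    )
    return sim.run(duration)
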