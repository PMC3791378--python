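# Methods

## Model

`fdcrowd` simulates facilitated diffusion of DNA-binding proteins on a
single genome segment with every molecule represented explicitly. The
DNA is a string over {A,C,G,T}; 3D organisation of the genome is
deliberately outside the model, and cytoplasmic crowding enters only
implicitly through the association rate to DNA. Two kinds of species
participate:

* **Cognate TF** (lac repressor as the model system): footprint 21 bp,
  sequence specificity from a PWM, searching for a designated 21 bp
  target (the strongest lac operator).
* **Non-cognate DNA-binding proteins**: footprint 46 bp, sequence-blind
  (flat landscape), either *mobile* (full kinetics) or *immobile*
  (placed uniformly at random without overlap at t = 0, never moved;
  they may cover the target).

A bound molecule at position *i* waits an exponential time with mean
τ(i) = τ₀·exp(β·S(i)), S the PWM score of the window (β = 1 by default:
scores are read as energies in units of kT). On expiry it slides ±1 bp,
hops a uniform ±1…hop_range displacement, or unbinds, with fixed
probabilities. Steric hindrance is absolute: no two footprints may share
a base pair at any time. A blocked slide leaves the molecule in place
with a fresh residence draw; a hop into an occluded window (or off the
end of a linear genome) converts to an unbinding — a micro-dissociation.
A free molecule attempts binding at a uniformly random admissible
position after an Exp(k_assoc) wait; a rejected attempt (occluded
window) simply redraws the wait, so the effective on-rate is k_assoc
times the vacant-window fraction — this is how crowding slows search in
the model.

The simulation is an exact next-event scheme: every mobile molecule owns
one pending event (residence expiry or binding attempt) in a single
time-ordered queue; one seeded RNG drives a replicate, and replicate *r*
of an ensemble uses seed base_seed + r.

Target occupancy is defined as a cognate molecule bound with its left
edge exactly at the target start. Combined with the steric rule this
gives the 66 bp exclusion arithmetic: an obstacle whose left edge lies
within footprint_cognate + footprint_nc − 1 = 66 bp of positions around
the site excludes the cognate from it.

## Parameters and calibration

The model's kinetic scales are anchored to two facts stated for the
reference system: mobile DNA-binding proteins are bound to DNA ~90% of
the time, and the zero-crowding non-cognate association rate is
1800 s⁻¹. Together these fix the mean bound episode of a mobile
molecule: T_b = (f/(1−f))/k = (0.9/0.1)/1800 = 5 ms, consistent with
single-molecule estimates of millisecond-scale nonspecific binding
events. `calibrate_association_rate(tau0, p_unbind, f)` inverts the same
relation (on a flat landscape T_b = τ₀/p_unbind).

Defaults (config-exposed; the published supplementary kinetic tables are
not available, so these are the package's own choices, fixed a priori
from the calibration above):

| parameter | non-cognate | cognate (lacI) | rationale |
|---|---|---|---|
| footprint | 46 bp | 21 bp | published footprints |
| τ₀ (zero-score residence) | 5·10⁻⁴ s | 1·10⁻⁵ s | T_b = τ₀/p_unbind = 5 ms for both |
| (p_left, p_right, p_hop, p_unbind) | (.445, .445, .01, .1) | (.494, .494, .01, .002) | slide-dominant; hops rare micro-dissociations |
| hop_range | 100 bp | 100 bp | short-range re-landing |
| β | — | 1 | scores are energies |
| PWM specificity | — | 0.8 per matched base | see below |

The cognate's finer steps (~2500 moves per episode, ~100 distinct sites
slid, hundred-bp slide lengths) reproduce the published empty-DNA search
times analytically: one lacI at k = 4.19 s⁻¹ on 100 kbp hits the target
with probability ≈10⁻³ per bound episode, giving a ~240 s mean search
versus the published 282 s. On the default PWM landscape the
genome-averaged cognate residence is ~2.7 ms per position and the
operator residence τ_target = τ₀·e^(0.8·21) ≈ 200 s, i.e. ~7% of the
3000 s cell cycle.

The published subsystem association rates (Table presets: non-cognate
1800–6000 s⁻¹; cognate 4.04–13.26 s⁻¹ per lacI abundance, 7.37 s⁻¹ for
the immobile case) are shipped verbatim; the association-rate reduction
model that produced them is cited prior work and is not re-derived.
Copy numbers reduce by N_sub = ⌈N_full·L_sub/L_full⌉ with
L_full = 4,639,675 bp — ceiling is the only rounding consistent with all
six published subsystem counts (216, 647, 863, 1078, 1509).

With no further tuning, the steady-state covered-DNA fractions at the
four crowded presets emerge at ~9/26/41.5/55% on a 10 kbp segment,
matching the published 9/26/42/55%. This is a genuine consistency check
of the calibration: coverage is set by the competition between the
5 ms bound episodes, the preset rates and the vacancy statistics of a
hard-rod adsorbate, none of which is fitted to the coverage numbers.

## Synthetic data

`generate_genome` draws i.i.d. bases at a chosen GC content (default
0.5) and splices the 21 bp lac O1 operator consensus at a known
coordinate (the shipped sequence is a documented stand-in constant, not
a data-derived fixture). `generate_pwm` builds a stand-in matrix —
+specificity for the consensus base, small seeded negative jitter
elsewhere — whose unique top-scoring window is the embedded operator.
Synthetic genomes are circular by default to avoid end artifacts in the
1D walk.

What the generator does *not* emulate: real promoter architecture and
binding-site clustering, sequence correlations, the true lacI PWM (the
published matrix is unavailable), strand effects (forward-strand scoring
only by default), and any 3D structure. Passing tests therefore show the
kinetic machinery is right, not that genomic sequence composition is
realistic.

## Scale of the shipped experiments

Full-scale conditions (100 kbp, 3000 s, up to 1509 mobile obstacles) are
shipped as config files under `configs/` but are deliberately not run by
the test suite — a single mobile-obstacle cell cycle is an
overnight-scale computation. The tests and the acceptance script use
reduced problem sizes chosen so the measured quantity is either
scale-invariant or its full-scale ordering is preserved:

* *Bound-fraction calibration*: 1 molecule, 10 kbp flat landscape,
  600 s (~10⁵ bind/unbind cycles).
* *Coverage*: presets rescaled to 10 kbp by the copy-number model;
  2.4 s per replicate with a 0.4 s burn-in (adsorption equilibrates
  within ~0.1 s, ~70 episode turnovers), 5–10 replicates. Coverage
  depends only on molecular densities, so it is scale-invariant.
* *Event-engine validation*: mean first-passage of a single molecule on
  a 60-position circular genome against an independent CTMC linear
  solve, 2500 replicates, 3-SE agreement.
* *Mobile-obstacle orderings*: 1 kbp, 10 lacI, cycle 40–60 s, PWM
  specificity 0.615 so that τ_target/cycle ≈ 0.066 matches the
  full-scale ratio (200 s/3000 s); 10–40 replicates.
* *Immobile-obstacle orderings*: 50 kbp, 1 lacI, 1500 s, default PWM,
  200 replicates per crowding arm — immobile obstacles generate no
  events, so near-full-scale runs are affordable here.

## Numerical choices and conventions

* Coordinates are 0-based; a footprint occupies [i, i+w) (half-open).
* Quartiles use linear interpolation of order statistics (type 7);
  whiskers follow the max(Q1−1.5·IQR, min)/min(Q3+1.5·IQR, max) rule
  with points outside the whisker span as outliers; notch half-width is
  1.57·IQR/√n.
* Censored replicates: first-passage statistics always report censored
  counts separately; occupancy statistics keep censored replicates as
  zeros (mobile protocol) or discard them (immobile protocol) behind an
  explicit `discard_censored` flag, never inferred.
* Multiple testing across crowding conditions uses Tukey's HSD only.
* Immobile placement is rejection sampling with a bounded retry budget;
  over-packed requests fail loudly, reporting the achievable coverage.
* Hop displacements are uniform on ±{1..hop_range}; a hop is classified
  before vacating, so a molecule may legally re-land overlapping its own
  previous footprint.
* Event ties are broken by molecule index; event-time regression aborts
  the run as an internal error.

## Known limitations

* The immobile-obstacle *occupancy* ordering (occupancy of reached
  targets increasing with roadblock crowding) does not reproduce under
  this parameterization: at 50 kbp/1500 s with 200 replicates per arm
  the occupancy difference between 10% and 40% (and 70%) covered DNA is
  statistically null, while the companion effects — reach probability
  falling to ≈0.09 at ~70% coverage, and all mobile-obstacle orderings —
  do reproduce. The expected effect size is only a few percent of the
  cycle, and it is sensitive to the unavailable published move kernel;
  the "blocked hop ⇒ unbind" rule also makes escape from a confining
  gap more frequent at high crowding, working against confinement. The
  corresponding test encodes the expected significance and currently
  fails; it documents this open discrepancy.
* k_assoc is interpreted per free molecule; collective depletion of a
  shared cytoplasmic pool is not modelled.
* No TF–TF cooperativity, no intersegmental transfer beyond the hop
  kernel, no nucleosomes/eukaryotic features.
* Trajectories record target-binding intervals and summary observables,
  not full per-molecule traces.
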