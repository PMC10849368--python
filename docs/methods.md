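# Methods

## Model and assumptions

The core object is the exact one-generation recursion for four allele
frequencies (p1, p2, p3, p4) of A1, a2, A3, a4 at a single diploid locus in
an infinite, randomly mating population with non-overlapping generations.
The life cycle is fixed: diploid viability selection first (via marginal
fitnesses `m_n = Σ_k p_k w_nk` and mean fitness `w̄ = Σ_n p_n m_n`), then
gametic transmission with at most one transition per gamete per generation —
mutation (μ, one-way A→a), epimutation (ε, unmodified→modified) or
back-epimutation (β, modified→unmodified). No drift, no environment-induced
switching, a single locus, random mating; these are model non-goals, not
simplifications to be toggled.

Parameters and defaults:

| parameter | meaning | units | default |
|---|---|---|---|
| μ | mutation rate (whole-allele) | per allele per generation | 1e−7 |
| ε | epimutation rate | per allele per generation | — (swept) |
| β | back-epimutation rate | per allele per generation | — (swept; focal 0.33, 0.1, 0.01) |
| s_nk | selection against genotype nk | dimensionless, [0,1] | 0 (neutral) |
| h | dominance of a deleterious allele | — | 0 (recessive) |

μ = 1e−7 is a realistic whole-locus mutation rate and is held fixed in all
scans. The focal β values model epialleles maintained ≈3, ≈10 and ≈100
generations without selection (expected maintenance −1/ln(1−β) ≈ 2.5, 9.5,
99.5). Epimutation rates are swept over [1e−5, 0.5]: the top of that range
exceeds plausible genome-wide rates but represents epimutation hotspots.

## Numerical choices

**State hygiene.** Frequencies are doubles. After each generation,
components in [−1e−15, 0) — rounding noise from products at the μ = 1e−7
scale — are clipped to zero and the vector renormalized; anything below
−1e−9 raises, since it indicates a bug rather than roundoff.

**Iteration vs root solving.** `iterate` exists for dynamics and
basin-of-attraction checks; its convergence test is an L∞ per-generation
change below `tol`. Equilibria at μ-scale forcing need ~1e8 generations to
reach by iteration, so equilibrium queries go to the multistart root solver
instead.

**Equilibrium search.** The fixed-point system is solved in the three free
coordinates (p1, p2, p3), with p4 eliminated. Starts are deterministic (no
RNG, so equilibrium counts are reproducible): the 4 simplex vertices, 6 edge
midpoints, the centroid, plus an unscrambled 4-D Halton sequence mapped to
the simplex interior by normalized exponentials, filling `n_starts`
(≥ 27; scans use 27, single solves 64). Each start runs MINPACK's hybrid
Powell method; converged roots must have a full step-residual
‖step(p) − p‖∞ < 1e−12 and all frequencies within [−1e−9, 1 + 1e−9].
Coordinates with |p| < 1e−12 are snapped to exact boundary zeros (with one
re-polish if snapping moved the residual). The residual gate deliberately
excludes "pseudo-equilibria" — points where the flow is merely slow
(|dp/dt| ~ 1e−6…1e−4), which plague lower-precision analyses of this
system. Roots are deduplicated greedily (first seen kept) within an L∞
radius of 1e−6 and returned sorted by p4 descending.

**Stability.** An equilibrium is classified by the eigenvalues of the 3×3
Jacobian of the continuous-time system f = step − identity, computed by
central differences with h_j = max(1e−7, 1e−7·|p_j|) (truncation O(h²),
rounding ~1e−9 per entry). Labels: *stable* if all real parts < −1e−9,
*unstable* if any real part > +1e−9, otherwise *marginal*. The explicit
marginal band matters: degenerate neutral cases have exact zero modes (e.g.
with μ = 0 the total A-genotype frequency is conserved, so the neutral EBE
point is marginal, becoming stable with any μ > 0 at rate −μ), and
transcritical crossings in the scans pass through ±1e−10 eigenvalues.
Because f is exactly the map minus the identity, the continuous criterion
coincides with the discrete-map modulus criterion for this system; a test
checks the two linearizations agree to 1e−5.

**Scans.** The default landscape scan is a deterministic 50×50 log-spaced
lattice on [1e−5, 0.5]² — chosen as a desk-scale stand-in for a 300×300
random log-uniform draw (~90,000 points); the seeded random mode is kept for
fidelity. Multistability *regions* are therefore resolved only to lattice
resolution, but per-point equilibrium counts, which is what the package
reports, are robust to this. A grid point where no start converges is
retried with 4× starts and otherwise recorded with an empty equilibrium
list and a warning, never a crash. A 50×50 scenario scan takes ~40–60 s on
one CPU.

## Closed forms and their validity

Every closed form is treated as a hypothesis pinned by tests against the
recursion (the single source of truth), because several printed equations
lose radicals and fraction bars in transcription:

* EBE `p4 = ε/(β+ε)` — exact (agrees with long-run iteration to <1e−8).
* Epimutation–selection balance `√(ε/s44)` (recessive) and `ε/(h·s44)`
  (dominance approximation) — the β=0 regime; 5% agreement with the solver
  at ε=1e−4, s44=0.01. The exact dominance radical is not exposed; only
  its leading-order approximation survives transcription trustworthily.
* Back-epimutation–selection balance `1 − √(β/s22)` — the ε=0 regime;
  returns 0 once β ≥ s22 (reversion outruns selection).
* Compensatory equilibria: recessive case p2 = √(μ/s22),
  p4 = (ε/β)√(μ/s22), genotype sums p1+p2 = β/(ε+β), p3+p4 = ε/(ε+β);
  general dominance p2+p4 ≈ (1+ε/β)·μ/(h·s22). Valid for s22 ≫ μ and β not
  ≪ μ; a warning fires (and values cap at 1) outside that regime. Numeric
  agreement is ~0.03% at the four focal rate combinations; tests assert 5%.
* Expected maintenance time uses the continuous area −1/ln(1−β) rather
  than the discrete sum (1−β)/β: the area reproduces 2.5/9.5/99.5 at one
  decimal at the three focal rates, the discrete sum does not (2.0 at
  β=0.33).

The classical reduction ε=β=0 reproduces two-allele mutation–selection
balance (√(μ/s) recessive, μ/(hs) with dominance). Note these classical
fixed points are *unstable* in the full four-allele embedding — a
fitness-neutral modified state can always invade a purely genetic
population — so tests select them by composition (p3+p4 ≈ 0), not label.

## Design choices where the design was open

* The stability zero-band (1e−9) and the third label "marginal" are our
  additions; only stable/unstable are standard for this model family.
* CLI defaults: n_starts 64 for single solves (completeness), 27 for scans
  (throughput); both well above the 11 structured starts.
* Scenario presets encode the published fitness regimes verbatim and carry
  a `swap_genotypes` transform (indices 1↔2, 3↔4) for the symmetric cases;
  swapped scenarios are *not* dynamically equivalent because mutation stays
  one-way.

## Known limitations and one honest discrepancy

* Completeness of the multistart search is empirical, not proven; it is
  validated against coarse-grid cross-checks with up to 256 starts and
  against forward iteration.
* Near fold/transcritical boundaries, distinct equilibria closer than the
  1e−6 dedup radius merge into one report.
* **Marginal-stability classification in the compensated
  dominant-deleterious scans.** In the scenarios where a deleterious allele
  is dominant and its epiallele compensates (the `fig7_*` presets), the
  a-genotype edge equilibria that shelter the deleterious allele carry a
  leading Jacobian eigenvalue of order +1e−7…+5e−7 throughout the scanned
  box — positive, but at the scale of μ. Verified at 50-digit precision,
  these states are destabilized by reinvasion of the purged genotype, whose
  marginal-fitness advantage (∝ s·p2·p4) exceeds its only loss rate (μ)
  everywhere on [1e−5, 0.5]²; they become genuinely stable only at rates
  a factor ~2–5 outside that box. Analyses performed at coarser numerical
  precision classify these O(μ)-margin states as stable and hence count one
  more stable equilibrium in a small corner region. This package reports
  the strict-sign classification: `fig7_a` has one stable equilibrium per
  grid point and `fig7_c` at most two. The practical reading: those extra
  states are "stable" on any timescale short of ~1/μ generations but are
  not exact attractors.
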