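# Methods

## The model

`knotloop` studies how two adhesive regions along a DNA-like polymer change
its probability of ending up knotted when it circularizes.  The chain is a
Kremer–Grest bead–spring polymer of `N` beads (default `N = 500` for the
full study design; the shipped demo campaign uses `N = 100`, see
*Problem sizes* below).  All quantities are in reduced units: bead diameter
`σ`, well depth `ε`, bead mass `m` all equal 1, time unit `τ = σ√(m/ε)`,
and `k_BT = ε`.

The Hamiltonian is

```
H = U_WCA + U_FENE + U_stick + U_bend
```

* **Excluded volume** — WCA (truncated–shifted Lennard-Jones) between every
  distinct bead pair, `4ε[(σ/r)¹² − (σ/r)⁶ + ¼]` for `r ≤ 2^{1/6}σ`, zero
  beyond.  Consecutive bonded beads interact too (pure Kremer–Grest
  convention; the pair sum has no exclusions).
* **Connectivity** — FENE springs between consecutive beads,
  `−(κ_fene/2)(R₀/σ)² ln[1 − (d/R₀)²]` with `κ_fene = 30ε`, `R₀ = 1.5σ`.
  The combined FENE+WCA bond minimum sits at `d ≈ 0.961σ`, which is also
  the spacing of the initial straight conformation.
* **Adhesion** — a deep Gaussian well
  `G(r) = −U₀ exp(−(r − 2^{1/6}σ)²/(2λ²))` with `U₀ = 100ε`, `λ = 2.5σ`,
  active on the shell `2^{1/6}σ ≤ r ≤ (2^{1/6}+5)σ` and only between the
  two designated pairs: the termini `(0, N−1)` and the internal pair
  `(X, Y)`.  There is no cross-pair attraction.  The potential is
  implemented literally, including its truncations: the force is
  continuous at both shell boundaries (the Gaussian is flat at the inner
  edge and we accept the `U₀e⁻² ≈ 13.5ε` energy step at the outer edge —
  it exerts no force and merely offsets the bookkeeping of a pair that
  crosses the boundary).  In practice a pair that has fallen into the well
  is ~100ε below thermal energy and never escapes.
* **Stiffness** — harmonic angle potential `(κ_bend/2)(θ − π)²` per
  interior triplet.  `κ_bend = 0` is the fully flexible regime ("L-DNA",
  persistence length of order one bead); `κ_bend = 10 k_BT` the
  semiflexible regime ("S-DNA", persistence length ≈ 10σ, the worm-like
  chain limit `l_p/b ≈ κ_bend/k_BT`).

## Dynamics and the circularization protocol

Each run starts from an open, nearly straight chain (equilibrium bond
spacing, transverse jitter < 0.01σ, Maxwell–Boltzmann velocities) and
integrates Langevin dynamics with the BAOAB splitting at `dt = 0.005τ`.
With zero friction and zero noise the integrator reduces exactly to
velocity Verlet; this limit is used for the energy-conservation tests.

The friction rate is `γ = 0.1 τ⁻¹` by default.  The physics of interest —
which adhesive pair meets first, and the conformational statistics at the
moment of capture — is set by the thermal ensemble and by the *ratio* of
the two capture rates, which a uniform change of the friction rescales
together; a low friction inside the stable range simply shortens the
diffusive search.  `γ` is configurable for anyone wanting the strongly
overdamped limit.

Adhesion is checked every step: when a designated pair first comes within
the capture distance, a permanent FENE bond with the standard parameters
is added between the two beads and the pair's flag is set.  The default
capture distance is `1.3σ` — inside the range where the Gaussian well
dwarfs thermal fluctuations, and safely below the FENE maximum extension
`R₀ = 1.5σ`: a bond created at `R₀` would diverge on the spot, so the
engine refuses capture distances near `R₀`.
Flags are monotone — adhesion never releases.  The run ends when the
*terminal* pair bonds (the chain is now a closed ring and its topology is
frozen), regardless of the internal pair's state; runs that exceed the
step cap are recorded as *censored* and excluded from numerator and
denominator of every probability (their count is reported).  Enforcing
permanence with a real bond, rather than relying on the deep well alone,
gives an unambiguous circularization event and a hard guarantee that
flags and geometry stay consistent.

## Knot identification

A circularized final frame is a closed polygon (the terminal adhesion
provides the closing edge; no auxiliary closure construction is needed).
Identification proceeds in two stages:

1. **KMT-style simplification.**  Any vertex whose triangle with its two
   neighbours is pierced by no other edge is deleted; repeated to a fixed
   point.  Each deletion is an isotopy, so the knot type is preserved.
   Geometric predicates are conservative: ambiguous (near-degenerate)
   intersections block a deletion, which can only leave the polygon less
   reduced, never mis-simplified.  Marked vertices (the internal sticky
   pair) are never deleted when the caller needs them.
2. **Alexander determinants.**  The reduced polygon is projected along a
   random direction (re-drawn on any degeneracy — crossing at a vertex,
   tangency, equal depths — up to 50 attempts), the crossing diagram is
   read off, and the Alexander matrix is built.  The determinant of its
   principal minor equals `±t^a Δ(t)`; we recover the polynomial exactly
   by integer determinant evaluation (fraction-free Bareiss) at `m+1`
   integer points and Lagrange interpolation, strip the unit `±t^a`, and
   check `|Δ(1)| = 1` (a failure marks an inconsistent diagram and
   triggers a retry).  The reported invariant is `(|Δ(−1)|, |Δ(−2)|)`:
   `(1,1) → 0₁`, `(3,7) → 3₁`, `(5,11) → 4₁`, `(5,31) → 5₁`,
   `(7,16) → 5₂`, anything else → `other`.  This pair separates every
   knot the study tracks; composites and ≥6-crossing knots land in
   `other`, and chirality is invisible to the Alexander polynomial (and
   irrelevant here).

Validation fixtures are parametric curves of known type: torus curves for
3₁ and 5₁, the standard figure-eight curve for 4₁, a Lissajous knot with
frequencies (3, 2, 7) and phases (0.7, 0.2, 0) for 5₂, and a circle for
the unknot, each with optional bounded radial noise.

## Sticky-loop relevance

For a knotted ring whose internal pair is adhered, the ring is split at
`X, Y` into the *sticky-loop ring* (`X..Y` plus a direct X–Y edge) and the
*excised ring* (the rest plus the same edge).  Because the pair is within
the capture distance, the closing edge is short (≤ 1.5σ) and cannot thread
anything at the scale of the chain.  The loop is **irrelevant** when the
knot is completely localized in one of the two sub-rings — exactly one
sub-ring carries the full ring's knot type and the other is unknotted —
and **relevant** otherwise, i.e. when loop and knot are entangled and the
excision changes the topology without leaving the knot intact in either
piece.  When both sub-rings turn out knotted (a composite-like situation
the two-ring test cannot localize) the verdict is *relevant*; the case is
rare and flagged by the `consistent` field.

## The experiment layer

**Grid.**  Arm lengths `l_x` (terminus A to X) and `l_y` (Ω to Y) run over
multiples of the grid spacing; placements are canonicalized by chain
reversal (`l_x ≤ l_y`), coincident sites are excluded, and the loop must
span at least one spacing.  For `N = 500`, spacing 50 this yields exactly
20 placements; for the demo scale `N = 100`, spacing 20 it yields 4.

**Statistics.**  `P_K` is the knotted fraction of non-censored runs;
`RKP = P_K/P_K⁰` with the reference `P_K⁰` simulated once per regime from
chains with adhesive termini only (the denominator is
placement-independent).  Intervals: Wilson for single proportions, the
Katz log method for the RKP ratio (with a 0.5 continuity correction on a
zero numerator; a zero *reference* knot count leaves the RKP undefined
and raises).  FCSL and FTRSL are, among knotted runs, the fractions with
a closed loop and with a closed *relevant* loop; `FTRSL ≤ FCSL` by
construction.  The knot spectrum is reported as fractions of knotted
runs.  The paper-scale campaign (`N = 500`, 20 placements, 104k/24k runs
per placement) is expressible in the same configuration schema but is a
cluster-scale computation, far beyond a desktop session.

**Persistence length.**  From an equilibrated open chain without adhesive
pairs, `⟨cos θ(s)⟩` is averaged over bonds and frames and fitted by
weighted least squares on the log over separations where the correlation
exceeds a noise floor (0.05).  `l_p = −b/slope` with `b` the equilibrium
bond length.  A non-decaying profile (rigid rod) raises instead of
returning an unbounded estimate.  For `κ_bend = 10 k_BT` the discrete
worm-like-chain expectation is `l_p ≈ 10σ`; excluded volume inflates the
apparent tail correlation slightly, which the noise floor suppresses.

## Problem sizes of the shipped tests and demo campaign

The shipped test suite and the acceptance script must run on a single CPU
in minutes, so they use a deliberately scaled-down version of the study
design; the full-scale design remains available through configuration.

* Topology: 100 noisy replicas of each of the five fixtures, plus
  hundreds of random closed polygons for invariance properties.
* Force field: finite-difference checks on 10-bead chains; NVE drift over
  10⁴ steps on a 20-bead chain; equipartition on a 4-bead chain over
  ~4×10⁶ steps.
* Persistence length: `N = 50` semiflexible chain, a few million steps.
* Demo knotting campaign: `N = 100`, spacing 20 (4 placements), L-DNA
  regime, 300 runs per placement and 400 reference runs.  The regime
  choice is a runtime trade-off: a semiflexible `N = 100` chain needs of
  order 10⁶ steps to circularize (many seconds per run), which puts even
  a single placement batch beyond a desk-scale session, while the
  flexible chain circularizes in ~10⁵ steps.

A caveat the campaign makes explicit rather than hiding: knotting at
`N = 100` is a very rare event (well below 10⁻³ per run — consistent
with the `N = 500` reference probability of ~2×10⁻⁴ and the decrease of
knotting with chain length), so a desk-scale campaign typically observes
*zero* knotted rings.  Knot-conditioned statistics — the RKP, FCSL and
FTRSL — are then undefined (a zero-knot reference is an error by
contract, not a silent zero), and the corresponding campaign test fails
with that diagnosis.  What the campaign *does* resolve sharply is the
adhesion mechanism underneath FCSL: the fraction of runs whose sticky
loop closed before circularization, which anti-correlates strongly with
the X..Y sequence separation (~0.99 at separation 19 vs ~0.59 at
separation 59 in a 1600-run campaign).  Resolving RKP itself at this chain length
needs of order 10⁴–10⁵ runs per batch — the paper-scale campaign — which
the configuration layer supports but a desktop session does not.

## Known limitations

* No electrostatics, twist rigidity, or hydrodynamics — the model probes
  topology-from-connectivity-and-adhesion only.
* The Alexander pair cannot distinguish chirality or resolve knots
  outside its table; `other` is a catch-all.
* The two-sub-ring relevance test reconstructs the loop-excision idea in
  its minimal form; configurations with knots in both sub-rings are
  classified conservatively as relevant.
* Censoring policy (excluded from both numerator and denominator) is a
  repository policy; with the default step caps censored runs are absent
  or negligible in practice.
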