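# Methods

`epilayout` turns the design of a multi-modal epidermal sensor — a single
patch of skin electrodes measuring any subset of surface EMG, electrodermal
activity (EDA) and ECG on the anterior forearm — into a constrained
geometric optimization problem.  This note records the model, its
parameters and assumptions, the numerical choices, and what the synthetic
anatomy does and does not capture.

## Anatomical model

The anterior forearm is modelled as a flat 2-D region.  A normalized
template (coordinates `(u, v)` in the unit square; `u` across the width,
`v` wrist → elbow) holds the outline, five muscle lines (FCR, BR, PL, PQ,
FCU) each as a pair of placement keypoints with innervation-zone (IZ)
polygons on the line, three candidate ECG electrode pairs with relative
SNR, an EDA anchor, and a sweat-gland density.  Four body measurements
scale it into millimetres: the length f1 multiplies `v`; the widths
f2/f3/f4 (wrist, mid, elbow) define a piecewise-linear width profile that
multiplies the centred `u`.  The map is affine per axis, so ordering along
the arm is preserved and identity measurements reproduce the template
exactly.

The shipped default template is **synthetic**: the muscle lines, IZ
positions and ECG keypoints are plausible constructions following the
qualitative arrangement of published placement guides (flexor bellies in
the proximal half, pronator quadratus distal, brachioradialis along the
radial edge; IZs mid-belly; ECG quality decreasing elbow → wrist), not
digitized anatomy.  Two quantities are literature values: forearm
sweat-gland density 1.08 glands/mm² (108 cm⁻²) and the wrist ECG pair
retaining a quarter of the best pair's SNR.  The mid-forearm ECG pair's
relative SNR is not published numerically; the default is 0.6 and is
template-editable.  Consequences: tests passing on this template validate
the *machinery* (scaling, scoring, optimization, selection rules), not the
anatomical accuracy of any specific design; for real use, substitute
digitized SENIAM-style coordinates through the JSON/YAML template file.

## Cost model

All modality costs are normalized to [0, 1] (0 best) so incompatible
quality metrics combine into one objective.

**EMG, per muscle.**  Pre-checks first: both electrode centres must be
within 10 mm of the muscle line, and neither electrode disk may intersect
an IZ; a violation scores 1.  Otherwise the cost is
`α·ω(θ) + (1−α)·ν(d)` with α = 0.5 by default:

- `ω(θ) = 0.0057·θ + 0.000181·θ²` for θ ≤ 60°, else 1 — the axial angle θ
  between the pair vector and the muscle line, folded into [0°, 90°]
  (a bipolar pair has no orientation sign, so antiparallel ≡ parallel;
  without the fold a perfectly aligned but reversed pair would score
  worst).
- `ν(d)`: 1 for d ≤ 5 mm (below the modelled range; unreachable anyway
  under the 12 mm spacing constraint, but scoring must be total),
  `max(0, 1.0125 − 0.0586·d + 0.0007·d²)` on (5, 25] mm, 0 on (25, 60] mm,
  1 beyond 60 mm.  The curve is continuous at 25 mm (the quadratic branch
  reaches 0 just before the breakpoint).

The EMG aggregate is the unweighted mean over selected muscles; the EMG
priority weight w1 is applied exactly once, in the global objective.

**EDA.**  Skin conductance is proportional to the number of sweat glands
bridged by the pair, `N_s = (π r² + 2 r d)·D_s` (disk surfaces plus the
strip between them).  With r = 5 mm (the EDA electrode is 0.78 cm²; r =
0.5 cm exactly) and the forearm density, the maximum at the recommended
6 cm spacing is N_max ≈ 733 glands.  Cost: 1 if N_s ≤ 140 (too few glands
for a functional measurement) or d > 60 mm (dermatome risk), else
`1 − N_s/N_max`.  Distances are centre-to-centre throughout.

**ECG.**  A discrete candidate model: the placed pair is matched to the
candidate keypoint pair minimizing the summed centre-to-keypoint distance
over both member assignments.  Within a capture budget of 2 × 20 mm
(20 mm per electrode) the cost is `1 − SNR/SNR_max` of the matched
candidate, so the best pair scores 0 and the wrist pair 0.75; beyond the
budget the cost is 1.  The capture rule bridges the discrete SNR table and
the continuous placement search; 20 mm is half the typical candidate-pair
spacing and is configurable.

**Area.**  The footprint is the area of the convex hull of the measurement
electrode *disks*, normalized by the footprint of the baseline layout.
Using the disks rather than centres matters: a centres-only hull assigns
zero area to any collinear arrangement, and the annealer reliably discovers
and exploits that degeneracy (collapsing high-quality layouts onto a tilted
line through all corridors); the disk hull instead charges such a strip its
true capsule footprint.  With equal radii the disk hull is computed exactly
(centres hull + perimeter·r + πr²); with mixed radii each circle is sampled
at 32 boundary points before the Graham scan (<0.7 % underestimate, which
cancels in the ratio).  Reference electrodes (at most two: a shared EMG
reference and an ECG reference, placed off the forearm) are excluded from
the hull and from all geometric constraints.

**Global objective.**  Three schemes.  `weights`:
`O = Σ w_k·O_k + w4·O4` with the enabled modality weights summing to 1.
`bounds`: per-modality cost ceilings ℓ_k with exponential penalties
`P_k = p·(exp(max(O_k − ℓ_k, 0)) − 1)` replacing the weighted terms
(modality weights zero).  `hybrid`: both.  The *quality* reported to users
is `1 − (weighted mean of enabled modality costs)` (unweighted mean under
`bounds`, where the weights are all zero); the area term is excluded from
quality — it measures size, not signal.  The baseline layout (pairs on
their keypoints, EDA at the anchor with 6 cm spacing, ECG on the best
candidate pair) scores 0 in every enabled modality under the default
template, so baseline quality is 1 and its footprint normalizes the area
term.

## Optimizer

Simulated annealing over electrode placements.  Validity is a hard
constraint checked before scoring: all measurement centres inside the
search region (forearm outline, intersected with a user shape or sweep
window; boundary counts as inside) and every pairwise centre distance at
least max(12 mm, r₁+r₂) — the 12 mm floor also guarantees non-overlap.
Invalid proposals are rejected outright, not penalized.

- Schedule: geometric cooling `T ← γ·T`, γ = 0.95, with
  `moves_per_temp = ⌈candidates/150⌉` so that any evaluation budget
  traverses the same T0 → ≈T0·γ¹⁵⁰ range.  Default budget 15,490 scored
  candidates per run.
- T0 = 0.1.  The objective deltas that must be retained are small (a
  single discovered muscle pair improves the 5-muscle multi-modal
  objective by only ~0.07), so the retention phase T ≲ ΔO/3 must cover
  most of the schedule; T0 = 1 wastes half the budget in an
  accept-everything random walk, and T0 ≲ 0.03 becomes too greedy to
  escape poor early locks (both measured on seeded benchmarks).
- Proposal kernel: a mixture of (a) local translation of one uniformly
  chosen electrode, direction uniform, magnitude uniform on (0, 10 mm]
  (probability 0.50); (b) uniform relocation of one electrode in the
  region bounding box (0.15); (c) joint relocation of a whole functional
  pair — first member uniform, second at a uniform direction and a spacing
  drawn from [12, 60] mm (0.35).  The jump moves are not cosmetic: each
  modality cost is *flat at 1* until both electrodes of its pair reach the
  target region, so purely local moves leave pairs stranded on the plateau
  (instrumented runs with local-only moves showed a pair never once
  co-occupying its 20 mm corridor in 15,490 evaluations).  Joint pair
  relocation turns corridor discovery from a coincidence of two
  independent walkers into a single-event probability.
- Acceptance: Metropolis — draw c ~ U(0,1), accept iff `c ≤ exp(−ΔO/T)`;
  improvements always accepted.  Best-so-far layout is returned, not the
  final state.
- Reproducibility: one `numpy` generator seeded from the config; all
  stochastic choices (initial rejection sampling, move type, coordinates,
  acceptance uniform) are drawn from it in a fixed order, so equal seeds
  give bit-identical designs end to end, including the saved JSON.

Initial layouts are rejection-sampled uniformly inside the region (60
placement tries per electrode, a configurable number of whole-layout
attempts); exhaustion raises an infeasible-region error, which the sweep
records as an infeasibility marker.

## Sweep protocol and design selection

A wrist-anchored window spanning the full width grows from the wrist in
fixed increments (1 mm reproduces the printed protocol; tests and the
scaled-down acceptance checks use 5 mm), each window optimized
independently with a seed derived deterministically from (base seed,
height) via `numpy` SeedSequence.  One upward pass serves both selections,
since the rules only consult the recorded list:

- AREA-OPTIMIZED: the design at the smallest window whose modality-cost
  aggregate (1 − quality; area excluded) is below 1 — the first window
  where any signal is predicted.
- QUALITY-OPTIMIZED: among designs with aggregate ≤ 0.05 (predicted
  quality ≥ 0.95), the smallest footprint.

Sweep runs default to a positive small-area weight (the acceptance checks
use w4 = 0.5 with w1 = 1): without it nothing inside a window rewards
compactness and the first-feasible design is an arbitrarily spread blob
rather than an aggressively shrunk one.  The selection aggregate itself
excludes the area term, since area is the quantity being traded.

## Problem sizes used in tests

The default test run uses scaled-down study sizes chosen once: single-
muscle annealing budgets of 600–2,500 candidates, the annealer-vs-grid
comparison on a 32 × 66 mm single-muscle region with a 2 mm exhaustive
grid and 20 seeded runs of 2,000 candidates, and a 5 mm-increment
uni-modal (FCR/BR/PL) sweep at 4,000 candidates per window.  The full
printed protocol (1 mm, 15,490 candidates per window) runs through the
same code path via the CLI.

## Numerical choices and degenerate inputs

- Boundary points count as inside for containment (permissive: layouts
  touching the sketched outline are not rejected).
- ν below 5 mm and pairs coincident in position cost 1 (total scoring for
  arbitrary layouts).
- IZ membership means the electrode *disk* intersects the IZ polygon, the
  conservative reading of "falls within".
- The 1 cm muscle-line check uses the electrode centre.
- Collinear or single-point disk hulls degenerate to capsule/disk
  formulas rather than errors.
- Angles are clipped before `arccos`; folding makes the pair unordered.
- Design files serialize with sorted keys and full float repr, so
  load(save(x)) == x exactly and equal-seed runs are byte-identical.

## Known limitations

- The anatomy is 2-D and the default template synthetic; per-subject
  accuracy requires real digitized guides.
- The ECG model is discrete (three candidate pairs + capture radius); a
  continuous forearm ECG map would remove the capture-radius construct.
- Skin properties that modulate real signal quality (subcutaneous fat,
  moisture, electrode–skin impedance) are outside the model.
- Simulated annealing offers no optimality certificate; the
  grid-comparison test bounds its gap only on a toy instance.
- Human-subject comparisons (area-reduction percentages against expert
  designs) depend on unpublished per-participant forearm measurements and
  recorded biosignals and are not reproduced here.
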