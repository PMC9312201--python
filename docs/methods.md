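# Methods

This note records the models, parameter choices and numerical decisions
behind `pentrack`, and what the synthetic-scene tests do and do not show
about real pen footage.

## Motion model

The tracker's state per identity is
x = (u, v, γ, h, u̇, v̇, γ̇, ḣ) ∈ ℝ⁸ — box center (pixels), aspect ratio
w/h (dimensionless), box height (pixels), and their per-frame rates. The
transition is the constant-velocity model x' = F x with F = [[I, I], [0, I]]
(block 4×4), i.e. a fixed time step of one frame; variable frame rates are
out of scope because pen surveillance runs at a fixed rate. The observation
model is linear: z = H x with H = [I 0] selecting (u, v, γ, h).

Noise is parameterized relative to the current box height h, the usual
convention for image-space tracking where uncertainty scales with apparent
size:

| term | std | default weight |
|---|---|---|
| position/height (process, measurement) | w_p · h | w_p = 1/20 |
| velocities (process) | w_v · h | w_v = 1/160 |
| aspect ratio (initiate / process / measurement) | 1e-2 / 1e-2 / 1e-1 | fixed |
| aspect-ratio velocity | 1e-5 | fixed |

Track birth doubles the position stds and uses 10 w_v h for velocities.
The γ terms use small fixed constants rather than h-proportional ones: γ is
of order one, and scaling its noise by a pixel height would let the aspect
ratio drift freely. Both weights are exposed in `TrackerConfig`.

The update solves the gain through a Cholesky factorization of the
innovation covariance S (raising `NumericalError` if S is not positive
definite) and re-symmetrizes the posterior covariance against round-off.
The gating distance is the squared Mahalanobis norm of the innovation,
computed by triangular solve against the same factor. Unit tests pin both
steps to an independent textbook implementation (explicit inverses) at
1e-8.

## Association

Per frame, after predicting all tracks:

1. **Preprocessing** — confidence filter (τ = 0.5 by default; detections
   with confidence ≥ τ survive) then greedy NMS at IoU 0.5. Both
   thresholds are conventions — reasonable defaults for modern detectors —
   and are config-overridable; ties at equal confidence keep the
   lower-index detection for determinism.
2. **Cascade matching** over *confirmed* tracks, grouped by staleness a_k
   ascending, so recently seen tracks have priority. Cost within a group:
   minimum cosine distance between the detection embedding and the track's
   gallery (a ring buffer of its last 100 accepted features), clipped by
   the motion gate: pairs with squared Mahalanobis distance above
   χ²₀.₉₅(4 dof) ≈ 9.4877 are infeasible. Assignments are solved with
   `scipy.optimize.linear_sum_assignment`; matched pairs costlier than
   0.2 (cosine) are demoted to unmatched. How motion and appearance should
   be *combined* is genuinely open; gate-then-appearance-cost is the
   simplest composition that lets appearance decide among motion-plausible
   candidates, and is what this package implements.
3. **IoU matching** for tentative tracks and confirmed tracks missed
   exactly one frame: cost 1 − IoU, pairs below IoU 0.3 unmatched.
   Tentative tracks never enter the cascade: a newborn track has little or
   no gallery, and its Kalman velocity is uninformed, so box overlap is the
   only reliable signal.
4. **Degraded mode** — when a frame's detections carry no appearance
   features the cascade cost falls back to the gating distance itself
   (ceiling = the gate threshold). Detection files without a re-ID sidecar
   therefore still track; the occlusion tests quantify what is lost:
   after a long mutual occlusion with direction changes, motion-only costs
   can prefer the swapped identity pairing while appearance keeps the
   correct one.

## Track lifecycle

New tracks are tentative and confirm after being matched `n_init = 3`
consecutive frames, *counting the spawning frame* (so a detection repeated
on frames 1–3 confirms on frame 3; the alternative reading — three frames
after the first — is available by setting `n_init = 4`). A tentative track
that misses a frame is deleted immediately. a_k counts frames since the
last successful match (incremented at predict, reset to 0 on update); a
track with a_k > A_max is deleted. A_max defaults to 30 frames — one
second of typical footage, long enough to ride out short occlusions while
keeping stale predictions from accumulating; it is the main knob to tune
per deployment. Ids are assigned by a monotone counter in first-seen order
and never reused.

## Single-line counting

The counting line is a segment with a band of half-width b around it
(default a few pixels); "touching" means the box center's perpendicular
distance to the line is ≤ b while its projection falls within the segment
(extended by b at the endpoints). Set A collects ids that touched; set B
collects ids that, being in A, were later observed off-band on the side
opposite their recorded entry side; the count is |B|. Implementation
details that the prose description leaves open, decided here:

- **Fast targets**: if a center jumps the band entirely between two
  observations (sign of the cross product flips), the touch is registered
  retroactively with the previous side as entry side.
- **Retreat**: an id that touches and withdraws to its entry side stays in
  A and is not counted; a later genuine crossing still counts (once).
- **Unknown entry side**: an id first observed *on* the band has no
  approach side; the first off-band side observed afterwards is adopted as
  its entry side, so only a subsequent full crossing counts.
- **Direction filter**: `direction_mode` restricts countable crossings to
  one orientation (left/right of the directed segment p1→p2).
- **Re-crossings**: B is a set, so an id crossing twice counts once. This
  is the literal two-set semantics; net-flow counting is a non-goal.

The optional region-of-interest polygon (the outer "counting area") merely
restricts which tracks reach the counter and carries no counting
semantics; it is not needed for any of the shipped scenarios and is left
to the caller (filter the track table before counting).

## Evaluation metrics

Frame-level matching for TP/FP/FN is greedy one-to-one by descending IoU
at a threshold (default 0.5), ties broken by lower prediction then gt
index. AP is the all-point-interpolated area under the precision–recall
curve over a global confidence ranking (an 11-point mode is available);
with one class, mAP = AP. AOR and ACLE average the per-matched-pair IoU
and Euclidean center distance over all N matched pairs (not per frame).
Counting accuracy is (1 − |pred − true|/true) · 100, floored at 0 — the
relative-error complement; with a true count of 26 and a prediction of 25
it gives 96.15%. Degenerate denominators (no predictions, no positives, no
matched pairs, true count 0) raise `UndefinedMetricError` rather than
returning a silent 0 or NaN.

## Synthetic scenes

`pentrack.scene.simulate` emulates exactly the statistics the pipeline is
sensitive to, with defaults chosen as plausible for pen surveillance:
15 targets (pens hold a dozen to two dozen animals) in a 1280×720 px
arena, 200 frames, speed ~ N(3, 1) px/frame with a heading random walk
(σ = 0.15 rad/frame) reflected at the walls, boxes ~ N(40, 6) px per side,
1 px detection jitter, 5% baseline miss rate rising to 50% when a box is
occluded (IoU > 0.3 with a nearer box — the box with the higher bottom
edge is the farther one in an oblique view and is the one dropped), 0.2
false positives per frame, and 32-dimensional appearance embeddings: one
fixed random unit vector per identity, emitted with σ = 0.1 noise and
renormalized. Randomness is split into named substreams (motion, dropout,
jitter, false positives, features) drawn unconditionally per target-frame,
so toggling one corruption never shifts another's draws; scenes are
byte-reproducible from the seed.

Scripted scenes (`scripted_crossing_scene`) replace the random walk with
straight constant-speed paths through the counting line at scheduled
frames (remaining targets parked on the entry side), giving an exactly
known crossing count; the same degradation pipeline applies on top.
`occlusion_encounter` is a hand-constructed two-target scene — head-on
approach, 10 frames of mutual occlusion during which both targets back
off — whose geometry is chosen so that all four track–detection pairings
at reappearance are inside the Mahalanobis gate but the motion-only cost
prefers the swapped pairing; it isolates the contribution of the
appearance term.

**What passing these tests does and does not show.** The simulator
exercises the tracker's failure modes (occlusion, misses, false positives,
crossing geometry) under controlled statistics; it does not render
appearance, so the re-ID embeddings are idealized (unit vectors with
isotropic noise) and say nothing about how a real re-ID network degrades
under blur, pose or lighting. Counting results on scripted scenes validate
the state machine and the tracker–counter interface, not performance on
crowded real footage, where detector quality dominates.

## Problem sizes and tolerances

The shipped tests run the tracker on scenes of 8–26 targets and 60–600
frames — small enough to iterate quickly, large enough that confirmation,
deletion, occlusion and crossing logic are all exercised many times per
run. Kalman and assignment equivalence checks run 500–1000 randomized
trials at 1e-8 absolute tolerance; geometric round-trips at 1e-9. The
count-recovery check demands exact counts on clean scenes and ±1 under 10%
misses with 1 px jitter across 20 seeds per load.

## Known limitations

- Appearance features are inputs; no re-ID model is trained or shipped.
- Single camera, single line; multi-camera fusion and net-flow counting
  are out of scope.
- The constant-velocity model has no camera-motion compensation; the
  camera is assumed fixed.
- Track confirmation counts the spawning frame (see lifecycle); deployments
  that read the rule differently should set `n_init` accordingly.
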