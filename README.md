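# pentrack

Tracking-by-detection and single-line counting for livestock pen
surveillance.

Counting animals in a pen from a fixed surveillance camera is hard to do by
detection alone: the same animal is seen in every frame, animals occlude
each other, and detectors miss or hallucinate boxes. `pentrack` takes the
*tracking* route: an external detector (typically a YOLO-family head
detector) proposes per-frame bounding boxes, a Kalman-filter tracker links
them into identity-preserving trajectories, and a virtual counting line
turns trajectories into a count in which each identity is counted exactly
once. The package is detection-agnostic — it consumes MOT-Challenge
detection files, so any detector can feed it — and ships a synthetic
pen-scene simulator so the entire pipeline is testable without video data.

It is aimed at people building or evaluating automated livestock counting
(goats, sheep, pigs) and at anyone who needs a compact, well-tested
DeepSORT-style tracker and line-crossing counter that runs on plain text
files.

## The method

**Motion model.** Each track carries an 8-dimensional state
(u, v, γ, h, u̇, v̇, γ̇, ḣ): box center, aspect ratio w/h, height, and their
per-frame velocities. A standard constant-velocity Kalman filter predicts
the state each frame and is corrected by the matched detection through a
linear observation model that reads off (u, v, γ, h). Noise scales with box
height (position σ = h/20, velocity σ = h/160 by default).

**Association.** Detections are preprocessed (confidence threshold τ, then
greedy NMS). Confirmed tracks are matched by *cascade matching*: tracks are
visited in increasing staleness a_k (frames since last match), so a freshly
seen track can never lose a detection to a stale one — this protects the
identities of briefly occluded animals. Within each age group the cost is
the smallest cosine distance between the detection's re-ID appearance
embedding and the track's feature gallery, gated by the squared Mahalanobis
distance in measurement space (χ²₀.₉₅, 4 dof ≈ 9.488); the Hungarian
algorithm solves the assignment. Tracks and detections left over go through
a second *IoU matching* stage (cost 1 − IoU, floor 0.3) that also handles
newborn tracks. Without appearance features the cascade falls back to
Mahalanobis-distance cost (a documented degraded mode).

**Lifecycle.** A new track is tentative and must be matched 3 consecutive
frames (n_init, counting its first) to be confirmed; a tentative track that
misses a frame is dropped. Every match resets the staleness counter a_k to
zero; when a_k exceeds A_max (default 30) the track ends.

**Single-line counting.** A red counting line is drawn across the scene.
Set **A** collects every track id whose box center has touched the line;
set **B** collects every id that touched it and then detached on the far
side. The count is |B|. Set semantics make the count robust: dithering on
the line, retreating, or re-crossing can never count an id twice.

**Evaluation.** precision = TP/(TP+FP), recall = TP/(TP+FN), mAP (area
under the precision–recall curve at IoU 0.5), overlap rate OR = IoU with
its mean AOR, center location error CLE = √((x_e−x_f)² + (y_e−y_f)²) with
its mean ACLE, and counting accuracy = (1 − |pred − true|/true) · 100%.

## Worked example

Simulate a pen scene in which 7 of 8 animals cross a vertical line at
x = 640 on a schedule, with detector noise (1 px box jitter, 5% missed
detections, 0.2 false positives/frame); track; count; evaluate:

```sh
pentrack simulate -c demo.yaml -o demo
pentrack track -d demo/det.csv -f demo/features.csv -o tracks.csv
pentrack count -t tracks.csv -c demo.yaml --interval 30
pentrack evaluate -t tracks.csv -g demo/gt.csv -d demo/det.csv -c demo.yaml
```

prints

```
wrote scene (8 targets, 120 frames) to demo
tracked 8 identities over 120 frames -> tracks.csv
interval 1: cumulative count 0
interval 2: cumulative count 3
interval 3: cumulative count 5
interval 4: cumulative count 7
count: 7
AOR: 0.941082
ACLE: 0.951669
matched_pairs: 895
AP: 0.952056
count: 7
true_count: 7
counting_accuracy_pct: 100.0
```

The tracker recovered all 8 identities without fragmentation, the
cumulative count per 30-frame interval follows the crossing schedule, and
the final count equals the 7 true crossings (100% counting accuracy). AOR
≈ 0.94 and ACLE ≈ 0.95 px reflect the 1 px detection jitter; AP ≈ 0.95
reflects the simulated misses and false positives. The same pipeline is
available as a library (`pentrack.Tracker`, `pentrack.LineCounter`,
`pentrack.simulate`, ...); see `docs/methods.md` for the model details and
parameter choices.

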