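# Methods

This note documents the models, defaults and design choices behind
`sefast`, in the order data flows through the pipeline.

## Label taxonomy and annotation format

Five labels: postures **Standing**, **Sternal recumbency**, **Lateral
recumbency** (mutually exclusive — every annotated animal-second carries
exactly one) and behaviors **Eating**, **Sleeping**. Eating (head lowered
to feed off the ground) implies Standing; Sleeping may accompany any
posture. Seven combinations are therefore legal, and the validator enforces
them over every `(video, second, entity)` group on both read and write.

Annotations use the public AVA-style CSV convention: one row per
`(video_id, second, box, action_id, entity_id)`, normalized corner
coordinates `x1,y1,x2,y2` in [0, 1] serialized with three decimals, 1-based
action ids, multiple actions as multiple rows. Coordinates are continuous
and inclusive; no pixel half-open convention is imposed at the annotation
level. Detector output travels as a JSON array of
`{video_id, timestamp_s, box, score}` objects.

## Synthetic stall scenes

The generator emulates the study conditions the pipeline targets: a fixed
camera over an individual stall, one horse per stall, 16:9 frames, 60 s
videos, and a 32-video corpus with the observed combination counts
(3, 11, 4, 4, 3, 3, 4) over the seven legal combinations — Standing-related
videos dominate (18 of 32) while each recumbency appears in only 7.
Stratified sampling (the default) reproduces those counts exactly — for
other corpus sizes quotas are apportioned by largest remainder — and an
i.i.d. mode draws combinations from the corresponding probabilities
(Standing+Eating mass 11/32).

The animal is a composite of ellipses whose silhouette separates the three
postures geometrically: an upright body on legs with a raised head
(Standing), a compact chest-down mound with a lifted head (Sternal), and a
flat elongated form with outstretched legs (Lateral). Behaviors add cues in
both appearance and motion: Eating lowers the head to ground level with a
1.5 Hz vertical bob; Sleeping freezes the animal (awake animals shift
weight sideways by ±1 px between frames), closes the eye (a dark patch
replaces a bright one) and darkens the scene to 55% illumination — sleeping
segments are night footage. A seeded smooth-noise texture varies the stall
background per video, global illumination drifts sinusoidally through each
video, and Gaussian pixel noise (default sd 4 gray levels) is added per
frame.

Ground truth is exact by construction: each second's box is the tight
bounding rectangle of the rendered silhouette's union over that second, so
the box-versus-mask IoU stays above 0.9 for every frame (tested). Because
posture classes are separable from two shape features alone (box aspect
ratio and height — verified by a logistic probe reaching accuracy 1.0),
the recognition task is learnable at desk scale *by design*. That is the
central caveat for interpreting green tests: they demonstrate the pipeline's
mechanics (sampling, fusion, attention, losses, matching, metrics), not
recognition difficulty. Real footage has occlusion, low-light noise,
appearance variation between horses, ambiguous sleeping postures — none of
which the generator attempts to model.

Default rendering is 256×144 @ 10 fps (desk scale, same aspect as the
1920×1080 @ 30 source geometry, which `RenderConfig.paper_scale()`
restores). Frames are written as
`frames/{video_id}/{frame_index:06d}.jpg`, with the annotation CSV,
ground-truth detection JSON, label map TSV and a YAML manifest beside them.

## Frame pipeline

Dual-rate extraction mirrors the annotation protocol: dense frames (30 fps
at paper scale, 10 fps at desk scale) for clip assembly, 1 fps keyframes
carrying annotations. For the reference 32 × 60 s corpus this yields
32·60·31 = 59,520 frames of which 1,920 are labeled; an 8:2 seeded shuffle
split (sizes `round(n·frac)`, remainder to train) gives 1536/384. Clip
windows are centered on the annotated second's first frame (`t·fps`, 0-based
indices) and padded at video edges by clamping, i.e. repeating the boundary
frame; the temporal anchoring is a package choice, as is edge handling.
`N_slow·S_slow = N_fast·S_fast = L` holds for every valid configuration, and
the slow view's indices are a subset of the fast view's because `S_slow` is
a multiple of `S_fast`.

Augmentation is photometric only (boxes are normalized coordinates and are
never touched): color jitter (brightness/contrast/saturation factors drawn
uniformly from `[1−s, 1+s]`), seeded Gaussian noise, and CLAHE
(via scikit-image; `clip_limit` follows the common convention where 2.0 is
mild, mapped internally to the fractional limit `clip_limit/256`; default
8×8 tiles). During training a random half of each batch (fraction
configurable) receives brightness/contrast scaling plus noise, reseeded per
epoch. Geometric augmentation is deliberately absent.

## Network

Both presets share the same skeleton: slow and fast stems, a stack of
stages downsampling spatially by 2, lateral fusions, optional SE block on
the slow pathway, a final fusion, ROI average pooling, and a linear 5-way
sigmoid head.

- **tiny** (default for experiments): single-conv stages, slow channels
  16→32→32→32 (temporal kernels 1,1,3,3), fast channels at β = 1/8 with
  3×3×3 kernels, four fusion points (before stages 2–4 plus the final one),
  input 32×18. ~78k parameters; a full train/evaluate cycle takes seconds
  on one CPU. The single-conv stage depth is the concession that keeps the
  NumPy engine tractable; channel ratio, strides, SE placements and fusion
  count match the full design.
- **resnet50-3d**: bottleneck stages 3-4-6-3, slow channels 256→2048
  (temporal kernels 1,1,3,3 on the first 1×1 conv), fast at β = 1/8 with
  temporal kernel 3, stem kernels 1×7² / 5×7². The stem's pooling stage is
  folded into a stride-2 first block of the second stage. Fusion points as
  in tiny: lateral convolutions feed stages 2–4 and the fourth fusion is
  the final one after the last stage.

Lateral connections transform the fast feature map by a 5×1² convolution
with temporal stride α = 8 and 2·C_fast output channels, then concatenate
onto the slow channels — so fast temporal length must be α× the slow length
at each fusion (guaranteed by the stride ratio).

The SE block pools over time *and* space: the map at the end of the slow
pathway is temporal (C×T×H×W), and collapsing T into the channel descriptor
is the natural extension of the 2-D formulation. Placement `end` applies it
after the last slow stage, before the final fusion; `front` applies it
after the stem; `none` disables it. The bottleneck uses reduction ratio 16
(the standard SE default) with biases; the first-layer bias initializes to
0.1 because a 2-unit bottleneck (32 channels / 16) with zero bias has an
appreciable chance of starting entirely in the ReLU dead zone. Forcing the
gates to 1 reproduces the attention-free network bitwise (tested at both
placements).

Normalization is per-sample, per-channel (instance norm without affine
parameters): batch-free, so train and inference behave identically and
results are independent of batch composition. Initialization is He-normal
scaled by fan-in. ROI pooling snaps the normalized box outward to the
feature grid (minimum one cell) and averages over time and the region; each
box yields one logit row, so duplicated boxes yield duplicated rows and an
empty box list is an error (detection is a prerequisite of recognition).

Training uses Adam (default lr 3e-3, batch 16, 5 epochs), with a fresh
epoch seed derived from the run seed; runs are bitwise reproducible.
Checkpoints are a single `.npz` holding every parameter plus the JSON-coded
network configuration.

## Losses

With logits `x`, binary targets `y`, the stable elementwise form
`softplus(x) − x·y` underlies all four variants. Class weights follow
inverse frequency normalized by class count, `w_i = (Σ_j n_j)/(C·n_i)`,
computed from positive-label counts of the training clips (weights from
video counts give the same ordering; the weight function is pluggable).
Zero-count classes are rejected with instructions to merge or drop. Focal
modulation is applied per element *before* reduction — the only reading
under which `p_t` (the predicted probability of the true binary outcome) is
well defined — and keeps a leading factor `r`, so the modulated loss is
`r·(1−p_t)^r·ℓ` with integer `r ≥ 1` (a warning is emitted outside the
well-behaved range [2, 4]). `orthodox_focal=True` drops the leading
constant, which only rescales the effective learning rate. With unit
weights `cw_f` reduces exactly to `bce_f`; losses remain finite for
|logit| ≥ 50 by construction.

## Detection and evaluation

The oracle detector degrades ground truth per annotated entity-second:
Gaussian corner jitter (clipped to [0, 1], minimum box extent 1e-3), box
dropout with probability `drop_rate`, score `1 − mean|jitter|` clipped to
(0.05, 1], and Poisson-distributed uniform false positives with low scores.
Association is greedy in descending score (ties by input index) at IoU 0.5;
unmatched detections carry empty label sets and unreached ground truth is
reported as missed — the failure mode where recognition never runs.

AP is the all-point-interpolated area under the precision–recall curve
(precision envelope integrated over recall), one sweep per class treating
each (box, class, box_score·class_score) as a detection; each ground-truth
box is matchable once. mAP averages classes with positive support. Score
ties are broken by input order, which matters because AP is tie-sensitive.
Since a plain "accuracy" number admits two readings for a multi-label
detector, the summary reports both per-class AP and thresholded (0.5)
per-class precision/recall/accuracy computed over associated
prediction–ground-truth pairs, labeled distinctly.

The comparison harness trains the tiny network per
(SE placement × loss × r × seed) cell on a synthetic corpus and tabulates
all of the above; it caches finished cells as JSON so interrupted grids
resume. The default grid is r ∈ {2, 3, 4} × {bce_f, cw_f}.

## Problem sizes and expectations

Desk-scale experiments use a 32-video stratified corpus of 8-second videos
at 256×144 @ 10 fps (256 annotated seconds; the reference composition
preserved exactly), the tiny backbone at 32×18 network input, 5 epochs —
sizes chosen so a full loss-comparison grid runs in a couple of minutes on
one CPU. On this task the trained recognizer reaches macro posture recall
≥ 0.8 and end-to-end mAP@0.5 ≥ 0.8 through the oracle detector (median
over three seeds); because the task is separable by design, both losses
typically saturate and the class-weighting comparison asserts a
non-inferiority direction (cw_f ≥ bce_f on minority-posture recall) rather
than a strict gap.

## Known limitations

- The synthetic scenes contain one animal, no occlusion, and no
  photorealism; conclusions about real-footage accuracy do not transfer.
- The NumPy engine is single-threaded and CPU-bound; the resnet50-3d preset
  is exercised for construction and forward correctness, not trained here.
- Sleeping is signaled by synchronized cues (stillness, eye, illumination);
  the generator cannot express the genuinely ambiguous cases (eyes-open
  sleep, standing sleep with leg shifts) that make the label hard in
  practice.
- The oracle detector's score model (`1 − mean|jitter|`) is a heuristic
  stand-in for a learned detector's confidence calibration.
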