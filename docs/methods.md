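# Methods

## The detection problem

Wet-dog shakes (WDS) are whole-body oscillations lasting ~0.3 s that serve
as a progression marker in the kainate rat seizure model. They are rare
(roughly 0.4% of frames even in an over-expressing model), short, and easy
to miss from any single camera — in particular when the animal faces away
from it. `mvshake` detects WDS events from one to four synchronized camera
streams by classifying each frame independently per view and then fusing
the per-view score series over a temporal window.

## Pipeline

Let the session have `V` views and `T` frames at `fps` frames per second.

1. **Localization.** One animal per arena. A matched-filter localizer
   produces exactly one box per frame and view: the mean appearance
   template (learned from annotated boxes) is cross-correlated with the
   frame; correlation peaks become candidate boxes through a learned
   foreground threshold (Otsu on training frames) and the bounding extent
   of the thresholded mask near each peak; overlapping candidates are
   de-duplicated with non-maximum suppression (IoU > 0.5 keeps the
   best-scoring box); a per-coordinate linear calibration fitted by least
   squares on the annotations corrects systematic bias. Confidence is the
   normalized correlation peak; boxes under 0.3 are flagged but never
   dropped, because downstream stages need a score for every frame.
   Any localizer meeting the IoU contract would do — direct box
   regression included; the matched filter is compact, deterministic, and
   needs no pretrained weights. Annotation frames are chosen by embedding
   a frame subsample with a fixed random-convolution feature bank,
   reducing to 100 principal components, and K-means clustering
   (k-means++, 10 restarts, seeded); the member nearest each centroid is
   annotated.

2. **Cropping.** `crop_square` cuts a square of side
   `ceil(max(w, h) * 1.1)` centered on the box, edge-replicates past frame
   borders, and resizes to 64 px. Predicted boxes are stored as predicted
   (width and height free); squaring happens at crop time.

3. **Per-frame classification.** A small seeded convolutional network
   (two strided conv layers, a 32-unit dense layer, dropout, softmax)
   maps each crop to `(p_nwds, p_wds)`. It is trained on a balanced crop
   set: every WDS frame in every view, plus an equal number of NWDS
   frames sampled uniformly without replacement. Labels annotate *time*,
   so a view in which the shake was invisible still contributes a
   WDS-labeled crop — deliberate, realistic label noise that caps
   attainable accuracy at `1 - (1 - mean visibility)/2` on the balanced
   set. The validation split holds out a whole session.

4. **Score-map fusion.** For each frame `t` a score map
   `X_t ∈ [0,1]^{V × (2n+1)}` stacks the per-view `p_wds` series over the
   window `t-n .. t+n` (default `n = 15`, i.e. 31 frames), edge-replicated
   at the series boundaries. A small convolutional network classifies the
   map: Conv2D with 30 filters and kernel (3, 5) spanning (views, time),
   flatten, dense 20 + ReLU, batch normalization, dropout (rate 0.3),
   dense 2 + softmax — 16 782 trainable parameters at `V = 3`, `n = 15`.
   The kernel's first extent spans views (rows) and the second time
   (columns), matching the map layout. With fewer than three views the
   map is zero-padded along the view axis; the network is retrained per
   camera configuration, so adding or removing cameras only retrains this
   stage. Training uses the label of the window's center frame and keeps
   every frame of the series as a (class-weight balanced) example: the
   network must see the classifier's full background score distribution,
   including its mid-confidence false-positive bumps, to learn to reject
   them.

   Fusion training data follows the stacking pattern. Two fold
   classifiers (one per training session) score the session they never
   trained on, and fusion trains on these out-of-fold series. In-sample
   scores are unusable: a classifier partly memorizes its own training
   crops, which would make events invisible in a view look detectable
   there, silencing exactly the effect fusion exists to fix. The
   *deployed* scorer is an ensemble — the two fold models plus a refit on
   all crops, averaged — so that individual models' overconfident
   background mistakes cancel while unanimous scores (actual shakes) stay
   near 1; inference-time bump amplitudes therefore sit at or below those
   of the training series, biasing fusion toward rejecting noise, the
   safe direction.

   Because a desk-scale benchmark holds only ~14 training events (the
   study had ~370), event neighborhoods are augmented with
   label-preserving score-map transforms: permutations of the
   data-carrying view rows (any camera may carry the signal); single-view
   isolation copies (keep one signal-carrying row, silence the others —
   events visible in exactly one view are otherwise too rare to learn);
   short-plateau masks (symmetric 3-frame and both asymmetric 2-frame
   cores, since events near the minimum duration are underrepresented);
   synthetic *bump negatives* (background windows with a mid-amplitude
   0.4-0.8 plateau pasted across the center, kept negative — the
   classifier's residual error mode, whose prevalence in any particular
   training series is too seed-dependent to rely on); and *context bumps*
   pasted off-center onto positive windows, so a bump next to a genuine
   plateau cannot veto it (the agent often faces away from a camera just
   before freezing into a shake). Augmented samples are capped at a
   fixed fraction of each class's weight, and training ends with two
   rounds of hard-example mining: negatives still scoring above 0.25 and
   signal-carrying positives still scoring below 0.75 are upweighted 8x
   and training continues, the second round at halved learning rate.

5. **Post-filtering and events.** The fused series is cleaned with a
   sliding median filter and then a sliding minimum filter (both
   edge-replicated; even minimum widths take the extra sample on the
   left), then thresholded at 0.5. Filtering precedes binarization so ROC
   analysis of filtered scores stays possible. Maximal runs of positive
   frames become predicted events. Defaults are median 5 / min 5 at
   30 fps, which suppresses detections shorter than ~0.17 s — just below
   the 0.10 s minimum plausible shake; the 15 fps benchmark profile uses
   median 3 / min 2, the same time cutoff scaled to its frame rate.

6. **Evaluation.** Predicted events are matched one-to-one to
   ground-truth events greedily in temporal order with a >= 1 frame
   overlap criterion; fragmented predictions over one truth event count
   one true positive and the rest false positives. Event precision and
   recall are reported per configuration, with per-frame ROC/AUC computed
   on the raw (fused, unfiltered) scores. For sorted non-overlapping
   interval lists the greedy matching attains the maximum bipartite
   matching, which the test suite verifies against an exhaustive oracle.

## The synthetic session generator

Real recordings of this kind are not redistributable, so the package
ships a generator that reproduces their statistical structure and serves
as the benchmark for every stage.

**Schedule.** Event durations are truncated-normal: mean 0.33 s,
sd 0.11 s, truncated at 0.10 s (the truncation shifts the realized mean
by only +0.005 s). Event counts are fixed per profile or drawn Poisson at
41.5 events/hour — the rate implied by a 0.38% WDS frame fraction and the
0.33 s mean (0.0038 x 3600 / 0.33 ≈ 41.5). Starts are uniform conditional
on a 1 s minimum gap (exact sorted-spacings placement). Durations round
to >= 1 frame.

**Rendering.** The agent is an oriented ellipse (semi-axes 16% and 8% of
the frame side) following an Ornstein-Uhlenbeck velocity random walk with
wall reflection in a square arena, viewed as a stylized 2-D projection —
all views share geometry and differ in visibility, which suffices to
reproduce the occlusion phenomenon that motivates multi-view fusion; no
3-D camera model is attempted. During an event the agent freezes, its
contour wobbles at the 12 Hz shake frequency, and a high-frequency stripe
texture whose phase advances at 12 Hz (aliased at the frame rate, as real
motion blur would be) is drawn on the body — but only in views where the
event is visible. Distractor bouts ("walking": 3.5x speed; "rearing":
transient shape change) are rendered without texture so false-positive
behavior is exercisable. Pixel noise is Gaussian (sd 0.03 of full scale).
Everything is a pure function of (parameters, seed).

**Visibility.** Each view carries a probability that a given event's
shake is visibly rendered, as a function of the agent's orientation at
the event. The default three-camera layout is two side cameras mounted
near each other on one wall (azimuths ±6°; visibility 0.97, falling to
0.62 inside a 72°-wide blind cone opposite the camera) and one overhead
camera (flat 0.99). The numbers were fixed by design arithmetic, once:

- mean per-view visibility (2 x 0.90 + 0.99)/3 ≈ 0.93, so the balanced
  crop set's accuracy ceiling is ≈ 0.96 — comfortably above the 0.92
  working floor while leaving real label noise in play;
- the side cameras share most of their blind cone, so the probability
  that *both* miss an event is ≈ 0.03-0.045 — large enough that adding
  the overhead camera measurably raises recall over ~150 events;
- the probability that all three views miss an event is ≈ 4 x 10⁻⁴, and
  the generator additionally guarantees every event at least one visible
  view, so three-view recall is limited mainly by the temporal filters.

**What the generator does not emulate** — and what passing its benchmark
therefore does not show about real data: photorealistic appearance and
lighting, 3-D perspective and lens distortion, partial occlusion by
enrichment objects, multi-animal interaction, annotator disagreement at
event boundaries, camera desynchronization, and graded (rather than
per-event) visibility. The benchmark demonstrates that the pipeline's
machinery — localization, balanced training, score-map fusion, filtering,
event matching — behaves correctly and reproduces the qualitative
view-count effect, not that the specific accuracy numbers transfer to any
real recording.

## Benchmark profiles and problem sizes

The package's standing benchmark (the `fast` profile) uses two training
sessions and one validation session of 600 s at 15 fps and 64 px, seven
events per session — chosen to preserve the ~0.38% WDS frame fraction at
desk scale. The localizer trains on 500 selected frames and is scored on
72 held-out frames, mirroring the study-scale 1500/72 split. View-count
comparisons pool events over 20 additionally generated validation
sessions (~150 events), because a single 7-event session cannot resolve
recall differences of a few percent. The `full` profile mirrors the
study's three one-hour recordings (149/220 training events, a 49-event
validation hour at 30 fps and 96 px). A `tiny` profile (20 s sessions)
exercises the full pipeline in seconds for tests.

## Numerical and design choices

- Coordinates are 0-based, origin top-left; boxes are (x, y, w, h) with
  inclusive integer pixel extents; IoU uses pixel-count areas.
- The fusion input uses one channel (`p_wds` only) by default; `p_nwds`
  is redundant under softmax, but a two-channel option is retained.
- Boundary handling is edge replication everywhere: score-map windows,
  median/minimum filters, and crops at frame borders.
- Ground-truth boxes in the generator are the bounding box of pixels
  with > 0.5 body coverage, the same contour a threshold localizer sees.
- The event matcher's overlap criterion (>= 1 frame) and the
  fragmentation penalty are the minimal-assumption reading of per-event
  counting; both are configurable.
- All training is float32 numpy with Adam; every random draw (weight
  init, batch order, dropout, subsampling, generation) flows from one
  `numpy.random.SeedSequence` per run, so repeated runs reproduce
  metrics bit for bit.

## Known limitations

- The matched-filter localizer assumes a single high-contrast agent; it
  would need replacement for textured backgrounds or multiple animals.
- Per-event (rather than per-frame) visibility makes missed events
  all-or-nothing within a view; real occlusion is graded.
- The fusion network is retrained per camera configuration by design;
  there is no variable-view-count inference.
- At 15 fps, events near the 0.10 s minimum duration span ~2 frames and
  sit at the edge of what the post-filters pass; the filter widths, not
  the classifier, bound recall there.
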