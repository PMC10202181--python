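# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the simulations show. Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## System model

The toolkit simulates an asynchronous shared-control loop with two states.
In **idle**, the robot navigates autonomously toward a destination while
the subject's EMG is monitored in 1 s windows (250 samples at 250 Hz, no
overlap, windows aligned to the stream start). A window fires the
idle→control switch when its peak-to-peak amplitude reaches the
subject-specific threshold T₀; the comparison is closed (`≥ T₀` triggers).
Once control is entered, EMG processing stops — the state machine never
runs ERP decoding in idle nor EMG monitoring in control, and the session
log preserves that contract for inspection.

In **control**, command selection runs through a 3×4 row–column oddball
interface: 7 flash groups (3 rows + 4 columns), stimulus onset asynchrony
140 ms (100 ms on + 40 ms off), so one repetition of all groups lasts
0.98 s and every item flashes twice per repetition. Online selections use
5 repetitions; decoder training uses 10.

## ERP decoding

Preprocessing is: common average reference over the five EEG channels
(Cz, PO4, PO7, PO8, Oz — the EMG channel FC5 is excluded from the
reference set, configurable), then a zero-phase 3rd-order Butterworth
band-pass 0.01–30 Hz. Epochs cover [50, 750) ms post-flash — half-open so
a 250 Hz epoch is exactly 175 samples — and are decimated by keeping every
7th sample (the 30 Hz low-pass provides anti-aliasing), giving 25 samples
per channel and a 4×25 = 100-dimensional feature vector.

The classifier is a Fisher linear discriminant trained on flash epochs
labeled target/nontarget. The pooled within-class covariance is shrunk
toward scaled identity, `(1−γ)S + γ(tr S/d)I` with γ = 0.1, because the
feature dimension (100) is comparable to the epoch count of a small
training set; w₀ puts the boundary at the midpoint of the projected class
means. Trial decoding sums discriminant scores per flash group over all
repetitions and intersects the winning row with the winning column; ties
break toward the lowest group index, which makes degenerate inputs (an
all-zero recording) decode deterministically to item 1.

Numerical notes: the 0.01 Hz band edge puts a filter pole essentially at
DC; forward–backward filtering uses even (mirror) padding because the
default odd padding excites a slow transient that leaks ~23% RMS of a
50 Hz probe into the output, while even padding keeps stop-band leakage
below 10% and pass-band transmission above 90%, as the frequency-response
oracle predicts. Sample-index arithmetic uses half-up rounding (50 ms at
250 Hz is sample 13).

## CVT road selection

Road extraction: 2-means clustering of the RGB values (deterministic
initialization: the color farthest from the image mean, then the color
farthest from that; a single k-means run), morphological closing then
opening with a 5×5 square element, and the 4-connected component
containing the bottom-center pixel — the point directly under the robot's
forward view — is the road region Ω. Anchoring on geometry rather than
brightness makes the binarization invariant to swapping road/background
colors. A single-color image raises an error instead of guessing.

The CVT is computed on the pixel grid: the centroid integral and the
objective `J = Σᵢ Σ_{y∈Vᵢ} ‖y−xᵢ‖²` become sums over pixel centers, with
an optional density ρ (uniform by default; centroids are invariant to
scaling ρ). Lloyd's iteration starts from n distinct random region pixels
(seeded) and alternates nearest-generator assignment (ties to the lowest
index) with centroid moves until the largest generator displacement is at
most `tol` = 0.5 px or 100 iterations. Both Lloyd steps weakly decrease J,
so the recorded J history is non-increasing up to float error; the tests
assert this together with the converged fixed-point condition (each
generator within `tol` of its cell centroid) and brute-force equivalence
of the assignment step. An emptied cell keeps its generator for that
iteration. Centroids stay continuous; they are never snapped to pixels.

n defaults to 11 because the selection interface exposes numeric commands
1–11 (item 12 is Exit). Sub-goals are numbered row-major in the image
(top-to-bottom then left-to-right), so the farthest goals get the lowest
numbers and the numbering is stable for the command map.

Projection: pixel rays are mapped at pixel centers — row v looks down
`pitch − vfov/2 + (v+0.5)/H·vfov` degrees, column u bears
`hfov/2 − (u+0.5)/W·hfov` (positive left) — and intersected with the
ground plane: forward = height/tan(depression), lateral =
forward·tan(bearing). With the default geometry (0.65 m, 30° pitch,
70°×60°) the top image *edge* lies exactly on the horizon; center-ray
mapping keeps every pixel on the ground, and edge coordinates at the
horizon raise. Conventions used throughout: image origin top-left, x
right, y down; robot frame x forward, y left; world heading
counterclockwise radians.

## Robot simulator

The published wheel-kinematics matrix is implemented verbatim
(`variant="printed"`): va = cosθ·vx − cosθ·vy, vb = sinθ·vx + sinθ·vy,
vc = r(vx + vy + θ'), θ = 30°. Its third row couples translation into one
wheel and omits rotation from the other two, which is dimensionally odd
for a 120° omniwheel platform; since the intended matrix cannot be
recovered with certainty, a conventional three-omniwheel matrix (wheels at
90°/210°/330°) is provided as `variant="standard"` and the printed form
stays the tested default. The discrepancy is documented, not fixed.

Single-step motions are body-frame: ±30° turns, 20 cm steps in the eight
compass directions, 40 cm long-forward; translations sweep in 5 mm
increments and stop at first contact, reporting the collision. The robot
is a disc of radius R = 0.2 m; contact at exactly R counts (closed rule).
Autonomous navigation plans with 8-connected A* on a 2.5 cm grid inflated
by R — fine enough to resolve the 20 cm steps — followed by line-of-sight
shortcutting, **against radar-visible obstacles only**; execution checks
the disc against *all* obstacles, so a radar-invisible (extremely low)
obstacle on the route stops the robot at contact with a collision event —
precisely the situation that requires human intervention. Destination
tolerance is 5 cm.

The built-in comparison world reproduces the stated scenario dimensions —
a 4.60 m × 2.25 m baffled field, start (0, 0), destination (4.0, 1.0), two
0.35 m × 0.60 m radar-invisible obstacles astride the direct route. The
exact published obstacle coordinates are not recoverable from the source
material, so obstacle placement here is a representative choice; scenario-
level outputs (durations, path lengths) characterize this world, not the
original one.

## Closed-loop sessions and the simulated subject

The session driver replaces the human with a deterministic oracle policy:

* it "clenches" when the upcoming planned path passes within
  R + 0.1 m of a radar-invisible obstacle inside a 0.7 m lookahead;
* in CVT mode it ranks sub-goals by the remaining path length to the
  destination *in its mental map*, where all obstacles are known (the
  subject sees the low obstacles on the video stream), subject to the
  straight-line approach being collision-free with 2 cm margin, a minimum
  0.25 m hop, and 12 cm of maneuvering clearance between the goal and any
  hidden obstacle (a goal hugging an obstacle would strand the next
  straight approach); it waits through up to five sub-goal display
  refreshes (0.5 s each — the road-selection system regenerates its layout
  continuously) until some goal offers at least 1.2 m of route progress;
* in SS mode it steps greedily toward a waypoint placed just past the
  blocking obstacle on the side nearer the destination;
* it issues Exit when the next 2.5 m of planned path is clear of invisible
  obstacles.

Entering control, the camera is aimed along the mental route (the subject
orients the omnidirectional robot toward where they intend to go); the
camera scene itself is rendered from the world map by ground-plane ray
intersection with a 3.5 m depth cutoff, which closes the loop without real
images. ERP selections are simulated by generating a fresh synthetic trial
for the intended item and decoding it with the session's trained FLDA, so
decode errors at low SNR propagate into the session exactly as they would
online. The simulated clock charges navigation at 0.2 m/s, EMG windows at
1 s, and n·0.98 s + t per selection (t = 3.0 s), letting SS and CVT
durations be compared qualitatively.

## Synthetic data: what it does and does not emulate

* **ERP trials** — Gaussian background noise on six channels; target
  flashes add a one-sided raised-cosine (Hann) bump of width 200 ms
  centered 300 ms post-flash on the four posterior channels, amplitude 5
  and noise SD 2 by default (a reliably decodable subject; amplitude 0
  yields chance-level decoding). Real ERPs have richer morphology, 1/f
  spectra, eye-blink artifacts, and latency jitter — none emulated, so
  passing tests show pipeline correctness and aggregation behavior, not
  expected human accuracy.
* **EMG traces** — uniform noise at rest amplitude 1 with 35 Hz sinusoid
  bursts at amplitude 40, making the peak-to-peak classes exactly
  separable; real EMG has spectral overlap with speech/swallowing
  artifacts, so the 100% sensitivity/specificity shown is a property of
  the separable synthetic regime, not a clinical claim.
* **Road scenes** — a two-tone full-width trapezoid narrowing to 35% at
  the top (a crude perspective road) with rectangular obstacle holes and
  optional Gaussian color noise; no texture, shadows, or photometric
  realism.

All generators return their ground truth (target item, burst intervals,
road mask) and are deterministic under a fixed seed.

## Timing parameters of the ITR

Q = 12 stimuli, D = 0.98 s per repetition, and an inter-trial interval t.
The source material prints t = 0.5 s next to the formula, but that value
reproduces no entry of its own offline ITR table, whereas t = 3.0 s
reproduces all 26 entries to one decimal place — verified here by
independent recomputation (`tests/test_acceptance.py`). The default is
therefore 3.0 s with 0.5 s selectable. Group rows average the *printed*
per-subject values (the published convention of averaging rounded cells);
sample SDs use the n−1 denominator; printed-precision comparisons round
half-up at one decimal.

## Problem sizes

The test suite and acceptance script run at desk scale: 50 decoder trials
at 5 repetitions (plus 120 at zero amplitude for the chance check), 15+15
EMG traces, 20 random regions of ≲300 px for the Lloyd invariants, 160×120
camera frames, and one CVT plus one SS closed-loop session on the
comparison world. These sizes keep every run deterministic and fast while
leaving the measured quantities (accuracies, counts, invariant violations)
stable across seeds.

## Known limitations

* Human-subject variability (per-subject Table-style rows, effort scores)
  is out of scope; sessions use one oracle subject model.
* The planner is grid-based A*, not the SLAM/ROS stack of the original
  robot; only the radar-visibility distinction is modeled.
* The CVT is Euclidean on the pixel grid; no geodesic or depth-aware
  metric.
* Session durations depend on the invented subject-timing constants
  (speed, refresh, lookahead) and support qualitative SS-vs-CVT
  comparison only.
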