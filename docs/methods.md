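# Methods

`cagetrack` analyses individual locomotor activity of small groups of
RFID-tagged mice living in an unmodified, rack-mounted home cage above a
baseplate of antennas. This note records the models the package
implements, the assumptions behind them, the defaults of the synthetic
cage simulator, and the numerical choices that were genuinely open.

## Localization model and quantization error

The plate is an `n_cols x n_rows` grid of antennas (3 x 6, 50 mm pitch
by default). A successful read places a tag at the *center* of one
antenna's detection tile, so reported positions are the true positions
quantized onto the grid of tile centers. We model the detection region
of each antenna as its square Voronoi tile of side `a` (the pitch)
rather than a disc of diameter `a`: the fields abut and jointly cover
the floor, so every point belongs to exactly one antenna, and the
square model is the one whose error statistics match the plate's
reported figures. For a tag uniform over one tile, the expected
distance to the tile center has the closed form

    E[d] = (a / 6) * (sqrt(2) + ln(1 + sqrt(2)))  ≈ 0.3826 a,

i.e. 19.13 mm ≈ 19 mm for `a = 50` mm, with worst case `a * sqrt(2)/2 =
35.36 ≈ 35` mm at a tile corner (a disc model would give 16.7/25 mm
instead). Both scale linearly with the pitch. A Monte-Carlo routine
(10^6 uniform draws by default) provides an independent numerical
cross-check of the closed form. Points exactly on a tile boundary are
assigned to the lower antenna index; the cage floor is fixed to the
grid extent (150 x 300 mm by default) and remains configurable because
the true wall positions relative to the plate edge are installation
details.

## Tracking, interpolation and distance

Reads are grouped per tag into sequences of tile centers, then linearly
interpolated onto a regular grid (1 s by default, matching the cadence
at which validation annotations are normally taken). Before the first
and after the last read the nearest observed position is held — no
movement is invented by extrapolation. Distance traveled is the summed
Euclidean step length on the grid. Because of center-snapping, missed
reads, and the one-tag-per-antenna-per-cycle limit, this systematically
*under*-estimates the true path length; a linear correction factor
(default 1.4) can be applied, but only on explicit request, and reports
always retain the raw value — for within-study contrasts the raw
estimate is the right quantity because the bias is shared. If a tag is
read by two antennas within one cycle (boundary jitter) both reads are
kept; interpolation absorbs the jitter. Duplicate `(t, tag)` rows keep
the first read with a warning.

Validation against ground truth cuts the common span into fixed-length
segments (6 min by default) and compares true with estimated distance
per animal-segment: Spearman rank correlation (average ranks on ties),
ordinary-least-squares slope/intercept, and the mean estimated/true
ratio. Fewer than three segments raise an error.

## Activity statistics

Distance is summed into bins whose width divides 24 h (6 min default;
12 min also common), attributing each grid step to the bin containing
its start so bin sums conserve total distance exactly. Statistics
computed on the binned series:

- **Double-plotted actogram**: row *d* shows days *d* and *d + 1*; the
  right half of each row equals the left half of the next, so phase
  drift is visible across rows.
- **Phase totals**: light/dark totals and mean-per-12-h-phase values on
  a retained window. The standard exclusion drops data before the
  first dark onset (acclimation after cage transfer) and, optionally,
  after the *n*-th lights-on (tear-down disturbance). With the default
  schedule anchor — recording starts at 12:00, lights 07:00–19:00 — a
  72 h recording retains exactly 60 h (36 dark + 24 light).
- **Settling bout**: cage transfer at t = 0 triggers a transient bout
  of elevated activity (typically up to ~60 min). Its boundary is not
  standardized anywhere, so we define it as the first time activity
  stays at or below the animal's light-phase median for `k = 2`
  consecutive bins. The `<=` comparison makes the rule exact on
  noise-free series; on noisy series the first-passage nature of the
  rule adds a lag of a bin or two — a known limitation. A series that
  never settles returns the full span with a warning.
- **Anticipatory index**: total activity in a fixed clock window before
  lights-off (18:00–19:00 by default) summed over the recording,
  paired with the total daytime activity as covariate. Clock windows
  are resolved against the wall clock carried in every file header,
  not against Zeitgeber time.

Group comparisons use a one-way ANOVA written directly from between-
and within-group sums of squares, or, when a covariate is supplied, an
ANCOVA (`value ~ group + covariate` versus `value ~ covariate`, F from
the residual-sum-of-squares difference) with group means adjusted to
the grand covariate mean. Pairwise tests are Tukey–Kramer using the
studentized-range distribution. The from-first-principles
implementation exists so it can be audited against independent
references (`scipy.stats.f_oneway`, statsmodels' Tukey HSD and OLS
ANCOVA), which the test suite does; zero within-group variance raises
rather than returning an infinite F. Animals are analysed as
independent units; cage-of-residence is not modelled as a nuisance
factor.

## Cosinor and onset/offset detection

With the period known (24 h under an entrained 12:12 cycle), the
cosinor model `x(t) = M + A cos(2 pi t / tau + phi) + e(t)` is linear
in `(M, beta, gamma)` after the harmonic substitution and solved by
least squares; `A = sqrt(beta^2 + gamma^2)`, `phi = atan2(-gamma,
beta)` reported in `[0, 2 pi)` and as clock time of the fitted peak
(the cycle's centre of gravity, CoG). A constant series is flagged
degenerate rather than given an arbitrary phase. Free-running period
estimation and periodograms are out of scope — the package assumes an
entrained, known period.

Onset/offset detection runs on a smoothed series (centered moving
average, default 5 bins = 30 min at 6-min binning, odd window, edges
truncated) to avoid premature onsets from single-bin spikes. For each
cycle the search window is CoG-centered, `[CoG - tau/2, CoG + tau/2]`
— a deliberate choice that makes the onset and offset searches
symmetric; a calendar-day window was the alternative. The threshold is
the mean smoothed activity over that window (the smoothed rather than
raw mean — also a choice; the two differ negligibly for full-cycle
windows). The onset is the first moment at or above threshold scanning
forward from the window start, the offset the last such moment before
the window end; both are refined below bin resolution by linearly
interpolating the threshold crossing between the bracketing bins.
Without that refinement a first-qualifying-bin rule carries a
systematic half-bin (0–6 min) late bias, which matters when recovery
within one bin is the requirement. Anticipation is `lights_off -
onset` and `lights_on - offset` in minutes (positive = anticipatory).
Detection is invariant to positive rescaling of the series because the
threshold scales with it.

## Social structure

Pairwise inter-animal distances are computed per grid point on the
shared tracking grid, with a huddle indicator (all pairs within a
radius, default 50 mm = one tile; "clustered" has no standard
definition, so the tile size is the honest choice). Occupancy heatmaps
around a detected onset histogram each animal's positions over antenna
tiles in 6-min bins, the central bin's midpoint coinciding with the
onset; fractions are normalized per bin, and both an occupancy map and
a per-bin mean position are reported (the map is the richer object, the
mean point the compact summary). A per-bin Shannon entropy summarizes
the huddle-to-dispersal transition.

## Synthetic cage simulator

The simulator is the package's source of ground truth, built so that
every analysis stage can be validated without animal data. It emulates
the *statistical* structure the analyses assume, not mouse biomechanics.

**Activity profile.** `lambda(t) in [0, 1]` is piecewise linear on a
24 h cycle: light-phase and dark-phase base levels, a linear
anticipatory ramp from the light level to a peak over the configurable
minutes before lights-off, a wind-down ramp before lights-on, and an
optional settling bout (elevated level for a configurable duration
after t = 0). Three presets emulate strain-like patterns: high
activity with post-dawn persistence and the longest settling bout
(C57BL/6J-like: dark 0.60 / light 0.18), low activity with suppressed
early-light activity (C57BL/6NTac-like: 0.30 / 0.05), and intermediate
activity with long, clear anticipation (C3H/HeH-like: 0.40 / 0.08,
100 min ramp). Per-animal variation is a single lognormal factor
(sd 0.08 on the log scale) on the levels — invented, as no source
quantifies it. The *programmed anticipation* of a profile is defined
exactly as the detector defines onset — the first mean-crossing of
`lambda` scanning from half a cycle before lights-off — so it is the
quantity a correct detector must recover, independent of simulation
noise.

**Movement.** A two-state (rest/active) correlated random walk at
25 Hz ground-truth sampling (matching video-annotation cadence;
long-horizon runs may use a coarser rate). Switching is an
inhomogeneous Markov process with rest-to-active rate `lambda(t)/120`
s^-1 and active-to-rest rate `(1 - lambda(t))/120` s^-1, so the
stationary active fraction equals `lambda` and bouts last minutes.
Active animals move at a per-animal mean speed (default 40 mm/s, CV
0.35) with heading diffusion 1.8 rad/sqrt(s); resting animals hold
still except for occasional repositions (rate 0.1 s^-1) that pull them
halfway toward a shared nest corner with 2 mm jitter — this produces
huddling with negligible path length, so a fully resting group
converges into one tile and travels essentially nothing. Walls
reflect. Everything derives from one seed; runs are bit-reproducible.

**Acquisition.** Antennas are polled in row-major sequence at a
configurable scan rate (default 3 Hz, inside the observed 2–3 Hz
range; physical ceiling 8 Hz). Per poll, the antenna reports the
nearest tag currently inside its tile with probability `p_read`
(default 0.9, a stated—not fitted—default since miss rates are not
quantified anywhere), at most one tag per antenna per cycle; when two
animals share a tile only the nearer is ever seen. Events are
timestamped at poll time, so timestamps strictly increase. The
slowing of the scan with read count is approximated by the fixed
effective rate rather than modelled dynamically.

**Direct series generation.** For rhythm-level studies (cosinor,
onset, group statistics) the generator can emit binned activity
directly: each bin gets `scale * lambda(mid)` mm (default scale
3000 mm per 6-min bin at `lambda = 1`, giving cage totals of the order
of 10^4 mm per bin at night) times mean-one gamma noise, default shape
10 (CV ≈ 0.32, a realistic bin-level variability). The
onset-*recovery* checks instead run at shape 200 (CV ≈ 7 %): they are
algorithm-correctness checks asking for per-cycle agreement within one
6-min bin, and crossing-time jitter under realistic noise exceeds one
bin by construction, so a weak-noise condition is the only setting in
which per-cycle recovery is a meaningful requirement. Consequently,
those passing tests certify the detector, not its per-cycle precision
on noisy animals.

**What the simulator does not emulate** — and therefore what passing
tests do not show about real data: thigmotaxis and wall-following,
realistic gait or tortuosity (the correlated walk is more tortuous
than real mouse paths, so the simulated distance under-estimation,
slope ≈ 0.55, is stronger than the ~1/1.4 seen against human
annotation; rank correlation is insensitive to this), identity
stability of real RFID hardware, dynamic scan-rate changes with
occupancy, and any social interaction beyond sharing a nest.

## Problem sizes and determinism

The distance-validation experiment uses 13 cages x 3 animals x 6 min
(39 segments, per-animal speeds log-uniform on 3–55 mm/s so true
distances span ~1–20 m) and reports the median Spearman rho over 10
seeds — the replication chosen to make a stochastic quantity stable.
Cosinor bias checks use 500 replicates of 7 days at 6-min bins with
Gaussian noise sigma = A/2; onset recovery uses ramps of 30/60/85/120
min over 3 animals x 7 cycles; the strain-structure checks use n = 12
animals per group over 7 days. All random streams derive from explicit
integer seeds via `numpy` `SeedSequence`, and the end-to-end pipeline
is bit-reproducible from one config seed.
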