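# Methods

## Problem

Care staff and researchers reviewing hours of facial-monitoring footage of
elderly care recipients need to know *when* to look: the moments at which the
subject's expression actually changed ("points of interest", PoIs). The input
is a set of per-second scalar feature values derived from facial landmarks —
mouth width `h9`, eyebrow height `a1`, eyes opening `a3`, mouth-corner
lowering `a4` — and the output is a short list of timestamps worth inspecting,
plus how much of the recording those timestamps represent.

## Model

### Composite feature: the Smile scale

Happiness moves several facial parts at once and in opposite directions:
the mouth widens while eyebrows, eye opening and mouth corners drop. Each
feature is first z-scored over the whole recording,
`z(t) = (x(t) − μ_x)/σ_x` (population σ by default, configurable via
`ddof`), then combined as

```
X(t) = 2·z_h9(t) − z_a1(t) − z_a3(t) − 2·z_a4(t)
```

The integer ±2/±1 weights encode that mouth-related movement is roughly
twice the magnitude of eye-related movement, as measured on paired
neutral/smiling samples (`derive_weights` reproduces that analysis: state
means, differences, and each |difference| relative to the mouth-width
reference). Measured per-subject ratios are deliberately *not* used as
weights — the degree of facial movement varies between individuals.

Standardisation is retrospective (batch); a streaming variant is out of
scope. A constant feature cannot be z-scored and raises an error naming the
feature.

### Two-stage SDAR change scoring

A sequentially discounting AR (SDAR) model of order `k` maintains, with
discount rate `r`:

```
μ_t     = (1−r) μ_{t−1} + r x_t
C_{t,i} = (1−r) C_{t−1,i} + r (x_t − μ_t)(x_{t−i} − μ_t),  i = 0..k
a_{t,·} : Yule–Walker solution of C_i = Σ_j a_j C_{i−j}, C_{−i} = C_i
x̂_t    = Σ_i a_{t,i}(x_{t−i} − μ_t) + μ_t
σ_t     = (1−r) σ_{t−1} + r (x_t − x̂_t)²
```

Each sample is scored by the negative log Gaussian density of its one-step
prediction under the *previous* step's model,
`y_t = ½ log(2πσ) + (x_t − x̂)²/(2σ)` with σ a **variance**. The score
stream is smoothed with a causal moving average of width `w`; the identical
machinery is then run a second time on the smoothed scores with width
`round(w/2)` (banker's rounding, so `w=5 → 2`). The second round makes the
final score respond to sustained shifts of the score process rather than
single outlying samples. Defaults: `k=1`, `r=0.025`, `w=5`.

### Thresholding and extraction

The extraction threshold is `γ = μ_S + σ_S` of the post-burn-in change
scores (population σ; the first 30 s are excluded because the discounted
learner is still converging). Every maximal run of consecutive samples with
`S(t) > γ` (strict) is one *excursion* and contributes exactly one PoI
candidate at its argmax. A baseline detector applies the same
excursion-argmax rule to the raw composite values with threshold
`μ + n·σ` computed over **all** raw values (n ∈ {0, 0.5, 1, 2} in the CLI
grid); the burn-in window is still excluded from extraction.

### Evaluation

A candidate matches an event point (a human-annotated onset/offset of a
happy-looking face) when `|t_c − t_e| ≤ 10 s` (closed interval). An event
point is counted at most once regardless of how many candidates surround
it; one candidate may serve several event points (no one-to-one
assignment). Recall = n_c/n_e, Precision = n_c/n_p; n_p/n and n_o/n
measure how much data still needs human inspection. Division-by-zero cases
report 0 with an explicit `*_defined = False` flag instead of raising.

## Numerical choices

- **Initialisation**: μ₀ = first observation, C = 0, σ = 0, coefficients 0.
  This makes a constant input an exact fixed point of the recurrences.
- **Scoring start**: a position is emitted as a flagged zero until the model
  both has `k` buffered observations *and* a strictly positive variance
  estimate. Scoring through the 1e-12 variance floor before any residual has
  been observed would emit a single ~10¹⁰-magnitude spike that corrupts the
  second-stage statistics for hundreds of seconds; a Gaussian density with
  exactly zero variance is degenerate, so those positions are treated as
  not-yet-scoreable. The 30 s burn-in additionally absorbs early transients.
- **Variance floor**: σ is floored at 1e-12 inside the log loss so long
  constant stretches (σ decaying geometrically toward 0) stay finite.
- **Yule–Walker singularity** (e.g. C₀ = 0 at the start): coefficients fall
  back to zero for that step — the predictor degrades to the running mean —
  and a flag is returned; no exception mid-stream. At `k=1` the solution is
  computed literally as C₁/C₀.
- **Smoothing prefix**: positions with fewer than `w` predecessors average
  over the available prefix, keeping output aligned 1:1 with input. Window
  sums are computed locally, not as global cumulative-sum differences, which
  lose all precision when one early value dwarfs the rest.
- **Ties within an excursion**: earliest sample wins. An excursion still
  open at the series end yields its candidate; its recorded end is one step
  past the last sample.
- **Forward fill**: grid cells take the most recent prior observation;
  cells before a feature's first observation are back-filled with that first
  observation (pure forward fill is undefined there).
- **Outlier removal** is off by default (never silently alter data). The
  optional rule marks points with `|x − median| > k·1.4826·MAD` (strict,
  `k=5`) missing and re-fills them. With MAD = 0 the strict inequality
  removes any point off the median while leaving constant columns untouched.

## Synthetic data

`EpisodeModel`/`generate` emulate a filmed care session: per-feature neutral
baselines with smile episodes that shift each feature by a signed delta,
ramped linearly over 2 s at onset and offset, plus i.i.d. Gaussian noise,
optional isolated ±10·noise-sd spikes, and a configurable observation
cadence (1 s, or ~3 s to exercise forward-fill padding). Defaults are the
measured neutral levels and neutral→smiling deltas of an expressive adult
face (h9 0.8199 +0.0715, a1 0.4270 −0.0289, a3 0.0901 −0.0398, a4 1.0431
−0.0614), noise sd 0.005 (about a tenth of the smallest delta), and three
3-minute episodes in a 20-minute session — the minute-scale episodic regime
of real sessions. Episode duration matters to the method itself: after an
onset the discounted variance needs roughly `4/r ≈ 160 s` to decay, so
offsets of much shorter episodes are intrinsically hard to detect.
`expression_gain` scales all deltas at once; values well below 1 emulate
the attenuated micro-expression regime of subjects with reduced facial
mobility.

What the generator does **not** model: baseline drift and incidental
non-emotional facial movement (talking, blinking bursts), per-subject noise
heterogeneity, annotation jitter in event times, and any correlation
between feature noises. A green end-to-end test therefore establishes that
the pipeline recovers clean, well-separated episodes — not performance on
real footage, where incidental movement lowers precision and attenuated
expressions lower recall.

## Known limitations

- Single composite target: only the Smile scale ships; other emotions need
  their own composites.
- The detector is univariate; features are combined before scoring, never
  modelled jointly.
- γ = μ_S + σ_S is a convention: score distributions are heavy-tailed, so
  σ_S is dominated by the largest excursions and the threshold rises with
  them. Users with different inspection budgets should set the threshold
  policy accordingly.
- Recall is asymmetric between onsets and offsets when episodes are shorter
  than the variance-recovery time (see above).
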