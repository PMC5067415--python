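# Methods

## Model

The package treats perception as prediction over multi-viewpoint symbol
streams with onset times. Three learned objects interact:

1. **Transition models.** Per viewpoint and hierarchy level, exact n-gram
   counts (default order 1) with add-k smoothing (default k = 1) over the
   declared alphabet and back-off to shorter contexts for unseen ones.
   Streams are never concatenated: no transition crosses a stream
   boundary. All information measures are base-2 (bits). Smoothing k = 1
   was chosen so that unseen-but-possible events carry finite surprisal,
   which deviant (oddball) detection requires; k = 0 recovers raw
   relative frequencies for analyses that need them.

2. **Chunking.** The online boundary rule is a rise in information
   content: a boundary falls before the current symbol iff
   IC(curr) − IC(prev) > θ, with θ = 0 by default, the prediction context
   being the growing buffer (empty after a flush, so the first in-chunk
   symbol is scored against shorter contexts). A peak rule would need
   lookahead; the rise rule is the simplest online reading of
   "increase in uncertainty". `max_len` (default 16) bounds buffers on
   pathological streams. Chunk labelling is exact-match identity in
   first-encounter order, so rebuilding from the same input is
   deterministic and relabelling is isomorphic. Similarity-based
   consolidation of chunk categories is a known omission (see
   Limitations). Per level the model is trained in batch on the fully
   chunked level below, for determinism; a fully incremental mode is
   future work.

3. **Temporal models.** Per transition (context → symbol), a histogram of
   the inter-onset interval on a fixed grid of 20 ms bins (the
   approximate lower bound at which listeners can order two onsets;
   quantum configurable). Histograms, not parametric densities, are the
   simplest representation faithful to observed experience; optional
   Gaussian kernel smoothing (bandwidth 1 bin) and a uniform ε floor are
   available. IOIs beyond the horizon (default 4000 ms) clamp to the last
   bin. An unseen transition with smoothing yields a uniform density
   (maximal temporal uncertainty); without smoothing it is an error.

## Instantaneous distributions and the expectation profile

The distribution over the alphabet at time t since the last event is the
product P(s | c) · f₍c,s₎(bin(t)), renormalized; if every product is zero
the Markov distribution is returned unchanged. The product-then-
renormalize fusion is this package's choice: the construction is only
shown graphically in the literature it models, with an explicit warning
that the illustrated superposition is not a combined distribution, so the
functional form was genuinely open.

Each hierarchy level's *onset expectation* is obtained by propagating the
level's Markov renewal process forward from an anchor context with a
dynamic program over (context, time-bin) states, using raw relative
frequencies and raw normalized histograms (only experienced continuations
propagate; zero-delay mass is dropped). For a level with deterministic
period P this yields unit mass at every multiple of P, so two levels with
periods 2 and 4 quanta superpose to strengths 2 / 1 / 0 at multiples of
4 / other even / odd bins — the additive-cycle picture. The combined
profile is the unweighted per-level sum; strengths are probability mass
per bin per level and hence comparable across levels. Per-level weights
are exposed but default to 1; whether per-level normalization before
summation would be preferable is undecidable from first principles and
left as configuration.

A single anchor context reflects one training run's idiosyncrasies, so
the metrical profile is the average over many downbeat anchors (both bar
positions and streams) and, in `meter_expectation_profile`, over 12
independently generated exposure corpora. An alternative construction —
accumulating each level's one-step next-event density along the realized
stream — was analysed and rejected: conditioning on the *realized* last
event selects against strong positions (they are usually reached after a
filled gap) and provably flattens the profile.

Loud rests are bins whose combined strength reaches a threshold yet
contain no onset. The default threshold is the median combined strength
over onset-containing bins: a loud rest is a beat expected at least as
strongly as a typical realized event. Bins after the last onset are never
flagged (expectation there free-runs; the rhythm has ended). The detector
works on grid-quantized onsets relative to the profile origin and is
therefore invariant under global time translation.

## Entrainment

The tapper takes a period from its source (an expectation profile's first
qualifying local maximum, an explicit period, or the first observed IOI),
observes two onsets, then predicts each subsequent onset and corrects its
phase by gain · (observed − predicted). With a correct period the phase
error satisfies e₍k₊₁₎ = (1 − gain) e₍k₎ exactly, which is the test
oracle; gain 0 disables correction and the tapper drifts with any tempo
change. Emitting taps at the profile's dominant period is a deliberate
simplification of "tap at each predicted local maximum of combined
expectation": it preserves the phase-correction dynamics under study
while keeping the update rule in closed form. Tap times must be strictly
increasing; ties in maximum selection break toward the earliest time.

The "jolt" analysis scores each event by the joint surprisal
−log₂ P(s | c) − log₂ f₍c,s₎(τ) with an ε = 10⁻⁴ floor per bin, so a
transition whose timing was never observed produces a large but finite
spike. A 4/4-enculturated model hearing 7/8 spikes at bar crossings
(e.g. the downbeat arriving three eighths after the mid-bar class, an
interval that cannot occur in 4/4) several baseline standard deviations
above its surprisal on held-out 4/4.

## Synthetic corpora: what they emulate and what they do not

**Metrical rhythm corpora** place onsets on the grid of a metrical
template (4/4 as three binary subdivisions of the bar; 7/8 as one
additive 2+2+3 grouping) with per-strength probabilities, default
(1.0, 0.9, 0.8, 0.6) from downbeat to offbeat eighths — the regularity
that makes meter statistically learnable. Events carry two viewpoints:
an IOI class (the intervallic code for time) and an accent class (the
metrical level of the position, as performed dynamics or notated accents
would convey it); the hierarchy is built over accents. The basic unit is
240 ms per eighth (125 bpm quarter), a realistic rock tempo that keeps
all onsets exactly on the 20 ms grid.

Two placement modes exist. Under independent Bernoulli placement
(default) the marginal frequency of each position equals its rank
probability exactly — but positions are then conditionally independent,
so the corpus carries *no* bar-phase information beyond those marginal
gaps, and no sequence learner can robustly distinguish downbeat from
mid-bar from it. Real music is not like that: new content enters at
strong positions (a new groove at the bar, a response figure at the
half-bar). The `grammar` mode models exactly this with a small
call-and-response vocabulary (6 calls × 2 responses by default, each
half-bar pattern sampled once from the same per-rank probabilities,
downbeats always articulated in calls). The information-content rise rule
then finds quarters, halves and bars because that is where uncertainty
genuinely sits, and the learned profile shows the canonical strength
ordering. Enculturation experiments use the grammar mode; the mode is a
study-condition choice documented here, not a tuned parameter.

**Segmentation streams** concatenate uniform-random words from a
disjoint-alphabet lexicon (4 words × 3 symbols, 300 tokens by default),
so within-word transition probability is 1 and between-word probability
1/4; true word joins are returned for scoring. **Performance sets** draw
per-onset deviations from one of three processes: +15 ms on backbeats
with 3 ms jitter (groove), zero-mean 25 ms jitter (inconsistent error),
or a linearly growing accelerando offset (tempo change). **Genre
exemplars** perturb a template's level periods with 10 ms timing noise
and re-estimate the ratio coordinates, which is what a listener could
recover from a jittered performance.

What passing on these corpora does *not* show: real music has expressive
timing, tempo drift, polyphony, and content viewpoints (pitch, harmony)
that both complicate and aid meter finding; real speech segmentation
contends with coarticulation and non-uniform word frequencies. The
synthetic results demonstrate the mechanisms under their stated
statistical assumptions, not performance on natural corpora.

## Meter space

Only the periodic-component space is built: coordinates are the
subdivision ratios, grouped (additive) levels contribute their normalized
group-length vector on a domain of their own, and tempo (basic unit in
ms) is an optional dimension removed by projection. The concrete
dimension set is this package's proposal — the formalizations it stands
in for live in cited prior work and are not reproduced. Distance is
Euclidean within a dimension domain (integral dimensions) and city-block
across domains (separable dimensions); optional per-dimension scaling
models salience shifts and is off by default. Nearest-neighbour
classification breaks distance ties by label order then training index,
for determinism.

Timing diagnosis thresholds: offset_min = 8 ms, disp_max = 15 ms,
trend_min = 0.8 (Spearman ρ of per-performance mean |deviation| against
performance index). The qualitative signatures (tight displaced point /
cloud / monotone trajectory) are from the literature; the numeric cut
points are this package's defaults, all configurable. The trend test is
applied first because an accelerando also inflates dispersion. A tight,
on-time family falls into `inconsistent_error` for want of a fourth
label.

## Numerical and procedural choices

- Time bins are half-open [t, t + 20 ms); onsets quantize by floor.
  Serialized times are integer ms.
- Distributions validate to ∑p = 1 within 1e-9; histogram densities
  likewise.
- The renewal DP prunes states below 1e-9 mass and drops same-bin
  transitions to guarantee progress.
- One global seed is expanded into independent per-stage substreams by
  hashing the stage name (blake2b, 4 bytes, < 2³¹), so stages can be
  re-run independently and identical configurations give identical
  outputs bit for bit.
- Problem sizes used by the validation runs (chosen as study conditions):
  100 random streams for the counting oracle; 300 word tokens for
  segmentation; 20 corpora for reconstruction; 500 events for renewal
  recovery; 12 exposure corpora × 150 bars × 4 streams for the 4/4
  profile (8 corpora for 7/8); 150 fixtures for timing diagnosis; 160
  exemplars for genre classification.

## Known limitations

- Exact-match chunk labelling only; similarity-based consolidation (and
  with it the efficiency pressure toward balanced trees) is not
  implemented, which is why bar-level structure must be present in the
  data rather than imposed by representation optimization.
- Single best reading per stream: no lattice over alternative
  perceptions, hence no competition among parallel readings in the flush
  criterion (the rise rule is its single-reading reduction).
- Viewpoints are modelled independently and couple only through shared
  chunk boundaries; no cross-viewpoint fusion formula is attempted.
- The entrainment simulator is a phase-correction model on top of the
  learned profile, not a neural oscillator; the oscillator-vs-timer
  debate is deliberately abstracted away.
- MIDI import is not provided; inputs are JSONL onset lists and the
  package's own generators.
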