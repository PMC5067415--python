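"""Synthetic corpus generators with the statistical structure the model
assumes, plus run configuration and seed management.

Three families of inputs are produced:

* metrical rhythm corpora — onsets on a metrical grid, placed by
  per-strength Bernoulli probabilities that decrease strictly from the
  downbeat to the weakest subdivision, mirroring the regularity that makes
  meter learnable from exposure. Each event carries two viewpoints: an
  IOI class (quantized inter-onset interval, the intervallic code for
  time) and an accent class (the metrical level of the event's position,
  as performed dynamics/notated accents would convey it).
* segmentation streams — uniform-random concatenations of a small
  artificial word lexicon, with the true word joins returned for scoring.
* performance sets — per-onset timing deviations drawn from a groove
  (constant offset + small jitter), inconsistent-error (zero-mean large
  jitter) or tempo-change (linearly growing offset) process, and noisy
  meter-space exemplars for nearest-neighbour genre classification.

Every generator takes a mandatory seed; one global seed can be expanded
into independent per-stage substreams by name so stages can be re-run
independently.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .meterspace import MeterPoint, MetricalStructure, PerformancePoint
from .sequence import Event, Symbol

__all__ = [
    "RunConfig",
    "stage_seed",
    "MeterCorpus",
    "gen_meter_corpus",
    "SegmentationCorpus",
    "gen_segmentation_corpus",
    "gen_performance_set",
    "gen_genre_corpus",
    "gen_renewal_stream",
    "iso_onsets",
    "rock_pattern_onsets",
    "METER_44",
    "METER_78",
]

#: 4/4 down to eighth notes (three binary subdivision levels).
METER_44 = MetricalStructure(levels=(2, 2, 2))
#: 7/8 as one additive 2+2+3 grouping of eighths.
METER_78 = MetricalStructure(levels=((2, 2, 3),))


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage substream seed (< 2**31) from a global seed."""
    h = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a full pipeline run.

    Identical configs give identical outputs: every stochastic stage reads
    its seed from ``substream``.
    """

    order: int = 1
    smoothing_k: float = 1.0
    theta: float = 0.0
    max_depth: int = 3
    max_alphabet: int = 256
    max_chunk_len: int = 16
    quantum_ms: int = 20
    horizon_ms: int = 4000
    gain: float = 0.5
    offset_min_ms: float = 8.0
    disp_max_ms: float = 15.0
    trend_min: float = 0.8
    seed: int = 0

    def substream(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


# ---------------------------------------------------------------------------
# Metrical rhythm corpora
# ---------------------------------------------------------------------------


@dataclass
class MeterCorpus:
    """Generated metrical event streams plus their ground truth."""

    streams: list[list[Event]]
    template: MetricalStructure
    unit_ms: int
    onset_probs: tuple[float, ...]
    strengths: list[int] = field(repr=False, default_factory=list)

    @property
    def bar_ms(self) -> int:
        return self.unit_ms * self.template.units_per_cycle

    def viewpoint_streams(
        self, viewpoint: str
    ) -> list[tuple[list[Symbol], list[int]]]:
        return [
            ([e.values[viewpoint] for e in ev], [e.onset_ms for e in ev])
            for ev in self.streams
        ]

    def bar_starts_ms(self, stream_index: int = 0) -> list[int]:
        last = self.streams[stream_index][-1].onset_ms
        return list(range(0, last + 1, self.bar_ms))


def accent_rank(strength: int, max_strength: int) -> int:
    """Rank from the top of the metrical hierarchy: 0 = downbeat."""
    return max_strength - strength


def gen_meter_corpus(
    template: MetricalStructure,
    onset_probs: Sequence[float],
    n_bars: int,
    n_streams: int = 1,
    unit_ms: int = 240,
    seed: int = 0,
    structure: str = "bernoulli",
    n_calls: int = 6,
    n_responses: int = 2,
    ioi_cap_units: int = 8,
) -> MeterCorpus:
    """Place onsets on the metrical grid with per-strength probabilities.

    ``onset_probs[r]`` is the onset probability for positions of accent
    rank r (0 = downbeat); probabilities must lie in [0, 1] and decrease
    strictly with decreasing metrical strength. Events carry an ``accent``
    viewpoint (symbol ``acc{r}``) and an ``ioi`` viewpoint (symbol ``i{k}``
    for an IOI of k grid units, capped; the first event of a stream gets
    ``i0``).

    ``structure`` selects how onsets are placed:

    * ``"bernoulli"`` — positions filled independently at their rank
      probability; the marginal frequency per position equals the rank
      probability exactly.
    * ``"grammar"`` — bars are drawn i.i.d. from a small call-and-response
      vocabulary: ``n_calls`` first-half patterns, each paired with
      ``n_responses`` second-half patterns, every half sampled once from
      the same per-rank probabilities (downbeats always articulated in
      calls). Positions keep their rank-dependent onset rates, but new
      content now enters at bar and half-bar boundaries, the within-bar
      dependence that real music has and that independent placement
      provably lacks. Requires an even cycle.
    """
    if n_bars < 1:
        raise ValueError("n_bars must be >= 1")
    if structure not in {"bernoulli", "grammar"}:
        raise ValueError(f"unknown structure {structure!r}")
    strengths = template.position_strengths()
    max_strength = max(strengths)
    n_ranks = len(set(strengths))
    probs = tuple(float(p) for p in onset_probs)
    if len(probs) != n_ranks:
        raise ValueError(
            f"need one probability per accent rank ({n_ranks}), got {len(probs)}"
        )
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError("onset probabilities must lie in [0, 1]")
    if any(b >= a for a, b in zip(probs, probs[1:])):
        raise ValueError(
            "onset probabilities must decrease strictly with metrical weakness"
        )
    rng = np.random.default_rng(seed)
    units = template.units_per_cycle

    def sample_span(lo: int, hi: int, force_first: bool) -> tuple[int, ...]:
        out = []
        for p in range(lo, hi):
            rank = accent_rank(strengths[p], max_strength)
            if (force_first and p == lo) or rng.random() < probs[rank]:
                out.append(p)
        return tuple(out)

    if structure == "grammar":
        # split the cycle at its strongest interior position (for 4/4 the
        # mid-bar, for 2+2+3 the start of the final group)
        interior = [
            p
            for p in range(1, units)
            if accent_rank(strengths[p], max_strength) == 1
        ]
        half = interior[-1] if interior else units // 2
        calls: list[tuple[int, ...]] = []
        tries = 0
        while len(calls) < n_calls and tries < 10_000:
            tries += 1
            c = sample_span(0, half, force_first=True)
            if c not in calls:
                calls.append(c)
        responses: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
        for c in calls:
            rs: list[tuple[int, ...]] = []
            tries = 0
            while len(rs) < n_responses and tries < 10_000:
                tries += 1
                r = sample_span(half, units, force_first=False)
                if r not in rs:
                    rs.append(r)
            responses[c] = rs
        if len(calls) < 2:
            warnings.warn("degenerate grammar vocabulary: fewer than 2 calls")

    streams: list[list[Event]] = []
    for _ in range(n_streams):
        events: list[Event] = []
        prev_pos: int | None = None
        for bar in range(n_bars):
            if structure == "bernoulli":
                pattern = sample_span(0, units, force_first=False)
            else:
                c = calls[rng.integers(len(calls))]
                rs = responses[c]
                pattern = c + rs[rng.integers(len(rs))]
            for p in pattern:
                rank = accent_rank(strengths[p], max_strength)
                pos = bar * units + p
                ioi_units = 0 if prev_pos is None else min(
                    pos - prev_pos, ioi_cap_units
                )
                events.append(
                    Event(
                        values={
                            "accent": Symbol(f"acc{rank}", 0, "accent"),
                            "ioi": Symbol(f"i{ioi_units}", 0, "ioi"),
                        },
                        onset_ms=pos * unit_ms,
                    )
                )
                prev_pos = pos
        streams.append(events)
    return MeterCorpus(
        streams=streams,
        template=template,
        unit_ms=unit_ms,
        onset_probs=probs,
        strengths=strengths,
    )


def iso_onsets(period_ms: int, n: int, start_ms: int = 0) -> list[int]:
    """Isochronous onset train."""
    return [start_ms + i * period_ms for i in range(n)]


def rock_pattern_onsets(unit_ms: int = 240, n_cycles: int = 1) -> list[int]:
    """A two-measure rock rhythm on the eighth grid of 4/4.

    Measure 1 anticipates the third beat (onset on the eighth before it)
    and leaves the strongly expected mid-bar position empty — the loud
    rest; measure 2 realizes all four beats.
    """
    bar1 = [0, 2, 3, 6]
    bar2 = [0, 2, 4, 6]
    out = []
    for c in range(n_cycles):
        base = c * 16
        out.extend(base + p for p in bar1)
        out.extend(base + 8 + p for p in bar2)
    return [p * unit_ms for p in out]


# ---------------------------------------------------------------------------
# Segmentation streams
# ---------------------------------------------------------------------------


@dataclass
class SegmentationCorpus:
    stream: list[Symbol]
    boundaries: list[int]  # indices where a word starts, excluding 0
    lexicon: list[tuple[Symbol, ...]]


def gen_segmentation_corpus(
    lexicon_size: int = 4,
    word_len: int = 3,
    n_tokens: int = 300,
    seed: int = 0,
    viewpoint: str = "phoneme",
) -> SegmentationCorpus:
    """Concatenate uniform-random words from an artificial lexicon.

    Words are built over disjoint symbol sets, so within-word transitions
    are deterministic and between-word transitions uniform at
    1/lexicon_size. The true word-join indices are returned for scoring.
    """
    if lexicon_size < 2:
        raise ValueError("lexicon_size must be >= 2")
    if word_len < 2:
        raise ValueError("word_len must be >= 2")
    alphabet = [
        Symbol(f"p{i}", 0, viewpoint) for i in range(lexicon_size * word_len)
    ]
    lexicon = [
        tuple(alphabet[w * word_len : (w + 1) * word_len])
        for w in range(lexicon_size)
    ]
    firsts = [w[0] for w in lexicon]
    if len(set(firsts)) < len(firsts) or len(set(lexicon)) < len(lexicon):
        warnings.warn(
            "lexicon words share prefixes; word joins may be undetectable"
        )
    rng = np.random.default_rng(seed)
    stream: list[Symbol] = []
    boundaries: list[int] = []
    for t in range(n_tokens):
        if t > 0:
            boundaries.append(len(stream))
        stream.extend(lexicon[rng.integers(lexicon_size)])
    return SegmentationCorpus(stream=stream, boundaries=boundaries, lexicon=lexicon)


# ---------------------------------------------------------------------------
# Performance sets and meter-space exemplars
# ---------------------------------------------------------------------------


def gen_performance_set(
    kind: str,
    n_performances: int = 10,
    n_onsets: int = 16,
    seed: int = 0,
    offset_ms: float = 15.0,
    jitter_ms: float = 3.0,
    sigma_ms: float = 25.0,
    drift_ms: float = 30.0,
) -> list[PerformancePoint]:
    """Draw timing-deviation families with a known diagnosis label.

    groove: ``offset_ms`` added on the backbeats (every fourth onset,
    starting at the second beat) plus N(0, jitter) everywhere.
    inconsistent_error: N(0, sigma) at every onset.
    tempo_change: an accelerando — deviations grow linearly to
    ``-drift_ms * (i + 1) / n`` by the end of performance i, plus jitter,
    so deviation magnitude increases monotonically with position.
    """
    if kind not in {"groove", "inconsistent_error", "tempo_change"}:
        raise ValueError(f"unknown performance kind {kind!r}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_performances):
        if kind == "groove":
            dev = rng.normal(0.0, jitter_ms, n_onsets)
            dev[2::4] += offset_ms
        elif kind == "inconsistent_error":
            dev = rng.normal(0.0, sigma_ms, n_onsets)
        else:
            ramp = np.linspace(0.0, 1.0, n_onsets)
            dev = -drift_ms * (i + 1) / n_performances * ramp
            dev += rng.normal(0.0, jitter_ms, n_onsets)
        out.append(PerformancePoint(deviations=tuple(dev), index=i))
    return out


GENRE_TEMPLATES: dict[str, tuple[int, int]] = {
    "four_four": (2, 2),
    "three_four": (3, 2),
    "six_eight": (2, 3),
    "nine_eight": (3, 3),
}


def gen_genre_corpus(
    n_each: int = 40,
    sigma_ms: float = 10.0,
    seed: int = 0,
    unit_range_ms: tuple[int, int] = (180, 320),
    templates: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[list[MeterPoint], list[str]]:
    """Noisy meter-space exemplars of two-level meter templates.

    Each exemplar draws a tempo (basic unit) uniformly, perturbs the three
    level periods (cycle, beat, unit) with N(0, sigma) timing noise, and
    re-estimates the subdivision ratios from the noisy periods — the
    coordinates a listener could recover from a jittered performance. The
    tempo dimension carries the noisy unit; project it out to abstract
    tempo.
    """
    if templates is None:
        templates = GENRE_TEMPLATES
    rng = np.random.default_rng(seed)
    points: list[MeterPoint] = []
    labels: list[str] = []
    for name, (r0, r1) in templates.items():
        for _ in range(n_each):
            unit = rng.uniform(*unit_range_ms)
            beat = unit * r1
            cycle = beat * r0
            unit_h = unit + rng.normal(0.0, sigma_ms)
            beat_h = beat + rng.normal(0.0, sigma_ms)
            cycle_h = cycle + rng.normal(0.0, sigma_ms)
            points.append(
                MeterPoint(
                    coords=(cycle_h / beat_h, beat_h / unit_h, unit_h),
                    dims=("ratio0", "ratio1", "unit_ms"),
                    domains=("periodicity", "periodicity", "tempo"),
                )
            )
            labels.append(name)
    return points, labels


# ---------------------------------------------------------------------------
# Known Markov renewal process (for recovery checks)
# ---------------------------------------------------------------------------


def gen_renewal_stream(
    n_events: int = 500,
    seed: int = 0,
    viewpoint: str = "s",
) -> tuple[list[Symbol], list[int], dict]:
    """Simulate a small Markov renewal process with known parameters.

    Two symbols; each transition has its own discrete IOI distribution on
    the 20 ms grid. Returns (symbols, onsets, truth) where ``truth`` holds
    the transition matrix and the exact binned IOI pmfs for scoring a
    learned model against the generator.
    """
    x = Symbol("x", 0, viewpoint)
    y = Symbol("y", 0, viewpoint)
    trans = {x: {x: 0.3, y: 0.7}, y: {x: 0.6, y: 0.4}}
    iois: dict[tuple[Symbol, Symbol], dict[int, float]] = {
        (x, x): {300: 0.6, 320: 0.4},
        (x, y): {400: 0.5, 420: 0.3, 440: 0.2},
        (y, x): {500: 0.7, 520: 0.2, 540: 0.1},
        (y, y): {340: 0.3, 360: 0.7},
    }
    rng = np.random.default_rng(seed)
    symbols = [x]
    onsets = [0]
    cur = x
    for _ in range(n_events - 1):
        nxts, ps = zip(*trans[cur].items())
        nxt = nxts[int(rng.choice(len(nxts), p=ps))]
        ts, tps = zip(*iois[(cur, nxt)].items())
        ioi = int(ts[int(rng.choice(len(ts), p=tps))])
        onsets.append(onsets[-1] + ioi)
        symbols.append(nxt)
        cur = nxt
    truth = {"transitions": trans, "iois": iois}
    return symbols, onsets, truth
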