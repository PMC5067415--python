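"""Temporal prediction: learning *when* the next symbol will occur.

Alongside the transition model's "what", each observed transition
(context -> symbol) accumulates a histogram over the inter-onset interval
(IOI) separating the context's last event from the symbol's event, on a
20 ms grid — the finest resolution at which listeners can order two
onsets. The pair of models forms a Markov renewal process: a Markov chain
whose transitions carry holding-time distributions.

From a trained pair of models this module derives:

* instantaneous distributions over the alphabet at a given time since the
  last event (the what x when product, renormalized);
* per-level onset-expectation profiles, obtained by propagating the Markov
  renewal process forward from an anchor context and summing the resulting
  event mass per time bin across hierarchy levels (the additive-cycle view
  of metrical strength: positions predicted by more levels are stronger);
* loud-rest detection (strongly expected beats with no event);
* a simple entrainment (tapping) simulator with proportional phase
  correction, and a joint what x when surprisal trace for jolt detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import StreamError
from .sequence import Distribution, Symbol, TransitionModel, predict_next

log = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "TemporalDistribution",
    "TemporalModel",
    "ExpectationProfile",
    "TapRecord",
    "observe_timing",
    "temporal_distribution",
    "instantaneous_distribution",
    "renewal_onset_mass",
    "expectation_profile",
    "averaged_expectation_profile",
    "detect_loud_rests",
    "profile_period",
    "entrain",
    "surprisal_trace",
]


@dataclass(frozen=True)
class TimeGrid:
    """Half-open time bins ``[t, t + quantum_ms)`` up to ``horizon_ms``."""

    quantum_ms: int = 20
    horizon_ms: int = 4000

    def __post_init__(self) -> None:
        if self.quantum_ms < 1:
            raise ValueError("quantum_ms must be >= 1")
        if self.horizon_ms < self.quantum_ms:
            raise ValueError("horizon_ms must cover at least one bin")

    @property
    def n_bins(self) -> int:
        return self.horizon_ms // self.quantum_ms

    def bin_of(self, t_ms: float) -> int:
        """Bin index of a time; times past the horizon clamp to the last bin."""
        if t_ms < 0:
            raise ValueError(f"time must be >= 0, got {t_ms}")
        return min(int(t_ms // self.quantum_ms), self.n_bins - 1)

    def bin_start(self, i: int) -> int:
        return i * self.quantum_ms


@dataclass
class TemporalDistribution:
    """Probability mass over IOI bins for one (context, symbol) transition."""

    context: tuple[Symbol, ...]
    symbol: Symbol
    density: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.shape != (self.grid.n_bins,):
            raise ValueError("density must have one value per grid bin")
        if (d < 0).any():
            raise ValueError("density must be non-negative")
        if abs(d.sum() - 1.0) > 1e-9:
            raise ValueError(f"density sums to {d.sum()}, not 1")
        self.density = d

    @property
    def mode_bin(self) -> int:
        return int(np.argmax(self.density))

    @property
    def mode_ms(self) -> int:
        return self.grid.bin_start(self.mode_bin)


class TemporalModel:
    """IOI histograms per (context, symbol) at one hierarchy level."""

    def __init__(self, grid: TimeGrid, order: int = 1, level: int = 0):
        self.grid = grid
        self.order = order
        self.level = level
        self.counts: dict[tuple[tuple[Symbol, ...], Symbol], np.ndarray] = {}
        self.n_observations = 0

    def observe(
        self, context: tuple[Symbol, ...], symbol: Symbol, ioi_ms: int
    ) -> None:
        if ioi_ms < 0:
            raise StreamError(f"negative IOI {ioi_ms} for {symbol!r}")
        key = (tuple(context)[-self.order :], symbol)
        if key not in self.counts:
            self.counts[key] = np.zeros(self.grid.n_bins)
        self.counts[key][self.grid.bin_of(ioi_ms)] += 1
        self.n_observations += 1

    def lookup(
        self, context: tuple[Symbol, ...], symbol: Symbol
    ) -> np.ndarray | None:
        """Raw bin counts, backing off to the longest recorded context suffix."""
        ctx = tuple(context)[-self.order :]
        for start in range(len(ctx) + 1):
            key = (ctx[start:], symbol)
            if key in self.counts:
                return self.counts[key]
        return None


def observe_timing(
    transition_model: TransitionModel,
    timed_streams: Sequence[tuple[Sequence[Symbol], Sequence[int]]],
    grid: TimeGrid | None = None,
) -> TemporalModel:
    """Build a TemporalModel from (symbols, onsets) streams.

    For each transition the IOI between the context's last event and the
    observed event is binned on the grid. Onsets must be non-decreasing.
    """
    if grid is None:
        grid = TimeGrid()
    tm = TemporalModel(
        grid=grid, order=transition_model.order, level=transition_model.level
    )
    for symbols, onsets in timed_streams:
        symbols = list(symbols)
        onsets = list(onsets)
        if len(symbols) != len(onsets):
            raise StreamError("symbols and onsets differ in length")
        for i in range(1, len(symbols)):
            ioi = onsets[i] - onsets[i - 1]
            if ioi < 0:
                raise StreamError(
                    f"onsets decrease at index {i}: {onsets[i - 1]} -> {onsets[i]}"
                )
            ctx = tuple(symbols[max(0, i - tm.order) : i])
            tm.observe(ctx, symbols[i], ioi)
    return tm


def temporal_distribution(
    tm: TemporalModel,
    context: Sequence[Symbol],
    symbol: Symbol,
    epsilon: float = 0.0,
    kernel_bw_bins: float = 0.0,
) -> TemporalDistribution:
    """Normalized IOI density for one transition.

    ``epsilon`` adds a uniform floor per bin (smoothing); an unseen
    (context, symbol) pair yields a uniform density when smoothing is on
    and raises otherwise. ``kernel_bw_bins`` optionally applies Gaussian
    kernel smoothing with the given bandwidth in bins.
    """
    counts = tm.lookup(tuple(context), symbol)
    n = tm.grid.n_bins
    if counts is None or counts.sum() == 0:
        if epsilon > 0:
            return TemporalDistribution(
                tuple(context), symbol, np.full(n, 1.0 / n), tm.grid
            )
        raise KeyError(
            f"no timing observed for context {tuple(context)!r} -> {symbol!r}; "
            "pass epsilon > 0 to smooth"
        )
    dens = counts / counts.sum()
    if kernel_bw_bins > 0:
        from scipy.ndimage import gaussian_filter1d

        dens = gaussian_filter1d(dens, sigma=kernel_bw_bins, mode="constant")
        dens = dens / dens.sum()
    if epsilon > 0:
        dens = (dens + epsilon) / (1.0 + epsilon * n)
    return TemporalDistribution(tuple(context), symbol, dens, tm.grid)


def instantaneous_distribution(
    tm: TemporalModel,
    what_model: TransitionModel,
    context: Sequence[Symbol],
    t_ms: float,
    epsilon: float = 1e-6,
) -> Distribution:
    """Distribution over the alphabet at time ``t_ms`` since the last event.

    Each symbol's Markov probability is weighted by its temporal density at
    the bin containing ``t_ms`` and the result renormalized; if every
    product is zero the time carries no evidence and the Markov
    distribution is returned unchanged (logged).
    """
    if t_ms < 0:
        raise ValueError("t_ms must be >= 0")
    what = predict_next(what_model, tuple(context))
    b = tm.grid.bin_of(t_ms)
    weighted = {}
    for s, p in what.items():
        td = temporal_distribution(tm, context, s, epsilon=epsilon)
        weighted[s] = p * td.density[b]
    total = sum(weighted.values())
    if total <= 0:
        log.info("no temporal evidence at t=%s ms; falling back to Markov", t_ms)
        return what
    return Distribution({s: w / total for s, w in weighted.items()})


# ---------------------------------------------------------------------------
# Markov renewal propagation and expectation profiles
# ---------------------------------------------------------------------------


def renewal_onset_mass(
    what_model: TransitionModel,
    tm: TemporalModel,
    anchor_context: Sequence[Symbol],
    n_bins: int,
    mass_floor: float = 1e-9,
) -> np.ndarray:
    """Expected event mass per bin from propagating the learned renewal
    process forward from ``anchor_context`` (last event at bin 0).

    ``out[t]`` is the probability that this level emits an event in bin
    ``t``; with a deterministic period P it is 1 at every multiple of P and
    0 elsewhere. Transition weights use raw relative frequencies (only
    experienced continuations propagate) and holding times use the raw
    normalized IOI histograms. Same-bin (zero-delay) mass is dropped.
    """
    order = what_model.order
    anchor = tuple(anchor_context)[-order:]
    onset = np.zeros(n_bins)
    # state -> mass of "last event in bin t with this context"
    mass: dict[tuple[Symbol, ...], np.ndarray] = {
        anchor: np.zeros(n_bins)
    }
    mass[anchor][0] = 1.0

    def resolve(ctx: tuple[Symbol, ...]) -> tuple[Symbol, ...] | None:
        for start in range(len(ctx) + 1):
            sub = ctx[start:]
            if sub in what_model.counts and what_model.context_total(sub) > 0:
                return sub
        return None

    for t in range(n_bins):
        for ctx in list(mass):
            m = mass[ctx][t]
            if m < mass_floor:
                continue
            seen = resolve(ctx)
            if seen is None:
                continue
            ctr = what_model.counts[seen]
            total = sum(ctr.values())
            for s, cnt in ctr.items():
                dens_counts = tm.lookup(seen, s)
                if dens_counts is None or dens_counts.sum() == 0:
                    continue
                dens = dens_counts / dens_counts.sum()
                w = m * cnt / total
                span = n_bins - t - 1
                if span <= 0:
                    continue
                contrib = w * dens[1 : span + 1]
                nxt = (ctx + (s,))[-order:]
                if nxt not in mass:
                    mass[nxt] = np.zeros(n_bins)
                mass[nxt][t + 1 : t + 1 + len(contrib)] += contrib
                onset[t + 1 : t + 1 + len(contrib)] += contrib
    return onset


@dataclass
class ExpectationProfile:
    """Per-level and combined onset-expectation strength per time bin.

    Strength is probability mass per bin per level, so levels are
    directly comparable; the combined profile is exactly the per-level sum
    (optionally weighted).
    """

    grid: TimeGrid
    per_level: dict[int, np.ndarray] = field(default_factory=dict)
    weights: dict[int, float] | None = None

    @property
    def n_bins(self) -> int:
        return next(iter(self.per_level.values())).shape[0]

    @property
    def combined(self) -> np.ndarray:
        out = None
        for lvl, arr in self.per_level.items():
            w = 1.0 if self.weights is None else self.weights.get(lvl, 1.0)
            out = w * arr if out is None else out + w * arr
        if out is None:
            raise ValueError("profile has no levels")
        return out

    def strength_at(self, t_ms: float) -> float:
        return float(self.combined[self.grid.bin_of(t_ms)])


def expectation_profile(
    memory,
    temporal_models: Mapping[int, TemporalModel],
    horizon_ms: int,
    anchor_ms: int,
    stream_index: int = 0,
    quantum_ms: int = 20,
    weights: Mapping[int, float] | None = None,
) -> ExpectationProfile:
    """Combine onset expectations across hierarchy levels after an anchor.

    For each level the context is the level's last event at or before
    ``anchor_ms`` (in the given stream of the memory); its renewal process
    is propagated forward and the resulting mass re-aligned so bin 0 of
    the profile starts at ``anchor_ms``. Levels lacking a temporal model
    are skipped with a warning. The combined strength is the per-level sum.
    """
    grid = TimeGrid(quantum_ms=quantum_ms, horizon_ms=horizon_ms)
    n_bins = grid.n_bins
    per_level: dict[int, np.ndarray] = {}
    for lvl_idx, lvl in enumerate(memory.levels):
        if lvl_idx not in temporal_models:
            log.warning("no temporal model for level %d; skipped", lvl_idx)
            continue
        if lvl.onsets is None:
            log.warning("level %d has no onsets; skipped", lvl_idx)
            continue
        onsets = lvl.onsets[stream_index]
        stream = lvl.streams[stream_index]
        js = [j for j, o in enumerate(onsets) if o <= anchor_ms]
        if not js:
            log.warning("no level-%d event before anchor; skipped", lvl_idx)
            continue
        j = js[-1]
        order = lvl.model.order
        ctx = tuple(stream[max(0, j - order + 1) : j + 1])
        delta_bins = (anchor_ms - onsets[j]) // quantum_ms
        tm = temporal_models[lvl_idx]
        raw = renewal_onset_mass(lvl.model, tm, ctx, n_bins + delta_bins)
        per_level[lvl_idx] = raw[delta_bins : delta_bins + n_bins]
    if not per_level:
        raise ValueError("no level produced an expectation profile")
    return ExpectationProfile(
        grid=grid,
        per_level=per_level,
        weights=dict(weights) if weights is not None else None,
    )


def averaged_expectation_profile(
    memory,
    temporal_models: Mapping[int, TemporalModel],
    horizon_ms: int,
    anchors: Sequence[tuple[int, int]],
    quantum_ms: int = 20,
    weights: Mapping[int, float] | None = None,
) -> ExpectationProfile:
    """Average expectation profiles over many (stream_index, anchor_ms)
    pairs — the expectation at a *generic* anchor (e.g. a generic
    downbeat) rather than one particular context."""
    if not anchors:
        raise ValueError("need at least one anchor")
    acc: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    grid = TimeGrid(quantum_ms=quantum_ms, horizon_ms=horizon_ms)
    for si, a in anchors:
        prof = expectation_profile(
            memory, temporal_models, horizon_ms, a,
            stream_index=si, quantum_ms=quantum_ms,
        )
        for lvl, arr in prof.per_level.items():
            acc[lvl] = acc.get(lvl, 0) + arr
            counts[lvl] = counts.get(lvl, 0) + 1
    per_level = {lvl: acc[lvl] / counts[lvl] for lvl in acc}
    return ExpectationProfile(
        grid=grid,
        per_level=per_level,
        weights=dict(weights) if weights is not None else None,
    )


def detect_loud_rests(
    profile: ExpectationProfile,
    onsets_ms: Sequence[int],
    strength_threshold: float | None = None,
    anchor_ms: int = 0,
) -> list[int]:
    """Bins whose expectation meets the threshold but contain no onset.

    Onsets are quantized onto the profile grid after subtracting
    ``anchor_ms`` (the profile's time origin), making the detector
    invariant under global time translation. With ``strength_threshold``
    None the threshold defaults to the median combined strength over the
    bins that *do* contain onsets: a loud rest is a beat expected at least
    as strongly as a typical realized event. Bin 0 (the anchor event
    itself) and bins after the last onset (where the rhythm has ended and
    expectation merely free-runs) are never flagged.
    """
    combined = profile.combined
    rel = [o - anchor_ms for o in onsets_ms]
    onset_bins = {
        profile.grid.bin_of(o) for o in rel if 0 <= o < profile.grid.horizon_ms
    }
    if not onset_bins:
        raise ValueError("no onsets fall inside the profile horizon")
    if strength_threshold is None:
        strength_threshold = float(
            np.median([combined[b] for b in sorted(onset_bins)])
        )
    elif strength_threshold <= 0:
        raise ValueError("strength_threshold must be > 0")
    last = max(onset_bins)
    return [
        b
        for b in range(1, last + 1)
        if combined[b] >= strength_threshold and b not in onset_bins
    ]


def profile_period(profile: ExpectationProfile, rel_height: float = 0.5) -> int:
    """Dominant period in ms: the first local maximum of the combined
    profile (after bin 0) reaching ``rel_height`` of the global maximum.
    Ties are broken toward the earliest time."""
    c = profile.combined
    thr = rel_height * float(c.max())
    for i in range(1, len(c) - 1):
        if c[i] >= thr and c[i] > c[i - 1] and c[i] >= c[i + 1]:
            return profile.grid.bin_start(i)
    raise ValueError("profile has no qualifying local maximum")


@dataclass
class TapRecord:
    """Taps emitted by the entrainment simulator and their phase errors
    (signed, tap minus nearest stimulus onset)."""

    tap_times_ms: list[float]
    phase_errors_ms: list[float]

    def __post_init__(self) -> None:
        t = self.tap_times_ms
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("tap times must be strictly increasing")


def entrain(
    source: ExpectationProfile | float | None,
    onsets_ms: Sequence[int],
    gain: float,
    initial_phase_ms: float = 0.0,
) -> TapRecord:
    """Tap along with an onset stream, correcting phase by
    ``gain * (observed - predicted)`` after each observed onset.

    ``source`` supplies the tapping period: an ExpectationProfile (its
    dominant inter-maximum period), a number (period in ms), or None (the
    first observed IOI). At least two onsets are observed before the first
    tap, which targets the third onset; ``initial_phase_ms`` models the
    tapper's initial asynchrony. With a correct period the phase error
    contracts by a factor of (1 - gain) per event; with gain 0 it tracks
    any drift uncorrected.
    """
    if not 0.0 <= gain <= 1.0:
        raise ValueError(f"gain must be in [0, 1], got {gain}")
    onsets = list(onsets_ms)
    if len(onsets) < 3:
        raise ValueError("need at least 2 onsets before the first tap")
    if isinstance(source, ExpectationProfile):
        period = float(profile_period(source))
    elif source is None:
        period = float(onsets[1] - onsets[0])
    else:
        period = float(source)
    if period <= 0:
        raise ValueError("period must be positive")

    predicted = onsets[1] + period + initial_phase_ms
    taps: list[float] = []
    errors: list[float] = []
    for k in range(2, len(onsets)):
        taps.append(predicted)
        nearest = min(onsets, key=lambda o: abs(o - predicted))
        errors.append(predicted - nearest)
        predicted = predicted + period + gain * (onsets[k] - predicted)
    return TapRecord(tap_times_ms=taps, phase_errors_ms=errors)


def surprisal_trace(
    what_model: TransitionModel,
    tm: TemporalModel,
    symbols: Sequence[Symbol],
    onsets: Sequence[int],
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Joint what x when surprisal (bits) for each event after the first.

    The entry for event i is -log2 P(s_i | context) - log2 f(IOI_i), with
    an epsilon floor per bin so that never-observed timings yield a large
    but finite jolt; a transition never observed at all falls back to a
    uniform temporal density (maximal temporal uncertainty).
    """
    symbols = list(symbols)
    onsets = list(onsets)
    out = np.zeros(len(symbols))
    for i in range(1, len(symbols)):
        ctx = tuple(symbols[max(0, i - what_model.order) : i])
        d = predict_next(what_model, ctx)
        ic_what = -math.log2(max(d.get(symbols[i], 0.0), 1e-12))
        td = temporal_distribution(tm, ctx, symbols[i], epsilon=epsilon)
        b = tm.grid.bin_of(onsets[i] - onsets[i - 1])
        ic_when = -math.log2(max(float(td.density[b]), 1e-12))
        out[i] = ic_what + ic_when
    return out
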