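"""Symbol alphabets, event streams, Markov transition models and
information-theoretic measures.

This is the "what will happen next" half of the architecture: n-gram
transition counts over symbol streams, smoothed predictive distributions
with back-off to shorter contexts, and the surprisal/entropy measures that
drive chunking and deviant detection downstream.

All logarithms are base 2; information is measured in bits.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import EmptyModelError, StreamError

log = logging.getLogger(__name__)

__all__ = [
    "Symbol",
    "Event",
    "Distribution",
    "TransitionModel",
    "train_transitions",
    "predict_next",
    "information_content",
    "entropy",
    "detect_deviants",
]


@dataclass(frozen=True, order=True)
class Symbol:
    """One token of a discrete alphabet.

    ``level`` 0 symbols come from input; level ``k > 0`` symbols label chunks
    of the level ``k - 1`` stream. ``viewpoint`` names the feature stream the
    symbol belongs to (phoneme, accent, IOI class, ...).
    """

    id: str
    level: int = 0
    viewpoint: str = "default"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"symbol level must be >= 0, got {self.level}")

    def __repr__(self) -> str:  # compact: most streams share level/viewpoint
        return f"Symbol({self.id!r}, L{self.level}, {self.viewpoint})"


@dataclass(frozen=True)
class Event:
    """One perceptual token: a symbol per viewpoint plus an onset time.

    Every viewpoint present in a stream must have a value on every event
    (viewpoints are integral dimensions of the percept), and onsets are
    non-decreasing within a stream.
    """

    values: Mapping[str, Symbol]
    onset_ms: int

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError(f"onset_ms must be >= 0, got {self.onset_ms}")
        for vp, sym in self.values.items():
            if sym.viewpoint != vp:
                raise ValueError(
                    f"symbol {sym!r} filed under viewpoint {vp!r}"
                )
            if sym.level != 0:
                raise ValueError("event values must be level-0 symbols")


def viewpoint_stream(events: Sequence[Event], viewpoint: str) -> list[Symbol]:
    """Project an event stream onto one viewpoint."""
    return [e.values[viewpoint] for e in events]


def onsets_of(events: Sequence[Event]) -> list[int]:
    return [e.onset_ms for e in events]


class Distribution:
    """A probability distribution over a finite set of symbols.

    Masses are non-negative and sum to one (checked to 1e-9).
    """

    __slots__ = ("_mass",)

    def __init__(self, mass: Mapping[Symbol, float]):
        if not mass:
            raise ValueError("distribution support must be non-empty")
        total = 0.0
        for s, p in mass.items():
            if p < 0:
                raise ValueError(f"negative mass {p} for {s!r}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total}, not 1")
        self._mass = dict(mass)

    @property
    def support(self) -> frozenset[Symbol]:
        return frozenset(self._mass)

    def mass(self, s: Symbol) -> float:
        return self._mass[s]

    def get(self, s: Symbol, default: float = 0.0) -> float:
        return self._mass.get(s, default)

    def items(self):
        return self._mass.items()

    def argmax(self) -> Symbol:
        return max(sorted(self._mass), key=lambda s: self._mass[s])

    def __len__(self) -> int:
        return len(self._mass)

    def __contains__(self, s: Symbol) -> bool:
        return s in self._mass

    def __repr__(self) -> str:
        body = ", ".join(
            f"{s.id}:{p:.3g}" for s, p in sorted(self._mass.items())
        )
        return f"Distribution({body})"


@dataclass
class TransitionModel:
    """n-gram transition counts at one (viewpoint, level).

    ``counts`` maps context tuples of every length from 0 (the unigram
    context ``()``) up to ``order`` to counters over continuation symbols.
    Prediction smooths with add-k over the observed alphabet and backs off
    to shorter contexts when a context was never seen.
    """

    order: int = 1
    viewpoint: str = "default"
    level: int = 0
    smoothing_k: float = 1.0
    counts: dict[tuple[Symbol, ...], Counter] = field(default_factory=dict)
    alphabet: set[Symbol] = field(default_factory=set)
    n_streams: int = 0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.smoothing_k < 0:
            raise ValueError("smoothing k must be >= 0")

    # -- training -----------------------------------------------------------

    def observe_stream(self, stream: Sequence[Symbol]) -> None:
        """Accumulate transition counts from one stream.

        Streams are never concatenated: no transition crosses a stream
        boundary.
        """
        if len(stream) == 0:
            warnings.warn("empty stream skipped", stacklevel=2)
            return
        for s in stream:
            if s.viewpoint != self.viewpoint or s.level != self.level:
                raise StreamError(
                    f"symbol {s!r} does not match model "
                    f"(viewpoint={self.viewpoint!r}, level={self.level})"
                )
        self.alphabet.update(stream)
        for i, s in enumerate(stream):
            for clen in range(0, self.order + 1):
                if clen > i:
                    break
                ctx = tuple(stream[i - clen : i])
                self.counts.setdefault(ctx, Counter())[s] += 1
        self.n_streams += 1

    # -- queries ------------------------------------------------------------

    def context_total(self, context: tuple[Symbol, ...]) -> int:
        return sum(self.counts.get(context, Counter()).values())

    def conditional(
        self, context: tuple[Symbol, ...], *, k: float | None = None
    ) -> Distribution:
        """Smoothed relative-frequency distribution for a seen context."""
        if k is None:
            k = self.smoothing_k
        ctr = self.counts[context]
        alpha = sorted(self.alphabet)
        total = sum(ctr.values()) + k * len(alpha)
        if k == 0:
            support = {s: ctr[s] / total for s in alpha if ctr[s] > 0}
            return Distribution(support)
        return Distribution({s: (ctr[s] + k) / total for s in alpha})


def train_transitions(
    corpus: Iterable[Sequence[Symbol]],
    order: int = 1,
    viewpoint: str | None = None,
    level: int | None = None,
    smoothing_k: float = 1.0,
    alphabet: Iterable[Symbol] | None = None,
) -> TransitionModel:
    """Exact n-gram transition counts over a corpus of symbol streams.

    ``viewpoint``/``level`` default to those of the first symbol seen; a
    stream mixing viewpoints or levels is rejected. ``alphabet`` may
    declare symbols beyond those observed, so that smoothing assigns them
    finite surprisal (needed for oddball/deviant detection).
    """
    streams = [list(s) for s in corpus]
    if not streams or all(len(s) == 0 for s in streams):
        raise StreamError("corpus must contain at least one non-empty stream")
    first = next(s[0] for s in streams if s)
    if viewpoint is None:
        viewpoint = first.viewpoint
    if level is None:
        level = first.level
    model = TransitionModel(
        order=order, viewpoint=viewpoint, level=level, smoothing_k=smoothing_k
    )
    for stream in streams:
        model.observe_stream(stream)
    if alphabet is not None:
        for s in alphabet:
            if s.viewpoint != model.viewpoint or s.level != model.level:
                raise StreamError(f"declared symbol {s!r} does not match model")
            model.alphabet.add(s)
    return model


def predict_next(
    model: TransitionModel, context: Sequence[Symbol]
) -> Distribution:
    """Predictive distribution over the model alphabet given a context.

    The context is truncated to the model order; a context never observed
    in training falls back to successively shorter suffixes, ultimately the
    unigram distribution. Context symbols outside the alphabet make the
    context unseen (logged at debug level).
    """
    if not model.alphabet:
        raise EmptyModelError("model has no training data")
    ctx = tuple(context)[-model.order :]
    for start in range(0, len(ctx) + 1):
        sub = ctx[start:]
        if sub and any(s not in model.alphabet for s in sub):
            log.debug("context %s outside alphabet; backing off", sub)
            continue
        if sub in model.counts and model.context_total(sub) > 0:
            return model.conditional(sub)
    return model.conditional(())


def information_content(d: Distribution, s: Symbol) -> float:
    """Surprisal of ``s`` under ``d``: -log2 p, in bits."""
    p = d.mass(s)  # KeyError if s outside support
    if p == 0.0:
        raise ValueError(
            f"zero mass for {s!r}: enable smoothing to assign unseen "
            "events finite information content"
        )
    return -math.log2(p)


def entropy(d: Distribution) -> float:
    """Shannon entropy of ``d`` in bits."""
    return -sum(p * math.log2(p) for _, p in d.items() if p > 0)


def detect_deviants(
    model: TransitionModel,
    stream: Sequence[Symbol],
    threshold_bits: float,
) -> list[int]:
    """Indices whose observed symbol exceeds ``threshold_bits`` of surprisal.

    An oddball embedded in a repetitive sequence carries far more
    information than the repeated element and is flagged; the model must be
    smoothed so that unseen-but-possible symbols have finite surprisal.
    """
    if threshold_bits <= 0:
        raise ValueError("threshold_bits must be > 0")
    flagged = []
    for i, s in enumerate(stream):
        ctx = tuple(stream[max(0, i - model.order) : i])
        d = predict_next(model, ctx)
        if s not in d:
            raise StreamError(f"symbol {s!r} outside model alphabet")
        if information_content(d, s) > threshold_bits:
            flagged.append(i)
    return flagged
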