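"""Online information-theoretic chunking and the layered memory.

A stream is segmented where the information content of the incoming symbol
rises relative to the previous one (boundary entropy): statistically
coherent runs stay cheap to predict, and the jump in surprisal at the start
of the next unit marks the seam. Each flushed chunk is labelled with a
next-level symbol; identical member sequences always share a label, so the
labelled stream is a lossless, shorter re-description of the level below.
Iterating train -> chunk -> label builds the hierarchical memory, subject to
configurable depth and alphabet-size caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import RegistryError, StreamError
from .sequence import (
    Symbol,
    TransitionModel,
    information_content,
    predict_next,
    train_transitions,
)

__all__ = [
    "Chunk",
    "ChunkRegistry",
    "HierarchicalMemory",
    "boundary_decision",
    "chunk_sequence",
    "label_chunks",
    "build_hierarchy",
    "reconstruct",
]


@dataclass
class Chunk:
    """A statistically coherent subsequence of one level's stream.

    ``span`` is half-open in level-k stream indices; ``duration_ms`` is the
    time from the first member's onset to the onset following the chunk
    (None when the stream is untimed).
    """

    members: tuple[Symbol, ...]
    span: tuple[int, int]
    label: Symbol | None = None
    onset_ms: int | None = None
    duration_ms: int | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("chunk must be non-empty")
        a, b = self.span
        if b - a != len(self.members):
            raise ValueError("span length does not match members")


class ChunkRegistry:
    """Deterministic member-sequence -> label mapping for one level seam.

    Labels are created in first-encounter order and named ``c{level}_{i}``,
    so re-running on the same input reproduces the same labelling.
    """

    def __init__(self, level: int):
        self.level = level  # level of the labels produced (members are level-1)
        self._forward: dict[tuple[Symbol, ...], Symbol] = {}
        self._inverse: dict[Symbol, tuple[Symbol, ...]] = {}

    def label(self, members: tuple[Symbol, ...], viewpoint: str) -> Symbol:
        if members in self._forward:
            return self._forward[members]
        sym = Symbol(
            id=f"c{self.level}_{len(self._forward)}",
            level=self.level,
            viewpoint=viewpoint,
        )
        self._forward[members] = sym
        self._inverse[sym] = members
        return sym

    def expand(self, label: Symbol) -> tuple[Symbol, ...]:
        try:
            return self._inverse[label]
        except KeyError:
            raise RegistryError(f"label {label!r} not in registry") from None

    def __len__(self) -> int:
        return len(self._forward)

    def items(self):
        return self._forward.items()


def boundary_decision(ic_prev: float, ic_curr: float, theta: float) -> bool:
    """True iff surprisal rises by more than ``theta`` bits.

    A True value places a chunk boundary *before* the current symbol.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return ic_curr - ic_prev > theta


def chunk_sequence(
    model: TransitionModel,
    stream: Sequence[Symbol],
    theta: float = 0.0,
    max_len: int = 16,
    onsets: Sequence[int] | None = None,
) -> list[Chunk]:
    """Partition a stream into chunks at rises in information content.

    The growing buffer is the prediction context; a boundary falls before
    the current symbol when its surprisal exceeds the previous symbol's by
    more than ``theta``, or when the buffer reaches ``max_len``. The chunks
    always partition the stream exactly.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    stream = list(stream)
    if not stream:
        return []
    if onsets is not None and len(onsets) != len(stream):
        raise StreamError("onsets must parallel the stream")

    ics: list[float] = []
    buffer: list[Symbol] = []
    start = 0
    spans: list[tuple[int, int]] = []
    for i, s in enumerate(stream):
        d = predict_next(model, tuple(buffer[-model.order :]))
        if s not in d:
            raise StreamError(
                f"symbol {s!r} at {i} outside the model alphabet"
            )
        ic = information_content(d, s)
        flush = False
        if buffer:
            if len(buffer) >= max_len:
                flush = True
            elif boundary_decision(ics[-1], ic, theta):
                flush = True
        if flush:
            spans.append((start, i))
            buffer = []
            start = i
        buffer.append(s)
        ics.append(ic)
    spans.append((start, len(stream)))

    chunks = []
    for a, b in spans:
        onset = onsets[a] if onsets is not None else None
        duration = None
        if onsets is not None:
            end = onsets[b] if b < len(onsets) else None
            if end is not None:
                duration = end - onsets[a]
        chunks.append(
            Chunk(
                members=tuple(stream[a:b]),
                span=(a, b),
                onset_ms=onset,
                duration_ms=duration,
            )
        )
    return chunks


def label_chunks(
    chunks: Sequence[Chunk], registry: ChunkRegistry, viewpoint: str
) -> list[Symbol]:
    """Label each chunk with its next-level symbol and return the new stream."""
    out = []
    for c in chunks:
        c.label = registry.label(c.members, viewpoint)
        out.append(c.label)
    return out


@dataclass
class Level:
    """One layer of the memory: its streams, their onsets, and its model."""

    streams: list[list[Symbol]]
    model: TransitionModel
    onsets: list[list[int]] | None = None
    chunks: list[list[Chunk]] | None = None  # chunks of *this* level's streams


@dataclass
class HierarchicalMemory:
    """Layered chunk structure over a corpus.

    ``levels[0]`` holds the surface streams; ``levels[k]`` the level-k label
    streams. ``registries[k]`` maps level-k member sequences to level-(k+1)
    labels. Expanding every label at any level reproduces the surface
    streams exactly.
    """

    levels: list[Level] = field(default_factory=list)
    registries: list[ChunkRegistry] = field(default_factory=list)
    max_depth: int = 0
    max_alphabet: int = 0

    @property
    def depth(self) -> int:
        return len(self.levels) - 1

    def alphabet_size(self, level: int) -> int:
        return len({s for stream in self.levels[level].streams for s in stream})


def build_hierarchy(
    corpus: Sequence[Sequence[Symbol]],
    theta: float = 0.0,
    max_depth: int = 3,
    max_alphabet: int = 256,
    order: int = 1,
    smoothing_k: float = 1.0,
    max_len: int = 16,
    onsets: Sequence[Sequence[int]] | None = None,
) -> HierarchicalMemory:
    """Iterate train -> chunk -> label until a stopping condition.

    Stops at ``max_depth`` levels above the surface, when a level's total
    stream length no longer shrinks, or when labelling would push the new
    level's alphabet past ``max_alphabet``. Per-level transition models are
    retained in the returned memory.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if max_alphabet < 1:
        raise ValueError("max_alphabet must be >= 1")
    streams = [list(s) for s in corpus]
    if not streams or all(len(s) == 0 for s in streams):
        raise StreamError("corpus must contain at least one non-empty stream")
    level_onsets = [list(o) for o in onsets] if onsets is not None else None

    mem = HierarchicalMemory(max_depth=max_depth, max_alphabet=max_alphabet)
    k = 0
    while True:
        model = train_transitions(
            [s for s in streams if s], order=order, smoothing_k=smoothing_k
        )
        lvl = Level(streams=streams, model=model, onsets=level_onsets)
        mem.levels.append(lvl)
        if k >= max_depth:
            break
        per_stream_chunks = [
            chunk_sequence(
                model,
                s,
                theta=theta,
                max_len=max_len,
                onsets=level_onsets[i] if level_onsets is not None else None,
            )
            for i, s in enumerate(streams)
        ]
        new_len = sum(len(cs) for cs in per_stream_chunks)
        cur_len = sum(len(s) for s in streams)
        if new_len >= cur_len:
            break  # no compression: chunking has converged
        distinct = {c.members for cs in per_stream_chunks for c in cs}
        if len(distinct) > max_alphabet:
            break  # alphabet cap would be exceeded
        registry = ChunkRegistry(level=k + 1)
        vp = model.viewpoint
        new_streams = [
            label_chunks(cs, registry, viewpoint=vp) for cs in per_stream_chunks
        ]
        lvl.chunks = per_stream_chunks
        mem.registries.append(registry)
        if level_onsets is not None:
            level_onsets = [
                [c.onset_ms for c in cs] for cs in per_stream_chunks
            ]
        streams = new_streams
        k += 1
    return mem


def _expand(
    memory: HierarchicalMemory, sym: Symbol, level: int
) -> list[Symbol]:
    if level == 0:
        return [sym]
    members = memory.registries[level - 1].expand(sym)
    out: list[Symbol] = []
    for m in members:
        out.extend(_expand(memory, m, level - 1))
    return out


def reconstruct(
    memory: HierarchicalMemory, level: int
) -> list[list[Symbol]]:
    """Recursively expand the level-``level`` streams back to the surface.

    By the partition invariant this reproduces the level-0 streams exactly.
    """
    if not 0 <= level <= memory.depth:
        raise ValueError(f"no level {level} in memory of depth {memory.depth}")
    out = []
    for stream in memory.levels[level].streams:
        surface: list[Symbol] = []
        for sym in stream:
            surface.extend(_expand(memory, sym, level))
        out.append(surface)
    return out
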