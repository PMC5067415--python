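"""Enculturation: learning a background model of meter from exposure.

This module glues the pieces into the rhythm pipeline: generate (or take)
metrical corpora, build the chunk hierarchy over the accent viewpoint,
train a temporal model per level, and average per-level Markov-renewal
expectation profiles over many downbeat anchors and several independent
exposure corpora. The averaged profile is the package's estimate of an
enculturated listener's metrical expectation — the additive superposition
of each hierarchy level's onset predictions — and is what the loud-rest
detector and the entrainment simulator consume.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chunking import HierarchicalMemory, build_hierarchy
from .meterspace import MetricalStructure
from .synth import MeterCorpus, gen_meter_corpus, stage_seed
from .temporal import (
    ExpectationProfile,
    TemporalModel,
    TimeGrid,
    averaged_expectation_profile,
)
from .temporal import observe_timing

__all__ = ["EnculturatedModel", "enculturate", "meter_expectation_profile"]


@dataclass
class EnculturatedModel:
    """A chunk hierarchy plus one temporal model per level."""

    memory: HierarchicalMemory
    temporal_models: dict[int, TemporalModel]
    grid: TimeGrid


def enculturate(
    corpus: MeterCorpus,
    viewpoint: str = "accent",
    order: int = 1,
    theta: float = 0.0,
    max_depth: int = 4,
    max_alphabet: int = 256,
    quantum_ms: int = 20,
    horizon_ms: int = 4000,
) -> EnculturatedModel:
    """Build hierarchy and per-level temporal models from one corpus."""
    streams = corpus.viewpoint_streams(viewpoint)
    memory = build_hierarchy(
        [s for s, _ in streams],
        onsets=[o for _, o in streams],
        theta=theta,
        max_depth=max_depth,
        max_alphabet=max_alphabet,
        order=order,
    )
    grid = TimeGrid(quantum_ms=quantum_ms, horizon_ms=horizon_ms)
    tms = {
        k: observe_timing(lvl.model, list(zip(lvl.streams, lvl.onsets)), grid)
        for k, lvl in enumerate(memory.levels)
        if lvl.onsets is not None
    }
    return EnculturatedModel(memory=memory, temporal_models=tms, grid=grid)


def meter_expectation_profile(
    template: MetricalStructure,
    onset_probs: tuple[float, ...],
    seed: int,
    horizon_cycles: int = 2,
    n_corpora: int = 12,
    n_bars: int = 150,
    n_streams: int = 4,
    unit_ms: int = 240,
    structure: str = "grammar",
    order: int = 1,
    quantum_ms: int = 20,
) -> ExpectationProfile:
    """Metrical expectation after a generic downbeat, from fresh exposure.

    Draws ``n_corpora`` independent exposure corpora, enculturates on
    each, computes per-level renewal profiles anchored at downbeats in the
    second half of every stream, and averages everything. Averaging over
    anchors and exposure histories removes the idiosyncrasies of any one
    training run; the result approximates the expectation of a listener
    with broad exposure to the given meter.
    """
    bar_ms = unit_ms * template.units_per_cycle
    horizon_ms = horizon_cycles * bar_ms + 2 * quantum_ms
    profiles = []
    for j in range(n_corpora):
        corpus = gen_meter_corpus(
            template,
            onset_probs,
            n_bars=n_bars,
            n_streams=n_streams,
            unit_ms=unit_ms,
            seed=stage_seed(seed, f"meter-corpus-{j}"),
            structure=structure,
        )
        model = enculturate(
            corpus, order=order, quantum_ms=quantum_ms,
            horizon_ms=max(4000, horizon_ms),
        )
        anchors = [
            (si, b * bar_ms)
            for si in range(n_streams)
            for b in range(n_bars // 2, n_bars - horizon_cycles - 1, 5)
        ]
        profiles.append(
            averaged_expectation_profile(
                model.memory, model.temporal_models, horizon_ms, anchors,
                quantum_ms=quantum_ms,
            )
        )
    # average across exposure histories, level by level
    acc: dict[int, object] = {}
    counts: dict[int, int] = {}
    for prof in profiles:
        for lvl, arr in prof.per_level.items():
            acc[lvl] = acc.get(lvl, 0) + arr
            counts[lvl] = counts.get(lvl, 0) + 1
    per_level = {lvl: acc[lvl] / counts[lvl] for lvl in acc}
    grid = TimeGrid(quantum_ms=quantum_ms, horizon_ms=horizon_ms)
    return ExpectationProfile(grid=grid, per_level=per_level)
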