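"""Serialization: JSONL event streams, JSON models/memories, CSV tables.

Formats are plain text and canonical (fixed key order, compact
separators), so write -> read -> write is byte-identical. Malformed
line-oriented input is reported with its line number.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chunking import ChunkRegistry, HierarchicalMemory, Level
from .errors import IdyotIOError
from .sequence import Event, Symbol, TransitionModel
from .temporal import ExpectationProfile, TapRecord, TimeGrid

__all__ = [
    "write_events_jsonl",
    "read_events_jsonl",
    "model_to_dict",
    "model_from_dict",
    "write_model_json",
    "read_model_json",
    "memory_to_dict",
    "memory_from_dict",
    "write_memory_json",
    "read_memory_json",
    "write_profile_csv",
    "read_profile_csv",
    "write_taps_csv",
    "read_taps_csv",
]


def _dumps(obj) -> str:
    return json.dumps(obj, separators=(",", ":"), sort_keys=False)


# ---------------------------------------------------------------------------
# Event streams (JSONL)
# ---------------------------------------------------------------------------


def write_events_jsonl(path, streams: Sequence[Sequence[Event]]) -> None:
    """One header record, then per stream a marker and its event records."""
    streams = [list(s) for s in streams]
    viewpoints = sorted({vp for s in streams for e in s for vp in e.values})
    lines = [_dumps({"record": "header", "viewpoints": viewpoints})]
    for i, stream in enumerate(streams):
        lines.append(_dumps({"record": "stream", "index": i}))
        for e in stream:
            lines.append(
                _dumps(
                    {
                        "record": "event",
                        "viewpoint_values": {
                            vp: e.values[vp].id for vp in viewpoints
                        },
                        "onset_ms": e.onset_ms,
                    }
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_events_jsonl(path) -> list[list[Event]]:
    text = Path(path).read_text()
    streams: list[list[Event]] = []
    viewpoints: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise IdyotIOError(f"invalid JSON: {exc.msg}", line=lineno) from None
        kind = rec.get("record")
        if kind == "header":
            viewpoints = list(rec.get("viewpoints", []))
        elif kind == "stream":
            streams.append([])
        elif kind == "event":
            if viewpoints is None:
                raise IdyotIOError("event before header", line=lineno)
            if not streams:
                raise IdyotIOError("event before stream marker", line=lineno)
            try:
                values = {
                    vp: Symbol(rec["viewpoint_values"][vp], 0, vp)
                    for vp in viewpoints
                }
                onset = int(rec["onset_ms"])
            except KeyError as exc:
                raise IdyotIOError(
                    f"missing field {exc.args[0]!r}", line=lineno
                ) from None
            if streams[-1] and onset < streams[-1][-1].onset_ms:
                raise IdyotIOError("onsets decrease within stream", line=lineno)
            streams[-1].append(Event(values=values, onset_ms=onset))
        else:
            raise IdyotIOError(f"unknown record type {kind!r}", line=lineno)
    if viewpoints is None:
        raise IdyotIOError("no header record found", line=1)
    return streams


# ---------------------------------------------------------------------------
# Transition models and memories (JSON)
# ---------------------------------------------------------------------------


def _sym_to_list(s: Symbol) -> list:
    return [s.id, s.level, s.viewpoint]


def _sym_from_list(v) -> Symbol:
    return Symbol(v[0], v[1], v[2])


def model_to_dict(model: TransitionModel) -> dict:
    return {
        "order": model.order,
        "viewpoint": model.viewpoint,
        "level": model.level,
        "smoothing_k": model.smoothing_k,
        "n_streams": model.n_streams,
        "alphabet": [_sym_to_list(s) for s in sorted(model.alphabet)],
        "counts": [
            {
                "context": [_sym_to_list(s) for s in ctx],
                "next": {s.id: int(n) for s, n in sorted(ctr.items())},
            }
            for ctx, ctr in sorted(
                model.counts.items(), key=lambda kv: (len(kv[0]), kv[0])
            )
        ],
    }


def model_from_dict(d: dict) -> TransitionModel:
    model = TransitionModel(
        order=d["order"],
        viewpoint=d["viewpoint"],
        level=d["level"],
        smoothing_k=d["smoothing_k"],
    )
    model.n_streams = d.get("n_streams", 0)
    model.alphabet = {_sym_from_list(v) for v in d["alphabet"]}
    by_id = {s.id: s for s in model.alphabet}
    for entry in d["counts"]:
        ctx = tuple(_sym_from_list(v) for v in entry["context"])
        model.counts[ctx] = Counter(
            {by_id[i]: n for i, n in entry["next"].items()}
        )
    return model


def write_model_json(path, model: TransitionModel) -> None:
    Path(path).write_text(_dumps(model_to_dict(model)) + "\n")


def read_model_json(path) -> TransitionModel:
    try:
        return model_from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError) as exc:
        raise IdyotIOError(f"invalid model file: {exc}") from None


def memory_to_dict(memory: HierarchicalMemory) -> dict:
    levels = []
    for lvl in memory.levels:
        levels.append(
            {
                "streams": [[s.id for s in st] for st in lvl.streams],
                "onsets": lvl.onsets,
                "model": model_to_dict(lvl.model),
            }
        )
    regs = []
    for reg in memory.registries:
        regs.append(
            {
                "level": reg.level,
                "entries": [
                    {"members": [s.id for s in mem], "label": lab.id}
                    for mem, lab in reg.items()
                ],
            }
        )
    return {
        "max_depth": memory.max_depth,
        "max_alphabet": memory.max_alphabet,
        "levels": levels,
        "registries": regs,
    }


def memory_from_dict(d: dict) -> HierarchicalMemory:
    mem = HierarchicalMemory(
        max_depth=d["max_depth"], max_alphabet=d["max_alphabet"]
    )
    for ld in d["levels"]:
        model = model_from_dict(ld["model"])
        by_id = {s.id: s for s in model.alphabet}
        streams = [[by_id[i] for i in st] for st in ld["streams"]]
        mem.levels.append(
            Level(streams=streams, model=model, onsets=ld.get("onsets"))
        )
    for k, rd in enumerate(d["registries"]):
        reg = ChunkRegistry(level=rd["level"])
        lower = {s.id: s for s in mem.levels[k].model.alphabet}
        vp = mem.levels[k + 1].model.viewpoint
        for entry in rd["entries"]:
            members = tuple(lower[i] for i in entry["members"])
            sym = reg.label(members, vp)
            if sym.id != entry["label"]:
                raise IdyotIOError(
                    f"registry labels out of order: {sym.id} != {entry['label']}"
                )
        mem.registries.append(reg)
    return mem


def write_memory_json(path, memory: HierarchicalMemory) -> None:
    Path(path).write_text(_dumps(memory_to_dict(memory)) + "\n")


def read_memory_json(path) -> HierarchicalMemory:
    try:
        return memory_from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError) as exc:
        raise IdyotIOError(f"invalid memory file: {exc}") from None


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def write_profile_csv(path, profile: ExpectationProfile) -> None:
    df = pd.DataFrame(
        {
            "bin_start_ms": [
                profile.grid.bin_start(i) for i in range(profile.n_bins)
            ],
            "strength": profile.combined,
        }
    )
    for lvl in sorted(profile.per_level):
        df[f"level_{lvl}"] = profile.per_level[lvl]
    df.to_csv(path, index=False)


def read_profile_csv(path) -> ExpectationProfile:
    df = pd.read_csv(path)
    starts = df["bin_start_ms"].to_numpy()
    if len(starts) < 2:
        raise IdyotIOError("profile needs at least two bins")
    quantum = int(starts[1] - starts[0])
    grid = TimeGrid(quantum_ms=quantum, horizon_ms=quantum * len(starts))
    per_level = {
        int(c.split("_", 1)[1]): df[c].to_numpy(dtype=float)
        for c in df.columns
        if c.startswith("level_")
    }
    if not per_level:
        per_level = {0: df["strength"].to_numpy(dtype=float)}
    return ExpectationProfile(grid=grid, per_level=per_level)


def write_taps_csv(path, record: TapRecord) -> None:
    pd.DataFrame(
        {"tap_ms": record.tap_times_ms, "error_ms": record.phase_errors_ms}
    ).to_csv(path, index=False)


def read_taps_csv(path) -> TapRecord:
    df = pd.read_csv(path)
    return TapRecord(
        tap_times_ms=list(df["tap_ms"].astype(float)),
        phase_errors_ms=list(df["error_ms"].astype(float)),
    )
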