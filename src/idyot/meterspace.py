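"""A geometric conceptual space of metrical structure.

Metrical structures become points in a quality-dimension space: one
dimension per subdivision ratio (a grouped, additive level such as 2+2+3
contributes its normalized group-length vector) plus an optional tempo
dimension carrying the basic unit in ms. Similarity is distance —
Euclidean within a dimension domain (integral dimensions), city-block
across domains (separable dimensions) — so rhythms can be classified by
nearest neighbour, tempo can be abstracted away by projection, and
families of performances can be diagnosed statistically: a groove is a
tight cluster displaced from the regularized rhythm, inconsistent timing
a diffuse cloud around it, and a tempo change a monotone trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetricalStructure",
    "MeterPoint",
    "PerformancePoint",
    "TimingDiagnosis",
    "meter_point",
    "meter_distance",
    "classify_nn",
    "diagnose_timing",
]


@dataclass(frozen=True)
class MetricalStructure:
    """Subdivision ratios from the whole cycle downward.

    Each level is either an integer ratio >= 2 (e.g. ``(2, 2, 2)`` for 4/4
    down to eighths) or an explicit additive group (``((2, 2, 3),)`` for
    7/8). ``basic_unit_ms`` is the duration of the smallest subdivision.
    """

    levels: tuple[int | tuple[int, ...], ...]
    basic_unit_ms: int | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("a metrical structure needs at least one level")
        for lvl in self.levels:
            if isinstance(lvl, tuple):
                if len(lvl) < 2 or any(g < 1 for g in lvl):
                    raise ValueError(f"malformed additive group {lvl}")
            elif lvl < 2:
                raise ValueError(f"subdivision ratio must be >= 2, got {lvl}")
        if self.basic_unit_ms is not None and self.basic_unit_ms < 1:
            raise ValueError("basic_unit_ms must be >= 1")
        self.position_strengths()  # cycle-consistency check; raises if malformed

    @property
    def units_per_cycle(self) -> int:
        n = 1
        for lvl in self.levels:
            n *= sum(lvl) if isinstance(lvl, tuple) else lvl
        return n

    @property
    def cycle_ms(self) -> int | None:
        if self.basic_unit_ms is None:
            return None
        return self.basic_unit_ms * self.units_per_cycle

    def position_strengths(self) -> list[int]:
        """Metrical strength of each grid position of one cycle.

        The downbeat scores ``len(levels) + 1``; a position first becoming
        a boundary at the i-th subdivision level scores ``len(levels) - i``;
        positions interior to the finest level score 0. Larger is stronger.
        Used by the corpus generators.
        """
        units = self.units_per_cycle
        strengths = [0] * units
        strengths[0] = len(self.levels) + 1
        spans = [(0, units)]
        rank = len(self.levels) + 1
        for lvl in self.levels:
            rank -= 1
            new_spans = []
            for a, b in spans:
                if isinstance(lvl, tuple):
                    if (b - a) % sum(lvl) != 0:
                        raise ValueError(
                            f"group {lvl} does not divide a span of {b - a} units"
                        )
                    unit = (b - a) // sum(lvl)
                    pos = a
                    for g in lvl:
                        new_spans.append((pos, pos + g * unit))
                        if pos != 0 and strengths[pos] == 0:
                            strengths[pos] = rank
                        pos += g * unit
                else:
                    if (b - a) % lvl != 0:
                        raise ValueError(
                            f"ratio {lvl} does not divide a span of {b - a} units"
                        )
                    step = (b - a) // lvl
                    for i in range(lvl):
                        p = a + i * step
                        new_spans.append((p, p + step))
                        if p != 0 and strengths[p] == 0:
                            strengths[p] = rank
            spans = new_spans
        return strengths


@dataclass(frozen=True)
class MeterPoint:
    """A metrical structure as a point on named quality dimensions.

    ``domains`` groups dimensions: distance is Euclidean within a domain
    and city-block (summed) across domains. Points are only comparable
    within one space (identical dims/domains).
    """

    coords: tuple[float, ...]
    dims: tuple[str, ...]
    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if not len(self.coords) == len(self.dims) == len(self.domains):
            raise ValueError("coords, dims and domains must align")

    def project_out(self, domain: str) -> "MeterPoint":
        """Drop every dimension of ``domain`` (e.g. abstract away tempo)."""
        keep = [i for i, d in enumerate(self.domains) if d != domain]
        return MeterPoint(
            coords=tuple(self.coords[i] for i in keep),
            dims=tuple(self.dims[i] for i in keep),
            domains=tuple(self.domains[i] for i in keep),
        )


def meter_point(
    ms: MetricalStructure, include_tempo: bool = False
) -> MeterPoint:
    """Encode a metrical structure as a meter point.

    Integer levels contribute their ratio on a shared periodicity domain;
    an additive group contributes its normalized group-length vector on a
    domain of its own; the tempo dimension (basic unit in ms) is included
    only when flagged and available.
    """
    coords: list[float] = []
    dims: list[str] = []
    domains: list[str] = []
    for i, lvl in enumerate(ms.levels):
        if isinstance(lvl, tuple):
            total = sum(lvl)
            for j, g in enumerate(lvl):
                coords.append(g / total)
                dims.append(f"group{i}_{j}")
                domains.append(f"group{i}")
        else:
            coords.append(float(lvl))
            dims.append(f"ratio{i}")
            domains.append("periodicity")
    if include_tempo:
        if ms.basic_unit_ms is None:
            raise ValueError("structure has no tempo to include")
        coords.append(float(ms.basic_unit_ms))
        dims.append("unit_ms")
        domains.append("tempo")
    return MeterPoint(tuple(coords), tuple(dims), tuple(domains))


def meter_distance(
    p: MeterPoint,
    q: MeterPoint,
    scales: Sequence[float] | None = None,
) -> float:
    """Distance between two meter points.

    Euclidean within each dimension domain, city-block across domains.
    ``scales`` optionally rescales dimensions before measuring (salience
    weighting); off by default.
    """
    if p.dims != q.dims or p.domains != q.domains:
        raise ValueError("points are from different spaces")
    a = np.asarray(p.coords, dtype=float)
    b = np.asarray(q.coords, dtype=float)
    if scales is not None:
        s = np.asarray(scales, dtype=float)
        if s.shape != a.shape:
            raise ValueError("scales must match dimensionality")
        a = a * s
        b = b * s
    total = 0.0
    for dom in dict.fromkeys(p.domains):  # preserves order
        idx = [i for i, d in enumerate(p.domains) if d == dom]
        total += float(np.sqrt(((a[idx] - b[idx]) ** 2).sum()))
    return total


def classify_nn(
    points: Sequence[MeterPoint],
    labels: Sequence[str],
    query: MeterPoint,
    scales: Sequence[float] | None = None,
) -> str:
    """Label of the nearest training point.

    Distance ties are broken by the smaller label (sorted order), then by
    training-set position, so classification is deterministic.
    """
    if not points:
        raise ValueError("empty training set")
    if len(points) != len(labels):
        raise ValueError("points and labels must align")
    best = min(
        range(len(points)),
        key=lambda i: (meter_distance(points[i], query, scales), labels[i], i),
    )
    return labels[best]


@dataclass(frozen=True)
class PerformancePoint:
    """Per-onset signed timing deviations (ms) of one performance from the
    regularized rhythm, plus the performance's position in a sequence."""

    deviations: tuple[float, ...]
    index: int
    reference: str = "regularized"

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.deviations)):
            raise ValueError("deviations must be finite")


@dataclass(frozen=True)
class TimingDiagnosis:
    label: str  # groove | inconsistent_error | tempo_change
    mean_offset_ms: float
    dispersion_ms: float
    trend: float

    def __post_init__(self) -> None:
        if self.label not in {"groove", "inconsistent_error", "tempo_change"}:
            raise ValueError(f"unknown diagnosis label {self.label!r}")


def diagnose_timing(
    performances: Sequence[PerformancePoint],
    offset_min_ms: float = 8.0,
    disp_max_ms: float = 15.0,
    trend_min: float = 0.8,
) -> TimingDiagnosis:
    """Classify a family of performances by its statistical signature.

    tempo_change: the per-performance deviation magnitude correlates
    monotonically (Spearman >= ``trend_min``) with position in the
    sequence — a trajectory. groove: a consistent displacement — the
    largest per-onset mean offset exceeds ``offset_min_ms`` while the
    residual dispersion stays below ``disp_max_ms``. Everything else is
    inconsistent_error (a cloud around the regularized rhythm; tight,
    on-time playing also lands here for want of a better label).

    Needs at least 5 performances of equal length.
    """
    if len(performances) < 5:
        raise ValueError("need at least 5 performances to diagnose")
    lengths = {len(p.deviations) for p in performances}
    if len(lengths) != 1:
        raise ValueError("performances must have equal onset counts")
    order = sorted(performances, key=lambda p: p.index)
    dev = np.array([p.deviations for p in order])  # (n_perf, n_onsets)
    magnitudes = np.abs(dev).mean(axis=1)
    rho = stats.spearmanr(np.arange(len(order)), magnitudes).statistic
    per_onset_mean = dev.mean(axis=0)
    mean_offset = float(np.max(np.abs(per_onset_mean)))
    dispersion = float((dev - per_onset_mean).std(ddof=1))
    if np.isfinite(rho) and rho >= trend_min:
        label = "tempo_change"
    elif mean_offset > offset_min_ms and dispersion < disp_max_ms:
        label = "groove"
    else:
        label = "inconsistent_error"
    return TimingDiagnosis(
        label=label,
        mean_offset_ms=mean_offset,
        dispersion_ms=dispersion,
        trend=float(rho) if np.isfinite(rho) else 0.0,
    )
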