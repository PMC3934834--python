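"""Segmentation of length-vs-time traces into paused / slow / fast phases.

Mirrors the kymograph analysis of processive growth: per-frame velocities by
finite differences, frame classification against velocity thresholds, merging
of sub-resolution runs, and least-squares per-phase slopes.  The default
thresholds at 1 µM PA sit between the three velocity regimes (0, 8.8 and 63
subunits/s) and scale linearly with the PA concentration.

Dwell times of interior phases are exact to within one frame interval;
boundary phases are flagged as censored by the movie start/end so downstream
exponential fits can handle them properly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ObservedTrace

__all__ = [
    "PhaseClass",
    "Phase",
    "PhaseTable",
    "frame_velocities",
    "segment_phases",
    "phase_statistics",
    "default_thresholds",
]

SUBUNIT_UM = 2.7e-3


class PhaseClass(str, enum.Enum):
    PAUSED = "PAUSED"   # Spire-capped: arrested growth
    SLOW = "SLOW"       # free barbed end
    FAST = "FAST"       # formin-bound processive growth


@dataclass
class Phase:
    phase_class: PhaseClass
    t_start: float
    t_end: float
    velocity: float          # subunits/s, least-squares slope over the phase
    n_frames: int
    censored_left: bool
    censored_right: bool

    @property
    def dwell_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PhaseTable:
    """Ordered, non-overlapping phases tiling one trace."""

    phases: list[Phase]
    filament_id: int
    thresholds: tuple[float, float]
    min_frames: int

    def __len__(self) -> int:
        return len(self.phases)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filament_id": self.filament_id,
                "phase_class": [p.phase_class.value for p in self.phases],
                "t_start": [p.t_start for p in self.phases],
                "t_end": [p.t_end for p in self.phases],
                "velocity": [p.velocity for p in self.phases],
                "censored_left": [p.censored_left for p in self.phases],
                "censored_right": [p.censored_right for p in self.phases],
            }
        )


def default_thresholds(pa_uM: float = 1.0) -> tuple[float, float]:
    """(paused_max, fast_min) in subunits/s, scaled linearly with [PA].

    At 1 µM PA: 2 and 25 subunits/s — between the arrested, free (8.8) and
    formin-bound (63) regimes.
    """
    return 2.0 * pa_uM, 25.0 * pa_uM


def frame_velocities(trace: ObservedTrace) -> np.ndarray:
    """Per-frame elongation velocity in subunits/s.

    Centred finite differences of the subunit-converted length over the frame
    times; one-sided differences at the two endpoints (``numpy.gradient``).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 frames to estimate velocities")
    subunits = trace.length_um / SUBUNIT_UM
    return np.gradient(subunits, trace.times)


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal labels as (start, stop) index pairs, stop exclusive."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i))
            start = i
    return out


def segment_phases(
    trace: ObservedTrace,
    thresholds: tuple[float, float] | None = None,
    min_frames: int = 2,
    velocities: np.ndarray | None = None,
) -> PhaseTable:
    """Classify frames by velocity thresholds and merge sub-resolution runs.

    Frames with velocity ≤ paused_max are PAUSED, ≥ fast_min FAST, SLOW in
    between.  Runs shorter than ``min_frames`` are merged (shortest first)
    into the neighbouring run whose mean velocity is closer.  Phase
    boundaries are placed midway between the adjacent frames; the per-phase
    velocity is the least-squares slope of length over the phase's frames.
    """
    if thresholds is None:
        thresholds = default_thresholds(trace.pa_uM if trace.pa_uM is not None else 1.0)
    paused_max, fast_min = thresholds
    if not (0 <= paused_max < fast_min):
        raise ValueError("thresholds must satisfy 0 <= paused_max < fast_min")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if velocities is None:
        velocities = frame_velocities(trace)
    v = np.asarray(velocities, float)
    labels = np.where(v <= paused_max, 0, np.where(v >= fast_min, 2, 1))

    runs = _runs(labels)
    # merge short runs into the neighbour with the closer mean velocity
    while len(runs) > 1:
        lengths = [stop - start for start, stop in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_frames]
        if not short:
            break
        i = min(short, key=lambda j: lengths[j])
        start, stop = runs[i]
        mean_v = v[start:stop].mean()
        candidates = []
        if i > 0:
            s0, s1 = runs[i - 1]
            candidates.append((abs(v[s0:s1].mean() - mean_v), i - 1))
        if i < len(runs) - 1:
            s0, s1 = runs[i + 1]
            candidates.append((abs(v[s0:s1].mean() - mean_v), i + 1))
        _, j = min(candidates)
        labels[start:stop] = labels[runs[j][0]]
        runs = _runs(labels)

    times = trace.times
    subunits = trace.length_um / SUBUNIT_UM
    phases: list[Phase] = []
    for k, (start, stop) in enumerate(runs):
        if stop - start >= 2:
            slope = np.polyfit(times[start:stop], subunits[start:stop], 1)[0]
        else:
            slope = float(v[start])
        t0 = times[0] if k == 0 else 0.5 * (times[start - 1] + times[start])
        t1 = times[-1] if k == len(runs) - 1 else 0.5 * (times[stop - 1] + times[stop])
        phases.append(
            Phase(
                phase_class=PhaseClass(("PAUSED", "SLOW", "FAST")[labels[start]]),
                t_start=float(t0),
                t_end=float(t1),
                velocity=float(slope),
                n_frames=stop - start,
                censored_left=(k == 0),
                censored_right=(k == len(runs) - 1),
            )
        )
    return PhaseTable(phases=phases, filament_id=trace.filament_id,
                      thresholds=thresholds, min_frames=min_frames)


def phase_statistics(
    tables: PhaseTable | list[PhaseTable],
    weight_by_frames: bool = True,
) -> pd.DataFrame:
    """Per-class velocity summaries and dwell samples over one or many filaments.

    Returns a long-format DataFrame (one row per phase) with columns
    filament_id, phase_class, velocity, dwell_s, n_frames, censored_left,
    censored_right, censored.  ``summarize_velocities`` can then aggregate it;
    dwell rows with censoring flags feed the censored exponential fits (phases
    censored on either side under-measure the true sojourn).
    """
    if isinstance(tables, PhaseTable):
        tables = [tables]
    if not tables or all(len(t) == 0 for t in tables):
        raise ValueError("empty phase table")
    rows = []
    for t in tables:
        for p in t.phases:
            rows.append(
                {
                    "filament_id": t.filament_id,
                    "phase_class": p.phase_class.value,
                    "velocity": p.velocity,
                    "dwell_s": p.dwell_s,
                    "n_frames": p.n_frames,
                    "censored_left": p.censored_left,
                    "censored_right": p.censored_right,
                    "censored": p.censored_left or p.censored_right,
                }
            )
    return pd.DataFrame(rows)


def summarize_velocities(phase_frame: pd.DataFrame, weight_by_frames: bool = True) -> pd.DataFrame:
    """Mean ± sd velocity per phase class (frame-weighted by default)."""
    out = []
    for cls, g in phase_frame.groupby("phase_class"):
        w = g["n_frames"].to_numpy(float) if weight_by_frames else np.ones(len(g))
        v = g["velocity"].to_numpy(float)
        mean = np.average(v, weights=w)
        sd = float(np.sqrt(np.average((v - mean) ** 2, weights=w))) if len(g) > 1 else 0.0
        out.append({"phase_class": cls, "mean_velocity": mean, "sd_velocity": sd,
                    "n_phases": len(g)})
    return pd.DataFrame(out)
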