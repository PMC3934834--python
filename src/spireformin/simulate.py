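"""Gillespie simulation of single filaments and the TIRF observation model.

A trajectory is the exact history of one barbed end: the sequence of occupancy
sojourns drawn from the generator's exponential exit laws, plus the times at
which subunits were added.  Within each sojourn, subunit addition is a Poisson
process at the state's elongation velocity, so short fast phases carry
realistic count noise.  The observation model samples the true length on a
regular frame grid (default 10 s, as in the time-lapse acquisitions) and adds
independent Gaussian position noise.

Reproducibility: a master seed is expanded into per-filament substreams via
``numpy.random.SeedSequence([master_seed, filament_index])``, so population
results do not depend on simulation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    SUBUNIT_UM,
    Conditions,
    EndState,
    RateConstants,
    elongation_velocity,
    generator_matrix,
)

__all__ = [
    "Trajectory",
    "ObservedTrace",
    "PopulationResult",
    "simulate_trajectory",
    "observe",
    "simulate_population",
    "filament_rng",
]


def filament_rng(master_seed: int, filament_index: int = 0) -> np.random.Generator:
    """Deterministic, order-independent per-filament random stream."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(filament_index)]))


@dataclass
class Trajectory:
    """Exact simulated history of one filament barbed end.

    ``sojourns`` is a contiguous list of (state, t_start, t_end) tiling
    [0, t_max]; ``addition_times`` holds one strictly increasing time per
    subunit added (never inside a SPIRE_CAPPED sojourn).
    """

    sojourns: list[tuple[EndState, float, float]]
    addition_times: np.ndarray
    t_max: float
    seed: int
    rc: RateConstants
    cond: Conditions
    initial_state: EndState = EndState.FREE

    def length_at(self, t: float | np.ndarray) -> np.ndarray:
        """True filament length (subunits added since t=0) at time(s) t."""
        return np.searchsorted(self.addition_times, np.asarray(t, float), side="right")

    def state_at(self, t: float) -> EndState:
        for state, t0, t1 in self.sojourns:
            if t0 <= t < t1:
                return state
        return self.sojourns[-1][0]

    def sojourn_frame(self, filament_id: int = 0) -> pd.DataFrame:
        """One row per sojourn: filament_id, state, t_start, t_end."""
        return pd.DataFrame(
            {
                "filament_id": filament_id,
                "state": [s.name for s, _, _ in self.sojourns],
                "t_start": [t0 for _, t0, _ in self.sojourns],
                "t_end": [t1 for _, _, t1 in self.sojourns],
            }
        )


@dataclass
class ObservedTrace:
    """Frame-sampled, noise-corrupted length record (kymograph readout).

    ``times`` are uniform multiples of ``frame_interval_s`` starting at 0;
    ``length_um`` is the measured length per frame.
    """

    times: np.ndarray
    length_um: np.ndarray
    frame_interval_s: float = 10.0
    noise_sd_um: float = 0.0
    filament_id: int = 0
    pa_uM: float | None = None

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filament_id": self.filament_id,
                "frame_time_s": self.times,
                "length_um": self.length_um,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, noise_sd_um: float = 0.0,
                   pa_uM: float | None = None) -> "ObservedTrace":
        times = df["frame_time_s"].to_numpy(float)
        dt = np.diff(times)
        interval = float(dt[0]) if len(dt) else 10.0
        return cls(times=times, length_um=df["length_um"].to_numpy(float),
                   frame_interval_s=interval, noise_sd_um=noise_sd_um,
                   filament_id=int(df["filament_id"].iloc[0]) if "filament_id" in df else 0,
                   pa_uM=pa_uM)


@dataclass
class PopulationResult:
    """Per-time-point state fractions over a simulated filament population."""

    times: np.ndarray
    fractions: np.ndarray  # shape (n_times, 3), columns indexed by EndState
    n_filaments: int
    cond: Conditions

    def fraction(self, state: EndState) -> np.ndarray:
        return self.fractions[:, int(state)]


def simulate_trajectory(
    rc: RateConstants,
    cond: Conditions,
    t_max: float,
    initial_state: EndState = EndState.FREE,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    track_additions: bool = True,
) -> Trajectory:
    """Simulate one filament by the Gillespie algorithm.

    Sojourn lengths are exponential with the generator's exit rate for the
    current state; the destination is chosen with probability proportional to
    the outgoing rates.  Subunit additions within a sojourn of duration d at
    velocity v are a Poisson(v·d) count placed at sorted uniform times.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if rng is None:
        rng = filament_rng(seed)
    Q = generator_matrix(rc, cond)
    sojourns: list[tuple[EndState, float, float]] = []
    additions: list[np.ndarray] = []
    t = 0.0
    state = EndState(initial_state)
    while t < t_max:
        rates = Q[int(state)].copy()
        rates[int(state)] = 0.0
        total = rates.sum()
        dwell = rng.exponential(1.0 / total) if total > 0 else np.inf
        t_end = min(t + dwell, t_max)
        if track_additions:
            v = elongation_velocity(state, rc, cond)
            if v > 0:
                n_add = rng.poisson(v * (t_end - t))
                if n_add:
                    additions.append(np.sort(rng.uniform(t, t_end, size=n_add)))
        sojourns.append((state, t, t_end))
        if t_end >= t_max:
            break
        state = EndState(rng.choice(3, p=rates / total))
        t = t_end
    addition_times = (
        np.concatenate(additions) if additions else np.empty(0, dtype=float)
    )
    return Trajectory(
        sojourns=sojourns,
        addition_times=addition_times,
        t_max=t_max,
        seed=seed,
        rc=rc,
        cond=cond,
        initial_state=EndState(initial_state),
    )


def observe(
    traj: Trajectory,
    frame_interval_s: float = 10.0,
    noise_sd_um: float = 0.05,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    filament_id: int = 0,
) -> ObservedTrace:
    """Sample a trajectory on the frame grid and add Gaussian position noise.

    Measured length per frame = (true subunit count at the frame time)
    × 2.7 nm/subunit + N(0, noise_sd_um²).  Frame 0 is at t = 0.
    """
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be >= 0")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(filament_id), 0xB5]))
    n_frames = int(np.floor(traj.t_max / frame_interval_s + 1e-9)) + 1
    times = np.arange(n_frames) * frame_interval_s
    true_um = traj.length_at(times) * (traj.rc.subunit_length_nm / 1e3)
    noise = rng.normal(0.0, noise_sd_um, size=n_frames) if noise_sd_um > 0 else 0.0
    return ObservedTrace(
        times=times,
        length_um=true_um + noise,
        frame_interval_s=frame_interval_s,
        noise_sd_um=noise_sd_um,
        filament_id=filament_id,
        pa_uM=traj.cond.pa_uM,
    )


def simulate_population(
    n: int,
    rc: RateConstants,
    cond: Conditions,
    t_max: float,
    initial_state: EndState = EndState.FREE,
    seed: int = 0,
    grid_dt: float = 10.0,
    track_additions: bool = False,
) -> PopulationResult:
    """Simulate n independent filaments and tabulate state fractions over time.

    Additions are not tracked by default (occupancy only), which keeps large
    populations cheap.  Reproducible and order-independent under the master
    seed via per-filament substreams.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    times = np.arange(0.0, t_max + 1e-9, grid_dt)
    counts = np.zeros((len(times), 3))
    for i in range(n):
        traj = simulate_trajectory(
            rc, cond, t_max, initial_state=initial_state,
            rng=filament_rng(seed, i), seed=seed, track_additions=track_additions,
        )
        starts = np.array([t0 for _, t0, _ in traj.sojourns])
        states = np.array([int(s) for s, _, _ in traj.sojourns])
        idx = np.searchsorted(starts, times, side="right") - 1
        counts[np.arange(len(times)), states[idx]] += 1
    return PopulationResult(times=times, fractions=counts / n, n_filaments=n, cond=cond)


def traces_to_csv(traces: list[ObservedTrace], path) -> None:
    """Write observed traces as a single long-format CSV."""
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path, noise_sd_um: float = 0.0, pa_uM: float | None = None) -> list[ObservedTrace]:
    df = pd.read_csv(path)
    return [
        ObservedTrace.from_frame(g, noise_sd_um=noise_sd_um, pa_uM=pa_uM)
        for _, g in df.groupby("filament_id", sort=True)
    ]
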