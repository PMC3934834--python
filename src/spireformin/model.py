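"""Three-state kinetic model of actin barbed-end occupancy by Spire and formin 2.

A filament barbed end growing from profilin-actin (PA) is described as a
continuous-time Markov chain over three occupancy states:

* ``FREE`` (B) — bare barbed end, slow elongation;
* ``SPIRE_CAPPED`` (BS) — Nt-Spire bound via its WH2 domains, growth arrested;
* ``FORMIN_BOUND`` (BF) — FH1-FH2 dimer bound, fast processive elongation.

Transitions are first order (dissociation) or pseudo-first order in the free
Spire / formin concentration (association and mutual displacement).  The
displacement reactions BS→BF and BF→BS proceed through short-lived ternary
complexes whose lifetimes are not resolved experimentally; they are collapsed
here into single effective transitions with the measured second-order entry
rates.  With the measured constants the cycle B→BS→BF→B carries a strictly
positive stationary flux: the ping-pong alternation is a driven cycle, not a
detailed-balance equilibrium.

Units: concentrations in µM, time in s, second-order rates in µM⁻¹ s⁻¹,
filament lengths in subunits internally (2.7 nm per subunit for µm output).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "EndState",
    "RateConstants",
    "Conditions",
    "DerivedConstants",
    "default_rate_constants",
    "generator_matrix",
    "stationary_distribution",
    "cycle_flux",
    "elongation_velocity",
    "derived_constants",
    "save_config",
    "load_config",
]

#: filament length contributed by one actin subunit, in µm
SUBUNIT_UM = 2.7e-3


class EndState(enum.IntEnum):
    """Barbed-end occupancy state.  Integer values index the generator matrix."""

    FREE = 0
    SPIRE_CAPPED = 1
    FORMIN_BOUND = 2


@dataclass(frozen=True)
class RateConstants:
    """Measured rate constants of the ping-pong scheme.

    Defaults are the single-filament microfluidics/TIRF measurements for
    Nt-Spire and the FH1-FH2 region of formin 2 at growing (ATP) barbed ends.
    Off-rates are independent of whether the partner protein transiently
    occupies the same end.
    """

    k_on_S_free: float = 2.7        # µM⁻¹s⁻¹, Spire association to B
    k_off_S: float = 0.0101         # s⁻¹, Spire dissociation (BS→B)
    k_on_F_free: float = 7.4e-3     # µM⁻¹s⁻¹, formin association to B
    k_off_F: float = 3.17e-3        # s⁻¹, formin dissociation (BF→B)
    k_on_S_displacing: float = 0.396  # µM⁻¹s⁻¹, Spire entry on BF (BF→BS)
    k_on_F_displacing: float = 0.29   # µM⁻¹s⁻¹, formin entry on BS (BS→BF)
    v_free_slope: float = 8.8       # subunits·s⁻¹ per µM PA, free-end growth
    v_formin_slope: float = 63.0    # subunits·s⁻¹ per µM PA, processive growth
    subunit_length_nm: float = 2.7  # nm added per subunit

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"rate constant {f.name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class Conditions:
    """Solution conditions: free Nt-Spire, formin, and profilin-actin, in µM."""

    spire_uM: float = 0.0
    formin_uM: float = 0.0
    pa_uM: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"concentration {f.name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class DerivedConstants:
    """Equilibrium and processivity quantities derived from the rate constants.

    Dwell times and run lengths refer to the formin-bound state; the *median*
    of the exponential dwell (ln2/k_off_F) is what matches the reported
    single-filament numbers, so both median and mean are carried explicitly.
    """

    K_S_nM: float                 # k_off_S / k_on_S_free
    K_F_nM: float                 # k_off_F / k_on_F_free
    fold_F_on_capped: float       # k'_+F / k_+F
    fold_S_on_formin: float       # k_+S / k'_+S
    median_dwell_BF_s: float
    mean_dwell_BF_s: float
    median_run_length_um: float   # at the pa_uM it was computed for
    pa_uM: float
    unbounded: bool = False       # true when k_off_F == 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def default_rate_constants() -> RateConstants:
    """Return the measured rate constants (the package defaults)."""
    return RateConstants()


def generator_matrix(rc: RateConstants, cond: Conditions) -> np.ndarray:
    """Infinitesimal generator Q of the three-state chain, rows indexed by EndState.

    Off-diagonal entries (s⁻¹)::

        B  → BS : k_on_S_free       * [S]
        B  → BF : k_on_F_free       * [F]
        BS → B  : k_off_S
        BS → BF : k_on_F_displacing * [F]
        BF → B  : k_off_F
        BF → BS : k_on_S_displacing * [S]

    Each diagonal entry closes its row to zero.
    """
    s, f = cond.spire_uM, cond.formin_uM
    Q = np.array(
        [
            [0.0, rc.k_on_S_free * s, rc.k_on_F_free * f],
            [rc.k_off_S, 0.0, rc.k_on_F_displacing * f],
            [rc.k_off_F, rc.k_on_S_displacing * s, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary probability vector π with π·Q = 0, Σπ = 1.

    For a reducible generator the stationary law of the closed communicating
    class is returned (states outside it get probability 0) and a
    ``ReducibleChainWarning``-style flag is not raised; reducibility is instead
    detectable from exact zeros in π.  An all-zero generator is rejected.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (3, 3):
        raise ValueError("expected a 3x3 generator")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("generator rows must sum to zero")
    if np.all(Q == 0.0):
        raise ValueError("no dynamics: all transition rates are zero")
    # Solve pi Q = 0 with the normalisation row appended; least squares copes
    # with the rank deficiency of reducible chains.
    A = np.vstack([Q.T, np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    # exact zeros for states that are transient (no inflow at stationarity)
    pi[pi < 1e-15] = 0.0
    residual = np.abs(pi @ Q).max()
    if residual > 1e-9 * max(1.0, np.abs(Q).max()):
        # reducible chains with several closed classes have no unique pi
        raise ValueError("stationary distribution did not converge (residual "
                         f"{residual:.2e}); generator may have multiple closed classes")
    return pi


def cycle_flux(rc: RateConstants, cond: Conditions) -> float:
    """Net stationary probability flux around the cycle B→BS→BF→B, in s⁻¹.

    Positive values mean the chain cycles in the ping-pong direction
    (capping by Spire, displacement by formin, spontaneous formin release).
    At stationarity the net flux is identical on every edge of the cycle;
    it vanishes exactly when the rates satisfy Kolmogorov's criterion
    (detailed balance), e.g. whenever [S] = 0 or [F] = 0.
    """
    Q = generator_matrix(rc, cond)
    pi = stationary_distribution(Q)
    b, bs = EndState.FREE, EndState.SPIRE_CAPPED
    return float(pi[b] * Q[b, bs] - pi[bs] * Q[bs, b])


def elongation_velocity(state: EndState, rc: RateConstants, cond: Conditions) -> float:
    """Barbed-end elongation velocity in subunits·s⁻¹ for a given occupancy state.

    Free ends grow at ``v_free_slope * [PA]``, formin-bound ends at
    ``v_formin_slope * [PA]``; Spire-capped ends are arrested (0).
    """
    if state == EndState.FREE:
        return rc.v_free_slope * cond.pa_uM
    if state == EndState.FORMIN_BOUND:
        return rc.v_formin_slope * cond.pa_uM
    if state == EndState.SPIRE_CAPPED:
        return 0.0
    raise ValueError(f"unknown state {state!r}")


def derived_constants(rc: RateConstants, pa_uM: float = 1.0) -> DerivedConstants:
    """Equilibrium constants, fold-changes, dwell times and processive run length.

    ``median_run_length_um = (ln2 / k_off_F) * v_formin_slope * pa_uM * subunit``:
    the length a formin-bound end assembles during the median of its
    exponential dwell.  A zero off-rate is flagged as an unbounded run.
    """
    if pa_uM <= 0:
        raise ValueError("pa_uM must be > 0")
    K_S = 1e3 * rc.k_off_S / rc.k_on_S_free
    K_F = 1e3 * rc.k_off_F / rc.k_on_F_free
    if rc.k_off_F > 0:
        mean_dwell = 1.0 / rc.k_off_F
        median_dwell = math.log(2.0) * mean_dwell
        run = median_dwell * rc.v_formin_slope * pa_uM * rc.subunit_length_nm / 1e3
        unbounded = False
    else:
        mean_dwell = median_dwell = run = math.inf
        unbounded = True
    return DerivedConstants(
        K_S_nM=K_S,
        K_F_nM=K_F,
        fold_F_on_capped=rc.k_on_F_displacing / rc.k_on_F_free,
        fold_S_on_formin=rc.k_on_S_free / rc.k_on_S_displacing,
        median_dwell_BF_s=median_dwell,
        mean_dwell_BF_s=mean_dwell,
        median_run_length_um=run,
        pa_uM=pa_uM,
        unbounded=unbounded,
    )


def occupancy_propagate(Q: np.ndarray, p0: np.ndarray, t: float) -> np.ndarray:
    """Propagate an initial law p0 to time t: p(t) = p0 · expm(Q t)."""
    return np.asarray(p0, float) @ scipy.linalg.expm(np.asarray(Q, float) * t)


# -- plain-text configuration (key = value, fixed units as in the docstrings) --

def save_config(path: str | Path, rc: RateConstants, cond: Conditions | None = None) -> None:
    """Write rate constants (and optionally conditions) as a ``key = value`` file."""
    lines = ["# spireformin configuration (uM, s, uM^-1 s^-1, nm)"]
    for f in fields(rc):
        lines.append(f"{f.name} = {getattr(rc, f.name)!r}")
    if cond is not None:
        for f in fields(cond):
            lines.append(f"{f.name} = {getattr(cond, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> tuple[RateConstants, Conditions]:
    """Read a ``key = value`` file written by :func:`save_config`.

    Missing keys fall back to the defaults, so partial configs are valid.
    """
    rc_names = {f.name for f in fields(RateConstants)}
    cond_names = {f.name for f in fields(Conditions)}
    rc_kw: dict[str, float] = {}
    cond_kw: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if key in rc_names:
            rc_kw[key] = float(val)
        elif key in cond_names:
            cond_kw[key] = float(val)
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return RateConstants(**rc_kw), Conditions(**cond_kw)
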