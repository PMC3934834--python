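"""Rate-constant and affinity inference from event tables and dose-response data.

The measurement designs all reduce to a few statistical primitives:

* censored exponential dwell fits (MLE, with a least-squares survival-curve
  compatibility mode mirroring single-exponential curve fitting of fraction
  data);
* pseudo-first-order regression of observed rates on concentration, through
  the origin;
* competing-risks likelihoods for the displacement experiments, where a
  filament prepared in one occupied state exits either by spontaneous
  dissociation or by direct displacement, with the displacement rate the only
  free parameter per concentration;
* the composite observed-rate correction for capping of formin-bound ends,
  where the transient free state is too short-lived to resolve and arrests
  via B are folded into the observed BF→BS rate;
* equilibrium binding isotherms (hyperbolic, or the exact two-component
  tight-binding quadratic) for dose-response tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .model import EndState, RateConstants

__all__ = [
    "FitResult",
    "fit_exponential_rate",
    "fit_second_order_rate",
    "kobs_capping_of_BF",
    "invert_kobs_capping_of_BF",
    "branch_model_uncapping",
    "fit_displacing_rate",
    "fit_binding_isotherm",
    "validate_event_table",
]

#: required columns of a transition-event table
EVENT_COLUMNS = ("filament_id", "initial_state", "destination", "waiting_time_s")


@dataclass
class FitResult:
    """Point estimate with uncertainty for a single fitted parameter."""

    estimate: float
    se: float
    ci: tuple[float, float]
    method: str
    n_used: int
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "method": self.method,
            "n_used": self.n_used,
            "converged": self.converged,
        }


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if (events["waiting_time_s"] <= 0).any():
        raise ValueError("waiting times must be > 0")
    return events


def fit_exponential_rate(
    waiting_times,
    censored=None,
    method: str = "mle",
    conf: float = 0.95,
) -> FitResult:
    """Fit the rate of an exponential waiting-time law with right censoring.

    MLE: k = (#uncensored events) / (sum of all waiting times, censored
    included); the exact closed form for censored exponential data.  The CI is
    lognormal-based (exact profile shape for this model): k·exp(±z/√d).

    ``method="ls"`` instead fits the empirical survival fraction to
    exp(−k t) by least squares, mirroring fraction-vs-time curve fitting;
    censored observations only contribute to the risk set.
    """
    t = np.asarray(waiting_times, float)
    c = np.zeros(len(t), bool) if censored is None else np.asarray(censored, bool)
    if len(t) == 0 or (t <= 0).any():
        raise ValueError("waiting times must be positive and non-empty")
    d = int((~c).sum())
    if d == 0:
        raise ValueError(
            "all observations are censored: only a lower bound on the rate "
            f"is identifiable (k < {scipy.stats.chi2.ppf(conf, 2) / (2 * t.sum()):.3g} s^-1)"
        )
    z = scipy.stats.norm.ppf(0.5 + conf / 2)
    if method == "mle":
        k = d / t.sum()
        se = k / np.sqrt(d)
        ci = (k * np.exp(-z / np.sqrt(d)), k * np.exp(z / np.sqrt(d)))
        return FitResult(k, se, ci, "MLE", len(t))
    if method == "ls":
        # Kaplan-Meier style survival at uncensored event times, fitted to exp(-kt)
        order = np.argsort(t)
        ts, cs = t[order], c[order]
        at_risk = len(ts)
        surv = 1.0
        xs, ys = [], []
        for ti, ci_ in zip(ts, cs):
            if not ci_:
                surv *= (at_risk - 1) / at_risk
                xs.append(ti)
                ys.append(surv)
            at_risk -= 1
        xs, ys = np.array(xs), np.array(ys)
        k0 = d / t.sum()
        popt, pcov = scipy.optimize.curve_fit(
            lambda x, k: np.exp(-k * x), xs, ys, p0=[k0], maxfev=10000
        )
        k = float(popt[0])
        se = float(np.sqrt(pcov[0, 0]))
        return FitResult(k, se, (k - z * se, k + z * se), "least-squares", len(t))
    raise ValueError(f"unknown method {method!r}")


def fit_second_order_rate(
    concentrations_uM,
    k_obs_values,
    through_origin: bool = True,
    weights=None,
    conf: float = 0.95,
) -> FitResult:
    """Slope of observed pseudo-first-order rate vs. concentration (µM⁻¹s⁻¹).

    Default is a (weighted) least-squares line through the origin, as the
    association rate constants are reported as slopes; ``through_origin=False``
    adds an intercept for diagnostics.

    When ``weights`` are supplied they are taken as known inverse variances of
    the k_obs values (the per-concentration fits report their own SEs), so the
    slope SE is the fixed-effects 1/√Σ(wᵢcᵢ²); without weights the SE comes
    from the residual scatter.
    """
    c = np.asarray(concentrations_uM, float)
    k = np.asarray(k_obs_values, float)
    known_var = weights is not None
    w = np.ones(len(c)) if weights is None else np.asarray(weights, float)
    if len(c) < (1 if through_origin else 2):
        raise ValueError("not enough points")
    if not through_origin and len(np.unique(c)) < 2:
        raise ValueError("rank deficient: all concentrations identical (need an intercept-free fit)")
    z = scipy.stats.norm.ppf(0.5 + conf / 2)
    if through_origin:
        sxx = np.sum(w * c * c)
        if sxx == 0:
            raise ValueError("all concentrations are zero")
        slope = float(np.sum(w * c * k) / sxx)
        if known_var:
            se = float(np.sqrt(1.0 / sxx))
        else:
            resid = k - slope * c
            dof = max(len(c) - 1, 1)
            sigma2 = float(np.sum(w * resid**2) / dof)
            se = float(np.sqrt(sigma2 / sxx)) if len(c) > 1 else float("nan")
        extra = {}
    else:
        X = np.column_stack([c, np.ones(len(c))])
        W = np.diag(w)
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * k, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])
        resid = k - X @ beta
        dof = max(len(c) - 2, 1)
        sigma2 = float(np.sum(w * resid**2) / dof)
        cov = sigma2 * np.linalg.inv(X.T @ W @ X)
        se = float(np.sqrt(cov[0, 0]))
        extra = {"intercept": intercept}
    return FitResult(slope, se, (slope - z * se, slope + z * se),
                     "weighted least-squares", len(c), extra=extra)


def kobs_capping_of_BF(k_prime_app: float, spire_uM: float, rc: RateConstants) -> float:
    """Observed arrest rate of formin-bound ends exposed to Spire.

    A formin-bound end reaches arrest either directly (rate k′app, the
    displacement rate at this Spire concentration) or via spontaneous formin
    release (k_off_F) followed by fast recapping — too fast to resolve, so both
    routes read out as one observed transition:

        k_obs = k_on_S_free·[S]·(k′app + k_off_F) / (k_on_S_free·[S] + k_off_F)
    """
    if k_prime_app < 0 or spire_uM < 0:
        raise ValueError("inputs must be >= 0")
    a = rc.k_on_S_free * spire_uM
    denom = a + rc.k_off_F
    if denom == 0:
        raise ValueError("k_on_S_free*[S] + k_off_F is zero: k_obs undefined")
    return a * (k_prime_app + rc.k_off_F) / denom


def invert_kobs_capping_of_BF(k_obs: float, spire_uM: float, rc: RateConstants) -> float:
    """Solve the composite-rate formula for k′app given an observed arrest rate."""
    a = rc.k_on_S_free * spire_uM
    if a == 0:
        raise ValueError("cannot invert at zero Spire concentration")
    return k_obs * (a + rc.k_off_F) / a - rc.k_off_F


def branch_model_uncapping(
    rc: RateConstants, formin_uM: float
) -> tuple[float, float, float]:
    """Loss of Spire capping in the presence of formin: rate and branch split.

    Capped ends are lost at total rate k_off_S + k′_+F·[F]; a fraction
    k_off_S/total exits to the free state and k′_+F·[F]/total is directly
    displaced into fast growth.  Returns (total_rate, fraction_to_B,
    fraction_to_BF); the fractions always sum to 1.
    """
    if formin_uM < 0:
        raise ValueError("formin_uM must be >= 0")
    displacing = rc.k_on_F_displacing * formin_uM
    total = rc.k_off_S + displacing
    if total == 0:
        return 0.0, 1.0, 0.0
    return total, rc.k_off_S / total, displacing / total


def fit_displacing_rate(
    events: pd.DataFrame,
    which: str,
    rc_known: RateConstants,
    conf: float = 0.95,
) -> FitResult:
    """Second-order displacement rate (k′_+S or k′_+F) from switch experiments.

    ``which``: ``"S_on_BF"`` (Spire flowed over formin-bound ends, events from
    initial FORMIN_BOUND, displaced destination SPIRE_CAPPED, concentration
    column ``spire_uM``) or ``"F_on_BS"`` (the converse).

    Per concentration, the competing-risks MLE of the displacement hazard is
    (#displaced events)/(Σ observed times) — exact for first-exit data where
    the only free parameter is the displacement rate, the spontaneous
    dissociation rate being known.  Per-concentration estimates are then
    regressed on concentration through the origin.
    """
    validate_event_table(events)
    if which == "S_on_BF":
        initial, displaced, conc_col = "FORMIN_BOUND", "SPIRE_CAPPED", "spire_uM"
    elif which == "F_on_BS":
        initial, displaced, conc_col = "SPIRE_CAPPED", "FORMIN_BOUND", "formin_uM"
    else:
        raise ValueError(f"which must be 'S_on_BF' or 'F_on_BS', got {which!r}")
    sel = events[events["initial_state"] == initial]
    if sel.empty:
        raise ValueError(f"no events with initial_state {initial}")
    if "censored" in sel.columns and sel["censored"].all():
        raise ValueError("all events censored: displacement rate unidentifiable")
    concs, rates, ses = [], [], []
    for conc, g in sel.groupby(conc_col):
        if conc == 0:
            continue
        d = int((g["destination"] == displaced).sum())
        T = float(g["waiting_time_s"].sum())
        concs.append(conc)
        if d == 0:
            # zero displaced events: point estimate 0 with a Poisson upper bound
            upper = scipy.stats.chi2.ppf(0.975, 2) / (2.0 * T)
            rates.append(0.0)
            ses.append(upper / scipy.stats.norm.ppf(0.975))
        else:
            rates.append(d / T)
            ses.append(d / T / np.sqrt(d))
    if not concs:
        raise ValueError("no usable concentrations (all at zero ligand)")
    w = 1.0 / np.square(ses)
    fit = fit_second_order_rate(concs, rates, through_origin=True, weights=w, conf=conf)
    fit.extra["per_concentration"] = {float(c): float(r) for c, r in zip(concs, rates)}
    fit.n_used = len(sel)
    return fit


def _occupancy(c, Kd, model, ends_nM):
    if model == "hyperbolic":
        return c / (c + Kd)
    if model == "quadratic_tight":
        e = ends_nM
        b = c + e + Kd
        return (b - np.sqrt(b * b - 4.0 * c * e)) / (2.0 * e)
    raise ValueError(f"unknown isotherm model {model!r}")


def fit_binding_isotherm(
    concentrations_nM,
    normalized_rates,
    model: str = "hyperbolic",
    direction: str = "inhibit",
    ends_nM: float | None = None,
    top: float = 1.0,
    conf: float = 0.95,
) -> FitResult:
    """Fit Kd (nM) and plateau from a normalized dose-response table.

    ``direction="inhibit"``: rate(c) = top − (top − plateau)·θ(c), starting at
    ``top`` (1 for rates normalized to the free-end value) and saturating at
    the plateau.  ``direction="activate"``: rate(c) = plateau·θ(c).
    θ is the hyperbolic occupancy c/(c+Kd), or the exact two-component
    tight-binding quadratic when the ends concentration is comparable to Kd
    (``model="quadratic_tight"`` with ``ends_nM``).
    """
    c = np.asarray(concentrations_nM, float)
    r = np.asarray(normalized_rates, float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if model == "quadratic_tight" and not ends_nM:
        raise ValueError("quadratic_tight requires ends_nM")

    if direction == "inhibit":
        def curve(x, Kd, plateau):
            return top - (top - plateau) * _occupancy(x, Kd, model, ends_nM)
        p0 = [np.median(c[c > 0]) if (c > 0).any() else 1.0, max(r.min(), 0.0)]
        bounds = ([1e-6, -0.5], [np.inf, top])
    elif direction == "activate":
        def curve(x, Kd, plateau):
            return plateau * _occupancy(x, Kd, model, ends_nM)
        p0 = [np.median(c[c > 0]) if (c > 0).any() else 1.0, r.max()]
        bounds = ([1e-6, 0.0], [np.inf, np.inf])
    else:
        raise ValueError(f"direction must be 'inhibit' or 'activate', got {direction!r}")

    converged = True
    try:
        popt, pcov = scipy.optimize.curve_fit(curve, c, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        converged = False
        popt, pcov = np.array(p0), np.full((2, 2), np.nan)
    Kd, plateau = float(popt[0]), float(popt[1])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    z = scipy.stats.norm.ppf(0.5 + conf / 2)
    return FitResult(Kd, se, (Kd - z * se, Kd + z * se), "least-squares", len(c),
                     converged=converged, extra={"plateau": plateau, "model": model,
                                                 "direction": direction})
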