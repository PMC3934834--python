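"""Closed-form models of the bulk assays.

Three pieces:

* dilution-induced depolymerization with multi-species barbed-end occupancy
  (equilibrium isotherms; rates normalized to 1 for free ends, of which a
  fraction ``f_barbed`` comes from barbed ends);
* the steady-state partition of unassembled actin between free G-actin and
  profilin-actin when barbed ends are capped or active;
* initial rates of seeded barbed-end growth as ends × stationary-occupancy-
  weighted elongation velocity.

The occupancy modelling is deliberately equilibrium-only: initial depolymer-
ization rates are read as snapshots of pre-equilibrated end occupancy, not as
time-resolved kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .model import Conditions, EndState, RateConstants, elongation_velocity, generator_matrix, stationary_distribution

__all__ = [
    "SpeciesBinding",
    "DepolyBindingModel",
    "SteadyStateParams",
    "depolymerization_rate",
    "steady_state_unassembled",
    "seeded_growth_rate",
    "kind_effect",
]


@dataclass(frozen=True)
class SpeciesBinding:
    """Equilibrium binding of one species to a class of barbed ends."""

    name: str
    Kd_nM: float
    barbed_inhibition: float  # fraction of barbed-end disassembly blocked at saturation
    mode: str = "cap"         # "cap" blocks disassembly, "uncap" restores the free-end rate

    def occupancy(self, conc_nM: float) -> float:
        if conc_nM < 0:
            raise ValueError("concentration must be >= 0")
        if math.isinf(conc_nM):
            return 1.0
        return conc_nM / (conc_nM + self.Kd_nM)


def _default_species() -> dict[str, SpeciesBinding]:
    # ADP-bound barbed ends; affinities from the depolymerization titrations.
    return {
        # FH1D-FH2 and FH2 bind free ADP ends equally tightly and block ~60%
        "formin": SpeciesBinding("formin", 6.0, 0.6),
        "fh2": SpeciesBinding("fh2", 6.0, 0.6),
        # Nt-Spire on free ends
        "spire": SpeciesBinding("spire", 9.0, 0.7),
        # Nt-Spire on a formin-occupied end: ~10-fold tighter, joint full block
        "spire_on_formin_end": SpeciesBinding("spire_on_formin_end", 0.75, 1.0),
        # KIND on FH1D-FH2-bound ends converts them to full caps
        "kind_on_fh1dfh2_end": SpeciesBinding("kind_on_fh1dfh2_end", 20.0, 1.0),
        # KIND on FH2-bound ends strips the formin: free-end behaviour restored
        "kind_on_fh2_end": SpeciesBinding("kind_on_fh2_end", 20.0, 0.0, mode="uncap"),
        # profilin shifts the formin affinities
        "formin_with_profilin": SpeciesBinding("formin_with_profilin", 1.5, 0.6),
        "fh2_with_profilin": SpeciesBinding("fh2_with_profilin", 20.0, 0.6),
    }


@dataclass(frozen=True)
class DepolyBindingModel:
    """Binding parameters for the dilution-induced depolymerization assay.

    ``f_barbed`` is the fraction of the total dilution-induced rate carried by
    barbed ends, back-calculated from the paired observation that a saturating
    formin halves the total rate while blocking about 60% of the barbed-end
    share: 0.5 = f_barbed × 0.6 → f_barbed ≈ 0.833.
    """

    f_barbed: float = 0.833
    species: dict[str, SpeciesBinding] = field(default_factory=_default_species)

    def __post_init__(self) -> None:
        if not (0 < self.f_barbed <= 1):
            raise ValueError("f_barbed must be in (0, 1]")
        for sp in self.species.values():
            if sp.Kd_nM <= 0 or not (0 <= sp.barbed_inhibition <= 1):
                raise ValueError(f"invalid binding record for {sp.name}")


def depolymerization_rate(
    model: DepolyBindingModel,
    species_concentrations_nM: dict[str, float],
    with_profilin: bool = False,
) -> float:
    """Normalized dilution-induced depolymerization rate (free ends = 1).

    rate = (1 − f_barbed) + f_barbed × (1 − inhibition), where the barbed-end
    inhibition combines the species occupancies:

    * a formin-type species ("formin" or "fh2") occupies a fraction θ_F of
      ends with inhibition 0.6;
    * "spire" occupies free ends (Kd 9 nM, inhibition 0.7) and formin-occupied
      ends with the ~10-fold enhanced affinity and joint full block;
    * "kind" acts only on formin-occupied ends: on FH1D-FH2 it completes the
      cap (inhibition 1), on FH2 it strips the formin and restores the free
      rate (inhibition 0).

    Spire and KIND on top of the same formin species are not combined (the
    assays add them separately).
    """
    conc = {k: float(v) for k, v in species_concentrations_nM.items()}
    unknown = set(conc) - {"formin", "fh2", "spire", "kind"}
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    if conc.get("formin", 0) > 0 and conc.get("fh2", 0) > 0:
        raise ValueError("specify only one formin-type species")
    if conc.get("spire", 0) > 0 and conc.get("kind", 0) > 0 and (
        conc.get("formin", 0) > 0 or conc.get("fh2", 0) > 0
    ):
        raise ValueError("spire and kind with a formin species are not modelled jointly")

    sp = model.species
    formin_kind = "formin" if conc.get("formin", 0) > 0 else (
        "fh2" if conc.get("fh2", 0) > 0 else None)
    if formin_kind is not None:
        key = f"{formin_kind}_with_profilin" if with_profilin else formin_kind
        frec = sp[key]
        theta_F = frec.occupancy(conc[formin_kind])
        inhib_F = frec.barbed_inhibition
    else:
        theta_F, inhib_F = 0.0, 0.0

    theta_S_free = sp["spire"].occupancy(conc.get("spire", 0.0))
    theta_S_on_F = sp["spire_on_formin_end"].occupancy(conc.get("spire", 0.0))

    if conc.get("kind", 0) > 0 and formin_kind is not None:
        krec = sp["kind_on_fh1dfh2_end" if formin_kind == "formin" else "kind_on_fh2_end"]
        theta_K = krec.occupancy(conc["kind"])
        kind_inhib = krec.barbed_inhibition if krec.mode == "cap" else 0.0
    else:
        theta_K, kind_inhib = 0.0, 0.0

    occupied_extra = theta_S_on_F * 1.0 + (1 - theta_S_on_F) * (
        theta_K * kind_inhib + (1 - theta_K) * inhib_F
    ) if formin_kind is not None else 0.0
    # KIND-stripped FH2 ends behave as free (inhibition already 0 above)
    inhibition = theta_F * occupied_extra + (1 - theta_F) * theta_S_free * sp["spire"].barbed_inhibition
    return (1.0 - model.f_barbed) + model.f_barbed * (1.0 - inhibition)


def kind_effect(target: str, kind_nM: float, model: DepolyBindingModel | None = None) -> dict:
    """Effect of the isolated KIND domain on formin-occupied barbed ends.

    On FH1D-FH2-bound ends KIND completes a full cap (occupancy at Kd 20 nM,
    inhibition → 1); on FH2-bound ends it strips the formin and restores
    free-end disassembly (inhibition → 0).  Returns the occupancy and the
    effective inhibition of the targeted end class, in the form used by
    :func:`depolymerization_rate`.
    """
    if kind_nM < 0:
        raise ValueError("kind_nM must be >= 0")
    model = model or DepolyBindingModel()
    if target == "FH1D_FH2":
        rec = model.species["kind_on_fh1dfh2_end"]
        base = model.species["formin"].barbed_inhibition
    elif target == "FH2":
        rec = model.species["kind_on_fh2_end"]
        base = model.species["fh2"].barbed_inhibition
    else:
        raise ValueError("target must be 'FH1D_FH2' or 'FH2'")
    theta = rec.occupancy(kind_nM)
    effective = theta * (rec.barbed_inhibition if rec.mode == "cap" else 0.0) + (1 - theta) * base
    return {"target": target, "occupancy": theta, "mode": rec.mode,
            "effective_inhibition": effective}


@dataclass(frozen=True)
class SteadyStateParams:
    """Parameters of the steady-state unassembled-actin partition (all µM).

    The defaults for K_P (profilin-actin dissociation constant) and the
    critical concentrations are literature-typical placeholders, not fitted
    values; override them per experiment.
    """

    P_total: float = 6.0
    K_P: float = 0.1
    A_cP: float = 0.6   # pointed-end critical concentration
    A_cB: float = 0.1   # barbed-end critical concentration
    A_total: float = 2.5

    def __post_init__(self) -> None:
        if min(self.P_total, self.K_P, self.A_cP, self.A_cB, self.A_total) < 0:
            raise ValueError("all parameters must be >= 0")
        if not self.A_cB < self.A_cP:
            raise ValueError("A_cB must be below A_cP")


def _mass_action_pa(P_total: float, A_unassembled: float, K_P: float) -> float:
    """Exact two-component PA complex concentration by mass action."""
    b = P_total + A_unassembled + K_P
    return (b - math.sqrt(b * b - 4.0 * P_total * A_unassembled)) / 2.0


def steady_state_unassembled(
    p: SteadyStateParams, all_ends_capped: bool
) -> dict[str, float | bool]:
    """Partition of actin at steady state among PA, free G-actin and F-actin.

    When every barbed end is capped, only pointed ends set the monomer level:
    G_free = A_cP and PA_ss = P_total·A_cP/(K_P + A_cP) — profilin acts as a
    sequestering protein.  With active barbed ends, G_free = A_cB and the
    analogous expression holds.  F-actin takes the mass balance remainder;
    if the closed form demands more unassembled actin than exists, F-actin is
    0 and PA is recomputed by exact mass action among profilin, total actin
    and K_P (flagged ``depleted``).
    """
    A_c = p.A_cP if all_ends_capped else p.A_cB
    G_free = A_c
    PA_ss = p.P_total * A_c / (p.K_P + A_c) if (p.K_P + A_c) > 0 else p.P_total
    F = p.A_total - G_free - PA_ss
    depleted = False
    if F < 0:
        depleted = True
        F = 0.0
        PA_ss = _mass_action_pa(p.P_total, p.A_total, p.K_P)
        G_free = p.A_total - PA_ss
    return {"PA_ss_uM": PA_ss, "G_free_uM": G_free, "F_actin_uM": F,
            "depleted": depleted}


def seeded_growth_rate(
    rc: RateConstants, cond: Conditions, ends_nM: float
) -> float:
    """Initial seeded-growth rate in µM of subunits per second.

    rate = [ends] × Σ_state π(state) × v(state), with π the stationary
    occupancy of the three-state model at the given Spire and formin
    concentrations.  Saturating Spire alone drives the rate to zero (all ends
    capped); adding formin restores growth via the formin-bound share.
    """
    if ends_nM < 0:
        raise ValueError("ends_nM must be >= 0")
    if cond.spire_uM == 0 and cond.formin_uM == 0:
        v_mean = elongation_velocity(EndState.FREE, rc, cond)
    else:
        pi = stationary_distribution(generator_matrix(rc, cond))
        v_mean = sum(
            pi[int(s)] * elongation_velocity(s, rc, cond) for s in EndState
        )
    return ends_nM * 1e-3 * v_mean
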