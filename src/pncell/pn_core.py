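"""Evaluation of the parallel-networks (PN) equation.

The PN-system groups, for every cell activity (CA) and every
pro-inflammatory cell state (CS), the stimulus→activity edges whose
stimulus acts on that state.  The activation of a CA is a bounded
semi-quantitative score

    ω_CA,CS = A · (1 − B)

with an activating term normalized against the whole system,

    A = ((1 + Σθ_α) / Σθ_α) · (S_α / (1 + S_α)),        S_α = Σ θ·x  (network, activating)

and an inhibiting term normalized against all inhibition converging on the
same activity,

    B = (Σθ_S,β / (Σθ_S,α + Σθ_S,β))
        · ((1 + Σθ_β^CA) / Σθ_β^CA)
        · (S_β / (1 + S_β)),                             S_β = Σ θ·x  (network, inhibiting)

where Σθ_α sums the weighting factors of *all* activating edges in the
PN-system (one count per unique stimulus→activity edge, the default; a
per-state-repeat count is available as a configuration switch), Σθ_S,α and
Σθ_S,β are the network's own weight sums, and Σθ_β^CA sums every inhibiting
weight converging on the activity regardless of cell state.  The
system-wide sums are what make activities comparable across the parallel
networks.  ω is clamped to [0, 1] and reported at 4 decimals.

Degenerate cases are made total: a network without activating edges yields
ω = 0, and an activity without any inhibiting weight has B = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .dose_response import DoseResponseCurve
from .sca_model import (
    CellActivityName,
    CellState,
    ConfigurationError,
    PN_ACTIVITIES,
    SCARelationship,
    Sign,
    Stimulus,
)

logger = logging.getLogger(__name__)

OMEGA_DECIMALS = 4


class GlobalSumMode(str, Enum):
    """How Σθ_α counts the system's activating edges."""

    UNIQUE_EDGES = "unique_edges"
    PER_STATE_REPEATS = "per_state_repeats"


class ThetaMode(str, Enum):
    """Individual calibrated weights vs. the invariant-0.01 comparison mode."""

    INDIVIDUAL = "individual"
    INVARIANT = "invariant_0.01"


@dataclass(frozen=True)
class PNSystem:
    """The full graph of calibrated PN-system relationships."""

    relationships: tuple[SCARelationship, ...]
    global_sum_mode: GlobalSumMode = GlobalSumMode.UNIQUE_EDGES

    def __post_init__(self) -> None:
        seen = set()
        for rel in self.relationships:
            if rel.theta is None:
                raise ConfigurationError(
                    f"relationship {rel.key} has no derived theta; calibrate first"
                )
            if rel.key in seen:
                raise ConfigurationError(f"duplicate edge {rel.key}")
            seen.add(rel.key)
        if not any(r.sign is Sign.ACTIVATING for r in self.relationships):
            raise ConfigurationError("PN-system needs at least one activating edge")

    def network(self, activity: CellActivityName, state: CellState) -> list[SCARelationship]:
        """Edges converging on ``activity`` whose stimulus acts on ``state``."""
        return [r for r in self.relationships
                if r.activity is activity and r.stimulus in state.active_stimuli]

    @property
    def theta_alpha_total(self) -> float:
        """Σθ_α over the system's activating edges (global normalization)."""
        total = 0.0
        for rel in self.relationships:
            if rel.sign is not Sign.ACTIVATING:
                continue
            if self.global_sum_mode is GlobalSumMode.UNIQUE_EDGES:
                total += rel.theta
            else:
                # one count per cell-state network the edge participates in
                n_states = sum(
                    1 for state in CellState
                    if rel.stimulus in state.active_stimuli
                )
                total += rel.theta * n_states
        return total

    def theta_beta_activity(self, activity: CellActivityName) -> float:
        """Σθ_β^CA: all inhibiting weights on ``activity``, independent of CS."""
        return sum(r.theta for r in self.relationships
                   if r.activity is activity and r.sign is Sign.INHIBITING)

    def with_invariant_theta(self, value: float = 0.01) -> "PNSystem":
        """Comparison system with every weighting factor replaced by ``value``."""
        from dataclasses import replace
        return PNSystem(
            tuple(replace(r, theta=value) for r in self.relationships),
            self.global_sum_mode,
        )


def pn_evaluate(
    system: PNSystem,
    activity: CellActivityName,
    state: CellState,
    x: Mapping[Stimulus, float],
    *,
    rounded: bool = True,
) -> float:
    """PN-activity ω_CA,CS for one network under sensitivities ``x``.

    ``x`` maps each stimulus of the (activity, state) network to its
    normalized sensitivity value in [0, 1].
    """
    edges = system.network(activity, state)
    for rel in edges:
        if rel.stimulus not in x:
            raise ConfigurationError(
                f"missing sensitivity value for edge {rel.key} "
                f"(state {state.value})"
            )
        xv = x[rel.stimulus]
        if not 0.0 <= xv <= 1.0:
            raise ConfigurationError(
                f"sensitivity for {rel.key} must lie in [0, 1], got {xv}"
            )

    activating = [r for r in edges if r.sign is Sign.ACTIVATING]
    inhibiting = [r for r in edges if r.sign is Sign.INHIBITING]

    if not activating:
        logger.warning(
            "network %s/%s has no activating edges; omega defined as 0",
            activity.value, state.value,
        )
        return 0.0

    theta_alpha_net = sum(r.theta for r in activating)
    theta_beta_net = sum(r.theta for r in inhibiting)
    s_alpha = sum(r.theta * x[r.stimulus] for r in activating)
    s_beta = sum(r.theta * x[r.stimulus] for r in inhibiting)

    g = system.theta_alpha_total
    a_term = ((1.0 + g) / g) * (s_alpha / (1.0 + s_alpha))

    theta_beta_ca = system.theta_beta_activity(activity)
    if theta_beta_net > 0.0 and theta_beta_ca > 0.0:
        b_term = (
            (theta_beta_net / (theta_alpha_net + theta_beta_net))
            * ((1.0 + theta_beta_ca) / theta_beta_ca)
            * (s_beta / (1.0 + s_beta))
        )
    else:
        b_term = 0.0

    omega = a_term * (1.0 - b_term)
    omega = min(max(omega, 0.0), 1.0)
    return round(omega, OMEGA_DECIMALS) if rounded else omega


@dataclass(frozen=True)
class CAProfile:
    """PN-activity of the five matrix/protease genes for one cell state."""

    cell_state: CellState
    activities: Mapping[CellActivityName, float]
    glucose: float
    ph: float
    theta_mode: ThetaMode

    def __post_init__(self) -> None:
        if set(self.activities) != set(PN_ACTIVITIES):
            raise ConfigurationError("profile must cover exactly the 5 PN activities")


def profile_all(
    system: PNSystem,
    glucose: float,
    ph: float,
    curves: Mapping[tuple[Stimulus, CellActivityName], DoseResponseCurve],
    cytokine_x: Mapping[Stimulus, float],
    theta_mode: ThetaMode = ThetaMode.INDIVIDUAL,
) -> list[CAProfile]:
    """CA profiles of all four cell states under one nutrient environment.

    ``cytokine_x`` supplies the normalized IL1β/TNF-α sensitivities produced
    by the inflammation submodel.  With ``theta_mode=INVARIANT`` every
    weighting factor is replaced by 0.01 before evaluation (the comparison
    experiment isolating the effect of stimulus-type calibration).
    """
    eval_system = (
        system if theta_mode is ThetaMode.INDIVIDUAL
        else system.with_invariant_theta()
    )
    for cyt in (Stimulus.IL1B, Stimulus.TNFA):
        if cyt not in cytokine_x:
            raise ConfigurationError(f"cytokine_x missing value for {cyt.value}")
    profiles = []
    for state in CellState:
        activities = {}
        for activity in PN_ACTIVITIES:
            x: dict[Stimulus, float] = {}
            for stim in state.active_stimuli:
                if stim in (Stimulus.GLUCOSE, Stimulus.PH):
                    key = (stim, activity)
                    if key not in curves:
                        raise ConfigurationError(
                            f"no dose-response curve for edge "
                            f"{stim.value}->{activity.value}"
                        )
                    conc = glucose if stim is Stimulus.GLUCOSE else ph
                    x[stim] = curves[key].evaluate(conc, rounded=False)
                else:
                    x[stim] = cytokine_x[stim]
            activities[activity] = pn_evaluate(eval_system, activity, state, x)
        profiles.append(CAProfile(state, activities, glucose, ph, theta_mode))
    return profiles


def profile_dispersion(profiles: Sequence[CAProfile]) -> float:
    """Across-state spread of a profile set.

    Maximum over activities of (max − min) of ω across the four cell
    states; the summary used to compare individual against invariant
    weighting.
    """
    out = 0.0
    for activity in PN_ACTIVITIES:
        vals = [p.activities[activity] for p in profiles]
        out = max(out, max(vals) - min(vals))
    return out
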