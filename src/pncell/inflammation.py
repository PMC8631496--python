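"""Inflammation submodel: cytokine mRNA activity, protein decay, immunopositivity.

Nutrients (glucose, pH) regulate the global — not cell-specific — normalized
mRNA activities ω_IL1β and ω_TNF-α through a small regulatory network that
reuses the PN-equation form with the submodel's own weight sums.  Because
the submodel reuses the PN-derived scaling factor, its pH→IL1β weight
exceeds 1 (θ = 2.8223); outputs are clamped to [0, 1].

Cytokine protein is synthesized proportionally to the mRNA activity and
decays exponentially with the published half-lives (IL1β 2 h, TNF-α 1 h) on
the 1-hour time step of the agent-based model:

    p(t + dt) = p(t) · 2^(−dt / t_half) + k_syn · ω

For constant ω the trajectory converges to k_syn·ω / (1 − 2^(−dt/t_half)).
The normalized protein level (relative to its ω = 1 steady state) is the
default carrier handed to the cytokine edges of the PN-system.

The fraction of immunopositive cells is an affine map of ω onto the ranges
reported for human NP tissue across degeneration grades: 10–59 % for IL1β
and 9–36 % for TNF-α (ω = 0 hits the floor, ω = 1 the ceiling, so pure
proportionality through zero — which would allow an unobserved 0 % — is
deliberately avoided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .dose_response import DoseResponseCurve
from .sca_model import (
    CellActivityName,
    ConfigurationError,
    SCARelationship,
    Sign,
    Stimulus,
)

logger = logging.getLogger(__name__)

#: model time step in hours, aligned with the shortest implementable half-life.
TIME_STEP_H = 1.0


@dataclass(frozen=True)
class CytokineParams:
    """Per-cytokine constants of the inflammation submodel."""

    name: Stimulus
    mrna_activity: CellActivityName
    half_life_h: float
    immunopositive_range: tuple[float, float]
    relationships: tuple[SCARelationship, ...]
    k_syn: float = 1.0

    def __post_init__(self) -> None:
        low, high = self.immunopositive_range
        if not (0.0 <= low < high <= 100.0):
            raise ConfigurationError(
                f"immunopositive range must satisfy 0 <= low < high <= 100, "
                f"got {self.immunopositive_range}"
            )
        if self.half_life_h < TIME_STEP_H:
            raise ConfigurationError(
                f"half-life {self.half_life_h} h shorter than the {TIME_STEP_H} h time step"
            )
        for rel in self.relationships:
            if rel.activity is not self.mrna_activity:
                raise ConfigurationError(
                    f"relationship {rel.key} does not belong to {self.name.value}"
                )
            if rel.theta is None:
                raise ConfigurationError(f"relationship {rel.key} lacks theta")

    @property
    def decay_factor(self) -> float:
        """Fraction of protein remaining after one time step."""
        return 2.0 ** (-TIME_STEP_H / self.half_life_h)

    @property
    def steady_state_max(self) -> float:
        """Protein level reached for sustained ω = 1 (geometric-series limit)."""
        return self.k_syn / (1.0 - self.decay_factor)


def default_cytokine_params(
    inflammation_rels: Sequence[SCARelationship], k_syn: float = 1.0
) -> dict[Stimulus, CytokineParams]:
    """The published IL1β/TNF-α constants bound to calibrated submodel edges."""
    groups: dict[CellActivityName, list[SCARelationship]] = {}
    for rel in inflammation_rels:
        groups.setdefault(rel.activity, []).append(rel)
    spec = {
        Stimulus.IL1B: (CellActivityName.IL1B_MRNA, 2.0, (10.0, 59.0)),
        Stimulus.TNFA: (CellActivityName.TNFA_MRNA, 1.0, (9.0, 36.0)),
    }
    out = {}
    for cyt, (activity, half_life, rng) in spec.items():
        rels = groups.get(activity)
        if not rels:
            raise ConfigurationError(f"no submodel relationships for {activity.value}")
        out[cyt] = CytokineParams(
            name=cyt, mrna_activity=activity, half_life_h=half_life,
            immunopositive_range=rng, relationships=tuple(rels), k_syn=k_syn,
        )
    return out


def cytokine_omega(
    params: CytokineParams,
    glucose: float,
    ph: float,
    curves: Mapping[tuple[Stimulus, CellActivityName], DoseResponseCurve],
) -> float:
    """Normalized mRNA activity of one cytokine under a nutrient environment.

    Single-node regulatory-network form with the submodel's own weight sums:
    ω = ((1+Σθ_α)/Σθ_α) · (Σθ·x / (1+Σθ·x)) · (1 − inhibition), clamped to
    [0, 1].  The shipped submodel has no inhibiting edges, so the
    inhibition term is 0 unless a user table adds one.
    """
    activating = [r for r in params.relationships if r.sign is Sign.ACTIVATING]
    inhibiting = [r for r in params.relationships if r.sign is Sign.INHIBITING]
    if not activating:
        logger.warning("%s submodel has no activating edges; omega = 0",
                       params.name.value)
        return 0.0

    def x_of(rel: SCARelationship) -> float:
        key = (rel.stimulus, rel.activity)
        if key not in curves:
            raise ConfigurationError(f"no dose-response curve for edge {rel.key}")
        conc = glucose if rel.stimulus is Stimulus.GLUCOSE else ph
        return curves[key].evaluate(conc, rounded=False)

    theta_a = sum(r.theta for r in activating)
    s_a = sum(r.theta * x_of(r) for r in activating)
    omega = ((1.0 + theta_a) / theta_a) * (s_a / (1.0 + s_a))
    if inhibiting:
        theta_b = sum(r.theta for r in inhibiting)
        s_b = sum(r.theta * x_of(r) for r in inhibiting)
        omega *= 1.0 - (
            (theta_b / (theta_a + theta_b))
            * ((1.0 + theta_b) / theta_b)
            * (s_b / (1.0 + s_b))
        )
    return min(max(omega, 0.0), 1.0)


def protein_step(
    protein: float, omega: float, params: CytokineParams, dt: float = TIME_STEP_H
) -> float:
    """One synthesis/decay update of the normalized protein level."""
    if dt <= 0:
        raise ValueError(f"time step must be positive, got {dt}")
    decay = 2.0 ** (-dt / params.half_life_h)
    return protein * decay + params.k_syn * omega


def simulate_protein(
    omega: float,
    params: CytokineParams,
    n_steps: int = 24,
    initial: float = 0.0,
) -> list[float]:
    """Protein trajectory for constant mRNA activity ``omega``."""
    levels = [float(initial)]
    for _ in range(n_steps):
        levels.append(protein_step(levels[-1], omega, params))
    return levels


def protein_steady_state(omega: float, params: CytokineParams) -> float:
    """Closed-form limit of the synthesis/decay recursion for constant ω."""
    return params.k_syn * omega / (1.0 - params.decay_factor)


def pct_immunopositive(params: CytokineParams, omega: float) -> float:
    """Percentage of immunopositive cells for a given mRNA activity.

    Affine (monotone, bijective) map [0, 1] → [low %, high %].
    """
    if not 0.0 <= omega <= 1.0:
        raise ConfigurationError(f"omega must lie in [0, 1], got {omega}")
    low, high = params.immunopositive_range
    return low + omega * (high - low)


@dataclass(frozen=True)
class InflammationState:
    """Submodel output for one nutrient environment."""

    omega_mrna: Mapping[Stimulus, float]
    protein: Mapping[Stimulus, float]
    pct_immunopositive: Mapping[Stimulus, float]
    cytokine_x: Mapping[Stimulus, float]


def evaluate_inflammation(
    cytokines: Mapping[Stimulus, CytokineParams],
    glucose: float,
    ph: float,
    curves: Mapping[tuple[Stimulus, CellActivityName], DoseResponseCurve],
    n_steps: int = 24,
    x_carrier: str = "protein",
) -> InflammationState:
    """Full submodel pass: ω, protein trajectory endpoint, %, cytokine x.

    ``x_carrier`` selects what the PN-system's cytokine edges consume:
    ``"protein"`` (default) hands over the protein level normalized by its
    ω = 1 steady state; ``"mRNA"`` hands over ω itself.
    """
    if x_carrier not in ("protein", "mRNA"):
        raise ConfigurationError(f"unknown cytokine x carrier {x_carrier!r}")
    omega, protein, pct, x = {}, {}, {}, {}
    for cyt, params in cytokines.items():
        w = cytokine_omega(params, glucose, ph, curves)
        traj = simulate_protein(w, params, n_steps=n_steps)
        omega[cyt] = w
        protein[cyt] = traj[-1]
        pct[cyt] = pct_immunopositive(params, w)
        if x_carrier == "protein":
            x[cyt] = min(1.0, traj[-1] / params.steady_state_max)
        else:
            x[cyt] = w
        logger.info(
            "%s: omega=%.4f protein=%.4f pct=%.2f%% x=%.4f",
            cyt.value, w, traj[-1], pct[cyt], x[cyt],
        )
    return InflammationState(omega, protein, pct, x)
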