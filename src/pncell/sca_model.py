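"""Stimulus–cell-activity (S-CA) relationships and weighting-factor calibration.

A nucleus pulposus (NP) cell is modelled as a black box that maps an
environmental stimulus (glucose, pH, or the pro-inflammatory cytokines IL1β
and TNF-α) onto a cell activity (CA): the normalized mRNA expression of one
of the matrix genes Agg, Col-I, Col-II or the proteases MMP3, ADAMTS4.  Each
directed stimulus→activity edge carries

* a sign (activating or inhibiting),
* a significance flag from the underlying in-vitro experiment,
* the maximal x-fold mRNA change ``ε`` observed over the physiological
  stimulus range, and
* a dimensionless weighting factor ``θ`` expressing the sensitivity of the
  activity to that stimulus *type*.

``θ`` is derived from ``ε`` through the *cellular effort* transform
``f(ε) = ε`` for ``ε ≥ 1`` and ``f(ε) = 1/ε`` for ``0 < ε < 1`` — a
symmetric magnitude of up-/down-regulation relative to the control level 1 —
scaled by the maximum effort found among the significant edges of the
PN-system so that ``0.01 ≤ θ ≤ 1`` there.  Non-significant edges are pinned
at ``θ = 0.01``, which approximates a linear coupling between the
dose–response value and the network output.  The inflammation submodel
(IL1β/TNF-α mRNA) reuses the PN-derived scaling factor, so its θ may
exceed 1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: θ assigned to statistically non-significant relationships.
THETA_NONSIGNIFICANT = 0.01

#: decimal places at which θ (and network activities) are reported.
THETA_DECIMALS = 4


class PNCellError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PNCellError):
    """Invalid or inconsistent model configuration."""


class ParseError(PNCellError):
    """A delimited input table could not be parsed."""


class Stimulus(str, Enum):
    """Environmental stimuli acting on NP cells.

    Glucose and pH are user-defined first-order stimuli; the cytokines are
    second-order stimuli whose levels are produced by the inflammation
    submodel.
    """

    GLUCOSE = "glucose"
    PH = "pH"
    IL1B = "IL1B"
    TNFA = "TNFA"

    @property
    def order(self) -> int:
        return 1 if self in (Stimulus.GLUCOSE, Stimulus.PH) else 2


class CellActivityName(str, Enum):
    """Modelled mRNA expressions (cell activities)."""

    AGG = "Agg"
    COL1 = "ColI"
    COL2 = "ColII"
    MMP3 = "MMP3"
    ADAMTS4 = "ADAMTS4"
    # inflammation submodel only:
    IL1B_MRNA = "IL1B_mRNA"
    TNFA_MRNA = "TNFA_mRNA"


#: the five activities that form the PN-system proper.
PN_ACTIVITIES: tuple[CellActivityName, ...] = (
    CellActivityName.AGG,
    CellActivityName.COL1,
    CellActivityName.COL2,
    CellActivityName.MMP3,
    CellActivityName.ADAMTS4,
)

#: activities belonging to the inflammation submodel.
INFLAMMATION_ACTIVITIES: tuple[CellActivityName, ...] = (
    CellActivityName.IL1B_MRNA,
    CellActivityName.TNFA_MRNA,
)


class CellState(str, Enum):
    """Pro-inflammatory cell state, defined by cytokine immunopositivity."""

    NONINFLAMED = "noninflamed"
    IL1B_POS = "IL1B_pos"
    TNFA_POS = "TNFA_pos"
    IL1B_TNFA_POS = "IL1B_TNFA_pos"

    @property
    def active_stimuli(self) -> frozenset[Stimulus]:
        """Stimuli that act on this state's networks.

        Non-inflamed cells respond to nutrients only; immunopositive cells
        are additionally stimulated by the cytokine(s) they stain for.
        """
        base = {Stimulus.GLUCOSE, Stimulus.PH}
        if self in (CellState.IL1B_POS, CellState.IL1B_TNFA_POS):
            base.add(Stimulus.IL1B)
        if self in (CellState.TNFA_POS, CellState.IL1B_TNFA_POS):
            base.add(Stimulus.TNFA)
        return frozenset(base)


class Sign(str, Enum):
    ACTIVATING = "activating"
    INHIBITING = "inhibiting"


def cellular_effort(epsilon: float) -> float:
    """Symmetric magnitude of an x-fold mRNA change relative to control.

    Returns ``epsilon`` when ``epsilon >= 1`` and ``1/epsilon`` otherwise, so
    that an n-fold increase and an n-fold decrease carry the same effort.
    The name carries no mechanistic meaning.

    Raises
    ------
    ValueError
        If ``epsilon`` is not strictly positive (fold-changes are ratios).
    """
    if not epsilon > 0:
        raise ValueError(f"fold-change must be > 0, got {epsilon!r}")
    return float(epsilon) if epsilon >= 1.0 else 1.0 / float(epsilon)


@dataclass(frozen=True)
class SCARelationship:
    """One stimulus→cell-activity edge of the regulatory graph."""

    stimulus: Stimulus
    activity: CellActivityName
    sign: Sign
    significant: bool
    epsilon: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.significant:
            if self.epsilon is None:
                raise ConfigurationError(
                    f"significant edge {self.stimulus.value}->{self.activity.value} "
                    "requires an x-fold change epsilon"
                )
            if not self.epsilon > 0:
                raise ConfigurationError(
                    f"epsilon must be > 0 for {self.stimulus.value}->{self.activity.value}"
                )

    @property
    def effort(self) -> float | None:
        """Cellular effort ``f(ε)``; undefined for non-significant edges."""
        if not self.significant or self.epsilon is None:
            return None
        return cellular_effort(self.epsilon)

    @property
    def in_pn_system(self) -> bool:
        return self.activity in PN_ACTIVITIES

    @property
    def key(self) -> tuple[str, str]:
        return (self.stimulus.value, self.activity.value)


@dataclass(frozen=True)
class ScalingFactor:
    """Constant ``ϑ_θmax`` that maps efforts onto the θ range [0.01, 1].

    Equals the maximum cellular effort over all significant PN-system edges;
    the edge attaining it receives θ = 1 exactly.  The same constant is
    reused for the inflammation submodel, whose θ may then exceed 1.
    """

    value: float
    source: SCARelationship

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ConfigurationError("scaling factor must be > 0")


def derive_scaling_factor(relationships: Sequence[SCARelationship]) -> ScalingFactor:
    """Maximum cellular effort among significant PN-system relationships.

    Inflammation-submodel rows are excluded: the submodel reuses the
    PN-derived constant rather than defining its own.
    """
    candidates = [r for r in relationships if r.significant and r.in_pn_system]
    if not candidates:
        raise ConfigurationError(
            "cannot derive a scaling factor: no significant PN-system relationship"
        )
    best = max(candidates, key=lambda r: (r.effort, r.key))
    logger.info(
        "scaling factor %.4f from %s->%s",
        best.effort, best.stimulus.value, best.activity.value,
    )
    return ScalingFactor(value=float(best.effort), source=best)


def derive_theta(rel: SCARelationship, scaling: ScalingFactor) -> float:
    """Weighting factor θ of one edge, reported at 4-decimal resolution.

    Significant edges: ``θ = f(ε) / ϑ_θmax`` (round half to even at the 4th
    decimal, the resolution at which θ tables are printed and consumed).
    Non-significant edges: θ = 0.01 regardless of ε.
    """
    if not rel.significant:
        return THETA_NONSIGNIFICANT
    return round(rel.effort / scaling.value, THETA_DECIMALS)


def calibrate(relationships: Sequence[SCARelationship]) -> tuple[list[SCARelationship], ScalingFactor]:
    """Derive θ for every relationship using the PN-system scaling factor.

    Returns new relationship instances with ``theta`` set, plus the scaling
    factor itself.  PN-system θ are checked against the design range
    [0.01, 1]; inflammation-submodel θ are allowed to exceed 1.
    """
    scaling = derive_scaling_factor(relationships)
    out = []
    for rel in relationships:
        theta = derive_theta(rel, scaling)
        if rel.in_pn_system and not (THETA_NONSIGNIFICANT <= theta <= 1.0):
            raise ConfigurationError(
                f"PN-system theta out of range for {rel.stimulus.value}->"
                f"{rel.activity.value}: {theta}"
            )
        out.append(replace(rel, theta=theta))
    return out, scaling


# ---------------------------------------------------------------------------
# table I/O

_TABLE_COLUMNS = ("stimulus", "activity", "sign", "significant", "epsilon")

_TRUTHY = {"true", "1", "yes", "y"}
_FALSY = {"false", "0", "no", "n"}


def _parse_row(row: dict[str, str], lineno: int) -> SCARelationship:
    try:
        stimulus = Stimulus(row["stimulus"].strip())
    except ValueError:
        raise ParseError(f"row {lineno}: unknown stimulus {row['stimulus']!r}")
    try:
        activity = CellActivityName(row["activity"].strip())
    except ValueError:
        raise ParseError(f"row {lineno}: unknown activity {row['activity']!r}")
    sign_raw = (row.get("sign") or "").strip().lower()
    if sign_raw in ("act", "activating"):
        sign = Sign.ACTIVATING
    elif sign_raw in ("inh", "inhibiting"):
        sign = Sign.INHIBITING
    else:
        raise ParseError(f"row {lineno}: missing or unknown sign {row.get('sign')!r}")
    sig_raw = (row.get("significant") or "").strip().lower()
    if sig_raw in _TRUTHY:
        significant = True
    elif sig_raw in _FALSY:
        significant = False
    else:
        raise ParseError(f"row {lineno}: significant must be boolean, got {sig_raw!r}")
    eps_raw = (row.get("epsilon") or "").strip()
    epsilon: float | None = None
    if eps_raw not in ("", "-", "—", "NA", "nan"):
        try:
            epsilon = float(eps_raw)
        except ValueError:
            raise ParseError(f"row {lineno}: epsilon not numeric: {eps_raw!r}")
        if not epsilon > 0:
            raise ParseError(f"row {lineno}: epsilon must be > 0, got {epsilon}")
    try:
        return SCARelationship(stimulus, activity, sign, significant, epsilon)
    except ConfigurationError as exc:
        raise ParseError(f"row {lineno}: {exc}")


def load_relationship_table(path: str | Path) -> list[SCARelationship]:
    """Read an S-CA relationship table (CSV).

    Expected header: ``stimulus,activity,sign,significant,epsilon``.  θ is
    not derived here; call :func:`calibrate` afterwards.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty relationship table")
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        rels = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    if not rels:
        raise ConfigurationError(f"{path}: no relationship rows")
    seen: set[tuple[str, str]] = set()
    for rel in rels:
        if rel.key in seen:
            raise ParseError(f"{path}: duplicate edge {rel.key}")
        seen.add(rel.key)
    return rels


def default_table_path(name: str) -> Path:
    """Path of a parameter table shipped with the package."""
    return Path(resources.files("pncell").joinpath("tables", name))


def load_default_relationships() -> list[SCARelationship]:
    """The shipped PN-system (20 edges) plus inflammation submodel (4 edges)."""
    pn = load_relationship_table(default_table_path("table1_pn.csv"))
    infl = load_relationship_table(default_table_path("table3_inflammation.csv"))
    return pn + infl


def export_theta_table(
    relationships: Iterable[SCARelationship], path: str | Path
) -> None:
    """Write the derived-parameter table (ε, f(ε), θ) as CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stimulus", "activity", "sign", "significant",
                         "epsilon", "effort", "theta"])
        for rel in relationships:
            writer.writerow([
                rel.stimulus.value,
                rel.activity.value,
                rel.sign.value,
                str(rel.significant).lower(),
                "" if rel.epsilon is None else f"{rel.epsilon:g}",
                "" if rel.effort is None else f"{rel.effort:.4f}",
                "" if rel.theta is None else f"{rel.theta:.4f}",
            ])
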