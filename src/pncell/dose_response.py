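"""Normalized stimulus-concentration sensitivity curves ``x_S^CA``.

Each stimulus→activity edge carries a continuous, monotone dose–response
curve that maps a stimulus concentration within its physiological range
(glucose 0–5 mM, pH 6.5–7.4) onto a normalized sensitivity ``x ∈ [0, 1]``.
``x`` encodes the *strength of the edge's effect*: for pH edges it grows
with acidity (the stressor), for glucose edges with glucose availability.
The activating/inhibiting sign of the edge is applied downstream by the
network equation, not here.

Curves are calibrated from discrete anchor points by least-squares fitting
of a four-parameter logistic (floor, ceiling, midpoint, steepness), then
rescaled so that the infimum over the range is exactly 0 and the supremum
exactly 1.  Fitting is deterministic: the initial guess is read off the
anchor endpoints, and no stochastic search is involved.  The shipped anchor
tables are phenomenological normalizations assembled from the experimental
designs underlying the relationship tables (glucose levels 0–5 mM with
half-effect below 1 mM; pH levels spanning 6.5–7.4 with gene-specific
midpoints); they can be overridden per edge via configuration.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .sca_model import (
    CellActivityName,
    ConfigurationError,
    ParseError,
    Stimulus,
    default_table_path,
)

logger = logging.getLogger(__name__)

#: physiological stimulus ranges; concentrations outside are clamped.
STIMULUS_RANGES: dict[Stimulus, tuple[float, float]] = {
    Stimulus.GLUCOSE: (0.0, 5.0),
    Stimulus.PH: (6.5, 7.4),
}

X_DECIMALS = 4


class CalibrationError(ConfigurationError):
    """Anchor points cannot be represented by a monotone sigmoid."""


@dataclass(frozen=True)
class AnchorPoint:
    """One experimental anchor: stimulus concentration → normalized response."""

    concentration: float
    normalized_response: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.normalized_response <= 1.0:
            raise ConfigurationError(
                f"anchor response must lie in [0, 1], got {self.normalized_response}"
            )


def _four_pl(c: np.ndarray, floor: float, ceil: float, mid: float, steep: float) -> np.ndarray:
    """4-parameter logistic; monotone in c for any parameter values."""
    return floor + (ceil - floor) * expit((c - mid) / steep)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Monotone sigmoid ``x_S^CA`` over a physiological concentration range.

    ``evaluate`` returns values normalized to span [0, 1] across the range
    (the raw logistic floor/ceiling are rescaled away), rounded at the
    4-decimal working resolution of the network model.
    """

    stimulus: Stimulus
    activity: CellActivityName
    c_min: float
    c_max: float
    anchors: tuple[AnchorPoint, ...]
    floor: float
    ceiling: float
    midpoint: float
    steepness: float

    @property
    def increasing(self) -> bool:
        return self.ceiling >= self.floor

    def _raw(self, c: np.ndarray | float) -> np.ndarray | float:
        return _four_pl(np.asarray(c, dtype=float), self.floor, self.ceiling,
                        self.midpoint, self.steepness)

    def evaluate(self, concentration: float, *, rounded: bool = True) -> float:
        """Normalized sensitivity at ``concentration``.

        Out-of-range concentrations are clamped to the range endpoints (the
        network equation requires x ∈ [0, 1], so no extrapolation), with a
        logged warning.
        """
        c = float(concentration)
        if c < self.c_min or c > self.c_max:
            logger.warning(
                "%s->%s: concentration %g outside [%g, %g]; clamping",
                self.stimulus.value, self.activity.value, c, self.c_min, self.c_max,
            )
            c = min(max(c, self.c_min), self.c_max)
        f0 = float(self._raw(self.c_min))
        f1 = float(self._raw(self.c_max))
        lo, hi = min(f0, f1), max(f0, f1)
        if math.isclose(lo, hi):
            x = 0.0
        else:
            x = (float(self._raw(c)) - lo) / (hi - lo)
        x = min(max(x, 0.0), 1.0)
        return round(x, X_DECIMALS) if rounded else x

    def residual(self) -> float:
        """Root-mean-square misfit of the normalized curve at its anchors."""
        err = [self.evaluate(a.concentration, rounded=False) - a.normalized_response
               for a in self.anchors]
        return float(np.sqrt(np.mean(np.square(err))))


def _monotone_direction(anchors: Sequence[AnchorPoint]) -> int:
    """+1 for increasing, -1 for decreasing anchor sequences.

    Duplicate concentrations are averaged first; a sequence that is not
    monotone after averaging (beyond a small tolerance) is rejected.
    """
    by_c: dict[float, list[float]] = {}
    for a in anchors:
        by_c.setdefault(a.concentration, []).append(a.normalized_response)
    cs = sorted(by_c)
    ys = [float(np.mean(by_c[c])) for c in cs]
    diffs = np.diff(ys)
    tol = 1e-9
    if np.all(diffs >= -tol):
        return 1
    if np.all(diffs <= tol):
        return -1
    raise CalibrationError(
        "anchor sequence is not consistent with a monotone curve: "
        + ", ".join(f"({c:g}, {y:g})" for c, y in zip(cs, ys))
    )


def fit_curve(
    anchors: Sequence[AnchorPoint],
    c_range: tuple[float, float],
    stimulus: Stimulus = Stimulus.GLUCOSE,
    activity: CellActivityName = CellActivityName.AGG,
) -> DoseResponseCurve:
    """Least-squares monotone 4PL through anchor points.

    The fitted raw logistic is subsequently normalized to [0, 1] over
    ``c_range`` by :meth:`DoseResponseCurve.evaluate`; the residuals being
    minimized are those of the normalized curve, so the reported fit is the
    curve actually used downstream.
    """
    c_min, c_max = float(c_range[0]), float(c_range[1])
    if not c_min < c_max:
        raise ConfigurationError(f"invalid range [{c_min}, {c_max}]")
    distinct = {a.concentration for a in anchors}
    if len(distinct) < 2:
        raise CalibrationError("need at least 2 anchors with distinct concentrations")
    for a in anchors:
        if not c_min <= a.concentration <= c_max:
            raise ConfigurationError(
                f"anchor concentration {a.concentration} outside range [{c_min}, {c_max}]"
            )
    direction = _monotone_direction(anchors)

    span = c_max - c_min
    cs = np.array([a.concentration for a in anchors])
    ys = np.array([a.normalized_response for a in anchors])

    def normalized(params: np.ndarray, c: np.ndarray) -> np.ndarray:
        raw = _four_pl(c, *params)
        f0 = float(_four_pl(np.array(c_min), *params))
        f1 = float(_four_pl(np.array(c_max), *params))
        lo, hi = min(f0, f1), max(f0, f1)
        if abs(hi - lo) < 1e-12:
            return np.zeros_like(c)
        return (raw - lo) / (hi - lo)

    def resid(params: np.ndarray) -> np.ndarray:
        return normalized(params, cs) - ys

    # deterministic initial guess from the anchor endpoints
    if direction > 0:
        p0 = np.array([0.0, 1.0, (c_min + c_max) / 2.0, span / 5.0])
    else:
        p0 = np.array([1.0, 0.0, (c_min + c_max) / 2.0, span / 5.0])
    bounds = (
        [-10.0, -10.0, c_min - span, 1e-3 * span],
        [10.0, 10.0, c_max + span, 10.0 * span],
    )
    sol = least_squares(resid, p0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    floor, ceiling, mid, steep = (float(v) for v in sol.x)
    if direction > 0 and ceiling < floor:
        floor, ceiling = ceiling, floor  # keep declared direction
    curve = DoseResponseCurve(
        stimulus=stimulus, activity=activity, c_min=c_min, c_max=c_max,
        anchors=tuple(sorted(anchors, key=lambda a: a.concentration)),
        floor=floor, ceiling=ceiling, midpoint=mid, steepness=steep,
    )
    logger.info(
        "fitted %s->%s: midpoint=%.4f steepness=%.4f rms=%.2e",
        stimulus.value, activity.value, mid, steep, curve.residual(),
    )
    return curve


# ---------------------------------------------------------------------------
# anchor-table I/O

def load_anchor_table(path: str | Path) -> dict[tuple[Stimulus, CellActivityName], list[AnchorPoint]]:
    """Read a CSV of anchors keyed by (stimulus, activity)."""
    path = Path(path)
    out: dict[tuple[Stimulus, CellActivityName], list[AnchorPoint]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"stimulus", "activity", "concentration", "normalized_response"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ParseError(f"{path}: expected columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                stim = Stimulus(row["stimulus"].strip())
                act = CellActivityName(row["activity"].strip())
                anchor = AnchorPoint(float(row["concentration"]),
                                     float(row["normalized_response"]))
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path} row {i}: {exc}")
            out.setdefault((stim, act), []).append(anchor)
    if not out:
        raise ConfigurationError(f"{path}: no anchor rows")
    return out


def build_curves(
    anchor_sets: dict[tuple[Stimulus, CellActivityName], list[AnchorPoint]],
) -> dict[tuple[Stimulus, CellActivityName], DoseResponseCurve]:
    """Fit one curve per (stimulus, activity) anchor set."""
    curves = {}
    for (stim, act), anchors in anchor_sets.items():
        if stim not in STIMULUS_RANGES:
            raise ConfigurationError(
                f"no concentration range defined for stimulus {stim.value}; "
                "cytokine sensitivities come from the inflammation submodel"
            )
        curves[(stim, act)] = fit_curve(anchors, STIMULUS_RANGES[stim], stim, act)
    return curves


def load_default_curves() -> dict[tuple[Stimulus, CellActivityName], DoseResponseCurve]:
    """Curves fitted to the anchor tables shipped with the package."""
    return build_curves(load_anchor_table(default_table_path("anchors_default.csv")))
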