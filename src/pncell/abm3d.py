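"""3D agent-based multicellular model of pro-inflammatory cell clusters.

A 1 mm³ nucleus pulposus sub-volume is populated with 4,000 spherical cell
agents of 10 µm diameter at uniformly random, non-overlapping positions
(≈ 0.2 % volume fraction, the average NP cell density).  For each cytokine,
a fixed number of agents is drawn as nucleation points (15 IL1β + 15 TNF-α
by default) and immunopositive clusters are grown around them: at every
step the non-inflamed agent with the globally shortest Euclidean distance
to any already-inflamed agent acquires the cytokine flag, until the target
count — round(%, immunopositive × n_agents) — is reached.  The two growth
processes are independent, so an agent claimed by both ends up
double-positive; the overlap of the two marked sets is exactly the
double-positive population.

Positions are static (no motility, division or death); domain walls are
hard boundaries.  All stochasticity comes from placement and nucleation
sampling, so a fixed seed reproduces a run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .sca_model import CellState, ConfigurationError, PNCellError, Stimulus

logger = logging.getLogger(__name__)

DEFAULT_N_AGENTS = 4000
DEFAULT_DOMAIN_UM = 1000.0
AGENT_DIAMETER_UM = 10.0
DEFAULT_SEEDS_PER_CYTOKINE = 15


class PlacementError(PNCellError):
    """Non-overlapping placement failed within the attempt budget."""


@dataclass
class ABMWorld:
    """Positioned cell agents with per-cytokine immunopositivity flags."""

    positions: np.ndarray            # (n, 3) µm
    domain_um: float
    seed: int
    il1b: np.ndarray = field(default=None)  # bool flags per agent
    tnfa: np.ndarray = field(default=None)
    nucleation: dict[Stimulus, np.ndarray] = field(default_factory=dict)
    growth_distances: dict[Stimulus, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.il1b is None:
            self.il1b = np.zeros(n, dtype=bool)
        if self.tnfa is None:
            self.tnfa = np.zeros(n, dtype=bool)

    @property
    def n_agents(self) -> int:
        return len(self.positions)

    def flags(self, cytokine: Stimulus) -> np.ndarray:
        if cytokine is Stimulus.IL1B:
            return self.il1b
        if cytokine is Stimulus.TNFA:
            return self.tnfa
        raise ConfigurationError(f"not a cytokine: {cytokine.value}")

    def state_of(self, i: int) -> CellState:
        if self.il1b[i] and self.tnfa[i]:
            return CellState.IL1B_TNFA_POS
        if self.il1b[i]:
            return CellState.IL1B_POS
        if self.tnfa[i]:
            return CellState.TNFA_POS
        return CellState.NONINFLAMED

    def content_hash(self) -> str:
        """Digest of positions and flags; equal hashes ⇒ identical worlds."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.positions).tobytes())
        h.update(self.il1b.tobytes())
        h.update(self.tnfa.tobytes())
        return h.hexdigest()


def place_agents(
    n: int = DEFAULT_N_AGENTS,
    domain_um: float = DEFAULT_DOMAIN_UM,
    seed: int = 0,
    min_distance_um: float = AGENT_DIAMETER_UM,
    max_attempts_per_agent: int = 200,
) -> ABMWorld:
    """Uniform random non-overlapping placement (center distance ≥ diameter).

    Rejection sampling against the already-accepted agents; deterministic
    for a fixed seed.  At the modelled density rejections are rare, but a
    bounded attempt budget guards against unsatisfiable configurations.
    """
    if n < 1:
        raise ConfigurationError("need at least one agent")
    expected_fill = n * (4.0 / 3.0) * math.pi * (min_distance_um / 2) ** 3
    if expected_fill > 0.3 * domain_um**3:
        raise PlacementError(
            f"requested density too high: {n} agents with spacing "
            f"{min_distance_um} µm in {domain_um} µm cube"
        )
    rng = np.random.default_rng(seed)
    positions = np.empty((n, 3), dtype=float)
    count = 0
    budget = n * max_attempts_per_agent
    d2 = min_distance_um**2
    while count < n:
        if budget <= 0:
            raise PlacementError(
                f"placement failed after attempt budget; placed {count}/{n}"
            )
        budget -= 1
        candidate = rng.uniform(0.0, domain_um, size=3)
        if count:
            delta = positions[:count] - candidate
            if np.min(np.einsum("ij,ij->i", delta, delta)) < d2:
                continue
        positions[count] = candidate
        count += 1
    return ABMWorld(positions=positions, domain_um=domain_um, seed=seed)


def select_nucleation(
    world: ABMWorld,
    rng: np.random.Generator,
    seeds_per_cytokine: int = DEFAULT_SEEDS_PER_CYTOKINE,
) -> None:
    """Randomly pick the nucleation agents: one disjoint draw per cytokine.

    Draws 2 × seeds_per_cytokine distinct agents and splits them between
    IL1β and TNF-α, mirroring the 30-out-of-4,000 selection.
    """
    total = 2 * seeds_per_cytokine
    if total > world.n_agents:
        raise ConfigurationError(
            f"{total} nucleation points exceed {world.n_agents} agents"
        )
    chosen = rng.choice(world.n_agents, size=total, replace=False)
    world.nucleation[Stimulus.IL1B] = np.sort(chosen[:seeds_per_cytokine])
    world.nucleation[Stimulus.TNFA] = np.sort(chosen[seeds_per_cytokine:])


def grow_clusters(world: ABMWorld, cytokine: Stimulus, target_count: int) -> ABMWorld:
    """Grow immunopositive clusters to exactly ``target_count`` agents.

    The marked set starts from the cytokine's nucleation points and is
    extended one agent at a time by the globally shortest distance from any
    marked to any unmarked agent (single marked set across all clusters of
    the cytokine).  Ties break on the lowest agent id.  The distance at
    which each agent joined is recorded for auditing; the sequence is the
    greedy nearest-first order.
    """
    if cytokine not in world.nucleation:
        raise ConfigurationError(f"no nucleation points for {cytokine.value}")
    if target_count > world.n_agents:
        raise ConfigurationError(
            f"target {target_count} exceeds {world.n_agents} agents"
        )
    seeds = world.nucleation[cytokine]
    if target_count < len(seeds):
        raise ConfigurationError(
            f"target {target_count} below {len(seeds)} nucleation points"
        )
    marked = world.flags(cytokine)
    marked[:] = False
    marked[seeds] = True

    # dmin[i]: distance from unmarked agent i to the nearest marked agent
    pos = world.positions
    dmin = np.full(world.n_agents, np.inf)
    unmarked = ~marked
    for s in seeds:
        d = np.linalg.norm(pos - pos[s], axis=1)
        np.minimum(dmin, d, out=dmin)
    dmin[marked] = np.inf

    added_distances = []
    for _ in range(target_count - len(seeds)):
        nxt = int(np.argmin(dmin))  # first occurrence = lowest id on ties
        added_distances.append(float(dmin[nxt]))
        marked[nxt] = True
        d = np.linalg.norm(pos - pos[nxt], axis=1)
        np.minimum(dmin, d, out=dmin)
        dmin[marked] = np.inf
    world.growth_distances[cytokine] = np.array(added_distances)
    return world


@dataclass(frozen=True)
class RunSummary:
    """Counts and percentages of the four cell-state classes for one run."""

    n_agents: int
    counts: Mapping[CellState, int]
    seed: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_agents:
            raise ConfigurationError("state counts must partition all agents")

    @property
    def percentages(self) -> dict[CellState, float]:
        return {s: 100.0 * c / self.n_agents for s, c in self.counts.items()}

    def total_positive(self, cytokine: Stimulus) -> int:
        """Single-positive plus double-positive count for one cytokine."""
        single = (CellState.IL1B_POS if cytokine is Stimulus.IL1B
                  else CellState.TNFA_POS)
        return self.counts[single] + self.counts[CellState.IL1B_TNFA_POS]


def classify_states(world: ABMWorld) -> RunSummary:
    """Partition agents into the four cell-state classes."""
    double = world.il1b & world.tnfa
    counts = {
        CellState.NONINFLAMED: int(np.sum(~world.il1b & ~world.tnfa)),
        CellState.IL1B_POS: int(np.sum(world.il1b & ~world.tnfa)),
        CellState.TNFA_POS: int(np.sum(world.tnfa & ~world.il1b)),
        CellState.IL1B_TNFA_POS: int(np.sum(double)),
    }
    return RunSummary(n_agents=world.n_agents, counts=counts, seed=world.seed)


def target_count(pct: float, n_agents: int) -> int:
    """Immunopositive cell count implied by a percentage (nearest integer)."""
    if not 0.0 <= pct <= 100.0:
        raise ConfigurationError(f"percentage must lie in [0, 100], got {pct}")
    return int(round(pct / 100.0 * n_agents))


def run_once(
    pct_by_cytokine: Mapping[Stimulus, float],
    n_agents: int = DEFAULT_N_AGENTS,
    domain_um: float = DEFAULT_DOMAIN_UM,
    seeds_per_cytokine: int = DEFAULT_SEEDS_PER_CYTOKINE,
    seed: int = 0,
) -> tuple[ABMWorld, RunSummary]:
    """Place agents, seed and grow both cytokine cluster sets, classify."""
    world = place_agents(n_agents, domain_um, seed)
    rng = np.random.default_rng((seed, 1))
    select_nucleation(world, rng, seeds_per_cytokine)
    for cyt in (Stimulus.IL1B, Stimulus.TNFA):
        grow_clusters(world, cyt, target_count(pct_by_cytokine[cyt], n_agents))
    return world, classify_states(world)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and 95% confidence interval per class over replicate runs."""

    n_runs: int
    mean: Mapping[CellState, float]
    sd: Mapping[CellState, float]
    ci95: Mapping[CellState, tuple[float, float]]
    runs: tuple[RunSummary, ...]


def summarize_replicates(runs: Sequence[RunSummary]) -> ReplicateSummary:
    """Descriptive statistics (mean, SD, 95% t-interval) across runs."""
    if not runs:
        raise ConfigurationError("need at least one run to summarize")
    n = len(runs)
    mean, sd, ci = {}, {}, {}
    for state in CellState:
        vals = np.array([r.counts[state] for r in runs], dtype=float)
        mean[state] = float(np.mean(vals))
        if n < 2:
            logger.warning("single run: no confidence interval")
            sd[state] = 0.0
            ci[state] = (mean[state], mean[state])
        else:
            sd[state] = float(np.std(vals, ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd[state] / math.sqrt(n)
            ci[state] = (mean[state] - half, mean[state] + half)
    return ReplicateSummary(n_runs=n, mean=mean, sd=sd, ci95=ci, runs=tuple(runs))


def replicate_runs(
    pct_by_cytokine: Mapping[Stimulus, float],
    n_runs: int = 10,
    base_seed: int = 0,
    n_agents: int = DEFAULT_N_AGENTS,
    domain_um: float = DEFAULT_DOMAIN_UM,
    seeds_per_cytokine: int = DEFAULT_SEEDS_PER_CYTOKINE,
) -> ReplicateSummary:
    """Independent runs with seeds base_seed … base_seed + n_runs − 1."""
    runs = []
    for k in range(n_runs):
        _, summary = run_once(
            pct_by_cytokine, n_agents, domain_um, seeds_per_cytokine,
            seed=base_seed + k,
        )
        runs.append(summary)
    return summarize_replicates(runs)


# ---------------------------------------------------------------------------
# snapshots and plots

def write_snapshot(world: ABMWorld, path: str | Path) -> None:
    """World snapshot as CSV: id, position, flags, derived state."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id,x_um,y_um,z_um,il1b,tnfa,state\n")
        for i in range(world.n_agents):
            x, y, z = world.positions[i]
            fh.write(
                f"{i},{x:.3f},{y:.3f},{z:.3f},"
                f"{int(world.il1b[i])},{int(world.tnfa[i])},"
                f"{world.state_of(i).value}\n"
            )


def write_metadata(world: ABMWorld, path: str | Path, extra: dict | None = None) -> None:
    meta = {
        "seed": world.seed,
        "n_agents": world.n_agents,
        "domain_um": world.domain_um,
        "content_hash": world.content_hash(),
        "nucleation": {k.value: v.tolist() for k, v in world.nucleation.items()},
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def plot_world(world: ABMWorld, path: str | Path) -> None:
    """3D scatter of the inflammatory environment (red IL1β, purple TNF-α,
    green double-positive, grey non-inflamed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    masks = {
        "noninflamed": (~world.il1b & ~world.tnfa, "0.8", 3),
        "IL1B": (world.il1b & ~world.tnfa, "red", 8),
        "TNFA": (world.tnfa & ~world.il1b, "purple", 8),
        "both": (world.il1b & world.tnfa, "green", 12),
    }
    for label, (mask, color, size) in masks.items():
        pts = world.positions[mask]
        if len(pts):
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=size, c=color,
                       label=label, alpha=0.6 if label == "noninflamed" else 0.9)
    ax.set_xlabel("x [µm]")
    ax.set_ylabel("y [µm]")
    ax.set_zlabel("z [µm]")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
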