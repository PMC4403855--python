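"""Stochastic model of a growing, folding filament of pole-to-pole attached cells.

The filament is a single chain of rod cells living in a fixed 1x1 arena. It starts
as a horizontal line of N cells at the bottom edge (y = 0) with both filament ends
pinned, as if attached to the colony. Each update step picks one cell uniformly at
random and attempts one event:

* **elongation** — the cell grows by a rate drawn from Uniform(0, G) toward a
  randomly chosen neighbor, pushing that neighbor away; a cell whose length then
  exceeds the maximum cell size S immediately divides into two equal daughters
  (division never changes the filament's shape);
* **turning** — a new local configuration is generated by rotating the pole shared
  with a randomly chosen neighbor by an angle beta ~ Normal(0, B) about that
  neighbor's far pole; the move is adopted only when it lowers the bending energy

      V = (pi - alpha_1)^2 + (pi - alpha_2)^2,

  where alpha_1, alpha_2 are the angles the focal cell makes with its left and
  right neighbors (pi = perfectly aligned), and then with probability

      P = 1 - exp(-k (V_c - V_n)),

  k being the bending rigidity: stiffer filaments convert an energy drop into a
  re-alignment more readily and therefore fold less.

Cells may never overlap (non-adjacent segments keep a clearance of at least the
cell width w) and no node may leave the unit square. Colony migration is read out
as the maximum advance of the filament along y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import clearance_ok, seg_seg_dist
from .geometry import circle_intersection, interior_angle, rotate_about, segment_to_segments_distance

__all__ = [
    "SimParams",
    "FilamentState",
    "JunctionAngles",
    "TurnProposal",
    "Trajectory",
    "ConditionComparison",
    "potential_energy",
    "turn_probability",
    "init_filament",
    "elongate",
    "divide",
    "propose_turn",
    "step",
    "run",
    "migration_extent",
    "compare_conditions",
    "default_conditions",
]

_PI = math.pi


@dataclass(frozen=True)
class SimParams:
    """All knobs of the filament model.

    N, T, G, S, B and k are the model's own symbols; the remaining fields
    (cell width ``w``, event mix ``p_turn``, initial length ``L0``, ``seed``)
    close gaps the model statement leaves open and are fully exposed here.
    """

    N: int = 20                # initial cell count
    T: int = 200_000           # number of update steps
    G: float = 0.004           # maximal elongation rate per step (domain units)
    S: float = 0.04            # maximum cell length (domain units)
    B: float = 0.15            # sd of the turning angle beta (radians)
    k: float = 0.5             # bending rigidity (dimensionless, >= 0)
    w: float = 0.005           # clearance width for the overlap test (domain units)
    p_turn: float = 0.5        # probability an update attempts a turn (else elongation)
    L0: float = 0.02           # initial cell length (domain units)
    seed: int = 0              # RNG seed

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not self.G >= 0.0:
            raise ValueError("G must be >= 0")
        if not (0.0 < self.L0 <= self.S <= 1.0):
            raise ValueError("need 0 < L0 <= S <= 1")
        if not self.B > 0.0:
            raise ValueError("B must be > 0")
        if self.k < 0.0:
            raise ValueError("k must be >= 0")
        if not (0.0 <= self.p_turn <= 1.0):
            raise ValueError("p_turn must be in [0, 1]")
        if self.w < 0.0:
            raise ValueError("w must be >= 0")
        if self.N * self.L0 > 1.0 + 1e-12:
            raise ValueError("initial filament does not fit the unit domain (N*L0 > 1)")


@dataclass
class JunctionAngles:
    """Interior angles (radians) a focal cell makes with its two neighbors.

    ``None`` marks an undefined side (the cell sits at a pinned filament end).
    pi means a perfectly straight junction.
    """

    alpha1: Optional[float]
    alpha2: Optional[float]


@dataclass
class TurnProposal:
    """One candidate re-orientation of a focal cell and its energy bookkeeping."""

    cell_idx: int
    side: str                      # "left" | "right": which neighbor was rotated
    beta: float                    # drawn turning angle (radians)
    candidate: dict                # node index -> proposed (x, y); empty if infeasible
    v_current: float
    v_new: float
    feasible: bool
    reason: str = ""               # why an infeasible proposal failed


class FilamentState:
    """Ordered chain of pole nodes; cell ``i`` spans nodes ``i`` and ``i+1``.

    The first and last node are pinned for the whole simulation. Node
    coordinates live in a preallocated array so division (node insertion)
    stays cheap.
    """

    __slots__ = ("_nodes", "_n_nodes", "step_count")

    def __init__(self, nodes: np.ndarray, step_count: int = 0):
        nodes = np.asarray(nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2 or nodes.shape[0] < 3:
            raise ValueError("nodes must be an (n>=3, 2) array")
        cap = max(64, 2 * nodes.shape[0])
        self._nodes = np.empty((cap, 2), dtype=float)
        self._nodes[: nodes.shape[0]] = nodes
        self._n_nodes = nodes.shape[0]
        self.step_count = int(step_count)

    # -- views -----------------------------------------------------------
    @property
    def nodes(self) -> np.ndarray:
        """Read-only view of the live node coordinates, shape (n_nodes, 2)."""
        v = self._nodes[: self._n_nodes]
        v.flags.writeable = False
        return v

    @property
    def n_nodes(self) -> int:
        return self._n_nodes

    @property
    def n_cells(self) -> int:
        return self._n_nodes - 1

    def cell_lengths(self) -> np.ndarray:
        n = self._nodes[: self._n_nodes]
        return np.hypot(np.diff(n[:, 0]), np.diff(n[:, 1]))

    def arc_length(self) -> float:
        return float(self.cell_lengths().sum())

    def copy(self) -> "FilamentState":
        return FilamentState(self._nodes[: self._n_nodes].copy(), self.step_count)

    def __eq__(self, other):
        return (
            isinstance(other, FilamentState)
            and self._n_nodes == other._n_nodes
            and bool(np.array_equal(self.nodes, other.nodes))
        )

    # -- geometry helpers --------------------------------------------------
    def _node(self, i: int):
        return (self._nodes[i, 0], self._nodes[i, 1])

    def junction_angles(self, cell_idx: int, overrides: Optional[dict] = None) -> JunctionAngles:
        """Angles the given cell makes with its left and right neighbors.

        ``overrides`` maps node indices to candidate coordinates, letting a
        proposal be scored without mutating the state.
        """
        if not 0 <= cell_idx < self.n_cells:
            raise IndexError(f"cell index {cell_idx} out of range")

        def pos(i):
            if overrides and i in overrides:
                return overrides[i]
            return self._node(i)

        a1 = None
        a2 = None
        if cell_idx >= 1:
            a1 = interior_angle(pos(cell_idx - 1), pos(cell_idx), pos(cell_idx + 1))
        if cell_idx <= self.n_cells - 2:
            a2 = interior_angle(pos(cell_idx), pos(cell_idx + 1), pos(cell_idx + 2))
        return JunctionAngles(a1, a2)

    def check_invariants(self, params: SimParams, rtol: float = 1e-9) -> None:
        """Full-state audit; raises AssertionError on any violation."""
        n = self.nodes
        assert n.shape[0] >= 3
        assert np.all(n >= -1e-12) and np.all(n <= 1.0 + 1e-12), "node outside unit domain"
        lens = self.cell_lengths()
        assert np.all(lens > 0.0), "zero-length cell"
        assert np.all(lens <= params.S * (1.0 + rtol) + 1e-15), "cell longer than S"
        # non-adjacent clearance, full O(n^2) sweep
        a = n[:-1]
        b = n[1:]
        m = len(a)
        for i in range(m):
            if i + 2 >= m:
                break
            d = segment_to_segments_distance(a[i], b[i], a[i + 2:], b[i + 2:])
            assert float(d.min()) >= params.w * (1.0 - 1e-9), (
                f"clearance violation at cell {i}: {float(d.min()):.3e} < w={params.w}"
            )

    # -- candidate legality ------------------------------------------------
    def _candidate_legal(self, candidate: dict, params: SimParams,
                         split_cell: Optional[int] = None) -> bool:
        """Domain + overlap test for a proposed set of node moves.

        ``candidate`` maps node index -> new (x, y); the touched node indices
        are contiguous for every local event here. When ``split_cell`` is
        given, that cell is tested in its post-division form (two daughter
        segments around the midpoint), so an elongation whose triggered
        division would break the clearance rule is rejected up front.

        Adjacency is by shared chain nodes: segments that share a node are
        exempt from the clearance requirement, everything else must stay at
        least ``w`` apart.
        """
        for (x, y) in candidate.values():
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                return False
        if params.w <= 0.0:
            return True

        idx = sorted(candidate)
        lo = max(0, idx[0] - 1)
        hi = min(self.n_cells - 1, idx[-1])  # inclusive block of touched cells

        nodes = self._nodes

        def pos(i):
            if i in candidate:
                return candidate[i]
            return (nodes[i, 0], nodes[i, 1])

        # candidate segments replacing cells lo..hi; ids = chain node indices
        # each segment touches (-1 marks a division midpoint)
        segs = []
        for c in range(lo, hi + 1):
            p = pos(c)
            q = pos(c + 1)
            if split_cell is not None and c == split_cell:
                mid = ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)
                segs.append((p, mid, (c, -1)))
                segs.append((mid, q, (-1, c + 1)))
            else:
                segs.append((p, q, (c, c + 1)))

        nn = self._n_nodes
        for (p, q, ids) in segs:
            extras = []
            for m in ids:
                if m >= 0:
                    for adj in (m - 1, m):
                        if not lo <= adj <= hi and adj not in extras:
                            extras.append(adj)
            e1 = extras[0] if len(extras) > 0 else -9
            e2 = extras[1] if len(extras) > 1 else -9
            if not clearance_ok(nodes, nn, p[0], p[1], q[0], q[1], lo, hi, e1, e2, params.w):
                return False

        # pairs inside the block that do not share an endpoint
        for i in range(len(segs)):
            pi, qi, ii = segs[i]
            for j in range(i + 1, len(segs)):
                pj, qj, jj = segs[j]
                if set(ii) & set(jj):
                    continue
                if seg_seg_dist(pi[0], pi[1], qi[0], qi[1], pj[0], pj[1], qj[0], qj[1]) < params.w:
                    return False
        return True

    def _apply(self, candidate: dict) -> None:
        for i, (x, y) in candidate.items():
            self._nodes[i, 0] = x
            self._nodes[i, 1] = y

    def _insert_node(self, after: int, pos) -> None:
        """Insert a node after index ``after`` (i.e., at index after+1)."""
        if self._n_nodes == self._nodes.shape[0]:
            grown = np.empty((2 * self._nodes.shape[0], 2), dtype=float)
            grown[: self._n_nodes] = self._nodes[: self._n_nodes]
            self._nodes = grown
        i = after + 1
        self._nodes[i + 1: self._n_nodes + 1] = self._nodes[i: self._n_nodes]
        self._nodes[i, 0] = pos[0]
        self._nodes[i, 1] = pos[1]
        self._n_nodes += 1


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def potential_energy(alpha1: Optional[float], alpha2: Optional[float]) -> float:
    """Bending energy V = (pi - alpha1)^2 + (pi - alpha2)^2 of a cell's junctions.

    Angles are in radians, each in (0, pi]; ``None`` marks the missing junction
    of an end cell and contributes zero. Straight junctions (alpha = pi) store
    no energy.
    """
    v = 0.0
    for a in (alpha1, alpha2):
        if a is None:
            continue
        if not (0.0 < a <= _PI + 1e-12):
            raise ValueError(f"junction angle {a!r} outside (0, pi]")
        v += (_PI - a) ** 2
    return v


def turn_probability(v_current: float, v_new: float, k: float) -> float:
    """Probability that a proposed re-orientation is adopted.

    Zero unless the move lowers the energy; otherwise 1 - exp(-k (V_c - V_n)),
    increasing in both the rigidity k and the energy drop.
    """
    if k < 0.0:
        raise ValueError("k must be >= 0")
    drop = v_current - v_new
    if drop <= 0.0:
        return 0.0
    return 1.0 - math.exp(-k * drop)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def init_filament(params: SimParams) -> FilamentState:
    """N collinear cells of length L0 along y = 0, centered at x = 0.5."""
    total = params.N * params.L0
    if total > 1.0 + 1e-12:
        raise ValueError("initial filament does not fit the unit domain (N*L0 > 1)")
    x0 = 0.5 - total / 2.0
    xs = x0 + params.L0 * np.arange(params.N + 1)
    nodes = np.column_stack([xs, np.zeros(params.N + 1)])
    return FilamentState(nodes)


def _try_elongate(state: FilamentState, cell_idx: int, rate: float, toward: str,
                  params: SimParams) -> bool:
    """In-place elongation attempt; returns True when the move was applied.

    The focal cell's pole shared with the chosen neighbor is pushed outward
    along the focal axis by ``rate`` (the neighbor is pushed away); the
    neighbor's other pole is then relocated by circle intersection so that the
    neighbor's and the next cell's lengths are conserved. Growth toward a
    pinned filament end is a rejection, as are moves that leave the domain,
    lose the circle intersection, or break the overlap clearance. Division is
    applied automatically when the focal cell ends up longer than S.
    """
    n_cells = state.n_cells
    if not 0 <= cell_idx < n_cells:
        raise IndexError(f"cell index {cell_idx} out of range")
    if toward not in ("left", "right"):
        raise ValueError("toward must be 'left' or 'right'")
    if rate <= 0.0:
        return False

    if toward == "right":
        # shared pole = cell_idx+1, relocated pole = cell_idx+2, anchor = cell_idx+3
        if cell_idx > n_cells - 3:
            return False  # no right neighbor, or its far pole is the pinned end
        far = state._node(cell_idx)
        shared_i = cell_idx + 1
        reloc_i = cell_idx + 2
        anchor_i = cell_idx + 3
    else:
        if cell_idx < 2:
            return False
        far = state._node(cell_idx + 1)
        shared_i = cell_idx
        reloc_i = cell_idx - 1
        anchor_i = cell_idx - 2

    shared = state._node(shared_i)
    reloc_old = state._node(reloc_i)
    anchor = state._node(anchor_i)

    focal_len = math.hypot(shared[0] - far[0], shared[1] - far[1])
    neigh_len = math.hypot(reloc_old[0] - shared[0], reloc_old[1] - shared[1])
    next_len = math.hypot(anchor[0] - reloc_old[0], anchor[1] - reloc_old[1])

    new_len = focal_len + rate
    ux = (shared[0] - far[0]) / focal_len
    uy = (shared[1] - far[1]) / focal_len
    new_shared = (far[0] + new_len * ux, far[1] + new_len * uy)

    pts = circle_intersection(new_shared, neigh_len, anchor, next_len)
    if pts is None:
        return False
    d0 = math.hypot(pts[0][0] - reloc_old[0], pts[0][1] - reloc_old[1])
    d1 = math.hypot(pts[1][0] - reloc_old[0], pts[1][1] - reloc_old[1])
    new_reloc = pts[0] if d0 <= d1 else pts[1]

    candidate = {shared_i: new_shared, reloc_i: new_reloc}
    will_divide = new_len > params.S
    if not state._candidate_legal(candidate, params,
                                  split_cell=cell_idx if will_divide else None):
        return False
    state._apply(candidate)

    if will_divide:
        divide(state, cell_idx, params)
    return True


def elongate(state: FilamentState, cell_idx: int, rate: float, toward: str,
             params: SimParams) -> FilamentState:
    """Functional elongation: returns a new state (unchanged on rejection)."""
    out = state.copy()
    _try_elongate(out, cell_idx, rate, toward, params)
    return out


def divide(state: FilamentState, cell_idx: int, params: SimParams) -> FilamentState:
    """Split a cell longer than S into two equal daughters (in place).

    A node is inserted at the cell midpoint; no existing node moves, so the
    filament shape (and total arc length) is exactly conserved.
    """
    if not 0 <= cell_idx < state.n_cells:
        raise IndexError(f"cell index {cell_idx} out of range")
    a = state._node(cell_idx)
    b = state._node(cell_idx + 1)
    length = math.hypot(b[0] - a[0], b[1] - a[1])
    if length <= params.S:
        raise ValueError(f"cell {cell_idx} has length {length:.4g} <= S={params.S}; nothing to divide")
    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    state._insert_node(cell_idx, mid)
    return state


def propose_turn(state: FilamentState, cell_idx: int, rng: np.random.Generator,
                 params: SimParams) -> TurnProposal:
    """Draw beta ~ Normal(0, B) and build the candidate re-orientation.

    One neighbor of the focal cell is chosen uniformly; the pole the focal cell
    shares with it is rotated by beta about that neighbor's far pole (rigidly
    re-orienting the neighbor), and the focal cell's other pole is relocated by
    circle intersection to conserve the focal and other-neighbor lengths.
    Geometry-breaking candidates are flagged infeasible, not errors.
    """
    n_cells = state.n_cells
    if not 0 <= cell_idx < n_cells:
        raise IndexError(f"cell index {cell_idx} out of range")

    sides = []
    if cell_idx >= 1:
        sides.append("left")
    if cell_idx <= n_cells - 2:
        sides.append("right")
    side = sides[int(rng.integers(len(sides)))] if len(sides) > 1 else sides[0]
    beta = float(rng.normal(0.0, params.B))

    ja = state.junction_angles(cell_idx)
    v_c = potential_energy(ja.alpha1, ja.alpha2)

    if side == "right":
        shared_i = cell_idx + 1
        pivot_i = cell_idx + 2
        other_i = cell_idx
        other_anchor_i = cell_idx - 1   # may not exist (cell 0)
    else:
        shared_i = cell_idx
        pivot_i = cell_idx - 1
        other_i = cell_idx + 1
        other_anchor_i = cell_idx + 2

    def infeasible(reason):
        return TurnProposal(cell_idx, side, beta, {}, v_c, math.inf, False, reason)

    pivot = state._node(pivot_i)
    shared = state._node(shared_i)
    new_shared = rotate_about(shared, pivot, beta)

    other_old = state._node(other_i)
    focal_len = math.hypot(shared[0] - other_old[0], shared[1] - other_old[1])

    if (side == "right" and cell_idx == 0) or (side == "left" and cell_idx == n_cells - 1):
        # the focal cell's other pole is a pinned filament end and cannot be
        # relocated; the rotation would change the focal length, so bail out
        new_focal = math.hypot(new_shared[0] - other_old[0], new_shared[1] - other_old[1])
        if abs(new_focal - focal_len) > 1e-12 * max(1.0, focal_len):
            return infeasible("pinned end blocks length restoration")
        candidate = {shared_i: new_shared}
    else:
        anchor = state._node(other_anchor_i)
        other_len = math.hypot(other_old[0] - anchor[0], other_old[1] - anchor[1])
        pts = circle_intersection(new_shared, focal_len, anchor, other_len)
        if pts is None:
            return infeasible("no circle intersection")
        d0 = math.hypot(pts[0][0] - other_old[0], pts[0][1] - other_old[1])
        d1 = math.hypot(pts[1][0] - other_old[0], pts[1][1] - other_old[1])
        new_other = pts[0] if d0 <= d1 else pts[1]
        candidate = {shared_i: new_shared, other_i: new_other}

    if not state._candidate_legal(candidate, params):
        return infeasible("domain or overlap violation")

    ja_new = state.junction_angles(cell_idx, overrides=candidate)
    v_n = potential_energy(ja_new.alpha1, ja_new.alpha2)
    return TurnProposal(cell_idx, side, beta, candidate, v_c, v_n, True)


def step(state: FilamentState, params: SimParams, rng: np.random.Generator) -> FilamentState:
    """One update: pick a random cell, then attempt a turn (prob. p_turn) or an
    elongation with automatic division. Mutates and returns ``state``."""
    cell_idx = int(rng.integers(state.n_cells))
    if float(rng.random()) < params.p_turn:
        prop = propose_turn(state, cell_idx, rng, params)
        if prop.feasible:
            p = turn_probability(prop.v_current, prop.v_new, params.k)
            if p > 0.0 and float(rng.random()) < p:
                state._apply(prop.candidate)
    else:
        rate = float(rng.uniform(0.0, params.G))
        toward = "left" if float(rng.random()) < 0.5 else "right"
        _try_elongate(state, cell_idx, rate, toward, params)
    state.step_count += 1
    return state


def migration_extent(state: FilamentState) -> float:
    """Colony-front advance: the maximum node y over the filament."""
    return float(state.nodes[:, 1].max())


@dataclass
class Trajectory:
    """Recorded course of one simulation run."""

    steps: np.ndarray              # recorded step indices
    migration: np.ndarray          # migration extent at each recorded step
    n_cells: np.ndarray
    arc_length: np.ndarray
    final_state: FilamentState
    params: SimParams

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "migration_extent": self.migration,
                "n_cells": self.n_cells,
                "arc_length": self.arc_length,
            }
        )


def run(params: SimParams, record_every: Optional[int] = None,
        validate_every: int = 0) -> Trajectory:
    """Run T steps from the initial line and record the migration readout.

    ``record_every`` sets the recording cadence (default: ~200 rows per run);
    ``validate_every`` > 0 audits the full state invariants on that cadence
    (slow; meant for tests).
    """
    if record_every is None:
        record_every = max(1, params.T // 200)
    rng = np.random.default_rng(params.seed)
    state = init_filament(params)

    steps = [0]
    mig = [migration_extent(state)]
    ncells = [state.n_cells]
    arc = [state.arc_length()]

    for t in range(1, params.T + 1):
        step(state, params, rng)
        if validate_every and t % validate_every == 0:
            state.check_invariants(params)
        if t % record_every == 0 or t == params.T:
            steps.append(t)
            mig.append(migration_extent(state))
            ncells.append(state.n_cells)
            arc.append(state.arc_length())
    if validate_every:
        state.check_invariants(params)

    return Trajectory(
        steps=np.asarray(steps),
        migration=np.asarray(mig),
        n_cells=np.asarray(ncells),
        arc_length=np.asarray(arc),
        final_state=state,
        params=params,
    )


# ---------------------------------------------------------------------------
# condition comparison (the three-condition migration experiment)
# ---------------------------------------------------------------------------

@dataclass
class ConditionComparison:
    """Replicate migration extents per condition plus a summary table."""

    samples: dict                  # label -> np.ndarray of final migration extents
    table: pd.DataFrame            # condition, mean, sd, relative_rate, n_rep


def default_conditions(base: Optional[SimParams] = None) -> dict:
    """The three canonical settings: default, high bending rigidity (k x10),
    and large cell size (S and L0 x2)."""
    if base is None:
        base = SimParams()
    return {
        "default": base,
        "high_rigidity": replace(base, k=base.k * 10.0),
        "large_cells": replace(base, S=base.S * 2.0, L0=base.L0 * 2.0),
    }


def compare_conditions(base: SimParams, variants, n_rep: int = 10) -> ConditionComparison:
    """Final migration extent, mean +/- sd over n_rep seeded replicates per condition.

    ``variants`` is a mapping label -> SimParams (or a sequence, labeled by
    position); every condition must share T with the base. Replicate r of a
    condition runs with seed = params.seed + r. ``relative_rate`` is the ratio
    of each condition's mean to the base mean.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if not isinstance(variants, dict):
        variants = {f"variant_{i}": v for i, v in enumerate(variants)}
    conditions = {"base": base, **variants}
    for label, p in conditions.items():
        if p.T != base.T:
            raise ValueError(f"condition {label!r} does not share T with the base")

    samples = {}
    for label, p in conditions.items():
        vals = np.empty(n_rep)
        for r in range(n_rep):
            traj = run(replace(p, seed=p.seed + r))
            vals[r] = migration_extent(traj.final_state)
        samples[label] = vals

    base_mean = samples["base"].mean()
    rows = []
    for label, vals in samples.items():
        rows.append(
            {
                "condition": label,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "relative_rate": vals.mean() / base_mean if base_mean > 0 else math.nan,
                "n_rep": n_rep,
            }
        )
    return ConditionComparison(samples=samples, table=pd.DataFrame(rows))
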