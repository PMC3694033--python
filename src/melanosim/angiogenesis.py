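"""Tissue-level angiogenesis: tip endothelial cells on a parent-linked tree.

Vasculature is represented by a forest of vessel nodes.  Roots sit on the
lattice boundary (the pre-existing main vessels); only the leaf *tip* cells
are motile.  Each step a tip:

1. goes quiescent if there is effectively no VEGF around it;
2. may die under sunitinib — rate ``lambda4 = w4*A_suni/(1 + w5*A_vegf)``
   (VEGF is protective) on top of the baseline ``lambda3``; on death the
   parent becomes the new tip;
3. otherwise extends toward an exceptionally strong VEGF direction if one
   exists (> mean + 3 sigma over the Von Neumann neighborhood), or
4. branches into two distinct roulette-selected free Moore sites (with
   probability ``branch_probability`` per step) or extends into one,
   ranked by ``R = V_l * A_vegf / (1 + w6*A_suni)``.

Vacated positions persist as inert *stalk* nodes that keep acting as
glucose/drug sources and VEGF sinks — the sprout trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microenvironment import Lattice, von_neumann_neighbors
from .tumor_agents import CROWDING_TABLE

__all__ = [
    "ECRates",
    "VesselTree",
    "CannotBranchError",
    "ec_drug_death_rate",
    "ec_apoptosis_probability",
    "strong_vegf_direction",
    "rank_ec_candidate",
    "branch_select",
    "ec_step",
]


class CannotBranchError(ValueError):
    """Fewer than two positive-rank candidates — fall back to extension."""


@dataclass
class ECRates:
    """Endothelial-cell rate constants.

    lambda3 : baseline tip death rate per hour (0 in the base model).
    w4, w5 : regulatory factors of the sunitinib death-rate law.
    w6 : drug penalty in the branching-site ranking.
    branch_probability : per-step probability that an advancing tip branches
        into two sprouts instead of extending once.
    vegf_quiescence_threshold : local VEGF average at or below which a tip is
        considered to see "no VEGF" and rests.
    branch_retry_cap : bounded redraws when both branching dice land in the
        same interval.
    """

    lambda3: float = 0.0
    w4: float = 0.01
    w5: float = 1.0
    w6: float = 0.01
    branch_probability: float = 0.1
    vegf_quiescence_threshold: float = 2e-3
    branch_retry_cap: int = 100

    def __post_init__(self) -> None:
        for name in ("lambda3", "w4", "w5", "w6", "vegf_quiescence_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")


class VesselTree:
    """Append-only array-of-structs vessel forest.

    Nodes are never reindexed; death clears ``alive``.  Invariants: the
    parent links are acyclic, tips are exactly the childless alive nodes,
    and no two alive nodes share a voxel.
    """

    def __init__(self, capacity: int = 64) -> None:
        self.n = 0
        self.pos = np.zeros(capacity, dtype=np.int64)  # flat voxel index
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=bool)
        self.is_tip = np.zeros(capacity, dtype=bool)
        self.quiescent = np.zeros(capacity, dtype=bool)
        self.n_children = np.zeros(capacity, dtype=np.int32)
        self.t_created = np.zeros(capacity, dtype=float)

    def _grow(self) -> None:
        cap = max(64, 2 * len(self.pos))
        for name in ("pos", "parent", "alive", "is_tip", "quiescent",
                     "n_children", "t_created"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            if name == "parent":
                new[:] = -1
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def add_node(self, pos: int, parent: int, t_h: float = 0.0) -> int:
        """Append a new tip node; the parent (if any) becomes a stalk."""
        if self.n == len(self.pos):
            self._grow()
        i = self.n
        self.n += 1
        self.pos[i] = pos
        self.parent[i] = parent
        self.alive[i] = True
        self.is_tip[i] = True
        self.quiescent[i] = False
        self.n_children[i] = 0
        self.t_created[i] = t_h
        if parent >= 0:
            self.n_children[parent] += 1
            self.is_tip[parent] = False
        return i

    def remove_tip(self, i: int) -> int:
        """Kill tip ``i``; its parent becomes the tip again if now childless.

        Returns the parent id (or -1).
        """
        if not (self.alive[i] and self.is_tip[i]):
            raise ValueError(f"node {i} is not an alive tip")
        self.alive[i] = False
        self.is_tip[i] = False
        p = int(self.parent[i])
        if p >= 0 and self.alive[p]:
            self.n_children[p] -= 1
            if self.n_children[p] == 0:
                self.is_tip[p] = True
        return p

    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self.n] & self.is_tip[: self.n])

    def n_alive(self) -> int:
        return int(self.alive[: self.n].sum())

    def validate(self) -> None:
        """Raise if the tree invariants are violated."""
        n = self.n
        alive = self.alive[:n]
        # acyclicity: walking parent links must terminate
        for i in np.flatnonzero(alive):
            seen = set()
            j = i
            while j >= 0:
                if j in seen:
                    raise AssertionError(f"cycle through node {i}")
                seen.add(j)
                j = int(self.parent[j])
        # tips <=> childless alive nodes
        child_count = np.zeros(n, dtype=int)
        for i in np.flatnonzero(alive):
            p = int(self.parent[i])
            if p >= 0 and self.alive[p]:
                child_count[p] += 1
        leaves = alive & (child_count == 0)
        if not np.array_equal(leaves, self.is_tip[:n] & alive):
            raise AssertionError("tip flags disagree with leaf structure")
        # voxel exclusivity
        positions = self.pos[:n][alive]
        if len(np.unique(positions)) != len(positions):
            raise AssertionError("two alive vessel nodes share a voxel")

    def to_dataframe(self, dims: tuple[int, int, int]) -> pd.DataFrame:
        """Alive nodes as (node_id, parent_id, x, y, z, is_tip, t_created)."""
        n = self.n
        alive = self.alive[:n]
        idx = np.flatnonzero(alive)
        ny, nz = dims[1], dims[2]
        pos = self.pos[idx]
        x, rem = np.divmod(pos, ny * nz)
        y, z = np.divmod(rem, nz)
        return pd.DataFrame(
            {
                "node_id": idx,
                "parent_id": self.parent[idx],
                "x": x,
                "y": y,
                "z": z,
                "is_tip": self.is_tip[idx],
                "t_created": self.t_created[idx],
            }
        )


# ---------------------------------------------------------------------------
# analytic rules


def ec_drug_death_rate(a_ssuni: float, a_svegf: float, w4: float, w5: float) -> float:
    """Anti-angiogenic death-rate contribution ``w4*A_suni/(1 + w5*A_vegf)``."""
    if a_ssuni < 0 or a_svegf < 0 or w4 < 0 or w5 < 0:
        raise ValueError("ec_drug_death_rate inputs must be nonnegative")
    return w4 * a_ssuni / (1.0 + w5 * a_svegf)


def ec_apoptosis_probability(
    dt_h: float, lambda3: float, lambda4: float = 0.0, with_drug: bool = False
) -> float:
    """Tip apoptosis probability ``1 - exp(-(lambda3 [+ lambda4])*dt)``."""
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    if lambda3 < 0 or lambda4 < 0:
        raise ValueError("rates must be nonnegative")
    rate = lambda3 + (lambda4 if with_drug else 0.0)
    return 1.0 - math.exp(-rate * dt_h)


def strong_vegf_direction(
    vegf: np.ndarray,
    p: tuple[int, int, int],
    rng: np.random.Generator,
    occupied: np.ndarray | None = None,
    lattice: Lattice | None = None,
):
    """Free VN neighbor whose VEGF exceeds the local mean by more than three
    population sigmas (over the site + VN neighbors), or ``None``; ties are
    broken uniformly at random.

    Note: for a full 7-voxel neighborhood this can never fire (the maximum
    deviation from a sample mean is bounded by ``sigma*sqrt(n-1) ~ 2.45
    sigma``); the rule is kept for fidelity and for degenerate boundaries.
    """
    lattice = lattice or Lattice(vegf.shape)
    nbrs = von_neumann_neighbors(p, lattice)
    vals = np.array([vegf[p]] + [vegf[q] for q in nbrs], dtype=float)
    mean = vals.mean()
    sigma = vals.std()
    qualifying = [
        q
        for q in nbrs
        if vegf[q] - mean > 3.0 * sigma
        and (occupied is None or not occupied[q])
    ]
    if not qualifying:
        return None
    return qualifying[int(rng.integers(len(qualifying)))]


def rank_ec_candidate(v_l: float, a_mvegf: float, a_msuni: float, w6: float) -> float:
    """Raw branching rank ``R = V_l * A_vegf / (1 + w6*A_suni)``."""
    if v_l < 0 or a_mvegf < 0 or a_msuni < 0 or w6 < 0:
        raise ValueError("rank inputs must be nonnegative")
    return v_l * a_mvegf / (1.0 + w6 * a_msuni)


def branch_select(
    norm_ranks, rng: np.random.Generator, retry_cap: int = 100
) -> tuple[int, int]:
    """Two distinct candidate indices via repeated paired roulette draws.

    If both dice land in the same interval the pair is redrawn; after
    ``retry_cap`` failures the two highest-weight distinct candidates are
    taken deterministically.
    """
    ranks = np.asarray(norm_ranks, dtype=float)
    if (ranks > 0).sum() < 2:
        raise CannotBranchError("need >= 2 positive-rank candidates to branch")
    cum = np.cumsum(ranks)
    total = cum[-1]
    last = len(ranks) - 1
    for _ in range(retry_cap):
        i = min(int(np.searchsorted(cum, rng.random() * total, side="right")), last)
        j = min(int(np.searchsorted(cum, rng.random() * total, side="right")), last)
        if i != j:
            return i, j
    order = np.argsort(-ranks, kind="stable")
    return int(order[0]), int(order[1])


# ---------------------------------------------------------------------------
# per-tip step


def _rank_free_sites(ctx, free: np.ndarray) -> np.ndarray:
    ranks = CROWDING_TABLE[ctx.nocc[free]] * ctx.mveg[free]
    if ctx.has_sun:
        ranks = ranks / (1.0 + ctx.w6 * ctx.msun[free])
    return ranks


def ec_step(ctx, tip_id: int, rng: np.random.Generator) -> None:
    """Advance one tip endothelial cell on the engine context ``ctx``."""
    tree: VesselTree = ctx.tree
    pos = int(tree.pos[tip_id])
    rates: ECRates = ctx.ec_rates

    # (a) no VEGF -> reversible quiescence
    a_vegf = ctx.vnveg[pos]
    if a_vegf <= rates.vegf_quiescence_threshold:
        tree.quiescent[tip_id] = True
        return
    tree.quiescent[tip_id] = False

    # (b) drug-driven degeneration
    rate = rates.lambda3
    if ctx.has_sun:
        a_suni = ctx.vnsun[pos]
        if a_suni > 0.0:
            rate += rates.w4 * a_suni / (1.0 + rates.w5 * a_vegf)
    if rate > 0.0 and rng.random() < 1.0 - math.exp(-rate * ctx.dt_h):
        tree.remove_tip(tip_id)
        ctx.free_vessel_voxel(pos)
        ctx.n_ec_deaths += 1
        return

    # (c) strong-VEGF directed extension over the VN neighborhood
    vn = ctx.vn_idx[pos]
    vn = vn[vn != ctx.sentinel]
    vals = np.concatenate(([ctx.veg[pos]], ctx.veg[vn]))
    mean = vals.mean()
    sigma = vals.std()
    hot = vn[(ctx.veg[vn] - mean > 3.0 * sigma) & (ctx.occ[vn] == 0)]
    if hot.size:
        site = int(hot[int(rng.integers(hot.size))])
        ctx.extend_vessel(tip_id, site)
        return

    # (d) branch into two sprouts, or extend into one
    cands = ctx.moore_idx[pos]
    free = cands[ctx.occ[cands] == 0]
    if free.size == 0:
        tree.quiescent[tip_id] = True
        return
    ranks = _rank_free_sites(ctx, free)
    total = ranks.sum()
    if total <= 0.0:
        tree.quiescent[tip_id] = True
        return
    if (
        free.size >= 2
        and (ranks > 0).sum() >= 2
        and rng.random() < rates.branch_probability
    ):
        i, j = branch_select(ranks / total, rng, rates.branch_retry_cap)
        ctx.extend_vessel(tip_id, int(free[i]))
        ctx.extend_vessel(tip_id, int(free[j]))
        ctx.n_branches += 1
    else:
        cum = np.cumsum(ranks)
        k = min(
            int(np.searchsorted(cum, rng.random() * total, side="right")),
            free.size - 1,
        )
        ctx.extend_vessel(tip_id, int(free[k]))
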