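"""Melanoma-cell rules: apoptosis, proliferation, site choice, quiescence.

Each melanoma cell re-evaluates its phenotype every step (default 2 h):

* starvation — local glucose (mean over the site and its Von Neumann
  neighbors) below the survival threshold starts a starvation clock and turns
  on VEGF secretion;
* apoptosis — probability ``1 - exp(-(lambda0 + lambda1) * dt)`` where the
  cytotoxic-drug contribution is ``lambda1 = w1 * A_dox / (1 + w2 * A_glu)``
  (glucose is protective); prolonged starvation adds a further rate;
* proliferation — cell-cycle entry with probability ``1 - exp(-lambda2*dt)``;
  division completes after one cell-cycle length, placing the daughter on a
  chosen free Moore site;
* migration — non-cycling cells move to a free Moore site favoring high
  glucose, low drug, and few occupied neighbors; an "abnormally high"
  glucose site (> mean + 3 sigma of the 27-voxel box) is taken outright;
* quiescence — reversible holding state when no free site exists.

Stochastic site choice is fitness-proportionate ("roulette wheel"): raw ranks
are normalized to proportions and a uniform die picks the half-open interval
they tile [0, 1) with.  The same machinery is shared by the endothelial
agents (:mod:`melanosim.angiogenesis`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .microenvironment import Lattice, moore_neighbors

__all__ = [
    "MelanomaCell",
    "TumorRates",
    "NoViableCandidateError",
    "ACTIVE",
    "QUIESCENT",
    "DEAD",
    "drug_death_rate",
    "apoptosis_probability",
    "proliferation_probability",
    "enters_cell_cycle",
    "crowding_preference",
    "CROWDING_TABLE",
    "rank_tumor_candidate",
    "normalize_ranks",
    "roulette_select",
    "abnormal_glucose_site",
    "tumor_step",
]

# phenotype state codes (compact for the array-of-structs state)
ACTIVE, QUIESCENT, DEAD = 0, 1, 2
STATE_NAMES = {ACTIVE: "active", QUIESCENT: "quiescent", DEAD: "apoptotic"}


class NoViableCandidateError(ValueError):
    """All candidate ranks are zero — the caller treats this as 'no space'."""


@dataclass
class MelanomaCell:
    """One melanoma cell (convenience view; the engine stores cells as
    parallel arrays for speed)."""

    position: tuple[int, int, int]
    age_h: float = 0.0
    state: int = ACTIVE
    in_cycle: bool = False
    cycle_clock_h: float = 0.0
    starve_clock_h: float = 0.0
    secreting: bool = False


@dataclass
class TumorRates:
    """Melanoma rate constants and thresholds.

    lambda0 : baseline death rate, per hour (0 for melanoma).
    lambda2 : cell-cycle entry rate, per hour; the reciprocal of the average
        proliferation time (1/32 h^-1).
    w1, w2 : regulatory factors of the cytotoxic death-rate law.
    w3 : drug penalty in the migration/proliferation site ranking.
    glucose_survival_threshold : local glucose below this starves the cell.
    starvation_limit_h : hours of continuous starvation tolerated before the
        starvation death rate applies.
    starvation_death_rate : per-hour rate added once the limit is exceeded.
    cell_cycle_length_h : time from cycle entry to division.
    """

    lambda0: float = 0.0
    lambda2: float = 1.0 / 32.0
    w1: float = 0.01
    w2: float = 1.0
    w3: float = 0.01
    glucose_survival_threshold: float = 1.0
    starvation_limit_h: float = 24.0
    starvation_death_rate: float = 0.05
    cell_cycle_length_h: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "lambda0", "lambda2", "w1", "w2", "w3",
            "glucose_survival_threshold", "starvation_limit_h",
            "starvation_death_rate", "cell_cycle_length_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# ---------------------------------------------------------------------------
# analytic rules


def drug_death_rate(a_sdox: float, a_sglucose: float, w1: float, w2: float) -> float:
    """Cytotoxic death-rate contribution ``w1*A_dox / (1 + w2*A_glu)``.

    Doxorubicin raises the rate; ambient glucose is protective.
    """
    if a_sdox < 0 or a_sglucose < 0 or w1 < 0 or w2 < 0:
        raise ValueError("drug_death_rate inputs must be nonnegative")
    return w1 * a_sdox / (1.0 + w2 * a_sglucose)


def apoptosis_probability(
    dt_h: float, lambda0: float, lambda1: float = 0.0, with_drug: bool = False
) -> float:
    """Per-step apoptosis probability ``1 - exp(-rate*dt)``.

    Without drug the rate is ``lambda0``; with drug ``lambda0 + lambda1``.
    """
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    if lambda0 < 0 or lambda1 < 0:
        raise ValueError("rates must be nonnegative")
    rate = lambda0 + (lambda1 if with_drug else 0.0)
    return 1.0 - math.exp(-rate * dt_h)


def proliferation_probability(dt_h: float, lambda2: float) -> float:
    """Cell-cycle entry probability ``1 - exp(-lambda2*dt)``."""
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    if lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    return 1.0 - math.exp(-lambda2 * dt_h)


def enters_cell_cycle(c_rand: float, p_prol: float) -> bool:
    """Die test: the cycle switches ON iff the die lands in [0, p_prol)."""
    if not 0.0 <= c_rand < 1.0:
        raise ValueError("c_rand must lie in [0, 1)")
    return c_rand < p_prol


def crowding_preference(cellnum: int) -> float:
    """Piecewise preference for sparsely populated candidate sites.

    ``cellnum`` counts occupied Moore neighbors of the candidate (tumor,
    vessel, or dead): 1 for 0-2 neighbors, 1/4 for 3-4, 1/6 for 5-6, and
    1/cellnum for 7-26.
    """
    if not 0 <= cellnum <= 26:
        raise ValueError(f"cellnum must be in [0, 26], got {cellnum}")
    if cellnum <= 2:
        return 1.0
    if cellnum <= 4:
        return 0.25
    if cellnum <= 6:
        return 1.0 / 6.0
    return 1.0 / cellnum


#: vectorized lookup of crowding_preference over cellnum = 0..26
CROWDING_TABLE = np.array([crowding_preference(k) for k in range(27)])


def rank_tumor_candidate(
    v_l: float, a_mglucose: float, a_mdox: float, w3: float
) -> float:
    """Raw rank ``R = V_l * A_glu / (1 + w3*A_dox)`` of a candidate site."""
    if v_l < 0 or a_mglucose < 0 or a_mdox < 0 or w3 < 0:
        raise ValueError("rank inputs must be nonnegative")
    return v_l * a_mglucose / (1.0 + w3 * a_mdox)


def normalize_ranks(raws) -> np.ndarray:
    """Normalize raw ranks to proportions summing to one (order preserved)."""
    raws = np.asarray(raws, dtype=float)
    if raws.size == 0 or np.any(raws < 0):
        raise ValueError("ranks must be a nonempty nonnegative sequence")
    total = raws.sum()
    if total <= 0.0:
        raise NoViableCandidateError("all candidate ranks are zero")
    return raws / total


def roulette_select(norm_ranks, die: float) -> int:
    """Pick the index whose half-open cumulative interval contains the die.

    Intervals are built in candidate order:
    ``S_l = [sum_{m<l} r_m, sum_{m<=l} r_m)``.
    """
    if not 0.0 <= die < 1.0:
        raise ValueError("die must lie in [0, 1)")
    cum = np.cumsum(np.asarray(norm_ranks, dtype=float))
    idx = int(np.searchsorted(cum, die, side="right"))
    return min(idx, len(cum) - 1)  # guard against rounding at the top end


# ---------------------------------------------------------------------------
# spatial site choice


def abnormal_glucose_site(
    glucose: np.ndarray,
    p: tuple[int, int, int],
    rng: np.random.Generator,
    occupied: np.ndarray | None = None,
    lattice: Lattice | None = None,
):
    """Uniformly random *free* Moore neighbor whose glucose exceeds the local
    mean by more than three population standard deviations, or ``None``.

    The mean and sigma are taken over the site plus its in-bounds Moore
    neighbors; the inequality is strict, so a uniform neighborhood (sigma=0)
    never qualifies.
    """
    lattice = lattice or Lattice(glucose.shape)
    nbrs = moore_neighbors(p, lattice)
    vals = np.array([glucose[p]] + [glucose[q] for q in nbrs], dtype=float)
    mean = vals.mean()
    sigma = vals.std()  # population sigma
    qualifying = [
        q
        for q in nbrs
        if glucose[q] - mean > 3.0 * sigma
        and (occupied is None or not occupied[q])
    ]
    if not qualifying:
        return None
    return qualifying[int(rng.integers(len(qualifying)))]


def _choose_tumor_site(ctx, pos: int, rng: np.random.Generator) -> int:
    """Flat index of the chosen free Moore site, or -1 (no space / no rank).

    Fast path over the engine's per-step context: the 3-sigma abnormal-glucose
    shortcut first, then the crowding x glucose / drug roulette.
    """
    cands = ctx.moore_idx[pos]
    free = cands[ctx.occ[cands] == 0]  # sentinel slot is never free
    if free.size == 0:
        return -1
    # rule 1: abnormally rich glucose site (> box mean + 3 * population sigma)
    hot = free[ctx.glu[free] - ctx.mglu[pos] > 3.0 * ctx.sglu[pos]]
    if hot.size:
        return int(hot[int(rng.integers(hot.size))])
    # rule 2: roulette over R = V_l * A_mglu / (1 + w3 * A_mdox)
    ranks = CROWDING_TABLE[ctx.nocc[free]] * ctx.mglu[free]
    if ctx.has_dox:
        ranks = ranks / (1.0 + ctx.w3 * ctx.mdox[free])
    total = ranks.sum()
    if total <= 0.0:
        return -1  # no viable candidate: treated as no-space (quiescence)
    cum = np.cumsum(ranks)
    idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
    return int(free[min(idx, free.size - 1)])


# ---------------------------------------------------------------------------
# per-cell step


def tumor_step(ctx, i: int, rng: np.random.Generator) -> None:
    """Advance melanoma cell ``i`` by one step on the engine context ``ctx``.

    Order: starvation bookkeeping, apoptosis draw, cell-cycle progression /
    entry, division or migration via the shared site choice, quiescence when
    no site is available.  Mutates the cell arrays, occupancy, and the
    step's event counters in place.
    """
    cells = ctx.cells
    pos = cells.pos[i]
    rates: TumorRates = ctx.tumor_rates
    dt = ctx.dt_h

    # (a) starvation check and VEGF secretion
    a_glu = ctx.vnglu[pos]
    if a_glu < rates.glucose_survival_threshold:
        cells.starve_h[i] += dt
        if not cells.secreting[i]:
            cells.secreting[i] = True
            ctx.secr[pos] = True
    else:
        if cells.secreting[i]:
            cells.secreting[i] = False
            ctx.secr[pos] = False
        cells.starve_h[i] = 0.0

    # (b) apoptosis draw
    rate = rates.lambda0
    if ctx.has_dox:
        a_dox = ctx.vndox[pos]
        if a_dox > 0.0:
            rate += rates.w1 * a_dox / (1.0 + rates.w2 * a_glu)
    if cells.starve_h[i] > rates.starvation_limit_h:
        rate += rates.starvation_death_rate
    if rate > 0.0 and rng.random() < 1.0 - math.exp(-rate * dt):
        cells.state[i] = DEAD  # voxel stays occupied (necrotic core)
        ctx.live[pos] = False
        if cells.secreting[i]:
            cells.secreting[i] = False
            ctx.secr[pos] = False
        ctx.n_deaths += 1
        ctx.log(i, "died", pos)
        return

    # (c/d) cell cycle: progression and division
    if cells.in_cycle[i]:
        cells.cycle_h[i] = min(
            cells.cycle_h[i] + dt, rates.cell_cycle_length_h
        )
        if cells.cycle_h[i] >= rates.cell_cycle_length_h:
            site = _choose_tumor_site(ctx, pos, rng)
            if site >= 0:
                cells.in_cycle[i] = False
                cells.cycle_h[i] = 0.0
                cells.state[i] = ACTIVE
                j = ctx.spawn_cell(site)
                ctx.n_divisions += 1
                ctx.log(j, "divided", site)
            else:
                cells.state[i] = QUIESCENT  # division deferred, retry next step
                ctx.log(i, "quiesced", pos)
        else:
            cells.state[i] = ACTIVE
        return

    # (c) cycle-entry die
    p_prol = 1.0 - math.exp(-rates.lambda2 * dt)
    if p_prol > 0.0 and rng.random() < p_prol:
        cells.in_cycle[i] = True
        cells.cycle_h[i] = 0.0
        cells.state[i] = ACTIVE
        return

    # (e) migration
    site = _choose_tumor_site(ctx, pos, rng)
    if site >= 0:
        ctx.move_cell(i, pos, site)
        cells.state[i] = ACTIVE
        ctx.log(i, "moved", site)
    else:
        cells.state[i] = QUIESCENT  # (f) reversible
        ctx.log(i, "quiesced", pos)
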