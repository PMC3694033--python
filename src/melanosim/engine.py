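"""Simulation engine: configuration, initialization, master loop, metrics.

One step (default 2 h) advances, in order: the four microenvironment fields
(glucose, VEGF, doxorubicin, sunitinib — synchronous updates reading the
previous step's occupancy), then every melanoma cell in a uniformly shuffled
order, then every tip endothelial cell in a uniformly shuffled order.  All
randomness flows from a single seeded ``numpy.random.Generator``, so a run is
bit-reproducible given (config, seed).

The default configuration encodes the base model: a 100x100x100 lattice of
10 um voxels, 100 melanoma cells seeded as a sphere at the center with ages
uniform in [0, 24) h, 16 tip endothelial cells as boundary roots, glucose and
VEGF drawn per voxel from clipped normals (mean 4 / sd 1 and mean 1 / sd
0.25), drugs at zero until dosing starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import microenvironment as micro
from .angiogenesis import ECRates, VesselTree, ec_step
from .microenvironment import DiffusionParams, Lattice, OccupancyMask
from .tumor_agents import ACTIVE, DEAD, QUIESCENT, STATE_NAMES, TumorRates, tumor_step

log = logging.getLogger("melanosim.engine")

__all__ = [
    "FieldInit",
    "DosingSchedule",
    "SimulationConfig",
    "SimulationState",
    "initialize",
    "step",
    "run",
    "dosing_active",
    "snapshot_frame",
]

# occupancy codes
OCC_FREE, OCC_TUMOR, OCC_VESSEL, OCC_BLOCKED = 0, 1, 2, 3


@dataclass
class FieldInit:
    """Per-voxel initial field level: i.i.d. normal clipped at zero."""

    glucose_mean: float = 4.0
    glucose_sd: float = 1.0
    vegf_mean: float = 1.0
    vegf_sd: float = 0.25


@dataclass
class DosingSchedule:
    """Constant drug infusion via the vessel source term.

    Multipliers scale the Table-default vessel release rate; dosing is active
    for ``start_h <= t < end_h`` (``end_h`` None = until the end of the run).
    """

    dox_multiplier: float = 0.0
    suni_multiplier: float = 0.0
    start_h: float = 0.0
    end_h: float | None = None

    def __post_init__(self) -> None:
        if self.dox_multiplier < 0 or self.suni_multiplier < 0:
            raise ValueError("dose multipliers must be nonnegative")
        if self.end_h is not None and self.start_h > self.end_h:
            raise ValueError("dosing start_h must not exceed end_h")


def _default_glucose() -> DiffusionParams:
    return DiffusionParams(lam=0.90, permeability=1.0, uptake=0.28, decay=0.2,
                           diffusivity_cm2_s=6.7e-7)


def _default_vegf() -> DiffusionParams:
    return DiffusionParams(lam=0.39, permeability=1.0 / 3.0, secretion=0.6,
                           decay=0.2, diffusivity_cm2_s=2.9e-7)


def _default_drug() -> DiffusionParams:
    return DiffusionParams(lam=0.70, permeability=1.0, uptake=0.2,
                           diffusivity_cm2_s=5.18e-7)


@dataclass
class SimulationConfig:
    """Every model constant, with base-model defaults.

    Transport parameters are dimensionless per-step quantities; physical
    permeabilities in cm/s map to the source terms by ``Pe / 3e-5`` (see
    docs/methods.md for the unit conventions).
    """

    dims: tuple[int, int, int] = (100, 100, 100)
    spacing_um: float = 10.0
    dt_h: float = 2.0
    t_end_h: float = 400.0
    seed: int = 0

    initial_tumor_count: int = 100
    initial_tip_count: int = 16
    init_age_range_h: tuple[float, float] = (0.0, 24.0)
    tip_positions: list[tuple[int, int, int]] | None = None

    tumor: TumorRates = dc_field(default_factory=TumorRates)
    ec: ECRates = dc_field(default_factory=ECRates)
    glucose: DiffusionParams = dc_field(default_factory=_default_glucose)
    vegf: DiffusionParams = dc_field(default_factory=_default_vegf)
    dox: DiffusionParams = dc_field(default_factory=_default_drug)
    sunitinib: DiffusionParams = dc_field(default_factory=_default_drug)
    field_init: FieldInit = dc_field(default_factory=FieldInit)
    dosing: DosingSchedule = dc_field(default_factory=DosingSchedule)

    n_sub: int = 1  # extra diffusion sub-steps per step (physical transport)
    log_events: bool = False
    audit_every_step: bool = True

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if self.t_end_h < 0:
            raise ValueError("t_end_h must be nonnegative")
        if self.initial_tumor_count < 0 or self.initial_tip_count < 0:
            raise ValueError("agent counts must be nonnegative")
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")
        lo, hi = self.init_age_range_h
        if not 0 <= lo <= hi:
            raise ValueError("init_age_range_h must satisfy 0 <= lo <= hi")
        self.dims = tuple(int(d) for d in self.dims)
        Lattice(self.dims, self.spacing_um)  # validates
        if self.initial_tumor_count > int(np.prod(self.dims)):
            raise ValueError("initial tumor count exceeds lattice volume")

    @property
    def lattice(self) -> Lattice:
        return Lattice(self.dims, self.spacing_um)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end_h / self.dt_h))


class _CellArrays:
    """Append-only array-of-structs melanoma population."""

    FIELDS = ("pos", "state", "age_h", "in_cycle", "cycle_h", "starve_h",
              "secreting")

    def __init__(self, capacity: int = 256) -> None:
        self.n = 0
        self.pos = np.zeros(capacity, dtype=np.int64)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.age_h = np.zeros(capacity, dtype=float)
        self.in_cycle = np.zeros(capacity, dtype=bool)
        self.cycle_h = np.zeros(capacity, dtype=float)
        self.starve_h = np.zeros(capacity, dtype=float)
        self.secreting = np.zeros(capacity, dtype=bool)

    def _grow(self) -> None:
        cap = 2 * len(self.pos)
        for name in self.FIELDS:
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def append(self, pos: int, age_h: float = 0.0) -> int:
        if self.n == len(self.pos):
            self._grow()
        i = self.n
        self.n += 1
        self.pos[i] = pos
        self.state[i] = ACTIVE
        self.age_h[i] = age_h
        self.in_cycle[i] = False
        self.cycle_h[i] = 0.0
        self.starve_h[i] = 0.0
        self.secreting[i] = False
        return i


def _ext_buffer(dims: tuple[int, int, int], dtype, fill=0):
    """Flat buffer of n_voxels + 1 guard slot, plus its 3D view."""
    n = int(np.prod(dims))
    buf = np.full(n + 1, fill, dtype=dtype)
    view = buf[:n].reshape(dims)
    return buf, view


class SimulationState:
    """Full mutable simulation state; also the per-step context handed to the
    agent step functions (field averages, occupancy, event counters)."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.dims = cfg.dims
        nx, ny, nz = cfg.dims
        self.n_voxels = nx * ny * nz
        self._yz = ny * nz

        self.glu_f, self.glu3 = _ext_buffer(cfg.dims, float)
        self.veg_f, self.veg3 = _ext_buffer(cfg.dims, float)
        self.dox_f, self.dox3 = _ext_buffer(cfg.dims, float)
        self.sun_f, self.sun3 = _ext_buffer(cfg.dims, float)
        self.occ, self.occ3 = _ext_buffer(cfg.dims, np.int8)
        self.occ[self.n_voxels] = OCC_BLOCKED  # guard slot is never free
        self.live, self.live3 = _ext_buffer(cfg.dims, bool)
        self.secr, self.secr3 = _ext_buffer(cfg.dims, bool)
        self.ves, self.ves3 = _ext_buffer(cfg.dims, bool)
        self.nocc, self.nocc3 = _ext_buffer(cfg.dims, np.int16)

        self.sentinel = self.n_voxels  # guard slot index
        self._tables = None  # flat neighbor tables, built lazily (large)

        self.cells = _CellArrays()
        self.tree = VesselTree()
        self.t_h = 0.0
        self.istep = 0
        self.records: list[dict] = []
        self.event_log: list[dict] = []
        self.dox_nonzero = False
        self.sun_nonzero = False

        # per-step scratch, filled by step(); guard-extended flat arrays
        zeros = np.zeros(self.n_voxels + 1)
        self.vnglu = self.vndox = self.vnsun = self.vnveg = zeros
        self.mglu = self.sglu = self.mdox = self.mveg = self.msun = zeros
        self._zeros = zeros
        self.has_dox = False
        self.has_sun = False
        self.n_divisions = 0
        self.n_deaths = 0
        self.n_ec_deaths = 0
        self.n_branches = 0

        # context aliases used by the agent step functions
        self.glu = self.glu_f
        self.veg = self.veg_f
        self.tumor_rates = cfg.tumor
        self.ec_rates = cfg.ec
        self.dt_h = cfg.dt_h
        self.w3 = cfg.tumor.w3
        self.w6 = cfg.ec.w6

    @property
    def vn_idx(self) -> np.ndarray:
        if self._tables is None:
            self._tables = micro.neighbor_tables(self.cfg.dims)
        return self._tables[0]

    @property
    def moore_idx(self) -> np.ndarray:
        if self._tables is None:
            self._tables = micro.neighbor_tables(self.cfg.dims)
        return self._tables[2]

    @property
    def moore_n(self) -> np.ndarray:
        if self._tables is None:
            self._tables = micro.neighbor_tables(self.cfg.dims)
        return self._tables[3]

    # -- occupancy bookkeeping ------------------------------------------------

    def _coords(self, pos: int) -> tuple[int, int, int]:
        x, rem = divmod(pos, self._yz)
        y, z = divmod(rem, self.dims[2])
        return int(x), int(y), int(z)

    def _nocc_shift(self, pos: int, delta: int) -> None:
        x, y, z = self._coords(pos)
        nx, ny, nz = self.dims
        self.nocc3[
            max(x - 1, 0): x + 2, max(y - 1, 0): y + 2, max(z - 1, 0): z + 2
        ] += delta
        self.nocc3.reshape(-1)[pos] -= delta  # a voxel is not its own neighbor

    def occupy_tumor(self, pos: int, live: bool = True) -> None:
        if self.occ[pos] != OCC_FREE:
            raise RuntimeError(f"voxel {self._coords(pos)} already occupied")
        self.occ[pos] = OCC_TUMOR
        self.live[pos] = live
        self._nocc_shift(pos, +1)

    def occupy_vessel(self, pos: int) -> None:
        if self.occ[pos] != OCC_FREE:
            raise RuntimeError(f"voxel {self._coords(pos)} already occupied")
        self.occ[pos] = OCC_VESSEL
        self.ves[pos] = True
        self._nocc_shift(pos, +1)

    def free_vessel_voxel(self, pos: int) -> None:
        self.occ[pos] = OCC_FREE
        self.ves[pos] = False
        self._nocc_shift(pos, -1)

    def spawn_cell(self, pos: int) -> int:
        self.occupy_tumor(pos)
        return self.cells.append(pos)

    def move_cell(self, i: int, old: int, new: int) -> None:
        self.occ[old] = OCC_FREE
        self.live[old] = False
        self._nocc_shift(old, -1)
        self.occupy_tumor(new)
        if self.cells.secreting[i]:
            self.secr[old] = False
            self.secr[new] = True
        self.cells.pos[i] = new

    def extend_vessel(self, tip_id: int, site: int) -> None:
        self.occupy_vessel(site)
        self.tree.add_node(site, tip_id, self.t_h)

    # -- event log ------------------------------------------------------------

    def log(self, cell_id: int, event: str, pos: int) -> None:
        if self.cfg.log_events:
            x, y, z = self._coords(int(pos))
            self.event_log.append(
                {
                    "t": self.t_h,
                    "cell_id": int(cell_id),
                    "event": event,
                    "x": x, "y": y, "z": z,
                    "state": STATE_NAMES[int(self.cells.state[cell_id])],
                }
            )

    # -- accounting -----------------------------------------------------------

    def counts(self) -> dict:
        n = self.cells.n
        by_state = np.bincount(self.cells.state[:n], minlength=3)
        return {
            "n_total": int(n),
            "n_active": int(by_state[ACTIVE]),
            "n_quiescent": int(by_state[QUIESCENT]),
            "n_apoptotic": int(by_state[DEAD]),
            "n_alive": int(by_state[ACTIVE] + by_state[QUIESCENT]),
            "n_ec": self.tree.n_alive(),
            "n_tips": int(len(self.tree.tips())),
        }

    def audit(self) -> None:
        """Occupancy consistency check; raises with step context on breakage."""
        n = self.cells.n
        problems = []
        if int((self.occ3 == OCC_TUMOR).sum()) != n:
            problems.append("tumor occupancy != cell count")
        if int((self.occ3 == OCC_VESSEL).sum()) != self.tree.n_alive():
            problems.append("vessel occupancy != alive node count")
        alive_mask = self.cells.state[:n] != DEAD
        if int(self.live3.sum()) != int(alive_mask.sum()):
            problems.append("live mask disagrees with living cell count")
        if np.any(self.live3 & self.ves3):
            problems.append("tumor/vessel exclusivity violated")
        if n and len(np.unique(self.cells.pos[:n])) != n:
            problems.append("two cells share a voxel")
        if problems:
            raise AssertionError(
                f"occupancy audit failed at t={self.t_h} h (step {self.istep}): "
                + "; ".join(problems)
            )

    def timeseries(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)


# ---------------------------------------------------------------------------
# initialization


def initialize(cfg: SimulationConfig) -> SimulationState:
    """Build the t=0 state: tumor sphere, boundary tip cells, initial fields.

    Tumor cells fill the ``initial_tumor_count`` voxels nearest the lattice
    center (ties broken lexicographically); tip endothelial roots are placed
    round-robin over the six faces at seeded-uniform positions.
    """
    rng = np.random.default_rng(cfg.seed)
    state = SimulationState(cfg, rng)
    nx, ny, nz = cfg.dims

    # tumor sphere at the center
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    x, y, z = x.ravel(), y.ravel(), z.ravel()
    dist = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    order = np.lexsort((z, y, x, dist))
    seats = order[: cfg.initial_tumor_count]
    ages = rng.uniform(*cfg.init_age_range_h, size=cfg.initial_tumor_count)
    for pos, age in zip(seats, ages):
        flat = int((x[pos] * ny + y[pos]) * nz + z[pos])
        state.occupy_tumor(flat)
        state.cells.append(flat, age_h=float(age))

    # tip endothelial roots on the boundary
    if cfg.tip_positions is not None:
        tip_sites = [
            int((px * ny + py) * nz + pz) for px, py, pz in cfg.tip_positions
        ]
        if len(tip_sites) != cfg.initial_tip_count:
            raise ValueError("tip_positions length must equal initial_tip_count")
    else:
        tip_sites = []
        taken = set()
        for k in range(cfg.initial_tip_count):
            face = k % 6
            for _ in range(1000):
                a = int(rng.integers(cfg.dims[(face // 2 + 1) % 3]))
                b = int(rng.integers(cfg.dims[(face // 2 + 2) % 3]))
                axis = face // 2
                coord = [0, 0, 0]
                coord[axis] = 0 if face % 2 == 0 else cfg.dims[axis] - 1
                coord[(axis + 1) % 3] = a
                coord[(axis + 2) % 3] = b
                flat = int((coord[0] * ny + coord[1]) * nz + coord[2])
                if flat not in taken and state.occ[flat] == OCC_FREE:
                    taken.add(flat)
                    tip_sites.append(flat)
                    break
            else:  # pragma: no cover - tiny lattices only
                raise RuntimeError("could not place all tip cells on the boundary")
    for flat in tip_sites:
        state.occupy_vessel(flat)
        state.tree.add_node(flat, parent=-1, t_h=0.0)

    # initial fields: clipped normals for glucose and VEGF, drugs at zero
    fi = cfg.field_init
    state.glu3[:] = np.maximum(
        rng.normal(fi.glucose_mean, fi.glucose_sd, size=cfg.dims), 0.0
    )
    state.veg3[:] = np.maximum(
        rng.normal(fi.vegf_mean, fi.vegf_sd, size=cfg.dims), 0.0
    )

    state.records.append(_record(state))
    return state


def _record(state: SimulationState) -> dict:
    c = state.counts()
    rec = {"t_h": state.t_h, **c}
    rec["n_divisions"] = state.n_divisions
    rec["volume"] = c["n_total"]  # one voxel per cell, dead cells included
    rec["proliferation_rate"] = state.n_divisions / max(c["n_active"], 1)
    return rec


# ---------------------------------------------------------------------------
# dosing and stepping


def dosing_active(t_h: float, cfg: SimulationConfig):
    """(dox_on, suni_on, dox_multiplier, suni_multiplier) at time ``t_h``."""
    if t_h < 0:
        raise ValueError("t_h must be nonnegative")
    d = cfg.dosing
    end = d.end_h if d.end_h is not None else float("inf")
    window = d.start_h <= t_h < end
    dox_on = window and d.dox_multiplier > 0
    suni_on = window and d.suni_multiplier > 0
    return dox_on, suni_on, d.dox_multiplier, d.suni_multiplier


def _extend_flat(state: SimulationState, arr3: np.ndarray) -> np.ndarray:
    out = np.empty(state.n_voxels + 1)
    out[: state.n_voxels] = arr3.reshape(-1)
    out[state.n_voxels] = 0.0
    return out


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one step (fields, tumor agents, EC agents)."""
    cfg = state.cfg
    rng = state.rng
    dox_on, sun_on, dox_mult, sun_mult = dosing_active(state.t_h, cfg)

    # (1) synchronous field updates, fixed order, reading last step's occupancy
    occm = OccupancyMask(state.live3, state.ves3)
    for _ in range(cfg.n_sub - 1):  # optional pure-transport sub-cycling
        state.glu3[:] = micro._diffuse(state.glu3, cfg.glucose.lam)
        state.veg3[:] = micro._diffuse(state.veg3, cfg.vegf.lam)
    state.glu3[:] = micro.update_glucose(state.glu3, occm, cfg.glucose)
    state.veg3[:] = micro.update_vegf(state.veg3, state.secr3, state.ves3,
                                      cfg.vegf)
    if dox_on:
        state.dox_nonzero = True
    if state.dox_nonzero:
        state.dox3[:] = micro.update_drug(state.dox3, state.ves3, cfg.dox,
                                          dox_mult, dox_on)
    if sun_on:
        state.sun_nonzero = True
    if state.sun_nonzero:
        state.sun3[:] = micro.update_drug(state.sun3, state.ves3,
                                          cfg.sunitinib, sun_mult, sun_on)

    # per-step derived neighborhood averages (guard-extended flat arrays)
    bc = micro.box_count(cfg.dims)
    state.vnglu = _extend_flat(state, micro.vn_average_field(state.glu3))
    state.vnveg = _extend_flat(state, micro.vn_average_field(state.veg3))
    mglu3 = micro.box_sum_field(state.glu3) / bc
    var3 = np.maximum(micro.box_sum_field(state.glu3 ** 2) / bc - mglu3 ** 2, 0.0)
    state.mglu = _extend_flat(state, mglu3)
    state.sglu = _extend_flat(state, np.sqrt(var3))
    state.mveg = _extend_flat(state, micro.box_sum_field(state.veg3) / bc)
    state.has_dox = bool(state.dox_nonzero and state.dox3.max() > 0)
    state.has_sun = bool(state.sun_nonzero and state.sun3.max() > 0)
    if state.has_dox:
        state.vndox = _extend_flat(state, micro.vn_average_field(state.dox3))
        state.mdox = _extend_flat(state, micro.box_sum_field(state.dox3) / bc)
    else:
        state.vndox = state.mdox = state._zeros
    if state.has_sun:
        state.vnsun = _extend_flat(state, micro.vn_average_field(state.sun3))
        state.msun = _extend_flat(state, micro.box_sum_field(state.sun3) / bc)
    else:
        state.vnsun = state.msun = state._zeros
    state.glu = state.glu_f
    state.veg = state.veg_f

    state.n_divisions = 0
    state.n_deaths = 0
    state.n_ec_deaths = 0
    state.n_branches = 0

    # (2) melanoma agents in uniformly shuffled order
    n = state.cells.n
    alive_idx = np.flatnonzero(state.cells.state[:n] != DEAD)
    state.cells.age_h[alive_idx] += cfg.dt_h
    for i in rng.permutation(alive_idx):
        tumor_step(state, int(i), rng)

    # (3) tip endothelial agents in uniformly shuffled order
    tips = state.tree.tips()
    for t in rng.permutation(tips):
        if state.tree.alive[t] and state.tree.is_tip[t]:
            ec_step(state, int(t), rng)

    state.t_h += cfg.dt_h
    state.istep += 1
    if cfg.audit_every_step:
        state.audit()
    rec = _record(state)
    state.records.append(rec)
    log.debug(
        "t=%.0f h total=%d active=%d quiescent=%d apoptotic=%d ec=%d "
        "divisions=%d",
        rec["t_h"], rec["n_total"], rec["n_active"], rec["n_quiescent"],
        rec["n_apoptotic"], rec["n_ec"], rec["n_divisions"],
    )
    return state


def run(cfg: SimulationConfig, snapshot_times_h=()):
    """Run a full simulation.

    Returns ``(timeseries, final_state, snapshots)`` where snapshots maps the
    requested times (snapped to the step grid) to agent-position frames.
    """
    state = initialize(cfg)
    want = sorted(float(t) for t in snapshot_times_h)
    snapshots: dict[float, pd.DataFrame] = {}

    def maybe_snapshot():
        while want and want[0] <= state.t_h + 1e-9:
            snapshots[want.pop(0)] = snapshot_frame(state)

    maybe_snapshot()
    for _ in range(cfg.n_steps):
        step(state)
        maybe_snapshot()
    c = state.counts()
    log.info(
        "run finished at t=%.0f h: %d melanoma cells (%d alive), %d "
        "endothelial nodes, seed=%s",
        state.t_h, c["n_total"], c["n_alive"], c["n_ec"], cfg.seed,
    )
    return state.timeseries(), state, snapshots


def snapshot_frame(state: SimulationState) -> pd.DataFrame:
    """Agent positions as (t, x, y, z, kind, state); 0-based voxel indices."""
    rows = []
    n = state.cells.n
    ny, nz = state.dims[1], state.dims[2]
    pos = state.cells.pos[:n]
    x, rem = np.divmod(pos, ny * nz)
    y, z = np.divmod(rem, nz)
    tumor = pd.DataFrame(
        {
            "t": state.t_h,
            "x": x, "y": y, "z": z,
            "kind": "tumor",
            "state": [STATE_NAMES[s] for s in state.cells.state[:n]],
        }
    )
    vdf = state.tree.to_dataframe(state.dims)
    vessel = pd.DataFrame(
        {
            "t": state.t_h,
            "x": vdf["x"], "y": vdf["y"], "z": vdf["z"],
            "kind": "vessel",
            "state": np.where(vdf["is_tip"], "tip", "stalk"),
        }
    )
    return pd.concat([tumor, vessel], ignore_index=True)
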