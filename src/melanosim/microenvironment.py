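"""3D lattice microenvironment: neighborhoods and reaction-diffusion updates.

The tumor extracellular matrix is a regular cubic lattice (default
100x100x100 voxels, 10 um spacing — one voxel per cell radius).  Four scalar
fields live on it: glucose, VEGF, and the two drugs (doxorubicin and
sunitinib).  Each simulation step every field is updated *synchronously* by a
discrete diffusion rule over the six face-adjacent (Von Neumann) neighbors

    f'(p) = [ f(p)*(1-lam) + (lam/6) * sum_{q in VN(p)} f(q)
              + sources(p) - sinks(p) ] * (1 - decay)

followed by a clamp at zero (sinks may overdraw a voxel).  Boundaries are
reflecting (zero-flux): a missing neighbor contributes the center's own
value, which conserves mass in the absence of sources/sinks/decay.

``lam`` is a dimensionless per-step mixing fraction in [0, 1].  Physical
diffusivities can be supplied instead; see :class:`DiffusionParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import numpy as np
from scipy import ndimage

__all__ = [
    "Lattice",
    "DiffusionParams",
    "OccupancyMask",
    "von_neumann_neighbors",
    "moore_neighbors",
    "local_average_vn",
    "local_average_moore",
    "vn_neighbor_sum",
    "vn_average_field",
    "box_sum_field",
    "box_count",
    "update_glucose",
    "update_vegf",
    "update_drug",
    "neighbor_tables",
]

#: fixed Von Neumann offset order: -x, +x, -y, +y, -z, +z
VN_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1),
)

#: Moore offsets in lexicographic order (dx, dy, dz), excluding (0, 0, 0)
MOORE_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass(frozen=True)
class Lattice:
    """Cubic lattice geometry.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z).  Each axis must be >= 3.
    spacing_um
        Edge length of one voxel in micrometers (default 10 um, roughly a
        melanoma cell radius).
    """

    dims: tuple[int, int, int] = (100, 100, 100)
    spacing_um: float = 10.0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 3 for d in self.dims):
            raise ValueError(f"lattice dims must be >= 3 per axis, got {self.dims}")
        if not self.spacing_um > 0:
            raise ValueError("lattice spacing must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def contains(self, p: tuple[int, int, int]) -> bool:
        return all(0 <= c < d for c, d in zip(p, self.dims))

    def check(self, p: tuple[int, int, int]) -> None:
        if not self.contains(p):
            raise IndexError(f"voxel {p} outside lattice {self.dims}")


@dataclass
class DiffusionParams:
    """Per-field transport constants of the discrete reaction-diffusion rule.

    All quantities are per simulation step and dimensionless unless noted.

    lam : mixing fraction in [0, 1] shared with the 6 neighbors.
    permeability : additive source (glucose/drug) or sink (VEGF) magnitude at
        vessel-occupied voxels.
    uptake : additive sink at tumor voxels (glucose) or multiplicative
        fractional removal in [0, 1] applied to the whole field (drug).
    decay : natural decay fraction in [0, 1] applied after transport.
    secretion : additive source at secreting tumor voxels (VEGF only).
    diffusivity_cm2_s : optional physical diffusivity; informational unless a
        caller derives ``lam`` from it (see docs/methods.md).
    """

    lam: float = 0.0
    permeability: float = 0.0
    uptake: float = 0.0
    decay: float = 0.0
    secretion: float = 0.0
    diffusivity_cm2_s: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError(f"decay must be in [0, 1], got {self.decay}")
        for name in ("permeability", "uptake", "secretion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class OccupancyMask:
    """Boolean per-voxel occupancy (one agent per voxel; masks are disjoint)."""

    tumor_occupied: np.ndarray
    vessel_occupied: np.ndarray

    def __post_init__(self) -> None:
        if self.tumor_occupied.shape != self.vessel_occupied.shape:
            raise ValueError("occupancy masks must share a shape")
        if np.any(self.tumor_occupied & self.vessel_occupied):
            raise ValueError("a voxel cannot be tumor- and vessel-occupied")


# ---------------------------------------------------------------------------
# neighborhoods


def von_neumann_neighbors(p, lattice: Lattice) -> list[tuple[int, int, int]]:
    """In-bounds face neighbors of ``p`` in fixed order -x,+x,-y,+y,-z,+z."""
    lattice.check(p)
    x, y, z = p
    out = []
    for dx, dy, dz in VN_OFFSETS:
        q = (x + dx, y + dy, z + dz)
        if lattice.contains(q):
            out.append(q)
    return out


def moore_neighbors(p, lattice: Lattice) -> list[tuple[int, int, int]]:
    """In-bounds 26-neighborhood of ``p`` in lexicographic offset order."""
    lattice.check(p)
    x, y, z = p
    out = []
    for dx, dy, dz in MOORE_OFFSETS:
        q = (x + dx, y + dy, z + dz)
        if lattice.contains(q):
            out.append(q)
    return out


def local_average_vn(values: np.ndarray, p, lattice: Lattice | None = None) -> float:
    """Mean of a field over ``p`` and its in-bounds Von Neumann neighbors."""
    lattice = lattice or Lattice(values.shape)
    nbrs = von_neumann_neighbors(p, lattice)
    total = float(values[p]) + sum(float(values[q]) for q in nbrs)
    return total / (1 + len(nbrs))


def local_average_moore(values: np.ndarray, p, lattice: Lattice | None = None) -> float:
    """Mean of a field over ``p`` and its in-bounds Moore neighbors."""
    lattice = lattice or Lattice(values.shape)
    nbrs = moore_neighbors(p, lattice)
    total = float(values[p]) + sum(float(values[q]) for q in nbrs)
    return total / (1 + len(nbrs))


# ---------------------------------------------------------------------------
# whole-field helpers (vectorized, used every step)


def _shifted(a: np.ndarray, axis: int, step: int, reflect: bool) -> np.ndarray:
    """Neighbor values along one axis; out-of-bounds replaced per boundary rule.

    With ``reflect`` the missing neighbor contributes the center's own value
    (zero-flux boundary); otherwise it contributes zero.
    """
    sl_src: list[slice] = [slice(None)] * 3
    sl_edge: list[slice] = [slice(None)] * 3
    out = np.empty_like(a)
    if step == -1:  # value of the -axis neighbor
        sl_dst = [slice(None)] * 3
        sl_dst[axis] = slice(1, None)
        sl_src[axis] = slice(None, -1)
        sl_edge[axis] = slice(0, 1)
        out[tuple(sl_dst)] = a[tuple(sl_src)]
        out[tuple(sl_edge)] = a[tuple(sl_edge)] if reflect else 0.0
    else:  # value of the +axis neighbor
        sl_dst = [slice(None)] * 3
        sl_dst[axis] = slice(None, -1)
        sl_src[axis] = slice(1, None)
        sl_edge[axis] = slice(-1, None)
        out[tuple(sl_dst)] = a[tuple(sl_src)]
        out[tuple(sl_edge)] = a[tuple(sl_edge)] if reflect else 0.0
    return out


def vn_neighbor_sum(a: np.ndarray, reflect: bool = True) -> np.ndarray:
    """Sum of the six VN neighbor values per voxel, in fixed -x,+x,-y,+y,-z,+z
    order (bitwise-reproducible against a naive loop using the same order)."""
    s = _shifted(a, 0, -1, reflect)
    s = s + _shifted(a, 0, +1, reflect)
    s = s + _shifted(a, 1, -1, reflect)
    s = s + _shifted(a, 1, +1, reflect)
    s = s + _shifted(a, 2, -1, reflect)
    s = s + _shifted(a, 2, +1, reflect)
    return s


@lru_cache(maxsize=8)
def _vn_count(dims: tuple[int, int, int]) -> np.ndarray:
    ones = np.ones(dims)
    return 1.0 + vn_neighbor_sum(ones, reflect=False)


@lru_cache(maxsize=8)
def box_count(dims: tuple[int, int, int]) -> np.ndarray:
    """Number of in-bounds voxels in each 3x3x3 box (site + Moore neighbors)."""
    ones = np.ones(dims)
    return box_sum_field(ones)


def vn_average_field(a: np.ndarray) -> np.ndarray:
    """Per-voxel mean over the site and its in-bounds VN neighbors."""
    s = a + vn_neighbor_sum(a, reflect=False)
    return s / _vn_count(a.shape)


def box_sum_field(a: np.ndarray) -> np.ndarray:
    """Per-voxel 3x3x3 box sum (site + in-bounds Moore neighbors), separable."""
    k = np.ones(3)
    out = ndimage.correlate1d(a, k, axis=0, mode="constant", cval=0.0)
    out = ndimage.correlate1d(out, k, axis=1, mode="constant", cval=0.0)
    out = ndimage.correlate1d(out, k, axis=2, mode="constant", cval=0.0)
    return out


def moore_average_field(a: np.ndarray) -> np.ndarray:
    """Per-voxel mean over the site and its in-bounds Moore neighbors."""
    return box_sum_field(a) / box_count(a.shape)


# ---------------------------------------------------------------------------
# field updates


def _diffuse(field: np.ndarray, lam: float) -> np.ndarray:
    return field * (1.0 - lam) + (lam / 6.0) * vn_neighbor_sum(field, reflect=True)


def update_glucose(
    field: np.ndarray,
    occ: OccupancyMask,
    params: DiffusionParams,
) -> np.ndarray:
    """One synchronous glucose step: diffusion, vessel delivery, tumor uptake,
    natural decay, then clamp at zero.

    Vessel voxels add ``permeability`` per step; live tumor voxels remove
    ``uptake`` per step (additive; a starving voxel clamps to zero rather than
    going negative).
    """
    if field.shape != occ.tumor_occupied.shape:
        raise ValueError("field and occupancy shapes disagree")
    new = _diffuse(field, params.lam)
    new = new + occ.vessel_occupied * params.permeability
    new = new - occ.tumor_occupied * params.uptake
    new = new * (1.0 - params.decay)
    return np.maximum(new, 0.0)


def update_vegf(
    field: np.ndarray,
    occ_secreting_tumor: np.ndarray,
    occ_vessel: np.ndarray,
    params: DiffusionParams,
) -> np.ndarray:
    """One synchronous VEGF step: secretion by *starving* tumor cells,
    consumption at vessel voxels, diffusion and decay, clamped at zero."""
    new = _diffuse(field, params.lam)
    new = new + occ_secreting_tumor * params.secretion
    new = new - occ_vessel * params.permeability
    new = new * (1.0 - params.decay)
    return np.maximum(new, 0.0)


def update_drug(
    field: np.ndarray,
    occ_vessel: np.ndarray,
    params: DiffusionParams,
    dose_multiplier: float = 1.0,
    dosing_active: bool = True,
) -> np.ndarray:
    """One synchronous drug step (doxorubicin or sunitinib share this rule).

    While dosing is active every vessel voxel releases
    ``permeability * dose_multiplier`` per step; the whole field then loses
    the ``uptake`` fraction (multiplicative cellular uptake/clearance).
    """
    if dose_multiplier < 0:
        raise ValueError("dose_multiplier must be nonnegative")
    if not 0.0 <= params.uptake <= 1.0:
        raise ValueError("drug uptake fraction must be in [0, 1]")
    new = _diffuse(field, params.lam)
    if dosing_active and dose_multiplier > 0:
        new = new + occ_vessel * (params.permeability * dose_multiplier)
    new = new * (1.0 - params.uptake)
    return np.maximum(new, 0.0)


# ---------------------------------------------------------------------------
# flat-index neighbor tables (hot-path support for the agent loops)


@lru_cache(maxsize=4)
def neighbor_tables(dims: tuple[int, int, int]):
    """Precomputed flat-index neighbor tables for a lattice shape.

    Returns ``(vn_idx, vn_n, moore_idx, moore_n, sentinel)`` where the index
    arrays have one row per voxel (C-order flat index) and out-of-bounds slots
    hold ``sentinel = n_voxels``, pointing at an extra guard element that
    callers append to their flat arrays.
    """
    nx, ny, nz = dims
    n = nx * ny * nz
    sentinel = n
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    x = x.ravel()
    y = y.ravel()
    z = z.ravel()

    def table(offsets):
        k = len(offsets)
        idx = np.full((n, k), sentinel, dtype=np.int64)
        for j, (dx, dy, dz) in enumerate(offsets):
            qx, qy, qz = x + dx, y + dy, z + dz
            ok = (
                (qx >= 0) & (qx < nx) & (qy >= 0) & (qy < ny) & (qz >= 0) & (qz < nz)
            )
            idx[ok, j] = (qx[ok] * ny + qy[ok]) * nz + qz[ok]
        counts = (idx != sentinel).sum(axis=1).astype(np.int16)
        return idx, counts

    vn_idx, vn_n = table(VN_OFFSETS)
    moore_idx, moore_n = table(MOORE_OFFSETS)
    return vn_idx, vn_n, moore_idx, moore_n, sentinel
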