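"""Synthetic study domains: terrain, soils, streams, farm parcels, D8 routing.

The generated landscape mimics an irrigated river-valley plantation: a
smooth elevation surface sloping toward a meandering stream channel,
slow-draining vertisol-like soil (SLOW) on the low flat ground, freely
draining soil (FAST) on the slopes, a persistently wet riparian corridor
(RIPARIAN) along the channel, and four contiguous farm parcels on the flat
valley floor.  Surface routing uses single-direction D8 steepest descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["DomainGrid", "make_domain", "SOIL_SLOW", "SOIL_FAST", "SOIL_RIPARIAN",
           "D8_OFFSETS", "local_slope"]

# Soil class codes
SOIL_SLOW = 0      # clay-rich, slow drainage (Ustert-like)
SOIL_FAST = 1      # well drained (Ustoll-like)
SOIL_RIPARIAN = 2  # stream corridor, persistently wet

SOIL_NAMES = {SOIL_SLOW: "SLOW", SOIL_FAST: "FAST", SOIL_RIPARIAN: "RIPARIAN"}

# D8 neighbor offsets, direction codes 0..7 starting north, clockwise.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
D8_PIT = -1


@dataclass
class DomainGrid:
    """Static layers of a regular-grid study domain.

    Row 0 is the northernmost row; cell indices are 0-based.  ``farm_id``
    is 0 outside farms and 1..4 inside the four irrigation parcels.
    ``flow_dir`` holds D8 direction codes 0..7 (see :data:`D8_OFFSETS`)
    or -1 for pits/outlets; it is acyclic because every non-pit cell
    drains to a strictly lower neighbor.
    """

    n_rows: int
    n_cols: int
    cell_size: float  # m
    soil_class: np.ndarray       # (rows, cols) int8 codes
    farm_id: np.ndarray          # (rows, cols) int8, 0 = outside
    elevation: np.ndarray        # (rows, cols) m
    flow_dir: np.ndarray         # (rows, cols) int8 D8 code or -1
    stream_mask_static: np.ndarray  # (rows, cols) bool, channel cells

    def __post_init__(self) -> None:
        shape = (self.n_rows, self.n_cols)
        for name in ("soil_class", "farm_id", "elevation", "flow_dir",
                     "stream_mask_static"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if not np.isin(np.unique(self.farm_id), [0, 1, 2, 3, 4]).all():
            raise ValueError("farm_id values must be in {0,1,2,3,4}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Cell area in m^2."""
        return self.cell_size ** 2

    def downstream_index(self) -> np.ndarray:
        """Flat index of each cell's downstream neighbor (-1 for pits)."""
        n_rows, n_cols = self.shape
        idx = np.full(n_rows * n_cols, -1, dtype=np.int64)
        rr, cc = np.indices(self.shape)
        for code, (dr, dc) in enumerate(D8_OFFSETS):
            sel = self.flow_dir == code
            idx[np.flatnonzero(sel.ravel())] = (
                (rr[sel] + dr) * n_cols + (cc[sel] + dc)
            )
        return idx


def local_slope(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Maximum downhill gradient to any D8 neighbor (dimensionless, >= 0)."""
    n_rows, n_cols = elevation.shape
    slope = np.zeros_like(elevation, dtype=float)
    for (dr, dc) in D8_OFFSETS:
        dist = cell_size * np.hypot(dr, dc)
        shifted = _shift(elevation, dr, dc)
        drop = (elevation - shifted) / dist
        valid = ~np.isnan(shifted)
        slope[valid] = np.maximum(slope[valid], drop[valid])
    return np.clip(slope, 0.0, None)


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Array of neighbor values at offset (dr, dc); NaN outside the grid."""
    out = np.full(arr.shape, np.nan)
    rs = slice(max(dr, 0), arr.shape[0] + min(dr, 0))
    rt = slice(max(-dr, 0), arr.shape[0] + min(-dr, 0))
    cs = slice(max(dc, 0), arr.shape[1] + min(dc, 0))
    ct = slice(max(-dc, 0), arr.shape[1] + min(-dc, 0))
    out[rt, ct] = arr[rs, cs]
    return out


def _d8_flow_dir(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Steepest-descent D8 directions; ties broken by the lowest code.

    Cells drain only to strictly lower neighbors, which makes the flow
    graph acyclic by construction; cells with no lower neighbor are pits
    (code -1), including boundary cells whose descent leaves the grid.
    """
    best_drop = np.zeros(elevation.shape)
    fdir = np.full(elevation.shape, D8_PIT, dtype=np.int8)
    for code, (dr, dc) in enumerate(D8_OFFSETS):
        dist = cell_size * np.hypot(dr, dc)
        shifted = _shift(elevation, dr, dc)
        drop = (elevation - shifted) / dist
        better = ~np.isnan(shifted) & (drop > 0) & (drop > best_drop + 1e-12)
        best_drop[better] = drop[better]
        fdir[better] = code
    return fdir


def make_domain(n_rows: int, n_cols: int, seed: int,
                farm_fraction: float = 0.25,
                cell_size: float = 50.0) -> DomainGrid:
    """Generate a synthetic valley domain with streams, soils and farms.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (>= 8 each).
    seed
        Seed for the terrain noise; identical seeds give bit-identical
        domains.
    farm_fraction
        Approximate fraction of all grid cells covered by the four farm
        parcels.
    cell_size
        Cell edge length in metres (default 50 m).
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("domain must be at least 8x8 cells")
    if not (0 < farm_fraction < 1):
        raise ValueError("farm_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    rows = np.arange(n_rows)[:, None].astype(float)
    cols = np.arange(n_cols)[None, :].astype(float)

    # Meandering north-south channel near the domain center.
    amplitude = 0.12 * n_cols
    channel_col = n_cols / 2.0 + amplitude * np.sin(
        2.0 * np.pi * rows[:, 0] / max(n_rows, 1) * 1.5
    )
    channel_idx = np.clip(np.round(channel_col), 1, n_cols - 2).astype(int)
    # Keep consecutive channel cells 8-connected so the carved channel
    # drains along itself.
    for r in range(1, n_rows):
        channel_idx[r] = int(np.clip(channel_idx[r], channel_idx[r - 1] - 1,
                                     channel_idx[r - 1] + 1))

    # Elevation: down-valley gradient + cross-valley rise + smooth noise.
    down = (n_rows - 1 - rows) * cell_size * 0.004
    dist_c = np.abs(cols - channel_col[:, None]) * cell_size
    cross = 0.008 * dist_c + 8e-6 * dist_c ** 2
    noise = gaussian_filter(rng.normal(0.0, 1.0, (n_rows, n_cols)),
                            sigma=max(min(n_rows, n_cols) / 12.0, 1.0))
    noise = 2.5 * noise / max(np.std(noise), 1e-9)
    elevation = 1350.0 + down + cross + noise

    # Carve the channel so it drains monotonically southward.
    stream = np.zeros((n_rows, n_cols), dtype=bool)
    stream[np.arange(n_rows), channel_idx] = True
    carve = 1.5 + 0.02 * cell_size * (rows[:, 0] / max(n_rows - 1, 1))
    elevation[stream] -= carve[np.where(stream)[0]] + 1.0
    # Enforce strictly decreasing down-channel elevation so no channel
    # cell is a pit short of the outlet.
    ch_elev = elevation[np.arange(n_rows), channel_idx]
    ch_elev = np.minimum.accumulate(ch_elev) - 0.05 * np.arange(n_rows)
    elevation[np.arange(n_rows), channel_idx] = ch_elev

    flow_dir = _d8_flow_dir(elevation, cell_size)
    slope = local_slope(elevation, cell_size)

    # Riparian corridor: channel cells plus their 8-neighborhood.
    riparian = stream.copy()
    for (dr, dc) in D8_OFFSETS:
        shifted = _shift(stream.astype(float), dr, dc)
        riparian |= shifted == 1.0
    soil = np.full((n_rows, n_cols), SOIL_FAST, dtype=np.int8)
    flat = slope < np.quantile(slope, 0.55)
    low = elevation < np.quantile(elevation, 0.5)
    soil[flat & low] = SOIL_SLOW
    soil[riparian] = SOIL_RIPARIAN

    # Four contiguous rectangular farm parcels centred on the slow flat
    # valley floor, split into quadrants (1=NW, 2=NE, 3=SW, 4=SE).
    farm_id = np.zeros((n_rows, n_cols), dtype=np.int8)
    target = farm_fraction * n_rows * n_cols
    aspect = n_rows / n_cols
    h = int(np.clip(np.round(np.sqrt(target * aspect)), 2, n_rows))
    w = int(np.clip(np.round(target / h), 2, n_cols))
    slow_cells = np.argwhere(soil == SOIL_SLOW)
    if slow_cells.size:
        cr, cc_ = slow_cells.mean(axis=0)
    else:  # fall back to the domain center
        cr, cc_ = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    r0 = int(np.clip(np.round(cr - h / 2), 0, n_rows - h))
    c0 = int(np.clip(np.round(cc_ - w / 2), 0, n_cols - w))
    rm, cm = r0 + h // 2, c0 + w // 2
    farm_id[r0:rm, c0:cm] = 1
    farm_id[r0:rm, cm:c0 + w] = 2
    farm_id[rm:r0 + h, c0:cm] = 3
    farm_id[rm:r0 + h, cm:c0 + w] = 4

    return DomainGrid(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
        soil_class=soil, farm_id=farm_id, elevation=elevation,
        flow_dir=flow_dir, stream_mask_static=stream,
    )
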