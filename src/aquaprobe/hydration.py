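"""Water-occupancy volumetric maps and per-probe hydration statistics.

An occupancy grid discretises space into cubic voxels and stores, per voxel,
the fraction of trajectory frames in which at least one selected atom
(water oxygen by default) lies inside it — the probability of water
presence.  Isoprobability surfaces of such grids (threshold 0.3 by
convention) visualise the hydrated regions of a receptor; difference grids
between conformational states localise activation-coupled hydration
changes.  Per-residue contact fractions quantify hydration at specific
probe positions (first-shell cutoff 3.5 A to side-chain heavy atoms).

Occupancy counts atom centers in half-open voxel cubes, so the grid is
exactly reproducible by exhaustive counting.  Trajectories must be
pre-imaged; frames should be superposed on the receptor before gridding
(see :func:`aquaprobe.trajectory.superpose_frames`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trajectory import (
    AtomSelection,
    BACKBONE_NAMES,
    TrajectoryEnsemble,
    water_oxygen_selection,
)

__all__ = [
    "HydrationGrid",
    "ProbeHydrationProfile",
    "HydrationChange",
    "StateComparison",
    "occupancy_grid",
    "threshold_mask",
    "difference_grid",
    "probe_hydration",
    "classify_hydration_change",
    "compare_states",
    "write_dx",
    "read_dx",
]

DEFAULT_SPACING = 1.0  # Angstrom
DEFAULT_PADDING = 3.0  # Angstrom
DEFAULT_CUTOFF = 3.5  # Angstrom, first hydration shell
DEFAULT_ISO_THRESHOLD = 0.3
DEFAULT_DELTA_THRESHOLD = 0.1


@dataclass(frozen=True)
class HydrationGrid:
    """Regular isotropic voxel grid of water-presence probability.

    ``values[i, j, k]`` is the probability for the half-open cube
    ``[origin + (i,j,k) * spacing, origin + (i+1,j+1,k+1) * spacing)``.
    Occupancy grids hold values in [0, 1] that are exact multiples of
    ``1 / n_frames``; difference grids hold signed values in [-1, 1].
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    n_frames: int
    selection_descriptor: str = ""

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("values must be a 3-D array with positive dims")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid values must be finite")
        if values.min() < -1.0 - 1e-12 or values.max() > 1.0 + 1e-12:
            raise ValueError("grid values must lie in [-1, 1]")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "values", values)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_geometry(self, other: "HydrationGrid", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )


@dataclass(frozen=True)
class ProbeHydrationProfile:
    """Hydration statistics for one probe residue."""

    probe_residue: int
    bw_label: str
    cutoff: float
    contact_fraction: float
    mean_count: float
    selection_descriptor: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must lie in [0, 1]")
        if self.mean_count < 0:
            raise ValueError("mean_count must be >= 0")


@dataclass(frozen=True)
class HydrationChange:
    """Direction call for one probe between two conformational states."""

    probe_residue: int
    bw_label: str
    fraction_inactive: float
    fraction_active: float
    delta: float
    call: str  # increase | decrease | none


@dataclass(frozen=True)
class StateComparison:
    entries: tuple[HydrationChange, ...]
    difference: HydrationGrid | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

def occupancy_grid(
    e: TrajectoryEnsemble,
    sel: AtomSelection | None = None,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    bounds: tuple | None = None,
) -> HydrationGrid:
    """Per-voxel water-presence probability over all frames.

    The grid covers the padded bounding box of the selected atoms across
    the whole trajectory (or explicit ``bounds = (lo, hi)`` corners, e.g.
    to grid two states on common geometry for differencing; atoms outside
    explicit bounds are ignored).  A voxel counts as occupied in a frame
    iff at least one selected atom center falls in its half-open cube; the
    voxel value is the occupied-frame count divided by the number of frames.
    """
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    if sel is None:
        sel = water_oxygen_selection()
    idx = sel.resolve(e)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    coords = e.frames[:, idx, :]  # (n_frames, n_sel, 3)
    if bounds is None:
        lo = coords.reshape(-1, 3).min(axis=0) - padding
        hi = coords.reshape(-1, 3).max(axis=0) + padding
    else:
        lo = np.asarray(bounds[0], dtype=float).reshape(3)
        hi = np.asarray(bounds[1], dtype=float).reshape(3)
        if np.any(hi <= lo):
            raise ValueError("bounds must satisfy hi > lo on every axis")
    origin = lo
    dims = np.floor((hi - origin) / spacing).astype(int) + 1
    counts = np.zeros(tuple(dims), dtype=np.int64)
    for f in range(e.n_frames):
        ijk = np.floor((coords[f] - origin) / spacing).astype(int)
        inside = np.all((ijk >= 0) & (ijk < dims), axis=1)
        occupied = np.unique(ijk[inside], axis=0)
        if occupied.size:
            counts[occupied[:, 0], occupied[:, 1], occupied[:, 2]] += 1
    return HydrationGrid(
        origin=origin,
        spacing=float(spacing),
        values=counts / e.n_frames,
        n_frames=e.n_frames,
        selection_descriptor=sel.descriptor,
    )


def threshold_mask(g: HydrationGrid, p: float = DEFAULT_ISO_THRESHOLD):
    """Boolean mask of voxels with probability >= p, and its volume in A^3."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = g.values >= p
    volume = float(mask.sum()) * g.spacing**3
    return mask, volume


def difference_grid(a: HydrationGrid, b: HydrationGrid) -> HydrationGrid:
    """Elementwise a - b on identical geometry (signed values in [-1, 1])."""
    if not a.same_geometry(b):
        raise ValueError("grids differ in origin, spacing or dims")
    return HydrationGrid(
        origin=a.origin,
        spacing=a.spacing,
        values=a.values - b.values,
        n_frames=max(a.n_frames, b.n_frames),
        selection_descriptor=f"difference ({a.selection_descriptor})",
    )


# ---------------------------------------------------------------------------
# Probe hydration
# ---------------------------------------------------------------------------

def _probe_reference_atoms(e: TrajectoryEnsemble, probe_residue: int) -> np.ndarray:
    residue_atoms = [
        i for i, a in enumerate(e.atoms) if a.residue_index == probe_residue
    ]
    if not residue_atoms:
        raise ValueError(f"residue {probe_residue} not found in ensemble")
    side_chain = [
        i
        for i in residue_atoms
        if e.atoms[i].element != "H" and e.atoms[i].name not in BACKBONE_NAMES
    ]
    if side_chain:
        return np.asarray(side_chain, dtype=int)
    ca = [i for i in residue_atoms if e.atoms[i].name == "CA"]
    if not ca:
        raise ValueError(
            f"residue {probe_residue} has neither side-chain heavy atoms nor CA"
        )
    return np.asarray(ca, dtype=int)


def probe_hydration(
    e: TrajectoryEnsemble,
    probe_residue: int,
    sel: AtomSelection | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    bw_label: str = "",
) -> ProbeHydrationProfile:
    """Water contact statistics around one probe residue.

    Per frame, waters within ``cutoff`` of any side-chain heavy atom of the
    probe residue are counted (falling back to the C-alpha for glycine-like
    residues).  ``contact_fraction`` is the fraction of frames with at least
    one such water; ``mean_count`` the average number per frame.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    if sel is None:
        sel = water_oxygen_selection()
    widx = sel.resolve(e)
    ref = _probe_reference_atoms(e, probe_residue)
    if widx.size == 0:
        return ProbeHydrationProfile(
            probe_residue=probe_residue,
            bw_label=bw_label,
            cutoff=float(cutoff),
            contact_fraction=0.0,
            mean_count=0.0,
            selection_descriptor=sel.descriptor,
        )
    waters = e.frames[:, widx, :]  # (F, W, 3)
    refc = e.frames[:, ref, :]  # (F, R, 3)
    # min distance of each water to the reference atoms, per frame
    d = np.linalg.norm(waters[:, :, None, :] - refc[:, None, :, :], axis=-1)
    near = (d.min(axis=2) <= cutoff)  # (F, W)
    counts = near.sum(axis=1)
    return ProbeHydrationProfile(
        probe_residue=probe_residue,
        bw_label=bw_label,
        cutoff=float(cutoff),
        contact_fraction=float(np.mean(counts >= 1)),
        mean_count=float(np.mean(counts)),
        selection_descriptor=sel.descriptor,
    )


def classify_hydration_change(
    inactive: ProbeHydrationProfile,
    active: ProbeHydrationProfile,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> HydrationChange:
    """Direction call between states: delta = active - inactive contact fraction."""
    if abs(inactive.cutoff - active.cutoff) > 1e-12:
        raise ValueError("profiles computed with different cutoffs")
    if inactive.selection_descriptor != active.selection_descriptor:
        raise ValueError("profiles computed with different atom selections")
    if inactive.probe_residue != active.probe_residue:
        raise ValueError("profiles describe different probe residues")
    delta = active.contact_fraction - inactive.contact_fraction
    if delta >= delta_threshold:
        call = "increase"
    elif delta <= -delta_threshold:
        call = "decrease"
    else:
        call = "none"
    return HydrationChange(
        probe_residue=inactive.probe_residue,
        bw_label=inactive.bw_label or active.bw_label,
        fraction_inactive=inactive.contact_fraction,
        fraction_active=active.contact_fraction,
        delta=float(delta),
        call=call,
    )


def compare_states(
    entries,
    difference: HydrationGrid | None = None,
) -> StateComparison:
    return StateComparison(entries=tuple(entries), difference=difference)


# ---------------------------------------------------------------------------
# OpenDX I/O (via GridDataFormats)
# ---------------------------------------------------------------------------

def write_dx(g: HydrationGrid, path: str | Path) -> None:
    """Write the grid as an OpenDX scalar field readable by molecular viewers."""
    from gridData import Grid

    Grid(g.values, origin=np.asarray(g.origin), delta=g.spacing).export(
        str(path), file_format="dx"
    )


def read_dx(path: str | Path, n_frames: int = 1, selection_descriptor: str = "") -> HydrationGrid:
    """Read an OpenDX scalar field.

    The DX format carries no frame count, so ``n_frames`` defaults to 1
    (probability semantics are preserved; occupancy-multiple semantics are
    not recoverable from the file alone).
    """
    import re

    from gridData import Grid

    # Validate completeness first: the gridData tokenizer does not fail
    # cleanly on truncated "data follows" sections.
    text = Path(path).read_text()
    header = re.search(r"items\s+(\d+)\s+data follows", text)
    if header is None:
        raise ValueError(f"cannot parse DX file {path}: no data section header")
    n_expected = int(header.group(1))
    number = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
    n_found = sum(1 for tok in text[header.end():].split() if number.match(tok))
    if n_found < n_expected:
        raise ValueError(
            f"cannot parse DX file {path}: truncated data section "
            f"({n_found} of {n_expected} values)"
        )
    try:
        grid = Grid(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse DX file {path}: {exc}") from exc
    delta = np.asarray(grid.delta, dtype=float)
    if delta.ndim == 2:
        diag = np.diag(delta)
    else:
        diag = delta
    if not np.allclose(diag, diag[0]):
        raise ValueError("anisotropic DX grids are not supported")
    return HydrationGrid(
        origin=np.asarray(grid.origin, dtype=float),
        spacing=float(diag[0]),
        values=np.asarray(grid.grid, dtype=float),
        n_frames=n_frames,
        selection_descriptor=selection_descriptor,
    )
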