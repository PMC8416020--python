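"""Trajectory ensembles: loading, atom selection, rigid superposition.

A :class:`TrajectoryEnsemble` is a lightweight in-memory container — an atom
table plus an (n_frames, n_atoms, 3) coordinate array in Angstrom — loaded
from standard topology/trajectory files through MDAnalysis.  Trajectories
are assumed pre-imaged (solute whole, waters wrapped into the primary cell);
no minimum-image correction is applied anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "TrajectoryEnsemble",
    "AtomSelection",
    "water_oxygen_selection",
    "load_ensemble",
    "kabsch",
    "superpose_frames",
]

#: Residue names recognised as water by the default selection.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})
#: Oxygen atom names used by common water models.
WATER_OXYGEN_NAMES = frozenset({"OW", "OH2"})
#: Backbone atom names excluded from side-chain selections.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_name: str
    residue_index: int  # 1-based
    chain: str = "A"


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Atom table plus per-frame coordinates (Angstrom)."""

    atoms: tuple[Atom, ...]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths, optional
    state_label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.frames, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {coords.shape[1]} != atom table length {len(self.atoms)}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        if any(a.residue_index < 1 for a in self.atoms):
            raise ValueError("residue indices must be >= 1")
        object.__setattr__(self, "frames", coords)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class AtomSelection:
    """A predicate over atoms together with a human-readable descriptor."""

    predicate: Callable[[Atom], bool]
    descriptor: str = "custom"

    def resolve(self, ensemble: TrajectoryEnsemble) -> np.ndarray:
        """Indices of matching atoms (unique, in order)."""
        idx = np.array(
            [i for i, a in enumerate(ensemble.atoms) if self.predicate(a)], dtype=int
        )
        return idx


def water_oxygen_selection() -> AtomSelection:
    """Default water selection: oxygen atoms (OW/OH2) of water residues."""
    return AtomSelection(
        predicate=lambda a: a.name in WATER_OXYGEN_NAMES
        and a.residue_name in WATER_RESNAMES,
        descriptor="water oxygens (OW/OH2 in HOH/TIP3/SOL/WAT)",
    )


def calpha_selection() -> AtomSelection:
    """Receptor C-alpha atoms (non-water residues)."""
    return AtomSelection(
        predicate=lambda a: a.name == "CA" and a.residue_name not in WATER_RESNAMES,
        descriptor="receptor CA atoms",
    )


def load_ensemble(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    state_label: str = "",
) -> TrajectoryEnsemble:
    """Load topology (PDB or equivalent) + trajectory (multi-model PDB/DCD/XTC).

    A single-structure PDB given as both topology and trajectory (or with
    ``trajectory_path`` omitted) yields a one-frame ensemble.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    try:
        if trajectory_path is None or Path(trajectory_path) == topology_path:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(Path(trajectory_path)))
    except Exception as exc:
        raise ValueError(
            f"cannot load ensemble from {topology_path} / {trajectory_path}: {exc}"
        ) from exc

    def _element(atom) -> str:
        try:
            el = atom.element
            if el:
                return str(el).capitalize()
        except Exception:
            pass
        name = atom.name.strip()
        # Strip leading digits (e.g. 1HB) then take the leading letter.
        stripped = name.lstrip("0123456789")
        return (stripped[:1] or "X").upper()

    atoms = tuple(
        Atom(
            name=str(a.name).strip(),
            element=_element(a),
            residue_name=str(a.resname).strip(),
            residue_index=int(a.resid),
            chain=str(getattr(a, "segid", "") or "A").strip() or "A",
        )
        for a in u.atoms
    )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    box = None
    try:
        dims = [ts.dimensions[:3].copy() for ts in u.trajectory if ts.dimensions is not None]
        if len(dims) == len(frames):
            box = np.asarray(dims, dtype=float)
    except Exception:
        box = None
    return TrajectoryEnsemble(atoms=atoms, frames=frames, box=box, state_label=state_label)


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal least-squares rotation R and translation t mapping mobile onto target.

    Both inputs are (n, 3); returns (R, t) such that ``mobile @ R.T + t``
    minimises the RMSD to ``target``.  Proper rotation enforced (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need matching coordinate sets with >= 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def superpose_frames(
    e: TrajectoryEnsemble,
    reference_selection: AtomSelection | Sequence[int] | None = None,
    reference_coords: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Rigid-body superpose every frame onto the reference over a selection.

    The default reference is frame 1 of the ensemble itself and the default
    selection is the receptor C-alpha atoms; grids and probe statistics are
    therefore accumulated in the receptor frame.
    """
    if reference_selection is None:
        reference_selection = calpha_selection()
    if isinstance(reference_selection, AtomSelection):
        idx = reference_selection.resolve(e)
    else:
        idx = np.asarray(reference_selection, dtype=int)
        if idx.size != np.unique(idx).size or (idx.size and idx.max() >= e.n_atoms):
            raise ValueError("selection indices must be unique and in range")
    if idx.size < 3:
        raise ValueError("superposition needs >= 3 reference atoms")
    ref = (
        np.asarray(reference_coords, dtype=float)
        if reference_coords is not None
        else e.frames[0, idx]
    )
    if ref.shape != (idx.size, 3):
        raise ValueError("reference coordinates do not match the selection size")
    out = np.empty_like(e.frames)
    for f in range(e.n_frames):
        R, t = kabsch(e.frames[f, idx], ref)
        out[f] = e.frames[f] @ R.T + t
    return replace(e, frames=out)
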