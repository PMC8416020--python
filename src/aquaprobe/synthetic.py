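"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and emits
objects that already satisfy the invariants of the analysis types they feed:

* three-band emission spectra with known fractional areas (hence known H);
* rigid toy "receptor" trajectories in which named probe sites contain a
  water with a stated per-frame, per-state probability — encoding the
  two-state hydration contrast (a site that gains water on activation, one
  that loses it, and an invariant control);
* two-cluster C-alpha ensembles with a hinge-like terminal displacement,
  coordinate noise, and injected missing residues;
* replicate H tables with additive noise.

The toy receptor is an idealized helical scaffold: no structural realism is
claimed — only the statistical structure (site-wise water-presence
probabilities, two states) matters for testing the analysis code.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .spectra import SPECIES, BandComponent, Spectrum, evaluate_band_model
from .trajectory import Atom, TrajectoryEnsemble
from .pca import StructureEntry

__all__ = [
    "SpectrumTruth",
    "SiteSpec",
    "EnsembleTruth",
    "gen_spectrum",
    "gen_two_state_trajectory",
    "site_residue_indices",
    "gen_structure_ensemble",
    "gen_h_replicates",
    "write_spectrum_table",
    "write_pdb",
    "write_structure_ensemble",
    "write_truth",
]

DEFAULT_WAVELENGTHS = np.arange(340.0, 601.0, 1.0)  # 261 points

#: Default band parameters (center nm, width nm) per species.
DEFAULT_BANDS = {
    "neutral": (380.0, 30.0),
    "anionic": (450.0, 30.0),
    "tautomer": (510.0, 30.0),
}

SITE_RADIUS = 2.5  # A, water placement sphere around a site anchor
SITE_EXCLUSION = 6.0  # A, bulk waters are rejection-sampled outside this
PROBE_RESID_START = 101


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumTruth:
    """Ground truth of one synthetic spectrum."""

    fractional_areas: dict[str, float]
    centers: dict[str, float] = field(default_factory=lambda: {
        sp: DEFAULT_BANDS[sp][0] for sp in SPECIES
    })
    widths: dict[str, float] = field(default_factory=lambda: {
        sp: DEFAULT_BANDS[sp][1] for sp in SPECIES
    })
    shape: str = "gaussian"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.fractional_areas) != set(SPECIES):
            raise ValueError(f"fractional_areas must cover species {SPECIES}")
        fracs = np.array([self.fractional_areas[sp] for sp in SPECIES])
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("fractional areas must be >= 0 and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def H_true(self) -> float:
        return self.fractional_areas["anionic"] + self.fractional_areas["tautomer"]

    def components(self) -> list[BandComponent]:
        """Band components realizing the truth fractional areas at unit peak."""
        amps = {}
        for sp in SPECIES:
            c, w = self.centers[sp], self.widths[sp]
            if self.shape == "gaussian":
                unit_area = w * np.sqrt(2.0 * np.pi)
            else:
                sigma = w / c
                unit_area = c * sigma * np.sqrt(2.0 * np.pi) * np.exp(sigma**2 / 2)
            amps[sp] = self.fractional_areas[sp] / unit_area
        comps = [
            BandComponent(
                species=sp, center=self.centers[sp], width=self.widths[sp],
                amplitude=amps[sp], shape=self.shape,
            )
            for sp in SPECIES
        ]
        peak = float(np.max(evaluate_band_model(comps, 0.0, DEFAULT_WAVELENGTHS)))
        return [
            BandComponent(
                species=c.species, center=c.center, width=c.width,
                amplitude=c.amplitude / peak, shape=c.shape,
            )
            for c in comps
        ]


def gen_spectrum(
    truth: SpectrumTruth, wavelengths: np.ndarray | None = None
) -> tuple[Spectrum, SpectrumTruth]:
    """Noisy realization of a three-band spectrum with known truth.

    Intensities are the band model at the truth parameters (unit peak) plus
    zero-mean Gaussian noise of SD ``noise_sd`` times the peak intensity.
    """
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    comps = truth.components()
    clean = evaluate_band_model(comps, 0.0, wl)
    rng = np.random.default_rng(truth.seed)
    noisy = clean + rng.normal(scale=truth.noise_sd * float(clean.max()), size=wl.size)
    return Spectrum(wavelengths=wl, intensities=noisy), truth


# ---------------------------------------------------------------------------
# Two-state trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """One probe site of the toy receptor.

    ``presence`` maps a state label to the per-frame probability that the
    site contains a water molecule in that state.
    """

    site_label: str
    anchor: tuple[float, float, float]
    presence: dict[str, float]

    def __post_init__(self) -> None:
        for state, p in self.presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability for {state!r} not in [0, 1]")


def default_sites(box: float = 40.0) -> list[SiteSpec]:
    """The two-state contrast pattern: one site gains water on activation
    (e.g. the 5.58 pocket), one loses it (6.44), one is an invariant control."""
    c = box / 2.0
    return [
        SiteSpec("5.58", (c - 8.0, c, c), {"inactive": 0.1, "active": 0.9}),
        SiteSpec("6.44", (c + 8.0, c, c), {"inactive": 0.9, "active": 0.1}),
        SiteSpec("control", (c, c + 8.0, c), {"inactive": 0.5, "active": 0.5}),
    ]


def site_residue_indices(sites: list[SiteSpec]) -> dict[str, int]:
    """Deterministic probe residue numbering used by the generator."""
    return {s.site_label: PROBE_RESID_START + i for i, s in enumerate(sites)}


def _scaffold_atoms_coords(sites: list[SiteSpec], box: float):
    """Rigid helical scaffold plus one CB-bearing probe residue per site."""
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    center = np.array([box / 2.0] * 3)
    n_scaffold = 10
    for i in range(n_scaffold):
        theta = np.deg2rad(100.0 * i)
        pos = center + np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * (i - n_scaffold / 2)])
        atoms.append(Atom(name="CA", element="C", residue_name="GLY", residue_index=i + 1))
        coords.append(pos)
    for i, site in enumerate(sites):
        anchor = np.asarray(site.anchor, dtype=float)
        resid = PROBE_RESID_START + i
        atoms.append(Atom(name="CA", element="C", residue_name="PRB", residue_index=resid))
        coords.append(anchor + np.array([1.5, 0.0, 0.0]))
        atoms.append(Atom(name="CB", element="C", residue_name="PRB", residue_index=resid))
        coords.append(anchor)
    return atoms, np.asarray(coords)


def _uniform_in_sphere(rng: np.random.Generator, center: np.ndarray, radius: float):
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) <= radius**2:
            return center + p


def _bulk_position(rng: np.random.Generator, box: float, anchors: np.ndarray):
    """Uniform in the box, rejection-sampled away from all site spheres."""
    for _ in range(10000):
        p = rng.uniform(0.0, box, size=3)
        if np.all(np.linalg.norm(anchors - p, axis=1) > SITE_EXCLUSION):
            return p
    raise RuntimeError("could not place a bulk water outside the site spheres")


def gen_two_state_trajectory(
    sites: list[SiteSpec] | None = None,
    state: str = "inactive",
    n_frames: int = 200,
    n_bulk_waters: int = 20,
    box: float = 40.0,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Toy receptor trajectory with per-site Bernoulli water presence.

    Each site owns one dedicated water: per frame it is placed uniformly in
    a 2.5 A sphere around the site anchor with the state's presence
    probability, and otherwise in bulk (uniform in the box, outside every
    site's exclusion sphere).  Bulk waters are always in bulk.  The receptor
    scaffold is rigid across frames.
    """
    if sites is None:
        sites = default_sites(box)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    anchors = np.asarray([s.anchor for s in sites], dtype=float)
    if len(sites) > 1:
        from scipy.spatial.distance import pdist

        if np.min(pdist(anchors)) < 2 * SITE_RADIUS:
            raise ValueError("site anchors closer than twice the placement radius")
    for s in sites:
        if state not in s.presence:
            raise ValueError(f"site {s.site_label!r} has no probability for state {state!r}")

    atoms, scaffold = _scaffold_atoms_coords(sites, box)
    water_resid = PROBE_RESID_START + len(sites)
    n_waters = len(sites) + n_bulk_waters
    for w in range(n_waters):
        atoms.append(
            Atom(name="OH2", element="O", residue_name="TIP3", residue_index=water_resid + w)
        )

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, len(atoms), 3))
    ns = scaffold.shape[0]
    for f in range(n_frames):
        frames[f, :ns] = scaffold
        k = ns
        for i, site in enumerate(sites):
            if rng.random() < site.presence[state]:
                frames[f, k] = _uniform_in_sphere(rng, anchors[i], SITE_RADIUS)
            else:
                frames[f, k] = _bulk_position(rng, box, anchors)
            k += 1
        for _ in range(n_bulk_waters):
            frames[f, k] = _bulk_position(rng, box, anchors)
            k += 1
    box_arr = np.tile(np.array([box, box, box]), (n_frames, 1))
    return TrajectoryEnsemble(
        atoms=tuple(atoms), frames=frames, box=box_arr, state_label=state
    )


# ---------------------------------------------------------------------------
# Structure ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleTruth:
    """Ground truth of a synthetic two-cluster structure ensemble."""

    hinge_magnitude: float = 10.0  # A, displacement of the terminal segment
    hinge_segment: int | None = None  # columns from the C-terminal end
    noise_sd: float = 0.5  # A, isotropic coordinate noise
    missing: tuple[tuple[int, int], ...] = ()  # (structure_index, column_index)
    seed: int = 0
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hinge_magnitude < 0:
            raise ValueError("hinge magnitude must be >= 0")


def _helix_chain(n_columns: int) -> np.ndarray:
    t = np.arange(n_columns)
    theta = np.deg2rad(100.0) * t
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t])


def gen_structure_ensemble(
    truth: EnsembleTruth, n_per_cluster: int = 10, n_columns: int = 40
) -> tuple[list[StructureEntry], EnsembleTruth]:
    """Two-cluster C-alpha ensemble with a hinge-like terminal displacement.

    The active-like cluster displaces the terminal ``hinge_segment`` columns
    rigidly by ``hinge_magnitude`` Angstrom (mimicking the outward spreading
    of a TM helix); isotropic Gaussian noise is added everywhere; missing
    flags are injected at the stated (structure, column) pairs.
    """
    if n_per_cluster < 2:
        raise ValueError("n_per_cluster must be >= 2")
    if n_columns < 4:
        raise ValueError("n_columns must be >= 4")
    segment = truth.hinge_segment if truth.hinge_segment is not None else n_columns // 3
    if segment > n_columns:
        raise ValueError("hinge segment longer than the chain")
    base = _helix_chain(n_columns)
    active_base = base.copy()
    if segment > 0:
        active_base[n_columns - segment:] += np.array([truth.hinge_magnitude, 0.0, 0.0])

    rng = np.random.default_rng(truth.seed)
    entries: list[StructureEntry] = []
    labels: list[str] = []
    coords_list: list[np.ndarray] = []
    for cluster, template in (("inactive-like", base), ("active-like", active_base)):
        for i in range(n_per_cluster):
            coords = template + rng.normal(scale=truth.noise_sd, size=template.shape)
            coords_list.append(coords)
            labels.append(cluster)
    for s_idx, c_idx in truth.missing:
        if not (0 <= s_idx < len(coords_list) and 0 <= c_idx < n_columns):
            raise ValueError(f"missing spec ({s_idx}, {c_idx}) out of range")
        coords_list[s_idx][c_idx] = np.nan
    for i, coords in enumerate(coords_list):
        short = "inact" if labels[i] == "inactive-like" else "activ"
        entries.append(StructureEntry(id=f"{short}_{i:03d}", calpha=coords))
    return entries, EnsembleTruth(
        hinge_magnitude=truth.hinge_magnitude,
        hinge_segment=segment,
        noise_sd=truth.noise_sd,
        missing=truth.missing,
        seed=truth.seed,
        labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# Replicate H tables
# ---------------------------------------------------------------------------

def gen_h_replicates(
    condition_effects: dict[str, float],
    n_reps: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Replicate H values per condition: truth + Gaussian noise, clipped to [0, 1]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    for label, h in condition_effects.items():
        if not 0.0 <= h <= 1.0:
            raise ValueError(f"true H for {label!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return {
        label: list(np.clip(h + rng.normal(scale=noise_sd, size=n_reps), 0.0, 1.0))
        for label, h in condition_effects.items()
    }


# ---------------------------------------------------------------------------
# Writers (the same formats the analysis modules read)
# ---------------------------------------------------------------------------

def write_spectrum_table(s: Spectrum, path: str | Path) -> None:
    """Two-column CSV with header, readable by read_spectrum."""
    with open(path, "w") as fh:
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(s.wavelengths, s.intensities):
            fh.write(f"{wl:.6g},{it:.10g}\n")


def write_pdb(e: TrajectoryEnsemble, path: str | Path) -> None:
    """Multi-model PDB trajectory (one MODEL per frame)."""
    with open(path, "w") as fh:
        if e.box is not None:
            a, b, c = e.box[0]
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for f in range(e.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(e.atoms):
                x, y, z = e.frames[f, i]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {i + 1:5d} {name:<4s} {atom.residue_name:<4s}"
                    f"{atom.chain[:1]}{atom.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_structure_ensemble(
    entries: list[StructureEntry], out_dir: str | Path
) -> tuple[Path, Path]:
    """Aligned FASTA (gaps at missing columns) + per-structure coordinate CSVs.

    Returns (alignment_path, coords_dir); readable by build_coordinate_table.
    """
    out_dir = Path(out_dir)
    coords_dir = out_dir / "coords"
    coords_dir.mkdir(parents=True, exist_ok=True)
    aln_path = out_dir / "alignment.fasta"
    with open(aln_path, "w") as fh:
        for e in entries:
            seq = "".join("-" if m else "A" for m in e.missing_mask)
            fh.write(f">{e.id}\n{seq}\n")
    for e in entries:
        with open(coords_dir / f"{e.id}.csv", "w") as fh:
            fh.write("alignment_column,x,y,z\n")
            for col, (miss, xyz) in enumerate(zip(e.missing_mask, e.calpha)):
                if not miss:
                    fh.write(f"{col + 1},{xyz[0]:.6f},{xyz[1]:.6f},{xyz[2]:.6f}\n")
    return aln_path, coords_dir


def write_truth(truth, path: str | Path) -> None:
    """Serialize a truth object as a JSON sidecar."""
    if hasattr(truth, "__dataclass_fields__"):
        payload = asdict(truth)
    else:
        payload = dict(truth)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
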