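"""Ensemble PCA of C-alpha coordinates with missing-residue curation.

Workflow: map each structure of a (class-A GPCR style) ensemble onto the
columns of a multiple sequence alignment, giving one C-alpha coordinate or
a missing flag per column; curate structures and columns so the coordinate
matrix is fully observed; superpose; and fit a covariance PCA whose leading
components capture the dominant collective motions (for GPCRs, intracellular
TM6 spreading and TM7 inward motion).  Simulation conformers sharing the
retained column set can then be projected onto the experimental modes.

Curation follows two rules, applied in a single pass over the initial set:
a structure is discarded if it is the only one missing a residue at some
alignment column; a column is discarded if it is missing in at least two
structures.  Columns with exactly one missing entry therefore survive via
the deletion of their sole offender.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .trajectory import kabsch

__all__ = [
    "StructureEntry",
    "CuratedEnsemble",
    "Projection",
    "EnsemblePCA",
    "build_coordinate_table",
    "curate_ensemble",
    "superpose_ensemble",
    "fit_pca",
    "project_conformers",
    "expand_interval_list",
    "count_retained",
    "GHSR_CONSERVED_POSITIONS",
    "REFERENCE_SET_INITIAL_COUNT",
    "REFERENCE_SET_DELETED_IDS",
]

#: Conserved transmembrane positions (GHSR residue numbering) shared by the
#: curated class-A GPCR reference ensemble.
GHSR_CONSERVED_POSITIONS = (
    "45, 46, 48-68, 76-102, 120-148, 162-179, 181, 212, 213, 215-219, "
    "221-239, 261, 263-286, 310-324"
)

#: Size of the initial class-A GPCR reference set and the entries removed
#: from it by the curation rules.
REFERENCE_SET_INITIAL_COUNT = 268
REFERENCE_SET_DELETED_IDS = ("5WB2", "4PY0", "5ZKP", "3RZE", "4RWA", "4DAJ")


@dataclass(frozen=True)
class StructureEntry:
    """Per-alignment-column C-alpha coordinates for one structure.

    ``calpha`` has shape (n_columns, 3); rows of NaN mark missing columns.
    """

    id: str
    calpha: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.calpha, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("calpha must have shape (n_columns, 3)")
        missing = np.isnan(coords).any(axis=1)
        # A partially-NaN row is ill-formed; force all-or-nothing.
        if np.any(np.isnan(coords).any(axis=1) != np.isnan(coords).all(axis=1)):
            raise ValueError(f"{self.id}: rows must be fully observed or fully NaN")
        if missing.all():
            raise ValueError(f"{self.id}: needs at least one observed column")
        if not np.all(np.isfinite(coords[~missing])):
            raise ValueError(f"{self.id}: observed coordinates must be finite")
        object.__setattr__(self, "calpha", coords)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calpha).any(axis=1)


@dataclass(frozen=True)
class CuratedEnsemble:
    """Fully observed coordinate matrix plus the curation report."""

    structure_ids: tuple[str, ...]
    column_indices: tuple[int, ...]  # retained alignment columns (0-based)
    matrix: np.ndarray  # (n_structures, 3 * n_columns)
    deleted_structure_ids: tuple[str, ...] = ()
    deleted_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.structure_ids), 3 * len(self.column_indices)):
            raise ValueError("matrix shape inconsistent with ids/columns")
        if not np.all(np.isfinite(m)):
            raise ValueError("curated matrix must be fully observed")
        object.__setattr__(self, "matrix", m)

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_indices)


@dataclass(frozen=True)
class Projection:
    conformer_id: str
    scores: np.ndarray


# ---------------------------------------------------------------------------
# Alignment → coordinate table
# ---------------------------------------------------------------------------

GAP_CHARS = set("-.")


def _read_alignment(alignment) -> dict[str, str]:
    if isinstance(alignment, dict):
        return {str(k): str(v) for k, v in alignment.items()}
    from Bio import SeqIO

    records = list(SeqIO.parse(str(alignment), "fasta"))
    if not records:
        raise ValueError(f"no sequences in alignment {alignment}")
    return {rec.id: str(rec.seq) for rec in records}


def _read_coord_table(source) -> dict[int, np.ndarray]:
    """Coordinate table: alignment_column (1-based), x, y, z."""
    if isinstance(source, dict):
        return {int(k): np.asarray(v, dtype=float) for k, v in source.items()}
    df = pd.read_csv(source, sep=None, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    required = {"alignment_column", "x", "y", "z"}
    if not required.issubset(cols):
        raise ValueError(f"coordinate table needs columns {sorted(required)}")
    return {
        int(row.alignment_column): np.array([row.x, row.y, row.z], dtype=float)
        for row in df.itertuples()
    }


def build_coordinate_table(alignment, structures) -> list[StructureEntry]:
    """Map per-structure C-alpha tables onto alignment columns.

    ``alignment``: aligned FASTA path or {id: aligned sequence}.
    ``structures``: {id: coordinate table} where a table is a delimited file
    path (columns alignment_column, x, y, z; 1-based columns) or an
    equivalent {column: (x, y, z)} dict; or a directory containing
    ``<id>.csv`` files.  Gap characters and absent table rows map to
    missing flags.
    """
    seqs = _read_alignment(alignment)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    n_columns = lengths.pop()

    if isinstance(structures, (str, Path)):
        root = Path(structures)
        structures = {sid: root / f"{sid}.csv" for sid in seqs}

    entries = []
    for sid, seq in seqs.items():
        if sid not in structures:
            raise ValueError(f"no coordinate table for alignment id {sid!r}")
        table = _read_coord_table(structures[sid])
        coords = np.full((n_columns, 3), np.nan)
        for col, char in enumerate(seq):
            if char in GAP_CHARS:
                continue
            xyz = table.get(col + 1)
            if xyz is not None:
                coords[col] = xyz
        entries.append(StructureEntry(id=sid, calpha=coords))
    return entries


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def curate_ensemble(entries: list[StructureEntry], iterate: bool = False) -> CuratedEnsemble:
    """Apply the sole-offender-structure and >=2-missing-column discard rules.

    Default is a single pass with both rules assessed on the initial set:
    structures that are the only one missing some column are deleted (those
    columns are kept), and columns missing in two or more structures are
    deleted.  ``iterate=True`` repeats the pass on the surviving set until
    stable.
    """
    if len(entries) < 2:
        raise ValueError("curation needs at least 2 structures")
    ids = [e.id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids")
    n_columns = {e.calpha.shape[0] for e in entries}
    if len(n_columns) != 1:
        raise ValueError("entries disagree on alignment length")

    current = list(entries)
    all_deleted_ids: list[str] = []
    all_deleted_cols: set[int] = set()
    active_cols = np.arange(n_columns.pop())

    while True:
        missing = np.stack([e.missing_mask[active_cols] for e in current])
        col_counts = missing.sum(axis=0)
        sole_mask = col_counts == 1
        drop_structs = [
            i for i in range(len(current)) if np.any(missing[i] & sole_mask)
        ]
        drop_cols = np.where(col_counts >= 2)[0]
        all_deleted_ids.extend(current[i].id for i in drop_structs)
        all_deleted_cols.update(int(active_cols[c]) for c in drop_cols)
        current = [e for i, e in enumerate(current) if i not in set(drop_structs)]
        active_cols = np.delete(active_cols, drop_cols)
        if not iterate or (not drop_structs and drop_cols.size == 0):
            break

    if active_cols.size == 0:
        raise ValueError("curation removed every alignment column")
    if len(current) < 2:
        raise ValueError("curation left fewer than 2 structures")

    matrix = np.stack([e.calpha[active_cols].reshape(-1) for e in current])
    if np.isnan(matrix).any():
        # Cannot occur under the single-pass rules; guards the iterate path.
        raise ValueError("curated matrix is not fully observed")
    return CuratedEnsemble(
        structure_ids=tuple(e.id for e in current),
        column_indices=tuple(int(c) for c in active_cols),
        matrix=matrix,
        deleted_structure_ids=tuple(all_deleted_ids),
        deleted_columns=tuple(sorted(all_deleted_cols)),
    )


def count_retained(initial_count: int, deleted_ids) -> int:
    """Structures surviving curation: initial count minus unique deleted ids."""
    deleted = set(deleted_ids)
    if len(deleted) > initial_count:
        raise ValueError("more deleted ids than structures")
    return initial_count - len(deleted)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose_ensemble(
    c: CuratedEnsemble, mode: str = "iterative-mean", tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Least-squares superpose all structures; returns the aligned matrix.

    ``mode="reference"`` superposes every structure onto the first;
    ``mode="iterative-mean"`` additionally re-superposes onto the running
    mean until the mean shifts by less than ``tol`` Angstrom.
    """
    if mode not in ("reference", "iterative-mean"):
        raise ValueError(f"unknown superposition mode {mode!r}")
    if c.n_columns < 3:
        raise ValueError("superposition needs >= 3 columns")
    coords = c.matrix.reshape(c.n_structures, c.n_columns, 3).copy()
    ref = coords[0]
    for i in range(c.n_structures):
        R, t = kabsch(coords[i], ref)
        coords[i] = coords[i] @ R.T + t
    if mode == "iterative-mean":
        mean = coords.mean(axis=0)
        for _ in range(max_iter):
            for i in range(c.n_structures):
                R, t = kabsch(coords[i], mean)
                coords[i] = coords[i] @ R.T + t
            new_mean = coords.mean(axis=0)
            shift = float(np.abs(new_mean - mean).max())
            mean = new_mean
            if shift < tol:
                break
    return coords.reshape(c.n_structures, 3 * c.n_columns)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class EnsemblePCA(TransformerMixin, BaseEstimator):
    """Covariance PCA of superposed flattened C-alpha coordinates.

    Eigendecomposition of the sample covariance (ddof = 1) of the row
    vectors about their mean; eigenvalues descending, eigenvectors
    orthonormal with a deterministic sign convention (the largest-magnitude
    loading of each component is positive) so projections are reproducible.

    Attributes
    ----------
    mean_ : (d,) ensemble mean configuration
    components_ : (r, d) orthonormal modes, rows sorted by eigenvalue
    explained_variance_ : (r,) eigenvalues, descending
    explained_variance_ratio_ : eigenvalues over the total variance
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 rows")
        n, d = X.shape
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = s**2 / (n - 1)
        total = float(eigvals.sum())
        if total <= 1e-30:
            raise ValueError("rank-0 input: all rows identical")
        # Deterministic sign: largest-magnitude loading positive.
        for i in range(Vt.shape[0]):
            j = int(np.argmax(np.abs(Vt[i])))
            if Vt[i, j] < 0:
                Vt[i] = -Vt[i]
        r = min(n - 1, d) if n > 1 else 1
        eigvals = eigvals[:r]
        Vt = Vt[:r]
        if self.n_components is not None:
            k = int(self.n_components)
            if not 1 <= k <= r:
                raise ValueError(f"n_components must be in [1, {r}]")
            eigvals, Vt = eigvals[:k], Vt[:k]
        self.components_ = Vt
        self.explained_variance_ = eigvals
        self.explained_variance_ratio_ = eigvals / total
        self.total_variance_ = total
        self.n_features_in_ = d
        return self

    def transform(self, X):
        """Scores of conformers in the eigenvector basis."""
        if not hasattr(self, "components_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError("column-count mismatch with the fitted model")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        scores = np.asarray(scores, dtype=float)
        return scores @ self.components_ + self.mean_


def fit_pca(matrix: np.ndarray, n_components: int | None = None) -> EnsemblePCA:
    """Fit :class:`EnsemblePCA` on a superposed coordinate matrix."""
    return EnsemblePCA(n_components=n_components).fit(matrix)


def project_conformers(
    m: EnsemblePCA,
    conformers: np.ndarray,
    conformer_ids=None,
    superpose: bool = True,
) -> list[Projection]:
    """Project external conformers (same retained column set) onto the modes.

    With ``superpose=True`` each conformer is first rigid-body superposed
    onto the model mean before scoring.
    """
    X = np.asarray(conformers, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != m.n_features_in_:
        raise ValueError("column-count mismatch with the fitted model")
    if conformer_ids is None:
        conformer_ids = [f"conformer_{i}" for i in range(X.shape[0])]
    if superpose:
        mean3 = m.mean_.reshape(-1, 3)
        aligned = np.empty_like(X)
        for i in range(X.shape[0]):
            c3 = X[i].reshape(-1, 3)
            R, t = kabsch(c3, mean3)
            aligned[i] = (c3 @ R.T + t).reshape(-1)
        X = aligned
    scores = m.transform(X)
    return [
        Projection(conformer_id=str(cid), scores=scores[i])
        for i, cid in enumerate(conformer_ids)
    ]


# ---------------------------------------------------------------------------
# Interval lists
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


def expand_interval_list(text: str) -> list[int]:
    """Expand "45, 46, 48-68, ..." (hyphen or en-dash, inclusive) to sorted indices."""
    result: set[int] = set()
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _RANGE_RE.match(token)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise ValueError(f"reversed range {token!r}")
            result.update(range(lo, hi + 1))
        elif token.isdigit():
            result.add(int(token))
        else:
            raise ValueError(f"non-numeric token {token!r}")
    return sorted(result)
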