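"""Emission-spectrum deconvolution and the hydration parameter H.

A 7-hydroxycoumarin probe excited at 320 nm emits from up to three species
whose relative weights report on the water content of the probe's
microenvironment: the neutral form, the anionic form, and the excited-state
tautomer.  The emission spectrum is modelled as a sum of peak functions (one
band per species, Gaussian in wavelength by default) plus an optional
baseline.  The hydration parameter H is the summed fractional band area of
the anionic and tautomer species; higher H means more local water.

The fit is exposed as the sklearn-style estimator :class:`SpectralDeconvolver`
(``fit`` on wavelength/intensity data, ``predict`` evaluates the fitted
model); :func:`fit_band_model` is a thin functional wrapper around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SPECIES",
    "Spectrum",
    "BandComponent",
    "DeconvolutionResult",
    "ConditionComparison",
    "read_spectrum",
    "normalize_spectrum",
    "evaluate_band_model",
    "SpectralDeconvolver",
    "fit_band_model",
    "hydration_parameter",
    "compare_hydration_groups",
]

#: Emitting species, in order of increasing emission wavelength.
SPECIES = ("neutral", "anionic", "tautomer")

DEFAULT_WINDOW = (340.0, 600.0)
DEFAULT_EXCITATION_NM = 320.0


class SpectrumValidationError(ValueError):
    """Raised when spectral data violate a structural invariant."""


@dataclass(frozen=True)
class Spectrum:
    """An emission spectrum on a strictly ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_nm: float = DEFAULT_EXCITATION_NM
    condition_label: str = ""
    probe_position: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.shape != it.shape:
            raise SpectrumValidationError(
                "wavelengths and intensities must be 1-D arrays of equal length"
            )
        if wl.size < 10:
            raise SpectrumValidationError(
                f"spectrum needs >= 10 points, got {wl.size}"
            )
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(it))):
            raise SpectrumValidationError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumValidationError(
                "wavelengths must be strictly increasing (duplicates rejected)"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def n_points(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class BandComponent:
    """One emission band with peak-height amplitude parameterization.

    ``amplitude`` is the intensity of the band at its ``center``; ``width``
    is the Gaussian sigma in nm (for the lognormal shape it is the
    equivalent nm-scale width at the peak, sigma_log = width / center).
    """

    species: str
    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.shape not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        if not self.center > 0:
            raise ValueError("band center must be positive")
        if not self.width > 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * ((wl - self.center) / self.width) ** 2)
        sigma = self.width / self.center
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.log(np.where(wl > 0, wl / self.center, np.nan))
        out = self.amplitude * np.exp(-0.5 * (u / sigma) ** 2)
        return np.where(np.isfinite(out), out, 0.0)

    @property
    def area(self) -> float:
        """Analytic integral of the band over wavelength."""
        if self.shape == "gaussian":
            return float(self.amplitude * self.width * np.sqrt(2.0 * np.pi))
        sigma = self.width / self.center
        return float(
            self.amplitude * self.center * sigma * np.sqrt(2.0 * np.pi) * np.exp(sigma**2 / 2.0)
        )


@dataclass(frozen=True)
class DeconvolutionResult:
    """Fitted band model: components, fit quality, and H."""

    components: tuple[BandComponent, ...]
    baseline: float
    r_squared: float
    fractional_areas: dict[str, float]
    H: float
    residuals: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        total = sum(self.fractional_areas.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractional areas must sum to 1, got {total}")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def component(self, species: str) -> BandComponent:
        for c in self.components:
            if c.species == species:
                return c
        raise KeyError(species)


@dataclass(frozen=True)
class ConditionComparison:
    """One-way ANOVA plus Dunnett-vs-reference comparison of H across conditions."""

    group_labels: tuple[str, ...]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_per_group: dict[str, int]
    anova_p: float
    dunnett_adjusted_p: dict[str, float]
    reference_label: str


# ---------------------------------------------------------------------------
# Spectrum I/O and normalization
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path, **metadata) -> Spectrum:
    """Read a two-column (wavelength, intensity) delimited text table.

    Comma, tab or whitespace separated; one optional header line.  Rows are
    sorted by wavelength; duplicated wavelengths are rejected.  Keyword
    arguments (``condition_label``, ``probe_position``, ``replicate_id``,
    ``excitation_nm``) are attached as metadata.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectrumValidationError(f"cannot parse {path}: {exc}") from exc
    # Drop a single header line if the first row is non-numeric.
    first = pd.to_numeric(table.iloc[0], errors="coerce")
    if first.isna().any():
        table = table.iloc[1:]
    if table.shape[1] != 2:
        raise SpectrumValidationError(
            f"{path}: expected 2 columns, got {table.shape[1]}"
        )
    numeric = table.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = int(numeric.isna().any(axis=1).idxmax())
        raise SpectrumValidationError(f"{path}: non-numeric data near row {bad}")
    wl = numeric.iloc[:, 0].to_numpy(dtype=float)
    it = numeric.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wl, kind="stable")
    wl, it = wl[order], it[order]
    if np.any(np.diff(wl) == 0):
        raise SpectrumValidationError(f"{path}: duplicated wavelengths")
    return Spectrum(wavelengths=wl, intensities=it, **metadata)


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Scale intensities so the maximum equals 1 (wavelengths unchanged)."""
    peak = float(np.max(s.intensities))
    if peak <= 0:
        raise SpectrumValidationError("cannot normalize: maximum intensity is not > 0")
    return replace(s, intensities=s.intensities / peak)


def evaluate_band_model(
    components: list[BandComponent] | tuple[BandComponent, ...],
    baseline: float,
    wavelengths: np.ndarray,
) -> np.ndarray:
    """Sum of peak functions plus a constant baseline on a wavelength grid."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    out = np.full(wl.shape, float(baseline))
    for comp in components:
        out = out + comp.evaluate(wl)
    return out


# ---------------------------------------------------------------------------
# Deconvolution estimator
# ---------------------------------------------------------------------------

class SpectralDeconvolver(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares deconvolution into three species bands.

    Fits intensity(wavelength) as the sum of three peak functions — neutral,
    anionic and tautomer bands with ordered centers — plus an optional
    constant baseline, then computes per-species fractional band areas and
    the hydration parameter ``h_`` = fraction(anionic) + fraction(tautomer).

    Parameters
    ----------
    shape : {"gaussian", "lognormal"}
        Peak-function family for all three bands.
    centers_init, widths_init : sequences of three floats, nm
        Starting values for band centers/widths (neutral, anionic, tautomer).
    center_bounds : sequence of three (lo, hi) pairs, optional
        Box constraints keeping the centers ordered
        neutral < anionic < tautomer; defaults to contiguous bins split at
        420 and 480 nm inside the recorded window.
    fit_baseline : bool
        Fit a constant offset (default: fixed at 0 for normalized spectra).
    normalize : bool
        Normalize the spectrum to unit peak before fitting, which makes the
        result invariant to overall intensity scaling.
    n_restarts : int
        Multi-start count; starts 2.. jitter the initial guess.
    random_state : int
        Seed for the jittered restarts.

    Attributes
    ----------
    components_ : tuple of BandComponent
    baseline_ : float
    r_squared_ : float
    fractional_areas_ : dict mapping species to area fraction (sums to 1)
    h_ : float
        The hydration parameter in [0, 1].
    result_ : DeconvolutionResult
    """

    def __init__(
        self,
        shape: str = "gaussian",
        centers_init=(380.0, 450.0, 510.0),
        widths_init=(30.0, 30.0, 30.0),
        center_bounds=None,
        width_bounds=(5.0, 120.0),
        fit_baseline: bool = False,
        normalize: bool = True,
        n_restarts: int = 10,
        tol: float = 1e-10,
        random_state: int = 0,
    ) -> None:
        self.shape = shape
        self.centers_init = centers_init
        self.widths_init = widths_init
        self.center_bounds = center_bounds
        self.width_bounds = width_bounds
        self.fit_baseline = fit_baseline
        self.normalize = normalize
        self.n_restarts = n_restarts
        self.tol = tol
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _coerce_xy(self, X, y):
        if isinstance(X, Spectrum):
            return X.wavelengths, X.intensities
        wl = np.asarray(X, dtype=float).reshape(-1)
        it = np.asarray(y, dtype=float).reshape(-1)
        # Route through Spectrum for validation (sorting already required).
        s = Spectrum(wavelengths=wl, intensities=it)
        return s.wavelengths, s.intensities

    def _default_center_bounds(self, wl_lo: float, wl_hi: float):
        split_1, split_2 = 420.0, 480.0
        return (
            (wl_lo, min(split_1, wl_hi)),
            (max(split_1, wl_lo), min(split_2, wl_hi)),
            (max(split_2, wl_lo), wl_hi),
        )

    def _model(self, params: np.ndarray, wl: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wl)
        for i in range(3):
            c, w, a = params[3 * i : 3 * i + 3]
            if self.shape == "gaussian":
                out = out + a * np.exp(-0.5 * ((wl - c) / w) ** 2)
            else:
                sigma = w / c
                out = out + a * np.exp(-0.5 * (np.log(wl / c) / sigma) ** 2)
        if self.fit_baseline:
            out = out + params[9]
        return out

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the three-band model.

        ``X`` may be a :class:`Spectrum`, or a 1-D wavelength array with the
        intensities in ``y``.
        """
        if self.shape not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        wl, it = self._coerce_xy(X, y)
        peak = float(np.max(it))
        if peak <= 0:
            raise ValueError("degenerate spectrum: maximum intensity is not > 0")
        scale = peak if self.normalize else 1.0
        yv = it / scale

        wl_lo, wl_hi = float(wl[0]), float(wl[-1])
        cbounds = self.center_bounds or self._default_center_bounds(wl_lo, wl_hi)
        if len(cbounds) != 3:
            raise ValueError("center_bounds must give (lo, hi) for each of 3 bands")
        w_lo, w_hi = self.width_bounds
        ymax = float(np.max(yv))

        lower, upper, x0 = [], [], []
        for i in range(3):
            lo, hi = cbounds[i]
            c0 = float(np.clip(self.centers_init[i], lo, hi))
            w0 = float(np.clip(self.widths_init[i], w_lo, w_hi))
            a0 = max(float(np.interp(c0, wl, yv)), 1e-3 * ymax)
            lower += [lo, w_lo, 0.0]
            upper += [hi, w_hi, 2.0 * ymax]
            x0 += [c0, w0, a0]
        if self.fit_baseline:
            lower.append(-0.5 * ymax)
            upper.append(0.5 * ymax)
            x0.append(0.0)
        lower, upper, x0 = map(np.asarray, (lower, upper, x0))

        def residual(p):
            return self._model(p, wl) - yv

        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(max(1, self.n_restarts)):
            xs = x0.copy()
            if start > 0:
                span = upper - lower
                xs = np.clip(x0 + rng.normal(scale=0.1 * span), lower, upper)
            try:
                sol = optimize.least_squares(
                    residual, xs, bounds=(lower, upper),
                    xtol=self.tol, ftol=self.tol, gtol=self.tol,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
            # Noiseless spectra hit machine-precision cost quickly.
            if best is not None and best.cost < 1e-22:
                break
        if best is None:
            raise RuntimeError("band-model fit failed to converge in all restarts")

        p = best.x
        comps = tuple(
            BandComponent(
                species=SPECIES[i],
                center=float(p[3 * i]),
                width=float(p[3 * i + 1]),
                amplitude=float(p[3 * i + 2]) * scale,
                shape=self.shape,
            )
            for i in range(3)
        )
        baseline = float(p[9]) * scale if self.fit_baseline else 0.0

        fitted = evaluate_band_model(comps, baseline, wl)
        res = it - fitted
        ss_res = float(np.sum(res**2))
        ss_tot = float(np.sum((it - np.mean(it)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        areas = np.array([c.area for c in comps])
        total = float(areas.sum())
        if total <= 0:
            raise RuntimeError("all fitted band areas are zero; cannot form H")
        fracs = {c.species: float(a / total) for c, a in zip(comps, areas)}
        # Renormalize away the last-bit rounding so the invariant is exact.
        correction = sum(fracs.values())
        fracs = {k: v / correction for k, v in fracs.items()}

        self.components_ = comps
        self.baseline_ = baseline
        self.r_squared_ = min(r2, 1.0)
        self.fractional_areas_ = fracs
        self.h_ = fracs["anionic"] + fracs["tautomer"]
        self.residuals_ = res
        self.n_features_in_ = 1
        self.result_ = DeconvolutionResult(
            components=comps,
            baseline=baseline,
            r_squared=self.r_squared_,
            fractional_areas=fracs,
            H=self.h_,
            residuals=res,
        )
        return self

    def predict(self, X):
        """Evaluate the fitted band model on a wavelength grid."""
        if not hasattr(self, "components_"):
            raise RuntimeError("estimator is not fitted")
        wl = X.wavelengths if isinstance(X, Spectrum) else np.asarray(X, float).reshape(-1)
        return evaluate_band_model(self.components_, self.baseline_, wl)


def fit_band_model(
    s: Spectrum,
    init: list[BandComponent] | None = None,
    bounds=None,
    shape: str | None = None,
    **kwargs,
) -> DeconvolutionResult:
    """Functional wrapper over :class:`SpectralDeconvolver`.

    ``init`` may carry three BandComponents (one per species, any order)
    whose centers/widths/shape seed the optimizer; ``bounds`` is passed as
    per-band center bounds.
    """
    if init is not None:
        by_species = {c.species: c for c in init}
        if set(by_species) != set(SPECIES):
            raise ValueError(f"init must contain exactly the species {SPECIES}")
        ordered = [by_species[sp] for sp in SPECIES]
        kwargs.setdefault("centers_init", tuple(c.center for c in ordered))
        kwargs.setdefault("widths_init", tuple(c.width for c in ordered))
        if shape is None:
            shape = ordered[0].shape
    dec = SpectralDeconvolver(
        shape=shape or "gaussian", center_bounds=bounds, **kwargs
    )
    dec.fit(s)
    return dec.result_


def hydration_parameter(d: DeconvolutionResult) -> float:
    """H = fractional area of the anionic plus the tautomer band."""
    try:
        h = d.fractional_areas["anionic"] + d.fractional_areas["tautomer"]
    except KeyError as exc:
        raise ValueError(f"missing species in result: {exc}") from exc
    return float(h)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_hydration_groups(
    h_values: dict[str, "list[float] | np.ndarray"],
    reference: str,
    rng: int | np.random.Generator | None = 0,
) -> ConditionComparison:
    """One-way ANOVA plus Dunnett's many-to-one test on per-condition H.

    ``h_values`` maps condition labels to replicate H lists; ``reference``
    names the control condition (e.g. the apo receptor).  Dunnett adjusted
    p-values are multiplicity-corrected within the family of
    non-reference-vs-reference comparisons.
    """
    if reference not in h_values:
        raise ValueError(f"reference group {reference!r} not present")
    if len(h_values) < 2:
        raise ValueError("need at least 2 groups to compare")
    groups = {k: np.asarray(v, dtype=float) for k, v in h_values.items()}
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} needs n >= 2 replicates")
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError("zero within-group variance in all groups: test undefined")

    labels = tuple(groups)
    others = [lab for lab in labels if lab != reference]
    anova = stats.f_oneway(*groups.values())
    dres = stats.dunnett(
        *(groups[lab] for lab in others), control=groups[reference], rng=rng
    )
    return ConditionComparison(
        group_labels=labels,
        group_means={lab: float(np.mean(v)) for lab, v in groups.items()},
        group_sds={lab: float(np.std(v, ddof=1)) for lab, v in groups.items()},
        n_per_group={lab: int(v.size) for lab, v in groups.items()},
        anova_p=float(anova.pvalue),
        dunnett_adjusted_p={lab: float(p) for lab, p in zip(others, dres.pvalue)},
        reference_label=reference,
    )
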