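"""Per-pixel XRF spectrum fitting and standard-based quantification.

The quantification chain is:

1. fit the specimen-summed spectrum with the full candidate element set
   (nonnegative Gaussian line templates + free polynomial continuum);
2. keep only elements with amplitude > z * sigma evidence in that summed
   fit (the inclusion rule), then re-fit every pixel with the kept set;
3. calibrate a single flux-area scale k against a certified standard
   measured under the same instrument settings (log-space least squares);
4. convert amplitude maps to ppm:  ppm = amplitude / (k * sensitivity * dwell).

Amplitudes are total counts in all lines of an element (templates are
normalised to unit integral with fixed within-element branching ratios).
Hutch/detector/grid channels (Ar, Kr, Si, Cu) are fitted but never
quantified, and the As channel is reported as ``As*`` because Pb L-lines
overlap the As K-alpha line and the two cannot be separated at 17.1 keV.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from scipy.special import ndtr

from .maps import SpecimenMap

#: Channels that belong to the hutch, detector or TEM support grid.
INSTRUMENT_ELEMENTS = frozenset({"Ar", "Kr", "Si", "Cu"})
#: Fit label for the merged As-K / Pb-L channel.
MERGED_AS_LABEL = "As*"

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class ConfigurationError(ValueError):
    """An element/line/sensitivity lookup failed."""


class CollinearityError(ValueError):
    """Two candidate element templates are indistinguishable."""


class CalibrationError(ValueError):
    """The standard measurement cannot constrain the flux-area scale."""


@dataclass(frozen=True)
class ElementLine:
    element: str
    line: str
    energy_keV: float
    relative_intensity: float

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ValueError("line energy must be positive")


def load_line_library(path: str | Path | None = None) -> pd.DataFrame:
    """Load a line library CSV (element, line, energy_keV, rel_intensity, sensitivity)."""
    if path is None:
        with resources.as_file(resources.files("coccomap.data") / "line_library.csv") as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    required = {"element", "line", "energy_keV", "rel_intensity", "sensitivity"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"line library missing columns {required - set(df.columns)}")
    for el, grp in df.groupby("element"):
        if grp["rel_intensity"].sum() > 1.0 + 1e-9:
            raise ConfigurationError(f"relative intensities for {el} sum above 1")
    return df


def sensitivities(library: pd.DataFrame) -> dict[str, float]:
    return dict(library.groupby("element")["sensitivity"].first())


def _gaussian_bin_integral(edges: np.ndarray, energy: float, sigma: float) -> np.ndarray:
    z = (edges - energy) / sigma
    cdf = ndtr(z)
    return np.diff(cdf)


def build_templates(candidates: Sequence[str], library: pd.DataFrame,
                    inst) -> tuple[np.ndarray, list[str]]:
    """Unit-integral spectral templates for each candidate element.

    Lines at or above the incident energy are not excitable and are
    dropped (remaining branching ratios renormalised).  An element with no
    excitable line raises :class:`ConfigurationError`.
    """
    edges = np.asarray(inst.bin_edges, dtype=float)
    cols = []
    names = []
    for el in candidates:
        grp = library[library["element"] == el]
        if grp.empty:
            raise ConfigurationError(f"element {el!r} has no line in the library")
        grp = grp[grp["energy_keV"] < inst.incident_energy_keV]
        if grp.empty:
            raise ConfigurationError(
                f"element {el!r} has no excitable line below "
                f"{inst.incident_energy_keV} keV")
        w = grp["rel_intensity"].to_numpy(dtype=float)
        w = w / w.sum()
        col = np.zeros(edges.size - 1)
        for weight, energy in zip(w, grp["energy_keV"].to_numpy(dtype=float)):
            sigma = inst.fwhm_keV(energy) / FWHM_TO_SIGMA
            col += weight * _gaussian_bin_integral(edges, energy, sigma)
        cols.append(col)
        names.append(el)
    return np.column_stack(cols), names


def _check_collinearity(templates: np.ndarray, names: list[str],
                        threshold: float = 0.9995) -> None:
    norms = np.linalg.norm(templates, axis=0)
    if np.any(norms == 0):
        idx = int(np.argmin(norms))
        raise ConfigurationError(f"template for {names[idx]!r} is empty on the energy axis")
    unit = templates / norms
    gram = unit.T @ unit
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if gram[i, j] > threshold:
                raise CollinearityError(
                    f"candidate templates for {names[i]!r} and {names[j]!r} "
                    f"are collinear (cosine {gram[i, j]:.5f})")


def _background_columns(inst, degree: int) -> np.ndarray:
    edges = np.asarray(inst.bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    x = 2.0 * (centers - centers.min()) / (centers.max() - centers.min()) - 1.0
    return np.polynomial.legendre.legvander(x, degree)


@dataclass
class FitResult:
    """One spectrum fit: per-element amplitudes, evidence and residual."""

    elements: pd.DataFrame          # index element; amplitude, amplitude_sigma, included
    background_coef: np.ndarray
    residual_norm: float

    def amplitude(self, element: str) -> float:
        return float(self.elements.loc[element, "amplitude"])

    def sigma(self, element: str) -> float:
        return float(self.elements.loc[element, "amplitude_sigma"])


def fit_spectrum(counts: np.ndarray, candidates: Sequence[str],
                 library: pd.DataFrame, inst,
                 weights: str = "poisson", bg_degree: int = 2) -> FitResult:
    """Fit one spectrum with nonnegative element amplitudes.

    ``weights='poisson'`` scales each bin by 1/sqrt(max(counts, 1)) (the
    amplitude covariance then assumes unit weighted variance);
    ``weights='none'`` is an ordinary fit with the residual variance
    estimated from the fit itself.
    """
    y = np.asarray(counts, dtype=float)
    T, names = build_templates(candidates, library, inst)
    if y.shape[0] != T.shape[0]:
        raise ValueError("spectrum length does not match instrument bins")
    _check_collinearity(T, names)
    B = _background_columns(inst, bg_degree)
    A = np.hstack([T, B])
    nel = len(names)
    if weights == "poisson":
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))
    elif weights == "none":
        w = np.ones_like(y)
    else:
        raise ValueError("weights must be 'poisson' or 'none'")
    Aw = A * w[:, None]
    yw = y * w
    lb = np.r_[np.zeros(nel), -np.inf * np.ones(B.shape[1])]
    ub = np.full(A.shape[1], np.inf)
    sol = lsq_linear(Aw, yw, bounds=(lb, ub), method="bvls")
    x = sol.x
    resid = yw - Aw @ x
    gram_inv = np.linalg.pinv(Aw.T @ Aw)
    if weights == "poisson":
        scale = 1.0
    else:
        dof = max(y.size - A.shape[1], 1)
        scale = float(resid @ resid) / dof
    sig = np.sqrt(np.maximum(np.diag(gram_inv) * scale, 0.0))
    df = pd.DataFrame({
        "amplitude": np.maximum(x[:nel], 0.0),
        "amplitude_sigma": sig[:nel],
        "included": True,
    }, index=pd.Index(names, name="element"))
    return FitResult(elements=df, background_coef=x[nel:],
                     residual_norm=float(np.linalg.norm(resid)))


def element_inclusion(fit: FitResult, z_threshold: float = 3.0) -> list[str]:
    """Elements with amplitude > z * sigma evidence in a (summed) fit."""
    df = fit.elements
    keep = df["amplitude"] > z_threshold * df["amplitude_sigma"]
    return list(df.index[keep])


def fit_pixels(cube, candidates: Sequence[str], library: pd.DataFrame,
               inst, bg_degree: int = 2) -> dict[str, np.ndarray]:
    """Per-pixel amplitude maps for a spectrum cube.

    The design matrix is shared by all pixels, so the unconstrained
    least-squares solution is computed for the whole cube at once; only
    pixels where an element amplitude comes out negative are re-solved
    with the nonnegativity bound.
    """
    T, names = build_templates(candidates, library, inst)
    _check_collinearity(T, names)
    B = _background_columns(inst, bg_degree)
    A = np.hstack([T, B])
    nel = len(names)
    h, w_, nb = cube.counts.shape
    Y = cube.counts.reshape(h * w_, nb).T.astype(float)
    X = np.linalg.pinv(A) @ Y                       # (p, npx)
    bad = np.any(X[:nel] < -1e-9, axis=0)
    if bad.any():
        lb = np.r_[np.zeros(nel), -np.inf * np.ones(B.shape[1])]
        ub = np.full(A.shape[1], np.inf)
        for j in np.flatnonzero(bad):
            sol = lsq_linear(A, Y[:, j], bounds=(lb, ub), method="bvls")
            X[:, j] = sol.x
    amps = np.maximum(X[:nel], 0.0)
    return {el: amps[i].reshape(h, w_) for i, el in enumerate(names)}


@dataclass
class SpecimenFit:
    """Summed-spectrum fit, inclusion decisions and per-pixel amplitude maps."""

    summed: FitResult
    included: list[str]
    amplitude_maps: dict[str, np.ndarray]


def fit_specimen(cube, candidates: Sequence[str], library: pd.DataFrame,
                 inst, z_threshold: float = 3.0) -> SpecimenFit:
    """Inclusion on the specimen-summed spectrum, then per-pixel re-fit.

    Deciding inclusion once per specimen (rather than per pixel) keeps the
    pixel maps mutually comparable; the summed spectrum also carries the
    evidence a single 200 ms pixel cannot.
    """
    ysum = cube.counts.sum(axis=(0, 1))
    summed = fit_spectrum(ysum, candidates, library, inst, weights="poisson")
    included = element_inclusion(summed, z_threshold)
    summed.elements["included"] = summed.elements.index.isin(included)
    if not included:
        raise ConfigurationError("no element passed the inclusion rule")
    maps = fit_pixels(cube, included, library, inst)
    return SpecimenFit(summed=summed, included=included, amplitude_maps=maps)


# ---------------------------------------------------------------------------
# calibration and quantification
# ---------------------------------------------------------------------------

@dataclass
class CalibrationStandard:
    """Certified mass fractions plus measured per-pixel line amplitudes."""

    certified_ppm: dict[str, float]
    amplitudes: dict[str, float]

    def __post_init__(self) -> None:
        for el, v in self.certified_ppm.items():
            if v <= 0:
                raise ValueError(f"certified value for {el!r} must be > 0")


@dataclass
class CalibrationResult:
    """Refined flux-area scale and per-element relative calibration error."""

    flux_area_scale: float
    residuals: pd.Series            # relative error, exp(log-residual) - 1

    def __post_init__(self) -> None:
        if self.flux_area_scale <= 0:
            raise ValueError("flux-area scale must be positive")


def calibrate(standard: CalibrationStandard, library: pd.DataFrame,
              dwell_s: float) -> CalibrationResult:
    """Refine the global flux-area scale k against a certified standard.

    k minimises sum_i (log predicted_ppm_i - log certified_ppm_i)^2 with
    predicted_ppm_i = amplitude_i / (k * sensitivity_i * dwell); the log
    metric weights elements spanning orders of magnitude evenly.
    """
    sens = sensitivities(library)
    els = [el for el in standard.certified_ppm if el in standard.amplitudes]
    if not els:
        raise CalibrationError("standard has no element with a measured amplitude")
    for el in els:
        if el not in sens:
            raise ConfigurationError(f"element {el!r} missing from the sensitivity table")
        if standard.amplitudes[el] <= 0:
            raise CalibrationError(f"measured amplitude for {el!r} is not positive")
    if len(els) < 2:
        warnings.warn("single-element standard: flux-area scale solved exactly",
                      stacklevel=2)
    logk = np.array([
        np.log(standard.amplitudes[el] /
               (sens[el] * dwell_s * standard.certified_ppm[el]))
        for el in els])
    k = float(np.exp(logk.mean()))
    resid = pd.Series(np.exp(logk - logk.mean()) - 1.0, index=els,
                      name="relative_error")
    return CalibrationResult(flux_area_scale=k, residuals=resid)


def quantify(amplitude_maps: Mapping[str, np.ndarray], cal: CalibrationResult,
             library: pd.DataFrame, dwell_s: float, pixel_size_nm: float,
             species: str = "", experiment: str = "") -> SpecimenMap:
    """Convert amplitude maps to a ppm SpecimenMap.

    ppm_i(x, y) = amplitude_i(x, y) / (k * sensitivity_i * dwell); hutch /
    detector / grid channels are dropped, and the As channel is relabelled
    ``As*`` (possible Pb L-line contribution).
    """
    sens = sensitivities(library)
    elements: dict[str, np.ndarray] = {}
    for el, amp in amplitude_maps.items():
        if el in INSTRUMENT_ELEMENTS:
            continue
        if el not in sens:
            raise ConfigurationError(f"element {el!r} missing from the sensitivity table")
        out = "As*" if el == "As" else el
        elements[out] = np.maximum(np.asarray(amp, dtype=float), 0.0) / (
            cal.flux_area_scale * sens[el] * dwell_s)
    return SpecimenMap(elements=elements, pixel_size_nm=pixel_size_nm,
                       species=species, experiment=experiment)
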