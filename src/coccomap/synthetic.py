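"""Ground-truthed synthetic coccolith specimens: geometry, fields, spectra.

The generator emulates the data the analysis pipeline assumes, at the
study's conditions: placolith geometry (a 9 um *C. pelagicus*-like
template with a central bar, a 5 um *G. oceanica*-like template with a
bridge), 50 x 50 nm pixels, thickness-proportional Ca, lattice elements
with an optional rimward i/Ca gradient, a shared organic surface coat for
surface-deposited elements, point-contaminant hotspots, hutch/detector
lines, and Poisson counting noise at 200 ms dwell under a 17.1 keV beam.

Every stage derives its random stream from one top-level seed via fixed
offsets, so identical config + seed gives bit-identical output at every
stage, and each specimen carries its ground truth (per-element mode,
intended mean molar ratio, partition coefficient) for recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .maps import (ATOMIC_WEIGHTS, CA_MASK_THRESHOLD_PPM, SpecimenMap,
                   mask_calcite, radial_coordinate)
from .partition import SolutionComposition
from .spectrum import (CalibrationStandard, ConfigurationError, build_templates,
                       load_line_library, sensitivities)

# Normalised elliptical radii of the tube ring (fractions of the outline).
R_TUBE_IN = 0.40
R_TUBE_OUT = 0.62

#: Thickness-to-Ca conversion, ppm per thickness unit.  With the default
#: shield/tube thicknesses this puts the control-template mean Ca near
#: 1.4e5 ppm while keeping shields in the 0.2-1e5 ppm "low" Ca band and
#: the tube above 1e5 ppm.
K_CA_DEFAULT = 9.0e4


class GeometrySizeError(ValueError):
    """The pixel grid cannot contain the requested geometry."""


class DegenerateInputError(ValueError):
    """A lattice element was requested on a specimen with no calcite."""


class GeometryConfig(BaseModel):
    """Placolith geometry for the thickness-map generator."""

    species_template: Literal["placolith_bar", "placolith_bridge"] = "placolith_bar"
    length_um: float = 9.0
    width_um: float = 7.0
    tube_thickness: float = 3.0
    shield_thickness: float = 1.0
    central_structure_present: bool = True
    outline_irregularity: float = Field(0.0, ge=0.0, le=1.0)
    pixel_size_nm: float = 50.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("require length_um >= width_um > 0")
        if self.tube_thickness <= self.shield_thickness:
            raise ValueError("tube must be thicker than the shields")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        return self


class IncorporationMode(str, Enum):
    LATTICE = "lattice"
    SURFACE = "surface"
    HOTSPOT = "hotspot"
    ABSENT = "absent"


class IncorporationModel(BaseModel):
    """Generative model for one element's spatial distribution.

    Exactly one mode applies:

    * ``lattice`` — co-located with calcite; per-pixel i/Ca molar ratio
      interpolates linearly from ``base_ratio_mmol_per_mol`` at the
      innermost rim to ``base * radial_gradient`` at the margin;
    * ``surface`` — a smooth positive coat field shared between all
      surface elements of the specimen, independent of thickness and
      nonzero also off the calcite;
    * ``hotspot`` — a faint coat baseline plus a few Gaussian point
      enrichments (needle/handling contaminants);
    * ``absent`` — a flat field everywhere (possibly zero), with no
      on-coccolith enrichment.
    """

    mode: IncorporationMode = IncorporationMode.ABSENT
    base_ratio_mmol_per_mol: float = Field(0.0, ge=0.0)
    radial_gradient: float = Field(1.0, ge=0.0)
    coat_field_scale: float = Field(0.0, ge=0.0)
    coat_correlation_length_px: float = Field(6.0, gt=0.0)
    n_hotspots: int = Field(0, ge=0)
    hotspot_radius_px: float = Field(2.0, gt=0.0)
    hotspot_intensity: float = Field(0.0, ge=0.0)
    noise_cv: float = Field(0.0, ge=0.0)


class InstrumentConfig(BaseModel):
    """Beamline + detector model for spectrum rendering and fitting."""

    incident_energy_keV: float = 17.1
    dwell_s: float = 0.2
    energy_min_keV: float = 1.0
    energy_max_keV: float = 17.0
    energy_step_keV: float = 0.01
    energy_bin_edges: Optional[list[float]] = None
    electronic_noise_eV: float = 60.0
    fano_like_slope_eV: float = 2.47
    background_level: float = 0.01          # counts / bin / pixel
    flux_area_scale_true: float = 7.5       # ground-truth k*
    contaminant_lines: Dict[str, float] = Field(
        default_factory=lambda: {"Ar": 20.0, "Si": 10.0, "Cu": 200.0, "Kr": 5.0})

    @property
    def bin_edges(self) -> np.ndarray:
        if self.energy_bin_edges is not None:
            edges = np.asarray(self.energy_bin_edges, dtype=float)
        else:
            n = int(round((self.energy_max_keV - self.energy_min_keV)
                          / self.energy_step_keV))
            edges = self.energy_min_keV + self.energy_step_keV * np.arange(n + 1)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("energy bin edges must be strictly increasing")
        return edges

    def fwhm_keV(self, energy_keV: float) -> float:
        """Detector line width: FWHM(E) = sqrt(noise^2 + slope * E) in eV."""
        e_eV = energy_keV * 1000.0
        return math.sqrt(self.electronic_noise_eV ** 2
                         + self.fano_like_slope_eV * e_eV) / 1000.0


@dataclass
class ThicknessMap:
    """Per-pixel calcite thickness proxy (arbitrary units, 0 = background)."""

    values: np.ndarray
    pixel_size_nm: float
    config: GeometryConfig


@dataclass
class PixelSpectrumCube:
    """Per-pixel binned photon counts with the noiseless expectation."""

    counts: np.ndarray            # (h, w, nbins)
    expected: np.ndarray          # (h, w, nbins) noiseless expectation
    bin_edges: np.ndarray
    pixel_size_nm: float
    species: str = ""
    experiment: str = ""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_geometry(config: GeometryConfig) -> ThicknessMap:
    """Build an elliptical-annulus placolith thickness map.

    Background 0; shields at ``shield_thickness``; a closed tube ring at
    ``tube_thickness``; central bar (along the major axis) or bridge
    (oblique) when flagged; outline perturbed by a smooth periodic radial
    deformation of amplitude ``outline_irregularity``.  Deterministic for
    a given config and seed.
    """
    pix_um = config.pixel_size_nm / 1000.0
    a_px = (config.length_um / 2.0) / pix_um
    b_px = (config.width_um / 2.0) / pix_um
    if min(a_px, b_px) < 6:
        raise GeometrySizeError(
            f"geometry too small for the grid: semi-axes ({a_px:.1f}, {b_px:.1f}) px")
    pad_frac = 0.12 + 0.5 * config.outline_irregularity
    pad = int(math.ceil(pad_frac * 2.0 * a_px))
    ny = int(math.ceil(2 * b_px)) + 2 * pad
    nx = int(math.ceil(2 * a_px)) + 2 * pad
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y = (np.arange(ny) - cy)[:, None]
    x = (np.arange(nx) - cx)[None, :]
    ex = x / a_px
    ey = y / b_px
    e = np.hypot(ex, ey)
    if config.outline_irregularity > 0:
        rng = np.random.default_rng([1, config.seed])
        theta = np.arctan2(ey, ex)
        pert = np.zeros_like(e)
        coef = rng.standard_normal((2, 4))
        for i, m in enumerate(range(2, 6)):
            pert += coef[0, i] * np.cos(m * theta) + coef[1, i] * np.sin(m * theta)
        pert /= np.abs(pert).max()
        e = e / (1.0 + config.outline_irregularity * pert)
    t = np.zeros((ny, nx), dtype=float)
    t[(e > R_TUBE_OUT) & (e <= 1.0)] = config.shield_thickness
    t[(e >= R_TUBE_IN) & (e <= R_TUBE_OUT)] = config.tube_thickness
    if config.central_structure_present:
        central = e < R_TUBE_IN
        hw = max(2.0, 0.08 * b_px)
        if config.species_template == "placolith_bar":
            strip = np.abs(np.broadcast_to(y, t.shape)) <= hw
        else:                                    # oblique bridge
            phi = math.radians(35.0)
            strip = np.abs(np.broadcast_to(x, t.shape) * math.sin(phi)
                           - np.broadcast_to(y, t.shape) * math.cos(phi)) <= hw
        t[central & strip] = config.shield_thickness
    return ThicknessMap(values=t, pixel_size_nm=config.pixel_size_nm, config=config)


# ---------------------------------------------------------------------------
# element fields
# ---------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _coat_pattern(white: np.ndarray, support: np.ndarray,
                  correlation_length_px: float) -> np.ndarray:
    """Smooth positive relative coat field (unit mean scale) from shared noise."""
    f = ndimage.gaussian_filter(white, correlation_length_px)
    f = (f - f.mean()) / f.std()
    coat = np.clip(1.0 + 0.5 * f, 0.0, None)
    # smooth on-coccolith envelope that saturates to 1 on the specimen
    # interior (a wide roll-off would correlate the coat with thickness)
    env = ndimage.gaussian_filter(support.astype(float), 2.0)
    envelope = 0.3 + 0.7 * np.clip(1.6 * env, 0.0, 1.0)
    return coat * envelope


def make_element_fields(thickness: ThicknessMap,
                        models: Dict[str, IncorporationModel],
                        k_ca: float = K_CA_DEFAULT,
                        seed: int = 0,
                        solution: SolutionComposition | None = None,
                        species: str = "",
                        experiment: str = "") -> SpecimenMap:
    """Generate ground-truth ppm fields for every modelled element.

    Ca is ``k_ca * thickness``.  For a lattice element the per-pixel ppm
    follows ppm_i = Ca_ppm * (A_i / A_Ca) * ratio(rho) / 1000 with
    ratio(rho) the linearly interpolated i/Ca molar ratio (mmol/mol);
    surface and hotspot fields are drawn as documented on
    :class:`IncorporationModel`.  Multiplicative mean-one lognormal noise
    with the stated CV is applied last.  The returned specimen carries a
    ``truth`` dict with each element's mode, intended (noise-free) mean
    molar ratio over the default calcite mask, and — when a solution with
    that element is supplied — the implied partition coefficient.
    """
    t = thickness.values
    support = t > 0
    ca = k_ca * t
    if not np.any(ca > 0):
        raise DegenerateInputError("specimen has zero Ca everywhere")
    mask = ca >= CA_MASK_THRESHOLD_PPM
    rho = radial_coordinate(support)
    white = np.random.default_rng([3, seed]).standard_normal(t.shape)
    elements: Dict[str, np.ndarray] = {"Ca": ca}
    truth: Dict[str, dict] = {"Ca": {"mode": "lattice", "k_ca": k_ca}}
    a_ca = ATOMIC_WEIGHTS["Ca"]
    for idx, el in enumerate(sorted(models)):
        model = models[el]
        rng = np.random.default_rng([2, idx, seed])
        if model.mode is IncorporationMode.LATTICE:
            g = model.radial_gradient
            ratio = model.base_ratio_mmol_per_mol * (g + (1.0 - g) * rho)
            field = ca * (ATOMIC_WEIGHTS[el] / a_ca) * ratio / 1000.0
            clean_mean_ratio = float(ratio[mask].mean()) if mask.any() else np.nan
        elif model.mode is IncorporationMode.SURFACE:
            field = model.coat_field_scale * _coat_pattern(
                white, support, model.coat_correlation_length_px)
            clean_mean_ratio = _mean_ratio(field, ca, el, mask)
        elif model.mode is IncorporationMode.HOTSPOT:
            field = model.coat_field_scale * _coat_pattern(
                white, support, model.coat_correlation_length_px)
            if model.n_hotspots > 0 and support.any():
                idx_pool = np.flatnonzero(support)
                centers = rng.choice(idx_pool, size=model.n_hotspots, replace=False)
                yy, xx = np.indices(t.shape)
                s = model.hotspot_radius_px
                for c in centers:
                    r0, c0 = np.unravel_index(c, t.shape)
                    d2 = (yy - r0) ** 2 + (xx - c0) ** 2
                    field = field + model.hotspot_intensity * np.exp(-d2 / (2 * s * s))
            clean_mean_ratio = _mean_ratio(field, ca, el, mask)
        else:                                    # absent: flat (possibly zero)
            field = np.full(t.shape, model.coat_field_scale, dtype=float)
            clean_mean_ratio = _mean_ratio(field, ca, el, mask)
        field = field * _lognormal_noise(rng, model.noise_cv, t.shape)
        elements[el] = np.clip(field, 0.0, None)
        rec = {"mode": model.mode.value,
               "mean_ratio_mmol_per_mol": clean_mean_ratio}
        if solution is not None and model.mode is IncorporationMode.LATTICE:
            try:
                rec["D"] = clean_mean_ratio / solution.ratio_mmol_per_mol(el)
            except KeyError:
                pass
        truth[el] = rec
    return SpecimenMap(elements=elements, pixel_size_nm=thickness.pixel_size_nm,
                       species=species, experiment=experiment, truth=truth)


def _mean_ratio(field: np.ndarray, ca: np.ndarray, el: str, mask: np.ndarray) -> float:
    if not mask.any():
        return float("nan")
    from .maps import molar_ratio_mmol_per_mol
    return float(np.mean(molar_ratio_mmol_per_mol(field[mask], ca[mask], el)))


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

def render_spectra(truth: SpecimenMap, inst: InstrumentConfig,
                   library=None, seed: int = 0,
                   poisson: bool = True) -> PixelSpectrumCube:
    """Render the per-pixel spectrum cube implied by a ground-truth specimen.

    Expected counts per bin are the flat continuum plus, per element, a
    unit-integral line template scaled by k* x sensitivity x ppm x dwell;
    hutch/detector/grid lines are added uniformly over every pixel
    (background included).  Observed counts are Poisson draws from the
    expectation unless ``poisson=False``; the noiseless expectation is
    stored alongside in either case.
    """
    if library is None:
        library = load_line_library()
    edges = inst.bin_edges
    nb = edges.size - 1
    elements = [el for el in truth.elements]
    lookup = {"As*": "As"}
    lib_names = [lookup.get(el, el) for el in elements]
    T, _ = build_templates(lib_names, library, inst)       # (nb, nel)
    sens = sensitivities(library)
    coef = np.array([inst.flux_area_scale_true * sens[n] * inst.dwell_s
                     for n in lib_names])
    h, w = truth.shape
    P = np.stack([truth.elements[el].ravel() for el in elements], axis=1)
    expected = P @ (coef[:, None] * T.T)                   # (npx, nb)
    expected += inst.background_level
    for el, rate in inst.contaminant_lines.items():
        Tc, _ = build_templates([el], library, inst)
        expected += rate * inst.dwell_s * Tc[:, 0][None, :]
    expected = expected.reshape(h, w, nb)
    if poisson:
        rng = np.random.default_rng([4, seed])
        counts = rng.poisson(expected).astype(np.int64)
    else:
        counts = expected.copy()
    return PixelSpectrumCube(counts=counts, expected=expected, bin_edges=edges,
                             pixel_size_nm=truth.pixel_size_nm,
                             species=truth.species, experiment=truth.experiment)


def synthetic_standard(certified_ppm: Dict[str, float], inst: InstrumentConfig,
                       library=None, seed: int = 0, n_pixels: int = 1000,
                       poisson: bool = False) -> CalibrationStandard:
    """Render and fit a certified standard measurement under ``inst``.

    The standard is measured off the TEM grid, so hutch/grid contaminant
    lines are omitted; the summed spectrum over ``n_pixels`` pixels is fit
    with the standard's own element set and per-pixel amplitudes returned.
    """
    from .spectrum import fit_spectrum
    if library is None:
        library = load_line_library()
    edges = inst.bin_edges
    els = sorted(certified_ppm)
    T, names = build_templates(els, library, inst)
    sens = sensitivities(library)
    coef = np.array([inst.flux_area_scale_true * sens[n] * inst.dwell_s * n_pixels
                     for n in names])
    expected = T @ (coef * np.array([certified_ppm[n] for n in names]))
    expected = expected + inst.background_level * n_pixels
    if poisson:
        rng = np.random.default_rng([5, seed])
        y = rng.poisson(expected).astype(float)
    else:
        y = expected
    fit = fit_spectrum(y, els, library, inst, weights="poisson")
    amps = {el: fit.amplitude(el) / n_pixels for el in els}
    return CalibrationStandard(certified_ppm=dict(certified_ppm), amplitudes=amps)


# ---------------------------------------------------------------------------
# study templates and benchmark suite
# ---------------------------------------------------------------------------

def template_geometry(experiment: str, species: str = "C. pelagicus",
                      seed: int = 0, pixel_size_nm: float = 50.0) -> GeometryConfig:
    """Default geometry for a control (C), medium (M) or high (H) specimen."""
    if species.startswith("C"):
        base = dict(species_template="placolith_bar", length_um=9.0, width_um=7.0)
    else:
        base = dict(species_template="placolith_bridge", length_um=5.0, width_um=4.0)
    if experiment == "C":
        extra = dict(tube_thickness=3.0, shield_thickness=1.0,
                     central_structure_present=True, outline_irregularity=0.0)
    elif experiment == "M":
        extra = dict(tube_thickness=2.6, shield_thickness=0.85,
                     central_structure_present=True, outline_irregularity=0.15)
    elif experiment == "H":
        extra = dict(tube_thickness=2.2, shield_thickness=0.7,
                     central_structure_present=False, outline_irregularity=0.25)
    else:
        raise ValueError("experiment must be 'C', 'M' or 'H'")
    return GeometryConfig(seed=seed, pixel_size_nm=pixel_size_nm, **base, **extra)


def template_models(experiment: str) -> Dict[str, IncorporationModel]:
    """Default per-element incorporation models per culture experiment.

    Lattice ratios follow the per-experiment magnitudes of the study's
    summary table (control Sr/Ca ~3.7, Se/Ca ~0.047 mmol/mol; both roughly
    doubled-to-quintupled under high metal stress); coat scales put the
    surface elements at the observed i/Ca orders of magnitude.
    """
    M = IncorporationModel
    common = {
        "Cl": M(mode="surface", coat_field_scale=1.5e4, noise_cv=0.1),
        "Fe": M(mode="surface", coat_field_scale=500.0, noise_cv=0.1),
        "W": M(mode="hotspot", coat_field_scale=0.0, n_hotspots=3,
               hotspot_radius_px=2.0, hotspot_intensity=2000.0, noise_cv=0.1),
    }
    if experiment == "C":
        spec = {
            "Sr": M(mode="lattice", base_ratio_mmol_per_mol=3.0,
                    radial_gradient=1.3, noise_cv=0.1),
            "Se": M(mode="lattice", base_ratio_mmol_per_mol=0.045,
                    radial_gradient=1.0, noise_cv=0.15),
            "Ni": M(mode="surface", coat_field_scale=150.0, noise_cv=0.1),
            "Zn": M(mode="absent", coat_field_scale=0.0),
            "V": M(mode="absent", coat_field_scale=0.0),
        }
    elif experiment == "M":
        spec = {
            "Sr": M(mode="lattice", base_ratio_mmol_per_mol=3.3,
                    radial_gradient=1.6, noise_cv=0.12),
            "Se": M(mode="lattice", base_ratio_mmol_per_mol=0.04,
                    radial_gradient=1.0, noise_cv=0.15),
            "Ni": M(mode="surface", coat_field_scale=400.0, noise_cv=0.1),
            "Zn": M(mode="hotspot", coat_field_scale=30.0, n_hotspots=4,
                    hotspot_radius_px=1.5, hotspot_intensity=8000.0, noise_cv=0.1),
            "V": M(mode="absent", coat_field_scale=0.0),
        }
    elif experiment == "H":
        spec = {
            "Sr": M(mode="lattice", base_ratio_mmol_per_mol=4.2,
                    radial_gradient=2.2, noise_cv=0.15),
            "Se": M(mode="lattice", base_ratio_mmol_per_mol=0.26,
                    radial_gradient=1.0, noise_cv=0.15),
            "Ni": M(mode="surface", coat_field_scale=300.0, noise_cv=0.1),
            "Zn": M(mode="absent", coat_field_scale=0.0),
            "V": M(mode="absent", coat_field_scale=20.0, noise_cv=0.05),
        }
    else:
        raise ValueError("experiment must be 'C', 'M' or 'H'")
    return {**common, **spec}


def make_specimen(experiment: str = "C", species: str = "C. pelagicus",
                  seed: int = 0, pixel_size_nm: float = 50.0,
                  k_ca: float = K_CA_DEFAULT,
                  models: Dict[str, IncorporationModel] | None = None,
                  solution: SolutionComposition | None = None) -> SpecimenMap:
    """One default-template synthetic specimen with ground truth attached."""
    geom = template_geometry(experiment, species, seed=seed,
                             pixel_size_nm=pixel_size_nm)
    thickness = make_geometry(geom)
    if models is None:
        models = template_models(experiment)
    return make_element_fields(thickness, models, k_ca=k_ca, seed=seed,
                               solution=solution, species=species,
                               experiment=experiment)


def benchmark_suite(seeds: Sequence[int] = range(5),
                    pixel_size_nm: float = 100.0) -> list[SpecimenMap]:
    """The shipped classification benchmark: seeds x (C, M, H) templates.

    100 nm pixels keep each specimen around 10k points so the whole
    15-specimen suite generates in seconds; ground truth travels on each
    specimen's ``truth`` attribute.
    """
    out = []
    for seed in seeds:
        for exp in ("C", "M", "H"):
            out.append(make_specimen(exp, seed=seed, pixel_size_nm=pixel_size_nm))
    return out
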