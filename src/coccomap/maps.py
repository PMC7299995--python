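"""Map-level analysis of single-coccolith elemental concentration maps.

This module operates on per-pixel concentration stacks (ppm), whether they
come from the synthetic specimen generator or from fitting measured
per-pixel XRF spectra.  It implements the map-level computations used to
characterise a placolith:

* calcite masking — pixels with Ca below a threshold (default 0.2e5 ppm)
  are background / unreliable and excluded from every statistic;
* molar i/Ca ratio maps in mmol/mol;
* specimen summary statistics (mean ratios, mean Ca, coccolith area);
* transect profiles with Ca band zoning (background / low / high);
* tube / external-rim / margin region segmentation with a minimum
  pixel-count rule;
* masked Pearson correlations between element maps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

#: Default calcite mask threshold: Ca below this is background/unreliable.
CA_MASK_THRESHOLD_PPM = 0.2e5
#: Boundary between the "low" and "high" Ca bands in transect zoning.
CA_HIGH_BAND_PPM = 1.0e5

#: Minimum pixels per morphological region for region statistics.
MIN_REGION_PIXELS = 30

ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "O": 15.999, "Mg": 24.305, "Si": 28.085,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845,
    "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "As": 74.922, "As*": 74.922,
    "Se": 78.971, "Kr": 83.798, "Sr": 87.62, "W": 183.84, "Pb": 207.2,
}

REGION_LABELS = {
    0: "background",
    1: "tube",
    2: "external_rim",
    3: "margin",
    4: "unassigned",
}


class EmptyTransectError(ValueError):
    """Raised when a transect never leaves the background."""


class RegionPartitionError(ValueError):
    """Raised when a tube/rim/margin partition violates the pixel-count rule."""


@dataclass
class SpecimenMap:
    """Multi-element per-pixel concentration stack for one specimen.

    Parameters
    ----------
    elements
        Mapping element symbol -> 2-D ppm grid.  Must contain ``"Ca"``;
        all grids share one shape and are nonnegative.
    pixel_size_nm
        Edge length of one (square) pixel in nanometres.
    species, experiment
        Free-text labels (e.g. ``"C. pelagicus"``, ``"C"``/``"M"``/``"H"``).
    truth
        Optional generator ground truth (per-element mode, intended mean
        molar ratios, partition coefficients) carried along for tests.
    excluded_from_regions
        Set for tilted specimens whose tube/rim/margin zones cannot be
        identified; region segmentation refuses to run on them.
    """

    elements: Dict[str, np.ndarray]
    pixel_size_nm: float
    species: str = ""
    experiment: str = ""
    truth: dict | None = None
    excluded_from_regions: bool = False

    def __post_init__(self) -> None:
        if "Ca" not in self.elements:
            raise ValueError("SpecimenMap requires a 'Ca' grid (reference element)")
        shape = None
        for name, grid in self.elements.items():
            grid = np.asarray(grid, dtype=float)
            if grid.ndim != 2:
                raise ValueError(f"element grid {name!r} is not 2-D")
            if shape is None:
                shape = grid.shape
            elif grid.shape != shape:
                raise ValueError(f"element grid {name!r} shape {grid.shape} != {shape}")
            if np.any(grid < 0):
                raise ValueError(f"element grid {name!r} has negative ppm values")
            self.elements[name] = grid
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elements["Ca"].shape

    @property
    def ca(self) -> np.ndarray:
        return self.elements["Ca"]

    def __getitem__(self, element: str) -> np.ndarray:
        return self.elements[element]

    def mask(self, threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> np.ndarray:
        return mask_calcite(self.ca, threshold_ppm)

    @property
    def pixel_area_um2(self) -> float:
        return (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class RatioMap:
    """Per-pixel molar ratio map i/Ca in mmol/mol, valid on the mask only."""

    element: str
    reference: str
    values: np.ndarray          # NaN off mask
    mask: np.ndarray

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class Transect:
    """Sampled polyline profile with per-sample Ca band labels.

    ``samples`` has one row per sampled pixel with columns
    ``x``, ``y``, ``ca_ppm``, ``band`` plus one ppm column per element and
    one ``<el>_over_ca_mmol_mol`` column per non-Ca element (NaN where the
    pixel is sub-threshold).  Background samples are retained in the table
    but excluded from all derived statistics.
    """

    samples: pd.DataFrame
    polyline: list[tuple[float, float]]

    def band_sequence(self) -> list[str]:
        """Condensed run-length band sequence along the transect."""
        bands = self.samples["band"].tolist()
        out: list[str] = []
        for b in bands:
            if not out or out[-1] != b:
                out.append(b)
        return out

    def band_means(self, column: str) -> pd.Series:
        """Mean of ``column`` per non-background band."""
        keep = self.samples[self.samples["band"] != "background"]
        return keep.groupby("band")[column].mean()


@dataclass
class RegionPartition:
    """Tube / external-rim / margin labelling of the calcite mask."""

    labels: np.ndarray          # integer codes per REGION_LABELS
    counts: Dict[str, int]
    d_margin_px: float
    q_tube: float

    def region_mask(self, name: str) -> np.ndarray:
        code = {v: k for k, v in REGION_LABELS.items()}[name]
        return self.labels == code


# ---------------------------------------------------------------------------
# masking and ratio maps
# ---------------------------------------------------------------------------

def mask_calcite(ca_map: np.ndarray, threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> np.ndarray:
    """Boolean calcite mask: True where Ca >= ``threshold_ppm``.

    An empty mask is legal (a warning is emitted); downstream statistics
    then return the empty-statistics sentinel rather than raising.
    """
    ca_map = np.asarray(ca_map, dtype=float)
    if np.any(ca_map < 0):
        raise ValueError("Ca map must be nonnegative")
    mask = ca_map >= threshold_ppm
    if not mask.any():
        warnings.warn("calcite mask is empty at this threshold", stacklevel=2)
    return mask


def molar_ratio_mmol_per_mol(ppm_i: np.ndarray | float, ppm_ca: np.ndarray | float,
                             element: str, reference: str = "Ca") -> np.ndarray | float:
    """(ppm_i/A_i)/(ppm_Ca/A_Ca) * 1000, i.e. the i/Ca molar ratio in mmol/mol."""
    a_i = ATOMIC_WEIGHTS[element]
    a_ca = ATOMIC_WEIGHTS[reference]
    return (np.asarray(ppm_i, dtype=float) / a_i) / (np.asarray(ppm_ca, dtype=float) / a_ca) * 1000.0


def ratio_map(i_map: np.ndarray, ca_map: np.ndarray, element: str,
              mask: np.ndarray | None = None,
              threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> RatioMap:
    """Per-pixel molar ratio map, defined on the calcite mask only."""
    ca_map = np.asarray(ca_map, dtype=float)
    i_map = np.asarray(i_map, dtype=float)
    if mask is None:
        mask = mask_calcite(ca_map, threshold_ppm)
    assert not np.any(mask & (ca_map <= 0)), "mask precondition violated: Ca==0 inside mask"
    values = np.full(ca_map.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[mask] = molar_ratio_mmol_per_mol(i_map[mask], ca_map[mask], element)
    return RatioMap(element=element, reference="Ca", values=values, mask=mask)


# ---------------------------------------------------------------------------
# specimen statistics
# ---------------------------------------------------------------------------

def specimen_stats(spec: SpecimenMap,
                   threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> dict:
    """Per-specimen summary record.

    Returns a dict with ``n_points`` (mask size), ``area_um2`` (mask pixel
    count times pixel area), ``mean_ca_ppm``, ``ca_per_area_ppm_per_um2``
    and an ``elements`` DataFrame (one row per element: mean of per-pixel
    molar ratios over the mask in mmol/mol, mean ppm over the mask).

    The mean ratio is the mean of per-pixel ratios, not the ratio of mean
    concentrations; the two differ whenever the ratio varies spatially.
    """
    mask = spec.mask(threshold_ppm)
    n = int(mask.sum())
    record: dict = {
        "species": spec.species,
        "experiment": spec.experiment,
        "n_points": n,
    }
    if n == 0:
        record.update({"area_um2": 0.0, "mean_ca_ppm": np.nan,
                       "ca_per_area_ppm_per_um2": np.nan,
                       "elements": pd.DataFrame(
                           columns=["mean_ratio_mmol_per_mol", "mean_ppm"])})
        return record
    area = n * spec.pixel_area_um2
    mean_ca = float(spec.ca[mask].mean())
    rows = {}
    for el, grid in spec.elements.items():
        mean_ppm = float(grid[mask].mean())
        if el == "Ca":
            ratio = np.nan
        else:
            ratio = float(np.mean(molar_ratio_mmol_per_mol(grid[mask], spec.ca[mask], el)))
        rows[el] = {"mean_ratio_mmol_per_mol": ratio, "mean_ppm": mean_ppm}
    record.update({
        "area_um2": area,
        "mean_ca_ppm": mean_ca,
        "ca_per_area_ppm_per_um2": mean_ca / area,
        "elements": pd.DataFrame.from_dict(rows, orient="index"),
    })
    return record


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def _ca_band(ca: float, threshold_ppm: float, high_ppm: float) -> str:
    if ca < threshold_ppm:
        return "background"
    if ca < high_ppm:
        return "low"
    return "high"


def extract_transect(spec: SpecimenMap,
                     polyline: Sequence[tuple[float, float]],
                     threshold_ppm: float = CA_MASK_THRESHOLD_PPM,
                     high_ppm: float = CA_HIGH_BAND_PPM) -> Transect:
    """Sample a polyline at ~1-pixel steps with nearest-pixel lookup.

    ``polyline`` is a sequence of (x, y) pixel coordinates (x = column,
    y = row, pixel centres at integer coordinates).  Raises
    :class:`EmptyTransectError` if every sample lies in the background.
    """
    polyline = [(float(x), float(y)) for x, y in polyline]
    if len(polyline) < 2:
        raise ValueError("polyline needs at least two vertices")
    h, w = spec.shape
    pts: list[tuple[int, int]] = []
    for (x0, y0), (x1, y1) in zip(polyline[:-1], polyline[1:]):
        seg_len = float(np.hypot(x1 - x0, y1 - y0))
        nstep = max(int(np.ceil(seg_len)), 1) + 1
        for t in np.linspace(0.0, 1.0, nstep):
            x = x0 + t * (x1 - x0)
            y = y0 + t * (y1 - y0)
            c, r = int(round(x)), int(round(y))
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"polyline leaves the grid at ({x:.1f}, {y:.1f})")
            if pts and pts[-1] == (c, r):
                continue
            pts.append((c, r))
    rows = []
    for i, (c, r) in enumerate(pts):
        ca = float(spec.ca[r, c])
        row = {"sample": i, "x": c, "y": r, "ca_ppm": ca,
               "band": _ca_band(ca, threshold_ppm, high_ppm)}
        for el, grid in spec.elements.items():
            if el == "Ca":
                continue
            row[f"{el}_ppm"] = float(grid[r, c])
            row[f"{el}_over_ca_mmol_mol"] = (
                float(molar_ratio_mmol_per_mol(grid[r, c], ca, el))
                if ca >= threshold_ppm else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    if (df["band"] == "background").all():
        raise EmptyTransectError("transect lies entirely in the background")
    return Transect(samples=df, polyline=polyline)


# ---------------------------------------------------------------------------
# region segmentation
# ---------------------------------------------------------------------------

def exterior_distance(support: np.ndarray) -> np.ndarray:
    """Distance (px) of each pixel to the exterior background.

    The exterior is the zero region connected to the image border; an
    enclosed central opening does not count, so distance grows from the
    coccolith outline inwards.
    """
    support = np.asarray(support, dtype=bool)
    bg = ~support
    lab, nlab = ndimage.label(bg)
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    exterior_ids = np.unique(lab[border & bg])
    exterior = np.isin(lab, exterior_ids) & bg
    return ndimage.distance_transform_edt(~exterior)


def radial_coordinate(support: np.ndarray) -> np.ndarray:
    """Normalised inward radial coordinate rho on the support.

    rho = 0 at the outline (margin pixels), rho = 1 at the innermost rim
    pixel (largest distance from the exterior).  Zero off the support.
    """
    support = np.asarray(support, dtype=bool)
    d = exterior_distance(support)
    rho = np.zeros(support.shape, dtype=float)
    if not support.any():
        return rho
    dmax = d[support].max()
    dmin = d[support].min()
    if dmax > dmin:
        rho[support] = (d[support] - dmin) / (dmax - dmin)
    return rho


def segment_regions(spec: SpecimenMap,
                    d_margin_px: float = 4.0,
                    q_tube: float = 0.80,
                    threshold_ppm: float = CA_MASK_THRESHOLD_PPM,
                    min_pixels: int = MIN_REGION_PIXELS) -> RegionPartition:
    """Partition the calcite mask into tube, external rim and margin.

    margin: masked pixels within ``d_margin_px`` of the outline (exterior
    distance transform); tube: remaining masked pixels with Ca at or above
    the ``q_tube`` quantile of the masked Ca distribution (quantile ties
    fall into the tube); external rim: everything else on the mask.
    Raises :class:`RegionPartitionError` unless each region has at least
    ``min_pixels`` pixels.
    """
    if spec.excluded_from_regions:
        raise RegionPartitionError(
            "specimen flagged as tilted/excluded: tube, rim and margin "
            "cannot be identified")
    mask = spec.mask(threshold_ppm)
    if not mask.any():
        raise RegionPartitionError("empty calcite mask")
    d = exterior_distance(mask)
    margin = mask & (d <= d_margin_px)
    q = float(np.quantile(spec.ca[mask], q_tube))
    tube = mask & (spec.ca >= q) & ~margin
    rim = mask & ~margin & ~tube
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[tube] = 1
    labels[rim] = 2
    labels[margin] = 3
    counts = {"tube": int(tube.sum()), "external_rim": int(rim.sum()),
              "margin": int(margin.sum())}
    bad = [k for k, v in counts.items() if v < min_pixels]
    if bad:
        raise RegionPartitionError(
            f"region(s) {bad} below the {min_pixels}-pixel minimum: {counts}")
    return RegionPartition(labels=labels, counts=counts,
                           d_margin_px=d_margin_px, q_tube=q_tube)


def region_means(spec: SpecimenMap, partition: RegionPartition,
                 element: str = "Sr") -> pd.Series:
    """Mean i/Ca molar ratio (mmol/mol) per region, ordered tube->margin."""
    out = {}
    for name in ("tube", "external_rim", "margin"):
        m = partition.region_mask(name)
        out[name] = float(np.mean(
            molar_ratio_mmol_per_mol(spec[element][m], spec.ca[m], element)))
    return pd.Series(out, name=f"{element}_over_ca_mmol_mol")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation between two maps over masked pixels.

    Returns NaN (the undefined-correlation sentinel) when either map has
    zero variance on the mask; raises on masks smaller than 3 pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask must contain at least 3 pixels")
    a = np.asarray(map_a, dtype=float)[mask]
    b = np.asarray(map_b, dtype=float)[mask]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance on mask: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_table(spec: SpecimenMap,
                      threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> pd.DataFrame:
    """Masked Pearson correlation matrix between all element maps."""
    mask = spec.mask(threshold_ppm)
    names = list(spec.elements)
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            if mask.sum() < 3:
                r = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = correlate(spec[a], spec[b], mask)
            out.loc[a, b] = out.loc[b, a] = r
    return out
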