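"""Evidence-based localisation verdicts for detected elements.

An element on a coccolith map is classified as one of

* ``lattice``  — incorporated in the calcite (co-distributed with Ca),
* ``surface``  — deposited on the organic coating (Cl-like distribution,
  no Ca correlation),
* ``hotspot``  — concentrated in a few point spots (handling/needle
  contamination),
* ``absent``   — not detected, all-zero, or present without any
  on-coccolith enrichment (V-style flat distributions).

The numeric thresholds formalise what the underlying study decides by
expert inspection of maps and transects; they are configurable for
exactly that reason and never hard-coded at call sites.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .maps import CA_MASK_THRESHOLD_PPM, SpecimenMap, correlate


class ClassifyThresholds(BaseModel):
    """Decision thresholds for the localisation classifier.

    ``theta_lattice`` is set below the ~0.7 Se-Ca correlation treated as
    lattice evidence in the literature and well above the coat-field
    correlations; ``theta_surface`` must stay below ``theta_lattice``.
    """

    theta_lattice: float = Field(0.6, gt=-1.0, lt=1.0)
    theta_surface: float = Field(0.3, gt=-1.0, lt=1.0)
    theta_coat: float = Field(0.3, gt=-1.0, lt=1.0)
    theta_spot: float = Field(0.25, gt=0.0, lt=1.0)
    contrast_ratio: float = Field(1.5, gt=1.0)
    top_fraction: float = Field(0.01, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _ordering(self) -> "ClassifyThresholds":
        if not self.theta_surface < self.theta_lattice:
            raise ValueError("theta_surface must be < theta_lattice")
        return self


@dataclass
class ClassificationResult:
    """Verdict plus the quantitative evidence it rests on."""

    element: str
    verdict: str                      # lattice | surface | hotspot | absent
    r_with_ca: float = float("nan")
    r_with_cl: float = float("nan")
    hotspot_fraction: float = float("nan")
    detected: bool = True
    flags: list[str] = dc_field(default_factory=list)


def hotspot_fraction(values_on_mask: np.ndarray, top_fraction: float = 0.01) -> float:
    """Share of the element's on-mask mass in its top-``top_fraction`` pixels."""
    v = np.sort(np.asarray(values_on_mask, dtype=float))[::-1]
    total = v.sum()
    if total <= 0:
        return 0.0
    k = max(1, int(np.ceil(top_fraction * v.size)))
    return float(v[:k].sum() / total)


def classify_element(spec: SpecimenMap, element: str,
                     thresholds: ClassifyThresholds | None = None,
                     mask: np.ndarray | None = None,
                     included: bool = True,
                     threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> ClassificationResult:
    """Classify one element from its map evidence.

    Decision order: not included -> absent; no on/off-coccolith contrast
    -> absent (no interaction); hotspot mass concentration -> hotspot;
    strong Ca correlation -> lattice; weak Ca correlation plus Cl-like
    distribution -> surface; otherwise the larger of the two correlations
    decides, with a low-confidence flag.  Verdicts are invariant to
    positive linear rescaling of the element map.
    """
    th = thresholds or ClassifyThresholds()
    if element == "Ca":
        raise ValueError("Ca is the reference element, not a classification target")
    flags: list[str] = []
    if element == "As*":
        flags.append("possible-Pb-L-contribution")
    if not included:
        return ClassificationResult(element, "absent", detected=False,
                                    flags=flags + ["failed-inclusion"])
    if mask is None:
        mask = spec.mask(threshold_ppm)
    vals = spec[element]
    on = vals[mask]
    if on.size == 0 or not np.any(on > 0):
        warnings.warn(f"{element}: map is zero on the calcite mask", stacklevel=2)
        return ClassificationResult(element, "absent", detected=False,
                                    flags=flags + ["all-zero-on-mask"])
    off = vals[~mask]
    mean_on = float(on.mean())
    mean_off = float(off.mean()) if off.size else 0.0
    contrast = np.inf if mean_off == 0 else mean_on / mean_off
    hf = hotspot_fraction(on, th.top_fraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_ca = correlate(vals, spec.ca, mask)
    cl_available = "Cl" in spec.elements and element != "Cl"
    if cl_available:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_cl = correlate(vals, spec["Cl"], mask)
    else:
        r_cl = float("nan")
        flags.append("no-Cl-reference")
    if contrast <= th.contrast_ratio:
        return ClassificationResult(element, "absent", r_ca, r_cl, hf,
                                    detected=True,
                                    flags=flags + ["no-coccolith-interaction"])
    if hf >= th.theta_spot:
        verdict = "hotspot"
    elif not np.isnan(r_ca) and r_ca >= th.theta_lattice:
        verdict = "lattice"
    elif (np.isnan(r_ca) or r_ca < th.theta_surface) and (
            not cl_available or (not np.isnan(r_cl) and r_cl >= th.theta_coat)):
        verdict = "surface"
    else:
        verdict = "lattice" if (np.nan_to_num(r_ca) >= np.nan_to_num(r_cl)) else "surface"
        flags.append("low-confidence")
    return ClassificationResult(element, verdict, r_ca, r_cl, hf, flags=flags)


def classify_specimen(spec: SpecimenMap,
                      thresholds: ClassifyThresholds | None = None,
                      included: Mapping[str, bool] | None = None,
                      threshold_ppm: float = CA_MASK_THRESHOLD_PPM) -> pd.DataFrame:
    """Classify every non-Ca element of a specimen; one row per element."""
    mask = spec.mask(threshold_ppm)
    rows = []
    for el in spec.elements:
        if el == "Ca":
            continue
        inc = True if included is None else bool(included.get(el, True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = classify_element(spec, el, thresholds, mask=mask, included=inc,
                                   threshold_ppm=threshold_ppm)
        rows.append({"element": el, "verdict": res.verdict,
                     "r_with_ca": res.r_with_ca, "r_with_cl": res.r_with_cl,
                     "hotspot_fraction": res.hotspot_fraction,
                     "detected": res.detected, "flags": ";".join(res.flags)})
    return pd.DataFrame(rows).set_index("element")


def classification_report(spec: SpecimenMap, table: pd.DataFrame) -> str:
    """Human-readable report section for one specimen's verdicts."""
    lines = [f"Specimen {spec.species} [{spec.experiment}]:"]
    for el, row in table.iterrows():
        ev = []
        if np.isfinite(row["r_with_ca"]):
            ev.append(f"r(el,Ca)={row['r_with_ca']:.2f}")
        if np.isfinite(row["r_with_cl"]):
            ev.append(f"r(el,Cl)={row['r_with_cl']:.2f}")
        if np.isfinite(row["hotspot_fraction"]):
            ev.append(f"top-1% mass={row['hotspot_fraction']:.2f}")
        flag = f" [{row['flags']}]" if row["flags"] else ""
        lines.append(f"  {el:>4s}: {row['verdict']:<8s} ({', '.join(ev)}){flag}")
    return "\n".join(lines) + "\n"
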