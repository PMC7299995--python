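"""File formats, configuration and the end-to-end pipeline.

Maps travel as multi-page 32-bit float TIFF (one page per element, element
order and pixel size in a JSON ImageDescription tag — inspectable with
ImageJ); spectrum cubes as NumPy ``.npz`` archives with arrays ``counts``,
``expected``, ``bin_edges`` plus scalar metadata; every tabular output is
CSV whose first line records the configuration hash, so re-running with a
changed parameter is visible in the artefacts themselves.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator

from . import classify as _classify
from . import maps as _maps
from . import partition as _partition
from . import spectrum as _spectrum
from . import synthetic as _synthetic
from .classify import ClassifyThresholds
from .maps import SpecimenMap
from .synthetic import InstrumentConfig, PixelSpectrumCube

log = logging.getLogger("coccomap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# maps I/O
# ---------------------------------------------------------------------------

def write_maps(spec: SpecimenMap, path: str | Path) -> Path:
    """Write a SpecimenMap as a multi-page 32-bit TIFF with JSON metadata."""
    path = Path(path)
    names = list(spec.elements)
    stack = np.stack([spec.elements[n] for n in names]).astype(np.float32)
    meta = {"elements": names, "pixel_size_nm": spec.pixel_size_nm,
            "species": spec.species, "experiment": spec.experiment}
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))
    return path


def read_maps(path: str | Path) -> SpecimenMap:
    """Read a multi-page TIFF back into a SpecimenMap.

    Integer (e.g. legacy 16-bit) pages are promoted losslessly to float.
    A file without a Ca page is rejected: Ca is the reference element for
    masking and every ratio.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray().astype(np.float64)
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        meta = None
    if not isinstance(meta, dict) or "elements" not in meta:
        raise ValueError(f"{path}: missing/invalid element metadata tag")
    names = meta["elements"]
    if stack.ndim == 2:
        stack = stack[None]
    if len(names) != stack.shape[0]:
        raise ValueError(f"{path}: {len(names)} element names for {stack.shape[0]} pages")
    if "Ca" not in names:
        raise ValueError(f"{path}: no 'Ca' page — Ca is the required reference element")
    elements = {n: stack[i] for i, n in enumerate(names)}
    return SpecimenMap(elements=elements, pixel_size_nm=float(meta["pixel_size_nm"]),
                       species=meta.get("species", ""),
                       experiment=meta.get("experiment", ""))


# ---------------------------------------------------------------------------
# spectra I/O
# ---------------------------------------------------------------------------

def write_spectra(cube: PixelSpectrumCube, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path, counts=cube.counts, expected=cube.expected,
        bin_edges=cube.bin_edges,
        pixel_size_nm=np.float64(cube.pixel_size_nm),
        species=np.str_(cube.species), experiment=np.str_(cube.experiment))
    return path


def read_spectra(path: str | Path) -> PixelSpectrumCube:
    with np.load(path, allow_pickle=False) as z:
        return PixelSpectrumCube(
            counts=z["counts"], expected=z["expected"], bin_edges=z["bin_edges"],
            pixel_size_nm=float(z["pixel_size_nm"]),
            species=str(z["species"]), experiment=str(z["experiment"]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class RegionParams(BaseModel):
    d_margin_px: float = Field(4.0, gt=0)
    q_tube: float = Field(0.80, gt=0, lt=1)
    min_pixels: int = Field(30, ge=1)


class SimulateParams(BaseModel):
    experiment: str = "C"
    species: str = "C. pelagicus"
    pixel_size_nm: float = Field(50.0, gt=0)
    k_ca: float = Field(_synthetic.K_CA_DEFAULT, gt=0)
    render_spectra: bool = False


class PipelineConfig(BaseModel):
    """Validated configuration for the full pipeline run."""

    seed: int = 0
    out_dir: str = "coccomap_out"
    simulate: Optional[SimulateParams] = None
    maps_path: Optional[str] = None
    spectra_path: Optional[str] = None
    standard_path: Optional[str] = None
    solution_path: Optional[str] = None
    candidates: list[str] = Field(default_factory=lambda: [
        "Ca", "Sr", "Se", "Cl", "Fe", "Ni", "Zn", "As", "V", "Mn", "Ti", "Cr",
        "W", "Ar", "Si", "Cu", "Kr"])
    instrument: InstrumentConfig = Field(default_factory=InstrumentConfig)
    z_threshold: float = Field(3.0, gt=0)
    mask_threshold_ppm: float = Field(_maps.CA_MASK_THRESHOLD_PPM, gt=0)
    regions: RegionParams = Field(default_factory=RegionParams)
    thresholds: ClassifyThresholds = Field(default_factory=ClassifyThresholds)
    transects: list[str] = Field(default_factory=list)
    exclude_from_regions: bool = False

    @field_validator("transects")
    @classmethod
    def _parse_ok(cls, v: list[str]) -> list[str]:
        for t in v:
            parse_transect(t)
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.model_validate(json.load(fh))


def demo_config(out_dir: str | Path) -> PipelineConfig:
    """The shipped demo: simulate a control specimen, analyse, classify."""
    with resources.as_file(resources.files("coccomap.data") / "demo_config.json") as p:
        cfg = load_config(p)
    cfg.out_dir = str(out_dir)
    return cfg


def parse_transect(text: str) -> list[tuple[float, float]]:
    """Parse ``"x1,y1:x2,y2[:x3,y3...]"`` into a polyline."""
    pts = []
    for chunk in text.split(":"):
        x, y = chunk.split(",")
        pts.append((float(x), float(y)))
    if len(pts) < 2:
        raise ValueError(f"transect {text!r} needs at least two points")
    return pts


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, **kwargs) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, **kwargs)
    return path


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path, cfg_hash: str):
    sim = config.simulate
    solution = _load_solution(config)
    spec = _synthetic.make_specimen(
        sim.experiment, sim.species, seed=config.seed,
        pixel_size_nm=sim.pixel_size_nm, k_ca=sim.k_ca, solution=solution)
    write_maps(spec, out / "simulated_maps.tif")
    truth_rows = {el: rec for el, rec in (spec.truth or {}).items()}
    truth_df = pd.DataFrame.from_dict(truth_rows, orient="index")
    _write_csv(truth_df, out / "ground_truth.csv", cfg_hash, index_label="element")
    cube = None
    if sim.render_spectra:
        cube = _synthetic.render_spectra(spec, config.instrument, seed=config.seed)
        write_spectra(cube, out / "spectra.npz")
    return spec, cube


def _stage_fit(config: PipelineConfig, cube: PixelSpectrumCube,
               out: Path, cfg_hash: str) -> SpecimenMap:
    library = _spectrum.load_line_library()
    fit = _spectrum.fit_specimen(cube, config.candidates, library,
                                 config.instrument, config.z_threshold)
    for el in config.candidates:
        state = "kept" if el in fit.included else "dropped"
        log.debug("inclusion: %s %s", el, state)
    log.info("fit: included elements %s", fit.included)
    standard = _load_standard(config)
    cal = _spectrum.calibrate(standard, library, config.instrument.dwell_s)
    log.info("fit: flux-area scale k=%.4g", cal.flux_area_scale)
    spec = _spectrum.quantify(fit.amplitude_maps, cal, library,
                              config.instrument.dwell_s, cube.pixel_size_nm,
                              species=cube.species, experiment=cube.experiment)
    write_maps(spec, out / "fitted_maps.tif")
    _write_csv(fit.summed.elements, out / "summed_fit.csv", cfg_hash)
    return spec


def _load_standard(config: PipelineConfig) -> _spectrum.CalibrationStandard:
    if config.standard_path is None:
        ctx = resources.as_file(
            resources.files("coccomap.data") / "standard_synthetic.csv")
        with ctx as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(config.standard_path, comment="#")
    certified = dict(zip(df["element"], df["certified_ppm"].astype(float)))
    if "amplitude" in df.columns:
        amps = dict(zip(df["element"], df["amplitude"].astype(float)))
        return _spectrum.CalibrationStandard(certified, amps)
    # no measured amplitudes supplied: render the standard measurement
    # synthetically under the configured instrument
    return _synthetic.synthetic_standard(certified, config.instrument,
                                         seed=config.seed)


def _load_solution(config: PipelineConfig) -> _partition.SolutionComposition:
    if config.solution_path is None:
        return _partition.default_solution()
    return _partition.SolutionComposition.from_csv(config.solution_path)


def _stage_analyze(config: PipelineConfig, spec: SpecimenMap,
                   out: Path, cfg_hash: str) -> dict:
    stats = _maps.specimen_stats(spec, config.mask_threshold_ppm)
    el_df = stats["elements"].copy()
    solution = _load_solution(config)
    part = _partition.partition_table(stats["elements"], solution)
    for el, row in part.iterrows():
        el_df.loc[el, "D"] = row["D"]
    summary = pd.DataFrame([{k: v for k, v in stats.items() if k != "elements"}])
    _write_csv(summary, out / "specimen_summary.csv", cfg_hash, index=False)
    _write_csv(el_df, out / "element_stats.csv", cfg_hash, index_label="element")
    _write_csv(part, out / "partition_coefficients.csv", cfg_hash,
               index_label="element")
    try:
        partn = _maps.segment_regions(
            spec, config.regions.d_margin_px, config.regions.q_tube,
            config.mask_threshold_ppm, config.regions.min_pixels)
        rows = {}
        for el in spec.elements:
            if el == "Ca":
                continue
            rows[el] = _maps.region_means(spec, partn, el)
        _write_csv(pd.DataFrame(rows).T, out / "region_means.csv", cfg_hash,
                   index_label="element")
    except _maps.RegionPartitionError as exc:
        log.warning("analyze: region segmentation skipped (%s)", exc)
    if config.transects:
        frames = []
        for i, text in enumerate(config.transects):
            tr = _maps.extract_transect(spec, parse_transect(text),
                                        config.mask_threshold_ppm)
            df = tr.samples.copy()
            df.insert(0, "transect", i)
            frames.append(df)
        _write_csv(pd.concat(frames, ignore_index=True), out / "transects.csv",
                   cfg_hash, index=False)
    corr = _maps.correlation_table(spec, config.mask_threshold_ppm)
    _write_csv(corr, out / "correlations.csv", cfg_hash, index_label="element")
    return stats


def _stage_classify(config: PipelineConfig, spec: SpecimenMap,
                    out: Path, cfg_hash: str,
                    included: dict[str, bool] | None = None) -> pd.DataFrame:
    table = _classify.classify_specimen(spec, config.thresholds, included,
                                        config.mask_threshold_ppm)
    _write_csv(table, out / "classification.csv", cfg_hash)
    report = _classify.classification_report(spec, table)
    (out / "classification_report.txt").write_text(
        f"# config_hash={cfg_hash}\n{report}")
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> fit -> analyze -> classify, as configured.

    Stages are gated on their inputs: no spectra means no fit stage, and
    the analysed maps are then the simulated (or loaded) ones.  Outputs
    land in ``config.out_dir``; re-running with an identical config and
    seed rewrites byte-identical CSVs.  Any stage error is re-raised as
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    timings: dict[str, float] = {}
    spec: SpecimenMap | None = None
    cube: PixelSpectrumCube | None = None
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            t0 = time.perf_counter()
            spec, cube = _stage_simulate(config, out, cfg_hash)
            timings[stage] = time.perf_counter() - t0
            log.info("simulate: %s done", spec.species)
        if config.maps_path is not None:
            stage = "read-maps"
            spec = read_maps(config.maps_path)
        if config.spectra_path is not None:
            stage = "read-spectra"
            cube = read_spectra(config.spectra_path)
        if cube is not None:
            stage = "fit"
            t0 = time.perf_counter()
            spec = _stage_fit(config, cube, out, cfg_hash)
            timings[stage] = time.perf_counter() - t0
        if spec is None:
            raise PipelineError("no maps to analyse: configure simulate, "
                                "maps_path or spectra_path")
        spec.excluded_from_regions = config.exclude_from_regions
        stage = "analyze"
        t0 = time.perf_counter()
        _stage_analyze(config, spec, out, cfg_hash)
        timings[stage] = time.perf_counter() - t0
        stage = "classify"
        t0 = time.perf_counter()
        _stage_classify(config, spec, out, cfg_hash)
        timings[stage] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    run_log = {"config_hash": cfg_hash, "seed": config.seed,
               "stage_timings_s": timings}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return {"out_dir": str(out), "config_hash": cfg_hash, "timings": timings}
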