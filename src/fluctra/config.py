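"""Run configuration and the multi-stage pipeline runner.

A run is described by a YAML/JSON document with one block per stage
(simulate / fcs / rics / nandb) plus shared blocks (psf, seed, outdir).
Unknown keys are rejected anywhere in the document.  Every run writes a
resolved copy of its configuration next to the outputs so it can be
re-executed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import correlation, fcs, nandb, rics, simulate
from .containers import ImageStack, IntensityTrace, ScanProtocol
from .errors import FluctraError
from .io import ResultRecord, input_hash, read_stack, read_trace, write_results, write_stack, write_trace
from .psf import PSFModel

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("fluctra")

_VERSION = "0.1.0"


def _build(cls, d: dict, where: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise FluctraError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class SimulateBlock:
    kind: str = "raster_stack"  # or "fcs_trace"
    species: tuple = ()
    dwell: float = 10e-6
    n_dwells: int = 2**15
    scan: Optional[dict] = None
    detector: Optional[dict] = None
    bleach: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.kind not in ("raster_stack", "fcs_trace"):
            raise FluctraError(f"unknown simulate kind {self.kind!r}")
        if not self.species:
            raise FluctraError("simulate block needs at least one species")


@dataclass(frozen=True)
class FCSBlock:
    trace: Optional[str] = None  # input path; defaults to simulated trace
    components: int = 1
    fixed_fast_d: Optional[float] = None


@dataclass(frozen=True)
class RICSBlock:
    stack: Optional[str] = None
    roi: tuple[int, int, int, int] = (96, 96, 64, 64)
    detrend_window: Optional[int] = 10
    detector_offset: float = 0.0


@dataclass(frozen=True)
class NandBBlock:
    stack: Optional[str] = None
    detrend_window: Optional[int] = 10
    s_factor: float = 1.0
    offset: float = 0.0
    readout_variance: float = 0.0
    reference_b: Optional[float] = None
    bin_width: float = 0.01


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[str, ...]
    outdir: str
    seed: int = 0
    psf: dict = field(default_factory=lambda: {"omega_r": 0.25, "structural_factor": 0.2})
    simulate: Optional[dict] = None
    fcs: Optional[dict] = None
    rics: Optional[dict] = None
    nandb: Optional[dict] = None

    def __post_init__(self) -> None:
        known = ("simulate", "fcs", "rics", "nandb")
        for s in self.stages:
            if s not in known:
                raise FluctraError(f"unknown stage {s!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = _build(cls, {**d, "stages": tuple(d.get("stages", ()))}, "config")
        # validate the blocks eagerly so bad keys fail before any compute
        if cfg.simulate is not None:
            _build(SimulateBlock, {**cfg.simulate, "species": tuple(cfg.simulate.get("species", ()))}, "simulate")
        if cfg.fcs is not None:
            _build(FCSBlock, cfg.fcs, "fcs")
        if cfg.rics is not None:
            _build(RICSBlock, {**cfg.rics, "roi": tuple(cfg.rics.get("roi", (96, 96, 64, 64)))}, "rics")
        if cfg.nandb is not None:
            _build(NandBBlock, cfg.nandb, "nandb")
        return cfg

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "outdir": self.outdir,
            "seed": self.seed,
            "psf": dict(self.psf),
            **{
                k: dict(v)
                for k, v in (
                    ("simulate", self.simulate),
                    ("fcs", self.fcs),
                    ("rics", self.rics),
                    ("nandb", self.nandb),
                )
                if v is not None
            },
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.from_dict(doc)


def _species_list(raw) -> list[simulate.ParticleSpecies]:
    return [_build(simulate.ParticleSpecies, dict(s), "species") for s in raw]


def _detector(raw: Optional[dict]) -> simulate.DetectorModel:
    if not raw:
        return simulate.DetectorModel.ideal()
    return _build(simulate.DetectorModel, dict(raw), "detector")


def _bleach(raw: Optional[dict]) -> simulate.BleachingModel:
    if not raw:
        return simulate.BleachingModel()
    return _build(simulate.BleachingModel, dict(raw), "bleach")


def run_pipeline(config: RunConfig) -> list[ResultRecord]:
    """Execute the requested stages in order with a shared seed.

    Simulated data flow into the analysis stages in memory and are also
    written to the output directory; a stage failure aborts with a
    stage-tagged error, preserving whatever was already written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)
    psf = _build(PSFModel, dict(config.psf), "psf")
    records: list[ResultRecord] = []
    trace: Optional[IntensityTrace] = None
    stack: Optional[ImageStack] = None
    provenance_base = {"seed": config.seed, "version": _VERSION}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                blk = _build(
                    SimulateBlock,
                    {**(config.simulate or {}), "species": tuple((config.simulate or {}).get("species", ()))},
                    "simulate",
                )
                species = _species_list(blk.species)
                det = _detector(blk.detector)
                if blk.kind == "fcs_trace":
                    trace = simulate.simulate_fcs_trace(
                        species, psf, blk.dwell, blk.n_dwells, det, seed=config.seed
                    )
                    write_trace(trace, outdir / "trace.csv")
                    est = {"n_dwells": len(trace), "mean_intensity": float(trace.values.mean())}
                else:
                    scan = ScanProtocol.from_dict(blk.scan or {})
                    stack = simulate.simulate_raster_stack(
                        species, psf, scan, det, _bleach(blk.bleach), seed=config.seed
                    )
                    write_stack(stack, outdir / "stack.tif")
                    est = {
                        "n_frames": stack.n_frames,
                        "mean_intensity": float(stack.data.mean()),
                    }
                rec = ResultRecord("simulate", est, provenance=dict(provenance_base))
            elif stage == "fcs":
                blk = _build(FCSBlock, config.fcs or {}, "fcs")
                if blk.trace is not None:
                    trace = read_trace(blk.trace)
                    provenance = {**provenance_base, "input_hash": input_hash(blk.trace)}
                elif trace is not None:
                    provenance = dict(provenance_base)
                else:
                    raise FluctraError("fcs stage has no trace (simulate first or give a path)")
                acf = correlation.temporal_acf(trace, scheme="multi_tau", n_segments=8)
                fit = fcs.fit_fcs(
                    acf, psf, n_components=blk.components, fixed_fast_d=blk.fixed_fast_d
                )
                rec = ResultRecord(
                    "fcs",
                    fit.derived,
                    uncertainties=fit.stderr,
                    diagnostics={"redchi": fit.redchi, "success": fit.success},
                    provenance=provenance,
                )
            elif stage == "rics":
                blk = _build(
                    RICSBlock,
                    {**(config.rics or {}), "roi": tuple((config.rics or {}).get("roi", (96, 96, 64, 64)))},
                    "rics",
                )
                if blk.stack is not None:
                    stack = read_stack(blk.stack)
                    provenance = {**provenance_base, "input_hash": input_hash(blk.stack)}
                elif stack is not None:
                    provenance = dict(provenance_base)
                else:
                    raise FluctraError("rics stage has no stack (simulate first or give a path)")
                roi = rics.RoiSelection(*blk.roi)
                res = rics.localized_roi_analysis(
                    stack,
                    roi,
                    psf,
                    detrend_window=blk.detrend_window,
                    detector_offset=blk.detector_offset,
                )
                rec = ResultRecord(
                    "rics",
                    res.fit.derived,
                    uncertainties=res.fit.stderr,
                    diagnostics={
                        "redchi": res.fit.redchi,
                        "success": res.fit.success,
                        "roi": blk.roi,
                        "warnings": res.warnings,
                    },
                    provenance=provenance,
                )
            elif stage == "nandb":
                blk = _build(NandBBlock, config.nandb or {}, "nandb")
                if blk.stack is not None:
                    stack = read_stack(blk.stack)
                    provenance = {**provenance_base, "input_hash": input_hash(blk.stack)}
                elif stack is not None:
                    provenance = dict(provenance_base)
                else:
                    raise FluctraError("nandb stage has no stack (simulate first or give a path)")
                cal = nandb.DetectorCalibration(
                    s_factor=blk.s_factor,
                    offset=blk.offset,
                    readout_variance=blk.readout_variance,
                )
                maps = nandb.compute_nandb_maps(stack, cal, detrend_window=blk.detrend_window)
                hist = nandb.fit_b_histogram(maps, bin_width=blk.bin_width)
                est = {"modal_b": hist.center, "b_width": hist.width}
                unc = {}
                if blk.reference_b is not None:
                    norm = nandb.normalize_brightness(hist.center, blk.reference_b, hist.width)
                    est["eps_norm"] = norm.value
                    unc["eps_norm"] = norm.uncertainty
                rec = ResultRecord(
                    "nandb",
                    est,
                    uncertainties=unc,
                    diagnostics={"n_pixels": hist.meta.get("n_pixels")},
                    provenance=provenance,
                )
            else:  # pragma: no cover - guarded in __post_init__
                raise FluctraError(f"unknown stage {stage!r}")
        except Exception as exc:
            write_results(records, outdir)
            raise FluctraError(f"stage '{stage}' failed: {exc}") from exc
        rec.diagnostics["elapsed_s"] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs: %s", stage, rec.diagnostics["elapsed_s"], rec.estimates)
        records.append(rec)
    write_results(records, outdir)
    return records
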