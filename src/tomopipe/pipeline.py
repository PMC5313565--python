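"""End-to-end orchestration: configuration, full runs, preview, backends.

``run_full`` drives the standard pipeline: flat-field normalization ->
calibration pre-pass (center / tilt / overlap) -> optional half-scan
stitching -> optional phase retrieval -> sinogram assembly -> artifact
filters -> gridrec reconstruction. ``preview`` reconstructs only selected
slices (its outputs are identical to the matching ``run_full`` slices).
Every run is a pure function of (inputs, config, seed); each stage appends
a structured record (stage, parameters, shapes, duration) to the run log.
"""

from __future__ import annotations

import dataclasses
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .artifacts import FilterConfig
from .calibration import ScanGeometry, calibrate_scan, stitch_pairs
from .errors import InvalidArgument
from .io_formats import RawScan, ScanLog, read_dxchange, read_tiff_dir
from .optics import OpticsConfig
from .phase import RetrievalConfig, retrieve
from .recon import FilterSpec, reconstruct_volume
from .sinogram import build_sinograms, normalize_scan

__all__ = ["PipelineConfig", "RunResult", "map_backend", "load_scan",
           "run_full", "preview"]


def map_backend(fn, items: list, backend: str = "serial",
                processes: int = 2) -> list:
    """Map a picklable function over items, serially or on a process pool.

    Results are returned in input order; both backends are bit-identical by
    construction (same code, same inputs).
    """
    if backend == "serial":
        return [fn(x) for x in items]
    if backend == "process":
        with ProcessPoolExecutor(max_workers=processes) as pool:
            return list(pool.map(fn, items))
    raise InvalidArgument(f"unknown backend {backend!r}: serial|process")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    contrast: str = "absorption"          # absorption | phase
    halfscan: bool = False
    rows: Optional[List[int]] = None      # None = all detector rows
    center: Optional[float] = None        # override: skip calibration
    tilt: Optional[float] = None
    overlap: Optional[int] = None
    filter_name: str = "ramlak"
    filter_cutoff: float = 1.0
    apply_zinger: bool = False
    apply_ring: Optional[str] = None      # None | unsharp | wavelet_fft
    filters: FilterConfig = field(default_factory=FilterConfig)
    retrieval: Optional[RetrievalConfig] = None
    optics: Optional[OpticsConfig] = None
    roi: Optional[Tuple[int, int, int, int]] = None
    rotate_by: float = 0.0
    backend: str = "serial"
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.filter_name, self.filter_cutoff)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("filters") is not None:
            d["filters"] = FilterConfig(**d["filters"])
        if d.get("retrieval") is not None:
            d["retrieval"] = RetrievalConfig(**d["retrieval"])
        if d.get("optics") is not None:
            d["optics"] = OpticsConfig(**d["optics"])
        if d.get("roi") is not None:
            d["roi"] = tuple(d["roi"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    volume: np.ndarray
    log: ScanLog
    geometry: ScanGeometry
    run_log: List[dict]
    config: PipelineConfig

    @property
    def slices(self) -> np.ndarray:
        return self.volume


def load_scan(source) -> RawScan:
    """Load a RawScan from an HDF5 file, a TIFF directory, or pass through."""
    if isinstance(source, RawScan):
        return source
    path = Path(source)
    if path.is_dir():
        return read_tiff_dir(path)
    return read_dxchange(path)


def _stage(run_log: List[dict], name: str, t0: float, **params) -> None:
    run_log.append({"stage": name, "duration_s": time.perf_counter() - t0,
                    **params})


def _process(scan: RawScan, config: PipelineConfig,
             rows: Optional[Sequence[int]]) -> RunResult:
    run_log: List[dict] = []
    t0 = time.perf_counter()
    normalized = normalize_scan(scan)
    _stage(run_log, "normalize", t0, shape=list(normalized.shape))

    t0 = time.perf_counter()
    if config.center is not None or (config.halfscan
                                     and config.overlap is not None):
        geometry = ScanGeometry(
            center=(config.center if config.center is not None
                    else normalized.shape[-1] - config.overlap / 2.0),
            tilt=config.tilt or 0.0, overlap=config.overlap)
        log = ScanLog(center=geometry.center, tilt=geometry.tilt,
                      overlap=geometry.overlap, n_proj=scan.n_proj)
    else:
        geometry, log = calibrate_scan(normalized, scan.angles,
                                       halfscan=config.halfscan)
    _stage(run_log, "calibrate", t0, center=geometry.center,
           tilt=geometry.tilt, overlap=geometry.overlap)

    angles = scan.angles
    if config.halfscan:
        t0 = time.perf_counter()
        normalized = stitch_pairs(normalized, geometry.overlap)
        angles = angles[:len(normalized)]
        geometry = ScanGeometry(center=(normalized.shape[-1] - 1) / 2.0,
                                overlap=geometry.overlap)
        _stage(run_log, "stitch", t0, width=normalized.shape[-1])

    contrast = config.contrast
    if config.retrieval is not None:
        if config.optics is None:
            raise InvalidArgument("phase retrieval requires an OpticsConfig")
        t0 = time.perf_counter()
        import functools
        fn = functools.partial(retrieve, optics=config.optics,
                               config=config.retrieval)
        normalized = np.stack(map_backend(fn, list(normalized),
                                          backend=config.backend))
        contrast = "phase"
        _stage(run_log, "phase_retrieval", t0,
               method=config.retrieval.method)

    t0 = time.perf_counter()
    n_rows = normalized.shape[1]
    use_rows = list(rows) if rows is not None else list(range(n_rows))
    sinos = build_sinograms(scan, rows=use_rows, log=log,
                            normalized=normalized)
    for s in sinos:
        s.angles = np.asarray(angles, dtype=float)
    _stage(run_log, "sinogen", t0, n_sinograms=len(sinos))

    t0 = time.perf_counter()
    fcfg = config.filters if (config.apply_zinger or config.apply_ring) else None
    slices = reconstruct_volume(sinos, geometry=geometry,
                                spec=config.filter_spec(), roi=config.roi,
                                rotate_by=config.rotate_by,
                                contrast=contrast, filter_config=fcfg,
                                apply_zinger=config.apply_zinger,
                                ring_method=config.apply_ring)
    _stage(run_log, "reconstruct", t0, n_slices=len(slices),
           filter=config.filter_name, cutoff=config.filter_cutoff)

    volume = np.stack([s.values for s in slices])
    return RunResult(volume=volume, log=log, geometry=geometry,
                     run_log=run_log, config=config)


def run_full(source, config: Optional[PipelineConfig] = None) -> RunResult:
    """Run the complete pipeline on a scan (file path, directory or RawScan)."""
    config = config or PipelineConfig()
    scan = load_scan(source)
    return _process(scan, config, rows=config.rows)


def preview(source, rows: Sequence[int],
            config: Optional[PipelineConfig] = None) -> RunResult:
    """Reconstruct only the requested slice rows (streaming preview mode).

    Builds sinograms solely for ``rows``; the returned slices equal the
    corresponding slices of :func:`run_full`.
    """
    rows = list(rows)
    if not rows:
        raise InvalidArgument("preview needs at least one row")
    config = config or PipelineConfig()
    scan = load_scan(source)
    return _process(scan, config, rows=rows)
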