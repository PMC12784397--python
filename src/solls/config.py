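"""Run configuration, end-to-end pipeline and fixture generation.

A :class:`RunConfig` collects every stage's parameters, round-trips
losslessly through YAML, and drives ``run_pipeline``: beam synthesis →
optional scattering → single-molecule movie → localization →
filtering / axial rescaling / drift correction → region statistics and
FRC.  Every run writes its fully resolved configuration beside the
outputs so any artifact can be regenerated from its sidecar.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beams import (MaskSpec, MirrorSpec, SheetSpec, make_gaussian_sheet,
                    make_lattice_sheet)
from .fields import OpticalTrain, write_volume
from .localize import (bin_regions, compute_sbr, filter_localizations,
                       frc_resolution, localize_movie, rescale_axial)
from .metrics import measure_sheet
from .smlm import (CameraModel, EmitterSet, PSFModel, make_cell_phantom,
                   simulate_frames, write_movie)

__all__ = ["RunConfig", "PipelineConfig", "run_pipeline", "make_fixtures",
           "sheet_vs_epi_sbr"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Movie/analysis stage parameters."""

    n_frames: int = 60
    fov_px: tuple[int, int] = (48, 48)
    background_photons: float = 2.0
    threshold_coeff: float = 2.0
    axial_factor: float = 0.75
    n_regions: int = 5
    frc_pixel_nm: float = 8.0
    x_span: float = 40.0
    n_planes: int = 41
    filter_rules: dict = dataclasses.field(default_factory=lambda: {
        "uncertainty_xy_nm": {"max": 100.0},
        "photons": {"max": 1_000_000.0},
    })


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration of one end-to-end run."""

    seed: int = 0
    outdir: str = "solls_run"
    train: OpticalTrain = dataclasses.field(default_factory=OpticalTrain)
    mask: MaskSpec = dataclasses.field(default_factory=MaskSpec)
    sheet: SheetSpec = dataclasses.field(
        default_factory=lambda: SheetSpec(family="gaussian"))
    mirror: MirrorSpec = dataclasses.field(default_factory=MirrorSpec)
    camera: CameraModel = dataclasses.field(default_factory=CameraModel)
    psf: PSFModel = dataclasses.field(default_factory=PSFModel)
    phantom_kind: str = "two_plane"
    phantom_params: dict = dataclasses.field(default_factory=lambda: {
        "extent": [6.0, 6.0], "separation": 4.0, "density": 0.25,
        "photon_rate": 4000.0, "on_probability": 0.08})
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for field in dataclasses.fields(cls):
            if field.name not in d:
                continue
            val = d.pop(field.name)
            typ = {"train": OpticalTrain, "mask": MaskSpec, "sheet": SheetSpec,
                   "mirror": MirrorSpec, "camera": CameraModel,
                   "psf": PSFModel, "pipeline": PipelineConfig}.get(field.name)
            if typ is not None and isinstance(val, dict):
                val = typ(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in val.items()})
            kwargs[field.name] = val
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | pathlib.Path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        pathlib.Path(path).write_text(
            yaml.safe_dump(clean(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))


def _build_sheet(config: RunConfig):
    p = config.pipeline
    if config.sheet.family == "lattice":
        return make_lattice_sheet(config.mask, config.train, config.sheet,
                                  x_span=p.x_span, n_planes=p.n_planes)
    return make_gaussian_sheet(config.sheet, config.train,
                               x_span=p.x_span, n_planes=p.n_planes)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns a report dict (also on disk).

    Artifacts written to ``config.outdir``: ``beam.tif`` (+ YAML
    sidecar), ``movie.tif``, ``locs.csv``, ``report.yaml`` and
    ``config.yaml`` (the resolved configuration).
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"version": __version__, "seed": config.seed, "stages": []}

    def stage(name):
        log.info("pipeline stage: %s", name)
        report["stages"].append(name)

    stage("simulate-beam")
    sheet = _build_sheet(config)
    write_volume(sheet, out / "beam.tif")
    m = measure_sheet(sheet)
    report["beam"] = {"thickness_w0_um": m.thickness_w0,
                      "width_1e2_um": m.width_1e2,
                      "effective_range_um": m.effective_range}

    stage("simulate-smlm")
    emitters = make_cell_phantom(config.phantom_kind, config.phantom_params,
                                 seed=config.seed)
    p = config.pipeline
    movie, truth = simulate_frames(emitters, sheet, config.psf, config.camera,
                                   p.n_frames, seed=config.seed,
                                   fov_px=p.fov_px,
                                   background_photons=p.background_photons)
    write_movie(out / "movie.tif", movie, truth, {"seed": config.seed})
    report["movie"] = {"n_frames": int(p.n_frames),
                       "n_true_emissions": int(len(truth))}

    stage("localize")
    locs = localize_movie(movie, config.camera, config.psf, p.threshold_coeff)
    report["localize"] = {"n_raw": int(len(locs))}

    stage("filter")
    if len(locs):
        locs = filter_localizations(locs, p.filter_rules)
        report["filter"] = {"n_kept": int(len(locs)),
                            "removed": locs.attrs.get("filter_counts", {})}
        if "z_um" in locs.columns:
            locs = rescale_axial(locs, p.axial_factor)
    if len(locs) == 0:
        log.warning("no localizations survive the filters")
    locs.to_csv(out / "locs.csv", index=False)

    stage("stats")
    if len(locs):
        locs = locs.assign(sbr=compute_sbr(locs, config.camera))
        regions = bin_regions(locs, p.n_regions, axis="x")
        report["regions"] = regions.table.to_dict("records")
        try:
            report["frc_nm"] = frc_resolution(locs, p.frc_pixel_nm,
                                              seed=config.seed)
        except ValueError as err:
            report["frc_nm"] = None
            log.info("FRC skipped: %s", err)
    (out / "report.yaml").write_text(yaml.safe_dump(_clean(report),
                                                    sort_keys=False))
    return report


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def sheet_vs_epi_sbr(illumination, seed: int = 0, separation: float = 4.0,
                     extent: float = 7.0, structure_density: float = 3.0,
                     n_probes: int = 3, n_frames: int = 5,
                     camera: CameraModel | None = None,
                     psf: PSFModel | None = None) -> tuple[float, float]:
    """Signal-to-background comparison of sheet vs epi illumination.

    Emulates the diffraction-limited benchmark: a dense emitter plane
    ``separation`` µm above focus plays the out-of-focus structure,
    while ``n_probes`` bright in-focus emitters are probed with
    intensity line scans (background from a 1.6 µm window) on the
    frame-averaged image.  Returns ``(sbr_sheet, sbr_epi)`` — the mean
    over the probes, under identical emitter configurations.
    """
    from .localize import sbr_from_line_scan

    camera = camera or CameraModel()
    psf = psf or PSFModel()
    rng = np.random.default_rng(seed)
    planes = make_cell_phantom("two_plane", {
        "extent": [extent, extent], "separation": separation,
        "density": structure_density, "photon_rate": 1500.0,
        "on_probability": 1.0}, seed=seed)
    above = planes.positions[:, 2] > separation / 2.0
    structure = EmitterSet(planes.positions[above],
                           planes.photon_rate[above], 1.0, False)
    probes = EmitterSet(
        np.column_stack([rng.uniform(-extent / 3, extent / 3, n_probes),
                         rng.uniform(-extent / 3, extent / 3, n_probes),
                         np.zeros(n_probes)]),
        4000.0, 1.0, np.zeros(n_probes, bool))
    emitters = EmitterSet.concatenate([structure, probes])
    fov = 48
    results = []
    for illum in (illumination, None):
        movie, _ = simulate_frames(emitters, illum, psf, camera, n_frames,
                                   seed=seed, fov_px=(fov, fov),
                                   background_photons=2.0)
        img = camera.photons_from_adu(movie.astype(float)).mean(axis=0)
        sbrs = []
        half = 10
        for px, py, _ in probes.positions:
            col = int(round(px / camera.pixel_size_x + fov / 2))
            row = int(round(py / camera.pixel_size_y + fov / 2))
            if col - half < 0 or col + half >= fov or not 0 <= row < fov:
                continue
            scan = img[row, col - half:col + half + 1]
            sbrs.append(sbr_from_line_scan(scan, camera.pixel_size_x))
        results.append(float(np.mean(sbrs)))
    return results[0], results[1]


def make_fixtures(seed: int = 0, outdir: str | pathlib.Path = "fixtures"
                  ) -> dict:
    """Small deterministic assets for tests and demos.

    Writes a 16-plane Gaussian-sheet volume, a 50-frame single-emitter
    movie with ground truth, and a 100-row localization table; returns
    the paths.  Regenerates bitwise-identically from the same seed.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    train = OpticalTrain()
    sheet = make_gaussian_sheet(SheetSpec(family="gaussian"), train,
                                x_span=15.0, n_planes=16, shape=(64, 128))
    beam_path = out / "beam_small.tif"
    write_volume(sheet, beam_path)

    camera = CameraModel()
    psf = PSFModel()
    emitters = EmitterSet(np.array([[0.0, 0.0, 0.0], [1.5, -1.0, 0.0]]),
                          3000.0, 0.6, np.array([False, False]))
    movie, truth = simulate_frames(emitters, None, psf, camera, 50,
                                   seed=seed, fov_px=(32, 32),
                                   background_photons=1.0)
    movie_path = out / "movie_small.tif"
    write_movie(movie_path, movie, truth, {"seed": seed})

    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "frame": np.arange(100),
        "x_um": rng.uniform(-3, 3, 100),
        "y_um": rng.uniform(-3, 3, 100),
        "z_um": rng.uniform(-0.5, 0.5, 100),
        "photons": rng.uniform(500, 8000, 100),
        "background": rng.uniform(1, 20, 100),
        "sigma_um": np.full(100, 0.165),
        "uncertainty_xy_nm": rng.uniform(5, 60, 100),
    })
    table_path = out / "locs_small.csv"
    table.to_csv(table_path, index=False)
    return {"beam": beam_path, "movie": movie_path, "locs": table_path}
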