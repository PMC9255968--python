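"""End-to-end orchestration: simulate -> detect -> analyze, with provenance.

A run is described by a single configuration (YAML file or dict): simulation
parameters or input paths, per-stage parameters, output directory and seed.
Every run writes a JSON manifest echoing all parameters, the package
version, input checksums and the list of output files, so any reported
number can be regenerated from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import CoreSet
from .detection import detect_cores, edge_transform, estimate_radii
from .dynamics import (bleach_correct, extract_signals, natural_frequencies,
                       pairwise_synchrony, spectrum, synchrony_curve)
from .morphometry import build_graph, direct_neighbor_stats, \
    nearest_neighbor_stats
from .synthetic import (LayoutParams, OscSpec, make_layout, render_frame,
                        simulate_movie)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_STAGE_KEYS = {"simulate", "detect", "morphometry", "dynamics"}
_TOP_KEYS = {"seed", "outdir", "input_frame", "input_movie",
             "pixel_size_nm", "dt_s"} | _STAGE_KEYS


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``simulate``/``detect``/``morphometry``/``dynamics`` are per-stage
    parameter dicts (a stage runs only if its key is present, except
    detection which also runs on simulated frames by default).  Unknown keys
    anywhere are rejected before any stage runs.
    """

    outdir: str
    seed: int = 0
    simulate: dict | None = None
    detect: dict | None = None
    morphometry: dict | None = None
    dynamics: dict | None = None
    input_frame: str | None = None
    input_movie: str | None = None
    pixel_size_nm: float | None = None
    dt_s: float | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config requires 'outdir'")
        for stage in _STAGE_KEYS:
            if stage in raw and raw[stage] is not None \
                    and not isinstance(raw[stage], dict):
                raise ValueError(f"stage {stage!r} must map to parameters")
        return cls(**raw)


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``<outdir>/manifest.json``).
    On stage failure the manifest records the failure point and completed
    outputs, then the exception propagates.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    for key in ("input_frame", "input_movie"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p),
                                       "sha256": _sha256(Path(p))}

    def _done(stage: str, outputs: list[Path], **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        manifest["outputs"] += [str(p) for p in outputs]
        _write_manifest()

    def _write_manifest() -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))

    frame = None
    movie = None
    layout = None
    current = "setup"
    try:
        if config.simulate is not None:
            current = "simulate"
            sim = dict(config.simulate)
            movie_cfg = sim.pop("movie", None)
            layout_keys = {f.name for f in dataclasses.fields(LayoutParams)}
            params = LayoutParams(**{k: v for k, v in sim.items()
                                     if k in layout_keys},
                                  seed=sim.get("seed", config.seed))
            render_kwargs = {k: v for k, v in sim.items()
                             if k not in layout_keys and k != "seed"}
            layout = make_layout(params)
            layout.to_dir(outdir)
            frame = render_frame(layout, rng=config.seed, **render_kwargs)
            frame.to_tiff(outdir / "frame.tif")
            outs = [outdir / "frame.tif", outdir / "cores_truth.csv",
                    outdir / "islets_truth.csv",
                    outdir / "layout_manifest.json"]
            if movie_cfg is not None:
                osc = OscSpec(**movie_cfg)
                movie, truth = simulate_movie(layout, osc, rng=config.seed,
                                              **render_kwargs)
                movie.to_tiff(outdir / "movie.tif")
                truth.to_csv(outdir / "signals_truth.csv")
                outs += [outdir / "movie.tif", outdir / "signals_truth.csv"]
            _done("simulate", outs, n_cores=len(layout),
                  n_islets=len(layout.islets))

        if frame is None and config.input_frame:
            from .core import Image2D
            frame = Image2D.from_tiff(config.input_frame,
                                      pixel_size_nm=config.pixel_size_nm)
        if movie is None and config.input_movie:
            from .core import ImageStack
            movie = ImageStack.from_tiff(config.input_movie,
                                         pixel_size_nm=config.pixel_size_nm,
                                         dt_s=config.dt_s)

        cores = None
        if config.detect is not None or frame is not None:
            current = "detect"
            if frame is None:
                raise ValueError("detect stage needs a frame")
            cores = detect_cores(frame, **(config.detect or {}))
            estimate_radii(frame, cores)
            cores.to_csv(outdir / "cores.csv")
            _done("detect", [outdir / "cores.csv"], n_detected=len(cores))

        if config.morphometry is not None:
            current = "morphometry"
            if cores is None:
                raise ValueError("morphometry stage needs detected cores")
            graph = build_graph(cores)
            graph.to_csv(outdir / "edges.csv")
            direct = direct_neighbor_stats(graph)
            nearest = nearest_neighbor_stats(graph)
            direct.per_vertex.to_csv(outdir / "direct_neighbors.csv",
                                     index=False)
            nearest.per_vertex.to_csv(outdir / "nearest_neighbors.csv",
                                      index=False)
            _done("morphometry",
                  [outdir / "edges.csv", outdir / "direct_neighbors.csv",
                   outdir / "nearest_neighbors.csv"],
                  direct_median_nm=direct.pooled_median_nm,
                  nearest_median_nm=nearest.pooled_median_nm)

        if config.dynamics is not None:
            current = "dynamics"
            if movie is None or cores is None:
                raise ValueError("dynamics stage needs a movie and cores")
            dyn = dict(config.dynamics)
            corrected = bleach_correct(movie) if dyn.pop("bleach_correct",
                                                         True) else movie
            signals = extract_signals(corrected, cores,
                                      radius_nm=dyn.pop("radius_nm", 100.0))
            signals.to_csv(outdir / "signals.csv")
            table = pairwise_synchrony(signals)
            table.to_csv(outdir / "synchrony.csv", index=False)
            curve = synchrony_curve(table,
                                    bin_width_nm=dyn.pop("bin_width_nm", 100.0))
            k_median = dyn.pop("k_median", 5.0)
            freqs = sorted({round(float(f), 6)
                            for row in signals.values
                            for f in natural_frequencies(
                                spectrum(row, signals.dt_s),
                                k_median=k_median)})
            _done("dynamics",
                  [outdir / "signals.csv", outdir / "synchrony.csv"],
                  half_decay_nm=curve.half_decay_nm,
                  natural_frequencies_Hz=freqs)
    except Exception as exc:
        manifest["stages"][current] = {"status": "failed", "error": str(exc)}
        _write_manifest()
        raise
    _write_manifest()
    return manifest
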