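"""End-to-end run orchestration: calibrate -> basis -> unmix -> render.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
executed stage by stage with timings and warnings collected into a JSON
manifest.  Reruns with an identical config and inputs produce numerically
identical coefficient and residual outputs; the manifest records the config
hash so a run can be reproduced from it alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .basis import (
    BasisSet,
    canonical_basis,
    load_basis_set,
    normalize_basis,
    save_basis_set,
)
from .calibration import ROIMask, measure_reference_envelope
from .hyperstack import HyperStack, load_hyperstack, save_hyperstack
from .phantom import NoiseModel, forward_simulate, generate_phantom
from .render import (
    RenderConfig,
    component_grayscale,
    false_color_composite,
    rgb_merge,
    save_png,
)
from .unmix import (
    UnmixConfig,
    save_coefficient_maps,
    scale_coefficient_maps,
    unmix_stack,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    stack: str | None = None  # path to an acquired stack (TIFF + sidecar)
    simulate: dict | None = None  # or generate one: {geometry, shape, seed, noise}
    basis: str = "canonical"  # basis directory, or the packaged synthetic set
    fad_scan: str | None = None  # optional reference scan for a calibration profile
    bands: tuple = ("blue", "green")
    reference: str = "epithelium"
    free_band_amplitude: bool = False
    render: dict = field(default_factory=lambda: {"wavelength_nm": 740.0, "range_nm": 0.0})
    clip_fraction: float = 0.0006
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "stack": self.stack,
            "simulate": self.simulate,
            "basis": self.basis,
            "fad_scan": self.fad_scan,
            "bands": list(self.bands),
            "reference": self.reference,
            "free_band_amplitude": self.free_band_amplitude,
            "render": self.render,
            "clip_fraction": self.clip_fraction,
            "seed": self.seed,
        }


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_simulate_stack(cfg: RunConfig, basis: BasisSet) -> HyperStack:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        geometry = sim.get("geometry", "checkerboard")
        shape = tuple(sim.get("shape", (64, 64)))
        noise_cfg = sim.get("noise", {}) or {}
        noise = NoiseModel(
            kind=noise_cfg.get("kind", "none"),
            peak_counts=float(noise_cfg.get("peak_counts", 1000.0)),
            read_sigma=float(noise_cfg.get("read_sigma", 0.0)),
        )
        scene = generate_phantom(geometry, shape, basis, seed=int(sim.get("seed", cfg.seed)))
        return forward_simulate(
            scene, basis, envelope=None, noise=noise, seed=int(sim.get("noise_seed", cfg.seed))
        )
    if cfg.stack is None:
        raise PipelineError("stage 'load': config names neither a stack nor a simulation")
    path = Path(cfg.stack)
    if not path.exists():
        raise PipelineError(f"stage 'load': stack file not found: {path}")
    return load_hyperstack(path)


def _load_basis(cfg: RunConfig, stack: HyperStack) -> BasisSet:
    if cfg.basis == "canonical":
        return canonical_basis(stack.excitation, stack.emission)
    path = Path(cfg.basis)
    if not path.exists():
        raise PipelineError(f"stage 'basis': basis directory not found: {path}")
    return load_basis_set(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; write outputs and return the run manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "stages": [],
        "warnings": [],
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 4), **extra}
            )

        return done

    try:
        done = stage("load")
        basis = _load_basis_pre(cfg)
        stack = _load_or_simulate_stack(cfg, basis)
        if cfg.simulate is not None:
            save_hyperstack(stack, out_dir / "stack.tif")
        done(shape=list(stack.shape))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise PipelineError(f"stage 'load': {exc}") from exc

    if cfg.fad_scan is not None:
        try:
            done = stage("calibrate")
            fad = load_hyperstack(cfg.fad_scan)
            profile = measure_reference_envelope(
                fad, ROIMask.full(fad.data.shape[:2]), band="green"
            )
            profile.to_json(out_dir / "calibration.json")
            done(outputs=["calibration.json"])
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'calibrate': {cfg.fad_scan}: {exc}") from exc

    try:
        done = stage("basis")
        basis = _load_basis(cfg, stack)
        basis = basis.map(normalize_basis) if not basis.normalized else basis
        save_basis_set(basis, out_dir / "basis")
        done(labels=list(basis.labels))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'basis': {cfg.basis}: {exc}") from exc

    try:
        done = stage("unmix")
        ucfg = UnmixConfig(
            bands_used=tuple(cfg.bands),
            display_reference=cfg.reference,
            free_band_amplitude=cfg.free_band_amplitude,
        )
        maps, residual = unmix_stack(stack, basis, ucfg)
        maps = scale_coefficient_maps(maps, ucfg)
        save_coefficient_maps(maps, residual, out_dir / "coefficients.tif")
        res = residual.values
        done(
            outputs=["coefficients.tif"],
            residual_total=float(res.sum()),
            residual_mean=float(res.mean()),
            residual_p99=float(np.percentile(res, 99)),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'unmix': {exc}") from exc

    try:
        done = stage("render")
        rcfg = RenderConfig(clip_fraction=cfg.clip_fraction)
        wl = float(cfg.render.get("wavelength_nm", 740.0))
        half = float(cfg.render.get("range_nm", 0.0)) / 2.0
        selection = wl if half == 0 else (wl - half, wl + half)
        outputs = []
        if set(("red", "green", "blue")) <= set(stack.emission.names):
            save_png(rgb_merge(stack, selection, rcfg), out_dir / "rgb_merge.png")
            outputs.append("rgb_merge.png")
        for label in maps.labels:
            panel, mv = component_grayscale(maps, label)
            save_png(panel, out_dir / f"component_{label}.png")
            outputs.append(f"component_{label}.png")
        if set(maps.labels) <= set(rcfg.colormap):
            save_png(false_color_composite(maps, rcfg), out_dir / "composite.png")
            outputs.append("composite.png")
        done(outputs=outputs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'render': {exc}") from exc

    manifest["residual_total"] = manifest["stages"][-2]["residual_total"]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _load_basis_pre(cfg: RunConfig) -> BasisSet:
    """Basis needed before simulation (the simulator mixes with it)."""
    if cfg.basis == "canonical":
        return canonical_basis()
    path = Path(cfg.basis)
    if not path.exists():
        raise PipelineError(f"stage 'basis': basis directory not found: {path}")
    return load_basis_set(path)
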