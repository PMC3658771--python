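"""Image readers/writers, run configuration and result serialization.

All outputs are plain inspectable formats: 8-bit PNG for label maps and
masks, CSV for polylines, JSON for the inclusion tree and the run
manifest, YAML for configuration.  Coordinates in every file are 0-based
(row, col) with pixel centers at integer positions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .contour_map import ContourMap, InclusionTree
from .errors import ImageFormatError, ParameterError
from .multipass import MultipassResult, ROFConfig
from .preprocessing import as_image_field
from .singlepass import AlgoParams
from .synthetic import PhantomSpec

__all__ = [
    "read_grayscale",
    "write_grayscale",
    "RunConfig",
    "save_run_outputs",
]

logger = logging.getLogger("mpcontour")


def read_grayscale(path) -> np.ndarray:
    """Load a single-channel PNG/PGM/TIFF image onto the real 0-255 scale.

    Multi-channel images are rejected (never silently converted); 16-bit
    inputs are rescaled to 0-255 with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"cannot read image: no such file {path}")
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as err:
        raise ImageFormatError(f"cannot read image {path}: {err}") from err
    if arr.ndim == 3:
        raise ImageFormatError(
            f"{path} has {arr.shape[2]} channels; only single-channel images are accepted"
        )
    arr = np.asarray(arr)
    if arr.dtype == np.uint16 or (np.issubdtype(arr.dtype, np.integer) and arr.max() > 255):
        logger.warning("%s is 16-bit; rescaling intensities to 0-255", path)
        arr = arr.astype(float) * (255.0 / 65535.0)
    return as_image_field(arr.astype(float))


def write_grayscale(path, image) -> None:
    """Write a 2-D intensity field as 8-bit PNG/PGM (values clipped to 0-255)."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


@dataclass(frozen=True)
class RunConfig:
    """Flat, serializable configuration for a full segmentation run.

    Holds every evolution weight, the ROF settings, the driver cap and
    the output/verbosity settings; round-trips losslessly through YAML.
    Loading validates the stability condition tau*alpha < 1/4 and rejects
    violations before any computation.
    """

    lambda1: float = 100.0
    lambda2: float = 100.0
    mu: float = 200.0 / 225.0**2
    v: float = 0.0
    alpha: float = 0.2
    tau: float = 1.0
    eps: float = 1.5
    eps_d: float = 1e-8
    rho: float = 6.0
    kappa: float = 4.0
    intensity_scale: float = 255.0
    mean_weighting: str = "sharp"
    max_iters_per_pass: int = 800
    stationary_window: int = 3
    rof_lam: float = 0.02
    rof_dt: float = 0.1
    rof_iters: int = 300
    rof_quantize: bool = True
    max_passes: int = 20
    out_dir: str = "mpcontour_out"
    verbosity: str = "info"

    def __post_init__(self) -> None:
        # Construct the sub-configs to run their validation (incl. tau*alpha < 1/4).
        self.algo_params()
        self.rof_config()
        if self.max_passes < 1:
            raise ParameterError(f"max_passes must be >= 1, got {self.max_passes}")

    def algo_params(self) -> AlgoParams:
        fields = {f.name for f in dataclasses.fields(AlgoParams)}
        return AlgoParams(**{k: v for k, v in dataclasses.asdict(self).items() if k in fields})

    def rof_config(self) -> ROFConfig:
        return ROFConfig(
            lam=self.rof_lam, dt=self.rof_dt, n_iters=self.rof_iters, quantize=self.rof_quantize
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _contours_csv_lines(cmap: ContourMap) -> list[str]:
    lines = [
        "# zero-level polylines; coordinates are 0-based (row, col), pixel centers at integers",
        "contour_id,polyline_id,vertex_index,row,col",
    ]
    poly_id = 0
    for k, polylines in enumerate(cmap.contours, start=1):
        for poly in polylines:
            poly_id += 1
            for vi, (r, c) in enumerate(poly):
                lines.append(f"{k},{poly_id},{vi},{r:.4f},{c:.4f}")
    return lines


def save_run_outputs(
    out_dir,
    result: MultipassResult,
    cmap: ContourMap,
    tree: InclusionTree,
    config: RunConfig,
) -> Path:
    """Write labeled PNG, polyline CSV, tree JSON and a reproducibility manifest.

    The manifest records the full configuration, package version, the
    per-pass summary and the termination reason -- enough to reproduce
    the run exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k_max = max(int(cmap.labels.max()), 1)
    write_grayscale(out / "labels.png", cmap.labels * (255 // k_max))
    for k, p in enumerate(result.passes, start=1):
        write_grayscale(out / f"mask_pass{k}.png", p.inner_mask * 255)
    (out / "contours.csv").write_text("\n".join(_contours_csv_lines(cmap)) + "\n")
    (out / "tree.json").write_text(json.dumps(tree.to_dict(), indent=2) + "\n")
    manifest = {
        "mpcontour_version": __version__,
        "config": dataclasses.asdict(config),
        "result": result.summary(),
        "coordinates": "0-based (row, col), pixel centers at integers",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def save_phantom_outputs(out_dir, spec: PhantomSpec, image, masks) -> Path:
    """Write a phantom PNG, its ground-truth mask PNGs and the spec JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_grayscale(out / "phantom.png", image)
    for i, m in enumerate(masks):
        write_grayscale(out / f"truth_mask{i}.png", m * 255)
    meta = dataclasses.asdict(spec)
    meta["shape"] = list(spec.shape)
    meta["levels"] = list(spec.levels)
    (out / "phantom_spec.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out
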