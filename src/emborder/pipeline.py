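"""End-to-end orchestration: simulate → segment → measure → compare.

Reproduces the study shape of the published analysis — ten follicle sections
per group, one λ/d ratio per section, two-tailed t-test between groups — on
synthetic phantoms or user-supplied images.  Every run writes a manifest
(config snapshot, per-image status, output index) so results are
reproducible from the recorded seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .acm import ACMParams, segment
from .boundary import compare_groups, extract_border, tortuosity
from .errors import ConfigError, EmborderError
from .phantom import PhantomSpec, make_dataset

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 1
EXIT_PARTIAL = 2
EXIT_TOTAL_FAILURE = 3

_MODES = ("simulate", "segment", "measure", "compare", "full")


@dataclass
class RunConfig:
    mode: str = "full"
    out_dir: str = "emborder_out"
    input_dir: str | None = None  # images to process in non-simulate modes
    n_pre: int = 10
    n_post: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acm: ACMParams = field(default_factory=ACMParams)
    roi: tuple[int, int, int, int] | None = None
    sides: tuple[str, str] = ("left", "right")
    polarity: str = "bright"
    pixel_size_um: float | None = None  # defaults to the phantom calibration
    seed: int = 0
    log_level: str = "INFO"


def validate_config(config: RunConfig | dict | None) -> RunConfig:
    """Normalize a config (dict or RunConfig), filling documented defaults;
    raises ConfigError listing every problem found."""
    if config is None:
        config = RunConfig()
    if isinstance(config, dict):
        config = _from_dict(config)
    errs = []
    if config.mode not in _MODES:
        errs.append(f"mode must be one of {_MODES}, got {config.mode!r}")
    if config.mode in ("segment", "measure", "compare") and not config.input_dir:
        errs.append(f"mode {config.mode!r} requires input_dir")
    if config.input_dir and not Path(config.input_dir).exists():
        errs.append(f"input_dir {config.input_dir!r} does not exist")
    if config.mode in ("simulate", "full"):
        if config.n_pre < 1 or config.n_post < 1:
            errs.append("n_pre and n_post must be >= 1 "
                        "(the comparison needs two groups)")
    try:
        config.phantom.validate()
    except EmborderError as e:
        errs.append(f"phantom: {e}")
    try:
        config.acm.validate()
    except EmborderError as e:
        errs.append(f"acm: {e}")
    if config.polarity not in ("bright", "dark"):
        errs.append("polarity must be 'bright' or 'dark'")
    if errs:
        raise ConfigError(errs)
    if config.pixel_size_um is None:
        config.pixel_size_um = config.phantom.pixel_size_um
    return config


def _from_dict(d: dict) -> RunConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError([f"unknown config field {k!r}" for k in sorted(unknown)])
    if "phantom" in d and isinstance(d["phantom"], dict):
        d["phantom"] = PhantomSpec(**d["phantom"])
    if "acm" in d and isinstance(d["acm"], dict):
        d["acm"] = ACMParams(**d["acm"])
    return RunConfig(**d)


def _measure_one(pid, group, img, px, config, analytic_ratio=None):
    """Segment one image and measure λ/d; returns (record dict, mask, trace)."""
    res = segment(img, params=config.acm, polarity=config.polarity)
    border = extract_border(mask=res.mask, pixel_size_um=px, roi=config.roi,
                            sides=config.sides, source_id=pid)
    rec = tortuosity(border, id=pid, group=group)
    row = {
        "id": pid,
        "group": group,
        "lambda_um": rec.lambda_um,
        "d_um": rec.d_um,
        "ratio": rec.ratio,
        "converged": res.converged,
    }
    if analytic_ratio is not None:
        row["analytic_ratio"] = analytic_ratio
        row["rel_err"] = abs(rec.ratio - analytic_ratio) / analytic_ratio
    return row, res


def run_full(config: RunConfig | dict | None = None) -> dict:
    """Simulate (or load), segment, measure and compare; returns the manifest.

    Per-image failures are logged and excluded; the manifest reports the
    failure count and the exit code the CLI should use.
    """
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    outputs = {}
    statuses = {}

    if config.mode in ("simulate", "full"):
        table, ds = make_dataset(config.n_pre, config.n_post, out / "dataset",
                                 base_spec=config.phantom, seed=config.seed)
        outputs["ground_truth_csv"] = str(out / "dataset" / "ground_truth.csv")
        items = [
            (pid, "pre" if spec.group == "pre_branch" else "post",
             str(out / "dataset" / "images" / f"{pid}.tif"), truth.ratio)
            for pid, spec, truth in ds["items"]
        ]
    else:
        items = _index_inputs(config)

    rows = []
    if config.mode in ("full", "segment", "measure"):
        mask_dir = out / "seg_masks"
        mask_dir.mkdir(exist_ok=True)
        for pid, group, path, analytic in items:
            try:
                img = read_image(path)
                px = config.pixel_size_um
                if config.mode == "measure":
                    # the input is already a mask; no segmentation performed
                    border = extract_border(mask=img > 0.5, pixel_size_um=px,
                                            roi=config.roi, sides=config.sides,
                                            source_id=pid)
                    rec = tortuosity(border, id=pid, group=group)
                    rows.append({"id": pid, "group": group,
                                 "lambda_um": rec.lambda_um, "d_um": rec.d_um,
                                 "ratio": rec.ratio})
                else:
                    row, res = _measure_one(pid, group, img, px, config, analytic)
                    iio.imwrite(mask_dir / f"{pid}_mask.png",
                                res.mask.astype(np.uint8) * 255)
                    rows.append(row)
                statuses[pid] = "ok"
            except (EmborderError, OSError) as e:  # pragma: no cover - per-image
                log.warning("image %s failed: %s", pid, e)
                statuses[pid] = f"failed: {e}"

    metrics = pd.DataFrame(rows)
    if len(rows):
        metrics_path = out / "metrics.csv"
        metrics.to_csv(metrics_path, index=False, float_format="%.10g")
        outputs["metrics_csv"] = str(metrics_path)

    comparison = None
    if config.mode in ("full", "compare"):
        if config.mode == "compare":
            metrics = pd.read_csv(Path(config.input_dir) / "metrics.csv")
        groups = set(metrics.get("group", []))
        if {"pre", "post"} <= groups:
            comparison = compare_groups(
                metrics.loc[metrics.group == "pre", "ratio"],
                metrics.loc[metrics.group == "post", "ratio"],
            )
            with open(out / "comparison.json", "w") as fh:
                json.dump(comparison, fh, indent=1)
            outputs["comparison_json"] = str(out / "comparison.json")
        else:
            raise ConfigError(["comparison requires both a 'pre' and a "
                               "'post' group in the metrics"])

    n_failed = sum(1 for s in statuses.values() if s != "ok")
    if statuses and n_failed == len(statuses):
        exit_code = EXIT_TOTAL_FAILURE
    elif n_failed:
        exit_code = EXIT_PARTIAL
    else:
        exit_code = EXIT_OK
    manifest = {
        "version": __version__,
        "config": _config_dict(config),
        "statuses": statuses,
        "n_failed": n_failed,
        "outputs": outputs,
        "comparison": comparison,
        "elapsed_s": round(time.time() - t_start, 3),
        "exit_code": exit_code,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _index_inputs(config: RunConfig):
    """Index input images: (id, group, path, analytic_ratio or None)."""
    root = Path(config.input_dir)
    truth = {}
    gt = root / "ground_truth.csv"
    if gt.exists():
        df = pd.read_csv(gt)
        truth = {r.id: r.ratio for r in df.itertuples()}
    items = []
    paths = sorted(root.glob("images/*.tif")) or sorted(
        p for pat in ("*.tif", "*.tiff", "*.png") for p in root.glob(pat)
    )
    for p in paths:
        pid = p.stem
        group = "pre" if pid.startswith("pre") else (
            "post" if pid.startswith("post") else "")
        items.append((pid, group, str(p), truth.get(pid)))
    return items


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG and rescale integer data to [0, 1] (logged)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        log.debug("rescaling %s from [0, %d] to [0, 1]", path.name, int(scale))
        return arr.astype(float) / scale
    return arr.astype(float)
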