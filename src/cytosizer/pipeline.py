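"""End-to-end orchestration: images -> pixel sizes -> um sizes -> report.

Two entry points mirror how the tool is used in practice:

* :func:`run_calibrate` — segment a set of certified bead frames, build
  (pixel, um) samples, fit the linear and quadratic converters, keep the one
  with smaller training RMSE and persist it as JSON.
* :func:`run_pipeline` — segment arbitrary particle frames and convert the
  pixel measurements to micrometres with the learned model, the fixed optics
  ratio, or both side by side (comparison mode shares a single segmentation
  pass, so the two columns differ only in the conversion step).

Per-frame failures (no segmentable particle, unreadable file) are isolated:
they appear as non-``ok`` status rows and never abort the batch unless every
frame fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import evaluation as ev
from . import segmentation as seg
from .errors import CalibrationFailedError, CytosizerError, InvalidInputError
from .synthetic import SyntheticSet

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "CalibrationResult",
    "load_segmentation_config",
    "measure_batch",
    "run_pipeline",
    "run_calibrate",
    "evaluate_segmentation",
]

log = logging.getLogger("cytosizer")

_RECORD_COLUMNS = ["source", "group", "status", "height_px", "width_px", "angle_deg",
                   "method", "height_um", "width_um"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: segmentation knobs plus conversion method(s)."""

    segmentation: seg.SegmentationConfig = field(default_factory=seg.SegmentationConfig)
    model: cal.SizeModel | None = None
    fixed_ratio: cal.FixedRatio | None = None
    comparison: bool = False
    bead_axis: str = "mean"  # "mean" of height/width, or "major", for bead diameters

    def __post_init__(self) -> None:
        if self.bead_axis not in ("mean", "major"):
            raise InvalidInputError(f"unknown bead_axis {self.bead_axis!r}")
        if self.comparison and (self.model is None or self.fixed_ratio is None):
            raise InvalidInputError("comparison mode needs both a model and a fixed ratio")
        if not self.comparison and (self.model is None) == (self.fixed_ratio is None):
            raise InvalidInputError("exactly one conversion method must be active")


@dataclass(frozen=True)
class PipelineResult:
    records: pd.DataFrame  # one row per (frame, method)
    summary: pd.DataFrame | None  # per-group report when truths were available


@dataclass(frozen=True)
class CalibrationResult:
    model: cal.SizeModel  # the selected converter
    linear: cal.SizeModel
    quadratic: cal.SizeModel
    samples: tuple[cal.CalibrationSample, ...]
    n_failed: int


def load_segmentation_config(path: str | Path) -> seg.SegmentationConfig:
    """Build a :class:`SegmentationConfig` from a nested YAML file.

    Recognised keys: ``resize.side``, ``blur.size``, ``blur.sigma``,
    ``canny.low``, ``canny.high``, ``morph.kernel``, ``morph.erode_iter``,
    ``morph.dilate_iter``, ``morph.order``, ``contour.min_area``.
    Unspecified keys keep their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    blur_cfg = raw.get("blur", {})
    sigma = float(blur_cfg.get("sigma", 1.4))
    blur = seg.GaussianKernelSpec(size=int(blur_cfg.get("size", 5)),
                                  sigma_i=sigma, sigma_j=sigma)
    return seg.SegmentationConfig(
        resize_side=int(raw.get("resize", {}).get("side", 120)),
        blur=blur,
        canny_low=float(raw.get("canny", {}).get("low", 50.0)),
        canny_high=float(raw.get("canny", {}).get("high", 150.0)),
        morph_kernel=int(raw.get("morph", {}).get("kernel", 3)),
        erode_iter=int(raw.get("morph", {}).get("erode_iter", 1)),
        dilate_iter=int(raw.get("morph", {}).get("dilate_iter", 1)),
        morph_order=str(raw.get("morph", {}).get("order", "dilate_first")),
        min_area=float(raw.get("contour", {}).get("min_area", 20.0)),
    )


def _iter_items(manifest: pd.DataFrame | SyntheticSet | Sequence,
                images_root: str | Path | None = None) -> Iterable[tuple[str, object, str]]:
    """Yield (source, image-or-path, group) from any supported input form."""
    if isinstance(manifest, SyntheticSet):
        for frame, (_, row) in zip(manifest.frames, manifest.manifest.iterrows()):
            yield str(row["path"]), frame.image_u8, str(row.get("group", ""))
        return
    if isinstance(manifest, pd.DataFrame):
        if manifest.empty:
            raise InvalidInputError("empty manifest")
        if "path" not in manifest.columns:
            raise InvalidInputError("manifest needs a 'path' column")
        root = Path(images_root) if images_root else None
        for _, row in manifest.iterrows():
            path = Path(row["path"])
            if root and not path.is_absolute():
                path = root / path
            yield str(row["path"]), path, str(row.get("group", ""))
        return
    items = list(manifest)
    if not items:
        raise InvalidInputError("empty manifest")
    for source, image, group in items:
        yield str(source), image, str(group)


def measure_batch(manifest: pd.DataFrame | SyntheticSet | Sequence,
                  config: seg.SegmentationConfig | None = None,
                  images_root: str | Path | None = None) -> pd.DataFrame:
    """Segment every frame; one row per frame with pixel sizes and status."""
    config = config or seg.SegmentationConfig()
    rows = []
    for source, image, group in _iter_items(manifest, images_root):
        row = {"source": source, "group": group, "status": "ok",
               "height_px": np.nan, "width_px": np.nan, "angle_deg": np.nan}
        try:
            if isinstance(image, Path):
                image = iio.imread(image)
            shape = seg.measure_pixels(np.asarray(image), config)
            row.update(height_px=shape.height_px, width_px=shape.width_px,
                       angle_deg=shape.angle_deg)
        except CytosizerError as exc:
            row["status"] = f"failed: {exc}"
            log.warning("skipping %s: %s", source, exc)
        except (OSError, ValueError) as exc:
            row["status"] = f"unreadable: {exc}"
            log.warning("cannot read %s: %s", source, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if (df["status"] != "ok").all():
        raise CytosizerError("every frame failed segmentation")
    return df


def _convert_frame(pixels_df: pd.DataFrame, method: str,
                   converter) -> pd.DataFrame:
    out = pixels_df.copy()
    out["method"] = method
    ok = out["status"] == "ok"
    for axis in ("height", "width"):
        um = np.full(len(out), np.nan)
        um[ok.to_numpy()] = converter(out.loc[ok, f"{axis}_px"].to_numpy())
        out[f"{axis}_um"] = um
    return out


def run_pipeline(manifest: pd.DataFrame | SyntheticSet | Sequence,
                 config: PipelineConfig,
                 truths: Mapping[str, float] | None = None,
                 images_root: str | Path | None = None,
                 feature: str = "diameter") -> PipelineResult:
    """Measure every frame and convert to um with the configured method(s)."""
    pixels = measure_batch(manifest, config.segmentation, images_root)
    parts = []
    if config.model is not None:
        parts.append(_convert_frame(pixels, "learned",
                                    lambda px: cal.convert(config.model, px)))
    if config.fixed_ratio is not None and (config.comparison or config.model is None):
        parts.append(_convert_frame(pixels, "fixed_ratio",
                                    lambda px: cal.fixed_ratio_convert(config.fixed_ratio, px)))
    records = pd.concat(parts, ignore_index=True)[_RECORD_COLUMNS]

    summary = None
    if truths is not None:
        recs = [
            ev.MeasurementRecord(source=r.source, group=r.group,
                                 height_um=float(r.height_um), width_um=float(r.width_um),
                                 method=r.method)
            for r in records.itertuples()
            if r.status == "ok" and np.isfinite(r.height_um)
        ]
        summary = ev.summary_frame(ev.summarize_groups(recs, truths, feature=feature))
    return PipelineResult(records=records, summary=summary)


def run_calibrate(manifest: pd.DataFrame | SyntheticSet | Sequence,
                  config: seg.SegmentationConfig | None = None,
                  nominal_um: Mapping[str, float] | Sequence[float] | None = None,
                  bead_axis: str = "mean",
                  images_root: str | Path | None = None,
                  force_kind: str | None = None,
                  out_model: str | Path | None = None,
                  plot: str | Path | None = None) -> CalibrationResult:
    """Segment bead frames, fit linear + quadratic converters, select by RMSE.

    Every successfully segmented bead contributes one (pixel, um) sample:
    x is the mean of height and width in original pixels (spherical beads;
    set ``bead_axis="major"`` to use the major axis only) and y the nominal
    certified diameter of its class.  Needs at least three distinct usable
    classes.  ``force_kind`` overrides the RMSE selection.
    """
    if isinstance(manifest, SyntheticSet):
        nominal = manifest.manifest["nominal_um"].to_list()
    elif isinstance(manifest, pd.DataFrame) and "nominal_um" in manifest.columns:
        nominal = manifest["nominal_um"].to_list()
    elif nominal_um is not None and not isinstance(nominal_um, Mapping):
        nominal = list(nominal_um)
    else:
        nominal = None

    pixels = measure_batch(manifest, config, images_root)
    if nominal is not None:
        if len(nominal) != len(pixels):
            raise InvalidInputError("nominal size list does not match manifest length")
        pixels = pixels.assign(nominal_um=nominal)
    elif isinstance(nominal_um, Mapping):
        pixels = pixels.assign(nominal_um=pixels["group"].map(nominal_um))
    else:
        raise InvalidInputError("no nominal bead sizes provided")

    ok = pixels[(pixels["status"] == "ok") & pixels["nominal_um"].notna()]
    n_failed = len(pixels) - len(ok)
    if ok["nominal_um"].nunique() < 3:
        raise CalibrationFailedError(
            f"only {ok['nominal_um'].nunique()} usable bead classes after segmentation; "
            "need >= 3")
    if bead_axis == "major":
        px = ok["height_px"].to_numpy()
    else:
        px = 0.5 * (ok["height_px"] + ok["width_px"]).to_numpy()
    samples = tuple(cal.CalibrationSample(x=float(p), y=float(y), label=str(g))
                    for p, y, g in zip(px, ok["nominal_um"], ok["group"]))

    linear = cal.fit_linear(samples)
    quadratic = cal.fit_quadratic(samples)
    if force_kind == "linear":
        model = linear
    elif force_kind == "quadratic":
        model = quadratic
    elif force_kind is None:
        model = cal.select_model(linear, quadratic)
    else:
        raise InvalidInputError(f"unknown force_kind {force_kind!r}")

    if out_model is not None:
        cal.save_model(model, out_model)
    if plot is not None:
        _plot_fit(samples, linear, quadratic, model, plot)
    return CalibrationResult(model=model, linear=linear, quadratic=quadratic,
                             samples=samples, n_failed=n_failed)


def _plot_fit(samples, linear, quadratic, selected, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([s.x for s in samples])
    y = np.array([s.y for s in samples])
    grid = np.linspace(x.min() * 0.9, x.max() * 1.1, 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.5, label="beads")
    ax.plot(grid, linear.predict(grid), "--",
            label=f"linear (RMSE {linear.rmse:.4f})")
    ax.plot(grid, quadratic.predict(grid),
            label=f"quadratic (RMSE {quadratic.rmse:.4f})")
    ax.set_xlabel("pixel diameter")
    ax.set_ylabel("physical diameter (um)")
    ax.set_title(f"selected: {selected.kind}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def evaluate_segmentation(frames_with_masks: Iterable[tuple[np.ndarray, np.ndarray]],
                          config: seg.SegmentationConfig | None = None) -> ev.IoUReport:
    """Mean IoU of pipeline masks against ground-truth masks.

    Each item is ``(image, truth_mask)`` in the original frame; the predicted
    mask is the filled fitted contour mapped back to original pixels.  Frames
    the pipeline cannot segment score an IoU of 0.
    """
    config = config or seg.SegmentationConfig()
    scores = []
    for image, truth in frames_with_masks:
        truth = np.asarray(truth)
        try:
            shape = seg.measure_pixels(np.asarray(image), config)
            pred = seg.contour_to_mask(shape.contour, truth.shape)
            scores.append(ev.iou(truth, pred))
        except CytosizerError:
            scores.append(0.0)
    if not scores:
        raise InvalidInputError("no frames to evaluate")
    return ev.IoUReport(mean_iou=float(np.mean(scores)), per_image=tuple(scores))
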