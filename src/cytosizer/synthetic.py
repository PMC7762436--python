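"""Seeded synthetic single-particle frames with ground truth.

Emulates the frames an imaging flow cytometer produces — one particle
centred on a clean background — so the segmentation, calibration and
evaluation stages can be exercised end-to-end without instrument data.
Two particle families are provided:

* circular beads at the certified calibration diameters
  (3, 4, 4.6, 5, 5.64, 7.32, 8, 10, 12 and 15 um, manufacturing spread
  CV < 2%), and
* oocyst-like particles: an elongated elliptical preset patterned on
  *Giardia* (mean height/width 11.87/7.92 um) and a near-spherical preset
  patterned on *Cryptosporidium* (mean diameter 5.03 um).

Rendering is supersampled (4x) so sub-pixel diameters are meaningful, then
optionally blurred (a stand-in for optics defocus) and corrupted with
additive Gaussian intensity noise.  The ground-truth mask is the exact
rasterised particle BEFORE blur and noise.  Everything is deterministic in
the seed: one master seed expands to per-frame seeds through a counter
scheme recorded in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "BEAD_DIAMETERS_UM",
    "OOCYST_PRESETS",
    "ParticleSpec",
    "OpticsSpec",
    "SyntheticFrame",
    "SyntheticSet",
    "render_frame",
    "generate_calibration_set",
    "generate_oocyst_set",
    "child_seed",
]

#: Certified calibration bead diameters (um).
BEAD_DIAMETERS_UM = (3.0, 4.0, 4.6, 5.0, 5.64, 7.32, 8.0, 10.0, 12.0, 15.0)

_SUPERSAMPLE = 4
_MARGIN_PX = 5.0


@dataclass(frozen=True)
class ParticleSpec:
    """Geometry of one particle: a circle or a rotated ellipse, sizes in um."""

    shape: str  # "circle" | "ellipse"
    major_um: float
    minor_um: float
    angle_deg: float = 0.0
    center_jitter_px: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "ellipse"):
            raise InvalidInputError(f"unknown shape {self.shape!r}")
        if not (self.major_um >= self.minor_um > 0):
            raise InvalidInputError("need major_um >= minor_um > 0")
        if self.shape == "circle" and self.major_um != self.minor_um:
            raise InvalidInputError("a circle needs major_um == minor_um")
        if self.center_jitter_px < 0:
            raise InvalidInputError("center_jitter_px must be >= 0")

    @classmethod
    def circle(cls, diameter_um: float, center_jitter_px: float = 2.0) -> "ParticleSpec":
        return cls("circle", diameter_um, diameter_um, 0.0, center_jitter_px)


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging conditions: pixel pitch, contrast, defocus blur and noise.

    Defaults emulate a bright-field frame at 60x magnification: bright
    background (0.9), dark particle (0.15), mild defocus (1 px blur) and
    2% additive intensity noise on a 256 px frame.
    """

    um_per_pixel: float = 0.33
    blur_sigma_px: float = 1.0
    background: float = 0.9
    foreground: float = 0.15
    noise_sigma: float = 0.02
    frame_side_px: int = 256

    def __post_init__(self) -> None:
        if self.um_per_pixel <= 0:
            raise InvalidInputError("um_per_pixel must be positive")
        if not (0 <= self.background <= 1 and 0 <= self.foreground <= 1):
            raise InvalidInputError("intensities must lie in [0, 1]")
        if self.noise_sigma < 0 or self.blur_sigma_px < 0:
            raise InvalidInputError("blur and noise sigmas must be >= 0")
        if self.frame_side_px < 16:
            raise InvalidInputError("frame side unreasonably small")


@dataclass(frozen=True)
class SyntheticFrame:
    """One rendered frame: noisy image, exact mask and the realised truth."""

    image: np.ndarray  # float in [0, 1], frame_side x frame_side
    mask: np.ndarray  # uint8 {0, 1}, exact pre-blur rasterisation
    truth: ParticleSpec
    center_px: tuple[float, float]  # (x, y)
    seed: int

    @property
    def image_u8(self) -> np.ndarray:
        return np.round(self.image * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class SyntheticSet:
    frames: tuple[SyntheticFrame, ...]
    manifest: pd.DataFrame


def child_seed(master_seed: int, *counters: int) -> int:
    """Derive an independent 31-bit stream seed from the master and counters."""
    state = np.random.SeedSequence([int(master_seed), *map(int, counters)])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


def _coverage(side: int, cx: float, cy: float, a_px: float, b_px: float,
              angle_deg: float) -> np.ndarray:
    """Supersampled area coverage of the ellipse per native pixel, in [0, 1]."""
    ss = _SUPERSAMPLE
    coords = (np.arange(side * ss) + 0.5) / ss - 0.5  # native pixel coords
    xs = coords[None, :] - cx
    ys = coords[:, None] - cy
    t = np.deg2rad(angle_deg)
    u = xs * np.cos(t) + ys * np.sin(t)
    v = -xs * np.sin(t) + ys * np.cos(t)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return inside.reshape(side, ss, side, ss).mean(axis=(1, 3))


def render_frame(spec: ParticleSpec, optics: OpticsSpec | None = None,
                 seed: int = 0) -> SyntheticFrame:
    """Render one frame deterministically from ``seed``.

    The particle centre receives uniform jitter of up to
    ``spec.center_jitter_px`` per axis; the exact mask is the >= 50% area
    coverage rasterisation before blur and noise are applied.
    """
    from scipy.ndimage import gaussian_filter

    optics = optics or OpticsSpec()
    side = optics.frame_side_px
    a_px = 0.5 * spec.major_um / optics.um_per_pixel
    b_px = 0.5 * spec.minor_um / optics.um_per_pixel
    if 2 * a_px + 2 * (_MARGIN_PX + spec.center_jitter_px) >= side:
        raise InvalidInputError(
            f"particle ({spec.major_um} um = {2 * a_px:.1f} px) does not fit a "
            f"{side} px frame with a {_MARGIN_PX} px margin")

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-spec.center_jitter_px, spec.center_jitter_px, size=2)
    cx = (side - 1) / 2.0 + jitter[0]
    cy = (side - 1) / 2.0 + jitter[1]

    alpha = _coverage(side, cx, cy, a_px, b_px, spec.angle_deg)
    mask = (alpha >= 0.5).astype(np.uint8)
    image = optics.background + (optics.foreground - optics.background) * alpha
    if optics.blur_sigma_px > 0:
        image = gaussian_filter(image, optics.blur_sigma_px, mode="reflect")
    if optics.noise_sigma > 0:
        image = image + rng.normal(0.0, optics.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticFrame(image=image, mask=mask, truth=spec,
                          center_px=(float(cx), float(cy)), seed=int(seed))


def _write_frames(frames: list[SyntheticFrame], names: list[str],
                  out_dir: Path) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame, name in zip(frames, names):
        path = out_dir / name
        iio.imwrite(path, frame.image_u8)
        iio.imwrite(out_dir / f"{path.stem}_mask.png",
                    (frame.mask * 255).astype(np.uint8))
        paths.append(str(path))
    return paths


def generate_calibration_set(
    sizes_um: tuple[float, ...] = BEAD_DIAMETERS_UM,
    n_per_size: int = 30,
    size_cv: float = 0.02,
    optics: OpticsSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticSet:
    """Seeded bead set: ``n_per_size`` circles per nominal diameter.

    Each bead's true diameter is drawn as ``nominal * (1 + N(0, size_cv))``,
    mirroring the manufacturing spread of certified beads.  The manifest
    records, per frame: path (when written), shape, group label, nominal and
    realised diameters and the per-frame seed.
    """
    if n_per_size < 1:
        raise InvalidInputError("n_per_size must be >= 1")
    if any(s <= 0 for s in sizes_um):
        raise InvalidInputError("bead sizes must be positive")
    optics = optics or OpticsSpec()

    frames: list[SyntheticFrame] = []
    names: list[str] = []
    rows: list[dict] = []
    idx = 0
    for nominal in sizes_um:
        for k in range(n_per_size):
            frame_seed = child_seed(seed, idx, 0)
            size_rng = np.random.default_rng(child_seed(seed, idx, 1))
            true = float(nominal * (1.0 + size_rng.normal(0.0, size_cv))) if size_cv > 0 \
                else float(nominal)
            true = max(true, 1e-3)
            frame = render_frame(ParticleSpec.circle(true), optics, frame_seed)
            name = f"bead_{nominal:g}um_{k:03d}.png"
            frames.append(frame)
            names.append(name)
            rows.append({"path": name, "shape": "circle", "group": f"{nominal:g} um",
                         "nominal_um": nominal, "true_major_um": true,
                         "true_minor_um": true, "seed": frame_seed})
            idx += 1

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest["path"] = _write_frames(frames, names, Path(out_dir))
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return SyntheticSet(frames=tuple(frames), manifest=manifest)


#: Oocyst-like presets: (shape, mean major, SD major, mean minor, SD minor).
OOCYST_PRESETS = {
    "giardia": ("ellipse", 11.87, 1.99, 7.92, 0.75),
    "cryptosporidium": ("circle", 5.03, 0.48, 5.03, 0.48),
}


def generate_oocyst_set(
    preset: str,
    n: int,
    seed: int = 0,
    optics: OpticsSpec | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticSet:
    """Seeded oocyst-like set drawn from a species preset.

    *Giardia*-like frames are ellipses with normally distributed axes (major
    11.87 +/- 1.99 um, minor 7.92 +/- 0.75 um, axes swapped if a draw inverts
    their order) at uniform orientation; *Cryptosporidium*-like frames are
    circles with diameter 5.03 +/- 0.48 um.
    """
    if preset not in OOCYST_PRESETS:
        raise InvalidInputError(
            f"unknown preset {preset!r}; choose from {sorted(OOCYST_PRESETS)}")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    optics = optics or OpticsSpec()
    shape, mu_a, sd_a, mu_b, sd_b = OOCYST_PRESETS[preset]

    frames: list[SyntheticFrame] = []
    names: list[str] = []
    rows: list[dict] = []
    for k in range(n):
        frame_seed = child_seed(seed, k, 0)
        size_rng = np.random.default_rng(child_seed(seed, k, 1))
        if shape == "circle":
            d = float(max(size_rng.normal(mu_a, sd_a), 0.5))
            spec = ParticleSpec.circle(d)
        else:
            major = float(max(size_rng.normal(mu_a, sd_a), 0.5))
            minor = float(max(size_rng.normal(mu_b, sd_b), 0.5))
            if minor > major:
                major, minor = minor, major
            angle = float(size_rng.uniform(0.0, 180.0))
            spec = ParticleSpec("ellipse", major, minor, angle)
        frame = render_frame(spec, optics, frame_seed)
        name = f"{preset}_{k:03d}.png"
        frames.append(frame)
        names.append(name)
        rows.append({"path": name, "shape": spec.shape, "group": preset,
                     "nominal_um": mu_a, "true_major_um": spec.major_um,
                     "true_minor_um": spec.minor_um, "seed": frame_seed})

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest["path"] = _write_frames(frames, names, Path(out_dir))
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return SyntheticSet(frames=tuple(frames), manifest=manifest)
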