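"""Pixel-to-micrometre conversion models.

The sizing pipeline replaces the fixed optics ratio (e.g. 0.33 um/pixel at
60x magnification) with a polynomial converter learned from beads of
certified diameter.  Both a linear model ``y = m*x + b`` and a quadratic
model ``y = a*x^2 + b*x + c`` are fitted by least squares on
(pixel diameter, physical diameter) pairs; the one with smaller in-sample
RMSE wins, ties going to the quadratic.

The quadratic fit is solved through the explicit normal equations built from
the raw moments

    s_k = sum_i x_i^k,   z = sum_i y_i,   g_j = sum_i y_i x_i^j,

i.e. the 3x3 system  [[n, s1, s2], [s1, s2, s3], [s2, s3, s4]] (c, b, a)^T
= (z, g1, g2)^T.  Raw Vandermonde moments become ill-conditioned for large
pixel values, so the solver warns when the condition number exceeds 1e8; a
QR-based fit is cross-checked in the test-suite, not used here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateDesignError, InvalidInputError, ModelParseError

__all__ = [
    "CalibrationSample",
    "SizeModel",
    "FixedRatio",
    "fit_linear",
    "fit_quadratic",
    "select_model",
    "convert",
    "fixed_ratio_convert",
    "save_model",
    "load_model",
]

_COND_WARN = 1e8


@dataclass(frozen=True)
class CalibrationSample:
    """One bead: measured size in pixels (x) and certified size in um (y)."""

    x: float
    y: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.x > 0 and self.y > 0):
            raise InvalidInputError(f"calibration sample must be positive, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class SizeModel:
    """A fitted pixel->um converter.

    ``coefficients`` are ``(m, b)`` for the linear kind and ``(a, b, c)``
    (descending powers) for the quadratic kind.  ``rmse`` is the in-sample
    training RMSE in um over the ``n`` fitted samples.
    """

    kind: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]
    rmse: float
    n: int

    def __post_init__(self) -> None:
        expected = {"linear": 2, "quadratic": 3}
        if self.kind not in expected:
            raise InvalidInputError(f"unknown model kind {self.kind!r}")
        if len(self.coefficients) != expected[self.kind]:
            raise InvalidInputError(
                f"{self.kind} model needs {expected[self.kind]} coefficients, "
                f"got {len(self.coefficients)}")
        if self.rmse < 0:
            raise InvalidInputError("rmse must be >= 0")

    def predict(self, pixels: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the polynomial (no positivity clamp; see :func:`convert`)."""
        x = np.asarray(pixels, dtype=float)
        if self.kind == "linear":
            m, b = self.coefficients
            out = m * x + b
        else:
            a, b, c = self.coefficients
            out = a * x**2 + b * x + c
        return float(out) if np.isscalar(pixels) else out


@dataclass(frozen=True)
class FixedRatio:
    """Optics-derived scalar conversion, um per pixel (0.33 at 60x)."""

    ratio: float = 0.33

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise InvalidInputError("ratio must be positive")


def _xy(samples: Sequence[CalibrationSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([s.x for s in samples], dtype=float)
    y = np.array([s.y for s in samples], dtype=float)
    return x, y


def _training_rmse(x: np.ndarray, y: np.ndarray, model: "SizeModel") -> float:
    resid = y - model.predict(x)
    return float(np.sqrt(np.mean(resid**2)))


def _solve_normal(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond):
        raise DegenerateDesignError("singular normal-equation matrix")
    if cond > _COND_WARN:
        warnings.warn(f"normal equations ill-conditioned (cond={cond:.3g}); "
                      "consider rescaling pixel values", stacklevel=3)
    try:
        return np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cond check usually fires first
        raise DegenerateDesignError("singular normal-equation matrix") from exc


def fit_linear(samples: Sequence[CalibrationSample]) -> SizeModel:
    """Ordinary least squares for y = m*x + b via the 2x2 normal equations."""
    if len(samples) < 2:
        raise DegenerateDesignError("linear fit needs at least 2 samples")
    x, y = _xy(samples)
    if len(np.unique(x)) < 2:
        raise DegenerateDesignError("linear fit needs at least 2 distinct pixel values")
    n = float(len(x))
    s1, s2 = x.sum(), (x**2).sum()
    mat = np.array([[n, s1], [s1, s2]])
    rhs = np.array([y.sum(), (y * x).sum()])
    b, m = _solve_normal(mat, rhs)
    model = SizeModel("linear", (float(m), float(b)), 0.0, len(samples))
    return SizeModel("linear", model.coefficients, _training_rmse(x, y, model), len(samples))


def fit_quadratic(samples: Sequence[CalibrationSample]) -> SizeModel:
    """Least squares for y = a*x^2 + b*x + c via the 3x3 moment system."""
    if len(samples) < 3:
        raise DegenerateDesignError("quadratic fit needs at least 3 samples")
    x, y = _xy(samples)
    if len(np.unique(x)) < 3:
        raise DegenerateDesignError("quadratic fit needs at least 3 distinct pixel values")
    n = float(len(x))
    s = [n] + [(x**k).sum() for k in (1, 2, 3, 4)]
    mat = np.array([[s[0], s[1], s[2]],
                    [s[1], s[2], s[3]],
                    [s[2], s[3], s[4]]])
    rhs = np.array([y.sum(), (y * x).sum(), (y * x**2).sum()])
    c, b, a = _solve_normal(mat, rhs)
    model = SizeModel("quadratic", (float(a), float(b), float(c)), 0.0, len(samples))
    return SizeModel("quadratic", model.coefficients, _training_rmse(x, y, model), len(samples))


def select_model(linear: SizeModel, quadratic: SizeModel) -> SizeModel:
    """Pick the model with smaller training RMSE; ties go to the quadratic."""
    return linear if linear.rmse < quadratic.rmse else quadratic


def convert(model: SizeModel, pixels: float | np.ndarray) -> float | np.ndarray:
    """Convert a pixel measurement to micrometres through the fitted model.

    Negative predictions (possible when extrapolating below the calibration
    range) are clamped to zero with a warning.
    """
    x = np.asarray(pixels, dtype=float)
    if np.any(x <= 0):
        raise InvalidInputError("pixel measurement must be positive")
    out = np.asarray(model.predict(x), dtype=float)
    if np.any(out < 0):
        warnings.warn("model predicted a negative size; clamping to 0 um", stacklevel=2)
        out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(pixels) else out


def fixed_ratio_convert(ratio: FixedRatio, pixels: float | np.ndarray) -> float | np.ndarray:
    """Baseline conversion: micrometres = ratio * pixels."""
    x = np.asarray(pixels, dtype=float)
    if np.any(x <= 0):
        raise InvalidInputError("pixel measurement must be positive")
    out = ratio.ratio * x
    return float(out) if np.isscalar(pixels) else out


def save_model(model: SizeModel, path: str | Path) -> None:
    """Persist a model as JSON: {kind, coefficients, rmse, n}."""
    payload = {"kind": model.kind, "coefficients": list(model.coefficients),
               "rmse": model.rmse, "n": model.n}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> SizeModel:
    """Load a JSON model file; malformed content raises :class:`ModelParseError`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"not valid JSON: {path}") from exc
    if not isinstance(payload, dict):
        raise ModelParseError(f"model file must hold a JSON object: {path}")
    missing = {"kind", "coefficients", "rmse", "n"} - payload.keys()
    if missing:
        raise ModelParseError(f"model file missing keys {sorted(missing)}: {path}")
    try:
        return SizeModel(kind=payload["kind"],
                         coefficients=tuple(float(v) for v in payload["coefficients"]),
                         rmse=float(payload["rmse"]), n=int(payload["n"]))
    except (TypeError, ValueError, InvalidInputError) as exc:
        raise ModelParseError(f"model file malformed: {path} ({exc})") from exc
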