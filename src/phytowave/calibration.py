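"""Log-linear biosensor calibration.

Fibre organic electrochemical transistors (fOECTs) respond to their analyte
(K⁺-type cations or H₂O₂) with a source–drain current change that is linear
in log₁₀ of the analyte concentration over the working range.  This module
fits that line, evaluates and inverts it, and computes the S/N = 3 limit of
detection by extrapolating the fitted line down to the concentration whose
predicted response equals ``snr`` times the baseline noise.

The response variable is whatever column the caller supplies — absolute
current change (μA, mA) or percentage change — and the fitted curve carries
a units label so downstream consumers can tell which they got.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DomainError,
    ExtrapolationWarning,
    NonInvertibleError,
)

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "fit_calibration",
    "predict_response",
    "invert_response",
    "detection_limit",
    "read_calibration_table",
    "write_calibration_table",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One (concentration, response) pair.  Concentration must be > 0."""

    concentration: float
    response: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise DomainError(
                f"concentration must be finite and > 0, got {self.concentration}"
            )
        if not np.isfinite(self.response):
            raise DomainError(f"response must be finite, got {self.response}")


@dataclass
class CalibrationCurve:
    """A fitted log-linear calibration: ``response = intercept +
    sensitivity * log10(concentration / reference_concentration)``.

    Attributes
    ----------
    sensitivity:
        Response change per decade of concentration (units/dec).  The sign
        follows the device chemistry: cation-responsive channels dedope and
        the current falls, H₂O₂ gates oxidise and the current rises.
    intercept:
        Response at ``reference_concentration``.
    reference_concentration:
        Concentration at which the intercept applies; by convention the
        lowest concentration in the fitted table.
    response_units:
        Free-form label (e.g. ``"uA"``, ``"mA"``, ``"percent"``).
    valid_range:
        (min, max) concentration span of the fit; evaluation outside it
        warns but proceeds (extrapolation is legitimate — the printed
        detection limit is itself extrapolated).
    """

    sensitivity: float
    intercept: float
    reference_concentration: float
    response_units: str = ""
    valid_range: tuple[float, float] = field(default=(0.0, np.inf))

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not (lo < hi):
            raise DomainError(f"valid_range must satisfy min < max, got {self.valid_range}")
        if self.reference_concentration <= 0:
            raise DomainError("reference_concentration must be > 0")

    @property
    def invertible(self) -> bool:
        """Whether the curve can map a response back to a concentration."""
        return np.isfinite(self.sensitivity) and self.sensitivity != 0.0

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "intercept": self.intercept,
            "reference_concentration": self.reference_concentration,
            "response_units": self.response_units,
            "valid_range": list(self.valid_range),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            sensitivity=float(d["sensitivity"]),
            intercept=float(d["intercept"]),
            reference_concentration=float(d["reference_concentration"]),
            response_units=str(d.get("response_units", "")),
            valid_range=tuple(d.get("valid_range", (0.0, np.inf))),  # type: ignore[arg-type]
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_calibration(
    points: Iterable[CalibrationPoint] | Sequence[tuple[float, float]],
    response_units: str = "",
) -> CalibrationCurve:
    """Least-squares fit of response versus log₁₀(concentration).

    The reference concentration is the lowest measured concentration and the
    intercept is the fitted response there, so the curve reads directly as
    "response relative to the bottom of the working range".

    Raises
    ------
    DegenerateInputError
        Fewer than two distinct concentrations.
    DomainError
        Any nonpositive concentration (raised by ``CalibrationPoint``).
    """
    pts = [
        p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points
    ]
    conc = np.array([p.concentration for p in pts], dtype=float)
    resp = np.array([p.response for p in pts], dtype=float)
    if np.unique(conc).size < 2:
        raise DegenerateInputError(
            "need at least 2 distinct concentrations to fit a line, "
            f"got {np.unique(conc).size}"
        )
    ref = float(conc.min())
    x = np.log10(conc / ref)
    # closed-form OLS; polyfit degree 1 == slope/intercept least squares
    slope, intercept = np.polyfit(x, resp, 1)
    # snap numerically-flat fits to an exactly-zero slope so the
    # non-invertible flag is deterministic
    scale = max(1.0, float(np.max(np.abs(resp))))
    if abs(slope) < 1e-12 * scale:
        slope = 0.0
    curve = CalibrationCurve(
        sensitivity=float(slope),
        intercept=float(intercept),
        reference_concentration=ref,
        response_units=response_units,
        valid_range=(float(conc.min()), float(conc.max())),
    )
    if curve.sensitivity == 0.0:
        warnings.warn(
            "fitted sensitivity is exactly 0 (flat responses); "
            "the curve is not invertible",
            UserWarning,
            stacklevel=2,
        )
    return curve


def _check_concentration(concentration: float) -> None:
    if not np.all(np.isfinite(concentration)) or np.any(np.asarray(concentration) <= 0):
        raise DomainError(f"concentration must be finite and > 0, got {concentration}")


def predict_response(curve: CalibrationCurve, concentration) -> float | np.ndarray:
    """Evaluate the fitted line at ``concentration`` (scalar or array).

    Warns with :class:`ExtrapolationWarning` outside ``curve.valid_range``.
    """
    _check_concentration(concentration)
    c = np.asarray(concentration, dtype=float)
    lo, hi = curve.valid_range
    if np.any(c < lo) or np.any(c > hi):
        warnings.warn(
            f"evaluating calibration outside fitted range [{lo:g}, {hi:g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = curve.intercept + curve.sensitivity * np.log10(c / curve.reference_concentration)
    return float(out) if np.isscalar(concentration) else out


def invert_response(curve: CalibrationCurve, response) -> float | np.ndarray:
    """Map a response back to concentration: the inverse of
    :func:`predict_response`.

    Raises :class:`NonInvertibleError` when ``sensitivity == 0``.  Warns
    with :class:`ExtrapolationWarning` when the recovered concentration
    falls outside the fitted range.
    """
    if not curve.invertible:
        raise NonInvertibleError("cannot invert a curve with zero sensitivity")
    r = np.asarray(response, dtype=float)
    c = 10.0 ** ((r - curve.intercept) / curve.sensitivity) * curve.reference_concentration
    lo, hi = curve.valid_range
    if np.any(c < lo) or np.any(c > hi):
        warnings.warn(
            f"inverted concentration outside fitted range [{lo:g}, {hi:g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(c) if np.isscalar(response) else c


def detection_limit(
    curve: CalibrationCurve,
    noise_sd: float,
    snr: float = 3.0,
    blank_response: float = 0.0,
) -> float:
    """Concentration at which the predicted response above the blank level
    equals ``snr * noise_sd`` — the extrapolated S/N-limited detection
    limit.

    ``blank_response`` is the response of the sensor in blank solution.
    For percentage-change responses the blank reads zero by construction,
    which is the default; pass ``curve.intercept`` to reference the limit
    to the fitted response at the lowest measured concentration instead.

    Raises
    ------
    DomainError
        ``noise_sd <= 0`` (a noiseless device has no finite S/N-limited
        concentration on a log-linear curve) or ``snr <= 0``.
    NonInvertibleError
        Zero-sensitivity curve.
    """
    if noise_sd <= 0 or not np.isfinite(noise_sd):
        raise DomainError(f"noise_sd must be > 0, got {noise_sd}")
    if snr <= 0:
        raise DomainError(f"snr must be > 0, got {snr}")
    if not curve.invertible:
        raise NonInvertibleError("cannot compute a detection limit with zero sensitivity")
    # Signed target: the detectable excursion has the sign of the sensitivity.
    target = blank_response + np.sign(curve.sensitivity) * snr * noise_sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        return float(invert_response(curve, target))


def read_calibration_table(path: str | Path) -> list[CalibrationPoint]:
    """Read a ``concentration,response`` CSV into calibration points."""
    df = pd.read_csv(path)
    missing = {"concentration", "response"} - set(df.columns)
    if missing:
        raise DomainError(f"calibration table missing column(s): {sorted(missing)}")
    return [
        CalibrationPoint(float(c), float(r))
        for c, r in zip(df["concentration"], df["response"])
    ]


def write_calibration_table(points: Iterable[CalibrationPoint], path: str | Path) -> None:
    pts = list(points)
    pd.DataFrame(
        {
            "concentration": [p.concentration for p in pts],
            "response": [p.response for p in pts],
        }
    ).to_csv(path, index=False)
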