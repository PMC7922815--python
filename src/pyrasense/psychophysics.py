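"""Geometric dilution series and group odor-threshold estimation.

Odor thresholds are measured by an ascending method: panelists run 3-AFC
tests at each step of a geometric dose ladder (factor 2 between steps, so
the steps are equally spaced on the log scale), and the group threshold is
the dose at which a criterion fraction of panelists — 50% by default —
picks the spiked sample correctly.

The estimator first makes the per-dose proportions monotone with the
pool-adjacent-violators algorithm (weights = panelists per dose), then
interpolates linearly on log-dose between the two steps bracketing the
criterion.  The criterion can be applied to raw proportion-correct (the
literal reading of "chosen by 50% of the panelists") or to chance-corrected
detection probability; because the 3-AFC guessing floor (1/3) is not far
below 0.5 the two readings differ materially, so the scale used is recorded
in every estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression, minimize
from scipy.special import expit

from ._util import CHANCE_3AFC, round_half_up
from .errors import DataError, DesignError, FitError, NoCrossingError

RAW_SCALE = "raw_correct"
DETECTION_SCALE = "chance_corrected"


@dataclass(frozen=True)
class DoseSeries:
    """Ascending dose ladder; ``factor`` is the step ratio (None if irregular)."""

    doses: tuple[float, ...]
    factor: float | None = None
    units: str = "mL"

    def __post_init__(self) -> None:
        arr = np.asarray(self.doses, float)
        if arr.size < 2:
            raise DesignError("a dose series needs >= 2 steps")
        if (arr <= 0).any():
            raise DataError("all doses must be > 0")
        if (np.diff(arr) <= 0).any():
            raise DataError("doses must be strictly increasing")

    def rounded(self, ndigits: int = 3) -> tuple[float, ...]:
        """Doses as reported, at 3-decimal rounding by default."""
        return tuple(round_half_up(d, ndigits) for d in self.doses)


def make_geometric_series(
    base: float, factor: float, n_steps: int, units: str = "mL"
) -> DoseSeries:
    """doses[i] = base · factorⁱ for i = 0..n_steps−1."""
    if base <= 0:
        raise DesignError("base dose must be > 0")
    if factor <= 1:
        raise DesignError("dilution factor must be > 1")
    if n_steps < 2:
        raise DesignError("need >= 2 steps")
    return DoseSeries(
        doses=tuple(base * factor**i for i in range(n_steps)), factor=factor, units=units
    )


@dataclass(frozen=True)
class DetectionCurve:
    """Per-dose 3-AFC counts with derived proportions.

    ``p_detect`` is Abbott-corrected proportion-correct (clipped at 0).
    """

    doses: tuple[float, ...]
    n: tuple[int, ...]
    k: tuple[int, ...]
    chance: float = CHANCE_3AFC

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.n) == len(self.k)):
            raise DataError("doses, n and k must have equal length")
        if any(not 0 <= ki <= ni for ki, ni in zip(self.k, self.n)):
            raise DataError("need 0 <= k <= n at every dose")
        arr = np.asarray(self.doses, float)
        if arr.size == 0 or (arr <= 0).any() or (np.diff(arr) <= 0).any():
            # a single dose is allowed: fixed-composition bundles are
            # replicate trials at one condition, not a ladder
            raise DataError("doses must be positive and strictly increasing")

    @property
    def p_correct(self) -> np.ndarray:
        return np.asarray(self.k, float) / np.asarray(self.n, float)

    @property
    def p_detect(self) -> np.ndarray:
        return np.clip((self.p_correct - self.chance) / (1.0 - self.chance), 0.0, 1.0)

    def proportions(self, scale: str) -> np.ndarray:
        if scale == RAW_SCALE:
            return self.p_correct
        if scale == DETECTION_SCALE:
            return self.p_detect
        raise DataError(f"unknown scale {scale!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.doses,
                "n": self.n,
                "k": self.k,
                "p_correct": self.p_correct,
                "p_detect": self.p_detect,
            }
        )


def read_dose_response_table(path, chance: float = CHANCE_3AFC) -> DetectionCurve:
    """Delimited per-dose table with columns dose, n, k."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"dose", "n", "k"} - set(df.columns)
    if missing:
        raise DataError(f"dose-response table missing columns: {sorted(missing)}")
    df = df.sort_values("dose")
    return DetectionCurve(
        doses=tuple(df["dose"].astype(float)),
        n=tuple(df["n"].astype(int)),
        k=tuple(df["k"].astype(int)),
        chance=chance,
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    value: float
    criterion: float
    scale: str
    method: str
    bracket: tuple[float, float]
    censored: str | None = None  # "left" => threshold <= lowest dose

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "criterion": self.criterion,
            "scale": self.scale,
            "method": self.method,
            "bracket": list(self.bracket),
            "censored": self.censored,
        }


def pava_smooth(proportions: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted increasing isotonic regression (pool adjacent violators)."""
    return np.asarray(
        isotonic_regression(np.asarray(proportions, float), weights=np.asarray(weights, float)).x
    )


def estimate_threshold(
    curve: DetectionCurve, criterion: float = 0.5, scale: str = RAW_SCALE
) -> ThresholdEstimate:
    """Group threshold: first dose level at which the smoothed curve reaches
    the criterion, with log-linear interpolation between bracketing doses.

    Raises :class:`NoCrossingError` when even the highest dose falls short;
    returns a left-censored estimate at the lowest dose when the whole curve
    is already at/above the criterion.
    """
    if not 0 < criterion < 1:
        raise DataError("criterion must lie in (0, 1)")
    doses = np.asarray(curve.doses, float)
    props = pava_smooth(curve.proportions(scale), np.asarray(curve.n, float))

    if props.max() < criterion:
        raise NoCrossingError(
            f"curve never reaches criterion {criterion} on scale {scale} "
            f"(max smoothed proportion {props.max():.3f})",
            max_proportion=float(props.max()),
        )
    hits = np.nonzero(np.isclose(props, criterion, atol=1e-12))[0]
    if hits.size:
        d = float(doses[hits[0]])
        return ThresholdEstimate(d, criterion, scale, "log-linear interpolation", (d, d))
    if props[0] > criterion:
        d = float(doses[0])
        return ThresholdEstimate(
            d, criterion, scale, "log-linear interpolation", (d, d), censored="left"
        )
    j = int(np.argmax(props > criterion))  # first dose strictly above
    i = j - 1  # props[i] < criterion by construction
    lo, hi = math.log10(doses[i]), math.log10(doses[j])
    frac = (criterion - props[i]) / (props[j] - props[i])
    value = 10 ** (lo + frac * (hi - lo))
    return ThresholdEstimate(
        float(value),
        criterion,
        scale,
        "log-linear interpolation",
        (float(doses[i]), float(doses[j])),
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood psychometric fit (alternative estimator)


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic-in-log₁₀-dose fit with guessing floor and zero lapse."""

    midpoint: float  # log10-dose at which p_detect = 0.5
    slope: float  # per log10-dose unit
    threshold: float  # 10**midpoint, the dose where p_correct = (1+chance)/2
    loglik: float


#: Bounds on the logistic steepness; hitting them signals separation.
_SLOPE_BOUNDS = (0.1, 100.0)


def fit_psychometric(curve: DetectionCurve) -> PsychometricFit:
    """MLE of p_correct(x) = chance + (1−chance)·logistic(slope·(x − midpoint)).

    Raises :class:`FitError` for non-identifiable data: all-correct or
    all-wrong responses, chance-level responding at every dose (midpoint
    drifts outside the dose range), or perfect separation (slope at bound).
    """
    k = np.asarray(curve.k, float)
    n = np.asarray(curve.n, float)
    if len(k) < 3:
        raise DataError("psychometric fit needs >= 3 doses")
    if k.sum() == 0 or (n - k).sum() == 0:
        raise FitError("all-wrong or all-correct responses: curve location unidentifiable")
    x = np.log10(np.asarray(curve.doses, float))
    c = curve.chance

    def nll(params):
        mid, log_slope = params
        p = c + (1.0 - c) * expit(np.exp(log_slope) * (x - mid))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()

    starts = [(float(np.median(x)), math.log(4.87)), (x[0], 0.0), (x[-1], 0.0)]
    best = None
    for s in starts:
        res = minimize(nll, s, method="Nelder-Mead", options={"xatol": 1e-7, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    mid, slope = float(best.x[0]), float(math.exp(best.x[1]))
    span = x[-1] - x[0]
    if not (x[0] - span <= mid <= x[-1] + span):
        raise FitError("midpoint outside plausible range: responses carry no dose signal")
    if not _SLOPE_BOUNDS[0] < slope < _SLOPE_BOUNDS[1]:
        raise FitError("slope at boundary: data are separated or flat")
    return PsychometricFit(
        midpoint=mid, slope=slope, threshold=10.0**mid, loglik=-float(best.fun)
    )


def stock_volume_to_concentration(
    volume_ml: float, stock_ug_per_l: float, matrix_ml: float = 15.0
) -> float:
    """Convert a threshold in stock volume to an in-glass concentration.

    Assumes additive volumes: c = stock · v / (v + matrix).  Thresholds are
    otherwise kept in the volume units in which they were measured.
    """
    if volume_ml <= 0 or stock_ug_per_l <= 0 or matrix_ml <= 0:
        raise DataError("volume, stock concentration and matrix volume must be > 0")
    return stock_ug_per_l * volume_ml / (volume_ml + matrix_ml)
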