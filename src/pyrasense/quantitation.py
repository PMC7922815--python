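"""QC computations for targeted MRM quantitation of pyrazines.

Pyrazine concentrations in Baijiu are measured by stable internal-standard
calibration: the response ratio (analyte peak area / internal-standard peak
area) is regressed on known standard concentrations, and unknowns are read
off the inverse of that line.  This module covers the surrounding QC
arithmetic — calibration fitting and linearity gating, inverse prediction,
spike recovery, replicate RSD and S/N-based LOD/LOQ — without touching raw
chromatograms (peak integration is out of scope; baseline noise enters as a
measured standard deviation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateModelError, DesignError, InsufficientDataError

#: Calibration curves below this coefficient of determination fail linearity QC.
R_SQUARED_GATE = 0.99

#: Signal-to-noise multiples defining the detection and quantification limits.
LOD_SNR = 3.0
LOQ_SNR = 10.0


@dataclass(frozen=True)
class CalibrationLevel:
    """One standard level: known concentration and raw instrument responses."""

    concentration: float  # μg·L⁻¹
    analyte_response: float  # arbitrary area units
    internal_standard_response: float  # arbitrary area units

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DataError("known concentration must be >= 0")
        if self.analyte_response < 0:
            raise DataError("analyte response must be >= 0")
        if self.internal_standard_response <= 0:
            raise DataError("internal-standard response must be > 0")

    @property
    def response_ratio(self) -> float:
        return self.analyte_response / self.internal_standard_response


@dataclass(frozen=True)
class CalibrationSeries:
    """Standard series for one compound (>= 2 distinct concentrations)."""

    compound: str
    levels: tuple[CalibrationLevel, ...]

    def __post_init__(self) -> None:
        if len({lv.concentration for lv in self.levels}) < 2:
            raise DesignError(
                f"{self.compound}: calibration needs >= 2 distinct concentration levels"
            )

    @classmethod
    def from_arrays(
        cls,
        compound: str,
        concentrations: Sequence[float],
        analyte_responses: Sequence[float],
        internal_standard_responses: Sequence[float] | float = 1.0,
    ) -> "CalibrationSeries":
        if np.isscalar(internal_standard_responses):
            internal_standard_responses = [float(internal_standard_responses)] * len(
                concentrations
            )
        levels = tuple(
            CalibrationLevel(float(c), float(a), float(i))
            for c, a, i in zip(
                concentrations, analyte_responses, internal_standard_responses, strict=True
            )
        )
        return cls(compound=compound, levels=levels)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted line ratio = slope·c + intercept, with linearity and limit QC."""

    compound: str
    slope: float  # response-ratio per μg·L⁻¹
    intercept: float  # response-ratio
    r_squared: float
    linear: bool  # r_squared >= R_SQUARED_GATE
    slope_stderr: float = float("nan")
    lod: float = float("nan")  # μg·L⁻¹
    loq: float = float("nan")  # μg·L⁻¹
    weighting: str = "none"

    def with_limits(self, noise_sd: float) -> "CalibrationModel":
        """Return a copy with LOD/LOQ filled in from a baseline noise sd."""
        lod, loq = estimate_lod_loq(noise_sd, self.slope)
        return CalibrationModel(
            compound=self.compound,
            slope=self.slope,
            intercept=self.intercept,
            r_squared=self.r_squared,
            linear=self.linear,
            slope_stderr=self.slope_stderr,
            lod=lod,
            loq=loq,
            weighting=self.weighting,
        )


class QuantPrediction(NamedTuple):
    """Inverse-predicted concentration; below_zero marks physically impossible values."""

    concentration: float
    below_zero: bool

    @property
    def reported(self) -> float:
        """Value for summary tables: negative predictions report as 0."""
        return 0.0 if self.below_zero else self.concentration


@dataclass(frozen=True)
class QuantResult:
    sample: str
    compound: str
    concentration: float  # μg·L⁻¹
    rsd_percent: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DataError("concentration must be >= 0")
        if self.rsd_percent < 0:
            raise DataError("RSD must be >= 0")


def fit_calibration(series: CalibrationSeries, weighting: str = "none") -> CalibrationModel:
    """Fit the calibration line by least squares on the response ratio.

    Unweighted OLS by default; ``weighting="1/x"`` down-weights high
    standards by 1/concentration (zero-concentration levels get the weight of
    the lowest nonzero standard).  R² is always the unweighted coefficient of
    determination, which is what the linearity gate refers to.
    """
    conc = np.array([lv.concentration for lv in series.levels], dtype=float)
    ratio = np.array([lv.response_ratio for lv in series.levels], dtype=float)

    if weighting == "none":
        res = stats.linregress(conc, ratio)
        slope, intercept, stderr = res.slope, res.intercept, res.stderr
    elif weighting == "1/x":
        w = np.where(conc > 0, conc, conc[conc > 0].min())
        w = 1.0 / w
        sw = w.sum()
        xbar = (w * conc).sum() / sw
        ybar = (w * ratio).sum() / sw
        sxx = (w * (conc - xbar) ** 2).sum()
        slope = (w * (conc - xbar) * (ratio - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        stderr = float("nan")
    else:
        raise DesignError(f"unknown weighting {weighting!r}")

    fitted = slope * conc + intercept
    ss_res = float(((ratio - fitted) ** 2).sum())
    ss_tot = float(((ratio - ratio.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    # two exactly-fitted points leave ss_res at rounding-noise level
    if len(conc) == 2:
        r_squared = 1.0
    return CalibrationModel(
        compound=series.compound,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(1.0, r_squared),
        linear=r_squared >= R_SQUARED_GATE,
        slope_stderr=float(stderr) if stderr is not None else float("nan"),
        weighting=weighting,
    )


def quantify(model: CalibrationModel, response_ratio: float) -> QuantPrediction:
    """Inverse prediction: c = (ratio − intercept)/slope.

    Negative predictions are flagged, not silently clamped; summary layers use
    :attr:`QuantPrediction.reported` (0 for flagged values) while the raw value
    stays available for QC.
    """
    if model.slope == 0:
        raise DegenerateModelError(f"{model.compound}: zero calibration slope")
    conc = (response_ratio - model.intercept) / model.slope
    return QuantPrediction(concentration=float(conc), below_zero=conc < 0)


def compute_recovery(measured_spiked: float, measured_unspiked: float, added: float) -> float:
    """Spike recovery in %: (spiked − unspiked)/added × 100. May exceed 100."""
    if added <= 0:
        raise DesignError("added concentration must be > 0")
    return (measured_spiked - measured_unspiked) / added * 100.0


def compute_rsd(replicates: Sequence[float]) -> float:
    """Relative standard deviation in %: 100·sd/mean (sample sd, ddof=1)."""
    values = np.asarray(replicates, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("RSD needs >= 2 replicates")
    mean = values.mean()
    if mean == 0:
        raise DataError("RSD undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def estimate_lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Concentrations whose expected signal reaches 3× and 10× baseline noise."""
    if slope <= 0:
        raise DesignError("calibration slope must be > 0 for LOD/LOQ")
    if noise_sd < 0:
        raise DataError("noise sd must be >= 0")
    return LOD_SNR * noise_sd / slope, LOQ_SNR * noise_sd / slope


# ---------------------------------------------------------------------------
# Table-level interface


def read_calibration_table(path) -> list[CalibrationSeries]:
    """Read a delimited calibration table.

    Expected columns: compound, concentration, analyte_response and
    (optionally) internal_standard_response (defaults to 1, i.e. the ratio is
    already formed).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound", "concentration", "analyte_response"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"calibration table missing columns: {sorted(missing)}")
    if "internal_standard_response" not in df.columns:
        df = df.assign(internal_standard_response=1.0)
    out = []
    for compound, grp in df.groupby("compound", sort=False):
        out.append(
            CalibrationSeries.from_arrays(
                str(compound),
                grp["concentration"].to_numpy(),
                grp["analyte_response"].to_numpy(),
                grp["internal_standard_response"].to_numpy(),
            )
        )
    return out


def qc_report(
    models: Sequence[CalibrationModel],
    rsds: dict[str, float] | None = None,
    recoveries: dict[str, float] | None = None,
) -> dict:
    """Assemble a machine-readable QC report over fitted calibrations."""
    rows = []
    for m in models:
        rows.append(
            {
                "compound": m.compound,
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "linear": bool(m.linear),
                "lod": None if math.isnan(m.lod) else m.lod,
                "loq": None if math.isnan(m.loq) else m.loq,
                "rsd_percent": (rsds or {}).get(m.compound),
                "recovery_percent": (recoveries or {}).get(m.compound),
            }
        )
    return {
        "r_squared_gate": R_SQUARED_GATE,
        "n_compounds": len(rows),
        "n_linear": sum(r["linear"] for r in rows),
        "compounds": rows,
    }


def write_qc_report(report: dict, json_path, tsv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if tsv_path is not None:
        pd.DataFrame(report["compounds"]).to_csv(tsv_path, sep="\t", index=False)
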