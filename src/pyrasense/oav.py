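"""Odor-activity-value (OAV) profiling.

OAV = concentration / odor threshold.  A compound with OAV >= 1 in a sample
is present above its detection threshold and is a candidate contributor to
the sample's aroma; 0.1 <= OAV < 1 marks the sub-threshold band whose
perceptual relevance the interaction analysis probes; OAV < 0.1 is treated
as negligible.

The packaged Baijiu dataset (see :mod:`pyrasense.datasets`) carries mean
triplicate concentrations of 16 pyrazines across 11 commercial soy-sauce-
aroma Baijiu samples, together with their odor thresholds measured in 53%
(v/v) ethanol/water.  Profile OAVs are reported at 1 decimal, spike-design
OAVs at 2 decimals, and percent-of-threshold at the nearest integer — all
half-up, matching how such tables are conventionally printed.  One printed
value in the source tables does not follow half-up rounding (80/172 =
46.5% appears as 46%); this is documented rather than special-cased.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import DataError

#: OAVs below this are considered negligible for aroma contribution.
NEGLIGIBLE_BOUND = 0.1
#: OAVs at or above this are supra-threshold (threshold itself counts as reached).
SUPRA_BOUND = 1.0


class Band(str, Enum):
    NEGLIGIBLE = "negligible"
    SUB_THRESHOLD = "sub_threshold"
    SUPRA_THRESHOLD = "supra_threshold"


@dataclass(frozen=True)
class OavRecord:
    sample: str
    compound: str
    concentration: float
    threshold: float
    oav: float
    band: Band


class MatrixMismatchWarning(UserWarning):
    """Threshold measured in a different matrix than the sample it is applied to."""


def compute_oav(concentration: float, threshold: float) -> float:
    """concentration / threshold (both μg·L⁻¹); dimensionless."""
    if threshold <= 0:
        raise DataError("odor threshold must be > 0")
    if concentration < 0:
        raise DataError("concentration must be >= 0")
    return concentration / threshold


def classify_oav(oav: float) -> Band:
    """Band an OAV: <0.1 negligible, [0.1, 1) sub-threshold, >=1 supra-threshold."""
    if oav < 0:
        raise DataError("OAV must be >= 0")
    if oav < NEGLIGIBLE_BOUND:
        return Band.NEGLIGIBLE
    if oav < SUPRA_BOUND:
        return Band.SUB_THRESHOLD
    return Band.SUPRA_THRESHOLD


def percent_of_threshold(concentration: float, threshold: float) -> int:
    """Concentration as a whole-number percentage of the odor threshold."""
    return int(round_half_up(100.0 * compute_oav(concentration, threshold)))


def summarize_compound(values) -> tuple[float, float, float]:
    """(min, max, mean) over the present (non-missing) per-sample values."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise DataError("no present values to summarize")
    return float(arr.min()), float(arr.max()), float(arr.mean())


# ---------------------------------------------------------------------------
# Table-level profiling


def read_concentration_table(path) -> pd.DataFrame:
    """Wide concentration table: index = compound, columns = samples (μg·L⁻¹)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "compound" not in df.columns:
        raise DataError("concentration table needs a 'compound' column")
    df = df.set_index("compound")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise DataError("sample and compound identifiers must be unique")
    if (df < 0).any().any():
        raise DataError("concentrations must be >= 0")
    return df.astype(float)


def read_threshold_table(path) -> pd.DataFrame:
    """Threshold table: index = compound; columns threshold_ug_per_l, matrix, source."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound", "threshold_ug_per_l"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"threshold table missing columns: {sorted(missing)}")
    df = df.set_index("compound")
    if df.index.duplicated().any():
        raise DataError("one threshold entry per compound required")
    if (df["threshold_ug_per_l"] <= 0).any():
        raise DataError("thresholds must be > 0")
    return df


def oav_profile(
    concentrations: pd.DataFrame,
    thresholds: pd.DataFrame,
    sample_matrix: str | None = None,
) -> pd.DataFrame:
    """Tidy per-(sample, compound) OAV table with banding.

    Missing concentrations propagate as missing rows (they never count as
    zero).  If ``sample_matrix`` is given and differs from a threshold's
    matrix tag, a :class:`MatrixMismatchWarning` is emitted — thresholds here
    come from dilute-ethanol model solutions, not from the Baijiu matrix
    itself, and that extrapolation should stay visible.
    """
    common = [c for c in concentrations.index if c in thresholds.index]
    if not common:
        raise DataError("no compounds shared between concentration and threshold tables")
    if sample_matrix is not None:
        mism = thresholds.loc[common].query("matrix != @sample_matrix")
        if len(mism):
            warnings.warn(
                f"thresholds for {list(mism.index)} were measured in a different "
                f"matrix than the samples ({sample_matrix})",
                MatrixMismatchWarning,
                stacklevel=2,
            )
    rows = []
    for compound in common:
        thr = float(thresholds.loc[compound, "threshold_ug_per_l"])
        for sample, conc in concentrations.loc[compound].items():
            if pd.isna(conc):
                continue
            oav = compute_oav(float(conc), thr)
            rows.append(
                {
                    "sample": sample,
                    "compound": compound,
                    "concentration": float(conc),
                    "threshold": thr,
                    "oav": oav,
                    "oav_1dp": round_half_up(oav, 1),
                    "band": classify_oav(oav).value,
                }
            )
    return pd.DataFrame(rows)


def profile_summary(profile: pd.DataFrame) -> dict:
    """Per-compound ranges of concentration and OAV (printed-precision rounding)."""
    out = {}
    for compound, grp in profile.groupby("compound", sort=False):
        cmin, cmax, cmean = summarize_compound(grp["concentration"])
        omin, omax, omean = summarize_compound(grp["oav"])
        out[compound] = {
            "n_samples": int(len(grp)),
            "concentration_min": round_half_up(cmin),
            "concentration_max": round_half_up(cmax),
            "concentration_mean": round_half_up(cmean, 2),
            "oav_min": round_half_up(omin, 1),
            "oav_max": round_half_up(omax, 1),
            "band_max": classify_oav(omax).value,
        }
    return out


def supra_threshold_contributors(
    concentrations: pd.DataFrame,
    thresholds: pd.DataFrame,
    on: str = "mean",
) -> list[str]:
    """Compounds whose concentration surpasses the odor threshold.

    ``on="mean"`` (default) tests the across-sample mean concentration —
    the rule under which exactly four pyrazines (26DM, 235TM, 2E6M, 2E35DM)
    qualify in the packaged dataset.  ``on="any"`` instead asks whether any
    single sample reaches OAV >= 1, a looser notion that additionally picks
    up compounds that cross the threshold only in their strongest sample
    (23DE does, in two of the eleven packaged samples).
    """
    if on not in {"mean", "any"}:
        raise DataError(f"unknown contributor rule {on!r}")
    profile = oav_profile(concentrations, thresholds)
    out = []
    for compound, grp in profile.groupby("compound", sort=False):
        if on == "mean":
            hit = grp["oav"].mean() >= SUPRA_BOUND
        else:
            hit = (grp["oav"] >= SUPRA_BOUND).any()
        if hit:
            out.append(compound)
    return out


def write_profile(profile: pd.DataFrame, tsv_path, summary_json_path=None) -> None:
    profile.to_csv(tsv_path, sep="\t", index=False)
    if summary_json_path is not None:
        with open(summary_json_path, "w") as fh:
            json.dump(profile_summary(profile), fh, indent=2)
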