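"""Synthetic study generator.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so each stage is testable with
known ground truth:

* a concentration table whose per-compound log-concentrations load on a
  latent per-sample roasted-aroma intensity (drives the Spearman screen);
* descriptive-panel ratings noisily reporting that latent intensity;
* per-panelist 3-AFC dose responses from a logistic psychometric function
  in log₁₀-dose with a 1/3 guessing floor, zero lapse, and log-normally
  heterogeneous individual thresholds;
* mixture experiments whose true joint detection is a power transform of
  the Feller complement, 1 − [(1 − p_A)(1 − p_B)]^θ, so θ = 1 reproduces
  independence exactly, θ > 1 yields synergy and θ < 1 suppression.

All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import CHANCE_3AFC, rng_from_seed
from .errors import DesignError
from .psychophysics import DetectionCurve, DoseSeries
from .quantitation import CalibrationSeries
from .feller import MixturePair

#: Default logistic steepness per log10-dose unit: the 10-90% detection span
#: then covers ~3 factor-2 dilution steps (2·ln 9 / slope ≈ 0.90 log10 units).
DEFAULT_SLOPE = 4.87

#: Default panelist heterogeneity: geometric sd of individual thresholds of
#: one dilution step (factor 2).
DEFAULT_THRESHOLD_GSD_LOG10 = math.log10(2.0)


@dataclass(frozen=True)
class CompoundDef:
    """One simulated pyrazine: odor threshold, stock level, aroma loading."""

    threshold: float  # μg·L⁻¹
    stock: float  # μg·L⁻¹, also the typical sample-level concentration
    loading: float = 0.0  # log10-concentration units per latent-intensity sd

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.stock <= 0:
            raise DesignError("thresholds and stock concentrations must be > 0")


#: The eight pyrazines of the mixture experiments: four supra-threshold
#: (26DM, 2E6M, 235TM, 2E35DM) and four sub-threshold (23DM, 23DE, 23DE5M,
#: 2A3M), with their measured odor thresholds and bundle stock levels.
DEFAULT_COMPOUNDS: dict[str, CompoundDef] = {
    "26DM": CompoundDef(threshold=791, stock=1110),
    "2E6M": CompoundDef(threshold=40, stock=250),
    "235TM": CompoundDef(threshold=730, stock=950),
    "2E35DM": CompoundDef(threshold=7.5, stock=150),
    "23DM": CompoundDef(threshold=965, stock=290),
    "23DE": CompoundDef(threshold=172, stock=100),
    "23DE5M": CompoundDef(threshold=18, stock=11),
    "2A3M": CompoundDef(threshold=415, stock=120),
}


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of a simulated study (defaults mirror the Baijiu study)."""

    seed: int = 0
    n_samples: int = 11  # commercial Baijiu samples profiled
    n_panelists: int = 20  # 3-AFC panel size
    n_assessors: int = 12  # descriptive panel size
    n_rating_replicates: int = 3
    compounds: dict[str, CompoundDef] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUNDS)
    )
    latent_range: tuple[float, float] = (1.0, 6.3)  # roasted-aroma intensity span
    conc_log_noise_sd: float = 0.15  # log10 units around the loading line
    rating_noise_sd: float = 0.8  # scale points, assessor-level
    slope: float = DEFAULT_SLOPE
    threshold_gsd_log10: float = DEFAULT_THRESHOLD_GSD_LOG10
    chance: float = CHANCE_3AFC
    p_a: float = 0.2  # detection probability of the fixed sub-threshold bundle
    interaction_factor: float = 1.0  # θ; 1 = Feller-exact mixtures

    def __post_init__(self) -> None:
        if self.interaction_factor <= 0:
            raise DesignError("interaction factor θ must be > 0")
        if not 0 <= self.p_a <= 1:
            raise DesignError("p_a must lie in [0, 1]")

    def with_loadings(self, loadings: dict[str, float]) -> "StudyConfig":
        comps = {
            name: replace(cd, loading=loadings.get(name, cd.loading))
            for name, cd in self.compounds.items()
        }
        return replace(self, compounds=comps)


def loading_for_rank_correlation(rho_s: float, noise_sd: float) -> float:
    """Loading giving a target population Spearman ρ against the latent.

    Uses the Gaussian-copula relation ρ_s = (6/π)·asin(r/2) between Pearson
    r and Spearman ρ; with latent drawn uniformly this is approximate but
    accurate to a few hundredths over |ρ| ≤ 0.95.
    """
    if not -1 < rho_s < 1:
        raise DesignError("target rank correlation must lie in (-1, 1)")
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    return noise_sd * r / math.sqrt(1.0 - r**2)


# ---------------------------------------------------------------------------
# Concentration table and panel ratings


def simulate_concentration_table(
    cfg: StudyConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """(wide compound × sample concentration table, latent intensity per sample).

    log₁₀(concentration) = log₁₀(stock) + loading·z + noise, where z is the
    standardized latent intensity; compounds with loading 0 are null
    controls.  Latent intensities are uniform on ``cfg.latent_range``.
    """
    rng = rng_from_seed(cfg.seed if rng is None else rng)
    lo, hi = cfg.latent_range
    latent = rng.uniform(lo, hi, size=cfg.n_samples)
    z = (latent - latent.mean()) / latent.std()
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    rows = {}
    for name, cd in cfg.compounds.items():
        noise = rng.normal(0.0, cfg.conc_log_noise_sd, size=cfg.n_samples)
        rows[name] = 10.0 ** (math.log10(cd.stock) + cd.loading * z + noise)
    table = pd.DataFrame(rows, index=pd.Index(samples, name="sample")).T
    table.index.name = "compound"
    return table, pd.Series(latent, index=samples, name="latent_intensity")


def simulate_ratings(
    cfg: StudyConfig,
    latent: pd.Series,
    attribute: str = "roasted",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format panel ratings: score = latent + assessor noise, clipped to 0-7."""
    rng = rng_from_seed(cfg.seed + 1 if rng is None else rng)
    rows = []
    for assessor in range(1, cfg.n_assessors + 1):
        for rep in range(1, cfg.n_rating_replicates + 1):
            noise = rng.normal(0.0, cfg.rating_noise_sd, size=len(latent))
            scores = np.clip(np.round(latent.to_numpy() + noise), 0, 7)
            for sample, score in zip(latent.index, scores):
                rows.append(
                    {
                        "assessor": f"A{assessor:02d}",
                        "replicate": rep,
                        "sample": sample,
                        "attribute": attribute,
                        "score": float(score),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3-AFC psychophysics


def _panelist_detection(
    doses: np.ndarray,
    group_threshold: float,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-panelist detection probabilities, shape (n_panelists, n_doses)."""
    log_t = rng.normal(
        math.log10(group_threshold), cfg.threshold_gsd_log10, size=cfg.n_panelists
    )
    x = np.log10(doses)[None, :] - log_t[:, None]
    return expit(cfg.slope * x)


def simulate_afc_responses(
    series: DoseSeries,
    cfg: StudyConfig,
    group_threshold: float,
    rng: np.random.Generator | None = None,
) -> DetectionCurve:
    """Simulate one ascending 3-AFC session over the dose ladder.

    Each panelist answers once per dose; an answer is correct with
    probability chance + (1 − chance)·p_detect.  The group threshold is the
    median of the log-normal individual thresholds, so the group detection
    curve crosses p_detect = 0.5 at ``group_threshold`` in expectation.
    """
    if group_threshold <= 0:
        raise DesignError("group threshold must be > 0")
    rng = rng_from_seed(cfg.seed if rng is None else rng)
    doses = np.asarray(series.doses, float)
    p_detect = _panelist_detection(doses, group_threshold, cfg, rng)
    p_correct = cfg.chance + (1.0 - cfg.chance) * p_detect
    correct = rng.random(p_correct.shape) < p_correct
    k = correct.sum(axis=0)
    return DetectionCurve(
        doses=tuple(doses),
        n=(cfg.n_panelists,) * len(doses),
        k=tuple(int(v) for v in k),
        chance=cfg.chance,
    )


def simulate_mixture_experiment(
    series: DoseSeries,
    cfg: StudyConfig,
    group_threshold_b: float,
    rng: np.random.Generator | None = None,
) -> MixturePair:
    """Simulate the A / B / AB design of a mixture-interaction experiment.

    Component A (fixed composition) is detected with probability ``cfg.p_a``
    by every panelist; component B follows the psychometric model; the true
    mixture detection is 1 − [(1 − p_A)(1 − p_B)]^θ with θ =
    ``cfg.interaction_factor``, so θ = 1 is exactly Feller-additive.

    One panel attends every session, as in real threshold practice: the
    individual thresholds are drawn once and shared between the B and AB
    ladders (responses stay independent across sessions).  Per-panelist
    additivity then aggregates to additivity of the realized group curves,
    which is what makes the additive null testable from group counts.
    """
    rng = rng_from_seed(cfg.seed if rng is None else rng)
    doses = np.asarray(series.doses, float)
    chance = cfg.chance

    # component A: replicate trials at its single fixed composition
    pa_correct = chance + (1.0 - chance) * cfg.p_a
    k_a = int(rng.binomial(cfg.n_panelists, pa_correct))
    curve_a = DetectionCurve(doses=(1.0,), n=(cfg.n_panelists,), k=(k_a,), chance=chance)

    # one shared panel for the B and AB sessions
    p_b = _panelist_detection(doses, group_threshold_b, cfg, rng)

    correct_b = rng.random(p_b.shape) < chance + (1.0 - chance) * p_b
    curve_b = DetectionCurve(
        doses=tuple(doses),
        n=(cfg.n_panelists,) * len(doses),
        k=tuple(int(v) for v in correct_b.sum(axis=0)),
        chance=chance,
    )

    # mixture: power transform of the Feller complement with θ
    p_ab = 1.0 - ((1.0 - cfg.p_a) * (1.0 - p_b)) ** cfg.interaction_factor
    correct_ab = rng.random(p_ab.shape) < chance + (1.0 - chance) * p_ab
    curve_ab = DetectionCurve(
        doses=tuple(doses),
        n=(cfg.n_panelists,) * len(doses),
        k=tuple(int(v) for v in correct_ab.sum(axis=0)),
        chance=chance,
    )
    return MixturePair(component_b=curve_b, mixture_observed=curve_ab, component_a=curve_a)


# ---------------------------------------------------------------------------
# Calibration series


def simulate_calibration(
    slope: float,
    intercept: float,
    noise_sd: float,
    levels,
    seed: int | np.random.Generator = 0,
    compound: str = "synthetic",
) -> CalibrationSeries:
    """Response ratios = slope·c + intercept + Gaussian noise (clipped at 0).

    ``levels`` is either a sequence of standard concentrations or an integer
    count (then levels are spread evenly over 10-1000 μg·L⁻¹).
    """
    if slope <= 0:
        raise DesignError("calibration slope must be > 0")
    rng = rng_from_seed(seed)
    if np.isscalar(levels):
        if int(levels) < 2:
            raise DesignError("need >= 2 calibration levels")
        conc = np.linspace(10.0, 1000.0, int(levels))
    else:
        conc = np.asarray(levels, float)
    ratios = slope * conc + intercept + rng.normal(0.0, noise_sd, size=conc.shape)
    ratios = np.maximum(ratios, 0.0)
    return CalibrationSeries.from_arrays(compound, conc, ratios)
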