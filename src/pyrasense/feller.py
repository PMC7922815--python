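"""Feller additive model for odor-mixture interaction.

If two odor stimuli A and B are detected independently, the probability of
detecting their mixture is

    p(AB) = p(A) + p(B) − p(A)·p(B)  ⇔  1 − p(AB) = (1 − p(A))(1 − p(B)),

the "additive" null of perceptual interaction.  Observed mixture detection
*above* this prediction means the components reinforce each other
(synergy); detection *below* it means suppression.  Equivalently, synergy
shows up as an observed mixture threshold below the threshold of the
predicted curve.

Here component A is a fixed-composition bundle (four sub-threshold
pyrazines) contributing a single dose-independent detection probability
p(A), and component B is a dose-varying bundle (four supra-threshold
pyrazines on a geometric ladder).  All model arithmetic runs on the
chance-corrected detection scale — applying the independence formula to
raw proportion-correct would double-count guessing.

Inference
---------
Departures from additivity are embedded in a one-parameter family,

    1 − p(AB; θ) = [(1 − p(A))(1 − p(B))]^θ ,

whose null is θ = 1, θ > 1 is synergy and θ < 1 suppression.  The test
statistic is the signed square-root likelihood-ratio of the mixture counts
over θ, with p(A) estimated from the A trials and the B curve smoothed by
a maximum-likelihood psychometric (logistic in log-dose) fit.  Because the
prediction is built from *measured* A/B curves, it carries sampling noise
of its own; the statistic's null distribution is therefore obtained by a
parametric bootstrap that redraws the A, B and (additive-null) mixture
counts and re-estimates every nuisance on each draw.  A verdict other than
additive additionally requires the implied threshold shift to reach half a
dilution step (fold √2) — the resolution of a factor-2 dose ladder.

When the component detection probabilities are known by design rather
than estimated, ``prediction_uncertainty="none"`` gives the exact
binomial-convolution tail at the doses bracketing the threshold criterion
instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .discrimination import abbott_correct, abbott_expand
from .errors import DataError, DesignError, InsufficientDataError, NoCrossingError
from .psychophysics import (
    DETECTION_SCALE,
    DetectionCurve,
    ThresholdEstimate,
    estimate_threshold,
    pava_smooth,
)
from ._util import round_half_up

#: Interaction exponents scanned by the likelihood-ratio statistic.
THETA_GRID = np.exp(np.linspace(np.log(0.1), np.log(10.0), 61))
_THETA_NULL_INDEX = int(np.argmin(np.abs(THETA_GRID - 1.0)))

#: Minimal threshold shift (fold) for a non-additive verdict: half a step of
#: a factor-2 dilution ladder, the smallest shift the design can resolve.
MIN_EFFECT_FOLD = math.sqrt(2.0)


@dataclass(frozen=True)
class MixturePair:
    """A/B/AB detection data for one interaction experiment.

    ``component_a`` may be None when the sub-threshold bundle was not tested
    on its own; then p(A) must be supplied (or assumed 0) explicitly.
    """

    component_b: DetectionCurve
    mixture_observed: DetectionCurve
    component_a: DetectionCurve | None = None

    def __post_init__(self) -> None:
        if tuple(self.component_b.doses) != tuple(self.mixture_observed.doses):
            raise DesignError("component B and mixture must share an identical dose axis")


@dataclass(frozen=True)
class InteractionVerdict:
    call: str  # "synergy" | "additive" | "suppression"
    p_a: float  # reported component-A detection probability (clipped at 0)
    theta_hat: float  # ML interaction exponent (1 = additive)
    predicted_detection: tuple[float, ...]  # Feller curve at the B doses
    threshold_observed: ThresholdEstimate | None
    threshold_predicted: ThresholdEstimate | None
    ratio: float | None  # threshold_predicted / threshold_observed, 1 dp
    p_value: float  # two-sided bootstrap p for departure from additivity
    p_value_high: float  # one-sided: observed detection above prediction
    p_value_low: float  # one-sided: observed detection below prediction
    censored: bool = False

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "p_a": self.p_a,
            "theta_hat": self.theta_hat,
            "predicted_detection": list(self.predicted_detection),
            "threshold_observed": self.threshold_observed.to_dict()
            if self.threshold_observed
            else None,
            "threshold_predicted": self.threshold_predicted.to_dict()
            if self.threshold_predicted
            else None,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "p_value_high": self.p_value_high,
            "p_value_low": self.p_value_low,
            "censored": self.censored,
        }


def feller_predict(p_a: float, p_b: float) -> float:
    """Independence prediction p(AB) = p(A) + p(B) − p(A)·p(B)."""
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise DataError("detection probabilities must lie in [0, 1]")
    return p_a + p_b - p_a * p_b


def threshold_ratio(reference_threshold: float, test_threshold: float) -> float:
    """Fold-change reference/test, reported at 1 decimal (half-up)."""
    if reference_threshold <= 0 or test_threshold <= 0:
        raise DataError("thresholds must be > 0")
    return round_half_up(reference_threshold / test_threshold, 1)


def estimate_component_a_detection(curve: DetectionCurve | None) -> float:
    """Pooled detection probability of the fixed-composition A bundle.

    A is presented at one composition, so its per-dose rows are replicate
    trials: counts are pooled before Abbott correction.  At-or-below-chance
    performance yields p(A) = 0 and the model degenerates to p(AB) = p(B).
    """
    if curve is None:
        return 0.0
    k, n = sum(curve.k), sum(curve.n)
    return abbott_correct(k / n, curve.chance)


# ---------------------------------------------------------------------------
# Internal machinery: psychometric grid fit and the signed LRT


def _curve_grid(log_doses: np.ndarray) -> np.ndarray:
    """Candidate B detection curves: logistic in log-dose on a (mid, slope) grid."""
    span = max(log_doses[-1] - log_doses[0], 1.0)
    mids = np.linspace(log_doses[0] - 0.5 * span, log_doses[-1] + 0.5 * span, 64)
    slopes = np.exp(np.linspace(np.log(0.3), np.log(40.0), 20))
    return expit(
        slopes[:, None, None] * (log_doses[None, None, :] - mids[None, :, None])
    ).reshape(-1, len(log_doses))


def _fit_curve(grid: np.ndarray, k: np.ndarray, n: np.ndarray, chance: float):
    """ML index/indices into the curve grid for binomial counts k of n."""
    pc = np.clip(chance + (1.0 - chance) * grid, 1e-9, 1 - 1e-9)
    log_pc, log_1mpc = np.log(pc), np.log1p(-pc)
    ll = np.atleast_2d(k) @ log_pc.T + np.atleast_2d(n - k) @ log_1mpc.T
    return np.argmax(ll, axis=-1)


def _signed_lrt(pa, pb, k, n, chance: float):
    """Signed-root LRT of the mixture counts over the θ grid.

    ``pa`` scalar or (s,); ``pb``/``k`` arrays with matching leading shape.
    Positive values point toward synergy (θ̂ > 1).
    """
    pa = np.asarray(pa, float)
    comp = np.clip((1.0 - pa)[..., None] * (1.0 - pb), 1e-12, None)
    q = 1.0 - comp[..., None, :] ** THETA_GRID[:, None]
    pc = np.clip(chance + (1.0 - chance) * q, 1e-9, 1 - 1e-9)
    ll = (k[..., None, :] * np.log(pc) + (n - k)[..., None, :] * np.log1p(-pc)).sum(
        axis=-1
    )
    ihat = np.argmax(ll, axis=-1)
    lmax = np.take_along_axis(ll, ihat[..., None], axis=-1)[..., 0]
    stat = np.sqrt(np.maximum(0.0, 2.0 * (lmax - ll[..., _THETA_NULL_INDEX])))
    return np.where(THETA_GRID[ihat] >= 1.0, stat, -stat), ihat


def _threshold_from_props(
    doses: np.ndarray, props: np.ndarray, criterion: float
) -> ThresholdEstimate:
    """Log-linear threshold interpolation on an already-smooth detection curve."""
    props = pava_smooth(props, np.ones_like(props))
    if props.max() < criterion:
        raise NoCrossingError(
            f"curve never reaches {criterion}", max_proportion=float(props.max())
        )
    hits = np.nonzero(np.isclose(props, criterion, atol=1e-12))[0]
    if hits.size:
        d = float(doses[hits[0]])
        return ThresholdEstimate(d, criterion, DETECTION_SCALE, "log-linear interpolation", (d, d))
    if props[0] > criterion:
        d = float(doses[0])
        return ThresholdEstimate(
            d, criterion, DETECTION_SCALE, "log-linear interpolation", (d, d), censored="left"
        )
    j = int(np.argmax(props > criterion))
    i = j - 1
    lo, hi = math.log10(doses[i]), math.log10(doses[j])
    frac = (criterion - props[i]) / (props[j] - props[i])
    return ThresholdEstimate(
        float(10 ** (lo + frac * (hi - lo))),
        criterion,
        DETECTION_SCALE,
        "log-linear interpolation",
        (float(doses[i]), float(doses[j])),
    )


def _binom_pmf(n: int, p: float) -> np.ndarray:
    ks = np.arange(n + 1)
    return np.array([math.comb(n, int(i)) for i in ks]) * p**ks * (1.0 - p) ** (n - ks)


def _poolwise_exact_tails(ns, ks, ps) -> tuple[float, float]:
    """Exact tails of sum(k_i), k_i ~ Binomial(n_i, p_i), by convolution."""
    dist = np.array([1.0])
    for n, p in zip(ns, ps):
        dist = np.convolve(dist, _binom_pmf(int(n), float(p)))
    total = int(sum(ks))
    p_high = float(dist[total:].sum())
    p_low = float(dist[: total + 1].sum())
    return min(1.0, p_high), min(1.0, p_low)


# ---------------------------------------------------------------------------
# The verdict


def classify_interaction(
    pair: MixturePair,
    alpha: float = 0.05,
    p_a: float | None = None,
    criterion: float = 0.5,
    prediction_uncertainty: str = "bootstrap",
    n_boot: int = 2000,
    random_state: int = 0,
    min_effect_fold: float = MIN_EFFECT_FOLD,
) -> InteractionVerdict:
    """Compare observed mixture detection with the Feller prediction.

    ``p_a`` overrides the component-A estimate (use 0.0 for the assumed-inert
    mode); by default it is pooled from ``pair.component_a``.  Thresholds are
    estimated on the chance-corrected detection scale at ``criterion``.

    The call is non-additive only when (i) the two-sided bootstrap LRT
    rejects additivity at ``alpha`` and (ii) the fitted threshold shift
    reaches ``min_effect_fold`` in the indicated direction.
    """
    if prediction_uncertainty not in {"bootstrap", "none"}:
        raise DataError(f"unknown prediction_uncertainty {prediction_uncertainty!r}")
    b = pair.component_b
    obs = pair.mixture_observed
    if len(b.doses) < 3:
        raise InsufficientDataError("interaction analysis needs >= 3 doses")
    chance = obs.chance
    n = np.asarray(obs.n, float)
    k = np.asarray(obs.k, float)
    nb = np.asarray(b.n, float)
    kb = np.asarray(b.k, float)
    doses = np.asarray(obs.doses, float)
    log_doses = np.log10(doses)

    # --- component A: detection probability (unclipped internally)
    p_a_fixed = p_a is not None
    if p_a_fixed:
        pa_internal = float(p_a)
        pa_reported = max(0.0, float(p_a))
        pc_a, n_a = None, None
    else:
        if pair.component_a is None:
            raise DesignError(
                "p_a must be given explicitly (e.g. 0.0) when component A was not tested"
            )
        n_a = int(sum(pair.component_a.n))
        pc_a = sum(pair.component_a.k) / n_a
        pa_internal = (pc_a - chance) / (1.0 - chance)
        pa_reported = max(0.0, pa_internal)

    # --- smoothed B curve and the additive prediction
    grid = _curve_grid(log_doses)
    pb_hat = grid[int(_fit_curve(grid, kb, nb, chance)[0])]
    predicted = np.clip(pa_internal + (1.0 - pa_internal) * pb_hat, 0.0, 1.0)

    # --- evidence against additivity
    if prediction_uncertainty == "none":
        t_obs, ihat = _signed_lrt(pa_internal, pb_hat, k, n, chance)
        theta_hat = float(THETA_GRID[int(np.atleast_1d(ihat)[0])])
        try:
            bracket = _threshold_from_props(doses, predicted, criterion).bracket
            idx = sorted({int(np.where(doses == d)[0][0]) for d in bracket})
        except NoCrossingError:
            idx = list(np.argsort(np.abs(predicted - criterion))[:2])
        ps = [abbott_expand(predicted[i], chance) for i in idx]
        p_high, p_low = _poolwise_exact_tails(
            [obs.n[i] for i in idx], [obs.k[i] for i in idx], ps
        )
    else:
        t_arr, ihat = _signed_lrt(pa_internal, pb_hat, k, n, chance)
        t_obs = float(np.atleast_1d(t_arr)[0])
        theta_hat = float(THETA_GRID[int(np.atleast_1d(ihat)[0])])
        # parametric bootstrap of the additive null: redraw A, B and AB
        # counts (AB from the additive transform of the raw B proportions,
        # preserving the coupling of B and AB to one realized panel curve)
        # and re-estimate every nuisance on each draw
        rng = np.random.default_rng(random_state)
        if p_a_fixed:
            pa_s = np.full(n_boot, pa_internal)
        else:
            ka_s = rng.binomial(n_a, pc_a, size=n_boot)
            pa_s = (ka_s / n_a - chance) / (1.0 - chance)
        kb_s = rng.binomial(nb.astype(int), kb / nb, size=(n_boot, len(doses))).astype(float)
        pb_s = grid[_fit_curve(grid, kb_s, nb, chance)]
        pb_raw = (kb / nb - chance) / (1.0 - chance)
        pc_ab0 = np.clip(
            chance + (1.0 - chance) * (pa_internal + (1.0 - pa_internal) * pb_raw), 0.0, 1.0
        )
        k_s = rng.binomial(n.astype(int), pc_ab0, size=(n_boot, len(doses))).astype(float)
        ts, _ = _signed_lrt(pa_s, pb_s, k_s, n, chance)
        p_high = (1.0 + np.count_nonzero(ts >= t_obs)) / (n_boot + 1.0)
        p_low = (1.0 + np.count_nonzero(ts <= t_obs)) / (n_boot + 1.0)

    p_two = min(1.0, 2.0 * min(p_high, p_low))

    # --- thresholds (reported on the observed/predicted curves)
    try:
        thr_obs = estimate_threshold(obs, criterion=criterion, scale=DETECTION_SCALE)
    except NoCrossingError:
        thr_obs = None
    try:
        thr_pred = _threshold_from_props(doses, predicted, criterion)
    except NoCrossingError:
        thr_pred = None
    ratio = None
    if thr_obs is not None and thr_pred is not None:
        ratio = round_half_up(thr_pred.value / thr_obs.value, 1)

    # --- fitted-model threshold shift used for the minimal-effect gate
    q_hat = np.clip(
        1.0
        - np.clip((1.0 - pa_internal) * (1.0 - pb_hat), 1e-12, None) ** theta_hat,
        0.0,
        1.0,
    )
    try:
        thr_model = _threshold_from_props(doses, q_hat, criterion)
    except NoCrossingError:
        thr_model = None
    model_ratio = None
    if thr_model is not None and thr_pred is not None:
        model_ratio = thr_pred.value / thr_model.value

    call = "additive"
    if p_two < alpha:
        if p_high < p_low:
            if (model_ratio is not None and model_ratio >= min_effect_fold) or (
                thr_pred is None and thr_model is not None
            ):
                call = "synergy"
        else:
            if (model_ratio is not None and model_ratio <= 1.0 / min_effect_fold) or (
                thr_model is None and thr_pred is not None
            ):
                call = "suppression"

    return InteractionVerdict(
        call=call,
        p_a=pa_reported,
        theta_hat=theta_hat,
        predicted_detection=tuple(float(p) for p in predicted),
        threshold_observed=thr_obs,
        threshold_predicted=thr_pred,
        ratio=ratio,
        p_value=p_two,
        p_value_high=float(p_high),
        p_value_low=float(p_low),
        censored=thr_obs is None or thr_pred is None,
    )


def write_verdict(verdict: InteractionVerdict, json_path) -> None:
    with open(json_path, "w") as fh:
        json.dump(verdict.to_dict(), fh, indent=2)
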