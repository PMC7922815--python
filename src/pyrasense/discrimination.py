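"""Exact 3-AFC discrimination testing and chance correction.

In a 3-alternative forced choice, a panelist gets one spiked and two blank
samples and must name the odd one; pure guessing succeeds with probability
1/3.  Whether a spike was perceived is judged by the exact upper-tail
binomial probability of the observed number of correct choices under
guessing, coded on the conventional */**/*** ladder.  Proportion-correct is
converted to a true detection probability by Abbott's correction,
p_d = (p_c − chance)/(1 − chance), the standard adjustment for an m-AFC
task with guessing rate 1/m; this detection scale is what the mixture
interaction model operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._util import CHANCE_3AFC
from .errors import DataError

#: p-value ladder for the significance codes, most stringent first.
SIGNIFICANCE_LADDER = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class AfcTest:
    """One forced-choice experiment: n panelists, k correct answers."""

    label: str
    n_panelists: int
    n_correct: int
    chance: float = CHANCE_3AFC

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_panelists:
            raise DataError("need 0 <= n_correct <= n_panelists")
        if not 0 < self.chance < 1:
            raise DataError("chance must lie in (0, 1)")

    @property
    def p_correct(self) -> float:
        return self.n_correct / self.n_panelists


@dataclass(frozen=True)
class AfcResult:
    label: str
    p_value: float
    code: str
    detection_probability: float
    p_correct: float


def afc_pvalue(test: AfcTest) -> float:
    """Exact upper-tail P(X >= k | n, chance) by direct summation of the pmf.

    Panel sizes here are 12-20, where a normal approximation would distort
    the significance ladder, so the tail is summed term by term.
    """
    n, k, p = test.n_panelists, test.n_correct, test.chance
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1.0 - p) ** (n - i)
    return min(1.0, total)


def significance_code(p_value: float) -> str:
    """Map a p-value to the ns/*/**/*** ladder (cuts at 0.05, 0.01, 0.001)."""
    if not 0 <= p_value <= 1:
        raise DataError("p-value must lie in [0, 1]")
    for cut, code in SIGNIFICANCE_LADDER:
        if p_value < cut:
            return code
    return "ns"


def abbott_correct(p_correct: float, chance: float = CHANCE_3AFC) -> float:
    """Proportion-correct -> detection probability, clipped below at 0.

    Observed proportions below chance (possible by sampling noise) map to a
    detection probability of 0; the raw value remains available upstream.
    """
    if not 0 <= p_correct <= 1:
        raise DataError("p_correct must lie in [0, 1]")
    return max(0.0, (p_correct - chance) / (1.0 - chance))


def abbott_expand(p_detect: float, chance: float = CHANCE_3AFC) -> float:
    """Inverse of Abbott's correction: p_c = chance + (1 − chance)·p_d."""
    if not 0 <= p_detect <= 1:
        raise DataError("p_detect must lie in [0, 1]")
    return chance + (1.0 - chance) * p_detect


def evaluate_test(test: AfcTest) -> AfcResult:
    """Full evaluation of one 3-AFC experiment."""
    p = afc_pvalue(test)
    return AfcResult(
        label=test.label,
        p_value=p,
        code=significance_code(p),
        detection_probability=abbott_correct(test.p_correct, test.chance),
        p_correct=test.p_correct,
    )


# ---------------------------------------------------------------------------
# Table-level interface


def read_trial_table(path) -> list[AfcTest]:
    """Delimited trial table with columns label, n, k (and optional chance)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"label", "n", "k"} - set(df.columns)
    if missing:
        raise DataError(f"trial table missing columns: {sorted(missing)}")
    chance = df["chance"] if "chance" in df.columns else pd.Series(CHANCE_3AFC, index=df.index)
    return [
        AfcTest(str(row.label), int(row.n), int(row.k), float(c))
        for (_, row), c in zip(df.iterrows(), chance)
    ]


def evaluate_trials(tests: list[AfcTest]) -> pd.DataFrame:
    rows = [evaluate_test(t).__dict__ for t in tests]
    return pd.DataFrame(rows)
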