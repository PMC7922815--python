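"""Panel aggregation, ANOVA and the Spearman concentration–aroma screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pyrasense import (
    DataError,
    DegenerateVarianceError,
    InsufficientDataError,
    StudyConfig,
    aggregate_intensity,
    anova_by_sample,
    loading_for_rank_correlation,
    simulate_concentration_table,
    simulate_ratings,
    spearman_pvalue,
    spearman_rho,
    spearman_screen,
)


def ratings_frame(rows):
    return pd.DataFrame(rows, columns=["assessor", "replicate", "sample", "attribute", "score"])


class TestAggregateIntensity:
    def test_constant_panel(self):
        df = ratings_frame(
            [(a, r, s, "roasted", 4) for a in "AB" for r in (1, 2) for s in ("S1", "S2")]
        )
        prof = aggregate_intensity(df, "roasted")
        assert (prof["mean"] == 4).all() and (prof["sd"] == 0).all()

    def test_mean_and_sd_arithmetic(self):
        df = ratings_frame([("A", 1, "S1", "roasted", 2), ("B", 1, "S1", "roasted", 3), ("C", 1, "S1", "roasted", 4)])
        prof = aggregate_intensity(df, "roasted")
        assert prof.loc["S1", "mean"] == pytest.approx(3.0)
        assert prof.loc["S1", "sd"] == pytest.approx(1.0)

    def test_unknown_attribute(self):
        df = ratings_frame([("A", 1, "S1", "roasted", 2)])
        with pytest.raises(DataError):
            aggregate_intensity(df, "fruity")


class TestAnova:
    def test_matches_hand_computed_decomposition(self):
        df = ratings_frame(
            [("A", i, "S1", "x", v) for i, v in enumerate((1, 1, 2, 2))]
            + [("A", i, "S2", "x", v) for i, v in enumerate((6, 6, 7, 7))]
        )
        f, p = anova_by_sample(df, "x")
        # one-way decomposition by hand: SSB = 2*4*(2.5**2)... groups (1,1,2,2),(6,6,7,7)
        g1, g2 = np.array([1, 1, 2, 2.0]), np.array([6, 6, 7, 7.0])
        grand = np.concatenate([g1, g2]).mean()
        ssb = 4 * (g1.mean() - grand) ** 2 + 4 * (g2.mean() - grand) ** 2
        ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / 6)
        assert f == pytest.approx(f_hand)
        assert p < 0.001

    def test_null_panels_give_small_f(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"A{a}", r, f"S{s}", "x", float(np.clip(round(3 + rng.normal(0, 1)), 0, 7)))
            for a in range(10)
            for r in range(3)
            for s in range(5)
        ]
        f, p = anova_by_sample(ratings_frame(rows), "x")
        assert p > 0.05 and f < 2.5

    def test_single_sample_errors(self):
        df = ratings_frame([("A", 1, "S1", "x", 1), ("B", 1, "S1", "x", 2)])
        with pytest.raises(InsufficientDataError):
            anova_by_sample(df, "x")

    def test_zero_variance_degenerate(self):
        df = ratings_frame(
            [("A", 1, "S1", "x", 1), ("B", 1, "S1", "x", 1), ("A", 1, "S2", "x", 2), ("B", 1, "S2", "x", 2)]
        )
        with pytest.raises(DegenerateVarianceError):
            anova_by_sample(df, "x")


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(11.0)
        rho, p, _ = spearman_pvalue(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p <= 1 / math.factorial(11) * 1.0000001

    def test_classical_formula_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        d2 = ((rx - ry) ** 2).sum()
        classical = 1 - 6 * d2 / (10 * (100 - 1))
        assert spearman_rho(x, y) == pytest.approx(classical, abs=1e-12)

    def test_exact_permutation_matches_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        rho_obs, p, method = spearman_pvalue(x, y, alternative="greater")
        assert method == "exact-permutation"
        # brute-force oracle over all 720 orderings
        count = 0
        for perm in itertools.permutations(y):
            if spearman_rho(x, perm) >= rho_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / 720)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y))
        assert spearman_rho(x, 3 * y + 2) == pytest.approx(spearman_rho(x, y))

    def test_anti_monotone_never_flagged(self):
        conc = pd.DataFrame(
            {f"S{i}": [float(10 - i)] for i in range(11)}, index=["cmp"]
        )
        profile = pd.Series(np.arange(11.0), index=[f"S{i}" for i in range(11)])
        res, edges = spearman_screen(conc, profile)
        assert res.loc[0, "rho"] == pytest.approx(-1.0)
        assert not res.loc[0, "significant"]
        assert edges.empty


class TestScreen:
    def test_requires_four_common_samples(self):
        conc = pd.DataFrame({"S1": [1.0], "S2": [2.0], "S3": [3.0]}, index=["c"])
        profile = pd.Series([1.0, 2, 3], index=["S1", "S2", "S3"])
        with pytest.raises(InsufficientDataError):
            spearman_screen(conc, profile)

    def test_zero_variance_column_flagged_degenerate(self):
        samples = [f"S{i}" for i in range(6)]
        conc = pd.DataFrame(
            {s: [1.0, float(i)] for i, s in enumerate(samples)}, index=["flat", "rising"]
        )
        profile = pd.Series(np.arange(6.0), index=samples)
        res, _ = spearman_screen(conc, profile)
        flat = res.set_index("compound").loc["flat"]
        assert flat["degenerate"] and not flat["significant"]

    def test_loaded_compounds_detected_more_often_than_weak(self):
        # synthetic-data recovery: strong rank-correlation compounds beat weak
        cfg = StudyConfig(seed=11, n_samples=11)
        hits = {"strong": 0, "weak": 0}
        reps = 200
        for r in range(reps):
            c = cfg.with_loadings(
                {
                    "2E35DM": loading_for_rank_correlation(0.8, cfg.conc_log_noise_sd),
                    "23DE": loading_for_rank_correlation(0.2, cfg.conc_log_noise_sd),
                }
            )
            rng = np.random.default_rng(1000 + r)
            conc, latent = simulate_concentration_table(c, rng=rng)
            res, _ = spearman_screen(conc, latent)
            res = res.set_index("compound")
            hits["strong"] += bool(res.loc["2E35DM", "significant"])
            hits["weak"] += bool(res.loc["23DE", "significant"])
        assert hits["strong"] > hits["weak"]
        assert hits["strong"] > reps / 2

    def test_noiseless_single_loading_gives_rho_one(self):
        cfg = StudyConfig(seed=4, conc_log_noise_sd=0.0).with_loadings({"2E35DM": 0.5})
        conc, latent = simulate_concentration_table(cfg)
        res, edges = spearman_screen(conc, latent)
        row = res.set_index("compound").loc["2E35DM"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["significant"]
        assert list(edges["compound"]) == ["2E35DM"]


def test_ratings_screen_round_trip():
    """End-to-end: ratings aggregate to a profile that drives the screen."""
    cfg = StudyConfig(seed=21).with_loadings(
        {"2E35DM": loading_for_rank_correlation(0.9, 0.15)}
    )
    conc, latent = simulate_concentration_table(cfg)
    ratings = simulate_ratings(cfg, latent)
    prof = aggregate_intensity(ratings, "roasted")
    assert set(prof.index) == set(latent.index)
    res, _ = spearman_screen(conc, prof)
    assert res.set_index("compound").loc["2E35DM", "rho"] > 0.5
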