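"""Odds-ratio estimation: closed forms, oracles and parameter recovery."""

from __future__ import annotations

import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from citenet import (
    annotate_paths,
    build_authority_table,
    build_citation_edges,
    covariate_frame,
    enumerate_paths,
)
from citenet.regression import (
    ModelSpec,
    categorize,
    contingency_or,
    discordance_test,
    fit_citation_model,
    fit_concordance_model,
    fit_logit_random_intercept,
    round_or,
)
from citenet.synthetic_network import SyntheticConfig, generate_network

from conftest import make_attrs, make_record


def frame_for(config: SyntheticConfig) -> pd.DataFrame:
    records, _, _ = generate_network(config)
    edges = build_citation_edges(records)
    dataset = enumerate_paths(records, edges)
    annotate_paths(dataset, records, build_authority_table(records, edges))
    return covariate_frame(dataset, records)


def binary_frame(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Expand a 2x2 table into a minimal one-binary-determinant path table."""
    rows = []
    for flag, realized, count in [(True, 1, a), (True, 0, b), (False, 1, c), (False, 0, d)]:
        rows += [{"self_citation": flag, "realized": realized}] * count
    frame = pd.DataFrame(rows)
    frame["citing_id"] = [f"G{i % 20}" for i in range(len(frame))]
    return frame


class TestContingencyOR:
    def test_published_self_citation_counts_reproduce_crude_or(self):
        oddsratio, lo, hi = contingency_or(54, 30, 137, 349)
        assert (round_or(oddsratio), round_or(lo), round_or(hi)) == (4.6, 2.8, 7.5)

    def test_symmetric_table_gives_unity(self):
        oddsratio, lo, hi = contingency_or(10, 10, 10, 10)
        assert oddsratio == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_computed_wald_interval(self):
        # OR 16, se = sqrt(4/20 + 2/5) ... = 0.70711, CI exp(2.7726 +- 1.3859)
        oddsratio, lo, hi = contingency_or(20, 5, 5, 20)
        assert oddsratio == pytest.approx(16.0)
        assert lo == pytest.approx(4.00175, rel=1e-4)
        assert hi == pytest.approx(63.9721, rel=1e-4)

    def test_zero_cell_is_an_error_not_a_correction(self):
        with pytest.raises(ValueError):
            contingency_or(10, 0, 5, 5)


class TestFixedEffectsLogit:
    def test_single_binary_determinant_equals_cross_product(self):
        frame = binary_frame(54, 30, 137, 349)
        res = fit_citation_model(
            frame, ModelSpec(determinant="self_citation", estimator="fixed")
        )
        expected, lo, hi = contingency_or(54, 30, 137, 349)
        eff = res.effect()
        assert eff.odds_ratio == pytest.approx(expected, abs=1e-6)
        assert eff.ci_low == pytest.approx(lo, rel=1e-4)
        assert eff.ci_high == pytest.approx(hi, rel=1e-4)
        assert eff.ci_low <= eff.odds_ratio <= eff.ci_high

    def test_ci_width_shrinks_like_root_n(self):
        narrow = fit_citation_model(
            binary_frame(54 * 4, 30 * 4, 137 * 4, 349 * 4),
            ModelSpec(determinant="self_citation", estimator="fixed"),
        ).effect()
        wide = fit_citation_model(
            binary_frame(54, 30, 137, 349),
            ModelSpec(determinant="self_citation", estimator="fixed"),
        ).effect()
        ratio = math.log(wide.ci_high / wide.ci_low) / math.log(
            narrow.ci_high / narrow.ci_low
        )
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_single_level_determinant_reports_non_convergence(self):
        frame = binary_frame(54, 30, 137, 349)
        frame["self_citation"] = True
        res = fit_citation_model(
            frame, ModelSpec(determinant="self_citation", estimator="fixed")
        )
        assert not res.converged and "single level" in res.message
        assert res.effects == []

    def test_separated_determinant_reports_non_convergence(self):
        frame = binary_frame(50, 1, 1, 50)
        frame["realized"] = frame["self_citation"].astype(int)  # perfect sep
        res = fit_citation_model(
            frame, ModelSpec(determinant="self_citation", estimator="fixed")
        )
        assert not res.converged


class TestRandomInterceptEstimator:
    @staticmethod
    def _simulate(seed=42, G=40, m=12, sd=0.7):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(G), m)
        x = rng.binomial(1, 0.3, size=G * m).astype(float)
        b = rng.normal(0, sd, G)
        eta = -0.5 + 1.2 * x + b[g]
        y = (rng.random(G * m) < 1 / (1 + np.exp(-eta))).astype(float)
        return y, np.column_stack([np.ones(G * m), x]), g

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        """Cross-check the in-package AGQ fit against R's glmer (nAGQ=15)."""
        y, X, g = self._simulate()
        fit = fit_logit_random_intercept(y, X, g, n_quad=15)
        assert fit.converged
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([y, X[:, 1], g]), delimiter=",",
                   header="y,x,g", comments="")
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15);"
            "s <- summary(m);"
            "cat(fixef(m), coef(s)[,2], attr(VarCorr(m)$g, 'stddev'), sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        b0, b1, se0, se1, sigma = map(float, out.stdout.strip().split(","))
        assert fit.params == pytest.approx([b0, b1], abs=2e-3)
        assert fit.bse == pytest.approx([se0, se1], abs=2e-3)
        assert fit.sigma == pytest.approx(sigma, abs=1e-2)

    def test_collapses_to_fixed_effects_when_variance_vanishes(self):
        config = SyntheticConfig(
            n_articles=40, coefficients={"self_citation": math.log(4)},
            intercept=-1.0, random_intercept_sd=0.0, group_structure=(7, 7),
            community_article_probs=(0.35, 0.35), author_pool_size=80, seed=11,
        )
        frame = frame_for(config)
        ri = fit_citation_model(
            frame, ModelSpec(determinant="self_citation")
        )
        a = int(((frame.self_citation) & (frame.realized == 1)).sum())
        b = int(((frame.self_citation) & (frame.realized == 0)).sum())
        c = int(((~frame.self_citation) & (frame.realized == 1)).sum())
        d = int(((~frame.self_citation) & (frame.realized == 0)).sum())
        expected, _, _ = contingency_or(a, b, c, d)
        assert ri.converged
        assert ri.random_intercept_sd == pytest.approx(0.0, abs=1e-3)
        assert ri.effect().odds_ratio == pytest.approx(expected, abs=1e-3)

    def test_cluster_count_reported(self):
        config = SyntheticConfig(n_articles=25, intercept=-0.5, seed=3)
        frame = frame_for(config)
        res = fit_citation_model(frame, ModelSpec(determinant="time_to_citation"))
        assert res.n_citing_clusters == frame["citing_id"].nunique()


class TestConcordanceModel:
    def test_constant_concordance_cannot_be_fitted(self):
        frame = binary_frame(10, 10, 10, 10)
        frame["conc_authors_conclusion"] = True
        frame["article_type"] = "empirical"
        res = fit_concordance_model(frame, "authors_conclusion")
        assert not res.converged

    def test_null_effect_estimates_center_on_unity(self):
        estimates, covered = [], 0
        for rep in range(30):
            config = SyntheticConfig(
                n_articles=30, intercept=-0.7, seed=500 + rep,
            )
            res = fit_concordance_model(frame_for(config), "authors_conclusion")
            if not res.converged:
                continue
            e = res.effect()
            estimates.append(e.coef)
            covered += e.ci_low <= 1.0 <= e.ci_high
        assert len(estimates) >= 25
        assert np.mean(estimates) == pytest.approx(0.0, abs=0.1)
        assert covered / len(estimates) >= 0.85

    def test_planted_concordance_effect_recovered(self):
        estimates = []
        for rep in range(30):
            config = SyntheticConfig(
                n_articles=45, year_range=(2000, 2015), intercept=-1.0,
                coefficients={"concordant_conclusion": 0.7}, seed=900 + rep,
            )
            res = fit_concordance_model(frame_for(config), "authors_conclusion")
            assert res.converged
            estimates.append(res.effect().coef)
        assert np.mean(estimates) == pytest.approx(0.7, abs=0.2)


class TestDiscordanceTest:
    @staticmethod
    def _records(pp, pn, np_, nn):
        records = []
        i = 0
        for (dbc, ac), count in {
            ("positive", "positive"): pp,
            ("positive", "negative"): pn,
            ("negative", "positive"): np_,
            ("negative", "negative"): nn,
        }.items():
            for _ in range(count):
                i += 1
                records.append(
                    make_record(
                        f"R{i}", epub="2005-01",
                        attributes=make_attrs(
                            data_based_conclusion=dbc, authors_conclusion=ac
                        ),
                    )
                )
        return records

    def test_perfect_association_equals_sample_size(self):
        chi2, dof, p, table = discordance_test(self._records(10, 0, 0, 10))
        assert (chi2, dof) == (pytest.approx(20.0), 1)
        assert p < 1e-4
        assert table.to_numpy().tolist() == [[10, 0], [0, 10]]

    def test_independent_balanced_table_gives_zero(self):
        chi2, *_ = discordance_test(self._records(5, 5, 5, 5))
        assert chi2 == pytest.approx(0.0)

    def test_asymmetric_spin_detected(self):
        # 40% of negative results written up as positive; no positive result
        # written up as negative -> positive statistic, asymmetric table
        rng = np.random.default_rng(8)
        pp = 12
        negatives = 30
        flipped = int(round(0.4 * negatives))
        records = self._records(pp, 0, flipped, negatives - flipped)
        chi2, dof, p, table = discordance_test(records)
        assert chi2 > 0
        assert table.loc["data-positive", "authors-not-positive"] == 0
        assert table.loc["data-negative", "authors-positive"] > 0

    def test_empty_margin_is_an_error(self):
        with pytest.raises(ValueError):
            discordance_test(self._records(10, 5, 0, 0))

    def test_type_one_error_near_nominal_under_the_null(self):
        """Null rejection rate of the chi-square at n=100 stays near 5%."""
        rng = np.random.default_rng(123)
        reps, n = 2000, 100
        rejections = 0
        usable = 0
        from scipy.stats import chi2_contingency

        for _ in range(reps):
            dbc = rng.random(n) < 0.4
            ac = rng.random(n) < 0.5
            table = np.array(
                [
                    [np.sum(dbc & ac), np.sum(dbc & ~ac)],
                    [np.sum(~dbc & ac), np.sum(~dbc & ~ac)],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            usable += 1
            _, p, _, _ = chi2_contingency(table, correction=False)
            rejections += p < 0.05
        assert usable == reps
        assert rejections / usable == pytest.approx(0.05, abs=0.02)


class TestCategorize:
    @pytest.mark.parametrize(
        "attribute, value, expected",
        [
            ("sample_size", 150, "low"),
            ("sample_size", 200, "medium"),
            ("sample_size", 2000, "high"),
            ("n_references", 40, ">=40"),  # boundary goes to the upper band
            ("n_references", 24, "<25"),
            ("journal_impact_factor", 2.0, "2-4"),
            ("journal_impact_factor", 1.99, "0-2"),
            ("authority", 5, "low"),
            ("authority", 51, "high"),
            ("n_authors", 7, ">=7"),
            ("n_affiliations", 3, ">=3"),
            ("time_to_citation", 0.5, "0-<1"),
            ("time_to_citation", 8.2, ">=8"),
        ],
    )
    def test_bands(self, attribute, value, expected):
        assert categorize(attribute, value) == expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            categorize("sample_size", -1)

    def test_missing_passes_through(self):
        assert categorize("sample_size", None) is None


class TestModelSpecValidation:
    def test_determinant_among_covariates_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(determinant="article_type", covariates=("article_type",))

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(determinant="x", estimator="bayes")
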