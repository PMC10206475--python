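"""Mixed-model wrappers and printed effect-size formulas."""

import math

import numpy as np
import pandas as pd
import pytest

from matrinet.models import (
    MODEL_SPECS,
    age_change_percent,
    build_model_table,
    fit_batch,
    fit_binomial_glmm,
    lmm_range_percent,
    model_formula,
    odds_percent,
    sex_effect_percent,
    spec_by_label,
)

GAUSS = spec_by_label("MP1b proximity")
BINOM = spec_by_label("MP1a proximity")


def gaussian_table(n_immatures=60, n_periods=10, beta_age=-0.02, seed=0):
    rng = np.random.default_rng(seed)
    mothers = [f"m{k // 2}" for k in range(n_immatures)]
    sex = rng.integers(0, 2, n_immatures)
    age0 = rng.uniform(3, 40, n_immatures)
    u_m = {m: rng.normal(0, 0.2) for m in set(mothers)}
    u_i = rng.normal(0, 0.2, n_immatures)
    rows = []
    for p in range(n_periods):
        year = 2019 + p // 5
        for i in range(n_immatures):
            age = age0[i] + 2 * p
            y = (
                0.5
                + beta_age * age
                + 0.1 * sex[i]
                - 0.005 * age * sex[i]
                + u_m[mothers[i]]
                + u_i[i]
                + rng.normal(0, 0.3)
            )
            rows.append(
                dict(
                    model="toy",
                    troop="T1" if i < n_immatures // 2 else "T2",
                    period_index=p,
                    year=year,
                    immature=f"i{i}",
                    mother=mothers[i],
                    age=age,
                    sex=int(sex[i]),
                    n_offspring=1 + (i % 3),
                    mother_rank=(i % 10) / 10,
                    y=y,
                )
            )
    return pd.DataFrame(rows)


class TestModelTable:
    def test_duplicate_rows_rejected(self):
        df = gaussian_table(4, 2)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            build_model_table(dup, GAUSS)

    def test_missing_covariates_dropped(self):
        df = gaussian_table(4, 2)
        df.loc[0, "mother_rank"] = np.nan
        out = build_model_table(df, GAUSS)
        assert len(out) == len(df) - 1

    def test_complete_grid_size(self):
        assert len(build_model_table(gaussian_table(2, 3), GAUSS)) == 6


class TestFormula:
    def test_binomial_lhs_and_random_effects(self):
        df = gaussian_table(4, 2)
        f = model_formula(BINOM, df)
        assert f.startswith("cbind(k, n - k) ~")
        assert "(1 | mother / immature)" in f and "(1 | year)" not in f

    def test_single_level_factors_dropped(self):
        df = gaussian_table(4, 2)
        df["troop"] = "T1"
        assert "troop" not in model_formula(GAUSS, df)
        df2 = gaussian_table(4, 12)  # spans two years
        assert "(1 | year)" in model_formula(GAUSS, df2)

    def test_mother_metric_included_when_spec_requires(self):
        spec = spec_by_label("MP2a proximity")
        df = gaussian_table(4, 2).assign(mother_metric=0.0)
        assert "mother_metric" in model_formula(spec, df)


class TestLMM:
    def test_parameter_recovery_and_shift_equivariance(self):
        """A known age slope is recovered within 3 s.e.; adding a constant
        to the response moves only the intercept."""
        df = build_model_table(gaussian_table(60, 10, beta_age=-0.02), GAUSS)
        shifted = df.assign(y=df.y + 5.0, **{".replicate": 1})
        fits = fit_batch(pd.concat([df.assign(**{".replicate": 0}), shifted]), GAUSS)
        fit, fit_shift = fits[0], fits[1]
        assert fit.converged
        assert abs(fit.estimate("age") - (-0.02)) < 3 * fit.se("age")
        assert fit_shift.estimate("(Intercept)") - fit.estimate("(Intercept)") == pytest.approx(5.0, abs=1e-6)
        assert fit_shift.estimate("age") == pytest.approx(fit.estimate("age"), abs=1e-8)

    def test_row_order_invariance(self):
        df = build_model_table(gaussian_table(20, 4), GAUSS)
        rev = df.iloc[::-1].reset_index(drop=True)
        a = fit_batch(df, GAUSS)[0]
        b = fit_batch(rev, GAUSS)[0]
        assert a.estimate("age") == pytest.approx(b.estimate("age"), abs=1e-8)


class TestBinomialGLMM:
    def test_degenerate_response_flagged(self):
        df = gaussian_table(6, 2).drop(columns="y")
        df["n"] = 10
        df["k"] = 10
        fit = fit_binomial_glmm(build_model_table(df, BINOM), BINOM)
        assert not fit.converged
        assert "degenerate" in fit.messages


class TestEffectFormulas:
    def test_odds_percent_identities(self):
        assert odds_percent(0.0) == 0.0
        assert odds_percent(math.log(2)) == pytest.approx(100.0)

    def test_odds_percent_log_roundtrip(self):
        for pct in (-75.0, -12.5, 0.0, 33.0, 250.0):
            assert odds_percent(math.log(1 + pct / 100)) == pytest.approx(pct)

    def test_age_change_zero_slope(self):
        assert age_change_percent(0.0) == 0.0

    def test_age_change_uses_interaction_for_males(self):
        female = age_change_percent(-0.01, -0.01, male=False)
        male = age_change_percent(-0.01, -0.01, male=True)
        assert male < female < 0

    def test_lmm_range_arithmetic(self):
        assert lmm_range_percent(-0.01, 2.0) == pytest.approx(-18.0)
        assert lmm_range_percent(0.0, 2.0) == 0.0
        assert lmm_range_percent(-0.01, 4.0) == pytest.approx(-9.0)

    def test_lmm_range_requires_positive_range(self):
        with pytest.raises(ValueError):
            lmm_range_percent(1.0, 0.0)

    def test_sex_effect_at_age(self):
        assert sex_effect_percent(0.0, 0.0, 30) == 0.0
        assert sex_effect_percent(math.log(2), 0.0, 30) == pytest.approx(100.0)


class TestModelRoster:
    def test_permutation_methods_follow_protocol(self):
        """Time-with-mother models are never permutation-tested; grooming and
        the partner-composition proximity models use node permutations; all
        other proximity models use datastream permutations."""
        for spec in MODEL_SPECS:
            if spec.name == "MP1a":
                assert spec.permutation is None
            elif spec.kind == "grooming":
                assert spec.permutation == "node"
            elif spec.name.startswith("MP2c"):
                assert spec.permutation == "node"
            else:
                assert spec.permutation == "datastream"

    def test_roster_covers_all_model_network_rows(self):
        assert len(MODEL_SPECS) == 34
        assert len({s.label for s in MODEL_SPECS}) == 34
        metric_specs = [s for s in MODEL_SPECS if s.name in ("MP2a", "MP2b.1", "MP2b.2")]
        assert all(s.mother_metric for s in metric_specs)
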