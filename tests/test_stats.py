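"""Model fitting vs independent oracles, assumption checks, post-hoc."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from calokit.metadata import MetadataTable
from calokit.stats import (
    AssumptionReport,
    ModelSpec,
    StatsError,
    adjust_pvalues,
    build_analysis_table,
    check_assumptions,
    fit_model,
    posthoc,
    significance_stars,
)
from calokit.synthetic import CohortSimParams, simulate_cohort_summary


# ---------------------------------------------------------------------------
# independent Type-II F-test oracle (explicit least squares, no statsmodels)
# ---------------------------------------------------------------------------

def _design(table, factors, covariates, drop=None):
    """Dummy-coded design matrix, optionally omitting one term."""
    cols = [np.ones(len(table))]
    for f in factors:
        if f == drop:
            continue
        levels = sorted(table[f].astype(str).unique())
        for lv in levels[1:]:
            cols.append((table[f].astype(str) == lv).to_numpy(dtype=float))
    for c in covariates:
        if c == drop:
            continue
        cols.append(table[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _sse(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), X.shape[1]


def oracle_type2_f(table, response, factors, covariates, term):
    """Type-II F and p for one term via explicit model comparison."""
    y = table[response].to_numpy(dtype=float)
    sse_full, p_full = _sse(y, _design(table, factors, covariates))
    sse_red, p_red = _sse(y, _design(table, factors, covariates, drop=term))
    df_num = p_full - p_red
    df_den = len(y) - p_full
    f = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
    return f, float(scipy.stats.f.sf(f, df_num, df_den))


def _random_design(rng):
    n_levels = int(rng.integers(2, 5))
    n_per = int(rng.integers(4, 9))
    with_cov = bool(rng.integers(0, 2))
    rows = []
    for li in range(n_levels):
        for _ in range(n_per):
            cov = rng.normal(25, 3)
            rows.append({
                "group": f"g{li}",
                "body_mass": cov,
                "y": rng.normal(li * rng.uniform(0, 1), 1.0) + 0.1 * cov,
            })
    return pd.DataFrame(rows), with_cov


def test_model_pvalues_match_bruteforce_oracle_on_random_designs():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        table, with_cov = _random_design(rng)
        covs = ["body_mass"] if with_cov else []
        spec = ModelSpec(response="y", factors=["group"], covariates=covs)
        res = fit_model(table, spec)
        row = res.model_table.set_index("term").loc["C(group)"]
        f_o, p_o = oracle_type2_f(table, "y", ["group"], covs, "group")
        assert row["statistic"] == pytest.approx(f_o, rel=1e-8)
        assert row["p"] == pytest.approx(p_o, abs=1e-6)
        if with_cov:
            row_c = res.model_table.set_index("term").loc["body_mass"]
            f_c, p_c = oracle_type2_f(table, "y", ["group"], covs, "body_mass")
            assert row_c["p"] == pytest.approx(p_c, abs=1e-6)


def test_two_way_anova_matches_oracle():
    rng = np.random.default_rng(5)
    rows = []
    for g in "ab":
        for s in "mf":
            for _ in range(6):
                rows.append({"geno": g, "sex": s,
                             "y": rng.normal((g == "a") * 1.5 + (s == "m") * 0.5, 1)})
    table = pd.DataFrame(rows)
    spec = ModelSpec(response="y", factors=["geno", "sex"])
    res = fit_model(table, spec).model_table.set_index("term")
    for term in ("geno", "sex"):
        _, p_o = oracle_type2_f(table, "y", ["geno", "sex"], [], term)
        assert res.loc[f"C({term})", "p"] == pytest.approx(p_o, abs=1e-6)


def test_known_shift_detected_and_matches_oracle():
    rng = np.random.default_rng(11)
    table = pd.DataFrame({
        "group": ["A"] * 10 + ["B"] * 10,
        "y": np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10)]),
    })
    spec = ModelSpec(response="y", factors=["group"])
    res = fit_model(table, spec)
    p = res.model_table.set_index("term").loc["C(group)", "p"]
    _, p_o = oracle_type2_f(table, "y", ["group"], [], "group")
    assert p < 0.05
    assert p == pytest.approx(p_o, abs=1e-8)


def test_identical_responses_give_zero_statistic():
    table = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5, "y": 3.0})
    res = fit_model(table, ModelSpec(response="y", factors=["group"]))
    stat = res.model_table.set_index("term").loc["C(group)", "statistic"]
    assert stat == pytest.approx(0.0, abs=1e-20) or np.isnan(stat)


def test_rank_deficient_design_names_aliased_terms():
    table = pd.DataFrame({
        "group": ["A"] * 5 + ["B"] * 5,
        "copy": ["A"] * 5 + ["B"] * 5,   # perfectly aliased with group
        "y": np.arange(10.0),
    })
    with pytest.raises(StatsError, match="rank deficient"):
        fit_model(table, ModelSpec(response="y", factors=["group", "copy"]))


def test_ancova_estimates_group_effect_with_nominal_coverage():
    """95% CI of the ANCOVA group contrast covers the true effect ~95% of
    the time across seeded cohort draws."""
    true_effect = 2.0
    covered = 0
    n_sim = 200
    for seed in range(n_sim):
        t = simulate_cohort_summary(CohortSimParams(
            n_per_group=8, group_effect=true_effect, seed=10_000 + seed))
        res = fit_model(t, ModelSpec(response="response", factors=["group"],
                                     covariates=["body_mass"]))
        ci = res.fit.conf_int().loc["C(group)[T.B]"]
        covered += ci[0] <= true_effect <= ci[1]
    assert 0.90 <= covered / n_sim <= 0.99


def test_poisson_family_fits_count_response():
    rng = np.random.default_rng(4)
    table = pd.DataFrame({
        "group": ["A"] * 30 + ["B"] * 30,
        "y": np.concatenate([rng.poisson(5, 30), rng.poisson(9, 30)]),
    })
    res = fit_model(table, ModelSpec(response="y", factors=["group"],
                                     family="poisson"))
    p = res.model_table.set_index("term").loc["C(group)", "p"]
    assert p < 0.01


def test_assumption_checks_match_reference_stats():
    rng = np.random.default_rng(77)
    table = pd.DataFrame({
        "group": ["A"] * 20 + ["B"] * 20,
        "y": rng.normal(0, 1, 40),
    })
    spec = ModelSpec(response="y", factors=["group"])
    report = check_assumptions(table, spec)
    assert report.shapiro_passed and report.levene_passed
    # residuals of a one-factor model are the group-centred values
    resid = table["y"] - table.groupby("group")["y"].transform("mean")
    assert report.shapiro_p == pytest.approx(
        scipy.stats.shapiro(resid).pvalue, abs=1e-10)


def test_assumption_checks_match_r_reference():
    """Cross-check Shapiro-Wilk and median-centred Levene against R
    (stats::shapiro.test, car::leveneTest) on a fixed dataset."""
    rng = np.random.default_rng(123)
    y = np.round(rng.normal(10, 2, 24), 6)
    groups = ["A"] * 12 + ["B"] * 12
    table = pd.DataFrame({"group": groups, "y": y})
    spec = ModelSpec(response="y", factors=["group"])
    report = check_assumptions(table, spec)
    resid = table["y"] - table.groupby("group")["y"].transform("mean")
    r_code = f"""
    y <- c({', '.join(map(str, resid.tolist()))})
    raw <- c({', '.join(map(str, y.tolist()))})
    g <- factor(c({', '.join(repr(g) for g in groups)}))
    cat(shapiro.test(y)$p.value, "\n")
    suppressMessages(library(car))
    cat(leveneTest(raw ~ g, center=median)$`Pr(>F)`[1], "\n")
    """
    out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                         text=True, check=True)
    shapiro_r, levene_r = (float(v) for v in out.stdout.split())
    assert report.shapiro_p == pytest.approx(shapiro_r, abs=1e-6)
    assert report.levene_p == pytest.approx(levene_r, abs=1e-6)


def test_heavy_tailed_residuals_fail_shapiro():
    rng = np.random.default_rng(3)
    table = pd.DataFrame({
        "group": ["A"] * 25 + ["B"] * 25,
        "y": rng.standard_cauchy(50),
    })
    report = check_assumptions(table, ModelSpec(response="y", factors=["group"]))
    assert report.shapiro_passed is False


def test_tiny_groups_reported_not_computable():
    table = pd.DataFrame({"group": ["A", "B"], "y": [1.0, 2.0]})
    report = check_assumptions(table, ModelSpec(response="y", factors=["group"]))
    assert report.shapiro_passed is None
    assert report.levene_passed is None


def test_build_analysis_table_joins_metric_and_factors():
    rmr = pd.DataFrame({"animal_id": ["A1", "A2"], "rmr": [8.0, 9.0],
                        "tee": [250.0, 260.0], "aee": [58.0, 44.0]})
    meta = MetadataTable(pd.DataFrame({
        "animal_id": ["A1", "A2"], "genotype": ["wildtype", "knockout"],
        "body_mass": [24.0, 26.0]}))
    table = build_analysis_table(None, rmr, meta, "rmr")
    assert list(table.columns) == ["animal_id", "rmr", "genotype", "body_mass"]
    with pytest.raises(StatsError, match="unavailable"):
        build_analysis_table(None, rmr, meta, "vo2max")


def test_holm_hand_vector():
    # sorted raw {0.01, 0.03, 0.04}: 3*0.01=0.03; 2*0.03=0.06; max(0.04, 0.06)=0.06
    adj = adjust_pvalues(np.array([0.01, 0.04, 0.03]), "holm")
    assert np.allclose(adj, [0.03, 0.06, 0.06])


@pytest.mark.parametrize("perm", list(itertools.permutations([0.01, 0.03, 0.04])))
def test_corrections_match_hand_computation_all_permutations(perm):
    raw = np.array(perm)
    order = np.argsort(raw)
    # hand Holm: step-down running maximum of (m - i) * p_(i)
    holm_sorted = np.maximum.accumulate(
        [(3 - i) * raw[order][i] for i in range(3)])
    holm = np.empty(3)
    holm[order] = np.minimum(holm_sorted, 1)
    assert np.allclose(adjust_pvalues(raw, "holm"), holm)
    assert np.allclose(adjust_pvalues(raw, "bonferroni"), np.minimum(3 * raw, 1))
    # hand BH: step-up running minimum of m/i * p_(i)
    bh_sorted = [3 / (i + 1) * raw[order][i] for i in range(3)]
    bh_sorted = np.minimum.accumulate(bh_sorted[::-1])[::-1]
    bh = np.empty(3)
    bh[order] = np.minimum(bh_sorted, 1)
    assert np.allclose(adjust_pvalues(raw, "BH"), bh)


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8))
def test_correction_monotonicity(ps):
    raw = np.array(ps)
    bonf = adjust_pvalues(raw, "bonferroni")
    holm = adjust_pvalues(raw, "holm")
    assert (bonf >= holm - 1e-12).all()
    assert (holm >= raw - 1e-12).all()


def test_posthoc_three_equal_groups_all_ns():
    table = pd.DataFrame({
        "group": ["A"] * 6 + ["B"] * 6 + ["C"] * 6,
        "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 3,
    })
    res = fit_model(table, ModelSpec(response="y", factors=["group"]))
    ph = posthoc(res, method="tukey")
    assert len(ph) == 3
    assert (ph["p_adj"] > 0.9).all()
    assert (ph["stars"] == "ns").all()


def test_posthoc_single_level_empty():
    from calokit.stats import StatResult
    table = pd.DataFrame({"group": ["A"] * 6, "y": np.arange(6.0)})
    spec = ModelSpec(response="y", factors=["group"])
    res = StatResult(model_table=pd.DataFrame(), spec=spec, data=table, fit=None)
    ph = posthoc(res, method="pairwise_t")
    assert len(ph) == 0
    # fitting itself refuses a single-level factor
    with pytest.raises(StatsError, match="single level"):
        fit_model(table, spec)


def test_posthoc_pairwise_t_adjusts_raw_p():
    rng = np.random.default_rng(8)
    table = pd.DataFrame({
        "group": np.repeat(["A", "B", "C"], 8),
        "y": np.concatenate([rng.normal(0, 1, 8), rng.normal(0.5, 1, 8),
                             rng.normal(3, 1, 8)]),
    })
    res = fit_model(table, ModelSpec(response="y", factors=["group"]))
    ph = posthoc(res, method="pairwise_t", correction="holm")
    assert (ph["p_adj"] >= ph["p_raw"] - 1e-12).all()
    assert ph.loc[ph["pair"] == "A vs C", "stars"].iloc[0] in ("**", "***")


def test_significance_star_codes():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.5) == "ns"
    with pytest.raises(StatsError):
        significance_stars(1.5)


def test_type_one_error_calibrated_on_null_cohorts():
    hits = 0
    n_sim = 500
    for seed in range(n_sim):
        t = simulate_cohort_summary(CohortSimParams(n_per_group=8,
                                                    group_effect=0.0, seed=seed))
        res = fit_model(t, ModelSpec(response="response", factors=["group"],
                                     covariates=["body_mass"]))
        hits += res.model_table.set_index("term").loc["C(group)", "p"] < 0.05
    assert 0.03 <= hits / n_sim <= 0.07


def test_power_against_two_kj_effect():
    hits = 0
    n_sim = 200
    for seed in range(n_sim):
        t = simulate_cohort_summary(CohortSimParams(
            n_per_group=8, group_effect=2.0, seed=50_000 + seed))
        res = fit_model(t, ModelSpec(response="response", factors=["group"],
                                     covariates=["body_mass"]))
        hits += res.model_table.set_index("term").loc["C(group)", "p"] < 0.05
    assert hits / n_sim >= 0.8
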