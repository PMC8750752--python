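"""Descriptive battery: chi-square, rank tests, phi correlations, admissions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hcedecomp import (
    PanelDataset,
    admission_ratio,
    incurrence_chisq,
    occurrence_correlation,
    total_ihce_tests,
)
from hcedecomp.panel import IND_COLS


def _panel_from_arrays(sexes, ages, costs_by_t):
    """Build a small panel with one claims row per person per given t."""
    n = len(sexes)
    persons = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "sex": sexes,
            "birth_month": [
                (pd.Period("2016-01", "M") - int(a) * 12).strftime("%Y-%m") for a in ages
            ],
            "death_month": "2016-01",
            "coverage_months": 30,
        }
    )
    claims = pd.concat(
        [
            pd.DataFrame(
                {
                    "person_id": [f"p{i}" for i in range(n)],
                    "ttd": t,
                    "total_cost": costs,
                    "ind_circulatory": 1,
                    "ind_ckd": 0,
                    "ind_neoplasms": 0,
                    "ind_respiratory": 0,
                    "ind_others": 0,
                    "inpatient_flag": 0,
                }
            )
            for t, costs in costs_by_t.items()
        ],
        ignore_index=True,
    )
    return PanelDataset(persons, claims).validate()


def test_chisq_matches_textbook_two_by_two(mid_panel):
    """Sex-vs-incurrence chi-square equals scipy's Pearson statistic on the
    identical 2x2 table built by hand."""
    panel, _ = mid_panel
    res = incurrence_chisq(panel, t=6, disease="ckd", grouping="sex", fixed_age_group="65-75")
    # rebuild the table by hand
    attrs = panel.persons.copy()
    age = panel.age_at_death()
    attrs["age_group"] = age.map(lambda a: "65-75" if a < 75 else ("75-85" if a < 85 else "85-95"))
    attrs = attrs[attrs["age_group"] == "65-75"]
    claims = panel.claims
    inc = set(claims.loc[(claims["ttd"] == 6) & (claims["ind_ckd"] == 1), "person_id"])
    table = []
    for sex in ("M", "F"):
        ids = attrs.loc[attrs["sex"] == sex, "person_id"]
        k = ids.isin(inc).sum()
        table.append([k, len(ids) - k])
    chi2, p, df, _ = sps.chi2_contingency(np.array(table).T, correction=False)
    assert res.statistic == pytest.approx(chi2)
    assert res.p_value == pytest.approx(p)
    assert res.df == 1


def test_chisq_printed_count_example():
    """A 2x2 incurred/not table with counts 691/10,008 vs 299/4,855 gives
    the plain Pearson chi-square ~2.57, p ~0.11."""
    chi2, p, _, _ = sps.chi2_contingency(
        np.array([[691, 10008], [299, 4855]]).T, correction=False
    )
    assert chi2 == pytest.approx(2.566, abs=0.01)
    assert p == pytest.approx(0.109, abs=0.005)


def test_chisq_equal_rates_p_one():
    sexes = ["M"] * 10 + ["F"] * 10
    ages = [70] * 20
    costs = {0: [1.0] * 20}
    panel = _panel_from_arrays(sexes, ages, costs)
    # everyone incurred circulatory -> constant column; drop half per sex
    panel.claims.loc[panel.claims.index[:5], "ind_circulatory"] = 0
    panel.claims.loc[panel.claims.index[:5], "total_cost"] = 0.0
    panel.claims.loc[panel.claims.index[10:15], "ind_circulatory"] = 0
    panel.claims.loc[panel.claims.index[10:15], "total_cost"] = 0.0
    res = incurrence_chisq(panel, t=0, disease="circulatory", grouping="sex")
    assert res.p_value == pytest.approx(1.0)
    assert res.stars == ""


def test_chisq_type_one_error_calibrated(mid_panel):
    """With sex labels randomized, the sex test rejects at ~5%."""
    panel, _ = mid_panel
    rng = np.random.default_rng(0)
    rejections = 0
    n_rep = 200
    shuffled = panel.copy()
    for _ in range(n_rep):
        shuffled.persons["sex"] = rng.permutation(shuffled.persons["sex"].to_numpy())
        res = incurrence_chisq(shuffled, t=3, disease="respiratory", grouping="sex")
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01


def test_rank_tests_identical_groups():
    sexes = (["M"] * 10 + ["F"] * 10) * 3
    ages = [70] * 20 + [80] * 20 + [90] * 20
    costs = {0: list(np.tile(np.arange(1.0, 11.0), 6))}  # same costs in every group
    panel = _panel_from_arrays(sexes, ages, costs)
    out = total_ihce_tests(panel, t=0)
    assert out["kruskal_wallis_age"].p_value > 0.99
    assert out["wilcoxon_sex"].p_value > 0.9


def test_rank_tests_detect_age_gradient(mid_panel):
    """Age-decreasing generator costs produce decisive Kruskal-Wallis and
    Bonferroni-corrected pairwise differences."""
    panel, _ = mid_panel
    out = total_ihce_tests(panel, t=1)
    assert out["kruskal_wallis_age"].p_value < 0.001
    assert out["kruskal_wallis_age"].stars == "***"
    for key, res in out.items():
        if key.startswith("wilcoxon_") and "vs" in key:
            assert res.p_value < 0.01


def test_bonferroni_caps_at_one():
    rng = np.random.default_rng(1)
    sexes = ["M"] * 30 + ["F"] * 30
    ages = list(rng.choice([70, 80, 90], size=60))
    costs = {0: list(rng.uniform(1, 2, size=60))}
    panel = _panel_from_arrays(sexes, ages, costs)
    out = total_ihce_tests(panel, t=0)
    for key, res in out.items():
        assert not np.isfinite(res.p_value) or res.p_value <= 1.0


def test_skipped_groups_reported():
    sexes = ["M"] * 6
    ages = [70] * 6
    panel = _panel_from_arrays(sexes, ages, {0: [1.0] * 6})
    out = total_ihce_tests(panel, t=0)
    assert "skipped" in out["kruskal_wallis_age"].note
    assert "skipped" in out["wilcoxon_sex"].note


def test_occurrence_correlation_independent(mid_panel):
    panel, _ = mid_panel
    corr = occurrence_correlation(panel, t=6)
    off = corr.to_numpy()[~np.eye(5, dtype=bool)]
    assert np.nanmax(np.abs(off)) < 0.05
    assert np.allclose(np.diag(corr), 1.0)


def test_occurrence_correlation_perfect_pair():
    sexes = ["M"] * 20
    ages = [70] * 20
    panel = _panel_from_arrays(sexes, ages, {0: [1.0] * 20})
    rng = np.random.default_rng(2)
    half = rng.permutation(20) < 10
    panel.claims["ind_circulatory"] = half.astype(int)
    panel.claims["ind_ckd"] = half.astype(int)
    panel.claims["ind_others"] = (~half).astype(int)
    corr = occurrence_correlation(panel, t=0)
    assert corr.loc["circulatory", "ckd"] == pytest.approx(1.0)
    assert corr.loc["circulatory", "others"] == pytest.approx(-1.0)
    # constant columns are reported missing
    assert np.isnan(corr.loc["neoplasms", "respiratory"])


def test_copula_association_recovered_by_phi():
    from hcedecomp import default_generator_config, generate_panel
    from hcedecomp.panel import DISEASES
    from hcedecomp.simulate import latent_rho_for_phi

    rho = latent_rho_for_phi(0.3, 0.3, 0.11)
    cfg = default_generator_config(scale=5000, seed=37, copula_rho=rho)
    cfg.p[:, :, DISEASES.index("circulatory")] = 0.3
    cfg.p[:, :, DISEASES.index("ckd")] = 0.3
    panel, _ = generate_panel(cfg)
    corr = occurrence_correlation(panel, t=1)
    assert corr.loc["circulatory", "ckd"] == pytest.approx(0.11, abs=0.03)


def test_admission_ratio_bounds_and_ramp(mid_panel):
    panel, _ = mid_panel
    r0 = admission_ratio(panel, t=0)
    r6 = admission_ratio(panel, t=6)
    assert ((r0 >= 0) & (r0 <= 1)).all()
    assert (r0 > r6).all()  # admissions ramp up toward death


def test_admission_ratio_degenerate_flags():
    panel = _panel_from_arrays(["M"] * 8, [70] * 8, {0: [1.0] * 8})
    assert (admission_ratio(panel, t=0, scheme="none") == 0).all()
    panel.claims["inpatient_flag"] = 1
    assert (admission_ratio(panel, t=0, scheme="none") == 1).all()
    panel.claims = panel.claims.drop(columns=["inpatient_flag"])
    with pytest.raises(ValueError, match="inpatient_flag"):
        admission_ratio(panel, t=0)


def test_statistics_invariant_to_person_order(mid_panel):
    panel, _ = mid_panel
    shuffled = panel.copy()
    shuffled.claims = shuffled.claims.sample(frac=1, random_state=9).reset_index(drop=True)
    a = total_ihce_tests(panel, t=2)["kruskal_wallis_age"]
    b = total_ihce_tests(shuffled, t=2)["kruskal_wallis_age"]
    assert a.statistic == pytest.approx(b.statistic)
    pd.testing.assert_frame_equal(
        occurrence_correlation(panel, t=2), occurrence_correlation(shuffled, t=2)
    )
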