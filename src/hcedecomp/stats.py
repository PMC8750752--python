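"""Descriptive statistical battery over a decedent panel.

Chi-square tests of incurrence against sex or age group, rank tests
(Kruskal-Wallis, two-sample Wilcoxon rank-sum with Bonferroni correction)
on monthly total incurred cost, Pearson (phi) correlations of the binary
occurrence indicators, and admission ratios by time to death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import AGE_GROUPS, DISEASES, IND_COLS, PanelDataset, age_group_of

__all__ = [
    "TestResult",
    "incurrence_chisq",
    "total_ihce_tests",
    "occurrence_correlation",
    "admission_ratio",
]


@dataclass
class TestResult:
    """One hypothesis-test outcome with the conventional star annotation."""

    name: str
    statistic: float
    p_value: float
    n: int
    df: float | None = None
    note: str = ""

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _person_attrs(panel: PanelDataset) -> pd.DataFrame:
    p = panel.persons[["person_id", "sex"]].copy()
    p["age_group"] = panel.age_at_death().map(age_group_of)
    return p


def incurrence_chisq(
    panel: PanelDataset,
    t: int,
    disease: str,
    grouping: str = "age",
    fixed_sex: str | None = None,
    fixed_age_group: str | None = None,
) -> TestResult:
    """Pearson chi-square for group membership vs incurrence at one TTD.

    Builds the 2xK contingency table (incurred / not incurred by group),
    where "not incurred" counts the full group membership minus the
    incurrence count -- persons without a claim row at t count as not
    incurred. No continuity correction is applied. ``grouping`` is "age"
    (K=3, optionally within one sex) or "sex" (K=2, optionally within one
    age group). A warning note is attached when an expected cell is < 1.
    """
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}")
    attrs = _person_attrs(panel)
    if fixed_sex is not None:
        attrs = attrs[attrs["sex"] == fixed_sex]
    if fixed_age_group is not None:
        attrs = attrs[attrs["age_group"] == fixed_age_group]
    groups = AGE_GROUPS if grouping == "age" else ["M", "F"]
    col = "age_group" if grouping == "age" else "sex"

    claims = panel.claims
    at_t = claims[(claims["ttd"] == t) & (claims[f"ind_{disease}"] == 1)]
    incurred_ids = set(at_t["person_id"])

    table = []
    n = 0
    for g in groups:
        members = attrs.loc[attrs[col] == g, "person_id"]
        n_g = len(members)
        k = int(members.isin(incurred_ids).sum())
        table.append([k, n_g - k])
        n += n_g
    table = np.asarray(table).T  # 2 x K
    if (table.sum(axis=0) == 0).any():
        raise ValueError("a group has no members")
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    note = "2xK incurred/not-incurred vs group; no continuity correction"
    if (expected < 1).any():
        note += "; WARNING: expected cell < 1"
    return TestResult(
        name=f"chisq[{grouping}] {disease} t={t}",
        statistic=float(chi2),
        p_value=float(p),
        n=n,
        df=float(df),
        note=note,
    )


def total_ihce_tests(
    panel: PanelDataset, t: int, include_zero_nonusers: bool = False
) -> dict[str, TestResult]:
    """Rank tests on monthly total incurred cost at one TTD.

    The sample is the monthly total over records with at least one active
    indicator (zero-cost non-users excluded unless requested). Returns the
    Kruskal-Wallis test across the three age groups, the three pairwise
    two-sample Wilcoxon rank-sum tests with Bonferroni correction (raw p
    times 3, capped at 1), and the male-vs-female Wilcoxon rank-sum test.
    Groups with fewer than two observations are skipped with a note.
    """
    attrs = _person_attrs(panel).set_index("person_id")
    claims = panel.claims[panel.claims["ttd"] == t].copy()
    if not include_zero_nonusers:
        claims = claims[claims[IND_COLS].sum(axis=1) > 0]
    claims["age_group"] = claims["person_id"].map(attrs["age_group"])
    claims["sex"] = claims["person_id"].map(attrs["sex"])

    out: dict[str, TestResult] = {}
    by_age = [claims.loc[claims["age_group"] == a, "total_cost"].to_numpy() for a in AGE_GROUPS]
    if all(len(g) >= 2 for g in by_age):
        h, p = sps.kruskal(*by_age)
        out["kruskal_wallis_age"] = TestResult(
            name=f"kruskal-wallis age t={t}", statistic=float(h), p_value=float(p),
            n=sum(map(len, by_age)), df=float(len(by_age) - 1),
        )
    else:
        out["kruskal_wallis_age"] = TestResult(
            name=f"kruskal-wallis age t={t}", statistic=np.nan, p_value=np.nan,
            n=sum(map(len, by_age)), note="skipped: a group has < 2 observations",
        )

    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        key = f"wilcoxon_{AGE_GROUPS[i]}_vs_{AGE_GROUPS[j]}"
        a, b = by_age[i], by_age[j]
        if len(a) < 2 or len(b) < 2:
            out[key] = TestResult(name=key, statistic=np.nan, p_value=np.nan,
                                  n=len(a) + len(b), note="skipped: < 2 observations")
            continue
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        out[key] = TestResult(
            name=key + f" t={t}", statistic=float(u),
            p_value=min(float(p) * len(pairs), 1.0), n=len(a) + len(b),
            note="two-sample Wilcoxon rank-sum, Bonferroni x3",
        )

    males = claims.loc[claims["sex"] == "M", "total_cost"].to_numpy()
    females = claims.loc[claims["sex"] == "F", "total_cost"].to_numpy()
    if len(males) >= 2 and len(females) >= 2:
        u, p = sps.mannwhitneyu(males, females, alternative="two-sided")
        out["wilcoxon_sex"] = TestResult(
            name=f"wilcoxon M vs F t={t}", statistic=float(u), p_value=float(p),
            n=len(males) + len(females), note="two-sample Wilcoxon rank-sum",
        )
    else:
        out["wilcoxon_sex"] = TestResult(
            name=f"wilcoxon M vs F t={t}", statistic=np.nan, p_value=np.nan,
            n=len(males) + len(females), note="skipped: < 2 observations",
        )
    return out


def occurrence_correlation(panel: PanelDataset, t: int) -> pd.DataFrame:
    """5x5 Pearson correlation matrix of occurrence indicators at one TTD.

    For binary indicators this is the phi coefficient. A constant column
    (a disease that everyone or no one incurred) yields NaN entries, which
    are reported as missing. Persons without a claim row at t count as
    all-zero rows.
    """
    claims = panel.claims[panel.claims["ttd"] == t]
    if len(claims) < 2:
        raise ValueError(f"need at least 2 records at ttd={t}")
    ids = set(claims["person_id"])
    missing = panel.persons.loc[~panel.persons["person_id"].isin(ids), "person_id"]
    mat = claims[IND_COLS].to_numpy(dtype=float)
    if len(missing):
        mat = np.vstack([mat, np.zeros((len(missing), len(IND_COLS)))])
    corr = pd.DataFrame(mat, columns=DISEASES).corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def admission_ratio(panel: PanelDataset, t: int, scheme: str = "sex_age") -> pd.Series:
    """Share of each stratum's members with an inpatient month at one TTD.

    Requires the panel's ``inpatient_flag`` column; denominators are the
    full stratum memberships, so persons without a claim row count as not
    admitted.
    """
    if "inpatient_flag" not in panel.claims.columns:
        raise ValueError("inpatient_flag not populated: admission ratio unavailable")
    from .panel import assign_strata

    labels = assign_strata(panel, scheme)
    n_g = panel.persons.groupby(labels.values).size()
    claims = panel.claims[panel.claims["ttd"] == t]
    label_of = dict(zip(panel.persons["person_id"], labels))
    adm = claims.groupby(claims["person_id"].map(label_of))["inpatient_flag"].sum()
    out = (adm.reindex(n_g.index).fillna(0) / n_g).rename("admission_ratio")
    out.index.name = "stratum"
    return out
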