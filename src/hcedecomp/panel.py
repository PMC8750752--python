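"""Decedent claims panel: data model, disease grouping, filtering, stratification.

The panel is long-format: one row per (person, month-before-death). Costs are
monthly claimed totals normalized to units of 100,000 JPY; each row carries a
binary occurrence indicator per disease group. Time to death (TTD) ``t`` counts
whole months before the death month, with ``t = 0`` the month of death.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "IND_COLS",
    "AGE_GROUPS",
    "DiseaseGroup",
    "StratumKey",
    "PanelDataset",
    "FilterReport",
    "assign_disease_group",
    "age_group_of",
    "filter_decedents",
    "stratify",
    "assign_strata",
    "read_panel",
    "write_panel",
    "MAX_TTD",
]

#: Disease-group order used everywhere (columns, grids, generator).
DISEASES = ["circulatory", "ckd", "neoplasms", "respiratory", "others"]
IND_COLS = [f"ind_{d}" for d in DISEASES]

#: Age-at-death bins: half-open [65,75), [75,85) and closed [85,95].
AGE_GROUPS = ["65-75", "75-85", "85-95"]

#: TTD window: months 0..23 before death (~2 years).
MAX_TTD = 23

SCHEMES = ("none", "sex", "age", "sex_age")

_PERSON_COLS = ["person_id", "sex", "birth_month", "death_month", "coverage_months"]
_CLAIM_COLS = ["person_id", "ttd", "total_cost"] + IND_COLS + ["inpatient_flag"]


class DiseaseGroup(str, Enum):
    """The five ICD-10 disease groups the monthly cost is decomposed into."""

    CIRCULATORY = "circulatory"  # I00-I99
    CKD = "ckd"                  # N18 (incl. subcodes)
    NEOPLASMS = "neoplasms"      # C00-D48
    RESPIRATORY = "respiratory"  # J00-J99
    OTHERS = "others"            # everything else


_ICD_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.[0-9A-Z]{1,4})?$")


def assign_disease_group(icd10_code: str) -> DiseaseGroup:
    """Map an ICD-10 code to its disease group.

    Circulatory is I00-I99, CKD is N18 and its subcodes, neoplasms C00-D48,
    respiratory J00-J99; every other valid code falls into "others" (this
    includes e.g. diabetes E11 and all other N codes). The mapping is total
    over syntactically valid codes and N18 takes precedence within N.

    Raises
    ------
    ValueError
        If the code is not letter + two digits (+ optional subcode).
    """
    if not isinstance(icd10_code, str):
        raise ValueError(f"malformed ICD-10 code: {icd10_code!r}")
    m = _ICD_RE.match(icd10_code.strip().upper())
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {icd10_code!r}")
    letter, digits = m.group(1), m.group(2)
    if letter == "I":
        return DiseaseGroup.CIRCULATORY
    if letter == "N" and digits == "18":
        return DiseaseGroup.CKD
    if letter == "C" or (letter == "D" and int(digits) <= 48):
        return DiseaseGroup.NEOPLASMS
    if letter == "J":
        return DiseaseGroup.RESPIRATORY
    return DiseaseGroup.OTHERS


def age_group_of(age_at_death: float) -> str:
    """Assign an age at death (completed years) to one of the three bins.

    Bins are half-open at the internal boundaries so each decedent lands in
    exactly one group; 95 is included to honor the 65-95 eligibility range.
    """
    if not 65 <= age_at_death <= 95:
        raise ValueError(f"age at death {age_at_death} outside the 65-95 study range")
    if age_at_death < 75:
        return "65-75"
    if age_at_death < 85:
        return "75-85"
    return "85-95"


@dataclass(frozen=True)
class StratumKey:
    """Identifies one stratum g under a stratification scheme.

    G = 1, 2, 3 or 6 strata for schemes none, sex, age and sex_age.
    """

    scheme: str
    sex: str | None = None        # "M" / "F"
    age_group: str | None = None  # "65-75" / "75-85" / "85-95"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def label(self) -> str:
        if self.scheme == "none":
            return "all"
        if self.scheme == "sex":
            return str(self.sex)
        if self.scheme == "age":
            return str(self.age_group)
        return f"{self.sex}|{self.age_group}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def stratum_keys(scheme: str) -> list[StratumKey]:
    """All strata of a scheme, in canonical order (G = 1, 2, 3, 6)."""
    if scheme == "none":
        return [StratumKey("none")]
    if scheme == "sex":
        return [StratumKey("sex", sex=s) for s in ("M", "F")]
    if scheme == "age":
        return [StratumKey("age", age_group=a) for a in AGE_GROUPS]
    if scheme == "sex_age":
        return [
            StratumKey("sex_age", sex=s, age_group=a)
            for s in ("M", "F")
            for a in AGE_GROUPS
        ]
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class FilterReport:
    """Bookkeeping from eligibility filtering."""

    n_input: int = 0
    n_retained: int = 0
    n_missing_dates: int = 0
    n_short_coverage: int = 0
    n_age_out_of_range: int = 0
    n_death_outside_window: int = 0
    n_records_dropped: int = 0


def _months_between(later: pd.Series, earlier: pd.Series) -> pd.Series:
    """Whole calendar months from `earlier` to `later` (YYYY-MM periods)."""
    return (later.dt.year - earlier.dt.year) * 12 + (later.dt.month - earlier.dt.month)


def _to_period(s: pd.Series) -> pd.Series:
    return pd.PeriodIndex(s.astype(str), freq="M").to_timestamp().to_series(index=s.index)


@dataclass
class PanelDataset:
    """A decedent claims panel: persons plus long-format monthly claim rows.

    ``persons`` columns: person_id, sex (M/F), birth_month, death_month
    (YYYY-MM strings), coverage_months. ``claims`` columns: person_id,
    ttd (0-23), total_cost (100k-JPY units), ind_* indicator per disease
    group, inpatient_flag. ``metadata`` records the study window and the
    cost normalization unit.
    """

    persons: pd.DataFrame
    claims: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("cost_unit", "100,000 JPY")
        self.metadata.setdefault("study_window", ("2012-11", "2018-10"))

    # -- validation ---------------------------------------------------------

    def validate(self) -> "PanelDataset":
        """Check schema and invariants; raise ValueError on the first breach."""
        for col in _PERSON_COLS:
            if col not in self.persons.columns:
                raise ValueError(f"persons table missing column {col!r}")
        for col in _CLAIM_COLS[:3] + IND_COLS:
            if col not in self.claims.columns:
                raise ValueError(f"claims table missing column {col!r}")
        if "inpatient_flag" not in self.claims.columns:
            self.claims["inpatient_flag"] = 0
        if self.persons["person_id"].duplicated().any():
            raise ValueError("duplicate person_id in persons")
        known = set(self.persons["person_id"])
        unknown = set(self.claims["person_id"]) - known
        if unknown:
            raise ValueError(f"claims reference unknown person_ids: {sorted(unknown)[:5]}")
        if self.claims.duplicated(subset=["person_id", "ttd"]).any():
            raise ValueError("duplicate (person_id, ttd) pairs in claims")
        cost = pd.to_numeric(self.claims["total_cost"], errors="coerce")
        if cost.isna().any() or not np.isfinite(cost).all():
            raise ValueError("non-numeric or non-finite total_cost")
        if (cost < 0).any():
            raise ValueError("negative total_cost")
        ind = self.claims[IND_COLS]
        if not ind.isin([0, 1]).all().all():
            raise ValueError("indicator values outside {0,1}")
        none_active = ind.sum(axis=1) == 0
        if (cost[none_active] != 0).any():
            raise ValueError("record with zero indicators but nonzero total_cost")
        bad_sex = ~self.persons["sex"].isin(["M", "F"])
        if bad_sex.any():
            raise ValueError(f"invalid sex values: {self.persons.loc[bad_sex, 'sex'].unique()}")
        return self

    # -- derived quantities -------------------------------------------------

    def age_at_death(self) -> pd.Series:
        """Completed years at the death month, indexed like ``persons``."""
        p = self.persons
        has = p["death_month"].notna() & p["birth_month"].notna()
        out = pd.Series(np.nan, index=p.index)
        if has.any():
            death = _to_period(p.loc[has, "death_month"])
            birth = _to_period(p.loc[has, "birth_month"])
            out.loc[has] = _months_between(death, birth) // 12
        return out

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.persons.copy(), self.claims.copy(), dict(self.metadata))


def filter_decedents(
    panel: PanelDataset,
    min_coverage: int = 24,
    age_range: tuple[int, int] = (65, 95),
) -> PanelDataset:
    """Apply the eligibility filters for the end-of-life analysis.

    Retains persons who died inside the study window, had at least
    ``min_coverage`` months of coverage (read as consecutive enrollment
    ending at the death month), and were within ``age_range`` (inclusive)
    at death. Claim rows outside TTD 0-23 are dropped. A
    :class:`FilterReport` is stored under ``metadata['filter_report']``.
    """
    p = panel.persons
    report = FilterReport(n_input=len(p))
    win_lo, win_hi = panel.metadata.get("study_window", ("2012-11", "2018-10"))

    missing = p["death_month"].isna() | p["birth_month"].isna()
    report.n_missing_dates = int(missing.sum())
    ok = ~missing

    dm = p.loc[ok, "death_month"].astype(str)
    in_window = (dm >= win_lo) & (dm <= win_hi)
    report.n_death_outside_window = int((~in_window).sum())
    ok.loc[ok] = in_window

    short = p.loc[ok, "coverage_months"] < min_coverage
    report.n_short_coverage = int(short.sum())
    ok.loc[ok] = ~short

    age = panel.age_at_death()
    in_age = (age.loc[ok] >= age_range[0]) & (age.loc[ok] <= age_range[1])
    report.n_age_out_of_range = int((~in_age).sum())
    ok.loc[ok] = in_age

    persons = p.loc[ok].reset_index(drop=True)
    keep_ids = set(persons["person_id"])
    c = panel.claims
    in_ttd = c["ttd"].between(0, MAX_TTD)
    keep = c["person_id"].isin(keep_ids) & in_ttd
    report.n_records_dropped = int((c["person_id"].isin(keep_ids) & ~in_ttd).sum())
    claims = c.loc[keep].reset_index(drop=True)
    report.n_retained = len(persons)

    meta = dict(panel.metadata)
    meta["filter_report"] = report
    meta["filtered"] = True
    return PanelDataset(persons, claims, meta)


def assign_strata(panel: PanelDataset, scheme: str) -> pd.Series:
    """Stratum label for every person, indexed like ``panel.persons``."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    p = panel.persons
    if scheme == "none":
        return pd.Series("all", index=p.index)
    age_lab = None
    if scheme in ("age", "sex_age"):
        age = panel.age_at_death()
        age_lab = age.map(age_group_of)
    if scheme == "sex":
        return p["sex"].astype(str)
    if scheme == "age":
        return age_lab.astype(str)
    return p["sex"].astype(str) + "|" + age_lab.astype(str)


def stratify(panel: PanelDataset, scheme: str) -> dict[StratumKey, pd.DataFrame]:
    """Partition the panel's persons into strata under a scheme.

    Returns a map StratumKey -> persons sub-frame. The strata are disjoint
    and exhaustive (sum of N_g equals N); empty strata are included so the
    caller can flag them.
    """
    labels = assign_strata(panel, scheme)
    out: dict[StratumKey, pd.DataFrame] = {}
    for key in stratum_keys(scheme):
        out[key] = panel.persons.loc[labels == key.label]
    assert sum(len(v) for v in out.values()) == len(panel.persons)
    return out


# -- persistence ------------------------------------------------------------


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write ``persons.csv`` and ``claims.csv`` under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    panel.persons.to_csv(path / "persons.csv", index=False)
    panel.claims.to_csv(path / "claims.csv", index=False)


def read_panel(path: str | Path, metadata: dict | None = None) -> PanelDataset:
    """Read a panel written by :func:`write_panel`; validates on load."""
    path = Path(path)
    persons = pd.read_csv(path / "persons.csv", dtype={"person_id": str})
    claims = pd.read_csv(path / "claims.csv", dtype={"person_id": str})
    panel = PanelDataset(persons, claims, dict(metadata or {}))
    return panel.validate()
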