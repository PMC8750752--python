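"""Frequency part of the two-part model: occurrence proportions F_gtd.

F_gtd is the share of stratum-g members with at least one claim in disease
group d at t months before death. The denominator is the full stratum
membership N_g, not the number of claim rows: a decedent with no claims row
at month t contributes zero to every indicator. Note this differs from a
share-of-total-panel percentage (count / N), which is also provided because
descriptive tables are often printed on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import DISEASES, IND_COLS, MAX_TTD, PanelDataset, assign_strata

__all__ = ["FrequencyTable", "FrequencyModel", "compute_frequency", "frequency_table"]


@dataclass
class FrequencyTable:
    """Grid of occurrence proportions over (stratum, ttd, disease).

    ``table`` columns: stratum, ttd, disease, count, n_g, frequency,
    pct_of_total. Each frequency is count / N_g, so frequency * N_g is an
    integer by construction.
    """

    table: pd.DataFrame
    n_g: dict[str, int]
    scheme: str

    @property
    def n_total(self) -> int:
        return sum(self.n_g.values())

    def lookup(self, stratum: str, ttd: int, disease: str) -> float:
        t = self.table
        row = t[(t["stratum"] == stratum) & (t["ttd"] == ttd) & (t["disease"] == disease)]
        if row.empty:
            raise KeyError((stratum, ttd, disease))
        return float(row["frequency"].iloc[0])

    def grid(self, stratum: str) -> np.ndarray:
        """(24, 5) frequency array for one stratum."""
        sub = self.table[self.table["stratum"] == stratum]
        out = np.zeros((MAX_TTD + 1, len(DISEASES)))
        for d, dis in enumerate(DISEASES):
            s = sub[sub["disease"] == dis].set_index("ttd")["frequency"]
            out[s.index.to_numpy(), d] = s.to_numpy()
        return out

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def compute_frequency(indicators: np.ndarray, n_g: int) -> np.ndarray:
    """Occurrence proportion per disease for one (stratum, ttd) cell.

    ``indicators`` is an (n_records, 5) 0/1 array of the claim rows present
    in the cell; ``n_g`` is the full stratum membership used as the
    denominator (missing rows count as all-zero).
    """
    if n_g <= 0:
        raise ValueError("empty stratum: frequency undefined")
    ind = np.asarray(indicators)
    if ind.ndim != 2 or ind.shape[1] != len(DISEASES):
        raise ValueError(f"indicators must be (n, {len(DISEASES)})")
    return ind.sum(axis=0) / n_g


class FrequencyModel(BaseEstimator):
    """Estimator computing the full F_gtd grid from a panel.

    Parameters
    ----------
    scheme : {"none", "sex", "age", "sex_age"}
        Stratification of the panel (G = 1, 2, 3, 6).

    Attributes
    ----------
    frequency_ : FrequencyTable
        The fitted grid.
    n_g_ : dict
        Person count per stratum.
    """

    def __init__(self, scheme: str = "none"):
        self.scheme = scheme

    def fit(self, X: PanelDataset, y=None) -> "FrequencyModel":
        labels = assign_strata(X, self.scheme)
        n_g = X.persons.groupby(labels.values).size().to_dict()
        label_of = dict(zip(X.persons["person_id"], labels))
        claims = X.claims
        strat = claims["person_id"].map(label_of)

        counts = (
            claims[IND_COLS]
            .groupby([strat.values, claims["ttd"].values], sort=True)
            .sum()
        )
        rows = []
        for stratum in sorted(n_g):
            for t in range(MAX_TTD + 1):
                if (stratum, t) in counts.index:
                    c = counts.loc[(stratum, t)]
                else:
                    c = pd.Series(0, index=IND_COLS)
                for dis, col in zip(DISEASES, IND_COLS):
                    rows.append((stratum, t, dis, int(c[col]), n_g[stratum]))
        table = pd.DataFrame(rows, columns=["stratum", "ttd", "disease", "count", "n_g"])
        table["frequency"] = table["count"] / table["n_g"]
        table["pct_of_total"] = table["count"] / len(X.persons)
        self.frequency_ = FrequencyTable(table=table, n_g=n_g, scheme=self.scheme)
        self.n_g_ = n_g
        return self


def frequency_table(panel: PanelDataset, scheme: str = "none") -> FrequencyTable:
    """Compute the complete F_gtd grid for a panel under a scheme."""
    return FrequencyModel(scheme=scheme).fit(panel).frequency_
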