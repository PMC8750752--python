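"""Directional Bayes factors for differences in component means between strata.

Construction: under the shared, 0-symmetric Normal prior on the two means,
the prior odds of the directional composite hypotheses (delta > 0 vs
delta < 0) are 1, so the Bayes factor equals the posterior odds of the
favored direction: BF = max(P(delta>0), P(delta<0)) / min(...), estimated
from posterior draws of the difference. Evidence is binned on the
conventional scale: (1,3] not worth more than a bare mention, (3,20]
positive, (20,150] strong, above 150 very strong; BFs beyond 150 are
displayed as ">150" (with all draws on one side only a lower bound is
identified anyway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .severity import CellPosterior

__all__ = ["BFResult", "directional_bf", "categorize", "bf_table", "EVIDENCE_STARS"]

EVIDENCE_STARS = {"none": "", "positive": "*", "strong": "**", "very_strong": "***"}
_BF_CAP = 150.0


def categorize(bf: float) -> str:
    """Evidence bin for an oriented BF >= 1; boundaries go to the lower bin."""
    if bf < 1:
        raise ValueError("orient the BF first (bf must be >= 1)")
    if bf <= 3:
        return "none"
    if bf <= 20:
        return "positive"
    if bf <= _BF_CAP:
        return "strong"
    return "very_strong"


@dataclass(frozen=True)
class BFResult:
    """Oriented directional Bayes factor for one stratum pair and cell."""

    orientation: str       # e.g. "85-95 - 75-85"
    bf: float              # >= 1, may be inf
    sign: int              # +1 if the first stratum is larger, -1 otherwise
    evidence: str
    n_draws: int

    @property
    def capped_display(self) -> str:
        if self.bf > _BF_CAP:
            return ">150"
        return f"{self.bf:.1f}"

    @property
    def stars(self) -> str:
        return EVIDENCE_STARS[self.evidence]


def directional_bf(
    draws_a: np.ndarray,
    draws_b: np.ndarray,
    orientation: str = "a - b",
) -> BFResult:
    """BF for a directional difference between two posterior draw sets.

    Differences are formed by pairing equal-length draw streams; when the
    lengths differ, the longer stream is truncated (both streams are
    post-warmup pools across chains, so truncation is innocuous). Ties at
    exactly zero are split evenly between the directions.
    """
    a = np.asarray(draws_a, dtype=float).reshape(-1)
    b = np.asarray(draws_b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("both draw sets must be nonempty")
    n = min(a.size, b.size)
    delta = a[:n] - b[:n]
    if n < 1000:
        warnings.warn(
            f"only {n} difference draws: BF resolution limited to ~{n}", stacklevel=2
        )
    n_pos = float((delta > 0).sum()) + 0.5 * float((delta == 0).sum())
    n_neg = n - n_pos
    sign = 1 if n_pos >= n_neg else -1
    hi, lo = max(n_pos, n_neg), min(n_pos, n_neg)
    bf = np.inf if lo == 0 else hi / lo
    return BFResult(
        orientation=orientation,
        bf=float(bf),
        sign=sign,
        evidence=categorize(max(bf, 1.0)),
        n_draws=n,
    )


def bf_table(
    posteriors_a: dict[tuple[str, int], CellPosterior],
    posteriors_b: dict[tuple[str, int], CellPosterior],
    stratum_a: str,
    stratum_b: str,
    ttd_range: range = range(0, 13),
) -> pd.DataFrame:
    """Grid of directional BFs over TTD x disease for one stratum pair.

    Defaults to TTD 0-12, the window the headline comparisons print.
    Cells missing in either stratum are marked absent.
    """
    orientation = f"{stratum_a} - {stratum_b}"
    rows = []
    for t in ttd_range:
        cp_a = posteriors_a.get((stratum_a, t))
        cp_b = posteriors_b.get((stratum_b, t))
        diseases = set(cp_a.diseases if cp_a else []) | set(cp_b.diseases if cp_b else [])
        for dis in sorted(diseases):
            present = (
                cp_a is not None
                and cp_b is not None
                and dis in cp_a.diseases
                and dis in cp_b.diseases
            )
            if not present:
                rows.append(
                    dict(stratum_pair=orientation, ttd=t, disease=dis, bf=np.nan,
                         display="absent", stars="", evidence="absent", sign=0)
                )
                continue
            res = directional_bf(
                cp_a.mu_draws_for(dis), cp_b.mu_draws_for(dis), orientation
            )
            rows.append(
                dict(
                    stratum_pair=orientation,
                    ttd=t,
                    disease=dis,
                    bf=res.bf,
                    display=res.capped_display,
                    stars=res.stars,
                    evidence=res.evidence,
                    sign=res.sign,
                )
            )
    return pd.DataFrame(rows)
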