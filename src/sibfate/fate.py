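"""Survival and sibling fate-coupling statistics.

If each cell survives a semi-lethal challenge independently with probability
p, two siblings share a fate (both survive or both die) with probability
``p^2 + (1-p)^2`` — the chance coupling level.  This module bins cells /
sibling pairs by (predicted) relative cell-cycle position and tests, per
bin, whether survival deviates from the overall rate (two-sided Fisher's
exact test of the bin against its complement) and whether fate coupling
deviates from the chance level (exact two-sided binomial test against the
analytic null proportion; a bin-vs-complement Fisher variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .lineage import FATE_DIED, FATE_SURVIVED, LineageSet

__all__ = [
    "SiblingPair",
    "BinSummary",
    "CouplingTestResult",
    "expected_coupling",
    "survival_ci",
    "survival_by_bin",
    "coupling_by_bin",
    "overall_coupling_test",
    "make_sibling_pairs",
    "bins_to_frame",
]


@dataclass
class SiblingPair:
    """Two sisters, their average (predicted) cycle position and fates."""

    cell_a: str
    cell_b: str
    avg_x: float
    fate_a: str
    fate_b: str
    resus_a: float | None = None
    resus_b: float | None = None

    @property
    def coupled(self) -> bool:
        """True when both cells share the same fate."""
        return self.fate_a == self.fate_b

    @property
    def both_survived(self) -> bool:
        return self.fate_a == FATE_SURVIVED and self.fate_b == FATE_SURVIVED


@dataclass
class BinSummary:
    """One cycle-position bin of a binned proportion analysis."""

    lo: float
    hi: float
    n: int
    successes: int
    fraction: float
    null_fraction: float
    p_value: float
    significant: bool

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass
class CouplingTestResult:
    n: int
    n_coupled: int
    observed_fraction: float
    null_fraction: float
    p_value: float


def expected_coupling(p: float) -> float:
    """Chance probability that two independent Bernoulli(p) siblings share
    a fate: ``p^2 + (1-p)^2``.  Symmetric in p vs 1-p, minimum 0.5 at p=0.5."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"survival probability must be in [0, 1], got {p}")
    return p * p + (1.0 - p) ** 2


def survival_ci(
    p_hat: float, n: int, conf: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial survival fraction.

    Wilson score interval by default (it reproduces the intervals printed in
    the source analyses); ``method="wald"`` selects the normal-approximation
    interval.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    if not (0.0 < conf < 1.0):
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    sm_method = {"wilson": "wilson", "wald": "normal"}[method]
    lo, hi = proportion_confint(p_hat * n, n, alpha=1.0 - conf, method=sm_method)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def _bin_edges(n_bins: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_bins + 1)


def _bin_index(x: np.ndarray, n_bins: int) -> np.ndarray:
    # bins [0, 1/n), ..., [(n-1)/n, 1]  (last bin closed)
    idx = np.floor(np.asarray(x, dtype=float) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def survival_by_bin(
    x: np.ndarray,
    survived: np.ndarray,
    n_bins: int = 10,
    alpha: float = 0.01,
) -> list[BinSummary]:
    """Survival fraction per cycle-position bin, each bin tested against the
    complement of all other cells with a two-sided Fisher's exact test."""
    x = np.asarray(x, dtype=float)
    survived = np.asarray(survived, dtype=bool)
    if len(x) == 0:
        raise ValueError("no cells given")
    if len(x) != len(survived):
        raise ValueError("x and survived must have equal length")
    idx = _bin_index(x, n_bins)
    edges = _bin_edges(n_bins)
    total_s = int(survived.sum())
    total_n = len(survived)
    out = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        s = int(survived[m].sum())
        if n == 0:
            out.append(
                BinSummary(edges[b], edges[b + 1], 0, 0, np.nan, np.nan, np.nan, False)
            )
            continue
        rest_s = total_s - s
        rest_n = total_n - n
        table = [[s, n - s], [rest_s, rest_n - rest_s]]
        p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
        null_frac = rest_s / rest_n if rest_n > 0 else np.nan
        out.append(
            BinSummary(
                edges[b], edges[b + 1], n, s, s / n, null_frac, p, bool(p < alpha)
            )
        )
    return out


def coupling_by_bin(
    pairs: list[SiblingPair],
    p: float,
    n_bins: int = 10,
    alpha: float = 0.01,
    method: str = "binomial",
) -> list[BinSummary]:
    """Coupled-fate fraction per bin of the pairs' average cycle position.

    ``method="binomial"`` (default) tests each bin's coupled count against
    the analytic chance level :func:`expected_coupling`(p) with an exact
    two-sided binomial test; ``method="fisher"`` instead compares the bin
    against the complement of all other pairs with Fisher's exact test.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"survival probability must be in (0, 1), got {p}")
    if method not in ("binomial", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    null = expected_coupling(p)
    xs = np.array([pr.avg_x for pr in pairs], dtype=float)
    coupled = np.array([pr.coupled for pr in pairs], dtype=bool)
    idx = _bin_index(xs, n_bins) if len(xs) else np.array([], dtype=int)
    edges = _bin_edges(n_bins)
    total_c = int(coupled.sum())
    total_n = len(coupled)
    out = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        c = int(coupled[m].sum())
        if n == 0:
            out.append(
                BinSummary(edges[b], edges[b + 1], 0, 0, np.nan, null, np.nan, False)
            )
            continue
        if method == "binomial":
            pv = float(stats.binomtest(c, n, null, alternative="two-sided").pvalue)
            null_frac = null
        else:
            rest_c = total_c - c
            rest_n = total_n - n
            table = [[c, n - c], [rest_c, rest_n - rest_c]]
            pv = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
            null_frac = rest_c / rest_n if rest_n > 0 else np.nan
        out.append(
            BinSummary(
                edges[b], edges[b + 1], n, c, c / n, null_frac, pv, bool(pv < alpha)
            )
        )
    return out


def overall_coupling_test(pairs: list[SiblingPair], p: float) -> CouplingTestResult:
    """Exact two-sided binomial test of the overall coupled-pair count
    against the chance level ``p^2 + (1-p)^2``."""
    if len(pairs) == 0:
        raise ValueError("no sibling pairs given")
    null = expected_coupling(p)
    k = sum(1 for pr in pairs if pr.coupled)
    n = len(pairs)
    pv = float(stats.binomtest(k, n, null, alternative="two-sided").pvalue)
    return CouplingTestResult(n, k, k / n, null, pv)


def make_sibling_pairs(
    ls: LineageSet,
    predicted_x: dict[str, float],
    resus_times: dict[str, float] | None = None,
) -> list[SiblingPair]:
    """Build sibling pairs among the shocked (leaf) cells.

    Only pairs where both sisters were alive at the shock (both are leaves
    with known fate) and both have a predicted position are returned; the
    pair's ``avg_x`` is the mean of the two predictions.
    """
    resus_times = resus_times or {}
    out = []
    for a, b in ls.sibling_pairs():
        if a.fate not in (FATE_SURVIVED, FATE_DIED):
            continue
        if b.fate not in (FATE_SURVIVED, FATE_DIED):
            continue
        if a.cell_id not in predicted_x or b.cell_id not in predicted_x:
            continue
        out.append(
            SiblingPair(
                cell_a=a.cell_id,
                cell_b=b.cell_id,
                avg_x=0.5 * (predicted_x[a.cell_id] + predicted_x[b.cell_id]),
                fate_a=a.fate,
                fate_b=b.fate,
                resus_a=resus_times.get(a.cell_id, a.resuscitation_time),
                resus_b=resus_times.get(b.cell_id, b.resuscitation_time),
            )
        )
    return out


def bins_to_frame(bins: list[BinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                bin_lo=b.lo,
                bin_hi=b.hi,
                n=b.n,
                successes=b.successes,
                fraction=b.fraction,
                null_fraction=b.null_fraction,
                p_value=b.p_value,
                significant=b.significant,
            )
            for b in bins
        ]
    )
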