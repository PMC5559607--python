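"""Post-stress resuscitation detection and sibling lag correlation.

A surviving cell's resuscitation time is read off its post-shock length
trace: the baseline is the mean of the first few measurements, and the
resuscitation time is the time of the first subsequent frame whose length
strictly exceeds 110% of that baseline, plus the dead time between the end
of the stress and the start of recording.  Sibling survivors' lags are
correlated; the correlation is quantified with Pearson's r, a two-sided
p-value and a seeded percentile bootstrap CI, overall and within
cycle-position intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fate import SiblingPair
from .lineage import FATE_SURVIVED, CellRecord, LineageSet

__all__ = [
    "ResuscitationParams",
    "ResusCorrelation",
    "IntervalCorrelation",
    "detect_resuscitation",
    "detect_for_lineage",
    "post_shock_trace",
    "sibling_resus_correlation",
    "correlation_by_interval",
]

DEFAULT_INTERVAL_EDGES = (0.0, 0.05, 0.2, 0.4, 1.0)


@dataclass
class ResuscitationParams:
    """Detection parameters.

    ``init_frames`` — number of leading frames averaged into the baseline
    length; ``threshold_ratio`` — the strict length-ratio threshold (1.10 =
    "increased over 10%"); ``recording_offset`` — minutes between the end of
    the stress and the first recorded frame (typically around 5 min), added
    to the reported time.
    """

    init_frames: int = 3
    threshold_ratio: float = 1.10
    recording_offset: float = 5.0

    def validate(self) -> None:
        if self.init_frames < 1:
            raise ValueError(f"init_frames must be >= 1, got {self.init_frames}")
        if not (self.threshold_ratio > 1.0):
            raise ValueError(
                f"threshold_ratio must be > 1, got {self.threshold_ratio}"
            )


def detect_resuscitation(
    times, lengths, params: ResuscitationParams | None = None
) -> float | None:
    """Resuscitation time from a post-shock (time, length) trace.

    Returns the time of the first frame (after the baseline frames) whose
    length strictly exceeds ``threshold_ratio`` x the baseline, plus
    ``recording_offset``; None if the threshold is never exceeded
    (a non-resuscitating trace).  The result is translation-equivariant in
    time and invariant under rescaling all lengths.
    """
    params = params or ResuscitationParams()
    params.validate()
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(times) < params.init_frames:
        raise ValueError(
            f"trace has {len(times)} frames; need at least {params.init_frames}"
        )
    baseline = float(np.mean(lengths[: params.init_frames]))
    above = lengths[params.init_frames :] > params.threshold_ratio * baseline
    hits = np.nonzero(above)[0]
    if len(hits) == 0:
        return None
    return float(times[params.init_frames + hits[0]] + params.recording_offset)


def post_shock_trace(cell: CellRecord, shock_time: float) -> tuple[np.ndarray, np.ndarray]:
    """The cell's (time, length) frames after the shock, with times
    re-zeroed to the start of post-shock recording."""
    m = cell.times > shock_time + 1e-9
    return cell.times[m] - shock_time, cell.lengths[m]


def detect_for_lineage(
    ls: LineageSet, params: ResuscitationParams | None = None
) -> pd.DataFrame:
    """Detected resuscitation times for all surviving shocked cells.

    Only survivors are analyzed (non-growing cells never committed to
    growth); returns a frame with cell_id and detected time in minutes.
    """
    if ls.shock_time is None:
        raise ValueError("LineageSet has no shock_time")
    rows = []
    for cell in ls:
        if cell.fate != FATE_SURVIVED:
            continue
        t, l = post_shock_trace(cell, ls.shock_time)
        if len(t) == 0:
            continue
        rows.append(
            dict(
                cell_id=cell.cell_id,
                resuscitation_min=detect_resuscitation(t, l, params),
            )
        )
    return pd.DataFrame(rows, columns=["cell_id", "resuscitation_min"])


@dataclass
class ResusCorrelation:
    """Pearson correlation of sibling resuscitation times with a percentile
    bootstrap CI (resampling unit: the pair)."""

    n: int
    r: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass
class IntervalCorrelation:
    lo: float
    hi: float
    n: int
    result: ResusCorrelation | None  # None: fewer than 3 complete pairs

    @property
    def computable(self) -> bool:
        return self.result is not None


def _complete_pairs(pairs: list[SiblingPair]) -> tuple[np.ndarray, np.ndarray]:
    ta, tb = [], []
    for pr in pairs:
        if pr.resus_a is not None and pr.resus_b is not None:
            ta.append(pr.resus_a)
            tb.append(pr.resus_b)
    return np.asarray(ta, dtype=float), np.asarray(tb, dtype=float)


def sibling_resus_correlation(
    pairs: list[SiblingPair],
    n_boot: int = 10_000,
    seed: int = 0,
    conf: float = 0.95,
) -> ResusCorrelation:
    """Pearson r between the two siblings' resuscitation times, with a
    two-sided correlation p-value and a seeded percentile bootstrap CI."""
    ta, tb = _complete_pairs(pairs)
    n = len(ta)
    if n < 3:
        raise ValueError(f"need >= 3 pairs with both resuscitation times, got {n}")
    if np.std(ta) == 0 and np.std(tb) == 0 and np.allclose(ta, tb):
        r, p = 1.0, 0.0
    elif np.std(ta) == 0 or np.std(tb) == 0:
        r, p = np.nan, np.nan
    else:
        res = stats.pearsonr(ta, tb)
        r, p = float(res.statistic), float(res.pvalue)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a = ta[idx]
    b = tb[idx]
    am = a.mean(axis=1, keepdims=True)
    bm = b.mean(axis=1, keepdims=True)
    num = ((a - am) * (b - bm)).sum(axis=1)
    den = np.sqrt(((a - am) ** 2).sum(axis=1) * ((b - bm) ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(den > 0, num / den, np.nan)
    tail = 100.0 * (1.0 - conf) / 2.0
    lo, hi = np.nanpercentile(rs, [tail, 100.0 - tail])
    return ResusCorrelation(n=n, r=r, p_value=p, ci_low=float(lo), ci_high=float(hi))


def correlation_by_interval(
    pairs: list[SiblingPair],
    edges=DEFAULT_INTERVAL_EDGES,
    n_boot: int = 10_000,
    seed: int = 0,
) -> list[IntervalCorrelation]:
    """Sibling resuscitation correlation within cycle-position intervals.

    Pairs are assigned by their average position ``avg_x`` to the intervals
    defined by ``edges`` (default 0-0.05, 0.05-0.2, 0.2-0.4, 0.4-1; the last
    interval is closed).  Intervals with fewer than 3 complete pairs are
    reported as not computable rather than raising.
    """
    edges = np.asarray(edges, dtype=float)
    out = []
    for i in range(len(edges) - 1):
        lo, hi = float(edges[i]), float(edges[i + 1])
        last = i == len(edges) - 2
        sel = [
            pr for pr in pairs if lo <= pr.avg_x < hi or (last and lo <= pr.avg_x <= hi)
        ]
        ta, tb = _complete_pairs(sel)
        if len(ta) < 3:
            out.append(IntervalCorrelation(lo, hi, len(ta), None))
            continue
        res = sibling_resus_correlation(sel, n_boot=n_boot, seed=seed + i)
        out.append(IntervalCorrelation(lo, hi, res.n, res))
    return out
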