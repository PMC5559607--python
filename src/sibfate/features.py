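"""Predictor computation, cell filtering and training-table assembly.

The cycle-position model uses six predictors per cell, evaluated at a time
``at``:

* ``Lb`` — length at birth (first frame at/after birth), µm
* ``dt`` — time since birth, min
* ``dL`` — length increase since birth, µm
* ``GR`` — instantaneous growth rate (log-linear fit over a 7 min window), 1/min
* ``dF`` — fluorescence increase since birth, a.u.
* ``F``  — fluorescence, a.u.

plus, when the division is observed, the ground-truth relative cycle
position ``x = (at - birth) / (division - birth)`` in [0, 1].

When the 7-minute growth-rate window reaches back before a cell's birth, the
mother's trace is spliced in after scaling by the daughter's share of the
mother's final length (which corrects for asymmetric division; the factor is
1/2 for a symmetric split), so the spliced log-length trace is continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import CellRecord, LineageSet

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureError",
    "InsufficientDataError",
    "MissingParentError",
    "fit_growth_rate",
    "instantaneous_growth_rate",
    "extract_features",
    "extract_features_from_lineage",
    "filter_cells",
    "FilterResult",
    "build_training_set",
    "colony_growth_rate",
]

FEATURE_NAMES = ("Lb", "dt", "dL", "GR", "dF", "F")

_TOL = 1e-6


class FeatureError(ValueError):
    pass


class InsufficientDataError(FeatureError):
    pass


class MissingParentError(FeatureError):
    pass


@dataclass
class FeatureVector:
    """The six predictors plus the (training-only) true cycle position."""

    Lb: float
    dt: float
    dL: float
    GR: float
    dF: float
    F: float
    x: float | None = None

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d["x"] = np.nan if self.x is None else self.x
        return d


def fit_growth_rate(times, lengths) -> float:
    """Elongation rate from a least-squares fit of log(length) versus time."""
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(times) < 3:
        raise InsufficientDataError(
            f"growth-rate fit needs >= 3 frames, got {len(times)}"
        )
    if np.any(lengths <= 0):
        raise FeatureError("lengths must be positive")
    slope, _ = np.polyfit(times, np.log(lengths), 1)
    return float(slope)


def instantaneous_growth_rate(
    cell: CellRecord,
    parent: CellRecord | None,
    at: float,
    window: float = 7.0,
) -> float:
    """Growth rate from a log-linear fit over the window ``[at - window, at]``.

    If the window predates the cell's birth, the mother's frames in
    ``[at - window, birth]`` are used after multiplication by this daughter's
    birth-length share of the mother's final length.  Raises
    :class:`MissingParentError` when the mother is needed but absent, and
    :class:`InsufficientDataError` when fewer than 3 frames fall in the
    window (e.g. the window is truncated by the start of recording).
    """
    t_lo = at - window
    m = (cell.times >= t_lo - _TOL) & (cell.times <= at + _TOL)
    times = list(cell.times[m])
    lengths = list(cell.lengths[m])
    if t_lo < cell.birth_time - _TOL:
        if parent is None:
            raise MissingParentError(
                f"cell {cell.cell_id}: growth-rate window crosses birth "
                f"({cell.birth_time:.3f} min) but no mother trace was given"
            )
        share = cell.lengths[0] / parent.lengths[-1]
        pm = (parent.times >= t_lo - _TOL) & (parent.times <= cell.birth_time + _TOL)
        p_times = parent.times[pm]
        p_lengths = parent.lengths[pm] * share
        # drop a mother frame duplicating the daughter's first frame time
        if times and len(p_times) and abs(p_times[-1] - times[0]) < _TOL:
            p_times, p_lengths = p_times[:-1], p_lengths[:-1]
        times = list(p_times) + times
        lengths = list(p_lengths) + lengths
    return fit_growth_rate(times, lengths)


def _nearest_frame(cell: CellRecord, at: float) -> int:
    if at < cell.times[0] - _TOL or at > cell.times[-1] + _TOL:
        raise FeatureError(
            f"cell {cell.cell_id}: time {at} outside tracked span "
            f"[{cell.times[0]}, {cell.times[-1]}]"
        )
    return int(np.argmin(np.abs(cell.times - at)))


def extract_features(
    cell: CellRecord,
    parent: CellRecord | None,
    at: float,
    window: float = 7.0,
) -> FeatureVector:
    """Evaluate the six predictors for ``cell`` at time ``at``.

    Length and fluorescence are taken from the frame nearest to ``at``;
    ``dt`` uses ``at`` itself.  ``x`` is filled only when the division was
    observed.  When the windowed growth-rate estimate is unavailable (the
    window crosses the birth of a cell without a mother trace, or covers
    fewer than 3 frames) the whole-trace exponential fit is used instead.
    """
    i = _nearest_frame(cell, at)
    lb = float(cell.lengths[0])
    f0 = float(cell.fluor[0])
    f_now = float(cell.fluor[i])
    try:
        gr = instantaneous_growth_rate(cell, parent, at, window=window)
    except (MissingParentError, InsufficientDataError):
        gr = fit_growth_rate(cell.times, cell.lengths)
    x = None
    if cell.division_time is not None and cell.division_time > cell.birth_time:
        x = (at - cell.birth_time) / (cell.division_time - cell.birth_time)
    return FeatureVector(
        Lb=lb,
        dt=float(at - cell.birth_time),
        dL=float(cell.lengths[i] - lb),
        GR=gr,
        dF=f_now - f0,
        F=f_now,
        x=x,
    )


def extract_features_from_lineage(
    ls: LineageSet, cell_id: str, at: float, window: float = 7.0
) -> FeatureVector:
    """:func:`extract_features` with the mother resolved from the lineage set."""
    cell = ls[cell_id]
    return extract_features(cell, ls.parent_of(cell_id), at, window=window)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    """Filtered lineage plus the number of cells removed per rule."""

    lineage_set: LineageSet
    n_filament_removed: int = 0
    n_division_rule_removed: int = 0


def _descendants(ls: LineageSet, cell_id: str) -> set[str]:
    out = set()
    stack = [cell_id]
    while stack:
        cid = stack.pop()
        out.add(cid)
        stack.extend(c.cell_id for c in ls.children_of(cid))
    return out


def filter_cells(
    ls: LineageSet,
    max_length: float = 11.0,
    required_divisions: int | None = None,
) -> FilterResult:
    """Apply the standard cell filters.

    * Filament exclusion: cells whose maximum pre-shock length strictly
      exceeds ``max_length`` µm are removed (together with any descendants,
      so the remaining lineage stays consistent); a cell at exactly the
      threshold is retained.
    * Generation-count rule: when ``required_divisions`` is given, only
      founder lineages with exactly that many pre-shock divisions are kept
      (e.g. 1 for the one-generation setup, which excludes founders that
      divided never or twice).
    """
    shock = ls.shock_time if ls.shock_time is not None else np.inf
    removed_filament: set[str] = set()
    for cell in ls:
        _, lengths = cell.frames_until(shock)
        if len(lengths) and float(np.max(lengths)) > max_length:
            removed_filament |= _descendants(ls, cell.cell_id)
    n_filament = len(removed_filament)

    removed_divrule: set[str] = set()
    if required_divisions is not None:
        for founder in ls.founders():
            lineage = _descendants(ls, founder.cell_id)
            n_div = sum(
                1
                for cid in lineage
                if ls[cid].division_time is not None and ls[cid].division_time < shock
            )
            if n_div != required_divisions:
                removed_divrule |= lineage
    removed_divrule -= removed_filament
    n_divrule = len(removed_divrule)

    keep = [
        cid for cid in ls.cells if cid not in removed_filament and cid not in removed_divrule
    ]
    out = ls.subset(keep)
    out.validate(require_complete_divisions=False)
    return FilterResult(out, n_filament, n_divrule)


# ---------------------------------------------------------------------------
# training table
# ---------------------------------------------------------------------------


def _training_eligible(ls: LineageSet, cell: CellRecord) -> bool:
    if cell.division_time is None:
        return False
    if cell.parent_id is None or cell.parent_id not in ls:
        # founders are born before the recording starts; their birth length
        # is not observed, so they cannot serve as training cells
        return False
    return cell.n_frames >= 3


def build_training_set(
    ls: LineageSet,
    seed: int,
    n_cells: int | None = None,
    window: float = 7.0,
) -> pd.DataFrame:
    """One training row per cell observed from birth to division.

    For each eligible cell a relative cycle position is drawn uniformly on
    [0, 1], mapped to the nearest sampled frame time, and the feature vector
    is extracted there with the ground-truth ``x`` of that frame.  With
    ``n_cells`` the eligible cells are first subsampled (without
    replacement).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    eligible = sorted(
        (c.cell_id for c in ls if _training_eligible(ls, c)),
    )
    if n_cells is not None and n_cells < len(eligible):
        idx = rng.choice(len(eligible), size=n_cells, replace=False)
        eligible = [eligible[i] for i in sorted(idx)]
    rows = []
    n_skipped = 0
    for cid in eligible:
        cell = ls[cid]
        u = rng.random()
        at = cell.birth_time + u * (cell.division_time - cell.birth_time)
        i = _nearest_frame(cell, min(max(at, cell.times[0]), cell.times[-1]))
        t_snap = float(cell.times[i])
        try:
            fv = extract_features(cell, ls.parent_of(cid), t_snap, window=window)
        except FeatureError:
            n_skipped += 1
            continue
        # ground truth at the snapped frame, clipped against frame rounding
        fv.x = float(
            np.clip(
                (t_snap - cell.birth_time) / (cell.division_time - cell.birth_time),
                0.0,
                1.0,
            )
        )
        row = fv.as_dict()
        row["cell_id"] = cid
        rows.append(row)
    if not rows:
        warnings.warn("no eligible training cells (no completed cell cycles)")
        return pd.DataFrame(columns=["cell_id", *FEATURE_NAMES, "x"])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} cells with insufficient trace data")
    df = pd.DataFrame(rows)
    return df[["cell_id", *FEATURE_NAMES, "x"]]


def colony_growth_rate(
    ls: LineageSet, colony_id: str, cell_width: float = 1.0
) -> float:
    """Microcolony-level growth rate: log-linear fit of summed cell area.

    Areas are approximated as length x a fixed width, summed over the cells
    of the colony present at each frame time (pre-shock only).
    """
    shock = ls.shock_time if ls.shock_time is not None else np.inf
    totals: dict[float, float] = {}
    for cell in ls:
        if cell.colony_id != colony_id:
            continue
        times, lengths = cell.frames_until(shock)
        for t, l in zip(times, lengths):
            totals[round(float(t), 9)] = totals.get(round(float(t), 9), 0.0) + float(l)
    if len(totals) < 3:
        raise InsufficientDataError(f"colony {colony_id}: fewer than 3 frame times")
    ts = np.array(sorted(totals))
    areas = np.array([totals[t] for t in ts]) * cell_width
    return fit_growth_rate(ts, areas)
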