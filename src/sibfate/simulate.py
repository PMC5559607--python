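"""Synthetic single-cell lineage generator.

Emulates time-lapse tracking of exponentially growing *E. coli* microcolonies
subjected to a semi-lethal heat challenge:

* single cells elongate exponentially, ``L(t) = Lb * exp(lambda * t)``, with a
  per-cell growth rate drawn around ``ln 2 / mean_doubling_time``;
* division follows an adder rule — a cell divides once it has added a drawn
  length increment to its birth length — with slightly asymmetric splitting;
* frames are sampled on a fixed grid (default every 30 s);
* a heat shock applied after a configured number of generations kills each
  cell with probability ``1 - survival_p`` independently of its cell-cycle
  position, while *sibling pairs* share fates with a probability that decays
  with their cycle position x (near-certain at birth, chance level soon
  after);
* surviving cells resume growth after a lag ("resuscitation time"); sibling
  survivors' lags are correlated, with a correlation that also decays in x.

The generator records ground truth (true cycle positions at the shock, the
pair-level coupling draws, programmed resuscitation times) so every
downstream estimator can be validated against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .lineage import (
    FATE_DIED,
    FATE_SURVIVED,
    CellRecord,
    LineageSet,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_growth",
    "apply_shock",
    "simulate_experiment",
    "coupling_kernel",
    "resus_correlation_kernel",
    "draw_pair_fates",
    "draw_pair_resus_times",
]

#: length-increase ratio defining resuscitation (mirrors the >10% rule used
#: by the detector in :mod:`sibfate.resuscitation`)
RESUS_THRESHOLD_RATIO = 1.10


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """All generator parameters.

    Defaults encode the study conditions the analysis assumes: a mean
    doubling time of 23.44 min sampled every 30 s (≈47 frames per cycle),
    adder-controlled division with mild asymmetry, ~50% heat-shock survival
    independent of cycle position, sibling fate coupling decaying from
    ``coupling_c0`` at birth to chance within the first cell-cycle decile,
    and sibling resuscitation-time correlation ``resus_rho0`` decaying over
    the cycle.
    """

    mean_doubling_time: float = 23.44  # minutes
    growth_rate_cv: float = 0.1
    frame_interval: float = 0.5  # minutes (30 s)
    founder_length_mean: float = 2.5  # µm
    added_length_mean: float | None = None  # µm; defaults to founder_length_mean
    added_length_cv: float = 0.15
    division_asymmetry_sd: float = 0.03  # sd of daughter length fraction around 0.5
    filament_probability: float = 0.0
    n_colonies: int = 29
    generations_before_shock: float = 4.0
    survival_p: float = 0.5
    coupling_c0: float = 0.875  # P(siblings share fate) at x = 0
    coupling_decay_scale: float = 0.03  # cycle-fraction units
    resus_mean: float = 60.0  # minutes
    resus_sd: float = 15.0  # minutes
    resus_rho0: float = 0.62  # sibling resuscitation-time correlation at x = 0
    resus_rho_decay_scale: float = 0.5  # cycle-fraction units
    post_shock_duration: float = 120.0  # minutes of post-shock recording
    seed: int = 0
    # fluorescence reporter emulation: length-proportional with per-frame
    # measurement noise and per-cell reporter-level variability (expression
    # noise), which keeps DNA-content features only weakly informative of
    # cycle progression, as observed for nucleoid reporters
    fluor_per_length: float = 100.0  # a.u. per µm
    fluor_noise_cv: float = 0.15
    fluor_cell_cv: float = 0.2
    fluor_sampling_interval: float = 4.0  # min between fluorescence exposures

    def __post_init__(self) -> None:
        if self.added_length_mean is None:
            self.added_length_mean = self.founder_length_mean

    @property
    def growth_rate(self) -> float:
        """Population mean elongation rate lambda = ln2 / doubling time (1/min)."""
        return math.log(2.0) / self.mean_doubling_time

    @property
    def shock_time(self) -> float:
        """Heat-shock time: configured generations times the mean doubling time."""
        return self.generations_before_shock * self.mean_doubling_time

    @property
    def frames_per_cycle(self) -> float:
        """Average number of sampling points per cell cycle."""
        return self.mean_doubling_time / self.frame_interval

    def validate(self) -> None:
        positive = [
            "mean_doubling_time",
            "frame_interval",
            "founder_length_mean",
            "added_length_mean",
            "coupling_decay_scale",
            "resus_rho_decay_scale",
            "resus_mean",
            "resus_sd",
            "post_shock_duration",
            "fluor_per_length",
        ]
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = [
            "growth_rate_cv",
            "added_length_cv",
            "division_asymmetry_sd",
            "generations_before_shock",
            "fluor_noise_cv",
            "fluor_cell_cv",
        ]
        if not (self.fluor_sampling_interval > 0):
            raise ConfigError(
                f"fluor_sampling_interval must be > 0, got {self.fluor_sampling_interval}"
            )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ["survival_p", "coupling_c0", "filament_probability"]:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (-1.0 <= self.resus_rho0 <= 1.0):
            raise ConfigError(f"resus_rho0 must be in [-1, 1], got {self.resus_rho0}")
        if self.n_colonies < 1:
            raise ConfigError(f"n_colonies must be >= 1, got {self.n_colonies}")
        chance = self.survival_p**2 + (1.0 - self.survival_p) ** 2
        if self.coupling_c0 < chance - 1e-12:
            raise ConfigError(
                f"coupling_c0 ({self.coupling_c0}) must be >= the chance coupling "
                f"level p^2+(1-p)^2 = {chance:.6f}"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Generator-side truth for validating downstream estimators.

    ``cells`` has one row per simulated cell: its true growth rate, scheduled
    division time (simulated past the shock for cells alive then), cycle
    position ``x_at_shock`` (NaN for cells not alive at the shock) and, for
    survivors, the programmed resuscitation time (minutes from the start of
    post-shock recording, before any recording offset).

    ``pairs`` has one row per sibling pair alive at the shock: the pair's
    average true position, whether the pair-level "copy" latent variable
    fired, and whether the realized fates were coupled.
    """

    cells: pd.DataFrame
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pair_id", "cell_a", "cell_b", "avg_x", "copied", "coupled"]
        )
    )

    def x_of(self, cell_id: str) -> float:
        row = self.cells.loc[self.cells["cell_id"] == cell_id]
        return float(row["x_at_shock"].iloc[0])

    def write(self, path) -> None:
        """Write the per-cell ground truth (with pair annotations) as TSV."""
        cells = self.cells.copy()
        pair_of: dict[str, tuple[str, bool]] = {}
        for _, row in self.pairs.iterrows():
            pair_of[row["cell_a"]] = (row["pair_id"], bool(row["coupled"]))
            pair_of[row["cell_b"]] = (row["pair_id"], bool(row["coupled"]))
        cells["pair_id"] = [pair_of.get(c, ("", False))[0] for c in cells["cell_id"]]
        cells["coupled"] = [
            pair_of[c][1] if c in pair_of else "" for c in cells["cell_id"]
        ]
        cells.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# kernels and pair-level draws
# ---------------------------------------------------------------------------


def coupling_kernel(x, cfg: SimulationConfig):
    """P(siblings share fate) at average cycle position ``x``:
    ``chance + (c0 - chance) * exp(-x / scale)`` with chance = p^2 + (1-p)^2.
    """
    p = cfg.survival_p
    chance = p * p + (1.0 - p) ** 2
    return chance + (cfg.coupling_c0 - chance) * np.exp(
        -np.asarray(x, dtype=float) / cfg.coupling_decay_scale
    )


def resus_correlation_kernel(x, cfg: SimulationConfig):
    """Target sibling resuscitation-time correlation rho(x) = rho0 * exp(-x/scale)."""
    return cfg.resus_rho0 * np.exp(
        -np.asarray(x, dtype=float) / cfg.resus_rho_decay_scale
    )


def draw_pair_fates(
    avg_x: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw fates for sibling pairs at average positions ``avg_x``.

    A mixture construction keeps each cell's marginal survival probability at
    ``survival_p`` for every x while the shared-fate probability follows
    :func:`coupling_kernel`: with probability ``w(x)`` a single pair-level
    Bernoulli(p) fate is copied to both siblings, otherwise the two fates are
    independent Bernoulli(p).  Solving ``w + (1-w)*chance = c(x)`` gives
    ``w(x) = (c(x) - chance) / (1 - chance)``.

    Returns (survive_a, survive_b, copied) boolean arrays.
    """
    avg_x = np.asarray(avg_x, dtype=float)
    p = cfg.survival_p
    chance = p * p + (1.0 - p) ** 2
    c = coupling_kernel(avg_x, cfg)
    if chance >= 1.0 - 1e-12:  # p in {0, 1}: fates are deterministic anyway
        w = np.ones_like(avg_x)
    else:
        w = (c - chance) / (1.0 - chance)
    copied = rng.random(avg_x.shape) < w
    fate_shared = rng.random(avg_x.shape) < p
    fate_a_ind = rng.random(avg_x.shape) < p
    fate_b_ind = rng.random(avg_x.shape) < p
    a = np.where(copied, fate_shared, fate_a_ind)
    b = np.where(copied, fate_shared, fate_b_ind)
    return a, b, copied


def draw_pair_resus_times(
    avg_x: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated sibling resuscitation-time pairs at positions ``avg_x``.

    Bivariate normal with mean ``resus_mean``, sd ``resus_sd`` and Pearson
    correlation :func:`resus_correlation_kernel`, truncated below at 0.
    Times are minutes from the start of post-shock recording.
    """
    avg_x = np.asarray(avg_x, dtype=float)
    rho = np.clip(resus_correlation_kernel(avg_x, cfg), -1.0, 1.0)
    z1 = rng.standard_normal(avg_x.shape)
    z2 = rng.standard_normal(avg_x.shape)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    t1 = np.maximum(cfg.resus_mean + cfg.resus_sd * z1, 0.0)
    t2 = np.maximum(cfg.resus_mean + cfg.resus_sd * z2, 0.0)
    return t1, t2


# ---------------------------------------------------------------------------
# growth simulation
# ---------------------------------------------------------------------------


def _rng_for(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    # counter-based sub-streams: changing n_colonies never shifts the draws
    # of other colonies or of the shock stage
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float
) -> float:
    if sd == 0:
        return max(mean, lo)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return lo + abs(rng.normal(0.0, sd))  # pathological cv; keep it positive


@dataclass
class _ScheduledCell:
    cell_id: str
    colony_id: str
    parent_id: str | None
    birth_time: float
    birth_length: float
    growth_rate: float
    added_length: float
    old_pole_daughter: bool
    generation: int

    @property
    def division_time(self) -> float:
        return self.birth_time + math.log(
            (self.birth_length + self.added_length) / self.birth_length
        ) / self.growth_rate

    def length_at(self, t) -> np.ndarray:
        return self.birth_length * np.exp(self.growth_rate * (np.asarray(t) - self.birth_time))


def simulate_growth(cfg: SimulationConfig) -> tuple[LineageSet, GroundTruth]:
    """Simulate microcolony growth up to the shock time.

    Founders are desynchronized by a uniform initial cycle phase (their birth
    predates the recording start).  Each cell's division schedule is computed
    analytically from its drawn growth rate and adder increment; frames are
    sampled on the global grid every ``frame_interval`` minutes from
    ``max(0, birth)`` to ``min(division, shock)``.  Cells alive at the shock
    keep their scheduled division time in the ground truth (it is never
    observed), which defines their true cycle position ``x_at_shock``.
    """
    cfg.validate()
    shock = cfg.shock_time
    # last observable frame before the shock; divisions after it cannot be
    # resolved by the tracker, so such cells count as undivided at the shock
    grid_max = math.floor(shock / cfg.frame_interval + 1e-9) * cfg.frame_interval
    lam0 = cfg.growth_rate
    cells: dict[str, CellRecord] = {}
    gt_rows: list[dict] = []
    ls = LineageSet({}, cfg.frame_interval, shock_time=shock)

    for j in range(cfg.n_colonies):
        rng = _rng_for(cfg, 0, j)
        colony_id = f"col{j:04d}"

        def draw_cell_params() -> tuple[float, float]:
            lam = _truncated_normal(rng, lam0, cfg.growth_rate_cv * lam0, 0.2 * lam0)
            add = _truncated_normal(
                rng,
                cfg.added_length_mean,
                cfg.added_length_cv * cfg.added_length_mean,
                0.1 * cfg.added_length_mean,
            )
            if cfg.filament_probability > 0 and rng.random() < cfg.filament_probability:
                add *= 6.0  # filamentous: division deferred far beyond normal size
            return lam, add

        lb0 = _truncated_normal(
            rng,
            cfg.founder_length_mean,
            cfg.added_length_cv * cfg.founder_length_mean,
            0.4 * cfg.founder_length_mean,
        )
        lam, add = draw_cell_params()
        phase = rng.random()
        t_cycle = math.log((lb0 + add) / lb0) / lam
        founder = _ScheduledCell(
            cell_id=f"{colony_id}_c0001",
            colony_id=colony_id,
            parent_id=None,
            birth_time=-phase * t_cycle,
            birth_length=lb0,
            growth_rate=lam,
            added_length=add,
            old_pole_daughter=True,
            generation=0,
        )
        queue = [founder]
        counter = 1
        while queue:
            sc = queue.pop(0)
            t_div = sc.division_time
            # frames on the global grid within the observed span
            t_lo = max(0.0, sc.birth_time)
            t_hi = min(t_div, shock)
            k_lo = math.ceil(t_lo / cfg.frame_interval - 1e-9)
            k_hi = math.floor(t_hi / cfg.frame_interval + 1e-9)
            times = np.arange(k_lo, k_hi + 1, dtype=float) * cfg.frame_interval
            if len(times) == 0:
                continue  # no observable frame (born immediately before shock)
            lengths = sc.length_at(times)
            cell_factor = (
                math.exp(rng.normal(0.0, cfg.fluor_cell_cv))
                if cfg.fluor_cell_cv > 0
                else 1.0
            )
            noise = (
                np.exp(rng.normal(0.0, cfg.fluor_noise_cv, size=len(times)))
                if cfg.fluor_noise_cv > 0
                else np.ones(len(times))
            )
            # fluorescence is exposed on its own sparser grid (held between
            # exposures), emulating reporter images taken every few minutes
            fiv = cfg.fluor_sampling_interval
            t_fluor = np.maximum(np.floor(times / fiv + 1e-9) * fiv, sc.birth_time)
            fluor = cell_factor * cfg.fluor_per_length * sc.length_at(t_fluor) * noise
            divides_before_shock = t_div <= grid_max
            alive_at_shock = sc.birth_time <= shock and not divides_before_shock
            cells[sc.cell_id] = CellRecord(
                cell_id=sc.cell_id,
                colony_id=sc.colony_id,
                parent_id=sc.parent_id,
                birth_time=sc.birth_time,
                division_time=t_div if divides_before_shock else None,
                times=times,
                lengths=lengths,
                fluor=fluor,
                old_pole_daughter=sc.old_pole_daughter,
            )
            gt_rows.append(
                dict(
                    cell_id=sc.cell_id,
                    colony_id=sc.colony_id,
                    growth_rate=sc.growth_rate,
                    scheduled_division=t_div,
                    x_at_shock=min(
                        (shock - sc.birth_time) / (t_div - sc.birth_time), 1.0
                    )
                    if alive_at_shock
                    else np.nan,
                )
            )
            if divides_before_shock:
                l_div = sc.birth_length + sc.added_length
                frac = 0.5 + (
                    rng.normal(0.0, cfg.division_asymmetry_sd)
                    if cfg.division_asymmetry_sd > 0
                    else 0.0
                )
                frac = min(max(frac, 0.3), 0.7)
                which_old = rng.random() < 0.5  # old pole goes to either side
                for side in (0, 1):
                    counter += 1
                    lam_d, add_d = draw_cell_params()
                    share = frac if side == 0 else 1.0 - frac
                    queue.append(
                        _ScheduledCell(
                            cell_id=f"{colony_id}_c{counter:04d}",
                            colony_id=colony_id,
                            parent_id=sc.cell_id,
                            birth_time=t_div,
                            birth_length=share * l_div,
                            growth_rate=lam_d,
                            added_length=add_d,
                            old_pole_daughter=(side == 0) == which_old,
                            generation=sc.generation + 1,
                        )
                    )

    ls = LineageSet(cells, cfg.frame_interval, shock_time=shock)
    gt = GroundTruth(cells=pd.DataFrame(gt_rows))
    return ls, gt


# ---------------------------------------------------------------------------
# heat shock
# ---------------------------------------------------------------------------


def apply_shock(
    ls: LineageSet, gt: GroundTruth, cfg: SimulationConfig
) -> tuple[LineageSet, GroundTruth]:
    """Assign fates and post-shock traces to the cells alive at the shock.

    Marginal survival is ``survival_p`` for every cell irrespective of cycle
    position; sibling pairs share fates per :func:`draw_pair_fates`.
    Survivors receive programmed resuscitation times (correlated within
    pairs, :func:`draw_pair_resus_times`) and post-shock length traces: flat
    at the pre-shock length until regrowth, then exponential elongation timed
    so the cell first exceeds 110% of its post-shock baseline exactly at its
    programmed resuscitation time.  Non-survivors stay flat.
    """
    cfg.validate()
    shock = ls.shock_time
    if shock is None:
        raise ValueError("LineageSet has no shock_time; run simulate_growth first")
    rng = _rng_for(cfg, 1)

    lam_of = dict(zip(gt.cells["cell_id"], gt.cells["growth_rate"]))
    x_of = dict(zip(gt.cells["cell_id"], gt.cells["x_at_shock"]))

    leaves = [c for c in ls.leaves() if c.division_time is None]
    leaf_ids = {c.cell_id for c in leaves}
    by_parent: dict[str, list[CellRecord]] = {}
    singletons: list[CellRecord] = []
    for c in leaves:
        if c.parent_id is None:
            singletons.append(c)
        else:
            by_parent.setdefault(c.parent_id, []).append(c)
    pairs: list[tuple[CellRecord, CellRecord]] = []
    for pid in sorted(by_parent):
        kids = sorted(by_parent[pid], key=lambda c: c.cell_id)
        if len(kids) == 2:
            pairs.append((kids[0], kids[1]))
        else:
            singletons.extend(kids)
    singletons.sort(key=lambda c: c.cell_id)

    pair_rows: list[dict] = []
    avg_x = np.array(
        [0.5 * (x_of[a.cell_id] + x_of[b.cell_id]) for a, b in pairs], dtype=float
    )
    if len(pairs):
        surv_a, surv_b, copied = draw_pair_fates(avg_x, cfg, rng)
        res_a, res_b = draw_pair_resus_times(avg_x, cfg, rng)
    for i, (a, b) in enumerate(pairs):
        a.fate = FATE_SURVIVED if surv_a[i] else FATE_DIED
        b.fate = FATE_SURVIVED if surv_b[i] else FATE_DIED
        if surv_a[i]:
            a.resuscitation_time = float(res_a[i])
        if surv_b[i]:
            b.resuscitation_time = float(res_b[i])
        pair_rows.append(
            dict(
                pair_id=f"pair{i:04d}",
                cell_a=a.cell_id,
                cell_b=b.cell_id,
                avg_x=avg_x[i],
                copied=bool(copied[i]),
                coupled=bool(surv_a[i] == surv_b[i]),
            )
        )
    for c in singletons:
        survives = rng.random() < cfg.survival_p
        c.fate = FATE_SURVIVED if survives else FATE_DIED
        if survives:
            c.resuscitation_time = float(
                max(rng.normal(cfg.resus_mean, cfg.resus_sd), 0.0)
            )

    # post-shock traces
    n_post = int(round(cfg.post_shock_duration / cfg.frame_interval))
    rel_times = np.arange(1, n_post + 1, dtype=float) * cfg.frame_interval
    for c in leaves:
        lam = lam_of[c.cell_id]
        l0 = c.lengths[-1]
        if c.fate == FATE_SURVIVED and c.resuscitation_time is not None:
            t_start = max(
                c.resuscitation_time - math.log(RESUS_THRESHOLD_RATIO) / lam, 0.0
            )
            lengths = np.where(
                rel_times <= t_start,
                l0,
                l0 * np.exp(lam * (rel_times - t_start)),
            )
        else:
            lengths = np.full_like(rel_times, l0)
        noise = (
            np.exp(rng.normal(0.0, cfg.fluor_noise_cv, size=len(rel_times)))
            if cfg.fluor_noise_cv > 0
            else np.ones(len(rel_times))
        )
        fluor = cfg.fluor_per_length * lengths * noise
        c.times = np.concatenate([c.times, shock + rel_times])
        c.lengths = np.concatenate([c.lengths, lengths])
        c.fluor = np.concatenate([c.fluor, fluor])

    gt_pairs = pd.DataFrame(
        pair_rows, columns=["pair_id", "cell_a", "cell_b", "avg_x", "copied", "coupled"]
    )
    return ls, GroundTruth(cells=gt.cells, pairs=gt_pairs)


def simulate_experiment(cfg: SimulationConfig) -> tuple[LineageSet, GroundTruth]:
    """Convenience: :func:`simulate_growth` followed by :func:`apply_shock`."""
    ls, gt = simulate_growth(cfg)
    return apply_shock(ls, gt, cfg)
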