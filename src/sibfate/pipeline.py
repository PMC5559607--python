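"""End-to-end analysis pipeline.

Orchestrates: simulate (or load) an unstressed training experiment → filter
cells → extract features → train and cross-validate the cycle-position
model → simulate (or load) a shocked experiment → predict every shocked
cell's cycle position → survival and sibling fate-coupling analyses → (for
one-generation runs) resuscitation detection and sibling lag correlations.

Two presets mirror the two experimental designs the analysis supports:

* ``fig1_like`` — ~4 generations of growth before the shock, survival
  probability 0.454, fluorescent nucleoid reporter, 635 training cells;
* ``fig2_like`` — exactly one generation before the shock, survival
  probability 0.558, 453 training cells, resuscitation analysis enabled,
  and the "exactly one pre-shock division" lineage filter.

A run is fully reproducible from its config: every stage derives its seed
from the master seed, and all outputs are plain TSV/text.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fate, resuscitation
from .cycle_model import CVReport, CyclePositionModel, CyclePositionResults
from .features import build_training_set, extract_features_from_lineage, filter_cells
from .lineage import FATE_SURVIVED, LineageSet, read_track_table, write_track_table
from .simulate import GroundTruth, SimulationConfig, simulate_experiment, simulate_growth

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "fig1_like", "fig2_like"]

log = logging.getLogger("sibfate.pipeline")


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that caused it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; see the preset constructors."""

    name: str = "custom"
    seed: int = 0
    # simulations (ignored when track tables are supplied)
    training_sim: SimulationConfig = field(default_factory=SimulationConfig)
    shock_sim: SimulationConfig = field(default_factory=SimulationConfig)
    training_tracks: str | None = None  # optional user-supplied track tables
    shock_tracks: str | None = None
    # filtering
    max_length: float = 11.0
    required_divisions: int | None = None
    # model
    n_training_cells: int | None = None
    max_depth: int = 3
    min_leaf: int = 25
    cv_folds: int = 10
    # analyses
    n_bins: int = 10
    alpha: float = 0.01
    analyze_resuscitation: bool = False
    interval_edges: tuple[float, ...] = resuscitation.DEFAULT_INTERVAL_EDGES
    n_boot: int = 10_000
    recording_offset: float = 5.0

    def validate(self) -> None:
        self.training_sim.validate()
        self.shock_sim.validate()
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["training_sim"] = self.training_sim.to_dict()
        d["shock_sim"] = self.shock_sim.to_dict()
        d["interval_edges"] = list(self.interval_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("training_sim", "shock_sim"):
            if key in d and isinstance(d[key], dict):
                d[key] = SimulationConfig.from_dict(d[key])
        if "interval_edges" in d:
            d["interval_edges"] = tuple(d["interval_edges"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _subseed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def fig1_like(seed: int = 0, n_colonies: int = 29, n_training_colonies: int = 60) -> PipelineConfig:
    """Multi-generation design: ~4 generations before the shock, p ≈ 0.454."""
    train = SimulationConfig(
        n_colonies=n_training_colonies, generations_before_shock=4.0, seed=_subseed(seed, 1)
    )
    shock = SimulationConfig(
        n_colonies=n_colonies,
        generations_before_shock=4.0,
        survival_p=0.454,
        seed=_subseed(seed, 2),
    )
    return PipelineConfig(
        name="fig1-like",
        seed=seed,
        training_sim=train,
        shock_sim=shock,
        n_training_cells=635,
        analyze_resuscitation=False,
    )


def fig2_like(seed: int = 0, n_colonies: int = 450, n_training_colonies: int = 45) -> PipelineConfig:
    """One-generation design: exactly one division before the shock,
    p ≈ 0.558, resuscitation analysis enabled."""
    train = SimulationConfig(
        n_colonies=n_training_colonies, generations_before_shock=4.0, seed=_subseed(seed, 1)
    )
    shock = SimulationConfig(
        n_colonies=n_colonies,
        generations_before_shock=1.0,
        survival_p=0.558,
        seed=_subseed(seed, 2),
    )
    return PipelineConfig(
        name="fig2-like",
        seed=seed,
        training_sim=train,
        shock_sim=shock,
        n_training_cells=453,
        required_divisions=1,
        analyze_resuscitation=True,
    )


@dataclass
class PipelineReport:
    """In-memory results of one pipeline run (files are also written when an
    output directory is given)."""

    config: PipelineConfig
    training_table: pd.DataFrame
    cv_report: CVReport
    fit_results: CyclePositionResults
    predictions: pd.DataFrame  # cell_id, x_pred, fate
    survival_fraction: float
    survival_ci: tuple[float, float]
    survival_bins: list[fate.BinSummary]
    pairs: list[fate.SiblingPair]
    coupling_bins: list[fate.BinSummary]
    overall_coupling: fate.CouplingTestResult
    resus_times: pd.DataFrame | None = None
    resus_overall: resuscitation.ResusCorrelation | None = None
    resus_intervals: list[resuscitation.IntervalCorrelation] | None = None
    ground_truth: GroundTruth | None = None

    def report_text(self) -> str:
        lines = [
            f"sibfate pipeline report — preset {self.config.name}, seed {self.config.seed}",
            "",
            "Cycle-position model",
            "--------------------",
            self.cv_report.summary(),
            "",
            self.fit_results.summary(),
            "",
            "Survival",
            "--------",
            f"shocked cells: {len(self.predictions)}",
            f"survival fraction: {self.survival_fraction:.3f} "
            f"(95% CI [{self.survival_ci[0]:.3f}, {self.survival_ci[1]:.3f}], Wilson)",
            f"bins significant vs complement (alpha={self.config.alpha}): "
            f"{[round(b.lo, 2) for b in self.survival_bins if b.significant]}",
            "",
            "Sibling fate coupling",
            "---------------------",
            f"pairs: {self.overall_coupling.n}  coupled: {self.overall_coupling.n_coupled} "
            f"({self.overall_coupling.observed_fraction:.3f})",
            f"chance level p^2+(1-p)^2: {self.overall_coupling.null_fraction:.3f}",
            f"overall binomial test p-value: {self.overall_coupling.p_value:.3f}",
            "significant bins (alpha={:g}): {}".format(
                self.config.alpha,
                [round(b.lo, 2) for b in self.coupling_bins if b.significant],
            ),
        ]
        if self.resus_overall is not None:
            lines += [
                "",
                "Resuscitation",
                "-------------",
                f"surviving pairs with both lags: {self.resus_overall.n}",
                f"Pearson r = {self.resus_overall.r:.4f} "
                f"(p = {self.resus_overall.p_value:.3g}, bootstrap 95% CI "
                f"[{self.resus_overall.ci_low:.3f}, {self.resus_overall.ci_high:.3f}])",
            ]
            for iv in self.resus_intervals or []:
                if iv.computable:
                    lines.append(
                        f"  x in [{iv.lo:g}, {iv.hi:g}): n={iv.n}  r={iv.result.r:.4f} "
                        f"CI [{iv.result.ci_low:.3f}, {iv.result.ci_high:.3f}] "
                        f"p={iv.result.p_value:.3g}"
                    )
                else:
                    lines.append(
                        f"  x in [{iv.lo:g}, {iv.hi:g}): n={iv.n}  (not computable)"
                    )
        return "\n".join(lines) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise PipelineStageError(name, e) from e

        return wrapped

    return deco


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path | None = None, figures: bool = False
) -> PipelineReport:
    """Execute every stage; see the module docstring.  With ``outdir`` all
    intermediate artifacts are written as TSV/text (and PNG figures when
    ``figures`` is set)."""
    cfg.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- training data ---------------------------------------------------
    @_stage("simulate-training")
    def get_training() -> LineageSet:
        if cfg.training_tracks:
            return read_track_table(cfg.training_tracks)
        ls, _ = simulate_growth(cfg.training_sim)
        return ls

    train_ls = get_training()
    log.info("training lineage: %d cells", len(train_ls))

    @_stage("filter-training")
    def filt_train() -> LineageSet:
        res = filter_cells(train_ls, max_length=cfg.max_length)
        log.info(
            "training filter: removed %d filamentous cells; %d remain",
            res.n_filament_removed,
            len(res.lineage_set),
        )
        return res.lineage_set

    train_ls_f = filt_train()

    @_stage("extract-features")
    def training_table() -> pd.DataFrame:
        t = build_training_set(
            train_ls_f, seed=_subseed(cfg.seed, 3), n_cells=cfg.n_training_cells
        )
        log.info("training table: %d rows", len(t))
        return t

    table = training_table()
    if out is not None:
        write_track_table(train_ls_f, out / "training_tracks.tsv")
        table.to_csv(out / "training_features.tsv", sep="\t", index=False, float_format="%.10g")

    # --- model -----------------------------------------------------------
    @_stage("train-model")
    def train_model() -> tuple[CyclePositionResults, CVReport]:
        model = CyclePositionModel(table, max_depth=cfg.max_depth, min_leaf=cfg.min_leaf)
        res = model.fit()
        cv = model.cross_validate(k=cfg.cv_folds, seed=_subseed(cfg.seed, 4))
        log.info("CV: R2=%.4f RMSE=%.4f", cv.r2, cv.rmse)
        return res, cv

    fit_res, cv = train_model()
    if out is not None:
        fit_res.tree.save(out / "model_tree.txt")
        cv.to_frame().to_csv(out / "cv_report.tsv", sep="\t", index=False, float_format="%.10g")

    # --- shocked experiment ----------------------------------------------
    @_stage("simulate-shock")
    def get_shocked() -> tuple[LineageSet, GroundTruth | None]:
        if cfg.shock_tracks:
            return read_track_table(cfg.shock_tracks), None
        return simulate_experiment(cfg.shock_sim)

    shock_ls, gt = get_shocked()
    log.info("shocked lineage: %d cells", len(shock_ls))

    @_stage("filter-shock")
    def filt_shock() -> LineageSet:
        res = filter_cells(
            shock_ls, max_length=cfg.max_length, required_divisions=cfg.required_divisions
        )
        log.info(
            "shock filter: removed %d filamentous, %d by division rule; %d remain",
            res.n_filament_removed,
            res.n_division_rule_removed,
            len(res.lineage_set),
        )
        return res.lineage_set

    shock_ls_f = filt_shock()

    @_stage("predict-at-shock")
    def predict() -> pd.DataFrame:
        shock_t = shock_ls_f.shock_time
        rows = []
        for cell in shock_ls_f.leaves():
            if cell.division_time is not None or cell.fate == "unobserved":
                continue
            fv = extract_features_from_lineage(shock_ls_f, cell.cell_id, shock_t)
            x_pred = float(fit_res.predict(pd.DataFrame([fv.as_dict()]))[0])
            rows.append(dict(cell_id=cell.cell_id, x_pred=x_pred, fate=cell.fate))
        log.info("predicted cycle positions for %d shocked cells", len(rows))
        return pd.DataFrame(rows)

    preds = predict()
    if out is not None:
        write_track_table(shock_ls_f, out / "shocked_tracks.tsv")
        preds.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.10g")
        if gt is not None:
            gt.write(out / "ground_truth.tsv")

    # --- survival & coupling ---------------------------------------------
    @_stage("analyze-survival")
    def survival():
        survived = (preds["fate"] == FATE_SURVIVED).to_numpy()
        frac = float(survived.mean())
        ci = fate.survival_ci(frac, len(survived))
        bins = fate.survival_by_bin(
            preds["x_pred"].to_numpy(), survived, n_bins=cfg.n_bins, alpha=cfg.alpha
        )
        return frac, ci, bins

    surv_frac, surv_ci, surv_bins = survival()

    @_stage("analyze-coupling")
    def coupling():
        xmap = dict(zip(preds["cell_id"], preds["x_pred"]))
        pairs = fate.make_sibling_pairs(shock_ls_f, xmap)
        bins = fate.coupling_by_bin(pairs, surv_frac, n_bins=cfg.n_bins, alpha=cfg.alpha)
        overall = fate.overall_coupling_test(pairs, surv_frac)
        log.info(
            "pairs: %d, coupled: %d, chance %.3f, overall p=%.3f",
            overall.n,
            overall.n_coupled,
            overall.null_fraction,
            overall.p_value,
        )
        return pairs, bins, overall

    pairs, coup_bins, overall = coupling()
    if out is not None:
        fate.bins_to_frame(surv_bins).to_csv(
            out / "survival_bins.tsv", sep="\t", index=False, float_format="%.10g"
        )
        fate.bins_to_frame(coup_bins).to_csv(
            out / "coupling_bins.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(
            [
                dict(
                    cell_a=p.cell_a,
                    cell_b=p.cell_b,
                    avg_x=p.avg_x,
                    fate_a=p.fate_a,
                    fate_b=p.fate_b,
                    coupled=p.coupled,
                )
                for p in pairs
            ]
        ).to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.10g")

    # --- resuscitation ----------------------------------------------------
    resus_df = resus_overall = resus_intervals = None
    if cfg.analyze_resuscitation:

        @_stage("analyze-resuscitation")
        def resus():
            params = resuscitation.ResuscitationParams(
                recording_offset=cfg.recording_offset
            )
            df = resuscitation.detect_for_lineage(shock_ls_f, params)
            detected = dict(zip(df["cell_id"], df["resuscitation_min"]))
            rp = [
                fate.SiblingPair(
                    p.cell_a,
                    p.cell_b,
                    p.avg_x,
                    p.fate_a,
                    p.fate_b,
                    detected.get(p.cell_a),
                    detected.get(p.cell_b),
                )
                for p in pairs
                if p.both_survived
            ]
            seed = _subseed(cfg.seed, 5)
            overall_r = resuscitation.sibling_resus_correlation(
                rp, n_boot=cfg.n_boot, seed=seed
            )
            intervals = resuscitation.correlation_by_interval(
                rp, edges=cfg.interval_edges, n_boot=cfg.n_boot, seed=seed
            )
            return df, overall_r, intervals

        resus_df, resus_overall, resus_intervals = resus()
        if out is not None:
            resus_df.to_csv(
                out / "resuscitation_times.tsv", sep="\t", index=False, float_format="%.10g"
            )
            pd.DataFrame(
                [
                    dict(
                        x_lo=iv.lo,
                        x_hi=iv.hi,
                        n=iv.n,
                        r=iv.result.r if iv.computable else np.nan,
                        p_value=iv.result.p_value if iv.computable else np.nan,
                        ci_low=iv.result.ci_low if iv.computable else np.nan,
                        ci_high=iv.result.ci_high if iv.computable else np.nan,
                    )
                    for iv in resus_intervals
                ]
            ).to_csv(
                out / "interval_correlations.tsv", sep="\t", index=False, float_format="%.10g"
            )

    report = PipelineReport(
        config=cfg,
        training_table=table,
        cv_report=cv,
        fit_results=fit_res,
        predictions=preds,
        survival_fraction=surv_frac,
        survival_ci=surv_ci,
        survival_bins=surv_bins,
        pairs=pairs,
        coupling_bins=coup_bins,
        overall_coupling=overall,
        resus_times=resus_df,
        resus_overall=resus_overall,
        resus_intervals=resus_intervals,
        ground_truth=gt,
    )
    if out is not None:
        (out / "report.txt").write_text(report.report_text(), encoding="utf-8")
        if figures:
            from . import plotting

            plotting.plot_bin_summaries(
                surv_bins, "survival fraction", out / "survival_bins.png"
            )
            plotting.plot_bin_summaries(
                coup_bins, "coupled-fate fraction", out / "coupling_bins.png"
            )
            if resus_intervals is not None:
                plotting.plot_interval_correlations(
                    resus_intervals, out / "interval_correlations.png"
                )
    return report
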