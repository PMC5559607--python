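import numpy as np
import pytest

from sibfate.lineage import CellRecord, LineageSet
from sibfate.simulate import SimulationConfig, simulate_experiment, simulate_growth


@pytest.fixture(scope="session")
def small_growth():
    """Five colonies grown for four generations, no shock applied."""
    cfg = SimulationConfig(n_colonies=5, seed=1)
    return simulate_growth(cfg) + (cfg,)


@pytest.fixture(scope="session")
def shocked():
    """Five colonies grown for four generations, shock applied."""
    cfg = SimulationConfig(n_colonies=5, seed=1)
    return simulate_experiment(cfg) + (cfg,)


@pytest.fixture(scope="session")
def training_table():
    """A paper-sized training table (635 cells) from a larger unstressed run."""
    from sibfate.features import build_training_set, filter_cells

    cfg = SimulationConfig(n_colonies=60, seed=11)
    ls, _ = simulate_growth(cfg)
    ls = filter_cells(ls).lineage_set
    return build_training_set(ls, seed=5, n_cells=635)


def make_cell(
    cell_id="c1",
    colony_id="col",
    parent_id=None,
    birth=0.0,
    division=None,
    times=None,
    lengths=None,
    fluor=None,
    **kw,
):
    times = np.asarray([0.0, 1.0, 2.0] if times is None else times, dtype=float)
    lengths = np.asarray(
        2.0 * np.exp(0.03 * times) if lengths is None else lengths, dtype=float
    )
    fluor = np.full_like(times, np.nan) if fluor is None else np.asarray(fluor, float)
    return CellRecord(
        cell_id=cell_id,
        colony_id=colony_id,
        parent_id=parent_id,
        birth_time=birth,
        division_time=division,
        times=times,
        lengths=lengths,
        fluor=fluor,
        **kw,
    )


def make_lineage(cells, frame_interval=1.0, shock_time=None):
    return LineageSet({c.cell_id: c for c in cells}, frame_interval, shock_time)
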