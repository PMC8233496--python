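import numpy as np
import pytest

from chronotree.simulate import (
    SimulationConfig,
    apply_rate_model,
    sample_tips_serially,
    simulate_timetree,
)


def simulated_phylogram(seed, n_tips=20, rate_model="strict", **kw):
    """Timetree + phylogram pair under one seeded RNG stream."""
    cfg = SimulationConfig(n_tips=n_tips, seed=seed, rate_model=rate_model, **kw)
    rng = cfg.rng()
    timetree = simulate_timetree(cfg, rng)
    phylo = apply_rate_model(timetree, cfg, rng)
    return timetree, phylo


def serial_phylogram(seed, n_tips=20, date_span=10.0, **kw):
    cfg = SimulationConfig(
        n_tips=n_tips, seed=seed, date_span=date_span, **kw
    )
    rng = cfg.rng()
    timetree = simulate_timetree(cfg, rng)
    timetree, dates = sample_tips_serially(timetree, cfg, rng)
    phylo = apply_rate_model(timetree, cfg, rng)
    return phylo, dates


def true_times(timetree):
    return {nd.id: float(nd.annotations["true_time"]) for nd in timetree.preorder()}


@pytest.fixture
def clock_tree():
    from chronotree.tree import read_newick

    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def uneven_tree():
    from chronotree.tree import read_newick

    return read_newick("((A:2,B:1):1,C:2);")
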