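"""Synthetic data for every method in the toolkit.

Generates Yule (pure-birth) timetrees with known node ages, dresses them with
branch-rate models (strict clock, independent lognormal, autocorrelated
geometric-Brownian), optionally staggers tip sampling times for serially
sampled data, and evolves sequence alignments under the substitution models
of :mod:`chronotree.likelihood`.  True parameters are always recorded next to
the data so downstream estimators have a recovery target.

All generators are deterministic under a fixed seed; the seed is a mandatory
field of :class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tree import Node, RootedTree

__all__ = [
    "SimulationConfig",
    "simulate_timetree",
    "apply_rate_model",
    "sample_tips_serially",
    "simulate_alignment",
]

RATE_MODELS = ("strict", "iid_lognormal", "autocorrelated")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated data set.

    mu is the mean evolutionary rate in substitutions/site per time unit;
    ``sdlog`` is the log-scale standard deviation of independent lognormal
    branch rates; ``step_sdlog`` the per-branch log-rate random-walk step of
    the autocorrelated model.  ``date_span`` (time units) staggers tip
    sampling for serially sampled fixtures.  ``seed`` is mandatory.
    """

    n_tips: int
    seed: int
    birth_rate: float = 1.0
    rate_model: str = "strict"
    mu: float = 0.01
    sdlog: float = 0.3
    step_sdlog: float = 0.2
    seq_length: int = 1000
    model: str = "jc"
    date_span: float = 0.0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0 or self.mu <= 0 or self.seq_length <= 0:
            raise ValueError("rates and lengths must be positive")
        if self.rate_model not in RATE_MODELS:
            raise ValueError(f"unknown rate model {self.rate_model!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_timetree(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> RootedTree:
    """Yule timetree with ``cfg.n_tips`` contemporaneous tips.

    Branch lengths are in time units; every node carries a ``true_time``
    annotation with its age before the tips (tips: 0).
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_tips
    lam = cfg.birth_rate

    # grow forward in time: k extant lineages wait Exp(k*lam) to the next split
    root = Node(0, name=None)
    extant = [root]
    birth = {id(root): 0.0}
    t = 0.0
    while len(extant) < n:
        k = len(extant)
        t += rng.exponential(1.0 / (k * lam))
        i = rng.integers(k)
        nd = extant.pop(i)
        nd.length = t - birth[id(nd)] if nd.parent is not None else 0.0
        birth[id(nd)] = birth.get(id(nd), 0.0)
        nd.annotations["split_time"] = repr(t)
        for _ in range(2):
            child = Node(0)
            child.parent = nd
            nd.children.append(child)
            birth[id(child)] = t
            extant.append(child)
    # final hold time, then cut all extant lineages at the present
    t += rng.exponential(1.0 / (n * lam))
    for j, nd in enumerate(extant):
        nd.length = t - birth[id(nd)]

    tree = RootedTree.from_root(root)
    for i, tip in enumerate(tree.tips()):
        tip.name = f"t{i + 1}"
    # ages before present
    for nd in tree.preorder():
        if nd.is_tip:
            nd.annotations["true_time"] = "0"
        else:
            split = float(nd.annotations.pop("split_time"))
            nd.annotations["true_time"] = repr(t - split)
    tree.validate()
    return tree


def apply_rate_model(
    timetree: RootedTree,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> RootedTree:
    """Convert a timetree to a phylogram: branch length = duration x rate.

    strict: every branch rate equals mu.  iid_lognormal: rates are drawn
    independently per branch with mean mu and log-sd ``sdlog``.
    autocorrelated: log-rates follow a random walk down the tree,
    child log-rate = parent log-rate + Normal(0, step_sdlog), rooted at
    log(mu).  The true rate of every branch is stored in the ``true_rate``
    annotation of the child node.
    """
    rng = cfg.rng() if rng is None else rng
    phylo = timetree.copy()
    lograte_at: dict[int, float] = {phylo.root.id: float(np.log(cfg.mu))}
    for nd in phylo.preorder():
        if nd.is_root:
            continue
        if cfg.rate_model == "strict":
            rate = cfg.mu
        elif cfg.rate_model == "iid_lognormal":
            # meanlog chosen so the arithmetic mean rate is mu
            rate = float(
                rng.lognormal(np.log(cfg.mu) - 0.5 * cfg.sdlog**2, cfg.sdlog)
            )
        else:  # autocorrelated geometric Brownian walk
            lograte = lograte_at[nd.parent.id] + float(
                rng.normal(0.0, cfg.step_sdlog)
            )
            lograte_at[nd.id] = lograte
            rate = float(np.exp(lograte))
        nd.annotations["true_rate"] = repr(rate)
        nd.length = nd.length * rate
    return phylo


def sample_tips_serially(
    timetree: RootedTree,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    present: float = 2020.0,
) -> tuple[RootedTree, dict[str, float]]:
    """Cut tips at exponentially staggered heights within ``cfg.date_span``.

    Each tip's terminal branch is shortened by an offset drawn from an
    exponential with mean span/3, truncated to the span and to the branch's
    own duration.  Returns the pruned timetree and a taxon -> decimal-year
    sampling-date table anchored at ``present``.
    """
    rng = cfg.rng() if rng is None else rng
    if cfg.date_span <= 0:
        raise ValueError("date_span must be > 0 for serial sampling")
    t = timetree.copy()
    dates: dict[str, float] = {}
    for tip in t.tips():
        off = min(rng.exponential(cfg.date_span / 3.0), cfg.date_span)
        off = min(off, 0.95 * tip.length)
        tip.length -= off
        tip.annotations["true_time"] = repr(off)
        dates[tip.name] = present - off
    return t, dates


def _encode(seqs: np.ndarray, alphabet: str) -> list[str]:
    lut = np.array(list(alphabet))
    return ["".join(lut[row]) for row in seqs]


def simulate_alignment(
    phylogram: RootedTree,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    model=None,
) -> list[tuple[str, str]]:
    """Evolve an alignment along ``phylogram`` (branch lengths = expected
    substitutions/site).  Root states are drawn from the model's stationary
    frequencies; each branch applies the model's transition matrix.
    Returns ``[(taxon, sequence), ...]`` in tip preorder.
    """
    from .likelihood import get_model

    rng = cfg.rng() if rng is None else rng
    mod = model if model is not None else get_model(cfg.model)
    k = mod.n_states
    L = cfg.seq_length

    states: dict[int, np.ndarray] = {}
    states[phylogram.root.id] = rng.choice(k, size=L, p=mod.freqs)
    for nd in phylogram.preorder():
        if nd.is_root:
            continue
        P = mod.transition_matrix(nd.length)
        parent = states[nd.parent.id]
        child = np.empty(L, dtype=np.int64)
        for s in range(k):
            idx = np.nonzero(parent == s)[0]
            if idx.size:
                child[idx] = rng.choice(k, size=idx.size, p=P[s])
        states[nd.id] = child
    out = []
    for tip in phylogram.tips():
        out.append((tip.name, "".join(mod.alphabet[s] for s in states[tip.id])))
    return out
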