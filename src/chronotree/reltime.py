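"""Relative-rate framework: lineage rates and relative node times.

Given a rooted phylogram (branch lengths in substitutions/site) the method
estimates, without assuming a molecular clock, a relative evolutionary rate
for every lineage and a relative time for every node (root = 1,
contemporaneous tips = 0).

The recursion, fixed as this package's normative definition:

* post-order, at a node with children c_1..c_k, let
  d(c_j) = branch(c_j) + mean rate-adjusted node-to-tip path below c_j;
* local relative rates r(c_j) = k * d(c_j) / sum_i d(c_i), so sister
  lineages average to 1 locally;
* the lineage rate of a branch is the product of local rates on the path
  from the root;
* adjusted node heights h satisfy h(i) = h(c) + branch(c)/lineage_rate(c),
  identical through every child by construction; relative time is h/h(root).

Multifurcations are handled directly by the k-way local-rate formula (an
order-invariant generalization of the two-child ratio); single-child chains
are collapsed before the recursion.  Uncertainty is propagated by Monte
Carlo: lineage rates are perturbed with mean-one lognormal noise of a given
coefficient of variation and heights recomputed per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError
from .tree import Node, RootedTree

__all__ = ["RelTimeResult", "relative_rates_and_times", "monte_carlo_time_samples"]

RATE_FLOOR = 1e-9
MIN_MC_SAMPLES = 100


@dataclass
class RelTimeResult:
    """Per-node relative times and per-lineage relative rates.

    Arrays are indexed by ``node.id`` of ``tree`` (the input after
    unifurcation collapse).  ``heights`` are adjusted node heights above the
    contemporaneous tip level; ``rel_times`` = heights / root height.
    ``lineage_rates`` holds the relative rate of the branch above each
    non-root node (root entry = 1).
    """

    tree: RootedTree
    rel_times: np.ndarray
    lineage_rates: np.ndarray
    heights: np.ndarray
    outgroup: frozenset[str] = field(default_factory=frozenset)

    @property
    def root_height(self) -> float:
        return float(self.heights[self.tree.root.id])

    def adjusted_depth(self, node: Node) -> float:
        """Rate-adjusted root-to-node depth (root = 0)."""
        return self.root_height - float(self.heights[node.id])

    def tip_regression_depth(self, tip: Node) -> float:
        """Root-to-tip depth used by tip-date regression.

        The terminal branch is divided by the *parent's* lineage rate: the
        tip's own rate would, by construction of the recursion, equalize all
        tip depths and erase any sampling-time signal.
        """
        if not tip.is_tip:
            raise ValueError("tip_regression_depth expects a tip node")
        return self.adjusted_depth(tip.parent) + tip.length / max(
            float(self.lineage_rates[tip.parent.id]), RATE_FLOOR
        )

    def reported_nodes(self) -> list[Node]:
        """Nodes with reported times (outgroup tips and their pure-outgroup
        ancestors are excluded, mirroring the usual outgroup convention)."""
        if not self.outgroup:
            return list(self.tree.preorder())
        keep = []
        below: dict[int, bool] = {}
        for nd in self.tree.postorder():
            if nd.is_tip:
                below[nd.id] = nd.name in self.outgroup
            else:
                below[nd.id] = all(below[c.id] for c in nd.children)
        for nd in self.tree.preorder():
            if not below[nd.id]:
                keep.append(nd)
        return keep


def relative_rates_and_times(
    tree: RootedTree, outgroup: Sequence[str] = ()
) -> RelTimeResult:
    """Run the relative-rate recursion on a rooted phylogram.

    Requires >= 3 tips and non-negative branch lengths.  An internal node
    whose subtree carries no substitutions at all gets local rates 1 with a
    warning.  Scale-invariant: multiplying all branch lengths by a positive
    constant leaves rates and relative times unchanged.
    """
    if tree.n_tips < 3:
        raise DegenerateInputError("relative-rate estimation needs >= 3 tips")
    work = tree.suppress_unifurcations()
    work.validate()
    n = len(work.nodes)

    mean_depth = np.zeros(n)  # mean adjusted node-to-tip path below node
    n_tips_below = np.zeros(n, dtype=np.int64)
    local_rate = np.ones(n)  # rate of the branch above each node, locally

    for nd in work.postorder():
        if nd.is_tip:
            n_tips_below[nd.id] = 1
            continue
        kids = nd.children
        d = np.array([c.length + mean_depth[c.id] for c in kids])
        total = d.sum()
        if total <= 0.0:
            warnings.warn(
                f"all-zero subtree at node {nd.id}: local rates set to 1",
                stacklevel=2,
            )
            rates = np.ones(len(kids))
        else:
            rates = np.maximum(len(kids) * d / total, RATE_FLOOR)
        for c, r in zip(kids, rates):
            local_rate[c.id] = r
        w = np.array([n_tips_below[c.id] for c in kids], dtype=float)
        n_tips_below[nd.id] = int(w.sum())
        # mean over tips of adjusted paths; equals total/k without clamping
        mean_depth[nd.id] = float(np.dot(w, d / rates) / w.sum())

    lineage = np.ones(n)
    for nd in work.preorder():
        if nd.is_root:
            continue
        lineage[nd.id] = max(lineage[nd.parent.id] * local_rate[nd.id], RATE_FLOOR)

    heights = np.zeros(n)
    for nd in work.postorder():
        if nd.is_tip:
            continue
        hs = [heights[c.id] + c.length / lineage[c.id] for c in nd.children]
        heights[nd.id] = float(np.mean(hs))

    h_root = heights[work.root.id]
    if h_root <= 0.0:
        raise DegenerateInputError(
            "tree has zero total depth; relative times are undefined"
        )
    rel_times = heights / h_root
    rel_times[work.root.id] = 1.0
    return RelTimeResult(
        tree=work,
        rel_times=rel_times,
        lineage_rates=lineage,
        heights=heights,
        outgroup=frozenset(outgroup),
    )


def monte_carlo_time_samples(
    result: RelTimeResult,
    n_samples: int,
    rate_cv: float = 0.2,
    seed: Optional[int] = None,
    relative: bool = True,
) -> np.ndarray:
    """Replicate node times under lineage-rate perturbation.

    Each replicate multiplies every lineage rate by independent mean-one
    lognormal noise with coefficient of variation ``rate_cv`` and recomputes
    adjusted heights.  Returns an ``(n_samples, n_nodes)`` matrix, columns
    indexed by ``node.id`` of ``result.tree``; with ``relative`` each row is
    normalized by its own root height.  ``rate_cv = 0`` reproduces the point
    estimate in every row.  Deterministic under a fixed seed.
    """
    if n_samples < MIN_MC_SAMPLES:
        raise ValueError(f"n_samples must be >= {MIN_MC_SAMPLES}")
    if rate_cv < 0:
        raise ValueError("rate_cv must be >= 0")
    tree = result.tree
    n = len(tree.nodes)
    heights = _perturbed_heights(result, n_samples, rate_cv, seed)
    if relative:
        return heights / heights[:, tree.root.id][:, None]
    return heights


def _perturbed_heights(
    result: RelTimeResult,
    n_samples: int,
    rate_cv: float,
    seed: Optional[int],
) -> np.ndarray:
    return perturbed_rates_and_heights(result, n_samples, rate_cv, seed)[1]


def perturbed_rates_and_heights(
    result: RelTimeResult,
    n_samples: int,
    rate_cv: float,
    seed: Optional[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Perturbed lineage rates and the matching heights (one RNG stream)."""
    tree = result.tree
    n = len(tree.nodes)
    rng = np.random.default_rng(seed)
    if rate_cv == 0:
        noise = np.ones((n_samples, n))
    else:
        sigma = float(np.sqrt(np.log1p(rate_cv**2)))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_samples, n))
    rates = np.maximum(result.lineage_rates[None, :] * noise, RATE_FLOOR)
    heights = np.zeros((n_samples, n))
    for nd in tree.postorder():
        if nd.is_tip:
            continue
        acc = np.zeros(n_samples)
        for c in nd.children:
            acc += heights[:, c.id] + c.length / rates[:, c.id]
        heights[:, nd.id] = acc / len(nd.children)
    return rates, heights
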