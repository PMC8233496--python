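"""Neutral evolutionary probabilities (EP) of alleles in a focal sequence.

Under neutrality, the probability of observing each possible allele
(4 nucleotides or 20 amino acids) at a position in a focal species is its
posterior given the other species' states and a timetree.  The first
sequence of the alignment is the focal taxon.  Alleles with EP < 0.05 are
flagged nonneutral; disease-associated and adaptive variants tend to fall in
this class.

Pipeline: the tree is reduced to relative times (applying the relative-rate
framework when a phylogram is supplied; an already-ultrametric tree is used
as-is), a single global rate converts relative durations to expected
substitutions per branch (fitted by scalar likelihood maximization over the
alignment with the focal sequence masked), and the focal tip's per-site
marginal posterior is computed by Felsenstein pruning plus one downward
pass, the focal tip contributing all-ones partials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError
from .likelihood import (
    PatternAlignment,
    SubstitutionModel,
    compress_patterns,
    log_likelihood,
)
from .reltime import relative_rates_and_times
from .tree import RootedTree

__all__ = ["EPResult", "ep_scores", "ep_report", "NONNEUTRAL_THRESHOLD"]

NONNEUTRAL_THRESHOLD = 0.05
_ULTRAMETRIC_RTOL = 1e-6


@dataclass
class EPResult:
    """Per-site EP vectors for the focal sequence.

    ``ep`` is (n_sites, n_states), each row summing to 1; ``observed`` holds
    the focal allele per site (missing -> ``-``); ``nonneutral`` flags sites
    whose observed allele has EP below 0.05.
    """

    focal: str
    alphabet: str
    ep: np.ndarray
    observed: list[str]
    nonneutral: np.ndarray
    rate: float
    durations: dict[int, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.ep.shape[0]


def _node_depths(tree: RootedTree) -> dict[int, float]:
    depth = {tree.root.id: 0.0}
    for nd in tree.preorder():
        if not nd.is_root:
            depth[nd.id] = depth[nd.parent.id] + nd.length
    return depth


def _is_ultrametric(tree: RootedTree) -> bool:
    depth = _node_depths(tree)
    d = [depth[t.id] for t in tree.tips()]
    top = max(d)
    return top > 0 and (top - min(d)) <= _ULTRAMETRIC_RTOL * top


def _relative_durations(tree: RootedTree) -> tuple[RootedTree, dict[int, float]]:
    """Branch durations on the working timetree.

    An ultrametric input is taken at face value in its own time units (so a
    fixed ``rate`` is substitutions/site per that unit); a phylogram goes
    through the relative-rate framework, yielding relative durations with
    root height 1.
    """
    if _is_ultrametric(tree):
        work = tree.suppress_unifurcations()
        return work, {
            nd.id: nd.length for nd in work.preorder() if not nd.is_root
        }
    rt = relative_rates_and_times(tree)
    work = rt.tree
    return work, {
        nd.id: float(rt.rel_times[nd.parent.id] - rt.rel_times[nd.id])
        for nd in work.preorder()
        if not nd.is_root
    }


def _fit_global_rate(
    tree: RootedTree,
    durations: dict[int, float],
    pa: PatternAlignment,
    model: SubstitutionModel,
) -> float:
    """Scalar rate maximizing the masked-alignment likelihood on the timetree."""

    def neg_ll(log10_rate: float) -> float:
        t = tree.copy()
        for nd in t.preorder():
            if not nd.is_root:
                nd.length = durations[nd.id] * 10.0**log10_rate
        return -log_likelihood(t, pa, model)

    res = minimize_scalar(
        neg_ll, bounds=(-6.0, 2.0), method="bounded", options={"xatol": 1e-8}
    )
    return float(10.0 ** res.x)


def ep_scores(
    alignment: Sequence[tuple[str, str]],
    tree: RootedTree,
    model: SubstitutionModel,
    rate: Union[float, str] = "auto",
) -> EPResult:
    """EP of every possible allele at every site of the focal sequence.

    The focal taxon is the first alignment record and must be a tree tip;
    the remaining taxa must cover the remaining tips.  ``rate="auto"`` fits
    the global rate to the focal-masked data; pass a number (e.g. 1.0 when
    branch lengths are already expected substitutions on a normalized
    timetree) to fix it.
    """
    if not alignment:
        raise ConfigurationError("empty alignment")
    focal = alignment[0][0]
    tip_names = set(tree.tip_names())
    if focal not in tip_names:
        raise ConfigurationError(f"focal taxon {focal!r} is not a tip of the tree")
    aln_names = {name for name, _ in alignment}
    missing = tip_names - aln_names
    if missing:
        raise ConfigurationError(f"tree tips absent from alignment: {sorted(missing)}")

    # mask the focal sequence so it contributes no information
    L = len(alignment[0][1])
    masked = [(focal, "-" * L)] + [
        (n, s) for n, s in alignment if n != focal
    ]
    pa = compress_patterns(masked, model)
    if model.alphabet != pa.alphabet:
        raise ConfigurationError("model alphabet does not match alignment")
    work, durations = _relative_durations(tree)

    if rate == "auto":
        fitted_rate = _fit_global_rate(work, durations, pa, model)
    else:
        fitted_rate = float(rate)
        if fitted_rate <= 0:
            raise ConfigurationError("rate must be positive")

    timed = work.copy()
    for nd in timed.preorder():
        if not nd.is_root:
            nd.length = durations[nd.id] * fitted_rate

    ep_patterns, warns = _focal_posterior(timed, pa, model, focal)
    ep_sites = _expand_to_sites(alignment, pa, model, ep_patterns)

    focal_seq = dict(alignment)[focal].upper()
    codes = model.encode(focal_seq)
    observed = [model.alphabet[c] if c >= 0 else "-" for c in codes]
    obs_ep = np.array(
        [
            ep_sites[i, codes[i]] if codes[i] >= 0 else np.nan
            for i in range(L)
        ]
    )
    with np.errstate(invalid="ignore"):
        nonneutral = obs_ep < NONNEUTRAL_THRESHOLD
    return EPResult(
        focal=focal,
        alphabet=model.alphabet,
        ep=ep_sites,
        observed=observed,
        nonneutral=nonneutral,
        rate=fitted_rate,
        durations=durations,
        warnings=warns,
    )


def _expand_to_sites(alignment, pa: PatternAlignment, model, ep_patterns):
    """Map per-pattern EP rows back to original site order."""
    focal = alignment[0][0]
    L = len(alignment[0][1])
    masked_rows = [model.encode("-" * L)] + [
        model.encode(s.upper(), where=n) for n, s in alignment if n != focal
    ]
    matrix = np.vstack(masked_rows)
    _, site_to_pattern = np.unique(matrix, axis=1, return_inverse=True)
    return ep_patterns[site_to_pattern]


def _focal_posterior(
    tree: RootedTree, pa: PatternAlignment, model: SubstitutionModel, focal: str
) -> tuple[np.ndarray, list[str]]:
    """(m, k) posterior state probabilities at the focal tip.

    Upward pruning partials U, then a downward (outside) pass O; the joint
    P(focal = x, rest of data) is O at the focal tip (its own partials are
    all ones), normalized over x.  Rate categories, when present, are summed
    with their weights before normalizing.
    """
    k = model.n_states
    m = pa.m
    warns: list[str] = []
    joint = np.zeros((m, k))
    for cat_rate, cat_w in model.rate_categories:
        P = {
            nd.id: model.transition_matrix(nd.length * cat_rate)
            for nd in tree.preorder()
            if not nd.is_root
        }
        # upward pass
        U: dict[int, np.ndarray] = {}
        up_msg: dict[int, np.ndarray] = {}  # child id -> P_c @ U_c (m, k of parent)
        from .likelihood import _tip_partials

        for nd in tree.postorder():
            if nd.is_tip:
                U[nd.id] = _tip_partials(pa.row(nd.name), k)
            else:
                part = np.ones((m, k))
                for c in nd.children:
                    up_msg[c.id] = U[c.id] @ P[c.id].T
                    part *= up_msg[c.id]
                U[nd.id] = part
        # downward pass
        O: dict[int, np.ndarray] = {tree.root.id: np.tile(model.freqs, (m, 1))}
        for nd in tree.preorder():
            for c in nd.children:
                sib = O[nd.id].copy()
                for s in nd.children:
                    if s is not c:
                        sib *= up_msg[s.id]
                O[c.id] = sib @ P[c.id]
        focal_node = tree.tip(focal)
        joint += cat_w * O[focal_node.id]
    totals = joint.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        warns.append("sites with zero likelihood set to stationary frequencies")
        joint[zero] = model.freqs
        totals = joint.sum(axis=1)
    # all-missing patterns: posterior is exactly the stationary distribution;
    # warn because such sites carry no information
    all_missing = np.all(pa.patterns < 0, axis=0)
    if np.any(all_missing):
        warns.append(
            f"{int(all_missing.sum())} site pattern(s) with no observed states: "
            "EP equals the stationary frequencies there"
        )
    return joint / totals[:, None], warns


def ep_report(result: EPResult) -> str:
    """TSV export: site, observed allele, EP per state, nonneutral flag."""
    header = ["site", "observed"] + [f"EP_{a}" for a in result.alphabet] + [
        "nonneutral"
    ]
    lines = ["\t".join(header)]
    for i in range(result.n_sites):
        row = [str(i + 1), result.observed[i]]
        row += [f"{v:.6f}" for v in result.ep[i]]
        flag = "1" if (result.observed[i] != "-" and result.nonneutral[i]) else "0"
        row.append(flag)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
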