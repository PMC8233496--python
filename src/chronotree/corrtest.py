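"""Test for autocorrelation of evolutionary rates among lineages.

Autocorrelated rates (inherited from ancestor to descendant) and
independently varying rates are the two classic relaxed-clock regimes;
knowing which fits a phylogeny guides the choice of clock prior.  The test
computes correlation features over the lineage rates estimated by the
relative-rate framework — Pearson and Spearman correlations of
(ancestor lineage rate, descendant lineage rate) pairs and of sister-pair
rates — and maps them through a logistic model to a CorrScore in [0, 1].
High scores indicate rate inheritance.

The logistic coefficients were fit once, on this package's own simulator
(Yule trees dressed with independent-lognormal vs geometric-Brownian
autocorrelated rates; see ``scripts/train_corrtest.py``, which records the
procedure and seed) and are frozen here.  The P-value is calibrated
empirically at run time: the observed score is ranked against CorrScores of
freshly simulated independent-rate trees of matched tip count (topology
resampled), with the +1/(n+1) correction, so it is exact to Monte-Carlo
error regardless of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .reltime import RelTimeResult, relative_rates_and_times
from .simulate import SimulationConfig, apply_rate_model, simulate_timetree
from .tree import RootedTree

__all__ = [
    "CorrTestResult",
    "rate_features",
    "corr_score",
    "null_corr_scores",
    "corrtest",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("pearson_pc", "spearman_pc", "pearson_ss", "spearman_ss")

# Frozen logistic model: CorrScore = sigmoid(intercept + coef . features).
# Trained by scripts/train_corrtest.py (seed 20260924) on 600 simulated
# trees per class, 50-300 tips, independent-lognormal (sdlog 0.2-0.5) vs
# autocorrelated geometric-Brownian (step sdlog 0.1-0.3) rates.
_LOGISTIC_INTERCEPT = -8.963102
_LOGISTIC_COEF = np.array([1.836785, 2.036255, 6.340297, 6.414564])

MIN_TIPS = 10
MIN_NULL_REPS = 100
NULL_SDLOG = 0.3


@dataclass
class CorrTestResult:
    """CorrScore in [0, 1], simulation-calibrated P-value, and features."""

    corr_score: float
    p_value: float
    features: dict[str, float]
    null_reps: int
    seed: Optional[int]
    null_scores: np.ndarray = field(repr=False, default=None)


def _rate_pairs(rt: RelTimeResult) -> tuple[np.ndarray, np.ndarray]:
    """(ancestor, descendant) lineage-rate pairs and sister-pair rates."""
    tree = rt.tree
    r = rt.lineage_rates
    pc, ss = [], []
    for nd in tree.preorder():
        if nd.is_tip:
            continue
        kids = nd.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                ss.append((r[kids[i].id], r[kids[j].id]))
        if not nd.is_root:
            for c in kids:
                pc.append((r[nd.id], r[c.id]))
    return np.array(pc), np.array(ss)


def rate_features(
    tree_or_result: Union[RootedTree, RelTimeResult]
) -> dict[str, float]:
    """Correlation features of the estimated lineage rates.

    Needs >= 10 tips for feature stability; raises
    :class:`DegenerateInputError` when rates have no variance (strict
    clock), where the test is inapplicable.
    """
    rt = (
        tree_or_result
        if isinstance(tree_or_result, RelTimeResult)
        else relative_rates_and_times(tree_or_result)
    )
    if rt.tree.n_tips < MIN_TIPS:
        raise DegenerateInputError(
            f"rate-autocorrelation features need >= {MIN_TIPS} tips"
        )
    pc, ss = _rate_pairs(rt)
    # a strict clock leaves only rounding jitter in the estimated rates
    tol = 1e-9 * max(1.0, float(np.max(np.abs(pc))))
    if np.ptp(pc[:, 0]) <= tol or np.ptp(pc[:, 1]) <= tol:
        raise DegenerateInputError(
            "lineage rates have zero variance (strict clock); "
            "the autocorrelation test is inapplicable"
        )
    feats = {
        "pearson_pc": float(np.corrcoef(pc[:, 0], pc[:, 1])[0, 1]),
        "spearman_pc": float(stats.spearmanr(pc[:, 0], pc[:, 1]).statistic),
        "pearson_ss": float(np.corrcoef(ss[:, 0], ss[:, 1])[0, 1]),
        "spearman_ss": float(stats.spearmanr(ss[:, 0], ss[:, 1]).statistic),
    }
    for k, v in feats.items():
        if not np.isfinite(v):
            feats[k] = 0.0
    return feats


def corr_score(features: dict[str, float]) -> float:
    """Logistic transform of the feature vector; always in [0, 1]."""
    x = np.array([features[k] for k in FEATURE_NAMES])
    z = _LOGISTIC_INTERCEPT + float(np.dot(_LOGISTIC_COEF, x))
    return float(1.0 / (1.0 + np.exp(-z)))


def null_corr_scores(
    n_tips: int, reps: int, seed: Optional[int] = None, sdlog: float = NULL_SDLOG
) -> np.ndarray:
    """CorrScores of independent-rate simulations (matched tip count,
    topology resampled per replicate): the empirical null."""
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for b in range(reps):
        sub = int(rng.integers(2**31 - 1))
        cfg = SimulationConfig(
            n_tips=n_tips,
            seed=sub,
            rate_model="iid_lognormal",
            sdlog=sdlog,
            mu=1.0,
        )
        srng = cfg.rng()
        phylo = apply_rate_model(simulate_timetree(cfg, srng), cfg, srng)
        out[b] = corr_score(rate_features(phylo))
    return out


def corrtest(
    tree: RootedTree,
    null_reps: int = 1000,
    seed: Optional[int] = None,
    null_scores: Optional[np.ndarray] = None,
) -> CorrTestResult:
    """Run the rate-autocorrelation test on a rooted phylogram.

    The P-value is the +1-corrected fraction of null (independent-rate)
    simulations whose CorrScore is at least the observed one; it is always
    >= 1/(null_reps + 1) and decreases as the CorrScore increases for a
    fixed null sample.  ``null_scores`` may supply a precomputed null pool
    (e.g. shared across trees of equal tip count); otherwise ``null_reps``
    fresh simulations are run.
    """
    feats = rate_features(tree)
    score = corr_score(feats)
    if null_scores is None:
        if null_reps < MIN_NULL_REPS:
            raise ValueError(f"null_reps must be >= {MIN_NULL_REPS}")
        null_scores = null_corr_scores(tree.n_tips, null_reps, seed=seed)
    else:
        null_scores = np.asarray(null_scores, dtype=float)
        if null_scores.size < MIN_NULL_REPS:
            raise ValueError(f"need >= {MIN_NULL_REPS} null scores")
    n = null_scores.size
    p = (1.0 + float(np.sum(null_scores >= score))) / (n + 1.0)
    return CorrTestResult(
        corr_score=score,
        p_value=p,
        features=feats,
        null_reps=n,
        seed=seed,
        null_scores=null_scores,
    )
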