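"""Site-configuration compression and pattern-weighted likelihood.

An alignment of L sites typically contains only m distinct site
configurations (the vector of states shown by all sequences at one column).
Identical configurations have identical likelihoods, so the engine stores
each distinct pattern once with an integer weight; the total log-likelihood
is the weight-sum of per-pattern log-likelihoods, and memory for conditional
partials scales with m rather than L.

Models: JC (equal rates, 4 states), HKY (transition/transversion ratio
kappa with arbitrary base frequencies), Poisson (equal rates, 20 amino-acid
states); each optionally under discrete-gamma rate variation.  Gaps and
ambiguity codes are treated as missing data (all-ones partials).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import ConfigurationError, InputError
from .tree import RootedTree

__all__ = [
    "NT_ALPHABET",
    "AA_ALPHABET",
    "PatternAlignment",
    "SubstitutionModel",
    "JC",
    "HKY",
    "Poisson",
    "get_model",
    "read_fasta",
    "compress_patterns",
    "log_likelihood",
    "pattern_log_likelihoods",
    "optimize_branch_lengths",
    "compression_report",
]

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

# characters accepted as missing data per alphabet
_NT_MISSING = set("-?NRYSWKMBDHVX.")
_AA_MISSING = set("-?XBZJ.")

MISSING = -1


# -- substitution models -------------------------------------------------------


class SubstitutionModel:
    """Time-reversible substitution model with unit mean rate.

    Subclasses define the alphabet, stationary frequencies and rate matrix;
    ``transition_matrix(t)`` returns P(t) whose rows sum to 1 for any
    branch length t >= 0.  Discrete-gamma rate variation is expressed as
    ``(rate, weight)`` categories applied at the likelihood level.
    """

    alphabet: str
    freqs: np.ndarray
    _Q: np.ndarray

    def __init__(self, gamma_alpha: Optional[float] = None, gamma_ncat: int = 4):
        if gamma_alpha is not None and gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self.gamma_alpha = gamma_alpha
        self.gamma_ncat = gamma_ncat

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    @property
    def rate_categories(self) -> list[tuple[float, float]]:
        """(rate, probability) pairs; a single (1, 1) without gamma."""
        if self.gamma_alpha is None:
            return [(1.0, 1.0)]
        return discrete_gamma_rates(self.gamma_alpha, self.gamma_ncat)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if t == 0:
            return np.eye(self.n_states)
        return expm(self._Q * t)

    def missing_codes(self) -> set:
        return _NT_MISSING if self.n_states == 4 else _AA_MISSING

    def encode(self, seq: str, where: str = "") -> np.ndarray:
        """Map a sequence string to integer state codes (missing = -1)."""
        lut = {c: i for i, c in enumerate(self.alphabet)}
        out = np.empty(len(seq), dtype=np.int8)
        missing = self.missing_codes()
        for j, c in enumerate(seq.upper()):
            if c in lut:
                out[j] = lut[c]
            elif c in missing:
                out[j] = MISSING
            else:
                raise InputError(
                    f"unknown character {c!r} at column {j + 1}"
                    + (f" of {where}" if where else "")
                )
        return out


def _normalize_q(Q: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(freqs, np.diag(Q)))
    return Q / mean_rate


class JC(SubstitutionModel):
    """Jukes-Cantor: equal rates, equal base frequencies."""

    alphabet = NT_ALPHABET

    def __init__(self, **kw):
        super().__init__(**kw)
        k = 4
        self.freqs = np.full(k, 1.0 / k)
        self._Q = _normalize_q(np.ones((k, k)), self.freqs)

    def transition_matrix(self, t: float) -> np.ndarray:
        # closed form: P_same = 1/4 + 3/4 e^{-4t/3}
        if t < 0:
            raise ValueError("branch length must be >= 0")
        e = np.exp(-4.0 * t / 3.0)
        same = 0.25 + 0.75 * e
        diff = 0.25 - 0.25 * e
        P = np.full((4, 4), diff)
        np.fill_diagonal(P, same)
        return P


class HKY(SubstitutionModel):
    """HKY: transition/transversion rate ratio kappa, free base frequencies."""

    alphabet = NT_ALPHABET
    _TRANSITIONS = ((0, 2), (2, 0), (1, 3), (3, 1))  # A<->G, C<->T

    def __init__(self, kappa: float = 2.0, freqs: Sequence[float] = None, **kw):
        super().__init__(**kw)
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        f = np.asarray(freqs if freqs is not None else [0.25] * 4, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must be 4 non-negative values summing to 1")
        self.kappa = kappa
        self.freqs = f / f.sum()
        Q = np.ones((4, 4))
        for i, j in self._TRANSITIONS:
            Q[i, j] = kappa
        Q = Q * self.freqs[None, :]
        self._Q = _normalize_q(Q, self.freqs)


class Poisson(SubstitutionModel):
    """Poisson amino-acid model: equal exchange rates, equal frequencies."""

    alphabet = AA_ALPHABET

    def __init__(self, **kw):
        super().__init__(**kw)
        k = 20
        self.freqs = np.full(k, 1.0 / k)
        self._Q = _normalize_q(np.ones((k, k)), self.freqs)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        k = 20
        e = np.exp(-k / (k - 1.0) * t)
        same = 1.0 / k + (1.0 - 1.0 / k) * e
        diff = (1.0 - e) / k
        P = np.full((k, k), diff)
        np.fill_diagonal(P, same)
        return P


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> list[tuple[float, float]]:
    """Equal-probability discrete-gamma categories (category-mean rates)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # mean rate within each slice via the incomplete gamma of shape alpha+1
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    means = (upper - lower) * ncat
    return [(float(m), 1.0 / ncat) for m in means]


def get_model(name: str, **kw) -> SubstitutionModel:
    name = name.lower()
    if name == "jc":
        return JC(**kw)
    if name == "hky":
        return HKY(**kw)
    if name == "poisson":
        return Poisson(**kw)
    raise ConfigurationError(f"unknown model {name!r} (expected jc, hky, poisson)")


# -- alignment handling --------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (wrapped, case-insensitive) FASTA file as [(name, seq), ...]."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


@dataclass
class PatternAlignment:
    """Alignment compressed to its distinct site configurations.

    ``patterns`` is an (n_taxa, m) integer matrix of state codes
    (missing = -1); ``weights`` are positive pattern counts summing to the
    original site count ``L``.
    """

    taxa: list[str]
    patterns: np.ndarray
    weights: np.ndarray
    L: int
    alphabet: str

    @property
    def m(self) -> int:
        return self.patterns.shape[1]

    @property
    def compression_factor(self) -> float:
        return self.m / self.L

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.patterns[self.taxa.index(taxon)]
        except ValueError:
            raise ConfigurationError(f"taxon {taxon!r} not in alignment") from None


def compress_patterns(
    alignment: Sequence[tuple[str, str]], model: Optional[SubstitutionModel] = None
) -> PatternAlignment:
    """Collapse an alignment to distinct site configurations with weights.

    Two columns differing only in gap placement are distinct patterns (the
    missing code participates in the pattern hash).  Raises
    :class:`InputError` on ragged rows or characters outside the alphabet
    plus its gap/ambiguity codes.
    """
    if not alignment:
        raise InputError("empty alignment")
    mod = model if model is not None else _guess_model(alignment)
    names = [name for name, _ in alignment]
    L = len(alignment[0][1])
    rows = []
    for name, seq in alignment:
        if len(seq) != L:
            raise InputError(
                f"ragged alignment: row {name!r} has {len(seq)} sites, expected {L}"
            )
        rows.append(mod.encode(seq, where=name))
    matrix = np.vstack(rows)  # (n_taxa, L)
    patterns, counts = np.unique(matrix, axis=1, return_counts=True)
    return PatternAlignment(
        taxa=names,
        patterns=patterns,
        weights=counts.astype(np.int64),
        L=L,
        alphabet=mod.alphabet,
    )


def _guess_model(alignment) -> SubstitutionModel:
    letters = set("".join(seq.upper() for _, seq in alignment))
    if letters - set(NT_ALPHABET) - _NT_MISSING:
        return Poisson()
    return JC()


def compression_report(pa: PatternAlignment, loglik: Optional[float] = None) -> str:
    lines = [
        f"sites\t{pa.L}",
        f"patterns\t{pa.m}",
        f"compression_factor\t{pa.compression_factor:.6g}",
    ]
    if loglik is not None:
        lines.append(f"log_likelihood\t{loglik:.10g}")
    return "\n".join(lines) + "\n"


# -- pruning likelihood --------------------------------------------------------


def _tip_partials(codes: np.ndarray, k: int) -> np.ndarray:
    """(m, k) one-hot partials; missing states contribute all-ones."""
    m = codes.shape[0]
    out = np.zeros((m, k))
    obs = codes >= 0
    out[np.nonzero(obs)[0], codes[obs]] = 1.0
    out[~obs] = 1.0
    return out


def pattern_log_likelihoods(
    tree: RootedTree, pa: PatternAlignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-pattern log-likelihoods by post-order pruning (length m)."""
    if model.alphabet != pa.alphabet:
        raise ConfigurationError("model alphabet does not match alignment alphabet")
    k = model.n_states
    taxa = set(pa.taxa)
    for name in tree.tip_names():
        if name not in taxa:
            raise ConfigurationError(f"tree tip {name!r} absent from alignment")

    site_lik = np.zeros(pa.m)
    for rate, weight in model.rate_categories:
        partials: dict[int, np.ndarray] = {}
        for nd in tree.postorder():
            if nd.is_tip:
                partials[nd.id] = _tip_partials(pa.row(nd.name), k)
            else:
                part = np.ones((pa.m, k))
                for c in nd.children:
                    P = model.transition_matrix(c.length * rate)
                    part *= partials.pop(c.id) @ P.T
                partials[nd.id] = part
        site_lik += weight * (partials[tree.root.id] @ model.freqs)
    with np.errstate(divide="ignore"):
        return np.log(site_lik)


def log_likelihood(
    tree: RootedTree, pa: PatternAlignment, model: SubstitutionModel
) -> float:
    """Total log-likelihood: pattern log-likelihoods weighted by counts."""
    return float(np.dot(pa.weights, pattern_log_likelihoods(tree, pa, model)))


# -- branch-length optimization ------------------------------------------------

_BL_MAX = 10.0


def optimize_branch_lengths(
    tree: RootedTree,
    pa: PatternAlignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 50,
    default_init: float = 0.1,
) -> RootedTree:
    """ML branch lengths on a fixed topology.

    Coordinate-wise scalar maximization per branch, round-robin until the
    largest per-round length change drops below ``tol`` (or ``max_rounds``,
    in which case a warning is issued and the best-so-far tree returned).
    Zero-length input branches are initialised at ``default_init`` only when
    the whole tree has no length information.
    """
    t = tree.copy()
    if all(nd.length == 0 for nd in t.preorder() if not nd.is_root):
        for nd in t.preorder():
            if not nd.is_root:
                nd.length = default_init
    branches = [nd for nd in t.preorder() if not nd.is_root]

    for _ in range(max_rounds):
        max_delta = 0.0
        for nd in branches:
            old = nd.length

            def neg_ll(x: float, nd=nd) -> float:
                nd.length = x
                return -log_likelihood(t, pa, model)

            res = minimize_scalar(
                neg_ll, bounds=(0.0, _BL_MAX), method="bounded",
                options={"xatol": min(tol * 1e-2, 1e-8)},
            )
            new = float(res.x)
            # snap to the boundary when it is at least as good
            if neg_ll(0.0, nd) <= res.fun:
                new = 0.0
            max_delta = max(max_delta, abs(new - old))
            nd.length = new
        if max_delta < tol:
            break
    else:
        warnings.warn(
            f"branch-length optimization did not converge in {max_rounds} rounds; "
            "returning best-so-far lengths",
            stacklevel=2,
        )
    return t
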