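"""Node dating: relative times -> absolute times via calibration densities.

A calibration attaches prior information about a node's true age: a
probability density (normal, lognormal with offset, exponential with offset,
uniform) or a hard constraint (point, minimum bound, maximum bound).  The
global scaling factor f that maps relative times to absolute ones is found
by maximizing the summed log-densities over density-type calibrations inside
the feasible interval implied by the hard constraints; absolute node time =
f * relative time, clamped into bounds with a monotonicity repair pass.

Confidence intervals combine two variance sources: lineage-rate
heterogeneity (Monte-Carlo relative-time replicates) and the calibration
densities themselves (a fresh draw of calibration ages per replicate).  With
a tree-only input there is no branch-length re-estimation variance, so
intervals are narrower than alignment-based ones would be.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import ConstraintError, ConfigurationError
from .reltime import RelTimeResult, monte_carlo_time_samples
from .tree import Node, RootedTree

__all__ = [
    "CalibrationDensity",
    "TimetreeResult",
    "fit_time_scale",
    "fixed_rate_scale",
    "read_calibration_file",
    "parse_calibration_line",
]

DENSITY_KINDS = ("normal", "lognormal", "exponential", "uniform")
CONSTRAINT_KINDS = ("point", "minbound", "maxbound")
DEFAULT_MC_SAMPLES = 10_000


@dataclass
class CalibrationDensity:
    """One calibration on one node.

    ``selector`` is either ``("mrca", taxonA, taxonB)`` or
    ``("node", name)``.  ``kind`` and its parameters follow the standard
    density menu: normal(mean, sd); lognormal(offset, mean, sd) on
    (time - offset) with log-scale mean/sd; exponential(offset, decay);
    uniform(min, max); plus hard point/minbound/maxbound constraints.
    Times are in the user's units (Ma, calendar years, ...).
    """

    selector: tuple
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k, p = self.kind, self.params
        if k not in DENSITY_KINDS + CONSTRAINT_KINDS:
            raise ConfigurationError(f"unknown calibration kind {k!r}")
        try:
            if k == "normal":
                if p["sd"] <= 0:
                    raise ConfigurationError("normal calibration needs sd > 0")
            elif k == "lognormal":
                if p["sd"] <= 0:
                    raise ConfigurationError("lognormal calibration needs sd > 0")
                if p.setdefault("offset", 0.0) < 0:
                    raise ConfigurationError("offset must be >= 0")
            elif k == "exponential":
                if p["decay"] <= 0:
                    raise ConfigurationError("exponential calibration needs decay > 0")
                if p.setdefault("offset", 0.0) < 0:
                    raise ConfigurationError("offset must be >= 0")
            elif k == "uniform":
                if not p["min"] < p["max"]:
                    raise ConfigurationError("uniform calibration needs min < max")
            else:
                if p["time"] < 0:
                    raise ConfigurationError("calibration time must be >= 0")
        except KeyError as exc:
            raise ConfigurationError(
                f"calibration kind {k!r} missing parameter {exc.args[0]!r}"
            ) from None

    # -- density interface ----------------------------------------------------

    @property
    def is_density(self) -> bool:
        return self.kind in DENSITY_KINDS

    def _dist(self):
        p = self.params
        if self.kind == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.kind == "lognormal":
            return stats.lognorm(s=p["sd"], scale=np.exp(p["mean"]), loc=p["offset"])
        if self.kind == "exponential":
            return stats.expon(loc=p["offset"], scale=1.0 / p["decay"])
        if self.kind == "uniform":
            return stats.uniform(loc=p["min"], scale=p["max"] - p["min"])
        raise ConfigurationError(f"{self.kind!r} is a hard constraint, not a density")

    def logpdf(self, t: float) -> float:
        return float(self._dist().logpdf(t))

    def pdf(self, t: float) -> float:
        return float(self._dist().pdf(t))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.params["time"])
        return self._dist().rvs(size=size, random_state=rng)

    def support(self) -> tuple[float, float]:
        """Interval outside which the density is zero (densities only)."""
        p = self.params
        if self.kind == "normal":
            return (-np.inf, np.inf)
        if self.kind in ("lognormal", "exponential"):
            return (p["offset"], np.inf)
        if self.kind == "uniform":
            return (p["min"], p["max"])
        raise ConfigurationError(f"{self.kind!r} has no density support")

    def resolve(self, tree: RootedTree) -> Node:
        if self.selector[0] == "mrca":
            return tree.mrca(list(self.selector[1:]))
        if self.selector[0] == "node":
            name = self.selector[1]
            for nd in tree.preorder():
                if nd.name == name:
                    return nd
            raise ConfigurationError(f"no node named {name!r} in tree")
        raise ConfigurationError(f"bad selector {self.selector!r}")


@dataclass
class TimetreeResult:
    """Absolute node times with 95% confidence intervals.

    Arrays are indexed by ``node.id`` of ``tree``; ``f`` is the global
    relative-to-absolute scaling factor (or 1/rate in fixed-rate mode);
    ``diagnostics`` records the density value of each density calibration at
    its fitted node time.
    """

    tree: RootedTree
    times: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    f: float
    rel_times: np.ndarray
    lineage_rates: np.ndarray
    diagnostics: list[dict] = field(default_factory=list)

    def annotate(self, digits: int = 6) -> RootedTree:
        """Copy of the tree with time/ci_lo/ci_hi node annotations."""
        t = self.tree.copy()
        for nd in t.preorder():
            nd.annotations["time"] = f"{self.times[nd.id]:.{digits}g}"
            nd.annotations["ci_lo"] = f"{self.ci_lo[nd.id]:.{digits}g}"
            nd.annotations["ci_hi"] = f"{self.ci_hi[nd.id]:.{digits}g}"
        return t


# -- fitting -------------------------------------------------------------------


def _feasible_interval(
    resolved: list[tuple[CalibrationDensity, Node]], rel_times: np.ndarray
) -> tuple[float, float, Optional[tuple]]:
    """Intersect hard constraints on f; returns (lo, hi, conflict_witness)."""
    lo, hi = 0.0, np.inf
    lo_src = hi_src = None
    for cal, node in resolved:
        tr = rel_times[node.id]
        if tr <= 0:
            raise ConstraintError(
                f"calibration {cal.kind} on a node with relative time 0 "
                "cannot constrain the time scale"
            )
        if cal.kind == "point":
            bound = cal.params["time"] / tr
            if bound > lo:
                lo, lo_src = bound, cal
            if bound < hi:
                hi, hi_src = bound, cal
        elif cal.kind == "minbound":
            bound = cal.params["time"] / tr
            if bound > lo:
                lo, lo_src = bound, cal
        elif cal.kind == "maxbound":
            bound = cal.params["time"] / tr
            if bound < hi:
                hi, hi_src = bound, cal
    witness = (lo_src, hi_src) if lo > hi * (1 + 1e-12) else None
    return lo, hi, witness


def fit_time_scale(
    rt: RelTimeResult,
    calibrations: Sequence[CalibrationDensity],
    n_samples: int = DEFAULT_MC_SAMPLES,
    rate_cv: float = 0.2,
    seed: Optional[int] = None,
) -> TimetreeResult:
    """Fit the global time scale to calibration densities and bounds.

    The scaling factor f maximizes the summed log-density of the calibrated
    node ages f * t_rel over density calibrations, restricted to the
    feasible interval implied by point/min/max constraints.  Node times are
    f * t_rel, clamped into any hard or uniform bounds, with parent >= child
    re-enforced by an upward pass.  CIs are 2.5/97.5 percentiles over Monte
    Carlo replicates that combine rate-heterogeneity noise with a fresh draw
    of each calibration age from its density.
    """
    if not calibrations:
        raise ConfigurationError("at least one calibration is required")
    tree = rt.tree
    resolved = [(cal, cal.resolve(tree)) for cal in calibrations]
    lo, hi, witness = _feasible_interval(resolved, rt.rel_times)
    if witness is not None:
        a, b = witness
        raise ConstraintError(
            f"infeasible calibration set: {a.kind} {a.params} conflicts with "
            f"{b.kind} {b.params}"
        )

    densities = [(cal, nd) for cal, nd in resolved if cal.is_density]

    def neg_obj(f: float) -> float:
        return -sum(cal.logpdf(f * rt.rel_times[nd.id]) for cal, nd in densities)

    if lo == hi or not densities:
        if lo == 0.0 and not np.isfinite(hi):
            raise ConstraintError(
                "no density calibration and no finite hard constraint: "
                "the time scale is unidentified"
            )
        f = lo if lo == hi else (lo + hi) / 2 if np.isfinite(hi) else lo
    else:
        f = _maximize_density(neg_obj, densities, rt, lo, hi)
    if densities and not np.isfinite(neg_obj(f)):
        raise ConstraintError(
            "density calibrations have zero density everywhere on the "
            f"feasible interval [{lo:g}, {hi:g}]"
        )

    times = f * rt.rel_times
    times, ci_bounds = _clamp_bounds(times, resolved, rt)
    times = _monotonicity_repair(tree, times)

    # Monte Carlo CIs
    trel_mc = monte_carlo_time_samples(rt, n_samples, rate_cv=rate_cv, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    draw_cals = [(cal, nd) for cal, nd in resolved if cal.is_density or cal.kind == "point"]
    if draw_cals:
        targets = np.column_stack([cal.draw(rng, n_samples) for cal, nd in draw_cals])
        trel_cal = np.column_stack([trel_mc[:, nd.id] for cal, nd in draw_cals])
        denom = np.sum(trel_cal**2, axis=1)
        f_b = np.sum(targets * trel_cal, axis=1) / np.where(denom > 0, denom, 1.0)
    else:
        # bounds-only calibration: the scale itself carries no density draw
        f_b = np.full(n_samples, f)
    times_b = f_b[:, None] * trel_mc
    ci_lo = np.percentile(times_b, 2.5, axis=0)
    ci_hi = np.percentile(times_b, 97.5, axis=0)
    for node_id, (blo, bhi) in ci_bounds.items():
        ci_lo[node_id] = max(ci_lo[node_id], blo)
        ci_hi[node_id] = min(ci_hi[node_id], bhi)
    ci_lo = np.minimum(ci_lo, times)
    ci_hi = np.maximum(ci_hi, times)

    diagnostics = [
        {
            "kind": cal.kind,
            "node": nd.id,
            "fitted_time": float(times[nd.id]),
            "density": cal.pdf(float(times[nd.id])),
        }
        for cal, nd in densities
    ]
    return TimetreeResult(
        tree=tree,
        times=times,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        f=float(f),
        rel_times=rt.rel_times,
        lineage_rates=rt.lineage_rates,
        diagnostics=diagnostics,
    )


def _maximize_density(neg_obj, densities, rt, lo: float, hi: float) -> float:
    if not np.isfinite(hi):
        # generous upper bracket from the densities' far quantiles
        hi = max(
            float(cal._dist().ppf(1 - 1e-9)) / rt.rel_times[nd.id]
            for cal, nd in densities
        )
        hi = max(hi, lo * (1 + 1e-6), 1e-12)
    if hi <= lo:
        return lo
    res = minimize_scalar(
        neg_obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    f = float(res.x)
    # bounded search can stall at an edge of a flat (zero-density) region
    for probe in (lo, hi):
        if neg_obj(probe) < neg_obj(f):
            f = probe
    return f


def _clamp_bounds(
    times: np.ndarray, resolved, rt: RelTimeResult
) -> tuple[np.ndarray, dict[int, tuple[float, float]]]:
    times = times.copy()
    bounds: dict[int, tuple[float, float]] = {}
    for cal, nd in resolved:
        if cal.kind == "minbound":
            blo, bhi = cal.params["time"], np.inf
        elif cal.kind == "maxbound":
            blo, bhi = 0.0, cal.params["time"]
        elif cal.kind == "uniform":
            blo, bhi = cal.params["min"], cal.params["max"]
        elif cal.kind == "point":
            blo = bhi = cal.params["time"]
        else:
            continue
        prev = bounds.get(nd.id, (0.0, np.inf))
        blo, bhi = max(blo, prev[0]), min(bhi, prev[1])
        if blo > bhi:
            raise ConstraintError(
                f"conflicting bounds on node {nd.id}: [{blo:g}, {bhi:g}]"
            )
        bounds[nd.id] = (blo, bhi)
        times[nd.id] = min(max(times[nd.id], blo), bhi)
    return times, bounds


def _monotonicity_repair(tree: RootedTree, times: np.ndarray) -> np.ndarray:
    """Upward max-propagation: every parent at least as old as its children."""
    times = times.copy()
    for nd in tree.postorder():
        if not nd.is_root:
            p = nd.parent.id
            if times[p] < times[nd.id]:
                times[p] = times[nd.id]
    return times


def fixed_rate_scale(
    rt: RelTimeResult,
    rate: float,
    n_samples: int = DEFAULT_MC_SAMPLES,
    rate_cv: float = 0.2,
    seed: Optional[int] = None,
) -> TimetreeResult:
    """Calibrate with a fixed evolutionary rate (substitutions/site/unit).

    Node age = adjusted height / rate; CIs reflect rate heterogeneity only
    (no calibration densities are involved).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    times = rt.heights / rate
    heights_b = monte_carlo_time_samples(
        rt, n_samples, rate_cv=rate_cv, seed=seed, relative=False
    )
    times_b = heights_b / rate
    return TimetreeResult(
        tree=rt.tree,
        times=times,
        ci_lo=np.minimum(np.percentile(times_b, 2.5, axis=0), times),
        ci_hi=np.maximum(np.percentile(times_b, 97.5, axis=0), times),
        f=1.0 / rate,
        rel_times=rt.rel_times,
        lineage_rates=rt.lineage_rates,
    )


# -- calibration file grammar --------------------------------------------------


def parse_calibration_line(line: str):
    """Parse one calibration record.

    Grammar (one record per line, ``#`` comments and blank lines ignored)::

        mrca TaxonA TaxonB normal mean=50 sd=5
        node NodeName uniform min=40 max=60
        mrca A B exponential offset=30 decay=0.1
        mrca A B point time=100
        mrca A B minbound time=40
        node X maxbound time=60
        rate value=0.01

    Returns a :class:`CalibrationDensity`, or ``("rate", value)`` for the
    fixed-rate record.
    """
    toks = line.split()
    if toks[0] == "rate":
        kv = _kvparse(toks[1:], "rate record")
        if "value" not in kv:
            raise ConfigurationError("rate record needs value=...")
        return ("rate", kv["value"])
    if toks[0] == "mrca":
        if len(toks) < 4:
            raise ConfigurationError(f"short mrca record: {line!r}")
        selector = ("mrca", toks[1], toks[2])
        kind, rest = toks[3], toks[4:]
    elif toks[0] == "node":
        if len(toks) < 3:
            raise ConfigurationError(f"short node record: {line!r}")
        selector = ("node", toks[1])
        kind, rest = toks[2], toks[3:]
    else:
        raise ConfigurationError(f"calibration record must start with mrca/node/rate: {line!r}")
    return CalibrationDensity(selector=selector, kind=kind, params=_kvparse(rest, line))


def _kvparse(tokens: Sequence[str], where: str) -> dict:
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise ConfigurationError(f"expected key=value, got {tok!r} in {where!r}")
        k, v = tok.split("=", 1)
        try:
            out[k] = float(v)
        except ValueError:
            raise ConfigurationError(f"non-numeric value {v!r} in {where!r}") from None
    return out


def read_calibration_file(path) -> tuple[list[CalibrationDensity], Optional[float]]:
    """Read a calibration file; returns (calibrations, fixed_rate_or_None)."""
    cals: list[CalibrationDensity] = []
    rate = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            rec = parse_calibration_line(line)
            if isinstance(rec, tuple):
                rate = rec[1]
            else:
                cals.append(rec)
    return cals, rate
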