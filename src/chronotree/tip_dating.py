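"""Tip dating: absolute times from serially sampled sequences.

For fast-evolving organisms (viruses, ancient DNA) the sampling dates of the
tips themselves calibrate the clock.  The fit here works on rate-adjusted
root-to-tip depths: lineage rates come from the relative-rate framework
(:mod:`chronotree.reltime`), each dated tip j gets an adjusted depth D_j,
and the evolutionary rate mu (substitutions/site/year) and root time T0
(decimal year) solve the least-squares regression

    D_j = mu * (s_j - T0)

over the dated tips with sampling dates s_j.  Internal nodes (and tips with
unknown dates) are then placed at T0 + depth/mu.  Confidence intervals come
from Monte-Carlo perturbation of the lineage rates with a per-replicate
re-fit.

A tip's terminal branch is adjusted with its *parent's* lineage rate: the
relative-rate recursion, applied blindly, equalizes all adjusted tip depths
(it assumes contemporaneous tips), which would erase the temporal signal the
regression needs.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, EstimationError
from .reltime import (
    RelTimeResult,
    relative_rates_and_times,
    perturbed_rates_and_heights,
    RATE_FLOOR,
)
from .tree import RootedTree, parse_taxon_meta

__all__ = [
    "TipDateTable",
    "TipDatingFit",
    "to_decimal_year",
    "parse_tip_dates",
    "read_tip_date_file",
    "fit_root_to_tip",
    "rtdt_fit",
    "undated_tip_times",
]

DEFAULT_MC_SAMPLES = 2_000


@dataclass
class TipDateTable:
    """Taxon -> decimal-year sampling dates with provenance.

    ``unknown`` lists taxa whose date could not be parsed; they are excluded
    from the regression and dated post hoc like internal nodes.
    """

    dates: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    unknown: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def span(self) -> float:
        if len(self.dates) < 2:
            return 0.0
        vals = list(self.dates.values())
        return max(vals) - min(vals)

    def update(self, other: "TipDateTable") -> None:
        self.dates.update(other.dates)
        self.provenance.update(other.provenance)
        self.unknown = [t for t in self.unknown + other.unknown if t not in self.dates]
        self.warnings.extend(other.warnings)


def to_decimal_year(text: str) -> float:
    """Convert an ISO date or decimal year string to a decimal year.

    YYYY-MM-DD maps to year + (day_of_year - 0.5)/days_in_year; YYYY-MM is
    pinned to the first of the month (same formula); plain YYYY maps to
    year.0 exactly.  Decimal years pass through.  Raises ValueError on
    unparseable input.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty date")
    if "-" not in text:
        value = float(text)  # covers both "2021" and "1999.25"
        return value
    bits = text.split("-")
    year = int(bits[0])
    month = int(bits[1]) if len(bits) > 1 else 1
    day = int(bits[2]) if len(bits) > 2 else 1
    date = _dt.date(year, month, day)  # validates the calendar date
    doy = date.timetuple().tm_yday
    days = 366 if calendar.isleap(year) else 365
    return year + (doy - 0.5) / days


def parse_tip_dates(
    names: Sequence[str], spec: str, delimiter: str = "|"
) -> TipDateTable:
    """Extract sampling dates encoded in taxon names.

    ``spec`` is the tag-extraction pattern of
    :func:`chronotree.tree.parse_taxon_meta` and must contain a ``date``
    field.  Unparseable dates flag the taxon as unknown (warning, never a
    hard failure).
    """
    fields = [f.strip().lower() for f in spec.split(delimiter)]
    if "date" not in fields:
        raise ConfigurationError("tag-extraction spec must contain a 'date' field")
    pos = fields.index("date")
    table = TipDateTable()
    for name in names:
        parts = name.split(delimiter)
        raw = parts[pos].strip() if pos < len(parts) else ""
        try:
            table.dates[name] = to_decimal_year(raw)
            table.provenance[name] = "parsed-from-name"
        except (ValueError, OverflowError):
            table.unknown.append(name)
            table.warnings.append(f"taxon {name!r}: unparseable date {raw!r}")
    return table


def read_tip_date_file(path) -> TipDateTable:
    """TSV tip-date file: ``taxon<TAB>date``, ``#`` comments, ISO or decimal."""
    table = TipDateTable()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                table.warnings.append(f"line {lineno}: expected 'taxon<TAB>date'")
                continue
            taxon, raw_date = parts[0].strip(), parts[1].strip()
            try:
                table.dates[taxon] = to_decimal_year(raw_date)
                table.provenance[taxon] = "file"
            except (ValueError, OverflowError):
                table.unknown.append(taxon)
                table.warnings.append(
                    f"line {lineno}: unparseable date {raw_date!r} for {taxon!r}"
                )
    return table


@dataclass
class TipDatingFit:
    """Fitted clock: rate mu, root time T0, per-node times and CIs.

    Arrays indexed by ``node.id`` of ``tree``.  ``inferred`` flags nodes
    whose time was not anchored by an observed sampling date (internal nodes
    and undated tips).  ``residuals`` maps dated taxa to (fitted - observed)
    years.
    """

    tree: RootedTree
    mu: float
    t0: float
    times: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    inferred: np.ndarray
    residuals: dict[str, float]
    reltime: RelTimeResult
    dates: TipDateTable

    def annotate(self, digits: int = 6) -> RootedTree:
        t = self.tree.copy()
        for nd in t.preorder():
            nd.annotations["time"] = f"{self.times[nd.id]:.{digits}g}"
            nd.annotations["ci_lo"] = f"{self.ci_lo[nd.id]:.{digits}g}"
            nd.annotations["ci_hi"] = f"{self.ci_hi[nd.id]:.{digits}g}"
            if self.inferred[nd.id]:
                nd.annotations["inferred"] = "1"
        return t


def fit_root_to_tip(
    depths: np.ndarray, dates: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Least squares for D_j = mu (s_j - T0) on rate-adjusted depths.

    Returns (mu, T0, residuals-in-depth-units).  Raises
    :class:`EstimationError` when the fitted slope is non-positive (no
    temporal signal) and :class:`ConfigurationError` when all dates are
    equal (singular design).
    """
    depths = np.asarray(depths, dtype=float)
    dates = np.asarray(dates, dtype=float)
    if depths.shape != dates.shape or depths.ndim != 1 or depths.size < 2:
        raise ConfigurationError("need matching 1-D depth/date vectors, length >= 2")
    s_var = float(np.var(dates))
    if s_var == 0.0:
        raise ConfigurationError("all sampling dates are equal; the fit is singular")
    s_mean, d_mean = float(np.mean(dates)), float(np.mean(depths))
    mu = float(np.mean((dates - s_mean) * (depths - d_mean)) / s_var)
    if mu <= 0:
        raise EstimationError(
            f"fitted rate is non-positive (mu = {mu:.3g}): the data carry no "
            "temporal signal; check dates, rooting and branch lengths"
        )
    t0 = s_mean - d_mean / mu
    residuals = depths - mu * (dates - t0)
    return mu, t0, residuals


def _raw_depths(tree: RootedTree, tips) -> np.ndarray:
    depth = {tree.root.id: 0.0}
    for nd in tree.preorder():
        if not nd.is_root:
            depth[nd.id] = depth[nd.parent.id] + nd.length
    return np.array([depth[t.id] for t in tips])


def rtdt_fit(
    tree: RootedTree,
    dates: TipDateTable,
    n_samples: int = DEFAULT_MC_SAMPLES,
    rate_cv: float = 0.2,
    seed: Optional[int] = None,
    outgroup: Sequence[str] = (),
    max_iter: int = 20,
    tol: float = 1e-10,
) -> TipDatingFit:
    """Date all nodes of a rooted phylogram from tip sampling dates.

    Needs >= 3 dated tips spanning a positive time interval.

    The rate-adjusted depths and the clock fit are mutually dependent, so
    the fit iterates to a fixed point: (1) an initial rate from raw
    root-to-tip regression; (2) dated terminal branches are extended by
    mu * (s_max - s_j), making tips pseudo-contemporaneous so the
    relative-rate recursion sees the geometry it assumes; (3) lineage rates
    are re-estimated on the extended tree and adjusted depths recomputed
    with the *original* terminal branch lengths; (4) mu, T0 re-fitted.  On
    a strict-clock tree the raw regression is already exact and the loop
    converges immediately.  CIs are 2.5/97.5 percentiles over ``n_samples``
    lineage-rate perturbations, the regression re-fitted per replicate.
    """
    base = relative_rates_and_times(tree, outgroup=outgroup)  # validates input
    work = base.tree
    tips = work.tips()
    dated = [t for t in tips if t.name in dates.dates]
    if len(dated) < 3:
        raise ConfigurationError(
            f"tip dating needs >= 3 dated tips, found {len(dated)}"
        )
    s = np.array([dates.dates[t.name] for t in dated])
    if s.max() - s.min() <= 0:
        raise ConfigurationError("sampling dates must span a positive interval")
    s_max = float(s.max())
    orig_len = {t.id: t.length for t in tips}

    mu, t0, resid = fit_root_to_tip(_raw_depths(work, dated), s)
    raw_all = _raw_depths(work, tips)
    # undated tips join the extension with their current estimated date so
    # they do not distort the pseudo-contemporaneous geometry
    est_date = {
        t.id: t0 + raw_all[j] / mu
        for j, t in enumerate(tips)
        if t.name not in dates.dates
    }
    rt = base
    for _ in range(max_iter):
        ext = work.copy()
        for t in ext.tips():
            date = dates.dates.get(t.name, est_date.get(t.id))
            t.length = orig_len[t.id] + mu * max(s_max - date, 0.0)
        rt = relative_rates_and_times(ext, outgroup=outgroup)

        def adj_tip_depth(t) -> float:
            return rt.adjusted_depth(t.parent) + orig_len[t.id] / max(
                float(rt.lineage_rates[t.id]), RATE_FLOOR
            )

        depths = np.array([adj_tip_depth(rt.tree.tip(t.name)) for t in dated])
        new_mu, t0, resid = fit_root_to_tip(depths, s)
        for t in rt.tree.tips():
            if t.id in est_date:
                est_date[t.id] = t0 + adj_tip_depth(t) / new_mu
        if abs(new_mu - mu) <= tol * mu:
            mu = new_mu
            break
        mu = new_mu

    def tip_depth(node_id: int) -> float:
        t = rt.tree.nodes[node_id]
        return rt.adjusted_depth(t.parent) + orig_len[node_id] / max(
            float(rt.lineage_rates[node_id]), RATE_FLOOR
        )

    n = len(work.nodes)
    times = np.empty(n)
    inferred = np.ones(n, dtype=bool)
    for nd in work.preorder():
        if nd.is_tip:
            times[nd.id] = t0 + tip_depth(nd.id) / mu
        else:
            times[nd.id] = t0 + rt.adjusted_depth(nd) / mu
    for t in dated:
        inferred[t.id] = False
    # ancestors must not postdate descendants; rate clamping can leave
    # hairline violations, repaired by a downward min pass
    for nd in work.postorder():
        if not nd.is_root and times[nd.parent.id] > times[nd.id]:
            times[nd.parent.id] = times[nd.id]

    # Monte-Carlo re-fit under rate perturbations
    rates_b, heights_b = perturbed_rates_and_heights(rt, n_samples, rate_cv, seed)
    hroot_b = heights_b[:, work.root.id]
    depth_b = hroot_b[:, None] - heights_b  # (R, n) adjusted root-to-node depths
    tipdepth_b = np.empty((n_samples, len(tips)))
    tip_col = {}
    for j, t in enumerate(rt.tree.tips()):
        tipdepth_b[:, j] = depth_b[:, t.parent.id] + orig_len[t.id] / np.maximum(
            rates_b[:, t.id], RATE_FLOOR
        )
        tip_col[t.id] = j
    dated_cols = [tip_col[t.id] for t in dated]
    D_b = tipdepth_b[:, dated_cols]
    s_c = s - s.mean()
    mu_b = (D_b - D_b.mean(axis=1, keepdims=True)) @ s_c / np.dot(s_c, s_c)
    mu_b = np.maximum(mu_b, RATE_FLOOR)
    t0_b = s.mean() - D_b.mean(axis=1) / mu_b
    times_b = np.empty((n_samples, n))
    for nd in work.preorder():
        col = (
            tipdepth_b[:, tip_col[nd.id]] if nd.is_tip else depth_b[:, nd.id]
        )
        times_b[:, nd.id] = t0_b + col / mu_b
    ci_lo = np.minimum(np.percentile(times_b, 2.5, axis=0), times)
    ci_hi = np.maximum(np.percentile(times_b, 97.5, axis=0), times)

    return TipDatingFit(
        tree=work,
        mu=mu,
        t0=t0,
        times=times,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        inferred=inferred,
        residuals={t.name: float(r) for t, r in zip(dated, resid)},
        reltime=rt,
        dates=dates,
    )


def undated_tip_times(fit: TipDatingFit) -> dict[str, float]:
    """Times of tips lacking observed dates (already in ``fit.times``,
    flagged ``inferred``); returned as a name -> decimal-year map."""
    return {
        nd.name: float(fit.times[nd.id])
        for nd in fit.tree.tips()
        if fit.inferred[nd.id]
    }
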