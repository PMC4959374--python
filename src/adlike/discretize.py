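"""Supervised discretization by maximization of the Ameva criterion.

For one continuous feature with class labels from ``l`` classes, a cut set
of size ``k - 1`` partitions the line into ``k`` half-open intervals
``(L^l_i, L^u_i]`` (outermost intervals extend to +-infinity).  The Ameva
criterion of the induced class-by-interval contingency table is

    Ameva(k) = chi2(k) / (k * (l - 1)),

with ``chi2(k) = N * (-1 + sum_ij n_ij^2 / (n_i. * n_.j))``.  Maximizing
it rewards class/interval dependence while the ``k`` in the denominator
penalizes fragmentation.

Two variants are provided:

* **original** — greedy top-down search: candidate cuts are midpoints
  between consecutive distinct sorted values where the class composition
  changes; each iteration adds the single candidate that maximizes the
  criterion and stops when no candidate strictly improves it (tolerance
  1e-12, ties broken toward the leftmost cut).
* **optimized** — seeds with the original variant's cuts, then makes one
  ascending pass over the remaining candidates, accepting every cut that
  strictly reduces the summed within-interval variance of the (numeric)
  class labels.  The label prefix sums are computed once and reused, the
  pass touches each candidate exactly once, and by construction the
  original cuts are a subset of the optimized cuts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, ValidationError

IMPROVEMENT_TOL = 1e-12


# ---------------------------------------------------------------------------
# Contingency table and criterion
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Counts ``n_ij`` of class ``j`` instances falling in interval ``i``."""

    counts: np.ndarray  # (k intervals, l classes)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("contingency table must be 2-D (intervals x classes)")
        if np.any(self.counts < 0):
            raise ValidationError("contingency table has negative counts")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def chi2_dependence(t: ContingencyTable) -> float:
    """``N * (-1 + sum_ij n_ij^2/(n_i. n_.j))`` with empty rows/cols skipped."""
    counts = t.counts
    ri = t.row_totals
    cj = t.col_totals
    keep_r = ri > 0
    keep_c = cj > 0
    c = counts[np.ix_(keep_r, keep_c)]
    denom = np.outer(ri[keep_r], cj[keep_c])
    return float(t.n * (-1.0 + np.sum(c**2 / denom)))


def ameva_statistic(t: ContingencyTable) -> float:
    """Ameva value ``chi2 / (k (l-1))`` of a contingency table.

    ``k`` counts all intervals (rows); a class with zero total is
    excluded from ``l`` with a warning, matching the criterion's
    definition over observed classes.
    """
    if t.n < 1:
        raise ParameterError("empty contingency table")
    k = t.counts.shape[0]
    col = t.col_totals
    if np.any(col == 0):
        warnings.warn(
            f"{int((col == 0).sum())} class(es) with zero total excluded from the "
            "Ameva denominator",
            stacklevel=2,
        )
    l = int((col > 0).sum())
    if l < 2:
        raise ParameterError("Ameva statistic needs at least 2 represented classes")
    return chi2_dependence(t) / (k * (l - 1))


# ---------------------------------------------------------------------------
# Discretization scheme
# ---------------------------------------------------------------------------

@dataclass
class FeatureScheme:
    """Ordered finite cut points of one feature; intervals are
    ``(-inf, c_1], (c_1, c_2], ..., (c_{k-1}, +inf)``."""

    cuts: np.ndarray

    def __post_init__(self) -> None:
        self.cuts = np.asarray(self.cuts, dtype=float)
        if self.cuts.size and np.any(np.diff(self.cuts) <= 0):
            raise ValidationError("cut points must be strictly increasing")

    @property
    def k(self) -> int:
        return self.cuts.size + 1

    def interval_of(self, values: np.ndarray | float) -> np.ndarray:
        """Index of the interval containing each value (half-open right)."""
        return np.searchsorted(self.cuts, np.asarray(values, dtype=float), side="left")


@dataclass
class DiscretizationScheme:
    """Per-feature cut lists plus bookkeeping from the search."""

    features: dict[str, FeatureScheme] = field(default_factory=dict)
    variant: str = "original"
    n_criterion_evals: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "variant": self.variant,
            "features": {name: fs.cuts.tolist() for name, fs in self.features.items()},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DiscretizationScheme":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        doc = json.loads(text)
        return cls(
            features={name: FeatureScheme(np.asarray(c)) for name, c in doc["features"].items()},
            variant=doc.get("variant", "original"),
        )


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def _sorted_problem(values: np.ndarray, labels: np.ndarray):
    """Sort values, encode classes, and locate candidate cut positions.

    Returns (sorted values, class codes, classes, cumulative class counts
    of shape (l, n+1), candidate split positions, candidate cut values).
    A candidate sits between consecutive distinct-value groups whose class
    composition differs; cuts elsewhere cannot increase the criterion.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ParameterError("values and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(v)):
        raise ParameterError("values must be finite")
    classes, codes = np.unique(y, return_inverse=True)
    order = np.argsort(v, kind="stable")
    vs, cs = v[order], codes[order]
    n, l = vs.size, classes.size

    cum = np.zeros((l, n + 1), dtype=np.int64)
    np.add.at(cum, (cs, np.arange(n) + 1), 1)
    np.cumsum(cum, axis=1, out=cum)

    # boundaries between distinct-value groups
    group_bounds = np.flatnonzero(np.diff(vs) > 0) + 1  # split positions
    cand_pos: list[int] = []
    starts = np.concatenate([[0], group_bounds])
    ends = np.concatenate([group_bounds, [n]])
    for gi in range(len(starts) - 1):
        a, b = starts[gi], ends[gi]
        b2 = ends[gi + 1]
        left = cum[:, b] - cum[:, a]
        right = cum[:, b2] - cum[:, b]
        # candidate only where normalized composition changes
        if not np.allclose(left / left.sum(), right / right.sum()):
            cand_pos.append(int(b))
    cand_pos_arr = np.asarray(cand_pos, dtype=np.int64)
    cand_cuts = (vs[cand_pos_arr - 1] + vs[cand_pos_arr]) / 2.0 if cand_pos_arr.size else np.empty(0)
    return vs, cs, classes, cum, cand_pos_arr, cand_cuts


def candidate_cuts(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values where the class
    composition changes — the candidate set both variants search over."""
    return _sorted_problem(values, labels)[5]


# ---------------------------------------------------------------------------
# The two variants
# ---------------------------------------------------------------------------

def _interval_terms(cum: np.ndarray, a, b, col_totals: np.ndarray) -> np.ndarray:
    """``sum_j n_ij^2/(n_i. n_.j)`` for intervals [a, b) given cumulative counts.

    ``a``/``b`` may be arrays; empty intervals contribute 0.
    """
    a = np.atleast_1d(a)
    b = np.atleast_1d(b)
    counts = cum[:, b] - cum[:, a]  # (l, m)
    ni = counts.sum(axis=0)
    keep = col_totals > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (counts[keep] ** 2) / (ni[None, :] * col_totals[keep, None])
    terms = np.where(ni[None, :] > 0, terms, 0.0)
    return terms.sum(axis=0)


def _greedy_original(vs, cs, classes, cum, cand_pos):
    """Greedy forward selection of cuts maximizing the Ameva criterion."""
    n = vs.size
    col_totals = cum[:, -1].astype(float)
    l_eff = int((col_totals > 0).sum())
    boundaries = np.array([0, n], dtype=np.int64)
    term_sum = float(_interval_terms(cum, [0], [n], col_totals)[0])
    best_value = n * (term_sum - 1.0) / (1 * (l_eff - 1))  # == 0 for k=1
    remaining = cand_pos.copy()
    n_evals = 0

    while remaining.size:
        k = boundaries.size - 1
        # locate each candidate's enclosing interval
        which = np.searchsorted(boundaries, remaining, side="right") - 1
        a = boundaries[which]
        b = boundaries[which + 1]
        t_old = _interval_terms(cum, a, b, col_totals)
        t_new = (
            _interval_terms(cum, a, remaining, col_totals)
            + _interval_terms(cum, remaining, b, col_totals)
        )
        sums = term_sum - t_old + t_new
        values = n * (sums - 1.0) / ((k + 1) * (l_eff - 1))
        n_evals += remaining.size
        best = int(np.argmax(values))  # first max -> leftmost cut on ties
        if values[best] <= best_value + IMPROVEMENT_TOL:
            break
        best_value = float(values[best])
        term_sum = float(sums[best])
        boundaries = np.sort(np.append(boundaries, remaining[best]))
        remaining = np.delete(remaining, best)
    return boundaries[1:-1], best_value, n_evals


def _variance_pass(vs, ys_numeric, boundaries, remaining):
    """One ascending pass accepting cuts that strictly lower within-interval
    label variance.  Prefix sums of the numeric labels are built once."""
    n = vs.size
    s1 = np.concatenate([[0.0], np.cumsum(ys_numeric)])
    s2 = np.concatenate([[0.0], np.cumsum(ys_numeric**2)])

    def sse(a: int, b: int) -> float:
        cnt = b - a
        if cnt <= 0:
            return 0.0
        tot = s1[b] - s1[a]
        return (s2[b] - s2[a]) - tot * tot / cnt

    bset = list(boundaries)
    n_evals = 0
    accepted: list[int] = []
    for p in remaining:
        i = np.searchsorted(bset, p, side="right") - 1
        a, b = bset[i], bset[i + 1]
        n_evals += 1
        if sse(a, b) - (sse(a, int(p)) + sse(int(p), b)) > IMPROVEMENT_TOL:
            bset.insert(i + 1, int(p))
            accepted.append(int(p))
    return np.asarray(sorted(bset[1:-1]), dtype=np.int64), n_evals


def discretize(
    values: np.ndarray,
    labels: np.ndarray,
    variant: str = "original",
) -> tuple[FeatureScheme, dict]:
    """Learn interval cut points for one feature.

    Returns the scheme plus an ``info`` dict holding the achieved Ameva
    value (original search), the criterion-evaluation count of the
    variant's own search loop, and the candidate count.  All identical
    values (or no usable candidate) yield a single-interval scheme with a
    warning.
    """
    if variant not in ("original", "optimized"):
        raise ParameterError(f"unknown variant {variant!r}")
    vs, cs, classes, cum, cand_pos, cand_cuts = _sorted_problem(values, labels)
    if classes.size < 2:
        raise ParameterError("discretization needs at least 2 distinct class labels")
    info: dict = {"n_candidates": int(cand_pos.size), "variant": variant}
    if cand_pos.size == 0:
        warnings.warn("no informative candidate cuts; returning a single interval", stacklevel=2)
        info.update(ameva=0.0, n_criterion_evals=0)
        return FeatureScheme(np.empty(0)), info

    pos_orig, best_value, evals_orig = _greedy_original(vs, cs, classes, cum, cand_pos)
    if variant == "original":
        cuts = _positions_to_cuts(vs, pos_orig, cand_pos, cand_cuts)
        info.update(ameva=float(best_value), n_criterion_evals=int(evals_orig))
        return FeatureScheme(cuts), info

    # optimized: numeric label values (ratings) enter the variance test
    try:
        ys_numeric = classes[cs].astype(float)
    except (TypeError, ValueError):
        ys_numeric = cs.astype(float)  # non-numeric labels: use class codes
    remaining = np.setdiff1d(cand_pos, pos_orig)
    boundaries = np.concatenate([[0], np.sort(pos_orig), [vs.size]])
    pos_opt, evals_opt = _variance_pass(vs, ys_numeric, boundaries, remaining)
    cuts = _positions_to_cuts(vs, pos_opt, cand_pos, cand_cuts)
    info.update(ameva=float(best_value), n_criterion_evals=int(evals_opt))
    return FeatureScheme(cuts), info


def _positions_to_cuts(vs, positions, cand_pos, cand_cuts) -> np.ndarray:
    lookup = dict(zip(cand_pos.tolist(), cand_cuts.tolist()))
    return np.asarray(sorted(lookup[int(p)] for p in positions), dtype=float)


def scheme_contingency(
    scheme: FeatureScheme, values: np.ndarray, labels: np.ndarray, classes: np.ndarray | None = None
) -> ContingencyTable:
    """Tabulate values/labels into the scheme's intervals."""
    if classes is None:
        classes = np.unique(labels)
    codes = np.searchsorted(classes, labels)
    iv = scheme.interval_of(values)
    counts = np.zeros((scheme.k, len(classes)))
    np.add.at(counts, (iv, codes), 1)
    return ContingencyTable(counts)
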