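"""Correlation-based feature-subset selection (CFS).

CFS scores a candidate subset S of k features by

    merit(S) = k * r_cf / sqrt(k + k*(k-1) * r_ff)

where r_cf is the mean absolute Pearson correlation of the subset's
features with the 0/1 class indicator and r_ff the mean absolute Pearson
correlation among subset feature pairs: a good subset correlates with the
class while its members are mutually uncorrelated.  Three search
strategies are provided — exhaustive enumeration (global optimum, capped
at 25 features), forward best-first with a stale limit, and greedy
forward stepwise.

Pearson correlation is used on the raw numeric values for both the
feature-class and feature-feature terms (deterministic, no
discretisation); zero-variance features get correlation 0.  Merit ties
break toward the lexicographically smallest feature-name set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .features import FeatureTable

__all__ = ["SubsetMerit", "CFSEvaluator", "cfs_merit", "search_subset"]

_EXHAUSTIVE_CAP = 25
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SubsetMerit:
    """A feature subset with its CFS merit."""

    subset: tuple[str, ...]
    merit: float

    @property
    def k(self) -> int:
        return len(self.subset)


def _safe_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


class CFSEvaluator:
    """Caches the feature-class and feature-feature correlations of a
    candidate pool so that many subsets can be scored cheaply."""

    def __init__(self, table: FeatureTable, candidates=None):
        labels = table.class_labels()
        if len(labels) != 2:
            raise ValueError(f"CFS needs exactly two classes, got {labels}")
        self.candidates = tuple(candidates) if candidates is not None else tuple(
            table.values.columns
        )
        sub = table.values[list(self.candidates)]
        complete = sub.dropna()
        y = (table.labels.reindex(complete.index) == labels[1]).to_numpy(dtype=float)
        X = complete.to_numpy(dtype=float)
        m = len(self.candidates)
        self.r_cf = np.array([_safe_abs_corr(X[:, i], y) for i in range(m)])
        self.r_ff = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                r = _safe_abs_corr(X[:, i], X[:, j])
                self.r_ff[i, j] = self.r_ff[j, i] = r
        self._index = {name: i for i, name in enumerate(self.candidates)}

    def merit_of_indices(self, idx: np.ndarray) -> float:
        k = len(idx)
        if k == 0:
            return 0.0
        sum_cf = self.r_cf[idx].sum()
        if k == 1:
            return float(sum_cf)
        sum_ff = self.r_ff[np.ix_(idx, idx)].sum() / 2.0
        rbar_cf = sum_cf / k
        rbar_ff = 2.0 * sum_ff / (k * (k - 1))
        return float(k * rbar_cf / np.sqrt(k + k * (k - 1) * rbar_ff))

    def merit(self, subset) -> float:
        idx = np.array([self._index[name] for name in subset], dtype=int)
        return self.merit_of_indices(idx)


def cfs_merit(subset, table: FeatureTable) -> float:
    """CFS merit of ``subset``; the empty set has merit 0."""
    subset = tuple(subset)
    if not subset:
        return 0.0
    return CFSEvaluator(table, candidates=subset).merit(subset)


def _better(cand: tuple[float, tuple[str, ...]], best: tuple[float, tuple[str, ...]]) -> bool:
    """Candidate beats incumbent on merit; ties go to the smaller name set."""
    if cand[0] > best[0] + _TIE_EPS:
        return True
    if abs(cand[0] - best[0]) <= _TIE_EPS:
        return tuple(sorted(cand[1])) < tuple(sorted(best[1]))
    return False


def _exhaustive(ev: CFSEvaluator, max_k: int | None) -> SubsetMerit:
    m = len(ev.candidates)
    if m > _EXHAUSTIVE_CAP:
        raise ValueError(
            f"exhaustive search over {m} features exceeds the 2^{_EXHAUSTIVE_CAP} cap; "
            "use method='best_first'"
        )
    # sum_ff[mask] built by dynamic programming over bit masks
    n_masks = 1 << m
    sum_ff = np.zeros(n_masks)
    sum_cf = np.zeros(n_masks)
    popcount = np.zeros(n_masks, dtype=np.int32)
    row_dot = ev.r_ff  # row_dot[i, j]
    for mask in range(1, n_masks):
        low = (mask & -mask).bit_length() - 1
        rest = mask & (mask - 1)
        popcount[mask] = popcount[rest] + 1
        sum_cf[mask] = sum_cf[rest] + ev.r_cf[low]
        # pair sum gains the correlations of the new bit with the rest
        acc = 0.0
        r = rest
        while r:
            j = (r & -r).bit_length() - 1
            acc += row_dot[low, j]
            r &= r - 1
        sum_ff[mask] = sum_ff[rest] + acc

    k = popcount[1:].astype(float)
    rbar_cf = sum_cf[1:] / k
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar_ff = np.where(k > 1, 2.0 * sum_ff[1:] / (k * (k - 1)), 0.0)
        merit = k * rbar_cf / np.sqrt(k + k * (k - 1) * rbar_ff)

    if max_k is not None:
        merit = np.where(k <= max_k, merit, -np.inf)
    best = (-np.inf, ())
    order = np.argsort(merit)[::-1]
    top = merit[order[0]]
    for pos in order:
        if merit[pos] < top - _TIE_EPS:
            break
        mask = pos + 1
        names = tuple(ev.candidates[i] for i in range(m) if mask >> i & 1)
        if _better((merit[pos], names), best):
            best = (float(merit[pos]), names)
    return SubsetMerit(subset=tuple(sorted(best[1])), merit=best[0])


def _greedy_forward(ev: CFSEvaluator, max_k: int | None) -> SubsetMerit:
    current: list[int] = []
    current_merit = 0.0
    remaining = set(range(len(ev.candidates)))
    while remaining and (max_k is None or len(current) < max_k):
        best_step = (-np.inf, ())
        best_i = None
        for i in sorted(remaining, key=lambda i: ev.candidates[i]):
            m = ev.merit_of_indices(np.array(current + [i], dtype=int))
            names = tuple(ev.candidates[j] for j in current + [i])
            if _better((m, names), best_step):
                best_step = (m, names)
                best_i = i
        if best_i is None or best_step[0] <= current_merit + _TIE_EPS:
            break
        current.append(best_i)
        current_merit = best_step[0]
        remaining.discard(best_i)
    names = tuple(sorted(ev.candidates[i] for i in current))
    return SubsetMerit(subset=names, merit=current_merit)


def _best_first(ev: CFSEvaluator, max_k: int | None, stale_limit: int = 5) -> SubsetMerit:
    m = len(ev.candidates)
    start: frozenset[int] = frozenset()
    open_list: list[tuple[float, frozenset[int]]] = [(0.0, start)]
    visited = {start}
    best = (0.0, start)
    stale = 0
    while open_list and stale < stale_limit:
        open_list.sort(key=lambda t: (-t[0], tuple(sorted(ev.candidates[i] for i in t[1]))))
        merit, node = open_list.pop(0)
        improved = False
        if max_k is None or len(node) < max_k:
            for i in range(m):
                if i in node:
                    continue
                child = node | {i}
                if child in visited:
                    continue
                visited.add(child)
                cm = ev.merit_of_indices(np.fromiter(child, dtype=int))
                open_list.append((cm, child))
                names = tuple(ev.candidates[j] for j in child)
                best_names = tuple(ev.candidates[j] for j in best[1])
                if _better((cm, names), (best[0], best_names)):
                    best = (cm, child)
                    improved = True
        stale = 0 if improved else stale + 1
    names = tuple(sorted(ev.candidates[i] for i in best[1]))
    return SubsetMerit(subset=names, merit=float(best[0]))


def search_subset(
    table: FeatureTable,
    method: str = "best_first",
    max_k: int | None = None,
    candidates=None,
) -> SubsetMerit:
    """Search for the CFS-merit-maximising feature subset.

    ``method`` is one of ``exhaustive`` (global optimum, candidate pool
    capped at 25 features), ``best_first`` (forward best-first, stops
    after 5 stale expansions) or ``greedy_forward`` (adds the single best
    feature until merit stops improving).  ``candidates`` restricts the
    pool (e.g. to the screened shortlist); default is every feature
    column in the table.
    """
    ev = CFSEvaluator(table, candidates=candidates)
    if method == "exhaustive":
        return _exhaustive(ev, max_k)
    if method == "greedy_forward":
        return _greedy_forward(ev, max_k)
    if method == "best_first":
        return _best_first(ev, max_k)
    raise ValueError(f"unknown search method {method!r}")
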