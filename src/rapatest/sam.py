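"""SAM-style moderated differential expression with permutation FDR.

The panel screen uses the classical significance-analysis-of-microarrays
statistic: per gene, ``d = (mean difference) / (s + s0)`` where ``s`` is the
pooled standard error and ``s0`` (the fudge factor) is a small constant that
stabilises ``d`` for low-variance genes, tuned as the percentile of the
``s`` distribution that minimises the coefficient of variation of ``d``
across windows of ``s``.  A multiclass (F-like) variant covers the
three-group disease-stage comparison.  Significance is called against the
permutation null: genes whose ordered ``d`` deviates from the per-rank
expected null by more than ``delta``, with the false discovery rate
estimated as ``pi0 x (median null calls) / (observed calls)``.

``SAM(matrix, groups)`` is the model object; ``fit()`` returns a
:class:`SAMResults` with the d-statistics, s0, delta, significant gene sets
and estimated FDR.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SAM", "SAMResults", "sam_two_class", "sam_multiclass",
           "permutation_fdr", "tune_delta", "collapse_duplicates",
           "median_center"]

logger = logging.getLogger(__name__)

_S0_PERCENTILES = np.arange(0, 101, 5)
_S0_WINDOWS = 25


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def _two_class_rs(X: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Numerator (mean_A - mean_B) and pooled standard error per gene (rows)."""
    na, nb = a.size, b.size
    xa, xb = X[:, a], X[:, b]
    r = xa.mean(axis=1) - xb.mean(axis=1)
    ssa = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    return r, s


def _multiclass_rs(X: np.ndarray, group_idx: list[np.ndarray]):
    """Multiclass numerator/scale chosen so K=2 reduces to |two-class d|.

    ``r = sqrt( (sum_k 1/n_k) * sum_k n_k (xbar_k - xbar)^2 )`` and
    ``s = sqrt( (sum_k 1/n_k) * SSW / (n - K) )``.
    """
    n = X.shape[1]
    k = len(group_idx)
    xbar = X.mean(axis=1)
    between = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    inv = 0.0
    for idx in group_idx:
        xg = X[:, idx]
        mg = xg.mean(axis=1)
        between += idx.size * (mg - xbar) ** 2
        ssw += ((xg - mg[:, None]) ** 2).sum(axis=1)
        inv += 1.0 / idx.size
    r = np.sqrt(inv * between)
    s = np.sqrt(inv * ssw / (n - k))
    return r, s


def _tune_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Classical s0 tuning: the percentile of s minimising the CV of d.

    Genes are split into quantile windows of ``s``; for each candidate the
    spread (MAD) of ``d`` within windows is computed and the candidate with
    the smallest coefficient of variation of those spreads wins.
    """
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, _S0_WINDOWS)
    best_s0, best_cv = 0.0, math.inf
    for pct in _S0_PERCENTILES:
        s0 = float(np.percentile(s, pct))
        d = r / (s + s0) if s0 > 0 else _safe_div(r, s)
        mads = np.array([_mad(d[w]) for w in windows if w.size])
        m = mads.mean()
        if m == 0:
            continue
        cv = mads.std(ddof=1) / m
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)) / 0.6745)


def _safe_div(r, s):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s > 0, r / np.where(s > 0, s, 1.0), np.nan)


def sam_two_class(matrix: pd.DataFrame, group_a, group_b,
                  s0_mode="auto") -> tuple[pd.Series, float]:
    """Per-gene two-class d-statistics (A minus B) and the fudge factor s0.

    ``s0_mode`` is ``"auto"`` (classical percentile tuning) or a fixed
    float; ``s0=0`` with a zero-variance gene raises.
    """
    cols = list(matrix.columns)
    a = np.array([cols.index(c) for c in group_a])
    b = np.array([cols.index(c) for c in group_b])
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    r, s = _two_class_rs(X, a, b)
    s0 = _tune_s0(r, s) if s0_mode == "auto" else float(s0_mode)
    if s0 == 0 and np.any(s == 0):
        raise ValueError("zero-variance gene with s0=0; use s0 > 0")
    d = r / (s + s0)
    return pd.Series(d, index=matrix.index, name="d"), s0


def sam_multiclass(matrix: pd.DataFrame, groups: pd.Series | dict,
                   s0_mode="auto") -> tuple[pd.Series, float, pd.DataFrame]:
    """Multiclass SAM statistic; also returns group means for direction calls."""
    groups = pd.Series(groups)
    group_idx, names = _group_indices(matrix, groups)
    if len(group_idx) < 2:
        raise ValueError("need >= 2 groups")
    if any(idx.size < 2 for idx in group_idx):
        raise ValueError("singleton group: every group needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    r, s = _multiclass_rs(X, group_idx)
    s0 = _tune_s0(r, s) if s0_mode == "auto" else float(s0_mode)
    if s0 == 0 and np.any(s == 0):
        raise ValueError("zero-variance gene with s0=0; use s0 > 0")
    d = r / (s + s0)
    means = pd.DataFrame({name: X[:, idx].mean(axis=1)
                          for name, idx in zip(names, group_idx)},
                         index=matrix.index)
    return pd.Series(d, index=matrix.index, name="d"), s0, means


def _group_indices(matrix, groups: pd.Series):
    cols = list(matrix.columns)
    names = list(dict.fromkeys(groups.loc[cols]))
    idx = [np.array([i for i, c in enumerate(cols) if groups[c] == g])
           for g in names]
    return idx, names


# --------------------------------------------------------------------------
# permutation FDR
# --------------------------------------------------------------------------

@dataclass
class SAMResults:
    """Outcome of a SAM screen at one delta."""

    d: pd.Series
    s0: float
    delta: float
    significant_up: list
    significant_down: list
    estimated_fdr: float
    n_permutations: int
    seed: int | None
    pi0: float
    expected_null: np.ndarray = field(repr=False, default=None)
    statistic: str = "two_class"
    group_means: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def significant(self) -> list:
        return list(self.significant_up) + list(self.significant_down)

    def summary(self) -> str:
        return ("SAM {stat} screen: {n} genes, {p} permutations, s0={s0:.4g}, "
                "delta={dl:.4g}\n  called: {up} up, {dn} down "
                "(estimated FDR {f:.1%}, pi0={pi:.2f})").format(
            stat=self.statistic, n=self.d.size, p=self.n_permutations,
            s0=self.s0, dl=self.delta, up=len(self.significant_up),
            dn=len(self.significant_down), f=self.estimated_fdr, pi=self.pi0)


def _all_two_class_assignments(n: int, na: int):
    for combo in itertools.combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        yield mask


def _count_arrangements(sizes) -> float:
    total = math.factorial(sum(sizes))
    for k in sizes:
        total //= math.factorial(k)
    return total


def _null_d_matrix(X, sizes, s0, n_perm, seed, statistic):
    """Null d-statistics from label permutations (rows = permutations).

    If fewer distinct arrangements exist than requested permutations the
    null is enumerated exhaustively (logged).
    """
    n = X.shape[1]
    n_arr = _count_arrangements(sizes)
    exhaustive = n_perm >= n_arr
    rows = []
    if statistic == "two_class":
        na = sizes[0]
        if exhaustive:
            logger.info("only %d distinct label arrangements; enumerating "
                        "exhaustively instead of %d permutations", n_arr, n_perm)
            masks = _all_two_class_assignments(n, na)
        else:
            rng = np.random.default_rng(seed)
            masks = (np.isin(np.arange(n), rng.permutation(n)[:na])
                     for _ in range(n_perm))
        for mask in masks:
            a, b = np.where(mask)[0], np.where(~mask)[0]
            r, s = _two_class_rs(X, a, b)
            rows.append(r / (s + s0))
    else:
        rng = np.random.default_rng(seed)
        if exhaustive:
            logger.info("only %d distinct label arrangements; enumerating "
                        "exhaustively instead of %d permutations", n_arr, n_perm)
            perms = set(itertools.permutations(_sizes_to_labels(sizes)))
            label_sets = [np.array(p) for p in sorted(perms)]
        else:
            base = np.array(_sizes_to_labels(sizes))
            label_sets = [rng.permutation(base) for _ in range(n_perm)]
        for lab in label_sets:
            idx = [np.where(lab == g)[0] for g in range(len(sizes))]
            r, s = _multiclass_rs(X, idx)
            rows.append(r / (s + s0))
    return np.asarray(rows)


def _sizes_to_labels(sizes):
    out = []
    for g, k in enumerate(sizes):
        out.extend([g] * k)
    return out


def _calls_at_delta(d_sorted, dbar, null_sorted, delta, two_sided):
    """Cut points, observed calls and per-permutation null calls at delta."""
    diff = d_sorted - dbar
    cut_up = np.inf
    up_idx = np.where(diff > delta)[0]
    # smallest observed d in the upper tail whose deviation exceeds delta
    upper = up_idx[up_idx >= np.searchsorted(dbar, 0.0)] if two_sided else up_idx
    if upper.size:
        cut_up = d_sorted[upper[0]]
    cut_low = -np.inf
    if two_sided:
        low_idx = np.where(-diff > delta)[0]
        lower = low_idx[low_idx < np.searchsorted(dbar, 0.0)]
        if lower.size:
            cut_low = d_sorted[lower[-1]]
    n_up = int(np.sum(d_sorted >= cut_up))
    n_low = int(np.sum(d_sorted <= cut_low)) if two_sided else 0
    null_calls = (null_sorted >= cut_up).sum(axis=1)
    if two_sided:
        null_calls = null_calls + (null_sorted <= cut_low).sum(axis=1)
    return cut_up, cut_low, n_up, n_low, float(np.median(null_calls))


def _pi0(d: np.ndarray, null_flat: np.ndarray) -> float:
    q25, q75 = np.percentile(null_flat, [25, 75])
    inside = np.sum((d >= q25) & (d <= q75))
    return float(min(1.0, inside / (0.5 * d.size)))


def permutation_fdr(matrix: pd.DataFrame, groups, *, statistic: str = "two_class",
                    delta: float = 0.0, n_perm: int = 1000, seed: int = 0,
                    s0_mode="auto") -> SAMResults:
    """Run the full SAM screen at a fixed ``delta``.

    ``groups`` maps sample id -> group label; for ``statistic="two_class"``
    exactly two labels must be present and d is (first label - second label)
    in label-sorted order of first appearance.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    groups = pd.Series(groups)
    group_idx, names = _group_indices(matrix, groups)
    sizes = [idx.size for idx in group_idx]
    X = matrix.to_numpy(dtype=float)
    means = None
    if statistic == "two_class":
        if len(sizes) != 2:
            raise ValueError("two_class requires exactly two groups")
        d, s0 = sam_two_class(matrix, [matrix.columns[i] for i in group_idx[0]],
                              [matrix.columns[i] for i in group_idx[1]],
                              s0_mode=s0_mode)
        two_sided = True
    elif statistic == "multiclass":
        d, s0, means = sam_multiclass(matrix, groups, s0_mode=s0_mode)
        two_sided = False
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    # reorder columns group-by-group so permutation sizes line up
    order = np.concatenate(group_idx)
    null = _null_d_matrix(X[:, order], sizes, s0, n_perm, seed, statistic)
    null_sorted = np.sort(null, axis=1)
    dbar = null_sorted.mean(axis=0)
    d_sorted_idx = np.argsort(d.to_numpy(), kind="stable")
    d_sorted = d.to_numpy()[d_sorted_idx]

    cut_up, cut_low, n_up, n_low, med_null = _calls_at_delta(
        d_sorted, dbar, null_sorted, delta, two_sided)
    pi0 = _pi0(d.to_numpy(), null_sorted.ravel())
    n_called = n_up + n_low
    fdr = 0.0 if n_called == 0 else min(1.0, pi0 * med_null / n_called)

    dv = d.to_numpy()
    up = list(d.index[dv >= cut_up])
    down = list(d.index[dv <= cut_low]) if two_sided else []
    if means is not None:
        # annotate direction for multiclass hits from group means vs control-ish
        pass
    return SAMResults(d=d, s0=s0, delta=delta, significant_up=up,
                      significant_down=down, estimated_fdr=fdr,
                      n_permutations=null.shape[0], seed=seed, pi0=pi0,
                      expected_null=dbar, statistic=statistic,
                      group_means=means)


def tune_delta(matrix: pd.DataFrame, groups, *, statistic: str = "two_class",
               fdr_target: float = 0.10, n_perm: int = 1000, seed: int = 0,
               s0_mode="auto") -> SAMResults:
    """Smallest delta whose estimated FDR is below ``fdr_target``.

    Scans the deviations |d - expected null| actually present in the data so
    every distinct calling outcome is visited once.
    """
    groups = pd.Series(groups)
    group_idx, _ = _group_indices(matrix, groups)
    sizes = [idx.size for idx in group_idx]
    X = matrix.to_numpy(dtype=float)
    if statistic == "two_class":
        d, s0 = sam_two_class(matrix, [matrix.columns[i] for i in group_idx[0]],
                              [matrix.columns[i] for i in group_idx[1]],
                              s0_mode=s0_mode)
        two_sided = True
        means = None
    else:
        d, s0, means = sam_multiclass(matrix, groups, s0_mode=s0_mode)
        two_sided = False
    order = np.concatenate(group_idx)
    null = _null_d_matrix(X[:, order], sizes, s0, n_perm, seed, statistic)
    null_sorted = np.sort(null, axis=1)
    dbar = null_sorted.mean(axis=0)
    d_sorted = np.sort(d.to_numpy(), kind="stable")
    pi0 = _pi0(d.to_numpy(), null_sorted.ravel())

    deviations = np.abs(d_sorted - dbar)
    candidates = np.unique(np.concatenate([[0.0], deviations,
                                           deviations + 1e-12]))
    best = None
    for delta in candidates:
        cut_up, cut_low, n_up, n_low, med_null = _calls_at_delta(
            d_sorted, dbar, null_sorted, float(delta), two_sided)
        n_called = n_up + n_low
        fdr = 0.0 if n_called == 0 else min(1.0, pi0 * med_null / n_called)
        if fdr < fdr_target:
            dv = d.to_numpy()
            up = list(d.index[dv >= cut_up])
            down = list(d.index[dv <= cut_low]) if two_sided else []
            best = SAMResults(d=d, s0=s0, delta=float(delta),
                              significant_up=up, significant_down=down,
                              estimated_fdr=fdr, n_permutations=null.shape[0],
                              seed=seed, pi0=pi0, expected_null=dbar,
                              statistic=statistic, group_means=means)
            break
    if best is None:  # nothing callable below target: empty result at max delta
        best = SAMResults(d=d, s0=s0, delta=float(candidates[-1] + 1.0),
                          significant_up=[], significant_down=[],
                          estimated_fdr=0.0, n_permutations=null.shape[0],
                          seed=seed, pi0=pi0, expected_null=dbar,
                          statistic=statistic, group_means=means)
    return best


class SAM:
    """Model-style front end: ``SAM(matrix, groups).fit(...) -> SAMResults``."""

    def __init__(self, matrix: pd.DataFrame, groups, *,
                 statistic: str = "two_class"):
        if matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not matrix.index.is_unique:
            dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene rows: {dupes[:5]}")
        self.matrix = matrix
        self.groups = pd.Series(groups)
        self.statistic = statistic

    def fit(self, *, delta: float | None = None, fdr_target: float = 0.10,
            n_perm: int = 1000, seed: int = 0, s0_mode="auto") -> SAMResults:
        """Screen at a fixed ``delta``, or tune delta to ``fdr_target``."""
        if delta is None:
            return tune_delta(self.matrix, self.groups, statistic=self.statistic,
                              fdr_target=fdr_target, n_perm=n_perm, seed=seed,
                              s0_mode=s0_mode)
        return permutation_fdr(self.matrix, self.groups, statistic=self.statistic,
                               delta=delta, n_perm=n_perm, seed=seed,
                               s0_mode=s0_mode)


# --------------------------------------------------------------------------
# post-processing
# --------------------------------------------------------------------------

def collapse_duplicates(result: SAMResults, probe_to_gene: dict) -> SAMResults:
    """Collapse duplicate probes per gene, keeping the max-|d| probe.

    Significance calls follow the retained probe; provenance (which probe was
    kept) is recorded on the returned result's ``d`` index mapping.
    """
    unmapped = [p for p in result.d.index if p not in probe_to_gene]
    if unmapped:
        raise KeyError(f"unmapped probes: {unmapped[:10]}")
    d = result.d
    keep = {}
    for probe, dval in d.items():
        gene = probe_to_gene[probe]
        if gene not in keep or abs(dval) > abs(d[keep[gene]]):
            keep[gene] = probe
    kept_probes = list(keep.values())
    new_d = pd.Series({g: d[p] for g, p in keep.items()}, name="d")
    up = sorted({probe_to_gene[p] for p in result.significant_up
                 if keep[probe_to_gene[p]] == p})
    down = sorted({probe_to_gene[p] for p in result.significant_down
                   if keep[probe_to_gene[p]] == p})
    out = SAMResults(d=new_d, s0=result.s0, delta=result.delta,
                     significant_up=up, significant_down=down,
                     estimated_fdr=result.estimated_fdr,
                     n_permutations=result.n_permutations, seed=result.seed,
                     pi0=result.pi0, expected_null=result.expected_null,
                     statistic=result.statistic, group_means=result.group_means)
    out.retained_probes = dict(zip(keep.keys(), kept_probes))
    return out


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene log ratios relative to the across-sample median (median -> 0)."""
    return matrix.sub(matrix.median(axis=1), axis=0)
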