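"""Exhaustive and stepwise scanning for SNP-combination association.

Two search engines rank SNP combinations by the information gain between the
joint genotype and a binary phenotype, with analytic gamma-null p-values:

* :class:`ExhaustiveIGScan` evaluates every :math:`\\binom{M}{k}` combination
  of a fixed order ``k`` (the practical regime is ``k <= 3``).
* :class:`StepwiseIGScan` grows combinations by forward selection: all single
  SNPs are tested first, those with raw p-value below a threshold ``t`` are
  extended by one SNP at a time, and the search advances an order whenever any
  extension again passes the threshold, until no combination passes or a
  maximum order is reached.  This explores a small fraction of the space but
  can only follow signals that leave a marginal footprint at lower orders.

Both engines are scikit-learn estimators (``fit(X, y)`` with fitted
``results_``), and both agree exactly with a naive per-combination count/IG
evaluation; the pairwise fast path used for order 2 is an implementation
detail.

Missing genotypes are handled per combination: samples missing any of the k
genotypes are excluded, and the null's sample size is the complete-case count
of that combination.  By default the number of genotype levels entering the
null is the number of *observed* nonempty joint categories, which adapts the
degrees of freedom to sparse tables; ``levels="theoretical"`` restores the
nominal ``3**k``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import MISSING, GenotypeMatrix
from .stats import ContingencyTable, ig_sf

__all__ = [
    "InteractionResult",
    "StepwiseState",
    "SearchConfig",
    "ExhaustiveIGScan",
    "StepwiseIGScan",
    "contingency_table",
    "scan_exhaustive",
    "scan_stepwise",
    "rank_results",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class InteractionResult:
    """One tested SNP combination.

    ``p_adjusted = min(1, m_tests * p_raw)`` (Bonferroni); ``levels_x`` is the
    number of genotype categories used for the null's degrees of freedom and
    ``n_complete`` the number of samples with no missing genotype among the
    combination.
    """

    snp_indices: tuple
    order_k: int
    ig_bits: float
    levels_x: int
    n_complete: int
    p_raw: float
    p_adjusted: float
    m_tests: int


@dataclass
class StepwiseState:
    """Bookkeeping of a stepwise search.

    ``selected[k]`` holds the combinations whose raw p-value passed the
    threshold at order ``k`` (``h_k[k]`` is their count), ``ordered_pvalues[k]``
    the sorted raw p-values of everything evaluated at that order, and
    ``evaluated_count`` the total number of IG evaluations performed.
    """

    current_order: int = 1
    selected: dict = field(default_factory=dict)
    h_k: dict = field(default_factory=dict)
    ordered_pvalues: dict = field(default_factory=dict)
    evaluated_count: int = 0
    evaluated_per_order: dict = field(default_factory=dict)


@dataclass
class SearchConfig:
    """Knobs of the two search engines.

    ``order`` drives the exhaustive scan; ``max_order`` and ``threshold`` the
    stepwise one.  ``alpha`` filters returned results on adjusted p-values;
    ``m_override`` replaces the Bonferroni test count; ``levels`` picks
    observed vs theoretical genotype-category counting for the null.
    """

    order: int = 2
    max_order: int = 4
    threshold: float = 0.05
    alpha: float = 0.05
    m_override: int = None
    m_mode: str = "adaptive"  # stepwise Bonferroni m: "adaptive" | "fixed"
    levels: str = "observed"  # "observed" | "theoretical"
    keep_all: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold t must lie in (0, 1]")
        if self.levels not in ("observed", "theoretical"):
            raise ValueError("levels must be 'observed' or 'theoretical'")
        if self.m_mode not in ("adaptive", "fixed"):
            raise ValueError("m_mode must be 'adaptive' or 'fixed'")


# ---------------------------------------------------------------------------
# contingency counting


def _as_arrays(g):
    if isinstance(g, GenotypeMatrix):
        return g.genotypes, g.phenotype
    raise TypeError("expected a GenotypeMatrix")


def contingency_table(g, snp_indices, phenotype=None) -> ContingencyTable:
    """Joint-genotype x phenotype contingency table for a SNP combination.

    Rows are the observed (nonzero-count) joint-genotype categories among
    complete cases — samples missing any of the k genotypes are excluded —
    and columns are control, case.
    """
    if isinstance(g, GenotypeMatrix):
        geno, y = g.genotypes, g.phenotype
    else:
        geno, y = np.asarray(g), np.asarray(phenotype)
    idx = tuple(snp_indices)
    if len(set(idx)) != len(idx):
        raise ValueError("snp_indices must be distinct")
    sub = geno[:, idx]
    ok = (sub != MISSING).all(axis=1)
    if not ok.any():
        raise ValueError("no complete cases for this SNP combination")
    k = len(idx)
    codes = sub[ok].astype(np.int64) @ (3 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    joint = np.bincount(codes * 2 + y[ok], minlength=2 * 3**k).reshape(-1, 2)
    return ContingencyTable(joint[joint.sum(axis=1) > 0])


def _ig_from_cells(case, ctrl):
    """IG in bits from per-cell case/control counts (…, n_cells) arrays."""
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    tot = case + ctrl
    n = tot.sum(axis=-1)
    a = case.sum(axis=-1)
    b = ctrl.sum(axis=-1)

    def xlog2(v):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = v * np.log2(v)
        return np.where(v > 0, out, 0.0)

    h_y = -(xlog2(a) + xlog2(b) - xlog2(n)) / n
    h_y_x = -(xlog2(case).sum(axis=-1) + xlog2(ctrl).sum(axis=-1) - xlog2(tot).sum(axis=-1)) / n
    return np.maximum(h_y - h_y_x, 0.0)


def _eval_combo(geno, y, idx, levels_mode):
    """(ig_bits, levels_x, n_complete, p_raw) for one SNP combination."""
    k = len(idx)
    sub = geno[:, idx]
    ok = (sub != MISSING).all(axis=1)
    # big-endian digit packing: cell order matches the pairwise fast path,
    # so the two code paths sum identical floats in identical order
    codes = sub[ok].astype(np.int64) @ (3 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    yk = y[ok]
    n = int(ok.sum())
    if n == 0:
        return 0.0, 0, 0, 1.0
    joint = np.bincount(codes * 2 + yk, minlength=2 * 3**k).reshape(-1, 2)
    nonzero = joint.sum(axis=1) > 0
    levels_obs = int(nonzero.sum())
    levels = 3**k if levels_mode == "theoretical" else levels_obs
    levels_y = int((joint.sum(axis=0) > 0).sum())
    ig = float(_ig_from_cells(joint[:, 1], joint[:, 0]))
    p = float(ig_sf(ig, n, levels, levels_y))
    return ig, levels, n, p


def _pairwise_stats(geno, y, levels_mode):
    """Vectorised order-2 statistics for all SNP pairs.

    One-hot encodes each SNP's three genotype classes (missing calls encode to
    the zero vector) and obtains all pairwise 3x3 case and control count
    blocks with two symmetric matrix products; a sample missing either
    genotype of a pair then contributes to no cell, which reproduces
    per-combination complete-case counting exactly.

    Returns (iu, ju, ig, levels, n_complete, p_raw) flat arrays over i<j.
    """
    n, m = geno.shape
    onehot = (geno.T[:, None, :] == np.arange(3)[None, :, None]).reshape(3 * m, n)
    onehot = np.asarray(onehot, dtype=np.float32)
    case_mask = y == 1
    a_case = onehot[:, case_mask]
    a_ctrl = onehot[:, ~case_mask]
    cc = (a_case @ a_case.T).reshape(m, 3, m, 3)
    ct = (a_ctrl @ a_ctrl.T).reshape(m, 3, m, 3)
    iu, ju = np.triu_indices(m, k=1)
    case = cc[iu, :, ju, :].reshape(len(iu), 9).astype(np.float64)
    ctrl = ct[iu, :, ju, :].reshape(len(iu), 9).astype(np.float64)
    tot = case + ctrl
    n_complete = tot.sum(axis=1)
    levels_obs = (tot > 0).sum(axis=1)
    levels = np.full(len(iu), 9) if levels_mode == "theoretical" else levels_obs
    levels_y = ((case.sum(axis=1) > 0).astype(int) + (ctrl.sum(axis=1) > 0).astype(int))
    ig = _ig_from_cells(case, ctrl)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ig_sf(ig, np.maximum(n_complete, 1), levels, levels_y)
    p = np.where(n_complete > 0, p, 1.0)
    return iu, ju, ig, levels, n_complete.astype(int), p


def rank_results(results):
    """Stable ranking: p_raw ascending, then IG descending, then indices."""
    return sorted(results, key=lambda r: (r.p_raw, -r.ig_bits, r.snp_indices))


# ---------------------------------------------------------------------------
# estimators


class _BaseIGScan(BaseEstimator):
    def _validate(self, X, y):
        if isinstance(X, GenotypeMatrix):
            geno, y = X.genotypes, X.phenotype
        else:
            geno = np.ascontiguousarray(X, dtype=np.int8)
            y = np.asarray(y)
        if geno.ndim != 2:
            raise ValueError("X must be a 2-D samples x SNPs matrix")
        if not np.isin(geno, [0, 1, 2, MISSING]).all():
            raise ValueError("genotype codes must be 0/1/2 or missing (-1)")
        if y is None:
            raise ValueError("a binary phenotype y is required")
        y = np.asarray(y, dtype=np.int8)
        if y.shape[0] != geno.shape[0]:
            raise ValueError("y length does not match the number of samples")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("phenotype must be binary (1=case, 0=control)")
        return geno, y

    def predict(self, X=None):
        """Return the ranked significant results of the fitted scan."""
        check_is_fitted(self, "results_")
        return self.results_


class ExhaustiveIGScan(_BaseIGScan):
    """Exhaustive information-gain scan over all k-SNP combinations.

    Parameters
    ----------
    order : int
        Combination order ``k``; all ``C(M, k)`` subsets are tested.
    alpha : float
        Significance level applied to Bonferroni-adjusted p-values when
        selecting ``results_``.
    m_override : int, optional
        Test count used for the Bonferroni adjustment instead of ``C(M, k)``.
    levels : {"observed", "theoretical"}
        Genotype-category counting for the null's degrees of freedom.
    keep_all : bool
        Keep every evaluated combination in ``all_results_``.

    Attributes
    ----------
    results_ : list of InteractionResult
        Significant combinations (adjusted p < alpha), ranked.
    all_results_ : list of InteractionResult
        All combinations, ranked (only when ``keep_all``).
    n_tests_ : int
        Number of combinations evaluated.
    """

    def __init__(self, order=2, alpha=0.05, m_override=None, levels="observed",
                 keep_all=False):
        self.order = order
        self.alpha = alpha
        self.m_override = m_override
        self.levels = levels
        self.keep_all = keep_all

    def fit(self, X, y=None):
        geno, yv = self._validate(X, y)
        k = int(self.order)
        m_snps = geno.shape[1]
        if k < 1:
            raise ValueError("order must be >= 1")
        if k > m_snps:
            raise ValueError(f"order {k} exceeds the number of SNPs {m_snps}")
        m_tests = self.m_override or math.comb(m_snps, k)

        results = []
        if k == 2:
            iu, ju, ig, levels, n_c, p = _pairwise_stats(geno, yv, self.levels)
            order_idx = np.argsort(p, kind="stable")
            keep_mask = p * m_tests < self.alpha
            for t in order_idx:
                if not self.keep_all and not keep_mask[t]:
                    continue
                results.append(
                    InteractionResult(
                        snp_indices=(int(iu[t]), int(ju[t])),
                        order_k=2,
                        ig_bits=float(ig[t]),
                        levels_x=int(levels[t]),
                        n_complete=int(n_c[t]),
                        p_raw=float(p[t]),
                        p_adjusted=min(1.0, m_tests * float(p[t])),
                        m_tests=m_tests,
                    )
                )
        else:
            for idx in itertools.combinations(range(m_snps), k):
                ig, levels, n_c, p = _eval_combo(geno, yv, idx, self.levels)
                p_adj = min(1.0, m_tests * p)
                if self.keep_all or p_adj < self.alpha:
                    results.append(
                        InteractionResult(idx, k, ig, levels, n_c, p, p_adj, m_tests)
                    )
        ranked = rank_results(results)
        self.n_snps_ = m_snps
        self.n_tests_ = math.comb(m_snps, k)
        if self.keep_all:
            self.all_results_ = ranked
            self.results_ = [r for r in ranked if r.p_adjusted < self.alpha]
        else:
            self.results_ = ranked
        return self


class StepwiseIGScan(_BaseIGScan):
    """Forward-selection information-gain search for higher-order interactions.

    All M single SNPs are evaluated first; those with raw p-value below
    ``threshold`` seed the search.  At each order the passing combinations are
    each extended by every SNP not already in them, the union of extensions is
    evaluated once (combinations reachable through several parents are
    deduplicated), and the search advances while any extension again passes
    the threshold, up to ``max_order``.  With ``threshold=1`` the search
    degenerates to the exhaustive scan.

    By construction the method only follows interactions whose components
    leave a marginal (lower-order) signal; pure-epistasis models with flat
    marginals, such as XOR at MAF one-half, are usually missed.

    The Bonferroni ``m`` at each order is, by default, the number of IG
    evaluations actually performed at that order (``m_mode="adaptive"``);
    ``m_mode="fixed"`` uses ``C(M, k)`` for comparability with the exhaustive
    scan.

    Attributes
    ----------
    results_ : list of InteractionResult
        Evaluated combinations with adjusted p < alpha, ranked.
    state_ : StepwiseState
        Selection sets, threshold counts ``h_k`` and evaluation tallies.
    """

    def __init__(self, max_order=4, threshold=0.05, alpha=0.05, m_mode="adaptive",
                 levels="observed", keep_all=False):
        self.max_order = max_order
        self.threshold = threshold
        self.alpha = alpha
        self.m_mode = m_mode
        self.levels = levels
        self.keep_all = keep_all

    def fit(self, X, y=None):
        geno, yv = self._validate(X, y)
        if self.max_order < 2:
            raise ValueError("max_order must be >= 2")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold t must lie in (0, 1]: t <= 0 passes nothing")
        m_snps = geno.shape[1]
        state = StepwiseState()
        evaluated = {}  # combo tuple -> (ig, levels, n, p_raw)

        def eval_batch(combos, order):
            stats = {}
            for idx in combos:
                stats[idx] = _eval_combo(geno, yv, idx, self.levels)
            state.evaluated_count += len(combos)
            state.evaluated_per_order[order] = (
                state.evaluated_per_order.get(order, 0) + len(combos)
            )
            evaluated.update(stats)
            return stats

        # step 1: first-order scan of every SNP
        stats = eval_batch([(j,) for j in range(m_snps)], order=1)
        frontier = self._select(stats, state, order=1)
        k = 1
        # steps 2-4: extend every passing combination by one SNP, advance
        # while anything passes; all passing combinations are expanded (the
        # rank order only fixes reporting, not reachability)
        while frontier and k < self.max_order:
            candidates = sorted(
                {
                    tuple(sorted(c + (s,)))
                    for c in frontier
                    for s in range(m_snps)
                    if s not in c
                }
                - evaluated.keys()
            )
            if not candidates:
                break
            stats = eval_batch(candidates, order=k + 1)
            frontier = self._select(stats, state, order=k + 1)
            k += 1
        state.current_order = k

        results = []
        for idx, (ig, levels, n_c, p) in evaluated.items():
            order = len(idx)
            if self.m_mode == "fixed":
                m_tests = math.comb(m_snps, order)
            else:
                m_tests = state.evaluated_per_order[order]
            p_adj = min(1.0, m_tests * p)
            if self.keep_all or p_adj < self.alpha:
                results.append(
                    InteractionResult(idx, order, ig, levels, n_c, p, p_adj, m_tests)
                )
        ranked = rank_results(results)
        self.n_snps_ = m_snps
        if self.keep_all:
            self.all_results_ = ranked
            self.results_ = [r for r in ranked if r.p_adjusted < self.alpha]
        else:
            self.results_ = ranked
        self.state_ = state
        return self

    def _select(self, stats, state, order):
        pvals = sorted(s[3] for s in stats.values())
        passing = [idx for idx, s in stats.items() if s[3] < self.threshold]
        passing.sort(key=lambda idx: (stats[idx][3], -stats[idx][0], idx))
        state.ordered_pvalues[order] = pvals
        state.selected[order] = passing
        state.h_k[order] = len(passing)
        return passing


# ---------------------------------------------------------------------------
# functional wrappers


def scan_exhaustive(g, config: SearchConfig = None, **kwargs):
    """Exhaustive scan of a :class:`GenotypeMatrix`; see :class:`ExhaustiveIGScan`."""
    config = config or SearchConfig(**kwargs)
    est = ExhaustiveIGScan(
        order=config.order,
        alpha=config.alpha,
        m_override=config.m_override,
        levels=config.levels,
        keep_all=config.keep_all,
    ).fit(*_as_arrays(g))
    return est.all_results_ if config.keep_all else est.results_


def scan_stepwise(g, config: SearchConfig = None, **kwargs):
    """Stepwise search of a :class:`GenotypeMatrix`; see :class:`StepwiseIGScan`.

    Returns ``(results, state)``.
    """
    config = config or SearchConfig(**kwargs)
    est = StepwiseIGScan(
        max_order=config.max_order,
        threshold=config.threshold,
        alpha=config.alpha,
        m_mode=config.m_mode,
        levels=config.levels,
        keep_all=config.keep_all,
    ).fit(*_as_arrays(g))
    results = est.all_results_ if config.keep_all else est.results_
    return results, est.state_
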