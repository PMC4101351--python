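"""Replicate-level experiment harness: type-I error, power, stepwise efficiency.

Three experiments mirror the standard way an interaction-scan method is
validated by simulation:

* :func:`type1_experiment` — family-wise error rate (FWER) of the exhaustive
  pairwise scan on null data: the fraction of null replicates in which the
  minimum Bonferroni-adjusted pairwise p-value falls below each nominal
  level.  A well-calibrated analytic null tracks the nominal levels.
* :func:`power_experiment` — detection power of a planted causal model: the
  fraction of replicates in which the exact causal SNP set is reported with
  Bonferroni-adjusted p below 0.05.
* :func:`stepwise_efficiency` — power and computation of the stepwise search
  relative to the exhaustive scan on the same replicates (shared seeds).
  Computation is measured in IG evaluations, not wall-clock, so the ratio is
  hardware-independent.

Replicate ``r`` of a run with base seed ``s`` uses the RNG stream seeded by
``(s, r)``, so reports are bit-identical across reruns and replicates are
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .search import ExhaustiveIGScan, StepwiseIGScan, _pairwise_stats
from .simulate import builtin_model, simulate_case_control, simulate_null

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "type1_experiment",
    "power_experiment",
    "stepwise_efficiency",
]

DEFAULT_FWER_LEVELS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class ExperimentConfig:
    """Shared configuration of the simulation experiments.

    ``model`` is a PenetranceModel, a registered model name, or None for the
    null; ``thresholds`` are the nominal FWER levels probed by
    :func:`type1_experiment`; ``stepwise_threshold`` is the marginal screen
    ``t``; ``max_order`` bounds both searches in the efficiency comparison.
    """

    n_replicates: int = 100
    m_snps: int = 1000
    n_cases: int = 500
    n_controls: int = 500
    model: object = None
    order: int = 2
    thresholds: tuple = DEFAULT_FWER_LEVELS
    alpha: float = 0.05
    stepwise_threshold: float = 0.05
    max_order: int = 2
    base_seed: int = 0
    include_first_order: bool = False
    exact_match: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for t in self.thresholds:
            if not 0.0 < t < 1.0 and t != 1.0:
                raise ValueError("thresholds must lie in (0, 1]")
        if isinstance(self.model, str):
            self.model = builtin_model(self.model)

    def replicate_rng(self, r: int) -> np.random.Generator:
        return np.random.default_rng([int(self.base_seed), int(r)])


@dataclass
class ExperimentReport:
    """Estimates from one experiment, with Monte-Carlo standard errors."""

    config: ExperimentConfig
    n_replicates: int
    fwer: dict = field(default_factory=dict)
    fwer_se: dict = field(default_factory=dict)
    power: float = None
    power_se: float = None
    power_stepwise: float = None
    power_exhaustive: float = None
    power_ratio: float = None
    computation_ratio: float = None
    evaluations_stepwise: float = None
    evaluations_exhaustive: float = None
    min_adjusted_pvalues: np.ndarray = None


def _mc_se(p_hat: float, r: int) -> float:
    return math.sqrt(p_hat * (1.0 - p_hat) / r)


def type1_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Family-wise error rate of the exhaustive pairwise scan on null data.

    Each replicate draws ``m_snps`` unassociated SNPs for the requested
    case/control split, scans all pairs, and records the minimum
    Bonferroni-adjusted p-value over the ``C(m_snps, 2)`` tests (plus the
    ``m_snps`` first-order tests when ``include_first_order``).  The FWER at
    each nominal level is the fraction of replicates whose minimum adjusted
    p-value falls below it.
    """
    r_total = config.n_replicates
    m = config.m_snps
    n_pairs = math.comb(m, 2)
    min_adj = np.empty(r_total)
    for r in range(r_total):
        rng = config.replicate_rng(r)
        ds = simulate_null(m, config.n_cases, config.n_controls, seed=rng)
        geno = ds.genotype_matrix.genotypes
        y = ds.genotype_matrix.phenotype
        _, _, _, _, _, p = _pairwise_stats(geno, y, "observed")
        m_family = n_pairs
        min_p = float(p.min())
        if config.include_first_order:
            from .search import _eval_combo

            p1 = min(
                _eval_combo(geno, y, (j,), "observed")[3] for j in range(m)
            )
            min_p = min(min_p, p1)
            m_family += m
        min_adj[r] = min(1.0, m_family * min_p)

    report = ExperimentReport(config=config, n_replicates=r_total)
    report.min_adjusted_pvalues = min_adj
    for level in config.thresholds:
        # at level 1 every performed test is trivially significant (p <= 1)
        est = float((min_adj < level).mean()) if level < 1.0 else 1.0
        report.fwer[level] = est
        report.fwer_se[level] = _mc_se(est, r_total)
    return report


def _detected(results, causal, alpha, exact_match=True):
    causal = tuple(sorted(causal))
    for res in results:
        if res.p_adjusted >= alpha:
            continue
        if res.snp_indices == causal:
            return True
        if not exact_match and set(causal) <= set(res.snp_indices):
            return True
    return False


def power_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Detection power of the exhaustive scan for a planted causal model.

    Power is the fraction of replicates in which the causal SNP combination
    itself (exact set match by default) appears among the results with
    Bonferroni-adjusted p-value below ``alpha``.
    """
    if config.model is None:
        raise ValueError("power_experiment needs a penetrance model")
    model = config.model
    n_noise = config.m_snps - model.k_loci
    hits = 0
    for r in range(config.n_replicates):
        rng = config.replicate_rng(r)
        ds = simulate_case_control(
            model, config.n_cases, config.n_controls, n_noise, seed=rng
        )
        est = ExhaustiveIGScan(order=model.k_loci, alpha=config.alpha).fit(
            ds.genotype_matrix.genotypes, ds.genotype_matrix.phenotype
        )
        if _detected(est.results_, ds.causal_indices, config.alpha, config.exact_match):
            hits += 1
    power = hits / config.n_replicates
    return ExperimentReport(
        config=config,
        n_replicates=config.n_replicates,
        power=power,
        power_se=_mc_se(power, config.n_replicates),
    )


def stepwise_efficiency(config: ExperimentConfig) -> ExperimentReport:
    """Stepwise-vs-exhaustive power and computation on shared replicates.

    Both engines run on the same simulated datasets.  The exhaustive
    reference evaluates every combination of orders 1..``max_order``
    (:math:`\\sum_k \\binom{M}{k}` IG evaluations); its power is the detection
    rate of the causal set at its own order with Bonferroni m = C(M, k).  The
    stepwise engine uses the marginal screen ``t = stepwise_threshold`` and
    adaptive Bonferroni counts.  Reported ratios are power(stepwise) /
    power(exhaustive) — undefined (None) when exhaustive power is zero — and
    mean IG evaluations stepwise / exhaustive.
    """
    if config.model is None:
        raise ValueError("stepwise_efficiency needs a penetrance model")
    model = config.model
    n_noise = config.m_snps - model.k_loci
    m = config.m_snps
    exhaust_evals = sum(math.comb(m, k) for k in range(1, config.max_order + 1))
    hits_ex = hits_sw = 0
    sw_evals = np.empty(config.n_replicates)
    for r in range(config.n_replicates):
        rng = config.replicate_rng(r)
        ds = simulate_case_control(
            model, config.n_cases, config.n_controls, n_noise, seed=rng
        )
        geno = ds.genotype_matrix.genotypes
        y = ds.genotype_matrix.phenotype
        ex = ExhaustiveIGScan(order=model.k_loci, alpha=config.alpha).fit(geno, y)
        if _detected(ex.results_, ds.causal_indices, config.alpha, config.exact_match):
            hits_ex += 1
        sw = StepwiseIGScan(
            max_order=config.max_order,
            threshold=config.stepwise_threshold,
            alpha=config.alpha,
        ).fit(geno, y)
        if _detected(sw.results_, ds.causal_indices, config.alpha, config.exact_match):
            hits_sw += 1
        sw_evals[r] = sw.state_.evaluated_count

    power_ex = hits_ex / config.n_replicates
    power_sw = hits_sw / config.n_replicates
    report = ExperimentReport(
        config=config,
        n_replicates=config.n_replicates,
        power_stepwise=power_sw,
        power_exhaustive=power_ex,
        power_ratio=(power_sw / power_ex) if power_ex > 0 else None,
        evaluations_stepwise=float(sw_evals.mean()),
        evaluations_exhaustive=float(exhaust_evals),
        computation_ratio=float(sw_evals.mean()) / exhaust_evals,
    )
    return report
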