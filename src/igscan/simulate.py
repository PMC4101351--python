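"""Penetrance-model case-control simulation and null-data generation.

A k-locus disease model is a table of ``3**k`` penetrances — the probability
of disease given each joint genotype, indexed by minor-allele dosage per
locus — together with the causal loci's minor allele frequencies.  Genotypes
are drawn under Hardy-Weinberg equilibrium (dosage ~ Binomial(2, q)), disease
status is Bernoulli with the cell's penetrance, and case/control quotas are
filled by rejection sampling from that population model.  Non-causal noise
SNPs are appended as independent HWE draws with frequencies from a MAF
sampler (uniform on [0.05, 0.5] by default, matching the usual MAF >= 5%
quality-control convention).

The registry ships representative two-locus fixtures — ``xor`` (pure
epistasis: elevated risk exactly where the dosage parity is odd, no marginal
effect at MAF one-half), ``multiplicative``, ``additive`` and
``constant-null`` — with user-overridable parameters; arbitrary published
penetrance tables can be supplied as TSV.

What the generator emulates: independent biallelic SNPs in HWE, a binary
phenotype driven only by the causal loci.  What it does not: linkage
disequilibrium, genotyping error, population structure, covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, default_snp_meta

__all__ = [
    "PenetranceModel",
    "SimulatedDataset",
    "builtin_model",
    "BUILTIN_MODELS",
    "marginal_penetrance",
    "simulate_null",
    "simulate_case_control",
    "simulate_population",
    "read_penetrance_tsv",
    "write_penetrance_tsv",
]


@dataclass
class PenetranceModel:
    """k-locus penetrance table with the causal loci's allele frequencies.

    ``penetrance`` has shape ``(3,) * k_loci`` and is indexed by minor-allele
    dosage per locus; entries are P(disease | joint genotype) in [0, 1].
    """

    penetrance: np.ndarray
    mafs: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        k = self.mafs.size
        if self.penetrance.shape != (3,) * k:
            raise ValueError(
                f"penetrance table shape {self.penetrance.shape} does not match "
                f"{k} loci (expected {(3,) * k})"
            )
        if np.any(self.penetrance < 0) or np.any(self.penetrance > 1):
            raise ValueError("penetrance entries must lie in [0, 1]")
        if np.any(self.mafs <= 0) or np.any(self.mafs > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")

    @property
    def k_loci(self) -> int:
        return self.mafs.size

    def genotype_weights(self) -> np.ndarray:
        """HWE probability of every joint genotype cell, shape (3,)*k."""
        per_locus = [_hwe_probs(q) for q in self.mafs]
        w = per_locus[0]
        for p in per_locus[1:]:
            w = np.multiply.outer(w, p)
        return w

    @property
    def prevalence(self) -> float:
        """Population disease probability under HWE genotype frequencies."""
        return float((self.penetrance * self.genotype_weights()).sum())


@dataclass
class SimulatedDataset:
    """A simulated case-control dataset: causal SNPs first, then noise SNPs."""

    genotype_matrix: GenotypeMatrix
    causal_indices: tuple
    seed: int
    model: PenetranceModel = None


def _hwe_probs(q: float) -> np.ndarray:
    """Genotype probabilities (dosage 0, 1, 2) at minor allele frequency q."""
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def uniform_maf_sampler(low: float = 0.05, high: float = 0.5):
    """MAF sampler drawing uniformly on [low, high]."""
    if not 0.0 < low <= high <= 0.5:
        raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")

    def sample(rng, size):
        return rng.uniform(low, high, size=size)

    return sample


# ---------------------------------------------------------------------------
# built-in penetrance models


def _xor_model(baseline=0.05, effect=0.3, mafs=(0.5, 0.5)):
    g = np.indices((3, 3)).sum(axis=0)
    pen = np.where(g % 2 == 1, baseline + effect, baseline)
    return PenetranceModel(pen, mafs, name="xor")


def _multiplicative_model(baseline=0.05, theta=2.0, mafs=(0.3, 0.3)):
    g = np.indices((3, 3)).sum(axis=0)
    pen = np.minimum(baseline * theta**g, 1.0)
    return PenetranceModel(pen, mafs, name="multiplicative")


def _additive_model(baseline=0.05, effect=0.1, mafs=(0.3, 0.3)):
    g = np.indices((3, 3)).sum(axis=0)
    pen = np.clip(baseline + effect * g, 0.0, 1.0)
    return PenetranceModel(pen, mafs, name="additive")


def _constant_null_model(baseline=0.1, mafs=(0.3, 0.3)):
    return PenetranceModel(np.full((3, 3), baseline), mafs, name="constant-null")


BUILTIN_MODELS = {
    "xor": _xor_model,
    "multiplicative": _multiplicative_model,
    "additive": _additive_model,
    "constant-null": _constant_null_model,
}


def builtin_model(name: str, **params) -> PenetranceModel:
    """Instantiate a registered two-locus penetrance model.

    ``xor``: penetrance ``baseline + effect`` exactly where the total dosage
    is odd, ``baseline`` elsewhere — a pure interaction with no marginal
    effects at MAF 0.5.  ``multiplicative``: ``baseline * theta**(g1+g2)``
    capped at 1.  ``additive``: ``baseline + effect*(g1+g2)`` clipped.
    ``constant-null``: every cell equal (no association).  Keyword arguments
    override the documented defaults, including ``mafs``.
    """
    try:
        factory = BUILTIN_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: "
            f"{sorted(BUILTIN_MODELS)}"
        ) from None
    return factory(**params)


def marginal_penetrance(model: PenetranceModel) -> list:
    """Per-locus marginal penetrance vectors (length 3 each).

    For each locus, the penetrance table averaged over the other loci's HWE
    genotype distribution.  A flat vector means the locus has no marginal
    effect.  For a single-locus model this is the table itself.
    """
    w = model.genotype_weights()
    out = []
    for axis in range(model.k_loci):
        others = tuple(a for a in range(model.k_loci) if a != axis)
        if not others:
            out.append(model.penetrance.copy())
            continue
        joint = (model.penetrance * w).sum(axis=others)
        norm = w.sum(axis=others)
        out.append(joint / norm)
    return out


# ---------------------------------------------------------------------------
# dataset generation


def simulate_null(
    m_snps: int,
    n_cases: int,
    n_controls: int,
    maf_sampler=None,
    seed=0,
) -> SimulatedDataset:
    """Null case-control data: no SNP is associated with the phenotype.

    Each SNP's genotypes are independent HWE draws at a MAF taken from
    ``maf_sampler`` (uniform [0.05, 0.5] by default); the phenotype is the
    requested case/control labelling, independent of every genotype.
    """
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    n = n_cases + n_controls
    if n < 2:
        raise ValueError("need at least two samples")
    rng = _as_rng(seed)
    sampler = maf_sampler or uniform_maf_sampler()
    mafs = np.asarray(sampler(rng, m_snps), dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("sampled MAFs must lie in (0, 0.5]")
    geno = rng.binomial(2, mafs, size=(n, m_snps)).astype(np.int8)
    pheno = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    g = GenotypeMatrix(geno, pheno, default_snp_meta(m_snps))
    return SimulatedDataset(g, causal_indices=(), seed=_seed_repr(seed))


def simulate_population(model: PenetranceModel, n: int, seed=0):
    """Draw ``n`` individuals from the population model.

    Returns ``(genotypes, status)``: causal-locus dosages of shape
    ``(n, k_loci)`` and the Bernoulli(penetrance) disease status.  Useful for
    checking that empirical cell penetrances converge to the table.
    """
    rng = _as_rng(seed)
    geno = rng.binomial(2, model.mafs, size=(n, model.k_loci)).astype(np.int8)
    pen = model.penetrance[tuple(geno.T)]
    status = (rng.random(n) < pen).astype(np.int8)
    return geno, status


def simulate_case_control(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    m_noise_snps: int = 0,
    noise_maf_sampler=None,
    seed=0,
    max_draws: int = 50_000_000,
) -> SimulatedDataset:
    """Case-control data with the model's loci causal and the rest noise.

    Population draws (HWE genotypes, Bernoulli(penetrance) status) are
    accepted into the case and control quotas until both are filled
    (rejection sampling); noise SNPs are then appended as independent HWE
    draws, unassociated with the phenotype.  Cases come first in the output.

    Raises
    ------
    RuntimeError
        If the quotas cannot be filled within ``max_draws`` population draws
        (e.g. an all-zero penetrance table with ``n_cases > 0``).
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("case/control counts must be nonnegative")
    rng = _as_rng(seed)
    k = model.k_loci
    need_case, need_ctrl = n_cases, n_controls
    cases, ctrls = [], []
    drawn = 0
    while need_case > 0 or need_ctrl > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"could not fill {n_cases} cases / {n_controls} controls within "
                f"{max_draws} population draws (prevalence {model.prevalence:.3g})"
            )
        batch = min(max(4096, 4 * (need_case + need_ctrl)), max_draws - drawn)
        geno, status = simulate_population(model, batch, rng)
        drawn += batch
        if need_case > 0:
            take = geno[status == 1][:need_case]
            cases.append(take)
            need_case -= len(take)
        if need_ctrl > 0:
            take = geno[status == 0][:need_ctrl]
            ctrls.append(take)
            need_ctrl -= len(take)
    causal = np.vstack(
        [c for c in cases if len(c)] + [c for c in ctrls if len(c)]
        or [np.empty((0, k), dtype=np.int8)]
    )
    n = n_cases + n_controls
    pheno = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )

    if m_noise_snps > 0:
        sampler = noise_maf_sampler or uniform_maf_sampler()
        noise_mafs = np.asarray(sampler(rng, m_noise_snps), dtype=float)
        if np.any(noise_mafs <= 0) or np.any(noise_mafs > 0.5):
            raise ValueError("sampled noise MAFs must lie in (0, 0.5]")
        noise = rng.binomial(2, noise_mafs, size=(n, m_noise_snps)).astype(np.int8)
        geno_all = np.hstack([causal, noise])
    else:
        geno_all = causal

    meta = default_snp_meta(geno_all.shape[1])
    meta.loc[: k - 1, "snp_id"] = [f"causal{i + 1}" for i in range(k)]
    g = GenotypeMatrix(geno_all, pheno, meta)
    return SimulatedDataset(
        g, causal_indices=tuple(range(k)), seed=_seed_repr(seed), model=model
    )


def _seed_repr(seed):
    return seed if isinstance(seed, (int, np.integer)) else None


# ---------------------------------------------------------------------------
# penetrance-table TSV


def read_penetrance_tsv(path) -> PenetranceModel:
    """Read a penetrance table TSV.

    Columns ``g1 ... gk penetrance`` (one row per joint genotype cell, all
    ``3**k`` cells present) plus a ``maf`` column or a ``#mafs: q1,q2,...``
    comment line.
    """
    mafs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#mafs:"):
            mafs = [float(v) for v in first.split(":", 1)[1].split(",")]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    locus_cols = [c for c in df.columns if c.startswith("g")]
    k = len(locus_cols)
    if "penetrance" not in df.columns or k == 0:
        raise ValueError(f"{path}: expected columns g1..gk and penetrance")
    if len(df) != 3**k:
        raise ValueError(f"{path}: expected {3**k} rows for {k} loci, got {len(df)}")
    table = np.zeros((3,) * k)
    for _, row in df.iterrows():
        idx = tuple(int(row[c]) for c in locus_cols)
        table[idx] = row["penetrance"]
    if mafs is None:
        if "maf" in df.columns:
            mafs = [df["maf"].iloc[0]] * k
        else:
            raise ValueError(f"{path}: MAFs missing (use a '#mafs:' header line)")
    return PenetranceModel(table, np.asarray(mafs), name=str(path))


def write_penetrance_tsv(model: PenetranceModel, path) -> None:
    """Write a penetrance model as TSV (inverse of :func:`read_penetrance_tsv`)."""
    k = model.k_loci
    with open(path, "w") as fh:
        fh.write("#mafs: " + ",".join(f"{q:g}" for q in model.mafs) + "\n")
        fh.write("\t".join(f"g{i + 1}" for i in range(k)) + "\tpenetrance\n")
        for idx in np.ndindex(*model.penetrance.shape):
            cells = "\t".join(str(i) for i in idx)
            fh.write(f"{cells}\t{model.penetrance[idx]:.10g}\n")
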