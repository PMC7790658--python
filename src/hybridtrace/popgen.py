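"""Within-population tests: Hardy-Weinberg, genotypic LD, admixture LD.

* :func:`hwe_exact` — the exact conditional Hardy-Weinberg test for a
  biallelic locus. All heterozygote counts compatible with the observed
  allele counts are enumerated with exact integer weights
  n! / (n_MM! n_MP! n_PP!) * 2^n_MP, and the two-sided p-value sums the
  probabilities of configurations no more probable than the observed one.
* :func:`genotypic_ld_test` — a G-test on the 3x3 genotype table of a locus
  pair with a Monte-Carlo permutation null.
* :func:`bh_adjust` — Benjamini-Hochberg step-up correction.
* :func:`admixture_ld` — mean pairwise covariance of scaled dosages
  (Barton & Gale's admixture linkage disequilibrium) with a percentile
  bootstrap over individuals; mixing of differentiated gene pools makes the
  covariance positive at loci with different founding frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_weights(n_m: int, n_p: int) -> dict[int, int]:
    """Exact integer enumeration weights for every compatible het count."""
    n = (n_m + n_p) // 2
    weights = {}
    for n_het in range(n_m % 2, min(n_m, n_p) + 1, 2):
        n_mm = (n_m - n_het) // 2
        n_pp = (n_p - n_het) // 2
        weights[n_het] = (math.factorial(n)
                          // (math.factorial(n_mm) * math.factorial(n_het)
                              * math.factorial(n_pp))) * 2 ** n_het
    return weights


def hwe_exact(n_mm: int, n_mp: int, n_pp: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for observed genotype counts.

    Conditions on the observed allele counts; computed in exact integer
    arithmetic, so ties between configuration probabilities are exact.
    """
    if min(n_mm, n_mp, n_pp) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n_mm + n_mp + n_pp < 1:
        raise ValueError("need at least one individual")
    n_m = 2 * n_mm + n_mp
    n_p = 2 * n_pp + n_mp
    weights = _hwe_weights(n_m, n_p)
    w_obs = weights[n_mp]
    total = sum(weights.values())
    p = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(p, total))


def hwe_direction(n_mm: int, n_mp: int, n_pp: int) -> str:
    """'deficit' or 'excess' of heterozygotes relative to expectation."""
    n = n_mm + n_mp + n_pp
    freq_m = (2 * n_mm + n_mp) / (2 * n)
    expected_het = 2 * freq_m * (1 - freq_m) * n
    return "deficit" if n_mp < expected_het else "excess"


def hwe_table(genotypes: GenotypeMatrix, samples: SampleTable,
              ) -> pd.DataFrame:
    """Exact HWE test per population x diploid locus."""
    diploid = genotypes.diploid_only()
    rows = []
    for pop in samples.populations:
        sub = diploid.take_individuals(
            [i for i in diploid.individual_ids
             if i in set(samples.individuals_in(pop))])
        for j, locus in enumerate(sub.locus_ids):
            d = sub.dosage[:, j]
            d = d[~np.isnan(d)]
            if d.size == 0:
                continue
            counts = (int((d == 2).sum()), int((d == 1).sum()),
                      int((d == 0).sum()))
            rows.append({
                "population": pop, "locus": locus,
                "n_MM": counts[0], "n_MP": counts[1], "n_PP": counts[2],
                "p_value": hwe_exact(*counts),
                "direction": hwe_direction(*counts)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    locus_i: str
    locus_j: str
    g_statistic: float
    p_value: float
    n_permutations: int
    n_individuals: int


def _g_statistic(codes_i: np.ndarray, codes_j: np.ndarray) -> float:
    observed = np.zeros((3, 3))
    np.add.at(observed, (codes_i, codes_j), 1)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row * col / observed.sum()
    nz = observed > 0
    return float(2 * (observed[nz] * np.log(observed[nz] / expected[nz])).sum())


def genotypic_ld_test(gi: np.ndarray, gj: np.ndarray,
                      n_permutations: int = 999, seed: int = 0) -> LDResult:
    """Permutation G-test of genotypic association between two diploid loci.

    Missing pairs are dropped; a monomorphic locus yields p = 1 by
    convention. p = (1 + #{permuted G >= observed}) / (B + 1).
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    keep = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[keep].astype(int), gj[keep].astype(int)
    if gi.size < 2:
        raise ValueError("need >= 2 individuals with both loci called")
    if len(np.unique(gi)) < 2 or len(np.unique(gj)) < 2:
        logger.debug("monomorphic locus in LD test; p = 1 by convention")
        return LDResult("", "", 0.0, 1.0, n_permutations, gi.size)
    g_obs = _g_statistic(gi, gj)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        if _g_statistic(gi, rng.permutation(gj)) >= g_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_permutations + 1)
    return LDResult("", "", g_obs, p, n_permutations, gi.size)


def ld_table(genotypes: GenotypeMatrix, samples: SampleTable,
             n_permutations: int = 999, seed: int = 0) -> pd.DataFrame:
    """Pairwise genotypic LD tests within each population (diploid loci)."""
    diploid = genotypes.diploid_only()
    rng = np.random.default_rng(seed)
    rows = []
    for pop in samples.populations:
        sub = diploid.take_individuals(
            [i for i in diploid.individual_ids
             if i in set(samples.individuals_in(pop))])
        for a in range(sub.n_loci):
            for b in range(a + 1, sub.n_loci):
                try:
                    res = genotypic_ld_test(
                        sub.dosage[:, a], sub.dosage[:, b], n_permutations,
                        seed=int(rng.integers(2 ** 31)))
                except ValueError:
                    continue
                rows.append({
                    "population": pop, "locus_i": sub.locus_ids[a],
                    "locus_j": sub.locus_ids[b], "G": res.g_statistic,
                    "p_value": res.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values, alpha: float = 0.05,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p_values, alpha=alpha,
                                           method="fdr_bh")
    return reject, adjusted


# ---------------------------------------------------------------------------
# admixture linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureLDResult:
    population: str
    d_bar: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    n_individuals: int
    n_loci: int

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI excludes zero."""
        return self.ci_lower > 0 or self.ci_upper < 0


def _mean_pairwise_cov(x: np.ndarray) -> float:
    """Mean over locus pairs of the dosage covariance (pairwise deletion).

    Uses the maximum-likelihood (1/n) covariance so that a 50/50 mix of the
    two pure species at fixed loci gives exactly 0.25 per pair.
    """
    n_loci = x.shape[1]
    if np.isnan(x).any():
        observed = ~np.isnan(x)
        z = np.where(observed, x, 0.0)
        obs = observed.astype(float)
        n_joint = obs.T @ obs
        with np.errstate(invalid="ignore", divide="ignore"):
            e_xy = (z.T @ z) / n_joint
            e_x = (z.T @ obs) / n_joint  # mean of locus i over joint rows
            cov = e_xy - e_x * e_x.T
        cov = np.where(n_joint >= 2, cov, 0.0)
        cov = np.nan_to_num(cov)
    else:
        cov = np.cov(x, rowvar=False, bias=True)
        cov = np.atleast_2d(cov)
    iu = np.triu_indices(n_loci, k=1)
    return float(cov[iu].mean())


def admixture_ld(dosage: np.ndarray, n_boot: int = 1000, seed: int = 0,
                 population: str = "") -> AdmixtureLDResult:
    """Barton-Gale admixture LD for one population's diploid diagnostic loci.

    ``dosage`` is individuals x loci with values 0/1/2 (NaN missing); scaled
    to x = dosage/2 before the pairwise covariance. The 95% CI is the
    percentile bootstrap over individuals.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim != 2 or dosage.shape[0] < 2 or dosage.shape[1] < 2:
        raise ValueError("need >= 2 individuals and >= 2 loci")
    x = dosage / 2.0
    d_bar = _mean_pairwise_cov(x)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _mean_pairwise_cov(x[rng.integers(n, size=n)])
    lower, upper = np.percentile(boot, [2.5, 97.5])
    return AdmixtureLDResult(population, d_bar, float(lower), float(upper),
                             n_boot, n, x.shape[1])


def admixture_ld_table(genotypes: GenotypeMatrix, samples: SampleTable,
                       loci: list[str] | None = None, n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Admixture LD per population over the diagnostic diploid panel."""
    diploid = genotypes.diploid_only()
    if loci is not None:
        diploid = diploid.take_loci([l for l in loci
                                     if l in diploid.locus_ids])
    rng = np.random.default_rng(seed)
    rows = []
    for pop in samples.populations:
        sub = diploid.take_individuals(
            [i for i in diploid.individual_ids
             if i in set(samples.individuals_in(pop))])
        if sub.n_individuals < 2:
            continue
        res = admixture_ld(sub.dosage, n_boot=n_boot,
                           seed=int(rng.integers(2 ** 31)), population=pop)
        rows.append({
            "population": pop, "D_bar": res.d_bar, "ci_lower": res.ci_lower,
            "ci_upper": res.ci_upper, "significant": res.significant,
            "n_individuals": res.n_individuals})
    return pd.DataFrame(rows)
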