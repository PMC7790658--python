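"""Structure-style admixture inference by maximum-likelihood EM.

The admixture model: individual i draws each allele copy at locus l from
cluster k with probability q_ik, and that copy is the species-M allele with
probability p_kl, so the observed dosage is

    g_il | q_i, p ~ Binomial(ploidy_l, sum_k q_ik p_kl).

:class:`AdmixtureModel` fits Q (individual ancestry proportions) and P
(cluster allele frequencies) by expectation-maximisation, which increases
the log-likelihood monotonically; random restarts stand in for MCMC
replicates. :func:`evanno_delta_k` selects the number of clusters K by the
second-difference statistic DeltaK = mean(|L''(K)|) / sd(L(K)), and
:func:`classify_q` cuts ancestry proportions into pure/admixed classes at
Q = 0.05 / 0.95 (boundary values count as admixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, SampleTable

_EPS = 1e-12


def classify_q(q_m: float, lower: float = 0.05, upper: float = 0.95) -> str:
    """Classify an ancestry proportion as pure_M / pure_P / admixed.

    Pure classes use strict inequalities, so a proportion exactly at a
    threshold is admixed.
    """
    if not 0 <= q_m <= 1:
        raise ValueError(f"ancestry proportion {q_m} outside [0, 1]")
    if q_m > upper:
        return "pure_M"
    if q_m < lower:
        return "pure_P"
    return "admixed"


@dataclass
class AdmixtureResults:
    """Fitted ancestry proportions and cluster allele frequencies."""

    k: int
    q: pd.DataFrame            # individuals x clusters
    p: pd.DataFrame            # clusters x loci
    loglik: float
    trace: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = False
    seed: int = 0
    samples: SampleTable | None = field(default=None, repr=False)

    @property
    def m_cluster(self) -> str:
        """Cluster carrying the species-M alleles (highest mean frequency)."""
        return str(self.p.mean(axis=1).idxmax())

    def q_m(self) -> pd.Series:
        """Per-individual proportion assigned to the species-M cluster."""
        return self.q[self.m_cluster].rename("Q_m")

    def classify(self, lower: float = 0.05, upper: float = 0.95) -> pd.Series:
        return self.q_m().map(lambda v: classify_q(v, lower, upper))

    def population_q(self) -> pd.Series:
        """Population means of Q_m (requires a sample table)."""
        if self.samples is None:
            raise ValueError("no sample table attached")
        pops = self.samples.df.set_index("individual").loc[
            self.q.index, "population"]
        return self.q_m().groupby(pops, sort=False).mean()

    def summary(self) -> str:
        lines = [
            "Admixture model (maximum-likelihood EM)",
            "=" * 43,
            f"clusters (K):        {self.k}",
            f"individuals:         {self.q.shape[0]}",
            f"loci:                {self.p.shape[1]}",
            f"log-likelihood:      {self.loglik:.3f}",
            f"EM iterations:       {self.n_iter}"
            f" ({'converged' if self.converged else 'not converged'})",
        ]
        if self.samples is not None:
            lines.append("")
            lines.append("population mean Q_m:")
            for pop, v in self.population_q().items():
                lines.append(f"  {pop:<16} {v:.3f}")
        return "\n".join(lines)


class AdmixtureModel:
    """Admixture-model likelihood over a genotype matrix.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Dosage matrix; haploid loci enter the likelihood with ploidy 1 and
        missing genotypes are skipped.
    samples : SampleTable, optional
        Metadata used only for population summaries of the fit.
    """

    def __init__(self, genotypes: GenotypeMatrix,
                 samples: SampleTable | None = None):
        self.genotypes = genotypes
        self.samples = samples
        g = genotypes.dosage
        self._observed = ~np.isnan(g)
        self._a = np.where(self._observed, g, 0.0)                 # M copies
        self._b = np.where(self._observed,
                           genotypes.ploidy[None, :] - g, 0.0)     # P copies

    # -- likelihood --------------------------------------------------------
    def loglik(self, q: np.ndarray, p: np.ndarray) -> float:
        theta = np.clip(q @ p, _EPS, 1 - _EPS)
        return float((self._a * np.log(theta)
                      + self._b * np.log1p(-theta)).sum())

    # -- fitting -----------------------------------------------------------
    def fit(self, k: int, seed: int = 0, max_iter: int = 2000,
            tol: float = 1e-6, restarts: int = 1) -> AdmixtureResults:
        """EM fit; with ``restarts`` > 1 the best log-likelihood is kept."""
        if k < 1:
            raise ValueError("K must be >= 1")
        if k > self.genotypes.n_individuals:
            raise ValueError("K exceeds the number of individuals")
        best: AdmixtureResults | None = None
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            res = self._fit_once(k, int(rng.integers(2 ** 31)), max_iter, tol)
            if best is None or res.loglik > best.loglik:
                best = res
        assert best is not None
        best.seed = seed
        return best

    def _fit_once(self, k: int, seed: int, max_iter: int,
                  tol: float) -> AdmixtureResults:
        rng = np.random.default_rng(seed)
        n, m = self._a.shape
        q = rng.dirichlet(np.ones(k), size=n)
        p = rng.uniform(0.05, 0.95, size=(k, m))
        trace = []
        prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            theta = np.clip(q @ p, _EPS, 1 - _EPS)
            ll = float((self._a * np.log(theta)
                        + self._b * np.log1p(-theta)).sum())
            trace.append(ll)
            if ll - prev < tol and it > 1:
                converged = True
                break
            prev = ll

            ratio_a = self._a / theta
            ratio_b = self._b / (1 - theta)
            # expected allele-assignment counts
            p_num = p * (q.T @ ratio_a)
            p_den = p_num + (1 - p) * (q.T @ ratio_b)
            q_num = q * (ratio_a @ p.T + ratio_b @ (1 - p).T)
            with np.errstate(invalid="ignore"):
                p = np.where(p_den > 0, p_num / p_den, p)
            q = q_num / q_num.sum(axis=1, keepdims=True)

        cluster_ids = [f"cluster{j + 1}" for j in range(k)]
        return AdmixtureResults(
            k=k,
            q=pd.DataFrame(q, index=self.genotypes.individual_ids,
                           columns=cluster_ids),
            p=pd.DataFrame(p, index=cluster_ids,
                           columns=self.genotypes.locus_ids),
            loglik=trace[-1], trace=np.array(trace), n_iter=len(trace),
            converged=converged, seed=seed, samples=self.samples)

    def fit_replicates(self, k_values, replicates: int = 10, seed: int = 0,
                       max_iter: int = 2000, tol: float = 1e-6,
                       ) -> dict[int, list[AdmixtureResults]]:
        """Independent EM replicates (random restarts) for each K."""
        rng = np.random.default_rng(seed)
        out: dict[int, list[AdmixtureResults]] = {}
        for k in k_values:
            out[k] = [self._fit_once(k, int(rng.integers(2 ** 31)),
                                     max_iter, tol)
                      for _ in range(replicates)]
        return out


# ---------------------------------------------------------------------------
# Evanno DeltaK
# ---------------------------------------------------------------------------

def evanno_from_summary(means: dict[int, float], sds: dict[int, float],
                        ) -> pd.DataFrame:
    """DeltaK from per-K replicate means and standard deviations.

    L''(K) = L(K+1) - 2 L(K) + L(K-1) on the replicate means;
    DeltaK(K) = |L''(K)| / sd(L(K)), defined only for interior K.
    """
    ks = sorted(means)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    rows = []
    for k in ks[1:-1]:
        if sds[k] == 0:
            raise ValueError(
                f"sd(L(K={k})) is zero: replicates are degenerate; use more "
                "replicates or perturb initialisation")
        second = means[k + 1] - 2 * means[k] + means[k - 1]
        rows.append({"K": k, "mean_L": means[k], "sd_L": sds[k],
                     "abs_L2": abs(second), "delta_K": abs(second) / sds[k]})
    return pd.DataFrame(rows)


def evanno_delta_k(logls_by_k: dict[int, list[float]],
                   ) -> tuple[pd.DataFrame, int]:
    """Evanno table and the K maximising DeltaK, from replicate logLs."""
    for k, lls in logls_by_k.items():
        if len(lls) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates")
    means = {k: float(np.mean(lls)) for k, lls in logls_by_k.items()}
    sds = {k: float(np.std(lls, ddof=1)) for k, lls in logls_by_k.items()}
    table = evanno_from_summary(means, sds)
    best = int(table.loc[table["delta_K"].idxmax(), "K"])
    return table, best
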