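"""Synthetic genotype landscapes and environmental tables.

The generators emulate the statistical structure of a two-species newt
contact zone so every downstream stage runs without field data:

* two parental species fixed (or near-fixed) at a panel of diagnostic
  biallelic SNPs plus one haploid mtDNA marker;
* an admixed enclave inside the range of the other species, with an optional
  geographically decaying introgression tail q(d) = q0 * exp(-d / lambda);
* within-family larval sampling (full-sib families sharing two parents),
  which induces heterozygote deficit and admixture linkage disequilibrium;
* i.i.d. missing genotype calls at a configurable rate (default 2.3%);
* presence/absence localities whose species label follows a logistic
  function of one climate driver, with nuisance variables calibrated to
  target Spearman correlations with the driver.

Admixture is simulated at the allele level: each allele copy is drawn from
the species-M gene pool independently with probability q, which is exactly
the likelihood the admixture model assumes; family sampling is the only
mechanism that breaks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .matrix import GenotypeMatrix, SampleTable

# Default printed-model coefficients: p_M = 1 / (1 + exp(b1 * bio17 + b0)).
DEFAULT_ENV_SLOPE = -0.156
DEFAULT_ENV_INTERCEPT = 7.767


@dataclass
class SimPanelSpec:
    """Marker-panel generator settings.

    ``delta`` is the parental allele-frequency differential at diagnostic
    loci (1 = fixed difference); ``background_delta`` applies to the
    remaining, non-diagnostic nuclear loci. Default panel: 60 nuclear SNPs of
    which 54 are diagnostic, plus a fixed-difference haploid mtDNA marker,
    with 2.3% missing calls.
    """

    n_loci_nuclear: int = 60
    n_diagnostic: int = 54
    include_mtdna: bool = True
    delta: float = 1.0
    background_delta: float = 0.2
    missing_rate: float = 0.023
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_diagnostic <= self.n_loci_nuclear:
            raise ValueError("n_diagnostic must be within [0, n_loci_nuclear]")
        for name in ("delta", "background_delta", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def locus_ids(self) -> list[str]:
        loci = [f"snp{j + 1:03d}" for j in range(self.n_loci_nuclear)]
        if self.include_mtdna:
            loci.append("mtND4")
        return loci

    @property
    def ploidy(self) -> np.ndarray:
        p = [2] * self.n_loci_nuclear
        if self.include_mtdna:
            p.append(1)
        return np.array(p)

    def parental_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus frequency of the species-M allele in each gene pool."""
        deltas = np.full(self.n_loci_nuclear, self.background_delta)
        deltas[: self.n_diagnostic] = self.delta
        if self.include_mtdna:
            deltas = np.append(deltas, 1.0)  # mtDNA haplotype is diagnostic
        freq_m = 0.5 + deltas / 2
        freq_p = 0.5 - deltas / 2
        return freq_m, freq_p

    @property
    def diagnostic_loci(self) -> list[str]:
        loci = self.locus_ids[: self.n_diagnostic]
        if self.include_mtdna:
            loci.append("mtND4")
        return loci


@dataclass
class PopulationSpec:
    """One sampled population in the simulated landscape."""

    name: str
    lat: float
    lon: float
    n_individuals: int
    q_mean: float | None = None  # None -> taken from the footprint tail
    n_families: int = 0  # 0 = unrelated individuals

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.q_mean is not None and not 0 <= self.q_mean <= 1:
            raise ValueError("q_mean must lie in [0, 1]")
        if self.n_families > self.n_individuals:
            raise ValueError(
                f"population {self.name!r}: {self.n_families} families exceed "
                f"{self.n_individuals} individuals")


@dataclass
class SimLandscapeSpec:
    """Enclave-plus-footprint geography.

    Populations with ``q_mean=None`` take their mean admixture proportion
    from the introgression tail q(d) = q0 * exp(-d / lambda), d being the
    great-circle-free planar distance (degrees) from ``origin``.
    """

    populations: list[PopulationSpec]
    q0: float = 0.0
    lam: float = 1.0
    origin: tuple[float, float] = (39.4, -9.1)  # (lat, lon)
    q_sd: float = 0.02  # individual spread around the population mean
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q0 <= 1:
            raise ValueError("q0 must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    def q_of(self, pop: PopulationSpec) -> float:
        if pop.q_mean is not None:
            return pop.q_mean
        d = float(np.hypot(pop.lat - self.origin[0], pop.lon - self.origin[1]))
        return float(self.q0 * np.exp(-d / self.lam))


@dataclass
class SimEnvSpec:
    """Presence/absence localities driven by one climate variable.

    Coefficients follow the printed-equation convention
    ``p_M = 1 / (1 + exp(slope * driver + intercept))``; the defaults are the
    two-species model for precipitation of the driest quarter (bio17).
    ``nuisance`` maps variable name -> target Spearman correlation with the
    driver (calibrated to within +/-0.02; +/-1 is an exact monotone
    transform).
    """

    n_localities: int = 108
    driver_name: str = "bio17"
    driver_range: tuple[float, float] = (0.0, 100.0)
    slope: float = DEFAULT_ENV_SLOPE
    intercept: float = DEFAULT_ENV_INTERCEPT
    nuisance: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_localities < 2:
            raise ValueError("need at least 2 localities")
        for name, r in self.nuisance.items():
            if not -1 <= r <= 1:
                raise ValueError(
                    f"nuisance {name!r}: correlation {r} outside [-1, 1]")


# ---------------------------------------------------------------------------
# genotype generators
# ---------------------------------------------------------------------------

def _draw_dosage(rng: np.random.Generator, q: np.ndarray,
                 freq_m: np.ndarray, freq_p: np.ndarray,
                 ploidy: np.ndarray) -> np.ndarray:
    """Dosages for individuals with admixture proportions ``q`` (allele-level)."""
    p_allele = q[:, None] * freq_m[None, :] + (1 - q[:, None]) * freq_p[None, :]
    return rng.binomial(ploidy[None, :], p_allele).astype(float)


def _mask_missing(rng: np.random.Generator, dosage: np.ndarray,
                  rate: float) -> np.ndarray:
    if rate > 0:
        dosage = dosage.copy()
        dosage[rng.random(dosage.shape) < rate] = np.nan
    return dosage


def simulate_reference_panels(spec: SimPanelSpec, n_marmoratus: int = 118,
                              n_pygmaeus: int = 120,
                              n_populations: int = 43,
                              ) -> tuple[GenotypeMatrix, SampleTable]:
    """Two pure parental reference cohorts, as used for marker validation.

    Genotypes are binomial draws from species-specific allele frequencies
    separated by the spec's delta; missing calls are masked i.i.d.
    """
    rng = np.random.default_rng(spec.seed)
    freq_m, freq_p = spec.parental_frequencies()
    ploidy = spec.ploidy

    q = np.concatenate([np.ones(n_marmoratus), np.zeros(n_pygmaeus)])
    dosage = _draw_dosage(rng, q, freq_m, freq_p, ploidy)
    dosage = _mask_missing(rng, dosage, spec.missing_rate)

    n = n_marmoratus + n_pygmaeus
    ids = [f"ref{i + 1:03d}" for i in range(n)]
    # reference populations lie outside the hybrid zone: each holds one species
    k_m = max(n_populations // 2, 1)
    k_p = max(n_populations - k_m, 1)
    pops = [f"refpop{(i % k_m) + 1:02d}" for i in range(n_marmoratus)] + \
        [f"refpop{k_m + (i % k_p) + 1:02d}" for i in range(n_pygmaeus)]
    lat = rng.uniform(36.0, 43.5, n)
    lon = rng.uniform(-9.5, 3.0, n)
    species = ["M"] * n_marmoratus + ["P"] * n_pygmaeus
    samples = SampleTable(pd.DataFrame({
        "individual": ids, "population": pops, "cohort": "reference",
        "species": species, "lat": np.round(lat, 4), "lon": np.round(lon, 4)}))
    genotypes = GenotypeMatrix(ids, spec.locus_ids, dosage, ploidy)
    return genotypes, samples


def _family_dosages(rng: np.random.Generator, n_children: int,
                    q_parents: np.ndarray, freq_m: np.ndarray,
                    freq_p: np.ndarray, ploidy: np.ndarray) -> np.ndarray:
    """Full-sib genotypes by Mendelian segregation from two simulated parents."""
    parents = _draw_dosage(rng, q_parents, freq_m, freq_p, ploidy)
    out = np.empty((n_children, len(ploidy)))
    diploid = ploidy == 2
    # each parent transmits its M allele with probability dosage/2
    p_mother = parents[0, diploid] / 2
    p_father = parents[1, diploid] / 2
    for c in range(n_children):
        a = rng.random(p_mother.shape) < p_mother
        b = rng.random(p_father.shape) < p_father
        out[c, diploid] = a.astype(int) + b.astype(int)
        out[c, ~diploid] = parents[0, ~diploid]  # maternal mtDNA
    return out


def simulate_admixed_landscape(panel: SimPanelSpec, land: SimLandscapeSpec,
                               ) -> tuple[GenotypeMatrix, SampleTable]:
    """Study-cohort genotypes across an enclave/footprint landscape.

    Each individual's admixture proportion q is drawn around its population
    mean (clipped normal, sd ``land.q_sd``); alleles are then independently
    species-M with probability q. Populations with family structure instead
    draw two parents per family and segregate offspring genotypes, which
    breaks within-population Hardy-Weinberg and creates admixture LD.
    """
    rng = np.random.default_rng(land.seed)
    freq_m, freq_p = panel.parental_frequencies()
    ploidy = panel.ploidy

    blocks, meta = [], []
    counter = 0
    for pop in land.populations:
        q_bar = land.q_of(pop)
        if pop.n_families > 0:
            sizes = np.full(pop.n_families, pop.n_individuals // pop.n_families)
            sizes[: pop.n_individuals % pop.n_families] += 1
            rows = []
            for size in sizes:
                q_par = np.clip(
                    rng.normal(q_bar, land.q_sd, 2), 0, 1)
                rows.append(_family_dosages(rng, int(size), q_par,
                                            freq_m, freq_p, ploidy))
            dosage = np.vstack(rows)
        else:
            q = np.clip(rng.normal(q_bar, land.q_sd, pop.n_individuals), 0, 1)
            dosage = _draw_dosage(rng, q, freq_m, freq_p, ploidy)
        dosage = _mask_missing(rng, dosage, panel.missing_rate)
        blocks.append(dosage)
        for _ in range(pop.n_individuals):
            counter += 1
            meta.append({"individual": f"ind{counter:04d}",
                         "population": pop.name, "cohort": "study",
                         "species": "unknown", "lat": pop.lat,
                         "lon": pop.lon})

    samples = SampleTable(pd.DataFrame(meta))
    genotypes = GenotypeMatrix(samples.individual_ids, panel.locus_ids,
                               np.vstack(blocks), ploidy)
    return genotypes, samples


# ---------------------------------------------------------------------------
# environmental generator
# ---------------------------------------------------------------------------

def _calibrated_nuisance(driver: np.ndarray, target: float,
                         rng: np.random.Generator,
                         tol: float = 0.02, max_iter: int = 40) -> np.ndarray:
    """Monotone-plus-noise transform of the driver hitting a target Spearman.

    Mixes a monotone transform of the driver with one fixed noise draw and
    bisects on the mixing weight until the measured rank correlation is
    within ``tol`` of the target.
    """
    sign = 1.0 if target >= 0 else -1.0
    base = sign * np.exp(driver / (driver.std() + 1e-12))  # monotone transform
    if abs(target) == 1.0:
        return base
    if target == 0.0:
        return rng.standard_normal(driver.size)
    z = rng.standard_normal(driver.size)
    base_std = (base - base.mean()) / base.std()
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        w = (lo + hi) / 2
        y = w * base_std + (1 - w) * z
        r = spearmanr(driver, y).statistic
        if abs(r - target) <= tol:
            return y
        if abs(r) < abs(target):
            lo = w
        else:
            hi = w
    raise ValueError(f"could not calibrate nuisance to Spearman {target}")


def simulate_env_presence(spec: SimEnvSpec) -> pd.DataFrame:
    """Presence localities whose labels follow the two-species logistic model.

    Returns a table with locality id, coordinates, the driver, any nuisance
    variables and the species label (M where the logistic fires).
    """
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(*spec.driver_range, spec.n_localities)
    p_m = expit(-(spec.slope * x + spec.intercept))
    labels = np.where(rng.random(spec.n_localities) < p_m, "M", "P")
    table = pd.DataFrame({
        "locality": [f"loc{i + 1:05d}" for i in range(spec.n_localities)],
        "lat": np.round(rng.uniform(36.0, 43.5, spec.n_localities), 4),
        "lon": np.round(rng.uniform(-9.5, 3.0, spec.n_localities), 4),
        spec.driver_name: x,
    })
    for name, target in spec.nuisance.items():
        table[name] = _calibrated_nuisance(x, target, rng)
    table["species"] = labels
    return table


def enclave_landscape(n_enclave: int = 2, n_pure: int = 30,
                      enclave_q: float = 0.93, n_per_population: int = 11,
                      q0: float = 0.0, lam: float = 1.0,
                      seed: int = 0) -> SimLandscapeSpec:
    """Convenience landscape: an admixed enclave inside a pure-P peninsula."""
    rng = np.random.default_rng(seed)
    pops = []
    for i in range(n_enclave):
        pops.append(PopulationSpec(
            name=f"enclave{i + 1}", lat=39.40 + 0.02 * i, lon=-9.10,
            n_individuals=n_per_population, q_mean=enclave_q))
    for i in range(n_pure):
        pops.append(PopulationSpec(
            name=f"pond{i + 1:02d}",
            lat=float(rng.uniform(38.6, 39.4)),
            lon=float(rng.uniform(-9.5, -8.8)),
            n_individuals=n_per_population,
            q_mean=None if q0 > 0 else 0.0))
    return SimLandscapeSpec(populations=pops, q0=q0, lam=lam, seed=seed)
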