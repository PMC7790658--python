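"""Core genotype containers.

The central object is :class:`GenotypeMatrix`: an individuals x loci matrix of
allele dosages, where the dosage at a locus is the number of copies of the
*species-M* (Triturus marmoratus-diagnostic) allele an individual carries.
Diploid nuclear loci take dosages 0/1/2, the haploid mitochondrial marker 0/1,
and missing calls are held as NaN (never a value inside the dosage range).

:class:`SampleTable` carries per-individual metadata (population, coordinates,
reference/study cohort, species label) and is kept aligned with the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIPLOID = 2
HAPLOID = 1

COHORTS = ("reference", "study")
SPECIES_LABELS = ("M", "P", "unknown")


class GenotypeError(ValueError):
    """Raised when genotype data violate the dosage/ploidy contract."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix.

    Parameters
    ----------
    individual_ids : sequence of str
        Unique individual identifiers (row labels).
    locus_ids : sequence of str
        Unique locus identifiers (column labels).
    dosage : ndarray of float, shape (n_individuals, n_loci)
        Count of the species-M allele; NaN encodes a missing call.
    ploidy : ndarray of int, shape (n_loci,)
        2 for diploid nuclear loci, 1 for the haploid mtDNA marker.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.ploidy = np.asarray(self.ploidy, dtype=int)
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.individual_ids), len(self.locus_ids)
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual ids")
        if len(set(self.locus_ids)) != m:
            raise GenotypeError("duplicate locus ids")
        if self.dosage.shape != (n, m):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} != ({n}, {m})"
            )
        if self.ploidy.shape != (m,):
            raise GenotypeError("ploidy must be per-locus")
        if not np.all(np.isin(self.ploidy, (HAPLOID, DIPLOID))):
            raise GenotypeError("ploidy entries must be 1 or 2")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > self.ploidy) | (
                ~np.isnan(self.dosage) & (self.dosage != np.round(self.dosage))
            )
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"dosage {self.dosage[i, j]!r} out of range for "
                f"individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r} (ploidy {self.ploidy[j]})"
            )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    @property
    def diploid_loci(self) -> np.ndarray:
        """Boolean mask over loci selecting diploid (nuclear) markers."""
        return self.ploidy == DIPLOID

    # -- subsetting --------------------------------------------------------
    def take_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.locus_ids),
                              self.dosage[rows, :], self.ploidy.copy())

    def take_loci(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {loc: j for j, loc in enumerate(self.locus_ids)}
        cols = [index[l] for l in ids]
        return GenotypeMatrix(list(self.individual_ids), list(ids),
                              self.dosage[:, cols], self.ploidy[cols])

    def diploid_only(self) -> "GenotypeMatrix":
        keep = [l for l, d in zip(self.locus_ids, self.diploid_loci) if d]
        return self.take_loci(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.individual_ids,
                            columns=self.locus_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.ploidy, other.ploidy)
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class SampleTable:
    """Per-individual metadata aligned with a :class:`GenotypeMatrix`.

    Wraps a DataFrame with columns ``individual, population, cohort, species,
    lat, lon``; ``cohort`` is ``reference`` or ``study`` and ``species`` is
    ``M``, ``P`` or ``unknown`` (reference individuals must be labelled).
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("individual", "population", "cohort", "species", "lat", "lon")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise GenotypeError(f"sample table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["individual"].duplicated().any():
            dup = self.df["individual"][self.df["individual"].duplicated()]
            raise GenotypeError(f"duplicate individuals: {sorted(set(dup))}")
        bad_cohort = set(self.df["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise GenotypeError(f"unknown cohort values: {sorted(bad_cohort)}")
        bad_sp = set(self.df["species"]) - set(SPECIES_LABELS)
        if bad_sp:
            raise GenotypeError(f"unknown species labels: {sorted(bad_sp)}")
        ref_unknown = (self.df["cohort"] == "reference") & (
            self.df["species"] == "unknown")
        if ref_unknown.any():
            raise GenotypeError(
                "reference individuals must carry a species label: "
                f"{list(self.df.loc[ref_unknown, 'individual'])[:5]}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.df["individual"])

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.df["population"]))

    def individuals_in(self, population: str) -> list[str]:
        return list(self.df.loc[self.df["population"] == population,
                                "individual"])

    def species_of(self, individuals: Iterable[str]) -> np.ndarray:
        lookup = dict(zip(self.df["individual"], self.df["species"]))
        return np.array([lookup[i] for i in individuals])

    def check_alignment(self, genotypes: GenotypeMatrix) -> None:
        """Every matrix individual must appear exactly once in the table."""
        table = set(self.individual_ids)
        absent = [i for i in genotypes.individual_ids if i not in table]
        if absent:
            raise GenotypeError(
                f"individuals absent from sample table: {absent[:5]}")


@dataclass
class RasterGrid:
    """ESRI-convention raster: lower-left origin, rows stored top-first."""

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def data_values(self) -> np.ndarray:
        """Valid cell values (nodata excluded), flattened."""
        return self.values[~self.nodata_mask]

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell centers, shaped like ``values``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.xllcorner + (cols + 0.5) * self.cellsize
        lat = self.yllcorner + (self.n_rows - 1 - rows + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)
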