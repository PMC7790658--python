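"""Marker diagnosticity scoring against reference-panel species labels.

Each allele copy observed in the reference panel is one observation: the
allele's identity (species-M vs species-P allele) "predicts" the carrier's
species, and Cohen's kappa of the resulting 2x2 allele x true-species table
measures chance-corrected diagnosticity. Heterozygotes contribute one allele
to each column; haploid loci contribute a single allele per individual.
A marker is declared diagnostic at kappa >= 0.9 (inclusive), informative if
the species differ at all in allele frequency, and uninformative otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, SampleTable


@dataclass
class MarkerReport:
    """Per-locus diagnosticity summary (one row of the marker table)."""

    locus: str
    kappa: float
    table: np.ndarray  # rows: true species (M, P); cols: allele (M, P)
    missing_fraction: float
    diagnostic: bool = False
    informative: bool = False


def _allele_table(dosage: np.ndarray, ploidy: int,
                  species: np.ndarray) -> np.ndarray:
    """2x2 counts of allele copies by carrier species at one locus."""
    table = np.zeros((2, 2))
    for row, sp in enumerate(("M", "P")):
        d = dosage[species == sp]
        d = d[~np.isnan(d)]
        table[row, 0] = d.sum()            # species-M allele copies
        table[row, 1] = (ploidy - d).sum()  # species-P allele copies
    return table


def kappa_from_table(table: np.ndarray) -> float:
    """Cohen's kappa for a 2x2 agreement table.

    When both margins are degenerate (expected agreement 1) kappa is defined
    as 1 for a diagonal table and 0 otherwise.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def allele_kappa(genotypes: GenotypeMatrix, samples: SampleTable,
                 locus: str) -> float:
    """Diagnosticity kappa of one locus against reference species labels."""
    j = genotypes.locus_ids.index(locus)
    species = samples.species_of(genotypes.individual_ids)
    table = _allele_table(genotypes.dosage[:, j], int(genotypes.ploidy[j]),
                         species)
    for row, sp in zip(table, ("M", "P")):
        if row.sum() == 0:
            raise ValueError(
                f"locus {locus!r}: no observed alleles for species {sp}")
    return kappa_from_table(table)


def missingness(genotypes: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Per-locus and overall missing-call fractions."""
    if genotypes.dosage.size == 0:
        raise ValueError("empty genotype matrix")
    mask = genotypes.missing_mask
    per_locus = pd.Series(mask.mean(axis=0), index=genotypes.locus_ids,
                          name="missing_fraction")
    return per_locus, float(mask.mean())


def marker_report(genotypes: GenotypeMatrix, samples: SampleTable,
                  kappa_threshold: float = 0.9) -> list[MarkerReport]:
    """Score every locus on the reference cohort and apply the screen."""
    ref_ids = list(samples.df.loc[samples.df["cohort"] == "reference",
                                  "individual"])
    ref = genotypes.take_individuals(
        [i for i in genotypes.individual_ids if i in set(ref_ids)])
    species = samples.species_of(ref.individual_ids)
    per_locus_missing, _ = missingness(genotypes)

    reports = []
    for j, locus in enumerate(ref.locus_ids):
        table = _allele_table(ref.dosage[:, j], int(ref.ploidy[j]), species)
        kappa = kappa_from_table(table)
        freq_m = table[0, 0] / max(table[0].sum(), 1)
        freq_p = table[1, 0] / max(table[1].sum(), 1)
        reports.append(MarkerReport(
            locus=locus, kappa=kappa, table=table,
            missing_fraction=float(per_locus_missing[locus]),
            diagnostic=kappa >= kappa_threshold,
            informative=abs(freq_m - freq_p) > 0))
    return reports


def diagnosticity_screen(reports: list[MarkerReport],
                         kappa_threshold: float = 0.9,
                         ) -> dict[str, list[str]]:
    """Partition the panel into diagnostic / informative-only / uninformative."""
    out: dict[str, list[str]] = {"diagnostic": [], "informative": [],
                                 "uninformative": []}
    for r in reports:
        if r.kappa >= kappa_threshold:
            out["diagnostic"].append(r.locus)
        elif r.informative:
            out["informative"].append(r.locus)
        else:
            out["uninformative"].append(r.locus)
    return out


def reports_to_frame(reports: list[MarkerReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": r.locus, "kappa": r.kappa,
        "missing_fraction": r.missing_fraction,
        "diagnostic": r.diagnostic, "informative": r.informative,
    } for r in reports])
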