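"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* Genotype CSV — header ``individual,population,cohort,species,lat,lon,
  <locus1>,...``; dosage cells ``0|1|2|NA`` (``0|1|NA`` at haploid loci).
  Haploid loci are identified by a ``#ploidy`` comment line or, absent that,
  by locus names starting with ``mt``.
* STRUCTURE text — two rows per individual, one allele column per locus,
  missing as ``-9``; the layout consumed by Structure-style programs.
* ESRI ASCII grid — the ``ncols/nrows/xllcorner/yllcorner/cellsize/
  NODATA_value`` header followed by rows from the top of the map down.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DIPLOID, HAPLOID, GenotypeError, GenotypeMatrix, RasterGrid, SampleTable

MISSING_TOKEN = "NA"
STRUCTURE_MISSING = "-9"
META_COLUMNS = ["individual", "population", "cohort", "species", "lat", "lon"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


# ---------------------------------------------------------------------------
# genotype CSV
# ---------------------------------------------------------------------------

def write_genotype_csv(genotypes: GenotypeMatrix, samples: SampleTable,
                       path: str | Path) -> None:
    samples.check_alignment(genotypes)
    path = Path(path)
    meta = samples.df.set_index("individual").loc[genotypes.individual_ids]
    with path.open("w") as fh:
        ploidy_tokens = " ".join(
            f"{loc}={p}" for loc, p in zip(genotypes.locus_ids, genotypes.ploidy))
        fh.write(f"#ploidy {ploidy_tokens}\n")
        fh.write(",".join(META_COLUMNS + list(genotypes.locus_ids)) + "\n")
        for i, ind in enumerate(genotypes.individual_ids):
            row = meta.loc[ind]
            cells = [ind, str(row["population"]), str(row["cohort"]),
                     str(row["species"]), repr(float(row["lat"])),
                     repr(float(row["lon"]))]
            for g in genotypes.dosage[i]:
                cells.append(MISSING_TOKEN if math.isnan(g) else str(int(g)))
            fh.write(",".join(cells) + "\n")


def read_genotype_csv(path: str | Path) -> tuple[GenotypeMatrix, SampleTable]:
    path = Path(path)
    ploidy_map: dict[str, int] = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#ploidy"):
            for token in first.split()[1:]:
                loc, p = token.rsplit("=", 1)
                ploidy_map[loc] = int(p)
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split(",")
        if header[: len(META_COLUMNS)] != META_COLUMNS:
            raise ParseError(
                f"{path.name}: header must start with {','.join(META_COLUMNS)}")
        locus_ids = header[len(META_COLUMNS):]
        if not locus_ids:
            raise ParseError(f"{path.name}: no locus columns")
        ploidy = np.array([
            ploidy_map.get(l, HAPLOID if l.startswith("mt") else DIPLOID)
            for l in locus_ids])

        meta_rows, dosage_rows, individuals = [], [], []
        for lineno, line in enumerate(fh, start=3 if ploidy_map else 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise ParseError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, "
                    f"got {len(cells)}")
            ind = cells[0]
            individuals.append(ind)
            meta_rows.append({
                "individual": ind, "population": cells[1], "cohort": cells[2],
                "species": cells[3], "lat": float(cells[4]),
                "lon": float(cells[5])})
            row = np.empty(len(locus_ids))
            for j, tok in enumerate(cells[len(META_COLUMNS):]):
                if tok == MISSING_TOKEN:
                    row[j] = np.nan
                    continue
                try:
                    g = int(tok)
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{lineno}: column {locus_ids[j]!r}: "
                        f"unknown allele code {tok!r}") from None
                if not 0 <= g <= ploidy[j]:
                    raise ParseError(
                        f"{path.name}:{lineno}: column {locus_ids[j]!r}: "
                        f"dosage {g} out of range for ploidy {ploidy[j]}")
                row[j] = g
            dosage_rows.append(row)

    try:
        genotypes = GenotypeMatrix(individuals, locus_ids,
                                   np.array(dosage_rows), ploidy)
        samples = SampleTable(pd.DataFrame(meta_rows))
    except GenotypeError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    samples.check_alignment(genotypes)
    return genotypes, samples


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------

def write_structure_file(genotypes: GenotypeMatrix, samples: SampleTable,
                         path: str | Path) -> None:
    """Two lines per individual; allele codes 1 (species M) and 2 (species P).

    A dosage of 1 at a diploid locus writes alleles ``1 2``; missing writes
    ``-9`` on both lines; the haploid mtDNA allele is duplicated across the
    two lines, the convention Structure users apply to haploid markers.
    """
    samples.check_alignment(genotypes)
    path = Path(path)
    pop_codes = {p: k + 1 for k, p in enumerate(samples.populations)}
    pop_of = dict(zip(samples.df["individual"], samples.df["population"]))
    with path.open("w") as fh:
        fh.write("\t".join(["individual", "pop"] + list(genotypes.locus_ids))
                 + "\n")
        for i, ind in enumerate(genotypes.individual_ids):
            lines = ([ind, str(pop_codes[pop_of[ind]])],
                     [ind, str(pop_codes[pop_of[ind]])])
            for g, p in zip(genotypes.dosage[i], genotypes.ploidy):
                if math.isnan(g):
                    alleles = (STRUCTURE_MISSING, STRUCTURE_MISSING)
                elif p == DIPLOID:
                    # dosage counts copies of allele "1" (species M)
                    alleles = ("1" if g >= 1 else "2", "1" if g == 2 else "2")
                else:
                    code = "1" if g == 1 else "2"
                    alleles = (code, code)
                lines[0].append(alleles[0])
                lines[1].append(alleles[1])
            fh.write("\t".join(lines[0]) + "\n")
            fh.write("\t".join(lines[1]) + "\n")


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                values.extend(float(v) for v in parts)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"{path.name}: missing header field {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(values) != nrows * ncols:
        raise ParseError(
            f"{path.name}: expected {nrows * ncols} values, got {len(values)}")
    return RasterGrid(np.array(values).reshape(nrows, ncols),
                      xllcorner=header["xllcorner"],
                      yllcorner=header["yllcorner"],
                      cellsize=header["cellsize"],
                      nodata=header.get("nodata_value", -9999.0))


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# environmental tables
# ---------------------------------------------------------------------------

def read_env_table(path: str | Path) -> pd.DataFrame:
    """Locality x climate table with a binary ``species`` column (M/P)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ParseError(f"{Path(path).name}: missing 'species' column")
    bad = set(df["species"]) - {"M", "P"}
    if bad:
        raise ParseError(f"{Path(path).name}: species labels must be M/P, "
                         f"got {sorted(bad)}")
    return df


def write_env_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
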