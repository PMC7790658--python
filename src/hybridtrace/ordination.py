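"""PCA of the genotype dosage matrix and geographic score surfaces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, RasterGrid


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a genotype PCA."""

    scores: pd.DataFrame          # individuals x components
    explained: np.ndarray         # variance fraction per component
    loadings: pd.DataFrame        # loci x components
    n_imputed: int                # missing dosages replaced by column means


def pca_genotypes(genotypes: GenotypeMatrix, n_components: int = 2,
                  ) -> PCAResult:
    """Principal components of mean-centred dosages.

    Missing dosages are imputed by the locus mean (the panel's missingness
    is low, ~2%, so imputation shrinks scores only marginally); the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if genotypes.n_individuals < 2 or genotypes.n_loci < 2:
        raise ValueError("need >= 2 individuals and >= 2 loci")
    x = genotypes.dosage.copy()
    mask = np.isnan(x)
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = [l for l, b in zip(genotypes.locus_ids, all_missing) if b]
        raise ValueError(f"loci with no called genotypes: {bad}")
    col_means = np.nanmean(x, axis=0)
    x[mask] = np.take(col_means, np.where(mask)[1])
    x -= x.mean(axis=0)

    _, s, vt = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, len(s))
    variances = s ** 2
    explained = variances[:n_components] / variances.sum()
    load = vt[:n_components].T
    # deterministic orientation: largest-magnitude loading entry positive
    flip = load[np.abs(load).argmax(axis=0), np.arange(n_components)] < 0
    load[:, flip] *= -1
    scores = x @ load
    cols = [f"PC{c + 1}" for c in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=genotypes.individual_ids,
                            columns=cols),
        explained=explained,
        loadings=pd.DataFrame(load, index=genotypes.locus_ids, columns=cols),
        n_imputed=int(mask.sum()))


def group_ellipses(scores: pd.DataFrame, grouping) -> pd.DataFrame:
    """Per-group mean and standard deviation for each component.

    Singleton groups get NaN standard deviations and a ``singleton`` flag,
    since an ellipse needs at least two members.
    """
    grouping = pd.Series(np.asarray(grouping), index=scores.index)
    rows = []
    for group, members in scores.groupby(grouping, sort=False):
        row = {"group": group, "n": len(members),
               "singleton": len(members) < 2}
        for col in scores.columns:
            row[f"{col}_mean"] = members[col].mean()
            row[f"{col}_sd"] = members[col].std(ddof=1) if len(members) > 1 \
                else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def weighted_contour_surface(points: pd.DataFrame, n_rows: int, n_cols: int,
                             xllcorner: float, yllcorner: float,
                             cellsize: float) -> RasterGrid:
    """Weight-scaled inverse-distance-squared surface of point values.

    ``points`` needs columns lat, lon, value, weight (the weight slot
    carries population sample size). Cell value =
    sum(w_i d_i^-2 v_i) / sum(w_i d_i^-2); a cell whose centre coincides
    with a data point takes that point's value exactly. The surface is a
    convex combination, so it never leaves [min(v), max(v)].
    """
    if len(points) < 1:
        raise ValueError("need at least one point")
    if (np.asarray(points["weight"]) <= 0).any():
        raise ValueError("weights must be positive")
    dup = points.groupby(["lat", "lon"])["value"].nunique()
    if (dup > 1).any():
        where = dup[dup > 1].index.tolist()
        raise ValueError(f"conflicting values at duplicate coordinates: "
                         f"{where}")

    grid = RasterGrid(np.zeros((n_rows, n_cols)), xllcorner, yllcorner,
                      cellsize)
    lon, lat = grid.cell_centers()
    values = np.asarray(points["value"], dtype=float)
    weights = np.asarray(points["weight"], dtype=float)
    d2 = ((lat[..., None] - np.asarray(points["lat"])[None, None, :]) ** 2
          + (lon[..., None] - np.asarray(points["lon"])[None, None, :]) ** 2)
    exact = d2 < 1e-18
    with np.errstate(divide="ignore", invalid="ignore"):
        w = weights[None, None, :] / d2
        num = (w * values[None, None, :]).sum(axis=-1)
        den = w.sum(axis=-1)
        surface = num / den
    hit = exact.any(axis=-1)
    if hit.any():
        first = exact.argmax(axis=-1)
        surface[hit] = values[first[hit]]
    grid.values = surface
    return grid
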