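"""Two-species climate distribution model.

A binary logistic regression of species identity (M = Triturus marmoratus,
P = T. pygmaeus) on bioclimatic predictors, assembled the way the classic
presence/presence workflow runs:

1. collinearity pruning — pairwise Spearman correlations, UPGMA clustering
   of 1 - |r_s|, cut at |r_s| = 0.7, one representative retained per cluster;
2. forward stepwise selection under the likelihood-ratio criterion with
   p_in = 0.05 and p_out = 0.10;
3. model fit assessed by AUC (Mann-Whitney formulation, Hanley-McNeil
   standard error);
4. hindcasting — the fitted logistic applied to raster climate surfaces,
   with binary (p_M > 0.5) maps stacked cumulatively across climate
   reconstructions.

The fitted model's natural presentation is the printed logistic form
p_M = 1 / (1 + exp(a * x + b)); :meth:`SDMResults.printed_coefficients`
returns (a, b) = (-slope, -intercept) of the standard logit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import expit
from scipy.stats import chi2, rankdata, spearmanr
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .matrix import RasterGrid

RESERVED_COLUMNS = {"locality", "lat", "lon", "species"}


class SeparationError(ValueError):
    """Complete separation: logistic ML coefficients diverge."""


# ---------------------------------------------------------------------------
# collinearity pruning
# ---------------------------------------------------------------------------

def collinearity_prune(env: pd.DataFrame, variables: list[str] | None = None,
                       r_threshold: float = 0.7,
                       ) -> tuple[list[str], np.ndarray]:
    """UPGMA-cluster predictors on 1 - |r_s| and keep one per cluster.

    Clusters are cut where cophenetic distance exceeds 1 - r_threshold;
    within each cluster the representative is the variable with the lowest
    mean |r_s| to all variables outside the cluster (ties broken by name).
    Returns (retained variables in input order, UPGMA linkage matrix).
    """
    if variables is None:
        variables = [c for c in env.columns if c not in RESERVED_COLUMNS]
    if len(variables) < 2:
        return list(variables), np.empty((0, 4))
    x = env[variables].to_numpy(dtype=float)
    constant = x.std(axis=0) == 0
    if constant.any():
        bad = [v for v, c in zip(variables, constant) if c]
        raise ValueError(f"constant predictors (correlation undefined): {bad}")
    corr = np.abs(spearmanr(x).statistic)
    corr = np.atleast_2d(corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(tree, t=1.0 - r_threshold, criterion="distance")

    retained = []
    for c in np.unique(clusters):
        inside = np.flatnonzero(clusters == c)
        outside = np.flatnonzero(clusters != c)
        if len(inside) == 1:
            retained.append(variables[inside[0]])
            continue
        if len(outside):
            mean_out = corr[np.ix_(inside, outside)].mean(axis=1)
        else:  # a single all-encompassing cluster: least internally redundant
            mean_out = np.array([corr[i, inside[inside != i]].mean()
                                 for i in inside])
        order = sorted(range(len(inside)),
                       key=lambda j: (mean_out[j], variables[inside[j]]))
        retained.append(variables[inside[order[0]]])
    return [v for v in variables if v in set(retained)], tree


# ---------------------------------------------------------------------------
# logistic primitive
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: pd.Series       # const + slopes, standard logit convention
    bse: pd.Series
    loglik: float
    n_obs: int
    converged: bool


def fit_logistic(x: pd.DataFrame | np.ndarray, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels).

    Raises :class:`SeparationError` when the classes are completely
    separated and the ML estimate does not exist.
    """
    x = pd.DataFrame(x)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if x.shape[1] and (x.to_numpy().std(axis=0) == 0).any():
        raise ValueError("constant predictor column")
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "error", category=PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, method="newton",
                                          maxiter=200, tol=1e-10)
    except (PerfectSeparationWarning, Exception) as exc:
        if "separation" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    if np.abs(fit.params.to_numpy()).max() > 1e3:
        raise SeparationError("diverging coefficients indicate separation")
    return LogisticFit(params=fit.params, bse=fit.bse, loglik=float(fit.llf),
                       n_obs=int(y.size), converged=bool(fit.mle_retvals
                                                         ["converged"]))


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = y.size
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC by the Mann-Whitney statistic (ties count one half) and its
    Hanley-McNeil standard error."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    a = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = a / (2 - a)
    q2 = 2 * a ** 2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a ** 2)
           + (n0 - 1) * (q2 - a ** 2)) / (n1 * n0)
    return float(a), float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

@dataclass
class SDMResults:
    """Selected variables, coefficients and fit diagnostics."""

    variables: list[str]
    params: pd.Series           # standard logit convention: const + slopes
    bse: pd.Series
    loglik: float
    auc: float
    auc_se: float
    trace: pd.DataFrame = field(repr=False)
    n_obs: int = 0

    def predict(self, data: pd.DataFrame | dict[str, np.ndarray],
                ) -> np.ndarray:
        """Probability of species M for rows/arrays of predictor values."""
        if not self.variables:
            n = len(data) if hasattr(data, "__len__") else 1
            return np.full(n, 1.0 / (1.0 + np.exp(-self.params["const"])))
        eta = np.full(np.asarray(data[self.variables[0]], dtype=float).shape,
                      float(self.params["const"]))
        for v in self.variables:
            eta = eta + self.params[v] * np.asarray(data[v], dtype=float)
        return expit(eta)

    def printed_coefficients(self) -> dict[str, float]:
        """Coefficients in the form p_M = 1 / (1 + exp(a*x + b)).

        Returns {variable: a, "intercept": b}, i.e. the negated standard
        logit parameters.
        """
        out = {v: -float(self.params[v]) for v in self.variables}
        out["intercept"] = -float(self.params["const"])
        return out

    def equation(self) -> str:
        printed = self.printed_coefficients()
        terms = "".join(f"{printed[v]:+.3f}*{v} " for v in self.variables)
        return (f"p_M = 1/(1 + exp({terms.strip()} "
                f"{printed['intercept']:+.3f}))")

    def summary(self) -> str:
        lines = [
            "Two-species distribution model (stepwise logistic regression)",
            "=" * 62,
            f"observations:     {self.n_obs}",
            f"selected:         {', '.join(self.variables) or '(none)'}",
            f"log-likelihood:   {self.loglik:.3f}",
            f"AUC:              {self.auc:.3f} +/- {self.auc_se:.3f}",
            f"model:            {self.equation()}",
            "",
            f"{'term':<12}{'coef':>10}{'std err':>10}",
        ]
        for term in self.params.index:
            lines.append(f"{term:<12}{self.params[term]:>10.4f}"
                         f"{self.bse[term]:>10.4f}")
        return "\n".join(lines)


class SpeciesDistributionModel:
    """Presence/presence logistic model of species identity on climate.

    Parameters
    ----------
    env : DataFrame
        Locality table with predictor columns and a ``species`` column
        (``M``/``P``); species M is the modelled presence.
    candidates : list of str, optional
        Predictor columns to consider (default: every non-reserved column).
    """

    def __init__(self, env: pd.DataFrame, candidates: list[str] | None = None,
                 p_in: float = 0.05, p_out: float = 0.10,
                 r_threshold: float = 0.7):
        if "species" not in env.columns:
            raise ValueError("env table needs a 'species' column")
        self.env = env.reset_index(drop=True)
        self.y = (self.env["species"] == "M").to_numpy(dtype=float)
        if self.y.sum() in (0, len(self.y)):
            raise ValueError("need localities for both species")
        self.candidates = candidates if candidates is not None else [
            c for c in env.columns if c not in RESERVED_COLUMNS]
        self.p_in, self.p_out, self.r_threshold = p_in, p_out, r_threshold

    def prune(self) -> list[str]:
        """Collinearity-prune the candidate set in place and return it."""
        retained, _ = collinearity_prune(self.env, self.candidates,
                                         self.r_threshold)
        self.candidates = retained
        return retained

    def fit(self, max_steps: int = 50) -> SDMResults:
        """Forward stepwise selection under the likelihood-ratio criterion."""
        y = self.y
        selected: list[str] = []
        loglik = _null_loglik(y)
        trace_rows = []
        seen_states = {tuple(selected)}
        for step in range(max_steps):
            changed = False
            # entry: candidate with the smallest LR p-value, if < p_in
            best = None
            for var in self.candidates:
                if var in selected:
                    continue
                try:
                    fit = fit_logistic(self.env[selected + [var]], y)
                except (SeparationError, ValueError):
                    continue
                lr = max(2 * (fit.loglik - loglik), 0.0)
                p = float(chi2.sf(lr, df=1))
                if best is None or p < best[0]:
                    best = (p, var, fit)
            if best is not None and best[0] < self.p_in:
                selected.append(best[1])
                loglik = best[2].loglik
                trace_rows.append({"step": step, "action": "add",
                                   "variable": best[1], "p_value": best[0]})
                changed = True
            # removal: any included variable whose LR p-value exceeds p_out
            worst = None
            for var in selected:
                reduced = [v for v in selected if v != var]
                ll_red = (fit_logistic(self.env[reduced], y).loglik
                          if reduced else _null_loglik(y))
                p = float(chi2.sf(max(2 * (loglik - ll_red), 0.0), df=1))
                if worst is None or p > worst[0]:
                    worst = (p, var, ll_red)
            if worst is not None and worst[0] > self.p_out:
                selected.remove(worst[1])
                loglik = worst[2]
                trace_rows.append({"step": step, "action": "remove",
                                   "variable": worst[1],
                                   "p_value": worst[0]})
                changed = True
            state = tuple(selected)
            if not changed or state in seen_states:
                break
            seen_states.add(state)

        trace = pd.DataFrame(trace_rows,
                             columns=["step", "action", "variable",
                                      "p_value"])
        if selected:
            fit = fit_logistic(self.env[selected], y)
            params, bse, loglik = fit.params, fit.bse, fit.loglik
            scores = SDMResults(selected, params, bse, loglik, 0, 0,
                                trace).predict(self.env)
            a, se = auc(scores, y.astype(bool))
        else:
            p0 = y.mean()
            params = pd.Series({"const": float(np.log(p0 / (1 - p0)))})
            bse = pd.Series({"const": np.nan})
            a, se = 0.5, np.nan
        return SDMResults(variables=selected, params=params, bse=bse,
                          loglik=loglik, auc=a, auc_se=se, trace=trace,
                          n_obs=len(y))


# ---------------------------------------------------------------------------
# hindcasting
# ---------------------------------------------------------------------------

def hindcast_stack(results: SDMResults,
                   raster_sets: list[dict[str, RasterGrid]],
                   threshold: float = 0.5,
                   ) -> tuple[list[RasterGrid], RasterGrid]:
    """Project the model on raster climate sets and stack binary maps.

    Returns per-set probability grids and the cumulative grid counting, per
    cell, how many climate reconstructions support presence (p_M > 0.5).
    Nodata in any input propagates to the outputs.
    """
    if not raster_sets:
        raise ValueError("no raster sets supplied")
    ref = None
    prob_grids = []
    cumulative = None
    for rasters in raster_sets:
        missing = [v for v in results.variables if v not in rasters]
        if missing:
            raise ValueError(f"raster set lacks variables: {missing}")
        grids = [rasters[v] for v in results.variables]
        if ref is None:
            ref = grids[0]
        for g in grids:
            if not g.aligned_with(ref):
                raise ValueError("raster grids are not aligned")
        nodata = np.zeros(ref.values.shape, dtype=bool)
        for g in grids:
            nodata |= g.nodata_mask
        data = {v: rasters[v].values for v in results.variables}
        prob = results.predict(data)
        prob[nodata] = ref.nodata
        prob_grids.append(RasterGrid(prob, ref.xllcorner, ref.yllcorner,
                                     ref.cellsize, ref.nodata))
        binary = (prob > threshold) & ~nodata
        if cumulative is None:
            cumulative = np.zeros(ref.values.shape)
            cum_nodata = np.zeros(ref.values.shape, dtype=bool)
        cumulative += binary
        cum_nodata |= nodata
    cumulative[cum_nodata] = ref.nodata
    return prob_grids, RasterGrid(cumulative, ref.xllcorner, ref.yllcorner,
                                  ref.cellsize, ref.nodata)
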