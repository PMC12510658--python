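"""Multistart calibration and AICc model comparison.

Each variant is fitted to the per-cell means of a
:class:`~ppiflux.dataset.TimeCourseDataset` by bounded least squares in
log10 parameter space.  Starts are drawn by Latin hypercube sampling from
the prior box (log10 in [-4, 2] for every free rate constant); each start
is refined with a trust-region-reflective local optimiser.  theta1 and r3
are fixed and never touched by the optimiser.

The cost is a species-normalised sum of squared errors: predictions and
data for each species are divided by that species' maximum observed mean
before residuals are formed, making species whose abundances differ by
orders of magnitude commensurate.  Models are ranked by AICc,

    AICc = n ln(SSE/n) + 2K + 2K(K+1)/(n - K - 1),

with n = 42 mean cells (7 timepoints x 6 species) and K the variant's
free-parameter count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dataset import TimeCourseDataset
from .models import DEFAULT_STIMULUS, ModelSpec, StimulusParams
from .simulate import (
    FIT_SETTINGS,
    IntegrationError,
    OBSERVED_SPECIES,
    SolverSettings,
    default_initial_conditions,
    integrate,
    observed_matrix,
)

__all__ = [
    "PriorBounds",
    "FitResult",
    "FitEnsemble",
    "ModelComparison",
    "lhs_sample",
    "sse",
    "normalised_sse",
    "fit_once",
    "multistart_fit",
    "aicc",
    "uncertainty_ranges",
    "rank_models",
]

logger = logging.getLogger(__name__)

#: default prior box on rate constants, log10 scale
DEFAULT_LOG10_BOUNDS = (-4.0, 2.0)

#: residual magnitude substituted when the solver fails during optimisation
_FAILED_RESIDUAL = 1e3


@dataclass(frozen=True)
class PriorBounds:
    """Per-parameter log10 bounds for one variant's free parameters."""

    parameter_names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def default(cls, spec: ModelSpec,
                box: tuple[float, float] = DEFAULT_LOG10_BOUNDS) -> "PriorBounds":
        names = spec.free_parameter_names
        d = len(names)
        return cls(names, np.full(d, box[0]), np.full(d, box[1]))

    def __post_init__(self) -> None:
        if np.any(self.lo >= self.hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        for fixed in ("theta1", "r3"):
            if fixed in self.parameter_names:
                raise ValueError(f"fixed parameter {fixed!r} cannot have prior bounds")


def lhs_sample(bounds: PriorBounds, n_starts: int, seed: int) -> np.ndarray:
    """Latin hypercube start points, (n_starts x d) on the log10 scale.

    Each marginal is stratified into ``n_starts`` equal-width bins with
    exactly one point per bin; a fixed seed reproduces the sample.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    d = len(bounds.parameter_names)
    unit = qmc.LatinHypercube(d=d, seed=seed).random(n=n_starts)
    return qmc.scale(unit, bounds.lo, bounds.hi)


def aicc(sse_value: float, n: int, K: int) -> float:
    """Corrected Akaike criterion: n ln(SSE/n) + 2K + 2K(K+1)/(n-K-1)."""
    if sse_value <= 0:
        raise ValueError("SSE must be positive for the log-likelihood surrogate")
    if n <= K + 1:
        raise ValueError(f"small-sample correction undefined for n={n} <= K+1={K + 1}")
    return float(n * np.log(sse_value / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1))


def _species_scales(dataset: TimeCourseDataset) -> np.ndarray:
    """Per-species normalisation: maximum observed mean (1.0 if all-zero)."""
    scales = dataset.mean_matrix().max(axis=0)
    return np.where(scales > 0, scales, 1.0)


def normalised_sse(pred: np.ndarray, data_means: np.ndarray,
                   scales: np.ndarray) -> float:
    """Sum over the grid cells of ((pred - data)/scale)^2 per species."""
    resid = (pred - data_means) / scales
    return float(np.sum(resid * resid))


def _predict(spec: ModelSpec, params: Mapping[str, float], dataset: TimeCourseDataset,
             stim: StimulusParams, settings: SolverSettings,
             ics: np.ndarray | None) -> np.ndarray:
    traj = integrate(spec, params, ics=ics, stim=stim, settings=settings,
                     t_grid=dataset.times)
    return observed_matrix(traj, spec)


def sse(spec: ModelSpec, params: Mapping[str, float], dataset: TimeCourseDataset,
        stim: StimulusParams = DEFAULT_STIMULUS,
        settings: SolverSettings = FIT_SETTINGS,
        ics: np.ndarray | None = None) -> float:
    """Species-normalised cost of one parameter set; +inf if the solver fails."""
    try:
        pred = _predict(spec, params, dataset, stim, settings, ics)
    except IntegrationError:
        return float("inf")
    return normalised_sse(pred, dataset.mean_matrix(), _species_scales(dataset))


@dataclass
class FitResult:
    """One converged local calibration."""

    variant_id: str
    params: dict[str, float]          # all rate constants incl. fixed, linear scale
    free_log10: np.ndarray            # fitted free parameters, log10 scale
    free_names: tuple[str, ...]
    sse: float
    n: int
    K: int
    aicc: float
    converged: bool
    start_index: int
    predictions: pd.DataFrame | None = None  # time x observed species

    def free_parameters(self) -> dict[str, float]:
        return {n: 10.0 ** v for n, v in zip(self.free_names, self.free_log10)}


@dataclass
class FitEnsemble:
    """Ranked fits of one variant to one dataset (ascending SSE)."""

    variant_id: str
    fits: list[FitResult]
    dataset: TimeCourseDataset
    n_starts: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fits = sorted(self.fits, key=lambda f: f.sse)

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def best(self) -> FitResult:
        if not self.fits:
            raise ValueError(f"{self.variant_id}: all starts failed, no fits")
        return self.fits[0]

    def top(self, k: int) -> list[FitResult]:
        """The k lowest-SSE fits (simulation ensembles use k=10,
        uncertainty ranges k=100)."""
        return self.fits[:k]

    def parameter_table(self, k: int | None = None) -> pd.DataFrame:
        """log10 free parameters of the top-k fits, one row per fit."""
        fits = self.fits if k is None else self.top(k)
        return pd.DataFrame(
            [f.free_log10 for f in fits],
            columns=list(self.best.free_names),
        )

    def to_frame(self) -> pd.DataFrame:
        """Serialisable summary: one row per fit with all parameters."""
        rows = []
        for rank, f in enumerate(self.fits):
            row = {"variant": f.variant_id, "rank": rank, "start_index": f.start_index,
                   "sse": f.sse, "aicc": f.aicc, "converged": f.converged}
            row.update(f.params)
            rows.append(row)
        return pd.DataFrame(rows)


def _make_residual_fn(spec, dataset, bounds, stim, settings, ics):
    """Lean residual closure: maps the log10 vector straight onto the
    reaction rate vector and calls the solver without the Trajectory
    bookkeeping of :func:`~ppiflux.simulate.integrate`."""
    from scipy.integrate import solve_ivp

    data_means = dataset.mean_matrix()
    scales = _species_scales(dataset)
    names = bounds.parameter_names
    n_cells = data_means.size
    times = dataset.times
    y0 = default_initial_conditions(spec) if ics is None else np.asarray(ics, float)

    free_pos = {n: i for i, n in enumerate(names)}
    rxn_free = np.array([free_pos.get(r.param, -1) for r in spec.reactions])
    fixed_k = np.array([spec.fixed_parameters.get(r.param, 0.0)
                        for r in spec.reactions])
    is_free = rxn_free >= 0
    # observed-species column map, pooling bound lipid with its free pool
    obs_cols = []
    for sp in OBSERVED_SPECIES:
        cols = [spec.state_names.index(sp)]
        if sp == "PIP3" and "PIP3b" in spec.state_names:
            cols.append(spec.state_names.index("PIP3b"))
        elif sp == "PIP2" and "PIP2b" in spec.state_names:
            cols.append(spec.state_names.index("PIP2b"))
        obs_cols.append(cols)

    def residuals(x_log10: np.ndarray) -> np.ndarray:
        kvec = np.where(is_free, 10.0 ** x_log10[rxn_free], fixed_k)
        f = spec.rhs_factory(kvec, stim)
        sol = solve_ivp(f, (times[0], times[-1]), y0, method=settings.method,
                        t_eval=times, rtol=settings.rtol, atol=settings.atol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            return np.full(n_cells, _FAILED_RESIDUAL)
        states = sol.y.T
        pred = np.column_stack([states[:, c].sum(axis=1) for c in obs_cols])
        resid = ((pred - data_means) / scales).ravel()
        if not np.all(np.isfinite(resid)):
            return np.full(n_cells, _FAILED_RESIDUAL)
        return resid

    return residuals


def fit_once(
    spec: ModelSpec,
    start: Mapping[str, float] | np.ndarray,
    dataset: TimeCourseDataset,
    bounds: PriorBounds | None = None,
    stim: StimulusParams = DEFAULT_STIMULUS,
    settings: SolverSettings = FIT_SETTINGS,
    ics: np.ndarray | None = None,
    start_index: int = 0,
    max_nfev: int | None = 500,
) -> FitResult:
    """Bounded local least squares from one start point.

    ``start`` is either a log10 vector in the bounds' parameter order or a
    mapping of linear-scale rate constants.  Convergence follows the
    optimiser's relative cost-improvement tolerance (1e-8); hitting the
    evaluation budget returns the best point found with
    ``converged=False``.
    """
    bounds = PriorBounds.default(spec) if bounds is None else bounds
    if isinstance(start, Mapping):
        x0 = np.array([np.log10(start[n]) for n in bounds.parameter_names])
    else:
        x0 = np.asarray(start, dtype=float)
    if x0.shape != (len(bounds.parameter_names),):
        raise ValueError("start point dimension does not match the free parameters")
    x0 = np.clip(x0, bounds.lo, bounds.hi)

    fn = _make_residual_fn(spec, dataset, bounds, stim, settings, ics)
    res = least_squares(
        fn, x0, bounds=(bounds.lo, bounds.hi), method="trf",
        ftol=1e-8, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev,
    )
    x = np.clip(res.x, bounds.lo, bounds.hi)
    free = {n: 10.0 ** v for n, v in zip(bounds.parameter_names, x)}
    params = spec.full_parameters(free)
    failed = bool(np.all(np.abs(res.fun) == _FAILED_RESIDUAL))
    sse_value = float("inf") if failed else float(np.sum(res.fun**2))

    n = dataset.n_cells
    K = spec.n_free_parameters
    crit = aicc(sse_value, n, K) if np.isfinite(sse_value) and sse_value > 0 else float("inf")
    predictions = None
    if not failed:
        try:
            pred = _predict(spec, params, dataset, stim, settings, ics)
            predictions = pd.DataFrame(pred, index=pd.Index(dataset.times, name="time_s"),
                                       columns=list(OBSERVED_SPECIES))
        except IntegrationError:  # pragma: no cover - defensive
            pass
    return FitResult(
        variant_id=spec.variant_id, params=params, free_log10=x,
        free_names=bounds.parameter_names, sse=sse_value, n=n, K=K, aicc=crit,
        converged=bool(res.status > 0 and not failed), start_index=start_index,
        predictions=predictions,
    )


def multistart_fit(
    spec: ModelSpec,
    dataset: TimeCourseDataset,
    bounds: PriorBounds | None = None,
    n_starts: int = 200,
    seed: int = 0,
    stim: StimulusParams = DEFAULT_STIMULUS,
    settings: SolverSettings = FIT_SETTINGS,
    ics: np.ndarray | None = None,
    max_nfev: int | None = 500,
    progress: bool = False,
) -> FitEnsemble:
    """Latin-hypercube multistart calibration of one variant.

    Returns every fit that produced a finite cost, ranked ascending by
    SSE.  Solver failures score +inf and are dropped; if every start
    fails a ``RuntimeError`` is raised.
    """
    bounds = PriorBounds.default(spec) if bounds is None else bounds
    starts = lhs_sample(bounds, n_starts, seed)
    iterator = range(n_starts)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc=f"fit {spec.variant_id}")
        except ImportError:
            pass
    fits = []
    for i in iterator:
        fit = fit_once(spec, starts[i], dataset, bounds, stim, settings, ics,
                       start_index=i, max_nfev=max_nfev)
        if np.isfinite(fit.sse):
            fits.append(fit)
    if not fits:
        raise RuntimeError(f"{spec.variant_id}: all {n_starts} starts failed")
    logger.info("%s: %d/%d starts converged, best SSE %.4g",
                spec.variant_id, len(fits), n_starts, min(f.sse for f in fits))
    return FitEnsemble(spec.variant_id, fits, dataset, n_starts, seed)


def uncertainty_ranges(ensemble: FitEnsemble, top_k: int = 100) -> pd.DataFrame:
    """Quantile bands of the best top-k fits on the log10 scale.

    Columns: median and the 5-95, 25-75 and 45-55 quantile interval edges,
    plus a ``non_identifiable`` flag for parameters whose 5-95 band spans
    at least five of the six prior decades.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if len(ensemble) < top_k:
        logger.warning("ensemble has %d fits < top_k=%d; using all",
                       len(ensemble), top_k)
    table = ensemble.parameter_table(min(top_k, len(ensemble)))
    qs = table.quantile([0.05, 0.25, 0.45, 0.50, 0.55, 0.75, 0.95])
    out = pd.DataFrame({
        "median": qs.loc[0.50],
        "q05": qs.loc[0.05], "q95": qs.loc[0.95],
        "q25": qs.loc[0.25], "q75": qs.loc[0.75],
        "q45": qs.loc[0.45], "q55": qs.loc[0.55],
    })
    out["non_identifiable"] = (out["q95"] - out["q05"]) >= 5.0
    out.index.name = "parameter"
    return out


@dataclass
class ModelComparison:
    """Per-variant fit summary and AICc ranking."""

    table: pd.DataFrame  # index variant; min_sse_n, median_sse_n, min_aicc, K, rank

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def ranking_string(self) -> str:
        return " < ".join(self.ranking)


def rank_models(ensembles: Sequence[FitEnsemble] | Mapping[str, FitEnsemble],
                median_k: int = 100) -> ModelComparison:
    """Compare fitted variants on a shared dataset.

    Reports per variant the minimum SSE/n, the median SSE/n of the best
    ``median_k`` fits, the minimum AICc and K; ranks ascending by minimum
    AICc with ties broken by smaller K then variant id.
    """
    if isinstance(ensembles, Mapping):
        ensembles = list(ensembles.values())
    if len(ensembles) < 2:
        raise ValueError("model ranking needs at least two fitted variants")
    ref = ensembles[0].dataset
    for ens in ensembles[1:]:
        if ens.dataset is not ref and not np.allclose(
            ens.dataset.mean_matrix(), ref.mean_matrix()
        ):
            raise ValueError("ensembles were fitted to different datasets")

    rows = {}
    for ens in ensembles:
        best = ens.best
        top = ens.top(min(median_k, len(ens)))
        rows[ens.variant_id] = {
            "min_sse_n": best.sse / best.n,
            "median_sse_n": float(np.median([f.sse for f in top])) / best.n,
            "min_aicc": min(f.aicc for f in ens.fits),
            "K": best.K,
        }
    table = pd.DataFrame(rows).T
    table.index.name = "variant"
    table["K"] = table["K"].astype(int)
    order = table.reset_index().sort_values(["min_aicc", "K", "variant"])["variant"]
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order.to_numpy())
    return ModelComparison(table.sort_values("rank"))
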