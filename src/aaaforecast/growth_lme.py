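"""Node-wise linear mixed-effects growth models and geometry forecasting.

Each geometric response — a centerline coordinate (x or y) per station, or an
unwrapped surface radius per lattice node — is modelled per patient and layer
as

    Y_tn = (alpha + b0_n) + (beta + b1_n) * t + eps_tn,

with a patient-level fixed intercept/slope (alpha, beta), node-level random
intercepts and slopes b0_n ~ N(0, sigma0^2), b1_n ~ N(0, sigma1^2)
(uncorrelated by assumption), and residual noise eps ~ N(0, sigma_eps^2).
Time t is in days since the patient's baseline scan.

Because the lattice guarantees a *balanced* design (every node observed at
every scan time), all nodes share one T x T marginal covariance

    V = sigma0^2 * 1 1' + sigma1^2 * t t' + sigma_eps^2 * I,

so the fixed effects can be profiled out in closed form and maximum
likelihood reduces to a 3-parameter search over the log-variances.  This is
what makes fitting 10,000-node grids a matter of seconds.

The module follows the statsmodels shape: :class:`NodeGrowthLME` is the
model for one response matrix and ``fit()`` returns an :class:`LMEFit`
results object (estimates, variance components, per-node BLUPs, predictions,
``summary()``); :class:`AneurysmGrowthModel` assembles the six response fits
of one patient and its ``fit()`` returns :class:`AneurysmGrowthResults`,
which forecasts full 3D geometry at arbitrary times.
"""

from __future__ import annotations

import enum
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .centerline import Centerline
from .cyl_param import (
    CylindricalGrid,
    SeriesParameterization,
    inverse_map,
    parameterize_series,
)
from .exceptions import ConvergenceError, RegimeError
from .mesh_io import Layer, PatientSeries

__all__ = [
    "Response",
    "FitRegime",
    "ResponseMatrix",
    "NodeGrowthLME",
    "LMEFit",
    "AneurysmGrowthModel",
    "AneurysmGrowthResults",
    "fit_lme",
    "neg_log_likelihood",
    "predict_nodes",
    "fit_patient",
    "forecast_geometry",
    "VARIANCE_FLOOR",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12
_BIG = 1e30  # finite penalty so finite-difference gradients stay defined
DAYS_PER_YEAR = 365.25
#: forecast horizon beyond which a warning is logged (explorer slider range)
HORIZON_GUARD_DAYS = 5 * DAYS_PER_YEAR


class Response(str, enum.Enum):
    CENTERLINE_X = "centerline_x"
    CENTERLINE_Y = "centerline_y"
    RADIUS = "radius"


class FitRegime(str, enum.Enum):
    ALL_FU = "all_fu"
    EXCLUDE_LAST = "exclude_last"


@dataclass
class ResponseMatrix:
    """Balanced G-node x T-time response panel for one patient and layer."""

    values: np.ndarray  # (G, T), cm
    times: np.ndarray  # (T,), days, times[0] == 0, strictly increasing
    response: Response
    layer: Layer

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.response = Response(self.response)
        self.layer = Layer(self.layer)
        if self.values.ndim != 2:
            raise ValueError("values must be a G x T matrix")
        G, T = self.values.shape
        if T < 2 or self.times.shape != (T,):
            raise ValueError(f"need T >= 2 times matching values, got {T}")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response matrix contains non-finite cells")

    @property
    def G(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


def _build_V(theta_log: np.ndarray, t: np.ndarray) -> np.ndarray:
    s0, s1, se = np.exp(theta_log)
    T = len(t)
    return (s0 * np.ones((T, T))
            + s1 * np.outer(t, t)
            + se * np.eye(T))


def _profile(theta_log: np.ndarray, Y: np.ndarray, t: np.ndarray):
    """Profiled GLS fixed effects and -2 log-likelihood pieces.

    Returns (gamma_hat, chol, neg2ll).  All nodes share V, so gamma solves
    the GLS normal equations against the node-mean trajectory.
    """
    G, T = Y.shape
    V = _build_V(theta_log, t)
    try:
        chol = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None, None, _BIG
    X = np.column_stack([np.ones(T), t])
    Vinv_X = cho_solve(chol, X)
    XtVinvX = X.T @ Vinv_X
    ybar = Y.mean(axis=0)
    try:
        gamma = np.linalg.solve(XtVinvX, Vinv_X.T @ ybar)
    except np.linalg.LinAlgError:
        return None, None, _BIG
    E = Y - (X @ gamma)  # (G, T) residuals, X @ gamma broadcast over nodes
    S = E.T @ E
    quad = float(np.trace(cho_solve(chol, S)))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    neg2ll = G * T * np.log(2.0 * np.pi) + G * logdet + quad
    if not np.isfinite(neg2ll):
        return None, None, _BIG
    return gamma, chol, neg2ll


def neg_log_likelihood(theta_log: np.ndarray, Y: ResponseMatrix) -> float:
    """-2 x profile log-likelihood at the GLS fixed effects.

    ``theta_log`` holds the three log-variances (log sigma0^2, log sigma1^2,
    log sigma_eps^2).  Equals the -2 log-density of the stacked G*T
    observations under the block-diagonal marginal covariance.
    """
    theta_log = np.asarray(theta_log, dtype=float)
    if not np.all(np.isfinite(theta_log)):
        raise ValueError("theta must be finite")
    _, _, neg2ll = _profile(theta_log, Y.values, Y.times)
    if not np.isfinite(neg2ll):
        raise FloatingPointError("likelihood evaluation is non-finite")
    return neg2ll


@dataclass
class LMEFit:
    """ML results for one node-wise growth model (statsmodels-style).

    Fixed effects ``alpha`` (cm) and ``beta`` (cm/day); variance components
    ``sigma0_sq`` (cm^2), ``sigma1_sq`` ((cm/day)^2), ``sigma_eps_sq``
    (cm^2); per-node BLUPs ``b0`` (cm) and ``b1`` (cm/day).
    """

    alpha: float
    beta: float
    sigma0_sq: float
    sigma1_sq: float
    sigma_eps_sq: float
    b0: np.ndarray
    b1: np.ndarray
    loglik: float
    converged: bool
    times: np.ndarray
    response: Response
    layer: Layer
    bse: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))

    @property
    def G(self) -> int:
        return len(self.b0)

    def predict(self, t_star: float) -> np.ndarray:
        """Per-node prediction (alpha + b0_n) + (beta + b1_n) * t_star."""
        return (self.alpha + self.b0) + (self.beta + self.b1) * float(t_star)

    def fittedvalues(self) -> np.ndarray:
        """(G, T) fitted values at the training times."""
        return ((self.alpha + self.b0)[:, None]
                + np.outer(self.beta + self.b1, self.times))

    def summary(self) -> str:
        rows = [
            f"Node-wise LME growth fit [{self.layer.value} / "
            f"{self.response.value}]",
            f"  nodes G = {self.G}, times T = {len(self.times)}, "
            f"converged = {self.converged}",
            f"  alpha (cm)            = {self.alpha: .6f}  "
            f"(SE {self.bse[0]:.2g})",
            f"  beta  (cm/day)        = {self.beta: .3e}  "
            f"(SE {self.bse[1]:.2g})  [{self.beta * DAYS_PER_YEAR: .4f} cm/yr]",
            f"  sigma0   (cm)         = {np.sqrt(self.sigma0_sq): .4e}",
            f"  sigma1   (cm/day)     = {np.sqrt(self.sigma1_sq): .4e}",
            f"  sigma_eps (cm)        = {np.sqrt(self.sigma_eps_sq): .4e}",
            f"  log-likelihood        = {self.loglik: .4f}",
        ]
        return "\n".join(rows)


class NodeGrowthLME:
    """Model object for one balanced response panel.

    Parameters
    ----------
    endog : ResponseMatrix or (G, T) array
        Node-by-time responses.
    times : array, optional
        Scan times in days (required when ``endog`` is a bare array).
    """

    def __init__(self, endog, times=None,
                 response: Response = Response.RADIUS,
                 layer: Layer = Layer.OUTER_WALL):
        if isinstance(endog, ResponseMatrix):
            self.data = endog
        else:
            self.data = ResponseMatrix(values=np.asarray(endog, dtype=float),
                                       times=np.asarray(times, dtype=float),
                                       response=response, layer=layer)

    def _starts(self) -> list[np.ndarray]:
        Y, t = self.data.values, self.data.times
        G, T = Y.shape
        total = max(float(Y.var()), VARIANCE_FLOOR * 10)
        t_scale = max(float(np.mean(t**2)), 1.0)
        starts = []
        # method-of-moments from per-node OLS lines
        X = np.column_stack([np.ones(T), t])
        coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (2, G)
        resid = Y.T - X @ coef
        s0 = max(float(coef[0].var()), VARIANCE_FLOOR * 10)
        s1 = max(float(coef[1].var()), VARIANCE_FLOOR * 10)
        if T > 2:
            se = max(float(resid.var()) * T / (T - 2), VARIANCE_FLOOR * 10)
        else:
            se = max(0.05 * total, VARIANCE_FLOOR * 10)
        starts.append(np.log([s0, s1, se]))
        # equal split
        starts.append(np.log([total / 3, total / (3 * t_scale), total / 3]))
        # residual-dominated
        starts.append(np.log([1e-4 * total, 1e-4 * total / t_scale, total]))
        return starts

    def fit(self, tol: float = 1e-10) -> LMEFit:
        """Maximum-likelihood fit over the three log-variances.

        Multi-start bounded L-BFGS-B on the profiled objective; the fixed
        effects are recovered in closed form at the optimum and BLUPs follow
        from the fitted variance components.
        """
        Y, t = self.data.values, self.data.times
        lo = np.log(VARIANCE_FLOOR)
        hi = np.log(max(1e6, 1e3 * float(Y.var()) + 1.0))
        bounds = [(lo, hi)] * 3
        obj = lambda th: _profile(th, Y, t)[2]
        best = None
        any_success = False
        for x0 in self._starts():
            x0 = np.clip(x0, lo, hi)
            res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": tol, "gtol": 1e-8,
                                    "maxiter": 500})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
            any_success = any_success or (res.success and np.isfinite(res.fun))
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("likelihood optimisation failed for all "
                                   "starts", best_fit=None)
        theta = best.x
        gamma, chol, neg2ll = _profile(theta, Y, t)
        s0, s1, se = np.maximum(np.exp(theta), VARIANCE_FLOOR)

        X = np.column_stack([np.ones(len(t)), t])
        E = Y - X @ gamma
        # BLUP: b_n = D Z' V^-1 (y_n - X gamma), Z = X, D = diag(s0, s1)
        VinvX = cho_solve(chol, X)
        B = (E @ VinvX) * np.array([s0, s1])  # (G, 2)
        # fixed-effect covariance: (sum_n X' V^-1 X)^-1
        XtVinvX = X.T @ VinvX
        cov_gamma = np.linalg.inv(Y.shape[0] * XtVinvX)
        bse = np.sqrt(np.diag(cov_gamma))

        fit = LMEFit(
            alpha=float(gamma[0]), beta=float(gamma[1]),
            sigma0_sq=float(s0), sigma1_sq=float(s1), sigma_eps_sq=float(se),
            b0=B[:, 0], b1=B[:, 1],
            loglik=-0.5 * float(neg2ll), converged=bool(any_success),
            times=t.copy(), response=self.data.response,
            layer=self.data.layer, bse=bse,
        )
        if not fit.converged:
            raise ConvergenceError("optimizer reported failure on every "
                                   "start", best_fit=fit)
        return fit


def fit_lme(Y: ResponseMatrix, tol: float = 1e-10) -> LMEFit:
    """Functional wrapper: ``NodeGrowthLME(Y).fit()``."""
    return NodeGrowthLME(Y).fit(tol=tol)


def predict_nodes(fit: LMEFit, t_star: float) -> np.ndarray:
    """Per-node forecast at ``t_star`` days since baseline."""
    if t_star > fit.times[-1] + HORIZON_GUARD_DAYS or \
       t_star < fit.times[0] - HORIZON_GUARD_DAYS:
        logger.warning(
            "forecast time %.0f d is more than 5 years outside the training "
            "span [%.0f, %.0f] d", t_star, fit.times[0], fit.times[-1]
        )
    return fit.predict(t_star)


class AneurysmGrowthModel:
    """Per-patient growth model over both layers and all responses.

    Built either from an existing :class:`SeriesParameterization` or
    directly from the patient's meshes via :meth:`from_series` (which runs
    centerline extraction and cylindrical parameterization).
    """

    def __init__(self, series: PatientSeries, param: SeriesParameterization):
        self.series = series
        self.param = param
        series.theta_axis = param.theta_axis
        series.z_axis = param.z_axis[Layer.OUTER_WALL]

    @classmethod
    def from_series(cls, series: PatientSeries, K: int = 100, N: int = 100,
                    n_harmonics: int = 5) -> "AneurysmGrowthModel":
        param = parameterize_series(series, K=K, N=N, n_harmonics=n_harmonics)
        return cls(series, param)

    def _response_matrices(self, keep: slice) -> dict:
        times = self.series.times_days[keep]
        times = times - times[0]
        out = {}
        for layer, lp in self.param.layers.items():
            cls_ = lp.centerlines[keep]
            grids = lp.grids[keep]
            X = np.stack([c.stations[:, 0] for c in cls_], axis=1)
            Yc = np.stack([c.stations[:, 1] for c in cls_], axis=1)
            R = np.stack([g.radii.ravel() for g in grids], axis=1)
            out[(layer, Response.CENTERLINE_X)] = ResponseMatrix(
                X, times, Response.CENTERLINE_X, layer)
            out[(layer, Response.CENTERLINE_Y)] = ResponseMatrix(
                Yc, times, Response.CENTERLINE_Y, layer)
            out[(layer, Response.RADIUS)] = ResponseMatrix(
                R, times, Response.RADIUS, layer)
        return out

    def fit(self, regime: FitRegime | str = FitRegime.ALL_FU,
            tol: float = 1e-10) -> "AneurysmGrowthResults":
        """Fit all six response models under the requested regime.

        ``exclude_last`` drops the final scan from training (honest
        forecasting) and requires at least three scans.
        """
        regime = FitRegime(regime)
        T = self.series.n_scans
        if regime is FitRegime.EXCLUDE_LAST:
            if T < 3:
                raise RegimeError(
                    f"exclude_last needs >= 3 scans, patient "
                    f"{self.series.patient_id!r} has {T}"
                )
            keep = slice(0, T - 1)
            held_out = [float(self.series.times_days[-1])]
        else:
            keep = slice(0, T)
            held_out = []
        t0 = _time.perf_counter()
        fits = {key: NodeGrowthLME(Y).fit(tol=tol)
                for key, Y in self._response_matrices(keep).items()}
        elapsed = _time.perf_counter() - t0
        logger.info("patient %s: six-model fit in %.2f s",
                    self.series.patient_id, elapsed)
        return AneurysmGrowthResults(
            model=self, fits=fits, regime=regime,
            held_out_times=held_out, fit_seconds=elapsed,
        )


@dataclass
class AneurysmGrowthResults:
    """Fitted per-patient model: six LME fits plus the shared lattice."""

    model: AneurysmGrowthModel
    fits: dict
    regime: FitRegime
    held_out_times: list[float]
    fit_seconds: float

    @property
    def series(self) -> PatientSeries:
        return self.model.series

    @property
    def param(self) -> SeriesParameterization:
        return self.model.param

    def forecast(self, t_star: float
                 ) -> dict[Layer, tuple[Centerline, CylindricalGrid, np.ndarray]]:
        """Forecast geometry of both layers at ``t_star`` days since baseline.

        Returns per layer the predicted centerline, the predicted radius
        grid, and the back-projected Cartesian point cloud.
        """
        out = {}
        for layer in (Layer.OUTER_WALL, Layer.LUMEN):
            z = self.param.z_axis[layer]
            theta = self.param.theta_axis
            x_hat = predict_nodes(self.fits[(layer, Response.CENTERLINE_X)],
                                  t_star)
            y_hat = predict_nodes(self.fits[(layer, Response.CENTERLINE_Y)],
                                  t_star)
            cl = Centerline(
                stations=np.column_stack([x_hat, y_hat, z]), layer=layer)
            r_hat = predict_nodes(self.fits[(layer, Response.RADIUS)], t_star)
            r_hat = np.maximum(r_hat, 1e-9).reshape(len(z), len(theta))
            grid = CylindricalGrid(radii=r_hat, z_axis=z, theta_axis=theta,
                                   layer=layer)
            cloud = inverse_map(grid, cl)
            out[layer] = (cl, grid, cloud)
        return out

    forecast_geometry = forecast  # spec-facing alias

    def evaluate(self, normalize_unwrapped: bool = False):
        """Spatial-similarity and scalar evaluation against every follow-up."""
        from .evaluation import evaluate_forecast
        return evaluate_forecast(self, normalize_unwrapped=normalize_unwrapped)

    def plot_forecast(self, t_star: float, layer: Layer = Layer.OUTER_WALL,
                      ax=None):
        """Unwrapped radius map r(z, θ) of the forecast at ``t_star``.

        Requires matplotlib.  Returns the axes.
        """
        import matplotlib.pyplot as plt

        layer = Layer(layer)
        _, grid, _ = self.forecast(t_star)[layer]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(grid.radii, origin="lower", aspect="auto",
                       extent=[grid.theta_axis[0], grid.theta_axis[-1],
                               grid.z_axis[0], grid.z_axis[-1]],
                       cmap="viridis")
        ax.set_xlabel("θ (rad)")
        ax.set_ylabel("z (cm)")
        ax.set_title(f"{layer.value} radius forecast at "
                     f"t* = {t_star / DAYS_PER_YEAR:.2f} yr (cm)")
        ax.figure.colorbar(im, ax=ax, label="r (cm)")
        return ax

    def summary(self) -> str:
        head = [
            f"Aneurysm growth model — patient {self.series.patient_id!r}",
            f"  regime = {self.regime.value}, scans = {self.series.n_scans}, "
            f"held out = {self.held_out_times or 'none'}",
            f"  fit wall time = {self.fit_seconds:.2f} s",
        ]
        body = [self.fits[key].summary()
                for key in sorted(self.fits, key=lambda k: (k[0].value,
                                                            k[1].value))]
        return "\n".join(head) + "\n" + "\n".join(body)


def fit_patient(series: PatientSeries, param: SeriesParameterization,
                regime: FitRegime | str = FitRegime.ALL_FU
                ) -> AneurysmGrowthResults:
    """Functional wrapper over :class:`AneurysmGrowthModel`."""
    return AneurysmGrowthModel(series, param).fit(regime=regime)


def forecast_geometry(results: AneurysmGrowthResults, t_star: float):
    """Functional wrapper over :meth:`AneurysmGrowthResults.forecast`."""
    return results.forecast(t_star)
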