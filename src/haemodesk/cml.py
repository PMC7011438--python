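r"""Biphasic CML treatment-response model.

Chronic myeloid leukaemia under continuous tyrosine kinase inhibitor (TKI)
therapy shows a characteristic biphasic decline of the BCR-ABL1 transcript
level: a steep first slope as the TKI eliminates cycling leukaemic cells,
followed by a shallow second slope attributed to a quiescent,
"TKI-protected" leukaemic stem-cell pool that is only slowly recruited into
cycle.  This module implements a deliberately reduced two-compartment
activation model of that pattern:

.. math::

    X'(t) = a\,Y(t) - d\,X(t), \qquad Y'(t) = -a\,Y(t)

where ``X`` is the active (TKI-exposed) leukaemic cell abundance, ``Y`` the
quiescent pool, ``d`` the TKI-induced elimination rate and ``a`` the
quiescent-to-active activation rate (both 1/day).  The clinical observable
is the BCR-ABL1 ratio on the international scale,

.. math::

    r(t) = 100\,\frac{X(t)}{X(t) + 2 N}

with ``N`` a fixed normal-cell reference abundance (BCR-ABL1 ratios are
conventionally computed against a control transcript present at two copies
per normal cell).  This is a surrogate for full single-cell models of CML
pathogenesis and treatment; it reproduces the biphasic log-decline and
exposes the latent stem-cell trajectory but does not describe pathogenesis,
competition with normal haematopoiesis, or TKI cessation.

Fitting is weighted least squares on the log10 % scale (the data span
several orders of magnitude and molecular assay noise is approximately
log-normal), with measurements below the assay detection limit treated as
left-censored.  Prediction bands come from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError, ValidationError

_DEGENERATE_TOL = 1e-10  # |d - a| below this uses the confluent limit form


# ---------------------------------------------------------------------------
# parameters and observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CMLParams:
    """Patient-specific parameters of the two-compartment TKI response model.

    Attributes
    ----------
    x0 : float
        Initial active leukaemic cell abundance (relative units, > 0).
    y0 : float
        Initial quiescent ("TKI-protected") leukaemic stem-cell abundance
        (relative units, >= 0).
    d_tki : float
        TKI elimination rate of active cells (1/day, > 0).
    a_act : float
        Activation rate quiescent -> active (1/day, >= 0).
    n_ref : float
        Normal-cell reference abundance (relative units, fixed, not fitted).
    """

    x0: float
    y0: float
    d_tki: float
    a_act: float
    n_ref: float = 1.0

    def __post_init__(self):
        if not (self.x0 > 0):
            raise ValidationError("x0 must be > 0")
        if self.y0 < 0:
            raise ValidationError("y0 must be >= 0")
        if not (self.d_tki > 0):
            raise ValidationError("d_tki must be > 0")
        if self.a_act < 0:
            raise ValidationError("a_act must be >= 0")
        if not (self.n_ref > 0):
            raise ValidationError("n_ref must be > 0")

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "d_tki": self.d_tki,
            "a_act": self.a_act,
            "n_ref": self.n_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CMLParams":
        return cls(**{k: float(d[k]) for k in ("x0", "y0", "d_tki", "a_act", "n_ref")})


@dataclass(frozen=True)
class MolecularObservation:
    """One BCR-ABL1 measurement (% on the international scale)."""

    time: float  # days since TKI start
    bcr_abl_pct: float
    below_lod: bool = False
    lod_pct: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError("observation time must be >= 0 days")
        if not self.below_lod and not (0 < self.bcr_abl_pct <= 100):
            raise ValidationError("bcr_abl_pct must lie in (0, 100]")
        if self.below_lod and self.lod_pct is None:
            raise ValidationError("below-LOD observation requires lod_pct")


# ---------------------------------------------------------------------------
# forward model (closed form)
# ---------------------------------------------------------------------------

def _abundances(x0, y0, d, a, t):
    """Closed-form X(t), Y(t); handles the confluent case d == a."""
    t = np.asarray(t, dtype=float)
    y = y0 * np.exp(-a * t)
    if abs(d - a) < _DEGENERATE_TOL:
        x = x0 * np.exp(-d * t) + a * y0 * t * np.exp(-d * t)
    else:
        x = x0 * np.exp(-d * t) + a * y0 * (np.exp(-a * t) - np.exp(-d * t)) / (d - a)
    return x, y


def ratio_pct(x: np.ndarray, n_ref: float) -> np.ndarray:
    """BCR-ABL1 % (international scale) from the active cell abundance."""
    return 100.0 * x / (x + 2.0 * n_ref)


def simulate_cml(params: CMLParams, times: Sequence[float]) -> np.ndarray:
    """BCR-ABL1 % trajectory at the requested times (days, >= 0)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValidationError("simulation times must be >= 0")
    x, _ = _abundances(params.x0, params.y0, params.d_tki, params.a_act, times)
    return ratio_pct(x, params.n_ref)


def latent_fraction(params: CMLParams, times: Sequence[float]) -> np.ndarray:
    """Quiescent stem-cell pool relative to baseline, Y(t)/Y(0) = exp(-a t)."""
    times = np.asarray(times, dtype=float)
    return np.exp(-params.a_act * times)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FREE_NAMES = ("x0", "y0", "d_tki", "a_act")

# box on the log parameters: generous biological plausibility limits that
# keep weakly identified fits from wandering into numerical overflow
_THETA_LO = np.log(np.array([1e-6, 1e-8, 1e-4, 1e-6]))
_THETA_HI = np.log(np.array([1e4, 1e4, 2.0, 1.0]))


@dataclass
class FittedCML:
    """Result of an individual fit.

    ``covariance`` is over the *log* of the free parameters
    (x0, y0, d_tki, a_act), from the local quadratic approximation at the
    optimum; ``residual_sd`` is the log10-scale residual standard deviation
    with ``dof`` residual degrees of freedom.
    """

    params: CMLParams
    covariance: np.ndarray
    residual_sd: float
    dof: int
    n_obs: int
    n_censored: int
    converged: bool
    objective: float
    free_names: tuple = _FREE_NAMES

    def to_json(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "covariance_log": self.covariance.tolist(),
            "residual_sd_log10": self.residual_sd,
            "dof": self.dof,
            "n_obs": self.n_obs,
            "n_censored": self.n_censored,
            "converged": self.converged,
            "objective": self.objective,
            "free_names": list(self.free_names),
        }

    @classmethod
    def from_json(cls, d: dict) -> "FittedCML":
        return cls(
            params=CMLParams.from_dict(d["params"]),
            covariance=np.asarray(d["covariance_log"], dtype=float),
            residual_sd=float(d["residual_sd_log10"]),
            dof=int(d["dof"]),
            n_obs=int(d["n_obs"]),
            n_censored=int(d["n_censored"]),
            converged=bool(d["converged"]),
            objective=float(d["objective"]),
            free_names=tuple(d.get("free_names", _FREE_NAMES)),
        )


def _model_log10(theta: np.ndarray, times: np.ndarray, n_ref: float) -> np.ndarray:
    x0, y0, d, a = np.exp(theta)
    x, _ = _abundances(x0, y0, d, a, times)
    return np.log10(np.maximum(ratio_pct(x, n_ref), 1e-300))


def _nll(theta_sigma, times, z, cens_mask, lod_log10, n_ref):
    """Negative log likelihood with left censoring at the detection limit."""
    theta, log_sigma = theta_sigma[:4], theta_sigma[4]
    sigma = np.exp(log_sigma)
    m = _model_log10(theta, times, n_ref)
    quant = ~cens_mask
    nll = 0.0
    if quant.any():
        r = (z[quant] - m[quant]) / sigma
        nll += 0.5 * np.sum(r * r) + quant.sum() * log_sigma
    if cens_mask.any():
        zc = (lod_log10[cens_mask] - m[cens_mask]) / sigma
        nll -= np.sum(stats.norm.logcdf(zc))
    return float(nll)


def _start_values(times, z, n_ref):
    """Heuristic start: slopes of the early and late segments of the log10
    course give d and a; intercepts give x0 and y0."""
    r0 = min(10 ** z[0], 99.0)
    x0 = 2.0 * n_ref * r0 / (100.0 - r0)
    # early slope from the first two points, late slope from the last two
    d = 0.05
    if len(times) >= 2 and times[1] > times[0]:
        d = max(np.log(10) * (z[0] - z[1]) / (times[1] - times[0]), 5e-3)
    a = 1e-3
    if len(times) >= 4 and times[-1] > times[-2]:
        a = np.log(10) * (z[-2] - z[-1]) / (times[-1] - times[-2])
        a = min(max(a, 1e-4), 0.9 * d)
    # back-extrapolate the late branch to t=0: X_late(0) ~ a*y0/(d-a)
    x_late0 = 10 ** (z[-1] + a * times[-1] / np.log(10)) / (100.0 - 10 ** z[-1]) * 2.0 * n_ref
    y0 = max(x_late0 * (d - a) / a, 1e-6 * x0)
    return np.array([np.log(x0), np.log(y0), np.log(d), np.log(a)])


def fit_cml(
    observations: Sequence[MolecularObservation],
    n_ref: float = 1.0,
    censoring: str = "likelihood",
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> FittedCML:
    """Fit the individual model to a molecular time course.

    Parameters
    ----------
    observations:
        Patient series; needs at least 4 quantifiable (non-censored) points
        because 4 parameters are free (``n_ref`` stays fixed).
    censoring:
        ``"likelihood"`` treats below-LOD points as left-censored with a
        normal-CDF likelihood contribution; ``"substitute"`` replaces them
        by LOD/2 and fits plain least squares.
    n_starts:
        Multi-start count; starts are the data-driven heuristic plus seeded
        log-scale perturbations of it.
    """
    if censoring not in ("likelihood", "substitute"):
        raise ValidationError(f"unknown censoring mode {censoring!r}")
    obs = sorted(observations, key=lambda o: o.time)
    times = np.array([o.time for o in obs], dtype=float)
    n_quant = sum(not o.below_lod for o in obs)
    if n_quant < 4:
        raise InsufficientDataError(
            f"need >= 4 quantifiable observations to fit 4 free parameters, got {n_quant}"
        )

    cens = np.array([o.below_lod for o in obs])
    lod = np.array([o.lod_pct if o.lod_pct is not None else np.nan for o in obs], dtype=float)
    if censoring == "substitute" and cens.any():
        z = np.array(
            [np.log10(o.lod_pct / 2.0) if o.below_lod else np.log10(o.bcr_abl_pct) for o in obs]
        )
        cens = np.zeros_like(cens)
    else:
        z = np.array(
            [np.log10(o.lod_pct) if o.below_lod else np.log10(o.bcr_abl_pct) for o in obs]
        )
    lod_log10 = np.log10(np.where(np.isnan(lod), 1.0, lod))

    quant = ~cens
    z_quant = z[quant]
    t_quant = times[quant]

    rng = np.random.default_rng(seed)
    base = np.clip(_start_values(t_quant, z_quant, n_ref), _THETA_LO + 0.1, _THETA_HI - 0.1)
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(np.clip(base + rng.normal(0.0, 0.5, size=4), _THETA_LO + 0.1, _THETA_HI - 0.1))

    best = None
    use_likelihood = cens.any()
    for th0 in starts:
        if use_likelihood:
            x0 = np.append(th0, np.log(0.15))
            res = optimize.minimize(
                _nll,
                x0,
                args=(times, z, cens, lod_log10, n_ref),
                method="L-BFGS-B",
                bounds=list(zip(np.append(_THETA_LO, np.log(0.01)), np.append(_THETA_HI, np.log(2.0)))),
                options={"ftol": tol, "maxiter": 500},
            )
            cand = (res.fun, res.x[:4], np.exp(res.x[4]), res.success)
        else:
            res = optimize.least_squares(
                lambda th: _model_log10(th, t_quant, n_ref) - z_quant,
                th0,
                method="trf",
                bounds=(_THETA_LO, _THETA_HI),
                xtol=tol,
                ftol=tol,
                max_nfev=2000,
            )
            rss = 2.0 * res.cost
            dof = max(len(t_quant) - 4, 1)
            cand = (rss, res.x, np.sqrt(rss / dof), res.success)
        if best is None or cand[0] < best[0]:
            best = cand

    objective, theta_hat, sigma_hat, success = best
    dof = max(n_quant - 4, 1)

    # covariance of the log parameters from the local quadratic approximation
    if use_likelihood:
        hess = _numerical_hessian(
            lambda th: _nll(np.append(th, np.log(sigma_hat)), times, z, cens, lod_log10, n_ref),
            theta_hat,
        )
        cov = _robust_inverse(hess)
    else:
        jac = _numerical_jacobian(lambda th: _model_log10(th, t_quant, n_ref), theta_hat)
        cov = sigma_hat**2 * _robust_inverse(jac.T @ jac)

    x0v, y0v, dv, av = np.exp(theta_hat)
    return FittedCML(
        params=CMLParams(x0=x0v, y0=y0v, d_tki=dv, a_act=av, n_ref=n_ref),
        covariance=cov,
        residual_sd=float(sigma_hat),
        dof=dof,
        n_obs=len(obs),
        n_censored=int(cens.sum()) if censoring == "likelihood" else sum(o.below_lod for o in obs),
        converged=bool(success),
        objective=float(objective),
    )


def _numerical_jacobian(f, x, eps=1e-6):
    f0 = np.asarray(f(x))
    jac = np.empty((len(f0), len(x)))
    for j in range(len(x)):
        dx = np.zeros_like(x)
        dx[j] = eps * max(1.0, abs(x[j]))
        jac[:, j] = (np.asarray(f(x + dx)) - np.asarray(f(x - dx))) / (2 * dx[j])
    return jac


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            hi = np.zeros(n)
            hj = np.zeros(n)
            hi[i] = eps * max(1.0, abs(x[i]))
            hj[j] = eps * max(1.0, abs(x[j]))
            fpp = f(x + hi + hj)
            fpm = f(x + hi - hj)
            fmp = f(x - hi + hj)
            fmm = f(x - hi - hj)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi[i] * hj[j])
    return hess


def _robust_inverse(mat, ridge=1e-10):
    """Pseudo-inverse with a tiny ridge; near-singular information matrices
    arise when a parameter is weakly identified and then get wide variances
    rather than crashing the fit."""
    mat = 0.5 * (mat + mat.T)
    n = mat.shape[0]
    scale = max(np.trace(mat) / n, 1e-12)
    try:
        inv = np.linalg.inv(mat + ridge * scale * np.eye(n))
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(mat)
    inv = 0.5 * (inv + inv.T)
    # clip negative eigenvalues that can appear through numerical error
    w, v = np.linalg.eigh(inv)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionBand:
    """Pointwise confidence band for the BCR-ABL1 % trajectory."""

    times: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self):
        if not np.all((self.lower <= self.central + 1e-12) & (self.central <= self.upper + 1e-12)):
            raise ValidationError("band ordering violated: need lower <= central <= upper")

    def to_json(self) -> dict:
        return {
            "times_days": self.times.tolist(),
            "central_pct": self.central.tolist(),
            "lower_pct": self.lower.tolist(),
            "upper_pct": self.upper.tolist(),
            "level": self.level,
        }


def predict_cml(
    fitted: FittedCML,
    horizon_days: float,
    level: float = 0.95,
    times: Optional[Sequence[float]] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PredictionBand:
    """Central prediction and pointwise confidence band.

    The band is a seeded parametric bootstrap: parameter vectors are drawn
    on the log scale from the fit's local Gaussian approximation, with the
    residual variance drawn from its scaled inverse-chi-square distribution
    (``dof`` degrees of freedom) so that small-sample uncertainty in sigma
    widens the band the way a t-interval would.  The band is symmetrized on
    the log10 scale: its half-width at each time is the ``level`` quantile
    of the absolute deviations of the bootstrap trajectories from the
    central one.  (The raw bootstrap quantiles are noticeably skewed at
    extrapolation times while the estimation error itself is symmetric on
    the log scale, so percentile bands undercover on one side.)
    """
    if not fitted.converged:
        raise ValidationError("cannot predict from a non-converged fit")
    if not (0 < level < 1):
        raise ValidationError("confidence level must lie in (0, 1)")
    if times is None:
        times = np.linspace(0.0, float(horizon_days), 181)
    times = np.asarray(times, dtype=float)

    central = simulate_cml(fitted.params, times)

    rng = np.random.default_rng(seed)
    theta_hat = np.log([fitted.params.x0, fitted.params.y0, fitted.params.d_tki, fitted.params.a_act])
    dof = max(fitted.dof, 1)
    # sigma^2_b / sigma^2_hat ~ dof / chi2_dof; scales the covariance draw-wise
    scale = dof / rng.chisquare(dof, size=n_boot)
    # eigendecomposition square root: covariances from weakly identified
    # fits can be singular after eigenvalue clipping
    w, v = np.linalg.eigh(fitted.covariance)
    sqrt_cov = v * np.sqrt(np.clip(w, 0.0, None))
    draws = theta_hat + (rng.standard_normal((n_boot, 4)) @ sqrt_cov.T) * np.sqrt(scale)[:, None]
    # weakly identified directions can throw draws far outside biological
    # plausibility; keep them inside the same box the fit searched
    draws = np.clip(draws, _THETA_LO, _THETA_HI)

    x0, y0, d, a = (np.exp(draws[:, j])[:, None] for j in range(4))
    t = times[None, :]
    near = np.abs(d - a) < _DEGENERATE_TOL
    denom = np.where(near, 1.0, d - a)
    x = x0 * np.exp(-d * t) + np.where(
        near,
        a * y0 * t * np.exp(-d * t),
        a * y0 * (np.exp(-a * t) - np.exp(-d * t)) / denom,
    )
    m_boot = np.log10(np.maximum(ratio_pct(x, fitted.params.n_ref), 1e-12))
    m_hat = np.log10(np.maximum(central, 1e-12))

    half_width = np.quantile(np.abs(m_boot - m_hat[None, :]), level, axis=0)
    lower = 10.0 ** (m_hat - half_width)
    upper = np.minimum(10.0 ** (m_hat + half_width), 100.0)
    return PredictionBand(
        times=times,
        central=central,
        lower=np.minimum(lower, central),
        upper=np.maximum(upper, central),
        level=level,
    )


@dataclass
class LSCTrajectory:
    """Latent quiescent leukaemic stem-cell pool relative to baseline."""

    times: np.ndarray
    fraction: np.ndarray  # Y(t)/Y(0), in [0, 1]
    identified: bool  # False when the fit found no latent pool (y0 == 0)

    def to_json(self) -> dict:
        return {
            "times_days": self.times.tolist(),
            "fraction_of_baseline": self.fraction.tolist(),
            "identified": self.identified,
        }


def predict_lsc(
    fitted: FittedCML, horizon_days: float, times: Optional[Sequence[float]] = None
) -> LSCTrajectory:
    """Predicted decline of the TKI-protected stem-cell pool, Y(t)/Y(0)."""
    if not fitted.converged:
        raise ValidationError("cannot predict from a non-converged fit")
    if times is None:
        times = np.linspace(0.0, float(horizon_days), 181)
    times = np.asarray(times, dtype=float)
    if fitted.params.y0 <= 0:
        return LSCTrajectory(times=times, fraction=np.zeros_like(times), identified=False)
    return LSCTrajectory(
        times=times, fraction=latent_fraction(fitted.params, times), identified=True
    )
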