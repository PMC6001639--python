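"""Nested Laplace approximate Bayesian inference for NMA latent Gaussian models.

The model is a three-stage latent Gaussian model: an arm-based likelihood, a
jointly Gaussian latent field alpha = (mu, d, beta, gamma, omega) given the
hyperparameters Psi = (tau^2, kappa^2), and uniform hyperpriors on the
standard-deviation scale.  Inference proceeds by

1. a Gaussian (Laplace) approximation of p(alpha | Psi, y) at each fixed Psi,
   obtained by Newton optimization of the latent log posterior;
2. the Laplace approximation of the hyperparameter posterior,
   p~(Psi | y) ∝ p(y | a*) p(a* | Psi) p(Psi) / p~_G(a* | Psi, y)
   evaluated at the conditional mode a*(Psi);
3. numerical integration over a set of hyperparameter points (a dense grid in
   standardized coordinates, or a central composite design) to produce the
   posterior marginals of each latent parameter as mixtures of Gaussian
   conditionals, and the marginals of tau and kappa themselves.

Internally the engine works on the log-variance scale theta = log(sd^2) with
the exact Jacobian applied to the uniform-on-sd hyperpriors; this keeps the
optimization unconstrained and well conditioned.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize

from .data import (
    DesignCatalog,
    LatentLayout,
    NetworkTable,
    build_layout,
    contrast_coefficients,
    enumerate_designs,
)
from .model import (
    HyperParams,
    ModelSpec,
    PredictorAssembly,
    build_assembly,
    latent_prior_precision,
    log_prior_hyper,
)

__all__ = [
    "MarginalDensity",
    "GaussianApprox",
    "HyperGrid",
    "HyperMode",
    "DICResult",
    "FitResult",
    "LaplaceEngine",
    "gaussian_approximation",
    "optimize_hyper",
    "explore_hyper",
    "latent_marginal",
    "hyper_marginal",
    "dic",
    "fit",
]

_LOG2PI = math.log(2.0 * math.pi)

# 20-point Gauss-Hermite rule against the standard normal weight
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(20)
_GH_W = _GH_W / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# gridded univariate posterior


@dataclass
class MarginalDensity:
    """A univariate posterior density on a grid, with summary functionals."""

    x: np.ndarray
    pdf: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.pdf = np.clip(np.asarray(self.pdf, dtype=float), 0.0, None)
        z = np.trapezoid(self.pdf, self.x)
        if not np.isfinite(z) or z <= 0:
            raise ValueError("density does not integrate to a positive value")
        self.pdf = self.pdf / z
        dx = np.diff(self.x)
        mids = 0.5 * (self.pdf[1:] + self.pdf[:-1])
        self._cdf = np.concatenate([[0.0], np.cumsum(mids * dx)])
        self._cdf /= self._cdf[-1]

    @classmethod
    def from_mixture(
        cls,
        means: Sequence[float],
        sds: Sequence[float],
        weights: Sequence[float],
        span: float = 6.0,
        points: int = 401,
    ) -> "MarginalDensity":
        """Mixture of normals, tabulated over the union of component ranges."""
        m = np.asarray(means, dtype=float)
        s = np.asarray(sds, dtype=float)
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        keep = w > 1e-12
        m, s, w = m[keep], s[keep], w[keep]
        lo = float(np.min(m - span * s))
        hi = float(np.max(m + span * s))
        x = np.linspace(lo, hi, points)
        z = (x[:, None] - m[None, :]) / s[None, :]
        pdf = (np.exp(-0.5 * z**2) / (s[None, :] * math.sqrt(2 * math.pi))) @ w
        return cls(x, pdf)

    def integral(self) -> float:
        return float(np.trapezoid(self.pdf, self.x))

    def mean(self) -> float:
        return float(np.trapezoid(self.x * self.pdf, self.x))

    def sd(self) -> float:
        m = self.mean()
        v = float(np.trapezoid((self.x - m) ** 2 * self.pdf, self.x))
        return math.sqrt(max(v, 0.0))

    def quantile(self, p: float) -> float:
        """Inverse CDF by interpolation on the tabulated density grid."""
        cdf, x = self._cdf, self.x
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        return float(np.interp(p, cdf[keep], x[keep]))

    def median(self) -> float:
        return self.quantile(0.5)

    def summary(self) -> dict[str, float]:
        return {
            "mean": self.mean(),
            "sd": self.sd(),
            "q2.5": self.quantile(0.025),
            "median": self.median(),
            "q97.5": self.quantile(0.975),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.x, "density": self.pdf})


# ---------------------------------------------------------------------------
# Gaussian approximation of the latent field at fixed hyperparameters


@dataclass
class GaussianApprox:
    """Mode and curvature of the latent field at one hyperparameter point.

    ``log_density`` is the (unnormalized) Laplace approximation of the
    hyperparameter log posterior log p~(Psi | y) at this point.  ``mean``
    carries a third-order skewness correction of the conditional mean (the
    first-order content of the simplified Laplace approximation); it equals
    the mode exactly for the normal family.
    """

    hp: HyperParams
    theta: tuple[float, ...]
    mode: np.ndarray
    mean_shift: np.ndarray
    chol: tuple  # cho_factor of the posterior precision at the mode
    log_density: float
    eta_mode: np.ndarray
    eta_var: np.ndarray  # conditional variance of each arm's linear predictor
    n_iter: int
    grad_norm: float
    _cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean(self) -> np.ndarray:
        return self.mode + self.mean_shift

    @property
    def cov(self) -> np.ndarray:
        if self._cov is None:
            self._cov = cho_solve(self.chol, np.eye(len(self.mode)))
        return self._cov

    def marginal_sd(self, slot: int) -> float:
        return math.sqrt(self.cov[slot, slot])


@dataclass
class HyperMode:
    """Posterior mode of the hyperparameters on the internal log-variance scale."""

    theta: np.ndarray
    hessian: np.ndarray  # negative Hessian of the log density (precision)
    names: tuple[str, ...]

    @property
    def cov(self) -> np.ndarray:
        return np.linalg.inv(self.hessian)

    @property
    def sds(self) -> dict[str, float]:
        return {n: math.exp(t / 2.0) for n, t in zip(self.names, self.theta)}


@dataclass
class HyperGrid:
    """Integration points with weights for the hyperparameter posterior."""

    thetas: np.ndarray  # (J, q)
    logdens: np.ndarray  # (J,) unnormalized log p~(theta | y)
    volumes: np.ndarray  # (J,) quadrature volumes Delta_j
    weights: np.ndarray  # (J,) normalized: sum(weights) == 1
    strategy: str
    mode: np.ndarray
    hessian: np.ndarray
    axes: list[np.ndarray] | None = None  # grid strategy only
    idx: np.ndarray | None = None  # (J, q) integer axis indices

    @property
    def n_points(self) -> int:
        return len(self.weights)

    @property
    def density(self) -> np.ndarray:
        """Normalized density values: sum(density * volumes) == 1."""
        return self.weights / self.volumes


@dataclass
class DICResult:
    dic: float
    pd: float
    mean_deviance: float
    deviance_at_mean: float
    convention: str


# ---------------------------------------------------------------------------
# engine


class LaplaceEngine:
    """Nested-Laplace inference for one model spec on one network."""

    def __init__(self, spec: ModelSpec, net: NetworkTable):
        self.spec = spec
        self.dropped_trials: list[str] = []
        if spec.model_kind.startswith("metareg"):
            net, self.dropped_trials = net.subset_with_covariate()
        self.net = net
        self.cat = enumerate_designs(net)
        # kappa pinned at zero degenerates omega at 0: drop the slots
        kind = spec.model_kind
        if spec.fixed_kappa == 0.0:
            kind = {
                "jackson": "consistency",
                "metareg-jackson": "metareg-consistency",
            }.get(kind, kind)
        self.layout = build_layout(net, self.cat, kind, spec.reference)
        self.asm = build_assembly(net, self.cat, self.layout)
        self.hyper_names: tuple[str, ...] = tuple(
            n
            for n, present in (("tau", spec.has_tau), ("kappa", spec.has_free_kappa))
            if present
        )
        self._cache: dict[tuple[float, ...], GaussianApprox] = {}
        self._warm: np.ndarray | None = None

    # -- hyperparameter packing ------------------------------------------

    def hp_from_theta(self, theta: Sequence[float]) -> HyperParams:
        vals = dict(zip(self.hyper_names, theta))
        tau = math.exp(vals["tau"] / 2.0) if "tau" in vals else 0.0
        if "kappa" in vals:
            kappa = math.exp(vals["kappa"] / 2.0)
        else:
            kappa = self.spec.fixed_kappa
        return HyperParams(tau=tau, kappa=kappa)

    def theta_from_hp(self, hp: HyperParams) -> tuple[float, ...]:
        out = []
        for n in self.hyper_names:
            sd = hp.tau if n == "tau" else hp.kappa
            if sd is None or sd <= 0:
                raise ValueError(f"{n} must be positive on the internal scale")
            out.append(2.0 * math.log(sd))
        return tuple(out)

    def _log_prior_theta(self, theta: Sequence[float]) -> float:
        """Hyperprior density on the log-variance scale (uniform-on-sd + Jacobian)."""
        hp = self.hp_from_theta(theta)
        lp = log_prior_hyper(hp, self.spec)
        if not math.isfinite(lp):
            return -math.inf
        # d sd / d theta = exp(theta/2) / 2
        for t in theta:
            lp += t / 2.0 - math.log(2.0)
        return lp

    # -- Gaussian approximation ------------------------------------------

    def gaussian_approximation(
        self,
        hp: HyperParams | None = None,
        start: np.ndarray | None = None,
        theta: Sequence[float] | None = None,
        grad_tol: float = 1e-8,
        max_iter: int = 100,
    ) -> GaussianApprox:
        """Newton optimization of the latent log posterior at fixed hyperparameters."""
        if theta is None:
            theta = self.theta_from_hp(hp) if self.hyper_names else ()
        theta = tuple(float(t) for t in theta)
        hp = self.hp_from_theta(theta)
        lp_theta = self._log_prior_theta(theta) if self.hyper_names else 0.0
        if not math.isfinite(lp_theta):
            raise ValueError("hyperparameters outside the prior support")

        Q, logdet_cov = latent_prior_precision(self.layout, self.spec, hp)
        X = self.asm.X
        alpha = np.array(
            start
            if start is not None
            else (self._warm if self._warm is not None else np.zeros(self.layout.dim)),
            dtype=float,
        )

        def objective(a: np.ndarray) -> float:
            return self.asm.loglik(X @ a) - 0.5 * float(a @ Q @ a)

        f = objective(alpha)
        trace: list[float] = []
        gnorm = math.inf
        chol = None
        for it in range(max_iter):
            eta = X @ alpha
            g, w = self.asm.grad_hess(eta)
            grad = X.T @ g - Q @ alpha
            gnorm = float(np.linalg.norm(grad))
            trace.append(gnorm)
            Qpost = X.T @ (w[:, None] * X) + Q
            chol = cho_factor(Qpost, lower=True)
            if gnorm < grad_tol:
                break
            step = cho_solve(chol, grad)
            t = 1.0
            while t > 1e-6:
                cand = alpha + t * step
                fc = objective(cand)
                if fc >= f - 1e-12 * max(1.0, abs(f)):
                    alpha, f = cand, fc
                    break
                t *= 0.5
            else:
                raise RuntimeError(
                    f"line search failed at iteration {it}; gradient trace {trace}"
                )
        else:
            raise RuntimeError(
                f"Newton did not converge in {max_iter} iterations; "
                f"gradient trace tail {trace[-5:]}"
            )

        logdet_qpost = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        quad = float(alpha @ Q @ alpha)
        eta = X @ alpha
        # log p~(theta|y) = loglik + log p(alpha*|theta) + log p(theta)
        #                   - log p~_G(alpha*|theta,y)
        log_density = (
            self.asm.loglik(eta)
            - 0.5 * (quad + logdet_cov)
            + lp_theta
            - 0.5 * logdet_qpost
        )
        # skewness correction of the conditional mean:
        # E[alpha] ~ mode + 1/2 Sigma X' (l'''(eta) * var(eta))
        S = cho_solve(chol, X.T)  # Sigma @ X'
        eta_var = np.einsum("ij,ji->i", X, S)
        d3 = self.asm.third_deriv(eta)
        mean_shift = 0.5 * (S @ (d3 * eta_var))
        self._warm = alpha.copy()
        return GaussianApprox(
            hp=hp,
            theta=theta,
            mode=alpha,
            mean_shift=mean_shift,
            chol=chol,
            log_density=log_density,
            eta_mode=eta,
            eta_var=eta_var,
            n_iter=it,
            grad_norm=gnorm,
        )

    def approx_at(self, theta: Sequence[float]) -> GaussianApprox:
        key = tuple(round(float(t), 12) for t in theta)
        ap = self._cache.get(key)
        if ap is None:
            ap = self.gaussian_approximation(theta=key)
            self._cache[key] = ap
        return ap

    def log_posterior_hyper(self, theta: Sequence[float]) -> float:
        hp = self.hp_from_theta(theta)
        if not math.isfinite(log_prior_hyper(hp, self.spec)):
            return -math.inf
        return self.approx_at(theta).log_density

    # -- hyperparameter mode ---------------------------------------------

    def optimize_hyper(
        self, start: HyperParams | None = None, fd_step: float = 0.02
    ) -> HyperMode:
        """Locate the mode of the Laplace hyperposterior on the internal scale."""
        if not self.hyper_names:
            raise ValueError("the fixed-effect model has no hyperparameters")
        if start is not None:
            x0 = np.array(self.theta_from_hp(start))
        else:
            x0 = []
            for n in self.hyper_names:
                lo, hi = self.spec.tau_prior if n == "tau" else self.spec.kappa_prior
                sd0 = min(max(0.3, lo + 0.02 * (hi - lo)), lo + 0.5 * (hi - lo))
                x0.append(2.0 * math.log(sd0))
            x0 = np.array(x0)

        def neg(th: np.ndarray) -> float:
            v = self.log_posterior_hyper(th)
            return 1e12 if not math.isfinite(v) else -v

        res = minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-6, "maxiter": 400},
        )
        if not res.success and not math.isfinite(-res.fun):
            raise RuntimeError(f"hyperparameter optimization failed: {res.message}")
        theta = np.asarray(res.x, dtype=float)

        q = len(theta)
        H = np.zeros((q, q))
        f0 = -neg(theta)
        h = fd_step
        for i in range(q):
            ei = np.zeros(q)
            ei[i] = h
            fp, fm = -neg(theta + ei), -neg(theta - ei)
            H[i, i] = -(fp - 2.0 * f0 + fm) / h**2
            for j in range(i + 1, q):
                ej = np.zeros(q)
                ej[j] = h
                fpp = -neg(theta + ei + ej)
                fpm = -neg(theta + ei - ej)
                fmp = -neg(theta - ei + ej)
                fmm = -neg(theta - ei - ej)
                H[i, j] = H[j, i] = -(fpp - fpm - fmp + fmm) / (4.0 * h**2)
        # guard against indefinite finite-difference curvature
        vals, vecs = eigh(H)
        vals = np.clip(vals, 1e-6, None)
        H = vecs @ np.diag(vals) @ vecs.T
        return HyperMode(theta=theta, hessian=H, names=self.hyper_names)

    # -- fitting -----------------------------------------------------------

    def explore(self, mode: HyperMode, strategy: str = "grid", **kw) -> HyperGrid:
        return explore_hyper(
            self.log_posterior_hyper, mode.theta, mode.hessian, strategy=strategy, **kw
        )

    def grid_approxs(self, grid: HyperGrid) -> list[GaussianApprox]:
        return [self.approx_at(th) for th in grid.thetas]

    def fit(
        self,
        strategy: str = "grid",
        deviance: str = "loglik",
        laplace_marginals: bool = False,
        grid_step: float = 0.5,
        drop: float = 6.0,
        seed: int | None = None,
    ) -> "FitResult":
        t0 = time.perf_counter()
        if not self.hyper_names:
            ap = self.gaussian_approximation(theta=())
            approxs, weights = [ap], np.array([1.0])
            grid = None
            hyper_mode = None
            hyper_marg: dict[str, MarginalDensity] = {}
        else:
            hyper_mode = self.optimize_hyper()
            grid = self.explore(hyper_mode, strategy="grid", step=grid_step, drop=drop)
            mix_grid = (
                grid
                if strategy == "grid"
                else self.explore(hyper_mode, strategy="ccd")
            )
            approxs = self.grid_approxs(mix_grid)
            weights = mix_grid.weights
            hyper_marg = {
                name: hyper_marginal(name, grid, self) for name in self.hyper_names
            }

        marginals: dict[str, MarginalDensity] = {}
        modes = np.array([ap.mean for ap in approxs])
        sds = np.array(
            [np.sqrt(np.diag(ap.cov)) for ap in approxs]
        )  # (J, dim)
        for i, name in enumerate(self.layout.names):
            marginals[name] = MarginalDensity.from_mixture(
                modes[:, i], sds[:, i], weights
            )
        if laplace_marginals:
            for t, slot in self.layout.d_index.items():
                marginals[self.layout.names[slot]] = self._slot_laplace_marginal(
                    slot, approxs, weights
                )
            if self.layout.beta_index is not None:
                slot = self.layout.beta_index
                marginals[self.layout.names[slot]] = self._slot_laplace_marginal(
                    slot, approxs, weights
                )
        marginals.update(hyper_marg)

        dic_res = dic(self.asm, approxs, weights, convention=deviance)

        rows = []
        for name in list(self.layout.names) + list(self.hyper_names):
            s = marginals[name].summary()
            rows.append({"parameter": name, **s})
        summaries = pd.DataFrame(rows)

        manifest = {
            "model": self.spec.to_dict(),
            "engine": "laplace",
            "strategy": strategy,
            "deviance_convention": deviance,
            "laplace_marginals": laplace_marginals,
            "grid_step": grid_step,
            "log_density_drop": drop,
            "n_trials": self.net.n_studies,
            "n_treatments": self.net.n_treatments,
            "n_designs": self.cat.n_designs,
            "latent_dim": self.layout.dim,
            "dropped_trials": self.dropped_trials,
            "hyper_mode_sd": hyper_mode.sds if hyper_mode else None,
            "n_integration_points": len(approxs),
            "seed": seed,
            "runtime_s": None,
        }
        res = FitResult(
            spec=self.spec,
            layout=self.layout,
            summaries=summaries,
            marginals=marginals,
            dic=dic_res,
            hyper_mode=hyper_mode,
            manifest=manifest,
            _approxs=approxs,
            _weights=weights,
        )
        manifest["runtime_s"] = round(time.perf_counter() - t0, 3)
        return res

    # -- per-slot nested Laplace marginal (optional correction) -----------

    def _slot_laplace_marginal(
        self,
        slot: int,
        approxs: list[GaussianApprox],
        weights: np.ndarray,
        n_values: int = 11,
        span: float = 4.0,
    ) -> MarginalDensity:
        """Recompute one latent marginal by a nested Laplace profile.

        For each integration point, the conditional density of the slot is
        profiled: the remaining latents are re-optimized with the slot fixed
        at each value of a grid, and the Laplace-corrected conditional density
        is normalized over that grid before mixing.
        """
        mix_mean = float(np.sum(weights * np.array([a.mode[slot] for a in approxs])))
        mix_sd = math.sqrt(
            float(
                np.sum(
                    weights
                    * np.array(
                        [a.cov[slot, slot] + a.mode[slot] ** 2 for a in approxs]
                    )
                )
            )
            - mix_mean**2
        )
        values = np.linspace(mix_mean - span * mix_sd, mix_mean + span * mix_sd, n_values)
        rest = np.array([i for i in range(self.layout.dim) if i != slot])
        X = self.asm.X
        Xr, xi = X[:, rest], X[:, slot]

        dens = np.zeros_like(values)
        for ap, w in zip(approxs, weights):
            if w < 1e-6:
                continue
            Q, _ = latent_prior_precision(self.layout, self.spec, ap.hp)
            Qrr = Q[np.ix_(rest, rest)]
            Qri = Q[rest, slot]
            logd = np.empty_like(values)
            a_r = ap.mode[rest].copy()
            for k, x in enumerate(values):
                for _ in range(50):
                    eta = Xr @ a_r + xi * x
                    g, wgt = self.asm.grad_hess(eta)
                    grad = Xr.T @ g - Qrr @ a_r - Qri * x
                    Qp = Xr.T @ (wgt[:, None] * Xr) + Qrr
                    ch = cho_factor(Qp, lower=True)
                    if np.linalg.norm(grad) < 1e-8:
                        break
                    a_r = a_r + cho_solve(ch, grad)
                eta = Xr @ a_r + xi * x
                full = np.empty(self.layout.dim)
                full[rest], full[slot] = a_r, x
                quad = float(full @ Q @ full)
                logd[k] = (
                    self.asm.loglik(eta)
                    - 0.5 * quad
                    - float(np.sum(np.log(np.diag(ch[0]))))
                )
            logd -= logd.max()
            p = np.exp(logd)
            p /= np.trapezoid(p, values)
            dens += w * p
        return MarginalDensity(values, dens)


# ---------------------------------------------------------------------------
# free functions (thin wrappers and reusable numerics)


def gaussian_approximation(
    spec: ModelSpec,
    net: NetworkTable,
    hp: HyperParams | None = None,
    start: np.ndarray | None = None,
) -> GaussianApprox:
    """Gaussian approximation of the latent field at fixed hyperparameters."""
    return LaplaceEngine(spec, net).gaussian_approximation(hp=hp, start=start)


def optimize_hyper(spec: ModelSpec, net: NetworkTable) -> HyperMode:
    """Mode and curvature of the Laplace hyperposterior (log-variance scale)."""
    return LaplaceEngine(spec, net).optimize_hyper()


def explore_hyper(
    logdens: Callable[[np.ndarray], float],
    mode: np.ndarray,
    hessian: np.ndarray,
    strategy: str = "grid",
    step: float = 0.5,
    drop: float = 6.0,
    max_steps: int = 25,
    ccd_scale: float = 1.65,
) -> HyperGrid:
    """Integration points for the hyperparameter posterior.

    ``grid``: an axis-aligned dense grid in coordinates standardized by the
    marginal standard deviations of the Gaussian approximation at the mode;
    each axis extends until the log density falls more than ``drop`` below
    the mode (capped at ``max_steps`` steps, with a warning).

    ``ccd``: a central composite design — the center plus satellites on a
    sphere of radius ``ccd_scale * sqrt(q)`` in fully standardized
    coordinates, with weights matched so that a Gaussian density would be
    integrated with exact mean and covariance.
    """
    mode = np.atleast_1d(np.asarray(mode, dtype=float))
    q = len(mode)
    hessian = np.atleast_2d(np.asarray(hessian, dtype=float))
    cov = np.linalg.inv(hessian)
    f0 = logdens(mode)

    if strategy == "grid":
        sds = np.sqrt(np.diag(cov))
        axes_offsets: list[np.ndarray] = []
        for k in range(q):
            h = step * sds[k]
            offs = [0.0]
            for direction in (+1.0, -1.0):
                for j in range(1, max_steps + 1):
                    th = mode.copy()
                    th[k] += direction * j * h
                    if f0 - logdens(th) > drop:
                        break
                    offs.append(direction * j * h)
                else:
                    warnings.warn(
                        "hyper grid extent capped before reaching the requested "
                        "log-density drop; the density may be very flat",
                        UserWarning,
                        stacklevel=2,
                    )
            axes_offsets.append(np.array(sorted(offs)))
        axes = [mode[k] + axes_offsets[k] for k in range(q)]
        mesh = np.meshgrid(*axes, indexing="ij")
        thetas = np.stack([m.ravel() for m in mesh], axis=1)
        idx_mesh = np.meshgrid(*[np.arange(len(a)) for a in axes], indexing="ij")
        idx = np.stack([m.ravel() for m in idx_mesh], axis=1)
        ld = np.array([logdens(t) for t in thetas])
        vol = float(np.prod([step * s for s in sds]))
        volumes = np.full(len(thetas), vol)
    elif strategy == "ccd":
        vals, vecs = eigh(cov)
        M = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
        r = ccd_scale * math.sqrt(q)
        zs = [np.zeros(q)]
        if q == 1:
            zs += [np.array([r]), np.array([-r])]
        else:
            for k in range(q):
                for s in (+1.0, -1.0):
                    z = np.zeros(q)
                    z[k] = s * r
                    zs.append(z)
            from itertools import product

            for signs in product((+1.0, -1.0), repeat=q):
                zs.append(np.array(signs) * r / math.sqrt(q))
        m = len(zs) - 1
        det_m = abs(np.linalg.det(M))
        w0 = (2 * math.pi) ** (q / 2.0) * (1.0 - q / r**2) * det_m
        ws = (2 * math.pi) ** (q / 2.0) * math.exp(r**2 / 2.0) * q / (m * r**2) * det_m
        thetas = np.array([mode + M @ z for z in zs])
        volumes = np.array([w0] + [ws] * m)
        ld = np.array([logdens(t) for t in thetas])
        axes = None
        idx = None
    else:
        raise ValueError(f"unknown exploration strategy {strategy!r}")

    lw = ld + np.log(volumes)
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    return HyperGrid(
        thetas=thetas,
        logdens=ld,
        volumes=volumes,
        weights=w,
        strategy=strategy,
        mode=mode,
        hessian=hessian,
        axes=axes,
        idx=idx,
    )


def latent_marginal(
    slot: int, grid: HyperGrid, approxs: Sequence[GaussianApprox]
) -> MarginalDensity:
    """Posterior marginal of one latent slot: mixture of Gaussian conditionals."""
    means = [ap.mean[slot] for ap in approxs]
    sds = [ap.marginal_sd(slot) for ap in approxs]
    return MarginalDensity.from_mixture(means, sds, grid.weights)


def hyper_marginal(
    which: str, grid: HyperGrid, engine: "LaplaceEngine"
) -> MarginalDensity:
    """1-D posterior of tau or kappa on the sd scale, from a dense grid.

    Weights are summed over the other hyperparameter axis, the axis profile is
    interpolated on the internal (log-variance) scale and transformed to the
    standard-deviation scale with the exact Jacobian.
    """
    if grid.strategy != "grid":
        raise ValueError("hyper marginals require the dense-grid strategy")
    names = engine.hyper_names
    if which not in names:
        raise KeyError(f"{which!r} is not a free hyperparameter of this model")
    axis = names.index(which)
    nodes = grid.axes[axis]
    h = nodes[1] - nodes[0] if len(nodes) > 1 else 1.0
    wsum = np.zeros(len(nodes))
    np.add.at(wsum, grid.idx[:, axis], grid.weights)

    keep = wsum > wsum.max() * 1e-12
    nodes_k, w_k = nodes[keep], wsum[keep]
    if len(nodes_k) < 4:
        # nearly degenerate axis: fall back to the Gaussian approximation
        sd_t = math.sqrt(np.linalg.inv(grid.hessian)[axis, axis])
        c = float(grid.mode[axis])
        tf = np.linspace(c - 5 * sd_t, c + 5 * sd_t, 400)
        p_t = np.exp(-0.5 * ((tf - c) / sd_t) ** 2)
    else:
        spline = CubicSpline(nodes_k, np.log(w_k / h))
        tf = np.linspace(nodes_k[0], nodes_k[-1], 600)
        p_t = np.exp(spline(tf))
    sd = np.exp(tf / 2.0)
    pdf = p_t * 2.0 / sd  # d theta / d sd = 2 / sd
    return MarginalDensity(sd, pdf)


def dic(
    asm: PredictorAssembly,
    approxs: Sequence[GaussianApprox],
    weights: np.ndarray,
    convention: str = "loglik",
) -> DICResult:
    """Deviance information criterion from the mixture posterior approximation.

    The posterior mean deviance is computed deterministically: under each
    integration point the linear predictor of every arm is Gaussian, so the
    expected per-arm deviance is a 1-D Gauss-Hermite quadrature; the mixture
    weights then average over hyperparameter points.  pD is the mean deviance
    minus the deviance at the posterior mean of the latent field.
    """
    weights = np.asarray(weights, dtype=float)
    dbar = 0.0
    for ap, w in zip(approxs, weights):
        if w < 1e-12:
            continue
        m = asm.X @ ap.mean
        s = np.sqrt(np.clip(ap.eta_var, 0.0, None))
        etas = m[None, :] + _GH_X[:, None] * s[None, :]  # (20, N)
        terms = asm.loglik_terms(etas)
        dbar += w * float(-2.0 * (_GH_W @ terms.sum(axis=1)))
    alpha_bar = np.sum(
        weights[:, None] * np.array([ap.mean for ap in approxs]), axis=0
    )
    dhat = -2.0 * asm.loglik(asm.X @ alpha_bar)
    if convention == "saturated":
        sat = 2.0 * asm.saturated_loglik()
        dbar += sat
        dhat += sat
    elif convention != "loglik":
        raise ValueError(f"unknown deviance convention {convention!r}")
    p_d = dbar - dhat
    return DICResult(
        dic=dbar + p_d,
        pd=p_d,
        mean_deviance=dbar,
        deviance_at_mean=dhat,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Posterior summaries, marginals and model fit statistics of one model."""

    spec: ModelSpec
    layout: LatentLayout
    summaries: pd.DataFrame
    marginals: dict[str, MarginalDensity]
    dic: DICResult
    hyper_mode: HyperMode | None
    manifest: dict
    _approxs: list[GaussianApprox] = field(default_factory=list, repr=False)
    _weights: np.ndarray | None = field(default=None, repr=False)

    def parameter(self, name: str) -> MarginalDensity:
        return self.marginals[name]

    def basic_parameters(self) -> pd.DataFrame:
        mask = self.summaries["parameter"].str.startswith("d[")
        return self.summaries[mask].reset_index(drop=True)

    def contrast(self, t1: int, tk: int) -> MarginalDensity:
        """Posterior of a functional relative effect d[t1, tk].

        Built from the joint Gaussian conditionals, so linear-combination
        summaries are consistent with the basic-parameter summaries by
        construction.
        """
        c = contrast_coefficients(t1, tk, self.layout)
        means = [float(c @ ap.mean) for ap in self._approxs]
        sds = [math.sqrt(float(c @ ap.cov @ c)) for ap in self._approxs]
        return MarginalDensity.from_mixture(means, sds, self._weights)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out / "summary.csv", index=False)
        marg = out / "marginals"
        marg.mkdir(exist_ok=True)
        for name, md in self.marginals.items():
            safe = name.replace("[", "_").replace("]", "").replace(":", "_").replace(",", "_")
            md.to_frame().to_csv(marg / f"{safe}.csv", index=False)
        with open(out / "dic.txt", "w") as fh:
            fh.write(
                f"DIC {self.dic.dic:.4f}\npD {self.dic.pd:.4f}\n"
                f"mean_deviance {self.dic.mean_deviance:.4f}\n"
                f"convention {self.dic.convention}\n"
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def fit(spec: ModelSpec, net: NetworkTable, **options) -> FitResult:
    """Fit an NMA model by nested Laplace approximation.

    The fixed-effect kind uses a single Gaussian approximation (no
    hyperparameter integration); all other kinds run the full pipeline.
    Deterministic: repeated fits produce identical summaries.
    """
    return LaplaceEngine(spec, net).fit(**options)
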