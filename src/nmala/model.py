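"""GLMM assembly for contrast-based network meta-analysis.

The linear predictor of a non-baseline arm of trial *i* comparing treatment
``t_k`` against the trial baseline ``t_1`` is

    eta = mu_i + d[t_1, t_k] + gamma[i, t_1 t_k] + omega[D(i), t_1 t_k]
          + (x_i - xbar) * beta

where the heterogeneity effects ``gamma`` of a trial and the inconsistency
effects ``omega`` of a design follow zero-mean multivariate normals with the
homogeneous compound-symmetric covariance (diagonal tau^2 resp. kappa^2,
off-diagonal tau^2/2 resp. kappa^2/2).  Baseline arms carry ``eta = mu_i``.
Relative effects are parametrized through basic parameters ``d[ref, t]``
against a reference treatment; other contrasts are linear combinations.

The likelihood is arm-based: binomial with logit link, normal with identity
link (arm mean with known standard error sd/sqrt(n)), or Poisson with log
link and an exposure offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

from .data import (
    ConfigurationError,
    DesignCatalog,
    LatentLayout,
    NetworkTable,
    contrast_coefficients,
    MODEL_KINDS,
)

__all__ = [
    "ModelSpec",
    "HyperParams",
    "PredictorAssembly",
    "cs_covariance",
    "cs_precision",
    "cs_decompose",
    "CSDecomposition",
    "build_assembly",
    "linear_predictor",
    "log_likelihood",
    "log_prior_latent",
    "log_prior_hyper",
    "latent_prior_precision",
]


@dataclass(frozen=True)
class ModelSpec:
    """Model kind, endpoint family, reference treatment and priors.

    ``prior_fixed_sd`` is the standard deviation of the independent zero-mean
    normal priors on all fixed-effect latents (mu, d, beta); the default
    sqrt(1000) corresponds to a variance of 1000.  Hyperpriors are uniform on
    the standard-deviation scale, U[0, 5] by default for both the
    heterogeneity tau and the inconsistency kappa.  ``fixed_kappa`` pins the
    inconsistency standard deviation instead of estimating it (0 drops the
    omega effects entirely, recovering the consistency model).
    """

    model_kind: str
    family: str
    reference: int = 1
    prior_fixed_sd: float = math.sqrt(1000.0)
    tau_prior: tuple[float, float] = (0.0, 5.0)
    kappa_prior: tuple[float, float] = (0.0, 5.0)
    fixed_kappa: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.model_kind!r}")
        if self.prior_fixed_sd <= 0:
            raise ConfigurationError("prior_fixed_sd must be positive")
        for name, (lo, hi) in (("tau", self.tau_prior), ("kappa", self.kappa_prior)):
            if not (hi > lo >= 0):
                raise ConfigurationError(f"{name} prior must satisfy upper > lower >= 0")

    @property
    def has_tau(self) -> bool:
        return self.model_kind != "fixed"

    @property
    def has_omega(self) -> bool:
        return self.model_kind in ("jackson", "metareg-jackson") and (
            self.fixed_kappa is None or self.fixed_kappa > 0
        )

    @property
    def has_free_kappa(self) -> bool:
        return (
            self.model_kind in ("jackson", "metareg-jackson")
            and self.fixed_kappa is None
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_prior"] = list(self.tau_prior)
        d["kappa_prior"] = list(self.kappa_prior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        known = {
            "model_kind",
            "family",
            "reference",
            "prior_fixed_sd",
            "tau_prior",
            "kappa_prior",
            "fixed_kappa",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown model keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("tau_prior", "kappa_prior"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class HyperParams:
    """Heterogeneity and inconsistency standard deviations."""

    tau: float = 0.0
    kappa: float | None = None


# ---------------------------------------------------------------------------
# compound symmetry


def cs_covariance(sd: float, dim: int) -> np.ndarray:
    """Homogeneous compound-symmetric covariance: diag sd^2, off-diag sd^2/2.

    This is the Higgins-Whitehead structure for the contrasts of a multi-arm
    trial under a common heterogeneity variance; the same shape is used for
    the design-level inconsistency effects.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    v = sd * sd
    return v / 2.0 * (np.eye(dim) + np.ones((dim, dim)))


def cs_precision(variance: float, dim: int) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of ``cs_covariance(sqrt(variance), dim)``.

    Closed form: Sigma = v/2 (I + J) so Sigma^{-1} = 2/v (I - J/(dim+1)) and
    log|Sigma| = dim log(v/2) + log(dim+1).
    """
    q = 2.0 / variance * (np.eye(dim) - np.ones((dim, dim)) / (dim + 1))
    logdet_cov = dim * math.log(variance / 2.0) + math.log(dim + 1)
    return q, logdet_cov


@dataclass(frozen=True)
class CSDecomposition:
    """Shared + idiosyncratic representation of a compound-symmetric vector.

    For ``dim >= 2`` each effect decomposes as ``e_k = a + b_k`` with
    ``a, b_k`` independent zero-mean normals of variance ``sd^2/2`` each,
    which reproduces the compound-symmetric covariance exactly.  For
    ``dim == 1`` a single component of variance ``sd^2`` suffices.
    """

    dim: int
    sd: float

    @property
    def single(self) -> bool:
        return self.dim == 1

    @property
    def shared_var(self) -> float:
        return self.sd**2 if self.single else self.sd**2 / 2.0

    @property
    def idio_var(self) -> float:
        return 0.0 if self.single else self.sd**2 / 2.0

    def expand(self, shared: float, idio: Sequence[float] | None = None) -> np.ndarray:
        if self.single:
            return np.array([shared])
        return shared + np.asarray(idio, dtype=float)

    def implied_covariance(self) -> np.ndarray:
        if self.single:
            return np.array([[self.sd**2]])
        return self.shared_var * np.ones((self.dim, self.dim)) + self.idio_var * np.eye(
            self.dim
        )


def cs_decompose(sd: float, dim: int) -> CSDecomposition:
    """Decompose a compound-symmetric effect group for diagonal-variance engines."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return CSDecomposition(dim=dim, sd=sd)


# ---------------------------------------------------------------------------
# likelihood families (per-arm terms, gradients and curvatures in eta)


def _binomial_terms(y, n, eta):
    return (
        gammaln(n + 1)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        + y * eta
        - n * np.logaddexp(0.0, eta)
    )


def _binomial_grad_hess(y, n, eta):
    p = expit(eta)
    return y - n * p, n * p * (1.0 - p)


def _binomial_saturated(y, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / n), 0.0) + np.where(
            n - y > 0, (n - y) * np.log(1 - y / n), 0.0
        )
    return gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1) + t


def _normal_terms(ybar, var, eta):
    return -0.5 * np.log(2 * np.pi * var) - 0.5 * (ybar - eta) ** 2 / var


def _normal_grad_hess(ybar, var, eta):
    return (ybar - eta) / var, np.full_like(eta, 1.0) / var


def _poisson_terms(y, exposure, eta):
    lam = exposure * np.exp(eta)
    return y * (np.log(exposure) + eta) - lam - gammaln(y + 1)


def _poisson_grad_hess(y, exposure, eta):
    lam = exposure * np.exp(eta)
    return y - lam, lam


def _poisson_saturated(y):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y) - y, 0.0)
    return t - gammaln(y + 1)


# ---------------------------------------------------------------------------
# predictor assembly


@dataclass
class PredictorAssembly:
    """Dense incidence of arms on latent slots, plus the outcome arrays.

    ``X`` has one row per arm; the latent linear predictor is ``X @ alpha``.
    The covariate column of meta-regression kinds already holds the centered
    covariate value for non-baseline arms.
    """

    layout: LatentLayout
    family: str
    X: np.ndarray
    studies: list[str]
    treatments: np.ndarray
    is_baseline: np.ndarray
    y: np.ndarray | None = None
    n: np.ndarray | None = None
    ybar: np.ndarray | None = None
    obs_var: np.ndarray | None = None  # known arm variance sd^2/n (normal family)
    exposure: np.ndarray | None = None
    covariate_center: float | None = None

    @property
    def n_arms(self) -> int:
        return self.X.shape[0]

    def loglik_terms(self, eta: np.ndarray) -> np.ndarray:
        eta = np.asarray(eta, dtype=float)
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite linear predictor")
        if self.family == "binomial":
            return _binomial_terms(self.y, self.n, eta)
        if self.family == "normal":
            return _normal_terms(self.ybar, self.obs_var, eta)
        return _poisson_terms(self.y, self.exposure, eta)

    def loglik(self, eta: np.ndarray) -> float:
        return float(np.sum(self.loglik_terms(eta)))

    def grad_hess(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-arm gradient and negative second derivative of the log likelihood."""
        if self.family == "binomial":
            return _binomial_grad_hess(self.y, self.n, eta)
        if self.family == "normal":
            return _normal_grad_hess(self.ybar, self.obs_var, eta)
        return _poisson_grad_hess(self.y, self.exposure, eta)

    def third_deriv(self, eta: np.ndarray) -> np.ndarray:
        """Per-arm third derivative of the log likelihood in eta.

        Drives the skewness (mean) correction of the Gaussian conditionals;
        identically zero for the normal family, where the Laplace
        approximation is exact.
        """
        if self.family == "binomial":
            p = expit(eta)
            return -self.n * p * (1.0 - p) * (1.0 - 2.0 * p)
        if self.family == "normal":
            return np.zeros_like(eta)
        return -self.exposure * np.exp(eta)

    def saturated_loglik(self) -> float:
        """Log likelihood at the per-arm maximum (saturated deviance baseline)."""
        if self.family == "binomial":
            return float(np.sum(_binomial_saturated(self.y, self.n)))
        if self.family == "normal":
            return float(np.sum(-0.5 * np.log(2 * np.pi * self.obs_var)))
        return float(np.sum(_poisson_saturated(self.y)))

    def deviance(self, eta: np.ndarray, convention: str = "loglik") -> float:
        """-2 log likelihood (``loglik``) or saturated deviance (``saturated``)."""
        d = -2.0 * self.loglik(eta)
        if convention == "saturated":
            d += 2.0 * self.saturated_loglik()
        elif convention != "loglik":
            raise ValueError(f"unknown deviance convention {convention!r}")
        return d


def build_assembly(
    net: NetworkTable,
    cat: DesignCatalog,
    layout: LatentLayout,
) -> PredictorAssembly:
    """Assemble the arm-by-latent incidence matrix and outcome arrays."""
    arms = net.arms
    N = len(arms)
    X = np.zeros((N, layout.dim))
    studies, treat, is_base = [], np.zeros(N, dtype=int), np.zeros(N, dtype=bool)
    xbar = net.covariate_mean if layout.beta_index is not None else None

    row = 0
    for study, trial_arms in net.trials():
        base = trial_arms[0].treatment
        did = cat.trial_design[study]
        for a in trial_arms:
            studies.append(study)
            treat[row] = a.treatment
            X[row, layout.mu_index[study]] = 1.0
            if a.treatment == base:
                is_base[row] = True
            else:
                X[row] += contrast_coefficients(base, a.treatment, layout)
                if layout.has_gamma:
                    X[row, layout.gamma_index[(study, a.treatment)]] = 1.0
                if layout.has_omega:
                    X[row, layout.omega_index[(did, a.treatment)]] = 1.0
                if layout.beta_index is not None:
                    X[row, layout.beta_index] = a.covariate - xbar
            row += 1

    kw: dict = {}
    if net.family == "binomial":
        kw["y"] = np.array([a.events for a in arms], dtype=float)
        kw["n"] = np.array([a.n for a in arms], dtype=float)
    elif net.family == "normal":
        kw["ybar"] = np.array([a.mean for a in arms], dtype=float)
        kw["obs_var"] = np.array([a.sd**2 / a.n for a in arms], dtype=float)
    else:
        kw["y"] = np.array([a.events for a in arms], dtype=float)
        kw["exposure"] = np.array([a.exposure for a in arms], dtype=float)

    return PredictorAssembly(
        layout=layout,
        family=net.family,
        X=X,
        studies=studies,
        treatments=treat,
        is_baseline=is_base,
        covariate_center=xbar,
        **kw,
    )


def linear_predictor(alpha: np.ndarray, assembly: PredictorAssembly) -> np.ndarray:
    """Per-arm linear predictor ``eta = X @ alpha``."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[-1] != assembly.X.shape[1]:
        raise ValueError(
            f"latent vector of length {alpha.shape[-1]} does not match layout "
            f"dimension {assembly.X.shape[1]}"
        )
    return alpha @ assembly.X.T


def log_likelihood(net: NetworkTable, eta: np.ndarray, assembly: PredictorAssembly | None = None) -> float:
    """Sum of per-arm log densities at linear predictor ``eta`` (arm order)."""
    eta = np.asarray(eta, dtype=float)
    if assembly is not None:
        return assembly.loglik(eta)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    if net.family == "binomial":
        y = np.array([a.events for a in net.arms], dtype=float)
        n = np.array([a.n for a in net.arms], dtype=float)
        return float(np.sum(_binomial_terms(y, n, eta)))
    if net.family == "normal":
        ybar = np.array([a.mean for a in net.arms], dtype=float)
        var = np.array([a.sd**2 / a.n for a in net.arms], dtype=float)
        return float(np.sum(_normal_terms(ybar, var, eta)))
    y = np.array([a.events for a in net.arms], dtype=float)
    ex = np.array([a.exposure for a in net.arms], dtype=float)
    return float(np.sum(_poisson_terms(y, ex, eta)))


# ---------------------------------------------------------------------------
# priors


def latent_prior_precision(
    layout: LatentLayout, spec: ModelSpec, hp: HyperParams
) -> tuple[np.ndarray, float]:
    """Prior precision of the latent field and the log-determinant of its covariance.

    Fixed-effect slots get independent N(0, prior_fixed_sd^2); each trial's
    gamma block and each design's omega block get the compound-symmetric
    covariance at tau resp. kappa.
    """
    dim = layout.dim
    Q = np.zeros((dim, dim))
    logdet_cov = 0.0
    v_fixed = spec.prior_fixed_sd**2
    for i in layout.fixed_slots:
        Q[i, i] = 1.0 / v_fixed
        logdet_cov += math.log(v_fixed)
    if layout.has_gamma:
        if hp.tau <= 0:
            raise ValueError("tau must be positive for models with heterogeneity")
        for group in layout.gamma_groups:
            q, ld = cs_precision(hp.tau**2, len(group))
            Q[np.ix_(group, group)] = q
            logdet_cov += ld
    if layout.has_omega:
        kappa = spec.fixed_kappa if spec.fixed_kappa is not None else hp.kappa
        if kappa is None or kappa <= 0:
            raise ValueError("kappa must be positive for Jackson-kind models")
        for group in layout.omega_groups:
            q, ld = cs_precision(kappa**2, len(group))
            Q[np.ix_(group, group)] = q
            logdet_cov += ld
    return Q, logdet_cov


def log_prior_latent(
    alpha: np.ndarray, hp: HyperParams, spec: ModelSpec, layout: LatentLayout
) -> float:
    """Gaussian log density of the latent field given the hyperparameters."""
    alpha = np.asarray(alpha, dtype=float)
    Q, logdet_cov = latent_prior_precision(layout, spec, hp)
    quad = float(alpha @ Q @ alpha)
    return -0.5 * (layout.dim * math.log(2 * math.pi) + logdet_cov + quad)


def log_prior_hyper(hp: HyperParams, spec: ModelSpec) -> float:
    """Log hyperprior density on the standard-deviation scale (uniform boxes)."""
    lp = 0.0
    if spec.has_tau:
        lo, hi = spec.tau_prior
        if not (lo <= hp.tau <= hi):
            return -math.inf
        lp += -math.log(hi - lo)
    if spec.has_free_kappa:
        lo, hi = spec.kappa_prior
        if hp.kappa is None or not (lo <= hp.kappa <= hi):
            return -math.inf
        lp += -math.log(hi - lo)
    return lp
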