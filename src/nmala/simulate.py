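"""Generate arm-level NMA datasets from the generative model itself.

The simulator draws trial baselines, compound-symmetric heterogeneity effects
(one vector per trial, variance tau^2, covariance tau^2/2), design-level
inconsistency effects (one vector per *design*, shared by all trials of that
design, variance kappa^2) and, optionally, a trial-level covariate acting
through a constant interaction coefficient beta.  Arm outcomes are then drawn
from the requested likelihood family.  The latent truth is returned alongside
the data so that recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ArmRecord, NetworkTable
from .model import cs_covariance

__all__ = ["TopologySpec", "simulate_network", "make_toy_fixture", "FIXTURES"]


@dataclass
class TopologySpec:
    """Design structure and true parameters of a simulated network.

    ``designs`` lists (treatment set, number of trials).  ``d`` maps each
    non-reference treatment to its true basic parameter d[1, t] (reference is
    treatment 1 with d = 0; missing treatments default to 0).  Trial baselines
    mu_i are drawn N(mu_mean, mu_sd^2); a dispersed baseline is all the model
    needs since mu is a nuisance parameter.  Binomial arms default to n = 100
    patients, which keeps desk-scale networks well identified.
    """

    designs: list[tuple[tuple[int, ...], int]]
    family: str = "binomial"
    d: dict[int, float] = field(default_factory=dict)
    tau: float = 0.0
    kappa: float = 0.0
    beta: float = 0.0
    mu_mean: float = 0.0
    mu_sd: float = 1.0
    arm_size: int = 100
    outcome_sd: float = 1.0  # per-patient sd (normal family)
    exposure: float = 100.0  # person-time per arm (poisson family)
    covariate: tuple[float, float] | None = None  # (mean, sd) of trial covariate
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.designs:
            raise ValueError("at least one design is required")
        for tset, ntr in self.designs:
            if len(set(tset)) < 2:
                raise ValueError("each design needs >= 2 distinct treatments")
            if ntr < 1:
                raise ValueError("each design needs >= 1 trial")


def simulate_network(ts: TopologySpec) -> tuple[NetworkTable, dict]:
    """Draw one arm-level dataset; returns (network, truth record)."""
    rng = np.random.default_rng(ts.seed)
    arms: list[ArmRecord] = []
    truth: dict = {
        "d": dict(ts.d),
        "tau": ts.tau,
        "kappa": ts.kappa,
        "beta": ts.beta,
        "mu": {},
        "gamma": {},
        "omega": {},
        "covariate": {},
    }

    def dval(t: int) -> float:
        return 0.0 if t == 1 else ts.d.get(t, 0.0)

    cov_mean = ts.covariate[0] if ts.covariate else 0.0
    study_no = 0
    for tset, ntrials in ts.designs:
        tset = tuple(sorted(tset))
        base, rest = tset[0], tset[1:]
        m = len(rest)
        omega = (
            rng.multivariate_normal(np.zeros(m), cs_covariance(ts.kappa, m))
            if ts.kappa > 0
            else np.zeros(m)
        )
        truth["omega"][tset] = dict(zip(rest, omega))
        for _ in range(ntrials):
            study_no += 1
            study = f"s{study_no:03d}"
            mu = ts.mu_mean + ts.mu_sd * rng.standard_normal()
            gamma = (
                rng.multivariate_normal(np.zeros(m), cs_covariance(ts.tau, m))
                if ts.tau > 0
                else np.zeros(m)
            )
            x = None
            if ts.covariate:
                x = float(rng.normal(ts.covariate[0], ts.covariate[1]))
            truth["mu"][study] = mu
            truth["gamma"][study] = dict(zip(rest, gamma))
            truth["covariate"][study] = x

            etas = {base: mu}
            for k, t in enumerate(rest):
                eta = mu + (dval(t) - dval(base)) + gamma[k] + omega[k]
                if ts.covariate:
                    eta += (x - cov_mean) * ts.beta
                etas[t] = eta
            for t in tset:
                arms.append(_draw_arm(rng, ts, study, t, etas[t], x))
    net = NetworkTable(arms, ts.family)
    return net, truth


def _draw_arm(rng, ts, study, treatment, eta, x) -> ArmRecord:
    if ts.family == "binomial":
        p = 1.0 / (1.0 + np.exp(-eta))
        y = int(rng.binomial(ts.arm_size, p))
        return ArmRecord(study, treatment, events=y, n=ts.arm_size, covariate=x)
    if ts.family == "normal":
        se = ts.outcome_sd / np.sqrt(ts.arm_size)
        ybar = float(eta + se * rng.standard_normal())
        return ArmRecord(
            study, treatment, mean=ybar, sd=ts.outcome_sd, n=ts.arm_size, covariate=x
        )
    y = int(rng.poisson(ts.exposure * np.exp(eta)))
    return ArmRecord(study, treatment, events=y, exposure=ts.exposure, covariate=x)


# ---------------------------------------------------------------------------
# deterministic fixtures


def _toy_s23_spec(seed: int) -> TopologySpec:
    # one 3-arm trial {1,2,3} plus 2-arm trials {1,2} and {1,3}:
    # 3 designs and 4 design-inconsistency slots
    return TopologySpec(
        designs=[((1, 2, 3), 1), ((1, 2), 1), ((1, 3), 1)],
        family="binomial",
        d={2: -0.4, 3: 0.3},
        tau=0.2,
        kappa=0.1,
        mu_sd=0.5,
        seed=seed,
    )


def _smoking_like_spec(seed: int) -> TopologySpec:
    # 24 dichotomous trials, 4 treatments, two 3-arm trials, 8 designs
    return TopologySpec(
        designs=[
            ((1, 3, 4), 1),
            ((2, 3, 4), 1),
            ((1, 2), 3),
            ((1, 3), 14),
            ((1, 4), 1),
            ((2, 3), 1),
            ((2, 4), 1),
            ((3, 4), 2),
        ],
        family="binomial",
        d={2: 0.5, 3: 0.8, 4: 1.1},
        tau=0.8,
        kappa=0.4,
        mu_mean=-1.5,
        mu_sd=1.0,
        seed=seed,
    )


def _diabetes_like_spec(seed: int) -> TopologySpec:
    # 26 continuous-endpoint trials, 10 treatments, one 3-arm trial, 16 designs
    return TopologySpec(
        designs=[
            ((1, 2, 3), 1),
            ((1, 2), 3),
            ((1, 3), 3),
            ((1, 4), 3),
            ((1, 5), 2),
            ((1, 6), 2),
            ((1, 7), 2),
            ((1, 8), 2),
            ((1, 9), 1),
            ((1, 10), 1),
            ((2, 3), 1),
            ((2, 4), 1),
            ((3, 4), 1),
            ((4, 5), 1),
            ((5, 7), 1),
            ((6, 7), 1),
        ],
        family="normal",
        d={t: v for t, v in zip(range(2, 11), (-1.0, -1.2, -1.1, -0.8, -0.9, 0.1, -0.6, -0.7, -0.9))},
        tau=0.35,
        mu_mean=0.0,
        mu_sd=0.8,
        arm_size=50,
        outcome_sd=1.2,
        seed=seed,
    )


FIXTURES = {
    "toy_s23": _toy_s23_spec,
    "smoking_like": _smoking_like_spec,
    "diabetes_like": _diabetes_like_spec,
}


def make_toy_fixture(name: str, seed: int = 20180116) -> NetworkTable:
    """Deterministic simulated networks with familiar topologies.

    ``toy_s23``: one 3-arm and two 2-arm trials over 3 treatments (3 designs,
    4 inconsistency slots).  ``smoking_like``: 24 dichotomous trials over 4
    treatments with two 3-arm trials and 8 designs.  ``diabetes_like``: 26
    continuous-endpoint trials over 10 treatments with one 3-arm trial and 16
    designs.  Outcomes are simulated; only the topology mirrors the eponymous
    benchmark networks.
    """
    try:
        spec = FIXTURES[name](seed)
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}"
        ) from None
    net, _ = simulate_network(spec)
    return net
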