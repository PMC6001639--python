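"""Metropolis-within-Gibbs sampler for the NMA GLMMs.

A from-scratch random-walk Metropolis sampler over the same models as the
Laplace engine, used as a validation oracle and as an alternative inference
backend.  The compound-symmetric random effects are sampled in their
shared + idiosyncratic decomposition (see :func:`nmala.model.cs_decompose`),
which is equivalent by construction and gives conditionally independent
scalar blocks.  Proposal scales adapt toward a 30-40% acceptance rate during
burn-in only, preserving detailed balance afterwards.

Updates within a block whose slots touch disjoint sets of arms are carried
out in parallel (vectorized across chains and slots); the basic parameters
``d`` overlap in arms and are updated one at a time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import NetworkTable, build_layout, enumerate_designs
from .model import ModelSpec, build_assembly

__all__ = ["ChainSet", "sample_posterior", "gelman_rubin", "chain_summaries"]


@dataclass
class ChainSet:
    """Posterior draws: one matrix of retained draws per chain.

    ``draws`` has shape (chains, kept, P) where the last columns are the
    hyperparameter standard deviations (tau and, for Jackson kinds, kappa);
    the leading columns follow the latent layout (mu, d, beta, gamma, omega),
    with the random effects reported on the effect scale (shared plus
    idiosyncratic components recombined).
    """

    draws: np.ndarray
    names: list[str]
    burnin: int
    thin: int
    seed: int
    acceptance: dict[str, float]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pooled(), columns=self.names)


# ---------------------------------------------------------------------------
# sampler construction helpers


class _Group:
    """A block of conditionally independent scalar components.

    Each slot touches its own disjoint set of arms; ``entry_arm`` lists arm
    rows, ``entry_slot`` the (local) slot each entry belongs to, ``entry_coef``
    the incidence coefficient of that slot on that arm.
    """

    def __init__(self, name, comp_idx, entry_arm, entry_slot, entry_coef, prior):
        self.name = name
        self.comp_idx = np.asarray(comp_idx, dtype=int)
        self.entry_arm = np.asarray(entry_arm, dtype=int)
        self.entry_slot = np.asarray(entry_slot, dtype=int)
        self.entry_coef = np.asarray(entry_coef, dtype=float)
        self.prior = prior  # ("fixed", var) | ("tau", mult) | ("kappa", mult)
        self.step = 0.5
        self.accepted = 0
        self.attempted = 0

    @property
    def m(self) -> int:
        return len(self.comp_idx)


def _build_groups(spec, net, cat, layout, asm):
    """Construct the update blocks from the latent layout."""
    groups: list[_Group] = []
    studies = net.studies
    arm_study = np.array([studies.index(s) for s in asm.studies])
    S = len(studies)
    v_fixed = spec.prior_fixed_sd**2

    comp_names: list[str] = []

    def add_comps(names):
        base = len(comp_names)
        comp_names.extend(names)
        return list(range(base, base + len(names)))

    # mu: slot per trial, touches every arm of its trial
    mu_idx = add_comps([f"mu[{s}]" for s in studies])
    ea, es, ec = [], [], []
    for a in range(asm.n_arms):
        ea.append(a)
        es.append(arm_study[a])
        ec.append(1.0)
    groups.append(_Group("mu", mu_idx, ea, es, ec, ("fixed", v_fixed)))

    # d: one scalar group per basic parameter (arms overlap across d's)
    d_comp: dict[int, int] = {}
    for t, slot in layout.d_index.items():
        (ci,) = add_comps([layout.names[slot]])
        d_comp[t] = ci
        col = asm.X[:, slot]
        rows = np.nonzero(col)[0]
        groups.append(
            _Group(
                f"d[{t}]",
                [ci],
                rows,
                np.zeros(len(rows), dtype=int),
                col[rows],
                ("fixed", v_fixed),
            )
        )

    beta_comp = None
    if layout.beta_index is not None:
        (beta_comp,) = add_comps(["beta"])
        col = asm.X[:, layout.beta_index]
        rows = np.nonzero(col)[0]
        groups.append(
            _Group(
                "beta",
                [beta_comp],
                rows,
                np.zeros(len(rows), dtype=int),
                col[rows],
                ("fixed", v_fixed),
            )
        )

    # gamma components: per trial, single (2-arm) or shared + idiosyncratic
    gamma_a = np.full(len(layout.gamma_index), -1, dtype=int)  # effect = comp[a] (+ comp[b])
    gamma_b = np.full(len(layout.gamma_index), -1, dtype=int)
    gamma_slot_order = {idx: k for k, idx in enumerate(layout.gamma_index.values())}

    if layout.has_gamma:
        single_ci, single_arm = [], []
        shared_ci, shared_ea, shared_es = [], [], []
        idio_ci, idio_arm = [], []
        for study, arms in net.trials():
            nonbase = arms[1:]
            rows = [
                np.nonzero(asm.X[:, layout.gamma_index[(study, a.treatment)]])[0][0]
                for a in nonbase
            ]
            keys = [gamma_slot_order[layout.gamma_index[(study, a.treatment)]] for a in nonbase]
            if len(nonbase) == 1:
                (ci,) = add_comps([f"g1[{study}]"])
                single_ci.append(ci)
                single_arm.append(rows[0])
                gamma_a[keys[0]] = ci
            else:
                (sh,) = add_comps([f"ga[{study}]"])
                for r, k, a in zip(rows, keys, nonbase):
                    (ci,) = add_comps([f"gb[{study}:{a.treatment}]"])
                    idio_ci.append(ci)
                    idio_arm.append(r)
                    gamma_a[k] = sh
                    gamma_b[k] = ci
                slot = len(shared_ci)
                shared_ci.append(sh)
                shared_ea.extend(rows)
                shared_es.extend([slot] * len(rows))
        if single_ci:
            groups.append(
                _Group(
                    "gamma_single",
                    single_ci,
                    single_arm,
                    np.arange(len(single_ci)),
                    np.ones(len(single_ci)),
                    ("tau", 1.0),
                )
            )
        if shared_ci:
            groups.append(
                _Group(
                    "gamma_shared",
                    shared_ci,
                    shared_ea,
                    shared_es,
                    np.ones(len(shared_ea)),
                    ("tau", 0.5),
                )
            )
            groups.append(
                _Group(
                    "gamma_idio",
                    idio_ci,
                    idio_arm,
                    np.arange(len(idio_ci)),
                    np.ones(len(idio_ci)),
                    ("tau", 0.5),
                )
            )

    # omega components: per design, shared across its trials
    omega_a = np.full(len(layout.omega_index), -1, dtype=int)
    omega_b = np.full(len(layout.omega_index), -1, dtype=int)
    omega_slot_order = {idx: k for k, idx in enumerate(layout.omega_index.values())}
    if layout.has_omega:
        single_ci, single_ea, single_es = [], [], []
        shared_ci, shared_ea, shared_es = [], [], []
        idio_ci, idio_ea, idio_es = [], [], []
        for did, tset in cat.designs.items():
            nonbase = tset[1:]
            slot_rows = {
                tk: np.nonzero(asm.X[:, layout.omega_index[(did, tk)]])[0]
                for tk in nonbase
            }
            if len(nonbase) == 1:
                tk = nonbase[0]
                (ci,) = add_comps([f"o1[{did}]"])
                slot = len(single_ci)
                single_ci.append(ci)
                single_ea.extend(slot_rows[tk])
                single_es.extend([slot] * len(slot_rows[tk]))
                omega_a[omega_slot_order[layout.omega_index[(did, tk)]]] = ci
            else:
                (sh,) = add_comps([f"oa[{did}]"])
                slot = len(shared_ci)
                shared_ci.append(sh)
                for tk in nonbase:
                    (ci,) = add_comps([f"ob[{did}:{tk}]"])
                    k = omega_slot_order[layout.omega_index[(did, tk)]]
                    omega_a[k] = sh
                    omega_b[k] = ci
                    islot = len(idio_ci)
                    idio_ci.append(ci)
                    idio_ea.extend(slot_rows[tk])
                    idio_es.extend([islot] * len(slot_rows[tk]))
                    shared_ea.extend(slot_rows[tk])
                    shared_es.extend([slot] * len(slot_rows[tk]))
        if single_ci:
            groups.append(
                _Group(
                    "omega_single",
                    single_ci,
                    single_ea,
                    single_es,
                    np.ones(len(single_ea)),
                    ("kappa", 1.0),
                )
            )
        if shared_ci:
            groups.append(
                _Group(
                    "omega_shared",
                    shared_ci,
                    shared_ea,
                    shared_es,
                    np.ones(len(shared_ea)),
                    ("kappa", 0.5),
                )
            )
            groups.append(
                _Group(
                    "omega_idio",
                    idio_ci,
                    idio_ea,
                    idio_es,
                    np.ones(len(idio_ea)),
                    ("kappa", 0.5),
                )
            )

    meta = {
        "comp_names": comp_names,
        "mu_idx": np.array(mu_idx),
        "d_comp": d_comp,
        "beta_comp": beta_comp,
        "gamma_a": gamma_a,
        "gamma_b": gamma_b,
        "omega_a": omega_a,
        "omega_b": omega_b,
    }
    return groups, meta


def sample_posterior(
    spec: ModelSpec,
    net: NetworkTable,
    iterations: int = 80_000,
    burnin: int = 30_000,
    thin: int = 5,
    chains: int = 3,
    seed: int = 0,
) -> ChainSet:
    """Random-walk Metropolis-within-Gibbs sampling of the NMA posterior.

    ``iterations`` counts total sweeps including burn-in; draws are retained
    every ``thin`` sweeps after ``burnin``, so each chain keeps
    ``ceil((iterations - burnin) / thin)`` draws.  Defaults mirror common
    long-run settings (30k burn-in, 50k sampling sweeps, thinning 5, 3
    chains); scale them down for quick checks.
    """
    if iterations <= burnin:
        raise ValueError("iterations must exceed burnin")
    dropped: list[str] = []
    if spec.model_kind.startswith("metareg"):
        net, dropped = net.subset_with_covariate()
    cat = enumerate_designs(net)
    kind = spec.model_kind
    if spec.fixed_kappa == 0.0:
        kind = {
            "jackson": "consistency",
            "metareg-jackson": "metareg-consistency",
        }.get(kind, kind)
    layout = build_layout(net, cat, kind, spec.reference)
    asm = build_assembly(net, cat, layout)
    groups, meta = _build_groups(spec, net, cat, layout, asm)

    rng = np.random.default_rng(seed)
    C = chains
    P = len(meta["comp_names"])
    comp = 0.01 * rng.standard_normal((C, P))

    has_tau = spec.has_tau
    has_free_kappa = spec.has_free_kappa
    ltau = np.log(0.3) + 0.2 * rng.standard_normal(C) if has_tau else None
    lkap = np.log(0.3) + 0.2 * rng.standard_normal(C) if has_free_kappa else None
    fixed_kappa = spec.fixed_kappa
    tau_step, kap_step = 0.5, 0.5
    tau_acc = kap_acc = tau_att = kap_att = 0

    # incidence of components on eta (rebuild eta from scratch is cheap & safe)
    comp_cols = np.zeros((asm.n_arms, P))
    for g in groups:
        comp_cols[g.entry_arm, g.comp_idx[g.entry_slot]] += g.entry_coef

    def full_eta(c):
        return c @ comp_cols.T

    eta = full_eta(comp)  # (C, N)
    ll = _ll_terms(asm, eta)

    def prior_var(g, tau2, kap2):
        kind_, val = g.prior
        if kind_ == "fixed":
            return np.full((C, 1), val)
        if kind_ == "tau":
            return (val * tau2)[:, None]
        k2 = kap2 if kap2 is not None else np.full(C, fixed_kappa**2)
        return (val * k2)[:, None]

    kept = math.ceil((iterations - burnin) / thin)
    names = list(layout.names) + (["tau"] if has_tau else []) + (
        ["kappa"] if has_free_kappa else []
    )
    draws = np.empty((C, kept, len(names)))
    kidx = 0

    tau2 = np.exp(2 * ltau) if has_tau else None
    kap2 = np.exp(2 * lkap) if has_free_kappa else None
    tau_comps = [g for g in groups if g.prior[0] == "tau"]
    kap_comps = [g for g in groups if g.prior[0] == "kappa"]

    tau_lo, tau_hi = spec.tau_prior
    kap_lo, kap_hi = spec.kappa_prior

    for it in range(iterations):
        adapting = it < burnin
        for g in groups:
            m = g.m
            prop = g.step * rng.standard_normal((C, m))
            d_eta = prop[:, g.entry_slot] * g.entry_coef[None, :]
            eta_new = eta[:, g.entry_arm] + d_eta
            ll_new = _ll_terms_subset(asm, eta_new, g.entry_arm)
            d_ll_e = ll_new - ll[:, g.entry_arm]
            d_ll = np.zeros((C, m))
            np.add.at(d_ll.T, g.entry_slot, d_ll_e.T)  # segment-sum entries per slot
            x = comp[:, g.comp_idx]
            v = prior_var(g, tau2, kap2)
            d_pr = -((x + prop) ** 2 - x**2) / (2.0 * v)
            acc = np.log(rng.random((C, m))) < d_ll + d_pr
            comp[:, g.comp_idx] = np.where(acc, x + prop, x)
            acc_e = acc[:, g.entry_slot]
            eta[:, g.entry_arm] = np.where(acc_e, eta_new, eta[:, g.entry_arm])
            ll[:, g.entry_arm] = np.where(acc_e, ll_new, ll[:, g.entry_arm])
            if adapting:
                g.attempted += acc.size
                g.accepted += int(acc.sum())
                if (it + 1) % 50 == 0 and g.attempted:
                    rate = g.accepted / g.attempted
                    if rate < 0.30:
                        g.step *= 0.8
                    elif rate > 0.40:
                        g.step *= 1.25
                    g.accepted = g.attempted = 0
            else:
                g.attempted += acc.size
                g.accepted += int(acc.sum())

        # hyperparameter updates on the log-sd scale
        if has_tau:
            ltau, tau2, tau_step, tau_acc, tau_att = _hyper_update(
                ltau, tau_step, tau_acc, tau_att, tau_lo, tau_hi, tau_comps,
                comp, rng, adapting, it,
            )
        if has_free_kappa:
            lkap, kap2, kap_step, kap_acc, kap_att = _hyper_update(
                lkap, kap_step, kap_acc, kap_att, kap_lo, kap_hi, kap_comps,
                comp, rng, adapting, it,
            )

        if it >= burnin and (it - burnin) % thin == 0:
            draws[:, kidx, :] = _report(
                comp, meta, layout, ltau, lkap, has_tau, has_free_kappa
            )
            kidx += 1

    acc_rates = {
        g.name: (g.accepted / g.attempted if g.attempted else float("nan"))
        for g in groups
    }
    if has_tau and tau_att:
        acc_rates["tau"] = tau_acc / tau_att
    if has_free_kappa and kap_att:
        acc_rates["kappa"] = kap_acc / kap_att
    for name, rate in acc_rates.items():
        if rate == 0.0:
            warnings.warn(
                f"block {name!r} accepted no proposals after adaptation",
                UserWarning,
                stacklevel=2,
            )
    return ChainSet(
        draws=draws,
        names=names,
        burnin=burnin,
        thin=thin,
        seed=seed,
        acceptance=acc_rates,
    )


def _hyper_update(lsd, step, acc_n, att_n, lo, hi, comps, comp, rng, adapting, it):
    """One Metropolis update of a log-standard-deviation hyperparameter.

    The prior is uniform on the sd scale, so the log proposal ratio carries
    the Jacobian term (lsd_new - lsd); each component group contributes its
    Gaussian density ratio at variance mult * sd^2.
    """
    C = lsd.shape[0]
    ls_new = lsd + step * rng.standard_normal(C)
    s_new = np.exp(ls_new)
    ok = (s_new >= max(lo, 1e-12)) & (s_new <= hi)
    logr = np.where(ok, ls_new - lsd, -np.inf)
    s2_old, s2_new = np.exp(2 * lsd), s_new**2
    with np.errstate(over="ignore", invalid="ignore"):
        for g in comps:
            mult = g.prior[1]
            x2 = (comp[:, g.comp_idx] ** 2).sum(axis=1)
            contrib = -g.m * (ls_new - lsd) - x2 / (2 * mult) * (
                1 / s2_new - 1 / s2_old
            )
            logr = logr + np.where(ok, contrib, 0.0)
    acc = np.log(rng.random(C)) < logr
    lsd = np.where(acc, ls_new, lsd)
    att_n += C
    acc_n += int(acc.sum())
    if adapting and (it + 1) % 50 == 0 and att_n:
        rate = acc_n / att_n
        if rate < 0.30:
            step *= 0.8
        elif rate > 0.40:
            step *= 1.25
        acc_n = att_n = 0
    return lsd, np.exp(2 * lsd), step, acc_n, att_n


def _report(comp, meta, layout, ltau, lkap, has_tau, has_free_kappa):
    C = comp.shape[0]
    cols = []
    cols.append(comp[:, meta["mu_idx"]])
    if meta["d_comp"]:
        cols.append(comp[:, [meta["d_comp"][t] for t in layout.d_index]])
    if meta["beta_comp"] is not None:
        cols.append(comp[:, [meta["beta_comp"]]])
    if len(meta["gamma_a"]):
        eff = comp[:, meta["gamma_a"]]
        b = meta["gamma_b"]
        mask = b >= 0
        if mask.any():
            eff = eff.copy()
            eff[:, mask] += comp[:, b[mask]]
        cols.append(eff)
    if len(meta["omega_a"]):
        eff = comp[:, meta["omega_a"]]
        b = meta["omega_b"]
        mask = b >= 0
        if mask.any():
            eff = eff.copy()
            eff[:, mask] += comp[:, b[mask]]
        cols.append(eff)
    if has_tau:
        cols.append(np.exp(ltau)[:, None])
    if has_free_kappa:
        cols.append(np.exp(lkap)[:, None])
    return np.concatenate(cols, axis=1)


# per-arm log-likelihood terms, vectorized over a leading chain axis


def _ll_terms(asm, eta):
    from .model import _binomial_terms, _normal_terms, _poisson_terms

    if asm.family == "binomial":
        return _binomial_terms(asm.y, asm.n, eta)
    if asm.family == "normal":
        return _normal_terms(asm.ybar, asm.obs_var, eta)
    return _poisson_terms(asm.y, asm.exposure, eta)


def _ll_terms_subset(asm, eta_sub, arm_idx):
    from .model import _binomial_terms, _normal_terms, _poisson_terms

    if asm.family == "binomial":
        return _binomial_terms(asm.y[arm_idx], asm.n[arm_idx], eta_sub)
    if asm.family == "normal":
        return _normal_terms(asm.ybar[arm_idx], asm.obs_var[arm_idx], eta_sub)
    return _poisson_terms(asm.y[arm_idx], asm.exposure[arm_idx], eta_sub)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(chains: ChainSet) -> dict[str, float]:
    """Potential scale reduction factor per scalar parameter (classic form)."""
    if chains.n_chains < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    x = chains.draws  # (C, n, P)
    C, n, P = x.shape
    means = x.mean(axis=1)  # (C, P)
    W = x.var(axis=1, ddof=1).mean(axis=0)  # (P,)
    B = n * means.var(axis=0, ddof=1)
    out = {}
    for j, name in enumerate(chains.names):
        if W[j] <= 0:
            out[name] = 1.0
        else:
            var_plus = (n - 1) / n * W[j] + B[j] / n
            out[name] = float(math.sqrt(var_plus / W[j]))
    return out


def _batch_sds(x: np.ndarray, stat) -> float:
    """Monte Carlo standard error of a statistic by batch means over chains."""
    C, n = x.shape
    b = max(int(math.sqrt(n)), 2)
    nb = n // b
    if nb < 2:
        return float("nan")
    vals = []
    for c in range(C):
        for k in range(nb):
            vals.append(stat(x[c, k * b : (k + 1) * b]))
    vals = np.asarray(vals)
    return float(vals.std(ddof=1) / math.sqrt(len(vals)))


def chain_summaries(chains: ChainSet) -> pd.DataFrame:
    """Posterior summaries per parameter, with batch-means Monte Carlo errors."""
    rows = []
    for j, name in enumerate(chains.names):
        x = chains.draws[:, :, j]
        pooled = x.ravel()
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
                "q2.5": float(np.quantile(pooled, 0.025)),
                "median": float(np.median(pooled)),
                "q97.5": float(np.quantile(pooled, 0.975)),
                "mcse_mean": _batch_sds(x, np.mean),
                "mcse_median": _batch_sds(x, np.median),
            }
        )
    return pd.DataFrame(rows)
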