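"""Arm-level network meta-analysis data: reading, validation, designs, latent layout.

A network meta-analysis (NMA) dataset is a long table with one row per trial
arm.  Each arm carries a study label, a treatment id (positive integer) and an
outcome payload whose shape depends on the endpoint family:

* ``binomial``  -- events and sample size (dichotomous endpoints, logit link),
* ``normal``    -- sample mean, standard deviation and sample size
  (continuous endpoints, identity link),
* ``poisson``   -- event count and exposure time (count endpoints, log link).

An optional trial-level covariate column supports network meta-regression.

This module validates such tables, groups arms into trials, enumerates the
*designs* of the network (the distinct treatment sets appearing in trials) and
lays out the latent parameter vector used by the inference engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmRecord",
    "NetworkTable",
    "DesignCatalog",
    "LatentLayout",
    "ConfigurationError",
    "ValidationError",
    "read_arm_table",
    "network_from_frame",
    "enumerate_designs",
    "contrast_coefficients",
    "build_layout",
    "MODEL_KINDS",
]

FAMILIES = ("binomial", "normal", "poisson")

#: model kinds; "metareg-*" add a constant covariate-by-treatment interaction
MODEL_KINDS = (
    "fixed",
    "consistency",
    "jackson",
    "metareg-consistency",
    "metareg-jackson",
)

#: conventional column names of the long arm-level format, per endpoint family
DEFAULT_COLUMNS: dict[str, dict[str, str]] = {
    "binomial": {
        "study": "study",
        "treatment": "treatment",
        "events": "responders",
        "n": "sampleSize",
    },
    "normal": {
        "study": "study",
        "treatment": "treatment",
        "mean": "mean",
        "sd": "std.dev",
        "n": "sampleSize",
    },
    "poisson": {
        "study": "study",
        "treatment": "treatment",
        "events": "responders",
        "exposure": "exposure",
    },
}


class ConfigurationError(ValueError):
    """A problem with the requested configuration (missing column, bad name)."""


class ValidationError(ValueError):
    """Input data violates an invariant of the arm-level format."""


@dataclass(frozen=True)
class ArmRecord:
    """One trial arm.

    Exactly one outcome payload variant is populated per dataset:
    ``(events, n)`` for binomial, ``(mean, sd, n)`` for normal and
    ``(events, exposure)`` for poisson endpoints.
    """

    study: str
    treatment: int
    events: int | None = None
    n: int | None = None
    mean: float | None = None
    sd: float | None = None
    exposure: float | None = None
    covariate: float | None = None


def _union_find_connected(edges: Iterable[tuple[int, int]], nodes: set[int]) -> bool:
    parent = {t: t for t in nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    roots = {find(t) for t in nodes}
    return len(roots) <= 1


@dataclass
class NetworkTable:
    """A validated arm-level NMA dataset grouped into trials.

    Arms are stored trial by trial (in order of first appearance of the study
    label) and, within a trial, sorted by ascending treatment id, so the trial
    baseline is always the lowest-numbered treatment of the trial.
    """

    arms: list[ArmRecord]
    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown endpoint family {self.family!r}")
        self._validate()
        # canonical ordering: trials in first-appearance order, arms by treatment
        order: dict[str, int] = {}
        for a in self.arms:
            order.setdefault(a.study, len(order))
        self.arms = sorted(self.arms, key=lambda a: (order[a.study], a.treatment))

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        by_study: dict[str, list[ArmRecord]] = {}
        for a in self.arms:
            by_study.setdefault(a.study, []).append(a)
        for study, arms in by_study.items():
            if len(arms) < 2:
                raise ValidationError(f"trial {study!r} has a single arm")
            ts = [a.treatment for a in arms]
            if len(set(ts)) != len(ts):
                raise ValidationError(f"trial {study!r} repeats a treatment")
            covs = {a.covariate for a in arms}
            if len(covs) > 1:
                raise ValidationError(f"trial {study!r} has a non-constant covariate")
        for i, a in enumerate(self.arms):
            if a.treatment < 1:
                raise ValidationError(f"row {i}: treatment id must be a positive integer")
            if self.family == "binomial":
                if a.events is None or a.n is None:
                    raise ValidationError(f"row {i} (study {a.study!r}): missing events/n")
                if a.n <= 0:
                    raise ValidationError(f"row {i} (study {a.study!r}): n must be positive")
                if a.events < 0 or a.events > a.n:
                    raise ValidationError(
                        f"row {i} (study {a.study!r}): events must lie in [0, n]"
                    )
            elif self.family == "normal":
                if a.mean is None or a.sd is None or a.n is None:
                    raise ValidationError(f"row {i} (study {a.study!r}): missing mean/sd/n")
                if a.sd <= 0:
                    raise ValidationError(f"row {i} (study {a.study!r}): sd must be > 0")
                if a.n <= 0:
                    raise ValidationError(f"row {i} (study {a.study!r}): n must be positive")
            else:  # poisson
                if a.events is None or a.exposure is None:
                    raise ValidationError(
                        f"row {i} (study {a.study!r}): missing count/exposure"
                    )
                if a.events < 0:
                    raise ValidationError(f"row {i} (study {a.study!r}): negative count")
                if a.exposure <= 0:
                    raise ValidationError(
                        f"row {i} (study {a.study!r}): exposure must be > 0"
                    )
        # connectivity (warn only; cross-component contrasts are inestimable)
        nodes = {a.treatment for a in self.arms}
        edges = []
        for arms in by_study.values():
            base = min(a.treatment for a in arms)
            edges.extend((base, a.treatment) for a in arms)
        if nodes and not _union_find_connected(edges, nodes):
            warnings.warn(
                "treatment comparison graph is disconnected; contrasts across "
                "components are not estimable",
                UserWarning,
                stacklevel=3,
            )

    # -- views -----------------------------------------------------------

    @property
    def studies(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arms:
            seen.setdefault(a.study)
        return list(seen)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def treatments(self) -> list[int]:
        return sorted({a.treatment for a in self.arms})

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def trials(self) -> Iterator[tuple[str, list[ArmRecord]]]:
        """Yield ``(study, arms)`` with arms sorted by treatment id."""
        cur: list[ArmRecord] = []
        for a in self.arms:
            if cur and a.study != cur[0].study:
                yield cur[0].study, cur
                cur = []
            cur.append(a)
        if cur:
            yield cur[0].study, cur

    @property
    def has_covariate(self) -> bool:
        return any(a.covariate is not None for a in self.arms)

    @property
    def covariate_mean(self) -> float | None:
        """Mean of the trial-level covariate over trials where it is present."""
        vals = [arms[0].covariate for _, arms in self.trials() if arms[0].covariate is not None]
        if not vals:
            return None
        return float(np.mean(vals))

    def subset_with_covariate(self) -> tuple["NetworkTable", list[str]]:
        """Drop trials with a missing covariate (meta-regression path).

        Returns the reduced network and the list of dropped study labels.
        """
        dropped = [s for s, arms in self.trials() if arms[0].covariate is None]
        if not dropped:
            return self, []
        keep = [a for a in self.arms if a.study not in set(dropped)]
        return NetworkTable(keep, self.family), dropped

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            rows.append(
                {
                    "study": a.study,
                    "treatment": a.treatment,
                    "events": a.events,
                    "n": a.n,
                    "mean": a.mean,
                    "sd": a.sd,
                    "exposure": a.exposure,
                    "covariate": a.covariate,
                }
            )
        df = pd.DataFrame(rows)
        return df.dropna(axis=1, how="all")


def network_from_frame(
    df: pd.DataFrame,
    family: str,
    column_map: Mapping[str, str] | None = None,
    covariate_column: str | None = None,
) -> NetworkTable:
    """Build a :class:`NetworkTable` from a long-format dataframe."""
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown endpoint family {family!r}")
    cols = dict(DEFAULT_COLUMNS[family])
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown column roles: {sorted(unknown)}")
        cols.update(column_map)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    if covariate_column is not None and covariate_column not in df.columns:
        raise ConfigurationError(f"missing covariate column {covariate_column!r}")

    arms: list[ArmRecord] = []
    for _, row in df.iterrows():
        cov = None
        if covariate_column is not None:
            v = row[covariate_column]
            cov = None if pd.isna(v) else float(v)
        kw: dict = {
            "study": str(row[cols["study"]]),
            "treatment": int(row[cols["treatment"]]),
            "covariate": cov,
        }
        if family == "binomial":
            kw["events"] = int(row[cols["events"]])
            kw["n"] = int(row[cols["n"]])
        elif family == "normal":
            kw["mean"] = float(row[cols["mean"]])
            kw["sd"] = float(row[cols["sd"]])
            kw["n"] = int(row[cols["n"]])
        else:
            kw["events"] = int(row[cols["events"]])
            kw["exposure"] = float(row[cols["exposure"]])
        arms.append(ArmRecord(**kw))
    return NetworkTable(arms, family)


def read_arm_table(
    path,
    family: str,
    column_map: Mapping[str, str] | None = None,
    covariate_column: str | None = None,
    sep: str | None = None,
) -> NetworkTable:
    """Read a delimited arm-level table (comma or tab separated, with header)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return network_from_frame(df, family, column_map, covariate_column)


# ---------------------------------------------------------------------------
# designs


@dataclass
class DesignCatalog:
    """Distinct treatment sets (designs) and their inconsistency-effect slots.

    Two trials share a design id iff their treatment sets are identical.  For
    each design the inconsistency random effects are indexed by the contrasts
    of the design's own baseline (its lowest treatment) against each remaining
    treatment, giving ``|design| - 1`` slots per design.
    """

    designs: dict[int, tuple[int, ...]]
    trial_design: dict[str, int]
    omega_slots: list[tuple[int, int, int]]  # (design_id, baseline, non-baseline)

    @property
    def n_designs(self) -> int:
        return len(self.designs)

    def trials_of(self, design_id: int) -> list[str]:
        return [s for s, d in self.trial_design.items() if d == design_id]

    def to_frame(self) -> pd.DataFrame:
        counts: dict[int, int] = {}
        for d in self.trial_design.values():
            counts[d] = counts.get(d, 0) + 1
        rows = [
            {
                "design_id": did,
                "treatments": "+".join(map(str, tset)),
                "n_trials": counts.get(did, 0),
            }
            for did, tset in self.designs.items()
        ]
        return pd.DataFrame(rows)


def enumerate_designs(net: NetworkTable) -> DesignCatalog:
    """Catalogue the designs of a network, in order of first appearance."""
    designs: dict[tuple[int, ...], int] = {}
    trial_design: dict[str, int] = {}
    for study, arms in net.trials():
        tset = tuple(sorted(a.treatment for a in arms))
        if tset not in designs:
            designs[tset] = len(designs) + 1
        trial_design[study] = designs[tset]
    catalog = {did: tset for tset, did in designs.items()}
    omega_slots = [
        (did, tset[0], tk) for did, tset in catalog.items() for tk in tset[1:]
    ]
    return DesignCatalog(catalog, trial_design, omega_slots)


# ---------------------------------------------------------------------------
# latent layout


@dataclass
class LatentLayout:
    """Index map from model symbols to one latent vector.

    The latent field stacks, in order: the trial baselines ``mu`` (one per
    trial), the basic parameters ``d`` (one per non-reference treatment), the
    interaction coefficient ``beta`` (meta-regression kinds only), the
    heterogeneity effects ``gamma`` (one per non-baseline arm; absent for the
    fixed-effect kind) and the design-inconsistency effects ``omega`` (one per
    (design, contrast) slot; Jackson kinds only).
    """

    model_kind: str
    reference: int
    names: list[str]
    mu_index: dict[str, int]
    d_index: dict[int, int]
    beta_index: int | None
    gamma_index: dict[tuple[str, int], int]
    omega_index: dict[tuple[int, int], int]
    gamma_groups: list[list[int]] = field(default_factory=list)
    omega_groups: list[list[int]] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def has_gamma(self) -> bool:
        return bool(self.gamma_index)

    @property
    def has_omega(self) -> bool:
        return bool(self.omega_index)

    @property
    def fixed_slots(self) -> list[int]:
        """Slots with independent vague normal priors (mu, d, beta)."""
        idx = list(self.mu_index.values()) + list(self.d_index.values())
        if self.beta_index is not None:
            idx.append(self.beta_index)
        return idx

    def d_slot(self, treatment: int) -> int:
        if treatment == self.reference:
            raise KeyError("the reference treatment has no basic-parameter slot")
        return self.d_index[treatment]


def contrast_coefficients(t1: int, tk: int, layout: LatentLayout) -> np.ndarray:
    """Coefficients over the basic-parameter slots expressing d_{t1,tk}.

    Any relative effect is a linear combination of the basic parameters:
    ``d[t1, tk] = d[ref, tk] - d[ref, t1]`` with the reference's own slot
    identically zero.  Returns a dense vector over the full latent dimension.
    """
    if t1 == tk:
        raise ValueError("degenerate contrast: the two treatments must differ")
    known = set(layout.d_index) | {layout.reference}
    for t in (t1, tk):
        if t not in known:
            raise KeyError(f"treatment {t} is not in the network")
    c = np.zeros(layout.dim)
    if tk != layout.reference:
        c[layout.d_index[tk]] += 1.0
    if t1 != layout.reference:
        c[layout.d_index[t1]] -= 1.0
    return c


def build_layout(
    net: NetworkTable,
    cat: DesignCatalog,
    model_kind: str,
    reference: int = 1,
) -> LatentLayout:
    """Lay out the latent vector (mu, d, beta, gamma, omega) for a model kind."""
    if model_kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {model_kind!r}")
    if reference not in net.treatments:
        raise ConfigurationError(f"reference treatment {reference} not in network")
    if model_kind.startswith("metareg") and not net.has_covariate:
        raise ConfigurationError(
            "meta-regression requested but the data carry no covariate"
        )

    names: list[str] = []
    mu_index: dict[str, int] = {}
    d_index: dict[int, int] = {}
    gamma_index: dict[tuple[str, int], int] = {}
    omega_index: dict[tuple[int, int], int] = {}
    gamma_groups: list[list[int]] = []
    omega_groups: list[list[int]] = []

    for study in net.studies:
        mu_index[study] = len(names)
        names.append(f"mu[{study}]")
    for t in net.treatments:
        if t == reference:
            continue
        d_index[t] = len(names)
        names.append(f"d[{reference},{t}]")
    beta_index = None
    if model_kind.startswith("metareg"):
        beta_index = len(names)
        names.append("beta")
    if model_kind != "fixed":
        for study, arms in net.trials():
            base = arms[0].treatment
            group = []
            for a in arms[1:]:
                gamma_index[(study, a.treatment)] = len(names)
                group.append(len(names))
                names.append(f"gamma[{study}:{base},{a.treatment}]")
            gamma_groups.append(group)
    if model_kind in ("jackson", "metareg-jackson"):
        by_design: dict[int, list[int]] = {}
        for did, t1, tk in cat.omega_slots:
            omega_index[(did, tk)] = len(names)
            by_design.setdefault(did, []).append(len(names))
            names.append(f"omega[{did}:{t1},{tk}]")
        omega_groups = [by_design[d] for d in sorted(by_design)]

    return LatentLayout(
        model_kind=model_kind,
        reference=reference,
        names=names,
        mu_index=mu_index,
        d_index=d_index,
        beta_index=beta_index,
        gamma_index=gamma_index,
        omega_index=omega_index,
        gamma_groups=gamma_groups,
        omega_groups=omega_groups,
    )
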