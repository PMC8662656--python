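"""Demographic scenarios for a vent/seep limpet metapopulation.

Three competing divergence/founder scenarios describe how four genetic
groups — three hydrocarbon-seep groups (JR: Jiaolong Ridge, OH: Off
Hatsushima, KK: Kuroshima Knoll) and one hydrothermal-vent group
(OT: Okinawa Trough) — may have formed:

* **Scenario 1** — an ancestral population splits at ``TA`` into a
  deeper-seep lineage (the later JR+OH ancestor) and the KK lineage.  A
  propagule of ``N_KKP`` larvae leaves KK at ``T3``, persists as a small
  founder population, and becomes the OT vent group at ``T2``.  The
  deeper-seep lineage splits into JR and OH at ``T1``.
* **Scenario 2** — the deeper-seep lineage is ancestral; KK is founded
  from it by ``N_AP`` larvae at ``TA`` (established at ``T4``); the OT
  group is then founded from KK as in scenario 1.
* **Scenario 3** — KK is ancestral; the deeper-seep lineage is founded
  from KK by ``N_KKP1`` larvae at ``TA`` (established at ``T4``) and the
  OT group by ``N_KKP2`` larvae at ``T3`` (established at ``T2``).

All times are in generations before present and satisfy
``T1 < T2 < T3 (< T4) < TA``; all sizes are diploid effective sizes.
There is no migration between branches: contemporary gene flow is the
business of other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("JR", "OH", "KK", "OT")

#: union of parameter names over the three scenarios
PARAM_NAMES = (
    "T1", "T2", "T3", "T4", "TA",
    "NA", "N_JRpOH", "N_JR", "N_OH", "N_KK", "N_OT",
    "N_KKP", "N_AP", "N_KKP1", "N_KKP2",
)

_TIME_PARAMS = {
    1: ("T1", "T2", "T3", "TA"),
    2: ("T1", "T2", "T3", "T4", "TA"),
    3: ("T1", "T2", "T3", "T4", "TA"),
}
_SIZE_PARAMS = {
    1: ("NA", "N_JRpOH", "N_JR", "N_OH", "N_KK", "N_OT", "N_KKP"),
    2: ("N_JRpOH", "N_JR", "N_OH", "N_KK", "N_OT", "N_KKP", "N_AP"),
    3: ("N_JRpOH", "N_JR", "N_OH", "N_KK", "N_OT", "N_KKP1", "N_KKP2"),
}
#: founder size -> size of the branch it founds (checked by default)
_FOUNDER_CONSTRAINTS = {
    1: (("N_KKP", "N_OT"),),
    2: (("N_KKP", "N_OT"), ("N_AP", "N_KK")),
    3: (("N_KKP2", "N_OT"), ("N_KKP1", "N_JRpOH")),
}

MISSING = -1  # missing-genotype sentinel in genotype matrices


def scenario_param_names(scenario_id: int) -> tuple[str, ...]:
    """Names of the parameters actually used by a scenario."""
    if scenario_id not in (1, 2, 3):
        raise ValueError(f"unknown scenario_id: {scenario_id}")
    return _TIME_PARAMS[scenario_id] + _SIZE_PARAMS[scenario_id]


@dataclass
class ScenarioParams:
    """One demographic parameter vector; unused parameters stay ``None``."""

    scenario_id: int
    T1: float | None = None
    T2: float | None = None
    T3: float | None = None
    T4: float | None = None
    TA: float | None = None
    NA: float | None = None
    N_JRpOH: float | None = None
    N_JR: float | None = None
    N_OH: float | None = None
    N_KK: float | None = None
    N_OT: float | None = None
    N_KKP: float | None = None
    N_AP: float | None = None
    N_KKP1: float | None = None
    N_KKP2: float | None = None

    def used(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in scenario_param_names(self.scenario_id)}

    def validate(self, check_founder: bool = True) -> None:
        sid = self.scenario_id
        if sid not in (1, 2, 3):
            raise ValueError(f"unknown scenario_id: {sid}")
        for name, value in self.used().items():
            if value is None:
                raise ValueError(f"scenario {sid} requires parameter {name}")
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        times = [getattr(self, t) for t in _TIME_PARAMS[sid]]
        if not all(a < b for a, b in zip(times, times[1:])):
            order = " < ".join(_TIME_PARAMS[sid])
            raise ValueError(f"event times must satisfy {order}, got {times}")
        if check_founder:
            for founder, branch in _FOUNDER_CONSTRAINTS[sid]:
                if getattr(self, founder) > getattr(self, branch):
                    raise ValueError(
                        f"founder size {founder}={getattr(self, founder)} exceeds "
                        f"founded branch size {branch}={getattr(self, branch)}"
                    )

    def as_array(self) -> np.ndarray:
        """Full-length vector over :data:`PARAM_NAMES`, NaN where unused."""
        out = np.full(len(PARAM_NAMES), np.nan)
        for i, name in enumerate(PARAM_NAMES):
            v = getattr(self, name)
            if v is not None:
                out[i] = v
        return out

    @classmethod
    def from_array(cls, scenario_id: int, values: np.ndarray) -> "ScenarioParams":
        kwargs = {
            name: (None if np.isnan(values[i]) else float(values[i]))
            for i, name in enumerate(PARAM_NAMES)
        }
        return cls(scenario_id=scenario_id, **kwargs)


#: default uniform prior bounds; the posterior 95% quantiles of the original
#: study press against ~99,600 (sizes) and ~967 (founders), implying prior
#: ceilings near 100,000 and 1,000.
DEFAULT_PRIOR_BOUNDS: dict[str, tuple[float, float]] = {
    **{t: (10.0, 100_000.0) for t in ("T1", "T2", "T3", "T4", "TA")},
    **{n: (10.0, 100_000.0) for n in ("NA", "N_JRpOH", "N_JR", "N_OH", "N_KK", "N_OT")},
    **{n: (5.0, 1_000.0) for n in ("N_KKP", "N_AP", "N_KKP1", "N_KKP2")},
}


@dataclass
class PriorSpec:
    """Per-parameter uniform prior bounds with an ordering constraint flag."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS)
    )
    enforce_order: bool = True
    check_founder: bool = True
    max_attempts: int = 100_000

    def validate(self, scenario_id: int | None = None) -> None:
        names = scenario_param_names(scenario_id) if scenario_id else self.bounds
        for name in names:
            if name not in self.bounds:
                raise ValueError(f"prior bounds missing for parameter {name}")
            lo, hi = self.bounds[name]
            if lo > hi:
                raise ValueError(f"prior for {name} has lower > upper: ({lo}, {hi})")


@dataclass
class SampleConfig:
    """Diploid sample sizes per genetic group (defaults follow the study)."""

    sizes: dict[str, int] = field(
        default_factory=lambda: {"JR": 12, "OH": 25, "KK": 21, "OT": 63}
    )

    def __post_init__(self) -> None:
        unknown = set(self.sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        for g, n in self.sizes.items():
            if n < 2:
                raise ValueError(f"group {g} needs >= 2 diploids, got {n}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUPS if g in self.sizes)

    @property
    def n_individuals(self) -> int:
        return sum(self.sizes.values())

    def lineage_counts(self) -> dict[str, int]:
        return {g: 2 * n for g, n in self.sizes.items()}


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (0/1/2, -1 = missing) for individuals x SNP loci."""

    genotypes: np.ndarray            # int8, shape (n_individuals, n_loci)
    individuals: list[str]
    groups: np.ndarray               # str array, shape (n_individuals,)
    loci: pd.DataFrame               # columns: scaffold, pos (1-based)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.groups = np.asarray(self.groups)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be in {0,1,2,missing}")
        if self.genotypes.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def group_names(self) -> tuple[str, ...]:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group_index(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise KeyError(f"no individuals in group {group!r}")
        return idx

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[:, keep],
            list(self.individuals),
            self.groups.copy(),
            self.loci.iloc[np.atleast_1d(keep)].reset_index(drop=True),
        )

    def popmap(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.individuals, "group": self.groups})


def draw_scenario_params(
    prior: PriorSpec, scenario_id: int, rng_seed: int | np.random.Generator
) -> ScenarioParams:
    """Rejection-sample one parameter vector from uniform priors.

    Draws every parameter the scenario uses independently from its uniform
    prior and rejects draws violating the time ordering or (optionally) the
    founder-size constraints.  Raises ``RuntimeError`` if ``max_attempts``
    rejections occur, which signals an infeasible prior.
    """
    prior.validate(scenario_id)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    names = scenario_param_names(scenario_id)
    los = np.array([prior.bounds[n][0] for n in names])
    his = np.array([prior.bounds[n][1] for n in names])
    tidx = [names.index(t) for t in _TIME_PARAMS[scenario_id]]
    fidx = [
        (names.index(a), names.index(b)) for a, b in _FOUNDER_CONSTRAINTS[scenario_id]
    ]
    for _ in range(prior.max_attempts):
        draw = los + (his - los) * rng.random(len(names))
        times = draw[tidx]
        if prior.enforce_order and not np.all(np.diff(times) > 0):
            continue
        if prior.check_founder and any(draw[a] > draw[b] for a, b in fidx):
            continue
        params = ScenarioParams(
            scenario_id=scenario_id, **{n: float(v) for n, v in zip(names, draw)}
        )
        params.validate(check_founder=prior.check_founder)
        return params
    raise RuntimeError(
        f"prior rejection sampling failed after {prior.max_attempts} attempts; "
        "the ordering/founder constraints are infeasible under these bounds"
    )


# --- event-table encoding of the backward-in-time demography ----------------
#
# Demes 0..3 are the sampled groups in GROUPS order; deme 4 is the internal
# deeper-seep (JR+OH) ancestor branch.  Each event is (time, src, dst,
# size_deme, size_value): lineages in `src` move to `dst` (src = -1: no
# merge), then deme `size_deme` changes to `size_value` (size_deme = -1: no
# change).  Events are time-sorted; after the last one a single ancestral
# deme remains.

_DEEP = 4


def scenario_event_table(
    params: ScenarioParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    params.validate(check_founder=False)
    p = params
    sizes0 = np.array([p.N_JR, p.N_OH, p.N_KK, p.N_OT, 1.0])
    if p.scenario_id == 1:
        events = [
            (p.T1, 0, _DEEP, _DEEP, p.N_JRpOH),
            (p.T1, 1, _DEEP, -1, 0.0),
            (p.T2, -1, -1, 3, p.N_KKP),
            (p.T3, 3, 2, -1, 0.0),
            (p.TA, _DEEP, 2, 2, p.NA),
        ]
    elif p.scenario_id == 2:
        events = [
            (p.T1, 0, _DEEP, _DEEP, p.N_JRpOH),
            (p.T1, 1, _DEEP, -1, 0.0),
            (p.T2, -1, -1, 3, p.N_KKP),
            (p.T3, 3, 2, -1, 0.0),
            (p.T4, -1, -1, 2, p.N_AP),
            (p.TA, 2, _DEEP, -1, 0.0),
        ]
    else:  # scenario 3
        events = [
            (p.T1, 0, _DEEP, _DEEP, p.N_JRpOH),
            (p.T1, 1, _DEEP, -1, 0.0),
            (p.T2, -1, -1, 3, p.N_KKP2),
            (p.T3, 3, 2, -1, 0.0),
            (p.T4, -1, -1, _DEEP, p.N_KKP1),
            (p.TA, _DEEP, 2, -1, 0.0),
        ]
    ev = np.array(events, dtype=float)
    return (
        sizes0,
        ev[:, 0].copy(),
        ev[:, 1].astype(np.int64),
        ev[:, 2].astype(np.int64),
        ev[:, 3].astype(np.int64),
        ev[:, 4].copy(),
    )


def published_median_params() -> ScenarioParams:
    """Scenario-1 parameter vector at the published posterior medians."""
    return ScenarioParams(
        scenario_id=1,
        T1=1220, T2=6410, T3=11_800, TA=24_400,
        NA=97_400, N_JRpOH=38_900, N_JR=10_700, N_OH=51_400,
        N_KK=43_800, N_KKP=650, N_OT=98_200,
    )


def degenerate_prior(params: ScenarioParams) -> PriorSpec:
    """Point-mass prior at a given parameter vector (useful for testing)."""
    bounds = dict(DEFAULT_PRIOR_BOUNDS)
    for name, value in params.used().items():
        bounds[name] = (value, value)
    return PriorSpec(bounds=bounds)
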