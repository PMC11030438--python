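"""Evolutionary model specifications and the Q-rescaling transform.

A model describes a diploid Wright-Fisher population: its size and demography,
genome length, per-bp mutation and recombination rates, the mix of neutral /
beneficial / deleterious mutations, the distribution of fitness effects (DFE)
for each class, the dominance coefficient, and an optional single selective
sweep.  Rescaling by a factor ``Q`` replaces the population of size ``N`` by
one of size ``N/Q`` while multiplying the mutation rate, recombination rate
and selection coefficients by ``Q`` and dividing all model time spans by
``Q``, so that the population-scaled parameters ``theta = 4*N*mu`` and ``N*s``
are preserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

__all__ = [
    "FitnessEffectDistribution",
    "MutationClassMix",
    "DemographyPlan",
    "SweepPlan",
    "ModelSpec",
    "rescale_model",
    "draw_selection_coefficient",
    "build_catalog_model",
    "CATALOG_NAMES",
]

_DFE_KINDS = ("neutral", "fixed", "gamma", "lognormal")


@dataclass(frozen=True)
class FitnessEffectDistribution:
    """Distribution of selection coefficients for one mutation class.

    kind
        ``neutral`` (s = 0 always), ``fixed`` (constant ``s_fixed``),
        ``gamma`` (mean ``gamma_mean``, shape ``gamma_shape``; the sign of the
        mean carries over to every draw), or ``lognormal``
        (``sign * exp(Normal(lognorm_mu, lognorm_sigma))``; the magnitude is
        stored on the positive log scale and ``sign`` is applied at draw time).
    """

    kind: str
    s_fixed: float = 0.0
    gamma_mean: float = 0.0
    gamma_shape: float = 0.0
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 0.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _DFE_KINDS:
            raise ValueError(f"unknown DFE kind {self.kind!r}; expected one of {_DFE_KINDS}")
        if self.kind == "gamma":
            if not self.gamma_shape > 0:
                raise ValueError("gamma_shape must be > 0")
            if self.gamma_mean == 0:
                raise ValueError("gamma_mean must be nonzero for kind='gamma'")
        if self.kind == "lognormal":
            if not self.lognorm_sigma > 0:
                raise ValueError("lognorm_sigma must be > 0")
            if self.sign not in (1, -1):
                raise ValueError("sign must be +1 or -1")

    def rescaled(self, Q: float) -> "FitnessEffectDistribution":
        """Return the DFE with selection coefficients multiplied by Q.

        For a gamma DFE this multiplies the mean and keeps the shape fixed;
        for a lognormal it adds ``ln(Q)`` to the log-space location.  Both are
        pure scale transforms: with a matched random stream every draw equals
        Q times the unscaled draw.
        """
        if self.kind == "neutral":
            return self
        if self.kind == "fixed":
            return replace(self, s_fixed=self.s_fixed * Q)
        if self.kind == "gamma":
            return replace(self, gamma_mean=self.gamma_mean * Q)
        return replace(self, lognorm_mu=self.lognorm_mu + math.log(Q))

    def draw(self, rng: np.random.Generator, size=None):
        """Draw selection coefficient(s) from this DFE."""
        if self.kind == "neutral":
            return 0.0 if size is None else np.zeros(size)
        if self.kind == "fixed":
            return self.s_fixed if size is None else np.full(size, self.s_fixed)
        if self.kind == "gamma":
            scale = abs(self.gamma_mean) / self.gamma_shape
            draws = rng.gamma(self.gamma_shape, scale, size=size)
            return math.copysign(1.0, self.gamma_mean) * draws
        draws = np.exp(rng.normal(self.lognorm_mu, self.lognorm_sigma, size=size))
        return self.sign * draws


def draw_selection_coefficient(dfe: FitnessEffectDistribution, rng: np.random.Generator) -> float:
    """Draw a single selection coefficient from ``dfe`` using ``rng``."""
    return float(dfe.draw(rng))


@dataclass(frozen=True)
class MutationClassMix:
    """Probabilities that a new mutation is neutral / beneficial / deleterious."""

    f_n: float
    f_b: float
    f_d: float

    def __post_init__(self) -> None:
        for name, f in (("f_n", self.f_n), ("f_b", self.f_b), ("f_d", self.f_d)):
            if f < 0:
                raise ValueError(f"{name} must be >= 0, got {f}")
        total = self.f_n + self.f_b + self.f_d
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mutation class fractions must sum to 1, got {total!r}")

    @property
    def classes_present(self) -> tuple[str, ...]:
        names = []
        for name, f in (("neutral", self.f_n), ("beneficial", self.f_b), ("deleterious", self.f_d)):
            if f > 0:
                names.append(name)
        return tuple(names)


@dataclass(frozen=True)
class DemographyPlan:
    """Single-epoch demography: ancestral size, post-change size, and spans.

    The burn-in lasts ``10 * N_anc`` generations; statistics are then recorded
    over ``4 * N_anc`` generations for constant-size models, or ``N_post``
    generations following the size change for expansion/contraction models.
    Spans may be overridden (e.g. a sweep model whose runtime is determined by
    fixation rather than a fixed span); the canonical values come from
    :meth:`for_sizes`.
    """

    N_anc: int
    N_post: int
    burn_in_generations: int
    recording_generations: int

    def __post_init__(self) -> None:
        if self.N_anc < 2 or self.N_post < 2:
            raise ValueError("population sizes must be >= 2")
        if self.burn_in_generations < 0 or self.recording_generations < 0:
            raise ValueError("generation spans must be >= 0")

    @classmethod
    def for_sizes(cls, N_anc: int, N_post: Optional[int] = None) -> "DemographyPlan":
        """Build the canonical plan: burn-in 10*N_anc, then 4*N_anc (constant)
        or N_post (size-change) recording generations."""
        if N_post is None:
            N_post = N_anc
        rec = 4 * N_anc if N_post == N_anc else N_post
        return cls(N_anc=N_anc, N_post=N_post, burn_in_generations=10 * N_anc,
                   recording_generations=rec)

    @property
    def is_canonical(self) -> bool:
        ref = DemographyPlan.for_sizes(self.N_anc, self.N_post)
        return (self.burn_in_generations == ref.burn_in_generations
                and self.recording_generations == ref.recording_generations)


@dataclass(frozen=True)
class SweepPlan:
    """A single conditional selective sweep.

    When enabled, one beneficial mutation with coefficient ``s_sweep`` is
    introduced (mid-genome unless ``position`` is given) after the burn-in.
    With ``condition_on_fixation`` the simulation is reset and re-run from the
    introduction point whenever the mutation is lost, so every retained
    replicate ends in fixation.
    """

    enabled: bool = False
    s_sweep: float = 0.0
    position: Optional[int] = None
    condition_on_fixation: bool = True

    def __post_init__(self) -> None:
        if self.enabled and not self.s_sweep > 0:
            raise ValueError("s_sweep must be > 0 when the sweep is enabled")


def _neutral() -> FitnessEffectDistribution:
    return FitnessEffectDistribution(kind="neutral")


@dataclass(frozen=True)
class ModelSpec:
    """Complete specification of one (scaled or unscaled) simulation model."""

    label: str
    L: int
    mu: float
    r: float
    mix: MutationClassMix
    demography: DemographyPlan
    dfe_neutral: FitnessEffectDistribution = field(default_factory=_neutral)
    dfe_beneficial: FitnessEffectDistribution = field(default_factory=_neutral)
    dfe_deleterious: FitnessEffectDistribution = field(default_factory=_neutral)
    h: float = 0.5
    sweep: SweepPlan = field(default_factory=SweepPlan)
    Q_applied: float = 1.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")
        if self.Q_applied < 1:
            raise ValueError("Q_applied must be >= 1")

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate 4*N_anc*mu (per bp), invariant under rescaling."""
        return 4.0 * self.demography.N_anc * self.mu

    def dfe_for(self, mclass: str) -> FitnessEffectDistribution:
        if mclass == "neutral":
            return self.dfe_neutral
        if mclass == "beneficial":
            return self.dfe_beneficial
        if mclass == "deleterious":
            return self.dfe_deleterious
        raise KeyError(mclass)

    @property
    def sweep_position(self) -> int:
        if self.sweep.position is not None:
            return self.sweep.position
        return self.L // 2

    # -- JSON round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["mix"] = MutationClassMix(**d["mix"])
        d["demography"] = DemographyPlan(**d["demography"])
        for key in ("dfe_neutral", "dfe_beneficial", "dfe_deleterious"):
            if key in d:
                d[key] = FitnessEffectDistribution(**d[key])
        if "sweep" in d:
            d["sweep"] = SweepPlan(**d["sweep"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _divide_exact(n: int, Q: float, what: str) -> int:
    scaled = n / Q
    rounded = round(scaled)
    if abs(scaled - rounded) > 1e-9:
        raise ValueError(
            f"{what} = {n} is not divisible by Q = {Q}; rescaling requires an "
            f"integer result (no silent rounding). Pick a Q that divides {what} evenly."
        )
    return int(rounded)


def rescale_model(model: ModelSpec, Q: float) -> ModelSpec:
    """Return ``model`` rescaled by factor ``Q``.

    Population sizes are divided by Q (rejecting non-integer results), the
    mutation and recombination rates and all selection coefficients are
    multiplied by Q, and the burn-in and recording spans are divided by Q
    (recomputed from the scaled sizes when the spans follow the canonical
    rule).  ``theta = 4*N_anc*mu`` is identical before and after.
    """
    if model.Q_applied != 1:
        raise ValueError("model has already been rescaled (Q_applied != 1)")
    if Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q}")
    if Q == 1:
        return model

    N_anc = _divide_exact(model.demography.N_anc, Q, "N_anc")
    N_post = _divide_exact(model.demography.N_post, Q, "N_post")
    if N_anc < 2 or N_post < 2:
        raise ValueError("rescaled population size would fall below 2 individuals")

    if model.demography.is_canonical:
        demography = DemographyPlan.for_sizes(N_anc, N_post)
    else:
        demography = DemographyPlan(
            N_anc=N_anc,
            N_post=N_post,
            burn_in_generations=_divide_exact(
                model.demography.burn_in_generations, Q, "burn_in_generations"),
            recording_generations=_divide_exact(
                model.demography.recording_generations, Q, "recording_generations"),
        )

    sweep = model.sweep
    if sweep.enabled:
        sweep = replace(sweep, s_sweep=sweep.s_sweep * Q)

    return replace(
        model,
        mu=model.mu * Q,
        r=model.r * Q,
        demography=demography,
        dfe_neutral=model.dfe_neutral.rescaled(Q),
        dfe_beneficial=model.dfe_beneficial.rescaled(Q),
        dfe_deleterious=model.dfe_deleterious.rescaled(Q),
        sweep=sweep,
        Q_applied=Q,
    )


# ---------------------------------------------------------------------------
# Catalog models
# ---------------------------------------------------------------------------

# Human-like parameterization shared by most catalog models.
_HUMAN_N = 10_000
_HUMAN_MU = 1.2e-8
_HUMAN_R = 1.2e-8
_HUMAN_L = 25_000_000

# Drosophila melanogaster parameterization (species-catalog style).
_DMEL_N = 1_720_600
_DMEL_MU = 5.49e-9
_DMEL_R = 1.98e-8
_DMEL_L = 10_000

_GAMMA_DFE = FitnessEffectDistribution(kind="gamma", gamma_mean=-0.0294, gamma_shape=0.184)
_BENEFICIAL_FIXED = FitnessEffectDistribution(kind="fixed", s_fixed=0.05)
_DMEL_DEL = FitnessEffectDistribution(kind="lognormal", lognorm_mu=9.679e-7,
                                      lognorm_sigma=3.36, sign=-1)

_FULL_MIX = MutationClassMix(f_n=0.25, f_b=0.75 * 0.05, f_d=0.75 * 0.95)
_NO_BEN_MIX = MutationClassMix(f_n=0.25, f_b=0.0, f_d=0.75)
_SPARSE_MIX = MutationClassMix(f_n=0.95, f_b=0.0, f_d=0.05)
_NEUTRAL_MIX = MutationClassMix(f_n=1.0, f_b=0.0, f_d=0.0)
# The Drosophila class mix is not pinned by the source tables; 26% neutral with
# the selected remainder split 5% beneficial / 95% deleterious mirrors the
# structure of the full model at a catalog-style neutral fraction.
_DMEL_MIX = MutationClassMix(f_n=0.26, f_b=0.74 * 0.05, f_d=0.74 * 0.95)

CATALOG_NAMES = (
    "full",
    "no_beneficials",
    "no_beneficials_sparse",
    "no_beneficials_larger",
    "strictly_neutral",
    "expansion",
    "contraction",
    "sweep",
    "drosophila",
    "drosophila_strong",
)


def build_catalog_model(name: str, L: Optional[int] = None) -> ModelSpec:
    """Return the unscaled (Q_applied=1) spec for a named catalog model.

    ``L`` overrides the genome length (default 25 Mb for human-like models,
    10 kb for the Drosophila models); all other parameters are fixed by the
    catalog.
    """
    if name not in CATALOG_NAMES:
        raise ValueError(f"unknown catalog model {name!r}; valid names: {', '.join(CATALOG_NAMES)}")

    def human(mix, N=_HUMAN_N, N_post=None, dfe_b=_BENEFICIAL_FIXED, sweep=SweepPlan()):
        return ModelSpec(
            label=name,
            L=_HUMAN_L if L is None else L,
            mu=_HUMAN_MU,
            r=_HUMAN_R,
            mix=mix,
            demography=DemographyPlan.for_sizes(N, N_post),
            dfe_beneficial=dfe_b if mix.f_b > 0 or sweep.enabled else _neutral(),
            dfe_deleterious=_GAMMA_DFE if mix.f_d > 0 else _neutral(),
            h=0.5,
            sweep=sweep,
        )

    if name == "full":
        return human(_FULL_MIX)
    if name == "no_beneficials":
        return human(_NO_BEN_MIX)
    if name == "no_beneficials_sparse":
        return human(_SPARSE_MIX)
    if name == "no_beneficials_larger":
        return human(_NO_BEN_MIX, N=2 * _HUMAN_N)
    if name == "strictly_neutral":
        return human(_NEUTRAL_MIX)
    if name == "expansion":
        return human(_FULL_MIX, N=_HUMAN_N, N_post=2 * _HUMAN_N)
    if name == "contraction":
        return human(_FULL_MIX, N=_HUMAN_N, N_post=_HUMAN_N // 2)
    if name == "sweep":
        return human(_NEUTRAL_MIX,
                     sweep=SweepPlan(enabled=True, s_sweep=0.05, condition_on_fixation=True))

    dfe_b = FitnessEffectDistribution(
        kind="fixed", s_fixed=7.125e-6 if name == "drosophila" else 0.01)
    return ModelSpec(
        label=name,
        L=_DMEL_L if L is None else L,
        mu=_DMEL_MU,
        r=_DMEL_R,
        mix=_DMEL_MIX,
        demography=DemographyPlan.for_sizes(_DMEL_N),
        dfe_beneficial=dfe_b,
        dfe_deleterious=_DMEL_DEL,
        h=0.5,
    )
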