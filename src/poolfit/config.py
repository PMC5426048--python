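"""Configuration objects for the pool-growth simulator and the pipeline.

A pooled hemizygote fitness screen co-grows thousands of barcoded strains in
one culture kept in exponential phase by serial back-dilution.  Strain ``i``
has relative fitness ``gamma_i`` expressed in doublings per *pool generation*
(one doubling of total pool biomass); ``gamma_i = 1`` is neutral.  Samples are
sequenced at scheduled pool generations and strain abundance is read out from
two independent barcodes (B1 = up-tag, B2 = down-tag) flanking the deletion
cassette.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

# Ten sampling points spaced 3-4 pool generations apart over 30 generations,
# mirroring the screen's serial-dilution sampling design.
DEFAULT_SCHEDULE: tuple[float, ...] = (0, 3, 6, 10, 13, 16, 20, 23, 26, 30)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class FitnessSpec:
    """Distribution of per-strain relative fitness values.

    A fraction ``fraction_affected`` of strains draw gamma uniformly from
    ``[effect_low, effect_high]``; the rest are neutral (gamma = 1).  Use
    ``fraction_affected=0`` for an all-neutral pool.
    """

    fraction_affected: float = 0.0
    effect_low: float = 0.7
    effect_high: float = 0.9

    def validate(self) -> None:
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ConfigurationError(
                f"fraction_affected must be in [0, 1], got {self.fraction_affected}"
            )
        if not 0.0 < self.effect_low <= self.effect_high:
            raise ConfigurationError(
                "effect range must satisfy 0 < low <= high, got "
                f"({self.effect_low}, {self.effect_high})"
            )


@dataclass(frozen=True)
class InitSpec:
    """Initial-proportion distribution across strains.

    ``kind='uniform'`` gives equal proportions; ``kind='lognormal'`` draws
    multiplicative factors exp(N(0, sigma^2)) and renormalizes, emulating the
    plate-pooling unevenness of a real library.
    """

    kind: str = "lognormal"
    sigma: float = 0.5

    def validate(self) -> None:
        if self.kind not in ("uniform", "lognormal"):
            raise ConfigurationError(f"unknown init_spec kind: {self.kind!r}")
        if self.kind == "lognormal" and self.sigma < 0:
            raise ConfigurationError("lognormal sigma must be >= 0")


@dataclass(frozen=True)
class TakeoverSpec:
    """Ethanol-style takeover regime: after pool generation ``g_star`` the
    majority of strains multiply their gamma by ``slowdown`` (< 1) while an
    unaffected minority (``survivor_fraction``) keeps growing and overtakes
    the pool."""

    g_star: float = 6.0
    slowdown: float = 0.2
    survivor_fraction: float = 0.02

    def validate(self) -> None:
        if self.g_star < 0:
            raise ConfigurationError("g_star must be >= 0")
        if not 0 < self.slowdown <= 1:
            raise ConfigurationError("slowdown must be in (0, 1]")
        if not 0 < self.survivor_fraction < 1:
            raise ConfigurationError("survivor_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic pooled-competition experiment."""

    n_strains: int = 1000
    fitness_spec: FitnessSpec = field(default_factory=FitnessSpec)
    init_spec: InitSpec = field(default_factory=InitSpec)
    schedule: Sequence[float] = DEFAULT_SCHEDULE
    depth: int = 1_000_000
    overdispersion: float | None = None  # Dirichlet concentration scale; None = pure multinomial
    bottleneck: int | None = None  # cells kept at each back-dilution; None = deterministic
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    barcode_len: int = 20
    tag_len: int = 5
    seq_error_rate: float = 0.0
    takeover: TakeoverSpec | None = None
    pool: str = "hybrid"
    condition: str = "YPD"
    seed: int = 0

    # explicit per-strain gammas override fitness_spec when provided
    gamma_overrides: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.n_strains <= 0:
            raise ConfigurationError("n_strains must be positive")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        sched = list(self.schedule)
        if not sched or sched[0] != 0:
            raise ConfigurationError("schedule must start at generation 0")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("schedule must be strictly increasing")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if not 0 <= self.seq_error_rate < 1:
            raise ConfigurationError("seq_error_rate must be in [0, 1)")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ConfigurationError("overdispersion concentration must be positive")
        if self.bottleneck is not None and self.bottleneck <= 0:
            raise ConfigurationError("bottleneck must be positive")
        self.fitness_spec.validate()
        self.init_spec.validate()
        if self.takeover is not None:
            self.takeover.validate()
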