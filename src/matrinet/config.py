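"""Configuration objects for the synthetic troop generator and the analysis pipeline.

All tunable quantities live here; nothing downstream hard-codes a protocol
constant. Defaults mirror the field protocol the pipeline targets: scan
sampling of 10 m proximity subgroups aggregated in 30-day periods, ad libitum
grooming with half-hour dyad deduplication, 95-observation period filter,
5-sighting individual filter, and a 300/200/100 permutation schedule with 20
checkerboard swaps per chain step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ImmatureSpec:
    """One immature to seed into a troop: age in months at simulation start."""

    age_months: float
    sex: str  # "F" or "M"
    matriline: int  # index of the natal matriline within the troop


@dataclass
class AttachmentParams:
    """Logit-scale model of the per-record probability that an immature is
    recorded together with its mother.

    logit P(with mother) = alpha + beta_age*age + beta_sex*male
                           + beta_age_sex*age*male      (age in months)

    Defaults are of the magnitude reported for wild chacma baboons: time with
    the mother declines with age and declines faster in males.
    """

    alpha: float = 1.1
    beta_age: float = -0.025
    beta_sex: float = -0.2
    beta_age_sex: float = -0.012

    def logit(self, age_months: float, is_male: bool) -> float:
        m = 1.0 if is_male else 0.0
        return (
            self.alpha
            + self.beta_age * age_months
            + self.beta_sex * m
            + self.beta_age_sex * age_months * m
        )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic troop generator.

    The generator produces multi-troop, multi-season observation streams with
    three built-in social forces, each switchable to zero:

    * social inheritance — an immature's association propensities are a
      mixture of its mother's row (weight ``w = lambda0 * exp(-(delta +
      delta_male*[male]) * age)``) and its own homophily kernel;
    * age homophily — a Gaussian kernel of age distance (bandwidth in months)
      plus a same-sex affinity that grows linearly with age;
    * mother attachment — the logit-linear model above, applied at the record
      level so the time-with-mother response is exactly binomial-logit.
    """

    # population structure (per troop)
    n_troops: int = 2
    n_matrilines: int = 5
    adults_per_matriline: int = 3
    adult_males_per_troop: int = 4
    immatures_per_troop: int = 12
    immatures: list[ImmatureSpec] | None = None  # explicit roster overrides count

    # observation calendar: (year, number of 30-day periods in that field
    # season); the gap year gives immatures a ~27-month longitudinal span
    seasons: list[tuple[int, int]] = field(default_factory=lambda: [(2019, 2), (2021, 3)])
    period_days: int = 30

    # sampling effort
    scans_per_individual_per_month: int = 14  # focal-list sweeps per 30-day period
    grooming_events_per_individual_per_month: int = 10

    # social inheritance
    lambda0: float = 0.9  # mixture weight at age 0, in [0, 1]
    delta: float = 0.05  # per-month decay of the inheritance weight
    delta_male: float = 0.01  # extra per-month decay for males

    # homophily kernel (entries are per-scan join probabilities; they compound
    # over ~2 x scans-per-month exposures per period, so they are kept small
    # enough that period-level networks stay realistically sparse)
    baseline: float = 0.004
    peer_affinity: float = 0.03
    age_bandwidth: float = 12.0  # months
    same_sex_slope: float = 0.0004  # per month of focal age

    # adult-adult association propensities
    within_matriline: float = 0.04
    between_matriline: float = 0.006
    adult_male_propensity: float = 0.008

    # mother attachment (record-level, logit scale)
    attachment: AttachmentParams = field(default_factory=AttachmentParams)

    # grooming: the mother dyad's event weight is
    # grooming_mother_weight * exp(attachment logit), so the share of an
    # immature's grooming involving the mother is logit-linear in age
    grooming_mother_weight: float = 0.5
    grooming_adult_within: float = 1.0
    grooming_adult_between: float = 0.15
    grooming_adult_male: float = 0.2

    # dominance
    dominance_steepness: float = 3.0
    interactions_per_dyad: int = 6

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_troops": self.n_troops,
            "n_matrilines": self.n_matrilines,
            "adults_per_matriline": self.adults_per_matriline,
            "scans_per_individual_per_month": self.scans_per_individual_per_month,
            "grooming_events_per_individual_per_month": self.grooming_events_per_individual_per_month,
            "period_days": self.period_days,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if not 0.0 <= self.lambda0 <= 1.0:
            raise ConfigurationError(f"lambda0 must be in [0, 1], got {self.lambda0}")
        if self.delta < 0 or self.delta_male < 0:
            raise ConfigurationError("delta and delta_male must be >= 0")
        if self.immatures is not None:
            for spec in self.immatures:
                if not 0 <= spec.matriline < self.n_matrilines:
                    raise ConfigurationError(
                        f"immature matriline {spec.matriline} outside 0..{self.n_matrilines - 1}"
                    )
                if spec.sex not in ("F", "M"):
                    raise ConfigurationError(f"immature sex must be F or M, got {spec.sex}")
        if not self.seasons:
            raise ConfigurationError("at least one season required")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seasons"] = [list(s) for s in self.seasons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "attachment" in d and isinstance(d["attachment"], dict):
            d["attachment"] = AttachmentParams(**d["attachment"])
        if "immatures" in d and d["immatures"] is not None:
            d["immatures"] = [
                ImmatureSpec(**s) if isinstance(s, dict) else ImmatureSpec(*s)
                for s in d["immatures"]
            ]
        if "seasons" in d:
            d["seasons"] = [tuple(s) for s in d["seasons"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def null_variant(self) -> "SimulationConfig":
        """A copy with every age/sex/inheritance effect switched off.

        Used for type-I-error calibration of the permutation machinery.
        """
        d = self.to_dict()
        d.update(
            lambda0=0.0,
            delta=0.0,
            delta_male=0.0,
            same_sex_slope=0.0,
            peer_affinity=0.0,
            attachment=dict(alpha=self.attachment.alpha, beta_age=0.0, beta_sex=0.0, beta_age_sex=0.0),
        )
        return SimulationConfig.from_dict(d)


@dataclass
class PermutationSchedule:
    """How many permuted networks to generate and keep per sampling period."""

    total: int = 300
    burn_in: int = 200
    swaps_per_step: int = 20  # datastream method only
    method: str = "datastream"  # or "node"
    rng_seed: int = 0

    @property
    def keep(self) -> int:
        return self.total - self.burn_in

    def __post_init__(self) -> None:
        if self.total <= 0 or self.burn_in < 0 or self.swaps_per_step <= 0:
            raise ConfigurationError("schedule counts must be positive")
        if self.burn_in >= self.total:
            raise ConfigurationError("burn_in must be < total")
        if self.method not in ("datastream", "node"):
            raise ConfigurationError(f"unknown permutation method {self.method!r}")


@dataclass
class FilterConfig:
    """Observation-count filters applied before network construction."""

    min_observations_per_period: int = 95
    min_sightings_per_season: int = 5


PEER_WINDOW_MONTHS = 6.0  # a peer is within +/- 6 months of the focal's age
IMMATURE_MAX_AGE_MONTHS = 60.0  # immature = 5 years old or less
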