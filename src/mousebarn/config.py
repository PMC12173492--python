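"""Configuration objects for the synthetic barn generator.

All rates are per-unit quantities with units stated in the field comments; the
defaults reproduce the statistical regularities of a high-density barn
population: stays that last about three minutes on average, crepuscular
activity peaks, roughly three vocalizations per recorded minute with squeaks
about ten times as common as ultrasonic calls, and an AudioMoth clock that
drifts a few seconds per day against the RFID system clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

SEASONS = ("spring", "summer", "autumn", "winter")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class SeasonParams:
    """Season-specific social and activity parameters.

    group_count
        Number of social groups planted in this season.
    mean_group_size
        Expected mice per group (population is split as evenly as possible).
    switch_rate
        Per-day probability that a mouse changes groups within the season.
    stay_rate
        Box stays per mouse per hour (time-averaged over the diel cycle).
    stay_duration_median
        Median stay duration in seconds (log-normal durations).
    stay_duration_sigma
        Log-scale standard deviation of stay durations.
    box_affinity
        Probability a stay is taken in one of the mouse's own group boxes
        rather than a uniformly random other box.
    """

    group_count: int = 4
    mean_group_size: float = 15.0
    switch_rate: float = 0.01
    stay_rate: float = 2.0
    stay_duration_median: float = 180.0
    stay_duration_sigma: float = 1.5
    box_affinity: float = 0.9

    def validate(self) -> None:
        if self.group_count < 1:
            raise ConfigurationError("group_count must be >= 1")
        if self.stay_rate < 0 or self.switch_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ConfigurationError("switch_rate is a probability")
        if self.stay_duration_median <= 0:
            raise ConfigurationError("stay_duration_median must be > 0")
        if self.stay_duration_sigma < 0:
            raise ConfigurationError("stay_duration_sigma must be >= 0")
        if not 0.0 <= self.box_affinity <= 1.0:
            raise ConfigurationError("box_affinity is a probability")


@dataclass
class VocalParams:
    """Vocal event-stream parameters.

    lambda0
        Baseline vocalizations per 55 s recorded segment.
    lambda_event
        Added event rate (events/s) at a box entrance or exit, decaying
        exponentially with timescale ``tau_event`` seconds on both sides of
        the kernel peak, which sits ``lag_event`` seconds after the box event.
    beta_pup
        Log-rate increase per pup present in the recorded box.
    squeak_usv_ratio
        Expected squeaks per USV among single-call bouts.
    q_joint
        Probability a vocal bout emits both a squeak and a USV inside the
        same recorded segment.
    gamma_pair
        Coupling strength between a pair's shared latent state and both its
        meeting durations and its vocal rate during meetings.
    """

    lambda0: float = 3.0
    lambda_event: float = 0.2
    tau_event: float = 5.0
    lag_event: float = 0.0
    beta_pup: float = 0.5
    # single-call ratio of 20 with q_joint = 0.05 gives an emergent overall
    # squeak:USV ratio close to 10, since every joint bout adds one of each
    squeak_usv_ratio: float = 20.0
    q_joint: float = 0.05
    gamma_pair: float = 0.5

    def validate(self) -> None:
        for name in ("lambda0", "lambda_event", "tau_event", "beta_pup",
                     "squeak_usv_ratio"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.q_joint <= 1.0:
            raise ConfigurationError("q_joint is a probability")


def _default_season_params() -> dict[str, SeasonParams]:
    # Groups are larger and stickier in autumn/winter, smaller and more
    # dynamic in spring/summer.
    return {
        "spring": SeasonParams(group_count=5, mean_group_size=12.0,
                               switch_rate=0.02),
        "summer": SeasonParams(group_count=5, mean_group_size=12.0,
                               switch_rate=0.02,
                               stay_duration_median=150.0),
        "autumn": SeasonParams(group_count=4, mean_group_size=15.0,
                               switch_rate=0.01),
        "winter": SeasonParams(group_count=3, mean_group_size=20.0,
                               switch_rate=0.005,
                               stay_duration_median=240.0),
    }


@dataclass
class SyntheticConfig:
    """Full configuration of the synthetic barn.

    diel_peaks are (hour-of-day, gaussian width in hours) pairs for the two
    crepuscular activity bumps over a uniform floor.
    """

    n_mice: int = 60
    n_boxes: int = 16
    box_grid_spacing: float = 2.0
    season_params: Mapping[str, SeasonParams] = field(
        default_factory=_default_season_params)
    diel_peaks: tuple[tuple[float, float], ...] = ((6.0, 2.0), (20.0, 2.0))
    diel_floor: float = 0.3
    vocal_params: VocalParams = field(default_factory=VocalParams)
    drift_rate: float = 2.0  # seconds of AudioMoth drift per day
    seed: int = 0

    def validate(self) -> None:
        if self.n_mice < 2 or self.n_boxes < 2:
            raise ConfigurationError("need n_mice >= 2 and n_boxes >= 2")
        if self.box_grid_spacing <= 0:
            raise ConfigurationError("box_grid_spacing must be > 0")
        missing = set(SEASONS) - set(self.season_params)
        if missing:
            raise ConfigurationError(
                f"season_params missing seasons: {sorted(missing)}")
        for sp in self.season_params.values():
            sp.validate()
        self.vocal_params.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "season_params" in d:
            d["season_params"] = {
                k: SeasonParams(**v) if not isinstance(v, SeasonParams) else v
                for k, v in d["season_params"].items()
            }
        if "vocal_params" in d and not isinstance(d["vocal_params"], VocalParams):
            d["vocal_params"] = VocalParams(**d["vocal_params"])
        if "diel_peaks" in d:
            d["diel_peaks"] = tuple(tuple(p) for p in d["diel_peaks"])
        return cls(**d)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one root seed.

    Each module of the generator draws from its own substream so components
    can be regenerated independently of one another.
    """
    child = np.random.SeedSequence(
        [seed, int.from_bytes(name.encode(), "little") % (2**31)])
    return np.random.default_rng(child)
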