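"""Synthetic 8-week, 4-arm electrode-activity study.

Each arm carries a mean weekly probability that a channel is active
(holds >= 1 unit) in each of two phases: weeks 1-4 and weeks 5-8.  Within a
phase the weekly probability ramps linearly with slope (p2 - p1)/4 per
week, centred so the phase mean equals the configured value exactly — the
study reports phase aggregates, so only phase means are treated as truths.
A small fraction of channels malfunctions from the outset and is inactive
(and flagged) in every week.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from imequant.yield_stats import STUDY_COLUMNS

__all__ = ["ArmSpec", "StudyConfig", "DEFAULT_ARMS", "gen_study", "weekly_probabilities"]


@dataclass(frozen=True)
class ArmSpec:
    name: str
    n_animals: int
    p_active_phase1: float  # mean weekly P(channel active), weeks 1-4
    p_active_phase2: float  # weeks 5-8
    p_dead_channel: float = 0.045
    units_per_active_channel: float = 1.8

    def __post_init__(self) -> None:
        for p in (self.p_active_phase1, self.p_active_phase2, self.p_dead_channel):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        if self.n_animals < 1:
            raise ValueError("each arm needs at least one animal")


#: Arm trajectories calibrated so the phase declines are 17% (DEXSPPIN),
#: 25% (PIN), 37% (DILUENT) and 54% (Free DEXSP), with the treated arm's
#: proportions 36% (phase 1) and ~80% (phase 2) above the vehicle arm's.
DEFAULT_ARMS = [
    ArmSpec("DEXSPPIN", n_animals=7, p_active_phase1=0.610, p_active_phase2=0.506),
    ArmSpec("PIN", n_animals=7, p_active_phase1=0.520, p_active_phase2=0.390),
    ArmSpec("DILUENT", n_animals=7, p_active_phase1=0.450, p_active_phase2=0.2835),
    ArmSpec("FreeDEXSP", n_animals=8, p_active_phase1=0.470, p_active_phase2=0.216),
]


@dataclass
class StudyConfig:
    arms: list[ArmSpec] = field(default_factory=lambda: list(DEFAULT_ARMS))
    weeks: int = 8
    channels_per_animal: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weeks < 2:
            raise ValueError("study needs at least 2 weeks")
        if not self.arms:
            raise ValueError("study needs at least one arm")


def weekly_probabilities(arm: ArmSpec, weeks: int) -> np.ndarray:
    """Per-week activity probability: linear ramp within each phase.

    Phase 1 is the first half of the study, phase 2 the second; each
    phase's mean equals the ArmSpec value.
    """
    half = weeks // 2
    slope = (arm.p_active_phase2 - arm.p_active_phase1) / half
    w = np.arange(1, weeks + 1, dtype=float)
    p = np.where(
        w <= half,
        arm.p_active_phase1 + slope * (w - (half + 1) / 2.0),
        arm.p_active_phase2 + slope * (w - (half + half + 1 + weeks) / 2.0 + half / 2.0),
    )
    return np.clip(p, 0.0, 1.0)


@dataclass
class StudyGroundTruth:
    weekly_p: dict[str, np.ndarray]
    dead_channels: pd.DataFrame  # arm, animal, channel


def gen_study(config: StudyConfig) -> tuple[pd.DataFrame, StudyGroundTruth]:
    """Draw one study realisation as a tidy table plus its ground truth.

    One record per (arm, animal, channel, week): the active flag is
    Bernoulli in the arm's weekly probability; active channels carry a
    shifted-Poisson unit count (>= 1) whose mean is the arm's
    units-per-active-channel.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    weekly_p: dict[str, np.ndarray] = {}
    dead_rows = []
    for arm in config.arms:
        p = weekly_probabilities(arm, config.weeks)
        weekly_p[arm.name] = p
        for animal in range(arm.n_animals):
            dead = rng.random(config.channels_per_animal) < arm.p_dead_channel
            for channel in range(config.channels_per_animal):
                if dead[channel]:
                    dead_rows.append(dict(arm=arm.name, animal=animal, channel=channel))
                active_draws = rng.random(config.weeks) < p
                extra_units = rng.poisson(
                    max(arm.units_per_active_channel - 1.0, 0.0), size=config.weeks
                )
                for wi in range(config.weeks):
                    is_active = bool(active_draws[wi]) and not dead[channel]
                    rows.append(
                        dict(
                            arm=arm.name,
                            animal=animal,
                            channel=channel,
                            week=wi + 1,
                            active=is_active,
                            n_units=int(1 + extra_units[wi]) if is_active else 0,
                            dead_from_outset=bool(dead[channel]),
                        )
                    )
    table = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    truth = StudyGroundTruth(
        weekly_p=weekly_p,
        dead_channels=pd.DataFrame(dead_rows, columns=["arm", "animal", "channel"]),
    )
    return table, truth
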