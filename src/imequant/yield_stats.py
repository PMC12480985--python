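"""Active-electrode-yield (AEY) statistics for a multi-week, multi-arm study.

Operates on a tidy study table with one record per (arm, animal, channel,
week) carrying an ``active`` flag (did the channel hold at least one
isolated single unit that week) and a unit count.  A channel is *viable*
unless it malfunctioned from the outset or was never active in any week of
the study; AEY is active viable channels over viable channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AeyResult",
    "ZTestResult",
    "validate_study_table",
    "viable_channels",
    "weekly_aey",
    "phase_proportion",
    "phase_decline",
    "two_prop_ztest",
    "units_per_active_channel",
]

STUDY_COLUMNS = ["arm", "animal", "channel", "week", "active", "n_units", "dead_from_outset"]


@dataclass(frozen=True)
class AeyResult:
    arm: str
    label: str  # week number or phase label, e.g. "week3" / "W1-4"
    n_active: int
    n_viable: int

    @property
    def aey(self) -> float:
        return self.n_active / self.n_viable if self.n_viable else float("nan")


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p: float
    p1: float
    p2: float


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy study-table contract: required columns, one record per key."""
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    key = ["arm", "animal", "channel", "week"]
    if table.duplicated(key).any():
        raise ValueError("study table has duplicate (arm, animal, channel, week) records")
    return table


def viable_channels(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-arm set of viable (animal, channel) pairs.

    Excludes channels flagged as malfunctioning from the outset and channels
    that were never active in any week of the entire study.
    """
    validate_study_table(table)
    out: dict[str, pd.DataFrame] = {}
    for arm, sub in table.groupby("arm", sort=False):
        per_chan = sub.groupby(["animal", "channel"]).agg(
            ever_active=("active", "any"), dead=("dead_from_outset", "any")
        )
        viable = per_chan[per_chan["ever_active"] & ~per_chan["dead"]]
        out[str(arm)] = viable.reset_index()[["animal", "channel"]]
    return out


def _viable_subset(table: pd.DataFrame, arm: str, viable: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["arm"] == arm]
    return sub.merge(viable, on=["animal", "channel"], how="inner")


def weekly_aey(
    table: pd.DataFrame, week: int, viable: dict[str, pd.DataFrame] | None = None
) -> list[AeyResult]:
    """AEY for one week: active viable channels / viable channels, per arm."""
    viable = viable if viable is not None else viable_channels(table)
    results = []
    for arm, vset in viable.items():
        sub = _viable_subset(table, arm, vset)
        wk = sub[sub["week"] == week]
        results.append(
            AeyResult(arm=arm, label=f"week{week}", n_active=int(wk["active"].sum()),
                      n_viable=len(vset))
        )
    return results


def phase_proportion(
    table: pd.DataFrame, weeks: list[int], viable: dict[str, pd.DataFrame] | None = None
) -> list[AeyResult]:
    """Pooled active proportion over a phase (e.g. weeks 1-4).

    Numerator: active viable channel-weeks summed over the phase.
    Denominator: viable channels x number of weeks in the phase.
    """
    if not weeks:
        raise ValueError("phase must contain at least one week")
    study_weeks = set(table["week"].unique())
    if not set(weeks) <= study_weeks:
        raise ValueError(f"phase weeks {sorted(set(weeks) - study_weeks)} not in study")
    viable = viable if viable is not None else viable_channels(table)
    label = f"W{min(weeks)}-{max(weeks)}"
    results = []
    for arm, vset in viable.items():
        sub = _viable_subset(table, arm, vset)
        ph = sub[sub["week"].isin(weeks)]
        results.append(
            AeyResult(arm=arm, label=label, n_active=int(ph["active"].sum()),
                      n_viable=len(vset) * len(weeks))
        )
    return results


def phase_decline(p1: float, p2: float) -> float:
    """Percent decline from the phase-1 to the phase-2 active proportion."""
    if p1 <= 0:
        raise ValueError("phase-1 proportion must be positive")
    return 100.0 * (p1 - p2) / p1


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Two-sided two-proportion z-test with pooled variance, no continuity correction.

    z = (p1 - p2) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n2)),
    p_pool = (x1 + x2) / (n1 + n2).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        z = 0.0
    else:
        z = (p1 - p2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return ZTestResult(z=float(z), p=float(p), p1=p1, p2=p2)


def units_per_active_channel(
    table: pd.DataFrame, weeks: list[int], viable: dict[str, pd.DataFrame] | None = None
) -> pd.DataFrame:
    """Mean units per week for each channel active at least once in the phase.

    Returns a tidy frame (arm, animal, channel, units_per_week); channels
    with no active week inside the phase are excluded from the statistic.
    """
    if not weeks:
        raise ValueError("phase must contain at least one week")
    viable = viable if viable is not None else viable_channels(table)
    frames = []
    for arm, vset in viable.items():
        ph = _viable_subset(table, arm, vset)
        ph = ph[ph["week"].isin(weeks)]
        per_chan = ph.groupby(["animal", "channel"]).agg(
            total_units=("n_units", "sum"), any_active=("active", "any")
        )
        per_chan = per_chan[per_chan["any_active"]]
        df = per_chan.reset_index()
        df["arm"] = arm
        df["units_per_week"] = df["total_units"] / len(weeks)
        frames.append(df[["arm", "animal", "channel", "units_per_week"]])
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["arm", "animal", "channel", "units_per_week"]
    )
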