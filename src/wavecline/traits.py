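"""Derived traits: shape/area ratios and maximum resisted flow velocity.

Raw morphometrics (areas in mm², lengths in mm) become size-independent
ratios: relative foot area RFA = FA/SA, relative outer/inner aperture areas
ROA = OA/SA and RIA = IA/SA, shell globosity S1 = L1/W1 and lateral
compression S2 = L2/W2.  Shell area SA itself is kept as the size proxy.

Flume trials run on a discrete valve-level ladder (free-stream velocities
0.75, 1.42, 1.88, 2.54, 2.69 m/s at levels 1–5 by default).  A snail faces
three 4-second flushes per level, escalating until dislodged; transect
snails go through two such rounds and are scored by the maximum velocity
resisted in either round.  "Resisting" a level means surviving all three of
its flushes.  Snails that survive level 5 are right-censored at the top of
the ladder; snails dislodged within level 1 in every round resisted nothing
on the ladder and are scored 0 m/s, left-censored.  Because drag scales with
the square of water velocity, analyses downstream use the squared maximum
velocity (SFR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlumeConfig",
    "ResistanceSummary",
    "derive_traits",
    "derive_traits_table",
    "max_resisted_velocity",
    "resistance_table",
    "filter_cohort",
]

MORPH_COLUMNS = ["SA_mm2", "OA_mm2", "IA_mm2", "FA_mm2", "L1_mm", "W1_mm", "L2_mm", "W2_mm"]
TRAIT_COLUMNS = ["RFA", "ROA", "RIA", "S1", "S2", "SA"]


@dataclass(frozen=True)
class FlumeConfig:
    """Valve-level → free-stream velocity map (m/s) and flushes per level."""

    level_velocities: dict[int, float] = field(
        default_factory=lambda: {1: 0.75, 2: 1.42, 3: 1.88, 4: 2.54, 5: 2.69})
    flushes_per_level: int = 3

    def __post_init__(self):
        levels = sorted(self.level_velocities)
        vels = [self.level_velocities[l] for l in levels]
        if any(b <= a for a, b in zip(vels, vels[1:])):
            raise ValueError("level velocities must be strictly increasing")

    @property
    def levels(self) -> list[int]:
        return sorted(self.level_velocities)

    @property
    def max_velocity(self) -> float:
        return self.level_velocities[self.levels[-1]]

    @property
    def ladder(self) -> list[float]:
        return [self.level_velocities[l] for l in self.levels]


@dataclass(frozen=True)
class ResistanceSummary:
    """max_velocity (m/s), its square SFR (m²/s²), and the censoring side."""

    max_velocity: float
    censoring: str  # "left", "none" or "right"

    @property
    def sfr(self) -> float:
        return self.max_velocity**2


def derive_traits(raw) -> dict[str, float]:
    """Compute the five ratios (and carry SA) from one morphometry record.

    ``raw`` is a mapping/Series with SA_mm2, OA_mm2, IA_mm2, FA_mm2 (may be
    NaN), L1_mm, W1_mm, L2_mm, W2_mm.  A missing foot area yields RFA = NaN —
    the record stays usable for the analyses that do not need the foot.
    """
    sa, oa, ia = float(raw["SA_mm2"]), float(raw["OA_mm2"]), float(raw["IA_mm2"])
    l1, w1, l2, w2 = (float(raw[k]) for k in ("L1_mm", "W1_mm", "L2_mm", "W2_mm"))
    fa = float(raw["FA_mm2"]) if "FA_mm2" in raw and pd.notna(raw["FA_mm2"]) else np.nan
    for name, v in (("SA_mm2", sa), ("OA_mm2", oa), ("IA_mm2", ia),
                    ("L1_mm", l1), ("W1_mm", w1), ("L2_mm", l2), ("W2_mm", w2)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be a positive finite number, got {v}")
    if not np.isnan(fa) and fa <= 0:
        raise ValueError("FA_mm2 must be positive when present")
    if ia > oa:
        raise ValueError("inner aperture area cannot exceed outer aperture area")
    return {
        "RFA": fa / sa,
        "ROA": oa / sa,
        "RIA": ia / sa,
        "S1": l1 / w1,
        "S2": l2 / w2,
        "SA": sa,
    }


def derive_traits_table(morph: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`derive_traits`; keeps ``snail_id``."""
    out = pd.DataFrame([derive_traits(row) for _, row in morph.iterrows()])
    if "snail_id" in morph.columns:
        out.insert(0, "snail_id", morph["snail_id"].to_numpy())
    return out


def _round_score_level(rnd: pd.DataFrame, config: FlumeConfig) -> int:
    """Highest level fully resisted in one round (0 = dislodged within level 1)."""
    levels = rnd["level"].to_numpy()
    if np.any(np.diff(levels) < 0):
        raise ValueError("levels must be non-decreasing within a round")
    dis = rnd["dislodged"].to_numpy().astype(bool)
    if dis.any():
        first = int(np.argmax(dis))
        if first != len(dis) - 1:
            raise ValueError("records found after a dislodgement within a round")
    resisted = 0
    for level in config.levels:
        at = rnd[rnd["level"] == level]
        if len(at) == config.flushes_per_level and not at["dislodged"].any():
            resisted = level
        else:
            break
    return resisted


def max_resisted_velocity(log: pd.DataFrame, config: FlumeConfig = FlumeConfig()
                          ) -> ResistanceSummary:
    """Score one snail's trial log by the maximum-of-rounds rule.

    ``log`` is long-format with columns round, level, flush, dislodged — the
    records of a single snail.  Each round contributes the velocity of the
    highest level whose flushes were all survived; the summary is the best
    round.  Censoring is "right" when the top of the ladder was survived and
    "left" when both rounds ended inside level 1 (scored 0.0 m/s).
    """
    if len(log) == 0:
        raise ValueError("empty trial log")
    best = 0
    for _, rnd in log.sort_values(["round", "level", "flush"]).groupby("round"):
        best = max(best, _round_score_level(rnd, config))
    if best == 0:
        return ResistanceSummary(0.0, "left")
    vel = config.level_velocities[best]
    censoring = "right" if best == config.levels[-1] else "none"
    return ResistanceSummary(vel, censoring)


def resistance_table(trials: pd.DataFrame, config: FlumeConfig = FlumeConfig()
                     ) -> pd.DataFrame:
    """Per-snail resistance summary from a long trial table (many snails)."""
    rows = []
    for snail_id, log in trials.groupby("snail_id", sort=True):
        summary = max_resisted_velocity(log, config)
        rows.append({
            "snail_id": snail_id,
            "max_velocity_ms": summary.max_velocity,
            "SFR": summary.sfr,
            "censoring": summary.censoring,
        })
    return pd.DataFrame(rows)


def filter_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into analysable snails and exclusions with reasons.

    Non-attachers (``attached`` falsy) are dropped outright, mirroring the
    field protocol where a snail that never gripped the pipe measures
    nothing.  Snails with missing foot area are kept but flagged
    (``fa_available`` False) so foot-area analyses can exclude them without
    losing the snail elsewhere.

    Returns ``(kept, excluded)``; ``excluded`` carries a ``reason`` column.
    """
    df = records.copy()
    attached = df["attached"].astype(bool) if "attached" in df.columns else pd.Series(
        True, index=df.index)
    excluded = df.loc[~attached].copy()
    excluded["reason"] = "did_not_attach"
    kept = df.loc[attached].copy()
    if "FA_mm2" in kept.columns:
        kept["fa_available"] = kept["FA_mm2"].notna()
    elif "RFA" in kept.columns:
        kept["fa_available"] = kept["RFA"].notna()
    else:
        kept["fa_available"] = True
    return kept, excluded
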