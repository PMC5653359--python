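"""Distance-weighted fucoid coverage, the wave-exposure proxy.

Fucoid seaweeds only persist where wave action is moderate, so the local
density of fucoids is an integrated, inverse proxy for wave exposure.  A
field survey scores presence (1) or absence (0) of fucoids in small quadrats
scattered over the shore; the coverage index at any focal point is the
weighted average of those scores, with weight falling linearly from 1 at the
focal point to 0 at ``radius`` metres (4 m by default).

Points at or beyond the radius get zero weight.  If no survey point carries
positive weight the index is undefined at that focal point and is returned
as NaN — never silently as 0, which would read as "fucoids absent".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FucoidSurvey", "ExposureConfig", "fucoid_coverage", "coverage_table"]

DEFAULT_RADIUS_M = 4.0


@dataclass(frozen=True)
class ExposureConfig:
    """radius: distance (m) at which a survey point's weight reaches zero."""

    radius: float = DEFAULT_RADIUS_M

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("radius must be positive")


class FucoidSurvey:
    """Presence/absence survey: (n, 2) coordinates and binary scores."""

    def __init__(self, points, scores):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        sc = np.asarray(scores, dtype=float).ravel()
        if pts.shape[0] == 0:
            raise ValueError("survey must contain at least one point")
        if pts.shape[0] != sc.shape[0]:
            raise ValueError("points and scores must align")
        if not np.all(np.isin(sc, (0.0, 1.0))):
            raise ValueError("scores must be strictly binary (0/1)")
        self.points = pts
        self.scores = sc

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FucoidSurvey":
        return cls(df[["x_m", "y_m"]].to_numpy(), df["presence"].to_numpy())

    def __len__(self) -> int:
        return len(self.scores)


def fucoid_coverage(survey: FucoidSurvey, focal,
                    config: ExposureConfig = ExposureConfig()) -> float:
    """Weighted-average fucoid presence around ``focal``.

    coverage = sum_i w_i s_i / sum_i w_i with w_i = max(0, 1 - d_i / radius).
    Returns NaN when every survey point lies at or beyond the radius.
    """
    focal = np.asarray(focal, dtype=float)
    d = np.linalg.norm(survey.points - focal, axis=1)
    w = np.maximum(0.0, 1.0 - d / config.radius)
    wsum = w.sum()
    if wsum == 0.0:
        return float("nan")
    return float(np.dot(w, survey.scores) / wsum)


def coverage_table(survey: FucoidSurvey, focal_points,
                   config: ExposureConfig = ExposureConfig()) -> pd.DataFrame:
    """Coverage at each row of ``focal_points`` ((m, 2) array or DataFrame).

    The ``coverage_defined`` column flags focal points with any in-radius
    survey support; undefined rows carry NaN coverage.
    """
    if isinstance(focal_points, pd.DataFrame):
        pts = focal_points[["x_m", "y_m"]].to_numpy(dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(focal_points, dtype=float))
    cov = np.array([fucoid_coverage(survey, p, config) for p in pts])
    return pd.DataFrame({
        "x_m": pts[:, 0],
        "y_m": pts[:, 1],
        "coverage": cov,
        "coverage_defined": ~np.isnan(cov),
    })
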