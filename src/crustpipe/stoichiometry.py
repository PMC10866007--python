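"""Ecoenzymatic stoichiometry and the vector model of nutrient limitation.

Four hydrolytic enzymes index microbial resource acquisition:
beta-1,4-glucosidase (BG, carbon), leucine aminopeptidase (LAP) and
beta-1,4-N-acetylglucosaminidase (NAG, nitrogen) and acid phosphatase
(AP, phosphorus).  Stoichiometric ratios are quotients of natural logs,
ln(BG) : ln(LAP+NAG), ln(BG) : ln(AP) and ln(LAP+NAG) : ln(AP).

The vector model places each sample at

    x = BG / (BG + AP),    y = BG / (BG + LAP + NAG)

with vector length sqrt(x^2 + y^2) indexing relative C limitation and the
vector angle atan2-style, degrees(arctan(y / x)), separating N limitation
(angle < 45 deg) from P limitation (angle > 45 deg).  Larger AP relative
to N-acquisition enzymes pushes the angle above 45 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ANGLE_BOUNDARY_DEG = 45.0
_BALANCED_TOL = 1e-9


class StoichiometryError(ValueError):
    """Raised for activity profiles outside the model's domain."""


@dataclass(frozen=True)
class ActivityProfile:
    """Per-sample enzyme activities, nmol g^-1 dry soil h^-1 (all > 0)."""

    sample_id: str
    BG: float
    LAP: float
    NAG: float
    AP: float

    def __post_init__(self) -> None:
        for enz in ("BG", "LAP", "NAG", "AP"):
            v = getattr(self, enz)
            if not (math.isfinite(v) and v > 0):
                raise StoichiometryError(
                    f"{self.sample_id}: {enz} activity must be finite and > 0, got {v}"
                )


@dataclass(frozen=True)
class StoichRatios:
    sample_id: str
    CN: float | None  # ln(BG) / ln(LAP + NAG)
    CP: float | None  # ln(BG) / ln(AP)
    NP: float | None  # ln(LAP + NAG) / ln(AP)
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class LimitationVector:
    sample_id: str
    x: float
    y: float
    length: float
    angle: float  # degrees
    limitation_class: str  # N-limited | P-limited | balanced

    @property
    def c_limitation_magnitude(self) -> float:
        return self.length


def _log_ratio(num: float, den: float) -> tuple[float | None, str | None]:
    """ln(num)/ln(den), or (None, flag) when the quotient is undefined."""
    if num <= 0 or den <= 0:
        return None, "nonpositive_activity"
    ld = math.log(den)
    if ld == 0.0:
        return None, "log_denominator_zero"
    return math.log(num) / ld, None


def stoich_ratios(p: ActivityProfile) -> StoichRatios:
    """Enzyme C:N, C:P and N:P stoichiometric ratios for one sample.

    A ratio whose log denominator is zero (activity exactly 1) is omitted
    and the sample flagged rather than reported as +-inf.
    """
    n_sum = p.LAP + p.NAG
    flags: list[str] = []
    out = {}
    for name, (num, den) in {
        "CN": (p.BG, n_sum),
        "CP": (p.BG, p.AP),
        "NP": (n_sum, p.AP),
    }.items():
        val, flag = _log_ratio(num, den)
        out[name] = val
        if flag:
            flags.append(f"{name}:{flag}")
    return StoichRatios(sample_id=p.sample_id, flags=tuple(flags), **out)


def classify_limitation(angle_deg: float, tol: float = _BALANCED_TOL) -> str:
    """N-limited below 45 deg, P-limited above, balanced at the boundary."""
    if abs(angle_deg - ANGLE_BOUNDARY_DEG) <= tol:
        return "balanced"
    return "N-limited" if angle_deg < ANGLE_BOUNDARY_DEG else "P-limited"


def limitation_vector(p: ActivityProfile) -> LimitationVector:
    """Vector-model coordinates, length, angle and limitation class."""
    x = p.BG / (p.BG + p.AP)
    y = p.BG / (p.BG + p.LAP + p.NAG)
    length = math.hypot(x, y)
    angle = math.degrees(math.atan2(y, x))
    return LimitationVector(
        sample_id=p.sample_id,
        x=x,
        y=y,
        length=length,
        angle=angle,
        limitation_class=classify_limitation(angle),
    )


def group_vector_summary(
    vectors: list[LimitationVector], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-group mean +- sd of vector length and angle.

    ``metadata`` is indexed by sample_id with a ``group`` column.  Vectors
    are computed per sample first and averaged afterwards, so the sd is a
    genuine between-replicate spread.  Groups with fewer than two samples
    get NaN sd and an ``sd_omitted`` flag.  The returned frame is sorted
    by mean length descending, so the first row is the group with the
    strongest relative C limitation (longest vector).
    """
    rows = []
    for v in vectors:
        if v.sample_id not in metadata.index:
            raise StoichiometryError(f"sample {v.sample_id} missing from metadata")
        rows.append(
            {
                "sample_id": v.sample_id,
                "group": metadata.loc[v.sample_id, "group"],
                "length": v.length,
                "angle": v.angle,
            }
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("group").agg(
        n=("length", "size"),
        length_mean=("length", "mean"),
        length_sd=("length", lambda s: s.std(ddof=1)),
        angle_mean=("angle", "mean"),
        angle_sd=("angle", lambda s: s.std(ddof=1)),
    )
    agg["flags"] = np.where(agg["n"] < 2, "sd_omitted", "")
    agg["limitation_class"] = [classify_limitation(a) for a in agg["angle_mean"]]
    return agg.sort_values("length_mean", ascending=False)
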