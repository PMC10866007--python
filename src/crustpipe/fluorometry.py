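"""Fluorometric extracellular enzyme activity (EEA) calculation.

Soil suspensions are incubated with methylumbelliferone (MU)- or
methylcoumarin-linked substrates in black 96-well plates.  Each sample ×
enzyme assay carries six well roles, eight replicate wells each:

* ``assay`` — soil suspension + substrate (mean fluorescence *f*)
* ``sample_control`` — soil suspension only (*fb*)
* ``quench_control`` — soil suspension + fluorophore standard (*fq*)
* ``reference_standard`` — fluorophore standard in buffer (*fr*)
* ``negative_control`` — substrate in buffer, no soil (*fs*)
* ``blank`` — buffer only (not used numerically, retained for QC)

The quench coefficient ``q = (fq - fb) / fr`` corrects for fluorescence
suppression by the soil suspension, the emission coefficient
``e = fr / (c * V2)`` converts fluorescence units to nmol of fluorophore,
the corrected fluorescence is ``F = (f - fb) / q - fs`` and the activity

    Ab = F * V / (e * V1 * t * m)      [nmol g^-1 dry soil h^-1]

with V the suspension volume, V1 the per-well aliquot, t the incubation
time and m the dry mass of the soil aliquot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

ROLES = (
    "assay",
    "sample_control",
    "quench_control",
    "reference_standard",
    "negative_control",
    "blank",
)

#: roles whose well means enter the activity formulas, keyed by symbol
_SYMBOL_BY_ROLE = {
    "assay": "f",
    "sample_control": "fb",
    "quench_control": "fq",
    "reference_standard": "fr",
    "negative_control": "fs",
}

ENZYMES = ("BG", "LAP", "NAG", "AP")


class FluorometryError(ValueError):
    """Raised for invalid assay inputs (bad constants, missing roles...)."""


class FullyQuenchedError(FluorometryError):
    """Quench coefficient <= 0: the suspension absorbed all standard signal."""


@dataclass(frozen=True)
class AssayConstants:
    """Physical constants of the microplate assay.

    Parameters
    ----------
    V : float
        Total soil-suspension volume, mL (2 g soil in 125 mL acetate buffer).
    V1 : float
        Suspension volume pipetted per well, mL.
    t : float
        Incubation time, h.
    m : float
        Dry mass of the wet-soil aliquot, g.  For a 2 g wet aliquot at
        gravimetric moisture ``w`` this is ``2 * (1 - w)``; use
        :meth:`from_moisture`.
    c : float
        Reference-standard concentration, uM.
    V2 : float
        Reference-standard volume per well, uL.  ``c * V2`` gives the
        standard amount in nmol after unit conversion (10 uM x 50 uL
        = 0.5 nmol).
    """

    V: float = 125.0
    V1: float = 0.2
    t: float = 4.0
    m: float = 1.8
    c: float = 10.0
    V2: float = 50.0

    def __post_init__(self) -> None:
        for name in ("V", "V1", "t", "m", "c", "V2"):
            if not getattr(self, name) > 0:
                raise FluorometryError(f"assay constant {name} must be > 0")

    @classmethod
    def from_moisture(
        cls, wet_mass: float = 2.0, moisture: float = 0.10, **kwargs
    ) -> "AssayConstants":
        """Constants with ``m`` derived from wet mass and moisture fraction."""
        if not 0 <= moisture < 1:
            raise FluorometryError("moisture fraction must be in [0, 1)")
        return cls(m=wet_mass * (1.0 - moisture), **kwargs)


def quench_coefficient(fq: float, fb: float, fr: float) -> float:
    """Quench coefficient q = (fq - fb) / fr.

    Raises
    ------
    FluorometryError
        If ``fr <= 0``.
    FullyQuenchedError
        If the computed q is <= 0 (standard signal fully suppressed).
    """
    if not fr > 0:
        raise FluorometryError("reference-standard mean fr must be > 0")
    q = (fq - fb) / fr
    if q <= 0:
        raise FullyQuenchedError(
            f"quench coefficient {q:.4g} <= 0: plate fully quenched"
        )
    return q


def emission_coefficient(fr: float, c: float = 10.0, V2: float = 50.0) -> float:
    """Emission (fluorescence release) coefficient e = fr / (c * V2).

    ``c`` is in uM and ``V2`` in uL, so ``c * V2 / 1000`` is the standard
    amount in nmol; e comes out in fluorescence units per nmol.
    """
    if not (fr > 0 and c > 0 and V2 > 0):
        raise FluorometryError("fr, c and V2 must all be > 0")
    nmol = c * V2 / 1000.0
    return fr / nmol


def corrected_fluorescence(f: float, fb: float, fs: float, q: float) -> float:
    """Corrected fluorescence F = (f - fb) / q - fs."""
    if not q > 0:
        raise FluorometryError("quench coefficient q must be > 0")
    return (f - fb) / q - fs


def activity(F: float, k: AssayConstants, e: float) -> float:
    """Enzyme activity Ab = F V / (e V1 t m), nmol g^-1 dry soil h^-1."""
    if not e > 0:
        raise FluorometryError("emission coefficient e must be > 0")
    return F * k.V / (e * k.V1 * k.t * k.m)


@dataclass
class WellGroupMeans:
    """Per-role replicate summaries of one sample x enzyme assay."""

    means: Mapping[str, float]
    n: Mapping[str, int]
    cv: Mapping[str, float]

    def __getattr__(self, symbol: str) -> float:
        for role, sym in _SYMBOL_BY_ROLE.items():
            if sym == symbol:
                return self.means[role]
        raise AttributeError(symbol)


@dataclass
class EnzymeActivity:
    """Result of one sample x enzyme assay."""

    sample_id: str
    enzyme: str
    q: float
    e: float
    F: float
    Ab: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def well_group_means(
    readings: Iterable, aggregate: str = "mean"
) -> WellGroupMeans:
    """Aggregate replicate wells per role (arithmetic mean by default).

    ``aggregate="median"`` switches to the median, e.g. for plates with
    suspected outlier wells.  The CV reported per role is always
    sd / mean of the raw wells.
    """
    if aggregate not in ("mean", "median"):
        raise FluorometryError(f"unknown aggregate {aggregate!r}")
    by_role: dict[str, list[float]] = {}
    for r in readings:
        by_role.setdefault(r.role, []).append(r.fluorescence)
    means, ns, cvs = {}, {}, {}
    for role, vals in by_role.items():
        arr = np.asarray(vals, dtype=float)
        center = float(np.mean(arr)) if aggregate == "mean" else float(np.median(arr))
        means[role] = center
        ns[role] = len(arr)
        mu = float(np.mean(arr))
        cvs[role] = float(np.std(arr, ddof=1) / mu) if len(arr) > 1 and mu != 0 else 0.0
    return WellGroupMeans(means=means, n=ns, cv=cvs)


def process_assay(
    readings: Iterable,
    k: AssayConstants | None = None,
    *,
    qmax: float = 1.5,
    cv_flag_threshold: float = 0.15,
    aggregate: str = "mean",
) -> EnzymeActivity:
    """Compute q, e, F and Ab for one sample x enzyme well set.

    All six roles must be present.  Negative corrected fluorescence is
    reported, not clipped, with a ``negative_F`` flag; replicate CV above
    ``cv_flag_threshold`` in any formula-relevant role adds a
    ``high_cv:<role>`` flag; q above ``qmax`` adds ``q_above_max``.
    Samples flagged ``negative_F`` must be excluded from downstream
    stoichiometry, which requires strictly positive activities.
    """
    readings = list(readings)
    if k is None:
        k = AssayConstants()
    sample_ids = {r.sample_id for r in readings if r.role != "blank"}
    enzymes = {r.enzyme for r in readings if r.role in ("assay", "negative_control")}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else ""
    enzyme = enzymes.pop() if len(enzymes) == 1 else ""

    g = well_group_means(readings, aggregate=aggregate)
    for role in ROLES:
        if role not in g.means:
            raise FluorometryError(f"{role} absent from assay well set")

    q = quench_coefficient(g.fq, g.fb, g.fr)
    e = emission_coefficient(g.fr, k.c, k.V2)
    F = corrected_fluorescence(g.f, g.fb, g.fs, q)
    Ab = activity(F, k, e)

    flags: list[str] = []
    if F < 0:
        flags.append("negative_F")
    if q > qmax:
        flags.append("q_above_max")
    for role in _SYMBOL_BY_ROLE:
        if g.cv.get(role, 0.0) > cv_flag_threshold:
            flags.append(f"high_cv:{role}")
    return EnzymeActivity(
        sample_id=sample_id, enzyme=enzyme, q=q, e=e, F=F, Ab=Ab, flags=tuple(flags)
    )
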