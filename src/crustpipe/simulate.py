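"""Synthetic study-design generator with known ground truth.

Emulates a six-fraction moss-biocrust design — biocrust sublayer soils
(BS_0.5, BS_0.2, BS), sifted biocrust-layer soils (BSS_0.2, BSS) and moss
rhizoid soil (BRS), five replicates each — so every downstream stage can
be tested against a known truth:

* plates: the fluorometry formulas are inverted from a chosen true
  activity, so a zero-noise plate round-trips to that activity exactly;
* ASV tables: a lognormal-multinomial compositional count model with
  group-shifted means and latent-factor-planted correlation blocks;
* soil chemistry: lognormal draws with multiplicative group shifts
  (rhizoid soil enriched over sifted layer over sublayer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from crustpipe.fluorometry import AssayConstants, ENZYMES
from crustpipe.io import GROUPS, PlateReading

CHEM_VARS = ("TOC", "TN", "TP", "NH4", "NO3")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of ASVs driven by one shared latent factor.

    ``loadings`` has one entry per member; two members with same-sign
    loadings are planted as a positive association, opposite signs as a
    negative one.
    """

    members: tuple[int, ...]
    loadings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.loadings):
            raise SimulationError("one loading per block member required")
        if len(set(self.members)) != len(self.members):
            raise SimulationError("block members must be distinct")


def _default_blocks() -> tuple[CorrelationBlock, ...]:
    # one all-positive block and one mixed-sign block, loading 0.9
    return (
        CorrelationBlock(members=tuple(range(6)), loadings=(0.9,) * 6),
        CorrelationBlock(
            members=tuple(range(6, 12)), loadings=(0.9, 0.9, 0.9, -0.9, -0.9, -0.9)
        ),
    )


def _default_activities() -> dict[str, dict[str, float]]:
    # nmol g^-1 dry soil h^-1; rhizoid soil (BRS) highest BG and lowest AP,
    # so its limitation vector is the longest; all groups N-limited
    # (AP < LAP + NAG everywhere).
    return {
        "BS_0.5": {"BG": 55.0, "LAP": 90.0, "NAG": 75.0, "AP": 60.0},
        "BS_0.2": {"BG": 60.0, "LAP": 70.0, "NAG": 60.0, "AP": 65.0},
        "BS": {"BG": 45.0, "LAP": 110.0, "NAG": 85.0, "AP": 70.0},
        "BSS_0.2": {"BG": 70.0, "LAP": 85.0, "NAG": 70.0, "AP": 55.0},
        "BSS": {"BG": 65.0, "LAP": 100.0, "NAG": 80.0, "AP": 58.0},
        "BRS": {"BG": 150.0, "LAP": 130.0, "NAG": 110.0, "AP": 40.0},
    }


def _default_chem_shifts() -> dict[str, dict[str, float]]:
    # multiplicative lognormal-median shifts; rhizoid > sifted > sublayer
    shifts = {g: {v: 1.0 for v in CHEM_VARS} for g in GROUPS}
    for v in CHEM_VARS:
        shifts["BRS"][v] = 2.0
        shifts["BSS"][v] = 1.5
        shifts["BSS_0.2"][v] = 1.4
    return shifts


@dataclass(frozen=True)
class SimulationDesign:
    """All knobs of the synthetic study, with the emulated-design defaults."""

    groups: tuple[str, ...] = GROUPS
    replicates_per_group: int = 5
    n_asv: int = 500
    depth_range: tuple[int, int] = (10_000, 60_000)
    true_activities: dict = field(default_factory=_default_activities)
    chem_baselines: dict = field(
        default_factory=lambda: {
            "TOC": 20.0,  # g/kg
            "TN": 2.0,  # g/kg
            "TP": 0.6,  # g/kg
            "NH4": 15.0,  # mg/kg
            "NO3": 10.0,  # mg/kg
        }
    )
    chem_shifts: dict = field(default_factory=_default_chem_shifts)
    chem_sigma: float = 0.15  # lognormal sd on the log scale
    blocks: tuple[CorrelationBlock, ...] = field(default_factory=_default_blocks)
    shifted_fraction: float = 0.30  # share of ASVs with group-specific means
    abundance_shift_sd: float = 0.5  # sd of group log-mean shifts
    base_log_sd: float = 1.5  # spread of baseline ASV log means
    block_log_mean: float = 2.0  # block members made abundant enough to
    # survive the 0.1% rare-feature filter
    within_log_sd: float = 0.3  # residual per-sample log noise
    plate_cv: float = 0.05  # multiplicative well noise
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise SimulationError("depth range must be positive and ordered")
        members = [m for b in self.blocks for m in b.members]
        if len(set(members)) != len(members):
            raise SimulationError("planted blocks must be disjoint")
        if members and max(members) >= self.n_asv:
            raise SimulationError("n_asv smaller than the largest planted block index")
        for name in ("within_log_sd", "plate_cv", "abundance_shift_sd", "chem_sigma"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sample_ids(self) -> list[str]:
        return [
            f"{g}_r{r}"
            for g in self.groups
            for r in range(1, self.replicates_per_group + 1)
        ]

    def metadata(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{g}_r{r}", "group": g, "replicate": r}
            for g in self.groups
            for r in range(1, self.replicates_per_group + 1)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# plates


#: nominal control-well fluorescence used when inverting the formulas
PLATE_BASELINES = {"fr": 1000.0, "q_true": 0.8, "fb": 100.0, "fs": 50.0, "blank": 5.0}

_WELL_ROWS = "ABCDEFGH"


def simulate_plate(
    design: SimulationDesign,
    group: str,
    enzyme: str,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
    constants: AssayConstants | None = None,
    baselines: dict | None = None,
) -> tuple[list[PlateReading], dict]:
    """Generate one sample x enzyme well set from the group's true activity.

    The chain is inverted exactly: with e = fr / (c V2), the corrected
    fluorescence implied by the true activity is F = Ab e V1 t m / V and
    the assay-well level is f = (F + fs) q + fb, with fq = q fr + fb.
    Eight wells per role get independent multiplicative Gaussian noise at
    ``design.plate_cv``; at zero CV the processing module recovers the
    true activity to machine precision.

    Returns the readings plus a ground-truth record (true Ab, q, e, F and
    the role levels).
    """
    if enzyme not in ENZYMES:
        raise SimulationError(f"unknown enzyme {enzyme!r}")
    ab_true = float(design.true_activities[group][enzyme])
    if ab_true <= 0:
        raise SimulationError("true activity must be > 0")
    if rng is None:
        rng = design.rng()
    k = constants if constants is not None else AssayConstants()
    b = dict(PLATE_BASELINES, **(baselines or {}))

    e = b["fr"] / (k.c * k.V2 / 1000.0)
    f_corr = ab_true * e * k.V1 * k.t * k.m / k.V
    levels = {
        "assay": (f_corr + b["fs"]) * b["q_true"] + b["fb"],
        "sample_control": b["fb"],
        "quench_control": b["q_true"] * b["fr"] + b["fb"],
        "reference_standard": b["fr"],
        "negative_control": b["fs"],
        "blank": b["blank"],
    }
    sample_id = f"{group}_r{replicate}"
    plate_id = f"{sample_id}_{enzyme}"
    readings: list[PlateReading] = []
    for col, (role, level) in enumerate(levels.items(), start=1):
        noise = 1.0 + design.plate_cv * rng.standard_normal(8)
        for row in range(8):
            value = max(level * noise[row], 0.0)
            readings.append(
                PlateReading(
                    plate_id=plate_id,
                    well=f"{_WELL_ROWS[row]}{col}",
                    role=role,
                    sample_id="" if role == "blank" else sample_id,
                    enzyme="" if role in ("reference_standard", "blank") else enzyme,
                    fluorescence=float(value),
                )
            )
    truth = {
        "sample_id": sample_id,
        "enzyme": enzyme,
        "Ab": ab_true,
        "q": b["q_true"],
        "e": e,
        "F": f_corr,
        **{r: lv for r, lv in levels.items()},
    }
    return readings, truth


def simulate_plates(
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
    constants: AssayConstants | None = None,
) -> tuple[list[PlateReading], pd.DataFrame]:
    """All plates of the design (group x replicate x enzyme)."""
    if rng is None:
        rng = design.rng()
    readings: list[PlateReading] = []
    truths = []
    for g in design.groups:
        for r in range(1, design.replicates_per_group + 1):
            for enz in ENZYMES:
                rd, tr = simulate_plate(
                    design, g, enz, replicate=r, rng=rng, constants=constants
                )
                readings.extend(rd)
                truths.append(tr)
    return readings, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# feature table


def simulate_feature_table(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Lognormal-multinomial ASV counts with planted structure.

    Per-feature baseline log means are Gaussian; a fixed fraction of
    ASVs receives group-specific shifts; planted block members share a
    per-sample latent factor scaled by their loadings, which induces the
    planted pairwise associations; per-sample relative abundances are the
    softmax of the log means plus residual noise, and counts are one
    multinomial draw at a uniform random depth.

    Returns (table features x samples, metadata, ground truth) where the
    truth records shifted ASV ids, block memberships and planted edges as
    (feature_a, feature_b, sign).
    """
    if rng is None:
        rng = design.rng()
    n = design.n_asv
    ids = [f"ASV_{i + 1:04d}" for i in range(n)]
    meta = design.metadata()
    samples = meta.index.to_list()

    mu = rng.normal(0.0, design.base_log_sd, size=n)
    for b in design.blocks:
        mu[list(b.members)] = design.block_log_mean

    # group shifts never land on block members: the blocks are the
    # controlled correlation ground truth
    block_members = {m for b in design.blocks for m in b.members}
    eligible = np.array([i for i in range(n) if i not in block_members])
    n_shift = min(int(round(design.shifted_fraction * n)), eligible.size)
    shifted = rng.choice(eligible, size=n_shift, replace=False)
    shift = np.zeros((len(design.groups), n))
    if design.abundance_shift_sd > 0 and n_shift:
        shift[:, shifted] = rng.normal(
            0.0, design.abundance_shift_sd, size=(len(design.groups), n_shift)
        )

    loading = np.zeros((n, len(design.blocks)))
    for kb, b in enumerate(design.blocks):
        loading[list(b.members), kb] = b.loadings

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    lo, hi = design.depth_range
    group_index = {g: i for i, g in enumerate(design.groups)}
    for j, sid in enumerate(samples):
        gi = group_index[meta.loc[sid, "group"]]
        z = rng.standard_normal(len(design.blocks))
        eps = rng.normal(0.0, design.within_log_sd, size=n)
        log_lam = mu + shift[gi] + loading @ z + eps
        p = np.exp(log_lam - log_lam.max())
        p /= p.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[:, j] = rng.multinomial(depth, p)

    table = pd.DataFrame(counts, index=ids, columns=samples)
    planted_edges = []
    for b in design.blocks:
        for a_i in range(len(b.members)):
            for b_i in range(a_i + 1, len(b.members)):
                sign = 1 if b.loadings[a_i] * b.loadings[b_i] > 0 else -1
                planted_edges.append(
                    (ids[b.members[a_i]], ids[b.members[b_i]], sign)
                )
    truth = {
        "shifted_asvs": [ids[i] for i in sorted(shifted)],
        "blocks": [tuple(ids[m] for m in b.members) for b in design.blocks],
        "planted_edges": planted_edges,
    }
    return table, meta, truth


# ---------------------------------------------------------------------------
# chemistry


def simulate_chemistry(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Lognormal soil chemistry with multiplicative group shifts.

    The lognormal median of variable v in group g is
    ``baseline[v] * shift[g][v]``; all draws are strictly positive.
    """
    if rng is None:
        rng = design.rng()
    meta = design.metadata()
    data = {}
    for v in CHEM_VARS:
        base = design.chem_baselines[v]
        vals = []
        for sid in meta.index:
            s = design.chem_shifts[meta.loc[sid, "group"]][v]
            vals.append(
                float(np.exp(np.log(base * s) + design.chem_sigma * rng.standard_normal()))
            )
        data[v] = vals
    out = pd.DataFrame(data, index=meta.index)
    return out.join(meta[["group", "replicate"]])
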