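"""Readers and writers for every on-disk artifact.

Formats are deliberately plain text: a tidy plate CSV (one well per row),
QIIME-orientation feature-table TSV (features x samples), metadata TSV,
distance-matrix TSV, edge-list CSV and GraphML for networks, and a flat
INI-style run configuration.  Every writer/reader pair round-trips at the
declared precision.
"""

from __future__ import annotations

import configparser
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from crustpipe.fluorometry import ROLES, ENZYMES, AssayConstants

GROUPS = ("BS_0.5", "BS_0.2", "BS", "BSS_0.2", "BSS", "BRS")

PLATE_COLUMNS = ("plate_id", "well", "role", "sample_id", "enzyme", "fluorescence")

_WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

#: float formatting for all results tables (6 significant digits)
FLOAT_FMT = "%.6g"


class IOError_(ValueError):
    """Parse or validation failure in an on-disk artifact."""


@dataclass(frozen=True)
class PlateReading:
    """One well of a fluorescence plate with its role annotations."""

    plate_id: str
    well: str
    role: str
    sample_id: str = ""
    enzyme: str = ""
    fluorescence: float = 0.0

    def __post_init__(self) -> None:
        if not _WELL_RE.match(self.well):
            raise IOError_(f"invalid well id {self.well!r} (A1..H12)")
        if self.role not in ROLES:
            raise IOError_(f"unknown role {self.role!r}")
        if self.enzyme not in ("",) + ENZYMES:
            raise IOError_(f"unknown enzyme {self.enzyme!r}")
        if not (math.isfinite(self.fluorescence) and self.fluorescence >= 0):
            raise IOError_(
                f"fluorescence must be finite and >= 0, got {self.fluorescence}"
            )


def read_plate_csv(path) -> dict[str, list[PlateReading]]:
    """Parse a tidy plate CSV into readings grouped by plate.

    Validates roles, enzymes, well ids and uniqueness of wells within a
    plate; the error message names the offending data row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"plate CSV missing column(s): {sorted(missing)}")
    plates: dict[str, list[PlateReading]] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            reading = PlateReading(
                plate_id=row.plate_id,
                well=row.well,
                role=row.role,
                sample_id=row.sample_id,
                enzyme=row.enzyme,
                fluorescence=float(row.fluorescence),
            )
        except (IOError_, ValueError) as exc:
            raise IOError_(f"{path}, row {i}: {exc}") from exc
        key = (reading.plate_id, reading.well)
        if key in seen:
            raise IOError_(f"{path}, row {i}: duplicate well {key[1]} in plate {key[0]}")
        seen.add(key)
        plates.setdefault(reading.plate_id, []).append(reading)
    return plates


def write_plate_csv(readings, path) -> None:
    df = pd.DataFrame([asdict(r) for r in readings], columns=list(PLATE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(
    path, metadata: pd.DataFrame | None = None, samples_as_rows: bool = False
) -> pd.DataFrame:
    """Read a feature-count TSV (features x samples).

    ``samples_as_rows=True`` accepts the transposed orientation.  Counts
    must be nonnegative integers; when metadata is given, every sample
    column must have a metadata row.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples_as_rows:
        df = df.T
    x = df.to_numpy()
    if not np.issubdtype(x.dtype, np.number) or not np.allclose(x, np.round(x)):
        raise IOError_(f"{path}: counts must be integers")
    if (x < 0).any():
        raise IOError_(f"{path}: counts must be nonnegative")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise IOError_(f"{path}: duplicate feature or sample ids")
    if metadata is not None:
        absent = [s for s in df.columns if s not in metadata.index]
        if absent:
            raise IOError_(f"{path}: sample(s) {absent} absent from metadata")
    return df.astype(np.int64)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path, validate_groups: bool = True) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, replicate), indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group", "replicate"):
        if col not in df.columns:
            raise IOError_(f"{path}: metadata missing column {col!r}")
    if validate_groups:
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise IOError_(f"{path}: unknown group label(s) {bad}")
    if df.duplicated(["group", "replicate"]).any():
        raise IOError_(f"{path}: duplicate (group, replicate) pair")
    if df["sample_id"].duplicated().any():
        raise IOError_(f"{path}: duplicate sample_id")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def write_distance_matrix(d: pd.DataFrame, path) -> None:
    d.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_distance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_network_graphml(net, path) -> None:
    """GraphML export with node abundance and signed weighted edges."""
    g = net.graph if hasattr(net, "graph") else net
    nx.write_graphml(g, path)


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


@dataclass
class RunConfig:
    """Seeds, thresholds and constants of one pipeline run."""

    assay: AssayConstants = field(default_factory=AssayConstants)
    rarefaction_seed: int = 1
    permutation_seed: int = 2
    n_perm: int = 999
    alpha: float = 0.05
    min_rel_abundance: float = 0.001
    r_threshold: float = 0.6
    alpha_fdr: float = 0.05
    min_copresence: int = 0
    jaccard_max_distance: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise IOError_("alpha must be in (0, 1)")

    def network_config(self):
        from crustpipe.network import NetworkConfig

        return NetworkConfig(
            min_rel_abundance=self.min_rel_abundance,
            r_threshold=self.r_threshold,
            alpha_fdr=self.alpha_fdr,
            min_copresence=self.min_copresence,
            jaccard_max_distance=self.jaccard_max_distance,
        )


def write_config(config: RunConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["assay"] = {k: repr(v) for k, v in asdict(config.assay).items()}
    cp["seeds"] = {
        "rarefaction_seed": str(config.rarefaction_seed),
        "permutation_seed": str(config.permutation_seed),
    }
    cp["stats"] = {"alpha": repr(config.alpha), "n_perm": str(config.n_perm)}
    cp["network"] = {
        "min_rel_abundance": repr(config.min_rel_abundance),
        "r_threshold": repr(config.r_threshold),
        "alpha_fdr": repr(config.alpha_fdr),
        "min_copresence": str(config.min_copresence),
        "jaccard_max_distance": repr(config.jaccard_max_distance),
    }
    with open(path, "w") as fh:
        cp.write(fh)


def read_config(path) -> RunConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise IOError_(f"cannot read config {path}")
    # configparser lowercases keys; map back to the dataclass field names
    fields = {f.lower(): f for f in ("V", "V1", "t", "m", "c", "V2")}
    assay = AssayConstants(**{fields[k]: float(v) for k, v in cp["assay"].items()})
    jmd = cp["network"].get("jaccard_max_distance", "None")
    return RunConfig(
        assay=assay,
        rarefaction_seed=cp["seeds"].getint("rarefaction_seed"),
        permutation_seed=cp["seeds"].getint("permutation_seed"),
        n_perm=cp["stats"].getint("n_perm", 999),
        alpha=cp["stats"].getfloat("alpha"),
        min_rel_abundance=cp["network"].getfloat("min_rel_abundance"),
        r_threshold=cp["network"].getfloat("r_threshold"),
        alpha_fdr=cp["network"].getfloat("alpha_fdr"),
        min_copresence=cp["network"].getint("min_copresence"),
        jaccard_max_distance=None if jmd == "None" else float(jmd),
    )
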