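"""End-to-end pipeline: plates + ASV table + chemistry -> report bundle.

Each stage failure aborts with a stage-named error; two runs with the
same inputs and configuration produce byte-identical numeric outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from crustpipe import diversity as dv
from crustpipe import network as netmod
from crustpipe import stats as st
from crustpipe import stoichiometry as stoich
from crustpipe.fluorometry import process_assay
from crustpipe.io import (
    FLOAT_FMT,
    RunConfig,
    read_feature_table,
    read_metadata,
    read_plate_csv,
    write_distance_matrix,
    write_network_graphml,
)


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("fluorometry")
def activities_from_plates(plate_path, config: RunConfig) -> pd.DataFrame:
    plates = read_plate_csv(plate_path)
    rows = []
    for plate_id, readings in plates.items():
        res = process_assay(readings, config.assay)
        rows.append(
            {
                "sample_id": res.sample_id,
                "enzyme": res.enzyme,
                "q": res.q,
                "e": res.e,
                "F": res.F,
                "Ab": res.Ab,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows).sort_values(["sample_id", "enzyme"]).reset_index(drop=True)


@_stage("stoichiometry")
def stoichiometry_tables(activities: pd.DataFrame, metadata: pd.DataFrame):
    wide = activities.pivot(index="sample_id", columns="enzyme", values="Ab")
    flagged = set(activities.loc[activities["flags"].str.contains("negative_F"), "sample_id"])
    rows, vectors = [], []
    for sid, r in wide.iterrows():
        if sid in flagged or (r <= 0).any():
            continue
        prof = stoich.ActivityProfile(
            sample_id=sid, BG=r["BG"], LAP=r["LAP"], NAG=r["NAG"], AP=r["AP"]
        )
        sr = stoich.stoich_ratios(prof)
        v = stoich.limitation_vector(prof)
        vectors.append(v)
        rows.append(
            {
                "sample_id": sid,
                "CN": sr.CN,
                "CP": sr.CP,
                "NP": sr.NP,
                "x": v.x,
                "y": v.y,
                "length": v.length,
                "angle": v.angle,
                "limitation_class": v.limitation_class,
                "flags": ";".join(sr.flags),
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    summary = stoich.group_vector_summary(vectors, metadata)
    return per_sample, summary


@_stage("diversity")
def diversity_tables(table: pd.DataFrame, metadata: pd.DataFrame, config: RunConfig):
    rarefied = dv.rarefy(table, "min", seed=config.rarefaction_seed)
    alpha = dv.alpha_diversity_table(rarefied)
    dm = dv.bray_curtis(rarefied)
    ord_res = dv.pcoa(dm, n_axes=3)
    groups = metadata.loc[dm.index, "group"]
    perm = dv.permanova(dm, groups, n_perm=config.n_perm, seed=config.permutation_seed)
    return rarefied, alpha, dm, ord_res, perm


@_stage("group-comparison")
def comparison_tables(
    alpha: pd.DataFrame, chemistry: pd.DataFrame | None, metadata: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    tidy = alpha.join(metadata["group"])
    variables = {c: tidy for c in alpha.columns}
    if chemistry is not None:
        chem = chemistry.drop(columns=["replicate"], errors="ignore")
        variables.update({c: chem for c in chem.columns if c != "group"})
    for var, frame in variables.items():
        f, p = st.one_way_anova(frame[var], frame["group"])
        pairs = st.tukey_hsd(frame[var], frame["group"])
        letters = pairs.attrs["letters"]
        rows.append(
            {
                "variable": var,
                "test": "anova+tukey",
                "statistic": f,
                "p": p,
                "stars": st.stars(p),
                "letters": ";".join(f"{g}={l}" for g, l in sorted(letters.items())),
            }
        )
    return pd.DataFrame(rows)


@_stage("network")
def network_tables(rarefied: pd.DataFrame, metadata: pd.DataFrame, config: RunConfig):
    nets = {"all": netmod.build_network(rarefied, config.network_config(), group="all")}
    for g, sub in metadata.groupby("group", sort=False):
        cols = [s for s in sub.index if s in rarefied.columns]
        if len(cols) >= 4:
            nets[g] = netmod.build_network(
                rarefied[cols], config.network_config(), group=g
            )
    props = {}
    for g, net in nets.items():
        if net.graph.number_of_nodes() >= 2:
            props[g] = netmod.network_properties(net).as_series()
    prop_table = pd.DataFrame(props)
    return nets, prop_table


def run_pipeline(
    config: RunConfig,
    plate_path,
    feature_path,
    metadata_path,
    chemistry_path=None,
    out_dir="results",
) -> dict:
    """Run every stage and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        metadata = read_metadata(metadata_path)
    except Exception as exc:
        raise PipelineError("metadata", exc) from exc
    try:
        table = read_feature_table(feature_path, metadata=metadata)
    except Exception as exc:
        raise PipelineError("feature-table", exc) from exc
    chemistry = None
    if chemistry_path is not None:
        try:
            chemistry = pd.read_csv(chemistry_path, sep="\t", index_col=0)
        except Exception as exc:
            raise PipelineError("chemistry", exc) from exc

    activities = activities_from_plates(plate_path, config)
    per_sample, summary = stoichiometry_tables(activities, metadata)
    rarefied, alpha, dm, ord_res, perm = diversity_tables(table, metadata, config)
    comparisons = comparison_tables(alpha, chemistry, metadata)
    nets, prop_table = network_tables(rarefied, metadata, config)

    activities.to_csv(out / "activities.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    per_sample.to_csv(out / "stoichiometry.tsv", sep="\t", float_format=FLOAT_FMT)
    summary.to_csv(out / "vector_group_summary.tsv", sep="\t", float_format=FLOAT_FMT)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", float_format=FLOAT_FMT)
    write_distance_matrix(dm, out / "bray_curtis.tsv")
    coords = ord_res.coordinates.copy()
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t", float_format=FLOAT_FMT)
    pd.DataFrame([perm]).to_csv(out / "permanova.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    comparisons.to_csv(out / "group_tests.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    for g, net in nets.items():
        net.edges_frame().to_csv(
            out / f"network_edges_{g}.csv", index=False, float_format=FLOAT_FMT
        )
        write_network_graphml(net, out / f"network_{g}.graphml")
    prop_table.to_csv(out / "network_properties.tsv", sep="\t", float_format=FLOAT_FMT)

    with open(out / "run_log.txt", "w") as fh:
        fh.write("crustpipe run log\n")
        fh.write(f"rarefaction_seed={config.rarefaction_seed}\n")
        fh.write(f"permutation_seed={config.permutation_seed}\n")
        fh.write(f"n_perm={config.n_perm}\n")
        fh.write(f"alpha={config.alpha}\n")
        fh.write(f"min_rel_abundance={config.min_rel_abundance}\n")
        fh.write(f"r_threshold={config.r_threshold}\n")
        fh.write(f"alpha_fdr={config.alpha_fdr}\n")
        fh.write("genus_difference_test=kruskal-wallis (nonparametric default)\n")

    return {
        "activities": activities,
        "stoichiometry": per_sample,
        "vector_summary": summary,
        "alpha": alpha,
        "distance": dm,
        "pcoa": ord_res,
        "permanova": perm,
        "comparisons": comparisons,
        "networks": nets,
        "network_properties": prop_table,
    }
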