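"""Tabular input/output, spot-signal reduction, and the end-to-end pipeline.

Table dialects (all TSV):

glycan library   glycan_id, structure [, composition, mass_label]
lectin table     lectin, motif, binding_score, terminal_required
enzyme table     enzyme, recognition_motif, replace_motif, terminal_required
spot table       slide_id, array_id, spot_id, protein, lectin, condition,
                 median_signal, mean_background
observed table   protein, condition, lectin, value   (already reduced)

The panel is a YAML document listing ordered conditions (each naming its
enzyme sequence) and lectin names, resolved against the lectin and enzyme
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glycan_core import (DEFAULT_MASS_TABLE, Composition, GlycanTree,
                          MassTable, canonical_form, composition_of, mass_of,
                          parse_glycan)
from .motif_enzyme import EnzymeSpec, LectinSpec, Motif
from .response_model import (Condition, Panel, build_model_matrix,
                             cluster_model_glycans, normalize_per_lectin,
                             restrict_candidates)
from .solver import GlycanDeconvolver, solution_fit_quality
from .summaries import (core_fractions, mass_fractions,
                        terminal_feature_fractions)

logger = logging.getLogger("gmapsolve")

__all__ = [
    "read_glycan_library", "write_glycan_library",
    "read_lectin_table", "write_lectin_table",
    "read_enzyme_table", "write_enzyme_table",
    "read_panel_config", "read_mass_table",
    "read_spot_table", "reduce_spot_table", "read_observed_table",
    "gpr_to_spot_table", "write_report", "run_pipeline", "PipelineError",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _to_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("1", "true", "yes", "y")


# ---------------------------------------------------------------------------
# libraries

def read_glycan_library(path) -> list[GlycanTree]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"glycan_id", "structure"} <= set(df.columns):
        raise ValueError("glycan library needs columns glycan_id, structure")
    return [parse_glycan(row.structure, id=row.glycan_id)
            for row in df.itertuples()]


def write_glycan_library(glycans: Sequence[GlycanTree], path,
                         mass_table: MassTable = DEFAULT_MASS_TABLE) -> None:
    rows = []
    for g in glycans:
        comp = composition_of(g)
        rows.append({"glycan_id": g.id, "structure": canonical_form(g),
                     "composition": str(comp),
                     "mass_label": round(mass_of(comp, mass_table), 3)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lectin_table(path) -> dict[str, LectinSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, LectinSpec] = {}
    for name, grp in df.groupby("lectin", sort=False):
        entries = tuple(
            (Motif.from_text(r.motif, _to_bool(getattr(r, "terminal_required", False))),
             float(r.binding_score))
            for r in grp.itertuples())
        out[name] = LectinSpec(name, entries)
    return out


def write_lectin_table(lectins: Sequence[LectinSpec], path) -> None:
    rows = [{"lectin": l.name, "motif": str(m), "binding_score": s,
             "terminal_required": m.terminal_required}
            for l in lectins for m, s in l.entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_enzyme_table(path) -> dict[str, EnzymeSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, EnzymeSpec] = {}
    for r in df.itertuples():
        out[r.enzyme] = EnzymeSpec.from_text(
            r.enzyme, r.recognition_motif, r.replace_motif,
            _to_bool(getattr(r, "terminal_required", True)))
    return out


def write_enzyme_table(enzymes: Sequence[EnzymeSpec], path) -> None:
    rows = [{"enzyme": e.name, "recognition_motif": str(e.recognition),
             "replace_motif": str(e.replace),
             "terminal_required": e.recognition.terminal_required}
            for e in enzymes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_config(panel_cfg, lectins: Mapping[str, LectinSpec],
                      enzymes: Mapping[str, EnzymeSpec]) -> Panel:
    """Build a Panel from a YAML path or an already-parsed mapping."""
    if not isinstance(panel_cfg, Mapping):
        with open(panel_cfg) as fh:
            panel_cfg = yaml.safe_load(fh)
    conditions = []
    for c in panel_cfg["conditions"]:
        if isinstance(c, str):
            name, enz_names = c, []
        else:
            name = c["name"]
            enz_names = c.get("enzymes", []) or []
        missing = [e for e in enz_names if e not in enzymes]
        if missing:
            raise KeyError(f"unknown enzyme name(s) {missing} in condition {name!r}")
        conditions.append(Condition(name, tuple(enzymes[e] for e in enz_names)))
    missing = [l for l in panel_cfg["lectins"] if l not in lectins]
    if missing:
        raise KeyError(f"unknown lectin name(s) {missing}")
    chosen = tuple(lectins[l] for l in panel_cfg["lectins"])
    return Panel(tuple(conditions), chosen,
                 binding_mode=panel_cfg.get("binding_mode", "max"))


def read_mass_table(path) -> MassTable:
    with open(path) as fh:
        return MassTable.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# observations

SPOT_COLUMNS = ["slide_id", "array_id", "spot_id", "protein", "lectin",
                "condition", "median_signal", "mean_background"]


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table lacks columns {missing}")
    return df


#: default GenePix (.gpr) column names -> spot-table columns
GPR_COLUMN_MAP = {
    "Block": "array_id",
    "ID": "spot_id",
    "Name": "protein",
    "F635 Median": "median_signal",
    "B635 Mean": "mean_background",
}


def gpr_to_spot_table(gpr: pd.DataFrame, lectin: str, condition: str,
                      slide_id: str = "S1",
                      column_map: Mapping[str, str] = GPR_COLUMN_MAP) -> pd.DataFrame:
    """Adapt a GenePix-style quantification frame (one lectin x condition
    incubation) to the spot-table dialect."""
    out = gpr.rename(columns=dict(column_map))
    out = out[[c for c in out.columns if c in SPOT_COLUMNS]]
    out = out.assign(lectin=lectin, condition=condition, slide_id=slide_id)
    missing = [c for c in SPOT_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"GPR adapter could not supply columns {missing}")
    return out[SPOT_COLUMNS]


def reduce_spot_table(records: pd.DataFrame, panel: Panel,
                      clamp_negative: bool = False) -> dict[str, pd.Series]:
    """Reduce spot records to one observed vector per protein.

    Net signal = median - mean local background per spot; replicate spots
    are averaged within each array, then across replicate arrays.  Channels
    follow the panel order; any (protein, condition, lectin) channel with no
    records is an error naming the gaps.
    """
    df = records.copy()
    df["net"] = df["median_signal"].astype(float) - df["mean_background"].astype(float)
    if clamp_negative:
        df["net"] = df["net"].clip(lower=0.0)
    per_array = (df.groupby(["protein", "condition", "lectin",
                             "slide_id", "array_id"], sort=False)["net"]
                 .mean())
    per_channel = per_array.groupby(["protein", "condition", "lectin"]).mean()

    idx = panel.channel_index()
    out: dict[str, pd.Series] = {}
    for protein in df["protein"].unique():
        vec = []
        gaps = []
        for cond, lec in idx:
            try:
                vec.append(float(per_channel.loc[(protein, cond, lec)]))
            except KeyError:
                gaps.append(f"{lec} x {cond}")
                vec.append(np.nan)
        if gaps:
            raise ValueError(f"protein {protein!r} is missing channels: "
                             + ", ".join(gaps))
        out[protein] = pd.Series(vec, index=idx, name=protein)
    return out


def read_observed_table(path, panel: Panel) -> dict[str, pd.Series]:
    """Read an already-reduced response-vector table
    (protein, condition, lectin, value)."""
    df = pd.read_csv(path, sep="\t")
    idx = panel.channel_index()
    out: dict[str, pd.Series] = {}
    for protein, grp in df.groupby("protein", sort=False):
        s = grp.set_index(["condition", "lectin"])["value"].astype(float)
        missing = [f"{l} x {c}" for c, l in idx if (c, l) not in s.index]
        if missing:
            raise ValueError(f"protein {protein!r} is missing channels: "
                             + ", ".join(missing))
        out[protein] = pd.Series([s.loc[c, l] for c, l in idx], index=idx,
                                 name=protein)
    return out


# ---------------------------------------------------------------------------
# report output and pipeline

def write_report(report, glycans: Mapping[str, GlycanTree], path,
                 clusters: pd.Series | None = None) -> None:
    tbl = report.table.copy()
    tbl.insert(0, "glycan_id", tbl.index)
    tbl.insert(1, "structure", [canonical_form(glycans[g]) if g in glycans else ""
                                for g in tbl.index])
    if "cluster" not in tbl.columns and clusters is not None:
        tbl["cluster"] = clusters.reindex(tbl.index)
    tbl.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> dict[str, Path]:
    """Execute build -> normalize -> (restrict) -> solve -> report ->
    summaries from a config mapping (or YAML path); returns written paths."""
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    written: dict[str, Path] = {}

    def stage(name, fn, *args, **kw):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc

    glycans = stage("read-library", read_glycan_library, inputs["glycans"])
    lectins = stage("read-lectins", read_lectin_table, inputs["lectins"])
    enzymes = stage("read-enzymes", read_enzyme_table, inputs["enzymes"])
    panel = stage("read-panel", read_panel_config, config["panel"],
                  lectins, enzymes)
    mass_table = (stage("read-masses", read_mass_table, inputs["mass_table"])
                  if inputs.get("mass_table") else DEFAULT_MASS_TABLE)

    restrict = config.get("restrict") or {}
    if restrict:
        comps = restrict.get("compositions")
        masses = restrict.get("masses")
        glycans = stage("restrict", restrict_candidates, glycans,
                        comps, masses, mass_table, restrict.get("tolerance"))

    matrix = stage("build-model", build_model_matrix, glycans, panel)
    matrix_n = stage("normalize", normalize_per_lectin, matrix)
    cutoff_frac = float(config.get("cluster_cutoff_fraction", 0.10))
    from scipy.spatial.distance import pdist
    dmax = (float(pdist(matrix_n.to_numpy().T).max())
            if matrix_n.shape[1] > 1 else 0.0)
    clusters = stage("cluster", cluster_model_glycans, matrix_n,
                     cutoff_frac * dmax)
    matrix_n.to_csv(outdir / "model_matrix.tsv", sep="\t")
    written["model_matrix"] = outdir / "model_matrix.tsv"

    if inputs.get("spots"):
        records = stage("read-spots", read_spot_table, inputs["spots"])
        observed = stage("reduce", reduce_spot_table, records, panel,
                         bool(config.get("clamp_negative", False)))
    else:
        observed = stage("read-observed", read_observed_table,
                         inputs["observed"], panel)
    if config.get("normalize_observed", False):
        observed = {p: normalize_per_lectin(v) for p, v in observed.items()}

    solver_cfg = dict(config.get("solver") or {})
    gmap = {g.id: g for g in glycans}
    for protein, d in observed.items():
        model = stage(f"solve[{protein}]",
                      GlycanDeconvolver(**solver_cfg).fit, matrix_n, d,
                      glycans=gmap, panel=panel, clusters=clusters)
        report = model.report_
        r, r2 = solution_fit_quality(report, d)
        path = outdir / f"report_{protein}.tsv"
        stage(f"write-report[{protein}]", write_report, report, gmap, path,
              clusters)
        written[f"report_{protein}"] = path
        weights = report.table["mean_weight"]
        summ = {
            "protein": protein,
            "n_accepted_fits": report.n_accepted,
            "initial_r2": report.initial_r2,
            "solution_correlation": r,
            "solution_r2": r2,
            "core_fractions": core_fractions(weights, gmap),
            "terminal_features": terminal_feature_fractions(weights, gmap),
            "mass_fractions": mass_fractions(weights, gmap),
        }
        spath = outdir / f"summary_{protein}.json"
        spath.write_text(json.dumps(summ, indent=2, sort_keys=True))
        written[f"summary_{protein}"] = spath

    log = {"package_version": __version__,
           "config_hash": _config_hash(config),
           "n_candidates": len(glycans),
           "n_channels": panel.n_channels}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    written["run_log"] = outdir / "run_log.json"
    return written
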