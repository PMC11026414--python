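"""End-to-end analysis runs driven by a config file.

A run takes a variant table (or a synthetic-panel config), builds one or
more phenotype landscapes per condition, gates them, collapses them to
residue barcodes, derives condition deltas / activity-to-monomer ratios,
classification and responder tables, and optionally Bayesian landscapes and
B-factor-annotated structures.  Every output is a CSV (or PDB) under the
output directory and a ``manifest.json`` records parameters, seeds and the
package version so a run can be replayed exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barcode import delta_barcode, ratio_delta_barcode
from .data import (VariantDataset, read_variant_table, write_variant_table)
from .model import PhenotypeLandscape
from .structure import NumberingMap, write_bfactor_pdb
from .synthetic import (ConditionEffect, SyntheticConfig,
                        simulate_condition_pair)
from .variogram import VariogramModel
from .varstats import classify_dataset, responder_table

log = logging.getLogger("vsprofile")


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    input_table: str | None = None
    chain_length: int = 418
    synthetic: dict | None = None
    landscapes: list = field(default_factory=lambda: [
        {"y": "monomer", "z": "activity"}])
    conditions: list = field(default_factory=lambda: ["vehicle"])
    basal_condition: str = "vehicle"
    treated_condition: str | None = None
    n_bins: int = 12
    max_lag: float | None = None
    n_y_grid: int = 101
    mixture_seed: int = 0
    mixture_restarts: int = 10
    ivw_fallback: str = "na"
    bayesian: bool = False
    classify: dict | None = None  # {"activity": ..., "polymer": ...}
    pdb_in: str | None = None
    pdb_offset: int = 24
    pdb_chain: str | None = None
    seed: int = 0
    out_dir: str = "vsp_out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") \
            else yaml.safe_load(text)
        return cls(**data)


def _synthetic_input(config: RunConfig) -> VariantDataset:
    spec = dict(config.synthetic or {})
    vg = spec.pop("variogram", None)
    if vg is not None:
        spec["variogram"] = VariogramModel(**vg)
    effect_spec = spec.pop("effect", None)
    spec.setdefault("seed", config.seed)
    spec.setdefault("chain_length", config.chain_length)
    cfg = SyntheticConfig(**spec)
    if effect_spec is not None:
        basal, treated = simulate_condition_pair(
            cfg, ConditionEffect(**effect_spec),
            treated_condition=config.treated_condition or "drug")
        merged = basal.table.merge(
            treated.table.drop(columns=["position", "x"]), on="variant")
        ds = VariantDataset(chain_length=cfg.chain_length, table=merged,
                            metadata={"basal": basal.metadata,
                                      "treated": treated.metadata})
        return ds
    from .synthetic import simulate_dataset
    return simulate_dataset(cfg)


def _write_landscape_outputs(res, out: Path, tag: str) -> None:
    emp = res.empirical
    pd.DataFrame({"lag_center": emp.lag_center,
                  "mean_gamma": emp.mean_gamma,
                  "sem_gamma": emp.sem_gamma,
                  "n_pairs": emp.n_pairs}).to_csv(
        out / f"{tag}.empirical_variogram.csv", index=False)
    m = res.variogram
    pd.DataFrame([{"family": m.family, "nugget": m.nugget,
                   "partial_sill": m.partial_sill, "range": m.range_,
                   "sill": m.sill, "effective_range": m.effective_range,
                   "rss": m.diagnostics.get("rss"),
                   "loocv_r": res.loocv.pearson_r,
                   "loocv_p": res.loocv.p_value}]).to_csv(
        out / f"{tag}.variogram_fit.csv", index=False)
    df = res.grid.to_dataframe()
    df["high_confidence"] = res.mask.ravel().astype(int)
    df.to_csv(out / f"{tag}.landscape.csv", index=False)
    res.barcode.to_dataframe().to_csv(out / f"{tag}.barcode.csv", index=False)
    pd.DataFrame({"x": res.model.x, "y": res.model.y, "z": res.model.z,
                  "loocv_pred": res.loocv.predictions}).to_csv(
        out / f"{tag}.loocv.csv", index=False)
    if res.bayes_grid is not None:
        bdf = res.bayes_grid.to_dataframe()
        bdf["high_confidence"] = res.bayes_mask.ravel().astype(int)
        bdf.to_csv(out / f"{tag}.bayes_landscape.csv", index=False)
        res.bayes_barcode.to_dataframe().to_csv(
            out / f"{tag}.bayes_barcode.csv", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns a manifest-like dict of outputs.

    A stage failure aborts with the stage name; outputs already written and
    the manifest survive.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": _jsonable(vars(config)),
                "stages": []}
    results: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            value = fn()
        except Exception as e:
            manifest["stages"].append({"name": name, "status": "failed",
                                       "error": str(e)})
            _dump_manifest(manifest, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest["stages"].append(
            {"name": name, "status": "ok",
             "seconds": round(time.perf_counter() - t0, 3)})
        return value

    if config.input_table:
        ds = stage("load", lambda: read_variant_table(
            config.input_table, chain_length=config.chain_length))
    elif config.synthetic is not None:
        ds = stage("simulate", lambda: _synthetic_input(config))
        write_variant_table(ds, out / "variant_table.csv")
    else:
        raise ValueError("config needs input_table or synthetic")

    barcodes: dict = {}
    for land in config.landscapes:
        py, pz = land["y"], land["z"]
        for cond in config.conditions:
            tag = f"{py}-{pz}.{cond}"

            def fit(py=py, pz=pz, cond=cond):
                model = PhenotypeLandscape.from_dataset(ds, py, pz, cond)
                y_grid = np.linspace(0.0, 1.05 * float(model.y.max()),
                                     config.n_y_grid)
                return model.fit(n_bins=config.n_bins,
                                 max_lag=config.max_lag, y_grid=y_grid,
                                 mixture_seed=config.mixture_seed,
                                 n_restarts=config.mixture_restarts,
                                 ivw_fallback=config.ivw_fallback,
                                 bayesian=config.bayesian)

            res = stage(f"landscape:{tag}", fit)
            stage(f"write:{tag}",
                  lambda res=res, tag=tag: _write_landscape_outputs(
                      res, out, tag))
            barcodes[(py, pz, cond)] = res.barcode
            results[tag] = res

    treated = config.treated_condition
    if treated and treated in config.conditions:
        basal_c = config.basal_condition
        for land in config.landscapes:
            py, pz = land["y"], land["z"]
            orientation = land.get("delta_orientation",
                                   "treated_minus_basal")
            key_b = (py, pz, basal_c)
            key_t = (py, pz, treated)
            if key_b in barcodes and key_t in barcodes:
                delta = stage(
                    f"delta:{py}-{pz}",
                    lambda b=barcodes[key_b], t=barcodes[key_t],
                    o=orientation: delta_barcode(b, t, o))
                delta.to_dataframe().to_csv(
                    out / f"{py}-{pz}.delta_barcode.csv", index=False)
        pairs = {(l["y"], l["z"]) for l in config.landscapes}
        if ("monomer", "activity") in pairs and \
                ("activity", "monomer") in pairs:
            rd = stage("ratio", lambda: ratio_delta_barcode(
                barcodes[("monomer", "activity", basal_c)],
                barcodes[("activity", "monomer", basal_c)],
                barcodes[("monomer", "activity", treated)],
                barcodes[("activity", "monomer", treated)]))
            rd.to_dataframe().to_csv(out / "ratio_delta_barcode.csv",
                                     index=False)

    if config.classify:
        act, pol = config.classify["activity"], config.classify["polymer"]
        cond = config.classify.get("condition", config.basal_condition)
        tab = stage("classify", lambda: classify_dataset(ds, act, pol, cond))
        tab.to_csv(out / "classification.csv", index=False)

    if treated and treated in ds.conditions:
        phen = config.landscapes[0]["z"]
        resp = stage("responders", lambda: responder_table(
            ds, phen, config.basal_condition, treated))
        if len(resp):
            resp.to_csv(out / "responders.csv", index=False)

    if config.pdb_in:
        nm = NumberingMap(offset=config.pdb_offset,
                          chain_id=config.pdb_chain)
        for (py, pz, cond), code in barcodes.items():
            stage(f"structure:{py}-{pz}.{cond}",
                  lambda c=code, tag=f"{py}-{pz}.{cond}": write_bfactor_pdb(
                      config.pdb_in, c, nm,
                      out / f"{tag}.bfactor.pdb"))

    _dump_manifest(manifest, out)
    manifest["results"] = results
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _dump_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")
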