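"""Top-level reproducible pipeline driver.

Chains simulate -> ldh -> cellcycle -> kinetics -> classify and the parallel
expression arm (simulate-expression -> sam -> cluster -> enrich) under a
single validated :class:`RunConfig`.  Every stage reads from and writes to
the configured run directory only; a :class:`RunManifest` records the config
hash and a checksum for every input/output file, and a re-run with an
unchanged config skips stages whose recorded checksums still match.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellcycle, cohort as cohort_mod, diagnostic, io, kinetics, ldh
from . import cluster as cluster_mod
from . import panel as panel_mod
from . import sam as sam_mod

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "responses_from_cohort",
           "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; message names every offending field."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults = study preset).

    ``seed`` is mandatory and feeds every stochastic stage through derived
    sub-seeds; the config round-trips losslessly through YAML.
    """

    seed: int | None = None
    out_dir: str = "run"
    cohort: dict = field(default_factory=dict)        # SyntheticCohortSpec overrides
    expression: dict = field(default_factory=dict)    # SyntheticExpressionSpec overrides
    qc_cv_threshold: float = 0.10
    ratio_cap: float = 10.0
    cutoff: float = 0.5
    fdr_target: float = 0.10
    n_perm: int = 1000
    train_fraction: float = 0.62                      # first-cohort share
    prevalence: dict = field(default_factory=lambda: {
        "p_low": 0.023, "p_high": 0.405, "age_low": 57, "age_high": 95})
    lr_apoe4_pos: float = 3.5
    lr_apoe4_neg: float = 0.56
    n_boot: int = 500

    def validate(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed: required, none given")
        if not (0 < self.cutoff < 1):
            problems.append(f"cutoff: must be in (0,1), got {self.cutoff}")
        if not (0 < self.fdr_target < 1):
            problems.append(f"fdr_target: must be in (0,1), got {self.fdr_target}")
        if self.n_perm < 100:
            problems.append(f"n_perm: must be >= 100, got {self.n_perm}")
        if not (0 < self.train_fraction < 1):
            problems.append(f"train_fraction: must be in (0,1), got {self.train_fraction}")
        for key in self.cohort:
            if key not in {f.name for f in dataclasses.fields(cohort_mod.SyntheticCohortSpec)}:
                problems.append(f"cohort.{key}: unknown parameter")
        for key in self.expression:
            if key not in {f.name for f in dataclasses.fields(cohort_mod.SyntheticExpressionSpec)}:
                problems.append(f"expression.{key}: unknown parameter")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)   # stage -> {status, outputs: {path: checksum}}
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path) -> None:
        io.write_json(dataclasses.asdict(self), path)


def _checksums(paths) -> dict:
    return {str(p): io.file_checksum(p) for p in paths}


def _stage_unchanged(prev: dict | None, stage: str, outputs) -> bool:
    if not prev or stage not in prev.get("stages", {}):
        return False
    rec = prev["stages"][stage]
    if rec.get("status") != "ok":
        return False
    recorded = rec.get("outputs", {})
    for p in outputs:
        p = str(p)
        if p not in recorded or not Path(p).exists():
            return False
        if io.file_checksum(p) != recorded[p]:
            return False
    return True


def responses_from_cohort(coh: cohort_mod.Cohort, *, ratio_cap: float = 10.0
                          ) -> pd.DataFrame:
    """Run the measurement chain in memory: LDH -> cell-cycle fit -> kinetics.

    Returns the per-subject response table (indexed by subject id) with
    diagnosis, age, ApoE4 flag, baseline PDT and the treated/untreated
    ratios — the feature table the diagnostic model consumes.
    """
    rows = []
    for s in coh.subjects:
        assay = coh.assays[s.id]
        curve = ldh.fit_calibration(assay.standards)
        counts = {}
        for cond, reps in assay.plate.items():
            m = ldh.LDHMeasurement(condition=cond, absorbances=reps)
            counts[cond] = ldh.absorbance_to_cells(m, curve,
                                                   allow_qc_fail=True).value
        fr_u = cellcycle.fit_histogram(assay.hist_untreated)
        fr_t = cellcycle.fit_histogram(assay.hist_treated)
        ku = kinetics.GrowthKinetics(
            n_seed=counts[ldh.Condition.SEED],
            n_end=counts[ldh.Condition.UNTREATED_72H],
            elapsed=cohort_mod.CULTURE_HOURS, fractions=fr_u)
        kt = kinetics.GrowthKinetics(
            n_seed=counts[ldh.Condition.SEED],
            n_end=counts[ldh.Condition.RAPAMYCIN_72H],
            elapsed=cohort_mod.CULTURE_HOURS, fractions=fr_t)
        resp = kinetics.rapamycin_response(ku, kt, ratio_cap=ratio_cap)
        rows.append({"id": s.id, "diagnosis": s.diagnosis, "age": s.age,
                     "apoe4": s.apoe4, "pdt_baseline": resp.pdt_baseline,
                     "pdt_ratio": resp.pdt_ratio, "g1_ratio": resp.g1_ratio,
                     "apoptotic_shift": resp.apoptotic_shift,
                     "flags": ";".join(resp.flags)})
    return pd.DataFrame(rows).set_index("id")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in dependency order; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    prev = None
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        prev = io.read_json(manifest_path)
        if prev.get("config_hash") != config.hash():
            prev = None

    manifest = RunManifest(config_hash=config.hash(), started=time.time())

    def record(stage, outputs, skipped=False):
        manifest.stages[stage] = {
            "status": "skipped" if skipped else "ok",
            "outputs": _checksums(outputs)}
        logger.info("stage %-10s %s", stage,
                    "skipped (inputs unchanged)" if skipped else "done")

    try:
        # ---- simulate ----------------------------------------------------
        spec = cohort_mod.SyntheticCohortSpec(seed=config.seed, **config.cohort)
        sim_dir = out / "cohort"
        coh = cohort_mod.generate_cohort(spec)
        sim_outputs = [sim_dir / "cohort.csv", sim_dir / "standards.csv",
                       sim_dir / "truth.json"]
        if _stage_unchanged(prev, "simulate", sim_outputs):
            record("simulate", sim_outputs, skipped=True)
        else:
            io.write_cohort_bundle(coh, sim_dir)
            record("simulate", sim_outputs)

        # ---- ldh ---------------------------------------------------------
        standards = io.read_standards(sim_dir / "standards.csv")
        curve = ldh.fit_calibration(standards)
        rows = []
        for s in coh.subjects:
            plate = io.read_plate(sim_dir / "plates" / f"{s.id}.csv")
            for cond, reps in plate.items():
                m = ldh.LDHMeasurement(condition=cond, absorbances=reps)
                cc = ldh.absorbance_to_cells(m, curve, allow_qc_fail=True)
                rows.append({"id": s.id, "condition": cond.value,
                             "cells": cc.value, "cv": m.cv,
                             "qc": m.qc.value})
        cells_df = pd.DataFrame(rows)
        cells_path = out / "cell_counts.csv"
        cells_df.to_csv(cells_path, index=False)
        record("ldh", [cells_path])

        # ---- cellcycle ---------------------------------------------------
        frac_rows = []
        for s in coh.subjects:
            for arm, fname in (("untreated", f"{s.id}_untreated.csv"),
                               ("rapamycin", f"{s.id}_rapamycin.csv")):
                hist = io.read_histogram(sim_dir / "hists" / fname)
                fr = cellcycle.fit_histogram(hist)
                nd = cellcycle.estimate_non_dividing(fr)
                frac_rows.append({
                    "id": s.id, "arm": arm, "sub_g1": fr.sub_g1,
                    "g0g1": fr.g0g1, "s": fr.s, "g2m": fr.g2m,
                    "non_dividing": nd, "non_dividing_definition": "growth-fraction heuristic",
                    "g1_mode": fr.g1_mode, "g1_cv": fr.g1_cv,
                    "g2_g1_ratio": fr.g2_g1_ratio,
                    "residual_norm": fr.residual_norm})
        frac_df = pd.DataFrame(frac_rows)
        frac_path = out / "phase_fractions.csv"
        frac_df.to_csv(frac_path, index=False)
        record("cellcycle", [frac_path])

        # ---- kinetics ----------------------------------------------------
        resp_rows = []
        cells_idx = cells_df.set_index(["id", "condition"])["cells"]
        for s in coh.subjects:
            n0 = cells_idx[(s.id, "seed")]
            fr = {r["arm"]: cellcycle.PhaseFractions(
                      sub_g1=r["sub_g1"], g0g1=r["g0g1"], s=r["s"], g2m=r["g2m"])
                  for r in frac_rows if r["id"] == s.id}
            ku = kinetics.GrowthKinetics(
                n_seed=n0, n_end=cells_idx[(s.id, "untreated_72h")],
                elapsed=cohort_mod.CULTURE_HOURS, fractions=fr["untreated"])
            kt = kinetics.GrowthKinetics(
                n_seed=n0, n_end=cells_idx[(s.id, "rapamycin_72h")],
                elapsed=cohort_mod.CULTURE_HOURS, fractions=fr["rapamycin"])
            resp = kinetics.rapamycin_response(ku, kt, ratio_cap=config.ratio_cap)
            resp_rows.append({"id": s.id, "diagnosis": s.diagnosis,
                              "age": s.age, "apoe4": s.apoe4,
                              "pdt_baseline": resp.pdt_baseline,
                              "pdt_ratio": resp.pdt_ratio,
                              "g1_ratio": resp.g1_ratio,
                              "apoptotic_shift": resp.apoptotic_shift,
                              "flags": ";".join(resp.flags)})
        resp_df = pd.DataFrame(resp_rows).set_index("id")
        resp_path = out / "responses.csv"
        resp_df.to_csv(resp_path)
        record("kinetics", [resp_path])

        # ---- classify ----------------------------------------------------
        fit_df = resp_df[resp_df["diagnosis"].isin(["AD", "Control"])]
        n_train = max(4, int(round(config.train_fraction * len(fit_df))))
        train, valid = fit_df.iloc[:n_train], fit_df.iloc[n_train:]
        model = diagnostic.DiagnosticModel.from_dataframe(
            train, cohort_id="cohort-1")
        res = model.fit()
        scores = res.predict(train)
        labels = (train["diagnosis"] == "AD").astype(float).to_numpy()
        roc = diagnostic.roc_analysis(scores, labels, n_boot=config.n_boot,
                                      seed=config.seed)
        table = diagnostic.operating_point(roc, config.cutoff)
        or_, or_ci, or_flag = table.odds_ratio()
        validation = None
        if len(valid) >= 4 and valid["diagnosis"].nunique() == 2:
            validation = diagnostic.validate_frozen(
                res, valid, (valid["diagnosis"] == "AD").astype(float),
                cohort_id="cohort-2", subject_ids=list(valid.index),
                cutoff=config.cutoff)
        model_json = {
            "coefficients": res.params.to_dict(),
            "bse": res.bse.to_dict(),
            "training_cohort": res.cohort_id,
            "seed": config.seed,
            "auc": roc.auc, "auc_ci": list(roc.auc_ci),
            "sensitivity": table.sensitivity, "specificity": table.specificity,
            "accuracy": table.accuracy,
            "odds_ratio": or_, "odds_ratio_ci": list(or_ci),
            "odds_ratio_haldane": or_flag,
            "validation": (None if validation is None else {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in validation.items()}),
            "config_hash": config.hash(),
        }
        model_path = out / "model.json"
        io.write_json(model_json, model_path)
        roc_df = pd.DataFrame({"threshold": roc.thresholds,
                               "sensitivity": roc.sensitivity,
                               "specificity": roc.specificity})
        roc_path = out / "roc.csv"
        roc_df.to_csv(roc_path, index=False)
        prev_model = diagnostic.PrevalenceModel(**config.prevalence)
        reports = []
        for sid, row in resp_df.iterrows():
            rep = diagnostic.risk_report(
                res, roc, sid, resp_df.loc[[sid]], row["age"], bool(row["apoe4"]),
                cutoff=config.cutoff, prevalence_model=prev_model,
                lr_apoe4_pos=config.lr_apoe4_pos,
                lr_apoe4_neg=config.lr_apoe4_neg)
            reports.append({**dataclasses.asdict(rep),
                            "diagnosis": row["diagnosis"]})
        risk_path = out / "risk_reports.csv"
        pd.DataFrame(reports).to_csv(risk_path, index=False)
        record("classify", [model_path, roc_path, risk_path])

        # ---- sam ---------------------------------------------------------
        espec = cohort_mod.SyntheticExpressionSpec(seed=config.seed,
                                                   **config.expression)
        matrix, groups_df, truth = cohort_mod.generate_expression(espec)
        io.write_expression(matrix, out / "expression.tsv")
        io.write_groups(groups_df, out / "groups.csv")
        groups = groups_df.set_index("sample_id")["group"]
        results = {}
        for name, keep in (("limbic_vs_control", ("Limbic", "Control")),
                           ("neocortical_vs_control", ("Neocortical", "Control"))):
            # disease group first so d > 0 means up-regulated in disease
            cols = (list(groups[groups == keep[0]].index)
                    + list(groups[groups == keep[1]].index))
            r = sam_mod.SAM(matrix[cols], groups[cols]).fit(
                fdr_target=config.fdr_target, n_perm=config.n_perm,
                seed=config.seed)
            results[name] = r
        results["multiclass"] = sam_mod.SAM(matrix, groups,
                                            statistic="multiclass").fit(
            fdr_target=config.fdr_target, n_perm=config.n_perm,
            seed=config.seed)
        sam_json = {}
        for name, r in results.items():
            sam_json[name] = {"s0": r.s0, "delta": r.delta,
                              "estimated_fdr": r.estimated_fdr,
                              "n_up": len(r.significant_up),
                              "n_down": len(r.significant_down),
                              "n_permutations": r.n_permutations,
                              "seed": r.seed, "config_hash": config.hash()}
            io.write_gene_list(r.significant, out / f"sam_{name}_genes.txt")
        sam_path = out / "sam_results.json"
        io.write_json(sam_json, sam_path)

        sig = results["multiclass"].significant
        if len(sig) >= 2:
            hm = cluster_mod.build_heatmap(matrix.loc[sig])
            cluster_mod.export_heatmap(hm, out / "heatmap.png",
                                       out / "heatmap.tsv")
        enr = panel_mod.overlap_and_enrichment(
            panel_mod.packaged_gene_list("mtor_panel_synthetic"),
            panel_mod.packaged_gene_list("apoe_regulated_synthetic"),
            universe_size=panel_mod.DEFAULT_UNIVERSE)
        io.write_json(enr, out / "enrichment.json")
        record("sam", [sam_path, out / "enrichment.json"])
    except Exception:
        manifest.finished = time.time()
        manifest.stages.setdefault("failed", {"status": "error"})
        manifest.to_json(manifest_path)
        raise

    manifest.finished = time.time()
    manifest.to_json(manifest_path)
    return manifest
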