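"""End-to-end orchestration: simulate or ingest, exclude, classify, report.

``run_pipeline`` drives the whole analysis from a YAML/JSON config and
writes plain TSV/CSV reports plus a JSON run manifest that itemizes every
exclusion and per-stage row count, so the subject-flow bookkeeping always
reconciles and reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort, read_cohort_csv
from .concordance import concordance_report
from .diagnostics import diagnostics_report
from .geometry import MedianTable, classify_cohort, tabulate_phenotypes
from .survival import ConvergenceError, fit_cox, geometry_design

__all__ = ["RunManifest", "apply_exclusions", "run_pipeline", "load_config"]


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    package_version: str
    input_checksum: str | None
    stage_counts: dict[str, int] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    completed: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows unusable for incidence analysis, itemized by reason.

    First removes subjects with any missing arterial measure (the analysis
    requires complete bilateral IMT and diameter), then subjects with
    prevalent stroke at baseline.
    """
    measure_cols = ["r_imt_mm", "l_imt_mm", "r_dia_mm", "l_dia_mm"]
    missing = cohort[measure_cols].isna().any(axis=1)
    after_measures = cohort[~missing]
    prevalent = after_measures["prevalent_stroke"].astype(int) == 1
    analysis = after_measures[~prevalent].reset_index(drop=True)
    tally = {
        "missing_measures": int(missing.sum()),
        "prevalent_stroke": int(prevalent.sum()),
    }
    return analysis, tally


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _median_table_from_config(cfg: dict) -> MedianTable | None:
    block = cfg.get("medians")
    if not block:
        return None
    vals = {}
    for sex, sides in block.items():
        for side, params in sides.items():
            for param, v in params.items():
                vals[(sex.upper(), side.upper(), param.upper())] = float(v)
    return MedianTable(vals)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Run simulate/ingest -> exclusions -> classify -> all reports.

    The config either names an ``input_csv`` or carries a ``simulate``
    block with :class:`~bicarotid.cohort.CohortConfig` fields.  Deterministic
    for a fixed seed and config.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = None
    checksum = None

    if "input_csv" in config:
        path = Path(config["input_csv"])
        checksum = hashlib.sha256(path.read_bytes()).hexdigest()
        cohort = read_cohort_csv(path)
    elif "simulate" in config:
        sim = dict(config["simulate"])
        cc = CohortConfig(**sim)
        seed = cc.seed
        cohort = generate_cohort(cc)
    else:
        raise ValueError("config needs either an 'input_csv' or a 'simulate' block")

    manifest = RunManifest(
        config=config, seed=seed, package_version=__version__, input_checksum=checksum
    )
    manifest.stage_counts["loaded"] = len(cohort)

    analysis, tally = apply_exclusions(cohort)
    manifest.exclusions = tally
    manifest.stage_counts["analysis"] = len(analysis)

    recompute = config.get("recompute_medians", True)
    medians = MedianTable.from_cohort(analysis) if recompute else _median_table_from_config(config)
    if medians is None:
        raise ValueError("recompute_medians is false but no 'medians' block was supplied")

    classified = classify_cohort(analysis, medians)
    manifest.stage_counts["classified"] = len(classified)

    def _write(df: pd.DataFrame, name: str, sep="\t") -> None:
        path = outdir / name
        df.to_csv(path, sep=sep, index=False, float_format="%.6g")
        manifest.outputs.append(name)

    classified.to_csv(outdir / "cohort_classified.csv", index=False, float_format="%.6g")
    manifest.outputs.append("cohort_classified.csv")

    _write(medians.to_frame(), "medians.tsv")

    seed_boot = int(config.get("bootstrap_seed", seed or 0))
    n_boot = int(config.get("n_boot", 2000))
    pooled = config.get("pooled", False)
    conc = []
    strata = ["M", "F"] + ([None] if pooled else [])
    for sex in strata:
        rep = concordance_report(classified, sex, n_boot=n_boot, seed=seed_boot)
        rep.insert(0, "sex", sex or "ALL")
        conc.append(rep)
    _write(pd.concat(conc, ignore_index=True), "concordance.tsv")

    _write(tabulate_phenotypes(classified, medians), "phenotypes.tsv")
    _write(diagnostics_report(classified), "diagnostics.tsv")

    ties = config.get("ties", "breslow")
    cox_rows = []
    for sex in ("M", "F"):
        sub = classified[classified["sex"] == sex]
        for side in ("R", "L"):
            t, e, X = geometry_design(sub, side)
            try:
                fit = fit_cox(t, e, X, ties=ties)
                s = fit.summary()
                s["note"] = ""
            except ConvergenceError as exc:
                # e.g. a stratum with no events in small cohorts: report and go on
                s = pd.DataFrame({"term": list(X.columns)})
                s["note"] = f"not estimable: {exc}"
                manifest.stage_counts.setdefault("cox_failures", 0)
                manifest.stage_counts["cox_failures"] += 1
            s.insert(0, "side", side)
            s.insert(0, "sex", sex)
            cox_rows.append(s)
    _write(pd.concat(cox_rows, ignore_index=True), "cox_fits.tsv")

    manifest.completed = True
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
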