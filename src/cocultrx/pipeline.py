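"""End-to-end report pipelines.

Each pipeline reads plain-text inputs (GMT / CSV), runs the corresponding
analysis chain, and writes a bundle of CSV reports plus a JSON manifest
(input hashes, parameters, package version) sufficient to reproduce the
run exactly.  Outputs carry no timestamps, so re-running with identical
inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import coculture_expression as ccx
from .enrichment import crosstalk, crosstalk_to_tidy, screen
from .exceptions import ValidationError
from .genesets import overlap_matrix, read_gene_sets, read_universe
from .rtca import RtcaTrace, delta_cell_index, dose_response_summary, linear_phase_slope
from .util import sha256_file

log = logging.getLogger(__name__)


def _write_manifest(out_dir: Path, stage: str, inputs: Mapping[str, str | Path],
                    parameters: Mapping, outputs: list[str]) -> Path:
    manifest = {
        "package": "cocultrx",
        "version": __version__,
        "stage": stage,
        "inputs": {str(k): {"path": str(v), "sha256": sha256_file(v)}
                   for k, v in inputs.items()},
        "parameters": dict(parameters),
        "outputs": outputs,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _prepare_out(out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_enrichment_pipeline(
    datasets_path: str | Path,
    pathways_path: str | Path,
    universe_path: str | Path,
    out_dir: str | Path,
    confidence: float = 0.90,
    variance: str = "binomial",
    focal: str | None = None,
) -> dict[str, Path]:
    """Overlap matrix + over-representation screen (+ crosstalk vs a focal
    pathway across every dataset, when one is named)."""
    for p in (datasets_path, pathways_path, universe_path):
        if not Path(p).is_file():
            raise ValidationError(f"input file not found: {p}")
    out = _prepare_out(out_dir)
    datasets = read_gene_sets(datasets_path)
    pathways = read_gene_sets(pathways_path)
    universe = read_universe(universe_path)

    log.info("enrich: overlap matrix over %d datasets", len(datasets))
    om = overlap_matrix(datasets, universe)
    om.to_formatted().to_csv(out / "overlap_matrix.csv")
    om.to_long().to_csv(out / "overlap_long.csv", index=False)

    log.info("enrich: screening %d pathways x %d datasets", len(pathways), len(datasets))
    matrix = screen(datasets, pathways, universe, confidence=confidence, variance=variance)
    matrix.to_tidy().to_csv(out / "enrichment.csv", index=False)
    matrix.to_marked().to_csv(out / "enrichment_marked.csv")

    outputs = ["overlap_matrix.csv", "overlap_long.csv", "enrichment.csv",
               "enrichment_marked.csv"]
    if focal is not None:
        by_name = {p.name: p for p in pathways}
        if focal not in by_name:
            raise ValidationError(f"focal pathway {focal!r} not in pathway collection")
        others = [p for p in pathways if p.name != focal]
        rows = []
        for ds in datasets:
            rows.append(crosstalk_to_tidy(
                crosstalk(by_name[focal], others, ds, universe,
                          confidence=confidence, variance=variance)))
        pd.concat(rows, ignore_index=True).to_csv(out / "crosstalk.csv", index=False)
        outputs.append("crosstalk.csv")

    _write_manifest(
        out, "enrich",
        {"datasets": datasets_path, "pathways": pathways_path, "universe": universe_path},
        {"confidence": confidence, "variance": variance, "focal": focal,
         "n_tests": matrix.n_tests},
        outputs,
    )
    return {name: out / name for name in outputs + ["manifest.json"]}


def run_qpcr_pipeline(
    table_path: str | Path,
    out_dir: str | Path,
    mixture: float = 0.9,
    threshold: float = 2.0,
    treated_condition: str | None = None,
    control_condition: str = ccx.COCULTURE,
) -> dict[str, Path]:
    """Mixture fold-change report from a tidy replicate table, with direction
    calls and a list of non-evaluable genes; optional treated-arm folds."""
    if not Path(table_path).is_file():
        raise ValidationError(f"input file not found: {table_path}")
    out = _prepare_out(out_dir)
    table = pd.read_csv(table_path)
    means = ccx.condition_means(table)
    fc = ccx.fc_vs_theoretical(means, prop=mixture, threshold=threshold)

    report = fc.merge(
        means.pivot(index="gene", columns="condition", values="mean").add_suffix("_mean"),
        left_on="gene", right_index=True, how="left",
    )
    outputs = ["fold_changes.csv", "not_evaluable.csv"]
    if treated_condition is not None:
        tf = ccx.treatment_folds_from_means(means, treated_condition, control_condition)
        tf.to_csv(out / "treatment_folds.csv", index=False)
        outputs.append("treatment_folds.csv")
    report.to_csv(out / "fold_changes.csv", index=False)
    fc.loc[~fc["evaluable"], ["gene", "direction"]].to_csv(
        out / "not_evaluable.csv", index=False)
    n_bad = int((~fc["evaluable"]).sum())
    if n_bad:
        log.warning("qpcr: %d genes not evaluable (undetected conditions)", n_bad)

    _write_manifest(
        out, "qpcr", {"table": table_path},
        {"mixture": mixture, "threshold": threshold,
         "treated_condition": treated_condition,
         "control_condition": control_condition},
        outputs,
    )
    return {name: out / name for name in outputs + ["manifest.json"]}


def run_rtca_pipeline(
    traces_path: str | Path,
    out_dir: str | Path,
    treat_time: float | None = None,
    eval_time: float | None = None,
    window: tuple[float, float] | None = None,
) -> dict[str, Path]:
    """Growth/dose report: per-group linear-phase slope, delta cell index at
    the evaluation time, and a dose-response summary when doses and a
    treatment time are given."""
    if not Path(traces_path).is_file():
        raise ValidationError(f"input file not found: {traces_path}")
    out = _prepare_out(out_dir)
    table = pd.read_csv(traces_path)
    if table.empty:
        raise ValidationError(f"{traces_path}: trace table is empty")
    if "condition" not in table.columns:
        table["condition"] = "all"
    if "dose_uM" not in table.columns:
        table["dose_uM"] = 0.0

    traces: dict[tuple[str, float], RtcaTrace] = {}
    for (cond, dose), sub in table.groupby(["condition", "dose_uM"]):
        traces[(cond, float(dose))] = RtcaTrace.from_long(
            sub, condition=cond, dose_uM=float(dose), t_treat=treat_time)

    slope_rows = []
    for (cond, dose), trace in traces.items():
        fit = linear_phase_slope(trace, window=window)
        slope_rows.append(
            {"condition": cond, "dose_uM": dose, "slope_per_h": fit.slope,
             "window_start_h": fit.window[0], "window_end_h": fit.window[1],
             "r2": fit.r2, "mean_ci": fit.mean_ci}
        )
    pd.DataFrame(slope_rows).to_csv(out / "slopes.csv", index=False)
    outputs = ["slopes.csv"]

    if treat_time is not None and eval_time is not None:
        delta_rows = []
        for (cond, dose), trace in traces.items():
            d = delta_cell_index(trace, treat_time).at(eval_time)
            for well, v in zip(trace.well_ids, d):
                delta_rows.append({"condition": cond, "dose_uM": dose,
                                   "well": well, "delta_ci": float(v)})
        pd.DataFrame(delta_rows).to_csv(out / "delta_ci.csv", index=False)
        outputs.append("delta_ci.csv")

        for cond in sorted({c for c, _ in traces}):
            by_dose = {dose: tr for (c, dose), tr in traces.items() if c == cond}
            if len(by_dose) > 1 and 0.0 in by_dose:
                summary = dose_response_summary(by_dose, eval_time, treat_time)
                summary.insert(0, "condition", cond)
                name = f"dose_response_{cond}.csv"
                summary.to_csv(out / name, index=False)
                outputs.append(name)

    _write_manifest(
        out, "rtca", {"traces": traces_path},
        {"treat_time": treat_time, "eval_time": eval_time, "window": window},
        outputs,
    )
    return {name: out / name for name in outputs + ["manifest.json"]}
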