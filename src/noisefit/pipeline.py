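"""End-to-end orchestration: study panel -> analysis tables.

Glue between the synthetic study panel (or equivalently structured
real data) and the per-stage operations: per-sample expression
summaries with batch correction and autofluorescence subtraction,
replicate-level fitness with reference normalization, and the merged
genotype table the ΔNoise/ΔFitness analysis consumes.
"""

from __future__ import annotations

import pandas as pd

from . import cytometry_expression as cyto
from . import competition_fitness as fit
from .noise_fitness_analysis import (AnalysisConfig, DeltaTable,
                                     delta_metrics, pearson_test)
from .synthetic_data import StudyPanel

__all__ = ["expression_table", "fitness_table", "analysis_panel",
           "correlation_by_class"]


def _summaries(samples, min_cells=1000):
    out = []
    for s in samples:
        out.append(cyto.process_sample(
            s.events, min_cells=min_cells,
            sample_id=f"{s.genotype_id}.{s.replicate}",
            flow_run=s.flow_run, row=s.row))
    return out


def expression_table(panel: StudyPanel, min_cells: int = 1000,
                     batch_correct: bool = True) -> pd.DataFrame:
    """Per-genotype expression and noise (percent of reference).

    Runs every flow sample through filtering, size normalization, the
    mRNA calibration and summarization; corrects flow-run effects using
    the reference-strain replicates as controls; subtracts the blank
    strain; and aggregates replicates relative to the reference.
    """
    if not panel.expression:
        raise ValueError("panel carries no flow events "
                         "(generated with generate_events=False?)")
    per_genotype = {gid: _summaries(samples, min_cells)
                    for gid, samples in panel.expression.items()}
    ref = _summaries(panel.reference_expression, min_cells)
    blank = _summaries(panel.blank_expression, min_cells)

    if batch_correct:
        flat = [s for group in per_genotype.values() for s in group] + ref
        corrected = cyto.correct_batch(flat, controls=ref,
                                       factors=("flow_run",))
        it = iter(corrected)
        per_genotype = {gid: [next(it) for _ in group]
                        for gid, group in per_genotype.items()}
        ref = [next(it) for _ in ref]

    per_genotype = {gid: cyto.subtract_autofluorescence(group, blank)
                    for gid, group in per_genotype.items()}
    ref = cyto.subtract_autofluorescence(ref, blank)

    rows = []
    for gid, group in per_genotype.items():
        summ = cyto.aggregate_genotype(group, ref, genotype_id=gid)
        row = {"genotype": gid,
               "median_expression_pct": summ.median_expression_pct,
               "n_replicates": summ.n_replicates}
        for met, val in summ.noise_pct.items():
            row[f"noise_{met}_pct"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def fitness_table(panel: StudyPanel) -> pd.DataFrame:
    """Per-genotype relative fitness from the competition series."""
    ref_w = [fit.fitness_from_series(s) for s in panel.reference_competition]
    rows = []
    for gid, series in panel.competition.items():
        est = fit.relative_fitness(
            [fit.fitness_from_series(s) for s in series], ref_w)
        rows.append({"genotype": gid, "fitness": est.w_rel,
                     "fitness_ci_low": est.ci95[0],
                     "fitness_ci_high": est.ci95[1],
                     "n_replicates": est.n_replicates})
    return pd.DataFrame(rows)


def analysis_panel(panel: StudyPanel, noise_metric: str = "strength",
                   min_cells: int = 1000) -> pd.DataFrame:
    """Merged genotype table for the residual analysis.

    Columns: genotype, median_expression_pct, noise_pct (the requested
    metric) and fitness.
    """
    expr = expression_table(panel, min_cells=min_cells)
    fitn = fitness_table(panel)
    merged = expr.merge(fitn, on="genotype", suffixes=("_expr", "_fit"))
    merged["noise_pct"] = merged[f"noise_{noise_metric}_pct"]
    return merged[["genotype", "median_expression_pct", "noise_pct",
                   "fitness"]]


def correlation_by_class(delta: DeltaTable, method: str = "t",
                         n_perm: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """ΔNoise–ΔFitness Pearson r per optimum class (far / close)."""
    rows = []
    for cls in ("far", "close"):
        sub = delta.table.loc[delta.table["optimum_class"] == cls]
        if len(sub) >= 3:
            r, p, r2 = pearson_test(sub["delta_noise"], sub["delta_fitness"],
                                    method=method, n_perm=n_perm, seed=seed)
        else:
            r = p = r2 = float("nan")
        rows.append({"optimum_class": cls, "n": len(sub), "r": r, "p": p,
                     "r_squared": r2})
    return pd.DataFrame(rows)
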