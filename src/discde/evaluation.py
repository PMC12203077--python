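"""Confusion metrics and the Monte-Carlo simulation harness.

A *run* is one simulated dataset pushed through the full test; its result is
scored against the simulation ground truth:

- **type I error** — fraction of truly null genes with raw permutation
  p < alpha (default 5%),
- **FDP** — FP / max(TP + FP, 1) among genes called at q ≤ the FDR target
  (default 10%); its average over runs is the empirical FDR,
- **TPR** — TP / (TP + FN) among truly DE genes, overall and split by the
  kind of injected signal (mean / variance / both).

A *study* repeats runs over a grid of simulator scenarios with
deterministically derived per-run seeds and aggregates means and standard
errors.  Under a global null it additionally reports the fraction of runs
with any positive call, which equals the mean FDP there and coincides with
the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import filter_sparsity
from .exceptions import ValidationError
from .inference import DiscResult, run_disc
from .simulate import DE_TYPES, SimTruth, generate_dataset

__all__ = ["RunMetrics", "ScenarioConfig", "StudySummary", "score_run", "run_study", "derive_seed"]


@dataclass
class RunMetrics:
    """Confusion metrics for one simulated run."""

    tp: int
    fp: int
    fn: int
    tn: int
    type_I_error: float
    fdp: float
    tpr: float  # NaN when no DE genes (global null)
    tpr_by_type: dict[str, float]
    n_null: int
    alpha: float
    fdr_target: float

    @property
    def n_genes(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def any_positive(self) -> bool:
        return (self.tp + self.fp) > 0


def score_run(
    result: DiscResult,
    truth: SimTruth,
    alpha: float = 0.05,
    fdr_target: float = 0.10,
) -> RunMetrics:
    """Score one test result against its simulation truth.

    Genes are matched by ID; metrics cover the genes present in the result
    (genes removed by sparsity filtering were never tested and are excluded).
    """
    t = truth.table.set_index("gene_id")
    missing = [g for g in result.gene_ids if g not in t.index]
    if missing:
        raise ValidationError(f"result genes absent from truth: {missing[:5]}")
    de_type = t.loc[list(result.gene_ids), "de_type"].to_numpy()
    is_de = de_type != "none"
    positive = result.q <= fdr_target

    tp = int(np.sum(positive & is_de))
    fp = int(np.sum(positive & ~is_de))
    fn = int(np.sum(~positive & is_de))
    tn = int(np.sum(~positive & ~is_de))

    n_null = int(np.sum(~is_de))
    type_i = float(np.sum((result.p < alpha) & ~is_de) / n_null) if n_null else float("nan")
    fdp = fp / max(tp + fp, 1)
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    by_type = {}
    for kind in DE_TYPES:
        sel = de_type == kind
        by_type[kind] = float(np.sum(positive & sel) / sel.sum()) if sel.any() else float("nan")
    return RunMetrics(
        tp, fp, fn, tn, type_i, fdp, tpr, by_type, n_null, alpha, fdr_target
    )


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid (generator settings for a scenario)."""

    name: str
    n_genes: int = 1000
    n_individuals: int = 24
    n_cell: int = 375
    fold: float = 1.0
    density: float = 0.05
    size_factor_sd: float = 0.0


@dataclass
class StudySummary:
    """Aggregated metrics per scenario (means and SEs over runs)."""

    table: pd.DataFrame
    runs: int
    seed: int
    B: int
    scenarios: list[ScenarioConfig] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        header = f"# runs={self.runs}\n# seed={self.seed}\n# B={self.B}\n"
        body = self.table.to_csv(sep="\t", index=False, float_format="%.6g")
        Path(path).write_text(header + body)

    def row(self, name: str) -> pd.Series:
        sel = self.table[self.table["scenario"] == name]
        if sel.empty:
            raise ValidationError(f"no scenario named {name!r}")
        return sel.iloc[0]


def derive_seed(master: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and counters."""
    ss = np.random.SeedSequence([int(master), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def _se(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def run_study(
    scenarios: list[ScenarioConfig],
    runs: int,
    seed: int = 0,
    B: int = 99,
    alpha: float = 0.05,
    fdr_target: float = 0.10,
    max_sparsity: float = 0.8,
    n_threads: int = 1,
    progress: bool = False,
) -> StudySummary:
    """Monte-Carlo study: generate → filter → test → score, per scenario.

    Per-run seeds are derived from (seed, scenario index, run index), so
    studies are reproducible and individual runs can be re-executed in
    isolation.  A failing run aborts the study rather than being skipped.
    """
    if runs < 2:
        raise ValidationError("need at least 2 runs for standard errors")
    rows = []
    for s_idx, scen in enumerate(scenarios):
        per_run: list[RunMetrics] = []
        for r_idx in range(runs):
            rs = derive_seed(seed, s_idx, r_idx)
            ds = generate_dataset(
                n_genes=scen.n_genes,
                n_individuals=scen.n_individuals,
                n_cell=scen.n_cell,
                fold=scen.fold,
                density=scen.density,
                size_factor_sd=scen.size_factor_sd,
                seed=rs,
            )
            cm = filter_sparsity(ds.counts, max_sparsity)
            res = run_disc(
                cm, ds.design, B=B, seed=derive_seed(rs, 1), n_threads=n_threads
            )
            per_run.append(score_run(res, ds.truth, alpha, fdr_target))
            if progress:  # pragma: no cover - cosmetic
                print(f"[{scen.name}] run {r_idx + 1}/{runs} done", flush=True)

        type1 = np.array([m.type_I_error for m in per_run])
        fdp = np.array([m.fdp for m in per_run])
        fps = np.array([m.fp for m in per_run], dtype=float)
        tpr = np.array([m.tpr for m in per_run])
        # pooled variant: all null gene-level tests across runs as one pool
        null_hits = sum(
            int(round(m.type_I_error * m.n_null)) for m in per_run if m.n_null
        )
        null_total = sum(m.n_null for m in per_run)
        row = {
            "scenario": scen.name,
            "fold": scen.fold,
            "n_genes": scen.n_genes,
            "n_individuals": scen.n_individuals,
            "n_cell": scen.n_cell,
            "density": scen.density,
            "runs": runs,
            "type1_mean": float(np.nanmean(type1)),
            "type1_se": _se(type1),
            "type1_pooled": null_hits / null_total if null_total else float("nan"),
            "fdp_mean": float(np.mean(fdp)),
            "fdp_se": _se(fdp),
            "any_positive_rate": float(np.mean([m.any_positive for m in per_run])),
            "avg_fp": float(np.mean(fps)),
            "avg_fp_se": _se(fps),
            "tpr_mean": float(np.nanmean(tpr)) if not np.all(np.isnan(tpr)) else float("nan"),
            "tpr_se": _se(tpr),
        }
        for kind in DE_TYPES:
            vals = np.array([m.tpr_by_type[kind] for m in per_run])
            all_nan = np.all(np.isnan(vals))
            row[f"tpr_{kind}_mean"] = float(np.nanmean(vals)) if not all_nan else float("nan")
            row[f"tpr_{kind}_se"] = _se(vals)
        rows.append(row)
    return StudySummary(pd.DataFrame(rows), runs, seed, B, list(scenarios))
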