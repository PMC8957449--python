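"""Benchmark harness: breakpoint matching, metrics, and coverage sweeps.

A call matches a truth breakpoint when they lie within a positional
tolerance (default ±5 bp) and — by default — agree on SV type.  Matching is
greedy nearest-first and strictly one-to-one, so redundant calls near one
truth point count as false positives.  Sensitivity is tp/(tp+fn) over truth
breakpoints, precision tp/(tp+fp) over calls, and F1 their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import ModelBundle, ModelConfig, SVCall, SVType, SV_TYPES
from .pipeline import DEFAULT_BACKGROUND_PER_MB, labeled_set_from_sim
from .simulate import SimConfig, SimResult, simulate_dataset
from .train import LabeledSiteSet, TrainConfig, train_all


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]      # (call index, truth index)
    tolerance: int

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of matched pairs")


@dataclass(frozen=True)
class MetricRow:
    svtype: str                       # a type name or "ALL"
    coverage: float | None
    sensitivity: float
    precision: float
    f1: float
    n_reps: int = 1


def match_calls(
    calls: list[SVCall],
    truth: list[tuple[int, SVType]],
    tolerance_bp: int = 5,
    require_type: bool = True,
) -> MatchResult:
    """Optimal one-to-one matching of calls to truth breakpoints.

    Maximizes the number of matched pairs within the tolerance (breaking
    remaining freedom by minimum total distance), which coincides with
    nearest-first pairing except in adversarial chains where the nearest
    pick would block a second match.  ``truth`` holds (0-based position,
    SVType) tuples; call positions are 1-based and converted internally.
    Unmatched calls are false positives, unmatched truth breakpoints false
    negatives.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    if not calls or not truth:
        return MatchResult(tp=0, fp=len(calls), fn=len(truth),
                           pairs=[], tolerance=tolerance_bp)
    from scipy.optimize import linear_sum_assignment

    FORBIDDEN = 10.0 ** 9
    cpos = np.array([c.pos - 1 for c in calls])
    tpos = np.array([t[0] for t in truth])
    cost = np.abs(cpos[:, None] - tpos[None, :]).astype(float)
    allowed = cost <= tolerance_bp
    if require_type:
        ctype = np.array([int(c.svtype) for c in calls])
        ttype = np.array([int(t[1]) for t in truth])
        allowed &= ctype[:, None] == ttype[None, :]
    cost[~allowed] = FORBIDDEN
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(ci), int(ti)) for ci, ti in zip(rows, cols)
             if allowed[ci, ti]]
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp,
                       pairs=pairs, tolerance=tolerance_bp)


def compute_metrics(match: MatchResult, svtype: str = "ALL",
                    coverage: float | None = None, n_reps: int = 1) -> MetricRow:
    """Sensitivity, precision and F1 from a match result (0 when undefined)."""
    sens = match.tp / (match.tp + match.fn) if match.tp + match.fn else 0.0
    prec = match.tp / (match.tp + match.fp) if match.tp + match.fp else 0.0
    f1 = 2 * sens * prec / (sens + prec) if sens + prec > 0 else 0.0
    return MetricRow(svtype=svtype, coverage=coverage, sensitivity=sens,
                     precision=prec, f1=f1, n_reps=n_reps)


def per_type_metrics(
    calls: list[SVCall],
    truth: list[tuple[int, SVType]],
    tolerance_bp: int = 5,
    coverage: float | None = None,
) -> list[MetricRow]:
    """One global type-aware matching, reported per type plus pooled ALL."""
    match = match_calls(calls, truth, tolerance_bp, require_type=True)
    rows = [compute_metrics(match, svtype="ALL", coverage=coverage)]
    matched_calls = {ci for ci, _ in match.pairs}
    matched_truth = {ti for _, ti in match.pairs}
    for t in SV_TYPES:
        tp = sum(1 for ci, ti in match.pairs if truth[ti][1] == t)
        fn = sum(1 for ti, (_, tt) in enumerate(truth)
                 if tt == t and ti not in matched_truth)
        fp = sum(1 for ci, c in enumerate(calls)
                 if c.svtype == t and ci not in matched_calls)
        sub = MatchResult(tp=tp, fp=fp, fn=fn,
                          pairs=[(ci, ti) for ci, ti in match.pairs
                                 if truth[ti][1] == t],
                          tolerance=tolerance_bp)
        rows.append(compute_metrics(sub, svtype=t.name, coverage=coverage))
    return rows


def run_replicate(
    bundle: ModelBundle,
    sim_config: SimConfig,
    tolerance_bp: int = 5,
    threshold: float | None = None,
    background_per_mb: float = DEFAULT_BACKGROUND_PER_MB,
    bg_seed: int = 0,
) -> tuple[list[MetricRow], list[SVCall], SimResult]:
    """Simulate one dataset, extract, predict, and score against truth."""
    sim = simulate_dataset(sim_config)
    siteset, ex = labeled_set_from_sim(
        sim, background_per_mb=background_per_mb,
        rng=np.random.default_rng(bg_seed),
    )
    calls = bundle.call(ex.sites, ex.matrix, threshold=threshold,
                        chrom=sim_config.chrom)
    rows = per_type_metrics(calls, sim.truth_breakpoints, tolerance_bp,
                            coverage=sim_config.coverage)
    return rows, calls, sim


def train_bundle_from_sims(
    base_config: SimConfig,
    train_config: TrainConfig,
    model_config: ModelConfig,
    train_coverages: tuple[float, ...] = 12 * (10.0, 20.0, 30.0, 40.0),
    seed: int = 0,
    background_per_mb: float = DEFAULT_BACKGROUND_PER_MB,
) -> ModelBundle:
    """Train the seven classifiers on independent simulated genomes, one per
    training coverage."""
    root = np.random.default_rng(seed)
    parts = []
    for g, cov in enumerate(train_coverages):
        cfg = replace(base_config, coverage=float(cov),
                      seed=int(root.integers(0, 2**31)))
        sim = simulate_dataset(cfg)
        siteset, _ = labeled_set_from_sim(
            sim, group=g, background_per_mb=background_per_mb,
            rng=np.random.default_rng(int(root.integers(0, 2**31))),
        )
        parts.append(siteset)
    merged = LabeledSiteSet.concatenate(parts)
    return train_all(merged, train_config, model_config)


@dataclass
class SweepResult:
    summary: pd.DataFrame      # mean metrics per (coverage, svtype)
    per_rep: pd.DataFrame      # one row per (coverage, replicate, svtype)
    bundle: ModelBundle


def coverage_sweep(
    coverages: "list[float] | dict[float, int]",
    n_reps: int,
    base_config: SimConfig,
    seed: int,
    bundle: ModelBundle | None = None,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    tolerance_bp: int = 5,
) -> SweepResult:
    """The coverage-replication study: per coverage and replicate, simulate,
    extract, predict with a bundle trained once on independent simulations,
    match to truth, and average the per-type metrics over replicates.

    ``coverages`` may map coverage -> replicate count to vary replication by
    coverage; a plain list uses ``n_reps`` everywhere.  Fully seeded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(coverages, dict):
        plan = {float(c): int(r) for c, r in coverages.items()}
    else:
        plan = {float(c): n_reps for c in coverages}
    train_config = train_config or TrainConfig(seed=seed)
    model_config = model_config or ModelConfig()
    root = np.random.default_rng(seed)
    train_seed = int(root.integers(0, 2**31))
    if bundle is None:
        bundle = train_bundle_from_sims(base_config, train_config, model_config,
                                        seed=train_seed)
    records = []
    for cov in sorted(plan):
        for rep in range(plan[cov]):
            rep_seed = int(np.random.default_rng(
                np.random.SeedSequence([seed, int(cov), rep])).integers(0, 2**31))
            cfg = replace(base_config, coverage=cov, seed=rep_seed)
            rows, _, _ = run_replicate(bundle, cfg, tolerance_bp,
                                       bg_seed=rep_seed + 1)
            for r in rows:
                records.append({
                    "coverage": cov, "replicate": rep, "svtype": r.svtype,
                    "sensitivity": r.sensitivity, "precision": r.precision,
                    "f1": r.f1,
                })
    per_rep = pd.DataFrame.from_records(records)
    summary = (
        per_rep.groupby(["coverage", "svtype"], as_index=False)
        .agg(sensitivity=("sensitivity", "mean"),
             precision=("precision", "mean"),
             f1=("f1", "mean"),
             n_reps=("replicate", "count"))
    )
    return SweepResult(summary=summary, per_rep=per_rep, bundle=bundle)


def sensitivity_gains(summary: pd.DataFrame, low: float = 10.0,
                      high: float = 40.0) -> dict[str, float]:
    """Per-type sensitivity gain (percentage points) from low to high coverage."""
    gains = {}
    for t in SV_TYPES:
        s_low = summary.query("coverage == @low and svtype == @t.name")["sensitivity"]
        s_high = summary.query("coverage == @high and svtype == @t.name")["sensitivity"]
        if len(s_low) and len(s_high):
            gains[t.name] = 100.0 * (float(s_high.iloc[0]) - float(s_low.iloc[0]))
    return gains


def write_metrics(summary: pd.DataFrame, tsv_path: str | None = None,
                  json_path: str | None = None) -> None:
    if tsv_path:
        summary.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        summary.to_json(json_path, orient="records", indent=2)
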