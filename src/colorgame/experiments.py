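"""Experiment orchestration: noise sweeps, term-count bucketing, efficiency
tables, noise-consistency tables and vocabulary-vs-noise trends.

A sweep trains one sender/receiver pair per (noise level, replicate) with
independently derived seeds; the standard design is ten environmental-noise
variances {1, 2, ..., 512} x 25 replicates at a fixed channel-noise scale of 0.1 (variance 0.01).  That
full design is hours-scale; ``runs_per_level``, episode counts and level sets
all scale down without changing the analysis structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .color_domain import ChipChart
from .corr_clustering import build_similarity_graph, solve
from .metrics import MetricReport, adjusted_rand_index, mean_pairwise_ari, report
from .partitioning import Partition, agent_partition, random_partition
from .training import GameConfig, TrainingDivergedError, TrainingTrace, train

__all__ = [
    "SweepSpec",
    "RunResult",
    "run_sweep",
    "bucket_by_terms",
    "term_histogram",
    "efficiency_tables",
    "noise_effect_table",
    "vocabulary_vs_noise",
]

STANDARD_NOISE_LEVELS = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0)


@dataclass(frozen=True)
class SweepSpec:
    """Design of a noise sweep over environmental-noise variances."""

    sigma_e_sq_levels: tuple = STANDARD_NOISE_LEVELS
    runs_per_level: int = 25
    sigma_c_sq: float = 0.01
    base_config: GameConfig = field(default_factory=GameConfig)
    seed: int = 0
    vary: str = "sigma_e_sq"  # or "sigma_c_sq" for the channel-noise sweep

    def __post_init__(self) -> None:
        if self.runs_per_level < 1:
            raise ValueError("runs_per_level must be >= 1")
        if self.vary not in ("sigma_e_sq", "sigma_c_sq"):
            raise ValueError(f"cannot sweep over {self.vary!r}")


@dataclass
class RunResult:
    """One trained run of the sweep with its derived partition and metrics."""

    noise_level: float
    replicate: int
    seed: int
    config: GameConfig
    partition: Partition
    metrics: MetricReport
    trace: TrainingTrace


def _run_seed(master: int, level_idx: int, rep: int) -> int:
    return int(np.random.SeedSequence([master, level_idx, rep]).generate_state(1)[0] % 2**31)


def run_sweep(
    spec: SweepSpec, chart: ChipChart, out_dir: str | Path | None = None
) -> list[RunResult]:
    """Train one run per (level, replicate); diverged runs are excluded with a count.

    With ``out_dir``, each run's partition (TSV) and a provenance record
    (seed, config, metrics) are persisted.
    """
    results: list[RunResult] = []
    diverged = 0
    for li, level in enumerate(spec.sigma_e_sq_levels):
        for rep in range(spec.runs_per_level):
            seed = _run_seed(spec.seed, li, rep)
            # the varied key wins if it collides with the fixed channel noise
            overrides = {"sigma_c_sq": spec.sigma_c_sq, "seed": seed, spec.vary: level}
            cfg = replace(spec.base_config, **overrides)
            try:
                params, trace = train(chart, cfg)
            except TrainingDivergedError:
                diverged += 1
                continue
            part = agent_partition(params, chart)
            res = RunResult(
                noise_level=level, replicate=rep, seed=seed, config=cfg,
                partition=part, metrics=report(part, chart, cfg.similarity_params),
                trace=trace,
            )
            results.append(res)
            if out_dir is not None:
                _persist(res, Path(out_dir))
    if diverged:
        print(f"warning: {diverged} run(s) diverged and were excluded")
    return results


def _persist(res: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"run_{res.config.message_mode}_level{res.noise_level:g}_rep{res.replicate}"
    res.partition.to_tsv(out_dir / f"{stem}.partition.tsv")
    record = {
        "seed": res.seed,
        "noise_level": res.noise_level,
        "replicate": res.replicate,
        "config": dataclasses.asdict(res.config),
        "metrics": dataclasses.asdict(res.metrics),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(record, indent=1))


def bucket_by_terms(results: list[RunResult]) -> dict[int, list[RunResult]]:
    """Group runs by the number of color terms their final partition uses."""
    if not results:
        raise ValueError("no results to bucket")
    buckets: dict[int, list[RunResult]] = {}
    for r in results:
        buckets.setdefault(r.partition.term_count, []).append(r)
    return dict(sorted(buckets.items()))


def term_histogram(results: list[RunResult]) -> pd.DataFrame:
    """Noise level x term count run-count matrix (the 2-D histogram view)."""
    df = pd.DataFrame(
        {"noise": [r.noise_level for r in results],
         "terms": [r.partition.term_count for r in results]}
    )
    return df.groupby(["noise", "terms"]).size().unstack(fill_value=0)


def _ci(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(1.96 * np.std(values, ddof=1) / np.sqrt(len(values)))


def efficiency_tables(
    buckets: dict[int, list[RunResult]],
    chart: ChipChart,
    human_buckets: dict[int, list[Partition]] | None = None,
    rng: np.random.Generator | None = None,
    n_random: int = 10,
    cc_restarts: int = 10,
) -> pd.DataFrame:
    """Per term-count efficiency table: RL runs vs random and correlation-
    clustering baselines (and optional human mode maps), mean +- 95% CI.

    The random baseline draws ``n_random`` equal-sized k-way partitions; the
    clustering baseline is the solver's best partition capped at k clusters.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    graph = build_similarity_graph(chart)
    rows = []
    for k, runs in sorted(buckets.items()):
        row: dict = {"terms": k, "n_runs": len(runs)}
        for name, attr in (
            ("kl", "kl_loss"), ("surprise", "expected_surprise"), ("wf", "wellformedness"),
        ):
            vals = np.array([getattr(r.metrics, attr) for r in runs])
            row[f"rl_{name}_mean"], row[f"rl_{name}_ci"] = float(vals.mean()), _ci(vals)
        rand_reports = [
            report(random_partition(chart, k, rng), chart) for _ in range(n_random)
        ]
        for name, attr in (
            ("kl", "kl_loss"), ("surprise", "expected_surprise"), ("wf", "wellformedness"),
        ):
            vals = np.array([getattr(m, attr) for m in rand_reports])
            row[f"random_{name}_mean"], row[f"random_{name}_ci"] = float(vals.mean()), _ci(vals)
        cc_part, _ = solve(graph, restarts=cc_restarts, rng=rng, max_clusters=k,
                           chart_ref=chart.name)
        cc_rep = report(cc_part, chart)
        row["cc_kl"], row["cc_surprise"], row["cc_wf"] = (
            cc_rep.kl_loss, cc_rep.expected_surprise, cc_rep.wellformedness,
        )
        if human_buckets and k in human_buckets:
            hum = [report(p, chart) for p in human_buckets[k]]
            for name, attr in (
                ("kl", "kl_loss"), ("surprise", "expected_surprise"), ("wf", "wellformedness"),
            ):
                vals = np.array([getattr(m, attr) for m in hum])
                row[f"human_{name}_mean"], row[f"human_{name}_ci"] = (
                    float(vals.mean()), _ci(vals),
                )
        rows.append(row)
    return pd.DataFrame(rows)


def noise_effect_table(results: list[RunResult]) -> pd.DataFrame:
    """Per term-count internal consistency: all runs pooled vs within noise groups.

    Column ``ari_all`` averages the pairwise ARI over every pair of runs that
    reached that term count, regardless of noise level; ``ari_within_noise``
    averages the per-noise-level internal consistencies.
    """
    rows = []
    for k, runs in bucket_by_terms(results).items():
        row: dict = {"terms": k, "n_runs": len(runs)}
        parts = [r.partition for r in runs]
        if len(parts) >= 2:
            s = mean_pairwise_ari(parts)
            row["ari_all"], row["ari_all_ci"] = s.mean, s.ci_halfwidth
        else:
            row["ari_all"], row["ari_all_ci"] = np.nan, np.nan
        by_noise: dict[float, list[Partition]] = {}
        for r in runs:
            by_noise.setdefault(r.noise_level, []).append(r.partition)
        group_means = [
            mean_pairwise_ari(ps).mean for ps in by_noise.values() if len(ps) >= 2
        ]
        if group_means:
            row["ari_within_noise"] = float(np.mean(group_means))
            row["ari_within_noise_ci"] = _ci(np.asarray(group_means))
        else:
            row["ari_within_noise"], row["ari_within_noise_ci"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def vocabulary_vs_noise(results: list[RunResult]) -> pd.DataFrame:
    """Mean term count per noise level plus the Spearman rank correlation
    between level and term count across runs (negative = noise shrinks the
    vocabulary).  The correlation is attached as ``df.attrs``."""
    levels = sorted({r.noise_level for r in results})
    if len(levels) < 3:
        raise ValueError("need at least three noise levels for a trend")
    df = pd.DataFrame(
        {"noise": [r.noise_level for r in results],
         "terms": [r.partition.term_count for r in results]}
    )
    out = df.groupby("noise", as_index=False)["terms"].agg(["mean", "std", "count"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, pval = stats.spearmanr(df["noise"], df["terms"])
    out.attrs["spearman_rho"] = 0.0 if np.isnan(rho) else float(rho)
    out.attrs["spearman_p"] = float(pval) if np.isfinite(pval) else float("nan")
    return out
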