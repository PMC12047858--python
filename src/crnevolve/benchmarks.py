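"""Batch experiments: many independent evolution trials, success rates,
diversity summaries, and the significance tests used to compare settings.

A trial succeeds if any of its per-species best networks classifies as an
oscillator (after single-deletion repair). Success rates come with a
Wilson binomial confidence interval; rate comparisons use a two-sided
binomial test and diversity comparisons a two-tailed t-test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassificationConfig, repair
from .evolution import EvolutionConfig, EvolutionResult, evolve
from .fitness import TimeSeriesTarget

__all__ = ["BatchResult", "run_batch", "diversity_report", "compare_success_rates"]


@dataclass
class BatchResult:
    n_trials: int
    n_oscillators: int
    per_trial: list[dict] = field(default_factory=list)
    config: EvolutionConfig | None = None
    results: list[EvolutionResult] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return self.n_oscillators / self.n_trials

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        res = stats.binomtest(self.n_oscillators, self.n_trials)
        ci = res.proportion_ci(confidence_level=level, method="wilson")
        return float(ci.low), float(ci.high)


def trial_seeds(root_seed: int, n_trials: int) -> list[int]:
    """Deterministic per-trial seeds derived from one root seed (< 2^31)."""
    state = np.random.SeedSequence(root_seed).generate_state(n_trials, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_batch(
    cfg: EvolutionConfig,
    n_trials: int,
    root_seed: int = 0,
    classify_cfg: ClassificationConfig = ClassificationConfig(),
    target: TimeSeriesTarget | None = None,
    keep_results: bool = False,
) -> BatchResult:
    """Run ``n_trials`` independent seeded trials and classify the outputs.

    Each trial gets its own derived seed; its per-species best networks are
    classified (with repair), and the trial counts as a success if any is
    an oscillator.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    batch = BatchResult(n_trials=n_trials, n_oscillators=0, config=cfg)
    for trial, seed in enumerate(trial_seeds(root_seed, n_trials)):
        result = evolve(replace(cfg, seed=seed), target=target)
        verdicts = [repair(net, classify_cfg).verdict for net in result.species_bests]
        success = "oscillator" in verdicts
        batch.n_oscillators += int(success)
        batch.per_trial.append(
            {
                "trial": trial,
                "seed": seed,
                "success": success,
                "best_fitness": result.records[-1].best_fitness,
                "generations": len(result.records),
                "stopped_early": result.stopped_early,
                "n_oscillators": verdicts.count("oscillator"),
            }
        )
        if keep_results:
            batch.results.append(result)
    return batch


def diversity_report(results: list[EvolutionResult]) -> pd.DataFrame:
    """Per-generation mean and 95% CI of the diversity metrics over trials.

    With a single trial the CI columns are NaN.
    """
    rows = []
    for res in results:
        for rec in res.records:
            rows.append(dataclasses.asdict(rec))
    df = pd.DataFrame(rows)
    out = []
    for gen, sub in df.groupby("generation"):
        row = {"generation": gen, "n_trials": len(sub)}
        for col in ("unique_fraction", "best_copies_fraction"):
            vals = sub[col].to_numpy()
            row[f"{col}_mean"] = vals.mean()
            if len(vals) > 1:
                sem = stats.sem(vals)
                half = sem * stats.t.ppf(0.975, len(vals) - 1)
            else:
                half = np.nan
            row[f"{col}_ci95"] = half
        out.append(row)
    return pd.DataFrame(out)


def compare_success_rates(batch_a: BatchResult, batch_b: BatchResult) -> float:
    """Two-sided p-value for batch A's success count against B's rate."""
    return float(
        stats.binomtest(
            batch_a.n_oscillators, batch_a.n_trials, batch_b.success_rate
        ).pvalue
    )
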