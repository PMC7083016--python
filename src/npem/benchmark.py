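"""Power / false-positive-rate benchmark over replicated simulated studies.

For each scenario, replicate datasets are generated with independent
derived seeds, every requested NPEM variant is fitted (the variants share
one mutual-information cache per dataset), taxa are called at a cutoff on
the composite mediation p-value, and the calls are scored against the
generator's truth labels.  Power is TP/(TP+FN) over true mediators and
the false positive rate FP/(FP+TN) over non-mediators; scenario summaries
report per-replicate means with Monte-Carlo standard errors sd/sqrt(R).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mediation import METHODS, NPEMMediation, NPEMMediationResults
from .simulate import ScenarioSpec, SyntheticDataset, build_scenario, simulate_dataset

__all__ = ["score_replicate", "run_scenario", "run_benchmark"]


def score_replicate(
    result: NPEMMediationResults | pd.DataFrame,
    truth: np.ndarray,
    cutoff: float = 0.05,
) -> tuple[float, float]:
    """(power, fpr) of one fitted replicate at a composite-p cutoff.

    Power is NaN when the truth has no positive taxa.
    """
    table = result.table if isinstance(result, NPEMMediationResults) else result
    truth = np.asarray(truth, dtype=bool)
    if len(table) != truth.size:
        raise ValueError("truth must cover every taxon in the result")
    called = table["p_composite"].to_numpy() < cutoff
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    power = float(called[truth].sum() / n_pos) if n_pos else float("nan")
    fpr = float(called[~truth].sum() / n_neg) if n_neg else float("nan")
    return power, fpr


def _replicate_seeds(master_seed: int, replicates: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(replicates) % (2**31)]


def run_scenario(
    spec: ScenarioSpec,
    methods: Sequence[str] = METHODS,
    replicates: int = 10,
    cutoff: float = 0.05,
    seed: int = 0,
    selection_threshold: float = 0.05,
    return_replicates: bool = False,
) -> pd.DataFrame:
    """Benchmark one scenario; one summary row per method.

    Columns: scenario, method, power, power_se, fpr, fpr_se,
    n_replicates.  With ``return_replicates`` the per-replicate rates are
    returned instead (one row per replicate x method).
    """
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for rep, rep_seed in enumerate(_replicate_seeds(seed, replicates)):
        ds: SyntheticDataset = simulate_dataset(replace(spec, seed=rep_seed))
        model = NPEMMediation(
            ds.genes, ds.taxa, ds.outcome, ds.gene_names, ds.taxon_names
        )
        for method in methods:
            res = model.fit(
                method=method,
                selection_threshold=selection_threshold,
                fdr_level=cutoff,
            )
            power, fpr = score_replicate(res, ds.truth, cutoff)
            rows.append(
                {
                    "scenario": spec.label or "custom",
                    "method": method,
                    "replicate": rep,
                    "power": power,
                    "fpr": fpr,
                }
            )
    per_rep = pd.DataFrame(rows)
    if return_replicates:
        return per_rep

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    summary = (
        per_rep.groupby(["scenario", "method"], sort=False)
        .agg(
            power=("power", "mean"),
            power_se=("power", _se),
            fpr=("fpr", "mean"),
            fpr_se=("fpr", _se),
            n_replicates=("replicate", "count"),
        )
        .reset_index()
    )
    return summary


def run_benchmark(
    setting: str,
    methods: Sequence[str] = METHODS,
    replicates: int = 10,
    cutoff: float = 0.05,
    seed: int = 0,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Benchmark every scenario of a named simulation setting.

    ``overrides`` (e.g. ``{"n_genes": 50, "n_taxa": 50}``) scale the
    scenario grid; the desk-scale default keeps the reference block
    proportions.  Returns the concatenated scenario summaries.
    """
    specs = build_scenario(setting, **(overrides or {}))
    parts: Iterable[pd.DataFrame] = (
        run_scenario(s, methods, replicates, cutoff, seed=seed + k)
        for k, s in enumerate(specs)
    )
    return pd.concat(parts, ignore_index=True)
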