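"""Scenario prediction: evaluate quantile-regression coefficients on grids
of covariate settings (ages x node counts x tumor sizes).

The coefficient vector is ordered (intercept, z-age^2, z-age, tumor size,
involved nodes); ages enter standardized, and the squared term is the square
of the age z-score.  Evaluation is on the raw month scale by default; a
log-time variant exponentiates the linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import StandardizationParams, standardize_age
from .exceptions import ConfigurationError


def predict_quantile(
    beta: Sequence[float],
    age: float,
    tumor_size: float,
    n_nodes: float,
    params: StandardizationParams,
    scale: str = "months",
) -> float:
    """Predicted conditional quantile (months) for one covariate setting."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (5,):
        raise ConfigurationError("beta must have 5 entries (const, z^2, z, size, nodes)")
    z = standardize_age(age, params)
    x = np.array([1.0, z**2, z, float(tumor_size), float(n_nodes)])
    pred = float(x @ beta)
    if scale == "log":
        return float(np.exp(pred))
    if scale != "months":
        raise ConfigurationError("scale must be 'months' or 'log'")
    return pred


@dataclass
class ScenarioGrid:
    """Complete cross-product of scenario predictions.

    ``long`` is tidy (one row per (tau, tumor_size, n_nodes, age) cell);
    ``wide()`` lays it out as the published grid: one row per quantile level,
    columns nested size x nodes x age.
    """

    ages: tuple[float, ...]
    node_counts: tuple[float, ...]
    tumor_sizes: tuple[float, ...]
    taus: tuple[float, ...]
    long: pd.DataFrame

    def wide(self) -> pd.DataFrame:
        wide = self.long.pivot_table(
            index="tau",
            columns=["tumor_size", "n_nodes", "age"],
            values="quantile_months",
        )
        cols = [
            (s, m, a)
            for s in self.tumor_sizes
            for m in self.node_counts
            for a in self.ages
        ]
        return wide.reindex(columns=pd.MultiIndex.from_tuples(cols))

    def lookup(self, tau: float, tumor_size: float, n_nodes: float, age: float) -> float:
        sel = self.long[
            (self.long.tau == tau)
            & (self.long.tumor_size == tumor_size)
            & (self.long.n_nodes == n_nodes)
            & (self.long.age == age)
        ]
        return float(sel.quantile_months.iloc[0])


def scenario_table(
    coefficients: Mapping[float, Sequence[float]],
    ages: Sequence[float],
    node_counts: Sequence[float],
    tumor_sizes: Sequence[float],
    params: StandardizationParams,
    scale: str = "months",
    rearrange: bool = False,
) -> ScenarioGrid:
    """Evaluate per-level coefficient vectors on the full scenario grid.

    Separately fitted quantile levels can cross at a given covariate
    setting; ``rearrange=True`` applies monotone rearrangement (sorting the
    predictions across tau within each cell).  Off by default: raw
    per-level predictions are reported.
    """
    if not (len(ages) and len(node_counts) and len(tumor_sizes) and len(coefficients)):
        raise ConfigurationError("scenario axes and coefficient map must be non-empty")
    taus = sorted(coefficients)
    rows = []
    for size in tumor_sizes:
        for nodes in node_counts:
            for age in ages:
                preds = [
                    predict_quantile(coefficients[tau], age, size, nodes, params, scale)
                    for tau in taus
                ]
                if rearrange:
                    preds = sorted(preds)
                rows.extend(
                    {
                        "tau": tau,
                        "tumor_size": size,
                        "n_nodes": nodes,
                        "age": age,
                        "quantile_months": pred,
                    }
                    for tau, pred in zip(taus, preds)
                )
    return ScenarioGrid(
        ages=tuple(ages),
        node_counts=tuple(node_counts),
        tumor_sizes=tuple(tumor_sizes),
        taus=tuple(taus),
        long=pd.DataFrame(rows),
    )
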