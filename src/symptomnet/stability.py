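"""Bootstrap accuracy of edges and case-drop stability of centralities.

Edge accuracy: nonparametric row resampling with full re-estimation per
resample, percentile intervals per edge. Centrality stability: case-dropping
subsamples over a grid of drop proportions; at each proportion the Spearman
correlation between the subsample and full-sample centralities is recorded,
and the CS coefficient summarizes the largest proportion that can be dropped
while at least 95% of subsamples stay correlated >= 0.7 with the full sample.
A CS above 0.25 is conventionally read as minimally stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import bridge_centrality, strength_centrality
from .estimation import EstimatorConfig, estimate_network

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
CENTRALITY_KINDS = ("strength", "bridge_strength", "bridge_betweenness",
                    "bridge_closeness")


@dataclass
class StabilityReport:
    point_weights: np.ndarray
    edge_lower: np.ndarray            # 2.5th percentile per edge
    edge_upper: np.ndarray            # 97.5th percentile per edge
    curves: dict[str, pd.DataFrame]   # kind -> rows (proportion, rep, correlation)
    cs: dict[str, float]
    B: int
    seed: int
    n_failed: int = 0
    nodes: tuple[str, ...] = field(default_factory=tuple)


def _centralities(net, kinds) -> dict[str, pd.Series]:
    out = {}
    if any(k.startswith("bridge") for k in kinds):
        table = bridge_centrality(net)
        for k in kinds:
            out[k] = table[k] if k != "strength" else table["strength"]
    else:
        out["strength"] = strength_centrality(net)
    return out


def edge_bootstrap(X: np.ndarray, B: int = 1000, seed: int = 0,
                   config: EstimatorConfig | None = None,
                   max_failure_fraction: float = 0.1):
    """Percentile bootstrap intervals for every edge weight.

    Resamples with estimator failures (e.g. a constant column after
    resampling) are dropped and counted; more than ``max_failure_fraction``
    failures aborts.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    config = config or EstimatorConfig()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    point = estimate_network(X, config)
    draws = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            net = estimate_network(X[idx], config)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failed += 1
            if failed > max_failure_fraction * B:
                raise RuntimeError(
                    f"more than {max_failure_fraction:.0%} of resamples failed"
                )
            continue
        draws.append(net.weights)
    stack = np.stack(draws)
    lower = np.percentile(stack, 2.5, axis=0)
    upper = np.percentile(stack, 97.5, axis=0)
    return point, lower, upper, failed


def case_drop_bootstrap(X: np.ndarray, drop_proportions=DEFAULT_DROP_GRID,
                        B: int = 1000, seed: int = 0,
                        config: EstimatorConfig | None = None,
                        kinds=CENTRALITY_KINDS,
                        max_failure_fraction: float = 0.1) -> dict[str, pd.DataFrame]:
    """Spearman correlation curves of subsample vs full-sample centralities."""
    if any(q <= 0 or q > 0.8 for q in drop_proportions):
        raise ValueError("drop proportions must lie in (0, 0.8]")
    config = config or EstimatorConfig()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    full = _centralities(estimate_network(X, config), kinds)
    rows: dict[str, list] = {k: [] for k in kinds}
    failed = 0
    for q in drop_proportions:
        keep = int(round((1.0 - q) * n))
        for rep in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                net = estimate_network(X[idx], config)
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                failed += 1
                if failed > max_failure_fraction * B * len(drop_proportions):
                    raise RuntimeError("too many failed subsamples")
                continue
            cents = _centralities(net, kinds)
            for k in kinds:
                r = stats.spearmanr(full[k].values, cents[k].values).statistic
                rows[k].append((q, rep, float(r) if np.isfinite(r) else np.nan))
    return {
        k: pd.DataFrame(rows[k], columns=["proportion", "rep", "correlation"])
        for k in kinds
    }


def cs_coefficient(curves: dict[str, pd.DataFrame],
                   cor_threshold: float = 0.7,
                   prob: float = 0.95) -> dict[str, float]:
    """CS = largest drop proportion where >= ``prob`` of the subsample
    correlations stay at or above ``cor_threshold``; 0 if none qualifies."""
    out = {}
    for kind, df in curves.items():
        cs = 0.0
        for q, grp in df.groupby("proportion"):
            vals = grp["correlation"].to_numpy()
            ok = np.mean(np.where(np.isfinite(vals), vals >= cor_threshold,
                                  False))
            if ok >= prob and q > cs:
                cs = float(q)
        out[kind] = cs
    return out


def stability_report(X: np.ndarray, B: int = 1000, seed: int = 0,
                     drop_proportions=DEFAULT_DROP_GRID,
                     config: EstimatorConfig | None = None,
                     kinds=CENTRALITY_KINDS) -> StabilityReport:
    """Edge bootstrap + case-drop curves + CS coefficients in one report."""
    point, lower, upper, failed = edge_bootstrap(X, B, seed, config)
    curves = case_drop_bootstrap(X, drop_proportions, B, seed + 1, config,
                                 kinds)
    return StabilityReport(
        point_weights=point.weights, edge_lower=lower, edge_upper=upper,
        curves=curves, cs=cs_coefficient(curves), B=B, seed=seed,
        n_failed=failed, nodes=point.nodes,
    )
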