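"""Change-trajectory network: per-participant OLS slopes, then a GGM on them.

For every participant observed at all requested waves, the slope of each
item's score on the wave code (0,1,2,3 by default) is the closed-form OLS
estimate beta = sum_t (t - tbar)(y_t - ybar) / sum_t (t - tbar)^2. The slopes
become continuous variables whose Pearson correlations feed the same
EBIC-glasso estimator as the cross-sectional networks, linking items whose
*changes* co-occur. The slope correlation matrix — hence the network — is
invariant to affine re-coding of time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ITEM_COLUMNS, NODE_LABELS, WAVES, ItemPanel, SymptomNetwork
from .estimation import EstimatorConfig, ebic_glasso
from .correlation import pearson_matrix


@dataclass
class SlopeMatrix:
    values: np.ndarray           # n_completers x p
    participant_ids: pd.Index
    time_codes: tuple[float, ...]
    n_excluded: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


def ols_slopes(panel: ItemPanel, waves=WAVES,
               time_codes=(0.0, 1.0, 2.0, 3.0)) -> SlopeMatrix:
    """Per-participant, per-item OLS slopes across the requested waves.

    Participants missing any requested wave (or any item at one of them) are
    excluded and counted.
    """
    if len(waves) < 2:
        raise ValueError("need at least two waves")
    t = np.asarray(time_codes, dtype=float)
    if len(t) != len(waves):
        raise ValueError("time_codes must match the number of waves")
    df = panel.data[panel.data["wave"].isin(waves)].copy()
    complete_rows = df[list(ITEM_COLUMNS)].notna().all(axis=1)
    df = df[complete_rows]
    counts = df.groupby("participant_id")["wave"].nunique()
    completers = counts.index[counts == len(waves)]
    all_ids = panel.data["participant_id"].unique()
    n_excluded = len(all_ids) - len(completers)
    if len(completers) == 0:
        raise ValueError("no participant observed at all requested waves")
    sub = df[df["participant_id"].isin(completers)]
    wave_order = {w: i for i, w in enumerate(waves)}
    sub = sub.sort_values(["participant_id", "wave"],
                          key=lambda s: s.map(wave_order) if s.name == "wave" else s)
    Y = sub[list(ITEM_COLUMNS)].to_numpy(dtype=float).reshape(
        len(completers), len(waves), len(ITEM_COLUMNS)
    )
    tc = t - t.mean()
    denom = float(np.sum(tc ** 2))
    betas = np.einsum("t,ntp->np", tc, Y - Y.mean(axis=1, keepdims=True)) / denom
    ids = pd.Index(sub["participant_id"].unique())
    return SlopeMatrix(values=betas, participant_ids=ids,
                       time_codes=tuple(t), n_excluded=n_excluded)


def slope_network(slopes: SlopeMatrix,
                  config: EstimatorConfig | None = None) -> SymptomNetwork:
    """EBIC-glasso network on the slope variables (Pearson correlations).

    Items whose slope is constant across all participants are dropped with a
    warning and come back as isolated nodes.
    """
    config = config or EstimatorConfig()
    X = slopes.values
    p = X.shape[1]
    nodes = NODE_LABELS if p == 16 else tuple(f"V{k+1}" for k in range(p))
    if X.shape[0] < 3 * p:
        warnings.warn(
            f"only {X.shape[0]} slope rows for {p} nodes; estimates may be "
            "unstable", stacklevel=2,
        )
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [nodes[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"constant slope column(s) dropped: {dropped}",
                      stacklevel=2)
    Xk = X[:, keep]
    kept_nodes = tuple(n for n, k in zip(nodes, keep) if k)
    R = pearson_matrix(Xk, labels=kept_nodes)
    sub = ebic_glasso(R, gamma=config.gamma, n_lambda=config.n_lambda,
                      lambda_min_ratio=config.lambda_min_ratio,
                      nodes=kept_nodes, tol=config.tol,
                      max_iter=config.max_iter)
    W = np.zeros((p, p))
    kept_idx = np.nonzero(keep)[0]
    W[np.ix_(kept_idx, kept_idx)] = sub.weights
    from .datamodel import default_partition_for
    return SymptomNetwork(tuple(nodes), W, default_partition_for(nodes),
                          n=X.shape[0], lambda_selected=sub.lambda_selected)
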