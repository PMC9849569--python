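"""Permutation Network Comparison Test (NCT) for paired wave data.

Two statistics compare networks estimated on two measurement occasions of
the same participants: M, the maximum absolute edge-weight difference
(structure invariance), and S, the absolute difference of global strengths
(global strength invariance). The null distribution preserves within-person
exchangeability: each permutation independently swaps a participant's pair
of response vectors between occasions with probability 1/2 and re-estimates
both networks. p-values use the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_perm). Edge-level differences are
tested with the same permutation draws and Holm-corrected across the edges
nonzero in at least one observed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import ItemPanel, SymptomNetwork, complete_cases
from .estimation import EstimatorConfig, estimate_network, global_strength


@dataclass
class NCTResult:
    M: float
    S: float
    p_M: float
    p_S: float
    edge_table: pd.DataFrame      # node_i, node_j, diff, p, p_holm
    n_perm: int
    seed: int
    n_pairs: int
    paired: bool = True
    network_a: SymptomNetwork | None = None
    network_b: SymptomNetwork | None = None


def _stats(netA: SymptomNetwork, netB: SymptomNetwork):
    diff = netA.weights - netB.weights
    iu = np.triu_indices(netA.p, k=1)
    M = float(np.max(np.abs(diff[iu]))) if netA.p > 1 else 0.0
    S = abs(global_strength(netA) - global_strength(netB))
    return M, S, diff


def nct_paired(dataA: np.ndarray, dataB: np.ndarray, n_perm: int = 1000,
               seed: int = 0, config: EstimatorConfig | None = None,
               min_n: int = 50, max_retries_factor: int = 10) -> NCTResult:
    """Paired-sample NCT on two row-aligned item-score matrices."""
    dataA = np.asarray(dataA)
    dataB = np.asarray(dataB)
    if dataA.shape != dataB.shape:
        raise ValueError("paired matrices must have identical shape")
    n = dataA.shape[0]
    if n < min_n:
        raise ValueError(f"fewer than {min_n} paired observations (n={n})")
    config = config or EstimatorConfig()
    rng = np.random.default_rng(seed)

    netA = estimate_network(dataA, config)
    netB = estimate_network(dataB, config)
    M_obs, S_obs, diff_obs = _stats(netA, netB)

    iu = np.triu_indices(netA.p, k=1)
    tested = (netA.weights[iu] != 0) | (netB.weights[iu] != 0)
    edge_obs = np.abs(diff_obs[iu][tested])

    M_null = np.empty(n_perm)
    S_null = np.empty(n_perm)
    edge_ge = np.zeros(tested.sum())
    retries_left = max_retries_factor * n_perm
    k = 0
    while k < n_perm:
        swap = rng.random(n) < 0.5
        permA = np.where(swap[:, None], dataB, dataA)
        permB = np.where(swap[:, None], dataA, dataB)
        try:
            pa = estimate_network(permA, config)
            pb = estimate_network(permB, config)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            retries_left -= 1
            if retries_left <= 0:
                raise RuntimeError("too many failed permutations in NCT")
            continue
        M_null[k], S_null[k], dnull = _stats(pa, pb)
        edge_ge += np.abs(dnull[iu][tested]) >= edge_obs
        k += 1

    p_M = (1.0 + np.sum(M_null >= M_obs)) / (1.0 + n_perm)
    p_S = (1.0 + np.sum(S_null >= S_obs)) / (1.0 + n_perm)
    edge_p = (1.0 + edge_ge) / (1.0 + n_perm)
    if len(edge_p):
        p_holm = multipletests(edge_p, method="holm")[1]
    else:
        p_holm = edge_p
    nodes = np.asarray(netA.nodes)
    edge_table = pd.DataFrame(
        {
            "node_i": nodes[iu[0][tested]],
            "node_j": nodes[iu[1][tested]],
            "diff": diff_obs[iu][tested],
            "p": edge_p,
            "p_holm": p_holm,
        }
    )
    return NCTResult(M=M_obs, S=S_obs, p_M=float(p_M), p_S=float(p_S),
                     edge_table=edge_table, n_perm=n_perm, seed=seed,
                     n_pairs=n, network_a=netA, network_b=netB)


ALL_PAIRS = (("T1", "T2"), ("T1", "T3"), ("T1", "T4"),
             ("T2", "T3"), ("T2", "T4"), ("T3", "T4"))


@dataclass
class WaveComparison:
    results: dict[tuple[str, str], NCTResult]
    alpha: float
    bonferroni_alpha: float
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self):
        rows = []
        for (a, b), res in self.results.items():
            rows.append(
                {
                    "wave_a": a, "wave_b": b, "n_pairs": res.n_pairs,
                    "M": res.M, "p_M": res.p_M, "S": res.S, "p_S": res.p_S,
                    "significant_M": res.p_M < self.bonferroni_alpha,
                    "significant_S": res.p_S < self.bonferroni_alpha,
                }
            )
        self.summary = pd.DataFrame(rows)


def compare_waves(panel: ItemPanel, pairs=ALL_PAIRS, n_perm: int = 1000,
                  seed: int = 0, alpha: float = 0.05,
                  config: EstimatorConfig | None = None,
                  min_n: int = 50) -> WaveComparison:
    """Paired NCT for every wave pair on their common complete cases, with a
    Bonferroni-corrected per-pair significance threshold."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one wave pair")
    config = config or EstimatorConfig()
    results: dict[tuple[str, str], NCTResult] = {}
    for i, (a, b) in enumerate(pairs):
        Xa, ids_a = complete_cases(panel, a)
        Xb, ids_b = complete_cases(panel, b)
        common = ids_a.intersection(ids_b)
        ia = pd.Series(np.arange(len(ids_a)), index=ids_a)
        ib = pd.Series(np.arange(len(ids_b)), index=ids_b)
        results[(a, b)] = nct_paired(
            Xa[ia[common].to_numpy()], Xb[ib[common].to_numpy()],
            n_perm=n_perm, seed=seed + i, config=config, min_n=min_n,
        )
    return WaveComparison(results, alpha=alpha,
                          bonferroni_alpha=alpha / len(pairs))
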