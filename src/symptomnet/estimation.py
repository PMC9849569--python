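"""Regularized Gaussian graphical model estimation with EBIC selection.

The estimator fits the graphical lasso over a log-spaced penalty path from
lambda_max (the largest absolute off-diagonal correlation, above which the
solution is diagonal) down to ``lambda_min_ratio * lambda_max``, scores every
fit with the extended BIC,

    EBIC = -2 l(K) + E log n + 4 E gamma log p,
    l(K) = (n/2) (log det K - tr(R K)),

and returns the partial-correlation network of the winning precision matrix,
w_ij = -K_ij / sqrt(K_ii K_jj). The additive Gaussian constant is omitted
from l; it cancels in model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _glasso
from .correlation import CorrelationMatrix, pearson_matrix, polychoric_matrix
from .datamodel import SymptomNetwork, default_partition_for, NODE_LABELS

EDGE_EPS = 1e-8


@dataclass
class EstimatorConfig:
    """Knobs of the estimation pipeline shared by every stage."""

    correlation: str = "pearson"       # or "polychoric"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-6
    max_iter: int = 500

    def correlation_matrix(self, X: np.ndarray, labels=None) -> CorrelationMatrix:
        if labels is None:
            labels = NODE_LABELS if X.shape[1] == 16 else \
                [f"V{k + 1}" for k in range(X.shape[1])]
        if self.correlation == "pearson":
            return pearson_matrix(X, labels)
        if self.correlation == "polychoric":
            return polychoric_matrix(X, labels)
        raise ValueError(f"unknown correlation method {self.correlation!r}")


@dataclass
class GlassoFit:
    lambda_: float
    precision: np.ndarray
    R: np.ndarray
    converged: bool
    n_sweeps: int

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def partial_corr(self) -> np.ndarray:
        K = self.precision
        d = np.sqrt(np.diag(K))
        W = -K / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        W[np.abs(W) < EDGE_EPS] = 0.0
        return W

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.partial_corr[iu]))


def log_likelihood(fit: GlassoFit, n: int) -> float:
    """Gaussian profile log-likelihood (n/2)(log det K - tr(R K))."""
    sign, logdet = np.linalg.slogdet(fit.precision)
    if sign <= 0:
        raise ValueError("precision is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(fit.R * fit.precision)))


def ebic(fit: GlassoFit, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a converged fit; gamma = 0 reduces to the BIC."""
    E = fit.edge_count
    return (-2.0 * log_likelihood(fit, n) + E * np.log(n)
            + 4.0 * E * gamma * np.log(fit.p))


def lambda_max(R: np.ndarray) -> float:
    off = R - np.diag(np.diag(R))
    return float(np.max(np.abs(off)))


def graphical_lasso(R: CorrelationMatrix | np.ndarray, lambda_: float,
                    tol: float = 1e-6, max_iter: int = 500,
                    _state=None) -> GlassoFit:
    """Solve the graphical lasso at one penalty value.

    ``lambda_ = 0`` requires a positive-definite R and returns K = R^-1.
    For ``lambda_ >= lambda_max(R)`` the solution is exactly diagonal.
    """
    Rm = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    p = Rm.shape[0]
    if lambda_ == 0.0:
        w = np.linalg.eigvalsh(Rm)
        if w.min() <= 0:
            raise np.linalg.LinAlgError(
                "lambda = 0 requires a positive definite correlation matrix"
            )
        return GlassoFit(0.0, np.linalg.inv(Rm), Rm, True, 0)
    if lambda_ >= lambda_max(Rm):
        K = np.diag(1.0 / np.diag(Rm))
        return GlassoFit(lambda_, K, Rm, True, 0)
    if _state is None:
        W, B = _glasso.init_state(Rm)
    else:
        W, B = _state
    sweeps, converged = _glasso.glasso_cd(
        np.ascontiguousarray(Rm), lambda_, W, B, tol, max_iter, tol * 1e-2,
        max_iter,
    )
    if not converged:
        raise RuntimeError(
            f"graphical lasso did not converge in {sweeps} sweeps at "
            f"lambda={lambda_:.4g}"
        )
    return GlassoFit(lambda_, _glasso.precision_from_state(W, B), Rm,
                     converged, sweeps)


def lambda_grid(R: np.ndarray, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    lmax = lambda_max(R)
    if lmax <= 0:
        return np.array([0.0])
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio),
                              n_lambda))


def ebic_glasso(R: CorrelationMatrix, n: int | None = None,
                gamma: float = 0.5, n_lambda: int = 100,
                lambda_min_ratio: float = 0.01, nodes=None,
                tol: float = 1e-6, max_iter: int = 500,
                return_path: bool = False):
    """EBIC-selected graphical lasso network.

    Fits the whole penalty path with warm starts (large to small lambda) and
    returns the :class:`SymptomNetwork` of the EBIC-minimizing fit. Ties are
    broken toward the sparser (larger-penalty) model.
    """
    Rm = R.values
    n = R.n if n is None else n
    if n <= 0:
        raise ValueError("sample size n must be positive")
    p = Rm.shape[0]
    if nodes is None:
        nodes = NODE_LABELS if p == 16 else tuple(f"V{k+1}" for k in range(p))
    grid = lambda_grid(Rm, n_lambda, lambda_min_ratio)
    if return_path:
        # object-building path, used by diagnostics and contract tests
        state = _glasso.init_state(Rm)
        lmax = lambda_max(Rm)
        fits: list[GlassoFit] = []
        scores: list[float] = []
        for lam in grid:
            if lam >= lmax:
                fit = graphical_lasso(Rm, float(lam), tol, max_iter)
            else:
                fit = graphical_lasso(Rm, float(lam), tol, max_iter,
                                      _state=state)
            fits.append(fit)
            scores.append(ebic(fit, n, gamma))
        best = int(np.argmin(scores))
        K = fits[best].precision
    else:
        best, K, path_scores, bad = _glasso.ebic_path(
            np.ascontiguousarray(Rm), grid, n, gamma, tol, max_iter,
            tol * 1e-2, max_iter,
        )
        if best < 0:
            raise RuntimeError("no graphical lasso fit converged on the grid")
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < EDGE_EPS] = 0.0
    net = SymptomNetwork(tuple(nodes), W, default_partition_for(nodes), n=n,
                         lambda_selected=float(grid[best]))
    if return_path:
        return net, fits, np.asarray(scores), grid
    return net


def estimate_network(X: np.ndarray, config: EstimatorConfig | None = None,
                     nodes=None) -> SymptomNetwork:
    """Correlation + EBIC-glasso in one step on an n x p item-score matrix."""
    config = config or EstimatorConfig()
    R = config.correlation_matrix(X, labels=nodes)
    return ebic_glasso(R, gamma=config.gamma, n_lambda=config.n_lambda,
                       lambda_min_ratio=config.lambda_min_ratio, nodes=nodes,
                       tol=config.tol, max_iter=config.max_iter)


def global_strength(net: SymptomNetwork) -> float:
    """Weighted absolute sum over all (unique) edges of the network."""
    iu = np.triu_indices(net.p, k=1)
    return float(np.sum(np.abs(net.weights[iu])))


def fr_layout(nets: SymptomNetwork | list[SymptomNetwork],
              seed: int = 0) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold coordinates shared across networks.

    The layout is computed on the element-wise mean of the absolute weight
    matrices so all waves get one fixed node placement; deterministic given
    the seed and invariant to node input order (initial positions are drawn
    per sorted node label). Coordinates are rescaled to the unit square.
    """
    if isinstance(nets, SymptomNetwork):
        nets = [nets]
    nodes = nets[0].nodes
    for net in nets[1:]:
        if set(net.nodes) != set(nodes):
            raise ValueError("all networks must share one node set")
    order = {lab: k for k, lab in enumerate(nodes)}
    mean_abs = np.zeros((len(nodes), len(nodes)))
    for net in nets:
        perm = [order[lab] for lab in nodes]
        idx = [list(net.nodes).index(lab) for lab in nodes]
        mean_abs[np.ix_(perm, perm)] += np.abs(net.weights[np.ix_(idx, idx)])
    mean_abs /= len(nets)

    G = nx.Graph()
    G.add_nodes_from(sorted(nodes))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if mean_abs[i, j] > 0:
                G.add_edge(nodes[i], nodes[j], weight=float(mean_abs[i, j]))
    rng = np.random.default_rng(seed)
    init = {lab: rng.uniform(-1, 1, size=2) for lab in sorted(nodes)}
    pos = nx.spring_layout(G, pos=init, weight="weight", seed=int(seed),
                           iterations=100)
    xs = np.array([pos[lab] for lab in nodes])
    lo, hi = xs.min(axis=0), xs.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    xs = (xs - lo) / span
    return {lab: (float(x), float(y)) for lab, (x, y) in zip(nodes, xs)}
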