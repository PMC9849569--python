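"""Input correlation matrices for network estimation.

Pearson product-moment correlation is the default. A two-step maximum
likelihood polychoric estimator is available for the latent-Gaussian reading
of the ordinal items: thresholds from the marginal category proportions via
the inverse normal CDF, then each pairwise latent correlation by 1-D
likelihood maximization over the bivariate-normal cell probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .datamodel import NODE_LABELS

RHO_BOUND = 0.999


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    method: str                 # "pearson" or "polychoric"
    n: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        R = np.asarray(self.values, dtype=float)
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = 0.5 * (R + R.T)

    @property
    def p(self) -> int:
        return self.values.shape[0]


def _check_columns(X: np.ndarray, labels) -> None:
    const = np.nonzero(X.std(axis=0) == 0)[0]
    if len(const):
        names = [labels[i] if labels is not None and i < len(labels) else str(i)
                 for i in const]
        raise ValueError(f"constant column(s): {names}")


def pearson_matrix(X: np.ndarray, labels=NODE_LABELS) -> CorrelationMatrix:
    """Product-moment correlations of an n x p item-score matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    _check_columns(X, labels)
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(np.clip(R, -1.0, 1.0), "pearson", n=X.shape[0])


def _thresholds_from_margins(x: np.ndarray, n_cat: int) -> np.ndarray:
    """Inverse-normal thresholds from cumulative category proportions."""
    counts = np.bincount(x, minlength=n_cat).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum)


def _bivariate_cell_probs(rho: float, ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """Cell probabilities of a discretized standard bivariate normal."""
    ea = np.concatenate(([-np.inf], ta, [np.inf]))
    eb = np.concatenate(([-np.inf], tb, [np.inf]))
    ga, gb = np.meshgrid(ea, eb, indexing="ij")
    pts = np.column_stack([ga.ravel(), gb.ravel()])
    dist = stats.multivariate_normal(mean=[0.0, 0.0],
                                     cov=[[1.0, rho], [rho, 1.0]],
                                     allow_singular=True)
    # CDF at -inf edges is 0; clip arguments for the scipy evaluator
    F = dist.cdf(np.clip(pts, -12, 12)).reshape(ga.shape)
    F[ea == -np.inf, :] = 0.0
    F[:, eb == -np.inf] = 0.0
    cells = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(cells, 1e-12, None)


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-step ML polychoric correlation of two ordinal vectors.

    Returns (rho, clamped); boundary estimates are clamped to +/-0.999.
    """
    # recode to observed categories so all thresholds are finite
    _, x = np.unique(x, return_inverse=True)
    _, y = np.unique(y, return_inverse=True)
    cats_x = int(x.max()) + 1
    cats_y = int(y.max()) + 1
    if cats_x < 2 or cats_y < 2:
        raise ValueError("each item needs at least 2 observed categories")
    table = np.zeros((cats_x, cats_y))
    np.add.at(table, (x, y), 1.0)
    ta = _thresholds_from_margins(x, cats_x)
    tb = _thresholds_from_margins(y, cats_y)

    def negloglik(rho: float) -> float:
        return -float(np.sum(table * np.log(_bivariate_cell_probs(rho, ta, tb))))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError("polychoric likelihood maximization failed")
    rho = float(res.x)
    clamped = abs(rho) >= RHO_BOUND - 1e-4
    if clamped:
        rho = float(np.sign(rho) * RHO_BOUND)
    return rho, clamped


def polychoric_matrix(X: np.ndarray, labels=NODE_LABELS,
                      epsilon: float = 1e-6) -> CorrelationMatrix:
    """Pairwise two-step ML polychoric correlations, PSD-repaired if needed."""
    X = np.asarray(X, dtype=int)
    _check_columns(X, labels)
    p = X.shape[1]
    R = np.eye(p)
    flags: list[str] = []
    for i in range(p):
        for j in range(i + 1, p):
            try:
                rho, clamped = polychoric_pair(X[:, i], X[:, j])
            except RuntimeError as e:
                li = labels[i] if labels is not None else i
                lj = labels[j] if labels is not None else j
                raise RuntimeError(f"polychoric failed for pair ({li}, {lj})") from e
            if clamped:
                li = labels[i] if labels is not None else i
                lj = labels[j] if labels is not None else j
                flags.append(f"clamped:{li}-{lj}")
            R[i, j] = R[j, i] = rho
    if np.linalg.eigvalsh(R).min() < epsilon:
        R = nearest_psd(CorrelationMatrix(R, "polychoric", X.shape[0]),
                        epsilon).values
        flags.append("psd-repaired")
    return CorrelationMatrix(R, "polychoric", n=X.shape[0], flags=flags)


def nearest_psd(corr: CorrelationMatrix | np.ndarray,
                epsilon: float = 1e-8) -> CorrelationMatrix:
    """Eigenvalue clipping at ``epsilon``, rescaled back to unit diagonal.

    Idempotent on input that is already PSD with unit diagonal.
    """
    if isinstance(corr, CorrelationMatrix):
        R, method, n = corr.values, corr.method, corr.n
    else:
        R = np.asarray(corr, dtype=float)
        method, n = "pearson", 0
    R = 0.5 * (R + R.T)
    for _ in range(100):
        w, V = np.linalg.eigh(R)
        if w.min() >= epsilon and np.allclose(np.diag(R), 1.0, atol=1e-12):
            break
        R = (V * np.clip(w, epsilon, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = 0.5 * (R + R.T)
        np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(np.clip(R, -1.0, 1.0), method, n=n)
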