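"""Synthetic 4-wave ordinal cohorts with known network ground truth.

The generator emulates the study conditions every downstream stage is tested
against: 16 ordinal items (scored 0-3) driven by a sparse latent Gaussian
graphical model with two symptom communities, four assessment waves with
non-increasing sample sizes, small latent mean drift across waves, and
age-dependent dropout.

The true network is built with the random-GGM recipe standard in network
simulation work: sparse precision off-diagonals with magnitudes in a fixed
range and a 90% share of positive partial correlations, made positive
definite through diagonal dominance and normalized to unit diagonal.
Ordinal items arise by thresholding the latent Gaussian at fixed quantiles
skewed toward the 0 response, mimicking low-prevalence symptoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ITEM_COLUMNS,
    NODE_LABELS,
    WAVES,
    ItemPanel,
)

#: Latent quantiles of the 0/1, 1/2 and 2/3 category cut points.
DEFAULT_THRESHOLD_QUANTILES = (0.55, 0.80, 0.93)

#: Per-wave-step latent mean drift (in latent SD units) applied by default:
#: anxiety items drift down, sadness and guilt drift up.
DEFAULT_DRIFT = 0.08


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TrueModel:
    """Ground truth for the generator: sparse partial correlations, ordinal
    thresholds, per-wave latent mean shifts, and the dropout age effect."""

    true_partial: np.ndarray          # p x p, zero diagonal
    density: float
    thresholds: np.ndarray            # p x 3, strictly increasing per item
    wave_effects: np.ndarray          # n_waves x p latent mean shifts
    dropout_age_effect: float
    seed: int

    def __post_init__(self):
        P = np.asarray(self.true_partial, dtype=float)
        if not np.allclose(P, P.T):
            raise ValueError("true_partial must be symmetric")
        if not np.allclose(np.diag(P), 0.0):
            raise ValueError("true_partial must have zero diagonal")
        if not (0.0 <= self.density < 1.0):
            raise ValueError("density must be in [0, 1)")
        thr = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(thr, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        K = self.precision
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("implied precision is not positive definite")

    @property
    def p(self) -> int:
        return self.true_partial.shape[0]

    @property
    def precision(self) -> np.ndarray:
        """Canonical unit-diagonal precision implied by the partials."""
        return np.eye(self.p) - self.true_partial

    @property
    def correlation(self) -> np.ndarray:
        """Latent correlation matrix implied by the precision."""
        S = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(S))
        return S / np.outer(d, d)

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean true-edge indicator (upper and lower triangles)."""
        return self.true_partial != 0.0


def default_thresholds(p: int = 16,
                       quantiles=DEFAULT_THRESHOLD_QUANTILES) -> np.ndarray:
    return np.tile(stats.norm.ppf(np.asarray(quantiles)), (p, 1))


def default_wave_effects(n_waves: int = 4, drift: float = DEFAULT_DRIFT) -> np.ndarray:
    """Latent mean drift: anxiety items decline, sadness/guilt rise over waves."""
    eff = np.zeros((n_waves, len(NODE_LABELS)))
    anx = [NODE_LABELS.index(n) for n in NODE_LABELS[9:]]
    up = [NODE_LABELS.index("Sdn"), NODE_LABELS.index("Glt")]
    for t in range(n_waves):
        eff[t, anx] = -drift * t
        eff[t, up] = drift * t
    return eff


def generate_true_network(
    p: int = 16,
    density: float = 0.2,
    weight_range: tuple[float, float] = (0.5, 1.0),
    seed: int | np.random.Generator = 0,
    prop_positive: float = 0.9,
    diag_constant: float = 1.5,
    min_eigenvalue: float = 1e-4,
    thresholds: np.ndarray | None = None,
    wave_effects: np.ndarray | None = None,
    dropout_age_effect: float = 0.0,
    community_sizes: tuple[int, int] | None = None,
    within_fraction: float = 0.75,
) -> TrueModel:
    """Draw a sparse random GGM with exactly round(density * p(p-1)/2) edges.

    Precision off-diagonals get magnitudes uniform in ``weight_range`` with a
    ``prop_positive`` share of positive partial correlations; the diagonal is
    set to ``diag_constant`` times the row-wise absolute sum (>=1), rows are
    normalized, and the matrix symmetrized, which keeps it diagonally
    dominant. If the minimum eigenvalue still falls below ``min_eigenvalue``,
    off-diagonals are uniformly shrunk (bounded number of attempts).

    When ``community_sizes`` is given (e.g. ``(9, 7)`` for the depression and
    anxiety blocks), roughly ``within_fraction`` of the edges are placed
    within the two blocks, giving the two-community structure of comorbidity
    networks; the remainder become cross-community (bridge) edges.
    """
    if p < 3:
        raise ValueError("need at least 3 nodes")
    if not (0.0 <= density < 1.0):
        raise ValueError("density must be in [0, 1)")
    lo, hi = weight_range
    if not (0.0 < lo <= hi):
        raise ValueError(f"infeasible weight_range {weight_range}")
    rng = _as_rng(seed)
    seed_int = int(seed) if not isinstance(seed, np.random.Generator) else -1
    n_pairs = p * (p - 1) // 2
    m = int(round(density * n_pairs))
    iu = np.triu_indices(p, k=1)
    if community_sizes is None:
        chosen = rng.choice(n_pairs, size=m, replace=False)
    else:
        k1 = community_sizes[0]
        within = np.nonzero((iu[0] < k1) == (iu[1] < k1))[0]
        cross = np.nonzero((iu[0] < k1) != (iu[1] < k1))[0]
        m_within = min(int(round(within_fraction * m)), len(within))
        m_cross = min(m - m_within, len(cross))
        m_within = m - m_cross
        chosen = np.concatenate([
            rng.choice(within, size=m_within, replace=False),
            rng.choice(cross, size=m_cross, replace=False),
        ])
    K = np.zeros((p, p))
    mags = rng.uniform(lo, hi, size=m)
    # negative precision off-diagonal <=> positive partial correlation
    signs = np.where(rng.random(m) < prop_positive, -1.0, 1.0)
    K[iu[0][chosen], iu[1][chosen]] = signs * mags
    K = K + K.T
    diag = diag_constant * np.sum(np.abs(K), axis=1)
    diag[diag == 0] = 1.0
    K = K / diag[:, None]
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    partial = -K.copy()
    np.fill_diagonal(partial, 0.0)
    for _ in range(100):
        if m == 0 or np.linalg.eigvalsh(np.eye(p) - partial).min() > min_eigenvalue:
            break
        partial *= 0.9
    else:
        raise RuntimeError(
            "could not reach positive definiteness by uniform shrinkage"
        )
    if thresholds is None:
        thresholds = default_thresholds(p)
    if wave_effects is None:
        wave_effects = np.zeros((len(WAVES), p))
    return TrueModel(
        true_partial=partial,
        density=density,
        thresholds=np.asarray(thresholds, dtype=float),
        wave_effects=np.asarray(wave_effects, dtype=float),
        dropout_age_effect=dropout_age_effect,
        seed=seed_int,
    )


def sample_latent(model: TrueModel, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(model.correlation)
    return rng.standard_normal((n, model.p)) @ L.T


def sample_wave(model: TrueModel, n: int, wave: str = "T1",
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` ordinal response vectors for one wave.

    Latent scores come from the zero-mean Gaussian implied by the true
    partial correlations, shifted by the wave's latent mean effect, then each
    coordinate is discretized by its item thresholds into {0,1,2,3}.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(seed)
    w = WAVES.index(wave)
    latent = sample_latent(model, n, rng) + model.wave_effects[w]
    return (latent[:, :, None] > model.thresholds[None, :, :]).sum(axis=2)


@dataclass
class CohortSpec:
    """Study-shaped cohort: wave targets, age model, dropout, and the truth."""

    n_baseline: int = 343
    retention: tuple[int, ...] = (343, 269, 261, 212)
    completers: int | None = 210
    age_mean: float = 30.68
    age_sd: float = 4.10
    dropout_age_effect: float = 0.1   # log-odds of dropping out per year
    model: TrueModel | None = None
    seed: int = 0

    def __post_init__(self):
        if list(self.retention) != sorted(self.retention, reverse=True):
            raise ValueError("retention must be non-increasing across waves")
        if self.n_baseline < self.retention[-1]:
            raise ValueError("n_baseline below final retention target")
        if self.n_baseline != self.retention[0]:
            raise ValueError("baseline retention target must equal n_baseline")
        _participation_patterns(tuple(self.retention), self.completers)
        if self.model is None:
            self.model = generate_true_network(
                p=16,
                density=0.2,
                seed=np.random.default_rng([self.seed, 7]),
                wave_effects=default_wave_effects(len(self.retention)),
                dropout_age_effect=self.dropout_age_effect,
                community_sizes=(9, 7),
            )


def _participation_patterns(retention: tuple[int, ...],
                            completers: int | None) -> list[tuple[int, ...]]:
    """Per-participant wave-presence patterns hitting the targets exactly.

    Mostly monotone dropout; when the completer target is below the final
    wave count, the minimal number of intermittent participants (present at
    T1, T3, T4 but missing T2) reconciles the two.
    """
    n1, n2, n3, n4 = retention
    c = n4 if completers is None else completers
    i4 = n4 - c                      # present T1,T3,T4; missing T2
    a = n3 - c - i4                  # 1110
    b = n2 - c - a                   # 1100
    rest = n1 - c - i4 - a - b       # 1000
    counts = {(1, 1, 1, 1): c, (1, 0, 1, 1): i4, (1, 1, 1, 0): a,
              (1, 1, 0, 0): b, (1, 0, 0, 0): rest}
    if any(v < 0 for v in counts.values()):
        raise ValueError(
            f"wave targets {retention} with {c} completers are unreachable"
        )
    patterns: list[tuple[int, ...]] = []
    # ordered from earliest dropout to full participation
    for pat in [(1, 0, 0, 0), (1, 1, 0, 0), (1, 1, 1, 0), (1, 0, 1, 1),
                (1, 1, 1, 1)]:
        patterns.extend([pat] * counts[pat])
    return patterns


def generate_cohort(spec: CohortSpec) -> ItemPanel:
    """Generate a full panel with exactly the target per-wave case counts.

    Dropout is age-dependent: participants are ranked by a Gumbel-perturbed
    age score (a Plackett-Luce draw, the sequential-logit analogue), and
    higher-propensity participants receive the sparser participation
    patterns, so a positive ``dropout_age_effect`` makes dropouts older on
    average while the wave counts stay exact.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    n = spec.n_baseline
    ages = rng.normal(spec.age_mean, spec.age_sd, size=n)
    patterns = _participation_patterns(tuple(spec.retention), spec.completers)
    # rank participants by dropout propensity (older => earlier dropout)
    score = spec.dropout_age_effect * ages + rng.gumbel(size=n)
    order = np.argsort(-score)       # most dropout-prone first
    pattern_by_participant = np.empty((n, len(spec.retention)), dtype=int)
    pattern_by_participant[order] = np.asarray(patterns)

    ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    frames = []
    for w, wave in enumerate(WAVES[: len(spec.retention)]):
        present = np.nonzero(pattern_by_participant[:, w])[0]
        X = sample_wave(model, len(present), wave, rng)
        df = pd.DataFrame(X, columns=list(ITEM_COLUMNS))
        df.insert(0, "age", ages[present])
        df.insert(0, "wave", wave)
        df.insert(0, "participant_id", ids[present])
        frames.append(df)
    panel = ItemPanel(pd.concat(frames, ignore_index=True))
    return panel


# ---------------------------------------------------------------------------
# TrueModel serialization (JSON: node labels, edge list, thresholds, seed)
# ---------------------------------------------------------------------------

def true_model_to_json(model: TrueModel, path: str | Path) -> None:
    i, j = np.nonzero(np.triu(model.true_partial, k=1))
    obj = {
        "nodes": list(NODE_LABELS) if model.p == 16 else
                 [f"V{k + 1}" for k in range(model.p)],
        "p": model.p,
        "density": model.density,
        "edges": [
            [int(a), int(b), float(model.true_partial[a, b])]
            for a, b in zip(i, j)
        ],
        "thresholds": model.thresholds.tolist(),
        "wave_effects": model.wave_effects.tolist(),
        "dropout_age_effect": model.dropout_age_effect,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def true_model_from_json(path: str | Path) -> TrueModel:
    obj = json.loads(Path(path).read_text())
    p = obj["p"]
    P = np.zeros((p, p))
    for a, b, w in obj["edges"]:
        P[a, b] = P[b, a] = w
    return TrueModel(
        true_partial=P,
        density=obj["density"],
        thresholds=np.asarray(obj["thresholds"], dtype=float),
        wave_effects=np.asarray(obj["wave_effects"], dtype=float),
        dropout_age_effect=obj["dropout_age_effect"],
        seed=obj["seed"],
    )


def cohort_spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    """Plain-text (YAML) round-trip of a cohort spec, excluding the model,
    which is reconstructed from the seed on load unless saved separately."""
    import yaml

    obj = {
        "n_baseline": spec.n_baseline,
        "retention": list(spec.retention),
        "completers": spec.completers,
        "age_mean": spec.age_mean,
        "age_sd": spec.age_sd,
        "dropout_age_effect": spec.dropout_age_effect,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    import yaml

    obj = yaml.safe_load(Path(path).read_text())
    obj["retention"] = tuple(obj["retention"])
    return CohortSpec(**obj)
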