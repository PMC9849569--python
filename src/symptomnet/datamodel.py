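"""Core domain types and validation for 4-wave PHQ-9/GAD-7 item panels.

The canonical node ordering is the nine PHQ-9 (depression) items followed by
the seven GAD-7 (anxiety) items; every matrix in the package uses this order.
Waves are the four assessment occasions T1..T4, coded 0..3 for time-dependent
operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Short reference names for the 16 symptom nodes (PHQ-9 then GAD-7).
NODE_LABELS: tuple[str, ...] = (
    "Anh", "Sdn", "Slp", "Enr", "App", "Glt", "Cnc", "Mtr", "Scd",
    "Nrv", "Cnt", "Wrr", "Rlx", "Rst", "Irr", "Afr",
)

DEPRESSION_NODES: tuple[str, ...] = NODE_LABELS[:9]
ANXIETY_NODES: tuple[str, ...] = NODE_LABELS[9:]

#: CSV column names for the item responses, in canonical node order.
ITEM_COLUMNS: tuple[str, ...] = tuple(
    [f"phq{i}" for i in range(1, 10)] + [f"gad{i}" for i in range(1, 8)]
)

WAVES: tuple[str, ...] = ("T1", "T2", "T3", "T4")
WAVE_CODES: dict[str, int] = {w: i for i, w in enumerate(WAVES)}

N_ITEMS = len(NODE_LABELS)
MAX_SCORE = 3


class PanelValidationError(ValueError):
    """Raised when an item panel violates its invariants; carries row indices."""

    def __init__(self, message: str, rows: Sequence[int] | None = None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class NoCompleteCasesError(ValueError):
    """Raised when a wave has no participant with all 16 items observed."""


@dataclass(frozen=True)
class CommunityPartition:
    """Assignment of each node to the depression or anxiety community."""

    mapping: Mapping[str, str] = field(
        default_factory=lambda: {
            **{n: "depression" for n in DEPRESSION_NODES},
            **{n: "anxiety" for n in ANXIETY_NODES},
        }
    )

    def __post_init__(self):
        communities = set(self.mapping.values())
        if len(communities) != 2:
            raise ValueError(f"expected exactly two communities, got {communities}")

    def community(self, node: str) -> str:
        return self.mapping[node]

    def members(self, community: str) -> list[str]:
        return [n for n, c in self.mapping.items() if c == community]

    @property
    def communities(self) -> list[str]:
        # stable order: community of the first node first
        seen: list[str] = []
        for c in self.mapping.values():
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class ItemPanel:
    """Long-format panel of ordinal item responses.

    One row per participant-wave actually observed; columns are
    ``participant_id, wave, age, phq1..phq9, gad1..gad7``. Missing item
    responses are NaN; a missing wave is simply an absent row.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = ["participant_id", "wave", "age", *ITEM_COLUMNS]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise PanelValidationError(f"panel is missing columns: {missing}")
        self.data = self.data[required].reset_index(drop=True)

    @property
    def waves(self) -> list[str]:
        return [w for w in WAVES if w in set(self.data["wave"])]

    def rows_at(self, wave: str) -> pd.DataFrame:
        return self.data[self.data["wave"] == wave]

    def participants_at(self, wave: str) -> pd.Index:
        return pd.Index(self.rows_at(wave)["participant_id"])


def validate_panel(panel: ItemPanel) -> ItemPanel:
    """Check panel invariants; return the panel unchanged if they all hold.

    Raises :class:`PanelValidationError` naming the offending row indices for
    out-of-range scores, unknown wave labels, or duplicate participant-wave
    pairs.
    """
    df = panel.data
    bad_wave = df.index[~df["wave"].isin(WAVES)]
    if len(bad_wave):
        raise PanelValidationError(
            f"unknown wave labels in rows {list(bad_wave)}", rows=bad_wave
        )
    items = df[list(ITEM_COLUMNS)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (
            (items < 0) | (items > MAX_SCORE) | (np.floor(items) != items)
        ) & ~np.isnan(items)
    bad_rows = np.nonzero(out_of_range.any(axis=1))[0]
    if len(bad_rows):
        raise PanelValidationError(
            f"item scores outside {{0,...,{MAX_SCORE}}} in rows {list(bad_rows)}",
            rows=bad_rows,
        )
    dup = df.duplicated(subset=["participant_id", "wave"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["participant_id", "wave"]].drop_duplicates()
        raise PanelValidationError(
            "duplicate participant-wave pairs: "
            + ", ".join(f"({r.participant_id}, {r.wave})" for r in keys.itertuples()),
            rows=df.index[dup],
        )
    return panel


def complete_cases(panel: ItemPanel, wave: str) -> tuple[np.ndarray, pd.Index]:
    """Item-score matrix of participants with all 16 items observed at ``wave``.

    Returns ``(X, participant_ids)`` where ``X`` is ``n_wave x 16`` int.
    Missingness is handled by listwise deletion only.
    """
    if wave not in WAVES:
        raise ValueError(f"unknown wave {wave!r}")
    rows = panel.rows_at(wave)
    items = rows[list(ITEM_COLUMNS)]
    keep = items.notna().all(axis=1)
    if not keep.any():
        raise NoCompleteCasesError(f"no complete cases at wave {wave}")
    X = items[keep].to_numpy(dtype=float).astype(int)
    return X, pd.Index(rows.loc[keep, "participant_id"])


def complete_case_counts(panel: ItemPanel) -> dict[str, int]:
    """Number of complete cases at each wave present in the panel."""
    out = {}
    for w in panel.waves:
        try:
            X, _ = complete_cases(panel, w)
            out[w] = X.shape[0]
        except NoCompleteCasesError:
            out[w] = 0
    return out


@dataclass
class SymptomNetwork:
    """Weighted undirected partial-correlation network over the 16 symptoms."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    partition: CommunityPartition | None
    n: int
    lambda_selected: float

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        p = len(self.nodes)
        if W.shape != (p, p):
            raise ValueError(f"weights shape {W.shape} does not match {p} nodes")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0, atol=1e-10):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(np.abs(W) > 1.0 + 1e-10):
            raise ValueError("partial correlations must lie in [-1, 1]")
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Nonzero upper-triangle edges as (node_i, node_j, weight) rows."""
        i, j = np.triu_indices(self.p, k=1)
        w = self.weights[i, j]
        nz = w != 0
        return pd.DataFrame(
            {
                "node_i": np.asarray(self.nodes)[i[nz]],
                "node_j": np.asarray(self.nodes)[j[nz]],
                "weight": w[nz],
            }
        )


def default_partition_for(nodes: Sequence[str]) -> CommunityPartition | None:
    if tuple(nodes) == NODE_LABELS:
        return CommunityPartition()
    return None


# ---------------------------------------------------------------------------
# I/O: wide CSV panels, edge lists, network JSON
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> ItemPanel:
    """Read a panel CSV (one row per participant-wave; empty cell = missing)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "wave": str})
    return validate_panel(ItemPanel(df))


def write_panel(panel: ItemPanel, path: str | Path) -> None:
    df = panel.data.copy()
    for c in ITEM_COLUMNS:
        df[c] = df[c].astype("Int64")  # keeps missing cells empty, not "nan"
    df.to_csv(path, index=False)


def read_edge_list(path: str | Path, nodes: Sequence[str] = NODE_LABELS,
                   n: int = 0, lambda_selected: float = float("nan")) -> SymptomNetwork:
    """Build a network from a (node_i, node_j, weight) table.

    This is the reading target for published edge-weight tables as well as for
    the package's own ``estimate`` output.
    """
    df = pd.read_csv(path)
    idx = {lab: k for k, lab in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for row in df.itertuples():
        i, j = idx[row.node_i], idx[row.node_j]
        W[i, j] = W[j, i] = float(row.weight)
    return SymptomNetwork(tuple(nodes), W, default_partition_for(nodes), n=n,
                          lambda_selected=lambda_selected)


def write_edge_list(net: SymptomNetwork, path: str | Path) -> None:
    df = net.edge_list()
    df["weight"] = df["weight"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def network_to_json(net: SymptomNetwork, path: str | Path) -> None:
    obj = {
        "nodes": list(net.nodes),
        "weights": net.weights.tolist(),
        "partition": dict(net.partition.mapping) if net.partition else None,
        "n": int(net.n),
        "lambda_selected": float(net.lambda_selected),
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def network_from_json(path: str | Path) -> SymptomNetwork:
    obj = json.loads(Path(path).read_text())
    partition = (
        CommunityPartition(obj["partition"]) if obj.get("partition") else None
    )
    return SymptomNetwork(
        tuple(obj["nodes"]), np.asarray(obj["weights"], dtype=float), partition,
        n=obj["n"], lambda_selected=obj["lambda_selected"],
    )
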