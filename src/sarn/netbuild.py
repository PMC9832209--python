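"""Construction of dynamic brain networks from ROI time series.

A subject's scan arrives as a regions-by-time matrix of BOLD-like signals.
It is divided into equal, contiguous time steps; each step yields one
snapshot of the dynamic functional network: a Pearson correlation adjacency
matrix, z-scored per-step signals as node features, a sparse top-k
neighborhood per region, and a capped shortest-path distance index used by
the encoder's learned spatial encoding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "ROITimeSeries",
    "NetworkSnapshot",
    "DynamicBrainNetwork",
    "segment_series",
    "pearson_connectivity",
    "sparsify_adjacency",
    "neighbor_mask",
    "spatial_distance_index",
    "build_network",
    "read_subject_tsv",
    "write_subject_tsv",
    "read_manifest",
    "write_network_bundle",
]


@dataclass
class ROITimeSeries:
    """One subject's region-by-time signal matrix with a binary label.

    ``values`` has one row per region and one column per time point; the
    label is 0 for control and 1 for addicted.
    """

    values: np.ndarray
    region_ids: list[str]
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D regions x time matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")
        if len(self.region_ids) != self.values.shape[0]:
            raise ValueError("region_ids length must match the number of rows")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        if int(self.label) not in (0, 1):
            raise ValueError("label must be 0 (control) or 1 (addicted)")
        self.label = int(self.label)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class NetworkSnapshot:
    """One time step of the dynamic network.

    ``adjacency`` holds Pearson coefficients (symmetric, unit diagonal);
    ``node_features`` is the z-scored per-step signal window.
    """

    adjacency: np.ndarray
    node_features: np.ndarray


@dataclass
class DynamicBrainNetwork:
    """Per-step snapshots plus the sparse structure the encoder consumes.

    Neighborhoods and shortest-path indices are recomputed per snapshot
    because the connectivity changes across time steps.
    """

    snapshots: list[NetworkSnapshot]
    neighbor_sets: list[list[np.ndarray]]  # [t][i] -> indices of N(i), incl. i
    neighbor_masks: list[np.ndarray]       # [t] -> boolean N x N, row i = N(i)
    spatial_index: list[np.ndarray]        # [t] -> integer N x N hop distances
    label: int
    region_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_steps(self) -> int:
        return len(self.snapshots)

    @property
    def n_regions(self) -> int:
        return self.snapshots[0].adjacency.shape[0]


def segment_series(ts: ROITimeSeries, n_steps: int) -> list[np.ndarray]:
    """Split the scan into ``n_steps`` contiguous, equal-width segments."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    T = ts.n_timepoints
    if T % n_steps != 0:
        raise ValueError(
            f"time series length T={T} is not divisible by n_steps={n_steps}"
        )
    return [np.array(seg) for seg in np.hsplit(ts.values, n_steps)]


def pearson_connectivity(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation between all region pairs of one segment.

    Rows with zero variance would make the coefficient undefined; such
    entries are set to 0 off-diagonal (with a warning) so downstream graph
    construction stays well-posed.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2 or segment.shape[1] < 2:
        raise ValueError("segment must be N x D with D >= 2 (correlation undefined)")
    constant = np.isclose(segment.std(axis=1), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(segment)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant region(s); their correlations set to 0",
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return (r + r.T) / 2.0


def sparsify_adjacency(adj: np.ndarray, k: int) -> list[np.ndarray]:
    """Per-region neighborhood: self plus the top-k partners by |r|.

    Ties are broken by ascending region index so the construction is
    deterministic. Returns, for each region i, the sorted index array N(i).
    """
    adj = np.asarray(adj, dtype=np.float64)
    n = adj.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= N-1 (got k={k}, N={n})")
    strength = np.abs(adj).copy()
    np.fill_diagonal(strength, -np.inf)  # self is added explicitly
    sets = []
    for i in range(n):
        order = np.argsort(-strength[i], kind="stable")  # stable => index ties ascend
        neigh = np.sort(np.append(order[:k], i))
        sets.append(neigh.astype(np.intp))
    return sets


def neighbor_mask(neighbor_sets: list[np.ndarray]) -> np.ndarray:
    """Boolean N x N matrix; row i marks the members of N(i)."""
    n = len(neighbor_sets)
    mask = np.zeros((n, n), dtype=bool)
    for i, neigh in enumerate(neighbor_sets):
        mask[i, neigh] = True
    return mask


def spatial_distance_index(
    neighbor_sets: list[np.ndarray], max_dist: int = 5
) -> np.ndarray:
    """Capped hop distances on the symmetrized k-NN graph.

    Entry (i, j) is the unweighted shortest-path length between regions i
    and j, capped at ``max_dist``; unreachable pairs fall in the extra
    bucket ``max_dist + 1``. These integers index the encoder's learned
    spatial-encoding table.
    """
    if not neighbor_sets:
        raise ValueError("neighbor_sets must be nonempty")
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    mask = neighbor_mask(neighbor_sets)
    sym = mask | mask.T
    np.fill_diagonal(sym, False)
    dist = shortest_path(csr_matrix(sym.astype(np.int8)), method="D", unweighted=True)
    out = np.where(np.isinf(dist), max_dist + 1, np.minimum(dist, max_dist))
    np.fill_diagonal(out, 0)
    return out.astype(np.intp)


def _zscore_rows(segment: np.ndarray) -> np.ndarray:
    mu = segment.mean(axis=1, keepdims=True)
    sd = segment.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (segment - mu) / sd


def build_network(
    ts: ROITimeSeries, n_steps: int = 4, k: int = 10, max_dist: int = 5
) -> DynamicBrainNetwork:
    """Full construction: segments -> FC snapshots -> sparse structure."""
    segments = segment_series(ts, n_steps)
    snapshots, nsets, masks, sidx = [], [], [], []
    for seg in segments:
        adj = pearson_connectivity(seg)
        sets = sparsify_adjacency(adj, k)
        snapshots.append(NetworkSnapshot(adjacency=adj, node_features=_zscore_rows(seg)))
        nsets.append(sets)
        masks.append(neighbor_mask(sets))
        sidx.append(spatial_distance_index(sets, max_dist))
    return DynamicBrainNetwork(
        snapshots=snapshots,
        neighbor_sets=nsets,
        neighbor_masks=masks,
        spatial_index=sidx,
        label=ts.label,
        region_ids=list(ts.region_ids),
        subject_id=ts.subject_id,
    )


# ---------------------------------------------------------------------
# on-disk formats: per-subject TSV + manifest TSV

def write_subject_tsv(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, index=pd.Index(ts.region_ids, name="region_id"))
    df.columns = [f"t{c}" for c in range(ts.n_timepoints)]
    df.to_csv(path, sep="\t")


def read_subject_tsv(path: str | Path, subject_id: str, label: int) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ROITimeSeries(
        values=df.to_numpy(dtype=np.float64),
        region_ids=[str(r) for r in df.index],
        subject_id=subject_id,
        label=label,
    )


def read_manifest(path: str | Path) -> list[ROITimeSeries]:
    """Load all subjects listed in a manifest TSV (subject_id, path, label).

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    man = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "path", "label"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    subjects = []
    for row in man.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        subjects.append(read_subject_tsv(p, str(row.subject_id), int(row.label)))
    return subjects


def write_network_bundle(
    net: DynamicBrainNetwork,
    out_dir: str | Path,
    n_steps: int,
    k: int,
    max_dist: int,
) -> None:
    """Write one subject's snapshots as TSVs plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, snap in enumerate(net.snapshots):
        np.savetxt(out / f"adjacency_step{t}.tsv", snap.adjacency, delimiter="\t")
        np.savetxt(out / f"features_step{t}.tsv", snap.node_features, delimiter="\t")
        np.savetxt(
            out / f"spatial_index_step{t}.tsv",
            net.spatial_index[t],
            delimiter="\t",
            fmt="%d",
        )
    meta = {
        "subject_id": net.subject_id,
        "label": net.label,
        "n_steps": n_steps,
        "knn": k,
        "max_dist": max_dist,
        "region_ids": net.region_ids,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
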