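"""Ward clustering of combined cleavage datasets and enzyme-specific cluster extraction.

A combined two-enzyme dataset of BLOSUM62-encoded subsite windows is
clustered agglomeratively with Ward linkage on Euclidean distance and the
dendrogram is cut at up to ``max_clusters`` clusters.  Clusters whose
members all come from a single enzyme (purity 1.0) and that reach a minimum
size are reported as enzyme-specific substrate groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .cleavage_io import CleavageRecord
from .encoding import EncodedDataset

DEFAULT_MAX_CLUSTERS = 400
DEFAULT_MIN_SIZE = 2


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    size: int
    enzyme_counts: dict[str, int]
    purity: float
    member_indices: tuple[int, ...]


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignment of every record plus per-cluster summaries."""

    assignments: np.ndarray  # record index -> cluster id
    summaries: tuple[ClusterSummary, ...]
    enzyme_per_record: tuple[str, ...]
    max_clusters: int
    n_clusters: int

    def cluster(self, cluster_id: int) -> ClusterSummary:
        for s in self.summaries:
            if s.cluster_id == cluster_id:
                return s
        raise KeyError(cluster_id)


def _summarize(
    assignments: np.ndarray, enzymes: Sequence[str]
) -> tuple[ClusterSummary, ...]:
    out = []
    for cid in sorted(np.unique(assignments)):
        idx = np.flatnonzero(assignments == cid)
        counts: dict[str, int] = {}
        for i in idx:
            counts[enzymes[i]] = counts.get(enzymes[i], 0) + 1
        size = int(idx.size)
        purity = max(counts.values()) / size
        out.append(
            ClusterSummary(
                cluster_id=int(cid),
                size=size,
                enzyme_counts=counts,
                purity=float(purity),
                member_indices=tuple(int(i) for i in idx),
            )
        )
    return tuple(out)


def ward_cluster(
    encoded: EncodedDataset,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
) -> ClusterResult:
    """Ward-linkage agglomerative clustering of the encoded records.

    The tree is cut at ``min(max_clusters, n_records)`` clusters.  The
    procedure is deterministic: identical input order and parameters give
    identical assignments.
    """
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    X = np.asarray(encoded.features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 records to cluster")
    Z = linkage(X, method="ward")
    heights = Z[:, 2]
    # Cut the tree to at most max_clusters clusters without ever splitting a
    # zero-height (duplicate-window) merge: identical records always co-cluster.
    m0 = n - int(np.sum(heights <= 0.0))  # clusters after zero merges only
    k_eff = min(max_clusters, m0)
    if k_eff >= n:
        assignments = np.arange(1, n + 1)
    else:
        thr = heights[n - 1 - k_eff]
        assignments = fcluster(Z, t=thr, criterion="distance")
    enzymes = tuple(
        encoded.provenance[int(lab)] for lab in encoded.labels
    )
    summaries = _summarize(assignments, enzymes)
    return ClusterResult(
        assignments=assignments,
        summaries=summaries,
        enzyme_per_record=enzymes,
        max_clusters=max_clusters,
        n_clusters=len(summaries),
    )


def enzyme_specific_clusters(
    result: ClusterResult, min_size: int = DEFAULT_MIN_SIZE
) -> list[ClusterSummary]:
    """Clusters containing substrates of only one enzyme (purity 1.0) with
    size >= ``min_size``, sorted by size descending."""
    specific = [
        s for s in result.summaries if s.purity == 1.0 and s.size >= min_size
    ]
    return sorted(specific, key=lambda s: (-s.size, s.cluster_id))


def specific_cluster_totals(specific: Sequence[ClusterSummary]) -> dict[str, dict[str, int]]:
    """Per-enzyme tallies: number of specific clusters and substrates in them."""
    totals: dict[str, dict[str, int]] = {}
    for s in specific:
        enzyme = next(iter(s.enzyme_counts))
        t = totals.setdefault(enzyme, {"clusters": 0, "substrates": 0})
        t["clusters"] += 1
        t["substrates"] += s.size
    return totals


def write_cluster_report(
    result: ClusterResult,
    records: Sequence[CleavageRecord],
    path: str | Path,
    min_size: int = DEFAULT_MIN_SIZE,
) -> None:
    """TSV of all clusters plus a JSON summary of enzyme-specific totals."""
    path = Path(path)
    rows = []
    for s in result.summaries:
        rows.append(
            {
                "cluster_id": s.cluster_id,
                "size": s.size,
                "enzyme_counts": ";".join(f"{k}={v}" for k, v in sorted(s.enzyme_counts.items())),
                "purity": s.purity,
                "member_protein_ids": ";".join(records[i].protein_id for i in s.member_indices),
                "member_windows": ";".join(records[i].window for i in s.member_indices),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    specific = enzyme_specific_clusters(result, min_size=min_size)
    summary = {
        "n_clusters": result.n_clusters,
        "n_records": int(result.assignments.size),
        "min_size": min_size,
        "specific_clusters": len(specific),
        "specific_substrates": sum(s.size for s in specific),
        "per_enzyme": specific_cluster_totals(specific),
    }
    path.with_suffix(".summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
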