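"""BLOSUM62 featurization of subsite residue strings and two-class dataset assembly.

Each residue is encoded as its full substitution-matrix row against the 20
standard amino acids (fixed NCBI order), so a span of length L becomes a
20*L-dimensional real vector.  The score of any residue pair, e.g. A vs. K
at P1, is then one coordinate of the feature vector.  Features are left on
the raw integer score scale (no standardization): all coordinates already
share one scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cleavage_io import AA20, CleavageRecord, SubsiteSpan, SubstitutionMatrix, extract_subsites


@dataclass(frozen=True)
class EncodedDataset:
    """Feature matrix + binary labels for one dataset pair.

    ``labels`` is 1 for the positive enzyme's records and 0 for the
    negative's; ``provenance`` maps the label value to the enzyme name.
    ``span_labels`` records the subsite label of each encoded position.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: dict[int, str]
    span_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on record count")
        if self.features.shape[1] != 20 * len(self.span_labels):
            raise ValueError(
                f"expected {20 * len(self.span_labels)} features for "
                f"{len(self.span_labels)} positions, got {self.features.shape[1]}"
            )

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == 0))


def encode_window(residues: str, matrix: SubstitutionMatrix) -> np.ndarray:
    """Encode a residue string as concatenated substitution-matrix rows.

    Block i (20 values) is the matrix row of residue i against the 20
    standard residues in fixed NCBI order (``AA20``).  Raises ``ValueError``
    naming the position for a residue outside the matrix alphabet.
    """
    out = np.empty(20 * len(residues), dtype=float)
    for i, res in enumerate(residues):
        if res not in matrix:
            raise ValueError(f"residue {res!r} at position {i} not in matrix alphabet")
        out[20 * i : 20 * (i + 1)] = [matrix.score(res, a) for a in AA20]
    return out


def encode_records(
    records: Sequence[CleavageRecord],
    span: SubsiteSpan,
    matrix: SubstitutionMatrix,
    position_mask: Sequence[str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode each record's span residues; returns (matrix, span labels).

    ``position_mask`` optionally restricts encoding to a subset of subsite
    labels within the span (e.g. only positions selected by the
    heterogeneity test); order within the span is preserved.
    """
    if not records:
        raise ValueError("no records to encode")
    half_width = records[0].half_width
    labels = span.labels(half_width)
    keep = list(range(len(labels)))
    if position_mask is not None:
        mask = set(position_mask)
        unknown = mask - set(labels)
        if unknown:
            raise ValueError(f"mask positions {sorted(unknown)} not in span {span}")
        keep = [i for i, lab in enumerate(labels) if lab in mask]
        if not keep:
            raise ValueError("position mask removed every span position")
    rows = []
    for rec in records:
        residues = extract_subsites(rec, span)
        residues = "".join(residues[i] for i in keep)
        rows.append(encode_window(residues, matrix))
    return np.vstack(rows), tuple(labels[i] for i in keep)


def encode_pair(
    dataset_a: Sequence[CleavageRecord],
    dataset_b: Sequence[CleavageRecord],
    span: SubsiteSpan,
    matrix: SubstitutionMatrix,
    position_mask: Sequence[str] | None = None,
) -> EncodedDataset:
    """Assemble the labeled two-class dataset: A labeled 1, B labeled 0."""
    if not dataset_a or not dataset_b:
        raise ValueError("both datasets must be nonempty")
    feats_a, span_labels = encode_records(dataset_a, span, matrix, position_mask)
    feats_b, _ = encode_records(dataset_b, span, matrix, position_mask)
    features = np.vstack([feats_a, feats_b])
    labels = np.concatenate(
        [np.ones(len(dataset_a), dtype=int), np.zeros(len(dataset_b), dtype=int)]
    )
    provenance = {1: dataset_a[0].enzyme, 0: dataset_b[0].enzyme}
    return EncodedDataset(
        features=features, labels=labels, provenance=provenance, span_labels=span_labels
    )


def write_encoded_tsv(encoded: EncodedDataset, path: str | Path) -> None:
    """Audit writer: one row per record, label first, then all features."""
    cols = [
        f"{pos}:{aa}" for pos in encoded.span_labels for aa in AA20
    ]
    frame = pd.DataFrame(encoded.features, columns=cols)
    frame.insert(0, "label", encoded.labels)
    frame.to_csv(Path(path), sep="\t", index=False)
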