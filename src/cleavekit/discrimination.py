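"""SVM-AUC discriminability of two cleavage-site datasets.

The discriminability of two sets of cleavage windows is measured as the
ROC-AUC of an SVM trained to tell them apart under repeated stratified
hold-out ("jackknife") cross-validation: in each repetition a fixed fraction
of each class is reserved for testing, the SVM is trained on the rest, and
AUC is computed from the held-out decision-function scores.  AUC ~ 0.5 means
the two specificities are indistinguishable; AUC -> 1 means fully distinct.

The reported AUC is the maximum over repetitions (an optimistically biased
summary); the mean and standard deviation over repetitions are carried
alongside for interpretation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .cleavage_io import CleavageRecord, SubsiteSpan, SubstitutionMatrix
from .encoding import EncodedDataset, encode_pair

logger = logging.getLogger(__name__)

#: Hyperparameter grid searched when none is given (C, kernel, gamma,
#: class weight, jackknife fraction), in the printed order used for
#: tie-breaking.
DEFAULT_GRID: dict[str, tuple] = {
    "regularization_C": (0.001, 0.01, 0.1, 1),
    "kernel": ("linear", "rbf", "poly", "sigmoid"),
    "gamma_mode": ("scale", "auto"),
    "class_weight": ("balanced", "none"),
    "jackknife_fraction": (0.10, 0.25),
}

#: AUC bin edges used to annotate similarity matrices.
AUC_BINS = ((0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0))


@dataclass(frozen=True)
class CVConfig:
    """SVM + cross-validation configuration.

    The defaults are the grid-search optimum of the reference workflow:
    RBF kernel, gamma='scale', C=0.001, balanced class weights, 25% held
    out per repetition, 25 repetitions, tolerance 1e-4, at most 200000
    training iterations, one-vs-one decision shape.
    """

    kernel: str = "rbf"
    regularization_C: float = 0.001
    gamma_mode: str = "scale"
    class_weight: str = "balanced"
    jackknife_fraction: float = 0.25
    repetitions: int = 25
    max_iterations: int = 200_000
    tolerance: float = 1e-4
    decision_shape: str = "ovo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf", "poly", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0 < self.jackknife_fraction < 1:
            raise ValueError("jackknife_fraction must lie in (0,1)")
        if self.regularization_C <= 0 or self.tolerance <= 0:
            raise ValueError("C and tolerance must be positive")
        if self.class_weight not in ("balanced", "none"):
            raise ValueError("class_weight must be 'balanced' or 'none'")

    def repetition_seed(self, rep: int) -> int:
        """Per-repetition seed: a documented counter scheme off one master seed."""
        return (self.seed * 1_000_003 + rep) % (2**31 - 1)

    def make_svc(self) -> SVC:
        return SVC(
            kernel=self.kernel,
            C=self.regularization_C,
            gamma=self.gamma_mode,
            class_weight=None if self.class_weight == "none" else "balanced",
            tol=self.tolerance,
            max_iter=self.max_iterations,
            decision_function_shape=self.decision_shape,
        )


@dataclass(frozen=True)
class DiscriminationResult:
    """Per-repetition AUCs and summary for one dataset-pair comparison."""

    auc_per_repetition: tuple[float, ...]
    auc_reported: float
    auc_mean: float
    auc_std: float
    roc_points: tuple[tuple[float, float], ...]
    config: CVConfig
    n_pos: int
    n_neg: int

    def to_json(self) -> str:
        d = {
            "auc_reported": self.auc_reported,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "auc_per_repetition": list(self.auc_per_repetition),
            "roc_points": [list(p) for p in self.roc_points],
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "config": asdict(self.config),
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _one_repetition(
    encoded: EncodedDataset, config: CVConfig, rep: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """One stratified hold-out repetition -> (auc, fpr, tpr)."""
    seed = config.repetition_seed(rep)
    for attempt in range(2):
        X_tr, X_te, y_tr, y_te = train_test_split(
            encoded.features,
            encoded.labels,
            test_size=config.jackknife_fraction,
            stratify=encoded.labels,
            random_state=(seed + attempt) % (2**31 - 1),
        )
        if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
            break
    else:
        raise ValueError(
            "a class has fewer than 2 members in the hold-out split even after reshuffling"
        )
    clf = config.make_svc()
    clf.fit(X_tr, y_tr)
    scores = clf.decision_function(X_te)
    auc = float(roc_auc_score(y_te, scores))
    fpr, tpr, _ = roc_curve(y_te, scores)
    return auc, fpr, tpr


def pairwise_auc(encoded: EncodedDataset, config: CVConfig | None = None) -> DiscriminationResult:
    """Discriminability of the two classes of ``encoded`` as a max-over-reps AUC.

    Both classes need at least 8 members.  Fully reproducible given
    ``config.seed``: repetition r uses the derived seed
    ``(seed * 1000003 + r) mod (2^31 - 1)`` for its stratified split.
    """
    config = config or CVConfig()
    if encoded.n_pos < 8 or encoded.n_neg < 8:
        raise ValueError(
            f"need >= 8 records per class, got {encoded.n_pos} / {encoded.n_neg}"
        )
    aucs: list[float] = []
    best_roc: tuple[np.ndarray, np.ndarray] | None = None
    for rep in range(config.repetitions):
        auc, fpr, tpr = _one_repetition(encoded, config, rep)
        if not aucs or auc > max(aucs):
            best_roc = (fpr, tpr)
        aucs.append(auc)
    assert best_roc is not None
    roc_points = tuple(zip(best_roc[0].tolist(), best_roc[1].tolist()))
    return DiscriminationResult(
        auc_per_repetition=tuple(aucs),
        auc_reported=float(max(aucs)),
        auc_mean=float(np.mean(aucs)),
        auc_std=float(np.std(aucs)),
        roc_points=roc_points,
        config=config,
        n_pos=encoded.n_pos,
        n_neg=encoded.n_neg,
    )


def grid_search(
    encoded: EncodedDataset,
    grid: Mapping[str, Sequence] | None = None,
    base_config: CVConfig | None = None,
) -> tuple[CVConfig, DiscriminationResult]:
    """Exhaustive hyperparameter search maximizing the reported AUC.

    Ties are broken by smallest C, then by the printed kernel order
    (linear, rbf, poly, sigmoid), then by remaining grid order.  A cell
    whose evaluation fails is logged and skipped; if every cell fails, a
    ``RuntimeError`` is raised.
    """
    grid = dict(grid or DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    base = base_config or CVConfig()
    names = list(grid)
    kernel_order = {k: i for i, k in enumerate(DEFAULT_GRID["kernel"])}
    best: tuple | None = None
    for values in itertools.product(*(grid[n] for n in names)):
        cfg = replace(base, **dict(zip(names, values)))
        try:
            result = pairwise_auc(encoded, cfg)
        except Exception as err:  # noqa: BLE001 - cell failures are survivable
            logger.warning("grid cell %s failed: %s", dict(zip(names, values)), err)
            continue
        key = (
            -result.auc_reported,
            cfg.regularization_C,
            kernel_order.get(cfg.kernel, 99),
        )
        if best is None or key < best[0]:
            best = (key, cfg, result)
    if best is None:
        raise RuntimeError("every grid cell failed")
    return best[1], best[2]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise AUCs over a collection of enzyme datasets (unordered pairs)."""

    enzymes: tuple[str, ...]
    values: dict[frozenset, float] = field(repr=False)
    span: str = ""

    def value(self, a: str, b: str) -> float:
        return self.values[frozenset((a, b))]

    def bin_label(self, a: str, b: str) -> str:
        v = self.value(a, b)
        for lo, hi in AUC_BINS:
            if lo <= v < hi or (hi == 1.0 and v == 1.0):
                return f"{lo:.1f}-{hi:.1f}"
        return "<0.5"

    def as_frame(self) -> pd.DataFrame:
        n = len(self.enzymes)
        arr = np.full((n, n), np.nan)
        for i, a in enumerate(self.enzymes):
            for j, b in enumerate(self.enzymes):
                if i != j:
                    arr[i, j] = self.value(a, b)
        return pd.DataFrame(arr, index=self.enzymes, columns=self.enzymes)

    def write_tsv(self, path: str | Path) -> None:
        self.as_frame().to_csv(Path(path), sep="\t", na_rep="")


def similarity_matrix(
    datasets: Mapping[str, Sequence[CleavageRecord]],
    span: SubsiteSpan,
    matrix: SubstitutionMatrix,
    config: CVConfig | None = None,
) -> tuple[SimilarityMatrix, dict[frozenset, DiscriminationResult]]:
    """All-pairs AUC similarity of enzyme cleavage datasets.

    Each unordered pair is compared once (first-listed enzyme as the
    positive class); label choice does not matter for AUC up to Monte-Carlo
    noise.  Returns the matrix plus the full per-pair results.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    enzymes = tuple(datasets)
    values: dict[frozenset, float] = {}
    details: dict[frozenset, DiscriminationResult] = {}
    for a, b in itertools.combinations(enzymes, 2):
        encoded = encode_pair(list(datasets[a]), list(datasets[b]), span, matrix)
        result = pairwise_auc(encoded, config)
        key = frozenset((a, b))
        values[key] = result.auc_reported
        details[key] = result
    return SimilarityMatrix(enzymes=enzymes, values=values, span=str(span)), details
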