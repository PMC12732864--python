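"""Synthetic inputs for every pipeline stage.

Two generators:

* cleavage-window datasets drawn from position-specific residue
  distributions, with a tunable divergence ``delta`` between two
  pseudo-enzymes — a statistical stand-in for paired protease substrate
  datasets with a controlled amount of specificity difference;
* initial-rate kinetic data drawn from the depletion-aware general modifier
  rate law with multiplicative Gaussian noise of a stated coefficient of
  variation.

Everything is deterministic given a seed.  Each generator consumes its own
``numpy.random.default_rng(seed)`` stream, so seeds act as named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cleavage_io import AA20, CleavageRecord
from .modifier_kinetics import ModifierParams, RatePoint, velocity_with_depletion

DEFAULT_WIDTH = 30  # full window length (2*W, W=15)

#: Substrate (uM) and inhibitor (nM) grids of the reference assay design.
DEFAULT_S_GRID = (135.0, 270.0, 540.0, 1080.0)
DEFAULT_IT_GRID = (53.7, 181.0, 483.0, 1448.9)

#: Reference hyperbolic mixed-type parameter set (Km uM; Ki nM).
REFERENCE_PARAMS = dict(Km=547.7, Ki=26.7, alpha=1.77, beta=0.047)


@dataclass(frozen=True)
class PositionSpecificModel:
    """Per-position residue probabilities over the 20 standard amino acids.

    ``probs`` has shape (width, 20), each row summing to 1; column order is
    the fixed NCBI residue order ``AA20``.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 20:
            raise ValueError(f"probs must have shape (width, 20), got {p.shape}")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each position's probabilities must sum to 1 (tol 1e-12)")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def uniform(cls, width: int = DEFAULT_WIDTH) -> "PositionSpecificModel":
        return cls(np.full((width, 20), 1.0 / 20.0))

    @classmethod
    def cathepsin_like(cls, width: int = DEFAULT_WIDTH) -> "PositionSpecificModel":
        """A papain-family-like preset: hydrophobic preference at P2, small
        residues at P1', mild positive-residue preference at P1; all other
        positions uniform."""
        p = np.full((width, 20), 1.0 / 20.0)
        half = width // 2
        idx = {aa: j for j, aa in enumerate(AA20)}

        def tilt(pos: int, weights: dict[str, float]) -> None:
            row = np.full(20, 1.0)
            for aa, w in weights.items():
                row[idx[aa]] = w
            p[pos] = row / row.sum()

        tilt(half - 2, {"L": 8.0, "F": 6.0, "V": 4.0, "I": 4.0, "W": 2.0})  # P2
        tilt(half - 1, {"R": 5.0, "K": 4.0})  # P1
        tilt(half, {"G": 4.0, "A": 3.0, "S": 3.0})  # P1'
        return cls(p)


@dataclass(frozen=True)
class DivergenceSpec:
    """How much and where pseudo-enzyme B departs from the base model."""

    delta: float
    positions: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0,1]")


def sample_cleavage_dataset(
    model: PositionSpecificModel,
    n: int,
    enzyme_label: str,
    seed: int,
) -> list[CleavageRecord]:
    """Draw ``n`` windows i.i.d. from the position-specific model.

    Protein identifiers are synthesized; p1_index is fixed at W+1 of a
    notional parent protein.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    half = model.width // 2
    aa = np.array(list(AA20))
    records = []
    # one multinomial draw per position over all records, position-independent
    draws = np.empty((n, model.width), dtype="<U1")
    for pos in range(model.width):
        draws[:, pos] = rng.choice(aa, size=n, p=model.probs[pos])
    for i in range(n):
        records.append(
            CleavageRecord(
                enzyme=enzyme_label,
                protein_id=f"{enzyme_label}_synth_{i:06d}",
                p1_index=half + 1,
                window="".join(draws[i]),
            )
        )
    return records


def make_divergent_pair(
    base: PositionSpecificModel, spec: DivergenceSpec
) -> tuple[PositionSpecificModel, PositionSpecificModel]:
    """(modelA, modelB) where B shifts probability mass at the affected positions.

    At each affected position a target residue distinct from the base
    model's most likely residue is chosen (seeded), and B's probability
    vector is the mixture (1-delta)*base + delta*one_hot(target).
    delta = 0 returns B identical to A; delta = 1 makes the affected
    positions deterministic at the target residue.
    """
    bad = [p for p in spec.positions if not 0 <= p < base.width]
    if bad:
        raise ValueError(f"affected position(s) {bad} outside span of width {base.width}")
    rng = np.random.default_rng(spec.seed)
    probs_b = base.probs.copy()
    for pos in spec.positions:
        top = int(np.argmax(base.probs[pos]))
        target = top
        while target == top:
            target = int(rng.integers(0, 20))
        shifted = np.zeros(20)
        shifted[target] = 1.0
        probs_b[pos] = (1.0 - spec.delta) * base.probs[pos] + spec.delta * shifted
    return base, PositionSpecificModel(probs_b)


def simulate_rate_data(
    S_grid: Sequence[float] = DEFAULT_S_GRID,
    It_grid: Sequence[float] = DEFAULT_IT_GRID,
    Et: float = 1.0,
    params: ModifierParams | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    include_uninhibited: bool = True,
) -> list[RatePoint]:
    """Initial-rate data from the depletion-aware modifier law.

    Every (S, It) combination yields one point
    v = velocity_with_depletion(S, It, Et) * (1 + eps), eps ~ N(0, noise_cv),
    independently per point and clipped at v >= 0.  With
    ``include_uninhibited`` an It = 0 series is prepended (required by the
    specific-velocity analysis).  Deterministic given ``seed``.
    """
    if not S_grid or It_grid is None or len(It_grid) == 0:
        raise ValueError("S_grid and It_grid must be nonempty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    params = params or ModifierParams(**REFERENCE_PARAMS)
    rng = np.random.default_rng(seed)
    It_all = ([0.0] if include_uninhibited else []) + [float(i) for i in It_grid]
    points = []
    for It in It_all:
        for S in S_grid:
            v = velocity_with_depletion(float(S), It, Et, params)
            if noise_cv > 0:
                v *= 1.0 + rng.normal(0.0, noise_cv)
            points.append(RatePoint(S=float(S), It=It, v=max(v, 0.0)))
    return points
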