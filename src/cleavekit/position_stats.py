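"""Per-subsite residue frequencies and Anderson-Darling heterogeneity classification.

A subsite position is called *heterogeneous* when its residue usage is
dominated by one or two amino acids.  Operationally, the vector of the 20
per-residue relative frequencies at that position is tested for normality
with the Anderson-Darling test: a position with one or two predominant
residues gives a strongly right-skewed frequency vector and a small p-value,
while a position whose residues are used with many comparable frequencies
looks like a unimodal (approximately normal) sample of 20 values.

Classification follows a three-level scheme:

* ``heterogeneous`` : p <= 0.05
* ``borderline``    : 0.05 < p <= 0.08
* ``normal``        : p > 0.08

The choice of test sample (relative frequencies over the 20 standard
residues, placeholder 'X' counts excluded) is isolated in
:func:`ad_normality` / :func:`anderson_darling_heterogeneity` so alternative
conventions can be swapped in one place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cleavage_io import AA20, ALPHABET, PLACEHOLDER, CleavageRecord, SubsiteSpan, extract_subsites

KLASS_HETEROGENEOUS = "heterogeneous"
KLASS_BORDERLINE = "borderline"
KLASS_NORMAL = "normal"

HETEROGENEOUS_P = 0.05
BORDERLINE_P = 0.08


@dataclass(frozen=True)
class ResidueFrequencyTable:
    """Residue counts per subsite position.

    ``counts`` is a DataFrame indexed by subsite label (N-to-C order) with
    one column per alphabet symbol (20 standard residues plus 'X'); each row
    sums to ``n_records``.
    """

    span: SubsiteSpan
    counts: pd.DataFrame
    n_records: int

    def relative_frequencies(self, include_placeholder: bool = False) -> pd.DataFrame:
        """Row-normalized frequencies; by default over the 20 standard residues."""
        cols = list(ALPHABET) if include_placeholder else list(AA20)
        sub = self.counts[cols]
        return sub.div(sub.sum(axis=1), axis=0)


@dataclass(frozen=True)
class PositionHeterogeneity:
    label: str
    ad_statistic: float
    p_value: float
    klass: str
    degenerate: bool = False


@dataclass(frozen=True)
class HeterogeneityReport:
    positions: tuple[PositionHeterogeneity, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [p.label for p in self.positions],
                "statistic": [p.ad_statistic for p in self.positions],
                "p": [p.p_value for p in self.positions],
                "klass": [p.klass for p in self.positions],
                "degenerate": [p.degenerate for p in self.positions],
            }
        )


def residue_frequencies(
    records: Sequence[CleavageRecord], span: SubsiteSpan
) -> ResidueFrequencyTable:
    """Count residue usage at each subsite position of ``span``.

    All records must share one window width.  Raises ``ValueError`` on empty
    input or mixed widths.
    """
    if not records:
        raise ValueError("residue_frequencies requires at least one record")
    widths = {r.half_width for r in records}
    if len(widths) != 1:
        raise ValueError(f"records have mixed window half widths: {sorted(widths)}")
    half_width = widths.pop()
    labels = span.labels(half_width)
    counts = np.zeros((len(labels), len(ALPHABET)), dtype=int)
    sym_index = {s: j for j, s in enumerate(ALPHABET)}
    for rec in records:
        residues = extract_subsites(rec, span)
        for i, res in enumerate(residues):
            counts[i, sym_index[res]] += 1
    frame = pd.DataFrame(counts, index=labels, columns=list(ALPHABET))
    return ResidueFrequencyTable(span=span, counts=frame, n_records=len(records))


def _ad_p_value(a2: float, n: int) -> float:
    """P-value for the Anderson-Darling normality statistic (case 3: mean and
    variance estimated).  Uses the Stephens small-sample correction
    AD* = A2 (1 + 0.75/n + 2.25/n^2) and the standard piecewise exponential
    approximation (as in R's nortest::ad.test)."""
    adj = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if adj >= 0.6:
        p = math.exp(1.2937 - 5.709 * adj + 0.0186 * adj**2)
    elif adj > 0.34:
        p = math.exp(0.9177 - 4.279 * adj - 1.38 * adj**2)
    elif adj > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * adj - 59.938 * adj**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * adj - 223.73 * adj**2)
    return min(max(p, 0.0), 1.0)


def ad_normality(sample: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling normality test: returns ``(A2, p)``.

    Mean and variance are estimated from the sample (composite null); the
    p-value uses the Stephens approximation in :func:`_ad_p_value`.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("Anderson-Darling test needs at least 3 observations")
    z = (x - x.mean()) / x.std(ddof=1)
    log_cdf = stats.norm.logcdf(z)
    log_sf = stats.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.mean((2 * i - 1) * (log_cdf + log_sf[::-1])))
    return a2, _ad_p_value(a2, n)


def _classify(p: float) -> str:
    if p <= HETEROGENEOUS_P:
        return KLASS_HETEROGENEOUS
    if p <= BORDERLINE_P:
        return KLASS_BORDERLINE
    return KLASS_NORMAL


def anderson_darling_heterogeneity(table: ResidueFrequencyTable) -> HeterogeneityReport:
    """Classify every span position as heterogeneous / borderline / normal.

    At each position the tested sample is the vector of relative frequencies
    of the 20 standard residues ('X' counts excluded).  A position whose
    counts sit entirely in one residue is flagged degenerate and reported at
    the smallest p the approximation attains for its statistic.
    """
    if table.n_records < 20:
        warnings.warn(
            f"only {table.n_records} records; heterogeneity p-values are unstable "
            "below ~20 records",
            stacklevel=2,
        )
    freqs = table.relative_frequencies(include_placeholder=False)
    out = []
    for label, row in freqs.iterrows():
        vec = row.to_numpy(dtype=float)
        if float(np.std(vec)) == 0.0:
            # exactly uniform usage: constant sample, test undefined
            out.append(
                PositionHeterogeneity(
                    label=str(label), ad_statistic=0.0, p_value=1.0,
                    klass=KLASS_NORMAL, degenerate=True,
                )
            )
            continue
        degenerate = bool(np.max(vec) == 1.0)
        a2, p = ad_normality(vec)
        out.append(
            PositionHeterogeneity(
                label=str(label), ad_statistic=a2, p_value=p,
                klass=_classify(p), degenerate=degenerate,
            )
        )
    return HeterogeneityReport(positions=tuple(out))


def select_specific_positions(
    report: HeterogeneityReport, threshold: float = HETEROGENEOUS_P
) -> list[str]:
    """Subsite labels with p <= threshold, in N-to-C order."""
    if not report.positions:
        raise ValueError("empty heterogeneity report")
    return [p.label for p in report.positions if p.p_value <= threshold]


def write_heterogeneity_report(report: HeterogeneityReport, path: str | Path) -> None:
    """TSV writer mirroring the three-level circle encoding of the figures."""
    report.as_frame().to_csv(Path(path), sep="\t", index=False)
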