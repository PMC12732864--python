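"""Cleavage-site windows, Schechter-Berger subsite indexing, substitution matrices.

A cleavage window is a fixed-length residue string centered on the scissile
bond: positions P_W ... P1 (N-terminal side) followed by P1' ... P_W'
(C-terminal side), so the bond lies between window indices W-1 and W
(0-based).  Positions that fall beyond the termini of the parent protein are
padded with the placeholder residue ``'X'``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Align import substitution_matrices

#: The 20 standard amino acids in NCBI substitution-matrix order.
AA20 = "ARNDCQEGHILKMFPSTWYV"

#: Placeholder for window positions beyond the parent protein's termini.
PLACEHOLDER = "X"

#: Full residue alphabet accepted in cleavage windows.
ALPHABET = AA20 + PLACEHOLDER

DEFAULT_WINDOW_HALF_WIDTH = 15

_TSV_COLUMNS = ("enzyme", "protein_id", "p1_index", "window")


class CleavageTableError(ValueError):
    """Malformed cleavage table or record."""


@dataclass(frozen=True)
class CleavageRecord:
    """One observed proteolytic cleavage event.

    Parameters
    ----------
    enzyme : str
        Label of the protease that produced the cleavage (e.g. ``"mCatB"``).
    protein_id : str
        Identifier of the parent protein.
    p1_index : int
        1-based index of the P1 residue in the parent protein sequence.
    window : str
        Residue string of length ``2*W`` spanning P_W..P1|P1'..P_W'.
    """

    enzyme: str
    protein_id: str
    p1_index: int
    window: str

    def __post_init__(self) -> None:
        if not self.enzyme:
            raise CleavageTableError("enzyme label must be nonempty")
        if self.p1_index < 1:
            raise CleavageTableError(
                f"p1_index must be a positive 1-based index, got {self.p1_index}"
            )
        if len(self.window) % 2 != 0 or not self.window:
            raise CleavageTableError(
                f"window length must be even and positive, got {len(self.window)} "
                f"({self.protein_id!r})"
            )
        bad = set(self.window) - set(ALPHABET)
        if bad:
            raise CleavageTableError(
                f"illegal residue(s) {sorted(bad)} in window of record "
                f"{self.protein_id!r}"
            )

    @property
    def half_width(self) -> int:
        """W: number of positions on each side of the scissile bond."""
        return len(self.window) // 2


_LABEL_RE = re.compile(r"^P(\d+)(['′p]?)$")


def parse_subsite_label(label: str) -> tuple[int, bool]:
    """Parse a subsite label such as ``P3`` or ``P4'`` (also ``P4p``/``P4′``).

    Returns ``(k, primed)`` where ``k >= 1``.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unrecognized subsite label {label!r}")
    k = int(m.group(1))
    if k < 1:
        raise ValueError(f"subsite number must be >= 1 in {label!r}")
    return k, bool(m.group(2))


def format_subsite_label(k: int, primed: bool) -> str:
    return f"P{k}'" if primed else f"P{k}"


def subsite_to_window_index(k: int, primed: bool, half_width: int) -> int:
    """0-based window index of subsite Pk (or Pk') for the given half width W.

    Pk maps to W-k; Pk' maps to W+k-1, so the scissile bond sits between
    indices W-1 (P1) and W (P1').
    """
    idx = half_width + k - 1 if primed else half_width - k
    if not 0 <= idx < 2 * half_width:
        raise ValueError(
            f"subsite {format_subsite_label(k, primed)} outside a window of "
            f"half width {half_width}"
        )
    return idx


@dataclass(frozen=True)
class SubsiteSpan:
    """A contiguous run of subsites, e.g. P3-P4' (always read N-to-C)."""

    start_label: str
    end_label: str

    def __post_init__(self) -> None:
        ks, ps = parse_subsite_label(self.start_label)
        ke, pe = parse_subsite_label(self.end_label)
        # N-to-C order: non-primed subsites descend toward P1, primed ascend.
        start_rank = ks if ps else -ks
        end_rank = ke if pe else -ke
        if start_rank >= end_rank and (ks, ps) != (ke, pe):
            raise ValueError(
                f"span {self.start_label}-{self.end_label} is not in N-to-C order"
            )

    @classmethod
    def from_string(cls, text: str) -> "SubsiteSpan":
        """Parse ``"P3:P4p"`` / ``"P3-P4'"`` style span strings."""
        parts = re.split(r"[:\-]", text.strip())
        if len(parts) != 2:
            raise ValueError(f"cannot parse span {text!r}; expected START:END")
        return cls(parts[0], parts[1])

    def indices(self, half_width: int) -> list[int]:
        """Resolved 0-based window indices, N-terminal to C-terminal."""
        ks, ps = parse_subsite_label(self.start_label)
        ke, pe = parse_subsite_label(self.end_label)
        i0 = subsite_to_window_index(ks, ps, half_width)
        i1 = subsite_to_window_index(ke, pe, half_width)
        return list(range(i0, i1 + 1))

    def labels(self, half_width: int) -> list[str]:
        """Subsite labels for each resolved position, N-to-C."""
        out = []
        for idx in self.indices(half_width):
            if idx < half_width:
                out.append(format_subsite_label(half_width - idx, False))
            else:
                out.append(format_subsite_label(idx - half_width + 1, True))
        return out

    def length(self, half_width: int) -> int:
        return len(self.indices(half_width))

    def __str__(self) -> str:
        return f"{self.start_label}-{self.end_label}"


def extract_subsites(record: CleavageRecord, span: SubsiteSpan) -> str:
    """Slice the record's window down to the span's subsites (N-to-C order)."""
    idx = span.indices(record.half_width)
    return "".join(record.window[i] for i in idx)


# ---------------------------------------------------------------------------
# Cleavage table I/O (TSV, '#' comments, UTF-8)
# ---------------------------------------------------------------------------

def read_cleavage_table(
    path: str | Path,
    window_width: int = DEFAULT_WINDOW_HALF_WIDTH,
) -> list[CleavageRecord]:
    """Read a cleavage-site TSV into a list of :class:`CleavageRecord`.

    The file must carry a header line naming the columns
    ``enzyme  protein_id  p1_index  window`` (tab-separated).  Lines starting
    with ``'#'`` and blank lines are ignored.  ``window_width`` is the half
    width W; every window must have length exactly ``2*W``.

    Raises
    ------
    CleavageTableError
        On a malformed row (message names the 1-based line number) or a
        window of wrong length / illegal characters (message names the
        record).
    """
    path = Path(path)
    records: list[CleavageRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _TSV_COLUMNS if c not in header]
                if missing:
                    raise CleavageTableError(
                        f"{path}: header line {lineno} missing column(s) {missing}"
                    )
                col = {name: header.index(name) for name in _TSV_COLUMNS}
                continue
            if len(fields) != len(header):
                raise CleavageTableError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            try:
                p1 = int(fields[col["p1_index"]])
            except ValueError:
                raise CleavageTableError(
                    f"{path}: line {lineno}: p1_index "
                    f"{fields[col['p1_index']]!r} is not an integer"
                ) from None
            window = fields[col["window"]].strip().upper()
            if len(window) != 2 * window_width:
                raise CleavageTableError(
                    f"{path}: line {lineno}: window of record "
                    f"{fields[col['protein_id']]!r} has length {len(window)}, "
                    f"expected {2 * window_width}"
                )
            try:
                rec = CleavageRecord(
                    enzyme=fields[col["enzyme"]].strip(),
                    protein_id=fields[col["protein_id"]].strip(),
                    p1_index=p1,
                    window=window,
                )
            except CleavageTableError as err:
                raise CleavageTableError(f"{path}: line {lineno}: {err}") from None
            records.append(rec)
    if header is None:
        raise CleavageTableError(f"{path}: empty file (no header)")
    return records


def write_cleavage_table(records: Iterable[CleavageRecord], path: str | Path) -> int:
    """Write records as the standard cleavage TSV; returns the row count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                f"{rec.enzyme}\t{rec.protein_id}\t{rec.p1_index}\t{rec.window}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

class SubstitutionMatrixError(ValueError):
    """Invalid substitution-matrix file."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair score table (e.g. BLOSUM62).

    ``alphabet`` is the ordered symbol set of the source matrix; ``scores``
    maps every ordered pair of symbols to its score.  Symmetry is enforced
    at construction.
    """

    alphabet: str
    scores: Mapping[tuple[str, str], float] = field(repr=False)

    def __post_init__(self) -> None:
        bad_pairs = []
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise SubstitutionMatrixError(f"missing score for pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    bad_pairs.append((a, b))
        if bad_pairs:
            raise SubstitutionMatrixError(
                f"asymmetric entries for pair(s): {sorted(set(map(frozenset, bad_pairs)), key=str)}"
            )

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(f"residue pair ({a},{b}) not in matrix alphabet") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.alphabet


def _from_biopython_array(arr) -> SubstitutionMatrix:
    alphabet = "".join(arr.alphabet)
    scores = {
        (a, b): float(arr[a, b]) for a in alphabet for b in alphabet
    }
    return SubstitutionMatrix(alphabet=alphabet, scores=scores)


def load_substitution_matrix(path: str | Path) -> SubstitutionMatrix:
    """Load an NCBI-format substitution matrix file (as distributed with BLAST).

    The format is a header row of symbols followed by one scored row per
    symbol; ``'#'`` lines are comments.  Symmetry and completeness are
    validated; an asymmetric or incomplete file raises
    :class:`SubstitutionMatrixError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    # Validate row completeness ourselves: every header symbol needs a row.
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise SubstitutionMatrixError(f"{path}: no matrix content")
    header_syms = lines[0].split()
    row_syms = [ln.split()[0] for ln in lines[1:]]
    missing = [s for s in header_syms if s not in row_syms]
    if missing:
        raise SubstitutionMatrixError(f"{path}: missing row(s) for symbol(s) {missing}")
    try:
        arr = substitution_matrices.read(io.StringIO(text))
    except Exception as err:
        raise SubstitutionMatrixError(f"{path}: cannot parse NCBI matrix: {err}") from None
    return _from_biopython_array(arr)


def default_blosum62() -> SubstitutionMatrix:
    """The canonical BLOSUM62 matrix (half-bit log-odds scores)."""
    return _from_biopython_array(substitution_matrices.load("BLOSUM62"))
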