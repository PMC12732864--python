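import numpy as np
import pytest

from cleavekit import (
    AA20,
    CleavageRecord,
    PositionSpecificModel,
    SubsiteSpan,
    default_blosum62,
)

AA_INDEX = {aa: j for j, aa in enumerate(AA20)}


@pytest.fixture(scope="session")
def blosum62():
    return default_blosum62()


@pytest.fixture(scope="session")
def span_p3_p4p():
    return SubsiteSpan("P3", "P4'")


@pytest.fixture
def simple_record():
    # W=15 window: P15..P1 = "AAAAAAAAAAAAAGK", P1'..P15' = "LVFAAAAAAAAAAAA"
    return CleavageRecord(
        enzyme="enzA",
        protein_id="prot1",
        p1_index=40,
        window="AAAAAAAAAAAAAGK" + "LVFAAAAAAAAAAAA",
    )


def fixed_span_model(span_residues: str, width: int = 30) -> PositionSpecificModel:
    """Uniform background with the P3-P4' span (window indices 12..18 for
    W=15) pinned to the given residues — a deterministic planted motif."""
    assert len(span_residues) == 7
    p = np.full((width, 20), 1 / 20)
    start = width // 2 - 3
    for i, aa in enumerate(span_residues):
        p[start + i] = np.eye(20)[AA_INDEX[aa]]
    return PositionSpecificModel(p)
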