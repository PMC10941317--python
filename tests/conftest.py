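import random

import pytest

from oligorepair.constraints import ConstraintSet

# Worked repair examples, constructed to match their published descriptions.
#
# FIG2_SEQ: 32 nt, one maximal homopolymer run of 5 (positions 5-9), GC
# content within [0.40, 0.60] globally and in every 15-base window, against a
# fixed-length-30 constraint: exactly one homopolymer violation and one
# length violation.
FIG2_SEQ = "CGTCG" + "AAAAA" + "CTGCT" + "GTCAGTCAGTCAGTC" + "AG"

# FIG3_SEQ: 30 nt with a C-run of 4 crossing the boundary between the two
# 15-base GC windows (positions 13-16); both windows sit exactly at the lower
# GC bound (6/15 = 0.40), so substituting any run base with A or T pushes
# that window below the bound — only a G substitution yields a valid
# sequence.
FIG3_SEQ = "ATGCATGCATAAT" + "CCCC" + "ATGATGCATGATA"


@pytest.fixture
def cs30() -> ConstraintSet:
    """The worked-example constraint set: GC [0.40, 0.60] overall and per
    15-base window, homopolymer max 3, fixed length 30."""
    return ConstraintSet(target_length=30)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


def random_seq(rnd: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rnd.choice(alphabet) for _ in range(length))
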