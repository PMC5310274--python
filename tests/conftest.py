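import numpy as np
import pytest
from hypothesis import settings

from rnnbias.genome_io import GeneModel, Genome

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def toy_genome():
    """Two small contigs: a patterned one for hand-checked windows and a
    seeded random 400 bp one."""
    rng = np.random.default_rng(7)
    rand = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    return Genome({"pat": "AACCGGTTAACCGGTTAACCGGTT", "c1": rand})


@pytest.fixture
def toy_genes():
    return [
        GeneModel("g1", "c1", "+", [(50, 150), (200, 280)]),
        GeneModel("g2", "c1", "+", [(300, 380)]),
    ]


@pytest.fixture
def sam_text():
    """Minimal SAM with forward, reverse, duplicate, multi-mapped and
    low-quality records."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        "@SQ\tSN:chr1\tLN:2000",
        # forward primary, unique: 5' end = 999 (0-based)
        "r1\t0\tchr1\t1000\t255\t100M\t*\t0\t0\t*\t*",
        # reverse primary: 5' end = rightmost aligned base = 1098
        "r2\t16\tchr1\t1000\t255\t100M\t*\t0\t0\t*\t*",
        # duplicate of r1's site
        "r3\t0\tchr1\t1000\t255\t100M\t*\t0\t0\t*\t*",
        # multi-mapped by NH tag -> dropped
        "r4\t0\tchr1\t1500\t255\t100M\t*\t0\t0\t*\t*\tNH:i:2",
        # low mapq, no NH tag -> dropped at min_mapq=255
        "r5\t0\tchr1\t1600\t10\t100M\t*\t0\t0\t*\t*",
        # secondary -> dropped
        "r6\t256\tchr1\t1700\t255\t100M\t*\t0\t0\t*\t*",
        # reverse with deletion and splice: reference span 30+5+100+20 = 155
        "r7\t16\tchr1\t101\t255\t30M5D100N20M\t*\t0\t0\t*\t*",
    ]
    return "\n".join(lines) + "\n"
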