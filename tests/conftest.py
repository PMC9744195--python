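import numpy as np
import pytest

from amplimut.example import example_spec, example_spectrum
from amplimut.model import AmpliconSpec, locate_target, revcomp

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def spec():
    return example_spec()


@pytest.fixture
def target(spec):
    return spec.targets[0]


@pytest.fixture
def spectrum():
    return example_spectrum()


def _dual_spec() -> AmpliconSpec:
    """A 218-bp amplicon with two plus-strand guides whose cut sites lie
    83 bp apart (cut1=39, cut2=122)."""
    rng = np.random.default_rng(911)
    proto1 = "GATTACCGGAAGTCCATGCA"
    proto2 = "CCTGAATTCGGATCAAGTGC"
    while True:
        fwd = random_dna(rng, 22)
        gap = random_dna(rng, 60)  # between pam1 end and proto2 start
        tail = random_dna(rng, 68)
        rev = random_dna(rng, 22)
        ref = fwd + proto1 + "TGG" + gap + proto2 + "AGG" + tail + rev
        ok = (ref.count(proto1) == 1 and revcomp(proto1) not in ref
              and ref.count(proto2) == 1 and revcomp(proto2) not in ref)
        if ok:
            break
    spec = AmpliconSpec(name="dual", ref_seq=ref, fwd_primer=(0, 22),
                        rev_primer=(len(ref) - 22, len(ref)), targets=[])
    spec.targets.append(locate_target(spec, proto1, "NGG", name="t1"))
    spec.targets.append(locate_target(spec, proto2, "NGG", name="t2"))
    assert spec.targets[1].cut_site - spec.targets[0].cut_site == 83
    return spec


@pytest.fixture
def dual_spec():
    return _dual_spec()
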