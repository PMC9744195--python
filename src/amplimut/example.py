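"""A small worked example: a 178-bp amplicon with one NGG guide target.

Used by the documentation, the test suite and the acceptance script as a
fully specified, reproducible stand-in for a real amplicon (synthetic
sequence, fixed once).  The protospacer cut site sits at reference position
79; the 22-nt primer regions at both ends are excluded from reporting.  The
default spectrum mirrors a typical mutagenesis + base-editing outcome mix:
a 2-bp deletion at -2..-1, a 1-bp T insertion at -1, a C->T edit at -13,
and half of the molecules unedited.
"""

from __future__ import annotations

from .model import AmpliconSpec, GuideTarget, locate_target
from .simulate import EventSpectrum, EventTemplate, unedited

EXAMPLE_REF = (
    "GAAGAGTGTCACAAGTCATCTTCTGTGACTCCGGTTTTCGCAACATCCGTTACGGTACTCTT"
    "GTCACTGCATCGATTGAAGCTGG"
    "TGATCCCAGTGAGATGATCACATTTACGTCAAGCTCCCATGGGGGGCGCCCGGATTTGCTTTAGAGCCACA"
    "TAATCCCTCGAGAAGTATTTCG"
)
EXAMPLE_PROTOSPACER = "GTCACTGCATCGATTGAAGC"
EXAMPLE_FWD_PRIMER = (0, 22)
EXAMPLE_REV_PRIMER = (156, 178)


def example_spec() -> AmpliconSpec:
    spec = AmpliconSpec(name="example", ref_seq=EXAMPLE_REF,
                        fwd_primer=EXAMPLE_FWD_PRIMER,
                        rev_primer=EXAMPLE_REV_PRIMER, targets=[])
    spec.targets.append(locate_target(spec, EXAMPLE_PROTOSPACER, "NGG",
                                      name="g1"))
    return spec


def example_target(spec: AmpliconSpec | None = None) -> GuideTarget:
    return (spec or example_spec()).targets[0]


def example_spectrum() -> EventSpectrum:
    """Deletion 25%, insertion 10%, C->T edit 15%, unedited 50%."""
    return EventSpectrum([
        (EventTemplate(id="del_-2_-1", kind="deletion",
                       start_label=-2, end_label=-1), 0.25),
        (EventTemplate(id="ins_-1_T", kind="insertion",
                       anchor_label=-1, bases="T"), 0.10),
        (EventTemplate(id="sub_-13_C_T", kind="substitution",
                       position_label=-13, alt="T"), 0.15),
        (unedited(), 0.50),
    ])
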