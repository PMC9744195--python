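"""Amplicon, primer and guide-target model.

Defines the cut-site-relative coordinate system used by the whole pipeline.
Reference coordinates are 0-based half-open; positions reported to the user
are signed labels relative to the Cas9 cleavage site (between protospacer
positions 17 and 18, i.e. 3 nt upstream of the PAM): the first base left of
the cut is -1, the first base right of it +1, and no position 0 exists.  For
a guide on the minus strand the labels follow the guide's own 5'->3'
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: distance of the blunt cut from the PAM-proximal protospacer end
CUT_OFFSET = 3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def pam_matches(pam: str, pattern: str) -> bool:
    if len(pam) != len(pattern):
        return False
    return all(b in _IUPAC.get(p.upper(), "") for b, p in zip(pam, pattern))


class AmpliconError(ValueError):
    """Raised for invalid amplicon/guide definitions."""


@dataclass(frozen=True)
class GuideTarget:
    """A resolved protospacer on the amplicon reference.

    ``proto_start`` is the 0-based reference index of the protospacer's
    leftmost base on the plus strand (for a minus-strand guide this is the
    3' end of the protospacer in guide orientation).  ``cut_site`` is a
    between-bases coordinate: the integer k means "between ref[k-1] and
    ref[k]".
    """

    name: str
    protospacer: str
    strand: str
    pam: str
    proto_start: int
    cut_site: int

    def __post_init__(self):
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise AmpliconError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got "
                f"{len(self.protospacer)}")
        if len(self.pam) != PAM_LEN:
            raise AmpliconError(f"PAM must be {PAM_LEN} nt, got {len(self.pam)}")
        if self.strand not in "+-":
            raise AmpliconError(f"strand must be + or -, got {self.strand!r}")
        expected = (self.proto_start + PROTOSPACER_LEN - CUT_OFFSET
                    if self.strand == "+" else self.proto_start + CUT_OFFSET)
        if self.cut_site != expected:
            raise AmpliconError(
                f"cut_site {self.cut_site} inconsistent with proto_start "
                f"{self.proto_start} on strand {self.strand} (expected {expected})")

    @property
    def window(self) -> range:
        """The 20 reference indices covered by the protospacer."""
        return range(self.proto_start, self.proto_start + PROTOSPACER_LEN)


@dataclass
class AmpliconSpec:
    """Reference amplicon with primer intervals and guide targets.

    Primer intervals are 0-based half-open on the reference and are excluded
    from all per-position mutation reporting.
    """

    name: str
    ref_seq: str
    fwd_primer: tuple[int, int]
    rev_primer: tuple[int, int]
    targets: list[GuideTarget] = field(default_factory=list)

    def __post_init__(self):
        self.ref_seq = self.ref_seq.upper()
        n = len(self.ref_seq)
        if n < 50:
            raise AmpliconError(f"reference too short ({n} < 50 nt)")
        if set(self.ref_seq) - set("ACGT"):
            raise AmpliconError("reference must contain only A/C/G/T")
        for label, (s, e) in (("fwd_primer", self.fwd_primer),
                              ("rev_primer", self.rev_primer)):
            if not (0 <= s < e <= n):
                raise AmpliconError(f"{label} interval ({s},{e}) outside [0,{n})")
        f, r = sorted([self.fwd_primer, self.rev_primer])
        if f[1] > r[0]:
            raise AmpliconError("primer intervals overlap")
        for t in self.targets:
            self._check_target(t)

    def _check_target(self, t: GuideTarget) -> None:
        n = len(self.ref_seq)
        if t.strand == "+":
            lo, hi = t.proto_start, t.proto_start + PROTOSPACER_LEN + PAM_LEN
            footprint = self.ref_seq[t.proto_start:t.proto_start + PROTOSPACER_LEN]
            pam = self.ref_seq[t.proto_start + PROTOSPACER_LEN:hi]
            if footprint != t.protospacer or pam != t.pam:
                raise AmpliconError(
                    f"target {t.name}: protospacer/PAM do not match the "
                    f"reference at +{t.proto_start}")
        else:
            lo, hi = t.proto_start - PAM_LEN, t.proto_start + PROTOSPACER_LEN
            footprint = self.ref_seq[t.proto_start:hi]
            pam = self.ref_seq[lo:t.proto_start]
            if revcomp(footprint) != t.protospacer or revcomp(pam) != t.pam:
                raise AmpliconError(
                    f"target {t.name}: protospacer/PAM do not match the "
                    f"reference at -{t.proto_start}")
        if lo < 0 or hi > n:
            raise AmpliconError(f"target {t.name} extends outside the amplicon")
        for s, e in (self.fwd_primer, self.rev_primer):
            if lo < e and s < hi:
                raise AmpliconError(
                    f"target {t.name} overlaps a primer interval ({s},{e})")

    @property
    def nonprimer_positions(self) -> list[int]:
        """Reference indices outside both primer intervals, ascending."""
        excluded = set(range(*self.fwd_primer)) | set(range(*self.rev_primer))
        return [i for i in range(len(self.ref_seq)) if i not in excluded]


def locate_target(spec: AmpliconSpec, protospacer: str,
                  pam_pattern: str = "NGG", name: str = "") -> GuideTarget:
    """Resolve a user-supplied guide against the amplicon reference.

    The protospacer must occur exactly once on either strand with an
    immediately 3' PAM matching ``pam_pattern`` (IUPAC).
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise AmpliconError(
            f"protospacer must be {PROTOSPACER_LEN} nt, got {len(protospacer)}")
    ref = spec.ref_seq
    hits: list[tuple[int, str, str]] = []
    # plus strand: protospacer then PAM
    start = 0
    while True:
        i = ref.find(protospacer, start)
        if i < 0:
            break
        pam = ref[i + PROTOSPACER_LEN:i + PROTOSPACER_LEN + PAM_LEN]
        if len(pam) == PAM_LEN and pam_matches(pam, pam_pattern):
            hits.append((i, "+", pam))
        start = i + 1
    # minus strand: reverse complement of the protospacer, PAM 5' of it on +
    rc = revcomp(protospacer)
    start = 0
    while True:
        i = ref.find(rc, start)
        if i < 0:
            break
        pam = revcomp(ref[i - PAM_LEN:i]) if i >= PAM_LEN else ""
        if len(pam) == PAM_LEN and pam_matches(pam, pam_pattern):
            hits.append((i, "-", pam))
        start = i + 1
    if not hits:
        raise AmpliconError(
            f"protospacer {protospacer} not found in amplicon {spec.name!r} "
            f"with PAM {pam_pattern}")
    if len(hits) > 1:
        pos = ", ".join(f"{s}{i}" for i, s, _ in hits)
        raise AmpliconError(
            f"protospacer {protospacer} is ambiguous in amplicon "
            f"{spec.name!r}: hits at {pos}")
    i, strand, pam = hits[0]
    cut = (i + PROTOSPACER_LEN - CUT_OFFSET) if strand == "+" else i + CUT_OFFSET
    return GuideTarget(name=name or protospacer, protospacer=protospacer,
                       strand=strand, pam=pam, proto_start=i, cut_site=cut)


def cut_relative_position(target: GuideTarget, ref_index: int) -> int:
    """Signed cut-relative label of a reference index (no position 0).

    On the plus strand the base just left of the cut is -1 and the base just
    right of it +1; on the minus strand the same convention applies in guide
    orientation.
    """
    cut = target.cut_site
    if target.strand == "+":
        return ref_index - cut if ref_index < cut else ref_index - cut + 1
    return cut - ref_index if ref_index < cut else cut - ref_index - 1


def ref_index_of(target: GuideTarget, label: int) -> int:
    """Inverse of :func:`cut_relative_position`."""
    if label == 0:
        raise ValueError("cut-relative labels have no position 0")
    cut = target.cut_site
    if target.strand == "+":
        return cut + label if label < 0 else cut + label - 1
    return cut - label - 1 if label < 0 else cut - label


def target_window(target: GuideTarget) -> set[int]:
    """The 20 protospacer-covered reference indices (labels -17..-1, +1..+3)."""
    return set(target.window)
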