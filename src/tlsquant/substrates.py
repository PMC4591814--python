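"""Primer-template substrates for translesion-synthesis extension assays.

A substrate is a 5'-labelled primer annealed to the 3' end of a longer
template, optionally with a downstream oligo annealed to the template's 5'
end so that the advancing primer meets a nick. Extension products are
indexed in N-coordinates: N0 is the unextended primer (length ``n0`` nt)
and Ni the product extended by i nucleotides, up to NK = full template
length. Template bases are counted 1..L from the *3'* end, the order in
which the polymerase copies them, so the base copied at step Ni sits at
template position ``n0 + i``.

All sequences are stored 5'->3'. The constructor accepts a template in
3'->5' orientation with an explicit flag, because bench protocols usually
print it that way; the flag exists to prevent silent reverse-complement
bugs.

A (5S)-thymine glycol lesion (``LesionKind.TG_5S``) is modelled as an
annotation on a T base and pairs as T for annealing purposes: the
undamaged control is the same sequence with a plain T at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

from .errors import AnnealingError, SequenceError

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Watson-Crick dNTP inserted opposite each template base (Tg templates as T).
DNTP_FOR_TEMPLATE_BASE = {"A": "dTTP", "C": "dGTP", "G": "dCTP", "T": "dATP"}


class LesionKind(str, Enum):
    NONE = "NONE"
    #: (5S)-thymine glycol, an oxidised thymine.
    TG_5S = "TG_5S"


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of a 5'->3' sequence (result 5'->3').

    Raises
    ------
    SequenceError
        If the sequence is empty or contains characters outside ACGT.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    bad = set(sequence) - VALID_BASES
    if bad:
        raise SequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Oligo:
    """A single oligonucleotide, stored 5'->3'.

    ``lesions`` maps 1-based positions along the stored (5'->3') sequence to
    a :class:`LesionKind`; TG_5S may only annotate a T.
    """

    label: str = field(compare=False)
    sequence: str = ""
    lesions: Mapping[int, LesionKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"oligo {self.label!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise SequenceError(
                f"oligo {self.label!r}: non-ACGT characters {sorted(bad)}"
            )
        lesions = {int(p): LesionKind(k) for p, k in dict(self.lesions).items()}
        for pos, kind in lesions.items():
            if not 1 <= pos <= len(self.sequence):
                raise SequenceError(
                    f"oligo {self.label!r}: lesion position {pos} outside "
                    f"1..{len(self.sequence)}"
                )
            if kind is LesionKind.TG_5S and self.sequence[pos - 1] != "T":
                raise SequenceError(
                    f"oligo {self.label!r}: TG_5S at position {pos} must "
                    f"annotate a T, found {self.sequence[pos - 1]}"
                )
        object.__setattr__(self, "lesions", lesions)

    def __len__(self) -> int:
        return len(self.sequence)

    def lesion_at(self, pos: int) -> LesionKind:
        return self.lesions.get(pos, LesionKind.NONE)


@dataclass(frozen=True)
class Substrate:
    """An annealed extension substrate with its N-coordinate map.

    ``n0`` is the primer length (product length of the unextended band N0);
    ``k`` the number of extendable positions (template length - n0);
    ``lesion_n``/``nick_n`` are N-indices in 1..k when present.
    """

    name: str
    primer: Oligo
    template: Oligo
    downstream: Optional[Oligo]
    n0: int
    k: int
    lesion_n: Optional[int]
    nick_n: Optional[int]

    @property
    def full_length(self) -> int:
        """Length in nt of the full-length product NK (= template length)."""
        return self.n0 + self.k

    def product_length(self, n: int) -> int:
        """Product length in nt of the band at N-index ``n``."""
        if not 0 <= n <= self.k:
            raise ValueError(f"N index {n} outside 0..{self.k}")
        return self.n0 + n

    def template_position_5to3(self, n: int) -> int:
        """1-based index, in the stored 5'->3' template, of the base copied
        at step Nn (template base ``n0 + n`` counted from the 3' end)."""
        return len(self.template) - (self.n0 + n) + 1

    def template_base(self, n: int) -> str:
        return self.template.sequence[self.template_position_5to3(n) - 1]

    def lesion_kind_at(self, n: int) -> LesionKind:
        return self.template.lesion_at(self.template_position_5to3(n))


@dataclass(frozen=True)
class PositionInfo:
    """One entry of the N-coordinate map: the template base copied at step
    Nn, its Watson-Crick dNTP, any lesion, and whether the position lies at
    or beyond the nick of a downstream oligo."""

    n: int
    template_base: str
    dntp: str
    lesion: LesionKind
    at_nick: bool

    @property
    def display_base(self) -> str:
        return "Tg" if self.lesion is LesionKind.TG_5S else self.template_base


def _as_oligo(obj: Oligo | str, label: str) -> Oligo:
    if isinstance(obj, Oligo):
        return obj
    return Oligo(label=label, sequence=obj)


def assemble_substrate(
    primer: Oligo | str,
    template: Oligo | str,
    downstream: Oligo | str | None = None,
    *,
    template_orientation: str = "5to3",
    name: str = "substrate",
) -> Substrate:
    """Validate annealing and build a :class:`Substrate`.

    ``template_orientation`` is ``"5to3"`` or ``"3to5"``; in the latter case
    the template sequence (and its lesion positions) are given as printed
    3'->5' and are flipped internally.

    Raises
    ------
    AnnealingError
        If the primer is not the exact reverse complement of the template's
        3'-terminal bases, or the downstream oligo is not complementary to a
        5'-terminal block of the template (TG_5S pairs as T).
    """
    primer = _as_oligo(primer, "primer")
    template = _as_oligo(template, "template")
    if downstream is not None:
        downstream = _as_oligo(downstream, "downstream")

    if template_orientation == "3to5":
        length = len(template)
        template = Oligo(
            label=template.label,
            sequence=template.sequence[::-1],
            lesions={length - p + 1: k for p, k in template.lesions.items()},
        )
    elif template_orientation != "5to3":
        raise ValueError(f"unknown template orientation {template_orientation!r}")

    n0 = len(primer)
    length = len(template)
    if length <= n0:
        raise AnnealingError(
            f"{name}: template ({length} nt) must be longer than primer ({n0} nt)"
        )
    k = length - n0

    if primer.sequence != reverse_complement(template.sequence[-n0:]):
        raise AnnealingError(
            f"{name}: primer is not the reverse complement of the template's "
            f"3'-terminal {n0} bases"
        )

    nick_n = None
    if downstream is not None:
        d = len(downstream)
        if d >= length - n0 + 1:
            raise AnnealingError(
                f"{name}: downstream oligo ({d} nt) overlaps the primer region"
            )
        if downstream.sequence != reverse_complement(template.sequence[:d]):
            raise AnnealingError(
                f"{name}: downstream oligo is not the reverse complement of the "
                f"template's 5'-terminal {d} bases"
            )
        nick_n = (length - n0 - d) + 1

    lesion_n = None
    lesion_positions = sorted(template.lesions)
    if len(lesion_positions) > 1:
        raise AnnealingError(f"{name}: more than one template lesion is unsupported")
    if lesion_positions:
        pos5 = lesion_positions[0]
        pos_from_3 = length - pos5 + 1
        n = pos_from_3 - n0
        if not 1 <= n <= k:
            raise AnnealingError(
                f"{name}: lesion at template position {pos_from_3} (from 3' end) "
                f"lies outside the extendable region N1..N{k}"
            )
        lesion_n = n

    return Substrate(
        name=name,
        primer=primer,
        template=template,
        downstream=downstream,
        n0=n0,
        k=k,
        lesion_n=lesion_n,
        nick_n=nick_n,
    )


def position_map(substrate: Substrate) -> list[PositionInfo]:
    """Ordered N-coordinate map (N1..NK) of template base, correct dNTP,
    lesion annotation and nick flag for each insertion step."""
    out = []
    for n in range(1, substrate.k + 1):
        base = substrate.template_base(n)
        at_nick = substrate.nick_n is not None and n >= substrate.nick_n
        out.append(
            PositionInfo(
                n=n,
                template_base=base,
                dntp=DNTP_FOR_TEMPLATE_BASE[base],
                lesion=substrate.lesion_kind_at(n),
                at_nick=at_nick,
            )
        )
    return out


# The assay's oligo set: 14/15/16-mer primers annealed to a 30-mer template
# whose first variable base X (template position 17 from the 3' end) is T, G
# or a (5S)-thymine glycol; a 14-mer downstream oligo converts the X=T
# substrate into a nicked one.
PRIMER_14 = "CACTGACTGTATGA"
PRIMER_15 = "CACTGACTGTATGAT"
PRIMER_16 = "CACTGACTGTATGATG"
TEMPLATE_3TO5_WITH_X = "GTGACTGACATACTACXTCTACGACTGCTC"
DOWNSTREAM_14 = "AAGATGCTGACGAG"
_X_POS_3TO5 = TEMPLATE_3TO5_WITH_X.index("X") + 1  # printed-string position of X


def _template_oligo(x: str) -> Oligo:
    """Template (3'->5' as printed) with the variable base X filled in.

    ``x`` is "T", "G" or "Tg"; "Tg" places a T carrying a TG_5S annotation.
    """
    base = "T" if x == "Tg" else x
    lesions = {_X_POS_3TO5: LesionKind.TG_5S} if x == "Tg" else {}
    seq = TEMPLATE_3TO5_WITH_X.replace("X", base)
    return Oligo(label=f"template-X={x}", sequence=seq, lesions=lesions)


def standard_substrates() -> dict[str, Substrate]:
    """The eight assay substrates, named ``<primer length>/<X base>``.

    14/T, 14/Tg, 15/T, 15/Tg, 16/T, 16/G, 16/Tg and nicked-16/T (the X=T
    template with the downstream 14-mer annealed flush to the 16-mer
    primer, so the nick is met at the first insertion).
    """
    primers = {"14": PRIMER_14, "15": PRIMER_15, "16": PRIMER_16}
    out: dict[str, Substrate] = {}
    for plen, primer in primers.items():
        xs = ("T", "Tg") if plen != "16" else ("T", "G", "Tg")
        for x in xs:
            name = f"{plen}/{x}"
            out[name] = assemble_substrate(
                Oligo(f"primer-{plen}", primer),
                _template_oligo(x),
                template_orientation="3to5",
                name=name,
            )
    out["nicked-16/T"] = assemble_substrate(
        Oligo("primer-16", PRIMER_16),
        _template_oligo("T"),
        Oligo("downstream-14", DOWNSTREAM_14),
        template_orientation="3to5",
        name="nicked-16/T",
    )
    return out
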