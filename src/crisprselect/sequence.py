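"""Reference-locus model, coordinate conventions and codon-level utilities.

All coordinates are 0-based, half-open internally.  Reports and the CLI
convert to 1-based inclusive for display.  Sequences are plain uppercase
A/C/G/T strings; IUPAC ambiguity codes are rejected on construction so the
designer rules always operate on concrete bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "ReferenceLocus",
    "VariantSpec",
    "ReferenceMismatchError",
    "reverse_complement",
    "apply_edit",
    "translate_coding",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReferenceMismatchError(ValueError):
    """Raised when a variant's reference bases disagree with the locus."""


def _check_sequence(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string.

    Involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    sequence = _check_sequence(sequence)
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceLocus:
    """A genomic locus with a single coding frame.

    Parameters
    ----------
    locus_id:
        Text label, e.g. ``"BRCA2_exon17"``.
    sequence:
        Uppercase nucleotide string (A/C/G/T only).
    coding_segments:
        Ordered ``(start, end, frame_offset)`` intervals in locus
        coordinates (0-based, half-open).  ``frame_offset`` is the number of
        bases of the segment that belong to a codon started upstream of the
        locus; it applies to the 5'-most segment in gene orientation.
    strand_of_gene:
        ``"+"`` or ``"-"`` — orientation of the gene relative to the stored
        sequence.
    """

    locus_id: str
    sequence: str
    coding_segments: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)
    strand_of_gene: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "locus sequence"))
        segs = tuple(tuple(s) for s in self.coding_segments)
        object.__setattr__(self, "coding_segments", segs)
        if self.strand_of_gene not in ("+", "-"):
            raise ValueError("strand_of_gene must be '+' or '-'")
        prev_end = 0
        for start, end, frame in segs:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"coding segment ({start},{end}) out of bounds")
            if start < prev_end:
                raise ValueError("coding segments must be sorted and non-overlapping")
            if frame not in (0, 1, 2):
                raise ValueError("frame_offset must be 0, 1 or 2")
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    def is_coding(self, position: int) -> bool:
        return any(s <= position < e for s, e, _ in self.coding_segments)

    def cds_index(self, position: int) -> int | None:
        """Index of a locus position within the gene-oriented coding sequence.

        Returns None for non-coding positions.  The index counts from the
        5' end of the gene, before the frame_offset is applied.
        """
        offset = 0
        hit = None
        for s, e, _ in self.coding_segments:
            if s <= position < e:
                hit = offset + (position - s)
            offset += e - s
        if hit is None:
            return None
        if self.strand_of_gene == "-":
            return offset - 1 - hit
        return hit

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e, _ in self.coding_segments)


@dataclass(frozen=True)
class VariantSpec:
    """A single edit under test.

    ``position`` is the locus coordinate of the first affected base
    (for a pure insertion, the base before which ``alt_bases`` is inserted).
    ``ref_bases`` is empty for a pure insertion, ``alt_bases`` empty for a
    pure deletion.
    """

    position: int
    ref_bases: str
    alt_bases: str
    label: str = ""
    variant_class: str = "missense"

    _CLASSES = (
        "missense",
        "nonsense",
        "synonymous",
        "splice",
        "inframe_indel",
        "frameshift_indel",
    )

    def __post_init__(self) -> None:
        ref = _check_sequence(self.ref_bases, "ref_bases") if self.ref_bases else ""
        alt = _check_sequence(self.alt_bases, "alt_bases") if self.alt_bases else ""
        object.__setattr__(self, "ref_bases", ref)
        object.__setattr__(self, "alt_bases", alt)
        if ref == alt:
            raise ValueError("ref_bases and alt_bases must differ")
        if self.position < 0:
            raise ValueError("position must be non-negative")
        if self.variant_class not in self._CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def end(self) -> int:
        """Locus coordinate one past the last reference base affected."""
        return self.position + len(self.ref_bases)

    def affected_positions(self) -> tuple[int, ...]:
        """Locus positions whose identity the edit changes.

        For a pure insertion the junction base at ``position`` is reported
        as the affected site.
        """
        if self.ref_bases:
            return tuple(range(self.position, self.end))
        return (self.position,)

    def validate_against(self, locus: ReferenceLocus) -> None:
        found = locus.sequence[self.position : self.end]
        if found != self.ref_bases:
            raise ReferenceMismatchError(
                f"{self.label or 'variant'}: expected {self.ref_bases!r} at "
                f"position {self.position} of {locus.locus_id}, found {found!r}"
            )


def apply_edit(locus: ReferenceLocus, edit: VariantSpec) -> str:
    """Return the locus sequence with ``ref_bases`` replaced by ``alt_bases``."""
    edit.validate_against(locus)
    seq = locus.sequence
    return seq[: edit.position] + edit.alt_bases + seq[edit.end :]


def coding_sequence(locus: ReferenceLocus, sequence: str | None = None) -> str:
    """Gene-oriented coding sequence with the frame offset applied.

    When ``sequence`` is given it is interpreted in the locus coordinate
    system (it must have the locus length); this is how edited sequences of
    unchanged length are translated.
    """
    if not locus.coding_segments:
        raise ValueError("locus has no coding segments")
    seq = locus.sequence if sequence is None else _check_sequence(sequence)
    if sequence is not None and len(seq) != len(locus.sequence):
        raise ValueError(
            "sequence length differs from locus; coding segments are undefined"
        )
    cat = "".join(seq[s:e] for s, e, _ in locus.coding_segments)
    if locus.strand_of_gene == "-":
        cat = reverse_complement(cat)
        frame = locus.coding_segments[-1][2]
    else:
        frame = locus.coding_segments[0][2]
    return cat[frame:]


def translate_coding(locus: ReferenceLocus, sequence: str | None = None) -> str:
    """Translate the locus coding segments with the standard genetic code.

    A trailing partial codon is dropped (partial loci are allowed); stop
    codons appear as ``*``.
    """
    cds = coding_sequence(locus, sequence)
    cds = cds[: len(cds) - len(cds) % 3]
    return str(Seq(cds).translate())
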