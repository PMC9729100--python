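"""Allele classification and editing-outcome quantification from amplicon reads.

Every read from the target-site PCR product is assigned to exactly one
allele category.  Because the primers anneal outside the ssODN-covered
region, all editing outcomes are sampled and their read frequencies
estimate allele frequencies in the template pool; combined with the known
genomic-DNA input mass this yields absolute cell-number estimates for each
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pysam
from Bio import Align

from .design import Cassette
from .sequence import VariantSpec

__all__ = [
    "AlleleCategory",
    "ClassifierConfig",
    "Alignment",
    "AmpliconContext",
    "EditingProfile",
    "CellEstimate",
    "align_read",
    "classify_read",
    "quantify_sample",
    "estimate_absolute_cells",
]


class AlleleCategory(str, Enum):
    VARIANT_KI = "VARIANT_KI"
    WTPRIME_KI = "WTPRIME_KI"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
    INFRAME_INDEL = "INFRAME_INDEL"
    WT = "WT"
    MIXED_KI = "MIXED_KI"
    OTHER = "OTHER"
    DISCARDED = "DISCARDED"


RETAINED = tuple(c for c in AlleleCategory if c is not AlleleCategory.DISCARDED)


@dataclass(frozen=True)
class ClassifierConfig:
    """Alignment and filtering parameters for read classification."""

    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_open_score: float = -6.0
    gap_extend_score: float = -0.5
    min_identity: float = 0.6       # below: read is unalignable -> OTHER
    min_read_length: int = 50
    min_mean_quality: float = 20.0
    min_base_quality: int = 10      # bases below are wildcards at edit sites
    strict_substitutions: bool = False  # True: any window substitution -> OTHER
    hamming_fastpath_identity: float = 0.9


@dataclass(frozen=True)
class Indel:
    """A gap in the read/reference alignment.

    ``ref_pos`` is the reference coordinate of the gap (for a deletion, the
    first deleted base; for an insertion, the base before which the extra
    sequence sits).  ``length`` is signed: negative for deletions.
    """

    ref_pos: int
    length: int

    @property
    def ref_span(self) -> tuple[int, int]:
        if self.length < 0:
            return (self.ref_pos, self.ref_pos - self.length)
        return (self.ref_pos, self.ref_pos)


@dataclass
class Alignment:
    """Global read/reference alignment in reference coordinates.

    ``read_bases[i]`` is the read base aligned to reference position ``i``
    (None under a deletion); ``read_quals`` likewise.  Insertions are kept
    separately.  Indels are left-normalized: each gap is shifted to its
    leftmost equivalent placement.
    """

    read_bases: list[str | None]
    read_quals: list[int | None]
    indels: list[Indel]
    identity: float
    unalignable: bool = False


def _left_normalize(ref: str, read: str, indels: list[Indel]) -> list[Indel]:
    out = []
    for ind in sorted(indels, key=lambda d: d.ref_pos):
        pos = ind.ref_pos
        if ind.length < 0:
            k = -ind.length
            while pos > 0 and ref[pos - 1] == ref[pos + k - 1]:
                pos -= 1
        out.append(Indel(pos, ind.length))
    return out


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(config: ClassifierConfig) -> Align.PairwiseAligner:
    key = (
        config.match_score,
        config.mismatch_score,
        config.gap_open_score,
        config.gap_extend_score,
    )
    if key not in _ALIGNER_CACHE:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = config.match_score
        al.mismatch_score = config.mismatch_score
        al.open_gap_score = config.gap_open_score
        al.extend_gap_score = config.gap_extend_score
        _ALIGNER_CACHE[key] = al
    return _ALIGNER_CACHE[key]


def _substitution_alignment(
    read: str, ref: str, quals: list[int] | None
) -> Alignment:
    matches = sum(a == b for a, b in zip(read, ref))
    return Alignment(
        read_bases=list(read),
        read_quals=list(quals) if quals is not None else [None] * len(read),
        indels=[],
        identity=matches / len(ref),
    )


def align_read(
    read: str,
    amplicon_ref: str,
    config: ClassifierConfig = ClassifierConfig(),
    qualities: list[int] | None = None,
) -> Alignment:
    """Global affine-gap alignment of one read against the amplicon.

    Gap placement is normalized to the leftmost equivalent position, so
    e.g. a 1-nt deletion inside a homopolymer is always reported at the
    run's first base.  Reads whose alignment identity falls below
    ``config.min_identity`` come back flagged unalignable.
    """
    read = read.upper()
    if read == amplicon_ref:
        return _substitution_alignment(read, amplicon_ref, qualities)
    if len(read) == len(amplicon_ref):
        matches = sum(a == b for a, b in zip(read, amplicon_ref))
        if matches / len(amplicon_ref) >= config.hamming_fastpath_identity:
            return _substitution_alignment(read, amplicon_ref, qualities)

    aln = _aligner(config).align(amplicon_ref, read)[0]
    ref_blocks, read_blocks = aln.aligned

    n = len(amplicon_ref)
    read_bases: list[str | None] = [None] * n
    read_quals: list[int | None] = [None] * n
    indels: list[Indel] = []
    matches = 0
    columns = 0
    prev_ref_end = 0
    prev_read_end = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > prev_ref_end:  # deletion in read
            indels.append(Indel(prev_ref_end, -(rs - prev_ref_end)))
            columns += rs - prev_ref_end
        if qs > prev_read_end:  # insertion in read
            indels.append(Indel(rs, qs - prev_read_end))
            columns += qs - prev_read_end
        for i in range(re_ - rs):
            b = read[qs + i]
            read_bases[rs + i] = b
            read_quals[rs + i] = qualities[qs + i] if qualities is not None else None
            if b == amplicon_ref[rs + i]:
                matches += 1
        columns += re_ - rs
        prev_ref_end, prev_read_end = re_, qe
    if n > prev_ref_end:
        indels.append(Indel(prev_ref_end, -(n - prev_ref_end)))
        columns += n - prev_ref_end
    if len(read) > prev_read_end:
        indels.append(Indel(n, len(read) - prev_read_end))
        columns += len(read) - prev_read_end

    identity = matches / columns if columns else 0.0
    return Alignment(
        read_bases=read_bases,
        read_quals=read_quals,
        indels=_left_normalize(amplicon_ref, read, indels),
        identity=identity,
        unalignable=identity < config.min_identity,
    )


# ---------------------------------------------------------------------------
# Amplicon context


@dataclass(frozen=True)
class AmpliconContext:
    """Everything the classifier needs, in amplicon coordinates.

    ``variant_sites`` / ``wtprime_sites`` are ``(position, ref, alt)``
    tuples for each edited base; ``window`` is the quantification interval
    (default: the ssODN-covered region); ``coding_intervals`` restrict the
    frameshift computation to bases where frame is defined.
    """

    reference: str
    variant_sites: tuple[tuple[int, str, str], ...]
    wtprime_sites: tuple[tuple[int, str, str], ...]
    window: tuple[int, int]
    coding_intervals: tuple[tuple[int, int], ...]
    amplicon_start: int = 0  # locus coordinate of amplicon position 0

    @classmethod
    def from_cassette(
        cls, cassette: Cassette, window: tuple[int, int] | None = None
    ) -> "AmpliconContext":
        locus = cassette.locus
        a = cassette.primers.forward_region[0]
        d = cassette.primers.reverse_region[1]
        ref = locus.sequence[a:d]

        def sites(edit: VariantSpec):
            out = []
            for i, pos in enumerate(edit.affected_positions()):
                if edit.ref_bases and len(edit.ref_bases) == len(edit.alt_bases):
                    out.append((pos - a, edit.ref_bases[i], edit.alt_bases[i]))
                else:  # indel knock-in: mark the junction base
                    out.append((pos - a, locus.sequence[pos], ""))
            return tuple(out)

        if window is None:
            lo, hi = cassette.ssodn_region
            window = (max(lo - a, 0), min(hi - a, len(ref)))
        coding = tuple(
            (max(s - a, 0), min(e - a, len(ref)))
            for s, e, _ in locus.coding_segments
            if e > a and s < d
        )
        return cls(
            reference=ref,
            variant_sites=sites(cassette.variant),
            wtprime_sites=sites(cassette.wtprime_spec),
            window=window,
            coding_intervals=coding,
            amplicon_start=a,
        )


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _coding_net_change(ctx: AmpliconContext, indels: list[Indel]) -> tuple[int, bool]:
    """Net coding-length change of window-overlapping indels.

    Returns (net change, any_overlap).  For deletions only the portion that
    intersects coding intervals counts; an insertion counts fully when its
    anchor lies inside a coding interval.
    """
    w0, w1 = ctx.window
    net = 0
    any_overlap = False
    for ind in indels:
        s, e = ind.ref_span
        in_window = (_overlap(s, e, w0, w1) > 0) if ind.length < 0 else (w0 <= s <= w1)
        if not in_window:
            continue
        any_overlap = True
        if ind.length < 0:
            net -= sum(_overlap(s, e, c0, c1) for c0, c1 in ctx.coding_intervals)
        else:
            if any(c0 <= s <= c1 for c0, c1 in ctx.coding_intervals):
                net += ind.length
    return net, any_overlap


def classify_read(
    alignment: Alignment,
    ctx: AmpliconContext,
    config: ClassifierConfig = ClassifierConfig(),
) -> AlleleCategory:
    """Assign one aligned read to an allele category.

    Decision order: unalignable reads are OTHER; any indel overlapping the
    quantification window makes the read an indel allele (frameshift when
    the net coding-length change is not a multiple of 3) regardless of
    point edits; otherwise the variant and WT' bases decide between the
    knock-in, WT, MIXED and OTHER categories.  Substitutions away from the
    edit sites are sequencing-error-tolerant by default.
    """
    if alignment.unalignable:
        return AlleleCategory.OTHER

    net, any_indel = _coding_net_change(ctx, alignment.indels)
    if any_indel:
        if net % 3 != 0:
            return AlleleCategory.FRAMESHIFT_INDEL
        return AlleleCategory.INFRAME_INDEL

    # Template matching over the union of edit-site positions.  Each
    # expected window haplotype (WT, variant knock-in, WT' knock-in, and --
    # when the edits do not share positions -- the double knock-in) fixes a
    # base at every edit site; a read matches a haplotype when every
    # readable edit-site base agrees with it.  Bases below the quality
    # floor, or removed by gaps, act as wildcards.
    positions = sorted(
        {p for p, _, _ in ctx.variant_sites} | {p for p, _, _ in ctx.wtprime_sites}
    )
    wt_map = {p: ctx.reference[p] for p in positions}
    v_map = dict(wt_map)
    for p, _r, alt in ctx.variant_sites:
        v_map[p] = alt
    w_map = dict(wt_map)
    for p, _r, alt in ctx.wtprime_sites:
        w_map[p] = alt
    haplotypes = {
        AlleleCategory.WT: wt_map,
        AlleleCategory.VARIANT_KI: v_map,
        AlleleCategory.WTPRIME_KI: w_map,
    }
    v_pos = {p for p, _, _ in ctx.variant_sites}
    w_pos = {p for p, _, _ in ctx.wtprime_sites}
    if not (v_pos & w_pos):
        m_map = dict(v_map)
        for p, _r, alt in ctx.wtprime_sites:
            m_map[p] = alt
        haplotypes[AlleleCategory.MIXED_KI] = m_map

    def matches(template: dict) -> bool:
        for pos, expected in template.items():
            b = alignment.read_bases[pos]
            q = alignment.read_quals[pos]
            if b is None or (q is not None and q < config.min_base_quality):
                continue  # unreadable base cannot contradict the template
            if not expected or b != expected:
                return False
        return True

    hits = {cat for cat, tmpl in haplotypes.items() if matches(tmpl)}
    if hits == {AlleleCategory.MIXED_KI}:
        category = AlleleCategory.MIXED_KI
    elif AlleleCategory.VARIANT_KI in hits and AlleleCategory.WTPRIME_KI not in hits:
        category = AlleleCategory.VARIANT_KI
    elif AlleleCategory.WTPRIME_KI in hits and AlleleCategory.VARIANT_KI not in hits:
        category = AlleleCategory.WTPRIME_KI
    elif AlleleCategory.WT in hits:
        category = AlleleCategory.WT  # fully wildcard reads default to WT
    elif hits:
        category = next(iter(hits))
    else:
        return AlleleCategory.OTHER

    if category is AlleleCategory.WT and config.strict_substitutions:
        w0, w1 = ctx.window
        pos_set = set(positions)
        for pos in range(w0, w1):
            if pos in pos_set:
                continue
            b = alignment.read_bases[pos]
            q = alignment.read_quals[pos]
            if b is not None and b != ctx.reference[pos]:
                if q is None or q >= config.min_base_quality:
                    return AlleleCategory.OTHER
    return category


# ---------------------------------------------------------------------------
# Absolute cell numbers


@dataclass(frozen=True)
class CellEstimate:
    """Absolute cell-number estimate behind a category frequency.

    ``cells`` uses the raw genome-equivalent count (linear in mass and
    frequency); ``cells_printed`` uses the equivalents rounded to the
    nearest thousand, matching how the numbers are usually quoted.
    ``allele_count`` is the alternative reading of a read frequency as a
    fraction of alleles rather than of cells (2 alleles per diploid
    genome).
    """

    genome_equivalents: float
    genome_equivalents_rounded: int
    cells: float
    cells_printed: float
    allele_count: float


def estimate_absolute_cells(
    gdna_ng: float, frequency: float, pg_per_diploid_genome: float = 6.0
) -> CellEstimate:
    """Cells represented by a read-frequency at a given template mass.

    A diploid human genome weighs ~6 pg, so 100 ng of genomic DNA carries
    ~16,667 (~17,000) genome equivalents; a category at 8% read frequency
    then derives from ~1,360 cells.
    """
    if gdna_ng <= 0:
        raise ValueError("template mass must be positive")
    if not 0.0 <= frequency <= 1.0:
        raise ValueError("frequency must be within [0, 1]")
    ge = gdna_ng * 1000.0 / pg_per_diploid_genome
    ge_rounded = int(round(ge / 1000.0) * 1000)
    return CellEstimate(
        genome_equivalents=ge,
        genome_equivalents_rounded=ge_rounded,
        cells=ge * frequency,
        cells_printed=ge_rounded * frequency,
        allele_count=2.0 * ge * frequency,
    )


# ---------------------------------------------------------------------------
# Per-sample quantification


@dataclass
class EditingProfile:
    """Per-sample table of allele-category read counts and estimates."""

    sample_id: str
    counts: dict[AlleleCategory, int]
    total_reads: int
    retained_reads: int
    gdna_ng: float | None = None
    genome_equivalents: float | None = None
    cell_estimates: dict[AlleleCategory, float] = field(default_factory=dict)
    warning: str | None = None

    @property
    def frequencies(self) -> dict[AlleleCategory, float]:
        if self.retained_reads == 0:
            return {c: 0.0 for c in RETAINED}
        return {c: self.counts.get(c, 0) / self.retained_reads for c in RETAINED}

    def frequency(self, category: AlleleCategory) -> float:
        return self.frequencies[category]


def _parse_fastq(path):
    """FASTQ records (plain or gzip) as (name, sequence, quality string)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper(), entry.quality or ""


def quantify_sample(
    fastq_path,
    cassette: Cassette | AmpliconContext,
    config: ClassifierConfig = ClassifierConfig(),
    gdna_ng: float | None = None,
    sample_id: str | None = None,
    pg_per_diploid_genome: float = 6.0,
) -> EditingProfile:
    """Stream a FASTQ and aggregate allele-category counts.

    Reads shorter than the minimum length or below the mean-quality filter
    are DISCARDED; frequencies are fractions of the retained reads.  With a
    template mass the per-category absolute cell estimates are attached.
    Identical (sequence, quality) records are classified once and cached.
    """
    ctx = (
        cassette
        if isinstance(cassette, AmpliconContext)
        else AmpliconContext.from_cassette(cassette)
    )
    counts: dict[AlleleCategory, int] = {c: 0 for c in AlleleCategory}
    cache: dict[tuple[str, str], AlleleCategory] = {}
    total = 0
    for _name, seq, qual in _parse_fastq(fastq_path):
        total += 1
        key = (seq, qual)
        cat = cache.get(key)
        if cat is None:
            quals = [ord(c) - 33 for c in qual] if qual else None
            if len(seq) < config.min_read_length or (
                quals and sum(quals) / len(quals) < config.min_mean_quality
            ):
                cat = AlleleCategory.DISCARDED
            else:
                aln = align_read(seq, ctx.reference, config, quals)
                cat = classify_read(aln, ctx, config)
            cache[key] = cat
        counts[cat] += 1
    if total == 0:
        raise ValueError(f"empty FASTQ: {fastq_path}")
    retained = total - counts[AlleleCategory.DISCARDED]

    profile = EditingProfile(
        sample_id=sample_id or str(fastq_path),
        counts={c: counts[c] for c in AlleleCategory},
        total_reads=total,
        retained_reads=retained,
        gdna_ng=gdna_ng,
    )
    if retained and counts[AlleleCategory.OTHER] / retained > 0.5:
        profile.warning = ">50% of retained reads are OTHER/unalignable"
    if gdna_ng is not None:
        est = estimate_absolute_cells(gdna_ng, 1.0, pg_per_diploid_genome)
        profile.genome_equivalents = est.genome_equivalents
        profile.cell_estimates = {
            c: est.genome_equivalents * f for c, f in profile.frequencies.items()
        }
    return profile
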