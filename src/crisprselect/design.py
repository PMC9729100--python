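"""Rule-based design of variant/WT' knock-in cassettes.

A cassette is the reagent set of the selection assay: an SpCas9 guide whose
target site is destroyed by the knock-in, two ssODN repair templates that
are identical except that one carries the variant of interest and the other
a nearby synonymous normalization edit (WT'), and a primer pair that
amplifies the locus from sequence untouched by either template so every
editing outcome is sampled.

Design rules implemented here:

* guide: NGG PAM, blunt cut 3 nt 5' of the PAM; the edited bases must fall
  in the PAM GG or within the 10 PAM-proximal protospacer nucleotides (the
  seed), so knock-in destroys re-cutting; candidates ranked by distance of
  the variant to the cut site;
* off-targets: the closest off-target site (within a mismatch budget,
  against user-supplied sequences) must carry at least one mismatch in the
  seed or PAM GG;
* WT': a single-nucleotide synonymous substitution at, or within 3 nt of,
  the variant, that does not create a splice motif, does not produce a rare
  codon, and also disrupts the guide site;
* ssODNs: 45-nt homology arms; sense polarity for edits >4 bp left of the
  cut, antisense for edits >4 bp right of it, sense otherwise;
* primers: anneal 40-120 nt outside the ssODN-covered region, product
  230-350 bp, with simple GC and Tm windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .codons import CodonUsageTable
from .sequence import (
    ReferenceLocus,
    VariantSpec,
    apply_edit,
    reverse_complement,
    translate_coding,
)
from . import splice

__all__ = [
    "DesignConfig",
    "DesignError",
    "GuideCandidate",
    "OffTargetHit",
    "OffTargetReport",
    "SsODN",
    "PrimerPair",
    "Cassette",
    "enumerate_guides",
    "screen_offtargets",
    "design_wtprime",
    "build_ssodn",
    "design_primers",
    "assemble_cassette",
]

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN
# Blunt cut between protospacer positions 17 and 18, i.e. 3 nt 5' of the PAM.
CUT_OFFSET_FROM_PAM = 3


class DesignError(RuntimeError):
    """A design stage could not satisfy its constraints."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the cassette designer (defaults as used in the assay)."""

    arm_length: int = 45          # ssODN homology arm, nt
    seed_max_offset: int = 10     # PAM-proximal nucleotides counted as seed
    wtprime_max_distance: int = 3  # nt between WT' and the variant
    rare_codon_threshold: float = 5.0   # per-thousand usage below which a codon is "rare"
    polarity_distance: int = 4    # |edit - cut| beyond which ssODN polarity is enforced
    primer_min_offset: int = 40   # nt outside the ssODN-covered region
    primer_max_offset: int = 120
    product_min: int = 230        # bp
    product_max: int = 350
    primer_min_len: int = 18
    primer_max_len: int = 25
    primer_gc_min: float = 0.35
    primer_gc_max: float = 0.65
    primer_tm_min: float = 44.0   # degC, GC-content rule
    primer_tm_max: float = 68.0
    max_mismatches: int = 3       # off-target scan budget
    require_joint_disruption: bool = True  # WT' must disrupt the guide too
    splice_mode: str = "standard"  # or "exon_offset" for splice-site variants
    splice_allow_positions: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Guides


@dataclass(frozen=True)
class GuideCandidate:
    """One SpCas9 guide option at the locus.

    ``protospacer`` is given 5'->3' on the protospacer strand; ``strand``
    refers to the stored locus sequence.  ``cut_position`` is the locus
    coordinate of the blunt-cut boundary (between the bases at
    ``cut_position - 1`` and ``cut_position``).  ``disruption_positions``
    maps each edited locus position to its placement in the site: ``"PAM"``
    for the GG or the 1-based seed offset from the PAM-proximal protospacer
    end.
    """

    protospacer: str
    pam: str
    strand: str
    site_start: int  # locus coord of the 23-nt site (protospacer+PAM on plus strand layout)
    cut_position: int
    variant_distance_to_cut: int
    disruption_positions: dict[int, object] = field(default_factory=dict)
    locus_id: str = ""

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")

    @property
    def min_seed_offset(self) -> int:
        """Smallest disruption offset, with a PAM hit counting as 0."""
        vals = [0 if v == "PAM" else int(v) for v in self.disruption_positions.values()]
        return min(vals) if vals else 99


def _site_geometry(start: int, strand: str) -> dict:
    """Locus-coordinate geometry of a 23-nt protospacer+PAM site."""
    if strand == "+":
        return {
            "protospacer": (start, start + PROTOSPACER_LEN),
            "pam_gg": (start + PROTOSPACER_LEN + 1, start + PROTOSPACER_LEN + 2),
            "cut": start + PROTOSPACER_LEN - CUT_OFFSET_FROM_PAM,
            # seed offset s (1..20) lives at locus index start + 20 - s
            "seed_index": lambda pos: start + PROTOSPACER_LEN - pos,
        }
    return {
        "protospacer": (start + PAM_LEN, start + SITE_LEN),
        "pam_gg": (start, start + 1),
        "cut": start + PAM_LEN + CUT_OFFSET_FROM_PAM,
        "seed_index": lambda pos: start + PAM_LEN - 1 + pos,
    }


def _classify_position(position: int, start: int, strand: str) -> object | None:
    """Place a locus position within a site: 'PAM', seed offset int, or None."""
    if strand == "+":
        gg = (start + PROTOSPACER_LEN + 1, start + PROTOSPACER_LEN + 2)
        p0, p1 = start, start + PROTOSPACER_LEN
        if position in gg:
            return "PAM"
        if p0 <= position < p1:
            return p1 - position  # 1 = PAM-proximal
    else:
        gg = (start, start + 1)
        p0, p1 = start + PAM_LEN, start + SITE_LEN
        if position in gg:
            return "PAM"
        if p0 <= position < p1:
            return position - p0 + 1
    return None


def _signed_distance_to_cut(position: int, cut: int) -> int:
    """Signed nt distance of a base to a blunt-cut boundary.

    The base immediately right of the cut is +1, immediately left is -1.
    """
    return position - cut + 1 if position >= cut else position - cut


def _scan_sites(sequence: str):
    """Yield (start, strand) for every NGG site on either strand."""
    n = len(sequence)
    for i in range(n - SITE_LEN + 1):
        if sequence[i + PROTOSPACER_LEN + 1 : i + PROTOSPACER_LEN + 3] == "GG":
            yield i, "+"
        if sequence[i : i + 2] == "CC":
            yield i, "-"


def _site_protospacer(sequence: str, start: int, strand: str) -> tuple[str, str]:
    if strand == "+":
        return (
            sequence[start : start + PROTOSPACER_LEN],
            sequence[start + PROTOSPACER_LEN : start + SITE_LEN],
        )
    return (
        reverse_complement(sequence[start + PAM_LEN : start + SITE_LEN]),
        reverse_complement(sequence[start : start + PAM_LEN]),
    )


def enumerate_guides(
    locus: ReferenceLocus,
    variant: VariantSpec,
    wtprime: VariantSpec | None = None,
    config: DesignConfig = DesignConfig(),
) -> list[GuideCandidate]:
    """All guides whose site is disrupted by the variant (and WT' if given).

    Every edited base must fall in the PAM GG or within
    ``config.seed_max_offset`` nt of the PAM-proximal protospacer end.
    Candidates are sorted by |variant distance to cut|, then by smallest
    seed offset, then plus strand first, then position.
    """
    if len(locus) < 60:
        raise DesignError("guide", f"locus too short ({len(locus)} nt < 60)")
    variant.validate_against(locus)

    edited_sets = [variant.affected_positions()]
    if wtprime is not None:
        edited_sets.append(wtprime.affected_positions())

    out: list[GuideCandidate] = []
    for start, strand in _scan_sites(locus.sequence):
        placements: dict[int, object] = {}
        ok = True
        for positions in edited_sets:
            for pos in positions:
                place = _classify_position(pos, start, strand)
                if place is None or (place != "PAM" and place > config.seed_max_offset):
                    ok = False
                    break
                placements[pos] = place
            if not ok:
                break
        if not ok:
            continue
        geom = _site_geometry(start, strand)
        cut = geom["cut"]
        dist = min(
            (_signed_distance_to_cut(p, cut) for p in variant.affected_positions()),
            key=abs,
        )
        protospacer, pam = _site_protospacer(locus.sequence, start, strand)
        out.append(
            GuideCandidate(
                protospacer=protospacer,
                pam=pam,
                strand=strand,
                site_start=start,
                cut_position=cut,
                variant_distance_to_cut=dist,
                disruption_positions=placements,
                locus_id=locus.locus_id,
            )
        )
    out.sort(
        key=lambda g: (
            abs(g.variant_distance_to_cut),
            g.min_seed_offset,
            0 if g.strand == "+" else 1,
            g.site_start,
        )
    )
    return out


# ---------------------------------------------------------------------------
# Off-targets


@dataclass(frozen=True)
class OffTargetHit:
    reference_id: str
    position: int
    strand: str
    site_sequence: str
    mismatch_count: int
    mismatch_seed_offsets: tuple[int, ...]  # 1 = PAM-proximal

    @property
    def has_seed_mismatch(self) -> bool:
        return any(o <= 10 for o in self.mismatch_seed_offsets)


@dataclass(frozen=True)
class OffTargetReport:
    guide: GuideCandidate
    hits: tuple[OffTargetHit, ...]
    passes: bool

    @property
    def closest(self) -> OffTargetHit | None:
        return min(self.hits, key=lambda h: h.mismatch_count) if self.hits else None


def screen_offtargets(
    guide: GuideCandidate,
    reference_sequences: dict[str, str],
    max_mismatches: int | None = None,
    seed_max_offset: int = 10,
    config: DesignConfig = DesignConfig(),
) -> OffTargetReport:
    """Exhaustive NGG off-target scan of the supplied sequences.

    Sites whose GG is broken are not functional Cas9 sites and are not
    reported.  The guide passes when every minimal-mismatch hit carries at
    least one mismatch within the seed (offsets 1..``seed_max_offset``);
    absence of any hit also passes.  The on-target site (same reference id,
    start and strand as the guide) is excluded.
    """
    if max_mismatches is None:
        max_mismatches = config.max_mismatches
    hits: list[OffTargetHit] = []
    for ref_id, seq in reference_sequences.items():
        seq = seq.upper()
        for start, strand in _scan_sites(seq):
            if (
                ref_id == guide.locus_id
                and start == guide.site_start
                and strand == guide.strand
            ):
                continue
            protospacer, _ = _site_protospacer(seq, start, strand)
            mismatch_offsets = tuple(
                PROTOSPACER_LEN - i  # index 19 is PAM-proximal = offset 1
                for i in range(PROTOSPACER_LEN)
                if protospacer[i] != guide.protospacer[i]
            )
            if len(mismatch_offsets) > max_mismatches:
                continue
            if not mismatch_offsets:
                # exact duplicate of the target elsewhere
                hits.append(
                    OffTargetHit(ref_id, start, strand, protospacer, 0, ())
                )
                continue
            hits.append(
                OffTargetHit(
                    ref_id,
                    start,
                    strand,
                    protospacer,
                    len(mismatch_offsets),
                    mismatch_offsets,
                )
            )
    if not hits:
        return OffTargetReport(guide, (), True)
    min_mm = min(h.mismatch_count for h in hits)
    closest = [h for h in hits if h.mismatch_count == min_mm]
    passes = min_mm > 0 and all(
        any(o <= seed_max_offset for o in h.mismatch_seed_offsets) for h in closest
    )
    return OffTargetReport(guide, tuple(hits), passes)


# ---------------------------------------------------------------------------
# WT'


def _codon_at(locus: ReferenceLocus, edited: str, position: int) -> str | None:
    """The (edited) codon containing a coding position, in gene orientation."""
    idx = locus.cds_index(position)
    if idx is None:
        return None
    from .sequence import coding_sequence

    frame = (
        locus.coding_segments[-1][2]
        if locus.strand_of_gene == "-"
        else locus.coding_segments[0][2]
    )
    cds = coding_sequence(locus, edited)
    idx -= frame
    if idx < 0:
        return None
    start = idx - idx % 3
    codon = cds[start : start + 3]
    return codon if len(codon) == 3 else None


def _edit_distance_nt(variant: VariantSpec, position: int) -> int:
    """Nucleotide distance between a candidate position and the variant."""
    if variant.position <= position < max(variant.end, variant.position + 1):
        return 0
    if position < variant.position:
        return variant.position - position
    return position - max(variant.end - 1, variant.position)


def design_wtprime(
    locus: ReferenceLocus,
    variant: VariantSpec,
    guide: GuideCandidate,
    usage_table: CodonUsageTable | None = None,
    config: DesignConfig = DesignConfig(),
) -> tuple[list[VariantSpec], dict[str, str]]:
    """Ranked synonymous WT' candidates near the variant.

    A candidate is a single-nucleotide substitution that (a) leaves the
    protein unchanged, (b) does not create a splice motif, (c) does not
    produce a codon rarer than the usage threshold, and (d) falls in the
    guide's PAM GG or seed.  Candidates are ranked by distance to the
    variant (0..3) then by resulting codon usage, descending.  The second
    return value maps rejected candidates to the violated rule.

    In ``splice_mode="exon_offset"`` (for splice-site variants) candidates
    are instead drawn from coding positions near the exon boundary closest
    to the variant, ranked by distance to that boundary.
    """
    if usage_table is None:
        usage_table = CodonUsageTable.human()
    wt_protein = translate_coding(locus) if locus.coding_segments else ""

    if config.splice_mode == "exon_offset":
        boundaries = [b for s, e, _ in locus.coding_segments for b in (s, e - 1)]
        if not boundaries:
            raise DesignError("wtprime", "exon_offset mode requires coding segments")
        boundary = min(boundaries, key=lambda b: abs(b - variant.position))
        positions = [
            p
            for p in range(boundary - 12, boundary + 13)
            if 0 <= p < len(locus) and locus.is_coding(p)
        ]
        positions.sort(key=lambda p: (abs(p - boundary), p))
    else:
        lo = variant.position - config.wtprime_max_distance
        hi = max(variant.end, variant.position + 1) + config.wtprime_max_distance
        positions = [p for p in range(lo, hi) if 0 <= p < len(locus)]

    candidates: list[tuple[tuple, VariantSpec]] = []
    rejections: dict[str, str] = {}
    variant_edited = apply_edit(locus, variant) if variant.ref_bases else None
    for pos in positions:
        ref_base = locus.sequence[pos]
        distance = _edit_distance_nt(variant, pos)
        if config.splice_mode != "exon_offset" and distance > config.wtprime_max_distance:
            continue
        for alt in "ACGT":
            if alt == ref_base:
                continue
            name = f"{pos}{ref_base}>{alt}"
            # same-position WT' must still differ from the variant allele
            if (
                variant.ref_bases
                and len(variant.ref_bases) == len(variant.alt_bases)
                and variant.position <= pos < variant.end
                and alt == variant.alt_bases[pos - variant.position]
            ):
                rejections[name] = "identical to variant allele"
                continue
            cand = VariantSpec(pos, ref_base, alt, label=name, variant_class="synonymous")
            edited = apply_edit(locus, cand)
            if locus.coding_segments and translate_coding(locus, edited) != wt_protein:
                rejections[name] = "not synonymous"
                continue
            if pos not in config.splice_allow_positions and splice.creates_splice_site(
                locus.sequence, edited, pos
            ):
                rejections[name] = "creates splice motif"
                continue
            codon = _codon_at(locus, edited, pos)
            usage = usage_table[codon] if codon else None
            if usage is not None and usage < config.rare_codon_threshold:
                rejections[name] = f"rare codon {codon} ({usage}/1000)"
                continue
            place = _classify_position(pos, guide.site_start, guide.strand)
            if place is None or (place != "PAM" and place > config.seed_max_offset):
                rejections[name] = "outside guide PAM/seed"
                continue
            rank = (distance, -(usage if usage is not None else 0.0), pos, alt)
            candidates.append((rank, cand))
    candidates.sort(key=lambda t: t[0])
    return [c for _, c in candidates], rejections


# ---------------------------------------------------------------------------
# ssODNs


@dataclass(frozen=True)
class SsODN:
    """A single-stranded repair template with symmetric homology arms.

    ``sequence`` is the oligo as synthesized (already reverse-complemented
    for antisense polarity); ``region`` is the genomic footprint
    [start, end) covered by the template.
    """

    sequence: str
    encoded_edit: VariantSpec
    arm_5_len: int
    arm_3_len: int
    polarity: str  # sense | antisense
    region: tuple[int, int]

    @property
    def sense_sequence(self) -> str:
        return (
            self.sequence if self.polarity == "sense" else reverse_complement(self.sequence)
        )


def build_ssodn(
    locus: ReferenceLocus,
    guide: GuideCandidate | None,
    edit: VariantSpec,
    arm_length: int | None = None,
    config: DesignConfig = DesignConfig(),
) -> SsODN:
    """Construct the repair template for one edit.

    Polarity rule: when the nearest edited base lies more than
    ``config.polarity_distance`` bp from the cut, the template is sense for
    edits left of the break and antisense for edits right of it; otherwise
    polarity defaults to sense.  With no guide supplied, polarity is sense.
    """
    if arm_length is None:
        arm_length = config.arm_length
    edit.validate_against(locus)
    start = edit.position - arm_length
    end = max(edit.end, edit.position) + arm_length
    if start < 0 or end > len(locus):
        raise DesignError(
            "ssodn",
            f"locus too short for {arm_length}-nt arms around position {edit.position}",
        )
    sense = (
        locus.sequence[start : edit.position]
        + edit.alt_bases
        + locus.sequence[edit.end : end]
    )
    polarity = "sense"
    if guide is not None:
        dist = min(
            (_signed_distance_to_cut(p, guide.cut_position) for p in edit.affected_positions()),
            key=abs,
        )
        if abs(dist) > config.polarity_distance:
            polarity = "sense" if dist < 0 else "antisense"
    sequence = sense if polarity == "sense" else reverse_complement(sense)
    return SsODN(
        sequence=sequence,
        encoded_edit=edit,
        arm_5_len=arm_length,
        arm_3_len=arm_length,
        polarity=polarity,
        region=(start, end),
    )


# ---------------------------------------------------------------------------
# Primers


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    forward_region: tuple[int, int]  # annealing interval on the locus
    reverse_region: tuple[int, int]
    product_length: int
    forward_offset: int  # nt between primer and the ssODN-covered region
    reverse_offset: int


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _tm_gc_rule(seq: str) -> float:
    """GC-content melting temperature rule: 64.9 + 41*(GC-16.4)/N."""
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def _primer_candidates(locus, side: str, region: tuple[int, int], config: DesignConfig):
    """Valid primers on one side of the ssODN-covered region.

    Returns tuples (offset, start, end, sequence) sorted by offset then
    length.  Offsets are measured from the primer edge nearest the region.
    """
    r0, r1 = region
    out = []
    for offset in range(config.primer_min_offset, config.primer_max_offset + 1):
        for length in range(config.primer_min_len, config.primer_max_len + 1):
            if side == "forward":
                end = r0 - offset
                start = end - length
                if start < 0:
                    continue
                seq = locus.sequence[start:end]
            else:
                start = r1 + offset
                end = start + length
                if end > len(locus):
                    continue
                seq = reverse_complement(locus.sequence[start:end])
            gc = _gc_fraction(seq)
            if not (config.primer_gc_min <= gc <= config.primer_gc_max):
                continue
            tm = _tm_gc_rule(seq)
            if not (config.primer_tm_min <= tm <= config.primer_tm_max):
                continue
            out.append((offset, start, end, seq, gc))
    return out


def design_primers(
    locus: ReferenceLocus,
    ssodn_region: tuple[int, int],
    config: DesignConfig = DesignConfig(),
) -> PrimerPair:
    """Deterministic target-site primer design.

    Both primers anneal entirely outside the ssODN-covered region at
    40-120 nt offset, the product is 230-350 bp, and candidates must pass
    GC- and Tm-window filters.  Among valid pairs the one with the smallest
    summed offset is returned; ties are broken by GC balance (closeness of
    both primers to 50% GC).
    """
    fwd = _primer_candidates(locus, "forward", ssodn_region, config)
    rev = _primer_candidates(locus, "reverse", ssodn_region, config)
    if not fwd or not rev:
        r0, r1 = ssodn_region
        side = "forward" if not fwd else "reverse"
        avail = r0 if not fwd else len(locus) - r1
        raise DesignError(
            "primer",
            f"offset window unsatisfiable on {side} side "
            f"({avail} nt available outside the ssODN-covered region)",
        )
    best = None
    best_key = None
    for f_off, f_start, f_end, f_seq, f_gc in fwd:
        for r_off, r_start, r_end, r_seq, r_gc in rev:
            product = r_end - f_start
            if product < config.product_min:
                continue
            if product > config.product_max:
                continue
            balance = abs(f_gc - 0.5) + abs(r_gc - 0.5)
            key = (f_off + r_off, balance, f_start, r_start)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    forward=f_seq,
                    reverse=r_seq,
                    forward_region=(f_start, f_end),
                    reverse_region=(r_start, r_end),
                    product_length=product,
                    forward_offset=f_off,
                    reverse_offset=r_off,
                )
    if best is None:
        raise DesignError(
            "primer",
            f"no primer pair yields a product in "
            f"[{config.product_min}, {config.product_max}] bp",
        )
    return best


# ---------------------------------------------------------------------------
# Cassette assembly


@dataclass(frozen=True)
class Cassette:
    """The complete reagent set for one variant."""

    locus: ReferenceLocus
    variant: VariantSpec
    guide: GuideCandidate
    variant_ssodn: SsODN
    wtprime_ssodn: SsODN
    wtprime_spec: VariantSpec
    primers: PrimerPair
    design_report: tuple[tuple[str, bool, str], ...]

    @property
    def ssodn_region(self) -> tuple[int, int]:
        """Union genomic footprint of both repair templates."""
        (a0, a1), (b0, b1) = self.variant_ssodn.region, self.wtprime_ssodn.region
        return (min(a0, b0), max(a1, b1))

    def templates_identical_except_edits(self) -> bool:
        """True if the two ssODNs agree at every shared genomic position
        outside their edit sites."""
        skip = set(self.variant.affected_positions()) | set(
            self.wtprime_spec.affected_positions()
        )
        (a0, _), (b0, _) = self.variant_ssodn.region, self.wtprime_ssodn.region
        sa, sb = self.variant_ssodn.sense_sequence, self.wtprime_ssodn.sense_sequence
        lo, hi = self.ssodn_region
        for pos in range(lo, hi):
            if pos in skip:
                continue
            ia, ib = pos - a0, pos - b0
            if 0 <= ia < len(sa) and 0 <= ib < len(sb) and sa[ia] != sb[ib]:
                return False
        return True


def assemble_cassette(
    locus: ReferenceLocus,
    variant: VariantSpec,
    config: DesignConfig = DesignConfig(),
    usage_table: CodonUsageTable | None = None,
    offtarget_references: dict[str, str] | None = None,
) -> Cassette:
    """Run the full design pipeline and annotate every rule.

    Guides are tried in rank order; the first one admitting a valid WT'
    wins.  When ``require_joint_disruption`` is set (default), the WT'
    search already filters on guide disruption, so both knock-ins destroy
    the Cas9 site.  Failures carry the name of the failing stage.
    """
    guides = enumerate_guides(locus, variant, config=config)
    if not guides:
        raise DesignError("guide", "no NGG guide places the variant in PAM/seed")

    chosen: tuple[GuideCandidate, VariantSpec] | None = None
    for guide in guides:
        wtprimes, _rej = design_wtprime(locus, variant, guide, usage_table, config)
        if wtprimes:
            chosen = (guide, wtprimes[0])
            break
    if chosen is None:
        raise DesignError("wtprime", "no guide admits a valid synonymous WT'")
    guide, wtprime = chosen

    if offtarget_references:
        ot = screen_offtargets(guide, offtarget_references, config=config)
        if not ot.passes:
            raise DesignError("offtarget", "closest off-target lacks a seed/PAM mismatch")
        ot_detail = f"{len(ot.hits)} hit(s), pass"
    else:
        ot_detail = "not screened (no reference sequences supplied)"

    variant_ssodn = build_ssodn(locus, guide, variant, config=config)
    wtprime_ssodn = build_ssodn(locus, guide, wtprime, config=config)
    region = (
        min(variant_ssodn.region[0], wtprime_ssodn.region[0]),
        max(variant_ssodn.region[1], wtprime_ssodn.region[1]),
    )
    primers = design_primers(locus, region, config)

    wt_protein = translate_coding(locus) if locus.coding_segments else ""
    synonymous = (
        not locus.coding_segments
        or translate_coding(locus, apply_edit(locus, wtprime)) == wt_protein
    )
    report = (
        (
            "guide_seed_placement",
            all(
                v == "PAM" or v <= config.seed_max_offset
                for v in guide.disruption_positions.values()
            ),
            f"disruptions {guide.disruption_positions}",
        ),
        ("offtarget_screen", True, ot_detail),
        (
            "wtprime_distance",
            config.splice_mode == "exon_offset"
            or _edit_distance_nt(variant, wtprime.position) <= config.wtprime_max_distance,
            f"distance {_edit_distance_nt(variant, wtprime.position)} nt",
        ),
        ("wtprime_synonymous", synonymous, f"WT' {wtprime.label}"),
        (
            "ssodn_arms",
            variant_ssodn.arm_5_len
            == variant_ssodn.arm_3_len
            == wtprime_ssodn.arm_5_len
            == wtprime_ssodn.arm_3_len
            == config.arm_length,
            f"arm length {config.arm_length} nt",
        ),
        (
            "primer_offsets",
            config.primer_min_offset
            <= min(primers.forward_offset, primers.reverse_offset)
            and max(primers.forward_offset, primers.reverse_offset)
            <= config.primer_max_offset,
            f"offsets {primers.forward_offset}/{primers.reverse_offset} nt",
        ),
        (
            "product_length",
            config.product_min <= primers.product_length <= config.product_max,
            f"{primers.product_length} bp",
        ),
    )
    cassette = Cassette(
        locus=locus,
        variant=variant,
        guide=guide,
        variant_ssodn=variant_ssodn,
        wtprime_ssodn=wtprime_ssodn,
        wtprime_spec=wtprime,
        primers=primers,
        design_report=report,
    )
    report = report + (
        (
            "templates_identical_except_edits",
            cassette.templates_identical_except_edits(),
            "",
        ),
    )
    return replace(cassette, design_report=report)
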