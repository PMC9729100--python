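"""Synthetic loci and variant fixtures for desk-scale validation.

Real target loci are a few hundred bases of genomic context around a
coding variant.  These generators produce random loci of that shape and
single-nucleotide variants inside the coding region, for exercising the
designer and the downstream pipeline without any external sequence data.
"""

from __future__ import annotations

import numpy as np

from .design import Cassette, DesignConfig, DesignError, assemble_cassette
from .sequence import ReferenceLocus, VariantSpec

__all__ = ["random_locus", "random_snv", "design_fixtures"]


def random_locus(
    seed: int | np.random.Generator,
    length: int = 2000,
    coding: tuple[int, int] | None = None,
    locus_id: str = "synthetic_locus",
) -> ReferenceLocus:
    """A random A/C/G/T locus with one central coding segment (frame 0)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    if coding is None:
        margin = min(200, length // 5)
        coding = (margin, length - margin)
    return ReferenceLocus(
        locus_id=locus_id,
        sequence=seq,
        coding_segments=((coding[0], coding[1], 0),),
        strand_of_gene="+",
    )


def random_snv(
    locus: ReferenceLocus,
    rng: np.random.Generator,
    margin: int = 300,
    label: str = "snv",
) -> VariantSpec:
    """A random coding single-nucleotide variant, away from the locus edges.

    The margin keeps room for homology arms and primers on both sides.
    """
    lo = max(locus.coding_segments[0][0], margin)
    hi = min(locus.coding_segments[-1][1], len(locus) - margin)
    pos = int(rng.integers(lo, hi))
    ref = locus.sequence[pos]
    alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
    return VariantSpec(pos, ref, alt, label=f"{label}_{pos}{ref}>{alt}")


def design_fixtures(
    n: int,
    seed: int,
    config: DesignConfig = DesignConfig(),
    locus_length: int = 2000,
    max_attempts: int = 400,
) -> list[tuple[ReferenceLocus, VariantSpec, Cassette]]:
    """``n`` designable (locus, variant, cassette) fixtures, deterministically.

    Random SNVs are drawn on fresh random loci and run through the full
    designer; draws without a rule-conformant cassette (no suitable guide
    or no synonymous WT' nearby — expected for a fraction of random sites)
    are skipped.  Raises if the attempt budget is exhausted first.
    """
    rng = np.random.default_rng(seed)
    out = []
    for attempt in range(max_attempts):
        locus = random_locus(rng, length=locus_length, locus_id=f"locus_{attempt}")
        variant = random_snv(locus, rng, label=f"var{attempt}")
        try:
            cassette = assemble_cassette(locus, variant, config)
        except DesignError:
            continue
        out.append((locus, variant, cassette))
        if len(out) == n:
            return out
    raise RuntimeError(
        f"only {len(out)}/{n} designable fixtures within {max_attempts} attempts"
    )
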