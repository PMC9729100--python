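"""Simplified splice-motif screen for WT' candidates.

A synonymous normalization edit must not create a splice site.  This module
implements a position-frequency screen over the canonical 9-nt donor motif
(3 exonic + 6 intronic bases, consensus MAG|GTRAGT) and a 15-nt acceptor
motif (polypyrimidine tract + invariant AG + first exonic base).  A
candidate substitution is rejected when it raises a motif score above the
screen threshold at a window where the unedited sequence scored below it —
i.e. when the edit *creates* a motif, not when it sits inside a pre-existing
one.

The scores are heuristic (frequency averages scaled to [0, 1]) and
deliberately conservative; positions that must be allowed can be whitelisted
via ``allow_positions``.
"""

from __future__ import annotations

__all__ = ["donor_score", "acceptor_score", "creates_splice_site"]

# Base frequencies at donor positions -3..+6 (canonical mammalian values,
# rounded).  +1/+2 are the invariant GT.
_DONOR_FREQS = [
    {"A": 0.33, "C": 0.37, "G": 0.18, "T": 0.12},  # -3
    {"A": 0.60, "C": 0.13, "G": 0.12, "T": 0.15},  # -2
    {"A": 0.08, "C": 0.04, "G": 0.81, "T": 0.07},  # -1
    {"A": 0.00, "C": 0.00, "G": 1.00, "T": 0.00},  # +1
    {"A": 0.00, "C": 0.00, "G": 0.00, "T": 1.00},  # +2
    {"A": 0.59, "C": 0.03, "G": 0.35, "T": 0.03},  # +3
    {"A": 0.71, "C": 0.08, "G": 0.12, "T": 0.09},  # +4
    {"A": 0.06, "C": 0.06, "G": 0.84, "T": 0.04},  # +5
    {"A": 0.15, "C": 0.15, "G": 0.25, "T": 0.45},  # +6
]
_DONOR_MAX = sum(max(p.values()) for p in _DONOR_FREQS)

DONOR_LEN = 9
ACCEPTOR_LEN = 15

# Screen thresholds on the 0-1 score scale.
DONOR_THRESHOLD = 0.80
ACCEPTOR_THRESHOLD = 0.85


def donor_score(window: str) -> float:
    """Score a 9-nt window as a splice donor, scaled to [0, 1].

    Zero unless the invariant GT dinucleotide is present at +1/+2.
    """
    if len(window) != DONOR_LEN:
        raise ValueError(f"donor window must be {DONOR_LEN} nt")
    if window[3:5] != "GT":
        return 0.0
    score = sum(p.get(b, 0.0) for p, b in zip(_DONOR_FREQS, window))
    return score / _DONOR_MAX


def acceptor_score(window: str) -> float:
    """Score a 15-nt window as a splice acceptor, scaled to [0, 1].

    Zero unless the invariant AG sits at positions -2/-1 (window[12:14]);
    otherwise the score combines the pyrimidine content of the 12-nt tract
    upstream of the AG with the invariant dinucleotide.
    """
    if len(window) != ACCEPTOR_LEN:
        raise ValueError(f"acceptor window must be {ACCEPTOR_LEN} nt")
    if window[12:14] != "AG":
        return 0.0
    tract = window[:12]
    pyr = sum(1 for b in tract if b in "CT") / len(tract)
    return 0.4 + 0.6 * pyr


def _max_scores(sequence: str, position: int) -> tuple[float, float]:
    """Max donor / acceptor score over all windows covering ``position``."""
    best_d = 0.0
    for start in range(position - DONOR_LEN + 1, position + 1):
        if start < 0 or start + DONOR_LEN > len(sequence):
            continue
        best_d = max(best_d, donor_score(sequence[start : start + DONOR_LEN]))
    best_a = 0.0
    for start in range(position - ACCEPTOR_LEN + 1, position + 1):
        if start < 0 or start + ACCEPTOR_LEN > len(sequence):
            continue
        best_a = max(best_a, acceptor_score(sequence[start : start + ACCEPTOR_LEN]))
    return best_d, best_a


def creates_splice_site(
    reference: str,
    edited: str,
    position: int,
    donor_threshold: float = DONOR_THRESHOLD,
    acceptor_threshold: float = ACCEPTOR_THRESHOLD,
) -> bool:
    """True if a substitution at ``position`` creates a new splice motif.

    Both strands are screened: ``reference`` and ``edited`` must have equal
    length (substitutions only).
    """
    if len(reference) != len(edited):
        raise ValueError("splice screen is defined for substitutions only")
    from .sequence import reverse_complement

    for ref, edt, pos in (
        (reference, edited, position),
        (
            reverse_complement(reference),
            reverse_complement(edited),
            len(reference) - 1 - position,
        ),
    ):
        d_before, a_before = _max_scores(ref, pos)
        d_after, a_after = _max_scores(edt, pos)
        if d_after > donor_threshold and d_before <= donor_threshold:
            return True
        if a_after > acceptor_threshold and a_before <= acceptor_threshold:
            return True
    return False
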