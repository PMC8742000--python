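"""IUPAC motif handling for the LpnPI recognition site.

LpnPI is a methylation-dependent restriction enzyme whose recognition site
belongs to the CCDG class (D = A, G or T).  All scanning in this package is
expressed over IUPAC degenerate alphabets so the motif remains a plain
configuration string.
"""
from __future__ import annotations

import re

#: Default LpnPI recognition motif (vendor-documented site class).
DEFAULT_MOTIF = "CCDG"

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (case-insensitive, returns upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def validate_motif(motif: str) -> str:
    """Upper-case and validate an IUPAC motif; raise ``ValueError`` on bad characters."""
    motif = motif.upper()
    bad = sorted(set(motif) - set(IUPAC_CODES))
    if bad:
        raise ValueError(f"non-IUPAC characters in motif {motif!r}: {bad}")
    if len(motif) < 3:
        raise ValueError(f"motif {motif!r} shorter than 3 bp")
    return motif


def motif_regex(motif: str) -> re.Pattern[str]:
    """Compile an overlapping-match regex for an IUPAC motif.

    Uses a lookahead group so overlapping occurrences are all reported.
    """
    motif = validate_motif(motif)
    body = "".join(c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in motif)
    return re.compile(f"(?=({body}))")


def find_occurrences(seq: str, motif: str) -> list[tuple[int, str]]:
    """All occurrences of ``motif`` in ``seq``, on both strands.

    Returns sorted ``(position, strand)`` pairs where position is the 0-based
    start of the match on the forward sequence; minus-strand occurrences are
    matches of the motif's reverse complement, still reported in forward
    coordinates.  A palindromic match yields both strands at one position.
    """
    seq = seq.upper()
    fwd = motif_regex(motif)
    rev = motif_regex(reverse_complement(motif))
    hits = [(m.start(), "+") for m in fwd.finditer(seq)]
    hits += [(m.start(), "-") for m in rev.finditer(seq)]
    return sorted(set(hits))


def matches_at(seq: str, pos: int, motif: str) -> bool:
    """True if ``motif`` (forward orientation only) matches ``seq`` at ``pos``."""
    window = seq[pos:pos + len(motif)].upper()
    if len(window) != len(motif):
        return False
    return all(b in IUPAC_CODES[c] for b, c in zip(window, motif.upper()))
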