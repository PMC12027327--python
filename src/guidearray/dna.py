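"""Low-level DNA string utilities shared across the package.

All sequences are handled as uppercase ACGT python strings on the top
strand; circular molecules are linear strings with a declared origin and
are compared after rotation normalization (lexicographically minimal
rotation, Booth's algorithm).
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: BsaI / BsmBI recognition motifs on the top strand (site, revcomp-site).
BSAI_SITES = ("GGTCTC", "GAGACC")
BSMBI_SITES = ("CGTCTC", "GAGACG")

_VALID_RE = re.compile(r"^[ACGT]+$")


def normalize(seq: str) -> str:
    """Canonicalize a sequence: uppercase, RNA U -> DNA T, strip whitespace."""
    return seq.strip().upper().replace("U", "T")


def is_dna(seq: str) -> bool:
    return bool(_VALID_RE.match(seq))


def revcomp(seq: str) -> str:
    """Reverse complement of a top-strand sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindrome(seq: str) -> bool:
    """True if the duplex reads the same on both strands (self-complementary)."""
    return seq == revcomp(seq)


def find_sites(seq: str, motifs=BSAI_SITES) -> list[tuple[int, str]]:
    """All (start, motif) occurrences of the given top-strand motifs.

    Searching both a motif and its reverse complement covers both strands
    of the duplex.
    """
    hits = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = seq.find(motif, start + 1)
    return sorted(hits)


def has_sites(seq: str, motifs=BSAI_SITES) -> bool:
    return any(motif in seq for motif in motifs)


def min_rotation(seq: str) -> str:
    """Lexicographically minimal rotation of a circular sequence (Booth)."""
    if not seq:
        return seq
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)
    k = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s[k : k + n]


def rotations_equal(a: str, b: str) -> bool:
    """Equality of two circular sequences irrespective of origin choice."""
    return len(a) == len(b) and min_rotation(a) == min_rotation(b)
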