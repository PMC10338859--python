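"""Tandem-repeat decomposition of repeat oligonucleotides and DPR peptides.

Dipeptide repeat proteins (DPRs) and the repeat RNA oligonucleotides used to
probe them are periodic sequences: a poly(PR) 20-mer is twenty ``PR`` units
followed by a linker/tag, and a "poly(GAAGA)" oligo is a 5-nt unit repeated in
tandem.  These helpers find the minimal period of such a sequence and count
its repeat units, which is how the repeat content of a construct is reported.
"""

from __future__ import annotations

# BLI oligonucleotides (biotin tag stripped, RNA sense).  Both are five tandem
# copies of a 5-nt unit; the GAAGA-series unit is the GAAGA pentamer read
# circularly (GAGAA as synthesized).
GAAGA_OLIGO = "GAGAAGAGAAGAGAAGAGAAGAGAA"
AUAAU_OLIGO = "AUAAUAUAAUAUAAUAUAAUAUAAU"

# Synthetic 20-mer DPR peptides: 20 dipeptide units, then a GS linker and a
# FLAG tag (DYKDDDDK preceded by FEG).
PR20_PEPTIDE = "PRPRPRPRPRPRPRPRPRPRPRPRPRPRPRPRPRPRPRPRGSFEGDYKDDDDK"
GR20_PEPTIDE = "GRGRGRGRGRGRGRGRGRGRGRGRGRGRGRGRGRGRGRGRGSFEGDYKDDDDK"


def minimal_period(seq: str) -> int:
    """Smallest ``p`` such that ``seq[i] == seq[i - p]`` for all ``i >= p``.

    This is the minimal period in the string-combinatorics sense; a sequence
    with no internal repetition returns its own length.
    """
    if not seq:
        raise ValueError("empty sequence has no period")
    n = len(seq)
    for p in range(1, n + 1):
        if all(seq[i] == seq[i - p] for i in range(p, n)):
            return p
    return n  # pragma: no cover - loop always returns


def tandem_repeat_units(seq: str) -> tuple[str, int, str]:
    """Decompose ``seq`` into ``(unit, n_full, remainder)`` at its minimal period.

    ``unit`` is the first ``minimal_period(seq)`` characters, ``n_full`` the
    number of complete tandem copies and ``remainder`` any trailing partial
    copy (empty when the length is an exact multiple of the period).

    >>> tandem_repeat_units("AUAAUAUAAU")
    ('AUAAU', 2, '')
    """
    p = minimal_period(seq)
    return seq[:p], len(seq) // p, seq[(len(seq) // p) * p :]


def leading_dipeptide_units(peptide: str, unit: str = "PR") -> int:
    """Number of consecutive copies of ``unit`` at the start of ``peptide``.

    For a DPR construct this counts the repeat units preceding the linker,
    e.g. 20 for a PR20 peptide ending in a GS linker plus FLAG tag.
    """
    if len(unit) == 0:
        raise ValueError("unit must be non-empty")
    n = 0
    i = 0
    while peptide.startswith(unit, i):
        n += 1
        i += len(unit)
    return n
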