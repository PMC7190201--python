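"""Standard nuclear genetic code utilities.

The pipeline works exclusively in DNA alphabet (A, C, G, T); RNA input is
normalised on entry. The code table itself comes from Biopython's standard
table (NCBI table 1).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
STOP = "*"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


class GeneticCode:
    """The standard genetic code: 61 sense codons, 3 stops.

    Attributes
    ----------
    table : dict
        codon -> one-letter amino acid, or ``"*"`` for stop codons.
    sense_codons : tuple of str
        The 61 codons that encode an amino acid.
    stop_codons : frozenset of str
    """

    def __init__(self) -> None:
        ncbi = unambiguous_dna_by_id[1]
        self.table: dict[str, str] = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            self.table[stop] = STOP
        self.stop_codons = frozenset(ncbi.stop_codons)
        self.sense_codons = tuple(
            sorted(c for c in self.table if self.table[c] != STOP)
        )
        # amino acid -> sorted tuple of its codons (the synonymous family)
        self.families: dict[str, tuple[str, ...]] = {}
        for codon in self.sense_codons:
            aa = self.table[codon]
            self.families.setdefault(aa, ())
        for aa in self.families:
            self.families[aa] = tuple(
                sorted(c for c in self.sense_codons if self.table[c] == aa)
            )

    def amino_acid(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_sense(self, codon: str) -> bool:
        return codon in self.table and codon not in self.stop_codons

    def translate(self, cds: str) -> str:
        """Translate a CDS (length divisible by 3); stops become '*'."""
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        return "".join(self.table[cds[i : i + 3]] for i in range(0, len(cds), 3))

    def synonyms(self, codon: str) -> tuple[str, ...]:
        """All codons (including ``codon``) encoding the same amino acid."""
        return self.families[self.table[codon]]


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    return GeneticCode()
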