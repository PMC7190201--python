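"""tRNA pools, per-codon tAI weights and directed synonymous codon pairs.

The tRNA adaptation index of a codon sums the genomic copy numbers (tGCN)
of every tRNA that can decode it, each discounted by a wobble penalty::

    W(codon) = sum over decoders  (1 - s_ij) * tGCN(anticodon)

Watson-Crick pairing and I:U pairing carry no penalty (s = 0); the four
penalised third-position wobble pairings use the eukaryotic selective
constraints s_G:U = 0.7861, s_I:C = 0.4659, s_I:A = 0.9075 and
s_U:G = 0.6295.  Within each amino-acid family, codons are ranked by W and
split into a high- and a low-optimality class; a single-base synonymous
substitution between two family members is then a "tAI-up" or "tAI-down"
mutation according to the sign of W(alt) - W(ref).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .genetic_code import BASES, GeneticCode, normalize_dna, revcomp, standard_code

log = logging.getLogger(__name__)

# anticodon position 34 (5' base, pairing the codon's third base) used by the
# penalised wobble decoder, keyed by the codon's third base
_WOBBLE_34 = {"T": "G", "C": "A", "A": "A", "G": "T"}
_WOBBLE_S_ATTR = {"T": "s_GU", "C": "s_IC", "A": "s_IA", "G": "s_UG"}
# pairing name for census reporting, anticodon34:codon3
_WOBBLE_NAME = {"T": "G:U", "C": "I:C", "A": "I:A", "G": "U:G"}


@dataclass(frozen=True)
class WobblePenalties:
    """Selective constraints of penalised anticodon:codon wobble pairings.

    Values are the eukaryotic constants; Watson-Crick and I:U pairings are
    penalty-free by definition.
    """

    s_GU: float = 0.7861
    s_IC: float = 0.4659
    s_IA: float = 0.9075
    s_UG: float = 0.6295

    def __post_init__(self) -> None:
        for name in ("s_GU", "s_IC", "s_IA", "s_UG"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class TRNAPool:
    """Anticodon -> tRNA gene copy number (tGCN).

    Anticodons are DNA-alphabet strings written 5'->3' (position 34 first).
    Records whose anticodon could not be determined are tallied in
    ``undetermined`` and take no part in decoding.
    """

    copies: dict[str, int] = field(default_factory=dict)
    undetermined: int = 0

    def __post_init__(self) -> None:
        for anticodon, n in self.copies.items():
            if n < 0:
                raise ValueError(f"negative copy number for {anticodon}")

    @property
    def n_anticodons(self) -> int:
        return sum(1 for n in self.copies.values() if n > 0)

    @property
    def total_loci(self) -> int:
        return sum(self.copies.values())

    def tgcn(self, anticodon: str) -> int:
        return self.copies.get(anticodon, 0)

    def scaled(self, factor: int) -> "TRNAPool":
        return TRNAPool({a: n * factor for a, n in self.copies.items()})


# GtRNAdb FASTA headers carry the isotype and anticodon in the record name,
# e.g. ">Zea_mays_tRNA-Ala-AGC-1-1 ..." or legacy ">chr1.trna5-AlaAGC ...".
_HEADER_PATTERNS = (
    re.compile(r"tRNA-[A-Za-z]{2,4}-([A-Za-z]{3})\b"),
    re.compile(r"-(?:[A-Z][a-z]{2})([ACGTU]{3})\b"),
)


def anticodon_from_header(header: str) -> str | None:
    """Extract the anticodon from a GtRNAdb-dialect FASTA header.

    Returns the DNA-alphabet anticodon, or None when no anticodon can be
    recovered. Undetermined anticodons (``NNN``/``???``) return ``"NNN"``.
    """
    for pat in _HEADER_PATTERNS:
        m = pat.search(header)
        if m:
            ac = normalize_dna(m.group(1))
            if ac in {"NNN", "???"} or any(b not in BASES for b in ac):
                return "NNN"
            return ac
    if "???" in header or "NNN" in header:
        return "NNN"
    return None


def parse_trna_pool(trna_fasta: str | Path, exclude_pseudogenes: bool = False) -> TRNAPool:
    """Count tRNA gene copies per anticodon from a GtRNAdb-dialect FASTA.

    Each FASTA record is one tRNA locus; its anticodon is read from the
    header. Records without a recoverable anticodon are skipped with a
    warning; records with an undetermined (NNN) anticodon are counted
    separately and excluded from decoding. An empty file yields an empty
    (valid) pool.
    """
    copies: dict[str, int] = {}
    undetermined = 0
    for record in SeqIO.parse(str(trna_fasta), "fasta"):
        header = record.description
        if exclude_pseudogenes and "pseudo" in header.lower():
            continue
        ac = anticodon_from_header(header)
        if ac is None:
            log.warning("tRNA record %r: no recoverable anticodon, skipped", record.id)
            continue
        if ac == "NNN":
            undetermined += 1
            continue
        copies[ac] = copies.get(ac, 0) + 1
    return TRNAPool(copies, undetermined=undetermined)


def read_trna_counts_tsv(path: str | Path) -> TRNAPool:
    """Read a two-column TSV (anticodon<TAB>copies) into a pool."""
    df = pd.read_csv(path, sep="\t", header=None, names=["anticodon", "copies"], comment="#")
    copies = {
        normalize_dna(str(a)): int(n) for a, n in zip(df["anticodon"], df["copies"])
    }
    return TRNAPool(copies)


def decoding_pairs(
    codon: str, pool: TRNAPool, s: WobblePenalties | None = None
) -> list[tuple[str, float]]:
    """Anticodons in the pool that decode ``codon``, with their s penalties.

    The Watson-Crick decoder (reverse complement of the codon) carries
    s = 0; the single penalised wobble decoder is determined by the codon's
    third base (G:U, I:C, I:A or U:G pairing at anticodon position 34).
    Only anticodons actually present in the pool are returned.
    """
    s = s or WobblePenalties()
    code = standard_code()
    codon = normalize_dna(codon)
    if not code.is_sense(codon):
        raise ValueError(f"{codon} is not a sense codon; decoding undefined")
    out: list[tuple[str, float]] = []
    wc = revcomp(codon)
    if pool.tgcn(wc) > 0:
        out.append((wc, 0.0))
    wobble = _WOBBLE_34[codon[2]] + wc[1:]
    if wobble != wc and pool.tgcn(wobble) > 0:
        out.append((wobble, getattr(s, _WOBBLE_S_ATTR[codon[2]])))
    return out


def codon_weight(codon: str, pool: TRNAPool, s: WobblePenalties | None = None) -> float:
    """Absolute tAI weight W = sum (1 - s_ij) * tGCN over decoders; >= 0."""
    return sum(
        (1.0 - sij) * pool.tgcn(anticodon)
        for anticodon, sij in decoding_pairs(codon, pool, s)
    )


@dataclass
class CodonTaiTable:
    """Per-codon tAI weight, within-family rank and optimality class.

    ``rank`` is 1 for the highest-W codon of its amino-acid family (ties
    broken by alphabetical codon order); ``optimality`` splits each family
    half/half, odd sizes rounded toward "high".
    """

    W: dict[str, float]
    rank: dict[str, int]
    optimality: dict[str, str]  # "high" | "low"

    def direction(self, ref_codon: str, alt_codon: str) -> str:
        """tai_up / tai_down / tie for a synonymous ref -> alt change."""
        w_ref, w_alt = self.W[ref_codon], self.W[alt_codon]
        if w_alt > w_ref:
            return "tai_up"
        if w_alt < w_ref:
            return "tai_down"
        return "tie"

    def normalized(self) -> dict[str, float]:
        """dos Reis-style reporting transform: W / max(W), zeros replaced by
        the geometric mean of the nonzero normalised weights. Within-family
        order is unchanged, so classification never depends on this."""
        import numpy as np

        wmax = max(self.W.values())
        if wmax == 0:
            return {c: 0.0 for c in self.W}
        norm = {c: w / wmax for c, w in self.W.items()}
        nonzero = [v for v in norm.values() if v > 0]
        gmean = float(np.exp(np.mean(np.log(nonzero))))
        return {c: (v if v > 0 else gmean) for c, v in norm.items()}

    def to_frame(self, code: GeneticCode | None = None) -> pd.DataFrame:
        code = code or standard_code()
        rows = [
            {
                "codon": c,
                "aa": code.amino_acid(c),
                "W": self.W[c],
                "rank": self.rank[c],
                "class": self.optimality[c],
            }
            for c in sorted(self.W)
        ]
        return pd.DataFrame(rows)


def build_tai_table(
    pool: TRNAPool,
    s: WobblePenalties | None = None,
    code: GeneticCode | None = None,
) -> CodonTaiTable:
    """Compute W for all 61 sense codons, rank within families, split classes.

    The class split is half/half per family (2 v 2 for four-codon families,
    3 v 3 for six-codon families); odd family sizes round toward "high"
    (Ile 2 high / 1 low; Met and Trp high). For the standard code this
    yields 32 high and 29 low codons for any pool.
    """
    code = code or standard_code()
    W = {c: codon_weight(c, pool, s) for c in code.sense_codons}
    rank: dict[str, int] = {}
    optimality: dict[str, str] = {}
    for family in code.families.values():
        ordered = sorted(family, key=lambda c: (-W[c], c))
        n_high = ceil(len(family) / 2)
        for i, codon in enumerate(ordered):
            rank[codon] = i + 1
            optimality[codon] = "high" if i < n_high else "low"
    return CodonTaiTable(W=W, rank=rank, optimality=optimality)


@dataclass(frozen=True)
class DirectedPair:
    """An ordered synonymous codon pair reachable by one base substitution."""

    from_codon: str
    to_codon: str
    position: int  # 1-3, the mutated codon position
    direction: str  # tai_up | tai_down | tie


def single_base_synonymous_neighbors(
    codon: str, code: GeneticCode | None = None
) -> list[tuple[str, int]]:
    """Sense codons one substitution away that encode the same amino acid."""
    code = code or standard_code()
    out = []
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if code.is_sense(alt) and code.amino_acid(alt) == code.amino_acid(codon):
            out.append((alt, pos + 1))
    return out


def enumerate_directed_pairs(
    tai: CodonTaiTable, code: GeneticCode | None = None
) -> list[DirectedPair]:
    """All ordered single-base synonymous codon pairs with tAI direction.

    For every pair labelled tai_up the reverse pair is tai_down; equal-W
    pairs are labelled tie (and belong to neither the up nor the down set).
    """
    code = code or standard_code()
    pairs = []
    for codon in code.sense_codons:
        for alt, pos in single_base_synonymous_neighbors(codon, code):
            pairs.append(DirectedPair(codon, alt, pos, tai.direction(codon, alt)))
    return pairs


def pairs_to_frame(pairs: Iterable[DirectedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "from": p.from_codon,
                "to": p.to_codon,
                "position": p.position,
                "direction": p.direction,
            }
            for p in pairs
        ]
    )


def wobble_pair_census(
    pool: TRNAPool, code: GeneticCode | None = None
) -> dict[str, int]:
    """Count realised penalised anticodon:codon wobble pairs.

    For each sense codon, the penalised wobble decoder (G:U, I:C, I:A or
    U:G at anticodon position 34) is counted when that anticodon is present
    in the pool. Maize's pool, for instance, realises 15 G:U, 9 I:C, 9 I:A
    and 13 U:G pairs.
    """
    code = code or standard_code()
    census = {"G:U": 0, "I:C": 0, "I:A": 0, "U:G": 0}
    for codon in code.sense_codons:
        wc = revcomp(codon)
        wobble = _WOBBLE_34[codon[2]] + wc[1:]
        if wobble != wc and pool.tgcn(wobble) > 0:
            census[_WOBBLE_NAME[codon[2]]] += 1
    return census


def unused_anticodons(pool: TRNAPool, code: GeneticCode | None = None) -> set[str]:
    """Anticodons present in the pool that decode no sense codon."""
    code = code or standard_code()
    used: set[str] = set()
    for codon in code.sense_codons:
        wc = revcomp(codon)
        used.add(wc)
        used.add(_WOBBLE_34[codon[2]] + wc[1:])
    return {a for a, n in pool.copies.items() if n > 0 and a not in used}
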