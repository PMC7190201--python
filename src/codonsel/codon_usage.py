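"""Expression (RPKM), highly expressed gene selection, codon usage weights
and gene-level CAI.

Codon-level usage weights w_ij follow the classical relative-adaptiveness
definition: the count of a codon in a reference set of highly expressed
genes divided by the maximum count among its synonymous codons, so
w_ij in [0, 1] with at least one codon per observed family at 1. Gene CAI
is the geometric mean of w_ij over the gene's sense codons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import BASES, GeneticCode, normalize_dna, standard_code

log = logging.getLogger(__name__)


@dataclass
class GeneRecord:
    """One protein-coding gene with its CDS and expression measurements."""

    gene_id: str
    cds: str
    read_count: int = 0
    rpkm: float = 0.0
    structured_pct: float | None = None  # fraction of CDS in RNA structure

    @property
    def length_bp(self) -> int:
        return len(self.cds)

    @property
    def gc(self) -> float:
        return gc_metrics(self.cds)[0]

    @property
    def gc3(self) -> float:
        return gc_metrics(self.cds)[1]


def compute_rpkm(read_count: float, cds_length_bp: int, total_mapped_reads: float) -> float:
    """Reads per kilobase of CDS per million mapped reads."""
    if cds_length_bp <= 0:
        raise ValueError("CDS length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return read_count / (cds_length_bp / 1000.0) / (total_mapped_reads / 1e6)


def select_high_expression(
    genes: Sequence[GeneRecord], fraction: float = 0.5
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split genes into (high, low) expression sets by RPKM.

    Genes are sorted by RPKM descending, ties broken by gene id; the top
    ``fraction`` (ceiling) forms the high set.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ranked = sorted(genes, key=lambda g: (-g.rpkm, g.gene_id))
    n_high = math.ceil(len(ranked) * fraction)
    return list(ranked[:n_high]), list(ranked[n_high:])


def validate_cds(cds: str, gene_id: str = "?", code: GeneticCode | None = None) -> str:
    """Normalise and validate a CDS: length divisible by 3, no internal stop.

    Raises ValueError on violation; ambiguous bases are tolerated (codons
    containing them are simply not counted downstream).
    """
    code = code or standard_code()
    cds = normalize_dna(cds)
    if not cds:
        raise ValueError(f"{gene_id}: empty CDS")
    if len(cds) % 3:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
    for i in range(0, len(cds) - 3, 3):
        codon = cds[i : i + 3]
        if codon in code.stop_codons:
            raise ValueError(f"{gene_id}: internal stop codon at position {i + 1}")
    return cds


@dataclass
class CodonUsageTable:
    """Per-codon counts and relative-adaptiveness weights w_ij.

    ``w`` maps each sense codon of an *observed* amino-acid family to
    count / max-family-count; codons of never-observed families are absent
    (missing, not zero).
    """

    counts: dict[str, int]
    w: dict[str, float]

    def weight(self, codon: str) -> float | None:
        """w_ij, or None when the codon's family was never observed."""
        return self.w.get(codon)

    def to_frame(self, code: GeneticCode | None = None) -> pd.DataFrame:
        code = code or standard_code()
        rows = [
            {
                "codon": c,
                "aa": code.amino_acid(c),
                "count": self.counts.get(c, 0),
                "w": self.w.get(c, float("nan")),
            }
            for c in code.sense_codons
        ]
        return pd.DataFrame(rows)


def count_codons(cds: str, code: GeneticCode | None = None) -> dict[str, int]:
    """Sense-codon counts of one validated CDS.

    The terminal stop codon and any codon containing an ambiguous base are
    excluded.
    """
    code = code or standard_code()
    counts: dict[str, int] = {}
    end = len(cds) - 3 if cds[-3:] in code.stop_codons else len(cds)
    for i in range(0, end, 3):
        codon = cds[i : i + 3]
        if any(b not in BASES for b in codon):
            continue
        if code.is_sense(codon):
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def build_usage_table(
    genes: Iterable[GeneRecord | str], code: GeneticCode | None = None
) -> CodonUsageTable:
    """Accumulate codon counts over a gene set and derive w_ij.

    Genes whose CDS fails validation (internal stop, length) are skipped
    with a warning. ``genes`` may be GeneRecords or raw CDS strings.
    """
    code = code or standard_code()
    counts: dict[str, int] = {}
    for g in genes:
        gene_id = g.gene_id if isinstance(g, GeneRecord) else "?"
        cds = g.cds if isinstance(g, GeneRecord) else g
        try:
            cds = validate_cds(cds, gene_id, code)
        except ValueError as exc:
            log.warning("gene skipped in usage table: %s", exc)
            continue
        for codon, n in count_codons(cds, code).items():
            counts[codon] = counts.get(codon, 0) + n
    w: dict[str, float] = {}
    for family in code.families.values():
        fam_max = max(counts.get(c, 0) for c in family)
        if fam_max == 0:
            continue  # family never observed: weights missing, not zero
        for c in family:
            w[c] = counts.get(c, 0) / fam_max
    return CodonUsageTable(counts=counts, w=w)


def gene_cai(
    cds: str, usage: CodonUsageTable, code: GeneticCode | None = None
) -> tuple[float, int]:
    """Gene CAI: geometric mean of w_ij over the gene's sense codons.

    Codons with w_ij = 0 or missing cannot enter a geometric mean and are
    skipped; the skip count is returned alongside. Raises ValueError when no
    codon is scorable.
    """
    code = code or standard_code()
    cds = validate_cds(cds, code=code)
    logs = []
    skipped = 0
    for codon, n in count_codons(cds, code).items():
        wij = usage.weight(codon)
        if wij is None or wij <= 0.0:
            skipped += n
            continue
        logs.extend([math.log(wij)] * n)
    if not logs:
        raise ValueError("gene has no scorable codons for CAI")
    return float(math.exp(np.mean(logs))), skipped


def gc_metrics(cds: str) -> tuple[float, float]:
    """(GC, GC3): G+C fraction over all positions and at third positions."""
    cds = normalize_dna(cds)
    if not cds:
        raise ValueError("empty sequence")
    gc = sum(1 for b in cds if b in "GC") / len(cds)
    third = cds[2::3]
    if not third:
        raise ValueError("sequence shorter than one codon")
    gc3 = sum(1 for b in third if b in "GC") / len(third)
    return gc, gc3


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """gene id -> CDS sequence; duplicate ids keep the longest record."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_dna(str(rec.seq))
        if rec.id not in out or len(seq) > len(out[rec.id]):
            out[rec.id] = seq
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression table with gene_id and read_count and/or rpkm columns."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression TSV needs a gene_id column")
    if "read_count" not in df.columns and "rpkm" not in df.columns:
        raise ValueError("expression TSV needs read_count or rpkm")
    return df


def build_gene_records(
    cds_by_id: dict[str, str],
    expression: pd.DataFrame | None = None,
    structured: dict[str, float] | None = None,
) -> list[GeneRecord]:
    """Join CDS sequences with expression; compute RPKM when only raw
    read counts are given (library size = sum of counts over these genes)."""
    counts: dict[str, int] = {}
    rpkm: dict[str, float] = {}
    if expression is not None:
        if "read_count" in expression.columns:
            counts = dict(
                zip(expression["gene_id"], expression["read_count"].astype(int))
            )
        if "rpkm" in expression.columns:
            rpkm = dict(zip(expression["gene_id"], expression["rpkm"].astype(float)))
        elif counts:
            total = sum(counts.get(g, 0) for g in cds_by_id)
            for g, cds in cds_by_id.items():
                rpkm[g] = compute_rpkm(counts.get(g, 0), len(cds), total) if total else 0.0
    records = []
    for gene_id, cds in sorted(cds_by_id.items()):
        records.append(
            GeneRecord(
                gene_id=gene_id,
                cds=cds,
                read_count=counts.get(gene_id, 0),
                rpkm=rpkm.get(gene_id, 0.0),
                structured_pct=(structured or {}).get(gene_id),
            )
        )
    return records
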