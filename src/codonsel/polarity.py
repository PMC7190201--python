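"""Two-outgroup polarization of CDS sites: fixed, polymorphic or excluded.

The ancestral state of a focal-species site is taken from two outgroup
species: the site is usable only when both outgroups agree, carry a real
base (no gap or N) at the orthologous alignment column, and are themselves
monomorphic. A usable site segregating two alleles within the focal species
is polymorphic (ancestral = shared outgroup base; DAF = derived-allele
frequency); a monomorphic focal site whose base differs from the shared
outgroup base is a fixed difference. Allele frequencies outside the
[0.02, 0.98] band (bounds inclusive) are treated as sequencing noise /
monomorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .genetic_code import normalize_dna

BAND_LOW = 0.02
BAND_HIGH = 0.98

EXCLUSION_REASONS = (
    "no_change",               # monomorphic, equal to shared outgroup base
    "outgroup_mismatch",       # the two outgroups disagree
    "outgroup_gap",            # gap or N in an outgroup at this column
    "outgroup_polymorphic",    # site polymorphic within an outgroup
    "focal_gap",               # no focal base in this alignment column
    "multi_allelic",           # > 2 alleles survive the frequency band
    "ancestral_not_segregating",  # neither retained allele matches outgroups
)


@dataclass
class SiteRecord:
    gene_id: str
    cds_pos: int  # 1-based focal CDS coordinate
    ref_base: str
    status: str  # polymorphic | fixed | excluded
    reason: str = ""  # exclusion reason code, empty otherwise
    out1_base: str = ""
    out2_base: str = ""
    ancestral: str = ""
    derived: str = ""
    daf: float | None = None
    maf: float | None = None
    frequencies: dict[str, float] = field(default_factory=dict)


def frequency_band_filter(
    frequencies: Mapping[str, float],
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
) -> dict[str, float]:
    """Retain alleles with frequency in [low, high], renormalised.

    An allele above ``high`` makes the site monomorphic for that allele;
    alleles below ``low`` are dropped as sequencing noise. The site is
    polymorphic iff at least two alleles survive.
    """
    total = sum(frequencies.values())
    if total > 1.0 + 1e-6:
        raise ValueError(f"allele frequencies sum to {total} > 1")
    for f in frequencies.values():
        if f < 0:
            raise ValueError("negative allele frequency")
    dominant = [a for a, f in frequencies.items() if f > high]
    if dominant:
        return {dominant[0]: 1.0}
    retained = {a: f for a, f in frequencies.items() if low <= f <= high}
    tot = sum(retained.values())
    if tot > 0:
        retained = {a: f / tot for a, f in retained.items()}
    return retained


def minor_allele_frequency(frequencies: Mapping[str, float]) -> float:
    """Frequency of the second most abundant allele.

    Computed on the raw (outgroup-free) frequencies; raises on monomorphic
    input. Equals min(DAF, 1 - DAF) for renormalised bi-allelic sites.
    """
    positive = sorted((f for f in frequencies.values() if f > 0), reverse=True)
    if len(positive) < 2:
        raise ValueError("MAF undefined for a monomorphic site")
    return positive[1]


def polarize_site(
    gene_id: str,
    cds_pos: int,
    ref_base: str,
    frequencies: Mapping[str, float],
    out1_base: str,
    out2_base: str,
    out1_polymorphic: bool = False,
    out2_polymorphic: bool = False,
    band: tuple[float, float] = (BAND_LOW, BAND_HIGH),
) -> SiteRecord:
    """Call one focal CDS site fixed / polymorphic / excluded.

    ``frequencies`` are the focal-species allele frequencies; an empty
    mapping means the site is uncovered by variant data and is called from
    the reference base alone (monomorphic at ``ref_base``).
    """
    ref_base = normalize_dna(ref_base)
    out1 = normalize_dna(out1_base) if out1_base else out1_base
    out2 = normalize_dna(out2_base) if out2_base else out2_base
    freqs = {normalize_dna(a): f for a, f in frequencies.items()}

    rec = SiteRecord(
        gene_id=gene_id, cds_pos=cds_pos, ref_base=ref_base,
        status="excluded", out1_base=out1, out2_base=out2, frequencies=dict(freqs),
    )
    retained = frequency_band_filter(freqs, *band) if freqs else {ref_base: 1.0}
    if len(retained) >= 2:
        try:
            rec.maf = minor_allele_frequency(freqs if len(freqs) >= 2 else retained)
        except ValueError:
            rec.maf = None

    if out1 in ("-", "N", "") or out2 in ("-", "N", ""):
        rec.reason = "outgroup_gap"
        return rec
    if out1 != out2:
        rec.reason = "outgroup_mismatch"
        return rec
    if out1_polymorphic or out2_polymorphic:
        rec.reason = "outgroup_polymorphic"
        return rec
    ancestral = out1

    if len(retained) > 2:
        rec.reason = "multi_allelic"
        return rec
    if len(retained) == 2:
        if ancestral not in retained:
            rec.reason = "ancestral_not_segregating"
            return rec
        derived = next(a for a in retained if a != ancestral)
        rec.status = "polymorphic"
        rec.ancestral = ancestral
        rec.derived = derived
        rec.daf = retained[derived]
        return rec

    focal_base = next(iter(retained))
    if focal_base not in "ACGT":
        rec.reason = "focal_gap"
        return rec
    if focal_base != ancestral:
        rec.status = "fixed"
        rec.ancestral = ancestral
        rec.derived = focal_base
        rec.daf = 1.0
    else:
        rec.reason = "no_change"
    return rec


@dataclass
class AlignedTriple:
    """A gapped three-way CDS alignment: focal species plus two outgroups."""

    gene_id: str
    focal: str
    out1: str
    out2: str

    def __post_init__(self) -> None:
        self.focal = normalize_dna(self.focal)
        self.out1 = normalize_dna(self.out1)
        self.out2 = normalize_dna(self.out2)
        if not len(self.focal) == len(self.out1) == len(self.out2):
            raise ValueError(f"{self.gene_id}: aligned lengths differ")

    @property
    def cds_length(self) -> int:
        return sum(1 for b in self.focal if b != "-")

    def column_map(self) -> dict[int, int]:
        """aligned column (0-based) -> focal CDS position (1-based)."""
        mapping = {}
        pos = 0
        for col, base in enumerate(self.focal):
            if base != "-":
                pos += 1
                mapping[col] = pos
        return mapping


def read_aligned_triples(
    path: str | Path,
    focal_tag: str = "focal",
    out1_tag: str = "out1",
    out2_tag: str = "out2",
) -> list[AlignedTriple]:
    """Read aligned multi-FASTA triples.

    Record ids follow ``<gene_id>|<role>`` with roles focal/out1/out2;
    every gene must contribute exactly one record per role (a strict 1:1:1
    orthology check).
    """
    per_gene: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"alignment record id {rec.id!r} lacks '|role' tag")
        gene_id, role = rec.id.rsplit("|", 1)
        if role in per_gene.setdefault(gene_id, {}):
            raise ValueError(f"{gene_id}: duplicate {role} record (not 1:1:1)")
        per_gene[gene_id][role] = str(rec.seq)
    triples = []
    for gene_id, seqs in sorted(per_gene.items()):
        missing = {focal_tag, out1_tag, out2_tag} - set(seqs)
        if missing:
            raise ValueError(f"{gene_id}: missing alignment records {sorted(missing)}")
        triples.append(
            AlignedTriple(gene_id, seqs[focal_tag], seqs[out1_tag], seqs[out2_tag])
        )
    return triples


def walk_alignment(
    triple: AlignedTriple,
    frequencies_by_pos: Mapping[int, Mapping[str, float]] | None = None,
    outgroup_poly_positions: Iterable[int] = (),
    band: tuple[float, float] = (BAND_LOW, BAND_HIGH),
) -> list[SiteRecord]:
    """Emit one SiteRecord per focal CDS position of an aligned triple.

    ``frequencies_by_pos`` maps focal CDS positions (1-based) to focal
    allele-frequency dicts; uncovered positions are called from the
    alignment alone. ``outgroup_poly_positions`` flags focal CDS positions
    whose orthologous outgroup site is polymorphic.
    """
    frequencies_by_pos = frequencies_by_pos or {}
    poly_flags = set(outgroup_poly_positions)
    records = []
    colmap = triple.column_map()
    for col in range(len(triple.focal)):
        if col not in colmap:  # outgroup-specific insertion: no focal base
            continue
        pos = colmap[col]
        records.append(
            polarize_site(
                triple.gene_id,
                pos,
                triple.focal[col],
                frequencies_by_pos.get(pos, {}),
                triple.out1[col],
                triple.out2[col],
                out1_polymorphic=pos in poly_flags,
                out2_polymorphic=False,
                band=band,
            )
        )
    if len(records) != triple.cds_length:
        raise ValueError(f"{triple.gene_id}: column map inconsistency")
    return records


def read_allele_frequencies(path: str | Path) -> dict[str, dict[int, dict[str, float]]]:
    """Long-format allele TSV (gene_id, cds_pos, allele, freq) ->
    nested mapping gene -> position -> allele -> frequency."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, dict[str, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), {}).setdefault(int(row.cds_pos), {})[
            normalize_dna(str(row.allele))
        ] = float(row.freq)
    return out


def sites_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    cols = [
        "gene_id", "cds_pos", "ref_base", "status", "reason",
        "out1_base", "out2_base", "ancestral", "derived", "daf", "maf",
    ]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in records], columns=cols
    )
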