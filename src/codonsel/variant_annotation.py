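"""Classify single-base CDS changes and attach tAI / CAI deltas.

A variant is synonymous when the altered codon encodes the same amino acid,
nonsense when it becomes a stop, nonsynonymous otherwise. Synonymous
variants additionally carry the direction and magnitude of the tAI change
(W(alt) - W(ref)) and of the usage-weight change (w_ij(alt) - w_ij(ref)).
Coordinates are 1-based on the coding strand of the CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .codon_usage import CodonUsageTable
from .genetic_code import BASES, GeneticCode, normalize_dna, standard_code
from .trna_tai import CodonTaiTable

log = logging.getLogger(__name__)

CLASSES = ("synonymous", "nonsynonymous", "nonsense")


@dataclass
class VariantAnnotation:
    gene_id: str
    cds_pos: int  # 1-based position in the CDS
    codon_index: int  # 1-based codon number
    codon_pos: int  # 1-3 within the codon
    ref_codon: str
    alt_codon: str
    functional_class: str  # synonymous | nonsynonymous | nonsense
    tai_direction: str = "n/a"  # up | down | tie | n/a
    cai_direction: str = "n/a"  # up | down | tie | missing | n/a
    delta_tai: float | None = None
    delta_cai: float | None = None

    @property
    def ref_base(self) -> str:
        return self.ref_codon[self.codon_pos - 1]

    @property
    def alt_base(self) -> str:
        return self.alt_codon[self.codon_pos - 1]


class ReferenceMismatch(ValueError):
    pass


class TerminalStopVariant(ValueError):
    """Variant falls in the terminal stop codon; excluded from analysis."""


def annotate_variant(
    cds: str,
    position: int,
    ref_base: str,
    alt_base: str,
    tai: CodonTaiTable | None = None,
    usage: CodonUsageTable | None = None,
    gene_id: str = "?",
    code: GeneticCode | None = None,
) -> VariantAnnotation:
    """Annotate one single-base change at a 1-based CDS position.

    Requires the CDS to match ``ref_base`` at ``position`` and the reference
    codon to be a sense codon; variants in the terminal stop codon raise
    TerminalStopVariant. tAI / CAI directions are attached only for
    synonymous changes; a missing usage weight yields cai_direction
    "missing".
    """
    code = code or standard_code()
    cds = normalize_dna(cds)
    ref_base = normalize_dna(ref_base)
    alt_base = normalize_dna(alt_base)
    if not 1 <= position <= len(cds):
        raise ValueError(f"{gene_id}: position {position} outside CDS of {len(cds)} bp")
    if ref_base == alt_base or alt_base not in BASES:
        raise ValueError(f"{gene_id}:{position}: invalid allele pair {ref_base}>{alt_base}")
    if cds[position - 1] != ref_base:
        raise ReferenceMismatch(
            f"{gene_id}:{position}: CDS has {cds[position - 1]}, variant claims {ref_base}"
        )
    idx = (position - 1) // 3
    within = (position - 1) % 3
    ref_codon = cds[idx * 3 : idx * 3 + 3]
    if any(b not in BASES for b in ref_codon):
        raise ValueError(f"{gene_id}:{position}: codon {ref_codon} contains ambiguous base")
    if code.is_stop(ref_codon):
        raise TerminalStopVariant(
            f"{gene_id}:{position}: reference codon {ref_codon} is a stop codon"
        )
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    if code.is_stop(alt_codon):
        fclass = "nonsense"
    elif code.amino_acid(alt_codon) == code.amino_acid(ref_codon):
        fclass = "synonymous"
    else:
        fclass = "nonsynonymous"

    ann = VariantAnnotation(
        gene_id=gene_id,
        cds_pos=position,
        codon_index=idx + 1,
        codon_pos=within + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        functional_class=fclass,
    )
    if fclass == "synonymous":
        if tai is not None:
            ann.delta_tai = tai.W[alt_codon] - tai.W[ref_codon]
            ann.tai_direction = {
                "tai_up": "up", "tai_down": "down", "tie": "tie"
            }[tai.direction(ref_codon, alt_codon)]
        if usage is not None:
            w_ref, w_alt = usage.weight(ref_codon), usage.weight(alt_codon)
            if w_ref is None or w_alt is None:
                ann.cai_direction = "missing"
            else:
                ann.delta_cai = w_alt - w_ref
                ann.cai_direction = (
                    "up" if w_alt > w_ref else "down" if w_alt < w_ref else "tie"
                )
    return ann


def annotate_site_change(
    cds: str,
    position: int,
    from_base: str,
    to_base: str,
    tai: CodonTaiTable | None = None,
    usage: CodonUsageTable | None = None,
    gene_id: str = "?",
    code: GeneticCode | None = None,
) -> VariantAnnotation:
    """Annotate a polarized ancestral -> derived change in its focal codon.

    Unlike :func:`annotate_variant`, the CDS base at ``position`` may be
    either allele (for a fixed difference the CDS carries the derived
    base). Both codon versions are built by substitution into the focal
    codon; a stop codon on either side makes the change nonsense (stop
    gain or stop loss).
    """
    code = code or standard_code()
    cds = normalize_dna(cds)
    from_base = normalize_dna(from_base)
    to_base = normalize_dna(to_base)
    if not 1 <= position <= len(cds):
        raise ValueError(f"{gene_id}: position {position} outside CDS of {len(cds)} bp")
    if from_base == to_base or {from_base, to_base} - set(BASES):
        raise ValueError(f"{gene_id}:{position}: invalid allele pair {from_base}>{to_base}")
    if cds[position - 1] not in (from_base, to_base):
        raise ReferenceMismatch(
            f"{gene_id}:{position}: CDS base {cds[position - 1]} matches neither allele"
        )
    idx = (position - 1) // 3
    within = (position - 1) % 3
    focal_codon = cds[idx * 3 : idx * 3 + 3]
    if any(b not in BASES for b in focal_codon):
        raise ValueError(f"{gene_id}:{position}: codon {focal_codon} contains ambiguous base")
    ref_codon = focal_codon[:within] + from_base + focal_codon[within + 1 :]
    alt_codon = focal_codon[:within] + to_base + focal_codon[within + 1 :]

    if code.is_stop(alt_codon) or code.is_stop(ref_codon):
        fclass = "nonsense"
    elif code.amino_acid(alt_codon) == code.amino_acid(ref_codon):
        fclass = "synonymous"
    else:
        fclass = "nonsynonymous"

    ann = VariantAnnotation(
        gene_id=gene_id,
        cds_pos=position,
        codon_index=idx + 1,
        codon_pos=within + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        functional_class=fclass,
    )
    if fclass == "synonymous":
        if tai is not None:
            ann.delta_tai = tai.W[alt_codon] - tai.W[ref_codon]
            ann.tai_direction = {
                "tai_up": "up", "tai_down": "down", "tie": "tie"
            }[tai.direction(ref_codon, alt_codon)]
        if usage is not None:
            w_ref, w_alt = usage.weight(ref_codon), usage.weight(alt_codon)
            if w_ref is None or w_alt is None:
                ann.cai_direction = "missing"
            else:
                ann.delta_cai = w_alt - w_ref
                ann.cai_direction = (
                    "up" if w_alt > w_ref else "down" if w_alt < w_ref else "tie"
                )
    return ann


def batch_annotate(
    variants: pd.DataFrame,
    cds_by_id: dict[str, str],
    tai: CodonTaiTable | None = None,
    usage: CodonUsageTable | None = None,
    code: GeneticCode | None = None,
) -> tuple[list[VariantAnnotation], dict[str, int]]:
    """Annotate a variant table (gene_id, cds_pos, ref, alt columns).

    Returns the annotations plus a tally: per-class counts, synonymous
    direction counts, and counts of rejected rows by reason.
    """
    tally = {
        "synonymous": 0,
        "nonsynonymous": 0,
        "nonsense": 0,
        "syn_tai_up": 0,
        "syn_tai_down": 0,
        "syn_tai_tie": 0,
        "rejected_unknown_gene": 0,
        "rejected_reference_mismatch": 0,
        "rejected_terminal_stop": 0,
        "rejected_invalid": 0,
    }
    annotations: list[VariantAnnotation] = []
    for row in variants.itertuples(index=False):
        gene_id = str(row.gene_id)
        if gene_id not in cds_by_id:
            tally["rejected_unknown_gene"] += 1
            continue
        try:
            ann = annotate_variant(
                cds_by_id[gene_id], int(row.cds_pos), str(row.ref), str(row.alt),
                tai=tai, usage=usage, gene_id=gene_id, code=code,
            )
        except ReferenceMismatch:
            tally["rejected_reference_mismatch"] += 1
            continue
        except TerminalStopVariant:
            tally["rejected_terminal_stop"] += 1
            continue
        except ValueError:
            tally["rejected_invalid"] += 1
            continue
        annotations.append(ann)
        tally[ann.functional_class] += 1
        if ann.functional_class == "synonymous" and ann.tai_direction != "n/a":
            tally[f"syn_tai_{ann.tai_direction}"] += 1
    return annotations, tally


def annotations_to_frame(annotations: list[VariantAnnotation]) -> pd.DataFrame:
    cols = [
        "gene_id", "cds_pos", "codon_index", "codon_pos", "ref_codon",
        "alt_codon", "functional_class", "tai_direction", "cai_direction",
        "delta_tai", "delta_cai",
    ]
    return pd.DataFrame(
        [{c: getattr(a, c) for c in cols} for a in annotations], columns=cols
    )
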