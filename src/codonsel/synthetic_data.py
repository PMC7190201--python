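"""Synthetic study-scale datasets for the whole pipeline.

The generator emits every input the pipeline consumes — a CDS set, a tRNA
pool (GtRNAdb-dialect FASTA and a counts TSV), an expression table, aligned
focal+two-outgroup triples, and a focal allele-frequency table — together
with a ground-truth ledger of every planted mutation. Planted synonymous
mutations are drawn from the directed codon-pair table of the generated
pool, so their tAI-up / tAI-down labels are exact by construction; derived
allele frequencies come from class-specific Beta distributions (the up
class right-shifted relative to the down class, nonsense left-shifted),
which emulates the rank structure of a frequency spectrum under weak
selection without simulating explicit population dynamics.

Outgroup sequences equal the ancestral focal sequence except at planted
fixed differences (where the focal allele is derived), planted
disagreement / gap / outgroup-polymorphism sites (which the polarization
stage must exclude), and occasional outgroup-specific insertions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .codon_usage import compute_rpkm
from .genetic_code import BASES, GeneticCode, revcomp, standard_code
from .trna_tai import (
    CodonTaiTable,
    TRNAPool,
    build_tai_table,
    enumerate_directed_pairs,
)

POLY_CLASSES = ("syn_up", "syn_down", "nonsynonymous", "nonsense")
EXCLUSION_PLANTS = ("outgroup_mismatch", "outgroup_polymorphic", "outgroup_gap")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    Rates are per gene (Poisson means) unless stated; Beta parameters are
    (alpha, beta) of the derived-allele-frequency model per mutation class.
    """

    seed: int = 0
    n_genes: int = 60
    length_codons: tuple[int, int] = (120, 400)  # uniform, inclusive
    gc_target: tuple[float, float] = (0.35, 0.65)  # uniform per gene
    n_anticodons: int = 52  # of the 61 Watson-Crick anticodons
    tgcn_mean: float = 22.0  # copies ~ 1 + Poisson(tgcn_mean - 1)
    expression_lognorm: tuple[float, float] = (3.0, 1.2)  # (mu, sigma) of read rate
    daf_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "syn_up": (3.0, 3.0),
            "syn_down": (2.0, 4.0),
            "nonsynonymous": (1.5, 4.5),
            "nonsense": (1.0, 8.0),
        }
    )
    poly_per_gene: dict[str, float] = field(
        default_factory=lambda: {
            "syn_up": 2.0,
            "syn_down": 2.0,
            "nonsynonymous": 3.0,
            "nonsense": 0.3,
        }
    )
    fixed_per_gene: dict[str, float] = field(
        default_factory=lambda: {
            "syn_up": 8.0,
            "syn_down": 5.0,
            "nonsynonymous": 6.0,
            "nonsense": 0.1,
        }
    )
    outgroup_mismatch_per_gene: float = 1.0
    outgroup_polymorphic_per_gene: float = 0.5
    outgroup_gap_per_gene: float = 0.5
    outgroup_insertion_per_gene: float = 0.3  # columns gapped in the focal row
    expression_interaction: float = 0.0  # Beta shift added in the high-RPKM stratum
    gc_interaction: float = 0.0  # Beta shift added in the high-GC stratum
    daf_margin: float = 0.005  # keep draws off the 0.02 / 0.98 band edges

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.length_codons[0] < 20 or self.length_codons[0] > self.length_codons[1]:
            raise ValueError("invalid gene length range")
        if not 1 <= self.n_anticodons <= 61:
            raise ValueError("n_anticodons must be in 1..61")
        for cls, (a, b) in self.daf_beta.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {cls} must be positive")
        for d in (self.poly_per_gene, self.fixed_per_gene):
            for cls, rate in d.items():
                if rate < 0:
                    raise ValueError(f"negative rate for {cls}")
        mean_len = sum(self.length_codons) / 2
        mean_plants = sum(self.poly_per_gene.values()) + sum(self.fixed_per_gene.values())
        if mean_plants > 0.5 * (mean_len - 2):
            raise ValueError("infeasible config: more planted mutations than codons")


@dataclass
class PlantedSite:
    """Ground truth for one planted feature at a focal CDS position."""

    gene_id: str
    cds_pos: int  # 1-based
    functional_class: str  # synonymous | nonsynonymous | nonsense | n/a
    direction: str  # up | down | n/a (tAI direction of ancestral -> derived)
    status: str  # polymorphic | fixed | excluded
    reason: str  # exclusion reason, empty otherwise
    ancestral: str = ""
    derived: str = ""
    daf: float | None = None


@dataclass
class SyntheticGene:
    gene_id: str
    cds: str
    ancestral: str
    out1: str
    out2: str
    read_count: int
    rpkm: float = 0.0
    gc: float = 0.0
    outgroup_poly_positions: list[int] = field(default_factory=list)
    insertion_columns: list[int] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pool: TRNAPool
    tai: CodonTaiTable
    genes: list[SyntheticGene]
    truth: pd.DataFrame  # one row per planted feature
    gene_truth: pd.DataFrame  # gene_id, gc, rpkm, expression_stratum, gc_stratum
    allele_rows: pd.DataFrame  # gene_id, cds_pos, allele, freq

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every pipeline input plus the ground truth as plain text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cds": outdir / "cds.fa",
            "trna": outdir / "trna.fa",
            "trna_counts": outdir / "trna_counts.tsv",
            "expression": outdir / "expression.tsv",
            "alignments": outdir / "alignments.fa",
            "alleles": outdir / "alleles.tsv",
            "outgroup_poly": outdir / "outgroup_polymorphic.tsv",
            "truth_sites": outdir / "truth_sites.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "config": outdir / "sim_config.json",
        }
        with open(paths["cds"], "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n{g.cds}\n")
        with open(paths["trna"], "w") as fh:
            fh.write(trna_pool_fasta(self.pool))
        with open(paths["trna_counts"], "w") as fh:
            for ac in sorted(self.pool.copies):
                fh.write(f"{ac}\t{self.pool.copies[ac]}\n")
        with open(paths["expression"], "w") as fh:
            fh.write("gene_id\tread_count\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.read_count}\n")
        with open(paths["alignments"], "w") as fh:
            for g in self.genes:
                focal, o1, o2 = aligned_rows(g)
                fh.write(f">{g.gene_id}|focal\n{focal}\n")
                fh.write(f">{g.gene_id}|out1\n{o1}\n")
                fh.write(f">{g.gene_id}|out2\n{o2}\n")
        self.allele_rows.to_csv(paths["alleles"], sep="\t", index=False)
        with open(paths["outgroup_poly"], "w") as fh:
            fh.write("gene_id\tcds_pos\n")
            for g in self.genes:
                for pos in g.outgroup_poly_positions:
                    fh.write(f"{g.gene_id}\t{pos}\n")
        self.truth.to_csv(paths["truth_sites"], sep="\t", index=False)
        self.gene_truth.to_csv(paths["truth_genes"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, default=list)
        return paths


def trna_pool_fasta(pool: TRNAPool) -> str:
    """Render a pool as a GtRNAdb-dialect FASTA, one record per locus."""
    code = standard_code()
    lines = []
    for ac in sorted(pool.copies):
        aa = seq3(code.amino_acid(revcomp(ac)))
        body = "GGGCCCGTAGCTCAGTGGTAGAGCA"  # placeholder tRNA body, not used
        for i in range(pool.copies[ac]):
            lines.append(f">synth_tRNA-{aa}-{ac}-{i + 1}-1 {aa} ({ac}) 72 bp")
            lines.append(body)
    return "\n".join(lines) + ("\n" if lines else "")


def aligned_rows(g: SyntheticGene) -> tuple[str, str, str]:
    """Apply planted outgroup-specific insertion columns to the three rows."""
    focal = list(g.cds)
    o1 = list(g.out1)
    o2 = list(g.out2)
    for col in sorted(g.insertion_columns, reverse=True):
        focal.insert(col, "-")
        o1.insert(col, "A")
        o2.insert(col, "A")
    return "".join(focal), "".join(o1), "".join(o2)


def _codon_weights_for_gc(gc: float, code: GeneticCode) -> tuple[list[str], np.ndarray]:
    """Sense codons (no ATG/TGG to keep rewrites unbiased is unnecessary;
    all sense codons allowed) weighted to hit a per-gene GC target."""
    codons = list(code.sense_codons)
    w = np.array(
        [
            np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c])
            for c in codons
        ]
    )
    return codons, w / w.sum()


def _random_cds(length_codons: int, gc: float, code: GeneticCode, rng) -> str:
    codons, probs = _codon_weights_for_gc(gc, code)
    middle = rng.choice(len(codons), size=length_codons - 2, p=probs)
    stop = rng.choice(sorted(code.stop_codons))
    return "ATG" + "".join(codons[i] for i in middle) + stop


def _draw_daf(cls: str, beta: dict, rng, margin: float, boost: float = 0.0) -> float:
    a, b = beta[cls]
    if boost:
        if cls == "syn_up":
            a += boost
        elif cls == "syn_down":
            b += boost
    lo, hi = 0.02 + margin, 0.98 - margin
    for _ in range(1000):
        x = float(rng.beta(a, b))
        if lo <= x <= hi:
            return x
    raise RuntimeError("Beta truncation failed; parameters too extreme")


def _single_base_changes(code: GeneticCode):
    """All (codon, pos0, alt_base, alt_codon, class) single-base changes
    from a sense codon, with class of the forward change."""
    out = []
    for codon in code.sense_codons:
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if code.is_stop(alt):
                    cls = "nonsense"
                elif code.amino_acid(alt) == code.amino_acid(codon):
                    cls = "synonymous"
                else:
                    cls = "nonsynonymous"
                out.append((codon, pos, b, alt, cls))
    return out


def plant_variants(
    cds: str,
    tai: CodonTaiTable,
    plan: dict[str, int],
    rng,
    gene_id: str = "gene",
    daf_sampler=None,
    code: GeneticCode | None = None,
) -> tuple[str, list[PlantedSite], dict[int, dict[str, float]]]:
    """Plant polymorphic mutations of each class into one CDS.

    For each planted site the codon is rewritten so the planted class and
    tAI direction are exact by construction: synonymous plants take the
    ancestral codon from a directed pair of the requested direction, with
    the derived allele segregating at a Beta-drawn frequency. Returns the
    (possibly rewritten) CDS, the truth rows, and the per-position focal
    allele frequencies. Raises when the plan exceeds the free codons.
    """
    code = code or standard_code()
    pairs = enumerate_directed_pairs(tai, code)
    by_dir = {
        "syn_up": [p for p in pairs if p.direction == "tai_up"],
        "syn_down": [p for p in pairs if p.direction == "tai_down"],
    }
    changes = _single_base_changes(code)
    nonsyn = [c for c in changes if c[4] == "nonsynonymous"]
    nonsense = [c for c in changes if c[4] == "nonsense"]
    n_codons = len(cds) // 3
    free = list(range(1, n_codons - 1))  # keep the start and stop codons
    total = sum(plan.values())
    if total > len(free):
        raise ValueError(
            f"{gene_id}: plan of {total} sites exceeds {len(free)} free codons"
        )
    chosen = rng.choice(len(free), size=total, replace=False)
    slots = [free[i] for i in chosen]
    daf_sampler = daf_sampler or (lambda cls: float(rng.uniform(0.1, 0.9)))

    cds_list = list(cds)
    truth: list[PlantedSite] = []
    freqs: dict[int, dict[str, float]] = {}
    slot_iter = iter(slots)
    for cls in POLY_CLASSES:
        for _ in range(plan.get(cls, 0)):
            idx = next(slot_iter)
            if cls in ("syn_up", "syn_down"):
                if not by_dir[cls]:
                    raise ValueError(f"no directed pairs of class {cls} in this pool")
                pair = by_dir[cls][rng.integers(len(by_dir[cls]))]
                ref_codon, pos0 = pair.from_codon, pair.position - 1
                derived_base = pair.to_codon[pos0]
                fclass, direction = "synonymous", cls.split("_")[1]
            elif cls == "nonsynonymous":
                ref_codon, pos0, derived_base, _, _ = nonsyn[rng.integers(len(nonsyn))]
                fclass, direction = cls, "n/a"
            else:
                ref_codon, pos0, derived_base, _, _ = nonsense[rng.integers(len(nonsense))]
                fclass, direction = cls, "n/a"
            cds_list[idx * 3 : idx * 3 + 3] = ref_codon
            cds_pos = idx * 3 + pos0 + 1
            daf = daf_sampler(cls)
            ancestral = ref_codon[pos0]
            freqs[cds_pos] = {ancestral: round(1 - daf, 6), derived_base: round(daf, 6)}
            truth.append(
                PlantedSite(
                    gene_id, cds_pos, fclass, direction, "polymorphic", "",
                    ancestral, derived_base, round(daf, 6),
                )
            )
    return "".join(cds_list), truth, freqs


def _plant_fixed(
    cds_list: list[str],
    ancestral_list: list[str],
    tai: CodonTaiTable,
    plan: dict[str, int],
    free_slots: list[int],
    rng,
    gene_id: str,
    code: GeneticCode,
) -> list[PlantedSite]:
    """Plant fixed differences: focal carries the derived codon, both
    outgroups keep the ancestral base. A fixed nonsense plant is a stop
    loss (ancestral codon is a stop, focal sense), the only arrangement
    compatible with a stop-free focal CDS."""
    pairs = enumerate_directed_pairs(tai, code)
    by_dir = {
        "syn_up": [p for p in pairs if p.direction == "tai_up"],
        "syn_down": [p for p in pairs if p.direction == "tai_down"],
    }
    changes = _single_base_changes(code)
    nonsyn = [c for c in changes if c[4] == "nonsynonymous"]
    # stop loss: (stop codon, pos, base) whose substitution yields a sense codon
    stop_loss = []
    for stop in sorted(code.stop_codons):
        for pos in range(3):
            for b in BASES:
                if b == stop[pos]:
                    continue
                alt = stop[:pos] + b + stop[pos + 1 :]
                if code.is_sense(alt):
                    stop_loss.append((stop, pos, alt))
    truth = []
    slot_iter = iter(free_slots)
    for cls in POLY_CLASSES:
        for _ in range(plan.get(cls, 0)):
            idx = next(slot_iter)
            if cls in ("syn_up", "syn_down"):
                pair = by_dir[cls][rng.integers(len(by_dir[cls]))]
                anc_codon, der_codon, pos0 = pair.from_codon, pair.to_codon, pair.position - 1
                fclass, direction = "synonymous", cls.split("_")[1]
            elif cls == "nonsynonymous":
                anc_codon, pos0, _, der_codon, _ = nonsyn[rng.integers(len(nonsyn))]
                fclass, direction = cls, "n/a"
            else:
                anc_codon, pos0, der_codon = stop_loss[rng.integers(len(stop_loss))]
                fclass, direction = "nonsense", "n/a"
            cds_list[idx * 3 : idx * 3 + 3] = der_codon
            ancestral_list[idx * 3 : idx * 3 + 3] = anc_codon
            cds_pos = idx * 3 + pos0 + 1
            truth.append(
                PlantedSite(
                    gene_id, cds_pos, fclass, direction, "fixed", "",
                    anc_codon[pos0], der_codon[pos0], 1.0,
                )
            )
    return truth


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset plus ground truth.

    Byte-reproducible for a fixed config (including the seed).
    """
    config = config or SimulationConfig()
    config.validate()
    code = standard_code()
    rng = np.random.default_rng(config.seed)

    # --- tRNA pool over a random subset of the 61 Watson-Crick anticodons
    anticodons = sorted({revcomp(c) for c in code.sense_codons})
    picked = rng.choice(len(anticodons), size=config.n_anticodons, replace=False)
    copies = {
        anticodons[i]: int(1 + rng.poisson(max(config.tgcn_mean - 1, 0)))
        for i in sorted(picked)
    }
    pool = TRNAPool(dict(sorted(copies.items())))
    tai = build_tai_table(pool, code=code)
    pairs = enumerate_directed_pairs(tai, code)
    if not any(p.direction == "tai_up" for p in pairs):
        raise ValueError("infeasible config: pool yields no tAI-changing pairs")

    # --- genes: sequence, expression
    lengths = rng.integers(config.length_codons[0], config.length_codons[1] + 1, config.n_genes)
    gc_targets = rng.uniform(*config.gc_target, config.n_genes)
    rates = rng.lognormal(*config.expression_lognorm, config.n_genes)
    raw = []
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:04d}"
        cds = _random_cds(int(lengths[i]), float(gc_targets[i]), code, rng)
        read_count = int(rng.poisson(rates[i] * len(cds) / 1000.0 * 20))
        raw.append((gene_id, cds, read_count))
    total_reads = sum(rc for _, _, rc in raw)

    # --- strata (needed before planting: interactions shift the Beta draws)
    rpkms = {
        gid: compute_rpkm(rc, len(cds), total_reads) if total_reads else 0.0
        for gid, cds, rc in raw
    }
    gcs = {gid: sum(1 for b in cds if b in "GC") / len(cds) for gid, cds, _ in raw}
    def _top_half(d: dict[str, float]) -> set[str]:
        order = sorted(d, key=lambda g: (-d[g], g))
        return set(order[: (len(order) + 1) // 2])
    high_expr = _top_half(rpkms)
    high_gc = _top_half(gcs)

    genes: list[SyntheticGene] = []
    truth_rows: list[PlantedSite] = []
    allele_rows = []
    for gene_id, cds, read_count in raw:
        boost = (config.expression_interaction if gene_id in high_expr else 0.0) + (
            config.gc_interaction if gene_id in high_gc else 0.0
        )
        poly_plan = {
            cls: int(rng.poisson(rate)) for cls, rate in sorted(config.poly_per_gene.items())
        }
        fixed_plan = {
            cls: int(rng.poisson(rate)) for cls, rate in sorted(config.fixed_per_gene.items())
        }
        sampler = lambda cls: _draw_daf(cls, config.daf_beta, rng, config.daf_margin, boost)
        cds, poly_truth, freqs = plant_variants(
            cds, tai, poly_plan, rng, gene_id, daf_sampler=sampler, code=code
        )
        # fixed plants go into codons not already carrying a polymorphism
        n_codons = len(cds) // 3
        used = {(p.cds_pos - 1) // 3 for p in poly_truth}
        free = [i for i in range(1, n_codons - 1) if i not in used]
        n_fixed = sum(fixed_plan.values())
        if n_fixed > len(free):
            raise ValueError(f"{gene_id}: fixed plan exceeds free codons")
        slots = [free[i] for i in rng.choice(len(free), size=n_fixed, replace=False)]
        cds_list, anc_list = list(cds), list(cds)
        fixed_truth = _plant_fixed(
            cds_list, anc_list, tai, fixed_plan, slots, rng, gene_id, code
        )
        cds = "".join(cds_list)
        ancestral = "".join(anc_list)
        out1, out2 = list(ancestral), list(ancestral)

        # --- planted exclusions on positions free of any planted mutation
        used_bp = {p.cds_pos for p in poly_truth + fixed_truth}
        avail = [p for p in range(4, len(cds) - 3) if p not in used_bp]
        rng.shuffle(avail)
        avail_iter = iter(avail)
        excl_truth = []
        out_poly_positions = []
        for reason, rate in (
            ("outgroup_mismatch", config.outgroup_mismatch_per_gene),
            ("outgroup_polymorphic", config.outgroup_polymorphic_per_gene),
            ("outgroup_gap", config.outgroup_gap_per_gene),
        ):
            for _ in range(int(rng.poisson(rate))):
                try:
                    pos = next(avail_iter)
                except StopIteration:
                    break
                if reason == "outgroup_mismatch":
                    alternatives = [b for b in BASES if b != out2[pos - 1]]
                    out2[pos - 1] = alternatives[rng.integers(3)]
                elif reason == "outgroup_gap":
                    out1[pos - 1] = "-"
                else:
                    out_poly_positions.append(pos)
                excl_truth.append(
                    PlantedSite(gene_id, pos, "n/a", "n/a", "excluded", reason)
                )
        n_ins = int(rng.poisson(config.outgroup_insertion_per_gene))
        insertion_columns = sorted(
            int(c) for c in rng.integers(3, len(cds) - 3, size=n_ins)
        )

        genes.append(
            SyntheticGene(
                gene_id=gene_id, cds=cds, ancestral=ancestral,
                out1="".join(out1), out2="".join(out2),
                read_count=read_count, rpkm=rpkms[gene_id],
                gc=sum(1 for b in cds if b in "GC") / len(cds),
                outgroup_poly_positions=sorted(out_poly_positions),
                insertion_columns=insertion_columns,
            )
        )
        truth_rows.extend(poly_truth + fixed_truth + excl_truth)
        for p in poly_truth:
            for allele, f in sorted(freqs[p.cds_pos].items()):
                allele_rows.append(
                    {"gene_id": gene_id, "cds_pos": p.cds_pos, "allele": allele, "freq": f}
                )

    truth = pd.DataFrame(
        [dataclasses.asdict(p) for p in truth_rows],
        columns=[f.name for f in dataclasses.fields(PlantedSite)],
    ).sort_values(["gene_id", "cds_pos"], kind="mergesort").reset_index(drop=True)
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gc": [g.gc for g in genes],
            "rpkm": [g.rpkm for g in genes],
            "expression_stratum": [
                "high" if g.gene_id in high_expr else "low" for g in genes
            ],
            "gc_stratum": ["high" if g.gene_id in high_gc else "low" for g in genes],
        }
    )
    return SyntheticDataset(
        config=config,
        pool=pool,
        tai=tai,
        genes=genes,
        truth=truth,
        gene_truth=gene_truth,
        allele_rows=pd.DataFrame(
            allele_rows, columns=["gene_id", "cds_pos", "allele", "freq"]
        ),
    )
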