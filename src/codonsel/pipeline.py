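"""End-to-end orchestration: tAI -> usage/CAI -> polarize -> annotate -> stats.

``run_pipeline`` consumes plain-text inputs (CDS FASTA, tRNA FASTA or
counts TSV, expression TSV, aligned triples, allele-frequency TSV, optional
outgroup-polymorphism mask), produces a per-site table with polarity and
functional annotation, the selection contrasts, and a machine-readable run
manifest whose counts reconcile across stages (conservation of sites).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_usage as cu
from . import polarity as pol
from . import selection_stats as ss
from .genetic_code import standard_code
from .trna_tai import (
    CodonTaiTable,
    TRNAPool,
    build_tai_table,
    enumerate_directed_pairs,
    pairs_to_frame,
    parse_trna_pool,
    read_trna_counts_tsv,
)
from .variant_annotation import ReferenceMismatch, annotate_site_change

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and analysis parameters of one pipeline run."""

    cds_fasta: str | Path
    alignments_fasta: str | Path
    alleles_tsv: str | Path
    trna_fasta: str | Path | None = None
    trna_counts_tsv: str | Path | None = None
    expression_tsv: str | Path | None = None
    outgroup_poly_tsv: str | Path | None = None
    structured_tsv: str | Path | None = None
    band: tuple[float, float] = (0.02, 0.98)
    high_expression_fraction: float = 0.5


@dataclass
class RunManifest:
    input_digests: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_digests": self.input_digests,
                "parameters": self.parameters,
                "counts": self.counts,
                "failure": self.failure,
            },
            indent=2,
        )

    def conserved(self) -> bool:
        """sites_in == polymorphic + fixed + sum of exclusions by reason."""
        c = self.counts
        excluded = sum(v for k, v in c.items() if k.startswith("excluded_"))
        return c.get("sites_in", -1) == c.get("polymorphic", 0) + c.get("fixed", 0) + excluded


@dataclass
class PipelineResult:
    sites: pd.DataFrame  # per-site polarity + annotation (+ gene covariates)
    gene_table: pd.DataFrame  # gene_id, rpkm, gc, gc3, cai
    tai: CodonTaiTable
    usage: cu.CodonUsageTable
    contingency: ss.ContingencyResult | None
    spectra: dict[str, ss.SpectrumSummary]
    regression: dict[str, ss.RegressionResult]
    gbgc: dict[str, dict[str, ss.SpectrumSummary]]
    neighbors: ss.NeighborResult | None
    manifest: RunManifest


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on the configured inputs; optionally write outputs."""
    code = standard_code()
    manifest = RunManifest(
        parameters={
            "band": list(config.band),
            "high_expression_fraction": config.high_expression_fraction,
        }
    )
    for name in (
        "cds_fasta", "alignments_fasta", "alleles_tsv", "trna_fasta",
        "trna_counts_tsv", "expression_tsv", "outgroup_poly_tsv",
    ):
        p = getattr(config, name)
        if p is not None:
            manifest.input_digests[name] = _digest(p)

    # --- stage 1: tRNA pool and tAI table
    if config.trna_fasta is not None:
        pool = parse_trna_pool(config.trna_fasta)
    elif config.trna_counts_tsv is not None:
        pool = read_trna_counts_tsv(config.trna_counts_tsv)
    else:
        raise ValueError("either trna_fasta or trna_counts_tsv is required")
    tai = build_tai_table(pool, code=code)
    pairs = enumerate_directed_pairs(tai, code)
    manifest.counts["trna_anticodons"] = pool.n_anticodons
    manifest.counts["trna_loci"] = pool.total_loci
    manifest.counts["directed_pairs"] = len(pairs)

    # --- stage 2: genes, expression, usage table, CAI
    cds_by_id = cu.read_cds_fasta(config.cds_fasta)
    expression = (
        cu.read_expression_tsv(config.expression_tsv)
        if config.expression_tsv is not None
        else None
    )
    structured = None
    if config.structured_tsv is not None:
        sdf = pd.read_csv(config.structured_tsv, sep="\t")
        structured = dict(zip(sdf["gene_id"], sdf["structured_pct"].astype(float)))
    genes = cu.build_gene_records(cds_by_id, expression, structured)
    high, low = cu.select_high_expression(genes, config.high_expression_fraction)
    usage = cu.build_usage_table(high, code)
    high_ids = {g.gene_id for g in high}
    gene_rows = []
    for g in genes:
        gc, gc3 = cu.gc_metrics(g.cds)
        try:
            cai, skipped = cu.gene_cai(g.cds, usage, code)
        except ValueError:
            cai, skipped = float("nan"), 0
        gene_rows.append(
            {
                "gene_id": g.gene_id, "rpkm": g.rpkm, "gc": gc, "gc3": gc3,
                "cai": cai, "cai_skipped_codons": skipped,
                "structured_pct": g.structured_pct,
                "stratum_rpkm": "high" if g.gene_id in high_ids else "low",
            }
        )
    gene_table = pd.DataFrame(gene_rows)
    manifest.counts["genes"] = len(genes)
    manifest.counts["genes_high_expression"] = len(high)

    # --- stage 3: polarization
    triples = pol.read_aligned_triples(config.alignments_fasta)
    freqs = pol.read_allele_frequencies(config.alleles_tsv)
    out_poly: dict[str, set[int]] = {}
    if config.outgroup_poly_tsv is not None:
        opdf = pd.read_csv(config.outgroup_poly_tsv, sep="\t")
        for row in opdf.itertuples(index=False):
            out_poly.setdefault(str(row.gene_id), set()).add(int(row.cds_pos))
    site_records: list[pol.SiteRecord] = []
    for triple in triples:
        if triple.gene_id not in cds_by_id:
            log.warning("alignment for unknown gene %s skipped", triple.gene_id)
            continue
        site_records.extend(
            pol.walk_alignment(
                triple,
                freqs.get(triple.gene_id, {}),
                out_poly.get(triple.gene_id, ()),
                band=config.band,
            )
        )
    manifest.counts["sites_in"] = len(site_records)
    for rec in site_records:
        key = f"excluded_{rec.reason}" if rec.status == "excluded" else rec.status
        manifest.counts[key] = manifest.counts.get(key, 0) + 1

    # --- stage 4: functional annotation of fixed + polymorphic sites
    gene_cov = gene_table.set_index("gene_id")
    rows = []
    for rec in site_records:
        row = {
            "gene_id": rec.gene_id, "cds_pos": rec.cds_pos, "status": rec.status,
            "reason": rec.reason, "ancestral": rec.ancestral, "derived": rec.derived,
            "daf": rec.daf, "maf": rec.maf, "functional_class": "",
            "tai_direction": "n/a", "cai_direction": "n/a",
            "delta_tai": None, "delta_cai": None,
        }
        if rec.status in ("polymorphic", "fixed"):
            try:
                ann = annotate_site_change(
                    cds_by_id[rec.gene_id], rec.cds_pos, rec.ancestral, rec.derived,
                    tai=tai, usage=usage, gene_id=rec.gene_id, code=code,
                )
            except (ReferenceMismatch, ValueError) as exc:
                log.warning("annotation failed: %s", exc)
                row["status"], row["reason"] = "excluded", "annotation_failed"
                manifest.counts[rec.status] -= 1
                manifest.counts["excluded_annotation_failed"] = (
                    manifest.counts.get("excluded_annotation_failed", 0) + 1
                )
                rows.append(row)
                continue
            row.update(
                functional_class=ann.functional_class,
                tai_direction=ann.tai_direction,
                cai_direction=ann.cai_direction,
                delta_tai=ann.delta_tai,
                delta_cai=ann.delta_cai,
            )
        rows.append(row)
    sites = pd.DataFrame(rows)
    if len(sites):
        sites = sites.merge(
            gene_cov[["rpkm", "gc", "gc3", "cai"]], left_on="gene_id",
            right_index=True, how="left",
        )
    mut = sites[sites["status"].isin(["polymorphic", "fixed"])]
    for cls in ("synonymous", "nonsynonymous", "nonsense"):
        manifest.counts[f"class_{cls}"] = int((mut["functional_class"] == cls).sum())
    syn = mut[mut["functional_class"] == "synonymous"]
    for d in ("up", "down", "tie"):
        manifest.counts[f"syn_tai_{d}"] = int((syn["tai_direction"] == d).sum())

    # --- stage 5: selection statistics
    contingency = None
    spectra: dict[str, ss.SpectrumSummary] = {}
    regression: dict[str, ss.RegressionResult] = {}
    gbgc: dict[str, dict[str, ss.SpectrumSummary]] = {}
    neighbors = None
    if len(mut):
        try:
            contingency = ss.class_contingency(sites)
        except ValueError as exc:
            log.warning("contingency skipped: %s", exc)
        for metric in ("daf", "maf"):
            spectra[metric] = ss.site_spectra(sites, metric=metric)
            gbgc[metric] = ss.gbgc_control_subsets(sites, metric=metric)
            syn_poly = sites[
                (sites["status"] == "polymorphic")
                & (sites["functional_class"] == "synonymous")
            ].dropna(subset=[metric])
            if len(syn_poly) >= 5:
                try:
                    regression[metric] = ss.regress_frequency(
                        syn_poly, response=metric,
                        predictors=("delta_cai", "delta_tai", "gc"),
                    )
                except ValueError as exc:
                    log.warning("regression (%s) skipped: %s", metric, exc)
        neighbors = ss.nearest_neighbor_classes(sites)

    result = PipelineResult(
        sites=sites, gene_table=gene_table, tai=tai, usage=usage,
        contingency=contingency, spectra=spectra, regression=regression,
        gbgc=gbgc, neighbors=neighbors, manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir, pairs_frame=pairs_to_frame(pairs))
    return result


def write_outputs(
    result: PipelineResult, outdir: str | Path, pairs_frame: pd.DataFrame | None = None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    result.gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    result.tai.to_frame().to_csv(outdir / "tai_table.tsv", sep="\t", index=False)
    result.usage.to_frame().to_csv(outdir / "usage_table.tsv", sep="\t", index=False)
    if pairs_frame is not None:
        pairs_frame.to_csv(outdir / "directed_pairs.tsv", sep="\t", index=False)
    summary_rows = []
    if result.contingency is not None:
        c = result.contingency
        summary_rows.append(
            {
                "analysis": "fixed_polymorphic_up_vs_down",
                "statistic": "odds_ratio", "value": c.odds_ratio, "p_value": c.p_value,
                "detail": f"ratio_up={c.ratio_a} ratio_down={c.ratio_b}",
            }
        )
    for metric, spec in result.spectra.items():
        for (a, b), p in spec.p_values.items():
            summary_rows.append(
                {
                    "analysis": f"spectrum_{metric}_{a}_vs_{b}",
                    "statistic": "median_diff",
                    "value": spec.median.get(a, np.nan) - spec.median.get(b, np.nan),
                    "p_value": p, "detail": f"n={spec.n.get(a)}/{spec.n.get(b)}",
                }
            )
    for metric, reg in result.regression.items():
        for name, coef in reg.params.items():
            summary_rows.append(
                {
                    "analysis": f"regression_{metric}", "statistic": f"coef_{name}",
                    "value": coef, "p_value": np.nan,
                    "detail": f"se={reg.bse[name]:.4g} n={reg.n}",
                }
            )
    pd.DataFrame(
        summary_rows, columns=["analysis", "statistic", "value", "p_value", "detail"]
    ).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(result.manifest.to_json())


def run_on_dataset(dataset, workdir: str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """Write a synthetic dataset to ``workdir`` and run the pipeline on it,
    exercising the same file-format path as real inputs."""
    paths = dataset.write(workdir)
    config = PipelineConfig(
        cds_fasta=paths["cds"],
        alignments_fasta=paths["alignments"],
        alleles_tsv=paths["alleles"],
        trna_fasta=paths["trna"],
        expression_tsv=paths["expression"],
        outgroup_poly_tsv=paths["outgroup_poly"],
    )
    return run_pipeline(config, outdir=outdir)
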