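"""Selection contrasts: fixed:polymorphic ratios, frequency-spectrum tests,
stratified analyses, GC-conservative (gBGC control) subsets, the
nearest-neighbour clustering test, correlations and the multiple
regression of allele frequency on codon-optimality changes.

The evidential logic is McDonald-Kreitman-style: if mutations that increase
codon optimality are favoured, they should show (i) a higher
fixed-to-polymorphic ratio and (ii) a right-shifted derived/minor allele
frequency spectrum relative to optimality-decreasing mutations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

SPECTRUM_CLASSES = ("syn_up", "syn_down", "syn_tie", "nonsynonymous", "nonsense")

# contrasts reported for every spectrum: deleterious-class ordering checks
# plus the central optimality contrast
DEFAULT_CONTRASTS = (
    ("nonsense", "nonsynonymous"),
    ("nonsynonymous", "syn_up"),
    ("nonsynonymous", "syn_down"),
    ("syn_up", "syn_down"),
)


@dataclass
class ContingencyResult:
    """A 2x2 fixed/polymorphic contrast between two mutation classes."""

    fixed_a: int
    poly_a: int
    fixed_b: int
    poly_b: int
    ratio_a: float | None
    ratio_b: float | None
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.fixed_a, self.poly_a], [self.fixed_b, self.poly_b]]


def fixed_polymorphic_contrast(
    fixed_a: int, poly_a: int, fixed_b: int, poly_b: int
) -> ContingencyResult:
    """Fixed:polymorphic ratios of two classes plus a two-sided Fisher test.

    The two-sided p-value sums the hypergeometric probabilities of all
    tables (with the observed margins) at most as probable as the observed
    one. A zero polymorphic count leaves that class's ratio undefined
    (None) and is logged.
    """
    counts = (fixed_a, poly_a, fixed_b, poly_b)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("counts must be non-negative integers")
    odds, p = stats.fisher_exact(
        [[fixed_a, poly_a], [fixed_b, poly_b]], alternative="two-sided"
    )
    ratio_a = fixed_a / poly_a if poly_a > 0 else None
    ratio_b = fixed_b / poly_b if poly_b > 0 else None
    if ratio_a is None or ratio_b is None:
        log.warning("zero polymorphic count: fixed:polymorphic ratio undefined")
    return ContingencyResult(
        fixed_a, poly_a, fixed_b, poly_b, ratio_a, ratio_b, float(odds), float(p)
    )


def _exact_permutation_ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group labellings.

    Uses midranks, so it is exact in the presence of ties. Feasible only
    for small samples: C(n1+n2, n1) labellings are enumerated.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(x)
    observed = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2.0
    obs_dev = abs(observed - mean)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 200_000
) -> float:
    """Two-sided Wilcoxon rank-sum p-value with an exact small-sample path.

    Tie-free samples with n1+n2 <= 50 use the exact null distribution;
    tied samples use full midrank permutation enumeration while
    C(n1+n2, n1) <= ``exact_limit``; everything else falls back to the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    n = len(x) + len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n
    if n <= 50 and not has_ties:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    if has_ties and comb(n, len(x)) <= exact_limit:
        return _exact_permutation_ranksum(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


@dataclass
class SpectrumSummary:
    """Per-class allele-frequency spectra with pairwise rank-sum tests."""

    metric: str  # "daf" | "maf"
    n: dict[str, int] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)
    median: dict[str, float] = field(default_factory=dict)
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    skipped_contrasts: list[tuple[str, str]] = field(default_factory=list)

    def median_gap(self, class_a: str = "syn_up", class_b: str = "syn_down") -> float | None:
        if class_a in self.median and class_b in self.median:
            return self.median[class_a] - self.median[class_b]
        return None

    def adjusted_p(self, method: str = "fdr_bh") -> dict[tuple[str, str], float]:
        """Optional multiple-testing correction across the reported contrasts."""
        if not self.p_values:
            return {}
        keys = list(self.p_values)
        _, adj, _, _ = multipletests([self.p_values[k] for k in keys], method=method)
        return dict(zip(keys, adj))


def spectrum_compare(
    class_values: Mapping[str, Sequence[float]],
    metric: str = "daf",
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
) -> SpectrumSummary:
    """Medians and pairwise two-sided rank-sum tests across mutation classes.

    Contrasts whose classes are empty or absent are skipped and reported in
    ``skipped_contrasts``.
    """
    summary = SpectrumSummary(metric=metric)
    for cls, vals in class_values.items():
        arr = np.asarray(list(vals), dtype=float)
        summary.values[cls] = arr
        summary.n[cls] = len(arr)
        if len(arr):
            summary.median[cls] = float(np.median(arr))
    for a, b in contrasts:
        if summary.n.get(a, 0) and summary.n.get(b, 0):
            summary.p_values[(a, b)] = rank_sum_test(summary.values[a], summary.values[b])
        else:
            summary.skipped_contrasts.append((a, b))
    return summary


def site_spectra(
    sites: pd.DataFrame,
    metric: str = "daf",
    direction_col: str = "tai_direction",
) -> SpectrumSummary:
    """Build per-class spectra from an annotated polarized site table.

    Expects columns: functional_class, ``direction_col``, and the metric
    column (daf or maf). Polymorphic sites only.
    """
    class_values: dict[str, list[float]] = {c: [] for c in SPECTRUM_CLASSES}
    poly = sites[sites["status"] == "polymorphic"]
    for row in poly.itertuples(index=False):
        fclass = row.functional_class
        if fclass == "synonymous":
            direction = getattr(row, direction_col)
            if direction not in ("up", "down", "tie"):
                continue
            key = f"syn_{direction}"
        else:
            key = fclass
        val = getattr(row, metric)
        if val is not None and not pd.isna(val):
            class_values[key].append(float(val))
    return spectrum_compare(class_values, metric=metric)


def class_contingency(
    sites: pd.DataFrame,
    class_a: str = "up",
    class_b: str = "down",
    direction_col: str = "tai_direction",
) -> ContingencyResult:
    """Fixed/polymorphic 2x2 between two synonymous direction classes."""
    syn = sites[sites["functional_class"] == "synonymous"]
    a = syn[syn[direction_col] == class_a]
    b = syn[syn[direction_col] == class_b]
    return fixed_polymorphic_contrast(
        int((a["status"] == "fixed").sum()),
        int((a["status"] == "polymorphic").sum()),
        int((b["status"] == "fixed").sum()),
        int((b["status"] == "polymorphic").sum()),
    )


def stratified_contrast(
    sites: pd.DataFrame,
    gene_values: Mapping[str, float],
    metric: str = "daf",
    fraction: float = 0.5,
) -> dict[str, dict]:
    """Recompute spectra and the up/down contingency per gene stratum.

    Genes are split into a high and a low stratum at the ``fraction``
    quantile of the stratifying value (RPKM or GC); the difference of
    up-minus-down median gaps between strata is reported as the effect-size
    contrast.
    """
    vals = pd.Series(gene_values, dtype=float)
    if vals.nunique() <= 1:
        raise ValueError("degenerate stratifier: constant gene values")
    order = vals.sort_values(ascending=False, kind="mergesort")
    n_high = int(np.ceil(len(order) * fraction))
    high_genes = set(order.index[:n_high])
    out: dict[str, dict] = {}
    for stratum, members in (("high", high_genes), ("low", set(vals.index) - high_genes)):
        sub = sites[sites["gene_id"].isin(members)]
        entry: dict = {"n_sites": len(sub)}
        if len(sub):
            entry["spectrum"] = site_spectra(sub, metric=metric)
            try:
                entry["contingency"] = class_contingency(sub)
            except ValueError:
                entry["contingency"] = None
        else:
            entry["empty"] = True
        out[stratum] = entry
    gaps = {
        s: out[s]["spectrum"].median_gap()
        for s in ("high", "low")
        if "spectrum" in out[s]
    }
    if len(gaps) == 2 and None not in gaps.values():
        out["gap_difference"] = gaps["high"] - gaps["low"]
    return out


def gbgc_control_subsets(sites: pd.DataFrame, metric: str = "daf") -> dict[str, SpectrumSummary]:
    """Spectra restricted to GC-conservative allele pairs (A<->T and C<->G).

    Because neither substitution changes GC content, GC-biased gene
    conversion cannot explain an up-versus-down shift within these subsets.
    """
    poly = sites[sites["status"] == "polymorphic"].copy()
    pairs = poly["ancestral"].astype(str) + poly["derived"].astype(str)
    subsets = {
        "AT": poly[pairs.isin(["AT", "TA"])],
        "CG": poly[pairs.isin(["CG", "GC"])],
    }
    return {
        name: site_spectra(sub, metric=metric) if len(sub) else SpectrumSummary(metric=metric)
        for name, sub in subsets.items()
    }


@dataclass
class NeighborResult:
    labels: pd.DataFrame  # gene_id, cds_pos, direction, neighbor_direction, label, distance
    gene_median_distance: dict[str, float]
    p_values: dict[tuple[str, str], float]
    skipped_genes: int


def nearest_neighbor_classes(sites: pd.DataFrame, metric: str = "daf") -> NeighborResult:
    """Label each synonymous up/down site by its nearest neighbour's class.

    Within each gene, the nearest other classified synonymous site by
    absolute CDS distance defines labels up_near_up, up_near_down,
    down_near_up, down_near_down (ties broken toward the upstream site).
    Rank-sum tests compare the near-up versus near-down spectra within each
    direction; under no clustering of high/low-frequency alleles these do
    not differ. Genes with fewer than two classified sites are skipped.
    """
    rows = []
    gene_median: dict[str, float] = {}
    skipped = 0
    syn = sites[
        (sites["functional_class"] == "synonymous")
        & (sites["status"] == "polymorphic")
        & (sites["tai_direction"].isin(["up", "down"]))
    ]
    for gene_id, sub in syn.groupby("gene_id"):
        sub = sub.sort_values("cds_pos")
        if len(sub) < 2:
            skipped += 1
            continue
        pos = sub["cds_pos"].to_numpy()
        dirs = sub["tai_direction"].to_numpy()
        vals = sub[metric].to_numpy(dtype=float)
        dists = []
        for i in range(len(sub)):
            d = np.abs(pos - pos[i])
            d[i] = np.iinfo(np.int64).max
            best = d.min()
            # tie toward the upstream (smaller-coordinate) site
            candidates = np.flatnonzero(d == best)
            j = candidates[np.argmin(pos[candidates])]
            dists.append(int(best))
            rows.append(
                {
                    "gene_id": gene_id,
                    "cds_pos": int(pos[i]),
                    "direction": dirs[i],
                    "neighbor_direction": dirs[j],
                    "label": f"{dirs[i]}_near_{dirs[j]}",
                    "distance": int(best),
                    metric: vals[i],
                }
            )
        gene_median[gene_id] = float(np.median(dists))
    labels = pd.DataFrame(
        rows,
        columns=["gene_id", "cds_pos", "direction", "neighbor_direction", "label", "distance", metric],
    )
    p_values: dict[tuple[str, str], float] = {}
    for direction in ("up", "down"):
        a = labels[labels["label"] == f"{direction}_near_up"][metric]
        b = labels[labels["label"] == f"{direction}_near_down"][metric]
        if len(a) and len(b):
            p_values[(f"{direction}_near_up", f"{direction}_near_down")] = rank_sum_test(a, b)
    return NeighborResult(labels, gene_median, p_values, skipped)


@dataclass
class RegressionResult:
    params: dict[str, float]
    bse: dict[str, float]
    n: int
    warnings: list[str]


def regress_frequency(
    data: pd.DataFrame,
    response: str = "daf",
    predictors: Sequence[str] = ("delta_cai", "delta_tai", "gc"),
) -> RegressionResult:
    """OLS of DAF or MAF on codon-optimality changes and gene GC content.

    Complete cases only; constant or collinear predictors are flagged in
    ``warnings`` but coefficients are still reported.
    """
    import statsmodels.api as sm

    cols = [response, *predictors]
    d = data[cols].dropna()
    if not len(d):
        raise ValueError("no complete cases for regression")
    warnings = [f"constant predictor: {p}" for p in predictors if d[p].nunique() <= 1]
    X = sm.add_constant(d[list(predictors)], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        warnings.append("collinear design matrix")
    fit = sm.OLS(d[response], X).fit()
    return RegressionResult(
        params=dict(fit.params), bse=dict(fit.bse), n=int(fit.nobs), warnings=warnings
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs equal-length vectors of length >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
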