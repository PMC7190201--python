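"""Contingency ratios, rank-sum tests, neighbours, regression, correlation —
each checked against an independent brute-force oracle where one exists."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonsel.selection_stats import (
    correlate,
    fixed_polymorphic_contrast,
    gbgc_control_subsets,
    nearest_neighbor_classes,
    rank_sum_test,
    regress_frequency,
    spectrum_compare,
    stratified_contrast,
)


# -------------------------------------------------- Fisher / contingency

def brute_force_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of tables with the
    observed margins, summing probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def table_p(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_p(a)
    return sum(p for x in range(lo, hi + 1) if (p := table_p(x)) <= p_obs * (1 + 1e-9))


def test_paper_scale_ratio_arithmetic():
    res = fixed_polymorphic_contrast(255236, 2220, 181820, 2645)
    assert round(res.ratio_a, 1) == 115.0
    assert round(res.ratio_b, 1) == 68.7
    assert res.p_value < 1e-10


def test_no_association_table():
    res = fixed_polymorphic_contrast(10, 10, 10, 10)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_small_table():
    res = fixed_polymorphic_contrast(8, 2, 1, 5)
    assert res.p_value == pytest.approx(brute_force_fisher_p(8, 2, 1, 5), rel=1e-9)


def test_fisher_matches_enumeration_sweep():
    for a, b, c, d in itertools.product(range(0, 7, 2), repeat=4):
        if (a + b) and (c + d) and (a + c) and (b + d):
            res = fixed_polymorphic_contrast(a, b, c, d)
            assert res.p_value == pytest.approx(
                brute_force_fisher_p(a, b, c, d), rel=1e-9, abs=1e-12
            ), (a, b, c, d)


def test_zero_polymorphic_ratio_flagged():
    res = fixed_polymorphic_contrast(5, 0, 3, 2)
    assert res.ratio_a is None
    assert res.ratio_b == pytest.approx(1.5)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        fixed_polymorphic_contrast(-1, 2, 3, 4)


# --------------------------------------------------------- rank-sum test

def brute_force_permutation_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mean = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mean)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= obs - 1e-9:
            hits += 1
    return hits / total


@pytest.mark.parametrize("seed", range(6))
def test_rank_sum_matches_permutation_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(2, 7))
    n2 = int(rng.integers(2, 13 - n1))
    # integer support forces ties with high probability
    x = rng.integers(0, 5, size=n1).astype(float)
    y = rng.integers(0, 5, size=n2).astype(float)
    assert rank_sum_test(x, y) == pytest.approx(brute_force_permutation_p(x, y), abs=1e-12)


def test_rank_sum_tie_free_exact_path():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=8), rng.normal(size=5)
    assert rank_sum_test(x, y) == pytest.approx(brute_force_permutation_p(x, y), abs=1e-12)


def test_rank_sum_rejects_empty():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


# ------------------------------------------------------------- spectra

def test_identical_spectra_p_one():
    v = [0.1, 0.2, 0.3, 0.4, 0.5]
    summary = spectrum_compare({"syn_up": v, "syn_down": v})
    assert summary.p_values[("syn_up", "syn_down")] == pytest.approx(1.0)
    assert summary.median["syn_up"] == summary.median["syn_down"]


def test_empty_class_contrast_skipped():
    summary = spectrum_compare({"syn_up": [0.1, 0.2], "syn_down": []})
    assert ("syn_up", "syn_down") in summary.skipped_contrasts


def test_shifted_betas_detected():
    rng = np.random.default_rng(42)
    up = rng.beta(3, 3, size=2000)
    down = rng.beta(2, 4, size=2000)
    summary = spectrum_compare({"syn_up": up, "syn_down": down})
    assert summary.median["syn_up"] > summary.median["syn_down"]
    assert summary.p_values[("syn_up", "syn_down")] < 0.05
    assert summary.median_gap() > 0


def test_benjamini_hochberg_adjustment_available():
    rng = np.random.default_rng(0)
    classes = {
        "syn_up": rng.beta(3, 3, 100),
        "syn_down": rng.beta(2, 4, 100),
        "nonsynonymous": rng.beta(1.5, 4.5, 100),
        "nonsense": rng.beta(1, 8, 50),
    }
    summary = spectrum_compare(classes)
    adjusted = summary.adjusted_p()
    assert set(adjusted) == set(summary.p_values)
    assert all(adjusted[k] >= summary.p_values[k] - 1e-12 for k in adjusted)


# --------------------------------------------------------- stratification

def _sites_frame(rows):
    cols = [
        "gene_id", "cds_pos", "status", "functional_class", "tai_direction",
        "ancestral", "derived", "daf", "maf",
    ]
    return pd.DataFrame(rows, columns=cols)


def _poly_row(gene, pos, direction, daf, anc="A", der="G"):
    return {
        "gene_id": gene, "cds_pos": pos, "status": "polymorphic",
        "functional_class": "synonymous", "tai_direction": direction,
        "ancestral": anc, "derived": der, "daf": daf, "maf": min(daf, 1 - daf),
    }


def test_identical_strata_give_equal_summaries():
    rows = []
    for gene in ("g1", "g2"):
        for i, (d, f) in enumerate([("up", 0.6), ("up", 0.4), ("down", 0.3), ("down", 0.2)]):
            rows.append(_poly_row(gene, 10 * (i + 1), d, f))
    sites = _sites_frame(rows)
    res = stratified_contrast(sites, {"g1": 2.0, "g2": 1.0})
    assert res["high"]["spectrum"].median == res["low"]["spectrum"].median
    assert res["gap_difference"] == pytest.approx(0.0)


def test_constant_stratifier_rejected():
    sites = _sites_frame([_poly_row("g1", 10, "up", 0.5)])
    with pytest.raises(ValueError, match="degenerate"):
        stratified_contrast(sites, {"g1": 1.0, "g2": 1.0})


def test_planted_stratum_interaction_recovered():
    """A generator configured with a larger up/down gap in the high-RPKM
    stratum must yield a larger recovered median gap there."""
    from codonsel.synthetic_data import SimulationConfig, simulate_dataset

    ds = simulate_dataset(SimulationConfig(seed=5, n_genes=40, expression_interaction=3.0))
    truth = ds.truth[ds.truth.status == "polymorphic"].copy()
    truth["maf"] = np.minimum(truth.daf, 1 - truth.daf)
    sites = truth.rename(columns={"direction": "tai_direction"})
    rpkm = dict(zip(ds.gene_truth.gene_id, ds.gene_truth.rpkm))
    res = stratified_contrast(sites, rpkm)
    assert res["gap_difference"] > 0
    assert res["high"]["spectrum"].median_gap() > res["low"]["spectrum"].median_gap()


# ------------------------------------------------------------ gBGC subsets

def test_gc_conservative_subset_membership():
    rows = [
        _poly_row("g1", 3, "up", 0.5, "A", "T"),
        _poly_row("g1", 9, "down", 0.3, "T", "A"),
        _poly_row("g1", 15, "up", 0.4, "C", "G"),
        _poly_row("g1", 21, "up", 0.6, "A", "G"),  # GC-changing: in neither
    ]
    subsets = gbgc_control_subsets(_sites_frame(rows))
    assert subsets["AT"].n["syn_up"] == 1
    assert subsets["AT"].n["syn_down"] == 1
    assert subsets["CG"].n["syn_up"] == 1
    assert subsets["CG"].n.get("syn_down", 0) == 0
    assert sum(subsets["AT"].n.values()) + sum(subsets["CG"].n.values()) == 3


def test_gc_conservative_planted_shift_recovered():
    rng = np.random.default_rng(8)
    rows = []
    pos = 0
    for _ in range(300):
        pos += 3
        rows.append(_poly_row("g1", pos, "up", float(rng.beta(3, 3)), "A", "T"))
        pos += 3
        rows.append(_poly_row("g1", pos, "down", float(rng.beta(2, 4)), "T", "A"))
    subsets = gbgc_control_subsets(_sites_frame(rows))
    at = subsets["AT"]
    assert at.median["syn_up"] > at.median["syn_down"]
    assert at.p_values[("syn_up", "syn_down")] < 0.05


# ------------------------------------------------------ nearest neighbour

def test_nearest_neighbor_toy_layout():
    rows = [
        _poly_row("g1", 10, "up", 0.5),
        _poly_row("g1", 100, "down", 0.3),
        _poly_row("g1", 110, "up", 0.4),
    ]
    res = nearest_neighbor_classes(_sites_frame(rows))
    labels = dict(zip(res.labels.cds_pos, res.labels.label))
    dists = dict(zip(res.labels.cds_pos, res.labels.distance))
    assert labels == {10: "up_near_down", 100: "down_near_up", 110: "up_near_down"}
    assert dists == {10: 90, 100: 10, 110: 10}
    assert res.gene_median_distance["g1"] == 10


def test_nearest_neighbor_tie_breaks_upstream():
    rows = [
        _poly_row("g1", 10, "up", 0.5),
        _poly_row("g1", 20, "down", 0.3),
        _poly_row("g1", 30, "up", 0.4),
    ]
    res = nearest_neighbor_classes(_sites_frame(rows))
    labels = dict(zip(res.labels.cds_pos, res.labels.label))
    assert labels[20] == "down_near_up"
    # the middle site is equidistant; the upstream neighbour (pos 10) wins
    assert dict(zip(res.labels.cds_pos, res.labels.neighbor_direction))[20] == "up"


def test_single_site_genes_contribute_nothing():
    res = nearest_neighbor_classes(_sites_frame([_poly_row("g1", 10, "up", 0.5)]))
    assert len(res.labels) == 0
    assert res.skipped_genes == 1


# ------------------------------------------------------------- regression

def test_noise_free_regression_recovers_exactly():
    rng = np.random.default_rng(2)
    n = 200
    x1, x2, x3 = rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
    y = 0.2 + 0.5 * x1 + 0.3 * x2 + 0.0 * x3
    df = pd.DataFrame({"daf": y, "delta_cai": x1, "delta_tai": x2, "gc": x3})
    res = regress_frequency(df)
    assert res.params["const"] == pytest.approx(0.2, abs=1e-10)
    assert res.params["delta_cai"] == pytest.approx(0.5, abs=1e-10)
    assert res.params["delta_tai"] == pytest.approx(0.3, abs=1e-10)
    assert res.params["gc"] == pytest.approx(0.0, abs=1e-10)
    assert res.n == n


def test_constant_predictor_flagged():
    df = pd.DataFrame(
        {"daf": [0.1, 0.2, 0.3, 0.4], "delta_cai": [1, 2, 3, 4],
         "delta_tai": [1.0, 1.0, 1.0, 1.0], "gc": [0.2, 0.5, 0.3, 0.6]}
    )
    res = regress_frequency(df)
    assert any("constant" in w for w in res.warnings)


def test_optimality_terms_dominate_gc_when_planted():
    rng = np.random.default_rng(9)
    n = 5000
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    x3 = rng.normal(size=n)
    y = 0.5 * x1 + 0.3 * x2 + 0.02 * x3 + rng.normal(scale=0.3, size=n)
    df = pd.DataFrame({"daf": y, "delta_cai": x1, "delta_tai": x2, "gc": x3})
    res = regress_frequency(df)
    assert abs(res.params["delta_cai"]) > abs(res.params["gc"])
    assert abs(res.params["delta_tai"]) > abs(res.params["gc"])


# ------------------------------------------------------------ correlation

def test_spearman_trivial_cases():
    assert correlate([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
    assert correlate([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)


def test_spearman_matches_rank_formula():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    rho, _ = correlate(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks == Spearman
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        correlate([1, 1, 1], [1, 2, 3])
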