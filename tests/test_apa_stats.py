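"""Gene-level KS and PAS-level NB-GLM statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrapa.apa_stats import (
    bh_adjust,
    estimate_dispersion,
    gene_level_apa,
    ks_signed,
    oriented_positions,
    pas_usage_test,
    proximal_distal_correlation,
    shrink_dispersions,
)
from lrapa.quantification import compute_pau, count_reads_at_pas, delta_pau


def ks_oracle(a, b):
    """Brute-force CDF scan over all distinct thresholds (vectorized
    membership counting, independent of the searchsorted implementation).
    Signed value = CDF difference at the first (most proximal) threshold
    attaining the maximum absolute difference."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    grid = np.array(sorted(set(a) | set(b)))
    f_a = (a[:, None] <= grid[None, :]).mean(axis=0)
    f_b = (b[:, None] <= grid[None, :]).mean(axis=0)
    diffs = f_a - f_b
    best = 0
    for j in range(len(grid)):
        if abs(diffs[j]) > abs(diffs[best]):
            best = j
    d = abs(float(diffs[best]))
    signed = float(diffs[best]) if diffs[best] != 0 else 0.0
    return signed, d


class TestOrientedPositions:
    def test_plus_identity(self):
        assert oriented_positions([100, 200], "+").tolist() == [100, 200]

    def test_minus_negation_distal_order(self):
        out = oriented_positions([100, 200], "-")
        assert out.tolist() == [-100, -200]
        assert out[0] > out[1]  # genomically left = more distal on '-'

    def test_empty(self):
        assert oriented_positions([], "+").size == 0


class TestKsSigned:
    def test_disjoint_supports_complete_lengthening(self):
        r = ks_signed([100] * 50, [200] * 50)
        assert r.apa_change == pytest.approx(1.0)
        assert r.statistic == pytest.approx(1.0)
        assert r.pvalue < 1e-10

    def test_identical_distributions(self):
        r = ks_signed([1, 2, 3] * 10, [1, 2, 3] * 10)
        assert r.apa_change == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_half_shift_example(self):
        # a = {0 x3, 10 x1}, b = {0 x1, 10 x3}: D+ = 0.5 at threshold 0
        r = ks_signed([0, 0, 0, 10], [0, 10, 10, 10])
        assert r.apa_change == pytest.approx(0.5)
        assert r.statistic == pytest.approx(0.5)

    def test_empty_side_raises(self):
        with pytest.raises(ValueError):
            ks_signed([], [1, 2])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-50, 50), min_size=1, max_size=500),
        b=st.lists(st.integers(-50, 50), min_size=1, max_size=500),
    )
    def test_oracle_equivalence(self, a, b):
        signed, d = ks_oracle(a, b)
        r = ks_signed(a, b)
        assert r.statistic == d  # exact
        assert abs(r.apa_change - signed) < 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-30, 30), min_size=1, max_size=100),
        b=st.lists(st.integers(-30, 30), min_size=1, max_size=100),
    )
    def test_antisymmetry(self, a, b):
        r_ab, r_ba = ks_signed(a, b), ks_signed(b, a)
        assert r_ab.apa_change == pytest.approx(-r_ba.apa_change, abs=1e-15)
        assert r_ab.pvalue == r_ba.pvalue

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-30, 30), min_size=1, max_size=80),
        b=st.lists(st.integers(-30, 30), min_size=1, max_size=80),
        shift=st.integers(-1000, 1000),
    )
    def test_shift_and_monotone_relabel_invariance(self, a, b, shift):
        r0 = ks_signed(a, b)
        r1 = ks_signed([x + shift for x in a], [x + shift for x in b])
        assert (r0.apa_change, r0.statistic, r0.pvalue) == (
            r1.apa_change, r1.statistic, r1.pvalue
        )
        # strictly monotone relabeling (cubic) preserves order, hence everything
        r2 = ks_signed([x**3 for x in a], [x**3 for x in b])
        assert (r0.apa_change, r0.statistic) == (r2.apa_change, r2.statistic)


class TestBhAdjust:
    def test_hand_computed_example(self):
        # m=3: q_(i) = min_{j>=i} p_(j) m / j -> all 0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_monotone_in_sorted_p(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
        assert np.all((np.asarray(q) >= np.asarray(ps) - 1e-12))


class TestEstimateDispersion:
    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(7)
        assert estimate_dispersion(rng.poisson(50, size=50)) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(8)
        size = 1 / 0.5
        y = rng.negative_binomial(size, size / (size + 50), size=50)
        assert 0.25 <= estimate_dispersion(y) <= 0.9

    def test_constant_counts_floored(self):
        assert estimate_dispersion(np.full(10, 20)) == pytest.approx(1e-8)

    def test_two_column_conditional_on_totals(self):
        """Library-size noise must not inflate the usage dispersion."""
        rng = np.random.default_rng(9)
        tot = rng.negative_binomial(10, 10 / 210, size=50)
        y = rng.binomial(tot, 0.3)
        est = estimate_dispersion(np.column_stack([y, tot - y]))
        assert est <= 0.01

    def test_condition_effect_not_counted_as_dispersion(self):
        rng = np.random.default_rng(10)
        cond = np.repeat(["a", "b"], 25)
        tot = np.full(50, 200)
        p = np.where(cond == "a", 0.2, 0.6)
        y = rng.binomial(tot, p)
        est = estimate_dispersion(np.column_stack([y, tot - y]), cond)
        assert est <= 0.01

    def test_shrinkage_moves_toward_trend(self):
        raw = np.array([0.0, 1.0, 0.5, 0.5])
        means = np.array([100.0, 100.0, 100.0, 100.0])
        shrunk = shrink_dispersions(raw, means, weight_raw=0.5)
        assert shrunk[0] > raw[0] and shrunk[1] < raw[1]


def _simulate_matrix(rng, n_genes, usage_a, usage_b, n_rep=3, depth=100):
    """Counts for K-PAS genes with per-condition usage vectors."""
    k = len(usage_a)
    idx, rows, genes = [], [], []
    samples = [f"a{i}" for i in range(n_rep)] + [f"b{i}" for i in range(n_rep)]
    for g in range(n_genes):
        mat = np.zeros((k, 2 * n_rep), dtype=int)
        for s in range(2 * n_rep):
            usage = usage_a if s < n_rep else usage_b
            mat[:, s] = rng.multinomial(rng.poisson(depth), usage)
        for i in range(k):
            idx.append(f"G{g}:PAS{i+1}")
            genes.append(f"G{g}")
            rows.append(mat[i])
    counts = pd.DataFrame(rows, index=idx, columns=samples, dtype=int)
    m = compute_pau(counts, pd.Series(genes, index=idx))
    m.conditions = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return m


class TestPasUsageTest:
    def test_planted_usage_switch_detected(self):
        rng = np.random.default_rng(11)
        m = _simulate_matrix(rng, 40, [0.7, 0.3], [0.2, 0.8], depth=100)
        res = pas_usage_test(m, "A", "B").set_index("pas_id")
        first = res[res.index.str.endswith("PAS1")]
        assert (first["significant"]).all()
        assert (first["log2fc_usage"] < 0).all()

    def test_identical_counts_pvalue_near_one(self):
        idx = ["G0:PAS1", "G0:PAS2"]
        counts = pd.DataFrame(
            [[30] * 6, [70] * 6], index=idx,
            columns=["a0", "a1", "a2", "b0", "b1", "b2"], dtype=int,
        )
        m = compute_pau(counts, pd.Series(["G0", "G0"], index=idx))
        m.conditions = {s: ("A" if s.startswith("a") else "B") for s in counts.columns}
        res = pas_usage_test(m, "A", "B")
        assert (res["pvalue"] > 0.9).all()
        assert (np.abs(res["log2fc_usage"]) < 1e-9).all()

    def test_single_pas_gene_not_tested(self):
        idx = ["G0:PAS1"]
        counts = pd.DataFrame([[50] * 4], index=idx,
                              columns=["a0", "a1", "b0", "b1"], dtype=int)
        m = compute_pau(counts, pd.Series(["G0"], index=idx))
        m.conditions = {"a0": "A", "a1": "A", "b0": "B", "b1": "B"}
        assert pas_usage_test(m, "A", "B").empty

    def test_unreplicated_design_rejected(self):
        idx = ["G0:PAS1", "G0:PAS2"]
        counts = pd.DataFrame([[30, 30], [70, 70]], index=idx,
                              columns=["a0", "b0"], dtype=int)
        m = compute_pau(counts, pd.Series(["G0", "G0"], index=idx))
        m.conditions = {"a0": "A", "b0": "B"}
        with pytest.raises(ValueError, match="replicates"):
            pas_usage_test(m, "A", "B")


class TestGeneLevelApa:
    def test_planted_shift_called_lengthening(self, small_ref, small_table,
                                              small_catalog, small_models):
        res = gene_level_apa(small_table, small_catalog, "control", "treated",
                            models=small_models)
        truth = {g.model.gene_id: g.effect for g in small_ref.genes}
        planted = [g for g, e in truth.items() if e == "lengthening"]
        sub = res[res["gene_id"].isin(planted)]
        assert (sub["direction"] == "lengthening").all()
        assert (sub["apa_change"] > 0.1).all()

    def test_swapped_conditions_negate(self, small_table, small_catalog):
        r1 = gene_level_apa(small_table, small_catalog, "control", "treated")
        r2 = gene_level_apa(small_table, small_catalog, "treated", "control")
        m = r1.merge(r2, on="gene_id", suffixes=("_f", "_r"))
        assert np.allclose(m["apa_change_f"], -m["apa_change_r"], atol=1e-15)
        assert np.allclose(m["pvalue_f"], m["pvalue_r"])

    def test_apa_type_attached(self, small_table, small_catalog, small_models,
                               small_ref):
        res = gene_level_apa(small_table, small_catalog, "control", "treated",
                            models=small_models)
        mixed_truth = {g.model.gene_id for g in small_ref.genes
                       if g.mixed and len(g.pas_positions) >= 2}
        got_mixed = set(res.loc[res["apa_type"] == "mixed", "gene_id"])
        # every truly mixed tested gene is labeled mixed
        assert mixed_truth & set(res["gene_id"]) <= got_mixed

    def test_single_pas_genes_excluded(self, small_table, small_catalog):
        res = gene_level_apa(small_table, small_catalog, "control", "treated")
        multi = {g for g, pl in small_catalog.genes.items() if len(pl) >= 2}
        assert set(res["gene_id"]) <= multi


class TestProximalDistalCorrelation:
    def test_distal_gain_sign_pattern(self, small_ref, small_table, small_catalog,
                                      small_matrix):
        res = gene_level_apa(small_table, small_catalog, "control", "treated")
        r_prox, r_dist = proximal_distal_correlation(
            res, small_matrix, "control", "treated"
        )
        assert r_prox < 0 and r_dist > 0

    def test_too_few_genes_errors(self, small_matrix):
        res = pd.DataFrame({"gene_id": ["G0001"], "apa_change": [0.2]})
        with pytest.raises(ValueError):
            proximal_distal_correlation(res, small_matrix, "control", "treated")

    def test_degenerate_variance_absent(self):
        idx = ["G0:PAS1", "G0:PAS2", "G1:PAS1", "G1:PAS2", "G2:PAS1", "G2:PAS2"]
        counts = pd.DataFrame(np.full((6, 4), 50), index=idx,
                              columns=["a0", "a1", "b0", "b1"], dtype=int)
        m = compute_pau(counts, pd.Series([i.split(":")[0] for i in idx], index=idx))
        m.conditions = {"a0": "A", "a1": "A", "b0": "B", "b1": "B"}
        res = pd.DataFrame({"gene_id": ["G0", "G1", "G2"],
                            "apa_change": [0.1, 0.2, 0.3]})
        r_prox, r_dist = proximal_distal_correlation(res, m, "A", "B")
        assert r_prox is None and r_dist is None
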