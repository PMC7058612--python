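import numpy as np
import pytest
from scipy import stats

from mitolandscape import ldstruct, simdata
from mitolandscape.iohap import (
    MISSING,
    HaploidGenotypeMatrix,
    VariantRecord,
    d_loop_annotation,
)


def brute_force_ld(x, y):
    """Independent 2x2 haplotype-count oracle for r2 and |D'|."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    n11 = np.sum((x == 1) & (y == 1))
    px = x.mean()
    py = y.mean()
    d = n11 / n - px * py
    r2 = d**2 / (px * (1 - px) * py * (1 - py))
    dmax = min(px * (1 - py), (1 - px) * py) if d >= 0 else min(px * py, (1 - px) * (1 - py))
    return r2, abs(d) / dmax


def matrix_at(positions, calls):
    calls = np.asarray(calls, dtype=np.int8)
    variants = [VariantRecord("MT", int(p), "A", "G") for p in positions]
    ids = [f"s{i}" for i in range(calls.shape[0])]
    return HaploidGenotypeMatrix(ids, variants, calls)


class TestPairwiseLD:
    def test_perfect_ld(self):
        assert ldstruct.haploid_r2([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert ldstruct.abs_dprime([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_independence(self):
        assert ldstruct.haploid_r2([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0)
        assert ldstruct.abs_dprime([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_worked_example(self):
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 1, 1, 0]
        assert ldstruct.haploid_r2(x, y) == pytest.approx(1 / 9)
        assert ldstruct.abs_dprime(x, y) == pytest.approx(1 / 3)

    def test_monomorphic_undefined(self):
        assert np.isnan(ldstruct.haploid_r2([0, 0, 0], [0, 1, 1]))
        assert np.isnan(ldstruct.abs_dprime([1, 1, 1], [0, 1, 1]))

    def test_missing_pairwise_complete(self):
        x = [0, 0, 1, 1, MISSING]
        y = [0, 0, 1, 1, 1]
        assert ldstruct.haploid_r2(x, y) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        checked = 0
        while checked < 500:
            n = int(rng.integers(4, 40))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            r2_o, dp_o = brute_force_ld(x, y)
            assert ldstruct.haploid_r2(x, y) == pytest.approx(r2_o, abs=1e-12)
            assert ldstruct.abs_dprime(x, y) == pytest.approx(dp_o, abs=1e-12)
            checked += 1

    def test_r2_equals_squared_pearson(self, rng):
        for _ in range(50):
            x = rng.integers(0, 2, 30)
            y = rng.integers(0, 2, 30)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            r = stats.pearsonr(x, y).statistic
            assert ldstruct.haploid_r2(x, y) == pytest.approx(r**2, abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self, rng):
        x = rng.integers(0, 2, 25)
        y = rng.integers(0, 2, 25)
        if len(set(x)) < 2 or len(set(y)) < 2:
            x[0], y[0] = 1 - x[1], 1 - y[1]
        assert ldstruct.haploid_r2(x, y) == pytest.approx(ldstruct.haploid_r2(y, x))
        assert ldstruct.haploid_r2(1 - x, 1 - y) == pytest.approx(ldstruct.haploid_r2(x, y))

    def test_r_bounded_by_dprime(self, rng):
        # |r| <= |D'| for every polymorphic pair
        for _ in range(100):
            x = rng.integers(0, 2, 20)
            y = rng.integers(0, 2, 20)
            r2 = ldstruct.haploid_r2(x, y)
            if np.isnan(r2):
                continue
            assert np.sqrt(r2) <= ldstruct.abs_dprime(x, y) + 1e-12


class TestMatchedNuclearPairs:
    @pytest.fixture(scope="class")
    def panel(self):
        return simdata.simulate_nuclear_panel(simdata.SimConfig(seed=17, n_samples=250))

    def test_distance_filter_contract(self, panel):
        pairs = ldstruct.matched_nuclear_pairs(panel, max_distance=8300, n_pairs=500, seed=0)
        assert (pairs["distance"] <= 8300).all()
        assert (pairs["source"] == "nuclear").all()

    def test_same_seed_same_sample(self, panel):
        a = ldstruct.matched_nuclear_pairs(panel, n_pairs=200, seed=4)
        b = ldstruct.matched_nuclear_pairs(panel, n_pairs=200, seed=4)
        assert a.equals(b)

    def test_no_qualifying_pairs_error(self, panel):
        with pytest.raises(ValueError):
            ldstruct.matched_nuclear_pairs(panel, max_distance=0, n_pairs=10, seed=0)

    def test_zero_recomb_panel_matches_founder_bruteforce(self):
        config = simdata.SimConfig(seed=23, n_samples=200, recomb_rate=0.0)
        panel = simdata.simulate_nuclear_panel(config)
        pairs = ldstruct.matched_nuclear_pairs(panel, max_distance=10**9, n_pairs=50, seed=1)
        for row in pairs.itertuples():
            r2_o, _ = brute_force_ld(panel.haplotypes[:, row.i], panel.haplotypes[:, row.j])
            assert row.r2 == pytest.approx(r2_o, abs=1e-12)


class TestDecayCorrelation:
    def test_constant_r2_is_degenerate(self):
        import pandas as pd

        pairs = pd.DataFrame({"distance": [100, 200, 300], "r2": [0.5, 0.5, 0.5]})
        res = ldstruct.ld_decay_correlation(pairs)
        assert np.isnan(res.pearson_r) and np.isnan(res.p_value)

    def test_too_few_distinct_distances(self):
        import pandas as pd

        pairs = pd.DataFrame({"distance": [100, 100, 100], "r2": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            ldstruct.ld_decay_correlation(pairs)

    def test_recombining_panel_decays(self):
        config = simdata.SimConfig(seed=31, n_samples=400)
        panel = simdata.simulate_nuclear_panel(config)
        pairs = ldstruct.matched_nuclear_pairs(panel, n_pairs=2000, seed=0)
        res = ldstruct.ld_decay_correlation(pairs)
        assert res.pearson_r < 0 and res.p_value < 0.01


class TestTagCounts:
    def test_duplicate_column_is_tagged(self):
        calls = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0], [1, 1, 0], [0, 0, 0], [1, 1, 1]])
        table = ldstruct.tag_counts(matrix_at([10, 20, 30], calls), maf_min=0.05)
        assert table.loc[table["variant"] == 0, "n_tags"].item() >= 1

    def test_orthogonal_variant_untagged(self):
        calls = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [0, 0], [0, 1], [1, 0], [1, 1]]
        )
        table = ldstruct.tag_counts(matrix_at([10, 20], calls), maf_min=0.05)
        assert (table["n_tags"] == 0).all()
        assert ldstruct.untagged_fraction(table) == 1.0

    def test_window_restricts_nuclear_search(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2, size=(40, 1)).astype(np.int8)
        calls = np.repeat(base, 3, axis=1)  # three perfect copies
        from mitolandscape.iohap import HaplotypePanel

        panel = HaplotypePanel(calls, np.array([1_000, 2_000, 9_000_000]))
        table = ldstruct.tag_counts(panel, window=5_000_000, maf_min=0.05)
        # the distant variant only sees partners beyond the window
        assert table.loc[table["position"] == 9_000_000, "n_tags"].item() == 0
        assert table.loc[table["position"] == 1_000, "n_tags"].item() == 1


class TestSpanningHaplotypes:
    def test_dispersed_perfect_ld_spans(self):
        col = np.array([0] * 5 + [1] * 5, dtype=np.int8).reshape(-1, 1)
        calls = np.repeat(col, 3, axis=1)
        spans = ldstruct.spanning_haplotypes(matrix_at([100, 8000, 16000], calls))
        assert len(spans) == 1
        assert spans[0].extent_bp == 15900
        assert spans[0].extent_fraction == pytest.approx(15900 / 16569)

    def test_local_cluster_does_not_span(self):
        col = np.array([0] * 5 + [1] * 5, dtype=np.int8).reshape(-1, 1)
        calls = np.repeat(col, 3, axis=1)
        spans = ldstruct.spanning_haplotypes(matrix_at([100, 500, 900], calls))
        assert spans == []

    def test_two_clades_each_span(self):
        rng = np.random.default_rng(1)
        clade = np.array([0] * 10 + [1] * 10, dtype=np.int8)
        other = rng.permutation(clade)
        calls = np.column_stack([clade, clade, clade, other, other, other])
        spans = ldstruct.spanning_haplotypes(
            matrix_at([50, 8100, 16200, 60, 8200, 16300], calls)
        )
        assert len(spans) == 2
        members = {s.positions for s in spans}
        assert (50, 8100, 16200) in members and (60, 8200, 16300) in members

    def test_membership_invariant_under_variant_reordering(self):
        rng = np.random.default_rng(2)
        clade = np.array([0] * 10 + [1] * 10, dtype=np.int8)
        calls = np.column_stack([clade, clade, clade])
        positions = [100, 8000, 16000]
        perm = rng.permutation(3)
        a = ldstruct.spanning_haplotypes(matrix_at(positions, calls))
        b = ldstruct.spanning_haplotypes(
            matrix_at([positions[i] for i in perm], calls[:, perm])
        )
        assert {s.positions for s in a} == {tuple(sorted(s.positions)) for s in b}


class TestDloopEnrichment:
    def _table(self, untagged_positions, tagged_positions):
        import pandas as pd

        rows = [(i, p, 0, True) for i, p in enumerate(untagged_positions)]
        rows += [(len(rows) + i, p, 3, False) for i, p in enumerate(tagged_positions)]
        return pd.DataFrame(rows, columns=["variant", "position", "n_tags", "untagged"])

    def test_perfect_association(self):
        table = self._table([16100] * 10, [8000] * 10)
        odds, p = ldstruct.dloop_untagged_enrichment(table, d_loop_annotation())
        assert np.isinf(odds)
        assert p == pytest.approx(2 / 184756, rel=1e-6)  # 1.08e-5 by enumeration
        assert p < 1e-4

    def test_no_association(self):
        table = self._table([16100] * 5 + [8000] * 5, [16100] * 5 + [8000] * 5)
        odds, p = ldstruct.dloop_untagged_enrichment(table, d_loop_annotation())
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        table = self._table([16100] * 5, [16200] * 5)
        with pytest.raises(ValueError):
            ldstruct.dloop_untagged_enrichment(table, d_loop_annotation())

    def test_hypermutable_dloop_enriched_in_simulation(self):
        config = simdata.SimConfig(
            seed=41, n_samples=1500, mutation_rate=1e-3, dloop_rate_multiplier=10.0
        )
        tree = simdata.simulate_haplotree(config)
        matrix, _ = simdata.simulate_mt_cohort(tree, config)
        # recurrent-mutation variants reach the low-frequency range; defining
        # variants tag each other while recurrences are uncorrelated
        table = ldstruct.tag_counts(matrix, maf_min=0.01)
        dloop = d_loop_annotation(config.mt_length)
        in_d = np.asarray(dloop.contains(table["position"].to_numpy()))
        assert table.loc[in_d, "untagged"].mean() > table.loc[~in_d, "untagged"].mean()
        odds, _ = ldstruct.dloop_untagged_enrichment(table, dloop)
        assert odds > 1
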