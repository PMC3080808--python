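"""tm/ts scores, typicality calls and alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import agep
from agep.exceptions import ConfigurationError, DomainError, InputError
from agep.scoring import (
    ATYPICAL,
    TYPICAL,
    align,
    call_typicality,
    null_cdf,
    ratio_weighted_difference as rwd,
    sample_from_density,
    tm_profile,
    tm_score,
    ts_matrix,
    typicality_null,
)
from agep.synthetic import generate_query


def brute_force_tm(value, gene, tissue):
    """Independent full-grid scan: fraction of points with density <= d."""
    dens = gene.densities[tissue]
    lo, hi = gene.ranges[tissue]
    if value < lo or value > hi:
        return 0.0
    d = np.interp(value, gene.grid, dens)
    if d <= 0:
        return 0.0
    return sum(1 for f in dens if f <= d) / len(dens)


class TestTmScore:
    def test_outside_observed_range_is_zero(self, small_model):
        gene = small_model.genes["g0"]
        t = "brain"
        lo, hi = gene.ranges[t]
        assert tm_score(hi + 1.0, gene, t) == 0.0
        assert tm_score(max(lo - 1.0, 0.0), gene, t) == 0.0

    def test_mode_scores_one(self, small_model):
        gene = small_model.genes["g0"]
        t = "brain"
        mode = gene.grid[np.argmax(gene.densities[t])]
        assert tm_score(mode, gene, t) == 1.0

    def test_matches_brute_force_scan(self, small_model):
        rng = np.random.default_rng(0)
        for gid in ["g1", "g5", "g9"]:
            gene = small_model.genes[gid]
            for t in gene.densities:
                lo, hi = gene.ranges[t]
                for value in rng.uniform(lo * 0.8, hi * 1.1, size=8):
                    assert tm_score(value, gene, t) == brute_force_tm(value, gene, t)

    def test_monotone_in_density(self, small_model):
        gene = small_model.genes["g3"]
        t = "liver"
        lo, hi = gene.ranges[t]
        xs = np.linspace(lo, hi, 100)
        d = [np.interp(x, gene.grid, gene.densities[t]) for x in xs]
        tm = [tm_score(x, gene, t) for x in xs]
        order = np.argsort(d)
        assert (np.diff(np.array(tm)[order]) >= 0).all()


class TestTmProfile:
    def test_self_query_prefers_own_tissue(self, small_matrix, small_model):
        query = small_matrix.query_of("brain0")
        tm = tm_profile(query, small_model)
        means = tm.mean(axis=0)
        assert means.idxmax() == "brain"

    def test_missing_genes_propagate(self, small_matrix, small_model):
        query = small_matrix.query_of("liver2")[::2]
        tm = tm_profile(query, small_model)
        assert set(tm.index) == set(query.index)

    def test_disjoint_gene_universe_errors(self, small_model):
        with pytest.raises(InputError):
            tm_profile(pd.Series({"nope": 1.0}), small_model)

    def test_all_zero_query_scores_zero(self, small_model):
        # every tissue expresses every gene well above zero
        query = pd.Series(0.0, index=list(small_model.genes))
        tm = tm_profile(query, small_model)
        assert (tm.fillna(0.0).to_numpy() == 0.0).all()


class TestTypicality:
    def test_null_weights_sum_to_one(self, small_model):
        gene = small_model.genes["g2"]
        for t in gene.densities:
            _, w = typicality_null(gene, t)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_density_single_atom(self):
        gene = agep.reference.GeneDensity(
            gene_id="u",
            grid=np.linspace(0.0, 1.0, 512),
            densities={"t": np.ones(512)},
            bandwidths={"t": 0.1},
            gene_max=1.0,
            ranges={"t": (0.0, 1.0)},
        )
        tm_vals, w = typicality_null(gene, "t")
        assert set(np.round(tm_vals, 12)) == {1.0}
        assert w.sum() == pytest.approx(1.0)

    def test_mode_typical_out_of_range_atypical(self, small_model):
        gene = small_model.genes["g4"]
        t = "muscle"
        null = typicality_null(gene, t)
        mode = gene.grid[np.argmax(gene.densities[t])]
        assert call_typicality(tm_score(mode, gene, t), null) == TYPICAL
        assert call_typicality(0.0, null) == ATYPICAL
        assert call_typicality(float("nan"), null) == "undefined"

    def test_hdr_equivalence(self, small_model):
        """Atypical call <=> query outside the (1-alpha) highest-density region."""
        alpha = 0.05
        gene = small_model.genes["g7"]
        for t in gene.densities:
            dens, grid = gene.densities[t], gene.grid
            tm_vals, w = typicality_null(gene, t)
            # HDR oracle: find the density cutoff c with mass(f >= c) >= 1-alpha
            order = np.argsort(dens)[::-1]
            cum = np.cumsum(w[order])
            cutoff_idx = order[np.searchsorted(cum, 1 - alpha)]
            cutoff = dens[cutoff_idx]
            null = typicality_null(gene, t)
            for i in range(0, 512, 31):
                if dens[i] <= 0:
                    continue
                call = call_typicality(tm_score(grid[i], gene, t), null, alpha)
                inside_hdr = dens[i] >= cutoff
                assert (call == TYPICAL) == inside_hdr

    def test_calibration_on_own_density(self, benchmark):
        """Draws from a tissue's own density are atypical at ~alpha."""
        _, _, model = benchmark
        rng = np.random.default_rng(11)
        gene = model.genes["gene_0050"]
        t = "tissue_00"
        null = typicality_null(gene, t)
        draws = sample_from_density(gene, t, 10_000, rng)
        calls = np.array(
            [call_typicality(tm_score(x, gene, t), null, 0.05) for x in draws]
        )
        rate = (calls == ATYPICAL).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_monte_carlo_null_agreement(self, benchmark):
        """Empirical tm CDF from density-weighted draws matches the analytic null."""
        _, _, model = benchmark
        rng = np.random.default_rng(17)
        for gid in ["gene_0010", "gene_0030"]:
            gene = model.genes[gid]
            t = "tissue_01"
            tm_vals, w = typicality_null(gene, t)
            xs = gene.grid[rng.choice(512, size=100_000, p=w)]
            tms = np.sort([tm_score(x, gene, t) for x in xs])
            tm_sorted, cum = null_cdf(gene, t)
            atoms = np.unique(tm_sorted)
            emp = np.searchsorted(tms, atoms, side="right") / tms.size
            ana = cum[np.searchsorted(tm_sorted, atoms, side="right") - 1]
            assert np.abs(emp - ana).max() < 0.01


class TestRatioWeightedDifference:
    def test_printed_anchors(self):
        assert rwd(0.5, 0.0) == pytest.approx(5 / 6)
        assert rwd(1.0, 0.5) == pytest.approx(1 / 2)

    def test_extremes(self):
        assert rwd(1.0, 0.0) == 1.0
        assert rwd(0.0, 1.0) == -1.0
        assert rwd(0.3, 0.3) == 0.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            rwd(1.2, 0.0)
        with pytest.raises(DomainError):
            rwd(0.5, 0.5, phi=0.0)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0.01, max_value=10),
    )
    def test_antisymmetric_and_bounded(self, a, b, phi):
        x = rwd(a, b, phi)
        assert -1.0 <= x <= 1.0
        assert x == pytest.approx(-rwd(b, a, phi), abs=1e-12)

    def test_low_pairs_differentiate_more(self):
        # same difference 0.4, lower pair scores higher in magnitude
        assert rwd(0.6, 0.2) > rwd(1.0, 0.6)


class TestTsMatrix:
    def make_tm(self, rows, tissues=("a", "b", "c")):
        return pd.DataFrame(rows, columns=list(tissues))

    def test_unique_marker_scores_one(self):
        tm = self.make_tm([[1.0, 0.0, 0.0]])
        ts = ts_matrix(tm)
        assert ts.iloc[0, 0] == pytest.approx(1.0)

    def test_identical_tm_gives_zero(self):
        tm = self.make_tm([[0.4, 0.4, 0.4]])
        assert (ts_matrix(tm).iloc[0] == 0.0).all()

    def test_hand_computed_three_tissue_case(self):
        tm = self.make_tm([[0.5, 0.0, 1.0]])
        ts = ts_matrix(tm)
        assert ts.iloc[0, 0] == pytest.approx((5 / 6 - 1 / 2) / 2)  # = 1/6

    def test_two_tissue_antisymmetry(self):
        tm = self.make_tm([[0.0, 1.0]], tissues=("a", "b"))
        ts = ts_matrix(tm)
        assert ts.iloc[0, 0] == -1.0
        assert ts.iloc[0, 1] == 1.0

    def test_missing_handling(self):
        tm = self.make_tm([[0.5, np.nan, 1.0], [np.nan, np.nan, 0.3]])
        ts = ts_matrix(tm)
        assert np.isnan(ts.iloc[0, 1])
        assert ts.iloc[0, 0] == pytest.approx(rwd(0.5, 1.0))
        assert np.isnan(ts.iloc[1]).all()  # single tissue: no comparator

    def test_single_tissue_model_errors(self):
        with pytest.raises(ConfigurationError):
            ts_matrix(pd.DataFrame({"only": [0.5]}))

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(2)
        tm = pd.DataFrame(rng.random((50, 6)))
        ts = ts_matrix(tm)
        assert ((ts >= -1) & (ts <= 1)).all().all()


class TestAlign:
    def test_query_from_tissue_ranks_it_first(self, benchmark):
        _, truth, model = benchmark
        for i, t in enumerate(["tissue_00", "tissue_03"]):
            query, _ = generate_query(truth, t, seed=900 + i)
            result = align(query, model)
            assert result.top_tissue == t

    def test_tissue_order_invariance(self, small_matrix):
        reordered = agep.ExpressionMatrix(
            small_matrix.values.iloc[:, ::-1], small_matrix.tissue_labels[::-1]
        )
        m1 = agep.build_reference(small_matrix)
        m2 = agep.build_reference(reordered)
        query = small_matrix.query_of("muscle3")
        r1, r2 = align(query, m1), align(query, m2)
        assert r1.ranking == r2.ranking
        pd.testing.assert_series_equal(
            r1.similarity.sort_index(), r2.similarity.sort_index()
        )

    def test_matching_and_specific_quadrant(self, benchmark):
        """Markers of the query's tissue land in the high-tm/high-ts quadrant."""
        _, truth, model = benchmark
        query, _ = generate_query(truth, "tissue_02", seed=31)
        result = align(query, model)
        scatter = result.scatter("tissue_02")
        markers = [g for g in truth.markers["tissue_02"] if g in scatter.index]
        quadrant = scatter[(scatter.tm > 0.5) & (scatter.ts > 0.5)]
        assert len(set(markers) & set(quadrant.index)) >= 0.8 * len(markers)

    def test_similarity_is_mean_ts_and_ranking_sorted(self, small_matrix, small_model):
        result = align(small_matrix.query_of("brain1"), small_model)
        for t in small_model.tissues:
            assert result.similarity[t] == pytest.approx(
                result.ts[t].mean(), abs=1e-12
            )
        sims = [result.similarity[t] for t in result.ranking]
        assert sims == sorted(sims, reverse=True)

    def test_marker_recovery_rate(self, benchmark):
        """Markers shifted 6 within-tissue SDs reach ts > 0.75 in >=90% of cases."""
        _, truth, model = benchmark
        hits = total = 0
        for i, t in enumerate(truth.spec.tissue_names):
            query, _ = generate_query(truth, t, seed=100 + i)
            result = align(query, model)
            for gene in truth.markers[t]:
                total += 1
                hits += bool(result.ts.at[gene, t] > 0.75)
        assert hits / total >= 0.90
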