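import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ximosaic import (CRE_NEG, CRE_POS, ReactivationModel,
                      expected_bulk_counts, reactivation_probability,
                      sample_reactivation_states, simulate_bulk_counts)
from ximosaic.reactivation import CellPopulation

from conftest import manual_fixture


class TestReactivationProbability:
    def test_limits(self):
        model = ReactivationModel(p_max=0.04, e50=1.5, h=1.2)
        assert reactivation_probability(1e-12, model) < 1e-10
        assert reactivation_probability(1e12, model) == pytest.approx(0.04, rel=1e-6)

    def test_nonpositive_expression_rejected(self):
        model = ReactivationModel()
        with pytest.raises(ValueError):
            reactivation_probability(0.0, model)
        with pytest.raises(ValueError):
            reactivation_probability(-1.0, model)

    def test_default_calibration_matches_reporter_rates(self, default_fixture):
        # a highly expressed gene (top-tercile median, the reporter regime)
        # reactivates in 2.3-4.8% of cells; at 100-fold lower expression
        # (the low-activity regime) in at most 0.2%
        model = ReactivationModel()
        top = float(np.quantile(default_fixture.x_genes["expr_rate"], 5 / 6))
        assert 0.023 <= reactivation_probability(top, model) <= 0.048
        assert reactivation_probability(top / 100, model) <= 0.002

    @given(e1=st.floats(1e-6, 1e6), e2=st.floats(1e-6, 1e6))
    def test_monotone_and_bounded(self, e1, e2):
        model = ReactivationModel(p_max=0.3, e50=2.0, h=1.5)
        p1, p2 = model.probability(e1), model.probability(e2)
        assert 0 <= p1 <= 0.3
        if e1 <= e2:
            assert p1 <= p2

    def test_invalid_model_parameters(self):
        with pytest.raises(ValueError):
            ReactivationModel(p_max=1.5)
        with pytest.raises(ValueError):
            ReactivationModel(h=0)


class TestSampleReactivationStates:
    def test_cre_negative_is_all_silent(self, small_fixture):
        pop = sample_reactivation_states(small_fixture, ReactivationModel(),
                                         100, CRE_NEG, seed=1)
        assert not pop.indicators.any()

    def test_ceiling_model_reactivates_everything(self, small_fixture):
        pop = sample_reactivation_states(
            small_fixture, ReactivationModel(p_max=1.0, e50=0.0), 50, CRE_POS, seed=1)
        assert pop.indicators.all()

    def test_per_gene_fraction_within_binomial_interval(self):
        # p=0.05 and 10,000 cells: fraction inside the 99.9% binomial band
        fx = manual_small_x_fixture(n_genes=5)
        pop = sample_reactivation_states(
            fx, ReactivationModel.uniform(0.05), 10_000, CRE_POS, seed=2)
        frac = pop.reactivated_fraction
        assert ((0.042 <= frac) & (frac <= 0.058)).all()

    def test_unknown_condition_and_coupling_rejected(self, small_fixture):
        with pytest.raises(ValueError):
            sample_reactivation_states(small_fixture, ReactivationModel(),
                                       10, "Cre?", seed=1)
        with pytest.raises(ValueError):
            sample_reactivation_states(small_fixture, ReactivationModel(),
                                       10, CRE_POS, seed=1, coupling="nope")

    def test_chromosome_coupling_preserves_marginals_and_couples_cells(self):
        fx = manual_small_x_fixture(n_genes=6)
        model = ReactivationModel(p_max=0.3, e50=1.0, h=1.0)
        pop = sample_reactivation_states(fx, model, 20_000, CRE_POS, seed=3,
                                         coupling="chromosome")
        p = model.probability(fx.x_genes["expr_rate"].to_numpy())
        se = np.sqrt(p * (1 - p) / 20_000)
        assert (np.abs(pop.reactivated_fraction - p) < 4 * se).all()
        # chromosome-wide events make per-cell gene states positively coupled
        corr = np.corrcoef(pop.indicators)[0, 1]
        assert corr > 0.1


class TestSimulateBulkCounts:
    def test_expected_value_contract(self, small_fixture):
        x_ids = pd.Index(small_fixture.x_genes["gene_id"])
        silent = CellPopulation(CRE_POS, 4, x_ids,
                                np.zeros((len(x_ids), 4), dtype=np.uint8))
        full = CellPopulation(CRE_POS, 4, x_ids,
                              np.ones((len(x_ids), 4), dtype=np.uint8))
        e_silent = expected_bulk_counts(small_fixture, silent, depth=10.0)
        e_full = expected_bulk_counts(small_fixture, full, depth=10.0)
        genes = small_fixture.genes.set_index("gene_id")
        on_x = genes["chrom"] == "X"
        # one active allele when silent, doubled when fully reactivated
        assert np.allclose(e_silent[on_x], genes.loc[on_x, "expr_rate"] * 10.0)
        assert np.allclose(e_full[on_x], 2 * e_silent[on_x])
        # autosomes always carry two active alleles
        assert np.allclose(e_silent[~on_x], 2 * genes.loc[~on_x, "expr_rate"] * 10.0)
        assert np.allclose(e_full[~on_x], e_silent[~on_x])

    def test_expectation_matches_per_cell_brute_force(self):
        # brute force: sum each cell's allele contributions explicitly
        fx = manual_small_x_fixture(n_genes=8)
        rng = np.random.default_rng(5)
        ind = (rng.random((8, 60)) < 0.3).astype(np.uint8)
        pop = CellPopulation(CRE_POS, 60, pd.Index(fx.x_genes["gene_id"]), ind)
        depth = 7.0
        expected = expected_bulk_counts(fx, pop, depth)
        expr = fx.genes.set_index("gene_id")["expr_rate"]
        for g, gene_id in enumerate(fx.x_genes["gene_id"]):
            brute = sum((1 + ind[g, c]) * expr[gene_id] * depth
                        for c in range(60)) / 60
            assert expected[gene_id] == pytest.approx(brute, rel=1e-12)

    def test_poisson_noise_variance_to_mean(self):
        # dispersion 0: index of dispersion near 1 over 1,000 replicate draws
        fx = manual_small_x_fixture(n_genes=2, expr=5.0)
        x_ids = pd.Index(fx.x_genes["gene_id"])
        zeros = np.zeros((2, 1), dtype=np.uint8)
        pops = [CellPopulation(CRE_POS, 1, x_ids, zeros) for _ in range(500)]
        pops += [CellPopulation(CRE_NEG, 1, x_ids, zeros) for _ in range(500)]
        cm = simulate_bulk_counts(fx, pops, depth=20.0, dispersion=0.0, seed=9)
        row = cm.counts.iloc[0].to_numpy(float)  # 1,000 draws of one gene
        assert 0.9 <= row.var(ddof=1) / row.mean() <= 1.1

    def test_negative_binomial_overdispersion(self):
        fx = manual_small_x_fixture(n_genes=2, expr=5.0)
        x_ids = pd.Index(fx.x_genes["gene_id"])
        zeros = np.zeros((2, 1), dtype=np.uint8)
        pops = [CellPopulation(CRE_POS, 1, x_ids, zeros) for _ in range(500)]
        pops += [CellPopulation(CRE_NEG, 1, x_ids, zeros) for _ in range(500)]
        cm = simulate_bulk_counts(fx, pops, depth=20.0, dispersion=0.1, seed=9)
        row = cm.counts.iloc[0].to_numpy(float)
        m = row.mean()
        assert row.var(ddof=1) > 1.5 * m  # far above Poisson at alpha=0.1, m=100

    def test_increasing_ceiling_increases_top_gene_reactivation(self, small_fixture):
        fracs = []
        for p_max in (0.02, 0.05, 0.1):
            pop = sample_reactivation_states(
                small_fixture, ReactivationModel(p_max=p_max), 20_000,
                CRE_POS, seed=11)
            expr = small_fixture.x_genes["expr_rate"].to_numpy()
            top = expr >= np.quantile(expr, 2 / 3)
            fracs.append(pop.reactivated_fraction[top].mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_input_validation(self, small_fixture):
        with pytest.raises(ValueError):
            simulate_bulk_counts(small_fixture, [], 10.0, 0.0, seed=1)
        x_ids = pd.Index(small_fixture.x_genes["gene_id"])
        pop = CellPopulation(CRE_POS, 1, x_ids,
                             np.zeros((len(x_ids), 1), dtype=np.uint8))
        with pytest.raises(ValueError):
            simulate_bulk_counts(small_fixture, [pop], -1.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_bulk_counts(small_fixture, [pop], 10.0, -0.1, seed=1)


def manual_small_x_fixture(n_genes=5, expr=2.0):
    """A minimal fixture with only X genes (plus one autosomal gene)."""
    import pandas as pd
    from ximosaic.genome import GenomeFixture, MethylomeState

    rows = [("auto_g0", "autosome_1", "+", 10, 1010, 10, expr)]
    rows += [(f"X_g{i}", "X", "+", 10 + 2000 * i, 1010 + 2000 * i,
              10 + 2000 * i, expr * (1 + 0.5 * i)) for i in range(n_genes)]
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss",
                       "expr_rate"]
    ).astype({"start": np.int64, "end": np.int64, "tss": np.int64})
    islands = pd.DataFrame(columns=["island_id", "chrom", "start", "end",
                                    "host_gene_id", "hyper"])
    sites = pd.DataFrame(columns=["island_id", "chrom", "pos", "assayable"])
    probs = {c: {a: np.empty(0) for a in ("auto", "xa", "xi")}
             for c in (CRE_NEG, CRE_POS)}
    return GenomeFixture({"autosome_1": 100_000, "X": 100_000}, genes,
                         islands, sites, MethylomeState(probs), {"seed": 0})
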