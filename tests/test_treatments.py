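"""The four non-response treatments and Rubin's-rules pooling."""

import numpy as np
import pytest

import netmiss as nm
from netmiss.missingness import MISSING, MissingnessSpec
from netmiss.synthetic import GenerationSpec
from netmiss.treatments import MIConfig

from conftest import RECONSTRUCTED_ROWS, REDUCED_EXPECTED


def complete_reports(net: nm.TrueNetwork) -> nm.ObservedReports:
    return nm.ObservedReports(net.ties, directed_data=net.directed, labels=net.labels,
                              source=net)


class TestCompleteCase:
    def test_worked_example_matches_printed_reduced_network(self, example_reports):
        res = nm.complete_case(example_reports)
        assert res.retained_actors == ("B", "C", "E", "G")
        assert np.array_equal(res.completed.ties, REDUCED_EXPECTED)

    def test_fully_observed_reports_keep_everyone(self):
        net = nm.generate_network(GenerationSpec(n=20, seed=0))
        res = nm.complete_case(complete_reports(net))
        assert res.retained_actors == net.labels
        assert np.array_equal(res.completed.ties, net.ties)

    def test_everyone_missing_signals_not_applicable(self):
        e = np.full((5, 5), MISSING, dtype=np.int8)
        np.fill_diagonal(e, 0)
        with pytest.raises(nm.NotApplicableError):
            nm.complete_case(nm.ObservedReports(e))

    def test_reduced_network_is_principal_submatrix_of_truth(self):
        net = nm.generate_network(GenerationSpec(n=30, seed=1))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.05, granularity="row", seed=1))
        res = nm.complete_case(rep)
        idx = [net.labels.index(a) for a in res.retained_actors]
        assert np.array_equal(res.completed.ties, np.asarray(net.ties)[np.ix_(idx, idx)])


class TestUnconditionalMeanImputation:
    def test_sparse_network_imputes_zeros(self):
        net = nm.generate_network(GenerationSpec(n=50, seed=2))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.25, seed=2))
        res = nm.unconditional_mean_impute(rep)
        filled = res.completed.ties[rep.missing_mask]
        assert (filled == 0).all()
        assert res.n_imputed == 613

    def test_dense_network_imputes_ones(self):
        ties = 1 - np.eye(6, dtype=np.int8)
        rep = nm.delete_ties(nm.TrueNetwork(ties), MissingnessSpec("MCAR", 0.2, seed=0))
        res = nm.unconditional_mean_impute(rep)
        assert (res.completed.ties[rep.missing_mask] == 1).all()

    def test_worked_example_observed_density_two_thirds_fills_ones(self, example_reports):
        # 16 observed ties over 24 observed cells >= 0.5, so all 18 fills are 1
        res = nm.unconditional_mean_impute(example_reports)
        assert res.n_imputed == 18
        assert (res.completed.ties[example_reports.missing_mask] == 1).all()

    def test_threshold_boundary_imputes_one(self):
        e = np.array([[0, 1, MISSING], [0, 0, 1], [MISSING, 0, 0]], dtype=np.int8)
        # observed mean exactly 2/4 = 0.5: the >= rule imputes 1
        res = nm.unconditional_mean_impute(nm.ObservedReports(e))
        assert res.completed.ties[0, 2] == 1 and res.completed.ties[2, 0] == 1

    def test_actor_variants_use_row_and_column_means(self):
        e = np.array(
            [
                [0, MISSING, 1, 1],
                [0, 0, 0, 0],
                [1, 0, 0, 1],
                [1, 1, 1, 0],
            ],
            dtype=np.int8,
        )
        rep = nm.ObservedReports(e)
        # sender A's observed outgoing mean = 1.0 -> impute 1
        out = nm.unconditional_mean_impute(rep, variant="actor_out")
        assert out.completed.ties[0, 1] == 1
        # receiver B's observed incoming mean = 1/2 -> threshold ties to 1
        inn = nm.unconditional_mean_impute(rep, variant="actor_in")
        assert inn.completed.ties[0, 1] == 1

    def test_no_observed_cells_not_applicable(self):
        e = np.full((4, 4), MISSING, dtype=np.int8)
        np.fill_diagonal(e, 0)
        with pytest.raises(nm.NotApplicableError):
            nm.unconditional_mean_impute(nm.ObservedReports(e))


class TestReconstruction:
    def test_worked_example_nonrespondent_rows(self, example_reports):
        res = nm.reconstruct(nm.load_fixture("friendship"))
        lab = res.completed.labels.index
        for actor, row in RECONSTRUCTED_ROWS.items():
            for j, val in enumerate(row):
                if val is None:
                    continue
                expected = 0 if val == MISSING else val  # secondary zero-fill
                assert res.completed.ties[lab(actor), j] == expected, (actor, j)

    def test_fully_observed_is_identity(self):
        net = nm.generate_network(GenerationSpec(n=20, seed=3))
        res = nm.reconstruct(complete_reports(net))
        assert np.array_equal(res.completed.ties, net.ties)

    def test_mutual_nonrespondents_resolved_by_secondary(self):
        e = np.zeros((4, 4), dtype=np.int8)
        e[0, :] = MISSING
        e[1, :] = MISSING
        np.fill_diagonal(e, 0)
        e[2, :2] = 1
        e[3, :2] = 1
        rep = nm.ObservedReports(e)
        zero = nm.reconstruct(rep, secondary="zero")
        assert zero.completed.ties[0, 1] == 0 and zero.completed.ties[1, 0] == 0
        # umi_density: observed density = 4/10 < 0.5 -> also 0; force dense case
        dense = np.where(e == 0, 1, e).astype(np.int8)
        np.fill_diagonal(dense, 0)
        res = nm.reconstruct(nm.ObservedReports(dense), secondary="umi_density")
        assert res.completed.ties[0, 1] == 1

    def test_reciprocal_truth_row_missingness_recovered_exactly(self, rng):
        """Symmetric truth + row deletion: reconstruction is exact except
        both-missing dyads."""
        for seed in range(10):
            net = nm.generate_network(GenerationSpec(n=20, directed=False, seed=seed))
            directed_view = nm.TrueNetwork(net.ties, directed=True, labels=net.labels)
            rep = nm.delete_ties(
                directed_view, MissingnessSpec("MCAR", 0.15, granularity="row", seed=seed)
            )
            res = nm.reconstruct(rep)
            both = rep.missing_mask & rep.missing_mask.T
            assert np.array_equal(res.completed.ties[~both], np.asarray(net.ties)[~both])

    def test_undirected_surviving_report_wins(self):
        net = nm.generate_network(GenerationSpec(n=20, directed=False, seed=6))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.25, seed=6))
        res = nm.reconstruct(rep)
        one_sided = rep.missing_mask & ~rep.missing_mask.T
        assert np.array_equal(res.completed.ties[one_sided], np.asarray(net.ties)[one_sided])


class TestMultipleImputation:
    def test_no_missing_cells_returns_m_copies(self):
        net = nm.generate_network(GenerationSpec(n=15, seed=4))
        res = nm.multiple_impute(complete_reports(net), MIConfig(m=3, seed=0))
        assert len(res.networks) == 3
        for out in res.networks:
            assert np.array_equal(out.ties, net.ties)

    def test_observed_cells_untouched(self):
        net = nm.generate_network(GenerationSpec(n=30, seed=5))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.25, seed=5))
        attrs = nm.generate_attributes(30, seed=5)
        res = nm.multiple_impute(rep, MIConfig(m=4, seed=5), attrs=attrs)
        obs = ~rep.missing_mask
        for out in res.networks:
            assert np.array_equal(out.ties[obs], net.ties[obs])

    def test_intercept_only_fallback_fills_at_observed_density(self):
        """With no usable predictors the fill rate matches the observed density."""
        net = nm.generate_network(GenerationSpec(n=40, target_density=0.3, seed=7))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.25, seed=7))
        d = rep.entries[(rep.entries != MISSING) & ~np.eye(40, dtype=bool)].mean()
        res = nm.multiple_impute(rep, MIConfig(m=100, predictors=(), seed=7))
        fills = np.array([out.ties[rep.missing_mask].mean() for out in res.networks])
        n_draws = res.n_imputed * 100
        se = np.sqrt(d * (1 - d) / n_draws)
        assert abs(fills.mean() - d) < 3 * se

    def test_between_imputation_variance_positive(self):
        net = nm.generate_network(GenerationSpec(n=50, seed=8))
        attrs = nm.generate_attributes(50, seed=8)
        rep = nm.delete_ties(net, MissingnessSpec("MAR", 0.25, seed=8), attrs=attrs)
        positive = 0
        for seed in range(30):
            res = nm.multiple_impute(rep, MIConfig(m=5, seed=seed), attrs=attrs)
            dens = [nm.density(out) for out in res.networks]
            if nm.rubin_combine(dens).between > 0:
                positive += 1
        assert positive >= 28

    def test_seeded_reproducibility(self):
        net = nm.generate_network(GenerationSpec(n=25, seed=9))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.1, seed=9))
        a = nm.multiple_impute(rep, MIConfig(m=3, seed=11))
        b = nm.multiple_impute(rep, MIConfig(m=3, seed=11))
        for x, y in zip(a.networks, b.networks):
            assert np.array_equal(x.ties, y.ties)

    def test_undirected_imputations_symmetric(self):
        net = nm.generate_network(GenerationSpec(n=25, directed=False, seed=10))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.4, seed=10))
        res = nm.multiple_impute(rep, MIConfig(m=3, seed=10))
        for out in res.networks:
            assert not out.directed
            assert np.array_equal(out.ties, out.ties.T)


class TestRubinCombine:
    def test_closed_form_point_and_between(self):
        pooled = nm.rubin_combine([1.0, 2.0, 3.0])
        assert pooled.point == pytest.approx(2.0)
        assert pooled.between == pytest.approx(1.0)

    def test_identical_estimates_have_zero_between(self):
        pooled = nm.rubin_combine([0.4, 0.4, 0.4], within_vars=[0.1, 0.1, 0.1])
        assert pooled.between == pytest.approx(0.0, abs=1e-30)
        assert pooled.total == pytest.approx(pooled.within) == pytest.approx(0.1)

    def test_total_variance_formula(self):
        pooled = nm.rubin_combine([0.0, 0.2, 0.4, 0.6], within_vars=[0.2] * 4)
        # T = W + (1 + 1/4) B with B the sample variance of the estimates
        assert pooled.total == pytest.approx(0.2 + 1.25 * pooled.between)
        b_hand = np.var([0.0, 0.2, 0.4, 0.6], ddof=1)
        assert pooled.between == pytest.approx(b_hand)

    def test_single_estimate_rejected(self):
        with pytest.raises(nm.ConfigurationError):
            nm.rubin_combine([1.0])


@pytest.mark.parametrize("treatment", ["umi", "re", "mi"])
def test_no_treatment_modifies_observed_cells(treatment, rng):
    """Bit-level check: observed report cells survive every treatment."""
    for seed in range(5):
        directed = seed % 2 == 0
        net = nm.generate_network(GenerationSpec(n=20, directed=directed, seed=seed))
        rep = nm.delete_ties(net, MissingnessSpec("MCAR", 0.2, seed=seed))
        attrs = nm.generate_attributes(20, seed=seed)
        if treatment == "umi":
            outs = [nm.unconditional_mean_impute(rep).completed]
        elif treatment == "re":
            outs = [nm.reconstruct(rep).completed]
        else:
            outs = nm.multiple_impute(rep, MIConfig(m=2, seed=seed), attrs=attrs).networks
        if directed:
            obs = ~rep.missing_mask
        else:
            obs = (nm.pair_reports(rep) != MISSING) & ~np.eye(20, dtype=bool)
        for out in outs:
            assert np.array_equal(out.ties[obs], net.ties[obs])
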