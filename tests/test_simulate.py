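"""Synthetic-data generator: structure, genetic signal, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pigsna.pedigree import Pedigree, build_A
from pigsna.simulate import (
    CompositionError,
    EdgeModel,
    TrueParameters,
    assign_pens,
    nearest_correlation,
    realistic_dataset,
    realistic_parameters,
    recovery_dataset,
    simulate_binary_trait,
    simulate_breeding_values,
    simulate_interactions,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestSimulatePedigree:
    def test_study_scale_counts(self):
        ped = simulate_pedigree(82, 217, 9.8, seed=1)
        founders = ped.founder_mask.sum()
        assert founders == 82 + 217
        # expected offspring 217 * 9.8 ~ 2127, total ~ 2427
        assert 2250 <= len(ped) <= 2600

    def test_minimal_trio(self):
        ped = simulate_pedigree(1, 1, 2, seed=0)
        assert len(ped) == 4
        off = ~ped.founder_mask
        assert np.all(ped.sire[off] == 1) and np.all(ped.dam[off] == 2)

    def test_offspring_parents_in_founder_sets(self):
        ped = simulate_pedigree(10, 30, 5.3, seed=2)
        off = ~ped.founder_mask
        assert np.all(np.isin(ped.sire[off], np.arange(1, 11)))
        assert np.all(np.isin(ped.dam[off], np.arange(11, 41)))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            simulate_pedigree(0, 5, 3, seed=0)


class TestAssignPens:
    def test_study_scale_composition(self):
        ped = simulate_pedigree(82, 217, 9.8, seed=3)
        pens = assign_pens(ped, seed=3)
        penned = pens[pens["pen"] >= 0]
        sizes = penned.groupby("pen").size()
        assert len(sizes) == 78 and (sizes == 15).all()
        per_pen = penned.groupby("pen")
        assert (per_pen["litter"].nunique() == 5).all()
        assert (per_pen["sex"].nunique() == 1).all()
        assert (per_pen["line"].nunique() == 1).all()
        counts = penned.groupby(["pen", "litter"]).size()
        assert (counts == 3).all()

    def test_each_animal_at_most_one_pen(self):
        ped = simulate_pedigree(20, 50, 9.8, seed=4)
        pens = assign_pens(ped, n_pens=20, seed=4)
        assert pens["animal"].is_unique

    def test_singleton_pens(self):
        ped = simulate_pedigree(5, 10, 4, seed=5)
        pens = assign_pens(
            ped, n_pens=6, pen_size=1, per_litter=1, litters_per_pen=1, seed=5
        )
        assert (pens[pens["pen"] >= 0].groupby("pen").size() == 1).all()

    def test_infeasible_composition_raises(self):
        ped = simulate_pedigree(2, 3, 4, seed=6)  # 3 litters < 5 per pen
        with pytest.raises(CompositionError):
            assign_pens(ped, n_pens=1, seed=6)

    def test_batches_shared_round_robin(self):
        ped = simulate_pedigree(82, 217, 9.8, seed=7)
        pens = assign_pens(ped, seed=7)
        penned = pens[pens["pen"] >= 0]
        assert penned["batch"].nunique() == 14
        assert (penned["batch"] == penned["pen"] % 14).all()


class TestBreedingValues:
    def test_zero_g0_gives_zero_values(self, trio_pedigree):
        bv = simulate_breeding_values(trio_pedigree, np.zeros((1, 1)), seed=0)
        assert np.all(bv == 0)

    def test_non_psd_rejected(self, trio_pedigree):
        with pytest.raises(ValueError):
            simulate_breeding_values(trio_pedigree, np.array([[-1.0]]), seed=0)

    def test_trio_covariances_match_theory(self, trio_pedigree):
        """Parent-offspring and full-sib covariance both equal G0/2."""
        g0 = np.array([[2.0]])
        reps = np.stack(
            [
                simulate_breeding_values(trio_pedigree, g0, seed=s)[:, 0]
                for s in range(10_000)
            ]
        )
        cov = np.cov(reps.T)
        A = build_A(trio_pedigree).A
        # 3 MC standard errors of a variance estimate at sigma2 = 2
        se = 3.0 * np.sqrt(2.0) * 2.0 / np.sqrt(10_000)
        assert abs(cov[0, 2] - 1.0) < se  # sire-offspring: 0.5 * G0
        assert abs(cov[2, 3] - 1.0) < se  # full sibs: 0.5 * G0
        np.testing.assert_allclose(cov, A * 2.0, atol=se)

    def test_bivariate_genetic_correlation(self):
        ds = recovery_dataset(
            n_animals=4000, n_sires=50, n_dams=400, h2=[0.4, 0.4], c2=[0.1, 0.1],
            rg=0.9, seed=8,
        )
        r = np.corrcoef(ds.breeding_values.T)[0, 1]
        assert abs(r - 0.9) < 0.03


class TestPhenotypes:
    def test_pure_genetic_signal(self, trio_pedigree):
        params = TrueParameters(
            ["t"], np.array([[1.0]]), np.array([[0.0]]), np.array([[1e-9]])
        )
        assignment = pd.DataFrame(
            {
                "animal": [1, 2, 3, 4], "pen": [0, 0, 1, 1], "litter": 0,
                "sex": "male", "line": "Y", "batch": 0, "weight": 28.0,
            }
        )
        bv = simulate_breeding_values(trio_pedigree, params.G0, seed=1)
        tt = simulate_phenotypes(assignment, bv, trio_pedigree, params, seed=1)
        np.testing.assert_allclose(tt["t"].to_numpy(), bv[:, 0], atol=1e-4)

    def test_variance_decomposition(self):
        ds = recovery_dataset(
            n_animals=20_000, n_sires=100, n_dams=2000, n_pens=800,
            h2=0.3, c2=0.1, seed=9,
        )
        y = ds.trait_table["trait_1"].to_numpy()
        # remove fixed effects by centering within pen groups is too crude;
        # compare total variance instead (fixed effects add a known amount)
        pos = [ds.pedigree.position(a) for a in ds.trait_table["animal"]]
        gv = ds.breeding_values[pos, 0]
        resid = y - gv
        # tolerance dominated by family sampling of the 100 sire effects,
        # not by the 20k-animal Monte-Carlo error
        assert abs(gv.var(ddof=1) - 0.3) < 0.05
        within = (
            pd.DataFrame({"pen": ds.trait_table["pen"], "r": resid})
            .groupby("pen")["r"].transform(lambda s: s - s.mean())
        )
        assert abs(within.var(ddof=1) - 0.6) < 0.03

    def test_pen_effects_shared_and_icc_matches(self):
        """With G0 = 0, the intraclass correlation is C0 / (C0 + R0)."""
        ds_params = TrueParameters(
            ["t"], np.array([[1e-12]]), np.array([[0.3]]), np.array([[0.7]]),
        )
        ped = simulate_pedigree(30, 100, 10, seed=10)
        pens = assign_pens(ped, n_pens=40, seed=10)
        bv = simulate_breeding_values(ped, ds_params.G0, seed=10)
        tt = simulate_phenotypes(pens, bv, ped, ds_params, seed=10)
        g = tt.groupby("pen")["t"]
        nbar = 15
        msb = g.mean().var(ddof=1) * nbar
        msw = (tt["t"] - g.transform("mean")).var(ddof=1) * len(tt) / (len(tt) - 40)
        icc = (msb - msw) / (msb + (nbar - 1) * msw)
        assert abs(icc - 0.3) < 0.08


class TestInteractions:
    @staticmethod
    def _assignment(n_pens=20, pen_size=15):
        n = n_pens * pen_size
        return pd.DataFrame(
            {
                "animal": np.arange(1, n + 1),
                "pen": np.repeat(np.arange(n_pens), pen_size),
                "litter": 0, "sex": "male", "line": "Y", "batch": 0, "weight": 28.0,
            }
        )

    def test_impossible_edges_give_empty_list(self):
        asn = self._assignment(4)
        lat = {int(a): 0.0 for a in asn["animal"]}
        em = EdgeModel(fight_intercept=-1e9, fight_slope=0.0,
                       bully_intercept=-1e9, bully_slope=0.0)
        assert simulate_interactions(asn, lat, em, seed=0) == []

    def test_coin_flip_edges_mean_degree(self):
        asn = self._assignment(40)
        lat = {int(a): 0.0 for a in asn["animal"]}
        em = EdgeModel(fight_intercept=0.0, fight_slope=0.0,
                       bully_intercept=-1e9, bully_slope=0.0)
        recs = simulate_interactions(asn, lat, em, seed=1)
        # Bernoulli(0.5) per dyad -> mean degree (pen_size - 1) / 2 = 7
        degree = np.zeros(len(asn) + 1)
        for r in recs:
            degree[r.initiator_id] += 1
            degree[r.receiver_id] += 1
        assert abs(degree[1:].mean() - 7.0) < 0.3

    def test_aggressive_animals_fight_more(self):
        asn = self._assignment(78)
        rng = np.random.default_rng(3)
        lat = {int(a): float(v) for a, v in zip(asn["animal"], rng.normal(size=len(asn)))}
        recs = simulate_interactions(asn, lat, EdgeModel(), seed=3)
        degree = {}
        for r in recs:
            for a in (r.initiator_id, r.receiver_id):
                degree[a] = degree.get(a, 0) + 1
        d = np.array([degree.get(int(a), 0) for a in asn["animal"]])
        l = np.array([lat[int(a)] for a in asn["animal"]])
        rho = spearmanr(l, d).statistic
        assert rho > 0.3

    def test_records_stay_within_pen(self):
        asn = self._assignment(5)
        lat = {int(a): 0.0 for a in asn["animal"]}
        pen_of = dict(zip(asn["animal"], asn["pen"]))
        for r in simulate_interactions(asn, lat, EdgeModel(), seed=4):
            assert pen_of[r.initiator_id] == pen_of[r.receiver_id] == r.pen_id
            assert r.initiator_id != r.receiver_id


class TestBinaryTrait:
    def test_extreme_thresholds(self):
        liab = np.random.default_rng(0).normal(size=100)
        assert simulate_binary_trait(liab, -np.inf).all()
        assert not simulate_binary_trait(liab, np.inf).any()

    def test_standard_normal_prevalence_half(self):
        liab = np.random.default_rng(1).normal(size=10_000)
        prev = simulate_binary_trait(liab, 0.0).mean()
        assert abs(prev - 0.5) < 0.02

    def test_monotone_in_threshold(self):
        liab = np.random.default_rng(2).normal(size=500)
        prevs = [simulate_binary_trait(liab, t).mean() for t in (-1, 0, 1, 2)]
        assert all(a >= b for a, b in zip(prevs, prevs[1:]))


class TestDeterminismAndPresets:
    def test_same_seed_byte_identical(self):
        a = realistic_dataset(seed=5, n_sires=12, n_dams=30, n_pens=6)
        b = realistic_dataset(seed=5, n_sires=12, n_dams=30, n_pens=6)
        assert a.trait_table.to_csv() == b.trait_table.to_csv()
        assert a.pedigree.to_frame().to_csv() == b.pedigree.to_frame().to_csv()
        c = realistic_dataset(seed=6, n_sires=12, n_dams=30, n_pens=6)
        assert a.trait_table.to_csv() != c.trait_table.to_csv()

    def test_realistic_parameters_valid(self):
        params = realistic_parameters()
        for m in (params.G0, params.C0, params.R0):
            assert np.linalg.eigvalsh(m).min() > -1e-10
        # preset keeps the published heritabilities for the centralities
        np.testing.assert_allclose(params.h2[:5], [0.26, 0.09, 0.26, 0.22, 0.18],
                                   atol=1e-6)
        rg = params.G0 / np.sqrt(np.outer(np.diag(params.G0), np.diag(params.G0)))
        i, j = 3, 4  # eigenvector vs clustering: strongly negative
        assert rg[i, j] < -0.75
        assert rg[3, 5] > 0.3  # eigenvector vs anterior SL24h stays positive
        assert rg[4, 10] > 0.2  # clustering vs posterior SL3wk stays positive

    def test_nearest_correlation_projects_indefinite_matrix(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        P = nearest_correlation(R)
        assert np.linalg.eigvalsh(P).min() >= -1e-8
        np.testing.assert_allclose(np.diag(P), 1.0, atol=1e-8)

    def test_true_parameters_validation(self):
        with pytest.raises(ValueError):
            TrueParameters(["t"], np.array([[1.0]]), np.array([[0.0]]),
                           np.array([[-1.0]]))
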