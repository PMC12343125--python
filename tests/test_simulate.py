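"""Synthetic FBD generator: trivial cases, Monte-Carlo calibration, determinism."""

import math

import numpy as np
import pytest

from fbdstrata.congruence import mig
from fbdstrata.occurrences import TaxonAgeTable
from fbdstrata.simulate import (ConditioningError, FBDParams, Timescale,
                                assign_genera, bin_occurrence_ages,
                                generate_pseudo_posterior, select_morph_taxa,
                                simulate_characters, simulate_fbd)
from fbdstrata.treespace import rf_distance
from fbdstrata.trees import tree_from_newick


def quiet_params(**kw):
    base = dict(lambda_=0.0, mu=0.0, psi=0.0, t_origin=10.0, rho=1.0,
                condition="none", seed=0)
    base.update(kw)
    return FBDParams(**base)


class TestSimulateFbd:
    def test_no_events_single_edge(self):
        history, recon, occ = simulate_fbd(quiet_params())
        assert recon.tree.n_tips() == 1
        assert len(occ) == 0
        assert recon.tree.root_age == 10.0
        (tip,) = recon.tree.tree.leaf_node_iter()
        assert tip.age == 0.0 and recon.roles[tip.taxon.label] == "extant"

    def test_seed_determinism(self):
        p = quiet_params(lambda_=0.4, psi=0.3, seed=7)
        a = simulate_fbd(p)
        b = simulate_fbd(p)
        assert a[2].equals(b[2])
        assert a[1].tree.taxa == b[1].tree.taxa
        assert rf_distance(a[1].tree, b[1].tree) == 0 or a[1].tree.n_tips() < 4

    def test_conditioning_failure_names_condition(self):
        p = FBDParams(lambda_=0.0, mu=0.0, psi=0.0, t_origin=10.0, rho=1.0,
                      condition="min_samples", min_samples=5, max_attempts=3,
                      seed=0)
        with pytest.raises(ConditioningError, match="min_samples"):
            simulate_fbd(p)

    def test_tree_invariants_and_leafset(self):
        p = quiet_params(lambda_=0.6, mu=0.2, psi=0.4, rho=0.5, seed=11,
                         condition="min_samples", min_samples=8)
        history, recon, occ = simulate_fbd(p)
        # leafset = sampled species; ages consistent (checked by DatedTree)
        assert recon.taxa == {f"S{s}" for s in history.sampled_species}
        fossil_taxa = set(occ["taxon"])
        extant_taxa = {f"S{s}" for s in history.retained_extant}
        assert recon.taxa == fossil_taxa | extant_taxa
        for label, role in recon.roles.items():
            assert role in ("extant", "fossil", "sampled_ancestor")

    def test_sampled_ancestors_are_zero_length_pendants(self):
        p = quiet_params(lambda_=0.5, psi=0.6, rho=0.0, seed=3,
                         condition="min_samples", min_samples=10)
        _, recon, _ = simulate_fbd(p)
        sa = [lf for lf in recon.tree.tree.leaf_node_iter()
              if recon.roles[lf.taxon.label] == "sampled_ancestor"]
        assert sa, "expected at least one sampled ancestor at these rates"
        for lf in sa:
            assert lf.parent_node.age == pytest.approx(lf.age)

    def test_yule_mean_tip_count(self):
        """With mu = psi = 0, rho = 1 the extant count has mean e^{lambda T}."""
        lam, T, reps = 0.3, 10.0, 400
        rng = np.random.default_rng(5)
        counts = []
        for _ in range(reps):
            p = quiet_params(lambda_=lam, t_origin=T, seed=int(rng.integers(2**31)))
            history, _, _ = simulate_fbd(p)
            counts.append(history.n_extant)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(reps)
        assert abs(mean - math.exp(lam * T)) < 3 * se

    def test_fossil_counts_poisson_in_duration(self):
        """Fossil count given total lineage duration L is Poisson(psi * L)."""
        psi, reps = 0.5, 400
        rng = np.random.default_rng(9)
        z = []
        for _ in range(reps):
            p = quiet_params(lambda_=0.3, mu=0.1, psi=psi, t_origin=8.0,
                             seed=int(rng.integers(2**31)))
            history, _, _ = simulate_fbd(p)
            m = psi * history.total_duration
            if m > 0:
                z.append((len(history.occurrences) - m) ** 2 / m)
        dispersion = np.mean(z)
        assert abs(dispersion - 1.0) < 4 / math.sqrt(len(z))


class TestAssignGenera:
    def _history(self):
        p = quiet_params(lambda_=0.5, psi=0.4, rho=0.0, seed=21,
                         condition="min_samples", min_samples=15)
        return simulate_fbd(p)[0]

    def test_tau_near_origin_single_genus(self):
        h = self._history()
        gm = assign_genera(h, h.params.t_origin - 1e-9)
        assert len(set(gm.values())) == 1

    def test_tau_near_zero_every_terminal_lineage_own_genus(self):
        h = self._history()
        gm = assign_genera(h, 1e-9)
        # species still alive just above 0 each found their own crossing edge;
        # species extinct before that level become singletons
        genera = {}
        for t, g in gm.items():
            genera.setdefault(g, []).append(t)
        for members in genera.values():
            ids = [int(t[1:]) for t in members]
            spans = [(h.species[i].start_age, h.species[i].end_age) for i in ids]
            if len(members) > 1:  # multi-species genera need shared young edge
                assert any(e <= 1e-9 for _, e in spans)

    def test_partition_and_monophyly(self):
        p = quiet_params(lambda_=0.5, psi=0.4, rho=0.0, seed=21,
                         condition="min_samples", min_samples=15)
        h, recon, _ = simulate_fbd(p)
        gm = assign_genera(h, h.params.t_origin * 0.4)
        assert set(gm) == {f"S{s}" for s in h.sampled_species}
        # MRCA test on the reconstructed tree (sampled ancestors are tips
        # there): each genus's members form a clade among sampled taxa
        for genus in set(gm.values()):
            members = {t for t, g in gm.items() if g == genus}
            if len(members) == 1:
                continue
            mrca = None
            for lf in recon.tree.tree.leaf_node_iter():
                if lf.taxon.label not in members:
                    continue
                chain = []
                nd = lf
                while nd is not None:
                    chain.append(nd)
                    nd = nd.parent_node
                mrca = chain if mrca is None else [n for n in mrca if n in chain]
            clade = {lf.taxon.label for lf in mrca[0].leaf_iter()}
            assert clade == members

    def test_balanced_four_taxon_example(self):
        # root at 10, both child clades originating at 6, tau = 8 -> 2 genera
        from fbdstrata.simulate import CompleteHistory, Species

        species = {
            0: Species(0, None, 12.0, 10.0, "birth", (1, 2)),
            1: Species(1, 0, 10.0, 6.0, "birth", (3, 4)),
            2: Species(2, 0, 10.0, 6.0, "birth", (5, 6)),
            3: Species(3, 1, 6.0, 0.0, "present"),
            4: Species(4, 1, 6.0, 0.0, "present"),
            5: Species(5, 2, 6.0, 0.0, "present"),
            6: Species(6, 2, 6.0, 0.0, "present"),
        }
        h = CompleteHistory(params=quiet_params(t_origin=12.0), species=species,
                            occurrences=[],
                            retained_extant=frozenset({3, 4, 5, 6}),
                            n_extant=4, total_duration=0.0)
        gm = assign_genera(h, 8.0)
        assert gm == {"S3": "G1", "S4": "G1", "S5": "G2", "S6": "G2"}

    def test_tau_out_of_range(self):
        h = self._history()
        with pytest.raises(ValueError):
            assign_genera(h, h.params.t_origin + 1)


class TestCharacters:
    def test_zero_rate_constant_columns(self):
        dt = tree_from_newick("((A:2,B:2):1,C:3);")
        mat = simulate_characters(dt, n_chars=10, rates=np.zeros(10), seed=1)
        assert (mat.nunique() == 1).all()

    def test_all_missing(self):
        dt = tree_from_newick("(A:1,B:1);")
        mat = simulate_characters(dt, n_chars=5, missing_frac=1.0, seed=1)
        assert (mat == "?").all().all()

    def test_two_state_mismatch_probability(self):
        """Two tips joined by path length t: P(differ) = (1 - e^{-2t})/2."""
        t = 0.4
        dt = tree_from_newick(f"(A:{t / 2},B:{t / 2});")
        n = 10_000
        mat = simulate_characters(dt, n_chars=n, n_states=2,
                                  rates=np.ones(n), seed=8)
        p_hat = (mat.loc["A"] != mat.loc["B"]).mean()
        p = (1 - math.exp(-2 * t)) / 2
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se

    def test_scale_and_determinism(self):
        p = quiet_params(lambda_=0.6, psi=0.4, rho=0.0, seed=13,
                         condition="min_samples", min_samples=20)
        _, recon, _ = simulate_fbd(p)
        a = simulate_characters(recon, n_chars=254, n_states=3,
                                missing_frac=0.3, seed=2)
        b = simulate_characters(recon, n_chars=254, n_states=3,
                                missing_frac=0.3, seed=2)
        assert a.equals(b)
        assert a.shape == (recon.tree.n_tips(), 254)


class TestSelectMorphTaxa:
    def _occ(self, counts):
        import pandas as pd

        rows = []
        i = 0
        for taxon, c in counts.items():
            for _ in range(c):
                rows.append({"occurrence_id": i, "taxon": taxon,
                             "rank": "species", "genus": None,
                             "max_ma": 5.0, "min_ma": 5.0})
                i += 1
        return pd.DataFrame(rows)

    def test_weighted_proportions(self):
        occ = self._occ({"A": 4, "B": 1})
        hits = sum(select_morph_taxa(occ, k=1, beta=1.0, seed=s) == ["A"]
                   for s in range(10_000))
        se = math.sqrt(0.8 * 0.2 / 10_000)
        assert abs(hits / 10_000 - 0.8) < 3 * se

    def test_beta_zero_uniform(self):
        from scipy.stats import chisquare

        occ = self._occ({"A": 10, "B": 2, "C": 1})
        counts = {"A": 0, "B": 0, "C": 0}
        for s in range(3000):
            counts[select_morph_taxa(occ, k=1, beta=0.0, seed=s)[0]] += 1
        _, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_dominant_taxon_under_large_beta(self):
        occ = self._occ({"A": 5, "B": 2, "C": 1})
        assert all(select_morph_taxa(occ, k=1, beta=50.0, seed=s) == ["A"]
                   for s in range(50))

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            select_morph_taxa(self._occ({"A": 1}), k=2, beta=1.0, seed=0)


class TestBinOccurrences:
    def _occ(self, ages):
        import pandas as pd

        return pd.DataFrame([{"occurrence_id": i, "taxon": f"S{i}",
                              "rank": "species", "genus": None,
                              "max_ma": a, "min_ma": a}
                             for i, a in enumerate(ages)])

    def test_containing_stage(self):
        scale = Timescale.uniform(25.0, 5)  # boundaries every 5 myr
        out = bin_occurrence_ages(self._occ([12.3]), scale, p_coarse=0.0)
        assert (out.loc[0, "max_ma"], out.loc[0, "min_ma"]) == (15.0, 10.0)

    def test_boundary_age_goes_to_older_stage(self):
        scale = Timescale.uniform(25.0, 5)
        out = bin_occurrence_ages(self._occ([10.0]), scale, p_coarse=0.0)
        assert (out.loc[0, "max_ma"], out.loc[0, "min_ma"]) == (15.0, 10.0)

    def test_full_widening(self):
        scale = Timescale.uniform(25.0, 5)
        out = bin_occurrence_ages(self._occ([3.0, 12.3, 24.0]), scale,
                                  p_coarse=1.0, widen_max=None, seed=0)
        assert (out["max_ma"] == 25.0).all() and (out["min_ma"] == 0.0).all()

    def test_true_age_always_inside(self, rng):
        scale = Timescale.uniform(25.0, 10)
        ages = rng.uniform(0, 25, 50)
        out = bin_occurrence_ages(self._occ(ages), scale, p_coarse=0.5, seed=1)
        assert ((out["min_ma"] <= ages) & (ages <= out["max_ma"])).all()

    def test_age_outside_scale_names_record(self):
        scale = Timescale.uniform(10.0, 2)
        with pytest.raises(ValueError, match="occurrence_id 0"):
            bin_occurrence_ages(self._occ([11.0]), scale)


class TestPseudoPosterior:
    def _truth(self):
        p = quiet_params(lambda_=0.5, psi=0.5, rho=0.0, seed=17,
                         condition="min_samples", min_samples=12)
        _, recon, occ = simulate_fbd(p)
        ages = TaxonAgeTable({t: (a, a) for t, a in recon.tree.tip_ages().items()})
        return recon.tree, ages

    def test_no_noise_reproduces_truth(self):
        truth, _ = self._truth()
        sample = generate_pseudo_posterior(truth, n_trees=5, nni_rate=0.0,
                                           age_jitter_sd=0.0, seed=1)
        for dt in sample:
            assert rf_distance(dt, truth) == 0
            assert dt.root_age == pytest.approx(truth.root_age)

    def test_rf_distance_nondecreasing_in_nni_rate(self):
        truth, _ = self._truth()
        means = []
        for rate in (0.5, 2.0, 8.0):
            sample = generate_pseudo_posterior(truth, n_trees=100,
                                               nni_rate=rate,
                                               age_jitter_sd=0.0, seed=4)
            means.append(np.mean([rf_distance(dt, truth) for dt in sample]))
        assert means[0] <= means[1] <= means[2]

    def test_congruence_weight_lowers_mig(self):
        truth, ages = self._truth()
        fads = ages.fads("old")
        wins = 0
        for rep in range(10):
            unweighted = generate_pseudo_posterior(truth, 30, nni_rate=2.0,
                                                   age_jitter_sd=0.0,
                                                   seed=100 + rep)
            weighted = generate_pseudo_posterior(truth, 30, nni_rate=2.0,
                                                 age_jitter_sd=0.0,
                                                 congruence_weight=5.0,
                                                 ages=ages, seed=100 + rep)
            m0 = np.mean([mig(dt, fads) for dt in unweighted])
            m5 = np.mean([mig(dt, fads) for dt in weighted])
            wins += m5 < m0
        assert wins >= 9

    def test_tips_keep_ages_and_determinism(self):
        truth, _ = self._truth()
        a = generate_pseudo_posterior(truth, 10, nni_rate=3.0,
                                      age_jitter_sd=0.2, seed=6)
        b = generate_pseudo_posterior(truth, 10, nni_rate=3.0,
                                      age_jitter_sd=0.2, seed=6)
        for dt, dt2 in zip(a, b):
            assert rf_distance(dt, dt2) == 0
            assert dt.tip_ages() == truth.tip_ages()
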