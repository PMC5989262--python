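"""Allele-frequency estimation, diversity, differentiation, distances, trees."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_genotype
from porphyra import popgen as pg
from porphyra.synthetic import SimConfig, study_cohort


def brute_force_ml(observations, alleles, step=0.002):
    """Independent grid-search oracle for the dosage-EM.

    The phenotype likelihood is computed by enumerating every dosage vector
    (composition of the ploidy over the shown alleles with all parts >= 1)
    and summing multinomial probabilities -- no shared code with the EM.
    """

    def loglik(p):
        ll = 0.0
        for shown, m in observations:
            idx = [alleles.index(a) for a in shown]
            prob = 0.0
            for cuts in itertools.combinations(range(1, m), len(idx) - 1):
                parts = [b - a for a, b in zip((0,) + cuts, cuts + (m,))]
                coef = math.factorial(m)
                term = 1.0
                for i, c in zip(idx, parts):
                    coef //= math.factorial(c)
                    term *= p[i] ** c
                prob += coef * term
            if prob <= 0:
                return -np.inf
            ll += math.log(prob)
        return ll

    k = len(alleles)
    best, best_ll = None, -np.inf
    ticks = np.arange(step, 1.0, step)
    if k == 2:
        grids = ([a, 1 - a] for a in ticks)
    elif k == 3:
        grids = (
            [a, b, 1 - a - b]
            for a in ticks
            for b in ticks
            if a + b < 1.0 - step / 2
        )
    else:
        raise NotImplementedError
    for p in grids:
        ll = loglik(p)
        if ll > best_ll:
            best, best_ll = p, ll
    return dict(zip(alleles, best))


class TestNaiveFreqs:
    def test_single_heterozygote_splits_evenly(self):
        genos = [make_genotype("i1", {"L": (1.0, 2.0)}, ploidy=4)]
        fr = pg.allele_freqs_naive(genos)
        assert fr.freqs["L"] == {1.0: 0.5, 2.0: 0.5}

    def test_fixed_allele(self):
        genos = [make_genotype(f"i{k}", {"L": (1.0,)}) for k in range(2)]
        assert pg.allele_freqs_naive(genos).freqs["L"] == {1.0: 1.0}

    def test_hand_mean_of_phenotype_weights(self):
        genos = [
            make_genotype("i1", {"L": (1.0, 2.0)}),
            make_genotype("i2", {"L": (1.0,)}),
        ]
        fr = pg.allele_freqs_naive(genos)
        assert fr.freqs["L"][1.0] == pytest.approx(0.75)
        assert fr.freqs["L"][2.0] == pytest.approx(0.25)


class TestDosageEM:
    def test_monomorphic_converges_immediately(self):
        genos = [make_genotype(f"i{k}", {"L": (5.0,)}, ploidy=4) for k in range(3)]
        fr = pg.allele_freqs_ml(genos)
        assert fr.freqs["L"] == {5.0: 1.0}
        assert fr.converged

    def test_symmetric_phenotypes_give_half(self):
        genos = [
            make_genotype(f"i{k}", {"L": (1.0, 2.0)}, ploidy=4) for k in range(4)
        ]
        fr = pg.allele_freqs_ml(genos)
        assert fr.freqs["L"][1.0] == pytest.approx(0.5, abs=1e-6)

    def test_em_matches_grid_oracle_two_alleles(self):
        genos = [
            make_genotype("i1", {"L": (1.0, 2.0)}, ploidy=4),
            make_genotype("i2", {"L": (1.0,)}, ploidy=4),
            make_genotype("i3", {"L": (1.0, 2.0)}, ploidy=4),
        ]
        fr = pg.allele_freqs_ml(genos)
        oracle = brute_force_ml([((1.0, 2.0), 4), ((1.0,), 4), ((1.0, 2.0), 4)], [1.0, 2.0], step=0.001)
        assert fr.freqs["L"][1.0] == pytest.approx(oracle[1.0], abs=0.005)

    @pytest.mark.parametrize(
        "observations",
        [
            [((1.0, 2.0, 3.0), 4), ((1.0,), 3), ((2.0, 3.0), 4)],
            [((1.0, 2.0), 6), ((1.0, 2.0, 3.0), 6), ((3.0,), 2), ((1.0, 3.0), 4)],
            [((1.0, 2.0), 3), ((2.0, 3.0), 3), ((1.0, 3.0), 3), ((1.0,), 3), ((2.0,), 3)],
        ],
    )
    def test_em_matches_grid_oracle_three_alleles(self, observations):
        genos = [
            make_genotype(f"i{k}", {"L": shown}, ploidy=m)
            for k, (shown, m) in enumerate(observations)
        ]
        fr = pg.allele_freqs_ml(genos)
        alleles = sorted({a for shown, _ in observations for a in shown})
        oracle = brute_force_ml(observations, alleles, step=0.0025)
        for a in alleles:
            assert fr.freqs["L"][a] == pytest.approx(oracle[a], abs=0.005)

    def test_loglik_monotone_every_iteration(self, rng):
        # random dosage-ambiguous instances must never decrease the likelihood
        for _ in range(10):
            genos = []
            for k in range(5):
                m = int(rng.integers(2, 7))
                n_shown = int(rng.integers(1, min(m, 3) + 1))
                shown = tuple(sorted(rng.choice([1.0, 2.0, 3.0], n_shown, replace=False)))
                genos.append(make_genotype(f"i{k}", {"L": shown}, ploidy=m))
            _, trace = pg.allele_freqs_ml(genos, return_trace=True)
            ll = trace["L"]
            assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))


class TestDiversity:
    def test_equal_frequency_pair(self):
        af = pg.AlleleFreqs("g", {"L": {1: 0.5, 2: 0.5}}, {"L": 10_000})
        rep = pg.diversity(af)
        row = rep.per_locus.iloc[0]
        assert row.num == 2
        assert row.eff_num == pytest.approx(2.0)
        assert row.hs == pytest.approx(0.5, abs=1e-3)

    def test_fixed_locus(self):
        af = pg.AlleleFreqs("g", {"L": {1: 1.0}}, {"L": 10})
        row = pg.diversity(af).per_locus.iloc[0]
        assert (row.num, row.eff_num, row.hs) == (1, 1.0, 0.0)

    def test_sampling_correction_hand_value(self):
        # p = (0.7, 0.3), n = 10 -> Hs = (10/9) * (1 - 0.58) = 0.4667
        af = pg.AlleleFreqs("g", {"L": {1: 0.7, 2: 0.3}}, {"L": 10})
        assert pg.diversity(af).hs == pytest.approx(0.46667, abs=1e-4)

    def test_eff_num_never_exceeds_num(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 7))
            p = rng.dirichlet(np.ones(k))
            af = pg.AlleleFreqs("g", {"L": dict(zip(range(k), p))}, {"L": 30})
            row = pg.diversity(af).per_locus.iloc[0]
            assert row.eff_num <= row.num + 1e-9


class TestDifferentiationStatistics:
    def test_gst_fixed_points_and_hand_value(self):
        assert pg.nei_gst(0.5, 0.5) == 0.0
        assert pg.nei_gst(0.0, 0.5) == 1.0
        assert pg.nei_gst(0.4, 0.5) == pytest.approx(0.2)
        assert math.isnan(pg.nei_gst(0.0, 0.0))

    def test_jost_fixed_points_and_hand_value(self):
        assert pg.jost_d(0.5, 0.5) == 0.0
        assert pg.jost_d(0.0, 0.5, 2) == 1.0
        assert pg.jost_d(0.4, 0.5, 2) == pytest.approx(1 / 3)
        assert math.isnan(pg.jost_d(1.0, 1.0))

    def test_duplicate_group_close_to_zero(self):
        genos = [
            make_genotype(f"i{k}", {"L": ((1.0,) if k % 2 else (1.0, 2.0))}, ploidy=4)
            for k in range(12)
        ]
        clones = [
            make_genotype(f"j{k}", dict(g.loci), ploidy=4)
            for k, g in enumerate(genos)
        ]
        diff = pg.pairwise_differentiation({"a": genos, "b": clones}, dosage_corrected=True)
        assert abs(diff.gst.loc["a", "b"]) < 0.02
        assert abs(diff.d.loc["a", "b"]) < 0.02

    def test_fixed_alternate_alleles_give_unity(self):
        a = [make_genotype(f"i{k}", {"L1": (1.0,), "L2": (3.0,)}, ploidy=4) for k in range(5)]
        b = [make_genotype(f"j{k}", {"L1": (2.0,), "L2": (4.0,)}, ploidy=4) for k in range(5)]
        diff = pg.pairwise_differentiation({"a": a, "b": b}, dosage_corrected=True)
        assert diff.gst.loc["a", "b"] == pytest.approx(1.0)
        assert diff.d.loc["a", "b"] == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal(self):
        a = [make_genotype(f"i{k}", {"L": (1.0, 2.0)}, ploidy=4) for k in range(4)]
        b = [make_genotype(f"j{k}", {"L": (2.0,)}, ploidy=4) for k in range(4)]
        diff = pg.pairwise_differentiation({"a": a, "b": b})
        assert diff.gst.loc["a", "a"] == 0.0
        assert diff.gst.loc["a", "b"] == diff.gst.loc["b", "a"]

    def test_hs_bounded_by_ht_for_divergent_groups(self):
        a = [make_genotype(f"i{k}", {"L": (1.0,)}, ploidy=2) for k in range(8)]
        b = [make_genotype(f"j{k}", {"L": (1.0, 2.0)}, ploidy=2) for k in range(8)]
        fr = [pg.allele_freqs_naive(a, "a"), pg.allele_freqs_naive(b, "b")]
        rep = pg.diversity(fr)
        assert rep.hs <= rep.ht + 1e-9


class TestDistancesAndTrees:
    def test_identical_genotypes_distance_zero(self):
        g1 = make_genotype("a", {"L1": (1.0, 2.0), "L2": (5.0,)})
        g2 = make_genotype("b", {"L1": (1.0, 2.0), "L2": (5.0,)})
        d = pg.individual_distances([g1, g2])
        assert d.values[0, 1] == 0.0

    def test_disjoint_alleles_distance_one(self):
        g1 = make_genotype("a", {"L1": (1.0,), "L2": (5.0,)})
        g2 = make_genotype("b", {"L1": (2.0,), "L2": (6.0,)})
        assert pg.individual_distances([g1, g2]).values[0, 1] == 1.0

    def test_half_shared_loci(self):
        g1 = make_genotype("a", {"L1": (1.0,), "L2": (5.0,)})
        g2 = make_genotype("b", {"L1": (1.0,), "L2": (6.0,)})
        assert pg.individual_distances([g1, g2]).values[0, 1] == 0.5

    def test_no_shared_loci_is_missing_and_tree_rejects(self):
        g1 = make_genotype("a", {"L1": (1.0,)})
        g2 = make_genotype("b", {"L2": (2.0,)})
        g3 = make_genotype("c", {"L1": (1.0,), "L2": (2.0,)})
        d = pg.individual_distances([g1, g2, g3])
        assert np.isnan(d.values[0, 1])
        with pytest.raises(ValueError, match="incomplete"):
            pg.nj_tree(d)

    def test_three_taxon_closed_form(self):
        # d(a,b)=0.4, d(a,c)=0.6, d(b,c)=0.8 -> branch lengths
        # a=(0.4+0.6-0.8)/2=0.1, b=0.3, c=0.5
        dm = pg.IndividualDistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]),
        )
        from skbio import TreeNode
        import io as _io

        tree = TreeNode.read(_io.StringIO(pg.nj_tree(dm)))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["b"] == pytest.approx(0.3, abs=1e-9)
        assert lengths["c"] == pytest.approx(0.5, abs=1e-9)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        # path-length oracle: distances derived from a known tree
        # ((a:2,b:3):3,c:4,(d:2,e:1):2);
        ids = ["a", "b", "c", "d", "e"]
        paths = {
            ("a", "b"): 5, ("a", "c"): 9, ("a", "d"): 9, ("a", "e"): 8,
            ("b", "c"): 10, ("b", "d"): 10, ("b", "e"): 9,
            ("c", "d"): 8, ("c", "e"): 7, ("d", "e"): 3,
        }
        m = np.zeros((5, 5))
        for (x, y), v in paths.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = v
        from skbio import TreeNode
        import io as _io

        tree = TreeNode.read(_io.StringIO(pg.nj_tree(pg.IndividualDistanceMatrix(ids, m))))
        td = tree.tip_tip_distances(ids)
        for (x, y), v in paths.items():
            assert td[x, y] == pytest.approx(v, abs=1e-9)

    def test_identical_taxa_form_zero_length_cherry(self):
        m = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        from skbio import TreeNode
        import io as _io

        tree = TreeNode.read(
            _io.StringIO(pg.nj_tree(pg.IndividualDistanceMatrix(["a", "b", "c"], m)))
        )
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.0, abs=1e-12)
        assert lengths["b"] == pytest.approx(0.0, abs=1e-12)


class TestPCA:
    def test_identical_individuals_give_zero_scores(self):
        genos = [make_genotype(f"i{k}", {"L": (1.0, 2.0)}) for k in range(4)]
        coords, explained = pg.pca_allelic(genos)
        assert np.allclose(coords.to_numpy(), 0.0)
        assert np.allclose(explained, 0.0)

    def test_two_fixed_groups_separate_on_pc1(self):
        a = [make_genotype(f"i{k}", {"L1": (1.0,), "L2": (3.0,)}) for k in range(5)]
        b = [make_genotype(f"j{k}", {"L1": (2.0,), "L2": (4.0,)}) for k in range(5)]
        coords, explained = pg.pca_allelic(a + b)
        pc1 = coords["PC1"].to_numpy()
        assert explained[0] == pytest.approx(1.0)
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()  # two opposite sides

    def test_three_species_cluster_by_silhouette(self):
        from sklearn.metrics import silhouette_score

        cfg = SimConfig(missing_rate=0.0)
        cohort = study_cohort(seed=2, cfg=cfg)
        coords, _ = pg.pca_allelic(cohort.genotypes)
        labels = [g.species for g in cohort.genotypes]
        score = silhouette_score(coords.iloc[:, :2].to_numpy(), labels)
        assert score > 0.5
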