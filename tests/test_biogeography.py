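import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from aquassembly.biogeography import (
    DistanceMatrix,
    altitude_difference,
    bray_curtis,
    distance_decay,
    env_association,
    gene_accumulation,
    geographic_distance,
    haversine_km,
    mantel,
    partial_mantel,
    pcoa,
    permanova,
    select_pairs,
    shared_gene_counts,
    similarity_matrix,
)
from aquassembly.io import AbundanceTable, OrfCatalog


def _dm(values, labels=None, name=""):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(list(labels), values, name)


def _random_dm(rng, n, dim=3):
    return squareform(pdist(rng.standard_normal((n, dim))))


class TestDistanceMatrices:
    def test_bray_curtis_identical_and_disjoint(self):
        ab = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        d = bray_curtis(AbundanceTable(["a", "b", "c"], ["x", "y", "z"], ab))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        ab = np.array([[0.6, 0.4, 0.0], [0.2, 0.4, 0.4]])
        d = bray_curtis(AbundanceTable(["a", "b"], ["x", "y", "z"], ab))
        # 1 - 2*(0.2+0.4+0)/(1+1) = 0.4
        assert d.values[0, 1] == pytest.approx(0.4)

    def test_haversine_closed_forms(self):
        assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            math.pi * 6371.0, rel=1e-9
        )
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(
            6371.0 * math.pi / 180.0, rel=1e-9
        )

    def test_geographic_matrix_and_missing(self, toy_metadata):
        meta = toy_metadata.copy()
        meta.loc["s4", "latitude"] = np.nan
        d = geographic_distance(meta)
        assert d.labels == ["s1", "s2", "s3"]
        assert d.values[0, 1] == pytest.approx(
            haversine_km(31.0, 88.0, 32.0, 89.0), rel=1e-9
        )

    def test_altitude_matrix(self, toy_metadata):
        d = altitude_difference(toy_metadata)
        expected = np.abs(
            toy_metadata["altitude_m"].to_numpy()[:, None]
            - toy_metadata["altitude_m"].to_numpy()[None, :]
        )
        np.testing.assert_allclose(d.values, expected)
        assert d.values[0, 2] == 1300.0


class TestPcoa:
    def test_collinear_points(self):
        d = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(d)
        assert (res.eigenvalues > 1e-10).sum() == 1
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d.values, atol=1e-10)

    def test_all_zero_distances(self):
        res = pcoa(_dm(np.zeros((4, 4))))
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_equilateral_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(_dm(d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((10, 4))
        d = _dm(squareform(pdist(pts)))
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates))
        assert np.linalg.norm(rec - d.values) / np.linalg.norm(
            d.values
        ) < 1e-8

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        d = _random_dm(rng, 8)
        mine = pcoa(_dm(d))
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d), method="eigh"
        )
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues)[::-1][:3],
            np.asarray(theirs.eigvals)[:3],
            atol=1e-8,
        )


class TestPermanova:
    def test_two_clusters_hand_value(self):
        # within-group distances 0, between-group 1
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        res = permanova(_dm(d), ["A", "A", "B", "B"], n_permutations=99,
                        seed=0)
        # SS_total = 4/4 = 1, SS_within = 0 -> R^2 = 1
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value >= 1.0 / 100.0

    def test_singleton_group_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="singleton"):
            permanova(_dm(_random_dm(rng, 4)), ["A", "A", "A", "B"])

    def test_one_group_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            permanova(_dm(_random_dm(rng, 4)), ["A"] * 4)

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        d = _random_dm(rng, 12)
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        mine = permanova(_dm(d), groups, n_permutations=9, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, [f"s{i}" for i in range(12)]),
            grouping=groups, permutations=0,
        )
        assert mine.pseudo_f == pytest.approx(
            float(theirs["test statistic"]), rel=1e-10
        )

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(3)
        d = _random_dm(rng, 10)
        labels = [f"s{i}" for i in range(10)]
        groups = ["A"] * 5 + ["B"] * 5
        base = permanova(_dm(d, labels), groups, n_permutations=49, seed=1)
        renamed = permanova(
            _dm(d, labels), ["X" if g == "A" else "Y" for g in groups],
            n_permutations=49, seed=1,
        )
        assert base.r_squared == pytest.approx(renamed.r_squared)
        perm = rng.permutation(10)
        reordered = permanova(
            _dm(d[np.ix_(perm, perm)], [labels[i] for i in perm]),
            [groups[i] for i in perm], n_permutations=49, seed=1,
        )
        assert base.r_squared == pytest.approx(reordered.r_squared)
        assert base.pseudo_f == pytest.approx(reordered.pseudo_f)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        d = _random_dm(rng, 12)
        groups = ["A"] * 6 + ["B"] * 6
        a = permanova(_dm(d), groups, n_permutations=99, seed=11)
        b = permanova(_dm(d), groups, n_permutations=99, seed=11)
        assert a.p_value == b.p_value


class TestMantel:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        a = _random_dm(rng, 8)
        res = mantel(_dm(a), _dm(2.0 * a), n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        a, b = _random_dm(rng, 10), _random_dm(rng, 10)
        mine = mantel(_dm(a), _dm(b), n_permutations=9, seed=0)
        theirs = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(a), skbio.DistanceMatrix(b),
            permutations=0,
        )[0]
        assert mine.statistic == pytest.approx(float(theirs), rel=1e-10)

    def test_small_n_exact_enumeration(self):
        a = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        b = np.array([[0, 1.5, 2.5], [1.5, 0, 2.9], [2.5, 2.9, 0]])
        res = mantel(_dm(a), _dm(b), n_permutations=999, seed=0)
        iu = np.triu_indices(3, k=1)
        r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
        hits = sum(
            abs(np.corrcoef(a[np.ix_(p, p)][iu], b[iu])[0, 1])
            >= abs(r_obs) - 1e-12
            for p in itertools.permutations(range(3))
        )
        assert res.p_value == pytest.approx(hits / 6.0)
        assert res.n_permutations == 5

    def test_label_mismatch_error(self):
        rng = np.random.default_rng(0)
        a = _dm(_random_dm(rng, 5))
        b = _dm(_random_dm(rng, 5), labels=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            mantel(a, b)

    def test_spearman_flavor(self):
        rng = np.random.default_rng(6)
        a = _random_dm(rng, 8)
        res = mantel(_dm(a), _dm(a**3), n_permutations=49, seed=0,
                     method="spearman")
        assert res.statistic == pytest.approx(1.0)


class TestPartialMantel:
    def test_confound_removed(self):
        # A and B both driven by C only: partial r should be small even
        # though the simple Mantel correlation is large
        rng = np.random.default_rng(7)
        n = 20
        z = rng.standard_normal((n, 2))
        c = squareform(pdist(z))
        noise_a = 0.05 * _random_dm(rng, n)
        noise_b = 0.05 * _random_dm(rng, n)
        a, b = c + noise_a, c + noise_b
        simple = mantel(_dm(a), _dm(b), n_permutations=99, seed=0)
        partial = partial_mantel(_dm(a), _dm(b), _dm(c),
                                 n_permutations=99, seed=0)
        assert simple.statistic > 0.9
        assert abs(partial.statistic) < 0.5
        assert partial.kind == "partial"

    def test_conditional_signal_detected(self):
        rng = np.random.default_rng(8)
        n = 20
        shared = _random_dm(rng, n)
        confound = _random_dm(rng, n)
        a = shared + 0.5 * confound + 0.05 * _random_dm(rng, n)
        b = shared + 0.5 * confound + 0.05 * _random_dm(rng, n)
        res = partial_mantel(_dm(a), _dm(b), _dm(confound),
                             n_permutations=199, seed=0)
        assert res.statistic > 0.5
        assert res.p_value <= 0.01

    def test_constant_control_falls_back(self):
        rng = np.random.default_rng(9)
        a, b = _random_dm(rng, 8), _random_dm(rng, 8)
        c = np.zeros((8, 8))
        with pytest.warns(UserWarning, match="simple"):
            res = partial_mantel(_dm(a), _dm(b), _dm(c),
                                 n_permutations=99, seed=3)
        simple = mantel(_dm(a), _dm(b), n_permutations=99, seed=3)
        assert res.statistic == pytest.approx(simple.statistic)
        assert res.kind == "partial"


class TestDistanceDecay:
    def test_strictly_decreasing_response(self):
        n = 6
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(
            float
        )
        resp = 10.0 - dist
        np.fill_diagonal(resp, 0.0)
        res = distance_decay(_dm(resp), _dm(dist), ["river"] * n,
                             [f"s{i}" for i in range(n)])
        assert res.spearman_r == pytest.approx(-1.0)

    def test_pair_filter_by_enumeration(self):
        labels = ["a", "b", "c", "d"]
        eco = ["river", "river", "wetland", "river"]
        reference = ["a"]
        pairs = select_pairs(labels, eco, reference)
        # same ecosystem AND at least one end in the reference subset
        expected = [
            (i, j)
            for i, j in itertools.combinations(range(4), 2)
            if eco[i] == eco[j]
            and (labels[i] in reference or labels[j] in reference)
        ]
        assert pairs == expected
        assert (0, 2) not in pairs  # cross-ecosystem excluded
        assert (1, 3) not in pairs  # not anchored to the reference

    def test_same_pair_logic_for_similarity_and_genes(self, toy_table,
                                                      toy_genes):
        eco = ["river"] * 4
        ref = ["s1", "s2"]
        sim = similarity_matrix(toy_table)
        genes = shared_gene_counts(toy_genes)
        d = _dm(np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0))),
                labels=toy_table.sample_ids)
        r1 = distance_decay(sim, d, eco, ref)
        r2 = distance_decay(genes, d, eco, ref)
        assert list(r1.pair_table["sample_a"]) == list(
            r2.pair_table["sample_a"]
        )
        assert list(r1.pair_table["sample_b"]) == list(
            r2.pair_table["sample_b"]
        )

    def test_too_few_pairs_error(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            distance_decay(_dm(d), _dm(d), ["river", "wetland"],
                           ["s0", "s1"])


class TestSharedGenes:
    def test_pair_values(self, toy_genes):
        counts = shared_gene_counts(toy_genes,
                                    [("s1", "s2"), ("s1", "s3"),
                                     ("s1", "s4")])
        np.testing.assert_array_equal(counts, [2, 1, 0])

    def test_identical_rows_count_everything(self, toy_genes):
        m = shared_gene_counts(toy_genes)
        assert m.values[0, 0] == 0.0  # diagonal cleared for decay use
        assert m.values[0, 1] == 2.0

    def test_unknown_sample_error(self, toy_genes):
        with pytest.raises(ValueError):
            shared_gene_counts(toy_genes, [("s1", "nope")])


class TestGeneAccumulation:
    def test_all_singletons_identity_line(self):
        catalog = OrfCatalog([f"o{i}" for i in range(40)],
                             {f"o{i}": f"u{i}" for i in range(40)})
        curve = gene_accumulation(catalog, fractions=[0.5, 1.0],
                                  n_repeats=5, seed=0)
        # sampling k ORFs that are all distinct unigenes yields k
        assert curve.iloc[0]["mean_unigenes"] == 20.0
        assert curve.iloc[1]["mean_unigenes"] == 40.0
        assert curve.iloc[1]["sd"] == 0.0

    def test_single_unigene(self):
        catalog = OrfCatalog([f"o{i}" for i in range(10)],
                             {f"o{i}": "u0" for i in range(10)})
        curve = gene_accumulation(catalog, fractions=[0.2, 0.6, 1.0],
                                  n_repeats=4, seed=1)
        assert (curve["mean_unigenes"] == 1.0).all()

    def test_matches_hypergeometric_expectation(self):
        # 20 ORFs in 6 unigenes with sizes 6,5,4,2,2,1; expected distinct
        # count in a draw of 10 = sum_u 1 - C(20-k_u,10)/C(20,10)
        sizes = [6, 5, 4, 2, 2, 1]
        mapping = {}
        k = 0
        for u, size in enumerate(sizes):
            for _ in range(size):
                mapping[f"o{k}"] = f"u{u}"
                k += 1
        catalog = OrfCatalog(list(mapping), mapping)
        expected = sum(
            1.0 - math.comb(20 - s, 10) / math.comb(20, 10) for s in sizes
        )
        curve = gene_accumulation(catalog, fractions=[0.5], n_repeats=400,
                                  seed=2)
        assert curve.iloc[0]["mean_unigenes"] == pytest.approx(
            expected, abs=0.15
        )


class TestEnvAssociation:
    def test_driving_variable_flagged(self):
        rng = np.random.default_rng(10)
        n = 30
        env = np.linspace(0, 1, n)
        # two taxa trading off monotonically along env, plus noise taxa
        ab = np.column_stack([
            0.2 + 0.6 * env,
            0.8 - 0.6 * env,
            *[0.05 + 0.01 * rng.random(n) for _ in range(4)],
        ])
        ab /= ab.sum(axis=1, keepdims=True)
        table = AbundanceTable([f"s{i}" for i in range(n)],
                               [f"t{j}" for j in range(6)], ab)
        meta = pd.DataFrame(
            {
                "region": "Tibet",
                "ecosystem": "river",
                "latitude": 31.0,
                "longitude": 88.0,
                "altitude_m": 4500.0,
                "driver": env,
                "unrelated": rng.standard_normal(n),
                "constant": 1.0,
            },
            index=pd.Index([f"s{i}" for i in range(n)], name="sample"),
        )
        out = env_association(table, meta,
                              ["driver", "unrelated", "constant"],
                              n_permutations=199, seed=0)
        assert set(out["variable"]) == {"driver", "unrelated"}  # constant skipped
        row = out.set_index("variable")
        assert bool(row.loc["driver", "significant"])
        assert not bool(row.loc["unrelated", "significant"])

    def test_benjamini_hochberg_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.5], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.03, 0.03, 0.5])
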