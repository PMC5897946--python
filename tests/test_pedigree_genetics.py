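"""Pedigree construction, gene-dropping, kinship, phasing and IBD matrices."""

import numpy as np
import pandas as pd
import pytest

import salmospot as sp
from salmospot.genedrop import haldane_r
from salmospot.pedigree import Pedigree


class TestPedigree:
    def test_design_arithmetic(self, small_pedigree):
        # 2 strains x 2 families x 5 offspring
        assert len(small_pedigree.offspring) == 20
        assert len(small_pedigree.founders) >= 4

    def test_half_sib_links_present(self, small_pedigree):
        off = small_pedigree.table[small_pedigree.table["sire"] != ""]
        mates = off.groupby("sire")["dam"].nunique()
        assert (mates >= 2).any()

    def test_cycle_rejected(self):
        tab = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "sire": ["b", "c", "a"],
                "dam": ["b", "c", "a"],
                "strain": ["s"] * 3,
            }
        )
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(tab)

    def test_single_known_parent_rejected(self):
        tab = pd.DataFrame(
            {
                "id": ["a", "b"],
                "sire": ["", "a"],
                "dam": ["", ""],
                "strain": ["s", "s"],
            }
        )
        with pytest.raises(ValueError, match="one known parent"):
            Pedigree(tab)


class TestKinship:
    def test_unrelated_founders_identity(self):
        tab = pd.DataFrame(
            {"id": list("abcd"), "sire": [""] * 4, "dam": [""] * 4, "strain": ["s"] * 4}
        )
        A = sp.additive_relationship(Pedigree(tab))
        np.testing.assert_allclose(A.to_numpy(), np.eye(4))

    def test_classic_relationships(self, small_pedigree):
        A = sp.additive_relationship(small_pedigree)
        t = small_pedigree.table
        off = t[t["sire"] != ""]
        fam = off.groupby(["sire", "dam"])["id"].apply(list)
        sibs = fam.iloc[0]
        assert A.loc[sibs[0], sibs[1]] == 0.5  # full sibs
        rec = off.iloc[0]
        assert A.loc[rec["id"], rec["sire"]] == 0.5  # parent-offspring
        # half sibs across the shared sire
        by_sire = off.groupby("sire")["dam"].nunique()
        sire = by_sire[by_sire >= 2].index[0]
        fams = off[off["sire"] == sire].groupby("dam")["id"].apply(list)
        assert A.loc[fams.iloc[0][0], fams.iloc[1][0]] == 0.25

    def test_three_generation_vs_gene_dropping_oracle(self):
        """Tabular A equals twice the Monte-Carlo kinship from gene dropping."""
        tab = pd.DataFrame(
            {
                "id": ["g1", "g2", "g3", "g4", "p1", "p2", "o1", "o2"],
                "sire": ["", "", "", "", "g1", "g3", "p1", "p1"],
                "dam": ["", "", "", "", "g2", "g4", "p2", "p2"],
                "strain": ["s"] * 8,
            }
        )
        ped = Pedigree(tab)
        A = sp.additive_relationship(ped)

        rng = np.random.default_rng(1)
        n_drop = 100_000
        alleles = {}
        counter = iter(range(10**6))
        for rec in ped.table.itertuples():
            if rec.sire == "":
                alleles[rec.id] = np.stack(
                    [np.full(n_drop, next(counter)), np.full(n_drop, next(counter))]
                )
            else:
                s = alleles[rec.sire][rng.integers(0, 2, n_drop), np.arange(n_drop)]
                d = alleles[rec.dam][rng.integers(0, 2, n_drop), np.arange(n_drop)]
                alleles[rec.id] = np.stack([s, d])

        def kin(i, j):
            ai, aj = alleles[i], alleles[j]
            share = sum(
                (ai[x] == aj[y]).mean() for x in range(2) for y in range(2)
            )
            return share / 4

        for i, j in [("o1", "o2"), ("o1", "g1"), ("o1", "p2"), ("p1", "p2")]:
            assert 2 * kin(i, j) == pytest.approx(A.loc[i, j], abs=0.01)


class TestGeneDropping:
    def test_zero_distance_identical_origins(self):
        gmap = sp.GeneticMap(
            pd.DataFrame(
                {
                    "linkage_group": ["LG1", "LG1"],
                    "marker_id": ["m1", "m2"],
                    "position_cM": [0.0, 1e-9],
                }
            )
        )
        ped = sp.gen_pedigree(["A", "B"], 2, 20)
        _, truth = sp.gen_genotypes(ped, gmap, 0.5, seed=0)
        np.testing.assert_array_equal(truth.sire_origin[:, 0], truth.sire_origin[:, 1])

    @pytest.mark.parametrize(
        "d, expected",
        [(20.0, 1 - haldane_r(20.0)), (10_000.0, 0.5)],
    )
    def test_origin_concordance_follows_haldane(self, d, expected):
        gmap = sp.GeneticMap(
            pd.DataFrame(
                {
                    "linkage_group": ["LG1", "LG1"],
                    "marker_id": ["m1", "m2"],
                    "position_cM": [0.0, d],
                }
            )
        )
        ped = sp.gen_pedigree(["A", "B"], 5, 1000)
        _, truth = sp.gen_genotypes(ped, gmap, 0.5, seed=1)
        conc = np.mean(truth.sire_origin[:, 0] == truth.sire_origin[:, 1])
        # 10,000 meioses: 3 sigma MC band
        se = np.sqrt(expected * (1 - expected) / truth.sire_origin.shape[0])
        assert abs(conc - expected) < max(3 * se, 0.02)

    def test_transmission_frequencies_balanced(self):
        ped = sp.gen_pedigree(["A", "B"], 5, 500)
        _, truth = sp.gen_genotypes(ped, sp.GeneticMap.regular(), 0.5, seed=3)
        freq = truth.sire_origin.mean(axis=0)
        assert np.all(np.abs(freq - 0.5) < 0.03)

    def test_strictly_increasing_positions_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            sp.GeneticMap(
                pd.DataFrame(
                    {
                        "linkage_group": ["LG1", "LG1"],
                        "marker_id": ["m1", "m2"],
                        "position_cM": [10.0, 10.0],
                    }
                )
            )

    def test_reproducible(self):
        ped = sp.gen_pedigree(["A", "B"], 2, 5)
        g1, _ = sp.gen_genotypes(ped, sp.GeneticMap.regular(), 0.5, seed=9)
        g2, _ = sp.gen_genotypes(ped, sp.GeneticMap.regular(), 0.5, seed=9)
        np.testing.assert_array_equal(g1.alleles, g2.alleles)


class TestPhasing:
    def _single_family(self, g_sire, g_dam, g_off, positions=(0.0, 20.0, 40.0)):
        """Hand-built one-offspring family with explicit dosages."""
        gmap = sp.GeneticMap(
            pd.DataFrame(
                {
                    "linkage_group": "LG1",
                    "marker_id": [f"m{i}" for i in range(len(positions))],
                    "position_cM": positions,
                }
            )
        )
        ped = Pedigree(
            pd.DataFrame(
                {
                    "id": ["sire", "dam", "off"],
                    "sire": ["", "", "sire"],
                    "dam": ["", "", "dam"],
                    "strain": ["s"] * 3,
                }
            )
        )
        def to_alleles(dose):
            return [(0, 0), (0, 1), (1, 1)][dose]
        alleles = np.array(
            [[to_alleles(d) for d in g] for g in (g_sire, g_dam, g_off)], dtype=np.int8
        )
        geno = sp.GenotypeMatrix(ids=["sire", "dam", "off"], alleles=alleles,
                                 gmap=gmap, phased=True)
        return ped, geno, gmap

    def test_informative_cross(self):
        # sire Aa x dam aa, offspring Aa: sire transmitted A -> origin known
        ped, geno, gmap = self._single_family([1, 1, 1], [0, 0, 0], [1, 1, 1])
        asn = sp.phase_offspring(ped, geno)
        assert asn.informative["sire"].all()
        p = asn.origin_prob("sire", "LG1", 20.0)
        assert p[0] in (0.0, 1.0)

    def test_double_het_uninformative(self):
        # sire Aa x dam Aa, offspring Aa: transmission ambiguous in isolation
        ped, geno, gmap = self._single_family([1], [1], [1], positions=(0.0,))
        asn = sp.phase_offspring(ped, geno)
        assert not asn.informative["sire"][0, 0]
        assert asn.origin_prob("sire", "LG1", 0.0)[0] == pytest.approx(0.5)

    def test_flanking_interpolation_formula(self):
        # uninformative middle marker, informative agreeing flanks 20 cM apart
        ped, geno, gmap = self._single_family(
            [1, 1, 1], [0, 1, 0], [1, 1, 1], positions=(0.0, 10.0, 20.0)
        )
        asn = sp.phase_offspring(ped, geno)
        assert not asn.informative["sire"][0, 1]
        p = asn.origin_prob("sire", "LG1", 10.0)[0]
        r = haldane_r(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert p in (
            pytest.approx(expected, abs=1e-12),
            pytest.approx(1 - expected, abs=1e-12),
        )

    def test_mendelian_error_flagged(self):
        ped, geno, gmap = self._single_family([0], [0], [2], positions=(0.0,))
        asn = sp.phase_offspring(ped, geno)
        assert len(asn.mendel_errors) > 0
        assert not asn.informative["sire"][0, 0]

    def test_unphased_reconstruction_matches_truth(self, nuclear_cohort):
        """Majority-linkage parent phasing recovers true origins (mod flip)."""
        ped, geno, truth = (
            nuclear_cohort["pedigree"], nuclear_cohort["geno"], nuclear_cohort["truth"]
        )
        unphased = sp.GenotypeMatrix(
            ids=geno.ids, alleles=geno.alleles, gmap=geno.gmap, phased=False
        )
        asn = sp.phase_offspring(ped, unphased)
        gmap = geno.gmap
        tab = ped.table
        off = tab[tab["sire"] != ""]
        accs = []
        for parent_key in ("sire", "dam"):
            for par, grp in off.groupby(parent_key):
                rows = [asn.offspring_ids.index(i) for i in grp["id"]]
                trows = [truth.origin_row(i) for i in grp["id"]]
                t_orig = truth.sire_origin if parent_key == "sire" else truth.dam_origin
                for lg in gmap.linkage_groups:
                    idx = gmap.group_indices(lg)
                    inf = asn.informative[parent_key][np.ix_(rows, idx)]
                    if inf.sum() < 10:
                        continue
                    est = asn.origins[parent_key][np.ix_(rows, idx)][inf]
                    tru = t_orig[np.ix_(trows, idx)][inf]
                    agree = (est == tru).mean()
                    accs.append(max(agree, 1 - agree))
        assert np.mean(accs) > 0.95


class TestIbdMatrix:
    def test_self_and_parent_offspring(self, nuclear_cohort):
        ped, gmap, truth = (
            nuclear_cohort["pedigree"], nuclear_cohort["geno"].gmap, nuclear_cohort["truth"]
        )
        asn = sp.assignment_from_truth(ped, gmap, truth)
        P = sp.ibd_matrix(asn, ped, "LG1", 25.0)
        np.testing.assert_allclose(np.diag(P.to_numpy()), 1.0)
        off = ped.table[ped.table["sire"] != ""].iloc[0]
        assert P.loc[off["id"], off["sire"]] == 0.5

    def test_half_sib_fully_informative_values(self, nuclear_cohort):
        """At a fully informative locus half-sib entries are exactly 0 or 0.5."""
        ped, gmap, truth = (
            nuclear_cohort["pedigree"], nuclear_cohort["geno"].gmap, nuclear_cohort["truth"]
        )
        asn = sp.assignment_from_truth(ped, gmap, truth)
        P = sp.ibd_matrix(asn, ped, "LG1", 0.0)
        tab = ped.table
        off = tab[tab["sire"] != ""]
        by_sire = off.groupby("sire")["dam"].nunique()
        sire = by_sire[by_sire >= 2].index[0]
        fams = off[off["sire"] == sire].groupby("dam")["id"].apply(list)
        vals = {
            float(P.loc[a, b]) for a in fams.iloc[0] for b in fams.iloc[1]
        }
        assert vals <= {0.0, 0.5}

    def test_full_sib_mean_half(self):
        """Mean realized full-sib IBD over many gene-drops approaches 0.5."""
        ped = sp.gen_pedigree(["A", "B"], 2, 6, half_sib=False)
        gmap = sp.GeneticMap.regular(1, 2, 25.0)
        vals = []
        for s in range(300):
            _, truth = sp.gen_genotypes(ped, gmap, 0.5, seed=s)
            asn = sp.assignment_from_truth(ped, gmap, truth)
            P = sp.ibd_matrix(asn, ped, "LG1", 25.0, ids=ped.offspring)
            fam = ped.family_of()
            sibs = fam[fam == fam.iloc[0]].index.tolist()
            vals.append(P.loc[sibs[0], sibs[1]])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_psd_and_symmetry(self, nuclear_cohort):
        ped, geno = nuclear_cohort["pedigree"], nuclear_cohort["geno"]
        asn = sp.phase_offspring(ped, geno)
        for pos in (0.0, 12.5, 60.0):
            P = sp.ibd_matrix(asn, ped, "LG1", pos).to_numpy()
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.linalg.eigvalsh(P).min() > -1e-8
            assert P.min() >= 0 and P.max() <= 1 + 1e-12
        A = sp.additive_relationship(ped).to_numpy()
        assert np.linalg.eigvalsh(A).min() > -1e-8

    def test_mean_over_positions_approaches_kinship(self):
        """Averaging realized IBD over loci and gene-drops converges to A."""
        ped = sp.gen_pedigree(["A", "B"], 2, 8)
        gmap = sp.GeneticMap.regular(2, 3, 30.0)
        A = sp.additive_relationship(ped, ids=ped.offspring).to_numpy()
        acc = np.zeros_like(A)
        count = 0
        for s in range(150):
            _, truth = sp.gen_genotypes(ped, gmap, 0.5, seed=1000 + s)
            asn = sp.assignment_from_truth(ped, gmap, truth)
            for lg, pos in (("LG1", 0.0), ("LG1", 60.0), ("LG2", 30.0)):
                acc += sp.ibd_matrix(asn, ped, lg, pos, ids=ped.offspring).to_numpy()
                count += 1
        assert np.abs(acc / count - A).max() < 0.05

    def test_off_map_position_rejected(self, nuclear_cohort):
        ped, geno, truth = (
            nuclear_cohort["pedigree"], nuclear_cohort["geno"], nuclear_cohort["truth"]
        )
        asn = sp.assignment_from_truth(ped, geno.gmap, truth)
        with pytest.raises(ValueError, match="off the mapped range"):
            sp.ibd_matrix(asn, ped, "LG1", 999.0)
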