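"""Family clustering, consensus building, variant splitting, naming."""

import numpy as np
import pytest

from satdna.canon import Monomer, canonical_monomer, reverse_complement, rotational_identity
from satdna.cluster import (
    SatelliteFamily,
    build_consensus,
    cluster_monomers,
    name_family,
    split_variants,
)
from satdna.simulate import random_monomer


def mono(seq, w=100):
    return Monomer.from_unit(seq, w)


def mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(out)


class TestClusterMonomers:
    def test_rotated_pair_merges(self):
        a = "ACGGATCATGCATCAGGCATACGATCAGTCAAGGACT"
        fams = cluster_monomers([mono(a), mono(a[10:] + a[:10])])
        assert len(fams) == 1

    def test_distant_pair_stays_apart(self):
        rng = np.random.default_rng(1)
        a = random_monomer(100, rng)
        b = random_monomer(100, rng)
        ident = rotational_identity(a, b)
        assert ident < 0.8  # verified precondition for this fixture pair
        fams = cluster_monomers([mono(a), mono(b)], id_threshold=0.8)
        assert len(fams) == 2

    def test_three_planted_families_recovered(self):
        rng = np.random.default_rng(2)
        pyrng = np.random.default_rng(3)
        ancestors = [random_monomer(L, rng) for L in (40, 80, 120)]
        monomers = []
        for anc in ancestors:
            for k in range(5):
                n_mut = int(0.05 * len(anc))
                pos = pyrng.choice(len(anc), size=n_mut, replace=False)
                mutated = mutate(anc, pos, pyrng)
                monomers.append(mono(mutated, w=50 + k))
        fams = cluster_monomers(monomers)
        assert len(fams) == 3
        for fam in fams:
            assert len(fam.members) == 5

    def test_members_match_representative_at_threshold(self):
        rng = np.random.default_rng(4)
        anc = random_monomer(60, rng)
        monomers = [mono(anc, 100)] + [
            mono(mutate(anc, rng.choice(60, size=3, replace=False), rng), 10) for _ in range(6)
        ]
        fams = cluster_monomers(monomers, id_threshold=0.8)
        for fam in fams:
            rep = fam.representative.canonical_seq
            for m in fam.members:
                assert rotational_identity(rep, m.canonical_seq) >= 0.8

    def test_sorted_by_total_bp_and_empty_ok(self):
        assert cluster_monomers([]) == []
        rng = np.random.default_rng(5)
        a, b = random_monomer(50, rng), random_monomer(90, rng)
        fams = cluster_monomers([mono(a, 10), mono(b, 1000)])
        assert fams[0].total_bp >= fams[1].total_bp


class TestBuildConsensus:
    def test_identical_members(self):
        a = "ACGGATCATGCATCAGGCAT"
        fams = cluster_monomers([mono(a), mono(a)])
        assert fams[0].consensus == canonical_monomer(a)

    def test_majority_restores_substitution(self):
        a = "ACGGATCATGCATCAGGCATACGATCAGTCAAGGACT"
        mutated = "ACGGATCATGCATCAGGCATACGATCAGTCAAGGACA"
        cons = build_consensus([mono(a, 1), mono(a, 1), mono(mutated, 1)])
        assert cons == canonical_monomer(a)

    def test_weighted_majority(self):
        a = "ACGGATCATGCATCAGGCATACGATCAGTCAAGGACT"
        alt = "ACGGATCATGCATCAGGCATACGATCAGTCAAGGACA"
        cons = build_consensus([mono(a, 10), mono(alt, 1), mono(alt, 1)])
        assert cons == canonical_monomer(a)  # heavy member wins the column

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestSplitVariants:
    def _family(self, members):
        return SatelliteFamily("F", members, build_consensus(members), sum(m.weight_bp for m in members))

    def test_homogeneous_family_has_no_variants(self):
        a = "ACGGATCATGCATCAGGCATACGATCAGTCAAGGACT"
        fam = self._family([mono(a, 100), mono(a, 80)])
        assert split_variants(fam) == []

    def test_balanced_variants_split(self):
        rng = np.random.default_rng(6)
        anc = random_monomer(145, rng)
        positions = list(range(30, 36))  # 6 diagnostic positions
        alt = mutate(anc, positions, rng)
        members = [mono(anc, 100) for _ in range(3)] + [mono(alt, 100) for _ in range(3)]
        fam = self._family(members)
        variants = split_variants(fam, variant_threshold=0.97, min_share=0.2)
        assert len(variants) == 2
        assert [v.label for v in variants] == ["A", "B"]
        for v in variants:
            assert v.member_share == pytest.approx(0.5)
        # the planted 6 diffs yield at least enough diagnostic columns to
        # discriminate (edlib may explain clustered diffs with an indel)
        assert len(variants[0].diagnostic_positions) >= 3

    def test_minor_variant_below_share_not_split(self):
        rng = np.random.default_rng(7)
        anc = random_monomer(100, rng)
        alt = mutate(anc, list(range(10, 16)), rng)
        members = [mono(anc, 95)] + [mono(alt, 5)]
        fam = self._family(members)
        assert split_variants(fam, variant_threshold=0.97, min_share=0.2) == []


class TestNameFamily:
    @pytest.mark.parametrize(
        "prefix,unit_len,taken,expected",
        [
            ("Bcop", 145, set(), "BcopSat-145"),
            ("Bcop", 155, {"BcopSat-155"}, "BcopSat-155b"),
            ("Bcop", 10, set(), "BcopSat-10"),
        ],
    )
    def test_naming(self, prefix, unit_len, taken, expected):
        assert name_family(prefix, unit_len, taken) == expected

    def test_invalid_unit_len(self):
        with pytest.raises(ValueError):
            name_family("Bcop", 0, set())


def test_order_invariance_of_family_count():
    """Permuting equal-weight inputs never changes the number of families."""
    rng = np.random.default_rng(8)
    ancestors = [random_monomer(L, rng) for L in (30, 60, 90)]
    monomers = []
    for anc in ancestors:
        monomers.extend(mono(anc, 100) for _ in range(3))
    n_ref = len(cluster_monomers(monomers))
    for seed in range(5):
        perm = np.random.default_rng(seed).permutation(len(monomers))
        assert len(cluster_monomers([monomers[i] for i in perm])) == n_ref
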