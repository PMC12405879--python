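"""Synthetic genome/read generation and recovery scoring."""

import numpy as np
import pytest

from satdna.canon import rotational_identity
from satdna.simulate import (
    ContigSpec,
    PlantedArray,
    PlantedFamily,
    SyntheticSpec,
    generate_genome,
    generate_reads,
    mutate_monomer,
    random_monomer,
    score_recovery,
)

UNIT = "ACGGATCATGCATCAGGCAT"


def small_spec(seed=1, sub=0.0, indel=0.0):
    return SyntheticSpec(
        seed=seed,
        contigs=[ContigSpec("c1", 20_000, 0.4), ContigSpec("L1", 10_000, 0.4)],
        planted=[
            PlantedFamily("f1", UNIT, [PlantedArray("c1", 2_000, 100)], sub, indel),
            PlantedFamily("priv", "AACGTATTAG", [PlantedArray("L1", 1_000, 200)], sub, indel),
        ],
        l_contigs={"L1"},
    )


class TestMutateMonomer:
    def test_zero_rates_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_monomer(UNIT, 0, 0, rng) == UNIT

    def test_mean_identity_tracks_rate(self):
        rng = np.random.default_rng(1)
        base = random_monomer(100, rng)
        idents = [
            rotational_identity(base, mutate_monomer(base, 0.05, 0.0, rng))
            for _ in range(300)
        ]
        # expected identity ~ 1 - sub_rate; allow binomial spread
        assert 0.93 <= np.mean(idents) <= 0.97

    def test_seeded_determinism(self):
        a = mutate_monomer(UNIT, 0.1, 0.05, np.random.default_rng(42))
        b = mutate_monomer(UNIT, 0.1, 0.05, np.random.default_rng(42))
        assert a == b

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            mutate_monomer(UNIT, 0.3, 0, np.random.default_rng(0))


class TestGenerateGenome:
    def test_contig_lengths_match_spec(self):
        assemblies, _ = generate_genome(small_spec())
        assert {n: len(s) for n, s in assemblies["germ"].items()} == {"c1": 20_000, "L1": 10_000}

    def test_private_contig_absent_from_soma(self):
        assemblies, _ = generate_genome(small_spec())
        assert set(assemblies["soma"]) == {"c1"}
        assert set(assemblies["germ"]) == {"c1", "L1"}

    def test_manifest_matches_fasta(self):
        assemblies, manifest = generate_genome(small_spec())
        germ = assemblies["germ"]
        for ra in manifest.arrays:
            planted = germ[ra.contig][ra.start : ra.end]
            # exact planting (zero mutation): the interval is a clean tandem
            unit = UNIT if ra.family == "f1" else "AACGTATTAG"
            assert planted == unit * ((ra.end - ra.start) // len(unit))

    def test_realized_bp_recorded(self):
        _, manifest = generate_genome(small_spec(sub=0.02, indel=0.02))
        f1 = manifest.planted_bp("germ", "f1")
        assert f1 == pytest.approx(100 * len(UNIT), rel=0.1)
        assert manifest.planted_bp("soma", "priv") == 0

    def test_overlapping_intervals_rejected(self):
        spec = SyntheticSpec(
            seed=0,
            contigs=[ContigSpec("c1", 10_000, 0.4)],
            planted=[
                PlantedFamily("a", UNIT, [PlantedArray("c1", 100, 50)]),
                PlantedFamily("b", "AACGTATTAG", [PlantedArray("c1", 500, 50)]),
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_genome(spec)

    def test_deterministic_under_seed(self):
        a1, m1 = generate_genome(small_spec(seed=9))
        a2, m2 = generate_genome(small_spec(seed=9))
        assert a1 == a2
        assert m1 == m2


class TestGenerateReads:
    def test_read_count_arithmetic(self):
        assemblies, _ = generate_genome(small_spec())
        rng = np.random.default_rng(0)
        reads = list(generate_reads(assemblies["soma"], 2.0, 100, 0.0, rng))
        assert len(reads) == round(2.0 * 20_000 / 100)

    def test_errorfree_reads_map_back(self):
        assemblies, _ = generate_genome(small_spec())
        genome = assemblies["soma"]["c1"]
        from satdna.canon import reverse_complement

        rng = np.random.default_rng(1)
        for _, seq in list(generate_reads(assemblies["soma"], 0.2, 100, 0.0, rng)):
            assert seq in genome or reverse_complement(seq) in genome

    def test_strand_balance(self):
        assemblies, _ = generate_genome(small_spec())
        rng = np.random.default_rng(2)
        reads = list(generate_reads(assemblies["germ"], 3.0, 100, 0.0, rng))
        frac_fwd = np.mean([name.endswith("_+") for name, _ in reads])
        n = len(reads)
        se = (0.25 / n) ** 0.5
        assert abs(frac_fwd - 0.5) <= 3 * se

    def test_short_contig_skipped(self):
        rng = np.random.default_rng(3)
        reads = list(generate_reads({"tiny": "ACGT" * 10, "ok": "ACGT" * 100}, 1.0, 100, 0.0, rng))
        assert all("_ok_" in name for name, _ in reads)


class TestScoreRecovery:
    def test_perfect_detection(self):
        _, manifest = generate_genome(small_spec())
        reported = [("R1", UNIT, manifest.planted_bp("germ", "f1") / 1000),
                    ("R2", "AACGTATTAG", manifest.planted_bp("germ", "priv") / 1000)]
        m = score_recovery(manifest, reported, planted_monomers={"f1": UNIT, "priv": "AACGTATTAG"})
        assert m.precision == 1.0 and m.recall == 1.0

    def test_nothing_reported(self):
        _, manifest = generate_genome(small_spec())
        m = score_recovery(manifest, [], planted_monomers={"f1": UNIT, "priv": "AACGTATTAG"})
        assert m.recall == 0.0

    def test_spurious_family_lowers_precision(self):
        _, manifest = generate_genome(small_spec())
        rng = np.random.default_rng(11)
        reported = [
            ("R1", UNIT, 2.0),
            ("R2", "AACGTATTAG", 2.0),
            ("junk", random_monomer(60, rng), 1.0),
        ]
        m = score_recovery(manifest, reported, planted_monomers={"f1": UNIT, "priv": "AACGTATTAG"})
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == 1.0
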