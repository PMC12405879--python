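"""Tandem array detection: periods, scanning, refinement, filtering."""

import itertools

import numpy as np
import pytest

from conftest import brute_primitive_period, random_dna
from satdna.detect import (
    DetectorParams,
    TandemArray,
    filter_arrays,
    primitive_period,
    refine_array,
    scan_contig,
)


class TestPrimitivePeriod:
    @pytest.mark.parametrize(
        "seq,period",
        [
            ("AAAACGTATTAAAACGTATTAAAACGTATT", 10),
            ("ACACACAC", 2),
            ("ACGTA", 5),  # primitive: period equals length
            ("A", 1),
        ],
    )
    def test_examples(self, seq, period):
        assert primitive_period(seq) == period

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            primitive_period("")

    def test_exhaustive_binary_strings(self):
        # every string over {A,C} up to length 12 against the brute oracle
        for n in range(1, 13):
            for tup in itertools.product("AC", repeat=n):
                s = "".join(tup)
                assert primitive_period(s) == brute_primitive_period(s)

    def test_random_long_strings(self):
        for seed in range(300):
            s = random_dna(1 + (seed * 37) % 200, seed)
            assert primitive_period(s) == brute_primitive_period(s)


def _params(**kw):
    defaults = dict(unit_min=5, min_array_score=40)
    defaults.update(kw)
    return DetectorParams(**defaults)


class TestScanContig:
    def test_planted_exact_array_recovered(self):
        unit = "AAAACGTATT"
        seq = random_dna(1000, 1) + unit * 50 + random_dna(1000, 2)
        arrays = scan_contig(seq, _params(), "c")
        assert len(arrays) == 1
        a = arrays[0]
        assert a.unit_len == 10
        assert a.copies == pytest.approx(50, abs=1)
        assert a.array_bp == pytest.approx(500, abs=10)
        # boundary within one unit of the planted truth
        assert abs(a.start - 1000) <= 10 and abs(a.end - 1500) <= 10

    def test_too_few_copies_not_reported(self):
        seq = random_dna(500, 3) + "ACGTTGCATGCATGCAGTACGGTACGTTAA" * 4 + random_dna(500, 4)
        arrays = scan_contig(seq, DetectorParams(min_copies=5), "c")
        assert arrays == []

    def test_random_sequence_yields_nothing(self):
        seq = random_dna(2000, 42)
        # oracle: no window autocorrelation supports >=5 copies at >=80%
        assert not _has_tandem_signal(seq, unit_min=20, unit_max=500)
        assert scan_contig(seq, DetectorParams(), "c") == []

    def test_short_contig_empty(self):
        assert scan_contig("ACGTACG", DetectorParams()) == []

    def test_n_runs_split_arrays(self):
        unit = "ACGGATCATGCATCAGGCAT"
        seq = unit * 10 + "N" * 5 + unit * 10
        arrays = scan_contig(seq, _params(), "c")
        assert len(arrays) == 2
        for a in arrays:
            assert "N" not in a.unit_seq

    def test_arrays_are_disjoint_and_in_bounds(self):
        rng = np.random.default_rng(9)
        pieces = [random_dna(300, 50)]
        for i, L in enumerate((11, 25, 40)):
            unit = random_dna(L, 60 + i)
            pieces.append(unit * 12)
            pieces.append(random_dna(200, 70 + i))
        seq = "".join(pieces)
        arrays = scan_contig(seq, _params(), "c")
        assert arrays == sorted(arrays, key=lambda a: a.start)
        for a, b in zip(arrays, arrays[1:]):
            assert a.end <= b.start
        for a in arrays:
            assert 0 <= a.start < a.end <= len(seq)

    def test_deterministic(self):
        seq = random_dna(500, 5) + "ACGGATCATGCATCAGGCAT" * 20 + random_dna(500, 6)
        p = _params()
        r1 = scan_contig(seq, p, "c")
        r2 = scan_contig(seq, p, "c")
        assert [(a.start, a.end, a.unit_seq, a.copies, a.mean_identity) for a in r1] == [
            (a.start, a.end, a.unit_seq, a.copies, a.mean_identity) for a in r2
        ]


def _has_tandem_signal(seq, unit_min, unit_max, min_copies=5, min_identity=0.8):
    """Exhaustive autocorrelation oracle: does any window support a tandem
    of >= min_copies consecutive unit matches at >= min_identity?"""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(codes)
    for p in range(unit_min, min(unit_max, n // 2) + 1):
        eq = codes[p:] == codes[:-p]
        # run of matches of length m supports span m + p
        need = int(np.ceil(p * (min_copies - 1) * min_identity))
        window = np.convolve(eq.astype(int), np.ones(p * (int(min_copies) - 1), dtype=int), "valid")
        if (window >= need).any():
            return True
    return False


class TestRefineArray:
    def test_single_substitution_mean_identity(self):
        unit = "AAAACGTATT"
        copies = [unit] * 10
        copies[5] = "AAAACGTCTT"  # one substitution in copy 6
        seq = random_dna(200, 11) + "".join(copies) + random_dna(200, 12)
        arr = refine_array(seq, 200, unit, _params())
        assert arr is not None
        assert arr.array_bp == 100
        assert arr.mean_identity == pytest.approx(0.99)

    def test_boundaries_within_one_unit(self):
        unit = "ACGGATCATGCATCAGGCAT"
        seq = random_dna(500, 13) + unit * 15 + random_dna(500, 14)
        arr = refine_array(seq, 500 + 3 * 20, unit, _params())
        assert abs(arr.start - 500) <= 20
        assert abs(arr.end - (500 + 300)) <= 20

    def test_two_copy_seed_survives_then_filtered(self):
        unit = "ACGGATCATGCATCAGGCAT"
        seq = random_dna(300, 15) + unit * 2 + random_dna(300, 16)
        arr = refine_array(seq, 300, unit, _params())
        assert arr is not None and arr.copies < 5
        assert filter_arrays([arr], DetectorParams(min_copies=5)) == []


class TestFilterArrays:
    def test_copy_threshold_boundary(self):
        arrays = []
        for c in (4.9, 5.0, 12.3):
            a = TandemArray("c", 0, int(c * 50), "ACGTT" * 10, c, 0.95, 500)
            arrays.append(a)
        kept = filter_arrays(arrays, DetectorParams(min_copies=5))
        assert [a.copies for a in kept] == [5.0, 12.3]

    def test_unit_range_boundary_inclusive(self):
        arrays = []
        for L in (15, 20, 500, 501):
            unit = ("ACGTT" * 101)[:L]
            arrays.append(TandemArray("c", 0, L * 10, unit, 10.0, 0.95, 10_000))
        kept = filter_arrays(arrays, DetectorParams(unit_min=20, unit_max=500))
        assert sorted(a.unit_len for a in kept) == [20, 500]

    def test_empty_input(self):
        assert filter_arrays([], DetectorParams()) == []


class TestDetectorParams:
    @pytest.mark.parametrize(
        "kw",
        [dict(unit_min=0), dict(unit_min=30, unit_max=20), dict(min_copies=1.5), dict(min_identity=0.0), dict(min_identity=1.2)],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            DetectorParams(**kw)
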