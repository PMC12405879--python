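"""Shared fixtures: brute-force oracles and seeded synthetic genomes."""

from __future__ import annotations

import random

import numpy as np
import pytest

from satdna.canon import reverse_complement
from satdna.pipeline import RunConfig, discover
from satdna.simulate import (
    ContigSpec,
    PlantedArray,
    PlantedFamily,
    SyntheticSpec,
    generate_genome,
    random_monomer,
)

# ---------------------------------------------------------------- oracles


def brute_primitive_period(s: str) -> int:
    """Smallest p dividing len(s) with s a tandem power of its p-prefix."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    raise AssertionError("unreachable")


def brute_canonical(s: str) -> str:
    """Lexicographic minimum over all rotations of both strands."""
    cands = []
    for t in (s, reverse_complement(s)):
        cands.extend(t[i:] + t[:i] for i in range(len(t)))
    return min(cands)


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_rotational_identity(a: str, b: str) -> float:
    """Quadratic-DP oracle over all rotations and both strands of b."""
    best = 0.0
    cols = max(len(a), len(b))
    for t in (b, reverse_complement(b)):
        for i in range(len(t)):
            rot = t[i:] + t[:i]
            best = max(best, (cols - levenshtein(a, rot)) / cols)
    return best


def random_dna(n: int, seed: int, alphabet: str = "ACGT") -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(alphabet) for _ in range(n))


# ------------------------------------------------------- synthetic genomes


@pytest.fixture(scope="session")
def planted_genome():
    """2 Mb assembly with six planted families (units 20-200 bp, ~5%
    divergence, >= 25 kb each) plus its truth manifest and discovery run."""
    rng = np.random.default_rng(20_240_001)
    unit_lens = (20, 45, 80, 120, 160, 200)
    units = [random_monomer(L, rng) for L in unit_lens]
    contigs = [ContigSpec(f"ctg{i}", 330_000, 0.4) for i in range(6)]
    planted = []
    for i, u in enumerate(units):
        copies = max(5, 20_000 // len(u))
        planted.append(
            PlantedFamily(
                name=f"planted{i}",
                ancestral_monomer=u,
                arrays=[
                    PlantedArray(f"ctg{i}", 40_000, copies),
                    PlantedArray(f"ctg{i}", 200_000, copies),
                ],
                sub_rate=0.04,
                indel_rate=0.01,
            )
        )
    spec = SyntheticSpec(seed=555, contigs=contigs, planted=planted)
    assemblies, manifest = generate_genome(spec)
    result = discover(assemblies["germ"], RunConfig(abundant_kb=20.0))
    return {
        "assembly": assemblies["germ"],
        "manifest": manifest,
        "result": result,
        "monomers": {f"planted{i}": u for i, u in enumerate(units)},
    }


def make_core_germ_pair(seed: int):
    """Synthetic core/germ assembly pair: 5 shared families on core
    contigs, 3 germ-private families (units 10, 38, 39) on L contigs."""
    rng = np.random.default_rng(seed)
    shared_units = [random_monomer(L, rng) for L in (24, 41, 67, 95, 130)]
    private_units = [random_monomer(L, rng) for L in (10, 38, 39)]
    contigs = [
        ContigSpec("core1", 60_000, 0.4),
        ContigSpec("core2", 60_000, 0.4),
        ContigSpec("L1", 40_000, 0.4),
        ContigSpec("L2", 40_000, 0.4),
    ]
    planted = []
    for i, u in enumerate(shared_units):
        ctg = "core1" if i % 2 == 0 else "core2"
        planted.append(
            PlantedFamily(
                name=f"shared{i}",
                ancestral_monomer=u,
                arrays=[PlantedArray(ctg, 5_000 + (i // 2) * 18_000, max(5, 8_000 // len(u)))],
                sub_rate=0.03,
            )
        )
    for i, u in enumerate(private_units):
        ctg = "L1" if i % 2 == 0 else "L2"
        planted.append(
            PlantedFamily(
                name=f"private{i}",
                ancestral_monomer=u,
                arrays=[PlantedArray(ctg, 4_000 + (i // 2) * 16_000, max(5, 9_000 // len(u)))],
                sub_rate=0.03,
            )
        )
    spec = SyntheticSpec(seed=seed, contigs=contigs, planted=planted, l_contigs={"L1", "L2"})
    assemblies, manifest = generate_genome(spec)
    return assemblies, manifest, {f.name: f.ancestral_monomer for f in planted}
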