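"""Seeded synthetic assemblies and reads with planted satellite landscapes.

The generator emulates the study design the pipeline targets: a
multi-contig assembly with planted tandem-repeat families (units 10-500
bp, >= 5 copies per array, per-family divergence up to ~10% identity
loss, optional A/B variant structure), a second assembly whose extra
contigs carry private families (emulating the germline-restricted L
chromosomes), and uniform-coverage reads from a "soma" and a "germ"
tissue.  Every product is deterministic under the spec seed, and a truth
manifest records realized (post-mutation) coordinates and bp so recovery
can be scored exactly.

Deliberately unmodeled: assembly collapse of repeats, read-quality
profiles beyond a flat score, and background repeat structure (an i.i.d.
background by default; low-copy decoy repeats can be planted explicitly
to stress the copy-count filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canon import rotational_identity
from .detect import primitive_period

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedArray:
    contig: str
    start: int
    copies: int
    variant: str | None = None  # variant label, assigned at generation


@dataclass
class PlantedFamily:
    name: str
    ancestral_monomer: str
    arrays: list[PlantedArray]
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    # optional A/B structure: list of (variant monomer, share) — arrays are
    # assigned to variants deterministically in proportion to share
    variant_spec: list[tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        if primitive_period(self.ancestral_monomer) != len(self.ancestral_monomer):
            raise ValueError(f"ancestral monomer of {self.name} is not primitive")
        if self.sub_rate + self.indel_rate > 0.2:
            raise ValueError("sub_rate + indel_rate must be <= 0.2")


@dataclass
class ContigSpec:
    name: str
    length: int
    gc: float = 0.4


@dataclass
class SyntheticSpec:
    seed: int
    contigs: list[ContigSpec]
    planted: list[PlantedFamily]
    l_contigs: set[str] = field(default_factory=set)

    def validate(self) -> None:
        lengths = {c.name: c.length for c in self.contigs}
        by_contig: dict[str, list[tuple[int, int, str]]] = {}
        for fam in self.planted:
            unit = len(fam.ancestral_monomer)
            for arr in fam.arrays:
                if arr.contig not in lengths:
                    raise ValueError(f"unknown contig {arr.contig}")
                # reserve nominal span plus indel headroom
                span = int(arr.copies * unit * (1 + 2 * fam.indel_rate)) + unit
                if arr.start < 0 or arr.start + span > lengths[arr.contig]:
                    raise ValueError(f"array of {fam.name} does not fit {arr.contig}")
                by_contig.setdefault(arr.contig, []).append((arr.start, arr.start + span, fam.name))
        for ctg, ivs in by_contig.items():
            ivs.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping planted intervals on {ctg}: {n1} and {n2}")
        unknown = self.l_contigs - set(lengths)
        if unknown:
            raise ValueError(f"l_contigs not in contig list: {sorted(unknown)}")


@dataclass
class RealizedArray:
    family: str
    contig: str
    start: int
    end: int
    variant: str | None
    mean_identity: float


@dataclass
class TruthManifest:
    seed: int
    arrays: list[RealizedArray] = field(default_factory=list)
    family_bp: dict[str, dict[str, int]] = field(default_factory=dict)  # assembly -> family -> bp
    variant_shares: dict[str, dict[str, float]] = field(default_factory=dict)
    read_counts: dict[str, int] = field(default_factory=dict)

    def planted_bp(self, assembly: str, family: str) -> int:
        return self.family_bp.get(assembly, {}).get(family, 0)


def mutate_monomer(monomer: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    """One mutated copy: i.i.d. per-base substitution (uniform over the 3
    alternatives) and single-base indel (50/50 insertion/deletion)."""
    if not (0 <= sub_rate <= 0.2 and 0 <= indel_rate <= 0.2):
        raise ValueError("rates must be in [0, 0.2]")
    if sub_rate == 0 and indel_rate == 0:
        return monomer
    out = []
    for base in monomer:
        r = rng.random()
        if r < sub_rate:
            alts = [b for b in "ACGT" if b != base]
            out.append(alts[rng.integers(3)])
        elif r < sub_rate + indel_rate:
            if rng.random() < 0.5:
                out.append(chr(_BASES[rng.integers(4)]) + base)  # insertion before
            # else deletion: emit nothing
        else:
            out.append(base)
    return "".join(out)


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _assign_variants(fam: PlantedFamily) -> list[str | None]:
    """Deterministic variant label per array, proportional to shares."""
    if not fam.variant_spec:
        return [None] * len(fam.arrays)
    labels = [chr(ord("A") + i) for i in range(len(fam.variant_spec))]
    shares = np.array([s for _, s in fam.variant_spec], dtype=float)
    shares = shares / shares.sum()
    n = len(fam.arrays)
    counts = np.floor(shares * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(shares * n - counts))] += 1
    out = []
    for lab, c in zip(labels, counts):
        out.extend([lab] * c)
    return out[:n]


def generate_genome(spec: SyntheticSpec) -> tuple[dict[str, dict[str, str]], TruthManifest]:
    """Build the "germ" (all contigs) and "soma" (minus l_contigs)
    assemblies with planted, per-copy-mutated arrays.

    Returns ``({"germ": {contig: seq}, "soma": {...}}, manifest)``; the
    manifest records realized post-mutation coordinates, bp and per-copy
    identity for every planted array.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, np.ndarray] = {
        c.name: _random_background(c.length, c.gc, rng) for c in spec.contigs
    }
    manifest = TruthManifest(seed=spec.seed)
    for fam in spec.planted:
        variant_of = _assign_variants(fam)
        monomer_of = dict(fam.variant_spec or [])
        for arr, vlabel in zip(fam.arrays, variant_of):
            monomer = (
                [m for m, _ in fam.variant_spec][ord(vlabel) - ord("A")]
                if vlabel is not None
                else fam.ancestral_monomer
            )
            copies, idents = [], []
            for _ in range(arr.copies):
                c = mutate_monomer(monomer, fam.sub_rate, fam.indel_rate, rng)
                copies.append(c)
                idents.append(rotational_identity(monomer, c) if c else 0.0)
            tandem = "".join(copies)
            seq = contigs[arr.contig]
            end = arr.start + len(tandem)
            if end > len(seq):
                raise ValueError(f"realized array of {fam.name} exceeds {arr.contig}")
            seq[arr.start : end] = np.frombuffer(tandem.encode(), dtype=np.uint8)
            manifest.arrays.append(
                RealizedArray(fam.name, arr.contig, arr.start, end, vlabel, float(np.mean(idents)))
            )
        # per-assembly realized bp
        for assembly, skip in (("germ", set()), ("soma", spec.l_contigs)):
            bp = sum(
                ra.end - ra.start
                for ra in manifest.arrays
                if ra.family == fam.name and ra.contig not in skip
            )
            manifest.family_bp.setdefault(assembly, {})[fam.name] = bp
        if fam.variant_spec:
            tot = sum(ra.end - ra.start for ra in manifest.arrays if ra.family == fam.name)
            manifest.variant_shares[fam.name] = {
                lab: sum(
                    ra.end - ra.start
                    for ra in manifest.arrays
                    if ra.family == fam.name and ra.variant == lab
                )
                / tot
                for lab in {v for v in variant_of if v}
            }
    germ = {name: arr.tobytes().decode() for name, arr in contigs.items()}
    soma = {name: seq for name, seq in germ.items() if name not in spec.l_contigs}
    return {"germ": germ, "soma": soma}, manifest


def generate_reads(
    assembly: dict[str, str],
    coverage: float,
    read_len: int,
    err_rate: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
):
    """Uniform-coverage error-bearing reads from an assembly.

    Yields ``(name, seq)``; read count = round(coverage x genome bp /
    read_len), start positions uniform over eligible contigs (weighted by
    length), strands equiprobable, substitution errors i.i.d. at
    ``err_rate``.  Contigs shorter than the read length are skipped with a
    warning.
    """
    import logging

    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    eligible = {n: s for n, s in assembly.items() if len(s) >= read_len}
    for name in assembly:
        if name not in eligible:
            logging.getLogger(__name__).warning(
                "contig %s shorter than read length %d: skipped", name, read_len
            )
    if not eligible:
        return
    genome_bp = sum(len(s) for s in assembly.values())
    n_reads = round(coverage * genome_bp / read_len)
    names = sorted(eligible)
    weights = np.array([len(eligible[n]) - read_len + 1 for n in names], dtype=float)
    weights /= weights.sum()
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(n_reads):
        ctg = names[rng.choice(len(names), p=weights)]
        seq = eligible[ctg]
        pos = int(rng.integers(0, len(seq) - read_len + 1))
        read = seq[pos : pos + read_len]
        strand = "+"
        if rng.random() < 0.5:
            read = read.translate(comp)[::-1]
            strand = "-"
        if err_rate > 0:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            errs = np.flatnonzero(rng.random(read_len) < err_rate)
            for j in errs:
                cur = arr[j]
                alts = _BASES[_BASES != cur]
                arr[j] = alts[rng.integers(len(alts))]
            read = arr.tobytes().decode()
        yield f"{sample_id}_{i}_{ctg}_{pos}_{strand}", read


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    per_family: dict[str, dict]  # planted family -> {matched, identity, abundance_rel_err}


def score_recovery(
    truth: TruthManifest,
    reported: list[tuple[str, str, float]],  # (family_id, consensus, total_kb)
    assembly: str = "germ",
    match_identity: float = 0.9,
    planted_monomers: dict[str, str] | None = None,
) -> RecoveryMetrics:
    """Precision/recall of reported families against the planted truth.

    A planted family is recovered when some reported consensus matches its
    ancestral monomer at >= ``match_identity`` rotational identity; the
    best match also yields the consensus identity and the relative
    abundance error against realized planted bp.
    """
    monomers = planted_monomers or {}
    per_family: dict[str, dict] = {}
    matched_reported: set[str] = set()
    planted_names = [f for f in truth.family_bp.get(assembly, {}) if truth.planted_bp(assembly, f) > 0]
    for fam in planted_names:
        anc = monomers.get(fam)
        if anc is None:
            raise ValueError(f"no ancestral monomer supplied for {fam}")
        best = (0.0, None, 0.0)
        for rep_id, consensus, kb in reported:
            ident = rotational_identity(anc, consensus)
            if ident > best[0]:
                best = (ident, rep_id, kb)
        ident, rep_id, kb = best
        ok = ident >= match_identity and rep_id is not None
        truth_bp = truth.planted_bp(assembly, fam)
        per_family[fam] = {
            "matched": ok,
            "reported_as": rep_id if ok else None,
            "consensus_identity": ident,
            "abundance_rel_err": abs(kb * 1000 - truth_bp) / truth_bp if ok else None,
        }
        if ok:
            matched_reported.add(rep_id)
    n_planted = len(planted_names)
    recall = sum(1 for v in per_family.values() if v["matched"]) / n_planted if n_planted else 1.0
    precision = len(matched_reported) / len(reported) if reported else (1.0 if recall == 1.0 and not n_planted else 0.0)
    return RecoveryMetrics(precision=precision, recall=recall, per_family=per_family)


def random_monomer(length: int, rng: np.random.Generator, gc: float = 0.4) -> str:
    """A random primitive monomer of the requested length."""
    for _ in range(100):
        s = _random_background(length, gc, rng).tobytes().decode()
        if primitive_period(s) == length:
            return s
    raise RuntimeError("failed to draw a primitive monomer")
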