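"""Greedy identity clustering of canonical monomers into satellite families.

Mirrors cd-hit-est's incremental strategy: monomers are visited in
descending abundance (total array bp) and join the first existing family
whose representative they match at or above the identity threshold under
rotation/strand symmetry; otherwise they found a new family.  Families are
summarized by a weighted column-majority consensus, optionally split into
abundant A/B sequence variants, and named `<prefix>Sat-<unit_len>`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canon import Monomer, best_orientation, canonical_monomer, rotational_identity

DEFAULT_ID_THRESHOLD = 0.80
DEFAULT_VARIANT_THRESHOLD = 0.95
DEFAULT_MIN_VARIANT_SHARE = 0.20


@dataclass
class FamilyVariant:
    label: str
    consensus: str
    member_share: float
    diagnostic_positions: list[int] = field(default_factory=list)
    members: list[Monomer] = field(default_factory=list)


@dataclass
class SatelliteFamily:
    """A cluster of monomers with a consensus and optional A/B variants."""

    family_id: str
    members: list[Monomer]
    consensus: str
    total_bp: int
    variants: list[FamilyVariant] = field(default_factory=list)

    @property
    def unit_len(self) -> int:
        return len(self.consensus)

    @property
    def representative(self) -> Monomer:
        return self.members[0]


def _orient_members(members: list[Monomer], ref: str) -> list[str]:
    """Each member's sequence rotated/stranded into the reference frame."""
    return [best_orientation(ref, m.canonical_seq)[1] for m in members]


def _weighted_consensus(oriented: list[str], weights: list[int], ref: str) -> str:
    """Per-column weighted majority in the reference frame.

    Members are globally aligned to the reference; ties resolve to the
    earlier base in A<C<G<T.
    """
    import edlib

    from .detect import _CIGAR_RE

    order = "ACGT"
    idx = {b: i for i, b in enumerate(order)}
    counts = np.zeros((len(ref), 4), dtype=np.int64)
    for seq, w in zip(oriented, weights):
        r = edlib.align(seq, ref, mode="NW", task="path")
        qi = ri = 0
        for num, op in _CIGAR_RE.findall(r["cigar"]):
            n = int(num)
            if op in "=XM":
                for j in range(n):
                    b = seq[qi + j]
                    if b in idx:
                        counts[ri + j, idx[b]] += w
                qi += n
                ri += n
            elif op == "I":
                qi += n
            else:
                ri += n
    out = []
    for j, base in enumerate(ref):
        col = counts[j]
        out.append(order[int(np.argmax(col))] if col.sum() else base)
    return "".join(out)


def build_consensus(members: list[Monomer]) -> str:
    """Weighted majority consensus of a family, in canonical form.

    Members are oriented against the representative (first member), padded
    into its frame by global alignment, and a per-column majority weighted
    by ``weight_bp`` is taken (ties A<C<G<T).
    """
    if not members:
        raise ValueError("empty family")
    ref = members[0].canonical_seq
    if len(members) == 1:
        return ref
    oriented = _orient_members(members, ref)
    cons = _weighted_consensus(oriented, [max(1, m.weight_bp) for m in members], ref)
    return canonical_monomer(cons)


def _greedy_cluster(monomers: list[Monomer], id_threshold: float) -> list[list[Monomer]]:
    clusters: list[list[Monomer]] = []
    for mono in monomers:
        for cl in clusters:
            if rotational_identity(cl[0].canonical_seq, mono.canonical_seq) >= id_threshold:
                cl.append(mono)
                break
        else:
            clusters.append([mono])
    return clusters


def cluster_monomers(
    monomers: list[Monomer],
    id_threshold: float = DEFAULT_ID_THRESHOLD,
) -> list[SatelliteFamily]:
    """Greedy incremental clustering into satellite families.

    Monomers are processed in descending ``weight_bp`` (stable for equal
    weights); each joins the first family whose representative it matches
    at >= ``id_threshold`` rotational identity, else founds a new family.
    Families are returned sorted by total bp, descending.
    """
    if not 0.5 <= id_threshold <= 1:
        raise ValueError("id_threshold must be in [0.5, 1]")
    ordered = sorted(monomers, key=lambda m: -m.weight_bp)
    clusters = _greedy_cluster(ordered, id_threshold)
    fams = [
        SatelliteFamily(
            family_id="",
            members=cl,
            consensus=build_consensus(cl),
            total_bp=sum(m.weight_bp for m in cl),
        )
        for cl in clusters
    ]
    fams.sort(key=lambda f: (-f.total_bp, f.consensus))
    return fams


def _diagnostic_positions(consensi: list[str]) -> list[int]:
    """Columns (frame of the first variant) where the variant consensi
    disagree, via pairwise global alignment to the first."""
    import edlib

    from .detect import _CIGAR_RE

    ref = consensi[0]
    differ = np.zeros(len(ref), dtype=bool)
    for other in consensi[1:]:
        oriented = best_orientation(ref, other)[1]
        r = edlib.align(oriented, ref, mode="NW", task="path")
        qi = ri = 0
        for num, op in _CIGAR_RE.findall(r["cigar"]):
            n = int(num)
            if op in "=M":
                qi += n
                ri += n
            elif op == "X":
                differ[ri : ri + n] = True
                qi += n
                ri += n
            elif op == "I":
                differ[min(ri, len(ref) - 1)] = True
                qi += n
            else:
                differ[ri : ri + n] = True
                ri += n
    return np.flatnonzero(differ).tolist()


def split_variants(
    family: SatelliteFamily,
    variant_threshold: float = DEFAULT_VARIANT_THRESHOLD,
    min_share: float = DEFAULT_MIN_VARIANT_SHARE,
) -> list[FamilyVariant]:
    """Split a family into abundant sequence variants (A, B, ...).

    Members are sub-clustered greedily at ``variant_threshold``; variants
    are emitted only when at least two sub-clusters each hold a bp share
    >= ``min_share`` of the family total.  Otherwise the family is treated
    as homogeneous and the empty list is returned.
    """
    if len(family.members) < 2 or family.total_bp == 0:
        return []
    subs = _greedy_cluster(sorted(family.members, key=lambda m: -m.weight_bp), variant_threshold)
    shares = [sum(m.weight_bp for m in s) / family.total_bp for s in subs]
    qualifying = [(sh, s) for sh, s in zip(shares, subs) if sh >= min_share]
    if len(qualifying) < 2:
        return []
    qualifying.sort(key=lambda t: -t[0])
    consensi = [build_consensus(s) for _, s in qualifying]
    diag = _diagnostic_positions(consensi)
    out = []
    for i, ((share, sub), cons) in enumerate(zip(qualifying, consensi)):
        out.append(
            FamilyVariant(
                label=chr(ord("A") + i),
                consensus=cons,
                member_share=share,
                diagnostic_positions=diag,
                members=sub,
            )
        )
    return out


def name_family(species_prefix: str, unit_len: int, taken: set[str]) -> str:
    """Family name `<prefix>Sat-<unit_len>` with letter suffixes on
    collision ("-155", then "-155b", "-155c", ...)."""
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    base = f"{species_prefix}Sat-{unit_len}"
    if base not in taken:
        return base
    for i in range(1, 26):
        cand = f"{base}{chr(ord('a') + i)}"
        if cand not in taken:
            return cand
    raise ValueError(f"name space exhausted for {base}")


def name_families(
    families: list[SatelliteFamily],
    species_prefix: str = "Bcop",
    variant_threshold: float = DEFAULT_VARIANT_THRESHOLD,
    min_share: float = DEFAULT_MIN_VARIANT_SHARE,
) -> list[SatelliteFamily]:
    """Assign names and variant structure to clustered families, in place."""
    taken: set[str] = set()
    for fam in families:
        fam.family_id = name_family(species_prefix, fam.unit_len, taken)
        taken.add(fam.family_id)
        fam.variants = split_variants(fam, variant_threshold, min_share)
    return families
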