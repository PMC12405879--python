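"""Cross-assembly satellite family comparison.

Matches family consensi between two assemblies (e.g. the core-chromosome
assembly vs a germline assembly that retains the germline-restricted L
chromosomes) by greedy best-first bipartite matching on rotational
identity, then flags families restricted to, or strongly enriched in, one
assembly.  "Low abundance or absent" is operationalized as an abundance
floor plus an abundance-ratio rule; both thresholds are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .canon import rotational_identity
from .cluster import SatelliteFamily

DEFAULT_MATCH_THRESHOLD = 0.8
DEFAULT_MIN_KB = 200.0
DEFAULT_RATIO_MIN = 5.0


@dataclass
class FamilyMatch:
    family_a_id: str | None
    family_b_id: str | None
    identity: float
    abundance_a_kb: float
    abundance_b_kb: float
    ratio_b_over_a: float
    status: str  # shared | a_only | b_only | b_enriched | a_enriched


def _ratio(b_kb: float, a_kb: float) -> float:
    # 1 kb pseudocount keeps the ratio finite and positive
    return (b_kb + 1.0) / (a_kb + 1.0)


def match_families(
    families_a: list[SatelliteFamily],
    families_b: list[SatelliteFamily],
    abundance_a: dict[str, float] | None = None,
    abundance_b: dict[str, float] | None = None,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> list[FamilyMatch]:
    """Greedy best-first bipartite matching of family consensi.

    Pairs are taken in descending rotational identity (ties by family id
    pair), each family participates in at most one match, and leftovers
    become a_only / b_only.  Abundances (kb) fill the ratio fields; a
    missing abundance map defaults to each family's clustered total bp.
    """
    ab_a = abundance_a if abundance_a is not None else {f.family_id: f.total_bp / 1000 for f in families_a}
    ab_b = abundance_b if abundance_b is not None else {f.family_id: f.total_bp / 1000 for f in families_b}
    pairs = []
    for fa in families_a:
        for fb in families_b:
            ident = rotational_identity(fa.consensus, fb.consensus)
            if ident >= match_threshold:
                pairs.append((ident, fa.family_id, fb.family_id))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out: list[FamilyMatch] = []
    for ident, ida, idb in pairs:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        a_kb = ab_a.get(ida, 0.0)
        b_kb = ab_b.get(idb, 0.0)
        out.append(FamilyMatch(ida, idb, ident, a_kb, b_kb, _ratio(b_kb, a_kb), "shared"))
    for fa in families_a:
        if fa.family_id not in used_a:
            a_kb = ab_a.get(fa.family_id, 0.0)
            out.append(FamilyMatch(fa.family_id, None, 0.0, a_kb, 0.0, _ratio(0.0, a_kb), "a_only"))
    for fb in families_b:
        if fb.family_id not in used_b:
            b_kb = ab_b.get(fb.family_id, 0.0)
            out.append(FamilyMatch(None, fb.family_id, 0.0, 0.0, b_kb, _ratio(b_kb, 0.0), "b_only"))
    return out


def flag_restricted(
    matches: list[FamilyMatch],
    min_kb: float = DEFAULT_MIN_KB,
    ratio_min: float = DEFAULT_RATIO_MIN,
    side: str = "b",
) -> list[FamilyMatch]:
    """Families restricted to / enriched in one assembly.

    For ``side == "b"``: b_only families with abundance_b >= ``min_kb``,
    plus shared families whose b/a abundance ratio is >= ``ratio_min``
    (relabeled b_enriched).  ``side == "a"`` is the mirror operation.
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    out = []
    for m in matches:
        if side == "b":
            if m.status == "b_only" and m.abundance_b_kb >= min_kb:
                out.append(m)
            elif m.status == "shared" and m.ratio_b_over_a >= ratio_min:
                out.append(
                    FamilyMatch(
                        m.family_a_id, m.family_b_id, m.identity,
                        m.abundance_a_kb, m.abundance_b_kb, m.ratio_b_over_a,
                        "b_enriched",
                    )
                )
        else:
            if m.status == "a_only" and m.abundance_a_kb >= min_kb:
                out.append(m)
            elif m.status == "shared" and m.ratio_b_over_a > 0 and 1.0 / m.ratio_b_over_a >= ratio_min:
                out.append(
                    FamilyMatch(
                        m.family_a_id, m.family_b_id, m.identity,
                        m.abundance_a_kb, m.abundance_b_kb, m.ratio_b_over_a,
                        "a_enriched",
                    )
                )
    return out


def matches_to_rows(matches: list[FamilyMatch]) -> list[dict]:
    return [
        {
            "family_a": m.family_a_id or ".",
            "family_b": m.family_b_id or ".",
            "identity": round(m.identity, 4),
            "abundance_a_kb": round(m.abundance_a_kb, 3),
            "abundance_b_kb": round(m.abundance_b_kb, 3),
            "ratio_b_over_a": round(m.ratio_b_over_a, 4),
            "status": m.status,
        }
        for m in matches
    ]
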