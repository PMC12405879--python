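"""Per-family genomic abundance accounting and report rendering.

Array intervals are merged per family before accounting (so overlapping or
abutting calls are not double counted), totals are kept in exact bp
internally and only rounded at rendering, and the percent-of-assembly
denominator is the full assembly length including N bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .detect import TandemArray


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str = "+"

    def to_line(self) -> str:
        return f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t{self.score}\t{self.strand}"


@dataclass
class AbundanceRecord:
    family_id: str
    unit_len: int
    n_arrays: int
    array_size_min_kb: float
    array_size_max_kb: float
    total_kb: float
    pct_assembly: float
    gc_content: list[float] = field(default_factory=list)  # one per variant, else one


def gc_content(seq: str) -> float:
    """G+C fraction over informative (non-N) bases."""
    if not seq:
        raise ValueError("empty input")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    informative = gc + s.count("A") + s.count("T")
    if informative == 0:
        raise ValueError("no informative bases")
    return gc / informative


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals."""
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def arrays_to_bed(
    assignments: list[tuple[TandemArray, str]],
    contig_lengths: dict[str, int] | None = None,
) -> list[BedRecord]:
    """BED6 records for family-assigned arrays.

    One line per array (0-based half-open), name = family id, score =
    int(100 x mean identity) clamped to [0, 1000], strand "+".  Sorted by
    (contig, start).  Raises if an array exceeds its contig bounds.
    """
    recs = []
    for arr, fam in assignments:
        if contig_lengths is not None:
            clen = contig_lengths.get(arr.contig_id)
            if clen is not None and not (0 <= arr.start < arr.end <= clen):
                raise ValueError(
                    f"array {arr.contig_id}:{arr.start}-{arr.end} exceeds contig bounds"
                )
        score = min(1000, max(0, int(round(100 * arr.mean_identity))))
        recs.append(BedRecord(arr.contig_id, arr.start, arr.end, fam, score))
    recs.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
    return recs


def write_bed(records: list[BedRecord], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for r in records:
            fh.write(r.to_line() + "\n")


def read_bed(path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(BedRecord(f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return out


def family_abundance(
    assignments: list[tuple[TandemArray, str]],
    assembly_bp: int,
    unit_lens: dict[str, int] | None = None,
    gc_by_family: dict[str, list[float]] | None = None,
) -> list[AbundanceRecord]:
    """Per-family abundance from merged array intervals.

    Same-family intervals on a contig are merged before accounting; kb
    values stay exact until rendering.  Records are ordered by total kb,
    descending (ties by family id).
    """
    if assembly_bp <= 0:
        raise ValueError("assembly_bp must be positive")
    by_family: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for arr, fam in assignments:
        by_family.setdefault(fam, {}).setdefault(arr.contig_id, []).append((arr.start, arr.end))
    records = []
    for fam, by_contig in by_family.items():
        merged = [iv for ivs in by_contig.values() for iv in merge_intervals(ivs)]
        sizes = [e - s for s, e in merged]
        total = sum(sizes)
        records.append(
            AbundanceRecord(
                family_id=fam,
                unit_len=(unit_lens or {}).get(fam, 0),
                n_arrays=len(merged),
                array_size_min_kb=min(sizes) / 1000,
                array_size_max_kb=max(sizes) / 1000,
                total_kb=total / 1000,
                pct_assembly=total / assembly_bp,
                gc_content=(gc_by_family or {}).get(fam, []),
            )
        )
    records.sort(key=lambda r: (-r.total_kb, r.family_id))
    return records


def select_abundant(records: list[AbundanceRecord], min_kb: float = 200.0) -> list[AbundanceRecord]:
    """Families present at >= ``min_kb`` in the assembly (inclusive),
    order preserved."""
    if min_kb < 0:
        raise ValueError("min_kb must be >= 0")
    return [r for r in records if r.total_kb >= min_kb]


def _fmt_range(lo_kb: float, hi_kb: float) -> str:
    hi = f"{hi_kb:.0f}" if hi_kb >= 10 else f"{hi_kb:.1f}"
    return f"{lo_kb:.1f}–{hi}"


def _fmt_amount(total_kb: float, pct: float) -> str:
    return f"{round(total_kb):,}({pct * 100:.2f}%)"


def _fmt_gc(gc_values: list[float]) -> str:
    return "/".join(f"{g * 100:.2f}%" for g in gc_values)


def render_family_table(
    records: list[AbundanceRecord],
    probes: dict[str, list[tuple[str, str]]] | None = None,
) -> str:
    """TSV family report: one row per family.

    Columns: family, monomer length, array-size range ("min-max" kb, one
    decimal on the minimum), amount "kb(x.xx%)", GC per variant as
    percentages, probe sequences as "label seq" entries.
    """
    rows = []
    for r in records:
        plist = (probes or {}).get(r.family_id, [])
        rows.append(
            {
                "family": r.family_id,
                "monomer_len_bp": r.unit_len,
                "array_size_kb": _fmt_range(r.array_size_min_kb, r.array_size_max_kb),
                "amount_kb": _fmt_amount(r.total_kb, r.pct_assembly),
                "gc_content": _fmt_gc(r.gc_content),
                "probes": " ".join(f"{label} {seq}" for label, seq in plist),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["family", "monomer_len_bp", "array_size_kb", "amount_kb", "gc_content", "probes"],
    )
    return df.to_csv(sep="\t", index=False)
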