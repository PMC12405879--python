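# satdna

Satellite DNA discovery and comparison for genome assemblies and raw
reads, with FISH oligo probe design.

Satellite DNAs are long tandem arrays of a short noncoding repeat unit
(the *monomer*) and a major component of heterochromatin. In the fungus
gnat *Bradysia coprophila* they are of particular interest because the
germline-restricted **L chromosomes** — eliminated from somatic cells
during embryogenesis — carry a satellite complement distinct from the core
chromosomes, including a centromeric satellite the core chromosomes lack.
`satdna` provides a tested, reusable pipeline for this style of analysis
in any species:

* **detect** tandem repeat arrays in assembly contigs (unit 20–500 bp by
  default, ≥ 5 tandem copies, ≥ 80% identity between copies);
* **canonicalize** each array's monomer so that rotations and reverse
  complements of the same unit compare equal;
* **cluster** monomers into satellite families (cd-hit-like greedy
  clustering at 80% rotational identity), build weighted consensus
  sequences, split abundant A/B sequence variants, and name families
  `<prefix>Sat-<unit length>` (e.g. `BcopSat-145`);
* **quantify** per-family abundance (merged array bp, kb and % of
  assembly, array-size ranges, GC content) and emit BED6 plus a family
  report table;
* **profile** simple short satellites (unit ≤ 20 bp) directly in raw
  FASTQ reads by exact tandem-run counting and compare germline vs
  somatic samples after depth normalization;
* **compare** family sets between two assemblies and flag families
  restricted to, or strongly enriched in, one of them — the
  L-chromosome logic;
* **design** 30–40-mer FISH oligo probes: a conserved probe per family,
  and discriminating probe pairs for A/B variants (≥ 3 cross-variant
  mismatches by default);
* **simulate** seeded synthetic assemblies and reads with planted
  satellite landscapes and exact truth manifests, so every stage is
  testable without external data.

## Core definitions

For a monomer `s` of length `L`, the **canonical monomer** is the
lexicographically smallest string (A<C<G<T) among all rotations of `s`
and of its reverse complement; the **primitive period** is the smallest
`p` dividing `L` with `s = (s[:p])^(L/p)`. Identity between monomers `a`
and `b` is

```
rotational_identity(a, b) = max over rotations/strands of b of
                            1 − editdistance(a, b') / max(|a|, |b'|)
```

so indels count against identity. Family clustering, cross-assembly
matching, and recovery scoring all use this statistic.

## Worked example

Simulate a two-tissue genome pair — a 40 kb core contig carrying a 37 bp
satellite, plus a 25 kb L contig (germline only) carrying a 10 bp
satellite — then discover, compare, and design probes:

```bash
satdna simulate --spec spec.json --out sim/
satdna discover --assembly sim/germ.fasta --out germ/ --unit-min 5 --abundant-kb 1
satdna discover --assembly sim/soma.fasta --out soma/ --unit-min 5 --abundant-kb 1
satdna compare  --a soma/ --b germ/ --out cmp/ --min-kb 2
satdna probes   --families germ/families.fasta --out probes.tsv
```

`germ/family_table.tsv` reports both families with their unit length,
array-size range, abundance and GC:

```
family      monomer_len_bp  array_size_kb  amount_kb   gc_content
BcopSat-10  10              2.9–5.1        8(12.29%)   20.00%
BcopSat-37  37              7.4–7.4        7(11.38%)   24.32%
```

(the 37 bp family's GC of 24.32% is a property of that monomer; the 10 bp
array is split across a few detection intervals, hence the size range).
`cmp/matches.tsv` shows the cross-assembly logic: the 37 bp family is
shared at identity 1.0 and abundance ratio ~1, while the 10 bp family is
germ-assembly-only and flagged:

```
family_a    family_b    identity  abundance_a_kb  abundance_b_kb  ratio_b_over_a  status
BcopSat-37  BcopSat-37  1.0       7.397           7.397           1.0             shared
.           BcopSat-10  0.0       0.0             7.989           8.989           b_only
```

and `probes.tsv` contains a conserved 30-mer per family — for the 10 bp
unit the probe is exactly three concatenated unit copies:

```
family      variant  sequence                        start  gc
BcopSat-10  .        AAAACGTATTAAAACGTATTAAAACGTATT  0      0.2
BcopSat-37  .        TAATTTAAACGTCGAAATTCGTCATTTGGA  8      0.3
```

The same operations are available as a library (`satdna.discover`,
`satdna.match_families`, `satdna.design_variant_probes`, ...); see
`docs/methods.md` for the model and parameter choices.

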