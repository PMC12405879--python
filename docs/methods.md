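# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `satdna`. Everything stated here is computed by the test
suite or the acceptance script; nothing is an external empirical claim.

## Tandem array detection (`satdna.detect`)

Detection is a three-stage in-repo algorithm (no third-party tandem
repeat finder is wrapped, so no claim of score equivalence with any such
tool is made — the filters, not the scores, are what downstream stages
consume).

**Seeding.** Each contig is split on runs of N (assembly gaps must not
fuse arrays) and scanned for exact k-mer recurrences (k = 10 by default)
at distances within the unit-length range. Recurrence distances vote for
candidate periods; runs of positionally consistent votes (distance
agreement within max(3, 15%), gap ≤ 2 periods) become candidate regions.
In i.i.d. random sequence a 10-mer recurrence within 500 bp has
probability ~5·10⁻⁴ per position, so spurious candidates are rare and are
removed by the downstream filters.

**Refinement.** From each candidate region a unit is extracted, reduced
to its fundamental period, and extended copy-by-copy in both directions:
each step aligns the unit semi-globally (edlib, indels allowed, slack of
max(4, p/4) bp) against the next window and accepts the copy while its
identity to the running consensus is ≥ `min_identity`. After a first
pass, a per-column majority consensus is rebuilt from up to 50 observed
copies and the walk is repeated with it; the consensus pass is what makes
consensus identity ≥ 95% achievable at 5% per-copy divergence, because
column majorities cancel independent per-copy errors.

*Fundamental-period reduction.* Seeds sometimes vote for a multiple of
the true period (e.g. 2× or 19× the unit), and exact primitivity cannot
reduce a *noisy* multiple whose copies carry different mutations. The
reducer therefore treats a candidate unit as circular and, for each
candidate period p (smallest first, prescreened by a cheap circular-shift
self-similarity floor of 0.45), tests whether the unit segments into
tandem copies of p covering ≥ 90% of it at the detector's identity floor,
trying all phase offsets on the doubled string. On success the unit is
replaced by the majority consensus of its segments and reduction recurses.

**Filtering.** Arrays must satisfy `unit_min ≤ unit_len ≤ unit_max`
(default 20–500 bp, boundaries inclusive), `copies ≥ min_copies` (default
5, real-valued span/unit so partial terminal copies count), mean per-copy
identity ≥ `min_identity` (default 0.8) and an alignment score floor
(match +2, mismatch −3, gap −5; `min_array_score` = 50). Overlapping
candidates are resolved deterministically: higher score, then smaller
unit length (favoring fundamental periods), then leftmost. Coordinates
are 0-based half-open on the forward strand throughout; strand is folded
later by canonicalization. `mean_identity` is the mean of per-copy
identities against the array consensus (so a single substitution in one
of ten 10 bp copies gives 0.99).

## Monomer canonicalization (`satdna.canon`)

The canonical monomer is the lexicographic minimum (A<C<G<T) over all
rotations of the unit and of its reverse complement, computed with
Booth's least-rotation scan on both strands. This is a declared
convention — any total order over the orbit would do — chosen because it
is deterministic, idempotent and common in satellite annotation practice.

`rotational_identity(a, b)` maximizes global-alignment identity over all
rotations and strands of `b`, with identity defined as
`1 − editdistance / max(|a|, |b|)`. The denominator is the minimal
possible alignment length: optimal-alignment tracebacks are not unique,
so a matches/columns definition read off one traceback would be
ambiguous at ties, whereas the edit-distance form is exact, symmetric and
deterministic, and indels still count fully against identity. The test
suite checks it against a quadratic Wagner–Fischer oracle over all
orientations.

## Family clustering (`satdna.cluster`)

Greedy incremental clustering in the cd-hit style: monomers are visited
in descending weight (total array bp — representatives are then the
highest-confidence monomers) and join the first family whose
representative they match at ≥ `id_threshold` rotational identity, else
found a new family. `id_threshold` defaults to 0.80, the conventional
nucleotide clustering floor; on planted families with ≤ 5% divergence
this reproduces the planted family count exactly and yields observed
within-family identities above 90%.

Consensus building orients every member into the representative's frame
(best rotation/strand), aligns it globally, and takes the per-column
weighted majority (weights = array bp; ties resolve to the earlier base
in A<C<G<T); the result is returned in canonical form.

Variant splitting re-clusters members at `variant_threshold` (default
0.95) and emits variants only when ≥ 2 sub-clusters each hold ≥
`min_share` (default 0.20) of family bp, labeled A, B, ... by descending
share. Both thresholds are package choices: the biological observation
they operationalize is only that some families carry two *abundant*
variants. Diagnostic positions are the aligned columns at which the
variant consensi disagree; clustered substitutions can be explained by an
optimal alignment as an indel, so the diagnostic-column count may be
slightly below the planted substitution count.

Families are named `<prefix>Sat-<unit length>` (prefix default `Bcop`);
naming deliberately encodes unit length, not abundance rank, since
abundance is strain-variable and not always measurable. Unit-length
collisions append a lowercase letter (`-155`, `-155b`, ...), a repo
convention for a case the naming scheme itself leaves open.

## Abundance accounting (`satdna.abundance`)

Per family, array intervals are merged per contig before accounting
(overlapping or abutting calls are never double counted), kb values stay
exact until rendering, and percent-of-assembly uses the full assembly
length including N bases as the denominator (configurable). GC content is
reported per variant consensus when variants exist, excluding N from both
numerator and denominator. The abundant-family selection is a simple
inclusive threshold (default ≥ 200 kb).

## Read k-mer profiling (`satdna.readsats`)

Simple short satellites (unit ≤ 20 bp) are profiled directly in reads by
*exact* maximal tandem-run counting — the semantics of k-mer tandem
counters for simple satellites; fuzzy matching is deliberately not
attempted, since divergent long-unit satellites are the assembly
detector's job. A run qualifies if it spans ≥ `min_copies` (default 3)
units and ≥ `min_span_frac` (default 0.5) of the read; qualifying bp is
credited to the unit's canonical form, so a read and its reverse
complement produce identical profiles. Runs found at a non-primitive
period are skipped (the fundamental period's run covers them).

Tissue comparison normalizes to bp per Gb of sequenced bases (the two
tissues are sequenced separately), then flags units with germ abundance ≥
`min_total_kb` (default 10 kb/Gb) and germ/soma ratio ≥ `ratio_min`
(default 5, with a 1 bp pseudocount on the denominator); the somatic
units clearing the same abundance floor are reported alongside.

## Cross-assembly comparison (`satdna.compare`)

Family consensi from two assemblies are matched by greedy best-first
bipartite matching on rotational identity (threshold 0.8; family sets are
~10², so greedy with deterministic tie-breaks is preferred over optimal
matching). "Restricted to one assembly" is operationalized as: private
(unmatched) families above an abundance floor, plus shared families whose
abundance ratio (1 kb pseudocount) exceeds `ratio_min` — both parameters
are exposed because no principled universal cutoff exists; the library
default floor of 200 kb matches the abundant-family selection rule. The
operation is side-symmetric: swapping assemblies swaps a/b statuses.

## Probe design (`satdna.probes`)

Probes are 30–40-mers on the family consensus treated as circular
(monomer rotation is arbitrary and the hybridization target is a tandem
array, so windows may wrap; wrapped windows count re-covered columns with
multiplicity). For units shorter than the probe, windows tile whole unit
copies, so a 10 bp unit yields exactly three concatenated copies.

*Conserved family probes* minimize the worst-case mismatch count against
any member (ties: higher base-composition entropy, then leftmost, then
shortest). *Variant probes* maximize mismatches against the rotationally
aligned sister variant and must reach `min_discrimination` (default 3)
mismatches — the separation at which a printed 37 bp A/B probe pair that
differs at exactly 3 positions is known to discriminate its variants in
competitive hybridization. There is no melting-temperature model; the
composition constraints are a GC window (0.15–0.65) and a homopolymer cap
(8 nt). `probe_hit_map` provides the in-silico specificity check: all
sliding-window hits on either strand within a mismatch budget
(substitutions only).

## Synthetic data (`satdna.simulate`)

The generator emulates the targeted study design: a multi-contig
assembly with planted tandem arrays (units 10–500 bp, ≥ 5 copies,
per-copy i.i.d. substitutions and single-base indels at ≤ 20% combined
rate, optional A/B variant structure with deterministic share-based
assignment), a second assembly whose extra contigs carry private families
(the germline-restricted chromosomes), and uniform-coverage, flat-quality
reads from both tissues. Everything is driven by one numpy RNG stream per
run, so outputs are byte-identical under a fixed seed, and a truth
manifest records realized post-mutation coordinates and bp for exact
recovery scoring.

Deliberately not modeled: assembly collapse of repeats (the real reason
short-read assemblies under-recover tandem repeats), background repeat
structure (background is i.i.d.), read-quality profiles, and PCR/GC
biases. Passing tests therefore demonstrate algorithmic correctness on
clean planted signal, not performance on real assemblies.

## Test problem sizes

The heavier checks run at desk scale chosen to exercise the stated study
conditions while keeping the suite fast: recovery uses one 2 Mb assembly
with six planted families (units 20–200 bp, 5% divergence, ~40 kb each);
restricted-family flagging uses twenty seeded 200 kb core/germ assembly
pairs (5 shared families, 3 germ-private with units 10/38/39 bp, flagging
floor scaled to 3 kb for the synthetic genome size); read profiling uses
10× coverage of a 55 kb two-tissue genome with planted 3:1 short
satellites. Flagging precision/recall of 1.0 at these settings reflects
well-separated random monomers; families near the 0.8 identity boundary
would be genuinely ambiguous.
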