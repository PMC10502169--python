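# Methods

This note records the models, conventions and numerical choices behind
`grnakit`, and what the synthetic test conditions do and do not show about
real genomes.

## Coordinates

Internally every interval is 0-based half-open `[start, end)`. GFF3 and
GenBank locations (1-based inclusive) and the results CSV (1-based
inclusive) are converted at the I/O boundary; BED stays 0-based half-open.
The round trip GFF3 → internal → BED → internal is the identity and is
tested as such.

Locus identifiers are taken with the precedence `locus_tag` > `gene` >
`ID` > `protein_id` (first qualifier/attribute present). Annotation
sources rarely agree on which of these keys a record carries; this order
prefers the most stable, assembly-specific key. When a genome arrives
with both GenBank and GFF3 annotation, the GFF3 wins (GenBank→GFF
conversion is lossy for complex eukaryote gene structure) and a warning is
logged.

## Region grammar

A region spec anchors each endpoint to `feature_start` or `feature_end`
*in the feature's own 5'→3' frame* with a signed offset: negative =
upstream, positive = downstream, offset 0 = the anchor base itself, and
the resolved region is half-open. Whether an offset is inclusive or
exclusive of the anchor base is a convention genuinely open to choice; we
fixed "0 = anchor base, right-open" because it makes
`(feature_start+0 .. feature_end+0)` exactly the feature, on both strands.
On the minus strand `feature_start` is the genomic *end* and upstream
offsets grow toward larger genomic coordinates; extracted sequence is
reverse-complemented. Regions running past a contig edge are clamped (and
logged) rather than dropped — genome-scale runs routinely touch contig
ends and losing those loci silently would bias libraries.

"Coding" means the union of CDS features; a base inside *any* CDS counts
as coding regardless of which locus is being targeted (overlapping-gene
ambiguity resolved conservatively). Annotations with no CDS at all fall
back to gene features, with a warning. Requesting coding-only limiting
together with a region upstream of the feature is reported as a spec
violation, since the requested region cannot contain the feature's own
coding sequence.

## Off-target search

The mismatch model is substitution-only (Hamming distance); bulges are out
of scope. The PAM is matched with IUPAC semantics on the pattern side
only — an ambiguity code in the genome never matches, so N-runs in
assemblies cannot spawn phantom sites; windows whose spacer part contains
non-ACGT bases are excluded (counted and logged).

The index stores every PAM-adjacent window under `floor(L/k)` disjoint
PAM-proximal slices of its spacer (seed length `k >= 4`). A query at
mismatch budget *m* looks up *m*+1 slices and verifies candidates by
direct comparison; by pigeonhole a site with ≤ *m* mismatches must match
one slice exactly, so the search is exact, and configurations where
`floor(L/k) < m+1` are rejected at call time. Slices sit PAM-proximal
because that end is biologically least tolerant of mismatches, keeping
candidate lists short for near-cognate queries. Mismatch positions are
numbered 1..L from the 5' (PAM-distal) end, so PAM-proximal positions
carry high indices for scoring. An exhaustive numpy scanner
(`brute_force_scan`) is maintained as the independent reference; the two
routes are compared on randomized genomes in the test suite.

## Guide scoring and selection

*Off-target score.* Each off-target site contributes `sum(1.2**p)` over
its mismatch positions. This exponential positional weighting is the
standard CRISPR off-target heuristic for SpCas9 ranking: sites whose
mismatches crowd the PAM-proximal end are the least likely to cut, so a
candidate whose off-targets all score high is comparatively safe. The
scorer is a plain function and can be swapped.

*Folding score.* Spacer accessibility is computed on spacer+scaffold with
a Nussinov-style maximum base-pairing dynamic program (Watson–Crick plus
G:U wobble; minimum hairpin loop 3, i.e. partners at least 4 apart). The
score is the fraction of spacer bases unpaired in one maximum structure,
selected by a deterministic traceback (prefer leaving the 3'-most base
unpaired, else pair it with the smallest admissible partner) so results
are bit-reproducible. A maximum-pairing model was chosen over a
thermodynamic MFE model deliberately: it is dependency-free, exactly
testable against exhaustive structure enumeration, and monotone in the
complementarity that matters for scaffold occlusion. The scorer is an
interface; a thermodynamic back-end can replace it without touching
selection. The DP is vectorised per diagonal (O(n³) work but O(n²) numpy
calls), ~10 ms for the default 96-nt construct. The default scaffold
constant is the canonical 76-nt hybrid crRNA:tracrRNA scaffold and is
user-editable.

*Selection.* Per locus, candidates order by: fewer off-target sites →
larger off-target score → larger folding score → genomic coordinate
(full deterministic key; permuting input order cannot change output).
Candidates with a perfect-match off-target are disqualified from normal
ranking — a spacer that cuts two places is unusable for screening — but
are emitted, flagged, when fewer than `n_guides` clean candidates exist;
the locus is then recorded in the shortfall report with its clean count.
This keeps genome-scale coverage (a duplicated locus still yields
actionable, clearly-flagged guides) while honouring the safety intent of
excluding perfect off-targets.

## Portability and ANI

A guide "matches" a genome when its spacer occurs with zero mismatches
adjacent to an IUPAC-valid PAM on either strand (strand is irrelevant to
cutting); guides with ≥ 2 such sites are counted as multi-match (each
extra site is a perfect off-target in the new genome). ANI is accepted
from user metadata when available and otherwise estimated natively:
bottom-5,000 MinHash over canonical 16-mers (lexicographic minimum of
k-mer and reverse complement, splitmix64 hashing), Jaccard estimated on
the bottom-s sketch of the union, and `ANI = 1 + ln(2J/(1+J))/k`, clamped
to (0,1]; sketches sharing nothing report "below resolution". On i.i.d.
genomes with uniform substitution rate r ≤ 0.1 this recovers 1−r within
±0.01 at 1 Mb scale; it is insensitive to coverage loss (deleting 10% of
a genome moves the estimate < 0.01), as an identity measure should be.

## Synthetic data and what it shows

`simkit` generates i.i.d. genomes (default: one 50 kb contig, GC 0.5 — a
neutral, desk-scale stand-in for a small prokaryote; the end-to-end tests
use 20 kb / 10 genes so a full design completes in seconds),
non-overlapping single-exon gene+CDS annotations (0.3–1.5 kb genes,
0.1–0.4 kb intergenic, mixed strands), uniform substitution mutants and
exact site planting. The mutation ladder is *coupled*: the per-base
uniform variate and replacement base are drawn once, independently of the
rate, so the mutation set at rate r₁ < r₂ is an exact subset of the set
at r₂ under the same seed — monotonicity of transfer fractions along a
ladder is then deterministic, not merely expected.

Under this null model the matched fraction of an NGG library at
substitution rate r is Binomial with p = (1−r)²² (20 spacer bases plus
the two fixed PAM bases; the N is free), e.g. ≈ 0.32 at r = 0.05. Real
genome pairs at ANI 95% retain substantially *more* of a coding-region
library (roughly 45% in practice, rising toward ~90% above ANI 98%),
because substitutions are not uniform — coding regions are more conserved
than the genome-wide average that ANI measures. The synthetic ladder
therefore validates the machinery and the direction and shape of the
decay, not the absolute fractions seen between real relatives.

i.i.d. genomes also lack repeats, so multi-match counts on synthetic
inputs are near zero, whereas real microbial genomes show hundreds of
multi-match guides; the duplication fixtures (`plant_site`) exercise that
code path explicitly.

## Problem sizes and limitations

The shipped verification suite uses: 50 kb genomes × 100 spacers × budgets
0–4 for search equivalence; 1,000 random features for coordinate round
trips; 200 sequences ≤ 12 nt for folding-DP-vs-enumeration; a 150 kb
source genome and 1,200 non-overlapping guides for the transfer ladder
(non-overlapping sites keep the binomial error bound exact); and 1 Mb
pairs for ANI recovery. These sizes were chosen as the smallest at which
the statistical bounds above are sharp.

Known limitations: no bulge-tolerant off-target search; no machine-learned
on-target activity model; no intron-aware splicing of extracted mRNA;
folding is secondary-structure-only (no pseudoknots, no thermodynamics);
ANI estimation assumes shared k-mer content is identity-driven and will
read horizontally transferred repeats as similarity.
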