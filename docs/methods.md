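# Methods

This note documents the models, rules and numerical choices behind
`ltrkit`, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Element model and coordinates

An element is modelled in the orientation given (5' LTR first) as

```
left_flank + TSD | 5'LTR(TG..CA)  PBS  [eORFs]  polyprotein  [eORFs/arrays]  3'LTR(TG..CA) | TSD + right_flank
```

All internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive. When flanks are present, GFF3 coordinates are offset by the
left-flank length so target-site-duplication rows (which live in the
flanks) stay inside the padded sequence region. The toolkit never
reverse-complements an input element; reverse orientation is a user
concern, not a transform.

## LTR pair detection

The finder is a seeded extender, not a re-implementation of a full LTR
prediction model: exact 20-mer matches between the first and last 8 kb
define candidate diagonals; each diagonal is extended by ungapped X-drop
(match +1, mismatch −2, drop 12) and snapped to the outermost position
where **both** copies start `TG` and end `CA` (within a 24 bp window). The
surviving pair must satisfy LTR length 100–6000 bp, inter-LTR start
distance 1000–20000 bp and global-alignment similarity ≥95%; ties go to
higher similarity, then longer LTR, then leftmost start. Because the
structural constraints are enforced post hoc, pre-delimited elements are
handled identically. Borderline agreement with dedicated LTR finders
(which score PPT and termini jointly) is out of scope by design.

LTR similarity uses a fixed scoring (match +1, mismatch −1, gap open −4,
extend −1; a gap of length k costs 4+(k−1)) because only the 95% threshold,
not a scoring scheme, is prescribed by the filtering rules this package
implements; identity is identical columns over all alignment columns,
gaps included. Alignments run through Biopython's `PairwiseAligner`
(whose gap convention — open charged on the first gap residue — the test
oracles replicate).

## Domain search and architecture

Each element is translated in six frames (codons containing N become X);
stop-free segments of ≥20 aa (shorter segments are noise) are aligned
locally (BLOSUM62, gap open 10 / extend 1) against every reference protein
sharing at least one amino-acid 4-mer. Hits need score ≥80 and identity
≥25%; these are scoring choices of this package, exposed in
`PipelineConfig`, since the source workflow named tools rather than
thresholds. Hit coordinates are mapped back to forward-strand DNA
frame-aware.

Frameshift tolerance is post-hoc chaining rather than a frameshift-aware
aligner: hits to the same reference, same strand, whose DNA and reference
coordinates both progress, with a DNA gap ≤300 bp, merge into one call
(score summed, best constituent kept as reference). Partial overlap
between chained hits is expected — local alignments extend past the
frameshift — so overlap does not veto chaining, only regression does.
Overlap resolution then keeps the higher-scoring call whenever it covers
≥50% of a weaker one; this applies to all call pairs, not only different
types, because hits to several reference variants of one locus must
collapse to a single call (otherwise every element would look like it
carried duplicate domains).

Architecture validation compares the ordered subsequence of
{GAG, PROT, INT, RT, RH} calls with the two templates
(GAG‑)PROT‑INT‑RT‑RH → Ty1/copia and (GAG‑)PROT‑RT‑RH‑INT → Ty3/gypsy.
A missing GAG is recorded (`missing_GAG`) but not fatal; any other order is
`bad_order`; a repeated type is `duplicate_domain`; disagreement among the
best-hit superfamily prefixes of PROT/INT/RT/RH is `chimera` — an
operational proxy, since "signs of chimerical origin" has no published
operational definition; the flag is never silently dropped. The aRH
position is read from its core-domain neighbours with a 15 bp slop:
PROT→RT, RH→INT, or after the final INT. Chromodomains and aRH never
affect the superfamily templates; they are lineage evidence.

## PBS typing

All detectors operate on the 50 bp window immediately downstream of the 5'
LTR (the published window for exact matches; this package applies it to
all modes, a documented choice). Precedence when several rules fire is
full > half > fuzzy > self > none — the source reports categories, not a
resolution order, so the order here is the package's own, most-specific
first.

- **full_tRNA**: longest exact complementary run between the window and a
  3'-terminal tRNA suffix (must include the final base of the CCA end),
  accepted at ≥12 bp. Ties: longest, then smallest offset, then tRNA id.
- **half_tRNA**: same matcher, but the tRNA-side endpoint must fall in the
  cleavage window `anticodon_start − 3 … + 5` — an operational proxy for
  cleavage in the anticodon stem, for which no coordinates are published.
  The exactness and ≥12 bp minimum are reused from the full rule (the
  source does not say whether half-matches were held to the same bar; one
  shared threshold keeps the rule set small). Positions annotated as
  edited (inosine wobble of the Bianca-type 1/2tRNA-Ile) accept any of
  A, T, C on the element strand.
- **fuzzy_tRNA**: requires TGG starting 0–5 bp after the LTR (the revcomp
  of a CCA end starts TGG); the 18 bp from the TGG are compared by
  unit-cost edit distance (free trailing overhang on either side) against
  the revcomp of each tRNA's 3'-terminal 18 bp; accepted at ≤2 total
  differences of which ≤1 may be an indel. The 18 bp window length is this
  package's choice (the rule prescribes the edit budget, not a window) and
  is configurable.
- **self**: for offsets 0–5, the downstream stretch of 10–20 bp whose
  reverse complement occurs exactly inside the 5' LTR; longest wins.

tRNA libraries are user-supplied FASTA plus a sidecar TSV (isoacceptor,
anticodon position, edited positions); `prepare_trnas` idempotently
ensures the post-transcriptional 3' CCA. tRNA gene prediction is out of
scope. U is mapped to T at load.

## eORFs and tandem repeats

ORFs are maximal ATG-to-stop stretches (both strands, three frames each,
forward-strand coordinates, stop codon inside the interval but excluded
from the codon count — whether the published 250-codon minimum counted the
stop is unstated; this package excludes it). eORFs must not overlap the
polyprotein span (first to last domain call); retained ORFs get one of the
four labels 5'/3' × F/R relative to the polyprotein.

The tandem detector compares the sequence with itself at every period
p ≤ 200: runs of perfect agreement at least max(p, 16) long seed arrays
that extend over neighbouring runs while total agreement stays ≥80%;
overlapping arrays at different periods merge keeping the higher copy
number. Arrays qualify for eORF exclusion at ≥3 copies spanning >150 bp,
and an eORF is excluded when qualifying arrays cover ≥50% of its length
(the published rule says "present at" repeat regions without a fraction;
50% is the package's cut). The seed requirement makes the detector blind
to heavily degraded arrays; the fixtures generate clean arrays, so tests
do not certify sensitivity on decayed repeats.

eORF proteins are grouped single-linkage on pairwise local alignments
using the ungapped Karlin–Altschul E-value with standard BLOSUM62
constants (λ=0.3176, K=0.134; search space = product of lengths × number
of pairs), threshold 1e-10. The corpus-level rule removing ORFs that are
part of the polyprotein in some family members only is out of scope (it
needs multi-element family inference).

## Lineage voting and consistency

Each PROT/INT/RT/RH call votes for its best reference's lineage path,
weighted by alignment score; GAG and chromodomains are excluded (too
variable / separate evidence). The deepest maximal-weight path wins;
`vote_share` is its weight fraction, and calls with share < 0.5 are marked
low-confidence — that cutoff is a package default, not a published rule.
Superfamily disagreement among votes, or between the winner and the
architecture template, raises `chimera`.

Expectations per lineage ship as an editable TSV
(`ltrkit/data/lineage_rules.tsv`): allowed chromodomain types (CHDCR only
in CRM; CHD in chromoviruses; none elsewhere), expected aRH position
(PROT_RT ↔ TatI/TatII, after_INT ↔ TatIII, RH_INT ↔ Ogre/Retand) and the
lineage's primer repertoire (e.g. tRNA-Met for Ty1/copia full-tRNA
lineages and most chromoviruses; non-Met tRNAs for the OTA clades;
half-tRNA-Met for Osser/Bryco/Gymco-II; edited half-tRNA-Ile for Bianca;
self-priming for TAR and Tcn1). A PBS call of mode `none` never flags; a
fuzzy call is compared as its full-tRNA token. Tat subclade separation
beyond aRH position (TatI vs TatII, Ogre vs Retand) relies on reference
best-hits, not phylogeny — a documented limitation. The aromatic cage is
checked by aligning a chromodomain to the best cage-annotated CHD
reference and requiring F/Y/W at the three mapped columns; an unaligned
column is `unknown` and blocks the cage.

## Clustering and trees

Concatenation order is PROT, RT, RH, INT for every element regardless of
genomic order (any fixed order works; this one follows the conventional
listing). Cluster edges need ≥80% local-alignment identity over ≥90% of
the shorter sequence (whether published identity was local or global is
unstated; local with a coverage constraint is used and configurable);
clusters are connected components, so output is order-independent.
Representative selection is the greedy incremental scheme: members sorted
by length descending, each joins the first seed it matches at ≥0.90
identity; the cluster representative is the seed of the largest sub-group.

Observed distance is 1 − identical/comparable columns with pairwise gap
deletion. `nj_tree` is classic Saitou–Nei agglomeration (not the
variance-weighted variant; immaterial on test matrices and cross-checked
against an independent implementation in the tests): negative pair
branches are clamped to zero with the deficit moved to the sister branch,
preserving the joined pair's path length, and the tree is returned
unrooted (trifurcating root) in newick. On additive matrices path lengths
reproduce the input to 1e-9. Multiple sequence alignment and
maximum-likelihood inference are consumed, never computed.

## Synthetic fixtures: what they emulate

`synth_fixtures` generates the three inputs and ground-truth elements. The
study conditions are fixed once: a 13-lineage roster covering both
superfamilies and every structural feature class (CRM with CHDCR, Tekay
and cage-bearing Tcn1 with CHD, Tat subclades at all three aRH positions,
Bianca/Osser half-tRNA primers, TAR/Tcn1 self-priming, lineage-typical
eORFs); reference databases with intra-lineage identity 0.95 and
inter-lineage identity 0.5 within a superfamily (per-branch divergence is
solved from the pairwise target counting coincidental re-substitutions;
the two superfamilies use independent ancestors, mirroring their
non-alignability); 300 bp LTRs at 96.5–100% similarity; TSD lengths
cycling 5,4,5,6,5 (5 bp dominant, as in real surveys); domain cassettes
reverse-translated from reference proteins with **no** mutation, making
identity-100 recovery exact by construction; substitution-only mutation
everywhere so identity targets are analytic.

Each built element verifies its own manifest before release by running the
cheap detectors (TSD, LTR pair, PBS, ORF labelling with tandem filtering);
if random filler accidentally contains a competing signal — e.g. a chance
≥10 bp self-primer complement in an element generated without one — the
filler is resampled under a derived sub-seed (at most 30 attempts). The
expensive domain scan is not part of verification: cassettes are exact
reference copies and domain-type ancestor pools are independent, so
recovery is structural. Corpus generation derives per-element seeds from
the global seed and stratifies deterministically so every PBS mode and
eORF label appears.

Consequently, a green round-trip certifies the detectors against clean,
fully specified elements. It does **not** certify behaviour on real
genomic data: no indel mutations in LTRs by default, no nested insertions,
no decayed arrays, no codon-usage structure, no solo LTRs, and inter-lineage
divergence far more uniform than nature's.

## Problem sizes and numerics

The shipped test suite uses a 13-element corpus for module tests and a
200-element corpus for the end-to-end recovery checks; the acceptance
script regenerates the 200-element corpus and re-measures everything, with
alignment oracles run at 100 pairs of ≤200 residues — sizes chosen so the
whole cycle completes in minutes on one core while every lineage, PBS mode
and eORF label is exercised multiple times. Floating-point comparisons in
tests use exact equality only where the arithmetic is exact (counting),
otherwise 1e-9 for tree distances and ±1 percentage point for similarity
recovery against substitution counts.
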