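# Methods

## Data model

The unit of analysis is the *template*: one sequenced DNA fragment,
reconstructed from its alignments. BAM records (primary, mapped,
non-duplicate) are projected onto reference coordinates through their
CIGAR strings — matched bases keep their coordinate, insertions and soft
clips carry no coordinate and are excluded from all reports, deletions
and reference skips produce nothing. Mate pairs are merged base-by-base:
a position covered by one mate keeps that mate's (base, quality, call)
triple; a position covered by both keeps the triple of the mate with the
strictly higher base quality, the first mate winning ties. This retains
high-quality read-2 bases that overlap low-quality read-1 tails instead
of discarding the overlap wholesale. Internally all coordinates are
0-based half-open; every report emits 1-based positions.

Filtering follows two knobs. `min_mapq` (default 30) drops whole
alignments; `min_baseq` (default 20) masks individual bases (base → N,
call → '.') so that an untrustworthy base contributes to no numerator or
denominator while the rest of the template is kept. Orphaned mates are
processed single-end; chimeric pairs (mates on different contigs) are
skipped with a logged count.

Methylation calls use the Bismark XM alphabet (z/Z CpG, x/X CHG, h/H CHH,
u/U unknown context, upper case = methylated). When a BAM lacks call
strings, the caller derives them from a FASTA reference under the
directional protocol: the conversion strand comes from the FLAG (first
mate forward → original top, OT; first mate reverse → OB), with an
existing conversion tag (XG) taking precedence. On OT, methylation is
read at reference C (read C methylated, read T converted); on OB,
symmetrically at reference G, with the trinucleotide context taken on the
reverse complement. Contexts that overrun the reference window or touch
an N are called u/U and excluded from all averages and reports — a
deliberate, documented choice for edge positions.

## Thresholding and VEF

A template passes the read-level threshold when

1. it carries ≥ `min_context_sites` cytosines of the target context
   (default CG, 2 sites),
2. their mean methylation is ≥ `min_context_beta` (default 0.5), and
3. the mean methylation over all other definite contexts is
   ≤ `max_outofcontext_beta` (default 0.1).

Clause 3 rejects incompletely converted molecules; a template with no
out-of-context cytosines trivially satisfies it (absence of evidence of
poor conversion is not evidence of it). A template with zero in-context
sites fails clause 1 for any positive site minimum, yet still counts in
every denominator — the denominators are "all templates", per the VEF
definition.

Per position, the cytosine report accumulates C (methylated), T
(unmethylated) and Cᵃ (methylated from passing templates), giving
β = C/(C+T) and VEF = Cᵃ/(C+T); since Cᵃ ≤ C, VEF ≤ β always, with
equality exactly when every methylated observation derives from a
passing template. Stricter policies can only shrink the passing set, so
VEF and Nᵃ are monotone in each policy parameter. With thresholding
disabled the report is the conventional one (β only) and the β values
are identical to the thresholded run's.

The reported context of a position is the most frequent context among
its calls across reads (reference-free majority vote, each retained base
weighted equally); ties break CG > CHG > CHH. Positions with zero
definite observations after masking are omitted rather than emitted as
zero-coverage rows. Plus- and minus-strand cytosines of a CpG are
separate records (no destranding); a strand's record carries the
conversion strand of its templates (OT → '+', OB → '−').

Region reports count a template in N when its span intersects the
region by ≥ 1 base (independently for every region it overlaps) and in
Nᵃ when it also passes; VEF = Nᵃ/N, NA when N = 0.

## Patterns and SNV linkage

Every distinct ordered set of (position, state) elements over a queried
region is one epiallele; elements are the template's target-context
calls inside the region (clipped to it), optionally extended with
observed base symbols at requested non-cytosine positions. The
identifier is a 64-bit FNV-1a hash (offset basis 14695981039346656037,
prime 1099511628211) of the canonical serialization: elements in
ascending position order, each as decimal position, one ':' byte, one
state byte. The serialization and the 64-bit width are this package's
own convention (chosen for collision headroom), fixed and stable across
runs and input orderings, but not guaranteed to equal other tools'
identifiers. Patterns with mean beta ≥ 0.5 are summarised as
hypermethylated epialleles.

For each biallelic SNV, templates covering the site are tabulated as
(ref-bearing, alt-bearing) × (pass, fail) and tested with a two-sided
Fisher exact test. The choice of statistic is this package's own — it is
the minimal defensible test for skew on a 2×2 table; raw p-values are
emitted with no multiple-testing correction (a downstream concern).
Because conversion mimics C>T on OT templates and G>A on OB templates,
templates whose conversion strand confounds the allele pair are excluded
per template.

## The simulator

`bs_simulator` emulates directional-protocol paired-end bisulfite
sequencing on a synthetic reference with exact GC content (default 0.5,
giving ~6 CpGs per 100 bp). Per fragment: uniform placement (or uniform
within amplicon regions), uniform length in `fragment_len` (default
70–400 bp), strand OT/OB with equal probability; per molecule, each CpG
is methylated i.i.d. with probability `cg_methylation` and each non-CpG
cytosine escapes conversion with probability 1 − `ch_conversion`
(default residual 0.005). Reads (default 2×151 bp) are cut from the
fragment ends; fragments shorter than the read length yield truncated,
fully overlapping mates. Base qualities follow
Q(i) = floor + (start − floor)·exp(−i/decay) (defaults 40 → 5, decay
300 cycles); substitution errors are drawn per cycle with probabilities
proportional to the quality-implied error rate, scaled so their mean
equals `error_rate` — errors therefore concentrate towards the 3′ end,
and the exact deviation of measured non-CpG beta from its baseline at a
given error rate depends on these decay constants, so error effects are
reproduced at trend level, not to a particular decimal. Call strings are
embedded by running the package's own caller against the simulated
reference, so fixtures exercise the full calling and I/O path.

Two constructions mirror standard benchmark designs. *Duplication*: each
pair is copied with every convertible base of its strand converted
(C→T on OT, G→A on OB, any context) at identical coordinates — on fully
methylated error-free input the merged set has beta exactly 0.5 at every
covered cytosine, an exactness the tests assert literally. *Admixture*:
round(f·|background|/(1−f)) fully methylated fragments are added to a
background so the spiked proportion is f to rounding; recovery of f as
the region VEF is the sensitivity benchmark.

What the simulator does not model: indel errors, PCR duplicates,
flowcell/read-name realism, per-molecule epiallele blocks in the
*accuracy* construction (CpG states are i.i.d. there; concordant
epialleles enter through the admixture spike-ins, which are fully
methylated molecules), mappability, or cell-type composition. Passing
tests therefore demonstrate correctness of counting, thresholding and
recovery under these idealised conditions, not robustness to alignment
artifacts in real data.

## Problem sizes and numerical choices

The headline computations run at desk scale, chosen to keep the full
pipeline exact yet fast on one CPU: the duplication benchmark uses
50,000 pairs on a 100 kb reference (~150× coverage; ~12,500 CpG
positions covered), the 1% admixture 100,000 pairs over a five-amplicon
panel, and the 0.03% admixture 60,000 pairs over one 400 bp amplicon
(~45,000× coverage, matching deep amplicon assays). Amplicon simulations
use fragment lengths of 350–400 bp over 400 bp regions because amplicon
libraries sequence fixed-length inserts spanning the assayed region —
every pair then covers many CpGs, as in real promoter panels; with
free fragment lengths, rare two-CpG reads would pass the default
threshold whenever one of their two CpGs is stochastically methylated,
which is a property of sparse coverage rather than of the assay being
emulated. Admixture recovery is assessed within three binomial standard
errors of the spiked fraction.

Degenerate inputs: empty template sets produce empty (not error)
reports; regions without templates report VEF = NA; a 2×2 table with a
zero margin has Fisher p = 1; templates with no in-context sites have
undefined per-read beta (NaN) and fail any positive threshold. All
randomness flows through a single integer seed per simulation profile.
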