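# Methods

## Problem and model

Repair of a DNA double-strand break using a spliced mRNA as template copies
the transcript back into the genome and therefore deletes the intron that
contained the break, precisely at its exon boundaries. In somatic deletion
calls this predicts a rare but highly specific event class: deletions whose
breakpoints coincide with both boundaries of an annotated intron (whole-intron
deletions, WIDs), and — because a spliced template lacks *all* introns —
occasional runs of several adjacent introns deleted in the same sample.
The package implements three connected analyses: boundary-matched WID calling
with consecutive-run detection, a Monte-Carlo enrichment test against
panel-constrained random deletions, and alignment-window classification of
amplicon reads from intron-loss and cut-site editing assays.

## Coordinates and annotations

All internal coordinates are 0-based half-open; converters sit at the I/O
boundaries (GTF/GFF3 and VCF are 1-based inclusive, BED is native). Introns
are derived per transcript as the gaps between sorted exons; book-ended exons
are merged first. Intron indices follow transcript orientation (intron *i*
separates exons *i* and *i+1* of the mature transcript), so on minus-strand
genes the index increases right-to-left along the genome; each intron also
carries the transcript-numbered labels of its genomically left and right
flanking exons, matching how panel reports write minus-strand runs
("exon27 / exon26").

When an annotation provides several isoforms, one canonical transcript per
gene is used for the intron index: by default the transcript with the largest
total exonic length, overridable by an explicit transcript list. This choice
is open — annotation sources rarely state which isoform a panel's reporting
used — so it is a configurable policy, not a claim.

## WID calling

A deletion matches an intron when each boundary offset is at most the margin
(default 2 bp) in absolute value, independently per edge; there is no extra
length-equality constraint, so deletion and intron size may differ by up to
twice the margin. The margin absorbs breakpoint ambiguity introduced by
aligners around homology at the junction. The margin is applied per edge
because the two breakpoints are called independently; a total-budget variant
would couple them without a mechanistic reason.

Scanning uses an interval tree per contig, with the query widened by the
margin so boundary-offset matches at the margin are never missed. A deletion
matching several introns of one gene (isoform redundancy) yields one call at
the lowest intron index, deterministically; matches in different genes yield
one call per gene and are flagged in the summary.

Consecutive-WID clusters are maximal runs of adjacent intron indices per
(gene, sample), computed after collapsing duplicate (gene, sample, index)
hits; singletons are size-1 clusters. Adjacency is transcript-order, not
genomic, adjacency — equivalent for a single transcript, but the former is
what the spliced-template mechanism predicts.

## Monte-Carlo null

The null distribution of WID counts under "no mechanism" is estimated by
simulating cohorts that mirror the observed one:

1. a placement unit is drawn with probability equal to its share of observed
   deletion *starts* (units: capture-panel intervals in panel mode, gene
   bodies in gene mode; weighting by starts rather than midpoints or overlap
   fractions is a documented, configurable choice);
2. a start is drawn uniformly within the unit;
3. a length is drawn from the empirical length distribution of the observed
   cohort.

A draw is kept only if it satisfies the placement constraint. In panel mode
the deletion must end within its unit, or its right breakpoint must fall
inside the immediately following panel interval on the same contig — both
breakpoints must lie in captured sequence to be detectable by a capture
assay. A strict variant (right breakpoint exactly at the next interval's
start) is available behind `strict_boundary`. In gene mode the whole deletion
must stay inside the selected gene body, and the observed cohort is
pre-filtered to deletions longer than 10 bp (exclusive) before fitting, the
whole-genome convention for reliable deletion calls. Violating draws are
rejected and redrawn jointly (start and length together), capped at
`max_attempts` (default 1,000) rounds, after which an error names the
offending unit — the signal that the length distribution is incompatible with
the placement space. Rejection makes the realized length marginal deviate
slightly from the fitted one near unit ends; in a rejection-free geometry the
marginal is exact (verified by goodness-of-fit at 10^5 draws).

Each cohort's random stream is keyed by `(base_seed, cohort_index)` through
NumPy's seed-sequence mechanism, so ensembles are bit-reproducible and can be
regenerated cohort-by-cohort. Default ensemble size is 10,000 cohorts of
73,030 deletions (the scale of the targeted-panel analysis this mirrors);
the tests and examples use 200–500 cohorts of 500 deletions, which keeps the
same algorithms and changes only the ensemble resolution.

The enrichment p-value is the plain empirical tail frequency
`#{count_i ≥ observed}/N`; when no simulated cohort reaches the observed
count this is 0 and is reported alongside the label `< 1/N`. An add-one
estimator `(k+1)/(N+1)`, which cannot return zero, is available.

On a toy geometry the null has a closed form: one 100 bp unit containing one
10 bp intron with all lengths fixed at 10 gives 91 equiprobable starts of
which 5 produce a WID at margin 2, so per-cohort counts are
Binomial(M, 5/91); the simulator agrees within Monte-Carlo error.

## Amplicon read classification

Reads (assumed pre-merged to single sequences) are aligned globally with an
affine-gap Needleman–Wunsch. Scoring defaults are match +2, mismatch −1, gap
open −5, gap extend −1, with a length-L gap costing `open + (L−1)·extend`;
the upstream analysis this reproduces delegates alignment to a published
tool without printing parameters, so these are this package's own documented
defaults, all configurable. Tie-breaks are deterministic: at equal score the
traceback prefers a diagonal step over gaps, a deletion (gap in the read)
over an insertion, and gap extension over re-opening. Operation coordinates
are reported on the target: deletions span the skipped target bases;
insertions are anchored at the target position before which the extra read
bases sit.

*Intron-loss assay*: a read is assigned to whichever of the reference or
intron-deleted amplicon scores higher (ties go to the reference,
conservative against over-calling intron loss). Reads assigned to the
intron-deleted amplicon are PERFECT_LOSS unless a gap operation overlaps the
half-open window `[junction − 3, junction + 3)` (3 bp per side, 6 bp total),
which demotes to IMPERFECT_LOSS. Substitutions never demote — only
insertions and deletions are counted against the window, so substitution
sequencing error cannot deflate the perfect fraction. Percent intron loss is
`100 · perfect / (reference + perfect + imperfect)`.

*Editing assay*: the 25 bp quantification window is centered on the cut
site — 12 bp each side plus the cut position, i.e. `[cut − 12, cut + 13)`;
the exact centering is not fixed by convention, so the half-width is
configurable. A read is INDEL when a gap operation overlaps the window, and
SIGNATURE when additionally an insertion anchored exactly at the cut position
inserts exactly the signature motif. Fractions: signature / total reads, and
signature / indel-harboring reads (signature reads count in the denominator;
the indel-denominator fraction is reported as missing when no read harbors
an indel).

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their biology. Defaults (chosen once as desk-scale study conditions): 30
genes of 4–12 exons on both strands, exons 80–250 bp, introns 60–400 bp, a
capture panel of exon ± 30 bp flanks (merged when they collide), cohorts of
500 deletions containing 20 planted boundary-exact WIDs in clusters of sizes
(5, 4, 3, 2, 2, 1, 1, 1, 1) over background drawn by the same constrained
placement sampler the null model uses, with a decaying length distribution
over 1–60 bp. Amplicon read sets follow configured compositions
(10/5/5 reference/perfect/imperfect; 60/30/10 unmodified/other-indel/
signature) with substitution-only sequencing error (default 0.1%).

Two structural guarantees make recovery tests exact: background deletion
boundaries are kept at least margin+1 bp from every intron boundary, so a
false positive is impossible by construction rather than improbable; and
amplicon sequences contain no adjacent repeated bases (and no
signature-shifting flanks at the cut site), so a planted 1-bp indel has a
unique optimal alignment placement and window sweeps measure the classifier,
not gap ambiguity. An adversarial mode plants background at 3–5 bp offsets
from intron boundaries to probe the margin's decision boundary. Consequences
for interpretation: passing recovery tests demonstrates correctness of the
calling and counting machinery under the stated conditions; it says nothing
about caller behavior on real breakpoint noise, homopolymer-rich amplicons,
indel sequencing error, or annotation errors, none of which the generator
models.

## Numerical and degenerate-input choices

- Empty intron lists, empty panels and cohorts that become empty after
  filtering raise typed errors rather than returning silent zeros wherever a
  downstream fit would be undefined; filters on empty cohorts return empty
  cohorts.
- Deduplication keeps the first occurrence; two keying conventions are
  exposed (by coordinates, matching "unique deletions" reporting; by
  sample+coordinates for per-sample run detection).
- The `>10 bp` pre-filter is a strict inequality (length 10 is excluded).
- p-value estimators require at least one simulated cohort; `p(observed=0)`
  is 1 by construction.
- All randomness flows through `numpy.random.Generator` seeded from explicit
  integers; no global state.

## Known limitations

- The null is cohort-global: no per-tumor-type stratification, mutational
  signatures, or sequence-context bias.
- WID calling uses deletion calls only; read-level evidence and mechanism
  inference per event are out of scope.
- The amplicon module is not a general editing-outcome tool: no allele
  plots, no quality-aware alignment, no paired-end handling (reads are
  pre-merged), and only the two quantifications described above.
- Gene-mode placement requires whole deletions inside gene bodies; deletions
  spanning gene boundaries are treated as unplaceable rather than split.
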