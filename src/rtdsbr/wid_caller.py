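"""Whole-intron deletion (WID) calling and consecutive-run detection.

A deletion is a WID for an intron when each deletion boundary falls within a
small tolerance (default ±2 bp, accommodating alignment ambiguity at the
breakpoints) of the corresponding intron boundary — independently per edge.
Runs of adjacent WID-deleted introns of one gene in one sample are the
hallmark of repair templated by a spliced transcript, and are reported as
maximal consecutive clusters on the transcript-order intron index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotations import GenomicInterval, IntronIndex, IntronRecord
from .deletion_io import DeletionCall, DeletionCohort


@dataclass(frozen=True)
class MarginPolicy:
    """Per-boundary tolerance in bp between deletion and intron edges."""

    margin_bp: int = 2

    def __post_init__(self) -> None:
        if self.margin_bp < 0:
            raise ValueError(f"margin_bp must be >= 0, got {self.margin_bp}")


@dataclass(frozen=True)
class WIDCall:
    deletion: DeletionCall
    intron: IntronRecord
    start_offset: int  # deletion.start - intron.start
    end_offset: int  # deletion.end - intron.end

    @property
    def deletion_size(self) -> int:
        return self.deletion.length

    @property
    def intron_size(self) -> int:
        return self.intron.interval.length()


@dataclass(frozen=True)
class WIDCluster:
    """Maximal run of consecutive WID-deleted introns for one gene+sample."""

    gene_symbol: str
    sample_id: str
    intron_indices: tuple

    def __post_init__(self) -> None:
        idx = self.intron_indices
        if not idx:
            raise ValueError("empty cluster")
        if any(b != a + 1 for a, b in zip(idx, idx[1:])):
            raise ValueError(f"non-consecutive intron indices {idx}")

    @property
    def size(self) -> int:
        return len(self.intron_indices)


def match_deletion_to_intron(
    deletion: DeletionCall,
    intron: IntronRecord,
    policy: MarginPolicy = MarginPolicy(),
) -> Optional[WIDCall]:
    """Return a WIDCall iff both boundaries match within the margin."""
    if deletion.contig != intron.contig:
        return None
    so = deletion.interval.start - intron.interval.start
    eo = deletion.interval.end - intron.interval.end
    if abs(so) <= policy.margin_bp and abs(eo) <= policy.margin_bp:
        return WIDCall(deletion=deletion, intron=intron, start_offset=so, end_offset=eo)
    return None


def scan_cohort(
    cohort: DeletionCohort,
    intron_index: IntronIndex,
    policy: MarginPolicy = MarginPolicy(),
) -> list:
    """Test every deletion against every overlapping intron.

    A deletion matching several introns of one gene (isoform redundancy in
    the index) yields a single call for the lowest intron index; matches in
    different genes each yield a call. Output is sorted by contig, deletion
    start, then sample.
    """
    m = policy.margin_bp
    out = []
    for deletion in cohort:
        # widen the query so boundary-offset matches at the margin are found
        q = GenomicInterval(
            deletion.contig,
            max(0, deletion.interval.start - m),
            deletion.interval.end + m,
        )
        per_gene: dict = {}
        for intron in intron_index.query(deletion.contig, q):
            call = match_deletion_to_intron(deletion, intron, policy)
            if call is None:
                continue
            prev = per_gene.get(intron.gene_symbol)
            if prev is None or call.intron.intron_index < prev.intron.intron_index:
                per_gene[intron.gene_symbol] = call
        out.extend(per_gene.values())
    out.sort(
        key=lambda c: (
            c.deletion.contig,
            c.deletion.interval.start,
            c.deletion.sample_id,
            c.intron.gene_symbol,
        )
    )
    return out


def find_consecutive_clusters(wids: Sequence[WIDCall]) -> list:
    """Maximal runs of consecutive intron indices per (gene, sample).

    Duplicate (gene, sample, intron_index) hits are collapsed before run
    detection; singleton WIDs are clusters of size 1.
    """
    by_pair: dict = {}
    for w in wids:
        by_pair.setdefault((w.intron.gene_symbol, w.deletion.sample_id), set()).add(
            w.intron.intron_index
        )
    clusters = []
    for (gene, sample), indices in by_pair.items():
        run: list = []
        for idx in sorted(indices):
            if run and idx == run[-1] + 1:
                run.append(idx)
            else:
                if run:
                    clusters.append(WIDCluster(gene, sample, tuple(run)))
                run = [idx]
        if run:
            clusters.append(WIDCluster(gene, sample, tuple(run)))
    clusters.sort(key=lambda c: (c.gene_symbol, c.intron_indices[0], c.sample_id))
    return clusters


@dataclass
class WIDSummary:
    total_wids: int
    unique_wids_by_coords: int
    cluster_size_histogram: dict  # size -> number of clusters
    per_gene_counts: dict  # gene -> WID count (distinct gene,sample,intron)
    multi_gene_deletions: int  # deletions yielding calls in >1 gene

    def to_dict(self) -> dict:
        return {
            "total_wids": self.total_wids,
            "unique_wids_by_coords": self.unique_wids_by_coords,
            "cluster_size_histogram": {str(k): v for k, v in sorted(self.cluster_size_histogram.items())},
            "per_gene_counts": dict(sorted(self.per_gene_counts.items())),
            "multi_gene_deletions": self.multi_gene_deletions,
        }


def summarize_wids(wids: Sequence[WIDCall], clusters: Sequence[WIDCluster]) -> WIDSummary:
    coords = {(w.deletion.contig, w.deletion.interval.start, w.deletion.interval.end) for w in wids}
    hist: dict = {}
    for c in clusters:
        hist[c.size] = hist.get(c.size, 0) + 1
    per_gene: dict = {}
    triples = set()
    for w in wids:
        t = (w.intron.gene_symbol, w.deletion.sample_id, w.intron.intron_index)
        if t not in triples:
            triples.add(t)
            per_gene[w.intron.gene_symbol] = per_gene.get(w.intron.gene_symbol, 0) + 1
    del_genes: dict = {}
    for w in wids:
        k = (w.deletion.sample_id, w.deletion.contig, w.deletion.interval.start, w.deletion.interval.end)
        del_genes.setdefault(k, set()).add(w.intron.gene_symbol)
    multi = sum(1 for genes in del_genes.values() if len(genes) > 1)
    return WIDSummary(
        total_wids=len(wids),
        unique_wids_by_coords=len(coords),
        cluster_size_histogram=hist,
        per_gene_counts=per_gene,
        multi_gene_deletions=multi,
    )


def write_wid_table(wids: Sequence[WIDCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("# WID calls; coordinates 0-based half-open\n")
        fh.write(
            "sample\tgene\ttranscript\tcontig\tdel_start\tdel_end\tintron_index\t"
            "left_exon\tright_exon\tstart_offset\tend_offset\tdeletion_size\tintron_size\n"
        )
        for w in wids:
            fh.write(
                f"{w.deletion.sample_id}\t{w.intron.gene_symbol}\t{w.intron.transcript_id}\t"
                f"{w.deletion.contig}\t{w.deletion.interval.start}\t{w.deletion.interval.end}\t"
                f"{w.intron.intron_index}\t{w.intron.left_exon_label}\t{w.intron.right_exon_label}\t"
                f"{w.start_offset}\t{w.end_offset}\t{w.deletion_size}\t{w.intron_size}\n"
            )


def write_cluster_table(clusters: Sequence[WIDCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsample\tfirst_intron_index\tlast_intron_index\tsize\n")
        for c in clusters:
            fh.write(
                f"{c.gene_symbol}\t{c.sample_id}\t{c.intron_indices[0]}\t"
                f"{c.intron_indices[-1]}\t{c.size}\n"
            )
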