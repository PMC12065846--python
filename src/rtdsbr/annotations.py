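"""Gene annotations, intron derivation and capture-panel intervals.

All coordinates inside the package are 0-based half-open. Converters sit at
every I/O boundary: GTF/GFF3 (1-based inclusive) and BED (native 0-based
half-open) are translated on read and write.

Introns are indexed in *transcript* orientation: intron ``i`` lies between
exon ``i`` and exon ``i+1`` of the mature transcript, so on minus-strand
genes the intron index increases as the genomic coordinate decreases. Exon
labels attached to each intron are the transcript-numbered labels of the
genomically left and right flanking exons, which is how targeted-panel WID
reports are conventionally written (e.g. "exon27 / exon26" on a minus-strand
gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(
                f"negative coordinate in interval {self.contig}:{self.start}-{self.end}"
            )
        if not self.start < self.end:
            raise AnnotationError(
                f"empty or inverted interval {self.contig}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript as an ordered set of exons in genomic order."""

    gene_symbol: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple  # tuple[GenomicInterval, ...] sorted by start

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if len(self.exons) < 1:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        for ex in self.exons:
            if ex.contig != self.contig:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon on {ex.contig}, transcript on {self.contig}"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping or unsorted exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self) -> GenomicInterval:
        """Gene-body interval from first exon start to last exon end."""
        return GenomicInterval(self.contig, self.exons[0].start, self.exons[-1].end)


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a transcript with transcript-order bookkeeping.

    ``intron_index`` is 1-based in the 5'→3' direction of the transcript;
    ``left_exon_label``/``right_exon_label`` are the transcript exon numbers
    of the genomically left / right flanking exons.
    """

    gene_symbol: str
    transcript_id: str
    contig: str
    interval: GenomicInterval
    intron_index: int
    left_exon_label: int
    right_exon_label: int


@dataclass(frozen=True)
class PanelInterval:
    """One captured region of a targeted sequencing panel."""

    interval: GenomicInterval
    interval_id: str


# ---------------------------------------------------------------------------
# transcript loading


def _merge_bookended(exons: list) -> list:
    """Merge exons that directly abut (end == next start)."""
    merged = [exons[0]]
    for ex in exons[1:]:
        prev = merged[-1]
        if ex.start == prev.end:
            merged[-1] = GenomicInterval(prev.contig, prev.start, ex.end)
        else:
            merged.append(ex)
    return merged


def load_transcripts(annotation_source) -> list:
    """Load transcript models from a GTF/GFF3 file or a tabular exon table.

    GTF/GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Book-ended exons are merged; overlapping
    exons within a transcript raise :class:`AnnotationError`.

    The tabular fallback is a TSV with header columns
    ``gene transcript contig strand exon_start exon_end`` already in 0-based
    half-open coordinates.
    """
    path = Path(annotation_source)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return _load_transcripts_gff(path)
    return _load_transcripts_table(path)


def _load_transcripts_gff(path: Path) -> list:
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a zoo of exception types
        raise AnnotationError(f"cannot parse annotation file {path}: {exc}") from exc

    by_transcript: dict = {}
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: exon feature at {feat.seqid}:{feat.start} lacks transcript_id"
            ) from exc
        gene = (
            feat.attributes.get("gene_name", [None])[0]
            or feat.attributes.get("gene_id", [tid])[0]
        )
        # GTF 1-based inclusive -> 0-based half-open
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        rec = by_transcript.setdefault(
            tid, {"gene": gene, "strand": feat.strand, "exons": []}
        )
        rec["exons"].append(iv)

    models = []
    for tid, rec in by_transcript.items():
        exons = sorted(rec["exons"], key=lambda iv: iv.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {tid}: overlapping exons {a.start}-{a.end} / {b.start}-{b.end}"
                )
        exons = _merge_bookended(exons)
        models.append(
            TranscriptModel(
                gene_symbol=rec["gene"],
                transcript_id=tid,
                contig=exons[0].contig,
                strand=rec["strand"] if rec["strand"] in {"+", "-"} else "+",
                exons=tuple(exons),
            )
        )
    models.sort(key=lambda m: (m.contig, m.exons[0].start, m.transcript_id))
    return models


def _load_transcripts_table(path: Path) -> list:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise AnnotationError(f"cannot parse exon table {path}: {exc}") from exc
    required = {"gene", "transcript", "contig", "strand", "exon_start", "exon_end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")

    models = []
    for tid, grp in df.groupby("transcript", sort=False):
        exons = sorted(
            (
                GenomicInterval(str(r.contig), int(r.exon_start), int(r.exon_end))
                for r in grp.itertuples()
            ),
            key=lambda iv: iv.start,
        )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(f"transcript {tid}: overlapping exons")
        exons = _merge_bookended(exons)
        models.append(
            TranscriptModel(
                gene_symbol=str(grp["gene"].iloc[0]),
                transcript_id=str(tid),
                contig=exons[0].contig,
                strand=str(grp["strand"].iloc[0]),
                exons=tuple(exons),
            )
        )
    models.sort(key=lambda m: (m.contig, m.exons[0].start, m.transcript_id))
    return models


def select_canonical(
    models: Sequence[TranscriptModel],
    preferred: Optional[Iterable[str]] = None,
) -> list:
    """Pick one transcript per gene.

    ``preferred`` is an optional explicit list of transcript ids; otherwise
    the transcript with the largest total exonic length wins (ties broken by
    transcript id for determinism).
    """
    preferred = set(preferred or ())
    by_gene: dict = {}
    for m in models:
        by_gene.setdefault(m.gene_symbol, []).append(m)
    out = []
    for gene, cands in by_gene.items():
        chosen = [m for m in cands if m.transcript_id in preferred]
        pool = chosen or cands
        pool = sorted(
            pool,
            key=lambda m: (-sum(e.length() for e in m.exons), m.transcript_id),
        )
        out.append(pool[0])
    out.sort(key=lambda m: (m.contig, m.exons[0].start, m.transcript_id))
    return out


# ---------------------------------------------------------------------------
# intron derivation


def derive_introns(model: TranscriptModel) -> list:
    """Derive introns with transcript-order indices from one transcript.

    A single-exon transcript yields an empty list. For a transcript with n
    exons there are n-1 introns; on the minus strand, transcript exon 1 is
    the genomically rightmost exon, so intron indices run right-to-left.
    """
    n = model.n_exons
    introns = []
    for i in range(n - 1):  # i = genomic index of the left flanking exon
        left_ex, right_ex = model.exons[i], model.exons[i + 1]
        if left_ex.end == right_ex.start:
            continue  # book-ended exons leave no intron
        iv = GenomicInterval(model.contig, left_ex.end, right_ex.start)
        if model.strand == "+":
            idx = i + 1
            left_label, right_label = i + 1, i + 2
        else:
            idx = n - i - 1
            left_label, right_label = n - i, n - i - 1
        introns.append(
            IntronRecord(
                gene_symbol=model.gene_symbol,
                transcript_id=model.transcript_id,
                contig=model.contig,
                interval=iv,
                intron_index=idx,
                left_exon_label=left_label,
                right_exon_label=right_label,
            )
        )
    return introns


class IntronIndex:
    """Contig-keyed interval index over :class:`IntronRecord` objects."""

    def __init__(self, introns: Iterable[IntronRecord] = ()):
        self._trees: dict = {}
        self._n = 0
        for rec in introns:
            self.add(rec)

    def add(self, rec: IntronRecord) -> None:
        tree = self._trees.setdefault(rec.contig, IntervalTree())
        tree[rec.interval.start : rec.interval.end] = rec
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, contig: str, interval: GenomicInterval) -> list:
        """All introns overlapping ``interval``, in deterministic order."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        hits.sort(key=lambda r: (r.interval.start, r.interval.end, r.transcript_id, r.intron_index))
        return hits


def build_intron_index(introns: Iterable[IntronRecord]) -> IntronIndex:
    return IntronIndex(introns)


# ---------------------------------------------------------------------------
# panel intervals (BED)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list:
    """Merge overlapping or book-ended intervals per contig; sorted output."""
    by_contig: dict = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_start, cur_end))
    return out


def load_panel(bed_path) -> list:
    """Load capture-panel intervals from a BED3+ file.

    Overlapping input intervals are merged; stable ``interval_id`` values are
    assigned in (contig, start) order.
    """
    raw = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise AnnotationError(f"{bed_path}:{lineno}: negative coordinate {start}")
            if end <= start:
                raise AnnotationError(f"{bed_path}:{lineno}: end {end} <= start {start}")
            raw.append(GenomicInterval(contig, start, end))
    merged = merge_intervals(raw)
    return [
        PanelInterval(interval=iv, interval_id=f"panel_{i:06d}")
        for i, iv in enumerate(merged, start=1)
    ]


def write_panel_bed(panel: Sequence[PanelInterval], path) -> None:
    with open(path, "w") as fh:
        for p in panel:
            fh.write(f"{p.interval.contig}\t{p.interval.start}\t{p.interval.end}\t{p.interval_id}\n")


def write_introns_bed(introns: Sequence[IntronRecord], path) -> None:
    """Export introns as BED4 (name = gene|transcript|intron_index)."""
    recs = sorted(introns, key=lambda r: (r.contig, r.interval.start, r.transcript_id, r.intron_index))
    with open(path, "w") as fh:
        for r in recs:
            name = f"{r.gene_symbol}|{r.transcript_id}|{r.intron_index}"
            fh.write(f"{r.contig}\t{r.interval.start}\t{r.interval.end}\t{name}\n")


def read_intervals_bed(path) -> list:
    """Read plain BED intervals back (for round-trip checks and exports)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out
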