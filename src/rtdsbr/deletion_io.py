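"""Reading, normalizing and filtering somatic deletion calls.

Sources are VCF (sequence-resolved indels) or MAF-like tabular exports. All
calls are normalized to the internal 0-based half-open convention on read;
the interval holds exactly the deleted bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd
import pysam

from .annotations import GenomicInterval

logger = logging.getLogger(__name__)


class DeletionIOError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionCall:
    """One somatic deletion event; ``interval`` spans the deleted bases."""

    sample_id: str
    contig: str
    interval: GenomicInterval
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise DeletionIOError("deletion call with empty sample_id")
        if self.contig != self.interval.contig:
            raise DeletionIOError(
                f"contig mismatch: {self.contig} vs interval on {self.interval.contig}"
            )

    @property
    def length(self) -> int:
        return self.interval.length()


@dataclass
class DeletionCohort:
    calls: list
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def lengths(self) -> list:
        return [c.length for c in self.calls]


# ---------------------------------------------------------------------------
# readers


def read_deletions_vcf(vcf_path, sample_id: Optional[str] = None) -> DeletionCohort:
    """Read sequence-resolved deletions from a VCF.

    A record contributes one call per deletion ALT (multi-allelic records are
    split). The deleted interval follows the left-anchored VCF convention:
    with 1-based POS and ALT a prefix of REF, the deleted bases occupy
    ``(POS - 1 + len(ALT), POS - 1 + len(REF))`` in 0-based half-open
    coordinates. Symbolic ALTs without sequence are skipped with a warning;
    insertions and SNVs are ignored.
    """
    calls = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        default_sample = sample_id or (
            list(vf.header.samples)[0] if len(vf.header.samples) == 1 else "unknown"
        )
        for rec in vf:
            ref = rec.ref or ""
            for alt in rec.alts or ():
                if alt is None:
                    continue
                if alt.startswith("<"):
                    logger.warning(
                        "skipping symbolic ALT %s at %s:%d", alt, rec.chrom, rec.pos
                    )
                    continue
                if len(alt) >= len(ref):
                    continue  # SNV or insertion
                if not ref.startswith(alt):
                    logger.warning(
                        "skipping non-left-anchored deletion at %s:%d (%s>%s)",
                        rec.chrom, rec.pos, ref, alt,
                    )
                    continue
                pos0 = rec.pos - 1
                iv = GenomicInterval(rec.chrom, pos0 + len(alt), pos0 + len(ref))
                calls.append(
                    DeletionCall(
                        sample_id=default_sample,
                        contig=rec.chrom,
                        interval=iv,
                        source_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    )
                )
    return DeletionCohort(calls=calls, provenance=f"vcf:{vcf_path}")


@dataclass(frozen=True)
class TableDialect:
    """Column map + coordinate convention for tabular deletion files."""

    sample: str = "sample"
    contig: str = "contig"
    start: str = "start"
    end: str = "end"
    one_based_inclusive: bool = False


def read_deletions_table(tsv_path, dialect: TableDialect = TableDialect()) -> DeletionCohort:
    """Read deletion calls from a TSV with a declared coordinate convention.

    1-based inclusive rows (``one_based_inclusive=True``) are shifted to the
    internal 0-based half-open convention (start-1, end).
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    for col in (dialect.sample, dialect.contig, dialect.start, dialect.end):
        if col not in df.columns:
            raise DeletionIOError(f"{tsv_path}: missing column {col!r}")
    calls = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        start, end = int(d[dialect.start]), int(d[dialect.end])
        if dialect.one_based_inclusive:
            start -= 1
        if end <= start:
            raise DeletionIOError(f"{tsv_path}: row {rownum}: end {end} <= start {start}")
        calls.append(
            DeletionCall(
                sample_id=str(d[dialect.sample]),
                contig=str(d[dialect.contig]),
                interval=GenomicInterval(str(d[dialect.contig]), start, end),
                source_id=str(d.get("source_id", "") or ""),
            )
        )
    return DeletionCohort(calls=calls, provenance=f"table:{tsv_path}")


def write_deletions_table(cohort: DeletionCohort, path) -> None:
    """Write a cohort as TSV, 0-based half-open (documented in the header)."""
    with open(path, "w") as fh:
        fh.write("# deletion calls; coordinates 0-based half-open; interval = deleted bases\n")
        fh.write("sample\tcontig\tstart\tend\tlength\tsource_id\n")
        for c in cohort:
            fh.write(
                f"{c.sample_id}\t{c.contig}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.length}\t{c.source_id}\n"
            )


# ---------------------------------------------------------------------------
# filters


def filter_min_length(cohort: DeletionCohort, min_len_exclusive: int) -> DeletionCohort:
    """Keep calls strictly longer than ``min_len_exclusive`` bp.

    The whole-genome (PCAWG-style) pre-filter retains deletions longer than
    10 bp; the threshold is exclusive.
    """
    if min_len_exclusive < 0:
        raise DeletionIOError(f"negative length threshold {min_len_exclusive}")
    kept = [c for c in cohort if c.length > min_len_exclusive]
    removed = len(cohort) - len(kept)
    if removed:
        logger.info("filter_min_length(>%d): removed %d of %d calls",
                    min_len_exclusive, removed, len(cohort))
    return DeletionCohort(calls=kept, provenance=cohort.provenance)


def deduplicate_events(cohort: DeletionCohort, key: str = "coords") -> DeletionCohort:
    """Collapse duplicate events, keeping the first occurrence.

    ``key='coords'`` counts a recurrent deletion once across samples (the
    "unique deletions" convention); ``key='sample+coords'`` keeps one per
    sample for per-sample analyses such as consecutive-run detection.
    """
    if key not in {"coords", "sample+coords"}:
        raise DeletionIOError(f"unknown deduplication key {key!r}")
    seen = set()
    kept = []
    for c in cohort:
        k = (c.contig, c.interval.start, c.interval.end)
        if key == "sample+coords":
            k = (c.sample_id,) + k
        if k not in seen:
            seen.add(k)
            kept.append(c)
    return DeletionCohort(calls=kept, provenance=cohort.provenance)
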