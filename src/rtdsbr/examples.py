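"""Curated worked-example datasets.

``CONSECUTIVE_WID_CASES`` transcribes a published table of consecutive
whole-intron deletion events observed in a targeted tumor-sequencing cohort:
for each case (patient), the gene, the flanking exon labels of each deleted
intron (genomic left/right order, transcript-numbered), the observed
deletion size, the annotated intron size, and the reported total number of
consecutive WIDs in the run. Descending exon labels indicate minus-strand
genes. ``build_consecutive_wid_example`` turns those printed sizes into toy
gene models plus one boundary-exact deletion per row, so the caller and the
run detector can be checked against the printed run totals.

The HLA-B example reproduces a single validated event: a 245 bp deletion
mapping precisely to the intron between exons 2 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .annotations import GenomicInterval, TranscriptModel, derive_introns
from .deletion_io import DeletionCall, DeletionCohort


@dataclass(frozen=True)
class WIDTableRow:
    case_id: str
    gene: str
    left_exon: int
    right_exon: int
    deletion_size: int
    intron_size: int
    run_total: int  # printed "total no of consecutive WIDs" for the run


# (case, gene, left exon, right exon, deletion bp, intron bp, run total)
_ROWS = [
    ("IMPACT_WID_45", "DICER1", 27, 26, 370, 370, 2),
    ("IMPACT_WID_45", "DICER1", 26, 25, 93, 93, 2),
    ("IMPACT_WID_42", "SF3B1", 20, 19, 85, 85, 2),
    ("IMPACT_WID_42", "SF3B1", 19, 18, 280, 280, 2),
    ("IMPACT_WID_42", "SF3B1", 17, 16, 216, 216, 2),
    ("IMPACT_WID_42", "SF3B1", 16, 15, 96, 96, 2),
    ("IMPACT_WID_26", "XPO1", 23, 22, 417, 417, 2),
    ("IMPACT_WID_26", "XPO1", 22, 21, 845, 845, 2),
    ("IMPACT_WID_36", "PIK3CA", 18, 19, 561, 561, 2),
    ("IMPACT_WID_36", "PIK3CA", 19, 20, 103, 103, 2),
    ("IMPACT_WID_32", "JAK1", 25, 24, 738, 738, 2),
    ("IMPACT_WID_32", "JAK1", 24, 23, 591, 591, 2),
    ("IMPACT_WID_32", "JAK1", 22, 21, 360, 360, 2),
    ("IMPACT_WID_32", "JAK1", 21, 20, 1013, 1013, 2),
    ("IMPACT_WID_05", "ERRFI1", 4, 3, 911, 911, 2),
    ("IMPACT_WID_05", "ERRFI1", 3, 2, 110, 110, 2),
    ("IMPACT_WID_11", "CSDE1", 13, 12, 877, 877, 2),
    ("IMPACT_WID_11", "CSDE1", 12, 11, 596, 596, 2),
    ("IMPACT_WID_21", "DAXX", 7, 6, 194, 194, 2),
    ("IMPACT_WID_21", "DAXX", 6, 5, 160, 160, 2),
    ("IMPACT_WID_20", "CSDE1", 13, 12, 877, 877, 2),
    ("IMPACT_WID_20", "CSDE1", 12, 11, 596, 596, 2),
    ("IMPACT_WID_12", "GNAS", 11, 12, 252, 252, 2),
    ("IMPACT_WID_12", "GNAS", 12, 13, 281, 281, 2),
    ("IMPACT_WID_04", "CDK8", 10, 11, 718, 718, 2),
    ("IMPACT_WID_04", "CDK8", 11, 12, 118, 118, 2),
    ("IMPACT_WID_34", "GNAS", 10, 11, 146, 146, 3),
    ("IMPACT_WID_34", "GNAS", 11, 12, 252, 252, 3),
    ("IMPACT_WID_34", "GNAS", 12, 13, 281, 281, 3),
    ("IMPACT_WID_29", "GNAS", 10, 11, 146, 146, 3),
    ("IMPACT_WID_29", "GNAS", 11, 12, 252, 252, 3),
    ("IMPACT_WID_29", "GNAS", 12, 13, 281, 281, 3),
    ("IMPACT_WID_22", "GNAS", 10, 11, 146, 146, 3),
    ("IMPACT_WID_22", "GNAS", 11, 12, 252, 252, 3),
    ("IMPACT_WID_22", "GNAS", 12, 13, 281, 281, 3),
    ("IMPACT_WID_09", "GNAS", 10, 11, 146, 146, 3),
    ("IMPACT_WID_09", "GNAS", 11, 12, 252, 252, 3),
    ("IMPACT_WID_09", "GNAS", 12, 13, 281, 281, 3),
    ("IMPACT_WID_26", "XPO1", 16, 15, 126, 126, 4),
    ("IMPACT_WID_26", "XPO1", 15, 14, 85, 85, 4),
    ("IMPACT_WID_26", "XPO1", 14, 13, 166, 166, 4),
    ("IMPACT_WID_26", "XPO1", 13, 12, 840, 840, 4),
    ("IMPACT_WID_19", "GNAS", 8, 9, 97, 97, 5),
    ("IMPACT_WID_19", "GNAS", 9, 10, 104, 104, 5),
    ("IMPACT_WID_19", "GNAS", 10, 11, 146, 146, 5),
    ("IMPACT_WID_19", "GNAS", 11, 12, 252, 252, 5),
    ("IMPACT_WID_19", "GNAS", 12, 13, 281, 281, 5),
    ("IMPACT_WID_35", "GNAS", 8, 9, 97, 97, 5),
    ("IMPACT_WID_35", "GNAS", 9, 10, 104, 104, 5),
    ("IMPACT_WID_35", "GNAS", 10, 11, 146, 146, 5),
    ("IMPACT_WID_35", "GNAS", 11, 12, 252, 252, 5),
    ("IMPACT_WID_35", "GNAS", 12, 13, 281, 281, 5),
]

CONSECUTIVE_WID_CASES: List[WIDTableRow] = [WIDTableRow(*r) for r in _ROWS]

_DEFAULT_EXON_LEN = 150
_DEFAULT_INTRON_LEN = 1500  # placeholder size for introns the table does not print


def _gene_geometry() -> Dict[str, dict]:
    """Per gene: strand, exon count and the printed intron sizes by index."""
    genes: Dict[str, dict] = {}
    for row in CONSECUTIVE_WID_CASES:
        strand = "+" if row.right_exon > row.left_exon else "-"
        idx = min(row.left_exon, row.right_exon)  # transcript-order intron index
        g = genes.setdefault(row.gene, {"strand": strand, "max_exon": 0, "sizes": {}})
        if g["strand"] != strand:
            raise ValueError(f"inconsistent strand inference for {row.gene}")
        g["max_exon"] = max(g["max_exon"], row.left_exon, row.right_exon)
        prev = g["sizes"].get(idx)
        if prev is not None and prev != row.intron_size:
            raise ValueError(f"conflicting intron sizes for {row.gene} intron {idx}")
        g["sizes"][idx] = row.intron_size
    return genes


def build_consecutive_wid_models() -> List[TranscriptModel]:
    """Toy transcript models realizing the printed intron sizes.

    Each gene lives on its own contig. Intron ``i`` (transcript order) gets
    the printed size where the table gives one, a large placeholder size
    otherwise, so no placeholder intron can collide with a printed deletion.
    """
    models = []
    for gene, geo in sorted(_gene_geometry().items()):
        n = geo["max_exon"]
        # exon sizes in genomic order; intron sizes between genomic exons i, i+1
        intron_sizes = []
        for gpos in range(n - 1):
            t_idx = gpos + 1 if geo["strand"] == "+" else n - gpos - 1
            intron_sizes.append(geo["sizes"].get(t_idx, _DEFAULT_INTRON_LEN))
        cursor = 1000
        exons = []
        for gpos in range(n):
            exons.append(GenomicInterval(f"chr_{gene}", cursor, cursor + _DEFAULT_EXON_LEN))
            cursor += _DEFAULT_EXON_LEN
            if gpos < n - 1:
                cursor += intron_sizes[gpos]
        models.append(
            TranscriptModel(
                gene_symbol=gene,
                transcript_id=f"{gene}_toy",
                contig=f"chr_{gene}",
                strand=geo["strand"],
                exons=tuple(exons),
            )
        )
    return models


def build_consecutive_wid_example() -> Tuple[List[TranscriptModel], DeletionCohort]:
    """Gene models plus one exact deletion per table row (sample = case id)."""
    models = build_consecutive_wid_models()
    intron_by_key = {}
    for m in models:
        for rec in derive_introns(m):
            intron_by_key[(rec.gene_symbol, rec.intron_index)] = rec
    calls = []
    for row in CONSECUTIVE_WID_CASES:
        idx = min(row.left_exon, row.right_exon)
        rec = intron_by_key[(row.gene, idx)]
        if rec.interval.length() != row.intron_size:
            raise AssertionError(
                f"{row.gene} intron {idx}: built size {rec.interval.length()} "
                f"!= printed {row.intron_size}"
            )
        calls.append(
            DeletionCall(
                sample_id=row.case_id,
                contig=rec.contig,
                interval=rec.interval,
            )
        )
    return models, DeletionCohort(calls=calls, provenance="worked-example:consecutive-WIDs")


def expected_run_sizes() -> Dict[Tuple[str, str], List[int]]:
    """Printed consecutive-run sizes per (gene, case), sorted ascending."""
    # rows of one run share (gene, case, run_total); a (gene, case) pair can
    # hold several runs of the same size (e.g. two separate pairs), so count
    # rows per (gene, case, run_total) and divide by the run size
    runs: Dict[Tuple[str, str], List[int]] = {}
    tally: Dict[Tuple[str, str, int], int] = {}
    for row in CONSECUTIVE_WID_CASES:
        k = (row.gene, row.case_id, row.run_total)
        tally[k] = tally.get(k, 0) + 1
    for (gene, case, total), n_rows in tally.items():
        if n_rows % total:
            raise ValueError(f"table rows for {gene}/{case} not a multiple of run size")
        runs.setdefault((gene, case), []).extend([total] * (n_rows // total))
    for v in runs.values():
        v.sort()
    return runs


# --- single-WID worked example: HLA-B exon 2-3 intron, 245 bp -------------

HLA_B_INTRON_SIZE = 245


def build_hla_b_example() -> Tuple[TranscriptModel, DeletionCall]:
    """A 245 bp intron between exons 2 and 3 and a deletion exactly spanning it.

    HLA-B is a minus-strand gene, so the intron between transcript exons 2
    and 3 (intron index 2) sits between the genomically *right* pair of
    exons in a 4-exon toy model.
    """
    n, exon_len = 4, 200
    intron_sizes = {2: HLA_B_INTRON_SIZE}  # transcript-order index -> size
    cursor = 1000
    exons = []
    for gpos in range(n):
        exons.append(GenomicInterval("chr_HLA_B", cursor, cursor + exon_len))
        cursor += exon_len
        if gpos < n - 1:
            t_idx = n - gpos - 1  # minus strand
            cursor += intron_sizes.get(t_idx, _DEFAULT_INTRON_LEN)
    model = TranscriptModel(
        gene_symbol="HLA-B",
        transcript_id="HLA-B_toy",
        contig="chr_HLA_B",
        strand="-",
        exons=tuple(exons),
    )
    intron = next(r for r in derive_introns(model) if r.intron_index == 2)
    deletion = DeletionCall(sample_id="P1", contig=intron.contig, interval=intron.interval)
    return model, deletion
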