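"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here from a single seed:
a toy genome with multi-exon genes on both strands, a capture panel built
the way targeted assays are designed (exons plus flanking intronic
sequence), deletion cohorts mixing constraint-respecting background with
boundary-exact planted whole-intron deletions (including consecutive runs),
and amplicon read sets of known composition with substitution-only
sequencing error.

Two structural guarantees make parameter-recovery tests exact rather than
statistical: background deletion boundaries are kept at least margin+1 bp
away from every intron boundary (so they can never be miscalled as WIDs at
the default margin), and amplicon sequences avoid adjacent repeated bases
(so a planted 1-bp indel has a unique optimal alignment placement). An
adversarial knob places extra background just outside the margin (3-5 bp
offsets) to probe the decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .annotations import (
    GenomicInterval,
    IntronRecord,
    PanelInterval,
    TranscriptModel,
    build_intron_index,
    derive_introns,
    merge_intervals,
)
from .amplicon import AmpliconSpec
from .deletion_io import DeletionCall, DeletionCohort
from .null_model import (
    LengthDistribution,
    SimulationConfig,
    SpaceWeights,
    simulate_cohort,
)

_BASES = np.array(list("ACGT"))


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic fixtures (one seed, all outputs)."""

    seed: int = 0
    # gene space
    n_genes: int = 30
    exons_per_gene: Tuple[int, int] = (4, 12)  # inclusive range
    exon_length: Tuple[int, int] = (80, 250)
    intron_length: Tuple[int, int] = (60, 400)
    panel_flank: int = 30  # captured intronic flank on each side of an exon
    intergenic_gap: Tuple[int, int] = (500, 2000)
    contig: str = "chrS"
    # cohort
    cohort_size: int = 500
    background_length_max: int = 60  # background lengths 1..max, geometric-ish decay
    planted_clusters: Tuple[int, ...] = (5, 4, 3, 2, 2, 1, 1, 1, 1)  # 20 planted WIDs
    margin_bp: int = 2  # background kept >= margin+1 bp from intron boundaries
    adversarial_near_boundary: int = 0  # extra background at 3-5 bp offsets
    # amplicon read sets
    n_reference: int = 10
    n_perfect: int = 5
    n_imperfect: int = 5
    n_unmodified: int = 60
    n_other_indel: int = 30
    n_signature: int = 10
    substitution_error: float = 0.001

    def __post_init__(self) -> None:
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length,
                       self.intergenic_gap):
            if lo < 1 or hi < lo:
                raise SynthesisError(f"invalid range ({lo}, {hi})")
        if self.exons_per_gene[0] < 2:
            raise SynthesisError("genes need >= 2 exons to have introns")
        if min(self.n_genes, self.cohort_size, self.panel_flank) < 1:
            raise SynthesisError("n_genes, cohort_size and panel_flank must be >= 1")
        if not 0.0 <= self.substitution_error < 1.0:
            raise SynthesisError("substitution_error must be in [0, 1)")


# ---------------------------------------------------------------------------
# gene space


@dataclass
class GeneSpace:
    genome: dict  # contig -> sequence
    transcripts: list  # list[TranscriptModel]
    panel: list  # list[PanelInterval]

    def introns(self) -> list:
        out = []
        for m in self.transcripts:
            out.extend(derive_introns(m))
        return out

    def intron_index(self):
        return build_intron_index(self.introns())

    def write(self, outdir) -> dict:
        """Write genome FASTA, transcripts GTF and panel BED; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gtf = outdir / "transcripts.gtf"
        bed = outdir / "panel.bed"
        write_genome_fasta(self.genome, fasta)
        write_transcripts_gtf(self.transcripts, gtf)
        from .annotations import write_panel_bed

        write_panel_bed(self.panel, bed)
        return {"fasta": fasta, "gtf": gtf, "bed": bed}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_gene_space(config: SynthConfig) -> GeneSpace:
    """Random multi-exon genes on one contig plus an exon+flank capture panel."""
    rng = np.random.default_rng([config.seed, 1])
    cursor = int(rng.integers(*config.intergenic_gap))
    transcripts = []
    panel_raw = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for e in range(n_exons):
            ex_len = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append(GenomicInterval(config.contig, cursor, cursor + ex_len))
            cursor += ex_len
            if e < n_exons - 1:
                cursor += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        transcripts.append(
            TranscriptModel(
                gene_symbol=f"SYNG{g + 1:03d}",
                transcript_id=f"SYNT{g + 1:03d}",
                contig=config.contig,
                strand=strand,
                exons=tuple(exons),
            )
        )
        for ex in exons:
            panel_raw.append(
                GenomicInterval(
                    config.contig,
                    max(0, ex.start - config.panel_flank),
                    ex.end + config.panel_flank,
                )
            )
        cursor += int(rng.integers(*config.intergenic_gap))

    merged = merge_intervals(panel_raw)
    panel = [PanelInterval(iv, f"panel_{i:06d}") for i, iv in enumerate(merged, start=1)]
    genome = {config.contig: _random_seq(rng, cursor + 100)}
    return GeneSpace(genome=genome, transcripts=transcripts, panel=panel)


def write_genome_fasta(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(genome):
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_transcripts_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """GTF export (1-based inclusive coordinates, gene/transcript/exon rows)."""
    with open(path, "w") as fh:
        for m in transcripts:
            span = m.span()
            attrs = f'gene_id "{m.gene_symbol}"; gene_name "{m.gene_symbol}"; transcript_id "{m.transcript_id}";'
            fh.write(
                f"{m.contig}\trtdsbr\ttranscript\t{span.start + 1}\t{span.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for ex in m.exons:
                fh.write(
                    f"{m.contig}\trtdsbr\texon\t{ex.start + 1}\t{ex.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# cohort with planted WIDs


@dataclass(frozen=True)
class PlantedWID:
    gene_symbol: str
    transcript_id: str
    sample_id: str
    intron_index: int
    interval: GenomicInterval


@dataclass(frozen=True)
class PlantedCluster:
    gene_symbol: str
    sample_id: str
    intron_indices: tuple


@dataclass
class PlantingLedger:
    planted: list  # list[PlantedWID]
    clusters: list  # list[PlantedCluster]
    background: list  # list[DeletionCall]

    @property
    def n_planted(self) -> int:
        return len(self.planted)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tgene\tsample\tintron_index\tcontig\tstart\tend\n")
            for p in self.planted:
                fh.write(
                    f"planted\t{p.gene_symbol}\t{p.sample_id}\t{p.intron_index}\t"
                    f"{p.interval.contig}\t{p.interval.start}\t{p.interval.end}\n"
                )
            for b in self.background:
                fh.write(
                    f"background\t.\t{b.sample_id}\t.\t{b.contig}\t"
                    f"{b.interval.start}\t{b.interval.end}\n"
                )


def _background_length_pmf(config: SynthConfig) -> LengthDistribution:
    """Decaying length distribution over 1..background_length_max.

    Short deletions dominate real indel calls; a geometric-style decay with a
    heavy head reproduces that shape without claiming realism beyond it.
    """
    lengths = np.arange(1, config.background_length_max + 1)
    probs = 0.9 ** lengths
    probs /= probs.sum()
    return LengthDistribution(support=tuple(int(x) for x in lengths),
                              probs=tuple(float(p) for p in probs))


def make_cohort_with_planted_wids(
    config: SynthConfig, space: GeneSpace
) -> Tuple[DeletionCohort, PlantingLedger]:
    """Background deletions + boundary-exact planted WIDs with known truth.

    Background deletions are drawn by the same constrained placement sampler
    the null model uses (panel units weighted by length), then re-drawn if
    either boundary lands within ``margin_bp + 1`` of any intron boundary.
    Planted WIDs exactly equal intron intervals; each configured cluster is
    a run of consecutive introns of one gene in one synthetic case.
    """
    rng = np.random.default_rng([config.seed, 2])
    introns = space.introns()
    by_gene: dict = {}
    for rec in introns:
        by_gene.setdefault(rec.gene_symbol, []).append(rec)
    for recs in by_gene.values():
        recs.sort(key=lambda r: r.intron_index)

    # --- planted clusters, one gene per cluster
    planted: list = []
    clusters: list = []
    genes = sorted(by_gene)
    order = rng.permutation(len(genes))
    gi = 0
    for k, size in enumerate(config.planted_clusters):
        placed = False
        while gi < len(order):
            gene = genes[order[gi]]
            gi += 1
            recs = by_gene[gene]
            if len(recs) >= size:
                start_idx = int(rng.integers(1, len(recs) - size + 2))
                run = [r for r in recs if start_idx <= r.intron_index < start_idx + size]
                sample = f"case_{k + 1:02d}"
                for r in run:
                    planted.append(
                        PlantedWID(r.gene_symbol, r.transcript_id, sample, r.intron_index, r.interval)
                    )
                clusters.append(PlantedCluster(gene, sample, tuple(r.intron_index for r in run)))
                placed = True
                break
        if not placed:
            raise SynthesisError(
                f"cannot place a cluster of {size} consecutive WIDs: too few introns"
            )

    # --- background under the null-model placement constraints
    n_background = config.cohort_size - len(planted)
    if n_background < 0:
        raise SynthesisError("cohort_size smaller than the number of planted WIDs")
    intron_starts = np.sort(np.array([r.interval.start for r in introns]))
    intron_ends = np.sort(np.array([r.interval.end for r in introns]))
    guard = config.margin_bp + 1

    def near(sorted_arr: np.ndarray, values: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(sorted_arr, values)
        dist = np.full(len(values), np.iinfo(np.int64).max, dtype=np.int64)
        left_ok = pos > 0
        dist[left_ok] = np.abs(values[left_ok] - sorted_arr[pos[left_ok] - 1])
        right_ok = pos < len(sorted_arr)
        dist[right_ok] = np.minimum(
            dist[right_ok], np.abs(sorted_arr[pos[right_ok]] - values[right_ok])
        )
        return dist < guard

    background: list = []
    if n_background > 0:
        lengths = _background_length_pmf(config)
        units = [p.interval for p in space.panel]
        sizes = np.array([u.length() for u in units], dtype=float)
        weights = SpaceWeights(units=tuple(units), weights=tuple(sizes / sizes.sum()))
        sim_cfg = SimulationConfig(
            mode="panel",
            cohort_size=max(1, int(n_background * 1.6)),
            n_cohorts=1,
            base_seed=int(rng.integers(0, 2**31 - 1)),
        )
        n_samples = max(4, config.cohort_size // 5)
        attempts = 0
        while len(background) < n_background:
            attempts += 1
            if attempts > 50:
                raise SynthesisError("cannot draw enough boundary-avoiding background")
            pool = simulate_cohort(sim_cfg, weights, lengths, cohort_index=attempts)
            starts = np.array([c.interval.start for c in pool])
            ends = np.array([c.interval.end for c in pool])
            bad = near(intron_starts, starts) | near(intron_ends, ends)
            for c, is_bad in zip(pool, bad):
                if not is_bad and len(background) < n_background:
                    background.append(
                        DeletionCall(
                            sample_id=f"bg_{int(rng.integers(0, n_samples)):03d}",
                            contig=c.contig,
                            interval=c.interval,
                        )
                    )

    # --- adversarial near-boundary background (offsets 3-5 bp, never WIDs)
    for _ in range(config.adversarial_near_boundary):
        rec = introns[int(rng.integers(0, len(introns)))]
        d1 = int(rng.choice([-5, -4, -3, 3, 4, 5]))
        d2 = int(rng.choice([-5, -4, -3, 3, 4, 5]))
        iv = rec.interval
        start, end = iv.start + d1, iv.end + d2
        if start < 0 or end <= start:
            continue
        background.append(
            DeletionCall(
                sample_id="adversarial",
                contig=iv.contig,
                interval=GenomicInterval(iv.contig, start, end),
            )
        )

    calls = [
        DeletionCall(sample_id=p.sample_id, contig=p.interval.contig, interval=p.interval)
        for p in planted
    ] + background
    order2 = sorted(range(len(calls)), key=lambda i: (calls[i].contig, calls[i].interval.start, calls[i].sample_id))
    cohort = DeletionCohort(calls=[calls[i] for i in order2], provenance=f"synthetic:seed={config.seed}")
    ledger = PlantingLedger(planted=planted, clusters=clusters, background=background)
    return cohort, ledger


# ---------------------------------------------------------------------------
# amplicon fixtures


def _seq_no_adjacent_repeat(rng: np.random.Generator, n: int) -> str:
    """Random sequence with no equal adjacent bases.

    Guarantees a unique optimal placement for any single 1-bp deletion, so
    window sweeps measure the classifier's window and not gap ambiguity.
    """
    out = [str(_BASES[rng.integers(0, 4)])]
    for _ in range(n - 1):
        choices = [b for b in "ACGT" if b != out[-1]]
        out.append(choices[int(rng.integers(0, 3))])
    return "".join(out)


def make_intron_loss_spec(
    rng: np.random.Generator,
    exon_len: int = 80,
    intron_len: int = 60,
    junction_halfwidth: int = 3,
) -> AmpliconSpec:
    """Two-exon amplicon pair: reference with intron, alt with perfect loss."""
    seq = _seq_no_adjacent_repeat(rng, 2 * exon_len + intron_len)
    e1, intron, e2 = seq[:exon_len], seq[exon_len : exon_len + intron_len], seq[exon_len + intron_len :]
    # keep the exon-exon seam free of an adjacent repeat too
    if e2[0] == e1[-1]:
        repl = next(b for b in "ACGT" if b != e1[-1] and b != e2[1])
        e2 = repl + e2[1:]
    return AmpliconSpec(
        reference_seq=e1 + intron + e2,
        alt_seq=e1 + e2,
        junction_pos=exon_len,
        junction_halfwidth=junction_halfwidth,
    )


def make_editing_spec(
    rng: np.random.Generator,
    amplicon_len: int = 160,
    signature_seq: str = "GAT",
    cut_window_width: int = 25,
) -> AmpliconSpec:
    """Cut-site amplicon with a signature motif whose placement is unambiguous."""
    seq = list(_seq_no_adjacent_repeat(rng, amplicon_len))
    cut = amplicon_len // 2
    # forbid signature-shifting flanks: ref[cut] != first sig base, ref[cut-1] != last
    if seq[cut] == signature_seq[0]:
        seq[cut] = next(b for b in "ACGT" if b not in {signature_seq[0], seq[cut - 1], seq[cut + 1]})
    if seq[cut - 1] == signature_seq[-1]:
        seq[cut - 1] = next(
            b for b in "ACGT" if b not in {signature_seq[-1], seq[cut - 2], seq[cut]}
        )
    return AmpliconSpec(
        reference_seq="".join(seq),
        cut_pos=cut,
        signature_seq=signature_seq,
        cut_window_width=cut_window_width,
    )


def _apply_substitutions(
    seq: str, rng: np.random.Generator, rate: float, protected: Tuple[int, int]
) -> str:
    """Substitution-only errors outside the protected half-open span."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if protected[0] <= i < protected[1]:
            continue
        chars[i] = next(
            b
            for b in "ACGT"
            if b != chars[i]
            and (i == 0 or b != chars[i - 1])
            and (i == len(chars) - 1 or b != chars[i + 1])
        )
    return "".join(chars)


def make_amplicon_readset(
    config: SynthConfig,
    spec: AmpliconSpec,
    mode: str,
) -> Tuple[list, list]:
    """Reads of known composition plus their truth labels.

    ``mode='intron_loss'`` emits reference copies, perfect intron-loss copies
    and imperfect copies (alt with a 1-bp deletion inside the junction
    window). ``mode='editing'`` emits unmodified copies, signature reads
    (the motif inserted at the cut) and other-indel reads (a 1-2 bp deletion
    inside the cut window). Substitution errors at the configured rate are
    applied outside a guard span around the window so they never perturb the
    planted indel's alignment.

    Returns ``(reads, truth)`` with reads as (id, sequence) pairs and truth
    as (id, expected_label) pairs.
    """
    rng = np.random.default_rng([config.seed, 3])
    reads: list = []
    truth: list = []
    err = config.substitution_error

    def emit(prefix: str, i: int, seq: str, label: str, protected: Tuple[int, int]) -> None:
        rid = f"{prefix}_{i:05d}"
        reads.append((rid, _apply_substitutions(seq, rng, err, protected)))
        truth.append((rid, label))

    if mode == "intron_loss":
        if config.n_reference + config.n_perfect + config.n_imperfect == 0:
            raise SynthesisError("empty read composition")
        j, hw = spec.junction_pos, spec.junction_halfwidth
        ref_guard = (j - hw - 2, j + hw + 2 + len(spec.reference_seq) - len(spec.alt_seq))
        alt_guard = (j - hw - 2, j + hw + 2)
        for i in range(config.n_reference):
            emit("ref", i, spec.reference_seq, "REF", ref_guard)
        for i in range(config.n_perfect):
            emit("perfect", i, spec.alt_seq, "PERFECT_LOSS", alt_guard)
        for i in range(config.n_imperfect):
            off = int(rng.integers(-hw, hw))  # deletion at j+off overlaps [j-hw, j+hw)
            p = j + off
            seq = spec.alt_seq[:p] + spec.alt_seq[p + 1 :]
            emit("imperfect", i, seq, "IMPERFECT_LOSS", (alt_guard[0], alt_guard[1]))
    elif mode == "editing":
        if config.n_unmodified + config.n_other_indel + config.n_signature == 0:
            raise SynthesisError("empty read composition")
        cut = spec.cut_pos
        w0, w1 = spec.cut_window()
        guard = (w0 - 2, w1 + 2)
        for i in range(config.n_unmodified):
            emit("unmod", i, spec.reference_seq, "UNMODIFIED", guard)
        for i in range(config.n_other_indel):
            off = int(rng.integers(-(spec.cut_window_width // 2 - 2), spec.cut_window_width // 2 - 2))
            p = cut + off
            ln = int(rng.integers(1, 3))
            seq = spec.reference_seq[:p] + spec.reference_seq[p + ln :]
            emit("indel", i, seq, "INDEL", guard)
        for i in range(config.n_signature):
            seq = spec.reference_seq[:cut] + spec.signature_seq + spec.reference_seq[cut:]
            emit("sig", i, seq, "SIGNATURE", guard)
    else:
        raise SynthesisError(f"unknown readset mode {mode!r}")
    return reads, truth


def write_reads_fastq(reads: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\n")
        for rid, label in truth:
            fh.write(f"{rid}\t{label}\n")
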