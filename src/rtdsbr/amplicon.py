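"""Amplicon read classification for repair-outcome quantification.

Two assays are supported:

* **Intron-loss quantification** — each merged read is globally aligned to
  both the reference amplicon and the intron-deleted amplicon and assigned
  to the higher-scoring one (ties go to the reference). Reads assigned to
  the intron-deleted amplicon are *perfect* intron loss unless an alignment
  insertion or deletion overlaps the quantification window of 3 bp on either
  side of the exon-exon junction (6 bp total); such reads are *imperfect*.
  Percent intron loss = 100 * perfect / (reference + perfect + imperfect).

* **Editing-outcome (cut-site) quantification** — each read is aligned to
  the reference amplicon; a read is *modified* (INDEL) when a gap operation
  overlaps the 25 bp quantification window centered on the cut site (12 bp
  each side plus the cut position). A modified read carries the *signature*
  when an insertion anchored exactly at the cut position inserts exactly the
  signature motif (e.g. GAT). Substitutions never count as modifications in
  either assay: only gap operations are scored against the windows.

Alignment is global (Needleman-Wunsch) with affine gaps. Default scoring is
match +2, mismatch -1, gap open -5, gap extend -1, where a gap of length L
costs open + (L-1)*extend. Tie-breaks are deterministic: diagonal over gaps,
deletion over insertion, and gap extension over re-opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from numba import njit

_NEG = -1.0e18
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class AmpliconError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class EditOp:
    """One alignment operation in target coordinates.

    ``target_pos`` is the first target base of a match/mismatch/delete run,
    or the anchor position (target index before which the bases sit) for an
    insert. ``seq`` holds the query bases for insert runs and the target
    bases for delete runs.
    """

    kind: str  # {"match", "mismatch", "insert", "delete"}
    target_pos: int
    length: int
    seq: str = ""


@dataclass(frozen=True)
class PairwiseAlignment:
    score: float
    aligned_query: str
    aligned_target: str
    ops: tuple  # tuple[EditOp, ...]

    def gap_ops(self) -> list:
        return [op for op in self.ops if op.kind in ("insert", "delete")]


class Assigned(str, Enum):
    REFERENCE = "REFERENCE"
    ALT = "ALT"


class ReadLabel(str, Enum):
    REF = "REF"
    PERFECT_LOSS = "PERFECT_LOSS"
    IMPERFECT_LOSS = "IMPERFECT_LOSS"
    UNMODIFIED = "UNMODIFIED"
    INDEL = "INDEL"
    SIGNATURE = "SIGNATURE"


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    assigned: Optional[Assigned]
    label: ReadLabel
    window_indels: int


@dataclass(frozen=True)
class AmpliconSpec:
    """Amplicon geometry for one assay.

    Intron-loss mode needs ``alt_seq`` (the intron-deleted amplicon) and
    ``junction_pos`` (0-based position of the exon-exon junction in
    ``alt_seq``); editing mode needs ``cut_pos`` (0-based cut-site position
    in ``reference_seq``) and ``signature_seq``.
    """

    reference_seq: str
    alt_seq: Optional[str] = None
    junction_pos: Optional[int] = None
    cut_pos: Optional[int] = None
    signature_seq: Optional[str] = None
    junction_halfwidth: int = 3
    cut_window_width: int = 25

    def __post_init__(self) -> None:
        if not self.reference_seq:
            raise AmpliconError("empty reference sequence")
        if self.junction_pos is not None:
            if self.alt_seq is None:
                raise AmpliconError("junction_pos given without alt_seq")
            if not 0 <= self.junction_pos <= len(self.alt_seq):
                raise AmpliconError("junction_pos outside alt_seq")
        if self.cut_pos is not None and not 0 <= self.cut_pos < len(self.reference_seq):
            raise AmpliconError("cut_pos outside reference_seq")
        if self.signature_seq is not None and len(self.signature_seq) < 1:
            raise AmpliconError("signature_seq must be non-empty when set")
        if self.junction_halfwidth < 0 or self.cut_window_width < 1:
            raise AmpliconError("invalid window parameters")

    def junction_window(self) -> Tuple[int, int]:
        j, hw = self.junction_pos, self.junction_halfwidth
        return j - hw, j + hw

    def cut_window(self) -> Tuple[int, int]:
        w0 = self.cut_pos - self.cut_window_width // 2
        return w0, w0 + self.cut_window_width

    def to_dict(self) -> dict:
        return {
            "reference_seq": self.reference_seq,
            "alt_seq": self.alt_seq,
            "junction_pos": self.junction_pos,
            "cut_pos": self.cut_pos,
            "signature_seq": self.signature_seq,
            "junction_halfwidth": self.junction_halfwidth,
            "cut_window_width": self.cut_window_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmpliconSpec":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# affine Needleman-Wunsch


@njit(cache=True)
def _affine_dp(q, t, ms, xs, go, ge):  # pragma: no cover - exercised via global_align
    n, m = q.shape[0], t.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in target: insertion, consumes query
    Y = np.full((n + 1, m + 1), _NEG)  # gap in query: deletion, consumes target
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
        pX[i, 0] = 0 if i == 1 else 1
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = ms if qi == t[j - 1] else xs
            # diagonal: prefer M, then Y (deletion), then X on ties
            best = M[i - 1, j - 1]
            p = 0
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            M[i, j] = best + s
            pM[i, j] = p
            # deletion state: prefer extension, then M, then X
            best = Y[i, j - 1] + ge
            p = 2
            if M[i, j - 1] + go > best:
                best = M[i, j - 1] + go
                p = 0
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                p = 1
            Y[i, j] = best
            pY[i, j] = p
            # insertion state: prefer extension, then M, then Y
            best = X[i - 1, j] + ge
            p = 1
            if M[i - 1, j] + go > best:
                best = M[i - 1, j] + go
                p = 0
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                p = 2
            X[i, j] = best
            pX[i, j] = p
    # final state: prefer M, then Y (deletion), then X (insertion)
    score = M[n, m]
    state = 0
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    if X[n, m] > score:
        score = X[n, m]
        state = 1

    qa = np.empty(n + m, np.int64)
    ta = np.empty(n + m, np.int64)
    k = 0
    i, j, s_ = n, m, state
    while i > 0 or j > 0:
        if s_ == 0:
            qa[k] = i - 1
            ta[k] = j - 1
            s_ = pM[i, j]
            i -= 1
            j -= 1
        elif s_ == 1:
            qa[k] = i - 1
            ta[k] = -1
            s_ = pX[i, j]
            i -= 1
        else:
            qa[k] = -1
            ta[k] = j - 1
            s_ = pY[i, j]
            j -= 1
        k += 1
    return score, qa[:k][::-1].copy(), ta[:k][::-1].copy()


def _encode(seq: str, what: str) -> np.ndarray:
    if not seq:
        raise AmpliconError(f"empty {what} sequence")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        bad = seq[int(np.argmax(codes == 255))]
        raise AmpliconError(f"invalid base {bad!r} in {what} (alphabet ACGTN)")
    return codes


def global_align(
    query: str,
    target: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``target``.

    Operation coordinates are on the target: a delete run spans the skipped
    target bases; an insert run is anchored at the target position before
    which the extra query bases sit.
    """
    q = _encode(query, "query")
    t = _encode(target, "target")
    score, qa, ta = _affine_dp(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )

    aq = "".join(query[i] if i >= 0 else "-" for i in qa)
    at = "".join(target[j] if j >= 0 else "-" for j in ta)

    ops: list = []
    cursor = 0  # target bases consumed so far = anchor for insertions
    for col in range(len(qa)):
        qi, tj = qa[col], ta[col]
        if qi >= 0 and tj >= 0:
            kind = "match" if query[qi] == target[tj] else "mismatch"
            pos, piece = int(tj), target[tj]
            cursor = int(tj) + 1
        elif tj >= 0:  # gap in query -> deletion of target base tj
            kind, pos, piece = "delete", int(tj), target[tj]
            cursor = int(tj) + 1
        else:  # gap in target -> insertion of query base qi
            kind, pos, piece = "insert", cursor, query[qi]
        if ops and ops[-1].kind == kind and (
            (kind == "insert" and ops[-1].target_pos == pos)
            or (kind != "insert" and ops[-1].target_pos + ops[-1].length == pos)
        ):
            last = ops[-1]
            ops[-1] = EditOp(kind, last.target_pos, last.length + 1, last.seq + piece)
        else:
            ops.append(EditOp(kind, pos, 1, piece))
    return PairwiseAlignment(score=float(score), aligned_query=aq, aligned_target=at, ops=tuple(ops))


def _gap_ops_in_window(ops: Sequence[EditOp], w0: int, w1: int) -> int:
    """Count gap operations overlapping the half-open window [w0, w1).

    A delete overlaps when its target span intersects the window; an insert
    overlaps when its anchor lies inside the window.
    """
    n = 0
    for op in ops:
        if op.kind == "delete":
            if op.target_pos < w1 and op.target_pos + op.length > w0:
                n += 1
        elif op.kind == "insert":
            if w0 <= op.target_pos < w1:
                n += 1
    return n


# ---------------------------------------------------------------------------
# intron-loss assay


def assign_read(
    read: str,
    spec: AmpliconSpec,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> Tuple[Assigned, PairwiseAlignment, PairwiseAlignment]:
    """Assign a read to the reference or intron-deleted amplicon by score."""
    if spec.alt_seq is None:
        raise AmpliconError("assign_read requires an intron-loss spec with alt_seq")
    ref_aln = global_align(read, spec.reference_seq, scoring)
    alt_aln = global_align(read, spec.alt_seq, scoring)
    assigned = Assigned.ALT if alt_aln.score > ref_aln.score else Assigned.REFERENCE
    return assigned, ref_aln, alt_aln


def classify_intron_loss_read(
    read_id: str,
    read: str,
    spec: AmpliconSpec,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> ReadClassification:
    """REF / PERFECT_LOSS / IMPERFECT_LOSS classification of one read.

    Only insertions and deletions inside the junction window demote a read
    to imperfect; substitutions there are tolerated (sequencing error).
    """
    if spec.junction_pos is None:
        raise AmpliconError("intron-loss classification requires junction_pos")
    assigned, _, alt_aln = assign_read(read, spec, scoring)
    if assigned is Assigned.REFERENCE:
        return ReadClassification(read_id, Assigned.REFERENCE, ReadLabel.REF, 0)
    w0, w1 = spec.junction_window()
    n_gap = _gap_ops_in_window(alt_aln.ops, w0, w1)
    label = ReadLabel.PERFECT_LOSS if n_gap == 0 else ReadLabel.IMPERFECT_LOSS
    return ReadClassification(read_id, Assigned.ALT, label, n_gap)


# ---------------------------------------------------------------------------
# editing (cut-site) assay


def classify_editing_read(
    read_id: str,
    read: str,
    spec: AmpliconSpec,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> ReadClassification:
    """UNMODIFIED / INDEL / SIGNATURE classification of one read."""
    if spec.cut_pos is None:
        raise AmpliconError("editing classification requires cut_pos")
    aln = global_align(read, spec.reference_seq, scoring)
    w0, w1 = spec.cut_window()
    n_gap = _gap_ops_in_window(aln.ops, w0, w1)
    if n_gap == 0:
        return ReadClassification(read_id, None, ReadLabel.UNMODIFIED, 0)
    label = ReadLabel.INDEL
    if spec.signature_seq is not None:
        for op in aln.ops:
            if op.kind == "insert" and op.target_pos == spec.cut_pos and op.seq == spec.signature_seq:
                label = ReadLabel.SIGNATURE
                break
    return ReadClassification(read_id, None, label, n_gap)


# ---------------------------------------------------------------------------
# cohort quantification


@dataclass
class QuantReport:
    counts: dict  # label value -> read count
    total: int
    percent_intron_loss: Optional[float] = None
    signature_fraction_of_total: Optional[float] = None
    signature_fraction_of_indels: Optional[float] = None  # None when no indel reads

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total": self.total,
            "percent_intron_loss": self.percent_intron_loss,
            "signature_fraction_of_total": self.signature_fraction_of_total,
            "signature_fraction_of_indels": self.signature_fraction_of_indels,
        }


def _tally(classifications: Sequence[ReadClassification]) -> dict:
    counts: dict = {}
    for c in classifications:
        counts[c.label.value] = counts.get(c.label.value, 0) + 1
    return counts


def quantify_intron_loss(
    reads: Iterable[Tuple[str, str]],
    spec: AmpliconSpec,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> Tuple[QuantReport, list]:
    """Classify reads and compute percent intron loss.

    percent = 100 * perfect / (reference + perfect + imperfect).
    Returns the report and the per-read classifications.
    """
    cls = [classify_intron_loss_read(rid, seq, spec, scoring) for rid, seq in reads]
    if not cls:
        raise AmpliconError("no reads to quantify")
    counts = _tally(cls)
    total = len(cls)
    perfect = counts.get(ReadLabel.PERFECT_LOSS.value, 0)
    report = QuantReport(
        counts=counts,
        total=total,
        percent_intron_loss=100.0 * perfect / total,
    )
    return report, cls


def quantify_signature_fraction(
    reads: Iterable[Tuple[str, str]],
    spec: AmpliconSpec,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> Tuple[QuantReport, list]:
    """Classify reads and compute signature-insertion fractions.

    Signature reads count among indel-harboring reads; the fraction over
    indel reads is undefined (None) when no read harbors an indel.
    """
    cls = [classify_editing_read(rid, seq, spec, scoring) for rid, seq in reads]
    if not cls:
        raise AmpliconError("no reads to quantify")
    counts = _tally(cls)
    total = len(cls)
    n_sig = counts.get(ReadLabel.SIGNATURE.value, 0)
    n_indel = n_sig + counts.get(ReadLabel.INDEL.value, 0)
    report = QuantReport(
        counts=counts,
        total=total,
        signature_fraction_of_total=n_sig / total,
        signature_fraction_of_indels=(n_sig / n_indel) if n_indel else None,
    )
    return report, cls


# ---------------------------------------------------------------------------
# read IO helpers


def iter_reads(path) -> list:
    """Read (id, sequence) pairs from FASTA or FASTQ (by extension)."""
    from Bio import SeqIO

    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_classifications_tsv(classifications: Sequence[ReadClassification], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tassigned\tlabel\twindow_indels\n")
        for c in classifications:
            assigned = c.assigned.value if c.assigned is not None else "."
            fh.write(f"{c.read_id}\t{assigned}\t{c.label.value}\t{c.window_indels}\n")
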