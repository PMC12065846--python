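"""Monte-Carlo null model for whole-intron deletion enrichment.

The null asks how many WIDs random deletions would produce if they carried
the empirical properties of the observed cohort but no mechanism. Each
simulated deletion is drawn in three steps: pick a placement unit (a capture
panel interval, or a gene body in whole-genome mode) with probability equal
to its observed share of deletion starts; pick a start uniformly inside the
unit; pick a length from the empirical length distribution. Draws violating
the placement constraint are rejected and redrawn.

Panel-mode constraint (both breakpoints must be in captured sequence): the
deletion either ends within its unit, or its right breakpoint falls inside
the immediately following panel interval on the same contig. A strict
variant additionally requires the right breakpoint to coincide exactly with
the next interval's start. Gene mode requires the deletion to lie entirely
within the selected gene body, and pre-filters the observed cohort to
deletions longer than 10 bp before fitting (the whole-genome convention).

An ensemble of N such cohorts (full-scale default: 10,000 cohorts of 73,030
deletions) is scanned with the WID caller, and the empirical p-value is the
frequency of simulated cohorts with a WID count at least the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .annotations import GenomicInterval, IntronIndex, PanelInterval, TranscriptModel
from .deletion_io import DeletionCall, DeletionCohort, filter_min_length
from .wid_caller import MarginPolicy, scan_cohort

logger = logging.getLogger(__name__)

PCAWG_MIN_DELETION_LENGTH = 10  # exclusive; gene-mode observed cohorts keep length > 10


class NullModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# empirical distributions


@dataclass(frozen=True)
class LengthDistribution:
    """Empirical probability mass over observed deletion lengths."""

    support: tuple  # unique lengths, ascending
    probs: tuple

    def __post_init__(self) -> None:
        s = np.asarray(self.support)
        p = np.asarray(self.probs, dtype=float)
        if len(s) == 0:
            raise NullModelError("empty length distribution")
        if len(s) != len(p):
            raise NullModelError("support/probs length mismatch")
        if np.any(s < 1) or len(np.unique(s)) != len(s):
            raise NullModelError("support must be unique lengths >= 1")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise NullModelError("probs must be non-negative and sum to 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.asarray(self.support), size=size, p=np.asarray(self.probs))


def fit_length_distribution(cohort: DeletionCohort) -> LengthDistribution:
    if len(cohort) == 0:
        raise NullModelError("cannot fit length distribution from an empty cohort")
    lengths, counts = np.unique(np.array(cohort.lengths()), return_counts=True)
    probs = counts / counts.sum()
    return LengthDistribution(support=tuple(int(x) for x in lengths),
                              probs=tuple(float(x) for x in probs))


def _as_interval(unit) -> GenomicInterval:
    return unit.interval if isinstance(unit, PanelInterval) else unit


@dataclass(frozen=True)
class SpaceWeights:
    """Placement units with observed-abundance selection probabilities.

    Units are sorted by (contig, start); ``next_index[i]`` points to the
    immediately following unit on the same contig (-1 if none), which the
    panel-mode constraint consults.
    """

    units: tuple  # tuple[GenomicInterval, ...] sorted by (contig, start)
    weights: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.units) == 0:
            raise NullModelError("no placement units")
        if len(self.units) != len(w):
            raise NullModelError("units/weights length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise NullModelError("weights must be non-negative and sum to 1")

    @property
    def next_index(self) -> np.ndarray:
        nxt = np.full(len(self.units), -1, dtype=np.int64)
        for i in range(len(self.units) - 1):
            if self.units[i].contig == self.units[i + 1].contig:
                nxt[i] = i + 1
        return nxt


def fit_space_weights(
    cohort: DeletionCohort,
    units: Sequence,
    mode: str = "panel",
) -> SpaceWeights:
    """Weight each unit by its share of observed deletion starts.

    Deletions starting outside every unit are excluded (their count is
    logged); an error is raised if no observed deletion starts in any unit.
    """
    if mode not in {"panel", "gene"}:
        raise NullModelError(f"unknown mode {mode!r}")
    ivs = sorted((_as_interval(u) for u in units), key=lambda v: (v.contig, v.start))
    counts = np.zeros(len(ivs), dtype=np.int64)
    by_contig: dict = {}
    for i, iv in enumerate(ivs):
        by_contig.setdefault(iv.contig, []).append(i)
    outside = 0
    for call in cohort:
        hit = False
        for i in by_contig.get(call.contig, ()):
            iv = ivs[i]
            if iv.start <= call.interval.start < iv.end:
                counts[i] += 1
                hit = True
                break
        if not hit:
            outside += 1
    total = counts.sum()
    if total == 0:
        raise NullModelError("no observed deletion starts fall inside any placement unit")
    if outside:
        logger.info("fit_space_weights: %d of %d deletions start outside all units",
                    outside, len(cohort))
    return SpaceWeights(units=tuple(ivs), weights=tuple(float(c) / total for c in counts))


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class SimulationConfig:
    mode: str = "panel"  # {"panel", "gene"}
    cohort_size: int = 73_030
    n_cohorts: int = 10_000
    margin: MarginPolicy = MarginPolicy()
    base_seed: int = 0
    max_attempts: int = 1_000
    strict_boundary: bool = False  # panel mode: end must equal next unit's start

    def __post_init__(self) -> None:
        if self.mode not in {"panel", "gene"}:
            raise NullModelError(f"unknown mode {self.mode!r}")
        if self.cohort_size < 1 or self.n_cohorts < 1 or self.max_attempts < 1:
            raise NullModelError("cohort_size, n_cohorts and max_attempts must be >= 1")


def _valid_placement(
    starts: np.ndarray,
    ends: np.ndarray,
    idx: np.ndarray,
    unit_end: np.ndarray,
    next_start: np.ndarray,
    next_end: np.ndarray,
    mode: str,
    strict: bool,
) -> np.ndarray:
    within = ends <= unit_end[idx]
    if mode == "gene":
        return within
    has_next = next_start[idx] >= 0
    if strict:
        spill = has_next & (ends == next_start[idx])
    else:
        spill = has_next & (ends >= next_start[idx]) & (ends <= next_end[idx])
    return within | spill


def _placement_arrays(weights: SpaceWeights):
    us = np.array([u.start for u in weights.units], dtype=np.int64)
    ue = np.array([u.end for u in weights.units], dtype=np.int64)
    nxt = weights.next_index
    ns = np.where(nxt >= 0, us[np.clip(nxt, 0, None)], -1)
    ne = np.where(nxt >= 0, ue[np.clip(nxt, 0, None)], -1)
    return us, ue, ns, ne


def simulate_deletion(
    weights: SpaceWeights,
    lengths: LengthDistribution,
    rng: np.random.Generator,
    mode: str = "panel",
    max_attempts: int = 1_000,
    strict_boundary: bool = False,
    sample_id: str = "sim",
) -> DeletionCall:
    """Draw a single constraint-satisfying deletion (rejection sampling)."""
    us, ue, ns, ne = _placement_arrays(weights)
    w = np.asarray(weights.weights)
    for _ in range(max_attempts):
        i = int(rng.choice(len(weights.units), p=w))
        start = int(rng.integers(us[i], ue[i]))
        length = int(lengths.sample(rng, 1)[0])
        end = start + length
        ok = _valid_placement(
            np.array([start]), np.array([end]), np.array([i]),
            ue, ns, ne, mode, strict_boundary,
        )[0]
        if ok:
            unit = weights.units[i]
            return DeletionCall(
                sample_id=sample_id,
                contig=unit.contig,
                interval=GenomicInterval(unit.contig, start, end),
            )
    raise NullModelError(
        f"max_attempts={max_attempts} exhausted; the length distribution is "
        f"incompatible with unit {weights.units[i].contig}:{weights.units[i].start}"
        f"-{weights.units[i].end}"
    )


def simulate_cohort(
    config: SimulationConfig,
    weights: SpaceWeights,
    lengths: LengthDistribution,
    cohort_index: int,
) -> DeletionCohort:
    """Simulate one cohort of exactly ``config.cohort_size`` deletions.

    Reproducible: the random stream is keyed by (base_seed, cohort_index),
    so ensembles can be re-run or parallelized cohort by cohort.
    """
    rng = np.random.default_rng([config.base_seed, cohort_index])
    M = config.cohort_size
    us, ue, ns, ne = _placement_arrays(weights)
    w = np.asarray(weights.weights)
    support = np.asarray(lengths.support)
    probs = np.asarray(lengths.probs)

    idx = np.empty(M, dtype=np.int64)
    starts = np.empty(M, dtype=np.int64)
    ends = np.empty(M, dtype=np.int64)
    pending = np.arange(M)
    for _ in range(config.max_attempts):
        k = len(pending)
        i = rng.choice(len(w), size=k, p=w)
        s = rng.integers(us[i], ue[i])
        ln = rng.choice(support, size=k, p=probs)
        e = s + ln
        ok = _valid_placement(s, e, i, ue, ns, ne, config.mode, config.strict_boundary)
        sel = pending[ok]
        idx[sel], starts[sel], ends[sel] = i[ok], s[ok], e[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        bad = int(i[~ok][0])
        raise NullModelError(
            f"max_attempts={config.max_attempts} exhausted; length distribution "
            f"incompatible with unit {weights.units[bad].contig}:"
            f"{weights.units[bad].start}-{weights.units[bad].end}"
        )

    contigs = [u.contig for u in weights.units]
    calls = [
        DeletionCall(
            sample_id=f"sim_{cohort_index}",
            contig=contigs[idx[j]],
            interval=GenomicInterval(contigs[idx[j]], int(starts[j]), int(ends[j])),
        )
        for j in range(M)
    ]
    return DeletionCohort(calls=calls, provenance=f"simulated:{config.base_seed}:{cohort_index}")


# ---------------------------------------------------------------------------
# ensemble + p-value


def empirical_pvalue(
    wid_counts: Sequence[int],
    observed: int,
    estimator: str = "plain",
) -> float:
    """Empirical tail probability of the observed WID count.

    ``plain``: (#counts >= observed) / N — the frequency at which a simulated
    cohort matches or exceeds the observation. ``add_one``: the
    (k+1)/(N+1) estimator, which never reports exactly zero.
    """
    counts = np.asarray(wid_counts)
    if counts.size == 0:
        raise NullModelError("empty count vector")
    k = int(np.sum(counts >= observed))
    if estimator == "plain":
        return k / counts.size
    if estimator == "add_one":
        return (k + 1) / (counts.size + 1)
    raise NullModelError(f"unknown estimator {estimator!r}")


@dataclass
class NullEnsembleResult:
    wid_counts: np.ndarray  # per simulated cohort
    observed: int
    p_value: float
    max_simulated: int
    n_cohorts: int
    cohort_size: int
    base_seed: int

    @property
    def p_label(self) -> str:
        """Human-readable p-value; a plain-estimator zero reads '< 1/N'."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_cohorts:g}"
        return f"= {self.p_value:g}"

    def summary_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_cohorts": self.n_cohorts,
            "cohort_size": self.cohort_size,
            "p_value": self.p_value,
            "p_label": self.p_label,
            "max_simulated": self.max_simulated,
            "mean_simulated": float(np.mean(self.wid_counts)),
            "seed": self.base_seed,
        }


def count_wids(cohort: DeletionCohort, intron_index: IntronIndex, margin: MarginPolicy) -> int:
    return len(scan_cohort(cohort, intron_index, margin))


def gene_units(models: Sequence[TranscriptModel]) -> list:
    """Gene-body placement units for whole-genome (gene) mode."""
    return [m.span() for m in models]


def run_null_ensemble(
    config: SimulationConfig,
    cohort_observed: DeletionCohort,
    units: Sequence,
    intron_index: IntronIndex,
    progress: bool = False,
) -> NullEnsembleResult:
    """Fit distributions from the observed cohort, simulate N cohorts, count
    WIDs in each and compare with the observed count.

    In gene mode the observed cohort is pre-filtered to deletions longer
    than :data:`PCAWG_MIN_DELETION_LENGTH` bp before fitting and counting.
    """
    if config.mode == "gene":
        cohort_observed = filter_min_length(cohort_observed, PCAWG_MIN_DELETION_LENGTH)
    lengths = fit_length_distribution(cohort_observed)
    weights = fit_space_weights(cohort_observed, units, mode=config.mode)
    observed = count_wids(cohort_observed, intron_index, config.margin)

    wid_counts = np.empty(config.n_cohorts, dtype=np.int64)
    for c in range(config.n_cohorts):
        sim = simulate_cohort(config, weights, lengths, cohort_index=c)
        wid_counts[c] = count_wids(sim, intron_index, config.margin)
        if progress and (c + 1) % max(1, config.n_cohorts // 20) == 0:
            logger.info("null ensemble: %d / %d cohorts", c + 1, config.n_cohorts)

    p = empirical_pvalue(wid_counts, observed, estimator="plain")
    return NullEnsembleResult(
        wid_counts=wid_counts,
        observed=observed,
        p_value=p,
        max_simulated=int(wid_counts.max()),
        n_cohorts=config.n_cohorts,
        cohort_size=config.cohort_size,
        base_seed=config.base_seed,
    )


def write_ensemble_counts(result: NullEnsembleResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("cohort_index\twid_count\n")
        for i, c in enumerate(result.wid_counts):
            fh.write(f"{i}\t{int(c)}\n")
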