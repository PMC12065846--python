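import numpy as np
import pytest

from rtdsbr.synthetic import (
    SynthConfig,
    make_cohort_with_planted_wids,
    make_editing_spec,
    make_gene_space,
    make_intron_loss_spec,
)


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=123)


@pytest.fixture(scope="session")
def gene_space(synth_config):
    return make_gene_space(synth_config)


@pytest.fixture(scope="session")
def planted_cohort(synth_config, gene_space):
    """(cohort, ledger) with 20 boundary-exact planted WIDs over background."""
    return make_cohort_with_planted_wids(synth_config, gene_space)


@pytest.fixture(scope="session")
def intron_loss_spec():
    return make_intron_loss_spec(np.random.default_rng(77))


@pytest.fixture(scope="session")
def editing_spec():
    return make_editing_spec(np.random.default_rng(77))


@pytest.fixture(scope="session")
def gene_space_files(gene_space, tmp_path_factory):
    """Gene space written to disk (FASTA/GTF/BED paths)."""
    outdir = tmp_path_factory.mktemp("gene_space")
    return gene_space.write(outdir)


def brute_force_align_score(query, target, scoring):
    """Exhaustive optimal global affine alignment score (small inputs only).

    Enumerates every alignment path; a gap of length L costs
    gap_open + (L-1) * gap_extend. Independent of the DP implementation.
    """
    best = [-float("inf")]

    def rec(i, j, prev, score):
        if i == len(query) and j == len(target):
            best[0] = max(best[0], score)
            return
        if i < len(query) and j < len(target):
            s = scoring.match if query[i] == target[j] else scoring.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if j < len(target):
            pen = scoring.gap_extend if prev == "D" else scoring.gap_open
            rec(i, j + 1, "D", score + pen)
        if i < len(query):
            pen = scoring.gap_extend if prev == "I" else scoring.gap_open
            rec(i + 1, j, "I", score + pen)

    rec(0, 0, "S", 0.0)
    return best[0]
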