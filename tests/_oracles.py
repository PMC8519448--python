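"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: survival functions
come from exhaustive enumeration of all 4^k sequences, q-values from
statsmodels, haplotype k-mer sets from plain substring scans of explicit
strings, and linear occurrence lists from a direct scan of the raw FASTA
sequence (no graph machinery).
"""

from __future__ import annotations

import numpy as np

from hapmotif.motif_io import NT_INDEX, NUCLEOTIDES

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def enumerate_scaled_scores(int_matrix: np.ndarray, bg: np.ndarray):
    """Scores and probabilities of every 4^k sequence under i.i.d. background."""
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1, dtype=float)
    for i in range(int_matrix.shape[1]):
        scores = (scores[:, None] + int_matrix[:, i][None, :]).ravel()
        probs = (probs[:, None] * bg[None, :]).ravel()
    return scores, probs


def exhaustive_survival(int_matrix: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """survival[s] = P(total >= s) for s = 0..max_total, by full enumeration."""
    scores, probs = enumerate_scaled_scores(int_matrix, bg)
    max_total = int(int_matrix.max(axis=0).sum())
    tail = np.zeros(max_total + 1, dtype=float)
    np.add.at(tail, scores, probs)
    return np.cumsum(tail[::-1])[::-1]


def bh_reference(pvalues) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def substring_kmers(strings_with_proj, k: int, start: int, end: int):
    """All (sequence, projected start, source) windows by plain substring scan.

    ``strings_with_proj`` is a list of ``(source_name, sequence, projection)``
    where projection gives the reference coordinate of each base.
    """
    out = set()
    for name, seq, proj in strings_with_proj:
        for off in range(len(seq) - k + 1):
            if start <= proj[off] < end:
                out.add((seq[off : off + k], proj[off], name))
    return out


def linear_scan_occurrences(sequence: str, spssm, table, table_rc, spssm_rc):
    """Directly scan a linear sequence with a scaled matrix on both strands.

    Returns rows ``(start_1based, stop, strand, kmer, scaled_score, pvalue)``
    without touching graph, path-scan or pipeline code.
    """
    from hapmotif.scoring import score_kmer

    k = spssm.width
    rows = []
    for off in range(len(sequence) - k + 1):
        kmer = sequence[off : off + k]
        if kmer.count("N") > k // 2:
            continue
        s_fwd = score_kmer(spssm, kmer)
        rows.append((off + 1, off + k, "+", kmer, s_fwd, table.pvalue(s_fwd)))
        s_rev = score_kmer(spssm_rc, kmer)
        rows.append((off + 1, off + k, "-", revcomp(kmer), s_rev, table_rc.pvalue(s_rev)))
    return rows


def random_count_pwm(rng: np.random.Generator, k: int, motif_id: str = "RND"):
    """A random count PWM with at least one informative column."""
    from hapmotif.motif_io import PWM

    matrix = rng.integers(0, 30, size=(4, k)).astype(float)
    # guarantee a non-degenerate scoring matrix
    matrix[rng.integers(0, 4), 0] += 40
    return PWM(motif_id=motif_id, name=motif_id, matrix=matrix, is_probability=False)


def random_background(rng: np.random.Generator):
    from hapmotif.motif_io import Background

    raw = rng.dirichlet(np.ones(4) * 5)
    raw = np.clip(raw, 0.05, None)
    raw = raw / raw.sum()
    return Background({b: float(p) for b, p in zip(NUCLEOTIDES, raw)})
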