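"""Log-odds scoring of k-mers with integer-scaled matrices and exact P-values.

The probability PWM is turned into a log2-odds PSSM against a background
distribution, then affinely rescaled so that every attainable total score of
a k-mer is a non-negative integer in [0, 1000]. On that integer grid the
exact null distribution of the total score is computed by dynamic
programming, giving each candidate an exact one-sided P-value. Raw log-odds
are recovered from scaled scores through the stored affine parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif_io import NT_INDEX, NUCLEOTIDES, Background, PWM

SCALE_RANGE = 1000  # scaled total scores live in [0, SCALE_RANGE]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NonFiniteScoreError(ValueError):
    """Raised when a zero probability makes a log-odds entry non-finite."""


class DegenerateMotifError(ValueError):
    """Raised when every column of a motif is constant (zero score range)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PSSM:
    """Real-valued log2-odds scoring matrix with its background."""

    motif_id: str
    name: str
    logodds: np.ndarray  # (4, k)
    bg: Background

    @property
    def width(self) -> int:
        return int(self.logodds.shape[1])


@dataclass
class ScaledPSSM:
    """Integer-scaled PSSM.

    ``int_matrix[b, i] = round((logodds[b, i] - offsets[i]) * scale)`` with a
    columnwise correction of at most 1 so that ``max_total <= 1000``. The real
    log-odds of a scaled total ``s`` is ``s / scale + offsets.sum()``.
    """

    motif_id: str
    name: str
    int_matrix: np.ndarray  # (4, k) non-negative ints
    offsets: np.ndarray  # (k,) per-column real offsets
    scale: float
    max_total: int

    @property
    def width(self) -> int:
        return int(self.int_matrix.shape[1])


@dataclass
class PValueTable:
    """Exact null distribution of the scaled total score.

    ``pmf[s]`` is P(total == s) under i.i.d. background draws; ``survival[s]``
    is P(total >= s). Both arrays span scores 0 .. max_total.
    """

    pmf: np.ndarray
    survival: np.ndarray

    def pvalue(self, score: int) -> float:
        if score < 0:
            return 1.0
        if score >= len(self.survival):
            return 0.0
        return float(self.survival[score])


def build_pssm(pwm: PWM, bg: Background | None = None) -> PSSM:
    """Build the log2-odds matrix ``log2(p(b,i) / bg(b))`` from a probability PWM."""
    if not pwm.is_probability:
        raise ValueError(
            f"motif {pwm.motif_id} holds counts; run pwm_to_probabilities first"
        )
    bg = bg or Background.uniform()
    if np.any(pwm.matrix <= 0):
        raise NonFiniteScoreError(
            f"motif {pwm.motif_id} has zero-probability cells; apply a positive "
            "pseudocount before building the PSSM"
        )
    logodds = np.log2(pwm.matrix / bg.as_array()[:, None])
    return PSSM(motif_id=pwm.motif_id, name=pwm.name, logodds=logodds, bg=bg)


def scale_pssm(pssm: PSSM) -> ScaledPSSM:
    """Affinely rescale log-odds so attainable totals are integers in [0, 1000].

    Per column, the minimum entry is subtracted; the single global scale is
    ``1000 / sum of column ranges``. Cells are rounded to integers, then the
    columns whose maxima rounded up furthest are decremented by 1 until the
    sum of column maxima is back within 1000.
    """
    lo = pssm.logodds
    if not np.all(np.isfinite(lo)):
        raise NonFiniteScoreError(f"motif {pssm.motif_id} has non-finite log-odds")
    offsets = lo.min(axis=0)
    ranges = lo.max(axis=0) - offsets
    total_range = float(ranges.sum())
    if total_range <= 0:
        raise DegenerateMotifError(
            f"motif {pssm.motif_id} is uninformative: all columns constant"
        )
    scale = SCALE_RANGE / total_range
    exact = (lo - offsets) * scale
    int_matrix = np.rint(exact).astype(np.int64)

    # rounding can push the sum of column maxima past 1000; walk it back by
    # decrementing, column by column, the maxima that rounded up the furthest
    while int(int_matrix.max(axis=0).sum()) > SCALE_RANGE:
        col_max = int_matrix.max(axis=0)
        err = np.where(int_matrix == col_max, int_matrix - exact, -np.inf)
        col_err = err.max(axis=0)
        col_err[col_max <= 0] = -np.inf
        c = int(np.argmax(col_err))
        int_matrix[int_matrix[:, c] == col_max[c], c] -= 1

    max_total = int(int_matrix.max(axis=0).sum())
    return ScaledPSSM(
        motif_id=pssm.motif_id,
        name=pssm.name,
        int_matrix=int_matrix,
        offsets=np.asarray(offsets, dtype=float),
        scale=scale,
        max_total=max_total,
    )


def score_kmer(spssm: ScaledPSSM, seq: str) -> int:
    """Scaled integer score of a k-mer; N scores the columnwise minimum (0)."""
    k = spssm.width
    if len(seq) != k:
        raise ValueError(f"sequence length {len(seq)} != motif width {k}")
    total = 0
    for i, ch in enumerate(seq.upper()):
        if ch == "N":
            total += int(spssm.int_matrix[:, i].min())
        else:
            idx = NT_INDEX.get(ch)
            if idx is None:
                raise ValueError(f"non-nucleotide character {ch!r} in sequence")
            total += int(spssm.int_matrix[idx, i])
    return total


def unscale_score(spssm: ScaledPSSM, score: int) -> float:
    """Recover the real log-odds value of a scaled total score."""
    if not (0 <= score <= SCALE_RANGE):
        raise ValueError(f"scaled score {score} outside [0, {SCALE_RANGE}]")
    return score / spssm.scale + float(spssm.offsets.sum())


def build_pvalue_table(spssm: ScaledPSSM, bg: Background | None = None) -> PValueTable:
    """Exact score distribution under i.i.d. background, by convolution.

    ``Q_0 = {0: 1}``; ``Q_i(x) = sum_b bg(b) * Q_{i-1}(x - M[b, i])``; the
    survival function of ``Q_k`` at the observed score is the P-value.
    """
    bg = bg or Background.uniform()
    bg_arr = bg.as_array()
    q = np.ones(1, dtype=float)
    for i in range(spssm.width):
        col = spssm.int_matrix[:, i]
        new = np.zeros(len(q) + int(col.max()), dtype=float)
        for b in range(4):
            new[col[b] : col[b] + len(q)] += bg_arr[b] * q
        q = new
    survival = np.cumsum(q[::-1])[::-1]
    return PValueTable(pmf=q, survival=survival)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted P-values (q-values), returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("P-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def reverse_complement_pssm(spssm: ScaledPSSM) -> ScaledPSSM:
    """Mirror a scaled matrix so it scores the reverse-complement strand.

    Rows are complemented and columns reversed; scoring a sequence with the
    result equals scoring its reverse complement with the original.
    """
    return ScaledPSSM(
        motif_id=spssm.motif_id,
        name=spssm.name,
        int_matrix=spssm.int_matrix[::-1, ::-1].copy(),
        offsets=spssm.offsets[::-1].copy(),
        scale=spssm.scale,
        max_total=spssm.max_total,
    )


def score_sequence_direct(pssm: PSSM, seq: str) -> float:
    """Unscaled log-odds of a k-mer by direct summation (no scaling)."""
    if len(seq) != pssm.width:
        raise ValueError("sequence length does not match motif width")
    return float(
        sum(pssm.logodds[NT_INDEX[ch], i] for i, ch in enumerate(seq.upper()))
    )
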