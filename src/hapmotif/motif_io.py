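"""Parsing and writing of motif models (JASPAR / MEME minimal formats).

Motifs are held as :class:`PWM` objects — 4 x k matrices of counts or
probabilities over the DNA alphabet A, C, G, T. ``pwm_to_probabilities``
converts counts to pseudocount-regularised probability matrices ready for
log-odds scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")
NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

_PROB_COLSUM_TOL = 1e-6


class MotifFormatError(ValueError):
    """Raised when a motif file does not conform to its declared format."""


class UnsupportedAlphabetError(MotifFormatError):
    """Raised when a motif file declares a non-ACGT alphabet."""


class DegenerateColumnError(ValueError):
    """Raised when a count column is all-zero and no pseudocount is given."""


@dataclass(frozen=True)
class Background:
    """I.i.d. background nucleotide distribution.

    Parameters
    ----------
    probabilities
        Mapping ``{"A": pA, "C": pC, "G": pG, "T": pT}``; each must lie in
        (0, 1) and the four must sum to 1 (tolerance 1e-9).
    """

    probabilities: dict = field(
        default_factory=lambda: {b: 0.25 for b in NUCLEOTIDES}
    )

    def __post_init__(self) -> None:
        missing = set(NUCLEOTIDES) - set(self.probabilities)
        if missing:
            raise ValueError(f"background missing nucleotides: {sorted(missing)}")
        vals = [self.probabilities[b] for b in NUCLEOTIDES]
        if any(not (0.0 < v < 1.0) for v in vals):
            raise ValueError("background probabilities must lie in (0, 1)")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {sum(vals)!r}, not 1")

    def as_array(self) -> np.ndarray:
        """Probabilities as a length-4 array in A, C, G, T order."""
        return np.array([self.probabilities[b] for b in NUCLEOTIDES], dtype=float)

    @classmethod
    def uniform(cls) -> "Background":
        return cls()

    @classmethod
    def from_array(cls, probs) -> "Background":
        return cls({b: float(p) for b, p in zip(NUCLEOTIDES, probs)})


@dataclass
class PWM:
    """A position weight matrix: per-position nucleotide counts or probabilities.

    Attributes
    ----------
    motif_id : str
        Accession, e.g. ``"MA0139.1"``.
    name : str
        Human-readable name, e.g. ``"CTCF"``.
    matrix : numpy.ndarray
        Shape ``(4, k)``; rows indexed A, C, G, T; entries >= 0.
    is_probability : bool
        True when every column sums to ~1.
    """

    motif_id: str
    name: str
    matrix: np.ndarray
    is_probability: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"PWM matrix must be 4 x k, got {self.matrix.shape}")
        if self.matrix.shape[1] < 1:
            raise ValueError("PWM must have width >= 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")
        if self.is_probability:
            colsums = self.matrix.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > _PROB_COLSUM_TOL):
                raise ValueError("probability PWM has a column not summing to 1")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])

    def consensus(self) -> str:
        """Highest-weight nucleotide at each position (ties: A<C<G<T order)."""
        return "".join(NUCLEOTIDES[i] for i in np.argmax(self.matrix, axis=0))


def _columns_are_probabilities(matrix: np.ndarray) -> bool:
    return bool(np.all(np.abs(matrix.sum(axis=0) - 1.0) <= _PROB_COLSUM_TOL))


# --------------------------------------------------------------------------
# JASPAR
# --------------------------------------------------------------------------

_JASPAR_ROW_RE = re.compile(r"^\s*([ACGTacgt])\s*[:|]?\s*\[?\s*([^\[\]]*?)\s*\]?\s*$")


def parse_jaspar(text: str) -> PWM:
    """Parse a single JASPAR-format record.

    Accepts both the bracketed dialect (``A [ 3 0 5 ]``) and the
    bracket-free one (``A 3 0 5``); nucleotide rows may appear in any order.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MotifFormatError("empty JASPAR record")
    header = lines[0].strip()
    if header.startswith(">"):
        parts = header[1:].split(None, 1)
        motif_id = parts[0] if parts else ""
        name = parts[1].strip() if len(parts) > 1 else motif_id
        rows_txt = lines[1:]
    else:
        motif_id = name = "motif"
        rows_txt = lines
    if not motif_id:
        raise MotifFormatError("JASPAR header carries no identifier")

    rows: dict[str, list[float]] = {}
    for ln in rows_txt:
        m = _JASPAR_ROW_RE.match(ln)
        if m is None:
            raise MotifFormatError(f"unparseable JASPAR row: {ln!r}")
        base = m.group(1).upper()
        if base in rows:
            raise MotifFormatError(f"duplicate JASPAR row for {base}")
        try:
            rows[base] = [float(x) for x in m.group(2).split()]
        except ValueError as exc:
            raise MotifFormatError(f"non-numeric value in row {base}: {ln!r}") from exc

    missing = set(NUCLEOTIDES) - set(rows)
    if missing:
        raise MotifFormatError(f"JASPAR record missing rows: {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise MotifFormatError(f"ragged JASPAR rows, lengths {sorted(lengths)}")
    if lengths == {0}:
        raise MotifFormatError("JASPAR rows carry no values")

    matrix = np.array([rows[b] for b in NUCLEOTIDES], dtype=float)
    if np.any(matrix < 0):
        raise MotifFormatError("negative value in JASPAR matrix")
    return PWM(
        motif_id=motif_id,
        name=name,
        matrix=matrix,
        is_probability=_columns_are_probabilities(matrix),
    )


def write_jaspar(pwm: PWM) -> str:
    """Serialise a PWM to bracketed JASPAR text."""
    out = [f">{pwm.motif_id} {pwm.name}"]
    for i, b in enumerate(NUCLEOTIDES):
        vals = " ".join(_fmt_num(v) for v in pwm.matrix[i])
        out.append(f"{b} [ {vals} ]")
    return "\n".join(out) + "\n"


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# --------------------------------------------------------------------------
# MEME minimal
# --------------------------------------------------------------------------


def parse_meme(text: str) -> tuple[list[PWM], Background | None]:
    """Parse a MEME minimal-format file.

    Returns the motifs in file order plus the file's background distribution
    (``None`` when no ``Background letter frequencies`` section is present).
    Probability rows must sum to 1 within 1e-3.
    """
    lines = text.splitlines()
    motifs: list[PWM] = []
    background: Background | None = None
    i = 0
    n = len(lines)
    saw_version = False
    while i < n:
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("ALPHABET"):
            alph = line.split("=", 1)[-1].strip().upper().replace(" ", "")
            if alph not in ("ACGT", "DNA"):
                raise UnsupportedAlphabetError(
                    f"unsupported alphabet {alph!r}; only ACGT is handled"
                )
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            probs = {}
            for b, v in zip(tokens[0::2], tokens[1::2]):
                if b.upper() not in NT_INDEX:
                    raise UnsupportedAlphabetError(
                        f"background letter {b!r} outside ACGT"
                    )
                probs[b.upper()] = float(v)
            background = Background(probs)
            continue
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifFormatError(f"MOTIF line carries no identifier: {line!r}")
            motif_id = parts[1]
            name = parts[2] if len(parts) > 2 else motif_id
            i += 1
            # seek the letter-probability matrix header
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifFormatError(
                        f"MOTIF {motif_id} lacks a letter-probability matrix"
                    )
                i += 1
            if i >= n:
                raise MotifFormatError(
                    f"MOTIF {motif_id} lacks a letter-probability matrix"
                )
            header = lines[i]
            m = re.search(r"w=\s*(\d+)", header)
            declared_w = int(m.group(1)) if m else None
            i += 1
            rows = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                try:
                    row = [float(x) for x in s.split()]
                except ValueError:
                    break
                if len(row) != 4:
                    raise MotifFormatError(
                        f"MOTIF {motif_id}: matrix row has {len(row)} values, expected 4"
                    )
                if abs(sum(row) - 1.0) > 1e-3:
                    raise MotifFormatError(
                        f"MOTIF {motif_id}: probability row sums to {sum(row)!r}"
                    )
                rows.append(row)
                i += 1
            if not rows:
                raise MotifFormatError(f"MOTIF {motif_id} has an empty matrix")
            if declared_w is not None and declared_w != len(rows):
                raise MotifFormatError(
                    f"MOTIF {motif_id}: declared w={declared_w} but found {len(rows)} rows"
                )
            matrix = np.array(rows, dtype=float).T  # rows A,C,G,T x positions
            # renormalise away the <=1e-3 tolerance so downstream invariants hold
            matrix = matrix / matrix.sum(axis=0, keepdims=True)
            motifs.append(
                PWM(motif_id=motif_id, name=name, matrix=matrix, is_probability=True)
            )
            continue
        i += 1
    if not saw_version:
        raise MotifFormatError("not a MEME minimal file (no 'MEME version' line)")
    if not motifs:
        raise MotifFormatError("MEME file contains no MOTIF block")
    return motifs, background


def write_meme(pwms: list[PWM], background: Background | None = None) -> str:
    """Serialise probability PWMs to MEME minimal text."""
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    if background is not None:
        out.append("Background letter frequencies")
        out.append(
            " ".join(
                f"{b} {background.probabilities[b]:.6f}" for b in NUCLEOTIDES
            )
        )
        out.append("")
    for pwm in pwms:
        if not pwm.is_probability:
            raise ValueError(
                f"motif {pwm.motif_id} holds counts; convert to probabilities first"
            )
        out.append(f"MOTIF {pwm.motif_id} {pwm.name}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0"
        )
        for col in pwm.matrix.T:
            out.append(" ".join(f"{v:.6f}" for v in col))
        out.append("")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# Counts -> probabilities
# --------------------------------------------------------------------------


def pwm_to_probabilities(
    pwm: PWM, bg: Background | None = None, pseudocount: float = 0.1
) -> PWM:
    """Convert a count (or probability) PWM to a probability PWM.

    Each cell becomes ``(c(b,i) + pseudocount * bg(b)) / (N_i + pseudocount)``
    where ``N_i`` is the column count total. Probability inputs behave as
    counts with ``N_i = 1``, so a positive pseudocount also regularises them.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = bg or Background.uniform()
    colsums = pwm.matrix.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        bad = int(np.flatnonzero(colsums == 0)[0])
        raise DegenerateColumnError(
            f"column {bad + 1} of motif {pwm.motif_id} has zero total count and "
            "pseudocount is 0"
        )
    bg_col = bg.as_array()[:, None]
    probs = (pwm.matrix + pseudocount * bg_col) / (colsums + pseudocount)
    return PWM(
        motif_id=pwm.motif_id, name=pwm.name, matrix=probs, is_probability=True
    )


# --------------------------------------------------------------------------
# File-level convenience
# --------------------------------------------------------------------------


def read_motif_file(path: str) -> tuple[list[PWM], Background | None]:
    """Read a motif file, auto-detecting JASPAR vs MEME minimal format."""
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("MEME") or "letter-probability matrix" in text:
        return parse_meme(text)
    # a JASPAR file may concatenate several records
    pwms = []
    chunks = re.split(r"(?m)^(?=>)", text)
    for chunk in chunks:
        if chunk.strip():
            pwms.append(parse_jaspar(chunk))
    if not pwms:
        raise MotifFormatError(f"no motif records found in {path}")
    return pwms, None
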