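"""Position weight matrices and promoter scanning.

Transcription factor binding sites (TFBS) are detected with a
matrix-similarity score: each window of the promoter is scored by the sum of
the per-position base probabilities, normalised by the maximal attainable
sum, so a window spelling the consensus at every position scores exactly 1.0.
Both strands are scanned; reverse-strand matches are reported on forward
coordinates (0-based, half-open) with strand ``-``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """A position weight matrix over A/C/G/T.

    Parameters
    ----------
    id : str
        Matrix identifier (e.g. a JASPAR accession or a library name).
    matrix : ndarray of shape (length, 4)
        Per-position base probabilities; every row must sum to 1.
    min_score : float
        Default matrix-similarity threshold used when scanning.
    """

    id: str
    matrix: np.ndarray
    min_score: float = 0.85

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: matrix must have shape (L, 4)")
        if len(self.matrix) < 4:
            raise ValueError(f"PWM {self.id}: length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id}: rows must sum to 1")
        if not (0 < self.min_score <= 1):
            raise ValueError(f"PWM {self.id}: min_score must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        """Highest-probability base at every position."""
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score_total(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass(frozen=True, order=True)
class TfbsMatch:
    """One PWM hit on a promoter, forward coordinates, half-open."""

    promoter_id: str
    pwm_id: str
    start: int
    end: int
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.upper().encode(), dtype=np.uint8)
              == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Similarity score of every window; NaN where the window contains N."""
    L = len(matrix)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = codes.copy()
    bad = safe < 0
    safe[bad] = 0
    for i in range(L):
        scores += matrix[i, safe[i:i + n_win]]
        valid &= ~bad[i:i + n_win]
    scores /= matrix.max(axis=1).sum()
    scores[~valid] = np.nan
    # 12-decimal rounding keeps threshold comparisons and the score-1.0
    # consensus identity free of float accumulation jitter
    return np.round(scores, 12)


def scan_pwm(sequence: str, pwm: Pwm, promoter_id: str = "",
             min_score: float | None = None) -> list[TfbsMatch]:
    """Scan one promoter with one PWM on both strands.

    Returns every window whose similarity score reaches ``min_score``
    (default: the PWM's own threshold). Overlapping matches are allowed;
    windows containing N are skipped. A sequence shorter than the matrix
    yields an empty list.
    """
    threshold = pwm.min_score if min_score is None else min_score
    codes = _encode(sequence)
    L = len(pwm)
    out: list[TfbsMatch] = []
    # reverse-strand hits = forward scan with the reverse-complement matrix
    rc_matrix = pwm.matrix[::-1, ::-1]
    for strand, matrix in (("+", pwm.matrix), ("-", rc_matrix)):
        scores = _window_scores(codes, matrix)
        hits = np.flatnonzero(scores >= threshold)  # NaN never passes
        for s in hits:
            out.append(TfbsMatch(promoter_id, pwm.id, int(s), int(s) + L,
                                 strand, float(scores[s])))
    out.sort(key=lambda m: (m.start, m.strand, m.pwm_id))
    return out


def scan_promoters(promoters: dict[str, str], pwms: dict[str, Pwm],
                   min_score: float | None = None,
                   ) -> dict[str, list[TfbsMatch]]:
    """Scan every promoter with every PWM; returns matches per promoter."""
    scans: dict[str, list[TfbsMatch]] = {}
    for pid, seq in promoters.items():
        matches: list[TfbsMatch] = []
        for pwm in pwms.values():
            matches.extend(scan_pwm(seq, pwm, pid, min_score=min_score))
        matches.sort(key=lambda m: (m.start, m.strand, m.pwm_id))
        scans[pid] = matches
    return scans


# ---------------------------------------------------------------------------
# PWM library readers/writers


def read_jaspar(handle_or_path) -> dict[str, Pwm]:
    """Read a JASPAR-format PWM file (counts normalised to probabilities)."""
    from Bio import motifs

    if isinstance(handle_or_path, (str, bytes)):
        with open(handle_or_path) as fh:
            records = motifs.parse(fh, "jaspar")
    else:
        records = motifs.parse(handle_or_path, "jaspar")
    out: dict[str, Pwm] = {}
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T
        probs = counts / counts.sum(axis=1, keepdims=True)
        name = m.matrix_id or m.name
        out[name] = Pwm(name, probs)
    return out


def read_pwm_table(handle_or_path) -> dict[str, Pwm]:
    """Read the simple tabular PWM dialect.

    Tab-separated columns ``pwm_id, position, A, C, G, T``; one row per
    matrix position, positions 0-based and contiguous per matrix.
    """
    import pandas as pd

    df = pd.read_csv(handle_or_path, sep="\t")
    out: dict[str, Pwm] = {}
    for pwm_id, grp in df.groupby("pwm_id", sort=False):
        grp = grp.sort_values("position")
        out[str(pwm_id)] = Pwm(str(pwm_id), grp[list(BASES)].to_numpy())
    return out


def write_pwm_table(pwms: dict[str, Pwm], path) -> None:
    rows = []
    for pwm in pwms.values():
        for pos, row in enumerate(pwm.matrix):
            rows.append((pwm.id, pos, *row))
    import pandas as pd

    pd.DataFrame(rows, columns=["pwm_id", "position", *BASES]).to_csv(
        path, sep="\t", index=False)
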