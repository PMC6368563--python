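"""Log-odds PWM scoring with exact match p-values under a zero-order background.

The match statistic is the log2 likelihood ratio summed over motif positions;
its null distribution under independent background base frequencies is computed
exactly (up to score discretization) by dynamic programming over an integer
score grid, one position-wise convolution per motif column. A window's p-value
is the survival probability P(score >= s) at its discretized score, mirroring
the approach FIMO-class scanners take.

Conventions: log base 2; additive pseudocount c * background before the ratio
(c = 0.1 by default) so every cell is finite; discretization at ``scale`` grid
units per log2 unit (1000 by default), which keeps the absolute rounding error
of a width-w motif below w / (2 * scale) log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidBackgroundError, ResolutionError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_SCALE = 1000
MAX_GRID = 50_000_000  # DP grid cells before we refuse and ask for a smaller scale

#: sentinel returned by pvalue_threshold_score when no window can pass
NO_PASSING_SCORE = np.iinfo(np.int64).max


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character (N) to -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-column base probabilities plus a zero-order
    background over the same alphabet."""

    name: str
    probs: np.ndarray  # (w, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # (4,)

    @classmethod
    def from_rows(
        cls,
        name: str,
        rows,
        background=(0.25, 0.25, 0.25, 0.25),
        renormalize: bool = True,
    ) -> "PWM":
        probs = np.asarray(rows, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"PWM {name!r}: probability matrix must be (w, 4)")
        if (probs < 0).any():
            raise ValueError(f"PWM {name!r}: negative probabilities")
        if renormalize:
            sums = probs.sum(axis=1, keepdims=True)
            if (sums <= 0).any():
                raise ValueError(f"PWM {name!r}: all-zero probability row")
            probs = probs / sums
        bg = np.asarray(background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-6:
            bg = bg / bg.sum()
        return cls(name=name, probs=probs, background=bg)

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: rows do not sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError(f"PWM {self.name!r}: background does not sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class LogOddsMatrix:
    """Pseudocount-regularized log2 likelihood-ratio matrix with its integer
    discretization: int_entries = round(entries * scale)."""

    source: str
    entries: np.ndarray  # (w, 4) float log2 LLR
    scale: int
    int_entries: np.ndarray  # (w, 4) int64
    background: np.ndarray  # (4,)

    @property
    def width(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the discretized score: pmf and survival
    function P(score >= s) over the reachable integer grid."""

    min_score: int  # grid offset of support[0]
    pmf: np.ndarray
    survival: np.ndarray

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.pmf) - 1

    def pvalue(self, int_score: int) -> float:
        """Survival probability at an integer score; scores below the support
        have p = 1, scores above it cannot arise from scoring."""
        if int_score <= self.min_score:
            return 1.0
        if int_score > self.max_score:
            return 0.0
        return float(self.survival[int_score - self.min_score])


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    window_start: int  # 0-based on the forward sequence
    strand: str  # "+" or "-"
    score: float  # log2 LLR
    pvalue: float


def build_log_odds(
    pwm: PWM,
    pseudocount_frac: float = DEFAULT_PSEUDOCOUNT,
    scale: int = DEFAULT_SCALE,
) -> LogOddsMatrix:
    """entry(i, a) = log2((p[i,a] + c*b[a]) / ((1+c) * b[a])) with c > 0."""
    if pseudocount_frac <= 0:
        raise ValueError("pseudocount_frac must be > 0")
    bg = pwm.background
    if (bg <= 0).any():
        raise InvalidBackgroundError(
            f"PWM {pwm.name!r}: background has a zero-probability base"
        )
    entries = np.log2((pwm.probs + pseudocount_frac * bg) / ((1 + pseudocount_frac) * bg))
    int_entries = np.rint(entries * scale).astype(np.int64)
    return LogOddsMatrix(
        source=pwm.name,
        entries=entries,
        scale=scale,
        int_entries=int_entries,
        background=bg.copy(),
    )


def score_window(lom: LogOddsMatrix, window: str, strand: str = "+") -> float:
    """Sum of per-position entries for a single window; the minus strand scores
    the reverse complement of the window against the forward matrix."""
    if len(window) != lom.width:
        raise ValueError(f"window length {len(window)} != motif width {lom.width}")
    if strand == "-":
        window = reverse_complement(window)
    idx = encode_sequence(window)
    if (idx < 0).any():
        raise ValueError("window contains an ambiguous base (N)")
    return float(lom.entries[np.arange(lom.width), idx].sum())


def _minus_strand_matrix(matrix: np.ndarray) -> np.ndarray:
    """Equivalent matrix for scoring the forward sequence as the minus strand:
    row i becomes complemented row w-1-i."""
    return matrix[::-1][:, _COMPLEMENT_INDEX]


def exact_pvalue_table(lom: LogOddsMatrix) -> ScoreDistribution:
    """Exact pmf/survival of the integer score under the zero-order background.

    D_0 = {0: 1}; D_i(s) = sum_a background[a] * D_{i-1}(s - int_entry(i, a)).
    Matches brute-force enumeration over all 4^w windows on the integer grid.
    """
    ints = lom.int_entries
    bg = lom.background
    mins = ints.min(axis=1)
    maxs = ints.max(axis=1)
    grid = int((maxs - mins).sum()) + 1
    if grid > MAX_GRID:
        raise ResolutionError(
            f"score grid of {grid} cells exceeds {MAX_GRID}; reduce scale"
        )
    pmf = np.ones(1)
    base = 0
    for i in range(lom.width):
        lo, hi = int(mins[i]), int(maxs[i])
        new = np.zeros(len(pmf) + hi - lo)
        for a in range(4):
            off = int(ints[i, a]) - lo
            new[off : off + len(pmf)] += bg[a] * pmf
        pmf = new
        base += lo
    survival = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(min_score=base, pmf=pmf, survival=survival)


def pvalue_threshold_score(dist: ScoreDistribution, alpha: float) -> int:
    """Smallest achievable score s (pmf > 0) with P(score >= s) <= alpha, or
    NO_PASSING_SCORE when even the maximum achievable score is too frequent."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha {alpha} outside (0, 1]")
    support = np.nonzero(dist.pmf > 0)[0]
    passing = support[dist.survival[support] <= alpha]
    if len(passing) == 0:
        return NO_PASSING_SCORE
    return dist.min_score + int(passing[0])


def _window_int_scores(int_matrix: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Integer scores of every window of an encoded sequence against one
    integer matrix; windows containing N get a sentinel minimum."""
    w = int_matrix.shape[0]
    n_win = len(idx) - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for i in range(w):
        col = idx[i : i + n_win]
        valid &= col >= 0
        scores += int_matrix[i, np.where(col >= 0, col, 0)]
    scores[~valid] = np.iinfo(np.int64).min
    return scores


def scan_sequence(
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
    seq: str,
    alpha: float = 1e-3,
) -> list[MotifMatch]:
    """Scan every window start on both strands, emitting matches with
    pvalue <= alpha. Windows containing N are skipped."""
    w = lom.width
    if len(seq) < w:
        return []
    idx = encode_sequence(seq.upper())
    matches: list[MotifMatch] = []
    for strand, int_m, float_m in (
        ("+", lom.int_entries, lom.entries),
        ("-", _minus_strand_matrix(lom.int_entries), _minus_strand_matrix(lom.entries)),
    ):
        int_scores = _window_int_scores(int_m, idx)
        for start in np.nonzero(int_scores > np.iinfo(np.int64).min)[0]:
            p = dist.pvalue(int(int_scores[start]))
            if p <= alpha:
                window = idx[start : start + w]
                score = float(float_m[np.arange(w), window].sum())
                matches.append(
                    MotifMatch(
                        motif=lom.source,
                        window_start=int(start),
                        strand=strand,
                        score=score,
                        pvalue=p,
                    )
                )
    matches.sort(key=lambda m: (m.window_start, m.strand))
    return matches
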