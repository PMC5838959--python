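"""Log-odds PWM construction, double-stranded scanning, and exact score
p-values.

A position frequency matrix (PFM, base counts per column) is turned into a
position weight matrix (PWM) of log2-odds scores against a background
composition.  Matches are reported on the *relative score* scale

    rel_score = (score - s_min) / (s_max - s_min)

where ``s_min``/``s_max`` are the least/greatest achievable log-odds sums,
the convention used by JASPAR-ecosystem scanners; the canonical X-box scan
threshold is rel_score >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and N as -1; any other symbol is an error."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = (arr < 0) & (
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8) != ord("N")
    ) & (np.frombuffer(seq.encode("ascii"), dtype=np.uint8) != ord("n"))
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos}")
    return arr


@dataclass(frozen=True)
class Pwm:
    """Log2-odds matrix (rows A, C, G, T) with achievable score range."""

    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float
    s_min: float
    s_max: float
    matrix_id: str = ""
    name: str = ""

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def score_at_rel(self, rel: float) -> float:
        return self.s_min + rel * (self.s_max - self.s_min)

    def rel_score(self, score: float) -> float:
        return (score - self.s_min) / (self.s_max - self.s_min)

    @property
    def reverse_matrix(self) -> np.ndarray:
        # complement = reverse row order (A<->T, C<->G), reverse columns
        return self.matrix[::-1, ::-1]


@dataclass(frozen=True)
class MotifHit:
    """A PWM match; ``offset`` is the promoter-coordinate position of the
    match's 5'-most base (TSS-relative when the scan origin is the TSS)."""

    window_id: str
    offset: int
    strand: str
    score: float
    rel_score: float


def build_pwm(
    pfm: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
    matrix_id: str = "",
    name: str = "",
) -> Pwm:
    """Build a log2-odds PWM from a 4 x L count matrix.

    Column probabilities use a background-distributed pseudocount:
    ``p(b,j) = (count(b,j) + pc * background(b)) / (N_j + pc)``.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4 or pfm.shape[1] < 1:
        raise ValueError("PFM must be a 4 x L matrix with L >= 1")
    if (pfm < 0).any():
        raise ValueError("PFM counts must be non-negative")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    totals = pfm.sum(axis=0)
    if pseudocount <= 0 and (totals == 0).any():
        raise ValueError("all-zero PFM column with zero pseudocount")
    p = (pfm + pseudocount * background[:, None]) / (totals + pseudocount)
    matrix = np.log2(p / background[:, None])
    s_min = float(matrix.min(axis=0).sum())
    s_max = float(matrix.max(axis=0).sum())
    return Pwm(matrix, background, float(pseudocount), s_min, s_max,
               matrix_id, name)


def _position_scores(matrix: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Score every start position of a 2-D batch of encoded sequences.

    ``enc`` is (n_seq, seq_len) with -1 for N; returns (n_seq, n_pos) with
    NaN at positions whose window contains an N.
    """
    L = matrix.shape[1]
    n_pos = enc.shape[1] - L + 1
    if n_pos <= 0:
        return np.empty((enc.shape[0], 0))
    scores = np.zeros((enc.shape[0], n_pos))
    valid = np.ones((enc.shape[0], n_pos), dtype=bool)
    safe = np.where(enc < 0, 0, enc)
    for j in range(L):
        col = safe[:, j : j + n_pos]
        scores += matrix[col, j]
        valid &= enc[:, j : j + n_pos] >= 0
    scores[~valid] = np.nan
    return scores


def scan_batch(
    pwm: Pwm, enc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward- and reverse-strand scores for a batch of encoded sequences.

    Both arrays are indexed by the forward-coordinate position of the
    match's 5'-most base; N-containing windows are NaN.
    """
    fwd = _position_scores(pwm.matrix, enc)
    rev = _position_scores(pwm.reverse_matrix, enc)
    return fwd, rev


def scan(
    pwm: Pwm,
    sequence: str,
    rel_threshold: float = 0.8,
    window_id: str = "",
    origin: int = 0,
) -> list[MotifHit]:
    """Scan both strands, returning hits with rel_score >= threshold.

    ``origin`` is the sequence index of the TSS; reported offsets are
    ``position - origin``.  Sequences shorter than the motif yield an empty
    list.  Hits are sorted by offset, then ``+`` before ``-``.
    """
    if len(sequence) < pwm.length:
        return []
    enc = encode_sequence(sequence)[None, :]
    fwd, rev = scan_batch(pwm, enc)
    span = pwm.s_max - pwm.s_min
    threshold = pwm.score_at_rel(rel_threshold)
    hits: list[MotifHit] = []
    for strand, scores in (("+", fwd[0]), ("-", rev[0])):
        # rounding guard so rel_score == threshold is kept
        idx = np.flatnonzero(scores >= threshold - 1e-12)
        for i in idx:
            s = float(scores[i])
            hits.append(
                MotifHit(window_id, int(i) - origin, strand, s,
                         (s - pwm.s_min) / span)
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def score_pvalue(pwm: Pwm, score: float, granularity: float = 1e-3) -> float:
    """Exact P(S >= score) under the background model.

    Dynamic programming over the integer lattice obtained by rounding each
    matrix entry to ``granularity``; column distributions are convolved.
    The rounding error of the reported tail point is at most
    ``L * granularity`` in score.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    if score <= pwm.s_min:
        return 1.0
    if score > pwm.s_max:
        return 0.0
    k = np.rint(pwm.matrix / granularity).astype(np.int64)  # 4 x L
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.length):
        col = k[:, j]
        c_lo, c_hi = int(col.min()), int(col.max())
        new = np.zeros(len(cur) + (c_hi - c_lo))
        for b in range(4):
            shift = int(col[b]) - c_lo
            new[shift : shift + len(cur)] += pwm.background[b] * cur
        cur = new
        cur_lo += c_lo
    t = int(np.rint(score / granularity))
    idx = t - cur_lo
    if idx <= 0:
        return 1.0
    if idx >= len(cur):
        return 0.0
    return float(cur[idx:].sum())


def hits_to_rows(hits: list[MotifHit], profile_id: str = "") -> list[dict]:
    rows = []
    for h in hits:
        row = {
            "window_id": h.window_id,
            "offset": h.offset,
            "strand": h.strand,
            "score": h.score,
            "rel_score": h.rel_score,
        }
        if profile_id:
            row["profile_id"] = profile_id
        rows.append(row)
    return rows
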