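"""TF binding-profile over-representation against GC-matched backgrounds.

For each binding profile, predicted sites are counted in the foreground
regions and in a 10-fold larger GC-matched random background; the
foreground count is scored by a continuity-corrected binomial z-score
using the background hit rate, and profiles with z above the mean + 2 sd
of the whole z distribution are called over-represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif_scanning import Pwm, encode_sequence, scan_batch


@dataclass
class EnrichmentResult:
    profile_id: str
    fg_hits: int
    bg_hits: int
    fg_positions: int
    bg_positions: int
    rate_bg: float
    z: float
    over_represented: bool = False


def gc_fraction(sequence: str) -> float:
    """(G + C) / (A + C + G + T); N bases excluded from both sides."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all-N (or empty) sequence has no GC fraction")
    return (counts["G"] + counts["C"]) / total


def sample_gc_matched(
    pool_sequences: dict[str, str],
    fg_sequences: dict[str, str],
    fold: int = 10,
    bin_width: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Draw ``fold`` background sequences per foreground sequence from the
    pool, matched on GC-content bins of ``bin_width``.

    Sampling is without replacement; when a bin is exhausted the draw
    spills to the nearest non-empty bin (ties: lower GC first), with a
    warning.  Deterministic under a seeded generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_needed = fold * len(fg_sequences)
    if len(pool_sequences) < n_needed:
        raise ValueError(
            f"pool too small: need {n_needed}, have {len(pool_sequences)}"
        )

    def gc_bin(seq: str) -> int:
        return min(int(gc_fraction(seq) / bin_width), int(1 / bin_width) - 1)

    bins: dict[int, list[str]] = {}
    for name in pool_sequences:
        bins.setdefault(gc_bin(pool_sequences[name]), []).append(name)
    for b in bins.values():
        perm = rng.permutation(len(b))
        b[:] = [b[i] for i in perm]

    selected: list[str] = []
    spilled = 0
    for name in fg_sequences:
        target = gc_bin(fg_sequences[name])
        for _ in range(fold):
            if bins.get(target):
                selected.append(bins[target].pop())
                continue
            # nearest non-empty bin; ties resolved to the lower-GC bin
            candidates = [b for b, lst in bins.items() if lst]
            if not candidates:
                raise ValueError("background pool globally exhausted")
            nearest = min(candidates, key=lambda b: (abs(b - target), b))
            selected.append(bins[nearest].pop())
            spilled += 1
    if spilled:
        warnings.warn(
            f"GC-matched sampling spilled {spilled} draws to adjacent bins",
            stacklevel=2,
        )
    return selected


def _encode_groups(sequences: dict[str, str]) -> list[np.ndarray]:
    """Encode sequences into 2-D batches grouped by length."""
    by_len: dict[int, list[np.ndarray]] = {}
    for seq in sequences.values():
        by_len.setdefault(len(seq), []).append(encode_sequence(seq))
    return [np.vstack(rows) for rows in by_len.values()]


def _count_hits_encoded(
    pwm: Pwm, groups: list[np.ndarray], rel_threshold: float
) -> tuple[int, int]:
    threshold = pwm.score_at_rel(rel_threshold) - 1e-12
    hits = 0
    positions = 0
    for enc in groups:
        if enc.shape[1] < pwm.length:
            continue
        fwd, rev = scan_batch(pwm, enc)
        for scores in (fwd, rev):
            valid = ~np.isnan(scores)
            positions += int(valid.sum())
            hits += int((scores[valid] >= threshold).sum())
    return hits, positions


def count_hits(
    pwm: Pwm, sequences: dict[str, str], rel_threshold: float = 0.8
) -> tuple[int, int]:
    """(hits, scannable positions) over both strands of all sequences.

    Scannable positions are ``2 * (len - L + 1)`` per sequence minus
    N-skipped windows.
    """
    return _count_hits_encoded(pwm, _encode_groups(sequences), rel_threshold)


def profile_zscore(
    fg_hits: int, bg_hits: int, fg_positions: int, bg_positions: int
) -> float:
    """Continuity-corrected binomial z-score of the foreground hit count
    under the background hit rate; z = 0 when the rate is degenerate."""
    if fg_positions <= 0 or bg_positions <= 0:
        raise ValueError("positions must be > 0")
    p = bg_hits / bg_positions
    mu = p * fg_positions
    sigma = np.sqrt(fg_positions * p * (1 - p))
    if sigma == 0:
        warnings.warn("degenerate background rate (sigma = 0): z set to 0",
                      stacklevel=2)
        return 0.0
    return float((fg_hits - mu - 0.5) / sigma)


def call_overrepresented(zscores: dict[str, float]) -> set[str]:
    """Profiles with z strictly above mean + 2 * sd of all z-scores
    (sample sd, n-1 denominator); empty when sd = 0."""
    if len(zscores) < 2:
        raise ValueError("need at least 2 profiles")
    z = np.array(list(zscores.values()), dtype=float)
    m = z.mean()
    sd = z.std(ddof=1)
    if sd == 0:
        return set()
    threshold = m + 2 * sd
    return {k for k, v in zscores.items() if v > threshold}


def enrichment_analysis(
    fg_sequences: dict[str, str],
    bg_sequences: dict[str, str],
    pwms: dict[str, Pwm],
    rel_threshold: float = 0.8,
) -> pd.DataFrame:
    """Score every profile and call over-represented ones; rows sorted by
    z descending."""
    fg_groups = _encode_groups(fg_sequences)
    bg_groups = _encode_groups(bg_sequences)
    results = []
    for profile_id, pwm in pwms.items():
        fg_hits, fg_pos = _count_hits_encoded(pwm, fg_groups, rel_threshold)
        bg_hits, bg_pos = _count_hits_encoded(pwm, bg_groups, rel_threshold)
        z = profile_zscore(fg_hits, bg_hits, fg_pos, bg_pos)
        results.append(EnrichmentResult(
            profile_id, fg_hits, bg_hits, fg_pos, bg_pos,
            bg_hits / bg_pos if bg_pos else 0.0, z,
        ))
    if len(results) >= 2:
        called = call_overrepresented({r.profile_id: r.z for r in results})
    else:
        warnings.warn("fewer than 2 profiles: over-representation not called",
                      stacklevel=2)
        called = set()
    for r in results:
        r.over_represented = r.profile_id in called
    frame = pd.DataFrame([vars(r) for r in results])
    return frame.sort_values("z", ascending=False).reset_index(drop=True)
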