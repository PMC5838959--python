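"""Enhancer-promoter linking by expression correlation with FDR control.

Candidate pairs are all same-chromosome enhancers whose midpoint lies
within +/-500 kb of a promoter's TSS point; each pair is tested by
Spearman correlation over shared samples with Benjamini-Hochberg control
of the false discovery rate at q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicRegion


@dataclass
class EnhancerLink:
    enhancer: GenomicRegion
    promoter_id: str
    distance_bp: int
    rho: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def candidate_pairs(
    promoters: list[tuple[str, GenomicRegion]],
    enhancers: list[GenomicRegion],
    window_bp: int = 500_000,
) -> list[tuple[str, GenomicRegion, int]]:
    """All same-chromosome (promoter, enhancer) pairs with
    |midpoint - TSS point| <= window_bp.

    The returned distance is signed and strand-oriented (positive =
    enhancer downstream of the TSS in transcription direction); the
    midpoint of an even-length region is the left-of-center base.
    """
    pairs = []
    for pid, prom in promoters:
        for enh in enhancers:
            if enh.chrom != prom.chrom:
                continue
            delta = enh.midpoint - prom.tss_point
            if abs(delta) > window_bp:
                continue
            signed = delta if prom.strand == "+" else -delta
            pairs.append((pid, enh, signed))
    return pairs


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho via average ranks; two-sided p from the
    t-approximation t = rho * sqrt((n-2) / (1-rho^2))."""
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc * rxc).sum() * (ryc * ryc).sum())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((rxc * ryc).sum() / denom)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * t_dist.sf(abs(t), n - 2)
    return rho, float(p)


def spearman_link(
    pairs: list[tuple[str, GenomicRegion, int]],
    values: pd.DataFrame,
    fdr: float = 0.05,
) -> list[EnhancerLink]:
    """Test every candidate pair; BH q-values are pooled over all tested
    pairs and significance is strict q < fdr.

    ``values`` must contain both promoter and enhancer expression rows over
    a shared sample space (>= 10 samples).  Constant profiles make rho
    undefined; such pairs are dropped with a warning.
    """
    if values.shape[1] < 10:
        raise ValueError("need at least 10 shared samples")
    links: list[EnhancerLink] = []
    dropped = 0
    for pid, enh, dist in pairs:
        x = values.loc[pid].to_numpy(dtype=float)
        y = values.loc[enh.name].to_numpy(dtype=float)
        rho, p = _spearman(x, y)
        if np.isnan(rho):
            dropped += 1
            continue
        links.append(EnhancerLink(enh, pid, int(dist), rho, p))
    if dropped:
        warnings.warn(
            f"dropped {dropped} pair(s) with constant profiles", stacklevel=2
        )
    if links:
        pvals = np.array([l.p_value for l in links])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for link, q in zip(links, qvals):
            link.q_value = float(q)
            # strict q < fdr; the relative guard keeps q values that equal
            # the threshold up to float rounding (e.g. 0.04*5/4) excluded
            link.significant = bool(q < fdr * (1 - 1e-9))
    return links


def links_table(links: list[EnhancerLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(promoter=l.promoter_id, enhancer=l.enhancer.name,
              chrom=l.enhancer.chrom, distance_bp=l.distance_bp,
              rho=l.rho, p_value=l.p_value, q_value=l.q_value,
              significant=l.significant) for l in links]
    )
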