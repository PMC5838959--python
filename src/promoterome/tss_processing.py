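"""Consolidation of raw CAGE TSS into named promoters.

Raw CAGE peaks of one gene are merged when they lie within 100 bp and
their tissue expression profiles correlate at r >= 0.7; merged promoters
below a TPM-1 tissue noise floor are discarded unless rescued by a
primary-cell or cell-line TPM >= 5; survivors are named pA, pB, ... in
descending order of total TPM over all samples, and classified by
expression breadth (broad / specific / low / noise) over the tissue panel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GenomicRegion


@dataclass(frozen=True)
class RawTss:
    """A raw CAGE peak: genomic region, owning gene, TPM profile."""

    region: GenomicRegion
    gene: str
    profile: np.ndarray

    def __post_init__(self):
        profile = np.asarray(self.profile, dtype=float)
        if (profile < 0).any():
            raise ValueError(f"{self.region.name}: negative TPM in profile")
        object.__setattr__(self, "profile", profile)

    @property
    def tss_id(self) -> str:
        return self.region.name


@dataclass
class PromoterRecord:
    gene: str
    span: GenomicRegion
    members: list[str]
    profile: np.ndarray
    rank_name: str = ""

    @property
    def total_tpm(self) -> float:
        return float(self.profile.sum())

    @property
    def name(self) -> str:
        return f"{self.rank_name}@{self.gene}" if self.rank_name else self.gene


@dataclass(frozen=True)
class ExpressionClass:
    label: str  # broad | specific | low | noise
    n_tissues_over5: int
    max_tissue_tpm: float
    dominant_organ: str
    organ_dominance: float
    multi_organ: bool


@dataclass(frozen=True)
class DomainComposition:
    """Presence of the five conserved family domains: activation (AD),
    DNA-binding (DBD), B, C and dimerization (DIM)."""

    has_AD: bool
    has_DBD: bool
    has_B: bool
    has_C: bool
    has_DIM: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with zero-variance vectors defined as r = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def read_raw_tss_table(path, expr: ExpressionMatrix) -> list[RawTss]:
    """Read a raw TSS table (tss_id, gene, chrom, start, end, strand) and
    attach the expression row of each TSS."""
    table = pd.read_csv(path, sep="\t", dtype={"tss_id": str, "gene": str})
    required = {"tss_id", "gene", "chrom", "start", "end", "strand"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(table.columns))}"
        )
    out = []
    for row in table.itertuples():
        if row.tss_id not in expr.values.index:
            raise ValueError(f"{path}: TSS {row.tss_id} absent from expression matrix")
        region = GenomicRegion(row.chrom, int(row.start), int(row.end),
                               row.strand, row.tss_id)
        out.append(RawTss(region, row.gene,
                          expr.values.loc[row.tss_id].to_numpy()))
    return out


def write_raw_tss_table(raw: list[RawTss], path) -> None:
    pd.DataFrame(
        [dict(tss_id=r.tss_id, gene=r.gene, chrom=r.region.chrom,
              start=r.region.start, end=r.region.end,
              strand=r.region.strand) for r in raw]
    ).to_csv(path, sep="\t", index=False)


def merge_tss(
    raw: list[RawTss],
    expr: ExpressionMatrix,
    min_corr: float = 0.7,
    max_dist_bp: int = 100,
) -> list[PromoterRecord]:
    """Merge raw TSS of each gene into promoter clusters (unnamed).

    Single left-to-right pass over the gene's TSS sorted by 5' point: a TSS
    joins the open cluster iff its 5' point is within ``max_dist_bp`` of
    the nearest member's 5' point (inclusive) AND the Pearson r between its
    tissue-sample vector and the cluster's current summed tissue vector is
    >= ``min_corr``; otherwise a new cluster opens.  Merged profile is the
    per-sample sum; merged span the union.  Zero-variance tissue vectors
    have r defined as 0 and never merge.  Mixed strands or chromosomes
    within one gene are a hard error.
    """
    tissue_mask = expr.category_mask("tissue")
    out: list[PromoterRecord] = []
    by_gene: dict[str, list[RawTss]] = {}
    for r in raw:
        by_gene.setdefault(r.gene, []).append(r)

    for gene, members in by_gene.items():
        chroms = {m.region.chrom for m in members}
        strands = {m.region.strand for m in members}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {gene}: raw TSS span multiple chromosomes/strands"
            )
        members = sorted(members, key=lambda m: m.region.tss_point)
        clusters: list[list[RawTss]] = []
        for tss in members:
            if clusters:
                cluster = clusters[-1]
                dist = min(abs(tss.region.tss_point - m.region.tss_point)
                           for m in cluster)
                summed = np.sum([m.profile for m in cluster], axis=0)
                r = _pearson(tss.profile[tissue_mask], summed[tissue_mask])
                if dist <= max_dist_bp and r >= min_corr:
                    cluster.append(tss)
                    continue
            clusters.append([tss])
        for cluster in clusters:
            start = min(m.region.start for m in cluster)
            end = max(m.region.end for m in cluster)
            span = GenomicRegion(cluster[0].region.chrom, start, end,
                                 cluster[0].region.strand,
                                 cluster[0].region.name)
            profile = np.sum([m.profile for m in cluster], axis=0)
            out.append(PromoterRecord(gene, span,
                                      [m.tss_id for m in cluster], profile))
    return out


def filter_tss(
    records: list[PromoterRecord],
    expr: ExpressionMatrix,
    tissue_noise: float = 1.0,
    rescue_tpm: float = 5.0,
) -> tuple[list[PromoterRecord], list[PromoterRecord]]:
    """Drop promoters whose highest tissue TPM is below the noise floor,
    unless rescued by a primary-cell or cell-line TPM >= ``rescue_tpm``."""
    tissue = expr.category_mask("tissue")
    pc = expr.category_mask("primary_cell")
    cl = expr.category_mask("cell_line")
    kept, discarded = [], []
    for rec in records:
        max_tissue = rec.profile[tissue].max() if tissue.any() else 0.0
        max_pc = rec.profile[pc].max() if pc.any() else 0.0
        max_cl = rec.profile[cl].max() if cl.any() else 0.0
        if max_tissue >= tissue_noise or max_pc >= rescue_tpm \
                or max_cl >= rescue_tpm:
            kept.append(rec)
        else:
            discarded.append(rec)
    return kept, discarded


def _rank_letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA (spreadsheet-style)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def name_promoters(records: list[PromoterRecord]) -> list[PromoterRecord]:
    """Assign pA, pB, ... within each gene by descending total TPM over all
    samples; ties broken by ascending genomic start coordinate."""
    by_gene: dict[str, list[PromoterRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)
    out = []
    for gene, recs in by_gene.items():
        recs = sorted(recs, key=lambda r: (-r.total_tpm, r.span.start))
        for i, rec in enumerate(recs):
            rec.rank_name = f"p{_rank_letters(i)}"
            out.append(rec)
    return out


def classify_expression(
    record: PromoterRecord,
    expr: ExpressionMatrix,
    expr_tpm: float = 5.0,
    broad_n: int = 10,
    noise_tpm: float = 1.0,
) -> ExpressionClass:
    """Classify a promoter's expression breadth over the tissue panel.

    noise: max tissue TPM < 1; low: < 5; else broad when more than
    ``broad_n`` tissues exceed ``expr_tpm``, specific otherwise.  The
    dominant organ is the one with the largest share of summed tissue TPM;
    ``multi_organ`` flags expressed tissues spanning more than one organ.
    """
    tissue = expr.category_mask("tissue")
    tpm = record.profile[tissue]
    organs = expr.meta.loc[tissue, "organ"].to_numpy()
    max_tissue = float(tpm.max()) if tpm.size else 0.0
    over = tpm > expr_tpm
    n_over = int(over.sum())

    totals: dict[str, float] = {}
    for organ in np.unique(organs):
        totals[organ] = float(tpm[organs == organ].sum())
    total = sum(totals.values())
    if total > 0:
        dominant_organ = max(totals, key=lambda o: (totals[o], o))
        dominance = totals[dominant_organ] / total
    else:
        dominant_organ, dominance = "", 0.0
    multi_organ = len(set(organs[over])) > 1

    if max_tissue < noise_tpm:
        label = "noise"
    elif max_tissue < expr_tpm:
        label = "low"
    elif n_over > broad_n:
        label = "broad"
    else:
        label = "specific"
    return ExpressionClass(label, n_over, max_tissue, dominant_organ,
                           dominance, multi_organ)


def call_novel(
    record: PromoterRecord,
    annotated_starts: list[GenomicRegion],
    tol_bp: int = 50,
) -> tuple[str | None, bool]:
    """Match a promoter's 5' TSS point to the nearest same-strand annotated
    start within ``tol_bp`` (point-to-point); no match means novel.

    Equidistant candidates resolve to the 5'-most one relative to the
    promoter's strand (lower coordinate on +, higher on -).
    """
    point = record.span.tss_point
    best: tuple[int, int, str] | None = None
    for ann in annotated_starts:
        if ann.strand != record.span.strand or ann.chrom != record.span.chrom:
            continue
        ann_point = ann.tss_point
        dist = abs(ann_point - point)
        if dist > tol_bp:
            continue
        # 5'-most tie-break: prefer lower coordinate on +, higher on -
        tie_key = ann_point if record.span.strand == "+" else -ann_point
        if best is None or (dist, tie_key) < (best[0], best[1]):
            best = (dist, tie_key, ann.name)
    if best is None:
        return None, True
    return best[2], False


def assign_domain_group(dc: DomainComposition) -> str:
    """Map a domain composition onto the family's four structural groups.

    Group 1: all five domains; group 2: all but the activation domain;
    group 3: only the DBD; group 4: no DBD; anything else is "other".
    """
    others = (dc.has_AD, dc.has_B, dc.has_C, dc.has_DIM)
    if not dc.has_DBD:
        return "4"
    if not any(others):
        return "3"
    if all(others):
        return "1"
    if not dc.has_AD and dc.has_B and dc.has_C and dc.has_DIM:
        return "2"
    return "other"


def promoters_to_bed(records: list[PromoterRecord]) -> list[GenomicRegion]:
    return [
        replace(rec.span, name=rec.name, score=round(rec.total_tpm, 3))
        for rec in records
    ]


def classification_table(
    records: list[PromoterRecord],
    expr: ExpressionMatrix,
    annotated_starts: list[GenomicRegion] | None = None,
    **kwargs,
) -> pd.DataFrame:
    rows = []
    for rec in records:
        cls = classify_expression(rec, expr, **kwargs)
        match_id, novel = (None, None)
        if annotated_starts is not None:
            match_id, novel = call_novel(rec, annotated_starts)
        rows.append(dict(
            promoter=rec.name, gene=rec.gene, chrom=rec.span.chrom,
            start=rec.span.start, end=rec.span.end, strand=rec.span.strand,
            members=",".join(rec.members), total_tpm=rec.total_tpm,
            label=cls.label, n_tissues_over5=cls.n_tissues_over5,
            max_tissue_tpm=cls.max_tissue_tpm,
            dominant_organ=cls.dominant_organ,
            organ_dominance=cls.organ_dominance, multi_organ=cls.multi_organ,
            matched_transcript=match_id, is_novel=novel,
        ))
    return pd.DataFrame(rows)
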