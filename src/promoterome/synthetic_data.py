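"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a CAGE promoterome
study of a small transcription-factor gene family: a log-normal TPM matrix
over tissue / primary-cell / cell-line samples with planted organ-group
structure, TSS-relative promoter windows with motif instances planted at
controlled rates and positional laws over an i.i.d. background, annotation
start sites at controlled offsets, enhancers with controlled Spearman
correlation to chosen TSS (Gaussian copula), and qPCR Ct tables with known
true fold changes and amplification efficiencies.

Determinism: every generator draws from its own ``numpy`` Generator seeded
as ``default_rng([seed, STREAM])`` with a fixed per-generator stream id, so
outputs are byte-identical under a fixed seed and independent of call
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GenomicRegion

# per-generator RNG stream ids
_STREAM_EXPR = 1
_STREAM_WINDOWS = 2
_STREAM_ANNOT = 3
_STREAM_ENH = 4
_STREAM_QPCR = 5
_STREAM_PFM = 6

ORGANS = ("immune", "gi", "testis", "brain", "uterus", "lung")
# adult/fetal tissue sample counts per organ, totalling 135 as in a
# FANTOM5-scale tissue panel
_TISSUES_PER_ORGAN = {"immune": 30, "gi": 30, "testis": 15, "brain": 30,
                      "uterus": 10, "lung": 20}


def default_sample_design() -> list[tuple[str, str, str, int]]:
    """(category, tissue_label, organ, n) rows: 135 tissues across six
    organ systems, 170 primary-cell and 255 cell-line samples."""
    design = []
    for organ, n in _TISSUES_PER_ORGAN.items():
        for i in range(n):
            design.append(("tissue", f"{organ}_t{i + 1}", organ, 1))
    design.append(("primary_cell", "primary_cell", "cell", 170))
    design.append(("cell_line", "cell_line", "cell", 255))
    return design


@dataclass
class SimulationConfig:
    """Study conditions for all generators; defaults emulate the scale and
    thresholds of the source CAGE atlas analysis."""

    seed: int = 0
    n_genes: int = 8
    n_tss_per_gene: int = 4
    sample_design: list[tuple[str, str, str, int]] = field(
        default_factory=default_sample_design
    )
    lognormal_sigma: float = 0.5
    # promoter windows
    window_up: int = 5000
    window_down: int = 2000
    gc_content: float = 0.5
    motif_rate_fg: float = 2.0
    motif_rate_bg: float = 0.5
    motif_position_law: tuple | None = ("normal", 0.0, 300.0)
    background_fold: int = 10
    # annotation offsets (signed bp, downstream positive), cycled over TSS
    annotation_offsets: tuple[int, ...] = (0, 30, -45, 200, 10, -300, 50, 120)
    # enhancers
    n_enhancers: int = 13
    enhancer_rho: float = 0.8
    enhancer_length: int = 400
    # qPCR: (gene, true_fc, efficiency); reference genes have true_fc 1
    qpcr_truth: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("RFX1", 1.3, 2.0), ("RFX2", 2.0, 1.9), ("RFX3", 1.6, 2.0),
            ("RFX5", 0.7, 1.9), ("RFX7", 2.5, 2.0),
        ]
    )
    qpcr_references: list[tuple[str, float]] = field(
        default_factory=lambda: [("HPRT1", 2.0), ("HSPCB", 2.0)]
    )
    n_bio_replicates: int = 6
    n_tech_replicates: int = 3
    ct_noise: float = 0.1

    def __post_init__(self):
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")
        if self.motif_rate_fg < 0 or self.motif_rate_bg < 0:
            raise ValueError("motif rates must be >= 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def window_length(self) -> int:
        return self.window_up + self.window_down + 1

    @property
    def base_probs(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


# ---------------------------------------------------------------------------
# TSS roster and expression

def default_tss_plan(config: SimulationConfig) -> pd.DataFrame:
    """Roster of raw TSS with planted expression archetypes.

    Kinds: ``broad`` (high in every organ), ``specific`` (high in one
    organ), ``low`` (max tissue TPM < 5), ``noise_rescued`` (max tissue
    TPM < 1, rescued by a cell-line TPM >= 5) and ``noise_dropped``
    (below every filter).  A subset of specific TSS carry a ``merge_partner``
    placed within 100 bp with a proportional profile, emulating CAGE peak
    pairs of one promoter that the consolidation step should merge.
    """
    rows = []
    organs = list(ORGANS)
    for g in range(1, config.n_genes + 1):
        gene = f"GENE{g}"
        chrom = f"chr{g}"
        strand = "+" if g % 2 == 1 else "-"
        organ = organs[(g - 1) % len(organs)]
        base = 1_000_000
        kinds = ["broad", "specific", "low"]
        if g >= 7:
            kinds.append("noise_rescued" if g == 7 else "noise_dropped")
        for i, kind in enumerate(kinds):
            tss_id = f"{gene}.t{i + 1}"
            pos = base + i * 5000
            rows.append(dict(tss_id=tss_id, gene=gene, chrom=chrom,
                             start=pos, end=pos + 20, strand=strand,
                             kind=kind, organ=organ, merge_partner_of=""))
            # plant a CAGE peak pair on the specific TSS of genes 1..7
            if kind == "specific" and g <= 7:
                rows.append(dict(tss_id=f"{tss_id}b", gene=gene, chrom=chrom,
                                 start=pos + 40, end=pos + 60, strand=strand,
                                 kind=kind, organ=organ,
                                 merge_partner_of=tss_id))
    return pd.DataFrame(rows)


_KIND_MEANS = {
    # (tissue-in-organ, tissue-elsewhere, primary_cell, cell_line)
    "broad": (20.0, 20.0, 15.0, 15.0),
    "specific": (40.0, 0.3, 2.0, 5.0),
    "low": (1.2, 0.3, 1.0, 2.0),
    "noise_rescued": (0.1, 0.05, 0.5, 8.0),
    "noise_dropped": (0.1, 0.05, 0.5, 0.5),
}

# a "specific" TSS is expressed in only this many tissues of its organ,
# keeping the expressed-tissue count below the broad/specific boundary
_SPECIFIC_N_TISSUES = 8


def sample_metadata_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    counters: dict[str, int] = {}
    for category, label, organ, n in config.sample_design:
        for _ in range(n):
            counters[category] = counters.get(category, 0) + 1
            rows.append(dict(sample_id=f"{category}_{counters[category]}",
                             category=category, tissue_label=label,
                             organ=organ))
    return pd.DataFrame(rows)


def gen_expression_matrix(
    config: SimulationConfig, plan: pd.DataFrame | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-normal TPM matrix with planted organ-group structure.

    ``value[i, s] = group_mean(i, group(s)) * exp(N(0, sigma^2))``; exact
    zeros where the group mean is zero.  Merge-partner rows are
    proportional (factor 0.5) to their primary peak's realized profile.
    Returns the matrix and the truth table (the plan).
    """
    rng = config.rng(_STREAM_EXPR)
    if plan is None:
        plan = default_tss_plan(config)
    meta = sample_metadata_frame(config)
    n_s = len(meta)
    organ_arr = meta["organ"].to_numpy()
    cat_arr = meta["category"].to_numpy()

    explicit = {"mean_in_organ", "mean_elsewhere", "mean_pc",
                "mean_cl"}.issubset(plan.columns)
    means = np.zeros((len(plan), n_s))
    for i, row in enumerate(plan.itertuples()):
        if explicit:
            in_organ, elsewhere, pc, cl = (row.mean_in_organ,
                                           row.mean_elsewhere,
                                           row.mean_pc, row.mean_cl)
        else:
            in_organ, elsewhere, pc, cl = _KIND_MEANS[row.kind]
        organ_mask = (organ_arr == row.organ) & (cat_arr == "tissue")
        if row.kind == "specific":
            # restrict high expression to the first few tissues of the organ
            keep = np.flatnonzero(organ_mask)[:_SPECIFIC_N_TISSUES]
            organ_mask = np.zeros_like(organ_mask)
            organ_mask[keep] = True
        mean_row = np.where(cat_arr == "primary_cell", pc,
                            np.where(cat_arr == "cell_line", cl,
                                     np.where(organ_mask, in_organ,
                                              elsewhere)))
        means[i] = mean_row

    noise = np.exp(rng.normal(0.0, config.lognormal_sigma, size=means.shape))
    values = means * noise
    values[means == 0] = 0.0

    # merge partners: proportional to the primary peak's realized profile
    idx = {t: i for i, t in enumerate(plan["tss_id"])}
    for i, row in enumerate(plan.itertuples()):
        if row.merge_partner_of:
            values[i] = 0.5 * values[idx[row.merge_partner_of]]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=list(plan["tss_id"]),
                     columns=list(meta["sample_id"])),
        meta,
    )
    return expr, plan.copy()


# ---------------------------------------------------------------------------
# Promoter windows with planted motifs

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(mat: np.ndarray) -> list[str]:
    return [bytes(_DECODE[row]).decode("ascii") for row in mat]


def _sample_offsets(rng, law, lo: int, hi: int, n: int) -> np.ndarray:
    """Draw n planting offsets in [lo, hi]; resample out-of-range draws up
    to 100 times each."""
    out = np.empty(n, dtype=int)
    for i in range(n):
        for attempt in range(100):
            if law is None:
                o = int(rng.integers(lo, hi + 1))
            elif law[0] == "uniform":
                o = int(np.floor(rng.uniform(law[1], law[2] + 1)))
            elif law[0] == "normal":
                o = int(np.rint(rng.normal(law[1], law[2])))
            else:
                raise ValueError(f"unknown position law {law!r}")
            if lo <= o <= hi:
                out[i] = o
                break
        else:
            raise ValueError(
                f"could not place motif instance within [{lo}, {hi}] "
                f"after 100 tries (law {law!r})"
            )
    return out


def gen_promoter_windows(
    config: SimulationConfig,
    pfm: np.ndarray,
    n_windows: int,
    motif_rate: float,
    position_law: tuple | None,
    id_prefix: str = "w",
    stream: int = _STREAM_WINDOWS,
) -> tuple[dict[str, str], list[GenomicRegion], pd.DataFrame]:
    """TSS-centred sequence windows with Poisson-planted motif instances.

    Background bases are i.i.d. from the configured composition; each
    window receives ``Poisson(motif_rate)`` instances whose letters are
    sampled from the PFM's per-column frequencies, placed at offsets drawn
    from ``position_law`` (offset = position of the instance's 5'-most base
    relative to the TSS), on either strand with probability 1/2.

    Returns (sequences, single-base TSS BED records, truth table of planted
    instances).
    """
    rng = config.rng(stream)
    pfm = np.asarray(pfm, dtype=float)
    L = pfm.shape[1]
    length = config.window_length
    col_probs = pfm / pfm.sum(axis=0, keepdims=True)

    mat = rng.choice(4, size=(n_windows, length), p=config.base_probs)
    mat = mat.astype(np.int8)

    lo = -config.window_up
    hi = config.window_down - L + 1
    counts = rng.poisson(motif_rate, size=n_windows)
    truth_rows = []
    for w in range(n_windows):
        if counts[w] == 0:
            continue
        offsets = _sample_offsets(rng, position_law, lo, hi, counts[w])
        for o in offsets:
            word = np.array(
                [rng.choice(4, p=col_probs[:, j]) for j in range(L)],
                dtype=np.int8,
            )
            strand = "+" if rng.random() < 0.5 else "-"
            planted = word if strand == "+" else (3 - word)[::-1]
            start = o + config.window_up
            mat[w, start : start + L] = planted
            truth_rows.append(dict(window_id=f"{id_prefix}{w + 1}",
                                   offset=int(o), strand=strand))

    ids = [f"{id_prefix}{w + 1}" for w in range(n_windows)]
    seqs = dict(zip(ids, _decode(mat)))
    tss = [
        GenomicRegion("chrW", 100_000 + w * (length + 1000) + config.window_up,
                      100_000 + w * (length + 1000) + config.window_up + 1,
                      "+", ids[w])
        for w in range(n_windows)
    ]
    truth = pd.DataFrame(truth_rows, columns=["window_id", "offset", "strand"])
    return seqs, tss, truth


# ---------------------------------------------------------------------------
# Annotation starts

def gen_annotation(
    config: SimulationConfig, tss: list[GenomicRegion]
) -> tuple[list[GenomicRegion], pd.DataFrame]:
    """Annotated transcript starts at configured signed offsets from each
    TSS (positive = downstream in transcription direction); truth marks
    which fall within the +/-50 bp novelty tolerance."""
    offsets = config.annotation_offsets
    regions, rows = [], []
    for i, t in enumerate(tss):
        off = offsets[i % len(offsets)]
        point = t.tss_point + off if t.strand == "+" else t.tss_point - off
        point = max(point, 0)
        regions.append(GenomicRegion(t.chrom, point, point + 1, t.strand,
                                     f"ENST_{t.name}"))
        rows.append(dict(tss_id=t.name, offset=off,
                         within_tolerance=abs(off) <= 50))
    return regions, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Enhancers (Gaussian copula on ranks)

def _normal_scores(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm, rankdata

    r = rankdata(x, method="average")
    return norm.ppf((r - 0.5) / len(x))


def gen_enhancers(
    config: SimulationConfig,
    expr: ExpressionMatrix,
    tss_regions: list[GenomicRegion],
) -> tuple[list[GenomicRegion], pd.DataFrame, pd.DataFrame]:
    """Enhancer regions paired with TSS, with controlled Spearman rho.

    Enhancer expression is built by a Gaussian copula on the paired TSS
    profile's normal scores (Pearson parameter r = 2 sin(pi * rho / 6)),
    then mapped through exp() to a TPM-like scale; rho = 1 degenerates to a
    monotone transform of the TSS profile.  Roughly half the enhancers use
    the configured rho, the rest are independent (rho = 0); some are placed
    beyond the +/-500 kb candidate window as negative controls.

    Returns (enhancer BED records, enhancer expression frame aligned to the
    samples of ``expr``, truth table).
    """
    rng = config.rng(_STREAM_ENH)
    distances = [50_000, -120_000, 300_000, -480_000, 150_000, 620_000]
    regions, rows, profiles = [], [], []
    row_ids = expr.row_ids
    for k in range(config.n_enhancers):
        tss = tss_regions[k % len(tss_regions)]
        dist = distances[k % len(distances)]
        rho = config.enhancer_rho if k % 2 == 0 else 0.0
        mid = tss.tss_point + (dist if tss.strand == "+" else -dist)
        start = max(mid - config.enhancer_length // 2, 0)
        name = f"enh{k + 1}"
        regions.append(GenomicRegion(tss.chrom, start,
                                     start + config.enhancer_length, "+", name))
        x = expr.values.loc[tss.name].to_numpy() if tss.name in row_ids else \
            expr.values.iloc[k % len(row_ids)].to_numpy()
        z = _normal_scores(x)
        if rho >= 1.0:
            ze = z
        else:
            r = 2 * np.sin(np.pi * rho / 6)
            ze = r * z + np.sqrt(1 - r * r) * rng.standard_normal(len(z))
        profiles.append(5.0 * np.exp(ze))
        rows.append(dict(enhancer_id=name, paired_tss=tss.name,
                         target_rho=rho, distance=dist,
                         in_window=abs(dist) <= 500_000))
    enh_values = pd.DataFrame(
        np.asarray(profiles), index=[r.name for r in regions],
        columns=list(expr.values.columns),
    )
    return regions, enh_values, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables

def gen_qpcr_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ct table (gene, condition, bio/tech replicate, ct) with known truth.

    ``Ct(test) = Ct(scr) - log_E(true_fc) + N(0, ct_noise^2)`` per
    technical measurement; reference genes have true fold change 1.
    Returns (ct table, efficiency table, truth table).
    """
    rng = config.rng(_STREAM_QPCR)
    genes = list(config.qpcr_truth) + [
        (g, 1.0, e) for g, e in config.qpcr_references
    ]
    ct_rows, eff_rows, truth_rows = [], [], []
    for gene, fc, eff in genes:
        eff_rows.append(dict(gene=gene, efficiency=eff))
        truth_rows.append(dict(gene=gene, true_fc=fc, efficiency=eff))
        shift = log(fc) / log(eff)
        for b in range(1, config.n_bio_replicates + 1):
            base = 20.0 + rng.normal(0.0, 0.5)
            for cond, delta in (("scr", 0.0), ("test", -shift)):
                for t in range(1, config.n_tech_replicates + 1):
                    noise = rng.normal(0.0, config.ct_noise) \
                        if config.ct_noise > 0 else 0.0
                    ct_rows.append(dict(gene=gene, condition=cond,
                                        bio_replicate=b, tech_replicate=t,
                                        ct=base + delta + noise))
    return (pd.DataFrame(ct_rows), pd.DataFrame(eff_rows),
            pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# PFMs

def default_xbox_pfm() -> tuple[str, str, np.ndarray]:
    """A synthetic 14-column imperfect-inverted-repeat PFM.

    Stand-in for a curated X-box binding profile: strongly conserved
    half-sites (GTTGCC ... GGCAAC) around a degenerate 2-bp spacer, 100
    observations per column.  Purely synthetic - not a JASPAR matrix.
    """
    consensus = "GTTGCCATGGCAAC"
    strong, weak = 82.0, 6.0
    counts = np.full((4, len(consensus)), weak)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strong
    # degenerate spacer columns
    for j in (6, 7):
        counts[:, j] = 25.0
    return "SYN0001", "XBOX_SYNTH", counts


def gen_profile_panel(
    config: SimulationConfig, n_profiles: int = 50, length: int = 10,
) -> list[tuple[str, str, np.ndarray]]:
    """A panel of binding profiles for over-representation scans: the
    synthetic X-box profile plus ``n_profiles - 1`` random informative
    profiles, emulating a curated vertebrate profile collection."""
    rng = config.rng(_STREAM_PFM)
    panel = [default_xbox_pfm()]
    for k in range(1, n_profiles):
        panel.append((f"SYN{k + 1:04d}", f"RANDOM_TF_{k}",
                      gen_random_pfm(rng, length=length)))
    return panel


def gen_random_pfm(
    rng: np.random.Generator, length: int = 10, n_obs: int = 100,
    concentration: float = 0.2,
) -> np.ndarray:
    """Random informative PFM: per-column Dirichlet frequencies scaled to
    ``n_obs`` observations.

    The default concentration produces information-rich columns comparable
    to curated vertebrate TF binding profiles, so that instances sampled
    from the column frequencies usually clear an 80% relative-score scan
    threshold."""
    freqs = rng.dirichlet(np.full(4, concentration), size=length).T
    return np.rint(freqs * n_obs) + 1.0
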