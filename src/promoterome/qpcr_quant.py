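"""Efficiency-adjusted qPCR fold changes with two-reference normalization.

Relative quantification follows the efficiency-adjusted ratio method:
within each biological replicate, technical replicates are averaged on the
Ct scale, per-gene ratios are ``E_g ^ (Ct_scr - Ct_test)``, and the target
ratio is normalized by the geometric mean of the reference-gene ratios
(the two-reference generalization of the Pfaffl method).  A fold change of
1 means unchanged expression.  Significance is a two-tailed one-sample
t-test of log2(fold change) against 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_CT_COLUMNS = ("gene", "condition", "bio_replicate",
                       "tech_replicate", "ct")


@dataclass
class FoldChangeResult:
    gene: str
    fc_per_bio_rep: list[float]
    fc_mean: float        # geometric mean
    sem: float            # delta-method SEM on the fold-change scale
    p_value: float        # NaN when undefined


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = set(table["condition"]) - {"test", "scr"}
    if bad:
        raise ValueError(f"{path}: unknown conditions {sorted(bad)}")
    if (table["ct"] <= 0).any():
        raise ValueError(f"{path}: non-positive Ct values")
    return table


def read_efficiency_table(path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "efficiency"}.issubset(table.columns):
        raise ValueError(f"{path}: need gene and efficiency columns")
    eff = dict(zip(table["gene"], table["efficiency"].astype(float)))
    for gene, e in eff.items():
        if not 1.0 < e <= 2.2:
            raise ValueError(f"{path}: efficiency {e} for {gene} outside (1, 2.2]")
    return eff


def _mean_ct(ct: pd.DataFrame, gene: str, condition: str,
             bio_rep: int) -> float:
    sel = ct[(ct["gene"] == gene) & (ct["condition"] == condition)
             & (ct["bio_replicate"] == bio_rep)]
    if sel.empty:
        raise ValueError(
            f"no Ct measurements for gene={gene}, condition={condition}, "
            f"bio_replicate={bio_rep}"
        )
    return float(sel["ct"].mean())


def fold_change(
    ct: pd.DataFrame,
    efficiencies: dict[str, float],
    target: str,
    references: tuple[str, ...] = ("HPRT1", "HSPCB"),
) -> list[float]:
    """Efficiency-adjusted fold change of ``target`` per biological
    replicate, normalized by the geometric mean of the reference ratios.

    Within a biological replicate: technical Cts are averaged,
    ``ratio_g = E_g ^ (Ct_scr - Ct_test)``, and
    ``fc = ratio_target / geomean_ref(ratio_ref)``.
    """
    for gene in (target, *references):
        if gene not in efficiencies:
            raise ValueError(f"no efficiency for gene {gene}")
        if gene not in set(ct["gene"]):
            raise ValueError(f"no Ct data for gene {gene}")
    bio_reps = sorted(ct.loc[ct["gene"] == target, "bio_replicate"].unique())
    fcs = []
    for b in bio_reps:
        def ratio(gene: str) -> float:
            dct = (_mean_ct(ct, gene, "scr", b)
                   - _mean_ct(ct, gene, "test", b))
            return efficiencies[gene] ** dct

        ref_ratios = np.array([ratio(r) for r in references])
        geo_ref = float(np.exp(np.log(ref_ratios).mean()))
        fcs.append(ratio(target) / geo_ref)
    return fcs


def fc_significance(
    fc_per_bio_rep: list[float],
    control_fc: list[float] | None = None,
) -> tuple[float, float, float]:
    """Geometric-mean fold change, delta-method SEM, and two-tailed
    one-sample t-test p-value of log2(fc) against 0.

    Passing ``control_fc`` switches to a two-sample t-test of log2 fold
    changes against the control group instead (alternative convention).
    With fewer than 3 replicates or zero variance the p-value is NaN (with
    a warning for the degenerate-variance case).
    """
    fcs = np.asarray(fc_per_bio_rep, dtype=float)
    if (fcs <= 0).any():
        raise ValueError("fold changes must be > 0")
    logs = np.log2(fcs)
    geo = float(2.0 ** logs.mean())
    n = len(fcs)
    if n < 2:
        return geo, float("nan"), float("nan")
    sem_log = logs.std(ddof=1) / np.sqrt(n)
    sem = geo * np.log(2.0) * float(sem_log)
    if n < 3:
        return geo, sem, float("nan")
    if control_fc is not None:
        controls = np.log2(np.asarray(control_fc, dtype=float))
        if logs.std(ddof=1) == 0 and controls.std(ddof=1) == 0:
            warnings.warn("zero variance in both groups: t undefined",
                          stacklevel=2)
            return geo, sem, float("nan")
        _, p = stats.ttest_ind(logs, controls)
        return geo, sem, float(p)
    if logs.std(ddof=1) == 0:
        warnings.warn("zero variance in log2 fold changes: t undefined",
                      stacklevel=2)
        return geo, sem, float("nan")
    t_stat, p = stats.ttest_1samp(logs, 0.0)
    return geo, sem, float(p)


def quantify(
    ct: pd.DataFrame,
    efficiencies: dict[str, float],
    targets: list[str],
    references: tuple[str, ...] = ("HPRT1", "HSPCB"),
) -> list[FoldChangeResult]:
    results = []
    for target in targets:
        fcs = fold_change(ct, efficiencies, target, references)
        geo, sem, p = fc_significance(fcs)
        results.append(FoldChangeResult(target, fcs, geo, sem, p))
    return results


def results_table(results: list[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(gene=r.gene, fc_mean=r.fc_mean, sem=r.sem, p_value=r.p_value,
              n_bio_replicates=len(r.fc_per_bio_rep),
              fc_per_bio_rep=",".join(f"{v:.6g}" for v in r.fc_per_bio_rep))
         for r in results]
    )
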