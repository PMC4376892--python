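"""Pausing and activity classification of genes from nascent-RNA counts.

A gene is *paused* when its promoter-proximal window holds significantly
more engaged polymerase than expected were its promoter+body reads spread
uniformly over the two regions (one-sided Fisher exact test, p < 0.01).
A gene is *transcriptionally active* when its gene-body count exceeds the
uniform-background Poisson null (1% of mapped reads spread over the
mappable genome) at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import LibraryStats

__all__ = [
    "PausingCall",
    "pausing_test",
    "activity_test",
    "pausing_index",
    "classify_genes",
    "make_crosstab",
    "crosstab_fisher",
    "PAUSE_ALPHA",
    "ACTIVE_ALPHA",
]

PAUSE_ALPHA = 0.01
ACTIVE_ALPHA = 0.01


@dataclass(frozen=True)
class PausingCall:
    gene_id: str
    xp: int
    xb: int
    Lp: int
    Lb: int
    p_pause: float
    p_active: float
    pausing_index: float
    is_paused: bool
    is_active: bool


def pausing_test(xp: int, xb: int, Lp: int = 100, Lb: int = 1) -> float:
    """One-sided Fisher exact p for promoter read excess over uniformity.

    The observed counts (xp, xb) are compared against the expected split of
    the same N = xp + xb reads proportional to region lengths:
    e_p = round(N * Lp / (Lp + Lb)) (ties to even), e_b = N - e_p.  The
    returned p is the hypergeometric upper tail for promoter excess.
    """
    if Lp <= 0 or Lb <= 0:
        raise ValueError("region lengths must be positive")
    n = xp + xb
    if n == 0:
        return 1.0
    e_p = int(np.round(n * Lp / (Lp + Lb)))
    e_b = n - e_p
    _, p = sps.fisher_exact([[xp, xb], [e_p, e_b]], alternative="greater")
    return float(p)


def activity_test(xb: int, region_len: int, stats: LibraryStats) -> float:
    """Upper-tail Poisson p-value for gene-body reads exceeding background.

    The null mean is the background density (1% of mapped reads distributed
    uniformly over the mappable genome) times the mappable body length.
    """
    if region_len <= 0:
        raise ValueError("region length must be positive")
    lam = stats.background_density * region_len
    return float(sps.poisson.sf(xb - 1, lam))


def pausing_index(xp: int, xb: int, Lp: int, Lb: int) -> float:
    """Promoter/body read density ratio; sentinel -1 when the body is empty."""
    if xb == 0:
        return -1.0
    return (xp / Lp) / (xb / Lb)


def classify_genes(quant: pd.DataFrame, stats: LibraryStats, label: str,
                   pause_alpha: float = PAUSE_ALPHA,
                   active_alpha: float = ACTIVE_ALPHA) -> pd.DataFrame:
    """Apply both tests to a quantification table for one library/condition.

    ``quant`` is the output of :func:`polpause.groseq_quant.quantify_genes`;
    ``label`` selects the xp_/xb_ column pair.  Flags use strict inequality
    (p < threshold).
    """
    xp = quant[f"xp_{label}"].to_numpy()
    xb = quant[f"xb_{label}"].to_numpy()
    Lp = quant["Lp"].to_numpy()
    Lb = quant["Lb"].to_numpy()
    p_pause = np.array([pausing_test(int(a), int(b), int(lp), int(lb))
                        for a, b, lp, lb in zip(xp, xb, Lp, Lb)])
    p_active = np.array([activity_test(int(b), int(lb), stats)
                         for b, lb in zip(xb, Lb)])
    pidx = np.array([pausing_index(int(a), int(b), int(lp), int(lb))
                     for a, b, lp, lb in zip(xp, xb, Lp, Lb)])
    return pd.DataFrame({
        "gene_id": quant["gene_id"],
        "xp": xp, "xb": xb, "Lp": Lp, "Lb": Lb,
        "p_pause": p_pause, "p_active": p_active,
        "pausing_index": pidx,
        "is_paused": p_pause < pause_alpha,
        "is_active": p_active < active_alpha,
    })


def make_crosstab(calls: pd.DataFrame, subset: pd.Series | None = None) -> pd.DataFrame:
    """Paused x active cross-tabulation with margins.

    Rows: all/paused/non-paused genes; columns: all/active/inactive.  With
    ``subset`` (boolean mask or gene_id list) the table is restricted to a
    gene subset (e.g. factor-bound genes).
    """
    df = calls
    if subset is not None:
        if getattr(subset, "dtype", None) == bool:
            df = calls[np.asarray(subset)]
        else:
            df = calls[calls["gene_id"].isin(subset)]
    paused = df["is_paused"].to_numpy()
    active = df["is_active"].to_numpy()
    tab = pd.DataFrame(
        {
            "all": [len(df), int(paused.sum()), int((~paused).sum())],
            "active": [int(active.sum()), int((paused & active).sum()),
                       int((~paused & active).sum())],
            "inactive": [int((~active).sum()), int((paused & ~active).sum()),
                         int((~paused & ~active).sum())],
        },
        index=["all", "paused", "non_paused"],
    )
    return tab


def crosstab_fisher(table: np.ndarray | pd.DataFrame, sided: str = "two") -> float:
    """Fisher exact test on an inner 2x2 table.

    ``table`` is [[a, b], [c, d]]; a DataFrame in :func:`make_crosstab`
    layout is reduced to its paused/non-paused x active/inactive core.
    Two-sided p sums all fixed-margin tables at most as probable as the
    observed one.
    """
    if isinstance(table, pd.DataFrame):
        core = table.loc[["paused", "non_paused"], ["active", "inactive"]].to_numpy()
    else:
        core = np.asarray(table)
    if core.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    _, p = sps.fisher_exact(core, alternative=alternative)
    return float(p)
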