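"""F1 inheritance-mode quantification and repressive-allele classification.

The per-feature dominance coefficient d scales the F1 deviation from the
parental midpoint by half the parental range: d = (F1 - MP)/(HP - MP), so
d = -1 when the F1 equals the low parent (dominant repression), d = 0 when it
sits at the midpoint (additivity), and |d| > 1 is representable
(over/under-dominance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dominance_coefficient",
    "dominance_table",
    "classify_repressive_allele",
    "classify_repressive_alleles",
    "compare_dominance",
    "rank_sum_test",
]


def dominance_coefficient(
    b6_mean: float, d2_mean: float, f1_mean: float, epsilon: float = 0.05
) -> float:
    """Dominance coefficient d, or NaN when the parental gap is below epsilon.

    Means must be on a common normalized log2 scale. Invariant under parent
    relabeling (HP/LP are order statistics) and under affine rescaling.
    """
    hp = max(b6_mean, d2_mean)
    lp = min(b6_mean, d2_mean)
    mp = (b6_mean + d2_mean) / 2.0
    if hp - mp < epsilon:
        return float("nan")  # parental gap too small for a stable ratio
    return (f1_mean - mp) / (hp - mp)


def dominance_table(
    log2_means: pd.DataFrame, epsilon: float = 0.05
) -> pd.DataFrame:
    """Per-feature dominance from a table with columns B6, D2, F1."""
    for col in ("B6", "D2", "F1"):
        if col not in log2_means.columns:
            raise ValueError(f"log2 means table missing strain column {col!r}")
    d = [
        dominance_coefficient(r.B6, r.D2, r.F1, epsilon)
        for r in log2_means.itertuples(index=False)
    ]
    out = log2_means[["B6", "D2", "F1"]].copy()
    out["midparent"] = (out["B6"] + out["D2"]) / 2.0
    out["d"] = d
    return out


def classify_repressive_allele(effect_size: float) -> str:
    """Repressive allele from a signed B6-minus-D2 accessibility effect.

    Positive effect (B6 higher) means accessibility is lower under the D2
    genotype, so D2 is the repressive allele; negative means B6. Zero is
    unclassifiable.
    """
    if effect_size > 0:
        return "D2"
    if effect_size < 0:
        return "B6"
    return "unclassified"


def classify_repressive_alleles(targets: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification over a QTL-target table with ``effect_size``."""
    if "effect_size" not in targets.columns:
        raise ValueError("targets table must carry a signed effect_size column")
    out = targets.copy()
    out["repressive_allele"] = [
        classify_repressive_allele(e) for e in out["effect_size"].to_numpy()
    ]
    return out


def _ranksum_normal(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Tie-corrected normal-approximation rank-sum: (W, Z, two-sided p)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 0.0, 1.0
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, z, min(1.0, p)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> dict:
    """Two-sided Wilcoxon rank-sum.

    Exact by enumeration of all group assignments when the pooled size is
    small (<= ``exact_max_n``); tie-corrected normal approximation otherwise.
    The effect size r = |Z|/sqrt(N) always uses the normal-approximation Z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    w, z, p_norm = _ranksum_normal(x, y)
    if len(set(np.concatenate([x, y]).tolist())) == 1:
        return dict(W=w, Z=0.0, pvalue=1.0, effect_size_r=0.0, method="degenerate",
                    median_x=float(np.median(x)), median_y=float(np.median(y)))
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs_dev = abs(w - n1 * (n1 + n2 + 1) / 2.0)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            ws = ranks[list(idx)].sum()
            if abs(ws - n1 * (n1 + n2 + 1) / 2.0) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        p = p_norm
        method = "normal"
    r = abs(z) / math.sqrt(n1 + n2)
    return dict(
        W=w,
        Z=z,
        pvalue=float(p),
        effect_size_r=float(min(1.0, r)),
        method=method,
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
    )


def compare_dominance(
    trans_d: Sequence[float], cis_d: Sequence[float]
) -> dict:
    """Rank-sum comparison of trans vs cis dominance coefficients."""
    trans = np.asarray(trans_d, dtype=float)
    cis = np.asarray(cis_d, dtype=float)
    trans = trans[np.isfinite(trans)]
    cis = cis[np.isfinite(cis)]
    if len(trans) < 2 or len(cis) < 2:
        raise ValueError("need >= 2 finite dominance values per group")
    res = rank_sum_test(trans, cis)
    res["median_trans"] = res.pop("median_x")
    res["median_cis"] = res.pop("median_y")
    res["n_trans"] = int(len(trans))
    res["n_cis"] = int(len(cis))
    return res
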