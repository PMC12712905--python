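"""TMM normalization, confidence filtering, and NB differential testing.

Implemented natively rather than wrapping edgeR/DESeq2: the contract is the
statistical family (trimmed-mean-of-M normalization; exact conditional NB
test with a single common dispersion), not numeric mimicry of either tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, Interaction, span

__all__ = [
    "NormalizationFactors",
    "FilterSpec",
    "FilterReport",
    "tmm_factors",
    "filter_interactions",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_differential",
    "cpm",
]


@dataclass
class NormalizationFactors:
    sample_ids: list[str]
    library_sizes: np.ndarray
    factors: np.ndarray
    reference_sample: str

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """edgeR-style doubly trimmed weighted mean of M values -> log2 factor."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(m)) < 1e-6:  # identical profiles
        return 0.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep2]
    return float(np.sum(inv_w * m[keep2]) / np.sum(inv_w))


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values factors, geometric mean rescaled to 1.

    Reference = the sample whose upper-quartile of depth-scaled counts is
    closest to the across-sample mean upper-quartile.
    """
    x = counts.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = [counts.sample_ids[i] for i in np.where(lib <= 0)[0]]
        raise ValueError(f"samples with all-zero counts: {bad}")
    uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    logf = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        logf[j] = _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    factors = np.exp2(logf)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        sample_ids=list(counts.sample_ids),
        library_sizes=lib,
        factors=factors,
        reference_sample=counts.sample_ids[ref_idx],
    )


def cpm(counts: CountMatrix, factors: NormalizationFactors | None = None) -> pd.DataFrame:
    """Counts per million on effective library sizes (TMM if factors given)."""
    x = counts.values.astype(float)
    if factors is None:
        eff = x.sum(axis=0)
    else:
        if factors.sample_ids != counts.sample_ids:
            raise ValueError("normalization factors do not match count matrix samples")
        eff = factors.effective_library_sizes
    return pd.DataFrame(x / eff * 1e6, index=counts.df.index, columns=counts.df.columns)


@dataclass(frozen=True)
class FilterSpec:
    min_span_bp: int = 5000
    confidence_fdr: float = 0.01  # honored upstream; accepted as given on called input
    min_count: int = 4
    min_samples: int = 2
    di_fdr: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.di_fdr <= 1:
            raise ValueError("di_fdr must lie in (0, 1]")
        if self.min_span_bp < 0 or self.min_count < 0 or self.min_samples < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_failed_span: int
    n_failed_counts: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def filter_interactions(
    interactions: Sequence[Interaction],
    counts: CountMatrix,
    spec: FilterSpec = FilterSpec(),
) -> tuple[list[Interaction], FilterReport]:
    """High-confidence filter: span > min_span AND >= min_count in >= min_samples."""
    idx = counts.df.index
    missing = [ixn.id for ixn in interactions if ixn.id not in idx]
    if missing:
        raise KeyError(f"interactions missing count rows: {missing[:5]}")
    retained = []
    n_span = n_counts = 0
    for ixn in interactions:
        ok_span = span(ixn) > spec.min_span_bp
        row = counts.df.loc[ixn.id].to_numpy()
        ok_counts = int((row >= spec.min_count).sum()) >= spec.min_samples
        if not ok_span:
            n_span += 1
        if not ok_counts:
            n_counts += 1
        if ok_span and ok_counts:
            retained.append(ixn)
    report = FilterReport(
        n_input=len(interactions),
        n_retained=len(retained),
        n_failed_span=n_span,
        n_failed_counts=n_counts,
    )
    return retained, report


def estimate_common_dispersion(counts: CountMatrix, groups: Sequence[str]) -> float:
    """Method-of-moments common NB dispersion from within-group variability.

    Counts are scaled to a common library size; per-feature dispersion
    (s^2 - mu)/mu^2 is combined across features with mu^2 precision weights
    and clipped at zero.
    """
    x = counts.values.astype(float)
    groups = np.asarray(groups)
    if x.shape[1] < 2 or len(set(groups)) < 1:
        raise ValueError("dispersion estimation needs >= 2 samples")
    if x.shape[1] != groups.size:
        raise ValueError("groups length must match sample count")
    lib = x.sum(axis=0)
    common = np.exp(np.mean(np.log(lib)))
    scaled = x * (common / lib)

    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        cols = scaled[:, groups == g]
        if cols.shape[1] < 2:
            continue
        mu = cols.mean(axis=1)
        s2 = cols.var(axis=1, ddof=1)
        ok = mu > 0
        num += float(np.sum(s2[ok] - mu[ok]))
        den += float(np.sum(mu[ok] ** 2))
    if den == 0.0:
        raise ValueError("no informative features/groups for dispersion estimation")
    return max(0.0, num / den)


def _exact_conditional_p(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for the group-A sum given the total under common-phi NB.

    Two-sided by doubling the smaller tail, capped at 1. phi = 0 is the
    Poisson limit where the conditional law is binomial(total, n_a/(n_a+n_b)).
    """
    if total == 0:
        return 1.0
    if phi == 0.0:
        pr = n_a / (n_a + n_b)
        lo = stats.binom.cdf(s_a, total, pr)
        hi = stats.binom.sf(s_a - 1, total, pr)
        return float(min(1.0, 2.0 * min(lo, hi)))
    mu = total / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    s = np.arange(total + 1)
    logp = stats.nbinom.logpmf(s, r_a, p_a) + stats.nbinom.logpmf(total - s, r_b, p_b)
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    lo = w[: s_a + 1].sum()
    hi = w[s_a:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def nb_exact_test(
    counts: CountMatrix,
    groups: Sequence[str],
    phi: float,
    factors: NormalizationFactors | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Exact conditional NB test per feature between exactly two groups.

    Counts are rescaled ("pseudo-counts") to the geometric-mean effective
    library size before the conditional split test. log2FC is group A over
    group B on normalized means with a 0.5 pseudo-count.
    """
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(
            f"nb_exact_test requires exactly two groups, got {labels}; run pairwise"
        )
    if group_order is not None:
        if set(group_order) != set(labels):
            raise ValueError("group_order does not match group labels")
        labels = list(group_order)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")

    x = counts.values.astype(float)
    if factors is None:
        eff = x.sum(axis=0)
    else:
        eff = factors.effective_library_sizes
    common = np.exp(np.mean(np.log(eff)))
    pseudo = x * (common / eff)

    mask_a = groups == labels[0]
    mask_b = groups == labels[1]
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())

    sum_a = pseudo[:, mask_a].sum(axis=1)
    sum_b = pseudo[:, mask_b].sum(axis=1)
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    cpm_a = mean_a / common * 1e6
    cpm_b = mean_b / common * 1e6
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    # round group sums separately so the split is exchangeable under label swap
    sa = np.round(sum_a).astype(np.int64)
    sb = np.round(sum_b).astype(np.int64)
    tot = sa + sb
    pvals = np.array(
        [_exact_conditional_p(int(sa[i]), int(tot[i]), n_a, n_b, phi) for i in range(len(sa))]
    )

    return pd.DataFrame(
        {
            "mean_cpm_a": cpm_a,
            "mean_cpm_b": cpm_b,
            "log2fc": log2fc,
            "dispersion": phi,
            "pvalue": pvals,
        },
        index=counts.df.index.copy(),
    )


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_differential(results: pd.DataFrame, di_fdr: float = 0.2) -> pd.DataFrame:
    """Significant subset at q <= di_fdr with direction labels.

    Features with log2fc exactly 0 get direction ``none`` and are excluded
    from downstream directional tallies.
    """
    df = results.copy()
    if "qvalue" not in df.columns:
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    sig = df[df["qvalue"] <= di_fdr].copy()
    sig["direction"] = np.where(
        sig["log2fc"] > 0, "higher_in_a", np.where(sig["log2fc"] < 0, "higher_in_b", "none")
    )
    return sig


def differential_pipeline(
    counts: CountMatrix,
    groups: Sequence[str],
    group_order: tuple[str, str] | None = None,
    phi: float | None = None,
) -> pd.DataFrame:
    """TMM -> dispersion -> exact test -> BH, returning the full result table."""
    factors = tmm_factors(counts)
    if phi is None:
        phi = estimate_common_dispersion(counts, groups)
    res = nb_exact_test(counts, groups, phi, factors, group_order=group_order)
    res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
    return res
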