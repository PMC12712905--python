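"""Integration of differential interactions with QTL targets.

Anchor-overlap classification, permutation enrichment against a peak
universe, interaction-strength vs QTL-effect correlation, allele
concordance, and factor-binding enrichment at trans-target anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .core_io import GenomicInterval, Interaction, IntervalIndex
from .normdiff import bh_adjust

__all__ = [
    "QtlTarget",
    "classify_anchor_overlap",
    "permutation_enrichment",
    "correlate_strength_effect",
    "pair_di_targets",
    "allele_concordance",
    "factor_binding_enrichment",
]

CATEGORIES = ("none", "one_anchor", "both_anchors")


@dataclass(frozen=True)
class QtlTarget:
    target_id: str
    interval: GenomicInterval
    mode: str  # cis | trans
    high_allele: str  # B6 | D2
    lod: float
    effect_size: float  # signed, B6-minus-D2
    qtl_locus: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"mode must be cis/trans, got {self.mode!r}")
        if self.lod < 0:
            raise ValueError("LOD must be >= 0")
        if self.effect_size > 0 and self.high_allele != "B6":
            raise ValueError("positive B6-minus-D2 effect requires high_allele B6")
        if self.effect_size < 0 and self.high_allele != "D2":
            raise ValueError("negative B6-minus-D2 effect requires high_allele D2")


def _classify_one(di: Interaction, index: IntervalIndex) -> str:
    hit1 = index.any_overlap(di.anchor1)
    hit2 = index.any_overlap(di.anchor2)
    if hit1 and hit2:
        return "both_anchors"
    if hit1 or hit2:
        return "one_anchor"
    return "none"


def classify_anchor_overlap(
    dis: Sequence[Interaction], targets: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-DI overlap category plus genome-wide proportions (in ``.attrs``)."""
    index = IntervalIndex(targets)
    cats = [_classify_one(di, index) for di in dis]
    df = pd.DataFrame({"di_id": [d.id for d in dis], "category": cats})
    n = max(1, len(dis))
    df.attrs["proportions"] = {c: cats.count(c) / n for c in CATEGORIES}
    return df


@dataclass
class EnrichmentResult:
    category: str
    observed: float
    perm_values: np.ndarray
    n_perm: int
    seed: int

    @property
    def pvalue(self) -> float:
        return (1 + int(np.sum(self.perm_values >= self.observed))) / (1 + self.n_perm)

    @property
    def degenerate(self) -> bool:
        return self.n_perm == 0


def permutation_enrichment(
    dis: Sequence[Interaction],
    targets: Sequence[GenomicInterval],
    peak_universe: Sequence[GenomicInterval],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """Null: redraw |targets| peaks uniformly from the universe, reclassify.

    Returns enrichment of the observed one_anchor and both_anchors
    proportions with add-one empirical p-values.
    """
    if len(targets) > len(peak_universe):
        raise ValueError("more targets than universe peaks")
    obs = classify_anchor_overlap(dis, targets).attrs["proportions"]
    rng = np.random.default_rng(seed)
    perm = {c: np.empty(n_perm) for c in ("one_anchor", "both_anchors")}
    universe = list(peak_universe)
    for b in range(n_perm):
        idx = rng.choice(len(universe), size=len(targets), replace=False)
        fake = [universe[i] for i in idx]
        props = classify_anchor_overlap(dis, fake).attrs["proportions"]
        for c in perm:
            perm[c][b] = props[c]
    return {
        c: EnrichmentResult(c, obs[c], perm[c], n_perm, seed) for c in perm
    }


def pair_di_targets(
    dis: Sequence[Interaction],
    di_log2fc: Mapping[str, float],
    targets: Sequence[QtlTarget],
) -> pd.DataFrame:
    """One row per (DI, overlapping target) pair; a DI overlapping k targets
    contributes k rows."""
    rows = []
    from .core_io import overlaps

    for di in dis:
        if di.id not in di_log2fc:
            continue
        for t in targets:
            if overlaps(di.anchor1, t.interval) or overlaps(di.anchor2, t.interval):
                rows.append(
                    dict(
                        di_id=di.id,
                        target_id=t.target_id,
                        mode=t.mode,
                        di_log2fc=di_log2fc[di.id],
                        effect_size=t.effect_size,
                        high_allele=t.high_allele,
                    )
                )
    return pd.DataFrame(
        rows, columns=["di_id", "target_id", "mode", "di_log2fc", "effect_size", "high_allele"]
    )


def correlate_strength_effect(
    di_log2fc: Sequence[float], target_effect_sizes: Sequence[float], mode: str = ""
) -> dict:
    """Pearson correlation between paired DI fold-changes and QTL effects."""
    x = np.asarray(di_log2fc, dtype=float)
    y = np.asarray(target_effect_sizes, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the paired vectors")
    r, p = stats.pearsonr(x, y)
    return dict(r=float(r), pvalue=float(p), n=int(len(x)), mode=mode,
                pairing="one row per (DI, overlapping target) pair")


def allele_concordance(
    di_directions: Sequence[str], target_high_alleles: Sequence[str]
) -> dict:
    """Cross-tab of DI direction vs QTL high allele with a Pearson chi-squared
    test (no continuity correction). Zero margins are dropped with a flag."""
    if len(di_directions) != len(target_high_alleles):
        raise ValueError("label vectors must be the same length")
    table = pd.crosstab(pd.Series(di_directions, name="di_direction"),
                        pd.Series(target_high_alleles, name="high_allele"))
    full = table.copy()
    dropped = False
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape != full.shape:
        dropped = True
    if table.shape[0] < 2 or table.shape[1] < 2:
        return dict(table=full, chi2=0.0, df=0, pvalue=1.0,
                    concordant_fraction=float("nan"),
                    degenerate=True, dropped_margin=dropped, low_expected=False)
    obs = table.to_numpy(dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    low_expected = bool(np.mean(expected < 1) > 0.20)

    concordant = sum(
        1 for d, a in zip(di_directions, target_high_alleles)
        if (d == "higher_in_a" and a == "B6") or (d == "higher_in_b" and a == "D2")
    )
    return dict(
        table=full, chi2=chi2, df=df, pvalue=p,
        concordant_fraction=concordant / len(di_directions),
        degenerate=False, dropped_margin=dropped, low_expected=low_expected,
    )


def factor_binding_enrichment(
    binding_site_sets: Mapping[str, Sequence[GenomicInterval]],
    trans_anchor_ids: Sequence[str],
    universe: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Per-factor 2x2 Fisher enrichment of binding-site overlap within the
    trans-anchor set vs the rest of the anchor universe.

    Reports the two-sided Fisher p, the conditional-MLE odds ratio, and the
    Haldane-corrected sample odds ratio; ranked by BH q then odds ratio.
    """
    if not universe:
        raise ValueError("empty anchor universe")
    trans_set = set(trans_anchor_ids)
    in_trans = np.array([iv.name in trans_set for iv in universe])
    rows = []
    for factor, sites in binding_site_sets.items():
        index = IntervalIndex(sites)
        hit = np.array([index.any_overlap(iv) for iv in universe])
        a = int(np.sum(in_trans & hit))
        b = int(np.sum(in_trans & ~hit))
        c = int(np.sum(~in_trans & hit))
        d = int(np.sum(~in_trans & ~hit))
        table = np.array([[a, b], [c, d]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        if min(a, b, c, d) == 0:
            sample_or = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            sample_or = (a * d) / (b * c)
        try:
            cond_or = float(_cond_odds_ratio(table).statistic)
        except ValueError:
            cond_or = float("nan")
        rows.append(dict(factor=factor, a=a, b=b, c=c, d=d,
                         odds_ratio=cond_or, sample_odds_ratio=float(sample_or),
                         pvalue=float(p)))
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df = df.sort_values(["qvalue", "sample_odds_ratio"], ascending=[True, False])
    return df.reset_index(drop=True)
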