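"""Cross-assay fold-change analysis distinguishing trans from cis regulation.

Includes the discordant-chromatin-state call (accessibility and H3K9me3
moving in opposite directions, each passing its differential-significance
gate), the trans-vs-cis discordance odds-ratio contrast, and the promoter
connectivity / expression quartile analysis.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, Gene, GenomicInterval, Interaction, SampleSheet
from .normdiff import cpm, tmm_factors

__all__ = [
    "foldchange_from_cpm",
    "assay_foldchanges",
    "correlate_assays",
    "call_discordance",
    "discordance_odds_ratio",
    "connectivity_expression",
]


def foldchange_from_cpm(mean_cpm_a: np.ndarray, mean_cpm_b: np.ndarray) -> np.ndarray:
    """log2((A + 0.5) / (B + 0.5)) on mean-CPM vectors."""
    a = np.asarray(mean_cpm_a, dtype=float)
    b = np.asarray(mean_cpm_b, dtype=float)
    return np.log2((a + 0.5) / (b + 0.5))


def assay_foldchanges(
    count_matrices: Mapping[str, CountMatrix],
    sample_sheet: SampleSheet,
    strain_pair: tuple[str, str] = ("B6", "D2"),
) -> pd.DataFrame:
    """Per-feature, per-assay log2(A/B) from TMM-normalized mean CPM.

    Long table: feature_id, assay, log2fc, mean_cpm_a, mean_cpm_b.
    """
    strain_a, strain_b = strain_pair
    frames = []
    for assay, counts in count_matrices.items():
        samples_a = sample_sheet.samples_for(strain=strain_a, assay=assay)
        samples_b = sample_sheet.samples_for(strain=strain_b, assay=assay)
        if not samples_a or not samples_b:
            raise ValueError(f"assay {assay!r} is missing strain {strain_a if not samples_a else strain_b!r}")
        sub = counts.subset_samples(samples_a + samples_b)
        norm = cpm(sub, tmm_factors(sub))
        mean_a = norm[samples_a].mean(axis=1).to_numpy()
        mean_b = norm[samples_b].mean(axis=1).to_numpy()
        frames.append(
            pd.DataFrame(
                dict(
                    feature_id=sub.feature_ids,
                    assay=assay,
                    log2fc=foldchange_from_cpm(mean_a, mean_b),
                    mean_cpm_a=mean_a,
                    mean_cpm_b=mean_b,
                )
            )
        )
    return pd.concat(frames, ignore_index=True)


def correlate_assays(
    fc_table: pd.DataFrame,
    assay_x: str,
    assay_y: str,
    feature_subset: Sequence[str] | None = None,
) -> dict:
    """Pearson correlation of paired fold-changes between two assays."""
    wide = fc_table.pivot(index="feature_id", columns="assay", values="log2fc")
    for assay in (assay_x, assay_y):
        if assay not in wide.columns:
            raise ValueError(f"assay {assay!r} absent from fold-change table")
    if feature_subset is not None:
        wide = wide.loc[wide.index.intersection(list(feature_subset))]
    wide = wide[[assay_x, assay_y]].dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 paired features")
    x, y = wide[assay_x].to_numpy(), wide[assay_y].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one assay's fold-changes")
    r, p = stats.pearsonr(x, y)
    return dict(r=float(r), pvalue=float(p), n=int(len(wide)))


def call_discordance(
    fc_table: pd.DataFrame, q_threshold: float = 0.05, require_significance: bool = True
) -> pd.DataFrame:
    """Discordant = ATAC and H3K9me3 change in opposite directions.

    By default both assays must also pass the differential gate
    (qvalue <= q_threshold); set ``require_significance=False`` for the
    raw-sign variant. ``fc_table`` needs rows for assays ATAC and H3K9me3 with
    columns log2fc and (gated mode) qvalue.
    """
    need = {"ATAC", "H3K9me3"}
    have = set(fc_table["assay"].unique())
    if not need <= have:
        raise ValueError(f"fold-change table missing assays {sorted(need - have)}")
    cols = ["log2fc"] + (["qvalue"] if require_significance else [])
    atac = fc_table[fc_table["assay"] == "ATAC"].set_index("feature_id")[cols]
    k9 = fc_table[fc_table["assay"] == "H3K9me3"].set_index("feature_id")[cols]
    joined = atac.join(k9, lsuffix="_atac", rsuffix="_k9", how="inner")

    sign_atac = np.sign(joined["log2fc_atac"].to_numpy())
    sign_k9 = np.sign(joined["log2fc_k9"].to_numpy())
    opposite = sign_atac * sign_k9 < 0
    if require_significance:
        gate = (joined["qvalue_atac"].to_numpy() <= q_threshold) & (
            joined["qvalue_k9"].to_numpy() <= q_threshold
        )
    else:
        gate = np.ones(len(joined), dtype=bool)
    return pd.DataFrame(
        {
            "feature_id": joined.index,
            "sign_atac": sign_atac,
            "sign_k9": sign_k9,
            "discordant": opposite & gate,
        }
    ).reset_index(drop=True)


def _log_or_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """(log OR, SE) with Haldane 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    beta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return beta, se


def discordance_odds_ratio(
    calls: pd.DataFrame, class_labels: Mapping[str, str]
) -> dict:
    """Trans-vs-cis contrast of discordance prevalence.

    Single-predictor logistic contrast: beta-hat equals the log of the 2x2
    sample odds ratio (Haldane-corrected on zero cells); Wald p from
    beta-hat / SE. ``class_labels`` maps feature_id -> 'trans' | 'cis';
    unlabeled features are ignored.
    """
    sub = calls[calls["feature_id"].isin(class_labels.keys())].copy()
    sub["cls"] = sub["feature_id"].map(class_labels)
    n_trans = int((sub["cls"] == "trans").sum())
    n_cis = int((sub["cls"] == "cis").sum())
    if n_trans == 0 or n_cis == 0:
        raise ValueError("both trans and cis classes must be nonempty")
    a = int(((sub["cls"] == "trans") & sub["discordant"]).sum())
    b = n_trans - a
    c = int(((sub["cls"] == "cis") & sub["discordant"]).sum())
    d = n_cis - c
    beta, se = _log_or_2x2(a, b, c, d)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return dict(
        table=[[a, b], [c, d]],
        beta=beta,
        se=se,
        odds_ratio=math.exp(beta),
        ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        pvalue=float(min(1.0, p)),
        n_trans=n_trans,
        n_cis=n_cis,
    )


def connectivity_expression(
    interactions: Sequence[Interaction],
    genes: Sequence[Gene],
    rna_counts: CountMatrix,
    promoter_halfwidth: int = 2000,
) -> tuple[pd.DataFrame, dict]:
    """Contacts-per-promoter quartiles vs expression.

    n_contacts = interactions with either anchor overlapping TSS +/- halfwidth;
    genes with >= 1 contact are quartiled at the empirical 25/50/75 cuts
    (ties to the lower quartile); one-way ANOVA of mean log2(CPM + 0.5) by
    quartile plus all pairwise Tukey HSD p-values.
    """
    expr = np.log2(cpm(rna_counts) + 0.5).mean(axis=1)

    records = []
    anchors: list[GenomicInterval] = []
    for ixn in interactions:
        anchors.extend((ixn.anchor1, ixn.anchor2))
    # count overlaps promoter-by-promoter (anchor multiset, both anchors count)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda iv: iv.start)

    for gene in genes:
        if gene.id not in rna_counts.df.index:
            continue
        lo = max(0, gene.tss - promoter_halfwidth)
        promoter = GenomicInterval(gene.chrom, lo, gene.tss + promoter_halfwidth)
        n = 0
        for a in by_chrom.get(gene.chrom, []):
            if a.start >= promoter.end:
                break
            if a.end > promoter.start:
                n += 1
        if n >= 1:
            records.append(dict(gene_id=gene.id, n_contacts=n, expr=float(expr[gene.id])))
    table = pd.DataFrame(records, columns=["gene_id", "n_contacts", "expr"])
    if table.empty or table["n_contacts"].nunique() < 4:
        raise ValueError("need >= 4 distinct connectivity values to form quartiles")

    cuts = np.quantile(table["n_contacts"], [0.25, 0.5, 0.75])
    labels = np.select(
        [table["n_contacts"] <= cuts[0], table["n_contacts"] <= cuts[1], table["n_contacts"] <= cuts[2]],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    table["quartile"] = labels

    groups = [table.loc[table["quartile"] == q, "expr"].to_numpy() for q in ("Q1", "Q2", "Q3", "Q4")]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("quartiling collapsed to a single group")
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    present = [q for q in ("Q1", "Q2", "Q3", "Q4") if (table["quartile"] == q).any()]
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [float(g.mean()) for g in groups]
    if ss_within == 0.0:
        # degenerate separation limit: identical groups give F = 0 / p = 1;
        # any mean difference is infinitely significant
        distinct = len({round(m, 12) for m in means}) > 1
        f = math.inf if distinct else 0.0
        p = 0.0 if distinct else 1.0
        pairwise = {
            f"{present[i]}-{present[j]}": (0.0 if means[i] != means[j] else 1.0)
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        }
    else:
        f, p = stats.f_oneway(*groups)
        tukey = stats.tukey_hsd(*groups)
        pairwise = {
            f"{present[i]}-{present[j]}": float(tukey.pvalue[i, j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        }
    statsd = dict(
        F=float(f), df_between=df_between, df_within=df_within, pvalue=float(p),
        tukey=pairwise, n_genes=int(len(table)),
    )
    return table, statsd
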