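"""Reciprocal-congenic direction prediction and validation.

BXD-derived repressive-allele calls are turned into signed per-assay
predictions for each parent -> congenic comparison; observed directions are
the sign of the TMM-normalized mean-CPM difference, scored with exact
binomial tests against a 0.5 null.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, GenomicInterval, Interaction, SampleSheet, overlaps
from .dominance import rank_sum_test
from .normdiff import cpm, tmm_factors

__all__ = [
    "COMPARISONS",
    "predict_direction",
    "predict_directions",
    "predict_interaction_directions",
    "observe_direction",
    "validate",
    "effectsize_validated_vs_not",
]

#: comparison name -> (parent strain, congenic strain, introduced allele)
COMPARISONS = {
    "B6->B6-13D2": ("B6", "B6-13D2", "D2"),
    "D2->D2-13B6": ("D2", "D2-13B6", "B6"),
}

VALIDATION_ASSAYS = ("H3K9me3", "ATAC", "H3K27ac", "PET")


def predict_direction(repressive_allele: str, assay: str, comparison: str) -> int:
    """Predicted sign of (congenic - parent) for one feature and assay.

    The comparison introduces an allele at the master locus. Introducing the
    repressive allele: H3K9me3 up (+1), active signals down (-1); introducing
    the non-repressive allele: the reverse.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if assay not in VALIDATION_ASSAYS:
        raise ValueError(f"unknown validation assay {assay!r}")
    if repressive_allele not in ("B6", "D2"):
        raise ValueError(f"unclassified repressive allele {repressive_allele!r}")
    introduced = COMPARISONS[comparison][2]
    repressing = introduced == repressive_allele
    if assay == "H3K9me3":
        return 1 if repressing else -1
    return -1 if repressing else 1


def predict_directions(
    calls: pd.DataFrame, assays: Sequence[str] = VALIDATION_ASSAYS
) -> pd.DataFrame:
    """Expand a repressive-allele table (target_id, repressive_allele) into
    per-(feature, assay, comparison) predictions; unclassified calls are
    skipped and counted in ``.attrs['n_skipped']``."""
    rows = []
    skipped = 0
    for rec in calls.itertuples(index=False):
        allele = rec.repressive_allele
        if allele not in ("B6", "D2"):
            skipped += 1
            continue
        for comparison in COMPARISONS:
            for assay in assays:
                rows.append(
                    dict(
                        feature_id=rec.target_id,
                        assay=assay,
                        comparison=comparison,
                        predicted_sign=predict_direction(allele, assay, comparison),
                    )
                )
    df = pd.DataFrame(rows, columns=["feature_id", "assay", "comparison", "predicted_sign"])
    df.attrs["n_skipped"] = skipped
    return df


def predict_interaction_directions(
    interactions: Sequence[Interaction],
    calls: pd.DataFrame,
    target_intervals: Mapping[str, GenomicInterval],
) -> pd.DataFrame:
    """PET predictions for interactions overlapping trans targets.

    Each interaction inherits the repressive-allele call of any target
    overlapping either anchor; interactions whose overlapping targets imply
    conflicting directions are excluded (counted in ``.attrs``)."""
    rows = []
    conflicts = 0
    classified = calls[calls["repressive_allele"].isin(["B6", "D2"])]
    per_target = {
        rec.target_id: rec.repressive_allele for rec in classified.itertuples(index=False)
    }
    for ixn in interactions:
        alleles = set()
        for tid, allele in per_target.items():
            iv = target_intervals.get(tid)
            if iv is None:
                continue
            if overlaps(ixn.anchor1, iv) or overlaps(ixn.anchor2, iv):
                alleles.add(allele)
        if not alleles:
            continue
        if len(alleles) > 1:
            conflicts += 1
            continue
        allele = alleles.pop()
        for comparison in COMPARISONS:
            rows.append(
                dict(
                    feature_id=ixn.id,
                    assay="PET",
                    comparison=comparison,
                    predicted_sign=predict_direction(allele, "PET", comparison),
                )
            )
    df = pd.DataFrame(rows, columns=["feature_id", "assay", "comparison", "predicted_sign"])
    df.attrs["n_conflicting"] = conflicts
    return df


def observe_direction(
    counts: CountMatrix, sample_sheet: SampleSheet, comparison: str, assay: str
) -> pd.DataFrame:
    """Observed sign and |delta CPM| of congenic - parent per feature.

    Counts are TMM-normalized within the comparison's sample set only.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    parent, congenic, _ = COMPARISONS[comparison]
    parent_samples = sample_sheet.samples_for(strain=parent, assay=assay)
    congenic_samples = sample_sheet.samples_for(strain=congenic, assay=assay)
    if not parent_samples or not congenic_samples:
        missing = parent if not parent_samples else congenic
        raise ValueError(f"strain {missing!r} missing from assay {assay!r}")
    sub = counts.subset_samples(parent_samples + congenic_samples)
    norm = cpm(sub, tmm_factors(sub))
    delta = norm[congenic_samples].mean(axis=1) - norm[parent_samples].mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": sub.feature_ids,
            "assay": assay,
            "comparison": comparison,
            "observed_sign": np.sign(delta.to_numpy()).astype(int),
            "magnitude": np.abs(delta.to_numpy()),
        }
    )


def validate(predictions: pd.DataFrame, observations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score predictions against observations.

    Returns (per-feature table, stratified summary). Strata are
    (assay, comparison, predicted direction); observed zeros are excluded and
    counted. One-sided exact binomial p: P(X >= k | n, 0.5).
    """
    merged = predictions.merge(
        observations, on=["feature_id", "assay", "comparison"], how="inner"
    )
    merged["validated"] = merged["predicted_sign"] == merged["observed_sign"]

    rows = []
    for (assay, comparison, pred), grp in merged.groupby(
        ["assay", "comparison", "predicted_sign"], sort=True
    ):
        nonzero = grp[grp["observed_sign"] != 0]
        n_zero = int(len(grp) - len(nonzero))
        n = int(len(nonzero))
        if n == 0:
            continue  # stratum omitted; zeros noted in pooled table
        k = int(nonzero["validated"].sum())
        p = float(stats.binom.sf(k - 1, n, 0.5))
        rows.append(
            dict(
                assay=assay,
                comparison=comparison,
                stratum="increase" if pred > 0 else "decrease",
                n_tested=n,
                n_in_predicted_direction=k,
                proportion=k / n,
                pvalue=p,
                n_zero_excluded=n_zero,
            )
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "assay", "comparison", "stratum", "n_tested",
            "n_in_predicted_direction", "proportion", "pvalue", "n_zero_excluded",
        ],
    )
    # pooled per (assay, comparison)
    pooled_rows = []
    for (assay, comparison), grp in merged.groupby(["assay", "comparison"], sort=True):
        nonzero = grp[grp["observed_sign"] != 0]
        n = int(len(nonzero))
        if n == 0:
            continue
        k = int(nonzero["validated"].sum())
        pooled_rows.append(
            dict(
                assay=assay,
                comparison=comparison,
                stratum="pooled",
                n_tested=n,
                n_in_predicted_direction=k,
                proportion=k / n,
                pvalue=float(stats.binom.sf(k - 1, n, 0.5)),
                n_zero_excluded=int(len(grp) - n),
            )
        )
    summary = pd.concat([summary, pd.DataFrame(pooled_rows, columns=summary.columns)],
                        ignore_index=True)
    return merged, summary


def effectsize_validated_vs_not(per_feature: pd.DataFrame) -> dict:
    """Rank-sum contrast of |delta CPM| between validated and non-validated
    features; omitted (with note) when either group has < 2 members."""
    nonzero = per_feature[per_feature["observed_sign"] != 0]
    val = nonzero.loc[nonzero["validated"], "magnitude"].to_numpy()
    not_val = nonzero.loc[~nonzero["validated"], "magnitude"].to_numpy()
    if len(val) < 2 or len(not_val) < 2:
        return dict(
            omitted=True,
            note="a group has < 2 members",
            n_validated=int(len(val)),
            n_not_validated=int(len(not_val)),
        )
    res = rank_sum_test(val, not_val)
    return dict(
        omitted=False,
        n_validated=int(len(val)),
        n_not_validated=int(len(not_val)),
        median_validated=res["median_x"],
        median_not_validated=res["median_y"],
        W=res["W"],
        pvalue=res["pvalue"],
        effect_size_r=res["effect_size_r"],
    )
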