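"""Multi-reference TMT ratiometric ranking of AIS enrichment.

A 10-plex TMT run quantifies the anti-NFASC (AIS) labeling alongside two
negative controls (no biotin-phenol substrate, no primary antibody) and
three spatial references (NeuN = soma, MAP2 = somatodendrites, SMI312 =
axon).  Proteins surviving the negative-control ratio cutoff are ranked by
their median-centered log2 enrichment against each reference; the average
of the three per-reference ranks orders the final list, and the overlap of
the per-reference top-N lists gives the high-confidence set.

Condition-level ratios use ratio-of-means by default (replicate channels
averaged before division); a mean-of-ratios mode is available for designs
whose replicate channels pair one-to-one.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .dimethyl import median_center_log_ratios
from .quant_io import ChannelDesign, QuantTable

__all__ = [
    "average_condition_channels",
    "negative_control_filter",
    "enrichment_ratios",
    "rank_per_reference",
    "overall_rank",
    "top_n_overlap",
    "replicate_correlation",
    "run_tmt_ranking",
]

NEGATIVE_CONDITIONS = ("no_BP", "no_1Ab")
REFERENCE_CONDITIONS = ("NeuN", "MAP2", "SMI312")


def average_condition_channels(
    table: QuantTable, design: ChannelDesign, stage: str | None = None
) -> pd.DataFrame:
    """Per-protein mean intensity per condition, keyed by leading accession.

    The mean runs over the condition's non-missing replicate channels; a
    condition is missing only when every one of its channels is missing.
    """
    conditions = {}
    for ch in design.channels:
        if stage is not None and ch.stage != stage:
            continue
        conditions.setdefault(ch.condition, []).append(ch.channel_id)
    out = pd.DataFrame(index=table.leading_ids)
    for cond, cols in conditions.items():
        out[cond] = table.values[cols].mean(axis=1, skipna=True).to_numpy()
    return out[~out.index.duplicated(keep="first")]


def negative_control_filter(
    means: pd.DataFrame, cutoff: float = 2.0, negatives: Iterable[str] = NEGATIVE_CONDITIONS
) -> set[str]:
    """Ids whose NFASC mean exceeds ``cutoff`` x every negative-control mean.

    The inequalities are strict.  A protein detected in NFASC but missing
    from a negative passes that negative's test (the ratio is effectively
    infinite); a protein missing in NFASC cannot pass.
    """
    keep = means["NFASC"].notna()
    for neg in negatives:
        if neg not in means.columns:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = means["NFASC"] / means[neg]
        keep &= (ratio > cutoff) | (means[neg].isna() & means["NFASC"].notna())
    return set(means.index[keep])


def enrichment_ratios(
    means: pd.DataFrame,
    ids: Iterable[str] | None = None,
    references: Iterable[str] = REFERENCE_CONDITIONS,
) -> pd.DataFrame:
    """Median-centered log2(NFASC/reference) per reference, for ``ids``.

    A protein detected in NFASC but not in a reference gets +inf there —
    maximally enriched, ranks first.  Centering subtracts the per-column
    median of the finite values, so each column's finite median is 0.
    """
    sub = means if ids is None else means.loc[means.index.intersection(set(ids))]
    out = pd.DataFrame(index=sub.index)
    for ref in references:
        if ref not in sub.columns:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.log2(sub["NFASC"] / sub[ref])
        raw = raw.where(sub[ref].notna(), np.inf).where(sub["NFASC"].notna())
        out[ref] = median_center_log_ratios(raw)
    return out


def _descending_int_ranks(values: pd.Series) -> pd.Series:
    """Integer ranks, 1 = largest value; ties broken by index (id) order."""
    order = pd.DataFrame(
        {"v": values.to_numpy(), "id": values.index.to_numpy()}
    ).sort_values(["v", "id"], ascending=[False, True], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order["id"].to_numpy())
    return ranks.reindex(values.index)


def rank_per_reference(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-reference descending ranks of the normalized log2 fold changes.

    Returns one integer column ``rank_<ref>`` (a permutation of 1..n,
    residual ties broken by id order) and one fractional column
    ``frac_rank_<ref>`` (ties share the mean of the tied positions) per
    reference.
    """
    out = pd.DataFrame(index=matrix.index)
    for ref in matrix.columns:
        vals = matrix[ref]
        out[f"rank_{ref}"] = _descending_int_ranks(vals).astype(int)
        out[f"frac_rank_{ref}"] = stats.rankdata(-vals.to_numpy())
    return out


def overall_rank(ranks: pd.DataFrame) -> pd.DataFrame:
    """Average the per-reference ranks and rank the averages.

    ``avg_rank_score`` is the mean of the fractional per-reference ranks
    (tied fold changes share the mean tied position); ``overall_rank`` is
    the ascending integer rank of that score, ties broken by id order.
    """
    frac_cols = [c for c in ranks.columns if c.startswith("frac_rank_")]
    out = ranks.copy()
    out["avg_rank_score"] = ranks[frac_cols].mean(axis=1)
    out["overall_rank"] = _descending_int_ranks(-out["avg_rank_score"]).astype(int)
    return out


def top_n_overlap(ranks: pd.DataFrame, n: int = 200) -> set[str]:
    """Intersection of the per-reference top-``n`` id lists."""
    rank_cols = [c for c in ranks.columns if c.startswith("rank_")]
    if n > len(ranks):
        warnings.warn(
            f"top-N of {n} exceeds table size {len(ranks)}; using the full table"
        )
        n = len(ranks)
    sets = [set(ranks.index[ranks[c] <= n]) for c in rank_cols]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def replicate_correlation(
    table: QuantTable, design: ChannelDesign, condition: str, stage: str | None = None
) -> list[dict]:
    """Squared Pearson correlation between replicate channels of a condition.

    Computed on log10 intensities over the proteins non-missing in both
    channels of a pair (MS intensities are log-normal).  One record per
    unordered channel pair, with the common-element count.
    """
    channels = design.channels_for(condition=condition, stage=stage)
    if len(channels) < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 replicate channels")
    out = []
    for i in range(len(channels)):
        for j in range(i + 1, len(channels)):
            a, b = channels[i].channel_id, channels[j].channel_id
            sub = table.values[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"channels {a}/{b}: only {len(sub)} common elements (need >= 3)"
                )
            r, _ = stats.pearsonr(np.log10(sub[a]), np.log10(sub[b]))
            out.append(
                {
                    "condition": condition,
                    "channel_a": a,
                    "channel_b": b,
                    "n_common": int(len(sub)),
                    "r_squared": float(r**2),
                }
            )
    return out


def run_tmt_ranking(
    table: QuantTable,
    design: ChannelDesign,
    min_unique: int = 2,
    neg_cutoff: float = 2.0,
    top_n: int = 200,
    ratio_mode: str = "ratio_of_means",
) -> dict:
    """Full DIV14 TMT branch: filters, ranking and the high-confidence set.

    Returns filter counts, the rank table (per-reference ranks, average
    rank score, overall rank, normalized fold changes) and the top-N
    overlap ids.
    """
    from .quant_io import filter_decoys_contaminants, filter_unique_peptides

    clean = filter_unique_peptides(filter_decoys_contaminants(table), min_unique)
    means = _condition_means(clean, design, ratio_mode)
    biotinylated = negative_control_filter(means, neg_cutoff)
    matrix = enrichment_ratios(means, biotinylated)
    ranks = overall_rank(rank_per_reference(matrix))
    high_confidence = top_n_overlap(ranks, top_n)

    rank_table = matrix.add_prefix("norm_log2_fc_").join(ranks).sort_values("overall_rank")
    rank_table.index.name = "protein_id"
    return {
        "counts": {
            "input_rows": len(table),
            "detected": len(clean),
            "biotinylated": len(biotinylated),
            "high_confidence": len(high_confidence),
        },
        "means": means,
        "rank_table": rank_table,
        "high_confidence": high_confidence,
    }


def _condition_means(
    table: QuantTable, design: ChannelDesign, ratio_mode: str
) -> pd.DataFrame:
    if ratio_mode == "ratio_of_means":
        return average_condition_channels(table, design)
    if ratio_mode == "mean_of_ratios":
        # Geometric-mean equivalent: average log2 per-replicate ratios by
        # pairing the k-th replicate channel of each condition with the k-th
        # NFASC channel, wrapping when replicate counts differ.
        nfasc = [c.channel_id for c in design.channels_for(condition="NFASC")]
        means = pd.DataFrame(index=table.leading_ids)
        means = means[~means.index.duplicated(keep="first")]
        vals = table.values.set_axis(table.leading_ids, axis=0)
        vals = vals[~vals.index.duplicated(keep="first")]
        means["NFASC"] = vals[nfasc].mean(axis=1, skipna=True)
        conds: dict[str, list[str]] = {}
        for ch in design.channels:
            if ch.condition != "NFASC":
                conds.setdefault(ch.condition, []).append(ch.channel_id)
        for cond, cols in conds.items():
            with np.errstate(divide="ignore", invalid="ignore"):
                log_ratios = [
                    np.log2(vals[nfasc[k % len(nfasc)]] / vals[col])
                    for k, col in enumerate(cols)
                ]
            mean_lr = pd.concat(log_ratios, axis=1).mean(axis=1, skipna=True)
            # report as an implied condition mean so downstream division
            # reproduces the averaged ratio
            means[cond] = means["NFASC"] / np.exp2(mean_lr)
        return means
    raise ValueError(
        f"ratio_mode must be 'ratio_of_means' or 'mean_of_ratios', got {ratio_mode!r}"
    )
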