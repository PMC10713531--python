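"""Developmental dynamics of the AIS proteome across DIV7/14/21.

Two bridged 10-plex TMT experiments cover three culture stages (TMT1:
DIV7 + DIV14; TMT2: DIV21 + DIV14), with DIV14 present in both as the
bridge.  Per stage, proteins pass a log2 enrichment filter of anti-NFASC
over the no-primary-antibody control; the stage lists are intersected
(together with the prior standalone DIV14 proteome) into a common core.
Abundances of the core proteins in the anti-NFASC channels are anchored on
the endogenously biotinylated carboxylase PCCA, which is captured in every
channel regardless of labeling and so serves as a cross-channel loading
control.  Proteins changing by more than 20% between any two stages are
z-scored per protein and clustered hierarchically into expression-pattern
clusters; stage pairs are compared by unpaired t-tests on log2 anchored
intensities (volcano statistics).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .quant_io import ChannelDesign, QuantTable

__all__ = [
    "stage_negative_filter",
    "cross_stage_intersection",
    "pcca_normalize",
    "nfasc_stage_values",
    "stage_mean_profiles",
    "change_filter",
    "zscore_profiles",
    "cluster_profiles",
    "cluster_fraction_summary",
    "volcano_stats",
    "run_development_analysis",
]

STAGE_ORDER = ("DIV7", "DIV14", "DIV21")
#: rat propionyl-CoA carboxylase alpha chain, the default anchor accession
DEFAULT_ANCHOR = "P14882"


def _indexed_values(table: QuantTable, columns: Sequence[str]) -> pd.DataFrame:
    vals = table.values[list(columns)].set_axis(table.leading_ids, axis=0)
    return vals[~vals.index.duplicated(keep="first")]


def stage_negative_filter(
    table: QuantTable, design: ChannelDesign, stage: str, threshold: float
) -> set[str]:
    """Ids passing the stage's anti-NFASC over no-antibody log2 cutoff.

    The statistic is the mean over NFASC replicate channels of
    log2(NFASC intensity) - log2(-1Ab intensity); a protein is kept when
    it strictly exceeds ``threshold``.  Proteins detected in NFASC but
    absent from the -1Ab channel are retained outright.
    """
    nfasc_cols = [c.channel_id for c in design.channels_for("NFASC", stage=stage)]
    neg_cols = [c.channel_id for c in design.channels_for("no_1Ab", stage=stage)]
    if not nfasc_cols or not neg_cols:
        raise ValueError(f"stage {stage!r} lacks NFASC or -1Ab channels in the design")
    vals = _indexed_values(table, nfasc_cols + neg_cols)
    nfasc = vals[nfasc_cols]
    neg = vals[neg_cols].mean(axis=1, skipna=True)

    detected = nfasc.notna().any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        diffs = np.log2(nfasc).sub(np.log2(neg), axis=0)
    mean_diff = diffs.mean(axis=1, skipna=True)
    keep = detected & ((mean_diff > threshold) | neg.isna())
    return set(vals.index[keep])


def cross_stage_intersection(*id_sets: Iterable[str]) -> set[str]:
    """Intersection of the per-stage (and prior) biotinylated id sets."""
    sets = [set(s) for s in id_sets]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def pcca_normalize(
    table: QuantTable, design: ChannelDesign, anchor_id: str = DEFAULT_ANCHOR
) -> QuantTable:
    """Scale every NFASC channel so the anchor protein's value is 1.

    Within-channel relative ratios are untouched; the operation is
    idempotent and removes per-channel loading/labeling scale.  Raises if
    the anchor is not quantified in some NFASC channel, naming the channel.
    """
    out = table.copy()
    anchor_rows = out.leading_ids == anchor_id
    if not anchor_rows.any():
        raise ValueError(f"anchor protein {anchor_id!r} not found in table")
    anchor = out.data.loc[anchor_rows.to_numpy()].iloc[0]
    for ch in design.channels_for("NFASC"):
        val = anchor[ch.channel_id]
        if pd.isna(val) or val <= 0:
            raise ValueError(
                f"anchor {anchor_id!r} is not quantified in channel {ch.channel_id!r}"
            )
        out.data[ch.channel_id] = out.data[ch.channel_id] / float(val)
    return out


def nfasc_stage_values(
    experiments: Sequence[tuple[QuantTable, ChannelDesign]], stage: str
) -> pd.DataFrame:
    """Pooled NFASC channel values for a stage across bridged experiments.

    DIV14 appears in both experiments, so its matrix carries all four NFASC
    channels; DIV7 and DIV21 carry two each.
    """
    frames = []
    for k, (table, design) in enumerate(experiments):
        cols = [c.channel_id for c in design.channels_for("NFASC", stage=stage)]
        if not cols:
            continue
        vals = _indexed_values(table, cols)
        vals.columns = [f"exp{k + 1}:{c}" for c in cols]
        frames.append(vals)
    if not frames:
        raise ValueError(f"no experiment carries NFASC channels for stage {stage!r}")
    return pd.concat(frames, axis=1)


def stage_mean_profiles(
    experiments: Sequence[tuple[QuantTable, ChannelDesign]],
    ids: Iterable[str] | None = None,
    stages: Sequence[str] = STAGE_ORDER,
) -> pd.DataFrame:
    """Per-protein mean anchored abundance at each stage (proteins x stages)."""
    cols = {}
    for stage in stages:
        vals = nfasc_stage_values(experiments, stage)
        cols[stage] = vals.mean(axis=1, skipna=True)
    out = pd.DataFrame(cols)
    if ids is not None:
        out = out.loc[out.index.intersection(set(ids))]
    return out.sort_index()


def change_filter(profiles: pd.DataFrame, min_change: float = 0.20) -> set[str]:
    """Ids whose stage means differ by more than ``min_change`` somewhere.

    A protein is kept when for some stage pair max/min > 1 + min_change
    (strict).  Proteins with a non-positive or missing stage mean are
    excluded with a warning.
    """
    valid = (profiles > 0).all(axis=1) & profiles.notna().all(axis=1)
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} protein(s) with non-positive or missing "
            "stage means excluded from the change filter"
        )
    sub = profiles[valid]
    ratio = sub.max(axis=1) / sub.min(axis=1)
    return set(sub.index[ratio > 1.0 + min_change])


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score across stages (population SD).

    Constant profiles map to all-zero z rather than NaN.
    """
    mean = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    # numerically constant rows (sd at float rounding level) map to zero
    degenerate = sd <= 1e-12 * mean.abs().clip(lower=np.finfo(float).tiny)
    z = profiles.sub(mean, axis=0).div(sd.mask(degenerate | (sd == 0.0)), axis=0)
    return z.fillna(0.0)


def cluster_profiles(
    zscored: pd.DataFrame,
    k: int = 6,
    method: str = "complete",
    metric: str = "euclidean",
) -> pd.Series:
    """Agglomerative clustering of z-scored profiles cut into ``k`` clusters.

    Euclidean distance + complete linkage by default (the R
    hclust/cutree behavior behind heatmap clustering).  Cluster ids are
    relabeled 1..k by descending cluster size; equal sizes keep the order
    of first appearance.
    """
    n = len(zscored)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        link = hierarchy.linkage(zscored.to_numpy(), method=method, metric=metric)
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=zscored.index, name="cluster_id")
    sizes = labels.value_counts()
    first_pos = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_pos[lab]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(remap)


def _trend_label(mean_profile: np.ndarray) -> str:
    a, b, c = mean_profile
    if a < b < c:
        return "monotone-up"
    if a > b > c:
        return "monotone-down"
    return "peaked"


def cluster_fraction_summary(
    assignments: pd.Series, zscored: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster size, percentage of clustered proteins, and trend label."""
    total = len(assignments)
    rows = []
    for cluster_id in sorted(assignments.unique()):
        members = assignments.index[assignments == cluster_id]
        mean_profile = zscored.loc[members].mean(axis=0).to_numpy()
        rows.append(
            {
                "cluster_id": int(cluster_id),
                "size": int(len(members)),
                "percent": 100.0 * len(members) / total,
                "trend": _trend_label(mean_profile),
                **{
                    f"mean_z_{stage}": float(v)
                    for stage, v in zip(zscored.columns, mean_profile)
                },
            }
        )
    return pd.DataFrame(rows)


def volcano_stats(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    fc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Unpaired two-tailed t statistics per protein between two stages.

    ``values_a``/``values_b`` are proteins x replicate-channel matrices of
    anchored intensities.  The fold change is log2(mean_b / mean_a); the
    p-value comes from a pooled-variance (Student) t-test on log2 values.
    Calls: ``up`` if log2_fc > fc_cutoff and p < p_cutoff, ``down`` if
    log2_fc < -fc_cutoff and p < p_cutoff, else ``ns``.  Proteins with
    fewer than 2 quantified replicates in either stage are dropped.

    Degenerate zero-variance groups: equal means give p = 1; unequal means
    give the smallest positive float, with a warning.
    """
    common = values_a.index.intersection(values_b.index)
    rows = []
    n_degenerate = 0
    for pid in common:
        a = values_a.loc[pid].dropna().to_numpy(dtype=float)
        b = values_b.loc[pid].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2 or (a <= 0).any() or (b <= 0).any():
            continue
        la, lb = np.log2(a), np.log2(b)
        log2_fc = float(np.log2(b.mean() / a.mean()))
        if la.var(ddof=1) == 0.0 and lb.var(ddof=1) == 0.0:
            if np.isclose(la.mean(), lb.mean()):
                p = 1.0
            else:
                p = float(np.finfo(float).tiny)
                n_degenerate += 1
        else:
            p = float(stats.ttest_ind(la, lb, equal_var=True).pvalue)
        if log2_fc > fc_cutoff and p < p_cutoff:
            call = "up"
        elif log2_fc < -fc_cutoff and p < p_cutoff:
            call = "down"
        else:
            call = "ns"
        rows.append({"protein_id": pid, "log2_fc": log2_fc, "p_value": p, "call": call})
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} protein(s) had zero within-group variance with "
            "unequal means; p set to the smallest positive float"
        )
    return pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame(
        columns=["log2_fc", "p_value", "call"]
    )


def run_development_analysis(
    tmt1: QuantTable,
    design1: ChannelDesign,
    tmt2: QuantTable,
    design2: ChannelDesign,
    prior_div14_ids: Iterable[str] | None = None,
    thresholds: dict | None = None,
    min_unique: int = 2,
    anchor_id: str = DEFAULT_ANCHOR,
    min_change: float = 0.20,
    k: int = 6,
) -> dict:
    """Full developmental branch on two bridged TMT experiments.

    ``thresholds`` maps stage -> log2 NFASC-over-control cutoff (defaults:
    3.5 for DIV7/DIV21, 1 for DIV14).  ``prior_div14_ids`` optionally adds
    the standalone DIV14 proteome to the intersection.
    """
    from .quant_io import filter_decoys_contaminants, filter_unique_peptides

    thresholds = thresholds or {"DIV7": 3.5, "DIV14": 1.0, "DIV21": 3.5}
    clean1 = filter_unique_peptides(filter_decoys_contaminants(tmt1), min_unique)
    clean2 = filter_unique_peptides(filter_decoys_contaminants(tmt2), min_unique)

    stage_ids = {
        "DIV7": stage_negative_filter(clean1, design1, "DIV7", thresholds["DIV7"]),
        "DIV14_tmt1": stage_negative_filter(
            clean1, design1, "DIV14", thresholds["DIV14"]
        ),
        "DIV14_tmt2": stage_negative_filter(
            clean2, design2, "DIV14", thresholds["DIV14"]
        ),
        "DIV21": stage_negative_filter(clean2, design2, "DIV21", thresholds["DIV21"]),
    }
    sets = list(stage_ids.values())
    if prior_div14_ids is not None:
        sets.append(set(prior_div14_ids))
    common = cross_stage_intersection(*sets)

    norm1 = pcca_normalize(clean1, design1, anchor_id)
    norm2 = pcca_normalize(clean2, design2, anchor_id)
    experiments = [(norm1, design1), (norm2, design2)]

    profiles = stage_mean_profiles(experiments, ids=common)
    changing = change_filter(profiles, min_change)
    profiles = profiles.loc[sorted(changing)]
    z = zscore_profiles(profiles)
    assignments = cluster_profiles(z, k=k)
    summary = cluster_fraction_summary(assignments, z)

    volcano = {}
    for sa, sb in (("DIV7", "DIV14"), ("DIV14", "DIV21"), ("DIV7", "DIV21")):
        va = nfasc_stage_values(experiments, sa).loc[
            lambda d: d.index.intersection(sorted(changing))
        ]
        vb = nfasc_stage_values(experiments, sb).loc[
            lambda d: d.index.intersection(sorted(changing))
        ]
        volcano[f"{sa}_vs_{sb}"] = volcano_stats(va, vb)

    return {
        "counts": {
            "detected_tmt1": len(clean1),
            "detected_tmt2": len(clean2),
            **{f"biotinylated_{k_}": len(v) for k_, v in stage_ids.items()},
            "common": len(common),
            "changing": len(changing),
        },
        "stage_ids": stage_ids,
        "common": common,
        "profiles": profiles,
        "zscores": z,
        "assignments": assignments,
        "cluster_summary": summary,
        "volcano": volcano,
    }
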