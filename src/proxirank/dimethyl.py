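"""Dimethyl-labeling H/L ratio analysis of AIS proximity labeling.

Three pairwise experiments are run in triplicate, each quantified as a
heavy/light (H/L) intensity ratio per protein: heavy is the anti-NFASC
(AIS-labeled) sample, light the control — no-primary-antibody (-1Ab), or a
spatial reference (NeuN for soma, MAP2 for somatodendrites).  The analysis:

1. per replicate: remove decoys/contaminants, require >= 2 unique peptides;
2. keep proteins quantified in >= 2 of 3 replicates of a pair;
3. for the -1Ab pair, additionally require H/L > 1.5 in every quantified
   replicate (labeling-dependent enrichment over background adsorption);
4. intersect the three surviving id sets;
5. median-center the log2(H/L) columns of the reference pairs and average
   the centered ratios across replicates, yielding the two-axis enrichment
   coordinates used for the final scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quant_io import (
    QuantTable,
    filter_decoys_contaminants,
    filter_unique_peptides,
)

__all__ = [
    "DimethylPair",
    "prefilter_replicates",
    "replicate_coverage_filter",
    "negative_pair_cutoff",
    "intersect_pairs",
    "median_center_log_ratios",
    "average_normalized_ratios",
    "run_dimethyl_analysis",
]

PAIR_LABELS = ("NFASC_vs_no1Ab", "NFASC_vs_NeuN", "NFASC_vs_MAP2")


@dataclass
class DimethylPair:
    """One pairwise dimethyl experiment: three replicate H/L tables.

    Heavy = anti-NFASC sample, light = the control named by ``label``.
    Each replicate table carries exactly one H/L value column.
    """

    label: str
    replicates: list[QuantTable]

    def __post_init__(self) -> None:
        if self.label not in PAIR_LABELS:
            raise ValueError(f"label must be one of {PAIR_LABELS}, got {self.label!r}")
        for rep in self.replicates:
            if rep.value_kind != "hl_ratio":
                raise ValueError("dimethyl replicates must carry H/L ratios")
            if len(rep.channel_names) != 1:
                raise ValueError(
                    "each dimethyl replicate table carries exactly one ratio column"
                )

    def ratio_frame(self) -> pd.DataFrame:
        """Proteins x replicates H/L matrix keyed by leading accession.

        A protein absent from a replicate's table, or present with a NaN
        ratio, is missing in that replicate.
        """
        cols = {}
        for i, rep in enumerate(self.replicates, start=1):
            s = rep.data.set_index(rep.leading_ids)[rep.channel_names[0]]
            s = s[~s.index.duplicated(keep="first")]
            cols[f"rep{i}"] = s
        return pd.DataFrame(cols)


def prefilter_replicates(pair: DimethylPair, min_unique: int = 2) -> DimethylPair:
    """Apply decoy/contaminant removal and the unique-peptide floor per replicate."""
    reps = [
        filter_unique_peptides(filter_decoys_contaminants(rep), min_unique)
        for rep in pair.replicates
    ]
    return DimethylPair(pair.label, reps)


def replicate_coverage_filter(pair: DimethylPair, min_quantified: int = 2) -> set[str]:
    """Ids with a non-missing H/L ratio in at least ``min_quantified`` replicates."""
    ratios = pair.ratio_frame()
    if ratios.empty:
        return set()
    n_quant = ratios.notna().sum(axis=1)
    return set(ratios.index[n_quant >= min_quantified])


def negative_pair_cutoff(
    pair: DimethylPair, threshold: float = 1.5, min_quantified: int = 2
) -> set[str]:
    """Ids passing the no-primary-antibody cutoff.

    A protein is kept when its H/L ratio is strictly above ``threshold`` in
    every replicate where it was quantified, and it was quantified in at
    least ``min_quantified`` replicates.
    """
    if pair.label != "NFASC_vs_no1Ab":
        raise ValueError(
            f"the negative cutoff applies to the -1Ab pair, got {pair.label}"
        )
    ratios = pair.ratio_frame()
    if ratios.empty:
        return set()
    quantified = ratios.notna()
    enough = quantified.sum(axis=1) >= min_quantified
    all_above = ((ratios > threshold) | ~quantified).all(axis=1)
    return set(ratios.index[enough & all_above])


def intersect_pairs(*id_sets: Iterable[str]) -> set[str]:
    """Intersection of per-pair surviving id sets (keyed by leading accession)."""
    sets = [set(s) for s in id_sets]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def median_center_log_ratios(values: pd.Series | np.ndarray) -> pd.Series:
    """Subtract the column median so unenriched proteins center at log2 = 0.

    Operates on log2(H/L) values.  Missing entries stay missing; infinite
    entries (detected-over-undetected sentinels) do not enter the median.
    The shift is constant, so the output median over finite values is 0.
    """
    s = pd.Series(values, dtype=float, copy=True)
    finite = s[np.isfinite(s)]
    if finite.empty:
        raise ValueError("median centering needs at least one finite value")
    return s - float(np.median(finite))


def average_normalized_ratios(centered: pd.DataFrame) -> pd.Series:
    """Per-protein mean of centered log2 ratios over non-missing replicates.

    Proteins missing in every replicate are dropped from the result.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = centered.mean(axis=1, skipna=True)
    return means.dropna()


def run_dimethyl_analysis(
    pair_no1ab: DimethylPair,
    pair_neun: DimethylPair,
    pair_map2: DimethylPair,
    min_unique: int = 2,
    min_quantified: int = 2,
    neg_threshold: float = 1.5,
    center: str = "median",
) -> dict:
    """Full dimethyl branch: filters, intersection and the two-axis scatter.

    Returns a dict with the per-pair id sets, the three-way intersection,
    pairwise Venn counts, and a DataFrame of average normalized log2(H/L)
    against NeuN and MAP2 for the intersected proteins.
    """
    pairs = {
        "NFASC_vs_no1Ab": prefilter_replicates(pair_no1ab, min_unique),
        "NFASC_vs_NeuN": prefilter_replicates(pair_neun, min_unique),
        "NFASC_vs_MAP2": prefilter_replicates(pair_map2, min_unique),
    }
    ids = {
        "NFASC_vs_no1Ab": negative_pair_cutoff(
            pairs["NFASC_vs_no1Ab"], neg_threshold, min_quantified
        ),
        "NFASC_vs_NeuN": replicate_coverage_filter(
            pairs["NFASC_vs_NeuN"], min_quantified
        ),
        "NFASC_vs_MAP2": replicate_coverage_filter(
            pairs["NFASC_vs_MAP2"], min_quantified
        ),
    }
    common = intersect_pairs(*ids.values())

    scatter = {}
    for axis, label in (("NeuN", "NFASC_vs_NeuN"), ("MAP2", "NFASC_vs_MAP2")):
        ratios = pairs[label].ratio_frame()
        with np.errstate(divide="ignore", invalid="ignore"):
            log2 = np.log2(ratios)
        if center == "median":
            centered = log2.apply(median_center_log_ratios, axis=0)
        elif center == "mean":
            centered = log2 - log2.mean(axis=0, skipna=True)
        else:
            raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
        scatter[f"avg_norm_log2_{axis.lower()}"] = average_normalized_ratios(centered)

    result = pd.DataFrame(scatter)
    result = result.loc[result.index.intersection(sorted(common))].sort_index()
    result.index.name = "protein_id"

    sets = list(ids.values())
    venn = {
        "no1Ab": len(ids["NFASC_vs_no1Ab"]),
        "NeuN": len(ids["NFASC_vs_NeuN"]),
        "MAP2": len(ids["NFASC_vs_MAP2"]),
        "no1Ab_and_NeuN": len(sets[0] & sets[1]),
        "no1Ab_and_MAP2": len(sets[0] & sets[2]),
        "NeuN_and_MAP2": len(sets[1] & sets[2]),
        "triple": len(common),
    }
    return {"ids": ids, "common": common, "venn": venn, "scatter": result}
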