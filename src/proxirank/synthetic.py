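"""Synthetic proteinGroups-style fixtures with planted ground truth.

Generates tables with the statistical structure the pipeline assumes —
log-normal background abundances, AIS proteins enriched in the anti-NFASC
channels, compartment-reference-enriched proteins, endogenously
biotinylated proteins (including a PCCA anchor) present in every channel,
contaminant/reverse decoy rows, multiplicative log-normal channel noise and
random missingness — so every analysis stage is testable without any
external download.  Every generator is a pure function of its spec (which
includes the seed); ground-truth labels are returned alongside each
fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .quant_io import Channel, ChannelDesign, QuantTable

__all__ = [
    "SyntheticSpec",
    "make_div14_design",
    "make_stage_designs",
    "generate_tmt_table",
    "generate_dimethyl_pairs",
    "generate_stage_series",
    "DEFAULT_TRENDS",
    "to_protein_groups_frame",
    "write_fixture",
]

PCCA_ACCESSION = "P14882"


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted composition and noise model of a synthetic experiment.

    Defaults reflect a realistic deep 10-plex run: a couple thousand
    background proteins over a log-normal dynamic range, a small planted
    AIS set with strong (8x) bait-proximal enrichment, moderate channel
    noise (0.25 on the log2 scale) and sparse missingness.
    """

    n_background: int = 2000
    n_ais: int = 20
    n_reference_enriched: Mapping[str, int] = field(
        default_factory=lambda: {"NeuN": 40, "MAP2": 40, "SMI312": 40}
    )
    n_endogenous_biotin: int = 30  # includes the PCCA anchor
    ais_enrichment_fold: float = 8.0
    reference_enrichment_fold: float = 4.0
    negative_background_fraction: float = 0.10
    log2_noise_sd: float = 0.25
    missing_rate: float = 0.02
    n_contaminant_decoys: int = 50
    low_peptide_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_background,
            self.n_ais,
            self.n_endogenous_biotin,
            self.n_contaminant_decoys,
            *self.n_reference_enriched.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all category counts must be >= 0")
        if self.ais_enrichment_fold <= 1:
            raise ValueError("ais_enrichment_fold must exceed 1")
        if not (0 < self.negative_background_fraction < 1):
            raise ValueError("negative_background_fraction must lie in (0, 1)")
        if self.log2_noise_sd < 0:
            raise ValueError("log2_noise_sd must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_total(self) -> int:
        return (
            self.n_background
            + self.n_ais
            + self.n_endogenous_biotin
            + self.n_contaminant_decoys
            + sum(self.n_reference_enriched.values())
        )


def make_div14_design() -> ChannelDesign:
    """The DIV14 10-plex layout: 3x NFASC, -1Ab, -BP, NeuN, 2x MAP2, 2x SMI312."""
    spec = [
        ("NFASC", "positive", 3),
        ("no_1Ab", "negative", 1),
        ("no_BP", "negative", 1),
        ("NeuN", "reference", 1),
        ("MAP2", "reference", 2),
        ("SMI312", "reference", 2),
    ]
    channels = []
    for cond, role, n in spec:
        for rep in range(1, n + 1):
            channels.append(
                Channel(f"{cond}_{rep}", cond, role, stage="DIV14", replicate_index=rep)
            )
    return ChannelDesign(tuple(channels))


def make_stage_designs() -> tuple[ChannelDesign, ChannelDesign]:
    """The bridged developmental pair of 10-plexes.

    Each experiment covers two stages with 2x NFASC, -1Ab, NeuN and MAP2
    per stage; DIV14 appears in both and bridges DIV7 to DIV21.
    """

    def one(stages: Sequence[str]) -> ChannelDesign:
        channels = []
        for stage in stages:
            for rep in (1, 2):
                channels.append(
                    Channel(f"{stage}_NFASC_{rep}", "NFASC", "positive", stage, rep)
                )
            channels.append(Channel(f"{stage}_no1Ab", "no_1Ab", "negative", stage))
            channels.append(Channel(f"{stage}_NeuN", "NeuN", "reference", stage))
            channels.append(Channel(f"{stage}_MAP2", "MAP2", "reference", stage))
        return ChannelDesign(tuple(channels))

    return one(("DIV7", "DIV14")), one(("DIV21", "DIV14"))


def _protein_catalog(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Row catalog: id, gene, category, base abundance, peptide count, flags."""
    rows = []
    for i in range(spec.n_ais):
        rows.append((f"AIS{i + 1:04d}", f"Ais{i + 1}", "ais"))
    for ref, n in spec.n_reference_enriched.items():
        for i in range(n):
            rows.append((f"{ref.upper()}E{i + 1:04d}", f"{ref}e{i + 1}", f"reference_{ref}"))
    for i in range(spec.n_endogenous_biotin):
        acc = PCCA_ACCESSION if i == 0 else f"ENDO{i + 1:04d}"
        gene = "Pcca" if i == 0 else f"Endo{i + 1}"
        rows.append((acc, gene, "endogenous_biotin"))
    for i in range(spec.n_background):
        rows.append((f"BG{i + 1:05d}", f"Bg{i + 1}", "background"))
    for i in range(spec.n_contaminant_decoys):
        kind = "contaminant" if i % 2 == 0 else "reverse"
        rows.append((f"{kind.upper()[:3]}{i + 1:04d}", "", kind))

    cat = pd.DataFrame(rows, columns=["protein_id", "gene_name", "category"])
    cat["base_intensity"] = 10.0 ** rng.normal(6.0, 0.8, size=len(cat))
    cat["unique_peptides"] = 2 + rng.poisson(6.0, size=len(cat))
    # a sliver of one-peptide background identifications exercises the
    # peptide-count floor without touching planted proteins
    bg = cat.index[cat["category"] == "background"]
    n_low = int(round(spec.low_peptide_fraction * len(bg)))
    if n_low:
        cat.loc[rng.choice(bg, size=n_low, replace=False), "unique_peptides"] = 1
    cat["is_contaminant"] = cat["category"] == "contaminant"
    cat["is_reverse"] = cat["category"] == "reverse"
    return cat


def _channel_signal(
    cat: pd.DataFrame, channel: Channel, spec: SyntheticSpec, stage_mult: np.ndarray | None = None
) -> np.ndarray:
    """Noise-free expected intensity of every protein in one channel."""
    base = cat["base_intensity"].to_numpy(copy=True)
    category = cat["category"].to_numpy()
    out = base.copy()
    if channel.role == "negative":
        # background adsorption proportional to abundance; endogenously
        # biotinylated proteins are captured at full strength regardless
        out = base * spec.negative_background_fraction
        out[category == "endogenous_biotin"] = base[category == "endogenous_biotin"]
        return out
    if channel.condition == "NFASC":
        mask = category == "ais"
        out[mask] = base[mask] * spec.ais_enrichment_fold
        if stage_mult is not None:
            out = out * stage_mult
    elif channel.role == "reference":
        mask = category == f"reference_{channel.condition}"
        out[mask] = base[mask] * spec.reference_enrichment_fold
    return out


def _apply_noise_and_missingness(
    values: pd.DataFrame, cat: pd.DataFrame, spec: SyntheticSpec, rng: np.random.Generator
) -> pd.DataFrame:
    noisy = values * 2.0 ** rng.normal(0.0, spec.log2_noise_sd, size=values.shape)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        # the anchor must stay quantified everywhere: it is the loading control
        mask[(cat["protein_id"] == PCCA_ACCESSION).to_numpy(), :] = False
        noisy = noisy.mask(pd.DataFrame(mask, index=noisy.index, columns=noisy.columns))
    return noisy


def _assemble(cat: pd.DataFrame, values: pd.DataFrame, channel_ids: list[str]) -> QuantTable:
    data = pd.DataFrame(
        {
            "protein_group_id": cat["protein_id"].to_numpy(),
            "gene_name": cat["gene_name"].to_numpy(),
            "unique_peptides": cat["unique_peptides"].to_numpy(),
            "is_contaminant": cat["is_contaminant"].to_numpy(),
            "is_reverse": cat["is_reverse"].to_numpy(),
        }
    )
    for c in channel_ids:
        data[c] = values[c].to_numpy()
    return QuantTable(data, channel_ids, "reporter_intensity")


def generate_tmt_table(
    spec: SyntheticSpec, design: ChannelDesign | None = None
) -> tuple[QuantTable, pd.DataFrame]:
    """A DIV14-style 10-plex table plus its ground-truth label frame."""
    design = design or make_div14_design()
    rng = np.random.default_rng(spec.seed)
    cat = _protein_catalog(spec, rng)
    values = pd.DataFrame(
        {ch.channel_id: _channel_signal(cat, ch, spec) for ch in design.channels}
    )
    values = _apply_noise_and_missingness(values, cat, spec, rng)
    table = _assemble(cat, values, design.channel_ids)
    truth = cat[["protein_id", "gene_name", "category", "base_intensity", "unique_peptides"]]
    return table, truth.copy()


def generate_dimethyl_pairs(
    spec: SyntheticSpec, n_replicates: int = 3
) -> tuple[dict, pd.DataFrame]:
    """Three pairwise dimethyl experiments (H/L tables) plus ground truth.

    Heavy is always the anti-NFASC sample.  Planted structure: AIS proteins
    carry H/L = ais_enrichment_fold against the spatial references and
    H/L = fold / negative_background_fraction against the no-antibody
    control; compartment-enriched proteins are depleted (H/L < 1) against
    their own reference; background and endogenously biotinylated proteins
    sit at H/L ~= 1 everywhere.
    """
    from .dimethyl import DimethylPair

    rng = np.random.default_rng(spec.seed)
    cat = _protein_catalog(spec, rng)
    category = cat["category"].to_numpy()

    def expected(label: str) -> np.ndarray:
        hl = np.ones(len(cat))
        if label == "NFASC_vs_no1Ab":
            hl[category == "ais"] = (
                spec.ais_enrichment_fold / spec.negative_background_fraction
            )
        else:
            ref = "NeuN" if label == "NFASC_vs_NeuN" else "MAP2"
            hl[category == "ais"] = spec.ais_enrichment_fold
            hl[category == f"reference_{ref}"] = 1.0 / spec.reference_enrichment_fold
        return hl

    pairs = {}
    for label in ("NFASC_vs_no1Ab", "NFASC_vs_NeuN", "NFASC_vs_MAP2"):
        hl = expected(label)
        reps = []
        for _ in range(n_replicates):
            noisy = hl * 2.0 ** rng.normal(0.0, spec.log2_noise_sd, size=len(cat))
            if spec.missing_rate > 0:
                noisy = np.where(rng.random(len(cat)) < spec.missing_rate, np.nan, noisy)
            values = pd.DataFrame({"H/L": noisy})
            data = pd.concat(
                [
                    cat[["protein_id", "gene_name", "unique_peptides"]].rename(
                        columns={"protein_id": "protein_group_id"}
                    ),
                    cat[["is_contaminant", "is_reverse"]],
                    values,
                ],
                axis=1,
            )
            reps.append(QuantTable(data, ["H/L"], "hl_ratio"))
        pairs[label] = DimethylPair(label, reps)
    truth = cat[["protein_id", "gene_name", "category", "unique_peptides"]]
    return pairs, truth.copy()


#: developmental expression templates: NFASC-channel multipliers at DIV7/14/21
DEFAULT_TRENDS: dict[str, tuple[float, float, float]] = {
    "up": (1.0, 2.0, 4.0),
    "down": (4.0, 2.0, 1.0),
    "peak14": (1.0, 3.0, 1.0),
    "dip14": (3.0, 1.0, 3.0),
    "late_up": (1.0, 1.0, 2.5),
    "early_down": (2.5, 1.0, 1.0),
}


def generate_stage_series(
    spec: SyntheticSpec,
    trends: Mapping[str, tuple[float, float, float]] | None = None,
    n_per_trend: int | None = None,
) -> tuple[QuantTable, ChannelDesign, QuantTable, ChannelDesign, pd.DataFrame]:
    """Two bridged developmental 10-plex tables plus ground truth.

    The planted AIS proteins are split across ``trends`` (stage multipliers
    applied to their NFASC channels); the PCCA anchor stays constant across
    channels up to noise.  Returns (tmt1, design1, tmt2, design2, truth),
    where truth carries each protein's category and trend class.
    """
    trends = dict(trends or DEFAULT_TRENDS)
    design1, design2 = make_stage_designs()
    if n_per_trend is not None:
        spec = replace(spec, n_ais=n_per_trend * len(trends))
    rng = np.random.default_rng(spec.seed)
    cat = _protein_catalog(spec, rng)

    trend_names = list(trends)
    ais_idx = np.flatnonzero((cat["category"] == "ais").to_numpy())
    assigned = [trend_names[i % len(trend_names)] for i in range(len(ais_idx))]
    cat["trend"] = ""
    cat.loc[cat.index[ais_idx], "trend"] = assigned

    stage_pos = {"DIV7": 0, "DIV14": 1, "DIV21": 2}

    def build(design: ChannelDesign, sub_rng: np.random.Generator) -> QuantTable:
        values = {}
        for ch in design.channels:
            mult = np.ones(len(cat))
            if ch.condition == "NFASC":
                for idx, name in zip(ais_idx, assigned):
                    mult[idx] = trends[name][stage_pos[ch.stage]]
            values[ch.channel_id] = _channel_signal(cat, ch, spec, stage_mult=mult)
        frame = pd.DataFrame(values)
        frame = _apply_noise_and_missingness(frame, cat, spec, sub_rng)
        return _assemble(cat, frame, design.channel_ids)

    tmt1 = build(design1, rng)
    tmt2 = build(design2, rng)
    truth = cat[["protein_id", "gene_name", "category", "trend", "unique_peptides"]]
    return tmt1, design1, tmt2, design2, truth.copy()


def to_protein_groups_frame(table: QuantTable) -> tuple[pd.DataFrame, dict[str, str]]:
    """Render a QuantTable in the MaxQuant proteinGroups column dialect.

    Returns the frame plus the channel-id -> value-column mapping, suitable
    for building a round-trippable design file.
    """
    out = pd.DataFrame(
        {
            "Protein IDs": table.data["protein_group_id"],
            "Gene names": table.data["gene_name"],
            "Unique peptides": table.data["unique_peptides"],
            "Potential contaminant": np.where(table.data["is_contaminant"], "+", ""),
            "Reverse": np.where(table.data["is_reverse"], "+", ""),
        }
    )
    mapping = {}
    for i, c in enumerate(table.channel_names, start=1):
        if table.value_kind == "reporter_intensity":
            col = f"Reporter intensity corrected {i}"
            out[col] = table.data[c].fillna(0.0)
        else:
            col = f"Ratio H/L {c}" if c != "H/L" else "Ratio H/L"
            out[col] = table.data[c]
        mapping[c] = col
    return out, mapping


def write_fixture(
    table: QuantTable, design: ChannelDesign, truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write a proteinGroups-dialect TSV, matching design YAML and truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame, mapping = to_protein_groups_frame(table)
    paths = {
        "protein_groups": out_dir / "proteinGroups.txt",
        "design": out_dir / "design.yaml",
        "truth": out_dir / "truth.tsv",
    }
    frame.to_csv(paths["protein_groups"], sep="\t", index=False)
    cfg = design.to_dict()
    for entry in cfg["channels"]:
        entry["column"] = mapping[entry["id"]]
    with open(paths["design"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
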