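"""Reading, validating and filtering protein-group quantification tables.

The pipeline consumes MaxQuant-style ``proteinGroups`` tables: one row per
inferred protein group, with identifier / peptide-count / decoy-flag columns
and one quantitative column per channel (TMT reporter intensities or
dimethyl H/L ratios).  Everything downstream operates on :class:`QuantTable`,
a thin wrapper around a :class:`pandas.DataFrame`, together with a
:class:`ChannelDesign` declaring what each channel measured.

Missing-value convention: a reporter intensity of 0 or an empty cell is
recorded as missing (MaxQuant emits 0 for undetected reporters); an H/L
ratio is missing only when the cell is empty/NaN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "Channel",
    "ChannelDesign",
    "QuantTable",
    "leading_accession",
    "read_protein_groups",
    "filter_decoys_contaminants",
    "filter_unique_peptides",
    "write_table",
    "read_table",
]

#: canonical condition names; aliases map alternate spellings onto them
CONDITIONS = ("NFASC", "no_1Ab", "no_BP", "NeuN", "MAP2", "SMI312")
_CONDITION_ALIASES = {
    "no_primary_antibody": "no_1Ab",
    "no_1ab": "no_1Ab",
    "no_bp": "no_BP",
    "nfasc": "NFASC",
    "neun": "NeuN",
    "map2": "MAP2",
    "smi312": "SMI312",
}
ROLES = ("positive", "negative", "reference")
STAGES = ("DIV7", "DIV14", "DIV21", "NA")

#: MaxQuant proteinGroups column dialect; overridable per design file
DEFAULT_COLUMNS = {
    "protein_group_id": "Protein IDs",
    "gene_name": "Gene names",
    "unique_peptides": "Unique peptides",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
}

META_COLUMNS = (
    "protein_group_id",
    "gene_name",
    "unique_peptides",
    "is_contaminant",
    "is_reverse",
)


class ConfigurationError(ValueError):
    """A design file or input table violates the declared contract."""


def leading_accession(protein_group_id: str) -> str:
    """First semicolon-separated accession of a protein-group identifier.

    Protein-group memberships drift between searches; the leading accession
    is the stable key used for all cross-table set operations.
    """
    return str(protein_group_id).split(";")[0].strip()


@dataclass(frozen=True)
class Channel:
    """One quantification channel and what it measured."""

    channel_id: str
    condition: str
    role: str
    stage: str = "NA"
    replicate_index: int = 1
    #: value column in the source table; defaults to the channel id itself
    column: str | None = None

    def __post_init__(self) -> None:
        cond = _CONDITION_ALIASES.get(self.condition, self.condition)
        cond = _CONDITION_ALIASES.get(cond.lower(), cond)
        object.__setattr__(self, "condition", cond)
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.role not in ROLES:
            raise ConfigurationError(
                f"unknown role {self.role!r}; expected one of {ROLES}"
            )
        if self.stage not in STAGES:
            raise ConfigurationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        if self.replicate_index < 1:
            raise ConfigurationError("replicate_index must be a positive integer")

    @property
    def value_column(self) -> str:
        return self.column if self.column is not None else self.channel_id


@dataclass(frozen=True)
class ChannelDesign:
    """Declarative mapping of channels to conditions, roles and stages.

    Invariants enforced at construction: channel ids are unique, NFASC is the
    only positive condition, at least one negative control is present, and
    reference channels are NeuN/MAP2/SMI312.
    """

    channels: tuple[Channel, ...]
    value_kind: str = "reporter_intensity"
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        cols = dict(DEFAULT_COLUMNS)
        cols.update(self.columns)
        object.__setattr__(self, "columns", cols)
        if self.value_kind not in ("reporter_intensity", "hl_ratio"):
            raise ConfigurationError(
                f"value_kind must be reporter_intensity or hl_ratio, got {self.value_kind!r}"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate channel ids: {dupes}")
        positives = {c.condition for c in self.channels if c.role == "positive"}
        if positives and positives != {"NFASC"}:
            raise ConfigurationError(
                f"the only positive condition is NFASC, got {sorted(positives)}"
            )
        # H/L-ratio designs carry one ratio column per replicate pair; the
        # positive/negative structure is implicit in the heavy/light labels.
        if self.value_kind == "reporter_intensity":
            if self.channels and not positives:
                raise ConfigurationError("design declares no positive (NFASC) channel")
            if not any(c.role == "negative" for c in self.channels):
                raise ConfigurationError("design declares no negative-control channel")
        bad_refs = {
            c.condition
            for c in self.channels
            if c.role == "reference" and c.condition not in ("NeuN", "MAP2", "SMI312")
        }
        if bad_refs:
            raise ConfigurationError(
                f"reference channels must be NeuN/MAP2/SMI312, got {sorted(bad_refs)}"
            )

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def channels_for(
        self, condition: str | None = None, stage: str | None = None, role: str | None = None
    ) -> list[Channel]:
        out = list(self.channels)
        if condition is not None:
            condition = _CONDITION_ALIASES.get(condition, condition)
            out = [c for c in out if c.condition == condition]
        if stage is not None:
            out = [c for c in out if c.stage == stage]
        if role is not None:
            out = [c for c in out if c.role == role]
        return out

    def stages(self) -> list[str]:
        seen: list[str] = []
        for c in self.channels:
            if c.stage != "NA" and c.stage not in seen:
                seen.append(c.stage)
        return seen

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ChannelDesign":
        channels = []
        for entry in cfg.get("channels", []):
            channels.append(
                Channel(
                    channel_id=str(entry["id"]),
                    condition=str(entry["condition"]),
                    role=str(entry["role"]),
                    stage=str(entry.get("stage", "NA")),
                    replicate_index=int(entry.get("replicate", 1)),
                    column=entry.get("column"),
                )
            )
        return cls(
            channels=tuple(channels),
            value_kind=cfg.get("value_kind", "reporter_intensity"),
            columns=dict(cfg.get("columns", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChannelDesign":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise ConfigurationError(f"design file {path} is not a mapping")
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        return {
            "value_kind": self.value_kind,
            "columns": dict(self.columns),
            "channels": [
                {
                    "id": c.channel_id,
                    "condition": c.condition,
                    "role": c.role,
                    "stage": c.stage,
                    "replicate": c.replicate_index,
                    **({"column": c.column} if c.column is not None else {}),
                }
                for c in self.channels
            ],
        }


@dataclass
class QuantTable:
    """Rectangular per-protein quantification table.

    ``data`` holds the metadata columns (:data:`META_COLUMNS`) plus one
    numeric column per channel, named by channel id; missing values are NaN.
    """

    data: pd.DataFrame
    channel_names: list[str]
    value_kind: str = "reporter_intensity"

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel_names must be unique")
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        missing += [c for c in self.channel_names if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"QuantTable data lacks columns: {missing}")
        if (self.data["protein_group_id"].astype(str).str.len() == 0).any():
            raise ConfigurationError("empty protein_group_id")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def leading_ids(self) -> pd.Series:
        return self.data["protein_group_id"].map(leading_accession)

    @property
    def values(self) -> pd.DataFrame:
        """Channel value matrix (proteins x channels), NaN = missing."""
        return self.data[self.channel_names]

    def subset(self, mask) -> "QuantTable":
        return QuantTable(
            self.data.loc[mask].copy(), list(self.channel_names), self.value_kind
        )

    def copy(self) -> "QuantTable":
        return QuantTable(self.data.copy(), list(self.channel_names), self.value_kind)


def _parse_flag(series: pd.Series) -> pd.Series:
    """MaxQuant marks contaminant/reverse rows with '+'; accept booleans too."""
    if series.dtype == bool:
        return series
    s = series.fillna("").astype(str).str.strip()
    return s.isin(("+", "True", "true", "1", "yes"))


def read_protein_groups(path: str | Path, design: ChannelDesign) -> QuantTable:
    """Parse a proteinGroups-dialect TSV into a :class:`QuantTable`.

    Rows keep file order.  Reporter intensities of 0 (or empty cells) become
    missing; H/L ratios are missing only when empty.  A design channel whose
    value column is absent from the header raises a
    :class:`ConfigurationError` naming the column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    cols = design.columns
    required = [cols["protein_group_id"], cols["unique_peptides"]]
    absent = [c for c in required if c not in raw.columns]
    value_cols = {c.channel_id: c.value_column for c in design.channels}
    absent += [v for v in value_cols.values() if v not in raw.columns]
    if absent:
        raise ConfigurationError(
            f"{path.name}: required column(s) absent from header: {absent}"
        )
    if len(set(value_cols.values())) != len(value_cols):
        raise ConfigurationError("duplicate channel value-column mapping")

    out = pd.DataFrame(
        {
            "protein_group_id": raw[cols["protein_group_id"]].astype(str),
            "gene_name": raw.get(cols["gene_name"], pd.Series("", index=raw.index)),
            "unique_peptides": pd.to_numeric(
                raw[cols["unique_peptides"]].replace("", "0")
            ).astype(int),
        }
    )
    for key, name in (("is_contaminant", "contaminant"), ("is_reverse", "reverse")):
        if cols[name] in raw.columns:
            out[key] = _parse_flag(raw[cols[name]])
        else:
            out[key] = False

    for channel_id, col in value_cols.items():
        vals = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        if design.value_kind == "reporter_intensity":
            vals = vals.mask(vals == 0)
        out[channel_id] = vals.astype(float)

    return QuantTable(out, list(value_cols), design.value_kind)


def filter_decoys_contaminants(table: QuantTable) -> QuantTable:
    """Drop contaminant and reverse-hit rows, preserving row order."""
    keep = ~(table.data["is_contaminant"] | table.data["is_reverse"])
    return table.subset(keep)


def filter_unique_peptides(table: QuantTable, min_unique: int = 2) -> QuantTable:
    """Keep rows with at least ``min_unique`` unique peptides."""
    if min_unique < 0:
        raise ValueError("min_unique must be >= 0")
    return table.subset(table.data["unique_peptides"] >= min_unique)


def write_table(table: QuantTable | pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV; values round-trip through :func:`read_table`."""
    df = table.data if isinstance(table, QuantTable) else table
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
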