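import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from proxirank.quant_io import Channel, ChannelDesign, QuantTable
from proxirank.synthetic import SyntheticSpec, make_div14_design


@pytest.fixture
def div14_design() -> ChannelDesign:
    return make_div14_design()


@pytest.fixture
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=1)


def make_quant_table(values: dict, channel_names=None, **meta) -> QuantTable:
    """Build a small QuantTable from {protein_id: {channel: value}}."""
    ids = list(values)
    channel_names = channel_names or sorted({c for v in values.values() for c in v})
    data = pd.DataFrame(
        {
            "protein_group_id": ids,
            "gene_name": meta.get("gene_names", [""] * len(ids)),
            "unique_peptides": meta.get("unique_peptides", [5] * len(ids)),
            "is_contaminant": meta.get("is_contaminant", [False] * len(ids)),
            "is_reverse": meta.get("is_reverse", [False] * len(ids)),
        }
    )
    for c in channel_names:
        data[c] = [values[i].get(c, np.nan) for i in ids]
    return QuantTable(data, list(channel_names), meta.get("value_kind", "reporter_intensity"))


@pytest.fixture
def toy_protein_groups_tsv(tmp_path):
    """3-row proteinGroups-dialect TSV with 10 reporter columns + design."""
    channels = make_div14_design().channel_ids
    header = [
        "Protein IDs",
        "Gene names",
        "Unique peptides",
        "Potential contaminant",
        "Reverse",
    ] + [f"Reporter intensity corrected {i}" for i in range(1, 11)]
    rows = [
        ["P1;P9", "Ankg", "12", "", ""] + [str(100 * (i + 1)) for i in range(10)],
        ["P2", "Nfasc", "8", "", ""] + ["0"] + [str(50 * (i + 1)) for i in range(9)],
        ["P3", "Krt1", "3", "+", ""] + ["10"] * 10,
    ]
    path = tmp_path / "proteinGroups.txt"
    path.write_text("\n".join("\t".join(r) for r in [header] + rows) + "\n")
    design = ChannelDesign(
        tuple(
            Channel(
                ch.channel_id,
                ch.condition,
                ch.role,
                ch.stage,
                ch.replicate_index,
                column=f"Reporter intensity corrected {i}",
            )
            for i, ch in enumerate(make_div14_design().channels, start=1)
        )
    )
    return path, design
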