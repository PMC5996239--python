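"""Packaged reference data: the default enzyme panel and the published
enset PCR-RFLP assay panel used as a coordinate-convention fixture.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .caps_design import RestrictionEnzyme

__all__ = ["load_default_enzymes", "load_enzymes_tsv", "load_enset_rflp_panel"]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("capsforge").joinpath("data", name)))


def load_enzymes_tsv(path) -> list[RestrictionEnzyme]:
    """Read an enzyme table (columns: name, recognition, cut_offset)."""
    df = pd.read_csv(path, sep="\t")
    return [
        RestrictionEnzyme(row["name"], row["recognition"], int(row["cut_offset"]))
        for _, row in df.iterrows()
    ]


def load_default_enzymes() -> list[RestrictionEnzyme]:
    """The six packaged palindromic 6-cutters, in alphabetical order.

    Alphabetical order doubles as the default design priority.
    """
    return load_enzymes_tsv(_data_path("enzymes.tsv"))


def load_enset_rflp_panel() -> pd.DataFrame:
    """Reference panel of 22 PCR-RFLP genotyping assays for enset.

    Primer pairs, printed product sizes, enzymes and 1-based inclusive
    target spans on the Bedadeti draft assembly (GenBank JTFG02 contigs).
    """
    return pd.read_csv(_data_path("enset_rflp_panel.tsv"), sep="\t")
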