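"""Bundled reference tables.

``load_seed_differential_sites`` returns the published set of 20
seed-region miRNA editing sites with stage-differential editing levels
from Ningxiang pig subcutaneous adipose development (chromosome,
genomic position, host mature miRNA, position in the miRNA, editing
type). It is the worked-example input for the seed-region selection
and summary stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_seed_differential_sites() -> pd.DataFrame:
    with resources.files("miredit.data").joinpath("seed_region_differential_sites.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
    df["site_id"] = (
        df["chromosome"].astype(str)
        + "_"
        + df["genomic_position"].astype(str)
        + "_"
        + df["editing_type"]
    )
    return df
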