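"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_dhcr7_region_rmsf() -> pd.DataFrame:
    """Region-summed RMSF table for the DHCR7 wild type and ten variants.

    Columns: ``variant``, ``group`` and one column per named region (A).
    """
    ref = resources.files("memtriage.data") / "dhcr7_region_rmsf.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
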