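"""Published summary counts packaged for arithmetic cross-checks.

These small tables transcribe the reported results of a four-accession
targeted-capture survey of flowering-time gene homologs in *Brassica
napus* (winter oilseed rape 25629-3, fodder rape Silona, spring canola
Campino and the swede Magres Pajberg): per-genotype SNP counts by zygosity
class inside and outside the 614 kbp target space, and the aggregate copy
inventory of the 29-gene panel plus the co-captured *CO-like 2* homologs
(30 genes in total).  They serve as fixed inputs for reproducing the
survey's derived statistics (percentage conventions, SNP density, copy
accounting); they are not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .copy_accounting import InventoryCounts


def _read(name: str) -> pd.DataFrame:
    with resources.files("polycap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_panel_snp_counts() -> pd.DataFrame:
    """Per-genotype SNP counts by zygosity, total vs on-target."""
    return _read("panel_snp_counts.tsv").set_index("genotype")


def load_panel_totals() -> dict[str, int]:
    """Panel-wide totals: SNP counts, target length, depth filter."""
    df = _read("panel_totals.tsv")
    return dict(zip(df["key"], df["value"].astype(int)))


def load_copy_inventory_counts() -> InventoryCounts:
    """Aggregate copy inventory of the flowering-time gene panel."""
    df = _read("copy_inventory_counts.tsv")
    values = dict(zip(df["key"], df["value"].astype(int)))
    return InventoryCounts(**values)
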