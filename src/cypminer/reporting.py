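"""Gene-table aggregation: summary statistics and distribution tables."""

from __future__ import annotations

import math

import pandas as pd

from .io_utils import load_packaged_gene_table

REQUIRED_COLUMNS = ["GeneName", "Type", "CYPClan", "CYPFamily",
                    "CYPSubfamily", "Length", "PI", "MolWt_kDa", "Loc"]


def validate_gene_table(table: pd.DataFrame) -> list[str]:
    """Itemised validation errors for a gene table (empty list = valid)."""
    errors = []
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            errors.append(f"missing column {col!r}")
    if errors:
        return errors
    dup = table.GeneName[table.GeneName.duplicated()]
    errors += [f"duplicate gene name {name!r}" for name in dup]
    bad_len = table.loc[~(table.Length.astype(float) > 0), "GeneName"]
    errors += [f"nonpositive length for {name!r}" for name in bad_len]
    # A-type must coincide with the CYP71 clan
    mism = table[(table.Type == "A") != (table.CYPClan.astype(str) == "71")]
    errors += [f"type/clan mismatch for {name!r}" for name in mism.GeneName]
    return errors


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(table: pd.DataFrame) -> dict:
    """Summary statistics of a full-length gene table.

    Mean length is rounded half-up to an integer (the reporting
    convention of the table this mirrors).
    """
    if table.empty:
        raise ValueError("gene table is empty")
    errors = validate_gene_table(table)
    if errors:
        raise ValueError("invalid gene table: " + "; ".join(errors))
    lengths = table.Length.astype(int)
    per_family = table.groupby("CYPFamily").size().sort_values(ascending=False)
    per_type = table.groupby("Type").size()
    per_loc = table.groupby("Loc").size()
    return dict(
        n_genes=int(len(table)),
        length_mean=_round_half_up(float(lengths.mean())),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        n_families=int(table.CYPFamily.nunique()),
        n_subfamilies=int(table.CYPSubfamily.nunique()),
        n_clans=int(table.CYPClan.astype(str).nunique()),
        family_counts=per_family.to_dict(),
        type_counts=per_type.to_dict(),
        loc_counts=per_loc.to_dict(),
        pct_a_type=round(100.0 * per_type.get("A", 0) / len(table), 1),
    )


def distribution_tables(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-family member counts, split A-type / non-A-type."""
    out = {}
    for cyp_type in ("A", "non-A"):
        sub = table[table.Type == cyp_type]
        out[cyp_type] = (sub.groupby("CYPFamily").size()
                         .rename("members").reset_index())
    return out


def packaged_table_summary() -> dict:
    """Summary of the packaged 116-gene table fixture."""
    return summarize(load_packaged_gene_table())
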