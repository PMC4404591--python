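"""Reading, validating and writing count matrices and study designs.

Conventions
-----------
counts : pandas.DataFrame, genes x libraries, non-negative integers, indexed
    by gene id with library ids as columns.
design : pandas.DataFrame indexed by library id with required columns
    ``individual``, ``group``, ``mapped_reads``, ``rin``; any further columns
    are treated as per-individual traits (e.g. sex, weight, length, cesarean,
    maternal_age, bmi, alcohol, vegetarian).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_DESIGN_COLUMNS = ("individual", "group", "mapped_reads", "rin")

#: canonical trait columns of the full expression model, in fitting order
TRAIT_COLUMNS = (
    "sex",
    "weight",
    "length",
    "cesarean",
    "maternal_age",
    "bmi",
    "alcohol",
    "vegetarian",
)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate library ids: {dup}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        bad = counts.index[np.where(~np.isclose(values, np.round(values)))[0]]
        raise ValueError(f"non-integer counts at genes: {bad.unique().tolist()[:5]}")
    return counts.astype(np.int64)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design missing required columns: {missing}")
    if design.index.has_duplicates:
        dup = design.index[design.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate library ids in design: {dup}")
    # every individual must belong to exactly one group
    ngroups = design.groupby("individual")["group"].nunique()
    bad = ngroups[ngroups > 1].index.tolist()
    if bad:
        raise ValueError(f"individuals assigned to multiple groups: {bad}")
    return design


def check_counts_match_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    extra = design.index.difference(counts.columns).tolist()
    if extra:
        raise ValueError(f"libraries in design but absent from counts: {extra}")
    extra = counts.columns.difference(design.index).tolist()
    if extra:
        raise ValueError(f"libraries in counts but absent from design: {extra}")


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(counts)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0)
    return validate_design(design)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="library_id")


def design_traits(design: pd.DataFrame) -> list[str]:
    """Trait columns present in a design, in canonical model order first."""
    known = [c for c in TRAIT_COLUMNS if c in design.columns]
    other = [
        c
        for c in design.columns
        if c not in REQUIRED_DESIGN_COLUMNS and c not in TRAIT_COLUMNS
    ]
    return known + other
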