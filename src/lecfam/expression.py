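"""FPKM tissue-specificity zoning and the specificity count matrix.

A gene counts as expressed in a tissue type when its FPKM reaches the
detection cutoff (default 1.0) in at least one sample of that type
(a strict all-samples mode is available).  Over the four standard
tissue types (root, leaf, stem, bud) each gene falls into exactly one
category:

* Zone I   — low or no expression in every tissue (FPKM < 1 throughout;
  the sub-flag "undetectable" marks FPKM = 0 everywhere);
* Zone II  — detected in all four tissue types;
* Zone III — detected in roots only;
* Zone IV  — detected in buds only;
* other    — stem-only, leaf-only, or expression in exactly two or
  three tissue types.

Reproductive (female/male) tissue types are handled separately with the
same any-sample rule.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

STANDARD_TISSUES = ("root", "leaf", "stem", "bud")

SPECIFICITY_COLUMNS = (
    "root_only",
    "stem_only",
    "leaf_only",
    "bud_only",
    "all_four",
    "two_tissues",
    "three_tissues",
    "low_or_no",
)

ZONE_OF_CATEGORY = {
    "low_or_no": "I",
    "all_four": "II",
    "root_only": "III",
    "bud_only": "IV",
}


def _validate(matrix: pd.DataFrame, grouping: Mapping[str, str]) -> None:
    if matrix.isna().any().any():
        raise ValueError("FPKM matrix contains missing cells")
    if (matrix.values < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    unmapped = [s for s in matrix.columns if s not in grouping]
    if unmapped:
        raise ValueError(f"samples without a tissue type: {unmapped[:5]}")


def samples_of_type(grouping: Mapping[str, str], tissue_type: str) -> list[str]:
    samples = [s for s, t in grouping.items() if t == tissue_type]
    if not samples:
        raise KeyError(f"tissue type {tissue_type!r} has no samples")
    return samples


def expressed_in_type(
    matrix: pd.DataFrame,
    gene: str,
    tissue_type: str,
    grouping: Mapping[str, str],
    cutoff: float = 1.0,
    all_samples: bool = False,
) -> bool:
    """FPKM >= cutoff in at least one sample of the tissue type
    (or in every sample with ``all_samples``)."""
    if gene not in matrix.index:
        raise KeyError(f"unknown gene {gene!r}")
    values = matrix.loc[gene, samples_of_type(grouping, tissue_type)]
    return bool((values >= cutoff).all() if all_samples else (values >= cutoff).any())


def specificity_category(
    matrix: pd.DataFrame,
    gene: str,
    grouping: Mapping[str, str],
    cutoff: float = 1.0,
    all_samples: bool = False,
) -> str:
    """One of the eight mutually exclusive specificity categories."""
    expressed = {
        t: expressed_in_type(matrix, gene, t, grouping, cutoff, all_samples) for t in STANDARD_TISSUES
    }
    on = [t for t, flag in expressed.items() if flag]
    if not on:
        return "low_or_no"
    if len(on) == 4:
        return "all_four"
    if len(on) == 1:
        return f"{on[0]}_only"
    return "two_tissues" if len(on) == 2 else "three_tissues"


def assign_zone(
    matrix: pd.DataFrame,
    gene: str,
    grouping: Mapping[str, str],
    cutoff: float = 1.0,
    all_samples: bool = False,
) -> str:
    """Zone I-IV, or 'other' for the remaining specificity patterns."""
    return ZONE_OF_CATEGORY.get(specificity_category(matrix, gene, grouping, cutoff, all_samples), "other")


def is_undetectable(matrix: pd.DataFrame, gene: str, grouping: Mapping[str, str]) -> bool:
    """FPKM exactly zero in every standard-tissue sample."""
    samples = [s for t in STANDARD_TISSUES for s in samples_of_type(grouping, t)]
    return bool((matrix.loc[gene, samples] == 0).all())


def specificity_table(
    matrix: pd.DataFrame,
    grouping: Mapping[str, str],
    type_labels: Mapping[str, str],
    cutoff: float = 1.0,
    all_samples: bool = False,
    types: Sequence[str] = ("G", "L", "C"),
) -> pd.DataFrame:
    """Per-subfamily count matrix over the specificity categories.

    Rows are the subfamily types plus a Total row; every gene falls in
    exactly one category column, so row totals equal family sizes and
    the Total row equals the column sums (asserted).
    """
    _validate(matrix, grouping)
    unlabeled = [g for g in matrix.index if g not in type_labels]
    if unlabeled:
        raise ValueError(f"genes without a subfamily label: {unlabeled[:5]}")
    table = pd.DataFrame(0, index=list(types) + ["Total"], columns=list(SPECIFICITY_COLUMNS) + ["Total"])
    for gene in matrix.index:
        cat = specificity_category(matrix, gene, grouping, cutoff, all_samples)
        t = type_labels[gene]
        table.loc[t, cat] += 1
        table.loc[t, "Total"] += 1
        table.loc["Total", cat] += 1
        table.loc["Total", "Total"] += 1
    cols = list(SPECIFICITY_COLUMNS)
    assert table.loc["Total", cols].sum() == table.loc["Total", "Total"], "column sums inconsistent"
    for t in types:
        assert table.loc[t, cols].sum() == table.loc[t, "Total"], f"row {t} inconsistent"
    return table


def sex_specific_expression(
    matrix: pd.DataFrame,
    grouping: Mapping[str, str],
    cutoff: float = 1.0,
    female_type: str = "female",
    male_type: str = "male",
    genes: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Per-gene reproductive-tissue label: female_only/male_only/both/neither."""
    samples_of_type(grouping, female_type)
    samples_of_type(grouping, male_type)
    out: dict[str, str] = {}
    for gene in matrix.index if genes is None else genes:
        f = expressed_in_type(matrix, gene, female_type, grouping, cutoff)
        m = expressed_in_type(matrix, gene, male_type, grouping, cutoff)
        out[gene] = "both" if f and m else "female_only" if f else "male_only" if m else "neither"
    return out


def long_format(matrix: pd.DataFrame, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Tidy gene/sample/tissue/FPKM table for plotting layers."""
    long = matrix.reset_index(names="gene").melt(id_vars="gene", var_name="sample", value_name="fpkm")
    long["tissue"] = long["sample"].map(dict(grouping))
    return long
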