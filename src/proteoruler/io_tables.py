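"""Reading and writing protein-groups tables and sample designs.

The on-disk input format is the tab-separated ``proteinGroups.txt`` dialect
produced by common label-free search software: one row per protein group,
per-sample raw intensity columns, razor+unique and unique peptide counts, a
group molecular weight in kDa, and ``+``/empty flag columns marking
contaminants, reversed decoys and groups identified only by modification
site.  Column header strings vary between software versions, so they are a
configurable :class:`TableDialect`.

In memory a protein-groups table is a :class:`pandas.DataFrame` with the
metadata columns listed in :data:`GROUP_META_COLUMNS` plus one float column
per sample holding the raw intensity (``NaN`` = not detected).  A sample
design is a DataFrame with columns ``sample_id, genotype, cell_type,
stimulation, replicate``; the condition label of a sample is
``"<genotype>.<cell_type>.<stimulation>"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "DialectError",
    "ValidationError",
    "GROUP_META_COLUMNS",
    "DESIGN_COLUMNS",
    "read_protein_groups",
    "write_protein_groups",
    "read_design",
    "write_table",
    "read_table",
    "condition_of",
    "condition_labels",
    "samples_by_condition",
]


class DialectError(KeyError):
    """A mandatory column is absent from the input table."""


class ValidationError(ValueError):
    """A row violates an invariant of the format."""


#: metadata columns of an in-memory protein-groups table, in canonical order
GROUP_META_COLUMNS = [
    "group_id",
    "gene_name",
    "mol_weight_da",
    "razor_unique_peptides",
    "unique_peptides",
    "flag_contaminant",
    "flag_reverse",
    "flag_only_by_site",
]

DESIGN_COLUMNS = ["sample_id", "genotype", "cell_type", "stimulation", "replicate"]


@dataclass(frozen=True)
class TableDialect:
    """Column-header map for the tab-separated protein-groups dialect.

    Defaults match the public ``proteinGroups.txt`` header strings.  Raw
    per-sample intensities are the columns named ``intensity_prefix +
    sample_id``; the bare summed column equal to ``intensity_prefix.strip()``
    is ignored.
    """

    majority_ids: str = "Majority protein IDs"
    gene_names: str = "Gene names"
    mol_weight_kda: str = "Mol. weight [kDa]"
    razor_unique_peptides: str = "Razor + unique peptides"
    unique_peptides: str = "Unique peptides"
    intensity_prefix: str = "Intensity "
    contaminant: str = "Potential contaminant"
    reverse: str = "Reverse"
    only_by_site: str = "Only identified by site"
    flag_true: str = "+"

    def mandatory(self) -> list[str]:
        return [
            self.majority_ids,
            self.gene_names,
            self.mol_weight_kda,
            self.razor_unique_peptides,
            self.unique_peptides,
            self.contaminant,
            self.reverse,
            self.only_by_site,
        ]


def _parse_flags(col: pd.Series, dialect: TableDialect) -> pd.Series:
    return col.fillna("").astype(str).str.strip().eq(dialect.flag_true)


def read_protein_groups(path, dialect: TableDialect | None = None) -> pd.DataFrame:
    """Read a tab-separated protein-groups table.

    Returns a DataFrame with :data:`GROUP_META_COLUMNS` followed by one
    float column per sample id (``NaN`` meaning not detected).  The reader is
    order-preserving: one output row per input row, no silent drops.

    Raises
    ------
    DialectError
        if a mandatory column named by the dialect is missing.
    ValidationError
        if a row has a non-positive molecular weight or more unique than
        razor+unique peptides.
    """
    dialect = dialect or TableDialect()
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in dialect.mandatory():
        if col not in raw.columns:
            raise DialectError(f"mandatory column {col!r} not found in {path}")

    prefix = dialect.intensity_prefix
    sample_cols = [
        c for c in raw.columns if c.startswith(prefix) and c != prefix.strip()
    ]
    sample_ids = [c[len(prefix):] for c in sample_cols]

    out = pd.DataFrame(
        {
            "group_id": raw[dialect.majority_ids]
            .fillna("")
            .astype(str)
            .str.split(";")
            .str[0],
            "gene_name": raw[dialect.gene_names].fillna("").astype(str),
            "mol_weight_da": pd.to_numeric(raw[dialect.mol_weight_kda], errors="coerce")
            * 1000.0,
            "razor_unique_peptides": pd.to_numeric(
                raw[dialect.razor_unique_peptides], errors="coerce"
            )
            .fillna(0)
            .astype(int),
            "unique_peptides": pd.to_numeric(raw[dialect.unique_peptides], errors="coerce")
            .fillna(0)
            .astype(int),
            "flag_contaminant": _parse_flags(raw[dialect.contaminant], dialect),
            "flag_reverse": _parse_flags(raw[dialect.reverse], dialect),
            "flag_only_by_site": _parse_flags(raw[dialect.only_by_site], dialect),
        }
    )

    bad_mw = ~(out["mol_weight_da"] > 0)
    if bad_mw.any():
        rows = out.index[bad_mw].tolist()[:5]
        raise ValidationError(f"non-positive molecular weight in rows {rows}")
    bad_pep = out["unique_peptides"] > out["razor_unique_peptides"]
    if bad_pep.any():
        rows = out.index[bad_pep].tolist()[:5]
        raise ValidationError(f"unique peptides exceed razor+unique in rows {rows}")

    for col, sid in zip(sample_cols, sample_ids):
        vals = pd.to_numeric(raw[col], errors="coerce")
        vals[vals <= 0] = np.nan  # zero encodes "no quantification"
        out[sid] = vals
    return out


def write_protein_groups(groups: pd.DataFrame, path, dialect: TableDialect | None = None) -> None:
    """Write an in-memory protein-groups table back to the on-disk dialect."""
    dialect = dialect or TableDialect()
    if len(groups) == 0:
        raise ValidationError("refusing to write an empty protein-groups table")
    sample_ids = [c for c in groups.columns if c not in GROUP_META_COLUMNS]
    flag = lambda s: np.where(s, dialect.flag_true, "")
    out = pd.DataFrame(
        {
            dialect.majority_ids: groups["group_id"],
            dialect.gene_names: groups["gene_name"],
            dialect.mol_weight_kda: groups["mol_weight_da"] / 1000.0,
            dialect.razor_unique_peptides: groups["razor_unique_peptides"],
            dialect.unique_peptides: groups["unique_peptides"],
            dialect.contaminant: flag(groups["flag_contaminant"]),
            dialect.reverse: flag(groups["flag_reverse"]),
            dialect.only_by_site: flag(groups["flag_only_by_site"]),
        }
    )
    for sid in sample_ids:
        out[dialect.intensity_prefix + sid] = groups[sid]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_design(path) -> pd.DataFrame:
    """Read a sample-design table and validate its invariants."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DialectError(f"design table missing columns {missing}")
    design = design[DESIGN_COLUMNS].copy()
    design["replicate"] = design["replicate"].astype(int)
    key = design[["genotype", "cell_type", "stimulation", "replicate"]]
    if key.duplicated().any():
        raise ValidationError("duplicate (genotype, cell_type, stimulation, replicate)")
    if design["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in design")
    return design


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as tab-separated UTF-8.

    Deterministic column order (as given), header row, ``NA`` for missing
    values; floats use Python's shortest round-trip representation so a
    read-back reproduces them bit-identically.  Refuses an empty table and
    creates no file in that case.
    """
    if records is None or len(records) == 0:
        raise ValidationError("refusing to write an empty result table")
    records.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (``NA`` -> NaN)."""
    return pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=["NA"], encoding="utf-8", **kwargs
    )


def condition_of(genotype: str, cell_type: str, stimulation: str) -> str:
    """Canonical condition label, e.g. ``'WT.CD4.naive'``."""
    return f"{genotype}.{cell_type}.{stimulation}"


def condition_labels(design: pd.DataFrame) -> pd.Series:
    """Condition label per sample, indexed by sample_id, in design order."""
    labels = [
        condition_of(g, c, s)
        for g, c, s in zip(design["genotype"], design["cell_type"], design["stimulation"])
    ]
    return pd.Series(labels, index=design["sample_id"].to_numpy(), name="condition")


def samples_by_condition(design: pd.DataFrame) -> dict[str, list[str]]:
    """Map condition label -> sample ids, conditions in design order."""
    labels = condition_labels(design)
    out: dict[str, list[str]] = {}
    for sid, cond in labels.items():
        out.setdefault(cond, []).append(sid)
    return out
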