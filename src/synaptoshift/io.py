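"""Readers and writers for the pipeline's tabular formats.

All formats are plain tab-separated UTF-8 text with "." as the decimal
point:

* **Expression matrix** — first column gene id, remaining columns one per
  sample, values FPKM (non-negative, finite).
* **Sample sheet** — columns ``sample_id, subject_id, group, fraction``
  followed by optional covariates (age, pmi, ph, sex, antidepressant,
  alcohol, ...). ``group`` is ``control``/``MDD``; ``fraction`` is
  ``total``/``synaptic``. Missing covariate values are allowed; operations
  that need a covariate drop those samples and log the count.
* **Ratio table** — columns ``gene_symbol, ensembl_id, ct_ratio,
  mdd_ratio, mdd_over_ct, p_value``. Ensembl IDs keep their version
  suffix verbatim and are compared as opaque strings; the symbol is
  display metadata.
* **Gene sets** — standard GMT (set name, description, then members).

A transcription of the published 119-gene ratio-shift table ships with the
package and is loaded with :func:`load_reference_ratio_table`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

PathType = Union[str, PathLike]

GROUPS = ("control", "MDD")
FRACTIONS = ("total", "synaptic")
SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "group", "fraction")
RATIO_TABLE_COLUMNS = (
    "gene_symbol",
    "ensembl_id",
    "ct_ratio",
    "mdd_ratio",
    "mdd_over_ct",
    "p_value",
)


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate {what}: {', '.join(map(str, dup))}")


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the matrix as float.

    Raises :class:`FormatError` on duplicate gene/sample ids or on negative,
    NaN or infinite values (reported with their (gene, sample) coordinates).
    """
    _check_unique(matrix.index, "gene ids")
    _check_unique(matrix.columns, "sample ids")
    try:
        values = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    bad = ~np.isfinite(values.to_numpy()) | (values.to_numpy() < 0)
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid FPKM value {values.iat[gi, si]!r} at "
            f"(gene {values.index[gi]!r}, sample {values.columns[si]!r})"
        )
    return values


def read_expression(path: PathType) -> pd.DataFrame:
    """Read a genes x samples FPKM matrix from TSV (first column = gene id)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene_id"
    return validate_expression(matrix)


def write_expression(matrix: pd.DataFrame, path: PathType) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {', '.join(missing)}")
    _check_unique(samples["sample_id"], "sample ids")
    bad_group = set(samples["group"]) - set(GROUPS)
    if bad_group:
        raise FormatError(f"unknown group labels: {sorted(bad_group)}; expected {GROUPS}")
    bad_frac = set(samples["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise FormatError(f"unknown fraction labels: {sorted(bad_frac)}; expected {FRACTIONS}")
    pair = samples[["subject_id", "fraction"]]
    dup = pair[pair.duplicated()]
    if not dup.empty:
        raise FormatError(
            "duplicate (subject, fraction) rows: "
            + ", ".join(f"({r.subject_id}, {r.fraction})" for r in dup.itertuples())
        )
    return samples.reset_index(drop=True)


def read_sample_sheet(path: PathType) -> pd.DataFrame:
    """Read a sample sheet TSV; columns beyond the four required are covariates."""
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_sample_sheet(samples)


def write_sample_sheet(samples: pd.DataFrame, path: PathType) -> None:
    samples.to_csv(path, sep="\t", index=False)


def covariate_columns(samples: pd.DataFrame) -> list[str]:
    return [c for c in samples.columns if c not in SAMPLE_SHEET_COLUMNS]


def validate_ratio_records(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATIO_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"ratio table missing columns: {', '.join(missing)}")
    for col in ("ct_ratio", "mdd_ratio", "mdd_over_ct"):
        vals = table[col].astype(float)
        if (vals <= 0).any() or not np.isfinite(vals).all():
            offender = table.loc[(vals <= 0) | ~np.isfinite(vals), "gene_symbol"].iloc[0]
            raise FormatError(f"non-positive {col} for gene {offender!r}")
    p = table["p_value"].astype(float)
    if ((p <= 0) | (p > 1)).any():
        offender = table.loc[(p <= 0) | (p > 1), "gene_symbol"].iloc[0]
        raise FormatError(f"p_value outside (0, 1] for gene {offender!r}")
    return table.reset_index(drop=True)


def read_ratio_table(path: PathType) -> pd.DataFrame:
    """Read a published-style ratio-shift table (one record per gene).

    Columns: gene_symbol, ensembl_id, ct_ratio (control-group mean
    synaptic/total ratio), mdd_ratio, mdd_over_ct (ratio of ratios), p_value.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "ensembl_id": str})
    if table.empty and set(RATIO_TABLE_COLUMNS) <= set(table.columns):
        return table
    table = validate_ratio_records(table)
    log.info("read %d ratio records from %s", len(table), path)
    return table


def load_reference_ratio_table() -> pd.DataFrame:
    """Load the packaged 119-gene ratio-shift reference table."""
    ref = resources.files("synaptoshift.data").joinpath("ratio_shift_table.tsv")
    with resources.as_file(ref) as path:
        return read_ratio_table(path)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT contents)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gene_sets(path: PathType) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    collection = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: gene set with empty member list")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in collection.sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        unique = frozenset(members)
        if len(unique) < len(members):
            log.warning(
                "gene set %r: %d duplicate members removed", name, len(members) - len(unique)
            )
        collection.sets[name] = unique
        collection.descriptions[name] = desc
    return collection


def load_demo_gene_sets() -> GeneSetCollection:
    """Load the small synthetic demonstration GMT shipped with the package."""
    ref = resources.files("synaptoshift.data").joinpath("demo_gene_sets.synthetic.gmt")
    with resources.as_file(ref) as path:
        return read_gene_sets(path)
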