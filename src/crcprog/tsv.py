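"""Shared tab-separated file dialect.

Every stage of the pipeline exchanges the same plain-text formats:

* gene x sample matrices: TSV with a ``gene_id`` index column and one
  column per sample;
* sample annotations: columns ``sample_id``, ``stage``, ``cohort``;
* gene annotations: columns ``gene_id``, ``class``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GENE_INDEX = "gene_id"


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample matrix (rows=genes, header row of sample IDs)."""
    values.to_csv(path, sep="\t", index_label=GENE_INDEX)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=GENE_INDEX)


def write_sample_annotations(stages: pd.Series, cohort: str, path: str | Path) -> None:
    """``stages`` maps sample_id -> stage label."""
    table = pd.DataFrame(
        {"sample_id": stages.index, "stage": stages.values, "cohort": cohort}
    )
    table.to_csv(path, sep="\t", index=False)


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_gene_annotations(classes: pd.Series, path: str | Path) -> None:
    """``classes`` maps gene_id -> simulation class (ground truth)."""
    table = pd.DataFrame({"gene_id": classes.index, "class": classes.values})
    table.to_csv(path, sep="\t", index=False)


def read_gene_annotations(path: str | Path) -> pd.Series:
    # keep_default_na=False: the class label "null" is a real value
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return pd.Series(table["class"].values, index=table["gene_id"].values)


def join_probe_annotation(
    probe_table: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Map probe-level results to gene level through a local annotation table.

    ``probe_table`` is indexed by probe ID; ``annotation`` has columns
    ``probe_id`` and ``gene_id``.  Probes without a gene are dropped; when
    several probes map to the same gene the first occurrence in annotation
    order wins (callers wanting a different aggregation can group themselves).
    """
    required = {"probe_id", "gene_id"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    merged = annotation.merge(
        probe_table, left_on="probe_id", right_index=True, how="inner"
    )
    return merged.drop_duplicates("gene_id").set_index("gene_id")
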