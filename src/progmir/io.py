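"""Readers and writers for the pipeline's plain-text formats.

Formats:

* expression matrix — TSV, feature ids in the first column, sample ids in
  the header row;
* sample annotations — TSV with columns ``sample``, ``group``,
  ``dataset_id``, ``compartment``;
* interaction table — TSV with columns ``mirna_id``, ``gene_id``,
  ``source_tag``;
* gene sets — GMT (``set_id<TAB>description<TAB>member...``);
* survival table — TSV with columns ``sample``, ``time``, ``event``.

All readers accept LF or CRLF line endings and reject duplicate ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .study import ExpressionStudy


def read_expression_tsv(path, annotations_path=None, dataset_id: str = "") -> ExpressionStudy:
    """Read a feature x sample TSV matrix (plus annotations) into a study."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    non_numeric = values.columns[
        [values[c].dtype.kind not in "fiu" for c in values.columns]
    ]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric cells in column {non_numeric[0]!r}")
    if annotations_path is None:
        raise ValueError("annotations_path is required to build a study")
    ann = read_annotations_tsv(annotations_path)
    return ExpressionStudy(values=values, annotations=ann, dataset_id=dataset_id)


def write_expression_tsv(study: ExpressionStudy, path) -> None:
    study.values.to_csv(path, sep="\t", index_label="feature")


def read_annotations_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    if "sample" not in ann.columns:
        raise ValueError(f"{path}: annotations need a 'sample' column")
    if ann["sample"].duplicated().any():
        dup = ann["sample"][ann["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return ann.set_index("sample")


def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample")


def read_interactions_tsv(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "gene_id"}
    if not required.issubset(tab.columns):
        raise ValueError(f"{path}: interaction table needs columns {sorted(required)}")
    if "source_tag" not in tab.columns:
        tab["source_tag"] = "unknown"
    return tab


def write_interactions_tsv(interactions: pd.DataFrame, path) -> None:
    interactions.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set_id: member set}``; descriptions dropped."""
    sets: dict[str, set[str]] = {}
    with open(path, newline=None) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line with <3 fields: {line[:60]!r}")
            set_id = parts[0]
            if set_id in sets:
                raise ValueError(f"{path}: duplicate set id {set_id!r}")
            sets[set_id] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            desc = (descriptions or {}).get(set_id, "na")
            members = sorted(sets[set_id])
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_survival_tsv(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required.issubset(tab.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    if tab["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample in survival table")
    if (tab["time"] <= 0).any():
        raise ValueError(f"{path}: nonpositive survival time")
    if not set(tab["event"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: event must be 0 or 1")
    return tab.set_index("sample")


def write_survival_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
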