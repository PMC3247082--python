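"""Readers and writers for the pipeline's file formats.

Expression matrices travel as tab-separated text (first row condition
labels, first column gene identifiers); gene sets as GMT; phenotype labels
as a two-column TSV; bicluster collections as a human-readable TSV report
plus a lossless machine-readable JSON twin.  Condition identifiers are
labels throughout — nothing relies on positional indexing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Bicluster, ExpressionMatrix, InvalidInputError, SupportDecision
from .evaluation import GeneSetCollection, PhenotypeLabels

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "read_labels_tsv",
    "write_biclusters",
    "read_biclusters",
]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Parse a genes x conditions TSV into a validated ExpressionMatrix.

    Rejects duplicate identifiers and non-numeric or missing cells, naming
    the offending gene/condition.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InvalidInputError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise InvalidInputError(f"{path}: duplicate condition id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise InvalidInputError(
            f"{path}: non-numeric or missing cell at gene "
            f"{df.index[i]!r}, condition {df.columns[j]!r} "
            f"(value {df.iat[i, j]!r})"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(Path(path), sep="\t", index_label="gene")


def read_gmt(
    path: str | Path, universe: Sequence[str] | None = None
) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes, tab-separated).

    Duplicate genes within a line are deduplicated; the universe defaults
    to the union of all sets.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name = fields[0]
            if name in sets:
                raise InvalidInputError(
                    f"{path}:{lineno}: duplicate gene-set name {name!r}"
                )
            seen: list[str] = []
            for g in fields[2:]:
                if g and g not in seen:
                    seen.append(g)
            sets[name] = seen
    return GeneSetCollection.from_sets(sets, universe=universe)


def read_labels_tsv(path: str | Path) -> PhenotypeLabels:
    """Parse a two-column TSV: condition_id <TAB> case|control (no header)."""
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            cond, lab = fields
            if lab not in ("case", "control"):
                raise InvalidInputError(
                    f"{path}:{lineno}: label must be case or control, "
                    f"got {lab!r}"
                )
            if cond in labels:
                raise InvalidInputError(
                    f"{path}:{lineno}: duplicate condition id {cond!r}"
                )
            labels[cond] = lab
    return PhenotypeLabels(labels)


def _decision_to_json(d: SupportDecision) -> dict:
    return {
        "supports": d.supports,
        "retained": list(d.retained),
        "discarded": list(d.discarded),
        "contribution": d.contribution,
    }


def _decision_from_json(obj: Mapping) -> SupportDecision:
    return SupportDecision(
        supports=bool(obj["supports"]),
        retained=tuple(obj["retained"]),
        discarded=tuple(obj["discarded"]),
        contribution=float(obj["contribution"]),
    )


def _json_twin(path: Path) -> Path:
    return path.with_suffix(".json") if path.suffix == ".tsv" \
        else Path(str(path) + ".json")


def write_biclusters(
    biclusters: Sequence[Bicluster],
    path: str | Path,
    header: Mapping | None = None,
    mse: Mapping[int, float] | None = None,
) -> Path:
    """Write a line-oriented TSV report plus a lossless JSON twin.

    ``header`` (config/seed echo) is written as ``#``-prefixed lines in the
    TSV and under "header" in the JSON.  ``mse`` optionally maps positional
    index -> mean squared residue.  Returns the JSON twin path.
    """
    path = Path(path)
    jpath = _json_twin(path)
    with path.open("w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        cols = ["level", "genes", "n_transactions", "transactions",
                "range_support", "errors", "mse"]
        fh.write("\t".join(cols) + "\n")
        for i, b in enumerate(biclusters):
            errs = ";".join(
                f"{t}:{','.join(b.errors_of(t))}"
                for t in b.transactions if b.errors_of(t)
            )
            row = [
                str(b.level),
                ",".join(b.genes),
                str(len(b.transactions)),
                ",".join(b.transactions),
                f"{b.range_support:.10g}",
                errs or "-",
                f"{mse[i]:.10g}" if mse and i in mse else "-",
            ]
            fh.write("\t".join(row) + "\n")
    payload = {
        "header": dict(header or {}),
        "biclusters": [
            {
                "genes": list(b.genes),
                "transactions": list(b.transactions),
                "range_support": b.range_support,
                "level": b.level,
                "per_transaction": {
                    t: _decision_to_json(d)
                    for t, d in b.per_transaction.items()
                },
            }
            for b in biclusters
        ],
    }
    jpath.write_text(json.dumps(payload, indent=1))
    return jpath


def read_biclusters(path: str | Path) -> list[Bicluster]:
    """Read a bicluster collection back from its JSON form (losslessly).

    Accepts the JSON path itself or the TSV path (the twin is looked up).
    """
    path = Path(path)
    if path.suffix != ".json":
        path = _json_twin(path)
    payload = json.loads(path.read_text())
    out = []
    for obj in payload["biclusters"]:
        out.append(Bicluster(
            genes=tuple(obj["genes"]),
            transactions=tuple(obj["transactions"]),
            range_support=float(obj["range_support"]),
            per_transaction={
                t: _decision_from_json(d)
                for t, d in obj["per_transaction"].items()
            },
            level=int(obj["level"]),
        ))
    return out
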