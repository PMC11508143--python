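"""Readers and writers for the tabular formats the pipeline consumes.

Counts arrive as a tab-delimited genes x samples matrix with a ``gene_id``
header column; the sample sheet is a CSV describing the two-condition
time-course design; gene-set annotations arrive as GMT files. Everything is
held in memory as pandas objects (counts and expression are genes x samples
DataFrames, matching the on-disk layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "salt")
TIME_POINTS_H = (0, 3, 6, 12, 24, 48)


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


def _check_unique(values, kind: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate {kind} id(s): {', '.join(map(str, dup))}")


def validate_counts(counts: pd.DataFrame, allow_real: bool = False) -> pd.DataFrame:
    """Validate a genes x samples count matrix and return it as float64.

    Counts must be finite and non-negative; unless ``allow_real`` is set they
    must also be whole numbers (raw read counts).
    """
    _check_unique(counts.index, "gene")
    _check_unique(counts.columns, "sample")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = counts.columns[
            [not np.issubdtype(d, np.number) for d in counts.dtypes]
        ].tolist()
        raise FormatError(f"non-numeric counts in column(s): {', '.join(map(str, bad))}")
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count {values[i, j]:g} at gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}"
        )
    if not allow_real and not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise FormatError(
            f"non-integer count {values[i, j]:g} at gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r} (pass allow_real for pre-normalized input)"
        )
    out = counts.astype(float)
    out.index.name = "gene_id"
    return out


def read_counts(path, allow_real: bool = False) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column ``gene_id``)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"malformed counts file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"counts file {path} has no sample columns")
    return validate_counts(df, allow_real=allow_real)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "time_h", "replicate")


def validate_sample_sheet(
    sheet: pd.DataFrame, counts: pd.DataFrame | None = None
) -> pd.DataFrame:
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise FormatError(f"sample sheet missing column(s): {', '.join(missing_cols)}")
    sheet = sheet.loc[:, list(SAMPLE_SHEET_COLUMNS)].copy()
    _check_unique(sheet["sample_id"], "sample")
    bad_cond = sorted(set(sheet["condition"]) - set(CONDITIONS))
    if bad_cond:
        raise FormatError(
            f"unknown condition label(s): {', '.join(map(str, bad_cond))} "
            f"(expected one of {', '.join(CONDITIONS)})"
        )
    sheet["time_h"] = pd.to_numeric(sheet["time_h"])
    sheet["replicate"] = pd.to_numeric(sheet["replicate"])
    if (sheet["replicate"] < 1).any() or (sheet["replicate"] % 1 != 0).any():
        raise FormatError("replicate must be a positive integer")
    sheet["replicate"] = sheet["replicate"].astype(int)
    triples = sheet[["condition", "time_h", "replicate"]].apply(tuple, axis=1)
    if triples.duplicated().any():
        dup = triples[triples.duplicated()].iloc[0]
        raise FormatError(f"duplicate (condition, time_h, replicate) triple: {dup}")
    if counts is not None:
        sheet_ids = list(sheet["sample_id"])
        count_ids = list(counts.columns)
        missing = sorted(set(count_ids) - set(sheet_ids))
        extra = sorted(set(sheet_ids) - set(count_ids))
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing from sheet: {', '.join(map(str, missing))}")
            if extra:
                parts.append(f"not in counts: {', '.join(map(str, extra))}")
            raise FormatError("sample sheet / count matrix mismatch — " + "; ".join(parts))
        # align sheet row order to the count-matrix column order
        sheet = sheet.set_index("sample_id").loc[count_ids].reset_index()
    return sheet.reset_index(drop=True)


def read_sample_sheet(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate the sample sheet CSV; optionally check against counts."""
    sheet = pd.read_csv(path)
    return validate_sample_sheet(sheet, counts=counts)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


@dataclass
class GeneSet:
    """One annotation term (GO term, pathway, ...) with its member genes."""

    term_id: str
    name: str
    genes: frozenset[str]
    namespace: str = ""

    def __post_init__(self):
        if not self.genes:
            raise FormatError(f"annotation term {self.term_id!r} has no member genes")


@dataclass
class AnnotationMap:
    """A collection of gene sets keyed by term id, as read from a GMT file."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self):
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.genes
        return frozenset(out)


def read_gmt(path) -> AnnotationMap:
    """Read a GMT file: ``term_id<TAB>term_name<TAB>gene1<TAB>gene2...``.

    A ``namespace`` tag (e.g. BP/CC/MF) may be embedded in the term name as a
    ``namespace|name`` prefix; otherwise the namespace is left empty.
    """
    terms: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line {lineno}: need term_id, name and at least one gene"
                )
            term_id, name = parts[0], parts[1]
            namespace = ""
            if "|" in name:
                namespace, name = name.split("|", 1)
            genes = frozenset(g for g in parts[2:] if g)
            if term_id in terms:
                raise FormatError(f"GMT line {lineno}: duplicate term id {term_id!r}")
            terms[term_id] = GeneSet(term_id, name, genes, namespace)
    if not terms:
        raise FormatError(f"GMT file {path} contains no gene sets")
    return AnnotationMap(terms)


def write_gmt(annotations: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for gs in annotations:
            name = f"{gs.namespace}|{gs.name}" if gs.namespace else gs.name
            fh.write("\t".join([gs.term_id, name, *sorted(gs.genes)]) + "\n")
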