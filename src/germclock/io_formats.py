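"""Readers and writers for every external artifact.

The pipeline consumes three tab-separated inputs — an FPKM expression matrix
(genes x samples), a sample sheet mapping sample IDs to (stage, replicate),
and a Mapman-style category mapping — and emits sorted, deterministic TSV
result tables plus a JSON run manifest.

The mapping dialect accepted is the classic five-column Mapman export
(BINCODE, NAME, IDENTIFIER, DESCRIPTION, TYPE) with optionally single-quoted
fields.  Bin codes are dot-separated integer paths ("2.1.3"); ancestors are
auto-created and, with roll-up, a gene assigned to a bin belongs to every
ancestor bin as well.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

_BINCODE_RE = re.compile(r"^\d+(\.\d+)*$")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """FPKM-scale expression values for genes across staged, replicated samples.

    ``values`` is a genes x samples DataFrame; ``sample_meta`` is indexed by
    sample_id with columns ``stage`` and ``replicate``; ``stage_order`` is the
    declared time axis (total order on stage labels).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    stage_order: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise ConfigError(f"unknown stage {stage!r}; stages are {self.stage_order}")
        meta = self.sample_meta
        sel = meta.index[meta["stage"] == stage]
        return list(sel)

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.values[self.samples_for_stage(stage)]

    def validate(self, min_replicates: int = 2) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {vals.index[bad[0]]!r}, sample {vals.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value {arr[bad[0], bad[1]]} at gene "
                f"{vals.index[bad[0]]!r}, sample {vals.columns[bad[1]]!r}"
            )
        missing = set(vals.columns) - set(self.sample_meta.index)
        if missing:
            raise FormatError(f"samples absent from sample sheet: {sorted(missing)}")
        extra = set(self.sample_meta.index) - set(vals.columns)
        if extra:
            raise FormatError(f"sample sheet rows without matrix columns: {sorted(extra)}")
        counts = self.sample_meta.groupby("stage", observed=True).size()
        thin = counts[counts < min_replicates]
        if len(thin):
            raise FormatError(
                f"stages with fewer than {min_replicates} replicates: "
                f"{sorted(thin.index.tolist())}"
            )
        unknown_stage = set(self.sample_meta["stage"]) - set(self.stage_order)
        if unknown_stage:
            raise FormatError(f"stages missing from stage order: {sorted(unknown_stage)}")


@dataclass
class CategoryMap:
    """Hierarchical bin-code -> gene assignment.

    ``bins`` maps bincode to human-readable name; ``assignments`` is the set
    of (bincode, gene_id) pairs as given (pre roll-up).  A gene may belong to
    several bins.
    """

    bins: dict[str, str]
    assignments: set[tuple[str, str]]

    def __post_init__(self) -> None:
        # ancestors of every known bin must themselves be known
        for code in list(self.bins):
            for anc in bin_ancestors(code):
                self.bins.setdefault(anc, anc)
        for code, _gene in self.assignments:
            if code not in self.bins:
                self.bins[code] = code
                for anc in bin_ancestors(code):
                    self.bins.setdefault(anc, anc)

    @property
    def genes(self) -> set[str]:
        return {g for _c, g in self.assignments}

    def membership(self, rollup: bool = True) -> dict[str, set[str]]:
        """Bin -> member genes; with roll-up a gene propagates to ancestors."""
        out: dict[str, set[str]] = {code: set() for code in self.bins}
        for code, gene in self.assignments:
            out[code].add(gene)
            if rollup:
                for anc in bin_ancestors(code):
                    out[anc].add(gene)
        return out


def bin_ancestors(code: str) -> list[str]:
    """Proper ancestor prefixes of a dot-separated bin code ("2.1.3" -> ["2", "2.1"])."""
    parts = code.split(".")
    return [".".join(parts[:i]) for i in range(1, len(parts))]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path, stage_order: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample_id, stage, replicate.

    Stage order defaults to order of first appearance. Returns a DataFrame
    indexed by sample_id with ``stage`` as an ordered categorical.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet {path} must have columns {sorted(required)}, "
            f"found {list(sheet.columns)}"
        )
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in sheet: {dupes}")
    try:
        sheet["replicate"] = sheet["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate index in {path}: {exc}") from None
    if (sheet["replicate"] < 1).any():
        raise FormatError("replicate indices must be positive integers")
    if sheet.duplicated(subset=["stage", "replicate"]).any():
        raise FormatError("(stage, replicate) pairs must be unique")
    if stage_order is None:
        stage_order = list(dict.fromkeys(sheet["stage"]))
    else:
        unknown = set(sheet["stage"]) - set(stage_order)
        if unknown:
            raise FormatError(f"sheet stages not in declared stage order: {sorted(unknown)}")
    sheet["stage"] = pd.Categorical(sheet["stage"], categories=stage_order, ordered=True)
    return sheet.set_index("sample_id")


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    stage_order: list[str] | None = None,
) -> ExpressionMatrix:
    """Read and validate an FPKM matrix together with its sample sheet.

    Columns are reordered to stage order then replicate index.  Raises
    :class:`FormatError` naming the offending cell for negative or
    non-numeric values, the offending column for samples missing from the
    sheet, and the gene id for duplicates.
    """
    meta = read_sample_sheet(sample_sheet_path, stage_order)
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{matrix_path}: expected gene_id column plus sample columns")
    gene_col = raw.columns[0]
    raw = raw.set_index(gene_col)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{matrix_path}: duplicate gene id(s) {dupes[:5]}")

    for col in raw.columns:
        if col not in meta.index:
            raise FormatError(
                f"{matrix_path}: sample column {col!r} is missing from the sample sheet"
            )
    numeric = raw.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{matrix_path}: non-numeric value {raw.iloc[gi, si]!r} at gene "
            f"{raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{matrix_path}: missing value at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r}"
        )
    arr = numeric.to_numpy(dtype=float)
    if (arr < 0).any():
        gi, si = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{matrix_path}: negative value {arr[gi, si]} at gene "
            f"{numeric.index[gi]!r}, sample {numeric.columns[si]!r}"
        )

    stage_order = list(meta["stage"].cat.categories)
    order = meta.loc[list(numeric.columns)].copy()
    order["_stage_idx"] = order["stage"].cat.codes
    ordered_samples = order.sort_values(["_stage_idx", "replicate"]).index.tolist()
    numeric = numeric[ordered_samples].astype(float)
    meta = meta.loc[ordered_samples]

    matrix = ExpressionMatrix(values=numeric, sample_meta=meta, stage_order=stage_order)
    matrix.validate()
    return matrix


def _strip_quotes(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == "'" and value[-1] == "'":
        value = value[1:-1]
    return value.strip()


def read_mapman_mapping(path: str | Path, case_insensitive: bool = True) -> CategoryMap:
    """Parse a classic Mapman mapping export into a :class:`CategoryMap`.

    Rows with an empty identifier define bin names only.  Single quotes are
    stripped; identifiers are case-folded by default (Mapman exports
    lowercase IDs); duplicate assignments collapse; ancestor bins are
    auto-created.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().strip("'").upper(): c for c in table.columns}
    for needed in ("BINCODE", "IDENTIFIER"):
        if needed not in cols:
            raise FormatError(
                f"{path}: mapping file must have BINCODE and IDENTIFIER columns, "
                f"found {list(table.columns)}"
            )
    bins: dict[str, str] = {}
    assignments: set[tuple[str, str]] = set()
    code_idx = table.columns.get_loc(cols["BINCODE"])
    ident_idx = table.columns.get_loc(cols["IDENTIFIER"])
    name_idx = table.columns.get_loc(cols["NAME"]) if "NAME" in cols else None
    for row_no, row in enumerate(table.itertuples(index=False, name=None), start=2):
        code = _strip_quotes(row[code_idx])
        if not _BINCODE_RE.match(code):
            raise FormatError(
                f"{path}: malformed bin code {code!r} at line {row_no} "
                "(expected dot-separated integers)"
            )
        name = _strip_quotes(row[name_idx]) if name_idx is not None else code
        if code not in bins or bins[code] == code:
            bins[code] = name or code
        ident = _strip_quotes(row[ident_idx])
        if ident:
            if case_insensitive:
                ident = ident.lower()
            assignments.add((code, ident))
    # CategoryMap fills any missing ancestor bins with their code as name
    return CategoryMap(bins=bins, assignments=assignments)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    input_paths: Iterable[str | Path] = (),
) -> list[Path]:
    """Write result tables as sorted TSVs plus a run manifest.

    Output is deterministic: rows are sorted on all columns with a stable
    sort, floats are printed with a fixed format, and the manifest records
    config, seed and SHA-256 checksums of the inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        df = tables[name].copy()
        if len(df):
            df = df.sort_values(by=list(df.columns), kind="mergesort")
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        written.append(path)
    manifest = {
        "config": dict(config) if config is not None else None,
        "seed": seed,
        "inputs": {str(p): _file_sha256(p) for p in input_paths},
        "tables": [p.name for p in written],
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path, sheet_path: str | Path) -> None:
    """Write an ExpressionMatrix back to the matrix + sample sheet dialect."""
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g", lineterminator="\n")
    sheet = matrix.sample_meta.reset_index()
    sheet.columns = ["sample_id", "stage", "replicate"]
    sheet.to_csv(sheet_path, sep="\t", index=False, lineterminator="\n")


def write_mapping(cmap: CategoryMap, path: str | Path) -> None:
    """Write a CategoryMap in the five-column Mapman dialect."""
    rows = []
    assigned_codes = {c for c, _g in cmap.assignments}
    for code in sorted(cmap.bins, key=_bincode_key):
        if code not in assigned_codes:
            rows.append((code, cmap.bins[code], "", "", "T"))
    for code, gene in sorted(cmap.assignments, key=lambda cg: (_bincode_key(cg[0]), cg[1])):
        rows.append((code, cmap.bins[code], gene, "", "T"))
    df = pd.DataFrame(rows, columns=["BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION", "TYPE"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _bincode_key(code: str) -> tuple[int, ...]:
    return tuple(int(p) for p in code.split("."))
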