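"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV (UTF-8, LF, '.' decimal separator) except gene sets (GMT)
and dendrograms (Newick).  Readers validate eagerly and report 1-based file
line numbers in error messages; every writer's output is re-parseable by the
matching reader.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GeneSet, GeneSetCollection
from .profiles import CorrelationResult, DendrogramResult
from .qpcr import CT_COLUMNS, validate_ct_table
from .screen import VENN_REGIONS, HitTable


class FileFormatError(ValueError):
    """Raised for malformed input files; messages carry line numbers."""


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FileFormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _to_float(df: pd.DataFrame, column: str, path) -> pd.Series:
    """Convert a string column to float, rejecting comma decimals by line."""
    values = df[column].astype(str)
    comma = values.str.contains(",", na=False)
    if comma.any():
        line = int(df.index[comma][0]) + 2  # +1 header, +1 one-based
        raise FileFormatError(
            f"{path}: line {line}: {column}={values[comma].iloc[0]!r} uses a "
            "comma decimal; this format requires the '.' decimal separator"
        )
    converted = pd.to_numeric(values, errors="coerce")
    bad = converted.isna() & values.notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FileFormatError(
            f"{path}: line {line}: cannot parse {column}={values[bad].iloc[0]!r}"
        )
    return converted.astype(float)


def read_ct_tsv(path) -> pd.DataFrame:
    """Read and validate a long-format Ct table."""
    df = _read_tsv(path, CT_COLUMNS)
    df["ct"] = _to_float(df, "ct", path)
    df["replicate"] = _to_float(df, "replicate", path).astype(int)
    try:
        return validate_ct_table(df)
    except ValueError as err:
        raise FileFormatError(f"{path}: {err}") from err


def write_ct_tsv(ct_table: pd.DataFrame, path) -> None:
    ct_table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_proliferation_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, ("kinase_id", "rel_prolif"))
    df["rel_prolif"] = _to_float(df, "rel_prolif", path)
    return df[["kinase_id", "rel_prolif"]]


def write_proliferation_tsv(prolif: pd.DataFrame, path) -> None:
    prolif.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_fold_change_tsv(path) -> pd.DataFrame:
    """Read a kinases × genes fold-change matrix (kinase_id index column)."""
    df = _read_tsv(path, ("kinase_id",))
    df = df.set_index("kinase_id")
    for col in df.columns:
        frame = df[[col]].reset_index(drop=True)
        df[col] = _to_float(frame, col, path).to_numpy()
    df.columns.name = "gene_id"
    return df


def write_fold_change_tsv(fc: pd.DataFrame, path) -> None:
    fc.to_csv(path, sep="\t", index=True, index_label="kinase_id", lineterminator="\n")


def read_gmt(path, population_total: int) -> GeneSetCollection:
    """Read a GMT file (term_id TAB description TAB gene ...) into a collection.

    Duplicate genes within a set are counted once; lines with fewer than 3
    fields are a hard error naming the line.
    """
    path = Path(path)
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(
                    f"{path}: line {lineno}: GMT requires >= 3 tab-separated "
                    f"fields, found {len(fields)}"
                )
            term_id, name, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise FileFormatError(f"{path}: line {lineno}: gene set is empty")
            sets.append(GeneSet(term_id=term_id, name=name, genes=frozenset(genes)))
    if not sets:
        raise FileFormatError(f"{path}: no gene sets (empty file)")
    return GeneSetCollection(sets=sets, population_total=population_total)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection.sets:
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.genes)]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    path = Path(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            g = raw.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    if not genes:
        raise FileFormatError(f"{path}: no genes found")
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def write_hit_table(hits: HitTable, path) -> None:
    hits.calls.to_csv(path, sep="\t", index=True, lineterminator="\n")


def read_hit_table(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        ("kinase_id", "anti_proliferative", "sasp_inducer", "p16_inducer", "senescence_hit"),
    ).set_index("kinase_id")
    return df == "True"


def write_venn_tsv(hits: HitTable, path) -> None:
    rows = [(region, hits.venn_counts[region]) for region in VENN_REGIONS]
    pd.DataFrame(rows, columns=["region", "count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_venn_tsv(path) -> dict[str, int]:
    df = _read_tsv(path, ("region", "count"))
    return dict(zip(df["region"], df["count"].astype(int)))


def write_correlation_tsv(corr: CorrelationResult, path) -> None:
    corr.to_long().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_correlation_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, ("var_a", "var_b", "rho", "p", "n"))
    for col in ("rho", "p", "n"):
        df[col] = _to_float(df, col, path)
    return df


def write_newick(dendro: DendrogramResult, path) -> None:
    Path(path).write_text(dendro.to_newick() + "\n", encoding="utf-8")


def read_config(path) -> dict[str, str]:
    """Flat ``key=value`` config file; '#' comments and blank lines allowed."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected key=value, got {line!r}"
                )
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
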