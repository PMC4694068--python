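"""Relative quantification of RT-qPCR screens by the comparative-Ct (ΔΔCt) method.

A screen produces, for every transduced kinase, cycle-threshold (Ct) values
for a handful of target transcripts plus a housekeeping reference (ACTB by
default).  This module turns those raw Ct measurements into

1. reference-normalized relative expression ``2**(-ΔCt)`` per (kinase, gene),
   with replicate Cts averaged arithmetically on the Ct scale, and
2. fold changes versus the empty-vector control, ``fc = rel / rel(CTRL)``.

Amplification efficiency is assumed to be 100% (base 2) and fold changes are
kept on the linear scale throughout; log transforms belong to
:mod:`senescreen.profiles`.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Required columns of a long-format Ct table.
CT_COLUMNS = ("sample_id", "kinase_id", "gene_id", "replicate", "ct")

DEFAULT_REFERENCE_GENE = "ACTB"
DEFAULT_CONTROL_ID = "CTRL"

#: Hard upper bound for a plausible cycle threshold.
CT_MAX = 45.0
#: Cts at or above this are accepted but flagged: near the detection floor.
CT_WARN = 40.0


class CtTableError(ValueError):
    """Raised when a Ct table violates its structural invariants."""


def validate_ct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format Ct table and return it with numeric dtypes.

    Checks: required columns present; every Ct finite and in (0, CT_MAX];
    (kinase, gene, replicate) unique within each sample.  Cts at or above
    ``CT_WARN`` cycles trigger a warning (near-detection-floor measurements),
    never an error.
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise CtTableError(f"Ct table is missing required column(s): {', '.join(missing)}")
    out = ct_table.copy()
    ct = pd.to_numeric(out["ct"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(ct)
    if bad.any():
        rows = out.index[bad].tolist()[:5]
        raise CtTableError(f"non-finite Ct value(s) at row(s) {rows}")
    if (ct <= 0).any() or (ct > CT_MAX).any():
        rows = out.index[(ct <= 0) | (ct > CT_MAX)].tolist()[:5]
        raise CtTableError(
            f"Ct values must lie in (0, {CT_MAX}]; offending row(s) {rows}"
        )
    out["ct"] = ct
    out["replicate"] = pd.to_numeric(out["replicate"], errors="raise").astype(int)
    if (out["replicate"] < 1).any():
        raise CtTableError("replicate indices must be positive integers")
    dup = out.duplicated(subset=["sample_id", "kinase_id", "gene_id", "replicate"])
    if dup.any():
        first = out.loc[dup, ["sample_id", "kinase_id", "gene_id", "replicate"]].iloc[0]
        raise CtTableError(
            "duplicate (kinase, gene, replicate) within a sample: "
            f"{tuple(first)}"
        )
    n_floor = int((ct >= CT_WARN).sum())
    if n_floor:
        warnings.warn(
            f"{n_floor} Ct value(s) >= {CT_WARN} cycles: near the qPCR detection "
            "floor; retained without a cutoff",
            UserWarning,
            stacklevel=2,
        )
    return out


def normalize_ct(
    ct_table: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Reference-normalize Ct measurements to relative expression 2**(-ΔCt).

    Replicate Cts are averaged arithmetically on the Ct scale per
    (kinase, gene), pooling samples; ΔCt is the target's mean Ct minus the
    reference gene's mean Ct for the same kinase.  The reference gene itself
    maps to relative expression 1 exactly.

    Parameters
    ----------
    ct_table
        Long-format table with columns ``sample_id, kinase_id, gene_id,
        replicate, ct``.
    reference_gene
        Housekeeping transcript used for normalization (default ``ACTB``).

    Returns
    -------
    DataFrame with columns ``kinase_id, gene_id, rel_expr`` and one row per
    (kinase, gene), reference gene included with rel_expr 1.

    Raises
    ------
    CtTableError
        If validation fails or any (sample, kinase) with target-gene records
        lacks a reference-gene measurement (the offending kinase is named).
    """
    ct = validate_ct_table(ct_table)
    has_ref = (
        ct.assign(is_ref=ct["gene_id"] == reference_gene)
        .groupby(["sample_id", "kinase_id"], sort=False)["is_ref"]
        .any()
    )
    if not has_ref.all():
        sample, kinase = has_ref.index[~has_ref][0]
        raise CtTableError(
            f"no reference-gene ({reference_gene}) measurement for kinase "
            f"{kinase!r} in sample {sample!r}"
        )
    mean_ct = ct.groupby(["kinase_id", "gene_id"], sort=False)["ct"].mean()
    ref_ct = mean_ct.xs(reference_gene, level="gene_id")
    delta = mean_ct - ref_ct.reindex(mean_ct.index.get_level_values("kinase_id")).to_numpy()
    rel = np.power(2.0, -delta)
    out = rel.rename("rel_expr").reset_index()
    # exact 1.0 for the reference gene (guards against -0.0 style noise)
    out.loc[out["gene_id"] == reference_gene, "rel_expr"] = 1.0
    return out


def fold_change(
    rel: pd.DataFrame,
    control_id: str = DEFAULT_CONTROL_ID,
    drop_reference: str | None = None,
) -> pd.DataFrame:
    """Fold change of each kinase's relative expression versus the control.

    Parameters
    ----------
    rel
        Output of :func:`normalize_ct` (columns kinase_id, gene_id, rel_expr).
    control_id
        Identifier of the empty-vector control (default ``CTRL``).
    drop_reference
        Optionally drop this gene column (the reference gene carries no
        information: its fold change is 1 by construction).

    Returns
    -------
    DataFrame of positive fold changes, kinases as rows (control first),
    genes as columns.  The control row is exactly 1.  A ``provenance`` note
    is stored in ``.attrs``.

    Raises
    ------
    CtTableError
        If the matrix is incomplete or the control is missing for any gene.
    """
    required = {"kinase_id", "gene_id", "rel_expr"}
    if not required.issubset(rel.columns):
        raise CtTableError(
            f"relative-expression table needs columns {sorted(required)}"
        )
    if (rel["rel_expr"] <= 0).any() or not np.isfinite(rel["rel_expr"]).all():
        raise CtTableError("relative expression values must be finite and > 0")
    mat = rel.pivot(index="kinase_id", columns="gene_id", values="rel_expr")
    if drop_reference is not None and drop_reference in mat.columns:
        mat = mat.drop(columns=drop_reference)
    if mat.isna().any().any():
        rows, cols = np.where(mat.isna().to_numpy())
        miss = [(mat.index[r], mat.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise CtTableError(f"incomplete matrix; missing (kinase, gene) pairs: {miss}")
    if control_id not in mat.index:
        raise CtTableError(f"control {control_id!r} absent from the table")
    ctrl = mat.loc[control_id]
    fc = mat.divide(ctrl, axis="columns")
    fc.loc[control_id] = 1.0
    order = [control_id] + [k for k in mat.index if k != control_id]
    fc = fc.loc[order]
    fc.index.name = "kinase_id"
    fc.columns.name = "gene_id"
    fc.attrs["provenance"] = f"fold change vs {control_id}, base-2 comparative Ct"
    return fc


def quantify(
    ct_table: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_id: str = DEFAULT_CONTROL_ID,
) -> pd.DataFrame:
    """Convenience composition: :func:`normalize_ct` then :func:`fold_change`.

    The reference gene's column is dropped from the resulting matrix.
    """
    rel = normalize_ct(ct_table, reference_gene=reference_gene)
    return fold_change(rel, control_id=control_id, drop_reference=reference_gene)
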