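"""Staged hit-calling for the pro-senescence kinase screen.

The screen selects kinases in three stages and intersects them:

1. anti-proliferative — relative proliferation at or below a threshold;
2. SASP inducer — fold change at or above a threshold in at least
   ``sasp_min_genes`` of the SASP-component genes (IL1A, IL1B, IL6, IL8);
3. p16 inducer — fold change of the p16 transcript at or above its own
   (lower) threshold, p16 being only weakly induced.

Kinases positive in all three stages are the senescence hits.  Calls are made
on point fold changes without a statistical test, mirroring a single-pass
screen; boundary values count as hits (inclusive thresholds).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr import DEFAULT_CONTROL_ID

DEFAULT_SASP_GENES = ("IL1A", "IL1B", "IL6", "IL8")
DEFAULT_P16_GENE = "p16"

#: Exclusive regions of the three-set Venn diagram, in reporting order.
VENN_REGIONS = (
    "prolif_only",
    "sasp_only",
    "p16_only",
    "prolif_sasp",
    "prolif_p16",
    "sasp_p16",
    "prolif_sasp_p16",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and gene panels for staged hit-calling.

    The defaults make synthetic-screen recovery behave like the published
    funnel shape (broad anti-proliferative set, narrower SASP and p16 sets,
    final three-way intersection); they are configuration, not constants of
    the method.
    """

    prolif_threshold: float = 0.5
    sasp_fc_threshold: float = 2.0
    sasp_min_genes: int = 2
    p16_fc_threshold: float = 1.5
    sasp_genes: tuple[str, ...] = DEFAULT_SASP_GENES
    p16_gene: str = DEFAULT_P16_GENE
    control_id: str = DEFAULT_CONTROL_ID

    def __post_init__(self) -> None:
        if not (0 < self.prolif_threshold <= 1):
            raise ValueError("prolif_threshold must lie in (0, 1]")
        if self.sasp_fc_threshold <= 1 or self.p16_fc_threshold <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        if not (1 <= self.sasp_min_genes <= len(self.sasp_genes)):
            raise ValueError("sasp_min_genes must be in [1, len(sasp_genes)]")


@dataclass
class HitTable:
    """Per-kinase stage calls plus the three-set Venn summary.

    ``calls`` holds boolean columns ``anti_proliferative``, ``sasp_inducer``,
    ``p16_inducer`` and their conjunction ``senescence_hit``; ``venn_counts``
    the sizes of the seven exclusive Venn regions.
    """

    calls: pd.DataFrame
    venn_counts: dict[str, int] = field(default_factory=dict)

    @property
    def senescence_hits(self) -> list[str]:
        return self.calls.index[self.calls["senescence_hit"]].tolist()


def call_proliferation_hits(prolif: pd.DataFrame, cfg: ScreenConfig) -> pd.Series:
    """Flag kinases whose relative proliferation is ≤ the threshold.

    ``prolif`` has columns ``kinase_id, rel_prolif`` with the control at 1.
    The control itself is never a hit.  Boundary values are hits.
    """
    required = {"kinase_id", "rel_prolif"}
    if not required.issubset(prolif.columns):
        raise ValueError(f"proliferation table needs columns {sorted(required)}")
    s = prolif.set_index("kinase_id")["rel_prolif"].astype(float)
    if not np.isfinite(s).all():
        raise ValueError("non-finite relative proliferation value")
    if (s < 0).any():
        bad = s.index[s < 0][0]
        raise ValueError(f"negative relative proliferation for kinase {bad!r}")
    if cfg.control_id not in s.index:
        raise ValueError(f"control {cfg.control_id!r} absent from proliferation table")
    if abs(s[cfg.control_id] - 1.0) > 1e-9:
        raise ValueError(
            f"control {cfg.control_id!r} must have rel_prolif 1, got {s[cfg.control_id]}"
        )
    hits = s <= cfg.prolif_threshold
    hits[cfg.control_id] = False
    hits.name = "anti_proliferative"
    return hits


def call_induction_hits(
    fc: pd.DataFrame,
    genes: list[str] | tuple[str, ...],
    fc_threshold: float,
    min_genes: int = 1,
) -> pd.Series:
    """Flag kinases inducing ≥ ``min_genes`` of ``genes`` at ≥ ``fc_threshold``.

    For the p16 call use a single-gene panel with ``min_genes=1``.  Unknown
    genes are a hard error; thresholds are inclusive.
    """
    genes = list(genes)
    unknown = [g for g in genes if g not in fc.columns]
    if unknown:
        raise ValueError(f"gene(s) not in fold-change matrix: {unknown}")
    if not (1 <= min_genes <= len(genes)):
        raise ValueError("min_genes must be in [1, len(genes)]")
    hits = (fc[genes] >= fc_threshold).sum(axis=1) >= min_genes
    hits.name = "induction_hit"
    return hits


def intersect_hits(
    prolif_hits: pd.Series, sasp_hits: pd.Series, p16_hits: pd.Series
) -> HitTable:
    """Intersect the three stage calls into a :class:`HitTable`.

    All three calls must cover the same kinase universe.  The Venn summary
    counts the seven exclusive regions of (anti-proliferative, SASP inducer,
    p16 inducer); their sum equals the number of kinases flagged anywhere.
    """
    universe = set(prolif_hits.index)
    if set(sasp_hits.index) != universe or set(p16_hits.index) != universe:
        raise ValueError("hit calls cover different kinase universes")
    idx = prolif_hits.index
    a = prolif_hits.astype(bool)
    b = sasp_hits.reindex(idx).astype(bool)
    c = p16_hits.reindex(idx).astype(bool)
    calls = pd.DataFrame(
        {
            "anti_proliferative": a,
            "sasp_inducer": b,
            "p16_inducer": c,
            "senescence_hit": a & b & c,
        }
    )
    calls.index.name = "kinase_id"
    venn = {
        "prolif_only": int((a & ~b & ~c).sum()),
        "sasp_only": int((~a & b & ~c).sum()),
        "p16_only": int((~a & ~b & c).sum()),
        "prolif_sasp": int((a & b & ~c).sum()),
        "prolif_p16": int((a & ~b & c).sum()),
        "sasp_p16": int((~a & b & c).sum()),
        "prolif_sasp_p16": int((a & b & c).sum()),
    }
    return HitTable(calls=calls, venn_counts=venn)


def call_hits(fc: pd.DataFrame, prolif: pd.DataFrame, cfg: ScreenConfig | None = None) -> HitTable:
    """Run the full staged selection on a fold-change matrix + proliferation table."""
    cfg = cfg or ScreenConfig()
    prolif_hits = call_proliferation_hits(prolif, cfg)
    fc = fc.reindex(prolif_hits.index)
    if fc.isna().any().any():
        missing = fc.index[fc.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"fold-change matrix lacks kinase(s) {missing}")
    sasp_hits = call_induction_hits(
        fc, cfg.sasp_genes, cfg.sasp_fc_threshold, cfg.sasp_min_genes
    )
    p16_hits = call_induction_hits(fc, [cfg.p16_gene], cfg.p16_fc_threshold, 1)
    # control is definitionally no hit anywhere (fc row is exactly 1)
    sasp_hits[cfg.control_id] = False
    p16_hits[cfg.control_id] = False
    return intersect_hits(prolif_hits, sasp_hits, p16_hits)
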