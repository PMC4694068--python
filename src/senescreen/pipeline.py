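"""End-to-end orchestration: normalize → fold change → hits → profiles → enrichment.

The profile stage (correlations, clustering) runs on the fold-change matrix
restricted to the anti-proliferative kinases, mirroring a screen workflow in
which only the first-stage selection is profiled; the control row is
excluded from correlations.  Every stage error is re-raised as a
:class:`PipelineStageError` naming the stage.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io, profiles, qpcr, screen
from .enrichment import QueryList, enrich

logger = logging.getLogger("senescreen")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run; flags mirror these keys."""

    ct_path: str
    prolif_path: str
    outdir: str
    gmt_path: str | None = None
    query_path: str | None = None
    population_total: int | None = None
    reference_gene: str = qpcr.DEFAULT_REFERENCE_GENE
    screen_config: screen.ScreenConfig = field(default_factory=screen.ScreenConfig)
    min_overlap: int = 2
    p_mode: str = "ease"
    seed: int = 0
    verbosity: int = 1


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as err:
                raise PipelineStageError(name, str(err)) from err
        return wrapped
    return decorator


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write all artifacts; returns artifact paths.

    Artifacts: relative expression, fold-change matrix, log2 and scaled01
    matrices, hit/Venn tables, long-format correlation table, Newick
    dendrogram, optional enrichment table, and ``run_log.txt`` echoing the
    package/library versions, the seed and the effective configuration.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    cfg = config.screen_config

    ct = _stage("read-inputs")(io.read_ct_tsv)(config.ct_path)
    prolif = _stage("read-inputs")(io.read_proliferation_tsv)(config.prolif_path)

    rel = _stage("normalize")(qpcr.normalize_ct)(ct, reference_gene=config.reference_gene)
    fc = _stage("fold-change")(qpcr.fold_change)(
        rel, control_id=cfg.control_id, drop_reference=config.reference_gene
    )
    artifacts["rel_expr"] = outdir / "rel_expr.tsv"
    rel.to_csv(artifacts["rel_expr"], sep="\t", index=False, lineterminator="\n")
    artifacts["fold_change"] = outdir / "fold_change.tsv"
    io.write_fold_change_tsv(fc, artifacts["fold_change"])

    hits = _stage("call-hits")(screen.call_hits)(fc, prolif, cfg)
    artifacts["hits"] = outdir / "hits.tsv"
    io.write_hit_table(hits, artifacts["hits"])
    artifacts["venn"] = outdir / "venn.tsv"
    io.write_venn_tsv(hits, artifacts["venn"])

    def _profiles():
        selected = hits.calls.index[hits.calls["anti_proliferative"]]
        sub = fc.loc[selected]
        if len(sub) < 3:
            raise ValueError(
                f"only {len(sub)} anti-proliferative kinases; need >= 3 to correlate"
            )
        corr = profiles.spearman_matrix(sub)
        dendro = profiles.cluster_profiles(sub)
        log2 = profiles.log2_matrix(fc)
        scaled = profiles.scale_matrix(fc)
        return corr, dendro, log2, scaled

    corr, dendro, log2, scaled = _stage("profiles")(_profiles)()
    artifacts["correlation"] = outdir / "correlation.tsv"
    io.write_correlation_tsv(corr, artifacts["correlation"])
    artifacts["dendrogram"] = outdir / "dendrogram.nwk"
    io.write_newick(dendro, artifacts["dendrogram"])
    artifacts["log2_matrix"] = outdir / "log2_matrix.tsv"
    io.write_fold_change_tsv(log2, artifacts["log2_matrix"])
    artifacts["scaled_matrix"] = outdir / "scaled_matrix.tsv"
    io.write_fold_change_tsv(scaled, artifacts["scaled_matrix"])

    if config.gmt_path is not None:
        def _enrich():
            if config.population_total is None:
                raise ValueError("population_total is required with a GMT file")
            collection = io.read_gmt(config.gmt_path, config.population_total)
            if config.query_path is not None:
                genes = io.read_gene_list(config.query_path)
            else:
                genes = hits.senescence_hits  # screen hits as the query list
            if not genes:
                raise ValueError("empty enrichment query (no senescence hits?)")
            query = QueryList(genes=set(genes), mapped_total=len(set(genes)))
            return enrich(query, collection, min_overlap=config.min_overlap,
                          p_mode=config.p_mode)
        result = _stage("enrichment")(_enrich)()
        artifacts["enrichment"] = outdir / "enrichment.tsv"
        result.to_csv(artifacts["enrichment"], sep="\t", index=False, lineterminator="\n")

    artifacts["run_log"] = outdir / "run_log.txt"
    _write_run_log(artifacts["run_log"], config, hits)
    logger.info("pipeline finished; %d artifacts in %s", len(artifacts), outdir)
    return artifacts


def _write_run_log(path: Path, config: PipelineConfig, hits: screen.HitTable) -> None:
    import numpy
    import pandas
    import scipy

    lines = [
        f"senescreen {__version__}",
        f"python {sys.version.split()[0]}",
        f"numpy {numpy.__version__}; scipy {scipy.__version__}; pandas {pandas.__version__}",
        f"seed = {config.seed}",
        "config:",
    ]
    for key, value in dataclasses.asdict(config).items():
        lines.append(f"  {key} = {value}")
    lines.append(f"senescence hits: {len(hits.senescence_hits)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
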