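"""Synthetic screen generator with the latent NF-κB program structure.

The generator emulates the shape of an activated-kinase senescence screen:
~200 transduced kinases plus an empty-vector control, profiled by qPCR for
four SASP components (IL1A, IL1B, IL6, IL8), three intracellular NF-κB
targets (IKBA, SOD2, COX2), p16 and the ACTB reference, plus a relative
proliferation readout.

A planted subset of kinases ("hits") carries a single latent program
strength e ≥ 0 (log2 units).  Every NF-κB-driven gene g responds with
``loading_g · e`` (loadings ≈ 1), so SASP components and intracellular
NF-κB targets co-vary tightly across hits.  p16 responds only weakly to the
shared program (loading 0.15) but carries its own NF-κB-independent
induction term, which keeps p16 induced in hits (fold changes around ~2.5×,
far below the >100× a strong SASP response reaches) yet decoupled from the
latent program's ordering — the structure that puts p16 on its own branch
when genes are clustered by induction profile.

Noise enters on the Ct scale (how qPCR variation actually arises), per
replicate.  All randomness flows from one integer seed through spawned
``numpy.random.SeedSequence`` streams, so each sub-generator is independent
yet fully reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)

import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCollection, QueryList

DEFAULT_SASP_GENES = ("IL1A", "IL1B", "IL6", "IL8")
DEFAULT_NFKB_GENES = ("IKBA", "SOD2", "COX2")

#: Baseline Ct per transcript in the control, chosen in the range typical of
#: fibroblast cDNA: abundant ACTB cycles early, silent cytokines late.
DEFAULT_BASE_CT = {
    "ACTB": 18.0,
    "IL1A": 31.0,
    "IL1B": 30.0,
    "IL6": 29.0,
    "IL8": 28.0,
    "IKBA": 24.0,
    "SOD2": 23.0,
    "COX2": 26.0,
    "p16": 28.0,
}


@dataclass
class SyntheticScreenSpec:
    """Parameters of the synthetic screen; defaults are the study conditions.

    ``hit_effect_log2`` mean 4, sd 1.5 (truncated at 0) puts the strongest
    hits' SASP inductions above 100×; the p16 loading of 0.15 plus an
    independent p16-specific induction (TruncNormal(0.7, 0.15, ≥0) log2)
    keeps p16 fold changes around 2–2.5× in typical hits.
    """

    n_kinases: int = 200
    n_hits: int = 33
    sasp_genes: tuple[str, ...] = DEFAULT_SASP_GENES
    nfkb_genes: tuple[str, ...] = DEFAULT_NFKB_GENES
    p16_gene: str = "p16"
    reference_gene: str = "ACTB"
    control_id: str = "CTRL"
    hit_effect_log2_mean: float = 4.0
    hit_effect_log2_sd: float = 1.5
    p16_loading: float = 0.15
    p16_independent_mean: float = 0.7
    p16_independent_sd: float = 0.15
    ct_noise_sd: float = 0.2
    replicates: int = 2
    prolif_hit_mean: float = 0.3
    prolif_hit_sd: float = 0.08
    prolif_null_mean: float = 1.0
    prolif_null_sd: float = 0.15
    base_ct: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_CT))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_hits <= self.n_kinases):
            raise ValueError("need 0 <= n_hits <= n_kinases")
        for name in (
            "hit_effect_log2_sd", "p16_independent_sd", "ct_noise_sd",
            "prolif_hit_sd", "prolif_null_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def target_genes(self) -> tuple[str, ...]:
        return tuple(self.sasp_genes) + tuple(self.nfkb_genes) + (self.p16_gene,)

    @property
    def gene_loadings(self) -> dict[str, float]:
        loadings = {g: 1.0 for g in self.sasp_genes + self.nfkb_genes}
        loadings[self.p16_gene] = self.p16_loading
        return loadings


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by resampling; degenerate sd → constant."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size)
    while (out < 0).any():
        bad = out < 0
        out[bad] = rng.normal(mean, sd, bad.sum())
    return out


def generate_screen(
    spec: SyntheticScreenSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic screen: (Ct table, proliferation table, truth).

    Returns
    -------
    ct_table
        Long-format Ct table (sample_id, kinase_id, gene_id, replicate, ct)
        for all kinases plus the control, every target gene and the
        reference.  ``Ct = base_ct[gene] − true_log2fc + N(0, ct_noise_sd)``
        per replicate; the reference gene never responds to the program.
    prolif_table
        (kinase_id, rel_prolif), hits drawn low, nulls around 1, control
        exactly 1.
    truth
        Per kinase: ``is_hit``, ``latent_effect`` (log2), and the true log2
        fold change per target gene as ``log2fc_<gene>`` columns.
    """
    spec = spec or SyntheticScreenSpec()
    ss = np.random.SeedSequence(spec.seed)
    rng_hits, rng_eff, rng_p16, rng_noise, rng_prolif = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    kinases = [f"KIN{i + 1:03d}" for i in range(spec.n_kinases)]
    hit_idx = np.sort(rng_hits.choice(spec.n_kinases, size=spec.n_hits, replace=False))
    is_hit = np.zeros(spec.n_kinases, dtype=bool)
    is_hit[hit_idx] = True

    latent = np.zeros(spec.n_kinases)
    latent[is_hit] = _trunc_normal(
        rng_eff, spec.hit_effect_log2_mean, spec.hit_effect_log2_sd, spec.n_hits
    )
    p16_extra = np.zeros(spec.n_kinases)
    p16_extra[is_hit] = _trunc_normal(
        rng_p16, spec.p16_independent_mean, spec.p16_independent_sd, spec.n_hits
    )

    loadings = spec.gene_loadings
    genes = list(spec.target_genes)
    true_log2fc = np.column_stack(
        [loadings[g] * latent + (p16_extra if g == spec.p16_gene else 0.0) for g in genes]
    )

    all_kinases = [spec.control_id] + kinases
    effects = np.vstack([np.zeros(len(genes)), true_log2fc])  # control row first
    all_genes = genes + [spec.reference_gene]
    base = np.array([spec.base_ct[g] for g in all_genes])
    effects_full = np.column_stack([effects, np.zeros(len(all_kinases))])

    n_k, n_g, n_r = len(all_kinases), len(all_genes), spec.replicates
    noise = rng_noise.normal(0.0, spec.ct_noise_sd, size=(n_k, n_g, n_r))
    ct = base[None, :, None] - effects_full[:, :, None] + noise

    idx = pd.MultiIndex.from_product(
        [all_kinases, all_genes, range(1, n_r + 1)],
        names=["kinase_id", "gene_id", "replicate"],
    )
    ct_table = (
        pd.Series(ct.reshape(-1), index=idx, name="ct")
        .reset_index()
        .assign(sample_id="S1")
    )[["sample_id", "kinase_id", "gene_id", "replicate", "ct"]]

    rel_prolif = np.where(
        is_hit,
        rng_prolif.normal(spec.prolif_hit_mean, spec.prolif_hit_sd, spec.n_kinases),
        rng_prolif.normal(spec.prolif_null_mean, spec.prolif_null_sd, spec.n_kinases),
    )
    rel_prolif = np.clip(rel_prolif, 0.0, None)
    prolif_table = pd.DataFrame(
        {
            "kinase_id": [spec.control_id] + kinases,
            "rel_prolif": np.concatenate([[1.0], rel_prolif]),
        }
    )

    truth = pd.DataFrame(
        {
            "kinase_id": kinases,
            "is_hit": is_hit,
            "latent_effect": latent,
            **{f"log2fc_{g}": true_log2fc[:, j] for j, g in enumerate(genes)},
        }
    )
    return ct_table, prolif_table, truth


def generate_genesets(
    n_terms: int = 20,
    population_total: int = 5590,
    query_size: int = 18,
    planted: list[tuple[int, int]] | None = None,
    filler_size_range: tuple[int, int] = (10, 300),
    seed: int = 0,
) -> tuple[GeneSetCollection, QueryList]:
    """Generate a gene-set collection with planted query overlaps.

    ``planted`` lists (term_size K, overlap k) pairs; each planted term
    contains exactly k genes of the query and K − k background genes.
    Remaining terms up to ``n_terms`` are filled with random non-query genes
    (overlap 0).  Gene symbols are synthetic (``GENE00001`` …).

    Raises ``ValueError`` for infeasible counts (k > min(K, L) or K >
    population_total).
    """
    planted = planted or []
    L = query_size
    N = population_total
    if L < 1 or L > N:
        raise ValueError("query_size must be in [1, population_total]")
    for K, k in planted:
        if k < 0 or k > min(K, L):
            raise ValueError(f"infeasible planted overlap (K={K}, k={k}) for L={L}")
        if K > N:
            raise ValueError(f"planted term size {K} exceeds population {N}")
    if len(planted) > n_terms:
        raise ValueError("more planted terms than n_terms")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = np.array([f"GENE{i + 1:05d}" for i in range(N)])
    query_genes = rng.choice(universe, size=L, replace=False)
    background = np.setdiff1d(universe, query_genes)

    sets = []
    for t, (K, k) in enumerate(planted):
        members = np.concatenate(
            [
                rng.choice(query_genes, size=k, replace=False),
                rng.choice(background, size=K - k, replace=False),
            ]
        )
        sets.append(
            GeneSet(
                term_id=f"TERM{t + 1:04d}",
                name=f"planted term {t + 1} (K={K}, k={k})",
                genes=frozenset(members),
            )
        )
    lo, hi = filler_size_range
    for t in range(len(planted), n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(background, size=min(size, background.size), replace=False)
        sets.append(
            GeneSet(
                term_id=f"TERM{t + 1:04d}",
                name=f"filler term {t + 1}",
                genes=frozenset(members),
            )
        )
    collection = GeneSetCollection(sets=sets, population_total=N)
    query = QueryList(genes=set(query_genes), mapped_total=L)
    return collection, query
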