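"""Surrogate-null inference: cross-stage overlap test and category enrichment.

Both procedures replace the real per-sample stage vectors with
variogram-matched surrogates (spatially fair nulls) and re-run the exact
association pipeline on each draw:

* overlap permutation test — does the number of genes significant in all
  three stages exceed what spatially autocorrelated but topographically
  random phenotypes would produce? Empirical p is the raw proportion of
  null overlap counts >= the observed count.
* gene-category enrichment analysis (GCEA) — each gene is scored by its
  mean |r| across the three stages, categories by the mean score of their
  member genes, and category significance is assessed against an ensemble
  of randomized phenotypes, upper tail only, with BH-FDR across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .association import ExpressionMatrix, RowPearson, StageAssociation, bh_fdr
from .errors import FormatError, InvalidConfigError, InvalidInputError
from .neuro_maps import STAGES, SampleTable
from .surrogates import SurrogateGenerator, SurrogateSpec, pairwise_distances

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Observed cross-stage overlap versus its surrogate null distribution."""

    observed_count: int
    observed_genes: frozenset[str]
    null_counts: np.ndarray  # int per iteration
    p_perm: float
    n_iterations: int
    seed: int | None
    stage_set_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "observed_genes": sorted(self.observed_genes),
            "null_counts": [int(c) for c in self.null_counts],
            "p_perm": self.p_perm,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "stage_set_sizes": self.stage_set_sizes,
        }


@dataclass
class CategoryCollection:
    """Gene categories parsed from a GMT file: id -> (name, member set)."""

    categories: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.categories)

    def ids(self) -> list[str]:
        return list(self.categories)

    def filtered(
        self,
        universe: set[str] | frozenset[str],
        min_size: int = 5,
        max_size: int = 500,
    ) -> "CategoryCollection":
        """Restrict members to the analysis universe and apply size bounds."""
        out = {}
        for cid, (name, members) in self.categories.items():
            kept = members & frozenset(universe)
            if min_size <= len(kept) <= max_size:
                out[cid] = (name, kept)
        return CategoryCollection(out)


@dataclass
class GCEAResult:
    """Per-category enrichment against the randomized-phenotype ensemble."""

    table: pd.DataFrame  # category_id, name, size, score, null_mean, null_sd, p, q
    gene_scores: pd.Series  # gene_id -> observed mean |r| across stages
    null_scores: np.ndarray  # (n_null, n_categories)
    n_null: int
    seed: int | None

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def empirical_p(
    null: np.ndarray, observed: float, plus_one: bool = False
) -> float:
    """Proportion of null draws at or above the observed value.

    The raw-proportion rule (default) can return exactly 0; ``plus_one``
    applies the standard (1 + k) / (1 + n) correction instead.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise InvalidConfigError("empty null distribution")
    k = int(np.sum(null >= observed))
    if plus_one:
        return (1 + k) / (1 + null.size)
    return k / null.size


def read_gmt(path: str | Path) -> CategoryCollection:
    """Parse a GMT file: tab-separated id, description, member genes.

    Duplicate member ids within a category are collapsed; malformed lines
    (fewer than three fields) raise a format error with the line number.
    """
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f">= 1 member, got {len(fields)} fields"
                )
            cid, name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: category '{cid}' has no members")
            categories[cid] = (name, frozenset(members))
    if not categories:
        raise InvalidInputError(f"GMT file {path} contains no categories")
    return CategoryCollection(categories)


def gene_score(abs_r_by_stage: Mapping[str, float] | np.ndarray) -> float:
    """Mean of a gene's absolute stage correlations: (sum of |r|) / n_stages."""
    if isinstance(abs_r_by_stage, Mapping):
        vals = np.asarray([abs_r_by_stage[s] for s in STAGES], dtype=float)
    else:
        vals = np.abs(np.asarray(abs_r_by_stage, dtype=float))
    if not np.all(np.isfinite(vals)):
        raise InvalidInputError("gene score requires a defined r in every stage")
    return float(np.abs(vals).mean())


def gene_scores_from_associations(
    assocs: Mapping[str, StageAssociation]
) -> pd.Series:
    """Observed gene scores (mean |r| over stages) for genes defined in all stages."""
    missing = [s for s in STAGES if s not in assocs]
    if missing:
        raise InvalidInputError(f"missing stage associations: {missing}")
    gene_ids = assocs[STAGES[0]].gene_ids
    for s in STAGES[1:]:
        if assocs[s].gene_ids != gene_ids:
            raise InvalidInputError("stage associations cover different gene lists")
    r = np.vstack([assocs[s].r for s in STAGES])
    defined = np.all([assocs[s].defined for s in STAGES], axis=0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("gene scoring: %d genes undefined in >= 1 stage, excluded", n_dropped)
    scores = np.abs(r).mean(axis=0)
    return pd.Series(
        scores[defined], index=[g for g, d in zip(gene_ids, defined) if d], name="gene_score"
    )


def category_score(
    gene_scores: pd.Series | Mapping[str, float], members: frozenset[str] | set[str]
) -> float:
    """Mean gene score over category members present in the analysis."""
    if not isinstance(gene_scores, pd.Series):
        gene_scores = pd.Series(dict(gene_scores))
    present = gene_scores.index.intersection(list(members))
    if len(present) == 0:
        raise InvalidInputError("category has no scored member genes")
    return float(gene_scores.loc[present].mean())


class _NullEngine:
    """Shared machinery for both surrogate-null procedures.

    Precomputes, once per analysis: the sample distance matrix, one
    surrogate generator per stage, and the standardized expression matrix.
    Each null draw then yields the per-gene |r| (or significance sets) for
    all three stages at matrix-multiplication cost.
    """

    def __init__(
        self,
        samples: SampleTable,
        stage_values: Mapping[str, np.ndarray],
        expr: ExpressionMatrix,
        spec: SurrogateSpec | None,
    ):
        missing = [s for s in STAGES if s not in stage_values]
        if missing:
            raise InvalidInputError(f"missing stage value vectors: {missing}")
        n = len(samples)
        if expr.sample_ids != list(samples.sample_ids):
            raise InvalidInputError(
                "expression columns must match the sample table (same ids, same order)"
            )
        self.stage_values = {
            s: np.asarray(stage_values[s], dtype=float) for s in STAGES
        }
        for s, v in self.stage_values.items():
            if v.shape != (n,):
                raise InvalidInputError(f"stage '{s}' value vector length != n_samples")
        self.spec = spec or SurrogateSpec()
        self.distances = pairwise_distances(samples)
        self.generators = {
            s: SurrogateGenerator(self.stage_values[s], self.distances, self.spec)
            for s in STAGES
        }
        self.pearson = RowPearson(expr.values)
        self.gene_ids = np.asarray(expr.gene_ids)
        self.defined = self.pearson.defined

    def stage_r(self, y: np.ndarray) -> np.ndarray:
        return self.pearson.corr(y)

    def stage_sig_mask(self, y: np.ndarray, alpha: float) -> np.ndarray:
        """Boolean per-gene significance after within-stage BH-FDR."""
        r = self.pearson.corr(y)
        p = self.pearson.pvalues(r)
        sig = np.zeros(r.shape[0], dtype=bool)
        if self.defined.any():
            q = bh_fdr(p[self.defined])
            sig[self.defined] = q < alpha
        return sig

    def observed_overlap(self, alpha: float) -> tuple[frozenset[str], dict[str, int]]:
        masks = {s: self.stage_sig_mask(self.stage_values[s], alpha) for s in STAGES}
        inter = np.logical_and.reduce([masks[s] for s in STAGES])
        sizes = {s: int(masks[s].sum()) for s in STAGES}
        return frozenset(self.gene_ids[inter]), sizes


def overlap_permutation_test(
    samples: SampleTable,
    stage_values: Mapping[str, np.ndarray],
    expr: ExpressionMatrix,
    spec: SurrogateSpec | None = None,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    plus_one: bool = False,
) -> OverlapResult:
    """Permutation test for the three-stage overlap count with spatial nulls.

    Per iteration one independent surrogate is generated per stage, the full
    correlation + BH-FDR + thresholding pipeline is re-run per stage, and
    the intersection count is recorded. Expression stays fixed under the
    null; only the phenotype maps are randomized.
    """
    if n_iter < 1:
        raise InvalidConfigError(f"n_iter must be >= 1, got {n_iter}")
    engine = _NullEngine(samples, stage_values, expr, spec)
    observed_genes, sizes = engine.observed_overlap(alpha)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        inter = None
        for s in STAGES:
            surr = engine.generators[s](rng)
            mask = engine.stage_sig_mask(surr, alpha)
            inter = mask if inter is None else (inter & mask)
        null_counts[it] = int(inter.sum())
    p = empirical_p(null_counts, len(observed_genes), plus_one=plus_one)
    return OverlapResult(
        observed_count=len(observed_genes),
        observed_genes=observed_genes,
        null_counts=null_counts,
        p_perm=float(p),
        n_iterations=n_iter,
        seed=seed,
        stage_set_sizes=sizes,
    )


def gcea(
    samples: SampleTable,
    stage_values: Mapping[str, np.ndarray],
    expr: ExpressionMatrix,
    categories: CategoryCollection,
    spec: SurrogateSpec | None = None,
    n_null: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    max_size: int = 500,
    plus_one: bool = False,
) -> GCEAResult:
    """Gene-category enrichment with an autocorrelation-preserving null.

    Observed category scores are means of member gene scores (mean |r| over
    the three stages). The null ensemble randomizes the phenotypes - one
    surrogate per stage per draw - and recomputes all category scores, so
    gene-gene coexpression and spatial autocorrelation are both preserved
    under the null. One-sided upper-tail p per category; BH-FDR across
    categories.
    """
    if n_null < 1:
        raise InvalidConfigError(f"n_null must be >= 1, got {n_null}")
    engine = _NullEngine(samples, stage_values, expr, spec)
    defined = engine.defined
    scored_genes = engine.gene_ids[defined]
    universe = set(scored_genes)
    kept = categories.filtered(universe, min_size=min_size, max_size=max_size)
    if len(kept) == 0:
        raise InvalidInputError(
            "no categories left after restricting to analyzed genes and size bounds"
        )

    cat_ids = kept.ids()
    # membership matrix over the scored-gene axis
    pos = {g: i for i, g in enumerate(scored_genes)}
    member_mat = np.zeros((len(cat_ids), len(scored_genes)))
    sizes = np.empty(len(cat_ids), dtype=int)
    for k, cid in enumerate(cat_ids):
        idx = [pos[g] for g in kept.categories[cid][1]]
        member_mat[k, idx] = 1.0
        sizes[k] = len(idx)
    member_mat /= sizes[:, None]

    def all_stage_abs_r(vectors: Mapping[str, np.ndarray]) -> np.ndarray:
        r = np.vstack([engine.stage_r(vectors[s]) for s in STAGES])
        return np.abs(r[:, defined]).mean(axis=0)

    observed_gene_scores = all_stage_abs_r(engine.stage_values)
    observed_cat = member_mat @ observed_gene_scores

    rng = np.random.default_rng(seed)
    null_scores = np.empty((n_null, len(cat_ids)))
    for it in range(n_null):
        surr = {s: engine.generators[s](rng) for s in STAGES}
        null_scores[it] = member_mat @ all_stage_abs_r(surr)

    p = np.array(
        [empirical_p(null_scores[:, k], observed_cat[k], plus_one=plus_one)
         for k in range(len(cat_ids))]
    )
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "category_id": cat_ids,
            "name": [kept.categories[c][0] for c in cat_ids],
            "size": sizes,
            "score": observed_cat,
            "null_mean": null_scores.mean(axis=0),
            "null_sd": null_scores.std(axis=0, ddof=1) if n_null > 1
            else np.zeros(len(cat_ids)),
            "p": p,
            "q": q,
        }
    )
    return GCEAResult(
        table=table,
        gene_scores=pd.Series(observed_gene_scores, index=list(scored_genes)),
        null_scores=null_scores,
        n_null=n_null,
        seed=seed,
    )
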