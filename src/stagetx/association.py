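"""Stage-wise gene-map spatial correlation with FDR and cross-stage intersection.

For each illness stage, every gene's normalized expression profile across
tissue samples is correlated (Pearson) against the per-sample map values of
that stage's case-control z-map. Two-sided p-values come from the exact
t transform with n-2 degrees of freedom, multiple testing is controlled by
Benjamini-Hochberg within the stage, and the three stage-significant gene
sets are intersected to find genes consistently associated across stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InvalidInputError
from .neuro_maps import STAGES, SampleValues

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression (unitless, typically in [0, 1])."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidInputError("duplicate sample ids")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidInputError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        self.values = values

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "gene_id":
            raise FormatError(f"expression TSV {path} must start with a gene_id column")
        return cls(
            gene_ids=df["gene_id"].astype(str).tolist(),
            sample_ids=[str(c) for c in df.columns[1:]],
            values=df.iloc[:, 1:].to_numpy(float),
        )


@dataclass
class StageAssociation:
    """Per-gene correlation results for one stage.

    ``defined`` is False for genes with zero expression variance across the
    used samples; such genes have NaN r/p/q and are excluded from FDR.
    """

    stage_label: str
    gene_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    defined: np.ndarray
    n_used: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "r": self.r,
                "p": self.p,
                "q": self.q,
                "significant": self.significant,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OverlapSet:
    """Per-stage significant gene sets and their three-way intersection."""

    stage_sets: dict[str, frozenset[str]]
    intersection: frozenset[str]
    observed_count: int


def restrict_to_gene_list(
    expr: ExpressionMatrix, gene_list: Iterable[str]
) -> ExpressionMatrix:
    """Keep only genes present in both the matrix and the list, in matrix order.

    Mirrors restricting the expression matrix to a disease-associated gene
    list (e.g. GWAS-derived genes) before the association analysis.
    """
    wanted = {str(g) for g in gene_list}
    if not wanted:
        raise InvalidInputError("gene list is empty")
    keep = [i for i, g in enumerate(expr.gene_ids) if g in wanted]
    if not keep:
        raise InvalidInputError("gene list shares no genes with the expression matrix")
    logger.info(
        "gene-list restriction: kept %d of %d genes (%d listed)",
        len(keep), expr.n_genes, len(wanted),
    )
    return ExpressionMatrix(
        gene_ids=[expr.gene_ids[i] for i in keep],
        sample_ids=list(expr.sample_ids),
        values=expr.values[keep, :],
    )


class RowPearson:
    """Vectorized Pearson correlation of many gene rows against one vector.

    The expression matrix is standardized once; each subsequent phenotype
    vector costs a single matrix-vector product. Used heavily by the
    surrogate-null loops where thousands of vectors hit the same matrix.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        self.n = values.shape[1]
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        self.defined = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
        safe_sd = np.where(sd > 0, sd, 1.0)
        self.z = (values - mu) / safe_sd
        self.z[~self.defined, :] = 0.0

    def corr(self, y: np.ndarray) -> np.ndarray:
        """Per-row Pearson r with y; NaN for zero-variance rows."""
        y = np.asarray(y, dtype=float)
        sd = y.std()
        if sd == 0 or not np.isfinite(sd):
            raise InvalidInputError("phenotype vector has zero variance")
        zy = (y - y.mean()) / sd
        r = self.z @ zy / self.n
        np.clip(r, -1.0, 1.0, out=r)
        r[~self.defined] = np.nan
        return r

    def pvalues(self, r: np.ndarray) -> np.ndarray:
        """Two-sided p from the t transform with n-2 degrees of freedom."""
        df = self.n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isfinite(t), p, np.where(np.isnan(r), np.nan, 0.0))
        return p


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError("pvals must be a 1-D array")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must be finite and within [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(q, 1.0)


def gene_map_correlation(
    expr: ExpressionMatrix,
    sample_values: SampleValues,
    alpha: float = 0.05,
    stage_label: str | None = None,
) -> StageAssociation:
    """Gene-wise Pearson correlation of expression against per-sample map values.

    Only samples shared between the expression columns and the value table
    and flagged included enter the correlation; at least 3 are required.
    Zero-variance genes are flagged undefined and excluded from FDR.
    """
    col_of = {s: j for j, s in enumerate(expr.sample_ids)}
    use_cols: list[int] = []
    use_vals: list[float] = []
    for sid, val, inc in zip(
        sample_values.sample_ids, sample_values.values, sample_values.included
    ):
        if inc and sid in col_of:
            use_cols.append(col_of[sid])
            use_vals.append(val)
    n_used = len(use_cols)
    if n_used < 3:
        raise InvalidInputError(
            f"need >= 3 usable samples shared with the expression matrix, got {n_used}"
        )
    y = np.asarray(use_vals, dtype=float)
    engine = RowPearson(expr.values[:, use_cols])
    r = engine.corr(y)
    p = engine.pvalues(r)
    q = np.full(expr.n_genes, np.nan)
    significant = np.zeros(expr.n_genes, dtype=bool)
    defined = engine.defined.copy()
    if defined.any():
        q[defined] = bh_fdr(p[defined])
        significant[defined] = q[defined] < alpha
    label = stage_label or sample_values.stage_label or "unknown"
    return StageAssociation(
        stage_label=label,
        gene_ids=list(expr.gene_ids),
        r=r,
        p=p,
        q=q,
        significant=significant,
        defined=defined,
        n_used=n_used,
        alpha=alpha,
    )


def stage_gene_set(assoc: StageAssociation, alpha: float = 0.05) -> frozenset[str]:
    """Genes with BH-adjusted q strictly below alpha."""
    with np.errstate(invalid="ignore"):
        sig = assoc.defined & (np.nan_to_num(assoc.q, nan=1.0) < alpha)
    return frozenset(g for g, s in zip(assoc.gene_ids, sig) if s)


def intersect_stages(
    stage_sets: Mapping[str, Iterable[str]],
    stages: tuple[str, ...] = STAGES,
) -> OverlapSet:
    """Intersect per-stage significant gene sets across the expected stages."""
    missing = [s for s in stages if s not in stage_sets]
    if missing:
        raise InvalidInputError(f"missing stage sets: {missing}")
    sets = {s: frozenset(str(g) for g in stage_sets[s]) for s in stages}
    inter = frozenset.intersection(*sets.values())
    return OverlapSet(stage_sets=sets, intersection=inter, observed_count=len(inter))
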