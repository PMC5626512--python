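"""Correlated sampling of single-cell protein copy numbers.

Co-regulation makes enzyme abundances correlate across cells. We estimate
gene-gene Pearson correlations from a (quantile-normalized) expression
matrix and impose them on the sampled protein counts with a Gaussian
copula (NORTA): correlated standard normals ``z = L @ eps`` are pushed
through the normal CDF and the per-protein gamma quantile functions, so
every protein keeps exactly its measured gamma marginal while acquiring
the target dependence structure on the latent normal scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .proteomics import CalibrationModel, ProteinMarginal

__all__ = [
    "ExpressionMatrix",
    "CorrelationModel",
    "CellCounts",
    "quantile_normalize",
    "compute_correlations",
    "nearest_psd_correlation",
    "sample_population",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x arrays matrix of non-negative expression values."""

    values: np.ndarray
    gene_ids: list[str]
    array_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x arrays)")
        n_genes, n_arrays = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.array_ids) != n_arrays:
            raise ValueError("gene/array id lengths inconsistent with matrix shape")
        if n_arrays < 2:
            raise ValueError("at least 2 arrays are required")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(g) for g in df.index],
                   [str(a) for a in df.columns])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.array_ids)


@dataclass
class CorrelationModel:
    """Gene-gene Pearson correlation matrix with its Cholesky factor.

    ``R`` is the raw (symmetrized) correlation estimate; ``L`` is the
    lower-triangular factor of the PSD-repaired matrix, used to impose the
    correlations on latent standard normals.
    """

    gene_ids: list[str]
    R: np.ndarray
    L: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        k = len(self.gene_ids)
        if self.R.shape != (k, k):
            raise ValueError("correlation matrix shape inconsistent with gene ids")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have a unit diagonal")
        if self.L is None:
            repaired = nearest_psd_correlation(self.R)
            self.L = np.linalg.cholesky(
                repaired + 1e-12 * np.eye(k))
            if np.abs(self.L @ self.L.T - repaired).max() > 1e-8:
                raise ValueError("Cholesky factorization failed to reproduce "
                                 "the repaired correlation matrix")

    @classmethod
    def identity(cls, gene_ids: Sequence[str]) -> "CorrelationModel":
        k = len(gene_ids)
        return cls(list(gene_ids), np.eye(k), np.eye(k))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.R, index=self.gene_ids, columns=self.gene_ids).to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CorrelationModel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(g) for g in df.index], df.to_numpy(float))


@dataclass
class CellCounts:
    """Cells x proteins matrix of sampled copy numbers."""

    values: np.ndarray
    protein_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.protein_ids):
            raise ValueError("protein id count inconsistent with matrix width")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.protein_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all arrays onto a common empirical distribution.

    Each array's sorted values are replaced by the across-array means of
    the order statistics; within-array ranks are preserved and ties
    receive the mean of the target values at their tied positions.
    """
    x = m.values
    n_genes, n_arrays = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_arrays):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return ExpressionMatrix(out, list(m.gene_ids), list(m.array_ids))


def nearest_psd_correlation(R: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair an indefinite pseudo-correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the reconstruction is
    rescaled back to a unit diagonal. Finite-sample Pearson estimates
    assembled gene-pair-wise are routinely indefinite; Cholesky requires
    PSD.
    """
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, eig_floor, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def compute_correlations(
    m: ExpressionMatrix,
    probe_map: Mapping[str, Sequence[str]] | None = None,
) -> CorrelationModel:
    """Estimate gene-gene Pearson correlations across arrays.

    When ``probe_map`` maps a gene to multiple probe row ids, the probe
    rows are averaged first. Zero-variance genes get correlation 0 with
    everything (self-correlation 1) and a logged warning.
    """
    if len(m.array_ids) < 3:
        raise ValueError("at least 3 arrays are required for a Pearson estimate")
    if probe_map is not None:
        row_of = {g: i for i, g in enumerate(m.gene_ids)}
        genes = list(probe_map)
        x = np.vstack([
            m.values[[row_of[p] for p in probes], :].mean(axis=0)
            for probes in probe_map.values()
        ])
    else:
        genes = list(m.gene_ids)
        x = m.values

    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning(
            "compute_correlations: %d zero-variance gene(s) "
            "(correlations set to 0): %s", flat.size,
            ", ".join(genes[i] for i in flat[:10]))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(x)
    R = np.atleast_2d(R)
    R[flat, :] = 0.0
    R[:, flat] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return CorrelationModel(genes, R)


def sample_population(
    n_cells: int,
    marginals: Sequence[ProteinMarginal],
    corr: CorrelationModel | None,
    cal: CalibrationModel,
    seed: int,
) -> CellCounts:
    """Draw one protein-count vector per cell via a Gaussian copula.

    For proteins covered by ``corr``: ``z = eps @ L.T`` with iid standard
    normal ``eps``, ``u = Phi(z)``, fluorescence ``f = F_gamma^{-1}(u)``
    per protein, count ``= max(a f^b, floor)``. Proteins absent from the
    correlation model are sampled independently. Bit-reproducible for a
    given seed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not marginals:
        raise ValueError("no protein marginals supplied")
    by_id = {m.protein_id: m for m in marginals}
    if len(by_id) != len(marginals):
        raise ValueError("duplicate protein ids in marginals")

    corr_ids = [g for g in (corr.gene_ids if corr is not None else [])
                if g in by_id]
    indep_ids = [m.protein_id for m in marginals if m.protein_id not in set(corr_ids)]

    rng = np.random.Generator(np.random.Philox(key=seed))
    fluor = np.empty((n_cells, len(marginals)))
    order = corr_ids + indep_ids

    if corr_ids:
        # draw on the full correlated set, then keep the measured columns:
        # marginalizing a multivariate normal preserves pairwise correlations
        idx = [corr.gene_ids.index(g) for g in corr_ids]
        eps = rng.standard_normal((n_cells, len(corr.gene_ids)))
        z = (eps @ corr.L.T)[:, idx]
        # guard against u exactly 0/1 before the gamma quantile transform
        u = np.clip(special.ndtr(z), 1e-15, 1 - 1e-15)
        for j, g in enumerate(corr_ids):
            marg = by_id[g]
            fluor[:, j] = stats.gamma.ppf(u[:, j], a=marg.shape, scale=marg.scale)
    for j, g in enumerate(indep_ids, start=len(corr_ids)):
        marg = by_id[g]
        fluor[:, j] = rng.gamma(shape=marg.shape, scale=marg.scale, size=n_cells)

    counts = np.maximum(cal.a * np.power(fluor, cal.b), cal.floor)
    return CellCounts(counts, order, seed)
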