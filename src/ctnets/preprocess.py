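"""Covariate residualization, interregional correlation, bootstrap, thresholding.

The covariance network of a group is the regions-by-regions Pearson
correlation of thickness residuals across subjects, after removing age,
sex, the age-by-sex interaction and each subject's mean cortical thickness
by ordinary least squares at every region.  Negative correlations are
discarded (set to zero) before graph construction; binary graphs are then
obtained by keeping the K strongest positive edges at each point of a
sparsity sweep.

Sparsity convention
-------------------
"Sparsity" here is the fraction of *absent* edges, so density = 1 -
sparsity and the standard sweep 0.5..0.9 spans densities 0.5 down to 0.1.
The opposite reading ("present" fraction) is available via the
``convention`` argument for datasets thresholded the other way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import ThicknessDataset

__all__ = [
    "ResidualMatrix",
    "CorrelationMatrix",
    "DESIGN_COLUMNS",
    "design_matrix",
    "residualize",
    "correlation_matrix",
    "residual_correlation",
    "bootstrap_indices",
    "bootstrap_sample",
    "sparsity_grid",
    "edge_capacity",
    "n_edges_at_sparsity",
    "rank_edges",
    "threshold_to_binary",
]

log = logging.getLogger(__name__)

DESIGN_COLUMNS = ("intercept", "age", "sex", "age_x_sex", "mean_ct")

#: The sweep used throughout: sparsity 0.5 to 0.9 in steps of 0.02.
DEFAULT_GRID = np.round(np.arange(0.5, 0.9 + 1e-9, 0.02), 10)


@dataclass
class ResidualMatrix:
    """OLS residuals of thickness on the nuisance design, per region."""

    values: np.ndarray  # (M, N)
    design: np.ndarray  # (M, P)
    design_labels: tuple[str, ...] = DESIGN_COLUMNS
    region_names: np.ndarray | None = None


@dataclass
class CorrelationMatrix:
    """Symmetric interregional Pearson matrix with a zero diagonal."""

    r: np.ndarray
    positive_only: bool = True
    region_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.r = r

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


def design_matrix(age: np.ndarray, sex: np.ndarray, thickness: np.ndarray) -> np.ndarray:
    """[1, age, sex, age*sex, subject mean thickness] design.

    The mean-thickness regressor is the unweighted mean over the N region
    columns (the region-table analogue of global mean cortical thickness).
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    mean_ct = np.asarray(thickness, dtype=float).mean(axis=1)
    return np.column_stack(
        [np.ones_like(age), age, sex, age * sex, mean_ct]
    )


def _collinear_columns(x: np.ndarray, labels, tol: float = 1e-8) -> list[str]:
    """Columns that add (numerically) nothing to the span of earlier ones."""
    bad = []
    basis: list[np.ndarray] = []
    for j in range(x.shape[1]):
        v = x[:, j].astype(float)
        nrm = np.linalg.norm(v)
        for b in basis:
            v = v - (b @ v) * b
        if nrm == 0 or np.linalg.norm(v) < tol * max(nrm, 1.0):
            bad.append(labels[j])
        else:
            basis.append(v / np.linalg.norm(v))
    return bad


def residualize(data: ThicknessDataset) -> ResidualMatrix:
    """Remove age, sex, age-by-sex and mean-thickness effects per region.

    Raises
    ------
    ValueError
        If there are not more subjects than design columns, or the design
        is rank deficient (the offending columns are named, e.g. a
        single-sex sample makes ``age_x_sex`` collinear with ``age``).
    """
    x = design_matrix(data.age, data.sex, data.thickness)
    m, p = x.shape
    if m <= p:
        raise ValueError(f"need more than {p} subjects to fit the design")
    if np.linalg.matrix_rank(x) < p:
        bad = _collinear_columns(x, DESIGN_COLUMNS)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, data.thickness, rcond=None)
    resid = data.thickness - x @ beta
    return ResidualMatrix(
        values=resid, design=x, region_names=np.asarray(data.atlas.names)
    )


def correlation_matrix(
    res: ResidualMatrix, positive_only: bool = True
) -> CorrelationMatrix:
    """Pearson correlation across subjects for every region pair.

    The diagonal is set to zero (self-connections excluded); with
    ``positive_only`` negative entries are clipped to zero.
    """
    v = np.asarray(res.values, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("Pearson correlation needs at least 3 subjects")
    sd = v.std(axis=0)
    if np.any(sd == 0):
        idx = np.flatnonzero(sd == 0)
        names = (
            list(np.asarray(res.region_names)[idx])
            if res.region_names is not None
            else list(idx)
        )
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(v, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    if positive_only:
        r = np.where(r > 0.0, r, 0.0)
    return CorrelationMatrix(
        r=r, positive_only=positive_only, region_names=res.region_names
    )


def residual_correlation(
    thickness: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    positive_only: bool = True,
) -> np.ndarray:
    """Fused residualize-then-correlate fast path used in bootstrap loops.

    Equivalent to ``correlation_matrix(residualize(...)).r`` but without
    the dataclass plumbing; rank problems surface as LinAlgError from the
    solver rather than named columns.
    """
    x = design_matrix(age, sex, thickness)
    beta, *_ = np.linalg.lstsq(x, thickness, rcond=None)
    resid = thickness - x @ beta
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    if positive_only:
        r[r < 0.0] = 0.0
    return r


def bootstrap_indices(
    m: int, rng: np.random.Generator, min_distinct: int = 3, max_redraws: int = 100
) -> np.ndarray:
    """Indices of one bootstrap resample (m draws with replacement)."""
    for attempt in range(max_redraws + 1):
        idx = rng.integers(0, m, size=m)
        if len(np.unique(idx)) >= min_distinct:
            if attempt:
                log.info("bootstrap redraw count: %d", attempt)
            return idx
    raise RuntimeError(
        f"could not draw a resample with >= {min_distinct} distinct subjects "
        f"in {max_redraws} redraws"
    )


def bootstrap_sample(data: ThicknessDataset, seed: int) -> ThicknessDataset:
    """One bootstrap resample of subjects, deterministic given ``seed``.

    Residualization and correlation are recomputed on the resampled table
    (resample-then-residualize), so regression uncertainty propagates into
    the bootstrap distribution.
    """
    rng = np.random.default_rng(seed)
    idx = bootstrap_indices(data.n_subjects, rng)
    return data.subset(idx)


def sparsity_grid(
    s_min: float = 0.5, s_max: float = 0.9, step: float = 0.02
) -> np.ndarray:
    """Ascending sparsity sweep; defaults give the 21-point 0.5..0.9 grid."""
    if not (0 < s_min < s_max < 1):
        raise ValueError("need 0 < s_min < s_max < 1")
    n = int(round((s_max - s_min) / step)) + 1
    grid = np.round(s_min + step * np.arange(n), 10)
    return grid[grid <= s_max + 1e-12]


def edge_capacity(n: int) -> int:
    return n * (n - 1) // 2


def n_edges_at_sparsity(n: int, sparsity: float, convention: str = "absent") -> int:
    """K, the retained edge count at one sweep point."""
    if not (0.0 < sparsity < 1.0):
        raise ValueError("sparsity must be in (0, 1)")
    frac = (1.0 - sparsity) if convention == "absent" else sparsity
    return int(round(frac * edge_capacity(n)))


def rank_edges(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle entries sorted by descending weight.

    Ties at equal weight are broken by ascending (row, column) index so
    thresholding is reproducible across platforms.  Returns (i, j, w)
    arrays.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = r[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def threshold_to_binary(
    corr: CorrelationMatrix | np.ndarray,
    sparsity: float,
    convention: str = "absent",
    on_insufficient: str = "error",
) -> np.ndarray:
    """Binary adjacency keeping the K strongest positive correlations.

    K = round((1 - sparsity) * N(N-1)/2) under the default "absent"
    convention.  If fewer than K strictly positive entries exist, the
    default is to raise (reporting the achievable maximum density);
    ``on_insufficient="cap"`` instead keeps every positive edge — the
    behavior of proportional thresholding in the standard connectivity
    toolboxes, where residual covariance matrices routinely carry fewer
    than 50% positive entries after global-mean removal.
    """
    if isinstance(corr, CorrelationMatrix):
        if not corr.positive_only:
            raise ValueError("thresholding requires a positive-only matrix")
        r = corr.r
    else:
        r = np.asarray(corr, dtype=float)
    n = r.shape[0]
    k = n_edges_at_sparsity(n, sparsity, convention)
    i, j, w = rank_edges(r)
    n_pos = int(np.count_nonzero(w > 0))
    if k > n_pos:
        if on_insufficient == "cap":
            log.info(
                "capping K=%d at %d positive entries (density %.3f)",
                k,
                n_pos,
                n_pos / edge_capacity(n),
            )
            k = n_pos
        else:
            raise ValueError(
                f"only {n_pos} positive entries available for K={k}; "
                f"achievable maximum density {n_pos / edge_capacity(n):.4f}"
            )
    a = np.zeros((n, n), dtype=np.uint8)
    a[i[:k], j[:k]] = 1
    a |= a.T
    return a
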