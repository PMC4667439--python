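"""Normalization and filtering for RNA-seq, microarray and proteome matrices.

The RNA-seq path is: median-of-ratios size factors, per-sample scaling with a
floor at 1 normalized count (to avoid spurious fold changes), a "present"
filter (group-mean normalized count > 10 in at least one population) and a
"variable" filter (one-way ANOVA across the five populations, unadjusted
p < 0.05). Microarray log2 intensities use a fixed background threshold
instead. Proteome tables are filtered for contaminants/decoys and for at
least three valid quantifications in one replicate group, log2-transformed,
and missing values are imputed from a down-shifted normal distribution
(missing-not-at-random model for intensities below the detection limit).

All filters preserve gene order and log how many genes go in and out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import (
    ALL_POPULATIONS,
    CountMatrix,
    PopulationLabel,
    ProteinTable,
    labels_series,
)

logger = logging.getLogger("cx3sig.preprocess")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with population labels.

    ``scale`` is ``"normalized_counts"`` (floored at 1) for RNA-seq or
    ``"log2"`` for microarray and protein intensities.
    """

    values: pd.DataFrame
    labels: dict[str, PopulationLabel]
    scale: str = "normalized_counts"

    def __post_init__(self) -> None:
        if self.scale not in ("normalized_counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        labels_series(self.labels, self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def label_series(self) -> pd.Series:
        return labels_series(self.labels, self.values.columns)

    def group_columns(self) -> dict[PopulationLabel, list[str]]:
        out: dict[PopulationLabel, list[str]] = {}
        for s in self.values.columns:
            out.setdefault(self.labels[s], []).append(s)
        return out

    def group_means(self) -> pd.DataFrame:
        """Per-population mean expression, columns ordered canonically."""
        cols = self.group_columns()
        data = {
            pop.value: self.values[cols[pop]].mean(axis=1)
            for pop in ALL_POPULATIONS
            if pop in cols
        }
        return pd.DataFrame(data, index=self.values.index)

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.labels,
                                self.scale)


# ---------------------------------------------------------------------------
# RNA-seq normalization
# ---------------------------------------------------------------------------

def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    ``count_gj / geometric_mean_g``, rescaled so the factors have geometric
    mean 1. The rescaling fixes the arbitrary global scale and makes
    normalization idempotent: recomputing factors on the normalized matrix
    returns exactly ones. Scaling one sample's counts by c moves its factor
    by c^(1-1/n) and every other factor by c^(-1/n) (the geometric-mean
    reference shifts too), so factor ratios are exactly scale-equivariant.
    """
    return size_factors_from_values(cm.values)


def size_factors_from_values(values: pd.DataFrame) -> pd.Series:
    """Median-of-ratios factors (geometric mean 1) for any positive matrix.

    Applying this to an already-normalized matrix returns exactly ones: the
    medians of the re-centered log-ratios are a single constant, and the
    geometric-mean-1 convention removes it.
    """
    counts = values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref = logc.mean(axis=1)  # -inf where any count is 0
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError(
            "no gene has a nonzero count in every sample; median-of-ratios "
            "size factors are undefined. Consider a pseudo-reference "
            "(e.g. adding genes quantified everywhere) before normalizing."
        )
    ratios = logc[usable] - ref[usable, None]
    logf = np.median(ratios, axis=0)
    factors = np.exp(logf - logf.mean())
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize_counts(cm: CountMatrix, factors: pd.Series,
                     floor: float = 1.0) -> ExpressionMatrix:
    """Divide counts by per-sample factors and floor at ``floor``."""
    if not factors.index.equals(cm.values.columns):
        factors = factors.reindex(cm.values.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    normalized = cm.values.divide(factors, axis=1).clip(lower=floor)
    return ExpressionMatrix(values=normalized, labels=dict(cm.labels),
                            scale="normalized_counts")


# ---------------------------------------------------------------------------
# present / variable filters
# ---------------------------------------------------------------------------

def filter_present_rna(em: ExpressionMatrix,
                       min_mean: float = 10.0) -> ExpressionMatrix:
    """Keep genes whose mean normalized count exceeds ``min_mean`` (strict)
    in at least one population."""
    gm = em.group_means()
    keep = (gm > min_mean).any(axis=1)
    logger.info("present filter (RNA): %d of %d genes kept", int(keep.sum()),
                len(keep))
    return ExpressionMatrix(em.values.loc[keep], em.labels, em.scale)


def filter_present_microarray(em: ExpressionMatrix,
                              background: float = 6.7886) -> ExpressionMatrix:
    """Keep probesets with group-mean log2 intensity >= ``background`` in at
    least one population (drop those below background in *all* groups)."""
    if em.scale != "log2":
        raise ValueError("microarray present filter expects log2 intensities")
    gm = em.group_means()
    keep = (gm >= background).any(axis=1)
    logger.info("present filter (microarray): %d of %d probesets kept",
                int(keep.sum()), len(keep))
    return ExpressionMatrix(em.values.loc[keep], em.labels, em.scale)


def anova_pvalues(em: ExpressionMatrix) -> pd.Series:
    """Per-gene one-way ANOVA p across populations (NaN for degenerate rows)."""
    groups = [em.values[cols].to_numpy() for cols in
              em.group_columns().values()]
    for g in groups:
        if g.shape[1] < 2:
            raise ValueError("every population needs >= 2 replicates for ANOVA")
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = scipy.stats.f_oneway(*groups, axis=1)
    return pd.Series(p, index=em.values.index, name="p")


def filter_variable(em: ExpressionMatrix,
                    alpha: float = 0.05) -> ExpressionMatrix:
    """Keep genes variable across populations (unadjusted ANOVA p < alpha).

    Genes with zero variance everywhere (undefined F) are dropped with a
    warning; genes with equal group means get p = 1 and are dropped.
    """
    p = anova_pvalues(em)
    degenerate = p.isna()
    if degenerate.any():
        logger.warning("variable filter: %d zero-variance genes dropped",
                       int(degenerate.sum()))
    keep = p < alpha
    logger.info("variable filter: %d of %d genes kept", int(keep.sum()),
                len(keep))
    return ExpressionMatrix(em.values.loc[keep.fillna(False)], em.labels,
                            em.scale)


# ---------------------------------------------------------------------------
# standardization and PCA
# ---------------------------------------------------------------------------

def z_transform(em: ExpressionMatrix, drop_constant: bool = True) -> pd.DataFrame:
    """Standardize every gene to mean 0, sample sd 1 (n-1 denominator).

    Zero-variance genes are dropped (with a warning) rather than producing
    NaN rows.
    """
    vals = em.values
    sd = vals.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        logger.warning("z-transform: %d constant genes dropped",
                       int(const.sum()))
        if drop_constant:
            vals = vals.loc[~const]
            sd = sd.loc[~const]
    return vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)


def pca(matrix: pd.DataFrame):
    """SVD-based PCA with samples as observations and genes as features.

    Returns ``(scores, loadings, explained_variance)`` where ``scores`` is
    sample x component, ``loadings`` gene x component with orthonormal
    columns, and explained variances sum to the total feature variance.
    Component signs are fixed so each component's largest-magnitude loading
    is positive.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    center = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(center, full_matrices=False)
    n = x.shape[0]
    # sign convention
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    explained = s**2 / (n - 1)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=comp),
        pd.DataFrame(vt.T, index=matrix.index, columns=comp),
        pd.Series(explained, index=comp, name="explained_variance"),
    )


# ---------------------------------------------------------------------------
# microarray utility
# ---------------------------------------------------------------------------

def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Standard quantile normalization: replace each sample's sorted values
    with the across-sample mean of sorted values (ties get the mean of their
    rank positions)."""
    vals = em.values
    ranks = vals.rank(axis=0, method="average")
    sorted_mean = pd.DataFrame(
        np.sort(vals.to_numpy(), axis=0), columns=vals.columns
    ).mean(axis=1)
    # rank r (1-based, possibly fractional for ties) -> interpolated mean
    grid = np.arange(1, len(sorted_mean) + 1, dtype=float)
    out = ranks.apply(lambda col: np.interp(col, grid, sorted_mean.to_numpy()))
    out.index = vals.index
    return ExpressionMatrix(out, em.labels, em.scale)


# ---------------------------------------------------------------------------
# proteome filtering and imputation
# ---------------------------------------------------------------------------

def filter_proteins(pt: ProteinTable, min_valid: int = 3) -> ExpressionMatrix:
    """Contaminant/decoy/site-only removal plus the valid-value filter.

    A protein is kept when it has at least ``min_valid`` quantified values in
    at least one replicate group. Output intensities are log2-transformed
    (NaN preserved for later imputation).
    """
    flags = pt.flags
    clean = ~(flags["contaminant"] | flags["reverse"] | flags["site_only"])
    logger.info("protein flag filter: %d of %d rows kept", int(clean.sum()),
                len(clean))
    inten = pt.intensities.loc[clean]
    if not pt.labels:
        raise ValueError("protein table has no sample labels")
    lab = labels_series(pt.labels, inten.columns)
    valid_ok = pd.Series(False, index=inten.index)
    for pop in set(lab):
        cols = lab.index[lab == pop]
        valid_ok |= inten[cols].notna().sum(axis=1) >= min_valid
    logger.info("protein valid-value filter: %d of %d rows kept",
                int(valid_ok.sum()), len(valid_ok))
    out = np.log2(inten.loc[valid_ok])
    return ExpressionMatrix(out, dict(pt.labels), scale="log2")


def impute_missing(em: ExpressionMatrix, shift: float = 1.8,
                   width: float = 0.3, seed: int = 0,
                   global_distribution: bool = False) -> ExpressionMatrix:
    """Impute missing log2 intensities from a down-shifted normal.

    For each sample column with observed mean mu and sd sigma, missing cells
    are drawn from Normal(mu - shift*sigma, (width*sigma)^2), emulating low
    abundance values below the noise level. With
    ``global_distribution=True``, mu and sigma come from all observed values.
    """
    if em.scale != "log2":
        raise ValueError("imputation expects log2 intensities")
    vals = em.values.copy()
    rng = np.random.default_rng(seed)
    if global_distribution:
        obs = vals.to_numpy()[np.isfinite(vals.to_numpy())]
        mu_all, sd_all = float(obs.mean()), float(obs.std(ddof=1))
    for col in vals.columns:
        v = vals[col]
        miss = v.isna()
        if not miss.any():
            continue
        if global_distribution:
            mu, sd = mu_all, sd_all
        else:
            obs = v.dropna()
            if obs.empty:
                raise ValueError(f"sample {col!r} has no observed intensities")
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        if not sd > 0:
            raise ValueError(f"sample {col!r} has zero observed sd")
        draws = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
        vals.loc[miss, col] = draws
    return ExpressionMatrix(vals, em.labels, scale="log2")
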