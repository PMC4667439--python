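"""Per-gene ANOVA, BH FDR, contrast fold changes, and concordance tables.

Differential expression is a classical one-way ANOVA across the five
populations with Benjamini-Hochberg correction over all tested genes. Fold
changes are ratios of floored normalized group means (never model
coefficients), so they are always positive and finite. ``common_upregulated``
implements the "commonly and significantly upregulated in both CX3CR1+
populations versus naive" selection that anchors the signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import PopulationLabel
from .preprocess import ExpressionMatrix

#: A contrast is (test population, reference population).
Contrast = tuple[PopulationLabel, PopulationLabel]

#: The two contrasts defining "commonly upregulated in CX3CR1+ cells".
CX3CR1P_VS_NAIVE: tuple[Contrast, Contrast] = (
    (PopulationLabel.CX3CR1P_CD62LHI, PopulationLabel.NAIVE),
    (PopulationLabel.CX3CR1P_CD62LLO, PopulationLabel.NAIVE),
)
#: The analogous CX3CR1-negative contrasts (used for the subtraction step).
CX3CR1N_VS_NAIVE: tuple[Contrast, Contrast] = (
    (PopulationLabel.CX3CR1N_CD62LHI, PopulationLabel.NAIVE),
    (PopulationLabel.CX3CR1N_CD62LLO, PopulationLabel.NAIVE),
)


def contrast_name(c: Contrast) -> str:
    return f"{c[0].value}_vs_{c[1].value}"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j>=i} min(1, p_(j) * m / j), mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Differential-expression result over a fixed gene universe.

    ``group_means`` holds the five floored normalized group means; ``fc`` and
    ``log2fc`` have one column per contrast name.
    """

    group_means: pd.DataFrame
    f: pd.Series
    p: pd.Series
    q: pd.Series
    contrasts: list[Contrast]
    fc: pd.DataFrame
    log2fc: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.group_means.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"F": self.f, "p": self.p, "q": self.q})
        for c in self.contrasts:
            name = contrast_name(c)
            out[f"FC_{name}"] = self.fc[name]
            out[f"log2FC_{name}"] = self.log2fc[name]
        return out


def anova_de(em: ExpressionMatrix,
             contrasts: list[Contrast] | None = None) -> DEResult:
    """One-way ANOVA across the five populations plus contrast fold changes.

    BH correction runs over all genes in ``em``; degenerate (zero-variance)
    genes get p = q = 1 and F = 0 so that the tested universe is preserved.
    """
    if contrasts is None:
        contrasts = list(CX3CR1P_VS_NAIVE)
    present = set(em.labels.values())
    for test, ref in contrasts:
        for pop in (test, ref):
            if pop not in present:
                raise ValueError(f"contrast population {pop.value} absent "
                                 "from sample labels")

    groups = [em.values[cols].to_numpy() for cols in
              em.group_columns().values()]
    import warnings

    import scipy.stats

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fstat, p = scipy.stats.f_oneway(*groups, axis=1)
    fstat = np.nan_to_num(fstat, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_fdr(p)

    gm = em.group_means()
    fc = {}
    log2fc = {}
    for c in contrasts:
        name = contrast_name(c)
        ratio = gm[c[0].value] / gm[c[1].value]
        fc[name] = ratio
        log2fc[name] = np.log2(ratio)
    idx = em.values.index
    return DEResult(
        group_means=gm,
        f=pd.Series(fstat, index=idx, name="F"),
        p=pd.Series(p, index=idx, name="p"),
        q=pd.Series(q, index=idx, name="q"),
        contrasts=list(contrasts),
        fc=pd.DataFrame(fc, index=idx),
        log2fc=pd.DataFrame(log2fc, index=idx),
    )


def common_upregulated(de: DEResult, fc: float = 2.0, fdr: float = 0.05,
                       contrasts: list[Contrast] | None = None) -> set[str]:
    """Genes with q < fdr and FC > fc in *both* CX3CR1+ vs naive contrasts
    (or in every contrast of ``contrasts`` when given)."""
    if contrasts is None:
        contrasts = list(CX3CR1P_VS_NAIVE)
    names = [contrast_name(c) for c in contrasts]
    missing = [n for n in names if n not in de.fc.columns]
    if missing:
        raise ValueError(f"contrasts not present in DE result: {missing}")
    mask = de.q < fdr
    for n in names:
        mask &= de.fc[n] > fc
    return set(de.group_means.index[mask])


def ratio_ratio(de: DEResult, contrast_x: Contrast, contrast_y: Contrast,
                fc: float = 2.0, fdr: float = 0.05) -> pd.DataFrame:
    """log10 mean-ratio table for genes differentially expressed in either
    contrast (FC > fc or FC < 1/fc, with q < fdr)."""
    nx, ny = contrast_name(contrast_x), contrast_name(contrast_y)
    for n in (nx, ny):
        if n not in de.fc.columns:
            raise ValueError(f"contrast {n} absent from DE result")
    sig = de.q < fdr
    de_either = sig & (
        (de.fc[nx] > fc) | (de.fc[nx] < 1 / fc)
        | (de.fc[ny] > fc) | (de.fc[ny] < 1 / fc)
    )
    out = pd.DataFrame(
        {
            "log10_ratio_x": np.log10(de.fc[nx][de_either]),
            "log10_ratio_y": np.log10(de.fc[ny][de_either]),
        }
    )
    out.index.name = "gene"
    return out


def fold_change_rank(primary_log2fc: pd.Series,
                     secondary_log2fc: pd.Series) -> tuple[pd.DataFrame, int]:
    """Rank genes by primary log2 fold change (descending) and overlay the
    matched secondary fold changes.

    Returns the ordered table plus the discordant count: genes whose
    secondary log2FC is negative. Genes absent from ``secondary_log2fc``
    carry NaN and do not count as discordant.
    """
    table = pd.DataFrame({"primary_log2fc": primary_log2fc})
    table["secondary_log2fc"] = secondary_log2fc.reindex(table.index)
    table = table.sort_values("primary_log2fc", ascending=False,
                              kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    discordant = int((table["secondary_log2fc"] < 0).sum())
    return table, discordant
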