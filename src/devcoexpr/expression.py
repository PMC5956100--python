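"""Normalization, the consecutive-stage DE filter, SDR and PCA.

Differential expression here is a deliberately transparent stand-in for a
full count-model fit: per-gene Welch two-sample t-tests on log2-CPM
values between each consecutive pair of developmental stages, with
Benjamini-Hochberg adjustment within each pair and the published filter
semantics — a gene is differentially expressed if, for at least one
consecutive pair, q <= q_max and |log2 fold change| >= log2(fc_min).

The signed difference ratio (SDR) is the per-gene mean-centered log2
expression rescaled into [-1, 1] by the maximum absolute centered value,
giving every non-constant gene a bounded, unit-scaled profile on which the
stage-specificity thresholds (0.4 level / 0.3 margin) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, SampleMetadata, ValidationError


def normalize_log2_cpm(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudocount); genes x samples."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total count")
    cpm = counts.counts * 1e6 / totals
    return np.log2(cpm + pseudocount)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted q-values, in input order, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEResult:
    """Per-consecutive-pair DE tables and the union DE gene list."""

    tables: dict[tuple[str, str], pd.DataFrame]  # columns: log2fc, p, q
    de_genes: list[str]
    fc_min: float
    q_max: float


def consecutive_stage_de(
    norm: pd.DataFrame,
    meta: SampleMetadata,
    fc_min: float = 1.5,
    q_max: float = 0.05,
) -> DEResult:
    """Welch-test DE filter between each consecutive pair of stages.

    log2 fold change is the difference of stage means of the log2-CPM
    values (later minus earlier stage); the magnitude filter is two-sided:
    |log2FC| >= log2(fc_min).
    """
    lfc_min = np.log2(fc_min)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    de: set[str] = set()
    for a, b in meta.consecutive_pairs():
        xa = norm[meta.samples_of(a)].to_numpy()
        xb = norm[meta.samples_of(b)].to_numpy()
        if xa.shape[1] < 2 or xb.shape[1] < 2:
            raise ValidationError(f"stage pair ({a}, {b}) needs >= 2 samples per stage")
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        lfc = xb.mean(axis=1) - xa.mean(axis=1)
        q = benjamini_hochberg(p)
        table = pd.DataFrame(
            {"log2fc": lfc, "p": p, "q": q}, index=norm.index
        )
        tables[(a, b)] = table
        hits = table.index[(table.q <= q_max) & (table.log2fc.abs() >= lfc_min)]
        de.update(hits)
    de_genes = [g for g in norm.index if g in de]  # preserve matrix order
    return DEResult(tables, de_genes, fc_min, q_max)


def pca_scores(norm: pd.DataFrame, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in gene space: scores (samples x components) and
    variance-explained fractions, components ordered by decreasing variance."""
    n_max = min(norm.shape)
    if not 1 <= n_components <= n_max:
        raise ValidationError(
            f"n_components must be in [1, {n_max}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(norm.to_numpy().T)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=norm.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def compute_sdr(norm: pd.DataFrame) -> pd.DataFrame:
    """Signed difference ratios: center each gene, scale by max |centered|.

    Constant genes map to all-zero rows; every non-constant gene attains
    |sdr| = 1 in at least one sample.
    """
    centered = norm.sub(norm.mean(axis=1), axis=0)
    scale = centered.abs().max(axis=1)
    scale = scale.where(scale > 0, 1.0)
    return centered.div(scale, axis=0)


def stage_mean_sdr(sdr: pd.DataFrame, meta: SampleMetadata) -> pd.DataFrame:
    """Mean SDR per stage (genes x stages, columns in stage order)."""
    return pd.DataFrame(
        {stage: sdr[meta.samples_of(stage)].mean(axis=1) for stage in meta.stage_order}
    )
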