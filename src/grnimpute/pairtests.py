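"""Pairwise causal tests between genes anchored on cis-eQTLs.

For an ordered gene pair (A, B), with E_A the strongest cis-eQTL of the
candidate regulator A, six nested Gaussian likelihood-ratio tests are
computed, genotype entering as a categorical variable:

====  =========================  =======================  ==================
test  alternative model          null model               hypothesis probed
====  =========================  =======================  ==================
0     B ~ A                      B ~ 1                    B correlated with A
1     A ~ E_A                    A ~ 1                    primary linkage
2     B ~ E_A                    B ~ 1                    secondary linkage
3     B ~ E_A + A                B ~ A                    B independent of E_A given A
4     B ~ E_A + A                B ~ 1                    relevance
5     B ~ E_A + A                B ~ E_A                  B dependent on A given E_A
====  =========================  =======================  ==================

Test 1 is never computed: only genes with a significant cis-eQTL enter the
catalog, so its posterior is fixed at 1.  Test 3's posterior is reported for
the *null* (conditional independence), so it is large when the statistic is
small; all other posteriors are for the alternative.

LLRs are converted to posterior probabilities P = 1 - lfdr per regulator
row via an empirical-null density ratio: statistics become p-values under
the chi-squared asymptotic null, the p-value density is estimated on a
log-scale histogram (uniform under the null), the null proportion pi0 comes
from the upper-half p-value mass, and the resulting lfdr curve is
monotonized by isotonic regression so P never decreases with the LLR.
Rows with too few pairs fall back to a pooled (all-rows) curve.

Posterior matrices are combined into edge scores P(A -> B) by four recipes:
the correlation network P0, the mediation network P2*P3, the
instrumental-variable network P2*P5, and the hidden-confounder compromise
0.5*(P2*P5 + P4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .data import EqtlCatalog, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "TESTS",
    "LlrResult",
    "PairwisePosteriors",
    "EdgeScoreMatrix",
    "llr_statistics",
    "estimate_posteriors",
    "combine_posteriors",
    "read_score_matrix",
    "write_score_matrix",
]

logger = logging.getLogger(__name__)

#: the computed tests (test 1 is fixed at posterior 1 and never run)
TESTS = (0, 2, 3, 4, 5)

#: cap applied to log-likelihood ratios before posterior conversion, so
#: degenerate pairs (perfectly collinear genes) stay finite
LLR_CAP = 1e6

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class LlrResult:
    """Log-likelihood-ratio matrices, entry (A, B) for the ordered pair A->B.

    ``llr[t]`` is gene-by-gene with NaN on the diagonal, on skipped pairs
    (shared eQTL variant) and on rows whose regulator was skipped.  ``dof[t]``
    gives each regulator row's null degrees of freedom (they vary with the
    number of genotype classes).
    """

    gene_ids: tuple[str, ...]
    llr: Mapping[int, np.ndarray]
    dof: Mapping[int, np.ndarray]
    n_samples: int
    skipped_regulators: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairwisePosteriors:
    """Posterior probability matrices for the five computed tests; P1 == 1."""

    gene_ids: tuple[str, ...]
    matrices: Mapping[int, np.ndarray]

    def matrix(self, test: int) -> np.ndarray:
        if test == 1:
            m = np.ones((len(self.gene_ids),) * 2)
            np.fill_diagonal(m, np.nan)
            return m
        return self.matrices[test]


@dataclass(frozen=True)
class EdgeScoreMatrix:
    """Asymmetric gene-by-gene edge scores P(A -> B) in [0, 1]."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    recipe: str = "P0"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.gene_ids), columns=list(self.gene_ids)
        )


def _group_centered(values: np.ndarray, groups: np.ndarray, n_groups: int):
    """Subtract per-genotype-class means; works for 1-D or column-stacked 2-D."""
    out = values.astype(float).copy()
    for g in range(n_groups):
        mask = groups == g
        if mask.any():
            out[mask] = out[mask] - out[mask].mean(axis=0)
    return out


def llr_statistics(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    catalog: EqtlCatalog,
) -> LlrResult:
    """Compute the five LLR matrices over all ordered catalog-gene pairs.

    Samples must already be aligned.  Pairs sharing the identical top eQTL
    variant are excluded (self-causation guard), as is the diagonal.
    Regulators whose top eQTL is monomorphic in the data are skipped with a
    warning; their rows are NaN and receive null posteriors downstream.
    """
    genes = [g for g in catalog.gene_ids if g in set(expr.gene_ids)]
    m = len(genes)
    n = expr.n_samples
    X = expr.data[genes].to_numpy(dtype=float)  # n x m
    top = {g: catalog.top_variant(g) for g in genes}

    llr = {t: np.full((m, m), np.nan) for t in TESTS}
    dof = {t: np.full(m, np.nan) for t in TESTS}
    skipped: list[str] = []

    Xc = X - X.mean(axis=0)
    ss_tot = (Xc**2).sum(axis=0)
    degenerate_target = ss_tot <= 0

    for a, gene_a in enumerate(genes):
        e = geno.column(top[gene_a])
        classes, codes = np.unique(e, return_inverse=True)
        K = len(classes)
        if K < 2:
            logger.warning(
                "regulator %s skipped: top eQTL %s is monomorphic",
                gene_a, top[gene_a],
            )
            skipped.append(gene_a)
            continue
        dof[0][a], dof[2][a], dof[3][a], dof[4][a], dof[5][a] = (
            1, K - 1, K - 1, K, 1,
        )
        if degenerate_target[a]:
            skipped.append(gene_a)
            continue

        A = Xc[:, a]
        ssA = ss_tot[a]
        # B ~ A
        r2 = (A @ Xc) ** 2 / np.where(ss_tot > 0, ssA * ss_tot, np.inf)
        rss_A = ss_tot * np.clip(1.0 - r2, 0.0, None)
        # B ~ E  (within-genotype-class centering)
        Xw = _group_centered(X, codes, K)
        rss_E = (Xw**2).sum(axis=0)
        # B ~ E + A: regress within-class-centered B on within-class-centered A
        Aw = Xw[:, a]
        ssAw = float(Aw @ Aw)
        if ssAw > 0:
            cross = Aw @ Xw
            rss_EA = np.clip(rss_E - cross**2 / ssAw, 0.0, None)
        else:
            rss_EA = rss_E

        with np.errstate(divide="ignore", invalid="ignore"):
            llr[0][a] = 0.5 * n * np.log(ss_tot / rss_A)
            llr[2][a] = 0.5 * n * np.log(ss_tot / rss_E)
            llr[3][a] = 0.5 * n * np.log(rss_A / rss_EA)
            llr[4][a] = 0.5 * n * np.log(ss_tot / rss_EA)
            llr[5][a] = 0.5 * n * np.log(rss_E / rss_EA)
        for t in TESTS:
            row = llr[t][a]
            row[degenerate_target] = np.nan
            np.clip(row, 0.0, LLR_CAP, out=row)

    # exclusions: diagonal and shared-eQTL pairs
    excl = np.eye(m, dtype=bool)
    variants = [top[g] for g in genes]
    for i in range(m):
        for j in range(i + 1, m):
            if variants[i] == variants[j]:
                excl[i, j] = excl[j, i] = True
    for t in TESTS:
        llr[t][excl] = np.nan

    return LlrResult(
        gene_ids=tuple(genes),
        llr=llr,
        dof=dof,
        n_samples=n,
        skipped_regulators=tuple(skipped),
    )


def _lfdr_from_pvalues(p: np.ndarray, pi0: float) -> np.ndarray:
    """Local FDR via a log-scale p-value histogram density ratio.

    Under the null p-values are uniform, so each bin's expected null mass is
    its width; lfdr(bin) = pi0 * width / observed mass.  Logarithmic bins
    give resolution in the far tail, where the signal lives.  The curve is
    monotonized (non-decreasing in p) by isotonic regression over bins.
    """
    n = len(p)
    pmin = max(float(p.min()) / 2.0, _P_FLOOR)
    n_bins = max(10, int(np.sqrt(n)))
    edges = np.concatenate([[0.0], np.logspace(np.log10(pmin), 0.0, n_bins)])
    edges[-1] = 1.0 + 1e-12
    idx = np.searchsorted(edges, p, side="right") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1)
    widths = np.diff(edges)
    used = counts > 0
    with np.errstate(divide="ignore"):
        lfdr_bin = np.clip(pi0 * widths * n / np.maximum(counts, 1), 0.0, 1.0)
    # monotone non-decreasing in p over the occupied bins
    order = np.nonzero(used)[0]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(
        order.astype(float), lfdr_bin[order], sample_weight=counts[order]
    )
    smooth = np.ones(len(edges) - 1)
    smooth[order] = fitted
    return np.clip(smooth[idx], 0.0, 1.0)


def _estimate_pi0(p: np.ndarray) -> float:
    """Null proportion by the exceedance mass above p = 0.5."""
    if len(p) == 0:
        return 1.0
    return float(np.clip(2.0 * np.mean(p > 0.5), 0.05, 1.0))


def estimate_posteriors(
    llr_result: LlrResult,
    min_row_pairs: int = 100,
) -> PairwisePosteriors:
    """Convert LLR matrices to posterior probabilities P = 1 - lfdr.

    Each regulator row gets its own empirical-null curve (regulator-specific
    background); rows with fewer than ``min_row_pairs`` scored pairs share a
    pooled curve estimated from all rows of that test.  Rows of skipped
    regulators receive the null posterior (0, or 1 for test 3).
    """
    gene_ids = llr_result.gene_ids
    m = len(gene_ids)
    skipped = set(llr_result.skipped_regulators)
    out = {t: np.full((m, m), np.nan) for t in TESTS}

    for t in TESTS:
        stat = 2.0 * llr_result.llr[t]
        # p-values under the row-specific chi-squared null
        pmat = np.full((m, m), np.nan)
        for a in range(m):
            d = llr_result.dof[t][a]
            if np.isnan(d):
                continue
            row = stat[a]
            valid = ~np.isnan(row)
            if valid.any():
                pmat[a, valid] = np.maximum(
                    stats.chi2.sf(row[valid], df=d), _P_FLOOR
                )
        pooled = pmat[~np.isnan(pmat)]
        pooled_pi0 = _estimate_pi0(pooled) if pooled.size else 1.0
        for a, gene_a in enumerate(gene_ids):
            if gene_a in skipped:
                out[t][a, :] = 1.0 if t == 3 else 0.0
                out[t][a, a] = np.nan
                continue
            valid = ~np.isnan(pmat[a])
            if not valid.any():
                continue
            p_row = pmat[a, valid]
            if valid.sum() >= min_row_pairs:
                lfdr = _lfdr_from_pvalues(p_row, _estimate_pi0(p_row))
            else:
                if valid.sum() < min_row_pairs and pooled.size:
                    logger.debug(
                        "test %d, regulator %s: %d pairs < %d, pooled null",
                        t, gene_a, int(valid.sum()), min_row_pairs,
                    )
                lfdr_all = _lfdr_from_pvalues(pooled, pooled_pi0)
                # evaluate the pooled curve at this row's p-values by rank
                order = np.argsort(pooled)
                pos = np.searchsorted(pooled[order], p_row, side="left")
                pos = np.clip(pos, 0, len(pooled) - 1)
                lfdr = lfdr_all[order][pos]
            out[t][a, valid] = lfdr if t == 3 else 1.0 - lfdr
    return PairwisePosteriors(gene_ids=gene_ids, matrices=out)


def combine_posteriors(pp: PairwisePosteriors, recipe: str) -> EdgeScoreMatrix:
    """Combine test posteriors into edge scores by a named recipe."""
    if recipe == "P0":
        scores = pp.matrix(0).copy()
    elif recipe == "P2P3":
        scores = pp.matrix(2) * pp.matrix(3)
    elif recipe == "P2P5":
        scores = pp.matrix(2) * pp.matrix(5)
    elif recipe == "HALF_P2P5_PLUS_P4":
        scores = 0.5 * (pp.matrix(2) * pp.matrix(5) + pp.matrix(4))
    else:
        raise ValueError(f"unknown recipe {recipe!r}")
    return EdgeScoreMatrix(gene_ids=pp.gene_ids, scores=scores, recipe=recipe)


def write_score_matrix(matrix: EdgeScoreMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_score_matrix(path: str | Path, recipe: str = "P0") -> EdgeScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"score matrix in {path} is not square over gene ids")
    return EdgeScoreMatrix(
        gene_ids=tuple(df.index), scores=df.to_numpy(dtype=float), recipe=recipe
    )
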