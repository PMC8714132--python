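"""Co-expression and differential-expression screens.

Autophagy-related lncRNAs are the lncRNAs whose expression correlates with
at least one autophagy mRNA beyond a Pearson r / p threshold (default
r > 0.6, p < 0.001); the candidate set is then restricted to lncRNAs
differentially expressed between tumor and normal tissue (Welch two-sample
t on log2 values, Benjamini-Hochberg FDR < 0.05 and |log2FC| > 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneAnnotation, TUMOR, NORMAL


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def correlation_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on t(n-2); r = +/-1 gives p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def coexpression_screen(
    expr: ExpressionMatrix,
    annot: GeneAnnotation,
    r_min: float = 0.6,
    p_max: float = 0.001,
    *,
    use_abs: bool = False,
    samples=None,
) -> tuple[pd.DataFrame, list[str]]:
    """All (autophagy mRNA, lncRNA) edges with r > r_min and p < p_max.

    Returns the edge table (mrna_id, lnc_id, r, p) and the distinct lncRNAs
    appearing in at least one edge. The screen is on signed r by default
    (positive co-expression); ``use_abs`` switches to |r|. ``samples``
    restricts the correlation to a subset (default: all samples).
    """
    mrnas = [g for g in annot.autophagy_mrnas if g in expr.gene_ids]
    lncs = [g for g in annot.lncrnas if g in expr.gene_ids]
    if not mrnas:
        raise ValueError("no autophagy mRNAs present in the expression matrix")
    if not lncs:
        raise ValueError("no lncRNAs present in the expression matrix")
    cols = list(samples) if samples is not None else list(expr.sample_ids)
    n = len(cols)
    M = expr.values.loc[mrnas, cols].to_numpy(float)
    L = expr.values.loc[lncs, cols].to_numpy(float)

    def _standardize(A):
        Ac = A - A.mean(axis=1, keepdims=True)
        s = np.sqrt((Ac**2).sum(axis=1, keepdims=True))
        ok = s[:, 0] > 0
        Ac[ok] /= s[ok]
        return Ac, ok

    Ms, m_ok = _standardize(M)
    Ls, l_ok = _standardize(L)
    R = np.clip(Ms @ Ls.T, -1.0, 1.0)  # mrna x lnc
    with np.errstate(divide="ignore"):
        T = np.abs(R) * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    P = 2.0 * stats.t.sf(T, n - 2)
    P[np.abs(R) == 1.0] = 0.0
    valid = np.outer(m_ok, l_ok)
    crit = np.abs(R) if use_abs else R
    hit = valid & (crit > r_min) & (P < p_max)
    ii, jj = np.nonzero(hit)
    edges = pd.DataFrame(
        {
            "mrna_id": [mrnas[i] for i in ii],
            "lnc_id": [lncs[j] for j in jj],
            "r": R[ii, jj],
            "p": P[ii, jj],
        }
    )
    selected = list(dict.fromkeys(edges["lnc_id"]))  # first-appearance order
    return edges, selected


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DifferentialResult:
    """Per-gene tumor-vs-normal comparison on the log2 scale."""

    table: pd.DataFrame  # index gene_id: log2fc, p, fdr, direction, passed


def differential_screen(
    expr: ExpressionMatrix,
    genes=None,
    fdr_max: float = 0.05,
    lfc_min: float = 2.0,
) -> DifferentialResult:
    """Welch t per gene; passes iff fdr < fdr_max and |log2fc| > lfc_min.

    log2fc = mean(tumor) - mean(normal) of the already-log2 values; BH is
    applied across the tested gene subset only.
    """
    tum = expr.samples_in_group(TUMOR)
    nor = expr.samples_in_group(NORMAL)
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError("both tumor and normal need at least 2 samples")
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    X = expr.values.loc[genes, tum].to_numpy(float)
    Y = expr.values.loc[genes, nor].to_numpy(float)
    lfc = X.mean(axis=1) - Y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(X, Y, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    fdr = bh_adjust(p)
    passed = (fdr < fdr_max) & (np.abs(lfc) > lfc_min)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(lfc > 0, "up", "down"),
            "passed": passed,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DifferentialResult(table)
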