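"""Risk-group comparisons: immune infiltration, ICI markers, drug response.

The group comparison statistic throughout is the two-independent-sample
Mann-Whitney rank-sum test (midranks for ties; exact enumeration for small
samples, tie-corrected normal approximation otherwise). Immune
infiltration is summarized by two generic engines — mean-z signature
scoring over marker gene sets and NNLS deconvolution against a reference
profile matrix — and chemotherapy response by ridge regression of cell-line
log-IC50 on expression, applied to patients after gene-wise quantile
normalization homogenizes the two cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .datamodel import CellTypeSignature, ExpressionMatrix

ICI_MARKERS = ("CD274", "CD28", "TGFBR1", "TNFSF4")

#: exact rank-sum path is used when min(n1, n2) <= this and the number of
#: arrangements stays enumerable
EXACT_MAX_MIN_N = 8
EXACT_MAX_ARRANGEMENTS = 500_000


@dataclass
class GroupComparison:
    feature: str
    median_x: float
    median_y: float
    statistic: float  # Mann-Whitney U for the first sample
    p: float
    direction: str  # "x" or "y": which sample is higher (by median)
    method: str = "exact"


def rank_sum_test(x, y, feature: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test with midranks.

    U is for the first sample. p is by full enumeration of rank
    arrangements when min(n1, n2) <= 8 (and the arrangement count is
    tractable), otherwise by normal approximation with tie correction and
    continuity correction. The two-sided exact p is the probability mass of
    |U - n1 n2 / 2| at least as extreme as observed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0

    exact_ok = min(n1, n2) <= EXACT_MAX_MIN_N and comb(n1 + n2, min(n1, n2)) <= EXACT_MAX_ARRANGEMENTS
    if exact_ok:
        k = min(n1, n2)
        rank_sum_min = k * (k + 1) / 2
        obs_dev = abs(u - mu)
        hits = total = 0
        n1n2 = n1 * n2
        for idx in combinations(range(n1 + n2), k):
            u_k = ranks[list(idx)].sum() - rank_sum_min
            u_first = u_k if k == n1 else n1n2 - u_k
            total += 1
            if abs(u_first - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)  # continuity-corrected
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        method = "normal"
    mx, my = float(np.median(x)), float(np.median(y))
    return GroupComparison(feature, mx, my, u, min(p, 1.0), "x" if mx >= my else "y", method)


# ---------------------------------------------------------------------------
# immune infiltration


@dataclass
class DeconvolutionResult:
    """Per-sample cell-type scores (mean-z) or fractions (NNLS)."""

    table: pd.DataFrame  # samples x cell types
    dropped: tuple[str, ...] = ()


def signature_score(expr: ExpressionMatrix, signatures: dict[str, list[str]]) -> DeconvolutionResult:
    """Mean of gene-wise z-scores (z across samples) over each signature.

    Cell types with no signature gene present in the matrix are dropped
    with a warning.
    """
    V = expr.values
    mu = V.mean(axis=1)
    sd = V.std(axis=1, ddof=0)
    scores = {}
    dropped = []
    for cell_type, genes in signatures.items():
        present = [g for g in genes if g in V.index and sd.get(g, 0) > 0]
        if not present:
            dropped.append(cell_type)
            continue
        Z = V.loc[present].sub(mu.loc[present], axis=0).div(sd.loc[present], axis=0)
        scores[cell_type] = Z.mean(axis=0)
    if dropped:
        warnings.warn(f"signatures with no present genes dropped: {dropped}", stacklevel=2)
    if not scores:
        raise ValueError("no signature has any gene present in the expression matrix")
    return DeconvolutionResult(pd.DataFrame(scores), tuple(dropped))


def nnls_deconvolve(
    expr: ExpressionMatrix, signature: CellTypeSignature, renormalize: bool = False
) -> DeconvolutionResult:
    """Nonnegative least-squares fractions against reference profiles.

    Each bulk sample is projected onto the signature columns over the
    shared genes; ``renormalize`` rescales fractions to sum to one.
    """
    shared = [g for g in signature.profiles.index if g in expr.gene_ids]
    k = signature.profiles.shape[1]
    if k < 2:
        raise ValueError("need at least 2 cell types")
    if len(shared) < k:
        raise ValueError(f"only {len(shared)} shared genes for {k} cell types")
    A = signature.profiles.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("signature is rank-deficient after gene intersection")
    B = expr.values.loc[shared].to_numpy(float)
    fracs = np.empty((B.shape[1], k))
    for j in range(B.shape[1]):
        fracs[j], _ = optimize.nnls(A, B[:, j])
    if renormalize:
        tot = fracs.sum(axis=1, keepdims=True)
        np.divide(fracs, tot, out=fracs, where=tot > 0)
    return DeconvolutionResult(
        pd.DataFrame(fracs, index=expr.sample_ids, columns=signature.cell_types)
    )


def compare_groups(
    features: pd.DataFrame, groups: pd.Series, low: str = "low", high: str = "high"
) -> pd.DataFrame:
    """Rank-sum comparison of every feature column between two risk groups.

    Direction reports which group has the higher median.
    """
    g = groups.reindex(features.index)
    rows = []
    for name in features.columns:
        lo = features.loc[g == low, name].dropna().to_numpy()
        hi = features.loc[g == high, name].dropna().to_numpy()
        res = rank_sum_test(hi, lo, feature=name)
        rows.append(
            {
                "feature": name,
                "median_high": res.median_x,
                "median_low": res.median_y,
                "U": res.statistic,
                "p": res.p,
                "direction": "high" if res.direction == "x" else "low",
                "method": res.method,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def ici_marker_comparison(
    expr: ExpressionMatrix, groups: pd.Series, markers=ICI_MARKERS
) -> tuple[pd.DataFrame, list[str]]:
    """Per-marker low/high rank-sum comparison of checkpoint-gene expression.

    Missing markers are reported in the skipped list, not fatal.
    """
    present = [m for m in markers if m in expr.gene_ids]
    skipped = [m for m in markers if m not in expr.gene_ids]
    if not present:
        return pd.DataFrame(columns=["median_high", "median_low", "U", "p", "direction", "method"]), skipped
    feats = expr.values.loc[present].T
    return compare_groups(feats, groups), skipped


# ---------------------------------------------------------------------------
# drug-response imputation


@dataclass
class DrugResponseModel:
    """Ridge model of log-IC50 on standardized, quantile-normalized expression."""

    drug: str
    genes: list[str]
    coef: np.ndarray
    intercept: float
    lambda_: float
    cv_curve: pd.DataFrame  # columns: alpha, mse
    train_matrix: pd.DataFrame  # filtered raw genes x lines (for homogenization)


def _quantile_normalize(matrix: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map each column's sorted values onto the target quantile vector."""
    out = np.empty_like(matrix, dtype=float)
    for j in range(matrix.shape[1]):
        order = np.argsort(matrix[:, j], kind="stable")
        out[order, j] = target
    return out


def _qn_target(matrix: np.ndarray) -> np.ndarray:
    return np.sort(matrix, axis=0).mean(axis=1)


def train_drug_model(
    cellline_expr: pd.DataFrame,
    log_ic50: pd.Series,
    drug: str,
    n_folds: int = 10,
    seed: int = 0,
    var_min: float = 0.2,
    alphas=None,
) -> DrugResponseModel:
    """Ridge regression of cell-line log-IC50 on expression.

    Training expression (genes x lines) is quantile-normalized, genes with
    variance below ``var_min`` are removed, remaining genes standardized,
    and the ridge penalty chosen by k-fold CV minimizing squared error.
    """
    resp = log_ic50.dropna()
    lines = [c for c in cellline_expr.columns if c in resp.index]
    if len(lines) < 20:
        raise ValueError(f"need >= 20 cell lines with response for {drug!r}, got {len(lines)}")
    if len(lines) < n_folds:
        raise ValueError("fewer cell lines than folds")
    E = cellline_expr[lines]
    y = resp.loc[lines].to_numpy(float)

    qn = _quantile_normalize(E.to_numpy(float), _qn_target(E.to_numpy(float)))
    var = qn.var(axis=1)
    keep = var >= var_min
    if not keep.any():
        raise ValueError("variance filter removed every gene")
    genes = [g for g, k in zip(E.index, keep) if k]
    X = qn[keep].T  # lines x genes
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)

    if alphas is None:
        alphas = np.geomspace(1e-2, 1e5, 30)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Z))
    mse = np.zeros(len(alphas))
    for ai, a in enumerate(alphas):
        errs = []
        for tr, te in splits:
            m = Ridge(alpha=a).fit(Z[tr], y[tr])
            errs.append(np.mean((m.predict(Z[te]) - y[te]) ** 2))
        mse[ai] = np.mean(errs)
    best = int(np.argmin(mse))
    model = Ridge(alpha=float(alphas[best])).fit(Z, y)
    return DrugResponseModel(
        drug=drug,
        genes=genes,
        coef=model.coef_.copy(),
        intercept=float(model.intercept_),
        lambda_=float(alphas[best]),
        cv_curve=pd.DataFrame({"alpha": alphas, "mse": mse}),
        train_matrix=E.loc[genes].copy(),
    )


def predict_ic50(model: DrugResponseModel, patient_expr: pd.DataFrame) -> pd.Series:
    """Predicted log-IC50 per patient sample.

    Training and patient matrices are jointly quantile-normalized gene-wise
    (target = mean of the sorted columns of the combined matrix) before the
    ridge coefficients are applied; standardization parameters are
    recomputed from the homogenized training matrix so a patient cohort
    identical to the training cohort reproduces the fitted values.
    """
    shared = [g for g in model.genes if g in patient_expr.index]
    if len(shared) < 0.5 * len(model.genes):
        raise ValueError(
            f"only {len(shared)}/{len(model.genes)} training genes present in patient matrix"
        )
    train = model.train_matrix.loc[shared].to_numpy(float)
    pat = patient_expr.loc[shared].to_numpy(float)
    combined = np.hstack([train, pat])
    target = _qn_target(combined)
    train_qn = _quantile_normalize(train, target)
    pat_qn = _quantile_normalize(pat, target)
    mu = train_qn.mean(axis=1)
    sd = train_qn.std(axis=1)
    Z = (pat_qn - mu[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    idx = [model.genes.index(g) for g in shared]
    pred = model.intercept + Z.T @ model.coef[idx]
    return pd.Series(pred, index=patient_expr.columns, name=f"predicted_log_ic50_{model.drug}")
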