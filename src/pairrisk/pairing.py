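"""Relative-ordering pair matrix and the stability filter.

For each unordered lncRNA pair (A, B) with A < B lexicographically, a
sample is scored 1 when A's expression strictly exceeds B's and 0 otherwise
(ties score 0). Because the indicator depends only on the within-sample
ordering of two genes, it is invariant to any per-sample monotone
normalization — the property that lets a pair signature cross platforms
without batch correction. Pairs whose indicator frequency falls outside the
20%-80% stability window are near-constant, carry almost no contrast
between patients, and are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

PAIR_SEP = "|"


@dataclass
class PairMatrix:
    """0/1 ordering indicators, pairs x samples.

    ``indicators`` is indexed by "lncA|lncB" (lncA < lncB); ``freq`` is the
    per-pair mean indicator over the frequency cohort (by default all
    columns of the matrix).
    """

    indicators: pd.DataFrame
    freq_samples: list[str] | None = None

    @property
    def pair_ids(self) -> pd.Index:
        return self.indicators.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    @property
    def freq(self) -> pd.Series:
        cols = self.freq_samples if self.freq_samples is not None else self.indicators.columns
        return self.indicators[list(cols)].mean(axis=1)

    def subset_samples(self, sample_ids) -> "PairMatrix":
        return PairMatrix(self.indicators[list(sample_ids)].copy(), self.freq_samples)


def pair_id(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}{PAIR_SEP}{b}"


def split_pair_id(pid: str) -> tuple[str, str]:
    a, b = pid.split(PAIR_SEP)
    return a, b


def build_pair_matrix(expr: ExpressionMatrix, lnc_set) -> PairMatrix:
    """All C(k,2) ordering indicators over the given lncRNAs.

    Pair IDs are canonical ("a|b" with a < b); equal expression scores 0.
    """
    lncs = sorted(dict.fromkeys(lnc_set))
    if len(lncs) < 2:
        raise ValueError("need at least 2 lncRNAs to build pairs")
    missing = [g for g in lncs if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"lncRNA(s) absent from expression matrix: {missing[:5]}")
    V = expr.values.loc[lncs]
    rows = {}
    for a, b in combinations(lncs, 2):
        rows[f"{a}{PAIR_SEP}{b}"] = (V.loc[a].to_numpy() > V.loc[b].to_numpy()).astype(np.int8)
    ind = pd.DataFrame(rows, index=expr.sample_ids).T
    ind.index.name = "pair_id"
    return PairMatrix(ind)


def stability_filter(pm: PairMatrix, lo: float = 0.2, hi: float = 0.8, *, samples=None) -> PairMatrix:
    """Keep pairs with lo <= freq <= hi (inclusive at both bounds).

    ``samples`` restricts the frequency computation to a cohort subset
    (e.g. the tumor samples used for modelling) while keeping all columns.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("need 0 <= lo < hi <= 1")
    cols = list(samples) if samples is not None else list(pm.indicators.columns)
    freq = pm.indicators[cols].mean(axis=1)
    keep = freq.index[(freq >= lo) & (freq <= hi)]
    return PairMatrix(pm.indicators.loc[keep].copy(), cols if samples is not None else pm.freq_samples)


def pair_batch_invariance_check(expr: ExpressionMatrix, shifts) -> bool:
    """True iff per-sample additive shifts leave the pair matrix unchanged.

    ``shifts`` maps sample -> additive constant on the log2 scale (a batch
    offset). Holds identically because the indicator compares two genes
    within one sample.
    """
    lncs = list(expr.gene_ids)
    if len(lncs) < 2:
        raise ValueError("need at least 2 genes")
    shifted_vals = expr.values.add(pd.Series(shifts).reindex(expr.sample_ids).fillna(0.0), axis=1)
    shifted = ExpressionMatrix(shifted_vals, expr.sample_group.copy())
    pm0 = build_pair_matrix(expr, lncs)
    pm1 = build_pair_matrix(shifted, lncs)
    return pm0.indicators.equals(pm1.indicators)
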