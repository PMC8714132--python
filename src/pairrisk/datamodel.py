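"""Domain containers and TSV readers/writers.

Expression is stored genes x samples on log2 scale in a pandas DataFrame;
sample groups (tumor/normal), gene annotation (biotype + autophagy flag),
clinical follow-up and cell-type reference profiles each get a thin,
validated container. All on-disk formats are tab-separated text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_GROUPS = (TUMOR, NORMAL)

#: significant digits preserved by write_results round-trips
_FLOAT_FMT = "%.12g"


class LoadError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene IDs with unique sample-ID columns.
    sample_group
        Per-sample label, ``"tumor"`` or ``"normal"``, aligned to columns.
    zero_variance_genes
        Genes whose expression is constant across all samples; retained in
        the matrix but flagged so correlation-based screens can skip them.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    zero_variance_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise LoadError(f"duplicate gene ID {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise LoadError(f"duplicate sample ID {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise LoadError(
                f"non-finite expression at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        self.sample_group = self.sample_group.reindex(v.columns)
        if self.sample_group.isna().any():
            missing = self.sample_group.index[self.sample_group.isna()][0]
            raise LoadError(f"sample {missing!r} has no group label")
        bad = set(self.sample_group.unique()) - set(VALID_GROUPS)
        if bad:
            raise LoadError(f"unknown sample group label(s): {sorted(bad)}")
        counts = self.sample_group.value_counts()
        if len(counts) == 2 and counts.min() < 2:
            raise LoadError("each group must contain at least 2 samples when both present")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> pd.Index:
        return self.sample_group.index[self.sample_group == group]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(genes)],
            self.sample_group.copy(),
            tuple(g for g in self.zero_variance_genes if g in set(genes)),
        )


@dataclass
class GeneAnnotation:
    """gene_id -> biotype ({mRNA, lncRNA}) and autophagy-gene flag."""

    table: pd.DataFrame  # index gene_id; columns biotype, is_autophagy

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise LoadError(f"gene {dup!r} annotated more than once")
        bad = set(self.table["biotype"].unique()) - {"mRNA", "lncRNA"}
        if bad:
            raise LoadError(f"unknown biotype(s): {sorted(bad)}")
        self.table["is_autophagy"] = self.table["is_autophagy"].astype(bool)

    @property
    def autophagy_mrnas(self) -> pd.Index:
        t = self.table
        return t.index[(t["biotype"] == "mRNA") & t["is_autophagy"]]

    @property
    def lncrnas(self) -> pd.Index:
        return self.table.index[self.table["biotype"] == "lncRNA"]


@dataclass
class SurvivalData:
    """Overall-survival follow-up per sample.

    ``table`` is indexed by sample ID with ``time`` (days, > 0), ``event``
    (1 = death observed, 0 = censored) and any further clinical covariates
    (age, sex, grade, stage ...). Samples missing time or event are dropped
    at load time; covariates may contain missing values and are excluded
    listwise only where a fit requires them.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise LoadError("duplicate sample IDs in clinical table")
        t = t.dropna(subset=["time", "event"])
        t = t.assign(time=t["time"].astype(float), event=t["event"].astype(int))
        if (t["time"] <= 0).any():
            bad = t.index[t["time"] <= 0][0]
            raise LoadError(f"non-positive follow-up time for sample {bad!r}")
        if not t["event"].isin([0, 1]).all():
            bad = t.index[~t["event"].isin([0, 1])][0]
            raise LoadError(f"event indicator for sample {bad!r} is not 0/1")
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]

    def subset(self, sample_ids) -> "SurvivalData":
        keep = [s for s in sample_ids if s in self.table.index]
        return SurvivalData(self.table.loc[keep].copy())


@dataclass
class CellTypeSignature:
    """Nonnegative reference expression profiles, genes x cell types."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.profiles.to_numpy(float)
        if (arr < 0).any():
            raise LoadError("signature profiles must be nonnegative")
        zero = (arr == 0).all(axis=0)
        if zero.any():
            ct = self.profiles.columns[zero][0]
            raise LoadError(f"cell type {ct!r} has an all-zero profile")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def read_expression(path: str, group_map, *, log2_transform: bool = False) -> ExpressionMatrix:
    """Load a genes-x-samples TSV (first column gene IDs, header sample IDs).

    ``group_map`` is either a ``{sample_id: group}`` mapping or the path of a
    two-column TSV (sample_id, group). Duplicate gene rows are collapsed by
    mean; zero-variance genes are retained but flagged. ``log2_transform``
    applies log2(x+1) for matrices delivered on the linear scale.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for col in header:  # pandas silently renames duplicate columns
        if col in seen:
            raise LoadError(f"duplicate sample ID {col!r} in header of {path}")
        seen.add(col)
    raw = _read_tsv(path)
    try:
        num = raw.astype(float)
    except ValueError:
        for gene, row in raw.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise LoadError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    if num.isna().any().any():
        j = num.isna().any(axis=0).idxmax()
        i = num[j].isna().idxmax()
        raise LoadError(f"non-numeric value at gene {i!r}, sample {j!r}")
    if num.index.has_duplicates:
        num = num.groupby(level=0, sort=False).mean()
    if log2_transform:
        num = np.log2(num + 1.0)
    if isinstance(group_map, (str, os.PathLike)):
        gm = pd.read_csv(group_map, sep="\t", index_col=0).iloc[:, 0]
    else:
        gm = pd.Series(dict(group_map))
    var = num.to_numpy().var(axis=1) if num.shape[1] else np.array([])
    flagged = tuple(num.index[var == 0]) if num.size else ()
    return ExpressionMatrix(num, gm.astype(str), flagged)


def read_annotation(path: str) -> GeneAnnotation:
    t = pd.read_csv(path, sep="\t", index_col=0)
    need = {"biotype", "is_autophagy"}
    if not need.issubset(t.columns):
        raise LoadError(f"annotation table must have columns {sorted(need)}")
    return GeneAnnotation(t)


def read_clinical(path: str) -> SurvivalData:
    t = pd.read_csv(path, sep="\t", index_col=0)
    need = {"time", "event"}
    if not need.issubset(t.columns):
        raise LoadError(f"clinical table must have columns {sorted(need)}")
    return SurvivalData(t)


def read_signature(path: str) -> CellTypeSignature:
    return CellTypeSignature(pd.read_csv(path, sep="\t", index_col=0).astype(float))


# ---------------------------------------------------------------------------
# writers


def write_results(tables: dict[str, pd.DataFrame], out_dir: str) -> dict[str, str]:
    """Write each result table as ``<out_dir>/<name>.tsv``.

    Column order is preserved; floats keep 12 significant digits so that
    re-reading reproduces values. Returns ``{name: path}``.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!r} is not writable")
    paths = {}
    for name, table in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
        paths[name] = path
    return paths


def read_result(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
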