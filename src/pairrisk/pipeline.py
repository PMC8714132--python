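"""End-to-end orchestration: screen -> pairs -> fit -> evaluate -> downstream.

A single PipelineConfig carries every stage threshold (defaults are the
published screening values: r > 0.6, p < 0.001, FDR < 0.05, |log2FC| > 2,
20-80% stability, univariate p < 0.01, 10-fold CV) plus the seed. The run
manifest records the effective config, its hash, and the stage-wise funnel
counts; identical config and inputs yield a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cox, evaluation, pairing, screening
from .datamodel import ExpressionMatrix, GeneAnnotation, SurvivalData, TUMOR, write_results
from .evaluation import DAYS_PER_YEAR

logger = logging.getLogger("pairrisk")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    r_min: float = 0.6
    p_corr: float = 0.001
    fdr: float = 0.05
    lfc: float = 2.0
    stability_lo: float = 0.2
    stability_hi: float = 0.8
    p_screen: float = 0.01
    folds: int = 10
    horizons: tuple[float, ...] = (1.0, 2.0, 3.0)  # years
    seed: int = 0
    use_abs_corr: bool = False
    corr_samples: str = "all"  # or "tumor"
    stability_samples: str = "modeling"  # or "all"
    cv_rule: str = "min"  # or "1se"
    ties: str = "efron"
    aic_backward: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.stability_lo < self.stability_hi <= 1):
            raise ValueError("stability window must satisfy 0 <= lo < hi <= 1")
        for name in ("p_corr", "fdr", "p_screen"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.corr_samples not in ("all", "tumor"):
            raise ValueError("corr_samples must be 'all' or 'tumor'")
        if self.stability_samples not in ("all", "modeling"):
            raise ValueError("stability_samples must be 'all' or 'modeling'")
        self.horizons = tuple(float(h) for h in self.horizons)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["horizons"] = list(self.horizons)
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    model: cox.RiskModel
    stratification: cox.RiskStratification
    tables: dict[str, pd.DataFrame] = field(repr=False)
    manifest: dict = field(repr=False, default=None)


def run_pipeline(
    config: PipelineConfig,
    expr: ExpressionMatrix,
    annot: GeneAnnotation,
    surv: SurvivalData,
    *,
    signatures: dict[str, list[str]] | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Execute the full pair-signature pipeline and build the run manifest."""
    counts: dict[str, int] = {"genes_in": int(len(expr.gene_ids))}

    # --- screen ------------------------------------------------------------
    try:
        corr_cols = expr.samples_in_group(TUMOR) if config.corr_samples == "tumor" else None
        edges, auto_lncs = screening.coexpression_screen(
            expr, annot, config.r_min, config.p_corr,
            use_abs=config.use_abs_corr, samples=corr_cols,
        )
        counts["edges"] = int(len(edges))
        counts["autophagy_lncrnas"] = int(len(auto_lncs))
        if len(auto_lncs) < 2:
            raise PipelineError("screen: fewer than 2 autophagy-related lncRNAs")
        de = screening.differential_screen(expr, auto_lncs, config.fdr, config.lfc)
        de_lncs = list(de.table.index[de.table["passed"]])
        counts["de_lncrnas"] = int(len(de_lncs))
        logger.info("screen: %d edges, %d autophagy lncRNAs, %d DE", counts["edges"],
                    counts["autophagy_lncrnas"], counts["de_lncrnas"])
        if len(de_lncs) < 2:
            raise PipelineError("screen: fewer than 2 differentially expressed lncRNAs")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"screen: {e}") from e

    # --- pairs -------------------------------------------------------------
    try:
        pm = pairing.build_pair_matrix(expr, de_lncs)
        counts["pairs_built"] = int(len(pm.pair_ids))
        model_samples = [s for s in surv.sample_ids if s in pm.indicators.columns]
        stab_cols = model_samples if config.stability_samples == "modeling" else None
        pm_stable = pairing.stability_filter(
            pm, config.stability_lo, config.stability_hi, samples=stab_cols
        )
        counts["pairs_stable"] = int(len(pm_stable.pair_ids))
        logger.info("pairs: %d built, %d stable", counts["pairs_built"], counts["pairs_stable"])
        if len(pm_stable.pair_ids) == 0:
            raise PipelineError("pairs: no pair passes the stability filter")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"pairs: {e}") from e

    # --- fit ---------------------------------------------------------------
    try:
        surv_model = surv.subset(model_samples)
        uni, skipped = cox.univariate_screen(pm_stable, surv_model, config.p_screen, config.ties)
        candidates = list(uni.index[uni["retained"]])
        counts["pairs_screened"] = int(len(candidates))
        if not candidates:
            raise PipelineError("fit: no pairs pass univariate screen")
        if len(candidates) >= 2:
            path = cox.lasso_cox(
                pm_stable.subset_samples(model_samples).indicators.loc[candidates].T,
                surv_model, config.folds, config.seed, config.ties, cv_rule=config.cv_rule,
            )
            selected = path.selected_pairs()
            lasso_table = pd.DataFrame(
                {"lambda": path.lambdas, "cv_deviance": path.cv_deviance, "cv_se": path.cv_se}
            )
        else:
            path, selected = None, candidates
            lasso_table = pd.DataFrame(columns=["lambda", "cv_deviance", "cv_se"])
        if not selected:
            raise PipelineError("fit: LASSO selected no pairs")
        counts["pairs_selected"] = int(len(selected))
        model = cox.finalize_model(
            selected, pm_stable, surv_model, config.ties, config.aic_backward
        )
        counts["pairs_in_model"] = int(len(model.pair_ids))
        strat = cox.risk_score(model, pm_stable.subset_samples(model_samples))
        counts["n_low"] = int((strat.group == "low").sum())
        counts["n_high"] = int((strat.group == "high").sum())
        logger.info("fit: %d screened, %d selected, groups %d low / %d high",
                    counts["pairs_screened"], counts["pairs_selected"],
                    counts["n_low"], counts["n_high"])
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"fit: {e}") from e

    # --- evaluate ----------------------------------------------------------
    try:
        scores = strat.score.loc[list(surv_model.sample_ids)]
        groups = strat.group.loc[list(surv_model.sample_ids)]
        lr = evaluation.logrank_test(surv_model, groups.to_numpy())
        km_tables = []
        for label in ("low", "high"):
            sub = surv_model.subset(groups.index[groups == label])
            kt = evaluation.km_curve(sub).table()
            kt.insert(0, "group", label)
            km_tables.append(kt)
        aucs = {}
        for h in config.horizons:
            try:
                aucs[h] = evaluation.td_auc(scores.to_numpy(), surv_model, h * DAYS_PER_YEAR).auc
            except ValueError:
                aucs[h] = float("nan")
        covars = surv_model.table[surv_model.covariate_names]
        uni_fit, multi_fit, independent = evaluation.independence_test(scores, covars, surv_model) \
            if len(covars.columns) else (None, None, None)
    except Exception as e:
        raise PipelineError(f"evaluate: {e}") from e

    tables = {
        "edges": edges,
        "de_lncrnas": de.table,
        "pair_freq": pm_stable.freq.rename("freq").to_frame(),
        "univariate_screen": uni,
        "lasso_path": lasso_table,
        "model": model.fit.summary().assign(coefficient=model.coefficients),
        "scores": strat.table,
        "km": pd.concat(km_tables, ignore_index=True),
        "auc_summary": pd.DataFrame(
            {"horizon_years": list(aucs), "auc": list(aucs.values())}
        ),
    }
    if multi_fit is not None:
        tables["independence"] = pd.concat(
            [uni_fit.summary().assign(fit="univariate"),
             multi_fit.summary().assign(fit="multivariate")]
        )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "counts": counts,
        "selected_pairs": model.pair_ids,
        "cutoff": round(model.cutoff, 12),
        "logrank_chi_square": round(lr.chi_square, 12),
        "logrank_p": round(lr.p, 15),
        "auc": {f"{h:g}y": (None if np.isnan(a) else round(a, 12)) for h, a in aucs.items()},
        "independent_predictor": independent,
    }
    result = PipelineResult(model, strat, tables, manifest)
    if out_dir is not None:
        write_results(tables, out_dir)
        with open(f"{out_dir}/manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
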