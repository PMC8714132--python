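"""Synthetic tumor/normal cohort generator with planted structure.

Emulates the statistical structure the pair-signature pipeline assumes:

* a set of autophagy mRNAs plus lncRNAs that are co-expressed with them at a
  planted Pearson correlation (each linked lncRNA is a correlation-weighted
  mixture of one standardized mRNA signal and independent Gaussian noise);
* a subset of linked lncRNAs with a planted tumor-vs-normal log2 mean shift
  (the partner mRNA receives the same shift, so the pooled-sample
  co-expression correlation is not attenuated by the group difference);
* overall-survival times for tumor samples drawn from an exponential model
  whose hazard is ``baseline_hazard * exp(sum_k beta_k * indicator_k)``,
  where ``indicator_k`` is the 0/1 within-sample ordering of a planted
  lncRNA pair computed from the generated expression itself;
* independent exponential censoring with its rate tuned numerically so the
  expected censored fraction equals ``censor_rate``.

Members of a planted survival pair always share the same differential shift:
an unequal shift would push the pair's ordering frequency toward 0 or 1 and
silently remove it in the stability filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GeneAnnotation, SurvivalData, TUMOR, NORMAL


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror a TCGA-like stomach-cancer design: ~375 tumors vs a
    small normal arm, strong planted co-expression (r = 0.85) well above
    the screening threshold of 0.6, large planted differential shifts
    (|log2FC| = 3 against a threshold of 2), pair log-hazard ratios of
    magnitude >= 1, and ~30% censoring.
    """

    n_tumor: int = 375
    n_normal: int = 32
    n_autophagy_mrna: int = 20
    n_lnc_linked: int = 30
    n_lnc_noise: int = 40
    planted_corr: float = 0.85
    n_de_lnc: int = 12
    de_log2fc: float = 3.0
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censor_rate: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.planted_corr < 1.0):
            raise ValueError("planted_corr must lie in (0, 1)")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValueError("noise_sd and baseline_hazard must be positive")
        if self.n_de_lnc > self.n_lnc_linked:
            raise ValueError("n_de_lnc cannot exceed n_lnc_linked")


def default_planted_pairs(spec: CohortSpec, betas=(1.2, -1.0, 1.0)) -> list[tuple[str, str, float]]:
    """Plant pairs among consecutive DE lncRNAs (which share their shift)."""
    pairs = []
    for k, beta in enumerate(betas):
        a, b = 2 * k, 2 * k + 1
        if b >= spec.n_de_lnc:
            break  # plant only as many pairs as the DE set can carry
        pairs.append((_lnc_name(a), _lnc_name(b), float(beta)))
    return pairs


def _lnc_name(i: int) -> str:
    return f"LNC{i + 1:04d}"


def _mrna_name(i: int) -> str:
    return f"ATG{i + 1:04d}"


def _noise_name(i: int) -> str:
    return f"LNCN{i + 1:04d}"


def _tune_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate mu with mean P(C < T) = target.

    For independent exponentials with rates lam and mu the censoring
    probability is mu / (lam + mu); solve mean_i mu/(lam_i+mu) = target
    by bisection on log mu.
    """
    if target <= 0:
        return 0.0

    def frac(mu):
        return float(np.mean(mu / (hazards + mu)))

    lo, hi = 1e-12, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(spec: CohortSpec):
    """Generate (ExpressionMatrix, GeneAnnotation, SurvivalData, truth).

    The truth record lists the planted co-expression edges, DE genes with
    their shifts, and the planted pairs with log hazard ratios. Identical
    spec (including seed) gives bit-identical output.
    """
    ss = np.random.SeedSequence(spec.seed)
    r_expr, r_surv, r_clin = [np.random.default_rng(s) for s in ss.spawn(3)]

    n = spec.n_tumor + spec.n_normal
    tumor_ids = [f"T{i + 1:04d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i + 1:04d}" for i in range(spec.n_normal)]
    samples = tumor_ids + normal_ids
    is_tumor = np.array([1] * spec.n_tumor + [0] * spec.n_normal, dtype=float)

    planted_pairs = list(spec.planted_pairs) or default_planted_pairs(spec)
    lnc_linked = [_lnc_name(i) for i in range(spec.n_lnc_linked)]
    for a, b, _ in planted_pairs:
        for g in (a, b):
            if g not in lnc_linked:
                raise ValueError(f"planted pair gene {g!r} is not a generated linked lncRNA")

    # standardized latent signal per autophagy mRNA
    z = r_expr.standard_normal((spec.n_autophagy_mrna, n))
    mrna_means = r_expr.uniform(4.0, 9.0, spec.n_autophagy_mrna)

    # linked lncRNA j follows mRNA partner j mod m
    partner = np.arange(spec.n_lnc_linked) % spec.n_autophagy_mrna
    rho = spec.planted_corr
    eps = r_expr.standard_normal((spec.n_lnc_linked, n))
    # lncRNA baselines sit in a narrow band so that a realistic fraction of
    # pairs has an informative (non-degenerate) ordering frequency
    lnc_means = r_expr.uniform(4.0, 6.0, spec.n_lnc_linked)

    # DE shifts: consecutive lncRNAs share sign so planted (2k, 2k+1) pairs
    # get identical shifts; partner mRNAs inherit the shift.
    de_shift = np.zeros(spec.n_lnc_linked)
    for j in range(spec.n_de_lnc):
        de_shift[j] = spec.de_log2fc if (j // 2) % 2 == 0 else -spec.de_log2fc
    # equalize means within planted pairs so ordering frequency sits near 1/2
    name_to_idx = {g: i for i, g in enumerate(lnc_linked)}
    for a, b, _ in planted_pairs:
        ia, ib = name_to_idx[a], name_to_idx[b]
        m = 0.5 * (lnc_means[ia] + lnc_means[ib])
        lnc_means[ia] = m
        lnc_means[ib] = m
        de_shift[ib] = de_shift[ia]

    mrna_shift = np.zeros(spec.n_autophagy_mrna)
    for j in range(spec.n_de_lnc):
        mrna_shift[partner[j]] = de_shift[j]

    mrna = mrna_means[:, None] + 1.0 * z + mrna_shift[:, None] * is_tumor[None, :]
    lnc = (
        lnc_means[:, None]
        + spec.noise_sd * (rho * z[partner] + np.sqrt(1.0 - rho**2) * eps)
        + de_shift[:, None] * is_tumor[None, :]
    )
    noise_lnc = r_expr.uniform(4.0, 6.0, spec.n_lnc_noise)[:, None] + spec.noise_sd * (
        r_expr.standard_normal((spec.n_lnc_noise, n))
    )

    gene_ids = (
        [_mrna_name(i) for i in range(spec.n_autophagy_mrna)]
        + lnc_linked
        + [_noise_name(i) for i in range(spec.n_lnc_noise)]
    )
    values = pd.DataFrame(np.vstack([mrna, lnc, noise_lnc]), index=gene_ids, columns=samples)
    group = pd.Series([TUMOR] * spec.n_tumor + [NORMAL] * spec.n_normal, index=samples)
    expr = ExpressionMatrix(values, group)

    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "biotype": ["mRNA"] * spec.n_autophagy_mrna
                + ["lncRNA"] * (spec.n_lnc_linked + spec.n_lnc_noise),
                "is_autophagy": [True] * spec.n_autophagy_mrna
                + [False] * (spec.n_lnc_linked + spec.n_lnc_noise),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )

    # survival for tumor samples; hazard driven by planted pair indicators
    # computed from the generated expression itself
    tumor_vals = values[tumor_ids]
    log_hr = np.zeros(spec.n_tumor)
    indicators = {}
    for a, b, beta in planted_pairs:
        ind = (tumor_vals.loc[a].to_numpy() > tumor_vals.loc[b].to_numpy()).astype(float)
        indicators[f"{a}|{b}"] = ind
        log_hr += beta * ind
    hazards = spec.baseline_hazard * np.exp(log_hr)
    t_event = r_surv.exponential(1.0 / hazards)
    mu = _tune_censor_rate(hazards, spec.censor_rate)
    if mu > 0:
        t_cens = r_surv.exponential(1.0 / mu, spec.n_tumor)
    else:
        t_cens = np.full(spec.n_tumor, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # keep strictly positive after rounding

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": np.round(r_clin.normal(65.0, 10.0, spec.n_tumor)),
            "sex": r_clin.integers(0, 2, spec.n_tumor),
            "grade": r_clin.integers(1, 4, spec.n_tumor),
            "stage": r_clin.integers(1, 5, spec.n_tumor),
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    surv = SurvivalData(clinical)

    truth = {
        "spec": asdict(spec),
        "edges": [
            {"mrna": _mrna_name(int(partner[j])), "lnc": lnc_linked[j], "r": rho}
            for j in range(spec.n_lnc_linked)
        ],
        "de_genes": [
            {"gene": lnc_linked[j], "log2fc": float(de_shift[j])}
            for j in range(spec.n_de_lnc)
        ],
        "planted_pairs": [
            {"lnc_a": a, "lnc_b": b, "beta": float(beta)} for a, b, beta in planted_pairs
        ],
        "pair_indicators": {k: v.tolist() for k, v in indicators.items()},
        "censor_rate_param": mu,
    }
    return expr, annot, surv, truth
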