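"""Cohort-level statistics for ordered-severity perfusion studies.

Covers the analysis chain applied to the per-eye parameter table: Spearman
rank trend against ordered stage, ANCOVA adjusted for age and scan
quality with covariate-adjusted group means, Benjamini-Hochberg-corrected
pairwise post-hoc contrasts, Cohen's d effect sizes, a-priori two-sample
sample size from noncentral-t power, and ROC screening statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigError,
    LabelError,
    ModelError,
    ParameterError,
    UndefinedStatisticError,
)
from .image_io import EyeRecord, records_to_frame

__all__ = [
    "SpearmanResult",
    "AncovaResult",
    "PairwiseResult",
    "EffectSize",
    "RocResult",
    "spearman_stage",
    "ancova_adjusted_means",
    "pairwise_posthoc",
    "benjamini_hochberg",
    "cohens_d",
    "min_sample_size",
    "roc_analysis",
    "run_cohort_report",
]


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float


def spearman_stage(values: Sequence[float], stages: Sequence[int]) -> SpearmanResult:
    """Spearman rank correlation (midrank ties) of a parameter vs stage."""
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages, dtype=float)
    if len(values) != len(stages):
        raise ParameterError("values and stages must be the same length")
    if len(values) < 3:
        raise ParameterError("need at least 3 eyes")
    if np.ptp(values) == 0 or np.ptp(stages) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    rho, p = sps.spearmanr(values, stages)
    return SpearmanResult(rho=float(rho), p_value=float(p))


@dataclass
class AncovaResult:
    """Covariate-adjusted group means and the machinery to contrast them.

    ``adjusted_means[s]`` is the model prediction for stage ``s`` with both
    covariates set to the whole-sample means.  ``coefficients`` holds the
    fitted age and q_score slopes.  The parameter vector, its covariance,
    and the per-stage design rows are kept so post-hoc contrasts reuse the
    model's pooled residual variance.
    """

    adjusted_means: Dict[int, float]
    overall_p: float
    f_statistic: float
    coefficients: Dict[str, float]
    residual_df: int
    stages: List[int] = field(default_factory=list)
    n_per_stage: Dict[int, int] = field(default_factory=dict)
    _beta: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)
    _stage_rows: Dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def adjusted_mean_se(self, stage: int) -> float:
        r = self._stage_rows[stage]
        return float(np.sqrt(r @ self._cov @ r))


def _ancova_design(
    stages: np.ndarray, covariates: List[np.ndarray]
) -> Tuple[np.ndarray, List[int]]:
    levels = sorted(set(int(s) for s in stages))
    cols = [np.ones(len(stages))]
    for s in levels[1:]:
        cols.append((stages == s).astype(float))
    cols.extend(covariates)
    return np.column_stack(cols), levels


def ancova_adjusted_means(
    values: Sequence[float],
    stages: Sequence[int],
    age: Optional[Sequence[float]] = None,
    q_score: Optional[Sequence[float]] = None,
) -> AncovaResult:
    """OLS of value on stage indicators plus age and q_score covariates.

    The overall p-value is the partial F-test for dropping all stage
    indicators; adjusted means are predictions at the sample covariate
    means, so with identical covariate distributions across groups they
    coincide with the raw group means.  Either covariate may be omitted
    (with both omitted and two groups, the overall test reduces exactly
    to the pooled two-sample t-test).
    """
    y = np.asarray(values, dtype=float)
    stages = np.asarray(stages, dtype=int)
    cov_named = []
    for name, vec in (("age", age), ("q_score", q_score)):
        if vec is not None:
            vec = np.asarray(vec, dtype=float)
            if len(vec) != len(y):
                raise ParameterError("input vectors must share a length")
            cov_named.append((name, vec))
    if len(y) != len(stages):
        raise ParameterError("input vectors must share a length")
    levels = sorted(set(stages.tolist()))
    if len(levels) < 2:
        raise ModelError("need at least 2 stages present")

    X, levels = _ancova_design(stages, [v for _, v in cov_named])
    n, p = X.shape
    if n <= p:
        raise ModelError(f"too few observations ({n}) for {p} parameters")
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise ModelError("singular design: stage indicators collinear with covariates")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * np.linalg.inv(XtX)

    # Partial F-test for the stage factor against the covariate-only model.
    Xr = np.column_stack([np.ones(n)] + [v for _, v in cov_named])
    beta_r, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    rss_full = float(resid @ resid)
    rss_red = float(((y - Xr @ beta_r) ** 2).sum())
    df_num = len(levels) - 1
    f_stat = ((rss_red - rss_full) / df_num) / sigma2
    overall_p = float(sps.f.sf(f_stat, df_num, df_resid))

    n_cov = len(cov_named)
    cov_means = [float(v.mean()) for _, v in cov_named]
    stage_rows: Dict[int, np.ndarray] = {}
    adjusted: Dict[int, float] = {}
    for s in levels:
        row = np.zeros(p)
        row[0] = 1.0
        if s != levels[0]:
            row[1 + levels[1:].index(s)] = 1.0
        for k, m in enumerate(cov_means):
            row[p - n_cov + k] = m
        stage_rows[s] = row
        adjusted[s] = float(row @ beta)

    return AncovaResult(
        adjusted_means=adjusted,
        overall_p=overall_p,
        f_statistic=float(f_stat),
        coefficients={
            name: float(beta[p - n_cov + k]) for k, (name, _) in enumerate(cov_named)
        },
        residual_df=df_resid,
        stages=levels,
        n_per_stage={s: int((stages == s).sum()) for s in levels},
        _beta=beta,
        _cov=cov,
        _stage_rows=stage_rows,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment: adj p_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass(frozen=True)
class PairwiseResult:
    pairs: List[Tuple[int, int]]
    differences: List[float]
    raw_p: List[float]
    adj_p: List[float]
    significant: List[bool]
    fdr: float


def pairwise_posthoc(model: AncovaResult, fdr: float = 0.05) -> PairwiseResult:
    """All pairwise adjusted-mean contrasts with BH correction.

    Each contrast uses the ANCOVA model's pooled residual variance: the
    difference of two adjusted means is a linear contrast of the fitted
    coefficients, its SE comes from the coefficient covariance, and the
    t-test uses the model's residual df.  The BH family is the set of
    contrasts for this one parameter.
    """
    pairs = list(combinations(model.stages, 2))
    diffs, raw = [], []
    for a, b in pairs:
        c = model._stage_rows[b] - model._stage_rows[a]
        diff = float(c @ model._beta)
        se = float(np.sqrt(c @ model._cov @ c))
        tval = diff / se
        raw.append(float(2.0 * sps.t.sf(abs(tval), model.residual_df)))
        diffs.append(diff)
    adj = benjamini_hochberg(raw)
    return PairwiseResult(
        pairs=pairs,
        differences=diffs,
        raw_p=raw,
        adj_p=adj.tolist(),
        significant=(adj <= fdr).tolist(),
        fdr=fdr,
    )


@dataclass(frozen=True)
class EffectSize:
    d: float


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> EffectSize:
    """Standardized mean difference with df-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("both groups need at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise UndefinedStatisticError("zero pooled SD: effect size undefined")
    return EffectSize(d=float((a.mean() - b.mean()) / np.sqrt(pooled_var)))


def two_sample_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = abs(d) * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def min_sample_size(d: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest per-group n giving the target power for effect size d."""
    if d <= 0:
        raise ParameterError(f"effect size must be positive, got {d}")
    n = 2  # df >= 1 requires n >= 2 per group
    while two_sample_power(d, n, alpha) < power:
        n += 1
        if n > 10_000_000:
            raise ParameterError("required sample size exceeds 1e7; check inputs")
    return n


@dataclass(frozen=True)
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    operating_threshold: float
    direction: str  # 'lower' => smaller values indicate the positive class


def roc_analysis(values: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Rank-based AUC with a Youden-maximizing operating point.

    The AUC is the Mann-Whitney probability of correct ordering with
    midrank tie handling, oriented so that AUC >= 0.5 (the orientation is
    reported in ``direction``; for perfusion parameters, lower values in
    the positive class).  The operating threshold maximizes sensitivity +
    specificity - 1; exact ties go to the higher-sensitivity point.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(v) != len(y):
        raise ParameterError("values and labels must share a length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise LabelError("both classes must be non-empty")

    ranks = sps.rankdata(v)  # midranks
    u = float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0
    auc_high = u / (n_pos * n_neg)  # P(value_pos > value_neg), ties half
    if auc_high >= 0.5:
        direction, auc = "higher", auc_high
    else:
        direction, auc = "lower", 1.0 - auc_high

    best = None  # (J, sens, spec, thr)
    for thr in np.unique(v):
        if direction == "lower":
            pred = v <= thr
        else:
            pred = v >= thr
        sens = float((pred & y).sum()) / n_pos
        spec = float((~pred & ~y).sum()) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and sens > best[1]
        ):
            best = (j, sens, spec, float(thr))
    _, sens, spec, thr = best
    return RocResult(
        auc=float(auc),
        sensitivity=sens,
        specificity=spec,
        operating_threshold=thr,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

DEFAULT_ROC_CONTRAST = (4, (2, 3))  # severe vs mild+moderate


def run_cohort_report(
    records: List[EyeRecord],
    params: Sequence[str],
    roc_params: Sequence[str] = (),
    fdr: float = 0.05,
    roc_contrast: Tuple[int, Sequence[int]] = DEFAULT_ROC_CONTRAST,
    posthoc_only_if_significant: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Produce the trend / adjusted-means / pairwise / ROC tables.

    Per-parameter failures (zero variance, missing stages, ...) are
    recorded in the ``errors`` table; the report still covers every
    parameter that succeeded.  Output is deterministic for fixed input.
    """
    df = records_to_frame(records)
    missing = [p for p in params if p not in df.columns or df[p].isna().all()]
    if missing:
        raise ConfigError(f"parameters absent from all records: {missing}")

    spearman_rows, adj_rows, pair_rows, roc_rows, err_rows = [], [], [], [], []
    for pname in params:
        sub = df.dropna(subset=[pname, "age", "q_score"])
        vals = sub[pname].to_numpy(float)
        stg = sub["stage"].to_numpy(int)
        try:
            sp = spearman_stage(vals, stg)
            spearman_rows.append({"parameter": pname, "rho": sp.rho, "p_value": sp.p_value})
        except Exception as exc:  # degraded but still reported
            err_rows.append({"parameter": pname, "step": "spearman", "error": str(exc)})
        try:
            anc = ancova_adjusted_means(
                vals, stg, sub["age"].to_numpy(float), sub["q_score"].to_numpy(float)
            )
            row = {"parameter": pname, "ancova_p": anc.overall_p}
            for s, m in anc.adjusted_means.items():
                row[f"stage_{s}_adj_mean"] = m
            adj_rows.append(row)
            if anc.overall_p < 0.05 or not posthoc_only_if_significant:
                pw = pairwise_posthoc(anc, fdr=fdr)
                for (a, b), diff, rp, ap, sig in zip(
                    pw.pairs, pw.differences, pw.raw_p, pw.adj_p, pw.significant
                ):
                    pair_rows.append(
                        {
                            "parameter": pname,
                            "stage_a": a,
                            "stage_b": b,
                            "difference": diff,
                            "raw_p": rp,
                            "adj_p": ap,
                            "significant": sig,
                        }
                    )
        except Exception as exc:
            err_rows.append({"parameter": pname, "step": "ancova", "error": str(exc)})

    pos_stage, neg_stages = roc_contrast
    for pname in roc_params:
        sub = df.dropna(subset=[pname])
        sel = sub[sub["stage"].isin([pos_stage, *neg_stages])]
        try:
            roc = roc_analysis(
                sel[pname].to_numpy(float), (sel["stage"] == pos_stage).to_numpy()
            )
            roc_rows.append(
                {
                    "parameter": pname,
                    "auc": roc.auc,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "operating_threshold": roc.operating_threshold,
                    "direction": roc.direction,
                }
            )
        except Exception as exc:
            err_rows.append({"parameter": pname, "step": "roc", "error": str(exc)})

    return {
        "spearman": pd.DataFrame(spearman_rows),
        "adjusted_means": pd.DataFrame(adj_rows),
        "pairwise": pd.DataFrame(pair_rows),
        "roc": pd.DataFrame(roc_rows),
        "errors": pd.DataFrame(err_rows),
    }
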