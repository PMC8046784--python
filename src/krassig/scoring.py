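"""Signature scoring and survival statistics.

Per-cell scoring is detection-based: the enrichment score of a cell is the
fraction of signature genes with at least one count, so a score of 1 means
every marker of the set is detected in that cell.

Cohort-level scoring z-transforms each signature gene across samples,
flips the sign of down-regulated genes, and averages with equal weights;
the cohort is split at the median score into low/high groups for
Kaplan-Meier comparison. The survival machinery (product-limit estimator,
two-group log-rank chi-square, single-covariate Cox partial likelihood
with Efron tie handling) is implemented here with explicit numerical
contracts; each routine is cross-checked against an independent survival
library in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix


def cell_enrichment_score(matrix: CountMatrix, genes) -> pd.DataFrame:
    """Fraction of the listed signature genes detected (count > 0) per cell.

    Genes absent from the matrix are excluded with a warning; if every
    gene is absent the score is undefined and an error is raised.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("signature gene list is empty")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from matrix: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = matrix.counts[[index[g] for g in present], :]
    n_detected = np.asarray((sub > 0).sum(axis=0)).ravel().astype(int)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "n_detected": n_detected,
            "n_signature": len(present),
            "enrichment": n_detected / len(present),
        }
    )


def cohort_signature_score(
    expression: pd.DataFrame,
    up_genes,
    down_genes=(),
    population_sd: bool = False,
) -> pd.Series:
    """Mean of per-gene z-scores, with down-gene z-scores sign-flipped.

    ``expression`` is samples x genes. Each signature gene is z-scored
    across samples (sample sd, n-1 denominator, unless ``population_sd``);
    down-regulated genes contribute with weight -1, up-regulated with +1,
    all equal in magnitude. Zero-variance genes are excluded with a
    warning; an error is raised if none remain.
    """
    up_genes, down_genes = list(up_genes), list(down_genes)
    if expression.shape[0] < 2:
        raise ValueError("cohort scoring needs >= 2 samples")
    ddof = 0 if population_sd else 1
    cols = []
    dropped = []
    for gene, sign in [(g, 1.0) for g in up_genes] + [
        (g, -1.0) for g in down_genes
    ]:
        if gene not in expression.columns:
            dropped.append(gene)
            continue
        x = expression[gene].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        if sd == 0:
            dropped.append(gene)
            continue
        cols.append(sign * (x - x.mean()) / sd)
    if dropped:
        warnings.warn(f"excluded {len(dropped)} signature genes: {dropped[:5]}")
    if not cols:
        raise ValueError("no usable signature gene (all missing or constant)")
    score = np.mean(cols, axis=0)
    return pd.Series(score, index=expression.index, name="score")


def median_split(scores) -> pd.Series:
    """Split samples at the median score: score <= median -> 'low'.

    The median element goes to the low group, so with distinct scores and
    odd n the low group holds one more sample than the high group. If all
    scores are equal everything is low and a warning is emitted.
    """
    s = pd.Series(scores)
    if s.size < 2:
        raise ValueError("median split needs >= 2 samples")
    med = float(np.median(s.to_numpy(dtype=float)))
    group = pd.Series(
        np.where(s.to_numpy(dtype=float) <= med, "low", "high"),
        index=s.index,
        name="group",
    )
    if (group == "low").all():
        warnings.warn("all scores at or below the median; high group is empty")
    return group


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n_risk: np.ndarray
    n_events: np.ndarray

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set after
    their time (censoring ties at an event time stay at risk for it)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if t.size == 0:
        raise ValueError("no subjects")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    surv, risks, deaths = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        risks.append(n_risk)
        deaths.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        n_risk=np.asarray(risks),
        n_events=np.asarray(deaths),
    )


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (df = 1) and two-sided p."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"exactly two groups required, got {levels.tolist()}")
    in1 = g == levels[1]
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == et) & e).sum())
        d1 = int(((t == et) & e & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _cox_loglik(beta: float, t, e, x):
    """Efron partial log-likelihood, gradient and Hessian for one binary
    covariate."""
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    ll = grad = hess = 0.0
    for et in np.unique(t[e]):
        tied = (t == et) & e
        at_risk = t >= et
        d = int(tied.sum())
        s0 = w[at_risk].sum()
        s1 = (w[at_risk] * x[at_risk]).sum()
        s2 = (w[at_risk] * x[at_risk] ** 2).sum()
        d0 = w[tied].sum()
        d1 = (w[tied] * x[tied]).sum()
        d2 = (w[tied] * x[tied] ** 2).sum()
        ll += eta[tied].sum()
        for l in range(d):
            f = l / d
            z0 = s0 - f * d0
            z1 = s1 - f * d1
            z2 = s2 - f * d2
            ll -= math.log(z0)
            grad_term = z1 / z0
            grad -= grad_term
            hess -= z2 / z0 - grad_term**2
        grad += x[tied].sum()
    return ll, grad, hess


def cox_hazard_ratio(
    times, events, group, tol: float = 1e-8, max_iter: int = 100,
    beta_cap: float = 15.0,
) -> float:
    """exp(beta) from a single-covariate Cox fit (Efron ties, Newton).

    Iterates Newton steps to |delta beta| < ``tol``. Monotone likelihood
    (complete separation of events) is detected when |beta| runs past
    ``beta_cap``; the estimate is capped there with a warning.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    x = (g == levels[1]).astype(float)
    for lvl in levels:
        if not e[g == lvl].any():
            raise ValueError(f"group {lvl!r} has no events")
    beta = 0.0
    for _ in range(max_iter):
        _, grad, hess = _cox_loglik(beta, t, e, x)
        if hess >= 0:  # flat or degenerate: no information
            break
        step = -grad / hess
        # dampen absurd steps to keep Newton stable
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(beta) > beta_cap:
            warnings.warn(
                "monotone partial likelihood (complete separation); "
                f"hazard ratio capped at exp({beta_cap})"
            )
            return float(np.exp(math.copysign(beta_cap, beta)))
        if abs(step) < tol:
            break
    return float(np.exp(beta))


@dataclass
class SurvivalResult:
    km_low: KMCurve
    km_high: KMCurve
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float


def survival_analysis(times, events, group) -> SurvivalResult:
    """KM curves per group plus log-rank p and Cox hazard ratio
    (high vs low)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    chi2, p = logrank_test(t, e, g)
    hr = cox_hazard_ratio(t, e, (g == "high").astype(int))
    return SurvivalResult(
        km_low=km_estimate(t[g == "low"], e[g == "low"]),
        km_high=km_estimate(t[g == "high"], e[g == "high"]),
        logrank_chi2=chi2,
        logrank_p=p,
        hazard_ratio=hr,
    )


def two_group_t(scores_a, scores_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed Student t; Welch (unequal variance) by default.

    Two constant groups with equal means give t = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ellipsoid_volume(length: float, width: float) -> float:
    """Caliper tumor volume: 1/2 * length * width**2 (same cubic units).

    The greatest diameter is the length by definition; swapped inputs are
    corrected with a warning.
    """
    if length < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    if width > length:
        warnings.warn("width exceeds length; swapping (length is the "
                      "greatest diameter)")
        length, width = width, length
    return 0.5 * length * width**2
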