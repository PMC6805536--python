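"""Direct pairwise meta-analysis for heterogeneity screening.

Before fitting the joint network model it is standard to pool every
treatment pair with head-to-head evidence separately and inspect the
between-study heterogeneity statistics: Cochran's Q, the
DerSimonian–Laird moment estimate of the between-study variance tau²,
and I² (the share of observed variability attributed to heterogeneity
rather than sampling error).

Per-study effects for dichotomous outcomes are log odds ratios with the
Woolf (inverse-cell-count) variance; a continuity correction of 0.5 is
added to all four cells of any study with a zero cell.  This is a
screening device only — multi-arm studies contribute each of their
within-study pairs without correlation adjustment here, because the
network model itself handles the multi-arm correlation properly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .data import ArmRecord, NetworkData

__all__ = ["PairwiseResult", "pool_pairwise", "pairwise_all", "study_effect"]

_DEFAULT_SCALE = {"continuous": "md", "dichotomous": "log-or",
                  "count": "log-rate-ratio"}


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    k_studies: int
    scale: str
    effect_fixed: float
    ci_fixed: tuple[float, float]
    effect_random: float
    ci_random: tuple[float, float]
    Q: float
    df: int
    p_Q: float
    tau2: float
    I2: float | None  # percent; None when k == 1 (undefined)


def study_effect(arm_a: ArmRecord, arm_b: ArmRecord,
                 scale: str) -> tuple[float, float]:
    """Effect of ``arm_b`` relative to ``arm_a`` and its variance.

    Scales: ``md`` (mean difference), ``log-or`` (Woolf), ``log-rr``,
    ``log-rate-ratio``.  Zero cells trigger a 0.5 correction applied to
    all cells of the affected two-by-two (or to both event counts for
    rates).
    """
    if scale == "md":
        return (arm_b.mean - arm_a.mean,
                arm_a.std_err ** 2 + arm_b.std_err ** 2)
    if scale in ("log-or", "log-rr"):
        r1, n1 = float(arm_a.events), float(arm_a.sample_size)
        r2, n2 = float(arm_b.events), float(arm_b.sample_size)
        if min(r1, n1 - r1, r2, n2 - r2) == 0:
            r1, r2 = r1 + 0.5, r2 + 0.5
            n1, n2 = n1 + 1.0, n2 + 1.0
        if scale == "log-or":
            y = log(r2 / (n2 - r2)) - log(r1 / (n1 - r1))
            v = 1 / r1 + 1 / (n1 - r1) + 1 / r2 + 1 / (n2 - r2)
        else:
            y = log(r2 / n2) - log(r1 / n1)
            v = 1 / r1 - 1 / n1 + 1 / r2 - 1 / n2
        return y, v
    if scale == "log-rate-ratio":
        r1, e1 = float(arm_a.events), arm_a.person_time
        r2, e2 = float(arm_b.events), arm_b.person_time
        if min(r1, r2) == 0:
            r1, r2 = r1 + 0.5, r2 + 0.5
        return log(r2 / e2) - log(r1 / e1), 1 / r1 + 1 / r2
    raise ValueError(f"unknown effect scale {scale!r}")


def pool_pairwise(y, v, *, pair: tuple[str, str] = ("a", "b"),
                  scale: str = "generic") -> PairwiseResult:
    """Inverse-variance pooling with DerSimonian–Laird heterogeneity.

    Parameters
    ----------
    y, v:
        Per-study effects on a linear scale and their variances.

    Notes
    -----
    Q is computed about the fixed-effect (inverse-variance) estimate;
    ``tau² = max(0, (Q − df) / (Σw − Σw²/Σw))``; random-effects weights
    are ``1/(v + tau²)``.  With a single study Q = 0, df = 0, tau² = 0
    and I² is reported as undefined (``None``), not zero.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.size == 0:
        raise ValueError("no studies to pool")
    if np.any(v <= 0):
        raise ValueError("study variances must be positive")
    k = y.size
    w = 1.0 / v
    mu_f = float(np.sum(w * y) / np.sum(w))
    se_f = float(1.0 / sqrt(np.sum(w)))
    Q = float(np.sum(w * (y - mu_f) ** 2))
    df = k - 1
    if df > 0:
        c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
        p_Q = float(stats.chi2.sf(Q, df))
        I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    else:
        tau2, p_Q, I2 = 0.0, float("nan"), None
    wr = 1.0 / (v + tau2)
    mu_r = float(np.sum(wr * y) / np.sum(wr))
    se_r = float(1.0 / sqrt(np.sum(wr)))
    z = stats.norm.ppf(0.975)
    return PairwiseResult(
        pair=pair, k_studies=k, scale=scale,
        effect_fixed=mu_f, ci_fixed=(mu_f - z * se_f, mu_f + z * se_f),
        effect_random=mu_r, ci_random=(mu_r - z * se_r, mu_r + z * se_r),
        Q=Q, df=df, p_Q=p_Q, tau2=tau2, I2=I2,
    )


def pairwise_all(nd: NetworkData, scale: str | None = None) -> list[PairwiseResult]:
    """One pooled result per treatment pair with direct evidence.

    Results are keyed ``(a, b)`` with ``a`` preceding ``b`` in the
    network's treatment index, and report the effect of ``b`` relative
    to ``a``.
    """
    if scale is None:
        scale = _DEFAULT_SCALE[nd.family]
    compatible = {"continuous": {"md"},
                  "dichotomous": {"log-or", "log-rr"},
                  "count": {"log-rate-ratio"}}[nd.family]
    if scale not in compatible:
        raise ValueError(f"scale {scale!r} is incompatible with the "
                         f"{nd.family} family")
    by_pair: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for s in nd.studies:
        arms = nd.study_arms(s)
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                a, b = arms[i], arms[j]
                if nd.treatment_index(a.treatment) > nd.treatment_index(b.treatment):
                    a, b = b, a
                key = (a.treatment, b.treatment)
                by_pair.setdefault(key, []).append(study_effect(a, b, scale))
    order = {t: i for i, t in enumerate(nd.treatments)}
    results = []
    for key in sorted(by_pair, key=lambda p: (order[p[0]], order[p[1]])):
        ys, vs = zip(*by_pair[key])
        results.append(pool_pairwise(np.array(ys), np.array(vs),
                                     pair=key, scale=scale))
    return results


def pairwise_table(results: list[PairwiseResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(dict(
            comparison=f"{r.pair[1]} vs {r.pair[0]}", k=r.k_studies,
            scale=r.scale, effect_fixed=r.effect_fixed,
            lo_fixed=r.ci_fixed[0], hi_fixed=r.ci_fixed[1],
            effect_random=r.effect_random,
            lo_random=r.ci_random[0], hi_random=r.ci_random[1],
            Q=r.Q, df=r.df, p_Q=r.p_Q, tau2=r.tau2,
            I2=r.I2 if r.I2 is not None else np.nan,
        ))
    return pd.DataFrame(rows)
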