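"""Decision output: relative effects, league tables, ranks, profiles.

All quantities are posterior functionals of the basic contrasts
``d_(1,t)`` (and regression coefficients), reconstructed per iteration
through transitivity ``d_(a,b) = d_(1,b) - d_(1,a)``.  Original-scale
(ratio) summaries are quantiles of the exponentiated samples — which,
by monotonicity, equal the exponentials of the linear-scale quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ComparisonTable", "RankResults", "relative_effects",
           "league_layout", "rank_statistics", "forest_data",
           "regression_profile"]

_RATIO_LINKS = {"logit", "log", "cloglog"}
_EFFECT_LABEL = {"logit": "odds ratio", "log": "risk ratio",
                 "cloglog": "hazard ratio", "identity": "mean difference"}


@dataclass
class ComparisonTable:
    """All-pairs grid of effect summaries.

    ``estimate[a, b]`` summarizes the effect of column treatment ``b``
    relative to row treatment ``a``: the posterior median (and central
    95% credible interval) of ``d_(a,b)`` on the requested scale.
    ``significant[a, b]`` flags cells whose interval excludes the null
    (0 on the linear scale, 1 on a ratio scale).
    """

    treatments: list[str]
    estimate: np.ndarray     # (T, T)
    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    significant: np.ndarray  # (T, T) bool
    scale: str               # "linear" | "original"
    link: str
    x0: float | None = None

    def cell(self, row: str, col: str) -> tuple[float, float, float]:
        a = self.treatments.index(row)
        b = self.treatments.index(col)
        return (self.estimate[a, b], self.lower[a, b], self.upper[a, b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.estimate, index=self.treatments,
                            columns=self.treatments)

    def formatted(self, fmt: str = "{:.2f}") -> pd.DataFrame:
        """League-table strings 'est (lo, hi)' with a '**' significance mark."""
        T = len(self.treatments)
        out = np.empty((T, T), dtype=object)
        for a in range(T):
            for b in range(T):
                if a == b:
                    out[a, b] = self.treatments[a]
                    continue
                s = (f"{fmt.format(self.estimate[a, b])} "
                     f"({fmt.format(self.lower[a, b])}, "
                     f"{fmt.format(self.upper[a, b])})")
                if self.significant[a, b]:
                    s += " **"
                out[a, b] = s
        return pd.DataFrame(out, index=self.treatments,
                            columns=self.treatments)


def _contrast_samples(d_samples: np.ndarray, beta_samples=None,
                      x0: float | None = None,
                      xbar: float | None = None) -> np.ndarray:
    """(S, T, T) per-iteration contrasts of column vs row treatment."""
    d = d_samples[:, None, :] - d_samples[:, :, None]
    if x0 is not None:
        if beta_samples is None:
            raise ValueError("x0 given but the model has no covariate")
        b = beta_samples[:, None, :] - beta_samples[:, :, None]
        d = d + b * (x0 - xbar)
    return d


def relative_effects(d_samples: np.ndarray, treatments: list[str],
                     link: str, scale: str = "linear", *,
                     beta_samples: np.ndarray | None = None,
                     x0: float | None = None,
                     xbar: float | None = None) -> ComparisonTable:
    """Posterior summaries of all pairwise contrasts.

    Parameters
    ----------
    d_samples:
        (S, T) pooled draws of the basic contrasts versus the
        reference, with the reference's identically-zero column first.
    scale:
        ``"linear"`` (link scale) or ``"original"`` — exponentials for
        ratio links, identical for the identity link.
    x0:
        Covariate value (original, non-centered scale) at which to
        evaluate meta-regression contrasts; requires ``beta_samples``
        and ``xbar``.
    """
    if scale not in ("linear", "original"):
        raise ValueError("scale must be 'linear' or 'original'")
    c = _contrast_samples(d_samples, beta_samples, x0, xbar)
    med = np.median(c, axis=0)
    lo = np.quantile(c, 0.025, axis=0)
    hi = np.quantile(c, 0.975, axis=0)
    mean = c.mean(axis=0)
    significant = (lo > 0) | (hi < 0)
    np.fill_diagonal(significant, False)
    if scale == "original" and link in _RATIO_LINKS:
        med, lo, hi = np.exp(med), np.exp(lo), np.exp(hi)
        mean = np.exp(c).mean(axis=0)
    return ComparisonTable(treatments=list(treatments), estimate=med,
                           lower=lo, upper=hi, mean=mean,
                           significant=significant, scale=scale, link=link,
                           x0=x0)


def league_layout(table: ComparisonTable, order: str = "given",
                  rank: "RankResults | None" = None) -> dict:
    """Ordered league table with heat values.

    ``order="sucra"`` permutes rows/columns by descending SUCRA (best
    treatment first); heat value per cell is the signed linear-scale
    point estimate; significance flags ride along for the
    double-asterisk annotation.
    """
    T = len(table.treatments)
    if order == "given":
        perm = list(range(T))
    elif order == "sucra":
        if rank is None:
            raise ValueError("order='sucra' needs RankResults")
        sucra = np.array([rank.sucra[t] for t in table.treatments])
        perm = list(np.argsort(-sucra, kind="stable"))
    else:
        raise ValueError("order must be 'given' or 'sucra'")
    idx = np.ix_(perm, perm)
    heat = table.estimate[idx]
    if table.scale == "original" and table.link in _RATIO_LINKS:
        heat = np.log(heat)
    return {
        "treatments": [table.treatments[p] for p in perm],
        "estimate": table.estimate[idx],
        "lower": table.lower[idx],
        "upper": table.upper[idx],
        "significant": table.significant[idx],
        "heat": heat,
        "order": perm,
    }


@dataclass
class RankResults:
    """Rank probabilities, their cumulative form, and SUCRA values.

    ``prob.loc[t, r]`` is the posterior probability that treatment
    ``t`` occupies rank ``r`` (rank 1 = best under the declared
    direction).  SUCRA_t = mean of the cumulative probabilities over
    ranks 1..T-1: 1 for a treatment certain to be best, 0 for one
    certain to be worst.
    """

    prob: pd.DataFrame       # treatments x ranks
    cumulative: pd.DataFrame
    sucra: pd.Series
    direction: str

    def rankogram_data(self) -> pd.DataFrame:
        df = self.prob.reset_index(names="treatment")
        return df.melt(id_vars="treatment", var_name="rank",
                       value_name="probability")


def rank_statistics(d_samples: np.ndarray, treatments: list[str],
                    direction: str) -> RankResults:
    """Per-iteration ranking of treatments by their contrast vs reference.

    ``direction`` must be explicit: ``"largest-is-best"`` or
    ``"smallest-is-best"`` — outcome semantics (benefit vs harm) are
    not guessed from the data.  Ties are broken by treatment index.
    """
    if direction not in ("largest-is-best", "smallest-is-best"):
        raise ValueError("direction must be 'largest-is-best' or "
                         "'smallest-is-best'")
    S, T = d_samples.shape
    vals = -d_samples if direction == "largest-is-best" else d_samples
    # stable argsort on values => ties resolved by treatment index
    order = np.argsort(vals, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(S)[:, None]
    ranks[rows, order] = np.arange(T)[None, :]  # 0-based rank per treatment
    P = np.zeros((T, T))
    for r in range(T):
        P[:, r] = (ranks == r).mean(axis=0)
    cum = np.cumsum(P, axis=1)
    sucra = cum[:, :T - 1].mean(axis=1) if T > 1 else np.ones(T)
    ranks_idx = pd.Index(np.arange(1, T + 1), name="rank")
    prob = pd.DataFrame(P, index=pd.Index(treatments, name="treatment"),
                        columns=ranks_idx)
    return RankResults(prob=prob,
                       cumulative=pd.DataFrame(cum, index=prob.index,
                                               columns=ranks_idx),
                       sucra=pd.Series(sucra, index=prob.index,
                                       name="sucra"),
                       direction=direction)


def forest_data(d_samples: np.ndarray, treatments: list[str],
                comparator: str, link: str, scale: str = "linear", *,
                beta_samples=None, x0=None, xbar=None) -> pd.DataFrame:
    """Forest-plot rows: each treatment against one comparator."""
    table = relative_effects(d_samples, treatments, link, scale,
                             beta_samples=beta_samples, x0=x0, xbar=xbar)
    a = treatments.index(comparator)
    rows = []
    for b, t in enumerate(treatments):
        if t == comparator:
            continue
        rows.append(dict(treatment=t, comparator=comparator,
                         estimate=table.estimate[a, b],
                         lower=table.lower[a, b], upper=table.upper[a, b],
                         significant=bool(table.significant[a, b]),
                         scale=table.scale,
                         measure=_EFFECT_LABEL.get(link, link)))
    return pd.DataFrame(rows)


def regression_profile(d_samples: np.ndarray, beta_samples: np.ndarray,
                       treatments: list[str], comparator: str,
                       x_grid, xbar: float) -> pd.DataFrame:
    """Relative-effect lines over the covariate range (linear scale).

    For each grid value x (original scale) and treatment t, summarizes
    ``d_(c,t) + beta_(c,t) (x - xbar)`` versus the comparator c by its
    posterior median and central 95% interval.
    """
    if beta_samples is None:
        raise ValueError("regression profiles need a meta-regression model")
    c = treatments.index(comparator)
    x_grid = np.asarray(x_grid, dtype=float)
    rows = []
    for b, t in enumerate(treatments):
        if b == c:
            continue
        dd = d_samples[:, b] - d_samples[:, c]
        bb = beta_samples[:, b] - beta_samples[:, c]
        for x in x_grid:
            v = dd + bb * (x - xbar)
            rows.append(dict(treatment=t, comparator=comparator, x=float(x),
                             estimate=float(np.median(v)),
                             lower=float(np.quantile(v, 0.025)),
                             upper=float(np.quantile(v, 0.975))))
    return pd.DataFrame(rows)
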