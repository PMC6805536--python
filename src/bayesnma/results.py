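"""Fitted-model results: posterior summaries and reporting surfaces."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assessment, reporting
from .sampler import PosteriorSamples

__all__ = ["NMAResults"]


class NMAResults:
    """Posterior results of a fitted :class:`~bayesnma.model.NMAModel`.

    Wraps the raw :class:`~bayesnma.sampler.PosteriorSamples` and
    exposes the decision output — league tables, SUCRA rankings, forest
    rows, meta-regression profiles — together with fit statistics
    (DIC / leverage) and convergence diagnostics.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # -- raw access ---------------------------------------------------
    @property
    def treatments(self) -> list[str]:
        return self.model.network.treatments

    def d_matrix(self) -> np.ndarray:
        """Pooled draws of d_(1,t) for every treatment, shape (S, T).

        The reference column is identically zero.  Only defined for
        consistency models — the unrelated-mean-effects variant has no
        single basic contrast per treatment.
        """
        if self.model.spec.model_type != "consistency":
            raise ValueError("basic contrasts are only defined under the "
                             "consistency model")
        names = [f"d[{t}]" for t in self.treatments[1:]]
        d = self.samples.stacked_matrix(names)
        S = self.samples.n_chains * self.samples.n_kept
        return np.column_stack([np.zeros(S), d])

    def beta_matrix(self) -> np.ndarray | None:
        spec = self.model.spec
        if spec.covariate is None:
            return None
        S = self.samples.n_chains * self.samples.n_kept
        if spec.covariate_prior == "equal":
            b = self.samples.stacked("B")
            mat = np.tile(b[:, None], (1, len(self.treatments) - 1))
        else:
            names = [f"beta[{t}]" for t in self.treatments[1:]]
            mat = self.samples.stacked_matrix(names)
        return np.column_stack([np.zeros(S), mat])

    @property
    def xbar(self) -> float | None:
        return self.model.definition.design.xbar

    # -- summaries ----------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior summary table for the monitored parameters."""
        conv = assessment.convergence(self.samples).table.set_index(
            "parameter")
        rows = []
        for name in self.samples.names:
            x = self.samples.stacked(name)
            rows.append(dict(
                parameter=name, mean=x.mean(), sd=x.std(ddof=1),
                median=np.median(x),
                q2_5=np.quantile(x, 0.025), q97_5=np.quantile(x, 0.975),
                psrf=conv.loc[name, "psrf"], ess=conv.loc[name, "ess"],
            ))
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self) -> str:
        s = self.model.spec
        return (f"<NMAResults {s.family}/{s.link} {s.effects} effects, "
                f"{s.model_type}, {self.samples.n_chains} chains x "
                f"{self.samples.n_kept} kept>")

    # -- reporting ----------------------------------------------------
    def relative_effects(self, scale: str = "linear",
                         x0: float | None = None) -> reporting.ComparisonTable:
        return reporting.relative_effects(
            self.d_matrix(), self.treatments, self.model.spec.link, scale,
            beta_samples=self.beta_matrix(), x0=x0, xbar=self.xbar)

    def league_table(self, scale: str = "linear", order: str = "given",
                     direction: str | None = None,
                     x0: float | None = None):
        """League table; ``order="sucra"`` needs a ranking direction."""
        table = self.relative_effects(scale=scale, x0=x0)
        rank = None
        if order == "sucra":
            rank = self.rank(direction, x0=x0)
        return reporting.league_layout(table, order=order, rank=rank)

    def rank(self, direction: str | None,
             x0: float | None = None) -> reporting.RankResults:
        """Rank probabilities / SUCRA; the direction must be explicit."""
        if direction is None:
            raise ValueError("ranking needs an explicit direction "
                             "('largest-is-best' or 'smallest-is-best'); "
                             "outcome semantics are not inferred")
        d = self.d_matrix()
        if x0 is not None:
            beta = self.beta_matrix()
            if beta is None:
                raise ValueError("x0 given but the model has no covariate")
            d = d + beta * (x0 - self.xbar)
        return reporting.rank_statistics(d, self.treatments, direction)

    def sucra(self, direction: str | None,
              x0: float | None = None) -> pd.Series:
        return self.rank(direction, x0=x0).sucra

    def forest(self, comparator: str, scale: str = "linear",
               x0: float | None = None) -> pd.DataFrame:
        return reporting.forest_data(
            self.d_matrix(), self.treatments, comparator,
            self.model.spec.link, scale,
            beta_samples=self.beta_matrix(), x0=x0, xbar=self.xbar)

    def regression_profile(self, comparator: str,
                           x_grid=None) -> pd.DataFrame:
        beta = self.beta_matrix()
        if beta is None:
            raise ValueError("regression profiles need a meta-regression "
                             "model")
        if x_grid is None:
            x = self.model.definition.design.x
            x_grid = np.linspace(float(x.min()), float(x.max()), 25)
        return reporting.regression_profile(
            self.d_matrix(), beta, self.treatments, comparator,
            x_grid, self.xbar)

    # -- assessment ---------------------------------------------------
    def fit_statistics(self) -> assessment.FitStats:
        return assessment.fit_statistics(self.samples, self.model.network)

    def convergence(self) -> assessment.ConvergenceReport:
        return assessment.convergence(self.samples)

    def compare_deviance(self, other: "NMAResults") -> dict:
        """Per-arm deviance comparison (e.g. consistency vs inconsistency)."""
        return assessment.compare_deviance(self.fit_statistics(),
                                           other.fit_statistics())
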