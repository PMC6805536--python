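"""Synthetic evidence networks with known truth, plus a toy dataset.

The generator draws study baselines and random study-level contrasts
from the exact generative model the sampler targets — compound-symmetry
multivariate-normal contrasts around the true ``d`` vector, the same
link functions and linear predictor (including the cloglog follow-up
offset and log-link truncation), and the matching family distribution
for arm responses.  That makes it the ground-truth oracle for
parameter-recovery tests: the fitted posterior should cover the planted
parameters.

It emulates arm-level aggregate trial data.  It does not emulate
features of real evidence bases such as selective reporting, covariate
imbalance correlated with design, or non-constant hazards, so recovery
here demonstrates correctness of the machinery, not robustness to those
violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import ArmRecord, NetworkData, prepare_network
from .model import inverse_link, linear_predictor

__all__ = ["FixtureConfig", "generate_synthetic_network",
           "load_toy_diabetes"]


@dataclass(frozen=True)
class FixtureConfig:
    """Generating parameters of a synthetic network.

    ``d`` is the true contrast vector versus treatment 1 (``d[0]`` must
    be 0); ``sigma`` the between-study heterogeneity SD (0 = fixed
    effects truth); ``arms_per_study`` either a fixed arm count or a
    sequence of probabilities for 2, 3, ... arms.
    """

    T: int
    M: int
    family: str = "dichotomous"      # network family
    link: str = "logit"
    d: Sequence[float] = (0.0, 0.0)
    sigma: float = 0.0
    beta: Sequence[float] | None = None
    covariate_mean: float = 0.0
    covariate_sd: float = 1.0
    baseline_mean: float = -1.0      # mu_i ~ Normal(mean, sd) on link scale
    baseline_sd: float = 0.3
    n_per_arm: int = 200             # dichotomous sample size
    se_per_arm: float = 0.1          # continuous standard error
    person_time: float = 100.0       # count exposure
    follow_up: float | None = None   # study follow-up (cloglog)
    arms_per_study: int | Sequence[float] = 2
    seed: int = 0

    def validate(self) -> None:
        if len(self.d) != self.T:
            raise ValueError("d must have one entry per treatment")
        if self.d[0] != 0.0:
            raise ValueError("d[0] (the reference's own contrast) must be 0")
        if self.T < 2 or self.M < 1:
            raise ValueError("need T >= 2 treatments and M >= 1 studies")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.link == "cloglog" and self.follow_up is None:
            raise ValueError("cloglog truth needs a follow-up time")
        if self.family == "dichotomous" and self.link == "log":
            # error out when truncation would distort > 1% of arms
            sd = np.sqrt(self.baseline_sd ** 2 + self.sigma ** 2)
            worst = max(self.baseline_mean + di for di in self.d)
            p_pos = stats.norm.sf(0.0, loc=worst, scale=max(sd, 1e-12))
            if p_pos > 0.01:
                raise ValueError(
                    "configuration implies theta > 0 (probability "
                    f"{p_pos:.3f} > 1%) under the log link; lower the "
                    "baseline mean or effects")


_COMPOUND_RHO = 0.5


def _draw_delta(rng, d_contrasts: np.ndarray, sigma: float) -> np.ndarray:
    m = d_contrasts.size
    if sigma == 0.0 or m == 0:
        return d_contrasts.copy()
    cov = sigma ** 2 * ((1 - _COMPOUND_RHO) * np.eye(m)
                        + _COMPOUND_RHO * np.ones((m, m)))
    return rng.multivariate_normal(d_contrasts, cov, method="cholesky")


def generate_synthetic_network(cfg: FixtureConfig) -> tuple[NetworkData, dict]:
    """Generate a network and its truth record, deterministically by seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = [f"T{t + 1}" for t in range(cfg.T)]
    d = np.asarray(cfg.d, dtype=float)
    beta = np.asarray(cfg.beta, dtype=float) if cfg.beta is not None else None

    rows = []
    truth_studies = []
    for i in range(cfg.M):
        if isinstance(cfg.arms_per_study, int):
            a = cfg.arms_per_study
        else:
            probs = np.asarray(cfg.arms_per_study, dtype=float)
            a = int(rng.choice(np.arange(2, 2 + probs.size),
                               p=probs / probs.sum()))
        a = min(a, cfg.T)
        trts = np.sort(rng.choice(cfg.T, size=a, replace=False))
        mu_i = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
        d_i = d[trts[1:]] - d[trts[0]]
        delta = np.concatenate(([0.0], _draw_delta(rng, d_i, cfg.sigma)))
        x_i = (rng.normal(cfg.covariate_mean, cfg.covariate_sd, size=a)
               if beta is not None else None)
        truth_studies.append(dict(study=f"S{i + 1:03d}",
                                  treatments=[labels[t] for t in trts],
                                  mu=float(mu_i), delta=delta.tolist()))
        for k, t in enumerate(trts):
            bc = None
            if beta is not None:
                bc = (beta[t] - beta[trts[0]])
            theta = linear_predictor(
                mu_i, delta[k],
                link=cfg.link,
                family={"dichotomous": "binomial", "count": "poisson",
                        "continuous": "normal"}[cfg.family],
                f=cfg.follow_up,
                beta_contrast=bc,
                x=x_i[k] if x_i is not None else None,
                xbar=cfg.covariate_mean if beta is not None else None)
            phi = float(inverse_link(theta, cfg.link))
            row = {"study": f"S{i + 1:03d}", "treatment": labels[t]}
            if cfg.family == "dichotomous":
                row["events"] = int(rng.binomial(cfg.n_per_arm, phi))
                row["sample_size"] = cfg.n_per_arm
                if cfg.follow_up is not None:
                    row["follow_up"] = cfg.follow_up
            elif cfg.family == "count":
                row["events"] = int(rng.poisson(cfg.person_time * phi))
                row["person_time"] = cfg.person_time
            else:
                row["mean"] = float(rng.normal(phi, cfg.se_per_arm))
                row["std_err"] = cfg.se_per_arm
            if x_i is not None:
                row["age"] = float(x_i[k])
            rows.append(row)

    nd = prepare_network(
        rows, cfg.family, reference=labels[0],
        covariate_cols=("age",) if beta is not None else ())
    truth = {
        "d": {labels[t]: float(d[t]) for t in range(cfg.T)},
        "sigma": cfg.sigma,
        "beta": ({labels[t]: float(beta[t]) for t in range(cfg.T)}
                 if beta is not None else None),
        "xbar": cfg.covariate_mean if beta is not None else None,
        "link": cfg.link,
        "studies": truth_studies,
        "seed": cfg.seed,
    }
    return nd, truth


# ---------------------------------------------------------------------------
# toy dataset: the printed rows of the antihypertensive/diabetes network


_TOY_ROWS = [
    # study, treatment, n, events, age mean, age sd
    ("MRC-E", "Diuretic", 1081, 43, 60.7, 14.3),
    ("MRC-E", "Placebo", 2213, 34, 59.2, 13.1),
    ("MRC-E", "blocker", 1102, 37, 60.2, 14.0),
    ("EWPH", "Diuretic", 416, 29, 59.0, 15.2),
    ("EWPH", "Placebo", 424, 20, 57.0, 14.8),
    ("VALUE", "CCB", 5074, 845, 56.4, 13.1),
    ("VALUE", "ARB", 5087, 690, 57.8, 13.0),
]


def load_toy_diabetes() -> NetworkData:
    """Three-study excerpt of the six-treatment antihypertensive network.

    Seven arms from the 22-trial network of trials of antihypertensive
    treatments and new-onset diabetes: the three-arm MRC-E trial
    (diuretic, placebo, beta-blocker), the two-arm EWPH trial and the
    two-arm VALUE trial (calcium-channel blocker vs angiotensin-receptor
    blocker), with mean participant age (and SD) as an arm-level
    covariate.  Dichotomous outcome: new diabetes cases / arm size.
    """
    rows = [dict(study=s, treatment=t, sample_size=n, events=r,
                 age=age, age_sd=sd)
            for s, t, n, r, age, sd in _TOY_ROWS]
    return prepare_network(rows, "dichotomous",
                           covariate_cols=("age", "age_sd"),
                           reference="Diuretic")
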