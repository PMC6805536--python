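"""Contrast-based Bayesian NMA models.

The model is an arm-level generalized linear model.  Arm ``k`` of study
``i`` received treatment ``t_ik`` from an indexed set ``1..T`` (index 1
is the reference).  The aggregate response ``R_ik`` follows a family
distribution with latent parameter ``phi_ik``; a link ``g`` maps it to a
linear predictor

    theta_ik = mu_i + delta_ik  (+ beta_(t_i1,t_ik) * (x_ik - xbar)),

where ``mu_i`` is the effect of the study's own control arm and
``delta_ik`` the relative effect of arm ``k`` versus that control arm
(``delta_i1 = 0``).  Two exceptions: the binomial/cloglog model adds the
log follow-up time, ``theta_ik = log(f_i) + mu_i + delta_ik`` (so that
contrasts are log hazard ratios under constant rates), and the
binomial/log model truncates ``theta_ik = min(mu_i + delta_ik, -1e-16)``
so event probabilities stay inside (0, 1).

Under random effects, the within-study contrast vector ``delta_i`` is
multivariate normal around the mean contrasts ``d_i`` with the
compound-symmetry covariance (variance ``sigma^2``, covariance
``0.5 sigma^2``), which makes multi-arm trials internally coherent.
Under consistency, every mean contrast derives from the basic
parameters through transitivity, ``d_(a,b) = d_(1,b) - d_(1,a)``; the
inconsistency (unrelated-mean-effects) variant instead places an
independent parameter on each directly compared pair, and the fit of
the two models is compared to screen for disagreement between direct
and indirect evidence.

Default priors are vague and data-scaled: with ``u`` the largest
absolute single-trial maximum-likelihood treatment difference on the
link scale, ``mu_i`` and the ``d``'s get Normal(0, (15u)^2) priors
(except the binomial/log baseline, where ``mu_i = log(p_i)`` with
``p_i ~ U(0,1)``), ``sigma ~ U(0, u)``, and regression coefficients get
heavy-tailed t(0, u^2, df=1) priors in one of three structures
(unrelated / exchangeable / equal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import log
from typing import Any, Mapping

import numpy as np

from .data import NetworkData

__all__ = [
    "ModelSpec", "ModelDefinition", "DesignArrays", "NMAModel",
    "compute_reference_scale", "default_priors", "linear_predictor",
    "conditional_re_moments", "build_model", "inverse_link",
    "arm_loglik", "FAMILY_LINKS",
]

# (family, link) pairs supported, mirroring the outcome-type table
FAMILY_LINKS = {
    ("normal", "identity"),
    ("binomial", "logit"),
    ("binomial", "log"),
    ("binomial", "cloglog"),
    ("poisson", "log"),
}

_DATA_FAMILY = {"continuous": "normal", "dichotomous": "binomial",
                "count": "poisson"}
_DEFAULT_LINK = {"normal": "identity", "binomial": "logit", "poisson": "log"}

LOG_TRUNCATION = -1e-16  # upper bound on theta under the binomial/log model


@dataclass(frozen=True)
class ModelSpec:
    """What model to fit: family/link, effects, consistency, regression."""

    family: str
    link: str
    effects: str = "random"                # "fixed" | "random"
    model_type: str = "consistency"        # "consistency" | "inconsistency"
    covariate: str | None = None
    covariate_prior: str = "unrelated"     # "unrelated"|"exchangeable"|"equal"
    priors: Mapping[str, Any] = field(default_factory=dict)

    def validate(self, nd: NetworkData) -> None:
        if (self.family, self.link) not in FAMILY_LINKS:
            raise ValueError(f"unsupported family/link pair "
                             f"({self.family}, {self.link})")
        if _DATA_FAMILY[nd.family] != self.family:
            raise ValueError(f"family {self.family!r} does not match the "
                             f"network's {nd.family} outcome")
        if self.effects not in ("fixed", "random"):
            raise ValueError("effects must be 'fixed' or 'random'")
        if self.model_type not in ("consistency", "inconsistency"):
            raise ValueError("model_type must be 'consistency' or "
                             "'inconsistency'")
        if self.link == "cloglog" and not nd.has_follow_up():
            raise ValueError("the cloglog link needs a follow-up time on "
                             "every study")
        if self.covariate is not None:
            if self.model_type != "consistency":
                raise ValueError("meta-regression requires a consistency "
                                 "model")
            if self.covariate_prior not in ("unrelated", "exchangeable",
                                            "equal"):
                raise ValueError("unknown coefficient prior structure "
                                 f"{self.covariate_prior!r}")
            missing = [a for a in nd.arms
                       if self.covariate not in a.covariates]
            if missing:
                a = missing[0]
                raise ValueError(
                    f"covariate {self.covariate!r} missing on arm "
                    f"({a.study}, {a.treatment}); meta-regression needs it "
                    "on every arm")


@dataclass
class DesignArrays:
    """Flat numpy views of the network used by the sampler."""

    study_of_arm: np.ndarray     # (n_arms,) int, 0-based study index
    trt_of_arm: np.ndarray       # (n_arms,) int, 0-based treatment index
    arm_pos: np.ndarray          # (n_arms,) int, 0 = control arm
    control_trt: np.ndarray      # (M,) treatment index of each control arm
    a: np.ndarray                # (M,) arms per study
    r: np.ndarray | None = None
    n: np.ndarray | None = None
    y: np.ndarray | None = None
    se: np.ndarray | None = None
    e: np.ndarray | None = None
    f: np.ndarray | None = None  # (M,) follow-up per study
    x: np.ndarray | None = None  # (n_arms,) covariate
    xbar: float | None = None

    @property
    def n_arms(self) -> int:
        return self.study_of_arm.size

    @property
    def n_studies(self) -> int:
        return self.a.size


def build_design(nd: NetworkData, covariate: str | None = None) -> DesignArrays:
    study_of_arm, trt_of_arm, arm_pos = [], [], []
    control_trt, a_sizes, f = [], [], []
    payload: dict[str, list] = {k: [] for k in ("r", "n", "y", "se", "e")}
    x: list[float] = []
    for si, s in enumerate(nd.studies):
        arms = nd.study_arms(s)
        a_sizes.append(len(arms))
        control_trt.append(nd.treatment_index(arms[0].treatment))
        f.append(arms[0].follow_up if arms[0].follow_up is not None else np.nan)
        for pos, arm in enumerate(arms):
            study_of_arm.append(si)
            trt_of_arm.append(nd.treatment_index(arm.treatment))
            arm_pos.append(pos)
            if nd.family == "dichotomous":
                payload["r"].append(arm.events)
                payload["n"].append(arm.sample_size)
            elif nd.family == "count":
                payload["r"].append(arm.events)
                payload["e"].append(arm.person_time)
            else:
                payload["y"].append(arm.mean)
                payload["se"].append(arm.std_err)
            if covariate is not None:
                x.append(arm.covariates[covariate])
    def arr(v, dtype=float):
        return np.asarray(v, dtype=dtype) if v else None
    xa = np.asarray(x, dtype=float) if covariate is not None else None
    return DesignArrays(
        study_of_arm=np.asarray(study_of_arm, dtype=int),
        trt_of_arm=np.asarray(trt_of_arm, dtype=int),
        arm_pos=np.asarray(arm_pos, dtype=int),
        control_trt=np.asarray(control_trt, dtype=int),
        a=np.asarray(a_sizes, dtype=int),
        r=arr(payload["r"]), n=arr(payload["n"]), y=arr(payload["y"]),
        se=arr(payload["se"]), e=arr(payload["e"]),
        f=np.asarray(f, dtype=float),
        x=xa, xbar=float(xa.mean()) if xa is not None else None,
    )


# ---------------------------------------------------------------------------
# reference scale u


def _pair_mle(arm_a, arm_b, link: str, family: str) -> float:
    """Single-trial MLE of the b-vs-a treatment difference on the link scale."""
    if family == "normal":
        return arm_b.mean - arm_a.mean
    if family == "poisson":
        r1, e1 = float(arm_a.events), arm_a.person_time
        r2, e2 = float(arm_b.events), arm_b.person_time
        if min(r1, r2) == 0:
            r1, r2 = r1 + 0.5, r2 + 0.5
        return log(r2 / e2) - log(r1 / e1)
    r1, n1 = float(arm_a.events), float(arm_a.sample_size)
    r2, n2 = float(arm_b.events), float(arm_b.sample_size)
    if min(r1, n1 - r1, r2, n2 - r2) == 0:
        r1, r2, n1, n2 = r1 + 0.5, r2 + 0.5, n1 + 1.0, n2 + 1.0
    p1, p2 = r1 / n1, r2 / n2
    if link == "logit":
        return log(p2 / (1 - p2)) - log(p1 / (1 - p1))
    if link == "log":
        return log(p2) - log(p1)
    if link == "cloglog":
        return log(-np.log1p(-p2)) - log(-np.log1p(-p1))
    raise ValueError(f"unknown link {link!r}")


def compute_reference_scale(nd: NetworkData, link: str) -> float:
    """Largest absolute single-trial MLE treatment difference (``u``).

    This data-driven scale calibrates the vague priors: prior standard
    deviations 15u on baselines and contrasts, U(0, u) on sigma.  Zero
    cells are handled with a 0.5 continuity correction on all cells of
    the affected two-by-two.  If every within-study difference is zero
    the scale degenerates; u falls back to 1 with a warning.
    """
    family = _DATA_FAMILY[nd.family]
    u = 0.0
    for s in nd.studies:
        arms = nd.study_arms(s)
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                u = max(u, abs(_pair_mle(arms[i], arms[j], link, family)))
    if u == 0.0:
        warnings.warn("all single-trial treatment differences are zero; "
                      "falling back to reference scale u = 1")
        u = 1.0
    return u


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSet:
    """Hyperparameters of the (possibly overridden) prior set."""

    u: float
    mu_sd: float                  # Normal(0, mu_sd^2) on baselines
    d_sd: float                   # Normal(0, d_sd^2) on contrasts
    sigma_upper: float | None     # U(0, sigma_upper) on sigma; None for FE
    beta_scale: float | None      # t(0, beta_scale^2, df=1) scale
    gamma_upper: float | None     # U(0, gamma_upper) on the exchangeable sd
    mu_log_baseline: bool         # binomial/log: p_i ~ U(0,1) instead

    def as_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)


def default_priors(nd: NetworkData, spec: ModelSpec,
                   u: float | None = None) -> PriorSet:
    """The vague data-scaled prior set (honouring ``spec.priors`` overrides)."""
    if u is None:
        u = compute_reference_scale(nd, spec.link)
    ov = dict(spec.priors)
    for k, v in ov.items():
        if v is not None and not np.isfinite(v):
            raise ValueError(f"prior override {k}={v!r} is not finite")
    ps = PriorSet(
        u=u,
        mu_sd=ov.get("mu_sd", 15.0 * u),
        d_sd=ov.get("d_sd", 15.0 * u),
        sigma_upper=(ov.get("sigma_upper", u)
                     if spec.effects == "random" else None),
        beta_scale=(ov.get("beta_scale", u)
                    if spec.covariate is not None else None),
        gamma_upper=(ov.get("gamma_upper", u)
                     if spec.covariate is not None
                     and spec.covariate_prior == "exchangeable" else None),
        mu_log_baseline=(spec.family == "binomial" and spec.link == "log"),
    )
    return ps


# ---------------------------------------------------------------------------
# linear predictor and likelihood


def linear_predictor(mu, delta, *, link: str, family: str,
                     f=None, beta_contrast=None, x=None,
                     xbar: float | None = None):
    """theta_ik from its components (vectorized).

    ``mu`` and ``delta`` broadcast; the cloglog link adds ``log(f)``
    (study follow-up, must be positive); the binomial/log model
    truncates at -1e-16 so probabilities stay below 1; meta-regression
    adds ``beta_contrast * (x - xbar)``.
    """
    theta = np.asarray(mu, dtype=float) + np.asarray(delta, dtype=float)
    if beta_contrast is not None:
        theta = theta + np.asarray(beta_contrast) * (np.asarray(x) - xbar)
    if family == "binomial" and link == "cloglog":
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("cloglog follow-up times must be positive")
        theta = theta + np.log(f)
    if family == "binomial" and link == "log":
        theta = np.minimum(theta, LOG_TRUNCATION)
    return theta


def inverse_link(theta, link: str):
    """phi = g^{-1}(theta)."""
    theta = np.asarray(theta, dtype=float)
    if link == "identity":
        return theta
    if link == "logit":
        return 1.0 / (1.0 + np.exp(-theta))
    if link == "log":
        return np.exp(theta)
    if link == "cloglog":
        return -np.expm1(-np.exp(np.minimum(theta, 700.0)))
    raise ValueError(f"unknown link {link!r}")


def arm_loglik(theta, design: DesignArrays, family: str, link: str):
    """Per-arm log-likelihood contributions (constants dropped).

    Written against theta directly for numerical stability:
    logit uses ``r*theta - n*log(1+e^theta)``; the log link uses
    ``log(1 - e^theta)`` via expm1 (theta <= -1e-16 by truncation);
    cloglog works on ``e^theta`` with a clipped exponent.
    """
    theta = np.asarray(theta, dtype=float)
    if family == "normal":
        return -0.5 * ((design.y - theta) / design.se) ** 2
    if family == "poisson":
        return design.r * theta - design.e * np.exp(np.minimum(theta, 700.0))
    r, n = design.r, design.n
    if link == "logit":
        return r * theta - n * np.logaddexp(0.0, theta)
    if link == "log":
        return r * theta + (n - r) * np.log(-np.expm1(theta))
    if link == "cloglog":
        et = np.exp(np.minimum(theta, 700.0))
        # log(phi) = log(1 - e^{-e^theta}); log(1-phi) = -e^theta
        logphi = np.log(np.maximum(-np.expm1(-et), 1e-300))
        return r * logphi - (n - r) * et
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# random-effects structure


def conditional_re_moments(d_contrasts, delta_prev, sigma: float, k: int):
    """Moments of ``delta_ik`` given the study's earlier contrasts.

    The joint compound-symmetry MVN on ``(delta_i2..delta_i,a)`` factors
    into a chain of univariate normals; for arm position ``k`` (2-based)

        mean = d_(t_i1,t_ik) + (1/(k-1)) * sum_{j<k} (delta_ij - d_(t_i1,t_ij))
        var  = k / (2(k-1)) * sigma^2,

    with the (empty-sum) ``k = 2`` case reducing to mean ``d_(t_i1,t_i2)``
    and variance ``sigma^2``.

    Parameters
    ----------
    d_contrasts:
        Mean contrasts ``(d_(t_i1,t_i2), ..., d_(t_i1,t_ia))``.
    delta_prev:
        Already-drawn ``delta_i2 .. delta_i,k-1`` (length ``k - 2``).
    """
    if k < 2:
        raise ValueError("arm position k must be >= 2")
    d = np.asarray(d_contrasts, dtype=float)
    prev = np.asarray(delta_prev, dtype=float)
    if prev.size != k - 2:
        raise ValueError(f"expected {k - 2} previously sampled contrasts, "
                         f"got {prev.size}")
    # j = 1 term is identically zero (delta_i1 = 0, d_(t,t) = 0)
    mean = d[k - 2] + (np.sum(prev - d[:k - 2]) / (k - 1) if k > 2 else 0.0)
    var = k / (2.0 * (k - 1)) * sigma ** 2
    return float(mean), float(var)


def sample_delta_conditional(d_contrasts, sigma: float, rng,
                             size: int = 1) -> np.ndarray:
    """Draw delta vectors through the sequential conditional chain.

    Equivalent in distribution to one MVN(d, Sigma) draw with the
    compound-symmetry Sigma; exposed for tests and simulation.
    Returns an array of shape (size, len(d_contrasts)).
    """
    d = np.asarray(d_contrasts, dtype=float)
    m = d.size
    out = np.empty((size, m))
    for j in range(m):
        k = j + 2
        var = k / (2.0 * (k - 1)) * sigma ** 2
        if j == 0:
            mean = np.full(size, d[0])
        else:
            mean = d[j] + (out[:, :j] - d[:j]).sum(axis=1) / (k - 1)
        out[:, j] = mean + np.sqrt(var) * rng.standard_normal(size)
    return out


# ---------------------------------------------------------------------------
# model definition


@dataclass
class ModelDefinition:
    """A fully assembled model: data views, parameters and priors."""

    nd: NetworkData
    spec: ModelSpec
    design: DesignArrays
    priors: PriorSet
    d_names: list[str]
    # inconsistency bookkeeping: per-arm index/sign into the d vector
    pair_index_of_arm: np.ndarray | None = None
    pair_sign_of_arm: np.ndarray | None = None

    @property
    def n_d(self) -> int:
        return len(self.d_names)

    def parameter_names(self) -> list[str]:
        names = list(self.d_names)
        if self.spec.effects == "random":
            names.append("sigma")
        if self.spec.covariate is not None:
            T = self.nd.n_treatments
            names += [f"beta[{t}]" for t in self.nd.treatments[1:]]
            if self.spec.covariate_prior == "exchangeable":
                names += ["b", "gamma"]
        names += [f"mu[{s}]" for s in self.nd.studies]
        return names

    def contrast_of_arm(self, d: np.ndarray) -> np.ndarray:
        """Per-arm mean contrast d_(t_i1, t_ik) from the d parameter vector."""
        des = self.design
        if self.spec.model_type == "consistency":
            d0 = np.concatenate(([0.0], d))
            return d0[des.trt_of_arm] - d0[des.control_trt[des.study_of_arm]]
        out = np.zeros(des.n_arms)
        nc = des.arm_pos > 0
        out[nc] = self.pair_sign_of_arm[nc] * d[self.pair_index_of_arm[nc]]
        return out

    def beta_contrast_of_arm(self, beta: np.ndarray) -> np.ndarray:
        des = self.design
        b0 = np.concatenate(([0.0], beta))
        return b0[des.trt_of_arm] - b0[des.control_trt[des.study_of_arm]]


def direct_pairs(nd: NetworkData) -> list[tuple[int, int]]:
    """Sorted 0-based treatment-index pairs with direct evidence."""
    pairs = set()
    for s in nd.studies:
        idx = sorted(nd.treatment_index(a.treatment) for a in nd.study_arms(s))
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                pairs.add((idx[i], idx[j]))
    return sorted(pairs)


def build_model(nd: NetworkData, spec: ModelSpec,
                u: float | None = None) -> ModelDefinition:
    """Assemble likelihood, linear predictors, priors and parameter graph."""
    spec.validate(nd)
    design = build_design(nd, spec.covariate)
    priors = default_priors(nd, spec, u=u)
    trts = nd.treatments
    if spec.model_type == "consistency":
        d_names = [f"d[{t}]" for t in trts[1:]]
        pair_idx = pair_sign = None
    else:
        pairs = direct_pairs(nd)
        lookup = {p: k for k, p in enumerate(pairs)}
        d_names = [f"d[{trts[a]}|{trts[b]}]" for a, b in pairs]
        pair_idx = np.zeros(design.n_arms, dtype=int)
        pair_sign = np.zeros(design.n_arms)
        for arm in range(design.n_arms):
            if design.arm_pos[arm] == 0:
                continue
            c = design.control_trt[design.study_of_arm[arm]]
            t = design.trt_of_arm[arm]
            a, b = (c, t) if c < t else (t, c)
            pair_idx[arm] = lookup[(a, b)]
            pair_sign[arm] = 1.0 if c < t else -1.0
    return ModelDefinition(nd=nd, spec=spec, design=design, priors=priors,
                           d_names=d_names, pair_index_of_arm=pair_idx,
                           pair_sign_of_arm=pair_sign)


# ---------------------------------------------------------------------------
# user-facing Model class (statsmodels-style)


class NMAModel:
    """Bayesian network meta-analysis model over an evidence network.

    Parameters
    ----------
    network:
        A prepared :class:`~bayesnma.data.NetworkData`.
    link:
        Link function; defaults to the family's canonical choice
        (identity / logit / log).
    effects:
        ``"random"`` (default) or ``"fixed"``.
    model_type:
        ``"consistency"`` (default) or ``"inconsistency"`` — the
        unrelated-mean-effects variant used to screen for disagreement
        between direct and indirect evidence.
    covariate / covariate_prior:
        Enable network meta-regression on an arm-level covariate with
        one of the three coefficient prior structures.
    priors:
        Optional hyperparameter overrides (``mu_sd``, ``d_sd``,
        ``sigma_upper``, ``beta_scale``, ``gamma_upper``).

    Examples
    --------
    >>> model = NMAModel(network, link="logit", effects="random")
    >>> res = model.fit(n_iter=5000, n_chains=2, seed=7)
    >>> res.summary()           # doctest: +SKIP
    """

    def __init__(self, network: NetworkData, *, link: str | None = None,
                 effects: str = "random", model_type: str = "consistency",
                 covariate: str | None = None,
                 covariate_prior: str = "unrelated",
                 priors: Mapping[str, Any] | None = None):
        family = _DATA_FAMILY[network.family]
        spec = ModelSpec(
            family=family,
            link=link if link is not None else _DEFAULT_LINK[family],
            effects=effects, model_type=model_type, covariate=covariate,
            covariate_prior=covariate_prior, priors=priors or {},
        )
        self.network = network
        self.spec = spec
        self.definition = build_model(network, spec)

    @classmethod
    def from_dataframe(cls, df, family: str, *, study_col: str = "study",
                       treatment_col: str = "treatment",
                       columns: Mapping[str, str] | None = None,
                       covariate_cols=(), reference: str | None = None,
                       **kwargs) -> "NMAModel":
        """Build directly from a long-format DataFrame of arm rows."""
        from .data import prepare_network
        nd = prepare_network(df.to_dict(orient="records"), family,
                             study_col=study_col, treatment_col=treatment_col,
                             columns=columns, covariate_cols=covariate_cols,
                             reference=reference)
        return cls(nd, **kwargs)

    @property
    def reference_scale(self) -> float:
        return self.definition.priors.u

    def fit(self, *, n_adapt: int = 1000, n_burnin: int = 2000,
            n_iter: int = 5000, n_chains: int = 2, seed: int = 0,
            monitors=None, monitor_phi: bool = True,
            prior_only: bool = False):
        """Run the MCMC and return an :class:`~bayesnma.results.NMAResults`."""
        from .sampler import McmcSettings, run_nma
        from .results import NMAResults
        settings = McmcSettings(n_adapt=n_adapt, n_burnin=n_burnin,
                                n_iter=n_iter, n_chains=n_chains, seed=seed,
                                monitors=monitors, monitor_phi=monitor_phi)
        samples = run_nma(self.definition, settings, prior_only=prior_only)
        return NMAResults(self, samples)
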