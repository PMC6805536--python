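"""Model assessment: residual deviance, leverage, DIC, convergence.

The fit of a Bayesian NMA is judged through per-arm residual deviance
contributions against the saturated model.  Averaging the deviance over
the posterior gives ``Dbar``; evaluating it at the posterior-mean
fitted values gives the plug-in deviance; their difference per arm is
the *leverage*, whose total is the effective number of parameters
``pD``; and ``DIC = Dbar + pD`` is the model-selection criterion used
to pick between fixed/random effects and consistency/inconsistency
variants.  Convergence is reported per monitored parameter through the
Gelman–Rubin potential scale reduction factor and an
autocorrelation-based effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import NetworkData
from .model import build_design
from .sampler import PosteriorSamples

__all__ = ["FitStats", "ConvergenceReport", "residual_deviance",
           "fit_statistics", "convergence", "compare_deviance",
           "gelman_rubin", "effective_sample_size"]


@dataclass
class FitStats:
    """Per-arm deviance/leverage and the aggregate fit criteria.

    ``plug_in`` convention: the plug-in deviance is evaluated at the
    posterior mean of the *fitted values* ``phi_ik``, not at the
    posterior mean of the underlying parameters.
    """

    dev_bar: np.ndarray       # posterior mean deviance per arm
    dev_plugin: np.ndarray    # deviance at posterior-mean phi per arm
    leverage: np.ndarray      # dev_bar - dev_plugin per arm
    Dbar: float
    pD: float
    DIC: float
    arms: pd.DataFrame        # study/treatment labels + per-arm stats
    plug_in: str = "posterior-mean fitted values"

    def leverage_plot_data(self) -> pd.DataFrame:
        """Points and parabola levels of the leverage plot.

        x = sign(observed - fitted) * sqrt(dev_bar), y = leverage; the
        usual reference bands are the parabolas x^2 + y = c, c = 1..3.
        """
        return self.arms[["study", "treatment", "x", "leverage"]].copy()


def residual_deviance(observed: dict, phi, family: str) -> np.ndarray:
    """Saturated-model deviance contributions per arm.

    Parameters
    ----------
    observed:
        Arrays keyed by payload: ``r``/``n`` (binomial), ``r``/``e``
        (poisson), ``y``/``se`` (normal).
    phi:
        Fitted values on the natural scale; may broadcast over a
        leading sample dimension.

    Notes
    -----
    binomial: ``2[r ln(r/rhat) + (n-r) ln((n-r)/(n-rhat))]`` with
    ``rhat = n*phi``; poisson: ``2[(rhat - r) + r ln(r/rhat)]`` with
    ``rhat = e*phi``; normal: ``((y - phi)/se)^2``.  Zero-count terms
    contribute zero.
    """
    phi = np.asarray(phi, dtype=float)
    if family == "binomial":
        if np.any(phi <= 0) or np.any(phi >= 1):
            raise ValueError("binomial fitted values must lie in (0, 1)")
        r = np.asarray(observed["r"], dtype=float)
        n = np.asarray(observed["n"], dtype=float)
        rhat = n * phi
        t1 = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0) / rhat), 0.0)
        nr = n - r
        t2 = np.where(nr > 0,
                      nr * np.log(np.where(nr > 0, nr, 1.0) / (n - rhat)),
                      0.0)
        return 2.0 * (t1 + t2)
    if family == "poisson":
        if np.any(phi <= 0):
            raise ValueError("poisson fitted rates must be positive")
        r = np.asarray(observed["r"], dtype=float)
        e = np.asarray(observed["e"], dtype=float)
        rhat = e * phi
        t = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0) / rhat), 0.0)
        return 2.0 * ((rhat - r) + t)
    if family == "normal":
        y = np.asarray(observed["y"], dtype=float)
        se = np.asarray(observed["se"], dtype=float)
        return ((y - phi) / se) ** 2
    raise ValueError(f"unknown family {family!r}")


def _observed_payload(nd: NetworkData):
    des = build_design(nd)
    if nd.family == "dichotomous":
        return {"r": des.r, "n": des.n}, "binomial", des
    if nd.family == "count":
        return {"r": des.r, "e": des.e}, "poisson", des
    return {"y": des.y, "se": des.se}, "normal", des


def fit_statistics(samples: PosteriorSamples, nd: NetworkData) -> FitStats:
    """Compute Dbar, pD (total leverage) and DIC from monitored phi."""
    if samples.phi is None:
        raise ValueError("fit statistics need fitted values: rerun with "
                         "monitor_phi=True")
    observed, family, des = _observed_payload(nd)
    phi = samples.phi.reshape(-1, samples.phi.shape[-1])  # (S, n_arms)
    dev = residual_deviance(observed, phi, family)
    dev_bar = dev.mean(axis=0)
    phi_hat = phi.mean(axis=0)
    dev_plug = residual_deviance(observed, phi_hat, family)
    leverage = dev_bar - dev_plug
    if family == "binomial":
        resid_sign = np.sign(observed["r"] - observed["n"] * phi_hat)
    elif family == "poisson":
        resid_sign = np.sign(observed["r"] - observed["e"] * phi_hat)
    else:
        resid_sign = np.sign(observed["y"] - phi_hat)
    arms = pd.DataFrame({
        "study": [a.study for a in nd.arms],
        "treatment": [a.treatment for a in nd.arms],
        "dev_bar": dev_bar,
        "dev_plugin": dev_plug,
        "leverage": leverage,
        "x": resid_sign * np.sqrt(dev_bar),
    })
    Dbar = float(dev_bar.sum())
    pD = float(leverage.sum())
    return FitStats(dev_bar=dev_bar, dev_plugin=dev_plug, leverage=leverage,
                    Dbar=Dbar, pD=pD, DIC=Dbar + pD, arms=arms)


# ---------------------------------------------------------------------------
# convergence


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor (with sqrt correction).

    ``chains`` has shape (m, n).  A single chain is split in half.
    Returns NaN for zero-variance chains (flagged, not fatal).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected a (chains, iterations) array")
    if chains.shape[0] == 1:
        n = chains.shape[1] // 2
        chains = np.stack([chains[0, :n], chains[0, n:2 * n]])
    m, n = chains.shape
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if W == 0.0:
        return float("nan")
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS from the chain-averaged autocorrelation function.

    The autocorrelation sum is truncated at the first negative paired
    sum (rho_{2k} + rho_{2k+1} < 0), the standard initial-positive-
    sequence rule, and the result is capped at the raw draw count.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros(n)
    for c in range(m):
        x = chains[c] - chains[c].mean()
        fx = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(fx * np.conjugate(fx))[:n] / n
        acov += ac
    acov /= m
    if acov[0] == 0:
        return float("nan")
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
    tau = 1.0 + 2.0 * s
    return float(min(m * n, m * n / max(tau, 1e-12)))


@dataclass
class ConvergenceReport:
    table: pd.DataFrame       # parameter, psrf, ess, flag
    threshold: float = 1.05   # advisory PSRF threshold

    def converged(self) -> bool:
        psrf = self.table["psrf"].dropna()
        return bool((psrf < self.threshold).all())


def convergence(samples: PosteriorSamples) -> ConvergenceReport:
    """Per-parameter PSRF and effective sample size."""
    rows = []
    for name in samples.names:
        ch = samples.get(name)
        psrf = gelman_rubin(ch)
        ess = effective_sample_size(ch)
        flag = ""
        if np.isnan(psrf):
            flag = "zero-variance chain"
        elif psrf >= 1.05:
            flag = "PSRF above 1.05"
        rows.append(dict(parameter=name, psrf=psrf, ess=ess, flag=flag))
    return ConvergenceReport(pd.DataFrame(rows))


def trace_data(samples: PosteriorSamples) -> pd.DataFrame:
    """(chain, iteration, parameter, value) triples for trace plotting."""
    recs = []
    for c in range(samples.n_chains):
        df = pd.DataFrame(samples.array[c], columns=samples.names)
        df.insert(0, "iteration", np.arange(len(df)))
        df.insert(0, "chain", c)
        recs.append(df.melt(id_vars=["chain", "iteration"],
                            var_name="parameter", value_name="value"))
    return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# consistency vs inconsistency comparison


def compare_deviance(fit_consistency: FitStats,
                     fit_inconsistency: FitStats) -> dict:
    """Pair per-arm posterior mean deviances of the two model variants.

    The scatter of these pairs against the identity line localizes
    arms whose fit improves when transitivity is dropped; a material
    DIC advantage for the inconsistency model is global evidence of
    inconsistency.
    """
    a, b = fit_consistency.arms, fit_inconsistency.arms
    if len(a) != len(b) or not (a["study"].tolist() == b["study"].tolist()
                                and a["treatment"].tolist()
                                == b["treatment"].tolist()):
        raise ValueError("fits cover different data points")
    points = pd.DataFrame({
        "study": a["study"], "treatment": a["treatment"],
        "dev_consistency": fit_consistency.dev_bar,
        "dev_inconsistency": fit_inconsistency.dev_bar,
    })
    return {
        "points": points,
        "dic_consistency": fit_consistency.DIC,
        "dic_inconsistency": fit_inconsistency.DIC,
        "dic_difference": fit_consistency.DIC - fit_inconsistency.DIC,
        "n_above_identity": int((points.dev_inconsistency
                                 > points.dev_consistency).sum()),
        "n_below_identity": int((points.dev_inconsistency
                                 < points.dev_consistency).sum()),
    }
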