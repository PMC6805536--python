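"""Adaptive Metropolis-within-Gibbs posterior sampler.

The sampler updates, in turn, the study baselines ``mu_i`` (as one
block of conditionally independent coordinates), the within-study
random contrasts ``delta_ik`` (blocked by arm position, again
conditionally independent across studies), each basic contrast ``d``,
the heterogeneity standard deviation ``sigma`` and any regression
coefficients, using Gaussian random-walk proposals.  Proposal scales
are tuned per parameter toward a 0.44 scalar acceptance rate during the
adaptation phase and frozen afterwards, which preserves detailed
balance for the burn-in and sampling phases.

The run is bitwise deterministic for a given seed: each chain draws
from its own generator spawned from a single ``SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (ModelDefinition, arm_loglik, inverse_link,
                    linear_predictor)

__all__ = ["McmcSettings", "PosteriorSamples", "run_nma"]

_TARGET_ACCEPT = 0.44
_ADAPT_WINDOW = 50


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run configuration (adaptation, burn-in, kept iterations)."""

    n_adapt: int = 1000
    n_burnin: int = 2000
    n_iter: int = 5000
    n_chains: int = 2
    seed: int = 0
    monitors: Sequence[str] | None = None
    monitor_phi: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        for nm in ("n_adapt", "n_burnin"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


class PosteriorSamples:
    """Named posterior draws: chains x kept iterations x parameters."""

    def __init__(self, names: list[str], array: np.ndarray,
                 phi: np.ndarray | None, settings: McmcSettings,
                 meta: dict):
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if not np.all(np.isfinite(array)):
            raise ValueError("kept samples contain non-finite values")
        self.names = names
        self.array = array              # (chains, n_iter, n_params)
        self.phi = phi                  # (chains, n_iter, n_arms) or None
        self.settings = settings
        self.meta = meta
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_kept(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, n_kept)."""
        return self.array[:, :, self._index[name]]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains."""
        return self.get(name).reshape(-1)

    def stacked_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Pooled draws for several parameters, shape (S, len(names))."""
        cols = [self.stacked(n) for n in names]
        return np.column_stack(cols) if cols else np.empty((0, 0))

    # -- persistence (text formats) ---------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = dict(self.meta)
        meta["names"] = self.names
        meta["settings"] = {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.settings.__dict__.items()}
        meta["settings"]["monitors"] = (list(self.settings.monitors)
                                        if self.settings.monitors else None)
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))
        for c in range(self.n_chains):
            pd.DataFrame(self.array[c], columns=self.names).to_csv(
                directory / f"chain{c}.csv", index=False)
            if self.phi is not None:
                pd.DataFrame(self.phi[c]).to_csv(
                    directory / f"phi{c}.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSamples":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        names = meta.pop("names")
        skw = meta.pop("settings")
        settings = McmcSettings(**skw)
        chains, phis = [], []
        c = 0
        while (directory / f"chain{c}.csv").exists():
            chains.append(pd.read_csv(directory / f"chain{c}.csv").to_numpy())
            if (directory / f"phi{c}.csv").exists():
                phis.append(pd.read_csv(directory / f"phi{c}.csv").to_numpy())
            c += 1
        arr = np.stack(chains)
        phi = np.stack(phis) if phis else None
        return cls(names, arr, phi, settings, meta)


# ---------------------------------------------------------------------------


class _ChainState:
    """Mutable state + cached likelihood for one chain."""

    def __init__(self, model: ModelDefinition, rng: np.random.Generator,
                 chain_index: int, prior_only: bool):
        self.model = model
        self.rng = rng
        self.prior_only = prior_only
        des = model.design
        spec = model.spec
        pr = model.priors
        M, A = des.n_studies, des.n_arms
        K = model.n_d

        # chain-indexed offsets of +/- 2 * (prior sd) / 10, alternating sign
        off = 0.2 * ((-1) ** chain_index) * ((chain_index + 1) // 2)

        if pr.mu_log_baseline:
            self.mu = np.full(M, np.log(0.5)) * (1.0 + 0.5 * abs(off))
        else:
            self.mu = np.zeros(M) + off * pr.mu_sd
        self.d = np.zeros(K) + off * pr.d_sd
        self.random = spec.effects == "random"
        self.sigma = None
        if self.random:
            up = pr.sigma_upper
            self.sigma = float(np.clip(up / 2 + off * up / 2, 1e-3 * up,
                                       (1 - 1e-3) * up))
        self.noncontrol = des.arm_pos > 0
        self.delta = np.zeros(A)
        self.has_beta = spec.covariate is not None
        self.beta_equal = self.has_beta and spec.covariate_prior == "equal"
        self.beta_exch = (self.has_beta
                          and spec.covariate_prior == "exchangeable")
        nb = 0
        if self.has_beta:
            nb = 1 if self.beta_equal else model.nd.n_treatments - 1
        self.beta = np.zeros(nb)
        self.b_hyper = 0.0
        self.gamma = pr.gamma_upper / 2 if self.beta_exch else None

        # proposal scales
        self.s_mu = np.full(M, 0.5)
        self.s_delta = np.full(A, 0.5)
        self.s_d = np.full(K, 0.5)
        self.s_dtrans = np.full(K, 0.5)
        self.s_sigma = 0.1 * (pr.sigma_upper if self.random else 1.0)
        self.s_beta = np.full(nb, 0.5)
        self.s_b = 0.5
        self.s_gamma = 0.1 * (pr.gamma_upper if self.beta_exch else 1.0)
        # acceptance bookkeeping (adaptation + reporting)
        self.acc = {k: np.zeros_like(v) for k, v in self._scales().items()}
        self.tries = {k: np.zeros_like(v) for k, v in self._scales().items()}

        self._refresh()

    # -- bookkeeping helpers -----------------------------------------
    def _scales(self):
        sc = {"mu": self.s_mu, "delta": self.s_delta, "d": self.s_d,
              "dtrans": self.s_dtrans, "beta": self.s_beta}
        sc["sigma"] = np.atleast_1d(np.float64(self.s_sigma))
        sc["b"] = np.atleast_1d(np.float64(self.s_b))
        sc["gamma"] = np.atleast_1d(np.float64(self.s_gamma))
        return sc

    def adapt(self) -> None:
        """Robbins-Monro-style scale tuning toward 0.44 acceptance."""
        for key in self.acc:
            tries = self.tries[key]
            mask = tries > 0
            if not np.any(mask):
                continue
            rate = np.where(mask, self.acc[key] / np.maximum(tries, 1), 0.0)
            factor = np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
            if key == "mu":
                self.s_mu[mask] *= factor[mask]
            elif key == "delta":
                self.s_delta[mask] *= factor[mask]
            elif key == "d":
                self.s_d[mask] *= factor[mask]
            elif key == "dtrans":
                self.s_dtrans[mask] *= factor[mask]
            elif key == "beta":
                self.s_beta[mask] *= factor[mask]
            elif key == "sigma":
                self.s_sigma *= float(factor[0])
            elif key == "b":
                self.s_b *= float(factor[0])
            elif key == "gamma":
                self.s_gamma *= float(factor[0])
            self.acc[key][:] = 0
            self.tries[key][:] = 0

    # -- likelihood cache --------------------------------------------
    def _delta_effective(self) -> np.ndarray:
        if self.random:
            return self.delta
        return self.model.contrast_of_arm(self.d)

    def _beta_vector(self) -> np.ndarray | None:
        if not self.has_beta:
            return None
        if self.beta_equal:
            return np.full(self.model.nd.n_treatments - 1, self.beta[0])
        return self.beta

    def _loglik(self, mu=None, delta_eff=None, beta=None) -> np.ndarray:
        des = self.model.design
        spec = self.model.spec
        if self.prior_only:
            return np.zeros(des.n_arms)
        mu = self.mu if mu is None else mu
        delta_eff = self._delta_effective() if delta_eff is None else delta_eff
        bc = None
        if self.has_beta:
            bvec = self._beta_vector() if beta is None else beta
            bc = self.model.beta_contrast_of_arm(bvec)
        theta = linear_predictor(
            mu[des.study_of_arm], delta_eff, link=spec.link,
            family=spec.family,
            f=des.f[des.study_of_arm] if spec.link == "cloglog" else None,
            beta_contrast=bc, x=des.x, xbar=des.xbar)
        return arm_loglik(theta, des, spec.family, spec.link)

    def _refresh(self) -> None:
        self.ll = self._loglik()

    # -- priors -------------------------------------------------------
    def _mu_logprior(self, mu: np.ndarray) -> np.ndarray:
        pr = self.model.priors
        if pr.mu_log_baseline:
            # p = e^mu ~ U(0,1)  =>  density e^mu on mu < 0
            return np.where(mu < 0, mu, -np.inf)
        return -0.5 * (mu / pr.mu_sd) ** 2

    def _d_logprior(self, d: np.ndarray) -> np.ndarray:
        return -0.5 * (d / self.model.priors.d_sd) ** 2

    def _beta_logprior(self, beta: np.ndarray) -> np.ndarray:
        pr = self.model.priors
        if self.beta_exch:
            g = self.gamma
            return -0.5 * ((beta - self.b_hyper) / g) ** 2 - np.log(g)
        # unrelated / equal: t(0, u^2, df=1) == Cauchy(0, u)
        return -np.log1p((beta / pr.beta_scale) ** 2)

    def _delta_logprior_studies(self, delta: np.ndarray,
                                dmean_arm: np.ndarray,
                                sigma: float) -> np.ndarray:
        """Per-study compound-symmetry MVN log-density of delta_i.

        Sigma = sigma^2 (0.5 I_m + 0.5 J_m); its inverse and determinant
        are closed-form, so the quadratic form reduces to per-study sums
        of z and z^2 over non-control arms.
        """
        des = self.model.design
        nc = self.noncontrol
        z = (delta - dmean_arm)[nc]
        sid = des.study_of_arm[nc]
        M = des.n_studies
        sz = np.bincount(sid, weights=z, minlength=M)
        sz2 = np.bincount(sid, weights=z * z, minlength=M)
        m = des.a - 1.0
        quad = (sz2 - sz ** 2 / (m + 1.0)) / sigma ** 2
        logdet = 2.0 * m * np.log(sigma) + m * np.log(0.5) + np.log(m + 1.0)
        return -0.5 * logdet - quad

    def total_delta_logprior(self, delta=None, d=None, sigma=None) -> float:
        delta = self.delta if delta is None else delta
        d = self.d if d is None else d
        sigma = self.sigma if sigma is None else sigma
        dmean = self.model.contrast_of_arm(d)
        return float(np.sum(self._delta_logprior_studies(delta, dmean, sigma)))

    # -- update sweeps -------------------------------------------------
    def update_mu(self) -> None:
        des = self.model.design
        M = des.n_studies
        prop = self.mu + self.s_mu * self.rng.standard_normal(M)
        ll_prop = self._loglik(mu=prop)
        dll = np.bincount(des.study_of_arm, weights=ll_prop - self.ll,
                          minlength=M)
        dprior = self._mu_logprior(prop) - self._mu_logprior(self.mu)
        with np.errstate(invalid="ignore"):
            accept = np.log(self.rng.random(M)) < dll + dprior
        self.tries["mu"] += 1
        self.acc["mu"] += accept
        if np.any(accept):
            self.mu = np.where(accept, prop, self.mu)
            self._refresh()

    def update_delta(self) -> None:
        """One sweep over arm-position slots; studies update independently."""
        des = self.model.design
        M = des.n_studies
        dmean = self.model.contrast_of_arm(self.d)
        for pos in range(1, int(des.arm_pos.max()) + 1):
            at = des.arm_pos == pos
            if not np.any(at):
                break
            prop = self.delta.copy()
            prop[at] = (self.delta[at] + self.s_delta[at]
                        * self.rng.standard_normal(int(at.sum())))
            ll_prop = self._loglik(delta_eff=prop)
            dll = np.bincount(des.study_of_arm, weights=ll_prop - self.ll,
                              minlength=M)
            dprior = (self._delta_logprior_studies(prop, dmean, self.sigma)
                      - self._delta_logprior_studies(self.delta, dmean,
                                                     self.sigma))
            with np.errstate(invalid="ignore"):
                acc_study = np.log(self.rng.random(M)) < dll + dprior
            acc_arm = at & acc_study[des.study_of_arm]
            self.tries["delta"][at] += 1
            self.acc["delta"][acc_arm] += 1
            if np.any(acc_arm):
                self.delta[acc_arm] = prop[acc_arm]
                self._refresh()

    def update_d(self) -> None:
        for k in range(self.model.n_d):
            prop = self.d.copy()
            prop[k] += self.s_d[k] * self.rng.standard_normal()
            dprior = float(self._d_logprior(prop[k])
                           - self._d_logprior(self.d[k]))
            if self.random:
                dlp = (self.total_delta_logprior(d=prop)
                       - self.total_delta_logprior())
                delta_acc = dlp + dprior
                ll_prop = None
            else:
                ll_prop = self._loglik(
                    delta_eff=self.model.contrast_of_arm(prop))
                delta_acc = float(np.sum(ll_prop - self.ll)) + dprior
            self.tries["d"][k] += 1
            if np.log(self.rng.random()) < delta_acc:
                self.acc["d"][k] += 1
                self.d = prop
                if ll_prop is not None:
                    self.ll = ll_prop
        if self.random:
            self._update_d_translated()

    def _update_d_translated(self) -> None:
        """Joint move: shift d_k and translate the deltas with it.

        Under random effects a plain d update only feels the tight
        MVN(delta; d, Sigma) coupling, so d diffuses with step ~ sigma.
        Translating the study contrasts by the change in their means
        leaves the delta prior term invariant (the residuals z are
        unchanged; the move's Jacobian is 1), so the proposal is judged
        by the likelihood and the d prior alone — restoring proper
        mixing along the d direction.
        """
        for k in range(self.model.n_d):
            prop = self.d.copy()
            prop[k] += self.s_dtrans[k] * self.rng.standard_normal()
            shift = (self.model.contrast_of_arm(prop)
                     - self.model.contrast_of_arm(self.d))
            delta_prop = self.delta + shift
            ll_prop = self._loglik(delta_eff=delta_prop)
            dacc = (float(np.sum(ll_prop - self.ll))
                    + float(self._d_logprior(prop[k])
                            - self._d_logprior(self.d[k])))
            self.tries["dtrans"][k] += 1
            if np.log(self.rng.random()) < dacc:
                self.acc["dtrans"][k] += 1
                self.d = prop
                self.delta = delta_prop
                self.ll = ll_prop

    def update_sigma(self) -> None:
        if not self.random:
            return
        up = self.model.priors.sigma_upper
        prop = self.sigma + self.s_sigma * self.rng.standard_normal()
        self.tries["sigma"] += 1
        if not (0.0 < prop < up):
            return
        dlp = (self.total_delta_logprior(sigma=prop)
               - self.total_delta_logprior())
        if np.log(self.rng.random()) < dlp:
            self.acc["sigma"] += 1
            self.sigma = prop

    def update_beta(self) -> None:
        if not self.has_beta:
            return
        for k in range(self.beta.size):
            prop = self.beta.copy()
            prop[k] += self.s_beta[k] * self.rng.standard_normal()
            bvec = (np.full(self.model.nd.n_treatments - 1, prop[0])
                    if self.beta_equal else prop)
            ll_prop = self._loglik(beta=bvec)
            dacc = (float(np.sum(ll_prop - self.ll))
                    + float(self._beta_logprior(prop[k])
                            - self._beta_logprior(self.beta[k])))
            self.tries["beta"][k] += 1
            if np.log(self.rng.random()) < dacc:
                self.acc["beta"][k] += 1
                self.beta = prop
                self.ll = ll_prop
        if self.beta_exch:
            self._update_beta_hyper()

    def _update_beta_hyper(self) -> None:
        pr = self.model.priors

        def hyper_lp(b: float, g: float) -> float:
            lp = float(np.sum(-0.5 * ((self.beta - b) / g) ** 2
                              - np.log(g)))
            return lp - np.log1p((b / pr.beta_scale) ** 2)

        prop_b = self.b_hyper + self.s_b * self.rng.standard_normal()
        self.tries["b"] += 1
        if np.log(self.rng.random()) < (hyper_lp(prop_b, self.gamma)
                                        - hyper_lp(self.b_hyper, self.gamma)):
            self.acc["b"] += 1
            self.b_hyper = prop_b
        prop_g = self.gamma + self.s_gamma * self.rng.standard_normal()
        self.tries["gamma"] += 1
        if 0.0 < prop_g < pr.gamma_upper:
            if np.log(self.rng.random()) < (hyper_lp(self.b_hyper, prop_g)
                                            - hyper_lp(self.b_hyper,
                                                       self.gamma)):
                self.acc["gamma"] += 1
                self.gamma = prop_g

    def sweep(self) -> None:
        self.update_mu()
        if self.random:
            self.update_delta()
        self.update_d()
        self.update_sigma()
        self.update_beta()

    def check_finite(self) -> None:
        for name, arr in (("mu", self.mu), ("d", self.d),
                          ("delta", self.delta), ("beta", self.beta)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise RuntimeError(
                    f"divergent chain: non-finite value in parameter {name}")
        if self.random and not np.isfinite(self.sigma):
            raise RuntimeError("divergent chain: non-finite sigma")

    # -- monitored values ---------------------------------------------
    def monitor_getters(self, names: list[str]):
        """Resolve monitor names to value getters once per run."""
        lut = self._value_lookup()
        try:
            return [lut[nm] for nm in names]
        except KeyError as exc:
            raise ValueError(f"unknown monitor {exc.args[0]!r}") from None

    def _value_lookup(self):
        model = self.model
        lut = {}
        for k, nm in enumerate(model.d_names):
            lut[nm] = (lambda kk=k: self.d[kk])
        if self.random:
            lut["sigma"] = lambda: self.sigma
        if self.has_beta:
            if self.beta_equal:
                lut["B"] = lambda: self.beta[0]
            else:
                for k, t in enumerate(model.nd.treatments[1:]):
                    lut[f"beta[{t}]"] = (lambda kk=k: self.beta[kk])
            if self.beta_exch:
                lut["b"] = lambda: self.b_hyper
                lut["gamma"] = lambda: self.gamma
        for i, s in enumerate(model.nd.studies):
            lut[f"mu[{s}]"] = (lambda ii=i: self.mu[ii])
        return lut

    def phi_values(self) -> np.ndarray:
        des = self.model.design
        spec = self.model.spec
        bc = None
        if self.has_beta:
            bc = self.model.beta_contrast_of_arm(self._beta_vector())
        theta = linear_predictor(
            self.mu[des.study_of_arm], self._delta_effective(),
            link=spec.link, family=spec.family,
            f=des.f[des.study_of_arm] if spec.link == "cloglog" else None,
            beta_contrast=bc, x=des.x, xbar=des.xbar)
        return inverse_link(theta, spec.link)


def default_monitors(model: ModelDefinition) -> list[str]:
    names = list(model.d_names)
    if model.spec.effects == "random":
        names.append("sigma")
    if model.spec.covariate is not None:
        if model.spec.covariate_prior == "equal":
            names.append("B")
        else:
            names += [f"beta[{t}]" for t in model.nd.treatments[1:]]
        if model.spec.covariate_prior == "exchangeable":
            names += ["b", "gamma"]
    return names


def run_nma(model: ModelDefinition, settings: McmcSettings,
            prior_only: bool = False) -> PosteriorSamples:
    """Sample the posterior of an assembled model.

    Runs ``n_chains`` independent chains (adaptation discarded, burn-in
    discarded, ``n_iter`` kept).  With ``prior_only=True`` the
    likelihood term is dropped, so the chains target the joint prior —
    useful for prior-predictive checks and for validating the prior
    machinery itself.
    """
    monitors = (list(settings.monitors) if settings.monitors
                else default_monitors(model))
    if "mu" in monitors:  # shorthand: expand to all baselines
        monitors.remove("mu")
        monitors += [f"mu[{s}]" for s in model.nd.studies]
    ss = np.random.SeedSequence(settings.seed)
    children = ss.spawn(settings.n_chains)
    arrs, phis, acc_meta = [], [], []
    for c in range(settings.n_chains):
        rng = np.random.Generator(np.random.PCG64(children[c]))
        state = _ChainState(model, rng, c, prior_only)
        getters = state.monitor_getters(monitors)
        for it in range(settings.n_adapt):
            state.sweep()
            if (it + 1) % _ADAPT_WINDOW == 0:
                state.adapt()
        for k in state.tries:  # reset counters for reporting
            state.tries[k][:] = 0
            state.acc[k][:] = 0
        for _ in range(settings.n_burnin):
            state.sweep()
        state.check_finite()
        out = np.empty((settings.n_iter, len(monitors)))
        phi = (np.empty((settings.n_iter, model.design.n_arms))
               if settings.monitor_phi else None)
        for it in range(settings.n_iter):
            state.sweep()
            out[it] = [g() for g in getters]
            if phi is not None:
                phi[it] = state.phi_values()
        state.check_finite()
        arrs.append(out)
        if phi is not None:
            phis.append(phi)
        acc_meta.append({k: float(np.mean(state.acc[k]
                                          / np.maximum(state.tries[k], 1)))
                         for k in state.acc if np.any(state.tries[k] > 0)})
    meta = {
        "treatments": list(model.nd.treatments),
        "studies": list(model.nd.studies),
        "u": model.priors.u,
        "priors": {k: v for k, v in model.priors.as_dict().items()},
        "acceptance_rates": acc_meta,
        "covariate": model.spec.covariate,
        "xbar": model.design.xbar,
        "effects": model.spec.effects,
        "model_type": model.spec.model_type,
        "family": model.spec.family,
        "link": model.spec.link,
        "prior_only": prior_only,
        "continuity_correction":
            "0.5 added to all cells of any zero-cell two-by-two when "
            "computing the reference scale u",
    }
    return PosteriorSamples(monitors, np.stack(arrs),
                            np.stack(phis) if phis else None, settings, meta)
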