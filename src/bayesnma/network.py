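"""Descriptive geometry of the evidence network.

These are the tabular counterparts of the usual network plot: how many
treatments and studies the network holds, which treatment pairs have
head-to-head (direct) evidence, whether the network is connected, and
summaries of a candidate effect-modifying covariate by study or by
treatment arm (the screening step for clinical heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import NetworkData

__all__ = [
    "NetworkSummary",
    "summarize_network",
    "connectivity",
    "comparison_matrix",
    "covariate_table",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Network characteristics table.

    Event-related fields are ``None`` for continuous outcomes rather
    than zero — the quantities are undefined there, not empty.
    """

    n_interventions: int
    n_studies: int
    total_patients: int | None
    possible_pairwise: int
    direct_pairwise: int
    connected: bool
    n_two_arm: int
    n_multi_arm: int
    total_events: int | None = None
    n_studies_no_zero_events: int | None = None
    n_studies_any_zero_event: int | None = None
    n_studies_all_zero_events: int | None = None
    mean_follow_up: float | None = None

    def to_series(self) -> pd.Series:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return pd.Series(d)


def _graph(nd: NetworkData) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nd.treatments)
    for s in nd.studies:
        labels = [a.treatment for a in nd.study_arms(s)]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                g.add_edge(labels[i], labels[j])
    return g


def connectivity(nd: NetworkData) -> tuple[bool, list[set[str]]]:
    """Connected components of the treatment graph.

    Two treatments are adjacent when they co-occur in at least one
    study.  An NMA can only compare treatments inside one component, so
    a disconnected network must be split (or bridged by more evidence)
    before modelling.
    """
    comps = [set(c) for c in nx.connected_components(_graph(nd))]
    return len(comps) == 1, comps


def comparison_matrix(nd: NetworkData) -> pd.DataFrame:
    """T×T study counts: entry (a, b) = number of studies containing both.

    The diagonal counts the studies containing each treatment.  A
    multi-arm study contributes one count to each of its within-study
    pairs.  This is the table behind edge widths of a network plot.
    """
    T = nd.n_treatments
    m = np.zeros((T, T), dtype=int)
    for s in nd.studies:
        idx = [nd.treatment_index(a.treatment) for a in nd.study_arms(s)]
        for i in idx:
            m[i, i] += 1
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                a, b = idx[i], idx[j]
                m[a, b] += 1
                m[b, a] += 1
    return pd.DataFrame(m, index=nd.treatments, columns=nd.treatments)


def summarize_network(nd: NetworkData) -> NetworkSummary:
    """Compute the network-characteristics table.

    ``total_patients`` sums arm sample sizes (dichotomous family only;
    person-time and continuous payloads do not carry a patient count
    unless sample sizes were supplied).  ``mean_follow_up`` is the
    unweighted mean of the study-level follow-up times, reflecting that
    follow-up is a per-study quantity in the model.
    """
    T = nd.n_treatments
    cm = comparison_matrix(nd).to_numpy()
    direct = int(np.count_nonzero(np.triu(cm, k=1)))
    connected, _ = connectivity(nd)
    a = nd.arms_per_study()
    n_two = sum(1 for v in a.values() if v == 2)

    total_patients = None
    if nd.family == "dichotomous":
        total_patients = int(sum(arm.sample_size for arm in nd.arms))

    ev_fields: dict[str, int | None] = dict(
        total_events=None, n_studies_no_zero_events=None,
        n_studies_any_zero_event=None, n_studies_all_zero_events=None)
    if nd.family in ("dichotomous", "count"):
        ev_fields["total_events"] = int(sum(arm.events for arm in nd.arms))
        no_zero = any_zero = all_zero = 0
        for s in nd.studies:
            evs = [arm.events for arm in nd.study_arms(s)]
            if all(e > 0 for e in evs):
                no_zero += 1
            else:
                any_zero += 1
                if all(e == 0 for e in evs):
                    all_zero += 1
        ev_fields.update(n_studies_no_zero_events=no_zero,
                         n_studies_any_zero_event=any_zero,
                         n_studies_all_zero_events=all_zero)

    fus = [nd.follow_up(s) for s in nd.studies]
    mean_fu = float(np.mean(fus)) if all(f is not None for f in fus) else None

    return NetworkSummary(
        n_interventions=T,
        n_studies=nd.n_studies,
        total_patients=total_patients,
        possible_pairwise=T * (T - 1) // 2,
        direct_pairwise=direct,
        connected=connected,
        n_two_arm=n_two,
        n_multi_arm=nd.n_studies - n_two,
        mean_follow_up=mean_fu,
        **ev_fields,
    )


def covariate_table(nd: NetworkData, covariate: str,
                    group_by: str = "study") -> tuple[pd.DataFrame, float]:
    """Covariate summary rows for heterogeneity screening.

    Returns ``(rows, grand_mean)``.  With ``group_by="study"`` there is
    one row per arm (study, treatment, mean, spread, n); with
    ``group_by="treatment"`` arms sharing a treatment are pooled with a
    sample-size-weighted mean when sample sizes are available and an
    unweighted mean otherwise.  ``grand_mean`` is the overall mean of
    the covariate over all arms that report it (the reference line of
    the screening plot).  Spread values (``<covariate>_sd`` when
    present on the arm) are carried as missing, not zero, when a study
    did not report them.
    """
    if group_by not in ("study", "treatment"):
        raise ValueError("group_by must be 'study' or 'treatment'")
    sd_key = f"{covariate}_sd"
    rows = []
    for arm in nd.arms:
        if covariate in arm.covariates:
            rows.append(dict(
                study=arm.study, treatment=arm.treatment,
                mean=arm.covariates[covariate],
                spread=arm.covariates.get(sd_key, np.nan),
                n=arm.sample_size if arm.sample_size is not None else np.nan,
            ))
    if not rows:
        raise ValueError(f"covariate {covariate!r} is present on no arm")
    df = pd.DataFrame(rows)
    grand_mean = float(df["mean"].mean())
    if group_by == "study":
        return df, grand_mean

    pooled = []
    for trt, grp in df.groupby("treatment", sort=False):
        if grp["n"].notna().all():
            w = grp["n"].to_numpy(float)
            mean = float(np.average(grp["mean"], weights=w))
            n = float(w.sum())
        else:
            mean = float(grp["mean"].mean())
            n = float(grp["n"].sum()) if grp["n"].notna().any() else np.nan
        spread = (float(grp["spread"].mean())
                  if grp["spread"].notna().any() else np.nan)
        pooled.append(dict(treatment=trt, mean=mean, spread=spread,
                           n=n, k_arms=len(grp)))
    return pd.DataFrame(pooled), grand_mean
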