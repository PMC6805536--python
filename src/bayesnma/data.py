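"""Arm-level evidence networks: ingestion, indexing and validation.

A network meta-analysis combines randomized trials that each compare a
subset of ``T`` treatments.  The data enter in *long format* — one row per
treatment arm — carrying the study label, the treatment label, and an
outcome payload whose shape depends on the outcome family:

``continuous``
    sample mean and its standard error per arm,
``dichotomous``
    event count and sample size per arm, optionally a per-study
    follow-up time (needed by the complementary log-log link),
``count``
    event count and person-time at risk per arm.

:func:`prepare_network` turns raw row mappings (e.g. ``csv.DictReader``
rows or a DataFrame's records) into a validated :class:`NetworkData` with
an explicit treatment index in which index 1 is the reference treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("continuous", "dichotomous", "count")

__all__ = [
    "ArmRecord",
    "NetworkData",
    "SchemaError",
    "ValidationError",
    "Issue",
    "prepare_network",
    "validate_network",
    "read_network_csv",
]


class SchemaError(ValueError):
    """A required column is missing or the outcome specification is malformed."""


class ValidationError(ValueError):
    """The rows do not form a usable evidence network."""


@dataclass(frozen=True)
class ArmRecord:
    """One treatment arm of one study.

    Exactly one outcome payload is populated per network: (``mean``,
    ``std_err``) for continuous outcomes, (``events``, ``sample_size``)
    for dichotomous ones, (``events``, ``person_time``) for counts.
    ``follow_up`` is the study-level follow-up time carried on each arm
    row for convenience; within a study all arms must agree on it.
    """

    study: str
    treatment: str
    mean: float | None = None
    std_err: float | None = None
    events: int | None = None
    sample_size: int | None = None
    person_time: float | None = None
    follow_up: float | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)


@dataclass
class NetworkData:
    """A validated arm-level evidence network.

    Attributes
    ----------
    arms:
        All arms, grouped contiguously by study.  Within each study the
        arm carrying the network reference treatment (when present) is
        listed first and acts as the study's control arm; otherwise the
        first-listed arm is the control.
    studies:
        Study labels in order of first appearance.
    treatments:
        Treatment labels in index order; ``treatments[0]`` is the
        reference (treatment index 1 in the usual 1-based notation).
    family:
        One of ``continuous`` / ``dichotomous`` / ``count``.
    """

    arms: list[ArmRecord]
    studies: list[str]
    treatments: list[str]
    family: str

    def __post_init__(self) -> None:
        self._tidx = {t: i for i, t in enumerate(self.treatments)}
        self._study_arms: dict[str, list[ArmRecord]] = {}
        for arm in self.arms:
            self._study_arms.setdefault(arm.study, []).append(arm)

    # -- basic shape -------------------------------------------------
    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def reference(self) -> str:
        return self.treatments[0]

    def treatment_index(self, label: str) -> int:
        """0-based index of a treatment label (reference is 0)."""
        return self._tidx[label]

    def study_arms(self, study: str) -> list[ArmRecord]:
        return self._study_arms[study]

    def arms_per_study(self) -> dict[str, int]:
        return {s: len(self._study_arms[s]) for s in self.studies}

    def follow_up(self, study: str) -> float | None:
        return self._study_arms[study][0].follow_up

    def has_follow_up(self) -> bool:
        return all(self.follow_up(s) is not None for s in self.studies)

    # -- restructuring ----------------------------------------------
    def with_reference(self, reference: str) -> "NetworkData":
        """Re-declare the reference treatment.

        Permutes the treatment index (new reference first, remaining
        labels keep their relative order) and re-orders arms within each
        study so the new reference arm, where present, is the control.
        Study and arm content are unchanged.
        """
        if reference not in self._tidx:
            raise ValidationError(f"unknown treatment {reference!r}")
        rest = [t for t in self.treatments if t != reference]
        treatments = [reference] + rest
        arms: list[ArmRecord] = []
        for s in self.studies:
            arms.extend(_control_first(self._study_arms[s], reference))
        return NetworkData(arms=arms, studies=list(self.studies),
                           treatments=treatments, family=self.family)

    def to_json_dict(self) -> dict:
        """JSON-serializable form (round-trips via :meth:`from_json_dict`)."""
        arms = []
        for a in self.arms:
            d = {"study": a.study, "treatment": a.treatment}
            for f in ("mean", "std_err", "events", "sample_size",
                      "person_time", "follow_up"):
                v = getattr(a, f)
                if v is not None:
                    d[f] = v
            if a.covariates:
                d["covariates"] = dict(a.covariates)
            arms.append(d)
        return {"family": self.family, "treatments": list(self.treatments),
                "studies": list(self.studies), "arms": arms}

    @classmethod
    def from_json_dict(cls, obj: Mapping[str, Any]) -> "NetworkData":
        arms = [ArmRecord(study=a["study"], treatment=a["treatment"],
                          mean=a.get("mean"), std_err=a.get("std_err"),
                          events=a.get("events"),
                          sample_size=a.get("sample_size"),
                          person_time=a.get("person_time"),
                          follow_up=a.get("follow_up"),
                          covariates=a.get("covariates", {}))
                for a in obj["arms"]]
        return cls(arms=arms, studies=list(obj["studies"]),
                   treatments=list(obj["treatments"]), family=obj["family"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view (one row per arm)."""
        rows = []
        for a in self.arms:
            row: dict[str, Any] = {"study": a.study, "treatment": a.treatment}
            for f in ("mean", "std_err", "events", "sample_size",
                      "person_time", "follow_up"):
                v = getattr(a, f)
                if v is not None:
                    row[f] = v
            row.update(a.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def _control_first(arms: Sequence[ArmRecord], reference: str) -> list[ArmRecord]:
    out = list(arms)
    for i, a in enumerate(out):
        if a.treatment == reference:
            out.insert(0, out.pop(i))
            break
    return out


_PAYLOAD_COLUMNS = {
    "continuous": ("mean", "std_err"),
    "dichotomous": ("events", "sample_size"),
    "count": ("events", "person_time"),
}
_OPTIONAL_COLUMNS = {"dichotomous": ("follow_up",)}


def _get(record: Mapping[str, Any], col: str) -> Any:
    if col not in record:
        raise SchemaError(f"missing column {col!r}")
    return record[col]


def _isnan(v: Any) -> bool:
    try:
        return bool(np.isnan(v))
    except TypeError:
        return v is None


def prepare_network(
    records: Iterable[Mapping[str, Any]],
    family: str,
    *,
    study_col: str = "study",
    treatment_col: str = "treatment",
    columns: Mapping[str, str] | None = None,
    covariate_cols: Sequence[str] = (),
    reference: str | None = None,
) -> NetworkData:
    """Build a :class:`NetworkData` from raw long-format rows.

    Parameters
    ----------
    records:
        One mapping per arm.  Every record must carry the study and
        treatment columns and the family's outcome payload columns.
    family:
        Outcome family; decides which payload columns are required
        (see module docstring).
    columns:
        Optional renaming from the canonical payload names (``mean``,
        ``std_err``, ``events``, ``sample_size``, ``person_time``,
        ``follow_up``) to the actual column names in ``records``.
    covariate_cols:
        Columns to attach as arm-level covariates (missing / NaN values
        are permitted and simply absent from the arm).
    reference:
        Reference treatment label.  ``None`` selects the alphabetically
        first label, which makes the indexing deterministic.

    Raises
    ------
    SchemaError
        If a named column is absent from some record.
    ValidationError
        On single-arm studies, duplicated (study, treatment) pairs,
        or disagreeing within-study follow-up times.
    """
    if family not in FAMILIES:
        raise SchemaError(f"unknown outcome family {family!r}; "
                          f"expected one of {FAMILIES}")
    records = list(records)
    if not records:
        raise SchemaError("no records supplied")
    colmap = dict(columns or {})

    def actual(name: str) -> str:
        return colmap.get(name, name)

    payload = _PAYLOAD_COLUMNS[family]
    takes_follow_up = "follow_up" in _OPTIONAL_COLUMNS.get(family, ())

    arms: list[ArmRecord] = []
    for rec in records:
        study = str(_get(rec, study_col))
        trt = str(_get(rec, treatment_col))
        fields: dict[str, Any] = {}
        for name in payload:
            v = _get(rec, actual(name))
            if _isnan(v):
                raise SchemaError(
                    f"missing value in column {actual(name)!r} "
                    f"(study {study}, treatment {trt})")
            fields[name] = int(v) if name in ("events", "sample_size") else float(v)
        if takes_follow_up and actual("follow_up") in rec:
            v = rec[actual("follow_up")]
            if not _isnan(v):
                fields["follow_up"] = float(v)
        cov = {}
        for c in covariate_cols:
            v = rec.get(c)
            if not _isnan(v):
                cov[c] = float(v)
        arms.append(ArmRecord(study=study, treatment=trt,
                              covariates=cov, **fields))

    # group by study, preserving first-appearance order
    studies: list[str] = []
    by_study: dict[str, list[ArmRecord]] = {}
    for arm in arms:
        if arm.study not in by_study:
            by_study[arm.study] = []
            studies.append(arm.study)
        by_study[arm.study].append(arm)

    for s in studies:
        sarm = by_study[s]
        if len(sarm) < 2:
            raise ValidationError(
                f"study {s} has {len(sarm)} arm; at least two are required "
                "for a contrast-based model")
        labels = [a.treatment for a in sarm]
        if len(set(labels)) != len(labels):
            dup = next(t for t in labels if labels.count(t) > 1)
            raise ValidationError(
                f"study {s} lists treatment {dup!r} more than once")
        fus = [a.follow_up for a in sarm if a.follow_up is not None]
        if fus and len(fus) != len(sarm):
            raise ValidationError(
                f"study {s} has follow-up on some arms but not all")
        if fus:
            f0 = fus[0]
            if any(abs(f - f0) > 1e-9 * max(abs(f0), 1.0) for f in fus):
                raise ValidationError(
                    f"study {s} has disagreeing per-arm follow-up times; "
                    "follow-up is a study-level quantity")

    labels = sorted({a.treatment for a in arms})
    if reference is None:
        reference = labels[0]
    elif reference not in labels:
        raise ValidationError(f"reference treatment {reference!r} does not "
                              "appear in the data")
    treatments = [reference] + [t for t in labels if t != reference]

    ordered: list[ArmRecord] = []
    for s in studies:
        ordered.extend(_control_first(by_study[s], reference))
    return NetworkData(arms=ordered, studies=studies,
                       treatments=treatments, family=family)


def read_network_csv(
    path: str,
    family: str,
    *,
    study_col: str = "study",
    treatment_col: str = "treatment",
    columns: Mapping[str, str] | None = None,
    covariate_cols: Sequence[str] = (),
    reference: str | None = None,
) -> NetworkData:
    """Read a long-format CSV (UTF-8, header row) into a network."""
    df = pd.read_csv(path)
    return prepare_network(df.to_dict(orient="records"), family,
                           study_col=study_col, treatment_col=treatment_col,
                           columns=columns, covariate_cols=covariate_cols,
                           reference=reference)


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning" | "info"
    study: str | None
    message: str


def validate_network(nd: NetworkData) -> list[Issue]:
    """Collect data-quality issues without raising.

    Returns an empty list iff every structural invariant holds and the
    outcome payloads are complete.  Zero-event arms are reported as
    informational only: the Bayesian binomial/Poisson likelihood handles
    them without continuity corrections.
    """
    issues: list[Issue] = []
    for s in nd.studies:
        sarm = nd.study_arms(s)
        if len(sarm) < 2:
            issues.append(Issue("error", s, "single-arm study"))
        for a in sarm:
            if nd.family == "dichotomous":
                if a.events is None or a.sample_size is None:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "missing events/sample size"))
                    continue
                if a.sample_size <= 0:
                    issues.append(Issue("error", s,
                                        f"arm {a.treatment}: sample size "
                                        f"{a.sample_size} is not positive"))
                if a.events < 0:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "negative event count"))
                elif a.events > a.sample_size:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "events exceed sample size"))
                elif a.events == 0:
                    issues.append(Issue("info", s, f"arm {a.treatment}: "
                                        "zero events"))
            elif nd.family == "count":
                if a.events is None or a.person_time is None:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "missing events/person-time"))
                    continue
                if a.person_time <= 0:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "person-time must be positive"))
                if a.events == 0:
                    issues.append(Issue("info", s, f"arm {a.treatment}: "
                                        "zero events"))
            else:
                if a.mean is None or a.std_err is None:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "missing mean/standard error"))
                    continue
                if a.std_err <= 0:
                    issues.append(Issue("error", s, f"arm {a.treatment}: "
                                        "standard error must be positive"))
    return issues
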