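"""Estimate a pathway configuration from an admissions table.

The estimation pipeline mirrors routine simulation input modelling: group
ICD-10 diagnoses into the four pathway classes, fit exponential inter-arrival
times per class, fit candidate LOS distributions per (class, ward,
ESD-eligibility) cell by maximum likelihood and rank them by AIC, and take
routing probabilities as exact empirical destination proportions.  A patient
is treated as ESD-eligible when their recorded route ends in early supported
discharge, which is observable from the destination field.

The lognormal sigma estimator uses the n-denominator (the MLE), not n-1.
No correlation between a patient's acute and rehabilitation stays is
estimated; the stays are modelled as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CLASS_NAMES,
    LOSModel,
    PathwayConfig,
    PatientClassSpec,
)

#: ICD-10 prefix table for grouping diagnoses into pathway classes.  Codes
#: that match no prefix fall through to "other" (displaced medical patients).
_PREFIX_GROUPS: list[tuple[str, str]] = [
    ("I60", "stroke"),
    ("I61", "stroke"),
    ("I62", "stroke"),
    ("I63", "stroke"),
    ("I64", "stroke"),
    ("G45", "tia"),
    ("G46", "tia"),
    ("G35", "complex_neuro"),
    ("G36", "complex_neuro"),
    ("G37", "complex_neuro"),
    ("G40", "complex_neuro"),
    ("G41", "complex_neuro"),
    ("G61", "complex_neuro"),
    ("G70", "complex_neuro"),
    ("G93", "complex_neuro"),
    ("C70", "complex_neuro"),
    ("C71", "complex_neuro"),
    ("C72", "complex_neuro"),
]


def classify_diagnosis(code: str) -> str:
    """Deterministic prefix mapping of an ICD-10-like code to a patient group."""
    if not code:
        raise ValueError("empty diagnosis code")
    code = code.strip().upper()
    for prefix, group in _PREFIX_GROUPS:
        if code.startswith(prefix):
            return group
    return "other"


@dataclass
class FitResult:
    """One fitted candidate distribution with its likelihood and AIC."""

    family: str
    params: dict[str, float]
    log_likelihood: float
    aic: float
    n: int
    note: str = ""

    def to_los_model(self) -> LOSModel:
        return LOSModel(self.family, dict(self.params))


def fit_interarrival(arrival_times) -> FitResult:
    """Exponential MLE for inter-arrival gaps: rate = (n-1)/(last-first)."""
    t = np.sort(np.asarray(arrival_times, dtype=float))
    if t.size < 2:
        raise ValueError("need at least two arrivals to fit inter-arrival times")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("arrival times are all identical")
    n_gaps = t.size - 1
    rate = n_gaps / span
    gaps = np.diff(t)
    ll = float(n_gaps * math.log(rate) - rate * gaps.sum())
    return FitResult(
        family="exponential",
        params={"mean": 1.0 / rate},
        log_likelihood=ll,
        aic=2.0 * 1 - 2.0 * ll,
        n=n_gaps,
    )


def _fit_family(family: str, x: np.ndarray) -> FitResult:
    n = x.size
    if family == "lognormal":
        logx = np.log(x)
        mu = float(logx.mean())
        sigma = float(logx.std(ddof=0))  # MLE (n-denominator)
        note = ""
        if sigma < 1e-12:
            note = "degenerate: zero log-scale spread"
            ll = math.inf
        else:
            ll = float(stats.lognorm.logpdf(x, s=sigma, scale=math.exp(mu)).sum())
        return FitResult(
            "lognormal", {"mu": mu, "sigma": sigma}, ll, 2.0 * 2 - 2.0 * ll, n, note
        )
    if family == "exponential":
        mean = float(x.mean())
        ll = float(-n * math.log(mean) - x.sum() / mean)
        return FitResult("exponential", {"mean": mean}, ll, 2.0 * 1 - 2.0 * ll, n)
    if family == "gamma":
        if x.std() < 1e-12:
            return FitResult(
                "gamma", {"shape": math.nan, "scale": math.nan}, -math.inf,
                math.inf, n, "degenerate: zero spread, gamma MLE undefined",
            )
        shape, _, scale = stats.gamma.fit(x, floc=0)
        ll = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
        return FitResult(
            "gamma", {"shape": float(shape), "scale": float(scale)}, ll,
            2.0 * 2 - 2.0 * ll, n,
        )
    raise ValueError(f"unknown family {family!r}")


def fit_los(
    durations, candidates: tuple[str, ...] = ("lognormal", "exponential", "gamma")
) -> list[FitResult]:
    """MLE fits per candidate family, sorted by ascending AIC."""
    x = np.asarray(durations, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three stays to fit a LOS distribution")
    if (x <= 0).any():
        raise ValueError("length of stay must be positive")
    fits = [_fit_family(f, x) for f in candidates]
    return sorted(fits, key=lambda r: r.aic)


@dataclass
class RoutingEstimate:
    routing: dict[str, dict[str, dict[str, float]]]  # class -> ward -> dest -> p
    esd_eligible_prob: dict[str, float]
    findings: list[str] = field(default_factory=list)


def estimate_routing(records: pd.DataFrame) -> RoutingEstimate:
    """Empirical destination proportions per (class, ward); exact fractions,
    no smoothing.  Classes/wards with zero departures are reported absent with
    a finding."""
    if records.empty:
        raise ValueError("empty records table")
    df = records.copy()
    df["group"] = df["diagnosis_code"].map(classify_diagnosis)
    routing: dict[str, dict[str, dict[str, float]]] = {}
    esd_prob: dict[str, float] = {}
    findings: list[str] = []
    for group, gdf in df.groupby("group"):
        routing[group] = {}
        for ward, wdf in gdf.groupby("ward"):
            n = len(wdf)
            if n == 0:  # pragma: no cover - groupby yields non-empty groups
                findings.append(f"{group}/{ward}: no departures")
                continue
            probs = (wdf["destination"].value_counts() / n).to_dict()
            routing[group][ward] = {k: float(v) for k, v in probs.items()}
        esd_patients = gdf.loc[gdf["destination"] == "esd", "patient_id"].nunique()
        esd_prob[group] = esd_patients / gdf["patient_id"].nunique()
    for name in CLASS_NAMES:
        if name not in routing:
            findings.append(f"{name}: no stays observed; routing absent")
    return RoutingEstimate(routing=routing, esd_eligible_prob=esd_prob, findings=findings)


#: Minimum stays for fitting a separate (ward, esd_flag) LOS cell; below this
#: the ESD-eligible and non-eligible stays are pooled.
MIN_CELL_N = 30


def estimate_config(records: pd.DataFrame) -> tuple[PathwayConfig, dict]:
    """Full pipeline: records table -> (PathwayConfig, fit report).

    The configured LOS family is lognormal (the standard choice for process
    durations); the report retains the full AIC ranking per cell so the choice
    can be audited.
    """
    if records.empty:
        raise ValueError("empty records table")
    df = records.copy()
    df["group"] = df["diagnosis_code"].map(classify_diagnosis)
    df["los"] = df["discharge_time"] - df["admit_time"]
    esd_patients = set(df.loc[df["destination"] == "esd", "patient_id"])
    df["esd_flag"] = df["patient_id"].isin(esd_patients)

    routing_est = estimate_routing(records)
    report: dict = {"classes": {}, "findings": list(routing_est.findings)}
    classes: list[PatientClassSpec] = []

    for group in CLASS_NAMES:
        gdf = df[df["group"] == group]
        if gdf.empty:
            continue
        entry = gdf[gdf["ward"] == "acute"]
        arrivals = np.sort(entry["admit_time"].to_numpy())
        ia_fit = fit_interarrival(arrivals)
        creport: dict = {
            "interarrival": {"mean": ia_fit.params["mean"], "n": ia_fit.n},
            "los": {},
        }
        los: dict[tuple[str, bool], LOSModel] = {}
        for ward, wdf in gdf.groupby("ward"):
            split = wdf["esd_flag"].value_counts().to_dict()
            separate = all(split.get(f, 0) >= MIN_CELL_N for f in (True, False)) and len(
                split
            ) == 2
            if separate:
                cells = [(flag, wdf[wdf["esd_flag"] == flag]) for flag in (True, False)]
            else:
                cells = [(None, wdf)]
            for flag, cdf_ in cells:
                fits = fit_los(cdf_["los"].to_numpy())
                lognorm = next(r for r in fits if r.family == "lognormal")
                flags = (flag,) if flag is not None else (True, False)
                for f in flags:
                    los[(str(ward), f)] = lognorm.to_los_model()
                creport["los"][f"{ward}:{flag if flag is not None else 'pooled'}"] = [
                    {
                        "family": r.family,
                        "params": r.params,
                        "aic": r.aic,
                        "n": r.n,
                        "note": r.note,
                    }
                    for r in fits
                ]
        routing = {
            w: dict(v) for w, v in routing_est.routing.get(group, {}).items()
        }
        classes.append(
            PatientClassSpec(
                name=group,
                interarrival_mean=ia_fit.params["mean"],
                esd_eligible_prob=routing_est.esd_eligible_prob.get(group, 0.0),
                routing=routing,
                los=los,
            )
        )
        creport["routing"] = routing
        creport["esd_eligible_prob"] = routing_est.esd_eligible_prob.get(group, 0.0)
        report["classes"][group] = creport

    if not classes:
        raise ValueError("no recognisable patient classes in the records")
    config = PathwayConfig(classes=classes)
    return config, report
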