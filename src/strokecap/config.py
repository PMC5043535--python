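"""Pathway parameterisation: patient classes, arrivals, length of stay, routing.

The pathway is the standard acute-stroke layout: every patient is admitted to
the acute stroke unit; on discharge from acute care a patient moves instantly
to inpatient community rehabilitation, to early supported discharge (ESD), or
leaves the pathway.  Rehabilitation patients then move to ESD or leave.  Four
patient classes share the wards: confirmed stroke, high-risk TIA, complex
neurological, and "other" medical patients displaced from elsewhere in the
hospital.  All rates are per day and all durations are in days.

Length of stay (LOS) is lognormal by default and may differ by ward and by
whether the patient's route passes through ESD (ESD-bound patients are milder
and stay for a shorter time).  A patient's ESD flag is defined by the sampled
route: it is True exactly when the route ends in ESD, so the class-level
``esd_eligible_prob`` is the total probability that a route reaches ESD and is
derivable from the routing vectors.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import yaml

WARDS: tuple[str, ...] = ("acute", "rehab")
DESTINATIONS: tuple[str, ...] = ("rehab", "esd", "exit")
CLASS_NAMES: tuple[str, ...] = ("stroke", "tia", "complex_neuro", "other")

#: Admissions by class over the 46-month study window used to anchor the
#: default configuration (stroke 54%, TIA 6%, complex-neurological 19%,
#: other 21% of 2444 admissions).
STUDY_CLASS_COUNTS: dict[str, int] = {
    "stroke": 1320,
    "tia": 158,
    "complex_neuro": 456,
    "other": 510,
}
STUDY_ESD_TOTAL = 463
STUDY_ESD_FROM_ACUTE = 300

_TOL = 1e-9


@dataclass(frozen=True)
class LOSModel:
    """A parametric length-of-stay distribution.

    ``family`` is one of ``lognormal`` (params ``mu``, ``sigma`` on the log-day
    scale), ``exponential`` (param ``mean``), or ``gamma`` (params ``shape``,
    ``scale``).
    """

    family: str
    params: dict[str, float]

    def mean(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.params["mu"] + 0.5 * self.params["sigma"] ** 2)
        if self.family == "exponential":
            return self.params["mean"]
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        raise ValueError(f"unknown LOS family {self.family!r}")

    def scaled(self, factor: float) -> "LOSModel":
        """Return a copy whose mean is multiplied by ``factor``.

        The dimensionless shape (coefficient of variation) is preserved: for a
        lognormal this shifts ``mu`` by ``log(factor)`` and leaves ``sigma``.
        """
        if factor <= 0 or not math.isfinite(factor):
            raise ValueError("scale factor must be positive and finite")
        if self.family == "lognormal":
            p = dict(self.params)
            p["mu"] = p["mu"] + math.log(factor)
            return LOSModel("lognormal", p)
        if self.family == "exponential":
            return LOSModel("exponential", {"mean": self.params["mean"] * factor})
        if self.family == "gamma":
            p = dict(self.params)
            p["scale"] = p["scale"] * factor
            return LOSModel("gamma", p)
        raise ValueError(f"unknown LOS family {self.family!r}")

    def sample(self, rng, size: int):
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size)
        if self.family == "exponential":
            return rng.exponential(self.params["mean"], size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size)
        raise ValueError(f"unknown LOS family {self.family!r}")


def lognormal_from_mean(mean: float, sigma: float) -> LOSModel:
    """Lognormal LOS with the given arithmetic mean (days) and log-scale sigma."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return LOSModel("lognormal", {"mu": math.log(mean) - 0.5 * sigma**2, "sigma": sigma})


@dataclass
class PatientClassSpec:
    """One patient class: arrivals, routing and length of stay.

    ``routing`` maps a ward to a probability vector over destinations
    ``{rehab, esd, exit}``; ``los`` maps ``(ward, esd_flag)`` to an
    :class:`LOSModel`.  ``entry_ward`` is ``acute`` for the stroke pathway; the
    option to enter at ``rehab`` exists so that simple two-stream loss systems
    (used to validate the pooling calculation) can be expressed in the same
    configuration language.
    """

    name: str
    interarrival_mean: float
    esd_eligible_prob: float
    routing: dict[str, dict[str, float]]
    los: dict[tuple[str, bool], LOSModel]
    entry_ward: str = "acute"

    def arrival_rate(self) -> float:
        return 1.0 / self.interarrival_mean

    def reach_prob(self, ward: str) -> float:
        """Probability that an admitted patient requires a bed on ``ward``."""
        if ward == self.entry_ward:
            return 1.0
        return self.routing.get(self.entry_ward, {}).get(ward, 0.0)

    def esd_prob_at(self, ward: str) -> float:
        """P(route passes through ESD | the patient occupies ``ward``)."""
        if ward == self.entry_ward:
            return self.esd_eligible_prob
        return self.routing.get(ward, {}).get("esd", 0.0)

    def mean_los_at(self, ward: str) -> float:
        """Mean LOS on ``ward`` mixed over the ESD flag, conditional on occupancy."""
        p = self.esd_prob_at(ward)
        m_esd = self.los[(ward, True)].mean() if (ward, True) in self.los else 0.0
        m_no = self.los[(ward, False)].mean() if (ward, False) in self.los else 0.0
        if p > 0 and (ward, True) not in self.los:
            raise KeyError(f"class {self.name}: missing LOS for ({ward}, esd)")
        if p < 1 and (ward, False) not in self.los:
            raise KeyError(f"class {self.name}: missing LOS for ({ward}, no-esd)")
        return p * m_esd + (1.0 - p) * m_no

    def route_esd_total(self) -> float:
        """Total probability that a sampled route ends in ESD."""
        entry = self.routing.get(self.entry_ward, {})
        p = entry.get("esd", 0.0)
        p += entry.get("rehab", 0.0) * self.routing.get("rehab", {}).get("esd", 0.0)
        return p


@dataclass
class Seasonality:
    """Multiplicative arrival-rate profiles; each averages to 1 so the annual
    offered load is unchanged."""

    day_of_week: list[float] = field(default_factory=lambda: [1.0] * 7)
    quarter: list[float] = field(default_factory=lambda: [1.0] * 4)

    def is_flat(self) -> bool:
        return all(abs(x - 1.0) < _TOL for x in self.day_of_week + self.quarter)

    def multiplier(self, t: float) -> float:
        dow = int(t) % 7
        doy = t % 365.0
        q = min(int(doy / 91.25), 3)
        return self.day_of_week[dow] * self.quarter[q]

    def peak(self) -> float:
        return max(self.day_of_week) * max(self.quarter)


@dataclass
class PathwayConfig:
    classes: list[PatientClassSpec]
    seasonality: Seasonality = field(default_factory=Seasonality)
    wards: tuple[str, ...] = WARDS

    def class_by_name(self, name: str) -> PatientClassSpec:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    def copy(self) -> "PathwayConfig":
        return copy.deepcopy(self)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def los_key(ward: str, esd: bool) -> str:
            return f"{ward}:{'esd' if esd else 'no_esd'}"

        return {
            "wards": list(self.wards),
            "seasonality": {
                "day_of_week": list(self.seasonality.day_of_week),
                "quarter": list(self.seasonality.quarter),
            },
            "classes": [
                {
                    "name": c.name,
                    "interarrival_mean": c.interarrival_mean,
                    "esd_eligible_prob": c.esd_eligible_prob,
                    "entry_ward": c.entry_ward,
                    "routing": {w: dict(v) for w, v in c.routing.items()},
                    "los": {
                        los_key(w, e): {"family": m.family, "params": dict(m.params)}
                        for (w, e), m in c.los.items()
                    },
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayConfig":
        classes = []
        for cd in d["classes"]:
            los = {}
            for key, md in cd["los"].items():
                ward, flag = key.split(":")
                los[(ward, flag == "esd")] = LOSModel(md["family"], dict(md["params"]))
            classes.append(
                PatientClassSpec(
                    name=cd["name"],
                    interarrival_mean=float(cd["interarrival_mean"]),
                    esd_eligible_prob=float(cd["esd_eligible_prob"]),
                    routing={w: dict(v) for w, v in cd["routing"].items()},
                    los=los,
                    entry_ward=cd.get("entry_ward", "acute"),
                )
            )
        seas = d.get("seasonality") or {}
        return cls(
            classes=classes,
            seasonality=Seasonality(
                day_of_week=list(seas.get("day_of_week", [1.0] * 7)),
                quarter=list(seas.get("quarter", [1.0] * 4)),
            ),
            wards=tuple(d.get("wards", WARDS)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathwayConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class BedPlan:
    """Bed allocation for co-located wards: dedicated acute beds, dedicated
    rehabilitation beds, and a shared pool usable by either stream."""

    dedicated_acute: int
    dedicated_rehab: int
    pooled: int

    def __post_init__(self):
        for v in (self.dedicated_acute, self.dedicated_rehab, self.pooled):
            if v < 0 or int(v) != v:
                raise ValueError("bed counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.dedicated_acute + self.dedicated_rehab + self.pooled


SCENARIO_NAMES = ("current", "plus5pct", "full_pool", "partial_pool", "no_complex_neuro")


@dataclass(frozen=True)
class Scenario:
    """A named what-if transformation of the pathway.

    ``current`` leaves the configuration unchanged; ``plus5pct`` raises every
    class's admission rate by 5%; ``full_pool`` and ``partial_pool`` leave
    flows unchanged and are evaluated against bed plans; ``no_complex_neuro``
    removes the complex-neurological class from the pathway.
    """

    name: str
    admission_multiplier: float = 1.0
    excluded_classes: frozenset[str] = frozenset()
    bed_plan: BedPlan | None = None

    def __post_init__(self):
        if self.admission_multiplier <= 0:
            raise ValueError("admission_multiplier must be positive")

    @classmethod
    def from_name(cls, name: str, bed_plan: BedPlan | None = None) -> "Scenario":
        if name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
        if name == "plus5pct":
            return cls(name, admission_multiplier=1.05)
        if name == "no_complex_neuro":
            return cls(name, excluded_classes=frozenset({"complex_neuro"}))
        return cls(name, bed_plan=bed_plan)


# ---------------------------------------------------------------------------
# Offered load and calibration
# ---------------------------------------------------------------------------


def offered_loads(config: PathwayConfig) -> dict[str, float]:
    """Offered load per ward: sum over inflows of arrival rate x mean LOS.

    By Little's law this equals the mean of the unconstrained (infinite-server)
    occupancy distribution of the ward.
    """
    loads = {w: 0.0 for w in config.wards}
    for c in config.classes:
        lam = c.arrival_rate()
        for w in config.wards:
            reach = c.reach_prob(w)
            if reach > 0:
                loads[w] += lam * reach * c.mean_los_at(w)
    return loads


def calibrate_offered_load(
    config: PathwayConfig, targets: dict[str, float]
) -> PathwayConfig:
    """Rescale every class's LOS means on each targeted ward by a common
    per-ward factor so the ward's offered load hits its target exactly.

    Arrival rates and routing are untouched; lognormal shape (``sigma``) is
    preserved.  Raises ``ValueError`` for a non-positive target or a target on
    a ward with zero inflow.
    """
    current = offered_loads(config)
    out = config.copy()
    for ward, target in targets.items():
        if target <= 0:
            raise ValueError(f"target offered load for {ward!r} must be positive")
        if ward not in current:
            raise ValueError(f"unknown ward {ward!r}")
        if current[ward] <= 0:
            raise ValueError(f"ward {ward!r} has zero inflow; target is infeasible")
        factor = target / current[ward]
        for c in out.classes:
            for (w, e), model in list(c.los.items()):
                if w == ward:
                    c.los[(w, e)] = model.scaled(factor)
    return out


def apply_scenario(config: PathwayConfig, scenario: Scenario | str) -> PathwayConfig:
    """Return the transformed configuration; the input is never modified."""
    if isinstance(scenario, str):
        scenario = Scenario.from_name(scenario)
    if scenario.name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {scenario.name!r}")
    out = config.copy()
    if scenario.excluded_classes:
        out.classes = [c for c in out.classes if c.name not in scenario.excluded_classes]
    if scenario.admission_multiplier != 1.0:
        for c in out.classes:
            c.interarrival_mean /= scenario.admission_multiplier
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_config(config: PathwayConfig) -> list[str]:
    """Return one human-readable finding per violated invariant (empty if valid)."""
    findings: list[str] = []
    names = [c.name for c in config.classes]
    if not names:
        findings.append("classes: at least one patient class is required")
    for n in names:
        if n not in CLASS_NAMES:
            findings.append(f"classes[{n}]: unknown class name")
    if len(set(names)) != len(names):
        findings.append("classes: duplicate class names")

    for c in config.classes:
        path = f"classes[{c.name}]"
        if not (c.interarrival_mean > 0 and math.isfinite(c.interarrival_mean)):
            findings.append(f"{path}.interarrival_mean: must be positive and finite")
        if not (0.0 <= c.esd_eligible_prob <= 1.0):
            findings.append(f"{path}.esd_eligible_prob: must lie in [0, 1]")
        if c.entry_ward not in config.wards:
            findings.append(f"{path}.entry_ward: unknown ward {c.entry_ward!r}")
        for ward, vec in c.routing.items():
            vpath = f"{path}.routing[{ward}]"
            if ward not in config.wards:
                findings.append(f"{vpath}: unknown ward")
                continue
            if any(k not in DESTINATIONS for k in vec):
                findings.append(f"{vpath}: destinations must be among {DESTINATIONS}")
            if any(v < 0 for v in vec.values()):
                findings.append(f"{vpath}: negative probability")
            if ward == "rehab" and vec.get("rehab", 0.0) > 0:
                findings.append(f"{vpath}: rehab cannot route to itself")
            total = sum(vec.values())
            if abs(total - 1.0) > _TOL:
                findings.append(f"{vpath}: probabilities sum to {total!r}, not 1")
        for (ward, esd), model in c.los.items():
            lpath = f"{path}.los[{ward}:{'esd' if esd else 'no_esd'}]"
            if ward not in config.wards:
                findings.append(f"{lpath}: unknown ward")
            try:
                m = model.mean()
                if not (m > 0 and math.isfinite(m)):
                    findings.append(f"{lpath}: implied mean must be positive and finite")
            except (ValueError, KeyError) as exc:
                findings.append(f"{lpath}: {exc}")
            if any(not math.isfinite(v) for v in model.params.values()):
                findings.append(f"{lpath}: non-finite parameter")
        # ESD flag consistency with the routing-derived total.
        try:
            derived = c.route_esd_total()
            if abs(derived - c.esd_eligible_prob) > 1e-6:
                findings.append(
                    f"{path}.esd_eligible_prob: {c.esd_eligible_prob:.6f} inconsistent "
                    f"with routing-derived P(route->ESD)={derived:.6f}"
                )
        except Exception as exc:  # pragma: no cover - defensive
            findings.append(f"{path}.routing: {exc}")

    seas = config.seasonality
    for prof_name, prof, length in (
        ("day_of_week", seas.day_of_week, 7),
        ("quarter", seas.quarter, 4),
    ):
        spath = f"seasonality.{prof_name}"
        if len(prof) != length:
            findings.append(f"{spath}: expected length {length}")
            continue
        if any(v <= 0 for v in prof):
            findings.append(f"{spath}: multipliers must be positive")
        mean = sum(prof) / length
        if abs(mean - 1.0) > _TOL:
            findings.append(f"{spath}: multipliers average to {mean!r}, not 1")
    return findings


# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

#: Offered-load calibration targets (beds) for the default configuration; the
#: fitted LOS parameters of the study hospital are not published, so LOS means
#: are chosen to make mean unfettered occupancy match the reported ward
#: averages (9 acute, 10 rehab, to the nearest bed).
DEFAULT_LOAD_TARGETS = {"acute": 8.5, "rehab": 10.0}

#: Calibrated default: probability a stroke patient is transferred from the
#: acute unit to inpatient rehabilitation (not printed for the study site).
STROKE_REHAB_PROB = 0.40


def build_default_config() -> PathwayConfig:
    """The default pathway: study-anchored arrivals and routing, LOS calibrated
    so ward offered loads are ``DEFAULT_LOAD_TARGETS``.

    Arrival anchors: a stroke patient needs an acute bed every 1.2 days; the
    other classes' interarrival means scale with the study admission counts
    (stroke 1320, TIA 158, complex-neuro 456, other 510).  Note the printed
    1.2-day figure is slightly slower than 1320 strokes in 46 months would
    imply (~1.06 days); the printed figure is used.
    """
    counts = STUDY_CLASS_COUNTS
    inter = {
        name: 1.2 * counts["stroke"] / counts[name] for name in CLASS_NAMES
    }
    stroke_esd_acute = STUDY_ESD_FROM_ACUTE / counts["stroke"]  # 300/1320
    esd_from_rehab = (STUDY_ESD_TOTAL - STUDY_ESD_FROM_ACUTE) / (
        counts["stroke"] * STROKE_REHAB_PROB
    )  # 163/528
    classes = [
        PatientClassSpec(
            name="stroke",
            interarrival_mean=inter["stroke"],
            esd_eligible_prob=STUDY_ESD_TOTAL / counts["stroke"],
            routing={
                "acute": {
                    "rehab": STROKE_REHAB_PROB,
                    "esd": stroke_esd_acute,
                    "exit": 1.0 - STROKE_REHAB_PROB - stroke_esd_acute,
                },
                "rehab": {"esd": esd_from_rehab, "exit": 1.0 - esd_from_rehab},
            },
            los={
                ("acute", True): lognormal_from_mean(6.0, 0.9),
                ("acute", False): lognormal_from_mean(8.0, 0.9),
                ("rehab", True): lognormal_from_mean(20.0, 0.8),
                ("rehab", False): lognormal_from_mean(28.0, 0.8),
            },
        ),
        PatientClassSpec(
            name="tia",
            interarrival_mean=inter["tia"],
            esd_eligible_prob=0.0,
            routing={"acute": {"exit": 1.0}},
            los={("acute", False): lognormal_from_mean(1.5, 0.7)},
        ),
        PatientClassSpec(
            name="complex_neuro",
            interarrival_mean=inter["complex_neuro"],
            esd_eligible_prob=0.0,
            routing={
                "acute": {"rehab": 0.11, "exit": 0.89},
                "rehab": {"exit": 1.0},
            },
            los={
                ("acute", False): lognormal_from_mean(4.0, 1.0),
                ("rehab", False): lognormal_from_mean(25.0, 0.8),
            },
        ),
        PatientClassSpec(
            name="other",
            interarrival_mean=inter["other"],
            esd_eligible_prob=0.0,
            routing={"acute": {"exit": 1.0}},
            los={("acute", False): lognormal_from_mean(3.0, 1.0)},
        ),
    ]
    config = PathwayConfig(classes=classes)
    return calibrate_offered_load(config, DEFAULT_LOAD_TARGETS)
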