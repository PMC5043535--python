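"""Model/Results interface over the simulation and estimation machinery.

:class:`UnfetteredDemandModel` plays the role of a statistical model object:
it is constructed from a pathway configuration (or estimated from an
admissions table via :meth:`from_records`), and ``simulate`` returns an
:class:`UnfetteredDemandResults` object carrying the occupancy audits together
with delay estimates, replication uncertainty and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .config import (
    BedPlan,
    PathwayConfig,
    Scenario,
    apply_scenario,
    build_default_config,
    offered_loads,
    validate_config,
)
from .engine import RunSpec, run_experiment
from .occupancy import occupancy_pmf, one_in_n, prob_delay, tradeoff_curve
from .pooling import joint_occupancy_pmf, partial_pool_delay


class UnfetteredDemandModel:
    """Unconstrained patient-flow model of the acute/rehab stroke pathway."""

    def __init__(self, config: PathwayConfig | None = None):
        self.config = config if config is not None else build_default_config()
        findings = validate_config(self.config)
        if findings:
            raise ValueError(
                "invalid pathway configuration:\n  " + "\n  ".join(findings)
            )

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "UnfetteredDemandModel":
        """Estimate the configuration from an admissions table and build the
        model from it (see :mod:`strokecap.fitting`)."""
        from .fitting import estimate_config

        config, _ = estimate_config(records)
        return cls(config)

    def with_scenario(self, scenario: Scenario | str) -> "UnfetteredDemandModel":
        return UnfetteredDemandModel(apply_scenario(self.config, scenario))

    def offered_loads(self) -> dict[str, float]:
        return offered_loads(self.config)

    def simulate(self, spec: RunSpec | None = None, **overrides) -> "UnfetteredDemandResults":
        """Run the replicated experiment and wrap the audits in a results
        object.  Keyword overrides (e.g. ``n_reps=30, base_seed=7``) modify the
        default :class:`RunSpec`."""
        if spec is None:
            spec = RunSpec(**overrides)
        elif overrides:
            raise TypeError("pass either a RunSpec or keyword overrides, not both")
        collection = run_experiment(self.config, spec)
        return UnfetteredDemandResults(self, spec, collection)


class UnfetteredDemandResults:
    """Occupancy audits plus the derived capacity-planning quantities."""

    def __init__(self, model: UnfetteredDemandModel, spec: RunSpec, collection):
        self.model = model
        self.spec = spec
        self.audits = collection

    def mean_occupancy(self, ward: str) -> float:
        return float(occupancy_pmf(self.audits[ward]).mean())

    def occupancy_pmf(self, ward: str):
        return occupancy_pmf(self.audits[ward])

    def prob_delay(self, ward: str, beds: int) -> float:
        return prob_delay(self.occupancy_pmf(ward), beds)

    def tradeoff(self, ward: str, beds) -> pd.DataFrame:
        table = tradeoff_curve(self.audits[ward], beds)
        return pd.DataFrame(
            {
                "beds": [e.beds for e in table],
                "p_delay": [e.p_delay for e in table],
                "one_in_n": [e.one_in_n for e in table],
                "ci_low": [e.ci_low for e in table],
                "ci_high": [e.ci_high for e in table],
            }
        )

    def pooling(self, plans: list[BedPlan]) -> pd.DataFrame:
        joint = joint_occupancy_pmf(self.audits["acute"], self.audits["rehab"])
        rows = [partial_pool_delay(joint, plan) for plan in plans]
        return pd.DataFrame(
            {
                "dedicated_acute": [r.bed_plan.dedicated_acute for r in rows],
                "dedicated_rehab": [r.bed_plan.dedicated_rehab for r in rows],
                "pooled": [r.bed_plan.pooled for r in rows],
                "p_delay_acute": [r.p_delay_acute for r in rows],
                "p_delay_rehab": [r.p_delay_rehab for r in rows],
            }
        )

    def plot_tradeoff(self, ward: str, beds, ax=None):
        import matplotlib.pyplot as plt

        table = tradeoff_curve(self.audits[ward], beds)
        if ax is None:
            _, ax = plt.subplots()
        ax.step([e.beds for e in table], [e.p_delay for e in table], where="post")
        ax.set_xlabel(f"No. of {ward} beds")
        ax.set_ylabel("p(delay)")
        return ax

    def summary(self, bed_ranges: dict[str, range] | None = None) -> str:
        from .scenarios import DEFAULT_BED_RANGES

        bed_ranges = bed_ranges or DEFAULT_BED_RANGES
        loads = self.model.offered_loads()
        buf = io.StringIO()
        buf.write("Unfettered demand simulation\n")
        buf.write(
            f"  replications: {self.spec.n_reps}   audited days/rep: "
            f"{int(np.floor(self.spec.run_length))}   warm-up: {self.spec.warmup:g} d\n"
        )
        for ward in self.model.config.wards:
            pmf = self.occupancy_pmf(ward)
            buf.write(
                f"\n{ward} ward: offered load {loads[ward]:.2f}, "
                f"simulated mean occupancy {pmf.mean():.2f}\n"
            )
            buf.write("  beds  p(delay)  1-in-every\n")
            for beds in bed_ranges.get(ward, []):
                p = prob_delay(pmf, beds)
                n = one_in_n(p)
                n_str = "no delays" if not np.isfinite(n) else f"{int(n)}"
                buf.write(f"  {beds:4d}    {p:6.2f}  {n_str:>10}\n")
        return buf.getvalue()
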