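"""End-to-end scenario orchestration and report rendering.

Runs the five planning scenarios (current admissions, 5% more admissions,
full pooling, partial pooling, no complex-neurological patients) with common
random numbers, producing per-ward bed-count/delay tables and, for pooling
scenarios, a dedicated/pooled bed-plan table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .config import (
    BedPlan,
    PathwayConfig,
    Scenario,
    apply_scenario,
)
from .engine import RunSpec, run_experiment
from .occupancy import DelayEstimate, one_in_n, tradeoff_curve
from .pooling import PoolingResult, joint_occupancy_pmf, partial_pool_delay

#: Default candidate bed ranges per ward.
DEFAULT_BED_RANGES = {"acute": range(9, 15), "rehab": range(10, 17)}

#: Bed plans for the pooling analysis: full pooling of the current stock (22)
#: and of an expanded stock (26), then partial pooling of the 26 beds with a
#: pool of 0 and of 4-9 beds.
TABLE_PLANS_FULL = [BedPlan(0, 0, 22), BedPlan(0, 0, 26)]
TABLE_PLANS_PARTIAL = [
    BedPlan(14, 12, 0),
    BedPlan(11, 11, 4),
    BedPlan(11, 10, 5),
    BedPlan(10, 10, 6),
    BedPlan(10, 9, 7),
    BedPlan(9, 9, 8),
    BedPlan(9, 8, 9),
]


@dataclass
class ScenarioResult:
    scenario: Scenario
    ward_tables: dict[str, list[DelayEstimate]]
    pooling_table: list[PoolingResult] | None
    provenance: dict

    def mean_occupancy(self) -> dict[str, float]:
        return self.provenance["mean_occupancy"]


def _default_plans(name: str) -> list[BedPlan] | None:
    if name == "full_pool":
        return list(TABLE_PLANS_FULL)
    if name == "partial_pool":
        return TABLE_PLANS_FULL[1:] + TABLE_PLANS_PARTIAL
    return None


def run_scenarios(
    config: PathwayConfig,
    scenarios: list[Scenario | str],
    spec: RunSpec | None = None,
    bed_ranges: dict[str, range] | None = None,
    pooling_plans: dict[str, list[BedPlan]] | None = None,
) -> list[ScenarioResult]:
    """Transform, simulate and summarise each scenario.

    All scenarios reuse the same replication substreams (common random
    numbers), so paired differences between scenarios are variance-reduced.
    """
    spec = spec or RunSpec()
    bed_ranges = bed_ranges or DEFAULT_BED_RANGES
    results = []
    for sc in scenarios:
        if isinstance(sc, str):
            sc = Scenario.from_name(sc)
        try:
            transformed = apply_scenario(config, sc)
            collection = run_experiment(transformed, spec)
            ward_tables = {
                ward: tradeoff_curve(collection[ward], bed_ranges.get(ward, []))
                for ward in transformed.wards
                if bed_ranges.get(ward)
            }
            plans = (pooling_plans or {}).get(sc.name) or (
                [sc.bed_plan] if sc.bed_plan else _default_plans(sc.name)
            )
            pooling_table = None
            if plans:
                joint = joint_occupancy_pmf(collection["acute"], collection["rehab"])
                pooling_table = [partial_pool_delay(joint, plan) for plan in plans]
            mean_occ = {
                ward: float(
                    sum(a.counts.sum() for a in audits)
                    / sum(a.counts.size for a in audits)
                )
                for ward, audits in collection.items()
            }
        except Exception as exc:
            raise RuntimeError(f"scenario {sc.name!r} failed") from exc
        results.append(
            ScenarioResult(
                scenario=sc,
                ward_tables=ward_tables,
                pooling_table=pooling_table,
                provenance={
                    "config_sha256": config.sha256(),
                    "scenario": {
                        "name": sc.name,
                        "admission_multiplier": sc.admission_multiplier,
                        "excluded_classes": sorted(sc.excluded_classes),
                    },
                    "run_spec": {
                        "warmup": spec.warmup,
                        "run_length": spec.run_length,
                        "n_reps": spec.n_reps,
                        "audit_epoch": spec.audit_epoch,
                        "base_seed": spec.base_seed,
                    },
                    "mean_occupancy": mean_occ,
                },
            )
        )
    return results


def _fmt_one_in_n(v: float) -> str:
    return "no delays" if math.isinf(v) else str(int(v))


def render_report(
    results: list[ScenarioResult], out_dir, plot: bool = False
) -> list[Path]:
    """Write CSV and JSON tables per scenario; optionally a trade-off step plot.

    Single-ward tables round p(delay) to 2 decimal places, pooling tables to
    3; the "1 in every n" column is always the nearest integer of the
    *unrounded* probability.
    """
    if not results:
        raise ValueError("no scenario results to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for res in results:
        if not res.ward_tables and not res.pooling_table:
            raise ValueError(f"scenario {res.scenario.name!r} produced no tables")
        payload = {"provenance": res.provenance, "wards": {}, "pooling": None}
        for ward, table in res.ward_tables.items():
            if not table:
                raise ValueError(f"empty ward table for {ward!r}")
            path = out_dir / f"{res.scenario.name}_{ward}.csv"
            lines = ["beds,p_delay,one_in_n,ci_low,ci_high"]
            for est in table:
                lines.append(
                    f"{est.beds},{est.p_delay:.2f},{_fmt_one_in_n(est.one_in_n)},"
                    f"{est.ci_low:.4f},{est.ci_high:.4f}"
                )
            path.write_text("\n".join(lines) + "\n")
            written.append(path)
            payload["wards"][ward] = [
                {
                    "beds": est.beds,
                    "p_delay": est.p_delay,
                    "one_in_n": est.one_in_n if math.isfinite(est.one_in_n) else None,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
                for est in table
            ]
        if res.pooling_table:
            path = out_dir / f"{res.scenario.name}_pooling.csv"
            lines = [
                "dedicated_acute,dedicated_rehab,pooled,"
                "p_delay_acute,p_delay_rehab,one_in_n_acute,one_in_n_rehab"
            ]
            for pr in res.pooling_table:
                plan = pr.bed_plan
                lines.append(
                    f"{plan.dedicated_acute},{plan.dedicated_rehab},{plan.pooled},"
                    f"{pr.p_delay_acute:.3f},{pr.p_delay_rehab:.3f},"
                    f"{_fmt_one_in_n(one_in_n(pr.p_delay_acute))},"
                    f"{_fmt_one_in_n(one_in_n(pr.p_delay_rehab))}"
                )
            path.write_text("\n".join(lines) + "\n")
            written.append(path)
            payload["pooling"] = [
                {
                    "dedicated_acute": pr.bed_plan.dedicated_acute,
                    "dedicated_rehab": pr.bed_plan.dedicated_rehab,
                    "pooled": pr.bed_plan.pooled,
                    "p_delay_acute": pr.p_delay_acute,
                    "p_delay_rehab": pr.p_delay_rehab,
                }
                for pr in res.pooling_table
            ]
        jpath = out_dir / f"{res.scenario.name}.json"
        jpath.write_text(json.dumps(payload, indent=2))
        written.append(jpath)
        if plot and res.ward_tables:
            written.extend(_plot_tradeoff(res, out_dir))
    return written


def _plot_tradeoff(res: ScenarioResult, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for ward, table in res.ward_tables.items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        beds = [e.beds for e in table]
        ax.step(beds, [e.p_delay for e in table], where="post")
        ax.set_xlabel(f"No. of {ward} beds")
        ax.set_ylabel("p(delay)")
        ax.set_title(f"{res.scenario.name}: {ward}")
        fig.tight_layout()
        path = out_dir / f"{res.scenario.name}_{ward}_tradeoff.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
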