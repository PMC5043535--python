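"""Delay probabilities for co-located wards with dedicated and pooled beds.

For a bed plan with ``d_a`` dedicated acute beds, ``d_r`` dedicated rehab beds
and a shared pool of ``p`` beds, a joint occupancy ``(x, y)`` is feasible when
an assignment of patients to beds exists, i.e.

    max(x - d_a, 0) + max(y - d_r, 0) <= p.

The delay probability for the acute stream is computed by truncating the
*unconstrained* joint occupancy distribution to the feasible set F and summing
probability over the feasible states from which one more acute admission would
leave F (and symmetrically for rehab):

    p(delay, acute) = P{(x, y) in F : (x+1, y) not in F} / P(F).

With no rehab beds and no pool this collapses exactly to the single-ward
truncated ratio P(N = d_a)/P(N <= d_a).  The construction generalises the
Erlang-loss truncation: for reversible (e.g. exponential-stay) two-stream loss
systems it is the exact stationary distribution of the constrained system, and
for the general pathway it is validated empirically against
:func:`finite_capacity_oracle`, a direct simulation of the bed-constrained
system in which blocked patients are counted and lost.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .config import BedPlan, PathwayConfig
from .engine import OccupancyAudit
from .sampling import DEST_REHAB, draw_pathway


@dataclass
class JointOccupancyPMF:
    """Empirical joint distribution of same-day (acute, rehab) occupancies."""

    p: np.ndarray  # 2-D array indexed [acute, rehab]
    n_days: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2:
            raise ValueError("joint PMF must be two-dimensional")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("joint probabilities must sum to 1")

    @property
    def probabilities(self) -> dict[tuple[int, int], float]:
        out = {}
        for (x, y), v in np.ndenumerate(self.p):
            if v > 0:
                out[(int(x), int(y))] = float(v)
        return out

    def marginal(self, axis_ward: str) -> np.ndarray:
        if axis_ward == "acute":
            return self.p.sum(axis=1)
        if axis_ward == "rehab":
            return self.p.sum(axis=0)
        raise ValueError(axis_ward)


@dataclass
class PoolingResult:
    bed_plan: BedPlan
    p_delay_acute: float
    p_delay_rehab: float


def joint_occupancy_pmf(
    acute_audits: list[OccupancyAudit], rehab_audits: list[OccupancyAudit]
) -> JointOccupancyPMF:
    """Pool same-day joint occupancy frequencies over replications.

    The two audit lists must come from the same replications (matching rep ids
    and day counts), otherwise the pairing is meaningless and an error is
    raised.
    """
    if len(acute_audits) != len(rehab_audits):
        raise ValueError("audit lists differ in number of replications")
    xs, ys = [], []
    for a, r in zip(acute_audits, rehab_audits):
        if a.rep_id != r.rep_id or a.counts.size != r.counts.size:
            raise ValueError(
                f"misaligned audits: rep {a.rep_id}/{r.rep_id}, "
                f"{a.counts.size}/{r.counts.size} days"
            )
        xs.append(a.counts)
        ys.append(r.counts)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size == 0:
        raise ValueError("audits contain no days")
    grid = np.zeros((int(x.max()) + 1, int(y.max()) + 1))
    np.add.at(grid, (x, y), 1.0)
    return JointOccupancyPMF(p=grid / x.size, n_days=int(x.size))


def _feasible(x: int, y: int, plan: BedPlan) -> bool:
    return max(x - plan.dedicated_acute, 0) + max(y - plan.dedicated_rehab, 0) <= plan.pooled


def partial_pool_delay(joint: JointOccupancyPMF, plan: BedPlan) -> PoolingResult:
    """Feasible-state truncation delay probabilities for a bed plan."""
    if plan.total <= 0:
        raise ValueError("bed plan must contain at least one bed")
    p_f = 0.0
    p_block_a = 0.0
    p_block_r = 0.0
    for (x, y), prob in np.ndenumerate(joint.p):
        if prob == 0.0 or not _feasible(x, y, plan):
            continue
        p_f += prob
        if not _feasible(x + 1, y, plan):
            p_block_a += prob
        if not _feasible(x, y + 1, plan):
            p_block_r += prob
    if p_f <= 0.0:
        raise ValueError("no feasible state has positive probability")
    return PoolingResult(
        bed_plan=plan,
        p_delay_acute=p_block_a / p_f,
        p_delay_rehab=p_block_r / p_f,
    )


# ---------------------------------------------------------------------------
# Finite-capacity oracle
# ---------------------------------------------------------------------------

_ARRIVAL, _DEPART_ENTRY, _DEPART_REHAB = 0, 1, 2


def finite_capacity_oracle(
    config: PathwayConfig,
    plan: BedPlan,
    horizon: float,
    seed: int,
    warmup: float = 0.0,
    rep_id: int = 0,
    repack: bool = True,
) -> PoolingResult:
    """Direct event-driven simulation of the bed-constrained system.

    An admission (or transfer) first uses its own ward's dedicated beds, then
    the pool; if neither has space the patient is counted as delayed and lost
    (Erlang-loss discipline), and any downstream stay never happens.  With the
    default ``repack=True`` a patient occupying a pooled bed is moved into
    their ward's dedicated stock as soon as one frees (equivalently, admission
    is decided from the occupancy counts alone), so the occupied states are
    exactly the feasible set of :func:`partial_pool_delay`.  With
    ``repack=False`` bed assignments are sticky — a pooled bed stays occupied
    even when a dedicated bed is free — which blocks slightly more often.
    Intended for small instances (total beds of order a dozen), where it
    serves as the independent check on :func:`partial_pool_delay`.
    """
    draws = draw_pathway(config, horizon, seed, rep_id)
    events: list[tuple[float, int, int, int, int]] = []
    # (time, order, kind, draw_index, patient_index); heap order breaks ties.
    order = 0
    for di, d in enumerate(draws):
        for pi in range(d.n):
            events.append((float(d.arrivals[pi]), order, _ARRIVAL, di, pi))
            order += 1
    heapq.heapify(events)

    occ = {"acute": 0, "rehab": 0}
    ded = {"acute": plan.dedicated_acute, "rehab": plan.dedicated_rehab}
    pool_free = plan.pooled
    in_pool = {"acute": 0, "rehab": 0}  # only used when repack=False
    bed_kind: dict[tuple[int, int, str], str] = {}
    attempts = {"acute": 0, "rehab": 0}
    blocked = {"acute": 0, "rehab": 0}

    def try_admit(ward: str, t: float, di: int, pi: int) -> bool:
        nonlocal pool_free
        if t >= warmup:
            attempts[ward] += 1
        if repack:
            x = occ["acute"] + (1 if ward == "acute" else 0)
            y = occ["rehab"] + (1 if ward == "rehab" else 0)
            if _feasible(x, y, plan):
                occ[ward] += 1
                return True
        else:
            if occ[ward] - in_pool[ward] < ded[ward]:
                occ[ward] += 1
                bed_kind[(di, pi, ward)] = "ded"
                return True
            if pool_free > 0:
                pool_free -= 1
                in_pool[ward] += 1
                occ[ward] += 1
                bed_kind[(di, pi, ward)] = "pool"
                return True
        if t >= warmup:
            blocked[ward] += 1
        return False

    def release(ward: str, di: int, pi: int) -> None:
        nonlocal pool_free
        occ[ward] -= 1
        if not repack:
            kind = bed_kind.pop((di, pi, ward))
            if kind == "pool":
                pool_free += 1
                in_pool[ward] -= 1

    while events:
        t, _, kind, di, pi = heapq.heappop(events)
        d = draws[di]
        if kind == _ARRIVAL:
            ward = d.entry_ward
            if try_admit(ward, t, di, pi):
                order += 1
                heapq.heappush(
                    events, (t + float(d.entry_los[pi]), order, _DEPART_ENTRY, di, pi)
                )
        elif kind == _DEPART_ENTRY:
            release(d.entry_ward, di, pi)
            # Transfer instantly to rehab if the sampled route continues there.
            if d.entry_ward == "acute" and d.entry_dest[pi] == DEST_REHAB:
                if try_admit("rehab", t, di, pi):
                    order += 1
                    heapq.heappush(
                        events, (t + float(d.rehab_los[pi]), order, _DEPART_REHAB, di, pi)
                    )
        else:
            release("rehab", di, pi)

    def frac(w: str) -> float:
        return blocked[w] / attempts[w] if attempts[w] else 0.0

    return PoolingResult(
        bed_plan=plan, p_delay_acute=frac("acute"), p_delay_rehab=frac("rehab")
    )
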