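"""Patient-level sampling shared by the unfettered engine, the synthetic-data
generator and the finite-capacity oracle.

Each replication/class/purpose triple gets its own independent random
substream derived from ``(base_seed, rep_id, class_index, purpose)`` via
``numpy.random.SeedSequence``.  Because the substream identity does not depend
on the scenario, scenarios compared at the same ``rep_id`` share common random
numbers, which variance-reduces paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CLASS_NAMES, PathwayConfig, PatientClassSpec, Seasonality

_PURPOSES = {"arrival": 0, "routing": 1, "los": 2, "codes": 3}

DEST_EXIT, DEST_REHAB, DEST_ESD = 0, 1, 2
DEST_LABELS = {DEST_EXIT: "exit", DEST_REHAB: "rehab", DEST_ESD: "esd"}


def substream(base_seed: int, rep_id: int, class_name: str, purpose: str):
    """Independent ``numpy`` Generator for one (rep, class, purpose) triple."""
    cls_idx = CLASS_NAMES.index(class_name)
    ss = np.random.SeedSequence(
        entropy=int(base_seed), spawn_key=(int(rep_id), cls_idx, _PURPOSES[purpose])
    )
    return np.random.default_rng(ss)


def _arrival_times(
    rate: float, horizon: float, seasonality: Seasonality, rng
) -> np.ndarray:
    """Poisson arrival instants on [0, horizon); thinning when non-flat."""
    if rate <= 0:
        return np.empty(0)
    peak = rate * seasonality.peak() if not seasonality.is_flat() else rate
    times = []
    t = 0.0
    # Draw gaps in blocks; extend until the horizon is crossed.
    expected = peak * horizon
    block = max(int(expected + 6 * np.sqrt(expected + 1.0)) + 16, 16)
    while t < horizon:
        gaps = rng.exponential(1.0 / peak, block)
        cand = t + np.cumsum(gaps)
        times.append(cand)
        t = cand[-1]
    cand = np.concatenate(times)
    cand = cand[cand < horizon]
    if not seasonality.is_flat():
        accept = rng.random(cand.size) * seasonality.peak() <= np.array(
            [seasonality.multiplier(x) for x in cand]
        )
        cand = cand[accept]
    return cand


@dataclass
class ClassDraw:
    """Sampled pathway journeys for every patient of one class in one
    replication.  All arrays are aligned by patient; ``rehab_*`` entries are
    NaN / -1 for patients who never occupy the rehabilitation ward."""

    name: str
    entry_ward: str
    arrivals: np.ndarray  # admission instants (days)
    esd_flag: np.ndarray  # bool: sampled route ends in ESD
    entry_los: np.ndarray
    entry_dest: np.ndarray  # int codes (DEST_*)
    rehab_start: np.ndarray  # NaN when no rehab stay
    rehab_los: np.ndarray
    rehab_dest: np.ndarray  # int codes; -1 when no rehab stay

    @property
    def n(self) -> int:
        return self.arrivals.size

    def ward_stays(self, ward: str) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) arrays of every stay on ``ward``."""
        if ward == self.entry_ward:
            return self.arrivals, self.arrivals + self.entry_los
        if ward == "rehab":
            mask = ~np.isnan(self.rehab_start)
            return self.rehab_start[mask], self.rehab_start[mask] + self.rehab_los[mask]
        return np.empty(0), np.empty(0)


def _sample_dest(vec: dict[str, float], rng, size: int) -> np.ndarray:
    p = np.array([vec.get("exit", 0.0), vec.get("rehab", 0.0), vec.get("esd", 0.0)])
    u = rng.random(size)
    cum = np.cumsum(p)
    return np.searchsorted(cum, u, side="right").clip(0, 2).astype(np.int64)


def _sample_los(model, rng, size: int) -> np.ndarray:
    return np.asarray(model.sample(rng, size), dtype=float)


def draw_class(
    cls: PatientClassSpec,
    seasonality: Seasonality,
    horizon: float,
    base_seed: int,
    rep_id: int,
) -> ClassDraw:
    """Sample every journey of one class over ``[0, horizon)``.

    The full route is sampled first; the ESD flag is then the indicator that
    the route ends in ESD, and the LOS on each ward is drawn from the
    class's ``(ward, esd_flag)`` model.  Transfers are instantaneous: the
    rehabilitation stay starts exactly when the acute stay ends (unfettered
    flow).
    """
    rng_arr = substream(base_seed, rep_id, cls.name, "arrival")
    rng_rout = substream(base_seed, rep_id, cls.name, "routing")
    rng_los = substream(base_seed, rep_id, cls.name, "los")

    arrivals = _arrival_times(cls.arrival_rate(), horizon, seasonality, rng_arr)
    n = arrivals.size
    entry = cls.entry_ward
    entry_dest = _sample_dest(cls.routing.get(entry, {"exit": 1.0}), rng_rout, n)

    rehab_dest = np.full(n, -1, dtype=np.int64)
    to_rehab = (entry_dest == DEST_REHAB) & (entry != "rehab")
    n_rehab = int(to_rehab.sum())
    if n_rehab:
        rehab_dest[to_rehab] = _sample_dest(
            cls.routing.get("rehab", {"exit": 1.0}), rng_rout, n_rehab
        )

    esd_flag = (entry_dest == DEST_ESD) | (rehab_dest == DEST_ESD)

    entry_los = np.empty(n)
    for flag in (True, False):
        mask = esd_flag == flag
        cnt = int(mask.sum())
        if cnt:
            key = (entry, flag) if (entry, flag) in cls.los else (entry, not flag)
            entry_los[mask] = _sample_los(cls.los[key], rng_los, cnt)

    rehab_start = np.full(n, np.nan)
    rehab_los = np.full(n, np.nan)
    if n_rehab:
        rehab_start[to_rehab] = arrivals[to_rehab] + entry_los[to_rehab]
        for flag in (True, False):
            mask = to_rehab & (esd_flag == flag)
            cnt = int(mask.sum())
            if cnt:
                key = ("rehab", flag) if ("rehab", flag) in cls.los else ("rehab", not flag)
                rehab_los[mask] = _sample_los(cls.los[key], rng_los, cnt)

    return ClassDraw(
        name=cls.name,
        entry_ward=entry,
        arrivals=arrivals,
        esd_flag=esd_flag,
        entry_los=entry_los,
        entry_dest=entry_dest,
        rehab_start=rehab_start,
        rehab_los=rehab_los,
        rehab_dest=rehab_dest,
    )


def draw_pathway(
    config: PathwayConfig, horizon: float, base_seed: int, rep_id: int = 0
) -> list[ClassDraw]:
    """One replication's journeys for every class in the configuration."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return [
        draw_class(c, config.seasonality, horizon, base_seed, rep_id)
        for c in config.classes
    ]
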