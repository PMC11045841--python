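"""Ensemble statistics: quantum efficiency, velocity-phase fractions, timing.

The quantum efficiency ``phi_iso`` is the fraction of classified trajectories
that reached the isomerized product.  The analysis conditions it on the sign
and amplitude of the orbital-overlap velocity at decay (``dtau_decay``):

* fraction of the population with dtau/dt < 0 at decay,
* fraction of *reactive* trajectories with dtau/dt < 0,
* probability of being reactive given dtau/dt < 0,
* the same quantities restricted to a low-amplitude band (default
  -0.8..0 deg/fs) where the sign loses predictive power.

Unless stated otherwise fractions are computed over classified trajectories
(undecided and undecayed ones are excluded and reported); a config switch
recounts undecided/undecayed as unreactive.  All fractions carry 95% Wilson
score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from statsmodels.stats.proportion import proportion_confint

from .errors import EmptyPopulationError
from .hop_analysis import HopRecord

DEFAULT_BAND = (-0.8, 0.0)


def wilson_interval(k: int, n: int) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class ConditionTable:
    """Quantum efficiency and dtau/dt-conditioned population fractions."""

    n_total: int
    n_reactive: int
    n_unreactive: int
    n_excluded: int
    phi_iso: float
    frac_dtau_neg: float
    p_neg_given_reactive: float
    p_reactive_given_neg: float
    p_reactive_given_pos: float
    band: tuple[float, float]
    frac_in_band_of_neg: float
    p_reactive_given_band: float
    wilson_ci: tuple[float, float]
    phi_iso_full_denominator: float = float("nan")
    intervals: dict = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return self.n_reactive + self.n_unreactive

    def as_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_reactive": self.n_reactive,
            "n_unreactive": self.n_unreactive,
            "n_excluded": self.n_excluded,
            "phi_iso": self.phi_iso,
            "phi_iso_full_denominator": self.phi_iso_full_denominator,
            "frac_dtau_neg": self.frac_dtau_neg,
            "p_neg_given_reactive": self.p_neg_given_reactive,
            "p_reactive_given_neg": self.p_reactive_given_neg,
            "p_reactive_given_pos": self.p_reactive_given_pos,
            "band_lo": self.band[0],
            "band_hi": self.band[1],
            "frac_in_band_of_neg": self.frac_in_band_of_neg,
            "p_reactive_given_band": self.p_reactive_given_band,
            "wilson_lo": self.wilson_ci[0],
            "wilson_hi": self.wilson_ci[1],
        }
        return d


def _frac(k: int, n: int) -> float:
    return k / n if n else float("nan")


def condition_table(
    records: list[HopRecord],
    band: tuple[float, float] = DEFAULT_BAND,
    count_undecided_unreactive: bool = False,
) -> ConditionTable:
    """Compute the conditional-fraction table over one set of decay records.

    Velocity-conditioned fractions use records with a defined decay velocity;
    an exact tie dtau/dt == 0 counts as non-negative.
    """
    if count_undecided_unreactive:
        records = [
            r if r.classified else _relabel(r, "unreactive") for r in records
        ]
    classified = [r for r in records if r.classified]
    if not classified:
        raise EmptyPopulationError("no classified trajectories")
    n_total = len(records)
    n_reactive = sum(r.reactive for r in classified)
    n_unreactive = len(classified) - n_reactive
    n_excluded = n_total - len(classified)

    vel = [r for r in classified if r.velocity_defined and np.isfinite(r.dtau_decay)]
    neg = [r for r in vel if r.dtau_decay < 0.0]
    pos = [r for r in vel if r.dtau_decay >= 0.0]
    reactive_vel = [r for r in vel if r.reactive]
    in_band = [r for r in neg if band[0] < r.dtau_decay < band[1]]

    phi = _frac(n_reactive, len(classified))
    table = ConditionTable(
        n_total=n_total,
        n_reactive=n_reactive,
        n_unreactive=n_unreactive,
        n_excluded=n_excluded,
        phi_iso=phi,
        phi_iso_full_denominator=_frac(n_reactive, n_total),
        frac_dtau_neg=_frac(len(neg), len(vel)),
        p_neg_given_reactive=_frac(sum(r.dtau_decay < 0 for r in reactive_vel), len(reactive_vel)),
        p_reactive_given_neg=_frac(sum(r.reactive for r in neg), len(neg)),
        p_reactive_given_pos=_frac(sum(r.reactive for r in pos), len(pos)),
        band=band,
        frac_in_band_of_neg=_frac(len(in_band), len(neg)),
        p_reactive_given_band=_frac(sum(r.reactive for r in in_band), len(in_band)),
        wilson_ci=wilson_interval(n_reactive, len(classified)),
    )
    table.intervals = {
        "phi_iso": table.wilson_ci,
        "frac_dtau_neg": wilson_interval(len(neg), len(vel)) if vel else (0.0, 1.0),
        "p_reactive_given_neg": wilson_interval(sum(r.reactive for r in neg), len(neg)),
        "p_reactive_given_band": wilson_interval(sum(r.reactive for r in in_band), len(in_band)),
    }
    return table


def _relabel(record: HopRecord, label: str) -> HopRecord:
    import dataclasses

    return dataclasses.replace(record, label=label)


@dataclass
class VelocityHistogram:
    """Stacked reactive/unreactive histogram of decay velocities (deg/fs)."""

    bin_edges: np.ndarray
    counts_reactive: np.ndarray
    counts_unreactive: np.ndarray
    fine_edges: np.ndarray
    fine_counts_reactive: np.ndarray
    fine_counts_unreactive: np.ndarray
    n_clipped: int


def velocity_histogram(
    records: list[HopRecord],
    width: float = 1.0,
    start: float = -10.0,
    fine_width: float = 0.2,
    fine_range: tuple[float, float] = (-1.0, 1.0),
) -> VelocityHistogram:
    """Bin decay velocities of classified records, reactive vs unreactive.

    Bins are ``width`` wide starting at ``start`` up to ``-start``; values
    outside are clipped into the end bins (and counted).  A finer histogram
    over ``fine_range`` resolves the region around zero.
    """
    usable = [r for r in records if r.classified and r.velocity_defined
              and np.isfinite(r.dtau_decay)]
    if not usable:
        raise EmptyPopulationError("no records with defined decay velocity")
    edges = np.arange(start, -start + width / 2, width)
    fine_edges = np.arange(fine_range[0], fine_range[1] + fine_width / 2, fine_width)

    def counts(values, edges):
        clipped = np.clip(values, edges[0] + 1e-12, edges[-1] - 1e-12)
        c, _ = np.histogram(clipped, bins=edges)
        return c

    v_r = np.array([r.dtau_decay for r in usable if r.reactive])
    v_u = np.array([r.dtau_decay for r in usable if not r.reactive])
    n_clipped = int(np.sum((np.concatenate([v_r, v_u]) < edges[0]))
                    + np.sum(np.concatenate([v_r, v_u]) > edges[-1]))
    return VelocityHistogram(
        bin_edges=edges,
        counts_reactive=counts(v_r, edges),
        counts_unreactive=counts(v_u, edges),
        fine_edges=fine_edges,
        fine_counts_reactive=np.histogram(v_r, bins=fine_edges)[0],
        fine_counts_unreactive=np.histogram(v_u, bins=fine_edges)[0],
        n_clipped=n_clipped,
    )


def decay_window(records: list[HopRecord]) -> dict:
    """Initial decay time (IDT) and decay time length (DTL) of an ensemble.

    IDT is the earliest hop time, DTL the spread between earliest and latest
    hop.  Percentile-based variants (5th/95th) are reported alongside as a
    robust alternative.
    """
    if len(records) < 2:
        raise EmptyPopulationError("DTL undefined for fewer than 2 records")
    t = np.array([r.hop_time for r in records])
    p5, p95 = np.percentile(t, [5, 95])
    return {
        "idt": float(t.min()),
        "dtl": float(t.max() - t.min()),
        "idt_p5": float(p5),
        "dtl_p5_p95": float(p95 - p5),
        "mean_decay_time": float(t.mean()),
    }


def ensemble_average(
    name: str,
    ensemble,
    series_by_traj: dict[str, dict],
    on_state: int = 1,
    velocities: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Survivor-only per-frame average of one series over the ensemble.

    At each time bin only trajectories still on ``on_state`` (or above)
    contribute; once a trajectory decays it drops out, so the average tracks
    the undecayed population (the convention behind the ensemble-average
    curves of the analysis).  Returns ``(times, mean, count)``; bins with no
    surviving trajectory are NaN-masked, never zero-filled.
    """
    n_max = max(t.n_frames for t in ensemble)
    ref = max(ensemble, key=lambda t: t.n_frames)
    times = ref.times[:n_max]
    total = np.zeros(n_max)
    count = np.zeros(n_max, dtype=int)
    for traj in ensemble:
        s = series_by_traj[traj.id][name]
        data = s.velocities if velocities else s.values
        alive = traj.states >= on_state
        ok = alive & np.isfinite(data)
        idx = np.flatnonzero(ok)
        total[idx] += data[idx]
        count[idx] += 1
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return times, mean, count
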