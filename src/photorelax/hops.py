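"""Effective-hop identification and conical-intersection statistics.

An *effective* hop for a band channel (B -> Qx or Qx -> Qy) is the last
allowed hop across the band boundary after which the trajectory never
re-enters the donor band: the event that irreversibly commits the transfer.
Its time is measured from the most recent entry into the donor band, so a
trajectory contributes at most one effective hop per channel.  Events with a
donor-acceptor gap at or below 0.1 eV are classed as passing through the
immediate conical-intersection region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fssh import HopEvent, Trajectory

__all__ = ["CHANNELS", "HopStats", "hop_summary", "identify_effective_hops", "events_table"]

CHANNELS = (("B", "Qx"), ("Qx", "Qy"))

#: Donor-acceptor gap separating the near-intersection class, eV (inclusive).
CI_GAP_THRESHOLD_EV = 0.1


def identify_effective_hops(
    trajectory: Trajectory, band_map: dict[int, str] | None = None
) -> list[HopEvent]:
    """Flag the effective hop (if any) of each band channel.

    Returns the trajectory's hop list with ``effective`` set, and with the
    effective events' times re-expressed relative to the donor-band entry
    in a parallel attribute-preserving copy (the returned events carry
    absolute times; relative times are computed by :func:`hop_summary`
    callers via ``effective_hop_records``).
    """
    bands = trajectory.band_series()
    times = trajectory.times
    for ev in trajectory.hops:
        ev.effective = False
    for donor, acceptor in CHANNELS:
        in_donor = bands == donor
        if not in_donor.any():
            continue
        last_donor_step = int(np.nonzero(in_donor)[0][-1])
        # the effective hop is the allowed boundary crossing at/after which
        # the donor band is never revisited
        candidates = [
            ev
            for ev in trajectory.hops
            if ev.allowed
            and ev.from_band == donor
            and ev.to_band == acceptor
            and ev.time >= times[last_donor_step]
        ]
        if candidates:
            max(candidates, key=lambda ev: ev.time).effective = True
    return trajectory.hops


def effective_hop_records(
    trajectories, channel: tuple[str, str]
) -> pd.DataFrame:
    """Per-trajectory effective-hop events of one channel, with times
    measured from the most recent donor-band entry."""
    donor, acceptor = channel
    rows = []
    for i, tr in enumerate(trajectories):
        identify_effective_hops(tr)
        bands = tr.band_series()
        for ev in tr.hops:
            if not (ev.effective and ev.from_band == donor and ev.to_band == acceptor):
                continue
            in_donor = bands == donor
            step = int(np.searchsorted(tr.times, ev.time))
            step = min(step, len(bands) - 1)
            entries = np.nonzero(in_donor[: step + 1] & ~np.roll(in_donor[: step + 1], 1))[0]
            if in_donor[0]:
                entries = np.union1d(entries, [0])
            t_entry = tr.times[entries[-1]] if len(entries) else 0.0
            rows.append(
                {
                    "trajectory": i,
                    "channel": f"{donor}->{acceptor}",
                    "time_fs": ev.time - t_entry,
                    "delta_e_ev": ev.delta_e,
                    "nac_magnitude": ev.nac_magnitude,
                }
            )
    return pd.DataFrame(rows, columns=["trajectory", "channel", "time_fs", "delta_e_ev", "nac_magnitude"])


@dataclass
class HopStats:
    """Channel-resolved effective-hop statistics."""

    channel: str
    times: np.ndarray  # fs, relative to donor-band entry
    delta_e: np.ndarray  # eV
    nac_magnitudes: np.ndarray
    near_ci: np.ndarray  # bool per event
    threshold: float = CI_GAP_THRESHOLD_EV
    mean_time_near_ci: float | None = None
    mean_time_far: float | None = None
    near_ci_fraction_pct: float | None = None
    cumulative: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.times)


def hop_summary(events: pd.DataFrame, threshold: float = CI_GAP_THRESHOLD_EV) -> HopStats:
    """Summarise one channel's effective hops.

    Events with ``delta_e <= threshold`` (boundary inclusive) form the
    near-intersection class.  Cumulative event-count curves are returned for
    each class and their total on the sorted event times.
    """
    channel = events["channel"].iloc[0] if len(events) else ""
    if len(events):
        times = events["time_fs"].to_numpy(dtype=float)
        de = np.abs(events["delta_e_ev"].to_numpy(dtype=float))
        nac = events["nac_magnitude"].to_numpy(dtype=float)
    else:
        times = np.empty(0)
        de = np.empty(0)
        nac = np.empty(0)
    near = de <= threshold
    stats = HopStats(
        channel=channel,
        times=times,
        delta_e=de,
        nac_magnitudes=nac,
        near_ci=near,
        threshold=threshold,
    )
    if len(times) == 0:
        stats.cumulative = {"times": np.empty(0), "near_ci": np.empty(0), "far": np.empty(0), "total": np.empty(0)}
        return stats
    stats.near_ci_fraction_pct = 100.0 * near.mean()
    if near.any():
        stats.mean_time_near_ci = float(times[near].mean())
    if (~near).any():
        stats.mean_time_far = float(times[~near].mean())
    order = np.argsort(times)
    ts = times[order]
    stats.cumulative = {
        "times": ts,
        "near_ci": np.cumsum(near[order]),
        "far": np.cumsum(~near[order]),
        "total": np.arange(1, len(ts) + 1),
    }
    return stats


def events_table(trajectories) -> pd.DataFrame:
    """Long-format effective-hop event table over both channels."""
    frames = [effective_hop_records(trajectories, ch) for ch in CHANNELS]
    non_empty = [f for f in frames if len(f)]
    if not non_empty:
        return frames[0]
    return pd.concat(non_empty, ignore_index=True)
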