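"""Deviation indices against the critical strength, firing-rate profiles,
inter-spike intervals and in-degree vs rate regressions.

The network-mean synaptic strength W[t] excludes edges whose presynaptic
neuron has in-degree 0 or 1.  Depression acts only when the presynaptic
neuron fires; a neuron with no afferents fires only spontaneously, and one
with a single afferent is driven only as often as that lone input, so the
outgoing strengths of such neurons grow by 1/tau essentially unopposed and
would bias the network mean upward for reasons unrelated to the collective
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, WindowError


def network_mean_weight(weights: np.ndarray, edge_sources: np.ndarray,
                        in_degree: np.ndarray) -> float:
    """Mean strength over edges whose presynaptic neuron has in-degree >= 2."""
    w = np.asarray(weights, dtype=float)
    src = np.asarray(edge_sources, dtype=np.int64)
    k = np.asarray(in_degree)
    mask = k[src] >= 2
    if not mask.any():
        raise InsufficientDataError(
            "no edges out of neurons with in-degree >= 2")
    return float(w[mask].mean())


@dataclass
class DeviationReport:
    """Windowed deviation of the network-mean strength from W_c.

    ME is the signed mean of W[t] - W_c over t in [t_a, t_b]; MAE is the
    mean absolute deviation.  Both use divisor t_b - t_a + 1.
    """

    ME: float
    MAE: float
    t_a: int
    t_b: int
    W_c: float


def deviation_report(mean_W_series: np.ndarray, W_c: float,
                     t_a: int = 10_000, t_b: int = 100_000,
                     t0: int = 1) -> DeviationReport:
    """ME and MAE of a mean-strength series over the window [t_a, t_b].

    ``t0`` is the time index of the first series entry (simulation traces
    index from 1).
    """
    w = np.asarray(mean_W_series, dtype=float)
    if t_a >= t_b:
        raise WindowError("t_a must be smaller than t_b")
    i0, i1 = t_a - t0, t_b - t0
    if i0 < 0 or i1 >= len(w):
        raise WindowError(
            f"window [{t_a}, {t_b}] not covered by series of length {len(w)}"
            f" starting at t={t0}")
    seg = w[i0:i1 + 1] - W_c
    me = float(seg.mean())
    mae = float(np.abs(seg).mean())
    return DeviationReport(ME=me, MAE=mae, t_a=t_a, t_b=t_b, W_c=W_c)


@dataclass
class RateProfile:
    """Per-neuron firing rates, in-degrees and pooled inter-spike intervals."""

    rho: np.ndarray
    in_degree: np.ndarray
    isi: np.ndarray
    window: tuple


def rate_profile(spike_t: np.ndarray, spike_i: np.ndarray,
                 in_degree: np.ndarray,
                 window: tuple) -> RateProfile:
    """Firing rates and ISIs from a spike raster over [window[0], window[1]].

    rho_i is the spike count of neuron i in the window divided by the window
    length t_b - t_a + 1; ISIs are successive spike-time differences pooled
    over neurons (neurons with fewer than two spikes contribute none).
    """
    t_a, t_b = window
    if t_a > t_b:
        raise WindowError("window start must not exceed its end")
    length = t_b - t_a + 1
    spike_t = np.asarray(spike_t, dtype=np.int64)
    spike_i = np.asarray(spike_i, dtype=np.int64)
    sel = (spike_t >= t_a) & (spike_t <= t_b)
    st, si = spike_t[sel], spike_i[sel]
    N = len(in_degree)
    counts = np.bincount(si, minlength=N)
    rho = counts / length
    order = np.lexsort((st, si))
    st_s, si_s = st[order], si[order]
    same = si_s[1:] == si_s[:-1]
    isi = (st_s[1:] - st_s[:-1])[same]
    return RateProfile(rho=rho, in_degree=np.asarray(in_degree),
                       isi=isi.astype(np.int64), window=(t_a, t_b))


@dataclass
class RegressionLine:
    slope: float
    intercept: float
    r_value: float
    n: int


def degree_rate_regression(
        profiles: Dict[str, RateProfile]) -> Dict[str, RegressionLine]:
    """OLS fit of per-neuron firing rate on in-degree, per partition.

    ``profiles`` maps a partition label (e.g. ``"dragon_king"`` /
    ``"power_law"``) to a :class:`RateProfile`.  Partitions with fewer than
    two distinct in-degree values are omitted.
    """
    out: Dict[str, RegressionLine] = {}
    for label, prof in profiles.items():
        k = prof.in_degree.astype(float)
        if len(np.unique(k)) < 2:
            continue
        res = stats.linregress(k, prof.rho)
        out[label] = RegressionLine(slope=float(res.slope),
                                    intercept=float(res.intercept),
                                    r_value=float(res.rvalue), n=len(k))
    return out


def isi_histogram(isi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique ISI values and their counts (for the `isi, count` CSV)."""
    vals, counts = np.unique(np.asarray(isi, dtype=np.int64),
                             return_counts=True)
    return vals, counts
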