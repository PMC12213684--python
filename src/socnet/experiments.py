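"""Experiment drivers: single-run characterizations, (tau, u) phase-diagram
sweeps with regime labels and deviation maps, repeated-run ME distributions,
and the hub-activity analysis for scale-free networks.

All drivers are deterministic given the master seed: every cell of a sweep
derives its own seed from (kind, tau, u, replicate, master_seed), so sweeps
are resumable and reproducible bit for bit.

Scale: the study conditions are N = 10,000 neurons and T = 100,000 steps.
The default configuration here runs at a reduced scale (N = 2,000,
T = 50,000) chosen so that a full five-topology sweep is desk-sized while
preserving every qualitative contrast; the full-scale conditions are one
configuration away.  W_c is size- and topology-dependent, so it is
re-estimated per (kind, N, avg_degree) and cached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .avalanches import AvalancheSet, estimate_critical_point, extract_avalanches
from .dynamics import LIFParams, PlasticityParams, SimTrace, run_simulation
from .errors import (DegenerateCatalogError, InsufficientDataError,
                     WindowError)
from .metrics import RateProfile, deviation_report
from .networks import NETWORK_KINDS, DirectedNetwork, NetworkSpec, build_network
from .scaling import (TPLFit, classify_regime, dragon_king_onset,
                      empirical_ccdf, fit_truncated_power_law)

_KIND_INDEX = {k: i for i, k in enumerate(NETWORK_KINDS)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale and analysis settings shared by all experiment drivers."""

    N: int = 2000
    avg_degree: int = 8
    T: int = 50_000
    tau_grid: Sequence[float] = tuple(range(100, 1001, 100))
    u_grid: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    replicates: int = 1
    #: avalanche-detection probe: the measurement protocol counts spikes on a
    #: fixed 400-neuron subset, so avalanche sizes measure network fractions
    #: on the same absolute scale at any N
    probe: object = 400
    dk_factor: float = 1.1
    master_seed: int = 0
    lif: LIFParams = field(default_factory=LIFParams)
    # susceptibility-scan settings used when a W_c estimate is needed
    wc_w_min: float = 0.5
    wc_w_max: float = 3.0
    wc_w_step: float = 0.05
    wc_steps_per_W: int = 20_000
    #: explicit deviation window (t_a, t_b); default scales with T in the
    #: same 1:10 proportion as the full-scale window
    dev_window: Optional[tuple] = None

    @property
    def t_a(self) -> int:
        """Deviation-window start: first tenth of the run is discarded."""
        return self.dev_window[0] if self.dev_window else self.T // 10

    @property
    def t_b(self) -> int:
        return self.dev_window[1] if self.dev_window else self.T

    def network_spec(self, kind: str, seed: int) -> NetworkSpec:
        return NetworkSpec(kind=kind, N=self.N, avg_degree=self.avg_degree,
                           seed=seed)


def cell_seed(kind: str, tau: float, u: float, replicate: int,
              master_seed: int) -> int:
    """Stable per-cell seed derived from the cell coordinates."""
    ss = np.random.SeedSequence(
        [master_seed, _KIND_INDEX.get(kind, 99), int(round(tau * 10)),
         int(round(u * 1000)), replicate])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# W_c cache
# ---------------------------------------------------------------------------

def _wc_key(kind: str, config: ExperimentConfig) -> str:
    return f"{kind}_N{config.N}_k{config.avg_degree}"


def estimate_wc(kind: str, config: ExperimentConfig,
                cache: Optional[dict] = None,
                cache_path=None) -> float:
    """Critical strength for one topology at the configured scale.

    Estimates via the susceptibility scan and memoises the result in
    ``cache`` (a dict) and optionally a JSON sidecar at ``cache_path``.
    """
    key = _wc_key(kind, config)
    if cache is not None and key in cache:
        return float(cache[key])
    if cache_path is not None and Path(cache_path).exists():
        disk = json.loads(Path(cache_path).read_text())
        if key in disk:
            if cache is not None:
                cache[key] = disk[key]
            return float(disk[key])
    net = build_network(config.network_spec(kind, seed=cell_seed(
        kind, 0, 0.0, 0, config.master_seed)))
    est = estimate_critical_point(
        net, config.lif, W_min=config.wc_w_min, W_max=config.wc_w_max,
        W_step=config.wc_w_step, steps_per_W=config.wc_steps_per_W,
        seed=cell_seed(kind, 0, 0.0, 1, config.master_seed),
        probe=config.probe)
    wc = est.W_c
    if cache is not None:
        cache[key] = wc
    if cache_path is not None:
        disk = (json.loads(Path(cache_path).read_text())
                if Path(cache_path).exists() else {})
        disk[key] = wc
        Path(cache_path).write_text(json.dumps(disk, indent=2))
    return wc


# ---------------------------------------------------------------------------
# Single-run characterization (distribution + trajectory + regime)
# ---------------------------------------------------------------------------

@dataclass
class RunCharacterization:
    kind: str
    tau: float
    u: float
    seed: int
    W_c: float
    trace: SimTrace
    avalanches: AvalancheSet
    regime: str
    evidence: dict
    fit: Optional[TPLFit]
    deviation: object
    ccdf_support: np.ndarray
    ccdf_values: np.ndarray


def run_single_characterization(kind: str, config: ExperimentConfig,
                                tau: float = 500.0, u: float = 0.1,
                                W_c: Optional[float] = None,
                                replicate: int = 0,
                                record_raster: bool = False,
                                wc_cache: Optional[dict] = None
                                ) -> RunCharacterization:
    """One full run at (tau, u): catalog, CCDF with fit, W[t], regime, ME/MAE."""
    if config.T < config.t_b:
        raise WindowError("T must cover the deviation window t_b")
    if W_c is None:
        W_c = estimate_wc(kind, config, cache=wc_cache)
    seed = cell_seed(kind, tau, u, replicate, config.master_seed)
    net = build_network(config.network_spec(kind, seed=seed))
    trace = run_simulation(net, config.lif,
                           PlasticityParams(tau=tau, u=u), config.T,
                           w_init=W_c, probe=config.probe, seed=seed,
                           record_raster=record_raster)
    av = extract_avalanches(trace.probe_counts)
    regime = classify_regime(av.sizes, dk_factor=config.dk_factor)
    fit = None
    support = values = np.empty(0)
    if len(av) > 5:
        body = av.sizes[5:]
        emp = empirical_ccdf(body)
        support, values = emp.support, emp.values
        if "alpha" in regime.evidence:
            fit = fit_truncated_power_law(body)
    dev = deviation_report(trace.mean_W, W_c, t_a=config.t_a, t_b=config.t_b)
    return RunCharacterization(
        kind=kind, tau=tau, u=u, seed=seed, W_c=W_c, trace=trace,
        avalanches=av, regime=regime.label, evidence=regime.evidence,
        fit=fit, deviation=dev, ccdf_support=support, ccdf_values=values)


# ---------------------------------------------------------------------------
# Phase sweep over (tau, u)
# ---------------------------------------------------------------------------

SWEEP_COLUMNS = ["kind", "tau", "u", "replicate", "seed", "regime",
                 "ME", "MAE", "alpha", "n_avalanches", "W_c_used", "error"]


def run_phase_sweep(config: ExperimentConfig,
                    kinds: Iterable[str] = NETWORK_KINDS,
                    wc_map: Optional[Dict[str, float]] = None,
                    existing: Optional[pd.DataFrame] = None,
                    wc_cache_path=None) -> pd.DataFrame:
    """Sweep the (tau, u) grid for each topology and tabulate the outcomes.

    Every requested (kind, tau, u, replicate) cell appears exactly once in
    the result.  Cells present in ``existing`` are carried over unchanged;
    per-cell failures are recorded in the ``error`` column, never raised.
    """
    wc_cache: dict = ({_wc_key(k, config): float(v) for k, v in wc_map.items()}
                      if wc_map else {})
    done = set()
    rows = []
    if existing is not None and len(existing):
        for _, r in existing.iterrows():
            done.add((r["kind"], float(r["tau"]), float(r["u"]),
                      int(r["replicate"])))
            rows.append(dict(r))
    for kind in kinds:
        wc = estimate_wc(kind, config, cache=wc_cache,
                         cache_path=wc_cache_path)
        for tau in config.tau_grid:
            for u in config.u_grid:
                for rep in range(config.replicates):
                    key = (kind, float(tau), float(u), rep)
                    if key in done:
                        continue
                    row = {"kind": kind, "tau": float(tau), "u": float(u),
                           "replicate": rep, "W_c_used": wc, "error": ""}
                    try:
                        rc = run_single_characterization(
                            kind, config, tau=tau, u=u, W_c=wc,
                            replicate=rep)
                        row.update(seed=rc.seed, regime=rc.regime,
                                   ME=rc.deviation.ME, MAE=rc.deviation.MAE,
                                   alpha=(rc.fit.alpha if rc.fit else np.nan),
                                   n_avalanches=len(rc.avalanches))
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        row.update(seed=cell_seed(kind, tau, u, rep,
                                                  config.master_seed),
                                   regime="error", ME=np.nan, MAE=np.nan,
                                   alpha=np.nan, n_avalanches=0,
                                   error=str(exc))
                    rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


# ---------------------------------------------------------------------------
# Repeated-run ME distributions (box-plot experiment)
# ---------------------------------------------------------------------------

def run_me_replicates(kind: str, config: ExperimentConfig,
                      tau: float = 200.0, u: float = 0.5,
                      n_runs: int = 100,
                      W_c: Optional[float] = None,
                      wc_cache: Optional[dict] = None) -> pd.DataFrame:
    """ME of W[t] against W_c for ``n_runs`` independently seeded runs."""
    if W_c is None:
        W_c = estimate_wc(kind, config, cache=wc_cache)
    rows = []
    for rep in range(n_runs):
        seed = cell_seed(kind, tau, u, rep, config.master_seed)
        net = build_network(config.network_spec(kind, seed=seed))
        trace = run_simulation(net, config.lif,
                               PlasticityParams(tau=tau, u=u), config.T,
                               w_init=W_c, probe=config.probe, seed=seed)
        dev = deviation_report(trace.mean_W, W_c,
                               t_a=config.t_a, t_b=config.t_b)
        rows.append({"kind": kind, "tau": tau, "u": u, "replicate": rep,
                     "seed": seed, "ME": dev.ME, "MAE": dev.MAE})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hub-activity analysis: spike attribution by avalanche class
# ---------------------------------------------------------------------------

def partition_spikes_by_regime(trace: SimTrace, av: AvalancheSet,
                               net: DirectedNetwork,
                               fit: Optional[TPLFit] = None,
                               dk_factor: float = 1.1,
                               window: Optional[tuple] = None
                               ) -> Dict[str, RateProfile]:
    """Split raster spikes into Dragon-king vs power-law avalanche periods.

    An avalanche inherits the label of its class: Dragon-king events are the
    avalanches whose size reaches the onset of the anomalous tail (smallest
    size >= 100 where the empirical CCDF exceeds the fitted one by more than
    ``dk_factor``); all other avalanches are power-law events.  Each class's
    firing rate uses the total time spent in that class as its denominator,
    so rates are comparable across classes of different prevalence.
    """
    if trace.spike_t is None:
        raise ValueError("trace must be recorded with record_raster=True")
    if fit is None:
        # body fit: the reference scaling law the DK tail is judged against
        try:
            fit = fit_truncated_power_law(av.sizes, s_max=316)
        except (InsufficientDataError, DegenerateCatalogError):
            fit = fit_truncated_power_law(av.sizes)
    onset = dragon_king_onset(av.sizes, fit, dk_factor=dk_factor)
    t_lo, t_hi = window if window is not None else (1, trace.T)
    label = np.zeros(trace.T + 1, dtype=np.int8)  # 0 none, 1 PL, 2 DK
    for s, d, t in zip(av.sizes, av.durations, av.start_times):
        cls = 2 if (onset is not None and s >= onset) else 1
        label[t:t + d] = cls
    in_win = np.zeros(trace.T + 1, dtype=bool)
    in_win[t_lo:t_hi + 1] = True
    out: Dict[str, RateProfile] = {}
    for cls, name in ((1, "power_law"), (2, "dragon_king")):
        steps = int(np.sum((label == cls) & in_win))
        if steps == 0:
            continue
        sel = (label[trace.spike_t] == cls) & in_win[trace.spike_t]
        counts = np.bincount(trace.spike_i[sel], minlength=net.N)
        out[name] = RateProfile(rho=counts / steps,
                                in_degree=net.in_degree,
                                isi=np.empty(0, dtype=np.int64),
                                window=(t_lo, t_hi))
    return out
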