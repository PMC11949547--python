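"""Perturbation experiments on constrained parameter sets.

The battery mirrors the numerical explorations used to assign roles to
the cell types: per-cell STIM sweeps with slope extraction, a global
("milieu") STIM range scan, single-connection removals, CCK silencing/
burst/over-activation protocols, and theta-regularity statistics with
and without CCK.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .model import CellType, ModelParams, WeightSet, MASK_EDGES
from .simulate import SimConfig, StimProtocol, simulate, remove_connection
from .spectral import spectral_summary, sufficiency

__all__ = ["SweepResult", "RegularityReport", "stim_sweep",
           "global_stim_range", "connection_removal_suite", "cck_protocols",
           "regularity_analysis", "mean_reference_powers", "detect_peaks"]


def mean_reference_powers(param_sets, params: ModelParams | None = None,
                          sim_config: SimConfig | None = None) -> tuple:
    """Mean baseline theta/gamma powers over the given weight sets.

    These averages are the reference against which the 25% sufficiency
    criterion is judged in all experiments.
    """
    params = params or ModelParams()
    sim_config = sim_config or SimConfig()
    thetas, gammas = [], []
    for ws in param_sets:
        trace = simulate(params.with_weights(ws), config=sim_config)
        s = spectral_summary(trace, sim_config)
        thetas.append(s.theta_power)
        gammas.append(s.gamma_power)
    return float(np.mean(thetas)), float(np.mean(gammas))


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a per-cell STIM sweep."""

    cell: CellType
    stim_values: np.ndarray
    summaries: list
    sufficient: np.ndarray
    slopes: dict | None          # per-metric OLS slope over sufficient points
    stim_range: tuple | None     # (min, max) sufficient STIM, au
    n_sufficient: int

    @property
    def range_width(self) -> float:
        if self.stim_range is None:
            return 0.0
        return self.stim_range[1] - self.stim_range[0]


def _ols_slope(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def stim_sweep(params: ModelParams, cell: CellType, reference,
               lo: float = -2.0, hi: float = 2.0, n: int = 121,
               sim_config: SimConfig | None = None) -> SweepResult:
    """Sweep constant STIM to one cell over an equally spaced grid.

    At each grid value the model is simulated with STIM applied to
    ``cell`` only, and theta power, gamma power and theta frequency are
    extracted.  Lines of best fit for those metrics against STIM use
    only the points with sufficient theta-gamma coupling (>= 25% of the
    ``reference`` powers); slopes require at least 5 such points.
    """
    sim_config = sim_config or SimConfig()
    grid = np.linspace(lo, hi, n)
    summaries, flags = [], []
    for v in grid:
        protocol = StimProtocol.single_cell(cell, float(v))
        trace = simulate(params, protocol, sim_config)
        s = spectral_summary(trace, sim_config, reference)
        summaries.append(s)
        flags.append(bool(s.sufficient))
    flags = np.array(flags)
    n_suff = int(flags.sum())
    slopes = None
    stim_range = None
    if n_suff > 0:
        sel = grid[flags]
        stim_range = (float(sel.min()), float(sel.max()))
    if n_suff >= 5:
        x = grid[flags]
        slopes = {
            "theta_power": _ols_slope(x, [summaries[i].theta_power
                                          for i in np.where(flags)[0]]),
            "gamma_power": _ols_slope(x, [summaries[i].gamma_power
                                          for i in np.where(flags)[0]]),
            "theta_freq": _ols_slope(x, [summaries[i].theta_freq
                                         for i in np.where(flags)[0]]),
        }
    return SweepResult(cell, grid, summaries, flags, slopes, stim_range,
                       n_suff)


def global_stim_range(param_sets, reference,
                      params: ModelParams | None = None,
                      lo: float = -2.0, hi: float = 2.0, n: int = 121,
                      sim_config: SimConfig | None = None) -> dict:
    """Milieu scan: the same STIM applied to all four populations.

    Returns the extreme STIM values at which sufficiency holds, both as
    the union over the provided weight sets (any set sufficient) and as
    the intersection (all sets sufficient).
    """
    params = params or ModelParams()
    sim_config = sim_config or SimConfig()
    grid = np.linspace(lo, hi, n)
    per_set = []
    for ws in param_sets:
        trial = params.with_weights(ws)
        flags = []
        for v in grid:
            protocol = StimProtocol.constant({c: float(v) for c in CellType})
            trace = simulate(trial, protocol, sim_config)
            s = spectral_summary(trace, sim_config, reference)
            flags.append(bool(s.sufficient))
        per_set.append(np.array(flags))
    per_set = np.array(per_set)
    union = per_set.any(axis=0)
    inter = per_set.all(axis=0)

    def _range(mask):
        if not mask.any():
            return None
        sel = grid[mask]
        return (float(sel.min()), float(sel.max()))

    return {"grid": grid, "per_set_sufficient": per_set,
            "union_range": _range(union), "intersection_range": _range(inter)}


def connection_removal_suite(params: ModelParams, reference,
                             sim_config: SimConfig | None = None) -> dict:
    """Remove each mask edge singly; summarize the spectra.

    Returns per-edge SpectralSummary plus the baseline summary, with
    each removal classified by whether theta-gamma coupling is
    retained (sufficiency against ``reference``).
    """
    sim_config = sim_config or SimConfig()
    baseline = spectral_summary(simulate(params, config=sim_config),
                                sim_config, reference)
    out = {"baseline": baseline, "removals": {}}
    for edge in MASK_EDGES:
        trial = remove_connection(params, edge)
        s = spectral_summary(simulate(trial, config=sim_config),
                             sim_config, reference)
        out["removals"][f"{edge[0].name}->{edge[1].name}"] = s
    return out


#: Default duration of the brief CCK "burst" (s): one to two theta cycles.
CCK_BURST_DURATION = 0.25


def cck_protocols(params: ModelParams, reference,
                  sim_config: SimConfig | None = None,
                  burst_duration: float = CCK_BURST_DURATION) -> dict:
    """The four CCK perturbation protocols.

    (a) silence-during : STIM_CCK = -1 from t = 4 s (outcome is
        set-dependent);
    (b) silence-from-start : STIM_CCK = -1 for the whole run;
    (c) burst : STIM_CCK = -1 from t = 0, then +0.25 for a brief
        interval at t = 4 s, then 0;
    (d) strong : STIM_CCK = +20 from t = 4 s.

    Each verdict is the sufficiency of the relevant analysis window
    (1 s after any STIM switch is dropped).  For protocol (c) the
    report also records whether the first post-burst CCK peak precedes
    the first post-burst PV peak.
    """
    sim_config = sim_config or SimConfig()
    dur = sim_config.duration
    cck = CellType.CCK

    def run(segments):
        protocol = StimProtocol({cck: segments})
        return simulate(params, protocol, sim_config)

    out = {}
    # (a) silence during ongoing rhythms; analysis window drops 1 s
    # after the switch at t = 4 s
    tr = run([(0.0, 4.0, 0.0), (4.0, np.inf, -1.0)])
    out["silence_during"] = _window_verdict(tr, 5.0, dur, reference)
    # (b) silence from the start
    tr = run([(0.0, np.inf, -1.0)])
    out["silence_from_start"] = _window_verdict(
        tr, sim_config.transient_discard, dur, reference)
    # (c) burst after silent start
    tr = run([(0.0, 4.0, -1.0), (4.0, 4.0 + burst_duration, 0.25),
              (4.0 + burst_duration, np.inf, 0.0)])
    verdict = _window_verdict(tr, 4.0 + burst_duration + 1.0, dur, reference)
    post = tr.after(4.0)
    t_cck = _first_peak_time(post.cell(cck), post.times)
    t_pv = _first_peak_time(post.cell(CellType.PV), post.times)
    verdict["cck_precedes_pv"] = bool(t_cck < t_pv)
    verdict["first_cck_peak_s"] = t_cck
    verdict["first_pv_peak_s"] = t_pv
    out["burst"] = verdict
    # (d) strong activation
    tr = run([(0.0, 4.0, 0.0), (4.0, np.inf, 20.0)])
    out["strong"] = _window_verdict(tr, 5.0, dur, reference)
    return out


def _window_verdict(trace, t0, t1, reference) -> dict:
    from .spectral import welch_psd, band_peak, THETA_BAND, GAMMA_BAND
    win = trace.window(t0, t1)
    pyr = win.cell(CellType.PYR)
    pv = win.cell(CellType.PV)
    freqs, psd_pyr = welch_psd(pyr, win.fs)
    theta_freq, theta_power = band_peak(freqs, psd_pyr, THETA_BAND)
    _, psd_pv = welch_psd(pv, win.fs)
    gamma_freq, _ = band_peak(freqs, psd_pv, GAMMA_BAND)
    gamma_power = float(psd_pyr[int(np.argmin(np.abs(freqs - gamma_freq)))])
    return {"window": (t0, t1),
            "theta_freq": theta_freq, "theta_power": theta_power,
            "gamma_freq": gamma_freq, "gamma_power": gamma_power,
            "sufficient": sufficiency((theta_power, gamma_power), reference)}


def detect_peaks(signal, fs: float,
                 prominence_fraction: float = 0.10,
                 min_separation_s: float = 0.020) -> np.ndarray:
    """Indices of local maxima used for regularity statistics.

    Peaks must have prominence >= 10% of the window's amplitude range
    and be separated by >= 20 ms, which rejects gamma ripples riding on
    theta peaks.
    """
    signal = np.asarray(signal, dtype=float)
    amp = float(signal.max() - signal.min())
    if amp <= 0:
        return np.array([], dtype=int)
    peaks, _ = scipy.signal.find_peaks(
        signal, prominence=prominence_fraction * amp,
        distance=max(1, int(round(min_separation_s * fs))))
    return peaks


def _first_peak_time(signal, times) -> float:
    fs = 1.0 / (times[1] - times[0])
    peaks = detect_peaks(signal, fs)
    return float(times[peaks[0]]) if len(peaks) else np.inf


@dataclass(frozen=True)
class RegularityReport:
    """Peak statistics for the CCK-on and CCK-off windows."""

    windows: dict = field(default_factory=dict)

    def interval_std(self, window: str, cell: CellType) -> float:
        return self.windows[window][cell.name]["interval_std"]


def regularity_analysis(params: ModelParams,
                        sim_config: SimConfig | None = None) -> RegularityReport:
    """Theta regularity with and without CCK.

    10 s run, STIM_CCK = -1 applied at t = 5 s.  Peaks of PYR and BiC
    are detected in the CCK-on window [1, 5] s and the CCK-off window
    [6, 10] s (1 s after the start and after the switch is ignored),
    and mean/median/std of peak amplitudes and inter-peak intervals are
    reported per window.  Fewer than 3 peaks in a window flags its
    statistics as unreliable.
    """
    sim_config = sim_config or SimConfig(duration=10.0)
    if sim_config.duration < 10.0:
        raise ValueError("regularity analysis requires a 10 s run")
    protocol = StimProtocol({CellType.CCK: [(0.0, 5.0, 0.0),
                                            (5.0, np.inf, -1.0)]})
    trace = simulate(params, protocol, sim_config)
    windows = {}
    for label, (t0, t1) in (("cck_on", (1.0, 5.0)), ("cck_off", (6.0, 10.0))):
        win = trace.window(t0, t1)
        per_cell = {}
        for cell in (CellType.PYR, CellType.BiC):
            x = win.cell(cell)
            peaks = detect_peaks(x, win.fs)
            times = win.times[peaks]
            amps = x[peaks]
            intervals = np.diff(times)
            reliable = len(peaks) >= 3
            per_cell[cell.name] = {
                "n_peaks": int(len(peaks)),
                "peak_times": times,
                "amp_mean": float(np.mean(amps)) if len(amps) else np.nan,
                "amp_median": float(np.median(amps)) if len(amps) else np.nan,
                "amp_std": float(np.std(amps)) if len(amps) else np.nan,
                "interval_mean": (float(np.mean(intervals))
                                  if len(intervals) else np.nan),
                "interval_median": (float(np.median(intervals))
                                    if len(intervals) else np.nan),
                "interval_std": (float(np.std(intervals))
                                 if len(intervals) else np.nan),
                "reliable": reliable,
            }
        windows[label] = per_cell
    return RegularityReport(windows)
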