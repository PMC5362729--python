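"""Per-site map statistics for photostimulation input maps.

The central statistic standardizes the post-flash charge of each spot
against the across-spot distribution of baseline charge within the same
map repetition:

    Z_spot,post = (Q_post − Q̄_baseline) / SD(Q_baseline)
    Z_spot,pre  = (Q_pre  − Q̄_baseline) / SD(Q_baseline)

with three 30-ms charge windows relative to the flash at 0 ms: baseline
(−40, −10), pre-stimulus control (−70, −40) and post-stimulus (10, 40).
Spots with |Z_post| > 2.575 (two-sided normal p < 0.01) are counted as
receiving putative presynaptic input.  First-event amplitude/charge, a
150-ms post-stimulus charge, per-site response probability across
repetitions, cell-centered genotype averages, radial profiles, PSTHs and
site-averaged traces complete the map summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lspsmap.trace import Trace, DegenerateMapError
from lspsmap.synthdata import MapRecording
from lspsmap.events import detect_events_deconvolution

__all__ = [
    "ChargeWindows",
    "CellMap",
    "GenotypeMap",
    "RadialProfile",
    "Z_CUTOFF",
    "trace_baseline",
    "window_charge",
    "compute_z_scores",
    "classify_evoked",
    "first_event_metrics",
    "charge_150",
    "site_probability",
    "measure_map_repetition",
    "average_within_cell",
    "measure_cell",
    "average_across_cells",
    "radial_profile",
    "radial_bin_values",
    "peristimulus_histogram",
    "average_evoked_trace",
]

#: |Z| cutoff for putative input sites; two-sided normal quantile for p = 0.01.
Z_CUTOFF = 2.575


@dataclass(frozen=True)
class ChargeWindows:
    """The three 30-ms charge windows (ms, relative to the flash at 0)."""

    baseline: tuple = (-40.0, -10.0)
    pre_control: tuple = (-70.0, -40.0)
    post: tuple = (10.0, 40.0)

    def __post_init__(self):
        for name, (a, b) in (("baseline", self.baseline),
                             ("pre_control", self.pre_control),
                             ("post", self.post)):
            if not b > a:
                raise ValueError(f"{name} window is empty")


@dataclass
class CellMap:
    """Per-site measures for one cell, averaged across map repetitions.

    ``sites`` columns: x_um, y_um, z_post, z_pre, first_amp_pA,
    first_charge_pC, charge150_pC, prob.  First-event fields are NaN at
    sites never classified as evoked.
    """

    cell_id: str
    genotype_label: str
    sites: pd.DataFrame
    n_repetitions: int
    cell_depth_from_pia: float = float("nan")


@dataclass
class GenotypeMap:
    """Cell-centered square-binned average of one measure across cells."""

    measure: str
    bin_size: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    mean: np.ndarray  # (ny, nx), NaN where no cell contributes
    n: np.ndarray  # (ny, nx) contributing cells


@dataclass
class RadialProfile:
    """Across-cell mean ± SEM of a measure in annular distance bins."""

    measure: str
    bin_edges: np.ndarray  # µm, contiguous
    mean: np.ndarray
    sem: np.ndarray  # NaN where n < 2
    n: np.ndarray


# ---------------------------------------------------------------------------
# charges and Z scores

def trace_baseline(trace: Trace, window=(-100.0, -70.0)) -> float:
    """Holding-current baseline: mean over the early pre-flash window (pA).

    Falls back to the whole-trace mean when the window is outside the
    trace extent.
    """
    a = max(window[0], trace.t0_ms)
    b = min(window[1], trace.t_end_ms)
    if b <= a:
        return float(np.mean(trace.samples))
    return float(np.mean(trace.slice_ms(a, b)))


def window_charge(trace: Trace, t_start: float, t_end: float,
                  baseline=None, signed: bool = False) -> float:
    """Integrated baseline-subtracted current over a window, in pC.

    Times in ms on the trace axis.  ``baseline`` defaults to the early
    pre-flash mean (see :func:`trace_baseline`).  By default the
    magnitude of the integral is returned (reported charges are
    magnitudes); ``signed=True`` keeps the sign (inward events negative),
    which is what the Z-score statistic standardizes so that its null
    distribution under pure noise is Gaussian.
    """
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if baseline is None:
        baseline = trace_baseline(trace)
    seg = trace.slice_ms(t_start, t_end)  # raises when outside trace
    q = float((seg - baseline).sum() * trace.sample_interval)
    return q if signed else abs(q)


def compute_z_scores(map_rep: MapRecording,
                     windows: ChargeWindows = ChargeWindows()) -> pd.DataFrame:
    """Per-spot charge Z scores for one map repetition.

    Returns a DataFrame (one row per site) with q_base, q_pre, q_post
    (signed pC; inward events negative) and z_post, z_pre standardized by
    the across-spot mean and SD (ddof=1) of the baseline-window charge.
    Signed charges keep the null distribution Gaussian, so the |Z| >
    2.575 cutoff retains its nominal p < 0.01.
    """
    n = map_rep.n_sites
    if n < 2:
        raise ValueError("Z scores require at least 2 sites")
    q = np.empty((n, 3))
    for s in range(n):
        tr = map_rep.trace(s)
        b = trace_baseline(tr)
        q[s, 0] = window_charge(tr, *windows.baseline, baseline=b, signed=True)
        q[s, 1] = window_charge(tr, *windows.pre_control, baseline=b, signed=True)
        q[s, 2] = window_charge(tr, *windows.post, baseline=b, signed=True)
    q_bar = q[:, 0].mean()
    sd = q[:, 0].std(ddof=1)
    if sd == 0:
        raise DegenerateMapError("baseline charge has zero variance across spots")
    return pd.DataFrame({
        "site": np.arange(n),
        "x_um": map_rep.sites[:, 0],
        "y_um": map_rep.sites[:, 1],
        "q_base": q[:, 0],
        "q_pre": q[:, 1],
        "q_post": q[:, 2],
        "z_post": (q[:, 2] - q_bar) / sd,
        "z_pre": (q[:, 1] - q_bar) / sd,
    })


def classify_evoked(z, cutoff: float = Z_CUTOFF):
    """True where |z| > cutoff (putative presynaptic input site)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    out = np.abs(z) > cutoff
    return bool(out) if out.ndim == 0 else out


def first_event_metrics(events, window=(10.0, 40.0)):
    """(peak pA, charge pC) of the earliest event with onset in ``window``.

    ``events`` must be sorted by onset; returns None when no event falls
    in the window.  Pre-flash events never qualify.
    """
    for ev in events:
        if window[0] <= ev.onset < window[1]:
            return ev.peak_amplitude, ev.charge
    return None


def charge_150(trace: Trace, window_ms: float = 150.0) -> float:
    """Post-stimulus charge over [0, window_ms) ms after the flash (pC)."""
    if trace.t_end_ms < window_ms:
        raise ValueError(f"trace must extend >= {window_ms} ms past the flash")
    return window_charge(trace, 0.0, window_ms)


def site_probability(evoked_flags_per_rep) -> np.ndarray:
    """Per-site fraction of repetitions classified evoked.

    ``evoked_flags_per_rep`` is (n_reps, n_sites) boolean.  A single
    repetition yields a 0/1 map.
    """
    flags = np.atleast_2d(np.asarray(evoked_flags_per_rep, dtype=float))
    if flags.shape[0] < 1:
        raise ValueError("at least one repetition required")
    return flags.mean(axis=0)


# ---------------------------------------------------------------------------
# per-repetition and per-cell pipelines

def measure_map_repetition(map_rep: MapRecording,
                           windows: ChargeWindows = ChargeWindows(),
                           cutoff: float = Z_CUTOFF,
                           tau_rise: float = 1.0, tau_decay: float = 15.0,
                           threshold_k: float = 4.0,
                           first_event_window=(10.0, 40.0)) -> pd.DataFrame:
    """All per-site measures for one repetition.

    Charges/Z from the charge windows; events from the deconvolution
    detector; first-event amplitude and charge (and the 150-ms charge)
    reported only for sites classified evoked (|z_post| > cutoff), NaN
    elsewhere.
    """
    df = compute_z_scores(map_rep, windows)
    df["evoked"] = classify_evoked(df["z_post"].to_numpy(), cutoff)
    first_amp = np.full(map_rep.n_sites, np.nan)
    first_charge = np.full(map_rep.n_sites, np.nan)
    q150 = np.full(map_rep.n_sites, np.nan)
    for s in np.flatnonzero(df["evoked"].to_numpy()):
        tr = map_rep.trace(s)
        evs = detect_events_deconvolution(tr, tau_rise=tau_rise,
                                          tau_decay=tau_decay,
                                          threshold_k=threshold_k)
        fe = first_event_metrics(evs, first_event_window)
        if fe is not None:
            first_amp[s], first_charge[s] = fe
        q150[s] = charge_150(tr)
    df["first_amp_pA"] = first_amp
    df["first_charge_pC"] = first_charge
    df["charge150_pC"] = q150
    return df


def average_within_cell(rep_measures, cell_id="cell", genotype_label="",
                        cell_depth_from_pia=float("nan")) -> CellMap:
    """Average per-site measures across repetitions of one cell's map.

    ``rep_measures`` is a list of per-repetition DataFrames from
    :func:`measure_map_repetition` sharing grid geometry.  Z and charge
    measures are arithmetic means; first-event fields are averaged over
    the repetitions where they are defined; ``prob`` is the fraction of
    repetitions classified evoked.
    """
    if len(rep_measures) == 0:
        raise ValueError("at least one repetition required")
    ref = rep_measures[0][["x_um", "y_um"]].to_numpy()
    for m in rep_measures[1:]:
        if not np.allclose(m[["x_um", "y_um"]].to_numpy(), ref):
            raise ValueError("repetitions must share grid geometry")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stacked = {c: np.nanmean(
            np.stack([m[c].to_numpy(dtype=float) for m in rep_measures]), axis=0)
            for c in ("z_post", "z_pre", "first_amp_pA", "first_charge_pC",
                      "charge150_pC")}
    prob = site_probability(np.stack(
        [m["evoked"].to_numpy() for m in rep_measures]))
    sites = pd.DataFrame({
        "x_um": ref[:, 0], "y_um": ref[:, 1], **stacked, "prob": prob,
    })
    return CellMap(cell_id=cell_id, genotype_label=genotype_label,
                   sites=sites, n_repetitions=len(rep_measures),
                   cell_depth_from_pia=cell_depth_from_pia)


def measure_cell(recordings, cell_id="cell", genotype_label="",
                 **kwargs) -> CellMap:
    """Full pipeline: repetitions of one cell's map → averaged CellMap."""
    reps = [measure_map_repetition(r, **kwargs) for r in recordings]
    return average_within_cell(reps, cell_id=cell_id,
                               genotype_label=genotype_label)


# ---------------------------------------------------------------------------
# cross-cell summaries

def average_across_cells(cell_maps, measure: str = "z_post",
                         bin_size: float = 50.0) -> GenotypeMap:
    """Cell-centered square-binned average of one measure across cells.

    Each cell's sites are already soma-centered (soma at the origin);
    sites are assigned to the nearest square bin of side ``bin_size`` and
    a per-cell bin mean computed, then averaged across contributing
    cells.  Bins no cell contributes to are NaN, with n = 0.
    """
    if len(cell_maps) == 0:
        raise ValueError("at least one cell map required")
    half = bin_size / 2.0
    all_xy = np.vstack([cm.sites[["x_um", "y_um"]].to_numpy() for cm in cell_maps])
    kmax_x = int(np.floor((np.abs(all_xy[:, 0]).max() + half) / bin_size))
    kmax_y = int(np.floor((np.abs(all_xy[:, 1]).max() + half) / bin_size))
    x_centers = np.arange(-kmax_x, kmax_x + 1) * bin_size
    y_centers = np.arange(-kmax_y, kmax_y + 1) * bin_size
    total = np.zeros((y_centers.size, x_centers.size))
    count = np.zeros_like(total, dtype=int)
    for cm in cell_maps:
        ix = np.rint(cm.sites["x_um"].to_numpy() / bin_size).astype(int) + kmax_x
        iy = np.rint(cm.sites["y_um"].to_numpy() / bin_size).astype(int) + kmax_y
        vals = cm.sites[measure].to_numpy(dtype=float)
        cell_sum = np.zeros_like(total)
        cell_n = np.zeros_like(total)
        ok = np.isfinite(vals)
        np.add.at(cell_sum, (iy[ok], ix[ok]), vals[ok])
        np.add.at(cell_n, (iy[ok], ix[ok]), 1.0)
        has = cell_n > 0
        total[has] += cell_sum[has] / cell_n[has]
        count[has] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return GenotypeMap(measure=measure, bin_size=bin_size,
                       x_centers=x_centers, y_centers=y_centers,
                       mean=mean, n=count)


def radial_profile(cell_maps, measure: str = "first_amp_pA",
                   bin_width: float = 50.0,
                   max_radius: float = 950.0) -> RadialProfile:
    """Across-cell mean ± SEM of a measure in annular distance bins.

    Half-open bins [k·bin_width, (k+1)·bin_width); per cell, sites in a
    bin are averaged (NaN sites ignored), then the mean/SEM (ddof=1)
    taken across cells per bin.  SEM is NaN where fewer than 2 cells
    contribute.
    """
    per_cell = radial_bin_values(cell_maps, measure, bin_width, max_radius)
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    n = np.sum(np.isfinite(per_cell), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(n > 0, per_cell, np.nan), axis=0)
        sd = np.nanstd(per_cell, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    mean = np.where(n > 0, mean, np.nan)
    return RadialProfile(measure=measure, bin_edges=edges, mean=mean,
                         sem=sem, n=n)


def radial_bin_values(cell_maps, measure: str, bin_width: float = 50.0,
                      max_radius: float = 950.0) -> np.ndarray:
    """Per-cell mean of a measure in each annular distance bin.

    Returns an (n_cells, n_bins) array with half-open bins
    [k·bin_width, (k+1)·bin_width); NaN where a cell has no finite site
    value in a bin.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(max_radius / bin_width))
    per_cell = np.full((len(cell_maps), n_bins), np.nan)
    for i, cm in enumerate(cell_maps):
        xy = cm.sites[["x_um", "y_um"]].to_numpy()
        r = np.hypot(xy[:, 0], xy[:, 1])
        vals = cm.sites[measure].to_numpy(dtype=float)
        idx = np.floor(r / bin_width).astype(int)
        for b in range(n_bins):
            sel = (idx == b) & np.isfinite(vals)
            if np.any(sel):
                per_cell[i, b] = vals[sel].mean()
    return per_cell


def peristimulus_histogram(event_onsets, bin_width: float,
                           time_range=(-100.0, 300.0)):
    """Histogram of event onsets (ms relative to the flash) over all sites.

    Returns (counts, bin_edges) as from numpy.histogram.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(time_range[0], time_range[1] + bin_width, bin_width)
    counts, edges = np.histogram(np.asarray(event_onsets, dtype=float), bins=edges)
    return counts, edges


def average_evoked_trace(map_rep: MapRecording) -> Trace:
    """Pointwise mean across all site traces, aligned on the flash."""
    return Trace(map_rep.traces.mean(axis=0),
                 sample_interval=map_rep.sample_interval,
                 t0=map_rep.t0, units="pA")
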