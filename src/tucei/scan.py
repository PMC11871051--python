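"""Time-resolved delay-scan pipeline.

Emulates a UV-pump / X-ray-probe Coulomb-explosion delay scan on synthetic
excited-state dynamics: at each pump-probe delay the excited subpopulation
is exploded at its deformed geometry while the remaining ground-state
fraction contributes thermally smeared S0 events.  A detector model adds
momentum resolution and reduces each record to a threefold S+/O+/H+
coincidence.  Per-delay proton angular maps are normalized to the
integrated number of ions per delay step; named angular regions are
integrated versus delay with Poisson statistics; onsets are detected as
the earliest delay departing from the unpumped baseline.

Monte-Carlo design: coincidence events are drawn (with replacement) from a
finite pool of exploded structures — ``n_trajectories`` excited-state
members per delay plus an ``n_thermal`` unpumped pool — mirroring how a
finite trajectory dataset is sampled by many detection shots.  Event
counts set the Poisson errors; the pool sizes set how finely the
underlying geometry distribution is resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .explosion import IntegratorConfig, explode_ensemble
from .frames import (
    CoincidenceEvent,
    Histogram1D,
    Histogram2D,
    angular_map,
    cos_alpha_histogram,
)
from .generator import (
    DEFAULT_SIGMA_OOP,
    DeformationParams,
    build_s0,
    deform_frame,
    thermal_ensemble,
)
from .geometry import GeometryError, Trajectory

PROTON_SITES = ("H9", "H10", "H11", "H12")


@dataclass
class DelayScanConfig:
    """Configuration of a simulated pump-probe delay scan.

    delays:
        Pump-probe delays in fs (strictly increasing).
    n_events:
        Coincidence events recorded per delay step (and for the unpumped
        set).
    excited_fraction:
        Probability f that a recorded molecule was UV-excited; the
        remaining 1 - f events come from the thermal ground-state pool.
    sigma_p:
        Detector momentum resolution, a.u., applied per momentum component.
    n_trajectories, n_thermal:
        Sizes of the exploded-structure pools (see module docstring).
    """

    delays: tuple[float, ...] = (65.0, 130.0, 260.0, 1000.0)
    n_events: int = 20_000
    excited_fraction: float = 0.2
    sigma_p: float = 2.0
    seed: int = 0
    n_trajectories: int = 100
    n_thermal: int = 1000
    sigma_oop: float = DEFAULT_SIGMA_OOP
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self):
        if not all(b > a for a, b in zip(self.delays, self.delays[1:])):
            raise ValueError("delays must be strictly increasing")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.excited_fraction <= 1.0:
            raise ValueError("excited_fraction must be in [0, 1]")
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be >= 0")


@dataclass
class DelayScanResult:
    """Per-delay event sets plus the unpumped reference set."""

    events_by_delay: dict[float, list[CoincidenceEvent]]
    unpumped: list[CoincidenceEvent]
    config: DelayScanConfig
    seeds: dict = field(default_factory=dict)


def excited_frames_at_delays(params: DeformationParams, n: int,
                             delays, sigma_oop: float = DEFAULT_SIGMA_OOP,
                             seed: int = 0):
    """Ensemble of deformed geometries at the requested delays only.

    Equivalent to generating ``n`` full staged-onset trajectories and
    extracting the frames at each delay, without building the intermediate
    frames.  Returns delay -> list of n geometries.
    """
    bases = thermal_ensemble(build_s0(), sigma_oop=sigma_oop, n=n, seed=seed)
    return {float(t): [deform_frame(b, params, float(t)) for b in bases]
            for t in delays}


def _frames_for_delay(traj_ensemble, delay: float):
    frames = []
    for k, traj in enumerate(traj_ensemble):
        try:
            frames.append(traj.frame_at(delay))
        except GeometryError:
            lo, hi = traj.times[0], traj.times[-1]
            raise GeometryError(
                f"delay {delay} fs not covered by trajectory {k} "
                f"(frames span {lo}..{hi} fs)") from None
    return frames


def simulate_delay_scan(traj_ensemble, cfg: DelayScanConfig
                        ) -> DelayScanResult:
    """Simulate the delay scan: explode pools, then draw coincidence events.

    ``traj_ensemble`` is either a sequence of :class:`Trajectory` (frames
    are taken at each configured delay) or a mapping delay -> list of
    geometries, as produced by :func:`excited_frames_at_delays`.

    For each delay, ``n_events`` events are drawn: with probability
    ``excited_fraction`` from the exploded excited-state pool at that
    delay, otherwise from the exploded thermal S0 pool.  A separate
    unpumped set of ``n_events`` is drawn from the thermal pool alone.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(traj_ensemble, dict):
        frames_by_delay = {float(t): list(v) for t, v in traj_ensemble.items()}
        for t in cfg.delays:
            if float(t) not in frames_by_delay:
                raise GeometryError(f"delay {t} fs missing from frame ensemble")
    else:
        traj_ensemble = list(traj_ensemble)
        frames_by_delay = {float(t): _frames_for_delay(traj_ensemble, t)
                           for t in cfg.delays}

    thermal_pool = thermal_ensemble(
        build_s0(), sigma_oop=cfg.sigma_oop, n=cfg.n_thermal,
        seed=int(rng.integers(2 ** 31)))
    thermal_results = explode_ensemble(thermal_pool, cfg=cfg.integrator)
    excited_results = {
        t: explode_ensemble(frames, cfg=cfg.integrator)
        for t, frames in frames_by_delay.items()}

    def draw(pool, delay, pumped, n):
        idx = rng.integers(len(pool), size=n)
        return [CoincidenceEvent.from_result(pool[i], delay=delay,
                                             pumped=pumped) for i in idx]

    unpumped = draw(thermal_results, None, False, cfg.n_events)
    events_by_delay = {}
    for t in cfg.delays:
        t = float(t)
        n_exc = int(rng.binomial(cfg.n_events, cfg.excited_fraction))
        ev = draw(excited_results[t], t, True, n_exc)
        ev += draw(thermal_results, t, False, cfg.n_events - n_exc)
        rng.shuffle(ev)
        events_by_delay[t] = ev
    return DelayScanResult(events_by_delay, unpumped, cfg,
                           seeds={"seed": cfg.seed})


def detector_model(events, sigma_p: float, seed: int = 0,
                   keep_labels: bool = True):
    """Finite momentum resolution plus threefold-coincidence reduction.

    Each momentum component receives independent Gaussian noise of width
    ``sigma_p`` (a.u.) and each output record retains exactly one S+, one
    O+, and one H+ — the proton chosen uniformly at random among those
    present, as a real coincidence selection would.  With
    ``keep_labels=False`` the proton site label is stripped ("measured
    mode", where proton identity is unknown).
    """
    if sigma_p < 0:
        raise ValueError("sigma_p must be >= 0")
    rng = np.random.default_rng(seed)
    events = list(events)
    n = len(events)
    picks = rng.random(n)            # one uniform draw per event
    noise = rng.normal(0.0, sigma_p, (n, 3, 3)) if sigma_p > 0 else \
        np.zeros((n, 3, 3))
    out = []
    for e, u, dn in zip(events, picks, noise):
        labels = sorted(e.protons)
        lab = labels[int(u * len(labels))]
        out.append(CoincidenceEvent(
            p_s=e.p_s + dn[0], p_o=e.p_o + dn[1],
            protons={(lab if keep_labels else "H"): e.protons[lab] + dn[2]},
            weight=e.weight, delay=e.delay, pumped=e.pumped))
    return out


# ---------------------------------------------------------------------------
# difference distributions and smoothing


def _check_binning(a, b):
    if isinstance(a, Histogram1D) != isinstance(b, Histogram1D):
        raise ValueError("histogram dimensionalities differ")
    if isinstance(a, Histogram1D):
        if not np.array_equal(a.edges, b.edges):
            raise ValueError("histogram binning mismatch")
    else:
        if (not np.array_equal(a.xedges, b.xedges)
                or not np.array_equal(a.yedges, b.yedges)):
            raise ValueError("histogram binning mismatch")


def difference_distribution(pumped, unpumped):
    """Pumped-minus-unpumped difference of per-total-ion normalized maps.

    Both inputs are normalized by their own total ion count first; errors
    combine in quadrature.  Accepts matching 1D or 2D histograms.
    """
    _check_binning(pumped, unpumped)
    p = pumped.normalized() if "per_total_ions" not in pumped.norm else pumped
    u = (unpumped.normalized()
         if "per_total_ions" not in unpumped.norm else unpumped)
    diff = p.counts - u.counts
    err = np.sqrt(p.errors ** 2 + u.errors ** 2)
    norm = {"difference": "pumped - unpumped, each per total ions"}
    if isinstance(pumped, Histogram1D):
        return Histogram1D(p.edges, diff, err, p.label, norm)
    return Histogram2D(p.xedges, p.yedges, diff, err,
                       p.xlabel, p.ylabel, norm)


def smooth(hist, width: float):
    """Gaussian smoothing with the kernel width in axis units.

    The total integral is preserved exactly (the smoothed map is rescaled
    to the input total, compensating truncation at open boundaries); the
    Phi axis of angular maps is treated as periodic.  Errors are smoothed
    with the same kernel, a conservative (correlation-ignoring) estimate.
    """
    if width < 0:
        raise ValueError("smoothing width must be >= 0")
    if width == 0:
        return replace(hist) if hasattr(hist, "__dataclass_fields__") else hist
    if isinstance(hist, Histogram1D):
        dx = hist.edges[1] - hist.edges[0]
        c = ndimage.gaussian_filter1d(hist.counts, width / dx, mode="constant")
        e = ndimage.gaussian_filter1d(hist.errors, width / dx, mode="constant")
        tot = hist.counts.sum()
        if tot != 0 and c.sum() != 0:
            factor = tot / c.sum()
            c, e = c * factor, e * factor
        return Histogram1D(hist.edges, c, e, hist.label,
                           {**hist.norm, "smoothed_width": width})
    dx = hist.xedges[1] - hist.xedges[0]
    dy = hist.yedges[1] - hist.yedges[0]
    periodic_x = np.isclose(hist.xedges[0], -180.0) and \
        np.isclose(hist.xedges[-1], 180.0)
    mode = ("wrap", "constant") if periodic_x else ("constant", "constant")
    c = ndimage.gaussian_filter(hist.counts, (width / dx, width / dy),
                                mode=mode)
    e = ndimage.gaussian_filter(hist.errors, (width / dx, width / dy),
                                mode=mode)
    tot = hist.counts.sum()
    if tot != 0 and c.sum() != 0:
        factor = tot / c.sum()
        c, e = c * factor, e * factor
    return Histogram2D(hist.xedges, hist.yedges, c, e, hist.xlabel,
                       hist.ylabel, {**hist.norm, "smoothed_width": width})


# ---------------------------------------------------------------------------
# angular regions


@dataclass(frozen=True)
class RegionBox:
    """A wrap-aware box in the (Phi, cos Theta) angular map.

    ``phi`` is (lo, hi) in degrees; lo > hi means the interval wraps
    through +-180 (e.g. (150, -150) covers |Phi| >= 150).  ``costheta``
    bounds must lie within [-1, 1].  ``exclude`` subtracts other boxes.
    """

    name: str
    phi: tuple[float, float]
    costheta: tuple[float, float]
    exclude: tuple["RegionBox", ...] = ()

    def __post_init__(self):
        lo, hi = self.costheta
        if not (-1.0 <= lo < hi <= 1.0):
            raise ValueError(f"costheta interval {self.costheta} invalid")

    def _phi_mask(self, centers: np.ndarray) -> np.ndarray:
        lo, hi = self.phi
        if lo <= hi:
            return (centers >= lo) & (centers <= hi)
        return (centers >= lo) | (centers <= hi)      # wraps through 180

    def mask(self, hist: Histogram2D) -> np.ndarray:
        cx, cy = hist.bin_centers()
        m = self._phi_mask(cx)[:, None] & \
            ((cy >= self.costheta[0]) & (cy <= self.costheta[1]))[None, :]
        for other in self.exclude:
            m &= ~other.mask(hist)
        return m


def default_regions() -> dict[str, RegionBox]:
    """The three named analysis regions, frozen on the validated layout.

    The H9 box is tight around the validated unpumped H9 peak
    (cos Theta = -0.35), making it maximally sensitive to the earliest
    frame distortion; the H11 box is wide around its peak (-0.60) so that
    it tolerates the small early tilt and responds to the large
    sulfur-driven migration of H11 through the map; the filament band
    covers -0.1 < cos(Theta) < 0.6 over all azimuths, excluding the other
    boxes.
    """
    h9 = RegionBox("H9", (-25.0, 25.0), (-0.50, -0.20))
    h11 = RegionBox("H11", (150.0, -150.0), (-0.80, -0.26))
    filament = RegionBox("filament", (-180.0, 180.0), (-0.1, 0.6),
                         exclude=(h9, h11))
    return {"H9": h9, "H11": h11, "filament": filament}


def integrate_region(hist: Histogram2D, box: RegionBox
                     ) -> tuple[float, float]:
    """Integral of a map over a region box with propagated Poisson error."""
    m = box.mask(hist)
    if not m.any():
        warnings.warn(f"region {box.name!r} covers no bins", stacklevel=2)
        return 0.0, 0.0
    value = float(hist.counts[m].sum())
    error = float(np.sqrt((hist.errors[m] ** 2).sum()))
    return value, error


@dataclass
class RegionSeries:
    """Per-delay integrated intensity of one angular region."""

    name: str
    delays: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    baseline: float = np.nan           # unpumped value
    baseline_error: float = 0.0
    scale: float = 1.0
    norm: dict = field(default_factory=dict)

    def scaled(self, factor: float) -> "RegionSeries":
        return RegionSeries(self.name, self.delays, self.values * factor,
                            self.errors * factor, self.baseline * factor,
                            self.baseline_error * factor,
                            self.scale * factor, dict(self.norm))


def region_series(maps_by_delay: dict[float, Histogram2D],
                  unpumped_map: Histogram2D,
                  box: RegionBox) -> RegionSeries:
    """Integrate one region across normalized per-delay maps."""
    delays = np.array(sorted(maps_by_delay))
    vals, errs = [], []
    for t in delays:
        v, e = integrate_region(maps_by_delay[t], box)
        vals.append(v)
        errs.append(e)
    b, be = integrate_region(unpumped_map, box)
    return RegionSeries(box.name, delays, np.array(vals), np.array(errs),
                        baseline=b, baseline_error=be,
                        norm={"normalized": "per total ions per delay step"})


def detect_onset(series: RegionSeries, k: float = 2.0) -> float | None:
    """Earliest delay departing from the unpumped baseline by > k errors.

    Returns the onset delay in fs, or None when the series never departs
    ("no onset").
    """
    if len(series.delays) < 2:
        raise ValueError("onset detection needs >= 2 delays")
    comb = np.sqrt(series.errors ** 2 + series.baseline_error ** 2)
    departed = np.abs(series.values - series.baseline) > k * comb
    idx = np.flatnonzero(departed)
    return float(series.delays[idx[0]]) if idx.size else None


@dataclass
class OnsetReport:
    """Per-region onset delays, sorted; equal onsets are reported as ties."""

    onsets: dict[str, float | None]
    order: list[tuple[str, ...]]       # groups of tied regions, earliest first
    k: float = 2.0

    def precedes(self, a: str, b: str) -> bool:
        """True when region a has a strictly earlier onset than region b."""
        ta, tb = self.onsets.get(a), self.onsets.get(b)
        return ta is not None and (tb is None or ta < tb)

    def __str__(self):
        lines = [f"onset threshold: {self.k} combined standard deviations"]
        for name, t in self.onsets.items():
            lines.append(f"  {name}: " +
                         ("no onset" if t is None else f"{t:g} fs"))
        if self.order:
            lines.append("order: " + " < ".join(
                "=".join(g) for g in self.order))
        return "\n".join(lines)


def onset_order(series_list, k: float = 2.0) -> OnsetReport:
    """Detect onsets for several region series and sort regions by onset."""
    onsets = {s.name: detect_onset(s, k=k) for s in series_list}
    detected = sorted((t, n) for n, t in onsets.items() if t is not None)
    groups: list[tuple[str, ...]] = []
    for t, n in detected:
        if groups and onsets[groups[-1][0]] == t:
            groups[-1] = groups[-1] + (n,)
        else:
            groups.append((n,))
    return OnsetReport(onsets=onsets, order=groups, k=k)


def scale_to_reference(series: RegionSeries, reference: RegionSeries
                       ) -> tuple[RegionSeries, float]:
    """Least-squares single-factor scaling of a series onto a reference.

    Returns the scaled series and the factor c minimizing
    sum_i (ref_i - c * series_i)^2; errors scale by the same factor.
    """
    if not np.array_equal(series.delays, reference.delays):
        raise ValueError("series and reference must share the delay grid")
    denom = float(np.sum(series.values ** 2))
    if np.all(reference.values == 0):
        raise ValueError("all-zero reference series")
    if denom == 0:
        raise ValueError("all-zero series cannot be scaled")
    factor = float(np.sum(reference.values * series.values)) / denom
    return series.scaled(factor), factor


# ---------------------------------------------------------------------------
# end-to-end report


@dataclass
class ScanReport:
    """Everything the time-resolved pipeline produces for one scan."""

    maps_by_delay: dict[float, Histogram2D]
    unpumped_map: Histogram2D
    cos_alpha_by_delay: dict[float, Histogram1D]
    cos_alpha_unpumped: Histogram1D
    cos_alpha_diffs: dict[float, Histogram1D]
    series: dict[str, RegionSeries]
    onsets: OnsetReport
    config: DelayScanConfig


def run_scan(params: DeformationParams | None = None,
             cfg: DelayScanConfig | None = None,
             regions: dict[str, RegionBox] | None = None,
             onset_k: float = 2.0) -> ScanReport:
    """Full pipeline: generate, explode, detect, histogram, integrate.

    Generates the excited-state geometry ensemble at the configured delays,
    simulates the scan, applies the detector model, builds per-delay
    normalized angular maps and cos(alpha) difference distributions,
    integrates the named regions and detects onsets.
    """
    params = params or DeformationParams()
    cfg = cfg or DelayScanConfig()
    regions = regions or default_regions()
    frames = excited_frames_at_delays(params, cfg.n_trajectories, cfg.delays,
                                      sigma_oop=cfg.sigma_oop, seed=cfg.seed)
    scan = simulate_delay_scan(frames, cfg)
    det_seed = cfg.seed + 1
    unpumped = detector_model(scan.unpumped, cfg.sigma_p, seed=det_seed)
    by_delay = {t: detector_model(ev, cfg.sigma_p, seed=det_seed + 1 + i)
                for i, (t, ev) in enumerate(sorted(scan.events_by_delay.items()))}

    unpumped_map = angular_map(unpumped, normalize=True)
    maps = {t: angular_map(ev, normalize=True) for t, ev in by_delay.items()}
    ca_un = cos_alpha_histogram(unpumped)
    ca = {t: cos_alpha_histogram(ev) for t, ev in by_delay.items()}
    ca_diff = {t: difference_distribution(h, ca_un) for t, h in ca.items()}

    series = {name: region_series(maps, unpumped_map, box)
              for name, box in regions.items()}
    if len(cfg.delays) >= 2:
        onsets = onset_order(list(series.values()), k=onset_k)
    else:
        # onset detection needs at least two delays; report none
        onsets = OnsetReport(onsets={name: None for name in series},
                             order=[], k=onset_k)
    return ScanReport(maps, unpumped_map, ca, ca_un, ca_diff,
                      series, onsets, cfg)
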