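"""Gaussian elution-peak models across wavelength channels.

A species eluting from the column produces a Gaussian concentration
profile centred at its retention time; a channel chromatogram is then a
non-negative sum of Gaussians. These fits serve three purposes:

* diagnosing hidden species — when a k-component fit is forced onto data
  containing more than k species, the fitted retention time of a peak
  drifts with the monitoring wavelength, which cannot happen for a true
  k-species window;
* determining shared retention times and widths by a joint fit across a
  few informative channels;
* producing the timepoints (10%-of-apex flanks, fitted Rt for hidden
  components) whose raw spectra seed the curve-resolution step.

The "Gaussian mixture" here is penalised nonlinear least squares on the
elution curve, not expectation–maximisation on samples: the data are
curves, not draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import find_peaks

from .io import SpectralChromatogram, ValidationError
from .preprocess import ChannelChromatogram, extract_channel

__all__ = [
    "ElutionComponent",
    "GmmFit",
    "fit_gaussian_sum",
    "rt_consistency_diagnostic",
    "fit_shared_rt",
    "flank_spectra",
    "FLANK_FRACTION",
]

#: flank spectra are sampled where the signal is this fraction of the apex
FLANK_FRACTION = 0.1


@dataclass
class ElutionComponent:
    """One species' Gaussian elution model."""

    rt: float                                   # retention time, min
    sigma: float                                # peak width, min
    amplitude_per_channel: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")

    def profile(self, t: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
        return amplitude * np.exp(-0.5 * ((t - self.rt) / self.sigma) ** 2)

    def unit_area_profile(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((t - self.rt) / self.sigma) ** 2) / (
            self.sigma * np.sqrt(2.0 * np.pi)
        )


@dataclass
class GmmFit:
    """A sum-of-Gaussians fit, components sorted by retention time."""

    components: list[ElutionComponent]
    residual_rms: dict[float, float]            # per channel center, AU
    shared_rt: bool = False
    converged: bool = True
    amplitude_spectra: np.ndarray | None = None  # (n_wavelength, k), from full refit
    wavelength: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components.sort(key=lambda c: c.rt)

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def rts(self) -> np.ndarray:
        return np.array([c.rt for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])


def _gaussian_sum(t: np.ndarray, params: np.ndarray, k: int) -> np.ndarray:
    """params = [a_1..a_k, rt_1..rt_k, sigma_1..sigma_k]."""
    a = params[:k]
    rt = params[k : 2 * k]
    sg = params[2 * k :]
    return (a[None, :] * np.exp(-0.5 * ((t[:, None] - rt[None, :]) / sg[None, :]) ** 2)).sum(
        axis=1
    )


def _default_init(t: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial (a, rt, sigma) from the k tallest local maxima.

    When fewer maxima than components are visible — the hidden-peak case —
    extra components start at the midpoints of the widest gaps between
    maxima, then stacked near the tallest maximum with a small stagger.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import peak_widths

    dt = float(np.mean(np.diff(t)))
    span = float(t[-1] - t[0])
    # light smoothing so noise wiggles are not mistaken for apexes
    ys = uniform_filter1d(y, size=max(3, t.size // 200))
    idx, props = find_peaks(ys, height=0.05 * max(float(ys.max()), 1e-12),
                            distance=max(2, t.size // 100))
    if idx.size:
        order = np.argsort(props["peak_heights"])[::-1]
        idx = idx[order][:k]
    # sigma guess from measured half-height widths (fallback: window heuristic)
    if idx.size:
        w_half = peak_widths(ys, np.sort(idx), rel_height=0.5)[0] * dt
        sig0 = float(np.median(w_half)) / 2.355
    else:
        sig0 = span / (8 * k)
    sig0 = min(max(sig0, 5 * dt), span / 2)
    rts = [(float(v), sig0) for v in sorted(t[idx])]
    interp = lambda rt: float(np.interp(rt, t, ys))
    if len(rts) >= 2:
        gaps = sorted(
            ((b[0] - a[0], (a[0] + b[0]) / 2) for a, b in zip(rts[:-1], rts[1:])),
            reverse=True,
        )
        for _, mid in gaps:
            if len(rts) >= k:
                break
            # a component hidden between two apexes must be broad to show
            # no maximum of its own: start it at twice the visible width
            rts.append((mid, 2.0 * sig0))
    anchor = float(t[idx[0]]) if idx.size else float(t[t.size // 2])
    i = 1
    while len(rts) < k:
        rts.append((min(max(anchor + 2 * sig0 * i, t[0]), t[-1]), sig0))
        i += 1
    rts = sorted(rts[:k])
    positions = np.array([r[0] for r in rts])
    sigs = np.array([r[1] for r in rts])
    amps = np.maximum(
        [interp(rt) for rt in positions], max(float(y.max()), 1e-12) * 0.05
    )
    return np.asarray(amps), positions, sigs


def _subtract_baseline(y: np.ndarray) -> np.ndarray:
    """Subtract the baseline level estimated from non-peak samples.

    The lowest decile anchors the baseline region; widening it by 4x the
    noise sd before taking the median removes the downward bias a pure
    lower-tail statistic would have.
    """
    from .preprocess import robust_noise_sd

    noise = robust_noise_sd(y)
    anchor = np.quantile(y, 0.1)
    base_samples = y[y <= anchor + 4.0 * noise]
    base = float(np.median(base_samples)) if base_samples.size else float(anchor)
    return y - base


def fit_gaussian_sum(
    channel: ChannelChromatogram,
    k: int,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> GmmFit:
    """Fit Σⱼ aⱼ·exp(−(t−Rtⱼ)²/2σⱼ²) to a baseline-subtracted channel.

    Non-negative amplitudes; retention times bounded to the window; σ
    bounded in [Δt, window/2]. Default initialisation takes the k tallest
    local maxima. Non-convergence is flagged on the fit, not raised.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    t = channel.time
    y = _subtract_baseline(channel.absorbance)
    if t.size < 5 * k:
        raise ValidationError(f"need at least {5 * k} points to fit {k} components")
    dt = float(np.mean(np.diff(t)))
    span = float(t[-1] - t[0])
    lb = np.concatenate([np.zeros(k), np.full(k, t[0]), np.full(k, dt)])
    ub = np.concatenate([np.full(k, np.inf), np.full(k, t[-1]), np.full(k, span / 2)])

    def solve(a0, rt0, sg0):
        x0 = np.concatenate(
            [
                np.clip(a0, 0.0, None),
                np.clip(rt0, t[0], t[-1]),
                np.clip(sg0, dt, span / 2),
            ]
        )
        return least_squares(
            lambda p: _gaussian_sum(t, p, k) - y,
            x0,
            bounds=(lb, ub),
            x_scale="jac",
            max_nfev=2000,
        )

    starts = []
    if init is not None:
        starts.append(tuple(np.asarray(v, dtype=float) for v in init))
    else:
        starts.append(_default_init(t, y, k))
        if k >= 2:
            # nested start: best (k−1)-fit plus a component at its residual
            # peak — guarantees the converged residual cannot exceed the
            # smaller model's and escapes single-start local minima
            sub = fit_gaussian_sum(channel, k - 1)
            resid = y - sum(
                c.profile(t, list(c.amplitude_per_channel.values())[0])
                for c in sub.components
            )
            i_extra = int(np.argmax(resid))
            starts.append(
                (
                    np.append(
                        [list(c.amplitude_per_channel.values())[0] for c in sub.components],
                        max(resid[i_extra], 1e-12),
                    ),
                    np.append(sub.rts, t[i_extra]),
                    np.append(sub.sigmas, float(np.median(sub.sigmas))),
                )
            )
    results = [solve(*s) for s in starts]
    res = min(results, key=lambda r: float(r.fun @ r.fun))
    a, rt, sg = res.x[:k], res.x[k : 2 * k], res.x[2 * k :]
    rms = float(np.sqrt(np.mean(res.fun**2)))
    comps = [
        ElutionComponent(float(r), float(s), {channel.center_wavelength: float(av)})
        for av, r, s in zip(a, rt, sg)
    ]
    return GmmFit(
        components=comps,
        residual_rms={channel.center_wavelength: rms},
        converged=bool(res.success),
    )


def rt_consistency_diagnostic(
    chrom: SpectralChromatogram,
    window: tuple[float, float],
    k: int,
    channel_centers: list[float],
    half_window_nm: float = 2.0,
) -> dict:
    """Independent k-component fits per channel; retention-time spread.

    For a true k-species window the fitted retention times agree across
    wavelengths; a spread above ~0.2·σ̂ signals that k under-counts the
    species present (a hidden peak is being absorbed into its
    neighbours). Channels whose fit fails to converge are excluded and
    listed.

    Returns a dict with ``rt_table`` (channel × component), ``spread``
    (max−min per component), ``spread_stat`` (worst component),
    ``sigma_hat``, ``tolerance`` and ``inconsistent``.
    """
    if len(channel_centers) < 3:
        raise ValidationError("need at least 3 channels for the diagnostic")
    sub = chrom.crop_time(*window)
    fits, ok_channels, excluded = [], [], []
    for c in channel_centers:
        ch = extract_channel(sub, c, half_window_nm)
        fit = fit_gaussian_sum(ch, k)
        if not fit.converged:
            excluded.append(c)
            continue
        fits.append(fit)
        ok_channels.append(c)
    if len(fits) < 2:
        raise ValidationError("too few channels converged for a spread estimate")
    # a channel where some species is spectrally dark cannot constrain all
    # k retention times (the optimiser reuses the dark component to model
    # the bright ones): keep only channels with all components visible
    informative = []
    for f, c in zip(list(fits), list(ok_channels)):
        amps = np.array(
            [list(comp.amplitude_per_channel.values())[0] for comp in f.components]
        )
        if amps.min() >= 0.02 * max(float(amps.max()), 1e-300):
            informative.append(f)
        else:
            excluded.append(c)
    if len(informative) >= 2:
        fits = informative
        ok_channels = [c for c in ok_channels if c not in excluded]
    rt_table = np.vstack([f.rts for f in fits])
    spread = rt_table.max(axis=0) - rt_table.min(axis=0)
    sigma_hat = float(np.median(np.concatenate([f.sigmas for f in fits])))
    tolerance = 0.2 * sigma_hat
    return {
        "channels": ok_channels,
        "excluded": excluded,
        "rt_table": rt_table,
        "spread": spread,
        "spread_stat": float(spread.max()),
        "sigma_hat": sigma_hat,
        "tolerance": tolerance,
        "inconsistent": bool(spread.max() > tolerance),
    }


def default_shared_channels(
    chrom: SpectralChromatogram,
    window: tuple[float, float],
    k: int,
    n_channels: int = 5,
    band: tuple[float, float] = (230.0, 330.0),
    dominance: float = 0.8,
) -> list[float]:
    """Channels for the shared-Rt fit: evenly spaced in ``band`` plus any
    channel where a single component carries > ``dominance`` of the
    fitted signal (a spectral region where a subset of peaks is present).
    """
    lo = max(band[0], float(chrom.wavelength[0]))
    hi = min(band[1], float(chrom.wavelength[-1]))
    if hi <= lo:
        lo, hi = float(chrom.wavelength[0]), float(chrom.wavelength[-1])
    centers = list(np.linspace(lo, hi, n_channels))
    # scan a coarse set of extra channels for single-component dominance
    sub = chrom.crop_time(*window)
    scan = np.linspace(float(chrom.wavelength[0]) + 2, float(chrom.wavelength[-1]) - 2, 12)
    for c in scan:
        ch = extract_channel(sub, float(c), 2.0)
        if ch.absorbance.max() <= 0:
            continue
        try:
            fit = fit_gaussian_sum(ch, k)
        except ValidationError:
            continue
        if not fit.converged:
            continue
        areas = np.array(
            [
                list(comp.amplitude_per_channel.values())[0] * comp.sigma
                for comp in fit.components
            ]
        )
        if areas.sum() > 0 and areas.max() / areas.sum() > dominance:
            centers.append(float(c))
    return sorted(set(round(c, 3) for c in centers))


def fit_shared_rt(
    chrom: SpectralChromatogram,
    window: tuple[float, float],
    k: int,
    rt_init: np.ndarray,
    channels: list[float] | None = None,
    half_window_nm: float = 2.0,
) -> GmmFit:
    """Joint Gaussian fit with retention times and widths shared across
    channels, then a full per-wavelength amplitude refit.

    Stage 1: over a small set of informative channels, fit shared
    (Rt_j, σ_j) with free non-negative per-channel amplitudes. σ is
    shared across channels per component — the physical elution width
    does not depend on wavelength.

    Stage 2: freeze (Rt, σ) and refit amplitudes on *every* wavelength by
    non-negative least squares against the unit-area Gaussian basis.
    This yields each component's full amplitude spectrum (an estimate of
    amount × species spectrum) and the concentration profiles.
    """
    rt_init = np.asarray(rt_init, dtype=float).ravel()
    if rt_init.size != k:
        raise ValidationError(f"rt_init has length {rt_init.size}, expected k={k}")
    sub = chrom.crop_time(*window)
    if channels is None:
        channels = default_shared_channels(chrom, window, k)
    chans = [extract_channel(sub, c, half_window_nm) for c in channels]
    t = sub.time
    dt = float(np.mean(np.diff(t)))
    span = float(t[-1] - t[0])
    ys = [_subtract_baseline(ch.absorbance) for ch in chans]
    n_ch = len(chans)

    # params: rt (k), sigma (k), amplitudes (n_ch * k)
    sg0 = np.full(k, max(5 * dt, span / (8 * k)))
    a0 = np.concatenate([np.full(k, max(y.max(), 1e-9) / k) for y in ys])
    x0 = np.concatenate([np.clip(rt_init, t[0], t[-1]), sg0, a0])
    lb = np.concatenate([np.full(k, t[0]), np.full(k, dt), np.zeros(n_ch * k)])
    ub = np.concatenate(
        [np.full(k, t[-1]), np.full(k, span / 2), np.full(n_ch * k, np.inf)]
    )

    G_cache = {}

    def basis(rt: np.ndarray, sg: np.ndarray) -> np.ndarray:
        key = (rt.tobytes(), sg.tobytes())
        if key not in G_cache:
            G_cache[key] = np.exp(-0.5 * ((t[:, None] - rt[None, :]) / sg[None, :]) ** 2)
            if len(G_cache) > 4:
                G_cache.pop(next(iter(G_cache)))
        return G_cache[key]

    def resid(p: np.ndarray) -> np.ndarray:
        rt, sg = p[:k], p[k : 2 * k]
        G = basis(rt, sg)
        out = []
        for j, y in enumerate(ys):
            a = p[2 * k + j * k : 2 * k + (j + 1) * k]
            out.append(G @ a - y)
        return np.concatenate(out)

    res = least_squares(resid, x0, bounds=(lb, ub), max_nfev=4000)
    rt, sg = res.x[:k], res.x[k : 2 * k]
    order = np.argsort(rt)
    rt, sg = rt[order], sg[order]

    # stage 2: amplitudes on all wavelengths, Rt and sigma frozen
    G = np.exp(-0.5 * ((t[:, None] - rt[None, :]) / sg[None, :]) ** 2)
    n_wl = sub.wavelength.size
    amp = np.empty((n_wl, k))
    for i in range(n_wl):
        amp[i], _ = nnls(G, _subtract_baseline(sub.absorbance[:, i]))

    comps = []
    for j in range(k):
        per_channel = {
            ch.center_wavelength: float(
                res.x[2 * k + m * k : 2 * k + (m + 1) * k][order][j]
            )
            for m, ch in enumerate(chans)
        }
        comps.append(ElutionComponent(float(rt[j]), float(sg[j]), per_channel))
    rms = {
        ch.center_wavelength: float(np.sqrt(np.mean((G @ np.array([
            comps[j].amplitude_per_channel[ch.center_wavelength] for j in range(k)
        ]) - y) ** 2)))
        for ch, y in zip(chans, ys)
    }
    return GmmFit(
        components=comps,
        residual_rms=rms,
        shared_rt=True,
        converged=bool(res.success),
        amplitude_spectra=amp,
        wavelength=sub.wavelength.copy(),
    )


def flank_spectra(
    chrom: SpectralChromatogram, fit: GmmFit, window: tuple[float, float] | None = None
) -> tuple[np.ndarray, dict]:
    """Initial spectra S0 for curve resolution from flank timepoints.

    The first (rising) component's estimate is the chromatogram row at
    the time where its fitted profile has risen to 10% of its apex; the
    last (trailing) component's is the row at its 10% trailing time.
    There the neighbours' contribution is smallest. Interior components
    are hidden — no timepoint is free of the flanking species — so their
    estimates are the rows at their fitted retention times. Rows are
    unit-max normalised.

    Returns ``(S0, record)`` with S0 of shape (n_wavelength, k) ordered
    by retention time, and a record of the sampling timepoints (flagged
    when a 10% crossing fell outside the window and was clamped).
    """
    if fit.k < 1:
        raise ValidationError("fit has no components")
    sub = chrom.crop_time(*window) if window is not None else chrom
    t = sub.time
    half_width = lambda sigma: sigma * np.sqrt(2.0 * np.log(1.0 / FLANK_FRACTION))
    times = []
    clamped = []
    for j, comp in enumerate(fit.components):
        if j == 0:
            tp = comp.rt - half_width(comp.sigma)
        elif j == fit.k - 1:
            tp = comp.rt + half_width(comp.sigma)
        else:
            tp = comp.rt
        lo, hi = float(t[0]), float(t[-1])
        clamped.append(tp < lo or tp > hi)
        times.append(min(max(tp, lo), hi))
    S0 = np.empty((sub.wavelength.size, fit.k))
    for j, tp in enumerate(times):
        row = sub.absorbance[int(np.argmin(np.abs(t - tp)))]
        m = row.max()
        S0[:, j] = row / m if m > 0 else row
    record = {"timepoints": np.array(times), "clamped": clamped}
    return S0, record
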