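"""End-to-end unsupervised pipeline.

Given a full-spectrum chromatogram and a trained fingerprint model:
detect peaks on the monitoring channel, group overlapping peaks into
congested regions, count species per region (PCA + K-means elbow),
deconvolve regions whose species count exceeds the visible apexes (or
whose retention times drift with wavelength) via shared-Rt Gaussian
fitting, flank-spectrum initialisation and MCR-AR, classify every
recovered spectrum, and emit an annotated peak table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FingerprintModel, classify_spectrum
from .elution import FLANK_FRACTION, fit_shared_rt, flank_spectra, rt_consistency_diagnostic
from .features import collect_window_spectra, estimate_k_elbow, pca_embed
from .io import PEAK_TABLE_COLUMNS, ReferenceSpectrum, SpectralChromatogram, ValidationError
from .mcr import mcr_ar
from .preprocess import Peak, detect_peaks, extract_channel

logger = logging.getLogger("chromspect")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs for the end-to-end run. Defaults follow the monitoring
    conventions of the portable instrument (230 ± 2 nm detection)."""

    detection_wavelength: float = 230.0
    detection_half_window: float = 2.0
    min_snr: float = 8.0
    min_separation_min: float = 0.05
    window_pad_sigma: float = 3.0       # extend region windows by this many widths
    k_max: int = 8
    n_restarts: int = 10
    pca_components: int = 4
    mcr_tol: float = 1e-8
    mcr_max_iter: int = 500
    p_conf: float = 0.95
    margin: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_snr", "min_separation_min", "k_max", "p_conf", "margin"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _group_regions(peaks: list[Peak]) -> list[list[Peak]]:
    """Group peaks whose 10% extents overlap into congested regions."""
    regions: list[list[Peak]] = []
    for p in sorted(peaks, key=lambda q: q.apex_time):
        if regions and p.rise_time_10pct <= regions[-1][-1].trail_time_10pct:
            regions[-1].append(p)
        else:
            regions.append([p])
    return regions


def _estimate_region_k(
    chrom: SpectralChromatogram, window: tuple[float, float], cfg: PipelineConfig
):
    spectra = collect_window_spectra(chrom, *window)
    scores, _ = pca_embed(spectra, n_components=cfg.pca_components)
    return estimate_k_elbow(
        scores, k_max=min(cfg.k_max, scores.shape[0]), n_restarts=cfg.n_restarts, seed=cfg.seed
    )


def _apex_spectrum(chrom: SpectralChromatogram, t: float) -> ReferenceSpectrum:
    row = chrom.absorbance[int(np.argmin(np.abs(chrom.time - t)))]
    return ReferenceSpectrum("query", chrom.wavelength, np.clip(row, 0.0, None), source="measured")


def _classify_row(model: FingerprintModel, spec: ReferenceSpectrum, cfg: PipelineConfig) -> dict:
    res = classify_spectrum(model, spec, p_conf=cfg.p_conf, margin=cfg.margin)
    return {
        "species": res.final_label,
        "posterior": res.posterior,
        "r2": res.r2_to_final,
        "frechet": res.frechet_to_final,
    }


def run_pipeline(
    chrom: SpectralChromatogram,
    model: FingerprintModel,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run detection → congestion analysis → deconvolution → classification.

    Returns ``(peak_table, artifacts)``. The table has one row per
    resolved component; any region whose analysis fails is recorded as
    a single "unresolved" row rather than aborting the run. Artifacts
    hold per-region diagnostics and every recovered spectrum.
    """
    cfg = config or PipelineConfig()
    channel = extract_channel(chrom, cfg.detection_wavelength, cfg.detection_half_window)
    peaks = detect_peaks(channel, cfg.min_snr, cfg.min_separation_min)
    regions = _group_regions(peaks)
    logger.info("detected %d peaks in %d regions", len(peaks), len(regions))

    rows: list[dict] = []
    artifacts: dict = {"regions": [], "channel": channel, "peaks": peaks}
    peak_id = 0
    for region in regions:
        sigma_guess = (
            np.median([(p.trail_time_10pct - p.rise_time_10pct) for p in region])
            / (2.0 * np.sqrt(2.0 * np.log(1.0 / FLANK_FRACTION)))
        )
        pad = cfg.window_pad_sigma * sigma_guess
        window = (
            max(float(chrom.time[0]), region[0].rise_time_10pct - pad),
            min(float(chrom.time[-1]), region[-1].trail_time_10pct + pad),
        )
        info: dict = {"window": window, "n_apexes": len(region)}
        try:
            rows_region = _analyse_region(chrom, model, region, window, cfg, info, peak_id)
        except ValidationError as exc:
            logger.warning("region %s unresolved: %s", window, exc)
            info["error"] = str(exc)
            rows_region = [
                {
                    "peak_id": peak_id,
                    "retention_time": region[0].apex_time,
                    "apex_absorbance": region[0].apex_absorbance,
                    "start": region[0].rise_time_10pct,
                    "end": region[-1].trail_time_10pct,
                    "species": "unresolved",
                    "posterior": np.nan,
                    "r2": np.nan,
                    "frechet": np.nan,
                    "deconvolved": False,
                }
            ]
        peak_id += len(rows_region)
        rows.extend(rows_region)
        artifacts["regions"].append(info)

    table = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    return table, artifacts


def _make_rt_init(window: tuple[float, float], apexes: np.ndarray, k: int) -> np.ndarray:
    """Initial retention times for a k-component fit given visible apexes.

    Hidden components are hypothesised first at the midpoints of the
    widest gaps between consecutive apexes (a species buried between two
    neighbours), then stacked onto the apexes themselves (a nearly
    coincident pair under one peak).
    """
    rts = list(apexes[:k])
    # midpoints of inter-apex gaps, widest first
    if len(rts) >= 2:
        gaps = sorted(
            ((b - a, (a + b) / 2) for a, b in zip(rts[:-1], rts[1:])), reverse=True
        )
        for _, mid in gaps:
            if len(rts) >= k:
                break
            rts.append(mid)
    # remaining hypotheses: coincident with an apex (small stagger so the
    # optimiser can separate widths)
    span = window[1] - window[0]
    i = 0
    while len(rts) < k:
        rts.append(float(apexes[i % len(apexes)]) + 0.01 * span * (1 + i // len(apexes)))
        i += 1
    return np.sort(np.asarray(rts[:k]))


def _analyse_region(
    chrom: SpectralChromatogram,
    model: FingerprintModel,
    region: list[Peak],
    window: tuple[float, float],
    cfg: PipelineConfig,
    info: dict,
    peak_id0: int,
) -> list[dict]:
    n_apex = len(region)
    clustering = _estimate_region_k(chrom, window, cfg)
    k = clustering.k
    info["k_estimate"] = k
    hidden = k > n_apex
    if not hidden and n_apex > 1:
        centers = list(np.linspace(230.0, 330.0, 4))
        try:
            diag = rt_consistency_diagnostic(chrom, window, n_apex, centers)
            info["rt_spread"] = diag["spread_stat"]
            hidden = diag["inconsistent"]
        except ValidationError:
            pass
    if not hidden:
        # take apex-time spectra directly
        out = []
        for i, p in enumerate(region):
            spec = _apex_spectrum(chrom, p.apex_time)
            out.append(
                {
                    "peak_id": peak_id0 + i,
                    "retention_time": p.apex_time,
                    "apex_absorbance": p.apex_absorbance,
                    "start": p.rise_time_10pct,
                    "end": p.trail_time_10pct,
                    "deconvolved": False,
                    **_classify_row(model, spec, cfg),
                }
            )
        return out

    # deconvolution path
    k = max(k, n_apex)
    apexes = np.array(sorted(p.apex_time for p in region))
    fit = fit_shared_rt(chrom, window, k, _make_rt_init(window, apexes, k))
    S0, flank_rec = flank_spectra(chrom, fit, window)
    info["flank"] = flank_rec
    sub = chrom.crop_time(*window)
    result = mcr_ar(sub.absorbance, S0, tol=cfg.mcr_tol, max_iter=cfg.mcr_max_iter)
    info["mcr_lof"] = result.lack_of_fit
    info["mcr"] = result
    channel = extract_channel(sub, cfg.detection_wavelength, cfg.detection_half_window)
    out = []
    half = np.sqrt(2.0 * np.log(1.0 / FLANK_FRACTION))
    for j, comp in enumerate(fit.components):
        spec = ReferenceSpectrum(
            "query", sub.wavelength, np.clip(result.S[:, j], 0.0, None), source="measured"
        )
        apex_a = float(
            channel.absorbance[int(np.argmin(np.abs(channel.time - comp.rt)))]
        )
        out.append(
            {
                "peak_id": peak_id0 + j,
                "retention_time": comp.rt,
                "apex_absorbance": apex_a,
                "start": comp.rt - half * comp.sigma,
                "end": comp.rt + half * comp.sigma,
                "deconvolved": True,
                **_classify_row(model, spec, cfg),
            }
        )
    return out
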