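"""Synthetic spectra, libraries and full-spectrum chromatograms.

The generator reproduces the statistical structure the analysis pipeline
assumes: absorbance obeys Beer–Lambert bilinearity ``A = C·Sᵀ`` where each
column of ``C`` is a unit-area Gaussian elution profile scaled by an
injected amount (AU·min) and each column of ``S`` is a species absorption
spectrum; measurement adds iid Gaussian noise and a linear baseline drift.

Spectra are sums of Gaussian absorption bands centred in the 200–450 nm
region where polycyclic aromatics absorb. Default grids are coarse
(Δλ 1 nm, Δt 0.005 min) so the whole pipeline runs at desk scale; a
full-resolution grid (Δλ 0.217 nm over 180–890 nm) is available through
:class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ReferenceSpectrum, SpectralChromatogram, SpectralLibrary

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "make_synthetic_spectrum",
    "make_library",
    "simulate_chromatogram",
    "hidden_peak_scenario",
    "panel_scenario",
]

#: wavelength support on which synthetic spectra are generated (nm)
SPECTRUM_GRID = (190.0, 470.0, 1.0)
#: absorption band centres are drawn in this range (nm)
BAND_CENTER_RANGE = (200.0, 450.0)
#: band standard deviations are drawn in this range (nm)
BAND_WIDTH_RANGE = (3.0, 20.0)


@dataclass
class SpeciesSpec:
    """One species' contribution to a simulated separation."""

    label: str
    rt: float          # retention time, min
    sigma: float       # elution peak width, min
    amount: float      # integrated signal, AU·min

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class SimulationConfig:
    """Grids, species layout and noise model for a simulated chromatogram."""

    species: list[SpeciesSpec]
    time_start: float = 0.0
    time_stop: float = 10.0
    time_step: float = 0.005
    wavelength_start: float = 200.0
    wavelength_stop: float = 450.0
    wavelength_step: float = 1.0
    noise_sd: float = 0.0          # AU
    baseline_drift: float = 0.0    # AU per min, constant across wavelength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.wavelength_step <= 0:
            raise ValueError("step sizes must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round((self.time_stop - self.time_start) / self.time_step)) + 1
        return self.time_start + self.time_step * np.arange(n)

    @property
    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)


def make_synthetic_spectrum(label: str, n_bands: int, seed: int) -> ReferenceSpectrum:
    """Generate a reference spectrum as a sum of Gaussian absorption bands.

    Band centres are drawn uniformly in 200–450 nm and widths in 3–20 nm;
    the curve is non-negative and normalised to unit maximum. Deterministic
    for a fixed seed.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi, step = SPECTRUM_GRID
    wl = np.arange(lo, hi + step / 2, step)
    centers = rng.uniform(*BAND_CENTER_RANGE, size=n_bands)
    widths = rng.uniform(*BAND_WIDTH_RANGE, size=n_bands)
    heights = rng.uniform(0.3, 1.0, size=n_bands)
    a = np.zeros_like(wl)
    for c, w, h in zip(centers, widths, heights):
        a += h * np.exp(-0.5 * ((wl - c) / w) ** 2)
    a /= a.max()
    return ReferenceSpectrum(label, wl, a, source="synthetic")


def make_library(
    n_species: int,
    replicates_per_species: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_shift_nm: float = 0.5,
) -> SpectralLibrary:
    """Build a library of synthetic species with noisy, shifted replicates.

    Replicates emulate reference spectra of the same compound acquired on
    different instruments: the base spectrum plus independent additive
    noise and a small wavelength registration shift (<= ``max_shift_nm``).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_species):
        label = f"species_{i:02d}"
        n_bands = int(rng.integers(2, 6))
        base = make_synthetic_spectrum(label, n_bands, seed=int(rng.integers(0, 2**31)))
        for _ in range(replicates_per_species):
            shift = rng.uniform(-max_shift_nm, max_shift_nm)
            noisy = base.absorbance + rng.normal(0.0, noise_sd, size=base.absorbance.size)
            entries.append(
                ReferenceSpectrum(
                    label, base.wavelength + shift, np.clip(noisy, 0.0, None), source="synthetic"
                )
            )
    return SpectralLibrary(entries)


def _species_matrix(config: SimulationConfig, library: SpectralLibrary) -> np.ndarray:
    """Library spectra interpolated onto the config wavelength grid (λ × k)."""
    wl = config.wavelength_grid
    cols = []
    for sp in config.species:
        matches = library.by_species(sp.label)
        if not matches:
            raise ValueError(f"species label not in library: {sp.label!r}")
        ref = matches[0]
        cols.append(np.interp(wl, ref.wavelength, ref.absorbance, left=0.0, right=0.0))
    return np.column_stack(cols)


def _concentration_matrix(config: SimulationConfig) -> np.ndarray:
    """Unit-area Gaussian profiles scaled by amount (t × k), AU·min semantics."""
    t = config.time_grid
    cols = []
    for sp in config.species:
        g = np.exp(-0.5 * ((t - sp.rt) / sp.sigma) ** 2)
        g /= sp.sigma * np.sqrt(2.0 * np.pi)  # unit area in time
        cols.append(sp.amount * g)
    return np.column_stack(cols)


def simulate_chromatogram(
    config: SimulationConfig, library: SpectralLibrary
) -> tuple[SpectralChromatogram, dict]:
    """Simulate ``A = C·Sᵀ + baseline + ε`` and return it with ground truth.

    The truth record holds the noiseless factors: ``C`` (time × k,
    unit-area Gaussians × amounts), ``S`` (wavelength × k, the library
    spectra on the simulation grid), labels, retention times and widths.
    """
    rng = np.random.default_rng(config.seed)
    t = config.time_grid
    wl = config.wavelength_grid
    S = _species_matrix(config, library)
    C = _concentration_matrix(config)
    A = C @ S.T
    A = A + config.baseline_drift * t[:, None]
    if config.noise_sd > 0:
        A = A + rng.normal(0.0, config.noise_sd, size=A.shape)
    chrom = SpectralChromatogram(
        t,
        wl,
        A,
        meta={
            "source": "simulated",
            "seed": config.seed,
            "noise_sd": config.noise_sd,
            "baseline_drift": config.baseline_drift,
        },
    )
    truth = {
        "C": C,
        "S": S,
        "labels": [sp.label for sp in config.species],
        "rt": np.array([sp.rt for sp in config.species]),
        "sigma": np.array([sp.sigma for sp in config.species]),
        "amounts": np.array([sp.amount for sp in config.species]),
        "config": config,
    }
    return chrom, truth


# ---------------------------------------------------------------------------
# canned scenarios

#: fractional noise level: noise sd = this fraction of the peak signal
SCENARIO_NOISE_FRACTION = 0.01


def _family_spectrum(
    label: str, backbone_seed: int, own_seed: int, own_bands: int, backbone_weight: float
) -> ReferenceSpectrum:
    """A species spectrum as backbone + species-specific bands.

    Chemically related species (isomers, shared ring systems) absorb
    through a common chromophore plus substituent-specific structure;
    mixing a shared backbone spectrum with an individual band set
    reproduces that family resemblance.
    """
    base = make_synthetic_spectrum("backbone", 4, backbone_seed)
    own = make_synthetic_spectrum(label, own_bands, own_seed)
    a = backbone_weight * base.absorbance + (1.0 - backbone_weight) * own.absorbance
    a = a / a.max()
    return ReferenceSpectrum(label, base.wavelength.copy(), a, source="synthetic")


# the scenario species: fixed spectral identities (seed drives noise only)
_TRIO_SPECS = [
    # (label, backbone weight, own seed, own bands) — backbone seed 900
    ("hidden_A", 0.5, 11, 3),
    ("hidden_B", 0.0, 22, 3),
    ("hidden_C", 0.5, 33, 3),
]
_QUINT_SPECS = [
    # backbone seed 910; the co-eluting pair (pair_D/pair_E) is spectrally
    # distinct while the resolved neighbours share the family backbone
    ("side_F", 0.45, 5, 3),
    ("pair_D", 0.0, 8, 4),
    ("pair_E", 0.25, 12, 3),
    ("side_G", 0.45, 16, 4),
    ("side_H", 0.45, 18, 3),
]


def _scenario_library(variant: str) -> SpectralLibrary:
    specs, backbone = (_TRIO_SPECS, 900) if variant == "three" else (_QUINT_SPECS, 910)
    return SpectralLibrary(
        [_family_spectrum(lab, backbone, s, nb, w) for lab, w, s, nb in specs]
    )


def hidden_peak_scenario(seed: int = 0, variant: str = "three"):
    """Co-elution scenarios with a spectrally hidden species.

    ``variant="three"``: three related species. The middle one elutes as
    a broader peak (σ = 0.12 min) exactly between two narrow neighbours
    (σ = 0.06 min) spaced 1.2·σ away, so it shows no apex of its own and
    its spectrum is convolved with a flanker at every timepoint (its
    maximum fractional contribution to the signal stays below 0.9).

    ``variant="five"``: five species in a wider window — three resolved
    but partially overlapping peaks plus a nearly coincident pair
    (ΔRt = 0.3·σ of the broader member) hidden under a single apex: a
    narrow dominant member riding on a broader partner.

    ``seed`` drives only the noise realisation; the species spectra and
    the elution layout are fixed, so replicate calls give replicate
    chromatograms of the same ground truth. Noise sd is 1% of the
    maximum noiseless signal.

    Returns ``(chromatogram, truth)`` where truth is the record from
    :func:`simulate_chromatogram` plus the library and analysis window.
    """
    if variant == "three":
        labels = [s[0] for s in _TRIO_SPECS]
        sigmas = [0.06, 0.12, 0.06]
        spacing = 1.2 * sigmas[1]
        rts = [6.0 - spacing, 6.0, 6.0 + spacing]
        amounts = [1.0, 1.0, 1.0]
        window = (5.0, 7.0)
    elif variant == "five":
        labels = [s[0] for s in _QUINT_SPECS]
        sigmas = [0.10, 0.06, 0.12, 0.10, 0.10]
        pair_sep = 0.3 * sigmas[2]
        rts = [8.45, 8.878 - pair_sep / 2, 8.878 + pair_sep / 2, 9.31, 9.74]
        amounts = [1.0, 1.3, 1.0, 1.0, 1.0]
        window = (8.0, 10.2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    library = _scenario_library(variant)
    species = [
        SpeciesSpec(lab, rt, sg, amount=am)
        for lab, rt, sg, am in zip(labels, rts, sigmas, amounts)
    ]
    cfg = SimulationConfig(
        species=species,
        time_start=window[0],
        time_stop=window[1],
        time_step=0.005,
        noise_sd=0.0,
        seed=int(seed),
    )
    # set noise relative to the clean peak signal
    clean, _ = simulate_chromatogram(cfg, library)
    cfg.noise_sd = SCENARIO_NOISE_FRACTION * float(clean.absorbance.max())
    chrom, truth = simulate_chromatogram(cfg, library)
    truth["library"] = library
    truth["window"] = window
    return chrom, truth


def panel_scenario(seed: int = 0, n_species: int = 24):
    """A full separation of ``n_species`` species for end-to-end runs.

    Layout: the hidden triplet of the three-species scenario, the
    nearly coincident pair of the five-species scenario, and the
    remaining species chromatographically resolved at 1 min spacing
    (ample at σ = 0.1 min). The returned library carries 3 replicate
    spectra per species (independent noise, ≤0.5 nm registration
    shifts) so it can train the fingerprint classifier. Chromatogram
    noise sd is 1% of the tallest peak.

    Returns ``(chromatogram, truth, library)``.
    """
    if n_species < 6:
        raise ValueError("panel needs at least 6 species (triplet + pair + singles)")
    # base spectra: the congested-scenario species keep their identities,
    # the resolved singles are fresh random species
    bases = [_family_spectrum(lab, 900, s, nb, w) for lab, w, s, nb in _TRIO_SPECS]
    bases += [
        _family_spectrum(lab, 910, s, nb, w) for lab, w, s, nb in _QUINT_SPECS[1:3]
    ]
    rng = np.random.default_rng(977)
    for i in range(n_species - 5):
        # the panel emulates a mix monitored at 230 nm, so every resolved
        # species must absorb there; redraw until the band layout does
        while True:
            cand = make_synthetic_spectrum(
                f"single_{i:02d}", int(rng.integers(2, 6)), seed=int(rng.integers(0, 2**31))
            )
            at230 = np.interp(230.0, cand.wavelength, cand.absorbance)
            if at230 >= 0.2:
                bases.append(cand)
                break
    # replicate library for classifier training
    entries = []
    for b in bases:
        for _ in range(3):
            shift = rng.uniform(-0.5, 0.5)
            noisy = np.clip(b.absorbance + rng.normal(0.0, 0.01, b.absorbance.size), 0.0, None)
            entries.append(ReferenceSpectrum(b.species, b.wavelength + shift, noisy, "synthetic"))
    library = SpectralLibrary(entries)

    # elution layout: triplet then pair then singles
    species = [
        SpeciesSpec("hidden_A", 1.856, 0.06, 1.0),
        SpeciesSpec("hidden_B", 2.000, 0.12, 1.0),
        SpeciesSpec("hidden_C", 2.144, 0.06, 1.0),
        SpeciesSpec("pair_D", 2.982, 0.06, 1.3),
        SpeciesSpec("pair_E", 3.018, 0.12, 1.0),
    ]
    t = 4.0
    for b in bases[5:]:
        species.append(SpeciesSpec(b.species, t, 0.10, 1.0))
        t += 1.0
    cfg = SimulationConfig(
        species=species,
        time_start=0.5,
        time_stop=species[-1].rt + 1.0,
        time_step=0.005,
        noise_sd=0.0,
        seed=int(seed),
    )
    clean, _ = simulate_chromatogram(cfg, library)
    cfg.noise_sd = SCENARIO_NOISE_FRACTION * float(clean.absorbance.max())
    chrom, truth = simulate_chromatogram(cfg, library)
    return chrom, truth, library
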