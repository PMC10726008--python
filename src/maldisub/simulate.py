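"""Synthetic cohorts of linear-mode MALDI-TOF protein fingerprint spectra.

The generator emulates the statistical structure of a two-subspecies
*Bifidobacterium longum* cohort: each strain carries each discriminatory
marker peak by a single strain-level Bernoulli draw at its subspecies
presence frequency, plus a set of backbone peaks shared by every strain.
Four replicate spectra per strain are produced with log-normal intensity
variation, Gaussian mass jitter (calibration error), an exponentially
decaying chemical baseline and additive detector noise, over the 2-20 kDa
acquisition window.

Replicate dropout (a small probability that a present marker is missed in
one replicate) makes replicates of one strain disagree occasionally, which
is what makes replicate-level voting meaningful downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from maldisub.markers import MarkerDef, default_marker_table
from maldisub.preprocess import Spectrum, write_spectrum_txt

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

MZ_MIN = 2000.0
MZ_MAX = 20000.0
BACKBONE_MZ_MAX = 12000.0  # most fingerprint biomarkers sit below ~10-12 kDa


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the published cohort design: 59 + 41 strains, 4 replicates
    each (400 spectra), the 18 published marker frequencies, calibration
    jitter whose 3-sigma span matches the instrument's <300 ppm statement,
    and a mass resolution that keeps the 5,381 / 5,394 doublet resolved.
    """

    n_longum: int = 59
    n_infantis: int = 41
    replicates_per_strain: int = 4
    markers: list[MarkerDef] = field(default_factory=default_marker_table)
    n_backbone_peaks: int = 30
    mass_jitter_ppm_sd: float = 100.0
    replicate_dropout_prob: float = 0.05
    resolution: float = 1000.0  # m/dm, sets Gaussian FWHM = mz/resolution
    intensity_cv: float = 0.3  # log-normal sigma per strain x peak
    baseline_amplitude: float = 0.05
    noise_sd: float = 0.01
    mode: str = "profile"  # "profile" or "centroid"
    grid_step_da: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_longum", "n_infantis", "replicates_per_strain"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1; got {getattr(self, name)}")
        if self.mass_jitter_ppm_sd < 0:
            raise ValueError(f"mass_jitter_ppm_sd must be >= 0; got {self.mass_jitter_ppm_sd}")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0; got {self.resolution}")
        if not (0.0 <= self.replicate_dropout_prob < 1.0):
            raise ValueError(
                f"replicate_dropout_prob must lie in [0, 1); got {self.replicate_dropout_prob}"
            )
        if self.mode not in ("profile", "centroid"):
            raise ValueError(f"mode must be 'profile' or 'centroid'; got {self.mode!r}")
        if self.n_backbone_peaks < 0:
            raise ValueError(f"n_backbone_peaks must be >= 0; got {self.n_backbone_peaks}")
        if self.grid_step_da <= 0:
            raise ValueError(f"grid_step_da must be > 0; got {self.grid_step_da}")


@dataclass
class StrainTraits:
    """Frozen per-strain state: marker carriage and intensity factors."""

    strain_id: str
    label: int  # 0 = longum, 1 = infantis
    marker_present: np.ndarray  # bool per marker
    marker_intensity: np.ndarray  # amplitude per marker (strain x peak log-normal)
    backbone_intensity: np.ndarray  # amplitude per backbone peak


def _draw_backbone_positions(rng: np.random.Generator, n: int,
                             marker_mz: np.ndarray) -> np.ndarray:
    """Backbone peak positions, uniform over [2, 12] kDa.

    Positions landing within 2000 ppm of a configured marker are rejected and
    redrawn: backbone peaks are by definition distinct from the markers, and a
    collision inside the alignment tolerance would merge a marker column with
    an always-present peak.
    """
    out: list[float] = []
    while len(out) < n:
        cand = rng.uniform(MZ_MIN, BACKBONE_MZ_MAX)
        if marker_mz.size and np.min(np.abs(marker_mz - cand)) <= 2000e-6 * cand:
            continue
        out.append(cand)
    return np.sort(np.asarray(out))


def simulate_spectrum(
    traits: StrainTraits,
    replicate: int,
    rng: np.random.Generator,
    config: SimConfig,
    backbone_mz: np.ndarray,
) -> Spectrum:
    """Render one replicate spectrum from frozen strain traits.

    Every peak center receives Gaussian mass jitter with sd
    ``mass_jitter_ppm_sd`` (relative), each amplitude a per-replicate
    log-normal factor, and present markers are dropped independently with
    probability ``replicate_dropout_prob``. Profile mode sums Gaussian peak
    shapes (FWHM = mz/resolution) on a uniform grid, adds a decaying baseline
    and clipped white noise; centroid mode returns the jittered stick list.
    """
    marker_mz = np.array([m.mz_true for m in config.markers], dtype=float)
    keep = traits.marker_present.copy()
    if config.replicate_dropout_prob > 0:
        drop = rng.random(keep.size) < config.replicate_dropout_prob
        keep &= ~drop
    else:
        rng.random(keep.size)  # keep the stream aligned across dropout settings

    centers = np.concatenate([marker_mz[keep], backbone_mz])
    amps = np.concatenate([traits.marker_intensity[keep], traits.backbone_intensity])
    # per-replicate intensity wobble, half the strain-level spread
    amps = amps * rng.lognormal(0.0, config.intensity_cv / 2.0, centers.size)
    centers = centers * (1.0 + rng.normal(0.0, config.mass_jitter_ppm_sd * 1e-6, centers.size))
    centers = np.clip(centers, MZ_MIN, MZ_MAX)

    if config.mode == "centroid":
        order = np.argsort(centers)
        mz, inten = centers[order], amps[order]
        # collapse pathological exact duplicates to keep m/z strictly ascending
        if mz.size > 1:
            uniq = np.concatenate([[True], np.diff(mz) > 0])
            mz, inten = mz[uniq], inten[uniq]
        return Spectrum(mz, inten, traits.strain_id, replicate, traits.label, centroid=True)

    grid = np.arange(MZ_MIN, MZ_MAX + config.grid_step_da, config.grid_step_da)
    y = config.baseline_amplitude * np.exp(-(grid - MZ_MIN) / 3000.0)
    for c, a in zip(centers, amps):
        sigma = (c / config.resolution) * GAUSS_FWHM_TO_SIGMA
        lo = np.searchsorted(grid, c - 5 * sigma)
        hi = np.searchsorted(grid, c + 5 * sigma)
        if hi > lo:
            y[lo:hi] += a * np.exp(-0.5 * ((grid[lo:hi] - c) / sigma) ** 2)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, grid.size)
    y = np.clip(y, 0.0, None)
    return Spectrum(grid, y, traits.strain_id, replicate, traits.label, centroid=False)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, list[Spectrum]]:
    """Simulate a full two-subspecies cohort.

    Returns
    -------
    manifest : pandas.DataFrame
        Columns ``strain_id, label, replicate, path`` (path empty until
        :func:`write_cohort` is used), one row per spectrum.
    spectra : list of Spectrum
        ``(n_longum + n_infantis) * replicates_per_strain`` spectra, in
        manifest order. Deterministic given the config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    marker_mz = np.array([m.mz_true for m in config.markers], dtype=float)
    backbone_mz = _draw_backbone_positions(rng, config.n_backbone_peaks, marker_mz)
    backbone_base = rng.lognormal(0.0, config.intensity_cv, config.n_backbone_peaks)

    labels = [0] * config.n_longum + [1] * config.n_infantis
    rows = []
    spectra: list[Spectrum] = []
    for i, label in enumerate(labels):
        strain_id = f"{'L' if label == 0 else 'I'}{i:03d}"
        probs = np.array(
            [m.p_infantis if label == 1 else m.p_longum for m in config.markers]
        )
        present = rng.random(len(config.markers)) < probs
        marker_amp = np.array([m.mean_rel_intensity for m in config.markers])
        marker_amp = marker_amp * rng.lognormal(0.0, config.intensity_cv, marker_amp.size)
        backbone_amp = backbone_base * rng.lognormal(0.0, config.intensity_cv, backbone_base.size)
        traits = StrainTraits(strain_id, label, present, marker_amp, backbone_amp)
        for rep in range(config.replicates_per_strain):
            spectra.append(simulate_spectrum(traits, rep, rng, config, backbone_mz))
            rows.append({"strain_id": strain_id, "label": label, "replicate": rep, "path": ""})
    manifest = pd.DataFrame(rows, columns=["strain_id", "label", "replicate", "path"])
    return manifest, spectra


def write_cohort(manifest: pd.DataFrame, spectra: list[Spectrum], outdir) -> pd.DataFrame:
    """Write spectra as two-column text files plus a ``manifest.csv``.

    Returns the manifest with ``path`` filled (relative to ``outdir``).
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for i, s in enumerate(spectra):
        rel = f"spectra/{s.strain_id}_r{s.replicate}.txt"
        write_spectrum_txt(s, outdir / rel)
        manifest.loc[manifest.index[i], "path"] = rel
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
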