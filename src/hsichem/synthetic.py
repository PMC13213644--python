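"""Synthetic data generation for the root-authentication pipeline.

Real acquisitions for this problem — powdered-root hypercubes with dark/white
reference frames, ROI mean spectra with HPLC reference concentrations, and
LC/GC-MS feature tables — are not publicly deposited, so every downstream
stage is exercised on simulated inputs with known ground truth.

The reflectance model is Beer–Lambert-in-reflectance with multiplicative and
additive scatter:

    R(lambda) = a * B_c(lambda) * exp(-sum_k c_k * eps_k(lambda)) + b + noise

where ``B_c`` is a smooth class-dependent baseline (old roots markedly lower
than tuberous roots and taproots), ``eps_k`` are analyte absorptivity
profiles built from Gaussian peaks, ``c_k`` latent analyte concentrations
(log-normal, tuberous medians highest), ``a`` log-normal multiplicative and
``b`` normal additive scatter.  SNV and derivative pre-processing are designed
for exactly this structure, which makes their effect testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteLibrary",
    "ClassProfile",
    "SimulationConfig",
    "SpectrumSet",
    "default_analyte_library",
    "default_class_profiles",
    "simulate_spectrum_set",
    "simulate_hypercube",
    "simulate_feature_table",
    "planted_band_design",
]

CLASS_LABELS = ("tuberous", "taproot", "old")


@dataclass(frozen=True)
class AnalyteLibrary:
    """Absorptivity profiles of the marker analytes.

    Each analyte's absorptivity ``eps_k(lambda)`` is a sum of Gaussian peaks
    (unitless absorptivity per concentration unit, mg/g).  Peak centers are
    recorded so wavelength-selector recovery can be scored against ground
    truth.
    """

    names: tuple[str, ...]
    centers_nm: tuple[tuple[float, ...], ...]   # per analyte
    widths_nm: tuple[tuple[float, ...], ...]
    amplitudes: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        for cs in self.centers_nm:
            if len(cs) < 2:
                raise ValueError("each analyte needs >= 2 absorption peaks")
        sets = [frozenset(cs) for cs in self.centers_nm]
        if len(set(sets)) != len(sets):
            raise ValueError("analyte peak-center sets must differ")

    def epsilon(self, wavelengths: np.ndarray) -> np.ndarray:
        """Absorptivity matrix, shape (n_analytes, n_bands); >= 0 everywhere."""
        wl = np.asarray(wavelengths, dtype=float)
        eps = np.zeros((len(self.names), wl.size))
        for k, (cs, ws, amps) in enumerate(
            zip(self.centers_nm, self.widths_nm, self.amplitudes)
        ):
            for c, w, a in zip(cs, ws, amps):
                eps[k] += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return eps

    def peak_band_indices(self, wavelengths: np.ndarray) -> list[np.ndarray]:
        """Band index nearest each peak center, one array per analyte."""
        wl = np.asarray(wavelengths, dtype=float)
        return [
            np.array(sorted({int(np.argmin(np.abs(wl - c))) for c in cs}))
            for cs in self.centers_nm
        ]


@dataclass(frozen=True)
class ClassProfile:
    """Baseline reflectance and analyte-concentration distribution of a root class.

    Besides an overall level, each class carries pigment absorption features in
    the VIS region (center/width/depth Gaussians multiplying the baseline):
    root classes differ visibly in color, and those chromophore differences are
    what the visible bands of real spectra encode.
    """

    label: str
    baseline_scale: float
    baseline_offset: float
    conc_median: tuple[float, ...]   # log-normal medians, mg/g
    conc_sigma: float                # log-scale SD, shared across analytes
    pigment_centers: tuple[float, ...] = ()
    pigment_widths: tuple[float, ...] = ()
    pigment_depths: tuple[float, ...] = ()    # fractional dips, each < 1

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        """Smooth reflectance baseline in %, strictly positive."""
        wl = np.asarray(wavelengths, dtype=float)
        base = (
            22.0
            + 55.0 / (1.0 + np.exp(-(wl - 620.0) / 90.0))
            - 8.0 * np.exp(-0.5 * ((wl - 985.0) / 40.0) ** 2)
        )
        pigment = np.ones_like(wl)
        for c, w, d in zip(
            self.pigment_centers, self.pigment_widths, self.pigment_depths
        ):
            pigment -= d * np.exp(-0.5 * ((wl - c) / w) ** 2)
        out = (self.baseline_scale * base + self.baseline_offset) * pigment
        if np.any(out <= 0) or np.any(out > 100):
            raise ValueError(f"baseline for {self.label!r} outside (0, 100]")
        return out


def default_analyte_library() -> AnalyteLibrary:
    """Three marker analytes emulating norisoboldine, linderane and lindenenol.

    Peak positions are placed strictly inside the 427–994 nm window and chosen
    so the three peak sets are disjoint; amplitudes give absorbances of
    roughly 0.1–0.5 at class-typical concentrations.
    """
    return AnalyteLibrary(
        names=("norisoboldine", "linderane", "lindenenol"),
        centers_nm=((520.0, 760.0, 910.0), (560.0, 830.0), (480.0, 700.0, 950.0)),
        widths_nm=((18.0, 22.0, 25.0), (20.0, 25.0), (16.0, 20.0, 28.0)),
        amplitudes=((0.12, 0.10, 0.08), (0.50, 0.40), (0.10, 0.08, 0.07)),
    )


def default_class_profiles() -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """Tuberous root, taproot and old root.

    Old-root baseline is scaled well below the other two (its reflectance is
    markedly lower across the band range); tuberous concentration medians are
    strictly the highest for all three analytes, taproot and old root similar.
    Each class has its own VIS pigment signature — fresh tuberous tissue,
    slightly different taproot coloration, and the darker oxidized browning of
    old roots — so the visible bands carry class identity the way real root
    color does.
    """
    return (
        ClassProfile(
            "tuberous", 1.00, 0.0, (2.0, 0.50, 2.5), 0.35,
            pigment_centers=(505.0,), pigment_widths=(35.0,),
            pigment_depths=(0.05,),
        ),
        ClassProfile(
            "taproot", 0.96, 2.0, (0.8, 0.20, 1.0), 0.35,
            pigment_centers=(548.0,), pigment_widths=(38.0,),
            pigment_depths=(0.06,),
        ),
        ClassProfile(
            "old", 0.78, 0.0, (0.7, 0.18, 0.9), 0.35,
            pigment_centers=(468.0, 642.0), pigment_widths=(30.0, 36.0),
            pigment_depths=(0.07, 0.05,),
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum simulator; the seed fully determines all outputs.

    Defaults mirror the study conditions: 270 bands on 427–994 nm and an
    87/30/30 tuberous/taproot/old sample layout.
    """

    n_bands: int = 270
    wavelength_range: tuple[float, float] = (427.0, 994.0)
    samples_per_class: tuple[int, int, int] = (87, 30, 30)
    scatter_mult_sigma: float = 0.05   # a ~ lognormal(0, sigma)
    scatter_add_sigma: float = 0.5     # b ~ normal(0, sigma), reflectance %
    noise_sd: float = 0.1              # per-band noise on ROI-mean spectra, reflectance %
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 10:
            raise ValueError("n_bands must be >= 10")
        if any(n < 2 for n in self.samples_per_class):
            raise ValueError("samples_per_class entries must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError("wavelength range must be increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_bands)


@dataclass
class SpectrumSet:
    """Samples x bands reflectance matrix with labels and reference concentrations."""

    wavelengths: np.ndarray            # (bands,)
    spectra: np.ndarray                # (samples, bands), reflectance %
    labels: np.ndarray                 # (samples,) class labels
    concentrations: pd.DataFrame       # samples x analytes, mg/g

    def __post_init__(self) -> None:
        if self.spectra.shape != (len(self.labels), self.wavelengths.size):
            raise ValueError("spectra shape inconsistent with labels/wavelengths")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    def to_csv(self, path) -> None:
        """One sample per row: label, analyte columns, then one column per band."""
        df = pd.DataFrame(
            self.spectra, columns=[f"{wl:.4f}" for wl in self.wavelengths]
        )
        df.insert(0, "label", self.labels)
        for i, name in enumerate(self.concentrations.columns):
            df.insert(1 + i, name, self.concentrations[name].to_numpy())
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c.replace(".", "", 1).isdigit()]
        conc_cols = [c for c in df.columns if c not in band_cols and c != "label"]
        return cls(
            wavelengths=np.array([float(c) for c in band_cols]),
            spectra=df[band_cols].to_numpy(float),
            labels=df["label"].to_numpy(),
            concentrations=df[conc_cols].copy(),
        )


def _reflectance(
    baseline: np.ndarray,
    eps: np.ndarray,
    conc: np.ndarray,
    a: float,
    b: float,
    noise: np.ndarray,
) -> np.ndarray:
    r = a * baseline * np.exp(-conc @ eps) + b + noise
    return np.clip(r, 0.0, 100.0)


def simulate_spectrum_set(
    config: SimulationConfig,
    classes: tuple[ClassProfile, ...] | None = None,
    library: AnalyteLibrary | None = None,
) -> SpectrumSet:
    """Draw a labeled spectrum set with known analyte concentrations.

    Deterministic for a fixed config (seed included).  Raises if a class
    baseline is non-positive anywhere on the band grid.
    """
    classes = default_class_profiles() if classes is None else classes
    library = default_analyte_library() if library is None else library
    if len(classes) != len(config.samples_per_class):
        raise ValueError("need one sample count per class profile")
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    eps = library.epsilon(wl)

    spectra, labels, concs = [], [], []
    for profile, n in zip(classes, config.samples_per_class):
        base = profile.baseline(wl)
        med = np.asarray(profile.conc_median, dtype=float)
        for _ in range(n):
            c = med * rng.lognormal(0.0, profile.conc_sigma, size=med.size)
            a = rng.lognormal(0.0, config.scatter_mult_sigma)
            b = rng.normal(0.0, config.scatter_add_sigma)
            noise = rng.normal(0.0, config.noise_sd, size=wl.size)
            spectra.append(_reflectance(base, eps, c, a, b, noise))
            labels.append(profile.label)
            concs.append(c)

    return SpectrumSet(
        wavelengths=wl,
        spectra=np.array(spectra),
        labels=np.array(labels),
        concentrations=pd.DataFrame(np.array(concs), columns=list(library.names)),
    )


def simulate_hypercube(
    config: SimulationConfig,
    layout: np.ndarray,
    library: AnalyteLibrary | None = None,
    classes: tuple[ClassProfile, ...] | None = None,
):
    """Simulate a raw hypercube plus its dark/white reference frames.

    ``layout`` is a (rows, cols) array of class labels; empty string (or None)
    marks background.  The raw cube is ``D + (W - D) * R / 100`` per pixel with
    R drawn from the reflectance model, so black/white calibration is exactly
    invertible when scatter and noise are off.  Background pixels carry a
    near-dark constant signature (2 % reflectance) so thresholding masks are
    testable.

    Returns ``(raw_cube, dark, white, truth)`` where ``raw_cube`` is a
    ``hsi_io.RawCube``, dark/white are per-band reference vectors, and
    ``truth`` maps per-pixel labels and true concentration grids.
    """
    from .hsi_io import RawCube, ReferenceFrames  # local import: avoid cycle

    classes = default_class_profiles() if classes is None else classes
    library = default_analyte_library() if library is None else library
    layout = np.asarray(layout, dtype=object)
    if layout.ndim != 2:
        raise ValueError("layout must be a 2-D grid of class labels")
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    eps = library.epsilon(wl)
    profiles = {p.label: p for p in classes}
    baselines = {lab: p.baseline(wl) for lab, p in profiles.items()}

    dark = 96.0 + 0.01 * np.arange(wl.size)
    white = 3600.0 + 0.4 * np.arange(wl.size)
    if np.any(white <= dark):
        raise ValueError("white frame must exceed dark frame at every band")

    rows, cols = layout.shape
    refl = np.zeros((rows, cols, wl.size))
    conc_grid = np.full((rows, cols, len(library.names)), np.nan)
    for i in range(rows):
        for j in range(cols):
            lab = layout[i, j]
            if lab is None or lab == "":
                refl[i, j] = np.clip(
                    2.0 + rng.normal(0.0, config.noise_sd, wl.size), 0.0, 100.0
                )
                continue
            if lab not in profiles:
                raise ValueError(f"unknown class label {lab!r} in layout")
            p = profiles[lab]
            c = np.asarray(p.conc_median) * rng.lognormal(
                0.0, p.conc_sigma, len(library.names)
            )
            a = rng.lognormal(0.0, config.scatter_mult_sigma)
            b = rng.normal(0.0, config.scatter_add_sigma)
            noise = rng.normal(0.0, config.noise_sd, wl.size)
            refl[i, j] = _reflectance(baselines[lab], eps, c, a, b, noise)
            conc_grid[i, j] = c

    raw = dark + (white - dark) * refl / 100.0
    truth = {
        "labels": np.where(np.equal(layout, None), "", layout).astype(str),
        "reflectance": refl,
        "concentrations": conc_grid,
        "analytes": list(library.names),
    }
    cube = RawCube(data=raw, wavelengths=wl)
    return cube, ReferenceFrames(dark=dark, white=white), truth


def simulate_feature_table(
    n_per_group: int | tuple[int, int, int] = (29, 10, 10),
    n_features: int = 500,
    n_differential: int = 40,
    fc: float = 4.0,
    seed: int = 0,
    n_qc: int = 6,
    log_sigma: float = 0.4,
    qc_sigma_factor: float = 0.15,
    base_log_mean: float = np.log(5e4),
):
    """Metabolomics feature table with planted differential features.

    Intensities are log-normal around feature-specific levels.  Each planted
    feature is elevated by the factor ``fc`` in one group (cycling through the
    three root groups) so its between-group population mean ratio equals
    ``fc``.  QC samples are drawn around the grand mean with strongly reduced
    variance, emulating pooled quality-control injections.  Planted feature
    ids are recorded in ``table.planted``.
    """
    from .metabolomics import FeatureTable  # local import: avoid cycle

    if isinstance(n_per_group, (int, np.integer)):
        n_per_group = (int(n_per_group),) * 3
    if len(n_per_group) != 3:
        raise ValueError("exactly three sample groups are modeled")
    if n_differential > n_features:
        raise ValueError("n_differential must be <= n_features")
    if fc <= 1:
        raise ValueError("fold change fc must exceed 1")

    rng = np.random.default_rng(seed)
    groups = CLASS_LABELS
    mu = rng.normal(base_log_mean, 1.0, size=n_features)   # per-feature level
    planted = rng.choice(n_features, size=n_differential, replace=False)
    planted.sort()
    up_group = {f: groups[i % 3] for i, f in enumerate(planted)}

    cols, labels = [], []
    for g, n in zip(groups, n_per_group):
        shift = np.zeros(n_features)
        for f in planted:
            if up_group[f] == g:
                shift[f] = np.log(fc)
        # log-normal mean correction keeps the arithmetic mean ratio exactly fc
        draw = rng.lognormal(
            mu[:, None] + shift[:, None] - log_sigma**2 / 2,
            log_sigma,
            size=(n_features, n),
        )
        cols.append(draw)
        labels += [g] * n
    grand = np.exp(mu)   # population grand level per feature
    qc = rng.lognormal(
        np.log(grand)[:, None] - (qc_sigma_factor * log_sigma) ** 2 / 2,
        qc_sigma_factor * log_sigma,
        size=(n_features, n_qc),
    )
    cols.append(qc)
    labels += ["QC"] * n_qc

    intensities = pd.DataFrame(
        np.hstack(cols),
        index=[f"F{i:04d}" for i in range(n_features)],
        columns=[f"S{i:03d}" for i in range(len(labels))],
    )
    table = FeatureTable(
        intensities=intensities, groups=pd.Series(labels, index=intensities.columns)
    )
    table.planted = [f"F{i:04d}" for i in planted]
    table.planted_up_group = {f"F{i:04d}": up_group[i] for i in planted}
    return table


def planted_band_design(
    n_samples: int = 100,
    n_bands: int = 270,
    n_informative: int = 10,
    coef_range: tuple[float, float] = (0.5, 1.5),
    background_sd: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Regression design with a known set of informative bands.

    The informative bands carry independent standard-normal signals that enter
    ``y`` linearly; the remaining bands are smooth correlated background plus
    independent noise, so only the planted bands predict ``y``.  This is the
    standard fixture for scoring wavelength-selector recovery.

    Returns ``(X, y, planted_indices)``.
    """
    rng = np.random.default_rng(seed)
    planted = np.sort(rng.choice(n_bands, size=n_informative, replace=False))
    # smooth background: random low-frequency cosines shared along the band axis
    t = np.linspace(0, 1, n_bands)
    background = np.zeros((n_samples, n_bands))
    for k in range(1, 6):
        amp = rng.normal(0.0, background_sd, size=(n_samples, 1))
        phase = rng.uniform(0, 2 * np.pi)
        background += amp * np.cos(2 * np.pi * k * t + phase)
    X = background + rng.normal(0.0, background_sd, size=(n_samples, n_bands))
    signals = rng.normal(0.0, 1.0, size=(n_samples, n_informative))
    X[:, planted] = signals
    w = rng.uniform(*coef_range, size=n_informative) * rng.choice(
        [-1.0, 1.0], size=n_informative
    )
    y = signals @ w + rng.normal(0.0, noise_sd, size=n_samples)
    return X, y, planted
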