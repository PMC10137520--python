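"""Synthetic production campaigns with known ground truth.

Real on-line campaigns from the plant are proprietary, so every downstream
stage is exercised on simulated data that reproduces the *structure* of the
real streams:

* NIR absorbance spectra (1100–1650 nm) built as mixtures of Gaussian
  absorption bands at the wavelengths the study flags — an intense water
  band near 1400 nm, olive-oil C–H bands near 1166/1213/1236/1461 nm, a
  lignin band near 1178 nm and an R–OH band near 1410 nm — with slow
  autoregressive drift of the band amplitudes (normal operating
  variability), multiplicative scatter, baseline offsets and white noise;
* RGB camera summary parameters on a 15 s cadence, held exactly constant
  during production stops (a frozen conveyor image);
* sparse quality responses — Bostwick consistency (cm) and total lipids
  (%) — measured at the end of the line, hence time-shifted by the process
  residence lag and linked to the latent drivers of the spectra;
* supplier/cut structure as contiguous segments with per-band intensity
  shifts, and restart anomalies: amplitude shifts on the flagged bands for
  a few points after each stop.

The generator is fully deterministic given a seed, and at zero noise the
stored ground-truth drivers reproduce the observables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .containers import QualitySeries, RGBSeries, SpectraBlock

__all__ = [
    "WavelengthGrid",
    "BandSpec",
    "CampaignConfig",
    "SyntheticCampaign",
    "DEFAULT_BANDS",
    "generate_campaign",
    "generate_noc_block",
    "inject_restart_anomaly",
    "nominal_spectrum",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform acquisition grid in nm (defaults cover 1100–1650 at 2 nm)."""

    start_nm: float = 1100.0
    end_nm: float = 1650.0
    step_nm: float = 2.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError("start_nm must be below end_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")

    def values(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + self.step_nm / 2, self.step_nm)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``restart_affected`` marks bands whose amplitude shifts when production
    restarts after a stop (residual old material in the pipe).
    """

    center_nm: float
    width_nm: float
    base_amplitude: float
    component_tag: str = "other"
    restart_affected: bool = False

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be nonnegative")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian profile on the grid."""
        return np.exp(-((wavelengths - self.center_nm) ** 2) / (2 * self.width_nm**2))


# Band set emulating the study system: water dominates the spectrum near
# 1400 nm; oil C-H bands drive the lipids response; the 1213/1236/1410/1178
# set carries the restart signature.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1400.0, 30.0, 1.00, "water"),
    BandSpec(1166.0, 12.0, 0.50, "oil"),
    BandSpec(1213.0, 10.0, 0.35, "oil", restart_affected=True),
    BandSpec(1236.0, 10.0, 0.30, "oil", restart_affected=True),
    BandSpec(1461.0, 15.0, 0.25, "oil"),
    BandSpec(1410.0, 18.0, 0.40, "roh", restart_affected=True),
    BandSpec(1178.0, 10.0, 0.20, "lignin", restart_affected=True),
)

# relative drift strength per component tag; water variability dominates so
# the first NOC principal component carries most of the variance, as on the
# real line
_TAG_DRIFT_SCALE = {"water": 2.5, "oil": 1.0, "roh": 1.0, "lignin": 1.0}

# fixed per-tag sensitivities of band intensity to raw-material origin: each
# supplier (and cut) shifts one common spectral direction by its own scalar,
# so origin effects are low-rank and stay inside the NOC model space, where
# the plant data showed them (score-plot separation, not off-model distance)
_SUPPLIER_SENSITIVITY = {"lignin": 1.0, "oil": 0.5, "roh": 0.3, "water": 0.1}
_CUT_SENSITIVITY = {"lignin": 1.0, "roh": 0.6, "oil": 0.3, "water": 0.1}


@dataclass
class CampaignConfig:
    """Everything needed to simulate one production campaign.

    Amplitude drivers are stationary AR(1) processes around 1 with
    autocorrelation ``drift_phi`` and marginal standard deviation
    ``drift_sd`` (scaled per component tag).  The latent physical state that
    sets consistency also modulates the multiplicative scatter through
    ``scatter_phys_coupling``, so consistency is not tied to any single
    absorption band.  Quality links are affine ``(intercept, slope)`` pairs:
    lipids % from the main oil-band amplitude, consistency cm from the
    physical-state driver.
    """

    n_time_points: int = 600
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    noise_sd: float = 0.0016
    scatter_multiplicative_sd: float = 0.002
    baseline_offset_sd: float = 0.005
    drift_sd: float = 0.05
    drift_phi: float = 0.0
    scatter_phys_coupling: float = 0.08
    phys_slope_coef: float = 0.02
    n_suppliers: int = 5
    n_cuts: int = 4
    supplier_effect_scale: float = 0.03
    cut_effect_scale: float = 0.02
    stop_schedule: tuple[tuple[int, int], ...] = (
        (100, 10),
        (200, 8),
        (320, 12),
        (430, 8),
        (520, 10),
    )
    restart_length: int = 5
    restart_anomaly_scale: float = 0.5
    lipid_link: tuple[float, float] = (20.0, 54.0)  # % = a + b * oil-band amplitude
    consistency_link: tuple[float, float] = (1.8, 5.0)  # cm = a + b * phys state
    lipids_noise_sd: float = 0.3
    consistency_noise_sd: float = 0.15
    rgb_noc_mean: tuple[float, float, float] = (60.0, 110.0, 55.0)
    rgb_noc_sd: tuple[float, float, float] = (4.0, 5.0, 3.0)
    quality_sampling_period: int = 3
    residence_lag_s: float = 300.0
    cadence_s: float = 15.0
    start_time: str = "2020-06-01T08:00:00"
    seed: int = 0

    def validate(self) -> None:
        if self.n_time_points < 1:
            raise ValueError("n_time_points must be >= 1")
        if len(self.bands) == 0:
            raise ValueError("band list must not be empty")
        wl = self.grid.values()
        for b in self.bands:
            if not (wl[0] <= b.center_nm <= wl[-1]):
                raise ValueError(f"band center {b.center_nm} nm lies outside the grid")
        for start, length in self.stop_schedule:
            if start < 0 or length < 1 or start + length > self.n_time_points:
                raise ValueError(
                    f"stop interval ({start}, {length}) does not fit in the campaign"
                )
        if self.quality_sampling_period < 1:
            raise ValueError("quality_sampling_period must be >= 1")

    def timeline(self, n: int | None = None) -> pd.DatetimeIndex:
        n = self.n_time_points if n is None else n
        start = pd.Timestamp(self.start_time)
        return pd.DatetimeIndex(
            [start + pd.Timedelta(seconds=self.cadence_s * i) for i in range(n)]
        )

    def to_yaml(self, path) -> None:
        d = {
            "n_time_points": self.n_time_points,
            "grid": {
                "start_nm": self.grid.start_nm,
                "end_nm": self.grid.end_nm,
                "step_nm": self.grid.step_nm,
            },
            "bands": [
                {
                    "center_nm": b.center_nm,
                    "width_nm": b.width_nm,
                    "base_amplitude": b.base_amplitude,
                    "component_tag": b.component_tag,
                    "restart_affected": b.restart_affected,
                }
                for b in self.bands
            ],
            "stop_schedule": [list(s) for s in self.stop_schedule],
        }
        for name in (
            "noise_sd",
            "scatter_multiplicative_sd",
            "baseline_offset_sd",
            "drift_sd",
            "drift_phi",
            "scatter_phys_coupling",
            "phys_slope_coef",
            "n_suppliers",
            "n_cuts",
            "supplier_effect_scale",
            "cut_effect_scale",
            "restart_length",
            "restart_anomaly_scale",
            "lipids_noise_sd",
            "consistency_noise_sd",
            "quality_sampling_period",
            "residence_lag_s",
            "cadence_s",
            "start_time",
            "seed",
        ):
            d[name] = getattr(self, name)
        d["lipid_link"] = list(self.lipid_link)
        d["consistency_link"] = list(self.consistency_link)
        d["rgb_noc_mean"] = list(self.rgb_noc_mean)
        d["rgb_noc_sd"] = list(self.rgb_noc_sd)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        kwargs = dict(d)
        if "grid" in kwargs:
            kwargs["grid"] = WavelengthGrid(**kwargs["grid"])
        if "bands" in kwargs:
            kwargs["bands"] = tuple(BandSpec(**b) for b in kwargs["bands"])
        if "stop_schedule" in kwargs:
            kwargs["stop_schedule"] = tuple(tuple(s) for s in kwargs["stop_schedule"])
        for name in ("lipid_link", "consistency_link", "rgb_noc_mean", "rgb_noc_sd"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


@dataclass
class SyntheticCampaign:
    """One simulated campaign with labels and ground truth.

    ``labels`` carries supplier, cut, is_stop and is_restart_anomaly per
    time point; ``ground_truth`` carries the latent drivers and the
    noise-free band amplitudes that generated the observables.
    """

    spectra: SpectraBlock
    rgb: RGBSeries
    quality: QualitySeries
    labels: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CampaignConfig

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spectra.to_csv(out / "spectra.csv")
        self.rgb.to_csv(out / "rgb.csv")
        self.quality.to_csv(out / "quality.csv")
        self.labels.to_csv(out / "labels.csv")
        self.ground_truth.to_csv(out / "ground_truth.csv")
        self.config.to_yaml(out / "config.yaml")


def nominal_spectrum(config: CampaignConfig) -> np.ndarray:
    """The deterministic band mixture at nominal (unit) driver levels."""
    wl = config.grid.values()
    return sum(b.base_amplitude * b.profile(wl) for b in config.bands)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary zero-mean AR(1) with marginal standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi**2) if abs(phi) < 1 else sd
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _segments(rng: np.random.Generator, n: int, n_groups: int) -> np.ndarray:
    """Contiguous group labels over n points (suppliers/cuts arrive in lots)."""
    if n_groups <= 1:
        return np.zeros(n, dtype=int)
    n_segments = min(max(n_groups, min(3 * n_groups, n)), n)
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_segments - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [n]])
    labels = np.empty(n, dtype=int)
    for k in range(n_segments):
        labels[bounds[k] : bounds[k + 1]] = k % n_groups
    return labels


def generate_campaign(config: CampaignConfig) -> SyntheticCampaign:
    """Simulate one full campaign; identical config ⇒ identical output."""
    config.validate()
    n = config.n_time_points
    wl = config.grid.values()
    bands = config.bands
    ss = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["drivers", "segments", "effects", "spectra", "rgb", "quality"],
            ss.spawn(6),
        )
    }

    # --- latent drivers: one AR(1) per band component tag + physical state
    tags = sorted({b.component_tag for b in bands})
    drivers = {}
    for tag in tags:
        scale = _TAG_DRIFT_SCALE.get(tag, 1.0)
        drivers[tag] = 1.0 + _ar1(
            rngs["drivers"], n, config.drift_phi, config.drift_sd * scale
        )
    phys = 1.0 + _ar1(rngs["drivers"], n, config.drift_phi, config.drift_sd)

    # --- supplier / cut structure: contiguous lots with per-band intensity shifts
    supplier = _segments(rngs["segments"], n, config.n_suppliers)
    cut = _segments(rngs["segments"], n, config.n_cuts)
    sup_eff = rngs["effects"].normal(0, config.supplier_effect_scale, config.n_suppliers)
    cut_eff = rngs["effects"].normal(0, config.cut_effect_scale, config.n_cuts)

    # --- stops and restart windows
    is_stop = np.zeros(n, dtype=bool)
    is_restart = np.zeros(n, dtype=bool)
    for start, length in config.stop_schedule:
        is_stop[start : start + length] = True
        r0 = start + length
        is_restart[r0 : min(r0 + config.restart_length, n)] = True
    is_restart &= ~is_stop

    # --- band amplitudes per time point; the clean amplitude is the material's
    # true composition, the restart shift only distorts the measured spectrum
    amplitudes_clean = np.empty((n, len(bands)))
    for j, b in enumerate(bands):
        amp = b.base_amplitude * drivers[b.component_tag]
        s_sens = _SUPPLIER_SENSITIVITY.get(b.component_tag, 0.5)
        c_sens = _CUT_SENSITIVITY.get(b.component_tag, 0.5)
        amplitudes_clean[:, j] = (
            amp * (1.0 + sup_eff[supplier] * s_sens) * (1.0 + cut_eff[cut] * c_sens)
        )
    restart_shift = np.array(
        [
            config.restart_anomaly_scale * b.base_amplitude if b.restart_affected else 0.0
            for b in bands
        ]
    )
    amplitudes = amplitudes_clean + np.outer(is_restart, restart_shift)

    # --- spectra: mixture × multiplicative scatter + scatter slope + baseline
    # + white noise; the physical state (texture/particle size) modulates both
    # the overall scatter level and its wavelength dependence, so consistency
    # is carried by scatter behaviour rather than any single absorption band
    profiles = np.vstack([b.profile(wl) for b in bands])  # (n_bands, n_wl)
    clean = amplitudes @ profiles
    scatter = config.scatter_multiplicative_sd * rngs["spectra"].normal(size=n)
    scatter = scatter + config.scatter_phys_coupling * (phys - 1.0)
    lam_norm = 2.0 * (wl - wl.mean()) / (wl[-1] - wl[0])
    slope = config.phys_slope_coef * np.outer(phys - 1.0, lam_norm)
    baseline = config.baseline_offset_sd * rngs["spectra"].normal(size=n)
    noise = config.noise_sd * rngs["spectra"].normal(size=(n, len(wl)))
    values = clean * (1.0 + scatter)[:, None] + slope + baseline[:, None] + noise

    timestamps = config.timeline()
    spectra = SpectraBlock(timestamps, wl, values)

    # --- RGB: noisy NOC level, frozen at the last pre-stop frame during stops
    rgb_mean = np.array(config.rgb_noc_mean) + rngs["rgb"].normal(
        0, config.rgb_noc_sd, size=(n, 3)
    )
    rgb_sd = np.abs(
        np.array([12.0, 15.0, 10.0]) + rngs["rgb"].normal(0, 1.0, size=(n, 3))
    )
    for start, length in config.stop_schedule:
        # the frame in view when the belt stops is the one that stays frozen
        rgb_mean[start : start + length] = rgb_mean[start]
        rgb_sd[start : start + length] = rgb_sd[start]
    rgb = RGBSeries(timestamps, rgb_mean, rgb_sd)

    # --- quality: sampled every period, measured at the end of the line
    oil_main = max(
        (b for b in bands if b.component_tag == "oil"),
        key=lambda b: b.base_amplitude,
        default=bands[0],
    )
    oil_idx = bands.index(oil_main)
    # the material's actual oil-band amplitude drives lipids (restart shifts
    # distort the spectrum, not the finished product)
    oil_amp_true = amplitudes_clean[:, oil_idx]
    a_l, b_l = config.lipid_link
    a_c, b_c = config.consistency_link
    lipids_true = a_l + b_l * oil_amp_true
    consistency_true = a_c + b_c * phys
    q_idx = np.arange(0, n, config.quality_sampling_period)
    lag = pd.Timedelta(seconds=config.residence_lag_s)
    q_times = timestamps[q_idx] + lag
    lipids = lipids_true[q_idx] + config.lipids_noise_sd * rngs["quality"].normal(
        size=q_idx.size
    )
    consistency = consistency_true[q_idx] + config.consistency_noise_sd * rngs[
        "quality"
    ].normal(size=q_idx.size)
    quality = QualitySeries(q_times, consistency, lipids)

    labels = pd.DataFrame(
        {
            "supplier": supplier,
            "cut": cut,
            "is_stop": is_stop,
            "is_restart_anomaly": is_restart,
        },
        index=timestamps,
    )
    gt = pd.DataFrame(
        {f"driver_{tag}": drivers[tag] for tag in tags}
        | {
            "phys_state": phys,
            "oil_band_amplitude": oil_amp_true,
            "lipids_true": lipids_true,
            "consistency_true": consistency_true,
        }
        | {f"amp_{b.center_nm:g}nm": amplitudes[:, j] for j, b in enumerate(bands)},
        index=timestamps,
    )
    gt.attrs["oil_band_index"] = oil_idx
    return SyntheticCampaign(spectra, rgb, quality, labels, gt, config)


def generate_noc_block(n: int, config: CampaignConfig | None = None) -> SpectraBlock:
    """Pure NOC spectra: drift, scatter, baseline and noise but no stops,
    restarts or supplier/cut shifts.  Used for MSPC calibration."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or CampaignConfig()
    noc_cfg = replace(
        config,
        n_time_points=n,
        stop_schedule=(),
        supplier_effect_scale=0.0,
        cut_effect_scale=0.0,
        n_suppliers=1,
        n_cuts=1,
    )
    return generate_campaign(noc_cfg).spectra


def inject_restart_anomaly(
    block: SpectraBlock,
    indices,
    scale: float,
    bands: tuple[BandSpec, ...] | None = None,
) -> SpectraBlock:
    """Shift the restart-affected band amplitudes at the given rows.

    Adds ``scale × base_amplitude`` of each restart-affected band's profile
    to the selected spectra; all other rows are untouched and the input
    block is never mutated.  ``scale = 0`` (or an empty index list) returns
    an identical copy.
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= block.n_samples):
        raise ValueError("anomaly indices outside the block")
    bands = bands if bands is not None else DEFAULT_BANDS
    affected = [b for b in bands if b.restart_affected]
    values = block.values.copy()
    if indices.size and affected:
        shift = sum(
            scale * b.base_amplitude * b.profile(block.wavelengths) for b in affected
        )
        values[indices] += shift
    return SpectraBlock(block.timestamps, block.wavelengths, values)
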