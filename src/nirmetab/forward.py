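"""Beer-Lambert forward model for the implanted NIR sensor and the
reference blood analyzers.

The sensor is modeled as a 24-channel absorbance spectrometer on a fixed
wavelength grid spanning 1680-2400 nm. Each spectrum is a baseline plus a
linear mixture of per-compound absorptivity profiles (absorbance units per
mM per mm of pathlength) evaluated at the ground-truth concentrations, with
i.i.d. Gaussian channel noise and a slow sinusoidal baseline drift. No
scattering, temperature or hydration effects are modeled.

Reference measurements emulate the clinical analyzers: multiplicative
Gaussian noise at the device's coefficient of variation, values clipped to
the device measuring range, and blood draws every 5 minutes tightening to
2.5 minutes while glucose is below 70 mg/dl.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .visits import MGDL_PER_MM, ConcentrationSeries

__all__ = [
    "AbsorptivityLibrary",
    "SpectraSeries",
    "ReferenceSeries",
    "DEVICES",
    "default_library",
    "default_baseline",
    "absorbance_spectrum",
    "simulate_sensor_series",
    "simulate_reference",
    "to_transmittance",
]

N_CHANNELS = 24
WAVELENGTH_MIN, WAVELENGTH_MAX = 1680.0, 2400.0


@dataclass(frozen=True)
class AbsorptivityLibrary:
    """Per-compound molar absorptivity profiles on the sensor wavelength grid.

    ``absorptivities`` maps compound name to a vector of absorbance units per
    mM per mm, one entry per channel. Glucose is keyed in mM internally; the
    mg/dl ground truth is converted on entry to the forward model.
    """

    wavelengths_nm: np.ndarray
    absorptivities: dict[str, np.ndarray]
    pathlength_mm: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise ValueError(
                f"wavelengths must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        for name, eps in self.absorptivities.items():
            eps = np.asarray(eps, float)
            if eps.shape != wl.shape:
                raise ValueError(f"absorptivity vector for {name!r} has wrong length")
            if np.any(eps < 0):
                raise ValueError(f"absorptivities must be >= 0 ({name!r})")

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths_nm)

    def matrix(self, compounds: list[str]) -> np.ndarray:
        """Channels x compounds absorptivity matrix."""
        return np.column_stack([self.absorptivities[c] for c in compounds])

    def to_frame(self) -> pd.DataFrame:
        data = {"wavelength_nm": self.wavelengths_nm}
        data.update({k: v for k, v in self.absorptivities.items()})
        return pd.DataFrame(data)


@dataclass
class SpectraSeries:
    """Time-stamped 24-channel absorbance spectra."""

    time_min: np.ndarray
    absorbance: np.ndarray  # (n_times, n_channels)
    wavelengths_nm: np.ndarray
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.absorbance.shape != (len(self.time_min), len(self.wavelengths_nm)):
            raise ValueError("absorbance matrix shape must be (n_times, n_channels)")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        cols = {f"a_{int(round(wl))}": self.absorbance[:, j]
                for j, wl in enumerate(self.wavelengths_nm)}
        return pd.DataFrame({"time_min": self.time_min, **cols})


@dataclass
class ReferenceSeries:
    """Time-stamped reference analyzer measurements for one analyte."""

    time_min: np.ndarray
    values: np.ndarray
    analyte: str
    device: str
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time_min,
            "analyte": self.analyte,
            "value": self.values,
            "device": self.device,
        })


def _gaussian_bands(wl: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian absorption bands (center nm, width nm, amplitude)."""
    eps = np.zeros_like(wl)
    for center, width, amp in bands:
        eps += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return eps


# Band positions follow literature NIR combination-band assignments
# (glucose ~2100/2270 nm, BHB ~2150 nm, lactate ~2250 nm, ethanol
# ~2260/1690 nm); amplitudes are set so physiological swings move the
# spectrum by roughly ten times the default channel noise. Confounder bands
# deliberately overlap the glucose bands so an uncompensated interferent
# genuinely perturbs glucose prediction.
_DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "glucose": [(2100.0, 45.0, 5.0e-3), (2270.0, 55.0, 3.0e-3)],
    "bhb": [(2150.0, 45.0, 4.0e-3), (1760.0, 60.0, 2.0e-3)],
    "lactate": [(2250.0, 40.0, 4.5e-3), (1730.0, 50.0, 2.0e-3)],
    "ethanol": [(2260.0, 45.0, 4.0e-3), (1690.0, 40.0, 3.5e-3)],
    "paracetamol": [(2110.0, 50.0, 2.0e-2), (2320.0, 60.0, 1.0e-2)],
    "aspartame": [(2090.0, 45.0, 2.5e-2), (1740.0, 50.0, 1.0e-2)],
    "acetylsalicylic_acid": [(2130.0, 55.0, 1.5e-2), (2280.0, 50.0, 8.0e-3)],
    "ibuprofen": [(2120.0, 45.0, 2.0e-2), (1700.0, 60.0, 9.0e-3)],
    "sorbitol": [(2100.0, 50.0, 8.0e-3), (2240.0, 55.0, 4.0e-3)],
    "caffeine": [(2160.0, 45.0, 2.2e-2), (2340.0, 55.0, 1.2e-2)],
    "fructose": [(2110.0, 55.0, 6.0e-3), (2260.0, 50.0, 3.0e-3)],
    "vitamin_c": [(2080.0, 45.0, 1.8e-2), (2300.0, 55.0, 9.0e-3)],
}

ANALYTES = ("glucose", "bhb", "lactate", "ethanol")


def default_library() -> AbsorptivityLibrary:
    """Synthetic absorptivity library on the 24-channel sensor grid.

    The four analyte profiles are numerically linearly independent, so
    noiseless spectra determine the analyte concentrations uniquely.
    """
    wl = np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, N_CHANNELS)
    eps = {name: _gaussian_bands(wl, bands) for name, bands in _DEFAULT_BANDS.items()}
    return AbsorptivityLibrary(wavelengths_nm=wl, absorptivities=eps)


def default_baseline(library: AbsorptivityLibrary) -> np.ndarray:
    """Smooth per-channel baseline absorbance (water/tissue background)."""
    wl = library.wavelengths_nm
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.10 + 0.05 * u + 0.02 * np.sin(2 * np.pi * u)


def absorbance_spectrum(
    concentrations: Mapping[str, float],
    library: AbsorptivityLibrary,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Single Beer-Lambert mixture spectrum.

    ``A(lambda) = baseline(lambda) + pathlength * sum_c eps_c(lambda) * conc_c``
    with concentrations in mM. Exactly linear in every concentration.
    """
    if baseline is None:
        baseline = np.zeros(library.n_channels)
    baseline = np.asarray(baseline, float)
    spectrum = baseline.copy()
    for name, conc in concentrations.items():
        if name not in library.absorptivities:
            raise KeyError(f"compound {name!r} missing from absorptivity library")
        spectrum += library.pathlength_mm * conc * library.absorptivities[name]
    return spectrum


def _concentration_matrix(series: ConcentrationSeries,
                          library: AbsorptivityLibrary) -> tuple[list[str], np.ndarray]:
    """Compound names and (n_times, n_compounds) concentrations in mM."""
    names = ["glucose", "bhb", "lactate", "ethanol"]
    cols = [series.glucose_mgdl / MGDL_PER_MM, series.bhb_mM,
            series.lactate_mM, series.ethanol_mM]
    for compound, conc in series.confounders_mM.items():
        if compound not in library.absorptivities:
            raise KeyError(f"compound {compound!r} missing from absorptivity library")
        names.append(compound)
        cols.append(conc)
    return names, np.column_stack(cols)


def simulate_sensor_series(
    series: ConcentrationSeries,
    library: AbsorptivityLibrary | None = None,
    noise_sd: float = 1e-3,
    drift_amplitude: float = 1e-3,
    seed: int = 0,
    baseline: np.ndarray | None = None,
) -> SpectraSeries:
    """Noisy sensor spectra for every time point of a concentration series.

    Adds per-channel i.i.d. Gaussian noise of standard deviation ``noise_sd``
    and a slow sinusoidal baseline drift (one period per visit, random phase,
    fixed smooth spectral shape) of amplitude ``drift_amplitude``.
    """
    if noise_sd < 0 or drift_amplitude < 0:
        raise ValueError("noise_sd and drift_amplitude must be >= 0")
    if library is None:
        library = default_library()
    if baseline is None:
        baseline = default_baseline(library)
    names, conc = _concentration_matrix(series, library)
    eps = library.matrix(names)  # channels x compounds
    clean = baseline[None, :] + library.pathlength_mm * conc @ eps.T

    rng = np.random.default_rng(seed)
    t = series.time_min
    if drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wl = library.wavelengths_nm
        shape = 1.0 + 0.5 * np.sin(2 * np.pi * (wl - wl[0]) / (wl[-1] - wl[0]))
        drift = drift_amplitude * np.sin(2 * np.pi * t / max(t[-1], 1.0) + phase)
        clean = clean + drift[:, None] * shape[None, :]
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)

    return SpectraSeries(time_min=t.copy(), absorbance=clean,
                         wavelengths_nm=library.wavelengths_nm.copy(),
                         noise_sd=noise_sd, drift_amplitude=drift_amplitude,
                         seed=seed)


def to_transmittance(spectra: SpectraSeries) -> np.ndarray:
    """Transmittance export, T = 10**(-A)."""
    return 10.0 ** (-spectra.absorbance)


def _ketone_strip_cv(value_mM: np.ndarray) -> np.ndarray:
    """Strip CV interpolated between 10.1% at 0.1 mM and 3.0% at 8.0 mM."""
    return np.interp(value_mM, [0.1, 8.0], [0.101, 0.030])


#: Reference device registry: measured analyte, measuring range in the
#: analyte's working units, CV model, base draw interval (min), and whether
#: the cadence tightens to 2.5 min during hypoglycemia (blood draws do; the
#: breathalyzer runs on its own 10-minute schedule).
DEVICES: dict[str, dict] = {
    "ekf_glucose": {
        "analyte": "glucose",
        "range": (0.5 * MGDL_PER_MM, 50.0 * MGDL_PER_MM),  # 0.5-50 mmol/l in mg/dl
        "cv": lambda v: np.full_like(v, 0.015),
        "interval_min": 5.0,
        "hypo_interval": True,
    },
    "strip_glucose": {
        "analyte": "glucose",
        "range": (0.5 * MGDL_PER_MM, 50.0 * MGDL_PER_MM),
        "cv": lambda v: np.full_like(v, 0.015),
        "interval_min": 5.0,
        "hypo_interval": True,
    },
    "ekf_lactate": {
        "analyte": "lactate",
        "range": (0.5, 40.0),
        "cv": lambda v: np.full_like(v, 0.015),
        "interval_min": 5.0,
        "hypo_interval": True,
    },
    "strip_ketone": {
        "analyte": "bhb",
        "range": (0.1, 8.0),
        "cv": _ketone_strip_cv,
        "interval_min": 5.0,
        "hypo_interval": True,
    },
    "breathalyzer": {
        "analyte": "ethanol",
        "range": (0.0, 50.0),
        "cv": lambda v: np.full_like(v, 0.05),
        "interval_min": 10.0,
        "hypo_interval": False,
    },
}


def reference_sample_times(series: ConcentrationSeries,
                           interval_min: float = 5.0,
                           hypo_interval: bool = True) -> np.ndarray:
    """Blood-draw schedule: every ``interval_min``, 2.5 min while the
    ground-truth glucose at the previous draw is below 70 mg/dl."""
    end = series.time_min[-1]
    times = [0.0]
    while times[-1] < end:
        g = float(np.interp(times[-1], series.time_min, series.glucose_mgdl))
        dt = 2.5 if (hypo_interval and g < 70.0) else interval_min
        nxt = times[-1] + dt
        if nxt > end + 1e-9:
            break
        times.append(nxt)
    return np.asarray(times)


def simulate_reference(
    series: ConcentrationSeries,
    device: str,
    seed: int = 0,
    cv_scale: float = 1.0,
) -> ReferenceSeries:
    """Noisy reference measurements of one analyte on the device's schedule.

    Multiplicative Gaussian noise at the device CV (scaled by ``cv_scale``;
    0 disables noise), clipped to the device measuring range.
    """
    if device not in DEVICES:
        raise ValueError(f"unknown device {device!r}; expected one of {sorted(DEVICES)}")
    spec = DEVICES[device]
    times = reference_sample_times(series, spec["interval_min"], spec["hypo_interval"])
    truth = np.interp(times, series.time_min, series.analyte(spec["analyte"]))
    rng = np.random.default_rng(seed)
    cv = spec["cv"](truth) * cv_scale
    values = truth * (1.0 + rng.normal(0.0, 1.0, size=truth.shape) * cv)
    lo, hi = spec["range"]
    values = np.clip(values, lo, hi)
    return ReferenceSeries(time_min=times, values=values,
                           analyte=spec["analyte"], device=device, seed=seed)
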