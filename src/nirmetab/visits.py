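"""Synthetic metabolic-visit generator.

Produces per-minute ground-truth concentration time courses for one 8-hour
measurement visit: an induced hyper-/hypoglycemic glucose excursion (type 1
diabetes arm), single-bolus challenges raising beta-hydroxybutyrate, lactate
or ethanol, and one-compartment pharmacokinetic profiles for eight named
interferent compounds.

The profiles are protocol-shaped, not mechanistic: they are built to honor
the clinical protocol's targets and rate caps (glucose confined to
40-400 mg/dl, downward rate at most 100 mg/dl/h, absolute 5-minute rate at
most 4 mg/dl/min, ketone peak >= 3.5 mM, lactate plateau at 13 mM, ethanol
around 20 mM), with a smooth low-amplitude jitter as the only stochastic
element of the glucose trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = [
    "CONFOUNDER_COMPOUNDS",
    "CHALLENGE_KINDS",
    "ChallengeParams",
    "Challenge",
    "VisitProtocol",
    "ConcentrationSeries",
    "ProtocolInfeasibleError",
    "glucose_excursion_profile",
    "challenge_profile",
    "confounder_profile",
    "generate_visit",
    "default_t1d_protocol",
    "default_healthy_protocol",
]

MGDL_PER_MM = 18.016  # glucose: mg/dl per mmol/l

#: The eight interferent compounds of the study schedule, with the
#: administered dose (mg) and the dose-to-peak-concentration scale (mM per
#: mg). The study reports doses only, never the interstitial concentrations
#: reached, so the scale constants are invented, physiologically plausible
#: values and are config entries, not measurements.
CONFOUNDER_COMPOUNDS: dict[str, dict[str, float]] = {
    "paracetamol": {"dose_mg": 1000.0, "peak_mM_per_mg": 1.3e-4},
    "aspartame": {"dose_mg": 2000.0, "peak_mM_per_mg": 5.0e-6},
    "acetylsalicylic_acid": {"dose_mg": 1000.0, "peak_mM_per_mg": 3.0e-4},
    "ibuprofen": {"dose_mg": 1000.0, "peak_mM_per_mg": 1.0e-4},
    "sorbitol": {"dose_mg": 20000.0, "peak_mM_per_mg": 5.0e-5},
    "caffeine": {"dose_mg": 260.0, "peak_mM_per_mg": 7.5e-5},
    "fructose": {"dose_mg": 50000.0, "peak_mM_per_mg": 3.0e-5},
    "vitamin_c": {"dose_mg": 2000.0, "peak_mM_per_mg": 1.25e-4},
}

CHALLENGE_KINDS = (
    "glucose_excursion",
    "ketone_drink",
    "lactate_exercise",
    "ethanol_intake",
    "confounder",
)

#: Default single-bolus kinetics per challenge kind (minutes / analyte units).
DEFAULT_KINETICS: dict[str, dict[str, float]] = {
    # ketone target slightly above the 3.5 mM floor: the protocol asks for
    # "at least" that level
    "ketone_drink": {"peak": 3.6, "time_to_peak": 30.0, "half_life": 60.0},
    "lactate_exercise": {
        "peak": 13.0,
        "time_to_peak": 30.0,
        "half_life": 20.0,
        "plateau_min": 60.0,
    },
    "ethanol_intake": {"peak": 20.0, "time_to_peak": 45.0, "half_life": 90.0},
    "confounder": {"time_to_peak": 30.0, "half_life": 120.0},
}

BASAL = {"glucose_t1d": 100.0, "glucose_healthy": 90.0, "bhb": 0.1, "lactate": 1.0, "ethanol": 0.0}

ANALYTE_OF_KIND = {
    "ketone_drink": "bhb",
    "lactate_exercise": "lactate",
    "ethanol_intake": "ethanol",
}


class ProtocolInfeasibleError(ValueError):
    """The visit is too short to fit the requested excursions at the rate caps."""


@dataclass(frozen=True)
class ChallengeParams:
    """Kinetic parameters of one metabolic challenge or interferent bolus.

    peak
        Target peak value in the analyte's units (mg/dl for glucose, mM
        otherwise). Must be >= 0; zero yields an all-zero profile.
    time_to_peak
        Minutes from administration to the peak.
    half_life
        First-order elimination half-life in minutes.
    plateau_min
        Exercise plateau duration (lactate only).
    dose_mg
        Administered dose, confounders only.
    """

    peak: float
    time_to_peak: float = 30.0
    half_life: float = 60.0
    plateau_min: float = 0.0
    dose_mg: float | None = None

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ValueError(f"peak must be >= 0, got {self.peak}")
        if self.time_to_peak <= 0 or self.half_life <= 0:
            raise ValueError("time_to_peak and half_life must be > 0")


@dataclass(frozen=True)
class Challenge:
    kind: str
    start_min: float = 0.0
    params: ChallengeParams | None = None
    compound: str | None = None  # confounders only

    def __post_init__(self) -> None:
        if self.kind not in CHALLENGE_KINDS:
            raise ValueError(
                f"unknown challenge kind {self.kind!r}; expected one of {CHALLENGE_KINDS}"
            )
        if self.kind == "confounder":
            if self.compound not in CONFOUNDER_COMPOUNDS:
                raise ValueError(
                    f"unknown confounder compound {self.compound!r}; "
                    f"expected one of {sorted(CONFOUNDER_COMPOUNDS)}"
                )


@dataclass(frozen=True)
class VisitProtocol:
    """One measurement visit: the arm, the challenge schedule, the time grid."""

    arm: str
    challenges: tuple[Challenge, ...] = ()
    duration_min: float = 480.0
    step_min: float = 1.0

    def __post_init__(self) -> None:
        if self.arm not in ("t1d", "healthy"):
            raise ValueError(f"arm must be 't1d' or 'healthy', got {self.arm!r}")
        starts = [c.start_min for c in self.challenges]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("challenge start times must be strictly increasing")
        if any(s < 0 or s >= self.duration_min for s in starts):
            raise ValueError("challenge start times must lie within the visit")
        if self.arm == "t1d" and not any(
            c.kind == "glucose_excursion" for c in self.challenges
        ):
            raise ValueError("the t1d arm always contains a glucose_excursion challenge")

    @property
    def confounders(self) -> tuple[Challenge, ...]:
        return tuple(c for c in self.challenges if c.kind == "confounder")


@dataclass
class ConcentrationSeries:
    """Per-minute ground-truth analyte and confounder concentrations."""

    time_min: np.ndarray
    glucose_mgdl: np.ndarray
    bhb_mM: np.ndarray
    lactate_mM: np.ndarray
    ethanol_mM: np.ndarray
    confounders_mM: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def analyte(self, name: str) -> np.ndarray:
        key = {"glucose": "glucose_mgdl", "bhb": "bhb_mM",
               "lactate": "lactate_mM", "ethanol": "ethanol_mM"}[name]
        return getattr(self, key)

    def confounder(self, compound: str) -> np.ndarray:
        return self.confounders_mM.get(compound, np.zeros_like(self.time_min))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_min": self.time_min,
            "glucose_mgdl": self.glucose_mgdl,
            "bhb_mM": self.bhb_mM,
            "lactate_mM": self.lactate_mM,
            "ethanol_mM": self.ethanol_mM,
        }
        for name, series in self.confounders_mM.items():
            data[f"{name}_mM"] = series
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# profile primitives
# ---------------------------------------------------------------------------

def _trapezoid_rate_ramp(t: np.ndarray, t0: float, delta: float,
                         rate: float, ramp_min: float = 10.0) -> np.ndarray:
    """Displacement of a smooth move of size ``delta`` starting at ``t0``.

    The velocity profile is trapezoidal: it ramps linearly from 0 to
    ``sign(delta) * rate`` over ``ramp_min`` minutes, holds, and ramps back,
    so the instantaneous rate never exceeds ``rate`` and the move completes
    in ``|delta| / rate + ramp_min`` minutes. Returns the cumulative
    displacement at each time in ``t`` (0 before t0, ``delta`` after the end).
    """
    total = abs(delta) / rate + ramp_min
    s = np.clip(t - t0, 0.0, total)
    r = ramp_min
    v = rate
    # piecewise integral of the trapezoidal velocity
    disp = np.where(
        s <= r,
        0.5 * v * s**2 / r,
        np.where(
            s <= total - r,
            0.5 * v * r + v * (s - r),
            abs(delta) - 0.5 * v * (total - s) ** 2 / r,
        ),
    )
    return np.sign(delta) * disp


def _required_move_time(delta: float, rate: float, ramp_min: float = 10.0) -> float:
    return abs(delta) / rate + ramp_min


def _smooth_jitter(t: np.ndarray, sd: float, rng: np.random.Generator,
                   knot_min: float = 25.0) -> np.ndarray:
    """Slow, differentiable noise: a cubic spline through Gaussian knots."""
    if sd == 0:
        return np.zeros_like(t)
    n_knots = max(int(np.ceil(t[-1] / knot_min)) + 3, 4)
    knots = np.linspace(t[0] - knot_min, t[-1] + knot_min, n_knots)
    values = rng.normal(0.0, sd, size=n_knots)
    return CubicSpline(knots, values)(t)


def glucose_excursion_profile(
    duration: float = 480.0,
    step: float = 1.0,
    seed: int = 0,
    *,
    start_level: float = 100.0,
    peak: float = 340.0,
    nadir: float = 45.0,
    recovery_level: float = 100.0,
    rise_rate: float = 2.8,
    fall_rate: float = 1.2,
    recovery_rate: float = 2.0,
    jitter_sd: float = 0.6,
) -> np.ndarray:
    """Sequential induced hyper- then hypoglycemia glucose trace (mg/dl).

    The trace starts in euglycemia, rises to ``peak`` (default 340 mg/dl,
    inside the protocol ceiling of 400), descends to ``nadir`` (default
    45 mg/dl, inside the 40 mg/dl floor) at a plateau rate of ``fall_rate``
    mg/dl/min (default 1.2 = 72 mg/dl/h, under the 100 mg/dl/h cap with
    margin for jitter), and recovers toward euglycemia. All shape parameters
    are deterministic; the seed drives only the smooth jitter, so setting
    ``jitter_sd=0`` yields a seed-independent trace.

    Raises
    ------
    ProtocolInfeasibleError
        If both excursions cannot be completed within ``duration`` at the
        configured rate caps.
    """
    if duration < 120:
        raise ValueError(f"duration must be >= 120 min, got {duration}")
    n_steps = duration / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must divide duration")

    hold_basal, hold_peak, hold_nadir = 35.0, 15.0, 5.0
    t_rise = _required_move_time(peak - start_level, rise_rate)
    t_fall = _required_move_time(peak - nadir, fall_rate)
    t_rec = _required_move_time(recovery_level - nadir, recovery_rate)
    needed = hold_basal + t_rise + hold_peak + t_fall + hold_nadir + t_rec
    if needed > duration:
        raise ProtocolInfeasibleError(
            f"visit of {duration} min cannot fit hyper- and hypoglycemia at the "
            f"rate caps (needs {needed:.0f} min)"
        )

    t = np.arange(0.0, duration + step / 2, step)
    g = np.full_like(t, start_level)
    t1 = hold_basal
    t2 = t1 + t_rise + hold_peak
    t3 = t2 + t_fall + hold_nadir
    g = g + _trapezoid_rate_ramp(t, t1, peak - start_level, rise_rate)
    g = g + _trapezoid_rate_ramp(t, t2, -(peak - nadir), fall_rate)
    g = g + _trapezoid_rate_ramp(t, t3, recovery_level - nadir, recovery_rate)

    rng = np.random.default_rng(seed)
    g = g + _smooth_jitter(t, jitter_sd, rng)
    return np.clip(g, 40.0, 400.0)


def _solve_absorption_rate(ke: float, time_to_peak: float) -> float:
    """Absorption constant ka of a one-compartment bolus with known tmax.

    tmax = ln(ka/ke) / (ka - ke); solved numerically for ka > ke.
    """
    def f(ka: float) -> float:
        return np.log(ka / ke) / (ka - ke) - time_to_peak

    lo, hi = ke * (1 + 1e-9), ke * 1e6
    # tmax decreases monotonically in ka; bracket is guaranteed for tmax < 1/ke
    if f(hi) > 0:
        raise ValueError(
            f"time_to_peak {time_to_peak} min unreachable with half-life "
            f"{np.log(2) / ke:.1f} min"
        )
    return brentq(f, lo, hi)


def one_compartment_bolus(t: np.ndarray, start: float, peak: float,
                          time_to_peak: float, half_life: float) -> np.ndarray:
    """Closed-form first-order absorption/elimination profile, scaled to peak.

    c(t) = peak * (exp(-ke s) - exp(-ka s)) / (exp(-ke tmax) - exp(-ka tmax)),
    with s = t - start, zero before the start.
    """
    if peak == 0:
        return np.zeros_like(t)
    ke = np.log(2) / half_life
    ka = _solve_absorption_rate(ke, time_to_peak)
    s = t - start
    shape = np.where(s > 0, np.exp(-ke * np.maximum(s, 0)) - np.exp(-ka * np.maximum(s, 0)), 0.0)
    norm = np.exp(-ke * time_to_peak) - np.exp(-ka * time_to_peak)
    return peak * shape / norm


def _plateau_profile(t: np.ndarray, start: float, peak: float, rise_min: float,
                     plateau_min: float, half_life: float) -> np.ndarray:
    """Exercise-type profile: smooth rise, plateau at peak, exponential decay."""
    if peak == 0:
        return np.zeros_like(t)
    s = t - start
    u = np.clip(s / rise_min, 0.0, 1.0)
    rise = u * u * (3 - 2 * u)  # C1 smoothstep
    end_plateau = rise_min + plateau_min
    ke = np.log(2) / half_life
    decay = np.exp(-ke * np.maximum(s - end_plateau, 0.0))
    return np.where(s <= 0, 0.0, peak * rise * decay)


def challenge_profile(
    kind: str,
    params: ChallengeParams,
    duration: float,
    step: float,
    seed: int = 0,
    *,
    start: float = 0.0,
) -> np.ndarray:
    """Concentration increment (above basal) of a single metabolic challenge.

    Drinks (ketone ester, ethanol) follow one-compartment bolus kinetics
    peaking at ``params.peak`` exactly ``params.time_to_peak`` minutes after
    ``start``; ``lactate_exercise`` holds a plateau at the peak for
    ``params.plateau_min`` minutes before first-order decay. The profiles are
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if kind not in ("ketone_drink", "lactate_exercise", "ethanol_intake", "confounder"):
        raise ValueError(f"unknown challenge kind {kind!r}")
    t = np.arange(0.0, duration + step / 2, step)
    if kind == "lactate_exercise":
        return _plateau_profile(t, start, params.peak, params.time_to_peak,
                                params.plateau_min, params.half_life)
    return one_compartment_bolus(t, start, params.peak, params.time_to_peak,
                                 params.half_life)


def confounder_profile(
    compound: str,
    dose_mg: float,
    duration: float,
    step: float,
    *,
    start: float = 0.0,
    time_to_peak: float | None = None,
    half_life: float | None = None,
) -> np.ndarray:
    """One-compartment concentration profile (mM) of an interferent bolus.

    The peak concentration is ``dose_mg`` times the compound's configured
    dose-to-peak scale; the profile is zero before administration. Doubling
    the dose doubles the whole profile (linear pharmacokinetics).
    """
    if compound not in CONFOUNDER_COMPOUNDS:
        raise ValueError(
            f"unknown confounder compound {compound!r}; "
            f"expected one of {sorted(CONFOUNDER_COMPOUNDS)}"
        )
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    kin = DEFAULT_KINETICS["confounder"]
    tp = kin["time_to_peak"] if time_to_peak is None else time_to_peak
    hl = kin["half_life"] if half_life is None else half_life
    peak = dose_mg * CONFOUNDER_COMPOUNDS[compound]["peak_mM_per_mg"]
    t = np.arange(0.0, duration + step / 2, step)
    return one_compartment_bolus(t, start, peak, tp, hl)


def _default_params(kind: str) -> ChallengeParams:
    kin = dict(DEFAULT_KINETICS[kind])
    return ChallengeParams(
        peak=kin.get("peak", 0.0),
        time_to_peak=kin["time_to_peak"],
        half_life=kin["half_life"],
        plateau_min=kin.get("plateau_min", 0.0),
    )


def generate_visit(protocol: VisitProtocol, seed: int = 0) -> ConcentrationSeries:
    """Ground-truth multi-analyte concentration series for one visit.

    Superposes the glucose excursion (T1D arm) and every scheduled challenge
    and confounder profile on basal levels. Each component draws from its own
    child of the master seed, so adding one challenge never perturbs the
    randomness of the others; the output is deterministic given
    ``(protocol, seed)``.
    """
    duration, step = protocol.duration_min, protocol.step_min
    t = np.arange(0.0, duration + step / 2, step)
    # one spawned stream per potential component, in schedule order
    children = np.random.SeedSequence(seed).spawn(len(protocol.challenges) + 1)
    glucose_seed = children[0].generate_state(1)[0] % 2**31

    if protocol.arm == "t1d":
        exc = [c for c in protocol.challenges if c.kind == "glucose_excursion"][0]
        kwargs = {} if exc.params is None else {"peak": exc.params.peak}
        glucose = glucose_excursion_profile(duration, step, glucose_seed, **kwargs)
    else:
        rng = np.random.default_rng(glucose_seed)
        glucose = BASAL["glucose_healthy"] + _smooth_jitter(t, 3.0, rng)

    bhb = np.full_like(t, BASAL["bhb"])
    lactate = np.full_like(t, BASAL["lactate"])
    ethanol = np.full_like(t, BASAL["ethanol"])
    confounders: dict[str, np.ndarray] = {}

    for i, ch in enumerate(protocol.challenges):
        child_seed = children[i + 1].generate_state(1)[0] % 2**31
        if ch.kind == "glucose_excursion":
            continue
        if ch.kind == "confounder":
            params = ch.params
            dose = CONFOUNDER_COMPOUNDS[ch.compound]["dose_mg"]
            if params is not None and params.dose_mg is not None:
                dose = params.dose_mg
            profile = confounder_profile(ch.compound, dose, duration, step,
                                         start=ch.start_min)
            confounders[ch.compound] = confounders.get(ch.compound, 0.0) + profile
            continue
        params = ch.params or _default_params(ch.kind)
        name = ANALYTE_OF_KIND[ch.kind]
        # challenge peaks are absolute analyte levels; superpose the
        # increment above basal so the visit peaks at the stated target
        basal = BASAL[name]
        eff = replace(params, peak=max(params.peak - basal, 0.0))
        profile = challenge_profile(ch.kind, eff, duration, step, child_seed,
                                    start=ch.start_min)
        if name == "bhb":
            bhb = bhb + profile
        elif name == "lactate":
            lactate = lactate + profile
        else:
            ethanol = ethanol + profile

    return ConcentrationSeries(
        time_min=t,
        glucose_mgdl=np.maximum(glucose, 0.0),
        bhb_mM=np.maximum(bhb, 0.0),
        lactate_mM=np.maximum(lactate, 0.0),
        ethanol_mM=np.maximum(ethanol, 0.0),
        confounders_mM=confounders,
        seed=seed,
    )


def resample_series(series: ConcentrationSeries, times: np.ndarray) -> ConcentrationSeries:
    """Linearly interpolate every channel of a concentration series onto a
    new strictly increasing time grid."""
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("resampling times must be strictly increasing")

    def interp(v: np.ndarray) -> np.ndarray:
        return np.interp(times, series.time_min, v)

    return ConcentrationSeries(
        time_min=times,
        glucose_mgdl=interp(series.glucose_mgdl),
        bhb_mM=interp(series.bhb_mM),
        lactate_mM=interp(series.lactate_mM),
        ethanol_mM=interp(series.ethanol_mM),
        confounders_mM={k: interp(v) for k, v in series.confounders_mM.items()},
        seed=series.seed,
    )


def default_t1d_protocol(
    confounders: Sequence[tuple[str, float]] = (),
    duration_min: float = 480.0,
) -> VisitProtocol:
    """Default T1D measurement visit: full four-analyte challenge panel.

    Sequential hyper-/hypoglycemia plus a ketone ester drink, an exercise
    lactate bout and moderate ethanol intake, so every calibrated analyte
    varies within the visit. ``confounders`` is a sequence of
    ``(compound, start_min)`` entries inserted into the schedule.
    """
    challenges = [
        Challenge("glucose_excursion", start_min=0.0),
        Challenge("ketone_drink", start_min=30.0),
        Challenge("ethanol_intake", start_min=70.0),
        Challenge("lactate_exercise", start_min=150.0),
    ]
    for compound, start in confounders:
        challenges.append(Challenge("confounder", start_min=start, compound=compound))
    challenges.sort(key=lambda c: c.start_min)
    return VisitProtocol("t1d", tuple(challenges), duration_min=duration_min)


def default_healthy_protocol(
    pair: str = "ketones+lactate",
    duration_min: float = 480.0,
) -> VisitProtocol:
    """Healthy-volunteer visit: one of the paired challenge designs."""
    designs = {
        "ketones+lactate": [("ketone_drink", 60.0), ("lactate_exercise", 150.0)],
        "ethanol+ketones": [("ethanol_intake", 60.0), ("ketone_drink", 180.0)],
        "lactate+ethanol": [("lactate_exercise", 60.0), ("ethanol_intake", 200.0)],
    }
    if pair not in designs:
        raise ValueError(f"unknown paired design {pair!r}; expected one of {sorted(designs)}")
    challenges = tuple(Challenge(kind, start_min=s) for kind, s in designs[pair])
    return VisitProtocol("healthy", challenges, duration_min=duration_min)
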