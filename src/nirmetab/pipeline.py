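"""End-to-end study pipeline: simulate (or load) one visit, pair spectra to
references, run per-analyte PLS with contiguous-blocks cross-validation,
and summarize accuracy and interferent equivalence in a study-style report.

All randomness flows from one master seed: the visit generator, the sensor
noise and every reference device draw from independently spawned child
streams, so the whole run is reproducible from ``(config, seed)`` and the
report carries a config hash as provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .crossval import (CVResult, EquivalenceResult, confounder_equivalence_test,
                       cross_validate, pair_measurements)
from .forward import (DEVICES, default_library, reference_sample_times,
                      simulate_reference, simulate_sensor_series)
from .io import (read_reference, read_spectra, write_concentrations,
                 write_reference, write_spectra)
from .metrics import DEFAULT_STRATUM_EDGES, AccuracyReport, accuracy_report
from .visits import (DEFAULT_KINETICS, VisitProtocol, Challenge, ChallengeParams,
                     default_t1d_protocol, generate_visit, resample_series)

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "protocol_from_dict"]

#: Analyte -> reference device used by the pipeline.
ANALYTE_DEVICE = {
    "glucose": "ekf_glucose",
    "bhb": "strip_ketone",
    "lactate": "ekf_lactate",
    "ethanol": "breathalyzer",
}


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one input mode is active."""

    mode: str = "simulate"                       # "simulate" | "from_files"
    protocol: VisitProtocol | None = None        # simulate mode
    input_dir: str | None = None                 # from_files mode
    seed: int = 0
    noise_sd: float = 1e-3
    drift_amplitude: float = 1e-3
    reference_cv_scale: float = 1.0
    analytes: tuple[str, ...] = ("glucose", "bhb", "lactate", "ethanol")
    k: int | str = "auto"
    k_max: int = 10
    pairing_tolerance_s: float = 60.0
    stratum_edges: tuple[float, ...] = DEFAULT_STRATUM_EDGES
    equivalence_threshold: float = 10.5
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "from_files"):
            raise ValueError(f"mode must be 'simulate' or 'from_files', got {self.mode!r}")
        if self.mode == "from_files" and not self.input_dir:
            raise ValueError("from_files mode requires input_dir")
        if self.equivalence_threshold <= 0:
            raise ValueError("equivalence threshold must be > 0")
        if self.mode == "simulate" and self.protocol is None:
            self.protocol = default_t1d_protocol()

    def to_canonical_dict(self) -> dict:
        d: dict[str, Any] = {
            "mode": self.mode, "seed": self.seed, "noise_sd": self.noise_sd,
            "drift_amplitude": self.drift_amplitude,
            "reference_cv_scale": self.reference_cv_scale,
            "analytes": list(self.analytes), "k": self.k, "k_max": self.k_max,
            "pairing_tolerance_s": self.pairing_tolerance_s,
            "stratum_edges": [e if np.isfinite(e) else "inf" for e in self.stratum_edges],
            "equivalence_threshold": self.equivalence_threshold,
            "input_dir": self.input_dir,
        }
        if self.protocol is not None:
            d["protocol"] = _protocol_to_dict(self.protocol)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "protocol" in raw and isinstance(raw["protocol"], dict):
            raw["protocol"] = protocol_from_dict(raw["protocol"])
        if "analytes" in raw:
            raw["analytes"] = tuple(raw["analytes"])
        if "stratum_edges" in raw:
            raw["stratum_edges"] = tuple(
                float("inf") if e == "inf" else float(e) for e in raw["stratum_edges"]
            )
        return cls(**raw)


def _protocol_to_dict(protocol: VisitProtocol) -> dict:
    out = {"arm": protocol.arm, "duration_min": protocol.duration_min,
           "step_min": protocol.step_min, "challenges": []}
    for c in protocol.challenges:
        entry: dict[str, Any] = {"kind": c.kind, "start_min": c.start_min}
        if c.compound:
            entry["compound"] = c.compound
        if c.params is not None:
            entry["params"] = {k: v for k, v in asdict(c.params).items() if v is not None}
        out["challenges"].append(entry)
    return out


def protocol_from_dict(raw: dict) -> VisitProtocol:
    """Build a :class:`VisitProtocol` from a YAML/JSON-style mapping."""
    challenges = []
    for entry in raw.get("challenges", []):
        params = None
        if "params" in entry:
            params = ChallengeParams(**entry["params"])
        challenges.append(Challenge(kind=entry["kind"],
                                    start_min=float(entry.get("start_min", 0.0)),
                                    params=params,
                                    compound=entry.get("compound")))
    return VisitProtocol(arm=raw["arm"], challenges=tuple(challenges),
                         duration_min=float(raw.get("duration_min", 480.0)),
                         step_min=float(raw.get("step_min", 1.0)))


@dataclass
class StudyReport:
    """Per-analyte accuracy, CV summaries and interferent equivalence."""

    accuracy: dict[str, AccuracyReport]
    cv: dict[str, CVResult]
    equivalence: dict[str, EquivalenceResult]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "accuracy": {a: r.to_dict() for a, r in self.accuracy.items()},
            "cv": {
                a: {
                    "pooled_rmsecv": r.pooled_rmsecv,
                    "per_block_rmsecv": r.per_block_rmsecv.tolist(),
                    "k_per_fold": list(r.k_per_fold),
                    "block_sizes": list(r.partition.sizes),
                }
                for a, r in self.cv.items()
            },
            "equivalence": {c: e.to_dict() for c, e in self.equivalence.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _exposure_windows(protocol: VisitProtocol) -> dict[str, tuple[float, float]]:
    """Interferent exposure window per compound: administration to
    administration + 2 elimination half-lives."""
    windows = {}
    for c in protocol.confounders:
        hl = DEFAULT_KINETICS["confounder"]["half_life"]
        if c.params is not None:
            hl = c.params.half_life
        windows[c.compound] = (c.start_min, c.start_min + 2 * hl)
    return windows


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(master).spawn(n)]


def run_pipeline(config: RunConfig) -> StudyReport:
    """Run the full study pipeline for one visit.

    simulate (or load) -> pair -> contiguous-blocks PLS cross-validation per
    analyte -> accuracy metrics -> interferent equivalence tests (glucose).
    Deterministic given ``(config, seed)``; intermediates are written to
    ``config.output_dir`` when set.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    library = default_library()
    if config.mode == "simulate":
        seeds = _child_seeds(config.seed, 2 + len(ANALYTE_DEVICE))
        series = generate_visit(config.protocol, seeds[0])
        # emit spectra on the visit grid plus the exact blood-draw times so
        # each reference sample has a simultaneous spectrum to pair with
        draw_times = np.concatenate([
            reference_sample_times(series, DEVICES[d]["interval_min"],
                                   DEVICES[d]["hypo_interval"])
            for d in set(ANALYTE_DEVICE.values())
        ])
        grid = np.union1d(series.time_min, np.round(draw_times, 9))
        sensor_series = resample_series(series, grid)
        spectra = simulate_sensor_series(sensor_series, library,
                                         noise_sd=config.noise_sd,
                                         drift_amplitude=config.drift_amplitude,
                                         seed=seeds[1])
        references = {
            analyte: simulate_reference(series, device, seed=seeds[2 + i],
                                        cv_scale=config.reference_cv_scale)
            for i, (analyte, device) in enumerate(ANALYTE_DEVICE.items())
        }
        windows = _exposure_windows(config.protocol)
        if outdir:
            write_concentrations(series, outdir / "concentrations.csv")
            write_spectra(spectra, outdir / "spectra.csv")
            for analyte, ref in references.items():
                write_reference(ref, outdir / f"reference_{analyte}.csv")
            (outdir / "protocol.yaml").write_text(
                yaml.safe_dump(_protocol_to_dict(config.protocol)))
    else:
        indir = Path(config.input_dir)
        spectra = read_spectra(indir / "spectra.csv")
        references = {}
        for analyte in config.analytes:
            p = indir / f"reference_{analyte}.csv"
            if p.exists():
                references[analyte] = read_reference(p)
        proto_path = indir / "protocol.yaml"
        windows = {}
        if proto_path.exists():
            windows = _exposure_windows(
                protocol_from_dict(yaml.safe_load(proto_path.read_text())))

    window_list = list(windows.values())
    accuracy: dict[str, AccuracyReport] = {}
    cv_results: dict[str, CVResult] = {}
    equivalence: dict[str, EquivalenceResult] = {}

    for analyte in config.analytes:
        if analyte not in references:
            raise KeyError(f"stage pairing: no reference series for analyte {analyte!r}")
        try:
            paired = pair_measurements(spectra, references[analyte],
                                       tolerance_s=config.pairing_tolerance_s,
                                       exposure_windows=window_list)
        except Exception as err:
            raise RuntimeError(f"stage pairing failed for {analyte}: {err}") from err
        try:
            cv = cross_validate(paired, spectra.absorbance, config.k,
                                k_max=config.k_max)
        except Exception as err:
            raise RuntimeError(f"stage cross-validation failed for {analyte}: {err}") from err
        cv_results[analyte] = cv
        accuracy[analyte] = accuracy_report(cv.time_min, cv.reference, cv.predicted,
                                            analyte=analyte,
                                            stratum_edges=config.stratum_edges)
        if outdir:
            cv.to_frame().to_csv(outdir / f"cv_{analyte}.csv", index=False)

    if "glucose" in cv_results and windows:
        cv = cv_results["glucose"]
        abs_err = np.abs(cv.predicted - cv.reference)
        for compound, (lo, hi) in windows.items():
            in_win = (cv.time_min >= lo) & (cv.time_min <= hi)
            if in_win.sum() >= 2 and (~in_win).sum() >= 2:
                equivalence[compound] = confounder_equivalence_test(
                    abs_err[in_win], abs_err[~in_win],
                    threshold=config.equivalence_threshold)

    report = StudyReport(
        accuracy=accuracy, cv=cv_results, equivalence=equivalence,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
    )
    if outdir:
        report.to_json(outdir / "report.json")
    return report
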