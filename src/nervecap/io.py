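"""File formats, scenario configuration, and run manifests.

All formats are plain text: two-column delimited tables with a mandatory
header line for waveforms, sensitivity profiles and recruitment curves;
YAML for nerve/scenario configuration; JSON for run manifests. Every
pipeline is deterministic under (config, seed), which the manifest's
checksums make verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .fiber import APWaveform
from .recruitment import RecruitmentCurve
from .sensitivity import SensitivityProfile
from .synth import NerveSpec

__all__ = [
    "read_waveform",
    "write_waveform",
    "read_profile",
    "write_profile",
    "read_recruitment",
    "write_recruitment",
    "read_nerve_spec",
    "write_nerve_spec",
    "RunManifest",
    "run_scenario",
]

log = logging.getLogger(__name__)

_VERSION = "0.1.0"


def _read_two_column(path) -> tuple:
    """Parse a header-bearing 2-column delimited file; returns (header, a, b)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0]
    try:
        float(header.replace(",", " ").split()[0])
    except (ValueError, IndexError):
        pass
    else:
        raise ValueError(f"{path}:1: header line required")
    a, b = [], []
    for ln, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected two columns")
        try:
            a.append(float(parts[0]))
            b.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value") from exc
    return header, np.asarray(a), np.asarray(b)


def read_waveform(path) -> APWaveform:
    """Load an AP waveform (time_s, voltage_V); the peak is re-centered at t=0."""
    _, t, v = _read_two_column(path)
    diffs = np.diff(t)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}:{int(bad[0]) + 3}: time column must be strictly increasing")
    ap = APWaveform(t, v)
    t_peak = t[int(np.argmax(v))]
    if t_peak != 0.0:
        log.info("read_waveform: re-centering AP peak from t=%.3g to 0", t_peak)
        ap = ap.recentered()
    return ap


def write_waveform(path, ap: APWaveform) -> None:
    data = np.column_stack([ap.time, ap.values])
    np.savetxt(path, data, header="time_s\tvoltage_V", comments="", delimiter="\t", fmt="%.12g")


def read_profile(path) -> SensitivityProfile:
    """Load a sensitivity profile (arclength_m, phi_V_per_A)."""
    _, l, phi = _read_two_column(path)
    return SensitivityProfile(l, phi, label=str(path))


def write_profile(path, profile: SensitivityProfile) -> None:
    data = np.column_stack([profile.arclength, profile.values])
    np.savetxt(path, data, header="arclength_m\tphi_V_per_A", comments="", delimiter="\t", fmt="%.12g")


def read_recruitment(path) -> RecruitmentCurve:
    """Load a recruitment curve (current_A, fraction); d0 is read from the header."""
    header, i, f = _read_two_column(path)
    if "d0_m=" not in header:
        raise ValueError(f"{path}:1: header must carry d0_m=<meters>")
    d0 = float(header.split("d0_m=")[1].split()[0])
    return RecruitmentCurve(i, f, d0)


def write_recruitment(path, curve: RecruitmentCurve) -> None:
    data = np.column_stack([curve.current, curve.fraction])
    np.savetxt(
        path,
        data,
        header=f"current_A\tfraction\td0_m={curve.d0:.12g}",
        comments="",
        delimiter="\t",
        fmt="%.12g",
    )


def read_nerve_spec(path) -> NerveSpec:
    with open(path) as fh:
        return NerveSpec.from_dict(yaml.safe_load(fh))


def write_nerve_spec(path, spec: NerveSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one run: config hash, seed, output checksums."""

    config_hash: str
    seed: int
    version: str
    checksums: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_outputs(cls, config: dict, seed: int, files) -> "RunManifest":
        blob = yaml.safe_dump(config, sort_keys=True).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            version=_VERSION,
            checksums={Path(f).name: _sha256(f) for f in files},
        )


_SCENARIO_KEYS = {
    "mode",
    "seed",
    "nerve",
    "current",
    "currents",
    "recording_pairs",
    "dt",
    "t_max",
    "invert",
}
_INVERT_KEYS = {"current", "init", "bounds", "max_evals", "reference"}


def _validate(config: dict) -> None:
    unknown = set(config) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "mode" not in config or config["mode"] not in {"ecap", "sweep", "invert"}:
        raise ValueError("scenario requires mode: one of ecap, sweep, invert")
    if "seed" not in config:
        raise ValueError("scenario requires an explicit seed")
    if config["mode"] == "invert":
        inv = config.get("invert", {})
        bad = set(inv) - _INVERT_KEYS
        if bad:
            raise ValueError(f"unknown invert keys: {sorted(bad)}")


def _write_trace(path, time, values) -> None:
    np.savetxt(
        path,
        np.column_stack([time, values]),
        header="time_s\tvolts",
        comments="",
        delimiter="\t",
        fmt="%.12g",
    )


def run_scenario(config_path, out_dir) -> Path:
    """Execute a schema-checked scenario config; returns the run directory.

    Modes: ``ecap`` (one eCAP per recording pair; default pair from the
    nerve spec), ``sweep`` (amplitude sweep table), ``invert`` (parameter
    recovery report). A manifest with the config hash and per-output
    checksums is always written; identical (config, seed) reproduce
    identical checksums.
    """
    from .ecap import amplitude_sweep, compute_ecap, default_ap_waveforms
    from .inverse import ECAPForwardModel, FitProblem, fit_diameter_distribution
    from .sfap import Signal
    from .synth import synth_nerve

    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config["seed"])
    nerve_over = dict(config.get("nerve", {}))
    nerve_over.setdefault("seed", seed)
    spec = NerveSpec.from_dict({**NerveSpec().to_dict(), **nerve_over})
    dt = float(config.get("dt", 1e-5))
    t_max = float(config.get("t_max", 25e-3))
    aps = default_ap_waveforms()
    outputs = []

    mode = config["mode"]
    if mode == "ecap":
        pairs = config.get("recording_pairs") or [list(spec.recording_pair)]
        current = float(config.get("current", spec.partial_current))
        for pair in pairs:
            pair_spec = NerveSpec.from_dict({**spec.to_dict(), "recording_pair": tuple(pair)})
            nerve = synth_nerve(pair_spec)
            res = compute_ecap(nerve.fascicles, aps, current, dt=dt, t_max=t_max)
            sep_mm = abs(pair[1] - pair[0]) * spec.cuff_ring_spacing * 1e3
            path = out / f"ecap_pair{pair[0]}-{pair[1]}_{sep_mm:g}mm.csv"
            _write_trace(path, res.time, res.total)
            outputs.append(path)
    elif mode == "sweep":
        nerve = synth_nerve(spec)
        currents = [float(c) for c in config.get("currents", spec.sweep_currents)]
        table = amplitude_sweep(nerve.fascicles, aps, currents, dt=dt, t_max=t_max)
        path = out / "sweep.csv"
        cols = np.column_stack(
            [table["current"], table["peak_to_peak"], table["recruited_fraction"]]
        )
        np.savetxt(
            path,
            cols,
            header="current_A\tpeak_to_peak_V\trecruited_fraction",
            comments="",
            delimiter="\t",
            fmt="%.12g",
        )
        outputs.append(path)
    else:  # invert
        inv = config.get("invert", {})
        current = float(inv.get("current", max(spec.sweep_currents)))
        nerve = synth_nerve(spec)
        model = ECAPForwardModel(nerve.fascicles, aps, current, dt=dt, t_max=t_max)
        if "reference" in inv:
            rt, rv = np.loadtxt(inv["reference"], skiprows=1, unpack=True)
            reference = Signal(rt, rv)
        else:
            k, th = spec.gamma_params["myelinated-afferent"]
            reference = model.simulate(k, th)
        x0 = tuple(float(x) for x in inv.get("init", (4.0, 1.0e-6)))
        bounds = inv.get("bounds", ((2.0, 12.0), (2e-7, 2e-6)))
        bounds = tuple((float(a), float(b)) for a, b in bounds)
        problem = FitProblem(model, reference, x0, bounds, max_evals=int(inv.get("max_evals", 500)), seed=seed)
        fit = fit_diameter_distribution(problem)
        path = out / "invert_report.json"
        with open(path, "w") as fh:
            json.dump(
                {
                    "shape": fit.shape,
                    "scale": fit.scale,
                    "objective": fit.objective,
                    "n_evals": fit.n_evals,
                    "converged": fit.converged,
                    "history": fit.history.tolist(),
                },
                fh,
                indent=2,
            )
        outputs.append(path)

    manifest = RunManifest.from_outputs(config, seed, outputs)
    manifest.write(out / "manifest.json")
    return out
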