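"""Synthetic multi-subject icEEG generator with known ground truth.

Emulates the statistical structure of trial-epoched subdural recordings
during a five-category visual naming task: 1/f^2 background plus white
noise, a band-limited (60-120 Hz) gamma source whose amplitude is
multiplicatively scaled for an electrode's preferred category from a
configured onset (50 ms linear ramp), category preference and effect size
varying smoothly with electrode coordinate plus a multiplicative
subject-level random effect, and Talairach-like coordinates with a
collinear axis pair per region (mirroring the cortical sheet geometry that
motivates the collinearity screen downstream).

Epochs are generated independently per trial (inter-stimulus structure is
not simulated; all analyses operate on epoched data). One global seed
drives a per-electrode substream so any electrode subset is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from gammatopo.bga import TrialEpochSet

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset",
           "write_dataset", "read_dataset", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

CATEGORIES = ("face", "animate", "place", "tool", "word")

#: post-rejection trial counts per category observed in comparable studies
DEFAULT_TRIALS = {"face": 46, "animate": 31, "place": 49, "tool": 29,
                  "word": 38}

#: per-region coordinate ranges (mm, Talairach-like); x sign flips for the
#: left hemisphere; one axis per region is generated collinear with another
DEFAULT_COORDINATES = {
    "VTC": {"x": (25.0, 45.0), "y": (-75.0, -30.0)},
    "LOC": {"y": (-95.0, -60.0), "z": (-10.0, 25.0)},
}
#: derived axis: region -> (axis, source_axis, slope, intercept, noise_sd);
#: computed from |source|, so ventral z rises with laterality in both
#: hemispheres and lateral |x| tracks y in the occipital cortex
DEFAULT_COLLINEAR = {
    "VTC": ("z", "x", 0.55, -30.0, 1.2),
    "LOC": ("x", "y", 0.45, 75.0, 2.5),
}
#: per-category amplitude-gain gradient: (base, slope_per_mm, axis)
DEFAULT_EFFECT = {
    "face": (1.2, 0.04, "x"),
    "animate": (0.9, 0.03, "x"),
    "place": (1.2, -0.04, "x"),
    "tool": (0.9, -0.03, "x"),
    "word": (0.9, 0.02, "y"),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic dataset."""

    n_subjects: int = 26
    n_subjects_left: int = 16
    electrodes_per_subject: int | tuple[int, int] = (3, 10)
    sampling_rate_hz: float = 1000.0
    categories: tuple[str, ...] = CATEGORIES
    trials_per_category: dict = field(default_factory=lambda: dict(DEFAULT_TRIALS))
    epoch_window_s: tuple[float, float] = (-1.0, 2.0)
    baseline_window_s: tuple[float, float] = (-0.7, -0.2)
    gamma_band_hz: tuple[float, float] = (60.0, 120.0)
    selectivity_effect: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    selective_fraction: float = 0.6
    onset_s: float = 0.15
    ramp_s: float = 0.05
    noise_exponent: float = 2.0
    pink_sd: float = 8.0
    white_sd: float = 2.0
    line_amplitude: float = 0.0
    gamma_source_sd: float = 1.5
    subject_sd: float = 0.3
    region_fraction_vtc: float = 0.65
    coordinate_ranges: dict = field(default_factory=lambda: {
        r: dict(v) for r, v in DEFAULT_COORDINATES.items()})
    collinear_axis: dict = field(default_factory=lambda: dict(DEFAULT_COLLINEAR))
    probe_tone: tuple | None = None   # (electrode_idx, freq_hz, amp, post_gain)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or not (0 <= self.n_subjects_left <= self.n_subjects):
            raise ValueError("invalid subject counts")
        for cat in self.categories:
            if self.trials_per_category.get(cat, 0) < 2:
                raise ValueError(f"trials_per_category[{cat!r}] must be >= 2")
        t0, t1 = self.epoch_window_s
        b0, b1 = self.baseline_window_s
        if not (t0 < t1):
            raise ValueError("epoch window inverted")
        if not (t0 <= b0 < b1 <= 0.0):
            raise ValueError("baseline window must precede stimulus onset and "
                             "lie inside the epoch")
        if t1 < 0.4:
            raise ValueError("epoch must extend to at least +0.4 s")
        lo, hi = self.gamma_band_hz
        if not (0 < lo < hi < self.sampling_rate_hz / 2):
            raise ValueError("gamma band outside (0, Nyquist)")
        if self.onset_s < 0:
            raise ValueError("onset must be at/after stimulus onset")
        ep = self.electrodes_per_subject
        if isinstance(ep, int):
            if ep < 1:
                raise ValueError("non-positive electrode count")
        elif not (1 <= ep[0] <= ep[1]):
            raise ValueError("invalid electrodes_per_subject range")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for key in ("electrodes_per_subject", "epoch_window_s",
                    "baseline_window_s", "gamma_band_hz", "categories",
                    "probe_tone"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        d["selectivity_effect"] = {k: tuple(v) for k, v in
                                   d["selectivity_effect"].items()}
        d["collinear_axis"] = {k: tuple(v) for k, v in
                               d["collinear_axis"].items()}
        d["coordinate_ranges"] = {r: {a: tuple(v) for a, v in axes.items()}
                                  for r, axes in d["coordinate_ranges"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Injected truth for parameter-recovery tests."""

    effects: pd.DataFrame          # electrode, category, selective, gain
    onset_s: float
    ramp_s: float
    gradient: dict                 # category -> (base, slope_per_mm, axis)
    subject_offsets: dict          # subject id -> log-scale random offset

    def __post_init__(self) -> None:
        sel = self.effects[self.effects["selective"]]
        if len(sel) and not np.all(sel["gain"] > 0):
            raise ValueError("flagged-selective electrode with non-positive gain")
        if self.onset_s < 0:
            raise ValueError("onset must be >= 0")


def _powerlaw_noise(rng: np.random.Generator, shape: tuple[int, int],
                    fs: float, exponent: float, sd: float) -> np.ndarray:
    """Fourier-synthesized 1/f^exponent noise, scaled to target SD."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((shape[0], freqs.size))
            + 1j * rng.standard_normal((shape[0], freqs.size))) * amp
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms * sd


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, int],
                       fs: float, band: tuple[float, float],
                       sd: float) -> np.ndarray:
    """Gaussian noise restricted to [band] by frequency-domain masking."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = (rng.standard_normal((shape[0], freqs.size))
            + 1j * rng.standard_normal((shape[0], freqs.size)))
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms * sd


def _axis_center(config: SimulationConfig, region: str, axis: str) -> float:
    """Mean |value| of an axis in a region (directly drawn or derived)."""
    ranges = config.coordinate_ranges[region]
    if axis in ranges:
        return float(np.mean(np.abs(ranges[axis])))
    dax, src, slope, icpt, _ = config.collinear_axis[region]
    if axis == dax and src in ranges:
        return float(abs(icpt + slope * np.mean(np.abs(ranges[src]))))
    return 0.0


def _gain_envelope(t: np.ndarray, gain: float, onset_s: float,
                   ramp_s: float) -> np.ndarray:
    """1 before onset, 1+gain after onset+ramp, linear in between."""
    if gain == 0.0:
        return np.ones_like(t)
    if ramp_s > 0:
        frac = np.clip((t - onset_s) / ramp_s, 0.0, 1.0)
    else:
        frac = (t >= onset_s).astype(float)
    frac[t < onset_s] = 0.0
    return 1.0 + gain * frac


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[list[TrialEpochSet], pd.DataFrame, GroundTruth]:
    """Generate one dataset: per-electrode epochs, geometry and ground truth.

    Deterministic for a fixed ``config.seed``; electrode ``k`` (global
    index) always draws from substream ``[seed, k]`` regardless of how many
    electrodes precede it.
    """
    config.validate()
    fs = config.sampling_rate_hz
    t0, t1 = config.epoch_window_s
    n_samples = int(round((t1 - t0) * fs))
    time_axis = t0 + np.arange(n_samples) / fs

    layout_rng = np.random.default_rng([config.seed, 999_983])
    subject_ids = ([f"L{i+1:02d}" for i in range(config.n_subjects_left)]
                   + [f"R{i+1:02d}" for i in
                      range(config.n_subjects - config.n_subjects_left)])
    subject_offsets = {sid: float(layout_rng.normal(0.0, config.subject_sd))
                       for sid in subject_ids}

    ep = config.electrodes_per_subject
    geo_rows, effect_rows, epochs = [], [], []
    electrode_index = 0
    for sid in subject_ids:
        hemi = "L" if sid.startswith("L") else "R"
        n_elec = ep if isinstance(ep, int) else int(layout_rng.integers(ep[0], ep[1] + 1))
        for _ in range(n_elec):
            rng = np.random.default_rng([config.seed, electrode_index])
            eid = f"{sid}-e{electrode_index:03d}"
            region = "VTC" if rng.random() < config.region_fraction_vtc else "LOC"
            coords = {}
            for ax, (lo, hi) in config.coordinate_ranges[region].items():
                coords[ax] = float(rng.uniform(lo, hi))
            dax, src, slope, icpt, nsd = config.collinear_axis[region]
            coords[dax] = float(icpt + slope * coords[src] + rng.normal(0, nsd))
            if hemi == "L" and "x" in coords:
                coords["x"] = -abs(coords["x"])

            # preferred category and injected gain; preference follows the
            # topology: classes with larger local gain are the more likely
            # preferred class, so selectivity clusters along the gradient
            allowed = [c for c in config.categories
                       if not (c == "word" and hemi != "L")]
            raw_gain = {}
            for c in allowed:
                base, slope_mm, gax = config.selectivity_effect[c]
                centered = abs(coords[gax]) - _axis_center(config, region, gax)
                raw_gain[c] = base + slope_mm * centered
            preferred = None
            gain = 0.0
            if rng.random() < config.selective_fraction:
                g = np.array([raw_gain[c] for c in allowed])
                if np.any(g > 0):
                    w = np.exp((g - g.max()) / 0.5)
                    w /= w.sum()
                    preferred = str(rng.choice(allowed, p=w))
                    raw = raw_gain[preferred]
                    if raw > 0:
                        gain = raw * np.exp(subject_offsets[sid])
                    else:
                        preferred = None

            labels, trial_gains = [], []
            for cat in config.categories:
                if cat == "word" and hemi != "L":
                    continue
                n_tr = int(config.trials_per_category[cat])
                labels += [cat] * n_tr
                trial_gains += [gain if cat == preferred else 0.0] * n_tr
            labels = np.array(labels)
            trial_gains = np.array(trial_gains)
            n_trials = labels.size

            volts = _powerlaw_noise(rng, (n_trials, n_samples), fs,
                                    config.noise_exponent, config.pink_sd)
            volts += rng.standard_normal((n_trials, n_samples)) * config.white_sd
            carrier = _bandlimited_noise(rng, (n_trials, n_samples), fs,
                                         config.gamma_band_hz,
                                         config.gamma_source_sd)
            for i in range(n_trials):
                env = _gain_envelope(time_axis, trial_gains[i],
                                     config.onset_s, config.ramp_s)
                volts[i] += env * carrier[i]
            if config.line_amplitude > 0:
                phase = rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
                volts += config.line_amplitude * np.sin(
                    2 * np.pi * 60.0 * time_axis[None, :] + phase)
            if (config.probe_tone is not None
                    and electrode_index == config.probe_tone[0]):
                _, f_hz, amp, post_gain = config.probe_tone
                tone_env = 1.0 + (post_gain - 1.0) * (time_axis >= 0)
                volts += amp * tone_env * np.sin(2 * np.pi * f_hz * time_axis)

            epochs.append(TrialEpochSet(voltages=volts, time_axis=time_axis,
                                        sampling_rate_hz=fs, categories=labels,
                                        electrode_id=eid))
            geo_rows.append({"electrode": eid, "subject": sid,
                             "hemisphere": hemi, "region": region,
                             "x": coords.get("x", 0.0),
                             "y": coords.get("y", 0.0),
                             "z": coords.get("z", 0.0)})
            for cat in config.categories:
                if cat == "word" and hemi != "L":
                    continue
                effect_rows.append({"electrode": eid, "category": cat,
                                    "selective": cat == preferred and gain > 0,
                                    "gain": gain if cat == preferred else 0.0})
            electrode_index += 1

    geometry = pd.DataFrame(geo_rows).set_index("electrode")
    truth = GroundTruth(effects=pd.DataFrame(effect_rows),
                        onset_s=config.onset_s, ramp_s=config.ramp_s,
                        gradient=dict(config.selectivity_effect),
                        subject_offsets=subject_offsets)
    return epochs, geometry, truth


# ---------------------------------------------------------------------------
# on-disk container: one HDF5 per simulation + JSON config sidecar


def write_dataset(dataset, path, config: SimulationConfig | None = None) -> None:
    """Serialize (epochs, geometry, truth) to an HDF5 container.

    Layout: /subjects/<sid>/electrodes/<eid>/{epochs,categories},
    /time_axis, /geometry/*, /ground_truth/*; schema version and sampling
    rate as root attributes. When ``config`` is given, its JSON is written
    both as a root attribute and as a ``<path>.config.json`` sidecar.
    """
    epochs, geometry, truth = dataset
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate_hz"] = epochs[0].sampling_rate_hz
        f.create_dataset(track_times=False, name="time_axis", data=epochs[0].time_axis)
        for ep in epochs:
            sid = geometry.loc[ep.electrode_id, "subject"]
            g = f.require_group(f"subjects/{sid}/electrodes/{ep.electrode_id}")
            g.create_dataset(track_times=False, name="epochs", data=ep.voltages)
            g.create_dataset(track_times=False, name="categories",
                             data=np.array(ep.categories, dtype="S"))
            g.create_dataset(track_times=False, name="rejected", data=ep.rejected)
        gg = f.create_group("geometry")
        gg.create_dataset(track_times=False, name="electrode", data=np.array(geometry.index, dtype="S"))
        for col in ("subject", "hemisphere", "region"):
            gg.create_dataset(col, data=np.array(geometry[col], dtype="S"))
        for col in ("x", "y", "z"):
            gg.create_dataset(col, data=geometry[col].to_numpy(float))
        tg = f.create_group("ground_truth")
        eff = truth.effects
        tg.create_dataset(track_times=False, name="electrode", data=np.array(eff["electrode"], dtype="S"))
        tg.create_dataset(track_times=False, name="category", data=np.array(eff["category"], dtype="S"))
        tg.create_dataset(track_times=False, name="selective", data=eff["selective"].to_numpy(bool))
        tg.create_dataset(track_times=False, name="gain", data=eff["gain"].to_numpy(float))
        tg.attrs["onset_s"] = truth.onset_s
        tg.attrs["ramp_s"] = truth.ramp_s
        tg.attrs["gradient_json"] = json.dumps(
            {k: list(v) for k, v in truth.gradient.items()})
        tg.attrs["subject_offsets_json"] = json.dumps(truth.subject_offsets)
        if config is not None:
            f.attrs["config_json"] = config.to_json()
    if config is not None:
        with open(path + ".config.json", "w") as fh:
            fh.write(config.to_json())


def read_dataset(path) -> tuple[list[TrialEpochSet], pd.DataFrame, GroundTruth]:
    """Read a dataset container written by :func:`write_dataset`."""
    path = str(path)
    try:
        f = h5py.File(path, "r")
    except (OSError, IOError) as exc:
        raise IOError(f"cannot read dataset file {path!r}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"dataset schema version {version!r} in {path!r} does not "
                f"match supported version {SCHEMA_VERSION!r}")
        try:
            fs = float(f.attrs["sampling_rate_hz"])
            time_axis = f["time_axis"][()]
            epochs = []
            for sid in f["subjects"]:
                for eid in f[f"subjects/{sid}/electrodes"]:
                    g = f[f"subjects/{sid}/electrodes/{eid}"]
                    epochs.append(TrialEpochSet(
                        voltages=g["epochs"][()], time_axis=time_axis,
                        sampling_rate_hz=fs,
                        categories=g["categories"][()].astype(str),
                        electrode_id=eid, rejected=g["rejected"][()]))
            gg = f["geometry"]
            geometry = pd.DataFrame({
                "electrode": gg["electrode"][()].astype(str),
                "subject": gg["subject"][()].astype(str),
                "hemisphere": gg["hemisphere"][()].astype(str),
                "region": gg["region"][()].astype(str),
                "x": gg["x"][()], "y": gg["y"][()], "z": gg["z"][()],
            }).set_index("electrode")
            tg = f["ground_truth"]
            effects = pd.DataFrame({
                "electrode": tg["electrode"][()].astype(str),
                "category": tg["category"][()].astype(str),
                "selective": tg["selective"][()].astype(bool),
                "gain": tg["gain"][()],
            })
            truth = GroundTruth(
                effects=effects, onset_s=float(tg.attrs["onset_s"]),
                ramp_s=float(tg.attrs["ramp_s"]),
                gradient={k: tuple(v) for k, v in
                          json.loads(tg.attrs["gradient_json"]).items()},
                subject_offsets=json.loads(tg.attrs["subject_offsets_json"]))
        except KeyError as exc:
            raise IOError(f"dataset file {path!r} is missing field {exc}") from exc
    # restore original electrode order
    order = geometry.index.tolist()
    epochs.sort(key=lambda e: order.index(e.electrode_id))
    return epochs, geometry, truth
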