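"""Dataset contract and on-disk layout.

One recording couples an STN spike train with a multi-channel ECoG strip
(LFP at 1000 Hz), an optional wideband channel (30 kHz, for high-frequency
activity), and a trial event table. Times are seconds (float) from recording
start; sample indices are 0-based; windows are half-open [t0, t1).

On disk, a dataset is a directory with a `manifest.json` naming one
sub-directory per recording; each holds diffable CSVs for events and spikes
and a binary `signals.npz` with a JSON metadata sidecar for the bulk
samples.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "trial_id", "cue_on_s", "go_on_s", "grip_on_s", "grip_off_s",
    "side", "rt_s", "peak_force_N", "peak_yank_N_per_ms", "valid",
]
SPIKE_COLUMNS = ["unit_id", "quality", "time_s"]
MIN_CONTRA_TRIALS = 8
RT_LIMIT_S = 2.0


class ValidationError(ValueError):
    pass


class LoadError(IOError):
    pass


@dataclass
class SpikeTrain:
    unit_id: str
    quality: str  # 'single' or 'multi'
    times: np.ndarray  # seconds, ascending

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class SignalChannel:
    label: str
    rate: float  # Hz
    samples: np.ndarray
    coords_mm: np.ndarray | None = None
    units: str = "uV"

    def __post_init__(self):
        self.samples = np.asarray(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Recording:
    recording_id: str
    spike_train: SpikeTrain
    lfp: list[SignalChannel]
    trials: pd.DataFrame
    wideband: SignalChannel | None = None

    @property
    def lfp_rate(self) -> float:
        return self.lfp[0].rate

    @property
    def lfp_array(self) -> np.ndarray:
        return np.stack([c.samples for c in self.lfp])

    @property
    def duration(self) -> float:
        return self.lfp[0].duration


def validate_trials(trials: pd.DataFrame, strict: bool = True) -> list[str]:
    """Check trial-table invariants; raise (strict) or warn otherwise."""
    problems = []
    v = trials["valid"].astype(bool)
    ev = trials.loc[v, ["cue_on_s", "go_on_s", "grip_on_s", "grip_off_s"]]
    if len(ev) and np.any(np.diff(ev.to_numpy(float), axis=1) <= 0):
        problems.append("event order violated (need cue_on < go_on < grip_on "
                        "< grip_off on valid trials)")
    rt = trials.loc[v, "grip_on_s"] - trials.loc[v, "go_on_s"]
    if len(rt) and not np.allclose(rt, trials.loc[v, "rt_s"], atol=1e-6):
        problems.append("rt_s inconsistent with grip_on_s - go_on_s")
    if len(rt) and np.any(trials.loc[v, "rt_s"] > RT_LIMIT_S + 1e-9):
        problems.append(f"valid trial with rt_s > {RT_LIMIT_S} s")
    if not set(trials["side"]) <= {"contra", "ipsi"}:
        problems.append("side must be 'contra' or 'ipsi'")
    if int((v & (trials["side"] == "contra")).sum()) < MIN_CONTRA_TRIALS:
        problems.append(f"fewer than {MIN_CONTRA_TRIALS} valid contralateral trials")
    if problems and strict:
        raise ValidationError("; ".join(problems))
    for p in problems:
        warnings.warn(p, stacklevel=2)
    return problems


def validate_recording(rec: Recording, strict: bool = True) -> list[str]:
    problems = validate_trials(rec.trials, strict=False)
    t = rec.spike_train.times
    if t.size < 1:
        problems.append("spike train is empty")
    if t.size and np.any(np.diff(t) < 0):
        problems.append("spike times not sorted")
    dur = rec.duration
    if t.size and (t[0] < 0 or t[-1] > dur):
        problems.append("spike times outside [0, duration]")
    rates = {c.rate for c in rec.lfp}
    lens = {len(c.samples) for c in rec.lfp}
    if len(rates) > 1 or len(lens) > 1:
        problems.append("LFP channels differ in rate or length")
    v = rec.trials["valid"].astype(bool)
    if len(rec.trials) and np.any(
        rec.trials.loc[v, "grip_off_s"].to_numpy(float) + 0.4 > dur + 1e-9
    ):
        problems.append("trial events extend past the signal duration")
    for c in rec.lfp + ([rec.wideband] if rec.wideband else []):
        if not np.all(np.isfinite(c.samples)):
            problems.append(f"non-finite samples in channel {c.label}")
    if problems and strict:
        raise ValidationError(f"{rec.recording_id}: " + "; ".join(problems))
    for p in problems:
        warnings.warn(f"{rec.recording_id}: {p}", stacklevel=2)
    return problems


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def write_dataset(recordings: list[Recording], path, overwrite: bool = False):
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise IOError(f"{path} exists and is not empty (pass overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"recordings": []}
    for rec in recordings:
        d = path / rec.recording_id
        d.mkdir(exist_ok=True)
        rec.trials.to_csv(d / "events.csv", index=False, columns=EVENT_COLUMNS)
        st = rec.spike_train
        pd.DataFrame({
            "unit_id": st.unit_id, "quality": st.quality, "time_s": st.times,
        }).to_csv(d / "spikes.csv", index=False)
        arrays, meta = {}, []
        for i, c in enumerate(rec.lfp):
            key = f"lfp_{i}"
            arrays[key] = c.samples.astype(np.float32)
            meta.append({"key": key, "label": c.label, "rate_hz": c.rate,
                         "n_samples": len(c.samples), "units": c.units,
                         "coords_mm": None if c.coords_mm is None
                         else list(map(float, c.coords_mm)),
                         "kind": "lfp"})
        if rec.wideband is not None:
            arrays["wideband"] = rec.wideband.samples.astype(np.float32)
            meta.append({"key": "wideband", "label": rec.wideband.label,
                         "rate_hz": rec.wideband.rate,
                         "n_samples": len(rec.wideband.samples),
                         "units": rec.wideband.units, "coords_mm": None,
                         "kind": "wideband"})
        np.savez(d / "signals.npz", **arrays)
        (d / "signals.json").write_text(json.dumps(meta, indent=1))
        manifest["recordings"].append({"id": rec.recording_id,
                                       "dir": rec.recording_id})
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(path, validate: str = "strict") -> list[Recording]:
    """Load a dataset directory; `validate` is 'strict' (errors), 'warn', or
    'skip'."""
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise LoadError(f"no manifest.json under {path}")
    manifest = json.loads(mf.read_text())
    out = []
    for entry in manifest["recordings"]:
        rid, d = entry["id"], path / entry["dir"]
        for fname in ("events.csv", "spikes.csv", "signals.npz", "signals.json"):
            if not (d / fname).exists():
                raise LoadError(f"recording {rid}: missing {fname}")
        trials = pd.read_csv(d / "events.csv")
        spikes = pd.read_csv(d / "spikes.csv")
        st = SpikeTrain(str(spikes["unit_id"].iloc[0]),
                        str(spikes["quality"].iloc[0]),
                        spikes["time_s"].to_numpy(float))
        meta = json.loads((d / "signals.json").read_text())
        with np.load(d / "signals.npz") as z:
            lfp, wb = [], None
            for m in meta:
                ch = SignalChannel(
                    m["label"], float(m["rate_hz"]),
                    z[m["key"]].astype(float),
                    None if m["coords_mm"] is None else np.asarray(m["coords_mm"]),
                    m.get("units", "uV"),
                )
                if m["kind"] == "wideband":
                    wb = ch
                else:
                    lfp.append(ch)
        rec = Recording(rid, st, lfp, trials, wb)
        if validate != "skip":
            validate_recording(rec, strict=(validate == "strict"))
        out.append(rec)
    return out
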