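"""On-disk formats: WAV audio, JSON stimulus sidecars, HDF5 session bundles."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .session import GroundTruthSite, SessionBundle
from .stimulus import SFGStimulus, build_frequency_pool, render_waveform


def write_wav(path: str | Path, samples: np.ndarray, fs: int = 44100) -> None:
    """Write mono 16-bit PCM WAV (samples expected within [-1, 1])."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), fs, (x * 32767).astype(np.int16))


def write_stimulus(
    out_dir: str | Path, stim: SFGStimulus, render: bool = True, name: str | None = None
) -> Path:
    """Write one stimulus: WAV (optional) plus a JSON metadata sidecar with
    the pool, the 60 x 15 element matrix, coherence and figure-onset info."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or stim.stimulus_id or "stimulus"
    meta = {
        "stimulus_id": stim.stimulus_id,
        "pool_hz": stim.pool.frequencies_hz.tolist(),
        "chord_elements": stim.chord_elements.tolist(),
        "coherence": stim.coherence,
        "figure_onset_chord": stim.figure_onset_chord,
        "figure_onset_ms": stim.figure_onset_ms,
        "figure_set": None if stim.figure_set is None else stim.figure_set.tolist(),
        "chord_dur_ms": stim.chord_dur_ms,
        "ramp_ms": stim.ramp_ms,
        "sample_rate_hz": stim.sample_rate_hz,
        "level_db_spl": stim.level_db_spl,
        "seed": stim.seed,
    }
    (out_dir / f"{name}.json").write_text(json.dumps(meta))
    if render:
        write_wav(out_dir / f"{name}.wav", render_waveform(stim), stim.sample_rate_hz)
    return out_dir / f"{name}.json"


def read_stimulus(json_path: str | Path) -> SFGStimulus:
    meta = json.loads(Path(json_path).read_text())
    pool = build_frequency_pool()
    if not np.allclose(pool.frequencies_hz, meta["pool_hz"]):
        freqs = np.asarray(meta["pool_hz"], dtype=float)
        freqs.setflags(write=False)
        pool = dataclasses.replace(pool, frequencies_hz=freqs)
    fig_set = meta["figure_set"]
    return SFGStimulus(
        chord_elements=np.asarray(meta["chord_elements"], dtype=np.intp),
        coherence=meta["coherence"],
        figure_onset_chord=meta["figure_onset_chord"],
        figure_set=None if fig_set is None else np.asarray(fig_set, dtype=np.intp),
        pool=pool,
        chord_dur_ms=meta["chord_dur_ms"],
        ramp_ms=meta["ramp_ms"],
        sample_rate_hz=meta["sample_rate_hz"],
        level_db_spl=meta["level_db_spl"],
        stimulus_id=meta["stimulus_id"],
        seed=meta["seed"],
    )


def save_session(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write a session bundle: trials.csv, traces + ground truth in HDF5
    (one group per site), and a JSON echo of seed/kind."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(out_dir / "trials.csv", index=False)
    with h5py.File(out_dir / "bundle.h5", "w") as f:
        f.attrs["t0_ms"] = bundle.t0_ms
        f.attrs["seed"] = bundle.seed
        f.attrs["kind"] = bundle.kind
        for i, site in enumerate(bundle.sites):
            g = f.create_group(f"site_{site.site_id:04d}")
            g.create_dataset("envelope", data=bundle.traces[i], compression="gzip")
            for k, v in dataclasses.asdict(site).items():
                g.attrs[k] = v
    (out_dir / "session.json").write_text(
        json.dumps({"seed": bundle.seed, "kind": bundle.kind,
                    "n_sites": len(bundle.sites), "n_trials": len(bundle.trials)})
    )
    for i, stim in enumerate(bundle.stimuli):
        # index-prefixed names keep on-disk order aligned with stimulus_index
        write_stimulus(out_dir / "stimuli", stim, render=False,
                       name=f"{i:02d}_{stim.stimulus_id}")
    return out_dir


def load_session(in_dir: str | Path) -> SessionBundle:
    in_dir = Path(in_dir)
    trials = pd.read_csv(in_dir / "trials.csv")
    sites, traces = [], []
    with h5py.File(in_dir / "bundle.h5", "r") as f:
        t0 = float(f.attrs["t0_ms"])
        seed = int(f.attrs["seed"])
        kind = str(f.attrs["kind"])
        for name in sorted(f.keys()):
            g = f[name]
            attrs = {k: g.attrs[k] for k in g.attrs}
            for key in ("field_label",):
                attrs[key] = str(attrs[key])
            attrs["site_id"] = int(attrs["site_id"])
            attrs["phase_lock"] = bool(attrs["phase_lock"])
            attrs["is_modulated"] = bool(attrs["is_modulated"])
            sites.append(GroundTruthSite(**attrs))
            traces.append(g["envelope"][...])
    stim_dir = in_dir / "stimuli"
    stimuli = []
    if stim_dir.exists():
        stimuli = [read_stimulus(p) for p in sorted(stim_dir.glob("*.json"))]
    return SessionBundle(
        trials=trials, traces=np.stack(traces), t0_ms=t0, sites=sites,
        stimuli=stimuli, seed=seed, kind=kind,
    )
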