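"""Reading and writing trial files.

The interchange format is plain delimited text: one file per trial with a
header row of channel labels and one row per sample (time x channels),
plus a tab-separated ``manifest.tsv`` mapping files to (subject,
condition, fs, seed).  EDF files referenced by a manifest are read
through MNE when it is installed.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from eegattn.simulate import CHANNELS, EEGTrial, normalize_condition

MANIFEST_NAME = "manifest.tsv"


def write_trial(trial: EEGTrial, path) -> None:
    """Write one trial as tab-delimited text, time x channels with header."""
    frame = pd.DataFrame(trial.samples.T, columns=list(trial.channels))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _reorder(samples: np.ndarray, channels: Sequence[str]) -> np.ndarray:
    found = tuple(channels)
    if sorted(found) != sorted(CHANNELS):
        raise ValueError(
            f"channel set mismatch: expected {sorted(CHANNELS)}, got {sorted(found)}"
        )
    order = [found.index(ch) for ch in CHANNELS]
    return samples[order]


def read_trial(path, subject_id: str, condition: str, fs: float) -> EEGTrial:
    """Read one trial file (delimited text or EDF), normalizing channel order."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        samples, file_fs, channels = _read_edf(path)
        if abs(file_fs - fs) > 1e-9:
            raise ValueError(f"sampling-rate mismatch: manifest says {fs}, file has {file_fs}")
    else:
        frame = pd.read_csv(path, sep="\t")
        channels = list(frame.columns)
        samples = frame.to_numpy(dtype=np.float64).T
    return EEGTrial(
        samples=_reorder(samples, channels),
        fs=fs,
        subject_id=subject_id,
        condition=normalize_condition(condition),
    )


def _read_edf(path: Path):
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment-dependent
        raise ImportError("reading EDF files requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def write_dataset(trials: Sequence[EEGTrial], outdir, seed: Optional[int] = None) -> Path:
    """Write every trial plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for trial in trials:
        fname = f"{trial.subject_id}_{trial.condition}.tsv"
        write_trial(trial, outdir / fname)
        records.append(
            {
                "file": fname,
                "subject": trial.subject_id,
                "condition": trial.condition,
                "fs": trial.fs,
                "seed": "" if seed is None else seed,
            }
        )
    manifest_path = outdir / MANIFEST_NAME
    pd.DataFrame.from_records(records).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def load_trials(source_dir) -> List[EEGTrial]:
    """Load all trials listed in a directory's manifest."""
    source_dir = Path(source_dir)
    manifest_path = source_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {source_dir}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"file", "subject", "condition", "fs"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    trials = []
    fs_values = set()
    for rec in manifest.to_dict("records"):
        trial = read_trial(
            source_dir / rec["file"], str(rec["subject"]), str(rec["condition"]), float(rec["fs"])
        )
        fs_values.add(trial.fs)
        trials.append(trial)
    if len(fs_values) > 1:
        raise ValueError(f"inconsistent sampling rates across trials: {sorted(fs_values)}")
    return trials
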