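"""File interchange: tab-delimited tables with provenance headers, raw-array
recordings with a montage sidecar, and EDF import.

Tables are plain TSV with ``NA`` as the missing-value sentinel and ``#``
comment lines carrying provenance (config hash, seed) at the top. Recordings
round-trip as a NumPy ``.npz`` plus a JSON sidecar describing the montage;
EDF files are read through MNE when real recordings are available in that
format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording
from .montage import make_montage


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a tidy table as TSV with ``NA`` sentinels and ``# key=value``
    provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], keep_default_na=False)


def read_provenance(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            out[k.strip()] = v
    return out


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as ``.npz`` (channels x samples, microvolts) with a
    JSON montage sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, data=rec.data, fs=rec.fs,
        subject=rec.subject, run_id=rec.run_id, handedness=rec.handedness,
    )
    sidecar = {
        "channels": list(rec.ch_names),
        "pos2d": {c: list(map(float, p)) for c, p in zip(rec.ch_names, rec.montage.pos2d)},
    }
    path.with_suffix(".montage.json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    z = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".montage.json").read_text())
    montage = make_montage(tuple(sidecar["channels"]))
    return Recording(
        data=z["data"], fs=float(z["fs"]), montage=montage,
        handedness=str(z["handedness"]), subject=int(z["subject"]), run_id=int(z["run_id"]),
    )


def read_edf(path: str | Path, subject: int = 0, run_id: int = 0,
             handedness: str = "right") -> Recording:
    """Read a 10/20-labeled EDF recording into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    montage = make_montage(tuple(raw.ch_names))
    return Recording(
        data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), montage=montage,
        handedness=handedness, subject=subject, run_id=run_id,
    )
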