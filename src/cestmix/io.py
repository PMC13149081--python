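"""NIfTI readers/writers, sidecar metadata and checkpoint serialization.

On disk a cohort directory holds, per patient ``<pid>``:

* ``<pid>_cest.nii.gz`` — 4-D Z-stack, axes (row, col, 1, offset)
* ``<pid>_m0.nii.gz``   — reference image (row, col)
* ``<pid>_mask.nii.gz`` — binary tumor mask (row, col)

plus two shared sidecars: ``offsets.txt`` (one ppm value per line) and
``labels.csv`` (header ``patient_id,split,idh,mgmt``).  Offsets live in a
plain-text sidecar rather than NIfTI intent codes so any reader can consume
them.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .nn.net import MixBranchNet, NetworkConfig
from .phantom import CESTVolume, PatientRecord


class FormatError(ValueError):
    pass


def _save_nifti(path: Path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine=np.eye(4)), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_cest_nifti(volume: CESTVolume, out_dir: str | Path, patient_id: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save_nifti(out / f"{patient_id}_cest.nii.gz", volume.data[:, :, None, :])
    _save_nifti(out / f"{patient_id}_m0.nii.gz", volume.m0)
    offsets_file = out / "offsets.txt"
    if not offsets_file.exists():
        np.savetxt(offsets_file, volume.offsets, fmt="%.10g")


def read_cest_nifti(in_dir: str | Path, patient_id: str) -> CESTVolume:
    src = Path(in_dir)
    stack = _load_nifti(src / f"{patient_id}_cest.nii.gz")
    if stack.ndim == 4:
        stack = stack[:, :, 0, :]
    elif stack.ndim != 3:
        raise FormatError(f"expected 3-D or 4-D stack, got {stack.ndim}-D")
    offsets = np.atleast_1d(np.loadtxt(src / "offsets.txt"))
    if stack.shape[-1] != offsets.size:
        raise FormatError(
            f"offset-count mismatch: stack has {stack.shape[-1]} channels, "
            f"sidecar lists {offsets.size} offsets"
        )
    m0 = _load_nifti(src / f"{patient_id}_m0.nii.gz")
    return CESTVolume(stack, m0, offsets)


def write_cohort(records, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_cest_nifti(rec.volume, out, rec.patient_id)
        _save_nifti(out / f"{rec.patient_id}_mask.nii.gz",
                    rec.tumor_mask.astype(np.uint8))
        rows.append(
            {"patient_id": rec.patient_id, "split": rec.split,
             "idh": rec.idh, "mgmt": rec.mgmt}
        )
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def read_cohort(in_dir: str | Path) -> list[PatientRecord]:
    src = Path(in_dir)
    table = pd.read_csv(src / "labels.csv")
    records = []
    for row in table.itertuples():
        pid = str(row.patient_id)
        vol = read_cest_nifti(src, pid)
        mask = _load_nifti(src / f"{pid}_mask.nii.gz").astype(bool)
        split = None if pd.isna(row.split) else row.split
        records.append(
            PatientRecord(pid, vol, mask, int(row.idh), int(row.mgmt), split=split)
        )
    return records


# --------------------------------------------------------------------------- #
# checkpoints
# --------------------------------------------------------------------------- #


def save_checkpoint(net: MixBranchNet, path: str | Path) -> None:
    """Weights as .npz with the architecture config embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> MixBranchNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint artifact: {path}")
    with np.load(path) as archive:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(archive["__config__"].tobytes()).decode())
        )
        net = MixBranchNet(cfg)
        net.load_state_dict(
            {k: archive[k] for k in archive.files if k != "__config__"}
        )
    return net
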