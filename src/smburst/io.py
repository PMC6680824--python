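"""Photon-HDF5-style file I/O.

Layout follows the Photon-HDF5 convention for the mandatory photon data —
``photon_data/timestamps``, ``photon_data/detectors`` and
``photon_data/timestamps_specs/timestamps_unit`` — plus a ``ground_truth``
extension group carrying the simulation-only molecule ids and emission
positions.  Files written by other tools that lack the ground-truth group
can still be read: burst search then works, but purity analyses raise a
capability error.
"""

from __future__ import annotations

import h5py
import numpy as np

from .photons import PhotonStream

__all__ = ["write_photon_file", "read_photon_file"]


def write_photon_file(stream: PhotonStream, path) -> None:
    with h5py.File(path, "w") as f:
        pd = f.create_group("photon_data")
        pd.create_dataset("timestamps", data=stream.timestamps)
        pd.create_dataset("detectors", data=stream.channel)
        spec = pd.create_group("timestamps_specs")
        spec.create_dataset("timestamps_unit", data=stream.timestep_ns * 1e-9)
        gt = f.create_group("ground_truth")
        gt.create_dataset("molecule_id", data=stream.molecule_id)
        gt.create_dataset("position_um", data=stream.position_um)
        f.attrs["duration_s"] = stream.duration_s
        f.attrs["n_molecules"] = stream.n_molecules


def read_photon_file(path) -> PhotonStream:
    """Read a photon file; tolerates a missing ground-truth group.

    Without ground truth, molecule ids are filled with −2 ("unknown") and
    positions with NaN, which downstream purity code rejects explicitly.
    """
    with h5py.File(path, "r") as f:
        if "photon_data" not in f or "timestamps" not in f["photon_data"]:
            raise ValueError(f"{path}: missing photon_data/timestamps")
        pd = f["photon_data"]
        ts = pd["timestamps"][()].astype(np.int64)
        if "detectors" not in pd:
            raise ValueError(f"{path}: missing photon_data/detectors")
        det = pd["detectors"][()].astype(np.uint8)
        if "timestamps_specs" not in pd or "timestamps_unit" not in pd["timestamps_specs"]:
            raise ValueError(f"{path}: missing timestamps_specs/timestamps_unit")
        unit_s = float(pd["timestamps_specs/timestamps_unit"][()])
        if "ground_truth" in f:
            mol = f["ground_truth/molecule_id"][()].astype(np.int32)
            pos = f["ground_truth/position_um"][()].astype(np.float32)
        else:
            from .photons import UNKNOWN_ID

            mol = np.full(len(ts), UNKNOWN_ID, np.int32)
            pos = np.full((len(ts), 3), np.nan, np.float32)
        duration = float(f.attrs.get("duration_s", ts[-1] * unit_s if len(ts) else 0.0))
        n_mol = int(f.attrs.get("n_molecules", 0))
    return PhotonStream(
        timestamps=ts,
        molecule_id=mol,
        channel=det,
        position_um=pos,
        timestep_ns=unit_s * 1e9,
        duration_s=duration,
        n_molecules=n_mol,
    )
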