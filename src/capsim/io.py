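"""Trajectory and topology I/O.

Coordinates travel as extended XYZ (one block per frame; the comment line
carries the elapsed time in tau and the box as a Lattice= triple), while
the constant topology — bonds, angles, frozen mask, species, molecule ids —
lives in a JSON sidecar.  A single-file HDF5 container with the same
schema is provided for larger runs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np

from .core import SPECIES, SPECIES_INDEX, SimulationBox, SimulationState


@dataclass
class Frame:
    """One trajectory frame as read back from extended XYZ."""

    positions: np.ndarray
    species: np.ndarray
    box: SimulationBox
    time: float


def write_xyz(path, state: SimulationState, append: bool = False) -> None:
    """Append one extended-XYZ frame for the current state."""
    e = state.box.edges
    lattice = f"{e[0]} 0.0 0.0 0.0 {e[1]} 0.0 0.0 0.0 {e[2]}"
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{state.n}\n")
        fh.write(
            f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 '
            f"Time={state.time:.6f}\n"
        )
        for s, p in zip(state.species, state.positions):
            fh.write(f"{SPECIES[s]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz(path) -> list[Frame]:
    """Read all frames of an extended-XYZ trajectory."""
    frames: list[Frame] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            m = re.search(r'Lattice="([^"]+)"', comment)
            cell = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
            tm = re.search(r"Time=([0-9eE+.\-]+)", comment)
            t = float(tm.group(1)) if tm else 0.0
            sp = np.empty(n, dtype=np.int64)
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                sp[i] = SPECIES_INDEX[parts[0]]
                pos[i] = [float(x) for x in parts[1:4]]
            frames.append(
                Frame(
                    positions=pos,
                    species=sp,
                    box=SimulationBox(edges=np.diag(cell)),
                    time=t,
                )
            )
    return frames


def write_topology(path, state: SimulationState) -> None:
    """JSON sidecar with the bond/angle network and per-bead labels."""
    doc = {
        "species": [SPECIES[s] for s in state.species],
        "bonds": state.bonds.tolist(),
        "angles": state.angles.tolist(),
        "frozen": state.frozen.astype(int).tolist(),
        "molecule": state.molecule.tolist(),
        "box": state.box.edges.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_topology(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        "species": np.array([SPECIES_INDEX[s] for s in doc["species"]], dtype=np.int64),
        "bonds": np.asarray(doc["bonds"], dtype=np.int64).reshape(-1, 2),
        "angles": np.asarray(doc["angles"], dtype=np.int64).reshape(-1, 3),
        "frozen": np.asarray(doc["frozen"], dtype=bool),
        "molecule": np.asarray(doc["molecule"], dtype=np.int64),
        "box": SimulationBox(edges=np.asarray(doc["box"], dtype=float)),
    }


def state_from_frame(frame: Frame, topology: dict) -> SimulationState:
    """Reassemble a SimulationState from a frame plus its topology sidecar."""
    return SimulationState(
        positions=frame.positions,
        velocities=np.zeros_like(frame.positions),
        species=frame.species,
        box=frame.box,
        bonds=topology["bonds"],
        angles=topology["angles"],
        frozen=topology["frozen"],
        molecule=topology["molecule"],
        time=frame.time,
    )


def save_hdf5(path, state: SimulationState, trajectory: np.ndarray | None = None,
              times: np.ndarray | None = None) -> None:
    """Single-file HDF5 container mirroring the XYZ + JSON schema."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["time"] = state.time
        h5.create_dataset("box", data=state.box.edges)
        h5.create_dataset("positions", data=state.positions)
        h5.create_dataset("velocities", data=state.velocities)
        h5.create_dataset("species", data=state.species)
        h5.create_dataset("bonds", data=state.bonds)
        h5.create_dataset("angles", data=state.angles)
        h5.create_dataset("frozen", data=state.frozen.astype(np.int8))
        h5.create_dataset("molecule", data=state.molecule)
        if trajectory is not None:
            h5.create_dataset("trajectory", data=trajectory)
            if times is not None:
                h5.create_dataset("times", data=times)


def load_hdf5(path) -> SimulationState:
    import h5py

    with h5py.File(path, "r") as h5:
        state = SimulationState(
            positions=h5["positions"][...],
            velocities=h5["velocities"][...],
            species=h5["species"][...],
            box=SimulationBox(edges=h5["box"][...]),
            bonds=h5["bonds"][...],
            angles=h5["angles"][...],
            frozen=h5["frozen"][...].astype(bool),
            molecule=h5["molecule"][...],
            time=float(h5.attrs["time"]),
        )
    return state
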