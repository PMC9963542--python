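"""Configuration loading and output writers (trajectory CSV, legacy-VTK
snapshots, JSON run summaries).

The config dialect is YAML with the blocks::

    scenario: focus | poiseuille | cavity | cylinder | sweep
    geometry: {width, ny, nx}                  # metres / node counts
    fluid:    {density, viscosity, compressibility, nu_lbm}
    particle: {type | (density, compressibility), radius}
    acoustic: {wavelength, energy_density | (voltage, a), phase_offset, active}
    flow:     {reynolds}
    numerics: {max_steps, steady_tolerance, steady_window, sample_every,
               stiffness, node_spacing, grid, re, lid_speed, diameter,
               re_values}
    sweep:    {parameter, values}
    initial:  {y}
    output:   {directory, snapshot_every}

Every writer embeds the full configuration echo so a run can be reproduced
from any of its outputs; the simulator contains no random number generation,
so re-running a configuration reproduces files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acoustics import AcousticConfig, WATER_COMPRESSIBILITY
from .exceptions import ConfigurationError, StabilityError
from .immersed_boundary import ParticleSpec, particle_from_library
from .lbm_core import LatticeState
from .scenarios import (ChannelConfig, DEFAULT_ENERGY_DENSITY, FocusingSetup,
                        Trajectory)

__all__ = ["RunConfig", "load_config", "write_trajectory", "read_trajectory",
           "write_snapshot", "read_snapshot", "write_summary"]

_SCENARIOS = ("focus", "sweep", "poiseuille", "cavity", "cylinder")


@dataclass
class RunConfig:
    """Validated run description assembled from the YAML blocks."""

    scenario: str
    channel: ChannelConfig
    particle: ParticleSpec | None
    acoustic: AcousticConfig | None
    numerics: dict
    initial_y: float | None
    sweep: dict | None
    output: dict
    raw: dict = field(default_factory=dict, repr=False)

    def focusing_setup(self) -> FocusingSetup:
        if self.scenario not in ("focus", "sweep"):
            raise ConfigurationError(
                f"scenario {self.scenario!r} has no focusing setup")
        num = self.numerics
        return FocusingSetup(
            particle=self.particle, acoustic=self.acoustic,
            channel=self.channel, initial_y=self.initial_y,
            max_steps=int(num.get("max_steps", 300000)),
            stiffness=float(num.get("stiffness", 0.0)),
            node_spacing=float(num.get("node_spacing", 0.65)),
            steady_tolerance=float(num.get("steady_tolerance", 0.5e-6)),
            steady_window=int(num.get("steady_window", 5000)),
            sample_every=int(num.get("sample_every", 100)),
            gravity=float(num.get("gravity", 0.0)),
        )


def _require(block: dict, key: str, block_name: str):
    if key not in block:
        raise ConfigurationError(f"missing required key '{block_name}.{key}'")
    return block[key]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    scenario = raw.get("scenario")
    if scenario not in _SCENARIOS:
        raise ConfigurationError(
            f"'scenario' must be one of {_SCENARIOS}, got {scenario!r}")

    geom = raw.get("geometry", {})
    fluid = raw.get("fluid", {})
    flow = raw.get("flow", {})
    numerics = dict(raw.get("numerics", {}))
    output = dict(raw.get("output", {}))

    nu_lbm = float(fluid.get("nu_lbm", 0.0167))
    if nu_lbm <= 0:
        raise StabilityError(
            "fluid.nu_lbm implies relaxation time tau <= 0.5 via the "
            "viscosity-relaxation relation nu = c_s^2 (tau - 1/2); the "
            "collision is unstable there"
        )
    channel = ChannelConfig(
        width=float(geom.get("width", 160e-6)),
        ny=int(geom.get("ny", 80)),
        nx=int(geom.get("nx", 24)),
        fluid_density=float(fluid.get("density", 1027.0)),
        nu_phys=float(fluid.get("viscosity", 1e-6)),
        nu_lbm=nu_lbm,
        reynolds=float(flow.get("reynolds", 0.70)),
    )
    mach = channel.reynolds * nu_lbm / channel.ny / (1.0 / np.sqrt(3.0))
    if mach >= 0.1:
        raise ConfigurationError(
            f"flow.reynolds gives lattice Mach {mach:.3f} >= 0.1; refine the "
            "grid or lower nu_lbm")

    particle = acoustic = None
    initial_y = None
    sweep_block = None
    if scenario in ("focus", "sweep"):
        pblock = raw.get("particle", {})
        radius = float(pblock.get("radius", 5e-6))
        if "type" in pblock:
            particle = particle_from_library(pblock["type"], radius)
        else:
            particle = ParticleSpec(
                radius=radius,
                density=float(pblock.get("density", 1050.0)),
                compressibility=float(pblock.get("compressibility", 2.49e-10)),
            )
        ablock = dict(raw.get("acoustic", {}))
        wavelength = float(_require(ablock, "wavelength", "acoustic"))
        kw = {}
        if "voltage" in ablock or "a" in ablock:
            kw["voltage"] = float(_require(ablock, "voltage", "acoustic"))
            kw["a"] = float(_require(ablock, "a", "acoustic"))
        else:
            kw["energy_density"] = float(
                ablock.get("energy_density", DEFAULT_ENERGY_DENSITY))
        acoustic = AcousticConfig(
            wavelength=wavelength,
            phase_offset=float(ablock.get("phase_offset", wavelength / 4.0)),
            active=bool(ablock.get("active", True)),
            fluid_density=channel.fluid_density,
            fluid_compressibility=float(
                fluid.get("compressibility", WATER_COMPRESSIBILITY)),
            **kw,
        )
        initial_y = float(_require(raw.get("initial", {}), "y", "initial"))
        if scenario == "sweep":
            sweep_block = dict(raw.get("sweep", {}))
            _require(sweep_block, "parameter", "sweep")
            _require(sweep_block, "values", "sweep")

    return RunConfig(scenario=scenario, channel=channel, particle=particle,
                     acoustic=acoustic, numerics=numerics,
                     initial_y=initial_y, sweep=sweep_block, output=output,
                     raw=raw)


# --------------------------------------------------------------------------
# trajectory CSV

def write_trajectory(traj: Trajectory, path) -> Path:
    """Write the trajectory as CSV with a config-echo comment header.

    Columns: time_s, x_um, y_um, uy_um_per_s, acoustic_force_N.  Output is
    deterministic for a fixed run.
    """
    if len(traj.times) == 0:
        raise ConfigurationError("refusing to write an empty trajectory")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(traj.meta)
    meta["settled"] = bool(traj.settled)
    meta["settle_time_s"] = traj.settle_time
    meta["steady_y_m"] = traj.steady_y
    meta["node_positions_m"] = traj.node_positions_m
    frame = pd.DataFrame({
        "time_s": traj.times,
        "x_um": traj.centroid_x * 1e6,
        "y_um": traj.centroid_y * 1e6,
        "uy_um_per_s": traj.centroid_velocity * 1e6,
        "acoustic_force_N": traj.applied_force,
    })
    with open(path, "w") as fh:
        fh.write("# acoustolbm trajectory\n")
        fh.write("# config: " + json.dumps(meta, sort_keys=True, default=float)
                 + "\n")
        frame.to_csv(fh, index=False, float_format="%.10e", lineterminator="\n")
    return path


def read_trajectory(path):
    """Read a trajectory CSV back as (DataFrame, meta dict)."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# config: "):
                meta = json.loads(line[len("# config: "):])
            elif not line.startswith("#"):
                break
    frame = pd.read_csv(path, comment="#")
    return frame, meta


# --------------------------------------------------------------------------
# legacy-VTK field snapshots

def write_snapshot(state: LatticeState, membrane=None, path="snapshot.vtk") -> Path:
    """Write density and velocity as a legacy-VTK structured-points file.

    When a membrane is given, its node coordinates go to a companion
    ``<stem>_membrane.vtk`` polydata point set.  Files load in any standard
    VTK viewer.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny = state.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("acoustolbm field snapshot\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write("ORIGIN 0 0 0\nSPACING 1 1 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        fh.write("SCALARS density double 1\nLOOKUP_TABLE default\n")
        for j in range(ny):  # x varies fastest in legacy VTK
            fh.write(" ".join(f"{state.rho[i, j]:.12e}" for i in range(nx)) + "\n")
        fh.write("VECTORS velocity double\n")
        for j in range(ny):
            fh.write(" ".join(
                f"{state.u[0, i, j]:.12e} {state.u[1, i, j]:.12e} 0.0"
                for i in range(nx)) + "\n")
    if membrane is not None:
        mpath = path.with_name(path.stem + "_membrane.vtk")
        with open(mpath, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("acoustolbm membrane nodes\n")
            fh.write("ASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {membrane.n_nodes} double\n")
            for x, y in membrane.nodes:
                fh.write(f"{x:.12e} {y:.12e} 0.0\n")
    return path


def read_snapshot(path):
    """Parse a snapshot written by :func:`write_snapshot`; returns (rho, u)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = next(l for l in lines if l.startswith("DIMENSIONS"))
    nx, ny, _ = (int(v) for v in dims.split()[1:])
    i_scal = lines.index(next(l for l in lines if l.startswith("SCALARS")))
    vals = []
    for line in lines[i_scal + 2:]:
        if line.startswith("VECTORS"):
            break
        vals.extend(float(v) for v in line.split())
    rho = np.array(vals).reshape(ny, nx).T
    i_vec = lines.index(next(l for l in lines if l.startswith("VECTORS")))
    vec = []
    for line in lines[i_vec + 1:]:
        if not line.strip():
            continue
        vec.extend(float(v) for v in line.split())
    vec = np.array(vec).reshape(ny, nx, 3)
    u = np.stack([vec[:, :, 0].T, vec[:, :, 1].T])
    return rho, u


def write_summary(summary: dict, path) -> Path:
    """JSON run summary (settle time, steady position, error norms, config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path
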