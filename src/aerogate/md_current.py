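"""Ionic current from framewise ion trajectories.

The instantaneous current between two consecutive trajectory snapshots is the
charge-weighted axial displacement of the ions inside the pore lumen,

    I(t) = (1 / (dt * L_p)) * sum_ion Q_ion [z_ion(t + dt) - z_ion(t)],

with dt the snapshot interval (0.2 ns by default) and L_p the barrel length
(9 nm for aerolysin).  An ion that crosses the whole lumen therefore transfers
exactly one elementary charge: I * T = e per translocation.  The average
current of a trajectory is the slope of a linear regression of the cumulative
transferred charge against time, which is robust to the large frame-to-frame
fluctuations of I(t).

A drift-diffusion trajectory generator provides an analytic validation target:
N ions of charge Q drifting at velocity v through a lumen of length L_p carry
an average current N Q v / L_p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .constants import ELEMENTARY_CHARGE, NM


class TrajectoryError(ValueError):
    """Malformed ion trajectory."""


@dataclass
class Frame:
    """One trajectory snapshot: parallel arrays over ions."""

    ion_id: np.ndarray  # int
    charge_e: np.ndarray  # elementary charges
    z_nm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ion_id)
        if not (len(self.charge_e) == len(self.z_nm) == n):
            raise TrajectoryError("frame arrays must have equal length")
        self.ion_id = np.asarray(self.ion_id, np.int64)
        self.charge_e = np.asarray(self.charge_e, float)
        self.z_nm = np.asarray(self.z_nm, float)


@dataclass
class IonTrajectory:
    """Framewise ion positions for the displacement-current estimator."""

    frames: list[Frame]
    frame_interval_s: float = 0.2e-9
    pore_length_nm: float = 9.0
    lumen_bounds_nm: tuple[float, float] = (0.0, 9.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.pore_length_nm <= 0:
            raise TrajectoryError("frame interval and pore length must be positive")
        if self.lumen_bounds_nm[0] >= self.lumen_bounds_nm[1]:
            raise TrajectoryError("lumen bounds must be ordered")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


InclusionRule = Literal["start", "both"]


def instantaneous_current(
    traj: IonTrajectory, frame_index: int, inclusion: InclusionRule = "start"
) -> float:
    """Displacement current (A) between frames ``t`` and ``t+1``.

    Ions are counted when inside the lumen bounds at frame ``t`` (rule
    "start") or at both frames (rule "both"); ions absent from either frame
    contribute nothing.
    """
    if frame_index < 0 or frame_index + 1 >= traj.n_frames:
        raise TrajectoryError("frame has no successor")
    f0, f1 = traj.frames[frame_index], traj.frames[frame_index + 1]
    common, i0, i1 = np.intersect1d(f0.ion_id, f1.ion_id, return_indices=True)
    if common.size == 0:
        return 0.0
    z0, z1 = f0.z_nm[i0], f1.z_nm[i1]
    lo, hi = traj.lumen_bounds_nm
    inside = (z0 >= lo) & (z0 <= hi)
    if inclusion == "both":
        inside &= (z1 >= lo) & (z1 <= hi)
    q = f0.charge_e[i0]
    total = float(np.sum(q[inside] * (z1[inside] - z0[inside])))
    return ELEMENTARY_CHARGE * total / (traj.frame_interval_s * traj.pore_length_nm)


def current_series(traj: IonTrajectory, inclusion: InclusionRule = "start") -> np.ndarray:
    """I(t) for every consecutive frame pair."""
    return np.array(
        [instantaneous_current(traj, k, inclusion) for k in range(traj.n_frames - 1)]
    )


def average_current(traj: IonTrajectory, inclusion: InclusionRule = "start",
                    equilibration_s: float = 0.0) -> float:
    """Average current (A): regression slope of cumulative charge vs time.

    The cumulative sum of I(t) dt (transferred charge, C) is regressed against
    time; the slope is the mean current.  ``equilibration_s`` discards the
    initial part of the trajectory before the regression.
    """
    if traj.n_frames < 11:
        raise TrajectoryError("need at least 10 current samples")
    i = current_series(traj, inclusion)
    t = (np.arange(i.size) + 1) * traj.frame_interval_s
    keep = t > equilibration_s
    if np.count_nonzero(keep) < 10:
        raise TrajectoryError("fewer than 10 samples after equilibration trim")
    charge = np.cumsum(i * traj.frame_interval_s)[keep]
    tt = t[keep]
    if tt[-1] == tt[0]:
        raise TrajectoryError("degenerate time axis")
    return float(linregress(tt, charge).slope)


def synth_trajectory(
    n_cations: int,
    n_anions: int,
    drift_cation_nm_ns: float,
    drift_anion_nm_ns: float,
    diffusion_nm2_ns: float,
    n_frames: int,
    seed: int | np.random.Generator = 0,
    frame_interval_s: float = 0.2e-9,
    pore_length_nm: float = 9.0,
    lumen_bounds_nm: tuple[float, float] = (0.0, 9.0),
) -> IonTrajectory:
    """Biased-random-walk ion trajectory with steady-state reinjection.

    Ions perform 1D drift-diffusion walks on a domain extending one pore
    length beyond each lumen bound.  An ion leaving the domain is reinjected
    at the opposite end under a fresh ion id, so wrap-around jumps never enter
    the displacement sum while the ion density stays stationary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = lumen_bounds_nm
    z_min, z_max = lo - pore_length_nm, hi + pore_length_nm
    span = z_max - z_min
    n = n_cations + n_anions
    charge = np.concatenate([np.ones(n_cations), -np.ones(n_anions)])
    drift = np.concatenate(
        [np.full(n_cations, drift_cation_nm_ns), np.full(n_anions, drift_anion_nm_ns)]
    )
    dt_ns = frame_interval_s * 1e9
    sigma = np.sqrt(2.0 * diffusion_nm2_ns * dt_ns)
    z = rng.uniform(z_min, z_max, size=n)
    ids = np.arange(n, dtype=np.int64)
    next_id = n
    frames = [Frame(ids.copy(), charge.copy(), z.copy())]
    for _ in range(n_frames - 1):
        z = z + drift * dt_ns
        if sigma > 0:
            z = z + rng.normal(0.0, sigma, size=n)
        out_hi = z > z_max
        out_lo = z < z_min
        for out in (out_hi, out_lo):
            k = int(np.count_nonzero(out))
            if k:
                ids[out] = next_id + np.arange(k)
                next_id += k
        z[out_hi] -= span
        z[out_lo] += span
        frames.append(Frame(ids.copy(), charge.copy(), z.copy()))
    return IonTrajectory(
        frames=frames, frame_interval_s=frame_interval_s,
        pore_length_nm=pore_length_nm, lumen_bounds_nm=lumen_bounds_nm,
        metadata={"generator": "synth_trajectory", "n_cations": n_cations,
                  "n_anions": n_anions, "drift_cation_nm_ns": drift_cation_nm_ns,
                  "drift_anion_nm_ns": drift_anion_nm_ns,
                  "diffusion_nm2_ns": diffusion_nm2_ns},
    )


def mean_lumen_occupancy(traj: IonTrajectory, charge_sign: int | None = None) -> float:
    """Average number of (optionally sign-selected) ions inside the lumen."""
    lo, hi = traj.lumen_bounds_nm
    counts = []
    for f in traj.frames:
        inside = (f.z_nm >= lo) & (f.z_nm <= hi)
        if charge_sign is not None:
            inside &= np.sign(f.charge_e) == charge_sign
        counts.append(np.count_nonzero(inside))
    return float(np.mean(counts))


def write_trajectory(traj: IonTrajectory, path: str | Path) -> Path:
    """Write a trajectory as TSV (frame, ion_id, charge_e, z_nm) + JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "frame_interval_s": traj.frame_interval_s,
        "pore_length_nm": traj.pore_length_nm,
        "lumen_bounds_nm": list(traj.lumen_bounds_nm),
        **traj.metadata,
    }
    rows = []
    for k, f in enumerate(traj.frames):
        rows.append(pd.DataFrame({"frame": k, "ion_id": f.ion_id,
                                  "charge_e": f.charge_e, "z_nm": f.z_nm}))
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, sep="\t", index=False,
                                                  float_format="%.6f")
    return path


def read_trajectory(path: str | Path) -> IonTrajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise TrajectoryError("missing JSON header line")
        header = json.loads(first[2:])
        df = pd.read_csv(fh, sep="\t")
    frames = [
        Frame(g["ion_id"].to_numpy(), g["charge_e"].to_numpy(), g["z_nm"].to_numpy())
        for _, g in df.groupby("frame", sort=True)
    ]
    meta = {k: v for k, v in header.items()
            if k not in ("frame_interval_s", "pore_length_nm", "lumen_bounds_nm")}
    return IonTrajectory(
        frames=frames,
        frame_interval_s=header["frame_interval_s"],
        pore_length_nm=header["pore_length_nm"],
        lumen_bounds_nm=tuple(header["lumen_bounds_nm"]),
        metadata=meta,
    )
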