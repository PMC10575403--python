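"""CSV readers/writers for the trial and result file dialects.

Columns:
    IMU    : t, ax, ay, az, gx, gy, gz
    GRF    : t, vgrf
    truth  : t, theta_true, phase_true_pct
    phase  : t, phi_rad, phi_comp_rad, phi_pct, stride_id, converged
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from gaitphase.engine import PhaseStreamResult
from gaitphase.synthetic import SyntheticTrial

__all__ = [
    "write_imu_csv",
    "read_imu_csv",
    "write_grf_csv",
    "read_grf_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_phase_csv",
    "read_phase_csv",
    "write_trial",
]

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def write_imu_csv(path, t, accel, gyro) -> None:
    df = pd.DataFrame(
        np.column_stack([t, accel, gyro]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False)


def read_imu_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    missing = set(IMU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IMU CSV missing columns: {sorted(missing)}")
    return (
        df["t"].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(),
        df[["gx", "gy", "gz"]].to_numpy(),
    )


def write_grf_csv(path, t, vgrf) -> None:
    pd.DataFrame({"t": t, "vgrf": vgrf}).to_csv(path, index=False)


def read_grf_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["t"].to_numpy(), df["vgrf"].to_numpy()


def write_truth_csv(path, t, theta_true, phase_true_pct) -> None:
    pd.DataFrame(
        {"t": t, "theta_true": theta_true, "phase_true_pct": phase_true_pct}
    ).to_csv(path, index=False)


def read_truth_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df["t"].to_numpy(),
        df["theta_true"].to_numpy(),
        df["phase_true_pct"].to_numpy(),
    )


def write_phase_csv(path, result: PhaseStreamResult) -> None:
    result.to_frame().to_csv(path, index=False)


def read_phase_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trial(outdir, trial: SyntheticTrial, stem: str = "trial") -> dict:
    """Write a synthetic trial's IMU, GRF and truth CSVs into ``outdir``.

    Returns the mapping of written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "imu": outdir / f"{stem}_imu.csv",
        "grf": outdir / f"{stem}_grf.csv",
        "truth": outdir / f"{stem}_truth.csv",
    }
    write_imu_csv(paths["imu"], trial.t, trial.accel, trial.gyro)
    write_grf_csv(paths["grf"], trial.t, trial.vgrf)
    write_truth_csv(paths["truth"], trial.t, trial.theta_true, trial.phase_true_pct)
    return paths
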