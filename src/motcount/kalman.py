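"""Constant-velocity Kalman filter over box state (cx, cy, aspect, height).

The 8-dimensional state holds the box center, aspect ratio (w/h), height,
and their per-frame velocities.  Process and observation noise are scaled
by the box height, and gating uses the squared Mahalanobis distance of a
candidate measurement against the predicted measurement distribution; the
0.95 chi-square quantile for 4 degrees of freedom (9.4877) is the default
gate.  The parameterisation and noise weights follow the standard
tracking-by-detection reference design and are overridable per filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .geometry import BoundingBox

__all__ = ["KalmanTrackState", "ConstantVelocityKalman", "CHI2_GATE_4DOF"]

# 0.95 quantile of chi-square with 4 degrees of freedom
CHI2_GATE_4DOF = 9.4877


@dataclass(frozen=True)
class KalmanTrackState:
    """Gaussian state estimate: 8-vector mean and 8x8 covariance."""

    mean: np.ndarray
    covariance: np.ndarray
    frame_of_last_update: int = 0

    def __post_init__(self) -> None:
        if self.mean.shape != (8,) or self.covariance.shape != (8, 8):
            raise ValueError("state must be an 8-vector mean with 8x8 covariance")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.covariance).all()):
            raise ValueError("non-finite Kalman state")

    def to_box(self) -> BoundingBox:
        cx, cy, a, h = self.mean[:4]
        return BoundingBox.from_xyah(cx, cy, a, h)


class ConstantVelocityKalman:
    """Shared filter model; states are immutable and passed explicitly."""

    def __init__(
        self,
        std_weight_position: float = 1.0 / 20,
        std_weight_velocity: float = 1.0 / 160,
    ) -> None:
        self._std_pos = std_weight_position
        self._std_vel = std_weight_velocity
        self._F = np.eye(8)
        self._F[:4, 4:] = np.eye(4)  # dt = 1 frame
        self._H = np.eye(4, 8)

    def initiate(self, box: BoundingBox, frame: int = 0) -> KalmanTrackState:
        """New track state from an unassociated detection; zero velocity."""
        cx, cy, a, h = box.to_xyah()
        mean = np.array([cx, cy, a, h, 0.0, 0.0, 0.0, 0.0])
        std = np.array(
            [
                2 * self._std_pos * h,
                2 * self._std_pos * h,
                1e-2,
                2 * self._std_pos * h,
                10 * self._std_vel * h,
                10 * self._std_vel * h,
                1e-5,
                10 * self._std_vel * h,
            ]
        )
        return KalmanTrackState(mean, np.diag(std**2), frame)

    def predict(self, state: KalmanTrackState) -> KalmanTrackState:
        """Advance one frame under constant velocity; inflate covariance."""
        h = state.mean[3]
        std = np.array(
            [
                self._std_pos * h,
                self._std_pos * h,
                1e-2,
                self._std_pos * h,
                self._std_vel * h,
                self._std_vel * h,
                1e-5,
                self._std_vel * h,
            ]
        )
        Q = np.diag(std**2)
        mean = self._F @ state.mean
        # extrapolating a shrinking box far beyond its last update can drive
        # aspect or height non-positive; clamp to keep the box well-defined
        mean[2] = max(mean[2], 1e-3)
        mean[3] = max(mean[3], 1.0)
        cov = self._F @ state.covariance @ self._F.T + Q
        cov = (cov + cov.T) / 2.0
        return KalmanTrackState(mean, cov, state.frame_of_last_update)

    def project(self, state: KalmanTrackState) -> tuple[np.ndarray, np.ndarray]:
        """Predicted measurement distribution (4-vector mean, 4x4 covariance)."""
        h = state.mean[3]
        std = np.array([self._std_pos * h, self._std_pos * h, 1e-1, self._std_pos * h])
        R = np.diag(std**2)
        mean = self._H @ state.mean
        cov = self._H @ state.covariance @ self._H.T + R
        return mean, (cov + cov.T) / 2.0

    def update(
        self, state: KalmanTrackState, box: BoundingBox, frame: int | None = None
    ) -> KalmanTrackState:
        """Condition the state on an associated detection box."""
        proj_mean, proj_cov = self.project(state)
        try:
            chol, lower = scipy.linalg.cho_factor(proj_cov, check_finite=False)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(f"singular innovation covariance: {exc}") from exc
        K = scipy.linalg.cho_solve(
            (chol, lower), (state.covariance @ self._H.T).T, check_finite=False
        ).T
        z = np.asarray(box.to_xyah())
        mean = state.mean + K @ (z - proj_mean)
        cov = state.covariance - K @ proj_cov @ K.T
        cov = (cov + cov.T) / 2.0
        new_frame = state.frame_of_last_update + 1 if frame is None else frame
        return KalmanTrackState(mean, cov, new_frame)

    def gating_distance(
        self, state: KalmanTrackState, boxes: Sequence[BoundingBox]
    ) -> np.ndarray:
        """Squared Mahalanobis distance from each box to the projected state."""
        if len(boxes) == 0:
            return np.empty(0)
        proj_mean, proj_cov = self.project(state)
        z = np.array([b.to_xyah() for b in boxes])
        d = z - proj_mean
        chol = np.linalg.cholesky(proj_cov)
        y = scipy.linalg.solve_triangular(
            chol, d.T, lower=True, check_finite=False
        )
        return np.sum(y * y, axis=0)
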