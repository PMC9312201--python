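"""Constant-velocity Kalman filter over the 8-dimensional box motion state.

The state stacks the measurement (u, v, gamma, h) — box center, aspect
ratio, height — with its per-frame velocities (du, dv, dgamma, dh).  The
transition is the standard constant-velocity model with a fixed time step
of one frame; the observation model is linear and selects the first four
components.

Noise is parameterized relative to the current box height h: position-like
standard deviations are ``pos_weight * h`` (default 1/20) and velocity-like
ones ``vel_weight * h`` (default 1/160).  The dimensionless aspect-ratio
terms use small fixed standard deviations instead of the h-proportional
ones, since scaling a ratio of order one by a pixel height would drown the
signal.  All weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import NumericalError
from .geometry import MeasurementVec

__all__ = ["KalmanState", "KalmanFilter", "GATING_DIM"]

#: dimensionality of the measurement space (u, v, gamma, h)
GATING_DIM = 4


@dataclass(frozen=True)
class KalmanState:
    """Gaussian belief over the 8-dim motion state: mean vector and covariance."""

    mean: np.ndarray  # shape (8,)
    covariance: np.ndarray  # shape (8, 8), symmetric PSD

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (8,) or cov.shape != (8, 8):
            raise ValueError("KalmanState is 8-dimensional")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def measurement(self) -> MeasurementVec:
        """The (u, v, gamma, h) part of the mean — the predicted box."""
        u, v, g, h = self.mean[:4]
        return MeasurementVec(u=u, v=v, gamma=g, h=h)


class KalmanFilter:
    """Shared filter model; states are passed in and returned functionally."""

    def __init__(self, pos_weight: float = 1.0 / 20, vel_weight: float = 1.0 / 160):
        self.pos_weight = pos_weight
        self.vel_weight = vel_weight
        self._F = np.eye(8)
        self._F[:4, 4:] = np.eye(4)
        self._H = np.eye(4, 8)

    # -- noise scales -------------------------------------------------------

    def _initiate_std(self, h: float) -> np.ndarray:
        wp, wv = self.pos_weight, self.vel_weight
        return np.array(
            [2 * wp * h, 2 * wp * h, 1e-2, 2 * wp * h,
             10 * wv * h, 10 * wv * h, 1e-5, 10 * wv * h]
        )

    def _process_std(self, h: float) -> np.ndarray:
        wp, wv = self.pos_weight, self.vel_weight
        return np.array(
            [wp * h, wp * h, 1e-2, wp * h, wv * h, wv * h, 1e-5, wv * h]
        )

    def _measurement_std(self, h: float) -> np.ndarray:
        wp = self.pos_weight
        return np.array([wp * h, wp * h, 1e-1, wp * h])

    # -- filter steps -------------------------------------------------------

    def initiate(self, m: MeasurementVec) -> KalmanState:
        """Birth a track from one measurement: zero velocity, h-scaled spread."""
        mean = np.concatenate([m.as_array(), np.zeros(4)])
        cov = np.diag(self._initiate_std(m.h) ** 2)
        return KalmanState(mean, cov)

    def predict(self, s: KalmanState) -> KalmanState:
        """Propagate one frame under constant velocity; covariance grows by Q."""
        q = np.diag(self._process_std(s.mean[3]) ** 2)
        mean = self._F @ s.mean
        cov = self._F @ s.covariance @ self._F.T + q
        return KalmanState(mean, cov)

    def project(self, s: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Project the belief into measurement space: (H x, H P H' + R)."""
        r = np.diag(self._measurement_std(s.mean[3]) ** 2)
        return self._H @ s.mean, self._H @ s.covariance @ self._H.T + r

    def update(self, s: KalmanState, m: MeasurementVec) -> KalmanState:
        """Standard Kalman correction with the linear observation model."""
        proj_mean, proj_cov = self.project(s)
        try:
            chol = scipy.linalg.cho_factor(proj_cov, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError("innovation covariance not positive definite") from exc
        # K = P H' S^-1, solved via the Cholesky factor of S
        gain = scipy.linalg.cho_solve(
            chol, (s.covariance @ self._H.T).T, check_finite=False
        ).T
        innovation = m.as_array() - proj_mean
        mean = s.mean + gain @ innovation
        cov = s.covariance - gain @ proj_cov @ gain.T
        cov = (cov + cov.T) / 2.0  # enforce symmetry against round-off
        return KalmanState(mean, cov)

    def gating_distance(
        self, s: KalmanState, ms: list[MeasurementVec] | np.ndarray
    ) -> np.ndarray:
        """Squared Mahalanobis distance of measurements under the projected belief."""
        proj_mean, proj_cov = self.project(s)
        if isinstance(ms, np.ndarray):
            arr = np.atleast_2d(np.asarray(ms, dtype=float))
        else:
            arr = np.array([m.as_array() for m in ms], dtype=float).reshape(-1, 4)
        if arr.size == 0:
            return np.zeros(0)
        try:
            chol = scipy.linalg.cholesky(proj_cov, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError("innovation covariance is singular") from exc
        z = scipy.linalg.solve_triangular(
            chol, (arr - proj_mean).T, lower=True, check_finite=False
        )
        return np.sum(z * z, axis=0)
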