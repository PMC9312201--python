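"""Independent reference implementations used to cross-check the package.

These are deliberately written with explicit matrix algebra and exhaustive
enumeration, sharing no code with the production paths they verify.
"""

import itertools

import numpy as np

POS_W, VEL_W = 1.0 / 20, 1.0 / 160


def kalman_matrices(h):
    """Transition/observation/noise matrices of the constant-velocity model."""
    F = np.eye(8)
    for i in range(4):
        F[i, 4 + i] = 1.0
    H = np.zeros((4, 8))
    for i in range(4):
        H[i, i] = 1.0
    q_std = np.array(
        [POS_W * h, POS_W * h, 1e-2, POS_W * h,
         VEL_W * h, VEL_W * h, 1e-5, VEL_W * h]
    )
    r_std = np.array([POS_W * h, POS_W * h, 1e-1, POS_W * h])
    return F, H, np.diag(q_std**2), np.diag(r_std**2)


def kalman_predict(mean, cov):
    F, _, Q, _ = kalman_matrices(mean[3])
    return F @ mean, F @ cov @ F.T + Q


def kalman_update(mean, cov, z):
    _, H, _, R = kalman_matrices(mean[3])
    S = H @ cov @ H.T + R
    K = cov @ H.T @ np.linalg.inv(S)
    return mean + K @ (z - H @ mean), (np.eye(8) - K @ H) @ cov


def min_cost_permutation(costs):
    """Exhaustive search for the minimum-total-cost full square assignment."""
    n = costs.shape[0]
    return min(
        sum(costs[i, p[i]] for i in range(n))
        for p in itertools.permutations(range(n))
    )
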