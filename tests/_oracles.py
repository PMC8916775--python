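"""Independent reference implementations used only to check the package.

These are deliberately written with explicit loops and textbook formulas,
sharing no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
import scipy.special


def geweke_gc_oracle(
    coef: np.ndarray, cov: np.ndarray, freqs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain Granger causality from known VAR parameters.

    Returns (gc_x_to_y, gc_y_to_x) evaluated frequency by frequency with
    explicit matrix inversions.
    """
    p = coef.shape[0]
    out_xy, out_yx = [], []
    for f in freqs:
        a_f = np.eye(2, dtype=complex)
        for k in range(p):
            a_f -= coef[k] * np.exp(-2j * np.pi * f * (k + 1) / fs)
        h = np.linalg.inv(a_f)
        s = h @ cov @ h.conj().T
        sxx, syy = s[0, 0].real, s[1, 1].real
        cov_yy_partial = cov[1, 1] - cov[0, 1] ** 2 / cov[0, 0]
        cov_xx_partial = cov[0, 0] - cov[0, 1] ** 2 / cov[1, 1]
        out_yx.append(np.log(sxx / (sxx - cov_yy_partial * abs(h[0, 1]) ** 2)))
        out_xy.append(np.log(syy / (syy - cov_xx_partial * abs(h[1, 0]) ** 2)))
    return np.asarray(out_xy), np.asarray(out_yx)


def brute_force_crossing(
    params: dict[str, float],
    threshold: float,
    window_ms: tuple[float, float] = (0.0, 200.0),
    grid_ms: float = 0.1,
) -> float:
    """First grid time where the transient model exceeds threshold (NaN if never).

    Evaluates the model with its own arithmetic (no shared code).
    """
    t = np.arange(window_ms[0], window_ms[1] + grid_ms / 2, grid_ms)
    r = np.zeros_like(t)
    for i in (1, 2):
        g, mu, sig = params[f"G{i}"], params[f"mu{i}"], params[f"sigma{i}"]
        r += g / (np.sqrt(2 * np.pi) * sig) * np.exp(-((t - mu) ** 2) / (2 * sig**2))
    r += 0.5 * params["G3"] * (
        1 + scipy.special.erf((t - params["mu3"]) / (np.sqrt(2) * params["sigma3"]))
    )
    hits = np.where(r > threshold)[0]
    return float(t[hits[0]]) if hits.size else float("nan")


def bh_adjust_by_hand(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjustment, textbook loop version."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj
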