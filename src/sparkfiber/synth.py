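"""Synthetic spatiotemporal J_RyR profiles with controlled statistics.

Spontaneous SR Ca2+ release is, to good approximation, an independent
stochastic process in each cell of a fiber.  The generator emulates that
structure directly: each interior cell receives one double-exponential
release pulse with independently drawn onset time and amplitude on top of a
small baseline leak; boundary-buffer cells carry baseline only.  An
optional coupling parameter mixes a shared onset into all cells to build
alternative-hypothesis fixtures for the independence diagnostics.

The companion surrogate constructs per-cell V_max as an exact affine
function of the width-W filtered flux maxima, giving ground truth on which
the filter-fitting machinery must recover W exactly with r^2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rare_events import FluxMatrix, jf_max, spatial_filter

__all__ = ["SyntheticProfileParams", "generate_profiles",
           "analytic_vmax_surrogate"]


@dataclass
class SyntheticProfileParams:
    """Statistical description of one synthetic fiber realization.

    The onset-time SD default (178 ms) matches the observed single-cell
    variability of the delay until the spontaneous-release peak at the
    lowest SR load; amplitudes are truncated at zero.
    """

    n_cells: int = 96
    n_times: int = 400
    dt: float = 5.0                 # ms between columns
    boundary_buffer: int = 24       # quiescent cells per end
    onset_mean: float = 700.0       # ms
    onset_sd: float = 178.0         # ms
    amplitude_mean: float = 0.9     # uM/ms whole-cell peak release flux
    amplitude_sd: float = 0.25      # uM/ms
    rise_tau: float = 20.0          # ms
    decay_tau: float = 100.0        # ms
    baseline: float = 0.002         # uM/ms leak floor
    coupling: float = 0.0           # 0 = independent, 1 = shared onset
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_times", "dt", "onset_sd",
                     "amplitude_mean", "rise_tau", "decay_tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.n_cells <= 2 * self.boundary_buffer:
            raise ValueError("n_cells must exceed 2 * boundary_buffer")


def _pulse(t, onset, rise_tau, decay_tau):
    """Unit-peak double-exponential pulse starting at ``onset``."""
    x = t[None, :] - onset[:, None]
    shape = np.where(x > 0,
                     np.exp(-x / decay_tau) * (1.0 - np.exp(-x / rise_tau)),
                     0.0)
    tpk = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = np.exp(-tpk / decay_tau) * (1.0 - np.exp(-tpk / rise_tau))
    return shape / peak


def generate_profiles(params: SyntheticProfileParams,
                      rng=None) -> FluxMatrix:
    """Draw one synthetic fiber J_RyR profile.

    Interior cells get independent pulses; with ``coupling`` > 0 each onset
    is the mix  c * shared + (1 - c) * independent  of a fiber-wide shared
    draw and the cell's own draw, so coupling = 1 synchronizes all cells.
    Reproducible from ``params.seed`` (or an explicit generator).
    """
    p = params
    if rng is None:
        rng = np.random.default_rng(p.seed)
    t = np.arange(p.n_times) * p.dt
    interior = np.zeros(p.n_cells, dtype=bool)
    interior[p.boundary_buffer:p.n_cells - p.boundary_buffer] = True
    n_int = int(interior.sum())
    own = rng.normal(p.onset_mean, p.onset_sd, size=n_int)
    shared = rng.normal(p.onset_mean, p.onset_sd)
    onsets = p.coupling * shared + (1.0 - p.coupling) * own
    amps = np.maximum(rng.normal(p.amplitude_mean, p.amplitude_sd,
                                 size=n_int), 0.0)
    values = np.full((p.n_cells, p.n_times), p.baseline, dtype=float)
    values[interior] += amps[:, None] * _pulse(t, onsets, p.rise_tau,
                                               p.decay_tau)
    return FluxMatrix(values=values, dt=p.dt, interior=interior)


def analytic_vmax_surrogate(j: FluxMatrix, true_w: int, gain: float,
                            offset: float, noise_sd: float = 0.0,
                            rng=None) -> np.ndarray:
    """Ground-truth per-cell V_max that is affine in J^f_max at ``true_w``.

    v_max = offset + gain * J^f_max(true_w) (+ optional Gaussian noise).
    With zero noise the filter fit must recover ``true_w`` with r^2 = 1;
    with gain 0 the fit is degenerate by construction.
    """
    if true_w % 2 == 0 or true_w < 1:
        raise ValueError("true_w must be an odd integer >= 1")
    jm = jf_max(spatial_filter(j, true_w))
    v = offset + gain * jm
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return v
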