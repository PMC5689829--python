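"""Stochastic Markov-chain gating of Ca2+ release channels.

Each release site holds a cluster of 48 ryanodine receptors (RyRs) and 8
L-type Ca2+ channels (LCCs).  RyRs follow a minimal two-state (closed/open)
chain whose opening rate depends on dyadic [Ca2+] with Hill coefficient eta
and is modulated by junctional-SR [Ca2+] through the luminal regulation term

    phi(ca_jsr) = phi_offset + (ca_jsr / jsr_ref) ** phi_exponent
    r_o = opening_scale * phi * k_plus * ca_ss ** eta

The closing rate is Ca2+-independent, r_c = 1 / mean_open_time.

LCCs use a reduced 4-state chain (closed, open, voltage-inactivated,
Ca-inactivated) with Boltzmann voltage activation and a Ca-dependent
inactivation rate that saturates in dyadic [Ca2+].  Channels are split into
gating and silent pools; a configurable fraction gates in a high-activity
mode with a longer mean open time (0.5 ms -> 5.8 ms under beta-adrenergic
stimulation).

All stepping kernels operate on integer occupancy-count arrays of arbitrary
shape so that a whole lattice (or a fiber of lattices) is advanced in single
vectorized calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GatingParams",
    "RyRClusterState",
    "LCC_CLOSED",
    "LCC_OPEN",
    "LCC_VINACT",
    "LCC_CAINACT",
    "ryr_opening_rate",
    "ryr_stationary_open_prob",
    "step_ryr_cluster",
    "step_ryr_counts",
    "step_lcc_counts",
    "step_lcc_channels",
    "lcc_activation_rate",
    "lcc_ca_inactivation_rate",
    "assign_lcc_pools",
]

# Maximum per-substep transition probability mass for the multi-state LCC
# kernel, which subdivides dt so that max(rate) * dt_sub <= RATE_DT_CAP.
# (The two-state RyR kernel uses the exact propagator and needs no substeps.)
RATE_DT_CAP = 0.1

LCC_CLOSED, LCC_OPEN, LCC_VINACT, LCC_CAINACT = 0, 1, 2, 3


@dataclass
class GatingParams:
    """Rate constants for RyR cluster and reduced LCC gating.

    Units: rates in ms^-1, concentrations in uM (dyadic) / mM (JSR),
    voltages in mV.
    """

    # --- RyR two-state chain ---
    k_plus: float = 1.107e-4      # ms^-1 uM^-eta, opening rate constant
    eta: float = 2.1              # dyadic Ca2+ Hill coefficient
    mean_open_time: float = 2.0   # ms; closing rate r_c = 0.5 ms^-1
    jsr_ref: float = 1.5          # mM, luminal-regulation reference load
    phi_offset: float = 0.8025
    phi_exponent: float = 4.0
    opening_scale: float = 1.0    # protocol ramps / beta-AR 1.5x or 4x

    # --- LCC reduced 4-state chain ---
    n_lcc: int = 8
    lcc_gating_fraction: float = 0.25       # beta-AR raises to 0.60
    lcc_high_fraction: float = 0.0          # beta-AR: 0.03-0.05 (default 0.04)
    lcc_mean_open_time: float = 0.5         # ms (normal mode)
    lcc_mean_open_time_high: float = 5.8    # ms (high-activity mode)
    lcc_act_rate: float = 8.0               # ms^-1, max C->O rate
    lcc_act_vhalf: float = 27.0             # mV  (calibrated: ECC gain)
    lcc_act_slope: float = 4.5              # mV
    lcc_ci_rate_max: float = 0.30           # ms^-1, saturating Ca inactivation
    lcc_ci_kd: float = 12.0                 # uM dyadic Ca2+
    lcc_ci_recovery: float = 0.006          # ms^-1, CI -> C
    lcc_vi_rate: float = 0.002              # ms^-1, max C -> VI
    lcc_vi_vhalf: float = -35.0             # mV
    lcc_vi_slope: float = 6.0               # mV
    lcc_vi_recovery: float = 0.024          # ms^-1, VI -> C at rest

    @property
    def r_c(self) -> float:
        """RyR closing rate, ms^-1."""
        return 1.0 / self.mean_open_time

    def validate(self) -> None:
        positive = {
            "k_plus": self.k_plus, "eta": self.eta,
            "mean_open_time": self.mean_open_time, "jsr_ref": self.jsr_ref,
            "phi_offset": self.phi_offset, "phi_exponent": self.phi_exponent,
            "opening_scale": self.opening_scale,
            "lcc_mean_open_time": self.lcc_mean_open_time,
            "lcc_mean_open_time_high": self.lcc_mean_open_time_high,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"GatingParams.{name} must be > 0, got {value}")
        if not 0.0 <= self.lcc_gating_fraction <= 1.0:
            raise ValueError("lcc_gating_fraction must lie in [0, 1]")
        if not 0.0 <= self.lcc_high_fraction <= 1.0:
            raise ValueError("lcc_high_fraction must lie in [0, 1]")


@dataclass
class RyRClusterState:
    """Occupancy of one RyR cluster (or an array of clusters)."""

    n_open: np.ndarray | int
    n_total: int = 48

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if np.any(np.asarray(self.n_open) < 0) or np.any(
            np.asarray(self.n_open) > self.n_total
        ):
            raise ValueError("n_open must satisfy 0 <= n_open <= n_total")


def _check_nonnegative(name, value):
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be nonnegative")


def ryr_opening_rate(ca_ss, ca_jsr, params: GatingParams):
    """Per-channel RyR opening rate r_o (ms^-1).

    Parameters
    ----------
    ca_ss : dyadic subspace [Ca2+], uM (scalar or array)
    ca_jsr : junctional SR [Ca2+], mM
    params : GatingParams
    """
    _check_nonnegative("ca_ss", ca_ss)
    _check_nonnegative("ca_jsr", ca_jsr)
    ca_ss = np.asarray(ca_ss, dtype=float)
    ca_jsr = np.asarray(ca_jsr, dtype=float)
    phi = params.phi_offset + (ca_jsr / params.jsr_ref) ** params.phi_exponent
    return params.opening_scale * phi * params.k_plus * ca_ss ** params.eta


def ryr_stationary_open_prob(ca_ss, ca_jsr, params: GatingParams):
    """Stationary open probability r_o / (r_o + r_c) of the two-state chain."""
    r_o = ryr_opening_rate(ca_ss, ca_jsr, params)
    return r_o / (r_o + params.r_c)


def _n_substeps(max_rate: float, dt: float) -> int:
    if max_rate <= 0:
        return 1
    return max(1, int(np.ceil(max_rate * dt / RATE_DT_CAP)))


def step_ryr_counts(n_open, n_total, r_o, r_c, dt, rng):
    """Advance RyR open counts by dt via binomial transition sampling.

    ``n_open`` is an integer array; ``r_o`` broadcasts against it.  Uses the
    exact two-state propagator of the frozen-rate chain: with R = r_o + r_c
    and pi = r_o / R, a closed channel is open after dt with probability
    pi (1 - e^{-R dt}) and an open channel has closed with probability
    (1 - pi)(1 - e^{-R dt}).  This is unbiased at any step size (multiple
    within-step transitions are accounted for), so no substepping is
    needed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_open = np.asarray(n_open)
    r_o = np.broadcast_to(np.asarray(r_o, dtype=float), n_open.shape)
    total_rate = r_o + r_c
    relax = -np.expm1(-total_rate * dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(total_rate > 0, r_o / np.where(total_rate > 0,
                                                     total_rate, 1.0), 0.0)
    p_open = pi * relax
    p_close = (1.0 - pi) * relax
    openings = rng.binomial(n_total - n_open, p_open)
    closings = rng.binomial(n_open, p_close)
    out = n_open + openings - closings
    if np.any(out < 0) or np.any(out > n_total):
        raise AssertionError("RyR occupancy left [0, n_total]")
    return out


def step_ryr_cluster(state: RyRClusterState, r_o, dt, rng) -> RyRClusterState:
    """Cluster-state wrapper of :func:`step_ryr_counts`."""
    params_r_c = 0.5  # default closing rate; overridable via step_ryr_counts
    n_open = step_ryr_counts(
        np.asarray(state.n_open), state.n_total, r_o, params_r_c, dt, rng
    )
    return RyRClusterState(n_open=n_open, n_total=state.n_total)


# ---------------------------------------------------------------------------
# LCC kinetics
# ---------------------------------------------------------------------------

def lcc_activation_rate(v, params: GatingParams):
    """Boltzmann C->O activation rate (ms^-1)."""
    v = np.asarray(v, dtype=float)
    return params.lcc_act_rate / (
        1.0 + np.exp(-(v - params.lcc_act_vhalf) / params.lcc_act_slope)
    )


def lcc_ca_inactivation_rate(ca_d, params: GatingParams):
    """Saturating Ca-dependent O->CI inactivation rate (ms^-1).

    r_CI = r_max * ca_d / (K_CI + ca_d); the ca_d -> inf limit equals r_max.
    """
    ca_d = np.asarray(ca_d, dtype=float)
    return params.lcc_ci_rate_max * ca_d / (params.lcc_ci_kd + ca_d)


def _lcc_vi_rates(v, params: GatingParams):
    gate = 1.0 / (1.0 + np.exp(-(v - params.lcc_vi_vhalf) / params.lcc_vi_slope))
    return params.lcc_vi_rate * gate, params.lcc_vi_recovery * (1.0 - gate)


def step_lcc_counts(counts, v, ca_d, dt, rng, params: GatingParams,
                    mean_open_time=None):
    """Advance LCC state counts for one gating pool.

    Parameters
    ----------
    counts : int array, shape (4, ...) indexed by LCC_CLOSED/OPEN/VINACT/CAINACT
    v : membrane potential, mV (scalar or broadcastable)
    ca_d : dyadic [Ca2+], uM, broadcastable over the site axes
    mean_open_time : ms; defaults to the normal-mode value.  Pass
        ``params.lcc_mean_open_time_high`` for the high-activity pool.

    Competing exits from a state are sampled as one binomial with the total
    exit probability, then split binomially by relative rate (exact for the
    frozen-rate chain within a substep).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    counts = np.asarray(counts)
    if counts.shape[0] != 4:
        raise ValueError("counts must have leading axis of length 4 "
                         "(closed, open, v-inactivated, ca-inactivated)")
    if mean_open_time is None:
        mean_open_time = params.lcc_mean_open_time
    shape = counts.shape[1:]
    alpha = np.broadcast_to(np.asarray(lcc_activation_rate(v, params)), shape)
    r_oc = 1.0 / mean_open_time
    r_ci = np.broadcast_to(np.asarray(lcc_ca_inactivation_rate(ca_d, params)),
                           shape)
    r_cvi, r_vic = _lcc_vi_rates(v, params)
    r_cvi = np.broadcast_to(np.asarray(r_cvi), shape)
    r_vic = np.broadcast_to(np.asarray(r_vic), shape)
    r_cic = params.lcc_ci_recovery

    max_rate = float(max(np.max(alpha + r_cvi, initial=0.0),
                         np.max(r_oc + r_ci, initial=0.0),
                         np.max(r_vic, initial=0.0), r_cic))
    nsub = _n_substeps(max_rate, dt)
    dt_sub = dt / nsub

    c, o, vi, ci = (counts[i].copy() for i in range(4))
    exit_c = alpha + r_cvi
    exit_o = r_oc + r_ci
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_co = np.where(exit_c > 0, alpha / np.where(exit_c > 0, exit_c, 1.0), 0.0)
        frac_oc = np.where(exit_o > 0, r_oc / np.where(exit_o > 0, exit_o, 1.0), 0.0)
    p_exit_c = -np.expm1(-exit_c * dt_sub)
    p_exit_o = -np.expm1(-exit_o * dt_sub)
    p_vic = -np.expm1(-r_vic * dt_sub)
    p_cic = -np.expm1(-r_cic * dt_sub)
    for _ in range(nsub):
        leave_c = rng.binomial(c, p_exit_c)
        to_o = rng.binomial(leave_c, frac_co)
        to_vi = leave_c - to_o
        leave_o = rng.binomial(o, p_exit_o)
        back_c = rng.binomial(leave_o, frac_oc)
        to_ci = leave_o - back_c
        vi_to_c = rng.binomial(vi, p_vic)
        ci_to_c = rng.binomial(ci, p_cic)
        c += back_c + vi_to_c + ci_to_c - leave_c
        o += to_o - leave_o
        vi += to_vi - vi_to_c
        ci += to_ci - ci_to_c
    out = np.stack([c, o, vi, ci])
    if np.any(out < 0):
        raise AssertionError("LCC occupancy went negative")
    return out


def step_lcc_channels(states, v, ca_d, dt, rng, params: GatingParams):
    """Advance a dict of per-pool LCC count arrays.

    ``states`` maps pool name ('normal', 'high') to a (4, ...) count array;
    silent (non-gating) channels are not represented and never open.
    """
    for name in states:
        if name not in ("normal", "high"):
            raise ValueError(f"unknown LCC pool {name!r}")
    out = {}
    if "normal" in states:
        out["normal"] = step_lcc_counts(
            states["normal"], v, ca_d, dt, rng, params,
            mean_open_time=params.lcc_mean_open_time)
    if "high" in states:
        out["high"] = step_lcc_counts(
            states["high"], v, ca_d, dt, rng, params,
            mean_open_time=params.lcc_mean_open_time_high)
    return out


def assign_lcc_pools(n_sites: int, params: GatingParams, rng):
    """Seeded draw of per-site gating-pool sizes.

    Each of the ``n_lcc`` channels at a site is high-activity with probability
    ``lcc_high_fraction`` (high-activity channels always gate); the remainder
    gate in normal mode with a residual probability chosen so the overall
    gating fraction equals ``lcc_gating_fraction``.

    Returns (n_normal, n_high) integer arrays of length n_sites.
    """
    f_high = params.lcc_high_fraction
    f_gate = params.lcc_gating_fraction
    n_high = rng.binomial(params.n_lcc, f_high, size=n_sites)
    resid = 0.0
    if f_high < 1.0:
        resid = min(1.0, max(0.0, (f_gate - f_high) / (1.0 - f_high)))
    n_normal = rng.binomial(params.n_lcc - n_high, resid)
    return n_normal, n_high
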