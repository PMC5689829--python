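"""1D fiber of gap-junction-coupled myocytes.

Each cell is a single voltage node coupled to its neighbours through linear
gap-junction currents I_gap = g_gap (V_i - V_{i+1}).  Voltage diffusion
along the cable is advanced with the Crank-Nicolson method at the macro
step (default 50 us) while each cell's interior (channels, Ca2+, local
currents) is advanced by the cell engine within the step (operator
splitting).  Cable ends are sealed (zero flux).

The outer ``boundary_buffer`` cells (24 per end at full scale) are
initialized to normal SR loads so they stay quiescent; they are excluded
from all statistics but still load their neighbours electrotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.linalg import solve_banded

from . import cell_sim as cs

__all__ = [
    "FiberConfig", "FiberTrace", "gap_junction_current", "make_fiber_state",
    "step_fiber", "run_fiber", "conduction_velocity", "calibrate_ggap",
    "independence_check", "paced_protocol",
]

#: Longitudinal extent of the full-scale lattice (50 planes x 2 um): the
#: physical cell length used to convert cell indices to distance.
FULL_SCALE_CELL_LENGTH_UM = 100.0


@dataclass
class FiberConfig:
    """Fiber geometry, coupling, and the shared per-cell model config."""

    n_cells: int = 96
    g_gap: float = 1750.0        # nS (calibrated for 55 cm/s at defaults)
    ggap_scale: float = 1.0
    boundary_buffer: int = 24    # quiescent cells per end
    cell: cs.CellConfig = field(default_factory=cs.default_config)
    cell_length: float | None = None  # um; None -> full-scale 100 um

    def __post_init__(self):
        if self.n_cells <= 2 * self.boundary_buffer:
            raise ValueError("n_cells must exceed 2 * boundary_buffer")
        if self.cell.dt <= 0:
            raise ValueError("macro step must be > 0")

    @property
    def cell_length_um(self) -> float:
        return (FULL_SCALE_CELL_LENGTH_UM if self.cell_length is None
                else self.cell_length)

    @property
    def interior(self) -> np.ndarray:
        mask = np.zeros(self.n_cells, dtype=bool)
        mask[self.boundary_buffer:self.n_cells - self.boundary_buffer] = True
        return mask

    @property
    def coupling_rate(self) -> float:
        """g_gap / C_m in ms^-1."""
        cm = self.cell.membrane.cm_per_site * self.cell.geometry.n_sites
        return self.g_gap * self.ggap_scale / cm


@dataclass
class FiberTrace:
    """Spatiotemporal record of a fiber simulation."""

    t: np.ndarray           # (n_times,)
    v: np.ndarray           # (n_cells, n_times)
    ca_i: np.ndarray        # (n_cells, n_times)
    j_ryr: np.ndarray       # (n_cells, n_times) cytosol-referred uM/ms
    interior: np.ndarray    # bool mask of non-buffer cells
    cell_length: float      # um
    seed: int
    config_hash: str
    dt_record: float

    def __post_init__(self):
        n_cells, n_times = self.v.shape
        if self.t.size != n_times or self.j_ryr.shape != self.v.shape:
            raise ValueError("inconsistent trace shapes")
        if self.interior.size != n_cells:
            raise ValueError("interior mask length mismatch")

    @property
    def v_max(self) -> np.ndarray:
        """Per-cell maximum V over the whole analysis window."""
        return self.v.max(axis=1)


def gap_junction_current(v_i, v_j, g_gap):
    """I_gap from cell i into cell j, pA: antisymmetric and linear."""
    if not (np.all(np.isfinite(v_i)) and np.all(np.isfinite(v_j))):
        raise ValueError("voltages must be finite")
    return g_gap * (np.asarray(v_i) - np.asarray(v_j))


def _cn_banded(n_cells: int, lam_dt_half: float):
    """Banded (ab) form of I - (lam dt/2) L for the sealed-end Laplacian."""
    main = np.full(n_cells, 1.0 + 2.0 * lam_dt_half)
    main[0] = main[-1] = 1.0 + lam_dt_half
    upper = np.full(n_cells, -lam_dt_half)
    lower = np.full(n_cells, -lam_dt_half)
    ab = np.zeros((3, n_cells))
    ab[0, 1:] = upper[1:]
    ab[1] = main
    ab[2, :-1] = lower[:-1]
    return ab


def _laplacian_apply(v):
    out = np.empty_like(v)
    out[1:-1] = v[:-2] - 2.0 * v[1:-1] + v[2:]
    out[0] = v[1] - v[0]
    out[-1] = v[-2] - v[-1]
    return out


def make_fiber_state(config: FiberConfig, seed=0, interior_ic=None,
                     boundary_ic=None) -> cs.CellState:
    """Fiber state with distinct interior / boundary initial conditions."""
    interior_ic = dict(interior_ic or {})
    boundary_ic = dict(boundary_ic or {})
    state = cs.init_state(config.cell, n_cells=config.n_cells, seed=seed,
                          **interior_ic)
    if boundary_ic:
        bstate = cs.init_state(config.cell, n_cells=config.n_cells,
                               seed=seed, **boundary_ic)
        edge = ~config.interior
        for name in ("ca_d", "ca_jsr", "ca_sm", "b_cam", "b_sl"):
            arr = getattr(state, name)
            arr[edge] = getattr(bstate, name)[edge]
        for name in ("v", "na_i", "ca_i", "ca_nsr"):
            arr = getattr(state, name)
            arr[edge] = getattr(bstate, name)[edge]
    return state


def step_fiber(state: cs.CellState, config: FiberConfig, rng, cn_ab=None,
               i_stim=0.0, **drive) -> dict:
    """One macro step: cell interiors then the Crank-Nicolson voltage solve.

    ``i_stim`` may be a scalar or per-cell array (pA/pF).  Returns the cell
    diagnostics dict from :func:`sparkfiber.cell_sim.step_cells`.
    """
    dt = config.cell.dt
    lam_half = 0.5 * config.coupling_rate * dt
    if cn_ab is None:
        cn_ab = _cn_banded(config.n_cells, lam_half)
    diag = cs.step_cells(state, config.cell, rng, i_stim=i_stim, **drive)
    rhs = state.v + lam_half * _laplacian_apply(state.v)
    state.v = solve_banded((1, 1), cn_ab, rhs)
    return diag


def paced_protocol(duration=60.0, stim_times=(5.0,), n_stim_cells=2,
                   amplitude=120.0) -> cs.Protocol:
    """End-pacing protocol: 2 ms current pulses into the first cells."""
    return cs.Protocol(duration=duration, stim_times=tuple(stim_times),
                       stim_amplitude=amplitude, stim_cells=n_stim_cells,
                       record_every=0.1)


def run_fiber(config: FiberConfig, protocol: cs.Protocol, seed=0,
              interior_ic=None, boundary_ic=None,
              state: cs.CellState | None = None) -> FiberTrace:
    """Integrate the fiber through a protocol and record V, ca_i, J_RyR."""
    rng = np.random.default_rng(seed)
    if state is None:
        state = make_fiber_state(config, seed=seed, interior_ic=interior_ic,
                                 boundary_ic=boundary_ic)
    else:
        state = state.copy()
    dt = config.cell.dt
    lam_half = 0.5 * config.coupling_rate * dt
    cn_ab = _cn_banded(config.n_cells, lam_half)
    n_steps = int(round(protocol.duration / dt))
    stride = max(1, int(round(protocol.record_every / dt)))
    stim_mask = np.zeros(config.n_cells)
    n_stim = protocol.stim_cells or config.n_cells
    stim_mask[:n_stim] = 1.0
    ts, vs, cais, jryrs = [], [], [], []
    for istep in range(n_steps):
        amp = protocol.stim_at(state.t)
        mult = (1.0 if protocol.opening_scale_ramp is None
                else protocol.opening_scale_ramp(state.t))
        if protocol.na_ramp is not None:
            state.na_i = np.full_like(state.na_i, protocol.na_ramp(state.t))
        diag = step_fiber(state, config, rng, cn_ab=cn_ab,
                          i_stim=amp * stim_mask, opening_mult=mult,
                          nsr_clamp=protocol.nsr_clamp,
                          sarcolemmal_ca=protocol.sarcolemmal_ca)
        if istep % stride == 0:
            ts.append(state.t)
            vs.append(state.v.copy())
            cais.append(state.ca_i.copy())
            jryrs.append(diag["j_ryr"].copy())
    return FiberTrace(
        t=np.asarray(ts), v=np.asarray(vs).T, ca_i=np.asarray(cais).T,
        j_ryr=np.asarray(jryrs).T, interior=config.interior,
        cell_length=config.cell_length_um, seed=seed,
        config_hash=cs.config_hash(config.cell), dt_record=protocol.record_every)


def _activation_times(t, v, threshold=-20.0):
    """First upward crossing of ``threshold`` per cell (linear interp)."""
    n_cells = v.shape[0]
    times = np.full(n_cells, np.nan)
    above = v >= threshold
    for i in range(n_cells):
        idx = np.flatnonzero(above[i, 1:] & ~above[i, :-1])
        if idx.size:
            k = idx[0]
            f = (threshold - v[i, k]) / (v[i, k + 1] - v[i, k])
            times[i] = t[k] + f * (t[k + 1] - t[k])
    return times


def conduction_velocity(trace: FiberTrace, threshold=-20.0):
    """AP conduction velocity, cm/s, from activation-time regression.

    Activation time (upstroke crossing of -20 mV) is regressed on position
    over the middle 50% of the fiber.  Returns (velocity_cm_s, block_flag);
    velocity is NaN when propagation fails to cover the middle segment.
    """
    n_cells = trace.v.shape[0]
    act = _activation_times(trace.t, trace.v, threshold)
    lo, hi = n_cells // 4, (3 * n_cells) // 4
    mid = np.arange(lo, hi)
    ok = np.isfinite(act[mid])
    if np.count_nonzero(ok) < max(3, 0.8 * mid.size):
        return np.nan, True
    x_um = mid[ok] * trace.cell_length
    slope = np.polyfit(act[mid][ok], x_um, 1)[0]  # um/ms
    return float(slope * 0.1), False  # 1 um/ms = 0.1 cm/s


def calibrate_ggap(config: FiberConfig, target_cv=55.0, tolerance=0.05,
                   seed=0, protocol: cs.Protocol | None = None,
                   max_iter=20):
    """Bracketing root search on log g_gap until |CV - target| <= tol.

    Conduction block at a trial g_gap is treated as CV below target.
    Returns dict with ``g_gap``, ``cv`` and the search history; raises if
    no bracket can be found.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be > 0")
    if protocol is None:
        protocol = paced_protocol(
            duration=10.0 + 0.02 * config.n_cells * config.cell_length_um
            / (0.1 * target_cv))
    history = []

    def measure(g):
        cfg = replace(config, g_gap=g)
        trace = run_fiber(cfg, protocol, seed=seed)
        cv, block = conduction_velocity(trace)
        history.append((g, cv))
        return -np.inf if block else cv

    log_g = np.log(config.g_gap * config.ggap_scale)
    cv0 = measure(np.exp(log_g))
    if np.isfinite(cv0) and abs(cv0 - target_cv) / target_cv <= tolerance:
        return {"g_gap": float(np.exp(log_g)), "cv": cv0, "history": history}
    lo, hi = log_g, log_g
    cv_lo = cv_hi = cv0
    for _ in range(max_iter):
        if cv_lo < target_cv and cv_hi > target_cv:
            break
        if cv_hi <= target_cv:
            hi += np.log(2.0)
            cv_hi = measure(np.exp(hi))
        if cv_lo >= target_cv:
            lo -= np.log(2.0)
            cv_lo = measure(np.exp(lo))
    else:
        raise RuntimeError("calibrate_ggap: could not bracket the target CV")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cv_mid = measure(np.exp(mid))
        if np.isfinite(cv_mid) and abs(cv_mid - target_cv) / target_cv <= tolerance:
            return {"g_gap": float(np.exp(mid)), "cv": cv_mid,
                    "history": history}
        if cv_mid < target_cv:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibrate_ggap: bisection did not converge")


def independence_check(ca_i_profiles, interior=None, far_lag=50,
                       min_interior=60):
    """Test spatial decoupling of spontaneous release along the fiber.

    Compares |difference| of per-cell peak [Ca2+]_i amplitude and peak time
    between adjacent interior cell pairs and pairs ``far_lag`` cells apart,
    with rank-based (Kruskal-Wallis) two-sample tests.  Coupled release
    would make lag-1 timing differences stochastically smaller.
    """
    prof = np.asarray(ca_i_profiles, dtype=float)
    n_cells = prof.shape[0]
    if interior is None:
        interior = np.ones(n_cells, dtype=bool)
    idx = np.flatnonzero(interior)
    if idx.size < min_interior:
        raise ValueError(f"need >= {min_interior} interior cells, have {idx.size}")
    peak_amp = prof.max(axis=1)
    peak_time = prof.argmax(axis=1).astype(float)

    def pair_diffs(lag):
        pairs = [(i, i + lag) for i in idx if i + lag in set(idx)]
        a = np.array([abs(peak_amp[i] - peak_amp[j]) for i, j in pairs])
        t = np.array([abs(peak_time[i] - peak_time[j]) for i, j in pairs])
        return a, t

    amp1, t1 = pair_diffs(1)
    ampf, tf = pair_diffs(far_lag)
    p_amp = stats.kruskal(amp1, ampf).pvalue
    p_time = stats.kruskal(t1, tf).pvalue
    return {"p_amplitude": float(p_amp), "p_time": float(p_time),
            "d_amp_lag1": amp1, "d_amp_far": ampf,
            "d_time_lag1": t1, "d_time_far": tf, "far_lag": far_lag}
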