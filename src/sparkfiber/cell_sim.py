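"""Single stochastic myocyte integration and the single-cell protocols.

The engine advances one or more cells (a fiber carries the cell axis) with a
fixed-step operator-split scheme:

1. stochastic channel update at the macro step (default 0.05 ms): RyR
   clusters by the exact two-state propagator (unbiased at any dt), LCC
   pools by substepped binomial sampling with rate * dt_sub <= 0.1;
2. Ca2+ compartment update.  The stiff dyadic subspace is advanced with the
   exact solution of its frozen-coefficient linear ODE, and the time
   integral of [Ca2+]_d over the step is used to move exact *amounts*
   between JSR, dyad and SM, so total Ca2+ is conserved to round-off in a
   closed cell.  JSR, SM and cytosol all use rapid buffering (the total
   pool is updated and inverted to free Ca2+); the SM buffers' free-Ca
   coupling time constant (~0.01 ms) is far below the macro step, which
   makes the explicit buffer ODE unstable and the rapid limit exact for
   practical purposes;
3. membrane update: HH gates by Rush-Larsen exponential steps and V by
   explicit Euler on a finer sub-step (default dt/4).

All randomness flows from one seeded numpy Generator per simulation; with
the fixed vectorized update order this makes traces bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from . import calcium as ca
from . import gating as gt
from . import membrane as mb

__all__ = [
    "CellConfig", "Protocol", "PiecewiseLinear", "CellState", "CellTrace",
    "DadEnsembleSummary", "default_config", "init_state", "step_cells",
    "run_cell", "ecc_gain_protocol", "leak_load_protocol", "dad_ensemble",
    "wave_metrics", "overload_pacing_protocol", "config_hash",
    "TRIGGER_V", "TRIGGER_DVDT", "AP_THRESHOLD_V",
]

# Triggered-AP classification: upstroke crossing of -20 mV with dV/dt > 5
# mV/ms in the diastolic window; ~ -55 mV is the I_Na activation threshold.
TRIGGER_V = -20.0
TRIGGER_DVDT = 5.0
AP_THRESHOLD_V = -55.0


@dataclass
class CellConfig:
    """Aggregated model configuration for one myocyte."""

    geometry: ca.LatticeGeometry = field(default_factory=ca.LatticeGeometry)
    gating: gt.GatingParams = field(default_factory=gt.GatingParams)
    transport: ca.TransportParams = field(default_factory=ca.TransportParams)
    membrane: mb.MembraneParams = field(default_factory=mb.MembraneParams)
    dt: float = 0.05          # ms macro step
    n_v_substeps: int = 4     # membrane sub-steps per macro step
    beta_ar: bool = False
    beta_opening_scale: float = 1.0

    def validate(self) -> None:
        self.gating.validate()
        self.transport.validate()
        self.membrane.validate()
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def default_config(nx=10, ny=8, nz=20, **overrides) -> CellConfig:
    """Calibrated baseline configuration at a configurable lattice scale."""
    cfg = CellConfig(geometry=ca.LatticeGeometry(nx=nx, ny=ny, nz=nz))
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def config_hash(config: CellConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha1(text).hexdigest()[:12]


@dataclass
class PiecewiseLinear:
    """Piecewise-linear time series: constant extrapolation outside knots."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t):
        return float(np.interp(t, self.times, self.values))


@dataclass
class Protocol:
    """Stimulus / clamp / ramp schedule for a simulation."""

    duration: float                       # ms
    stim_times: tuple = ()                # onsets of 2 ms current pulses
    stim_duration: float = 2.0            # ms
    stim_amplitude: float = 80.0          # pA/pF, depolarizing
    stim_cells: int | None = None         # None = all cells; n = first n
    v_clamp: PiecewiseLinear | None = None
    na_ramp: PiecewiseLinear | None = None
    opening_scale_ramp: PiecewiseLinear | None = None
    nsr_clamp: float | None = None        # mM, clamps [Ca2+]_NSR
    sarcolemmal_ca: bool = True           # False = closed-cell Ca2+
    record_every: float = 1.0             # ms
    snapshot_every: float | None = None   # ms, [Ca2+]_SM lattice snapshots

    def stim_at(self, t: float) -> float:
        for onset in self.stim_times:
            if onset <= t < onset + self.stim_duration:
                return self.stim_amplitude
        return 0.0


class CellState:
    """Mutable state of an ensemble of cells (site arrays + per-cell scalars).

    Site arrays have shape (n_cells, nx, ny, nz); per-cell quantities have
    shape (n_cells,).
    """

    __slots__ = ("ca_d", "ca_jsr", "ca_sm", "b_cam", "b_sl", "n_ryr_open",
                 "lcc_norm", "lcc_high", "n_lcc_norm", "n_lcc_high",
                 "v", "m", "h", "j", "xr", "xs", "na_i", "ca_i", "ca_nsr", "t")

    def __init__(self, **kw):
        for name in self.__slots__:
            setattr(self, name, kw[name])

    @property
    def n_cells(self) -> int:
        return self.ca_d.shape[0]

    def copy(self) -> "CellState":
        return CellState(**{name: np.copy(getattr(self, name))
                            if isinstance(getattr(self, name), np.ndarray)
                            else getattr(self, name)
                            for name in self.__slots__})

    def site_state(self) -> ca.ReleaseSiteState:
        return ca.ReleaseSiteState(ca_d=self.ca_d, ca_jsr=self.ca_jsr,
                                   ca_sm=self.ca_sm, b_cam=self.b_cam,
                                   b_sl=self.b_sl)

    def globals_state(self) -> ca.GlobalCaState:
        return ca.GlobalCaState(ca_i=self.ca_i, ca_nsr=self.ca_nsr)


def init_state(config: CellConfig, n_cells: int = 1, seed=0, ca_i=0.1,
               ca_nsr=0.75, na_i=10.0, v=-90.5) -> CellState:
    """Quiescent state with buffers equilibrated and channels closed."""
    rng = np.random.default_rng(seed)
    g = config.geometry
    shape = (n_cells,) + g.shape
    p = config.transport
    ca_i_arr = np.full(n_cells, float(ca_i))
    ca_sm = np.full(shape, float(ca_i))
    b_cam = ca.bound_rapid(ca_sm, p.bt_cam_sm, p.koff_cam / p.kon_cam)
    b_sl = ca.bound_rapid(ca_sm, p.bt_sl_sm, p.koff_sl / p.kon_sl)
    n_norm, n_high = gt.assign_lcc_pools(n_cells * g.n_sites, config.gating,
                                         rng)
    zeros4 = np.zeros((4,) + shape, dtype=np.int64)
    lcc_norm = zeros4.copy()
    lcc_high = zeros4.copy()
    lcc_norm[0] = n_norm.reshape(shape)
    lcc_high[0] = n_high.reshape(shape)
    infs = mb.gate_infs_taus(float(v), config.membrane)
    return CellState(
        ca_d=np.full(shape, float(ca_i)),
        ca_jsr=np.full(shape, float(ca_nsr)),
        ca_sm=ca_sm, b_cam=b_cam, b_sl=b_sl,
        n_ryr_open=np.zeros(shape, dtype=np.int64),
        lcc_norm=lcc_norm, lcc_high=lcc_high,
        n_lcc_norm=lcc_norm[0].copy(), n_lcc_high=lcc_high[0].copy(),
        v=np.full(n_cells, float(v)),
        m=np.full(n_cells, infs["m"][0]), h=np.full(n_cells, infs["h"][0]),
        j=np.full(n_cells, infs["j"][0]), xr=np.full(n_cells, infs["xr"][0]),
        xs=np.full(n_cells, infs["xs"][0]),
        na_i=np.full(n_cells, float(na_i)),
        ca_i=ca_i_arr, ca_nsr=np.full(n_cells, float(ca_nsr)), t=0.0)


def _invert_jsr_total(total, p: ca.TransportParams):
    """Free [Ca2+]_JSR (mM) from total (free + CSQ-bound) concentration."""
    b = p.kd_csq + p.bt_csq - total
    return 0.5 * (-b + np.sqrt(b * b + 4.0 * p.kd_csq * total))


def _buffered_total(free, pools):
    total = np.asarray(free, dtype=float)
    for bt, kd in pools:
        total = total + ca.bound_rapid(free, bt, kd)
    return total


def _invert_buffered_total(total, guess, pools):
    """Newton inversion of free Ca2+ from a rapid-buffered total pool."""
    x = np.maximum(guess, 1e-9)
    for _ in range(4):
        f = _buffered_total(x, pools) - total
        fp = np.ones_like(x)
        for bt, kd in pools:
            fp = fp + bt * kd / (kd + x) ** 2
        x = np.maximum(x - f / fp, 1e-9)
    return x


def _cyto_total(ca_i, p: ca.TransportParams):
    return (ca_i + ca.bound_rapid(ca_i, p.bt_cmdn, p.kd_cmdn)
            + ca.bound_rapid(ca_i, p.bt_trpn, p.kd_trpn))


def _invert_cyto_total(total, guess, p: ca.TransportParams):
    """Newton inversion of the cytosolic free+rapid-buffer pool."""
    x = np.maximum(guess, 1e-6)
    for _ in range(4):
        f = _cyto_total(x, p) - total
        fp = (1.0 + p.bt_cmdn * p.kd_cmdn / (p.kd_cmdn + x) ** 2
              + p.bt_trpn * p.kd_trpn / (p.kd_trpn + x) ** 2)
        x = np.maximum(x - f / fp, 1e-9)
    return x


def step_cells(state: CellState, config: CellConfig, rng,
               i_stim=0.0, v_clamp=None, opening_mult=1.0,
               nsr_clamp=None, sarcolemmal_ca=True):
    """Advance all cells by one macro step ``config.dt`` (in place).

    Returns a dict of per-cell diagnostics: whole-cell ``j_ryr`` and
    ``j_lcc`` (uM/ms, cytosol-referred) and the summed ionic current.
    """
    p = config.transport
    gp = config.gating
    mp = config.membrane
    dt = config.dt
    g = config.geometry
    n_sites = g.n_sites
    cell_axes = (1, 2, 3)
    cm_total = mp.cm_per_site * n_sites

    vb = state.v[:, None, None, None]

    # --- 1. stochastic channels -------------------------------------------
    phi = gp.phi_offset + (state.ca_jsr / gp.jsr_ref) ** gp.phi_exponent
    r_o = (gp.opening_scale * opening_mult * gp.k_plus * phi
           * state.ca_d ** gp.eta)
    state.n_ryr_open = gt.step_ryr_counts(
        state.n_ryr_open, p.n_ryr, r_o, gp.r_c, dt, rng)
    # LCC pools are skipped while provably idle (all channels closed and the
    # per-step opening probability negligible at the current voltages)
    v_max_now = float(np.max(state.v))
    lcc_idle_p = float(gt.lcc_activation_rate(v_max_now, gp)) * dt
    for pool, sizes, tau_o in (
            ("lcc_norm", state.n_lcc_norm, gp.lcc_mean_open_time),
            ("lcc_high", state.n_lcc_high, gp.lcc_mean_open_time_high)):
        counts = getattr(state, pool)
        n_gating = int(sizes.sum())
        if n_gating == 0 or (lcc_idle_p * n_gating < 1e-4
                             and not counts[1:].any()):
            continue
        setattr(state, pool, gt.step_lcc_counts(
            counts, vb, state.ca_d, dt, rng, gp, mean_open_time=tau_o))
    n_lcc_open = state.lcc_norm[gt.LCC_OPEN] + state.lcc_high[gt.LCC_OPEN]
    any_lcc_open = bool(n_lcc_open.any())

    # --- 2. Ca2+ transport -------------------------------------------------
    # the GHK unitary LCC flux is linear in ca_d (a - b*ca_d), so it joins
    # the dyad's exact linear solve; freezing it would overshoot through
    # the local reversal at high dyadic Ca2+
    if sarcolemmal_ca and any_lcc_open:
        lcc_a, lcc_b = mb.lcc_flux_coeffs(vb, mp)
        # influx-only: drop the LCC term at sites already at/above the
        # nominal reversal concentration (spark sites)
        influx = (lcc_a - lcc_b * state.ca_d) > 0
        lcc_a = np.where(influx, n_lcc_open * lcc_a, 0.0)
        lcc_b = np.where(influx, n_lcc_open * lcc_b, 0.0)
    else:
        lcc_a = lcc_b = 0.0
    frac_open = state.n_ryr_open / p.n_ryr
    krel_f = p.k_rel * frac_open
    bcoef = krel_f + 1.0 / p.tau_ds + lcc_b
    acoef = (krel_f * 1000.0 * state.ca_jsr + lcc_a
             + state.ca_sm / p.tau_ds)
    eq = acoef / bcoef
    decay = np.exp(-bcoef * dt)
    ca_d_new = eq + (state.ca_d - eq) * decay
    int_ca_d = eq * dt + (state.ca_d - eq) * (1.0 - decay) / bcoef
    rel_amt = krel_f * (1000.0 * state.ca_jsr * dt - int_ca_d) * p.v_d
    sm_amt = (int_ca_d - state.ca_sm * dt) / p.tau_ds * p.v_d
    j_lcc_int = lcc_a * dt - lcc_b * int_ca_d  # time-integrated, uM dyad
    state.ca_d = ca_d_new

    # JSR: total pool update (release out, NSR refill in), then invert CSQ
    refill = (state.ca_nsr[:, None, None, None] - state.ca_jsr) / p.tau_refill
    jsr_total = (state.ca_jsr
                 + ca.bound_rapid(state.ca_jsr, p.bt_csq, p.kd_csq)
                 - rel_amt / (1000.0 * p.v_jsr) + refill * dt)
    state.ca_jsr = _invert_jsr_total(jsr_total, p)

    # SM pool: rapid buffering (calmodulin + sarcolemmal sites); at the
    # working step size the buffer-free coupling is far below dt, so the
    # total pool is updated and inverted to free Ca2+ (Newton).
    diff = ca.sm_diffusion_fluxes(state.ca_sm, g, p) * dt
    ca_i_b = state.ca_i[:, None, None, None]
    to_cyto = (state.ca_sm - ca_i_b) / p.tau_sm_cyto * dt  # uM, SM-referred
    if sarcolemmal_ca:
        i_ncx_site = mb.ncx_current(vb, state.na_i[:, None, None, None],
                                    state.ca_sm, mp)  # pA/pF
        ncx_sm_amt = (i_ncx_site * mp.cm_per_site * mp.ncx_sm_fraction
                      * (10.364 * dt))  # uM.um^3, positive = influx
    else:
        ncx_sm_amt = 0.0
    sm_pools = ((p.bt_cam_sm, p.koff_cam / p.kon_cam),
                (p.bt_sl_sm, p.koff_sl / p.kon_sl))
    sm_total = (_buffered_total(state.ca_sm, sm_pools)
                + (sm_amt + ncx_sm_amt) / p.v_sm + diff - to_cyto)
    state.ca_sm = _invert_buffered_total(sm_total, state.ca_sm, sm_pools)
    state.b_cam = ca.bound_rapid(state.ca_sm, *sm_pools[0])
    state.b_sl = ca.bound_rapid(state.ca_sm, *sm_pools[1])

    # globals: cytosol (rapid-buffered total pool) and NSR
    v_cyto_total = p.v_cyto * n_sites
    v_nsr_total = p.v_nsr * n_sites
    sm_influx_amt = np.sum(to_cyto, axis=cell_axes) * p.v_sm
    serca = ca.serca_flux(state.ca_i, p)  # uM/ms cytosol-referred
    serca_amt = serca * dt * v_cyto_total
    cyto_amt = sm_influx_amt - serca_amt
    if sarcolemmal_ca:
        i_ncx_cyto = mb.ncx_current(state.v, state.na_i, state.ca_i, mp)
        i_pca = mb.ipca_current(state.ca_i, mp)
        i_cab = mb.icab_current(state.v, state.ca_i, mp)
        cyto_amt += (i_ncx_cyto * (1.0 - mp.ncx_sm_fraction) * 10.364
                     - i_pca * 5.182 - i_cab * 5.182) * cm_total * dt
    cyto_total = _cyto_total(state.ca_i, p) + cyto_amt / v_cyto_total
    state.ca_i = _invert_cyto_total(cyto_total, state.ca_i, p)
    if nsr_clamp is None:
        refill_amt = np.sum(refill, axis=cell_axes) * dt * 1000.0 * p.v_jsr
        state.ca_nsr = state.ca_nsr + (serca_amt - refill_amt) / (
            1000.0 * v_nsr_total)
    else:
        state.ca_nsr = np.full_like(state.ca_nsr, nsr_clamp)

    # --- 3. membrane -------------------------------------------------------
    j_lcc_cell_amt = np.sum(j_lcc_int, axis=cell_axes) / dt * p.v_d \
        if np.ndim(j_lcc_int) else np.zeros(state.n_cells)  # uM.um^3/ms
    n_open_cell = np.sum(n_lcc_open, axis=cell_axes)
    mean_ca_d = np.mean(state.ca_d, axis=cell_axes)
    mean_ca_sm = np.mean(state.ca_sm, axis=cell_axes)
    if v_clamp is not None:
        state.v = np.full_like(state.v, v_clamp)
    currents = _membrane_currents(state, mp, mean_ca_sm, mean_ca_d,
                                  n_open_cell, p.v_d, cm_total,
                                  sarcolemmal_ca)
    total_i = sum(currents.values())
    if np.any(np.isnan(total_i)):
        bad = [k for k, val in currents.items() if np.any(np.isnan(val))]
        raise FloatingPointError(
            f"NaN in membrane current(s) {bad} at t={state.t:.3f} ms")
    dv0 = -(total_i) + i_stim
    # sub-step only when V is actually moving (upstroke/stimulus)
    nsub = 1 if float(np.max(np.abs(dv0))) * dt < 0.5 else config.n_v_substeps
    dt_v = dt / nsub
    for isub in range(nsub):
        if isub > 0:
            currents = _membrane_currents(state, mp, mean_ca_sm, mean_ca_d,
                                          n_open_cell, p.v_d, cm_total,
                                          sarcolemmal_ca)
            total_i = sum(currents.values())
        if v_clamp is None:
            state.v = state.v + dt_v * (-(total_i) + i_stim)
        gates = mb.gate_infs_taus(state.v, mp)
        for name in ("m", "h", "j", "xr", "xs"):
            inf, tau = gates[name]
            old = getattr(state, name)
            setattr(state, name, inf + (old - inf) * np.exp(-dt_v / tau))

    state.t += dt
    j_ryr_cell = ca.whole_cell_jryr(
        ca.release_flux(state.n_ryr_open, state.ca_jsr, state.ca_d, p), p)
    return {"j_ryr": j_ryr_cell,
            "j_lcc": j_lcc_cell_amt / (p.v_cyto * n_sites),
            "i_total": total_i}


def _membrane_currents(state, mp, mean_ca_sm, mean_ca_d, n_open_cell, v_d,
                       cm_total, sarcolemmal_ca):
    v = state.v
    out = {
        "i_na": mb.ina_current(v, state.m, state.h, state.j, state.na_i, mp),
        "i_k1": mb.ik1_current(v, mp.scale_k1, mp),
        "i_kr": mb.ikr_current(v, state.xr, mp),
        "i_ks": mb.iks_current(v, state.xs, state.na_i, mp),
        "i_nak": mb.inak_current(v, state.na_i, mp),
    }
    if mp.g_leak != 0.0:
        out["i_leak"] = mp.g_leak * (v - mp.e_leak)
    if sarcolemmal_ca:
        out["i_ncx"] = (
            mp.ncx_sm_fraction * mb.ncx_current(v, state.na_i, mean_ca_sm, mp)
            + (1 - mp.ncx_sm_fraction) * mb.ncx_current(v, state.na_i,
                                                        state.ca_i, mp))
        out["i_pca"] = mb.ipca_current(state.ca_i, mp)
        out["i_cab"] = mb.icab_current(v, state.ca_i, mp)
        # whole-cell L-type current from the open-channel count and the
        # unitary GHK flux at the (cell-mean) dyadic Ca2+
        flux_amt = n_open_cell * mb.lcc_unitary_flux(v, mean_ca_d, mp) * v_d
        out["i_cal"] = -mb.PA_PER_UMUM3_MS_Z2 * flux_amt / cm_total
    return out


@dataclass
class CellTrace:
    """Recorded time series of one simulation (single cell or per-cell)."""

    t: np.ndarray
    v: np.ndarray
    ca_i: np.ndarray
    ca_nsr: np.ndarray
    j_ryr: np.ndarray
    j_lcc: np.ndarray
    snapshots: np.ndarray | None
    snapshot_times: np.ndarray | None
    seed: int
    config_hash: str

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name in ("v", "ca_i", "ca_nsr", "j_ryr", "j_lcc"):
            if getattr(self, name).shape[-1] != self.t.size:
                raise ValueError(f"{name} length does not match time grid")


def run_cell(config: CellConfig, initial_state: CellState | dict | None,
             protocol: Protocol, seed: int = 0) -> CellTrace:
    """Integrate one stochastic myocyte through a protocol.

    ``initial_state`` may be a prepared :class:`CellState`, a dict of
    overrides passed to :func:`init_state` (e.g. ``{"ca_nsr": 1.1}``), or
    None for the quiescent default.  Reproducible given (config, state,
    seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if initial_state is None:
        state = init_state(config, seed=seed)
    elif isinstance(initial_state, dict):
        state = init_state(config, seed=seed, **initial_state)
    else:
        state = initial_state.copy()
    if protocol.nsr_clamp is not None:
        state.ca_nsr = np.full_like(state.ca_nsr, protocol.nsr_clamp)
        state.ca_jsr = np.full_like(state.ca_jsr, protocol.nsr_clamp)

    n_steps = int(round(protocol.duration / config.dt))
    rec_stride = max(1, int(round(protocol.record_every / config.dt)))
    snap_stride = (None if protocol.snapshot_every is None
                   else max(1, int(round(protocol.snapshot_every / config.dt))))
    rec = {k: [] for k in ("t", "v", "ca_i", "ca_nsr", "j_ryr", "j_lcc")}
    snaps, snap_times = [], []

    single = state.n_cells == 1
    for istep in range(n_steps):
        t = state.t
        stim = protocol.stim_at(t)
        clamp = None if protocol.v_clamp is None else protocol.v_clamp(t)
        mult = (1.0 if protocol.opening_scale_ramp is None
                else protocol.opening_scale_ramp(t))
        if protocol.na_ramp is not None:
            state.na_i = np.full_like(state.na_i, protocol.na_ramp(t))
        diag = step_cells(state, config, rng, i_stim=stim, v_clamp=clamp,
                          opening_mult=mult, nsr_clamp=protocol.nsr_clamp,
                          sarcolemmal_ca=protocol.sarcolemmal_ca)
        if istep % rec_stride == 0:
            rec["t"].append(state.t)
            for key, val in (("v", state.v), ("ca_i", state.ca_i),
                             ("ca_nsr", state.ca_nsr),
                             ("j_ryr", diag["j_ryr"]),
                             ("j_lcc", diag["j_lcc"])):
                rec[key].append(val[0] if single else val.copy())
        if snap_stride is not None and istep % snap_stride == 0:
            snaps.append(state.ca_sm[0].copy() if single
                         else state.ca_sm.copy())
            snap_times.append(state.t)

    arrays = {k: np.asarray(v) for k, v in rec.items()}
    if not single:
        for key in ("v", "ca_i", "ca_nsr", "j_ryr", "j_lcc"):
            arrays[key] = arrays[key].T  # (n_cells, n_times)
    return CellTrace(
        t=arrays["t"], v=arrays["v"], ca_i=arrays["ca_i"],
        ca_nsr=arrays["ca_nsr"], j_ryr=arrays["j_ryr"],
        j_lcc=arrays["j_lcc"],
        snapshots=np.asarray(snaps) if snaps else None,
        snapshot_times=np.asarray(snap_times) if snap_times else None,
        seed=seed, config_hash=config_hash(config))


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def ecc_gain_protocol(config: CellConfig, test_potentials, n_reps=10,
                      seed=0, hold_ms=20.0, step_ms=200.0, ca_nsr=1.0,
                      smooth_ms=20.0):
    """Voltage-clamp ECC gain: hold -80 mV, step to each test potential.

    Returns dict with per-potential normalized peak LCC and RyR fluxes
    (each normalized to its maximum over the sweep) and their ratio (the
    gain), averaged over ``n_reps`` stochastic repetitions.
    """
    test_potentials = np.asarray(test_potentials, dtype=float)
    if np.any(test_potentials <= -40) or np.any(test_potentials >= 60):
        raise ValueError("test potentials must lie in (-40, +60) mV")
    ss = np.random.SeedSequence(seed)
    mean_lcc = np.zeros(test_potentials.size)
    mean_ryr = np.zeros(test_potentials.size)
    # the clamp is time-locked, so fluxes are averaged across repetitions
    # *as traces* before peak-taking: at reduced lattice scale the
    # instantaneous whole-cell flux carries channel shot noise whose
    # maximum-statistic would otherwise bias the low-open-probability
    # potentials upward (the full-scale cell self-averages over 2e5
    # channels); a short boxcar removes the residual noise
    smooth = max(1, int(round(smooth_ms / config.dt)))
    kernel = np.ones(smooth) / smooth
    sub_lcc = np.zeros((n_reps, test_potentials.size))
    sub_ryr = np.zeros_like(sub_lcc)
    for ipot, v_test in enumerate(test_potentials):
        acc_lcc = acc_ryr = 0.0
        for irep, child in enumerate(ss.spawn(n_reps)):
            sub = int(child.generate_state(1)[0] % (2 ** 31))
            clamp = PiecewiseLinear(
                np.array([0.0, hold_ms - 1e-9, hold_ms,
                          hold_ms + step_ms - 1e-9, hold_ms + step_ms]),
                np.array([-80.0, -80.0, v_test, v_test, -80.0]))
            proto = Protocol(duration=hold_ms + step_ms, v_clamp=clamp,
                             record_every=config.dt)
            trace = run_cell(config, {"ca_nsr": ca_nsr}, proto,
                             seed=sub + ipot)
            window = trace.t > hold_ms
            acc_lcc = acc_lcc + trace.j_lcc[window]
            acc_ryr = acc_ryr + trace.j_ryr[window]
            sub_lcc[irep, ipot] = np.max(
                np.convolve(trace.j_lcc[window], kernel, mode="same"))
            sub_ryr[irep, ipot] = np.max(
                np.convolve(trace.j_ryr[window], kernel, mode="same"))
        mean_lcc[ipot] = np.max(np.convolve(acc_lcc / n_reps, kernel,
                                            mode="same"))
        mean_ryr[ipot] = np.max(np.convolve(acc_ryr / n_reps, kernel,
                                            mode="same"))
    norm_lcc = mean_lcc / np.max(mean_lcc)
    norm_ryr = mean_ryr / np.max(mean_ryr)
    undefined = norm_lcc <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(undefined, np.nan, norm_ryr / norm_lcc)
    return {"test_potentials": test_potentials, "norm_lcc": norm_lcc,
            "norm_ryr": norm_ryr, "gain": gain, "undefined": undefined}


def leak_load_protocol(config: CellConfig, nsr_clamp_values, duration=400.0,
                       seed=0, snapshot_every=10.0):
    """Clamp [Ca2+]_NSR at increasing loads; measure RyR leak and waves.

    Returns dict with the SR load (umol/L cytosol), the mean whole-cell RyR
    leak over the last half of each run, a wave flag per load, and the
    lowest waving load.
    """
    values = np.asarray(nsr_clamp_values, dtype=float)
    if np.any(np.diff(values) <= 0) or np.any(values < 0):
        raise ValueError("nsr_clamp_values must be positive ascending")
    leaks, loads, waves = [], [], []
    ss = np.random.SeedSequence(seed)
    for clamp, child in zip(values, ss.spawn(values.size)):
        proto = Protocol(duration=duration, nsr_clamp=float(clamp),
                         snapshot_every=snapshot_every,
                         record_every=1.0)
        trace = run_cell(config, None, proto,
                         seed=int(child.generate_state(1)[0] % (2 ** 31)))
        half = trace.t > duration / 2
        leaks.append(float(np.mean(trace.j_ryr[half])))
        loads.append(ca.sr_load_per_cytosol(clamp, clamp, config.transport))
        wm = wave_metrics(trace, config)
        waves.append(wm["wave"])
    waves = np.asarray(waves)
    threshold = (float(np.asarray(loads)[waves][0]) if waves.any() else None)
    return {"nsr_clamp": values, "sr_load": np.asarray(loads),
            "leak": np.asarray(leaks), "wave": waves,
            "wave_threshold_load": threshold}


@dataclass
class DadEnsembleSummary:
    """Per-realization DAD statistics and ensemble aggregates."""

    v_max: np.ndarray          # mV, per realization (triggered ones = peak V)
    delay: np.ndarray          # ms to DAD peak
    peak_ca_i: np.ndarray      # uM
    peak_j_ryr: np.ndarray     # uM/ms
    triggered: np.ndarray      # bool
    mean_v_max: float
    sd_v_max: float
    mean_delay: float
    sd_delay: float
    trigger_probability: float
    r2_vmax_jryr: float
    r2_vmax_cai: float

    def __post_init__(self):
        if not 0.0 <= self.trigger_probability <= 1.0:
            raise ValueError("trigger probability must lie in [0, 1]")


def _classify_trigger(t, v):
    dvdt = np.gradient(v, t)
    return bool(np.any((v > TRIGGER_V) & (dvdt > TRIGGER_DVDT)))


def dad_ensemble(config: CellConfig, initial_condition: dict,
                 n_realizations: int, seed=0, duration=1500.0) -> DadEnsembleSummary:
    """Ensemble of stochastic realizations from identical initial conditions.

    ``initial_condition`` holds init_state overrides (ca_i, ca_nsr, na_i).
    Realizations differ only in the RNG seed.  V_max statistics are over
    sub-threshold (non-triggered) realizations when any exist.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    ss = np.random.SeedSequence(seed)
    v_max = np.zeros(n_realizations)
    delay = np.zeros(n_realizations)
    peak_cai = np.zeros(n_realizations)
    peak_jryr = np.zeros(n_realizations)
    trig = np.zeros(n_realizations, dtype=bool)
    proto = Protocol(duration=duration, record_every=1.0)
    for i, child in enumerate(ss.spawn(n_realizations)):
        s = int(child.generate_state(1)[0] % (2 ** 31))
        trace = run_cell(config, dict(initial_condition), proto, seed=s)
        v_max[i] = np.max(trace.v)
        delay[i] = trace.t[int(np.argmax(trace.v))]
        peak_cai[i] = np.max(trace.ca_i)
        peak_jryr[i] = np.max(trace.j_ryr)
        trig[i] = _classify_trigger(trace.t, trace.v)
    sub = ~trig if (~trig).any() else np.ones_like(trig)
    def _r2(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)
    return DadEnsembleSummary(
        v_max=v_max, delay=delay, peak_ca_i=peak_cai, peak_j_ryr=peak_jryr,
        triggered=trig,
        mean_v_max=float(np.mean(v_max[sub])),
        sd_v_max=float(np.std(v_max[sub])),
        mean_delay=float(np.mean(delay[sub])),
        sd_delay=float(np.std(delay[sub])),
        trigger_probability=float(np.mean(trig)),
        r2_vmax_jryr=_r2(v_max[sub], peak_jryr[sub]),
        r2_vmax_cai=_r2(v_max[sub], peak_cai[sub]))


# ---------------------------------------------------------------------------
# Wave detection
# ---------------------------------------------------------------------------

def wave_metrics(trace: CellTrace, config: CellConfig, threshold=None,
                 seed_window=40.0, min_extent=20.0):
    """Wave flag, front velocity (um/s) and nucleation count from snapshots.

    Works on the [Ca2+]_SM lattice snapshots.  A site's onset is the first
    snapshot at which its [Ca2+]_SM exceeds ``threshold`` (default: 6x the
    initial lattice median, floor 2 uM).  The wave flag requires a connected
    activated region whose longitudinal extent grows monotonically to at
    least ``min_extent`` um.  Velocity is the slope of front distance vs
    onset time along the longitudinal axis (median onset per z-plane);
    nucleation sites are connected components of early-onset seeds.
    """
    if trace.snapshots is None or trace.snapshot_times is None:
        raise ValueError("trace has no lattice snapshots")
    times = trace.snapshot_times
    if times.size >= 2 and np.min(np.diff(times)) > 10.0 + 1e-9:
        raise ValueError("snapshot resolution coarser than 10 ms")
    snaps = trace.snapshots  # (n_snap, nx, ny, nz)
    g = config.geometry
    if threshold is None:
        # a quarter of the peak SM Ca2+ tracks the regenerative front while
        # ignoring isolated sparks ahead of it; floor keeps a quiescent
        # lattice from "activating" on noise
        threshold = max(2.0, 0.25 * float(np.max(snaps)))
    active = snaps > threshold
    onset_idx = np.where(active.any(axis=0), active.argmax(axis=0),
                         -1)  # -1 = never
    activated = onset_idx >= 0
    out = {"wave": False, "velocity": np.nan, "n_nucleation": 0,
           "threshold": threshold}
    if not activated.any():
        return out

    onset_t = np.where(activated, times[np.clip(onset_idx, 0, None)], np.inf)
    # nucleation: connected components of the earliest-onset seed regions
    t0 = float(onset_t.min())
    seeds = onset_t <= t0 + seed_window
    _, n_nuc = ndimage.label(seeds)
    out["n_nucleation"] = int(n_nuc)

    # longitudinal extent growth of the largest *connected* activated
    # region: a propagating front is a single component sweeping the
    # lattice, whereas independent sparks form many small components
    extents = []
    for k in range(len(times)):
        act_k = onset_t <= times[k]
        if not act_k.any():
            extents.append(0.0)
            continue
        labels, n_lab = ndimage.label(act_k)
        best = 0.0
        for lab in range(1, n_lab + 1):
            z_any = (labels == lab).any(axis=(0, 1))
            best = max(best, float(np.count_nonzero(z_any))
                       * g.spacing_longitudinal)
        extents.append(best)
    extents = np.asarray(extents)
    grew = np.all(np.diff(extents) >= -1e-9)
    out["wave"] = bool(grew and extents.max() >= min_extent
                       and activated.mean() > 0.25)

    # velocity: median onset per z-plane, robust (Theil-Sen) slope of front
    # distance vs onset time along the monotone run away from the earliest
    # plane (multiple nuclei produce V-shaped onset fields; only the
    # monotone segments track a single front)
    plane_onset = np.array([
        np.median(onset_t[:, :, z][activated[:, :, z]])
        if activated[:, :, z].any() else np.nan for z in range(g.nz)])
    valid = np.isfinite(plane_onset)
    if np.count_nonzero(valid) >= 5:
        z_star = int(np.nanargmin(plane_onset))
        snap_dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
        slopes = []
        for step in (1, -1):
            zz, tt = [z_star], [plane_onset[z_star]]
            z = z_star + step
            while 0 <= z < g.nz and np.isfinite(plane_onset[z]) and \
                    plane_onset[z] >= tt[-1] - snap_dt:
                zz.append(z)
                tt.append(plane_onset[z])
                z += step
            tt = np.asarray(tt)
            if len(zz) >= 4 and np.ptp(tt) > 0:
                dist = np.abs(np.asarray(zz) - z_star) * g.spacing_longitudinal
                slope = stats.theilslopes(dist, tt)[0]  # um/ms
                if slope > 0 and dist.max() >= min_extent / 2:
                    slopes.append(slope * 1000.0)  # um/s
        if slopes:
            out["velocity"] = float(np.mean(slopes))
    return out


def wave_velocity_protocol(config: CellConfig, ca_nsr=1.55, seed=0,
                           duration=1400.0, ignite_planes=3,
                           ignite_ca_sm=30.0, clamp=True):
    """Measure Ca2+-wave front velocity from a seeded ignition region.

    At reduced lattice scale, spontaneous nucleation near the load
    threshold is dense relative to front traversal, so free-running waves
    form a patchwork with no macroscopic front.  Seeding an elevated-SM
    region at one longitudinal end launches a single unidirectional front
    into quiescent loaded tissue whose onset field is clean enough for the
    front-distance regression of :func:`wave_metrics`.

    Returns the wave_metrics dict.
    """
    state = init_state(config, seed=seed, ca_nsr=ca_nsr, ca_i=0.1)
    p = config.transport
    state.ca_sm[..., :ignite_planes] = ignite_ca_sm
    state.b_cam[..., :ignite_planes] = ca.bound_rapid(
        ignite_ca_sm, p.bt_cam_sm, p.koff_cam / p.kon_cam)
    state.b_sl[..., :ignite_planes] = ca.bound_rapid(
        ignite_ca_sm, p.bt_sl_sm, p.koff_sl / p.kon_sl)
    proto = Protocol(duration=duration, snapshot_every=10.0,
                     record_every=2.0,
                     nsr_clamp=float(ca_nsr) if clamp else None)
    trace = run_cell(config, state, proto, seed=seed)
    return wave_metrics(trace, config)


def overload_pacing_protocol(duration=20000.0) -> Protocol:
    """Ca2+-overload pacing protocol (1 Hz, RyR and Na+ ramps).

    RyR opening scale ramps 1.5x -> 5x over 0-5 s; [Na+]_i is held at 15 mM
    then ramped 15 -> 23 mM over 10-15 s; pair with a config whose Na/K
    pump is scaled to 10% (scale_nak=0.1) and beta-adrenergic mode applied.
    """
    return Protocol(
        duration=duration,
        stim_times=tuple(np.arange(0.0, duration, 1000.0)),
        stim_amplitude=80.0,
        opening_scale_ramp=PiecewiseLinear(
            np.array([0.0, 5000.0]), np.array([1.5, 5.0])),
        na_ramp=PiecewiseLinear(
            np.array([0.0, 10000.0, 15000.0]), np.array([15.0, 15.0, 23.0])),
        record_every=1.0)
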