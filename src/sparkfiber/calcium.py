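"""Deterministic Ca2+ transport on the release-site lattice.

Compartment layout per release site (volumes in um^3 = fL):

    JSR --(RyR release)--> dyadic subspace (SS) <--> submembrane shell (SM)
    SM <--> SM of the six lattice neighbours (longitudinal exchange 2x slower)
    SM <--> bulk cytosol (global, cell-averaged)
    cytosol --SERCA--> NSR (global) --refill--> JSR

Concentration units: uM for dyad/SM/cytosol, mM for JSR/NSR; time in ms.
Fluxes are expressed as concentration rates referred to the compartment named
in each helper's docstring; volume ratios convert between compartments.

Buffering: the SM carries explicit calmodulin and sarcolemmal-site buffer
ODEs (they relax on the same ~ms scale as the SM itself); the bulk cytosol
uses the rapid-buffering approximation (calmodulin + troponin); the JSR uses
rapid calsequestrin buffering; the NSR is treated as unbuffered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeGeometry",
    "TransportParams",
    "ReleaseSiteState",
    "GlobalCaState",
    "beta_rapid",
    "bound_rapid",
    "release_flux",
    "site_derivatives",
    "sm_diffusion_fluxes",
    "global_derivatives",
    "total_cell_calcium",
    "whole_cell_jryr",
    "sr_load_per_cytosol",
]


@dataclass
class LatticeGeometry:
    """Release-site lattice dimensions.

    Full scale is 25 x 20 x 50 = 25,000 sites spaced 1 um transversally
    (x, y) and 2 um longitudinally (z); reduced scales are configurable.
    """

    nx: int = 10
    ny: int = 8
    nz: int = 20
    spacing_transverse: float = 1.0    # um
    spacing_longitudinal: float = 2.0  # um
    sm_inner_radius: float = 100.0     # nm
    sm_outer_radius: float = 180.0     # nm
    sm_length: float = 1.0             # um

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("lattice counts must be >= 1")
        if self.spacing_transverse <= 0 or self.spacing_longitudinal <= 0:
            raise ValueError("spacings must be > 0")
        if self.sm_inner_radius >= self.sm_outer_radius:
            raise ValueError("sm_inner_radius must be < sm_outer_radius")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def longitudinal_extent(self) -> float:
        """Cell length along the fiber axis, um."""
        return self.nz * self.spacing_longitudinal


@dataclass
class TransportParams:
    """Inter-compartment Ca2+ transport rates, buffers, and volumes.

    Defaults are the package's calibrated baseline set (see docs/methods.md):
    they reproduce a diastolic [Ca2+]_i near 0.1 uM, a spontaneous-wave
    threshold SR load of ~140 umol/(L cytosol), and wave velocities in the
    50-100 um/s range.
    """

    # release and inter-compartment exchange
    k_rel: float = 12.0         # ms^-1; J_rel = k_rel*(n_open/N)*(ca_jsr-ca_d)
    tau_ds: float = 0.03        # ms, dyad <-> SM exchange (dyad-referred)
    tau_sm_trans: float = 28.0  # ms, SM <-> SM transverse exchange
    anisotropy: float = 2.0    # longitudinal tau = anisotropy * transverse
    tau_sm_cyto: float = 24.0  # ms, SM -> cytosol (SM-referred)
    tau_refill: float = 60.0   # ms, NSR -> JSR (JSR-referred)

    # SERCA pump (cytosol-referred), Hill coefficient 2
    v_serca: float = 0.30      # uM/ms
    k_serca: float = 0.42      # uM; halved under beta-adrenergic stimulation
    serca_hill: float = 2.0

    # SM buffers (explicit ODEs)
    bt_cam_sm: float = 24.0    # uM calmodulin sites
    kon_cam: float = 0.10      # uM^-1 ms^-1
    koff_cam: float = 0.238    # ms^-1  (Kd = 2.38 uM)
    bt_sl_sm: float = 300.0    # uM sarcolemmal sites
    kon_sl: float = 0.115      # uM^-1 ms^-1
    koff_sl: float = 1.0       # ms^-1  (Kd = 8.7 uM)

    # cytosolic rapid buffers
    bt_cmdn: float = 24.0      # uM
    kd_cmdn: float = 2.38      # uM
    bt_trpn: float = 70.0      # uM
    kd_trpn: float = 0.5       # uM

    # JSR calsequestrin (rapid)
    bt_csq: float = 10.0       # mM
    kd_csq: float = 0.63       # mM

    # per-site compartment volumes, um^3
    v_d: float = 1.0e-3
    v_sm: float = 0.0704       # cylinder pi*(0.18^2 - 0.10^2)*1 um
    v_jsr: float = 5.0e-3
    v_cyto: float = 0.50       # cytosol share per site
    v_nsr: float = 0.02        # NSR share per site

    n_ryr: int = 48

    def validate(self) -> None:
        for name in ("k_rel", "tau_ds", "tau_sm_trans", "tau_sm_cyto",
                     "tau_refill", "v_serca", "k_serca", "v_d", "v_sm",
                     "v_jsr", "v_cyto", "v_nsr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TransportParams.{name} must be > 0")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be > 0")


@dataclass
class ReleaseSiteState:
    """Per-site concentrations (arrays broadcast over the lattice)."""

    ca_d: np.ndarray     # uM
    ca_jsr: np.ndarray   # mM
    ca_sm: np.ndarray    # uM
    b_cam: np.ndarray    # uM bound calmodulin in SM
    b_sl: np.ndarray     # uM bound sarcolemmal buffer in SM


@dataclass
class GlobalCaState:
    """Cell-averaged cytosolic and network-SR Ca2+."""

    ca_i: float | np.ndarray   # uM
    ca_nsr: float | np.ndarray  # mM


def beta_rapid(ca, bt, kd):
    """Rapid-buffering fraction d[Ca_free]/d[Ca_total] for one buffer pool."""
    return 1.0 / (1.0 + bt * kd / (kd + ca) ** 2)


def bound_rapid(ca, bt, kd):
    """Equilibrium buffer-bound concentration."""
    return bt * ca / (kd + ca)


def beta_cyto(ca_i, p: TransportParams):
    return 1.0 / (1.0 + p.bt_cmdn * p.kd_cmdn / (p.kd_cmdn + ca_i) ** 2
                  + p.bt_trpn * p.kd_trpn / (p.kd_trpn + ca_i) ** 2)


def beta_jsr(ca_jsr, p: TransportParams):
    return 1.0 / (1.0 + p.bt_csq * p.kd_csq / (p.kd_csq + ca_jsr) ** 2)


def release_flux(n_ryr_open, ca_jsr, ca_d, p: TransportParams):
    """RyR release flux into the dyad, uM/ms dyad-referred.

    Proportional to the open fraction of the cluster and the JSR-dyad
    gradient (ca_jsr in mM -> x1000 to uM).
    """
    frac = np.asarray(n_ryr_open) / p.n_ryr
    return p.k_rel * frac * (1000.0 * np.asarray(ca_jsr) - np.asarray(ca_d))


def site_derivatives(site: ReleaseSiteState, n_ryr_open, lcc_flux,
                     globals_: GlobalCaState, p: TransportParams):
    """Time derivatives of the per-site compartments.

    Parameters
    ----------
    lcc_flux : LCC Ca2+ influx into the dyad, uM/ms dyad-referred.

    Returns
    -------
    dict with keys ``ca_d`` (uM/ms), ``ca_jsr`` (mM/ms), ``ca_sm`` (uM/ms,
    excluding lattice diffusion, which :func:`sm_diffusion_fluxes` adds),
    ``b_cam``/``b_sl`` (uM/ms) and ``j_ryr`` (the dyad-referred release
    flux itself).

    Pure function; SM<->SM diffusion and NCX extrusion are composed by the
    caller.
    """
    if np.any(np.asarray(n_ryr_open) < 0):
        raise ValueError("n_ryr_open must be >= 0")
    j_ryr = release_flux(n_ryr_open, site.ca_jsr, site.ca_d, p)
    j_ds = (site.ca_d - site.ca_sm) / p.tau_ds
    dca_d = j_ryr + lcc_flux - j_ds
    refill = (globals_.ca_nsr - site.ca_jsr) / p.tau_refill
    dca_jsr = beta_jsr(site.ca_jsr, p) * (
        refill - j_ryr * (p.v_d / p.v_jsr) / 1000.0)
    db_cam = (p.kon_cam * site.ca_sm * (p.bt_cam_sm - site.b_cam)
              - p.koff_cam * site.b_cam)
    db_sl = (p.kon_sl * site.ca_sm * (p.bt_sl_sm - site.b_sl)
             - p.koff_sl * site.b_sl)
    dca_sm = (j_ds * (p.v_d / p.v_sm)
              - (site.ca_sm - globals_.ca_i) / p.tau_sm_cyto
              - db_cam - db_sl)
    return {"ca_d": dca_d, "ca_jsr": dca_jsr, "ca_sm": dca_sm,
            "b_cam": db_cam, "b_sl": db_sl, "j_ryr": j_ryr}


def sm_diffusion_fluxes(ca_sm, geometry: LatticeGeometry, p: TransportParams):
    """Net nearest-neighbour SM diffusion flux per site, uM/ms (SM-referred).

    ``ca_sm`` has shape (..., nx, ny, nz); leading axes (e.g. cells of a
    fiber) are carried through.  Transverse exchange (x, y axes) uses
    tau_sm_trans; longitudinal exchange (z axis) is ``anisotropy`` times
    slower.  Boundaries are zero-flux, so the flux sums to zero over the
    lattice (pairwise antisymmetry).
    """
    ca_sm = np.asarray(ca_sm, dtype=float)
    if ca_sm.shape[-3:] != geometry.shape:
        raise ValueError(
            f"ca_sm lattice shape {ca_sm.shape[-3:]} does not match "
            f"geometry {geometry.shape}")
    out = np.zeros_like(ca_sm)
    rate_t = 1.0 / p.tau_sm_trans
    rate_l = rate_t / p.anisotropy
    for axis, rate in ((-3, rate_t), (-2, rate_t), (-1, rate_l)):
        d = np.diff(ca_sm, axis=axis)  # neighbour difference along axis
        lo = [slice(None)] * ca_sm.ndim
        hi = [slice(None)] * ca_sm.ndim
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        out[tuple(lo)] += rate * d
        out[tuple(hi)] -= rate * d
    return out


def global_derivatives(globals_: GlobalCaState, j_sm_cyto, j_ncx_cyto,
                       j_serca, j_refill_total, p: TransportParams,
                       j_other_cyto=0.0):
    """Derivatives of the global cytosolic and NSR pools.

    Parameters
    ----------
    j_sm_cyto : summed SM->cytosol flux, uM/ms cytosol-referred (in > 0)
    j_ncx_cyto : net sarcolemmal Ca2+ extrusion from the cytosolic pool,
        uM/ms cytosol-referred (out > 0)
    j_serca : SERCA uptake, uM/ms cytosol-referred
    j_refill_total : summed NSR->JSR refill, mM/ms NSR-referred
    j_other_cyto : optional extra cytosol-referred flux (background leak in)

    Returns (dca_i, dca_nsr) in (uM/ms, mM/ms).
    """
    dca_i = beta_cyto(globals_.ca_i, p) * (
        j_sm_cyto - j_serca - j_ncx_cyto + j_other_cyto)
    dca_nsr = j_serca * (p.v_cyto / p.v_nsr) / 1000.0 - j_refill_total
    return dca_i, dca_nsr


def serca_flux(ca_i, p: TransportParams):
    """SERCA uptake, uM/ms cytosol-referred (forward only)."""
    x = (np.asarray(ca_i) / p.k_serca) ** p.serca_hill
    return p.v_serca * x / (1.0 + x)


def total_cell_calcium(site: ReleaseSiteState, globals_: GlobalCaState,
                       p: TransportParams):
    """Total free + buffer-bound Ca2+ in the cell, fmol.

    Volume-weighted over dyads, SM (free + explicit buffers), JSR (free +
    calsequestrin), cytosol (free + rapid buffers) and NSR.  1 uM.um^3 =
    1e-6 fmol.
    """
    n_sites = np.asarray(site.ca_d).size
    amount = 0.0  # uM.um^3
    amount += np.sum(site.ca_d) * p.v_d
    amount += np.sum(site.ca_sm + site.b_cam + site.b_sl) * p.v_sm
    jsr_total = 1000.0 * (np.asarray(site.ca_jsr)
                          + bound_rapid(np.asarray(site.ca_jsr),
                                        p.bt_csq, p.kd_csq))
    amount += np.sum(jsr_total) * p.v_jsr
    ca_i = np.asarray(globals_.ca_i)
    cyto_total = (ca_i + bound_rapid(ca_i, p.bt_cmdn, p.kd_cmdn)
                  + bound_rapid(ca_i, p.bt_trpn, p.kd_trpn))
    amount += float(np.mean(cyto_total)) * p.v_cyto * n_sites
    amount += float(np.mean(globals_.ca_nsr)) * 1000.0 * p.v_nsr * n_sites
    return amount * 1.0e-6


def whole_cell_jryr(j_ryr_dyad, p: TransportParams):
    """Whole-cell release flux, uM/ms referred to the cytosolic volume.

    ``j_ryr_dyad`` is the per-site dyad-referred release flux; the sum of
    per-site amounts is renormalized by the total cytosolic volume.  With a
    common per-site cytosol share this reduces to mean(j) * v_d / v_cyto.
    Sums over the lattice axes; leading (cell) axes are preserved.
    """
    j = np.asarray(j_ryr_dyad, dtype=float)
    lattice_axes = tuple(range(j.ndim - 3, j.ndim)) if j.ndim >= 3 else None
    mean_j = np.mean(j, axis=lattice_axes) if lattice_axes else np.mean(j)
    return mean_j * (p.v_d / p.v_cyto)


def sr_load_per_cytosol(ca_jsr, ca_nsr, p: TransportParams):
    """SR Ca2+ content (free + calsequestrin-bound), umol/(L cytosol)."""
    jsr_total = 1000.0 * (np.asarray(ca_jsr, dtype=float)
                          + bound_rapid(np.asarray(ca_jsr, dtype=float),
                                        p.bt_csq, p.kd_csq))
    per_site = float(np.mean(jsr_total)) * p.v_jsr
    per_site += float(np.mean(np.asarray(ca_nsr, dtype=float))) * 1000.0 * p.v_nsr
    return per_site / p.v_cyto
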