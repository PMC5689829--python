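"""Sarcolemmal currents and single-cell voltage dynamics.

Current conventions: all currents are densities in pA/pF with outward
positive, so dV/dt = -(sum of ionic currents - I_stim - I_gap_in) in mV/ms
(1 pA/pF == 1 mV/ms for a 1 uF/cm^2 membrane).

The current set is a standard, calibrated complement: fast Na+ current with
m^3 h j gating (Luo-Rudy style rate functions), Boltzmann-rectified inward
rectifier I_K1, two-gate delayed rectifiers I_Kr / I_Ks, a saturating Na/K
ATPase, an electrogenic 3:1 Na/Ca exchanger evaluated against both the
submembrane and cytosolic Ca2+ pools (50/50 split), GHK-type unitary L-type
flux, and small background/pump terms.  Every maximal conductance carries a
protocol-scalable multiplier.

Half of the NCX population senses the submembrane [Ca2+] of the release-site
shells (summed per site); the other half senses the cell-averaged cytosolic
[Ca2+].  The inward NCX current during spontaneous release is what carries
delayed afterdepolarizations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "F_CONST", "RT_OVER_F", "PA_PER_UMUM3_MS_Z2",
    "MembraneParams", "MembraneState",
    "ncx_current", "ik1_current", "ina_current", "ikr_current", "iks_current",
    "inak_current", "icab_current", "ipca_current", "lcc_unitary_flux",
    "nernst", "membrane_rhs", "gate_infs_taus",
    "apply_beta_adrenergic", "remove_beta_adrenergic",
]

F_CONST = 96.485       # C/mmol
RT_OVER_F = 26.712     # mV at 310 K
# 1 uM.um^3/ms of divalent flux corresponds to this many pA
PA_PER_UMUM3_MS_Z2 = 2.0 * F_CONST * 1.0e-3  # = 0.19297


@dataclass
class MembraneParams:
    """Conductances (mS/uF ~ pA/pF/mV), permeabilities and fixed ions."""

    g_na: float = 13.0
    g_k1: float = 0.42
    g_kr: float = 0.042
    g_ks: float = 0.0104
    i_nak_max: float = 1.05     # pA/pF
    km_nai: float = 10.0        # mM
    km_ko: float = 1.5          # mM
    k_ncx: float = 315.0        # pA/pF scale of the exchanger numerator
    km_na_ncx: float = 87.5     # mM
    km_ca_ncx: float = 1.38     # mM
    ksat_ncx: float = 0.27
    eta_ncx: float = 0.35
    ncx_sm_fraction: float = 0.5
    g_cab: float = 2.1e-4       # background Ca2+ conductance
    i_pca_max: float = 0.052    # sarcolemmal Ca2+ pump, pA/pF
    km_pca: float = 0.45        # uM
    p_lcc: float = 20.0         # unitary LCC flux scale (uM/ms dyad-referred)
    cm_per_site: float = 0.004  # pF of membrane per release site
    g_leak: float = 0.0         # linear leak (passive-membrane mode)
    e_leak: float = -90.0       # mV

    # protocol-scalable multipliers
    scale_k1: float = 1.0
    scale_na: float = 1.0
    scale_kr: float = 1.0
    scale_ks: float = 1.0
    scale_ncx: float = 1.0
    scale_nak: float = 1.0
    iks_shift: float = 0.0      # mV shift of I_Ks activation (beta-AR: -35)

    # fixed ionic concentrations, mM
    na_o: float = 140.0
    ca_o: float = 1.8
    k_o: float = 5.0
    k_i: float = 145.0
    prnak: float = 0.01833      # Na+ permeability ratio in E_Ks

    def validate(self) -> None:
        for name in ("g_na", "g_k1", "g_kr", "g_ks", "i_nak_max", "k_ncx",
                     "g_cab", "i_pca_max", "p_lcc", "cm_per_site"):
            if getattr(self, name) < 0:
                raise ValueError(f"MembraneParams.{name} must be >= 0")
        if not 0.0 <= self.ncx_sm_fraction <= 1.0:
            raise ValueError("ncx_sm_fraction must lie in [0, 1]")


@dataclass
class MembraneState:
    """Voltage, channel gates, and intracellular Na+ (scalar or per-cell)."""

    v: float | np.ndarray = -90.0
    m: float | np.ndarray = 0.0
    h: float | np.ndarray = 0.99
    j: float | np.ndarray = 0.99
    xr: float | np.ndarray = 0.0
    xs: float | np.ndarray = 0.0
    na_i: float | np.ndarray = 10.0  # mM; protocol-controlled


def nernst(z, c_out, c_in):
    return RT_OVER_F / z * np.log(c_out / c_in)


def ncx_current(v, na_i, ca_local, p: MembraneParams, scale=None):
    """Electrogenic 3Na+:1Ca2+ exchanger current, pA/pF.

    ``ca_local`` is the sensed Ca2+ in uM (SM or cytosolic pool).  Inward
    (negative) current corresponds to Ca2+ extrusion.  Zero at
    v = 3 E_Na - 2 E_Ca.
    """
    if scale is None:
        scale = p.scale_ncx
    ca_mm = np.asarray(ca_local, dtype=float) / 1000.0
    ef1 = np.exp(p.eta_ncx * np.asarray(v) / RT_OVER_F)
    ef2 = np.exp((p.eta_ncx - 1.0) * np.asarray(v) / RT_OVER_F)
    num = ef1 * np.asarray(na_i) ** 3 * p.ca_o - ef2 * p.na_o ** 3 * ca_mm
    den = ((p.km_na_ncx ** 3 + p.na_o ** 3) * (p.km_ca_ncx + p.ca_o)
           * (1.0 + p.ksat_ncx * ef2))
    return scale * p.k_ncx * num / den


def ik1_current(v, scale, p: MembraneParams):
    """Inward-rectifier K+ current: Boltzmann rectification x (v - E_K).

    Outward conductance declines with depolarization above ~ -60 mV; the
    current scales linearly with ``scale`` (1.0 = normal density).
    """
    e_k = nernst(1, p.k_o, p.k_i)
    rect = 1.0 / (1.0 + np.exp((np.asarray(v) - e_k - 15.0) / 8.0))
    return scale * p.g_k1 * rect * (np.asarray(v) - e_k)


def _safe_exp_ratio(num_coeff, v, c, denom_scale):
    # a*(v+c)/(1-exp(-k*(v+c))) with the v -> -c limit handled
    x = np.asarray(v, dtype=float) + c
    small = np.abs(x) < 1e-7
    xs = np.where(small, 1.0, x)
    out = num_coeff * xs / (1.0 - np.exp(-denom_scale * xs))
    return np.where(small, num_coeff / denom_scale, out)


def ina_gate_rates(v):
    """Luo-Rudy 1991 alpha/beta rates for m, h, j (ms^-1)."""
    v = np.asarray(v, dtype=float)
    am = _safe_exp_ratio(0.32, v, 47.13, 0.1)
    bm = 0.08 * np.exp(-v / 11.0)
    low = v < -40.0
    ah = np.where(low, 0.135 * np.exp(-(80.0 + v) / 6.8), 0.0)
    bh = np.where(low,
                  3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
                  1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    aj = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0)
    bj = np.where(
        low,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))
    return am, bm, ah, bh, aj, bj


def ina_current(v, m, h, j, na_i, p: MembraneParams):
    e_na = nernst(1, p.na_o, na_i)
    return p.scale_na * p.g_na * m ** 3 * h * j * (np.asarray(v) - e_na)


def ikr_current(v, xr, p: MembraneParams):
    e_k = nernst(1, p.k_o, p.k_i)
    r = 1.0 / (1.0 + np.exp((np.asarray(v) + 9.0) / 22.4))
    return p.scale_kr * p.g_kr * xr * r * (np.asarray(v) - e_k)


def iks_current(v, xs, na_i, p: MembraneParams):
    e_ks = RT_OVER_F * np.log((p.k_o + p.prnak * p.na_o)
                              / (p.k_i + p.prnak * np.asarray(na_i)))
    return p.scale_ks * p.g_ks * xs ** 2 * (np.asarray(v) - e_ks)


def inak_current(v, na_i, p: MembraneParams):
    sigma = (np.exp(p.na_o / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * np.asarray(v) / RT_OVER_F)
                   + 0.0365 * sigma * np.exp(-np.asarray(v) / RT_OVER_F))
    return (p.scale_nak * p.i_nak_max * f_nak
            * (p.k_o / (p.k_o + p.km_ko))
            / (1.0 + (p.km_nai / np.asarray(na_i)) ** 1.5))


def icab_current(v, ca_i, p: MembraneParams):
    e_ca = nernst(2, p.ca_o, np.asarray(ca_i) / 1000.0)
    return p.g_cab * (np.asarray(v) - e_ca)


def ipca_current(ca_i, p: MembraneParams):
    return p.i_pca_max * np.asarray(ca_i) / (p.km_pca + np.asarray(ca_i))


def lcc_unitary_flux(v, ca_d, p: MembraneParams):
    """GHK unitary L-type Ca2+ flux into the dyad, uM/ms (dyad-referred).

    Positive = influx.  ``ca_d`` in uM; activity coefficients 1 and 0.341
    for the internal/external solutions.
    """
    v = np.asarray(v, dtype=float)
    u = 2.0 * v / RT_OVER_F
    small = np.abs(u) < 1e-7
    us = np.where(small, 1.0, u)
    expu = np.exp(us)
    ca_d_mm = np.asarray(ca_d, dtype=float) / 1000.0
    grad = ca_d_mm * expu - 0.341 * p.ca_o
    frac = np.where(small, ca_d_mm - 0.341 * p.ca_o, us * grad / (expu - 1.0))
    # influx-only: the unitary L-type current does not reverse at
    # physiological potentials; the nominal GHK reversal against the
    # single bulk-dyad Ca2+ during a spark is a compartment artifact
    return np.maximum(-p.p_lcc * 100.0 * frac, 0.0)


def lcc_flux_coeffs(v, p: MembraneParams):
    """Decompose the GHK unitary flux as a(v) - b(v) * ca_d (uM).

    The flux is exactly linear in the internal concentration, which lets
    the dyad integrator treat the LCC term implicitly (no reversal
    overshoot).  Returns (a, b) with a in uM/ms and b in ms^-1.
    """
    v = np.asarray(v, dtype=float)
    u = 2.0 * v / RT_OVER_F
    small = np.abs(u) < 1e-7
    us = np.where(small, 1.0, u)
    expu = np.exp(us)
    ratio = np.where(small, 1.0, us * expu / (expu - 1.0))
    ratio_out = np.where(small, 1.0, us / (expu - 1.0))
    a = p.p_lcc * 100.0 * 0.341 * p.ca_o * ratio_out
    b = p.p_lcc * 100.0 * ratio / 1000.0
    return a, b


def lcc_reversal_ca(v, p: MembraneParams):
    """Dyadic [Ca2+] (uM) above which the nominal GHK flux would reverse."""
    a, b = lcc_flux_coeffs(v, p)
    return a / b


def gate_infs_taus(v, p: MembraneParams):
    """Steady states and time constants for the HH-style gates.

    Returns dict of (x_inf, tau_x) pairs for m, h, j, xr, xs (tau in ms).
    """
    am, bm, ah, bh, aj, bj = ina_gate_rates(v)
    out = {}
    for name, a, b in (("m", am, bm), ("h", ah, bh), ("j", aj, bj)):
        tau = 1.0 / (a + b)
        out[name] = (a * tau, tau)
    v = np.asarray(v, dtype=float)
    xr_inf = 1.0 / (1.0 + np.exp(-(v + 21.5) / 7.5))
    tau_xr = 1.0 + 250.0 / (1.0 + np.exp((v + 35.0) / 10.0)) + 50.0
    out["xr"] = (xr_inf, tau_xr)
    xs_inf = 1.0 / (1.0 + np.exp(-(v - 1.5 - p.iks_shift) / 16.7))
    tau_xs = 990.0 / (1.0 + np.exp(-(v + 2.4) / 14.0)) + 60.0
    out["xs"] = (xs_inf, tau_xs)
    return out


def membrane_rhs(state: MembraneState, currents: dict, p: MembraneParams,
                 i_stim=0.0, i_gap_in=0.0, clamped=False):
    """dV/dt (mV/ms) and gate derivatives from a dict of named currents.

    ``currents`` maps current name -> pA/pF (outward positive).  Any NaN in
    a current raises with the offending name.  In clamped mode dV/dt = 0.
    """
    total = 0.0
    for name, value in currents.items():
        if np.any(np.isnan(value)):
            raise FloatingPointError(f"NaN encountered in current {name!r}")
        total = total + value
    dv = 0.0 if clamped else -(total - i_stim - i_gap_in)
    gates = gate_infs_taus(state.v, p)
    dgates = {name: (inf - getattr(state, name)) / tau
              for name, (inf, tau) in gates.items()}
    return dv, dgates


# ---------------------------------------------------------------------------
# Beta-adrenergic parameter mode
# ---------------------------------------------------------------------------

_BETA_OPENING_SCALES = {"leak": 1.5, "ouabain": 4.0}


def apply_beta_adrenergic(config, opening_scale="leak", high_fraction=0.04):
    """Return a copy of a cell config with beta-adrenergic modifications.

    Deltas applied: LCC gating fraction 0.25 -> 0.60 with ``high_fraction``
    (3-5%) of channels in high-activity mode; I_Ks activation shifted by
    -35 mV and conductance +40%; I_Kr enhanced (+30% conductance); SERCA K_d
    halved; RyR opening_scale x1.5 ("leak") or x4.0 ("ouabain").

    Applying the mode twice raises; :func:`remove_beta_adrenergic` undoes it.
    """
    if getattr(config, "beta_ar", False):
        raise ValueError("beta-adrenergic mode already applied (idempotency guard)")
    if isinstance(opening_scale, str):
        try:
            opening_scale = _BETA_OPENING_SCALES[opening_scale]
        except KeyError:
            raise ValueError(
                f"unknown opening_scale option {opening_scale!r}; "
                f"choose from {sorted(_BETA_OPENING_SCALES)} or a number")
    gating = replace(
        config.gating,
        lcc_gating_fraction=0.60,
        lcc_high_fraction=high_fraction,
        opening_scale=config.gating.opening_scale * opening_scale,
    )
    transport = replace(config.transport,
                        k_serca=config.transport.k_serca * 0.5)
    membrane = replace(config.membrane,
                       iks_shift=config.membrane.iks_shift - 35.0,
                       scale_ks=config.membrane.scale_ks * 1.4,
                       scale_kr=config.membrane.scale_kr * 1.3)
    return replace(config, gating=gating, transport=transport,
                   membrane=membrane, beta_ar=True,
                   beta_opening_scale=float(opening_scale))


def remove_beta_adrenergic(config):
    """Invert :func:`apply_beta_adrenergic` exactly."""
    if not getattr(config, "beta_ar", False):
        raise ValueError("beta-adrenergic mode is not applied")
    gating = replace(
        config.gating,
        lcc_gating_fraction=0.25,
        lcc_high_fraction=0.0,
        opening_scale=config.gating.opening_scale / config.beta_opening_scale,
    )
    transport = replace(config.transport,
                        k_serca=config.transport.k_serca * 2.0)
    membrane = replace(config.membrane,
                       iks_shift=config.membrane.iks_shift + 35.0,
                       scale_ks=config.membrane.scale_ks / 1.4,
                       scale_kr=config.membrane.scale_kr / 1.3)
    return replace(config, gating=gating, transport=transport,
                   membrane=membrane, beta_ar=False, beta_opening_scale=1.0)
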