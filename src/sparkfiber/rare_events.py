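"""Rare-event estimation for extreme delayed afterdepolarizations.

Membrane-potential fluctuations along a fiber are driven by the whole-cell
SR release flux J_RyR(x, t); electrotonic coupling makes the peak diastolic
potential of a cell an average of release activity over a window of
neighbours.  The method here:

1. smooths J_RyR with a uniform spatial filter of odd width W,
       J^f(x,t) = (1/W) sum_{k=-(W-1)/2}^{(W-1)/2} J(x+k, t);
2. takes the per-cell temporal maximum J^f_max(x) = max_t J^f(x,t);
3. picks W maximizing the squared Pearson correlation between simulated
   V_max and J^f_max, and z-score-normalizes to predict
       V^f_max(x) = mu_V + (sigma_V / sigma_J) (J^f_max(x) - mu_J);
4. generates independent fiber realizations by shuffling interior cell
   positions of the J_RyR profile (spontaneous release is decoupled across
   cells), yielding the tail of the V_peak = max_x V_max(x) distribution
   from millions of cheap resampled realizations.

The summary S_V = (sigma_V / sigma_J) / W scales with the SD of the
predicted V^f_max: smaller filter windows and steeper V-J relations both
widen the predicted distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FluxMatrix", "FilterModel", "TailEstimate", "REFERENCE_FILTER_FITS",
    "spatial_filter", "jf_max", "fit_filter_model", "predict_vmax",
    "shuffle_realization", "estimate_tail", "s_v", "expected_waiting_time",
    "validate_method",
]


@dataclass
class FluxMatrix:
    """Spatiotemporal whole-cell J_RyR over a fiber, uM/ms, (cell, time)."""

    values: np.ndarray
    dt: float                    # ms between columns
    interior: np.ndarray         # bool mask; False = boundary-buffer cell

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.interior = np.asarray(self.interior, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (cells x times)")
        if self.interior.size != self.values.shape[0]:
            raise ValueError("interior mask length must equal n_cells")
        if np.any(self.values < -1e-12):
            raise ValueError("J_RyR values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class FilterModel:
    """Fitted spatial-filter parameters mapping J_RyR to predicted V_max."""

    w: int                 # odd filter width, cells
    mu_v: float            # mV
    sigma_v: float         # mV
    mu_j: float            # uM/ms
    sigma_j: float         # uM/ms
    r2: float

    def __post_init__(self):
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("W must be an odd integer >= 1")
        if self.sigma_v <= 0 or self.sigma_j <= 0:
            raise ValueError("sigma_V and sigma_J must be > 0")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


#: Published filter fits for the three remodeling conditions (reference
#: parameter sets; mu/sigma in mV and uM/ms, W in cells).
REFERENCE_FILTER_FITS = {
    "baseline": FilterModel(w=43, mu_v=-77.0, sigma_v=0.665,
                            mu_j=0.526, sigma_j=0.00873, r2=0.900),
    "ik1_50": FilterModel(w=49, mu_v=-78.3, sigma_v=1.38,
                          mu_j=0.248, sigma_j=0.0124, r2=0.946),
    "ik1_50_ggap_50": FilterModel(w=27, mu_v=-79.1, sigma_v=1.34,
                                  mu_j=0.242, sigma_j=0.0150, r2=0.953),
}


@dataclass
class TailEstimate:
    """Exceedance-probability curve of V_peak relative to mu_V."""

    thresholds: np.ndarray       # mV above mu_V
    probabilities: np.ndarray
    standard_errors: np.ndarray
    n_realizations: int
    max_exceedance: float        # largest observed V_peak - mu_V, mV
    seed: int

    def __post_init__(self):
        p = np.asarray(self.probabilities)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("exceedance probabilities must be non-increasing")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _window_margin(interior):
    """Largest half-window that keeps every interior cell's window on-fiber."""
    idx = np.flatnonzero(interior)
    if idx.size == 0:
        return 0
    return int(min(idx[0], interior.size - 1 - idx[-1]))


def _check_w(w, n_cells):
    w = int(w)
    if w < 1 or w % 2 == 0 or w > n_cells:
        raise ValueError(f"W must be odd and within [1, {n_cells}], got {w}")
    return w


def spatial_filter(j: FluxMatrix | np.ndarray, w: int) -> np.ndarray:
    """Uniform moving average of width ``w`` along the cell axis.

    Positions whose window would overhang the fiber ends are NaN; all other
    positions (in particular every interior cell when the boundary buffer
    is at least (w-1)/2 wide) use the actual neighbour values, boundary
    cells included.
    """
    values = j.values if isinstance(j, FluxMatrix) else np.asarray(j, float)
    n_cells = values.shape[0]
    w = _check_w(w, n_cells)
    half = (w - 1) // 2
    out = np.full_like(values, np.nan, dtype=float)
    if w == 1:
        return values.astype(float).copy()
    csum = np.cumsum(values, axis=0)
    pad = np.vstack([np.zeros((1,) + csum.shape[1:]), csum])
    out[half:n_cells - half] = (pad[w:] - pad[:-w]) / w
    return out


def jf_max(filtered: np.ndarray, return_times=False):
    """Per-cell maximum of the filtered flux over time (NaN rows stay NaN).

    Ties resolve to the earliest time index.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 2 or filtered.shape[1] < 1:
        raise ValueError("need a 2D matrix with a non-empty time axis")
    valid = ~np.isnan(filtered).all(axis=1)
    out = np.full(filtered.shape[0], np.nan)
    out[valid] = np.max(filtered[valid], axis=1)
    if return_times:
        tidx = np.full(filtered.shape[0], -1)
        tidx[valid] = np.argmax(filtered[valid], axis=1)
        return out, tidx
    return out


def fit_filter_model(j: FluxMatrix, v_max, w_candidates=None,
                     min_interior=50) -> FilterModel:
    """Select W maximizing r^2 between V_max and J^f_max over interior cells.

    ``v_max`` is the per-cell simulated peak diastolic potential (mV).
    Ties in r^2 resolve to the smaller W.  mu/sigma are the interior-cell
    mean/SD (sample SD) of V_max and of J^f_max at the chosen W.
    """
    v_max = np.asarray(v_max, dtype=float)
    if v_max.size != j.n_cells:
        raise ValueError("v_max length must equal n_cells")
    interior = j.interior
    if interior.sum() < min_interior:
        raise ValueError(f"need >= {min_interior} interior cells")
    if w_candidates is None:
        w_candidates = range(1, min(102, 2 * _window_margin(interior) + 2), 2)
    vv = v_max[interior]
    if np.std(vv) == 0:
        raise ValueError("degenerate fit: V_max has zero variance")
    best = None
    for w in w_candidates:
        w = _check_w(w, j.n_cells)
        jm = jf_max(spatial_filter(j, w))[interior]
        if np.any(np.isnan(jm)):
            raise ValueError(
                f"W={w}: filter window overhangs the fiber for interior "
                "cells; widen the boundary buffer or restrict w_candidates")
        if np.std(jm) == 0:
            continue
        r2 = float(np.corrcoef(vv, jm)[0, 1] ** 2)
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, w, jm)
    if best is None:
        raise ValueError("degenerate fit: J^f_max has zero variance at all W")
    r2, w, jm = best
    return FilterModel(
        w=w, mu_v=float(np.mean(vv)), sigma_v=float(np.std(vv, ddof=1)),
        mu_j=float(np.mean(jm)), sigma_j=float(np.std(jm, ddof=1)), r2=r2)


def predict_vmax(j: FluxMatrix, model: FilterModel) -> np.ndarray:
    """Predicted per-cell V_max (mV): z-score-matched affine map of J^f_max."""
    jm = jf_max(spatial_filter(j, model.w))
    return model.mu_v + (model.sigma_v / model.sigma_j) * (jm - model.mu_j)


def s_v(model: FilterModel) -> float:
    """S_V = (sigma_V / sigma_J) / W, proportional to the SD of V^f_max."""
    return (model.sigma_v / model.sigma_j) / model.w


def expected_waiting_time(p_per_beat, beat_rate_hz):
    """Expected waiting time in days for an event of per-beat probability p."""
    if not 0.0 <= p_per_beat <= 1.0:
        raise ValueError("p_per_beat must lie in [0, 1]")
    if beat_rate_hz <= 0:
        raise ValueError("beat_rate_hz must be > 0")
    if p_per_beat == 0.0:
        return np.inf
    seconds = (1.0 / p_per_beat) / beat_rate_hz
    return seconds / 86400.0


def shuffle_realization(j: FluxMatrix, rng, mode="permute",
                        pool=None) -> FluxMatrix:
    """Resample a fiber by shuffling interior cell positions of J_RyR.

    ``mode='permute'`` permutes the fiber's own interior rows;
    ``mode='replace'`` fills interior positions by sampling (with
    replacement) rows from ``pool`` (default: the fiber's interior rows).
    Boundary-buffer positions keep their quiescent profiles and time axes
    are untouched.
    """
    idx = np.flatnonzero(j.interior)
    if idx.size < 1:
        raise ValueError("empty interior-cell pool")
    values = j.values.copy()
    if mode == "permute":
        values[idx] = j.values[idx][rng.permutation(idx.size)]
    elif mode == "replace":
        pool_rows = (j.values[idx] if pool is None
                     else np.asarray(pool, dtype=float))
        if pool_rows.shape[0] < 1:
            raise ValueError("empty interior-cell pool")
        pick = rng.integers(0, pool_rows.shape[0], size=idx.size)
        values[idx] = pool_rows[pick]
    else:
        raise ValueError("mode must be 'permute' or 'replace'")
    return FluxMatrix(values=values, dt=j.dt, interior=j.interior.copy())


def estimate_tail(j: FluxMatrix, model: FilterModel, n_realizations,
                  thresholds, seed=0, mode="replace",
                  pool=None) -> TailEstimate:
    """Empirical upper tail of V_peak - mu_V over resampled realizations.

    Each realization: shuffle -> spatial filter -> J^f_max -> predicted
    V_max -> V_peak (max over interior cells).  Returns exceedance
    probabilities P(V_peak - mu_V > theta) with binomial standard errors.
    """
    n_realizations = int(n_realizations)
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    rng = np.random.default_rng(seed)
    interior = j.interior
    exceed = np.zeros(n_realizations)
    for i in range(n_realizations):
        real = shuffle_realization(j, rng, mode=mode, pool=pool)
        vf = predict_vmax(real, model)
        exceed[i] = np.nanmax(vf[interior]) - model.mu_v
    probs = np.array([(exceed > th).mean() for th in thresholds])
    se = np.sqrt(probs * (1.0 - probs) / n_realizations)
    return TailEstimate(thresholds=thresholds, probabilities=probs,
                        standard_errors=se, n_realizations=n_realizations,
                        max_exceedance=float(exceed.max()), seed=seed)


def validate_method(flux_list, vmax_list, w_candidates=None, n_shuffle=None,
                    seed=0, min_interior=50, subset_size=5):
    """Compare V_peak from full simulation, filter-only, and filter+shuffle.

    Parameters
    ----------
    flux_list : list of FluxMatrix, fully simulated fibers
    vmax_list : matching list of per-cell simulated V_max arrays

    Fits one filter model on the pooled interior cells of all fibers, then
    reports the mean bias (filter-only and filter+shuffle vs simulation)
    and Kruskal-Wallis p-values after mean-centering, plus a rerun whose
    model and shuffle pool use only ``subset_size`` fibers (pool-size
    sufficiency check).
    """
    if len(flux_list) < 2 or len(flux_list) != len(vmax_list):
        raise ValueError("need >= 2 fibers with matching v_max arrays")
    rng = np.random.default_rng(seed)
    if n_shuffle is None:
        n_shuffle = len(flux_list)

    def fit_pooled(fluxes, vmaxes):
        big = FluxMatrix(
            values=np.vstack([f.values for f in fluxes]),
            dt=fluxes[0].dt,
            interior=np.concatenate([f.interior for f in fluxes]))
        # guard the per-fiber window: fit on each fiber's interior jointly
        vv = np.concatenate([np.asarray(v) for v in vmaxes])
        if w_candidates is None:
            margin = min(_window_margin(f.interior) for f in fluxes)
            cands = range(1, min(102, 2 * margin + 2), 2)
        else:
            cands = w_candidates
        best = None
        for w in cands:
            jms, ok = [], True
            for f in fluxes:
                jm = jf_max(spatial_filter(f, w))
                if np.any(np.isnan(jm[f.interior])):
                    ok = False
                    break
                jms.append(jm[f.interior])
            if not ok:
                continue
            jm_all = np.concatenate(jms)
            v_all = vv[big.interior]
            if np.std(jm_all) == 0 or np.std(v_all) == 0:
                continue
            r2 = float(np.corrcoef(v_all, jm_all)[0, 1] ** 2)
            if best is None or r2 > best[0] + 1e-15:
                best = (r2, w, jm_all, v_all)
        if best is None:
            raise ValueError("degenerate pooled fit")
        r2, w, jm_all, v_all = best
        return FilterModel(
            w=w, mu_v=float(np.mean(v_all)),
            sigma_v=float(np.std(v_all, ddof=1)),
            mu_j=float(np.mean(jm_all)),
            sigma_j=float(np.std(jm_all, ddof=1)), r2=r2)

    def peaks(model, fluxes, vmaxes, shuffle):
        true_p, filt_p, shuf_p = [], [], []
        for f, v in zip(fluxes, vmaxes):
            true_p.append(np.max(np.asarray(v)[f.interior]))
            filt_p.append(np.nanmax(predict_vmax(f, model)[f.interior]))
        pool = np.vstack([f.values[f.interior] for f in fluxes])
        for k in range(shuffle):
            f = fluxes[k % len(fluxes)]
            real = shuffle_realization(f, rng, mode="replace", pool=pool)
            shuf_p.append(np.nanmax(predict_vmax(real, model)[f.interior]))
        return map(np.asarray, (true_p, filt_p, shuf_p))

    def compare(a, b):
        bias = float(np.mean(b) - np.mean(a))
        p = float(stats.kruskal(a - np.mean(a), b - np.mean(b)).pvalue)
        return bias, p

    model = fit_pooled(flux_list, vmax_list)
    true_p, filt_p, shuf_p = peaks(model, flux_list, vmax_list, n_shuffle)
    bias_f, p_f = compare(true_p, filt_p)
    bias_s, p_s = compare(true_p, shuf_p)
    out = {"model": model,
           "bias_filter": bias_f, "p_filter": p_f,
           "bias_shuffle": bias_s, "p_shuffle": p_s,
           "v_peak_sim": true_p, "v_peak_filter": filt_p,
           "v_peak_shuffle": shuf_p}
    if len(flux_list) > subset_size:
        sub_model = fit_pooled(flux_list[:subset_size],
                               vmax_list[:subset_size])
        _, _, sub_shuf = peaks(sub_model, flux_list[:subset_size],
                               vmax_list[:subset_size], n_shuffle)
        bias_sub, p_sub = compare(true_p, sub_shuf)
        out.update({"bias_subset": bias_sub, "p_subset": p_sub,
                    "subset_model": sub_model})
    return out
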