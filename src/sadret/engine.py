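"""Dual-space phase-retrieval engine for anomalous substructures.

The iteration alternates a reciprocal-space constraint (measured moduli
replace calculated ones; optional pi-half phase perturbation of the
weakest observed reflections; optional tangent-formula refinement of the
strongest ones) with a relaxed real-space constraint that mixes the
current and previous density maps below a dynamic low-density threshold.
Plain charge flipping and unmodified relaxation are available as baseline
algorithm variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .records import DensityGrid, ReflectionSet
from .symmetry import SpaceGroupOps, UnitCell, generate_asu_indices

__all__ = [
    "EngineConfig",
    "TrialResult",
    "EngineSetup",
    "n_tf_rule",
    "amplitude_projection",
    "pi_half_perturb",
    "tangent_refine",
    "triplet_sums",
    "raar_real_space",
    "cf_real_space",
    "cc_pearson",
    "monitor_fom",
    "init_random_density",
    "run_trial",
    "run_multi",
    "fft_grid_dims",
]

log = logging.getLogger(__name__)

ALGORITHMS = ("cf", "raar", "raar_pihalf", "raar_pihalf_tf")
W_BEST_GRID = (0.20, 0.30, 0.40, 0.50)


@dataclass
class EngineConfig:
    """Tunable parameters of the retrieval iteration."""

    beta: float = 0.82
    perturb_fraction: float = 0.13
    w_best: object = "auto"  # fraction in [0, 1] or "auto"
    n_tf: int = None  # None -> size-based rule
    tf_start: int = 100
    tf_stride: int = 20
    tf_early: bool = True  # apply every iteration before tf_start
    n_iter: int = 500
    n_trials: int = 400
    algorithm: str = "raar_pihalf_tf"
    seed: int = 0
    delta_mode: str = "fraction_perturbed"  # or "fraction_passed"
    weak_mode: str = "static"  # or "dynamic"
    weak_keep_calc: bool = False
    pi_half_sign: int = 1
    cc_jump: float = 0.05
    cc_window: int = 50
    grid_factor: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if not 0 < self.perturb_fraction < 1:
            raise ValueError("perturb_fraction must lie in (0, 1)")
        if self.w_best != "auto" and not 0.0 <= float(self.w_best) <= 1.0:
            raise ValueError("w_best must be 'auto' or a fraction in [0, 1]")
        if self.n_iter < 1 or self.n_trials < 1:
            raise ValueError("n_iter and n_trials must be >= 1")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.delta_mode not in ("fraction_perturbed", "fraction_passed"):
            raise ValueError("bad delta_mode")
        if self.pi_half_sign not in (1, -1):
            raise ValueError("pi_half_sign must be +1 or -1")


@dataclass
class TrialResult:
    """Outcome of one random-start trial."""

    cc_trace: np.ndarray
    final_phases: np.ndarray
    final_density: DensityGrid
    best_cc: float
    seed: int
    converged: bool
    jump_iter: int = None
    w_best: float = None
    failed: bool = False


def n_tf_rule(n_obs: int) -> int:
    """Size of the tangent-refined strong set from the observed count."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if n_obs < 5000:
        n = 1000
    elif n_obs < 8000:
        n = 1300
    else:
        n = 1500
    return min(n, n_obs)


_FAST_SIZES = sorted(
    {
        2**a * 3**b * 5**c
        for a in range(1, 11)
        for b in range(7)
        for c in range(5)
        if 2**a * 3**b * 5**c <= 1024
    }
)


def fft_grid_dims(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple:
    """Smallest even FFT-friendly grid with spacing <= d_min / factor."""
    rstar = cell.reciprocal_metric
    dims = []
    for i in range(3):
        hmax = int(np.floor(1.0 / (d_min * np.sqrt(rstar[i, i]))))
        need = max(2 * hmax + 1, int(np.ceil(factor * cell.lengths[i] / d_min)))
        good = [n for n in _FAST_SIZES if n >= need]
        if not good:
            raise ValueError(
                f"grid dimension {need} along axis {i} exceeds supported sizes; "
                "aliasing would corrupt the synthesis"
            )
        dims.append(good[0])
    return tuple(dims)


def convolution_grid_dims(hmax) -> tuple:
    """Smallest even FFT-friendly grid free of wrap-around in a squared map.

    Cyclic convolution of coefficients with |h_i| <= hmax_i is exact on a
    grid with dims_i >= 3 * hmax_i + 1 (difference vectors cannot alias
    back onto occupied indices).
    """
    dims = []
    for hm in np.atleast_1d(np.asarray(hmax, dtype=int)):
        good = [n for n in _FAST_SIZES if n >= 3 * hm + 1]
        if not good:
            raise ValueError(f"convolution grid for hmax={hm} exceeds supported sizes")
        dims.append(good[0])
    return tuple(dims)


# ---------------------------------------------------------------------------
# elementary operations (array-level, independently testable)
# ---------------------------------------------------------------------------

def amplitude_projection(calc: ReflectionSet, obs: ReflectionSet) -> ReflectionSet:
    """Reciprocal-space moduli constraint.

    Observed reflections take the measured normalized amplitude and keep
    the calculated phase; unobserved in-limit reflections pass through
    untouched; absent and beyond-limit reflections are zeroed.
    """
    if not np.array_equal(calc.hkl, obs.hkl):
        raise ValueError("calc and obs must share the same index ordering")
    out = calc.copy()
    mask = obs.observed & ~obs.absent & ~obs.beyond
    out.E = np.where(mask, obs.E, calc.E)
    zero = obs.absent | obs.beyond
    out.E[zero] = 0.0
    out.observed = obs.observed.copy()
    out.absent = obs.absent.copy()
    out.beyond = obs.beyond.copy()
    return out


def pi_half_perturb(
    refl: ReflectionSet, w_best: float, sign: int = 1
) -> ReflectionSet:
    """Shift the phases of the weakest observed reflections by 90 degrees.

    The weak set is the floor(w_best * n_obs) observed reflections with the
    smallest E; everything else is untouched.
    """
    out = refl.copy()
    obs_idx = np.flatnonzero(refl.observed & ~refl.absent & ~refl.beyond)
    n_weak = int(np.floor(w_best * len(obs_idx)))
    if n_weak == 0:
        return out
    order = np.argsort(refl.E[obs_idx], kind="stable")
    weak_idx = obs_idx[order[:n_weak]]
    out.weak[:] = False
    out.weak[weak_idx] = True
    out.phase[weak_idx] = out.phase[weak_idx] + sign * np.pi / 2
    return out


def triplet_sums(
    member_hkl: np.ndarray,
    member_values: np.ndarray,
    target_hkl: np.ndarray,
    dims: tuple = None,
    method: str = "fft",
) -> np.ndarray:
    """Convolution sums G(h) = sum_k E(k) E(h-k) over a reflection set.

    ``member_hkl``/``member_values`` describe the full (symmetry-expanded,
    Friedel-complete) strong set; ``target_hkl`` are the indices at which G
    is evaluated.  The FFT path squares the strong-set map on an alias-free
    grid; the direct path is the brute-force double loop used as an
    oracle / fallback.
    """
    member_hkl = np.asarray(member_hkl, dtype=np.int64)
    target_hkl = np.asarray(target_hkl, dtype=np.int64)
    hmax = np.abs(np.vstack([member_hkl, target_hkl])).max(axis=0)
    if dims is None:
        dims = convolution_grid_dims(hmax)
    else:
        dims = tuple(int(n) for n in dims)
        need = 3 * hmax + 1
        if any(d < m for d, m in zip(dims, need)):
            raise ValueError(
                f"dims {dims} too small for alias-free convolution (need {tuple(need)})"
            )
    if method == "fft":
        idx = np.ravel_multi_index(
            (member_hkl % np.array(dims)).T, dims
        )
        # average duplicates (stabilized indices appear once per op)
        cnt = np.bincount(idx, minlength=np.prod(dims))
        re = np.bincount(idx, weights=member_values.real, minlength=np.prod(dims))
        im = np.bincount(idx, weights=member_values.imag, minlength=np.prod(dims))
        flat = np.where(cnt > 0, (re + 1j * im) / np.maximum(cnt, 1), 0.0)
        grid = flat.reshape(dims)
        q = sfft.ifftn(grid)
        conv = sfft.fftn(q * q) * np.prod(dims)
        tidx = np.ravel_multi_index((target_hkl % np.array(dims)).T, dims)
        return conv.ravel()[tidx]
    if method == "direct":
        table = {}
        for h, v in zip(member_hkl, member_values):
            table[tuple(h)] = v
        out = np.zeros(len(target_hkl), dtype=complex)
        items = list(table.items())
        for n, h in enumerate(target_hkl):
            acc = 0.0 + 0.0j
            for k, vk in items:
                mate = table.get((h[0] - k[0], h[1] - k[1], h[2] - k[2]))
                if mate is not None:
                    acc += vk * mate
            out[n] = acc
        return out
    raise ValueError("method must be 'fft' or 'direct'")


def tangent_refine(
    refl: ReflectionSet,
    sg: SpaceGroupOps,
    n_tf: int,
    dims: tuple = None,
    method: str = "fft",
) -> ReflectionSet:
    """Tangent-formula phase refinement of the strongest reflections.

    For each strong h, G(h) = sum E(k) E(h-k) over the symmetry-expanded
    strong set; phi_tf = atan2(Im G, Re G); the refined phase is the
    argument of the confidence-weighted blend
    (1 - alpha) exp(i phi_c) + alpha exp(i phi_tf) with
    alpha = |E_h||G(h)| / max over the strong set.
    """
    out = refl.copy()
    obs_idx = np.flatnonzero(refl.observed & ~refl.absent & ~refl.beyond)
    if len(obs_idx) == 0:
        return out
    order = np.argsort(-refl.E[obs_idx], kind="stable")
    strong_idx = obs_idx[order[: min(n_tf, len(obs_idx))]]
    out.strong[:] = False
    out.strong[strong_idx] = True
    hkl = refl.hkl[strong_idx]
    values = refl.E[strong_idx] * np.exp(1j * refl.phase[strong_idx])
    members = sg.transformed_indices(hkl)  # (N, m, 3)
    factors = sg.phase_factors(hkl)
    mem_hkl = np.concatenate([members, -members], axis=1).reshape(-1, 3)
    mem_val = np.concatenate(
        [values[:, None] * factors, np.conj(values[:, None] * factors)], axis=1
    ).reshape(-1)
    G = triplet_sums(mem_hkl, mem_val, hkl, dims, method=method)
    mag = np.abs(G)
    M = refl.E[strong_idx] * mag
    m_max = M.max()
    if m_max <= 0:
        log.info("tangent refinement skipped: all triplet sums vanish")
        return out
    alpha = M / m_max
    phi_tf = np.angle(G)
    phi_c = refl.phase[strong_idx]
    blend = (1 - alpha) * np.exp(1j * phi_c) + alpha * np.exp(1j * phi_tf)
    new_phase = np.where(mag > 0, np.angle(blend), phi_c)
    out.phase[strong_idx] = new_phase
    return out


def _threshold(values: np.ndarray, fraction: float, mode: str) -> float:
    """Value below which ``fraction`` of the entries fall (O(n) partition)."""
    if mode == "fraction_passed":
        fraction = 1.0 - fraction
    flat = np.asarray(values).ravel()
    k = int(fraction * flat.size)
    if k <= 0:
        return float(flat.min())
    if k >= flat.size:
        return float(flat.max()) + 1.0
    return float(np.partition(flat, k)[k])


def raar_real_space(
    rho_tilde: np.ndarray,
    rho_last: np.ndarray,
    beta: float,
    perturb_fraction: float,
    delta_mode: str = "fraction_perturbed",
    delta: float = None,
) -> np.ndarray:
    """Relaxed real-space update with positivity.

    Working on a = |rho_tilde|: values at or above the dynamic threshold
    delta pass through; below it the output is beta * rho_last +
    (1 - 2 beta) * a.  The final map is returned in absolute value.
    """
    rho_tilde = np.asarray(rho_tilde)
    rho_last = np.asarray(rho_last)
    if rho_tilde.shape != rho_last.shape:
        raise ValueError("density grids have mismatched shapes")
    a = np.abs(rho_tilde)
    if delta is None:
        delta = _threshold(a, perturb_fraction, delta_mode)
    low = a < delta
    out = np.where(low, beta * rho_last + (1.0 - 2.0 * beta) * a, a)
    return np.abs(out)


def cf_real_space(
    rho_tilde: np.ndarray,
    perturb_fraction: float,
    delta_mode: str = "fraction_perturbed",
    delta: float = None,
) -> np.ndarray:
    """Charge-flipping update: negate densities below the threshold."""
    v = np.asarray(rho_tilde)
    if delta is None:
        delta = _threshold(v, perturb_fraction, delta_mode)
    return np.where(v < delta, -v, v)


def cc_pearson(e_obs, e_calc) -> float:
    """Pearson correlation; defined as 0 for degenerate input."""
    x = np.asarray(e_obs, dtype=float)
    y = np.asarray(e_calc, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length with >= 2 entries")
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        log.info("cc_pearson: zero variance, returning 0")
        return 0.0
    return float((xm * ym).sum() / denom)


def monitor_fom(rho, e_obs, e_calc) -> dict:
    """Figures of merit: scaled R factor, map skewness and Pearson CC."""
    from scipy.stats import skew

    e_obs = np.asarray(e_obs, float)
    e_calc = np.asarray(e_calc, float)
    denom = (e_calc**2).sum()
    k = (e_obs * e_calc).sum() / denom if denom > 0 else 0.0
    r = np.abs(e_obs - k * e_calc).sum() / e_obs.sum() if e_obs.sum() > 0 else np.inf
    values = rho.values if isinstance(rho, DensityGrid) else np.asarray(rho)
    return {
        "r_factor": float(r),
        "skewness": float(skew(values.ravel())),
        "cc": cc_pearson(e_obs, e_calc),
    }


# ---------------------------------------------------------------------------
# grid/symmetry plumbing shared by all trials
# ---------------------------------------------------------------------------

class EngineSetup:
    """Precomputed index maps binding an ASU reflection table to a grid.

    Holds the full Laue-unique table to the resolution limit (observed
    entries carry E values; the rest iterate freely), the flattened member
    indices of every symmetry image and Friedel mate, and the per-grid-point
    multiplicities used to average duplicate writes.
    """

    def __init__(
        self,
        refl: ReflectionSet,
        cell: UnitCell,
        sg: SpaceGroupOps,
        cfg: EngineConfig,
        d_min: float = None,
    ) -> None:
        kept = refl.kept()
        if len(kept) == 0:
            raise ValueError("no usable observed reflections")
        self.cell = cell
        self.sg = sg
        self.cfg = cfg
        self.d_min = float(d_min) if d_min else float(kept.d.min())
        self.dims = fft_grid_dims(cell, self.d_min, cfg.grid_factor)
        self.ngrid = int(np.prod(self.dims))

        asu = generate_asu_indices(cell, sg, self.d_min)
        self.hkl = asu
        n = len(asu)
        lookup = {tuple(h): i for i, h in enumerate(asu)}
        canon = sg.canonical(kept.hkl)
        self.E_obs = np.zeros(n)
        self.obs_mask = np.zeros(n, bool)
        dropped = 0
        for row, h in enumerate(canon):
            i = lookup.get(tuple(h))
            if i is None:
                dropped += 1
                continue
            self.obs_mask[i] = True
            self.E_obs[i] = kept.E[row]
        if dropped:
            log.info("%d observed reflections fell outside the ASU table", dropped)
        self.n_obs = int(self.obs_mask.sum())

        members = sg.transformed_indices(asu)  # (n, m, 3)
        factors = sg.phase_factors(asu)  # (n, m)
        dims_arr = np.array(self.dims)
        idx_plus = np.ravel_multi_index(
            np.moveaxis(members % dims_arr, -1, 0), self.dims
        )
        idx_minus = np.ravel_multi_index(
            np.moveaxis((-members) % dims_arr, -1, 0), self.dims
        )
        self._idx_all = np.concatenate([idx_plus, idx_minus], axis=1)  # (n, 2m)
        self._flat_idx = self._idx_all.ravel()
        self._fac = factors
        self._conj_fac = np.conj(factors)
        counts = np.bincount(self._flat_idx, minlength=self.ngrid)
        self._inv_counts = 1.0 / np.maximum(counts, 1)

        # observed index order used for CC and phase reporting
        self.obs_idx = np.flatnonzero(self.obs_mask)
        order = np.argsort(self.E_obs[self.obs_idx], kind="stable")
        self.weak_order = self.obs_idx[order]  # ascending E
        self.strong_order = self.obs_idx[order[::-1]]  # descending E
        n_tf = cfg.n_tf if cfg.n_tf else n_tf_rule(self.n_obs)
        self.strong_idx = self.strong_order[: min(n_tf, self.n_obs)]
        self._strong_prepared = False

    # -- dual-space transforms ------------------------------------------

    def _expand_to_grid(self, z: np.ndarray) -> np.ndarray:
        vals_plus = z[:, None] * self._fac
        vals = np.concatenate([vals_plus, np.conj(vals_plus)], axis=1).ravel()
        re = np.bincount(self._flat_idx, weights=vals.real, minlength=self.ngrid)
        im = np.bincount(self._flat_idx, weights=vals.imag, minlength=self.ngrid)
        grid = (re + 1j * im) * self._inv_counts
        return grid.reshape(self.dims)

    def synthesize(self, z: np.ndarray) -> np.ndarray:
        """Real map from ASU coefficients (symmetry + Friedel expansion)."""
        return sfft.ifftn(self._expand_to_grid(z)).real

    def synth_imag_ratio(self, z: np.ndarray) -> float:
        """Relative imaginary leakage of a synthesis (invariant check)."""
        rho = sfft.ifftn(self._expand_to_grid(z))
        scale = np.abs(rho.real).max()
        return float(np.abs(rho.imag).max() / scale) if scale > 0 else 0.0

    def analyze(self, rho: np.ndarray) -> np.ndarray:
        """ASU coefficients from a real map (orbit-averaged reduction)."""
        F = sfft.fftn(rho).ravel()
        m = self._fac.shape[1]
        gathered = F[self._idx_all]  # (n, 2m)
        back = np.empty_like(gathered)
        back[:, :m] = gathered[:, :m] * self._conj_fac
        back[:, m:] = np.conj(gathered[:, m:]) * self._conj_fac
        return back.mean(axis=1)

    def project(self, z: np.ndarray) -> np.ndarray:
        """Moduli replacement: observed amplitudes forced to E_obs."""
        out = z.copy()
        obs = self.obs_mask
        phase = np.angle(z[obs])
        out[obs] = self.E_obs[obs] * np.exp(1j * phase)
        return out

    def weak_mask_for(self, w_best: float, z: np.ndarray = None) -> np.ndarray:
        n_weak = int(np.floor(w_best * self.n_obs))
        mask = np.zeros(len(self.hkl), bool)
        if n_weak == 0:
            return mask
        if self.cfg.weak_mode == "dynamic" and z is not None:
            order = np.argsort(np.abs(z[self.obs_idx]), kind="stable")
            mask[self.obs_idx[order[:n_weak]]] = True
        else:
            mask[self.weak_order[:n_weak]] = True
        return mask

    def _prepare_strong(self) -> None:
        if self._strong_prepared:
            return
        hkl = self.hkl[self.strong_idx]
        members = self.sg.transformed_indices(hkl)
        factors = self.sg.phase_factors(hkl)
        self._s_mem_hkl = np.concatenate([members, -members], axis=1)
        self._s_fac = factors
        # alias-free cyclic convolution needs dims > 3 * max member index
        hmax = np.abs(self._s_mem_hkl).reshape(-1, 3).max(axis=0)
        self.tangent_dims = tuple(
            convolution_grid_dims(hmax)
        )
        tdims = np.array(self.tangent_dims)
        mem = self._s_mem_hkl
        idx = np.ravel_multi_index(np.moveaxis(mem % tdims, -1, 0), self.tangent_dims)
        self._s_idx = idx.reshape(len(hkl), -1)
        self._s_target_idx = np.ravel_multi_index(
            np.moveaxis(hkl % tdims, -1, 0), self.tangent_dims
        )
        self._s_ngrid = int(np.prod(self.tangent_dims))
        self._strong_prepared = True

    def tangent_step(self, z: np.ndarray) -> np.ndarray:
        """FFT-convolution tangent refinement of the strong set (in place
        on a copy of the ASU coefficient vector)."""
        self._prepare_strong()
        s = self.strong_idx
        values = z[s]
        vals_plus = values[:, None] * self._s_fac
        vals = np.concatenate([vals_plus, np.conj(vals_plus)], axis=1).ravel()
        flat_idx = self._s_idx.ravel()
        cnt = np.bincount(flat_idx, minlength=self._s_ngrid)
        re = np.bincount(flat_idx, weights=vals.real, minlength=self._s_ngrid)
        im = np.bincount(flat_idx, weights=vals.imag, minlength=self._s_ngrid)
        grid = np.where(cnt > 0, (re + 1j * im) / np.maximum(cnt, 1), 0.0)
        q = sfft.ifftn(grid.reshape(self.tangent_dims))
        conv = sfft.fftn(q * q).ravel() * self._s_ngrid
        G = conv[self._s_target_idx]
        mag = np.abs(G)
        M = np.abs(values) * mag
        m_max = M.max()
        out = z.copy()
        if m_max <= 0:
            return out
        alpha = M / m_max
        phi_c = np.angle(values)
        phi_tf = np.angle(G)
        blend = (1 - alpha) * np.exp(1j * phi_c) + alpha * np.exp(1j * phi_tf)
        new_phase = np.where(mag > 0, np.angle(blend), phi_c)
        out[s] = np.abs(values) * np.exp(1j * new_phase)
        return out


def init_random_density(
    refl: ReflectionSet,
    cell: UnitCell,
    sg: SpaceGroupOps,
    dims: tuple = None,
    seed: int = 0,
    cfg: EngineConfig = None,
) -> DensityGrid:
    """Random-phase starting map from the observed amplitudes.

    Coefficients are E_obs * exp(i phi_rand) on the observed set (zero
    elsewhere, F(0) = 0) expanded over the full sphere with Friedel-law
    phases; the map is the real synthesis.
    """
    cfg = cfg or EngineConfig()
    setup = EngineSetup(refl, cell, sg, cfg)
    if dims is not None and tuple(dims) != setup.dims:
        raise ValueError(
            f"requested dims {tuple(dims)} below the anti-aliasing minimum "
            f"{setup.dims}" if np.prod(dims) < np.prod(setup.dims) else
            f"requested dims {tuple(dims)} != computed {setup.dims}"
        )
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, len(setup.hkl))
    z = np.where(setup.obs_mask, setup.E_obs * np.exp(1j * phases), 0.0)
    return DensityGrid(setup.synthesize(z), cell)


def _detect_jump(cc: np.ndarray, window: int, jump: float, skip: int = 10):
    """(converged, jump_iter) from a CC trace.

    A jump is a gain > ``jump`` over a ``window``-iteration span, measured
    after the first ``skip`` iterations so the initial rise from a random
    start does not count; the trial is converged when the tail plateaus at
    or above the jump level.
    """
    n = len(cc)
    if n < window + skip + 5:
        return False, None
    gains = cc[window + skip :] - cc[skip : n - window]
    hits = np.flatnonzero(gains > jump)
    if len(hits) == 0:
        return False, None
    jump_iter = int(hits[0] + window + skip)
    tail = cc[-min(25, n) :]
    converged = bool(tail.mean() >= cc[jump_iter] - 0.02)
    return converged, jump_iter


def run_trial(
    refl: ReflectionSet,
    cell: UnitCell,
    sg: SpaceGroupOps,
    cfg: EngineConfig,
    seed: int = None,
    w_best: float = None,
    initial_phases: np.ndarray = None,
    setup: EngineSetup = None,
    callback=None,
) -> TrialResult:
    """One complete retrieval trial from a random (or given) phase start.

    ``callback(iteration, z_projected, rho_tilde)`` is invoked after each
    reciprocal-space constraint, before the real-space update (used by
    invariant checks and diagnostics).
    """
    setup = setup or EngineSetup(refl, cell, sg, cfg)
    seed = cfg.seed if seed is None else seed
    if w_best is None:
        w_best = 0.30 if cfg.w_best == "auto" else float(cfg.w_best)
    rng = np.random.default_rng(seed)
    if initial_phases is None:
        phases = rng.uniform(0, 2 * np.pi, len(setup.hkl))
    else:
        phases = np.asarray(initial_phases, dtype=float)
        if phases.shape != (len(setup.hkl),):
            raise ValueError("initial_phases must cover the full ASU table")
    z = np.where(setup.obs_mask, setup.E_obs * np.exp(1j * phases), 0.0)
    rho = setup.synthesize(z)
    rho_last = np.abs(rho)

    use_pihalf = cfg.algorithm in ("raar_pihalf", "raar_pihalf_tf")
    use_tf = cfg.algorithm == "raar_pihalf_tf"
    static_weak = setup.weak_mask_for(w_best) if cfg.weak_mode == "static" else None
    shift = np.exp(1j * cfg.pi_half_sign * np.pi / 2)

    cc = np.zeros(cfg.n_iter)
    eo = setup.E_obs[setup.obs_idx]
    failed = False
    for it in range(cfg.n_iter):
        z = setup.analyze(rho)
        if it > 0:
            cc[it - 1] = cc_pearson(eo, np.abs(z[setup.obs_idx]))
        z_calc = z
        z = setup.project(z)
        if use_pihalf:
            weak = (
                static_weak
                if static_weak is not None
                else setup.weak_mask_for(w_best, z_calc)
            )
            if cfg.weak_keep_calc:
                z[weak] = np.abs(z_calc[weak]) * np.exp(
                    1j * np.angle(z[weak])
                )
            z[weak] = z[weak] * shift
        if use_tf:
            apply_tf = (
                (cfg.tf_early and it < cfg.tf_start)
                or (it >= cfg.tf_start and (it - cfg.tf_start) % cfg.tf_stride == 0)
            )
            if apply_tf:
                z = setup.tangent_step(z)
        rho_tilde = setup.synthesize(z)
        if callback is not None:
            callback(it, z, rho_tilde)
        if cfg.algorithm == "cf":
            rho_new = cf_real_space(rho_tilde, cfg.perturb_fraction, cfg.delta_mode)
        else:
            rho_new = raar_real_space(
                rho_tilde, rho_last, cfg.beta, cfg.perturb_fraction, cfg.delta_mode
            )
        if not np.all(np.isfinite(rho_new)):
            failed = True
            log.warning("trial seed=%s aborted: non-finite density", seed)
            break
        rho_last = rho_new
        rho = rho_new
    z = setup.analyze(rho)
    cc[-1] = cc_pearson(eo, np.abs(z[setup.obs_idx]))
    converged, jump_iter = _detect_jump(cc, cfg.cc_window, cfg.cc_jump)
    best_cc = float(cc[-min(cfg.cc_window, len(cc)) :].max())
    return TrialResult(
        cc_trace=cc,
        final_phases=np.angle(z),
        final_density=DensityGrid(rho, cell),
        best_cc=best_cc,
        seed=seed,
        converged=converged and not failed,
        jump_iter=jump_iter,
        w_best=w_best,
        failed=failed,
    )


def run_multi(
    refl: ReflectionSet,
    cell: UnitCell,
    sg: SpaceGroupOps,
    cfg: EngineConfig,
    n_jobs: int = 1,
):
    """Run ``cfg.n_trials`` random starts and return the best trial.

    Trial i uses seed ``cfg.seed + i``; with ``w_best='auto'`` the trials
    cycle through the standard weak-fraction grid so each value gets an
    equal share.  Returns ``(best TrialResult, summary DataFrame)``.
    """
    import pandas as pd

    setup = EngineSetup(refl, cell, sg, cfg)
    if cfg.w_best == "auto":
        w_values = [W_BEST_GRID[i % len(W_BEST_GRID)] for i in range(cfg.n_trials)]
    else:
        w_values = [float(cfg.w_best)] * cfg.n_trials
    seeds = [cfg.seed + i for i in range(cfg.n_trials)]

    def one(seed, w):
        return run_trial(refl, cell, sg, cfg, seed=seed, w_best=w, setup=setup)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(one)(s, w) for s, w in zip(seeds, w_values)
        )
    else:
        results = [one(s, w) for s, w in zip(seeds, w_values)]

    rows = []
    for i, res in enumerate(results):
        rows.append(
            {
                "trial": i,
                "seed": res.seed,
                "w_best": res.w_best,
                "best_cc": res.best_cc,
                "converged": res.converged,
                "jump_iter": res.jump_iter,
                "failed": res.failed,
            }
        )
    summary = pd.DataFrame(rows)
    ok = [r for r in results if not r.failed]
    if not ok:
        raise RuntimeError(f"all trials failed:\n{summary}")
    best = max(ok, key=lambda r: r.best_cc)
    return best, summary
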