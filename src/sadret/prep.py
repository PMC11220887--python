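"""Anomalous-difference extraction, resolution cutoff and E normalization.

Pipeline: Bijvoet pairs -> |dF| with propagated sigmas (simple documented
filters only) -> signal-based high-resolution cutoff at mean |dF|/sigma =
1.2 -> shell-wise normalization to E values with smooth interpolation in
1/d^2 and optional symmetry-enhancement (epsilon) correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import BijvoetPairSet, ReflectionSet
from .symmetry import SpaceGroupOps, UnitCell

__all__ = [
    "ShellTable",
    "make_shells",
    "compute_anomalous_differences",
    "estimate_resolution_cutoff",
    "normalize_to_E",
    "prep_pipeline",
]

log = logging.getLogger(__name__)

#: Signal threshold on the per-shell mean |dF|/sigma used for the cutoff.
SIGNAL_THRESHOLD = 1.2
DEFAULT_N_SHELLS = 10


@dataclass
class ShellTable:
    """Resolution-shell statistics (boundaries stored as 1/d^2)."""

    boundaries_s2: np.ndarray  # (n_shells + 1,) ascending
    mean_signal: np.ndarray  # per-shell mean |dF|/sigma
    mean_dF2: np.ndarray  # per-shell mean |dF|^2
    count: np.ndarray
    scale: np.ndarray  # normalization scale sqrt(<dF^2/eps>) per shell

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.boundaries_s2) > 0):
            raise ValueError("shell boundaries must be strictly increasing")

    @property
    def n_shells(self) -> int:
        return len(self.boundaries_s2) - 1

    def assign(self, s2: np.ndarray) -> np.ndarray:
        """Shell index per reflection (clipped into range)."""
        idx = np.searchsorted(self.boundaries_s2, s2, side="right") - 1
        return np.clip(idx, 0, self.n_shells - 1)

    def centers_s2(self) -> np.ndarray:
        return 0.5 * (self.boundaries_s2[:-1] + self.boundaries_s2[1:])


def make_shells(refl: ReflectionSet, n_shells: int = DEFAULT_N_SHELLS) -> ShellTable:
    """Equal-reciprocal-volume shells (uniform in 1/d^3) over kept data."""
    mask = refl.observed & ~refl.absent
    d = refl.d[mask]
    if len(d) == 0:
        raise ValueError("no observed reflections to shell")
    s3 = 1.0 / d**3
    lo, hi = s3.min(), s3.max()
    if hi <= lo:
        hi = lo * (1 + 1e-9) + 1e-12
    edges_s3 = np.linspace(lo, hi, n_shells + 1)
    edges_s3[0] -= 1e-12
    edges_s3[-1] += 1e-12
    b_s2 = np.maximum(edges_s3, 0.0) ** (2.0 / 3.0)
    s2 = 1.0 / d**2
    idx = np.clip(np.searchsorted(b_s2, s2, side="right") - 1, 0, n_shells - 1)
    sig = refl.sig_dF[mask]
    dF = refl.dF[mask]
    mean_signal = np.zeros(n_shells)
    mean_dF2 = np.zeros(n_shells)
    count = np.zeros(n_shells, dtype=int)
    for i in range(n_shells):
        sel = idx == i
        count[i] = sel.sum()
        if count[i]:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(sig[sel] > 0, dF[sel] / sig[sel], 0.0)
            mean_signal[i] = ratio.mean()
            mean_dF2[i] = (dF[sel] ** 2).mean()
    scale = np.sqrt(np.maximum(mean_dF2, 0.0))
    return ShellTable(b_s2, mean_signal, mean_dF2, count, scale)


def compute_anomalous_differences(
    pairs: BijvoetPairSet,
    cell: UnitCell,
    sg: SpaceGroupOps,
    k_reject: float = np.inf,
) -> ReflectionSet:
    """Turn Bijvoet pairs into |dF| = ||F+| - |F-|| with honest sigmas.

    Records are dropped when either mate is unobserved (NaN), a sigma is
    non-positive, the difference exceeds ``k_reject`` sigmas, or the index
    is centric (phase-restricted, hence carrying no Bijvoet signal).
    """
    n0 = len(pairs)
    both = np.isfinite(pairs.fplus) & np.isfinite(pairs.fminus)
    sig_ok = (pairs.sig_fplus > 0) & (pairs.sig_fminus > 0)
    centric = sg.is_centric(pairs.hkl)
    keep = both & sig_ok & ~centric
    dF = np.abs(pairs.fplus - pairs.fminus)
    sig = np.sqrt(pairs.sig_fplus**2 + pairs.sig_fminus**2)
    if np.isfinite(k_reject):
        keep &= dF <= k_reject * sig
    log.info(
        "anomalous differences: %d in, %d dropped (missing mate %d, bad sigma %d, "
        "centric %d, k_reject %d), %d kept",
        n0,
        int((~keep).sum()),
        int((~both).sum()),
        int((both & ~sig_ok).sum()),
        int((both & sig_ok & centric).sum()),
        int((both & sig_ok & ~centric & ~keep).sum()),
        int(keep.sum()),
    )
    if not keep.any():
        raise ValueError(
            "no reflections survived anomalous-difference filtering; "
            "relax k_reject or check the input pairs"
        )
    hkl = pairs.hkl[keep]
    return ReflectionSet(
        hkl,
        dF=dF[keep],
        sig_dF=sig[keep],
        d=cell.d_spacing(hkl),
        centric=np.zeros(keep.sum(), bool),
        absent=np.zeros(keep.sum(), bool),
    )


def estimate_resolution_cutoff(
    refl: ReflectionSet,
    shells: ShellTable = None,
    n_shells: int = DEFAULT_N_SHELLS,
    threshold: float = SIGNAL_THRESHOLD,
):
    """High-resolution cutoff where the shell mean |dF|/sigma reaches the
    threshold; flags reflections at higher resolution as beyond-limit.

    Scanning from the highest-resolution shell towards low resolution, the
    cutoff is the high-resolution edge of the first shell whose mean
    |dF|/sigma exceeds the threshold.  Returns ``d_cut`` in angstrom, or
    ``None`` when no truncation applies.
    """
    if shells is None:
        shells = make_shells(refl, n_shells)
    populated = shells.count > 0
    if populated.sum() < 3:
        raise ValueError("need at least 3 populated resolution shells")
    order = np.argsort(shells.centers_s2())[::-1]  # high resolution first
    order = [i for i in order if populated[i]]
    passing = [i for i in order if shells.mean_signal[i] > threshold]
    if not passing:
        raise ValueError(
            f"no resolution shell reaches mean |dF|/sigma > {threshold}; "
            "data carry no usable anomalous signal"
        )
    first = passing[0]
    if first == order[0]:
        return None  # already significant at the highest resolution
    s2_cut = shells.boundaries_s2[first + 1]  # high-res edge of that shell
    d_cut = 1.0 / np.sqrt(s2_cut)
    refl.beyond |= refl.d < d_cut - 1e-9
    log.info("anomalous resolution cutoff at %.3f A (%d flagged beyond)",
             d_cut, int(refl.beyond.sum()))
    return float(d_cut)


def normalize_to_E(
    refl: ReflectionSet,
    n_shells: int = DEFAULT_N_SHELLS,
    sg: SpaceGroupOps = None,
    use_epsilon: bool = True,
    smooth_passes: int = 3,
) -> ReflectionSet:
    """Normalize |dF| to E with <E^2> = 1 per resolution shell.

    The shell scale sqrt(<dF^2/eps>) is interpolated linearly in 1/d^2
    between shell centers; a few fixed-point correction passes pull the
    per-shell <E^2> onto unity while keeping the curve smooth.  Empty
    shells are absorbed by the interpolation over populated neighbours.
    """
    out = refl.copy()
    mask = out.observed & ~out.absent & ~out.beyond
    if mask.sum() == 0:
        raise ValueError("nothing to normalize")
    eps = np.ones(len(out))
    if use_epsilon and sg is not None:
        eps = sg.epsilon(out.hkl).astype(float)
    s2 = 1.0 / out.d**2
    kept = out.select(mask)
    kept_s2 = s2[mask]
    kept_y = out.dF[mask] ** 2 / eps[mask]

    shells = make_shells(kept, n_shells)
    idx = shells.assign(kept_s2)
    centers = shells.centers_s2()
    scale2 = np.full(shells.n_shells, np.nan)
    for i in range(shells.n_shells):
        sel = idx == i
        if sel.sum():
            scale2[i] = kept_y[sel].mean()
        else:
            log.info("empty normalization shell %d merged with neighbours", i)
    pop = np.isfinite(scale2)
    interp = np.interp(kept_s2, centers[pop], scale2[pop])
    E2 = kept_y / interp
    for _ in range(max(0, smooth_passes)):
        corr = np.full(shells.n_shells, np.nan)
        for i in range(shells.n_shells):
            sel = idx == i
            if sel.sum():
                corr[i] = E2[sel].mean()
        pop = np.isfinite(corr)
        E2 = E2 / np.interp(kept_s2, centers[pop], corr[pop])
    E = np.zeros(len(out))
    E[mask] = np.sqrt(np.maximum(E2, 0.0))
    out.E = E
    return out


def prep_pipeline(
    pairs: BijvoetPairSet,
    cell: UnitCell,
    sg: SpaceGroupOps,
    n_shells: int = DEFAULT_N_SHELLS,
    k_reject: float = np.inf,
    apply_cutoff: bool = True,
    use_epsilon: bool = True,
):
    """Full preparation: differences -> cutoff -> E values.

    Returns ``(refl, shells, d_cut)``.
    """
    refl = compute_anomalous_differences(pairs, cell, sg, k_reject=k_reject)
    shells = make_shells(refl, n_shells)
    d_cut = None
    if apply_cutoff:
        d_cut = estimate_resolution_cutoff(refl, shells)
    refl = normalize_to_E(refl, n_shells, sg=sg, use_epsilon=use_epsilon)
    return refl, shells, d_cut
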