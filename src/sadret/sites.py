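"""Peak search on density maps and symmetry-aware site-list comparison.

Site lists are fractional coordinates with peak heights in map-sigma
units.  Matching accounts for the full ambiguity of a phase-retrieval
solution: space-group symmetry, permissible origin shifts (continuous
along polar axes) and the enantiomorph (inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import linear_sum_assignment, minimize

from .records import DensityGrid
from .symmetry import SpaceGroupOps, UnitCell, permissible_origin_shifts

__all__ = [
    "SiteList",
    "MatchReport",
    "find_peaks",
    "default_n_peaks",
    "match_sites",
    "positional_stats",
]

DEFAULT_MATCH_TOL = 1.5  # angstrom, "correctly matched" threshold
DEFAULT_MIN_SEP = 1.0  # angstrom, peak suppression radius


@dataclass
class SiteList:
    """Fractional sites sorted by descending peak height."""

    frac: np.ndarray
    height: np.ndarray = None

    def __post_init__(self) -> None:
        self.frac = np.mod(np.asarray(self.frac, dtype=float).reshape(-1, 3), 1.0)
        if self.height is None:
            self.height = np.zeros(len(self.frac))
        self.height = np.asarray(self.height, dtype=float).reshape(-1)
        if len(self.height) != len(self.frac):
            raise ValueError("height and frac lengths differ")
        order = np.argsort(-self.height, kind="stable")
        self.frac = self.frac[order]
        self.height = self.height[order]

    def __len__(self) -> int:
        return len(self.frac)

    def top(self, n: int) -> "SiteList":
        return SiteList(self.frac[:n].copy(), self.height[:n].copy())


@dataclass
class MatchReport:
    """Outcome of comparing a calculated site list against a reference."""

    n_ref: int
    n_calc: int
    n_matched: int
    fraction_matched: float
    mean_dist: float
    rmsd_dist: float
    transform: dict
    success: bool
    distances: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pairs: list = field(default_factory=list)


def default_n_peaks(n_expected: int) -> int:
    """Peak-list length rule: two more than the expected site count."""
    return int(n_expected) + 2


def _wrap(delta: np.ndarray) -> np.ndarray:
    return delta - np.round(delta)


def find_peaks(
    rho: DensityGrid,
    n_peaks: int,
    min_sep: float = DEFAULT_MIN_SEP,
    cell: UnitCell = None,
    sg: SpaceGroupOps = None,
    min_height: float = 0.0,
) -> SiteList:
    """Locate the ``n_peaks`` highest local maxima of a periodic map.

    Maxima over the 26-neighbourhood (periodic) are refined per axis by
    3-point parabolic interpolation; peaks within ``min_sep`` angstrom of a
    higher peak -- symmetry mates included when ``sg`` is given -- are
    suppressed.  Heights are reported in sigma-of-map units; candidates at
    or below ``min_height`` sigma (flat plateaus, background) are ignored.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    cell = cell if cell is not None else rho.cell
    if cell is None:
        raise ValueError("a unit cell is required for peak separation")
    v = rho.sigma_scaled()
    if not v.any():
        return SiteList(np.zeros((0, 3)), np.zeros(0))
    dims = np.array(v.shape)
    is_max = (v >= maximum_filter(v, size=3, mode="wrap")) & (v > min_height)
    cand = np.argwhere(is_max)
    if len(cand) == 0:
        return SiteList(np.zeros((0, 3)), np.zeros(0))
    heights = np.empty(len(cand))
    fracs = np.empty((len(cand), 3))
    for n, (i, j, k) in enumerate(cand):
        pos = np.array([i, j, k], dtype=float)
        h = v[i, j, k]
        for ax in range(3):
            lo = list((i, j, k))
            hi = list((i, j, k))
            lo[ax] = (lo[ax] - 1) % dims[ax]
            hi[ax] = (hi[ax] + 1) % dims[ax]
            fm, fp = v[tuple(lo)], v[tuple(hi)]
            denom = fm - 2 * v[i, j, k] + fp
            if denom < -1e-12:
                off = np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5)
                pos[ax] += off
                h += -((fm - fp) ** 2) / (8.0 * denom)
        heights[n] = h
        fracs[n] = pos / dims
    order = np.argsort(-heights, kind="stable")
    fracs, heights = fracs[order], heights[order]

    rots = sg.rotations if sg is not None else np.eye(3, dtype=np.int64)[None]
    trans = sg.translations if sg is not None else np.zeros((1, 3))
    kept_images = np.zeros((0, 3))
    keep_idx = []
    for n in range(len(fracs)):
        if kept_images.size:
            delta = _wrap(kept_images[:, None, :] - fracs[n])
            dist = np.linalg.norm(cell.frac_to_cart(delta), axis=-1)
            if dist.min() < min_sep:
                continue
        keep_idx.append(n)
        imgs = fracs[n] @ rots.transpose(0, 2, 1) + trans
        kept_images = np.vstack([kept_images, np.mod(imgs, 1.0)])
        if len(keep_idx) >= n_peaks:
            break
    return SiteList(fracs[keep_idx], heights[keep_idx])


def _sym_distance_matrix(
    calc_frac: np.ndarray,
    ref_frac: np.ndarray,
    cell: UnitCell,
    rots: np.ndarray,
    trans: np.ndarray,
) -> np.ndarray:
    """Min-over-symmetry periodic Cartesian distances, shape (n_calc, n_ref)."""
    imgs = calc_frac @ rots.transpose(0, 2, 1) + trans[:, None, :]  # (m, n, 3)
    delta = _wrap(imgs[:, :, None, :] - ref_frac[None, None, :, :])
    dist = np.linalg.norm(cell.frac_to_cart(delta), axis=-1)
    return dist.min(axis=0)


def _greedy_pairs(dist: np.ndarray, tol: float) -> list:
    pairs = []
    d = dist.copy()
    while d.size:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > tol:
            break
        pairs.append((i, j, float(d[i, j])))
        d[i, :] = np.inf
        d[:, j] = np.inf
    return pairs


def _assignment_pairs(dist: np.ndarray, tol: float) -> list:
    cost = np.where(dist <= tol, dist, 1e6)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if dist[i, j] <= tol
    ]


def match_sites(
    calc: SiteList,
    ref: SiteList,
    sg: SpaceGroupOps,
    cell: UnitCell,
    tol: float = DEFAULT_MATCH_TOL,
    assignment: str = "greedy",
    polar_steps: int = 24,
) -> MatchReport:
    """Compare site lists modulo symmetry, origin shifts and handedness.

    The search runs over inversion x permissible origin shifts; components
    along polar axes are scanned on a coarse grid and refined continuously.
    Per-site distances are minimized over all symmetry images with the
    periodic minimum-image convention, then sites are paired greedily (or
    by optimal assignment) under the ``tol`` threshold.  Success follows
    the more-than-half-matched rule.
    """
    if len(calc) == 0 or len(ref) == 0:
        raise ValueError("both site lists must be non-empty")
    pair_fn = _assignment_pairs if assignment == "assignment" else _greedy_pairs
    shifts, polar = permissible_origin_shifts(sg)
    polar_idx = ["xyz".index(ax) for ax in polar]
    rots, trans = sg.rotations, sg.translations

    def dist_matrix(inv: int, shift: np.ndarray) -> np.ndarray:
        moved = np.mod(inv * calc.frac + shift, 1.0)
        return _sym_distance_matrix(moved, ref.frac, cell, rots, trans)

    def evaluate(inv: int, shift: np.ndarray):
        dist = dist_matrix(inv, shift)
        pairs = pair_fn(dist, tol)
        dists = np.array([p[2] for p in pairs])
        mean = dists.mean() if len(dists) else np.inf
        return len(pairs), mean, pairs, dists

    # Gaussian-smeared overlap used for the continuous (polar) alignment;
    # wide enough that the coarse grid cannot step over a basin.
    sigma = max(tol, 1.2 * float(cell.lengths.max()) / polar_steps)

    def soft_score_batch(inv: int, shift_batch: np.ndarray) -> np.ndarray:
        out = np.empty(len(shift_batch))
        for lo in range(0, len(shift_batch), 2048):
            batch = shift_batch[lo : lo + 2048]
            moved = np.mod(inv * calc.frac[None] + batch[:, None, :], 1.0)
            imgs = np.einsum("snj,mkj->msnk", moved, rots) + trans[:, None, None, :]
            delta = _wrap(imgs[:, :, :, None, :] - ref.frac[None, None, None, :, :])
            dist = np.linalg.norm(cell.frac_to_cart(delta), axis=-1)
            dmin = dist.min(axis=0)  # (s, n_calc, n_ref)
            out[lo : lo + 2048] = np.exp(-(dmin**2) / (2 * sigma**2)).sum(axis=(1, 2))
        return out

    candidates = []
    for inv in (1, -1):
        for base in shifts:
            if polar_idx:
                steps = np.arange(polar_steps) / polar_steps
                grids = np.meshgrid(*([steps] * len(polar_idx)), indexing="ij")
                offs = np.stack([g.ravel() for g in grids], axis=-1)
                batch = np.tile(base, (len(offs), 1))
                for k, ax in enumerate(polar_idx):
                    batch[:, ax] = offs[:, k]
                scores = soft_score_batch(inv, batch)
                shift0 = batch[int(np.argmax(scores))].copy()

                def neg_soft(lam, inv=inv, shift0=shift0):
                    s = shift0.copy()
                    for k, ax in enumerate(polar_idx):
                        s[ax] = lam[k]
                    return -float(soft_score_batch(inv, s[None])[0])

                x0 = np.array([shift0[ax] for ax in polar_idx])
                res = minimize(neg_soft, x0, method="Nelder-Mead",
                               options={"xatol": 1e-7, "fatol": 1e-10,
                                        "maxiter": 400})
                shift = shift0.copy()
                for k, ax in enumerate(polar_idx):
                    shift[ax] = res.x[k] % 1.0
            else:
                shift = base.copy()
            candidates.append((inv, shift))

    best = None  # (n_matched, -mean, inv, shift, pairs, dists)
    for inv, shift in candidates:
        n, mean, pairs, dists = evaluate(inv, shift)
        cand = (n, -mean, inv, shift, pairs, dists)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand

    n, negmean, inv, shift, pairs, dists = best
    if polar_idx and pairs:
        # final polish: minimize the mean distance of the found pairing
        pairing = [(i, j) for i, j, _ in pairs]

        def objective(lam):
            s = shift.copy()
            for k, ax in enumerate(polar_idx):
                s[ax] = lam[k]
            dist = dist_matrix(inv, s)
            return float(np.mean([dist[i, j] for i, j in pairing]))

        x0 = np.array([shift[ax] for ax in polar_idx])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 400})
        refined = shift.copy()
        for k, ax in enumerate(polar_idx):
            refined[ax] = res.x[k] % 1.0
        n2, mean2, pairs2, dists2 = evaluate(inv, refined)
        if (n2, -mean2) >= (n, negmean):
            shift, pairs, dists, n = refined, pairs2, dists2, n2

    frac = n / len(ref)
    report = MatchReport(
        n_ref=len(ref),
        n_calc=len(calc),
        n_matched=n,
        fraction_matched=frac,
        mean_dist=float(dists.mean()) if n else np.inf,
        rmsd_dist=float(np.sqrt((dists**2).mean())) if n else np.inf,
        transform={"inversion": inv == -1, "shift": shift.tolist()},
        success=frac > 0.5,
        distances=dists,
        pairs=[(i, j) for i, j, _ in pairs],
    )
    return report


def positional_stats(reports) -> dict:
    """Summarize matched-site distances over a stream of reports."""
    import pandas as pd

    rows = []
    for k, rep in enumerate(reports):
        d = np.asarray(rep.distances, dtype=float)
        rows.append(
            {
                "dataset": k,
                "n_matched": rep.n_matched,
                "fraction_matched": rep.fraction_matched,
                "mean": d.mean() if d.size else np.nan,
                "std": d.std() if d.size else np.nan,
                "median": np.median(d) if d.size else np.nan,
            }
        )
    if not rows:
        raise ValueError("at least one report required")
    table = pd.DataFrame(rows)
    aggregate = {
        "median_mean": float(table["mean"].median()),
        "median_std": float(table["std"].median()),
        "median_fraction": float(table["fraction_matched"].median()),
    }
    return {"table": table, "aggregate": aggregate}
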