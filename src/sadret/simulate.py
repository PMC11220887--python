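"""Ground-truth SAD fixtures: substructures, structure factors, noise.

Everything a test needs without external data: point-atom anomalous
substructures in an arbitrary space group, an optional light-atom
background that generates realistic Friedel-pair differences, and simple
Gaussian measurement noise with honest sigmas.  All randomness flows from
a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BijvoetPairSet, ReflectionSet
from .sites import SiteList
from .symmetry import SpaceGroupOps, UnitCell, generate_asu_indices

__all__ = ["SyntheticSpec", "place_substructure", "structure_factors", "make_dataset"]

_CHUNK = 4096


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic SAD dataset."""

    cell: UnitCell
    sg: SpaceGroupOps
    n_atoms: int = 8
    f0: float = 34.0  # normal scattering of the anomalous species
    f_prime: float = -8.0
    f_dprime: float = 4.5
    f0_light: float = 7.0
    b_factor: float = 15.0
    occupancy: float = 1.0
    d_min: float = 2.5
    noise_frac: float = 0.0
    n_background: int = 0
    min_sep: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")


def place_substructure(spec: SyntheticSpec, rng=None) -> SiteList:
    """Rejection-sample fractional sites respecting min_sep under symmetry.

    Every accepted site keeps all its symmetry images (including its own)
    at least ``min_sep`` angstrom from every other image.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cell, sg = spec.cell, spec.sg
    rots, trans = sg.rotations, sg.translations
    placed = []
    images = np.zeros((0, 3))
    attempts = 0
    max_attempts = 2000 * spec.n_atoms
    while len(placed) < spec.n_atoms:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not pack {spec.n_atoms} sites with min_sep="
                f"{spec.min_sep} A after {max_attempts} attempts"
            )
        x = rng.random(3)
        own = np.mod(x @ rots.transpose(0, 2, 1) + trans, 1.0)
        # check against existing images and against own non-identity images
        cand_pool = np.vstack([images, own]) if len(images) else own
        delta = cand_pool[:, None, :] - own[None, :, :]
        delta -= np.round(delta)
        dist = np.linalg.norm(cell.frac_to_cart(delta), axis=-1)
        # ignore zero self-distances (each image vs itself)
        dist[dist < 1e-9] = np.inf
        if dist.min() < spec.min_sep:
            continue
        placed.append(np.mod(x, 1.0))
        images = np.vstack([images, own])
    return SiteList(np.array(placed), np.ones(spec.n_atoms))


def structure_factors(
    sites_frac: np.ndarray,
    hkl: np.ndarray,
    cell: UnitCell,
    sg: SpaceGroupOps,
    f=1.0,
    b_factor=0.0,
    occupancy=1.0,
) -> np.ndarray:
    """Point-atom structure factors with symmetry summation.

    F(h) = sum_j occ_j f_j exp(-B_j s^2 / 4) sum_ops exp(2 pi i h.(R x_j + t))
    with s = 1/d(h).  ``f`` may be complex (anomalous scattering).
    """
    sites = np.atleast_2d(np.asarray(sites_frac, dtype=float))
    hkl = np.asarray(hkl, dtype=np.int64)
    n_at = len(sites)
    f = np.broadcast_to(np.asarray(f, dtype=complex), (n_at,))
    b = np.broadcast_to(np.asarray(b_factor, dtype=float), (n_at,))
    occ = np.broadcast_to(np.asarray(occupancy, dtype=float), (n_at,))
    out = np.zeros(len(hkl), dtype=complex)
    s2_all = 1.0 / cell.d_spacing(hkl) ** 2
    for start in range(0, len(hkl), _CHUNK):
        sl = slice(start, start + _CHUNK)
        h = hkl[sl]
        hr = sg.transformed_indices(h)  # (n, m, 3)
        ht = h.astype(float) @ sg.translations.T  # (n, m)
        dots = np.einsum("nmk,jk->nmj", hr.astype(float), sites) + ht[:, :, None]
        geom = np.exp(2j * np.pi * dots).sum(axis=1)  # (n, j)
        dw = np.exp(-b[None, :] * s2_all[sl, None] / 4.0)
        out[sl] = (geom * dw * (occ * f)[None, :]).sum(axis=1)
    return out


def _shell_means(d: np.ndarray, amp: np.ndarray, n_shells: int = 10) -> np.ndarray:
    """Per-reflection shell-mean amplitude (equal volume in 1/d^3)."""
    s3 = 1.0 / d**3
    edges = np.linspace(s3.min() - 1e-12, s3.max() + 1e-12, n_shells + 1)
    idx = np.clip(np.searchsorted(edges, s3, side="right") - 1, 0, n_shells - 1)
    means = np.array(
        [amp[idx == i].mean() if np.any(idx == i) else np.nan for i in range(n_shells)]
    )
    # fill empty shells from the global mean
    means = np.where(np.isfinite(means), means, amp.mean())
    return means[idx]


def make_dataset(spec: SyntheticSpec, mode: str = "direct_fa"):
    """Generate a synthetic dataset plus its ground-truth bundle.

    ``direct_fa``: returns a :class:`ReflectionSet` whose dF are noisy
    substructure amplitudes |F_A|.  ``bijvoet``: returns a
    :class:`BijvoetPairSet` with F+/F- from substructure plus light-atom
    background with complex anomalous scattering.  The truth bundle holds
    sites, true |F_A| and true substructure phases.
    """
    rng = np.random.default_rng(spec.seed)
    sites = place_substructure(spec, rng)
    cell, sg = spec.cell, spec.sg
    hkl = generate_asu_indices(cell, sg, spec.d_min)
    d = cell.d_spacing(hkl)
    f_anom = spec.f0 + spec.f_prime + 1j * spec.f_dprime
    S = structure_factors(
        sites.frac, hkl, cell, sg, f=1.0, b_factor=spec.b_factor,
        occupancy=spec.occupancy,
    )
    # substructure amplitude carries |f_anom|; the truth phases are those of
    # the real point-atom density (the constant anomalous phase rotation is
    # not representable by a real map and is irrelevant to site recovery)
    truth = {
        "sites": sites,
        "hkl": hkl,
        "d": d,
        "f_a": np.abs(f_anom) * np.abs(S),
        "phases": np.angle(S),
    }
    FA = f_anom * S
    if mode == "direct_fa":
        base = np.abs(FA)
        sigma = spec.noise_frac * base.mean()
        sig_floor = max(sigma, 1e-6 * max(base.mean(), 1.0))
        dF = base + rng.normal(0.0, 1.0, len(base)) * sigma
        dF = np.abs(dF)
        refl = ReflectionSet(
            hkl,
            dF=dF,
            sig_dF=np.full(len(hkl), sig_floor),
            d=d,
            centric=sg.is_centric(hkl),
        )
        return refl, truth
    if mode == "bijvoet":
        bg = rng.random((spec.n_background, 3)) if spec.n_background else np.zeros((0, 3))
        truth["background"] = bg
        B = (
            structure_factors(
                bg, hkl, cell, sg, f=spec.f0_light, b_factor=spec.b_factor
            )
            if len(bg)
            else np.zeros(len(hkl), dtype=complex)
        )
        fplus = np.abs(B + f_anom * S)
        fminus = np.abs(np.conj(B) + f_anom * np.conj(S))
        mean_amp = _shell_means(d, 0.5 * (fplus + fminus))
        sigma = spec.noise_frac * mean_amp
        sig_out = np.where(sigma > 0, sigma, 1e-6 * max(mean_amp.mean(), 1.0))
        fplus_obs = np.abs(fplus + rng.normal(0.0, 1.0, len(hkl)) * sigma)
        fminus_obs = np.abs(fminus + rng.normal(0.0, 1.0, len(hkl)) * sigma)
        pairs = BijvoetPairSet(hkl, fplus_obs, sig_out, fminus_obs, sig_out)
        return pairs, truth
    raise ValueError("mode must be 'direct_fa' or 'bijvoet'")
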