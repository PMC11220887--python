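"""Unit-cell geometry, space-group operators and reflection symmetry.

Symmetry is driven entirely by an explicit list of ``"x,y,z"``-style
operator strings; a small built-in table of common symbols is provided as a
convenience only.  Reflection indices transform as row vectors, ``h' = h R``,
with phases ``phi(h R) = phi(h) - 2*pi*h.t``, and Friedel mates carry the
conjugate phase.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .records import ReflectionSet

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroupOps",
    "parse_symop",
    "expand_reflections",
    "reduce_to_asu",
    "is_systematically_absent",
    "permissible_origin_shifts",
    "generate_asu_indices",
]

#: Discrete permissible-origin search grid (denominator of candidate shifts).
ORIGIN_GRID = 12

_AXES = {"x": 0, "y": 1, "z": 2}


def parse_symop(text: str) -> "SymOp":
    """Parse one operator string like ``"-x, y+1/2, -z"``."""
    parts = text.lower().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"bad symmetry operator {text!r}")
    rot = np.zeros((3, 3), dtype=np.int64)
    trans = np.zeros(3)
    for i, part in enumerate(parts):
        # tokenize into signed terms
        terms = []
        buf = ""
        for ch in part:
            if ch in "+-" and buf:
                terms.append(buf)
                buf = ch
            else:
                buf += ch
        if buf:
            terms.append(buf)
        if not terms:
            raise ValueError(f"bad symmetry operator component {part!r}")
        for term in terms:
            sign = 1
            body = term
            while body and body[0] in "+-":
                if body[0] == "-":
                    sign = -sign
                body = body[1:]
            if body in _AXES:
                rot[i, _AXES[body]] += sign
            elif body:
                trans[i] += sign * float(Fraction(body))
            else:
                raise ValueError(f"bad term {term!r} in {text!r}")
    return SymOp(rot, trans)


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (angstrom) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")
        if np.linalg.det(self.metric) <= 0:
            raise ValueError("cell metric is not positive definite")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def metric(self) -> np.ndarray:
        """Real-space metric tensor G (fractional -> squared length)."""
        a, b, c = self.lengths
        ca, cb, cg = np.cos(np.radians(self.angles))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric)))

    @property
    def orthogonalization(self) -> np.ndarray:
        """Matrix M with cartesian = M @ fractional (PDB convention)."""
        a, b, c = self.lengths
        ca, cb, cg = np.cos(np.radians(self.angles))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (a * b * sg)],
            ]
        )

    def frac_to_cart(self, x) -> np.ndarray:
        return np.asarray(x, float) @ self.orthogonalization.T

    def d_spacing(self, hkl) -> np.ndarray:
        """Resolution d(hkl) in angstrom; inf for (0,0,0)."""
        h = np.asarray(hkl, dtype=float)
        inv_d2 = np.einsum("...i,ij,...j->...", h, self.reciprocal_metric, h)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def to_list(self) -> list:
        return [self.a, self.b, self.c, self.alpha, self.beta, self.gamma]


@dataclass(frozen=True)
class SymOp:
    """One crystallographic operator x' = R x + t (t reduced mod 1)."""

    rot: np.ndarray
    trans: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rot, dtype=np.int64).reshape(3, 3)
        det = int(round(np.linalg.det(rot)))
        if det not in (1, -1):
            raise ValueError(f"operator rotation has determinant {det}")
        trans = np.mod(np.asarray(self.trans, dtype=float).reshape(3), 1.0)
        trans = np.round(trans * ORIGIN_GRID * 2) / (ORIGIN_GRID * 2)
        trans = np.mod(trans, 1.0)
        object.__setattr__(self, "rot", rot)
        object.__setattr__(self, "trans", trans)

    def key(self) -> tuple:
        return (
            tuple(self.rot.ravel().tolist()),
            tuple(np.round(self.trans * 24).astype(int).tolist()),
        )

    def __mul__(self, other: "SymOp") -> "SymOp":
        return SymOp(self.rot @ other.rot, self.rot @ other.trans + self.trans)

    def apply(self, x) -> np.ndarray:
        return np.asarray(x, float) @ self.rot.T + self.trans

    def __str__(self) -> str:
        out = []
        for i in range(3):
            s = ""
            for j, name in enumerate("xyz"):
                cij = self.rot[i, j]
                if cij:
                    s += ("+" if cij > 0 else "-") if abs(cij) == 1 else f"{cij:+d}*"
                    s += name
            t = Fraction(self.trans[i]).limit_denominator(24)
            if t:
                s += f"+{t}" if t > 0 else f"{t}"
            out.append(s.lstrip("+"))
        return ",".join(out)


IDENTITY = SymOp(np.eye(3, dtype=np.int64), np.zeros(3))

# Minimal convenience table; the supported interface is operator strings.
SYMBOL_TABLE = {
    "P1": ["x,y,z"],
    "P-1": ["x,y,z", "-x,-y,-z"],
    "P2": ["x,y,z", "-x,y,-z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "C2": ["x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"],
    "P222": ["x,y,z", "-x,-y,z", "-x,y,-z", "x,-y,-z"],
    "P21212": [
        "x,y,z",
        "-x,-y,z",
        "-x+1/2,y+1/2,-z",
        "x+1/2,-y+1/2,-z",
    ],
    "P212121": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ],
    "P4": ["x,y,z", "-x,-y,z", "-y,x,z", "y,-x,z"],
}


class SpaceGroupOps:
    """A closed set of space-group operators with derived symmetry data."""

    def __init__(self, ops) -> None:
        ops = [op if isinstance(op, SymOp) else parse_symop(op) for op in ops]
        self.ops = self._close(ops)
        self.rotations = np.stack([op.rot for op in self.ops])
        self.translations = np.stack([op.trans for op in self.ops])
        lr = {}
        for rot in self.rotations:
            for r in (rot, -rot):
                lr[tuple(r.ravel().tolist())] = r
        self.laue_rotations = np.stack(sorted(lr.values(), key=lambda r: tuple(r.ravel())))

    @staticmethod
    def _close(ops) -> list:
        if not ops:
            raise ValueError("at least one operator required")
        group = {IDENTITY.key(): IDENTITY}
        for op in ops:
            group[op.key()] = op
        # fixed-point closure under composition (mod lattice translations)
        changed = True
        while changed:
            changed = False
            items = list(group.values())
            for a in items:
                for b in items:
                    c = a * b
                    if c.key() not in group:
                        group[c.key()] = c
                        changed = True
            if len(group) > 192:
                raise ValueError("operator list does not close into a small group")
        return sorted(group.values(), key=lambda op: op.key())

    @classmethod
    def from_strings(cls, strings) -> "SpaceGroupOps":
        return cls(strings)

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupOps":
        key = symbol.replace(" ", "").replace("(", "").replace(")", "").upper()
        if key not in SYMBOL_TABLE:
            raise KeyError(
                f"unknown space-group symbol {symbol!r}; pass explicit operators"
            )
        return cls(SYMBOL_TABLE[key])

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    # -- reciprocal-space index machinery -------------------------------

    def transformed_indices(self, hkl) -> np.ndarray:
        """All h R for every op; shape (N, n_ops, 3)."""
        h = np.asarray(hkl, dtype=np.int64)
        return np.einsum("nj,mjk->nmk", h, self.rotations)

    def phase_factors(self, hkl) -> np.ndarray:
        """exp(-2*pi*i h.t) for every op; shape (N, n_ops)."""
        h = np.asarray(hkl, dtype=float)
        return np.exp(-2j * np.pi * (h @ self.translations.T))

    def laue_orbit(self, h) -> np.ndarray:
        """Unique members of {+-(h R)} as an (M, 3) array."""
        h = np.asarray(h, dtype=np.int64)
        mem = np.einsum("j,mjk->mk", h, self.rotations)
        mem = np.concatenate([mem, -mem])
        return np.unique(mem, axis=0)

    def canonical(self, hkl) -> np.ndarray:
        """Lexicographically greatest Laue-orbit member for each index."""
        h = np.asarray(hkl, dtype=np.int64)
        single = h.ndim == 1
        h = np.atleast_2d(h)
        mem = np.einsum("nj,mjk->nmk", h, self.laue_rotations)
        # lexicographic maximum over orbit members
        score = (
            mem[..., 0] * np.int64(4_000_000_000_000)
            + mem[..., 1] * np.int64(2_000_000)
            + mem[..., 2]
        )
        best = np.argmax(score, axis=1)
        out = mem[np.arange(len(h)), best]
        return out[0] if single else out

    def is_centric(self, hkl) -> np.ndarray:
        """True where some point-group rotation maps h to -h."""
        h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        mem = self.transformed_indices(h)
        flag = np.any(np.all(mem == -h[:, None, :], axis=2), axis=1)
        return bool(flag[0]) if np.asarray(hkl).ndim == 1 else flag

    def epsilon(self, hkl) -> np.ndarray:
        """Symmetry enhancement factor: order of the stabilizer of h."""
        h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        mem = self.transformed_indices(h)
        return np.sum(np.all(mem == h[:, None, :], axis=2), axis=1)

    @property
    def polar_axes(self) -> list:
        """Axes with continuous origin freedom."""
        out = []
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            if all(np.allclose(op.rot @ e, e) for op in self.ops):
                out.append("xyz"[i])
        return out


def is_systematically_absent(hkl, sg: SpaceGroupOps):
    """Extinction flag: some op fixes h with a non-integral phase shift."""
    h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    mem = sg.transformed_indices(h)  # (N, m, 3)
    fixes = np.all(mem == h[:, None, :], axis=2)  # (N, m)
    shift = h.astype(float) @ sg.translations.T  # (N, m)
    bad = np.abs(shift - np.round(shift)) > 1e-9
    flag = np.any(fixes & bad, axis=1)
    return flag if np.asarray(hkl).ndim == 2 else bool(flag[0])


def permissible_origin_shifts(sg: SpaceGroupOps, grid: int = ORIGIN_GRID):
    """Discrete allowed origin shifts plus continuous polar axes.

    Brute force over the 1/``grid`` fractional lattice: a shift t is allowed
    when (I - R) t = 0 (mod 1) for every rotation R.  Components along polar
    axes are zeroed before deduplication (they are reported separately as
    continuous freedoms).
    """
    polar = sg.polar_axes
    polar_idx = ["xyz".index(ax) for ax in polar]
    eye = np.eye(3)
    cand = np.array(
        list(itertools.product(range(grid), repeat=3)), dtype=float
    ) / grid
    ok = np.ones(len(cand), dtype=bool)
    for op in sg.ops:
        resid = cand @ (eye - op.rot).T
        resid -= np.round(resid)
        ok &= np.all(np.abs(resid) < 1e-9, axis=1)
    shifts = cand[ok]
    shifts[:, polar_idx] = 0.0
    shifts = np.unique(np.mod(shifts, 1.0), axis=0)
    return shifts, polar


def generate_asu_indices(
    cell: UnitCell,
    sg: SpaceGroupOps,
    d_min: float,
    include_absent: bool = False,
) -> np.ndarray:
    """All Laue-unique Miller indices with d >= d_min (h=0 excluded).

    Representatives are the lexicographically greatest orbit members;
    systematic absences are dropped unless requested.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    rstar = cell.reciprocal_metric
    hmax = [int(np.floor(1.0 / (d_min * np.sqrt(rstar[i, i])))) for i in range(3)]
    axes = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    d = cell.d_spacing(grid)
    grid = grid[d >= d_min - 1e-9]
    canon = sg.canonical(grid)
    keep = np.all(grid == canon, axis=1)
    out = grid[keep]
    if not include_absent:
        out = out[~is_systematically_absent(out, sg)]
    # deterministic ordering: descending lexicographic
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))[::-1]
    return out[order]


def expand_reflections(
    asu_set: ReflectionSet, sg: SpaceGroupOps, tol: float = 1e-6
) -> ReflectionSet:
    """Symmetry-expand Laue-unique reflections to the full sphere.

    Each op (R, t) contributes (h R) with phase phi - 2*pi*h.t, and the
    Friedel mate with conjugated phase.  Inconsistent duplicate amplitudes
    raise with the offending index named.
    """
    values = asu_set.values
    members = sg.transformed_indices(asu_set.hkl)  # (N, m, 3)
    factors = sg.phase_factors(asu_set.hkl)  # (N, m)
    seen: dict = {}
    parent: dict = {}
    for i in range(len(asu_set)):
        for j in range(len(sg)):
            for h, v in (
                (tuple(members[i, j]), values[i] * factors[i, j]),
                (tuple(-members[i, j]), np.conj(values[i] * factors[i, j])),
            ):
                if h in seen:
                    ref = seen[h]
                    scale = max(abs(ref), abs(v), 1.0)
                    if abs(ref - v) > tol * scale:
                        raise ValueError(
                            "inconsistent symmetry duplicates at "
                            f"{tuple(int(x) for x in h)}: {complex(ref)} vs {complex(v)}"
                        )
                else:
                    seen[h] = v
                    parent[h] = i
    hkl = np.array(sorted(seen), dtype=np.int64)
    vals = np.array([seen[tuple(h)] for h in hkl])
    idx = np.array([parent[tuple(h)] for h in hkl])
    return ReflectionSet(
        hkl,
        dF=asu_set.dF[idx],
        sig_dF=asu_set.sig_dF[idx],
        E=np.abs(vals),
        phase=np.angle(vals),
        d=asu_set.d[idx],
        observed=asu_set.observed[idx],
        centric=asu_set.centric[idx],
        absent=asu_set.absent[idx],
        beyond=asu_set.beyond[idx],
    )


def reduce_to_asu(full_set: ReflectionSet, sg: SpaceGroupOps) -> ReflectionSet:
    """Reduce full-sphere coefficients to Laue-unique representatives.

    Every orbit member is back-transformed to the representative frame and
    the complex values are averaged (phase-aligned averaging absorbs any
    inconsistency).  Representative = lexicographically greatest triple.
    """
    canon = sg.canonical(full_set.hkl)
    values = full_set.values
    acc: dict = {}
    for i in range(len(full_set)):
        rep = tuple(canon[i])
        # back-transform through every op/Friedel relation linking rep to
        # this member; averaging over all of them makes the reduction a
        # projection (idempotent even on symmetry-inconsistent input)
        found = False
        for j, rot in enumerate(sg.rotations):
            target = np.asarray(rep, dtype=np.int64) @ rot
            fac = np.exp(2j * np.pi * float(np.dot(rep, sg.translations[j])))
            if np.array_equal(target, full_set.hkl[i]):
                acc.setdefault(rep, []).append((values[i] * fac, i))
                found = True
            if np.array_equal(-target, full_set.hkl[i]):
                acc.setdefault(rep, []).append((np.conj(values[i]) * fac, i))
                found = True
        if not found:  # cannot happen for a closed group
            raise RuntimeError(f"orbit bookkeeping failed at {tuple(full_set.hkl[i])}")
    hkl = np.array(sorted(acc, reverse=True), dtype=np.int64)
    vals = np.empty(len(hkl), dtype=complex)
    src = np.empty(len(hkl), dtype=np.int64)
    for k, h in enumerate(hkl):
        entries = acc[tuple(h)]
        vals[k] = np.mean([z for z, _ in entries])
        src[k] = entries[0][1]
    return ReflectionSet(
        hkl,
        dF=full_set.dF[src],
        sig_dF=full_set.sig_dF[src],
        E=np.abs(vals),
        phase=np.angle(vals),
        d=full_set.d[src],
        observed=full_set.observed[src],
        centric=full_set.centric[src],
        absent=full_set.absent[src],
        beyond=full_set.beyond[src],
    )
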