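"""Readers and writers for the plain-text interchange formats.

Reflections travel as fixed-column HKL (3I4,2F8.2) or whitespace tables;
sites as CSV (fractional x,y,z + height) or PDB HETATM records; maps as
CCP4/MRC (mode 2, float32).  Unobserved Bijvoet mates are encoded as an
amplitude/sigma pair of 0.00/0.00 and round-trip to NaN.
"""

from __future__ import annotations

import numpy as np

from .records import BijvoetPairSet, ReflectionSet
from .sites import SiteList
from .symmetry import UnitCell

__all__ = [
    "write_hkl",
    "read_hkl",
    "write_pairs",
    "read_pairs",
    "write_phases",
    "read_phases",
    "write_sites_csv",
    "read_sites_csv",
    "write_sites_pdb",
    "write_ccp4_map",
    "read_ccp4_map",
]


def write_hkl(path, hkl, dF, sig) -> None:
    """SHELX-style fixed columns: 3I4,2F8.2."""
    with open(path, "w") as fh:
        for (h, k, l), a, s in zip(np.asarray(hkl), dF, sig):
            fh.write(f"{h:4d}{k:4d}{l:4d}{a:8.2f}{s:8.2f}\n")


def _parse_fixed(line: str):
    try:
        h = int(line[0:4])
        k = int(line[4:8])
        l = int(line[8:12])
        a = float(line[12:20])
        s = float(line[20:28])
        return h, k, l, a, s
    except (ValueError, IndexError):
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"unparseable HKL line: {line!r}")
        return int(parts[0]), int(parts[1]), int(parts[2]), float(parts[3]), float(parts[4])


def read_hkl(path):
    """Returns (hkl, dF, sig) arrays; blank/short lines are skipped."""
    hkl, dF, sig = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            h, k, l, a, s = _parse_fixed(line)
            if (h, k, l) == (0, 0, 0):
                continue  # conventional terminator record
            hkl.append((h, k, l))
            dF.append(a)
            sig.append(s)
    return np.array(hkl, dtype=np.int64), np.array(dF), np.array(sig)


def write_pairs(path, pairs: BijvoetPairSet) -> None:
    """Whitespace table: h k l F+ sigF+ F- sigF- (missing mate -> 0 0)."""
    with open(path, "w") as fh:
        for i in range(len(pairs)):
            h, k, l = pairs.hkl[i]
            fp, sp = pairs.fplus[i], pairs.sig_fplus[i]
            fm, sm = pairs.fminus[i], pairs.sig_fminus[i]
            if not np.isfinite(fp):
                fp, sp = 0.0, 0.0
            if not np.isfinite(fm):
                fm, sm = 0.0, 0.0
            fh.write(
                f"{h:5d}{k:5d}{l:5d}{fp:12.4f}{sp:12.4f}{fm:12.4f}{sm:12.4f}\n"
            )


def read_pairs(path) -> BijvoetPairSet:
    hkl, fp, sp, fm, sm = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7:
                if parts:
                    raise ValueError(f"unparseable pairs line: {line!r}")
                continue
            hkl.append(tuple(int(x) for x in parts[:3]))
            vals = [float(x) for x in parts[3:7]]
            if vals[0] == 0.0 and vals[1] == 0.0:
                vals[0] = np.nan
            if vals[2] == 0.0 and vals[3] == 0.0:
                vals[2] = np.nan
            fp.append(vals[0])
            sp.append(vals[1])
            fm.append(vals[2])
            sm.append(vals[3])
    return BijvoetPairSet(
        np.array(hkl, dtype=np.int64),
        np.array(fp), np.array(sp), np.array(fm), np.array(sm)
    )


def write_phases(path, hkl, amp, phase_rad) -> None:
    """h k l |E| phase(degrees) as a whitespace table."""
    deg = np.degrees(np.asarray(phase_rad))
    with open(path, "w") as fh:
        for (h, k, l), a, p in zip(np.asarray(hkl), amp, deg):
            fh.write(f"{h:5d}{k:5d}{l:5d}{a:12.4f}{p:10.2f}\n")


def read_phases(path):
    hkl, amp, ph = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5:
                continue
            hkl.append(tuple(int(x) for x in parts[:3]))
            amp.append(float(parts[3]))
            ph.append(np.radians(float(parts[4])))
    return np.array(hkl, dtype=np.int64), np.array(amp), np.array(ph)


def write_sites_csv(path, sites: SiteList) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,z,height\n")
        for (x, y, z), h in zip(sites.frac, sites.height):
            fh.write(f"{x:.6f},{y:.6f},{z:.6f},{h:.4f}\n")


def read_sites_csv(path) -> SiteList:
    frac, height = [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) < 3:
                continue
            frac.append([float(p) for p in parts[:3]])
            height.append(float(parts[3]) if len(parts) > 3 else 0.0)
    return SiteList(np.array(frac).reshape(-1, 3), np.array(height))


def write_sites_pdb(path, sites: SiteList, cell: UnitCell, element: str = "SE") -> None:
    """HETATM records with orthogonalized coordinates; occupancy carries the
    height normalized to the tallest peak."""
    cart = cell.frac_to_cart(sites.frac)
    hmax = sites.height.max() if len(sites) and sites.height.max() > 0 else 1.0
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} P 1\n"
        )
        for i, ((x, y, z), h) in enumerate(zip(cart, sites.height), start=1):
            occ = h / hmax
            fh.write(
                f"HETATM{i:5d} {element:<3s} SUB A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{20.0:6.2f}          "
                f"{element:>2s}\n"
            )
        fh.write("END\n")


def write_ccp4_map(path, values: np.ndarray, cell: UnitCell) -> None:
    """Minimal CCP4/MRC mode-2 map over one unit cell (axis order X,Y,Z)."""
    v = np.asarray(values, dtype=np.float32)
    nx, ny, nz = v.shape
    header = np.zeros(256, dtype=np.int32)
    fheader = header.view(np.float32)
    header[0:3] = (nx, ny, nz)
    header[3] = 2  # mode: float32
    header[4:7] = 0  # start
    header[7:10] = (nx, ny, nz)  # sampling
    fheader[10:13] = (cell.a, cell.b, cell.c)
    fheader[13:16] = (cell.alpha, cell.beta, cell.gamma)
    header[16:19] = (1, 2, 3)  # axis order
    fheader[19] = float(v.min())
    fheader[20] = float(v.max())
    fheader[21] = float(v.mean())
    header[22] = 1  # space group placeholder
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = 0x00004144  # little-endian machine stamp
    fheader[54] = float(v.std())
    with open(path, "wb") as fh:
        header.tofile(fh)
        # CCP4 fastest axis is the first header axis; store Fortran order
        np.ascontiguousarray(v.T, dtype=np.float32).tofile(fh)


def read_ccp4_map(path):
    with open(path, "rb") as fh:
        header = np.fromfile(fh, dtype=np.int32, count=256)
        fheader = header.view(np.float32)
        nx, ny, nz = (int(x) for x in header[0:3])
        if header[3] != 2:
            raise ValueError("only mode-2 (float32) CCP4 maps supported")
        cell = UnitCell(*fheader[10:16].tolist())
        data = np.fromfile(fh, dtype=np.float32, count=nx * ny * nz)
    values = data.reshape((nz, ny, nx)).T.astype(float)
    return values, cell
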