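"""Hexagonal apatite unit-cell geometry and lattice refinement.

Bone mineral is a hexagonal apatite (space group P6_3/m), so its cell is
fixed by two lengths: a = b and c, with volume V = (sqrt(3)/2) a^2 c.
The interplanar spacing of reflection (hkl) is

    1/d^2 = (4/3) (h^2 + hk + k^2) / a^2 + l^2 / c^2

which is linear in (1/a^2, 1/c^2): given indexed powder-peak positions,
(a, c) follow from weighted linear least squares on observed 1/d^2 —
a desk-scale stand-in for full-profile Rietveld refinement. Fluoride
substitution in the channel site contracts the a-axis, so the refined
cell places a sample on the hydroxylapatite-to-fluorapatite axis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CU_KALPHA1",
    "DEFAULT_HKLS",
    "UnitCell",
    "Reflection",
    "ReflectionList",
    "cell_volume",
    "d_spacing",
    "reflection_positions",
    "refine_cell",
    "endmember_axis_position",
]

#: Cu K-alpha-1 wavelength (Angstrom)
CU_KALPHA1 = 1.5406

#: standard strong apatite reflections used by default
DEFAULT_HKLS = [
    (0, 0, 2), (1, 0, 2), (2, 1, 0), (2, 1, 1), (1, 1, 2), (3, 0, 0),
    (2, 0, 2), (3, 0, 1), (3, 1, 0), (2, 2, 2), (2, 1, 3), (0, 0, 4),
]


def cell_volume(a, c):
    """Hexagonal cell volume (sqrt(3)/2) a^2 c in Angstrom^3."""
    if a <= 0 or c <= 0:
        raise ValueError("cell axes must be positive")
    return (math.sqrt(3.0) / 2.0) * a * a * c


@dataclass
class UnitCell:
    """Hexagonal cell: axes in Angstrom, volume in Angstrom^3."""

    a: float
    c: float
    a_sd: float | None = None
    c_sd: float | None = None
    volume_sd: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("cell axes must be positive")

    @property
    def volume(self):
        return cell_volume(self.a, self.c)

    def to_json(self):
        return json.dumps(
            {
                "a": self.a, "c": self.c, "volume": self.volume,
                "a_sd": self.a_sd, "c_sd": self.c_sd, "volume_sd": self.volume_sd,
                **({"meta": self.meta} if self.meta else {}),
            },
            indent=2,
        )


@dataclass
class Reflection:
    h: int
    k: int
    l: int
    two_theta: float
    weight: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.two_theta < 180.0):
            raise ValueError("two_theta must lie in (0, 180) degrees")
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("(000) is not a reflection")

    @property
    def hk_term(self):
        return (4.0 / 3.0) * (self.h**2 + self.h * self.k + self.k**2)


@dataclass
class ReflectionList:
    entries: list
    wavelength: float = CU_KALPHA1

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        self.entries = [
            e if isinstance(e, Reflection) else Reflection(*e) for e in self.entries
        ]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_csv(cls, source, wavelength=None):
        """Read ``h,k,l,two_theta[,weight]`` CSV; wavelength from a
        ``# wavelength=...`` header line unless given explicitly."""
        from pathlib import Path

        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        entries, wl = [], wavelength
        for i, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "wavelength" in line and wl is None:
                    wl = float(line.split("=")[1])
                continue
            parts = line.split(",")
            if parts[0].strip().lower() == "h":
                continue  # header row
            try:
                h, k, l = (int(p) for p in parts[:3])
                tt = float(parts[3])
                w = float(parts[4]) if len(parts) > 4 else 1.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed reflection CSV at line {i}: {line!r}") from exc
            entries.append(Reflection(h, k, l, tt, w))
        return cls(entries, wl if wl is not None else CU_KALPHA1)

    def to_csv(self, path):
        from pathlib import Path

        lines = [f"# wavelength={self.wavelength}", "h,k,l,two_theta,weight"]
        lines += [
            f"{e.h},{e.k},{e.l},{e.two_theta:.6f},{e.weight:g}" for e in self.entries
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def d_spacing(cell: UnitCell, h, k, l):
    """Interplanar spacing of (hkl) for a hexagonal cell."""
    inv_d2 = (4.0 / 3.0) * (h * h + h * k + k * k) / cell.a**2 + l * l / cell.c**2
    return 1.0 / math.sqrt(inv_d2)


def reflection_positions(cell: UnitCell, hkls=None, wavelength=CU_KALPHA1) -> ReflectionList:
    """Bragg 2-theta positions (degrees) of the given reflections.

    Reflections with lambda/(2d) > 1 are geometrically inaccessible and
    dropped with a warning.
    """
    hkls = DEFAULT_HKLS if hkls is None else hkls
    entries = []
    for h, k, l in hkls:
        d = d_spacing(cell, h, k, l)
        s = wavelength / (2.0 * d)
        if s > 1.0:
            warnings.warn(f"reflection ({h}{k}{l}) inaccessible at lambda={wavelength}")
            continue
        entries.append(Reflection(h, k, l, math.degrees(2.0 * math.asin(s))))
    return ReflectionList(entries, wavelength)


def _wls_cell(peaks: ReflectionList, offset=0.0):
    """Weighted linear LS of observed 1/d^2 on (hk-term, l^2) -> (a, c, cov)."""
    X, yv, w = [], [], []
    for e in peaks:
        theta = math.radians((e.two_theta - offset) / 2.0)
        d = peaks.wavelength / (2.0 * math.sin(theta))
        X.append([e.hk_term, e.l * e.l])
        yv.append(1.0 / d**2)
        w.append(e.weight)
    X, yv, w = np.asarray(X), np.asarray(yv), np.asarray(w)
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError(
            "degenerate reflection geometry: need both a-sensitive and "
            "c-sensitive reflections"
        )
    Xw = X * w[:, None]
    XtX = X.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yv)
    if beta[0] <= 0 or beta[1] <= 0:
        raise ValueError("refinement produced a non-physical cell")
    resid = yv - X @ beta
    dof = max(len(yv) - 2, 1)
    sigma2 = float(resid @ (w * resid)) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    rss = float(resid @ (w * resid))
    return beta, cov, rss


def refine_cell(peaks: ReflectionList, refine_zero_offset=None) -> UnitCell:
    """Refine (a, c) from indexed powder-peak positions.

    Weighted linear least squares of observed 1/d^2 against the hexagonal
    metric terms yields (1/a^2, 1/c^2); parameter covariance propagates to
    a_sd, c_sd and volume_sd by the delta method. A constant 2-theta zero
    offset can additionally be refined (nested 1-D search) when at least
    6 reflections are available; it is off by default because it trades
    variance into the cell axes when no instrumental offset exists.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 reflections")
    if refine_zero_offset is None:
        refine_zero_offset = False
    if refine_zero_offset and len(peaks) < 6:
        raise ValueError("zero-offset refinement needs at least 6 reflections")
    offset = 0.0
    if refine_zero_offset:
        res = minimize_scalar(
            lambda z: _wls_cell(peaks, z)[2], bounds=(-0.25, 0.25), method="bounded",
            options={"xatol": 1e-7},
        )
        offset = float(res.x)
    beta, cov, _ = _wls_cell(peaks, offset)
    a = beta[0] ** -0.5
    c = beta[1] ** -0.5
    # delta method: a = beta0^(-1/2) => da/dbeta0 = -a^3/2, same for c
    da = 0.5 * a**3
    dc = 0.5 * c**3
    a_sd = float(da * math.sqrt(max(cov[0, 0], 0.0)))
    c_sd = float(dc * math.sqrt(max(cov[1, 1], 0.0)))
    v = cell_volume(a, c)
    # V = (sqrt3/2) a^2 c: dV = V (2 da/a + dc/c), with (a, c) covariance
    g = np.array([2.0 * v / a * -da, v / c * -dc])  # dV/dbeta
    v_sd = float(math.sqrt(max(g @ cov @ g, 0.0)))
    return UnitCell(
        a=float(a), c=float(c), a_sd=a_sd, c_sd=c_sd, volume_sd=v_sd,
        meta={"zero_offset_deg": offset, "n_reflections": len(peaks)},
    )


def endmember_axis_position(cell: UnitCell, hap_ref: UnitCell, fap_ref: UnitCell):
    """Linear position of the a-axis between hydroxylapatite (0) and
    fluorapatite (1) reference cells, clipped to [0, 1].

    No default references are asserted; both must be supplied.
    """
    if math.isclose(hap_ref.a, fap_ref.a):
        raise ValueError("reference cells have equal a-axes")
    t = (cell.a - hap_ref.a) / (fap_ref.a - hap_ref.a)
    return float(min(max(t, 0.0), 1.0))
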