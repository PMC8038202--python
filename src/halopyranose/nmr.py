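"""Solution-state conformational analysis of pyranoses from NMR observables.

Four pieces:

* a generalized Karplus model ``3J(phi) = C0 + C1 cos phi + C2 cos 2phi +
  C3 cos 3phi + S1 sin phi + S2 sin 2phi`` relating a vicinal proton-proton
  coupling to the H-C-C-H torsion, with coefficients that may be derived
  from substituent electronegativities (Haasnoot–Altona parameterization),
  plus a root-finding inversion that returns *all* torsions consistent with
  a measured J;
* hydroxymethyl (C5-C6) rotamer populations gt/gg/tg from the two
  H5-H6 couplings via the limiting-value linear system
  ``J_56R = 9.9 A + 0.8 B + 4.5 C``, ``J_56S = 1.5 A + 1.3 B + 10.8 C``,
  ``A + B + C = 1``;
* C6-O6 gauche/trans populations from the apparent geminal H6R-H6S
  coupling, ``J_gauche = 12.7 (A+B) + 11.5 C``,
  ``J_trans = 9.7 (A+B) - 8.5 C``, ``J_app = D J_gauche + E J_trans``,
  ``D + E = 1``;
* NOE analysis: cross-relaxation rates sigma as initial-buildup slopes of
  NOESY peak intensity vs mixing time, and distances
  ``r = r_ref (sigma/sigma_ref)^(-1/6)`` referenced to the geminal
  H6R-H6S pair at r_ref = 1.77 Å.

Geminal couplings are negative in reality; magnitudes are used throughout,
matching how the limiting values are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KarplusParams",
    "CouplingSet",
    "RotamerPopulations",
    "NOEBuildup",
    "karplus_forward",
    "karplus_invert",
    "haasnoot_altona_params",
    "rotamers_c5c6",
    "rotamers_c6o6",
    "c5c6_forward",
    "c6o6_gauche_trans",
    "fit_sigma",
    "noe_distance",
    "anomer_fraction",
    "C5C6_MATRIX",
    "NOE_R_REF",
    "LAMBDA_DEFAULTS",
]

# limiting coupling values (Hz) of the gt/gg/tg C5-C6 rotamers
C5C6_MATRIX = np.array([
    [9.9, 0.8, 4.5],    # 3J_H5,H6R
    [1.5, 1.3, 10.8],   # 3J_H5,H6S
    [1.0, 1.0, 1.0],    # closure A+B+C = 1
])

# limiting geminal couplings (Hz, magnitudes) of the C6-O6 rotamers,
# as linear functions of the C5-C6 fractions: J = p*(A+B) + q*C
C6O6_GAUCHE = (12.7, 11.5)
C6O6_TRANS = (9.7, -8.5)

NOE_R_REF = 1.77  # Å, geminal H6R-H6S distance used as NOE reference

# relative substituent electronegativities (Huggins scale, relative to H)
# for the Haasnoot-Altona correction; editable config.
LAMBDA_DEFAULTS: Mapping[str, float] = {
    "H": 0.0, "C": 0.40, "N": 0.85, "O": 1.30, "OH": 1.40,
    "F": 1.70, "Cl": 0.95, "Br": 0.75, "I": 0.45,
}

# Haasnoot-Altona generalized Karplus parameters P1..P6
_HA_P = (13.70, -0.73, 0.0, 0.56, -2.47, 16.9)


@dataclass(frozen=True)
class KarplusParams:
    """Six-term Fourier coefficients (Hz) of the generalized Karplus curve."""

    C0: float = 0.0
    C1: float = 0.0
    C2: float = 0.0
    C3: float = 0.0
    S1: float = 0.0
    S2: float = 0.0
    lambdas: tuple = ()   # substituent electronegativities used, if any

    def as_array(self) -> np.ndarray:
        return np.array([self.C0, self.C1, self.C2, self.C3, self.S1, self.S2])


@dataclass
class CouplingSet:
    """Named scalar couplings (Hz) for one compound/anomer."""

    ring: dict = field(default_factory=dict)   # e.g. {"H1H2": 3.6, ...}
    J_56R: float | None = None
    J_56S: float | None = None
    J_6R6S: float | None = None                # apparent geminal, magnitude
    uncertainties: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, val in {**self.ring,
                          "J_56R": self.J_56R, "J_56S": self.J_56S,
                          "J_6R6S": self.J_6R6S}.items():
            if val is not None and abs(val) >= 30.0:
                raise ValueError(f"implausible coupling {name} = {val} Hz")


@dataclass(frozen=True)
class RotamerPopulations:
    """gt/gg/tg (A,B,C) and gauche/trans (D,E) molar fractions."""

    A: float = np.nan
    B: float = np.nan
    C: float = np.nan
    D: float = np.nan
    E: float = np.nan
    raw: tuple = ()      # unconstrained solution, may leave [0,1]
    constrained: bool = False


@dataclass
class NOEBuildup:
    """NOESY peak intensity vs mixing time for one proton pair."""

    pair: tuple
    mixing_times: np.ndarray   # s
    intensities: np.ndarray
    sigma: float | None = None       # fitted slope, 1/s
    sigma_se: float | None = None
    sigma_ref: float | None = None
    r_ref: float = NOE_R_REF

    def __post_init__(self):
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mixing_times.shape != self.intensities.shape:
            raise ValueError("mixing_times and intensities must match")
        if self.r_ref <= 0:
            raise ValueError("r_ref must be positive")


# --- Karplus model ---------------------------------------------------------

def karplus_forward(phi, params: KarplusParams):
    """Vicinal 3J(H,H) (Hz) at torsion ``phi`` (degrees)."""
    p = np.radians(np.asarray(phi, dtype=float))
    return (params.C0 + params.C1 * np.cos(p) + params.C2 * np.cos(2 * p)
            + params.C3 * np.cos(3 * p) + params.S1 * np.sin(p)
            + params.S2 * np.sin(2 * p))


def haasnoot_altona_params(lambdas: Sequence[float] = (),
                           xis: Sequence[int] = ()) -> KarplusParams:
    """Fourier coefficients of the Haasnoot–Altona equation.

    The HA curve ``J = P1 cos^2 phi + P2 cos phi + P3 +
    sum_i lambda_i (P4 + P5 cos^2(xi_i phi + P6 |lambda_i|))`` is an exact
    member of the six-term Fourier family (C3 = 0), so the projection below
    is closed-form, not a fit.  ``lambdas`` are relative substituent
    electronegativities (see :data:`LAMBDA_DEFAULTS`), ``xis`` their
    orientation factors (+1/-1); both default to no substituent correction.
    """
    P1, P2, P3, P4, P5, P6 = _HA_P
    lambdas = tuple(lambdas)
    xis = tuple(xis) if xis else tuple([1] * len(lambdas))
    if len(xis) != len(lambdas):
        raise ValueError("lambdas and xis must have equal length")
    C0 = P1 / 2 + P3
    C1 = P2
    C2 = P1 / 2
    S2 = 0.0
    for lam, xi in zip(lambdas, xis):
        delta = np.radians(P6 * abs(lam))
        # lambda*(P4 + P5*cos^2(xi phi + delta))
        #   = lambda*(P4 + P5/2) + lambda*P5/2 * cos(2 phi + 2 xi delta)
        C0 += lam * (P4 + P5 / 2)
        C2 += lam * P5 / 2 * np.cos(2 * delta)
        S2 += -lam * P5 / 2 * np.sin(2 * delta) * xi
    return KarplusParams(C0=C0, C1=C1, C2=C2, C3=0.0, S1=0.0, S2=S2,
                         lambdas=lambdas)


def karplus_invert(J: float, params: KarplusParams,
                   tol: float = 0.05, scan_step: float = 0.1) -> np.ndarray:
    """All torsions phi in [-180, 180) with ``karplus_forward(phi) == J``.

    Dense scan (``scan_step`` degrees) followed by bracketed root
    refinement.  Returns a sorted array; empty when J lies outside the
    attainable range by more than ``tol`` Hz.  Because Karplus curves are
    multi-valued, selecting the physically relevant root (e.g. the one
    compatible with a 4C1 chair) is an explicit downstream decision.
    """
    grid = np.arange(-180.0, 180.0 + scan_step, scan_step)
    f = karplus_forward(grid, params) - J
    roots: list[float] = []
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0):
        r = optimize.brentq(lambda x: float(karplus_forward(x, params) - J),
                            grid[i], grid[i + 1], xtol=1e-9)
        roots.append(r)
    for i in np.flatnonzero(f == 0.0):
        roots.append(float(grid[i]))
    # grazing extrema within tol but without a sign change
    if not roots and np.min(np.abs(f)) <= tol:
        i = int(np.argmin(np.abs(f)))
        res = optimize.minimize_scalar(
            lambda x: (float(karplus_forward(x, params)) - J) ** 2,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded")
        roots.append(float(res.x))
    uniq: list[float] = []
    for r in sorted(((r + 180.0) % 360.0) - 180.0 for r in roots):
        if not uniq or abs(r - uniq[-1]) > 1e-6:
            uniq.append(r)
    if uniq and abs(uniq[0] + 180.0) < 1e-6 and abs(uniq[-1] - 180.0) < 1e-6:
        uniq.pop()
    return np.array(uniq)


# --- rotamer populations ---------------------------------------------------

def c5c6_forward(A: float, B: float, C: float) -> tuple[float, float]:
    """(3J_H5,H6R, 3J_H5,H6S) in Hz predicted for gt/gg/tg fractions."""
    JR, JS, _ = C5C6_MATRIX @ np.array([A, B, C])
    return float(JR), float(JS)


def _constrain_simplex(M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least-squares solution on the probability simplex (sum=1, >=0)."""
    from scipy.optimize import nnls
    W = 1e4  # weight pinning the closure row
    Mw = M.copy()
    Mw[-1] *= W
    bw = b.copy()
    bw[-1] *= W
    x, _ = nnls(Mw, bw)
    s = x.sum()
    return x / s if s > 0 else x


def rotamers_c5c6(J_56R: float, J_56S: float) -> RotamerPopulations:
    """gt/gg/tg fractions (A, B, C) from the two H5-H6 couplings.

    The raw solution of the exact 3x3 linear system is always reported;
    when it leaves [0,1] a non-negative least-squares solution on the
    simplex is reported alongside (``constrained=True``).  Values are never
    silently clipped.
    """
    if not (np.isfinite(J_56R) and np.isfinite(J_56S)):
        raise ValueError("non-finite coupling input")
    b = np.array([J_56R, J_56S, 1.0])
    raw = np.linalg.solve(C5C6_MATRIX, b)
    if np.all((raw >= -1e-12) & (raw <= 1 + 1e-12)):
        A, B, C = np.clip(raw, 0.0, 1.0)
        return RotamerPopulations(A=float(A), B=float(B), C=float(C),
                                  raw=tuple(raw))
    A, B, C = _constrain_simplex(C5C6_MATRIX, b)
    return RotamerPopulations(A=float(A), B=float(B), C=float(C),
                              raw=tuple(raw), constrained=True)


def c6o6_gauche_trans(A: float, B: float, C: float) -> tuple[float, float]:
    """Limiting apparent geminal couplings (J_gauche, J_trans) in Hz."""
    ab = A + B
    Jg = C6O6_GAUCHE[0] * ab + C6O6_GAUCHE[1] * C
    Jt = C6O6_TRANS[0] * ab + C6O6_TRANS[1] * C
    return float(Jg), float(Jt)


def rotamers_c6o6(J_app: float, A: float, B: float, C: float) -> RotamerPopulations:
    """gauche/trans fractions (D, E) of the C6-O6 bond.

    Solves ``J_app = D J_gauche + E J_trans`` with ``D + E = 1``, where the
    limiting couplings depend on the C5-C6 fractions.
    """
    if abs(A + B + C - 1.0) > 1e-6:
        raise ValueError("C5-C6 fractions must satisfy A+B+C=1")
    Jg, Jt = c6o6_gauche_trans(A, B, C)
    if abs(Jg - Jt) < 1e-9:
        raise ValueError("J_gauche equals J_trans: populations indeterminate")
    D = (J_app - Jt) / (Jg - Jt)
    E = 1.0 - D
    raw = (D, E)
    if 0.0 <= D <= 1.0:
        return RotamerPopulations(A=A, B=B, C=C, D=float(D), E=float(E), raw=raw)
    Dc = min(max(D, 0.0), 1.0)
    return RotamerPopulations(A=A, B=B, C=C, D=Dc, E=1.0 - Dc, raw=raw,
                              constrained=True)


# --- NOE -------------------------------------------------------------------

def fit_sigma(buildup: NOEBuildup, t_max: float | None = None) -> NOEBuildup:
    """Fit the cross-relaxation rate as the slope of intensity vs mixing time.

    Ordinary least squares over all supplied points (optionally restricted
    to ``t <= t_max`` to stay in the initial linear buildup regime).  The
    fitted slope and its standard error are stored on the buildup, which is
    returned for chaining.
    """
    t, y = buildup.mixing_times, buildup.intensities
    if t_max is not None:
        keep = t <= t_max
        t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError("need at least three mixing times for a slope fit")
    res = stats.linregress(t, y)
    buildup.sigma = float(res.slope)
    buildup.sigma_se = float(res.stderr)
    return buildup


def noe_distance(sigma: float, sigma_ref: float, r_ref: float = NOE_R_REF) -> float:
    """Interproton distance r = r_ref (sigma/sigma_ref)^(-1/6) in Å."""
    if sigma <= 0 or sigma_ref <= 0 or r_ref <= 0:
        raise ValueError("rates and reference distance must be positive")
    return float(r_ref * (sigma / sigma_ref) ** (-1.0 / 6.0))


def anomer_fraction(integral_alpha: float, integral_beta: float) -> float:
    """Molar fraction of the alpha anomer from two peak integrals."""
    if integral_alpha < 0 or integral_beta < 0:
        raise ValueError("integrals must be non-negative")
    total = integral_alpha + integral_beta
    if total == 0:
        raise ValueError("both integrals are zero")
    return integral_alpha / total
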