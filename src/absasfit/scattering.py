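"""Scattering-curve mathematics.

Implements the Debye sum over equal-sphere bead models, Guinier and
cross-sectional Guinier fits, a direct numeric distance-distribution
transform P(r), nearest-Q matching of theoretical to experimental grids,
flat-baseline subtraction, and the percentage R factor with fitted scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .coarse_grain import SphereModel

logger = logging.getLogger(__name__)

XRAY = "xray_hydrated"
NEUTRON = "neutron_unhydrated"

DEFAULT_RFACTOR_QMAX = 1.1          # nm^-1; fits use the low-noise Q range
# Default Guinier windows for intact IgG (nm^-1)
GUINIER_RANGE = (0.15, 0.28)
XS1_RANGE = (0.31, 0.47)
XS1_RANGE_IGG4 = (0.31, 0.51)
XS2_RANGE = (0.65, 1.04)


@dataclass
class ScatteringCurve:
    """(Q, I, optional sigma) with contrast metadata.  Q in nm^-1."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    contrast: str = XRAY
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma length mismatch")
        if len(self.q) != len(self.i):
            raise ValueError("Q and I length mismatch")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("Q values must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("Q values must be positive")

    def __len__(self) -> int:
        return len(self.q)


def read_curve(path: str, q_units: str = "nm^-1", contrast: str = XRAY,
               label: str = "") -> ScatteringCurve:
    """Read a 2-3 column whitespace text curve; '#' starts a comment.

    Q in inverse Angstroms is converted to nm^-1; rows are sorted by Q and
    non-positive-Q rows dropped (the count is logged).
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns")
    q, i = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if q_units in ("A^-1", "angstrom^-1", "1/A"):
        q = q * 10.0
    elif q_units not in ("nm^-1", "1/nm"):
        raise ValueError(f"unknown q_units {q_units!r}")
    keep = q > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d rows with Q <= 0", path, dropped)
    q, i = q[keep], i[keep]
    if sigma is not None:
        sigma = sigma[keep]
    order = np.argsort(q, kind="stable")
    q, i = q[order], i[order]
    if sigma is not None:
        sigma = sigma[order]
    if len(q) < 5:
        raise ValueError(f"{path}: fewer than 5 usable data points")
    return ScatteringCurve(q=q, i=i, sigma=sigma, contrast=contrast,
                           label=label or path)


def write_curve(curve: ScatteringCurve, path: str) -> None:
    cols = [curve.q, curve.i]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    header = f"label {curve.label} contrast {curve.contrast}\nQ(nm^-1) I(Q)" + \
        (" sigma" if curve.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header)


def baseline_subtract(curve: ScatteringCurve, fraction_of_i0: float,
                      i0: float | None = None) -> ScatteringCurve:
    """Subtract a flat baseline of ``fraction_of_i0 * I(0)`` from the curve.

    ``i0`` defaults to the forward scattering from a Guinier fit over the
    default low-Q window (incoherent-background correction for neutron data).
    """
    if fraction_of_i0 < 0:
        raise ValueError("baseline fraction must be >= 0")
    if i0 is None:
        i0 = guinier_fit(curve, GUINIER_RANGE).i0
    corr = fraction_of_i0 * i0
    meta = dict(curve.meta)
    meta["baseline_subtracted"] = corr
    return ScatteringCurve(q=curve.q.copy(), i=curve.i - corr,
                           sigma=None if curve.sigma is None else curve.sigma.copy(),
                           contrast=curve.contrast, label=curve.label, meta=meta)


# ---------------------------------------------------------------------------
# Debye calculation
# ---------------------------------------------------------------------------

def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Uniform-sphere form factor F(Q), normalised to F(0) = 1."""
    x = np.asarray(q, dtype=float) * radius
    out = np.ones_like(x)
    nz = x != 0
    xn = x[nz]
    out[nz] = 3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn ** 3
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the x=0 limit
    return np.sinc(x / np.pi)


def debye_curve(spheres: SphereModel, q_grid: np.ndarray,
                method: str = "binned", bin_width: float = 0.05,
                contrast: str | None = None, label: str = "") -> ScatteringCurve:
    """Debye scattering curve I(Q) of an equal-sphere model.

    I(Q) = F(Q)^2 [N + 2 sum_{i<j} sin(Q d_ij)/(Q d_ij)], so I(0) = N^2
    with the F(0)=1 normalisation.  The ``binned`` method histograms the
    pair distances (default 0.05 nm bins); ``exact`` evaluates the double
    sum and serves as the reference in tests.
    """
    q = np.asarray(q_grid, dtype=float)
    n = spheres.n_spheres
    if n == 0:
        raise ValueError("empty sphere model")
    ff2 = sphere_form_factor(q, spheres.radius) ** 2
    if n == 1:
        return ScatteringCurve(q=q, i=ff2.copy(),
                               contrast=contrast or XRAY, label=label)
    d = pdist(spheres.centers)
    if method == "exact":
        s = np.array([np.sum(_sinc(qk * d)) for qk in q])
    elif method == "binned":
        nbins = max(1, int(np.ceil(d.max() / bin_width)))
        hist, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width))
        centers = 0.5 * (edges[:-1] + edges[1:])
        nz = hist > 0
        s = (hist[nz][None, :] * _sinc(np.outer(q, centers[nz]))).sum(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    i = ff2 * (n + 2.0 * s)
    return ScatteringCurve(q=q, i=i, contrast=contrast or XRAY, label=label)


# ---------------------------------------------------------------------------
# Guinier-type fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuinierResult:
    rg: float                    # nm
    i0: float
    q_range: tuple[float, float]
    n_points: int
    correlation: float


@dataclass(frozen=True)
class CrossSectionResult:
    rxs: float                   # nm
    which: str                   # xs1 | xs2
    q_range: tuple[float, float]
    n_points: int


def _window(curve: ScatteringCurve, q_range: tuple[float, float]) -> np.ndarray:
    lo, hi = q_range
    return (curve.q >= lo) & (curve.q <= hi)


def guinier_fit(curve: ScatteringCurve,
                q_range: tuple[float, float] = GUINIER_RANGE) -> GuinierResult:
    """Unweighted linear fit of ln I vs Q^2; R_g = sqrt(-3 slope)."""
    sel = _window(curve, q_range)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 points in Q range {q_range}")
    q2 = curve.q[sel] ** 2
    i = curve.i[sel]
    if np.any(i <= 0):
        raise ValueError("non-positive intensities in Guinier range")
    ln_i = np.log(i)
    slope, intercept = np.polyfit(q2, ln_i, 1)
    if slope >= 0:
        raise ValueError("non-negative Guinier slope; R_g undefined")
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    r = float(pearsonr(q2, ln_i)[0]) if len(q2) > 2 else -1.0
    if q_range[1] * rg > 1.5:
        warnings.warn(
            f"Guinier fit outside validity: Q_max*R_g = {q_range[1] * rg:.2f} > 1.5",
            stacklevel=2)
    return GuinierResult(rg=rg, i0=i0, q_range=q_range,
                         n_points=int(sel.sum()), correlation=r)


def cross_section_fit(curve: ScatteringCurve, q_range: tuple[float, float],
                      which: str = "xs1") -> CrossSectionResult:
    """Linear fit of ln(I*Q) vs Q^2; R_xs = sqrt(-2 slope)."""
    sel = _window(curve, q_range)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 points in Q range {q_range}")
    iq = curve.i[sel] * curve.q[sel]
    if np.any(iq <= 0):
        raise ValueError("non-positive I*Q in cross-section range")
    slope, _ = np.polyfit(curve.q[sel] ** 2, np.log(iq), 1)
    if slope >= 0:
        raise ValueError("non-negative cross-section slope")
    return CrossSectionResult(rxs=float(np.sqrt(-2.0 * slope)), which=which,
                              q_range=q_range, n_points=int(sel.sum()))


# ---------------------------------------------------------------------------
# Distance distribution P(r)
# ---------------------------------------------------------------------------

@dataclass
class PofRResult:
    r: np.ndarray
    p: np.ndarray
    length: float          # L, maximum dimension (nm)
    mode: float            # M, most common distance (nm)
    rg_real: float         # R_g from the second moment of P(r)


def p_of_r(curve: ScatteringCurve, r_max_hint: float,
           n_r: int = 256) -> PofRResult:
    """Distance distribution by direct quadrature of the sine transform.

    P(r) = (r / 2 pi^2) * Int Q I(Q) sin(Qr) dQ, evaluated by trapezoid on
    the measured Q support.  A cosine taper over the last 10% of the Q range
    suppresses truncation ringing.  L is the largest r with P > 1% of the
    maximum, M the mode, and R_g the second moment of P.
    """
    if r_max_hint <= 0:
        raise ValueError("r_max_hint must be positive")
    q, i = curve.q, curve.i
    if q[-1] * r_max_hint < np.pi:
        warnings.warn("curve may not extend far enough in Q for this r_max",
                      stacklevel=2)
    taper = np.ones_like(q)
    q_edge = q[-1] - 0.1 * (q[-1] - q[0])
    tail = q > q_edge
    taper[tail] = 0.5 * (1.0 + np.cos(np.pi * (q[tail] - q_edge) / (q[-1] - q_edge)))
    r = np.linspace(0.0, r_max_hint, n_r)
    integrand = q * i * taper
    # (n_r, n_q) sine kernel
    p = r / (2.0 * np.pi ** 2) * np.trapezoid(
        integrand[None, :] * np.sin(np.outer(r, q)), q, axis=1)
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("P(r) is non-positive everywhere; bad input curve")
    above = np.flatnonzero(p > 0.01 * pmax)
    length = float(r[above[-1]]) if len(above) else 0.0
    mode = float(r[int(np.argmax(p))])
    pc = np.clip(p, 0.0, None)
    norm = np.trapezoid(pc, r)
    rg_real = float(np.sqrt(np.trapezoid(r ** 2 * pc, r) / (2.0 * norm)))
    return PofRResult(r=r, p=p, length=length, mode=mode, rg_real=rg_real)


# ---------------------------------------------------------------------------
# Curve comparison
# ---------------------------------------------------------------------------

def match_q(theoretical: ScatteringCurve,
            experimental: ScatteringCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match each experimental point to the nearest-Q theoretical point.

    Ties are broken toward the lower theoretical Q.  Experimental points
    outside the theoretical support are kept (matched to the end point) with
    a warning.  Returns (q_exp, i_exp, i_theor_matched).
    """
    qt, qe = theoretical.q, experimental.q
    if qe[0] < qt[0] or qe[-1] > qt[-1]:
        warnings.warn("experimental Q range extends beyond theoretical support",
                      stacklevel=2)
    pos = np.searchsorted(qt, qe)
    lo = np.clip(pos - 1, 0, len(qt) - 1)
    hi = np.clip(pos, 0, len(qt) - 1)
    # tie toward lower Q: use <= for the low candidate
    take_lo = np.abs(qe - qt[lo]) <= np.abs(qt[hi] - qe)
    idx = np.where(take_lo, lo, hi)
    return qe, experimental.i, theoretical.i[idx]


@dataclass(frozen=True)
class FitResult:
    r_factor: float              # percent
    eta: float
    q_max: float
    n_points: int
    model_id: str = ""
    curve_label: str = ""


def r_factor(experimental: ScatteringCurve, theoretical: ScatteringCurve,
             q_max: float = DEFAULT_RFACTOR_QMAX,
             model_id: str = "") -> FitResult:
    """Percentage R factor, minimised over the theoretical scale eta.

    R = 100 * sum|I_exp - eta I_theor| / sum|I_exp|.  eta is found by
    golden-section search around the closed-form least-squares scale.
    """
    qe, ie, it = match_q(theoretical, experimental)
    sel = qe <= q_max
    if sel.sum() < 5:
        raise ValueError("fewer than 5 matched points below q_max")
    ie, it = ie[sel], it[sel]
    denom = np.abs(ie).sum()
    if denom == 0:
        raise ValueError("experimental intensities are all zero")
    tt = float(np.dot(it, it))
    if tt == 0:
        raise ValueError("theoretical intensities are all zero")
    eta0 = float(np.dot(ie, it)) / tt
    if eta0 <= 0:
        eta0 = np.abs(ie).sum() / np.abs(it).sum()

    def objective(eta: float) -> float:
        return float(np.abs(ie - eta * it).sum() / denom * 100.0)

    # golden-section on a wide bracket around the least-squares eta;
    # the objective is convex (piecewise linear) in eta.
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    lo, hi = eta0 * 0.05, eta0 * 20.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = objective(c), objective(d)
    while (hi - lo) > 1e-6 * eta0:
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = objective(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = objective(d)
    eta = 0.5 * (lo + hi)
    return FitResult(r_factor=objective(eta), eta=eta, q_max=q_max,
                     n_points=int(sel.sum()), model_id=model_id,
                     curve_label=experimental.label)
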