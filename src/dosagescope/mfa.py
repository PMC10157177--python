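"""Marker frequency analysis: copy-number gradients from DNA coverage.

Replicating cells carry more copies of oriC-proximal loci than terminus
loci; sequencing an exponentially growing culture against a stationary one
therefore yields a log-linear coverage ratio along each replichore.  This
module computes that profile in sliding windows, fits a per-replichore
log2-linear regression, and intersects the two lines to estimate oriC/ter
positions and copy numbers.  Models are normalized to a terminus copy
number of 1 and can be evaluated at any locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .chromosome import CircularChromosome
from .errors import DegenerateFitError, InputError
from .io import CoverageTrack

__all__ = [
    "MfaProfile",
    "CopyNumberModel",
    "ZeroDifferenceResult",
    "compute_mfa_profile",
    "fit_copy_number_model",
    "copy_number_at",
    "copy_number_difference",
    "zero_difference_locus",
]

FLAT_SLOPE_TOL = 1e-12  # log2 per bp; |slope| below this on both arms -> flat


@dataclass
class MfaProfile:
    """Sliding-window log2 coverage ratio (exponential / stationary)."""

    chrom_name: str
    length: int
    midpoints: np.ndarray      # bp, sorted on the circle
    log2_ratio: np.ndarray
    window: int
    step: int
    n_dropped: int = 0         # windows with zero stationary depth


def _track_integral(track: CoverageTrack, length: int):
    """Cumulative depth integral F(x) of a piecewise-constant track.

    Uncovered gaps integrate as depth 0.  Returns breakpoints and values
    suitable for np.interp; F is extended periodically by the caller.
    """
    xs = [0.0]
    Fs = [0.0]
    acc = 0.0
    pos = 0
    for s, e, d in zip(track.starts, track.ends, track.depths):
        if s > pos:
            xs.append(float(s))
            Fs.append(acc)
        acc += d * (e - s)
        xs.append(float(e))
        Fs.append(acc)
        pos = e
    if pos < length:
        xs.append(float(length))
        Fs.append(acc)
    return np.array(xs), np.array(Fs)


def compute_mfa_profile(cov_exp: CoverageTrack, cov_stat: CoverageTrack,
                        window: int = 5000, step: Optional[int] = None,
                        ) -> MfaProfile:
    """Average both tracks in sliding windows and take log2(exp/stat).

    Windows wrap around the origin (circular chromosome); windows whose
    stationary mean is zero are dropped and counted.  The default step is
    window/5 (1 kb for the canonical 5 kb windows).
    """
    if cov_exp.chrom != cov_stat.chrom:
        raise InputError(
            f"tracks on different chromosomes: {cov_exp.chrom} vs {cov_stat.chrom}")
    if window < 1:
        raise InputError("window must be >= 1")
    step = step or max(1, window // 5)
    length = int(max(cov_exp.ends.max(), cov_stat.ends.max()))

    xe, Fe = _track_integral(cov_exp, length)
    xs_, Fs_ = _track_integral(cov_stat, length)
    total_e, total_s = Fe[-1], Fs_[-1]

    starts = np.arange(0, length, step, dtype=float)
    ends = starts + window

    def winsum(x, F, total):
        lo = np.interp(starts, x, F)
        # wrap: integral past L continues at the start of the circle
        hi = np.where(ends <= length, np.interp(np.minimum(ends, length), x, F),
                      total + np.interp(ends - length, x, F))
        return hi - lo

    mean_e = winsum(xe, Fe, total_e) / window
    mean_s = winsum(xs_, Fs_, total_s) / window
    keep = mean_s > 0
    n_dropped = int((~keep).sum())
    if not np.any(keep):
        raise InputError("all windows dropped: stationary track has no coverage")
    mids = ((starts + window / 2.0) % length)[keep]
    ratio = np.log2(mean_e[keep] / mean_s[keep])
    order = np.argsort(mids)
    return MfaProfile(cov_exp.chrom, length, mids[order], ratio[order],
                      window, step, n_dropped)


@dataclass
class CopyNumberModel:
    """Fitted piecewise log2-linear copy-number model on a circle.

    After fitting, log2 copy number falls linearly from ``log2_oric_copy``
    at ``oriC_est`` to 0 at ``ter_est`` along each replichore (terminus
    normalized to copy number 1).  ``slopes``/``intercepts`` keep the raw
    per-replichore regressions (in clockwise/counterclockwise offset from
    the initial oriC) for diagnostics.
    """

    length: int
    oriC_est: float
    ter_est: float
    log2_oric_copy: float      # after ter normalization
    normalization: float       # log2 value subtracted so that ter copy = 1
    slopes: Tuple[float, float]      # (right, left), log2 per bp of offset
    intercepts: Tuple[float, float]  # (right, left), ter-normalized
    flat: bool = False

    @property
    def ratio(self) -> float:
        """oriC/ter copy-number ratio."""
        return float(2.0 ** self.log2_oric_copy)

    def to_dict(self) -> dict:
        return {
            "length": self.length, "oriC_est": self.oriC_est,
            "ter_est": self.ter_est, "log2_oric_copy": self.log2_oric_copy,
            "normalization": self.normalization,
            "slopes": list(self.slopes), "intercepts": list(self.intercepts),
            "flat": self.flat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CopyNumberModel":
        return cls(int(d["length"]), float(d["oriC_est"]), float(d["ter_est"]),
                   float(d["log2_oric_copy"]), float(d["normalization"]),
                   tuple(d["slopes"]), tuple(d["intercepts"]), bool(d["flat"]))

    @property
    def oric_copy(self) -> float:
        return self.ratio

    @property
    def ter_copy(self) -> float:
        return 1.0

    def arcs(self) -> Tuple[float, float]:
        L = self.length
        arc_right = (self.ter_est - self.oriC_est) % L
        return arc_right, L - arc_right

    def log2_copy_at(self, p):
        """log2 copy number at position(s) p (ter-normalized)."""
        L = self.length
        if self.flat:
            out = np.zeros_like(np.asarray(p, dtype=float))
            return out.item() if out.ndim == 0 else out
        arc_right, arc_left = self.arcs()
        t = (np.asarray(p, dtype=float) - self.oriC_est) % L
        on_right = t <= arc_right
        frac = np.where(on_right, t / arc_right, (L - t) / arc_left)
        out = self.log2_oric_copy * (1.0 - frac)
        return out.item() if out.ndim == 0 else out


def copy_number_at(model: CopyNumberModel, p):
    """Copy number at locus p under a fitted, ter-normalized model."""
    return 2.0 ** np.asarray(model.log2_copy_at(p)) if np.ndim(p) else float(
        2.0 ** model.log2_copy_at(p))


def _smooth_circular(y: np.ndarray, k: int) -> np.ndarray:
    k = max(1, k | 1)  # odd
    pad = k // 2
    ext = np.concatenate([y[-pad:], y, y[:pad]])
    kernel = np.ones(k) / k
    return np.convolve(ext, kernel, mode="valid")


def _auto_init(profile: MfaProfile) -> Tuple[float, float]:
    k = max(3, len(profile.midpoints) // 40)
    smooth = _smooth_circular(profile.log2_ratio, k)
    return (float(profile.midpoints[int(np.argmax(smooth))]),
            float(profile.midpoints[int(np.argmin(smooth))]))


def _fit_once(profile: MfaProfile, oriC0: float, ter0: float):
    L = profile.length
    mids = profile.midpoints
    y = profile.log2_ratio
    arc_right = (ter0 - oriC0) % L
    t = (mids - oriC0) % L
    right = t < arc_right

    if right.sum() < 3 or (~right).sum() < 3:
        raise DegenerateFitError("need >= 3 windows per replichore")

    # right: clockwise offset from oriC0; left: counterclockwise offset
    tr = t[right]
    sl = (L - t[~right])
    fit_r = stats.linregress(tr, y[right])
    fit_l = stats.linregress(sl, y[~right])
    return (fit_r.slope, fit_r.intercept), (fit_l.slope, fit_l.intercept)


def _intersect(oriC0: float, L: float, right: Tuple[float, float],
               left: Tuple[float, float]):
    br, ar = right
    bl, al = left
    denom = br + bl
    if abs(denom) < FLAT_SLOPE_TOL:
        raise DegenerateFitError("parallel replichore regressions (no intersection)")
    x_ori = (al - ar) / denom          # signed clockwise offset from oriC0
    t_ter = (al + bl * L - ar) / denom  # clockwise offset from oriC0
    oriC_est = (oriC0 + x_ori) % L
    ter_est = (oriC0 + t_ter) % L
    log2_ori = ar + br * x_ori
    log2_ter = ar + br * t_ter
    return oriC_est, ter_est, log2_ori, log2_ter


def fit_copy_number_model(profile: MfaProfile,
                          chrom: Optional[CircularChromosome] = None,
                          oriC0: Optional[float] = None,
                          ter0: Optional[float] = None) -> CopyNumberModel:
    """Fit per-replichore OLS lines and intersect them on the circle.

    The initial oriC/ter come from ``chrom`` (annotated) or from the
    arg-max/arg-min of a smoothed profile; after the first fit, windows are
    re-assigned using the fitted intersections and the fit is repeated once
    so auto-initialization is self-consistent.  The model is rescaled so
    the terminus copy number is 1.

    A profile with |slope| below tolerance on both arms (no gradient, e.g.
    two stationary samples) returns a model flagged ``flat`` with ratio 1.
    """
    L = profile.length
    if oriC0 is None or ter0 is None:
        if chrom is not None:
            oriC0 = float(chrom.oriC) if oriC0 is None else oriC0
            ter0 = float(chrom.ter) if ter0 is None else ter0
        else:
            a, b = _auto_init(profile)
            oriC0 = a if oriC0 is None else oriC0
            ter0 = b if ter0 is None else ter0

    (br, ar), (bl, al) = _fit_once(profile, oriC0, ter0)
    if abs(br) < FLAT_SLOPE_TOL and abs(bl) < FLAT_SLOPE_TOL:
        mid = np.mean(profile.log2_ratio)
        return CopyNumberModel(L, float(oriC0), float(ter0), 0.0, float(mid),
                               (0.0, 0.0), (0.0, 0.0), flat=True)
    oriC1, ter1, _, _ = _intersect(oriC0, L, (br, ar), (bl, al))

    # one refinement pass with the fitted axis
    (br, ar), (bl, al) = _fit_once(profile, oriC1, ter1)
    if abs(br) < FLAT_SLOPE_TOL and abs(bl) < FLAT_SLOPE_TOL:
        mid = np.mean(profile.log2_ratio)
        return CopyNumberModel(L, float(oriC1), float(ter1), 0.0, float(mid),
                               (0.0, 0.0), (0.0, 0.0), flat=True)
    oriC_est, ter_est, log2_ori, log2_ter = _intersect(oriC1, L, (br, ar), (bl, al))

    norm = log2_ter
    return CopyNumberModel(L, float(oriC_est), float(ter_est),
                           float(log2_ori - log2_ter), float(norm),
                           (float(br), float(bl)),
                           (float(ar - norm), float(al - norm)))


def copy_number_difference(model_a: CopyNumberModel, model_b: CopyNumberModel, p):
    """Fold change of local copy number between two fitted models at p.

    Both models must live on the same coordinate system (e.g. a rearranged
    strain mapped against the reference genome).
    """
    la = np.asarray(model_a.log2_copy_at(p), dtype=float)
    lb = np.asarray(model_b.log2_copy_at(p), dtype=float)
    out = 2.0 ** (la - lb)
    return out.item() if out.ndim == 0 else out


@dataclass
class ZeroDifferenceResult:
    """Location where two copy-number models coincide, per replichore."""

    replichore: str
    locus: float
    flag: str = "crossing"  # crossing | everywhere | none (anchored at minimum)


def zero_difference_locus(model_a: CopyNumberModel, model_b: CopyNumberModel,
                          n_grid: int = 4096, tol: float = 1e-9,
                          ) -> List[ZeroDifferenceResult]:
    """Find where the copy-number difference curve crosses 1 (log2 diff 0).

    One locus per replichore of ``model_a``.  If the curves coincide
    everywhere on an arm the arm midpoint is returned with flag
    'everywhere'; if there is no crossing, the |log2 difference| minimum is
    returned with flag 'none' (the documented fallback anchor).
    """
    L = model_a.length
    arc_right, arc_left = model_a.arcs()
    out: List[ZeroDifferenceResult] = []

    def diff_at(pos):
        return (np.asarray(model_a.log2_copy_at(pos), dtype=float)
                - np.asarray(model_b.log2_copy_at(pos), dtype=float))

    for name, start, arc, direction in (
            ("right", model_a.oriC_est, arc_right, +1),
            ("left", model_a.oriC_est, arc_left, -1)):
        offs = np.linspace(0.0, arc, n_grid)
        pos = (start + direction * offs) % L
        d = diff_at(pos)
        if np.max(np.abs(d)) < tol:
            out.append(ZeroDifferenceResult(name, float(pos[n_grid // 2]),
                                            "everywhere"))
            continue
        sign = np.sign(d)
        crossing_idx = np.nonzero(np.diff(sign) != 0)[0]
        near_zero = np.abs(d) < tol
        if len(crossing_idx) > 0:
            i = crossing_idx[0]
            # linear interpolation between grid neighbours
            x0, x1 = offs[i], offs[i + 1]
            y0, y1 = d[i], d[i + 1]
            xz = x0 if y1 == y0 else x0 - y0 * (x1 - x0) / (y1 - y0)
            out.append(ZeroDifferenceResult(name, float((start + direction * xz) % L)))
        elif np.any(near_zero):
            i = int(np.nonzero(near_zero)[0][0])
            out.append(ZeroDifferenceResult(name, float(pos[i])))
        else:
            i = int(np.argmin(np.abs(d)))
            out.append(ZeroDifferenceResult(name, float(pos[i]), "none"))
    return out
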