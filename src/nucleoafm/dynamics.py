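"""Histone-core mobility and tetrasome-positioning subpopulations.

Confined diffusion of the (H3.H4)2 tetramer on the 601 positioning
sequence shows up as a time-averaged mean square displacement that levels
off near the square of the confinement radius (~80-90 nm^2, i.e. ~10 nm of
displacement in under 10 s).  Tetrasome positioning is resolved by k-means
clustering of measured (short, long) arm-length pairs against the expected
geometry for a tetramer sitting at the NPS center (T) or shifted one dimer
footprint to the left or right (T_L / T_R): with the tetramer shifted by
``delta`` bp toward the short arm,

    short = (bp_short - delta) * rise + r
    long  = (bp_long  + delta) * rise + r

where r ~ 5 nm is the histone core radius included by the measurement
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .synthetic import ConstructSpec, TET_100W50

__all__ = ["MsdCurve", "ClusterModel", "GeometryModel", "msd", "average_msd",
           "estimate_plateau", "cluster_arm_lengths", "expected_arm_lengths",
           "occupancy_heatmap"]


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

@dataclass
class MsdCurve:
    """Time-averaged MSD(tau) with the pair counts behind each lag."""

    tau_s: np.ndarray
    msd: np.ndarray      # nm^2
    counts: np.ndarray


def msd(track, fps: float, max_lag_fraction: float = 0.25) -> MsdCurve:
    """Time-averaged MSD of a 2D centroid track.

    ``track`` is (T, 2) positions in nm, NaN rows marking frames where the
    particle is missing; pairs spanning a missing frame are excluded.
    Lags run from 0 up to ``max_lag_fraction`` of the span.
    """
    track = np.asarray(track, float)
    if track.ndim != 2 or track.shape[1] != 2:
        raise ValueError("track must be (T, 2)")
    n = len(track)
    if n < 5:
        raise ValueError("need at least 5 frames")
    valid = np.all(np.isfinite(track), axis=1)
    max_lag = max(int(n * max_lag_fraction), 1)
    taus = np.arange(max_lag + 1)
    out = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, int)
    counts[0] = valid.sum()
    for k in taus[1:]:
        ok = valid[:-k] & valid[k:]
        if ok.any():
            d = track[k:][ok] - track[:-k][ok]
            out[k] = np.mean(np.sum(d * d, axis=1))
            counts[k] = ok.sum()
        else:
            out[k] = np.nan
    return MsdCurve(taus / fps, out, counts)


def average_msd(curves) -> MsdCurve:
    """Average MSD curves across tracks, weighting lags by pair counts."""
    n_lags = min(len(c.msd) for c in curves)
    msd_sum = np.zeros(n_lags)
    cnt = np.zeros(n_lags)
    for c in curves:
        m = np.nan_to_num(c.msd[:n_lags])
        w = c.counts[:n_lags] * np.isfinite(c.msd[:n_lags])
        msd_sum += m * w
        cnt += w
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = msd_sum / cnt
    avg[0] = 0.0
    return MsdCurve(curves[0].tau_s[:n_lags], avg, cnt.astype(int))


def estimate_plateau(curve: MsdCurve, tail_fraction: float = 0.25):
    """Mean MSD over the final ``tail_fraction`` of lags.

    Returns ``(plateau_nm2, reliable)``; the flag drops when a linear fit
    over the tail still rises by more than 20% of the plateau across the
    tail (the curve has not leveled off, e.g. ballistic motion).
    """
    tail = max(int(len(curve.msd) * tail_fraction), 4)
    if len(curve.msd) < tail:
        raise ValueError("curve too short for the requested tail")
    m = curve.msd[-tail:]
    t = curve.tau_s[-tail:]
    ok = np.isfinite(m)
    m, t = m[ok], t[ok]
    if len(m) < 4:
        raise ValueError("need at least 4 finite tail lags")
    plateau = float(np.mean(m))
    slope = np.polyfit(t, m, 1)[0]
    rise = slope * (t[-1] - t[0])
    reliable = bool(abs(rise) <= 0.2 * max(plateau, 1e-12))
    return plateau, reliable


# ---------------------------------------------------------------------------
# tetrasome positioning
# ---------------------------------------------------------------------------

@dataclass
class GeometryModel:
    """Expected arm lengths vs tetramer offset along the NPS."""

    construct: ConstructSpec = TET_100W50
    max_offset_bp: int = 45   # one dimer footprint

    def expected(self, delta_bp: float):
        return expected_arm_lengths(self.construct, delta_bp,
                                    self.max_offset_bp)


def expected_arm_lengths(spec: ConstructSpec, delta_bp: float,
                         max_offset_bp: int = 45):
    """(short_nm, long_nm) for a tetramer shifted ``delta_bp`` toward the
    short (rigid) arm; positive offsets shorten the short arm."""
    if abs(delta_bp) > max_offset_bp:
        raise ValueError("offset beyond one dimer footprint")
    short = (spec.arm_bp_short - delta_bp) * spec.rise + spec.core_radius
    long_ = (spec.arm_bp_long + delta_bp) * spec.rise + spec.core_radius
    if short <= 0 or long_ <= 0:
        raise ValueError("offset produces a non-positive arm")
    return float(short), float(long_)


@dataclass
class ClusterModel:
    centers: np.ndarray     # (k, 2) in (short_nm, long_nm)
    fractions: np.ndarray
    labels: np.ndarray
    seed: int
    names: tuple | None = None   # T / T_L / T_R per cluster


def cluster_arm_lengths(pairs, k: int = 3, seed: int = 0, restarts: int = 20,
                        geometry: GeometryModel | None = None,
                        dimer_bp: int = 35) -> ClusterModel:
    """k-means (k-means++ seeding, best of ``restarts``) on arm-length pairs.

    With a :class:`GeometryModel` the clusters are named T / T_L / T_R by
    nearest expected (short, long) point for tetramer offsets 0 and
    -/+ one dimer footprint (``dimer_bp``).
    """
    X = np.asarray(pairs, float)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    fractions = np.bincount(labels, minlength=k) / len(labels)
    names = None
    if geometry is not None:
        # pairs are flank-identified (short-flank, long-flank) coordinates
        ref = {
            "T": np.asarray(geometry.expected(0)),
            "T_R": np.asarray(geometry.expected(dimer_bp)),
            "T_L": np.asarray(geometry.expected(-dimer_bp)),
        }
        names = tuple(
            min(ref, key=lambda nm: np.hypot(*(c - ref[nm])))
            for c in km.cluster_centers_
        )
    return ClusterModel(km.cluster_centers_, fractions, labels, seed, names)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def _rigid_fit(src, dst):
    """Least-squares rotation+translation mapping src points onto dst."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    cs, cd = src.mean(0), dst.mean(0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cd - R @ cs
    return R, t


def _resample(poly, n):
    poly = np.asarray(poly, float)
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate trace")
    u = np.linspace(0, s[-1], n)
    return np.column_stack([np.interp(u, s, poly[:, 0]),
                            np.interp(u, s, poly[:, 1])])


def occupancy_heatmap(positions, traces, bins: int = 20, n_resample: int = 50):
    """Histone occupancy histogram in a DNA-aligned frame.

    Each frame's DNA trace (polyline, nm) is rigidly registered onto the
    first trace; the same transform moves that frame's histone position.
    Returns ``(hist, y_edges, x_edges, aligned_positions)``.
    """
    if len(positions) == 0:
        raise ValueError("need at least one position")
    ref = _resample(traces[0], n_resample)
    aligned = []
    for pos, trace in zip(positions, traces):
        pts = _resample(trace, n_resample)
        # polyline orientation is arbitrary: try both and keep the better fit
        best = None
        for cand in (pts, pts[::-1]):
            R, t = _rigid_fit(cand, ref)
            resid = np.linalg.norm((cand @ R.T + t) - ref)
            if best is None or resid < best[0]:
                best = (resid, R, t)
        _, R, t = best
        aligned.append(R @ np.asarray(pos, float) + t)
    aligned = np.asarray(aligned)
    hist, ye, xe = np.histogram2d(aligned[:, 0], aligned[:, 1], bins=bins)
    return hist, ye, xe, aligned
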