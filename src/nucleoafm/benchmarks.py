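"""Ground-truth recovery suites run at the pipeline's study conditions.

Real HS-AFM disassembly movies are not publicly deposited, so the
pipeline's quantitative behaviour is exercised against the synthetic
generator: each function here sets up one planted-truth experiment at a
documented problem size, runs the relevant pipeline stage from scratch,
and returns the measured quantities.  The functions are deliberately
deterministic given a seed; both the test suite and the reproduction
script call them.
"""

from __future__ import annotations

import math

import numpy as np

from . import dynamics, geometry, pipeline, segmentation, synthetic, tracing, volumetrics
from .preprocess import RasterStack

__all__ = [
    "classifier_benchmark",
    "step_recovery_benchmark",
    "ladder_recovery_benchmark",
    "lifetime_ratio_benchmark",
    "cluster_fraction_benchmark",
    "msd_plateau_benchmark",
    "cap_volume_error",
    "rotation_detection_benchmark",
]


def classifier_benchmark(seed: int = 0, n_frames: int = 50,
                         shape=(200, 200), train_frames: int = 40,
                         noise_sigma: float = 0.3):
    """Train and score the 11x11 patch classifier on synthetic fields.

    Fifty 200x200 px frames at 1.9 nm/px, ~14 molecules each (class balance
    near the 89/3/7% background/NCP/DNA prior of manually labeled data),
    additive height noise sigma 0.3 nm.  The classifier trains on the first
    40 frames with class-balanced patch sampling and is scored on every
    pixel of the 10 held-out frames.

    Returns the per-class correct-labeling rates (fractions) plus the
    realized class proportions.
    """
    rng = np.random.default_rng(seed)
    noise = synthetic.NoiseModel(height_sigma=noise_sigma,
                                 line_offset_sigma=0.0)
    frames, masks = [], []
    for _ in range(n_frames):
        f, m = synthetic.simulate_field(
            shape=shape, noise=noise, seed=int(rng.integers(2**31)))
        frames.append(f)
        masks.append(m)
    model, table = segmentation.train_classifier(
        frames, masks, split=train_frames / n_frames, seed=seed)
    priors = np.vstack([np.bincount(m.ravel(), minlength=3) for m in masks])
    priors = priors.sum(0) / priors.sum()
    return {
        "rates": table.rates,
        "class_proportions": {
            "background": float(priors[0]),
            "NCP": float(priors[1]),
            "DNA": float(priors[2]),
        },
        "layer_sizes": model.layer_sizes,
    }


def step_recovery_benchmark(seed: int = 0, n_movies: int = 50,
                            n_frames: int = 100, drop: float = 200.0,
                            sigma: float = 30.0):
    """Recovery of single planted volume drops from noisy traces.

    Each movie is a 100-frame trace at 1 fps with one sudden -200 nm^3 drop
    at a random interior frame plus N(0, 30 nm^3) noise.  Returns per-movie
    location errors (frames) and relative amplitude errors.
    """
    rng = np.random.default_rng(seed)
    loc_err, amp_err = [], []
    for _ in range(n_movies):
        bp = int(rng.integers(20, n_frames - 20))
        V = np.full(n_frames, 600.0)
        V[bp:] -= drop
        V = V + rng.normal(0, sigma, n_frames)
        events = volumetrics.detect_steps(V, fps=1.0, min_step=120.0)
        if len(events) != 1:
            loc_err.append(np.inf)
            amp_err.append(np.inf)
            continue
        loc_err.append(abs(events[0].frame - bp))
        amp_err.append(abs(-events[0].dV - drop) / drop)
    return {"location_err_frames": np.array(loc_err),
            "amplitude_rel_err": np.array(amp_err)}


def ladder_recovery_benchmark(seed: int = 0, n_movies: int = 50,
                              fps: float = 1.0, sigma: float = 30.0):
    """State-ladder recovery from noisy disassembly volume traces.

    Each movie plants a nucleosome -> ... schedule with uniform 8-30 s
    dwells (every state resolvable at 1 fps), builds the implied volume
    trace with measurement noise N(0, 30 nm^3), then re-detects steps
    (min_step 80 nm^3: consecutive species bands sit ~120 nm^3 apart) and
    assigns states per segment.  Returns the fraction of movies whose
    detected state sequence equals the planted one.
    """
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_movies):
        n_events = int(rng.integers(1, 4))
        dwells = rng.uniform(8.0, 30.0, n_events + 1)
        times = np.cumsum(dwells)[:n_events]
        modes = ["sudden" if rng.random() < 0.5 else "gradual"
                 for _ in range(n_events)]
        schedule = synthetic.planted_schedule(times, modes=modes)
        n_frames = int((times[-1] + rng.uniform(10, 25)) * fps)
        V, species = synthetic.schedule_to_volume_trace(schedule, fps, n_frames)
        noisy = V + rng.normal(0, sigma, n_frames)
        events = volumetrics.detect_steps(noisy, fps=fps, min_step=80.0)
        detected = volumetrics.state_sequence(noisy, events)
        truth = ["nucleosome"] + [e.transition[1] for e in schedule.events]
        n_ok += detected == truth
    return n_ok / n_movies


def lifetime_ratio_benchmark(seed: int = 0, n_molecules: int = 100,
                             median_fast: float = 25.0,
                             median_slow: float = 50.0,
                             span_s: float = 300.0):
    """Median first-ejection lifetime ratio between two rate regimes.

    Draws first-ejection times for 100 molecules per regime via the
    schedule sampler (exponential dwells; nucleosome-like median 25 s vs
    chromatosome-like 50 s), right-censoring at the observation span, and
    returns the ratio of empirical medians (slow / fast).
    """
    rng = np.random.default_rng(seed)
    medians = []
    for median, start in ((median_fast, "nucleosome"),
                          (median_slow, "chromatosome")):
        rate = math.log(2.0) / median
        firsts = []
        for _ in range(n_molecules):
            sched = synthetic.sample_schedule(
                {start: rate}, seed=int(rng.integers(2**31)),
                start_species=start)
            t = sched.events[0].time_s if sched.events else None
            firsts.append(t if (t is not None and t <= span_s) else None)
        records, t, F = volumetrics.first_ejection_stats(
            firsts, [span_s] * n_molecules)
        obs = records.loc[records.observed, "time_s"]
        medians.append(float(np.median(obs)))
    return {"median_fast": medians[0], "median_slow": medians[1],
            "ratio": medians[1] / medians[0]}


def cluster_fraction_benchmark(seed: int = 0, n: int = 130,
                               sigma_nm: float = 2.0,
                               fractions=(0.55, 0.26, 0.20)):
    """k-means recovery of planted tetrasome-positioning fractions.

    Plants n=130 (short-flank, long-flank) arm-length pairs at the three
    expected 100W50 tetramer configurations (center, left, right of the
    NPS; pairwise separations ~16 nm, well separated at 2 nm scatter) with
    the given T/T_L/T_R fractions, clusters them, and returns planted vs
    recovered fractions matched by center.
    """
    rng = np.random.default_rng(seed)
    geom = dynamics.GeometryModel()
    centers = [np.asarray(geom.expected(0)), np.asarray(geom.expected(-35)),
               np.asarray(geom.expected(35))]
    counts = [int(round(f * n)) for f in fractions]
    counts[0] += n - sum(counts)
    X, planted = [], []
    for c, (ctr, cnt) in enumerate(zip(centers, counts)):
        X.append(ctr + rng.normal(0, sigma_nm, (cnt, 2)))
        planted += [c] * cnt
    X = np.vstack(X)
    model = dynamics.cluster_arm_lengths(X, k=3, seed=seed,
                                         geometry=geom)
    # match recovered clusters to planted centers
    recovered = []
    for ctr in centers:
        j = int(np.argmin([np.hypot(*(cc - ctr)) for cc in model.centers]))
        recovered.append(float(model.fractions[j]))
    return {"planted": [c / n for c in counts], "recovered": recovered,
            "names": model.names}


def msd_plateau_benchmark(seed: int = 0, radius_nm: float = 9.5,
                          n_tracks: int = 8, n_frames: int = 2000,
                          step_nm: float = 1.0, fps: float = 2.0):
    """MSD plateau of Brownian walks reflected in a disc.

    For a particle uniformly exploring a disc of radius a the long-lag MSD
    is E|r1 - r2|^2 = a^2.  Returns the estimated plateau (nm^2), the
    reliability flag, and the a^2 reference.
    """
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_tracks):
        pos = np.zeros(2)
        track = np.empty((n_frames, 2))
        for i in range(n_frames):
            pos = pos + rng.normal(0, step_nm, 2)
            rr = np.hypot(*pos)
            if rr > radius_nm:
                pos *= (2 * radius_nm - rr) / rr
            track[i] = pos
        curves.append(dynamics.msd(track, fps=fps))
    avg = dynamics.average_msd(curves)
    plateau, reliable = dynamics.estimate_plateau(avg)
    return {"plateau_nm2": plateau, "reliable": reliable,
            "expected_nm2": radius_nm**2}


def cap_volume_error(pixel_size: float = 0.5, height: float = 5.0,
                     volume: float = 594.8):
    """Relative error of the rendered noiseless spherical-cap volume
    against the closed form pi h^2 (3R - h) / 3 (no tip convolution)."""
    R = synthetic.cap_sphere_radius(volume, height)
    state = synthetic.build_construct(synthetic.NUC_200W100)
    n = int(math.ceil(20.0 / pixel_size))
    shape = (2 * n + 1, 2 * n + 1)
    center = np.array([n * pixel_size, n * pixel_size])
    state.core_center = center
    state.core_height = height
    state.nominal_volume = volume
    frame, mask = synthetic.render_frame(
        state, synthetic.TipModel(0.0), synthetic.NOISELESS, pixel_size, shape)
    measured = float(frame.sum() * pixel_size**2)
    return abs(measured - volume) / volume


def rotation_detection_benchmark(seed: int = 0, n_seeds: int = 20,
                                 window: int = 8, fps: float = 1.0):
    """Released-arm identification from angle jumps at the first ejection.

    For each seed a short 100W50 nucleosome movie is rendered around a
    single sudden ejection with the planted ~90 deg rotation of the short
    (released) arm.  The full tracing + angle pipeline runs on the truth
    masks; the arm with the larger |delta theta| jump across the event is
    compared to the released-side ground truth.  Returns the fraction of
    seeds where they coincide.
    """
    rng = np.random.default_rng(seed)
    n_frames = 2 * window + 1
    t_event = (window + 0.5) / fps
    hits = 0
    for _ in range(n_seeds):
        schedule = synthetic.planted_schedule([t_event])
        movie = synthetic.simulate_movie(
            spec=synthetic.TET_100W50, schedule=schedule, fps=fps,
            n_frames=n_frames, seed=int(rng.integers(2**31)),
            shape=(110, 110), noise=synthetic.NoiseModel(height_sigma=0.1),
        )
        stack = RasterStack(movie.frames, movie.pixel_size, movie.fps)
        table = pipeline.track_arms(stack, movie.truth_masks)
        series = geometry.delta_series(table["theta1_deg"].to_numpy(),
                                       table["theta2_deg"].to_numpy())
        jump1 = _jump_at(series.delta1, window)
        jump2 = _jump_at(series.delta2, window)
        if np.isnan(jump1) and np.isnan(jump2):
            continue
        flagged = "short" if (np.nan_to_num(jump1) >= np.nan_to_num(jump2)) \
            else "long"
        hits += flagged == schedule.events[0].side
    return hits / n_seeds


def _jump_at(delta, event_frame):
    before = delta[:event_frame + 1]
    after = delta[event_frame + 1:]
    b = np.nanmedian(before) if np.isfinite(before).any() else np.nan
    a = np.nanmedian(after) if np.isfinite(after).any() else np.nan
    return abs(a - b)
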