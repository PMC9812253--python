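"""Synthetic source-space MEG cohort with age-dependent auditory responses.

The generator emulates the data structure a developmental 40 Hz ASSR
study assumes at the source level: per-child epoch arrays
(trials x vertices x time, -1500..+1500 ms around stimulus onset) over
two hemispheric vertex clouds, with

* a 40 Hz steady-state component whose trial-wise phase is drawn from a
  von Mises distribution centred at 0 with concentration ``kappa`` that
  grows linearly with age and is larger in the right hemisphere
  (``kappa`` is the latent that produces the observed age-related ITPC
  increase; the von Mises choice gives closed-form expectations for the
  resultant length),
* a sustained evoked component (unipolar plateau from ~200 ms to
  stimulus offset) whose amplitude declines linearly with age —
  polarity is immaterial downstream because the sustained-field measure
  rectifies the z-scores,
* a Gaussian spatial profile over the vertex cloud, centred on a
  per-subject "true peak" whose right-hemisphere Y coordinate drifts
  posteriorly with age,
* white plus 1/f background noise, independent across trials and
  vertices.

Hemispheric vertex clouds are jittered grids centred on the
grand-average auditory-cortex locations reported for this paradigm in
MNI space (left (-49.47, -22.25, 6.53), right (52.46, -23.85, 10.51) mm),
so coordinate summaries are on a realistic scale.

Reproducibility: a single master seed; the per-subject stream is
``default_rng([seed, subject_index])`` so cohorts are reproducible
subject by subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "KAPPA_MAX",
    "LEFT_CENTROID_MM",
    "RIGHT_CENTROID_MM",
    "CohortParams",
    "SubjectEpochs",
    "simulate_subject",
    "simulate_cohort",
    "write_epochs",
    "read_epochs",
]

#: Concentrations at or above this cap mean "perfect locking": the
#: trial phase is set to exactly 0 instead of being drawn.
KAPPA_MAX = 1e6

LEFT_CENTROID_MM = np.array([-49.47, -22.25, 6.53])
RIGHT_CENTROID_MM = np.array([52.46, -23.85, 10.51])

_REFERENCE_AGE = 7.0  # years; intercepts of the age-linear latents


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of the synthetic cohort.

    Ages are drawn uniformly on ``age_range_years`` (or laid on an even
    grid when ``age_grid`` is set); ``kappa0``/``erf_amp0`` are the
    left-hemisphere phase concentration and the evoked amplitude at age
    7, with linear per-year slopes.  Amplitudes are in arbitrary source
    units; what matters downstream is their ratio to the noise SDs.
    """

    n_subjects: int = 30
    age_range_years: tuple[float, float] = (7.06, 12.03)
    trials_range: tuple[int, int] = (72, 87)
    n_vertices_per_hemisphere: int = 50
    epoch_window_s: tuple[float, float] = (-1.5, 1.5)
    sample_rate_hz: float = 500.0
    kappa0: float = 0.4
    kappa_age_slope: float = 0.5
    kappa_right_bonus: float = 0.8
    assr_amp: float = 1.0
    erf_amp0: float = 3.0
    erf_age_slope: float = -0.3
    topo_shift_mm_per_year: float = -2.0
    noise_white_sd: float = 1.0
    noise_pink_sd: float = 1.0
    spatial_sigma_mm: float = 10.0
    grid_spacing_mm: float = 4.0
    coord_jitter_mm: float = 1.0
    latency_jitter_s: float = 0.005
    stim_duration_s: float = 1.0
    rise_time_s: float = 0.2
    age_grid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        lo, hi = self.trials_range
        if lo < 1 or hi < lo:
            raise ValueError("trials_range must be a nonempty range within [1, inf)")
        w0, w1 = self.epoch_window_s
        if w0 > -0.5 or w1 < 1.0:
            raise ValueError(
                "epoch window must contain [-0.5, 1.0] s to cover the analysis windows"
            )
        for name in ("kappa0", "kappa_right_bonus", "assr_amp", "erf_amp0",
                     "noise_white_sd", "noise_pink_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def times_s(self) -> np.ndarray:
        """Epoch time axis; strictly increasing and containing 0."""
        fs = self.sample_rate_hz
        w0, w1 = self.epoch_window_s
        return np.arange(int(np.ceil(w0 * fs)), int(np.floor(w1 * fs)) + 1) / fs


@dataclass
class SubjectEpochs:
    """One child's source-space epochs with metadata and ground truth.

    ``data`` is (trials, vertices, times) in arbitrary source units;
    ``hemisphere`` labels every vertex ``"left"`` or ``"right"``;
    ``ground_truth`` (absent for externally supplied data) records the
    generating parameters realised for this subject.
    """

    subject_id: str
    age_years: float
    data: np.ndarray
    times_s: np.ndarray
    vertex_coords_mm: np.ndarray
    hemisphere: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.vertex_coords_mm = np.asarray(self.vertex_coords_mm, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype="U5")
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, vertices, times)")
        if self.data.shape[1] != len(self.hemisphere) or self.data.shape[1] != len(
            self.vertex_coords_mm
        ):
            raise ValueError("vertex axes of data, coords and hemisphere disagree")
        if self.data.shape[2] != len(self.times_s):
            raise ValueError("time axes of data and times_s disagree")
        if np.any(np.diff(self.times_s) <= 0) or not np.isclose(
            self.times_s[np.argmin(np.abs(self.times_s))], 0.0, atol=1e-9
        ):
            raise ValueError("times_s must be strictly increasing and include 0")
        if not set(np.unique(self.hemisphere)) <= {"left", "right"}:
            raise ValueError("hemisphere labels must be 'left' or 'right'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def vertices_of(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemisphere)


def _hemisphere_cloud(n: int, centroid: np.ndarray, spacing: float,
                      jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered cubic grid of ``n`` vertices centred on ``centroid``."""
    per_axis = int(np.ceil(n ** (1.0 / 3.0)))
    axis = (np.arange(per_axis) - (per_axis - 1) / 2.0) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    # take the n points closest to the centre so the cloud stays compact
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    pts = pts[order[:n]]
    return centroid + pts + rng.uniform(-jitter, jitter, size=pts.shape)


def _smooth_gate(t: np.ndarray, rise_s: float, duration_s: float) -> np.ndarray:
    """0 before onset, raised-cosine rise over ``rise_s``, plateau 1
    until ``duration_s``, exponential decay (tau = 100 ms) after offset."""
    gate = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_s)
    gate[rising] = np.sin(np.pi * t[rising] / (2 * rise_s)) ** 2
    gate[(t >= rise_s) & (t <= duration_s)] = 1.0
    after = t > duration_s
    gate[after] = np.exp(-(t[after] - duration_s) / 0.1)
    return gate


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float,
                n_times: int) -> np.ndarray:
    """1/f-power noise, unit-SD per trace, scaled by ``sd``."""
    white = rng.standard_normal(shape + (n_times,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=n_times, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    return sd * pink


def subject_rng(params: CohortParams, subject_index: int) -> np.random.Generator:
    """Per-subject random stream derived from the master seed."""
    return np.random.default_rng([params.seed, subject_index])


def simulate_subject(
    params: CohortParams, subject_index: int, rng: np.random.Generator | None = None
) -> SubjectEpochs:
    """Simulate one child's source-space epochs.

    Each trial's time course at vertex ``v`` is::

        G(v) * [ a_erf * env(t - jitter) + a_assr * gate(t) * sin(2 pi 40 t + phi) ] + noise

    with ``phi ~ vonMises(0, kappa_hemisphere(age))`` per trial and
    hemisphere, ``env``/``gate`` the smooth stimulus envelope, ``G`` a
    spatial Gaussian centred on the subject's true peak, and white +
    1/f noise per trial and vertex.
    """
    rng = rng if rng is not None else subject_rng(params, subject_index)
    lo_age, hi_age = params.age_range_years
    if params.age_grid and params.n_subjects > 1:
        age = lo_age + (hi_age - lo_age) * subject_index / (params.n_subjects - 1)
        rng.uniform()  # keep stream alignment with the sampled-age path
    else:
        age = rng.uniform(lo_age, hi_age)
    n_trials = int(rng.integers(params.trials_range[0], params.trials_range[1] + 1))
    dage = age - _REFERENCE_AGE
    kappa_left = max(0.0, params.kappa0 + params.kappa_age_slope * dage)
    kappa_right = kappa_left + params.kappa_right_bonus
    a_erf = max(0.0, params.erf_amp0 + params.erf_age_slope * dage)

    coords = np.vstack(
        [
            _hemisphere_cloud(params.n_vertices_per_hemisphere, LEFT_CENTROID_MM,
                              params.grid_spacing_mm, params.coord_jitter_mm, rng),
            _hemisphere_cloud(params.n_vertices_per_hemisphere, RIGHT_CENTROID_MM,
                              params.grid_spacing_mm, params.coord_jitter_mm, rng),
        ]
    )
    hemisphere = np.array(
        ["left"] * params.n_vertices_per_hemisphere
        + ["right"] * params.n_vertices_per_hemisphere
    )
    peak_loc = {
        "left": LEFT_CENTROID_MM.copy(),
        "right": RIGHT_CENTROID_MM + np.array([0.0, params.topo_shift_mm_per_year * dage, 0.0]),
    }

    times = params.times_s()
    n_times = len(times)
    n_vertices = len(coords)
    gate = _smooth_gate(times, params.rise_time_s, params.stim_duration_s)

    data = np.zeros((n_trials, n_vertices, n_times))
    kappas = {"left": kappa_left, "right": kappa_right}
    true_peak_vertex = {}
    for hemi in ("left", "right"):
        vidx = np.flatnonzero(hemisphere == hemi)
        d2 = np.sum((coords[vidx] - peak_loc[hemi]) ** 2, axis=1)
        profile = np.exp(-d2 / (2 * params.spatial_sigma_mm**2))
        true_peak_vertex[hemi] = int(vidx[np.argmin(d2)])
        kappa = kappas[hemi]
        if kappa >= KAPPA_MAX:
            phases = np.zeros(n_trials)
        else:
            phases = rng.vonmises(0.0, kappa, size=n_trials)
        if params.latency_jitter_s > 0:
            jitters = rng.uniform(-params.latency_jitter_s, params.latency_jitter_s, n_trials)
        else:
            jitters = np.zeros(n_trials)
        # (trials, times) envelopes/oscillation, broadcast over the vertex profile
        env = _smooth_gate(times[None, :] - jitters[:, None],
                           params.rise_time_s, params.stim_duration_s)
        trial_tc = a_erf * env + params.assr_amp * gate[None, :] * np.sin(
            2 * np.pi * 40.0 * times[None, :] + phases[:, None]
        )
        data[:, vidx, :] += profile[None, :, None] * trial_tc[:, None, :]

    if params.noise_white_sd > 0:
        data += rng.normal(0.0, params.noise_white_sd, size=data.shape)
    if params.noise_pink_sd > 0:
        data += _pink_noise(rng, (n_trials, n_vertices), params.noise_pink_sd, n_times)

    ground_truth = {
        "age_years": age,
        "kappa_left": kappa_left,
        "kappa_right": kappa_right,
        "erf_amp": a_erf,
        "assr_amp": params.assr_amp,
        "peak_vertex_left": true_peak_vertex["left"],
        "peak_vertex_right": true_peak_vertex["right"],
        "peak_loc_left_mm": peak_loc["left"],
        "peak_loc_right_mm": peak_loc["right"],
    }
    return SubjectEpochs(
        subject_id=f"S{subject_index:03d}",
        age_years=age,
        data=data,
        times_s=times,
        vertex_coords_mm=coords,
        hemisphere=hemisphere,
        ground_truth=ground_truth,
    )


def simulate_cohort(params: CohortParams):
    """Simulate all subjects; returns (subjects, ground-truth table).

    The table has one row per subject with the realised latents
    (kappa per hemisphere, evoked amplitude, true peak coordinates).
    Bit-reproducible for a fixed ``params.seed``.
    """
    import pandas as pd

    subjects = [simulate_subject(params, i) for i in range(params.n_subjects)]
    rows = []
    for s in subjects:
        gt = s.ground_truth
        rows.append(
            {
                "subject": s.subject_id,
                "age": s.age_years,
                "kappa_left": gt["kappa_left"],
                "kappa_right": gt["kappa_right"],
                "erf_amp": gt["erf_amp"],
                "peak_y_right_mm": gt["peak_loc_right_mm"][1],
            }
        )
    return subjects, pd.DataFrame(rows)


_REQUIRED_DATASETS = ("data", "times", "coords", "hemisphere", "age")


def write_epochs(subjects: list[SubjectEpochs], path) -> None:
    """Write subjects to the HDF5 epoch container.

    Schema: groups ``/subjects/<id>/`` with datasets ``data``
    (trials x vertices x times), ``times`` (s), ``coords`` (mm),
    ``hemisphere`` (bytes 'left'/'right'), scalar ``age`` and an
    optional ``ground_truth`` subgroup.  Externally preprocessed source
    epochs following this schema (without ``ground_truth``) enter the
    identical pipeline.
    """
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for s in subjects:
            g = root.create_group(s.subject_id)
            g.create_dataset("data", data=s.data)
            g.create_dataset("times", data=s.times_s)
            g.create_dataset("coords", data=s.vertex_coords_mm)
            g.create_dataset("hemisphere", data=s.hemisphere.astype("S5"))
            g.create_dataset("age", data=float(s.age_years))
            if s.ground_truth is not None:
                gt = g.create_group("ground_truth")
                for key, value in s.ground_truth.items():
                    gt.create_dataset(key, data=value)


def read_epochs(path) -> list[SubjectEpochs]:
    """Read an HDF5 epoch container written by :func:`write_epochs`
    (or by an external tool following the documented schema)."""
    subjects = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise ValueError("malformed epoch container: missing group 'subjects'")
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            for name in _REQUIRED_DATASETS:
                if name not in g:
                    raise ValueError(
                        f"malformed epoch container: subject {sid!r} missing field {name!r}"
                    )
            ground_truth = None
            if "ground_truth" in g:
                ground_truth = {k: _read_gt(g["ground_truth"][k]) for k in g["ground_truth"]}
            subjects.append(
                SubjectEpochs(
                    subject_id=sid,
                    age_years=float(g["age"][()]),
                    data=g["data"][()],
                    times_s=g["times"][()],
                    vertex_coords_mm=g["coords"][()],
                    hemisphere=g["hemisphere"][()].astype("U5"),
                    ground_truth=ground_truth,
                )
            )
    return subjects


def _read_gt(dataset):
    value = dataset[()]
    if np.ndim(value) == 0:
        value = value.item()
        return int(value) if isinstance(value, (int, np.integer)) else value
    return np.asarray(value)
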