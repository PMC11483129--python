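"""Generative model of synchronization-continuation tapping (SCT).

Two standard components reproduce the known phenomenology of paced
finger tapping:

* Synchronization epoch -- a linear phase-correction process on the
  stimulus-tap asynchronies,

      A[n+1] = (1 - alpha) A[n] + T[n] + (M[n+1] - M[n]),

  offset so the mean asynchrony is negative (taps anticipate the
  metronome) with magnitude ``asynchrony_scale``.  Visual metronomes
  multiply both the offset and the noise by configurable factors > 1,
  reproducing the larger asynchronies seen with flashing metronomes.

* Continuation epoch -- a two-level timekeeper/motor model,

      I[n] = C[n] + M[n+1] - M[n],

  with i.i.d. timekeeper intervals C ~ N(mu_c, sigma_T^2) and motor delays
  M ~ N(0, sigma_M^2).  Its produced-interval lag-1 autocorrelation has the
  closed form -sigma_M^2 / (sigma_T^2 + 2 sigma_M^2), in [-0.5, 0].  The
  timekeeper mean is regressed toward the subject's indifference interval,

      mu_c = target + w * (indifference_interval - target),

  which yields overestimation of short targets, underestimation of long
  ones, and a constant-error-vs-target line crossing zero at the
  indifference interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubjectSpec", "Trial", "TappingSession", "simulate_tapping_session",
           "DEFAULT_TARGETS"]

DEFAULT_TARGETS = (550.0, 650.0, 750.0, 850.0, 950.0)


@dataclass
class SubjectSpec:
    """Subject-level parameters of the generative models.

    tan_amplitude : unitless U-fiber density scale inside the planted ROI.
    asynchrony_scale : ms, magnitude of the (negative) mean asynchrony.
    phase_correction_alpha : error-correction gain, in (0, 2) for stability.
    timekeeper_sd, motor_sd : ms, noise SDs of the two-level model.
    indifference_interval : ms, target with zero constant error.
    central_tendency_weight : regression weight toward the indifference
        interval (0 = veridical timekeeper).
    visual_scale_factor, visual_noise_factor : multipliers applied to the
        asynchrony offset and noise in the visual modality.
    target_asynchrony_ms : optional {(modality, target): scale} overrides
        used to plant target-specific behavioral effects.
    """

    tan_amplitude: float = 1.0
    asynchrony_scale: float = 40.0
    phase_correction_alpha: float = 0.9
    timekeeper_sd: float = 10.0
    motor_sd: float = 5.0
    indifference_interval: float = 654.0
    seed: int = 0
    central_tendency_weight: float = 0.15
    visual_scale_factor: float = 1.5
    visual_noise_factor: float = 1.5
    target_asynchrony_ms: dict | None = None

    def __post_init__(self):
        if not (0.0 < self.phase_correction_alpha < 2.0):
            raise ValueError("phase_correction_alpha must lie in (0, 2)")
        if self.timekeeper_sd < 0 or self.motor_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class Trial:
    """One SCT trial: paced synchronization then unpaced continuation."""

    modality: str
    target_ms: float
    stimulus_onsets: np.ndarray  # metronome onsets (synchronization epoch)
    tap_onsets: np.ndarray       # all taps, synchronization then continuation
    n_sync: int                  # number of synchronization intervals

    @property
    def sync_taps(self) -> np.ndarray:
        return self.tap_onsets[: self.n_sync + 1]

    @property
    def sync_intervals(self) -> np.ndarray:
        return np.diff(self.tap_onsets[: self.n_sync + 1])

    @property
    def cont_intervals(self) -> np.ndarray:
        return np.diff(self.tap_onsets[self.n_sync:])


@dataclass
class TappingSession:
    subject_id: int
    trials: list = field(default_factory=list)

    def by_cell(self):
        """Group trials into (modality, target_ms) cells."""
        cells: dict = {}
        for t in self.trials:
            cells.setdefault((t.modality, t.target_ms), []).append(t)
        return cells


def _continuation_intervals(rng, n, mu_c, sigma_t, sigma_m):
    """Two-level model produced intervals I[n] = C[n] + M[n+1] - M[n]."""
    c = rng.normal(mu_c, sigma_t, size=n)
    m = rng.normal(0.0, sigma_m, size=n + 1)
    return c + m[1:] - m[:-1]


def simulate_tapping_session(
    subject: SubjectSpec,
    modality: str = "auditory",
    target_intervals=DEFAULT_TARGETS,
    trials_per_interval: int = 10,
    n_sync: int = 6,
    n_cont: int = 6,
    seed: int | None = None,
) -> TappingSession:
    """Simulate a full SCT session for one subject and one modality.

    Each trial has ``n_sync`` paced intervals (n_sync + 1 metronome onsets
    and paired taps) followed by ``n_cont`` self-paced intervals.  All
    onsets are in ms from trial start; trial streams are independent.
    """
    if modality not in ("auditory", "visual"):
        raise ValueError("modality must be 'auditory' or 'visual'")
    if n_sync < 2 or n_cont < 2:
        raise ValueError("need at least 2 intervals per epoch")
    targets = [float(t) for t in target_intervals]
    if any(t <= 0 for t in targets):
        raise ValueError("target intervals must be positive")

    alpha = subject.phase_correction_alpha
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    vis = modality == "visual"
    noise_fac = subject.visual_noise_factor if vis else 1.0

    session = TappingSession(subject_id=subject.seed)
    for target in targets:
        scale = subject.asynchrony_scale
        if subject.target_asynchrony_ms:
            scale = subject.target_asynchrony_ms.get((modality, target), scale)
        offset = -scale * (subject.visual_scale_factor if vis else 1.0)
        sigma_t = subject.timekeeper_sd * noise_fac
        sigma_m = subject.motor_sd * noise_fac

        T = trials_per_interval
        stim = np.arange(n_sync + 1) * target
        # zero-mean phase-correction process, then anticipatory offset;
        # vectorized across the trials of this (modality, target) cell
        gain = 1.0 - alpha
        drive = sigma_t**2 + 2 * sigma_m**2
        a = np.zeros((T, n_sync + 1))
        if abs(gain) < 1.0 and drive > 0:
            # stationary start of the AR(1) driven by both noise sources
            a[:, 0] = rng.normal(0.0, np.sqrt(drive / (1 - gain**2)), size=T)
        t_noise = rng.normal(0.0, sigma_t, size=(T, n_sync))
        m = rng.normal(0.0, sigma_m, size=(T, n_sync + 1))
        for n in range(n_sync):
            a[:, n + 1] = gain * a[:, n] + t_noise[:, n] + (m[:, n + 1] - m[:, n])
        taps_sync = stim[None, :] + a + offset

        mu_c = target + subject.central_tendency_weight * (
            subject.indifference_interval - target)
        c = rng.normal(mu_c, sigma_t, size=(T, n_cont))
        m2 = rng.normal(0.0, sigma_m, size=(T, n_cont + 1))
        intervals = c + m2[:, 1:] - m2[:, :-1]
        taps_cont = taps_sync[:, -1:] + np.cumsum(intervals, axis=1)

        for k in range(T):
            session.trials.append(Trial(
                modality=modality,
                target_ms=target,
                stimulus_onsets=stim,
                tap_onsets=np.concatenate([taps_sync[k], taps_cont[k]]),
                n_sync=n_sync,
            ))
    return session
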