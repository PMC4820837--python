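"""Forward simulation of BOLD time-series from ground-truth patterns.

Signal: each scene's impulse train convolved with the double-gamma HRF,
scaled voxelwise by that scene's latent pattern.  Noise: AR(1) Gaussian
with marginal sd ``sigma`` plus a slow linear + sinusoidal drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .._rng import substream
from ..design import TrialSequence
from ..estimation import HRFSpec, build_design_matrix, scene_events
from .representations import GroundTruthPatterns

__all__ = ["NoiseSpec", "BoldTimeseries", "simulate_bold"]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise parameters (artifact plumbing, not a claim
    about real scanner noise)."""

    sigma: float = 1.0
    ar1_phi: float = 0.3
    drift_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("ar1_phi must be in [0, 1)")


@dataclass(frozen=True)
class BoldTimeseries:
    """One run of simulated (or loaded) data, voxels x timepoints."""

    data: np.ndarray
    tr: float
    run_index: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("time-series must be finite")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _ar1_noise(
    rng: np.random.Generator, n_vox: int, n_tp: int, sigma: float, phi: float
) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sigma``."""
    if sigma == 0:
        return np.zeros((n_vox, n_tp))
    eps = rng.standard_normal((n_vox, n_tp))
    out = np.empty((n_vox, n_tp))
    out[:, 0] = eps[:, 0]
    innov_sd = math.sqrt(1.0 - phi * phi)
    for t in range(1, n_tp):
        out[:, t] = phi * out[:, t - 1] + innov_sd * eps[:, t]
    return sigma * out


def simulate_bold(
    patterns: GroundTruthPatterns,
    sequence: TrialSequence,
    hrf: HRFSpec | None = None,
    noise: NoiseSpec | None = None,
    run_jitter: float = 0.1,
    amplitude: float = 1.0,
) -> list[BoldTimeseries]:
    """Simulate one run of BOLD data per run in ``sequence``.

    ``run_jitter`` in [0, 1) re-draws a small fraction of each scene's
    pattern variance independently per run, so that estimates of the
    same latent pattern are not degenerate at r = 1 in the noiseless
    limit.  Deterministic given ``noise.seed``.
    """
    hrf = hrf or HRFSpec()
    noise = noise or NoiseSpec()
    if sequence.tr <= 0 or sequence.trial_duration <= 0:
        raise ValueError("TR and trial duration must be positive")
    if not (0.0 <= run_jitter < 1.0):
        raise ValueError("run_jitter must be in [0, 1)")

    rng = substream(noise.seed, "synth", "bold", patterns.roi)
    scene_ids = list(patterns.scene_ids)
    n_vox = patterns.pattern.shape[1]
    runs: list[BoldTimeseries] = []
    for r in sorted(sequence.trials["run"].unique()):
        events = scene_events(sequence, r)
        all_trials = sequence.run(r)
        run_duration = all_trials["onset"].max() + sequence.trial_duration
        n_tp = math.ceil(run_duration / sequence.tr)
        design = build_design_matrix(
            events,
            hrf=hrf,
            tr=sequence.tr,
            n_timepoints=n_tp,
            events_as="impulse",
            add_intercept=False,
        )
        order = [design.names.index(s) for s in scene_ids]
        X = design.matrix[:, order]  # (n_tp, n_scenes)

        pat = patterns.pattern
        if run_jitter > 0:
            jit = rng.standard_normal(pat.shape)
            pat = math.sqrt(1.0 - run_jitter**2) * pat + run_jitter * jit
        signal = amplitude * (X @ pat)  # (n_tp, n_vox)

        data = signal.T + _ar1_noise(rng, n_vox, n_tp, noise.sigma, noise.ar1_phi)
        if noise.drift_amplitude > 0:
            t = np.arange(n_tp) / max(n_tp - 1, 1)
            slope = rng.standard_normal(n_vox)[:, None]
            phase = rng.uniform(0, 2 * np.pi, size=n_vox)[:, None]
            period = rng.uniform(0.5, 1.5, size=n_vox)[:, None]
            drift = slope * (t - 0.5) + np.cos(2 * np.pi * t / period + phase)
            data = data + noise.drift_amplitude * drift
        runs.append(BoldTimeseries(data=data, tr=sequence.tr, run_index=int(r)))
    return runs
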