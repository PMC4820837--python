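"""Latent scene representations as a Gaussian factor model.

Each scene's representation is a read-out of latent feature units.  A
condition-level factor induces correlation ``c_global`` among all
same-condition scenes; an additional pair factor adds ``c_pair`` between
pairmates (negative values flip the pair-factor sign between pairmates,
i.e. repulsion past orthogonality).  With unit-variance components the
expected voxelwise correlations are exactly

* pairmates:                 c_global + c_pair
* same-condition nonpairmates: c_global

(diluted by ``1 / (1 + pattern_noise_sd**2)`` when idiosyncratic voxel
noise is added), which gives closed-form oracles for testing.

A per-voxel selectivity profile scales how strongly the learning-driven
change in pair coupling (relative to the baseline condition) is expressed
in that voxel, producing a selectivity-tercile gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .._rng import substream
from ..design import NO_FACE, StimulusSet

__all__ = [
    "RepresentationModel",
    "GroundTruthPatterns",
    "sample_ground_truth_patterns",
    "apply_differentiation",
]


def _as_condition_map(value, conditions) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [c for c in conditions if c not in value]
        if missing:
            raise ValueError(f"missing coupling for conditions: {missing}")
        return {c: float(value[c]) for c in conditions}
    return {c: float(value) for c in conditions}


@dataclass(frozen=True)
class RepresentationModel:
    """Parameters of the latent factor model for one ROI.

    ``c_global`` / ``c_pair`` may be scalars or per-condition mappings.
    ``selectivity_profile`` is an optional (n_voxels,) array of
    nonnegative weights; it is normalized to mean 1 so the mean coupling
    per condition is preserved.
    """

    n_voxels: int = 120
    n_units: int = 60
    c_global: float | Mapping[str, float] = 0.1
    c_pair: float | Mapping[str, float] = 0.15
    selectivity_profile: np.ndarray | None = None
    pattern_noise_sd: float = 0.0
    seed: int = 0
    label: str = "ROI"

    def couplings(self, conditions) -> tuple[dict[str, float], dict[str, float]]:
        cg = _as_condition_map(self.c_global, conditions)
        cp = _as_condition_map(self.c_pair, conditions)
        for c in conditions:
            if not (0.0 <= cg[c] < 1.0):
                raise ValueError(f"c_global[{c}]={cg[c]} must be in [0, 1)")
            if not (-1.0 < cg[c] + cp[c] < 1.0):
                raise ValueError(
                    f"implied pairmate coupling c_global+c_pair={cg[c] + cp[c]} "
                    f"for {c} outside (-1, 1)"
                )
            if cg[c] + abs(cp[c]) >= 1.0:
                raise ValueError(
                    f"c_global + |c_pair| must stay below 1 for {c} "
                    f"(got {cg[c] + abs(cp[c])})"
                )
        return cg, cp

    def validate(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.pattern_noise_sd < 0:
            raise ValueError("pattern_noise_sd must be >= 0")
        if self.selectivity_profile is not None:
            w = np.asarray(self.selectivity_profile, dtype=float)
            if w.shape != (self.n_voxels,):
                raise ValueError("selectivity_profile must have shape (n_voxels,)")
            if (w < 0).any():
                raise ValueError("selectivity_profile weights must be nonnegative")


@dataclass(frozen=True)
class GroundTruthPatterns:
    """Latent scene x voxel patterns for one ROI plus the factor
    decomposition needed to apply unit dropout / repulsion later."""

    pattern: np.ndarray  # (n_scenes, n_voxels)
    scene_ids: tuple[str, ...]
    roi: str
    model: RepresentationModel
    pair_of_scene: np.ndarray = field(repr=False)  # (n_scenes,) pair index
    unit_of_voxel: np.ndarray = field(repr=False)  # (n_voxels,)
    pair_amp: np.ndarray = field(repr=False)  # signed sqrt|c_pair_v| per scene,voxel
    pair_factor: np.ndarray = field(repr=False)  # (n_pairs, n_units)
    base: np.ndarray = field(repr=False)  # pattern minus pair-factor part
    selectivity: np.ndarray = field(repr=False)  # per-voxel weight, mean 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.pattern).all():
            raise ValueError("patterns must be finite")


def _per_voxel_pair_coupling(
    cp_cond: float, cp_base: float, selectivity: np.ndarray
) -> np.ndarray:
    """Learning-driven change in pair coupling, scaled per voxel by
    selectivity; mean over voxels equals ``cp_cond``."""
    return cp_base + selectivity * (cp_cond - cp_base)


def sample_ground_truth_patterns(
    model: RepresentationModel, stimset: StimulusSet
) -> GroundTruthPatterns:
    """Draw scene x voxel ground-truth patterns for one ROI."""
    model.validate()
    cg_map, cp_map = model.couplings(tuple(sorted(set(stimset.condition.values()))))
    rng = substream(model.seed, "synth", "patterns", model.label)

    scenes = list(stimset.scenes)
    pair_ids = list(stimset.pair_ids)
    pair_index = {p: i for i, p in enumerate(pair_ids)}
    n_scenes, n_vox, n_units = len(scenes), model.n_voxels, model.n_units

    if model.selectivity_profile is None:
        selectivity = np.ones(n_vox)
    else:
        w = np.asarray(model.selectivity_profile, dtype=float)
        selectivity = w * n_vox / w.sum()

    unit_of_voxel = np.arange(n_vox) % n_units
    cond_factor = {c: rng.standard_normal(n_units) for c in sorted(cg_map)}
    pair_factor = rng.standard_normal((len(pair_ids), n_units))
    scene_factor = rng.standard_normal((n_scenes, n_units))

    # baseline pair coupling against which learning-driven change is
    # expressed per voxel; NoFace when present, else the condition mean
    if NO_FACE in cp_map:
        cp_base = cp_map[NO_FACE]
    else:
        cp_base = float(np.mean(list(cp_map.values())))

    pair_of_scene = np.empty(n_scenes, dtype=int)
    pair_amp = np.empty((n_scenes, n_vox))
    base = np.empty((n_scenes, n_vox))
    for i, scene in enumerate(scenes):
        pid = stimset.pair_of_scene(scene)
        pidx = pair_index[pid]
        pair_of_scene[i] = pidx
        cond = stimset.condition[pid]
        cg = cg_map[cond]
        cp_v = _per_voxel_pair_coupling(cp_map[cond], cp_base, selectivity)
        cp_v = np.clip(cp_v, -(1 - cg) + 1e-9, (1 - cg) - 1e-9)
        mate_first = stimset.pairs[pid][0] == scene
        sign = np.ones(n_vox) if mate_first else np.sign(cp_v) + (cp_v == 0)
        pair_amp[i] = sign * np.sqrt(np.abs(cp_v))
        resid_sd = np.sqrt(1.0 - cg - np.abs(cp_v))
        base[i] = (
            np.sqrt(cg) * cond_factor[cond][unit_of_voxel]
            + resid_sd * scene_factor[i, unit_of_voxel]
        )
    if model.pattern_noise_sd > 0:
        base = base + model.pattern_noise_sd * rng.standard_normal((n_scenes, n_vox))

    pattern = base + pair_amp * pair_factor[pair_of_scene][:, unit_of_voxel]

    return GroundTruthPatterns(
        pattern=pattern,
        scene_ids=tuple(scenes),
        roi=model.label,
        model=model,
        pair_of_scene=pair_of_scene,
        unit_of_voxel=unit_of_voxel,
        pair_amp=pair_amp,
        pair_factor=pair_factor,
        base=base,
        selectivity=selectivity,
    )


def apply_differentiation(
    patterns: GroundTruthPatterns,
    dropout_fraction: float,
    repulsion_strength: float,
    seed: int | None = None,
) -> GroundTruthPatterns:
    """Drop a fraction of shared pair-factor units and push pairmates
    apart with an opposite-signed perturbation.

    ``dropout_fraction`` zeroes that fraction of each pair's shared
    factor units, replacing them with fresh scene-specific variance so
    total variance is preserved: expected pairmate correlation falls from
    ``c_global + c_pair`` to ``c_global + (1-f) * c_pair``.
    ``repulsion_strength`` r adds +-r-scaled opposite perturbations to
    the two pairmates (then renormalizes), driving the pair difference
    score through zero into negative territory as r grows.
    """
    if not 0.0 <= dropout_fraction <= 1.0:
        raise ValueError("dropout_fraction must be in [0, 1]")
    if dropout_fraction == 0.0 and repulsion_strength == 0.0:
        return patterns

    rng = substream(
        patterns.model.seed if seed is None else seed, "synth", "differentiation", patterns.roi
    )
    n_scenes, n_vox = patterns.pattern.shape
    n_units = patterns.pair_factor.shape[1]
    n_pairs = patterns.pair_factor.shape[0]

    pair_part = patterns.pair_amp * patterns.pair_factor[patterns.pair_of_scene][
        :, patterns.unit_of_voxel
    ]

    if dropout_fraction > 0.0:
        n_drop = int(round(dropout_fraction * n_units))
        dropped = np.zeros((n_pairs, n_units), dtype=bool)
        for p in range(n_pairs):
            idx = rng.choice(n_units, size=n_drop, replace=False)
            dropped[p, idx] = True
        fresh = rng.standard_normal((n_scenes, n_units))
        vox_dropped = dropped[patterns.pair_of_scene][:, patterns.unit_of_voxel]
        replacement = np.abs(patterns.pair_amp) * fresh[:, patterns.unit_of_voxel]
        pair_part = np.where(vox_dropped, replacement, pair_part)

    new_pattern = patterns.base + pair_part
    if repulsion_strength != 0.0:
        r = float(repulsion_strength)
        push = rng.standard_normal((n_pairs, n_vox))
        sign = np.where(_is_first_pairmate(patterns), 1.0, -1.0)[:, None]
        new_pattern = (new_pattern + r * sign * push[patterns.pair_of_scene]) / np.sqrt(
            1.0 + r * r
        )

    return replace(patterns, pattern=new_pattern, base=patterns.base)


def _is_first_pairmate(patterns: GroundTruthPatterns) -> np.ndarray:
    """True for the first-seen scene of each pair in scene order."""
    seen: set[int] = set()
    first = np.zeros(len(patterns.scene_ids), dtype=bool)
    for i, p in enumerate(patterns.pair_of_scene):
        if int(p) not in seen:
            first[i] = True
            seen.add(int(p))
    return first
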