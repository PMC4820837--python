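"""Cross-set representational similarity: Fisher-z correlation matrix,
scene pair difference scores, condition summaries, and classical MDS
embedding of the representational space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import StimulusSet
from .estimation import PatternEstimates, RoiMask

__all__ = [
    "CLIP",
    "SimilarityMatrix",
    "MdsEmbedding",
    "fisher_z",
    "build_similarity_matrix",
    "pair_difference_scores",
    "condition_summary",
    "mds_embed",
]

CLIP = 1.0 - 1e-7  # |r| clip before arctanh


def fisher_z(r):
    """Fisher z-transform, arctanh(r), with |r| clipped to 1 - 1e-7.

    Rejects values outside [-1, 1]; the clip only guards exactly
    degenerate (|r| = 1) inputs from noiseless data.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(arr, -CLIP, CLIP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairs x pairs matrix of Fisher-z across-set correlations.

    Rows index set-A scenes by pair, columns set-B scenes by pair, so
    the diagonal holds pairmate similarities.  ``valid_mask`` is False
    for across-condition nonpairmate cells, which never enter any
    average.
    """

    z: np.ndarray
    valid_mask: np.ndarray
    pair_ids: tuple[str, ...]
    conditions: tuple[str, ...]  # per pair
    row_scenes: tuple[str, ...]
    col_scenes: tuple[str, ...]
    roi: str = "roi"

    def __post_init__(self) -> None:
        n = len(self.pair_ids)
        if self.z.shape != (n, n) or self.valid_mask.shape != (n, n):
            raise ValueError("matrix shape must be n_pairs x n_pairs")
        if not np.isfinite(self.z).all():
            raise ValueError("similarity values must be finite")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def build_similarity_matrix(
    patterns,
    roi: RoiMask | None,
    stimset: StimulusSet,
    use_betas: bool = False,
    zscore_patterns: bool = False,
) -> SimilarityMatrix:
    """Correlate every set-A scene pattern with every set-B pattern.

    ``patterns`` is a PatternEstimates whose regressor names include
    every scene id, or a (scene_names, array) tuple.  Correlations are
    computed over the ROI voxels on t-maps by default (set
    ``use_betas`` for betas; ``zscore_patterns`` standardizes each
    pattern across voxels first — off by default).
    """
    if isinstance(patterns, PatternEstimates):
        names = list(patterns.names)
        data = patterns.beta if use_betas else patterns.tmap
    else:
        names, data = list(patterns[0]), np.asarray(patterns[1], dtype=float)
    missing = [s for s in stimset.scenes if s not in names]
    if missing:
        raise ValueError(f"patterns missing for scenes: {missing[:5]}")

    if roi is not None:
        if roi.n_voxels < 2:
            raise ValueError("ROI must contain at least 2 voxels")
        data = data[:, roi.mask]
    if data.shape[1] < 2:
        raise ValueError("need at least 2 voxels to correlate")

    pair_ids = stimset.pair_ids
    row_scenes = tuple(stimset.pairs[p][0] for p in pair_ids)  # set A
    col_scenes = tuple(stimset.pairs[p][1] for p in pair_ids)  # set B
    conditions = tuple(stimset.condition[p] for p in pair_ids)

    def extract(scenes: Sequence[str]) -> np.ndarray:
        rows = np.stack([data[names.index(s)] for s in scenes])
        sd = rows.std(axis=1)
        if (sd == 0).any():
            bad = [s for s, z in zip(scenes, sd == 0) if z]
            raise ValueError(f"zero-variance pattern(s), correlation undefined: {bad}")
        if zscore_patterns:
            rows = (rows - rows.mean(axis=1, keepdims=True)) / sd[:, None]
        return rows

    A = extract(row_scenes)
    B = extract(col_scenes)
    Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    r = (Az @ Bz.T) / A.shape[1]
    r = np.clip(r, -1.0, 1.0)  # guard rounding past unity
    cond_arr = np.asarray(conditions)
    valid = cond_arr[:, None] == cond_arr[None, :]
    return SimilarityMatrix(
        z=fisher_z(r),
        valid_mask=valid,
        pair_ids=pair_ids,
        conditions=conditions,
        row_scenes=row_scenes,
        col_scenes=col_scenes,
        roi=roi.label if roi is not None else "all",
    )


def pair_difference_scores(
    simmat: SimilarityMatrix, subject: str | int | None = None
) -> pd.DataFrame:
    """Per-pair pairmate similarity, mean same-condition nonpairmate
    similarity (row and column cells of the pair, jointly averaged),
    and their difference."""
    n = simmat.n_pairs
    rows = []
    for i in range(n):
        others = [
            j for j in range(n) if j != i and simmat.valid_mask[i, j]
        ]
        if not others:
            raise ValueError(
                f"pair {simmat.pair_ids[i]!r} has no same-condition nonpairmates"
            )
        cells = np.concatenate([simmat.z[i, others], simmat.z[others, i]])
        mean_np = float(cells.mean())
        pairmate = float(simmat.z[i, i])
        rows.append(
            {
                "pair": simmat.pair_ids[i],
                "condition": simmat.conditions[i],
                "pairmate_z": pairmate,
                "mean_nonpairmate_z": mean_np,
                "difference_score": pairmate - mean_np,
                "roi": simmat.roi,
                "subject": subject,
            }
        )
    return pd.DataFrame(rows)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Subject-level condition means, then across-subject mean and
    s.e.m. for difference score, pairmate and nonpairmate similarity."""
    if table.empty:
        raise ValueError("empty score table")
    measures = ["difference_score", "pairmate_z", "mean_nonpairmate_z"]
    per_subj = table.groupby(["subject", "condition"], sort=True)[measures].mean().reset_index()
    out = []
    for cond, grp in per_subj.groupby("condition", sort=True):
        row: dict = {"condition": cond, "n_subjects": len(grp)}
        for m in measures:
            vals = grp[m].to_numpy()
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class MdsEmbedding:
    """2-D classical (Torgerson) MDS coordinates, centred at the
    origin; deterministic up to rotation/reflection."""

    coords: pd.DataFrame  # columns scene, x, y
    stress: float

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be nonnegative")


def _scene_dissimilarity(
    simmat: SimilarityMatrix, pairs: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Scene-level dissimilarity d = z_max - z.

    Across-set cells (the measured ones) use d directly; within-set
    cells, which are never measured, are imputed from the symmetrized
    across-set counterpart (M + M^T)/2.  ``pairs`` optionally restricts
    the embedding to a subset of pairs (as in a per-condition plot)."""
    z = simmat.z
    zmax = float(z.max())
    M = zmax - z  # rows: set-A scenes (by pair), cols: set-B scenes
    sym = 0.5 * (M + M.T)
    if pairs is None:
        keep = np.arange(simmat.n_pairs)
    else:
        keep = np.array([simmat.pair_ids.index(p) for p in pairs])
    M = M[np.ix_(keep, keep)]
    sym = sym[np.ix_(keep, keep)]
    n = len(keep)
    scenes = [simmat.row_scenes[i] for i in keep] + [simmat.col_scenes[i] for i in keep]
    D = np.zeros((2 * n, 2 * n))
    D[:n, n:] = M  # measured: A_i vs B_j
    D[n:, :n] = M.T
    D[:n, :n] = sym  # within set A: imputed
    D[n:, n:] = sym  # within set B: imputed
    np.fill_diagonal(D, 0.0)
    return scenes, D


def mds_embed(
    simmat: SimilarityMatrix | np.ndarray,
    scene_ids: Sequence[str] | None = None,
    n_components: int = 2,
    pairs: Sequence[str] | None = None,
) -> MdsEmbedding:
    """Classical MDS: double-centre squared dissimilarities and embed on
    the top eigendimensions."""
    if isinstance(simmat, SimilarityMatrix):
        scenes, D = _scene_dissimilarity(simmat, pairs=pairs)
    else:
        D = np.asarray(simmat, dtype=float)
        scenes = list(scene_ids) if scene_ids is not None else [str(i) for i in range(len(D))]
    m = D.shape[0]
    if m < 3:
        raise ValueError("need at least 3 items to embed")
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(lam)[None, :]
    emb_d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    denom = (D**2).sum()
    stress = float(np.sqrt(((emb_d - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    coords = pd.DataFrame({"scene": scenes, "x": X[:, 0], "y": X[:, 1]})
    return MdsEmbedding(coords=coords, stress=stress)
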