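"""Experimental design generation.

Deterministic, seeded generators for the three design artefacts used by
the rest of the pipeline:

* :class:`StimulusSet` — pair/condition/subcategory structure plus face
  and object assignments for 72 scenes in 36 pairmate pairs.
* :class:`TrialSequence` — scanner runs of 72 scene + 24 null trials with
  pairmates confined to opposite half-blocks and rare target flags.
* :class:`LearningSchedule` — day-1 scene–face study/test cycles and the
  post-scan three-cycle scene–object task with pairmate/nonpairmate foils.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "DesignSpec",
    "StimulusSet",
    "TrialSequence",
    "LearningSchedule",
    "make_stimulus_set",
    "make_scan_sequence",
    "make_learning_schedule",
    "write_events_tsv",
    "read_events_tsv",
]

NO_FACE = "NoFace"
DIFFERENT_FACE = "DifferentFace"
SAME_FACE = "SameFace"
DEFAULT_CONDITIONS = (NO_FACE, DIFFERENT_FACE, SAME_FACE)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the experimental design.

    Defaults reproduce the published design: 36 pairs, 12 per condition,
    balanced indoor/outdoor, 4 s trials at TR 2 s, 96-trial runs with
    1-in-12 target trials.
    """

    n_pairs_total: int = 36
    n_pairs_per_condition: int = 12
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    subcategories: tuple[str, ...] = ("indoor", "outdoor")
    n_runs: int = 8
    trial_duration: float = 4.0
    stim_duration: float = 0.5
    tr: float = 2.0
    n_null_interleaved: int = 18
    n_lead_in: int = 3
    n_lead_out: int = 3
    target_rate: float = 1.0 / 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_per_condition * len(self.conditions) != self.n_pairs_total:
            raise ValueError(
                "n_pairs_per_condition x n_conditions must equal n_pairs_total "
                f"({self.n_pairs_per_condition} x {len(self.conditions)} != {self.n_pairs_total})"
            )
        if self.n_pairs_per_condition % len(self.subcategories) != 0:
            raise ValueError(
                "subcategory balance impossible: n_pairs_per_condition "
                f"({self.n_pairs_per_condition}) not divisible by "
                f"{len(self.subcategories)} subcategories"
            )
        if not (0.0 <= self.target_rate < 0.5):
            raise ValueError(f"target_rate must be in [0, 0.5), got {self.target_rate}")
        if self.trial_duration <= 0 or self.tr <= 0:
            raise ValueError("trial_duration and tr must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be distinct")

    @property
    def n_scenes(self) -> int:
        return 2 * self.n_pairs_total

    @property
    def n_trials_per_run(self) -> int:
        return (
            self.n_scenes
            + self.n_null_interleaved
            + self.n_lead_in
            + self.n_lead_out
        )

    @property
    def run_duration(self) -> float:
        return self.n_trials_per_run * self.trial_duration


@dataclass(frozen=True)
class StimulusSet:
    """Scene/pair structure with condition, subcategory, half, face and
    object assignments.  ``pairs`` maps pair id -> (set-A scene, set-B
    scene)."""

    scenes: tuple[str, ...]
    pairs: Mapping[str, tuple[str, str]]
    condition: Mapping[str, str]
    subcategory: Mapping[str, str]
    set_half: Mapping[str, str]
    face_assignment: Mapping[str, str]
    object_assignment: Mapping[str, str]

    @property
    def pair_ids(self) -> tuple[str, ...]:
        return tuple(self.pairs)

    def pair_of_scene(self, scene: str) -> str:
        return self._scene_to_pair()[scene]

    def _scene_to_pair(self) -> Mapping[str, str]:
        return {s: p for p, (a, b) in self.pairs.items() for s in (a, b)}

    def pairmate(self, scene: str) -> str:
        a, b = self.pairs[self.pair_of_scene(scene)]
        return b if scene == a else a

    def scenes_in_condition(self, cond: str) -> list[str]:
        return [s for p, (a, b) in self.pairs.items() if self.condition[p] == cond for s in (a, b)]

    def pairs_in_condition(self, cond: str) -> list[str]:
        return [p for p in self.pairs if self.condition[p] == cond]

    def validate(self) -> None:
        owners: dict[str, list[str]] = {}
        for p, (a, b) in self.pairs.items():
            for s in (a, b):
                owners.setdefault(s, []).append(p)
        for s in self.scenes:
            if len(owners.get(s, [])) != 1:
                raise ValueError(f"scene {s!r} must belong to exactly one pair")
        for p, (a, b) in self.pairs.items():
            if self.set_half[a] == self.set_half[b]:
                raise ValueError(f"pairmates of {p!r} share set half")
            cond = self.condition[p]
            if cond == SAME_FACE:
                if self.face_assignment.get(a) != self.face_assignment.get(b):
                    raise ValueError(f"SameFace pair {p!r} pairmates must share a face")
            elif cond == DIFFERENT_FACE:
                if self.face_assignment.get(a) == self.face_assignment.get(b):
                    raise ValueError(f"DifferentFace pair {p!r} pairmates must have distinct faces")
            elif cond == NO_FACE:
                if a in self.face_assignment or b in self.face_assignment:
                    raise ValueError(f"NoFace pair {p!r} scenes must have no faces")
        objs = [self.object_assignment[s] for s in self.scenes]
        if len(set(objs)) != len(objs):
            raise ValueError("object assignments must be unique per scene")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, (a, b) in self.pairs.items():
            for s in (a, b):
                rows.append(
                    {
                        "scene": s,
                        "pair": p,
                        "condition": self.condition[p],
                        "subcategory": self.subcategory[p],
                        "set_half": self.set_half[s],
                        "face": self.face_assignment.get(s, ""),
                        "object": self.object_assignment[s],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        pairs: dict[str, list[str | None]] = {}
        condition: dict[str, str] = {}
        subcategory: dict[str, str] = {}
        set_half: dict[str, str] = {}
        faces: dict[str, str] = {}
        objects: dict[str, str] = {}
        for row in df.itertuples(index=False):
            slot = pairs.setdefault(row.pair, [None, None])
            slot[0 if row.set_half == "A" else 1] = row.scene
            condition[row.pair] = row.condition
            subcategory[row.pair] = row.subcategory
            set_half[row.scene] = row.set_half
            if isinstance(row.face, str) and row.face:
                faces[row.scene] = row.face
            objects[row.scene] = row.object
        return cls(
            scenes=tuple(df["scene"]),
            pairs={p: (a, b) for p, (a, b) in pairs.items()},  # type: ignore[misc]
            condition=condition,
            subcategory=subcategory,
            set_half=set_half,
            face_assignment=faces,
            object_assignment=objects,
        )


@dataclass(frozen=True)
class TrialSequence:
    """Ordered scanner trials for all runs.

    ``trials`` has columns run, onset, duration, kind (scene|null),
    scene_id ('' for null), target (bool).
    """

    trials: pd.DataFrame
    trial_duration: float
    tr: float

    def run(self, run_index: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run_index].reset_index(drop=True)

    @property
    def n_runs(self) -> int:
        return int(self.trials["run"].nunique())

    def validate(self, stimset: StimulusSet, spec: DesignSpec) -> None:
        for r in sorted(self.trials["run"].unique()):
            run = self.run(r)
            scene_rows = run[run["kind"] == "scene"]
            if sorted(scene_rows["scene_id"]) != sorted(stimset.scenes):
                raise ValueError(f"run {r}: must contain every scene exactly once")
            n_null = int((run["kind"] == "null").sum())
            if n_null != spec.n_null_interleaved + spec.n_lead_in + spec.n_lead_out:
                raise ValueError(f"run {r}: wrong null-trial count {n_null}")
            if not (run["kind"].iloc[: spec.n_lead_in] == "null").all():
                raise ValueError(f"run {r}: lead-in trials must be null")
            if not (run["kind"].iloc[-spec.n_lead_out :] == "null").all():
                raise ValueError(f"run {r}: lead-out trials must be null")
            # pairmates in opposite contiguous half-blocks
            pos = {s: i for i, s in zip(scene_rows.index, scene_rows["scene_id"])}
            order = sorted(pos, key=pos.get)  # type: ignore[arg-type]
            half = len(order) // 2
            first = set(order[:half])
            for p, (a, b) in stimset.pairs.items():
                if (a in first) == (b in first):
                    raise ValueError(f"run {r}: pairmates of {p!r} share a half-block")
            onsets = run["onset"].to_numpy()
            if not np.allclose(onsets % self.trial_duration, 0.0):
                raise ValueError(f"run {r}: onsets must be multiples of trial_duration")


@dataclass(frozen=True)
class LearningSchedule:
    """Study/test trial listing for day-1 scene–face learning and the
    post-scan scene–object task.

    ``trials`` columns: phase (day1_face|postscan_object), cycle, block,
    block_type (study|test), trial, cue_scene, target, pairmate_foil,
    nonpairmate_foil, condition.  Foil columns are empty for study trials
    and for conditions where the foil kind does not exist.
    """

    trials: pd.DataFrame

    def phase(self, name: str) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == name].reset_index(drop=True)

    @property
    def scene_object_associations(self) -> dict[str, str]:
        df = self.phase("postscan_object")
        study = df[df["block_type"] == "study"]
        return dict(zip(study["cue_scene"], study["target"]))


def make_stimulus_set(spec: DesignSpec) -> StimulusSet:
    """Assign pairs to conditions and subcategories, pairmates to halves,
    and faces/objects to scenes, deterministically from ``spec.seed``."""
    rng = substream(spec.seed, "design", "stimulus_set")
    n_sub = len(spec.subcategories)
    pair_ids = [f"pair{p:02d}" for p in range(spec.n_pairs_total)]
    scene_ids = [f"scene{i:02d}" for i in range(spec.n_scenes)]
    pairs_scenes = {
        pid: (scene_ids[2 * i], scene_ids[2 * i + 1]) for i, pid in enumerate(pair_ids)
    }

    if spec.n_pairs_total % n_sub != 0:
        raise ValueError("n_pairs_total must divide evenly across subcategories")
    sub_assign: dict[str, str] = {}
    shuffled = list(pair_ids)
    rng.shuffle(shuffled)
    per_sub = spec.n_pairs_total // n_sub
    for k, sub in enumerate(spec.subcategories):
        for pid in shuffled[k * per_sub : (k + 1) * per_sub]:
            sub_assign[pid] = sub

    # deal conditions within each subcategory so that condition x
    # subcategory cells are exactly balanced
    cond_assign: dict[str, str] = {}
    per_cell = spec.n_pairs_per_condition // n_sub
    for sub in spec.subcategories:
        members = [pid for pid in pair_ids if sub_assign[pid] == sub]
        rng.shuffle(members)
        for k, cond in enumerate(spec.conditions):
            for pid in members[k * per_cell : (k + 1) * per_cell]:
                cond_assign[pid] = cond

    set_half: dict[str, str] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for pid in pair_ids:
        a, b = pairs_scenes[pid]
        if rng.random() < 0.5:
            a, b = b, a
        set_half[a] = "A"
        set_half[b] = "B"
        pairs[pid] = (a, b)

    faces: dict[str, str] = {}
    face_counter = 0
    for pid in pair_ids:
        cond = cond_assign[pid]
        a, b = pairs[pid]
        if cond == SAME_FACE:
            fid = f"face{face_counter:02d}"
            face_counter += 1
            faces[a] = fid
            faces[b] = fid
        elif cond == DIFFERENT_FACE:
            for s in (a, b):
                faces[s] = f"face{face_counter:02d}"
                face_counter += 1

    object_ids = [f"object{i:02d}" for i in range(spec.n_scenes)]
    rng.shuffle(object_ids)
    objects = dict(zip(scene_ids, object_ids))

    stimset = StimulusSet(
        scenes=tuple(scene_ids),
        pairs=pairs,
        condition=cond_assign,
        subcategory=sub_assign,
        set_half=set_half,
        face_assignment=faces,
        object_assignment=objects,
    )
    stimset.validate()
    return stimset


def make_scan_sequence(stimset: StimulusSet, spec: DesignSpec) -> TrialSequence:
    """Generate ``spec.n_runs`` scanner runs.

    Each run: lead-in nulls, a contiguous half-block of all set-A (or -B)
    scenes with half of the interleaved nulls mixed in, the opposite
    half-block, then lead-out nulls.  AB/BA order alternates across runs
    with the starting order decided by seed.  Exactly
    ``round(target_rate * n_trials)`` trials per run are flagged targets.
    """
    rng = substream(spec.seed, "design", "scan_sequence")
    n_trials = spec.n_trials_per_run
    n_targets = int(round(spec.target_rate * n_trials))
    if spec.target_rate > 0 and n_targets == 0:
        raise ValueError(
            f"target_rate={spec.target_rate} rounds to zero target trials per run"
        )

    set_a = sorted([s for s in stimset.scenes if stimset.set_half[s] == "A"])
    set_b = sorted([s for s in stimset.scenes if stimset.set_half[s] == "B"])
    n_first_nulls = (spec.n_null_interleaved + 1) // 2
    n_second_nulls = spec.n_null_interleaved - n_first_nulls
    start_ab = bool(rng.random() < 0.5)

    rows = []
    for r in range(spec.n_runs):
        ab = start_ab if r % 2 == 0 else not start_ab
        halves = (set_a, set_b) if ab else (set_b, set_a)
        kinds: list[tuple[str, str]] = [("null", "")] * spec.n_lead_in
        for scene_half, n_nulls in zip(halves, (n_first_nulls, n_second_nulls)):
            block = [("scene", s) for s in rng.permutation(scene_half)]
            block += [("null", "")] * n_nulls
            idx = rng.permutation(len(block))
            kinds.extend(block[i] for i in idx)
        kinds += [("null", "")] * spec.n_lead_out
        assert len(kinds) == n_trials
        target_idx = set(rng.choice(n_trials, size=n_targets, replace=False).tolist())
        for i, (kind, scene) in enumerate(kinds):
            rows.append(
                {
                    "run": r,
                    "onset": i * spec.trial_duration,
                    "duration": spec.stim_duration,
                    "kind": kind,
                    "scene_id": scene,
                    "target": i in target_idx,
                }
            )
    trials = pd.DataFrame(rows)
    seq = TrialSequence(trials=trials, trial_duration=spec.trial_duration, tr=spec.tr)
    seq.validate(stimset, spec)
    return seq


def _balanced_pair_sets(
    stimset: StimulusSet, spec: DesignSpec, rng: np.random.Generator, n_sets: int
) -> list[list[str]]:
    """Partition all pairs into ``n_sets`` groups balanced by condition."""
    per_set = {c: spec.n_pairs_per_condition // n_sets for c in spec.conditions}
    if spec.n_pairs_per_condition % n_sets != 0:
        raise ValueError("pairs per condition must divide evenly into sets")
    by_cond = {c: list(rng.permutation(stimset.pairs_in_condition(c))) for c in spec.conditions}
    sets: list[list[str]] = []
    for k in range(n_sets):
        chunk: list[str] = []
        for c in spec.conditions:
            chunk.extend(by_cond[c][k * per_set[c] : (k + 1) * per_set[c]])
        sets.append(chunk)
    return sets


def _object_test_trials(
    set_pairs: list[str],
    stimset: StimulusSet,
    rng: np.random.Generator,
) -> list[dict]:
    """Test trials for one 24-trial scene–object set: three choices per
    trial — target, pairmate foil, same-condition nonpairmate foil from
    the same (immediately preceding) study set."""
    scenes = [s for p in set_pairs for s in stimset.pairs[p]]
    trials = []
    for cue in rng.permutation(scenes):
        pair = stimset.pair_of_scene(cue)
        cond = stimset.condition[pair]
        mate = stimset.pairmate(cue)
        candidates = [
            s
            for s in scenes
            if s not in (cue, mate) and stimset.condition[stimset.pair_of_scene(s)] == cond
        ]
        foil_scene = candidates[rng.integers(len(candidates))]
        trials.append(
            {
                "cue_scene": cue,
                "target": stimset.object_assignment[cue],
                "pairmate_foil": stimset.object_assignment[mate],
                "nonpairmate_foil": stimset.object_assignment[foil_scene],
                "condition": cond,
            }
        )
    return trials


def _face_test_trials(
    set_pairs: list[str],
    stimset: StimulusSet,
    rng: np.random.Generator,
) -> list[dict]:
    """Test trials for a scene–face block.  DifferentFace cues get the
    pairmate's face as a foil; SameFace cues (pairmate face identical to
    the target) get two nonpairmate foils instead."""
    scenes = [s for p in set_pairs for s in stimset.pairs[p]]
    trials = []
    for cue in rng.permutation(scenes):
        pair = stimset.pair_of_scene(cue)
        cond = stimset.condition[pair]
        mate = stimset.pairmate(cue)
        same_cond = [
            s
            for s in scenes
            if s not in (cue, mate) and stimset.condition[stimset.pair_of_scene(s)] == cond
        ]
        if cond == DIFFERENT_FACE:
            foil_scene = same_cond[rng.integers(len(same_cond))]
            pairmate_foil = stimset.face_assignment[mate]
            nonpair_foil = stimset.face_assignment[foil_scene]
        else:  # SameFace: pairmate shares the target face, use two nonpairmates
            picks = rng.choice(len(same_cond), size=2, replace=False)
            pairmate_foil = ""
            nonpair_foil = ";".join(stimset.face_assignment[same_cond[i]] for i in picks)
        trials.append(
            {
                "cue_scene": cue,
                "target": stimset.face_assignment[cue],
                "pairmate_foil": pairmate_foil,
                "nonpairmate_foil": nonpair_foil,
                "condition": cond,
            }
        )
    return trials


def make_learning_schedule(stimset: StimulusSet, spec: DesignSpec) -> LearningSchedule:
    """Build the default (error-free learner) schedule.

    Day 1: two study–test cycles over half-splits of the face-bearing
    associations followed by four full test blocks — six test exposures
    per association.  Post-scan: three study–test cycles of all 72
    scene–object associations in condition-balanced 24-trial sets.
    """
    rng = substream(spec.seed, "design", "learning_schedule")
    rows: list[dict] = []

    def emit(phase: str, cycle: int, block: int, block_type: str, trials: list[dict]) -> None:
        for t, tr_ in enumerate(trials):
            rows.append(
                {
                    "phase": phase,
                    "cycle": cycle,
                    "block": block,
                    "block_type": block_type,
                    "trial": t,
                    **tr_,
                }
            )

    face_pairs = [
        p for p in stimset.pairs if stimset.condition[p] in (DIFFERENT_FACE, SAME_FACE)
    ]
    if face_pairs:
        # two half-split study-test cycles
        for cycle in range(2):
            halves: dict[int, list[str]] = {0: [], 1: []}
            for cond in (DIFFERENT_FACE, SAME_FACE):
                members = list(rng.permutation(stimset.pairs_in_condition(cond)))
                half = len(members) // 2
                halves[0].extend(members[:half])
                halves[1].extend(members[half:])
            for block, half_pairs in halves.items():
                study = [
                    {
                        "cue_scene": s,
                        "target": stimset.face_assignment[s],
                        "pairmate_foil": "",
                        "nonpairmate_foil": "",
                        "condition": stimset.condition[stimset.pair_of_scene(s)],
                    }
                    for s in rng.permutation(
                        [s for p in half_pairs for s in stimset.pairs[p]]
                    )
                ]
                emit("day1_face", cycle, block, "study", study)
                emit("day1_face", cycle, block, "test", _face_test_trials(half_pairs, stimset, rng))
        # four full test blocks (error-free learner: no extra blocks needed)
        for block in range(4):
            emit(
                "day1_face",
                2 + block,
                0,
                "test",
                _face_test_trials(face_pairs, stimset, rng),
            )

    n_sets = 3 if spec.n_pairs_per_condition % 3 == 0 else 1
    for cycle in range(3):
        sets = _balanced_pair_sets(stimset, spec, rng, n_sets)
        for block, set_pairs in enumerate(sets):
            scenes = [s for p in set_pairs for s in stimset.pairs[p]]
            study = [
                {
                    "cue_scene": s,
                    "target": stimset.object_assignment[s],
                    "pairmate_foil": "",
                    "nonpairmate_foil": "",
                    "condition": stimset.condition[stimset.pair_of_scene(s)],
                }
                for s in rng.permutation(scenes)
            ]
            emit("postscan_object", cycle, block, "study", study)
            emit("postscan_object", cycle, block, "test", _object_test_trials(set_pairs, stimset, rng))

    return LearningSchedule(trials=pd.DataFrame(rows))


def write_events_tsv(sequence: TrialSequence, path: str | Path) -> None:
    """Write a BIDS-style events table (onset, duration, trial_type,
    stimulus_id, run); the target flag is folded into trial_type."""
    df = sequence.trials.copy()
    df["trial_type"] = np.where(
        df["target"], df["kind"] + "_target", df["kind"]
    )
    out = df[["onset", "duration", "trial_type", "scene_id", "run"]].rename(
        columns={"scene_id": "stimulus_id"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(
    path: str | Path, trial_duration: float = 4.0, tr: float = 2.0
) -> TrialSequence:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    kind = df["trial_type"].str.replace("_target", "", regex=False)
    target = df["trial_type"].str.endswith("_target")
    trials = pd.DataFrame(
        {
            "run": df["run"].astype(int),
            "onset": df["onset"].astype(float),
            "duration": df["duration"].astype(float),
            "kind": kind,
            "scene_id": df["stimulus_id"].astype(str),
            "target": target,
        }
    )
    trials.loc[trials["kind"] == "null", "scene_id"] = ""
    return TrialSequence(trials=trials, trial_duration=trial_duration, tr=tr)
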