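"""End-to-end orchestration.

Stages (design -> simulate -> estimate -> rsa -> infer -> report) are
file-based: each reads the previous stage's artifacts from the output
directory and writes its own, so a failed run leaves partial outputs in
place and any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import io as pio
from ._rng import substream
from .config import PipelineConfig
from .design import (
    DesignSpec,
    DIFFERENT_FACE,
    SAME_FACE,
    make_learning_schedule,
    make_scan_sequence,
    make_stimulus_set,
    read_events_tsv,
    write_events_tsv,
)
from .estimation import HRFSpec, RoiMask, build_design_matrix, fit_glm, highpass_filter, scene_events
from .inference import GlmmSpec, fit_mixed_logistic, lrt, one_sample_t, paired_tests
from .rsa import build_similarity_matrix, condition_summary, mds_embed, pair_difference_scores
from .synth import BehaviorModelTruth, NoiseSpec, RepresentationModel, sample_ground_truth_patterns, simulate_behavior, simulate_bold

__all__ = ["PipelineStageError", "RunReport", "run_experiment", "STAGES"]

log = logging.getLogger("pairdiff")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    condition_summaries: dict[str, pd.DataFrame]
    test_results: pd.DataFrame
    glmm_summary: pd.DataFrame
    lrt_results: pd.DataFrame
    score_table: pd.DataFrame
    behaviour: pd.DataFrame
    figure_paths: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _subject_seed(cfg: PipelineConfig, subject: int) -> int:
    return int(substream(cfg.seed, "pipeline", f"subject{subject}").integers(2**62))


def _subject_spec(cfg: PipelineConfig, subject: int) -> DesignSpec:
    return DesignSpec(**cfg.design.model_dump(), seed=_subject_seed(cfg, subject))


def _selectivity(kind: str, n_voxels: int, rng) -> np.ndarray | None:
    if kind == "uniform":
        return None
    # linear gradient from weakly to strongly scene-selective voxels
    return np.linspace(0.2, 1.8, n_voxels)


def _roi_model(cfg: PipelineConfig, roi: str, subject: int) -> RepresentationModel:
    rc = cfg.rois[roi]
    rng = substream(cfg.seed, "pipeline", "selectivity", roi)
    return RepresentationModel(
        n_voxels=rc.n_voxels,
        n_units=rc.n_units,
        c_global=rc.c_global,
        c_pair=rc.c_pair,
        selectivity_profile=_selectivity(rc.selectivity, rc.n_voxels, rng),
        pattern_noise_sd=rc.pattern_noise_sd,
        seed=_subject_seed(cfg, subject),
        label=roi,
    )


def stage_design(cfg: PipelineConfig, out: Path) -> None:
    for s in range(cfg.n_subjects):
        sdir = out / "design" / f"sub-{s:02d}"
        sdir.mkdir(parents=True, exist_ok=True)
        spec = _subject_spec(cfg, s)
        stimset = make_stimulus_set(spec)
        sequence = make_scan_sequence(stimset, spec)
        schedule = make_learning_schedule(stimset, spec)
        stimset.to_frame().to_csv(sdir / "stimulus_set.csv", index=False)
        write_events_tsv(sequence, sdir / "events.tsv")
        schedule.trials.to_csv(sdir / "learning_schedule.csv", index=False)
        pio.write_provenance(sdir / "design_spec.yaml", **{
            k: v for k, v in spec.__dict__.items() if not k.startswith("_")
        })


def _load_subject_design(cfg: PipelineConfig, out: Path, s: int):
    from .design import StimulusSet

    sdir = out / "design" / f"sub-{s:02d}"
    stimset = StimulusSet.from_frame(pd.read_csv(sdir / "stimulus_set.csv", keep_default_na=False))
    sequence = read_events_tsv(
        sdir / "events.tsv", trial_duration=cfg.design.trial_duration, tr=cfg.design.tr
    )
    return stimset, sequence


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    hrf = HRFSpec(**cfg.glm.hrf)
    for s in range(cfg.n_subjects):
        stimset, sequence = _load_subject_design(cfg, out, s)
        sdir = out / "sim" / f"sub-{s:02d}"
        sdir.mkdir(parents=True, exist_ok=True)
        noise = NoiseSpec(
            sigma=cfg.noise.sigma,
            ar1_phi=cfg.noise.ar1_phi,
            drift_amplitude=cfg.noise.drift_amplitude,
            seed=_subject_seed(cfg, s),
        )
        for roi in sorted(cfg.rois):
            patterns = sample_ground_truth_patterns(_roi_model(cfg, roi, s), stimset)
            pio.write_pattern_table(
                patterns.scene_ids, patterns.pattern, sdir / f"roi-{roi}_truth.csv"
            )
            runs = simulate_bold(
                patterns, sequence, hrf=hrf, noise=noise, run_jitter=cfg.noise.run_jitter
            )
            for ts in runs:
                pio.write_bold_nifti(ts, sdir / f"roi-{roi}_run-{ts.run_index:02d}_bold.nii")


def stage_estimate(cfg: PipelineConfig, out: Path) -> None:
    hrf = HRFSpec(**cfg.glm.hrf)
    for s in range(cfg.n_subjects):
        stimset, sequence = _load_subject_design(cfg, out, s)
        sim_dir = out / "sim" / f"sub-{s:02d}"
        est_dir = out / "est" / f"sub-{s:02d}"
        est_dir.mkdir(parents=True, exist_ok=True)
        run_ids = sorted(sequence.trials["run"].unique())
        for roi in sorted(cfg.rois):
            run_ts, designs = [], []
            for r in run_ids:
                ts = pio.read_bold_nifti(sim_dir / f"roi-{roi}_run-{r:02d}_bold.nii")
                ts = highpass_filter(ts, sigma=cfg.glm.highpass_sigma)
                events = scene_events(sequence, r)
                design = build_design_matrix(
                    events, hrf=hrf, tr=ts.tr, n_timepoints=ts.n_timepoints,
                    events_as="impulse", run_index=int(r),
                )
                run_ts.append(ts)
                designs.append(design)
            est = fit_glm(run_ts, designs, prewhiten=cfg.glm.prewhiten)
            scene_est = est.subset(list(stimset.scenes))
            pio.write_pattern_table(scene_est.names, scene_est.tmap, est_dir / f"roi-{roi}_tmap.csv")
            pio.write_pattern_table(scene_est.names, scene_est.beta, est_dir / f"roi-{roi}_beta.csv")


def stage_rsa(cfg: PipelineConfig, out: Path) -> None:
    rsa_dir = out / "rsa"
    rsa_dir.mkdir(parents=True, exist_ok=True)
    all_scores = []
    for s in range(cfg.n_subjects):
        stimset, _ = _load_subject_design(cfg, out, s)
        est_dir = out / "est" / f"sub-{s:02d}"
        for roi in sorted(cfg.rois):
            kind = "beta" if cfg.rsa.use_betas else "tmap"
            names, data = pio.read_pattern_table(est_dir / f"roi-{roi}_{kind}.csv")
            mask = RoiMask(mask=np.ones(data.shape[1], dtype=bool), label=roi)
            simmat = build_similarity_matrix(
                (names, data), mask, stimset, zscore_patterns=cfg.rsa.zscore_patterns
            )
            pd.DataFrame(simmat.z, index=simmat.pair_ids, columns=simmat.pair_ids).to_csv(
                rsa_dir / f"sub-{s:02d}_roi-{roi}_simmat.csv", index_label="pair"
            )
            all_scores.append(pair_difference_scores(simmat, subject=s))
    pd.concat(all_scores, ignore_index=True).to_csv(rsa_dir / "scores.csv", index=False)


def stage_infer(cfg: PipelineConfig, out: Path) -> None:
    inf_dir = out / "infer"
    inf_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(out / "rsa" / "scores.csv")

    # classical tests on difference scores, per ROI
    test_rows = []
    n_subjects = scores["subject"].nunique()
    for roi, grp in scores.groupby("roi", sort=True):
        if n_subjects < 2:
            break  # group-level tests need >= 2 subjects
        res = paired_tests(grp, dv="difference_score", within="condition")
        test_rows.append(
            {"roi": roi, "test": res.name, "statistic": res.statistic,
             "df": str(res.df), "p": res.p_value, "contrast": "condition effect"}
        )
        per_subj = grp.groupby(["subject", "condition"])["difference_score"].mean().reset_index()
        for cond, cg in per_subj.groupby("condition", sort=True):
            if cg["difference_score"].size >= 2:
                t = one_sample_t(cg["difference_score"].to_numpy())
                test_rows.append(
                    {"roi": roi, "test": t.name, "statistic": t.statistic,
                     "df": str(t.df), "p": t.p_value, "contrast": f"{cond} vs 0"}
                )
    pd.DataFrame(
        test_rows, columns=["roi", "test", "statistic", "df", "p", "contrast"]
    ).to_csv(inf_dir / "tests.csv", index=False)

    # behaviour generated from the HIPP-like ROI's scores (learning
    # conditions only), then brain-behaviour GLMM + LRT
    roi_for_behaviour = "HIPP" if "HIPP" in set(scores["roi"]) else sorted(set(scores["roi"]))[0]
    hs = scores[
        (scores["roi"] == roi_for_behaviour)
        & (scores["condition"].isin([DIFFERENT_FACE, SAME_FACE]))
    ]
    truth = BehaviorModelTruth(
        intercept=cfg.behavior.intercept,
        slope_score=cfg.behavior.slope_score,
        condition_effects=cfg.behavior.condition_effects,
        repetition_effect=cfg.behavior.repetition_effect,
        interaction=cfg.behavior.interaction,
        subject_sd=cfg.behavior.subject_sd,
        other_rate=cfg.behavior.other_rate,
        seed=int(substream(cfg.seed, "pipeline", "behaviour").integers(2**62)),
    )
    behaviour = simulate_behavior(truth, hs, n_subjects=cfg.n_subjects)
    behaviour.to_csv(inf_dir / "behaviour.csv", index=False)

    data = behaviour.merge(
        hs[["subject", "pair", "difference_score"]],
        left_on=["subject", "pair_id"],
        right_on=["subject", "pair"],
    )
    data = data[data["outcome"] != "other"].copy()
    data["correct"] = (data["outcome"] == "correct").astype(int)
    if cfg.n_subjects < 2:
        # mixed model undefined with a single subject; record and stop
        pd.DataFrame(columns=["term", "estimate", "se", "z", "p"]).to_csv(
            inf_dir / "glmm.csv", index=False
        )
        pd.DataFrame(
            [{"test": "likelihood ratio test", "term": cfg.inference.score_term,
              "chi2": np.nan, "df": np.nan, "p": np.nan,
              "full_loglik": np.nan, "nested_loglik": np.nan,
              "random_structure": "skipped: single subject"}]
        ).to_csv(inf_dir / "lrt.csv", index=False)
        with open(inf_dir / "glmm.json", "w") as fh:
            json.dump({"skipped": "single subject"}, fh)
        return

    spec_full = GlmmSpec(
        response="correct", fixed=cfg.inference.fixed, random_slopes=cfg.inference.random_slopes
    )
    nested_fixed = tuple(t for t in cfg.inference.fixed if t != cfg.inference.score_term)
    spec_nested = GlmmSpec(
        response="correct", fixed=nested_fixed, random_slopes=tuple(
            t for t in cfg.inference.random_slopes if t != cfg.inference.score_term
        )
    )
    full = fit_mixed_logistic(data, spec_full)
    nested = fit_mixed_logistic(data, spec_nested)
    test = lrt(full, nested)

    summary = full.summary().reset_index(names="term")
    summary.to_csv(inf_dir / "glmm.csv", index=False)
    lrt_df = pd.DataFrame(
        [{"test": test.name, "term": cfg.inference.score_term,
          "chi2": test.statistic, "df": test.df, "p": test.p_value,
          "full_loglik": full.loglik, "nested_loglik": nested.loglik,
          "random_structure": full.random_structure}]
    )
    lrt_df.to_csv(inf_dir / "lrt.csv", index=False)
    with open(inf_dir / "glmm.json", "w") as fh:
        json.dump(
            {
                "params": full.params.to_dict(),
                "se": full.se.to_dict(),
                "loglik": full.loglik,
                "n_obs": full.n_obs,
                "converged": full.converged,
                "random_structure": full.random_structure,
                "random_sd": full.random_sd.to_dict(),
            },
            fh,
            indent=2,
        )


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep_dir = out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(out / "rsa" / "scores.csv")
    figures = []

    summaries = {}
    for roi, grp in scores.groupby("roi", sort=True):
        summaries[roi] = condition_summary(grp)

    fig, axes = plt.subplots(1, len(summaries), figsize=(4 * len(summaries), 3.2), squeeze=False)
    for ax, (roi, summ) in zip(axes[0], summaries.items()):
        ax.bar(summ["condition"], summ["difference_score_mean"],
               yerr=summ["difference_score_sem"].fillna(0.0), color="0.6")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_title(roi)
        ax.set_ylabel("pair difference score (z)")
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    path = rep_dir / "condition_scores.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(str(path))

    glmm_path = out / "infer" / "glmm.csv"
    if glmm_path.exists():
        behaviour = pd.read_csv(out / "infer" / "behaviour.csv")
        roi0 = "HIPP" if "HIPP" in set(scores["roi"]) else sorted(set(scores["roi"]))[0]
        hs = scores[scores["roi"] == roi0]
        data = behaviour.merge(
            hs[["subject", "pair", "difference_score"]],
            left_on=["subject", "pair_id"], right_on=["subject", "pair"],
        )
        data = data[data["outcome"] != "other"]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        jitter = (np.arange(len(data)) % 7 - 3) * 0.004
        ax.plot(data["difference_score"], (data["outcome"] == "correct").astype(int) + jitter,
                ".", alpha=0.25)
        ax.set_xlabel("pair difference score (z)")
        ax.set_ylabel("P(correct)")
        fig.tight_layout()
        path = rep_dir / "score_vs_memory.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(str(path))

    # MDS of subject 0's first-ROI similarity structure
    roi0 = sorted(cfg.rois)[0]
    sim_path = out / "rsa" / f"sub-00_roi-{roi0}_simmat.csv"
    if sim_path.exists():
        stimset, _ = _load_subject_design(cfg, out, 0)
        names, data_t = pio.read_pattern_table(out / "est" / "sub-00" / f"roi-{roi0}_tmap.csv")
        mask = RoiMask(mask=np.ones(data_t.shape[1], dtype=bool), label=roi0)
        simmat = build_similarity_matrix((names, data_t), mask, stimset)
        emb = mds_embed(simmat)
        fig, ax = plt.subplots(figsize=(3.6, 3.6))
        ax.scatter(emb.coords["x"], emb.coords["y"], s=12)
        ax.set_title(f"MDS ({roi0}), stress={emb.stress:.2f}")
        fig.tight_layout()
        path = rep_dir / "mds.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(str(path))

    report = {
        "figures": figures,
        "condition_summaries": {roi: s.to_dict(orient="records") for roi, s in summaries.items()},
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
    }
    with open(rep_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)


STAGES: dict[str, Callable[[PipelineConfig, Path], None]] = {
    "design": stage_design,
    "simulate": stage_simulate,
    "estimate": stage_estimate,
    "rsa": stage_rsa,
    "infer": stage_infer,
    "report": stage_report,
}


def run_experiment(
    cfg: PipelineConfig, out_dir: str | Path | None = None, quiet: bool = False
) -> RunReport:
    """Run all stages in order and assemble the report.

    A stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts from completed stages remain on disk.
    """
    import tempfile

    out = Path(out_dir or cfg.out_dir or tempfile.mkdtemp(prefix="pairdiff_"))
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())

    timings = {}
    for name, fn in STAGES.items():
        t0 = time.perf_counter()
        try:
            fn(cfg, out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        if not quiet:
            log.info("stage %s done in %.2fs", name, timings[name])

    scores = pd.read_csv(out / "rsa" / "scores.csv")
    summaries = {roi: condition_summary(grp) for roi, grp in scores.groupby("roi", sort=True)}
    return RunReport(
        condition_summaries=summaries,
        test_results=pd.read_csv(out / "infer" / "tests.csv"),
        glmm_summary=pd.read_csv(out / "infer" / "glmm.csv"),
        lrt_results=pd.read_csv(out / "infer" / "lrt.csv"),
        score_table=scores,
        behaviour=pd.read_csv(out / "infer" / "behaviour.csv"),
        figure_paths=json.loads((out / "report" / "report.json").read_text())["figures"],
        provenance={"out_dir": str(out), "seed": cfg.seed, "timings": timings},
    )
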