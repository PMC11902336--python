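"""End-to-end orchestration: screen -> clean -> features -> CV -> report.

Cross-validation is always split by subject: all windows of one night stay
in the same fold.  Per fold the full model trains, in order, the initial
window classifier, the two AHI regressors (global-feature and
detection-statistics), applies the SDFFU probability correction, trains the
confidence-gated context classifiers, the final incremental detector, and
the fused AHI regressor.  The ablated arm (``use_global=False``) drops the
global branch and the SDFFU: probabilities pass uncorrected into the
context stage and AHI is regressed from detection-derived statistics only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import ahi_branch, bls, metrics, sas_branch, sdffu
from .features import global_features, sample_feature_matrix
from .preprocess import preprocess_recording, screen_subject
from .synth import Recording

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ablation_mode",
           "window_sweep"]


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    window_s: int = 30
    min_overlap_s: float = 5.0
    n_folds: int = 5
    seed: int = 0
    sdffu_trigger: float = 10.0
    top_fraction: float = 0.1
    evend_mode: str = "verbatim"
    use_global: bool = True        # False = ablated arm (no SDFFU / AHI branch)
    clf: dict = field(default_factory=dict)   # BLSConfig overrides, classifier
    # subject-level regressions see tens of rows, not tens of thousands;
    # a unit ridge keeps the wide random design from interpolating them
    reg: dict = field(default_factory=lambda: {"ridge_lambda": 1.0})

    def validate(self) -> None:
        if self.n_folds < 2:
            raise PipelineError("n_folds must be >= 2")
        if self.window_s < 10:
            raise PipelineError("window_s must be >= 10 s")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(eq=False)
class SubjectData:
    subject_id: str
    X1: np.ndarray
    y: np.ndarray
    positions: np.ndarray
    n_total: int
    tst_min: float
    G: np.ndarray
    ahi_true: float


@dataclass
class PipelineResult:
    report: metrics.EvalReport
    subjects: pd.DataFrame          # subject_id, ahi_true, ahi_hat, ahi_g, severity
    corrections: list[sdffu.CorrectionRecord]
    manifest: dict
    sample_predictions: pd.DataFrame | None = None


def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return out


def prepare_subjects(recordings: list[Recording], config: RunConfig) -> list[SubjectData]:
    """Screen, clean, segment and featurize every admissible subject."""
    out = []
    for rec in recordings:
        if screen_subject(rec).excluded:
            continue
        samples, clean = preprocess_recording(
            rec, window_s=config.window_s, min_overlap_s=config.min_overlap_s
        )
        if len(samples.labels) == 0:
            continue
        X1 = sample_feature_matrix(samples).to_numpy()
        G = global_features(clean).to_numpy() if config.use_global else np.empty(0)
        out.append(SubjectData(
            subject_id=rec.subject_id, X1=X1, y=samples.labels,
            positions=samples.positions, n_total=samples.n_total,
            tst_min=samples.tst_min, G=G, ahi_true=rec.ahi_label,
        ))
    return out


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def run_pipeline(
    recordings: list[Recording] | None = None,
    config: RunConfig | None = None,
    subjects: list[SubjectData] | None = None,
) -> PipelineResult:
    """Subject-wise cross-validated training and evaluation.

    ``subjects`` may be passed directly (already prepared) to reuse feature
    extraction across runs; otherwise it is computed from ``recordings``.
    """
    config = config or RunConfig()
    config.validate()
    if subjects is None:
        if recordings is None:
            raise PipelineError("need recordings or prepared subjects")
        subjects = prepare_subjects(recordings, config)
    ns = len(subjects)
    if ns < config.n_folds:
        raise PipelineError("fewer admissible subjects than folds")

    folds = _fold_assignment(ns, config.n_folds, config.seed)
    clf_cfg = bls.BLSConfig(task="classify", **config.clf)
    reg_cfg = bls.BLSConfig(task="regress", **config.reg)

    corrections: list[sdffu.CorrectionRecord] = []
    all_true, all_pred = [], []
    subj_rows = []
    sample_rows = []

    for fold in range(config.n_folds):
        tr = [s for s, f in zip(subjects, folds) if f != fold]
        te = [s for s, f in zip(subjects, folds) if f == fold]
        fold_seed = (config.seed * 1009 + fold) % (2**31 - 1)
        ccfg = replace(clf_cfg, seed=fold_seed)
        rcfg = replace(reg_cfg, seed=fold_seed + 1)

        Xtr = np.vstack([s.X1 for s in tr])
        ytr = np.concatenate([s.y for s in tr])
        clf0 = bls.fit(Xtr, _onehot(ytr), ccfg)

        per: dict[str, dict] = {}
        for s in tr + te:
            scores = bls.predict(clf0, s.X1)
            p0 = sas_branch.softmax2(scores)[:, 1]
            per[s.subject_id] = {"scores": scores, "p0": p0,
                                 "y0": (p0 > 0.5).astype(int)}

        ahi_tr = np.array([s.ahi_true for s in tr])
        yp_tr = sdffu.ahi_transform(ahi_tr)
        if config.use_global:
            Gtr = np.vstack([s.G for s in tr])
            reg_g = bls.fit(Gtr, yp_tr, rcfg)
            Etr = np.vstack([
                sdffu.event_stat_features(per[s.subject_id]["p0"],
                                          per[s.subject_id]["y0"],
                                          config.window_s,
                                          s.tst_min * 60.0).as_array()
                for s in tr
            ])
            reg_s = bls.fit(Etr, yp_tr, rcfg)
            for s in tr + te:
                d = per[s.subject_id]
                ahig = float(ahi_branch.predict_ahig(s.G, reg_g)[0])
                es = sdffu.event_stat_features(
                    d["p0"], d["y0"], config.window_s, s.tst_min * 60.0
                ).as_array()
                ahis = float(sdffu.predict_ahis(es, reg_s)[0])
                p0c, rec_c = sdffu.correct_probabilities(
                    d["p0"], ahig, ahis, s.tst_min, s.n_total,
                    positions=s.positions, subject_id=s.subject_id,
                    trigger=config.sdffu_trigger,
                    top_fraction=config.top_fraction,
                    evend_mode=config.evend_mode,
                )
                d["p0c"], d["ahig"] = p0c, ahig
                if s in te:
                    corrections.append(rec_c)
        else:
            for s in tr + te:
                d = per[s.subject_id]
                d["p0c"], d["ahig"] = d["p0"], 0.0

        # context stage
        for s in tr + te:
            d = per[s.subject_id]
            d["xcon"] = sas_branch.build_context(d["p0c"]).xcon
            hi, _ = sas_branch.confidence_split(d["scores"])
            mask = np.zeros(len(d["p0"]), dtype=bool)
            mask[hi] = True
            d["hi"] = mask
        ctx = sas_branch.ContextDetector(ccfg).fit(
            np.vstack([per[s.subject_id]["xcon"] for s in tr]),
            ytr,
            np.concatenate([per[s.subject_id]["hi"] for s in tr]),
        )
        for s in tr + te:
            d = per[s.subject_id]
            d["ctx"] = ctx.predict_proba(d["xcon"], d["hi"])

        # final incremental detector
        ctx_tr = np.concatenate([per[s.subject_id]["ctx"] for s in tr])
        inc_model = bls.fit_incremental(
            clf0, Xtr, ctx_tr.reshape(-1, 1), _onehot(ytr)
        )
        for s in tr + te:
            d = per[s.subject_id]
            sc = bls.predict(inc_model, s.X1, d["ctx"].reshape(-1, 1))
            d["pf"] = sas_branch.softmax2(sc)[:, 1]
            d["yf"] = (d["pf"] > 0.5).astype(int)
            d["ahi_det"] = ahi_branch.ahi_from_detections(d["yf"], s.tst_min)

        # fused AHI output
        if config.use_global:
            reg2 = ahi_branch.fit_final_ahi(
                np.vstack([s.G for s in tr]),
                np.array([per[s.subject_id]["ahi_det"] for s in tr]),
                ahi_tr, rcfg,
            )
            for s in te:
                d = per[s.subject_id]
                d["ahi_hat"] = float(ahi_branch.predict_final_ahi(
                    s.G, [d["ahi_det"]], reg2)[0])
        else:
            Dtr = np.column_stack([
                np.vstack([
                    sdffu.event_stat_features(per[s.subject_id]["pf"],
                                              per[s.subject_id]["yf"],
                                              config.window_s,
                                              s.tst_min * 60.0).as_array()
                    for s in tr
                ]),
                [per[s.subject_id]["ahi_det"] for s in tr],
            ])
            reg_d = bls.fit(Dtr, yp_tr, rcfg)
            for s in te:
                d = per[s.subject_id]
                row = np.concatenate([
                    sdffu.event_stat_features(d["pf"], d["yf"], config.window_s,
                                              s.tst_min * 60.0).as_array(),
                    [d["ahi_det"]],
                ])
                d["ahi_hat"] = float(np.maximum(
                    sdffu.ahi_inverse(bls.predict(reg_d, row[None, :])[0, 0]), 0.0))

        for s in te:
            d = per[s.subject_id]
            all_true.append(s.y)
            all_pred.append(d["yf"])
            cls, _ = ahi_branch.severity_from_ahi(d["ahi_hat"])
            subj_rows.append({
                "subject_id": s.subject_id, "fold": fold,
                "ahi_true": s.ahi_true, "ahi_hat": d["ahi_hat"],
                "ahi_g": d["ahig"], "ahi_det": d["ahi_det"], "severity": cls,
            })
            sample_rows.append(pd.DataFrame({
                "subject_id": s.subject_id,
                "segment_index": s.positions,
                "p0": d["p0"], "p0_corrected": d["p0c"],
                "context_pred": d["ctx"], "final_label": d["yf"],
                "label": s.y,
            }))

    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    subj = pd.DataFrame(subj_rows).sort_values("subject_id").reset_index(drop=True)

    report = metrics.EvalReport(
        sas_detection=metrics.classification_metrics(y_true, y_pred),
        ahi_regression=metrics.regression_metrics(
            subj["ahi_true"].to_numpy(), subj["ahi_hat"].to_numpy()),
        severity=metrics.classification_metrics(
            ahi_branch.severity_codes(subj["ahi_true"]),
            ahi_branch.severity_codes(subj["ahi_hat"])),
        binary={
            cut: metrics.classification_metrics(
                (subj["ahi_true"].to_numpy() >= cut).astype(int),
                (subj["ahi_hat"].to_numpy() >= cut).astype(int))
            for cut in (5, 15, 30)
        },
        n_subjects=ns,
        n_samples=int(len(y_true)),
    )
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "config": asdict(config)}
    return PipelineResult(report=report, subjects=subj, corrections=corrections,
                          manifest=manifest,
                          sample_predictions=pd.concat(sample_rows, ignore_index=True))


def ablation_mode(
    recordings: list[Recording], config: RunConfig | None = None
) -> tuple[PipelineResult, PipelineResult]:
    """Paired full / ablated runs on the same cohort and seeds."""
    config = config or RunConfig()
    full = run_pipeline(recordings, replace(config, use_global=True))
    ablated = run_pipeline(recordings, replace(config, use_global=False))
    return full, ablated


def window_sweep(
    recordings: list[Recording],
    windows: tuple[int, ...] = (10, 30, 60, 120),
    config: RunConfig | None = None,
    labels_only: bool = False,
) -> pd.DataFrame:
    """Positive-sample fraction (and optionally full reports) per window length."""
    config = config or RunConfig()
    rows = []
    for w in windows:
        cfg = replace(config, window_s=int(w))
        subs = prepare_subjects(recordings, replace(cfg, use_global=False))
        labels = np.concatenate([s.y for s in subs]) if subs else np.empty(0)
        row = {"window_s": w, "positive_fraction": float(labels.mean())
               if len(labels) else 0.0, "n_samples": int(len(labels))}
        if not labels_only:
            row.update(run_pipeline(recordings, cfg).report.flat())
        rows.append(row)
    return pd.DataFrame(rows)
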