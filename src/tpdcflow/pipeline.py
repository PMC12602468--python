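"""End-to-end orchestration: simulate -> estimate -> threshold -> group ->
classify -> correlate, driven by one YAML config.

Every stage writes its outputs as files under the run directory (series and
matrices as TSV, reports as JSON) so intermediates are inspectable and a run
can be resumed from any stage. A manifest records the config hash and the
per-stage seeds; rerunning the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clinical import adjust_family, correlate
from .datatypes import DEFAULT_BAND, YEO7_CHANNELS, MatrixRecord
from .io import load_matrix, load_report, load_timeseries, save_matrix, save_report
from .significance import binarize, bootstrap_threshold, group_significance
from .staging import build_features, train_eval
from .synthetic import ClinicalModel, CohortSpec, make_template, simulate_cohort, write_cohort
from .tpdc import EKFConfig, estimate_tpdc

STAGES = ("simulate", "estimate", "threshold", "group", "classify", "correlate")

logger = logging.getLogger("tpdcflow")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def validate_config(cfg: dict) -> dict:
    """Check required keys and fill documented defaults; no compute happens here."""
    if "tr" not in cfg:
        raise ConfigError("config missing required key 'tr' (repetition time, s)")
    if cfg["tr"] <= 0:
        raise ConfigError(f"tr must be positive, got {cfg['tr']}")
    if "seed" not in cfg:
        raise ConfigError("config missing required key 'seed'")
    if "simulate" not in cfg and "input_dir" not in cfg:
        raise ConfigError("config needs either a 'simulate' block or 'input_dir'")
    out = dict(cfg)
    out.setdefault("band", list(DEFAULT_BAND))
    out.setdefault("order", 1)
    out.setdefault("ekf", {})
    out.setdefault("bootstrap", {})
    out.setdefault("group", {})
    b = out["band"]
    if not (isinstance(b, (list, tuple)) and len(b) == 2 and 0 < b[0] < b[1]):
        raise ConfigError(f"invalid band {b}")
    if out["order"] < 1:
        raise ConfigError("order must be >= 1")
    return out


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _ekf_config(cfg: dict) -> EKFConfig:
    return EKFConfig(**cfg.get("ekf", {}))


def _build_cohort_spec(cfg: dict) -> CohortSpec:
    sim = cfg["simulate"]
    groups = []
    for g in sim["groups"]:
        tmpl = make_template(
            g["template"],
            base_coupling=g.get("coupling", sim.get("coupling", 0.3)),
            self_coupling=g.get("self_coupling", sim.get("self_coupling", 0.5)),
            edges=tuple(tuple(e) for e in g["edges"]) if "edges" in g else None,
        )
        groups.append((tmpl, int(g["n_subjects"])))
    clinical = [
        ClinicalModel(
            edge=tuple(c["edge"]),
            score_name=c["score"],
            slope=float(c.get("slope", 1.0)),
            noise_sd=float(c.get("noise_sd", 0.0)),
        )
        for c in sim.get("clinical", [])
    ]
    return CohortSpec(
        groups=groups,
        n_times=int(sim.get("n_times", 400)),
        tr=float(cfg["tr"]),
        coupling_jitter_sd=float(sim.get("coupling_jitter_sd", 0.0)),
        innovation_sd=float(sim.get("innovation_sd", 1.0)),
        observation_noise_sd=float(sim.get("observation_noise_sd", 0.0)),
        clinical_models=clinical,
        seed=int(cfg["seed"]),
    )


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    resume_from: str | None = None,
) -> Path:
    """Execute the full analysis described by ``config``; return the run dir.

    Stage outputs are files; ``resume_from`` skips earlier stages and loads
    their outputs from the run directory instead of recomputing them.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    if resume_from is not None and resume_from not in STAGES:
        raise ConfigError(f"unknown resume stage {resume_from!r}; stages: {STAGES}")
    start_at = STAGES.index(resume_from) if resume_from else 0

    out = Path(out_dir or cfg.get("out_dir", "tpdcflow_run"))
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    root_seq = np.random.SeedSequence(int(cfg["seed"]))
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, root_seq.spawn(len(STAGES)))
    }
    t_start = time.time()
    try:
        logger.info("run start: config hash %s", config_hash(cfg))

        # ---- simulate (or point at provided inputs)
        series_dir = out / "series"
        if "simulate" in cfg:
            if start_at <= STAGES.index("simulate") or not series_dir.exists():
                spec = _build_cohort_spec(cfg)
                cohort = simulate_cohort(spec)
                write_cohort(cohort, series_dir)
                logger.info("simulate: %d subjects -> %s", len(cohort.subjects), series_dir)
        else:
            series_dir = Path(cfg["input_dir"])
            if not series_dir.exists():
                raise ConfigError(f"input_dir {series_dir} does not exist")

        subjects = _load_subjects(series_dir, float(cfg["tr"]))
        if not subjects:
            raise ConfigError(f"no subject series found under {series_dir}")

        band = tuple(cfg["band"])
        order = int(cfg["order"])
        ekf = _ekf_config(cfg)

        # ---- estimate + threshold (bootstrap recomputes TPDC per surrogate,
        # so the two stages share one batched pass per subject)
        tpdc_dir = out / "tpdc"
        bin_dir = out / "binary"
        boot = cfg["bootstrap"]
        if start_at <= STAGES.index("threshold") or not bin_dir.exists():
            tpdc_dir.mkdir(exist_ok=True)
            bin_dir.mkdir(exist_ok=True)
            sub_seqs = np.random.SeedSequence(stage_seeds["threshold"]).spawn(
                len(subjects)
            )
            for (sid, group, ts), seq in zip(subjects, sub_seqs):
                observed, null = bootstrap_threshold(
                    ts,
                    n_shuffles=int(boot.get("n_shuffles", 100)),
                    percentile=float(boot.get("percentile", 99.0)),
                    window_len=int(boot.get("window_len", 10)),
                    seed=np.random.default_rng(seq),
                    order=order,
                    band=band,
                    cfg=ekf,
                )
                save_matrix(observed.to_record(), tpdc_dir / f"{sid}.tsv")
                save_matrix(binarize(observed, null), bin_dir / f"{sid}.tsv")
            logger.info("estimate+threshold: %d subjects", len(subjects))

        # ---- group-level permutation inference, one matrix per group
        group_cfg = cfg["group"]
        group_dir = out / "group"
        if start_at <= STAGES.index("group") or not group_dir.exists():
            group_dir.mkdir(exist_ok=True)
            by_group: dict[str, list[MatrixRecord]] = {}
            for sid, group, _ in subjects:
                by_group.setdefault(group or "all", []).append(
                    load_matrix(bin_dir / f"{sid}.tsv")
                )
            rng = np.random.default_rng(stage_seeds["group"])
            summary = {}
            for gname, recs in sorted(by_group.items()):
                if len(recs) < 2:
                    logger.info("group %s: <2 subjects, skipped", gname)
                    continue
                gn = group_significance(
                    recs,
                    n_perm=int(group_cfg.get("n_perm", 1000)),
                    percentile=float(group_cfg.get("percentile", 99.0)),
                    seed=rng,
                )
                save_matrix(
                    MatrixRecord(
                        subject_id=gname,
                        values=gn.significant,
                        kind="binary",
                        channels=gn.channels,
                    ),
                    group_dir / f"{gname}_significant.tsv",
                )
                save_matrix(
                    MatrixRecord(
                        subject_id=gname,
                        values=gn.observed_frequency,
                        kind="frequency",
                        channels=gn.channels,
                    ),
                    group_dir / f"{gname}_frequency.tsv",
                )
                summary[gname] = {
                    "n_subjects": gn.n_subjects,
                    "n_significant_edges": int(gn.significant.sum()),
                    "threshold_max": float(gn.threshold.max()),
                }
            save_report(
                {"n_perm": int(group_cfg.get("n_perm", 1000)), "groups": summary},
                group_dir / "null_summary.json",
            )
            logger.info("group: %d groups", len(summary))

        # ---- classification between two designated groups
        if "classify" in cfg:
            cls = cfg["classify"]
            pair = cls.get("groups")
            mode = cls.get("mode", "tpdc")
            src_dir = tpdc_dir if mode == "tpdc" else bin_dir
            mats, labels = [], []
            for sid, group, _ in subjects:
                if pair and group not in pair:
                    continue
                mats.append(load_matrix(src_dir / f"{sid}.tsv"))
                labels.append(group)
            table = build_features(mats, labels, mode=mode)
            report = train_eval(
                table,
                n_trees=int(cls.get("n_trees", 100)),
                test_fraction=float(cls.get("test_fraction", 0.30)),
                seed=stage_seeds["classify"],
                cv_folds=int(cls.get("cv_folds", 10)) or None,
                positive_class=cls.get("positive_class"),
            )
            save_report(report.to_dict(), out / "classifier_report.json")
            logger.info(
                "classify: accuracy %.3f cv %.3f", report.accuracy, report.cv_mean or -1
            )

        # ---- clinical correlations
        if "correlate" in cfg:
            cor = cfg["correlate"]
            scores = _load_scores(series_dir)
            results = []
            for conn in cor.get("connections", []):
                src, tgt = conn
                for score_name in cor.get("scores", []):
                    vals, svals = [], []
                    for sid, group, ts in subjects:
                        if sid not in scores or score_name not in scores[sid]:
                            continue
                        rec = load_matrix(tpdc_dir / f"{sid}.tsv")
                        i = rec.channels.index(tgt)
                        j = rec.channels.index(src)
                        vals.append(rec.values[i, j])
                        svals.append(scores[sid][score_name])
                    if len(vals) >= 5:
                        results.append(
                            correlate(
                                np.asarray(vals),
                                np.asarray(svals),
                                method=cor.get("method", "auto"),
                                score_name=score_name,
                                connection=(src, tgt),
                            )
                        )
            if results:
                adjust_family(results)
            save_report(
                {
                    "results": [
                        {
                            "connection": list(r.connection),
                            "score": r.score_name,
                            "method": r.method,
                            "r": r.r,
                            "p": r.p,
                            "p_adjusted": r.p_adjusted,
                            "n": r.n,
                        }
                        for r in results
                    ]
                },
                out / "correlations.json",
            )
            logger.info("correlate: %d tests", len(results))

        manifest = {
            "config": cfg,
            "config_hash": config_hash(cfg),
            "stage_seeds": stage_seeds,
            "version": __version__,
            "elapsed_s": round(time.time() - t_start, 2),
        }
        save_report(manifest, out / "manifest.json")
        logger.info("run complete in %.1fs", time.time() - t_start)
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _load_subjects(series_dir: Path, tr: float):
    """Load all subject TSVs (with optional sidecar JSON group labels)."""
    subjects = []
    for path in sorted(series_dir.glob("*.tsv")):
        sid = path.stem
        group = None
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = load_report(sidecar)
            group = meta.get("group")
            tr = float(meta.get("tr", tr))
        subjects.append((sid, group, load_timeseries(path, tr, subject_id=sid, group=group)))
    return subjects


def _load_scores(series_dir: Path) -> dict[str, dict[str, float]]:
    scores = {}
    for path in sorted(Path(series_dir).glob("*.json")):
        meta = load_report(path)
        if "clinical_scores" in meta:
            scores[path.stem] = meta["clinical_scores"]
    return scores
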