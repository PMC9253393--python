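"""End-to-end pipeline: simulate -> screen -> train -> attribute -> dose-volume -> match.

Every stage reads and writes files under one output directory, so stages
can be re-run independently; numeric outputs are deterministic given the
seed. Each CSV artifact begins with a stamped comment line
(``# radlymph seed=<seed> config=<hash>``); read them with
``pandas.read_csv(..., comment="#")``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from radlymph import attribution as attr
from radlymph import dosevol, matching, modeling, synthetic, univariate
from radlymph.preprocess import DEFAULT_LLN, ModelMatrix, encode

logger = logging.getLogger(__name__)

#: Dose metrics probed in the matched-pair validation: the ones whose tree
#: attributions disagree with univariate screening or are dropped by the
#: Lasso because stronger collinear dose metrics overshadow them.
DEFAULT_PROBES = ("mean_heart_dose", "max_heart_dose", "v20_ipsilateral_lung")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "radlymph_run"
    cohort_csv: str | None = None  # None -> simulate
    n_patients: int = 589
    n_validation: int = 203
    B: int = 100
    seed: int = 0
    grid_mode: str = "fast"  # fast | random | full
    n_candidates: int = 200
    n_estimators: int = 200
    threshold: float = 0.5
    lower_limit_normal: float = DEFAULT_LLN
    pairing_threshold: float = 0.10
    attribution_against: str = "feature"  # or "outcome" (see attribution module)
    missingness_rate: float = 0.03
    probes: tuple[str, ...] = DEFAULT_PROBES

    def config_hash(self) -> str:
        # output location does not change the science: hash everything else
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> str:
    return f"# radlymph seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, index=index, lineterminator="\n")


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"seed": cfg.seed, "config": cfg.config_hash(), "report": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns a bundle of the in-memory results.

    A missing dose catalog (possible only with an external cohort) skips
    the dose-volume stage with a notice; any stage exception aborts with
    the stage name while earlier artifacts stay on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"seed": cfg.seed, "config_hash": cfg.config_hash(), "config": asdict(cfg)},
            fh, indent=2, default=str,
        )
    bundle: dict = {}

    stage = "simulate"
    try:
        schema = synthetic.default_schema()
        if cfg.cohort_csv is None:
            gen = synthetic.default_config(
                n_patients=cfg.n_patients, seed=cfg.seed,
                missingness_rate=cfg.missingness_rate,
            )
            cohort, catalog, truth = synthetic.generate_cohort(gen)
            val_gen = synthetic.default_config(
                n_patients=cfg.n_validation, seed=cfg.seed + 1,
                missingness_rate=cfg.missingness_rate,
            )
            validation, _, _ = synthetic.generate_cohort(val_gen)
            _write_csv(cohort, out / "cohort.csv", cfg, index=True)
            _write_csv(validation, out / "validation_cohort.csv", cfg, index=True)
            _write_csv(catalog.table, out / "dose_catalog.csv", cfg)
            _write_csv(catalog.dvh_samples, out / "dvh_samples.csv", cfg)
            truth.to_json(out / "ground_truth.json")
        else:
            cohort = synthetic.read_cohort_csv(cfg.cohort_csv)
            validation, catalog, truth = None, None, None
        schema.to_yaml(out / "schema.yaml")
        bundle.update(cohort=cohort, validation=validation, catalog=catalog, truth=truth)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "screen"
    try:
        screen = univariate.screen_cohort(cohort, schema)
        _write_csv(screen, out / "univariate_screen.csv", cfg)
        bundle["screen"] = screen
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "train"
    try:
        matrix = encode(cohort, schema)
        val_matrix = encode(validation, schema) if validation is not None else None
        iterations = modeling.run_bootstrap(
            matrix, B=cfg.B, seed=cfg.seed, validation=val_matrix,
            mode=cfg.grid_mode, n_candidates=cfg.n_candidates,
            n_estimators=cfg.n_estimators, threshold=cfg.threshold,
        )
        per_iter = modeling.metrics_frame(iterations)
        summary = modeling.summarize_metrics(per_iter)
        _write_csv(per_iter, out / "metrics_iterations.csv", cfg)
        _write_csv(summary, out / "metrics_summary.csv", cfg)
        bundle.update(matrix=matrix, val_matrix=val_matrix,
                      iterations=iterations, metrics_summary=summary)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "attribute"
    try:
        mats, outcomes, feats = [], [], []
        for it in iterations:
            Xte = matrix.X.iloc[it.plan.test]
            mats.append(attr.per_instance_attributions(it.model, Xte))
            outcomes.append(matrix.y.to_numpy()[it.plan.test])
            feats.append(Xte)
        gain = pd.concat([it.gain for it in iterations], axis=1).mean(axis=1)
        freq = pd.concat([it.frequency for it in iterations], axis=1).mean(axis=1)
        lasso_fits = [it.lasso for it in iterations if it.lasso is not None]
        lasso_coef = lasso_p = None
        if lasso_fits:
            lasso_coef = pd.concat(
                [f.coef for f in lasso_fits], axis=1
            ).reindex(matrix.columns).fillna(0.0).mean(axis=1)
            lasso_p = pd.concat(
                [f.p_values for f in lasso_fits], axis=1
            ).reindex(matrix.columns).median(axis=1)
        summary_table = attr.summarize_attributions(
            mats, outcomes, gain=gain, frequency=freq,
            lasso_coef=lasso_coef, lasso_p=lasso_p,
            against=cfg.attribution_against,
            feature_values=feats,
        )
        _write_csv(summary_table, out / "attribution_summary.csv", cfg, index=True)
        groups = {c: schema.column_group(c) for c in matrix.columns}
        attr.export_attribution_graph(
            summary_table, groups, out / "attribution_graph.graphml"
        )
        bundle["attribution"] = summary_table
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "dosevol"
    if catalog is None:
        logger.warning("no dose catalog available; skipping dose-volume stage")
        bundle["dose_volume"] = None
    else:
        try:
            importance = summary_table["mean_abs_shap"]
            report = dosevol.dose_volume_report(
                catalog.table, importance, dvh_samples=catalog.dvh_samples
            )
            pts = dosevol.attribution_points(
                catalog.table, importance, summary_table["direction"]
            )
            _write_csv(pts, out / "dose_volume_points.csv", cfg)
            _write_json(report, out / "dose_volume_report.json", cfg)
            bundle["dose_volume"] = report
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "match"
    try:
        reports = {}
        pair_frames = []
        for probe in cfg.probes:
            if probe not in summary_table.index:
                logger.warning("probe %r not in attribution summary; skipped", probe)
                continue
            paired = matching.select_pairs(
                matrix.X, matrix.y, probe, summary_table["mean_abs_shap"],
                threshold=cfg.pairing_threshold,
            )
            if len(paired) >= 2:
                test = matching.paired_test(paired, cohort[probe])
                reports[probe] = {
                    "n_pairs": test.n_pairs,
                    "t_statistic": test.t_statistic,
                    "p_value": test.p_value,
                    "mean_with_lymphopenia": test.mean_event,
                    "mean_without_lymphopenia": test.mean_no_event,
                    "degenerate": test.degenerate,
                }
            else:
                reports[probe] = {"n_pairs": len(paired), "p_value": None}
            frame = paired.to_frame()
            frame.insert(0, "probe", probe)
            pair_frames.append(frame)
        if pair_frames:
            _write_csv(pd.concat(pair_frames, ignore_index=True),
                       out / "matched_pairs.csv", cfg)
        _write_json(reports, out / "pairing_report.json", cfg)
        bundle["pairing"] = reports
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return bundle
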