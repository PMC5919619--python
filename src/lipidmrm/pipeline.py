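"""Config-driven end-to-end orchestration of the MRM-profiling workflow.

One YAML (or dict) config drives simulate -> ingest -> attribute -> stats ->
ROC -> quantify.  Every randomized stage receives a logged sub-seed derived
from the master seed, so re-running a config byte-reproduces the numeric
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import attribution, biomarker_roc, ingest, quantify, stats_profiles, synthetic_data
from .reference import CERAMIDE_PANEL
from .scan_library import read_method, synthetic_screening_methods, write_method

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("lipidmrm")


@dataclass
class RunConfig:
    """Validated pipeline configuration with derived per-stage sub-seeds."""

    output_dir: str = "lipidmrm_run"
    seed: int = 0
    method_files: Optional[list] = None  # TSV paths; None -> synthetic methods
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    tolerance: float = attribution.DEFAULT_TOLERANCE
    alpha: float = 0.05
    p_max: float = 0.05
    min_fold: float = 2.0
    panel: list = field(default_factory=lambda: list(CERAMIDE_PANEL))
    algorithm: str = "plsda"
    run_quant: bool = True

    def subseed(self, stage: str) -> int:
        import zlib

        rng = np.random.default_rng([self.seed, zlib.crc32(stage.encode()) % 2**31])
        sub = int(rng.integers(0, 2**31 - 1))
        logger.info("stage %s sub-seed %d", stage, sub)
        return sub


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid pipeline config {path}: {exc}") from exc


def _stage(name):
    """Re-raise stage errors with the failing stage named."""

    class _ctx:
        def __enter__(self):
            logger.info("stage %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name}: {exc}") from exc
            return False

    return _ctx()


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow, writing a report bundle to the output dir.

    Emits matrix_<polarity>.csv, attributions.tsv, stats.tsv, volcano.tsv,
    profiles.csv, roc.json, quant.tsv, qpcr.tsv and run.log; returns the
    in-memory bundle.  Stage errors propagate as :class:`StageError`
    naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    bundle = {}
    try:
        with _stage("scan_library"):
            if config.method_files:
                methods = [read_method(p) for p in config.method_files]
            else:
                methods = list(synthetic_screening_methods())
            for m in methods:
                write_method(m, out / f"method_{'pos' if m.polarity == '+' else 'neg'}.tsv")

        matrices = {}
        with _stage("synthetic_data+ingest"):
            for m in methods:
                cohort_cfg = synthetic_data.CohortConfig(
                    seed=config.subseed(f"cohort{m.polarity}"), **config.cohort
                )
                table = synthetic_data.generate_cohort(cohort_cfg, m)
                profiles = ingest.profiles_from_table(table, m)
                matrix = ingest.assemble_matrix(profiles)
                matrices[m.polarity] = matrix
                tag = "pos" if m.polarity == "+" else "neg"
                matrix.X.to_csv(out / f"matrix_{tag}.csv")

        with _stage("attribution"):
            attr_rows = []
            attributions = {}
            for m in methods:
                result = attribution.attribute_method(m, tolerance=config.tolerance)
                attributions.update(result)
                for trans_id, res in result.items():
                    attr_rows.append(
                        {
                            "transition": trans_id,
                            "polarity": m.polarity,
                            "class_call": res.class_call,
                            "status": res.status,
                            "top_candidate": res.top.name if res.top else "",
                            "mass_error": res.top.mass_error if res.top else np.nan,
                            "co_candidates": "|".join(c.name for c in res.candidates[1:4]),
                        }
                    )
            pd.DataFrame(attr_rows).to_csv(out / "attributions.tsv", sep="\t", index=False)

        with _stage("stats_profiles"):
            stat_rows, volcano_rows = [], []
            for pol, matrix in matrices.items():
                stats_list = stats_profiles.holm_sidak_ttests(matrix, alpha=config.alpha)
                selected = {
                    s.transition
                    for s in stats_profiles.volcano_select(stats_list, config.p_max, config.min_fold)
                }
                for s in stats_list:
                    stat_rows.append({**asdict(s), "polarity": pol, "volcano": s.transition in selected})
                relevant = {t: r for t, r in attributions.items() if t in matrix.X.columns}
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")  # schemes absent from this polarity
                    profiles_out = stats_profiles.aggregate_profiles(matrix, relevant)
                for agg in profiles_out:
                    t = agg.table.copy()
                    t.insert(0, "scheme", agg.scheme)
                    volcano_rows.append(t)
            pd.DataFrame(stat_rows).to_csv(out / "stats.tsv", sep="\t", index=False)
            if volcano_rows:
                pd.concat(volcano_rows, ignore_index=True).to_csv(out / "profiles.csv", index=False)

        with _stage("biomarker_roc"):
            matrix = matrices.get("+", next(iter(matrices.values())))
            model, cv_auc, cv_acc = biomarker_roc.fit_panel(
                matrix,
                config.panel,
                algorithm=config.algorithm,
                cv=biomarker_roc.CvConfig(seed=config.subseed("roc")),
            )
            roc_report = {
                "panel": config.panel,
                "algorithm": config.algorithm,
                "cv_auc": cv_auc,
                "cv_accuracy": cv_acc,
            }
            if (matrix.splits == "validation").any():
                pred = biomarker_roc.predict_validation(model, matrix)
                roc_report.update(
                    {
                        "validation_accuracy": pred.accuracy,
                        "validation_auc": pred.auc,
                        "probabilities": {k: float(v) for k, v in pred.probabilities.items()},
                    }
                )
            else:
                logger.info("validation split empty; blind prediction skipped")
            (out / "roc.json").write_text(json.dumps(roc_report, indent=2))
            bundle["roc"] = roc_report

        if config.run_quant:
            with _stage("quantify"):
                quant, qpcr = synthetic_data.generate_quant_and_qpcr(
                    seed=config.subseed("quant")
                )
                quantified = quantify.quantify_table(
                    quant.rename(columns={"sample": "sample", "analyte": "analyte"})
                )
                quantified.to_csv(out / "quant.tsv", sep="\t", index=False)
                records = quantify.ddct_fold_change(qpcr)
                pd.DataFrame([asdict(r) for r in records]).to_csv(
                    out / "qpcr.tsv", sep="\t", index=False
                )
        bundle["output_dir"] = str(out)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
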