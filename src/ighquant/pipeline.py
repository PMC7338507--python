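"""End-to-end orchestration: quantify many alignment files into an Ig
expression matrix, then run the cohort statistics and survival batteries and
write a TSV + JSON report bundle.

Per-sample quantification failures are isolated and reported rather than
aborting the batch; a batch where every sample fails is an error.  All
outputs embed the seed and a config hash in a header comment, and rerunning
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import stats as cstats
from . import survival as surv
from .locus import LocusModel
from .quantify import quantify_sample

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_VALIDATION, EXIT_IO, EXIT_FIT = 0, 1, 2, 3


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Parameters of a full run; see the CLI for the file-level interface."""

    seed: int = 0
    mapq_min: int = 10
    top_k: int = 100
    enrichment_p_threshold: float = 1e-15
    ig_vars: tuple[str, ...] = ("IGHM", "IGHA2", "IGJ", "IGHG1")
    batteries: tuple[str, ...] = ("model1", "model2", "strata_single", "subgroups")
    metagene_cols: tuple[str, ...] = ()
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
        return cls(**payload)

    def hash(self) -> str:
        # out_dir is a destination, not an analysis parameter
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_quantify_batch(
    bam_paths: Sequence[str | Path],
    model: LocusModel,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Quantify each alignment file; returns (samples × classes matrix, failures).

    Sample identifiers are the file stems.  A file that cannot be read or
    quantified contributes a row to the failure map instead of the matrix.
    """
    config = config or RunConfig()
    if not bam_paths:
        raise PipelineError("no alignment files given")
    rows: dict[str, dict[str, float]] = {}
    failures: dict[str, str] = {}
    for path in bam_paths:
        sample = Path(path).stem
        try:
            result = quantify_sample(path, model, mapq_min=config.mapq_min)
            rows[sample] = {cls: expr.value for cls, expr in result.items()}
        except Exception as exc:
            logger.error("sample %s failed: %s", sample, exc)
            failures[sample] = str(exc)
    if not rows:
        raise PipelineError(f"all {len(bam_paths)} samples failed quantification")
    matrix = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    matrix.index.name = "sample"
    return matrix, failures


def _tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def run_full_analysis(
    cohort: pd.DataFrame,
    expr: pd.DataFrame,
    gene_sets: cstats.GeneSetCollection | None,
    config: RunConfig,
    metagenes: Sequence[cstats.MetageneDefinition] = (),
) -> dict:
    """Run correlations, metagenes, enrichment, KM and Cox batteries.

    ``cohort`` carries clinical columns plus the Ig expression columns;
    ``expr`` is the whole-transcriptome matrix used for correlation ranking
    and enrichment.  Writes TSVs plus a machine-readable JSON summary into
    ``config.out_dir`` and returns the summary dict.
    """
    missing = [s for s in cohort.index if s not in expr.index]
    if missing:
        raise PipelineError(
            f"{len(missing)} cohort samples absent from expression matrix, "
            f"e.g. {missing[:5]}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"ighquant seed={config.seed} config={config.hash()}"
    summary: dict = {"seed": config.seed, "config_hash": config.hash()}

    ig_present = [g for g in config.ig_vars if g in cohort.columns]
    if not ig_present:
        raise PipelineError("none of the configured Ig variables is in the cohort")

    corr = cstats.correlation_matrix(cohort[ig_present])
    _tsv(corr, out / "ig_correlation.tsv", stamp)
    summary["ig_correlation_mean_offdiag"] = float(
        (corr.to_numpy().sum() - len(corr)) / (corr.size - len(corr)))

    scores = {}
    for mg in metagenes:
        scores[mg.name] = cstats.metagene_score(expr.loc[cohort.index], mg)
    if scores:
        score_df = pd.DataFrame(scores)
        _tsv(score_df, out / "metagene_scores.tsv", stamp)
        summary["metagenes"] = sorted(scores)

    if gene_sets is not None:
        enr_summary = {}
        target = ig_present[0]
        joint = expr.loc[cohort.index].copy()
        joint[target] = cohort.loc[joint.index, target]
        hits = cstats.top_correlated_genes(joint, target, k=config.top_k)
        enr = cstats.enrichment_fisher(hits, gene_sets)
        _tsv(enr, out / f"enrichment_{target}.tsv", stamp)
        enr_summary[target] = {
            "top_set": enr.index[0],
            "top_p": float(enr["p"].iloc[0]),
            "n_below_threshold": int((enr["p"] < config.enrichment_p_threshold).sum()),
        }
        summary["enrichment"] = enr_summary

    km_summary = {}
    for ig in ig_present:
        labels = surv.dichotomize_median(cohort[ig])
        km = surv.km_logrank(cohort["os_time"], cohort["os_event"], labels)
        km_summary[ig] = {"logrank_stat": km.statistic, "logrank_p": km.p_value}
        for grp, curve in km.groups.items():
            _tsv(curve, out / f"km_{ig}_{grp}.tsv", stamp)
    summary["km_os"] = km_summary

    battery_frames = []
    cohort_with_scores = cohort.join(pd.DataFrame(scores)) if scores else cohort
    for battery in config.batteries:
        mg_cols = config.metagene_cols or tuple(scores)
        results = surv.run_model_battery(
            cohort_with_scores, ig_present, battery,
            metagene_cols=mg_cols if battery == "metagene_adjusted" else (),
        )
        frame = surv.battery_table(results)
        frame.insert(0, "battery", battery)
        battery_frames.append(frame)
    cox = pd.concat(battery_frames, ignore_index=True)
    _tsv(cox.set_index("battery"), out / "cox_batteries.tsv", stamp)
    summary["cox_models"] = int(cox["model"].nunique())
    summary["cox_rows"] = int(len(cox))

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
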