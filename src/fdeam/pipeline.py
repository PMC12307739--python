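"""End-to-end orchestration: classify HR causes, compute biomarkers,
evaluate, and run the purity experiment.

``run_pipeline`` consumes a cohort directory (the file set written by
:func:`fdeam.synthetic_cohort.write_fixture_files`, or equivalent real
data exports) and writes:

* ``classification.tsv`` — per-sample cause-of-HRD class and benchmark label;
* ``biomarkers.tsv`` — per-sample TMB, f_deam, LOH/LST/TAI/HRDsum;
* ``evaluation.json`` — AUCs, paired DeLong p, optimal and fixed-cutpoint
  operating points, Spearman correlations, Cohen's kappa between the two
  binary HRD calls, and the cohort accounting (NA and excluded samples);
* ``differential_channels.tsv`` — the 96-channel group comparison;
* ``purity_experiment.tsv`` — biomarker performance across purity levels.

Identical config + seed give byte-identical outputs.  The log records the
defaults in effect and the exclusion ledger (NA f_deam samples, excluded
H classes) so cohort accounting is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker_eval as be
from . import catalog96, hr_class, purity_sim, scar_scores
from .catalog96 import ValidationError
from .synthetic_cohort import SyntheticCohort, SyntheticSample

logger = logging.getLogger("fdeam")


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    fdeam_cutpoint: float = 13.1     # percent; HRD-positive iff f_deam < cutpoint
    hrdsum_cutpoint: float = 42.0    # HRD-positive iff HRDsum >= cutpoint
    min_tmb: int = catalog96.DEFAULT_MIN_TMB
    purities: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2, 0.1, 0.05)
    purity_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fdeam_cutpoint) and math.isfinite(self.hrdsum_cutpoint)):
            raise ValidationError("cutpoints must be finite")
        if any(not (0 < p <= 1) for p in self.purities):
            raise ValidationError("purity levels must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


INPUT_FILES = (
    "mutations.tsv",
    "segments.tsv",
    "labels.tsv",
    "annotation.tsv",
    "alterations.tsv",
    "methylation.tsv",
)


def _check_inputs(input_dir: Path) -> None:
    absent = [f for f in INPUT_FILES if not (input_dir / f).exists()]
    if absent:
        raise FileNotFoundError(
            f"missing input files in {input_dir}: {', '.join(absent)}"
        )


def _binary_calls(scores, cutpoint, direction):
    s = np.asarray(scores, dtype=float)
    if direction == "lower_predicts_positive":
        return np.where(np.isnan(s), 0, (s < cutpoint)).astype(int)
    return np.where(np.isnan(s), 0, (s >= cutpoint)).astype(int)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on a cohort directory; returns the report dict."""
    input_dir = Path(config.input_dir)
    output_dir = Path(config.output_dir)
    _check_inputs(input_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run config: fdeam_cutpoint=%.4g (positive iff <), hrdsum_cutpoint=%.4g "
        "(positive iff >=), min_tmb=%d, seed=%d",
        config.fdeam_cutpoint, config.hrdsum_cutpoint, config.min_tmb, config.seed,
    )

    # --- classify HR causes → benchmark labels
    alterations = hr_class.read_alterations(input_dir / "alterations.tsv")
    methylation = hr_class.read_methylation(input_dir / "methylation.tsv")
    sample_info = pd.read_csv(input_dir / "labels.tsv", sep="\t", dtype={"sample": str})
    classifications = hr_class.classify_cohort(
        alterations, methylation, all_samples=sample_info["sample"]
    )
    labels_df = hr_class.build_benchmark_labels(classifications)
    class_df = hr_class.classifications_to_frame(classifications).merge(
        labels_df, on="sample"
    )
    class_df.to_csv(output_dir / "classification.tsv", sep="\t", index=False)
    n_excluded = int((labels_df["label"] == "excluded").sum())
    if n_excluded:
        logger.info("excluded %d samples outside the H1a*/H3 benchmark", n_excluded)

    # --- biomarkers
    mutations = catalog96.read_maf(input_dir / "mutations.tsv")
    catalogs = catalog96.build_catalogs(mutations)
    segments = scar_scores.read_segments(input_dir / "segments.tsv")
    annotation = scar_scores.read_annotation(input_dir / "annotation.tsv")
    scars = scar_scores.scores_by_sample(segments, annotation)

    biomarkers = (
        catalog96.catalogs_to_frame(catalogs, min_tmb=config.min_tmb)
        [["sample", "TMB", "f_deam"]]
        .merge(scars, on="sample", how="outer")
        .merge(labels_df[["sample", "label"]], on="sample", how="left")
    )
    biomarkers.to_csv(output_dir / "biomarkers.tsv", sep="\t", index=False)

    bench = biomarkers[biomarkers["label"].isin(["positive", "negative"])].reset_index(drop=True)
    if bench.empty or bench["label"].nunique() < 2:
        raise ValidationError(
            "benchmark needs both H1a* (positive) and H3 (negative) samples"
        )
    y = bench["label"].tolist()
    fdeam = bench["f_deam"].to_numpy(dtype=float)
    hrdsum = bench["hrdsum"].to_numpy(dtype=float)
    tmb = bench["TMB"].to_numpy(dtype=float)
    n_na = int(np.isnan(fdeam).sum())
    logger.info("exclusion ledger: %d NA f_deam samples (TMB < %d)", n_na, config.min_tmb)

    # --- evaluation
    roc_f = be.roc_auc(fdeam, y, "lower_predicts_positive")
    roc_h = be.roc_auc(hrdsum, y, "higher_predicts_positive")
    auc_f, auc_h, delong_p = be.delong_paired(
        fdeam, hrdsum, y, "lower_predicts_positive", "higher_predicts_positive"
    )
    opt_f = be.optimize_cutpoint(fdeam, y, "lower_predicts_positive")
    opt_h = be.optimize_cutpoint(hrdsum, y, "higher_predicts_positive")
    fix_f = be.evaluate_at_cutpoint(fdeam, y, config.fdeam_cutpoint, "lower_predicts_positive")
    fix_h = be.evaluate_at_cutpoint(hrdsum, y, config.hrdsum_cutpoint, "higher_predicts_positive")
    calls_f = _binary_calls(fdeam, config.fdeam_cutpoint, "lower_predicts_positive")
    calls_h = _binary_calls(hrdsum, config.hrdsum_cutpoint, "higher_predicts_positive")
    kappa = be.cohens_kappa(calls_f, calls_h)
    r_fh, p_fh = be.spearman(fdeam, hrdsum)
    r_ft, p_ft = be.spearman(fdeam, tmb)
    r_ht, p_ht = be.spearman(hrdsum, tmb)

    pos_cats = [catalogs[s] for s, l in zip(bench["sample"], y) if l == "positive" and s in catalogs]
    neg_cats = [catalogs[s] for s, l in zip(bench["sample"], y) if l == "negative" and s in catalogs]
    diff = be.differential_channels(pos_cats, neg_cats)
    diff.to_csv(output_dir / "differential_channels.tsv", sep="\t", index=False)

    # --- purity experiment
    cohort = _cohort_from_inputs(bench, mutations, segments, sample_info, annotation)
    purity_df = purity_sim.run_purity_experiment(
        cohort,
        purities=[p for p in config.purities if p <= min(s.purity for s in cohort.samples)],
        fdeam_cutpoint=config.fdeam_cutpoint,
        hrdsum_cutpoint=config.hrdsum_cutpoint,
        reps=config.purity_reps,
        seed=config.seed,
        annotation=annotation,
        min_tmb=config.min_tmb,
    )
    purity_df.to_csv(output_dir / "purity_experiment.tsv", sep="\t", index=False)

    def _cp(c: be.CutpointResult) -> dict:
        return {
            "threshold": round(c.threshold, 6),
            "sensitivity": round(c.sensitivity, 6),
            "specificity": round(c.specificity, 6),
            "balanced_accuracy": round(c.balanced_accuracy, 6),
        }

    report = {
        "n_samples": int(len(biomarkers)),
        "n_benchmark_positive": int((bench["label"] == "positive").sum()),
        "n_benchmark_negative": int((bench["label"] == "negative").sum()),
        "n_excluded_classes": n_excluded,
        "n_na_fdeam": n_na,
        "auc": {"f_deam": round(auc_f, 6), "hrdsum": round(auc_h, 6)},
        "delong_p": round(delong_p, 6),
        "optimal_cutpoint": {"f_deam": _cp(opt_f), "hrdsum": _cp(opt_h)},
        "fixed_cutpoint": {"f_deam": _cp(fix_f), "hrdsum": _cp(fix_h)},
        "kappa_fdeam_vs_hrdsum": round(kappa, 6),
        "spearman": {
            "f_deam_vs_hrdsum": {"r": round(r_fh, 6), "p": round(p_fh, 6)},
            "f_deam_vs_tmb": {"r": round(r_ft, 6), "p": round(p_ft, 6)},
            "hrdsum_vs_tmb": {"r": round(r_ht, 6), "p": round(p_ht, 6)},
        },
        "n_significant_channels": int(diff["significant"].sum()),
        "config": {
            **dataclasses.asdict(config),
            "purities": list(config.purities),
        },
    }
    with open(output_dir / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _cohort_from_inputs(
    bench: pd.DataFrame,
    mutations: pd.DataFrame,
    segments: dict,
    sample_info: pd.DataFrame,
    annotation,
) -> SyntheticCohort:
    """Assemble the variant-level cohort view the purity experiment needs."""
    purity_by_sample = dict(zip(sample_info["sample"].astype(str), sample_info["purity"]))
    if "vaf" not in mutations.columns:
        raise ValidationError("purity experiment needs per-variant VAFs in mutations.tsv")
    per_sample = catalog96.records_from_frame(mutations)
    samples = []
    for row in bench.itertuples(index=False):
        sid = str(row.sample)
        recs = [r for r in per_sample.get(sid, []) if r.is_sbs]
        for r in recs:
            if r.vaf is None:
                raise ValidationError(f"record {r.chrom}:{r.pos} of {sid} lacks a VAF")
        idx = np.array(
            [catalog96.CHANNEL_INDEX[catalog96.classify_channel(r)] for r in recs],
            dtype=np.int64,
        )
        samples.append(
            SyntheticSample(
                sample_id=sid,
                label=str(row.label),
                purity=float(purity_by_sample.get(sid, 1.0)),
                channel_indices=idx,
                vafs=np.array([r.vaf for r in recs], dtype=float),
                chroms=np.array([r.chrom for r in recs]),
                positions=np.array([r.pos for r in recs], dtype=np.int64),
                segments=segments.get(sid, []),
            )
        )
    return SyntheticCohort(samples=samples, annotation=dict(annotation), config=None)
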