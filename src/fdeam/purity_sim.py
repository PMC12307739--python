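"""Variant-level simulation of tumor-purity dilution.

The purity experiment asks how robust the two HRD biomarkers are when the
sequenced tissue contains fewer tumor cells.  The read-mixing idea — a
tumor of source purity ``q`` diluted to target purity ``p`` by combining a
fraction ``p/q`` of tumor reads with ``1 - p/q`` of matched-normal reads —
is modeled exactly at the variant level:

* somatic variants: normal reads carry no somatic alternate allele, so the
  expected VAF scales by ``p/q``.  Each variant's observed depth is drawn
  from the sequencing model (Poisson by default), the alternate-read count
  is Binomial(depth, expected VAF), and the variant is *detected* when it
  clears the caller thresholds (min alternate reads, min VAF).  Detection
  depends only on VAF and depth, never on the mutation channel, so the
  expected f_deam of the surviving catalog is unchanged by dilution — only
  its sampling noise grows as the TMB shrinks.

* copy-number segments: at purity ``p`` a segment with allele copies
  (a, b) shows a major-allele fraction of (p*a + (1-p)) / (p*(a+b) + 2(1-p))
  — the tumor signal mixed with the diploid balanced normal.  Gaussian
  measurement noise with sd ~ 1/sqrt(depth) is added; a segment is re-called
  to the nearest integer allele state only when the observed fraction
  deviates from 1/2 beyond a calling threshold, otherwise it collapses to
  the balanced (1,1) state.  As purity drops the allelic imbalance shrinks
  toward 1/2 and scar events become invisible, which is why HRDsum degrades
  at low purity while f_deam does not.

``run_purity_experiment`` ties the two together: for each purity level it
dilutes every sample's catalog, attenuates its segments, recomputes f_deam
and HRDsum, and evaluates both biomarkers (AUC and balanced accuracy at the
fixed clinical cutpoints) against the HR-cause ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biomarker_eval import evaluate_at_cutpoint, roc_auc
from .catalog96 import (
    CHANNEL_INDEX,
    DEFAULT_MIN_TMB,
    MutationCatalog96,
    ValidationError,
)
from .scar_scores import (
    AlleleSegment,
    GenomeAnnotation,
    ScarConfig,
    compute_hrdsum,
)

logger = logging.getLogger("fdeam")


@dataclass(frozen=True)
class PuritySpec:
    """Source purity ``q`` and target purity ``p`` of a dilution."""

    q: float
    p: float

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValidationError(f"source purity q must be in (0, 1], got {self.q}")
        if not (0 <= self.p <= 1):
            raise ValidationError(f"target purity p must be in [0, 1], got {self.p}")
        if self.p > self.q:
            raise ValidationError(
                f"cannot concentrate a sample by mixing with normal (p={self.p} > q={self.q})"
            )


@dataclass
class SequencingModel:
    """Depth distribution and caller detection thresholds.

    Depth is Poisson(mean_depth) by default; a negative-binomial is used
    when ``depth_dispersion`` (the NB size parameter) is given.  A variant
    is detected when alt_count >= min_alt_reads and alt_count/depth >=
    min_vaf.  ``base_error_rate`` > 0 adds Binomial(depth, error/3)
    false alternate reads.
    """

    mean_depth: float = 100.0
    depth_dispersion: float | None = None
    min_alt_reads: int = 3
    min_vaf: float = 0.02
    base_error_rate: float = 0.0

    def draw_depth(self, rng: np.random.Generator, size: int | None = None):
        if self.depth_dispersion is None:
            return rng.poisson(self.mean_depth, size=size)
        k = self.depth_dispersion
        p = k / (k + self.mean_depth)
        return rng.negative_binomial(k, p, size=size)


@dataclass
class VariantObservation:
    expected_vaf: float
    depth: int
    alt_count: int
    detected: bool


def dilution_fraction(spec: PuritySpec) -> tuple[float, float]:
    """Fractions of tumor and normal reads in the simulated mixture."""
    t = spec.p / spec.q
    return t, 1.0 - t


def dilute_variant(
    true_vaf_at_q: float,
    spec: PuritySpec,
    model: SequencingModel,
    rng: np.random.Generator,
) -> VariantObservation:
    """Resample one variant's detection after dilution to purity p."""
    if not (0 <= true_vaf_at_q <= 1):
        raise ValidationError(f"VAF must be in [0, 1], got {true_vaf_at_q}")
    tumor_frac, _ = dilution_fraction(spec)
    expected_vaf = true_vaf_at_q * tumor_frac
    depth = int(model.draw_depth(rng))
    alt = int(rng.binomial(depth, expected_vaf)) if depth > 0 else 0
    if model.base_error_rate > 0 and depth > 0:
        alt = min(depth, alt + int(rng.binomial(depth, model.base_error_rate / 3)))
    detected = (
        depth > 0
        and alt >= model.min_alt_reads
        and alt / depth >= model.min_vaf
    )
    return VariantObservation(expected_vaf, depth, alt, detected)


def dilute_catalog(
    channels: Sequence[str] | Sequence[int],
    vafs: Sequence[float],
    spec: PuritySpec,
    model: SequencingModel,
    rng: np.random.Generator,
    sample_id: str = "",
) -> tuple[np.ndarray, MutationCatalog96]:
    """Thin a sample's variants by dilution and rebuild its catalog.

    ``channels`` are canonical channel labels (or indices) of the sample's
    SBS records, ``vafs`` the matching VAFs at source purity.  Returns the
    boolean detection mask and the catalog of the surviving variants.
    Detection uses VAF and depth only, so thinning is channel-blind.
    """
    idx = np.array(
        [CHANNEL_INDEX[c] if isinstance(c, str) else int(c) for c in channels],
        dtype=int,
    )
    v = np.asarray(vafs, dtype=float)
    if np.isnan(v).any():
        bad = int(np.flatnonzero(np.isnan(v))[0])
        raise ValidationError(f"variant {bad} of sample {sample_id!r} lacks a VAF")
    if v.shape != idx.shape:
        raise ValidationError("channels and vafs differ in length")
    tumor_frac, _ = dilution_fraction(spec)
    n = len(v)
    depth = model.draw_depth(rng, size=n)
    alt = rng.binomial(depth, np.clip(v * tumor_frac, 0.0, 1.0))
    if model.base_error_rate > 0:
        alt = np.minimum(depth, alt + rng.binomial(depth, model.base_error_rate / 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf_obs = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    detected = (alt >= model.min_alt_reads) & (vaf_obs >= model.min_vaf) & (depth > 0)
    counts = np.bincount(idx[detected], minlength=96)
    return detected, MutationCatalog96(sample_id=sample_id, counts=counts)


# -- copy-number attenuation ---------------------------------------------------

#: integer allele states considered when re-calling an attenuated segment
RECALL_STATES: tuple[tuple[int, int], ...] = (
    (1, 0), (1, 1), (2, 0), (2, 1), (2, 2),
    (3, 0), (3, 1), (3, 2), (4, 1), (4, 2),
)


def expected_major_fraction(a: int, b: int, p: float) -> float:
    """Major-allele read fraction of state (a, b) at tumor purity p.

    The normal compartment is diploid balanced, contributing one copy of
    each allele: (p*a + (1-p)) / (p*(a+b) + 2*(1-p)).
    """
    denom = p * (a + b) + 2 * (1 - p)
    if denom == 0:  # (0,0) tumor state at p=1: no DNA at all
        return 0.5
    return (p * a + (1 - p)) / denom


def expected_total_ratio(a: int, b: int, p: float) -> float:
    """Total-copy read ratio (logR-like, diploid-normalized) of (a, b) at
    purity p: (p*(a+b) + 2*(1-p)) / 2."""
    return (p * (a + b) + 2 * (1 - p)) / 2.0


def attenuate_segments(
    segments: Iterable[AlleleSegment],
    p: float,
    model: SequencingModel,
    rng: np.random.Generator,
    noise_sd_at_unit_depth: float = 0.25,
    calling_threshold: float = 0.075,
) -> list[AlleleSegment]:
    """Re-call allele states as they would be observed at purity ``p``.

    Each segment's observed major-allele fraction and diploid-normalized
    total-copy ratio are the purity-mixture expectations plus Gaussian
    noise with sd ``noise_sd_at_unit_depth / sqrt(mean_depth)``.  If the
    observed fraction deviates from 1/2 by more than ``calling_threshold``
    the segment is re-called to the integer allele state whose expected
    (fraction, ratio) pair at purity ``p`` is nearest in Euclidean distance
    (ties -> lower total copy number); otherwise the allelic imbalance is
    indistinguishable from balanced and the segment collapses to (1, 1).
    """
    if not (0 < p <= 1):
        raise ValidationError(f"purity must be in (0, 1], got {p}")
    sd = noise_sd_at_unit_depth / np.sqrt(model.mean_depth)
    out: list[AlleleSegment] = []
    for seg in segments:
        m_true = expected_major_fraction(seg.cn_major, seg.cn_minor, p)
        r_true = expected_total_ratio(seg.cn_major, seg.cn_minor, p)
        m_obs = m_true + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        r_obs = r_true + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        if abs(m_obs - 0.5) <= calling_threshold:
            a, b = 1, 1
        else:
            a, b = min(
                RECALL_STATES,
                key=lambda st: (
                    (expected_major_fraction(st[0], st[1], p) - m_obs) ** 2
                    + (expected_total_ratio(st[0], st[1], p) - r_obs) ** 2,
                    st[0] + st[1],
                ),
            )
        out.append(
            AlleleSegment(seg.chrom, seg.start, seg.end, cn_major=a, cn_minor=b)
        )
    return out


# -- the experiment ------------------------------------------------------------


def run_purity_experiment(
    cohort,
    purities: Sequence[float],
    fdeam_cutpoint: float = 13.1,
    hrdsum_cutpoint: float = 42.0,
    reps: int = 1,
    seed: int = 0,
    model: SequencingModel | None = None,
    annotation: GenomeAnnotation | None = None,
    scar_config: ScarConfig | None = None,
    min_tmb: int = DEFAULT_MIN_TMB,
    noise_sd_at_unit_depth: float = 0.25,
    calling_threshold: float = 0.075,
) -> pd.DataFrame:
    """Dilute a labeled cohort to each purity level and evaluate biomarkers.

    ``cohort`` is a :class:`fdeam.synthetic_cohort.SyntheticCohort` (or any
    object with the same ``samples`` attribute: label, purity, channel
    indices, VAFs and segments per sample).  Returns a tidy frame with one
    row per (purity, replicate, biomarker): AUC and balanced accuracy /
    sensitivity / specificity at the fixed cutpoints.  Fully reproducible
    from ``seed``.
    """
    model = model or SequencingModel()
    annotation = annotation if annotation is not None else getattr(cohort, "annotation", None)
    if annotation is None:
        raise ValidationError("run_purity_experiment needs a genome annotation")
    labels = [s.label for s in cohort.samples]
    if len(set(labels)) < 2:
        raise ValidationError("cohort must contain both benchmark classes")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        for p in purities:
            fdeams, hrdsums = [], []
            for s in cohort.samples:
                spec = PuritySpec(q=s.purity, p=p)
                _, cat = dilute_catalog(
                    s.channel_indices, s.vafs, spec, model, rng, sample_id=s.sample_id
                )
                fdeams.append(cat.fdeam(min_tmb=min_tmb))
                obs = attenuate_segments(
                    s.segments, p, model, rng,
                    noise_sd_at_unit_depth=noise_sd_at_unit_depth,
                    calling_threshold=calling_threshold,
                )
                hrdsums.append(compute_hrdsum(obs, annotation, scar_config).hrdsum)
            for name, scores, direction, cut in (
                ("f_deam", fdeams, "lower_predicts_positive", fdeam_cutpoint),
                ("hrdsum", hrdsums, "higher_predicts_positive", hrdsum_cutpoint),
            ):
                auc = roc_auc(scores, labels, direction).auc
                cp = evaluate_at_cutpoint(scores, labels, cut, direction)
                rows.append(
                    {
                        "purity": p,
                        "replicate": rep,
                        "biomarker": name,
                        "auc": auc,
                        "sensitivity": cp.sensitivity,
                        "specificity": cp.specificity,
                        "balanced_accuracy": cp.balanced_accuracy,
                    }
                )
    return pd.DataFrame(rows)
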