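"""Labeled synthetic cohorts with the statistical structure of the analysis.

The generator emulates a cohort of HR-deficient (benchmark-positive, H1a*)
and HR-proficient (benchmark-negative, H3) tumors at the level the pipeline
consumes — it does not place mutations on a real genome sequence:

* **mutation spectra** — each class has a 96-channel probability profile;
  by default the HR-proficient profile carries 25% of its mass on the four
  CpG-site C>T channels (an SBS1-like clock-dominated spectrum) and the
  HR-deficient profile only 8% (a flat, SBS3-like spectrum), echoing the
  direction and approximate magnitude of the contrast observed in ovarian
  cancer.  Per-sample channel counts are multinomial draws.
* **TMB** — log-normal (meanlog 4.0, sdlog 0.8, rounded), so the median is
  ~55 SBS per exome and over 90% of samples have TMB >= 10.
* **VAFs** — Beta(8, 12), mean 0.4: clonal heterozygous variants at the
  default source purity of 0.8.
* **scar segments** — each sample receives allele-specific copy-number
  segments constructed to contain an exactly known number of qualifying
  LOH / LST / TAI events (planted on separate chromosome arms so the
  events cannot interact), calibrated to class-dependent HRDsum targets
  (truncated normal, mean 55 vs 20).  The planted counts are recorded as
  ground truth and are recovered exactly by the scar scorer.
* **purity** — every sample carries a source tumor purity (default 0.8,
  matching a high-purity source cohort for dilution experiments).

Cohorts are bitwise reproducible from (config, seed), and
:func:`write_fixture_files` emits the TSV file set that round-trips through
the pipeline's readers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog96 import (
    CHANNELS_96,
    CPG_CT_INDICES,
    MutationCatalog96,
    ValidationError,
)
from .scar_scores import (
    MB,
    AlleleSegment,
    ChromosomeAnnotation,
    compute_hrdsum,
    write_annotation,
    write_segments,
)

# ---------------------------------------------------------------------------
# genome annotation fixture: 22 autosomes with synthetic lengths/centromeres
# ---------------------------------------------------------------------------


def default_annotation() -> dict[str, ChromosomeAnnotation]:
    """22 autosomes, lengths 240..60 Mb, centromere at 40% (3 Mb wide)."""
    lengths = np.round(np.linspace(240, 60, 22)).astype(int) * MB
    out = {}
    for i, length in enumerate(lengths, start=1):
        cen_start = int(round(0.4 * length))
        out[f"chr{i}"] = ChromosomeAnnotation(
            length=int(length),
            centromere_start=cen_start,
            centromere_end=cen_start + 3 * MB,
        )
    return out


# ---------------------------------------------------------------------------
# class profiles
# ---------------------------------------------------------------------------


def profile_with_cpg_mass(cpg_mass: float) -> np.ndarray:
    """96-channel profile: ``cpg_mass`` split over the four CpG-C>T
    channels, the remainder uniform over the other 92."""
    if not (0 <= cpg_mass <= 1):
        raise ValidationError(f"CpG mass must be in [0, 1], got {cpg_mass}")
    p = np.full(96, (1.0 - cpg_mass) / 92.0)
    p[list(CPG_CT_INDICES)] = cpg_mass / 4.0
    return p


def _validate_profile(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (96,):
        raise ValidationError(f"profile must have length 96, got {p.shape}")
    if (p < 0).any():
        raise ValidationError("profile has negative entries")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-8):
        raise ValidationError(f"profile sums to {s}, expected 1")
    return p / s


@dataclass
class GeneratorConfig:
    n_pos: int = 20
    n_neg: int = 20
    cpg_mass_pos: float = 0.08      # HR-deficient: CpG-C>T depleted
    cpg_mass_neg: float = 0.25      # HR-proficient: clock-dominated
    profile_pos: np.ndarray | None = None   # overrides cpg_mass_pos
    profile_neg: np.ndarray | None = None
    tmb_meanlog: float = 4.0
    tmb_sdlog: float = 0.8
    hrdsum_pos: tuple[float, float] = (55.0, 15.0)   # (mean, sd)
    hrdsum_neg: tuple[float, float] = (20.0, 10.0)
    hrdsum_max: int = 80            # planting capacity of the synthetic genome
    vaf_beta: tuple[float, float] = (8.0, 12.0)
    purity: float = 0.8
    seed: int = 0

    def resolved_profiles(self) -> tuple[np.ndarray, np.ndarray]:
        pos = (
            _validate_profile(self.profile_pos)
            if self.profile_pos is not None
            else profile_with_cpg_mass(self.cpg_mass_pos)
        )
        neg = (
            _validate_profile(self.profile_neg)
            if self.profile_neg is not None
            else profile_with_cpg_mass(self.cpg_mass_neg)
        )
        return pos, neg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("profile_pos", "profile_neg"):
            if d[k] is not None:
                d[k] = list(map(float, d[k]))
        for k in ("hrdsum_pos", "hrdsum_neg", "vaf_beta"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in ("hrdsum_pos", "hrdsum_neg", "vaf_beta"):
            if k in d:
                d[k] = tuple(d[k])
        for k in ("profile_pos", "profile_neg"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# scar-event planting
# ---------------------------------------------------------------------------

_TAI_MIN_ARM = 35 * MB   # 20 Mb event + 5 Mb buffer + >=10 Mb balanced rest


@dataclass(frozen=True)
class _Arm:
    chrom: str
    start: int
    end: int
    telomere_at_start: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _arms(annotation) -> list[_Arm]:
    arms = []
    for chrom, ann in annotation.items():
        (p_lo, p_hi), (q_lo, q_hi) = ann.arms
        arms.append(_Arm(chrom, p_lo, p_hi, telomere_at_start=True))
        arms.append(_Arm(chrom, q_lo, q_hi, telomere_at_start=False))
    return arms


def _oriented(pattern: list[tuple[int, tuple[int, int]]], arm: _Arm) -> list[AlleleSegment]:
    """Lay out (length, state) blocks along the arm, telomere side first.

    The last block absorbs any rounding slack so the arm is fully covered.
    """
    blocks = pattern if arm.telomere_at_start else list(reversed(pattern))
    total = sum(length for length, _ in pattern)
    if total > arm.length:
        raise ValidationError("planting pattern exceeds arm length")
    segs = []
    pos = arm.start
    for i, (length, (a, b)) in enumerate(blocks):
        end = arm.end if i == len(blocks) - 1 else pos + length - 1
        segs.append(AlleleSegment(arm.chrom, pos, end, a, b))
        pos = end + 1
    return segs


def _loh_pattern(k: int, arm: _Arm) -> list[tuple[int, tuple[int, int]]]:
    # telomeric balanced anchor, then per event a 5 Mb (3,1) buffer and a
    # 20 Mb (2,0) LOH block, closed by a buffer and balanced fill
    pattern = [(10 * MB, (1, 1))]
    for _ in range(k):
        pattern += [(5 * MB, (3, 1)), (20 * MB, (2, 0))]
    pattern += [(5 * MB, (3, 1))]
    used = sum(length for length, _ in pattern)
    pattern += [(arm.length - used, (1, 1))] if arm.length > used else []
    return pattern


def _lst_pattern(k: int, arm: _Arm) -> list[tuple[int, tuple[int, int]]]:
    # telomeric balanced anchor >=10 Mb, then k alternating 12 Mb blocks:
    # every junction is a transition between >=10 Mb flanks
    anchor = arm.length - k * 12 * MB
    pattern = [(anchor, (1, 1))]
    for i in range(k):
        pattern.append((12 * MB, (2, 1) if i % 2 == 0 else (1, 1)))
    return pattern


def _tai_pattern(arm: _Arm) -> list[tuple[int, tuple[int, int]]]:
    # imbalanced telomere-touching block, buffer, balanced rest
    return [
        (20 * MB, (2, 1)),
        (5 * MB, (3, 1)),
        (arm.length - 25 * MB, (1, 1)),
    ]


def plant_scar_events(
    n_loh: int,
    n_lst: int,
    n_tai: int,
    annotation,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlleleSegment], tuple[int, int, int]]:
    """Build a segment set containing exactly known qualifying scar events.

    Events of different types are planted on disjoint chromosome arms so
    they cannot interact; all remaining arms are balanced (1,1).  Returns
    the segments and the actually-planted ``(loh, lst, tai)`` counts, which
    can fall short of the request if the 44-arm genome saturates.
    """
    arms = _arms(annotation)
    segments: list[AlleleSegment] = []
    free = sorted(arms, key=lambda a: a.length)

    # TAI first on the smallest suitable arms (one event per telomere)
    planted_tai = 0
    remaining = []
    for arm in free:
        if planted_tai < n_tai and arm.length >= _TAI_MIN_ARM:
            segments += _oriented(_tai_pattern(arm), arm)
            planted_tai += 1
        else:
            remaining.append(arm)

    # LOH on the largest remaining arms
    planted_loh = 0
    remaining.sort(key=lambda a: a.length, reverse=True)
    still = []
    for arm in remaining:
        cap = (arm.length - 15 * MB) // (25 * MB)
        k = int(min(cap, n_loh - planted_loh))
        if k > 0:
            segments += _oriented(_loh_pattern(k, arm), arm)
            planted_loh += k
        else:
            still.append(arm)

    # LST on the next largest arms
    planted_lst = 0
    rest = []
    for arm in still:
        cap = (arm.length - 10 * MB) // (12 * MB)
        k = int(min(cap, n_lst - planted_lst))
        if k > 0:
            segments += _oriented(_lst_pattern(k, arm), arm)
            planted_lst += k
        else:
            rest.append(arm)

    for arm in rest:  # balanced background
        segments.append(AlleleSegment(arm.chrom, arm.start, arm.end, 1, 1))

    return segments, (planted_loh, planted_lst, planted_tai)


# ---------------------------------------------------------------------------
# sample and cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSample:
    sample_id: str
    label: str                       # "positive" (H1a*) / "negative" (H3)
    purity: float
    channel_indices: np.ndarray      # per-variant canonical channel index
    vafs: np.ndarray
    chroms: np.ndarray               # per-variant chromosome names
    positions: np.ndarray
    segments: list[AlleleSegment]
    truth: dict = field(default_factory=dict)

    @property
    def catalog(self) -> MutationCatalog96:
        counts = np.bincount(self.channel_indices, minlength=96)
        return MutationCatalog96(self.sample_id, counts)


@dataclass
class SyntheticCohort:
    samples: list[SyntheticSample]
    annotation: dict[str, ChromosomeAnnotation]
    config: GeneratorConfig

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            cat = s.catalog
            scores = compute_hrdsum(s.segments, self.annotation)
            rows.append(
                {
                    "sample": s.sample_id,
                    "label": s.label,
                    "purity": s.purity,
                    "tmb": cat.tmb,
                    "f_deam": cat.fdeam(),
                    "loh": scores.loh,
                    "lst": scores.lst,
                    "tai": scores.tai,
                    "hrdsum": scores.hrdsum,
                }
            )
        return pd.DataFrame(rows)


def generate_sample(
    config: GeneratorConfig,
    label: str,
    rng: np.random.Generator,
    sample_id: str,
    annotation=None,
) -> SyntheticSample:
    """Draw one labeled sample from the class-conditional distributions."""
    if label not in ("positive", "negative"):
        raise ValidationError(f"label must be positive/negative, got {label!r}")
    annotation = annotation or default_annotation()
    profile_pos, profile_neg = config.resolved_profiles()
    profile = profile_pos if label == "positive" else profile_neg

    tmb = max(int(round(rng.lognormal(config.tmb_meanlog, config.tmb_sdlog))), 0)
    channels = rng.choice(96, size=tmb, p=profile)
    a, b = config.vaf_beta
    vafs = rng.beta(a, b, size=tmb)

    chrom_names = list(annotation)
    lengths = np.array([annotation[c].length for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=tmb, p=lengths / lengths.sum())
    positions = np.array(
        [rng.integers(2, annotation[chrom_names[i]].length - 1) for i in chrom_idx],
        dtype=np.int64,
    )

    mean, sd = config.hrdsum_pos if label == "positive" else config.hrdsum_neg
    target = int(np.clip(round(rng.normal(mean, sd)), 0, config.hrdsum_max))
    n_loh, n_lst, n_tai = rng.multinomial(target, [1 / 3] * 3)
    segments, planted = plant_scar_events(n_loh, n_lst, n_tai, annotation, rng)

    return SyntheticSample(
        sample_id=sample_id,
        label=label,
        purity=config.purity,
        channel_indices=np.asarray(channels, dtype=np.int64),
        vafs=vafs,
        chroms=np.array([chrom_names[i] for i in chrom_idx]),
        positions=positions,
        segments=segments,
        truth={
            "expected_fdeam": 100.0 * float(profile[list(CPG_CT_INDICES)].sum()),
            "tmb": tmb,
            "loh": planted[0],
            "lst": planted[1],
            "tai": planted[2],
            "hrdsum": sum(planted),
        },
    )


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate n_pos + n_neg samples; identical (config, seed) gives an
    identical cohort."""
    config = config or GeneratorConfig()
    if config.n_pos + config.n_neg == 0:
        raise ValidationError("empty cohort: n_pos = n_neg = 0")
    rng = np.random.default_rng(config.seed)
    annotation = default_annotation()
    samples = []
    for i in range(config.n_pos):
        samples.append(
            generate_sample(config, "positive", rng, f"POS_{i + 1:03d}", annotation)
        )
    for i in range(config.n_neg):
        samples.append(
            generate_sample(config, "negative", rng, f"NEG_{i + 1:03d}", annotation)
        )
    return SyntheticCohort(samples=samples, annotation=annotation, config=config)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------


def _channel_fields(index: int) -> tuple[str, str, str, str]:
    """(ref, alt, up, down) of a canonical channel, pyrimidine strand."""
    label = CHANNELS_96[index]
    up, ref, alt, down = label[0], label[2], label[4], label[6]
    return ref, alt, up, down


def write_fixture_files(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the cohort as the TSV file set the pipeline readers consume.

    Emits mutations.tsv (MAF-like with context columns and VAFs),
    segments.tsv, labels.tsv, annotation.tsv, alterations.tsv,
    methylation.tsv and manifest.yaml (config + seed).  The files
    round-trip losslessly through the corresponding readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    mut_rows = []
    for s in cohort.samples:
        for j in range(len(s.channel_indices)):
            ref, alt, up, down = _channel_fields(int(s.channel_indices[j]))
            mut_rows.append(
                {
                    "sample": s.sample_id,
                    "chrom": s.chroms[j],
                    "pos": int(s.positions[j]),
                    "ref": ref,
                    "alt": alt,
                    "context_up": up,
                    "context_down": down,
                    "vaf": float(s.vafs[j]),
                }
            )
    mut_cols = ["sample", "chrom", "pos", "ref", "alt", "context_up", "context_down", "vaf"]
    paths = {"mutations": directory / "mutations.tsv"}
    pd.DataFrame(mut_rows, columns=mut_cols).to_csv(
        paths["mutations"], sep="\t", index=False
    )

    paths["segments"] = directory / "segments.tsv"
    write_segments({s.sample_id: s.segments for s in cohort.samples}, paths["segments"])

    paths["labels"] = directory / "labels.tsv"
    pd.DataFrame(
        [
            {"sample": s.sample_id, "label": s.label, "purity": s.purity}
            for s in cohort.samples
        ],
        columns=["sample", "label", "purity"],
    ).to_csv(paths["labels"], sep="\t", index=False)

    paths["annotation"] = directory / "annotation.tsv"
    write_annotation(cohort.annotation, paths["annotation"])

    # HR-cause inputs consistent with the labels: positives carry a biallelic
    # deleterious BRCA1/2 alteration, negatives carry none
    alt_rows = []
    for i, s in enumerate(cohort.samples):
        if s.label == "positive":
            alt_rows.append(
                {
                    "sample": s.sample_id,
                    "gene": "BRCA1" if i % 2 == 0 else "BRCA2",
                    "effect": "deleterious",
                    "allelic": "biallelic",
                }
            )
    paths["alterations"] = directory / "alterations.tsv"
    pd.DataFrame(
        alt_rows, columns=["sample", "gene", "effect", "allelic"]
    ).to_csv(paths["alterations"], sep="\t", index=False)

    paths["methylation"] = directory / "methylation.tsv"
    pd.DataFrame(
        [{"sample": s.sample_id, "brca1_promoter_hm": "false"} for s in cohort.samples],
        columns=["sample", "brca1_promoter_hm"],
    ).to_csv(paths["methylation"], sep="\t", index=False)

    paths["manifest"] = directory / "manifest.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump({"generator": cohort.config.to_dict()}, fh, sort_keys=True)
    return paths
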