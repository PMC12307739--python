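"""Cause-of-HRD classification of tumors from gene-level alterations.

Tumors are assigned one of five classes by the most severe alteration found
in homologous-recombination (HR) pathway genes:

* **H1a** — deleterious alteration in BRCA1/BRCA2,
* **H1b** — deleterious alteration in another HR-pathway gene,
* **H2a** — variant of unknown significance (VUS) in BRCA1/BRCA2,
* **H2b** — VUS in another HR-pathway gene,
* **H3**  — none of the above.

The class precedence is strict: H1a > H1b > H2a > H2b > H3, and a tumor
always gets the highest class among its alterations.  Deleterious classes
additionally carry a biallelic (BA) / monoallelic (MA) suffix taken from the
alterations at the achieved class (biallelic wins when both occur).

The benchmark ground truth for biomarker evaluation contrasts

* **positives (H1a\\*)** — biallelic deleterious BRCA1/2 (H1a-BA) or BRCA1
  promoter hypermethylation, i.e. tumors almost certainly HR-deficient, and
* **negatives (H3)** — tumors with no HR-pathway alteration and no BRCA1
  hypermethylation.

All other classes are of mixed or uncertain HR status and are excluded from
the benchmark with a recorded reason.

The HR gene list is configuration: the default below contains well-known
HR-pathway genes and is NOT an authoritative clinical list — supply your own
via ``gene_groups``/TSV for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .catalog96 import ValidationError

BRCA12 = frozenset({"BRCA1", "BRCA2"})

#: placeholder HR-pathway gene list (non-authoritative; configurable)
DEFAULT_OTHER_HR_GENES = frozenset(
    {
        "ATM", "ATR", "BAP1", "BARD1", "BLM", "BRIP1", "CHEK1", "CHEK2",
        "FANCA", "FANCC", "FANCD2", "FANCE", "FANCF", "FANCG", "FANCI",
        "FANCL", "FANCM", "MRE11", "NBN", "PALB2", "RAD50", "RAD51",
        "RAD51B", "RAD51C", "RAD51D", "RAD52", "RAD54L", "RBBP8", "XRCC2",
        "XRCC3",
    }
)

Effect = Literal["deleterious", "VUS"]
Allelic = Literal["biallelic", "monoallelic", "unknown"]
GeneGroup = Literal["BRCA12", "other_HR", "non_HR"]

H_CLASSES = ("H1a", "H1b", "H2a", "H2b", "H3")
_PRECEDENCE = {c: i for i, c in enumerate(H_CLASSES)}  # lower index = higher


def gene_group(
    gene: str, other_hr_genes: frozenset[str] | Iterable[str] = DEFAULT_OTHER_HR_GENES
) -> GeneGroup:
    """Deterministic gene → group mapping given a configured HR-gene list."""
    g = gene.upper()
    if g in BRCA12:
        return "BRCA12"
    if g in set(x.upper() for x in other_hr_genes):
        return "other_HR"
    return "non_HR"


@dataclass
class GeneAlteration:
    sample_id: str
    gene: str
    effect: Effect
    allelic: Allelic = "unknown"

    def __post_init__(self) -> None:
        if self.effect not in ("deleterious", "VUS"):
            raise ValidationError(f"unknown effect {self.effect!r}")
        if self.allelic not in ("biallelic", "monoallelic", "unknown"):
            raise ValidationError(f"unknown allelic status {self.allelic!r}")


@dataclass
class HRClassification:
    sample_id: str
    h_class: str
    allelic_suffix: Literal["BA", "MA", "none"] = "none"
    brca1_hypermethylated: bool | None = None  # None = unknown
    h1a_star: bool = False


def _class_of(effect: Effect, group: GeneGroup) -> str | None:
    if group == "non_HR":
        return None
    if effect == "deleterious":
        return "H1a" if group == "BRCA12" else "H1b"
    return "H2a" if group == "BRCA12" else "H2b"


def classify_hr_status(
    alterations: Iterable[GeneAlteration],
    methylation: bool | None = None,
    other_hr_genes: frozenset[str] | Iterable[str] = DEFAULT_OTHER_HR_GENES,
) -> HRClassification:
    """Assign the highest cause-of-HRD class among a sample's alterations.

    ``methylation`` is the BRCA1-promoter hypermethylation call (None =
    unknown, treated as not hypermethylated for classification but recorded).
    The H1a* flag is set for biallelic deleterious BRCA1/2 or BRCA1
    hypermethylation; alterations of unknown allelic status are treated as
    monoallelic for this purpose (conservative).
    """
    alterations = list(alterations)
    samples = {a.sample_id for a in alterations}
    if len(samples) > 1:
        raise ValidationError(f"alterations from multiple samples: {sorted(samples)}")
    sample_id = alterations[0].sample_id if alterations else ""

    other = frozenset(x.upper() for x in other_hr_genes)
    best_class = "H3"
    for a in alterations:
        c = _class_of(a.effect, gene_group(a.gene, other))
        if c is not None and _PRECEDENCE[c] < _PRECEDENCE[best_class]:
            best_class = c

    suffix: str = "none"
    if best_class in ("H1a", "H1b"):
        at_class = [
            a
            for a in alterations
            if _class_of(a.effect, gene_group(a.gene, other)) == best_class
        ]
        suffix = "BA" if any(a.allelic == "biallelic" for a in at_class) else "MA"

    star = (best_class == "H1a" and suffix == "BA") or methylation is True
    return HRClassification(
        sample_id=sample_id,
        h_class=best_class,
        allelic_suffix=suffix,
        brca1_hypermethylated=methylation,
        h1a_star=star,
    )


def build_benchmark_labels(
    classifications: Iterable[HRClassification],
) -> pd.DataFrame:
    """Derive the H1a* vs H3 benchmark labels from classifications.

    Returns a frame with columns sample, label ("positive"/"negative"/
    "excluded") and reason.  Positives are H1a* samples; negatives are H3
    samples without BRCA1 hypermethylation; everything else is excluded.
    """
    rows = []
    seen: set[str] = set()
    for c in classifications:
        if c.sample_id in seen:
            raise ValidationError(f"duplicate classification for {c.sample_id!r}")
        seen.add(c.sample_id)
        if c.h1a_star:
            rows.append((c.sample_id, "positive", "H1a* (H1a-BA or BRCA1 hypermethylation)"))
        elif c.h_class == "H3":
            rows.append((c.sample_id, "negative", "H3, no HR-pathway alteration"))
        else:
            rows.append(
                (c.sample_id, "excluded", f"class {c.h_class}-{c.allelic_suffix}")
            )
    return pd.DataFrame(rows, columns=["sample", "label", "reason"])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_alterations(path) -> dict[str, list[GeneAlteration]]:
    """Read a gene-alteration TSV (sample, gene, effect, allelic)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample", "gene", "effect") if c not in df.columns]
    if missing:
        raise ValidationError(f"alteration file {path} lacks columns: {missing}")
    out: dict[str, list[GeneAlteration]] = {}
    for row in df.itertuples(index=False):
        allelic = getattr(row, "allelic", "unknown")
        if pd.isna(allelic):
            allelic = "unknown"
        out.setdefault(str(row.sample), []).append(
            GeneAlteration(str(row.sample), str(row.gene), str(row.effect), str(allelic))
        )
    return out


def read_methylation(path) -> dict[str, bool | None]:
    """Read a methylation TSV (sample, brca1_promoter_hm as true/false/NA)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, bool | None] = {}
    for row in df.itertuples(index=False):
        v = str(row.brca1_promoter_hm).strip().lower()
        out[str(row.sample)] = {"true": True, "false": False}.get(v)
    return out


def classify_cohort(
    alterations_by_sample: Mapping[str, list[GeneAlteration]],
    methylation_by_sample: Mapping[str, bool | None] | None = None,
    all_samples: Iterable[str] | None = None,
    other_hr_genes: frozenset[str] | Iterable[str] = DEFAULT_OTHER_HR_GENES,
) -> list[HRClassification]:
    """Classify every sample; samples without alteration rows become H3."""
    meth = methylation_by_sample or {}
    samples = set(alterations_by_sample)
    if all_samples is not None:
        samples |= set(all_samples)
    out = []
    for sid in sorted(samples):
        alts = alterations_by_sample.get(sid, [])
        c = classify_hr_status(alts, meth.get(sid), other_hr_genes)
        if not alts:
            c.sample_id = sid
        out.append(c)
    return out


def classifications_to_frame(classifications: Iterable[HRClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "h_class": c.h_class,
                "allelic_suffix": c.allelic_suffix,
                "brca1_hypermethylated": c.brca1_hypermethylated,
                "h1a_star": c.h1a_star,
            }
            for c in classifications
        ]
    )
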