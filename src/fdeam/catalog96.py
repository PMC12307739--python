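"""96-channel somatic SBS catalogs, TMB, and the CpG-deamination fraction.

Somatic single-base substitutions (SBS) are classified into the standard 96
trinucleotide-context channels: six pyrimidine-reference substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) times the 5' and 3' flanking bases.
Purine-reference calls are mapped onto the opposite strand by
reverse-complementing the trinucleotide, so every mutation has exactly one
canonical channel.

From a per-sample catalog two scalar biomarkers are derived:

* **TMB** — tumor mutational burden, here simply the number of SBS calls in
  the sequenced region.
* **f_deam** — the fraction (in percent) of C>T transitions at CpG sites
  (channels ``A[C>T]G``, ``C[C>T]G``, ``G[C>T]G``, ``T[C>T]G``) among all
  SBS.  These mutations are attributed to spontaneous deamination of
  5-methylcytosine, the clock-like process of signature SBS1.  Low f_deam
  indicates that other mutational processes (notably the ones active in
  HR-deficient tumors) dominate the spectrum, so f_deam is a *negative*
  predictor of homologous recombination deficiency.  For very low TMB the
  ratio is statistically meaningless and is reported as NA
  (``min_tmb`` default 10).

Channel order is fixed and substitution-major: for each substitution in the
order C>A, C>G, C>T, T>A, T>C, T>G, the 5' base cycles A,C,G,T and, within
it, the 3' base cycles A,C,G,T.  This matches the row layout of COSMIC
signature matrices so signature files align row-wise after label matching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fdeam")

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical channel labels, substitution-major then 5' then 3' base
CHANNELS_96 = tuple(
    f"{up}[{sub}]{down}" for sub in SUBSTITUTIONS for up in BASES for down in BASES
)
CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}

#: the four CpG-site C>T channels defining the f_deam numerator
CPG_CT_CHANNELS = ("A[C>T]G", "C[C>T]G", "G[C>T]G", "T[C>T]G")
CPG_CT_INDICES = tuple(CHANNEL_INDEX[c] for c in CPG_CT_CHANNELS)

DEFAULT_MIN_TMB = 10


class ValidationError(ValueError):
    """Raised when an input record violates a precondition."""


class ReferenceMismatchError(ValidationError):
    """Genome base at the record position disagrees with the stated ref."""


class ChromosomeEdgeError(ValidationError):
    """Position too close to a chromosome end for context extraction."""


def _check_base(value: str, name: str) -> str:
    if not isinstance(value, str) or value.upper() not in COMPLEMENT:
        raise ValidationError(f"invalid base {value!r} for field {name!r}")
    return value.upper()


@dataclass
class MutationRecord:
    """One somatic variant call.

    ``ref``/``alt`` are single bases for SBS records; longer alleles mark
    the record as non-SBS and it is skipped by :func:`build_catalog`.
    ``up``/``down`` are the 5'/3' flanking reference bases, either supplied
    by the caller or filled in by :func:`extract_context_from_reference`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    up: str | None = None
    down: str | None = None
    vaf: float | None = None
    depth: int | None = None

    @property
    def is_sbs(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref.upper() in COMPLEMENT
            and self.alt.upper() in COMPLEMENT
            and self.ref.upper() != self.alt.upper()
        )

    @property
    def has_context(self) -> bool:
        return self.up is not None and self.down is not None


def normalize_to_pyrimidine(
    ref: str, alt: str, up: str, down: str
) -> tuple[str, str, str]:
    """Map a substitution with context to the pyrimidine-reference strand.

    Returns ``(substitution, up', down')`` where the substitution has a C or
    T reference.  Purine-reference inputs are reverse-complemented: the
    flanks swap and complement, and the substitution maps to its complement.
    """
    ref = _check_base(ref, "ref")
    alt = _check_base(alt, "alt")
    up = _check_base(up, "up")
    down = _check_base(down, "down")
    if ref == alt:
        raise ValidationError(f"ref and alt are identical ({ref!r})")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", up, down
    return (
        f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}",
        COMPLEMENT[down],
        COMPLEMENT[up],
    )


def classify_channel(record: MutationRecord) -> str:
    """Return the canonical ``"A[C>T]G"`` style channel label of a record."""
    if not record.has_context:
        raise ValidationError(
            f"record {record.chrom}:{record.pos} lacks flanking context; "
            "run extract_context_from_reference first"
        )
    sub, up, down = normalize_to_pyrimidine(
        record.ref, record.alt, record.up, record.down
    )
    return f"{up}[{sub}]{down}"


def extract_context_from_reference(
    genome: Mapping[str, Sequence[str]],
    chrom: str,
    pos: int,
    expected_ref: str | None = None,
) -> tuple[str, str, str]:
    """Look up the trinucleotide ``(up, ref, down)`` at a 1-based position.

    ``genome`` is any mapping from chromosome name to an indexable sequence
    (a ``pyfaidx.Fasta`` object or a plain dict of strings).  Bases are
    uppercased, so soft-masked references are handled.  Raises
    :class:`ChromosomeEdgeError` at chromosome ends and
    :class:`ReferenceMismatchError` when ``expected_ref`` disagrees with the
    genome.
    """
    seq = genome[chrom]
    n = len(seq)
    if pos < 2 or pos > n - 1:
        raise ChromosomeEdgeError(
            f"position {chrom}:{pos} too close to a chromosome end "
            f"(length {n}) for trinucleotide context"
        )
    tri = str(seq[pos - 2 : pos + 1]).upper()
    up, ref, down = tri[0], tri[1], tri[2]
    if expected_ref is not None and ref != expected_ref.upper():
        raise ReferenceMismatchError(
            f"reference base at {chrom}:{pos} is {ref!r}, record says "
            f"{expected_ref!r}"
        )
    return up, ref, down


@dataclass
class MutationCatalog96:
    """Per-sample counts over the 96 canonical channels.

    ``n_skipped_non_sbs`` counts records skipped as indels/MNVs;
    ``n_skipped_ambiguous`` counts SBS records dropped because of ambiguity
    codes (N) in ref/alt/context.
    """

    sample_id: str
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(96, dtype=np.int64)
    )
    n_skipped_non_sbs: int = 0
    n_skipped_ambiguous: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValidationError(
                f"catalog needs exactly 96 counts, got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative channel count")

    @property
    def tmb(self) -> int:
        return int(self.counts.sum())

    def fdeam(self, min_tmb: int = DEFAULT_MIN_TMB) -> float:
        return compute_fdeam(self, min_tmb=min_tmb)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96), name=self.sample_id)


def build_catalog(
    records: Iterable[MutationRecord], sample_id: str
) -> MutationCatalog96:
    """Count classified SBS records into a 96-channel catalog.

    Non-SBS records (indels, MNVs) are skipped and tallied; records whose
    bases or context contain ambiguity codes are skipped with a warning.
    Records must carry flanking context (see
    :func:`extract_context_from_reference`).
    """
    catalog = MutationCatalog96(sample_id=sample_id)
    for i, rec in enumerate(records):
        if rec.sample_id and rec.sample_id != sample_id:
            raise ValidationError(
                f"record {i} belongs to sample {rec.sample_id!r}, "
                f"not {sample_id!r}"
            )
        if not rec.is_sbs:
            if (
                len(rec.ref) == 1
                and len(rec.alt) == 1
                and ("N" in rec.ref.upper() or "N" in rec.alt.upper())
            ):
                catalog.n_skipped_ambiguous += 1
                logger.warning(
                    "record %d (%s:%s) skipped: ambiguous ref/alt", i, rec.chrom, rec.pos
                )
            else:
                catalog.n_skipped_non_sbs += 1
            continue
        if not rec.has_context:
            raise ValidationError(
                f"record {i} ({rec.chrom}:{rec.pos}) lacks flanking context; "
                "run extract_context_from_reference first"
            )
        if rec.up.upper() not in COMPLEMENT or rec.down.upper() not in COMPLEMENT:
            catalog.n_skipped_ambiguous += 1
            logger.warning(
                "record %d (%s:%s) skipped: ambiguous context %r/%r",
                i, rec.chrom, rec.pos, rec.up, rec.down,
            )
            continue
        try:
            label = classify_channel(rec)
        except ValidationError as exc:
            raise ValidationError(f"record {i}: {exc}") from exc
        catalog.counts[CHANNEL_INDEX[label]] += 1
    return catalog


def compute_tmb(catalog: MutationCatalog96) -> int:
    """Tumor mutational burden: the total SBS count of the catalog."""
    return catalog.tmb


def compute_fdeam(
    catalog: MutationCatalog96, min_tmb: int = DEFAULT_MIN_TMB
) -> float:
    """CpG-site C>T fraction of all SBS, as a percentage in [0, 100].

    Returns NaN (the NA value) when TMB < ``min_tmb``: with only a handful
    of mutations the fraction carries a stochastic error of order
    1/sqrt(TMB) and is not a usable biomarker.
    """
    tmb = catalog.tmb
    if tmb < min_tmb:
        return math.nan
    cpg = int(catalog.counts[list(CPG_CT_INDICES)].sum())
    return 100.0 * cpg / tmb


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

MAF_REQUIRED = ("sample", "chrom", "pos", "ref", "alt")
MAF_OPTIONAL = ("context_up", "context_down", "vaf", "depth")


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV of somatic calls.

    Required columns: sample, chrom, pos (1-based), ref, alt.  Optional:
    context_up, context_down, vaf, depth.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"MAF-like file {path} lacks columns: {missing}")
    return df


def records_from_frame(df: pd.DataFrame) -> dict[str, list[MutationRecord]]:
    """Group a MAF-like frame into per-sample MutationRecord lists."""
    has = {c: c in df.columns for c in MAF_OPTIONAL}
    out: dict[str, list[MutationRecord]] = {}
    for row in df.itertuples(index=False):
        rec = MutationRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            sample_id=str(row.sample),
            up=str(row.context_up) if has["context_up"] and pd.notna(row.context_up) else None,
            down=str(row.context_down) if has["context_down"] and pd.notna(row.context_down) else None,
            vaf=float(row.vaf) if has["vaf"] and pd.notna(row.vaf) else None,
            depth=int(row.depth) if has["depth"] and pd.notna(row.depth) else None,
        )
        out.setdefault(rec.sample_id, []).append(rec)
    return out


def fill_context(
    records: Iterable[MutationRecord], genome: Mapping[str, Sequence[str]]
) -> list[MutationRecord]:
    """Fill missing up/down context from a reference genome accessor."""
    filled = []
    for rec in records:
        if not rec.has_context and rec.is_sbs:
            up, _, down = extract_context_from_reference(
                genome, rec.chrom, rec.pos, expected_ref=rec.ref
            )
            rec.up, rec.down = up, down
        filled.append(rec)
    return filled


def read_vcf(
    path,
    sample_id: str,
    genome: Mapping[str, Sequence[str]] | None = None,
) -> list[MutationRecord]:
    """Read SNV records from a VCF; context from ``genome`` when given."""
    from cyvcf2 import VCF

    records: list[MutationRecord] = []
    for v in VCF(str(path)):
        if not v.is_snp or not v.ALT:
            continue
        records.append(
            MutationRecord(
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=str(v.REF),
                alt=str(v.ALT[0]),
                sample_id=sample_id,
            )
        )
    if genome is not None:
        records = fill_context(records, genome)
    return records


def build_catalogs(
    df: pd.DataFrame,
    genome: Mapping[str, Sequence[str]] | None = None,
    min_vaf: float | None = None,
    min_depth: int | None = None,
) -> dict[str, MutationCatalog96]:
    """Build one catalog per sample from a MAF-like frame.

    No VAF/depth filter is applied by default; pass ``min_vaf`` /
    ``min_depth`` to exclude low-support calls before counting.
    """
    per_sample = records_from_frame(df)
    catalogs = {}
    for sid, recs in per_sample.items():
        if min_vaf is not None:
            recs = [r for r in recs if r.vaf is not None and r.vaf >= min_vaf]
        if min_depth is not None:
            recs = [r for r in recs if r.depth is not None and r.depth >= min_depth]
        if genome is not None:
            recs = fill_context(recs, genome)
        catalogs[sid] = build_catalog(recs, sid)
    return catalogs


def catalogs_to_frame(
    catalogs: Mapping[str, MutationCatalog96], min_tmb: int = DEFAULT_MIN_TMB
) -> pd.DataFrame:
    """One row per sample: 96 channel columns plus TMB and f_deam."""
    rows = []
    for sid, cat in catalogs.items():
        row = {"sample": sid}
        row.update(dict(zip(CHANNELS_96, cat.counts.tolist())))
        row["TMB"] = cat.tmb
        row["f_deam"] = cat.fdeam(min_tmb=min_tmb)
        rows.append(row)
    return pd.DataFrame(rows)


def write_catalogs(catalogs, path, min_tmb: int = DEFAULT_MIN_TMB) -> None:
    catalogs_to_frame(catalogs, min_tmb=min_tmb).to_csv(path, sep="\t", index=False)


def read_catalogs(path) -> dict[str, MutationCatalog96]:
    """Read back a catalog TSV written by :func:`write_catalogs`."""
    df = pd.read_csv(path, sep="\t")
    counts = df[list(CHANNELS_96)].to_numpy(dtype=np.int64)
    return {
        str(sid): MutationCatalog96(str(sid), counts[i])
        for i, sid in enumerate(df["sample"])
    }
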