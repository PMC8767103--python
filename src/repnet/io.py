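"""Ingestion of clonotype tables, sample manifests and clinical tables.

Clonotype tables are tab-separated exports of an RNA-seq immune-repertoire
extraction run (MiXCR-style by default, AIRR-rearrangement-style as a second
built-in dialect). Sample identifiers follow the TCGA barcode convention,
whose fourth field encodes the sample type (01 primary tumor, 06 metastatic,
11 adjacent non-tumor) and the vial letter.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError

IG_CHAINS = ("IGH", "IGK", "IGL")

_SAMPLE_TYPE_CLASSES = {
    "01": "primary_tumor",
    "06": "metastatic",
    "11": "adjacent_non_tumor",
}

_CDR3_RE = re.compile(r"^[ACGT]+$")
_BARCODE_RE = re.compile(r"^(\d{2})([A-Z])$")


@dataclass(frozen=True)
class ClonotypeRecord:
    """One aligned BCR clonotype row in one sample."""

    sample_id: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    read_count: int


@dataclass(frozen=True)
class BarcodeInfo:
    project: str
    participant_id: str
    sample_type_code: str
    vial: str

    @property
    def sample_class(self) -> str:
        return _SAMPLE_TYPE_CLASSES.get(self.sample_type_code, "other")


@dataclass(frozen=True)
class SampleManifestEntry:
    sample_id: str
    tumor_type: str
    total_reads: int


@dataclass(frozen=True)
class ClinicalRecord:
    participant_id: str
    age_at_diagnosis: float | None = None
    sex: str | None = None                # "female" / "male"
    stage_group: str | None = None        # "early" (I-II) / "late" (III-IV)
    os_time: float | None = None
    os_event: int | None = None
    subtype: str | None = None
    mutation_load: float | None = None


@dataclass(frozen=True)
class Dialect:
    """Mapping of logical clonotype fields to column names.

    ``chain`` may be None, in which case the chain is derived from the
    locus prefix of the collapsed V gene (first three characters).
    """

    v_hits: str
    j_hits: str
    cdr3_nt: str
    count: str
    chain: str | None = None


MIXCR_DIALECT = Dialect(
    chain="chain",
    v_hits="allVHitsWithScore",
    j_hits="allJHitsWithScore",
    cdr3_nt="nSeqCDR3",
    count="cloneCount",
)

AIRR_DIALECT = Dialect(
    v_hits="v_call",
    j_hits="j_call",
    cdr3_nt="junction",
    count="duplicate_count",
)

DIALECTS = {"mixcr": MIXCR_DIALECT, "airr": AIRR_DIALECT}


def collapse_gene_hit(hits: str) -> str:
    """Collapse a V/J hit string to a single gene-level identifier.

    Takes the first (top-scoring) comma-separated hit, then strips the
    ``*nn`` allele suffix and any parenthesised alignment score, e.g.
    ``"IGHV3-23*00(1250),IGHV3-30*00(900)"`` -> ``"IGHV3-23"``.
    """
    first = hits.split(",")[0].strip()
    first = re.sub(r"\(.*?\)", "", first)
    first = first.split("*")[0]
    return first.strip()


def parse_clonotype_table(
    source,
    sample_id: str,
    dialect: Dialect = MIXCR_DIALECT,
) -> list[ClonotypeRecord]:
    """Parse one sample's clonotype table into records.

    Rows with a missing or non-ACGT CDR3 are dropped, as are rows whose
    chain is not one of IGH/IGK/IGL (TCR chains are not analyzed). V/J hits
    are collapsed to gene level. A missing mapped column raises
    :class:`FormatError`; a non-integer count raises :class:`FormatError`
    naming the offending row.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    needed = [dialect.v_hits, dialect.j_hits, dialect.cdr3_nt, dialect.count]
    if dialect.chain is not None:
        needed.append(dialect.chain)
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"clonotype table is missing column {col!r}")

    records: list[ClonotypeRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        cdr3 = row[dialect.cdr3_nt].strip().upper()
        if not _CDR3_RE.match(cdr3):
            continue  # missing or ambiguous CDR3
        v_gene = collapse_gene_hit(row[dialect.v_hits])
        j_gene = collapse_gene_hit(row[dialect.j_hits])
        chain = (
            row[dialect.chain].strip().upper()
            if dialect.chain is not None
            else v_gene[:3].upper()
        )
        if chain not in IG_CHAINS:
            continue
        if not (v_gene.startswith(chain + "V") and j_gene.startswith(chain + "J")):
            continue  # V/J locus inconsistent with the declared chain
        raw_count = row[dialect.count].strip()
        try:
            count = int(float(raw_count)) if raw_count else 0
            if float(raw_count) != count:
                raise ValueError
        except ValueError:
            raise FormatError(
                f"row {idx}: count {raw_count!r} is not an integer"
            ) from None
        if count < 1:
            continue
        records.append(
            ClonotypeRecord(
                sample_id=sample_id,
                chain=chain,
                v_gene=v_gene,
                j_gene=j_gene,
                cdr3_nt=cdr3,
                read_count=count,
            )
        )
    return records


def write_clonotype_table(
    records: Iterable[ClonotypeRecord],
    target,
    dialect: Dialect = MIXCR_DIALECT,
) -> None:
    """Write records in the given dialect (round-trips with the parser)."""
    rows = []
    for rec in records:
        row = {
            dialect.v_hits: rec.v_gene,
            dialect.j_hits: rec.j_gene,
            dialect.cdr3_nt: rec.cdr3_nt,
            dialect.count: rec.read_count,
        }
        if dialect.chain is not None:
            row[dialect.chain] = rec.chain
        rows.append(row)
    cols = ([dialect.chain] if dialect.chain else []) + [
        dialect.v_hits, dialect.j_hits, dialect.cdr3_nt, dialect.count
    ]
    pd.DataFrame(rows, columns=cols).to_csv(target, sep="\t", index=False)


def parse_tcga_barcode(barcode: str) -> BarcodeInfo:
    """Split a TCGA-style barcode into project, participant, type and vial.

    The fourth dash-separated field must be two digits plus one letter
    (e.g. ``01A``); further fields (portion, analyte, plate...) are ignored.
    """
    fields = barcode.strip().split("-")
    if len(fields) < 4:
        raise FormatError(f"barcode {barcode!r} has fewer than 4 fields")
    m = _BARCODE_RE.match(fields[3])
    if not m:
        raise FormatError(
            f"barcode {barcode!r}: 4th field {fields[3]!r} is not "
            "two digits + one letter"
        )
    return BarcodeInfo(
        project=fields[0],
        participant_id="-".join(fields[:3]),
        sample_type_code=m.group(1),
        vial=m.group(2),
    )


def select_cohort(
    manifest: Sequence[SampleManifestEntry],
    include_metastatic_for: Iterable[str] = (),
) -> list[SampleManifestEntry]:
    """Apply the cohort sample-selection rules.

    Keeps primary-tumor and adjacent-non-tumor samples; metastatic samples
    are kept only for tumor types in ``include_metastatic_for`` (melanoma in
    the original cohort). When a participant has several vials of the same
    sample type, only the alphabetically first vial is retained.
    """
    met_ok = set(include_metastatic_for)
    eligible: list[tuple[BarcodeInfo, SampleManifestEntry]] = []
    for entry in manifest:
        info = parse_tcga_barcode(entry.sample_id)
        cls = info.sample_class
        if cls in ("primary_tumor", "adjacent_non_tumor") or (
            cls == "metastatic" and entry.tumor_type in met_ok
        ):
            eligible.append((info, entry))

    best: dict[tuple[str, str], tuple[str, SampleManifestEntry]] = {}
    for info, entry in eligible:
        key = (info.participant_id, info.sample_type_code)
        if key not in best or info.vial < best[key][0]:
            best[key] = (info.vial, entry)
    chosen = {id(entry) for _, entry in best.values()}
    return [entry for _, entry in eligible if id(entry) in chosen]


def clinical_frame(clinical: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a participant-keyed DataFrame (unique key enforced)."""
    df = pd.DataFrame([vars(rec) for rec in clinical])
    if df.empty:
        df = pd.DataFrame(columns=list(ClinicalRecord.__dataclass_fields__))
    dupes = df["participant_id"][df["participant_id"].duplicated()]
    if not dupes.empty:
        raise IntegrityError(
            f"duplicate participant_id in clinical table: {sorted(set(dupes))}"
        )
    return df


def join_clinical(
    features: pd.DataFrame,
    clinical: Sequence[ClinicalRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Left-join clinical covariates onto a sample-keyed feature table.

    The join key is the participant id (first three barcode fields of
    ``sample_id``). Samples without a clinical match keep missing covariates.
    Duplicate participant rows in the clinical table raise
    :class:`IntegrityError`.
    """
    if isinstance(clinical, pd.DataFrame):
        dupes = clinical["participant_id"][clinical["participant_id"].duplicated()]
        if not dupes.empty:
            raise IntegrityError(
                f"duplicate participant_id in clinical table: {sorted(set(dupes))}"
            )
        cdf = clinical
    else:
        cdf = clinical_frame(clinical)
    out = features.copy()
    out["participant_id"] = [
        parse_tcga_barcode(s).participant_id for s in out["sample_id"]
    ]
    return out.merge(cdf, on="participant_id", how="left")


# ---------------------------------------------------------------------------
# File-level helpers used by the command-line interface


def load_manifest(path) -> list[SampleManifestEntry]:
    """Read a manifest TSV with columns sample_id, tumor_type, total_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tumor_type": str})
    for col in ("sample_id", "tumor_type", "total_reads"):
        if col not in df.columns:
            raise FormatError(f"manifest is missing column {col!r}")
    return [
        SampleManifestEntry(r.sample_id, r.tumor_type, int(r.total_reads))
        for r in df.itertuples(index=False)
    ]


def load_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical TSV; unknown columns are ignored, missing ones are None."""
    df = pd.read_csv(path, sep="\t")
    if "participant_id" not in df.columns:
        raise FormatError("clinical table is missing column 'participant_id'")
    fields = [f for f in ClinicalRecord.__dataclass_fields__ if f in df.columns]
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for f in fields:
            val = getattr(row, f)
            kwargs[f] = None if pd.isna(val) else val
        if kwargs.get("os_event") is not None:
            kwargs["os_event"] = int(kwargs["os_event"])
        records.append(ClinicalRecord(**kwargs))
    return records


def normalize_stage(stage: str | None) -> str | None:
    """Collapse sub-stages to early (I-II) / late (III-IV); X/missing -> None."""
    if stage is None or (isinstance(stage, float) and pd.isna(stage)):
        return None
    s = str(stage).upper().replace("STAGE", "").strip()
    s = re.sub(r"[ABC]\d?$", "", s)
    if s in ("I", "II"):
        return "early"
    if s in ("III", "IV"):
        return "late"
    if s in ("EARLY", "LATE"):
        return s.lower()
    return None
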