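"""Data model and readers/writers for the longitudinal plasma variant pipeline.

All variant coordinates are 1-based (VCF convention); BED inputs are converted
at the boundary and every internal comparison uses 1-based closed positions.
Chromosome names are normalized to the "chr"-prefixed dialect on read.
Variant tables, manifests and signature matrices are plain TSV; "." marks an
absent value.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._genome import CHANNELS

log = logging.getLogger("ctlong")

EXONIC_FUNCTIONS = ("nonsynonymous", "stopgain", "stoploss", "synonymous", "unknown", "other")
SAMPLE_CLASSES = ("tumour", "plasma", "germline", "cp_control")

REQUIRED_VARIANT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "sample_id",
    "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "mean_alt_bq",
)
ANNOTATION_COLUMNS = (
    "cosmic_id", "dbsnp_id", "exonic_function",
    "af_1000g", "af_gnomad", "af_hapmap", "gene", "driver_class", "biomarker",
)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A record violates a type invariant."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(slots=True)
class AnnotationRecord:
    """External annotations attached to one variant (consumed as input columns)."""

    cosmic_id: str | None = None
    dbsnp_id: str | None = None
    exonic_function: str | None = None
    af_1000g: float | None = None
    af_gnomad: float | None = None
    af_hapmap: float | None = None
    gene: str | None = None
    driver_class: str | None = None
    biomarker: str | None = None

    def __post_init__(self) -> None:
        for name in ("af_1000g", "af_gnomad", "af_hapmap"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")

    @property
    def population_afs(self) -> tuple[float | None, float | None, float | None]:
        return (self.af_1000g, self.af_gnomad, self.af_hapmap)


@dataclass(slots=True)
class VariantRecord:
    """One candidate variant at one locus in one sample.

    Read support is held per strand; ``depth`` and ``vaf`` are derived.
    ``flags`` accumulates filter-stage labels; ``extra`` passes unknown table
    columns through unmodified.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int
    mean_alt_bq: float
    annotations: AnnotationRecord = field(default_factory=AnnotationRecord)
    flags: set = field(default_factory=set)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.pos = int(self.pos)
        self.ref = str(self.ref).upper()
        self.alt = str(self.alt).upper()
        if self.pos < 1:
            raise ValidationError(f"pos={self.pos} < 1")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for name in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
            v = int(getattr(self, name))
            if v < 0:
                raise ValidationError(f"{name}={v} negative at {self.chrom}:{self.pos}")
            setattr(self, name, v)
        self.mean_alt_bq = float(self.mean_alt_bq)
        if not self.is_snv:
            self.flags.add("unsupported")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"

    @property
    def depth(self) -> int:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Sample-independent variant identity (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def copy(self) -> "VariantRecord":
        return replace(self, annotations=replace(self.annotations),
                       flags=set(self.flags), extra=dict(self.extra))


@dataclass(slots=True)
class SampleMeta:
    """One sequenced sample: who, when, and what kind."""

    patient_id: str
    sample_id: str
    sample_class: str
    timepoint_label: str | None = None
    day: int | None = None
    target_depth: int | None = None

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValidationError(
                f"sample_class {self.sample_class!r} not in {SAMPLE_CLASSES}")


class IntervalSet:
    """Half-open 0-based genomic intervals with O(log n) membership queries.

    Overlapping or book-ended intervals are merged on construction, which
    leaves membership semantics unchanged and lets queries bisect a sorted,
    disjoint list per chromosome.
    """

    def __init__(self, intervals: list[tuple[str, int, int]] | None = None):
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals or []:
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(f"interval start {start} >= end {end}")
            raw.setdefault(normalize_chrom(chrom), []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._n = 0
        for chrom, ivs in raw.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]
            self._n += len(merged)

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        for chrom in sorted(self._starts):
            yield from ((chrom, s, e)
                        for s, e in zip(self._starts[chrom], self._ends[chrom]))

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` lies inside any interval."""
        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return False
        zero = pos - 1  # convert to the stored 0-based system
        i = bisect.bisect_right(starts, zero) - 1
        return i >= 0 and zero < self._ends[chrom][i]


def _absent(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or \
        str(value).strip() in (".", "", "nan", "NA")


def _parse_annotations(row: dict) -> AnnotationRecord:
    kw = {}
    for col in ANNOTATION_COLUMNS:
        v = row.get(col)
        if _absent(v):
            continue
        if col.startswith("af_"):
            kw[col] = float(v)
        else:
            kw[col] = str(v)
    fn = kw.get("exonic_function")
    if fn is not None and fn not in EXONIC_FUNCTIONS:
        kw["exonic_function"] = "other"
    return AnnotationRecord(**kw)


def read_variant_table(path) -> list[VariantRecord]:
    """Read a TSV variant table into validated :class:`VariantRecord` objects.

    Required columns: chrom, pos, ref, alt, sample_id, ref_fwd, ref_rev,
    alt_fwd, alt_rev, mean_alt_bq. Recognized annotation columns populate
    :class:`AnnotationRecord`; any other column is preserved in ``extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    other = [c for c in df.columns
             if c not in REQUIRED_VARIANT_COLUMNS and c not in ANNOTATION_COLUMNS]
    records = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            rec = VariantRecord(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                alt=row["alt"], sample_id=row["sample_id"],
                ref_fwd=int(row["ref_fwd"]), ref_rev=int(row["ref_rev"]),
                alt_fwd=int(row["alt_fwd"]), alt_rev=int(row["alt_rev"]),
                mean_alt_bq=float(row["mean_alt_bq"]),
                annotations=_parse_annotations(row),
                extra={c: row[c] for c in other if not _absent(row[c])},
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
        records.append(rec)
    log.info("read_variant_table: %s -> %d records", path, len(records))
    return records


def write_variant_table(records: list[VariantRecord], path) -> None:
    """Write records as TSV, the inverse of :func:`read_variant_table`."""
    extra_cols = sorted({c for r in records for c in r.extra})
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "sample_id": r.sample_id, "ref_fwd": r.ref_fwd, "ref_rev": r.ref_rev,
            "alt_fwd": r.alt_fwd, "alt_rev": r.alt_rev,
            "mean_alt_bq": f"{r.mean_alt_bq:.6g}",
        }
        a = r.annotations
        for col in ANNOTATION_COLUMNS:
            v = getattr(a, col)
            if v is None:
                row[col] = "."
            elif col.startswith("af_"):
                row[col] = f"{v:.6g}"
            else:
                row[col] = v
        for c in extra_cols:
            row[c] = r.extra.get(c, ".")
        rows.append(row)
    cols = list(REQUIRED_VARIANT_COLUMNS) + list(ANNOTATION_COLUMNS) + extra_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    log.info("write_variant_table: %d records -> %s", len(records), path)


def read_blacklist(path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into an :class:`IntervalSet`."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED line with <3 columns: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    out = IntervalSet(intervals)
    log.info("read_blacklist: %s -> %d merged intervals", path, len(out))
    return out


def write_blacklist(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a COSMIC-style 96xS signature matrix.

    Rows are keyed by channel labels like ``A[C>A]A`` and reordered to the
    canonical channel order; each column must sum to 1 within 1e-3 and is
    renormalized to sum exactly to 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate channel label {dup!r}")
    if set(df.index) != set(CHANNELS):
        raise FormatError(
            f"{path}: expected the 96 trinucleotide channels, got {len(df.index)} rows")
    df = df.loc[list(CHANNELS)].astype(float)
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-3]
    if len(bad):
        raise FormatError(
            f"{path}: column(s) {list(bad.index)} sum to {bad.values} (not 1 within 1e-3)")
    df = df / sums
    log.info("read_signature_matrix: %s -> 96x%d", path, df.shape[1])
    return df


def write_signature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="channel")


def read_manifest(path) -> list[SampleMeta]:
    """Read a sample manifest TSV and check per-patient invariants.

    Every patient with tumour or plasma samples must have exactly one matched
    germline; a patient's plasma samples must carry strictly increasing days.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("patient_id", "sample_id", "sample_class")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    metas = []
    for row in df.to_dict("records"):
        metas.append(SampleMeta(
            patient_id=row["patient_id"], sample_id=row["sample_id"],
            sample_class=row["sample_class"],
            timepoint_label=None if _absent(row.get("timepoint_label"))
            else row["timepoint_label"],
            day=None if _absent(row.get("day")) else int(row["day"]),
            target_depth=None if _absent(row.get("target_depth"))
            else int(row["target_depth"]),
        ))
    validate_manifest(metas)
    log.info("read_manifest: %s -> %d samples", path, len(metas))
    return metas


def validate_manifest(metas: list[SampleMeta]) -> None:
    by_patient: dict[str, list[SampleMeta]] = {}
    for m in metas:
        by_patient.setdefault(m.patient_id, []).append(m)
    for pid, group in by_patient.items():
        germ = [m for m in group if m.sample_class == "germline"]
        somatic = [m for m in group if m.sample_class in ("tumour", "plasma")]
        if len(germ) > 1:
            raise ValidationError(f"patient {pid}: {len(germ)} germline samples (expected 1)")
        if somatic and not germ:
            raise ValidationError(f"patient {pid}: tumour/plasma samples but no germline")
        days = [m.day for m in group if m.sample_class == "plasma" and m.day is not None]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"patient {pid}: plasma days not strictly increasing: {days}")


def write_manifest(metas: list[SampleMeta], path) -> None:
    rows = [{
        "patient_id": m.patient_id, "sample_id": m.sample_id,
        "sample_class": m.sample_class,
        "timepoint_label": m.timepoint_label or ".",
        "day": "." if m.day is None else m.day,
        "target_depth": "." if m.target_depth is None else m.target_depth,
    } for m in metas]
    cols = ["patient_id", "sample_id", "sample_class", "timepoint_label", "day", "target_depth"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
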