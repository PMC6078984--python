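"""Typed readers and writers for every external table the pipeline touches.

All tabular formats are plain TSV/CSV (MAF-like mutation tables, SEG
segments, probe-level log2-ratio tables, expression and clinical tables,
and the 96-context signature reference).  Readers validate strictly and
enumerate every rejected row; writers produce files that round-trip
losslessly through the corresponding reader.

Conventions: coordinates are 1-based inclusive; chromosome labels are
normalised by stripping any ``chr`` prefix and mapping ``23``/``24`` to
``X``/``Y``; missing values are written as ``.``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, fields as _dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS, canonicalize_label

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "splice", "frameshift", "inframe_indel",
     "synonymous", "noncoding"}
)

#: translation of common foreign consequence vocabularies (MAF-style)
DEFAULT_CONSEQUENCE_DIALECT = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "splice_site": "splice",
    "splice_region": "splice",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "silent": "synonymous",
    "igr": "noncoding",
    "intron": "noncoding",
    "3'utr": "noncoding",
    "5'utr": "noncoding",
    "rna": "noncoding",
}

_MISSING = {"", "."}


class SchemaError(ValueError):
    """A table is structurally unusable (missing column, wrong shape)."""


class RowError(ValueError):
    """One or more rows failed validation; ``errors`` lists (line, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        msgs = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {msgs}{more}")


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    if c == "24":
        c = "Y"
    if not c:
        raise ValueError("empty chromosome label")
    return c


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MutationRecord:
    """One somatic variant call."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    protein_change: str | None = None
    vaf: float | None = None
    in_known_db: bool | None = None

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.ref = str(self.ref).upper()
        self.alt = str(self.alt).upper()
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.vaf is not None:
            self.vaf = float(self.vaf)
            if not 0.0 <= self.vaf <= 1.0:
                raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and "-" not in (self.ref, self.alt)


@dataclass
class SegmentRecord:
    """One copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    log2_ratio: float
    copy_number: int | None = None

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.start, self.end = int(self.start), int(self.end)
        self.n_probes = int(self.n_probes)
        self.log2_ratio = float(self.log2_ratio)
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProbeSeries:
    """Ordered probe-level log2 ratios (and optional BAFs) for one sample."""

    sample_id: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    log2_ratio: dict[str, np.ndarray] = field(default_factory=dict)
    b_allele_freq: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
            if len(pos) != len(self.log2_ratio[chrom]):
                raise ValueError(f"positions/log2 length mismatch on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)


@dataclass
class ClinicalRecord:
    """Group label, covariates and survival endpoints for one patient."""

    patient_id: str
    group: str
    age_at_diagnosis: float
    date_of_diagnosis: _dt.date
    pathological_stage: int
    subtype_ihc: str
    er_status: str
    pr_status: str
    dfs_time: float
    os_time: float
    dfs_event: int
    os_event: int

    def __post_init__(self):
        if self.group not in ("BCP", "control"):
            raise ValueError(f"group must be BCP or control, got {self.group!r}")
        if isinstance(self.date_of_diagnosis, str):
            self.date_of_diagnosis = _dt.date.fromisoformat(self.date_of_diagnosis)
        for name in ("dfs_time", "os_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dfs_event", "os_event"):
            v = int(getattr(self, name))
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0/1")
            setattr(self, name, v)
        if self.er_status not in ("pos", "neg") or self.pr_status not in ("pos", "neg"):
            raise ValueError("er_status/pr_status must be pos/neg")


class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        self.values = values.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def __eq__(self, other):
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


class SignatureReference:
    """96-context probability matrix, one column per reference signature."""

    def __init__(self, matrix: pd.DataFrame):
        if list(matrix.index) != list(CONTEXT_LABELS):
            raise ValueError("signature matrix must be indexed by the 96 canonical contexts")
        arr = matrix.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("signature matrix contains negative entries")
        sums = arr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = matrix.columns[np.abs(sums - 1.0) > 1e-3].tolist()
            raise ValueError(f"signature column(s) do not sum to 1: {bad}")
        self.matrix = matrix / sums  # renormalise within tolerance

    @property
    def signatures(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    def __eq__(self, other):
        return (
            isinstance(other, SignatureReference)
            and list(self.signatures) == list(other.signatures)
            and np.allclose(self.matrix.to_numpy(), other.matrix.to_numpy(), atol=1e-9)
        )


# ---------------------------------------------------------------------------
# helpers


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _opt(value: str):
    return None if value in _MISSING else value


# ---------------------------------------------------------------------------
# mutation tables


def read_mutation_table(path, dialect: dict[str, str] | None = None) -> list[MutationRecord]:
    """Read a MAF-like TSV of somatic variants.

    *dialect* maps foreign consequence spellings onto the fixed vocabulary;
    it is merged over the MAF defaults.  Rejected rows abort the read with a
    :class:`RowError` enumerating every offending line.
    """
    df = _read_tsv(path)
    _require_columns(
        df, ["patient_id", "chrom", "pos", "ref", "alt", "gene", "consequence"],
        "mutation table",
    )
    cmap = dict(DEFAULT_CONSEQUENCE_DIALECT)
    if dialect:
        cmap.update({k.lower(): v for k, v in dialect.items()})
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            raw_cons = str(row.consequence)
            cons = raw_cons if raw_cons in CONSEQUENCES else cmap.get(raw_cons.lower())
            if cons is None:
                raise ValueError(f"unknown consequence {raw_cons!r}")
            try:
                pos = int(row.pos)
            except ValueError:
                raise ValueError(f"malformed coordinate {row.pos!r}")
            vaf = _opt(getattr(row, "vaf", "."))
            known = _opt(getattr(row, "in_known_db", "."))
            records.append(
                MutationRecord(
                    patient_id=row.patient_id,
                    chrom=row.chrom,
                    pos=pos,
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    consequence=cons,
                    protein_change=_opt(getattr(row, "protein_change", ".")),
                    vaf=None if vaf is None else float(vaf),
                    in_known_db=None if known is None else known.lower() in ("1", "true"),
                )
            )
        except ValueError as e:
            errors.append((line, str(e)))
    if errors:
        raise RowError(errors)
    return records


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    mutations_to_frame(records).to_csv(path, sep="\t", index=False)


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                patient_id=r.patient_id, chrom=r.chrom, pos=r.pos, ref=r.ref,
                alt=r.alt, gene=r.gene, consequence=r.consequence,
                protein_change=r.protein_change if r.protein_change else ".",
                vaf="." if r.vaf is None else f"{r.vaf:.17g}",
                in_known_db="." if r.in_known_db is None else str(r.in_known_db).lower(),
            )
        )
    cols = [f.name for f in _dc_fields(MutationRecord)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# segments


def read_segment_table(path) -> list[SegmentRecord]:
    """Read a SEG-style TSV; per-sample segments must be non-overlapping."""
    df = _read_tsv(path)
    _require_columns(
        df, ["sample_id", "chrom", "start", "end", "n_probes", "log2_ratio"],
        "segment table",
    )
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            cn = _opt(getattr(row, "copy_number", "."))
            records.append(
                SegmentRecord(
                    sample_id=row.sample_id, chrom=row.chrom,
                    start=int(row.start), end=int(row.end),
                    n_probes=int(row.n_probes), log2_ratio=float(row.log2_ratio),
                    copy_number=None if cn is None else int(cn),
                )
            )
        except ValueError as e:
            errors.append((line, str(e)))
    if errors:
        raise RowError(errors)
    _check_segment_overlap(records)
    return records


def _check_segment_overlap(records: list[SegmentRecord]):
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.chrom), []).append(r)
    bad = []
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                bad.append(f"{sample} {chrom}:{a.start}-{a.end} overlaps {b.start}-{b.end}")
    if bad:
        raise ValueError("overlapping segments: " + "; ".join(bad[:5]))


def write_segment_table(records: Iterable[SegmentRecord], path) -> None:
    segments_to_frame(records).to_csv(path, sep="\t", index=False)


def segments_to_frame(records: Iterable[SegmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_id=r.sample_id, chrom=r.chrom, start=r.start, end=r.end,
                n_probes=r.n_probes, log2_ratio=f"{r.log2_ratio:.17g}",
                copy_number="." if r.copy_number is None else r.copy_number,
            )
            for r in records
        ],
        columns=["sample_id", "chrom", "start", "end", "n_probes", "log2_ratio", "copy_number"],
    )


# ---------------------------------------------------------------------------
# probes


def read_probe_table(path) -> dict[str, ProbeSeries]:
    """Read a probe-level TSV (sample_id, chrom, pos, log2_ratio[, baf])."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "chrom", "pos", "log2_ratio"], "probe table")
    has_baf = "baf" in df.columns
    out: dict[str, ProbeSeries] = {}
    df = df.assign(pos=df["pos"].astype(int), log2_ratio=df["log2_ratio"].astype(float))
    for sample, sdf in df.groupby("sample_id", sort=False):
        positions, log2, baf = {}, {}, {}
        for chrom, cdf in sdf.groupby("chrom", sort=False):
            chrom = normalize_chrom(chrom)
            positions[chrom] = cdf["pos"].to_numpy()
            log2[chrom] = cdf["log2_ratio"].to_numpy()
            if has_baf:
                baf[chrom] = cdf["baf"].replace(".", "nan").astype(float).to_numpy()
        out[sample] = ProbeSeries(
            sample_id=sample, positions=positions, log2_ratio=log2,
            b_allele_freq=baf if has_baf else None,
        )
    return out


def write_probe_table(series: Iterable[ProbeSeries], path) -> None:
    frames = []
    for ps in series:
        for chrom in ps.chromosomes:
            f = pd.DataFrame(
                dict(
                    sample_id=ps.sample_id, chrom=chrom,
                    pos=ps.positions[chrom],
                    log2_ratio=[f"{v:.17g}" for v in ps.log2_ratio[chrom]],
                )
            )
            if ps.b_allele_freq is not None:
                f["baf"] = [f"{v:.17g}" for v in ps.b_allele_freq[chrom]]
            frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical and expression


_CLINICAL_COLUMNS = [
    "patient_id", "group", "age_at_diagnosis", "date_of_diagnosis",
    "pathological_stage", "subtype_ihc", "er_status", "pr_status",
    "dfs_time", "os_time", "dfs_event", "os_event",
]


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = _read_tsv(path)
    _require_columns(df, _CLINICAL_COLUMNS, "clinical table")
    dup = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dup))}")
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            records.append(
                ClinicalRecord(
                    patient_id=row.patient_id, group=row.group,
                    age_at_diagnosis=float(row.age_at_diagnosis),
                    date_of_diagnosis=row.date_of_diagnosis,
                    pathological_stage=int(row.pathological_stage),
                    subtype_ihc=row.subtype_ihc,
                    er_status=row.er_status, pr_status=row.pr_status,
                    dfs_time=float(row.dfs_time), os_time=float(row.os_time),
                    dfs_event=int(row.dfs_event), os_event=int(row.os_event),
                )
            )
        except ValueError as e:
            errors.append((line, str(e)))
    if errors:
        raise RowError(errors)
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path) -> None:
    clinical_to_frame(records).to_csv(path, sep="\t", index=False)


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                patient_id=r.patient_id, group=r.group,
                age_at_diagnosis=f"{r.age_at_diagnosis:.17g}",
                date_of_diagnosis=r.date_of_diagnosis.isoformat(),
                pathological_stage=r.pathological_stage, subtype_ihc=r.subtype_ihc,
                er_status=r.er_status, pr_status=r.pr_status,
                dfs_time=f"{r.dfs_time:.17g}", os_time=f"{r.os_time:.17g}",
                dfs_event=r.dfs_event, os_event=r.os_event,
            )
            for r in records
        ],
        columns=_CLINICAL_COLUMNS,
    )


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.round(6).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# signature reference


def read_signature_reference(path) -> SignatureReference:
    """Read a 96-row CSV of context probabilities, one column per signature."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != 96:
        raise SchemaError(f"signature reference must have 96 rows, got {df.shape[0]}")
    try:
        df.index = [canonicalize_label(lab) for lab in df.index]
    except ValueError as e:
        raise SchemaError(str(e)) from e
    if len(set(df.index)) != 96:
        raise SchemaError("duplicate context labels in signature reference")
    df = df.loc[list(CONTEXT_LABELS)]
    return SignatureReference(df)


def write_signature_reference(ref: SignatureReference, path) -> None:
    ref.matrix.round(8).to_csv(path)
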