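"""Per-sample mutation burdens, the co-mutation frequency table, and the
MATH intra-tumor heterogeneity score.

Non-silent mutations are the protein-altering and splice-affecting classes
(missense, nonsense, splice, frameshift, in-frame indel); synonymous and
noncoding variants are silent.  MATH is the median absolute deviation of the
variant allele fractions divided by their median, computed over all
mutations with a VAF (coding and noncoding alike).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalRecord, MutationRecord
from .stats import ComparisonResult, adjusted_association, mann_whitney

logger = logging.getLogger(__name__)

NON_SILENT = frozenset({"missense", "nonsense", "splice", "frameshift", "inframe_indel"})

#: normal-consistency x percent scaling used by the original MATH publication
MATH_PUBLISHED_SCALE = 1.4826 * 100.0


def classify_non_silent(record: MutationRecord) -> bool:
    """True iff the variant is protein-altering or splice-affecting."""
    return record.consequence in NON_SILENT


def math_score(vafs, scaled: bool = False) -> float:
    """MATH = MAD(VAFs) / median(VAFs).

    Uses the raw median absolute deviation (no 1.4826 consistency constant,
    no x100) by default; ``scaled=True`` applies the original published
    scaling for cross-tool comparison.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size == 0:
        raise ValueError("math_score requires at least one VAF")
    med = float(np.median(v))
    if med <= 0:
        raise ValueError("median VAF is zero; MATH undefined")
    mad = float(np.median(np.abs(v - med)))
    score = mad / med
    return score * MATH_PUBLISHED_SCALE if scaled else score


@dataclass
class SampleCatalog:
    """All variants of one tumor plus derived burden metrics.

    ``n_snv`` may exceed the number of stored SNV records when the catalog
    was built from a summarised source (e.g. the simulator materialises all
    coding mutations but only a capped sample of the genome-wide ones); by
    default it is derived from the records.
    """

    patient_id: str
    records: list[MutationRecord] = field(default_factory=list)
    n_snv: int | None = None
    n_indel: int | None = None

    def __post_init__(self):
        if self.n_snv is None:
            self.n_snv = sum(1 for r in self.records if r.is_snv)
        if self.n_indel is None:
            self.n_indel = sum(1 for r in self.records if not r.is_snv)

    @property
    def n_nonsilent(self) -> int:
        return sum(1 for r in self.records if classify_non_silent(r))

    @property
    def n_known_db(self) -> int:
        return sum(1 for r in self.records if r.in_known_db)

    def vafs(self) -> np.ndarray:
        v = [r.vaf for r in self.records if r.vaf is not None]
        n_missing = len(self.records) - len(v)
        if n_missing:
            logger.info(
                "%s: %d record(s) without VAF excluded from MATH", self.patient_id, n_missing
            )
        return np.asarray(v, dtype=float)

    @property
    def math_score(self) -> float:
        return math_score(self.vafs())

    def metric(self, name: str) -> float:
        if name not in ("n_snv", "n_nonsilent", "n_known_db", "math_score", "n_indel"):
            raise ValueError(f"unknown burden metric {name!r}")
        return float(getattr(self, name))


def catalogs_from_records(records: list[MutationRecord]) -> dict[str, SampleCatalog]:
    by_patient: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return {pid: SampleCatalog(pid, recs) for pid, recs in by_patient.items()}


def gene_frequency_table(
    catalogs: dict[str, SampleCatalog],
    groups: dict[str, str] | None = None,
    min_freq: float = 0.05,
) -> pd.DataFrame:
    """Genes with a non-silent mutation in at least ``min_freq`` of patients.

    Carrier semantics: a patient counts once per gene regardless of how many
    mutations it harbors.  The closed bound retains genes exactly at the
    threshold.  Rows are sorted by overall frequency (descending), ties by
    gene name.
    """
    if not catalogs:
        raise ValueError("no catalogs supplied")
    n_total = len(catalogs)
    carriers: dict[str, set[str]] = {}
    for pid, cat in catalogs.items():
        for r in cat.records:
            if classify_non_silent(r):
                carriers.setdefault(r.gene, set()).add(pid)
    rows = []
    group_ids: dict[str, set[str]] = {}
    if groups:
        for pid, g in groups.items():
            group_ids.setdefault(g, set()).add(pid)
    for gene, pids in carriers.items():
        freq = len(pids) / n_total
        if freq < min_freq:
            continue
        row = {"gene": gene, "n_carriers": len(pids), "freq": freq}
        for g, members in sorted(group_ids.items()):
            n_g = len(members & set(catalogs))
            row[f"n_{g}"] = len(pids & members)
            row[f"freq_{g}"] = len(pids & members) / n_g if n_g else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["freq", "gene"], ascending=[False, True], ignore_index=True)
    return out


def burden_comparison(
    catalogs: dict[str, SampleCatalog],
    clinical: list[ClinicalRecord] | pd.DataFrame,
    metric: str = "n_nonsilent",
    adjust: bool = True,
) -> ComparisonResult:
    """Compare a burden metric between BCP and controls.

    Reports group medians, the Mann-Whitney p, and (optionally) the
    covariate-adjusted p from the nested linear-model comparison with the
    standard clinicopathological covariates.
    """
    from .io import clinical_to_frame

    if isinstance(clinical, pd.DataFrame):
        cdf = clinical.copy()
    else:
        cdf = clinical_to_frame(clinical)
        cdf["age_at_diagnosis"] = cdf["age_at_diagnosis"].astype(float)
        cdf["pathological_stage"] = cdf["pathological_stage"].astype(int)
    cdf = cdf[cdf["patient_id"].isin(catalogs)].reset_index(drop=True)
    missing = set(catalogs) - set(cdf["patient_id"])
    if missing:
        raise ValueError(f"catalogs without clinical records: {sorted(missing)[:5]}")
    values = np.array([catalogs[p].metric(metric) for p in cdf["patient_id"]])
    is_bcp = (cdf["group"] == "BCP").to_numpy()
    if is_bcp.all() or (~is_bcp).all():
        raise ValueError("both groups must be non-empty")
    res = mann_whitney(values[is_bcp], values[~is_bcp])
    res.test = f"burden[{metric}]:" + res.test
    res.group_summaries = {
        "median_bcp": float(np.median(values[is_bcp])),
        "median_control": float(np.median(values[~is_bcp])),
    }
    if adjust:
        covs = pd.DataFrame(
            {
                "age_at_diagnosis": cdf["age_at_diagnosis"].astype(float),
                "diagnosis_year": pd.to_datetime(cdf["date_of_diagnosis"]).dt.year.astype(float),
                "pathological_stage": cdf["pathological_stage"].astype(float),
                "subtype_ihc": cdf["subtype_ihc"],
            }
        )
        res.adjusted_p = adjusted_association(values, is_bcp.astype(float), covs).p
    return res
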