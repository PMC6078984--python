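"""96-channel spectra, signature refitting, presence calls and the
MMR-deficiency (Signature_20) association analyses.

Refitting solves a non-negative least-squares problem between the
normalised sample spectrum and the reference signature matrix, then
discards exposures below a proportion cutoff (default 6%) and renormalises
the survivors — a convex, deterministic equivalent of the forward-selection
heuristic used by the standard refitting tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import CONTEXT_LABELS, channel
from .genome import ReferenceGenome
from .io import ExpressionMatrix, SegmentRecord, SignatureReference
from .mutations import SampleCatalog
from .stats import bh_fdr, fisher_exact, mann_whitney, spearman

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.06
LOW_COUNT_SNVS = 50
MMR_SIGNATURE = "Signature_20"


@dataclass
class MutationalSpectrum:
    """Counts over the 96 canonical trinucleotide channels for one sample."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("negative channel count")

    @property
    def total_snv(self) -> int:
        return int(round(self.counts.sum()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name=self.sample_id)


@dataclass
class SignatureExposure:
    """Per-sample signature proportions after cutoff, with presence calls."""

    sample_id: str
    proportions: pd.Series
    residual: float
    cutoff: float = DEFAULT_CUTOFF
    low_confidence: bool = False
    presence: pd.Series = field(init=False)

    def __post_init__(self):
        total = float(self.proportions.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"exposures sum to {total}, expected 1")
        self.presence = self.proportions > 0

    def proportion(self, signature: str) -> float:
        if signature not in self.proportions.index:
            raise KeyError(f"unknown signature {signature!r}")
        return float(self.proportions[signature])


def build_spectrum(catalog: SampleCatalog, reference: ReferenceGenome) -> MutationalSpectrum:
    """Map each SNV in the catalog to its trinucleotide channel.

    Purine-reference sites are folded onto the pyrimidine strand; indels are
    excluded.  Reference-base mismatches with the FASTA abort with a list of
    offending records.
    """
    counts = np.zeros(96)
    mismatches = []
    from .contexts import CONTEXT_INDEX

    for r in catalog.records:
        if not r.is_snv:
            continue
        tri = reference.context(r.chrom, r.pos)  # raises outside reference
        if tri[1] != r.ref:
            mismatches.append(f"{r.chrom}:{r.pos} ref {r.ref} != FASTA {tri[1]}")
            continue
        counts[CONTEXT_INDEX[channel(tri, r.ref, r.alt)]] += 1
    if mismatches:
        raise ValueError(
            f"{len(mismatches)} record(s) mismatch the reference: " + "; ".join(mismatches[:5])
        )
    return MutationalSpectrum(catalog.patient_id, counts)


def refit_exposures(
    spectrum: MutationalSpectrum,
    reference: SignatureReference,
    cutoff: float = DEFAULT_CUTOFF,
) -> SignatureExposure:
    """Non-negative least-squares refit of a spectrum onto the reference.

    Weights below ``cutoff`` are zeroed and the survivors renormalised to
    sum one; the reported residual is the L2 distance between the normalised
    spectrum and its reconstruction (before thresholding).  Samples with
    fewer than 50 SNVs are flagged low-confidence.
    """
    total = spectrum.counts.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum cannot be refit")
    target = spectrum.counts / total
    A = reference.matrix.to_numpy()
    w, res = nnls(A, target)
    s = w.sum()
    if s <= 0:
        raise ValueError("degenerate refit: all weights zero")
    w = w / s
    w[w < cutoff] = 0.0
    if w.sum() == 0:
        # keep the dominant signature rather than returning an empty mixture
        w = np.zeros_like(w)
        w[np.argmax(nnls(A, target)[0])] = 1.0
    w = w / w.sum()
    props = pd.Series(w, index=reference.signatures, name=spectrum.sample_id)
    low = total < LOW_COUNT_SNVS
    if low:
        logger.info("%s: only %d SNVs; refit flagged low-confidence", spectrum.sample_id, total)
    return SignatureExposure(
        sample_id=spectrum.sample_id, proportions=props, residual=float(res) / 1.0,
        cutoff=cutoff, low_confidence=low,
    )


def call_presence(exposure: SignatureExposure, signature: str) -> bool:
    """A signature is present iff its post-cutoff proportion is > 0."""
    return exposure.proportion(signature) > 0


def exposures_to_frame(exposures: list[SignatureExposure]) -> pd.DataFrame:
    return pd.DataFrame({e.sample_id: e.proportions for e in exposures}).T


# ---------------------------------------------------------------------------
# Signature_20 association suite


def _gene_call_for(segments: list[SegmentRecord], sample: str, region, threshold=-0.3):
    from .cna import gene_level_call

    segs = [s for s in segments if s.sample_id == sample]
    if not segs:
        return None
    try:
        return gene_level_call(segs, region, del_threshold=threshold)
    except ValueError:
        return None


def sig20_association_suite(
    exposures: list[SignatureExposure],
    catalogs: dict[str, SampleCatalog],
    expr: ExpressionMatrix | None = None,
    segments: list[SegmentRecord] | None = None,
    msh2_region=None,
    signature: str = MMR_SIGNATURE,
    min_group: int = 3,
) -> pd.DataFrame:
    """Association of Signature_20 presence/proportion with mutational load,
    MSH2 expression and MSH2 copy-number deletion.

    Returns one row per test with statistic, p and a BH-FDR column; tests
    whose groups have fewer than ``min_group`` members are skipped with a
    notice in the ``note`` column.
    """
    ids = [e.sample_id for e in exposures if e.sample_id in catalogs]
    props = np.array([e.proportion(signature) for e in exposures if e.sample_id in catalogs])
    present = props > 0
    loads = np.array([catalogs[i].n_snv for i in ids], dtype=float)
    rows = []

    # Spearman: proportion vs SNV load
    try:
        sp = spearman(props, loads)
        rows.append(("sig20_vs_snv_load", "spearman", sp.statistic, sp.p, None))
    except ValueError as e:
        rows.append(("sig20_vs_snv_load", "spearman", np.nan, np.nan, str(e)))

    def groups_ok() -> bool:
        return present.sum() >= min_group and (~present).sum() >= min_group

    # MSH2 expression by presence
    if expr is not None and "MSH2" in expr.genes:
        common = [i for i in ids if i in expr.samples]
        mask = np.array([i in expr.samples for i in ids])
        if groups_ok() and len(common) >= 2 * min_group:
            vals = expr.values.loc["MSH2", common].to_numpy()
            mw = mann_whitney(vals[present[mask]], vals[~present[mask]])
            rows.append(("msh2_expression_by_sig20", "mann_whitney", mw.statistic, mw.p, None))
        else:
            rows.append(("msh2_expression_by_sig20", "mann_whitney", np.nan, np.nan,
                         f"skipped: group below {min_group}"))

    # MSH2 deletion by presence
    if segments is not None and msh2_region is not None:
        calls = {i: _gene_call_for(segments, i, msh2_region) for i in ids}
        have = np.array([calls[i] is not None for i in ids])
        deleted = np.array([calls[i] == "deleted" for i in ids])
        if groups_ok() and have.sum() >= 2 * min_group:
            table = [
                [int((deleted & present & have).sum()), int((~deleted & present & have).sum())],
                [int((deleted & ~present & have).sum()), int((~deleted & ~present & have).sum())],
            ]
            try:
                fe = fisher_exact(table)
                rows.append(("msh2_deletion_by_sig20", "fisher_exact", fe.statistic, fe.p, None))
            except ValueError as e:
                rows.append(("msh2_deletion_by_sig20", "fisher_exact", np.nan, np.nan, str(e)))
        else:
            rows.append(("msh2_deletion_by_sig20", "fisher_exact", np.nan, np.nan,
                         f"skipped: group below {min_group}"))

    out = pd.DataFrame(rows, columns=["analysis", "test", "statistic", "p", "note"])
    valid = out["p"].notna()
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out
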