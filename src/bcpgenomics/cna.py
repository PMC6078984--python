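"""Copy-number array QC and genome-wide CNA summaries.

QC metrics are the median absolute pairwise deviation (MAPD) of adjacent
probe log2 ratios and the median lag-1 autocorrelation across chromosomes,
gated at 0.30 and 0.5 respectively; samples with cancer cell fraction below
30% are also excluded.  Summaries cover the fraction of genome altered,
arm-level gain/loss frequencies with Fisher/BH comparison between groups,
and length-weighted gene-level calls (used for MSH2 deletions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProbeSeries, SegmentRecord
from .stats import bh_fdr, fisher_exact

logger = logging.getLogger(__name__)

MAPD_THRESHOLD = 0.30
AUTOCORR_THRESHOLD = 0.5
MIN_CCF = 0.30
NEUTRAL_BAND = 0.2
DEL_THRESHOLD = -0.3
GAIN_THRESHOLD = 0.3
ARM_CALL_FRACTION = 0.5  # strict: > 50% of arm length altered with one sign


@dataclass
class ArrayQc:
    sample_id: str
    mapd: float
    median_autocorr: float
    mapd_threshold: float = MAPD_THRESHOLD
    autocorr_threshold: float = AUTOCORR_THRESHOLD

    @property
    def passes(self) -> bool:
        return self.mapd <= self.mapd_threshold and self.median_autocorr <= self.autocorr_threshold


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int
    end: int


def mapd(probes: ProbeSeries) -> float:
    """Median absolute pairwise deviation of adjacent probes.

    Differences are taken within chromosomes only and pooled before the
    median, so the metric is invariant to a constant shift of all log2
    ratios.
    """
    diffs = []
    for chrom in probes.chromosomes:
        v = np.asarray(probes.log2_ratio[chrom], dtype=float)
        if len(v) >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        raise ValueError("need at least 2 probes on one chromosome")
    return float(np.median(np.concatenate(diffs)))


def median_autocorrelation(probes: ProbeSeries) -> float:
    """Median across chromosomes of the lag-1 Pearson autocorrelation.

    Zero-variance chromosomes are excluded with a notice; if every
    chromosome is excluded the metric is undefined.
    """
    acs = []
    for chrom in probes.chromosomes:
        v = np.asarray(probes.log2_ratio[chrom], dtype=float)
        if len(v) < 3:
            continue
        a, b = v[:-1], v[1:]
        if np.std(a) == 0 or np.std(b) == 0:
            logger.info("%s: zero-variance chromosome %s excluded", probes.sample_id, chrom)
            continue
        acs.append(float(np.corrcoef(a, b)[0, 1]))
    if not acs:
        raise ValueError("no chromosome with >= 3 probes and non-zero variance")
    return float(np.median(acs))


def array_qc(probes: ProbeSeries) -> ArrayQc:
    return ArrayQc(probes.sample_id, mapd(probes), median_autocorrelation(probes))


def qc_gate(
    qc_metrics: list[ArrayQc],
    ccf: dict[str, float],
    mapd_threshold: float = MAPD_THRESHOLD,
    autocorr_threshold: float = AUTOCORR_THRESHOLD,
    min_ccf: float = MIN_CCF,
) -> pd.DataFrame:
    """Apply the three QC criteria; returns one row per sample with the
    pass flag and the enumerated failure reasons."""
    rows = []
    for qc in qc_metrics:
        reasons = []
        if qc.mapd > mapd_threshold:
            reasons.append("MAPD")
        if qc.median_autocorr > autocorr_threshold:
            reasons.append("autocorrelation")
        sample_ccf = ccf.get(qc.sample_id)
        if sample_ccf is None or sample_ccf < min_ccf:
            reasons.append("CCF")
        rows.append(
            dict(
                sample_id=qc.sample_id, mapd=qc.mapd,
                median_autocorr=qc.median_autocorr,
                ccf=np.nan if sample_ccf is None else sample_ccf,
                passed=not reasons, reasons=";".join(reasons),
            )
        )
    return pd.DataFrame(rows)


def fraction_genome_altered(
    segments: list[SegmentRecord], neutral_band: float = NEUTRAL_BAND
) -> float:
    """Fraction of segmented autosomal bases with |log2 ratio| > the band."""
    autosomes = [s for s in segments if s.chrom not in ("X", "Y", "MT", "M")]
    total = sum(s.length for s in autosomes)
    if total == 0:
        raise ValueError("segments cover zero bases")
    altered = sum(s.length for s in autosomes if abs(s.log2_ratio) > neutral_band)
    return altered / total


def _arm_call(segments: list[SegmentRecord], chrom: str, start: int, end: int,
              neutral_band: float) -> str | None:
    """Call an arm gained/lost when > 50% of its length is altered with a
    consistent sign; None when the arm has no segment coverage."""
    arm_len = end - start + 1
    gained = lost = 0
    covered = 0
    for s in segments:
        if s.chrom != chrom:
            continue
        ov = min(s.end, end) - max(s.start, start) + 1
        if ov <= 0:
            continue
        covered += ov
        if s.log2_ratio > neutral_band:
            gained += ov
        elif s.log2_ratio < -neutral_band:
            lost += ov
    if covered == 0:
        return None
    if gained / arm_len > ARM_CALL_FRACTION:
        return "gain"
    if lost / arm_len > ARM_CALL_FRACTION:
        return "loss"
    return "neutral"


def arm_frequency_comparison(
    segments_by_sample: dict[str, list[SegmentRecord]],
    groups: dict[str, str],
    arms: pd.DataFrame,
    neutral_band: float = NEUTRAL_BAND,
) -> pd.DataFrame:
    """Per-arm gain/loss frequencies in each group with Fisher tests and a
    BH-FDR column over all performed tests."""
    samples = [s for s in segments_by_sample if s in groups]
    rows = []
    for arm in arms.itertuples():
        calls = {}
        for s in samples:
            c = _arm_call(segments_by_sample[s], str(arm.chrom), int(arm.start),
                          int(arm.end), neutral_band)
            if c is not None:
                calls[s] = c
        if not calls:
            logger.info("arm %s has no coverage; excluded", arm.arm)
            continue
        for direction in ("gain", "loss"):
            n = {g: 0 for g in ("BCP", "control")}
            tot = {g: 0 for g in ("BCP", "control")}
            for s, c in calls.items():
                g = groups[s]
                tot[g] += 1
                if c == direction:
                    n[g] += 1
            table = [
                [n["BCP"], tot["BCP"] - n["BCP"]],
                [n["control"], tot["control"] - n["control"]],
            ]
            try:
                p = fisher_exact(table).p
            except ValueError:
                p = 1.0
            rows.append(
                dict(
                    arm=arm.arm, direction=direction,
                    n_bcp=n["BCP"], n_control=n["control"],
                    freq_bcp=n["BCP"] / tot["BCP"] if tot["BCP"] else np.nan,
                    freq_control=n["control"] / tot["control"] if tot["control"] else np.nan,
                    p=p,
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def gene_level_call(
    segments: list[SegmentRecord],
    region: GeneRegion,
    del_threshold: float = DEL_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> str:
    """Copy-number call for a gene from the length-weighted mean log2 over
    its span: ``deleted`` at or below the deletion threshold, ``gained`` at
    or above the gain threshold, otherwise ``neutral``."""
    weights, values = [], []
    for s in segments:
        if s.chrom != region.chrom:
            continue
        ov = min(s.end, region.end) - max(s.start, region.start) + 1
        if ov > 0:
            weights.append(ov)
            values.append(s.log2_ratio)
    if not weights:
        raise ValueError(f"gene {region.gene} not covered by any segment")
    mean = float(np.average(values, weights=weights))
    if mean <= del_threshold:
        return "deleted"
    if mean >= gain_threshold:
        return "gained"
    return "neutral"


def cna_summary(
    segments_by_sample: dict[str, list[SegmentRecord]],
    ccf: dict[str, float],
    ploidy: dict[str, float] | None = None,
    msh2_region: GeneRegion | None = None,
    neutral_band: float = NEUTRAL_BAND,
) -> pd.DataFrame:
    """Per-sample FGA, CCF, ploidy and (optionally) the MSH2 call."""
    rows = []
    for sample, segs in segments_by_sample.items():
        row = dict(
            sample_id=sample,
            fga=fraction_genome_altered(segs, neutral_band),
            ccf=ccf.get(sample, np.nan),
            ploidy=(ploidy or {}).get(sample, np.nan),
        )
        if msh2_region is not None:
            try:
                row["msh2_call"] = gene_level_call(segs, msh2_region)
            except ValueError:
                row["msh2_call"] = "missing"
        rows.append(row)
    return pd.DataFrame(rows)
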