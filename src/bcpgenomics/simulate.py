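"""Synthetic cohort generator.

Generates complete case-control cohorts — clinical covariates and survival,
per-patient mutation catalogs with 96-channel spectra on the bundled
synthetic genome, copy-number probes/segments, and an expression matrix —
whose population-level structure matches the pregnancy-associated breast
cancer study design this package analyses: two groups with different
non-silent mutation medians, mucin-family carrier prevalences and a
serine-gain bias among mucin missense changes, an MMR-deficiency signature
(Signature_20) present in a subset of cases and coupled to SNV load and to
MSH2 deletion/expression, equal copy-number profiles between groups, a
mucin expression upshift in cases, and survival with prescribed adjusted
hazard ratios.

Everything is deterministic given the root seed; every stochastic component
draws from its own labelled child stream.
"""

from __future__ import annotations

import datetime as _dt
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy import stats as sps

from .cna import GeneRegion
from .contexts import CONTEXT_LABELS, COMPLEMENT
from .genome import ReferenceGenome, load_reference, arm_table
from .io import (
    ClinicalRecord, ExpressionMatrix, MutationRecord, ProbeSeries,
    SegmentRecord, SignatureReference,
    write_clinical_table, write_expression_matrix, write_mutation_table,
    write_probe_table, write_segment_table,
)
from .mucins import ARTIFACT_PRONE_MUCINS
from .mutations import SampleCatalog
from .refsigs import load_reference_signatures
from .signatures import MutationalSpectrum, MMR_SIGNATURE
from .simseed import child_rng

ALL_STAGES = frozenset({"clinical", "mutations", "spectra", "cna", "expression"})

# covariate model: cases are younger (pregnancy), which confounds the
# marginal group contrast and is resolved by the covariate-adjusted models
AGE_MEAN = {"BCP": 33.0, "control": 40.0}
AGE_SD = {"BCP": 4.0, "control": 5.0}
DIAGNOSIS_YEARS = (1996.0, 2010.0)
STAGE_LEVELS = (1, 2, 3)
STAGE_PROBS = (0.3, 0.5, 0.2)
STAGE_EFFECT = 0.4  # log-hazard per stage level
SUBTYPES = ("LumA", "LumB", "HER2", "TNBC")
SUBTYPE_PROBS = (0.40, 0.30, 0.12, 0.18)
SUBTYPE_EFFECT = {"LumA": 0.0, "LumB": 0.25, "HER2": 0.4, "TNBC": 0.6}

# arm-level CNA plan: one candidate arm per chromosome with a fixed
# direction (breast-like recurrent events), identical in both groups
DEFAULT_ARM_EVENTS = {"1q": ("gain", 0.40, 0.40), "2q": ("gain", 0.20, 0.20),
                      "3p": ("loss", 0.35, 0.35)}
ARM_AMPLITUDE = (0.24, 0.36)  # |log2| range of an altered arm
FOCAL_DEL_LOG2 = -0.8
PROBE_SPACING = 80
PROBE_NOISE_SD = 0.18

_NONMUCIN_CONSEQ = (("missense", 0.78), ("nonsense", 0.12), ("splice", 0.10))


def _pair(value, name):
    v = tuple(float(x) for x in value)
    if len(v) != 2:
        raise ValueError(f"{name} must be a (BCP, control) pair")
    return v


@dataclass
class CohortParams:
    """Generator parameters; pair-valued fields are (BCP, control)."""

    n_bcp: int = 35
    n_control: int = 18
    median_snv: tuple = (13829.0, 10084.0)
    median_nonsilent: tuple = (20.0, 12.0)
    median_indel: tuple = (21.0, 26.0)
    mucin_carrier_prob: tuple = (0.457, 0.111)
    #: among carriers, probability that all mucin hits are in MUC4/MUC16 so
    #: that excluding those genes reclassifies the patient (0.457 -> 0.371)
    mucin_only_artifact_prob: tuple = (0.1882, 0.5)
    serine_gain_prob_mucin: float = 0.409
    sig20_prevalence: tuple = (0.371, 0.111)
    sig20_snv_medians: tuple = (31632.0, 7352.0)
    msh2_del_prob_by_sig20: tuple = (0.333, 0.026)
    dfs_hr: float = 1.81
    os_hr: float = 2.53
    dfs_median_years: tuple = (9.8, 12.5)  # marginal KM medians (BCP, control)
    os_5yr_control: float = 0.851
    ccf_range: tuple = (0.3, 1.0)
    vaf_overdispersion: float = 0.05
    censor_years: tuple = (5.0, 15.0)
    # burden mixture: carriers of mucin mutations are the high-burden mode
    nonsilent_dispersion: tuple = (10.0, 6.0)  # NB size r: (non-carrier, carrier)
    nonsilent_mean_noncarrier: tuple = (12.5, 11.5)
    nonsilent_mean_carrier: float = 70.0
    snv_log_sd: float = 0.9
    sig20_exposure_range: tuple = (0.15, 0.55)
    mucin_upshift: float = 0.5
    msh2_expr_del_effect: float = -1.2
    msh2_expr_sig20_effect: float = -0.4
    driver_carrier_probs: dict = field(default_factory=lambda: {"TP53": 0.34, "PIK3CA": 0.30})
    arm_events: dict = field(default_factory=lambda: dict(DEFAULT_ARM_EVENTS))
    n_hotspots: int = 3
    known_db_fraction: float = 0.08
    known_db_enrichment: float = 0.5  # prob a BCP mucin missense is drawn from the known set
    max_noncoding_records: int = 60
    n_vaf_per_sample: int = 150
    probe_noise_sd: float = PROBE_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.n_bcp < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        for name in ("mucin_carrier_prob", "sig20_prevalence",
                     "msh2_del_prob_by_sig20", "mucin_only_artifact_prob"):
            v = _pair(getattr(self, name), name)
            if not all(0.0 <= x <= 1.0 for x in v):
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, v)
        for name in ("median_snv", "median_nonsilent", "median_indel",
                     "sig20_snv_medians", "dfs_median_years"):
            v = _pair(getattr(self, name), name)
            if not all(x > 0 for x in v):
                raise ValueError(f"{name} must be positive")
            setattr(self, name, v)
        if not 0.0 <= self.serine_gain_prob_mucin <= 1.0:
            raise ValueError("serine_gain_prob_mucin must lie in [0, 1]")
        lo, hi = self.ccf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("ccf_range must satisfy 0 < lo <= hi <= 1")
        if self.dfs_hr <= 0 or self.os_hr <= 0:
            raise ValueError("hazard ratios must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort with its observables and ground truth."""

    params: CohortParams
    truth: pd.DataFrame  # one row per patient: latent states and targets
    clinical: list[ClinicalRecord] = field(default_factory=list)
    exposures_true: pd.DataFrame | None = None
    catalogs: dict[str, SampleCatalog] = field(default_factory=dict)
    spectra: dict[str, MutationalSpectrum] = field(default_factory=dict)
    probes: dict[str, ProbeSeries] = field(default_factory=dict)
    segments: dict[str, list[SegmentRecord]] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None
    known_sites: set = field(default_factory=set)
    planted_hotspots: list = field(default_factory=list)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.truth.index)

    def groups(self) -> dict[str, str]:
        return self.truth["group"].to_dict()

    def all_mutations(self) -> list[MutationRecord]:
        return [r for cat in self.catalogs.values() for r in cat.records]

    def clinical_frame(self) -> pd.DataFrame:
        from .io import clinical_to_frame

        df = clinical_to_frame(self.clinical)
        for col in ("age_at_diagnosis", "dfs_time", "os_time"):
            df[col] = df[col].astype(float)
        for col in ("pathological_stage", "dfs_event", "os_event"):
            df[col] = df[col].astype(int)
        return df

    def ground_truth(self) -> dict:
        return {
            "seed": self.params.seed,
            "patients": json.loads(self.truth.to_json(orient="index")),
            "planted_hotspots": [list(h) for h in self.planted_hotspots],
            "n_known_sites": len(self.known_sites),
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_clinical_table(self.clinical, out / "clinical.tsv")
        if self.catalogs:
            write_mutation_table(self.all_mutations(), out / "mutations.tsv")
        if self.spectra:
            pd.DataFrame({s.sample_id: s.as_series() for s in self.spectra.values()}).to_csv(
                out / "spectra.tsv", sep="\t"
            )
        if self.segments:
            write_segment_table(
                [s for segs in self.segments.values() for s in segs], out / "segments.seg"
            )
        if self.probes:
            write_probe_table(self.probes.values(), out / "probes.tsv")
        if self.expression is not None:
            write_expression_matrix(self.expression, out / "expression.tsv")
        if self.known_sites:
            pd.DataFrame(sorted(self.known_sites), columns=["chrom", "pos", "alt"]).to_csv(
                out / "known_sites.tsv", sep="\t", index=False
            )
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth(), indent=1))


# ---------------------------------------------------------------------------
# low-level samplers


def simulate_vafs(ccf: float, n: int, overdispersion: float = 0.05,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Beta-distributed VAFs around ccf/2 (diploid heterozygous model).

    ``overdispersion`` is 1/concentration: variance = m(1-m)/(1/od + 1),
    so the draws degenerate to exactly ccf/2 as it approaches zero.
    """
    if not 0.0 < ccf <= 1.0:
        raise ValueError("ccf must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "vafs")
    m = ccf / 2.0
    if overdispersion <= 0:
        return np.full(n, m)
    kappa = 1.0 / overdispersion
    v = rng.beta(m * kappa, (1.0 - m) * kappa, size=n)
    return np.clip(v, 1e-6, 1.0 - 1e-6)


def _nb_mean_for_median(target_median: float, r: float) -> float:
    """Mean of a negative binomial (size r) whose median equals the target."""
    def med_minus(mu):
        return sps.nbinom.ppf(0.5, r, r / (r + mu)) - target_median
    lo, hi = max(target_median / 4.0, 0.1), target_median * 4.0
    try:
        return brentq(med_minus, lo, hi)
    except ValueError:
        # median is a step function; fall back to a fine grid
        grid = np.linspace(lo, hi, 4001)
        med = sps.nbinom.ppf(0.5, r, r / (r + grid))
        ok = grid[med == target_median]
        if len(ok) == 0:
            raise ValueError(f"no NB(size={r}) mean gives median {target_median}")
        return float(ok.mean())


# ---------------------------------------------------------------------------
# substitution index over the synthetic genome


@functools.lru_cache(maxsize=2)
def _substitution_index(genome_key: int = 0) -> dict[str, pd.DataFrame]:
    """Per-channel table of every possible SNV in the synthetic genome.

    Each row carries genomic coordinates, strand-resolved ref/alt, the gene
    (or None), consequence and protein-change annotation.  Coding rows come
    from the per-gene substitution-effect enumeration; intergenic rows are
    noncoding.
    """
    genome = load_reference()
    frames = []
    for gene, gm in genome.genes.items():
        eff = genome.substitution_effects(gene)
        sub = eff[eff["consequence"] != "noncoding"].copy()  # drop stop-codon edge cases
        pc = []
        for row in sub.itertuples():
            if row.consequence == "synonymous":
                pc.append(f"p.{row.ref_aa}{row.protein_pos}=")
            elif row.consequence == "nonsense":
                pc.append(f"p.{row.ref_aa}{row.protein_pos}*")
            else:
                pc.append(f"p.{row.ref_aa}{row.protein_pos}{row.alt_aa}")
        frames.append(pd.DataFrame(dict(
            chrom=gm.chrom, pos=sub["pos"].to_numpy(), ref=sub["ref"].to_numpy(),
            alt=sub["alt"].to_numpy(), gene=gene, consequence=sub["consequence"].to_numpy(),
            protein_change=pc, channel=sub["channel"].to_numpy(),
            alt_aa=sub["alt_aa"].to_numpy(),
        )))
    from .contexts import channel as _channel

    for chrom, seq in genome.sequences.items():
        covered = np.zeros(len(seq) + 1, dtype=bool)
        for gm in genome.genes.values():
            if gm.chrom == chrom:
                covered[gm.start : gm.end + 1] = True
        rows = {"pos": [], "ref": [], "alt": [], "channel": []}
        for pos in range(2, len(seq)):
            if covered[pos]:
                continue
            tri = seq[pos - 2 : pos + 1]
            ref = tri[1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                rows["pos"].append(pos)
                rows["ref"].append(ref)
                rows["alt"].append(alt)
                rows["channel"].append(_channel(tri, ref, alt))
        frames.append(pd.DataFrame(dict(
            chrom=chrom, pos=rows["pos"], ref=rows["ref"], alt=rows["alt"],
            gene=None, consequence="noncoding", protein_change=None,
            channel=rows["channel"], alt_aa=None,
        )))
    full = pd.concat(frames, ignore_index=True)
    index = {c: df.reset_index(drop=True) for c, df in full.groupby("channel")}
    missing = set(CONTEXT_LABELS) - set(index)
    if missing:  # pragma: no cover - genome is large enough by construction
        raise RuntimeError(f"synthetic genome lacks channels: {sorted(missing)}")
    return index


@functools.lru_cache(maxsize=2)
def _noncoding_index(genome_key: int = 0) -> dict[str, pd.DataFrame]:
    return {
        c: df[df["consequence"] == "noncoding"].reset_index(drop=True)
        for c, df in _substitution_index(genome_key).items()
    }


def _records_from_channel_rows(rows: pd.DataFrame, patient_id: str,
                               vafs: np.ndarray | None) -> list[MutationRecord]:
    recs = []
    for i, row in enumerate(rows.itertuples(index=False)):
        recs.append(MutationRecord(
            patient_id=patient_id, chrom=row.chrom, pos=int(row.pos),
            ref=row.ref, alt=row.alt,
            gene=row.gene if row.gene else ".",
            consequence=row.consequence,
            protein_change=row.protein_change,
            vaf=None if vafs is None else float(vafs[i]),
        ))
    return recs


def simulate_catalog(
    exposures: pd.Series,
    n_mutations: int,
    reference: SignatureReference | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    max_records: int | None = None,
    ccf: float = 0.8,
    vaf_overdispersion: float = 0.05,
) -> tuple[MutationalSpectrum, list[MutationRecord]]:
    """Draw a mutation catalog from a signature mixture.

    The 96-channel spectrum is Multinomial(n, reference x exposures); each
    materialised record is placed at a genome position whose trinucleotide
    context matches its channel (purine-strand placements are recorded on
    the purine strand, exercising the downstream strand folding).  With
    ``max_records`` set, only a uniform subsample of records is
    materialised while the spectrum keeps the full counts.
    """
    reference = reference or load_reference_signatures()
    exposures = exposures.reindex(reference.signatures).fillna(0.0)
    if abs(float(exposures.sum()) - 1.0) > 1e-6:
        raise ValueError("exposures must sum to 1")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "catalog")
    probs = reference.matrix.to_numpy() @ exposures.to_numpy()
    probs = probs / probs.sum()
    counts = rng.multinomial(n_mutations, probs)
    spectrum = MutationalSpectrum(sample_id, counts.astype(float))
    index = _substitution_index()
    mat_counts = counts
    if max_records is not None and n_mutations > max_records:
        mat_counts = rng.multinomial(max_records, counts / counts.sum())
    chunks = []
    for ci, k in enumerate(mat_counts):
        if k == 0:
            continue
        tbl = index[CONTEXT_LABELS[ci]]
        chunks.append(tbl.iloc[rng.integers(0, len(tbl), size=int(k))])
    records: list[MutationRecord] = []
    if chunks:
        rows = pd.concat(chunks, ignore_index=True)
        vafs = simulate_vafs(ccf, len(rows), vaf_overdispersion, rng)
        records = _records_from_channel_rows(rows, sample_id, vafs)
    return spectrum, records


# ---------------------------------------------------------------------------
# survival calibration

_CALIBRATION_SEED = 424242
_CALIBRATION_N = 20000


def _draw_covariates(group: str, rng: np.random.Generator, n: int):
    age = rng.normal(AGE_MEAN[group], AGE_SD[group], n)
    stage = rng.choice(STAGE_LEVELS, n, p=STAGE_PROBS)
    subtype = rng.choice(len(SUBTYPES), n, p=SUBTYPE_PROBS)
    return age, stage, subtype


def _base_lp(age, stage, subtype, b_age):
    sub_eff = np.array([SUBTYPE_EFFECT[s] for s in SUBTYPES])
    return b_age * (age - 40.0) / 10.0 + STAGE_EFFECT * (stage - 2.0) + sub_eff[subtype]


@functools.lru_cache(maxsize=32)
def _calibrate_survival(dfs_hr: float, bcp_median: float, control_median: float,
                        os_hr: float, os_5yr_control: float):
    """Solve (baseline hazards, age effect) so that the marginal control and
    BCP DFS medians equal the targets while the *conditional* group log
    hazard ratio stays at log(dfs_hr).

    The younger age of the cases is the confounder that reconciles the
    adjusted hazard ratio with the much smaller marginal median contrast.
    Marginal survival is integrated over a fixed Monte-Carlo sample of the
    covariate distribution.
    """
    rng_c = np.random.default_rng(_CALIBRATION_SEED)
    rng_b = np.random.default_rng(_CALIBRATION_SEED + 1)
    age_c, st_c, su_c = _draw_covariates("control", rng_c, _CALIBRATION_N)
    age_b, st_b, su_b = _draw_covariates("BCP", rng_b, _CALIBRATION_N)

    def lam_control(b_age):
        lp = _base_lp(age_c, st_c, su_c, b_age)
        return brentq(
            lambda lam: np.mean(np.exp(-lam * np.exp(lp) * control_median)) - 0.5,
            1e-6, 10.0,
        )

    def bcp_median_given(b_age):
        lam = lam_control(b_age)
        lp = _base_lp(age_b, st_b, su_b, b_age) + np.log(dfs_hr)
        return brentq(
            lambda t: np.mean(np.exp(-lam * np.exp(lp) * t)) - 0.5, 1e-4, 5e4
        )

    b_age = brentq(lambda b: bcp_median_given(b) - bcp_median, -1.5, 5.0, xtol=1e-5)
    lam_dfs = lam_control(b_age)
    # OS: same covariate effects; baseline anchored at the control 5-year rate
    lp_os_c = _base_lp(age_c, st_c, su_c, b_age)
    lam_os = brentq(
        lambda lam: np.mean(np.exp(-lam * np.exp(lp_os_c) * 5.0)) - os_5yr_control,
        1e-8, 10.0,
    )
    return lam_dfs, lam_os, b_age


# ---------------------------------------------------------------------------
# cohort generation


def _mucin_genes_in_genome(genome: ReferenceGenome):
    from .genome import MUCIN_GENES

    return [g for g in MUCIN_GENES if g in genome.genes]


def msh2_region(genome: ReferenceGenome | None = None) -> GeneRegion:
    genome = genome or load_reference()
    gm = genome.genes["MSH2"]
    return GeneRegion("MSH2", gm.chrom, gm.start, gm.end)


def simulate_cohort(params: CohortParams, stages=ALL_STAGES) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic given params.seed)."""
    stages = set(stages)
    unknown = stages - ALL_STAGES
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    genome = load_reference()
    seed = params.seed
    n_b, n_c = params.n_bcp, params.n_control
    n = n_b + n_c
    ids = [f"BCP{i + 1:03d}" for i in range(n_b)] + [f"C{i + 1:03d}" for i in range(n_c)]
    group = np.array(["BCP"] * n_b + ["control"] * n_c)
    is_bcp = group == "BCP"

    # ---- latent per-patient states -------------------------------------
    rng = child_rng(seed, "latent")
    carrier_p = np.where(is_bcp, *params.mucin_carrier_prob)
    carrier = rng.random(n) < carrier_p
    only_artifact_p = np.where(is_bcp, *params.mucin_only_artifact_prob)
    only_artifact = carrier & (rng.random(n) < only_artifact_p)
    sig20_p = np.where(is_bcp, *params.sig20_prevalence)
    sig20 = rng.random(n) < sig20_p
    lo_e, hi_e = params.sig20_exposure_range
    sig20_exposure = np.where(sig20, rng.uniform(lo_e, hi_e, n), 0.0)
    msh2_p = np.where(sig20, *params.msh2_del_prob_by_sig20)
    msh2_del = rng.random(n) < msh2_p
    ccf = rng.uniform(params.ccf_range[0], params.ccf_range[1], n)
    ploidy = np.clip(rng.normal(2.6, 0.5, n), 1.5, 4.5)

    # total SNV load: log-normal with a Signature_20 multiplier, rescaled so
    # each group's sample median matches its configured median exactly
    rng_load = child_rng(seed, "snv_load")
    k_load = np.log(params.sig20_snv_medians[0] / params.sig20_snv_medians[1]) / (
        0.5 * (lo_e + hi_e)
    )
    mult = np.exp(rng_load.normal(0.0, params.snv_log_sd, n) + k_load * sig20_exposure)
    n_snv = np.empty(n)
    for g, target in (("BCP", params.median_snv[0]), ("control", params.median_snv[1])):
        m = group == g
        n_snv[m] = mult[m] * (target / np.median(mult[m]))
    n_snv = np.maximum(np.round(n_snv).astype(int), 50)

    # non-silent burden: carrier-coupled negative-binomial mixture
    rng_burden = child_rng(seed, "burden")
    r_nc, r_car = params.nonsilent_dispersion
    mu_car = params.nonsilent_mean_carrier
    n_nonsilent = np.empty(n, dtype=int)
    for g, mu_nc in (("BCP", params.nonsilent_mean_noncarrier[0]),
                     ("control", params.nonsilent_mean_noncarrier[1])):
        m = group == g
        mus = np.where(carrier[m], mu_car, mu_nc)
        rs = np.where(carrier[m], r_car, r_nc)
        n_nonsilent[m] = rng_burden.negative_binomial(rs, rs / (rs + mus))
    n_indel = np.empty(n, dtype=int)
    for g, med in (("BCP", params.median_indel[0]), ("control", params.median_indel[1])):
        m = group == g
        mu = _nb_mean_for_median(med, 8.0)
        n_indel[m] = rng_burden.negative_binomial(8.0, 8.0 / (8.0 + mu), size=m.sum())

    truth = pd.DataFrame(
        dict(
            group=group, mucin_carrier=carrier,
            mucin_carrier_excl_artifact=carrier & ~only_artifact,
            sig20=sig20, sig20_exposure=sig20_exposure, msh2_deleted=msh2_del,
            ccf=ccf, ploidy=ploidy, n_snv=n_snv, n_nonsilent_target=n_nonsilent,
            n_indel=n_indel,
        ),
        index=pd.Index(ids, name="patient_id"),
    )

    cohort = SyntheticCohort(params=params, truth=truth)

    # ---- true signature exposures --------------------------------------
    sigref = load_reference_signatures()
    rng_sig = child_rng(seed, "exposures")
    base_means = {
        "BCP": {"Signature_1": 0.32, "Signature_5": 0.18, "Signature_3": 0.18,
                "Signature_8": 0.12, "Signature_2": 0.11, "Signature_13": 0.09},
        "control": {"Signature_1": 0.20, "Signature_5": 0.32, "Signature_3": 0.18,
                    "Signature_8": 0.10, "Signature_2": 0.11, "Signature_13": 0.09},
    }
    expo = pd.DataFrame(0.0, index=truth.index, columns=sigref.signatures)
    conc = 60.0
    for i, pid in enumerate(ids):
        means = base_means[group[i]]
        alpha = np.array([means[s] for s in means]) * conc
        w = rng_sig.dirichlet(alpha)
        row = dict(zip(means, w * (1.0 - sig20_exposure[i])))
        row[MMR_SIGNATURE] = sig20_exposure[i]
        for s, v in row.items():
            expo.loc[pid, s] = v
    cohort.exposures_true = expo

    # ---- survival + clinical -------------------------------------------
    if "clinical" in stages:
        rng_cl = child_rng(seed, "clinical")
        lam_dfs, lam_os, b_age = _calibrate_survival(
            params.dfs_hr, params.dfs_median_years[0], params.dfs_median_years[1],
            params.os_hr, params.os_5yr_control,
        )
        records = []
        for g in ("BCP", "control"):
            m = group == g
            nm = int(m.sum())
            age, stage, subtype = _draw_covariates(g, rng_cl, nm)
            lp = _base_lp(age, stage, subtype, b_age)
            gflag = 1.0 if g == "BCP" else 0.0
            t_dfs = rng_cl.exponential(1.0 / (lam_dfs * np.exp(lp + np.log(params.dfs_hr) * gflag)))
            t_os = rng_cl.exponential(1.0 / (lam_os * np.exp(lp + np.log(params.os_hr) * gflag)))
            cens = rng_cl.uniform(*params.censor_years, nm)
            dates = rng_cl.uniform(*DIAGNOSIS_YEARS, nm)
            er = np.where(
                np.isin(subtype, [0, 1]), "pos",
                np.where(rng_cl.random(nm) < 0.25, "pos", "neg"),
            )
            pr = np.where(
                (er == "pos") & (rng_cl.random(nm) < 0.85), "pos", "neg"
            )
            idx = np.where(m)[0]
            for j in range(nm):
                year = dates[j]
                date = _dt.date(int(year), 1, 1) + _dt.timedelta(
                    days=float((year % 1.0) * 364.0)
                )
                records.append(
                    ClinicalRecord(
                        patient_id=ids[idx[j]], group=g,
                        age_at_diagnosis=float(age[j]),
                        date_of_diagnosis=date,
                        pathological_stage=int(stage[j]),
                        subtype_ihc=SUBTYPES[subtype[j]],
                        er_status=str(er[j]), pr_status=str(pr[j]),
                        dfs_time=float(min(t_dfs[j], cens[j])),
                        os_time=float(min(t_os[j], cens[j])),
                        dfs_event=int(t_dfs[j] <= cens[j]),
                        os_event=int(t_os[j] <= cens[j]),
                    )
                )
        order = {pid: i for i, pid in enumerate(ids)}
        records.sort(key=lambda r: order[r.patient_id])
        cohort.clinical = records

    # ---- known-variant catalog (COSMIC surrogate) ----------------------
    mucins = _mucin_genes_in_genome(genome)
    rng_known = child_rng(seed, "known_db")
    mucin_rows = pd.concat(
        [genome.substitution_effects(g).assign(gene=g, chrom=genome.genes[g].chrom)
         for g in mucins],
        ignore_index=True,
    )
    mucin_missense = mucin_rows[mucin_rows["consequence"] == "missense"].reset_index(drop=True)
    n_known = int(round(params.known_db_fraction * len(mucin_missense)))
    known_idx = rng_known.choice(len(mucin_missense), size=n_known, replace=False)
    known = mucin_missense.iloc[known_idx]
    cohort.known_sites = set(zip(known["chrom"], known["pos"].astype(int), known["alt"]))

    # ---- mutation catalogs ---------------------------------------------
    if "mutations" in stages or "spectra" in stages:
        _simulate_mutations(cohort, genome, sigref, stages)

    # ---- copy number ----------------------------------------------------
    if "cna" in stages:
        _simulate_cna(cohort, genome)

    # ---- expression ------------------------------------------------------
    if "expression" in stages:
        _simulate_expression(cohort, genome)

    return cohort


def _site_effect_pools(genome: ReferenceGenome, genes: list[str]):
    """Per-gene site pools by outcome class (tuple lists for fast drawing)."""
    pools = {}
    for g in genes:
        eff = genome.substitution_effects(g)
        miss = eff[eff["consequence"] == "missense"]
        pools[g] = {
            "ser": list(miss[miss["alt_aa"] == "S"].itertuples(index=False)),
            "other": list(miss[miss["alt_aa"] != "S"].itertuples(index=False)),
            "nonsense": list(eff[eff["consequence"] == "nonsense"].itertuples(index=False)),
            "synonymous": list(eff[eff["consequence"] == "synonymous"].itertuples(index=False)),
        }
    return pools


def _record_from_site(site, gene: str, genome: ReferenceGenome, patient_id: str,
                      vaf: float, known_sites: set) -> MutationRecord:
    chrom = genome.genes[gene].chrom
    if site.consequence == "synonymous":
        pc = f"p.{site.ref_aa}{site.protein_pos}="
    elif site.consequence == "nonsense":
        pc = f"p.{site.ref_aa}{site.protein_pos}*"
    else:
        pc = f"p.{site.ref_aa}{site.protein_pos}{site.alt_aa}"
    return MutationRecord(
        patient_id=patient_id, chrom=chrom, pos=int(site.pos), ref=site.ref,
        alt=site.alt, gene=gene, consequence=site.consequence, protein_change=pc,
        vaf=float(vaf),
        in_known_db=(chrom, int(site.pos), site.alt) in known_sites,
    )


def _simulate_mutations(cohort: SyntheticCohort, genome: ReferenceGenome,
                        sigref: SignatureReference, stages: set) -> None:
    params = cohort.params
    truth = cohort.truth
    seed = params.seed
    rng = child_rng(seed, "mutations")
    mucins = _mucin_genes_in_genome(genome)
    regular_mucins = [g for g in mucins if g not in ARTIFACT_PRONE_MUCINS]
    artifact_mucins = [g for g in mucins if g in ARTIFACT_PRONE_MUCINS]
    other_genes = [g for g in genome.genes if g not in mucins]
    driver_genes = list(params.driver_carrier_probs)
    filler_genes = [g for g in other_genes if g not in driver_genes]
    pools = _site_effect_pools(genome, list(genome.genes))
    known = cohort.known_sites

    conseq_names = [c for c, _ in _NONMUCIN_CONSEQ]
    conseq_probs = np.array([p for _, p in _NONMUCIN_CONSEQ])
    conseq_probs = conseq_probs / conseq_probs.sum()

    spectra_probs = sigref.matrix.to_numpy() @ cohort.exposures_true.to_numpy().T

    bcp_mucin_missense: list[tuple[str, int]] = []  # (patient, record index) for hotspots
    catalogs: dict[str, SampleCatalog] = {}
    spectra: dict[str, MutationalSpectrum] = {}

    known_pools = {
        g: {
            cat: [
                s for s in pools[g][cat]
                if (genome.genes[g].chrom, int(s.pos), s.alt) in known
            ]
            for cat in ("ser", "other")
        }
        for g in mucins
    }

    def draw_site(gene: str, pool_name: str, enrich_known: bool):
        pool = pools[gene][pool_name]
        if not pool:
            return None
        if enrich_known and rng.random() < params.known_db_enrichment:
            sub = known_pools.get(gene, {}).get(pool_name, ())
            if sub:
                return sub[int(rng.integers(0, len(sub)))]
        return pool[int(rng.integers(0, len(pool)))]

    for pi, pid in enumerate(truth.index) if "mutations" in stages else ():
        row = truth.iloc[pi]
        vaf_rng = rng
        records: list[MutationRecord] = []

        def vaf():
            return float(simulate_vafs(row["ccf"], 1, params.vaf_overdispersion, vaf_rng)[0])

        # mucin mutations for carriers
        n_assigned_nonsilent = 0
        if row["mucin_carrier"]:
            k_muc = 1 + rng.poisson(0.6)
            gene_pool = (
                artifact_mucins
                if not row["mucin_carrier_excl_artifact"]
                else regular_mucins
            )
            for _ in range(k_muc):
                gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
                if rng.random() < 0.95:
                    is_ser = rng.random() < params.serine_gain_prob_mucin
                    site = draw_site(
                        gene, "ser" if is_ser else "other",
                        enrich_known=row["group"] == "BCP",
                    )
                else:
                    site = draw_site(gene, "nonsense", enrich_known=False)
                if site is None:
                    continue
                rec = _record_from_site(site, gene, genome, pid, vaf(), known)
                if rec.consequence == "missense" and row["group"] == "BCP":
                    bcp_mucin_missense.append((pid, len(records)))
                records.append(rec)
                n_assigned_nonsilent += 1

        # driver genes, identical prevalence in both groups
        for gene, p_carrier in params.driver_carrier_probs.items():
            if rng.random() < p_carrier:
                site = draw_site(gene, "ser" if rng.random() < 0.06 else "other", False)
                if site is not None:
                    records.append(_record_from_site(site, gene, genome, pid, vaf(), known))
                    n_assigned_nonsilent += 1

        # remaining non-silent burden spread over the other genes
        n_rest = max(0, int(row["n_nonsilent_target"]) - n_assigned_nonsilent)
        for _ in range(n_rest):
            cons = conseq_names[int(rng.choice(len(conseq_names), p=conseq_probs))]
            gene = filler_genes[int(rng.integers(0, len(filler_genes)))]
            if cons == "splice":
                gm = genome.genes[gene]
                pos = gm.start - 2
                ref = genome.base(gm.chrom, pos)
                alt = COMPLEMENT[ref]
                records.append(MutationRecord(
                    patient_id=pid, chrom=gm.chrom, pos=pos, ref=ref, alt=alt,
                    gene=gene, consequence="splice", vaf=vaf(),
                ))
            else:
                pool = "nonsense" if cons == "nonsense" else (
                    "ser" if rng.random() < 0.06 else "other"
                )
                site = draw_site(gene, pool, False)
                if site is not None:
                    records.append(_record_from_site(site, gene, genome, pid, vaf(), known))

        # a handful of synonymous passengers
        for _ in range(rng.poisson(4)):
            gene = list(genome.genes)[int(rng.integers(0, len(genome.genes)))]
            site = draw_site(gene, "synonymous", False)
            if site is not None:
                records.append(_record_from_site(site, gene, genome, pid, vaf(), known))

        # indels: group-level count only, noncoding by construction
        for _ in range(int(row["n_indel"])):
            chrom = str(rng.choice(["1", "2", "3"]))
            seq_len = len(genome.sequences[chrom])
            pos = int(rng.integers(10, seq_len - 10))
            ref = genome.base(chrom, pos)
            records.append(MutationRecord(
                patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt="-",
                gene=genome.gene_at(chrom, pos) or ".", consequence="noncoding",
                vaf=vaf(),
            ))

        catalogs[pid] = SampleCatalog(pid, records, n_snv=int(row["n_snv"]),
                                      n_indel=int(row["n_indel"]))

    # plant protein-level hotspots among regular BCP mucin missense records
    planted = []
    if params.n_hotspots > 0 and "mutations" in stages:
        hot_rng = child_rng(seed, "hotspots")
        hotspot_genes = ["MUC17", "MUC17", "MUC20", "MUC2", "MUC12"][: params.n_hotspots]
        by_patient: dict[str, list[int]] = {}
        for pid, ri in bcp_mucin_missense:
            if catalogs[pid].records[ri].gene in set(regular_mucins):
                by_patient.setdefault(pid, []).append(ri)
        candidates = list(by_patient)
        for gene in hotspot_genes:
            if len(candidates) < 2:
                break
            pick = hot_rng.choice(len(candidates), size=2, replace=False)
            is_ser = hot_rng.random() < params.serine_gain_prob_mucin
            pool = pools[gene]["ser" if is_ser else "other"]
            site = pool[int(hot_rng.integers(0, len(pool)))]
            pair = [candidates[i] for i in sorted(pick)]
            for pid in pair:
                ri = by_patient[pid][0]
                old = catalogs[pid].records[ri]
                catalogs[pid].records[ri] = _record_from_site(
                    site, gene, genome, pid, old.vaf, known
                )
            planted.append((gene, int(site.protein_pos)))
            candidates = [c for c in candidates if c not in pair]
    cohort.planted_hotspots = planted
    cohort.catalogs = catalogs

    # 96-channel spectra and a capped sample of genome-wide records
    if "spectra" in stages:
        nc_index = _noncoding_index()
        rng_sp = child_rng(seed, "spectra")
        for pi, pid in enumerate(truth.index):
            probs = spectra_probs[:, pi]
            probs = probs / probs.sum()
            n_total = int(truth["n_snv"].iloc[pi])
            counts = rng_sp.multinomial(n_total, probs)
            spectra[pid] = MutationalSpectrum(pid, counts.astype(float))
            if cohort.catalogs:
                cap = min(params.max_noncoding_records, n_total)
                sub = rng_sp.multinomial(cap, counts / counts.sum())
                chunks = []
                for ci, k in enumerate(sub):
                    if k == 0:
                        continue
                    tbl = nc_index[CONTEXT_LABELS[ci]]
                    if len(tbl) == 0:
                        continue
                    chunks.append(tbl.iloc[rng_sp.integers(0, len(tbl), size=int(k))])
                if chunks:
                    rows = pd.concat(chunks, ignore_index=True)
                    ccf = float(truth["ccf"].iloc[pi])
                    vafs = simulate_vafs(ccf, len(rows), params.vaf_overdispersion, rng_sp)
                    cohort.catalogs[pid].records.extend(
                        _records_from_channel_rows(rows, pid, vafs)
                    )
        cohort.spectra = spectra


def _simulate_cna(cohort: SyntheticCohort, genome: ReferenceGenome) -> None:
    params = cohort.params
    seed = params.seed
    rng = child_rng(seed, "cna")
    arms = arm_table(genome.sequences)
    arm_lookup = {r.arm: (str(r.chrom), int(r.start), int(r.end)) for r in arms.itertuples()}
    msh2 = msh2_region(genome)
    probes: dict[str, ProbeSeries] = {}
    segments: dict[str, list[SegmentRecord]] = {}
    fga_true = {}
    is_bcp = cohort.truth["group"] == "BCP"
    for pid in cohort.truth.index:
        plan: list[tuple[str, int, int, float]] = []  # chrom,start,end,log2
        altered = 0
        total = 0
        sample_arms = {}
        for arm_name, (direction, p_b, p_c) in params.arm_events.items():
            p = p_b if is_bcp[pid] else p_c
            if arm_name not in arm_lookup:
                continue
            sample_arms[arm_name] = direction if rng.random() < p else None
        for arm_row in arms.itertuples():
            chrom, start, end = str(arm_row.chrom), int(arm_row.start), int(arm_row.end)
            total += end - start + 1
            ev = sample_arms.get(arm_row.arm)
            if ev:
                amp = float(np.clip(rng.normal(0.30, 0.03), *ARM_AMPLITUDE))
                log2 = amp if ev == "gain" else -amp
                altered += end - start + 1
            else:
                log2 = float(np.clip(rng.normal(0.0, 0.02), -0.19, 0.19))
            plan.append((chrom, start, end, log2))
        if cohort.truth.loc[pid, "msh2_deleted"]:
            new_plan = []
            f_start, f_end = msh2.start - 100, msh2.end + 100
            for chrom, start, end, log2 in plan:
                if chrom == msh2.chrom and start <= f_start and f_end <= end:
                    if start <= f_start - 1:
                        new_plan.append((chrom, start, f_start - 1, log2))
                    new_plan.append((chrom, f_start, f_end, FOCAL_DEL_LOG2))
                    if f_end + 1 <= end:
                        new_plan.append((chrom, f_end + 1, end, log2))
                    altered += f_end - f_start + 1
                else:
                    new_plan.append((chrom, start, end, log2))
            plan = new_plan
        fga_true[pid] = altered / total
        seg_records = []
        pos_by_chrom: dict[str, list] = {}
        log2_by_chrom: dict[str, list] = {}
        for chrom, start, end, log2 in plan:
            n_pr = max((end - start + 1) // PROBE_SPACING, 1)
            seg_records.append(SegmentRecord(
                sample_id=pid, chrom=chrom, start=start, end=end,
                n_probes=n_pr, log2_ratio=round(log2, 6),
            ))
            grid = np.arange(start, end + 1, PROBE_SPACING)
            pos_by_chrom.setdefault(chrom, []).append(grid)
            log2_by_chrom.setdefault(chrom, []).append(
                log2 + rng.normal(0.0, params.probe_noise_sd, len(grid))
            )
        segments[pid] = seg_records
        probes[pid] = ProbeSeries(
            sample_id=pid,
            positions={c: np.concatenate(v) for c, v in pos_by_chrom.items()},
            log2_ratio={c: np.concatenate(v) for c, v in log2_by_chrom.items()},
        )
    cohort.truth["fga_true"] = pd.Series(fga_true)
    cohort.probes = probes
    cohort.segments = segments


def _simulate_expression(cohort: SyntheticCohort, genome: ReferenceGenome) -> None:
    params = cohort.params
    rng = child_rng(params.seed, "expression")
    genes = list(genome.genes)
    base = rng.normal(7.0, 1.0, len(genes))
    truth = cohort.truth
    n = len(truth)
    values = base[:, None] + rng.normal(0.0, 1.0, (len(genes), n))
    mucins = set(_mucin_genes_in_genome(genome))
    is_bcp = (truth["group"] == "BCP").to_numpy()
    for gi, g in enumerate(genes):
        if g in mucins:
            values[gi, is_bcp] += params.mucin_upshift
        if g == "MSH2":
            values[gi] += params.msh2_expr_del_effect * truth["msh2_deleted"].to_numpy()
            values[gi] += params.msh2_expr_sig20_effect * truth["sig20"].to_numpy()
    cohort.expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=list(truth.index))
    )
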