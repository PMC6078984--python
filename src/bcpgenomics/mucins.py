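"""Mucin gene family analysis.

Covers carrier status (with optional exclusion of artifact-prone members
such as MUC4/MUC16), protein-level hotspot detection, serine-gain
classification of missense changes (serine being an O-glycosylation
acceptor), two Monte-Carlo enrichment tests, and the MUCsig expression
metagene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .contexts import BASES, COMPLEMENT, PYRIMIDINES
from .genome import ReferenceGenome, load_reference
from .io import ExpressionMatrix, MutationRecord
from .mutations import SampleCatalog, classify_non_silent
from .simseed import child_rng

logger = logging.getLogger(__name__)

#: all members of the mucin gene family considered by default
DEFAULT_MUCIN_FAMILY = (
    "MUC1", "MUC2", "MUC3A", "MUC3B", "MUC4", "MUC5AC", "MUC5B", "MUC6",
    "MUC7", "MUC12", "MUC13", "MUC15", "MUC16", "MUC17", "MUC19", "MUC20",
    "MUC21", "MUC22",
)

#: members known to attract false-positive calls from technical artifacts
ARTIFACT_PRONE_MUCINS = frozenset({"MUC4", "MUC16"})

_PROTEIN_RE = re.compile(r"^p\.(?:[A-Z]|\*)(\d+)(?:([A-Z])|\*|=|fs.*|del.*|ins.*)?$")


@dataclass(frozen=True)
class GeneFamily:
    """A named gene family; coding sequences come from the reference genome."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("gene family must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate gene symbols in family")

    def without(self, exclude) -> "GeneFamily":
        exclude = set(exclude)
        extra = exclude - set(self.members)
        if extra:
            logger.warning("excluded gene(s) not in family: %s", sorted(extra))
        kept = tuple(g for g in self.members if g not in exclude)
        return GeneFamily(self.name, kept)


def mucin_family() -> GeneFamily:
    return GeneFamily("mucin", DEFAULT_MUCIN_FAMILY)


@dataclass
class McTestResult:
    """Empirical Monte-Carlo test result with the (1+k)/(1+N) estimator."""

    observed: float
    n_draws: int
    p: float
    seed: int
    null_mean: float
    null_sd: float
    note: str | None = None


def _empirical_p(observed: float, null_draws: np.ndarray) -> float:
    k = int(np.sum(null_draws >= observed))
    return (1 + k) / (1 + len(null_draws))


def is_serine_gain(ref_codon: str, alt_codon: str) -> bool:
    """True iff the codon change is a missense gain of serine."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in BASES for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
    diffs = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if diffs != 1:
        raise ValueError(f"codons must differ at exactly one position (got {diffs})")
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return alt_aa == "S" and ref_aa != "S" and ref_aa != "*"


def _alt_aa_from_protein_change(pc: str | None) -> str | None:
    if not pc:
        return None
    m = _PROTEIN_RE.match(pc)
    if not m:
        return None
    return m.group(2)  # None for nonsense/synonymous/indel spellings


def serine_gain_fraction(mutations: list[MutationRecord]) -> float:
    """Fraction of missense mutations whose mutant amino acid is serine.

    Parses the ``p.X###Y`` protein-change notation; records that cannot be
    parsed are collected into a single error.
    """
    missense = [r for r in mutations if r.consequence == "missense"]
    if not missense:
        raise ValueError("no missense mutations: serine-gain fraction undefined")
    bad = [r.protein_change for r in missense if _alt_aa_from_protein_change(r.protein_change) is None]
    if bad:
        raise ValueError(f"unparseable protein change(s): {bad[:5]}")
    n_ser = sum(
        1 for r in missense if _alt_aa_from_protein_change(r.protein_change) == "S"
    )
    return n_ser / len(missense)


def _pyrimidine_type(ref: str, alt: str) -> str:
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def _family_effects(family: GeneFamily, reference: ReferenceGenome) -> pd.DataFrame:
    genes = [g for g in family.members if g in reference.genes]
    if not genes:
        raise ValueError("family has no coding sequences in the reference genome")
    frames = []
    for g in genes:
        eff = reference.substitution_effects(g).copy()
        eff["gene"] = g
        eff["chrom"] = reference.genes[g].chrom
        frames.append(eff)
    out = pd.concat(frames, ignore_index=True)
    out["sub_type"] = [
        _pyrimidine_type(r, a) for r, a in zip(out["ref"], out["alt"])
    ]
    return out


def mc_serine_test(
    observed: list[MutationRecord],
    family: GeneFamily,
    n_draws: int = 9999,
    seed: int = 0,
    reference: ReferenceGenome | None = None,
    null: str = "spectrum",
) -> McTestResult:
    """Monte-Carlo test of serine-gain enrichment among family missense calls.

    Null model: for each of the |observed| substitutions, draw a substitution
    type (from the observed type spectrum by default, or uniformly with
    ``null="uniform"``), place it uniformly among the family coding positions
    where that substitution is possible, and keep only missense outcomes.
    The statistic is the serine-gain fraction.
    """
    if not observed:
        raise ValueError("observed mutation set is empty")
    if n_draws < 100:
        logger.warning("n_draws=%d is very small for an empirical p", n_draws)
    reference = reference or load_reference()
    eff = _family_effects(family, reference)
    missense = eff[eff["consequence"] == "missense"]

    obs_frac = serine_gain_fraction(observed)
    types = [_pyrimidine_type(r.ref, r.alt) for r in observed if r.is_snv]
    if not types:
        raise ValueError("observed set contains no SNVs")

    # serine-gain probability conditional on a missense outcome, per type
    ser_prob = missense.groupby("sub_type")["alt_aa"].apply(lambda s: float(np.mean(s == "S")))
    feasible = set(ser_prob.index)
    note = None
    if null == "spectrum":
        kept = [t for t in types if t in feasible]
        if len(kept) < len(types):
            note = f"{len(types) - len(kept)} observed type(s) infeasible in family; redrawn"
        type_labels, counts = np.unique(kept if kept else list(feasible), return_counts=True)
        probs = counts / counts.sum()
    elif null == "uniform":
        type_labels = np.array(sorted(feasible))
        probs = np.full(len(type_labels), 1.0 / len(type_labels))
    else:
        raise ValueError(f"unknown null {null!r}")

    m = len(observed)
    rng = child_rng(seed, "mc_serine")
    per_type = rng.multinomial(m, probs, size=n_draws)  # (n_draws, n_types)
    ser_counts = np.zeros(n_draws)
    for j, t in enumerate(type_labels):
        ser_counts += rng.binomial(per_type[:, j], ser_prob[t])
    null_frac = ser_counts / m
    return McTestResult(
        observed=obs_frac, n_draws=n_draws, p=_empirical_p(obs_frac, null_frac),
        seed=seed, null_mean=float(null_frac.mean()), null_sd=float(null_frac.std()),
        note=note,
    )


def mc_known_db_overlap_test(
    variants: list[MutationRecord],
    known_positions,
    family: GeneFamily,
    n_draws: int = 9999,
    seed: int = 0,
    reference: ReferenceGenome | None = None,
    match: str = "allele",
) -> McTestResult:
    """Monte-Carlo test of overlap with a known-variant catalog.

    Null model: |variants| substitutions placed uniformly over the family
    coding footprint (position and, in ``allele`` mode, alternate allele
    drawn uniformly); the statistic is the count overlapping the known set.
    ``known_positions`` holds ``(chrom, pos)`` pairs in ``position`` mode or
    ``(chrom, pos, alt)`` triples in ``allele`` mode.
    """
    if not variants:
        raise ValueError("variant set is empty")
    reference = reference or load_reference()
    eff = _family_effects(family, reference)
    known = set(known_positions)
    if match == "position":
        observed = sum(1 for v in variants if (v.chrom, v.pos) in known)
        footprint = set(zip(eff["chrom"], eff["pos"]))
    elif match == "allele":
        observed = sum(1 for v in variants if (v.chrom, v.pos, v.alt) in known)
        footprint = set(zip(eff["chrom"], eff["pos"], eff["alt"]))
    else:
        raise ValueError(f"unknown match mode {match!r}")
    if not known:
        logger.warning("empty known-variant set: p = 1 by construction")
        return McTestResult(
            observed=float(observed), n_draws=n_draws, p=1.0, seed=seed,
            null_mean=0.0, null_sd=0.0, note="empty known set",
        )
    q = len(known & footprint) / len(footprint)
    rng = child_rng(seed, "mc_known_db")
    null_counts = rng.binomial(len(variants), q, size=n_draws).astype(float)
    return McTestResult(
        observed=float(observed), n_draws=n_draws,
        p=_empirical_p(observed, null_counts), seed=seed,
        null_mean=float(null_counts.mean()), null_sd=float(null_counts.std()),
    )


def hotspot_detect(mutations: list[MutationRecord]) -> pd.DataFrame:
    """Identical protein-position variants seen in >= 2 distinct patients.

    Matching is at the protein position (merging equivalent codon changes);
    the list is sorted by recurrence, then gene, then position.
    """
    rows = []
    for r in mutations:
        if not r.protein_change:
            continue
        m = _PROTEIN_RE.match(r.protein_change)
        if not m:
            continue
        rows.append((r.gene, int(m.group(1)), r.patient_id, r.protein_change))
    if not rows:
        return pd.DataFrame(columns=["gene", "protein_pos", "n_patients", "patients"])
    df = pd.DataFrame(rows, columns=["gene", "protein_pos", "patient_id", "protein_change"])
    agg = (
        df.groupby(["gene", "protein_pos"])["patient_id"]
        .agg(lambda s: sorted(set(s)))
        .reset_index(name="patients")
    )
    agg["n_patients"] = agg["patients"].str.len()
    hot = agg[agg["n_patients"] >= 2].copy()
    hot = hot.sort_values(
        ["n_patients", "gene", "protein_pos"], ascending=[False, True, True],
        ignore_index=True,
    )
    return hot[["gene", "protein_pos", "n_patients", "patients"]]


def carrier_status(
    catalogs: dict[str, SampleCatalog],
    family: GeneFamily,
    exclude=frozenset(),
) -> pd.Series:
    """Per-patient carrier flag: >= 1 non-silent mutation in the family.

    ``exclude`` removes artifact-prone members before testing.
    """
    fam = family.without(exclude) if exclude else family
    members = set(fam.members)
    status = {
        pid: any(
            r.gene in members and classify_non_silent(r) for r in cat.records
        )
        for pid, cat in catalogs.items()
    }
    return pd.Series(status, name="mucin_carrier")


def mucsig(expr: ExpressionMatrix, family: GeneFamily) -> pd.Series:
    """MUCsig metagene: per-sample mean of family-gene expression,
    z-standardised across the analysed cohort (mean 0, sd 1)."""
    present = [g for g in family.members if g in expr.genes]
    if not present:
        raise ValueError("no family gene present in expression matrix")
    missing = set(family.members) - set(present)
    if missing:
        logger.info("family genes absent from expression matrix: %s", sorted(missing))
    if expr.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardise")
    means = expr.values.loc[present].mean(axis=0)
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("family-gene means identical across samples; sd = 0")
    return ((means - means.mean()) / sd).rename("MUCsig")
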