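"""Synthetic reference genome bundled with the package.

The genome is a deliberately small, fully synthetic stand-in for the human
reference: three chromosomes carrying twenty single-exon genes on the forward
strand — breast-cancer drivers (TP53, PIK3CA, ...), the mismatch-repair genes
MSH2/MSH6 and twelve mucin family members.  It is large enough to extract
trinucleotide contexts and enumerate codon-level substitution effects, and
small enough to ship as plain FASTA.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .contexts import BASES, channel

_BUILD_SEED = 77003
_SPACER = 400  # intergenic spacer length (bp)

# gene -> (chromosome, CDS length in codons); mucins are longer, mimicking
# the large tandem-repeat-rich mucin coding sequences
GENE_PLAN: tuple[tuple[str, str, int], ...] = (
    ("MUC1", "1", 400), ("TP53", "1", 300), ("GATA3", "1", 300),
    ("MUC2", "1", 400), ("MUC3A", "1", 400), ("MUC4", "1", 400),
    ("AKT1", "1", 300),
    ("MSH2", "2", 300), ("MSH6", "2", 300), ("MUC5AC", "2", 400),
    ("MUC5B", "2", 400), ("MUC6", "2", 400), ("PIK3CA", "2", 300),
    ("MUC12", "3", 400), ("MUC13", "3", 400), ("MUC16", "3", 400),
    ("MUC17", "3", 400), ("MUC20", "3", 400), ("CDH1", "3", 300),
    ("MAP3K1", "3", 300),
)

MUCIN_GENES: tuple[str, ...] = tuple(
    g for g, _, _ in GENE_PLAN if g.startswith("MUC") and g not in ("MUC1x",)
)

_SENSE_CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if str(Seq(a + b + c).translate()) != "*"
]


@dataclass(frozen=True)
class GeneModel:
    """A single-exon forward-strand gene; start/end are 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def build_synthetic_genome(seed: int = _BUILD_SEED):
    """Deterministically construct the synthetic genome.

    Returns ``(sequences, genes)`` where *sequences* maps chromosome name to
    its DNA string and *genes* is a list of :class:`GeneModel`.  The bundled
    FASTA/TSV data files are the frozen output of this function; a unit test
    keeps them in sync.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    for chrom in ("1", "2", "3"):
        parts: list[str] = []
        pos = 0
        for name, gchrom, n_codons in GENE_PLAN:
            if gchrom != chrom:
                continue
            spacer = "".join(rng.choice(BASES, size=_SPACER))
            parts.append(spacer)
            pos += _SPACER
            body = "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2))
            stop = rng.choice(["TAA", "TAG", "TGA"])
            cds = "ATG" + body + stop
            genes.append(GeneModel(name, chrom, pos + 1, pos + len(cds)))
            parts.append(cds)
            pos += len(cds)
        parts.append("".join(rng.choice(BASES, size=_SPACER)))
        sequences[chrom] = "".join(parts)
    return sequences, genes


def genome_to_fasta(sequences: dict[str, str], width: int = 70) -> str:
    out = StringIO()
    for chrom, seq in sequences.items():
        out.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    return out.getvalue()


def genes_to_table(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.name, g.chrom, g.start, g.end, "+") for g in genes],
        columns=["gene", "chrom", "start", "end", "strand"],
    )


def arm_table(sequences: dict[str, str]) -> pd.DataFrame:
    """Split each chromosome at its midpoint into synthetic p and q arms."""
    rows = []
    for chrom, seq in sequences.items():
        mid = len(seq) // 2
        rows.append((chrom, f"{chrom}p", 1, mid))
        rows.append((chrom, f"{chrom}q", mid + 1, len(seq)))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])


class ReferenceGenome:
    """In-memory accessor over the (small) reference sequences.

    Provides base/trinucleotide lookup for spectrum construction and
    codon-level substitution-effect enumeration for the coding genes.
    """

    def __init__(self, sequences: dict[str, str], genes: list[GeneModel]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.genes = {g.name: g for g in genes}

    @classmethod
    def from_fasta(cls, fasta_path, gene_table: pd.DataFrame) -> "ReferenceGenome":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        genes = [
            GeneModel(r.gene, str(r.chrom), int(r.start), int(r.end))
            for r in gene_table.itertuples()
        ]
        return cls(seqs, genes)

    def base(self, chrom: str, pos: int) -> str:
        seq = self._chrom(chrom)
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {chrom}:{pos} outside reference")
        return seq[pos - 1]

    def context(self, chrom: str, pos: int) -> str:
        """Trinucleotide centred on *pos* (1-based); requires interior position."""
        seq = self._chrom(chrom)
        if not 2 <= pos <= len(seq) - 1:
            raise ValueError(f"position {chrom}:{pos} has no flanking bases")
        return seq[pos - 2 : pos + 1]

    def _chrom(self, chrom: str) -> str:
        if chrom not in self.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        return self.sequences[chrom]

    def cds(self, gene: str) -> str:
        g = self.genes[gene]
        return self.sequences[g.chrom][g.start - 1 : g.end]

    def gene_at(self, chrom: str, pos: int) -> str | None:
        for g in self.genes.values():
            if g.chrom == chrom and g.start <= pos <= g.end:
                return g.name
        return None

    @functools.lru_cache(maxsize=64)
    def substitution_effects(self, gene: str) -> pd.DataFrame:
        """Enumerate every single-base substitution in a gene's CDS.

        Returns one row per (cds_offset, alt) with the genomic position,
        ref/alt bases, consequence (missense/nonsense/synonymous and, for
        the ATG/stop edge codons, possible start/stop effects folded into
        nonsense/missense), the ref and alt amino acids, and the channel.
        """
        g = self.genes[gene]
        cds = self.cds(gene)
        rows = []
        for off, ref in enumerate(cds):
            codon_i = off // 3
            within = off % 3
            ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
            ref_aa = str(Seq(ref_codon).translate())
            pos = g.start + off
            tri = self.context(g.chrom, pos)
            for alt in BASES:
                if alt == ref:
                    continue
                alt_codon = (
                    ref_codon[:within] + alt + ref_codon[within + 1 :]
                )
                alt_aa = str(Seq(alt_codon).translate())
                if alt_aa == ref_aa:
                    cons = "synonymous"
                elif alt_aa == "*":
                    cons = "nonsense"
                elif ref_aa == "*":
                    cons = "noncoding"  # stop-loss; not modelled further
                else:
                    cons = "missense"
                rows.append(
                    (
                        off, pos, ref, alt, codon_i + 1, ref_codon, alt_codon,
                        ref_aa, alt_aa, cons, channel(tri, ref, alt),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cds_offset", "pos", "ref", "alt", "protein_pos", "ref_codon",
                "alt_codon", "ref_aa", "alt_aa", "consequence", "channel",
            ],
        )


def _data_path(name: str):
    return resources.files("bcpgenomics.data").joinpath(name)


@functools.lru_cache(maxsize=1)
def load_reference() -> ReferenceGenome:
    """Load the bundled synthetic genome."""
    gene_table = pd.read_csv(_data_path("genes_synthetic.tsv"), sep="\t")
    with resources.as_file(_data_path("genome_synthetic.fa")) as p:
        return ReferenceGenome.from_fasta(p, gene_table)


@functools.lru_cache(maxsize=1)
def load_arms() -> pd.DataFrame:
    """Load the bundled synthetic chromosome-arm definitions."""
    return pd.read_csv(_data_path("arms_synthetic.tsv"), sep="\t", dtype={"chrom": str})
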