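"""Partitioned supermatrix assembly from annotated mitogenomes.

The concatenation rules follow standard mitogenome phylogenetics practice:
per protein-coding gene the start and stop codons are stripped; columns shared
by overlapping gene pairs (ATP8/ATP6, ND4L/ND4, ND5/ND6 by default) appear
once (removed from the downstream member; a strict mode drops them from both);
L-strand genes enter as their reverse complement; the matrix is the CDS block,
then the RNA block, then the D-loop, with partitions for the three codon
positions, the RNAs and the D-loop.

Inputs must be per-gene homologous columns (pre-aligned; simulated data is
indel-free by construction), so no multiple alignment is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from mitodate.reads import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Gene", "AnnotatedGenome", "Supermatrix", "build_supermatrix",
    "count_unambiguous", "DEFAULT_OVERLAP_PAIRS",
]

DEFAULT_OVERLAP_PAIRS = [("ATP8", "ATP6"), ("ND4L", "ND4"), ("ND5", "ND6")]

_UNAMBIG = frozenset("ACGT")


@dataclass(frozen=True)
class Gene:
    """Annotated feature: 0-based half-open interval on the genome."""

    name: str
    start: int
    end: int
    strand: str = "H"  # H (heavy/forward) or L (light/reverse)
    gclass: str = "CDS"  # CDS, tRNA, rRNA, D-loop

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for gene {self.name}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"gene {self.name}: strand must be H or L")
        if self.gclass not in ("CDS", "tRNA", "rRNA", "D-loop"):
            raise ValueError(f"gene {self.name}: unknown class {self.gclass}")


@dataclass
class AnnotatedGenome:
    """A (pre-aligned) mitogenome sequence plus its gene table."""

    id: str
    seq: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.end > len(self.seq):
                raise ValueError(
                    f"gene {g.name} interval outside sequence bounds in {self.id}"
                )

    def gene_table(self) -> list[tuple]:
        return [(g.name, g.start, g.end, g.strand, g.gclass) for g in self.genes]


@dataclass
class Supermatrix:
    """Taxon-by-site character matrix over {A,C,G,T,N,-} with partitions."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites), dtype U1
    partitions: dict[str, np.ndarray]

    def __post_init__(self):
        cover = np.concatenate(list(self.partitions.values())) if self.partitions else np.array([], int)
        if len(cover) != self.matrix.shape[1] or len(np.unique(cover)) != len(cover):
            raise ValueError("partitions must be disjoint and jointly exhaustive")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def unambiguous_counts(self) -> dict[str, int]:
        return {t: count_unambiguous(self.row(t)) for t in self.taxa}

    @classmethod
    def from_sequences(
        cls, sequences: dict[str, str],
        partitions: dict[str, np.ndarray] | None = None,
    ) -> "Supermatrix":
        """Build directly from equal-length sequences (single partition default)."""
        taxa = list(sequences)
        lens = {len(s) for s in sequences.values()}
        if len(lens) != 1:
            raise ValueError("sequences have unequal lengths")
        n = lens.pop()
        mat = np.array([list(sequences[t]) for t in taxa], dtype="U1")
        if partitions is None:
            partitions = {"all": np.arange(n)}
        return cls(taxa, mat, partitions)

    def replace_taxon(self, old: str | list[str], new_name: str, new_row: str) -> "Supermatrix":
        """Drop taxa and add one replacement row (ancestor-for-tips swap)."""
        drop = {old} if isinstance(old, str) else set(old)
        keep = [i for i, t in enumerate(self.taxa) if t not in drop]
        taxa = [self.taxa[i] for i in keep] + [new_name]
        mat = np.vstack([self.matrix[keep], np.array(list(new_row), dtype="U1")])
        return Supermatrix(taxa, mat, self.partitions)


def count_unambiguous(row: str) -> int:
    """Number of unambiguous bases (A, C, G or T) in a matrix row."""
    return sum(1 for c in row if c in _UNAMBIG)


# ---------------------------------------------------------------------- build
def build_supermatrix(
    genomes: list[AnnotatedGenome],
    overlap_pairs: list[tuple[str, str]] | None = None,
    overlap_mode: str = "dedupe",
    strip_terminal_codons: bool = True,
) -> Supermatrix:
    """Assemble the partitioned matrix from annotated, pre-aligned genomes.

    ``overlap_mode='dedupe'`` keeps shared columns once (via the first gene of
    each named pair); ``'strict'`` drops them from both.  Genes missing from a
    taxon's table are filled with N (logged).  Raises if a CDS is not a codon
    multiple after exclusions, naming the gene.
    """
    if not genomes:
        raise ValueError("no genomes")
    if overlap_pairs is None:
        overlap_pairs = DEFAULT_OVERLAP_PAIRS
    if overlap_mode not in ("dedupe", "strict"):
        raise ValueError("overlap_mode must be 'dedupe' or 'strict'")
    ref = genomes[0]
    ref_genes = {g.name: g for g in ref.genes}
    for g in genomes[1:]:
        for gene in g.genes:
            r = ref_genes.get(gene.name)
            if r is not None and (gene.start, gene.end, gene.strand, gene.gclass) != (
                r.start, r.end, r.strand, r.gclass
            ):
                raise ValueError(
                    f"gene table mismatch for {gene.name} between "
                    f"{ref.id} and {g.id} (inputs must share homologous columns)"
                )

    # canonical order: CDS as listed, then tRNA+rRNA, then D-loop
    cds = [g for g in ref.genes if g.gclass == "CDS"]
    rnas = [g for g in ref.genes if g.gclass in ("tRNA", "rRNA")]
    dloops = [g for g in ref.genes if g.gclass == "D-loop"]

    # genomic columns to drop because of overlaps
    drop_cols: dict[str, set[int]] = {g.name: set() for g in ref.genes}
    for first, second in overlap_pairs:
        a, b = ref_genes.get(first), ref_genes.get(second)
        if a is None or b is None:
            continue
        shared = set(range(a.start, a.end)) & set(range(b.start, b.end))
        if not shared:
            continue
        drop_cols[second].update(shared)
        if overlap_mode == "strict":
            drop_cols[first].update(shared)

    def retained_positions(g: Gene) -> tuple[list[int], list[int]]:
        """(genomic positions in coding orientation, codon offsets)."""
        pos = list(range(g.start, g.end))
        if g.strand == "L":
            pos = pos[::-1]
        offs = list(range(len(pos)))
        if g.gclass == "CDS" and strip_terminal_codons:
            if len(pos) < 9:
                raise ValueError(f"CDS {g.name} too short to strip terminal codons")
            pos, offs = pos[3:-3], offs[3:-3]
        keep = [(p, o) for p, o in zip(pos, offs) if p not in drop_cols[g.name]]
        pos = [p for p, _ in keep]
        offs = [o for _, o in keep]
        if g.gclass == "CDS" and len(pos) % 3 != 0:
            raise ValueError(
                f"CDS {g.name} has {len(pos)} retained sites, not divisible by 3"
            )
        return pos, offs

    taxa = [g.id for g in genomes]
    columns: list[np.ndarray] = []  # per block, (n_taxa, width)
    codon_pos: list[np.ndarray] = []  # codon offsets (or -1) per block column

    def gene_block(g: Gene) -> tuple[np.ndarray, np.ndarray]:
        pos, offs = retained_positions(g)
        width = len(pos)
        block = np.full((len(taxa), width), "N", dtype="U1")
        for ti, genome in enumerate(genomes):
            has = any(x.name == g.name for x in genome.genes)
            if not has:
                logger.warning("gene %s missing in taxon %s: filled with N",
                               g.name, genome.id)
                continue
            chars = [genome.seq[p] for p in pos]
            if g.strand == "L":
                chars = list(reverse_complement("".join(chars))[::-1])
            block[ti] = chars
        cp = (np.array(offs) % 3) if g.gclass == "CDS" else np.full(width, -1)
        return block, cp

    for g in cds + rnas + dloops:
        b, cp = gene_block(g)
        columns.append(b)
        codon_pos.append(cp)

    matrix = np.concatenate(columns, axis=1) if columns else np.empty((len(taxa), 0), "U1")
    cpos = np.concatenate(codon_pos) if codon_pos else np.array([], int)
    widths = [c.shape[1] for c in columns]
    starts = np.concatenate([[0], np.cumsum(widths)]).astype(int)
    n_cds = len(cds)
    n_rna = len(rnas)
    cds_sites = np.arange(0, starts[n_cds])
    rna_sites = np.arange(starts[n_cds], starts[n_cds + n_rna])
    dloop_sites = np.arange(starts[n_cds + n_rna], matrix.shape[1])

    partitions: dict[str, np.ndarray] = {}
    for cp in (0, 1, 2):
        sel = cds_sites[cpos[cds_sites] == cp]
        partitions[f"cds_pos{cp + 1}"] = sel
    if len(rna_sites):
        partitions["rna"] = rna_sites
    if len(dloop_sites):
        partitions["dloop"] = dloop_sites
    partitions = {k: v for k, v in partitions.items() if len(v)}
    return Supermatrix(taxa, matrix, partitions)
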