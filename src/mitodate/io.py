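"""Readers and writers: FASTA/FASTQ, minimal SAM, Newick, tables, flat config.

FASTA is canonical internally; abundance annotations follow the dereplication
convention ``>id;size=N;``.  SAM output is deliberately minimal (header plus
mandatory fields, ungapped CIGAR) for interoperability without a binary
dependency.  All outputs are deterministic given the same inputs.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from Bio import SeqIO

from mitodate.reads import Placement, Read
from mitodate.trees import Tree

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "read_newick", "write_newick",
    "write_sam", "read_config", "write_config", "write_table",
    "read_gene_table", "write_gene_table", "read_partitions",
    "write_partitions",
]

_SIZE_RE = re.compile(r";size=(\d+);?")
_WRAP = 70


def read_fasta(path) -> list[Read]:
    """Parse FASTA into reads; ``;size=N;`` header annotations set abundance."""
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.description or rec.id
            m = _SIZE_RE.search(header)
            abundance = int(m.group(1)) if m else 1
            rid = _SIZE_RE.sub("", header).strip()
            records.append(Read(id=rid, seq=str(rec.seq).upper(),
                                abundance=abundance))
    return records


def write_fasta(path, reads, with_size: bool = False) -> None:
    """Write reads (or a dict name->sequence) as wrapped FASTA."""
    if isinstance(reads, dict):
        reads = [Read(id=k, seq=v) for k, v in reads.items()]
    with open(path, "w") as fh:
        for r in reads:
            header = r.id + (f";size={r.abundance};" if with_size else "")
            fh.write(f">{header}\n")
            for i in range(0, len(r.seq), _WRAP):
                fh.write(r.seq[i:i + _WRAP] + "\n")


def read_fastq(path) -> list[Read]:
    """Parse FASTQ; qualities are ignored beyond parsing."""
    with open(path) as fh:
        return [Read(id=rec.id, seq=str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fastq")]


def read_newick(path_or_text) -> Tree:
    text = path_or_text
    p = Path(str(path_or_text))
    if not str(path_or_text).strip().startswith("(") and p.exists():
        text = p.read_text()
    return Tree.from_newick(text)


def write_newick(path, tree: Tree, comments: dict[int, str] | None = None) -> None:
    Path(path).write_text(tree.to_newick(comments=comments) + "\n")


def write_sam(path, placements: list[Placement], reads, reference_name: str,
              reference_length: int) -> None:
    """Minimal SAM: @HD/@SQ header plus mandatory fields, ungapped CIGAR."""
    if isinstance(reads, list):
        reads = {r.id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference_name}\tLN:{reference_length}\n")
        for pl in placements:
            r = reads[pl.read_id]
            flag = 0 if pl.strand == "+" else 16
            fh.write(
                f"{pl.read_id}\t{flag}\t{reference_name}\t{pl.pos + 1}\t255\t"
                f"{pl.length}M\t*\t0\t0\t{r.seq}\t*\tNM:i:{pl.n_mismatch}\n"
            )


def write_table(path, df) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    """Flat ``key = value`` config; values are int/float/bool/str-coerced."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = _coerce(value.strip())
    return out


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        for k in sorted(config):
            fh.write(f"{k} = {config[k]}\n")


def read_gene_table(path) -> list:
    """TSV gene table: name, start, end, strand (H/L), class (0-based half-open)."""
    from mitodate.supermatrix import Gene

    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
        name, start, end, strand, gclass = parts
        genes.append(Gene(name, int(start), int(end), strand, gclass))
    return genes


def write_gene_table(path, genes) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tstart\tend\tstrand\tclass\n")
        for g in genes:
            fh.write(f"{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{g.gclass}\n")


def write_partitions(path, partitions: dict) -> None:
    """Partition file: ``name = start-end[,start-end...]`` (1-based inclusive)."""
    with open(path, "w") as fh:
        for name, sites in partitions.items():
            fh.write(f"{name} = {_ranges(np.asarray(sites))}\n")


def read_partitions(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _, spec = line.partition("=")
        sites = []
        for rng in spec.strip().split(","):
            a, _, b = rng.strip().partition("-")
            sites.extend(range(int(a) - 1, int(b if b else a)))
        out[name.strip()] = np.array(sites, dtype=int)
    return out


def _ranges(sites: np.ndarray) -> str:
    sites = np.sort(sites)
    chunks = []
    start = prev = int(sites[0])
    for s in sites[1:]:
        s = int(s)
        if s != prev + 1:
            chunks.append((start, prev))
            start = s
        prev = s
    chunks.append((start, prev))
    return ",".join(f"{a + 1}-{b + 1}" for a, b in chunks)


def _coerce(v: str):
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if "," in v:
        return [_coerce(x.strip()) for x in v.split(",")]
    return v
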