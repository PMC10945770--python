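"""Alignment preprocessing: codon threading, ungapped-column trimming, filters.

Alignments are :class:`Bio.Align.MultipleSeqAlignment` objects with ``-`` as
the gap character. A codon alignment is a nucleotide alignment whose length
is divisible by three and whose columns are handled in codon triplets.

The threading step back-translates a protein alignment onto the coding
sequences that produced it: each residue becomes its codon, each gap becomes
``---``. Trimming then keeps only the ubiquitously aligned (gap-free)
columns, which is the preprocessing the downstream tree-length metrics
assume.
"""

from __future__ import annotations

import os
import warnings
from statistics import median
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "alignment_from_pairs",
    "thread_codon_alignment",
    "trim_ungapped",
    "length_filter",
    "min_columns_gate",
]

GAP = "-"


class AlignmentError(ValueError):
    """Raised for inconsistent sequence input."""


def read_fasta(path: str | os.PathLike, *, aligned: bool = False):
    """Read FASTA into a dict id→sequence string, or an alignment if ``aligned``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids in FASTA input")
    if aligned:
        return alignment_from_pairs([(r.id, str(r.seq)) for r in records])
    return {r.id: str(r.seq) for r in records}


def write_fasta(seqs, path: str | os.PathLike) -> None:
    if isinstance(seqs, MultipleSeqAlignment):
        pairs = [(r.id, str(r.seq)) for r in seqs]
    elif isinstance(seqs, Mapping):
        pairs = list(seqs.items())
    else:
        pairs = list(seqs)
    with open(path, "w") as fh:
        for sid, seq in pairs:
            fh.write(f">{sid}\n{seq}\n")


def alignment_from_pairs(pairs: Iterable[tuple[str, str]]) -> MultipleSeqAlignment:
    pairs = list(pairs)
    if not pairs:
        raise AlignmentError("empty alignment")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    return MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in pairs
    )


def thread_codon_alignment(
    protein_aln: MultipleSeqAlignment, cds: Mapping[str, str]
) -> MultipleSeqAlignment:
    """Thread coding sequences through their aligned proteins (back-translation).

    Every aligned protein record must have a CDS of exactly three nucleotides
    per ungapped residue; a single terminal stop codon on the CDS is
    tolerated and dropped. The CDS must translate to the protein under the
    standard genetic code.
    """
    out: list[tuple[str, str]] = []
    for rec in protein_aln:
        sid = rec.id
        if sid not in cds:
            raise AlignmentError(f"no coding sequence supplied for record {sid!r}")
        prot = str(rec.seq)
        nuc = cds[sid].upper().replace("U", "T")
        residues = prot.replace(GAP, "")
        if len(nuc) == 3 * len(residues) + 3:
            last = nuc[-3:]
            if Seq(last).translate() == "*":
                nuc = nuc[:-3]
        if len(nuc) != 3 * len(residues):
            raise AlignmentError(
                f"record {sid!r}: CDS length {len(nuc)} does not match "
                f"{len(residues)} residues (expected {3 * len(residues)})"
            )
        translated = str(Seq(nuc).translate())
        for i, (aa_cds, aa_aln) in enumerate(zip(translated, residues)):
            if aa_cds != aa_aln and aa_aln != "X":
                raise AlignmentError(
                    f"record {sid!r}: CDS translation disagrees with aligned protein "
                    f"at residue {i + 1} ({aa_cds!r} vs {aa_aln!r})"
                )
        codons = iter(nuc[i : i + 3] for i in range(0, len(nuc), 3))
        threaded = "".join("---" if aa == GAP else next(codons) for aa in prot)
        out.append((sid, threaded))
    return alignment_from_pairs(out)


def trim_ungapped(aln: MultipleSeqAlignment, *, codon: bool = False) -> MultipleSeqAlignment:
    """Keep only ubiquitously aligned columns (no gap in any record).

    With ``codon=True`` the alignment is treated as codon triplets and a
    whole codon column is dropped if any of its three positions is gapped in
    any record.
    """
    ncol = aln.get_alignment_length()
    step = 3 if codon else 1
    if codon and ncol % 3:
        raise AlignmentError("codon alignment length not divisible by 3")
    rows = [str(rec.seq) for rec in aln]
    kept: list[int] = []
    for start in range(0, ncol, step):
        block = slice(start, start + step)
        if all(GAP not in row[block] for row in rows):
            kept.append(start)
    if not kept:
        warnings.warn("trim_ungapped removed every column", stacklevel=2)
        return MultipleSeqAlignment(
            SeqRecord(Seq(""), id=rec.id, description="") for rec in aln
        )
    out = [
        (rec.id, "".join(row[i : i + step] for i in kept))
        for rec, row in zip(aln, rows)
    ]
    return alignment_from_pairs(out)


def length_filter(seqs: Mapping[str, str], min_fraction: float = 0.5) -> dict[str, str]:
    """Drop sequences shorter than ``min_fraction`` of the others' median length.

    The median is computed leave-one-out: each sequence is compared with the
    median length of all *other* sequences in the cohort, so one truncated
    record cannot shelter itself by dragging the median down.
    """
    if not seqs:
        raise AlignmentError("empty sequence set")
    items = list(seqs.items())
    lengths = [len(s) for _, s in items]
    kept: dict[str, str] = {}
    for i, (sid, seq) in enumerate(items):
        others = lengths[:i] + lengths[i + 1 :]
        if not others or len(seq) >= min_fraction * median(others):
            kept[sid] = seq
    return kept


def min_columns_gate(aln: MultipleSeqAlignment, min_cols: int = 50, *, codon: bool = False) -> bool:
    """True iff the (trimmed) alignment has strictly more than ``min_cols`` positions.

    Positions are codons for codon alignments, residues/nucleotides otherwise.
    """
    ncol = aln.get_alignment_length()
    if codon:
        if ncol % 3:
            raise AlignmentError("codon alignment length not divisible by 3")
        ncol //= 3
    return ncol > min_cols
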