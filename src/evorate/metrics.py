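"""Extent-of-molecular-evolution statistics on gene trees.

The central quantity is total tree length — the summed branch length of a
gene tree in substitutions per aligned site — which measures how much
sequence space a gene has explored since the last common ancestor of the
sampled species. Companions here:

* a stratified bootstrap that resamples exactly one gene copy per species
  per replicate, so multi-copy gene families (e.g. a nuclear small-subunit
  family) can be compared fairly against single-copy genes;
* percentage ratios between tree lengths (gene vs gene, protein vs
  nucleotide), used to contrast how fast two loci evolve and how much
  protein change accompanies nucleotide change;
* the neutral expectation for that protein-per-nucleotide ratio, from
  exhaustive enumeration of single-nucleotide mutations under the standard
  genetic code. A protein/nucleotide ratio far below the neutral line is
  the signature of purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
from Bio.Seq import Seq

from .trees import (
    TreeError,
    prune_preserving_lengths,
    species_leaf_index,
    tree_total_length,
)

__all__ = [
    "BootstrapSummary",
    "stratified_bootstrap_tree_length",
    "subunit_ratio",
    "protein_per_nucleotide_ratio",
    "neutral_expected_fraction",
    "neutral_ratio_line",
    "simulate_neutral_codon_substitutions",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class BootstrapSummary:
    """Mean ± SD of total tree length over stratified bootstrap replicates."""

    mean: float
    sd: float
    n_reps: int
    seed: int
    lengths: np.ndarray = field(repr=False, compare=False, default=None)


def stratified_bootstrap_tree_length(
    tree: dendropy.Tree,
    species_map: Mapping[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
) -> BootstrapSummary:
    """Stratified bootstrap of total tree length over multi-copy gene families.

    Each replicate samples exactly one leaf (gene copy) uniformly per
    species, prunes the tree to that sample preserving path lengths, and
    records its total length. With every species single-copy the procedure
    is degenerate: every replicate equals the full tree length and SD is 0.
    """
    if seed is None:
        raise TreeError("a seed is required for the stratified bootstrap")
    leaves = {lf.taxon.label if lf.taxon else lf.label for lf in tree.leaf_node_iter()}
    unmapped = leaves - set(species_map)
    if unmapped:
        raise TreeError(f"leaves without a species assignment: {sorted(unmapped)}")
    index = species_leaf_index({lf: sp for lf, sp in species_map.items() if lf in leaves})
    for sp, ls in index.items():
        if not ls:
            raise TreeError(f"species {sp!r} has no leaves in the tree")

    rng = np.random.default_rng(seed)
    species = list(index)
    copies = [index[sp] for sp in species]
    multi = any(len(c) > 1 for c in copies)
    full_length = tree_total_length(tree)

    lengths = np.empty(n_reps)
    cache: dict[frozenset, float] = {}
    for r in range(n_reps):
        picked = frozenset(c[rng.integers(len(c))] for c in copies)
        if not multi or len(picked) == len(leaves):
            lengths[r] = full_length
            continue
        if picked not in cache:
            cache[picked] = tree_total_length(prune_preserving_lengths(tree, picked))
        lengths[r] = cache[picked]
    sd = float(np.std(lengths, ddof=1)) if n_reps > 1 else 0.0
    return BootstrapSummary(float(np.mean(lengths)), sd, n_reps, seed, lengths)


def subunit_ratio(length_a: float, length_b: float) -> float:
    """Percentage ratio of two extents of evolution: 100 × a / b."""
    if length_b <= 0:
        raise ValueError("denominator tree length must be positive")
    return 100.0 * length_a / length_b


def protein_per_nucleotide_ratio(
    nuc_tree: dendropy.Tree, prot_tree: dendropy.Tree, *, invert: bool = False
) -> float:
    """Percentage ratio of protein to nucleotide tree length.

    Both lengths are per-site (amino-acid sites vs nucleotide sites) so
    under neutral evolution the expected value is 300 × f_N where f_N is the
    nonsynonymous fraction of single-nucleotide changes
    (:func:`neutral_ratio_line`); purifying selection drives it lower.
    ``invert=True`` reports nucleotide-per-protein instead.
    """
    nuc = tree_total_length(nuc_tree)
    prot = tree_total_length(prot_tree)
    if invert:
        return subunit_ratio(nuc, prot)
    return subunit_ratio(prot, nuc)


def _codon_fraction(codon: str) -> float:
    """Nonsynonymous fraction of the ≤9 viable single-nucleotide mutants."""
    aa = str(Seq(codon).translate())
    nonsyn = 0
    allowed = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            allowed += 1
            if str(Seq(mut).translate()) != aa:
                nonsyn += 1
    if allowed == 0:  # cannot happen for sense codons under the standard code
        raise ValueError(f"codon {codon} admits no non-stop mutations")
    return nonsyn / allowed


def neutral_expected_fraction(codon_seq: str) -> float:
    """Expected nonsynonymous fraction of random single-nucleotide changes.

    For each codon, all single-nucleotide changes are enumerated (9 per
    codon, uniform), changes creating stop codons are excluded, and the
    nonsynonymous fraction of the rest is computed; the result is the mean
    over codons. A terminal stop codon is ignored; internal stops are
    errors.
    """
    seq = codon_seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    if any(c in _STOPS for c in codons):
        raise ValueError("internal stop codon in sequence")
    if not codons:
        raise ValueError("no sense codons in sequence")
    return float(np.mean([_codon_fraction(c) for c in codons]))


def neutral_ratio_line(codon_seq: str) -> float:
    """Neutral expectation (%) for the protein-per-nucleotide length ratio.

    Protein branch lengths are per amino-acid site (3 nucleotides), so the
    no-selection expectation of 100 × protein/nucleotide tree length is
    300 × f_N.
    """
    return 300.0 * neutral_expected_fraction(codon_seq)


def simulate_neutral_codon_substitutions(
    codon_seq: str, n_subs: int, seed: int | None = None
) -> tuple[str, int, int]:
    """Evolve a codon sequence by uniform single-nucleotide substitutions.

    Substitutions are applied sequentially at uniform random positions with
    uniform alternative bases; proposals creating a stop codon are rejected
    and redrawn. Returns the mutated sequence and the realised counts of
    nucleotide and amino-acid changes — the Monte-Carlo oracle for
    :func:`neutral_expected_fraction`.
    """
    if seed is None:
        raise ValueError("a seed is required")
    seq = list(codon_seq.upper().replace("U", "T"))
    if len(seq) % 3:
        raise ValueError("sequence length must be divisible by 3")
    rng = np.random.default_rng(seed)
    n_aa = 0
    applied = 0
    while applied < n_subs:
        pos = int(rng.integers(len(seq)))
        alternatives = [b for b in _BASES if b != seq[pos]]
        base = alternatives[rng.integers(3)]
        start = 3 * (pos // 3)
        codon = seq[start : start + 3]
        mutant = list(codon)
        mutant[pos - start] = base
        if "".join(mutant) in _STOPS:
            continue
        old_aa = str(Seq("".join(codon)).translate())
        new_aa = str(Seq("".join(mutant)).translate())
        seq[pos] = base
        applied += 1
        if new_aa != old_aa:
            n_aa += 1
    return "".join(seq), applied, n_aa
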