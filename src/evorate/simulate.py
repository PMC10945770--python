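"""Synthetic trees, orthogroup cohorts, gene families and trait tables.

Everything here is built to have exactly the statistical structure the
analysis modules assume, so the whole pipeline can be exercised and its
estimators validated without any external data:

* Yule (pure-birth) species trees with exponential waiting times;
* orthogroup cohorts in which each gene tree is the species tree scaled by
  a gene-specific rate drawn from a heavy-tailed LogNormal, plus optional
  per-branch jitter — the generative model behind percentile ranking;
* multi-copy gene families, in which species tips are replaced by stars of
  diverged copies — the target of the stratified bootstrap;
* tip traits generated as intercept + slope × root-to-tip distance +
  independent Gaussian noise — the model the root-to-tip regression fits.

Defaults mirror the study conditions of the angiosperm analysis this
package implements: 93 taxa (the C3 kinetic sample), an ancestral
intercept of 81.1 (the CO2/O2 specificity of the inferred angiosperm
ancestor), and a mean gene-copy number just over two (the multi-copy
small-subunit family).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .trees import read_newick, root_to_tip, write_newick

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "jitter_branch_lengths",
    "simulate_orthogroup_cohort",
    "simulate_multicopy_family",
    "simulate_directional_traits",
    "make_fixture_bundle",
]

DEFAULT_COPY_NUMBERS: dict[int, float] = {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}


@dataclass
class SimulationConfig:
    """Generating parameters for a complete synthetic study."""

    seed: int
    n_taxa: int = 93
    birth_rate: float = 1.0
    n_orthogroups: int = 200
    rate_mu: float = 0.0  # LogNormal location of gene rates
    rate_sigma: float = 1.0  # LogNormal scale of gene rates
    branch_jitter_cv: float = 0.1
    focal_jitter_cv: float = 0.3  # lineage rate variation of the focal gene tree
    intercept: float = 81.1
    slope: float = 20.0
    noise_sd: float = 5.0
    copy_numbers: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_COPY_NUMBERS)
    )
    within_species_divergence: float = 0.02


def _spawn(seed: int, salt: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Pure-birth tree: split a uniformly chosen lineage after Exp(k·λ) waits.

    Starting from two lineages at the root, while k lineages are active the
    next speciation arrives after an Exponential(k·λ) wait; when n lineages
    exist one final Exponential(n·λ) stretch is added so every tip has a
    positive pendant edge. Expected root-to-tip depth is therefore
    (1/λ) Σ_{k=2..n} 1/k. Leaves are labelled sp01, sp02, …
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.edge.length += wait
        if k == n_taxa:
            break
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        for _ in range(2):
            active.append(parent.new_child(edge_length=0.0))
        k += 1
    width = max(2, len(str(n_taxa)))
    for i, node in enumerate(active, start=1):
        node.taxon = taxa.new_taxon(label=f"sp{i:0{width}d}")
    return tree


def jitter_branch_lengths(
    tree: dendropy.Tree, cv: float, seed: int | None = None
) -> dendropy.Tree:
    """Multiply every branch by an independent Gamma(mean 1, given CV) factor.

    Turns an ultrametric species tree into a gene tree with lineage-specific
    rate variation, so root-to-tip distances vary across tips the way they
    do in real substitution trees. ``cv = 0`` returns an identical copy.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    out = read_newick(write_newick(tree))
    if cv > 0:
        shape = 1.0 / cv**2
        for node in out.preorder_node_iter():
            if node is out.seed_node or node.edge.length is None:
                continue
            node.edge.length *= rng.gamma(shape, 1.0 / shape)
    return out


def simulate_orthogroup_cohort(
    species_tree: dendropy.Tree,
    n_orthogroups: int,
    rate_mu: float = 0.0,
    rate_sigma: float = 1.0,
    branch_jitter_cv: float = 0.0,
    seed: int | None = None,
) -> tuple[dict[str, dendropy.Tree], dict[str, str], np.ndarray]:
    """Orthogroup gene trees: the species tree scaled by LogNormal gene rates.

    Orthogroup g gets every branch of the species tree multiplied by
    r_g ~ LogNormal(rate_mu, rate_sigma); with ``branch_jitter_cv`` > 0 each
    branch additionally receives an independent Gamma multiplier with mean 1
    and the stated coefficient of variation. Leaf ``sp`` of orthogroup g is
    labelled ``sp|OGg``. Returns (trees, leaf→species map, gene rates).
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    rates = rng.lognormal(rate_mu, rate_sigma, size=n_orthogroups)
    trees: dict[str, dendropy.Tree] = {}
    species_map: dict[str, str] = {}
    newick = write_newick(species_tree)
    for g in range(n_orthogroups):
        og_id = f"OG{g:05d}"
        gene_tree = read_newick(newick)
        for node in gene_tree.preorder_node_iter():
            if node is gene_tree.seed_node or node.edge.length is None:
                continue
            factor = rates[g]
            if branch_jitter_cv > 0:
                shape = 1.0 / branch_jitter_cv**2
                factor *= rng.gamma(shape, 1.0 / shape)
            node.edge.length *= factor
        for leaf in gene_tree.leaf_node_iter():
            sp = leaf.taxon.label
            gene = f"{sp}|{og_id}"
            leaf.taxon.label = gene
            species_map[gene] = sp
        trees[og_id] = gene_tree
    return trees, species_map, rates


def simulate_multicopy_family(
    species_tree: dendropy.Tree,
    copy_numbers: Mapping[int, float] | Mapping[str, int] | None = None,
    within_species_divergence: float = 0.02,
    seed: int | None = None,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Replace species tips by stars of gene copies (a multi-copy family).

    ``copy_numbers`` is either a distribution {copies: probability} sampled
    per species, or an explicit {species: copies} assignment. Each copy
    hangs from the original tip on its own pendant edge drawn uniformly on
    (0, ``within_species_divergence``), so copies of one species differ in
    length (expected pairwise separation = the stated divergence) and a
    stratified bootstrap over copies has genuine variance. With divergence
    0 all copies are interchangeable. Single-copy species keep their
    original tip (and label) untouched.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    tree = read_newick(write_newick(species_tree))  # deep, namespace-fresh copy
    species_map: dict[str, str] = {}
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)

    if copy_numbers is None:
        copy_numbers = DEFAULT_COPY_NUMBERS
    explicit = all(isinstance(k, str) for k in copy_numbers)
    if not explicit:
        ks = sorted(copy_numbers)
        probs = np.array([copy_numbers[k] for k in ks], dtype=float)
        probs /= probs.sum()

    for leaf in leaves:
        sp = leaf.taxon.label
        k = int(copy_numbers[sp]) if explicit else int(rng.choice(ks, p=probs))
        if k < 1:
            raise ValueError(f"species {sp!r} assigned {k} copies")
        if k == 1:
            species_map[sp] = sp
            continue
        leaf.taxon = None
        for c in range(1, k + 1):
            gene = f"{sp}_copy{c}"
            pendant = (
                float(rng.uniform(0.0, within_species_divergence))
                if within_species_divergence > 0
                else 0.0
            )
            child = leaf.new_child(edge_length=pendant)
            child.taxon = tree.taxon_namespace.new_taxon(label=gene)
            species_map[gene] = sp
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree, species_map


def simulate_directional_traits(
    tree: dendropy.Tree,
    intercept: float,
    slope: float,
    noise_sd: float,
    seed: int | None = None,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Tip traits: intercept + slope × root-to-tip distance + Gaussian noise.

    This is exactly the linear model the root-to-tip regression fits, with
    independent residuals (no phylogenetic correlation). Returns a
    species-indexed single-column table.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rtt = root_to_tip(tree)
    species = sorted(rtt)
    values = [
        intercept + slope * rtt[sp] + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        for sp in species
    ]
    frame = pd.DataFrame({trait_name: values}, index=pd.Index(species, name="species"))
    return frame


def make_fixture_bundle(config: SimulationConfig, out_dir: str | os.PathLike) -> dict:
    """Write a complete, self-consistent synthetic study to ``out_dir``.

    Contents: species tree, a rate-jittered focal gene tree (traits are
    simulated on its root-to-tip distances, which vary across tips), a
    multi-copy focal family tree + species map, an orthogroup cohort (one
    Newick per orthogroup) + species map, a trait table, and a JSON
    manifest recording every generating parameter. The same config
    reproduces a byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    species_tree = simulate_yule_tree(
        config.n_taxa, config.birth_rate, seed=int(_spawn(config.seed, "tree").integers(2**31))
    )
    write_newick(species_tree, out / "species_tree.nwk")

    cohort, cohort_map, rates = simulate_orthogroup_cohort(
        species_tree,
        config.n_orthogroups,
        config.rate_mu,
        config.rate_sigma,
        config.branch_jitter_cv,
        seed=int(_spawn(config.seed, "cohort").integers(2**31)),
    )
    og_dir = out / "orthogroups"
    og_dir.mkdir(exist_ok=True)
    for og_id, tr in cohort.items():
        write_newick(tr, og_dir / f"{og_id}.nwk")

    family_tree, family_map = simulate_multicopy_family(
        species_tree,
        config.copy_numbers,
        config.within_species_divergence,
        seed=int(_spawn(config.seed, "family").integers(2**31)),
    )
    write_newick(family_tree, out / "focal_family.nwk")

    focal_gene_tree = jitter_branch_lengths(
        species_tree,
        cv=config.focal_jitter_cv,
        seed=int(_spawn(config.seed, "focal").integers(2**31)),
    )
    write_newick(focal_gene_tree, out / "focal_gene_tree.nwk")

    traits = simulate_directional_traits(
        focal_gene_tree,
        config.intercept,
        config.slope,
        config.noise_sd,
        seed=int(_spawn(config.seed, "traits").integers(2**31)),
        trait_name="trait",
    )
    traits.to_csv(out / "traits.tsv", sep="\t")

    combined_map = {**{sp: sp for sp in root_to_tip(species_tree)}, **family_map, **cohort_map}
    pd.Series(combined_map, name="species").rename_axis("leaf").to_csv(
        out / "species_map.tsv", sep="\t"
    )

    manifest = {
        "config": {
            k: (v if not isinstance(v, dict) else {str(kk): vv for kk, vv in v.items()})
            for k, v in asdict(config).items()
        },
        "n_orthogroups": len(cohort),
        "gene_rates_mean": float(np.mean(rates)),
        "files": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
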