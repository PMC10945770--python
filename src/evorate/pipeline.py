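"""End-to-end analyses with manifests, built from the stage modules.

Each pipeline returns a plain dict of pandas tables plus a run manifest
(input checksums, configuration snapshot, seeds, package version, per-stage
row counts) so a run can be reproduced and audited. The three pipelines
mirror the three analyses the metrics support: trait regression against
root-to-tip distance, percentile ranking against an orthogroup cohort, and
a two-tree comparison of evolutionary extent with a stratified bootstrap.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import metrics, rank, regression
from .trees import leaf_labels, patristic_matrix, root_to_tip, tree_total_length, write_newick

__all__ = [
    "pipeline_kinetics",
    "pipeline_rank",
    "pipeline_subunit_compare",
    "read_species_map",
    "read_trait_table",
]


def _pkg_version() -> str:
    try:
        return version("evorate")
    except PackageNotFoundError:
        return "unknown"


def _checksum(obj) -> str:
    if isinstance(obj, dendropy.Tree):
        payload = write_newick(obj)
    elif isinstance(obj, pd.DataFrame):
        payload = obj.to_csv()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest(inputs: dict, config: dict, counts: dict) -> dict:
    return {
        "tool_version": _pkg_version(),
        "inputs": {k: _checksum(v) for k, v in inputs.items()},
        "config": config,
        "row_counts": counts,
    }


def read_species_map(path) -> dict[str, str]:
    """Read a two-column (leaf, species) TSV/CSV with header into a dict."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    leaf_col, sp_col = frame.columns[:2]
    return dict(zip(frame[leaf_col], frame[sp_col]))


def read_trait_table(path) -> pd.DataFrame:
    """Read a species-keyed trait table (first column = species)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    return frame.set_index(frame.columns[0])


def pipeline_kinetics(
    tree_or_distances: dendropy.Tree | Mapping[str, float] | pd.Series,
    trait_table: pd.DataFrame,
    trait_names: Sequence[str] | None = None,
    n_sites: int | None = None,
    clade_age: float = regression.DEFAULT_CLADE_AGE_MY,
) -> dict:
    """Trait-vs-evolution analysis: regressions, ancestral estimates, rates.

    Accepts either a rooted tree (root-to-tip distances are computed) or a
    precomputed species→distance mapping. Produces the regression table,
    the ancestral-trait table (intercept ± 1 SE per trait) and — when
    ``n_sites`` is given — the improvement-rate table (change per
    substitution, percent per substitution and per million years, My per
    substitution).
    """
    if isinstance(tree_or_distances, dendropy.Tree):
        distances = pd.Series(root_to_tip(tree_or_distances), name="distance")
    else:
        distances = pd.Series(tree_or_distances, dtype=float, name="distance")
    if trait_names is None:
        trait_names = list(trait_table.columns)
    joined = distances.index.intersection(trait_table.index)
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} species shared between distances and traits"
        )
    regs = regression.run_trait_regressions(distances, trait_table, trait_names)
    ancestral = regs[["intercept", "se_intercept", "n"]].rename(
        columns={"intercept": "ancestral_value", "se_intercept": "ancestral_se"}
    )
    result = {
        "distances": distances.rename_axis("species"),
        "regressions": regs,
        "ancestral": ancestral,
    }
    if n_sites is not None:
        mean_rtt = float(distances.loc[joined].mean())
        rows = []
        for trait_name, row in regs.iterrows():
            reg = regression.RegressionResult(
                row["slope"], row["intercept"], row["se_slope"],
                row["se_intercept"], row["r2_percent"] / 100.0, row["p"], int(row["n"]),
            )
            rows.append(
                regression.improvement_rates(trait_name, reg, mean_rtt, n_sites, clade_age)
            )
        result["improvements"] = pd.DataFrame([vars(r) for r in rows]).set_index("trait")
    result["manifest"] = _manifest(
        {"distances": dict(distances), "traits": trait_table},
        {"trait_names": list(trait_names), "n_sites": n_sites, "clade_age": clade_age},
        {k: len(v) for k, v in result.items() if isinstance(v, (pd.Series, pd.DataFrame))},
    )
    return result


def pipeline_rank(
    focal_tree: dendropy.Tree,
    orthogroup_trees: Mapping[str, dendropy.Tree],
    species_map: Mapping[str, str],
    min_n: int = rank.DEFAULT_MIN_N,
    species_pairs: Sequence[tuple[str, str]] | None = None,
) -> dict:
    """Percentile ranking of the focal gene over every species pair.

    For each species pair, the focal distance is the patristic distance
    between the species' focal-gene copies; duplicate copies yield multiple
    percentiles which are averaged. Pairs failing the minimum-background
    threshold are flagged, retained in the per-pair table, and excluded
    from the summary.
    """
    focal_leaves = leaf_labels(focal_tree)
    unmapped = [lf for lf in focal_leaves if lf not in species_map]
    if unmapped:
        raise ValueError(f"focal leaves without species assignment: {unmapped}")
    by_species: dict[str, list[str]] = {}
    for lf in focal_leaves:
        by_species.setdefault(species_map[lf], []).append(lf)
    species = sorted(by_species)
    if species_pairs is None:
        species_pairs = [
            (a, b) for i, a in enumerate(species) for b in species[i + 1 :]
        ]
    focal_mat = patristic_matrix(focal_tree)

    per_pair: list[rank.PercentileResult] = []
    for sp_a, sp_b in species_pairs:
        cohort = rank.background_pair_distances(
            orthogroup_trees, species_map, sp_a, sp_b
        )
        copies = []
        for ga in by_species.get(sp_a, []):
            for gb in by_species.get(sp_b, []):
                focal_d = float(focal_mat.loc[ga, gb])
                copies.append(rank.percentile_faster(focal_d, cohort, min_n))
        if not copies:
            continue
        per_pair.append(
            copies[0] if len(copies) == 1 else rank.aggregate_duplicate_percentiles(copies)
        )

    table = pd.DataFrame(
        {
            "species_a": [r.species_pair[0] for r in per_pair],
            "species_b": [r.species_pair[1] for r in per_pair],
            "focal_distance": [r.focal_distance for r in per_pair],
            "percent_faster": [r.percent_faster for r in per_pair],
            "n_background": [r.n_background for r in per_pair],
            "passed": [r.passed_threshold for r in per_pair],
        }
    )
    result = {"per_pair": table}
    if any(r.passed_threshold for r in per_pair):
        result["summary"] = rank.summarize_percentiles(per_pair)
    else:
        import warnings

        warnings.warn("no species pair met the background-size threshold", stacklevel=2)
        result["summary"] = pd.DataFrame()
    result["manifest"] = _manifest(
        {"focal_tree": focal_tree, "species_map": dict(species_map)},
        {"min_n": min_n, "n_orthogroups": len(orthogroup_trees)},
        {"per_pair": len(table), "summary": len(result["summary"])},
    )
    return result


def pipeline_subunit_compare(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    species_map_b: Mapping[str, str] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
    codon_seq: str | None = None,
) -> dict:
    """Compare the extent of evolution of two loci (e.g. two subunits).

    Reports both total lengths and their percentage ratio; when the second
    locus is multi-copy (``species_map_b``), a stratified bootstrap of its
    tree length; and, when a codon sequence is supplied, the neutral
    expectation for the protein-per-nucleotide ratio.
    """
    len_a = tree_total_length(tree_a)
    len_b = tree_total_length(tree_b)
    result: dict = {
        "total_length_a": len_a,
        "total_length_b": len_b,
        "ratio_a_to_b_percent": metrics.subunit_ratio(len_a, len_b),
    }
    if species_map_b is not None:
        result["bootstrap_b"] = metrics.stratified_bootstrap_tree_length(
            tree_b, species_map_b, n_reps=n_reps, seed=seed
        )
    if codon_seq is not None:
        result["neutral_ratio_percent"] = metrics.neutral_ratio_line(codon_seq)
    result["manifest"] = _manifest(
        {"tree_a": tree_a, "tree_b": tree_b},
        {"n_reps": n_reps, "seed": seed},
        {},
    )
    return result
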