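"""Percentile ranking of a focal gene's rate against an orthogroup cohort.

For a pair of species, the extent of evolution separating their copies of a
focal gene (a patristic distance in the focal gene tree) is ranked against
the distances separating every other pair of orthologous sequences for the
same species pair, measured across a collection of orthogroup trees. The
rank is reported as the percentage of the background cohort evolving
*faster* than the focal gene; a slow-evolving gene therefore scores near
100. Species pairs with fewer than ``min_n`` background measurements are
flagged and excluded from summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import patristic_matrix

__all__ = [
    "BackgroundCohort",
    "PercentileResult",
    "background_pair_distances",
    "percentile_faster",
    "aggregate_duplicate_percentiles",
    "summarize_percentiles",
]

DEFAULT_MIN_N = 100


@dataclass(frozen=True)
class BackgroundCohort:
    """Ortholog patristic distances for one species pair across orthogroups."""

    species_pair: tuple[str, str]
    distances: tuple[tuple[str, str, str, float], ...]  # (orthogroup, gene_a, gene_b, d)

    @property
    def values(self) -> np.ndarray:
        return np.array([d for *_, d in self.distances], dtype=float)

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class PercentileResult:
    species_pair: tuple[str, str]
    focal_distance: float
    percent_faster: float  # NaN when the cohort is empty
    n_background: int
    passed_threshold: bool


def background_pair_distances(
    orthogroup_trees: Mapping[str, dendropy.Tree] | Sequence[dendropy.Tree],
    species_map: Mapping[str, str],
    species_a: str,
    species_b: str,
    ortholog_pairs: Iterable[tuple[str, str]] | None = None,
) -> BackgroundCohort:
    """Collect ortholog patristic distances between two species.

    By default every cross-species leaf pair within each orthogroup tree is
    treated as an ortholog pair (which over-counts in the presence of
    paralogs); supplying ``ortholog_pairs`` — e.g. exported from an
    orthology tool — restricts the cohort to the listed gene pairs.
    """
    if not isinstance(orthogroup_trees, Mapping):
        orthogroup_trees = {f"OG{i:04d}": t for i, t in enumerate(orthogroup_trees)}
    wanted = (
        {frozenset(p) for p in ortholog_pairs} if ortholog_pairs is not None else None
    )
    collected: list[tuple[str, str, str, float]] = []
    for og_id, tree in orthogroup_trees.items():
        leaves = [
            lf.taxon.label if lf.taxon else lf.label for lf in tree.leaf_node_iter()
        ]
        genes_a = [g for g in leaves if species_map.get(g) == species_a]
        genes_b = [g for g in leaves if species_map.get(g) == species_b]
        if not genes_a or not genes_b:
            continue
        mat = patristic_matrix(tree)
        for ga in genes_a:
            for gb in genes_b:
                if wanted is not None and frozenset((ga, gb)) not in wanted:
                    continue
                collected.append((og_id, ga, gb, float(mat.loc[ga, gb])))
    if not collected:
        warnings.warn(
            f"no orthogroup contains both {species_a!r} and {species_b!r}",
            stacklevel=2,
        )
    return BackgroundCohort((species_a, species_b), tuple(collected))


def percentile_faster(
    focal: float, cohort: BackgroundCohort, min_n: int = DEFAULT_MIN_N
) -> PercentileResult:
    """Percentage of the background cohort evolving faster than the focal gene.

    Midrank tie handling: ties contribute half weight, so
    percent = 100 × (#{d > focal} + 0.5 #{d = focal}) / n.
    """
    values = cohort.values
    n = len(values)
    if n == 0:
        return PercentileResult(cohort.species_pair, focal, math.nan, 0, False)
    greater = int(np.sum(values > focal))
    ties = int(np.sum(values == focal))
    percent = 100.0 * (greater + 0.5 * ties) / n
    return PercentileResult(cohort.species_pair, focal, percent, n, n >= min_n)


def aggregate_duplicate_percentiles(
    results: Sequence[PercentileResult],
) -> PercentileResult:
    """Average the percentiles of duplicate focal copies for one species pair.

    When a species pair yields several focal comparisons (gene duplications,
    or one assembly matching several sub-species), the mean percentile is
    taken; the reported background size is the smallest of the group's.
    """
    if not results:
        raise ValueError("cannot aggregate an empty group")
    pairs = {r.species_pair for r in results}
    if len(pairs) != 1:
        raise ValueError(f"results span multiple species pairs: {sorted(pairs)}")
    return PercentileResult(
        results[0].species_pair,
        float(np.mean([r.focal_distance for r in results])),
        float(np.mean([r.percent_faster for r in results])),
        min(r.n_background for r in results),
        all(r.passed_threshold for r in results),
    )


def summarize_percentiles(
    results: Sequence[PercentileResult],
    groups: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Five-number summary (plus mean) of percentiles over species pairs.

    Only results passing the minimum-background threshold contribute.
    ``groups`` optionally maps species pairs to taxonomic-group labels, in
    which case one summary row per group is returned.
    """
    passing = [r for r in results if r.passed_threshold and not math.isnan(r.percent_faster)]
    if not passing:
        raise ValueError("no species pair passes the background-size threshold")
    frame = pd.DataFrame(
        {
            "group": [
                groups.get(r.species_pair, "all") if groups else "all" for r in passing
            ],
            "percent_faster": [r.percent_faster for r in passing],
        }
    )
    agg = frame.groupby("group")["percent_faster"].agg(
        n_pairs="size",
        mean="mean",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
    )
    return agg.reset_index()
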