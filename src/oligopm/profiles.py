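"""Comparative analysis of consumption profiles.

Given a strains × substrates level matrix, these operations answer the
questions a transporter-specificity study asks: which substrates does a
strain utilize; which are consumed by a transporter *pair* but by neither
single-transporter strain (synergy); which fraction is specific to strains
carrying a given transporter complement; how are substrate sets biased in
amino-acid composition at the N-/C-terminus; and how do strains cluster by
consumption preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .peptides import Peptide
from .scoring import ProfileMatrix


@dataclass(frozen=True)
class SubstrateSet:
    """A labeled set of peptide substrates."""

    label: str
    members: frozenset[Peptide]

    def __len__(self) -> int:
        return len(self.members)

    def names(self) -> list[str]:
        return sorted(p.display_name for p in self.members)


def _strain_levels(m: ProfileMatrix, strain: str) -> pd.Series:
    if strain not in m.levels.index:
        raise ValidationError(f"strain {strain!r} not in profile matrix")
    return m.levels.loc[strain]


def consumed_set(m: ProfileMatrix, strain: str, min_level: int = 1) -> SubstrateSet:
    """Substrates with level ≥ *min_level* for *strain* (missing ≠ consumed)."""
    row = _strain_levels(m, strain)
    by_name = {p.display_name: p for p in m.substrates}
    members = frozenset(
        by_name[name]
        for name, lev in row.items()
        if pd.notna(lev) and int(lev) >= min_level
    )
    return SubstrateSet(label=strain, members=members)


def combination_specific(
    m: ProfileMatrix,
    combo: str,
    singles: Sequence[str],
    min_level: int = 1,
) -> SubstrateSet:
    """Substrates consumed by the *combo* strain but by no *singles* strain."""
    members = set(consumed_set(m, combo, min_level).members)
    for s in singles:
        members -= consumed_set(m, s, min_level).members
    label = f"{combo} minus {'+'.join(singles) if singles else 'nothing'}"
    return SubstrateSet(label=label, members=frozenset(members))


def level_difference_set(
    m: ProfileMatrix,
    combo: str,
    singles: Sequence[str],
    min_diff: int,
) -> SubstrateSet:
    """Substrates where combo level − max(single levels) ≥ *min_diff*.

    A level-aware refinement of :func:`combination_specific`, e.g. to pull
    out substrates at high level in the pair strain but level 0 in both
    singles.
    """
    if not singles:
        raise ValidationError("level_difference_set requires at least one single")
    combo_row = _strain_levels(m, combo).astype(float)
    single_max = (
        pd.concat([_strain_levels(m, s).astype(float) for s in singles], axis=1)
        .max(axis=1)
        .fillna(0.0)
    )
    diff = combo_row.fillna(0.0) - single_max
    by_name = {p.display_name: p for p in m.substrates}
    members = frozenset(by_name[n] for n, d in diff.items() if d >= min_diff)
    return SubstrateSet(label=f"{combo} Δlevel≥{min_diff}", members=members)


def specific_fraction(
    m: ProfileMatrix,
    reference: str,
    lacking: Sequence[str],
    having: Sequence[str],
    min_level: int = 1,
) -> SubstrateSet:
    """Substrates consumed by *reference* and every *having* strain, and by
    no *lacking* strain."""
    members = set(consumed_set(m, reference, min_level).members)
    for s in having:
        members &= consumed_set(m, s, min_level).members
    for s in lacking:
        members -= consumed_set(m, s, min_level).members
    return SubstrateSet(label=f"{reference}-specific", members=frozenset(members))


# ---------------------------------------------------------------------------
# Positional amino-acid composition

POSITIONS = ("N_terminal", "C_terminal", "any")


def _position_codes(p: Peptide, position: str) -> list[str]:
    if position == "N_terminal":
        return [p.n_terminal.code]
    if position == "C_terminal":
        return [p.c_terminal.code]
    if position == "any":
        return [r.code for r in p.residues]
    raise ValidationError(f"unknown position {position!r}")


@dataclass
class CompositionTable:
    """Residue counts/frequencies at a peptide position, with fold enrichment
    of the set's frequencies over a background set's frequencies."""

    position: str
    counts: dict[str, int]
    frequencies: dict[str, float]
    fold_vs_background: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        codes = sorted(self.counts)
        return pd.DataFrame(
            {
                "residue": codes,
                "count": [self.counts[c] for c in codes],
                "frequency": [self.frequencies[c] for c in codes],
                "fold_vs_background": [self.fold_vs_background[c] for c in codes],
            }
        )


def positional_composition(
    s: SubstrateSet, background: SubstrateSet, position: str = "N_terminal"
) -> CompositionTable:
    """Residue composition of *s* at *position*, as fold over *background*."""
    if len(s.members) == 0:
        raise ValidationError("cannot profile an empty substrate set")
    if len(background.members) == 0:
        raise ValidationError("background set is empty")

    def tally(members: Iterable[Peptide]) -> tuple[dict[str, int], dict[str, float]]:
        counts: dict[str, int] = {}
        for p in members:
            for code in _position_codes(p, position):
                counts[code] = counts.get(code, 0) + 1
        total = sum(counts.values())
        return counts, {c: n / total for c, n in counts.items()}

    counts, freqs = tally(s.members)
    _, bg_freqs = tally(background.members)
    fold = {
        c: (freqs[c] / bg_freqs[c]) if c in bg_freqs else float("inf")
        for c in freqs
    }
    return CompositionTable(position, counts, freqs, fold)


def composition_permutation_pvalue(
    s: SubstrateSet,
    background: SubstrateSet,
    residue: str,
    position: str = "N_terminal",
    n_resamples: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for residue enrichment (optional add-on).

    Resamples sets of size |s| from the background and asks how often the
    resampled frequency of *residue* at *position* reaches the observed
    one.  This significance layer goes beyond plain fold reporting.
    """
    obs = positional_composition(s, background, position).frequencies.get(residue, 0.0)
    bg = sorted(background.members, key=lambda p: p.display_name)
    rng = np.random.default_rng(seed)
    hits = 0
    k = len(s.members)
    for _ in range(n_resamples):
        idx = rng.choice(len(bg), size=k, replace=False)
        sample = SubstrateSet("perm", frozenset(bg[i] for i in idx))
        f = positional_composition(sample, background, position).frequencies.get(
            residue, 0.0
        )
        if f >= obs:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


# ---------------------------------------------------------------------------
# Clustering

@dataclass
class ClusteringResult:
    """Agglomerative clustering of one matrix axis."""

    axis: str
    labels: list[str]
    linkage: np.ndarray
    order: list[int] = field(default_factory=list)

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, flat)}


def cluster_profiles(
    m: ProfileMatrix,
    axis: str = "rows",
    metric: str = "euclidean",
    method: str = "average",
) -> ClusteringResult:
    """Hierarchically cluster strains (rows) or substrates (cols) on levels.

    Missing levels are treated as 0 for distance purposes.  Leaf order is
    the scipy dendrogram order without optimal leaf ordering, so ties
    resolve by input index and results are reproducible.
    """
    data = m.levels.astype(float).fillna(0.0)
    if axis == "cols":
        data = data.T
    elif axis != "rows":
        raise ValidationError(f"axis must be 'rows' or 'cols', got {axis!r}")
    labels = [str(i) for i in data.index]
    if len(labels) < 2:
        raise ValidationError(f"need at least 2 items on axis {axis!r} to cluster")
    dists = pdist(data.to_numpy(), metric=metric)
    Z = hierarchy.linkage(dists, method=method)
    order = hierarchy.leaves_list(Z).tolist()
    return ClusteringResult(axis=axis, labels=labels, linkage=Z, order=order)


def to_newick(c: ClusteringResult) -> str:
    """Serialize the merge tree as Newick; branch lengths are height gaps."""
    tree = hierarchy.to_tree(c.linkage)

    def walk(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{c.labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def export_heatmap(
    m: ProfileMatrix,
    row_clustering: ClusteringResult | None = None,
    col_clustering: ClusteringResult | None = None,
    image_path: str | None = None,
    tsv_path: str | None = None,
) -> pd.DataFrame:
    """Write the clustered level heatmap (image) and the reordered matrix (TSV).

    Returns the reordered level DataFrame.
    """
    levels = m.levels
    if row_clustering is not None:
        levels = levels.loc[row_clustering.ordered_labels]
    if col_clustering is not None:
        levels = levels[col_clustering.ordered_labels]
    if tsv_path is not None:
        levels.to_csv(tsv_path, sep="\t")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(6, 0.05 * levels.shape[1]), max(3, 0.4 * levels.shape[0]))
        )
        im = ax.imshow(
            levels.astype(float).fillna(-1).to_numpy(),
            aspect="auto",
            cmap="viridis",
            vmin=-1,
            vmax=5,
            interpolation="nearest",
        )
        ax.set_yticks(range(levels.shape[0]), labels=list(levels.index), fontsize=7)
        ax.set_xticks([])
        ax.set_xlabel(f"{levels.shape[1]} substrates")
        fig.colorbar(im, ax=ax, label="consumption level")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return levels
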