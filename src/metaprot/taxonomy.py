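"""Peptide-level LCA taxonomy profiles and 16S count-table roll-ups.

A peptide that maps to several organisms is placed at the lowest common
ancestor (LCA) of its candidate taxa; profiling at a rank then accrues its
intensity to the LCA's ancestor at that rank, or to "Unassigned/unknown"
when the LCA sits above the requested rank — the convention that puts
broadly shared peptides into the unassigned bin at finer ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus",
         "species")
UNASSIGNED = "Unassigned/unknown"


@dataclass
class TaxonomyTree:
    """taxid -> (parent, rank, name), NCBI-taxdump style, with one root."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if p == t or p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for t in self.parent:
            self.lineage(t)  # raises on cycles / dangling parents

    def lineage(self, taxid: int) -> list[int]:
        """Path from taxid up to (and including) the root."""
        if taxid not in self.parent:
            raise KeyError(f"unknown taxid {taxid}")
        path = [taxid]
        seen = {taxid}
        while path[-1] != self.root:
            nxt = self.parent[path[-1]]
            if nxt not in self.parent:
                raise KeyError(f"parent {nxt} of {path[-1]} not in tree")
            if nxt in seen:
                raise ValueError(f"cycle detected at taxid {nxt}")
            path.append(nxt)
            seen.add(nxt)
        return path

    @classmethod
    def from_tables(cls, nodes: pd.DataFrame, names: pd.DataFrame
                    ) -> "TaxonomyTree":
        return cls(
            parent=dict(zip(nodes["taxid"].astype(int),
                            nodes["parent"].astype(int))),
            rank=dict(zip(nodes["taxid"].astype(int), nodes["rank"])),
            name=dict(zip(names["taxid"].astype(int), names["name"])),
        )

    @classmethod
    def from_tsv(cls, nodes_path: str | Path, names_path: str | Path
                 ) -> "TaxonomyTree":
        return cls.from_tables(pd.read_csv(nodes_path, sep="\t"),
                               pd.read_csv(names_path, sep="\t"))


def lca(taxids, tree: TaxonomyTree) -> int:
    """Lowest node ancestral to (or equal to) every input taxid."""
    ids = set(taxids)
    if not ids:
        raise ValueError("lca of an empty taxid set")
    it = iter(ids)
    common = tree.lineage(next(it))
    common_set = set(common)
    for t in it:
        lin = set(tree.lineage(t))
        common = [n for n in common if n in lin]
        common_set = set(common)
    return common[0]


def _rank_index(rank: str) -> int | None:
    return RANKS.index(rank) if rank in RANKS else None


def bin_at_rank(taxid: int, rank: str, tree: TaxonomyTree) -> int | None:
    """Ancestor-or-self of ``taxid`` used for profiling at ``rank``.

    Returns None (Unassigned) when the taxon sits above the requested rank.
    A lineage missing the requested rank rolls to the nearest named
    ancestor at or above it.
    """
    want = _rank_index(rank)
    if want is None:
        raise ValueError(f"invalid rank {rank!r}")
    ranked = [(idx, node) for node in tree.lineage(taxid)
              if (idx := _rank_index(tree.rank.get(node, ""))) is not None]
    if not ranked or ranked[0][0] < want:
        return None  # taxon is above (less specific than) the requested rank
    for idx, node in ranked:
        if idx <= want:
            return node
    return None


def _normalise(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=0)
    out = table.div(totals.where(totals > 0, 1.0), axis=1)
    out.index.name = "taxon"
    return out.sort_index()


def peptide_taxon_profile(
    peptide_taxa: dict[str, set[int]],
    intensities: pd.DataFrame,
    tree: TaxonomyTree,
    rank: str,
) -> pd.DataFrame:
    """Intensity-weighted taxon shares per sample at one rank.

    ``intensities`` is a peptide x sample table; each peptide's intensity
    accrues to its LCA's ancestor at ``rank`` or to "Unassigned/unknown".
    Peptides absent from the map are unassigned. Shares sum to 1 per sample.
    """
    if (intensities.fillna(0.0) < 0).to_numpy().any():
        raise ValueError("intensities must be non-negative")
    acc: dict[str, pd.Series] = {}
    zero = pd.Series(0.0, index=intensities.columns)
    for pep in intensities.index:
        w = intensities.loc[pep].fillna(0.0)
        taxa = peptide_taxa.get(pep)
        node = bin_at_rank(lca(taxa, tree), rank, tree) if taxa else None
        label = tree.name.get(node, str(node)) if node is not None else UNASSIGNED
        acc[label] = acc.get(label, zero) + w
    return _normalise(pd.DataFrame(acc).T)


def amplicon_profile(
    counts: pd.DataFrame, tree: TaxonomyTree, rank: str
) -> pd.DataFrame:
    """Roll a 16S taxon(taxid) x sample count table up to one rank.

    Counts on taxa above the requested rank go to "Unassigned/unknown";
    taxa absent from the tree raise.
    """
    if (counts.fillna(0) < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    acc: dict[str, pd.Series] = {}
    zero = pd.Series(0.0, index=counts.columns)
    for taxid in counts.index:
        node = bin_at_rank(int(taxid), rank, tree)
        label = tree.name.get(node, str(node)) if node is not None else UNASSIGNED
        acc[label] = acc.get(label, zero) + counts.loc[taxid].fillna(0).astype(float)
    return _normalise(pd.DataFrame(acc).T)


def taxon_ratio(
    profile: pd.Series, numerator_taxon: str, denominator_taxon: str
) -> tuple[float, str]:
    """Share ratio of two taxa plus its "1:x" presentation.

    Returns (numerator share / denominator share, "1:x") with
    x = denominator/numerator rounded to the nearest integer — e.g. shares
    of 4.2% and 22.7% give (0.185, "1:5").
    """
    num = float(profile[numerator_taxon])
    den = float(profile[denominator_taxon])
    if den == 0:
        raise ZeroDivisionError(f"denominator taxon {denominator_taxon!r} has zero share")
    if num == 0:
        raise ZeroDivisionError(f"numerator taxon {numerator_taxon!r} has zero share")
    return num / den, f"1:{round(den / num)}"
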