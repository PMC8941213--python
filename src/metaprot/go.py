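"""Gene-ontology relative abundance (count- and intensity-weighted) and
hypergeometric term enrichment.

Count-based shares depict sequence diversity (each observed protein group
contributes one count to each of its terms); intensity-weighted shares
depict material abundance (each group contributes the *mean* intensity of
its observed constituent peptides, controlling for protein length).
Groups without a term in a namespace accrue to "None"; minor terms can be
collapsed into "Other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
NONE_CATEGORY = "None"
OTHER_CATEGORY = "Other"


@dataclass
class GoAnnotationMap:
    """group_id -> set of (go_id, namespace), plus go_id -> readable name."""

    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, pairs in self.annotations.items():
            for go_id, ns in pairs:
                if ns not in NAMESPACES:
                    raise ValueError(f"invalid namespace {ns!r} on {group}/{go_id}")

    def terms_for(self, group_id: str, namespace: str) -> list[str]:
        return sorted(go for go, ns in self.annotations.get(group_id, set())
                      if ns == namespace)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GoAnnotationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        ann: dict[str, set[tuple[str, str]]] = {}
        names: dict[str, str] = {}
        for _, row in df.iterrows():
            ann.setdefault(row["group_id"], set()).add(
                (row["go_id"], row["namespace"]))
            if "name" in df.columns and pd.notna(row.get("name")):
                names[row["go_id"]] = row["name"]
        return cls(annotations=ann, names=names)


def collapse_other(table: pd.DataFrame, min_share: float = 0.01) -> pd.DataFrame:
    """Collapse terms whose share is below ``min_share`` in every sample.

    The "None" category is never collapsed. Shares still sum to 1.
    """
    terms = [t for t in table.index if t != NONE_CATEGORY]
    minor = [t for t in terms if (table.loc[t] < min_share).all()]
    if not minor:
        return table
    kept = table.drop(index=minor)
    kept.loc[OTHER_CATEGORY] = table.loc[minor].sum(axis=0)
    return kept


def unweighted_go_abundance(
    presence: pd.DataFrame,
    annotations: GoAnnotationMap,
    namespace: str,
    min_share_other: float | None = None,
) -> pd.DataFrame:
    """Count-based GO shares per sample.

    ``presence`` is a group x sample boolean table (group observed in
    sample). Each observed group contributes one full count to each of its
    terms in the namespace — no fractional splitting — and one count to
    "None" if unannotated there. Shares are counts over the per-sample
    total including "None".
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"invalid namespace {namespace!r}")
    counts: dict[str, np.ndarray] = {}
    n_samples = presence.shape[1]
    for group in presence.index:
        obs = presence.loc[group].to_numpy(dtype=bool).astype(float)
        terms = annotations.terms_for(group, namespace) or [NONE_CATEGORY]
        for term in terms:
            counts[term] = counts.get(term, np.zeros(n_samples)) + obs
    table = pd.DataFrame(counts, index=presence.columns).T
    table = table.div(table.sum(axis=0), axis=1).fillna(0.0)
    table.index.name = "term"
    if min_share_other is not None:
        table = collapse_other(table, min_share_other)
    return table.sort_index()


def group_weights(peptide_intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-sample group weight = mean of its observed peptide intensities.

    Input is the long unshared peptide table (sample, peptide, group_id,
    intensity); output is group x sample means (NaN where unobserved).
    """
    return peptide_intensities.pivot_table(
        index="group_id", columns="sample", values="intensity", aggfunc="mean")


def weighted_go_abundance(
    peptide_intensities: pd.DataFrame,
    annotations: GoAnnotationMap,
    namespace: str,
    min_share_other: float | None = None,
) -> pd.DataFrame:
    """Intensity-weighted GO shares per sample.

    Term intensity = sum over its constituent observed groups of the mean
    intensity of that group's observed peptides; a group with zero observed
    peptides contributes nothing. Unannotated groups accrue to "None".
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"invalid namespace {namespace!r}")
    weights = group_weights(peptide_intensities)
    acc: dict[str, np.ndarray] = {}
    n_samples = weights.shape[1]
    for group in weights.index:
        w = np.nan_to_num(weights.loc[group].to_numpy(dtype=float))
        terms = annotations.terms_for(group, namespace) or [NONE_CATEGORY]
        for term in terms:
            acc[term] = acc.get(term, np.zeros(n_samples)) + w
    table = pd.DataFrame(acc, index=weights.columns).T
    table = table.div(table.sum(axis=0), axis=1).fillna(0.0)
    table.index.name = "term"
    if min_share_other is not None:
        table = collapse_other(table, min_share_other)
    return table.sort_index()


def fold_expansion(
    weighted: pd.DataFrame, unweighted: pd.DataFrame, go_id: str
) -> tuple[float, int]:
    """Mean over samples of weighted/unweighted share for one term.

    Samples where the unweighted share is zero are excluded from the mean
    and returned as a count. A ratio > 1 is an expansion going from
    count-based to intensity-based representation; < 1 a contraction.
    """
    if go_id not in weighted.index or go_id not in unweighted.index:
        raise KeyError(f"term {go_id!r} absent from abundance tables")
    w = weighted.loc[go_id]
    u = unweighted.loc[go_id]
    usable = u > 0
    n_excluded = int((~usable).sum())
    if usable.sum() == 0:
        raise ValueError(f"term {go_id!r} has zero unweighted share everywhere")
    return float((w[usable] / u[usable]).mean()), n_excluded


def hypergeom_pvalue(k: int, n_total: int, n_annotated: int,
                     n_significant: int) -> float:
    """One-sided over-representation tail P(X >= k) for the 2x2 table.

    X ~ Hypergeometric(n_total, n_annotated, n_significant): the number of
    annotated groups among the significant ones under the null of no
    association.
    """
    return float(stats.hypergeom.sf(k - 1, n_total, n_annotated,
                                    n_significant))


def go_enrichment(
    significant_groups: set[str],
    universe_groups: set[str],
    annotations: GoAnnotationMap,
    min_universe_annotated: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term and namespace.

    Background = significant ∪ universe; 2x2 table of (significant vs not)
    x (annotated vs not). Odds ratios use a Haldane 0.5 correction when a
    cell is zero. Terms annotated on fewer than ``min_universe_annotated``
    background groups are skipped.
    """
    if not significant_groups:
        raise ValueError("empty significant set")
    background = set(universe_groups) | set(significant_groups)
    n_total = len(background)
    n_sig = len(significant_groups)
    term_groups: dict[tuple[str, str], set[str]] = {}
    for group in background:
        for go_id, ns in annotations.annotations.get(group, set()):
            term_groups.setdefault((go_id, ns), set()).add(group)
    rows = []
    for (go_id, ns), groups_with in sorted(term_groups.items()):
        if len(groups_with) < min_universe_annotated:
            continue
        k = len(groups_with & set(significant_groups))
        K = len(groups_with)
        p = hypergeom_pvalue(k, n_total, K, n_sig)
        a = k
        b = n_sig - k
        c = K - k
        d = (n_total - n_sig) - c
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b * c)
        rows.append((go_id, ns, annotations.names.get(go_id, ""),
                     k, K, n_sig, n_total, odds, p))
    return pd.DataFrame(rows, columns=[
        "go_id", "namespace", "name", "n_sig_annotated", "n_annotated",
        "n_significant", "n_background", "odds_ratio", "p_value",
    ])
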