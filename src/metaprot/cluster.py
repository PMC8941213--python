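"""Greedy protein-sequence clustering at an identity threshold.

Groups protein sequences at >= 95% global-alignment identity into protein
groups with stable representatives — the unit at which peptide intensities
are aggregated and differential testing is done. The strategy is the
classic greedy longest-first one: sequences are visited in order of
decreasing length and join the first existing group whose representative
they match at or above the threshold, otherwise they found a new group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import global_identity


@dataclass
class ProteinGroup:
    group_id: str
    representative: str
    members: list[str] = field(default_factory=list)
    member_identities: dict[str, float] = field(default_factory=dict)


def _shared_kmer(a: str, b: str, k: int = 5) -> bool:
    if len(a) < k or len(b) < k:
        return True  # too short to screen; always align
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[j:j + k] in kmers for j in range(len(b) - k + 1))


def greedy_cluster(
    sequences: dict[str, str],
    threshold: float = 0.95,
    prefilter: bool = False,
) -> list[ProteinGroup]:
    """Cluster sequences greedily, longest first (ties by accession).

    Each sequence is compared against existing group representatives in
    group-creation order and joins the first one attaining
    ``global_identity >= threshold`` (first-fit, as in CD-HIT); otherwise
    it becomes the representative of a new group. With ``prefilter`` a
    shared-5-mer screen skips alignments against representatives sharing
    no 5-mer — a safe shortcut for near-full-length matches at high
    thresholds, but not in general, hence off by default.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    order = sorted(sequences, key=lambda acc: (-len(sequences[acc]), acc))
    groups: list[ProteinGroup] = []
    for acc in order:
        seq = sequences[acc]
        placed = False
        for grp in groups:
            rep_seq = sequences[grp.representative]
            if prefilter and not _shared_kmer(seq, rep_seq):
                continue
            ident = global_identity(seq, rep_seq)
            if ident >= threshold:
                grp.members.append(acc)
                grp.member_identities[acc] = ident
                placed = True
                break
        if not placed:
            gid = f"G{len(groups):05d}"
            groups.append(ProteinGroup(
                group_id=gid, representative=acc, members=[acc],
                member_identities={acc: 1.0},
            ))
    return groups


def accession_to_group(groups: list[ProteinGroup]) -> dict[str, str]:
    return {acc: g.group_id for g in groups for acc in g.members}


def write_groups_tsv(groups: list[ProteinGroup], path: str | Path) -> None:
    pd.DataFrame(
        [(g.group_id, g.representative, ";".join(g.members)) for g in groups],
        columns=["group_id", "representative", "members"],
    ).to_csv(path, sep="\t", index=False)


def read_groups_tsv(path: str | Path) -> list[ProteinGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        members = row["members"].split(";")
        out.append(ProteinGroup(
            group_id=row["group_id"], representative=row["representative"],
            members=members, member_identities={},
        ))
    return out


def write_clstr(groups: list[ProteinGroup], sequences: dict[str, str],
                path: str | Path) -> None:
    """Write a .clstr-style cluster listing (representative marked '*')."""
    with open(path, "w") as fh:
        for i, g in enumerate(groups):
            fh.write(f">Cluster {i}\n")
            for j, acc in enumerate(g.members):
                mark = ("*" if acc == g.representative
                        else f"{100 * g.member_identities.get(acc, float('nan')):.2f}%")
                fh.write(f"{j}\t{len(sequences[acc])}aa, >{acc}... {mark}\n")
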