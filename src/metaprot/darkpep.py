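"""Dark-peptidome estimation: reconciling de novo and database PSMs.

Per-scan pairing of de novo calls with database assignments, a scaled
global-alignment similarity between the two sequences, score histograms,
and the headline estimator: spectra that score as peptide-like (de novo
score at or above a conservative cutoff, 75 by default) yet received no
database assignment — an estimate of database-elusive peptide space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import scaled_similarity

_MOD_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]|[^A-Za-z]")


def preprocess_peptide(peptide: str) -> str:
    """Strip modification annotations and collapse L to I.

    De novo sequencing cannot distinguish leucine from isoleucine by mass,
    so both are compared as I; parenthesised/bracketed mass tags and any
    non-letter characters are removed first.
    """
    bare = _MOD_RE.sub("", peptide).upper()
    return bare.replace("L", "I")


def nw_similarity(peptide_a: str, peptide_b: str) -> float:
    """Needleman-Wunsch similarity scaled to [0, 100] after preprocessing.

    100 is attained exactly when the processed sequences are identical
    (a perfect de novo/database match up to I/L and modifications).
    """
    a = preprocess_peptide(peptide_a)
    b = preprocess_peptide(peptide_b)
    if not a or not b:
        raise ValueError("empty peptide after preprocessing")
    return scaled_similarity(a, b)


def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df.duplicated(subset=["sample", "scan"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (sample, scan) in {label}: "
            f"({first['sample']}, {first['scan']})")


def pair_psms(database_psms: pd.DataFrame,
              denovo_psms: pd.DataFrame) -> pd.DataFrame:
    """Outer-join database and de novo PSMs on (sample, scan).

    Unidentified database feature rows (empty peptide) are ignored.
    Paired records get a Novor-database similarity score; database-only
    records carry no de novo score and are excluded from score histograms.
    Columns: sample, scan, denovo_peptide, novor_score, database_peptide,
    similarity.
    """
    db = database_psms[database_psms["peptide"].astype(str).str.len() > 0]
    db = db[["sample", "scan", "peptide"]].rename(
        columns={"peptide": "database_peptide"})
    dn = denovo_psms[["sample", "scan", "peptide", "score"]].rename(
        columns={"peptide": "denovo_peptide", "score": "novor_score"})
    _check_unique(db, "database PSMs")
    _check_unique(dn, "de novo PSMs")
    merged = dn.merge(db, on=["sample", "scan"], how="outer")
    paired = merged["denovo_peptide"].notna() & merged["database_peptide"].notna()
    merged["similarity"] = np.nan
    merged.loc[paired, "similarity"] = [
        nw_similarity(a, b)
        for a, b in zip(merged.loc[paired, "denovo_peptide"],
                        merged.loc[paired, "database_peptide"])
    ]
    return merged.sort_values(["sample", "scan"]).reset_index(drop=True)


def score_histograms(matches: pd.DataFrame, bin_width: float = 1.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stacked histogram data by Novor score plus joint (score, similarity).

    Returns (per-sample bin counts split into database-assigned vs
    unassigned de novo PSMs, joint pairs for paired records only).
    Database-only records carry no de novo score and are excluded.
    """
    dn = matches[matches["novor_score"].notna()].copy()
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    dn["bin"] = pd.cut(dn["novor_score"], bins=edges, right=False,
                       include_lowest=True)
    dn.loc[dn["novor_score"] >= edges[-2], "bin"] = dn["bin"].cat.categories[-1]
    dn["assigned"] = dn["database_peptide"].notna()
    hist = (dn.groupby(["sample", "bin", "assigned"], observed=False)
              .size().rename("count").reset_index())
    hist["bin_left"] = hist["bin"].apply(lambda iv: iv.left).astype(float)
    hist = hist[["sample", "bin_left", "assigned", "count"]]
    joint = dn[dn["assigned"]][["sample", "scan", "novor_score", "similarity"]]
    return hist, joint.reset_index(drop=True)


def dark_count(matches: pd.DataFrame, cutoff: float = 75.0
               ) -> tuple[pd.Series, float]:
    """Per-sample count of high-scoring, database-unassigned de novo PSMs.

    A record is dark when novor_score >= cutoff and it has no database
    peptide. Returns (per-sample counts, cross-sample average).
    """
    dark = (matches["novor_score"].notna()
            & (matches["novor_score"] >= cutoff)
            & matches["database_peptide"].isna())
    counts = (matches.assign(dark=dark).groupby("sample")["dark"].sum()
              .astype(int))
    return counts, float(counts.mean())


@dataclass
class DarkSummary:
    """Per-study accounting of the dark peptidome estimate."""

    per_sample_dark: pd.Series
    per_sample_total_ms2: pd.Series
    total_identified: int
    average_dark: float
    average_total_ms2: float
    assigned_fraction: float       # identified / total MS2, study-wide
    dark_fraction: float           # avg dark / avg total MS2 per sample
    projected_increase: float      # sum dark / total identified


def dark_summary(
    dark_counts: pd.Series,
    total_ms2_per_sample: pd.Series,
    total_identified: int,
) -> DarkSummary:
    """Project the dark count onto the study's spectrum accounting.

    dark fraction = average dark count / average total MS2 per sample;
    projected identification increase = sum of dark counts / total
    identified spectra. Values are kept unrounded; rounding is a
    presentation concern.
    """
    dark_counts = pd.Series(dark_counts)
    totals = pd.Series(total_ms2_per_sample)
    if (totals <= 0).any() or total_identified <= 0:
        raise ValueError("totals must be positive")
    if ((dark_counts - totals.reindex(dark_counts.index)) > 0).any():
        raise ValueError("dark count exceeds total MS2 in some sample")
    avg_dark = float(dark_counts.mean())
    avg_total = float(totals.mean())
    return DarkSummary(
        per_sample_dark=dark_counts,
        per_sample_total_ms2=totals,
        total_identified=int(total_identified),
        average_dark=avg_dark,
        average_total_ms2=avg_total,
        assigned_fraction=float(total_identified / totals.sum()),
        dark_fraction=avg_dark / avg_total,
        projected_increase=float(dark_counts.sum() / total_identified),
    )
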