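"""Peptide-to-protein-group label-free quantification.

Turns database PSM tables plus protein groups into a filtered, normalized
group x sample intensity matrix: shared-peptide exclusion, simplified
match-between-runs (10 ppm / 15 min by default), the three-rule missing
value filter, and a median/MAD-calibrated generalized-log normalization
standing in for variance-stabilizing normalization. Zero intensity is
treated as missing (MS1 non-detection), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cluster import ProteinGroup, accession_to_group

RAW = "raw"
NORMALIZED = "normalized-log"


@dataclass
class QuantMatrix:
    """Group x sample intensities with explicit missingness (NaN)."""

    values: pd.DataFrame          # index group_id, columns sample ids
    cohorts: pd.Series            # sample -> cohort label
    scale: str = RAW

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.cohorts.index)
        if missing:
            raise ValueError(f"samples without cohort label: {sorted(missing)}")
        if self.scale not in (RAW, NORMALIZED):
            raise ValueError(f"unknown scale flag {self.scale!r}")

    def cohort_columns(self, cohort: str) -> list[str]:
        cols = [s for s in self.values.columns if self.cohorts[s] == cohort]
        if not cols:
            raise ValueError(f"cohort {cohort!r} has zero samples")
        return cols


def _identified(psms: pd.DataFrame) -> pd.Series:
    return psms["peptide"].astype(str).str.len() > 0


def build_peptide_group_map(
    psms: pd.DataFrame, groups: list[ProteinGroup]
) -> pd.DataFrame:
    """Assign every identified peptide to a protein group.

    A peptide is assigned to the single group containing all of its parent
    accessions; if its accessions span more than one group it is flagged
    shared (and its intensity is later discarded).
    Returns columns peptide, group_id, shared.
    """
    acc2grp = accession_to_group(groups)
    ident = psms[_identified(psms)]
    parents: dict[str, set[str]] = {}
    for pep, accs in zip(ident["peptide"], ident["proteins"]):
        parents.setdefault(pep, set()).update(a for a in str(accs).split(";") if a)
    rows = []
    for pep in sorted(parents):
        gids = set()
        for acc in parents[pep]:
            if acc not in acc2grp:
                raise KeyError(f"accession {acc!r} not found in any protein group")
            gids.add(acc2grp[acc])
        shared = len(gids) > 1
        rows.append((pep, min(gids), shared))
    return pd.DataFrame(rows, columns=["peptide", "group_id", "shared"])


def peptide_intensity_table(
    psms: pd.DataFrame, pep_map: pd.DataFrame
) -> pd.DataFrame:
    """Long table of unshared identified peptide intensities with group ids.

    Columns: sample, peptide, group_id, intensity. Zero intensities are
    dropped (missing, not zero).
    """
    ident = psms[_identified(psms) & (psms["intensity"] > 0)]
    unshared = pep_map[~pep_map["shared"]][["peptide", "group_id"]]
    merged = ident.merge(unshared, on="peptide", how="inner")
    return merged[["sample", "peptide", "group_id", "intensity"]]


def aggregate_intensities(
    psms: pd.DataFrame, pep_map: pd.DataFrame, cohorts: pd.Series
) -> QuantMatrix:
    """Sum unshared peptide intensities within protein groups per sample.

    Shared peptides contribute nothing; a group with no observed peptide in
    a sample is missing there (NaN).
    """
    long = peptide_intensity_table(psms, pep_map)
    mat = long.pivot_table(index="group_id", columns="sample",
                           values="intensity", aggfunc="sum")
    mat = mat.reindex(columns=list(cohorts.index))
    mat.columns.name = None
    mat.index.name = "group_id"
    return QuantMatrix(values=mat, cohorts=cohorts, scale=RAW)


def match_between_runs(
    psms: pd.DataFrame,
    pep_map: pd.DataFrame | None = None,
    ppm_tol: float = 10.0,
    rt_window_min: float = 15.0,
) -> pd.DataFrame:
    """Transfer identifications onto unidentified MS1 features across runs.

    For a peptide identified in donor run(s) but absent from an acceptor
    run, an unidentified acceptor feature is assigned that peptide when its
    m/z lies within ``ppm_tol`` and its retention time within
    ``rt_window_min`` of the donor medians; the closest-ppm candidate wins.
    Transferred rows get ``mbr=True``; existing identifications are never
    overwritten. Each feature receives at most one peptide.
    """
    if psms["sample"].nunique() < 2:
        return psms.assign(mbr=False)
    out = psms.copy()
    out["mbr"] = False
    ident = out[_identified(out)]
    donor = ident.groupby("peptide").agg(
        mz=("mz", "median"), rt_min=("rt_min", "median"),
        proteins=("proteins", "first"),
    )
    donor_samples = ident.groupby("peptide")["sample"].agg(set)

    features = out[~_identified(out)]
    assignments: list[tuple[float, int, str]] = []  # (ppm, feature row idx, peptide)
    for sample, feats in features.groupby("sample"):
        absent = donor.loc[[p for p in donor.index
                            if sample not in donor_samples[p]]]
        if absent.empty or feats.empty:
            continue
        fmz = feats["mz"].to_numpy()
        frt = feats["rt_min"].to_numpy()
        fidx = feats.index.to_numpy()
        for pep, drow in absent.iterrows():
            ppm = np.abs(fmz - drow["mz"]) / drow["mz"] * 1e6
            ok = (ppm <= ppm_tol) & (np.abs(frt - drow["rt_min"]) <= rt_window_min)
            if ok.any():
                k = np.argmin(np.where(ok, ppm, np.inf))
                assignments.append((float(ppm[k]), int(fidx[k]), pep))
    taken_rows: set[int] = set()
    taken_peps: set[tuple[str, str]] = set()
    for ppm, ridx, pep in sorted(assignments):
        sample = out.at[ridx, "sample"]
        if ridx in taken_rows or (sample, pep) in taken_peps:
            continue
        out.at[ridx, "peptide"] = pep
        out.at[ridx, "proteins"] = donor.at[pep, "proteins"]
        out.at[ridx, "mbr"] = True
        taken_rows.add(ridx)
        taken_peps.add((sample, pep))
    return out


def filter_missing(matrix: QuantMatrix, min_nonnull: int = 4) -> QuantMatrix:
    """Remove groups with too many missing values, by the three rules:

    a group is removed if (1) both cohorts contain only nulls, (2) one
    cohort contains only nulls and the other has < ``min_nonnull``
    non-nulls, or (3) both cohorts have < ``min_nonnull`` non-nulls each.
    The literal rules are asserted against their closed form
    ``max(n_healthy, n_uc) >= min_nonnull`` as an internal cross-check.
    """
    h_cols = matrix.cohort_columns("healthy")
    u_cols = matrix.cohort_columns("UC")
    n1 = matrix.values[h_cols].notna().sum(axis=1)
    n2 = matrix.values[u_cols].notna().sum(axis=1)
    rule1 = (n1 == 0) & (n2 == 0)
    rule2 = ((n1 == 0) & (n2 < min_nonnull)) | ((n2 == 0) & (n1 < min_nonnull))
    rule3 = (n1 < min_nonnull) & (n2 < min_nonnull)
    removed = rule1 | rule2 | rule3
    shortcut_keep = np.maximum(n1, n2) >= min_nonnull
    assert (shortcut_keep == ~removed).all(), \
        "three-rule filter disagrees with max(n1,n2) shortcut"
    return replace(matrix, values=matrix.values[~removed])


def _glog2(x: np.ndarray) -> np.ndarray:
    # log2(x + sqrt(x^2 + 1)) - 1, via arcsinh for stability at large |x|
    return np.arcsinh(x) / np.log(2.0) - 1.0


def normalize_glog(matrix: QuantMatrix) -> QuantMatrix:
    """Affine-calibrated generalized-log normalization, per sample.

    value -> glog2((value - a_s) / b_s) with glog2(x) = log2(x + sqrt(x^2+1)) - 1,
    where (a_s, b_s) put each sample's transformed non-missing values at
    median 0 and MAD 1. The transform is monotone within a sample, missing
    stays missing, and applying it to an already-normalized matrix is the
    identity. Constant samples (MAD 0) map to all-zero columns.
    """
    if matrix.scale == NORMALIZED:
        return replace(matrix, values=matrix.values.copy())
    values = matrix.values.copy().astype(float)
    for col in values.columns:
        x = values[col].dropna().to_numpy()
        if len(x) < 3:
            raise ValueError(f"sample {col!r} has fewer than 3 non-missing values")
        med = np.median(x)
        if np.all(x == med):
            values.loc[values[col].notna(), col] = 0.0
            continue
        # the transform is monotone, so the post-transform median depends
        # only on the central order statistic(s); solve a exactly on them
        xs = np.sort(x)
        n = len(xs)
        if n % 2:
            central = (xs[n // 2],)
        else:
            central = (xs[n // 2 - 1], xs[n // 2])

        def a_for(b: float) -> float:
            if len(central) == 1:
                return central[0] - 0.75 * b  # glog2(0.75) = 0 exactly

            def g(a: float) -> float:
                return float(_glog2((central[0] - a) / b)
                             + _glog2((central[1] - a) / b))

            lo_a, hi_a = central[0] - 2.0 * b, central[1] + 2.0 * b
            for _ in range(200):
                if g(lo_a) > 0:
                    break
                lo_a -= 2.0 * b
            for _ in range(200):
                if g(hi_a) < 0:
                    break
                hi_a += 2.0 * b
            return brentq(g, lo_a, hi_a, xtol=1e-13 * b, rtol=8.9e-16)

        def mad_minus_1(log_b: float) -> float:
            b = np.exp(log_b)
            t = _glog2((x - a_for(b)) / b)
            return float(np.median(np.abs(t))) - 1.0

        spread = float(np.median(np.abs(x - med)))
        center = np.log(max(spread, 1e-12))
        b = np.exp(brentq(mad_minus_1, center - 40.0, center + 40.0,
                          xtol=1e-12, rtol=1e-14))
        a = a_for(b)
        mask = values[col].notna()
        values.loc[mask, col] = _glog2((values.loc[mask, col].to_numpy() - a) / b)
    return QuantMatrix(values=values, cohorts=matrix.cohorts, scale=NORMALIZED)


def write_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="")


def read_matrix(path: str | Path, samples_path: str | Path,
                scale: str = RAW) -> QuantMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    cohorts = sheet.set_index("sample")["cohort"]
    return QuantMatrix(values=values, cohorts=cohorts, scale=scale)
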