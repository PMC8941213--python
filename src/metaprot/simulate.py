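"""Synthetic metaproteomics experiment generator.

Produces every input the downstream pipeline consumes — a protein database
with near-duplicate families, per-sample database PSM tables with MS1
intensities and intensity-dependent dropout, and per-sample de novo PSM
tables with a high-scoring identified component and a mixed unidentified
component — from a single seeded configuration, together with the ground
truth needed to score the pipeline's recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as pmass
from scipy.special import expit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)

PEPTIDE_MIN_LEN = 6
PEPTIDE_MAX_LEN = 50


@dataclass
class DeNovoScoreParams:
    """Mixture model for per-spectrum de novo confidence scores (0-100).

    ``weights`` split the *appended* unidentified spectra between real
    peptides deleted from the database ("dark") and non-peptide noise.
    Identified spectra and dark spectra draw from ``beta_identified``;
    noise draws from ``beta_noise``. Beta(8, 1) puts mass 1 - 0.75^8
    (~0.90) above a score of 75.
    """

    weights: tuple[float, float] = (0.5, 0.5)  # (dark, noise)
    beta_identified: tuple[float, float] = (8.0, 1.0)
    beta_noise: tuple[float, float] = (1.5, 6.0)
    n_extra_scans: int = 400
    denovo_error_rate: float = 0.03

    def validate(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("de novo mixture weights must sum to 1")
        if min(self.weights) < 0:
            raise ValueError("de novo mixture weights must be non-negative")
        for a, b in (self.beta_identified, self.beta_noise):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        if not 0 <= self.denovo_error_rate <= 1:
            raise ValueError("denovo_error_rate must lie in [0, 1]")


@dataclass
class SimConfig:
    """One seeded description of the whole simulated study.

    Defaults emulate the study design the pipeline targets: two cohorts of
    8 healthy and 10 UC samples, a database of near-duplicate protein
    families, log-normal MS1 intensities with left-censored missingness,
    and a minority of protein groups carrying a planted cohort effect.
    """

    seed: int = 0
    n_families: int = 200
    family_size: int = 3
    within_family_identity: float = 0.97
    protein_length: int = 300
    n_samples_per_cohort: tuple[int, int] = (8, 10)  # (healthy, UC)
    n_diff_groups: int = 30
    log2_effect_size: float = 2.0
    intensity_log_mean: float = 23.0
    intensity_log_sd: float = 2.0
    biological_sd: float = 0.5   # per group x sample replicate variability
    peptide_offset_sd: float = 1.0
    noise_log_sd: float = 0.5    # per peptide x sample measurement noise
    dropout_midpoint: float = 19.0
    dropout_steepness: float = 1.0
    mbr_feature_prob: float = 0.5
    rt_jitter_min: float = 0.2
    missed_cleavages_max: int = 1
    denovo_score_params: DeNovoScoreParams = field(default_factory=DeNovoScoreParams)

    def validate(self) -> None:
        for name in ("n_families", "family_size", "protein_length",
                     "missed_cleavages_max"):
            if getattr(self, name) < (0 if name == "missed_cleavages_max" else 1):
                raise ValueError(f"{name} out of range")
        if not 0.5 < self.within_family_identity <= 1.0:
            raise ValueError("within_family_identity must lie in (0.5, 1]")
        if min(self.n_samples_per_cohort) < 1:
            raise ValueError("each cohort needs at least one sample")
        if self.n_diff_groups < 0:
            raise ValueError("n_diff_groups must be >= 0")
        if not 0 <= self.mbr_feature_prob <= 1:
            raise ValueError("mbr_feature_prob must lie in [0, 1]")
        self.denovo_score_params.validate()

    @property
    def sample_names(self) -> list[str]:
        n_h, n_u = self.n_samples_per_cohort
        return [f"H{i + 1}" for i in range(n_h)] + [f"UC{i + 1}" for i in range(n_u)]

    @property
    def cohorts(self) -> pd.Series:
        n_h, n_u = self.n_samples_per_cohort
        return pd.Series(["healthy"] * n_h + ["UC"] * n_u,
                         index=self.sample_names, name="cohort")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    true_group_membership: dict[str, str]          # accession -> family id
    true_differential: dict[str, float]            # family id -> signed log2 FC
    true_dark_count: dict[str, int] = field(default_factory=dict)  # sample -> count


def digest_protein(sequence: str, missed_cleavages_max: int = 0) -> set[str]:
    """In-silico tryptic digest: cleave C-terminal to K/R except before P.

    Returns all peptides with 0..missed_cleavages_max missed cleavages,
    restricted to the 6-50 residue detectability window.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - _AA_SET
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    # cleavage sites: position after index i
    sites = [i + 1 for i in range(len(sequence) - 1)
             if sequence[i] in "KR" and sequence[i + 1] != "P"]
    bounds = [0] + sites + [len(sequence)]
    peptides: set[str] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages_max, len(bounds))):
            pep = sequence[bounds[i]:bounds[j]]
            if PEPTIDE_MIN_LEN <= len(pep) <= PEPTIDE_MAX_LEN:
                peptides.add(pep)
    return peptides


def generate_protein_database(
    config: SimConfig, self_check: bool = False
) -> tuple[dict[str, str], GroundTruth]:
    """Generate near-duplicate protein families over the 20-residue alphabet.

    Each family has a random founder; the other members substitute a
    family-wide set of ``round(L * (1 - identity))`` positions, so both the
    member-founder identity and every within-family pairwise identity are at
    least the configured value. With ``self_check=True`` all within-family
    pairs are verified >= 0.95 identity by global alignment (small databases
    only; quadratic in family size).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    length = config.protein_length
    n_mut = round(length * (1.0 - config.within_family_identity))
    if config.within_family_identity < 1.0 and n_mut == 0:
        raise ValueError(
            "within_family_identity cannot be realized: mutation count rounds "
            f"to 0 for founder length {length}"
        )
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    proteins: dict[str, str] = {}
    membership: dict[str, str] = {}
    for f in range(config.n_families):
        fam_id = f"FAM{f:04d}"
        founder = rng.choice(aa, size=length)
        positions = rng.choice(length, size=n_mut, replace=False) if n_mut else []
        for m in range(config.family_size):
            seq = founder.copy()
            if m > 0 and n_mut:
                for pos in positions:
                    choices = aa[aa != founder[pos]]
                    seq[pos] = rng.choice(choices)
            acc = f"F{f:04d}P{m:02d}"
            proteins[acc] = seq.tobytes().decode("ascii")
            membership[acc] = fam_id
    truth = GroundTruth(true_group_membership=membership, true_differential={})
    if self_check:
        from .align import global_identity

        by_fam: dict[str, list[str]] = {}
        for acc, fam in membership.items():
            by_fam.setdefault(fam, []).append(acc)
        for fam, accs in by_fam.items():
            for i in range(len(accs)):
                for j in range(i + 1, len(accs)):
                    ident = global_identity(proteins[accs[i]], proteins[accs[j]])
                    if ident < 0.95:
                        raise AssertionError(
                            f"self-check failed: {accs[i]} vs {accs[j]} "
                            f"identity {ident:.3f} < 0.95"
                        )
    return proteins, truth


def _dropout_probability(log2_intensity: np.ndarray, config: SimConfig) -> np.ndarray:
    """Left-censoring: lower log2 intensity -> higher dropout probability."""
    if math.isinf(config.dropout_midpoint) and config.dropout_midpoint < 0:
        return np.zeros_like(np.asarray(log2_intensity, dtype=float))
    return expit(config.dropout_steepness * (config.dropout_midpoint - log2_intensity))


def simulate_quant_experiment(
    database: dict[str, str], truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-sample database PSM tables at the MS1-intensity level.

    Each detectable peptide receives, per sample, a log2 intensity =
    family baseline + cohort effect (for planted differential families) +
    per-family-per-sample biological replicate effect + peptide offset +
    measurement noise; an observation indicator is drawn from a
    logistic function of that intensity. A fraction of dropped
    identifications still leave an unidentified MS1 feature row (empty
    peptide), which is what match-between-runs later fills in.
    Returns one long table with columns
    sample, scan, peptide, proteins, mz, rt_min, intensity.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    families = sorted({fam for fam in truth.true_group_membership.values()})
    if config.n_diff_groups > len(families):
        raise ValueError("n_diff_groups exceeds the number of families")

    # peptide -> parent accessions over the whole database
    pep_parents: dict[str, set[str]] = {}
    for acc, seq in database.items():
        for pep in digest_protein(seq, config.missed_cleavages_max):
            pep_parents.setdefault(pep, set()).add(acc)
    peptides = sorted(pep_parents)

    # planted differential families, sign randomised
    diff_fams = rng.choice(families, size=config.n_diff_groups, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_diff_groups)
    truth.true_differential = {
        fam: float(s * config.log2_effect_size) for fam, s in zip(diff_fams, signs)
    }

    baseline = {
        fam: rng.normal(config.intensity_log_mean, config.intensity_log_sd)
        for fam in families
    }
    samples = config.sample_names
    cohorts = config.cohorts

    pep_family = {}
    for pep, parents in pep_parents.items():
        fams = {truth.true_group_membership[a] for a in parents}
        # peptides spanning families inherit the first family's baseline;
        # they are later excluded from quantification as shared anyway
        pep_family[pep] = sorted(fams)[0]

    n_pep = len(peptides)
    n_smp = len(samples)
    pep_offset = rng.normal(0.0, config.peptide_offset_sd, size=n_pep)
    pep_rt = rng.uniform(5.0, 115.0, size=n_pep)
    pep_mz = np.array([pmass.fast_mass(p, charge=2) for p in peptides])
    pep_proteins = np.array([";".join(sorted(pep_parents[p])) for p in peptides])
    pep_arr = np.array(peptides)

    base_vec = np.array([baseline[pep_family[p]] for p in peptides])
    effect_vec = np.array(
        [truth.true_differential.get(pep_family[p], 0.0) for p in peptides])
    is_uc = (cohorts[samples] == "UC").to_numpy()

    # biological replicate effect: shared by all peptides of a family
    fam_index = {fam: i for i, fam in enumerate(families)}
    bio = rng.normal(0.0, config.biological_sd, size=(len(families), n_smp))
    pep_fam_idx = np.array([fam_index[pep_family[p]] for p in peptides])

    x = (base_vec[:, None] + pep_offset[:, None]
         + np.outer(effect_vec, is_uc.astype(float))
         + bio[pep_fam_idx, :]
         + rng.normal(0.0, config.noise_log_sd, size=(n_pep, n_smp)))
    dropped = rng.random((n_pep, n_smp)) < _dropout_probability(x, config)
    feature_only = dropped & (rng.random((n_pep, n_smp)) < config.mbr_feature_prob)
    rt = pep_rt[:, None] + rng.normal(0.0, config.rt_jitter_min,
                                      size=(n_pep, n_smp))

    frames = []
    for s_idx, sample in enumerate(samples):
        emit = (~dropped[:, s_idx]) | feature_only[:, s_idx]
        idx = np.nonzero(emit)[0]
        observed = ~dropped[idx, s_idx]
        frames.append(pd.DataFrame({
            "sample": sample,
            "scan": idx + 1,
            "peptide": np.where(observed, pep_arr[idx], ""),
            "proteins": np.where(observed, pep_proteins[idx], ""),
            "mz": pep_mz[idx],
            "rt_min": rt[idx, s_idx],
            "intensity": 2.0 ** x[idx, s_idx],
        }))
    psms = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "scan", "peptide", "proteins", "mz", "rt_min",
                 "intensity"])
    return psms, truth


def _random_tryptic_peptide(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(AMINO_ACIDS.replace("K", "").replace("R", "").replace("P", "")),
                      size=length - 1)
    return "".join(body) + str(rng.choice(["K", "R"]))


def _mutate_peptide(pep: str, eps: float, rng: np.random.Generator) -> str:
    if eps <= 0:
        return pep
    out = list(pep)
    for i, ch in enumerate(out):
        if rng.random() < eps:
            out[i] = rng.choice([a for a in AMINO_ACIDS if a != ch])
    return "".join(out)


def simulate_denovo_run(
    psms: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a Novor-style de novo run over the same spectra.

    Every database-assigned scan receives a de novo peptide (the true
    peptide with per-residue error rate epsilon) and a score from the
    identified Beta component. Per sample, ``n_extra_scans`` additional
    spectra are appended: "dark" ones (real peptides absent from the
    database, identified-component score; counted in true_dark_count) and
    noise spectra (random sequence, low-component score).
    Returns a table with columns sample, scan, peptide, score.
    """
    params = config.denovo_score_params
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    a_id, b_id = params.beta_identified
    a_no, b_no = params.beta_noise
    w_dark, _ = params.weights

    rows: list[dict] = []
    dark_counts: dict[str, int] = {}
    eps = params.denovo_error_rate
    for sample, table in psms.groupby("sample", sort=True):
        identified = table[table["peptide"].astype(str) != ""]
        scores = 100.0 * rng.beta(a_id, b_id, size=len(identified))
        for scan, pep, score in zip(identified["scan"].to_numpy(),
                                    identified["peptide"].to_numpy(), scores):
            rows.append({
                "sample": sample, "scan": int(scan),
                "peptide": _mutate_peptide(pep, eps, rng),
                "score": score,
            })
        next_scan = int(table["scan"].max()) + 1 if len(table) else 1
        n_dark = 0
        for k in range(params.n_extra_scans):
            is_dark = rng.random() < w_dark
            length = int(rng.integers(8, 21))
            if is_dark:
                pep = _random_tryptic_peptide(rng, length)
                score = 100.0 * rng.beta(a_id, b_id)
                n_dark += 1
            else:
                pep = "".join(rng.choice(list(AMINO_ACIDS), size=length))
                score = 100.0 * rng.beta(a_no, b_no)
            rows.append({"sample": sample, "scan": next_scan + k,
                         "peptide": pep, "score": score})
        dark_counts[sample] = n_dark
    truth.true_dark_count = dark_counts
    denovo = pd.DataFrame(rows, columns=["sample", "scan", "peptide", "score"])
    return denovo, truth


# ---------------------------------------------------------------------------
# writers

def write_fasta(database: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="")
               for acc, seq in database.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_experiment(
    outdir: str | Path,
    database: dict[str, str],
    psms: pd.DataFrame,
    denovo: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
) -> None:
    """Write the complete simulated study under one directory."""
    out = Path(outdir)
    (out / "psms").mkdir(parents=True, exist_ok=True)
    (out / "denovo").mkdir(exist_ok=True)
    write_fasta(database, out / "database.fasta")
    for sample, table in psms.groupby("sample"):
        table.to_csv(out / "psms" / f"{sample}.tsv", sep="\t", index=False)
    for sample, table in denovo.groupby("sample"):
        table.to_csv(out / "denovo" / f"{sample}.csv", index=False)
    config.cohorts.rename_axis("sample").reset_index().to_csv(
        out / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_group_membership.items()),
        columns=["accession", "family"],
    ).to_csv(out / "truth_membership.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_differential.items()),
        columns=["family", "log2_fc"],
    ).to_csv(out / "truth_differential.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_dark_count.items()),
        columns=["sample", "dark_count"],
    ).to_csv(out / "truth_dark.tsv", sep="\t", index=False)


def read_psm_tables(directory: str | Path) -> pd.DataFrame:
    frames = [pd.read_csv(p, sep="\t", keep_default_na=False,
                          dtype={"peptide": str, "proteins": str})
              for p in sorted(Path(directory).glob("*.tsv"))]
    if not frames:
        raise FileNotFoundError(f"no PSM tables under {directory}")
    return pd.concat(frames, ignore_index=True)
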