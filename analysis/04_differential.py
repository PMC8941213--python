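"""Moderated differential testing of UC vs healthy, significance calls at
p <= 0.005 and q < 0.1, recovery against the planted ground truth, and the
PCA / Euclidean-distance sample summaries."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from metaprot import diff, quant
from metaprot.cluster import read_groups_tsv
from common import GROUPS_TSV, MATRIX_TSV, RESULTS_TSV, SIM_DIR, outdir


def main() -> None:
    out = outdir()
    matrix = quant.read_matrix(MATRIX_TSV, SIM_DIR / "samples.tsv",
                               scale=quant.NORMALIZED)
    results = diff.moderated_ttest(matrix)
    results, (n_h, n_uc, total) = diff.call_significant(results,
                                                        p_max=0.005,
                                                        q_max=0.1)
    results.to_csv(RESULTS_TSV, sep="\t", index=False)

    # recovery against the planted effects (groups are named by their
    # representative's family via the clustering step)
    truth = pd.read_csv(SIM_DIR / "truth_differential.tsv", sep="\t")
    membership = pd.read_csv(SIM_DIR / "truth_membership.tsv", sep="\t")
    rep_fam = dict(zip(membership["accession"], membership["family"]))
    groups = read_groups_tsv(GROUPS_TSV)
    grp_fam = {g.group_id: rep_fam[g.representative] for g in groups}
    sig_fams = {grp_fam[g] for g in
                results.loc[results["significant"], "group_id"]}
    recovered = len(sig_fams & set(truth["family"]))

    print(f"{(~results['presence_only']).sum()} testable groups; "
          f"prior df d0 = {results.attrs['d0']:.2f}")
    print(f"{total} significant groups (p<=0.005 & q<0.1): "
          f"{n_h} healthy-enriched, {n_uc} UC-enriched")
    print(f"expected false positives at q<0.1: "
          f"{diff.expected_false_positives(total, 0.1)}")
    print(f"recovered {recovered}/{len(truth)} planted differential groups")

    scores, var = diff.pca_scores(matrix)
    scores.join(matrix.cohorts).to_csv(out / "pca_scores.tsv", sep="\t")
    diff.sample_distance_matrix(matrix).to_csv(out / "sample_distances.tsv",
                                               sep="\t")
    print(f"PCA: PC1 {100 * var[0]:.1f}%, PC2 {100 * var[1]:.1f}% of "
          f"variance; coordinates and distances written")


if __name__ == "__main__":
    main()
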