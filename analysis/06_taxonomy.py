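"""Peptide LCA taxonomy profiles (intensity-weighted) next to a 16S-style
count profile at the phylum level, with the Bacteroidetes:Firmicutes ratio
under each basis.

The taxonomy tree and peptide-to-taxa map are synthetic: family-unique
peptides resolve to a species, peptides shared across families get a
coarser LCA, so a realistic Unassigned share emerges at finer ranks. The
16S counts are drawn to over-represent Firmicutes relative to the peptide
profile, mirroring how extraction efficiencies skew amplicon data.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from metaprot import amplicon_profile, peptide_taxon_profile, taxon_ratio
from metaprot.taxonomy import UNASSIGNED, TaxonomyTree
from common import MATRIX_TSV, SIM_DIR, STUDY_CONFIG, outdir

PHYLA = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
         "Chordata", "Streptophyta"]
PHYLUM_WEIGHTS = [0.30, 0.12, 0.08, 0.05, 0.35, 0.10]


def build_tree(n_species_per_phylum: int = 4) -> TaxonomyTree:
    parent, rank, name = {1: 1}, {1: "no rank"}, {1: "root"}
    parent[2], rank[2], name[2] = 1, "superkingdom", "Bacteria"
    parent[3], rank[3], name[3] = 1, "superkingdom", "Eukaryota"
    tid = 10
    species_by_phylum = {}
    for i, phylum in enumerate(PHYLA):
        sk = 3 if phylum in ("Chordata", "Streptophyta") else 2
        parent[tid], rank[tid], name[tid] = sk, "phylum", phylum
        phylum_id, tid = tid, tid + 1
        species_by_phylum[phylum] = []
        for s in range(n_species_per_phylum):
            parent[tid], rank[tid] = phylum_id, "species"
            name[tid] = f"{phylum[:4]}. sp{s + 1}"
            species_by_phylum[phylum].append(tid)
            tid += 1
    return TaxonomyTree(parent=parent, rank=rank, name=name), \
        species_by_phylum


def main() -> None:
    out = outdir()
    rng = np.random.default_rng(STUDY_CONFIG.seed + 60)
    tree, species_by_phylum = build_tree()

    peptides = pd.read_csv(MATRIX_TSV.with_name("peptide_intensities.tsv"),
                           sep="\t")
    intens = peptides.pivot_table(index="peptide", columns="sample",
                                  values="intensity").fillna(0.0)

    # peptide -> candidate species: most peptides are species-unique, a
    # fraction are conserved across species or phyla (coarse LCA)
    mapping = {}
    all_species = [s for sp in species_by_phylum.values() for s in sp]
    for pep in intens.index:
        phylum = rng.choice(PHYLA, p=PHYLUM_WEIGHTS)
        u = rng.random()
        if u < 0.55:      # species-unique
            mapping[pep] = {int(rng.choice(species_by_phylum[phylum]))}
        elif u < 0.85:    # conserved within the phylum
            mapping[pep] = set(map(int, rng.choice(
                species_by_phylum[phylum], size=2, replace=False)))
        else:             # broadly conserved: LCA above phylum
            mapping[pep] = set(map(int, rng.choice(all_species, size=3,
                                                   replace=False)))

    for rank_name in ("phylum", "species"):
        prof = peptide_taxon_profile(mapping, intens, tree, rank_name)
        prof.to_csv(out / f"taxonomy_peptide_{rank_name}.tsv", sep="\t")
        unassigned = (prof.loc[UNASSIGNED].mean()
                      if UNASSIGNED in prof.index else 0.0)
        print(f"peptide-intensity profile at {rank_name}: "
              f"{prof.shape[0]} categories, "
              f"{100 * unassigned:.1f}% Unassigned/unknown on average")

    prof_phylum = peptide_taxon_profile(mapping, intens, tree, "phylum")
    mean_pep = prof_phylum.mean(axis=1)
    ratio, label = taxon_ratio(mean_pep, "Bacteroidetes", "Firmicutes")
    print(f"proteomics Bacteroidetes:Firmicutes = {label} "
          f"(shares {100 * mean_pep['Bacteroidetes']:.1f}% vs "
          f"{100 * mean_pep['Firmicutes']:.1f}%)")

    # 16S counts: bacteria only, Firmicutes-dominated
    samples = intens.columns
    counts = pd.DataFrame(0, index=all_species, columns=samples)
    weights_16s = {"Firmicutes": 0.86, "Bacteroidetes": 0.01,
                   "Proteobacteria": 0.08, "Actinobacteria": 0.05}
    for phylum, w in weights_16s.items():
        for sp in species_by_phylum[phylum]:
            counts.loc[sp] = rng.poisson(
                w * 5000 / len(species_by_phylum[phylum]), size=len(samples))
    prof_16s = amplicon_profile(counts, tree, "phylum")
    prof_16s.to_csv(out / "taxonomy_16s_phylum.tsv", sep="\t")
    mean_16s = prof_16s.mean(axis=1)
    ratio2, label2 = taxon_ratio(mean_16s, "Bacteroidetes", "Firmicutes")
    print(f"16S Bacteroidetes:Firmicutes = {label2} "
          f"(shares {100 * mean_16s['Bacteroidetes']:.1f}% vs "
          f"{100 * mean_16s['Firmicutes']:.1f}%)")
    print(f"peptide basis sees {prof_phylum.shape[0]} phylum-level "
          f"categories vs {prof_16s.shape[0]} by 16S")


if __name__ == "__main__":
    main()
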