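import sys
from pathlib import Path

import pytest

import metaprot as mp
from metaprot import diff, quant

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`


def groups_from_truth(truth: mp.GroundTruth) -> list[mp.ProteinGroup]:
    """Protein groups taken from the generator's family ground truth."""
    fam_groups: dict[str, mp.ProteinGroup] = {}
    for acc, fam in sorted(truth.true_group_membership.items()):
        grp = fam_groups.setdefault(fam, mp.ProteinGroup(
            group_id=fam, representative=acc, members=[],
            member_identities={}))
        grp.members.append(acc)
    return list(fam_groups.values())


def run_differential_pipeline(cfg: mp.SimConfig):
    """Simulate -> aggregate -> filter -> normalize -> moderated test."""
    db, truth = mp.generate_protein_database(cfg)
    psms, truth = mp.simulate_quant_experiment(db, truth, cfg)
    pep_map = quant.build_peptide_group_map(psms, groups_from_truth(truth))
    matrix = quant.aggregate_intensities(psms, pep_map, cfg.cohorts)
    matrix = quant.normalize_glog(quant.filter_missing(matrix))
    return diff.moderated_ttest(matrix), truth


@pytest.fixture(scope="session")
def family_db():
    """The 15-sequence fixture: 5 families x 3 members at 0.97 identity."""
    cfg = mp.SimConfig(seed=7, n_families=5, family_size=3,
                       within_family_identity=0.97, protein_length=300,
                       n_diff_groups=2)
    db, truth = mp.generate_protein_database(cfg, self_check=True)
    return cfg, db, truth


@pytest.fixture(scope="session")
def small_study(family_db):
    """A complete small simulated study over the 15-sequence database."""
    cfg, db, truth = family_db
    psms, truth = mp.simulate_quant_experiment(db, truth, cfg)
    denovo, truth = mp.simulate_denovo_run(psms, truth, cfg)
    return cfg, db, psms, denovo, truth
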