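"""Generate the synthetic study: protein database, per-sample database PSM
tables with MS1 intensities and left-censored dropout, and de novo PSM
tables with planted database-absent peptides."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import metaprot as mp
from common import SIM_DIR, STUDY_CONFIG, outdir


def main() -> None:
    outdir()
    cfg = STUDY_CONFIG
    database, truth = mp.generate_protein_database(cfg)
    psms, truth = mp.simulate_quant_experiment(database, truth, cfg)
    denovo, truth = mp.simulate_denovo_run(psms, truth, cfg)
    from metaprot.simulate import write_experiment

    write_experiment(SIM_DIR, database, psms, denovo, truth, cfg)

    identified = psms["peptide"].str.len() > 0
    print(f"database: {len(database)} proteins in "
          f"{cfg.n_families} families of {cfg.family_size}")
    print(f"PSM rows: {identified.sum()} identified, "
          f"{(~identified).sum()} unidentified MS1 features")
    print(f"de novo rows: {len(denovo)}; planted dark spectra/sample: "
          f"{next(iter(truth.true_dark_count.values()))}")
    print(f"planted differential groups: {len(truth.true_differential)} "
          f"at |log2FC| = {cfg.log2_effect_size}")
    print(f"wrote {SIM_DIR}")


if __name__ == "__main__":
    main()
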