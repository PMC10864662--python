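"""Generate the study fixture: an AML-like cohort of protease-active samples.

Three untreated and three inhibitor-treated (DFP) replicate samples are
simulated from one 200-protein proteome with elastase-like ({A,I,V})
endogenous activity 0.25, 95%-occupied inhibitor adduct on an active-site
serine, 10% dropout and 10% intensity noise. Large per-peptide tables go to
scratch/fixture/; the ground-truth summary table goes to results/.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from cleaveqc.digestion import TRYPSIN_P, digest
from cleaveqc.io_formats import observations_to_frame, write_fasta, write_table
from cleaveqc.synthetic_data import (
    AdductSpec,
    SimulationConfig,
    generate_observations,
    generate_proteome,
    generate_reporter_matrix,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240112
FIXTURE = Path("scratch/fixture")
RESULTS = Path("results")


def pick_adduct_site(record):
    """An interior, non-K/R residue of a mid-size tryptic peptide: a position a
    0-missed peptide will always cover once it is forced to serine."""
    for pep in digest(record, TRYPSIN_P, 0, (8, 30)):
        for offset in range(2, len(pep.peptide) - 2):
            if pep.peptide[offset] not in "KR":
                return pep.start + offset
    raise RuntimeError(f"no suitable adduct site on {record.accession}")


def main():
    FIXTURE.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    base = SimulationConfig(seed=SEED)
    site = pick_adduct_site(generate_proteome(base)[0])
    config = dataclasses.replace(
        base, adducts=[AdductSpec("SYN0001", site, 0.95, n_features=150)]
    )

    proteome = generate_proteome(config)
    write_fasta(proteome, FIXTURE / "proteome.fasta")
    observations, ledger = generate_observations(proteome, config)
    write_table(observations_to_frame(observations), FIXTURE / "psm_table.tsv")

    design = {
        ch: ("treated" if i < 3 else "untreated")
        for i, ch in enumerate(config.tmt.sample_channels)
    }
    matrix, fold_changes = generate_reporter_matrix(observations, config, design, ledger)
    write_table(matrix.data, FIXTURE / "reporter_matrix.tsv")
    roles = {**{c: "sample" for c in config.tmt.sample_channels},
             **{c: "reference" for c in config.tmt.reference_channels}}
    write_table(
        pd.DataFrame(
            [{"channel": c, "role": roles[c], "condition": design.get(c, "")}
             for c in roles]
        ),
        FIXTURE / "design.tsv",
    )

    truth = pd.DataFrame(
        [
            {
                "sample_id": s,
                "true_nontryptic_share_pct": 100.0 * ledger.nontryptic_share(s),
                "dfp_treated": s in config.dfp_samples,
            }
            for s in sorted(ledger.total_intensity)
        ]
    )
    write_table(truth, RESULTS / "simulation_truth.tsv")
    write_table(
        pd.DataFrame(
            [{"protein": p, "true_log2_fc": f} for p, f in sorted(fold_changes.items()) if f != 0]
        ),
        RESULTS / "simulation_true_fold_changes.tsv",
    )
    print(f"fixture written to {FIXTURE} (seed {SEED}, adduct site SYN0001:{site})")
    print(truth.to_string(index=False))


if __name__ == "__main__":
    main()
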