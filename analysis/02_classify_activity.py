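"""Classify the fixture's peptides and quantify endogenous protease activity.

Reads scratch/fixture (from 01_simulate.py), classifies every peptide terminus
as tryptic or nontryptic, attributes nontryptic events to ELANE/PRTN3 vs CTSG
specificity, and writes per-sample activity summaries plus the specificity
profile to results/. The printed comparison shows the drop in percent
nontryptic intensity under simulated DFP treatment.

Run from the repository root:  python analysis/02_classify_activity.py
"""

from pathlib import Path

import pandas as pd

from cleaveqc.io_formats import RunConfig, read_table
from cleaveqc.report import run_classify

FIXTURE = Path("scratch/fixture")
RESULTS = Path("results")


def main():
    summaries, profile, bundle = run_classify(
        FIXTURE / "psm_table.tsv", FIXTURE / "proteome.fasta", RunConfig(), RESULTS
    )
    truth = read_table(RESULTS / "simulation_truth.tsv").set_index("sample_id")
    print("sample           pct_nontryptic   truth    |err|")
    for s in summaries:
        t = truth.loc[s.sample_id, "true_nontryptic_share_pct"]
        print(f"{s.sample_id:<16} {s.pct_nontryptic_intensity:>12.2f} {t:>8.2f} "
              f"{abs(s.pct_nontryptic_intensity - t):>8.2f}")
    cls = profile[(profile['kind'] == 'class')]
    elane = cls[cls['key'] == 'ELANE_PRTN3']
    print("\nELANE/PRTN3 fraction of nontryptic events per sample:")
    print(elane[["sample_id", "fraction_by_count"]].to_string(index=False))


if __name__ == "__main__":
    main()
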