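"""Viability at 39 C: CFU/mL per OD from the spotting dilution series.

Quantifies each replicate's colony-forming units from the densest countable
spot, normalizes by end-point turbidity, and reports the fold differences
between the 8x transgenic, the recipient, and the donor wild types.
"""

import pathlib

import numpy as np
import pandas as pd

from thermopanel.io import read_measurements
from thermopanel.phenotypes import viability_table
from thermopanel.effects import rank_sum_test
from thermopanel.synthetic import strain_id_for

ROOT = pathlib.Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main():
    records = read_measurements(DATA / "viability_39C.csv", "viability").records
    df = viability_table(records)
    df.to_csv(OUT / "viability_estimates_39C.csv", index=False)

    means = df.groupby("strain_id")["cfu_per_ml_per_od"].mean()
    joint = strain_id_for([1] * 8)
    rec, don = means["recipient_wt"], means["donor_wt"]
    print("Mean CFU/mL/OD at 39 C:")
    for sid, m in means.items():
        print(f"  {sid}: {m:.3e}")
    print(f"Transgenic vs recipient: {means[joint] / rec:.1f}-fold")
    print(f"Donor vs recipient: {np.log10(don / rec):.1f} logs")
    x = df.loc[df["strain_id"] == joint, "cfu_per_ml_per_od"]
    y = df.loc[df["strain_id"] == "recipient_wt", "cfu_per_ml_per_od"]
    res = rank_sum_test(x, y, "greater", names=(joint, "recipient_wt"))
    print(f"One-tailed Wilcoxon transgenic > recipient: p = {res.p_value:.4g}")


if __name__ == "__main__":
    main()
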