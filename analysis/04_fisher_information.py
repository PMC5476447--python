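#!/usr/bin/env python
"""Linear Fisher information along the attention path.

The total E+I information is exactly invariant with attention (gain and
noise pass through the same linearized circuit), but the excitatory-only
readout improves: attention raises G_E while lowering V_E.  Writes
results/fisher/fisher.tsv (chi = 0.9; chi = 1 is the singular
fully-common-noise limit).
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from attncov.fisher import fisher_report
from attncov.meanfield import REFERENCE, equilibrium

OUT = Path("results/fisher")
CHI = 0.9


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for A in np.linspace(0.0, 1.0, 21):
        p = replace(REFERENCE, chi=CHI, A=float(A))
        rep = fisher_report(equilibrium(p), p)
        rows.append({"A": A, "FI_EI": rep.FI_EI, "FI_E": rep.FI_E,
                     "FI_uc": rep.FI_uc, "chi": CHI})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "fisher.tsv", sep="\t", index=False,
              float_format="%.10g")
    print(f"chi={CHI}: FI_EI = {df.FI_EI.iloc[0]:.6f} at every A "
          f"(spread {df.FI_EI.max() - df.FI_EI.min():.2e}) -- total "
          "information is attention-invariant.")
    print(f"FI_E rises {df.FI_E.iloc[0]:.2f} -> {df.FI_E.iloc[-1]:.2f} "
          f"({100 * (df.FI_E.iloc[-1] / df.FI_E.iloc[0] - 1):+.0f}%): the "
          "excitatory readout improves with attention.")
    print(f"uncoupled benchmark FI_uc = {df.FI_uc.iloc[0]:.2f} "
          "(independent of the operating point).")


if __name__ == "__main__":
    main()
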