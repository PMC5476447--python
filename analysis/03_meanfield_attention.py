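#!/usr/bin/env python
"""Attention in the E-I mean-field model: rates, stability, variance, gain.

Sweeps the attention parameter along the reference path, maps the sign of
the variance change over the top-down input plane, and probes robustness
to broken coupling symmetry.  Writes tables under results/meanfield/.
"""

from pathlib import Path

import numpy as np

from attncov.meanfield import (REFERENCE, attention_sweep,
                               coupling_asymmetry_map, delta_mu_region)

OUT = Path("results/meanfield")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sweep = attention_sweep(REFERENCE, np.linspace(0.0, 1.0, 21))
    sweep.to_csv(OUT / "attention_sweep.tsv", sep="\t", index=False,
                 float_format="%.10g")
    a, b = sweep.iloc[0], sweep.iloc[-1]
    print(f"attention A=0 -> 1: r_E {a.r_E_sps:.1f} -> {b.r_E_sps:.1f} sp/s, "
          f"r_I {a.r_I_sps:.1f} -> {b.r_I_sps:.1f} sp/s")
    print(f"  leading eigenvalue {a.lambda1:.3f} -> {b.lambda1:.3f} "
          "(more stable)")
    print(f"  population variance V_E {a.V_E:.5f} -> {b.V_E:.5f} "
          f"({100 * (b.V_E / a.V_E - 1):+.0f}%), stimulus gain "
          f"G_E {a.G_E:.3f} -> {b.G_E:.3f}")

    grid = np.linspace(0.0, 0.4, 9)
    dmu, summary = delta_mu_region(REFERENCE, grid, grid)
    dmu.to_csv(OUT / "delta_mu_region.tsv", sep="\t", index=False,
               float_format="%.6g")
    neg = dmu[dmu.dV_E < 0]
    frac = float((neg.dmu_I >= neg.dmu_E).mean()) if len(neg) else 1.0
    print(f"\ninput-plane map: {len(neg)}/{len(dmu)} sampled modulations "
          f"lower the variance; {100 * frac:.0f}% of them have "
          "dmu_I >= dmu_E (variance reduction requires recruiting "
          "inhibition at least as strongly as excitation).")

    amap = coupling_asymmetry_map(REFERENCE, np.linspace(0.7, 1.3, 7),
                                  np.linspace(0.7, 1.3, 7))
    amap.to_csv(OUT / "coupling_asymmetry.tsv", sep="\t", index=False,
                float_format="%.6g")
    ok = amap[amap.stable]
    print(f"coupling-asymmetry map: variance still decreases with attention "
          f"in {int((ok.dV_E < 0).sum())}/{len(ok)} stable cells around the "
          "symmetric point.")


if __name__ == "__main__":
    main()
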