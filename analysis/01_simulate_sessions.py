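#!/usr/bin/env python
"""Generate synthetic attended/unattended spike-count sessions.

Each session mimics a bilateral-array recording: tens of units, 200 ms
count windows at 10-40 spikes/s, shared variability carried by one global
latent dimension, and an attended condition whose pairwise covariances are
scaled by per-unit gains g_i (mostly < 1).  Sessions and their generative
ground truth are written under results/sessions/.
"""

import json
from pathlib import Path

import numpy as np

from attncov.covstats import count_covariance, summary_stats
from attncov.session import make_session, write_session

OUT = Path("results/sessions")
N_SESSIONS = 3
N_UNITS = 30
N_TRIALS = 600


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summaries = []
    for k in range(N_SESSIONS):
        seed = 100 + k
        sess = make_session(N_UNITS, N_TRIALS, seed=seed)
        write_session(OUT / f"session_{k:02d}", sess, seed=seed)
        C_U = count_covariance(sess.unattended)
        C_A = count_covariance(sess.attended)
        s = summary_stats(C_U, C_A)
        s["session"] = k
        summaries.append(s)
        print(f"session {k}: mean corr {s['mean_corr_unattended']:.3f} -> "
              f"{s['mean_corr_attended']:.3f}, "
              f"mean cov change {s['mean_norm_dcov']:+.3f}, "
              f"mean var change {s['mean_norm_dvar']:+.3f}")
    (OUT / "summaries.json").write_text(json.dumps(summaries, indent=2))
    dcov = np.mean([s["mean_norm_dcov"] for s in summaries])
    dvar = np.mean([s["mean_norm_dvar"] for s in summaries])
    print(f"\nAcross sessions: attention lowers covariance "
          f"({dcov:+.2f} normalized) far more than it moves variance "
          f"({dvar:+.2f}), so the correlation decrease is a covariance "
          "effect.")


if __name__ == "__main__":
    main()
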