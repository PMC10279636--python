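"""Run a complete simulated experiment: signals -> PLV -> graphs -> stats.

Plants stronger core-extended coupling when negative expressions are
attended (overt fear/sad), runs the pipeline end to end and prints the
mixed-model F tests and the FDR-corrected overt contrasts.
"""

import tempfile
from pathlib import Path

import pandas as pd

from plvnet import RunConfig, run

cfg = RunConfig(
    n_subjects=6,
    n_nodes=20,
    trials_per_cell=30,
    effects={("overt", "fear"): 0.3, ("overt", "sad"): 0.3},
    n_restarts=20,
    seed=11,
)

out = run(cfg, Path(tempfile.mkdtemp()) / "demo")
print(f"outputs in {out}\n")

ftests = pd.read_csv(out / "ftests.csv")
print("F tests (Satterthwaite df):")
print(ftests.round(3).to_string(index=False))

contrasts = pd.read_csv(out / "contrasts.csv")
overt = contrasts[
    (contrasts.condition == "overt") & (contrasts.metric == "routing_efficiency")
]
print("\novert routing-efficiency contrasts (BH-adjusted):")
print(overt[["contrast", "estimate", "t", "df", "p_adj"]].round(4).to_string(index=False))
print(
    "\nA significant condition x emotion interaction with positive "
    "fear/sad-minus-happy/neutral contrasts in the overt condition "
    "reproduces the planted pattern: attended negative expressions "
    "increase integration between the face network's subsystems."
)
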