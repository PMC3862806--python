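"""Shared configuration for the numbered analysis scripts.

One synthetic "behaviorally activated" cohort emulating the study design
(2 cognitive phenotypes x 2 training conditions, 8/8/8/7 arrays) plus a
paired "basal" dataset sharing half of the planted effects. Scripts run in
order from the repository root:

    python analysis/01_simulate_cohort.py
    python analysis/02_qc_normalize_filter.py
    ...

Each writes its tables under results/analysis/.
"""

from pathlib import Path

from samflow import SimConfig
from samflow.synthio import config_with

SEED = 20130904
N_GENES = 8000
B_PERMUTATIONS = 300

RESULTS = Path("results/analysis")
DATA = RESULTS / "data"

COHORT = SimConfig(n_genes=N_GENES, seed=SEED)
# paired basal dataset: half the activated effects recur under basal conditions
PAIRED = config_with(COHORT, cross_dataset_share=0.5, seed=SEED + 1)
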