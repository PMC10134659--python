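"""Reference fixture built from published marginal counts.

Reconstructs a patient-level table from the death-stratified categorical
counts published for a one-year EMS-transported suspected-stroke cohort
(Mashhad, Iran; n printed as 1170 with per-variable column sums of 1171).
Only categorical structure is reconstructable from counts, and variables
are filled independently within each outcome stratum — the joint
distribution across variables is synthetic.  The hypertension counts sum
below the stratum totals in the source; the shortfall is encoded as
missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reference_counts_cohort", "REFERENCE_COUNTS"]

# per-variable (dead, alive) counts per level; strata sum to 167 / 1004
REFERENCE_COUNTS = {
    "sex": {"male": (74, 513), "female": (93, 491)},
    "age_group": {"le60": (24, 259), "gt60": (143, 745)},
    "hypertension": {"yes": (104, 669), "no": (58, 314)},  # 5 / 21 missing
    "residency": {"urban": (139, 846), "suburban": (28, 158)},
    "los_group": {"le7": (94, 810), "gt7": (73, 194)},
    "triage": {"levels12": (143, 666), "levels34": (24, 338)},
    "final_dx": {"yes": (60, 239), "no": (107, 765)},
}

_N_DEAD = 167
_N_ALIVE = 1004


def _fill(col_counts: dict, n_dead: int, n_alive: int) -> np.ndarray:
    dead_vals, alive_vals = [], []
    for level, (d, a) in col_counts.items():
        dead_vals += [level] * d
        alive_vals += [level] * a
    dead_vals += [None] * (n_dead - len(dead_vals))
    alive_vals += [None] * (n_alive - len(alive_vals))
    return np.array(dead_vals + alive_vals, dtype=object)


def reference_counts_cohort() -> pd.DataFrame:
    """Patient-level frame matching every published categorical count.

    Rows are ordered deaths-first; each variable independently reproduces
    its published death-stratified counts, so any per-variable summary (and
    its chi-square test) equals what the published counts imply.
    """
    death = np.concatenate([np.ones(_N_DEAD), np.zeros(_N_ALIVE)])
    data = {"death": death}
    for var, counts in REFERENCE_COUNTS.items():
        data[var] = _fill(counts, _N_DEAD, _N_ALIVE)
    return pd.DataFrame(data)
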