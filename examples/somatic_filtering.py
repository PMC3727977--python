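"""Somatic filtering of OSA calls against normal panels.

Ten private (somatic) calls and fifty polymorphisms shared with two
normal panels are intersected with type-specific windows (100 bp for
MC, 4200 bp for EC, 0 bp for size events).  Candidates are the calls
matched in no panel.
"""

import numpy as np
import pandas as pd

from rmapforge import filter_somatic
from rmapforge.compare import OM_PANEL

rng = np.random.default_rng(99)
somatic = [("chr1", int(p), int(p) + 1, "EC")
           for p in rng.choice(10_000_000, 10, replace=False)]
shared = [("chr2", int(p), int(p) + 1, "MC")
          for p in rng.choice(10_000_000, 50, replace=False)]
osas = pd.DataFrame(somatic + shared, columns=["chrom", "start", "end", "class"])
panels = {
    "blood_normal": (pd.DataFrame(shared[:25], columns=["chrom", "start", "end", "name"]),
                     OM_PANEL),
    "lymphoblast": (pd.DataFrame(shared[25:], columns=["chrom", "start", "end", "name"]),
                    OM_PANEL),
}

candidates, removed, tallies = filter_somatic(osas, panels)
print(f"input calls          : {len(osas)}")
print(f"removed (polymorphic): {len(removed)}")
print(f"somatic candidates   : {len(candidates)}")
print(f"per-panel matches    : {tallies}")
# Every shared call is absorbed by exactly the panel that carries it;
# the ten private calls survive as somatic candidates.
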