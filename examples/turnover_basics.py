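"""Temporal turnover of single plots: Morisita-Horn and Hill numbers.

Builds a two-plot paired survey by hand, computes the abundance-based
similarity between the survey periods and the effective species numbers.
"""

import numpy as np

from resurvey import (
    hill_simpson,
    morisita_horn,
    pairwise_turnover,
    relative_abundance,
)
from resurvey.datatypes import CoverMatrix, PairedSurvey
import pandas as pd

meta = pd.DataFrame(
    {"fertility": ["fertile", "fertile"], "subregion": "MB",
     "survey_year": 1970},
    index=pd.Index(["plot1", "plot2"], name="plot_id"),
)
species = ["fern", "grass", "moss"]
old = CoverMatrix(["plot1", "plot2"], species,
                  np.array([[60.0, 10.0, 5.0], [5.0, 40.0, 20.0]]), meta)
new_meta = meta.assign(survey_year=2014)
new = CoverMatrix(["plot1", "plot2"], species,
                  np.array([[20.0, 40.0, 5.0], [5.0, 45.0, 15.0]]), new_meta)
ps = PairedSurvey(old, new, [("plot1", "plot1"), ("plot2", "plot2")])

p = relative_abundance(old.plot_cover("plot1"))
q = relative_abundance(new.plot_cover("plot1"))
print(f"plot1 relative abundances, original: {np.round(p, 3)}")
print(f"plot1 Morisita-Horn similarity old vs new: {morisita_horn(p, q):.4f}")
print(f"plot1 effective species number (order 2): {hill_simpson(p):.3f}")
print()
print(pairwise_turnover(ps).to_string(index=False))
print()
print("d is 1 - Morisita-Horn: 0 = identical composition and abundances,")
print("1 = no shared species. plot1 changed much more than plot2.")
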