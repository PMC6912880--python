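import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from resurvey.datatypes import CoverMatrix, PairedSurvey, TraitTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_meta(plot_ids, fertility="fertile", subregion="MB", year=1970):
    return pd.DataFrame(
        {
            "fertility": fertility,
            "subregion": subregion,
            "survey_year": year,
        },
        index=pd.Index(plot_ids, name="plot_id"),
    )


def make_cover(covers, fertility="fertile", subregion="MB", year=1970,
               species=None, plots=None):
    covers = np.atleast_2d(np.asarray(covers, dtype=float))
    n, s = covers.shape
    plots = plots or [f"p{i}" for i in range(n)]
    species = species or [f"sp{j}" for j in range(s)]
    return CoverMatrix(
        plot_ids=plots,
        species_ids=species,
        covers=covers,
        site_meta=make_meta(plots, fertility, subregion, year),
    )


def make_pair(old_covers, new_covers, **kw):
    """Paired survey over identical plot/species axes."""
    year_old = kw.pop("year_old", 1970)
    year_new = kw.pop("year_new", 2014)
    old = make_cover(old_covers, year=year_old, **kw)
    new = make_cover(new_covers, year=year_new, **kw)
    return PairedSurvey(old, new, [(p, p) for p in old.plot_ids])


@pytest.fixture
def simple_traits():
    df = pd.DataFrame(
        {
            "C": [20.0, 100.0, 0.0, 60.0, np.nan, np.nan],
            "S": [70.0, 0.0, 100.0, 30.0, np.nan, np.nan],
            "R": [10.0, 0.0, 0.0, 10.0, np.nan, np.nan],
            "morph_group": [
                "forbs",
                "graminoids",
                "dwarf shrubs",
                "forbs",
                "bryophytes",
                "lichens",
            ],
            "is_vascular": [True, True, True, True, False, False],
            "csr_class": ["S", "C", "S", "C", np.nan, np.nan],
        },
        index=pd.Index(["sp0", "sp1", "sp2", "sp3", "sp4", "sp5"], name="species"),
    )
    return TraitTable(df)
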