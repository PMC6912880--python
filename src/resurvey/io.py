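"""File I/O for community, trait and climate tables.

All tables are UTF-8 comma-delimited with a header row and decimal points.
Community tables are long format::

    plot_id,species,cover,fertility,subregion,survey_year

Trait tables::

    species,C,S,R,morph_group,is_vascular[,csr_class]

Climate tables::

    site,date,tmean_c,prec_mm          (date ISO-8601)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

from .datatypes import AnalysisConfig, CoverMatrix, PairedSurvey, TraitTable
from .errors import PairingError, SchemaError, ValidationError

log = logging.getLogger("resurvey")

COMMUNITY_COLUMNS = [
    "plot_id",
    "species",
    "cover",
    "fertility",
    "subregion",
    "survey_year",
]


def read_community(path, survey_label: str = "") -> CoverMatrix:
    """Read a long-format community table into a :class:`CoverMatrix`.

    Duplicate (plot, species) rows are an error — resurvey data should be
    taxonomically harmonized upstream, and silently summing duplicates
    would hide harmonization mistakes.
    """
    df = pd.read_csv(path, dtype={"plot_id": str, "species": str})
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    neg = df[df["cover"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise ValidationError(
            f"{path}: negative cover {row['cover']} at row "
            f"{neg.index[0] + 2} (plot {row['plot_id']!r}, "
            f"species {row['species']!r})"
        )
    dup = df.duplicated(subset=["plot_id", "species"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate entry for plot {row['plot_id']!r}, "
            f"species {row['species']!r}"
        )
    plot_ids = list(dict.fromkeys(df["plot_id"]))
    species_ids = sorted(df["species"].unique())
    covers = np.zeros((len(plot_ids), len(species_ids)))
    prow = {p: i for i, p in enumerate(plot_ids)}
    scol = {s: j for j, s in enumerate(species_ids)}
    for rec in df.itertuples(index=False):
        covers[prow[rec.plot_id], scol[rec.species]] = rec.cover
    meta = (
        df.drop_duplicates("plot_id")
        .set_index("plot_id")[["fertility", "subregion", "survey_year"]]
    )
    incons = df.groupby("plot_id")[["fertility", "subregion", "survey_year"]].nunique()
    bad = incons[(incons > 1).any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"{path}: inconsistent metadata for plot {bad.index[0]!r}"
        )
    cm = CoverMatrix(plot_ids, species_ids, covers, meta)
    log.info(
        "read_community(%s%s): %d plots x %d species",
        path,
        f", {survey_label}" if survey_label else "",
        cm.n_plots,
        cm.n_species,
    )
    return cm


def write_community(cm: CoverMatrix, path) -> None:
    cm.to_long().to_csv(path, index=False)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, dtype={"species": str})
    if "species" not in df.columns:
        raise SchemaError(f"{path}: missing 'species' column")
    df = df.set_index("species")
    for col in ("C", "S", "R"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing {col!r} column")
    if "is_vascular" not in df.columns:
        raise SchemaError(f"{path}: missing 'is_vascular' column")
    df["is_vascular"] = df["is_vascular"].astype(bool)
    return TraitTable(df)


def write_traits(tt: TraitTable, path) -> None:
    tt.data.rename_axis("species").to_csv(path)


def read_climate(path) -> pd.DataFrame:
    """Daily climate series: one row per site per day, dates parsed."""
    df = pd.read_csv(path, parse_dates=["date"])
    for col in ("site", "date", "tmean_c", "prec_mm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing {col!r} column")
    if (df["prec_mm"] < 0).any():
        i = df.index[df["prec_mm"] < 0][0]
        raise ValidationError(f"{path}: negative precipitation at row {i + 2}")
    for site, grp in df.groupby("site"):
        d = grp["date"]
        if not d.is_monotonic_increasing or d.duplicated().any():
            raise ValidationError(f"{path}: dates not strictly increasing for {site}")
    return df


def pair_surveys(old: CoverMatrix, new: CoverMatrix, pairing=None) -> PairedSurvey:
    """Align an original and a resurveyed cover matrix into a pair.

    ``pairing`` maps old plot id -> new plot id; by default plots are
    matched by identical id. Species axes are harmonized to the union,
    zero-filled where a species was absent in one period.
    """
    if pairing is None:
        if set(old.plot_ids) != set(new.plot_ids):
            raise PairingError(
                "no pairing given and plot ids differ between surveys"
            )
        pairing = {p: p for p in old.plot_ids}
    unmatched = [p for p in old.plot_ids if p not in pairing]
    if unmatched:
        raise PairingError(f"old plots without a pairing entry: {unmatched[:5]}")
    union = sorted(set(old.species_ids) | set(new.species_ids))
    old_h = old.with_species_axis(union)
    new_h = new.with_species_axis(union)
    plot_pairs = [(p, pairing[p]) for p in old.plot_ids]
    return PairedSurvey(old_h, new_h, plot_pairs)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return AnalysisConfig(extra=extra, **kwargs)


def save_config(cfg: AnalysisConfig, path) -> None:
    d = {k: getattr(cfg, k) for k in AnalysisConfig.__dataclass_fields__}
    d.update(d.pop("extra"))
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
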