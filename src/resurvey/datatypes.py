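"""Core data model for paired vegetation resurveys.

A survey period is a :class:`CoverMatrix`: plots x species percent covers
plus per-plot site metadata (fertility class, subregion, survey year).
Covers are percentages per species; within a plot they may sum past 100
because vegetation layers overlap. A :class:`PairedSurvey` aligns an
original and a resurveyed :class:`CoverMatrix` on plot identity and on the
union of their species axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyCommunityError,
    MetadataError,
    PairingError,
    ValidationError,
)

FERTILITY_LEVELS = ("fertile", "infertile")
SUBREGIONS = ("MB", "NBs", "NBm", "NBn")
MORPH_GROUPS = (
    "shrubs",
    "dwarf shrubs",
    "forbs",
    "graminoids",
    "pteridophytes",
    "bryophytes",
    "lichens",
)
CSR_CLASSES = ("C", "CR", "R", "SR", "S", "CS", "CSR")


@dataclass
class CoverMatrix:
    """Plots x species percent-cover table for one survey period.

    Parameters
    ----------
    plot_ids : list of str
        Plot identifiers, one per row of ``covers``.
    species_ids : list of str
        Species identifiers, one per column of ``covers``.
    covers : ndarray, shape (n_plots, n_species)
        Percent cover (>= 0). Column sums per plot may exceed 100.
    site_meta : DataFrame indexed by plot_id
        Columns ``fertility`` (fertile/infertile), ``subregion``
        (MB/NBs/NBm/NBn) and ``survey_year`` (int).
    """

    plot_ids: list
    species_ids: list
    covers: np.ndarray
    site_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.covers = np.asarray(self.covers, dtype=float)
        if self.covers.shape != (len(self.plot_ids), len(self.species_ids)):
            raise ValidationError(
                f"cover matrix shape {self.covers.shape} does not match "
                f"{len(self.plot_ids)} plots x {len(self.species_ids)} species"
            )
        if len(set(self.plot_ids)) != len(self.plot_ids):
            raise ValidationError("duplicate plot_ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError("duplicate species_ids")
        if np.any(self.covers < 0):
            i, j = np.argwhere(self.covers < 0)[0]
            raise ValidationError(
                f"negative cover for plot {self.plot_ids[i]!r}, "
                f"species {self.species_ids[j]!r}"
            )
        empty = np.flatnonzero(self.covers.sum(axis=1) <= 0)
        if empty.size:
            raise EmptyCommunityError(
                f"plot {self.plot_ids[empty[0]]!r} has no species with cover > 0"
            )
        missing = [p for p in self.plot_ids if p not in self.site_meta.index]
        if missing:
            raise ValidationError(f"site_meta missing plots: {missing[:5]}")
        self.site_meta = self.site_meta.loc[self.plot_ids]

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def plot_cover(self, plot_id) -> np.ndarray:
        """Cover vector (over ``species_ids``) of one plot."""
        return self.covers[self.plot_ids.index(plot_id)]

    def site_label(self, plot_id) -> str:
        """Site label: ``<subregion>-<fertility>`` of a plot."""
        row = self.site_meta.loc[plot_id]
        return f"{row['subregion']}-{row['fertility']}"

    def subset_plots(self, plot_ids: Sequence) -> "CoverMatrix":
        idx = [self.plot_ids.index(p) for p in plot_ids]
        return CoverMatrix(
            plot_ids=list(plot_ids),
            species_ids=list(self.species_ids),
            covers=self.covers[idx],
            site_meta=self.site_meta.loc[list(plot_ids)],
        )

    def with_species_axis(self, species_ids: Sequence) -> "CoverMatrix":
        """Re-index the species axis, zero-filling absent species."""
        species_ids = list(species_ids)
        new = np.zeros((self.n_plots, len(species_ids)))
        pos = {s: k for k, s in enumerate(species_ids)}
        for j, s in enumerate(self.species_ids):
            if s in pos:
                new[:, pos[s]] = self.covers[:, j]
        return CoverMatrix(
            plot_ids=list(self.plot_ids),
            species_ids=species_ids,
            covers=new,
            site_meta=self.site_meta,
        )

    def to_long(self, survey_label: str | None = None) -> pd.DataFrame:
        """Long-format table with one row per (plot, species) with cover > 0."""
        rows = []
        for i, p in enumerate(self.plot_ids):
            meta = self.site_meta.loc[p]
            for j, s in enumerate(self.species_ids):
                c = self.covers[i, j]
                if c > 0:
                    rows.append(
                        {
                            "plot_id": p,
                            "species": s,
                            "cover": c,
                            "fertility": meta["fertility"],
                            "subregion": meta["subregion"],
                            "survey_year": int(meta["survey_year"]),
                        }
                    )
        df = pd.DataFrame(rows)
        if survey_label is not None:
            df.insert(0, "survey", survey_label)
        return df


@dataclass
class PairedSurvey:
    """Old/new survey pair aligned on plot identity and species union."""

    old: CoverMatrix
    new: CoverMatrix
    plot_pairs: list  # (old_plot_id, new_plot_id)

    def __post_init__(self) -> None:
        if self.old.species_ids != self.new.species_ids:
            raise ValidationError("old and new species axes differ")
        olds = [a for a, _ in self.plot_pairs]
        news = [b for _, b in self.plot_pairs]
        if sorted(olds) != sorted(self.old.plot_ids) or len(set(olds)) != len(olds):
            raise PairingError("plot_pairs does not cover old plots bijectively")
        if sorted(news) != sorted(self.new.plot_ids) or len(set(news)) != len(news):
            raise PairingError("plot_pairs does not cover new plots bijectively")
        for a, b in self.plot_pairs:
            ma = self.old.site_meta.loc[a]
            mb = self.new.site_meta.loc[b]
            for col in ("fertility", "subregion"):
                if ma[col] != mb[col]:
                    raise MetadataError(
                        f"{col} mismatch within pair ({a!r}, {b!r}): "
                        f"{ma[col]!r} vs {mb[col]!r}"
                    )

    @property
    def n_pairs(self) -> int:
        return len(self.plot_pairs)

    def sampling_time(self, pair) -> int:
        """Years elapsed between the two surveys of one plot pair."""
        a, b = pair
        return int(self.new.site_meta.loc[b, "survey_year"]) - int(
            self.old.site_meta.loc[a, "survey_year"]
        )

    def sites(self) -> list:
        """Sorted unique site labels (subregion-fertility) across pairs."""
        return sorted({self.old.site_label(a) for a, _ in self.plot_pairs})

    def site_pairs(self, site: str) -> list:
        """Plot pairs belonging to one site label."""
        return [
            (a, b) for a, b in self.plot_pairs if self.old.site_label(a) == site
        ]


@dataclass
class TraitTable:
    """Per-species Grime CSR coordinates and morphological grouping.

    ``data`` is indexed by species id with columns ``C``, ``S``, ``R``
    (percentages summing to 100 for vascular species with strategy data,
    NaN otherwise), ``morph_group``, ``is_vascular`` and optionally
    ``csr_class`` (the specified strategy class, one of C/CR/R/SR/S/CS/CSR).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"C", "S", "R", "morph_group", "is_vascular"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"trait table missing columns: {sorted(missing)}")
        has_csr = self.data[["C", "S", "R"]].notna().all(axis=1)
        sums = self.data.loc[has_csr, ["C", "S", "R"]].sum(axis=1)
        bad = sums[(sums - 100).abs() > 1e-9]
        if len(bad):
            raise ValidationError(
                f"C+S+R != 100 for species {bad.index[0]!r} (sum {bad.iloc[0]})"
            )
        nonvasc_with_csr = has_csr & ~self.data["is_vascular"].astype(bool)
        if nonvasc_with_csr.any():
            sp = self.data.index[nonvasc_with_csr][0]
            raise ValidationError(
                f"strategy data present for non-vascular species {sp!r}"
            )

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    def has_strategy(self, species_id) -> bool:
        if species_id not in self.data.index:
            return False
        row = self.data.loc[species_id]
        return bool(row["is_vascular"]) and not pd.isna(row["C"])

    def csr(self, species_id) -> tuple:
        row = self.data.loc[species_id]
        return float(row["C"]), float(row["S"]), float(row["R"])


@dataclass
class AnalysisConfig:
    """Run configuration for the full pipeline.

    All seeds used downstream are derived deterministically from
    ``rng_seed`` so an identical config reproduces identical outputs.
    """

    community_old: str = ""
    community_new: str = ""
    traits: str = ""
    climate: str = ""
    out_dir: str = "resurvey_out"
    bootstrap_reps: int = 2000
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    rng_seed: int = 0
    logit_epsilon: float = 0.001
    gdd_base_temp: float = 5.0
    gdd_window_days: int = 10
    gdd_mode: str = "excess"
    csr_denominator: str = "vascular"  # or "total"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if self.chains < 1:
            raise ValidationError("chains must be >= 1")
        if not (0 < self.logit_epsilon < 0.5):
            raise ValidationError("logit_epsilon must lie in (0, 0.5)")
        if self.gdd_mode not in ("excess", "raw"):
            raise ValidationError("gdd_mode must be 'excess' or 'raw'")
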