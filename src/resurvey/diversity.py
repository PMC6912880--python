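"""Abundance-based similarity, turnover and effective-species diversity.

Temporal turnover of a plot is ``1 - C_MH`` where ``C_MH`` is the
Morisita-Horn similarity between its two survey periods,

    C_MH(p, q) = 2 * sum_i p_i q_i / (sum_i p_i^2 + sum_i q_i^2),

computed on within-plot relative abundances. Being abundance-weighted,
the index is insensitive to rare-species richness differences between
plots of unequal size.

Alpha diversity is the Hill number of order 2 (the effective number of
species of Simpson diversity), ``D2 = 1 / sum_i p_i^2``. Within-site beta
turnover generalizes Morisita-Horn to N plots through the gamma/alpha Hill
decomposition at order 2 with equal plot weights:

    D_gamma = D2(pooled mean abundances)
    D_alpha = 1 / mean_j sum_i p_ij^2
    D_beta  = D_gamma / D_alpha
    overlap = (1/D_beta - 1/N) / (1 - 1/N)
    turnover = 1 - overlap

which is 0 when all plots share identical relative abundances and 1 when
all plots are pairwise disjoint.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CoverMatrix, PairedSurvey, TraitTable
from .errors import EmptyCommunityError, UndefinedError, ValidationError

__all__ = [
    "relative_abundance",
    "morisita_horn",
    "pairwise_turnover",
    "hill_simpson",
    "diversity_by_group",
    "multi_assemblage_turnover",
    "bootstrap_se_beta",
    "delta_beta",
    "beta_change",
]


def relative_abundance(covers) -> np.ndarray:
    """Normalize a nonnegative cover vector to relative abundances."""
    c = np.asarray(covers, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative cover in abundance vector")
    total = c.sum()
    if total <= 0:
        raise EmptyCommunityError("all-zero cover vector")
    return c / total


def morisita_horn(p, q) -> float:
    """Morisita-Horn similarity of two relative-abundance vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(
            f"species axes differ in length: {p.shape} vs {q.shape}"
        )
    denom = np.sum(p * p) + np.sum(q * q)
    return float(2.0 * np.sum(p * q) / denom)


def hill_simpson(p) -> float:
    """Effective number of species of order 2 (inverse Simpson)."""
    p = np.asarray(p, dtype=float)
    return float(1.0 / np.sum(p * p))


def pairwise_turnover(ps: PairedSurvey) -> pd.DataFrame:
    """Per-plot temporal turnover 1 - Morisita-Horn between surveys.

    Returns a table with ``plot_id`` (old-survey id), ``d`` (turnover in
    [0, 1]), ``fertility``, ``subregion`` and ``sampling_time`` (years).
    """
    rows = []
    for a, b in ps.plot_pairs:
        try:
            p = relative_abundance(ps.old.plot_cover(a))
            q = relative_abundance(ps.new.plot_cover(b))
        except EmptyCommunityError as exc:
            raise EmptyCommunityError(f"plot pair ({a!r}, {b!r}): {exc}") from exc
        meta = ps.old.site_meta.loc[a]
        rows.append(
            {
                "plot_id": a,
                "d": 1.0 - morisita_horn(p, q),
                "fertility": meta["fertility"],
                "subregion": meta["subregion"],
                "sampling_time": ps.sampling_time((a, b)),
            }
        )
    return pd.DataFrame(rows)


_GROUPS = ("total", "vascular", "bryophyte", "lichen")


def _group_mask(cm: CoverMatrix, traits: TraitTable, group: str) -> np.ndarray:
    known = traits.data
    mask = np.zeros(cm.n_species, dtype=bool)
    unknown = []
    for j, s in enumerate(cm.species_ids):
        if s not in known.index:
            unknown.append(s)
            continue
        row = known.loc[s]
        if group == "total":
            mask[j] = True
        elif group == "vascular":
            mask[j] = bool(row["is_vascular"])
        elif group == "bryophyte":
            mask[j] = row["morph_group"] == "bryophytes"
        elif group == "lichen":
            mask[j] = row["morph_group"] == "lichens"
    if unknown and group == "total":
        # total diversity uses all species, traits known or not
        for j, s in enumerate(cm.species_ids):
            if s in unknown:
                mask[j] = True
        warnings.warn(
            f"{len(unknown)} species missing from trait table, excluded from "
            f"group diversities (e.g. {unknown[0]!r})",
            stacklevel=3,
        )
    return mask


def diversity_by_group(cm: CoverMatrix, traits: TraitTable) -> pd.DataFrame:
    """Per-plot Hill-Simpson effective species numbers by plant group.

    One row per plot x group for groups total / vascular / bryophyte /
    lichen; a group absent from a plot yields NaN (not zero: an absent
    group has no diversity, low diversity is a different statement).
    """
    masks = {g: _group_mask(cm, traits, g) for g in _GROUPS}
    rows = []
    for i, plot in enumerate(cm.plot_ids):
        meta = cm.site_meta.loc[plot]
        for g in _GROUPS:
            sub = cm.covers[i, masks[g]]
            if sub.sum() > 0:
                d = hill_simpson(relative_abundance(sub))
            else:
                d = np.nan
            rows.append(
                {
                    "plot_id": plot,
                    "group": g,
                    "effective_species": d,
                    "fertility": meta["fertility"],
                    "subregion": meta["subregion"],
                }
            )
    return pd.DataFrame(rows)


def _rel_abundance_matrix(cm: CoverMatrix) -> np.ndarray:
    totals = cm.covers.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        i = int(np.argmax(totals.ravel() <= 0))
        raise EmptyCommunityError(f"plot {cm.plot_ids[i]!r} has zero total cover")
    return cm.covers / totals


def multi_assemblage_turnover(cm: CoverMatrix | np.ndarray) -> float:
    """Within-site beta turnover of N plots (order-2 Hill decomposition).

    Accepts a :class:`CoverMatrix` or a raw plots x species cover array.
    Equal plot weights; ranges from 0 (identical relative abundances in
    every plot) to 1 (all plots pairwise disjoint).
    """
    if isinstance(cm, CoverMatrix):
        P = _rel_abundance_matrix(cm)
    else:
        arr = np.asarray(cm, dtype=float)
        totals = arr.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise EmptyCommunityError("a plot has zero total cover")
        P = arr / totals
    n = P.shape[0]
    if n < 2:
        raise UndefinedError("beta turnover undefined for fewer than 2 plots")
    pooled = P.mean(axis=0)
    d_gamma = 1.0 / np.sum(pooled**2)
    d_alpha = 1.0 / np.mean(np.sum(P**2, axis=1))
    d_beta = d_gamma / d_alpha
    overlap = (1.0 / d_beta - 1.0 / n) / (1.0 - 1.0 / n)
    return float(1.0 - overlap)


def bootstrap_se_beta(cm: CoverMatrix | np.ndarray, reps: int = 2000, seed=None) -> float:
    """Bootstrap standard error of :func:`multi_assemblage_turnover`.

    Plots are resampled with replacement; resamples with fewer than two
    distinct plots are redrawn (the statistic is undefined there).
    """
    if isinstance(cm, CoverMatrix):
        covers = cm.covers
    else:
        covers = np.asarray(cm, dtype=float)
    n = covers.shape[0]
    if n < 2:
        raise UndefinedError("beta turnover undefined for fewer than 2 plots")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if reps == 1:  # degenerate bootstrap: no spread to estimate
        return 0.0
    rng = np.random.default_rng(seed)
    stats = np.empty(reps)
    for r in range(reps):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= 2:
                break
        stats[r] = multi_assemblage_turnover(covers[idx])
    return float(np.std(stats, ddof=1))


def delta_beta(beta_old: float, beta_new: float) -> float:
    """Change in within-site beta turnover between surveys.

    Positive values indicate heterogenization, negative homogenization.
    """
    for name, b in (("beta_old", beta_old), ("beta_new", beta_new)):
        if not 0.0 <= b <= 1.0:
            raise ValidationError(f"{name}={b} outside [0, 1]")
    return beta_new - beta_old


def beta_change(
    ps: PairedSurvey, bootstrap_reps: int = 2000, seed=None
) -> pd.DataFrame:
    """Per-site beta diversity before/after and its change.

    Positive ``delta_beta`` marks heterogenization (plots of a site grew
    more dissimilar between surveys), negative marks homogenization.
    Bootstrap SEs come from plot resampling within each site and survey.
    """
    seq = np.random.SeedSequence(seed)
    rows = []
    for site, child in zip(ps.sites(), seq.spawn(len(ps.sites()))):
        pairs = ps.site_pairs(site)
        if len(pairs) < 2:
            raise UndefinedError(f"site {site!r} has fewer than 2 plot pairs")
        old_cm = ps.old.subset_plots([a for a, _ in pairs])
        new_cm = ps.new.subset_plots([b for _, b in pairs])
        b_old = multi_assemblage_turnover(old_cm)
        b_new = multi_assemblage_turnover(new_cm)
        s_old, s_new = child.spawn(2)
        rows.append(
            {
                "site": site,
                "beta_old": b_old,
                "se_old": bootstrap_se_beta(old_cm, bootstrap_reps, s_old),
                "beta_new": b_new,
                "se_new": bootstrap_se_beta(new_cm, bootstrap_reps, s_new),
                "delta_beta": b_new - b_old,
            }
        )
    return pd.DataFrame(rows)
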