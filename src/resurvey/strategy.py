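"""Cover-weighted Grime CSR strategy proportions and group cover changes.

Each vascular species carries percentage coordinates (C, S, R) summing to
100 on Grime's competitor / stress-tolerator / ruderal triangle. The
community-weighted profile of a plot weights each coordinate by the
species' percent cover and normalizes by the summed cover of the species
entering the average, so the three proportions again sum to 100:

    propX = sum_i cover_i * X_i / sum_i cover_i,   X in {C, S, R}.

By default only vascular species with strategy data enter both numerator
and denominator (cryptogams carry no CSR coordinates; including their
cover in the denominator would deflate all three proportions on
bryophyte-dominated plots). Set ``denominator='total'`` to divide by the
whole-plot cover instead.

Proportions are logit-transformed (with boundary clamping) before linear
modeling so that residuals are unbounded and approximately normal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CSR_CLASSES, MORPH_GROUPS, CoverMatrix, PairedSurvey, TraitTable
from .errors import UndefinedError, ValidationError

__all__ = [
    "cwm_csr",
    "logit_fraction",
    "inv_logit",
    "strategy_profiles",
    "group_cover_change",
]


def cwm_csr(
    covers,
    species_ids,
    traits: TraitTable,
    denominator: str = "vascular",
) -> tuple[float, float, float]:
    """Cover-weighted (propC, propS, propR) of one plot, in percent.

    ``covers`` is the percent-cover vector over ``species_ids``. Species
    without strategy data are skipped; with ``denominator='total'`` their
    cover still enters the denominator.
    """
    c = np.asarray(covers, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative cover")
    num = np.zeros(3)
    denom_strategy = 0.0
    for cov, sp in zip(c, species_ids):
        if cov <= 0:
            continue
        if traits.has_strategy(sp):
            csr = traits.csr(sp)
            num += cov * np.asarray(csr)
            denom_strategy += cov
    if denom_strategy <= 0:
        raise UndefinedError(
            "no vascular species with cover > 0 and strategy data in plot"
        )
    denom = c.sum() if denominator == "total" else denom_strategy
    props = num / denom
    return tuple(float(x) for x in props)


def logit_fraction(x: float, epsilon: float = 0.001) -> float:
    """Logit of a fraction with boundary clamping to [eps, 1-eps].

    Proportions can sit exactly on 0 or 1 where the logit diverges; the
    clamp keeps transformed values finite while remaining strictly
    increasing on the interior.
    """
    if not 0 <= x <= 1:
        raise ValidationError(f"fraction {x} outside [0, 1]")
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must lie in (0, 0.5)")
    xc = min(max(x, epsilon), 1.0 - epsilon)
    return float(np.log(xc / (1.0 - xc)))


def inv_logit(z: float) -> float:
    """Inverse of the logit; maps the real line to (0, 1)."""
    return float(1.0 / (1.0 + np.exp(-z)))


def strategy_profiles(
    ps: PairedSurvey,
    traits: TraitTable,
    epsilon: float = 0.001,
    denominator: str = "vascular",
) -> pd.DataFrame:
    """Per-plot, per-period CSR strategy profiles.

    Plots where no strategy-bearing species occurs in a period are
    dropped with a warning. Returns one row per plot x period with
    ``propC/propS/propR`` (percent) and ``logitC/logitS``.
    """
    rows = []
    dropped = []
    for a, b in ps.plot_pairs:
        meta = ps.old.site_meta.loc[a]
        for period, cm, plot in (("old", ps.old, a), ("new", ps.new, b)):
            try:
                pc, psn, pr = cwm_csr(
                    cm.plot_cover(plot), cm.species_ids, traits, denominator
                )
            except UndefinedError:
                dropped.append((plot, period))
                continue
            rows.append(
                {
                    "plot_id": a,
                    "period": period,
                    "propC": pc,
                    "propS": psn,
                    "propR": pr,
                    "logitC": logit_fraction(pc / 100.0, epsilon),
                    "logitS": logit_fraction(psn / 100.0, epsilon),
                    "fertility": meta["fertility"],
                    "subregion": meta["subregion"],
                }
            )
    if dropped:
        warnings.warn(
            f"{len(dropped)} plot/period combinations without strategy data "
            f"dropped (e.g. {dropped[0]})",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _group_cover(
    cm: CoverMatrix, plot, traits: TraitTable, grouping: str
) -> dict[str, float]:
    cover = cm.plot_cover(plot)
    groups = MORPH_GROUPS if grouping == "morphological" else CSR_CLASSES
    out = {g: 0.0 for g in groups}
    for cov, sp in zip(cover, cm.species_ids):
        if cov <= 0 or sp not in traits.data.index:
            continue
        row = traits.data.loc[sp]
        if grouping == "morphological":
            g = row["morph_group"]
        else:
            g = row.get("csr_class", np.nan)
        if isinstance(g, str) and g in out:
            out[g] += cov
    return out


def group_cover_change(
    ps: PairedSurvey,
    traits: TraitTable,
    grouping: str = "morphological",
    reps: int = 2000,
    seed=None,
) -> pd.DataFrame:
    """Mean absolute cover change per site and group, with bootstrap CI.

    For each site and plant group: the mean over plots of
    (summed group cover at resurvey) - (summed group cover originally),
    in percent-cover units, with a percentile 95% CI from resampling
    plots with replacement. Groups absent from a site in both periods
    are flagged ``absent``.
    """
    if grouping not in ("morphological", "csr_class"):
        raise ValidationError("grouping must be 'morphological' or 'csr_class'")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    groups = MORPH_GROUPS if grouping == "morphological" else CSR_CLASSES
    seq = np.random.SeedSequence(seed)
    rows = []
    for site, child in zip(ps.sites(), seq.spawn(len(ps.sites()))):
        pairs = ps.site_pairs(site)
        # plots x groups matrix of per-plot cover changes
        deltas = np.zeros((len(pairs), len(groups)))
        present = np.zeros(len(groups), dtype=bool)
        for i, (a, b) in enumerate(pairs):
            old_c = _group_cover(ps.old, a, traits, grouping)
            new_c = _group_cover(ps.new, b, traits, grouping)
            for j, g in enumerate(groups):
                deltas[i, j] = new_c[g] - old_c[g]
                if old_c[g] > 0 or new_c[g] > 0:
                    present[j] = True
        means = deltas.mean(axis=0)
        if reps == 1:  # degenerate bootstrap: CI collapses to the estimate
            lo = hi = means
        else:
            rng = np.random.default_rng(child)
            n = len(pairs)
            idx = rng.integers(0, n, size=(reps, n))
            boot_means = deltas[idx].mean(axis=1)  # reps x groups
            lo = np.percentile(boot_means, 2.5, axis=0)
            hi = np.percentile(boot_means, 97.5, axis=0)
        for j, g in enumerate(groups):
            rows.append(
                {
                    "site": site,
                    "group": g,
                    "mean_change": means[j],
                    "ci_low": min(lo[j], means[j]),
                    "ci_high": max(hi[j], means[j]),
                    "absent": not present[j],
                }
            )
    return pd.DataFrame(rows)
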