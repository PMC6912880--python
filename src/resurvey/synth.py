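"""Synthetic paired-survey data with known ground truth.

The generator emulates a boreal understorey resurvey: four subregions
(MB, NBs, NBm, NBn) each holding one fertile (herb-rich) and one
infertile (heath) site, 78 plots in total, surveyed decades apart.

* **Traits** — species belong to a fertile or infertile guild. Vascular
  species draw Grime CSR coordinates from guild-specific Dirichlet
  distributions: the fertile guild skews toward competitive/ruderal
  strategies (C, CR, R), the infertile guild toward stress tolerance
  (S, SR). Cryptogams (bryophytes, lichens) carry no CSR data.
* **Communities** — each site holds a species subset drawn mostly from
  its own guild. A site-level base composition and a low-concentration
  Dirichlet give plots with few dominant and many rare species.
  Resurvey abundances mix the original plot toward an independent
  dispersed draw; the mixing weight is calibrated by bisection (against
  the realized Morisita-Horn dissimilarity in a pilot simulation) so the
  mean plot turnover of each fertility class hits its target. Fertile
  communities additionally receive an exponential tilt away from C
  toward S species, reproducing the directional strategy shift.
* **Climate** — daily mean temperature is a seasonal cosine plus a
  linear warming trend plus Gaussian noise; daily precipitation is
  gamma-distributed. Series are gap-free including leap days.

Identical seeds reproduce identical outputs everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CoverMatrix, PairedSurvey, TraitTable
from .diversity import morisita_horn
from .errors import CalibrationError, ValidationError

__all__ = ["SimulationTruth", "gen_traits", "gen_paired_survey", "gen_climate", "gen_dataset"]

# study design: plots per (subregion, fertility) and original survey years,
# resurveys in 2013-2014, sampling times spanning 33-57 years
DESIGN = {
    ("MB", "fertile"): (8, 1969),
    ("MB", "infertile"): (9, 1980),
    ("NBs", "fertile"): (10, 1971),
    ("NBs", "infertile"): (10, 1979),
    ("NBm", "fertile"): (10, 1975),
    ("NBm", "infertile"): (10, 1980),
    ("NBn", "fertile"): (10, 1958),
    ("NBn", "infertile"): (11, 1957),
}
RESURVEY_YEAR = {"MB": 2013, "NBs": 2013, "NBm": 2014, "NBn": 2014}

_FERTILE_MORPH = {
    "forbs": 0.40,
    "graminoids": 0.15,
    "pteridophytes": 0.07,
    "shrubs": 0.08,
    "dwarf shrubs": 0.05,
    "bryophytes": 0.25,
}
_INFERTILE_MORPH = {
    "dwarf shrubs": 0.25,
    "bryophytes": 0.30,
    "lichens": 0.20,
    "graminoids": 0.10,
    "forbs": 0.10,
    "shrubs": 0.05,
}
# Dirichlet concentrations over (C, S, R) per guild
_CSR_ALPHA = {"fertile": (4.0, 1.5, 2.5), "infertile": (1.2, 5.0, 1.8)}


@dataclass
class SimulationTruth:
    """Ground-truth parameters of one synthetic study.

    Turnover targets are mean plot-level Morisita-Horn dissimilarities
    per fertility class; the default contrast (0.36 vs 0.15) mirrors the
    greater turnover of fertile sites. ``csr_time_effects`` are
    log-scale abundance tilts applied at resurvey per fertility class
    (negative C-tilt = competitive species lose cover). Climate defaults
    describe a northern boreal station with a contemporary warming trend.
    """

    turnover_mean_fertile: float = 0.36
    turnover_mean_infertile: float = 0.15
    csr_time_effects: dict = field(
        default_factory=lambda: {
            "fertile": {"C": -0.8, "S": 0.8},
            "infertile": {"C": 0.0, "S": 0.0},
        }
    )
    diversity_effects: dict = field(
        default_factory=lambda: {"fertile": 1.0, "infertile": 1.0}
    )
    climate: dict = field(
        default_factory=lambda: {
            "mean_temp": 1.5,  # degC annual mean
            "amplitude": 13.0,  # degC seasonal half-range
            "warming_slope": 0.03,  # degC per year
            "noise_sd": 3.0,  # degC daily
            "prec_shape": 0.7,
            "prec_scale": 2.6,  # mm; ~665 mm/yr expected
        }
    )
    n_species_fertile: int = 120
    n_species_infertile: int = 100
    species_per_site: int = 40
    site_concentration: float = 0.3  # Dirichlet mass per species, site base
    plot_kappa: float = 60.0  # plot concentration around the site base
    target_kappa: float = 8.0  # plot concentration around the resurvey base
    replacement_rate: float = 0.0  # mass on previously absent species
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.turnover_mean_fertile, self.turnover_mean_infertile):
            if not 0.0 < t < 1.0:
                raise ValidationError(f"turnover target {t} outside (0, 1)")
        if self.species_per_site < 5:
            raise ValidationError("species_per_site must be >= 5")


def _csr_class(c: float, s: float, r: float) -> str:
    """Specified strategy class from (C, S, R) percentages."""
    vals = {"C": c, "S": s, "R": r}
    if min(vals.values()) >= 25.0:
        return "CSR"
    top = max(vals.values())
    if top >= 60.0:
        return max(vals, key=vals.get)
    two = sorted(vals, key=vals.get, reverse=True)[:2]
    pair = "".join(sorted(two, key="CSR".index))
    return {"CS": "CS", "CR": "CR", "SR": "SR"}[pair]


def gen_traits(
    n_fertile: int = 120, n_infertile: int = 100, seed=0
) -> TraitTable:
    """Generate a species trait table with guild-structured CSR values."""
    if min(n_fertile, n_infertile) < 5:
        raise ValidationError("need at least 5 species per guild")
    rng = np.random.default_rng(seed)
    rows = []
    for guild, n in (("fertile", n_fertile), ("infertile", n_infertile)):
        morph_probs = _FERTILE_MORPH if guild == "fertile" else _INFERTILE_MORPH
        groups = rng.choice(
            list(morph_probs), size=n, p=list(morph_probs.values())
        )
        alpha = np.asarray(_CSR_ALPHA[guild])
        for i, mg in enumerate(groups):
            vascular = mg not in ("bryophytes", "lichens")
            if vascular:
                d = rng.dirichlet(alpha)
                c = round(100.0 * d[0], 6)
                s = round(100.0 * d[1], 6)
                r = 100.0 - c - s
                cls = _csr_class(c, s, r)
            else:
                c = s = r = np.nan
                cls = np.nan
            rows.append(
                {
                    "species": f"sp_{guild[:4]}_{i:03d}",
                    "C": c,
                    "S": s,
                    "R": r,
                    "morph_group": mg,
                    "is_vascular": vascular,
                    "csr_class": cls,
                    "guild": guild,
                }
            )
    return TraitTable(pd.DataFrame(rows).set_index("species"))


def _tilt_vector(traits: TraitTable, species, effects: dict, evenness: float):
    """Per-species multiplicative log-tilt for the resurvey."""
    tilt = np.zeros(len(species))
    for j, sp in enumerate(species):
        if traits.has_strategy(sp):
            c, s, _ = traits.csr(sp)
            tilt[j] = effects.get("C", 0.0) * c / 100.0 + effects.get(
                "S", 0.0
            ) * s / 100.0
    return tilt


def _site_plots(
    rng, n_plots, base, kappa, n_species
) -> np.ndarray:
    return rng.dirichlet(kappa * base + 1e-8, size=n_plots)


def _resurvey_plots(rng, old_p, w, alpha_target, target_kappa, tilt, evenness):
    """Mix each old plot toward a dispersed site-level resurvey draw.

    The resurvey base is drawn once per site so plots of a site drift in
    a correlated direction; each plot's own target scatters around it.
    """
    target_base = rng.dirichlet(alpha_target)
    new = np.empty_like(old_p)
    for i in range(old_p.shape[0]):
        target = rng.dirichlet(target_kappa * target_base + 1e-8)
        mixed = (1.0 - w) * old_p[i] + w * target
        mixed = mixed * np.exp(tilt)
        if evenness != 1.0:
            pos = mixed > 0
            mixed[pos] = mixed[pos] ** (1.0 / evenness)
        new[i] = mixed / mixed.sum()
    return new


def _mean_turnover(old_p, new_p) -> float:
    return float(
        np.mean(
            [1.0 - morisita_horn(old_p[i], new_p[i]) for i in range(len(old_p))]
        )
    )


def _calibrate_w(
    truth: SimulationTruth, target, alpha_target, tilt, evenness, pilot_seed
) -> float:
    """Bisection on the mixing weight against pilot realized turnover."""

    def realized(w: float) -> float:
        rng = np.random.default_rng(pilot_seed)
        ds = []
        for _ in range(6):  # average over pilot sites to damp base-draw noise
            base = rng.dirichlet(
                np.full(len(alpha_target), truth.site_concentration) + 1e-8
            )
            old_p = _site_plots(rng, 15, base, truth.plot_kappa, len(alpha_target))
            new_p = _resurvey_plots(
                rng, old_p, w, alpha_target, truth.target_kappa, tilt, evenness
            )
            ds.append(_mean_turnover(old_p, new_p))
        return float(np.mean(ds))

    lo, hi = 0.0, 1.0
    d_lo, d_hi = realized(lo), realized(hi)
    if target > d_hi + 0.02 or target < d_lo - 0.02:
        raise CalibrationError(
            f"turnover target {target} outside achievable range "
            f"[{d_lo:.3f}, {d_hi:.3f}] for this species pool"
        )
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_paired_survey(truth: SimulationTruth):
    """Generate a full paired survey from ground truth.

    Returns ``(PairedSurvey, TraitTable, manifest)``; the manifest
    records the seed, calibrated mixing weights and design.
    """
    seq = np.random.SeedSequence(truth.seed)
    s_traits, s_comm, s_pilot = seq.spawn(3)
    traits = gen_traits(
        truth.n_species_fertile, truth.n_species_infertile, s_traits
    )
    pool = {
        g: [sp for sp in traits.species_ids if traits.data.loc[sp, "guild"] == g]
        for g in ("fertile", "infertile")
    }
    rng = np.random.default_rng(s_comm)
    pilot_root = s_pilot.generate_state(1)[0] % (2**31)

    # calibrate one mixing weight per fertility class, with the class's own
    # CSR tilt and evenness shift included so they do not bias the targets
    weights = {}
    for k, fert in enumerate(("fertile", "infertile")):
        target = (
            truth.turnover_mean_fertile
            if fert == "fertile"
            else truth.turnover_mean_infertile
        )
        prng = np.random.default_rng(pilot_root + k)
        own = pool[fert]
        other = pool["fertile" if fert == "infertile" else "infertile"]
        n_own = int(round(0.85 * truth.species_per_site))
        pilot_sp = list(prng.choice(own, size=n_own, replace=False)) + list(
            prng.choice(other, size=truth.species_per_site - n_own, replace=False)
        )
        tilt = _tilt_vector(traits, pilot_sp, truth.csr_time_effects[fert], 1.0)
        alpha_t = np.full(len(pilot_sp), truth.site_concentration)
        weights[fert] = _calibrate_w(
            truth, target, alpha_t, tilt, truth.diversity_effects[fert],
            pilot_seed=pilot_root + k,
        )

    all_old, all_new, meta_rows = [], [], []
    plot_ids = []
    species_union = list(traits.species_ids)
    col = {sp: j for j, sp in enumerate(species_union)}
    n_total = len(species_union)

    for (subregion, fert), (n_plots, year0) in DESIGN.items():
        own = pool[fert]
        other = pool["fertile" if fert == "infertile" else "infertile"]
        n_own = int(round(0.85 * truth.species_per_site))
        n_oth = truth.species_per_site - n_own
        site_sp = list(rng.choice(own, size=n_own, replace=False)) + list(
            rng.choice(other, size=n_oth, replace=False)
        )
        base = rng.dirichlet(
            np.full(len(site_sp), truth.site_concentration) + 1e-8
        )
        old_p = _site_plots(rng, n_plots, base, truth.plot_kappa, len(site_sp))
        effects = truth.csr_time_effects[fert]
        tilt = _tilt_vector(traits, site_sp, effects, 1.0)
        alpha_t = np.full(len(site_sp), truth.site_concentration)
        if truth.replacement_rate > 0:
            extra = [sp for sp in own if sp not in site_sp]
            k_extra = min(len(extra), truth.species_per_site // 2)
            extra = list(rng.choice(extra, size=k_extra, replace=False))
            site_sp = site_sp + extra
            old_p = np.hstack([old_p, np.zeros((n_plots, k_extra))])
            alpha_t = np.concatenate(
                [
                    alpha_t,
                    np.full(
                        k_extra, truth.site_concentration * truth.replacement_rate
                    ),
                ]
            )
            tilt = _tilt_vector(traits, site_sp, effects, 1.0)
        new_p = _resurvey_plots(
            rng,
            old_p,
            weights[fert],
            alpha_t,
            truth.target_kappa,
            tilt,
            truth.diversity_effects[fert],
        )
        totals = np.exp(rng.normal(np.log(110.0), 0.25, size=(n_plots, 2)))
        for i in range(n_plots):
            pid = f"{subregion}-{fert}-p{i + 1:02d}"
            plot_ids.append(pid)
            row_old = np.zeros(n_total)
            row_new = np.zeros(n_total)
            for j, sp in enumerate(site_sp):
                row_old[col[sp]] = old_p[i, j] * totals[i, 0]
                row_new[col[sp]] = new_p[i, j] * totals[i, 1]
            # percent covers: clip to scale, drop trace occurrences
            for row in (row_old, row_new):
                np.minimum(row, 100.0, out=row)
                row[row < 0.05] = 0.0
                np.round(row, 2, out=row)
            all_old.append(row_old)
            all_new.append(row_new)
            meta_rows.append(
                {
                    "plot_id": pid,
                    "fertility": fert,
                    "subregion": subregion,
                    "year_old": year0,
                    "year_new": RESURVEY_YEAR[subregion],
                }
            )

    meta = pd.DataFrame(meta_rows).set_index("plot_id")
    meta_old = meta.rename(columns={"year_old": "survey_year"})[
        ["fertility", "subregion", "survey_year"]
    ]
    meta_new = meta.rename(columns={"year_new": "survey_year"})[
        ["fertility", "subregion", "survey_year"]
    ]
    old_cm = CoverMatrix(plot_ids, species_union, np.vstack(all_old), meta_old)
    new_cm = CoverMatrix(plot_ids, species_union, np.vstack(all_new), meta_new)
    ps = PairedSurvey(old_cm, new_cm, [(p, p) for p in plot_ids])
    manifest = {
        "seed": int(truth.seed),
        "mixing_weights": {k: float(v) for k, v in weights.items()},
        "targets": {
            "fertile": truth.turnover_mean_fertile,
            "infertile": truth.turnover_mean_infertile,
        },
        "csr_time_effects": truth.csr_time_effects,
        "n_plots": len(plot_ids),
        "n_species": n_total,
    }
    return ps, traits, manifest


def gen_climate(
    truth: SimulationTruth, site: str, n_years: int, seed=0, year0: int = 1957
) -> pd.DataFrame:
    """Daily climate for one site: seasonal cycle + warming trend + noise."""
    if n_years < 3:
        raise ValidationError("n_years must be >= 3")
    c = truth.climate
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{year0}-01-01", f"{year0 + n_years - 1}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy()
    yrs = dates.year.to_numpy() - year0
    seasonal = -np.cos(2.0 * np.pi * (doy - 15) / 365.25)  # peak mid-July
    tmean = (
        c["mean_temp"]
        + c["amplitude"] * seasonal
        + c["warming_slope"] * yrs
        + rng.normal(0.0, c["noise_sd"], size=len(dates))
    )
    prec = rng.gamma(c["prec_shape"], c["prec_scale"], size=len(dates))
    return pd.DataFrame(
        {
            "site": site,
            "date": dates,
            "tmean_c": np.round(tmean, 3),
            "prec_mm": np.round(prec, 3),
        }
    )


def gen_dataset(truth: SimulationTruth):
    """Full synthetic bundle: paired survey, traits, climate, survey years.

    Returns ``(PairedSurvey, TraitTable, climate_df, survey_years, manifest)``
    where ``survey_years`` maps site label -> (original year, resurvey year).
    """
    ps, traits, manifest = gen_paired_survey(truth)
    seq = np.random.SeedSequence(truth.seed + 1)
    frames = []
    survey_years = {}
    for (subregion, fert), (_, year0) in DESIGN.items():
        site = f"{subregion}-{fert}"
        y1 = RESURVEY_YEAR[subregion]
        survey_years[site] = (year0, y1)
        child = seq.spawn(1)[0]
        frames.append(
            gen_climate(
                truth, site, n_years=y1 - year0 + 1, seed=child, year0=year0
            )
        )
    climate = pd.concat(frames, ignore_index=True)
    return ps, traits, climate, survey_years, manifest
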