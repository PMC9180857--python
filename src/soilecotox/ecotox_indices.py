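"""Ecotoxicology indices for factorial soil-contamination studies.

Implements the ratio-type influence factors (IF) for xenobiotics, humic acid
and plants, the plant tolerance index (TI), the biochemical fertility index
BA21, the shoot:root mass ratio (PR), and the two kinetic indices derived from
10-day colony-emergence counting: colony development (CD) and ecophysiological
diversity (EP).  ``build_index_report`` assembles all of them from the tidy
tables the synthetic-data module (or a real study) provides.

Conventions
-----------
* IF and TI are ratios of replicate *means* (ratio of means, not mean of
  ratios): the defining formulas are written on treatment-level activities.
* IF < 1 / TI < 100 signal inhibition; IF > 1 / TI > 100 signal stimulation.
* CD lives in [10, 100]: 100 when every colony appears on day 1, 10 when all
  appear on day 10.  EP is the Shannon entropy of the daily emergence
  proportions, base 10 by default so a uniform 10-day series scores 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ENZYMES = ("deh", "cat", "ure", "pac", "pal", "aryl", "glu")
#: enzymes entering BA21 as printed in its defining formula (Pac excluded)
BA21_ENZYMES = ("deh", "cat", "pal", "ure", "glu", "aryl")
N_DAYS = 10

__all__ = [
    "ENZYMES",
    "BA21_ENZYMES",
    "EnzymeProfile",
    "ContrastPair",
    "BiomassRecord",
    "influence_factor",
    "tolerance_index",
    "fertility_index_ba21",
    "shoot_root_ratio",
    "colony_development_index",
    "ecophysiological_diversity_index",
    "build_index_report",
]


@dataclass(frozen=True)
class EnzymeProfile:
    """Activities of the seven assayed soil enzymes for one experimental unit.

    Units are enzyme-specific (per kg dry soil) and opaque here; every index
    built from them is dimensionless.
    """

    deh: float
    cat: float
    ure: float
    pac: float
    pal: float
    aryl: float
    glu: float

    def __post_init__(self) -> None:
        for name in ENZYMES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"negative activity for {name}: {v}")


@dataclass(frozen=True)
class ContrastPair:
    """Replicate measurements for one treated-vs-control contrast."""

    treated_values: tuple[float, ...]
    control_values: tuple[float, ...]


@dataclass(frozen=True)
class BiomassRecord:
    """Aerial and root dry masses (g per pot) with their controls."""

    aerial_mass: float
    root_mass: float
    control_aerial: float | None = None
    control_root: float | None = None


def influence_factor(
    treated: Iterable[float] | float, control: Iterable[float] | float
) -> float:
    """Ratio of treated mean to control mean (IF).

    Values below 1 signal inhibition of the measured variable, above 1
    stimulation.  Scalars are accepted as single-replicate lists.
    """
    t = np.atleast_1d(np.asarray(treated, dtype=float))
    c = np.atleast_1d(np.asarray(control, dtype=float))
    if t.size == 0 or c.size == 0:
        raise ValueError("influence_factor needs non-empty treated and control values")
    c_mean = c.mean()
    if c_mean <= 0:
        raise ValueError(f"control mean must be positive, got {c_mean}")
    return float(t.mean() / c_mean)


def tolerance_index(
    yield_treated: Iterable[float] | float, yield_control: Iterable[float] | float
) -> float:
    """Plant biomass under contamination as a percentage of control (TI).

    TI = 100 x Yp / Yc.  TI < 100 means the xenobiotic inhibited growth,
    TI > 100 that it stimulated it.
    """
    return 100.0 * influence_factor(yield_treated, yield_control)


def fertility_index_ba21(profile: EnzymeProfile, *, include_pac: bool = False) -> float:
    """Biochemical soil fertility index: the sum of six enzyme activities.

    The defining formula sums Deh + Cat + Pal + Ure + Glu + Aryl; acid
    phosphatase is assayed but not part of the printed sum.  ``include_pac``
    adds it for a seven-enzyme variant.
    """
    names = ENZYMES if include_pac else BA21_ENZYMES
    return float(sum(getattr(profile, n) for n in names))


def shoot_root_ratio(rec: BiomassRecord) -> float:
    """Aerial dry mass over root dry mass (PR)."""
    if rec.root_mass <= 0:
        raise ValueError(f"root mass must be positive, got {rec.root_mass}")
    return rec.aerial_mass / rec.root_mass


def _daily(series: Sequence[float]) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.shape != (N_DAYS,):
        raise ValueError(f"colony series must have exactly {N_DAYS} daily counts, got shape {x.shape}")
    if (x < 0).any():
        raise ValueError("negative daily colony counts")
    if x.sum() <= 0:
        raise ValueError("colony series with zero total carries no kinetic information")
    return x


def colony_development_index(series: Sequence[float]) -> float:
    """Day-weighted colony-emergence index CD in [10, 100].

    CD = 100 x sum_d (N_d / N_total) / d over days 1..10: 100 when every
    colony appears on day 1 (a fast-growing, zymogenous community), 10 when
    all appear on day 10 (slow-growing oligotrophs).
    """
    x = _daily(series)
    p = x / x.sum()
    days = np.arange(1, N_DAYS + 1, dtype=float)
    return float(100.0 * (p / days).sum())


def ecophysiological_diversity_index(series: Sequence[float], *, base: float = 10.0) -> float:
    """Shannon entropy of the daily colony-emergence distribution (EP).

    EP = -sum p_d log p_d with p_d the fraction of all colonies appearing on
    day d; zero-count days contribute nothing.  Base 10 by default, so EP of a
    uniform 10-day series is exactly 1; base e is available via ``base``.
    """
    x = _daily(series)
    p = x[x > 0] / x.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


# ---------------------------------------------------------------------------
# report assembly over a factorial design
# ---------------------------------------------------------------------------

_FACTORS = ["contamination", "amendment", "crop"]


def _cell_means(tidy: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per (variable, contamination, amendment, crop)."""
    return (
        tidy.groupby(["variable", *_FACTORS], sort=False, observed=True)["value"]
        .mean()
        .reset_index()
    )


def _ratio_contrast(
    means: pd.DataFrame,
    factor: str,
    numerator_levels: Sequence[str],
    reference: str,
    index_name: str,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Generic within-stratum ratio: numerator level vs reference level of one factor."""
    strata = ["variable"] + [f for f in _FACTORS if f != factor]
    ref = means[means[factor] == reference].set_index(strata)["value"]
    rows = []
    for level in numerator_levels:
        num = means[means[factor] == level].set_index(strata)["value"]
        common = num.index.intersection(ref.index)
        missing = num.index.difference(ref.index)
        if len(missing):
            raise ValueError(
                f"{index_name}: no {factor}={reference!r} reference cell for strata {list(missing)}"
            )
        for key in common:
            denom = ref.loc[key]
            if denom <= 0:
                raise ValueError(f"{index_name}: non-positive reference mean in stratum {key}")
            row = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
            row[factor] = level
            row["index"] = index_name
            row["value"] = scale * num.loc[key] / denom
            rows.append(row)
    return pd.DataFrame(rows, columns=["index", "variable", *_FACTORS, "value"])


def build_index_report(
    design: pd.DataFrame,
    enzyme_table: pd.DataFrame | None = None,
    colony_table: pd.DataFrame | None = None,
    biomass_table: pd.DataFrame | None = None,
    *,
    control_contamination: str = "C",
    reference_amendment: str = "none",
    reference_crop: str = "unsown",
    strict_control_reference: bool = False,
    ep_base: float = 10.0,
    include_pac: bool = False,
    cd_ep_mode: str = "per_replicate",
) -> pd.DataFrame:
    """Assemble all indices for one study into a tidy report.

    Contrast layout over the factorial design:

    * IF_X - each contaminated level vs the uncontaminated control, within the
      same (amendment, crop) stratum;
    * IF_H - amended vs unamended, within (contamination, crop);
    * IF_P - each sown crop vs unsown, within (contamination, amendment);
    * TI   - biomass of contaminated vs control, within (amendment, crop),
      scaled by 100;
    * PR, BA21, replicate cell means - per treatment cell;
    * CD, EP - per colony-emergence series, by default computed per replicate
      then averaged within the cell (``cd_ep_mode="pooled"`` sums the daily
      counts across replicates first).

    ``strict_control_reference=True`` makes IF_H and IF_P divide by the fully
    untreated control cell instead of the within-stratum reference, the
    literal reading of the defining formula's A_C denominator.

    Returns a tidy frame (index, variable, contamination, amendment, crop,
    value); factor columns not fixed by a contrast carry the contrast's own
    level so every row is traceable.
    """
    contaminated = [
        c for c in design["contamination"].unique() if c != control_contamination
    ]
    sown = [c for c in design["crop"].unique() if c != reference_crop]
    amended = [a for a in design["amendment"].unique() if a != reference_amendment]
    parts: list[pd.DataFrame] = []

    def strict_reference(means: pd.DataFrame) -> pd.DataFrame:
        ctrl = means[
            (means["contamination"] == control_contamination)
            & (means["amendment"] == reference_amendment)
            & (means["crop"] == reference_crop)
        ].set_index("variable")["value"]
        out = means.copy()
        out["value"] = [
            means.loc[i, "value"] / ctrl[means.loc[i, "variable"]] for i in means.index
        ]
        return out

    measured = []
    if enzyme_table is not None:
        measured.append(enzyme_table)
    if colony_table is not None:
        # IF on microbial counts uses total cfu per series
        totals = (
            colony_table.groupby(
                ["variable", *_FACTORS, "replicate"], sort=False, observed=True
            )["value"]
            .sum()
            .reset_index()
        )
        measured.append(totals)
    if measured:
        tidy = pd.concat(measured, ignore_index=True)
        means = _cell_means(tidy)
        parts.append(
            _ratio_contrast(means, "contamination", contaminated, control_contamination, "IF_X")
        )
        if strict_control_reference:
            rel = strict_reference(means)
            for factor, levels, name in (
                ("amendment", amended, "IF_H"),
                ("crop", sown, "IF_P"),
            ):
                sub = rel[rel[factor].isin(levels)].copy()
                sub["index"] = name
                parts.append(sub[["index", "variable", *_FACTORS, "value"]])
        else:
            parts.append(
                _ratio_contrast(means, "amendment", amended, reference_amendment, "IF_H")
            )
            parts.append(_ratio_contrast(means, "crop", sown, reference_crop, "IF_P"))
        mm = means.copy()
        mm["index"] = "mean"
        parts.append(mm[["index", "variable", *_FACTORS, "value"]])

    if enzyme_table is not None:
        # BA21 per cell from enzyme cell means
        means = _cell_means(enzyme_table)
        wide = means.pivot_table(
            index=_FACTORS, columns="variable", values="value", observed=True
        )
        missing = [e for e in ENZYMES if e not in wide.columns]
        if missing:
            raise ValueError(f"enzyme table lacks activities for: {missing}")
        ba = wide.apply(
            lambda r: fertility_index_ba21(
                EnzymeProfile(**{e: r[e] for e in ENZYMES}), include_pac=include_pac
            ),
            axis=1,
        )
        ba_df = ba.rename("value").reset_index()
        ba_df["index"] = "BA21"
        ba_df["variable"] = "BA21"
        parts.append(ba_df[["index", "variable", *_FACTORS, "value"]])

    if biomass_table is not None:
        means = _cell_means(biomass_table)
        parts.append(
            _ratio_contrast(
                means, "contamination", contaminated, control_contamination, "TI", scale=100.0
            )
        )
        wide = means.pivot_table(
            index=_FACTORS, columns="variable", values="value", observed=True
        )
        if {"aerial_mass", "root_mass"} <= set(wide.columns):
            pr = wide.apply(
                lambda r: shoot_root_ratio(
                    BiomassRecord(aerial_mass=r["aerial_mass"], root_mass=r["root_mass"])
                ),
                axis=1,
            )
            pr_df = pr.rename("value").reset_index()
            pr_df["index"] = "PR"
            pr_df["variable"] = "PR"
            parts.append(pr_df[["index", "variable", *_FACTORS, "value"]])

    if colony_table is not None:
        if cd_ep_mode not in ("per_replicate", "pooled"):
            raise ValueError(f"unknown cd_ep_mode {cd_ep_mode!r}")
        keys = ["variable", *_FACTORS] + (
            ["replicate"] if cd_ep_mode == "per_replicate" else []
        )
        rows = []
        for key, grp in colony_table.groupby(keys, sort=False, observed=True):
            daily = grp.groupby("day", observed=True)["value"].sum().reindex(
                range(1, N_DAYS + 1), fill_value=0
            )
            rec = dict(zip(keys, key))
            rows.append(
                {
                    **rec,
                    "CD": colony_development_index(daily.to_numpy()),
                    "EP": ecophysiological_diversity_index(daily.to_numpy(), base=ep_base),
                }
            )
        kin = pd.DataFrame(rows)
        kin_means = kin.groupby(["variable", *_FACTORS], sort=False, observed=True)[
            ["CD", "EP"]
        ].mean()
        for name in ("CD", "EP"):
            sub = kin_means[name].rename("value").reset_index()
            sub["index"] = name
            parts.append(sub[["index", "variable", *_FACTORS, "value"]])

    if not parts:
        raise ValueError("no input tables provided")
    report = pd.concat(parts, ignore_index=True)
    return report[["index", "variable", *_FACTORS, "value"]]
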