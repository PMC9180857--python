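"""Synthetic factorial greenhouse studies with known ground truth.

Generates complete studies with the statistical structure the downstream
analysis assumes: a full-factorial treatment design (4 contamination levels x
2 humic-acid levels x 3 cropping levels x replicates), multiplicative
treatment effects with lognormal measurement noise on enzyme activities and
plant biomass, multinomial 10-day colony-emergence series, and
Dirichlet-multinomial OTU tables with treatment-unique genera.  Because every
effect multiplier (theta) is known, parameter-recovery of the influence
factors and of the community structure is exactly testable.

Randomness: one global seed; every sub-generator derives an independent child
stream from it by name via ``numpy.random.SeedSequence.spawn``-style keying,
so adding a new simulated table never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_diversity import OtuTable
from .ecotox_indices import ENZYMES, N_DAYS

CONTAMINATION_LEVELS = ("C", "B", "Zn", "B_Zn")
AMENDMENT_LEVELS = ("none", "H")
CROP_LEVELS = ("unsown", "S", "P")

__all__ = [
    "CONTAMINATION_LEVELS",
    "AMENDMENT_LEVELS",
    "CROP_LEVELS",
    "TreatmentDesign",
    "EffectModel",
    "CommunityModel",
    "build_design",
    "simulate_enzyme_activities",
    "simulate_colony_series",
    "simulate_plant_biomass",
    "simulate_otu_table",
    "default_effect_model",
    "default_biomass_model",
    "default_community_model",
    "default_colony_profiles",
]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child PRNG stream derived deterministically from one study seed."""
    # stable across processes (unlike hash()), so runs are reproducible
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class TreatmentDesign:
    """The full-factorial layout every measurement table is keyed by."""

    units: pd.DataFrame  # unit_id, contamination, amendment, crop, replicate
    contamination_levels: tuple[str, ...] = CONTAMINATION_LEVELS
    amendment_levels: tuple[str, ...] = AMENDMENT_LEVELS
    crop_levels: tuple[str, ...] = CROP_LEVELS
    n_replicates: int = 3

    def __post_init__(self) -> None:
        expected = (
            len(self.contamination_levels)
            * len(self.amendment_levels)
            * len(self.crop_levels)
            * self.n_replicates
        )
        if len(self.units) != expected:
            raise ValueError(f"design has {len(self.units)} units, expected {expected}")
        if self.units["unit_id"].duplicated().any():
            raise ValueError("unit ids must be unique")

    def __len__(self) -> int:
        return len(self.units)


def build_design(
    n_replicates: int = 3,
    *,
    contamination_levels: Sequence[str] = CONTAMINATION_LEVELS,
    amendment_levels: Sequence[str] = AMENDMENT_LEVELS,
    crop_levels: Sequence[str] = CROP_LEVELS,
) -> TreatmentDesign:
    """Enumerate the full factorial design (deterministic)."""
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    rows = [
        {
            "unit_id": f"{c}.{a}.{p}.r{r}",
            "contamination": c,
            "amendment": a,
            "crop": p,
            "replicate": r,
        }
        for c, a, p in product(contamination_levels, amendment_levels, crop_levels)
        for r in range(1, n_replicates + 1)
    ]
    return TreatmentDesign(
        units=pd.DataFrame(rows),
        contamination_levels=tuple(contamination_levels),
        amendment_levels=tuple(amendment_levels),
        crop_levels=tuple(crop_levels),
        n_replicates=n_replicates,
    )


@dataclass
class EffectModel:
    """Multiplicative ground truth for positive-valued measurements.

    The expected value in a treatment cell is ``baseline[var] * theta(var,
    cell)``; observed values add lognormal noise exp(N(0, sigma)).  Theta is
    stored per (variable, contamination, amendment, crop); the factor-effect
    constructor builds it as a product of per-factor multipliers, in which
    case the influence factors IF_X / IF_H / IF_P recover the per-factor
    multipliers exactly in the noiseless limit.
    """

    baselines: dict[str, float]
    theta: dict[tuple[str, str, str, str], float]
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for v, b in self.baselines.items():
            if b <= 0:
                raise ValueError(f"baseline for {v} must be positive")
        for key, t in self.theta.items():
            if t <= 0:
                raise ValueError(f"theta{key} must be positive")

    @classmethod
    def from_factor_effects(
        cls,
        baselines: Mapping[str, float],
        contamination_effects: Mapping[str, Mapping[str, float]],
        amendment_effects: Mapping[str, Mapping[str, float]] | None = None,
        crop_effects: Mapping[str, Mapping[str, float]] | None = None,
        *,
        noise_sigma: float = 0.1,
        seed: int = 0,
        design_levels: tuple[Sequence[str], Sequence[str], Sequence[str]] = (
            CONTAMINATION_LEVELS,
            AMENDMENT_LEVELS,
            CROP_LEVELS,
        ),
    ) -> "EffectModel":
        """Build theta as a product of per-factor multipliers.

        Each ``*_effects[var]`` maps a factor level to its multiplier; missing
        levels (and the reference level) default to 1.
        """
        conts, amends, crops = design_levels
        theta = {}
        for var in baselines:
            ce = dict(contamination_effects.get(var, {}))
            ae = dict((amendment_effects or {}).get(var, {}))
            pe = dict((crop_effects or {}).get(var, {}))
            for c, a, p in product(conts, amends, crops):
                theta[(var, c, a, p)] = ce.get(c, 1.0) * ae.get(a, 1.0) * pe.get(p, 1.0)
        return cls(baselines=dict(baselines), theta=theta, noise_sigma=noise_sigma, seed=seed)

    def expected(self, var: str, contamination: str, amendment: str, crop: str) -> float:
        key = (var, contamination, amendment, crop)
        if key not in self.theta:
            raise KeyError(f"no theta for cell {key}")
        return self.baselines[var] * self.theta[key]


def _simulate_tidy(
    design: TreatmentDesign, model: EffectModel, variables: Sequence[str], stream: str
) -> pd.DataFrame:
    missing = [v for v in variables if v not in model.baselines]
    if missing:
        raise ValueError(f"effect model lacks baselines for: {missing}")
    rng = _stream(model.seed, stream)
    rows = []
    for _, u in design.units.iterrows():
        for var in variables:
            mu = model.expected(var, u["contamination"], u["amendment"], u["crop"])
            noise = np.exp(rng.normal(0.0, model.noise_sigma)) if model.noise_sigma > 0 else 1.0
            rows.append(
                {
                    "unit_id": u["unit_id"],
                    "contamination": u["contamination"],
                    "amendment": u["amendment"],
                    "crop": u["crop"],
                    "replicate": u["replicate"],
                    "variable": var,
                    "value": mu * noise,
                }
            )
    return pd.DataFrame(rows)


def simulate_enzyme_activities(design: TreatmentDesign, model: EffectModel) -> pd.DataFrame:
    """Tidy activities for the seven assayed enzymes, one row per unit x enzyme."""
    return _simulate_tidy(design, model, ENZYMES, "enzymes")


def simulate_plant_biomass(
    design: TreatmentDesign, model: EffectModel, *, sown_only: bool = True
) -> pd.DataFrame:
    """Aerial and root dry masses per pot (sown units only by default)."""
    tidy = _simulate_tidy(design, model, ("aerial_mass", "root_mass"), "biomass")
    if sown_only:
        tidy = tidy[tidy["crop"] != "unsown"].reset_index(drop=True)
    return tidy


def simulate_colony_series(
    design: TreatmentDesign,
    profiles: Mapping[str, Sequence[float]] | Mapping[str, Mapping[str, Sequence[float]]],
    totals: Mapping[str, float] | float,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily new-colony counts over 10 days of incubation, per microbial group.

    ``profiles[group]`` is either one emergence-probability vector (length 10,
    summing to 1) or a mapping from contamination level to such a vector;
    ``totals`` gives the plated total cfu per unit (scalar or per group).
    Counts are multinomial(total, profile), so per-series sums equal the
    configured totals exactly.
    """
    rng = _stream(seed, "colonies")
    rows = []

    def profile_for(group: str, contamination: str) -> np.ndarray:
        spec = profiles[group]
        vec = spec.get(contamination, spec.get("*")) if isinstance(spec, Mapping) else spec
        if vec is None:
            raise KeyError(f"no emergence profile for group {group!r} at {contamination!r}")
        p = np.asarray(vec, dtype=float)
        if p.shape != (N_DAYS,):
            raise ValueError(f"profile for {group!r} must have length {N_DAYS}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile for {group!r} sums to {p.sum()}, not 1")
        if (p < 0).any():
            raise ValueError(f"negative emergence probability for {group!r}")
        return p

    for group in profiles:
        total = totals[group] if isinstance(totals, Mapping) else totals
        if total < 0:
            raise ValueError("totals must be >= 0")
        for _, u in design.units.iterrows():
            p = profile_for(group, u["contamination"])
            counts = rng.multinomial(int(round(total)), p)
            for day, n in enumerate(counts, start=1):
                rows.append(
                    {
                        "unit_id": u["unit_id"],
                        "contamination": u["contamination"],
                        "amendment": u["amendment"],
                        "crop": u["crop"],
                        "replicate": u["replicate"],
                        "variable": group,
                        "day": day,
                        "value": int(n),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class CommunityModel:
    """Ground truth for Dirichlet-multinomial OTU count generation.

    ``base_proportions`` is the community composition of the uncontaminated
    reference; ``shift_multipliers[(taxon, level)]`` rescales a taxon's
    expected proportion under a contamination level (renormalized);
    ``unique_taxa[level]`` are taxa whose expected proportion is zero in every
    other level.  Sampled compositions are Dirichlet with concentration
    ``overdispersion * expected proportions``; counts are multinomial with the
    given library size.
    """

    base_proportions: pd.Series
    lineage: pd.DataFrame
    shift_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    unique_taxa: dict[str, set[str]] = field(default_factory=dict)
    library_size: int = 50_000
    overdispersion: float = 500.0

    def __post_init__(self) -> None:
        if len(self.base_proportions) == 0:
            raise ValueError("empty taxon set")
        if abs(self.base_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("base_proportions must sum to 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        levels = list(self.unique_taxa)
        for i, li in enumerate(levels):
            for lj in levels[i + 1 :]:
                clash = self.unique_taxa[li] & self.unique_taxa[lj]
                if clash:
                    raise ValueError(f"unique taxa of {li} and {lj} overlap: {clash}")

    def expected_proportions(self, level: str) -> pd.Series:
        p = self.base_proportions.copy()
        for other, taxa in self.unique_taxa.items():
            if other != level:
                p[p.index.isin(taxa)] = 0.0
        for t in p.index:
            p[t] *= self.shift_multipliers.get((t, level), 1.0)
        s = p.sum()
        if s <= 0:
            raise ValueError(f"expected composition for level {level!r} is empty")
        return p / s


def simulate_otu_table(
    design: TreatmentDesign,
    model: CommunityModel,
    seed: int = 0,
    *,
    per_unit: bool = False,
) -> OtuTable:
    """Dirichlet-multinomial OTU counts, one pooled sample per contamination
    level by default (mirroring one sequencing library per contamination
    object), or one sample per experimental unit with ``per_unit=True``."""
    rng = _stream(seed, "otu")
    if per_unit:
        sample_specs = [(u["unit_id"], u["contamination"]) for _, u in design.units.iterrows()]
    else:
        sample_specs = [(level, level) for level in design.contamination_levels]
    cols = {}
    groups = {}
    for sample, level in sample_specs:
        p = model.expected_proportions(level).to_numpy()
        alive = p > 0
        alpha = model.overdispersion * p[alive]
        draw = np.zeros_like(p)
        draw[alive] = rng.dirichlet(alpha)
        cols[sample] = rng.multinomial(model.library_size, draw)
        groups[sample] = level
    counts = pd.DataFrame(cols, index=model.base_proportions.index)
    return OtuTable(counts=counts, lineage=model.lineage.copy(), sample_groups=groups)


# ---------------------------------------------------------------------------
# Default study: the stated world the analysis is exercised on
# ---------------------------------------------------------------------------

# Qualitative pattern of the emulated study: both xenobiotics inhibit most
# enzymes, their combination most strongly; humic acid mildly stimulates
# (urease most); cropping stimulates microbial activity.
_ENZYME_CONT_EFFECTS = {"B": 0.80, "Zn": 0.55, "B_Zn": 0.40}
_ENZYME_BASELINES = {
    "deh": 8.0, "cat": 0.45, "ure": 1.2, "pac": 95.0, "pal": 70.0, "aryl": 0.25, "glu": 0.9,
}


def default_effect_model(noise_sigma: float = 0.1, seed: int = 0) -> EffectModel:
    """Enzyme-activity ground truth for the default synthetic study."""
    cont = {v: dict(_ENZYME_CONT_EFFECTS) for v in _ENZYME_BASELINES}
    amend = {v: {"H": 1.15} for v in _ENZYME_BASELINES}
    amend["ure"] = {"H": 1.40}  # urease responds most to humic acid
    crop = {v: {"S": 1.10, "P": 1.20} for v in _ENZYME_BASELINES}
    return EffectModel.from_factor_effects(
        _ENZYME_BASELINES, cont, amend, crop, noise_sigma=noise_sigma, seed=seed
    )


def default_biomass_model(noise_sigma: float = 0.1, seed: int = 0) -> EffectModel:
    """Plant dry-mass ground truth; sorghum is hit harder than switchgrass.

    Crop multipliers set the species' control masses; contamination
    multipliers set the tolerance indices (TI = 100 x theta in the noiseless
    limit)."""
    baselines = {"aerial_mass": 10.0, "root_mass": 4.0}
    cont = {
        "aerial_mass": {"B": 0.85, "Zn": 0.55, "B_Zn": 0.40},
        "root_mass": {"B": 0.90, "Zn": 0.60, "B_Zn": 0.45},
    }
    amend = {v: {"H": 1.05} for v in baselines}
    crop = {v: {"S": 1.0, "P": 0.7} for v in baselines}
    return EffectModel.from_factor_effects(
        baselines, cont, amend, crop, noise_sigma=noise_sigma, seed=seed
    )


def default_colony_profiles() -> dict[str, dict[str, np.ndarray]]:
    """10-day emergence profiles per microbial group and contamination level.

    Uncontaminated soil hosts faster-emerging (higher-CD) communities; the
    combined contamination shifts emergence late and narrows its spread.
    """
    days = np.arange(1, N_DAYS + 1, dtype=float)

    def profile(peak: float, width: float) -> np.ndarray:
        w = np.exp(-0.5 * ((days - peak) / width) ** 2)
        return w / w.sum()

    peaks = {"C": 3.0, "B": 4.0, "Zn": 5.0, "B_Zn": 6.5}
    widths = {"C": 2.5, "B": 2.2, "Zn": 2.0, "B_Zn": 1.6}
    group_lag = {"organotrophic": 0.0, "actinomycetes": 1.0, "fungi": 0.5}
    return {
        g: {lvl: profile(peaks[lvl] + lag, widths[lvl]) for lvl in CONTAMINATION_LEVELS}
        for g, lag in group_lag.items()
    }


_BASE_GENERA = [
    # (genus, class, phylum, base proportion) — dominant taxa of the emulated soils
    ("Cellulosimicrobium", "Actinobacteria", "Actinobacteriota", 0.22),
    ("Arthrobacter", "Actinobacteria", "Actinobacteriota", 0.13),
    ("Streptomyces", "Actinobacteria", "Actinobacteriota", 0.09),
    ("Sphingomonas", "Alphaproteobacteria", "Proteobacteria", 0.12),
    ("Rhodanobacter", "Gammaproteobacteria", "Proteobacteria", 0.10),
    ("Burkholderia-Caballeronia-Paraburkholderia", "Gammaproteobacteria", "Proteobacteria", 0.08),
    ("Pseudomonas", "Gammaproteobacteria", "Proteobacteria", 0.07),
    ("Flavobacterium", "Bacteroidia", "Bacteroidota", 0.04),
    ("Bacillus", "Bacilli", "Firmicutes", 0.03),
    ("Gemmatimonas", "Gemmatimonadetes", "Gemmatimonadota", 0.02),
]

_UNIQUE_GENERA = {
    # treatment-characteristic genera injected at equal expected share
    "B": ["Novosphingobium", "Luteibacter", "Sphingobium", "Chitinophaga", "Mucilagnibacter"],
    "Zn": ["Lapilicoccus", "Kribella"],
    "B_Zn": ["Serratia", "Enterobacter", "Rahnella1", "Bordetella"],
}
_UNIQUE_LINEAGE = {
    "Novosphingobium": ("Alphaproteobacteria", "Proteobacteria"),
    "Luteibacter": ("Gammaproteobacteria", "Proteobacteria"),
    "Sphingobium": ("Alphaproteobacteria", "Proteobacteria"),
    "Chitinophaga": ("Bacteroidia", "Bacteroidota"),
    "Mucilagnibacter": ("Bacteroidia", "Bacteroidota"),
    "Lapilicoccus": ("Actinobacteria", "Actinobacteriota"),
    "Kribella": ("Actinobacteria", "Actinobacteriota"),
    "Serratia": ("Gammaproteobacteria", "Proteobacteria"),
    "Enterobacter": ("Gammaproteobacteria", "Proteobacteria"),
    "Rahnella1": ("Gammaproteobacteria", "Proteobacteria"),
    "Bordetella": ("Gammaproteobacteria", "Proteobacteria"),
}


def default_community_model(
    *,
    unique_share: float = 0.05,
    library_size: int = 50_000,
    overdispersion: float = 500.0,
) -> CommunityModel:
    """Bacterial community ground truth with treatment-unique genera.

    Each injected unique genus carries ``unique_share`` (default 5 %) expected
    proportion in its own contamination level and exactly zero elsewhere; the
    dominant background mirrors an Actinobacteriota/Proteobacteria soil.  The
    library size defaults to the ~50,000 reads per sample of a MiSeq run.
    """
    n_unique = sum(len(v) for v in _UNIQUE_GENERA.values())
    base_mass = 1.0 - unique_share * n_unique
    if base_mass <= 0:
        raise ValueError("unique_share too large for the background community")
    taxa, props, lineage_rows = [], [], []
    for genus, cls, phylum, share in _BASE_GENERA:
        taxa.append(genus)
        props.append(share * base_mass)
        lineage_rows.append({"phylum": phylum, "class": cls, "genus": genus})
    for level, genera in _UNIQUE_GENERA.items():
        for genus in genera:
            cls, phylum = _UNIQUE_LINEAGE[genus]
            taxa.append(genus)
            props.append(unique_share)
            lineage_rows.append({"phylum": phylum, "class": cls, "genus": genus})
    base = pd.Series(props, index=pd.Index(taxa, name="taxon_id"))
    base /= base.sum()
    lineage = pd.DataFrame(lineage_rows, index=base.index)
    shifts = {
        # the emulated regime shifts: B favors Alphaproteobacteria, Zn and
        # B+Zn favor Cellulosimicrobium, Zn eliminates Burkholderia-group
        ("Sphingomonas", "B"): 2.0,
        ("Cellulosimicrobium", "Zn"): 2.2,
        ("Cellulosimicrobium", "B_Zn"): 2.5,
        ("Burkholderia-Caballeronia-Paraburkholderia", "Zn"): 1e-12,
        ("Burkholderia-Caballeronia-Paraburkholderia", "B_Zn"): 1.8,
        ("Rhodanobacter", "B_Zn"): 0.4,
        ("Sphingomonas", "B_Zn"): 0.4,
    }
    return CommunityModel(
        base_proportions=base,
        lineage=lineage,
        shift_multipliers=shifts,
        unique_taxa={lvl: set(genera) for lvl, genera in _UNIQUE_GENERA.items()},
        library_size=library_size,
        overdispersion=overdispersion,
    )
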