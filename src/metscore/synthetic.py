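"""Synthetic serum/urine cohorts with the correlation and effect structure
the downstream analysis assumes.

Real NMR cohorts of this kind carry three structural features the pipeline
relies on: (i) strong block correlation among lipoprotein parameters of the
same particle family, (ii) mean shifts of metabolite/lipoprotein levels
that depend on which metabolic risk factors are active, and (iii) mild
gender and age covariate effects.  The generator reproduces exactly those
features and nothing else:

* each variable belongs to one *block*; within a block, values share a
  latent Gaussian factor giving equicorrelation ``rho``;
* a sample with risk profile ``p`` has the mean of variable ``v`` shifted
  by ``effect_matrix[v, p]`` standard-deviation units (built by default
  from additive per-risk-factor loadings, so e.g. glucose rises with the
  diabetes bit in every profile that contains it);
* optional per-variable gender shifts and linear age slopes, in SD units;
* values are reported on a concentration-like scale ``baseline + value``
  (baseline 10 SD) so they are positive and log-transformable.

Profile prevalences default to the published population pattern in which
the asymptomatic profile 0000 dominates (68.5%) and the four WHO
metabolic-syndrome profiles are rare (~2% combined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import Spectrum, bin_names
from .profiles import ALL_CODES, RISK_FACTORS, RiskProfile, classify_mets

DATASET_TYPES = ("serum_metabolite", "serum_lipoprotein", "urine_bin")

#: Age-group boundaries (years), half-open except the last.
AGE_GROUP_EDGES = (18, 25, 35, 45, 55, 64, 70, 81, 105)

#: Per-profile sample counts of the reference population
#: (asymptomatic-dominated working-age cohort, n = 20,662).
_REFERENCE_COUNTS: dict[str, int] = {
    "0000": 14145, "0001": 1004, "0010": 1721, "0011": 578,
    "0100": 1182, "0101": 361, "0110": 491, "0111": 300,
    "1000": 166, "1001": 139, "1010": 86, "1011": 124,
    "1100": 79, "1101": 91, "1110": 62, "1111": 133,
}
_REFERENCE_TOTAL = sum(_REFERENCE_COUNTS.values())

#: Profile prevalences derived from the reference counts (0000 = 68.5%).
DEFAULT_PREVALENCE: dict[str, float] = {
    c: n / _REFERENCE_TOTAL for c, n in _REFERENCE_COUNTS.items()
}


def age_group_label(age: float) -> str:
    """Ordinal age-group label, e.g. ``'[35,45)'``; last group is closed."""
    for lo, hi in zip(AGE_GROUP_EDGES[:-1], AGE_GROUP_EDGES[1:]):
        if (lo <= age < hi) or (hi == AGE_GROUP_EDGES[-1] and age == hi):
            closer = "]" if hi == AGE_GROUP_EDGES[-1] else ")"
            return f"[{lo},{hi}{closer}"
    raise ValueError(f"age {age} outside the supported range "
                     f"[{AGE_GROUP_EDGES[0]}, {AGE_GROUP_EDGES[-1]}]")


@dataclass(frozen=True)
class VariableBlock:
    """A named group of variables sharing a latent factor."""

    name: str
    dataset_type: str
    members: tuple[str, ...]
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.dataset_type not in DATASET_TYPES:
            raise ValueError(f"unknown dataset type {self.dataset_type!r}")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(
                f"block {self.name!r}: within-block correlation must be in "
                f"[0, 1), got {self.correlation}"
            )
        if len(self.members) == 0:
            raise ValueError(f"block {self.name!r} has no members")


@dataclass
class CovariateEffect:
    """Per-variable covariate shifts in SD units."""

    gender: float = 0.0      # added for male samples
    age_slope: float = 0.0   # per year, centred at the cohort mean age


@dataclass
class GeneratorConfig:
    """Full description of a synthetic cohort."""

    n_samples: int
    blocks: list[VariableBlock]
    effect_matrix: pd.DataFrame              # variables x 16 profile codes, SD units
    profile_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    age_range: tuple[float, float] = (18.0, 90.0)
    age_mean: float = 44.7
    age_sd: float = 10.3
    female_fraction: float = 0.379
    noise_sd: float = 1.0
    baseline: float = 10.0                   # positivity offset, SD units
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def variables(self) -> list[str]:
        return [m for b in self.blocks for m in b.members]

    def variable_types(self) -> dict[str, str]:
        return {m: b.dataset_type for b in self.blocks for m in b.members}

    def block_of(self) -> dict[str, str]:
        return {m: b.name for b in self.blocks for m in b.members}

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        total = sum(self.profile_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"profile prevalences must sum to 1 (got {total:.12f})")
        unknown = set(self.profile_prevalence) - set(ALL_CODES)
        if unknown:
            raise ValueError(f"unknown profile codes in prevalence: {sorted(unknown)}")
        seen: set[str] = set()
        for b in self.blocks:
            dup = seen & set(b.members)
            if dup:
                raise ValueError(f"variables in more than one block: {sorted(dup)}")
            seen |= set(b.members)
        missing = set(self.effect_matrix.index) - seen
        if missing:
            raise ValueError(
                f"effect_matrix rows not present in any block: {sorted(missing)}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass
class CohortTable:
    """Samples x (metadata + typed numeric variables).

    ``data`` holds columns ``sample_id, gender, age, age_group, profile``
    followed by one numeric column per variable; ``variable_types`` maps
    every variable to serum_metabolite | serum_lipoprotein | urine_bin.
    """

    data: pd.DataFrame
    variable_types: dict[str, str]

    METADATA_COLUMNS = ("sample_id", "gender", "age", "age_group", "profile")

    def __post_init__(self) -> None:
        for col in self.METADATA_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"cohort table missing metadata column {col!r}")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        for v in self.variables:
            if v not in self.variable_types:
                raise ValueError(f"variable {v!r} has no declared type")
            t = self.variable_types[v]
            if t not in DATASET_TYPES:
                raise ValueError(f"variable {v!r} has unknown type {t!r}")
        vals = self.values
        if not np.all(np.isfinite(vals.to_numpy())):
            bad = vals.columns[~np.isfinite(vals.to_numpy()).all(axis=0)]
            raise ValueError(f"non-finite values in variables: {list(bad)[:5]}")
        bad_codes = set(self.data["profile"]) - set(ALL_CODES)
        if bad_codes:
            raise ValueError(f"invalid profile codes: {sorted(bad_codes)}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.METADATA_COLUMNS]

    def variables_of_type(self, dataset_type: str) -> list[str]:
        return [v for v in self.variables if self.variable_types[v] == dataset_type]

    @property
    def values(self) -> pd.DataFrame:
        return self.data[self.variables]

    def mets_labels(self, definition: str = "WHO") -> np.ndarray:
        return np.array(
            [classify_mets(c, definition) for c in self.data["profile"]], dtype=int)

    def factor_labels(self, factor: str) -> np.ndarray:
        idx = RISK_FACTORS.index(factor)
        return np.array([int(c[idx]) for c in self.data["profile"]])

    def subset(self, sample_ids) -> "CohortTable":
        mask = self.data["sample_id"].isin(list(sample_ids))
        return CohortTable(self.data.loc[mask].reset_index(drop=True),
                           dict(self.variable_types))


def effects_from_loadings(loadings: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a (variable x profile-code) effect matrix from additive
    per-risk-factor loadings in SD units.

    ``effect[v, code] = sum_f loadings[v][f] * bit_f(code)`` — a variable
    loaded +2 on diabetes is shifted +2 SD in every diabetes-containing
    profile, cumulating with other loaded factors.
    """
    variables = list(loadings)
    mat = np.zeros((len(variables), len(ALL_CODES)))
    for i, v in enumerate(variables):
        for f, weight in loadings[v].items():
            if f not in RISK_FACTORS:
                raise ValueError(f"unknown risk factor {f!r} for variable {v!r}")
            j = RISK_FACTORS.index(f)
            for k, code in enumerate(ALL_CODES):
                mat[i, k] += weight * int(code[j])
    return pd.DataFrame(mat, index=variables, columns=list(ALL_CODES))


# --------------------------------------------------------------------------
# Default panel: 112 lipoprotein parameters in 7 particle-family blocks,
# 41 serum metabolites (mostly singletons), optional 290 urine bins.
# --------------------------------------------------------------------------

_LIPO_COMPONENTS = ("TG", "CH", "CE", "PL", "FC")


def _default_lipoprotein_blocks(rho: float) -> list[VariableBlock]:
    def blk(name, members):
        return VariableBlock(name, "serum_lipoprotein", tuple(members), rho)

    vldl = [f"{p}-{c}" for p in ("VLDL-1", "VLDL-2", "VLDL-3", "VLDL-4",
                                 "VLDL-5", "IDL") for c in _LIPO_COMPONENTS]
    vldl += ["VLDL-ApoB", "VLDL-PN", "IDL-PN", "Total-TG"]                    # 34
    ldl13 = [f"{p}-{c}" for p in ("LDL-1", "LDL-2", "LDL-3")
             for c in _LIPO_COMPONENTS + ("ApoB",)]
    ldl13 += ["LDL-1-PN", "LDL-2-PN", "LDL-3-PN"]                             # 21
    ldl45 = [f"{p}-{c}" for p in ("LDL-4", "LDL-5")
             for c in _LIPO_COMPONENTS + ("ApoB",)]
    ldl45 += ["Total-ApoB", "Total-CH", "LDL-CH", "LDL-4-PN", "LDL-5-PN"]     # 17
    ldl6 = [f"LDL-6-{c}" for c in _LIPO_COMPONENTS + ("ApoB",)] + ["LDL-6-PN"]  # 7
    hdl_no_tg = [f"{p}-{c}" for p in ("HDL-1", "HDL-2", "HDL-3")
                 for c in ("CH", "CE", "PL", "FC", "ApoA1", "ApoA2")]
    hdl_no_tg += ["Total-ApoA1", "Total-ApoA2", "HDL-CH", "HDL-PL", "HDL-PN"]  # 23
    hdl_tg = ["HDL-1-TG", "HDL-2-TG", "HDL-3-TG", "HDL-TG"]                   # 4
    hdl4 = [f"HDL-4-{c}" for c in ("CH", "CE", "PL", "FC", "ApoA1", "ApoA2")]  # 6
    return [
        blk("VLDLs_IDLs", vldl),
        blk("LDLs_1_3", ldl13),
        blk("LDLs_4_5", ldl45),
        blk("LDLs_6", ldl6),
        blk("HDLs_1_3_noTGs", hdl_no_tg),
        blk("HDLs_1_3_TGs", hdl_tg),
        blk("HDLs_4_noTGs", hdl4),
    ]


_METABOLITE_SINGLETONS = (
    "Glucose", "Lactate", "Pyruvate", "Alanine", "Glutamine", "Glutamate",
    "Glycine", "Histidine", "Phenylalanine", "Tyrosine", "Proline",
    "Sarcosine", "Creatinine", "Creatine", "Citrate", "Acetate", "Formate",
    "Methanol", "Ethanol", "TMAO", "Dimethylglycine", "Dimethylsulfone",
    "Betaine", "Choline", "Ornithine", "Lysine", "Threonine", "Methionine",
    "Asparagine", "Aspartate", "2-Aminobutyrate", "2-Oxoglutarate",
    "Succinate", "Ca-EDTA", "K-EDTA",
)
_BCAA = ("Valine", "Leucine", "Isoleucine")
_KETONES = ("Acetone", "Acetoacetate", "3-Hydroxybutyrate")


def _default_metabolite_blocks(rho: float) -> list[VariableBlock]:
    blocks = [
        VariableBlock("BCAAs", "serum_metabolite", _BCAA, rho),
        VariableBlock("Ketone_bodies", "serum_metabolite", _KETONES, rho),
    ]
    blocks += [VariableBlock(m, "serum_metabolite", (m,), 0.0)
               for m in _METABOLITE_SINGLETONS]
    return blocks


#: Per-risk-factor effect loadings (SD units) applied to whole blocks or
#: single metabolites; directions follow the serum pattern in which
#: dyslipidemia raises VLDL/IDL, dense LDL and TG-rich HDL while lowering
#: light HDL/LDL, and diabetes is dominated by glucose.
DEFAULT_BLOCK_LOADINGS: dict[str, dict[str, float]] = {
    "VLDLs_IDLs": {"dyslipidemia": 1.0, "diabetes": 0.2},
    "LDLs_4_5": {"dyslipidemia": 0.9},
    "HDLs_1_3_TGs": {"dyslipidemia": 0.7},
    "LDLs_6": {"dyslipidemia": 0.6},
    "HDLs_1_3_noTGs": {"dyslipidemia": -0.8},
    "LDLs_1_3": {"dyslipidemia": -0.5},
    "HDLs_4_noTGs": {"dyslipidemia": -0.4, "obesity": -0.2},
    "BCAAs": {"obesity": 0.5, "diabetes": 0.3},
    "Ketone_bodies": {"diabetes": 0.6},
    "Glucose": {"diabetes": 2.0},
    "Alanine": {"diabetes": 0.7, "obesity": 0.3},
    "Lactate": {"obesity": 0.4},
    "Proline": {"obesity": 0.5, "hypertension": 0.4},
    "Phenylalanine": {"obesity": 0.4, "hypertension": 0.4},
    "Sarcosine": {"dyslipidemia": 0.6},
    "Tyrosine": {"obesity": 0.3},
    "Creatinine": {"hypertension": 0.3},
}

DEFAULT_COVARIATE_EFFECTS: dict[str, CovariateEffect] = {
    "VLDLs_IDLs": CovariateEffect(gender=0.3, age_slope=0.015),
    "LDLs_4_5": CovariateEffect(age_slope=0.015),
    "HDLs_1_3_noTGs": CovariateEffect(gender=-0.3),
    "Creatinine": CovariateEffect(gender=0.4),
}

_N_URINE_BLOCKS = 15
#: Urine-bin block loadings keyed by block index (0-based, contiguous split
#: of the 290 bins); chosen so urine mirrors the diabetes-heavy serum signal.
DEFAULT_URINE_BLOCK_LOADINGS: dict[int, dict[str, float]] = {
    6: {"diabetes": 1.5},          # sugar region bins
    4: {"dyslipidemia": -0.4},
    9: {"hypertension": 0.4},
    11: {"obesity": 0.3},
}


def _default_urine_blocks(rho: float) -> list[VariableBlock]:
    names = bin_names()
    cuts = np.array_split(np.arange(len(names)), _N_URINE_BLOCKS)
    return [
        VariableBlock(f"urine_block_{i:02d}", "urine_bin",
                      tuple(names[j] for j in idx), rho)
        for i, idx in enumerate(cuts)
    ]


def default_config(
    n_samples: int = 2000,
    seed: int = 0,
    block_correlation: float = 0.9,
    include_urine: bool = False,
    effect_scale: float = 1.0,
) -> GeneratorConfig:
    """The package's reference cohort configuration.

    ~153 serum variables (112 lipoprotein parameters in 7 correlated
    blocks + 41 metabolites) with the default loadings; optionally 290
    urine bins in 15 correlated blocks.  ``effect_scale`` multiplies every
    loading (0 gives a global-null cohort).
    """
    blocks = (_default_lipoprotein_blocks(block_correlation)
              + _default_metabolite_blocks(block_correlation))
    loadings: dict[str, dict[str, float]] = {}
    covars: dict[str, CovariateEffect] = {}
    block_map = {b.name: b for b in blocks}
    for target, load in DEFAULT_BLOCK_LOADINGS.items():
        members = block_map[target].members if target in block_map else (target,)
        for m in members:
            loadings[m] = {f: w * effect_scale for f, w in load.items()}
    for target, eff in DEFAULT_COVARIATE_EFFECTS.items():
        members = block_map[target].members if target in block_map else (target,)
        for m in members:
            covars[m] = CovariateEffect(eff.gender, eff.age_slope)
    if include_urine:
        ublocks = _default_urine_blocks(block_correlation)
        blocks = blocks + ublocks
        for i, load in DEFAULT_URINE_BLOCK_LOADINGS.items():
            for m in ublocks[i].members:
                loadings[m] = {f: w * effect_scale for f, w in load.items()}
    all_vars = [m for b in blocks for m in b.members]
    effect = effects_from_loadings(loadings).reindex(all_vars, fill_value=0.0)
    return GeneratorConfig(
        n_samples=n_samples,
        blocks=blocks,
        effect_matrix=effect,
        covariate_effects=covars,
        seed=seed,
    )


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort from the configured generative model (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    codes = list(config.profile_prevalence)
    probs = np.array([config.profile_prevalence[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    profile = rng.choice(codes, size=n, p=probs)

    gender = np.where(rng.random(n) < config.female_fraction, "female", "male")
    lo, hi = config.age_range
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), lo, hi)
    age = np.round(age, 1)
    age_centered = age - config.age_mean

    code_index = {c: k for k, c in enumerate(config.effect_matrix.columns)}
    profile_idx = np.array([code_index[c] for c in profile])
    is_male = (gender == "male").astype(float)

    columns: dict[str, np.ndarray] = {}
    for block in config.blocks:
        latent = rng.standard_normal(n)
        r = block.correlation
        for m in block.members:
            eps = rng.standard_normal(n)
            g = np.sqrt(r) * latent + np.sqrt(1.0 - r) * eps
            shift = config.effect_matrix.loc[m].to_numpy()[profile_idx]
            cov = config.covariate_effects.get(m)
            if cov is not None:
                g = g + cov.gender * is_male + cov.age_slope * age_centered
            columns[m] = (config.baseline + g + shift) * config.noise_sd

    meta = pd.DataFrame({
        "sample_id": [f"S{i:06d}" for i in range(n)],
        "gender": gender,
        "age": age,
        "age_group": [age_group_label(a) for a in age],
        "profile": profile,
    })
    values = pd.DataFrame({m: columns[m] for m in config.variables})
    return CohortTable(pd.concat([meta, values], axis=1), config.variable_types())


def generate_urine_spectrum(
    peaks: list[tuple[float, float, float]],
    axis: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Sum-of-Gaussians urine spectrum on a ppm grid, clipped at zero.

    ``peaks`` are (center ppm, width sigma, amplitude) triples; the peak
    contributes ``amplitude * exp(-(ppm-center)^2 / (2 width^2))`` per
    grid point.  Additive Gaussian noise with SD ``noise_sd``.
    """
    ppm = np.asarray(axis, dtype=float)
    if ppm.size == 0:
        raise ValueError("empty ppm axis")
    d = np.diff(ppm)
    if ppm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("ppm grid must be strictly monotone")
    intensity = np.zeros_like(ppm)
    for center, width, amplitude in peaks:
        if width <= 0:
            raise ValueError(f"peak width must be positive, got {width}")
        intensity += amplitude * np.exp(-((ppm - center) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        intensity += np.random.default_rng(seed).normal(0.0, noise_sd, ppm.size)
    return Spectrum(ppm, np.clip(intensity, 0.0, None))


def cohort_summary(cohort: CohortTable) -> pd.DataFrame:
    """Counts and percentages per gender, age group, profile and WHO status."""
    n = cohort.n_samples
    rows = []

    def add_block(block: str, counts: dict) -> None:
        for level, count in counts.items():
            rows.append({"block": block, "level": str(level),
                         "count": int(count), "percent": 100.0 * count / n})

    add_block("gender", cohort.data["gender"].value_counts().to_dict())
    groups = [f"[{lo},{hi}{']' if hi == AGE_GROUP_EDGES[-1] else ')'}"
              for lo, hi in zip(AGE_GROUP_EDGES[:-1], AGE_GROUP_EDGES[1:])]
    age_counts = cohort.data["age_group"].value_counts()
    add_block("age_group", {g: int(age_counts.get(g, 0)) for g in groups})
    prof_counts = cohort.data["profile"].value_counts()
    add_block("profile", {c: int(prof_counts.get(c, 0)) for c in ALL_CODES})
    who = cohort.mets_labels("WHO")
    add_block("mets_who", {"no": int((who == 0).sum()), "yes": int(who.sum())})
    return pd.DataFrame(rows)
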