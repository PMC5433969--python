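"""Calibrated synthetic strandings, cortisol, and assay-plate generator.

The generator emulates the statistical structure the analyses assume, with
defaults calibrated to the study system's published summary values:

* age-class-structured lengths with allometric mass
  ``mass = delta + alpha * length**beta`` (beta near 2.33) times a
  cause-of-death-dependent condition factor calibrated so the acute and
  chronic groups hit their target mean mass/length^2;
* a site/layer/sex/age/condition-structured blubber cortisol field,
  gamma-distributed on the response scale with a per-individual
  log-normal random intercept, calibrated to target stratum means;
* ELISA plates: a 4PL standard curve plus duplicate sample wells whose
  effective-concentration noise is calibrated so the measured mean
  intra-assay CV matches the target.

Same seed and config give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fourpl import FourPLParams, fourpl_response
from .records import MorphRecord, assign_season

__all__ = [
    "AllometryConfig",
    "ConditionConfig",
    "MorphometricsConfig",
    "CortisolConfig",
    "AssayConfig",
    "SynthConfig",
    "ConfigError",
    "generate_morphometrics",
    "generate_cortisol",
    "generate_assay_plate",
    "plates_for_samples",
    "CORTISOL_CSV_COLUMNS",
]

# mean of the sample standard deviation of n i.i.d. normals is c4(n) * sigma;
# used to calibrate duplicate noise so the *measured* mean pair CV hits the
# target rather than the underlying sigma
_C4_2 = math.sqrt(2.0 / math.pi)


class ConfigError(ValueError):
    """Synthetic-data configuration is infeasible or inconsistent."""


@dataclass
class AllometryConfig:
    """mass = delta + alpha * length**beta, in kg and cm."""

    delta: float = -3.17
    alpha: float = 0.0004
    beta: float = 2.33


@dataclass
class ConditionConfig:
    """Cause-of-death structure of condition (mass/length^2, kg/cm^2).

    ``mode='calibrated'`` rescales the allometric baseline per COD group so
    the group mean mass/length^2 equals the target; ``mode='none'`` leaves
    every condition factor at 1 (pure allometry plus noise).
    """

    mode: str = "calibrated"
    acute_mean_quetelet: float = 0.0022
    chronic_mean_quetelet: float = 0.0018
    # target *total* within-group SDs of mass/length^2; the generator adds
    # only enough individual condition noise to top up the structural
    # cross-age spread to these values
    acute_sd_quetelet: float = 0.00035
    chronic_sd_quetelet: float = 0.00050
    #: P(acute | age class)
    acute_prop: dict = field(
        default_factory=lambda: {"calf": 0.25, "juvenile": 0.478, "adult": 0.491}
    )
    #: multiplicative log-scale shift of condition in the breeding season
    season_effect: float = 0.0


@dataclass
class MorphometricsConfig:
    n_animals: int = 291
    #: stranding age-class mix
    age_mix: dict = field(
        default_factory=lambda: {"calf": 0.10, "juvenile": 0.45, "adult": 0.45}
    )
    # length distributions per age class (cm): truncated normals for calves
    # and adults around published cutoffs, uniform across the juvenile band
    calf_length_mean: float = 75.0
    calf_length_sd: float = 8.0
    calf_length_range: tuple = (60.0, 90.0)
    juvenile_length_range: tuple = (90.0, 135.0)
    adult_length_mean: float = 145.0
    adult_length_sd: float = 8.0
    adult_length_range: tuple = (135.0, 175.0)
    #: residual log-normal mass noise sd ("additive" uses kg instead)
    mass_noise_sd: float = 0.05
    mass_noise_mode: str = "lognormal"  # lognormal | additive | none
    #: girth ~ girth_factor * length * condition**girth_condition_exp
    girth_factor: float = 0.55
    girth_condition_exp: float = 0.5
    girth_noise_sd: float = 0.03
    #: blubber depth (mm) ~ factor * length * condition, per site
    blubber_factors: dict = field(
        default_factory=lambda: {"dorsal": 0.095, "lateral": 0.100, "ventral": 0.105}
    )
    blubber_condition_exp: float = 1.0
    blubber_noise_sd: float = 0.10
    proportion_female: float = 0.0  # condition analyses use males only
    year_range: tuple = (2006, 2015)


@dataclass
class CortisolConfig:
    """Blubber cortisol field, ng/g, calibrated to target stratum means."""

    #: full-depth marginal means per body site
    site_means: dict = field(
        default_factory=lambda: {"dorsal": 69.09, "lateral": 90.48, "ventral": 83.22}
    )
    #: target across-site layer means; multipliers are derived relative to
    #: the mean of the site means, with the full-depth multiplier fixed at 1
    layer_mean_targets: dict = field(
        default_factory=lambda: {
            "outer": 77.84,
            "full": 88.65,
            "middle": 156.28,
            "inner": 180.02,
        }
    )
    #: outer-dorsal marginal means per sex
    sex_means_outer_dorsal: dict = field(
        default_factory=lambda: {"female": 111.37, "male": 66.77}
    )
    #: log-scale juvenile-vs-adult shift (juveniles run higher)
    age_effect_log: float = 0.45
    #: log-scale slope on mass/length^2 (negative: better condition, less cortisol)
    condition_slope_log: float = -250.0
    #: per-individual random-intercept SD on the log scale
    sigma_individual: float = 0.4
    #: gamma shape (response-scale skew); inf means no gamma noise
    gamma_shape: float = 2.5
    #: shape for the one-sample-per-animal covariate design, where most
    #: dispersion is between individuals; calibrated so the total CV of the
    #: outer-dorsal sex groups approximates their reported SDs (~0.5)
    covariate_gamma_shape: float = 15.0
    #: optional additive progesterone cross-reactivity bias for females, ng/g
    progesterone_bias_female: float = 0.0
    proportion_female: float = 0.45
    proportion_juvenile: float = 0.35
    proportion_acute: float = 0.65


@dataclass
class AssayConfig:
    """ELISA plate simulator: 4PL curve and noise calibration targets."""

    a: float = 2.0
    d: float = 0.1
    c: float = 100.0
    b: float = 1.2
    standards_ngml: tuple = (0.0, 2.5, 10.0, 30.0, 100.0, 300.0, 800.0)
    #: target *measured* mean intra-assay duplicate CV, percent
    intra_cv_target: float = 5.65
    #: target *measured* mean inter-assay CV of controls across plates, percent
    inter_cv_target: float = 10.84
    tissue_mass_range: tuple = (0.1, 0.2)
    resuspension_volume_ml: float = 0.5
    #: extraction efficiency rises to a plateau over 0.15-0.2 g, then falls
    efficiency_max: float = 0.85
    efficiency_plateau: tuple = (0.15, 0.20)
    efficiency_rise_exp: float = 0.4
    efficiency_fall_exp: float = 0.6

    @property
    def fourpl(self) -> FourPLParams:
        return FourPLParams(a=self.a, d=self.d, c=self.c, b=self.b)

    @property
    def duplicate_log_sd(self) -> float:
        """Log-sd of per-well concentration noise hitting the intra target.

        The mean CV of duplicate pairs underestimates the underlying sigma
        by the normal-order factor c4(2) = sqrt(2/pi), so the generator
        inflates sigma accordingly.
        """
        return (self.intra_cv_target / 100.0) / _C4_2

    @property
    def plate_log_sd(self) -> float:
        """Plate-level log shift sd implied by the inter-assay target."""
        target = self.inter_cv_target / 100.0
        dup_var = self.duplicate_log_sd**2 / 2.0  # duplicate means per plate
        return math.sqrt(max(target**2 - dup_var, 0.0))

    def efficiency(self, mass_g) -> np.ndarray:
        m = np.asarray(mass_g, dtype=float)
        lo, hi = self.efficiency_plateau
        e = np.where(
            m < lo,
            self.efficiency_max * (m / lo) ** self.efficiency_rise_exp,
            np.where(
                m > hi,
                self.efficiency_max * (hi / m) ** self.efficiency_fall_exp,
                self.efficiency_max,
            ),
        )
        return np.clip(e, 1e-6, 1.0)


@dataclass
class SynthConfig:
    """Full parameterization of the generative model, with seed."""

    seed: int = 1
    allometry: AllometryConfig = field(default_factory=AllometryConfig)
    condition: ConditionConfig = field(default_factory=ConditionConfig)
    morphometrics: MorphometricsConfig = field(default_factory=MorphometricsConfig)
    cortisol: CortisolConfig = field(default_factory=CortisolConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)

    def validate(self) -> None:
        mix = self.morphometrics.age_mix
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ConfigError(f"age_mix must sum to 1, got {mix}")
        for k, v in self.condition.acute_prop.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"acute_prop[{k}]={v} outside [0, 1]")
        for name, v in [
            ("site_means", self.cortisol.site_means),
            ("layer_mean_targets", self.cortisol.layer_mean_targets),
            ("sex_means_outer_dorsal", self.cortisol.sex_means_outer_dorsal),
        ]:
            if any(x <= 0 for x in v.values()):
                raise ConfigError(f"cortisol {name} must be positive, got {v}")
        lo_c, hi_c = self.morphometrics.calf_length_range
        lo_j, hi_j = self.morphometrics.juvenile_length_range
        if not (lo_c < hi_c <= lo_j < hi_j <= self.morphometrics.adult_length_range[0]):
            raise ConfigError("length ranges must be ordered calf < juvenile < adult")
        alo = self.allometry
        m_min = alo.delta + alo.alpha * lo_c**alo.beta
        if m_min <= 0:
            raise ConfigError(
                f"implied mass at the smallest calf length {lo_c} cm is "
                f"{m_min:.3f} kg <= 0; adjust allometry or length ranges"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            return klass(**kwargs)

        cfg = cls(
            seed=int(d.get("seed", 1)),
            allometry=build(AllometryConfig, d.get("allometry", {})),
            condition=build(ConditionConfig, d.get("condition", {})),
            morphometrics=build(MorphometricsConfig, d.get("morphometrics", {})),
            cortisol=build(CortisolConfig, d.get("cortisol", {})),
            assay=build(AssayConfig, d.get("assay", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# morphometrics


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _lognormal_mean1(rng, cv: float, size: int) -> np.ndarray:
    """Log-normal multiplier with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-0.5 * s2, math.sqrt(s2), size=size)


def generate_morphometrics(
    config: SynthConfig, seed: int | None = None
) -> list[MorphRecord]:
    """Draw a synthetic strandings morphometrics dataset.

    Lengths are drawn per age class; baseline mass follows the configured
    power law; a condition multiplier per cause-of-death class is
    calibrated in-sample so each group's mean mass/length^2 matches its
    target; girth and blubber depths scale with length and condition.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mc, al, cc = config.morphometrics, config.allometry, config.condition
    n = mc.n_animals

    ages = rng.choice(
        list(mc.age_mix), size=n, p=np.array(list(mc.age_mix.values()), dtype=float)
    )
    length = np.empty(n)
    for cls_name in ("calf", "juvenile", "adult"):
        idx = ages == cls_name
        k = int(idx.sum())
        if k == 0:
            continue
        if cls_name == "calf":
            length[idx] = _truncated_normal(
                rng, mc.calf_length_mean, mc.calf_length_sd, *mc.calf_length_range, k
            )
        elif cls_name == "juvenile":
            length[idx] = rng.uniform(*mc.juvenile_length_range, size=k)
        else:
            length[idx] = _truncated_normal(
                rng, mc.adult_length_mean, mc.adult_length_sd, *mc.adult_length_range, k
            )

    p_acute = np.array([cc.acute_prop[a] for a in ages])
    cod = np.where(rng.random(n) < p_acute, "acute", "chronic")

    years = rng.integers(mc.year_range[0], mc.year_range[1] + 1, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    dates = [_dt.date(int(y), int(m), int(d)) for y, m, d in zip(years, months, days)]
    season = np.array([assign_season(d) for d in dates])

    m0 = al.delta + al.alpha * length**al.beta
    if np.any(m0 <= 0):
        raise ConfigError("allometric baseline mass non-positive for drawn lengths")
    q0 = m0 / length**2

    cond = np.ones(n)
    if cc.mode == "calibrated":
        for group, target, target_sd in (
            ("acute", cc.acute_mean_quetelet, cc.acute_sd_quetelet),
            ("chronic", cc.chronic_mean_quetelet, cc.chronic_sd_quetelet),
        ):
            idx = cod == group
            if not idx.any():
                continue
            base = target / q0[idx].mean()
            # structural spread already present from the cross-age length mix
            structural_sd = float(np.std(base * q0[idx]))
            noise_var = max(target_sd**2 - structural_sd**2, 0.0)
            cv = math.sqrt(noise_var) / target
            cond[idx] = base * _lognormal_mean1(rng, cv, int(idx.sum()))
    elif cc.mode != "none":
        raise ConfigError(f"unknown condition mode {cc.mode!r}")
    if cc.season_effect:
        cond = cond * np.where(season == "breeding", math.exp(cc.season_effect), 1.0)

    mass = m0 * cond
    if mc.mass_noise_mode == "lognormal" and mc.mass_noise_sd > 0:
        mass = mass * rng.lognormal(0.0, mc.mass_noise_sd, size=n)
    elif mc.mass_noise_mode == "additive" and mc.mass_noise_sd > 0:
        mass = mass + rng.normal(0.0, mc.mass_noise_sd, size=n)
        mass = np.maximum(mass, 0.05 * m0)
    elif mc.mass_noise_mode not in ("lognormal", "additive", "none"):
        raise ConfigError(f"unknown mass_noise_mode {mc.mass_noise_mode!r}")

    girth = (
        mc.girth_factor
        * length
        * cond**mc.girth_condition_exp
        * rng.lognormal(0.0, mc.girth_noise_sd, size=n)
    )
    blubber = {
        site: factor
        * length
        * cond**mc.blubber_condition_exp
        * rng.lognormal(0.0, mc.blubber_noise_sd, size=n)
        for site, factor in mc.blubber_factors.items()
    }
    sex = np.where(rng.random(n) < mc.proportion_female, "female", "male")

    records = []
    for i in range(n):
        records.append(
            MorphRecord(
                id=f"S{i:05d}",
                sex=str(sex[i]),
                date=dates[i],
                cod_class=str(cod[i]),
                mass=float(mass[i]),
                length=float(length[i]),
                girth=float(girth[i]),
                blubber_dorsal=float(blubber["dorsal"][i]),
                blubber_lateral=float(blubber["lateral"][i]),
                blubber_ventral=float(blubber["ventral"][i]),
                age_class=str(ages[i]),
                season=str(season[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# cortisol field

CORTISOL_CSV_COLUMNS = [
    "individual_id",
    "sex",
    "age_class",
    "cod_class",
    "quetelet",
    "site",
    "layer",
    "tissue_mass_g",
    "efficiency",
    "concentration_ngg",
]

_DESIGNS = {
    "site_full": [("dorsal", "full"), ("lateral", "full"), ("ventral", "full")],
    "site_layer": [
        (site, layer)
        for site in ("dorsal", "lateral", "ventral")
        for layer in ("full", "outer", "middle", "inner")
    ],
    "covariate": [("dorsal", "outer")],
}


def _draw_individuals(rng, cfg: CortisolConfig, n: int, prefix: str = "C") -> pd.DataFrame:
    sex = np.where(rng.random(n) < cfg.proportion_female, "female", "male")
    age = np.where(rng.random(n) < cfg.proportion_juvenile, "juvenile", "adult")
    cod = np.where(rng.random(n) < cfg.proportion_acute, "acute", "chronic")
    q = np.where(
        cod == "acute",
        rng.normal(0.0022, 0.00035, size=n),
        rng.normal(0.0018, 0.00050, size=n),
    )
    q = np.clip(q, 5e-4, None)
    u = rng.normal(0.0, cfg.sigma_individual, size=n)
    return pd.DataFrame(
        {
            "individual_id": [f"{prefix}{i:05d}" for i in range(n)],
            "sex": sex,
            "age_class": age,
            "cod_class": cod,
            "quetelet": q,
            "_u": u,
        }
    )


def _gamma_draw(rng, mu: np.ndarray, shape: float) -> np.ndarray:
    if not np.isfinite(shape):
        return mu.copy()
    return rng.gamma(shape, mu / shape)


def generate_cortisol(
    config: SynthConfig,
    design: str = "site_full",
    n_individuals: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a stratified blubber-cortisol dataset (ng/g).

    ``design`` selects the sampling layout: ``site_full`` (three full-depth
    sites per individual), ``site_layer`` (three sites x four layers), or
    ``covariate`` (one outer-dorsal sample per individual, with the sex/age
    /condition structure of the covariate analysis).

    Log-scale structure: stratum baseline + age shift + condition slope +
    individual random intercept, recentred within each calibration stratum
    (site/layer, or sex for the covariate design) so stratum means equal
    their configured targets in expectation; gamma noise on the response
    scale preserves those means exactly.
    """
    config.validate()
    if design not in _DESIGNS:
        raise ConfigError(f"unknown design {design!r}; choose from {sorted(_DESIGNS)}")
    cfg = config.cortisol
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if n_individuals is None:
        n_individuals = {"site_full": 20, "site_layer": 6, "covariate": 20}[design]
    prefix = {"site_full": "F", "site_layer": "L", "covariate": "D"}[design]
    ind = _draw_individuals(rng, cfg, n_individuals, prefix=prefix)

    site_means = cfg.site_means
    mean_site = float(np.mean(list(site_means.values())))
    layer_mult = {
        layer: (1.0 if layer == "full" else target / mean_site)
        for layer, target in cfg.layer_mean_targets.items()
    }

    rows = []
    for site, layer in _DESIGNS[design]:
        if design == "covariate":
            base = np.log(
                np.array([cfg.sex_means_outer_dorsal[s] for s in ind["sex"]])
            )
            strata = ind["sex"].to_numpy()
        else:
            base = np.full(len(ind), math.log(site_means[site] * layer_mult[layer]))
            strata = np.full(len(ind), "all")
        dev = (
            cfg.age_effect_log * (ind["age_class"] == "juvenile").to_numpy(float)
            + cfg.condition_slope_log
            * (ind["quetelet"] - ind["quetelet"].mean()).to_numpy()
            + ind["_u"].to_numpy()
        )
        # recentre deviations within each calibration stratum so the
        # stratum mean on the response scale stays on target
        dev_centred = dev.copy()
        for s in np.unique(strata):
            m = strata == s
            dev_centred[m] = dev[m] - math.log(np.mean(np.exp(dev[m])))
        mu = np.exp(base + dev_centred)
        shape = cfg.covariate_gamma_shape if design == "covariate" else cfg.gamma_shape
        y = _gamma_draw(rng, mu, shape)
        if cfg.progesterone_bias_female:
            y = y + np.where(ind["sex"] == "female", cfg.progesterone_bias_female, 0.0)
        mass = rng.uniform(*config.assay.tissue_mass_range, size=len(ind))
        eff = config.assay.efficiency(mass)
        for j in range(len(ind)):
            rows.append(
                {
                    "individual_id": ind["individual_id"][j],
                    "sex": ind["sex"][j],
                    "age_class": ind["age_class"][j],
                    "cod_class": ind["cod_class"][j],
                    "quetelet": float(ind["quetelet"][j]),
                    "site": site,
                    "layer": layer,
                    "tissue_mass_g": float(mass[j]),
                    "efficiency": float(eff[j]),
                    "concentration_ngg": float(y[j]),
                }
            )
    return pd.DataFrame(rows, columns=CORTISOL_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# assay plates


def generate_assay_plate(
    config: SynthConfig,
    true_concentrations_ngml: dict[str, float],
    seed: int | None = None,
    controls_ngml: dict[str, float] | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Simulate one ELISA plate as interchange CSV rows.

    Standards are noise-free nominal points on the 4PL curve; each sample
    and control is read in duplicate with multiplicative effective-
    concentration noise calibrated to the intra-assay CV target, plus a
    plate-level shift (samples/controls only) giving the inter-assay CV.
    With ``noise=False`` the quantification chain returns the true
    concentrations exactly.
    """
    config.validate()
    ac = config.assay
    params = ac.fourpl
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma_dup = ac.duplicate_log_sd if noise else 0.0
    sigma_plate = ac.plate_log_sd if noise else 0.0
    plate_shift = math.exp(rng.normal(0.0, sigma_plate)) if sigma_plate > 0 else 1.0

    rows = []
    well = 1
    for conc in ac.standards_ngml:
        rows.append(
            {
                "well": f"W{well:03d}",
                "sample_id": f"STD_{conc:g}",
                "role": "standard",
                "concentration_ngml": conc,
                "response": float(fourpl_response(conc, params)),
            }
        )
        well += 1

    def add_duplicates(sid: str, role: str, x: float):
        nonlocal well
        for _ in range(2):
            x_eff = x * plate_shift * (
                math.exp(rng.normal(0.0, sigma_dup)) if sigma_dup > 0 else 1.0
            )
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "sample_id": sid,
                    "role": role,
                    "concentration_ngml": np.nan,
                    "response": float(fourpl_response(x_eff, params)),
                }
            )
            well += 1

    for sid, x in true_concentrations_ngml.items():
        add_duplicates(sid, "sample", float(x))
    for sid, x in (controls_ngml or {}).items():
        add_duplicates(sid, "control", float(x))
    return pd.DataFrame(
        rows, columns=["well", "sample_id", "role", "concentration_ngml", "response"]
    )


def plates_for_samples(
    config: SynthConfig,
    samples: pd.DataFrame,
    per_plate: int = 20,
    seed: int | None = None,
    controls_ngml: dict[str, float] | None = None,
    noise: bool = True,
) -> list[pd.DataFrame]:
    """Split a cortisol sample table into simulated plates.

    Each sample's true extract concentration (ng/ml) is derived from its
    true tissue concentration, subsample mass, efficiency, and the
    resuspension volume; the same controls are placed on every plate.
    """
    base_seed = config.seed if seed is None else seed
    plates = []
    samples = samples.reset_index(drop=True)
    sample_key = samples["individual_id"].astype(str) + ":" + samples["site"] + ":" + samples["layer"]
    conc_ngml = (
        samples["concentration_ngg"]
        * samples["tissue_mass_g"]
        * samples["efficiency"]
        / config.assay.resuspension_volume_ml
    )
    for start in range(0, len(samples), per_plate):
        chunk = dict(
            zip(sample_key[start : start + per_plate], conc_ngml[start : start + per_plate])
        )
        plates.append(
            generate_assay_plate(
                config,
                chunk,
                seed=base_seed + 7919 * (start // per_plate + 1),
                controls_ngml=controls_ngml,
                noise=noise,
            )
        )
    return plates
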