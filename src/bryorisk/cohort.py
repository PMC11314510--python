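"""Synthetic moss cohorts with the dependence structure the analysis assumes.

The generator emulates the study cohort: ~723 species with ~22% threatened
prevalence, monoicous/dioicous plant sex, vegetative reproduction and
sporophyte presence drawn *conditionally on sex* (dioicous species more
likely to show both), right-skewed log-normal lengths, seta shape driven by
log seta length, and a block of sporophyte-morphology traits missing for a
configurable fraction of species.  Threat status is Bernoulli with a logit
linear in the published risk-model predictors, so every downstream stage
(screening, stepwise selection, cutoffs, triage) can be tested for parameter
and decision recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .registry import CANONICAL_TRAITS, SPOROPHYTE_MORPHOLOGY_TRAITS
from .trait_matrix import ScalingParams, TraitMatrix

#: Sample moments of the real cohort's key continuous traits (natural scale)
#: used to parameterise the log-normal draws: seta length 14 ± 13.32 mm,
#: substrate breadth 1.69 ± 0.94 substrates.
SETA_SCALING = ScalingParams(mean=14.0, sd=13.32)
BREADTH_SCALING = ScalingParams(mean=1.69, sd=0.94)


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (location, scale) of a log-normal with given natural moments."""
    if mean <= 0 or sd <= 0:
        raise ValueError("moments must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def conditional_rates_from_odds(
    marginal: float, prevalence: float, odds_ratio: float
) -> tuple[float, float]:
    """Solve the 2×2 margin problem in closed form.

    Given a trait's marginal presence rate, the prevalence of group B (e.g.
    monoicous), and the odds ratio of presence in group A (dioicous) relative
    to B, return ``(rate_A, rate_B)``.  The constraint reduces to a quadratic
    in ``rate_B`` with exactly one root in (0, 1).
    """
    m, pi, psi = marginal, prevalence, odds_ratio
    if not (0 < m < 1 and 0 <= pi < 1 and psi > 0):
        raise ValueError("need marginal in (0,1), prevalence in [0,1), odds > 0")
    if psi == 1.0:
        return m, m
    # pi*(psi-1)*x^2 + [(1-pi)*psi + pi - m*(psi-1)]*x - m = 0, x = rate_B
    a = pi * (psi - 1.0)
    b = (1.0 - pi) * psi + pi - m * (psi - 1.0)
    c = -m
    if a == 0.0:
        x = -c / b
    else:
        disc = math.sqrt(b * b - 4.0 * a * c)
        roots = [(-b + disc) / (2 * a), (-b - disc) / (2 * a)]
        valid = [r for r in roots if 0.0 < r < 1.0]
        x = valid[0]
    rate_b = x
    odds_a = psi * rate_b / (1.0 - rate_b)
    rate_a = odds_a / (1.0 + odds_a)
    return rate_a, rate_b


def _default_continuous_params() -> dict[str, tuple[float, float]]:
    return {
        "Seta length": lognormal_params_from_moments(SETA_SCALING.mean, SETA_SCALING.sd),
        "Capsule length": lognormal_params_from_moments(2.5, 1.5),
        "Stem length": lognormal_params_from_moments(20.0, 25.0),
        "Leaf length": lognormal_params_from_moments(2.0, 1.0),
        "Spore diameter": lognormal_params_from_moments(15.0, 8.0),
    }


def _default_coefficients() -> dict[str, float]:
    # Published minimum-adequate-model estimates, per level (binary) or per
    # SD of the real cohort (continuous).
    return {
        "Plant sex": 0.54,           # monoicous vs dioicous
        "Sporophyte presence": -1.18,
        "Substrate breadth": -0.83,  # per SD (0.94) around mean 1.69
        "Seta length": -0.61,        # per SD (13.32) around mean 14
    }


def _default_dependence_odds() -> dict[str, float]:
    # Odds of the trait for dioicous relative to monoicous species; the
    # seta entry is the odds of a curved seta per log-mm of seta length.
    return {
        "sex_vegetative": 2.0,
        "sex_sporophyte": 2.0,
        "setalength_setashape": 2.0,
    }


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the study conditions: 723 species, ~22% threatened,
    true coefficients equal to the published model estimates, dioicous
    species twice as likely (odds) to reproduce vegetatively and to bear
    sporophytes, and 22% of species missing the sporophyte-morphology block
    (the fraction by which the morphology model's sample is smaller).
    """

    n_species: int = 723
    seed: int = 0
    # Calibrated at large n so the marginal threatened fraction over the
    # default trait distribution is ~0.222 (the study prevalence); the
    # published model intercept (-0.79) is conditional on the reference
    # trait profile, not the marginal rate.
    baseline_logit: float = -1.0
    true_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    sex_monoicous_prob: float = 0.4
    vegetative_prob: float = 0.35
    sporophyte_prob: float = 0.65
    dependence_odds: dict[str, float] = field(default_factory=_default_dependence_odds)
    continuous_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_continuous_params
    )
    sporophyte_missing_rate: float = 0.22
    protonema_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for p in (
            self.sex_monoicous_prob,
            self.vegetative_prob,
            self.sporophyte_prob,
        ):
            if not 0 < p < 1:
                raise ValueError("probabilities must lie in (0, 1)")
        if not 0 <= self.sporophyte_missing_rate < 1:
            raise ValueError("sporophyte_missing_rate must lie in [0, 1)")
        for k, v in self.dependence_odds.items():
            if v <= 0:
                raise ValueError(f"odds ratio {k} must be > 0")


def generate_cohort(config: CohortConfig) -> tuple[TraitMatrix, dict]:
    """Draw a cohort; deterministic given ``config.seed``.

    Returns the trait matrix (raw units, block missingness applied) and a
    truth record holding every generating parameter, the latent linear
    predictor, the true 0/1 status and the missingness mask — everything a
    recovery test needs.
    """
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_sex, rng_dep, rng_cont, rng_cat, rng_threat, rng_miss, _, _ = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_species

    monoicous = rng_sex.random(n) < config.sex_monoicous_prob

    rates = {}
    for key, marginal in (
        ("sex_vegetative", config.vegetative_prob),
        ("sex_sporophyte", config.sporophyte_prob),
    ):
        rate_di, rate_mono = conditional_rates_from_odds(
            marginal, config.sex_monoicous_prob, config.dependence_odds[key]
        )
        rates[key] = (rate_di, rate_mono)
    p_veg = np.where(monoicous, rates["sex_vegetative"][1], rates["sex_vegetative"][0])
    p_spo = np.where(monoicous, rates["sex_sporophyte"][1], rates["sex_sporophyte"][0])
    vegetative = rng_dep.random(n) < p_veg
    sporophyte = rng_dep.random(n) < p_spo

    cont = {
        name: rng_cont.lognormal(mu, sigma, n)
        for name, (mu, sigma) in config.continuous_params.items()
    }
    breadth = 1.0 + rng_cont.poisson(0.72, n).astype(float)

    seta = cont["Seta length"]
    slope_shape = math.log(config.dependence_odds["setalength_setashape"])
    p_curved = 1.0 / (1.0 + np.exp(-(slope_shape * (np.log(seta) - math.log(SETA_SCALING.mean)))))
    curved = rng_cat.random(n) < p_curved
    capsule_pendent = rng_cat.random(n) < 0.5
    spore_ellips = rng_cat.random(n) < 0.5
    spore_papill = rng_cat.random(n) < 0.5
    capsule_ovoid = rng_cat.random(n) < 0.5
    protonema = rng_cat.random(n) < config.protonema_prob

    beta = config.true_coefficients
    eta = np.full(n, config.baseline_logit)
    eta += beta.get("Plant sex", 0.0) * monoicous
    eta += beta.get("Sporophyte presence", 0.0) * sporophyte
    eta += beta.get("Vegetative reproduction", 0.0) * vegetative
    eta += beta.get("Substrate breadth", 0.0) * BREADTH_SCALING.transform(breadth)
    eta += beta.get("Seta length", 0.0) * SETA_SCALING.transform(seta)
    p_threat = 1.0 / (1.0 + np.exp(-eta))
    if p_threat.mean() > 0.95:
        import logging

        logging.getLogger(__name__).warning(
            "degenerate config: expected threatened fraction %.2f", p_threat.mean()
        )
    threatened = rng_threat.random(n) < p_threat

    missing_block = rng_miss.random(n) < config.sporophyte_missing_rate

    names = [f"Species_{i:04d}" for i in range(n)]
    data = pd.DataFrame(index=pd.Index(names, name="species"))
    data["iucn_category"] = np.where(threatened, "EN", "LC")
    data["threat_status"] = pd.array(threatened.astype(int), dtype="Int64")
    data["Plant sex"] = np.where(monoicous, "monoicous", "dioicous")
    data["Sporophyte presence"] = np.where(sporophyte, "present", "absent")
    data["Vegetative reproduction"] = np.where(vegetative, "present", "absent")
    data["Capsule length"] = cont["Capsule length"]
    data["Capsule shape"] = np.where(capsule_ovoid, "ovoid", "cylindric")
    data["Capsule on seta"] = np.where(capsule_pendent, "pendent", "erect")
    data["Seta length"] = seta
    data["Seta shape"] = np.where(curved, "curved", "straight")
    data["Spore diameter"] = cont["Spore diameter"]
    data["Spore shape"] = np.where(spore_ellips, "ellipsoidal", "spherical")
    data["Spore ornamentation"] = np.where(spore_papill, "papillose", "smooth")
    data["Persistent protonema"] = np.where(protonema, "present", "absent")
    data["Leaf length"] = cont["Leaf length"]
    data["Stem length"] = cont["Stem length"]
    data["Substrate breadth"] = breadth

    for col in SPOROPHYTE_MORPHOLOGY_TRAITS:
        if pd.api.types.is_float_dtype(data[col]):
            data.loc[missing_block, col] = np.nan
        else:
            data[col] = data[col].astype(object)
            data.loc[missing_block, col] = None

    matrix = TraitMatrix(
        data=data,
        definitions=list(CANONICAL_TRAITS),
        log=[f"synthetic cohort: n={n}, seed={config.seed}"],
    )
    truth = {
        "config": asdict(config),
        "true_status": threatened.astype(int).tolist(),
        "linear_predictor": eta.tolist(),
        "threat_probability": p_threat.tolist(),
        "conditional_rates": {k: list(v) for k, v in rates.items()},
        "sporophyte_block_missing": missing_block.tolist(),
        "scaling": {
            "Substrate breadth": (BREADTH_SCALING.mean, BREADTH_SCALING.sd),
            "Seta length": (SETA_SCALING.mean, SETA_SCALING.sd),
        },
    }
    return matrix, truth


def make_dd_holdout(
    matrix: TraitMatrix, fraction: float, seed: int
) -> tuple[TraitMatrix, dict]:
    """Relabel a random species subset as Data Deficient.

    The visible matrix loses those species' categories and statuses; the
    returned truth record keeps the original labels so triage verdicts can
    be validated against them.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = matrix.n_species
    mask = rng.random(n) < fraction
    if not mask.any():
        import logging

        logging.getLogger(__name__).warning("fraction %.4f selected 0 records", fraction)
    out = matrix.copy()
    idx = out.data.index[mask]
    truth = {
        "holdout_species": list(idx),
        "original_category": out.data.loc[idx, "iucn_category"].tolist(),
        "original_status": out.data.loc[idx, "threat_status"].astype(float).tolist(),
    }
    out.data.loc[idx, "iucn_category"] = "DD"
    out.data["threat_status"] = out.data["threat_status"].mask(
        pd.Series(mask, index=out.data.index), pd.NA
    )
    out.log.append(f"DD holdout: {int(mask.sum())} of {n} species masked (seed={seed})")
    return out, truth
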