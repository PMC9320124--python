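"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a pooled school-based accelerometer study: per-sex
nine-band time-use compositions drawn logistic-normally around target
geometric means, covariates (sex, age by school phase, area-deprivation
decile, device model, sampling frequency) matching the published descriptive
distributions, an outcome linear in the clr coordinates of the composition
plus covariates with Gaussian noise, and an exactly-sized missingness cascade
(outcome, wear validity, deprivation decile).

Default calibration targets:

* geometric-mean compositions per sex — the published per-sex nine-band
  geometric means (960-min closure);
* girls' share 57.5%, outcome mean/SD 0.51/1.24, deciles 1-5 at 67.4%;
* clr effect vectors per sex derived from the published per-band first-pivot
  coefficients via the pivot identity beta_ILR1 = sqrt(D/(D-1)) * a_band,
  centred to sum to zero;
* roster missingness 67 (outcome), 233 (wear), 50 (decile) on a roster of
  1803, reproducing the 1453-record analytical sample.

Because the outcome is genuinely linear in clr coordinates, the pivot scan
estimates beta_ILR1 = sqrt(9/8) * a_band without bias — the basis of the
parameter-recovery and coverage checks in the test suite.

The generator does not emulate device noise, diurnal activity profiles or
autocalibration drift; epoch streams place each band's minutes uniformly at
random within the 16-h day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, NINE_BAND_SCHEME, BandScheme, EpochSeries
from .composition import DAY_MINUTES, close

__all__ = [
    "TABLE_GM",
    "ILR1_BETA",
    "clr_effect_from_ilr1",
    "GeneratorConfig",
    "generate_cohort",
    "inject_missingness",
    "generate_epoch_stream",
]

#: Published geometric-mean band minutes (closed to 960) per stratum.
TABLE_GM = {
    "all": (722.9, 105.7, 51.1, 27.8, 15.4, 9.1, 5.8, 14.3, 8.0),
    "boy": (719.9, 102.6, 49.6, 27.8, 16.1, 9.8, 6.4, 16.7, 11.1),
    "girl": (724.0, 108.0, 52.0, 28.0, 15.0, 9.0, 5.0, 13.0, 6.3),
}

#: Published per-band first-pivot-coordinate coefficients (BMI z-score per
#: unit ILR_1), by sex.
ILR1_BETA = {
    "boy": (-0.20, -0.74, -0.34, 0.88, -0.50, -1.75, 1.39, 0.57, -0.77),
    "girl": (0.03, 1.39, -2.55, 1.87, -1.64, 1.04, -0.09, 0.39, -0.71),
}


def clr_effect_from_ilr1(betas) -> np.ndarray:
    """Invert the pivot identity: a_j = beta_ILR1_j / sqrt(D/(D-1)), centred.

    The nine first-pivot coefficients of one model determine a clr effect
    vector only up to the sum-to-zero identification, so the result is
    centred (printed tables need not satisfy the identity exactly).
    """
    b = np.asarray(betas, dtype=float)
    D = b.size
    a = b / np.sqrt(D / (D - 1.0))
    return a - a.mean()


# EIMD decile probabilities (deciles 1..10): lower deciles over-represented,
# deciles 1-5 carrying 67.4% of the sample.
EIMD_PROBS = (0.17, 0.15, 0.13, 0.12, 0.104, 0.08, 0.07, 0.066, 0.06, 0.05)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort, with published-calibrated defaults."""

    n: int = 1803
    prop_girls: float = 0.575
    n_schools: int = 63
    prop_primary_schools: float = 0.663
    age_primary: tuple = (9.0, 1.9)  # mean, SD (years)
    age_secondary: tuple = (13.4, 1.5)
    eimd_probs: tuple = EIMD_PROBS
    accel_models: tuple = ("GT9X", "GENEActiv", "AX3")
    accel_model_probs: tuple = (0.7, 0.2, 0.1)
    prop_100hz: float = 0.8
    band_labels: tuple = BAND_LABELS
    #: per-sex target geometric-mean compositions (min/day, closed to total)
    target_gm: dict = field(
        default_factory=lambda: {"boy": TABLE_GM["boy"], "girl": TABLE_GM["girl"]}
    )
    #: per-band SD of log minutes (independent log-normal parts before closure)
    log_sd: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45)
    #: per-sex true clr effect vectors (sum to zero)
    clr_effect: dict = field(
        default_factory=lambda: {
            sex: tuple(clr_effect_from_ilr1(ILR1_BETA[sex])) for sex in ("boy", "girl")
        }
    )
    #: per-sex marginal outcome means
    outcome_mean: dict = field(default_factory=lambda: {"boy": 0.53, "girl": 0.49})
    outcome_sd: float = 1.24  # marginal target; noise SD is derived from it
    ses_effect: float = -0.02  # outcome shift per EIMD decile
    age_effect: float = 0.0  # outcome shift per year of age
    noise_sd: float | None = None  # None -> calibrated to hit outcome_sd
    #: cascade missingness counts: outcome, wear, SES
    n_missing_outcome: int = 67
    n_missing_wear: int = 233
    n_missing_ses: int = 50
    total: float = DAY_MINUTES

    # -- validation and derived quantities ---------------------------------
    def validate(self) -> None:
        errors = []
        D = len(self.band_labels)
        for p, name in [
            (self.prop_girls, "prop_girls"),
            (self.prop_primary_schools, "prop_primary_schools"),
            (self.prop_100hz, "prop_100hz"),
        ]:
            if not 0 <= p <= 1:
                errors.append(f"{name} = {p} outside [0, 1]")
        for probs, name in [
            (self.eimd_probs, "eimd_probs"),
            (self.accel_model_probs, "accel_model_probs"),
        ]:
            if abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                errors.append(f"{name} is not a probability vector")
        for sex, gm in self.target_gm.items():
            if len(gm) != D or min(gm) <= 0:
                errors.append(f"target_gm[{sex!r}] must be {D} positive parts")
        for sex, a in self.clr_effect.items():
            if len(a) != D:
                errors.append(f"clr_effect[{sex!r}] must have {D} entries")
            elif abs(sum(a)) > 1e-8:
                errors.append(f"clr_effect[{sex!r}] must sum to 0 (got {sum(a):g})")
        if len(self.log_sd) != D or min(self.log_sd) <= 0:
            errors.append(f"log_sd must be {D} positive SDs")
        for cnt, name in [
            (self.n_missing_outcome, "n_missing_outcome"),
            (self.n_missing_wear, "n_missing_wear"),
            (self.n_missing_ses, "n_missing_ses"),
        ]:
            if cnt < 0:
                errors.append(f"{name} must be non-negative")
        if self.noise_sd is not None and self.noise_sd <= 0:
            errors.append("noise_sd must be positive")
        if errors:
            raise ValueError("invalid generator config:\n  " + "\n  ".join(errors))

    def _sex_props(self) -> dict:
        return {"girl": self.prop_girls, "boy": 1 - self.prop_girls}

    def _eimd_mean_var(self) -> tuple[float, float]:
        k = np.arange(1, 11)
        p = np.asarray(self.eimd_probs)
        m = float(p @ k)
        return m, float(p @ k**2 - m**2)

    def _age_mean_var(self) -> tuple[float, float]:
        pp = self.prop_primary_schools
        m = pp * self.age_primary[0] + (1 - pp) * self.age_secondary[0]
        v = (
            pp * self.age_primary[1] ** 2
            + (1 - pp) * self.age_secondary[1] ** 2
            + pp * (1 - pp) * (self.age_primary[0] - self.age_secondary[0]) ** 2
        )
        return m, v

    def linear_mean(self, sex: str) -> float:
        """Expected linear predictor for a sex, excluding the intercept.

        With independent log-normal parts, a . clr(x) has expectation
        a . log(target) because the closure and centring terms cancel against
        sum(a) = 0.
        """
        a = np.asarray(self.clr_effect[sex])
        gm = np.asarray(self.target_gm[sex])
        eimd_m, _ = self._eimd_mean_var()
        age_m, _ = self._age_mean_var()
        return float(a @ np.log(gm) + self.ses_effect * eimd_m + self.age_effect * age_m)

    def intercept(self, sex: str) -> float:
        return self.outcome_mean[sex] - self.linear_mean(sex)

    def calibrated_noise_sd(self) -> float:
        """Noise SD such that the marginal outcome SD hits ``outcome_sd``.

        Decomposes the target variance into the per-sex compositional and
        covariate contributions plus the between-sex mean spread; the
        remainder is residual noise.  Explicit ``noise_sd`` overrides.
        """
        if self.noise_sd is not None:
            return self.noise_sd
        s2 = np.asarray(self.log_sd) ** 2
        _, eimd_v = self._eimd_mean_var()
        _, age_v = self._age_mean_var()
        props = self._sex_props()
        within = sum(
            props[sex] * float(np.asarray(self.clr_effect[sex]) ** 2 @ s2)
            for sex in props
        )
        within += self.ses_effect**2 * eimd_v + self.age_effect**2 * age_v
        means = {sex: self.outcome_mean[sex] for sex in props}
        mix_mean = sum(props[s] * means[s] for s in props)
        between = sum(props[s] * (means[s] - mix_mean) ** 2 for s in props)
        resid = self.outcome_sd**2 - within - between
        if resid <= 0:
            raise ValueError(
                f"outcome_sd = {self.outcome_sd} is below the structural SD "
                f"{np.sqrt(within + between):.3f}; raise outcome_sd or shrink effects"
            )
        return float(np.sqrt(resid))

    def with_shared_effect(self, a) -> "GeneratorConfig":
        """Copy with one clr effect vector for both sexes (recovery studies)."""
        a = tuple(np.asarray(a, dtype=float))
        return replace(self, clr_effect={"boy": a, "girl": a})


def generate_cohort(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> pd.DataFrame:
    """Draw a complete synthetic cohort (no missingness) for one seed.

    Returns a frame with covariates, nine band columns (closed to the 960-min
    day), the ``bmi_z`` outcome and a ``wear_ok`` flag (all True here;
    :func:`inject_missingness` applies the cascade).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n

    sex = np.where(rng.random(n) < config.prop_girls, "girl", "boy")

    # schools: heterogeneous sizes via Dirichlet weights, type drawn per school
    school_w = rng.dirichlet(np.full(config.n_schools, 5.0))
    school = rng.choice(config.n_schools, size=n, p=school_w)
    school_primary = rng.random(config.n_schools) < config.prop_primary_schools
    is_primary = school_primary[school]
    school_type = np.where(is_primary, "primary", "secondary")

    age = np.where(
        is_primary,
        rng.normal(*config.age_primary, size=n),
        rng.normal(*config.age_secondary, size=n),
    ).clip(4.5, 16.9)

    eimd = rng.choice(np.arange(1, 11), size=n, p=config.eimd_probs).astype(float)
    model = rng.choice(config.accel_models, size=n, p=config.accel_model_probs)
    freq = np.where(rng.random(n) < config.prop_100hz, 100, 30)

    # compositions: independent log-normal parts around the sex target, closed
    D = len(config.band_labels)
    log_x = np.empty((n, D))
    for s in ("boy", "girl"):
        mask = sex == s
        mu = np.log(np.asarray(config.target_gm[s], dtype=float))
        log_x[mask] = mu + rng.normal(size=(mask.sum(), D)) * np.asarray(config.log_sd)
    comp = close(np.exp(log_x), config.total)

    # outcome: linear in clr coordinates plus covariates, Gaussian noise.
    # a . clr(x) = a . log(x_raw) because sum(a) = 0 kills closure/centring.
    noise_sd = config.calibrated_noise_sd()
    lin = np.empty(n)
    for s in ("boy", "girl"):
        mask = sex == s
        a = np.asarray(config.clr_effect[s])
        lin[mask] = config.intercept(s) + log_x[mask] @ a
    lin += config.ses_effect * eimd + config.age_effect * age
    bmi_z = lin + rng.normal(scale=noise_sd, size=n)

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sex,
            "age": age,
            "school": school,
            "school_type": school_type,
            "eimd_decile": eimd,
            "accel_model": model,
            "sampling_freq": freq,
            "bmi_z": bmi_z,
            "wear_ok": True,
        }
    )
    df[list(config.band_labels)] = comp
    return df


def inject_missingness(
    records: pd.DataFrame, config: GeneratorConfig = GeneratorConfig(), seed: int = 0
) -> pd.DataFrame:
    """Blank exactly the configured record counts, in cascade order.

    Outcome, wear and SES missingness hit disjoint random records, so the
    downstream sequential cascade removes exactly the configured number at
    each stage.
    """
    config.validate()
    n = len(records)
    total = config.n_missing_outcome + config.n_missing_wear + config.n_missing_ses
    if total > n:
        raise ValueError(f"missingness counts ({total}) exceed the roster ({n})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=total, replace=False)
    i1 = picks[: config.n_missing_outcome]
    i2 = picks[config.n_missing_outcome : config.n_missing_outcome + config.n_missing_wear]
    i3 = picks[config.n_missing_outcome + config.n_missing_wear :]
    out = records.copy()
    out.iloc[i1, out.columns.get_loc("bmi_z")] = np.nan
    out.iloc[i2, out.columns.get_loc("wear_ok")] = False
    out.iloc[i3, out.columns.get_loc("eimd_decile")] = np.nan
    return out


def generate_epoch_stream(
    comp,
    scheme: BandScheme = NINE_BAND_SCHEME,
    seed: int = 0,
    epoch_seconds: float = 1.0,
    day: object = 1,
) -> EpochSeries:
    """Emit a shuffled 1-s epoch stream whose band minutes equal ``comp``.

    Band minutes are apportioned to whole epochs by largest remainder, so the
    57,600-epoch day is preserved exactly and banding inverts the stream to
    within one epoch (1/60 min) per band.
    """
    comp = np.asarray(comp, dtype=float)
    if abs(comp.sum() - DAY_MINUTES) > 1e-6:
        raise ValueError("composition must be closed to the 960-min day")
    rng = np.random.default_rng(seed)
    per_epoch = 60.0 / epoch_seconds  # epochs per minute
    quotas = comp * per_epoch
    counts = np.floor(quotas).astype(int)
    short = int(round(quotas.sum())) - counts.sum()
    if short > 0:
        frac = quotas - np.floor(quotas)
        counts[np.argsort(-frac)[:short]] += 1

    edges = list(scheme.edges) + [max(2 * scheme.edges[-1], scheme.edges[-1] + 700)]
    values = []
    for j, c in enumerate(counts):
        lo, hi = edges[j], edges[j + 1]
        values.append(rng.uniform(lo, hi, size=c))
    enmo_mg = np.concatenate(values)
    rng.shuffle(enmo_mg)
    return EpochSeries(day=day, enmo_mg=enmo_mg, epoch_seconds=epoch_seconds)
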