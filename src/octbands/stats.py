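"""Stage 3: device and region comparisons with linear mixed-effects models.

Cohorts often include both eyes of some patients, so observations are not
independent: models use a random intercept per patient, with an additional
eye-within-patient intercept (as a variance component) whenever any patient
contributes two eyes and the fit supports it.  Estimation is restricted
maximum likelihood via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

Inference uses Wald statistics referred to a t distribution with a
containment-style denominator degrees of freedom,
``df = n_obs - n_eyes - (p - 1)`` (p = number of fixed-effect parameters):
for a within-eye device contrast on E paired eyes this gives E - 1, the
paired-design degrees of freedom.  A plain normal reference would be
anticonservative at these cohort sizes.

Right-skewed loss areas are log-transformed before modelling; means and
confidence limits are reported after back-transformation (so the intervals
are asymmetric), and exact zeros are offset to half the smallest positive
observed value (documented, configurable).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "MeasurementTable",
    "validate_table",
    "fit_device_comparison",
    "fit_region_comparison",
    "bonferroni",
    "back_transform_log",
]

#: required columns of the tidy measurement table
TABLE_COLUMNS = ("patient_id", "eye_id", "device", "subfield", "outcome", "value")

MeasurementTable = pd.DataFrame  # tidy long table, see TABLE_COLUMNS


@dataclasses.dataclass
class ComparisonResult:
    """One fitted contrast with its interval and (corrected) p-values.

    ``scale`` is ``"identity"`` or ``"log-back-transformed"``; on the log
    scale the contrast estimate and CI are back-transformed to a ratio and
    per-level means to geometric means.
    """

    outcome: str
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonferroni: float
    scale: str
    level_means: dict[str, tuple[float, float, float]]
    df: float
    degraded: bool = False
    m: int = 1

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket the "
                f"estimate {self.estimate}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["level_means"] = {
            k: {"mean": v[0], "ci_low": v[1], "ci_high": v[2]}
            for k, v in self.level_means.items()
        }
        return d


def validate_table(table: MeasurementTable) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    key = ["eye_id", "device", "subfield", "outcome"]
    dup = table.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate (eye, device, subfield, outcome) rows: "
            f"{table.loc[dup, key].head().to_dict('records')}"
        )
    n_pat = table.groupby("eye_id")["patient_id"].nunique()
    if (n_pat > 1).any():
        raise ValueError(
            f"eyes mapped to multiple patients: {list(n_pat[n_pat > 1].index)}"
        )


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: min(1, m * p), elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


def back_transform_log(mean_log: float, ci_log: tuple[float, float]):
    """Exponentiate a log-scale mean and CI (asymmetric about the mean)."""
    return float(np.exp(mean_log)), (
        float(np.exp(ci_log[0])),
        float(np.exp(ci_log[1])),
    )


def _log_with_zero_offset(values: pd.Series, outcome: str) -> pd.Series:
    negative = values < 0
    if negative.any():
        raise ValueError(
            f"log transform of {outcome!r} impossible: negative values at "
            f"rows {list(values.index[negative])[:5]}"
        )
    positive = values[values > 0]
    if positive.empty:
        raise ValueError(
            f"log transform of {outcome!r} impossible: no positive values"
        )
    offset = positive.min() / 2.0
    return np.log(values.where(values > 0, offset).astype(float))


def _fit_mixed(df: pd.DataFrame, formula: str):
    """REML mixed fit; eye-within-patient component dropped when singular."""
    nested = df.groupby("patient_id")["eye_id"].nunique().max() > 1
    degraded = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if nested:
            try:
                model = smf.mixedlm(
                    formula, df, groups=df["patient_id"],
                    re_formula="1", vc_formula={"eye": "0 + C(eye_id)"},
                )
                res = model.fit(reml=True)
                if not res.converged or not np.all(np.isfinite(res.bse_fe)):
                    raise ValueError("singular nested fit")
            except (ValueError, np.linalg.LinAlgError):
                degraded = True
                res = None
        else:
            res = None
        if res is None:
            model = smf.mixedlm(formula, df, groups=df["patient_id"],
                                re_formula="1")
            res = model.fit(reml=True)
    if not np.all(np.isfinite(res.fe_params)):
        raise ValueError("mixed model failed to produce finite fixed effects")
    return res, degraded


def _wald_t(est: float, se: float, df: float):
    t_stat = est / se if se > 0 else np.inf * np.sign(est or 1.0)
    p = float(2.0 * scipy.stats.t.sf(abs(t_stat), df))
    crit = float(scipy.stats.t.ppf(0.975, df))
    return p, (est - crit * se, est + crit * se), crit


def _fe_cov(res) -> np.ndarray:
    k = len(res.fe_params)
    return np.asarray(res.cov_params())[:k, :k]


def fit_device_comparison(
    table: MeasurementTable,
    outcome: str,
    log_scale: bool = False,
    subfield: str = "whole_field",
    m: int = 1,
    reference: str | None = None,
) -> ComparisonResult:
    """Paired two-device comparison of one outcome.

    Fits ``value ~ device`` with a patient random intercept (plus an
    eye-within-patient component when applicable) on one row per eye x
    device and returns the device contrast (the non-reference device minus
    ``reference``; default reference is the first device in sorted label
    order) with its 95% CI, raw and Bonferroni-corrected p-value, and
    per-device model means.
    """
    validate_table(table)
    df = table[(table["outcome"] == outcome) & (table["subfield"] == subfield)]
    df = df.copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}, subfield {subfield!r}")
    devices = sorted(df["device"].unique())
    if len(devices) != 2:
        raise ValueError(f"need exactly 2 devices, got {devices}")
    per_eye = df.groupby("eye_id")["device"].nunique()
    if (per_eye < 2).any():
        raise ValueError(
            f"unpaired eyes (missing one device): {list(per_eye[per_eye < 2].index)}"
        )
    if df["patient_id"].nunique() < 2:
        raise ValueError("insufficient grouping levels: need >= 2 patients")

    scale = "identity"
    if log_scale:
        df["value"] = _log_with_zero_offset(df["value"], outcome)
        scale = "log-back-transformed"

    if reference is None:
        reference = devices[0]
    if reference not in devices:
        raise ValueError(f"reference device {reference!r} not in {devices}")
    ref = reference
    other = next(d for d in devices if d != ref)
    formula = f"value ~ C(device, Treatment(reference='{ref}'))"
    res, degraded = _fit_mixed(df, formula)

    n_obs = len(df)
    n_eyes = df["eye_id"].nunique()
    p_fixed = len(res.fe_params)
    dof = max(1.0, n_obs - n_eyes - (p_fixed - 1))

    beta_name = [n for n in res.fe_params.index if "T." in n][0]
    cov = _fe_cov(res)
    names = list(res.fe_params.index)
    i0, i1 = names.index("Intercept"), names.index(beta_name)

    est = float(res.fe_params[beta_name])
    se = float(np.sqrt(cov[i1, i1]))
    p_raw, ci, crit = _wald_t(est, se, dof)

    level_means = {}
    for dev, L in ((ref, np.eye(1, p_fixed, i0)[0]),
                   (other, _sum_vec(p_fixed, [i0, i1]))):
        mu = float(L @ res.fe_params.values)
        se_mu = float(np.sqrt(L @ cov @ L))
        lo, hi = mu - crit * se_mu, mu + crit * se_mu
        if log_scale:
            mu, (lo, hi) = back_transform_log(mu, (lo, hi))
        level_means[dev] = (mu, lo, hi)

    lo, hi = ci
    if log_scale:
        est, (lo, hi) = back_transform_log(est, ci)
    return ComparisonResult(
        outcome=outcome,
        contrast=f"{other} - {ref}" if not log_scale else f"{other} / {ref}",
        estimate=est, ci_low=lo, ci_high=hi,
        p_raw=p_raw, p_bonferroni=bonferroni(p_raw, m),
        scale=scale, level_means=level_means, df=dof,
        degraded=degraded, m=m,
    )


def _sum_vec(p: int, idx: list[int]) -> np.ndarray:
    L = np.zeros(p)
    L[idx] = 1.0
    return L


def fit_region_comparison(
    table: MeasurementTable,
    outcome: str,
    regions: list[str],
    log_scale: bool = False,
    correction_m: int | None = None,
) -> list[ComparisonResult]:
    """All pairwise region contrasts of one outcome within one device's data.

    Fits ``value ~ region`` with the same random-effects structure as the
    device comparison and Bonferroni-corrects over the number of pairwise
    contrasts (or ``correction_m`` when given).
    """
    validate_table(table)
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    df = table[(table["outcome"] == outcome)
               & (table["subfield"].isin(regions))].copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r} in regions {regions}")
    present = df.groupby("eye_id")["subfield"].nunique()
    if (present < 2).any():
        raise ValueError("each eye must contribute >= 2 regions")
    if df["patient_id"].nunique() < 2:
        raise ValueError("insufficient grouping levels: need >= 2 patients")

    scale = "identity"
    if log_scale:
        df["value"] = _log_with_zero_offset(df["value"], outcome)
        scale = "log-back-transformed"

    ref = regions[0]
    formula = f"value ~ C(subfield, Treatment(reference='{ref}'))"
    res, degraded = _fit_mixed(df, formula)
    cov = _fe_cov(res)
    names = list(res.fe_params.index)
    p_fixed = len(names)

    n_obs = len(df)
    n_eyes = df["eye_id"].nunique()
    dof = max(1.0, n_obs - n_eyes - (p_fixed - 1))

    def level_vec(region: str) -> np.ndarray:
        L = np.zeros(p_fixed)
        L[names.index("Intercept")] = 1.0
        if region != ref:
            L[[n.endswith(f"[T.{region}]") for n in names].index(True)] = 1.0
        return L

    pairs = list(itertools.combinations(regions, 2))
    m = correction_m if correction_m is not None else len(pairs)
    _, _, crit = _wald_t(0.0, 1.0, dof)

    level_means = {}
    for region in regions:
        L = level_vec(region)
        mu = float(L @ res.fe_params.values)
        se_mu = float(np.sqrt(L @ cov @ L))
        lo, hi = mu - crit * se_mu, mu + crit * se_mu
        if log_scale:
            mu, (lo, hi) = back_transform_log(mu, (lo, hi))
        level_means[region] = (mu, lo, hi)

    results = []
    for r_a, r_b in pairs:
        L = level_vec(r_b) - level_vec(r_a)
        est = float(L @ res.fe_params.values)
        se = float(np.sqrt(L @ cov @ L))
        p_raw, ci, _ = _wald_t(est, se, dof)
        lo, hi = ci
        contrast = f"{r_b} - {r_a}"
        if log_scale:
            est, (lo, hi) = back_transform_log(est, ci)
            contrast = f"{r_b} / {r_a}"
        results.append(ComparisonResult(
            outcome=outcome, contrast=contrast,
            estimate=est, ci_low=lo, ci_high=hi,
            p_raw=p_raw, p_bonferroni=bonferroni(p_raw, m),
            scale=scale,
            level_means={r: level_means[r] for r in (r_a, r_b)},
            df=dof, degraded=degraded, m=m,
        ))
    return results
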