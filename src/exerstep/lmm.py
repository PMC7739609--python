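"""Long-format study table and linear mixed-effects fitting.

The study design has five two-level fixed effects (game speed, obstacle
presence, trial repetition, gender, body side) and, per participant, a random
intercept plus a random slope for body side.  Estimation is restricted
maximum likelihood via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

Denominator degrees of freedom use a between-within (containment) split:
effects that vary within participants are tested against
``n_obs - n_groups - n_within_effects`` denominator df, purely
between-participant effects (gender) against ``n_groups - n_between - 1``.
The method name is recorded in every fit; calibration (null p-value
uniformity, CI coverage) is the supported validation route, not reproduction
of any particular reference df value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DuplicateRow, TestUnavailable, UndefinedMean
from .metrics import TrialMetrics

#: Treatment-coding reference levels, declared in all outputs.
REFERENCE_LEVELS = {
    "speed": "low",
    "obstacles": "without",
    "repetition": 1,
    "gender": "female",
    "side": "left",
}

FIXED_EFFECTS = ("speed", "obstacles", "repetition", "gender", "side")

#: Metrics reported per body side.
SIDE_METRICS = (
    "mean_single_support",
    "single_support_ratio",
    "mean_step_size",
    "cadence",
    "arm_lift_frequency",
)
TRIAL_METRICS = ("anterior_drift",)

DF_METHOD = "between-within"


@dataclass(frozen=True)
class LmmSpec:
    response: str = "cadence"
    fixed: tuple[str, ...] = FIXED_EFFECTS
    random_slope_side: bool = True
    reml: bool = True


@dataclass
class LmmFit:
    spec: LmmSpec
    effects: pd.DataFrame        # estimate, se, df, t, F, p, ci_low, ci_high
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    n_groups: int
    n_dropped: int
    df_method: str = DF_METHOD

    def effect(self, name: str) -> pd.Series:
        return self.effects.loc[name]


def assemble_metrics_table(metrics: list[TrialMetrics]) -> pd.DataFrame:
    """Long-format table: one row per trial x side x metric.

    Side-specific metrics produce one row per body side; trial-level metrics
    one row with side ``none``.  Missing values are preserved as NaN.
    """
    rows = []
    seen = set()
    for m in metrics:
        base = m.meta.as_dict()
        key0 = (base["participant"], base["speed"], base["obstacles"],
                base["repetition"])
        per_side = {
            "mean_single_support": m.mean_single_support,
            "single_support_ratio": m.single_support_ratio,
            "mean_step_size": m.mean_step_size,
            "cadence": m.cadence,
            "arm_lift_frequency": {k: v for k, v in m.arm_lift_frequency.items()
                                   if k in ("left", "right")},
        }
        for name, values in per_side.items():
            for side, value in values.items():
                key = key0 + (side, name)
                if key in seen:
                    raise DuplicateRow(f"duplicate metric row {key}")
                seen.add(key)
                rows.append({**base, "side": side, "metric": name,
                             "value": float(value)})
        for name in TRIAL_METRICS:
            key = key0 + ("none", name)
            if key in seen:
                raise DuplicateRow(f"duplicate metric row {key}")
            seen.add(key)
            rows.append({**base, "side": "none", "metric": name,
                         "value": float(getattr(m, name))})
    cols = ["participant", "gender", "speed", "obstacles", "repetition",
            "side", "metric", "value"]
    return pd.DataFrame(rows, columns=cols)


def _encode(df: pd.DataFrame, fixed: tuple[str, ...]) -> pd.DataFrame:
    """Treatment-code the factor columns against REFERENCE_LEVELS."""
    out = pd.DataFrame(index=df.index)
    codes = {
        "speed": ("speed[high]", df.get("speed") == "high"),
        "obstacles": ("obstacles[with]", df.get("obstacles") == "with"),
        "repetition": ("repetition[2]", df.get("repetition") == 2),
        "gender": ("gender[male]", df.get("gender") == "male"),
        "side": ("side[right]", df.get("side") == "right"),
    }
    for eff in fixed:
        name, col = codes[eff]
        out[name] = col.astype(float)
    return out


def fit_lmm(table: pd.DataFrame, spec: LmmSpec = LmmSpec()) -> LmmFit:
    """REML fit of the mixed model for one response metric.

    Rows with missing response are dropped (count reported).  Singular or
    non-converged optimizations are flagged in the result rather than raised;
    coefficient estimates are still returned.
    """
    import statsmodels.api as sm

    df = table[table["metric"] == spec.response].copy()
    n_before = len(df)
    df = df.dropna(subset=["value"])
    n_dropped = n_before - len(df)
    groups = df["participant"]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 participants")

    fixed = tuple(e for e in spec.fixed
                  if e != "side" or (df["side"] != "none").any())
    X = _encode(df, fixed)
    X.insert(0, "Intercept", 1.0)
    y = df["value"].to_numpy()

    use_slope = spec.random_slope_side and "side" in fixed
    if use_slope:
        exog_re = np.column_stack(
            [np.ones(len(df)), (df["side"] == "right").astype(float)])
        re_names = ["intercept", "side[right]"]
    else:
        exog_re = np.ones((len(df), 1))
        re_names = ["intercept"]

    model = sm.MixedLM(y, X.to_numpy(), groups=groups.to_numpy(),
                       exog_re=exog_re)
    converged = False
    fallback = None
    res = fe = se = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs", "bfgs"], "powell", "nm"):
            try:
                cand = model.fit(reml=spec.reml, method=method, maxiter=500)
                cfe = np.asarray(cand.fe_params, dtype=float)
                cse = np.asarray(cand.bse_fe, dtype=float)
            except Exception:
                continue
            finite = (np.isfinite(cfe).all() and np.isfinite(cse).all()
                      and (cse > 0).all())
            if finite and cand.converged:
                res, fe, se, converged = cand, cfe, cse, True
                break
            if finite and fallback is None:
                fallback = (cand, cfe, cse)
        if res is None:
            if fallback is None:
                raise RuntimeError("mixed-model optimization failed outright")
            res, fe, se = fallback
            converged = False

    n_obs = len(df)
    n_groups = groups.nunique()
    between = {"gender"}
    n_between = sum(1 for e in fixed if e in between)
    n_within = len(fixed) - n_between
    df_within = max(1, n_obs - n_groups - n_within)
    df_between = max(1, n_groups - n_between - 1)

    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    scale = float(res.scale)

    def side_df() -> float:
        # Satterthwaite blend: the side contrast's variance mixes the
        # random-slope stratum (df ~ g - 1) and the residual stratum
        var_slope = max(0.0, float(cov_re[1, 1])) if use_slope else 0.0
        m = n_obs / (2.0 * n_groups)    # obs per side per participant
        a = var_slope / n_groups
        b = 2.0 * scale / (m * n_groups)
        if a + b <= 0:
            return df_within
        return (a + b) ** 2 / (a ** 2 / (n_groups - 1) + b ** 2 / df_within)

    # Between-participant effects are estimated and tested in the between
    # stratum (OLS on participant means): exactly calibrated in balanced
    # designs, where the asymptotic Wald standard error undercovers with
    # few clusters.
    stratum: dict[str, tuple[float, float]] = {}
    if any(e in between for e in fixed):
        pm = df.groupby("participant").agg(
            value=("value", "mean"), gender=("gender", "first"))
        Xb = np.column_stack([np.ones(len(pm)),
                              (pm["gender"] == "male").astype(float)])
        bb, res_ss, rank, _ = np.linalg.lstsq(Xb, pm["value"].to_numpy(),
                                              rcond=None)
        dfb = len(pm) - rank
        if dfb > 0 and res_ss.size:
            s2 = float(res_ss[0]) / dfb
            cov_b = s2 * np.linalg.inv(Xb.T @ Xb)
            stratum["gender[male]"] = (float(bb[1]), float(np.sqrt(cov_b[1, 1])))

    rows = []
    for i, name in enumerate(X.columns):
        eff = name.split("[")[0]
        if eff in between:
            dof = df_between
            if name in stratum:
                fe = fe.copy()
                se = se.copy()
                fe[i], se[i] = stratum[name]
        elif eff == "side" and use_slope:
            dof = side_df()
        else:
            dof = df_within
        t = fe[i] / se[i] if se[i] > 0 else math.nan
        p = 2 * stats.t.sf(abs(t), dof) if np.isfinite(t) else math.nan
        half = stats.t.ppf(0.975, dof) * se[i]
        rows.append({"effect": name, "estimate": fe[i], "se": se[i],
                     "df_num": 1, "df_den": dof, "t": t, "F": t * t, "p": p,
                     "ci_low": fe[i] - half, "ci_high": fe[i] + half})
    effects = pd.DataFrame(rows).set_index("effect")

    vc = {"residual": float(res.scale)}
    for i, a in enumerate(re_names):
        for j, b in enumerate(re_names[:i + 1]):
            key = f"var[{a}]" if a == b else f"cov[{a},{b}]"
            vc[key] = float(cov_re[i, j])

    return LmmFit(spec=spec, effects=effects, variance_components=vc,
                  converged=converged, n_obs=n_obs, n_groups=n_groups,
                  n_dropped=n_dropped)


def effect_tests(fit: LmmFit) -> pd.DataFrame:
    """Per-effect conditional F-tests (two-level factors: F = t^2, 1 num df)."""
    if not fit.converged:
        raise TestUnavailable("model fit did not converge")
    out = fit.effects.drop(index="Intercept", errors="ignore")
    return out[["F", "df_num", "df_den", "p"]].copy()


def pooled_group_mean(groups: list[tuple[float, int]]) -> float:
    """Sample-size-weighted mean of subgroup means: sum(n*m) / sum(n)."""
    if not groups:
        raise UndefinedMean("no groups")
    if any(n <= 0 for _, n in groups):
        raise ValueError("group sizes must be positive")
    total = sum(n for _, n in groups)
    return sum(m * n for m, n in groups) / total


# ---------------------------------------------------------------------------
# simulation-based calibration / parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryConfig:
    """Metrics-level generative model for calibration experiments.

    ``effects`` holds the true coefficients on the treatment-coded scale
    (e.g. ``{"speed": 6.89}`` for the high-vs-low contrast).  Omitted
    effects are zero.
    """

    n_participants: int = 15
    effects: dict = field(default_factory=dict)
    intercept: float = 30.0
    sd_intercept: float = 2.0
    sd_side_slope: float = 1.0
    sd_residual: float = 3.0
    response: str = "cadence"


def balanced_design(n_participants: int) -> pd.DataFrame:
    """Participant x condition x repetition x side design frame."""
    from .simulator.cohort import assign_genders, condition_order

    genders = assign_genders(n_participants)
    rows = []
    for i in range(n_participants):
        for rep in (1, 2):
            for speed, obstacles in condition_order(i):
                for side in ("left", "right"):
                    rows.append({
                        "participant": f"P{i + 1:02d}", "gender": genders[i],
                        "speed": speed, "obstacles": obstacles,
                        "repetition": rep, "side": side,
                    })
    return pd.DataFrame(rows)


def simulate_metrics_table(
    config: RecoveryConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one synthetic long-format table from the generative model."""
    df = balanced_design(config.n_participants)
    X = _encode(df, FIXED_EFFECTS)
    beta = np.array([float(config.effects.get(e, 0.0)) for e in FIXED_EFFECTS])
    mean = config.intercept + X.to_numpy() @ beta

    pids = df["participant"].unique()
    b0 = dict(zip(pids, rng.normal(0, config.sd_intercept, len(pids))))
    b1 = dict(zip(pids, rng.normal(0, config.sd_side_slope, len(pids))))
    re = (df["participant"].map(b0).to_numpy()
          + (df["side"] == "right").to_numpy()
          * df["participant"].map(b1).to_numpy())
    y = mean + re + rng.normal(0, config.sd_residual, len(df))
    out = df.copy()
    out["metric"] = config.response
    out["value"] = y
    return out


def recovery_experiment(
    config: RecoveryConfig, n_reps: int, seed: int,
    spec: LmmSpec | None = None,
) -> pd.DataFrame:
    """Bias / RMSE / 95% CI coverage / p-values over repeated fits.

    Returns one row per fixed effect with columns ``true``, ``bias``,
    ``rmse``, ``coverage`` and the per-replicate p-values in ``pvals``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spec = spec or LmmSpec(response=config.response)
    rng = np.random.default_rng(seed)
    names = {e: f"{e}[{ {'speed': 'high', 'obstacles': 'with', 'repetition': '2', 'gender': 'male', 'side': 'right'}[e] }]"
             for e in FIXED_EFFECTS}
    est = {e: [] for e in FIXED_EFFECTS}
    cover = {e: [] for e in FIXED_EFFECTS}
    pvals = {e: [] for e in FIXED_EFFECTS}
    n_failed = 0
    for _ in range(n_reps):
        table = simulate_metrics_table(config, rng)
        fit = fit_lmm(table, spec)
        if not fit.converged or not np.isfinite(fit.effects["p"].drop("Intercept")).all():
            n_failed += 1
            continue
        for e in FIXED_EFFECTS:
            row = fit.effects.loc[names[e]]
            truth = float(config.effects.get(e, 0.0))
            est[e].append(row["estimate"])
            cover[e].append(row["ci_low"] <= truth <= row["ci_high"])
            pvals[e].append(row["p"])
    rows = []
    for e in FIXED_EFFECTS:
        truth = float(config.effects.get(e, 0.0))
        arr = np.asarray(est[e])
        rows.append({
            "effect": e,
            "true": truth,
            "bias": float(arr.mean() - truth),
            "rmse": float(np.sqrt(np.mean((arr - truth) ** 2))),
            "coverage": float(np.mean(cover[e])),
            "pvals": np.asarray(pvals[e]),
            "n_failed": n_failed,
        })
    return pd.DataFrame(rows).set_index("effect")
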