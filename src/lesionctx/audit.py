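"""Causal-consistency auditing of frozen lesion-risk models.

For each concept-risk pair with a stated clinical prior direction the suite
checks: (i) directionality/monotonicity — tie-adjusted Kendall's tau with a
bootstrap CI and an isotonic violation rate; (ii) cross-subgroup invariance —
stability of the logit(risk)-on-concept slope across patient strata, with a
Holm-adjusted heterogeneity test; (iii) counterfactual sensitivity — the
risk change under controlled geometric edits of the fixed masks, summarized
as mean dRisk +/- SD and direction-consistency. Inter-rater reliability of
concept measurements is quantified by ICC(2,1) (two-way random effects).

These are post-hoc consistency checks against clinical priors; they do not
establish formal causality.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import edits as ed
from .phantoms import Cohort

RISK_CLAMP = 1e-6

#: The three default concept-risk priors (concept, risk, direction, edit kind).
DEFAULT_PRIORS = (
    ("min_pleura_distance_mm", "pneumothorax", -1, "pleura_distance"),
    ("vessel_proximity_per_mm", "hemorrhage", +1, "vessel_proximity"),
    ("log_adhesion_area", "pleural_reaction", +1, "adhesion_toggle"),
)

DEFAULT_STRATIFIERS = ("age_group", "sex", "copd", "tumor_size_class", "lobe", "scanner")


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class MonotonicityResult:
    concept: str
    risk: str
    prior_direction: int
    tau: float
    tau_ci: tuple[float, float]
    ci_level: float
    n_bootstrap: int
    violation_rate: float
    n: int
    undefined: bool = False

    @property
    def direction_consistent(self) -> bool:
        return not self.undefined and np.sign(self.tau) == self.prior_direction


@dataclass
class InvarianceResult:
    stratifier: str
    concept: str
    risk: str
    slopes: dict[str, float]
    subgroup_n: dict[str, int]
    max_abs_delta_beta: float
    heterogeneity_p: float
    holm_p: float
    direction_stable: bool
    skipped_subgroups: list[str] = field(default_factory=list)


@dataclass
class CounterfactualResult:
    edit_kind: str
    risk: str
    prior_direction: int
    mean_delta_risk: float
    sd_delta_risk: float
    direction_consistency: float  # percent over valid edits
    n_applicable: int
    n_excluded: int
    exclusion_reasons: dict[str, int] = field(default_factory=dict)


@dataclass
class AuditReport:
    monotonicity: list[MonotonicityResult]
    invariance: list[InvarianceResult]
    counterfactual: list[CounterfactualResult]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=float))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "AuditReport":
        return cls(
            monotonicity=[
                MonotonicityResult(**{**m, "tau_ci": tuple(m["tau_ci"])}) for m in d["monotonicity"]
            ],
            invariance=[InvarianceResult(**i) for i in d["invariance"]],
            counterfactual=[CounterfactualResult(**c) for c in d["counterfactual"]],
            config=d.get("config", {}),
        )


# ---------------------------------------------------------------------------
# Monotonicity


def kendall_tau(
    x: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float], bool]:
    """Tie-adjusted Kendall's tau (tau-b) with a percentile bootstrap CI.

    Returns (tau, (lo, hi), undefined): ``undefined`` flags all-tied input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, (math.nan, math.nan), True
    tau = float(stats.kendalltau(x, y, variant="b").statistic)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(x)
    for _ in range(B):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            continue
        boots.append(stats.kendalltau(xb, yb, variant="b").statistic)
    if boots:
        lo, hi = np.percentile(boots, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
        ci = (float(lo), float(hi))
    else:
        ci = (math.nan, math.nan)
    return tau, ci, False


def isotonic_violation_rate(x: np.ndarray, y: np.ndarray, direction: int) -> float:
    """Fraction of adjacent concept-ordered pairs whose risk change contradicts
    the prior direction.

    Cases are sorted by x; ties in x are collapsed to their mean y. The
    denominator counts adjacent pairs with distinct x; exact-zero y changes
    are not violations. ``direction`` is +1 or -1.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    ux = np.unique(x)
    if len(ux) < 2:
        return 0.0
    means = np.array([y[x == v].mean() for v in ux])
    dy = np.diff(means)
    violations = int(np.sum(dy * direction < 0))
    return violations / (len(ux) - 1)


# ---------------------------------------------------------------------------
# Subgroup invariance


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running_max = max(running_max, val)
        adj[idx] = running_max
    return adj


def _logit_clamped(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), RISK_CLAMP, 1 - RISK_CLAMP)
    return np.log(p / (1 - p))


def _with_age_group(table: pd.DataFrame) -> pd.DataFrame:
    if "age_group" not in table.columns and "age" in table.columns:
        table = table.copy()
        table["age_group"] = np.where(table["age"] < 70, "lt70", "ge70")
    return table


def subgroup_invariance(
    table: pd.DataFrame,
    pairs: list[tuple[str, str, int]],
    stratifiers: tuple[str, ...] = DEFAULT_STRATIFIERS,
    min_subgroup_n: int = 5,
    risk_prefix: str = "risk_",
) -> list[InvarianceResult]:
    """Per-subgroup OLS slopes of logit(risk) on the z-scored concept, with a
    heterogeneity (interaction) F-test per (pair, stratifier), Holm-adjusted
    jointly across everything audited in this call.

    ``pairs`` lists (concept, risk, prior direction); concept columns are
    assumed already z-scored. Subgroups below ``min_subgroup_n`` or with a
    constant concept are flagged and skipped.
    """
    table = _with_age_group(table)
    results: list[InvarianceResult] = []
    for concept, risk, direction in pairs:
        risk_col = f"{risk_prefix}{risk}"
        if concept not in table.columns or risk_col not in table.columns:
            raise ValueError(f"table lacks columns for pair ({concept}, {risk})")
        for strat in stratifiers:
            if strat not in table.columns:
                continue
            slopes: dict[str, float] = {}
            counts: dict[str, int] = {}
            skipped: list[str] = []
            frames = []
            for g, sub in table.groupby(strat, observed=True):
                xg = sub[concept].to_numpy(dtype=float)
                if len(sub) < min_subgroup_n or np.all(xg == xg[0]):
                    skipped.append(str(g))
                    continue
                yg = _logit_clamped(sub[risk_col].to_numpy())
                X = sm.add_constant(xg)
                fit = sm.OLS(yg, X).fit()
                slopes[str(g)] = float(fit.params[1])
                counts[str(g)] = int(len(sub))
                frames.append((str(g), xg, yg))
            if len(slopes) >= 2:
                vals = list(slopes.values())
                delta = max(abs(a - b) for a in vals for b in vals)
                # pooled interaction F-test: group x concept
                xs = np.concatenate([f[1] for f in frames])
                ys = np.concatenate([f[2] for f in frames])
                gs = np.concatenate([[f[0]] * len(f[1]) for f in frames])
                dummies = pd.get_dummies(pd.Series(gs), drop_first=True, dtype=float)
                X0 = np.column_stack([np.ones_like(xs), xs, dummies.to_numpy()])
                X1 = np.column_stack([X0] + [xs * dummies[c].to_numpy()[:, None].ravel() for c in dummies])
                fit0 = sm.OLS(ys, X0).fit()
                fit1 = sm.OLS(ys, X1).fit()
                scale = float(np.var(ys)) + 1e-30
                if fit1.ssr / (len(ys) * scale) < 1e-12:
                    # residuals at numerical zero (risk is an exact function of
                    # the concept): the F-ratio is noise; fall back to the
                    # slope difference itself
                    p_het = 1.0 if delta < 1e-6 else 0.0
                else:
                    ftest = fit1.compare_f_test(fit0)
                    p_het = float(ftest[1]) if np.isfinite(ftest[1]) else 1.0
                stable = all(np.sign(v) == direction for v in vals)
            else:
                delta, p_het = 0.0, 1.0
                stable = all(np.sign(v) == direction for v in slopes.values()) if slopes else False
            results.append(
                InvarianceResult(
                    stratifier=strat,
                    concept=concept,
                    risk=risk,
                    slopes=slopes,
                    subgroup_n=counts,
                    max_abs_delta_beta=delta,
                    heterogeneity_p=p_het,
                    holm_p=math.nan,
                    direction_stable=stable,
                    skipped_subgroups=skipped,
                )
            )
    if results:
        adj = holm_adjust([r.heterogeneity_p for r in results])
        for r, a in zip(results, adj):
            r.holm_p = float(a)
    return results


# ---------------------------------------------------------------------------
# Counterfactual sensitivity


def _apply_edit(volume, edit_kind: str, edit_params: dict) -> ed.EditResult:
    if edit_kind == "pleura_distance":
        return ed.edit_pleura_distance(volume, edit_params.get("delta_mm", 5.0))
    if edit_kind == "vessel_proximity":
        return ed.edit_vessel_proximity(volume, edit_params.get("delta_mm", -3.0))
    if edit_kind == "adhesion_toggle":
        return ed.toggle_adhesion(volume, edit_params.get("mode", "add"))
    raise ValueError(f"unknown edit kind '{edit_kind}'")


def counterfactual_sensitivity(
    model,
    cases,
    edit_kind: str,
    risk: str,
    prior_direction: int,
    edit_params: dict | None = None,
) -> CounterfactualResult:
    """dRisk statistics over valid edits of the given kind.

    dRisk_i = risk(edited_i) - risk(original_i). Direction consistency is the
    percentage of valid edits whose sign matches the *expected* risk response
    (the prior direction times the concept change the edit induces); exact
    zeros count as inconsistent. Invalid edits are excluded and tallied.
    """
    edit_params = dict(edit_params or {})
    # expected sign of dRisk: pleura edit increases distance, vessel edit
    # increases proximity, adhesion add increases area (remove decreases)
    concept_change = -1.0 if edit_params.get("mode") == "remove" else 1.0
    if edit_kind == "pleura_distance":
        concept_change = 1.0
    expected_sign = prior_direction * concept_change

    deltas = []
    reasons: dict[str, int] = {}
    for case in cases:
        vol = case.volume if hasattr(case, "volume") else case
        try:
            result = _apply_edit(vol, edit_kind, edit_params)
        except ValueError as e:
            reasons[str(e)] = reasons.get(str(e), 0) + 1
            continue
        if not result.valid:
            for r in result.reasons or ["invalid"]:
                key = r.split(":")[0]
                reasons[key] = reasons.get(key, 0) + 1
            continue
        r0 = model.predict(vol)[risk]
        r1 = model.predict(result.volume)[risk]
        deltas.append(r1 - r0)
    if not deltas:
        raise ValueError(f"zero valid '{edit_kind}' edits")
    deltas = np.asarray(deltas)
    consistent = np.sign(deltas) == expected_sign  # exact zeros inconsistent
    return CounterfactualResult(
        edit_kind=edit_kind,
        risk=risk,
        prior_direction=prior_direction,
        mean_delta_risk=float(deltas.mean()),
        sd_delta_risk=float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
        direction_consistency=float(consistent.mean() * 100.0),
        n_applicable=int(len(deltas)),
        n_excluded=int(sum(reasons.values())),
        exclusion_reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Inter-rater reliability


def icc_two_way_random(ratings: np.ndarray, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects x raters, complete (no missing cells). The CI is
    the F-based (Satterthwaite) interval.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = R.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 subjects")
    if not np.isfinite(R).all():
        raise ValueError("ratings matrix has missing cells")

    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0 and msc == 0:  # perfect agreement: CI degenerates
        return 1.0, (1.0, 1.0)

    alpha = 1 - ci_level
    fj = msc / mse
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a * fj + b) ** 2 / (a**2 * fj**2 / (k - 1) + b**2 / ((n - 1) * (k - 1)))
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return float(icc), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Full audit


def run_audit(
    model,
    cohort: Cohort,
    priors=DEFAULT_PRIORS,
    stratifiers: tuple[str, ...] = DEFAULT_STRATIFIERS,
    edit_cases: int | None = 30,
    edit_params: dict[str, dict] | None = None,
    use_model_risks: bool = True,
    B: int = 1000,
    seed: int = 0,
) -> AuditReport:
    """Assemble the full audit report for a frozen model over a cohort.

    Monotonicity and invariance run on the whole cohort table (z-scored
    concepts, model-predicted risks unless ``use_model_risks`` is False, in
    which case the cohort's generating risks are audited); counterfactual
    sensitivity runs the per-prior edit on the first ``edit_cases`` cases.
    """
    table = cohort.table.copy()
    if use_model_risks:
        for risk in {p[1] for p in priors}:
            table[f"risk_{risk}"] = [model.predict(c.volume)[risk] for c in cohort.cases]
    ztable = cohort.zscorer.transform(table)

    monotonicity = []
    for i, (concept, risk, direction, _edit) in enumerate(priors):
        x = table[concept].to_numpy(dtype=float)
        y = table[f"risk_{risk}"].to_numpy(dtype=float)
        tau, ci, undefined = kendall_tau(x, y, B=B, seed=seed + i)
        monotonicity.append(
            MonotonicityResult(
                concept=concept,
                risk=risk,
                prior_direction=direction,
                tau=tau,
                tau_ci=ci,
                ci_level=0.95,
                n_bootstrap=B,
                violation_rate=isotonic_violation_rate(x, y, direction),
                n=len(x),
                undefined=undefined,
            )
        )

    invariance = subgroup_invariance(
        ztable, [(c, r, d) for c, r, d, _ in priors], stratifiers=stratifiers
    )

    counterfactual = []
    n_edit = edit_cases or len(cohort.cases)
    for concept, risk, direction, edit_kind in priors:
        params = (edit_params or {}).get(edit_kind, {})
        if edit_kind == "adhesion_toggle" and params.get("mode", "add") == "add":
            # the inserted patch only moves the adhesion concept when it lands
            # contiguous with the tumor, so draw from juxtapleural cases first
            candidates = sorted(
                cohort.cases, key=lambda c: c.concepts["min_pleura_distance_mm"]
            )[:n_edit]
        else:
            candidates = cohort.cases[:n_edit]
        counterfactual.append(
            counterfactual_sensitivity(model, candidates, edit_kind, risk, direction, params)
        )

    config = {
        "priors": [list(p) for p in priors],
        "stratifiers": list(stratifiers),
        "n_cases": len(cohort.table),
        "n_edit_cases": n_edit,
        "bootstrap_B": B,
        "seed": seed,
        "cohort_seed": cohort.seed,
        "use_model_risks": use_model_risks,
    }
    return AuditReport(monotonicity, invariance, counterfactual, config)


def summary_tables(report: AuditReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shape the report as two summary tables: concept-risk monotonicity and
    counterfactual sensitivity."""
    mono = pd.DataFrame(
        [
            {
                "concept": m.concept,
                "risk": m.risk,
                "prior": "+" if m.prior_direction > 0 else "-",
                "kendall_tau": m.tau,
                "tau_ci_low": m.tau_ci[0],
                "tau_ci_high": m.tau_ci[1],
                "isotonic_violation_pct": m.violation_rate * 100.0,
                "n": m.n,
            }
            for m in report.monotonicity
        ]
    )
    cf = pd.DataFrame(
        [
            {
                "edit": c.edit_kind,
                "risk": c.risk,
                "mean_delta_risk": c.mean_delta_risk,
                "sd_delta_risk": c.sd_delta_risk,
                "direction_consistency_pct": c.direction_consistency,
                "applicable_n": c.n_applicable,
                "excluded_n": c.n_excluded,
            }
            for c in report.counterfactual
        ]
    )
    return mono, cf
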