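"""Assumption-gated cohort statistics for ALPS / hippocampal analyses.

The chain mirrors standard clinical-neuroimaging practice: Shapiro–Wilk
normality and Levene homogeneity gates (both at α = 0.05, Levene on group
means) route each comparison to a parametric test (one-way ANOVA + Tukey
HSD, two-sample t) or its rank-based counterpart (Kruskal–Wallis + Dunn,
Mann–Whitney U); post hoc families are Benjamini–Hochberg adjusted.
Covariate-adjusted group contrasts use an OLS general linear model; binary
logistic regression reports odds ratios with Wald intervals; partial
correlations are Pearson correlations of least-squares residuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

GATE_ALPHA = 0.05

GROUPS = ("HC", "DMNC", "DMMCI")


@dataclass
class StatResult:
    """Uniform record of one analysis."""

    name: str
    route: str
    statistic: float
    df: float | tuple | None
    p: float
    pairwise: list[dict] = field(default_factory=list)
    effect: dict = field(default_factory=dict)
    n: int | None = None
    n_dropped: int = 0
    descriptives: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


def _clean_groups(values, groups, min_n: int = 2):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = list(pd.unique(groups))
    parts = [values[groups == g] for g in labels]
    for g, part in zip(labels, parts):
        if part.size < min_n:
            raise ValueError(f"group {g!r} has fewer than {min_n} observations")
    return labels, parts


def _gate_parametric(parts) -> tuple[bool, dict]:
    """Shapiro–Wilk per group and Levene (center='mean') across groups.

    Groups where the test is undefined (constant values, n < 3) fail the
    normality gate, routing the comparison to the rank-based branch.
    """

    def _shapiro_p(x) -> float:
        if x.size < 3 or np.ptp(x) == 0:
            return 0.0
        return float(sps.shapiro(x).pvalue)

    shapiro_p = [_shapiro_p(p) for p in parts]
    levene_p = float(sps.levene(*parts, center="mean").pvalue)
    passed = all(p > GATE_ALPHA for p in shapiro_p) and levene_p > GATE_ALPHA
    return passed, {"shapiro_p": shapiro_p, "levene_p": levene_p}


def _describe(parts, labels, parametric: bool) -> dict:
    out = {}
    for g, part in zip(labels, parts):
        if parametric:
            out[str(g)] = {"mean": float(np.mean(part)), "sd": float(np.std(part, ddof=1))}
        else:
            q1, med, q3 = np.percentile(part, [25, 50, 75])
            out[str(g)] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def omnibus_three_group(values, groups, name: str = "omnibus") -> StatResult:
    """Gated three-group omnibus: ANOVA if every group is Shapiro-normal and
    Levene passes, else Kruskal–Wallis with midrank ties."""
    labels, parts = _clean_groups(values, groups, min_n=3)
    if len(labels) != 3:
        raise ValueError(f"expected 3 groups, found {len(labels)}")
    if all(np.ptp(p) == 0 for p in parts):
        raise ValueError("zero within-group variance in all groups")
    parametric, gate = _gate_parametric(parts)
    n = sum(p.size for p in parts)
    if parametric:
        res = sps.f_oneway(*parts)
        df = (len(parts) - 1, n - len(parts))
        route, stat, p = "anova", float(res.statistic), float(res.pvalue)
    else:
        res = sps.kruskal(*parts)
        df = len(parts) - 1
        route, stat, p = "kruskal_wallis", float(res.statistic), float(res.pvalue)
    return StatResult(
        name=name,
        route=route,
        statistic=stat,
        df=df,
        p=p,
        n=n,
        effect=gate,
        descriptives=_describe(parts, labels, parametric),
    )


def _dunn_pairwise(parts, labels) -> list[dict]:
    """Dunn's z-tests on midranks with tie-corrected variance."""
    all_vals = np.concatenate(parts)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)  # midranks
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for part in parts:
        mean_ranks.append(float(ranks[start : start + part.size].mean()))
        sizes.append(part.size)
        start += part.size
    out = []
    for i, j in itertools.combinations(range(len(parts)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        out.append(
            {
                "a": str(labels[i]),
                "b": str(labels[j]),
                "statistic": float(z),
                "p": float(2 * sps.norm.sf(abs(z))),
            }
        )
    return out


def posthoc_pairwise(values, groups, route: str, name: str = "posthoc") -> StatResult:
    """Tukey HSD after ANOVA, Dunn after Kruskal–Wallis; the family of
    pairwise p-values is BH-adjusted and both raw and adjusted reported."""
    labels, parts = _clean_groups(values, groups, min_n=2)
    if len(labels) < 2:
        raise ValueError("post hoc needs at least 2 groups")
    if route == "anova":
        res = sps.tukey_hsd(*parts)
        pairs = [
            {
                "a": str(labels[i]),
                "b": str(labels[j]),
                "statistic": float(res.statistic[i, j]),
                "p": float(res.pvalue[i, j]),
            }
            for i, j in itertools.combinations(range(len(parts)), 2)
        ]
        sub = "tukey_hsd"
    elif route == "kruskal_wallis":
        pairs = _dunn_pairwise(parts, labels)
        sub = "dunn"
    else:
        raise ValueError(f"unknown omnibus route {route!r}")
    adj = bh_adjust([p["p"] for p in pairs])
    for rec, a in zip(pairs, adj):
        rec["p_adjusted"] = float(a)
    return StatResult(
        name=name,
        route=route,
        statistic=float("nan"),
        df=None,
        p=float(min(rec["p"] for rec in pairs)),
        pairwise=pairs,
        n=sum(p.size for p in parts),
        effect={"posthoc": sub},
    )


def _check_collinear(X: pd.DataFrame, cond_threshold: float = 1e10) -> None:
    arr = np.asarray(X, dtype=float)
    cond = np.linalg.cond(arr)
    if cond > cond_threshold or np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name offending columns via pairwise correlation of the design
        bad = set()
        cols = list(X.columns)
        corr = np.corrcoef(arr, rowvar=False)
        for i, j in itertools.combinations(range(len(cols)), 2):
            if abs(corr[i, j]) > 1 - 1e-10:
                bad.update((cols[i], cols[j]))
        raise ValueError(
            f"collinear design (condition number {cond:.3g}); "
            f"offending columns: {sorted(bad) or cols}"
        )


def ancova_group_effect(
    outcome,
    group,
    covariates: pd.DataFrame | None = None,
    name: str = "ancova",
) -> StatResult:
    """Two-group GLM: outcome ~ group indicator + covariates (complete case).

    Reports the adjusted group coefficient with t/F statistics and a 95% CI.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    labels = list(pd.unique(g))
    if len(labels) != 2:
        raise ValueError(f"ANCOVA expects exactly 2 groups, found {len(labels)}")
    ind = (g == labels[1]).astype(float)
    X = pd.DataFrame({"group": ind})
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X.insert(0, "const", 1.0)
    keep = np.isfinite(y) & np.isfinite(np.asarray(X, dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    y, X = y[keep], X.loc[keep]
    _check_collinear(X)
    fit = sm.OLS(y, X).fit()
    coef = float(fit.params["group"])
    tval = float(fit.tvalues["group"])
    ci = fit.conf_int().loc["group"]
    return StatResult(
        name=name,
        route="glm",
        statistic=tval**2,  # F = t² for a single-df contrast
        df=(1, float(fit.df_resid)),
        p=float(fit.pvalues["group"]),
        effect={
            "coefficient": coef,
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "reference": str(labels[0]),
            "contrast": str(labels[1]),
        },
        n=int(keep.sum()),
        n_dropped=n_dropped,
    )


def logistic_or(
    outcome,
    predictor,
    scale_percent: bool = False,
    covariates: pd.DataFrame | None = None,
    name: str = "logistic",
) -> StatResult:
    """Binary logistic regression; OR = exp(coefficient) with Wald 95% CI.

    ``scale_percent`` multiplies the predictor by 100 before fitting, so the
    OR is per 0.01 increment of the raw predictor (the "percentage form" of
    a ratio index like ALPS). Complete separation raises instead of
    returning a silently huge OR.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y[np.isfinite(y)])) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    x = np.asarray(predictor, dtype=float)
    if scale_percent:
        x = 100.0 * x
    X = pd.DataFrame({"predictor": x})
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X.insert(0, "const", 1.0)
    keep = np.isfinite(y) & np.isfinite(np.asarray(X, dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    y, X = y[keep], X.loc[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    _check_collinear(X)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as exc:
        raise ValueError("complete separation in logistic regression") from exc
    beta = float(fit.params["predictor"])
    se = float(fit.bse["predictor"])
    if not np.isfinite(se) or abs(beta) > 50 or se > 50:
        raise ValueError("quasi-complete separation: unstable logistic estimate")
    z = sps.norm.ppf(0.975)
    return StatResult(
        name=name,
        route="logistic",
        statistic=(beta / se) ** 2,  # Wald chi-square
        df=1,
        p=float(fit.pvalues["predictor"]),
        effect={
            "or": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - z * se)),
            "ci_high": float(np.exp(beta + z * se)),
            "coefficient": beta,
            "per": "0.01 of the raw predictor" if scale_percent else "1 unit",
        },
        n=int(keep.sum()),
        n_dropped=n_dropped,
    )


def partial_correlation(x, y, covariates: pd.DataFrame | None = None, name: str = "partial_correlation") -> StatResult:
    """Pearson correlation of least-squares residuals of x and y on the
    covariates (with intercept); p from t with df = n − 2 − k.

    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=range(x.size))
    Z = np.asarray(covariates, dtype=float).reshape(x.size, -1)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(Z).all(axis=1)
    n_dropped = int((~keep).sum())
    x, y, Z = x[keep], y[keep], Z[keep]
    n, k = x.size, Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c * r_c))
    p = float(2 * sps.t.sf(abs(t), df))
    # Fisher-z interval
    zr = np.arctanh(r_c)
    zse = 1.0 / np.sqrt(n - k - 3) if n - k - 3 > 0 else np.inf
    zcrit = sps.norm.ppf(0.975)
    return StatResult(
        name=name,
        route="partial_correlation",
        statistic=float(t),
        df=df,
        p=p,
        effect={
            "r": r,
            "ci_low": float(np.tanh(zr - zcrit * zse)),
            "ci_high": float(np.tanh(zr + zcrit * zse)),
        },
        n=n,
        n_dropped=n_dropped,
    )


def two_sample_compare(values, groups, name: str = "two_sample") -> StatResult:
    """Gated two-group comparison: pooled-variance t-test when both groups
    pass Shapiro–Wilk and Levene passes, Mann–Whitney U otherwise."""
    labels, parts = _clean_groups(values, groups, min_n=2)
    if len(labels) != 2:
        raise ValueError(f"expected 2 groups, found {len(labels)}")
    gate_parts = parts
    try:
        parametric, gate = _gate_parametric(gate_parts)
    except ValueError:
        parametric, gate = False, {}
    n = sum(p.size for p in parts)
    if parametric:
        res = sps.ttest_ind(*parts, equal_var=True)
        route, stat, p, df = "t_test", float(res.statistic), float(res.pvalue), n - 2
    else:
        res = sps.mannwhitneyu(*parts, alternative="two-sided")
        route, stat, p, df = "mann_whitney", float(res.statistic), float(res.pvalue), None
    return StatResult(
        name=name,
        route=route,
        statistic=stat,
        df=df,
        p=p,
        n=n,
        effect=gate,
        descriptives=_describe(parts, labels, parametric),
    )


def chi_square_counts(table, name: str = "chi_square") -> StatResult:
    """Pearson chi-square on an r×c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2-D non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return StatResult(
        name=name,
        route="chi_square",
        statistic=float(stat),
        df=int(dof),
        p=float(p),
        n=int(t.sum()),
    )


# --------------------------------------------------------------------------
# full analysis roster

ALPS_COLUMNS = ("alps_left", "alps_right", "alps_mean")
HIPPO_COLUMNS = tuple(
    f"hippo_{m}_{s}" for m in ("fa", "md", "ad", "rd") for s in ("left", "right")
)
TABLE1_CONTINUOUS = (
    "age", "education", "bmi", "sbp", "dbp", "hba1c", "fpg", "fins", "homa_ir",
    "ldl", "hdl", "tg", "tc", "moca", "avlt_immediate", "avlt_5min",
    "avlt_delay", "avlt_recall", "gpt_r", "gpt_l", "dst_forward",
    "dst_backward", "cdt", "dsst", "tmt_a",
)
COGNITIVE_COLUMNS = (
    "moca", "avlt_immediate", "avlt_5min", "avlt_delay", "avlt_recall",
    "gpt_r", "gpt_l", "dst_forward", "dst_backward", "cdt", "dsst", "tmt_a",
)
#: Covariates of the ALPS × cognition partial correlations (all participants).
COGNITION_COVARIATES = (
    "gender", "age", "education", "sbp", "dbp", "fpg", "fins", "hba1c",
    "homa_ir", "bmi", "ldl", "hdl", "tg", "tc",
)
#: Covariates of the ALPS × hippocampus partial correlations.
HIPPO_COVARIATES = ("gender", "age", "education", "bmi")
#: Covariates of the DMNC-vs-DMMCI adjusted group contrast.
ANCOVA_COVARIATES = ("duration", "fpg", "ldl")

REQUIRED_COLUMNS = (
    ("subject_id", "group", "gender", "duration")
    + TABLE1_CONTINUOUS
    + ALPS_COLUMNS
    + HIPPO_COLUMNS
)


def expected_report_keys() -> list[str]:
    """The fixed key schema of ``run_full_stats`` output."""
    keys = [f"table1/{c}" for c in ("gender", "duration") + TABLE1_CONTINUOUS]
    keys += [f"table1_posthoc/{c}" for c in TABLE1_CONTINUOUS]
    for a in ALPS_COLUMNS:
        keys += [f"alps_omnibus/{a}", f"alps_posthoc/{a}", f"ancova/{a}", f"logistic/{a}"]
    keys += [f"alps_within_group/{g}" for g in GROUPS]
    keys += [f"alps_within_group_posthoc/{g}" for g in GROUPS]
    keys += [f"hippo_t2dm_vs_hc/{h}" for h in HIPPO_COLUMNS]
    for cohort in ("T2DM", "HC"):
        for a in ALPS_COLUMNS:
            for h in HIPPO_COLUMNS:
                keys.append(f"partialcorr_hippo/{cohort}/{a}~{h}")
    for a in ALPS_COLUMNS:
        for c in COGNITIVE_COLUMNS:
            keys.append(f"partialcorr_cog/{a}~{c}")
    return keys


def run_full_stats(cohort: pd.DataFrame, config: dict | None = None) -> dict[str, StatResult]:
    """Run the full analysis roster over a cohort table.

    Expects one row per subject with group ∈ {HC, DMNC, DMMCI}, the clinical
    and cognitive columns, the three ALPS indices, and the eight hippocampal
    metrics. Returns StatResults keyed by the fixed schema of
    ``expected_report_keys``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    df = cohort.copy()
    grp = df["group"].astype(str)
    is_t2dm = grp.isin(("DMNC", "DMMCI"))
    report: dict[str, StatResult] = {}

    # --- demographic/clinical/cognitive group comparisons
    counts = pd.crosstab(df["gender"], grp).reindex(columns=list(GROUPS))
    report["table1/gender"] = chi_square_counts(counts.to_numpy(), name="table1/gender")
    dm = df[is_t2dm]
    report["table1/duration"] = StatResult(
        name="table1/duration",
        route="kruskal_wallis",
        statistic=float(sps.kruskal(
            dm.loc[dm["group"] == "DMNC", "duration"].dropna(),
            dm.loc[dm["group"] == "DMMCI", "duration"].dropna(),
        ).statistic),
        df=1,
        p=float(sps.kruskal(
            dm.loc[dm["group"] == "DMNC", "duration"].dropna(),
            dm.loc[dm["group"] == "DMMCI", "duration"].dropna(),
        ).pvalue),
        n=int(dm["duration"].notna().sum()),
    )
    for col in TABLE1_CONTINUOUS:
        omni = omnibus_three_group(df[col], grp, name=f"table1/{col}")
        report[f"table1/{col}"] = omni
        report[f"table1_posthoc/{col}"] = posthoc_pairwise(
            df[col], grp, omni.route, name=f"table1_posthoc/{col}"
        )

    # --- three-group ALPS comparisons with BH-adjusted post hoc
    for a in ALPS_COLUMNS:
        omni = omnibus_three_group(df[a], grp, name=f"alps_omnibus/{a}")
        report[f"alps_omnibus/{a}"] = omni
        report[f"alps_posthoc/{a}"] = posthoc_pairwise(
            df[a], grp, omni.route, name=f"alps_posthoc/{a}"
        )

    # --- within-group comparison of the three ALPS variants
    for g in GROUPS:
        sub = df[grp == g]
        stacked = np.concatenate([sub[a].to_numpy(float) for a in ALPS_COLUMNS])
        labels = np.repeat(list(ALPS_COLUMNS), len(sub))
        omni = omnibus_three_group(stacked, labels, name=f"alps_within_group/{g}")
        report[f"alps_within_group/{g}"] = omni
        report[f"alps_within_group_posthoc/{g}"] = posthoc_pairwise(
            stacked, labels, omni.route, name=f"alps_within_group_posthoc/{g}"
        )

    # --- DMNC vs DMMCI adjusted contrast and MCI logistic models
    for a in ALPS_COLUMNS:
        report[f"ancova/{a}"] = ancova_group_effect(
            dm[a],
            dm["group"],
            covariates=dm[list(ANCOVA_COVARIATES)],
            name=f"ancova/{a}",
        )
        report[f"logistic/{a}"] = logistic_or(
            (dm["group"] == "DMMCI").astype(float),
            dm[a],
            scale_percent=True,
            name=f"logistic/{a}",
        )

    # --- hippocampal metrics: T2DM vs HC
    tvh = np.where(is_t2dm, "T2DM", "HC")
    for h in HIPPO_COLUMNS:
        report[f"hippo_t2dm_vs_hc/{h}"] = two_sample_compare(
            df[h], tvh, name=f"hippo_t2dm_vs_hc/{h}"
        )

    # --- partial correlations ALPS × hippocampus within T2DM and within HC
    for cohort_name, sel in (("T2DM", is_t2dm), ("HC", ~is_t2dm)):
        sub = df[sel]
        cov = sub[list(HIPPO_COVARIATES)].astype(float)
        for a in ALPS_COLUMNS:
            for h in HIPPO_COLUMNS:
                key = f"partialcorr_hippo/{cohort_name}/{a}~{h}"
                report[key] = partial_correlation(sub[a], sub[h], cov, name=key)

    # --- partial correlations ALPS × cognition in all participants
    cov_all = df[list(COGNITION_COVARIATES)].astype(float)
    for a in ALPS_COLUMNS:
        for c in COGNITIVE_COLUMNS:
            key = f"partialcorr_cog/{a}~{c}"
            report[key] = partial_correlation(df[a], df[c], cov_all, name=key)

    return report


def report_to_json_dict(report: dict[str, StatResult]) -> dict:
    return {k: v.to_dict() for k, v in report.items()}


def report_to_markdown(report: dict[str, StatResult]) -> str:
    """Human-readable Markdown summary of a full-stats report."""
    lines = ["# Cohort statistics report", ""]
    sections: dict[str, list[str]] = {}
    for key, res in report.items():
        section = key.split("/", 1)[0]
        sections.setdefault(section, []).append(key)
    for section, keys in sections.items():
        lines.append(f"## {section}")
        lines.append("")
        lines.append("| analysis | route | statistic | p |")
        lines.append("|---|---|---|---|")
        for key in keys:
            r = report[key]
            stat = "" if not np.isfinite(r.statistic) else f"{r.statistic:.4g}"
            lines.append(f"| {key} | {r.route} | {stat} | {r.p:.4g} |")
        lines.append("")
    return "\n".join(lines)
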