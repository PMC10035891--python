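"""Non-parametric group statistics.

ICC(1,1) run reliability, aligned-rank-transform (ART) mixed factorial
ANOVA, Friedman and Wilcoxon tests with rank effect sizes, permutation
Welch t-tests, Bonferroni correction, parametric-assumption checks, and the
seven-step decision flowchart that strings them together for a
two-group-by-runs design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "icc_1_1",
    "art_align",
    "art_anova",
    "friedman",
    "wilcoxon_paired",
    "wilcoxon_independent",
    "perm_welch_t",
    "assumption_checks",
    "bonferroni",
    "flowchart",
    "StatsReport",
]

ICC_BANDS = [
    (0.2, "low"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0 + 1e-12, "almost perfect"),
]


def icc_band(value: float) -> str:
    for upper, name in ICC_BANDS:
        if value <= upper:
            return name
    return "almost perfect"


def icc_1_1(ratings: np.ndarray) -> tuple[float, str]:
    """One-way random-effects, single-rater ICC (agreement across runs).

    ``ratings`` is subjects x runs with no missing cells.
    ``ICC = (BMS - WMS) / (BMS + (k - 1) * WMS)`` from the one-way ANOVA
    decomposition, with the qualitative band on the Landis-Koch scale.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be subjects x runs with >= 2 of each")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    bss = k * np.sum((row_means - grand) ** 2)
    wss = np.sum((x - row_means[:, None]) ** 2)
    bms = bss / (n - 1)
    wms = wss / (n * (k - 1))
    icc = (bms - wms) / (bms + (k - 1) * wms)
    return float(icc), icc_band(float(icc))


def _cell_means(df: pd.DataFrame, value: str, group: str, run: str):
    grand = df[value].mean()
    mu_g = df.groupby(group, observed=True)[value].mean()
    mu_r = df.groupby(run, observed=True)[value].mean()
    mu_gr = df.groupby([group, run], observed=True)[value].mean()
    return grand, mu_g, mu_r, mu_gr


def art_align(
    df: pd.DataFrame,
    effect: str,
    value: str = "value",
    group: str = "group",
    run: str = "run",
) -> np.ndarray:
    """Aligned response for one effect of a two-factor design.

    The response is stripped to its cell residual and the estimate of the
    effect of interest is added back:

    - ``"group"``:        residual + (group mean - grand mean)
    - ``"run"``:          residual + (run mean - grand mean)
    - ``"group:run"``:    residual + interaction estimate

    where residual = value - cell (group x run) mean. By construction the
    marginal means of every *other* effect are constant over the aligned
    response (the standard alignment diagnostic).
    """
    grand, mu_g, mu_r, mu_gr = _cell_means(df, value, group, run)
    g = df[group].to_numpy()
    r = df[run].to_numpy()
    y = df[value].to_numpy(dtype=float)
    cell = mu_gr.loc[list(zip(g, r))].to_numpy()
    resid = y - cell
    if effect == "group":
        est = mu_g.loc[g].to_numpy() - grand
    elif effect == "run":
        est = mu_r.loc[r].to_numpy() - grand
    elif effect == "group:run":
        est = cell - mu_g.loc[g].to_numpy() - mu_r.loc[r].to_numpy() + grand
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return resid + est


def _alignment_diagnostic(
    aligned: pd.DataFrame, effect: str, value: str, group: str, run: str
) -> float:
    """Max absolute stripped-effect estimate on the aligned response."""
    grand, mu_g, mu_r, mu_gr = _cell_means(aligned, value, group, run)
    devs = []
    inter = (
        mu_gr
        - mu_g.reindex(mu_gr.index.get_level_values(0)).to_numpy()
        - mu_r.reindex(mu_gr.index.get_level_values(1)).to_numpy()
        + grand
    )
    if effect != "group":
        devs.append(np.max(np.abs(mu_g.to_numpy() - grand)))
    if effect != "run":
        devs.append(np.max(np.abs(mu_r.to_numpy() - grand)))
    if effect != "group:run":
        devs.append(np.max(np.abs(inter.to_numpy())))
    return float(max(devs)) if devs else 0.0


def _mixed_anova_on_ranks(
    df: pd.DataFrame,
    ranks: np.ndarray,
    effect: str,
    subject: str,
    group: str,
    run: str,
) -> tuple[float, int, int, float]:
    """Balanced mixed (split-plot) factorial ANOVA F test for one effect.

    Group is between-subjects (error: subjects within groups); run and
    group x run are within-subjects (error: run x subject residual).
    """
    d = df.copy()
    d["_rank"] = ranks
    groups = sorted(d[group].unique())
    runs = sorted(d[run].unique())
    n_g, n_r = len(groups), len(runs)
    subj_means = d.groupby(subject, observed=True)["_rank"].mean()
    subj_group = d.groupby(subject, observed=True)[group].first()
    n_subj = len(subj_means)
    grand = d["_rank"].mean()
    mu_g = d.groupby(group, observed=True)["_rank"].mean()
    mu_r = d.groupby(run, observed=True)["_rank"].mean()
    mu_gr = d.groupby([group, run], observed=True)["_rank"].mean()
    counts_g = subj_group.value_counts()

    ss_group = n_r * sum(
        counts_g[g] * (mu_g[g] - grand) ** 2 for g in groups
    )
    ss_subj = n_r * sum(
        (subj_means[s] - mu_g[subj_group[s]]) ** 2 for s in subj_means.index
    )
    ss_run = n_subj * sum((mu_r[r] - grand) ** 2 for r in runs)
    ss_inter = sum(
        counts_g[g] * (mu_gr[(g, r)] - mu_g[g] - mu_r[r] + grand) ** 2
        for g in groups
        for r in runs
    )
    # run x subject residual
    resid = (
        d["_rank"].to_numpy()
        - subj_means.loc[d[subject]].to_numpy()
        - mu_gr.loc[list(zip(d[group], d[run]))].to_numpy()
        + mu_g.loc[d[group]].to_numpy()
    )
    ss_err = float(np.sum(resid**2))

    df_subj = n_subj - n_g
    df_err = df_subj * (n_r - 1)
    if effect == "group":
        df1, df2 = n_g - 1, df_subj
        ms1, ms2 = ss_group / df1, ss_subj / df2
    elif effect == "run":
        df1, df2 = n_r - 1, df_err
        ms1, ms2 = ss_run / df1, ss_err / df2
    elif effect == "group:run":
        df1, df2 = (n_g - 1) * (n_r - 1), df_err
        ms1, ms2 = ss_inter / df1, ss_err / df2
    else:
        raise ValueError(f"unknown effect {effect!r}")
    if ms2 <= 0:
        f_stat = np.inf if ms1 > 0 else 0.0
    else:
        f_stat = ms1 / ms2
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), df1, df2, p


def art_anova(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    group: str = "group",
    run: str = "run",
) -> dict[str, dict]:
    """Aligned-rank-transform mixed 2 x R factorial ANOVA.

    For each effect (group, run, group:run) the response is aligned for
    that effect, mid-ranked over the whole table, and a balanced
    split-plot ANOVA is fitted on the ranks with subject as the blocking
    factor. Requires every subject observed in every run (no imputation).

    Returns ``{effect: {"F", "df1", "df2", "p", "align_max_dev"}}``.
    """
    df = table[[subject, group, run, value]].dropna()
    if df.shape[0] != table.shape[0]:
        raise ValueError("missing cells are not supported (no imputation)")
    counts = df.groupby(subject, observed=True)[run].nunique()
    n_runs = df[run].nunique()
    if (counts != n_runs).any():
        bad = counts[counts != n_runs].index.tolist()
        raise ValueError(f"subjects missing runs: {bad}")
    if df[group].nunique() != 2:
        raise ValueError("exactly two groups required")

    results = {}
    for effect in ("group", "run", "group:run"):
        aligned_vals = art_align(df, effect, value=value, group=group, run=run)
        aligned_df = df.copy()
        aligned_df[value] = aligned_vals
        diag = _alignment_diagnostic(aligned_df, effect, value, group, run)
        ranks = sps.rankdata(aligned_vals)
        f_stat, df1, df2, p = _mixed_anova_on_ranks(
            df, ranks, effect, subject, group, run
        )
        results[effect] = {
            "F": f_stat,
            "df1": df1,
            "df2": df2,
            "p": p,
            "align_max_dev": diag,
        }
    return results


def friedman(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman repeated-measures test over runs (columns).

    Returns ``(chi2, p)``; identical columns give chi2 = 0, p = 1.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        # scipy requires >= 3 measurements; for 2 fall back to paired Wilcoxon
        raise ValueError("need a subjects x runs matrix with >= 3 runs")
    if np.allclose(x, x[:, [0]]):
        return 0.0, 1.0
    res = sps.friedmanchisquare(*[x[:, j] for j in range(x.shape[1])])
    return float(res.statistic), float(res.pvalue)


_EXACT_N = 25


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Paired Wilcoxon signed-rank test with rank effect size.

    Exact p for <= 25 non-zero differences (no ties), normal approximation
    with continuity correction above. ``z`` always comes from the normal
    approximation; effect size ``r = |z| / sqrt(N)`` with N the total
    number of observations (both members of each pair).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    n_total = 2 * x.size
    if nz.size == 0:
        return {"statistic": 0.0, "z": 0.0, "p": 1.0, "r": 0.0, "n": n_total}
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    method = "approx" if (nz.size > _EXACT_N or has_ties) else "exact"
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True, method=method)
    approx = sps.wilcoxon(
        x, y, zero_method="wilcox", correction=True, method="approx"
    )
    z = float(approx.zstatistic)
    return {
        "statistic": float(res.statistic),
        "z": z,
        "p": float(res.pvalue),
        "r": abs(z) / np.sqrt(n_total),
        "n": n_total,
    }


def wilcoxon_independent(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Independent two-sample rank-sum (Mann-Whitney) test with effect size.

    Exact p for small tie-free samples, otherwise normal approximation
    with continuity and tie correction. ``r = |z| / sqrt(n1 + n2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(n1, n2) <= _EXACT_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        z = 0.0
    else:
        num = u - mean_u
        num -= 0.5 * np.sign(num)  # continuity correction
        z = num / np.sqrt(var_u)
    return {
        "statistic": u,
        "z": float(z),
        "p": float(res.pvalue),
        "r": abs(float(z)) / np.sqrt(n),
        "n": n,
    }


def welch_t_stat(x: np.ndarray, y: np.ndarray) -> float:
    vx = np.var(x, ddof=1) / x.size
    vy = np.var(y, ddof=1) / y.size
    denom = np.sqrt(vx + vy)
    if denom == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / denom)


def perm_welch_t(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Two-sided permutation Welch t-test.

    ``p = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1)`` over random label
    permutations (add-one estimator, so p is never exactly 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    rng = np.random.default_rng(seed)
    t_obs = welch_t_stat(x, y)
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size

    # vectorized label permutations: argsort of uniforms is a random perm
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm_data = pooled[order]
    px, py = perm_data[:, :n1], perm_data[:, n1:]
    vx = np.var(px, axis=1, ddof=1) / n1
    vy = np.var(py, axis=1, ddof=1) / n2
    denom = np.sqrt(vx + vy)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(
            denom > 0, (px.mean(axis=1) - py.mean(axis=1)) / denom, 0.0
        )
    count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-14))
    p = (1 + count) / (n_perm + 1)
    return t_obs, float(p)


def assumption_checks(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Shapiro-Wilk normality per sample, Levene variance test, Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3 per sample")
    sh_x = sps.shapiro(x).pvalue
    sh_y = sps.shapiro(y).pvalue
    lev = sps.levene(x, y).pvalue
    n1, n2 = x.size, y.size
    pooled_sd = np.sqrt(
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1))
        / (n1 + n2 - 2)
    )
    d = 0.0 if pooled_sd == 0 else (np.mean(x) - np.mean(y)) / pooled_sd
    return {
        "shapiro_p_x": float(sh_x),
        "shapiro_p_y": float(sh_y),
        "levene_p": float(lev),
        "cohens_d": float(d),
    }


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction ``p_corr = min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


@dataclass
class StatsReport:
    """Result of the seven-step flowchart with a full decision trace."""

    effects: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=list)
    trace: list = field(default_factory=list)
    alpha: float = 0.05

    def retained_contrasts(self) -> list[dict]:
        return [c for c in self.contrasts if c.get("retained")]

    def to_json(self, **kwargs) -> str:
        def default(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not serializable: {type(obj)}")

        payload = {
            "alpha": self.alpha,
            "effects": self.effects,
            "contrasts": self.contrasts,
            "trace": self.trace,
        }
        return json.dumps(payload, default=default, indent=2, **kwargs)


def _pivot(table: pd.DataFrame, value: str, subject: str, run: str) -> pd.DataFrame:
    return table.pivot_table(index=subject, columns=run, values=value, observed=True)


def flowchart(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    group: str = "group",
    run: str = "run",
    alpha: float = 0.05,
) -> StatsReport:
    """Seven-step non-parametric testing of group differences across runs.

    1. ART mixed 2 x R ANOVA (Bonferroni over the three effects).
    2./3. If the interaction is significant: per-group Friedman test and
       paired Wilcoxon run drivers.
    6. Per-run independent Wilcoxon group contrasts.
    4./5. Otherwise, if the run main effect is significant: pooled
       Friedman and paired Wilcoxon run drivers.
    7. If the group main effect is significant: independent Wilcoxon on
       subject-mean values across all runs.

    A group contrast is *retained* only when its effect size exceeds the
    largest significant run-driver effect size.
    """
    report = StatsReport(alpha=alpha)
    groups = sorted(table[group].unique())
    runs = sorted(table[run].unique())

    if len(runs) < 2:
        g0 = table.loc[table[group] == groups[0], value].to_numpy()
        g1 = table.loc[table[group] == groups[1], value].to_numpy()
        w = wilcoxon_independent(g0, g1)
        c = {
            "type": "group",
            "scope": "single_run",
            **w,
            "p_corrected": float(min(1.0, w["p"])),
            "significant": w["p"] < alpha,
            "retained": w["p"] < alpha,
        }
        report.contrasts.append(c)
        report.trace.append(
            {"step": 7, "action": "single-run independent Wilcoxon", "p": w["p"]}
        )
        return report

    art = art_anova(table, value=value, subject=subject, group=group, run=run)
    raw_ps = [art[e]["p"] for e in ("group", "run", "group:run")]
    corr_ps = bonferroni(raw_ps, m=3)
    for e, pc in zip(("group", "run", "group:run"), corr_ps):
        art[e]["p_corrected"] = float(pc)
        art[e]["significant"] = bool(pc < alpha)
    report.effects = art
    report.trace.append(
        {
            "step": 1,
            "action": "ART 2xR mixed ANOVA",
            "p_corrected": {e: art[e]["p_corrected"] for e in art},
        }
    )

    max_run_r = 0.0
    run_pairs = list(combinations(runs, 2))

    def run_drivers(sub_table: pd.DataFrame, scope: str) -> None:
        nonlocal max_run_r
        wide = _pivot(sub_table, value, subject, run)
        if wide.shape[1] >= 3:
            chi2, p_f = friedman(wide.to_numpy())
        else:
            chi2, p_f = float("nan"), 0.0  # 2 runs: go straight to Wilcoxon
        step = 2 if scope != "pooled" else 4
        report.trace.append(
            {"step": step, "action": f"Friedman ({scope})", "chi2": chi2, "p": p_f}
        )
        if p_f >= alpha:
            return
        pair_results = []
        for r1, r2 in run_pairs:
            w = wilcoxon_paired(wide[r1].to_numpy(), wide[r2].to_numpy())
            pair_results.append((r1, r2, w))
        pcorr = bonferroni([w["p"] for _, _, w in pair_results], m=len(pair_results))
        for (r1, r2, w), pc in zip(pair_results, pcorr):
            sig = bool(pc < alpha)
            if sig:
                max_run_r = max(max_run_r, w["r"])
            report.contrasts.append(
                {
                    "type": "run",
                    "scope": scope,
                    "pair": (r1, r2),
                    **w,
                    "p_corrected": float(pc),
                    "significant": sig,
                    "retained": False,
                }
            )
        report.trace.append(
            {
                "step": step + 1,
                "action": f"paired Wilcoxon run drivers ({scope})",
                "n_significant": int(sum(pc < alpha for pc in pcorr)),
            }
        )

    def group_contrast(x: np.ndarray, y: np.ndarray, scope, m: int, step: int):
        w = wilcoxon_independent(x, y)
        pc = float(min(1.0, m * w["p"]))
        sig = bool(pc < alpha)
        retained = bool(sig and w["r"] > max_run_r)
        report.contrasts.append(
            {
                "type": "group",
                "scope": scope,
                **w,
                "p_corrected": pc,
                "significant": sig,
                "retained": retained,
            }
        )
        return w, pc

    if art["group:run"]["significant"]:
        for g in groups:
            run_drivers(table[table[group] == g], scope=g)
        for r in runs:
            sub = table[table[run] == r]
            x = sub.loc[sub[group] == groups[0], value].to_numpy()
            y = sub.loc[sub[group] == groups[1], value].to_numpy()
            group_contrast(x, y, scope=f"run_{r}", m=len(runs), step=6)
        report.trace.append(
            {"step": 6, "action": "independent Wilcoxon per run", "n_runs": len(runs)}
        )
    else:
        if art["run"]["significant"]:
            run_drivers(table, scope="pooled")
        if art["group"]["significant"]:
            wide = _pivot(table, value, subject, run)
            subj_mean = wide.mean(axis=1)
            subj_group = table.groupby(subject, observed=True)[group].first()
            x = subj_mean[subj_group == groups[0]].to_numpy()
            y = subj_mean[subj_group == groups[1]].to_numpy()
            group_contrast(x, y, scope="all_runs", m=1, step=7)
            report.trace.append(
                {"step": 7, "action": "independent Wilcoxon across all runs"}
            )
        if not (art["run"]["significant"] or art["group"]["significant"]):
            report.trace.append(
                {"step": 1, "action": "no significant effects; stop"}
            )
    return report
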