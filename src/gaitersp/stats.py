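"""Split-plot (mixed) repeated-measures ANOVA, GG correction, post hoc tests.

The design has one between-subject factor (group) and one or more fully
crossed within-subject factors (condition, time window, ROI).  Each
within-involving effect is built from orthonormal (Helmert) contrasts of
the within cells and tested against its own effect x subject(group) error
stratum; the between effect is tested against subject(group).  For effects
with more than two levels the Greenhouse-Geisser epsilon is estimated from
the pooled error covariance of the contrast scores and applied to both
degrees of freedom unconditionally (conservative; no sphericity pre-test).
Uncorrected p-values are reported alongside.  Group sizes may differ (the
within design must be complete); with equal group sizes the decomposition
reduces exactly to the classical split-plot sums of squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.linalg import helmert


@dataclass
class MixedAnovaResult:
    """Per-effect SS, df, GG epsilon, F, p (uncorrected and GG), partial eta^2."""

    table: pd.DataFrame
    dv: str = ""
    within: tuple[str, ...] = ()
    between: str = ""
    ss_total: float = float("nan")
    n_subjects_per_group: dict[str, int] = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return rows.iloc[0]

    def p(self, name: str, corrected: bool = True) -> float:
        row = self.effect(name)
        return float(row["p_gg"] if corrected else row["p_unc"])


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows orthogonal to the constant."""
    if k < 2:
        raise ValueError("a within factor needs at least 2 levels")
    return helmert(k)


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an n x k matrix of level scores.

    Box's correction computed from the sample covariance of the k repeated
    measures projected onto orthonormal contrasts:
    ``eps = tr(M)^2 / ((k-1) tr(M^2))`` with ``M = C S C'``.  Bounded by
    ``[1/(k-1), 1]``; exactly 1 for k = 2.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x levels")
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 levels")
    if n < k:
        raise ValueError(f"need at least as many subjects ({n}) as levels ({k})")
    C = _orthonormal_contrast(k)
    S = np.cov(data, rowvar=False)
    M = C @ S @ C.T
    tr = float(np.trace(M))
    tr2 = float(np.trace(M @ M))
    if tr2 <= 0:
        return 1.0
    return float(tr * tr / ((k - 1) * tr2))


def _effect_contrast(
    subset: tuple[str, ...], within: tuple[str, ...], levels: dict[str, list]
) -> np.ndarray:
    """Kronecker contrast over all within factors (contrast in subset, mean out)."""
    C = np.ones((1, 1))
    for f in within:
        k = len(levels[f])
        block = _orthonormal_contrast(k) if f in subset else np.full((1, k), k ** -0.5)
        C = np.kron(C, block)
    return C


def _pivot_complete(
    table: pd.DataFrame, dv: str, within: tuple[str, ...], subject: str
) -> tuple[np.ndarray, pd.Index, dict[str, list]]:
    counts = table.groupby([subject, *within], sort=False).size()
    if (counts > 1).any():
        dup = counts[counts > 1].index[:5].tolist()
        raise ValueError(f"duplicate observations for cells {dup}")
    levels = {f: list(pd.unique(table[f])) for f in within}
    piv = table.pivot_table(index=subject, columns=list(within), values=dv,
                            aggfunc="first", sort=False)
    if len(within) == 1:
        full = pd.Index(levels[within[0]], name=within[0])
    else:
        full = pd.MultiIndex.from_product([levels[f] for f in within], names=list(within))
    piv = piv.reindex(columns=full)
    if piv.isna().any().any():
        missing = [
            (subj, col)
            for subj in piv.index
            for col in piv.columns[piv.loc[subj].isna()]
        ][:5]
        raise ValueError(f"incomplete design; missing cells (first 5): {missing}")
    return piv.to_numpy(dtype=float), piv.index, levels


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str] | tuple[str, ...],
    between: str,
    subject: str = "subject_id",
) -> MixedAnovaResult:
    """Split-plot ANOVA of a complete within design with a group factor.

    Raises on duplicated or missing subject x within cells and when a group
    has fewer than two subjects.  Zero-variance (constant) strata report
    F = 0, p = 1 so null-simulation sweeps never crash.
    """
    within = tuple(within)
    if not within:
        raise ValueError("need at least one within-subject factor")
    Y, subjects, levels = _pivot_complete(table, dv, within, subject)
    n, p = Y.shape

    grp_per_subject = table.groupby(subject, sort=False)[between].agg(pd.unique)
    if (grp_per_subject.apply(len) != 1).any():
        bad = grp_per_subject[grp_per_subject.apply(len) != 1].index.tolist()
        raise ValueError(f"subjects assigned to multiple groups: {bad}")
    grp = grp_per_subject.apply(lambda x: x[0]).reindex(subjects)
    group_levels = list(pd.unique(grp))
    G = len(group_levels)
    if G < 2:
        raise ValueError("need at least two groups")
    sizes = grp.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"each group needs at least 2 subjects; too small: {small}")

    codes = grp.map({g: i for i, g in enumerate(group_levels)}).to_numpy()
    X = np.zeros((n, G))
    X[:, 0] = 1.0
    for j in range(G - 1):
        X[codes == j, j + 1] = 1.0
    X[codes == G - 1, 1:] = -1.0

    XtX_inv = np.linalg.inv(X.T @ X)
    proj = XtX_inv @ X.T
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    tol = 1e-12 * max(ss_total, 1.0)

    def glh(T: np.ndarray, L: list[int]) -> tuple[float, float, np.ndarray]:
        """General linear hypothesis SS for coefficient rows L, plus residuals."""
        B = proj @ T
        resid = T - X @ B
        LB = B[L, :]
        M = XtX_inv[np.ix_(L, L)]
        ssh = float(np.sum(LB * np.linalg.solve(M, LB)))
        sse = float(np.sum(resid ** 2))
        return ssh, sse, resid

    def f_and_p(ssh, dfh, sse, dfe):
        if sse < tol:
            if ssh < tol:
                return 0.0, 1.0, 0.0
            return float("inf"), 0.0, 1.0
        F = (ssh / dfh) / (sse / dfe)
        return F, float(spstats.f.sf(F, dfh, dfe)), ssh / (ssh + sse)

    rows: list[dict] = []

    # between-subject effect, tested against subject(group)
    C0 = _effect_contrast((), within, levels)
    T0 = Y @ C0.T
    ssh, sse, _ = glh(T0, list(range(1, G)))
    F, p_unc, np2 = f_and_p(ssh, G - 1, sse, n - G)
    rows.append({"effect": between, "ss": ssh, "ss_error": sse, "df1": float(G - 1),
                 "df2": float(n - G), "eps": np.nan, "F": F, "p_unc": p_unc,
                 "p_gg": p_unc, "np2": np2, "stratum": "subject(group)"})

    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            C = _effect_contrast(subset, within, levels)
            q = C.shape[0]
            T = Y @ C.T
            ssh_w, sse_w, resid = glh(T, [0])
            ssh_i, _, _ = glh(T, list(range(1, G)))
            dfe = q * (n - G)
            Sigma = (resid.T @ resid) / (n - G)
            tr, tr2 = float(np.trace(Sigma)), float(np.trace(Sigma @ Sigma))
            eps = 1.0 if (q == 1 or tr2 <= 0) else tr * tr / (q * tr2)
            stratum = ":".join(subset) + " x subject(group)"
            for name, ssh, dfh in (
                (":".join(subset), ssh_w, float(q)),
                (":".join(subset) + f":{between}", ssh_i, float(q * (G - 1))),
            ):
                F, p_unc, np2 = f_and_p(ssh, dfh, sse_w, dfe)
                if q > 1 and np.isfinite(F) and F > 0:
                    p_gg = float(spstats.f.sf(F, eps * dfh, eps * dfe))
                else:
                    p_gg = p_unc
                rows.append({"effect": name, "ss": ssh, "ss_error": sse_w,
                             "df1": dfh, "df2": float(dfe), "eps": eps, "F": F,
                             "p_unc": p_unc, "p_gg": p_gg, "np2": np2,
                             "stratum": stratum})

    result = pd.DataFrame(rows)
    return MixedAnovaResult(
        table=result, dv=dv, within=within, between=between, ss_total=ss_total,
        n_subjects_per_group={g: int(sizes[g]) for g in group_levels},
    )


def _t_from_samples(a: np.ndarray, b: np.ndarray, kind: str) -> tuple[float, float, float]:
    if kind == "independent":
        na, nb = len(a), len(b)
        df = na + nb - 2
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        diff = a.mean() - b.mean()
    elif kind == "paired":
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        df = len(d) - 1
        se = d.std(ddof=1) / np.sqrt(len(d))
        diff = d.mean()
    else:
        raise ValueError("kind must be 'independent' or 'paired'")
    if df < 1:
        raise ValueError("not enough observations for a t-test")
    if se == 0:
        t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return float(t), float(df), p
    t = diff / se
    return float(t), float(df), float(2 * spstats.t.sf(abs(t), df))


def posthoc_tests(
    table: pd.DataFrame,
    contrasts: list[dict],
    dv: str,
    subject: str = "subject_id",
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Classical pooled-variance / difference-score t-tests over a contrast family.

    Each contrast is ``{"label", "kind": "independent"|"paired", "a": {col: value},
    "b": {col: value}}``; the cell filters select rows of ``table``.  Bonferroni
    adjusts over the declared family (``p_adj = min(1, m * p)``).
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    m = len(contrasts)
    rows = []
    for c in contrasts:
        kind = c["kind"]

        def select(filt: dict) -> pd.DataFrame:
            sel = table
            for col, val in filt.items():
                if col not in table.columns or val not in set(table[col]):
                    raise ValueError(f"unknown cell {col}={val!r} in contrast {c['label']!r}")
                sel = sel[sel[col] == val]
            if sel.empty:
                raise ValueError(f"contrast {c['label']!r} selects no rows")
            return sel

        sa, sb = select(c["a"]), select(c["b"])
        if kind == "paired":
            merged = sa.set_index(subject)[dv].to_frame("a").join(
                sb.set_index(subject)[dv].to_frame("b"), how="inner")
            if merged.empty:
                raise ValueError(f"contrast {c['label']!r}: no common subjects to pair")
            a, b = merged["a"].to_numpy(), merged["b"].to_numpy()
        else:
            a, b = sa[dv].to_numpy(), sb[dv].to_numpy()
        t, df, p_raw = _t_from_samples(a, b, kind)
        p_adj = min(1.0, m * p_raw) if correction == "bonferroni" else p_raw
        rows.append({"contrast": c["label"], "kind": kind, "t": t, "df": df,
                     "p_raw": p_raw, "p_adjusted": p_adj, "n_comparisons": m})
    return pd.DataFrame(rows)


def analyze_speed(
    speed_table: pd.DataFrame,
    dv: str = "speed",
    subject: str = "subject_id",
) -> tuple[MixedAnovaResult, pd.DataFrame]:
    """Walking-speed analysis: 3 (condition) x 2 (group) split-plot ANOVA.

    ``speed_table`` holds per-subject per-condition mean speeds.  Follow-up:
    per-condition between-group independent t-tests, Bonferroni-corrected
    over the three comparisons.
    """
    anova = mixed_anova(speed_table, dv=dv, within=["condition"],
                        between="group", subject=subject)
    groups = list(pd.unique(speed_table["group"]))
    conditions = list(pd.unique(speed_table["condition"]))
    contrasts = [
        {"label": f"{groups[0]} vs {groups[1]} | {cond}", "kind": "independent",
         "a": {"group": groups[0], "condition": cond},
         "b": {"group": groups[1], "condition": cond}}
        for cond in conditions
    ]
    tests = posthoc_tests(speed_table, contrasts, dv=dv, subject=subject)
    return anova, tests
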