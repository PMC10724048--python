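"""Brute-force split-plot ANOVA oracle for balanced designs.

Computes the classical sums-of-squares decomposition directly from marginal
means with inclusion-exclusion on a full (group, subject, within...) data
grid.  Deliberately independent of the package's contrast-based GLM: no
contrast matrices, no regression; nothing but means and subtractions.
"""

from __future__ import annotations

import itertools

import numpy as np

GROUP_AXIS = "G"
SUBJECT_AXIS = "S"


def _terms(y: np.ndarray, within_names: list[str]) -> dict[frozenset, np.ndarray]:
    """Effect terms (full-grid broadcast) for every admissible factor subset.

    ``y`` has axes (group, subject-within-group, w1, w2, ...).  Admissible
    subsets are any subset of {G, w...} plus any subset containing both G
    and S (subjects are nested in groups, so S never appears without G).
    """
    names = [GROUP_AXIS, SUBJECT_AXIS] + within_names
    axes = {name: i for i, name in enumerate(names)}
    all_sets = []
    factors = [GROUP_AXIS] + within_names
    for r in range(len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            all_sets.append(frozenset(sub))
            if GROUP_AXIS in sub:
                all_sets.append(frozenset(sub) | {SUBJECT_AXIS})
    all_sets = sorted(set(all_sets), key=len)

    terms: dict[frozenset, np.ndarray] = {}
    for sub in all_sets:
        collapse = tuple(axes[n] for n in names if n not in sub)
        margin = y.mean(axis=collapse, keepdims=True)
        est = np.broadcast_to(margin, y.shape).copy()
        for prev, val in terms.items():
            if prev < sub:
                est -= val
        terms[sub] = est
    return terms


def split_plot_oracle(y: np.ndarray, within_names: list[str]) -> dict[str, dict]:
    """All split-plot effects of a balanced design, from first principles.

    Returns a mapping from effect name (within factors joined by ':',
    interactions with the group factor suffixed ':G') to
    ``{ss, ss_error, df1, df2, F, np2}``.
    """
    terms = _terms(y, within_names)

    def ss(sub: frozenset) -> float:
        return float((terms[sub] ** 2).sum())

    g, s = y.shape[0], y.shape[1]
    k = {name: y.shape[2 + i] for i, name in enumerate(within_names)}

    out: dict[str, dict] = {}
    # between effect against subject(group)
    ssh, sse = ss(frozenset({GROUP_AXIS})), ss(frozenset({GROUP_AXIS, SUBJECT_AXIS}))
    df1, df2 = g - 1, g * (s - 1)
    out["G"] = {"ss": ssh, "ss_error": sse, "df1": df1, "df2": df2,
                "F": (ssh / df1) / (sse / df2), "np2": ssh / (ssh + sse)}

    for r in range(1, len(within_names) + 1):
        for sub in itertools.combinations(within_names, r):
            fs = frozenset(sub)
            dfw = int(np.prod([k[n] - 1 for n in sub]))
            sse = ss(fs | {GROUP_AXIS, SUBJECT_AXIS})
            df2 = dfw * g * (s - 1)
            for name, hset, df1 in (
                (":".join(sub), fs, dfw),
                (":".join(sub) + ":G", fs | {GROUP_AXIS}, dfw * (g - 1)),
            ):
                ssh = ss(hset)
                out[name] = {"ss": ssh, "ss_error": sse, "df1": df1, "df2": df2,
                             "F": (ssh / df1) / (sse / df2),
                             "np2": ssh / (ssh + sse)}
    return out


def oracle_total_ss(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def random_balanced_table(
    rng: np.random.Generator,
    n_per_group: int,
    within_levels: dict[str, int],
):
    """A random balanced split-plot data set as (tidy DataFrame, data grid)."""
    import pandas as pd

    names = list(within_levels)
    shape = (2, n_per_group, *within_levels.values())
    y = rng.standard_normal(shape)
    rows = []
    for gi, group in enumerate(("A", "B")):
        for si in range(n_per_group):
            for combo in itertools.product(*(range(within_levels[n]) for n in names)):
                rows.append({
                    "subject_id": f"{group}{si}",
                    "group": group,
                    **{n: f"{n}{c}" for n, c in zip(names, combo)},
                    "y": y[(gi, si, *combo)],
                })
    return pd.DataFrame(rows), y
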