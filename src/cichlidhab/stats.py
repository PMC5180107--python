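"""Within-ecomorph habitat-preference statistics.

Per-individual depth (or inclination) observations are compared among the
species of an ecomorph with a one-way ANOVA followed by Tukey's honestly
significant difference test, and the pairwise outcomes are condensed into
a compact letter display: species sharing a letter are not significantly
different at the chosen alpha.  Gaussian GLMs relate cell depth to
substratum class (with Tukey contrasts) and to substratum inclination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    mean_difference: float
    p_adjusted: float
    significant: bool


def _as_groups(obs) -> dict[str, np.ndarray]:
    if isinstance(obs, pd.DataFrame):
        label_col, value_col = obs.columns[:2]
        return {
            str(k): g[value_col].to_numpy(float) for k, g in obs.groupby(label_col, sort=True)
        }
    return {str(k): np.asarray(v, dtype=float) for k, v in obs.items()}


def _check_groups(groups: dict[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    pooled = np.concatenate(list(groups.values()))
    within = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    if pooled.var() == 0:
        raise ValueError("all observations identical: zero total variance")
    if within == 0:
        raise ValueError("zero within-group variance: F statistic undefined")


def one_way_anova(obs) -> dict:
    """One-way ANOVA across species groups.

    ``obs`` is either a mapping label -> 1D values or a two-column
    DataFrame (label, value).  Returns F, degrees of freedom and p.
    """
    groups = _as_groups(obs)
    _check_groups(groups)
    F, p = sps.f_oneway(*groups.values())
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    return {"F": float(F), "df_between": k - 1, "df_within": n - k, "p": float(p)}


def tukey_pairwise(obs, alpha: float = 0.05) -> list[PairwiseResult]:
    """All unordered pairwise comparisons with Tukey-HSD adjusted p-values."""
    groups = _as_groups(obs)
    _check_groups(groups)
    labels = list(groups.keys())
    res = sps.tukey_hsd(*groups.values())
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            diff = float(groups[labels[i]].mean() - groups[labels[j]].mean())
            out.append(
                PairwiseResult(
                    pair=(labels[i], labels[j]),
                    mean_difference=diff,
                    p_adjusted=p,
                    significant=p < alpha,
                )
            )
    return out


def compact_letters(pairwise: list[PairwiseResult], means: dict[str, float] | None = None
                    ) -> dict[str, str]:
    """Compact letter display from pairwise significance (insert-and-absorb).

    Two groups share at least one letter iff their comparison is
    non-significant.  Letters are assigned in order of group means when
    ``means`` is given, else in label order.
    """
    labels = sorted({l for r in pairwise for l in r.pair})
    sig: dict[frozenset, bool] = {}
    for r in pairwise:
        key = frozenset(r.pair)
        if key in sig and sig[key] != r.significant:
            raise ValueError(f"inconsistent significance for pair {tuple(r.pair)}")
        sig[key] = r.significant
    expected = {frozenset((a, b)) for i, a in enumerate(labels) for b in labels[i + 1:]}
    if set(sig) != expected:
        raise ValueError("pairwise results must cover every unordered pair exactly")

    if means:
        labels = sorted(labels, key=lambda l: means[l])

    # insert-and-absorb: columns are sets of mutually non-different groups
    columns: list[set[str]] = [set(labels)]
    for key, is_sig in sig.items():
        if not is_sig:
            continue
        a, b = sorted(key, key=labels.index)
        for col in list(columns):
            if a in col and b in col:
                col_a = col - {b}
                col_b = col - {a}
                columns.remove(col)
                for new in (col_a, col_b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # absorb any residual subset columns
    columns = [c for c in columns if not any(c < o for o in columns if o is not c)]
    # order columns by the earliest group they contain, so letter 'a' goes
    # to the lowest-mean block
    columns.sort(key=lambda c: min(labels.index(l) for l in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {l: "" for l in labels}
    for letter, col in zip(alphabet, columns):
        for l in labels:
            if l in col:
                assignment[l] += letter
    return assignment


def letters_consistent(pairwise: list[PairwiseResult], letters: dict[str, str]) -> bool:
    """Check that letter sharing reproduces the significance relation."""
    for r in pairwise:
        a, b = r.pair
        share = bool(set(letters[a]) & set(letters[b]))
        if share == r.significant:
            return False
    return True


def species_letter_analysis(observations: pd.DataFrame, alpha: float = 0.05) -> dict:
    """ANOVA + Tukey + letters for one ecomorph's per-individual values."""
    groups = _as_groups(observations)
    anova = one_way_anova(groups)
    pairwise = tukey_pairwise(groups, alpha=alpha)
    means = {k: float(v.mean()) for k, v in groups.items()}
    letters = compact_letters(pairwise, means=means)
    return {"anova": anova, "pairwise": pairwise, "means": means, "letters": letters}


def fit_depth_glms(cell_attrs: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Gaussian GLMs of cell depth on substratum class and on inclination.

    Returns the depth-by-substratum fit with Tukey pairwise contrasts
    (skipped with a notice when fewer than two classes are present) and
    the depth-versus-inclination slope with its p-value.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    out: dict = {}
    df = cell_attrs.rename(columns={"mean_depth_m": "depth", "inclination_deg": "inclination"})

    if "substratum" in df.columns:
        classes = [c for c in df["substratum"].unique()]
        if len(classes) >= 2:
            fit = smf.ols("depth ~ C(substratum)", data=df).fit()
            groups = {c: g["depth"].to_numpy(float) for c, g in df.groupby("substratum")}
            groups = {c: v for c, v in groups.items() if len(v) >= 2}
            if df["depth"].var() == 0:
                # degenerate flat depth: every contrast is exactly zero
                labels = sorted(groups)
                contrasts = [
                    PairwiseResult((a, b), 0.0, 1.0, False)
                    for i, a in enumerate(labels)
                    for b in labels[i + 1:]
                ]
            elif len(groups) >= 2:
                contrasts = tukey_pairwise(groups, alpha=alpha)
            else:
                contrasts = []
            out["substratum"] = {
                "model": fit,
                "class_means": df.groupby("substratum")["depth"].mean().to_dict(),
                "contrasts": contrasts,
            }
        else:
            out["substratum"] = {"notice": "single substratum class: contrasts skipped"}

    X = sm.add_constant(df["inclination"].to_numpy(float))
    incl_fit = sm.OLS(df["depth"].to_numpy(float), X).fit()
    out["inclination"] = {
        "slope": float(incl_fit.params[1]),
        "p": float(incl_fit.pvalues[1]),
        "model": incl_fit,
    }
    return out


def pairwise_to_frame(pairwise: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_a": [r.pair[0] for r in pairwise],
            "species_b": [r.pair[1] for r in pairwise],
            "mean_difference": [r.mean_difference for r in pairwise],
            "p_adjusted": [r.p_adjusted for r in pairwise],
            "significant": [r.significant for r in pairwise],
        }
    )
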