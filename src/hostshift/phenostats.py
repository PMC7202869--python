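"""Endpoint statistics: consistent-DE core sets, symbiont titer, probit LC50.

* ``core_de_intersect`` finds genes differentially expressed with the same
  sign in every one of a set of pairwise comparisons (the k-way consistent
  intersection; with independent per-table significance rate r the expected
  number of surviving background genes is about N * r**k).
* ``relative_titer`` quantifies endosymbiont abundance as the copy number
  of a symbiont-specific gene relative to two host single-copy genes, via
  the ddCt machinery.
* ``anova_tukey`` runs a one-way fixed-effects ANOVA with Tukey HSD and a
  compact letter display (groups sharing a letter are not significantly
  different).
* ``probit_lc50`` fits mortality ~ probit(a + b log10 dose) by IRLS after
  Abbott-correcting for control mortality, and reports the LC50 with its
  Fieller 95% interval.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genefate import FoldEstimate, ddct_fold


# ---------------------------------------------------------------------------
# Consistent-DE intersection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreDEResult:
    core: dict[str, str]              # gene -> "up" | "down"
    n_comparisons: int
    excluded_missing: dict[str, int]  # gene -> number of tables it was absent from


def core_de_intersect(
    tables: Mapping[object, pd.DataFrame] | Sequence[pd.DataFrame],
    q_threshold: float = 0.05,
    min_abs_lfc: float = 0.0,
) -> CoreDEResult:
    """Genes significant with a consistent sign in every comparison.

    A gene is core iff in EVERY table q <= q_threshold,
    |log2fc| >= min_abs_lfc, and the sign of log2fc never flips.  A gene
    absent from any table is excluded (not imputed) and counted in the
    report.  Relaxing q_threshold can only grow the core set.
    """
    if hasattr(tables, "values"):
        dfs = list(tables.values())
    else:
        dfs = list(tables)
    if not dfs:
        return CoreDEResult(core={}, n_comparisons=0, excluded_missing={})
    universe: set[str] = set()
    for df in dfs:
        universe |= set(df["gene"])
    core: dict[str, str] = {}
    excluded: dict[str, int] = {}
    for gene in sorted(universe):
        sign = None
        ok = True
        missing = 0
        for df in dfs:
            rows = df[df["gene"] == gene]
            if rows.empty:
                missing += 1
                ok = False
                continue
            lfc = float(rows["log2fc"].iloc[0])
            q = float(rows["q"].iloc[0])
            if q > q_threshold or abs(lfc) < min_abs_lfc or lfc == 0:
                ok = False
                break
            s = 1 if lfc > 0 else -1
            if sign is None:
                sign = s
            elif s != sign:
                ok = False
                break
        if missing:
            excluded[gene] = missing
        elif ok and sign is not None:
            core[gene] = "up" if sign > 0 else "down"
    return CoreDEResult(
        core=core, n_comparisons=len(dfs), excluded_missing=excluded
    )


# ---------------------------------------------------------------------------
# Symbiont titer
# ---------------------------------------------------------------------------

def relative_titer(
    ct: pd.DataFrame,
    pool: str,
    calibrator: str,
    symbiont_gene: str = "GroEL",
    host_genes: Sequence[str] = ("actin", "para"),
) -> FoldEstimate:
    """Symbiont titer of one pool relative to a control-diet calibrator.

    Titer is the copy number of the symbiont-specific gene relative to host
    single-copy genes, so this delegates to the ddCt fold with
    ``symbiont_gene`` as target and the host genes as housekeepers.
    """
    if ct[ct["target"] == symbiont_gene].empty:
        raise ValueError(f"symbiont gene {symbiont_gene!r} absent from Ct table")
    return ddct_fold(
        ct,
        target=symbiont_gene,
        housekeepers=tuple(host_genes),
        test=pool,
        calibrator=calibrator,
    )


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]           # group -> letters; shared letter = n.s.
    significant_pairs: frozenset[frozenset]


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way fixed-effects F test with all-pairs Tukey HSD letters.

    The HSD criterion uses the studentized range distribution on the pooled
    within-group mean square.  Letters are assigned by insert-and-absorb
    over groups ordered by descending mean (ties broken by name), so the
    display is deterministic.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    k = len(names)
    n_total = sum(len(a) for a in arrays.values())
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        if ss_between == 0:
            return AnovaTukeyResult(
                f_statistic=0.0,
                p_value=1.0,
                letters={g: "a" for g in names},
                significant_pairs=frozenset(),
            )
        # zero noise, distinct means: every unequal pair differs
        pairs = frozenset(
            frozenset((a, b))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if arrays[a].mean() != arrays[b].mean()
        )
        F = math.inf
        p = 0.0
        return AnovaTukeyResult(F, p, _letters(names, arrays, pairs), pairs)
    F = (ss_between / df_b) / ms_within
    p = float(stats.f.sf(F, df_b, df_w))
    qcrit = float(stats.studentized_range.ppf(1 - alpha, k, df_w))
    sig = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            na, nb = len(arrays[a]), len(arrays[b])
            se = math.sqrt(ms_within / 2 * (1 / na + 1 / nb))
            qstat = abs(arrays[a].mean() - arrays[b].mean()) / se
            if qstat > qcrit:
                sig.add(frozenset((a, b)))
    return AnovaTukeyResult(F, p, _letters(names, arrays, frozenset(sig)), frozenset(sig))


def _letters(
    names: Sequence[str],
    arrays: Mapping[str, np.ndarray],
    significant: frozenset,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display."""
    order = sorted(names, key=lambda g: (-float(np.mean(arrays[g])), g))
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in significant for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb: drop sets fully contained in another
    keep: list[set[str]] = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if t is not s):
            if s not in keep:
                keep.append(s)
    out: dict[str, str] = {g: "" for g in names}
    for letter, s in zip(string.ascii_lowercase, keep):
        for g in sorted(s):
            out[g] += letter
    for g in out:
        out[g] = "".join(sorted(out[g]))
    return out


# ---------------------------------------------------------------------------
# Probit dose-response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    slope: float
    intercept: float
    log10_lc50: float
    lc50: float
    ci_low: float                    # Fieller 95%; may be 0/inf when flagged
    ci_high: float
    control_mortality: float
    deviance: float
    separation_flagged: bool = False

    @property
    def ci_finite(self) -> bool:
        return math.isfinite(self.ci_low) and math.isfinite(self.ci_high)


def probit_lc50(
    dose_table: pd.DataFrame,
    alpha: float = 0.05,
) -> DoseResponseFit:
    """Probit LC50 with Abbott correction and Fieller confidence limits.

    ``dose_table`` has columns dose, n, dead; dose == 0 rows are pooled into
    the control mortality c, and observed mortalities at positive doses are
    corrected to (p - c)/(1 - c) before the probit GLM fit (only when
    c > 0).  LC50 = 10**(-intercept/slope); its interval comes from the
    Fieller construction on the fitted covariance.  A non-monotone fit
    (slope <= 0) raises; complete separation (only 0% and 100% responses)
    is flagged with an infinite interval.
    """
    df = dose_table.copy()
    controls = df[df["dose"] == 0]
    c = float(controls["dead"].sum() / controls["n"].sum()) if len(controls) else 0.0
    dosed = df[df["dose"] > 0]
    if dosed["dose"].nunique() < 3:
        raise ValueError("need >= 3 nonzero doses")
    if (dosed["dead"] > dosed["n"]).any():
        raise ValueError("deaths exceed n at some dose")
    grouped = dosed.groupby("dose", as_index=False)[["n", "dead"]].sum()
    p_obs = grouped["dead"] / grouped["n"]
    if c > 0:
        p_adj = ((p_obs - c) / (1 - c)).clip(lower=0.0, upper=1.0)
    else:
        p_adj = p_obs
    separation = bool(p_adj.isin([0.0, 1.0]).all())
    x = np.log10(grouped["dose"].to_numpy())
    exog = sm.add_constant(x)
    model = sm.GLM(
        p_adj.to_numpy(),
        exog,
        family=sm.families.Binomial(link=sm.families.links.Probit()),
        var_weights=grouped["n"].to_numpy(),
    )
    try:
        import warnings

        with warnings.catch_warnings():
            # a noiseless table fits perfectly; the warning is expected
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, tol=1e-10)
    except Exception:
        if separation:
            return DoseResponseFit(
                slope=float("nan"),
                intercept=float("nan"),
                log10_lc50=float("nan"),
                lc50=float("nan"),
                ci_low=0.0,
                ci_high=float("inf"),
                control_mortality=c,
                deviance=float("nan"),
                separation_flagged=True,
            )
        raise
    a, b = float(res.params[0]), float(res.params[1])
    if b <= 0:
        raise ValueError("non-monotone response: fitted slope <= 0")
    theta = -a / b
    cov = np.asarray(res.cov_params())
    v_aa, v_ab, v_bb = cov[0, 0], cov[0, 1], cov[1, 1]
    z = float(stats.norm.ppf(1 - alpha / 2))
    # Fieller limits for the ratio -a/b
    g = z**2 * v_bb / b**2
    if separation or g >= 1:
        lo10, hi10 = -math.inf, math.inf
    else:
        centre = theta + g * (theta + v_ab / v_bb) / (1 - g)
        spread = (
            z
            / (b * (1 - g))
            * math.sqrt(
                v_aa + 2 * theta * v_ab + theta**2 * v_bb - g * (v_aa - v_ab**2 / v_bb)
            )
        )
        lo10, hi10 = centre - abs(spread), centre + abs(spread)
    return DoseResponseFit(
        slope=b,
        intercept=a,
        log10_lc50=theta,
        lc50=10.0**theta,
        ci_low=10.0**lo10 if math.isfinite(lo10) else 0.0,
        ci_high=10.0**hi10 if math.isfinite(hi10) else float("inf"),
        control_mortality=c,
        deviance=float(res.deviance),
        separation_flagged=separation,
    )
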