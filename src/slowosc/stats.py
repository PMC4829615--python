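"""Group comparisons of band fALFF and discrete-bin spectra.

Three test families, matching the analysis design of a four-group
cross-sectional study (young, old, stroke-early, stroke-late):

* per-frequency-bin two-sample Student t-tests between two groups on
  the 0.009-0.060 Hz / 0.0015 Hz grid, reported uncorrected (optional
  Benjamini-Hochberg columns);
* one-way fixed-effects ANOVA on component fALFF with Tukey HSD
  (Tukey-Kramer for unequal n) post hoc pairwise comparisons;
* a priori directional two-sample t-tests for registered one-tailed
  contrasts (direction must be declared, never inferred from the data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ValidationError

__all__ = [
    "bin_ttest",
    "anova_tukey",
    "directional_ttest",
    "contrast_report",
    "OmnibusResult",
    "Contrast",
]


def bin_ttest(
    bins_a: np.ndarray,
    bins_b: np.ndarray,
    centers: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-bin two-sample t-test (pooled variance by default).

    ``bins_a``/``bins_b`` are (subjects x bins) amplitude matrices on a
    common grid.  Significance flags are uncorrected at ``alpha``;
    ``fdr=True`` appends Benjamini-Hochberg-adjusted columns.
    """
    bins_a, bins_b = np.atleast_2d(bins_a), np.atleast_2d(bins_b)
    if bins_a.shape[0] < 2 or bins_b.shape[0] < 2:
        raise ValidationError("need at least 2 subjects per group")
    if bins_a.shape[1] != bins_b.shape[1] or bins_a.shape[1] != len(centers):
        raise ValidationError("bin grids do not match")
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(bins_a, bins_b, axis=0, equal_var=equal_var)
    # zero within-group variance: identical groups test as no difference,
    # any mean separation is infinitely significant
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        same = np.isclose(bins_a.mean(axis=0), bins_b.mean(axis=0))
        t = np.where(degenerate & same, 0.0, t)
        p = np.where(degenerate & same, 1.0, p)
        t = np.where(degenerate & ~same, np.inf, t)
        p = np.where(degenerate & ~same, 0.0, p)
    df = pd.DataFrame(
        {
            "center_hz": np.asarray(centers, float),
            "mean_a": bins_a.mean(axis=0),
            "mean_b": bins_b.mean(axis=0),
            "diff": bins_a.mean(axis=0) - bins_b.mean(axis=0),
            "t": t,
            "p": p,
            "significant": p < alpha,
        }
    )
    if fdr:
        rej, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        df["p_fdr"] = p_adj
        df["significant_fdr"] = rej
    return df


@dataclass
class OmnibusResult:
    """One-way ANOVA with Tukey HSD pairwise follow-up on one measure."""

    label: str
    band: str
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)
    tukey_meandiff: dict[tuple[str, str], float] = field(default_factory=dict)

    def pair_p(self, a: str, b: str) -> float:
        return self.tukey_p.get((a, b), self.tukey_p.get((b, a), np.nan))

    def summary(self) -> str:
        lines = [
            f"{self.label} / {self.band}: F = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4f}",
            "  group means: "
            + "  ".join(
                f"{g}={m:.3f} (n={self.group_sizes[g]})"
                for g, m in self.group_means.items()
            ),
        ]
        for (a, b), p in self.tukey_p.items():
            lines.append(
                f"  Tukey {a} vs {b}: diff = {self.tukey_meandiff[(a, b)]:+.4f}, "
                f"p = {p:.4f}"
            )
        return "\n".join(lines)


def anova_tukey(
    values_by_group: Mapping[str, np.ndarray],
    label: str = "",
    band: str = "",
    alpha: float = 0.05,
) -> OmnibusResult:
    """One-way fixed-effects ANOVA plus Tukey HSD on subject fALFF values.

    Uses the studentized-range distribution with the Tukey-Kramer
    unequal-n correction (group sizes in this design differ: ~43/42/14/16).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    for g, a in zip(groups, arrays):
        if len(a) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    F, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    res = OmnibusResult(
        label=label,
        band=band,
        f_statistic=float(F),
        p_value=float(p),
        group_means={g: float(a.mean()) for g, a in zip(groups, arrays)},
        group_sizes={g: int(len(a)) for g, a in zip(groups, arrays)},
    )
    pairs = [
        (tk.groupsunique[i], tk.groupsunique[j])
        for i, j in zip(*tk._multicomp.pairindices)
    ]
    for (a, b), pv, md in zip(pairs, tk.pvalues, tk.meandiffs):
        res.tukey_p[(str(a), str(b))] = float(pv)
        res.tukey_meandiff[(str(a), str(b))] = float(md)
    return res


def directional_ttest(
    a: np.ndarray, b: np.ndarray, direction: str, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t with one-tailed p in a pre-registered direction.

    ``direction`` is "greater" (mean(a) > mean(b)) or "less"; it must be
    stated explicitly — inferring it from the observed means would turn
    a one-tailed test into a two-tailed one at double the nominal rate.
    """
    if direction not in ("greater", "less"):
        raise ParameterError("direction must be declared: 'greater' or 'less'")
    t, p = sps.ttest_ind(
        np.asarray(a, float), np.asarray(b, float),
        equal_var=equal_var, alternative=direction,
    )
    return float(t), float(p)


@dataclass(frozen=True)
class Contrast:
    """A registered two-group comparison, optionally one-tailed."""

    group_a: str
    group_b: str
    direction: str | None = None  # "greater" | "less" | None (two-sided)

    @property
    def name(self) -> str:
        return f"{self.group_a}-{self.group_b}"


# The study's contrast set: late-stroke effect against age-matched
# controls, and the aging effect.
DEFAULT_CONTRASTS = (
    Contrast("stroke_late", "old"),
    Contrast("young", "old"),
    Contrast("stroke_early", "old"),
)


def contrast_report(
    falff: pd.DataFrame,
    contrasts: Sequence[Contrast] = DEFAULT_CONTRASTS,
    bands: Sequence[str] = ("slow5", "slow4", "resting", "slow5_share"),
    alpha: float = 0.05,
    anova: bool = True,
    ground_truth: Mapping[str, Mapping[str, float]] | None = None,
) -> dict:
    """Full component x band x contrast report.

    ``falff`` is the long-format table (subject_id, group, component,
    band, falff).  For every component (including composites present in
    the table) and band, the report carries each contrast's group means,
    mean difference, t, p (one-tailed when the contrast declares a
    direction), plus the 4-group ANOVA/Tukey block when requested.  When
    per-subject generative targets are supplied the true effect
    direction is recorded alongside.  Returns a JSON-serialisable dict.
    """
    report: dict = {"alpha": alpha, "components": {}, "notes": []}
    if falff.empty:
        return report
    required = {"subject_id", "group", "component", "band", "falff"}
    if not required <= set(falff.columns):
        raise ValidationError(f"fALFF table must have columns {sorted(required)}")
    for comp in sorted(falff["component"].unique()):
        comp_block: dict = {}
        for band in bands:
            sl = falff[(falff["component"] == comp) & (falff["band"] == band)]
            if sl.empty:
                continue
            by_group = {
                g: gdf["falff"].to_numpy() for g, gdf in sl.groupby("group")
            }
            band_block: dict = {"group_means": {g: float(v.mean()) for g, v in by_group.items()}}
            if anova and len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
                om = anova_tukey(by_group, label=comp, band=band, alpha=alpha)
                band_block["anova"] = {
                    "F": om.f_statistic,
                    "p": om.p_value,
                    "tukey_p": {f"{a}-{b}": p for (a, b), p in om.tukey_p.items()},
                }
            band_block["contrasts"] = {}
            for c in contrasts:
                if c.group_a not in by_group or c.group_b not in by_group:
                    continue
                va, vb = by_group[c.group_a], by_group[c.group_b]
                if len(va) < 2 or len(vb) < 2:
                    continue
                if c.direction is None:
                    t, p = sps.ttest_ind(va, vb)
                    tails = "two-sided"
                else:
                    t, p = directional_ttest(va, vb, c.direction)
                    tails = f"one-tailed ({c.direction})"
                entry = {
                    "mean_a": float(va.mean()),
                    "mean_b": float(vb.mean()),
                    "diff": float(va.mean() - vb.mean()),
                    "t": float(t),
                    "p": float(p),
                    "tails": tails,
                    "significant": bool(p < alpha),
                }
                if ground_truth is not None and band == "slow5":
                    true_diff = _true_mean_diff(ground_truth, falff, comp, c)
                    if true_diff is not None:
                        entry["generative_diff"] = true_diff
                        entry["sign_matches_truth"] = bool(
                            np.sign(entry["diff"]) == np.sign(true_diff)
                        ) if true_diff != 0 else None
                band_block["contrasts"][c.name] = entry
            comp_block[band] = band_block
        report["components"][comp] = comp_block
    report["notes"].append(
        "bin/contrast p-values are uncorrected, as in the per-bin analysis design"
    )
    return report


def _true_mean_diff(ground_truth, falff, comp, c) -> float | None:
    """Generative slow-5 fALFF group mean difference for a contrast."""
    sl = falff[(falff["component"] == comp) & (falff["band"] == "slow5")]
    means = {}
    for g in (c.group_a, c.group_b):
        subs = sl[sl["group"] == g]["subject_id"].unique()
        vals = [
            ground_truth[s][comp]
            for s in subs
            if s in ground_truth and comp in ground_truth[s]
        ]
        if not vals:
            return None
        means[g] = float(np.mean(vals))
    return means[c.group_a] - means[c.group_b]


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a contrast report into a tidy DataFrame."""
    rows = []
    for comp, comp_block in report.get("components", {}).items():
        for band, band_block in comp_block.items():
            for cname, e in band_block.get("contrasts", {}).items():
                rows.append(
                    {"component": comp, "band": band, "contrast": cname, **e}
                )
    return pd.DataFrame(rows)
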