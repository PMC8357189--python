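"""Moderated time-course differential-transcription testing.

Labeled (>=2 T>C conversion) counts are log2-CPM transformed, fit gene-wise
with an ordinary least-squares group-means model over (arm x time) levels,
and tested with an empirical-Bayes moderated t-statistic: gene-wise residual
variances s_g^2 are shrunk toward a global prior s0^2 with prior degrees of
freedom d0,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and t = log2FC / (s~_g * SE_unscaled) is referred to a t distribution on
d0 + d_g degrees of freedom. (d0, s0^2) are estimated by method of moments on
log s_g^2, matching the scaled-F distribution sample variances follow under
normality. Two contrast families are produced per arm: each time point vs the
0 h baseline, and consecutive time points. Benjamini-Hochberg adjustment is
applied per contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("slamwaves")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Group-means design over (arm, time) factor levels."""

    samples: pd.DataFrame               # sample_id, arm, time_h, replicate
    levels: list[tuple[str, float]] = field(init=False)
    assignment: np.ndarray = field(init=False)  # level index per sample

    def __post_init__(self) -> None:
        pairs = list(zip(self.samples["arm"], self.samples["time_h"].astype(float)))
        self.levels = sorted(set(pairs), key=lambda p: (p[0], p[1]))
        index = {lv: i for i, lv in enumerate(self.levels)}
        self.assignment = np.array([index[p] for p in pairs])
        counts = np.bincount(self.assignment, minlength=len(self.levels))
        thin = [lv for lv, c in zip(self.levels, counts) if c < 2]
        if thin:
            raise ValueError(
                f"levels with <2 replicates (variance inestimable): {thin}")

    @property
    def matrix(self) -> np.ndarray:
        X = np.zeros((len(self.assignment), len(self.levels)))
        X[np.arange(len(self.assignment)), self.assignment] = 1.0
        return X

    def level_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=len(self.levels))

    def contrast_pairs(self, arm: str,
                       family: str) -> list[tuple[str, tuple, tuple]]:
        """(label, levelA, levelB) pairs: A - B is the reported log2FC."""
        times = sorted(t for a, t in self.levels if a == arm)
        if family == "vs0":
            return [(f"{arm}:{t:g}h_vs_0h", (arm, t), (arm, times[0]))
                    for t in times[1:]]
        if family == "consecutive":
            return [(f"{arm}:{b:g}h_vs_{a:g}h", (arm, b), (arm, a))
                    for a, b in zip(times, times[1:])]
        raise ValueError(f"unknown contrast family {family!r}")


# ---------------------------------------------------------------------------
# normalisation and per-gene fits
# ---------------------------------------------------------------------------

def normalize_counts(labeled: pd.DataFrame, library_sizes: pd.Series,
                     pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + c) / (libsize + 2c) * 1e6).

    Library sizes are the per-sample total read counts. With ``pseudocount``
    zero the transform is exactly scale invariant.
    """
    lib = library_sizes.reindex(labeled.columns)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"non-positive library sizes for samples: {bad}")
    vals = (labeled.to_numpy(dtype=float) + pseudocount) / (
        lib.to_numpy(dtype=float) + 2 * pseudocount) * 1e6
    return pd.DataFrame(np.log2(vals), index=labeled.index,
                        columns=labeled.columns)


@dataclass
class GeneFit:
    """OLS group-means fits for all genes at once."""

    coef: pd.DataFrame      # genes x levels (group means)
    sigma2: np.ndarray      # residual variance per gene
    df_resid: int
    design: DesignSpec

    @property
    def level_names(self) -> list[str]:
        return [f"{a}:{t:g}h" for a, t in self.design.levels]


def fit_models(logcpm: pd.DataFrame, design: DesignSpec) -> GeneFit:
    """Gene-wise OLS under the group-means parameterisation."""
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear levels)")
    Y = logcpm.to_numpy(dtype=float)            # genes x samples
    n_samples, n_levels = X.shape
    sizes = design.level_sizes()
    # group means: Y averaged within each level
    coef = np.stack(
        [Y[:, design.assignment == j].mean(axis=1) for j in range(n_levels)],
        axis=1)
    resid = Y - coef[:, design.assignment]
    df_resid = n_samples - n_levels
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    coef_df = pd.DataFrame(coef, index=logcpm.index,
                           columns=[f"{a}:{t:g}h" for a, t in design.levels])
    return GeneFit(coef_df, sigma2, df_resid, design)


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


@dataclass
class ModeratedStats:
    """Empirical-Bayes hyperparameters and shrunken variances."""

    prior_df: float          # d0; may be inf
    prior_var: float         # s0^2
    s2_post: np.ndarray      # posterior (moderated) variance per gene
    df_total: float          # d0 + d_g (inf-safe)


def ebayes(fits: GeneFit, prior_df: float | None = None) -> ModeratedStats:
    """Estimate (d0, s0^2) and shrink gene variances.

    Method of moments on z = log s_g^2 (Smyth-style): with d_g residual df,
    e_g = z_g - digamma(d_g/2) + log(d_g/2) has mean log s0^2 - digamma(d0/2)
    + log(d0/2) and excess variance trigamma(d0/2) beyond trigamma(d_g/2).
    A non-positive excess-variance estimate means no detectable dispersion of
    true variances: d0 = +inf and every moderated variance equals s0^2.
    ``prior_df`` overrides estimation (0 recovers the ordinary t-test).
    """
    d = fits.df_resid
    if d < 1:
        raise ValueError("no residual degrees of freedom; add replicates")
    s2 = fits.sigma2
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all gene variances are zero: degenerate ensemble")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    ebar = float(e.mean())
    if prior_df is not None:
        d0 = float(prior_df)
        if math.isinf(d0) or d0 == 0.0:
            # infinite prior: best single variance is the ensemble mean;
            # zero prior carries no weight, value irrelevant
            s0 = float(s2[ok].mean())
        else:
            s0 = math.exp(ebar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        n = e.size
        excess = float(((e - ebar) ** 2).sum() / max(n - 1, 1)) - float(
            special.polygamma(1, d / 2.0))
        if n < 2 or excess <= 0:
            # no detectable spread of true variances beyond sampling noise
            d0 = math.inf
            s0 = float(s2[ok].mean())
        else:
            d0 = 2.0 * _trigamma_inverse(excess)
            s0 = math.exp(ebar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = math.inf
    elif d0 == 0.0:
        s2_post = s2.copy()
        df_total = float(d)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    logger.info("ebayes: d0=%.4g s0^2=%.4g (df_resid=%d, %d genes)",
                d0, s0, d, s2.size)
    return ModeratedStats(d0, s0, s2_post, df_total)


def moderated_contrast(fits: GeneFit, mod: ModeratedStats,
                       level_a: tuple[str, float],
                       level_b: tuple[str, float]) -> pd.DataFrame:
    """Moderated t-test of levelA - levelB for every gene."""
    design = fits.design
    sizes = design.level_sizes()
    ia, ib = design.levels.index(level_a), design.levels.index(level_b)
    lfc = fits.coef.iloc[:, ia] - fits.coef.iloc[:, ib]
    se_unscaled = math.sqrt(1.0 / sizes[ia] + 1.0 / sizes[ib])
    se = np.sqrt(mod.s2_post) * se_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if math.isinf(mod.df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=mod.df_total)
    return pd.DataFrame({"log2fc": lfc, "t": t, "p": p}, index=fits.coef.index)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    arr = np.asarray(p, dtype=float)
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contrast tables
# ---------------------------------------------------------------------------

@dataclass
class TimeCourseStats:
    """Per-gene, per-contrast moderated statistics for both contrast families."""

    table: pd.DataFrame          # long: gene_id, family, arm, contrast, times...
    prior_df: float
    prior_var: float
    fdr_threshold: float
    lfc_threshold: float

    def significance_matrix(self, arm: str,
                            family: str = "vs0") -> pd.DataFrame:
        """Genes x times boolean significance for one arm/family."""
        sub = self.table[(self.table["arm"] == arm)
                         & (self.table["family"] == family)]
        return sub.pivot(index="gene_id", columns="time_h",
                         values="significant").fillna(False).astype(bool)

    def lfc_matrix(self, arm: str, family: str = "vs0") -> pd.DataFrame:
        sub = self.table[(self.table["arm"] == arm)
                         & (self.table["family"] == family)]
        return sub.pivot(index="gene_id", columns="time_h", values="log2fc")

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for contrast, sub in self.table.groupby("contrast"):
            safe = contrast.replace(":", "_")
            sub.to_csv(outdir / f"contrast_{safe}.tsv", sep="\t", index=False)
        self.table.to_csv(outdir / "contrasts_all.tsv", sep="\t", index=False)
        import json

        (outdir / "hyperparameters.json").write_text(json.dumps({
            "prior_df": self.prior_df if math.isfinite(self.prior_df) else "inf",
            "prior_var": self.prior_var,
            "fdr_threshold": self.fdr_threshold,
            "lfc_threshold": self.lfc_threshold,
        }, indent=1))


def run_contrasts(logcpm: pd.DataFrame, design: DesignSpec,
                  fdr: float = 0.05, lfc: float = 0.5,
                  prior_df: float | None = None) -> TimeCourseStats:
    """Fit, moderate, and test both contrast families in both arms.

    A gene is flagged significant in a contrast when its BH q-value is below
    ``fdr`` AND |log2FC| exceeds ``lfc``. BH adjustment is applied within each
    contrast across genes.
    """
    fits = fit_models(logcpm, design)
    mod = ebayes(fits, prior_df=prior_df)
    frames = []
    arms = sorted(set(a for a, _ in design.levels))
    for arm in arms:
        for family in ("vs0", "consecutive"):
            for label, la, lb in design.contrast_pairs(arm, family):
                res = moderated_contrast(fits, mod, la, lb)
                res["q"] = bh_adjust(res["p"])
                res["significant"] = (res["q"] < fdr) & (res["log2fc"].abs() > lfc)
                res = res.reset_index(names="gene_id")
                res.insert(1, "family", family)
                res.insert(2, "arm", arm)
                res.insert(3, "contrast", label)
                res.insert(4, "time_h", la[1])
                frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    return TimeCourseStats(table, mod.prior_df, mod.prior_var, fdr, lfc)
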