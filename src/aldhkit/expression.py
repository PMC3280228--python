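"""Microarray-style differential-expression screen.

The screen consumes summarized probe-set log2 intensities with per-cell
detection calls (P/M/A): quantile normalization, removal of probes
absent or marginal on every array, a moderated two-sample t-test with
empirical-Bayes variance shrinkage (prior df and variance estimated by
the method of moments on log sample variances), Benjamini-Hochberg FDR
adjustment, and gene-level responsiveness calls with a clustered log2
fold-change matrix for heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError

CALLS = ("P", "M", "A")


@dataclass
class ExpressionMatrix:
    """Probes x arrays log2 intensities with detection calls.

    ``design`` maps each array to a condition; ``probe_gene`` maps each
    probe set to a gene (many probes may share a gene).
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    design: pd.Series
    probe_gene: pd.Series

    def __post_init__(self):
        if not self.values.index.equals(self.calls.index) or \
                not self.values.columns.equals(self.calls.columns):
            raise InputError("calls matrix not congruent to intensity matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("non-finite intensities")
        unmapped = [a for a in self.values.columns if a not in self.design.index]
        if unmapped:
            raise InputError(f"arrays without a condition: {unmapped}")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise InputError(f"unknown detection calls: {sorted(bad)}")

    def arrays_for(self, condition: str) -> list[str]:
        return [a for a in self.values.columns if self.design[a] == condition]

    def subset(self, probes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[probes], self.calls.loc[probes],
            self.design, self.probe_gene)


# ---------------------------------------------------------------------------
# Normalization and filtering

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all array columns onto the mean empirical distribution.

    Ranks within each array are preserved; tied values receive the mean
    of the reference quantiles they span.
    """
    v = m.values.to_numpy(dtype=float)
    if v.shape[1] < 2:
        raise InputError("quantile normalization needs at least 2 arrays")
    ref = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    n = v.shape[0]
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(v.shape[1]):
        ranks = stats.rankdata(v[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.calls.copy(), m.design, m.probe_gene)


def filter_absent(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Drop probes whose call is absent or marginal on every array.

    Returns the filtered matrix and the drop log (probe ids removed).
    """
    calls = m.calls.to_numpy()
    informative = (calls == "P").any(axis=1)
    kept = m.values.index[informative]
    dropped = list(m.values.index[~informative])
    return m.subset(list(kept)), dropped


# ---------------------------------------------------------------------------
# Moderated t-test (empirical-Bayes variance shrinkage)

@dataclass
class ModeratedTParams:
    d0: float          # prior degrees of freedom (may be inf)
    s02: float         # prior variance
    d: float           # residual df per probe

    def __post_init__(self):
        if self.d0 < 0 or self.s02 <= 0:
            raise ParameterError("invalid prior parameters")

    def posterior_variance(self, s2: np.ndarray) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s02)
        return (self.d0 * self.s02 + self.d * s2) / (self.d0 + self.d)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log-convex target)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float) -> ModeratedTParams:
    """Moment estimation of (d0, s0^2) from log sample variances.

    Fits a scaled F distribution to the sample variances: the mean and
    variance of log(s^2) identify the prior df and prior variance. A
    non-positive excess variance means no detectable variance spread
    across probes; the prior df is then infinite (full pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise InputError("too few positive sample variances to fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return ModeratedTParams(d0=d0, s02=s02, d=d)


def moderated_t(
    m: ExpressionMatrix,
    contrast: tuple[str, str],
    prior: ModeratedTParams | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t between two conditions (treatment, control).

    The log2 fold change is the treatment-minus-control mean difference;
    the pooled within-group variance is shrunk toward the moments-
    estimated prior, and p-values come from a t distribution with
    d + d0 degrees of freedom. Pass an explicit ``prior`` to override
    estimation (d0=0 recovers the ordinary equal-variance t-test).
    """
    treat, ctrl = contrast
    at = m.arrays_for(treat)
    ac = m.arrays_for(ctrl)
    for cond, arrays in ((treat, at), (ctrl, ac)):
        if len(arrays) < 2:
            raise InputError(
                f"condition {cond!r} has {len(arrays)} array(s); at least 2 are "
                "needed for a variance estimate — use descriptive fold changes only")
    x = m.values[at].to_numpy(dtype=float)
    y = m.values[ac].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    d = n1 + n2 - 2
    lfc = x.mean(axis=1) - y.mean(axis=1)
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / d
    if prior is None:
        prior = estimate_prior(s2, d)
    s2_post = prior.posterior_variance(s2)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = d + prior.d0
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({
        "lfc": lfc, "t": t, "pvalue": p,
        "s2": s2, "s2_post": s2_post,
    }, index=m.values.index)
    out.attrs["prior"] = prior
    out.attrs["contrast"] = contrast
    return out


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise InputError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_call(result: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Append BH-adjusted p-values and the DE flag at ``alpha``."""
    out = result.copy()
    out["padj"] = bh_fdr(out["pvalue"].to_numpy())
    out["de"] = out["padj"] < alpha
    out.attrs.update(result.attrs)
    return out


def de_screen(
    m: ExpressionMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full screen for one contrast: normalize, filter, test, adjust."""
    if normalize:
        m = quantile_normalize(m)
    m, _dropped = filter_absent(m)
    return de_call(moderated_t(m, contrast), alpha=alpha)


# ---------------------------------------------------------------------------
# Gene-level responsiveness report

@dataclass
class ResponsivenessReport:
    calls: pd.DataFrame        # genes x contrasts: up/down/not_de/not_assayed
    lfc: pd.DataFrame          # genes x contrasts log2 fold changes (clustered order)
    order: list[str]           # gene order after hierarchical clustering


def responsiveness_report(
    results: Mapping[str, pd.DataFrame],
    probe_gene: pd.Series,
    alpha: float = 0.05,
    aggregate: Literal["any", "all"] = "any",
) -> ResponsivenessReport:
    """Per-gene stress-responsiveness calls and a clusterable lfc matrix.

    A gene is responsive in a contrast iff (any | all) of its surviving
    probe sets are DE there; its fold change is taken from the probe
    with the smallest adjusted p-value. Genes with no surviving probes
    in a contrast are ``not_assayed`` — distinct from ``not_de``. Rows
    are ordered by average-linkage hierarchical clustering under
    correlation distance; reordering never alters the stored values.
    """
    if not results:
        raise InputError("no contrasts given")
    genes = sorted(probe_gene.unique())
    contrasts = list(results)
    calls = pd.DataFrame("not_assayed", index=genes, columns=contrasts)
    lfc = pd.DataFrame(np.nan, index=genes, columns=contrasts)
    for cname, res in results.items():
        if "padj" not in res.columns:
            res = de_call(res, alpha=alpha)
        probes_by_gene: dict[str, list[str]] = {}
        for probe in res.index:
            if probe in probe_gene.index:
                probes_by_gene.setdefault(probe_gene[probe], []).append(probe)
        for gene in genes:
            probes = probes_by_gene.get(gene, [])
            if not probes:
                continue
            sub = res.loc[probes]
            is_de = sub["de"].any() if aggregate == "any" else sub["de"].all()
            top = sub["padj"].idxmin()
            lfc.loc[gene, cname] = sub.loc[top, "lfc"]
            if is_de:
                calls.loc[gene, cname] = "up" if sub.loc[top, "lfc"] > 0 else "down"
            else:
                calls.loc[gene, cname] = "not_de"
    order = list(genes)
    assayed = lfc.dropna(how="any")
    if len(assayed) >= 3 and len(contrasts) >= 2:
        filled = assayed.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows give NaN correlation
            dvec = pdist(filled, metric="correlation")
        dvec = np.nan_to_num(dvec, nan=1.0)
        link = hierarchy.linkage(dvec, method="average")
        leaf_order = hierarchy.leaves_list(link)
        clustered = [assayed.index[i] for i in leaf_order]
        rest = [g for g in genes if g not in set(clustered)]
        order = clustered + rest
    return ResponsivenessReport(calls.loc[order], lfc.loc[order], order)


# ---------------------------------------------------------------------------
# TSV I/O

def read_expression_tsv(
    matrix_tsv: str | Path,
    calls_tsv: str | Path,
    design_tsv: str | Path,
    probe_map_tsv: str | Path | None = None,
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    calls = pd.read_csv(calls_tsv, sep="\t", index_col=0)
    design = pd.read_csv(design_tsv, sep="\t", index_col=0)["condition"]
    if probe_map_tsv is not None:
        probe_gene = pd.read_csv(probe_map_tsv, sep="\t", index_col=0)["gene_id"]
    else:
        probe_gene = pd.Series(values.index, index=values.index, name="gene_id")
    return ExpressionMatrix(values, calls, design, probe_gene)


def write_expression_tsv(
    m: ExpressionMatrix,
    matrix_tsv: str | Path,
    calls_tsv: str | Path,
    design_tsv: str | Path,
    probe_map_tsv: str | Path,
) -> None:
    m.values.to_csv(matrix_tsv, sep="\t", index_label="probe_id")
    m.calls.to_csv(calls_tsv, sep="\t", index_label="probe_id")
    m.design.rename("condition").to_csv(design_tsv, sep="\t", index_label="array")
    m.probe_gene.rename("gene_id").to_csv(probe_map_tsv, sep="\t", index_label="probe_id")
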