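"""Promoter-level differential methylation and gene-set KS testing.

The comparison pipeline mirrors the array workflow: per-sample genome-wide
mean methylation compared between groups; CpG betas averaged within gene
promoters; promoter values location-normalized within array-processing
batches before pooling; per-promoter Welch t-tests with Benjamini-Hochberg
adjustment; and a two-sample Kolmogorov-Smirnov comparison of each gene
set's promoter t-statistics against all out-of-set promoters, again
BH-adjusted, to find pathways whose promoters shift together even when no
single promoter is significant on its own.

Sign convention: t > 0 means higher methylation in the exposed (PGD)
group, so pathway "direction" is hypo when the median in-set t is
negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .io import BetaMatrix, GeneSetCollection, PromoterMap

__all__ = [
    "PromoterMethylation",
    "DiffMethTable",
    "GeneSetResult",
    "global_mean_compare",
    "aggregate_promoters",
    "batch_normalize",
    "promoter_tests",
    "gene_set_ks",
    "benjamini_hochberg",
]


@dataclass
class PromoterMethylation:
    """Samples x promoters mean beta matrix; promoters named by gene."""

    values: pd.DataFrame            # index: sample ids, columns: genes
    batch: pd.Series | None = None  # per-sample batch labels, same order

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError("promoter methylation outside [0, 1]")
        if self.batch is not None and len(self.batch) != len(self.values):
            raise ValidationError("batch labels do not match samples")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DiffMethTable:
    """Per-promoter group means, Welch t, p, and BH q."""

    table: pd.DataFrame  # columns: gene, mean_control, mean_case, t, p, q

    def __post_init__(self) -> None:
        t = self.table
        ok = t["q"].notna()
        if np.any(t.loc[ok, "q"] + 1e-12 < t.loc[ok, "p"]):
            raise ValidationError("BH q smaller than p")

    def tested(self) -> pd.DataFrame:
        return self.table[self.table["p"].notna()]


@dataclass
class GeneSetResult:
    """KS comparison of one gene set's promoter t-statistics."""

    name: str
    n_in: int
    n_out: int
    statistic: float
    p: float
    q: float
    direction: str                  # "hypo" | "hyper" | "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValidationError("KS D outside [0, 1]")
        if self.direction not in ("hypo", "hyper", "none"):
            raise ValidationError(f"bad direction {self.direction!r}")


# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted q-values (NaN p-values stay NaN, excluded from m)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def global_mean_compare(
    betas: BetaMatrix,
    group,
    *,
    batch=None,
) -> tuple[pd.Series, float]:
    """Genome-wide mean methylation per group, compared by Student's t.

    The per-sample statistic is the mean beta over all probes (missing
    excluded); ``batch`` only labels which batch each sample's mean came
    from — the mean itself is per-sample.  Samples with no usable probes
    are excluded with a warning.  Returns ``(per-group means, p)``.
    """
    g = np.asarray(group).astype(bool)
    if g.size != betas.shape[0]:
        raise ValidationError("group length does not match samples")
    sample_mean = betas.values.mean(axis=1, skipna=True)
    usable = sample_mean.notna().to_numpy()
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} all-missing sample(s)",
            stacklevel=2)
    sm_, g = sample_mean[usable], g[usable]
    if min(g.sum(), (~g).sum()) < 2:
        raise ValidationError("need >= 2 samples per group")
    means = pd.Series({
        "control": float(sm_[~g].mean()),
        "case": float(sm_[g].mean()),
    })
    a, b = sm_[~g].to_numpy(), sm_[g].to_numpy()
    if np.ptp(np.concatenate([a, b])) == 0:
        return means, 1.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return means, float(res.pvalue)


def aggregate_promoters(
    betas: BetaMatrix,
    pmap: PromoterMap,
    *,
    batch=None,
) -> PromoterMethylation:
    """Average each promoter's CpG betas per sample.

    Promoter value = unweighted mean of the promoter's CpGs present in the
    matrix; missing betas are excluded per sample.  CpGs mapping to no
    promoter are dropped at this stage; a CpG inside two overlapping
    promoters contributes to both.
    """
    entries = pmap.entries[pmap.entries["cpg_id"].isin(betas.cpg_ids)]
    if entries.empty:
        raise ValidationError("no mapped CpGs present in the beta matrix")
    cols: dict[str, np.ndarray] = {}
    for gene, sub in entries.groupby("gene", sort=True):
        cols[gene] = betas.values[sub["cpg_id"].tolist()].mean(
            axis=1, skipna=True).to_numpy(float)
    values = pd.DataFrame(cols, index=betas.values.index)
    b = None
    if batch is not None:
        b = pd.Series(np.asarray(batch).astype(str),
                      index=betas.values.index)
    return PromoterMethylation(values=values, batch=b)


def batch_normalize(pm: PromoterMethylation, batch=None) -> PromoterMethylation:
    """Remove per-batch location shifts, preserving each promoter's grand mean.

    Per promoter: subtract the batch mean and add back the pre-normalization
    grand mean, then clip to [0, 1].  Scale is deliberately untouched.  A
    single batch is a no-op; a single-sample batch raises (its offset is
    unidentifiable).
    """
    labels = pm.batch if batch is None else pd.Series(
        np.asarray(batch).astype(str), index=pm.values.index)
    if labels is None:
        raise ValidationError("no batch labels available")
    levels = labels.unique()
    if len(levels) == 1:
        return PromoterMethylation(pm.values.copy(), labels)
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(
            f"cannot estimate batch offset from single-sample batch(es): "
            f"{small}")
    grand = pm.values.mean(axis=0)
    out = pm.values.copy()
    for lev in levels:
        mask = (labels == lev).to_numpy()
        out.loc[mask] = (pm.values.loc[mask]
                         - pm.values.loc[mask].mean(axis=0) + grand)
    out = out.clip(0.0, 1.0)
    return PromoterMethylation(out, labels)


def promoter_tests(pm: PromoterMethylation, group) -> DiffMethTable:
    """Welch t-test per promoter with BH adjustment across promoters.

    t > 0 means higher methylation in the exposed group.  Promoters with
    zero variance in both groups have no defined t; they are reported with
    NaN statistics and excluded from the BH family size m.
    """
    g = np.asarray(group).astype(bool)
    if g.size != len(pm.values):
        raise ValidationError("group length does not match samples")
    if min(g.sum(), (~g).sum()) < 2:
        raise ValidationError("need >= 2 samples per group")
    A = pm.values.loc[~g].to_numpy(float)   # control
    B = pm.values.loc[g].to_numpy(float)    # case / exposed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(B, A, equal_var=False, axis=0,
                              nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    q = benjamini_hochberg(p)
    table = pd.DataFrame({
        "gene": pm.genes,
        "mean_control": A.mean(axis=0),
        "mean_case": B.mean(axis=0),
        "t": t,
        "p": p,
        "q": q,
    })
    return DiffMethTable(table)


def gene_set_ks(
    dm: DiffMethTable,
    sets: GeneSetCollection,
    *,
    top_k: int = 15,
    q_threshold: float = 0.01,
    min_set_size: int = 3,
) -> list[GeneSetResult]:
    """Two-sample KS test of each set's promoter t-statistics.

    For every gene set with at least ``min_set_size`` mapped promoters, the
    in-set t-statistics are compared against all out-of-set t-statistics by
    a two-sided two-sample Kolmogorov-Smirnov test (exact for small sets,
    asymptotic otherwise); p-values are BH-adjusted across the tested sets.
    Returns up to ``top_k`` sets with q < ``q_threshold``, ranked by q then
    D, labeled hypo/hyper by the sign of the median in-set t.  Sets too
    small to test are skipped with a warning.
    """
    tested = dm.tested()
    t_by_gene = tested.set_index("gene")["t"]
    names, records = [], []
    for name in sets.names():
        genes = [g for g in sets[name] if g in t_by_gene.index]
        if len(genes) < min_set_size:
            warnings.warn(
                f"gene set {name!r}: only {len(genes)} mapped promoter(s); "
                f"skipped", stacklevel=2)
            continue
        t_in = t_by_gene.loc[genes].to_numpy(float)
        t_out = t_by_gene.drop(index=genes).to_numpy(float)
        if t_out.size == 0:
            warnings.warn(f"gene set {name!r} covers every promoter; skipped",
                          stacklevel=2)
            continue
        method = "exact" if min(t_in.size, t_out.size) <= 10 else "asymp"
        res = stats.ks_2samp(t_in, t_out, alternative="two-sided",
                             method=method)
        med = float(np.median(t_in))
        direction = "hypo" if med < 0 else ("hyper" if med > 0 else "none")
        names.append(name)
        records.append((len(genes), t_out.size, float(res.statistic),
                        float(res.pvalue), direction))
    if not records:
        return []
    q = benjamini_hochberg([r[3] for r in records])
    results = [
        GeneSetResult(name=nm, n_in=r[0], n_out=r[1], statistic=r[2],
                      p=r[3], q=float(qq), direction=r[4])
        for nm, r, qq in zip(names, records, q)
    ]
    results.sort(key=lambda r: (r.q, -r.statistic, r.p, r.name))
    passing = [r for r in results if r.q < q_threshold]
    return passing[:top_k]


def gene_set_ks_all(
    dm: DiffMethTable,
    sets: GeneSetCollection,
    *,
    min_set_size: int = 3,
) -> list[GeneSetResult]:
    """Like :func:`gene_set_ks` but returning every tested set, unranked
    by threshold (sorted by q).  Useful for reporting full tables."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gene_set_ks(dm, sets, top_k=len(sets.names()),
                           q_threshold=np.inf, min_set_size=min_set_size)
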