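"""Differential chromatin accessibility.

The engine follows the count-based limma-style workflow: trimmed-mean-of-M
(TMM) library normalization, a voom transformation (log2-cpm plus precision
weights from a fitted mean-variance trend), a single consensus intra-individual
correlation shared across regions (repeated measures per donor modelled as a
block-compound-symmetry covariance), generalized-least-squares contrasts of
each drug against the vehicle at each timepoint, empirical-Bayes shrinkage of
residual variances, and Benjamini-Hochberg adjustment per contrast.

Design matrix convention: one column per (treatment, time) cell mean. The
individual enters only through the block correlation, never as a fixed effect,
so the treatment contrasts stay estimable in the 4-donors-x-all-conditions
repeated-measures layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.linalg import cholesky, solve_triangular
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .quant_qc import CountExperiment


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def cell_means_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """One indicator column per (treatment, time) cell.

    Returns (design matrix S x C, list of (treatment, time) cell labels in
    column order).
    """
    cells = list(
        meta[["treatment", "time"]]
        .astype(str)
        .drop_duplicates()
        .sort_values(["treatment", "time"])
        .itertuples(index=False, name=None)
    )
    idx = {cell: j for j, cell in enumerate(cells)}
    X = np.zeros((len(meta), len(cells)))
    for i, row in enumerate(meta[["treatment", "time"]].astype(str).itertuples(index=False, name=None)):
        X[i, idx[row]] = 1.0
    return X, cells


def contrast_vector(cells: list[tuple[str, str]], treatment: str, time: str,
                    vehicle: str) -> np.ndarray:
    c = np.zeros(len(cells))
    try:
        c[cells.index((treatment, time))] = 1.0
        c[cells.index((vehicle, time))] = -1.0
    except ValueError as exc:
        raise ValidationError(
            f"contrast ({treatment} - {vehicle}) at time {time} not expressible: "
            f"missing design cell"
        ) from exc
    return c


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

@dataclass
class NormFactors:
    factors: np.ndarray
    lib_sizes: np.ndarray

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abs_trim: float, a_cutoff: float) -> float:
    """TMM factor of one sample against the reference (log2 scale trimmed mean)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    ok = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a = m[ok], a[ok]
    o, r = obs[ok], ref[ok]
    if len(m) == 0:
        raise ValidationError("sample shares no usable regions with the TMM reference")
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 0.0
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    experiment: CountExperiment,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> NormFactors:
    """Trimmed-mean-of-M normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.
    """
    counts = experiment.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs >= 2 samples")
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValidationError("every sample needs >= 1 nonzero count")
    f75 = np.array([
        np.quantile(counts[:, j], 0.75) / libs[j] for j in range(counts.shape[1])
    ])
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(counts.sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = np.array([
        0.0 if j == ref else _tmm_pair(
            counts[:, j], counts[:, ref], libs[j], libs[ref],
            logratio_trim, abs_trim, a_cutoff,
        )
        for j in range(counts.shape[1])
    ])
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(factors=factors, lib_sizes=libs)


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------

@dataclass
class VoomData:
    y: np.ndarray            # R x S log2-cpm
    w: np.ndarray            # R x S precision weights
    design: np.ndarray       # S x C
    trend_x: np.ndarray      # fitted mean -> sqrt-sd curve (sorted)
    trend_y: np.ndarray
    meta: pd.DataFrame


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Row-wise OLS of y (R x S) on X (S x C): (coef R x C, residual sd, df)."""
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T
    resid = y - coef @ X.T
    df = y.shape[1] - np.linalg.matrix_rank(X)
    if df < 1:
        raise ValidationError("no residual degrees of freedom")
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    return coef, sigma, df


def voom_transform(
    experiment: CountExperiment,
    factors: NormFactors,
    design: np.ndarray,
    span: float = 0.5,
) -> VoomData:
    """Log2-cpm with observation-level precision weights.

    The mean-variance trend regresses per-region residual sqrt-sd on average
    log2 count via lowess (span 0.5); each observation's weight is the
    predicted sqrt-sd at its fitted log2 count, raised to the -4th power, with
    predictions clamped to the trend's range at the extremes.
    """
    lib = factors.effective_lib_sizes
    counts = experiment.counts.astype(float)
    y = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)
    coef, sigma, df = _ols_fit(y, design)
    fitted_logcpm = coef @ design.T
    # average log2 count per region (cpm scale shifted back to counts)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    smoothed = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = smoothed[:, 0], smoothed[:, 1]
    fitted_logcount = fitted_logcpm + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)  # clamps at trend extremes
    pred = np.clip(pred, 1e-6, None)
    w = pred**-4.0
    return VoomData(y=y, w=w, design=design, trend_x=tx, trend_y=ty,
                    meta=experiment.samples.copy())


# ---------------------------------------------------------------------------
# consensus intra-block correlation
# ---------------------------------------------------------------------------

@dataclass
class BlockCorrelation:
    rho_consensus: float
    per_region: np.ndarray = field(default_factory=lambda: np.empty(0))


def consensus_correlation(
    voom: VoomData,
    block: np.ndarray | pd.Series,
    design: np.ndarray | None = None,
    trim: float = 0.15,
) -> BlockCorrelation:
    """Consensus intra-block correlation of residuals.

    Per region, the intraclass correlation is estimated by the moment (ANOVA
    cross-product) estimator on sqrt-weight-scaled residuals from the
    fixed-effects fit: the mean within-block cross-product divided by the mean
    squared residual. The consensus is tanh of the ``trim``-trimmed mean of
    atanh of the per-region estimates.
    """
    X = voom.design if design is None else design
    labels = pd.Series(block).astype(str).to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("intra-block correlation needs >= 2 blocks")
    yw = voom.y * np.sqrt(voom.w)
    # residuals of the weighted observations on the (unweighted) design; with
    # roughly constant weights per region this matches the OLS residual scale
    resid = np.empty_like(voom.y)
    for r in range(voom.y.shape[0]):
        sw = np.sqrt(voom.w[r])
        Xw = X * sw[:, None]
        beta, *_ = np.linalg.lstsq(Xw, yw[r], rcond=None)
        resid[r] = yw[r] - Xw @ beta
    masks = [labels == b for b in uniq]
    n_pairs = sum(int(m.sum()) * (int(m.sum()) - 1) // 2 for m in masks)
    if n_pairs == 0:
        raise ValidationError("no within-block pairs: correlation unidentifiable")
    cross = np.zeros(voom.y.shape[0])
    for m in masks:
        e = resid[:, m]
        cross += 0.5 * (e.sum(axis=1) ** 2 - (e**2).sum(axis=1))
    msq = (resid**2).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (cross / n_pairs) / msq
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -0.9999, 0.9999)
    consensus = float(np.tanh(stats.trim_mean(np.arctanh(rho), trim)))
    return BlockCorrelation(rho_consensus=consensus, per_region=rho)


# ---------------------------------------------------------------------------
# GLS contrast fitting
# ---------------------------------------------------------------------------

@dataclass
class ContrastFit:
    """Pre-moderation per-region, per-contrast estimates."""

    coef: np.ndarray             # R x K log2FC
    stdev_unscaled: np.ndarray   # R x K
    sigma2: np.ndarray           # R residual variances
    df_resid: int
    contrasts: list[tuple[str, str]]
    region_ids: np.ndarray


def _block_correlation_matrix(labels: np.ndarray, rho: float) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    V = np.where(same, rho, 0.0)
    np.fill_diagonal(V, 1.0)
    return V


def fit_contrasts(
    voom: VoomData,
    rho: BlockCorrelation | float,
    design: np.ndarray | None = None,
    contrasts: list[tuple[str, str]] | None = None,
    cells: list[tuple[str, str]] | None = None,
    vehicle: str = "VEH",
    block: np.ndarray | pd.Series | None = None,
) -> ContrastFit:
    """Weighted GLS per region under block compound symmetry.

    With ``rho == 0`` this reduces exactly to weighted least squares. Contrasts
    are (treatment, time) pairs, each contrasted against (vehicle, time).
    """
    X = voom.design if design is None else design
    if cells is None or contrasts is None:
        raise ValidationError("fit_contrasts needs design cells and contrast list")
    rho_val = rho.rho_consensus if isinstance(rho, BlockCorrelation) else float(rho)
    if not (-1.0 < rho_val < 1.0):
        raise ValidationError("|rho| must be < 1")
    S = X.shape[0]
    if block is None:
        block = voom.meta["individual"]
    labels = pd.Series(block).astype(str).to_numpy()
    V = _block_correlation_matrix(labels, rho_val)
    L = cholesky(V, lower=True)
    Li = solve_triangular(L, np.eye(S), lower=True)

    C = np.stack([contrast_vector(cells, t, tm, vehicle) for t, tm in contrasts])
    R = voom.y.shape[0]
    K = C.shape[0]
    df = S - np.linalg.matrix_rank(X)
    if df < 1:
        raise ValidationError("no residual degrees of freedom")

    sw = np.sqrt(voom.w)                                  # R x S
    Xw = sw[:, :, None] * X[None, :, :]                   # R x S x C
    Xt = np.einsum("us,rsc->ruc", Li, Xw)                 # whitened designs
    yt = (sw * voom.y) @ Li.T                             # R x S
    G = np.einsum("rsc,rsd->rcd", Xt, Xt)
    h = np.einsum("rsc,rs->rc", Xt, yt)
    beta = np.linalg.solve(G, h[..., None])[..., 0]
    resid = yt - np.einsum("rsc,rc->rs", Xt, beta)
    sigma2 = (resid**2).sum(axis=1) / df
    Ginv = np.linalg.inv(G)
    coef = beta @ C.T                                     # R x K
    var_unscaled = np.einsum("kc,rcd,kd->rk", C, Ginv, C)
    stdev_unscaled = np.sqrt(var_unscaled)
    return ContrastFit(
        coef=coef,
        stdev_unscaled=stdev_unscaled,
        sigma2=sigma2,
        df_resid=int(df),
        contrasts=list(contrasts),
        region_ids=np.arange(R),
    )


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_variance_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) on log variances."""
    s2 = np.maximum(np.asarray(sigma2, float), 1e-10)
    if len(s2) < 10:
        raise ValidationError("need >= 10 regions to estimate the variance prior")
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def ebayes_moderate(fit: ContrastFit) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values.

    Posterior variance: ``(d0*s0^2 + df*s^2) / (d0 + df)``; moderated t uses
    ``df + d0`` degrees of freedom. With infinite d0 every variance shrinks
    fully to s0^2 and the reference distribution is normal.
    """
    d0, s0 = fit_variance_prior(fit.sigma2, fit.df_resid)
    df = fit.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * fit.sigma2) / (d0 + df)
        df_total = df + d0
    rows = []
    for k, (trt, tm) in enumerate(fit.contrasts):
        se = fit.stdev_unscaled[:, k] * np.sqrt(s2_post)
        t = fit.coef[:, k] / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        rows.append(pd.DataFrame({
            "region_index": np.arange(len(t)),
            "treatment": trt,
            "time": tm,
            "log2fc": fit.coef[:, k],
            "t": t,
            "p": p,
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["d0"] = d0
    out.attrs["s0_squared"] = s0
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def label_dars(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-contrast BH adjustment and DAR/CAR labelling.

    DAR iff adjusted p < alpha (strict); every other tested region is a CAR for
    that contrast. Direction: opening iff log2FC > 0.
    """
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(["treatment", "time"], sort=False).groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["label"] = np.where(out["p_adj"] < alpha, "DAR", "CAR")
    out["direction"] = np.where(out["log2fc"] > 0, "opening", "closing")
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    table: pd.DataFrame
    norm: NormFactors
    voom: VoomData
    correlation: BlockCorrelation
    cells: list[tuple[str, str]]

    def contrast_table(self, treatment: str, time: str) -> pd.DataFrame:
        t = self.table
        return t[(t["treatment"] == treatment) & (t["time"] == str(time))].reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["treatment", "time"])
            .agg(n_regions=("label", "size"),
                 n_dar=("label", lambda s: int((s == "DAR").sum())))
            .reset_index()
        )


def differential_accessibility(
    experiment: CountExperiment,
    vehicle: str = "VEH",
    alpha: float = 0.05,
) -> DifferentialResult:
    """Full TMM -> voom -> consensus correlation -> GLS -> eBayes -> BH run."""
    meta = experiment.samples
    X, cells = cell_means_design(meta)
    contrasts = [
        (trt, tm) for (trt, tm) in cells if trt != vehicle
    ]
    if not contrasts:
        raise ValidationError(f"no non-vehicle cells to contrast against {vehicle!r}")
    if vehicle not in set(meta["treatment"].astype(str)):
        raise ValidationError(f"vehicle level {vehicle!r} absent from metadata")
    norm = tmm_factors(experiment)
    voom = voom_transform(experiment, norm, X)
    corr = consensus_correlation(voom, meta["individual"], X)
    fit = fit_contrasts(voom, corr, X, contrasts=contrasts, cells=cells,
                        vehicle=vehicle, block=meta["individual"])
    results = ebayes_moderate(fit)
    table = label_dars(results, alpha=alpha)
    ids = experiment.regions.region_ids.to_numpy()
    table["region_id"] = ids[table["region_index"].to_numpy()]
    return DifferentialResult(table=table, norm=norm, voom=voom,
                              correlation=corr, cells=cells)
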