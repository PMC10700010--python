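"""Expression filtering and negative-binomial differential expression.

Two contrasts mirror the two biological questions of the sampling design:

* **criteria (i)** — featured regions of predicted rapid-softening fruits
  vs featured regions of control fruits (RS-F vs C-F), an *unpaired*
  across-fruit comparison (early fate-specific physiology);
* **criteria (ii)** — featured vs non-featured regions within the same
  fruit (RS-F vs RS-NF), a *paired* comparison with fruit as a blocking
  factor (region-specific premonitory reactions).

Both are NB log-linear models fitted per gene by IRLS with a log
library-size offset, vectorised across genes.  Per-gene dispersions are
moment-estimated from full-model Pearson residuals and shrunk toward a
mean–dispersion trend (alpha ~ a0 + a1/mu); significance is a
likelihood-ratio chi-square on the condition coefficient, with
Benjamini–Hochberg adjustment across tested genes.

Expression is filtered on RPKM (reads per kilobase per million mapped
reads): a gene is tested only when its group-mean RPKM exceeds 1 in at
least one of the two compared groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rpkm",
    "filter_expressed",
    "de_unpaired",
    "de_paired",
    "overlap_and_concordance",
    "pca_expression",
    "enrichment_hypergeometric",
]

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# normalisation and filtering


def rpkm(counts, gene_lengths, library_sizes) -> pd.DataFrame:
    """RPKM = count / (length_kb * libsize_millions)."""
    counts = pd.DataFrame(counts)
    lengths = np.asarray(gene_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths / 1e3, libs / 1e6)
    return pd.DataFrame(counts.to_numpy(float) / denom,
                        index=counts.index, columns=counts.columns)


def filter_expressed(rpkm_matrix: pd.DataFrame, groups, threshold: float = 1.0,
                     compare: tuple[str, str] | None = None) -> pd.Index:
    """Genes whose mean RPKM strictly exceeds ``threshold`` in at least one
    of the two compared groups."""
    groups = pd.Series(np.asarray(groups), index=rpkm_matrix.columns)
    levels = list(compare) if compare else list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups must be compared")
    keep = np.zeros(len(rpkm_matrix), dtype=bool)
    for lev in levels:
        cols = groups.index[groups == lev]
        if len(cols) == 0:
            raise ValueError(f"group {lev!r} has no samples")
        keep |= rpkm_matrix[cols].mean(axis=1).to_numpy() > threshold
    return rpkm_matrix.index[keep]


# ---------------------------------------------------------------------------
# vectorised NB GLM machinery


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, n_iter: int = 50, tol: float = 1e-8):
    """Fit NB log-linear models gene-wise (shared design).

    y: (G, S) counts; X: (S, p); offset: (S,); alpha: (G,) dispersions.
    Returns (beta (G, p), deviance (G,)).
    """
    G, S = y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    z0 = np.log((y + 0.5) / np.exp(offset)[None, :])
    beta = z0 @ pinv.T
    a = alpha[:, None]
    dev = np.full(G, np.inf)
    for _ in range(n_iter):
        eta = np.clip(offset[None, :] + beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("gs,sp,sq->gpq", W, X, X)
        A += 1e-9 * np.eye(p)[None, :, :]
        b = np.einsum("gs,sp->gp", W * z, X)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        new_dev = _nb_deviance(y, np.exp(np.clip(offset[None, :] + beta_new @ X.T,
                                                 -30.0, 30.0)), a)
        done = np.abs(new_dev - dev) < tol * (np.abs(new_dev) + 1.0)
        beta, dev = beta_new, new_dev
        if done.all():
            break
    return beta, dev


def _nb_deviance(y, mu, a):
    """2 * [ll(saturated) - ll(mu)] for NB with dispersion a (broadcastable)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        r = 1.0 / np.maximum(a, 1e-12)
        t2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (t1 - t2).sum(axis=1)


def _estimate_dispersion(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                         prior_df: float = 20.0) -> np.ndarray:
    """Pearson-residual moment estimate under the full design, shrunk toward
    an alpha ~ a0 + a1/mu trend fitted across genes."""
    G, S = y.shape
    p = X.shape[1]
    beta0, _ = _irls_nb(y, X, offset, np.zeros(G) + 1e-8, n_iter=25)
    mu = np.exp(np.clip(offset[None, :] + beta0 @ X.T, -30.0, 30.0))
    resid_df = max(S - p, 1)
    # E[(y-mu)^2 / mu] ~= 1 + alpha * mu  =>  alpha ~= sum[(y-mu)^2/mu - 1] / sum mu
    num = ((y - mu) ** 2 / np.maximum(mu, 1e-8) - 1.0).sum(axis=1) * (S / resid_df)
    den = mu.sum(axis=1)
    alpha_mom = np.clip(num / np.maximum(den, 1e-8), 1e-6, 10.0)

    mean_mu = mu.mean(axis=1)
    ok = mean_mu > 1.0
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mean_mu[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha_mom[ok], rcond=None)
        trend = np.clip(coef[0] + coef[1] / np.maximum(mean_mu, 1e-8), 1e-6, 10.0)
    else:
        trend = np.full(G, np.median(alpha_mom))
    w = resid_df / (resid_df + prior_df)
    return np.clip(w * alpha_mom + (1.0 - w) * trend, 1e-6, 10.0)


def _nb_lrt(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray,
            offset: np.ndarray, coef_idx: int, prior_df: float = 10.0):
    """Quasi-likelihood moderated F test of the coefficient dropped between
    the full and reduced designs; returns (log2fc, pvalue).

    The deviance drop is scaled by a per-gene quasi-dispersion (full-model
    deviance over its residual df, shrunk toward 1 with ``prior_df`` prior
    degrees of freedom) and referred to F(1, prior_df + residual df).  The
    moderation absorbs per-gene error in the estimated NB dispersion, which
    an unscaled chi-square LRT ignores at these sample sizes.
    """
    alpha = _estimate_dispersion(y, X_full, offset)
    beta_f, dev_f = _irls_nb(y, X_full, offset, alpha)
    _, dev_r = _irls_nb(y, X_red, offset, alpha)
    lrt = np.maximum(dev_r - dev_f, 0.0)
    resid_df = max(y.shape[1] - X_full.shape[1], 1)
    s2 = dev_f / resid_df
    s2_mod = (prior_df + resid_df * s2) / (prior_df + resid_df)
    pvals = stats.f.sf(lrt / np.maximum(s2_mod, 1e-8), 1, prior_df + resid_df)
    log2fc = beta_f[:, coef_idx] / LN2
    allzero = (y == 0).all(axis=1)
    pvals[allzero] = 1.0
    log2fc[allzero] = 0.0
    return log2fc, pvals


def _deg_table(genes, log2fc, pvals, criteria: str) -> pd.DataFrame:
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": genes,
        "log2fc": log2fc,
        "pvalue": pvals,
        "fdr": fdr,
        "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        "criteria": criteria,
    }).set_index("gene")


def de_unpaired(counts: pd.DataFrame, groups, numerator: str = "RS-F",
                denominator: str = "C-F", library_sizes=None) -> pd.DataFrame:
    """Criteria (i): unpaired NB test of ``numerator`` vs ``denominator``.

    ``counts`` are genes x samples (pre-filtered); log2fc is
    numerator-over-denominator.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    cols = groups.index[groups.isin([numerator, denominator])]
    sub = counts[cols]
    grp = groups[cols]
    if (grp == numerator).sum() < 2 or (grp == denominator).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    libs = (sub.sum(axis=0).to_numpy(float) if library_sizes is None
            else np.asarray(pd.Series(library_sizes)[cols], dtype=float))
    y = sub.to_numpy(float)
    X_full = np.column_stack([np.ones(len(cols)), (grp == numerator).to_numpy(float)])
    X_red = X_full[:, :1]
    log2fc, pvals = _nb_lrt(y, X_full, X_red, np.log(libs), coef_idx=1)
    return _deg_table(sub.index, log2fc, pvals, "i")


def de_paired(counts: pd.DataFrame, sample_meta: pd.DataFrame,
              numerator: str = "RS-F", denominator: str = "RS-NF") -> pd.DataFrame:
    """Criteria (ii): paired NB test with fruit as a blocking factor.

    Only fruits contributing both a ``numerator`` and a ``denominator``
    sample enter; at least 3 complete pairs are required.
    """
    meta = sample_meta.set_index("sample_id")
    meta = meta[meta["group"].isin([numerator, denominator])]
    pair_ct = meta.groupby("fruit_id")["group"].nunique()
    complete = pair_ct.index[pair_ct == 2]
    meta = meta[meta["fruit_id"].isin(complete)]
    if meta.groupby("fruit_id").size().ne(2).any():
        raise ValueError("each fruit must contribute exactly one sample per region")
    if len(complete) < 3:
        raise ValueError("need at least 3 complete RS-F/RS-NF pairs")
    cols = [c for c in counts.columns if c in meta.index]
    sub = counts[cols]
    grp = meta.loc[cols, "group"]
    fruits = meta.loc[cols, "fruit_id"]
    libs = sub.sum(axis=0).to_numpy(float)

    fruit_levels = list(pd.unique(fruits))
    blocks = np.column_stack([(fruits == f).to_numpy(float) for f in fruit_levels[1:]])
    X_red = np.column_stack([np.ones(len(cols)), blocks])
    X_full = np.column_stack([X_red, (grp == numerator).to_numpy(float)])
    log2fc, pvals = _nb_lrt(sub.to_numpy(float), X_full, X_red, np.log(libs),
                            coef_idx=X_full.shape[1] - 1)
    return _deg_table(sub.index, log2fc, pvals, "ii")


# ---------------------------------------------------------------------------
# downstream summaries


def overlap_and_concordance(table_i: pd.DataFrame, table_ii: pd.DataFrame,
                            p_threshold: float = 0.05, fdr_threshold: float = 0.1):
    """Direction-matched DEG overlap between the two criteria and the Pearson
    correlation of log2 fold changes over the union of DEGs."""
    shared = table_i.index.intersection(table_ii.index)
    ti, tii = table_i.loc[shared], table_ii.loc[shared]
    sig_i = ti["pvalue"] < p_threshold
    sig_ii = tii["fdr"] < fdr_threshold
    common_up = int((sig_i & sig_ii & (ti["direction"] == "up")
                     & (tii["direction"] == "up")).sum())
    common_down = int((sig_i & sig_ii & (ti["direction"] == "down")
                       & (tii["direction"] == "down")).sum())
    union = shared[(sig_i | sig_ii).to_numpy()]
    if len(union) >= 2:
        r = float(np.corrcoef(ti.loc[union, "log2fc"], tii.loc[union, "log2fc"])[0, 1])
    else:
        r = float("nan")
    return common_up, common_down, r


def pca_expression(rpkm_matrix: pd.DataFrame, groups, n_components: int = 5):
    """PCA of samples on log2(RPKM+1), gene-centred.

    Returns (variance fractions over all components, sample scores DataFrame,
    per-PC two-sided t-test p-values for every group pair).
    """
    groups = pd.Series(np.asarray(groups), index=rpkm_matrix.columns)
    if rpkm_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = np.log2(rpkm_matrix.to_numpy(float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    if not (x != 0).any():
        raise ValueError("constant expression matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    k = min(n_components, len(s))
    scores = pd.DataFrame(vt[:k].T * s[:k], index=rpkm_matrix.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    levels = list(pd.unique(groups))
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            for pc in scores.columns:
                t, p = stats.ttest_ind(scores.loc[groups == a, pc],
                                       scores.loc[groups == b, pc])
                rows.append(dict(group_a=a, group_b=b, pc=pc, pvalue=float(p)))
    return var_frac, scores, pd.DataFrame(rows)


def read_gmt(path) -> dict:
    """GMT gene-set file -> {set name: list of genes} (description dropped)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na"):
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def enrichment_hypergeometric(deg_set, gene_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``deg_set`` in each gene set,
    BH-adjusted across sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    degs = set(deg_set) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(degs & members)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(degs)))
        rows.append(dict(gene_set=name, set_size=len(members), overlap=k,
                         pvalue=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out.sort_values(["pvalue", "gene_set"]).reset_index(drop=True)
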