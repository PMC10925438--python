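"""FPKM computation and single-tumor-vs-controls differential expression.

The differential test is a deliberately simple negative-binomial
exceedance test: the control samples define a per-gene NB null (mean
from size-factor-normalized control counts, dispersion from a
genome-wide mean-dispersion trend fitted across controls), and the
two-sided p-value is the NB probability of a tumor count as or more
extreme than observed. This replaces a full two-group NB fit, which is
not identifiable with a single tumor sample; gene lists will differ
from shrinkage-based tools.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM = count / (gene_length_kb * library_size_millions).

    Library size is the per-sample total of assigned counts.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise KeyError(f"genes missing from lengths: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    kb = lengths.to_numpy()[:, None] / 1000.0
    millions = libsize.to_numpy()[None, :] / 1e6
    return pd.DataFrame(counts.to_numpy() / (kb * millions),
                        index=counts.index, columns=counts.columns)


def size_factors(counts: pd.DataFrame, reference_cols: list[str]) -> pd.Series:
    """Median-of-ratios size factors against the geometric mean of the
    reference (control) columns; genes with a zero anywhere in the
    reference are excluded from the reference."""
    ref = counts[reference_cols]
    log_ref = np.log(ref.where(ref > 0))
    log_geo = log_ref.mean(axis=1)
    usable = log_geo.notna()
    if not usable.any():
        raise ValueError("no gene with nonzero counts in all reference samples")
    geo = np.exp(log_geo[usable])
    factors = {}
    for col in counts.columns:
        ratios = counts.loc[usable, col] / geo
        ratios = ratios[ratios > 0]
        factors[col] = float(np.median(ratios)) if len(ratios) else 1.0
    return pd.Series(factors)


def _dispersion_trend(norm_controls: pd.DataFrame) -> tuple[float, float]:
    """Fit d = a0 + a1 / mu through per-gene method-of-moments
    dispersions from the normalized control counts."""
    mu = norm_controls.mean(axis=1).to_numpy()
    var = norm_controls.var(axis=1, ddof=1).to_numpy()
    ok = mu > 0
    mu, var = mu[ok], var[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (var - mu) / mu**2
    use = np.isfinite(d) & (d > 0)
    if use.sum() < 3:
        return 1e-3, 0.0
    x = 1.0 / mu[use]
    a1, a0 = np.polyfit(x, d[use], 1)
    return max(float(a0), 1e-6), max(float(a1), 0.0)


def _nb_two_sided_p(k: float, mu: float, d: float) -> float:
    """Two-sided exceedance p for count k under NB(mean mu, dispersion d)
    (variance mu + d*mu^2); d == 0 degrades to Poisson."""
    k = int(round(k))
    if mu <= 0:
        return 1.0 if k == 0 else 0.0
    if d <= 0:
        lower = stats.poisson.cdf(k, mu)
        upper = stats.poisson.sf(k - 1, mu)
    else:
        r = 1.0 / d
        p = r / (r + mu)
        lower = stats.nbinom.cdf(k, r, p)
        upper = stats.nbinom.sf(k - 1, r, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def differential_expression(counts: pd.DataFrame, gene_lengths: pd.Series,
                            tumor_id: str, control_ids: list[str],
                            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-gene differential expression of one tumor against the
    averaged controls.

    Returns a frame indexed by gene with columns: control_mean_norm,
    tumor_norm, fpkm_tumor, fpkm_control_mean, fold_change, log2fc,
    p_value, significant. Fold change is the ratio of pseudo-stabilized
    FPKM means; significance requires the fold-change threshold AND
    p < alpha.
    """
    config = config or PipelineConfig()
    if len(control_ids) < 2:
        raise ValueError("need >= 2 control samples")
    if tumor_id not in counts.columns:
        raise KeyError(f"tumor sample {tumor_id!r} not in counts")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise KeyError(f"genes missing from lengths: {missing[:5]}")

    cols = sorted(control_ids) + [tumor_id]
    sf = size_factors(counts[cols], sorted(control_ids))
    norm = counts[cols] / sf
    norm_controls = norm[sorted(control_ids)]
    a0, a1 = _dispersion_trend(norm_controls)

    mu = norm_controls.mean(axis=1)
    fpkm = compute_fpkm(counts, gene_lengths)
    pseudo = config.de_pseudo_fpkm
    fpkm_control_mean = fpkm[sorted(control_ids)].mean(axis=1)
    fpkm_tumor = fpkm[tumor_id]
    fc = (fpkm_tumor + pseudo) / (fpkm_control_mean + pseudo)

    sf_t = float(sf[tumor_id])
    pvals = np.ones(len(counts))
    tumor_raw = counts[tumor_id].to_numpy(dtype=float)
    mu_arr = mu.to_numpy()
    for i, (k, m) in enumerate(zip(tumor_raw, mu_arr)):
        d = a0 + (a1 / m if m > 0 else 0.0)
        pvals[i] = _nb_two_sided_p(k, m * sf_t, d)

    result = pd.DataFrame({
        "control_mean_norm": mu,
        "tumor_norm": counts[tumor_id] / sf_t,
        "fpkm_tumor": fpkm_tumor,
        "fpkm_control_mean": fpkm_control_mean,
        "fold_change": fc,
        "log2fc": np.log2(fc),
        "p_value": pvals,
    })
    thr = config.de_fc_threshold
    result["significant"] = (
        ((result["fold_change"] >= thr) | (result["fold_change"] <= 1.0 / thr))
        & (result["p_value"] < config.alpha)
    )
    return result


def high_expression_set(fpkm: pd.DataFrame, config: PipelineConfig | None = None,
                        sample: str | None = None) -> set[str]:
    """Genes at or above the FPKM threshold (inclusive) in the queried
    sample, or in the mean over samples when no sample is given."""
    config = config or PipelineConfig()
    values = fpkm[sample] if sample is not None else fpkm.mean(axis=1)
    return set(values.index[values >= config.high_expression_fpkm])
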