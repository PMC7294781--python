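"""Two-group differential analysis of count matrices.

The statistical chain mirrors the classic count-based differential framework
for sequencing libraries:

1. between-sample normalization by the trimmed mean of M-values (TMM),
2. a common negative-binomial (NB) dispersion estimated across rows,
3. an exact conditional test on the two group sums of library-equalized
   counts, and
4. a fold-change threshold taken from a permutation null distribution.

A row (consensus peak region, promoter, gene body, or transcript) is called
differential when ``p < alpha`` and ``|log2FC|`` exceeds the permutation
cutoff.

The module is organized statsmodels-style: :class:`TwoGroupCountModel` is
built from a count matrix plus group labels and ``fit()`` returns a
:class:`DifferentialResults` object carrying estimates, p-values, the
permutation cutoff and a ``summary()`` table.  The underlying primitives
(:func:`tmm_factors`, :func:`estimate_common_dispersion`,
:func:`nb_exact_test`, :func:`permutation_fc_cutoff`,
:func:`call_differential`) are importable on their own.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from scipy.optimize import minimize_scalar

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "PermutationCutoff",
    "TwoGroupCountModel",
    "DifferentialResults",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "permutation_fc_cutoff",
    "call_differential",
]


@dataclass
class CountMatrix:
    """Integer counts: rows are regions/genes, columns are samples.

    ``group`` assigns each sample to one of exactly two labels; the second
    label in sorted-unique order (or the explicit ``group_order``) is the
    "case" group B, and fold-changes are reported as B vs A.
    """

    counts: pd.DataFrame
    group: pd.Series
    lib_sizes: pd.Series | None = None
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.group = pd.Series(self.group).reindex(self.counts.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        levels = sorted(self.group.unique())
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        if self.group_order is None:
            self.group_order = (levels[0], levels[1])
        elif sorted(self.group_order) != levels:
            raise ValueError("group_order does not match group labels")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes).reindex(
                self.counts.columns
            ).astype(float)
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def row_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.group_order
        return (self.group.values == a), (self.group.values == b)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str,
        sample_sheet_path: str,
        group_order: tuple[str, str] | None = None,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_path, sep="\t")
        group = sheet.set_index("sample_id")["group"]
        return cls(counts=counts, group=group, group_order=group_order)


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors, centered so their product is 1."""

    factors: pd.Series
    ref_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    def effective_lib_sizes(self, lib_sizes: pd.Series) -> pd.Series:
        return lib_sizes * self.factors


@dataclass
class PermutationCutoff:
    """|log2FC| threshold from a permutation null pool."""

    cutoff: float
    n_permutations: int
    percentile: float
    null_pool_size: int
    mode: str
    n_distinct_used: int

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if not (0 < self.percentile < 1):
            raise ValueError("percentile must be in (0, 1)")


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        raise ValueError("sample shares no co-detected rows with the reference")
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # precision weights: inverse of the delta-method variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 0.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep2]
    f = np.sum(inv_w * m[keep2]) / np.sum(inv_w)
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str = "auto",
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against a reference sample, over rows detected in both:
    ``M = log2[(x_k/N_k)/(x_r/N_r)]`` and ``A = 0.5*log2[(x_k/N_k)(x_r/N_r)]``.
    The top and bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A
    are dropped and the factor is ``2**(sum(w*M)/sum(w))`` with
    precision weights ``w`` equal to the inverse delta-method variance of M.
    Factors are then centered to product 1.  The reference (``ref='auto'``)
    is the sample whose 75th-percentile count fraction is closest to the
    mean across samples.
    """
    x = matrix.counts.values.astype(float)
    n = matrix.lib_sizes.values.astype(float)
    samples = list(matrix.sample_ids)
    if ref == "auto":
        nz = x[x.sum(axis=1) > 0]
        q75 = np.quantile(nz / n, 0.75, axis=0) if nz.size else np.ones(len(samples))
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = samples.index(ref)
    log_factors = np.zeros(len(samples))
    for k in range(len(samples)):
        if k == ref_idx:
            continue
        log_factors[k] = _tmm_pair_factor(
            x[:, k], x[:, ref_idx], n[k], n[ref_idx], trim_m, trim_a
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # center to product 1
    return NormalizationFactors(
        factors=pd.Series(factors, index=matrix.sample_ids),
        ref_sample=samples[ref_idx],
    )


# ---------------------------------------------------------------------------
# dispersion


def _equalized_counts(
    matrix: CountMatrix, factors: NormalizationFactors
) -> tuple[np.ndarray, float]:
    """Counts rescaled to a common effective library size (not rounded)."""
    eff = factors.effective_lib_sizes(matrix.lib_sizes).values
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = matrix.counts.values * (common / eff)[None, :]
    return scaled, common


def estimate_common_dispersion(
    matrix: CountMatrix,
    factors: NormalizationFactors | None = None,
    method: str = "moments",
    trim: float = 0.1,
) -> float:
    """Common NB dispersion phi across rows (variance = mu + phi*mu^2).

    ``moments``: per-row, within each group, the method-of-moments estimate
    ``max(0, (s^2 - xbar)/xbar^2)`` on effective-library-scaled counts,
    averaged across groups weighted by degrees of freedom, then combined as
    a two-sided trimmed mean over rows with nonzero mean.

    ``profile``: phi maximizing the summed NB log-likelihood with the
    per-row group means profiled out (replaced by group sample means).
    """
    if factors is None:
        factors = NormalizationFactors(
            factors=pd.Series(1.0, index=matrix.sample_ids),
            ref_sample=str(matrix.sample_ids[0]),
        )
    scaled, _ = _equalized_counts(matrix, factors)
    mask_a, mask_b = matrix.group_masks
    groups = [m for m in (mask_a, mask_b) if m.sum() >= 2]
    if not groups:
        raise ValueError("need at least 2 samples in some group")

    if method == "moments":
        num = np.zeros(scaled.shape[0])
        den = np.zeros(scaled.shape[0])
        for m in groups:
            sub = scaled[:, m]
            xbar = sub.mean(axis=1)
            s2 = sub.var(axis=1, ddof=1)
            df = m.sum() - 1
            ok = xbar > 0
            phi_g = np.zeros(scaled.shape[0])
            phi_g[ok] = np.maximum(0.0, (s2[ok] - xbar[ok]) / xbar[ok] ** 2)
            num += np.where(ok, df * phi_g, 0.0)
            den += np.where(ok, df, 0.0)
        valid = den > 0
        if not valid.any():
            return 0.0
        per_row = num[valid] / den[valid]
        per_row.sort()
        k = int(math.floor(per_row.size * trim))
        trimmed = per_row[k: per_row.size - k] if per_row.size > 2 * k else per_row
        return float(trimmed.mean())

    if method == "profile":
        def neg_loglik(log_phi: float) -> float:
            phi = math.exp(log_phi)
            r = 1.0 / phi
            total = 0.0
            for m in groups:
                sub = scaled[:, m]
                mu = sub.mean(axis=1, keepdims=True)
                ok = mu[:, 0] > 0
                y, muv = sub[ok], mu[ok]
                ll = (
                    gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                    + r * np.log(r / (r + muv))
                    + y * np.log(muv / (r + muv))
                )
                total += ll.sum()
            return -total

        res = minimize_scalar(neg_loglik, bounds=(-12.0, 3.0), method="bounded")
        phi = float(math.exp(res.x))
        return phi if phi > 1e-5 else 0.0

    raise ValueError(f"unknown dispersion method {method!r}")


# ---------------------------------------------------------------------------
# exact conditional test


def _conditional_split_logpmf(s_total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log-probabilities of splits (a, S-a), a = 0..S, of the total S between
    group-sum NB variables with per-sample dispersion phi and equal
    per-sample means (the null).

    The sum of n iid NB(mu, phi) is NB(n*mu, phi/n), i.e. shape r = n/phi.
    Conditional on the total, the NB success probabilities cancel and the
    split follows a beta-binomial-type law; with phi = 0 it degenerates to
    Binomial(S, n_a/(n_a+n_b)).
    """
    a = np.arange(s_total + 1)
    if phi <= 0:
        p = n_a / (n_a + n_b)
        logp = (
            gammaln(s_total + 1) - gammaln(a + 1) - gammaln(s_total - a + 1)
            + a * math.log(p) + (s_total - a) * math.log1p(-p)
        )
        return logp
    r_a, r_b = n_a / phi, n_b / phi
    logp = (
        gammaln(a + r_a) - gammaln(a + 1)
        + gammaln(s_total - a + r_b) - gammaln(s_total - a + 1)
    )
    return logp - logsumexp(logp)


def _two_sided_exact_p(s_a: int, s_total: int, n_a: int, n_b: int, phi: float) -> float:
    if s_total == 0:
        return 1.0
    logp = _conditional_split_logpmf(s_total, n_a, n_b, phi)
    obs = logp[s_a]
    # two-sided: mass of all splits no more probable than the observed one
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(1.0, p)


def nb_exact_test(
    matrix: CountMatrix,
    factors: NormalizationFactors | None = None,
    dispersion: float = 0.0,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Exact conditional two-group test on library-equalized counts.

    Counts are rescaled to the geometric-mean effective library size and
    rounded (half-even).  Per row, conditional on the total pseudo-count
    ``S = S_A + S_B``, the two-sided p-value sums the probabilities of all
    splits at most as likely as the observed one under the null NB law.
    ``log2fc`` is ``log2`` of the ratio of prior-count-augmented per-sample
    group means (B vs A).

    Returns a DataFrame indexed by row id with columns ``log2fc``,
    ``p_value``, ``mean_A``, ``mean_B``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if factors is None:
        factors = NormalizationFactors(
            factors=pd.Series(1.0, index=matrix.sample_ids),
            ref_sample=str(matrix.sample_ids[0]),
        )
    scaled, _ = _equalized_counts(matrix, factors)
    pseudo = np.round(scaled).astype(np.int64)
    mask_a, mask_b = matrix.group_masks
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    s_a = pseudo[:, mask_a].sum(axis=1)
    s_b = pseudo[:, mask_b].sum(axis=1)
    mean_a = s_a / n_a
    mean_b = s_b / n_b
    log2fc = np.log2((mean_b + prior_count) / (mean_a + prior_count))
    pvals = np.ones(len(s_a))
    for i in range(len(s_a)):
        pvals[i] = _two_sided_exact_p(
            int(s_a[i]), int(s_a[i] + s_b[i]), n_a, n_b, dispersion
        )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "mean_A": mean_a, "mean_B": mean_b},
        index=matrix.row_ids,
    )


# ---------------------------------------------------------------------------
# permutation fold-change cutoff


def _group_log2fc(
    pseudo: np.ndarray, mask_b: np.ndarray, prior_count: float
) -> np.ndarray:
    n_b = mask_b.sum()
    n_a = mask_b.size - n_b
    mean_b = pseudo[:, mask_b].sum(axis=1) / n_b
    mean_a = pseudo[:, ~mask_b].sum(axis=1) / n_a
    return np.log2((mean_b + prior_count) / (mean_a + prior_count))


def permutation_fc_cutoff(
    matrix: CountMatrix,
    factors: NormalizationFactors | None = None,
    n_permutations: int = 1000,
    percentile: float = 0.10,
    mode: str = "literal",
    prior_count: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_enumerate: int = 200_000,
) -> PermutationCutoff:
    """|log2FC| cutoff from random relabelings of the samples.

    Samples are relabeled into groups of the original sizes; the identity
    labeling (and, for equal group sizes, its label-swap) is excluded.
    Distinct relabelings are drawn without replacement until exhausted, then
    with replacement.  Per relabeling the per-row |log2fc| is computed as in
    the exact test; all values are pooled.

    ``mode='literal'`` takes the ``percentile`` quantile of the pooled
    distribution (a permissive threshold); ``mode='upper-tail'`` takes the
    ``1 - percentile`` quantile (the conventional null-tail threshold).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if mode not in ("literal", "upper-tail"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if factors is None:
        factors = NormalizationFactors(
            factors=pd.Series(1.0, index=matrix.sample_ids),
            ref_sample=str(matrix.sample_ids[0]),
        )
    scaled, _ = _equalized_counts(matrix, factors)
    pseudo = np.round(scaled).astype(np.int64)
    mask_a, mask_b = matrix.group_masks
    n_samples = mask_b.size
    n_b = int(mask_b.sum())
    identity = frozenset(np.flatnonzero(mask_b))
    excluded = {identity}
    if n_samples - n_b == n_b:
        excluded.add(frozenset(np.flatnonzero(mask_a)))

    n_choose = math.comb(n_samples, n_b)
    picks: list[frozenset] = []
    if n_choose <= max_enumerate:
        distinct = [
            frozenset(c)
            for c in itertools.combinations(range(n_samples), n_b)
            if frozenset(c) not in excluded
        ]
        order = rng.permutation(len(distinct))
        picks = [distinct[i] for i in order[:n_permutations]]
        n_distinct_used = len(picks)
        while len(picks) < n_permutations:
            picks.append(distinct[int(rng.integers(len(distinct)))])
    else:
        seen: set[frozenset] = set()
        while len(picks) < n_permutations:
            c = frozenset(rng.choice(n_samples, size=n_b, replace=False).tolist())
            if c in excluded:
                continue
            picks.append(c)
            seen.add(c)
        n_distinct_used = len(seen)

    pool = np.empty((len(picks), pseudo.shape[0]))
    for j, c in enumerate(picks):
        m = np.zeros(n_samples, dtype=bool)
        m[list(c)] = True
        pool[j] = np.abs(_group_log2fc(pseudo, m, prior_count))
    flat = pool.ravel()
    q = percentile if mode == "literal" else 1.0 - percentile
    cutoff = float(np.quantile(flat, q))
    return PermutationCutoff(
        cutoff=cutoff,
        n_permutations=len(picks),
        percentile=percentile,
        null_pool_size=flat.size,
        mode=mode,
        n_distinct_used=n_distinct_used,
    )


def call_differential(
    result: pd.DataFrame,
    alpha: float = 0.05,
    cutoff: PermutationCutoff | float = 0.0,
) -> pd.DataFrame:
    """Flag rows with ``p < alpha`` and ``|log2fc| > cutoff`` (both strict).

    Adds ``passes`` (bool) and ``direction`` (+1/-1 for passing rows, 0
    otherwise) columns; returns a new DataFrame.
    """
    thr = cutoff.cutoff if isinstance(cutoff, PermutationCutoff) else float(cutoff)
    out = result.copy()
    out["passes"] = (out["p_value"] < alpha) & (out["log2fc"].abs() > thr)
    out["direction"] = np.where(out["passes"], np.sign(out["log2fc"]).astype(int), 0)
    return out


# ---------------------------------------------------------------------------
# statsmodels-style wrapper


class TwoGroupCountModel:
    """Two-group NB model for a region/gene count matrix.

    Examples
    --------
    >>> model = TwoGroupCountModel(counts_df, groups)
    >>> res = model.fit(seed=7)
    >>> res.summary()          # doctest: +SKIP
    >>> res.table.head()       # doctest: +SKIP
    """

    def __init__(
        self,
        counts: pd.DataFrame | CountMatrix,
        group: pd.Series | None = None,
        group_order: tuple[str, str] | None = None,
    ):
        if isinstance(counts, CountMatrix):
            self.data = counts
        else:
            self.data = CountMatrix(counts=counts, group=group, group_order=group_order)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        group_order: tuple[str, str] | None = None,
    ) -> "TwoGroupCountModel":
        group = sample_sheet.set_index("sample_id")["group"]
        return cls(df, group, group_order)

    def fit(
        self,
        alpha: float = 0.05,
        n_permutations: int = 1000,
        percentile: float = 0.10,
        cutoff_mode: str = "literal",
        prior_count: float = 0.5,
        dispersion: float | None = None,
        dispersion_method: str = "moments",
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        bh_correction: bool = False,
        seed: int = 0,
    ) -> "DifferentialResults":
        factors = tmm_factors(self.data, trim_m=trim_m, trim_a=trim_a)
        if dispersion is None:
            dispersion = estimate_common_dispersion(
                self.data, factors, method=dispersion_method
            )
        table = nb_exact_test(self.data, factors, dispersion, prior_count)
        cutoff = permutation_fc_cutoff(
            self.data,
            factors,
            n_permutations=n_permutations,
            percentile=percentile,
            mode=cutoff_mode,
            prior_count=prior_count,
            seed=seed,
        )
        if bh_correction:
            from statsmodels.stats.multitest import multipletests

            table = table.copy()
            table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
            test_p = table["p_adj"]
        else:
            test_p = table["p_value"]
        called = table.copy()
        called["passes"] = (test_p < alpha) & (
            called["log2fc"].abs() > cutoff.cutoff
        )
        called["direction"] = np.where(
            called["passes"], np.sign(called["log2fc"]).astype(int), 0
        )
        return DifferentialResults(
            model=self,
            table=called,
            factors=factors,
            dispersion=float(dispersion),
            cutoff=cutoff,
            alpha=alpha,
            prior_count=prior_count,
            seed=seed,
        )


@dataclass
class DifferentialResults:
    """Fitted two-group differential analysis.

    ``table`` holds per-row ``log2fc``, ``p_value``, ``mean_A``, ``mean_B``,
    ``passes`` and ``direction`` (+1 = higher in group B).
    """

    model: TwoGroupCountModel
    table: pd.DataFrame
    factors: NormalizationFactors
    dispersion: float
    cutoff: PermutationCutoff
    alpha: float
    prior_count: float
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.table["passes"].sum())

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]

    def run_metadata(self) -> dict:
        a, b = self.model.data.group_order
        return {
            "alpha": self.alpha,
            "dispersion": self.dispersion,
            "prior_count": self.prior_count,
            "cutoff": self.cutoff.cutoff,
            "cutoff_mode": self.cutoff.mode,
            "cutoff_percentile": self.cutoff.percentile,
            "n_permutations": self.cutoff.n_permutations,
            "n_distinct_permutations": self.cutoff.n_distinct_used,
            "null_pool_size": self.cutoff.null_pool_size,
            "seed": self.seed,
            "group_A": a,
            "group_B": b,
            "ref_sample": self.factors.ref_sample,
            "tmm_factors": {
                k: float(v) for k, v in self.factors.factors.items()
            },
            **self.metadata,
        }

    def summary(self) -> str:
        a, b = self.model.data.group_order
        n_up = int((self.table["direction"] == 1).sum())
        n_dn = int((self.table["direction"] == -1).sum())
        lines = [
            "Two-group NB exact test (TMM-normalized)",
            "=" * 46,
            f"rows:                 {len(self.table)}",
            f"samples:              {len(self.model.data.sample_ids)}"
            f" ({a}: {int(self.model.data.group_masks[0].sum())},"
            f" {b}: {int(self.model.data.group_masks[1].sum())})",
            f"common dispersion:    {self.dispersion:.4f}",
            f"alpha:                {self.alpha}",
            f"|log2FC| cutoff:      {self.cutoff.cutoff:.4f}"
            f" ({self.cutoff.mode}, q={self.cutoff.percentile})",
            f"permutations:         {self.cutoff.n_permutations}"
            f" ({self.cutoff.n_distinct_used} distinct)",
            f"significant rows:     {self.n_significant}"
            f" (up in {b}: {n_up}, down: {n_dn})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.index.name = "id"
        out.to_csv(path, sep="\t", float_format="%.10g")
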