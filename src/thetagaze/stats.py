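"""Balanced subsampling and restricted permutation inference.

Statistical comparisons between conditions with unequal sample counts are
balanced by repeatedly (default 500 times) subsampling the larger group to
the size of the smaller and averaging the statistic across iterations.
Channel-level group statistics are tested with one-sided permutation tests
(default 10,000 permutations) whose exchangeability is restricted within
participants: sign flips (one-sample) or condition-label exchanges (paired)
are applied to all of a participant's channels together.  With few
participants the null is enumerated exhaustively and the attainable-p floor
is reported.  Ties count as exceedances, so p is never zero.  Multiple
comparisons use Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


@dataclass
class PermutationSpec:
    n_permutations: int = 10_000
    alternative: str = "greater"       # one-sided by default
    exhaustive_max_blocks: int = 20
    block_synchronized: bool = True    # flip all of a participant's channels together
    seed: int = 0


@dataclass
class StatResult:
    observed_t: float
    p: float
    per_channel: np.ndarray
    null: np.ndarray = None
    n_channels: int = 0
    scheme: str = ""
    exhaustive: bool = False
    min_attainable_p: float = None
    q: float = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self):
        return self.p <= 0.05


def one_sample_t(values):
    """Across-channel one-sample t statistic (mean / SEM)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.inf * np.sign(values.mean()) if values.mean() != 0 else 0.0
    return values.mean() / (sd / np.sqrt(n))


# ---------------------------------------------------------------------------
# balanced subsampling
# ---------------------------------------------------------------------------

def balanced_subsample_means(values_a, values_b, n_iterations=500, seed=0):
    """Iteratively matched-size group means, averaged across iterations.

    Each iteration draws, without replacement, from the larger group to match
    the smaller group's size and records both group means; the returned pair
    is the across-iteration average.  With equal group sizes the procedure is
    the identity for the larger group's mean.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("balanced subsampling requires non-empty groups")
    rng = np.random.default_rng(seed)
    n = min(len(a), len(b))
    mean_small = a.mean() if len(a) == n else b.mean()
    big = b if len(a) == n else a
    if len(big) == n:
        mean_big = big.mean()
    else:
        acc = 0.0
        for _ in range(n_iterations):
            acc += big[rng.choice(len(big), size=n, replace=False)].mean()
        mean_big = acc / n_iterations
    if len(a) == n:
        return mean_small, mean_big, n
    return mean_big, mean_small, n


# ---------------------------------------------------------------------------
# permutation engines
# ---------------------------------------------------------------------------

def _block_sign_matrix(blocks, spec, rng):
    """(n_patterns, n_channels) sign matrix; exhaustive when feasible."""
    blocks = np.asarray(blocks)
    uniq = pd.unique(blocks)
    nb = len(uniq)
    block_of = np.searchsorted(np.sort(uniq), blocks) if blocks.dtype != object else \
        np.array([list(uniq).index(b) for b in blocks])
    if spec.block_synchronized:
        if nb <= spec.exhaustive_max_blocks:
            n_pat = 2 ** nb
            pat = ((np.arange(n_pat)[:, None] >> np.arange(nb)) & 1) * 2 - 1
            return pat[:, block_of].astype(float), True
        pat = rng.choice([-1.0, 1.0], size=(spec.n_permutations, nb))
        return pat[:, block_of], False
    nc = len(blocks)
    if nc <= spec.exhaustive_max_blocks:
        n_pat = 2 ** nc
        pat = ((np.arange(n_pat)[:, None] >> np.arange(nc)) & 1) * 2 - 1
        return pat.astype(float), True
    return rng.choice([-1.0, 1.0], size=(spec.n_permutations, nc)), False


def signflip_test(values, blocks, spec: PermutationSpec | None = None) -> StatResult:
    """One-sample test of per-channel values against zero by sign flipping.

    The observed statistic is the across-channel one-sample t.  Under the
    null, signs are flipped per exchangeability block (participant): all of a
    participant's channels flip together.  One-sided p with ties included;
    exhaustive enumeration replaces Monte Carlo when the number of blocks is
    small enough.
    """
    spec = spec or PermutationSpec()
    values = np.asarray(values, dtype=float)
    if np.all(values == 0):
        return StatResult(observed_t=0.0, p=1.0, per_channel=values,
                          n_channels=len(values), scheme="sign-flip")
    rng = np.random.default_rng(spec.seed)
    signs, exhaustive = _block_sign_matrix(blocks, spec, rng)
    obs = one_sample_t(values)
    flipped = signs * values[None, :]
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        null = np.where(sd > 0, mean / (sd / np.sqrt(values.size)),
                        np.where(mean != 0, np.inf * np.sign(mean), 0.0))
    if spec.alternative == "less":
        obs, null = -obs, -null
    if exhaustive:
        p = float(np.mean(null >= obs - 1e-12))
        min_p = 1.0 / len(null)
    else:
        p = (1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + len(null))
        min_p = 1.0 / (len(null) + 1.0)
    return StatResult(observed_t=float(one_sample_t(values)), p=float(p),
                      per_channel=values, null=null, n_channels=len(values),
                      scheme="sign-flip", exhaustive=exhaustive,
                      min_attainable_p=min_p)


def paired_label_test(group_a, group_b, blocks,
                      spec: PermutationSpec | None = None) -> StatResult:
    """Paired two-condition test via within-participant label exchange.

    Exchanging a participant's condition labels flips the sign of that
    participant's per-channel differences, so the null reduces to the
    block-synchronized sign-flip engine applied to ``group_a - group_b``.
    One-sided for mean(a) > mean(b) by default.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired_label_test: unpaired inputs")
    res = signflip_test(a - b, blocks, spec)
    res.scheme = "paired-label-exchange"
    return res


def permutation_index_audit(blocks, spec: PermutationSpec | None = None):
    """Sign matrix used by the engines, for structural audits (shuffles never
    mix channels across participants)."""
    spec = spec or PermutationSpec()
    rng = np.random.default_rng(spec.seed)
    signs, exhaustive = _block_sign_matrix(blocks, spec, rng)
    return signs, exhaustive


def fdr_correct(p_values):
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_correct: empty input")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def median_split_contrast(values_high, values_low, blocks,
                          spec: PermutationSpec | None = None) -> StatResult:
    """High-vs-low median-split contrast as a paired label-exchange test."""
    res = paired_label_test(values_high, values_low, blocks, spec)
    res.scheme = "median-split"
    return res


# ---------------------------------------------------------------------------
# mixed-effects contract
# ---------------------------------------------------------------------------

def mixed_model_theta(theta, eye_speed, body_speed, channel_ids):
    """Linear mixed model: z-theta ~ eye speed + body speed, random intercept
    per recording channel, fit by REML with standardized predictors.

    Returns a dict of standardized beta, t (z) and p per predictor.
    """
    df = pd.DataFrame({
        "theta": np.asarray(theta, dtype=float),
        "eye": np.asarray(eye_speed, dtype=float),
        "body": np.asarray(body_speed, dtype=float),
        "channel": np.asarray(channel_ids),
    }).dropna()
    if df["channel"].nunique() < 2:
        raise ValueError("mixed model requires >= 2 channels")
    for col in ("eye", "body"):
        sd = df[col].std()
        if sd == 0:
            raise ValueError(f"rank-deficient predictor {col!r}")
        df[col] = (df[col] - df[col].mean()) / sd
    model = smf.mixedlm("theta ~ eye + body", df, groups=df["channel"])
    import warnings
    with warnings.catch_warnings():
        # degenerate random-effects variance on null data is expected
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    out = {}
    for name in ("eye", "body"):
        out[name] = {
            "beta": float(fit.params[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
            "se": float(fit.bse[name]),
        }
    out["converged"] = bool(fit.converged)
    return out
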