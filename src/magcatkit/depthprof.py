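"""Effect of sequencing depth on taxonomic profiling, stratified by abundance.

Profiles at lower depths are subsampled from a reference count table
(without replacement, or multinomially), taxa are stratified into eight
ten-fold bins of mean relative abundance with upper bounds 1e-07 ... 1, and
Pearson/Spearman correlations against the deepest profile are computed per
stratum — rare strata need deeper sequencing to correlate well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

#: Upper bounds of the eight relative-abundance strata (upper-inclusive).
STRATUM_BOUNDS = 10.0 ** np.arange(-7, 1)
MIN_FEATURES_PER_STRATUM = 3


@dataclass
class AbundanceProfile:
    counts: pd.Series  # taxon -> read count
    depth: int
    seed: int | None = None

    def __post_init__(self):
        total = int(self.counts.sum())
        if total != self.depth:
            raise ValueError(f"counts sum {total} != depth {self.depth}")

    @property
    def relative(self) -> pd.Series:
        return self.counts / self.depth


def subsample_profile(
    reference_counts: pd.Series,
    depth: int,
    seed: int = 0,
    mode: str = "without_replacement",
) -> AbundanceProfile:
    """Subsample a reference count table to a lower sequencing depth.

    ``without_replacement`` draws a multivariate hypergeometric sample (the
    rarefaction a read subsampler performs; requires depth <= total reads);
    ``multinomial`` resamples from the reference's relative abundances at
    any depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = reference_counts.astype(np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    if mode == "without_replacement":
        if depth > total:
            raise ValueError(f"depth {depth} exceeds reference total {total}")
        drawn = rng.multivariate_hypergeometric(counts.to_numpy(), depth)
    elif mode == "multinomial":
        drawn = rng.multinomial(depth, counts.to_numpy() / total)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AbundanceProfile(
        counts=pd.Series(drawn, index=counts.index), depth=depth, seed=seed
    )


def stratify_features(mean_abundance: pd.Series) -> pd.Series:
    """Assign each taxon to the abundance stratum containing its mean.

    Strata are half-open intervals (lower, upper] with upper bounds
    1e-07, 1e-06, ..., 1; means at or below 1e-08 (the undefined lower
    edge) fall into the lowest stratum.  Returns the stratum upper bound
    per taxon.
    """
    m = mean_abundance.to_numpy(dtype=float)
    if np.any(m > 1) or np.any(m < 0):
        raise ValueError("mean abundances must lie in [0, 1]")
    idx = np.searchsorted(STRATUM_BOUNDS, m, side="left")
    return pd.Series(STRATUM_BOUNDS[idx], index=mean_abundance.index, name="stratum")


def stratified_correlation(
    p_low: AbundanceProfile,
    p_ref: AbundanceProfile,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-stratum Pearson and Spearman correlation between two profiles.

    Correlations are computed on relative abundances over each stratum's
    taxa; strata with fewer than 3 features are reported undefined (NaN).
    By default the strata come from the reference profile's relative
    abundances.
    """
    common = p_low.counts.index.intersection(p_ref.counts.index)
    if len(common) == 0:
        raise ValueError("profiles share no taxa")
    low = p_low.relative.reindex(common)
    ref = p_ref.relative.reindex(common)
    if strata is None:
        strata = stratify_features(ref)
    strata = strata.reindex(common)
    rows = []
    for bound in STRATUM_BOUNDS:
        taxa = strata.index[strata == bound]
        n = len(taxa)
        if n < MIN_FEATURES_PER_STRATUM:
            pcc = scc = float("nan")
        else:
            x, y = low[taxa].to_numpy(), ref[taxa].to_numpy()
            # a constant vector (e.g. all-zero counts at shallow depth, or
            # tied ranks collapsing) leaves the coefficient undefined
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                pcc = scc = float("nan")
            else:
                pcc = float(scipy.stats.pearsonr(x, y)[0])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
                    scc = float(scipy.stats.spearmanr(x, y)[0])
        rows.append({"stratum": bound, "pcc": pcc, "scc": scc, "n_features": n})
    return pd.DataFrame(rows)


def depth_correlation_curve(
    reference_counts: pd.Series,
    depths: list[int],
    seed: int = 0,
    mode: str = "without_replacement",
) -> pd.DataFrame:
    """Stratified correlation of subsampled profiles against the deepest one.

    The deepest requested depth defines the reference profile and the
    stratification; each shallower depth is subsampled with a seed derived
    from ``seed`` and correlated per stratum.
    """
    depths = sorted(set(depths))
    rng = np.random.default_rng(seed)
    ref = subsample_profile(
        reference_counts, depths[-1], seed=int(rng.integers(2**31)), mode=mode
    )
    strata = stratify_features(ref.relative)
    frames = []
    for depth in depths[:-1]:
        low = subsample_profile(
            reference_counts, depth, seed=int(rng.integers(2**31)), mode=mode
        )
        df = stratified_correlation(low, ref, strata)
        df.insert(0, "depth", depth)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
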