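"""Per-sample alpha-diversity, coverage and rarefaction-curve statistics.

Index formulas follow the classical definitions: Chao1 (both the classic
``S + F1^2/(2 F2)`` and the bias-corrected ``S + F1(F1-1)/(2(F2+1))``
variants), ACE with a rare-taxon cutoff of 10 reads, Shannon in nats,
Pielou's evenness ``H/ln S``, Gini-Simpson ``1 - sum p^2`` and Good's
coverage ``1 - F1/N``.  The numerical kernels come from scikit-bio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skalpha
from skbio.stats import subsample_counts

from .otu import OtuTable, OtuTableError


def alpha_indices(table: OtuTable, ace_rare_cutoff: int = 10) -> pd.DataFrame:
    """All alpha indices, one row per sample.

    Columns: richness, chao1 (bias-corrected), chao1_classic, ace, shannon,
    pielou, simpson, goods_coverage.  Pielou is NaN (with a warning) for
    single-OTU samples, where evenness is undefined.
    """
    sums = table.sample_sums()
    if (sums == 0).any():
        raise OtuTableError(f"all-zero samples: {sums.index[sums == 0].tolist()}")
    rows = {}
    for sample, row in table.counts.iterrows():
        c = row.to_numpy()
        c = c[c > 0]
        s = int(c.size)
        pielou = np.nan
        if s > 1:
            pielou = float(_skalpha.pielou_e(c))
        else:
            warnings.warn(
                f"sample {sample!r} has a single OTU; Pielou evenness undefined",
                stacklevel=2,
            )
        rows[sample] = {
            "richness": s,
            "chao1": float(_skalpha.chao1(c, bias_corrected=True)),
            "chao1_classic": float(_skalpha.chao1(c, bias_corrected=False)),
            "ace": float(_skalpha.ace(c, rare_threshold=ace_rare_cutoff)),
            "shannon": float(_skalpha.shannon(c)),  # natural log
            "pielou": pielou,
            "simpson": float(_skalpha.simpson(c)),
            "goods_coverage": float(_skalpha.goods_coverage(c)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]


def goods_coverage(table: OtuTable) -> pd.Series:
    """Good's coverage 1 - F1/N per sample (F1 = singleton OTUs)."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise OtuTableError(f"all-zero samples: {sums.index[sums == 0].tolist()}")
    out = {
        s: float(_skalpha.goods_coverage(row.to_numpy()[row.to_numpy() > 0]))
        for s, row in table.counts.iterrows()
    }
    return pd.Series(out, name="goods_coverage").loc[table.sample_ids]


def rarefaction_curve(
    table: OtuTable,
    depths: list[int],
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    For each depth ``d`` the sample is rarefied ``repeats`` times without
    replacement and the mean OTU count of the draws is reported; rows are
    samples, columns the depths.  Depths above a sample's total raise.
    """
    depths = sorted(int(d) for d in depths)
    if depths and depths[0] < 1:
        raise ValueError("depths must be >= 1")
    sums = table.sample_sums()
    too_deep = sums.index[sums < max(depths, default=1)].tolist()
    if too_deep:
        raise OtuTableError(f"max depth exceeds totals of samples: {too_deep}")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(table.n_samples * len(depths) * repeats).tolist())
    out = pd.DataFrame(index=table.sample_ids, columns=depths, dtype=float)
    for sample, row in table.counts.iterrows():
        vec = row.to_numpy()
        for d in depths:
            rich = [
                int(np.count_nonzero(subsample_counts(vec, d, seed=next(seeds))))
                for _ in range(repeats)
            ]
            out.loc[sample, d] = float(np.mean(rich))
    return out


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form hypergeometric expectation of richness at a subsampling depth.

    E[S_d] = sum_i (1 - C(N - n_i, d)/C(N, d)).  Used as the analytic
    reference for :func:`rarefaction_curve`.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if depth > n:
        raise ValueError("depth exceeds sample total")
    # log-space ratio of binomial coefficients to avoid overflow
    from scipy.special import gammaln

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    absent = np.where(
        n - counts >= depth,
        np.exp(logc(n - counts, depth) - logc(n, depth)),
        0.0,
    )
    return float(np.sum(1.0 - absent))
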