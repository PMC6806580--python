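"""Sloan neutral community model: fit, bootstrap, and neutral partitioning.

The model treats each local community as a large assemblage whose composition
drifts neutrally while receiving immigrants from a common metacommunity.  At
stationarity the local relative abundance x_i of a taxon with metacommunity
relative abundance p_i follows

    x_i ~ Beta(Nm * p_i, Nm * (1 - p_i)),

where Nm (metacommunity size N times immigration probability m) controls how
tightly local communities track the metacommunity.  A taxon is detected in a
sample when its relative abundance exceeds the detection limit d (one read at
the sequencing depth, d = 1/N), so its expected occurrence frequency across
sites is

    freq(p_i) = 1 - BetaCDF(d; Nm p_i, Nm (1 - p_i)).

Fitting Nm to the observed (p_i, freq_i) cloud by least squares, and reading
off R^2 against the fitted curve, quantifies how much of the occupancy-
abundance relationship neutral dispersal alone explains.  Taxa whose observed
frequency escapes the 95% envelope around the prediction form the "above"
(dispersal-favoured) and "below" (dispersal-limited) partitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .otu import OtuTable, relative_abundance

logger = logging.getLogger(__name__)

_LOG10_NM_BOUNDS = (-2.0, 9.0)


class NcmFitError(RuntimeError):
    """Raised when the Nm optimisation cannot be completed."""


@dataclass
class NcmInput:
    """Observed occupancy-abundance data feeding the model.

    p: per-OTU mean relative abundance across local communities.
    freq: per-OTU detection frequency (fraction of samples with count > 0).
    N: reads per sample (all samples share this depth, i.e. rarefied).
    n_sites: number of local communities.
    """

    p: np.ndarray
    freq: np.ndarray
    N: int
    n_sites: int
    otu_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.p.shape != self.freq.shape:
            raise ValueError("p and freq must align")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValueError("p must lie in (0, 1]")
        if np.any((self.freq <= 0) | (self.freq > 1)):
            raise ValueError("freq must lie in (0, 1]; drop never-detected OTUs")
        if self.N <= 0 or self.n_sites <= 0:
            raise ValueError("N and n_sites must be positive")


@dataclass
class NcmFit:
    """Fitted model: Nm, m = Nm/N, R² and the per-OTU prediction envelope."""

    Nm: float
    N: int
    r2: float
    detection_limit: float
    predicted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    partition: np.ndarray  # labels in {"above", "neutral", "below"}
    envelope: str = "binomial"
    otu_ids: list[str] | None = None
    boot_Nm: np.ndarray | None = field(default=None, repr=False)
    boot_r2: np.ndarray | None = field(default=None, repr=False)

    @property
    def m(self) -> float:
        """Immigration rate, exactly Nm / N."""
        return self.Nm / self.N

    def partition_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.partition, return_counts=True)
        out = {"above": 0, "neutral": 0, "below": 0}
        out.update(dict(zip(labels.tolist(), counts.tolist())))
        return out

    def to_frame(self, input: NcmInput) -> pd.DataFrame:
        idx = self.otu_ids if self.otu_ids is not None else np.arange(len(self.predicted))
        return pd.DataFrame(
            {
                "p": input.p,
                "freq": input.freq,
                "predicted": self.predicted,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
                "partition": self.partition,
            },
            index=pd.Index(idx, name="otu_id"),
        )


def ncm_input_from_table(table: OtuTable, N: int | None = None) -> NcmInput:
    """Build model input from a (rarefied) count table.

    ``p`` is the mean relative abundance of each OTU over all samples,
    ``freq`` the fraction of samples in which it is detected; OTUs absent
    from every sample are excluded.  ``N`` defaults to the shared row sum.
    """
    sums = table.sample_sums().to_numpy()
    if N is None:
        if sums.size == 0 or not np.all(sums == sums[0]):
            raise ValueError("table is not at a uniform depth; rarefy first or pass N")
        N = int(sums[0])
    rel = relative_abundance(table).values.to_numpy()
    p = rel.mean(axis=0)
    freq = (table.counts.to_numpy() > 0).mean(axis=0)
    keep = freq > 0
    return NcmInput(
        p=p[keep],
        freq=freq[keep],
        N=N,
        n_sites=table.n_samples,
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
    )


def ncm_predicted_frequency(p, Nm: float, d: float):
    """Probability that local relative abundance exceeds the detection limit.

    1 - BetaCDF(d; Nm*p, Nm*(1-p)); limits p=0 -> 0, p=1 -> 1, d=0 -> 1.
    Vectorised over ``p``.
    """
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0 <= d < 1):
        raise ValueError("detection limit must lie in [0, 1)")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[p == 0] = 0.0
    out[p == 1] = 1.0
    if d == 0:
        out[interior] = 1.0
    else:
        pi = p[interior]
        out[interior] = stats.beta.sf(d, Nm * pi, Nm * (1.0 - pi))
    return float(out[0]) if scalar else out


def _sse(log10_nm: float, p: np.ndarray, freq: np.ndarray, d: float) -> float:
    pred = stats.beta.sf(d, 10.0 ** log10_nm * p, 10.0 ** log10_nm * (1.0 - p))
    return float(np.sum((freq - pred) ** 2))


def fit_ncm(
    input: NcmInput,
    d: float | None = None,
    envelope: str = "binomial",
    conf: float = 0.95,
) -> NcmFit:
    """Least-squares fit of Nm to the occupancy-abundance cloud.

    Nm is optimised in log10 space over [1e-2, 1e9]: a coarse grid locates
    the basin, then bounded scalar minimisation refines it.  R² is
    1 - SSE/SStot with SStot about the mean observed frequency.  The default
    detection limit is one read at the shared depth, d = 1/N.

    The 95% envelope around the fitted curve is, per OTU, the acceptance
    region of an observed frequency k/n (n = number of sites) given the
    predicted detection probability: the exact binomial quantile band by
    default (``envelope="binomial"``), which is calibrated as a prediction
    band, or the Wilson score interval centred on the prediction
    (``envelope="wilson"``), the convention of several published fits —
    note the latter is a confidence-interval shape and runs anticonservative
    when used as an acceptance region.  Taxa are partitioned into
    above/neutral/below against the chosen band.
    """
    if len(np.unique(input.p)) < 10:
        raise NcmFitError("need >= 10 OTUs with distinct p values")
    if d is None:
        d = 1.0 / input.N
    p, freq = input.p, input.freq

    grid = np.linspace(*_LOG10_NM_BOUNDS, 56)
    sse_grid = [_sse(g, p, freq, d) for g in grid]
    i0 = int(np.argmin(sse_grid))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _sse, bounds=(lo, hi), args=(p, freq, d), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise NcmFitError(f"Nm optimisation failed at log10 Nm = {res.x}: {res.message}")
    Nm = 10.0 ** float(res.x)

    pred = ncm_predicted_frequency(p, Nm, d)
    sse = float(np.sum((freq - pred) ** 2))
    sstot = float(np.sum((freq - freq.mean()) ** 2))
    if sstot == 0:
        warnings.warn("all observed frequencies equal; R² undefined", stacklevel=2)
        r2 = np.nan
    else:
        r2 = 1.0 - sse / sstot

    lower, upper = _prediction_envelope(pred, input.n_sites, envelope, conf)
    partition = _label_partition(freq, lower, upper)
    return NcmFit(
        Nm=Nm,
        N=input.N,
        r2=r2,
        detection_limit=d,
        predicted=pred,
        ci_lower=lower,
        ci_upper=upper,
        partition=partition,
        envelope=envelope,
        otu_ids=input.otu_ids,
    )


def _prediction_envelope(pred, n_sites, envelope, conf):
    alpha = 1 - conf
    if envelope == "binomial":
        lower = stats.binom.ppf(alpha / 2, n_sites, pred) / n_sites
        upper = stats.binom.ppf(1 - alpha / 2, n_sites, pred) / n_sites
        return np.clip(lower, 0, 1), np.clip(upper, 0, 1)
    if envelope == "wilson":
        lower, upper = proportion_confint(
            pred * n_sites, n_sites, alpha=alpha, method="wilson"
        )
        return np.clip(lower, 0, 1), np.clip(upper, 0, 1)
    raise ValueError(f"unknown envelope {envelope!r} (use fit + bootstrap_envelope)")


def _label_partition(freq, lower, upper):
    labels = np.full(freq.shape, "neutral", dtype=object)
    labels[freq > upper] = "above"
    labels[freq < lower] = "below"
    return labels


def partition_taxa(input: NcmInput, fit: NcmFit) -> np.ndarray:
    """Above/neutral/below labels against the fit's 95% envelope."""
    return _label_partition(input.freq, fit.ci_lower, fit.ci_upper)


def bootstrap_ci(
    input: NcmInput,
    fit: NcmFit,
    replicates: int = 1000,
    seed: int = 0,
    conf: float = 0.95,
    max_dropped_frac: float = 0.05,
) -> dict:
    """Percentile bootstrap over OTUs of the fitting statistics Nm and R².

    OTUs are resampled with replacement and the model refitted per replicate;
    non-converging replicates are dropped and counted, with an error if more
    than ``max_dropped_frac`` of them fail.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(input.p)
    nms, r2s = [], []
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        p_b, f_b = input.p[idx], input.freq[idx]
        if len(np.unique(p_b)) < 10:
            dropped += 1
            continue
        try:
            sub = NcmInput(p=p_b, freq=f_b, N=input.N, n_sites=input.n_sites)
            refit = fit_ncm(sub, d=fit.detection_limit, envelope=fit.envelope)
        except NcmFitError:
            dropped += 1
            continue
        nms.append(refit.Nm)
        r2s.append(refit.r2)
    if replicates and dropped / replicates > max_dropped_frac:
        raise NcmFitError(f"{dropped}/{replicates} bootstrap replicates failed")
    nms = np.asarray(nms)
    r2s = np.asarray(r2s)
    q = [100 * (1 - conf) / 2, 100 * (1 + conf) / 2]
    fit.boot_Nm = nms
    fit.boot_r2 = r2s
    return {
        "Nm": (float(np.percentile(nms, q[0])), float(np.percentile(nms, q[1]))),
        "r2": (float(np.percentile(r2s, q[0])), float(np.percentile(r2s, q[1]))),
        "replicates_used": int(len(nms)),
        "replicates_dropped": int(dropped),
    }


def bootstrap_envelope(
    input: NcmInput, fit: NcmFit, replicates: int = 1000, seed: int = 0,
    conf: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternative per-OTU envelope from the bootstrap spread of the curve.

    Refits Nm on OTU resamples and takes percentile bands of the predicted
    frequency at each observed p.  Emitted alongside the Wilson envelope so
    the partitioning rule is auditable.
    """
    rng = np.random.default_rng(seed)
    n = len(input.p)
    curves = []
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        try:
            sub = NcmInput(
                p=input.p[idx], freq=input.freq[idx], N=input.N, n_sites=input.n_sites
            )
            refit = fit_ncm(sub, d=fit.detection_limit)
        except (NcmFitError, ValueError):
            continue
        curves.append(ncm_predicted_frequency(input.p, refit.Nm, fit.detection_limit))
    arr = np.asarray(curves)
    q = [100 * (1 - conf) / 2, 100 * (1 + conf) / 2]
    return np.percentile(arr, q[0], axis=0), np.percentile(arr, q[1], axis=0)


def partition_migration_rates(
    table: OtuTable,
    partition: np.ndarray | pd.Series,
    N: int | None = None,
    min_otus: int = 10,
) -> pd.DataFrame:
    """Refit Nm (hence m = Nm/N) within each above/neutral/below partition.

    Partitions with fewer than ``min_otus`` OTUs are reported as missing
    with a warning rather than fitted.
    """
    inp = ncm_input_from_table(table, N=N)
    labels = pd.Series(np.asarray(partition, dtype=object), index=inp.otu_ids)
    rows = {}
    for part in ("above", "neutral", "below"):
        otus = labels.index[labels == part]
        mask = np.isin(inp.otu_ids, otus)
        row = {"n_otus": int(mask.sum()), "Nm": np.nan, "m": np.nan, "r2": np.nan}
        if mask.sum() >= min_otus and len(np.unique(inp.p[mask])) >= 10:
            sub = NcmInput(
                p=inp.p[mask], freq=inp.freq[mask], N=inp.N, n_sites=inp.n_sites
            )
            try:
                fit = fit_ncm(sub)
                row.update(Nm=fit.Nm, m=fit.m, r2=fit.r2)
            except NcmFitError as err:
                warnings.warn(f"partition {part!r} fit failed: {err}", stacklevel=2)
        else:
            warnings.warn(
                f"partition {part!r} has {mask.sum()} OTUs (< {min_otus}); skipped",
                stacklevel=2,
            )
        rows[part] = row
    return pd.DataFrame.from_dict(rows, orient="index")
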