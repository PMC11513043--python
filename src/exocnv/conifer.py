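"""SVD-residual CNV caller on RPKM-normalised coverage.

RPKM values are computed per enrichment kit, standardised per target, and the
leading singular components — which capture batch structure rather than rare
variants — are removed. Runs of consecutive targets whose residual
(SVD-ZRPKM) exceeds +1.75 are emitted as duplication calls, below −1.75 as
deletions; no copy number is estimated. A batch-level QC loop raises the
number of removed components or discards noisy samples until call counts
are plausible. X-chromosome calling runs in sex-specific pools; Y is not
called by this strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._genome import AUTOSOMES


@dataclass
class SvdConfig:
    """Thresholds of the SVD calling strategy."""

    n_components_removed: int = 3  # starting k; adapted within [3, 15]
    z_threshold: float = 1.75
    max_calls_per_sample: int = 30
    median_calls_limit: int = 10
    k_min: int = 3
    k_max: int = 15
    #: moving-average window (targets) applied to the residual before
    #: thresholding, as in the original SVD caller; dilutes 1-2-target
    #: signals (its characteristic blindness to short CNVs) while leaving
    #: multi-target events intact
    smoothing_window: int = 3

    def __post_init__(self):
        if not (self.k_min <= self.n_components_removed <= self.k_max):
            raise ValueError("n_components_removed must start within [3, 15]")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def compute_rpkm(counts: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Reads Per Kilobase of target per Million mapped reads:
    rpkm[t, s] = count * 1e9 / (target_length_bp * total_reads_of_sample)."""
    totals = counts.sum(axis=0).to_numpy(float)
    if (totals == 0).any():
        raise ValueError("sample with zero total reads")
    lengths = (targets["end"] - targets["start"]).to_numpy(float)
    rpkm = counts.to_numpy(float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def standardize_rpkm(rpkm: pd.DataFrame) -> pd.DataFrame:
    """Target-wise z-scores; invariant targets map to 0."""
    x = rpkm.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    return pd.DataFrame((x - mu) / sd, index=rpkm.index, columns=rpkm.columns)


def svd_zrpkm(rpkm: pd.DataFrame, k: int) -> pd.DataFrame:
    """Standardise RPKM per target and subtract the first k singular
    components. k=0 returns the standardised matrix unchanged."""
    z = standardize_rpkm(rpkm)
    if k == 0:
        return z
    x = z.to_numpy(float)
    if k >= min(x.shape):
        raise ValueError(f"k={k} out of range for matrix {x.shape}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention: largest-|loading| element of each
    # left singular vector is positive
    for i in range(len(s)):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]
    resid = x - (u[:, :k] * s[:k]) @ vt[:k, :]
    return pd.DataFrame(resid, index=rpkm.index, columns=rpkm.columns)


def singular_value_elbow(rpkm: pd.DataFrame, k_min: int = 3, k_max: int = 15) -> int:
    """Automated stand-in for scree-plot inspection: the elbow of the
    singular-value curve (max distance to its chord), clipped to [3, 15]."""
    z = standardize_rpkm(rpkm).to_numpy(float)
    s = np.linalg.svd(z, compute_uv=False)
    n = len(s)
    if n < 3:
        return k_min
    x = np.arange(n, dtype=float)
    x0, y0, x1, y1 = x[0], s[0], x[-1], s[-1]
    d = np.abs((y1 - y0) * x - (x1 - x0) * s + x1 * y0 - y1 * x0)
    elbow = int(np.argmax(d)) + 1
    return int(np.clip(elbow, k_min, min(k_max, min(z.shape) - 1)))


def smooth_zrpkm(z: pd.DataFrame, targets: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Moving average of the SVD residual over adjacent targets within a
    chromosome (the original tool smooths before thresholding)."""
    if window <= 1:
        return z
    out = z.copy()
    chrom = targets["chrom"].to_numpy()
    for ch in pd.unique(chrom):
        m = chrom == ch
        block = z.loc[m]
        out.loc[m] = block.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return out


def call_from_zrpkm(z: pd.DataFrame, targets: pd.DataFrame,
                    threshold: float = 1.75) -> pd.DataFrame:
    """Maximal runs of consecutive targets beyond +/-threshold become
    DUP/DEL calls; runs never span a chromosome boundary. Quality is the
    extremal |z| within the run; copy number is not estimated."""
    chrom = targets["chrom"].to_numpy()
    start = targets["start"].to_numpy()
    end = targets["end"].to_numpy()
    x = z.to_numpy(float)
    calls = []
    for si, sid in enumerate(z.columns):
        col = x[:, si]
        state = np.where(col > threshold, 1, np.where(col < -threshold, -1, 0))
        boundaries = np.r_[0, np.where((state[1:] != state[:-1])
                                       | (chrom[1:] != chrom[:-1]))[0] + 1, len(state)]
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if state[a] == 0:
                continue
            calls.append(dict(
                sample_id=sid, chrom=chrom[a], start=int(start[a]), end=int(end[b - 1]),
                copy_number=pd.NA, type="DUP" if state[a] > 0 else "DEL",
                caller="conifer", quality=float(np.max(np.abs(col[a:b]))),
                n_windows=b - a, n_targets=b - a,
            ))
    cols = ["sample_id", "chrom", "start", "end", "copy_number", "type",
            "caller", "quality", "n_windows", "n_targets"]
    return pd.DataFrame(calls, columns=cols)


def batch_qc_loop(rpkm: pd.DataFrame, targets: pd.DataFrame,
                  config: SvdConfig | None = None,
                  k_start: int | None = None) -> tuple[pd.DataFrame, list[str], int, str]:
    """Iterative batch QC.

    Run SVD calling; if every sample has <30 calls, accept. Otherwise, if
    the median calls per sample is <10, discard samples with >30 calls and
    accept the rest. Otherwise increase the number of removed components and
    rerun; a batch still unresolved at k=15 is returned with status
    'unresolved'. Returns (calls, discarded sample ids, final k, status).
    """
    config = config or SvdConfig()
    k = k_start if k_start is not None else config.n_components_removed
    k = int(np.clip(k, config.k_min, config.k_max))
    while True:
        z = svd_zrpkm(rpkm, min(k, min(rpkm.shape) - 1))
        z = smooth_zrpkm(z, targets, config.smoothing_window)
        calls = call_from_zrpkm(z, targets, config.z_threshold)
        per_sample = calls.groupby("sample_id").size().reindex(rpkm.columns, fill_value=0)
        if (per_sample < config.max_calls_per_sample).all():
            return calls, [], k, "ok"
        if per_sample.median() < config.median_calls_limit:
            bad = list(per_sample.index[per_sample > config.max_calls_per_sample])
            kept = calls[~calls["sample_id"].isin(bad)].reset_index(drop=True)
            return kept, bad, k, "ok"
        if k >= config.k_max:
            return calls, [], k, "unresolved"
        k += 1


class ConiferCaller(BaseEstimator):
    """SVD-residual caller with the batch QC loop, run per enrichment kit.

    Autosomes use the full batch; the X chromosome is called in sex-specific
    pools; Y targets are skipped.
    """

    def __init__(self, z_threshold: float = 1.75, k_start: int | None = None,
                 max_calls_per_sample: int = 30, median_calls_limit: int = 10,
                 min_rpkm_fraction: float = 0.2, smoothing_window: int = 3):
        self.z_threshold = z_threshold
        self.k_start = k_start
        self.max_calls_per_sample = max_calls_per_sample
        self.median_calls_limit = median_calls_limit
        self.smoothing_window = smoothing_window
        # targets with median RPKM below this fraction of the cohort-typical
        # RPKM carry mostly shot noise and are masked before SVD (the
        # standard practice for this caller family)
        self.min_rpkm_fraction = min_rpkm_fraction

    def _config(self) -> SvdConfig:
        return SvdConfig(z_threshold=self.z_threshold,
                         max_calls_per_sample=self.max_calls_per_sample,
                         median_calls_limit=self.median_calls_limit,
                         smoothing_window=self.smoothing_window)

    def fit(self, counts: pd.DataFrame, y=None, *, targets: pd.DataFrame,
            samples: pd.DataFrame):
        rpkm = compute_rpkm(counts, targets)
        med = rpkm.median(axis=1)
        ok = (med >= self.min_rpkm_fraction * med.median()).to_numpy()
        self.masked_targets_ = targets.index[~ok]
        self.rpkm_ = rpkm[ok]
        self.targets_ = targets[ok]
        self.samples_ = samples.reset_index(drop=True)
        return self

    def predict(self) -> pd.DataFrame:
        cfg = self._config()
        auto_mask = self.targets_["chrom"].isin(AUTOSOMES).to_numpy()
        pools: list[tuple[pd.DataFrame, pd.DataFrame]] = []
        pools.append((self.rpkm_[auto_mask], self.targets_[auto_mask]))
        x_mask = (self.targets_["chrom"] == "X").to_numpy()
        if x_mask.any():
            sex = self.samples_.set_index("sample_id")["sex"]
            for s in ("M", "F"):
                cols = [c for c in self.rpkm_.columns if sex.get(c) == s]
                if len(cols) >= 2:
                    pools.append((self.rpkm_.loc[x_mask, cols], self.targets_[x_mask]))
        all_calls = []
        self.discarded_ = []
        self.final_k_ = {}
        for i, (rpkm, targets) in enumerate(pools):
            if min(rpkm.shape) < cfg.k_min + 2:
                continue
            k0 = self.k_start if self.k_start is not None else \
                singular_value_elbow(rpkm, cfg.k_min, cfg.k_max)
            calls, discarded, k, status = batch_qc_loop(rpkm, targets, cfg, k0)
            all_calls.append(calls)
            self.discarded_.extend(discarded)
            self.final_k_[i] = (k, status)
        all_calls = [c for c in all_calls if len(c)]
        if not all_calls:
            return call_from_zrpkm(svd_zrpkm(self.rpkm_, 0)[:0], self.targets_[:0])
        return pd.concat(all_calls, ignore_index=True)

    def fit_predict(self, counts: pd.DataFrame, *, targets: pd.DataFrame,
                    samples: pd.DataFrame) -> pd.DataFrame:
        return self.fit(counts, targets=targets, samples=samples).predict()
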