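"""Likelihood-segmentation CNV caller on variance-stabilised coverage.

Pipeline: coverage-profile clustering (variance-quintile trimming, rolling
median smoothing, 2-D embedding, density clustering with minimum subgroup
size 15) -> cluster-median normalisation -> per-window Gaussian
log-likelihoods of copy-number states 0..6 in sqrt space -> iterative
maximum-subarray segmentation per chromosome (the contiguous segment with
the highest summed evidence for an alternative copy number is emitted,
masked, and the search repeated) -> call threshold at summed log-likelihood
ratio 20 -> robust-regression sample QC on per-chromosome call counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
import statsmodels.api as sm

from ._genome import ploidy

MIN_CLUSTER_SIZE = 15
ROLLING_WINDOW = 11
DEFAULT_MIN_LOGLIK = 20.0
CN_STATES = np.arange(0, 7)
#: CN=0 model mean in copy-number units; avoids a degenerate zero mean.
CN0_FLOOR = 0.05
SIGMA_FLOOR = 1e-3
#: De novo consistency band: parent mean normalised coverage within this
#: distance of baseline (sqrt space). A carrier parent of a CN=3 duplication
#: sits at sqrt(3/2)-1 ~= 0.22, so the band must stay below that.
DE_NOVO_BAND = 0.15
QC_PREDICTION_LEVEL = 0.995


# ---------------------------------------------------------------- clustering

def cluster_samples(matrix: pd.DataFrame, min_cluster_size: int = MIN_CLUSTER_SIZE,
                    random_state: int = 0, embedding_dim: int = 3) -> pd.DataFrame:
    """Assign every sample to a coverage-profile subgroup of >= 15 members.

    Windows in the top and bottom variance quintiles are dropped (polymorphic
    and dead regions distort profiles), profiles are smoothed with a rolling
    median, embedded in a low-dimensional space (deterministic PCA; k batch
    centroids span a rank k-1 subspace, so 3 components separate realistic
    batch counts where 2 can collide), and density-clustered with DBSCAN
    whose radius is set at the knee of the 15-NN distance curve. Noise
    samples are reassigned to the nearest cluster centroid; if no cluster of
    sufficient size emerges (or the cohort itself is smaller than the
    minimum), all samples form a single cluster.
    """
    ns = matrix.shape[1]
    sample_ids = list(matrix.columns)
    if ns < min_cluster_size:
        warnings.warn("cohort below minimum cluster size; using a single cluster")
        return pd.DataFrame({"sample_id": sample_ids, "cluster_id": 0, "is_noise": False})

    var = matrix.var(axis=1)
    lo, hi = var.quantile([0.2, 0.8])
    keep = (var > lo) & (var < hi)
    prof = matrix[keep.to_numpy()].to_numpy().T  # samples x windows
    prof = _rolling_median(prof, ROLLING_WINDOW)
    prof = (prof - prof.mean(axis=0)) / (prof.std(axis=0) + 1e-9)

    dim = min(embedding_dim, ns - 1, prof.shape[1])
    emb = PCA(n_components=dim, svd_solver="full", random_state=random_state).fit_transform(prof)
    k = min(min_cluster_size, ns - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    dist, _ = nn.kneighbors(emb)
    kdist = np.sort(dist[:, -1])
    eps = max(_knee(kdist), 1e-6)
    labels = DBSCAN(eps=eps, min_samples=min_cluster_size).fit_predict(emb)

    # drop clusters below the minimum size, then reassign noise to centroids
    sizes = pd.Series(labels[labels >= 0]).value_counts()
    for cl, sz in sizes.items():
        if sz < min_cluster_size:
            labels[labels == cl] = -1
    valid = sorted(set(labels[labels >= 0]))
    if not valid:
        return pd.DataFrame({"sample_id": sample_ids, "cluster_id": 0,
                             "is_noise": labels < 0})
    centroids = {cl: emb[labels == cl].mean(axis=0) for cl in valid}
    is_noise = labels < 0
    for i in np.where(is_noise)[0]:
        d = {cl: np.linalg.norm(emb[i] - c) for cl, c in centroids.items()}
        labels[i] = min(d, key=d.get)
    remap = {cl: j for j, cl in enumerate(valid)}
    return pd.DataFrame({"sample_id": sample_ids,
                         "cluster_id": [remap[v] for v in labels],
                         "is_noise": is_noise})


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    return pd.DataFrame(x.T).rolling(window, center=True, min_periods=1).median().to_numpy().T


def _knee(sorted_vals: np.ndarray) -> float:
    """Value at the point of maximum distance to the chord of the curve."""
    n = len(sorted_vals)
    if n < 3:
        return float(sorted_vals[-1])
    x = np.arange(n, dtype=float)
    y = sorted_vals.astype(float)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    return float(y[int(np.argmax(d))])


# ------------------------------------------------------------- normalisation

def normalize_by_cluster(matrix: pd.DataFrame, assignments: pd.DataFrame,
                         windows: pd.DataFrame | None = None,
                         samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Divide each window by its median within the sample's cluster.

    On gonosomal (non-pseudo-autosomal X, Y) windows the median is taken
    within the same-sex subgroup of the cluster so the normalised baseline
    is 1 for both sexes; requires `windows` and `samples` (sex column).
    """
    values = matrix.to_numpy(float).copy()
    col_ix = {c: i for i, c in enumerate(matrix.columns)}
    cl = assignments.set_index("sample_id")["cluster_id"]
    gono = np.zeros(len(matrix), bool)
    sex = None
    if windows is not None and samples is not None:
        from ._genome import PAR1_END
        gono = ((windows["chrom"] == "Y")
                | ((windows["chrom"] == "X") & (windows["start"] >= PAR1_END))).to_numpy()
        sex = samples.set_index("sample_id")["sex"]
    for _, cols in _groups(matrix.columns, cl):
        ci = [col_ix[c] for c in cols]
        block = matrix.iloc[:, ci].to_numpy()
        med = np.median(block, axis=1)
        med[med == 0] = np.nan
        if gono.any() and sex is not None:
            values[np.ix_(~gono, ci)] = block[~gono] / med[~gono, None]
            fallback = med[gono]
            for s in ("M", "F"):
                si = [col_ix[c] for c in cols if sex.get(c) == s]
                if not si:
                    continue
                if len(si) >= 5:
                    smed = np.median(matrix.iloc[:, si].to_numpy()[gono], axis=1)
                    smed[smed == 0] = np.nan
                else:
                    smed = fallback
                values[np.ix_(gono, si)] = matrix.iloc[:, si].to_numpy()[gono] / smed[:, None]
        else:
            values[:, ci] = block / med[:, None]
    return pd.DataFrame(np.nan_to_num(values), index=matrix.index, columns=matrix.columns)


def _groups(columns, cl: pd.Series):
    by = {}
    for c in columns:
        by.setdefault(int(cl.get(c, 0)), []).append(c)
    return sorted(by.items())


# ------------------------------------------------------------ log-likelihood

def state_means(baseline: np.ndarray, states: np.ndarray = CN_STATES) -> np.ndarray:
    """Expected normalised sqrt coverage per state: sqrt(max(c, floor)/ploidy)."""
    c = np.maximum(states.astype(float), CN0_FLOOR)
    return np.sqrt(c[None, :] / baseline[:, None].astype(float))


def robust_sigma(normalized: pd.DataFrame) -> np.ndarray:
    """Per-window standard deviation estimated robustly across the cohort.

    The larger of the scaled MAD and a normal-consistent 10%-trimmed
    standard deviation is used: both ignore the rare CNV carriers, and
    taking the maximum guards the likelihood against the light-tailed bias
    of either estimator on overdispersed counts. Floored to avoid
    degenerate likelihoods.
    """
    x = np.asarray(normalized)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1) * 1.4826
    n = x.shape[1]
    t = max(1, n // 10)
    xs = np.sort(x, axis=1)
    tstd = xs[:, t:n - t].std(axis=1) / 0.789 if n - 2 * t >= 2 else mad
    return np.maximum(np.maximum(mad, tstd), SIGMA_FLOOR)


def window_loglik(normalized: pd.DataFrame, baseline: np.ndarray,
                  sigma: np.ndarray | None = None,
                  states: np.ndarray = CN_STATES) -> np.ndarray:
    """Gaussian log-density of each sample's normalised coverage under each
    copy-number state. Returns array (windows, samples, states)."""
    if sigma is None:
        sigma = robust_sigma(normalized)
    means = state_means(baseline, states)  # windows x states
    x = normalized.to_numpy()
    ll = stats.norm.logpdf(x[:, :, None], loc=means[:, None, :], scale=sigma[:, None, None])
    return ll


# -------------------------------------------------------------- segmentation

def _max_subarray(scores: np.ndarray) -> tuple[float, int, int]:
    """Maximum-sum contiguous segment with deterministic tie-breaking:
    highest sum, then longest segment, then leftmost start.
    Returns (sum, i, j) half-open. Vectorised prefix-sum formulation:
    the best segment ending at j is cumsum[j] - min(cumsum[0..j-1])."""
    n = len(scores)
    cs = np.empty(n + 1)
    cs[0] = 0.0
    np.cumsum(scores, out=cs[1:])
    prefmin = np.minimum.accumulate(cs[:-1])
    vals = cs[1:] - prefmin
    m = vals.max()
    tol = 1e-9 * max(1.0, abs(m))
    ends = np.flatnonzero(vals >= m - tol)
    best = (-np.inf, 0, 0)
    for j in ends:
        # leftmost prefix achieving the minimum gives the longest segment
        i = int(np.flatnonzero(cs[: j + 1] <= prefmin[j] + tol)[0])
        cand = (float(cs[j + 1] - cs[i]), i, int(j) + 1)
        if _better(cand, best):
            best = cand
    return best


def _better(a: tuple[float, int, int], b: tuple[float, int, int]) -> bool:
    sa, ia, ja = a
    sb, ib, jb = b
    if not np.isclose(sa, sb):
        return sa > sb
    la, lb = ja - ia, jb - ib
    if la != lb:
        return la > lb
    return ia < ib


def max_subarray_brute_force(scores: np.ndarray) -> tuple[float, int, int]:
    """Exhaustive search over all contiguous segments; oracle for Kadane."""
    best = (-np.inf, 0, 0)
    n = len(scores)
    for i in range(n):
        s = 0.0
        for j in range(i + 1, n + 1):
            s += scores[j - 1]
            if _better((s, i, j), best):
                best = (s, i, j)
    return best


def segment_scores(loglik: np.ndarray, baseline_state: int,
                   states: np.ndarray = CN_STATES) -> np.ndarray:
    """Per-window per-state evidence against the baseline state."""
    base_ix = int(np.where(states == baseline_state)[0][0])
    return loglik - loglik[:, [base_ix]]


def segment_max_subarray(loglik: np.ndarray, baseline_state: int,
                         min_loglik: float = DEFAULT_MIN_LOGLIK,
                         states: np.ndarray = CN_STATES) -> list[tuple[int, int, int, float]]:
    """Iterative maximum-subarray segmentation over one chromosome.

    At each step the (state, segment) pair with the highest summed
    log-likelihood ratio over the baseline is found jointly across all
    alternative states; if the sum reaches the threshold a call
    (state, i, j, sum) is emitted, its windows are masked, and the search
    repeats. Ties break to the longer then leftmost segment, then the
    smaller state.
    """
    scores = segment_scores(loglik, baseline_state, states)
    nw = scores.shape[0]
    masked = np.zeros(nw, bool)
    calls = []
    alt = [s for s in range(len(states)) if states[s] != baseline_state]
    while True:
        best = (-np.inf, 0, 0)
        best_state = None
        for s in alt:
            col = np.where(masked, -np.inf, scores[:, s])
            # masked windows split the array; scan maximal unmasked runs
            cand = _max_subarray_masked(col)
            if cand is not None and _better(cand, best):
                best = cand
                best_state = s
        if best_state is None or best[0] < min_loglik:
            break
        total, i, j = best
        calls.append((int(states[best_state]), i, j, float(total)))
        masked[i:j] = True
    return calls


def _max_subarray_masked(scores: np.ndarray) -> tuple[float, int, int] | None:
    best = None
    n = len(scores)
    i = 0
    while i < n:
        if not np.isfinite(scores[i]):
            i += 1
            continue
        j = i
        while j < n and np.isfinite(scores[j]):
            j += 1
        s, a, b = _max_subarray(scores[i:j])
        cand = (s, a + i, b + i)
        if best is None or _better(cand, best):
            best = cand
        i = j
    return best


# -------------------------------------------------------------------- caller

class ClinCnvCaller(BaseEstimator):
    """Cohort CNV caller by per-window copy-number likelihoods and iterative
    maximum-subarray segmentation.

    fit() learns cluster assignments, cluster-normalised coverage and
    per-window noise from a variance-stabilised window matrix; predict()
    emits one call table for all samples.
    """

    def __init__(self, min_loglik: float = DEFAULT_MIN_LOGLIK,
                 min_cluster_size: int = MIN_CLUSTER_SIZE, random_state: int = 0):
        self.min_loglik = min_loglik
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def fit(self, matrix: pd.DataFrame, y=None, *, windows: pd.DataFrame,
            samples: pd.DataFrame):
        self.windows_ = windows
        self.samples_ = samples.reset_index(drop=True)
        self.clusters_ = cluster_samples(matrix, self.min_cluster_size, self.random_state)
        self.normalized_ = normalize_by_cluster(matrix, self.clusters_, windows, samples)
        self.sigma_ = robust_sigma(self.normalized_)
        self.sample_noise_ = sample_noise_factors(self.normalized_, self.sigma_)
        return self

    def predict(self, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
        windows = self.windows_
        norm = self.normalized_
        sigma = self.sigma_
        x = norm.to_numpy()
        nw, ns = x.shape
        chrom = windows["chrom"].to_numpy()
        wstart = windows["start"].to_numpy()
        wend = windows["end"].to_numpy()
        tid = windows["target_id"].to_numpy()
        sexes = self.samples_.set_index("sample_id")["sex"]
        male = np.array([sexes.get(c, "F") == "M" for c in norm.columns])
        from ._genome import PAR1_END
        x_hemi = (chrom == "X") & (wstart >= PAR1_END)
        on_y = chrom == "Y"
        base = np.full((nw, ns), 2, dtype=np.int8)
        if male.any():
            base[np.ix_(x_hemi | on_y, male)] = 1
        base[np.ix_(on_y, ~male)] = 0

        sigma_eff = sigma[:, None] * self.sample_noise_[None, :]
        ll = _gaussian_ll(x, sigma_eff, baseline=2)
        gono = x_hemi | on_y
        if gono.any() and male.any():
            ll[np.ix_(gono, male)] = _gaussian_ll(x[gono][:, male],
                                                  sigma_eff[gono][:, male], baseline=1)

        calls = []
        sample_ids = list(norm.columns)
        for ch in pd.unique(chrom):
            cm = np.flatnonzero(chrom == ch)
            for s in range(ns):
                bvals = base[cm, s]
                # segment separately per baseline ploidy block (splits X into
                # pseudo-autosomal and hemizygous parts); Y in females has no model
                for bstate in np.unique(bvals):
                    if bstate == 0:
                        continue
                    idx = cm[bvals == bstate]
                    segs = segment_max_subarray(ll[idx, s, :], int(bstate),
                                                self.min_loglik)
                    for cn, i, j, q in segs:
                        calls.append(dict(
                            sample_id=sample_ids[s], chrom=ch,
                            start=int(wstart[idx[i]]), end=int(wend[idx[j - 1]]),
                            copy_number=cn,
                            type="DEL" if cn < bstate else "DUP",
                            caller="clincnv", quality=q, n_windows=j - i,
                            n_targets=len(set(tid[idx[i]:idx[j - 1] + 1])),
                        ))
        cols = ["sample_id", "chrom", "start", "end", "copy_number", "type",
                "caller", "quality", "n_windows", "n_targets"]
        return pd.DataFrame(calls, columns=cols)

    def fit_predict(self, matrix: pd.DataFrame, *, windows: pd.DataFrame,
                    samples: pd.DataFrame) -> pd.DataFrame:
        return self.fit(matrix, windows=windows, samples=samples).predict()


# ---------------------------------------------------------------- sample QC

def sample_qc_regression(calls: pd.DataFrame, samples: pd.DataFrame,
                         level: float = QC_PREDICTION_LEVEL) -> pd.DataFrame:
    """Robust-regression sample QC.

    Response: 75th percentile across chromosomes of the per-chromosome CNV
    count (insensitive to one long fragmented CNV). Predictors: median read
    depth, enrichment kit, ancestry (one-hot; collinear columns dropped).
    Fails a sample iff its response lies outside the central `level`
    prediction interval of a Huber-weighted IRLS fit.
    """
    chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
    per = calls.groupby(["sample_id", "chrom"]).size().unstack(fill_value=0)
    per = per.reindex(index=samples["sample_id"], columns=chroms, fill_value=0).fillna(0)
    response = per.quantile(0.75, axis=1).to_numpy(float)

    depth = samples["library_size"].to_numpy(float) if "library_size" in samples \
        else np.ones(len(samples))
    X = [np.ones(len(samples)), depth]
    names = ["const", "depth"]
    for col in ("kit_id", "ancestry_label"):
        if col in samples:
            dummies = pd.get_dummies(samples[col], drop_first=True)
            for c in dummies:
                X.append(dummies[c].to_numpy(float))
                names.append(f"{col}={c}")
    X = np.column_stack(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("singular design; dropping collinear predictors")
        _, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10
        X = X[:, keep]
    fit = sm.RLM(response, X, M=sm.robust.norms.HuberT()).fit()
    pred = fit.predict(X)
    scale = max(fit.scale, 1e-9)
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = pred - z * scale, pred + z * scale
    ok = (response >= lo) & (response <= hi)
    return pd.DataFrame({
        "sample_id": samples["sample_id"],
        "response": response,
        "predicted_low": lo,
        "predicted_high": hi,
        "pass": ok,
    })


# ------------------------------------------------------------------ de novo

def annotate_de_novo(calls: pd.DataFrame, samples: pd.DataFrame,
                     normalized: pd.DataFrame, windows: pd.DataFrame,
                     band: float = DE_NOVO_BAND) -> pd.DataFrame:
    """Flag calls in trio children as de novo when both parents' mean
    normalised coverage over the call interval is within `band` of their
    baseline (sqrt space). Missing parents give 'unknown'."""
    parents = {}
    for fam, group in samples.groupby("family_id"):
        pro = group[group["relationship"] == "proband"]["sample_id"]
        mo = group[group["relationship"] == "mother"]["sample_id"]
        fa = group[group["relationship"] == "father"]["sample_id"]
        for p in pro:
            parents[p] = (mo.iloc[0] if len(mo) else None,
                          fa.iloc[0] if len(fa) else None)
    sex = samples.set_index("sample_id")["sex"]
    chrom = windows["chrom"].to_numpy()
    wstart = windows["start"].to_numpy()
    out = []
    for _, call in calls.iterrows():
        mo, fa = parents.get(call["sample_id"], (None, None))
        if mo is None or fa is None:
            out.append("unknown")
            continue
        m = ((chrom == call["chrom"]) & (wstart >= call["start"])
             & (wstart < call["end"]))
        status = "de_novo"
        for par in (mo, fa):
            if par not in normalized.columns:
                status = "unknown"
                break
            base = np.array([ploidy(call["chrom"], s, sex[par])
                             for s in wstart[m]], float)
            if (base == 0).all():
                continue
            expect = 1.0  # normalised baseline
            obs = normalized[par].to_numpy()[m][base > 0].mean()
            if abs(obs - expect) > band:
                status = "inherited"
                break
        out.append(status)
    calls = calls.copy()
    calls["de_novo"] = out
    return calls


def sample_noise_factors(normalized: pd.DataFrame, sigma: np.ndarray) -> np.ndarray:
    """Per-sample noise level relative to the cohort: the scaled MAD of each
    sample's standardised residuals from the window medians. Deeper, cleaner
    libraries get factors below 1, noisy ones above."""
    x = normalized.to_numpy()
    med = np.median(x, axis=1, keepdims=True)
    z = (x - med) / sigma[:, None]
    f = np.median(np.abs(z), axis=0) * 1.4826
    return np.clip(f, 0.5, 2.0)


def _gaussian_ll(x: np.ndarray, sigma: np.ndarray, baseline: int) -> np.ndarray:
    """Gaussian log-density of every sample/window value under each state
    mean sqrt(max(c, floor)/baseline); sigma may be per-window (1-D) or
    per-window-per-sample (2-D). Returns (windows, samples, states)."""
    c_eff = np.maximum(CN_STATES.astype(float), CN0_FLOOR)
    means = np.sqrt(c_eff / baseline)
    sigma = np.asarray(sigma, float)
    if sigma.ndim == 1:
        sigma = np.broadcast_to(sigma[:, None], x.shape)
    const = np.log(sigma) + 0.5 * np.log(2.0 * np.pi)
    z = (x[:, :, None] - means[None, None, :]) / sigma[:, :, None]
    return -0.5 * z * z - const[:, :, None]
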